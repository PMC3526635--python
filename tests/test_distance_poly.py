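import cmath
import math

import numpy as np
import pytest

from fftbor import (
    DistanceBookkeeping,
    NussinovModel,
    RnaSequence,
    SecondaryStructure,
    StructureError,
    TurnerModel,
    bp_distance,
    empty_structure,
    enumerate_structures,
    evaluate_at,
    evaluate_on_roots,
    parse_dot_bracket,
    random_rna,
)
from fftbor.distance_poly import pair_distance_increment, unpaired_increment
from fftbor.oracle import mccaskill_partition
from fftbor.synth_utils import GeneratorConfig, random_structure


def brute_polynomial(seq, Sstar, model, x):
    """Direct Boltzmann sum over the enumerated ensemble."""
    total = 0j
    for S in enumerate_structures(seq).structures:
        total += math.exp(-model.energy(seq, S) / model.RT) * x ** bp_distance(
            S, Sstar
        )
    return total


class TestIncrements:
    def test_reference_pair_costs_nothing(self):
        book = DistanceBookkeeping(parse_dot_bracket("..(....).."))
        assert pair_distance_increment(book, 1, 3, 8) == 0

    def test_novel_pair_costs_one(self):
        book = DistanceBookkeeping(empty_structure(10))
        assert pair_distance_increment(book, 1, 3, 8) == 1

    def test_nested_reference_pair_survives(self):
        # reference (4,8) sits strictly inside the introduced pair (3,9):
        # it stays representable, so only the novel pair is charged
        book = DistanceBookkeeping(SecondaryStructure({(4, 8)}, 10))
        assert pair_distance_increment(book, 1, 3, 9) == 1

    def test_index_errors(self):
        book = DistanceBookkeeping(empty_structure(10))
        with pytest.raises(StructureError):
            pair_distance_increment(book, 3, 2, 8)
        with pytest.raises(StructureError):
            unpaired_increment(book, 5, 11)

    @pytest.mark.parametrize(
        "ref,i,j,expect",
        [(".(......).", 1, 9, 1), (".(......).", 3, 9, 0), ("..........", 1, 10, 0)],
    )
    def test_unpaired_increment(self, ref, i, j, expect):
        book = DistanceBookkeeping(parse_dot_bracket(ref))
        assert unpaired_increment(book, i, j) == expect

    def test_increment_matches_symmetric_difference(self):
        # b(l,j) must equal the distance gained when {(l,j)} joins empty
        # flanks, measured directly on restrictions of the reference
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = 14
            seq = random_rna(GeneratorConfig(seed=int(rng.integers(1 << 30)), length=n))
            Sstar = random_structure(seq, seed=int(rng.integers(1 << 30)))
            book = DistanceBookkeeping(Sstar)
            for _ in range(10):
                i = int(rng.integers(1, n - 4))
                j = int(rng.integers(i + 4, n + 1))
                l = int(rng.integers(i, j - 3))
                if j - l <= Sstar.theta:
                    continue
                got = pair_distance_increment(book, i, l, j)
                ref_ij = {p for p in Sstar.pairs if i <= p[0] < p[1] <= j}
                inner = {p for p in ref_ij if i <= p[0] < p[1] <= l - 1} | {
                    p for p in ref_ij if l + 1 <= p[0] < p[1] <= j - 1
                }
                # novel-pair cost + reference pairs straddling the split
                expect = len({(l, j)} - ref_ij) + len(ref_ij - inner - {(l, j)})
                assert got == expect


class TestEvaluateAt:
    def test_no_pair_sequence_is_one(self, micro_model):
        seq = RnaSequence("AAAAA")
        for x in (1.0, -1.0, 0.3 + 0.7j):
            assert evaluate_at(seq, empty_structure(5), x, micro_model) == 1.0

    def test_two_structure_hand_case(self, micro_model):
        seq = RnaSequence("GAAAC")
        S0 = empty_structure(5)
        assert evaluate_at(seq, S0, 1.0, micro_model) == pytest.approx(1 + math.e)
        assert evaluate_at(seq, S0, -1.0, micro_model) == pytest.approx(1 - math.e)

    def test_incompatible_reference_rejected_unless_relaxed(self, micro_model):
        seq = RnaSequence("AAAAA")
        Sstar = SecondaryStructure({(1, 5)}, 5)
        with pytest.raises(StructureError):
            evaluate_at(seq, Sstar, 1.0, micro_model)
        val = evaluate_at(seq, Sstar, 1.0, micro_model, validate=False)
        assert val == pytest.approx(1.0)  # only the empty structure; d=1 absorbed

    @pytest.mark.parametrize("model_name", ["nussinov", "turner"])
    def test_matches_brute_force_on_unit_circle(self, model_name):
        model = NussinovModel() if model_name == "nussinov" else TurnerModel()
        rng = np.random.default_rng(2024)
        for _ in range(6):
            n = int(rng.integers(8, 17))
            seq = random_rna(GeneratorConfig(seed=int(rng.integers(1 << 30)), length=n))
            Sstar = random_structure(seq, seed=int(rng.integers(1 << 30)))
            for _ in range(10):
                x = cmath.exp(2j * math.pi * rng.random())
                got = evaluate_at(seq, Sstar, x, model)
                ref = brute_polynomial(seq, Sstar, model, x)
                tol = 1e-10 if model_name == "nussinov" else 1e-8
                assert abs(got - ref) <= tol * abs(ref)

    @pytest.mark.parametrize("model", [NussinovModel(), TurnerModel()])
    def test_at_one_equals_independent_partition_function(self, model):
        rng = np.random.default_rng(9)
        for _ in range(8):
            n = int(rng.integers(10, 36))
            seq = random_rna(GeneratorConfig(seed=int(rng.integers(1 << 30)), length=n))
            z = evaluate_at(seq, empty_structure(n), 1.0, model).real
            zi = mccaskill_partition(seq, model)
            assert abs(z - zi) <= 1e-10 * zi


class TestEvaluateOnRoots:
    def test_gaaac_fourth_roots(self, micro_model):
        ev = evaluate_on_roots(
            RnaSequence("GAAAC"), empty_structure(5), micro_model, m=4
        )
        e = math.e
        expect = [1 + e, 1 + e * 1j, 1 - e, 1 - e * 1j]
        assert np.allclose(ev.values, expect, atol=1e-12)
        assert ev.Z == pytest.approx(1 + e)

    def test_conjugate_symmetry(self):
        seq = random_rna(GeneratorConfig(seed=77, length=20))
        Sstar = random_structure(seq, seed=78)
        ev = evaluate_on_roots(seq, Sstar, NussinovModel(), full=True)
        for j in range(1, ev.m):
            assert abs(ev.values[ev.m - j] - np.conj(ev.values[j])) <= 1e-8 * ev.Z
        assert ev.values[0].imag == 0.0 and ev.Z > 0

    def test_m_below_bound_is_rejected(self, micro_model):
        with pytest.raises(ValueError):
            evaluate_on_roots(
                RnaSequence("GAAAC"), parse_dot_bracket("(...)"), micro_model, m=2
            )

    def test_parallel_map_is_bit_identical(self):
        seq = random_rna(GeneratorConfig(seed=5, length=18))
        Sstar = random_structure(seq, seed=6)
        serial = evaluate_on_roots(seq, Sstar, NussinovModel())
        parallel = evaluate_on_roots(seq, Sstar, NussinovModel(), workers=2)
        assert np.array_equal(serial.values, parallel.values)
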