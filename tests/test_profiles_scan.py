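import math

import numpy as np
import pytest

from fftbor import (
    GeneratorConfig,
    NussinovModel,
    RnaSequence,
    StructuralProfile,
    StructureError,
    TurnerModel,
    bp_distance,
    embed_hairpin,
    empty_structure,
    enumerate_structures,
    expected_distance_to,
    mfe_structure,
    parse_dot_bracket,
    prefix_scan,
    profile_stats,
    random_rna,
    window_scan,
)
from fftbor.profiles_scan import nussinov_mfe, turner_mfe


def _profile(p):
    return StructuralProfile(probabilities=np.asarray(p, float), digits=6)


class TestProfileStats:
    def test_symmetric_three_point(self):
        stats = profile_stats(_profile([0.25, 0.5, 0.25]))
        assert stats.mean == pytest.approx(1.0)
        assert stats.sd == pytest.approx(math.sqrt(0.5))
        assert stats.cv == pytest.approx(math.sqrt(0.5))

    def test_point_mass_has_undefined_cv(self):
        stats = profile_stats(_profile([1.0]))
        assert stats.mean == 0.0 and stats.sd == 0.0 and stats.cv is None

    def test_bernoulli_mean(self, micro_model):
        e = math.e
        stats = profile_stats(_profile([1 / (1 + e), e / (1 + e)]))
        assert stats.mean == pytest.approx(e / (1 + e))


class TestExpectedDistance:
    def test_sole_structure_target(self, micro_model):
        seq = RnaSequence("AAAAA")
        assert expected_distance_to(seq, empty_structure(5), micro_model) == \
            pytest.approx(0.0, abs=1e-12)

    def test_gaaac(self, micro_model):
        e = math.e
        got = expected_distance_to(
            RnaSequence("GAAAC"), empty_structure(5), micro_model
        )
        assert got == pytest.approx(e / (1 + e), abs=1e-12)

    def test_empty_reference_mean_is_expected_pair_count(self):
        # with the empty reference the profile is the distribution of the
        # number of pairs per structure, so its mean must equal the
        # ensemble average pair count from enumeration
        model = NussinovModel()
        rng = np.random.default_rng(21)
        for _ in range(5):
            n = int(rng.integers(10, 21))
            seq = random_rna(GeneratorConfig(seed=int(rng.integers(1 << 30)), length=n))
            mu = expected_distance_to(seq, empty_structure(n), model)
            enum = enumerate_structures(seq)
            w = np.array(
                [math.exp(-model.energy(seq, S) / model.RT) for S in enum.structures]
            )
            k = np.array([len(S.pairs) for S in enum.structures])
            expect = float((w * k).sum() / w.sum())
            assert mu == pytest.approx(expect, rel=1e-8)


class TestWindowScan:
    def test_offset_count_formula(self, micro_model):
        seq = random_rna(GeneratorConfig(seed=1, length=10))
        target = parse_dot_bracket("(...)")
        track = window_scan(seq, target, model=micro_model)
        assert track.offsets == tuple(range(1, 7))

    def test_unpairable_sequence_gives_flat_track(self, micro_model):
        seq = RnaSequence("A" * 12)
        target = parse_dot_bracket("((...))")
        track = window_scan(seq, target, model=micro_model)
        assert all(v == pytest.approx(2.0, abs=1e-9) for v in track.values)

    def test_self_window_is_zero_when_sole_structure(self, micro_model):
        # sequence equal to its own target window, whose only compatible
        # structure is the target itself
        track = window_scan(
            RnaSequence("AAAAA"), parse_dot_bracket("....."), model=micro_model
        )
        assert track.offsets == (1,)
        assert track.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_embedded_hairpin_is_localized(self):
        seq, target = embed_hairpin(
            GeneratorConfig(seed=424242, length=80), stem=5, loop=4, offset=33
        )
        track = window_scan(seq, target, model=TurnerModel())
        assert track.minimum_offset() == 33

    def test_target_longer_than_sequence(self, micro_model):
        with pytest.raises(StructureError):
            window_scan(
                RnaSequence("GAAAC"), parse_dot_bracket("(....(...)....)"),
                model=micro_model,
            )


class TestPrefixScan:
    def test_single_prefix(self, micro_model):
        seq = random_rna(GeneratorConfig(seed=2, length=12))
        profiles = prefix_scan(seq, 12, 12, micro_model, ref="empty")
        assert len(profiles) == 1

    def test_profiles_are_distributions(self):
        seq = random_rna(GeneratorConfig(seed=3, length=16))
        for prof in prefix_scan(seq, 8, 16, NussinovModel(), ref="mfe"):
            assert prof.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
            assert prof.probabilities[0] > 0  # reference is reachable (d = 0)

    def test_invalid_range(self, micro_model):
        seq = random_rna(GeneratorConfig(seed=4, length=10))
        with pytest.raises(StructureError):
            prefix_scan(seq, 8, 20, micro_model)


class TestMfe:
    def test_nussinov_max_pairs_matches_enumeration(self):
        rng = np.random.default_rng(31)
        for _ in range(8):
            n = int(rng.integers(8, 17))
            seq = random_rna(GeneratorConfig(seed=int(rng.integers(1 << 30)), length=n))
            best = max(len(S.pairs) for S in enumerate_structures(seq).structures)
            assert len(nussinov_mfe(seq).pairs) == best

    def test_nussinov_tie_break_is_deterministic(self):
        # G1 can close with C5 or C9; the traceback resolves the tie the
        # same way on every run
        seq = RnaSequence("GAAACAAAC")
        S = nussinov_mfe(seq)
        assert S.pairs == nussinov_mfe(seq).pairs
        assert len(S.pairs) == 1 and min(p[0] for p in S.pairs) == 1

    def test_turner_mfe_matches_enumeration_minimum(self):
        model = TurnerModel()
        rng = np.random.default_rng(32)
        for _ in range(8):
            n = int(rng.integers(8, 17))
            seq = random_rna(GeneratorConfig(seed=int(rng.integers(1 << 30)), length=n))
            energies = [
                model.energy(seq, S)
                for S in enumerate_structures(seq).structures
            ]
            S = turner_mfe(seq, model)
            assert model.energy(seq, S) == pytest.approx(min(energies), abs=1e-9)

    def test_dispatch(self):
        seq = random_rna(GeneratorConfig(seed=33, length=14))
        assert mfe_structure(seq, NussinovModel()).pairs == nussinov_mfe(seq).pairs
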