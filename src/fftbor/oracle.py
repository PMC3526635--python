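"""Desk-scale ground truth: exhaustive enumeration and the integer-k DP.

Three independent routes to the distance distribution exist in this
package:

1. exhaustive enumeration of every secondary structure (this module),
   feasible up to roughly 30 nt;
2. the classical integer-indexed recursion that convolves restricted
   partition functions ``Z_k(i, j)`` over split points (this module,
   per-pair energy model);
3. the roots-of-unity evaluation plus inverse DFT
   (:mod:`fftbor.distance_poly` / :mod:`fftbor.fft_recover`).

Their pairwise agreement on random instances is the package's central
correctness argument.  A McCaskill-style partition function with no
distance bookkeeping is also provided as an independent check of the
polynomial evaluated at ``x = 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .energy import MAX_INTERIOR_LOOP, NussinovModel, TurnerModel
from .rna_core import (
    DEFAULT_RULE,
    BasePairRule,
    RnaSequence,
    SecondaryStructure,
    StructureError,
    bp_distance,
    max_distance_bound,
)

__all__ = [
    "EnsembleEnumeration",
    "enumerate_structures",
    "count_structures",
    "exact_profile",
    "exact_distribution",
    "rnabor_integer_dp",
    "mccaskill_partition",
    "total_variation",
]

ENUMERATION_CAP = 30


@dataclass(frozen=True)
class EnsembleEnumeration:
    sequence: RnaSequence
    theta: int
    structures: tuple


def enumerate_structures(
    seq: RnaSequence,
    theta: int = 3,
    rule: BasePairRule = DEFAULT_RULE,
    cap: int = ENUMERATION_CAP,
) -> EnsembleEnumeration:
    """All secondary structures of ``seq``, duplicate-free.

    Interval recursion: the last position of ``[i, j]`` is either
    unpaired or paired to some admissible ``l`` — the same case split as
    the counting recursion, so no structure is produced twice.
    """
    n = len(seq)
    if n > cap:
        raise StructureError(
            f"n={n} exceeds the enumeration cap {cap}; use the DP instead"
        )
    res = seq.residues

    def rec(i: int, j: int) -> list[frozenset]:
        if j - i < theta + 1:
            return [frozenset()]
        out = []
        for left in rec(i, j - 1):
            out.append(left)
        for l in range(i, j - theta):
            if rule.admits(res[l - 1], res[j - 1]):
                for a in rec(i, l - 1):
                    for b in rec(l + 1, j - 1):
                        out.append(a | b | {(l, j)})
        return out

    structs = tuple(
        SecondaryStructure(p, n, theta) for p in rec(1, n)
    )
    return EnsembleEnumeration(seq, theta, structs)


def count_structures(
    seq: RnaSequence, theta: int = 3, rule: BasePairRule = DEFAULT_RULE
) -> int:
    """Structure count by the standard recursion
    ``N(i,j) = N(i,j-1) + sum_l N(i,l-1) * N(l+1,j-1)``."""
    n = len(seq)
    res = seq.residues
    N = [[1] * (n + 2) for _ in range(n + 2)]
    for s in range(theta + 1, n):
        for i in range(1, n - s + 1):
            j = i + s
            total = N[i][j - 1]
            for l in range(i, j - theta):
                if rule.admits(res[l - 1], res[j - 1]):
                    total += N[i][l - 1] * N[l + 1][j - 1]
            N[i][j] = total
    return N[1][n]


def exact_distribution(
    seq: RnaSequence, Sstar: SecondaryStructure, model=None
) -> np.ndarray:
    """Exact ``p(k)`` by full enumeration (vector indexed 0..bound)."""
    model = model if model is not None else NussinovModel()
    enum = enumerate_structures(seq, theta=Sstar.theta, rule=model.rule)
    bound = max_distance_bound(Sstar)
    Zk = np.zeros(bound + 1)
    for S in enum.structures:
        k = bp_distance(S, Sstar)
        Zk[k] += math.exp(-model.energy(seq, S) / model.RT)
    return Zk / Zk.sum()


def exact_profile(seq: RnaSequence, Sstar: SecondaryStructure, model=None):
    """Exact profile as a :class:`~fftbor.fft_recover.StructuralProfile`."""
    from .fft_recover import StructuralProfile

    model = model if model is not None else NussinovModel()
    p = exact_distribution(seq, Sstar, model)
    meta = {
        "sequence": seq.id,
        "reference": Sstar.to_dot_bracket(),
        "model": model.name,
        "method": "enumeration",
    }
    return StructuralProfile(probabilities=p, digits=12, metadata=meta)


def rnabor_integer_dp(
    seq: RnaSequence, Sstar: SecondaryStructure, model=None
) -> np.ndarray:
    """Restricted partition functions ``Z_k`` by the integer-k recursion.

    Per-pair energy model only.  Each interval carries the coefficient
    vector of its distance polynomial; introducing pair ``(l, j)``
    convolves the flanking vectors and shifts by the distance increment
    — exact polynomial arithmetic, no complex evaluation involved.
    """
    model = model if model is not None else NussinovModel()
    if not isinstance(model, NussinovModel):
        raise StructureError(
            "the integer-k recursion is stated for the per-pair model; "
            "cross-check the Turner model through enumeration"
        )
    from .distance_poly import DistanceBookkeeping

    n = len(seq)
    theta = Sstar.theta
    res = seq.residues
    book = DistanceBookkeeping(Sstar)
    P, star = book.P, book.star
    bound = max_distance_bound(Sstar)
    w = math.exp(-model.epsilon / model.RT)

    one = np.zeros(bound + 1)
    one[0] = 1.0
    Z = [[one.copy() for _ in range(n + 2)] for _ in range(n + 2)]

    def shifted(vec: np.ndarray, by: int) -> np.ndarray:
        out = np.zeros(bound + 1)
        if by <= bound:
            out[by:] = vec[: bound + 1 - by]
        return out

    for s in range(theta + 1, n):
        for i in range(1, n - s + 1):
            j = i + s
            acc = shifted(Z[i][j - 1], int(P[i, j] - P[i, j - 1]))
            for l in range(i, j - theta):
                if not model.rule.admits(res[l - 1], res[j - 1]):
                    continue
                b = int(
                    P[i, j] - P[i, l - 1] - P[l + 1, j - 1]
                    + 1 - 2 * int(star[l, j])
                )
                conv = np.convolve(Z[i][l - 1], Z[l + 1][j - 1])[: bound + 1]
                acc = acc + w * shifted(conv, b)
            Z[i][j] = acc
    return Z[1][n]


# -- independent partition function (no distance bookkeeping) ---------------


def mccaskill_partition(seq: RnaSequence, model=None, theta: int = 3) -> float:
    """Plain partition function by an independent scalar dynamic program.

    Deliberately written without the distance bookkeeping or the
    vectorized diagonals of :mod:`fftbor.distance_poly`, so it serves as
    a cross-check of the polynomial evaluated at ``x = 1``.
    """
    model = model if model is not None else NussinovModel()
    if isinstance(model, TurnerModel):
        return _mccaskill_turner(seq, model, theta)
    return _mccaskill_nussinov(seq, model, theta)


def _mccaskill_nussinov(seq: RnaSequence, model: NussinovModel, theta: int) -> float:
    n = len(seq)
    res = seq.residues
    w = math.exp(-model.epsilon / model.RT)
    Z = [[1.0] * (n + 2) for _ in range(n + 2)]
    for s in range(theta + 1, n):
        for i in range(1, n - s + 1):
            j = i + s
            total = Z[i][j - 1]
            for l in range(i, j - theta):
                if model.rule.admits(res[l - 1], res[j - 1]):
                    total += w * Z[i][l - 1] * Z[l + 1][j - 1]
            Z[i][j] = total
    return Z[1][n]


def _mccaskill_turner(seq: RnaSequence, model: TurnerModel, theta: int) -> float:
    n = len(seq)
    res = seq.residues
    params = model.params
    RT = model.RT
    expa = math.exp(-params.scalars["ml_a"] / RT)
    expb = math.exp(-params.scalars["ml_b"] / RT)
    expc = math.exp(-params.scalars["ml_c"] / RT)

    def pairable(i: int, j: int) -> bool:
        return j - i > theta and model.rule.admits(res[i - 1], res[j - 1])

    def wsym(i: int, j: int) -> str:
        return res[i - 1] + res[j - 1]

    ZB = [[0.0] * (n + 2) for _ in range(n + 2)]
    ZM = [[0.0] * (n + 2) for _ in range(n + 2)]
    ZM1 = [[0.0] * (n + 2) for _ in range(n + 2)]
    for s in range(theta + 1, n):
        for i in range(1, n - s + 1):
            j = i + s
            if pairable(i, j):
                e = params.hairpin(j - i - 1)
                if wsym(i, j) not in ("CG", "GC"):
                    e += params.scalars["terminal_au_hairpin"]
                acc = math.exp(-e / RT)
                for k in range(i + 1, j - theta - 1):
                    for l in range(k + theta + 1, j):
                        if not ZB[k][l]:
                            continue
                        n1, n2 = k - i - 1, j - l - 1
                        if n1 + n2 == 0:
                            eil = params.stack[(wsym(i, j), wsym(k, l))]
                        elif n1 + n2 > MAX_INTERIOR_LOOP:
                            continue
                        elif 0 in (n1, n2):
                            eil = params.bulge(n1 + n2)
                        else:
                            eil = params.internal(n1, n2)
                        acc += math.exp(-eil / RT) * ZB[k][l]
                for l in range(i + 2, j - 1):
                    acc += expa * ZM[i + 1][l - 1] * ZM1[l][j - 1]
                ZB[i][j] = acc
            zm1 = 0.0
            for h in range(i + theta + 1, j + 1):
                zm1 += ZB[i][h] * expb * expc ** (j - h)
            ZM1[i][j] = zm1
            zm = expc * ZM[i][j - 1]
            for l in range(i, j - theta):
                zm += expb * ZB[l][j] * (expc ** (l - i) + ZM[i][l - 1])
            ZM[i][j] = zm
    E = [1.0] * (n + 1)
    for j in range(1, n + 1):
        E[j] = E[j - 1]
        for l in range(1, j - theta):
            E[j] += E[l - 1] * ZB[l][j]
    return E[n]


def total_variation(p, q) -> float:
    """Total variation distance between two distance distributions.

    Vectors are zero-padded to a common length.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    m = max(len(p), len(q))
    pp = np.zeros(m)
    qq = np.zeros(m)
    pp[: len(p)] = p
    qq[: len(q)] = q
    return 0.5 * float(np.abs(pp - qq).sum())
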