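"""Profile statistics and moving-window / prefix-scan applications.

The mean of a distance profile is the expected base-pair distance

    <d> = sum_k k * p(k)

to the reference structure — a one-number summary of how concentrated
the Boltzmann ensemble is around it.  Scanning a genomic region with a
moving window and a fixed target structure localizes windows whose
ensemble sits close to the target (e.g. riboswitch aptamers or
expression platforms); running the pipeline on all prefixes of a
sequence, each against its own MFE structure, exposes emerging bimodal
(two-state) behaviour as the sequence elongates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .energy import MAX_INTERIOR_LOOP, NussinovModel, TurnerModel
from .fft_recover import StructuralProfile, structural_profile
from .rna_core import (
    DEFAULT_RULE,
    RnaSequence,
    SecondaryStructure,
    StructureError,
    empty_structure,
)

__all__ = [
    "ProfileStats",
    "ScanTrack",
    "profile_stats",
    "expected_distance_to",
    "window_scan",
    "prefix_scan",
    "nussinov_mfe",
    "turner_mfe",
    "mfe_structure",
]


@dataclass(frozen=True)
class ProfileStats:
    """Ruggedness descriptors of a distance profile.

    ``mean`` and ``sd`` are in base pairs; ``cv = sd/mean`` is
    dimensionless and undefined (``None``) when the mean is zero;
    ``support`` is the largest ``k`` with ``p(k) > 0``.
    """

    mean: float
    sd: float
    cv: float | None
    support: int


def profile_stats(profile: StructuralProfile) -> ProfileStats:
    p = profile.probabilities
    k = np.arange(len(p))
    mean = float(np.sum(k * p))
    var = max(0.0, float(np.sum(k * k * p) - mean * mean))
    sd = math.sqrt(var)
    cv = sd / mean if mean > 0 else None
    return ProfileStats(mean=mean, sd=sd, cv=cv, support=profile.support())


def expected_distance_to(
    seq: RnaSequence,
    target: SecondaryStructure,
    model=None,
    m: int | None = None,
    validate: bool = True,
) -> float:
    """Expected base-pair distance of the ensemble of ``seq`` to ``target``."""
    prof = structural_profile(seq, target, model, m=m, validate=validate)
    return profile_stats(prof).mean


@dataclass(frozen=True)
class ScanTrack:
    """Expected distance per window offset (1-based, strictly increasing)."""

    offsets: tuple
    values: tuple
    window: int
    step: int

    def minimum_offset(self) -> int:
        """Offset of the global track minimum (first one on ties)."""
        return self.offsets[int(np.argmin(self.values))]

    def to_tsv(self, stream) -> None:
        stream.write(f"# window: {self.window}\n# step: {self.step}\n")
        stream.write("offset\texpected_distance\n")
        for o, v in zip(self.offsets, self.values):
            stream.write(f"{o}\t{v:.6f}\n")


def window_scan(
    seq: RnaSequence,
    target: SecondaryStructure,
    step: int = 1,
    model=None,
) -> ScanTrack:
    """Slide a window of the target's length along ``seq``.

    At each offset the expected base-pair distance between the window's
    Boltzmann ensemble and the target structure is recorded; local
    minima flag windows whose ensemble resembles the target.  The target
    need not be compatible with a window's nucleotides — distance
    bookkeeping is purely combinatorial — so reference validation is
    skipped here.
    """
    n = len(seq)
    L = target.n
    if L > n:
        raise StructureError(f"target length {L} exceeds sequence length {n}")
    offsets, values = [], []
    for o in range(1, n - L + 2, step):
        window = RnaSequence(
            seq.residues[o - 1 : o - 1 + L], id=f"{seq.id}[{o}..{o + L - 1}]"
        )
        target_here = SecondaryStructure(target.pairs, L, target.theta)
        values.append(
            expected_distance_to(window, target_here, model, validate=False)
        )
        offsets.append(o)
    return ScanTrack(tuple(offsets), tuple(values), window=L, step=step)


def prefix_scan(
    seq: RnaSequence,
    from_len: int,
    to_len: int,
    model=None,
    ref: str = "mfe",
    digits: int = 6,
) -> list[StructuralProfile]:
    """Distance profiles of all prefixes ``[1..L]`` for ``L`` in the range.

    The reference for each prefix is its own MFE structure
    (``ref="mfe"``) or the empty structure (``ref="empty"``).
    """
    if not (1 <= from_len <= to_len <= len(seq)):
        raise StructureError(
            f"prefix range [{from_len},{to_len}] invalid for length {len(seq)}"
        )
    if ref not in ("mfe", "empty"):
        raise StructureError(f"ref must be 'mfe' or 'empty', got {ref!r}")
    model = model if model is not None else NussinovModel()
    out = []
    for L in range(from_len, to_len + 1):
        prefix = RnaSequence(seq.residues[:L], id=f"{seq.id}[1..{L}]")
        if ref == "mfe":
            Sstar = mfe_structure(prefix, model)
        else:
            Sstar = empty_structure(L)
        out.append(structural_profile(prefix, Sstar, model, digits=digits))
    return out


# -- MFE folding ------------------------------------------------------------


def mfe_structure(seq: RnaSequence, model=None) -> SecondaryStructure:
    """MFE structure under the given model (maximum pairs for Nussinov)."""
    model = model if model is not None else NussinovModel()
    if isinstance(model, TurnerModel):
        return turner_mfe(seq, model)
    return nussinov_mfe(seq, rule=model.rule)


def nussinov_mfe(
    seq: RnaSequence, theta: int = 3, rule=DEFAULT_RULE
) -> SecondaryStructure:
    """Maximum-pairs structure; ties broken toward the smaller 5' index."""
    n = len(seq)
    res = seq.residues
    M = [[0] * (n + 2) for _ in range(n + 2)]
    for s in range(theta + 1, n):
        for i in range(1, n - s + 1):
            j = i + s
            best = M[i][j - 1]
            for l in range(i, j - theta):
                if rule.admits(res[l - 1], res[j - 1]):
                    best = max(best, 1 + M[i][l - 1] + M[l + 1][j - 1])
            M[i][j] = best

    pairs = set()

    def trace(i: int, j: int) -> None:
        if j - i <= theta:
            return
        target = M[i][j]
        for l in range(i, j - theta):  # smallest pairing index wins ties
            if (
                rule.admits(res[l - 1], res[j - 1])
                and 1 + M[i][l - 1] + M[l + 1][j - 1] == target
            ):
                pairs.add((l, j))
                trace(i, l - 1)
                trace(l + 1, j - 1)
                return
        trace(i, j - 1)

    trace(1, n)
    return SecondaryStructure(frozenset(pairs), n, theta)


def turner_mfe(seq: RnaSequence, model: TurnerModel) -> SecondaryStructure:
    """Zuker-style MFE under the nearest-neighbor model.

    Mirrors the loop cases of the partition-function decomposition
    (hairpin, capped interior loop, affine multiloop).  Ties are broken
    toward the smaller 5' pairing index by scan order.
    """
    n = len(seq)
    theta = 3
    res = seq.residues
    params = model.params
    INF = float("inf")
    a_ml = params.scalars["ml_a"]
    b_ml = params.scalars["ml_b"]
    c_ml = params.scalars["ml_c"]

    def pairable(i: int, j: int) -> bool:
        return j - i > theta and model.rule.admits(res[i - 1], res[j - 1])

    def sym(i: int, j: int) -> str:
        return res[i - 1] + res[j - 1]

    def hp(i: int, j: int) -> float:
        e = params.hairpin(j - i - 1)
        if sym(i, j) not in ("CG", "GC"):
            e += params.scalars["terminal_au_hairpin"]
        return e

    def il(i: int, j: int, k: int, l: int) -> float:
        n1, n2 = k - i - 1, j - l - 1
        if n1 + n2 == 0:
            return params.stack[(sym(i, j), sym(k, l))]
        if n1 + n2 > MAX_INTERIOR_LOOP:
            return INF
        if 0 in (n1, n2):
            return params.bulge(n1 + n2)
        return params.internal(n1, n2)

    V = [[INF] * (n + 2) for _ in range(n + 2)]
    WM = [[INF] * (n + 2) for _ in range(n + 2)]
    WM1 = [[INF] * (n + 2) for _ in range(n + 2)]
    for s in range(theta + 1, n):
        for i in range(1, n - s + 1):
            j = i + s
            if pairable(i, j):
                best = hp(i, j)
                for k in range(i + 1, j - theta - 1):
                    if k - i - 1 > MAX_INTERIOR_LOOP:
                        break
                    for l in range(k + theta + 1, j):
                        if V[k][l] < INF:
                            best = min(best, il(i, j, k, l) + V[k][l])
                for l in range(i + 2, j - 1):
                    if WM[i + 1][l - 1] < INF and WM1[l][j - 1] < INF:
                        best = min(best, a_ml + WM[i + 1][l - 1] + WM1[l][j - 1])
                V[i][j] = best
            zm1 = INF
            for h in range(i + theta + 1, j + 1):
                if V[i][h] < INF:
                    zm1 = min(zm1, V[i][h] + b_ml + c_ml * (j - h))
            WM1[i][j] = zm1
            zm = WM[i][j - 1] + c_ml if WM[i][j - 1] < INF else INF
            for l in range(i, j - theta):
                if V[l][j] < INF:
                    zm = min(
                        zm,
                        V[l][j] + b_ml + c_ml * (l - i),
                        (V[l][j] + b_ml + WM[i][l - 1])
                        if WM[i][l - 1] < INF
                        else INF,
                    )
            WM[i][j] = zm
    W = [0.0] * (n + 1)
    for j in range(1, n + 1):
        best = W[j - 1]
        for l in range(1, j - theta):
            if V[l][j] < INF:
                best = min(best, W[l - 1] + V[l][j])
        W[j] = best

    pairs: set = set()
    TOL = 1e-9

    def close(a: float, b: float) -> bool:
        return abs(a - b) <= TOL

    def trace_v(i: int, j: int) -> None:
        pairs.add((i, j))
        e = V[i][j]
        if close(e, hp(i, j)):
            return
        for k in range(i + 1, j - theta - 1):
            if k - i - 1 > MAX_INTERIOR_LOOP:
                break
            for l in range(k + theta + 1, j):
                if V[k][l] < INF and close(e, il(i, j, k, l) + V[k][l]):
                    trace_v(k, l)
                    return
        for l in range(i + 2, j - 1):
            if (
                WM[i + 1][l - 1] < INF
                and WM1[l][j - 1] < INF
                and close(e, a_ml + WM[i + 1][l - 1] + WM1[l][j - 1])
            ):
                trace_wm(i + 1, l - 1)
                trace_wm1(l, j - 1)
                return
        raise AssertionError(f"traceback failed for V({i},{j})")

    def trace_wm1(i: int, j: int) -> None:
        e = WM1[i][j]
        for h in range(i + theta + 1, j + 1):
            if V[i][h] < INF and close(e, V[i][h] + b_ml + c_ml * (j - h)):
                trace_v(i, h)
                return
        raise AssertionError(f"traceback failed for WM1({i},{j})")

    def trace_wm(i: int, j: int) -> None:
        e = WM[i][j]
        for l in range(i, j - theta):
            if V[l][j] < INF and close(e, V[l][j] + b_ml + c_ml * (l - i)):
                trace_v(l, j)
                return
            if (
                V[l][j] < INF
                and WM[i][l - 1] < INF
                and close(e, V[l][j] + b_ml + WM[i][l - 1])
            ):
                trace_wm(i, l - 1)
                trace_v(l, j)
                return
        if WM[i][j - 1] < INF and close(e, WM[i][j - 1] + c_ml):
            trace_wm(i, j - 1)
            return
        raise AssertionError(f"traceback failed for WM({i},{j})")

    def trace_w(j: int) -> None:
        if j <= theta:
            return
        e = W[j]
        for l in range(1, j - theta):
            if V[l][j] < INF and close(e, W[l - 1] + V[l][j]):
                trace_v(l, j)
                trace_w(l - 1)
                return
        trace_w(j - 1)

    trace_w(n)
    return SecondaryStructure(frozenset(pairs), n, theta)
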