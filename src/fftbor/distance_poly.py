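"""Evaluation of the distance-indexed partition-function polynomial.

For a sequence ``s`` and a fixed reference structure ``S*``, define

    Z-hat(x) = sum_S exp(-E(S)/RT) * x**d(S, S*)

over all secondary structures ``S`` of ``s``, where ``d`` is base-pair
distance.  ``Z-hat`` is a polynomial in ``x`` whose ``k``-th coefficient
is the restricted partition function ``Z_k`` over structures at distance
exactly ``k``; its value at ``x = 1`` is the full partition function.

The polynomial is never expanded.  Instead, for a fixed complex ``x`` an
interval dynamic program propagates scalar values ``Z-hat(i,j)(x)``,
where each table entry tracks distance relative to the restriction of
``S*`` to ``[i, j]``.  The distance bookkeeping rests on one counting
identity: when a decomposition step confines all further pairs to
sub-intervals ``R_1..R_m`` of ``[i, j]`` and introduces the pair set
``Q`` (empty or a single pair), the base-pair distance gains

    delta = |Q \\ S*|  +  |S*_[i,j]| - |Q ∩ S*| - sum_k |S*_[R_k]|

-- one for a novel introduced pair, plus one for every reference pair
made unrepresentable by the split.  For the per-pair (Nussinov) model
this reduces to the classical two-case recursion ("last position
unpaired, or paired to l"); for the nearest-neighbor model the same
rule decorates a McCaskill-style loop decomposition (closed-pair,
multiloop-part and exterior matrices).

Evaluating at the ``m``-th roots of unity and applying the inverse DFT
(:mod:`fftbor.fft_recover`) recovers the coefficients.  Because the
coefficients are real, values at conjugate roots are conjugate, so only
``floor(m/2) + 1`` dynamic programs are run and the rest are filled by
conjugation.
"""

from __future__ import annotations

import cmath
import math
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass

import numpy as np

from .energy import (
    MAX_INTERIOR_LOOP,
    NussinovModel,
    PAIR_TYPES,
    TurnerModel,
)
from .rna_core import (
    RnaSequence,
    SecondaryStructure,
    StructureError,
    max_distance_bound,
    validate_compatibility,
)

__all__ = [
    "DistanceBookkeeping",
    "ComplexEvaluation",
    "pair_distance_increment",
    "unpaired_increment",
    "evaluate_at",
    "evaluate_on_roots",
]


class DistanceBookkeeping:
    """Prefix pair counts and pair membership for a reference structure.

    ``P[i, j]`` holds ``|S*_[i,j]|``, the number of reference pairs lying
    entirely inside the closed interval ``[i, j]`` (zero for empty or
    inverted intervals).
    """

    def __init__(self, Sstar: SecondaryStructure):
        self.Sstar = Sstar
        n = Sstar.n
        partner = Sstar.partner()
        P = np.zeros((n + 2, n + 2), dtype=np.int64)
        for i in range(n, 0, -1):
            p = partner.get(i)
            for j in range(i, n + 1):
                P[i, j] = P[i + 1, j] + (1 if p is not None and i < p <= j else 0)
        self.P = P
        star = np.zeros((n + 2, n + 2), dtype=bool)
        for i, j in Sstar.pairs:
            star[i, j] = True
        self.star = star
        self.n = n


def pair_distance_increment(book: DistanceBookkeeping, i: int, l: int, j: int) -> int:
    """Distance gained by introducing pair ``(l, j)`` while splitting ``[i, j]``.

    Equals ``|S*_[i,j]| - |S*_[i,l-1]| - |S*_[l+1,j-1]| + 1 - 2*[(l,j) in S*]``:
    a reference pair costs nothing, a novel pair costs one, and every
    reference pair straddling the split is lost.  Always non-negative.
    """
    if not (1 <= i <= l < j <= book.n):
        raise StructureError(f"indices violate 1 <= {i} <= {l} < {j} <= {book.n}")
    P = book.P
    return int(
        P[i, j] - P[i, l - 1] - P[l + 1, j - 1] + 1 - 2 * int(book.star[l, j])
    )


def unpaired_increment(book: DistanceBookkeeping, i: int, j: int) -> int:
    """1 iff ``j`` is paired within the restriction of ``S*`` to ``[i, j]``."""
    if not (1 <= i <= j <= book.n):
        raise StructureError(f"indices violate 1 <= {i} <= {j} <= {book.n}")
    return int(book.P[i, j] - book.P[i, j - 1])


@dataclass(frozen=True)
class ComplexEvaluation:
    """Values of the distance polynomial at the ``m``-th roots of unity.

    ``values[j] = Z-hat(omega**j)`` with ``omega = exp(2*pi*1j/m)``;
    ``Z = values[0]`` is the (real, positive) full partition function.
    """

    m: int
    values: np.ndarray
    Z: float


class _EvalContext:
    """Shared per-instance precomputation, reused across evaluation points.

    Holds the O(n^2) integer bookkeeping and energy-weight tables; each
    call to :meth:`evaluate` runs one O(n^3)-time, O(n^2)-space dynamic
    program for a single complex point.
    """

    def __init__(self, seq: RnaSequence, Sstar: SecondaryStructure,
                 model, validate: bool = True):
        if Sstar.n != len(seq):
            raise StructureError(
                f"reference length {Sstar.n} != sequence length {len(seq)}"
            )
        if validate:
            bad = validate_compatibility(seq, Sstar, model.rule)
            if bad:
                i, j, a, b = bad[0]
                raise StructureError(
                    f"reference pair ({i},{j}) {a}-{b} violates the pairing rule"
                )
        self.seq = seq
        self.Sstar = Sstar
        self.model = model
        self.theta = Sstar.theta
        self.n = len(seq)
        self.book = DistanceBookkeeping(Sstar)

        n, theta = self.n, self.theta
        res = seq.residues
        can = np.zeros((n + 2, n + 2), dtype=bool)
        ptype = np.zeros((n + 2, n + 2), dtype=np.int64)  # index into PAIR_TYPES
        for i in range(1, n + 1):
            for j in range(i + theta + 1, n + 1):
                sym = res[i - 1] + res[j - 1]
                if model.rule.admits(res[i - 1], res[j - 1]):
                    can[i, j] = True
                    if sym in PAIR_TYPES:
                        ptype[i, j] = PAIR_TYPES.index(sym)
        self.can = can
        self.ptype = ptype

        if isinstance(model, TurnerModel):
            self._prepare_turner()

    # -- per-pair (Nussinov) engine ---------------------------------------

    def _nussinov(self, x: complex) -> complex:
        n, theta = self.n, self.theta
        P, star, can = self.book.P, self.book.star, self.can
        px = np.power(np.complex128(x), np.arange(n + 2))
        w = math.exp(-self.model.epsilon / self.model.RT)
        Z = np.ones((n + 2, n + 2), dtype=np.complex128)
        for s in range(theta + 1, n):
            i = np.arange(1, n - s + 1)
            j = i + s
            acc = px[P[i, j] - P[i, j - 1]] * Z[i, j - 1]
            for t in range(0, s - theta):
                l = i + t
                b = P[i, j] - P[i, l - 1] - P[l + 1, j - 1] + 1 - 2 * star[l, j]
                acc = acc + can[l, j] * (w * px[b]) * Z[i, l - 1] * Z[l + 1, j - 1]
            Z[i, j] = acc
        return complex(Z[1, n])

    # -- nearest-neighbor (Turner) engine ----------------------------------

    def _prepare_turner(self) -> None:
        n = self.n
        params = self.model.params
        RT = self.model.RT
        res = self.seq.residues
        # hairpin closing weights, 0 where (i,j) cannot pair
        HW = np.zeros((n + 2, n + 2))
        for i in range(1, n + 1):
            for j in range(i + self.theta + 1, n + 1):
                if self.can[i, j]:
                    e = params.hairpin(j - i - 1)
                    if res[i - 1] + res[j - 1] not in ("CG", "GC"):
                        e += params.scalars["terminal_au_hairpin"]
                    HW[i, j] = math.exp(-e / RT)
        self._HW = HW
        SW = np.zeros((6, 6))
        for a, pa in enumerate(PAIR_TYPES):
            for b, pb in enumerate(PAIR_TYPES):
                SW[a, b] = math.exp(-params.stack[(pa, pb)] / RT)
        self._SW = SW
        L = MAX_INTERIOR_LOOP
        ILW = np.zeros((L + 1, L + 1))
        for n1 in range(L + 1):
            for n2 in range(L + 1 - n1):
                if n1 == n2 == 0:
                    continue  # stack, handled separately
                if 0 in (n1, n2):
                    ILW[n1, n2] = math.exp(-params.bulge(n1 + n2) / RT)
                else:
                    ILW[n1, n2] = math.exp(-params.internal(n1, n2) / RT)
        self._ILW = ILW
        self._expa = math.exp(-params.scalars["ml_a"] / RT)
        self._expb = math.exp(-params.scalars["ml_b"] / RT)
        self._expc = math.exp(-params.scalars["ml_c"] / RT)

    def _turner(self, x: complex) -> complex:
        n, theta = self.n, self.theta
        P, star = self.book.P, self.book.star
        can, ptype = self.can, self.ptype
        HW, SW, ILW = self._HW, self._SW, self._ILW
        expa, expb, expc = self._expa, self._expb, self._expc
        px = np.power(np.complex128(x), np.arange(n + 2))

        ZB = np.zeros((n + 2, n + 2), dtype=np.complex128)
        ZM = np.zeros((n + 2, n + 2), dtype=np.complex128)
        ZM1 = np.zeros((n + 2, n + 2), dtype=np.complex128)

        for s in range(theta + 1, n):
            i = np.arange(1, n - s + 1)
            j = i + s
            pm = can[i, j]
            # d0: distance increment when (i,j) is introduced and every
            # other reference pair of S*[i,j] is lost
            d0 = P[i, j] + 1 - 2 * star[i, j]
            # hairpin closed by (i,j): everything inside unpaired
            acc = HW[i, j] * px[d0]
            # interior loop (stack / bulge / internal) to inner pair (k,l)
            for dk in range(1, min(MAX_INTERIOR_LOOP + 2, s - theta)):
                for dl in range(1, s - theta - dk + 1):
                    if (dk - 1) + (dl - 1) > MAX_INTERIOR_LOOP:
                        break
                    k = i + dk
                    l = j - dl
                    inner = ZB[k, l]
                    if dk == 1 and dl == 1:
                        wv = SW[ptype[i, j], ptype[k, l]]
                    else:
                        wv = ILW[dk - 1, dl - 1]
                    acc = acc + wv * inner * px[d0 - P[k, l]]
            # multiloop closed by (i,j): >= 2 branches inside
            for t in range(2, s - 1):
                l = i + t
                acc = acc + expa * ZM[i + 1, l - 1] * ZM1[l, j - 1] * px[
                    d0 - P[i + 1, l - 1] - P[l, j - 1]
                ]
            ZB[i, j] = pm * acc

            # ZM1: exactly one multiloop branch (i,h), rest unpaired
            zm1 = np.zeros(len(i), dtype=np.complex128)
            for u in range(theta + 1, s + 1):
                h = i + u
                zm1 = zm1 + ZB[i, h] * (expb * expc ** (s - u)) * px[
                    P[i, j] - P[i, h]
                ]
            ZM1[i, j] = zm1

            # ZM: at least one branch in a multiloop fragment
            zm = expc * px[P[i, j] - P[i, j - 1]] * ZM[i, j - 1]
            for t in range(0, s - theta):
                l = i + t
                zb = ZB[l, j]
                zm = zm + expb * zb * (
                    expc ** t * px[P[i, j] - P[l, j]]
                    + ZM[i, l - 1] * px[P[i, j] - P[i, l - 1] - P[l, j]]
                )
            ZM[i, j] = zm

        # exterior loop over [1, j]
        E = np.ones(n + 1, dtype=np.complex128)
        for j in range(1, n + 1):
            E[j] = E[j - 1] * px[P[1, j] - P[1, j - 1]]
            l = np.arange(1, j - theta)
            if len(l):
                E[j] += np.sum(
                    E[l - 1] * ZB[l, j] * px[P[1, j] - P[1, l - 1] - P[l, j]]
                )
        return complex(E[n])

    def evaluate(self, x: complex) -> complex:
        if isinstance(self.model, TurnerModel):
            return self._turner(x)
        return self._nussinov(x)


def evaluate_at(
    seq: RnaSequence,
    Sstar: SecondaryStructure,
    x: complex,
    model=None,
    validate: bool = True,
) -> complex:
    """``Z-hat(1,n)(x)``: one dynamic-programming pass at a fixed complex point.

    At ``x = 1`` this is the full partition function.
    """
    model = model if model is not None else NussinovModel()
    return _EvalContext(seq, Sstar, model, validate=validate).evaluate(x)


def _eval_chunk(args):
    seq, Sstar, model, validate, xs = args
    ctx = _EvalContext(seq, Sstar, model, validate=validate)
    return [ctx.evaluate(x) for x in xs]


def evaluate_on_roots(
    seq: RnaSequence,
    Sstar: SecondaryStructure,
    model=None,
    m: int | None = None,
    full: bool = False,
    validate: bool = True,
    workers: int = 1,
) -> ComplexEvaluation:
    """Evaluate the distance polynomial at all ``m``-th roots of unity.

    Only points ``j = 0 .. floor(m/2)`` are computed by dynamic
    programming; the remainder are complex conjugates (real
    coefficients), unless ``full=True`` forces every point through the
    DP.  ``m`` defaults to the sequence length, which always exceeds the
    distance bound.  ``workers > 1`` distributes the independent point
    evaluations over processes; results are identical to serial runs.
    """
    model = model if model is not None else NussinovModel()
    n = len(seq)
    bound = max_distance_bound(Sstar)
    if m is None:
        m = max(n, bound + 1)
    if m < bound + 1:
        raise ValueError(
            f"m={m} is below the distance bound + 1 = {bound + 1} "
            f"(coefficients would alias)"
        )
    roots = np.exp(2j * np.pi * np.arange(m) / m)
    roots[0] = 1.0
    top = m if full else m // 2 + 1
    xs = [complex(roots[j]) for j in range(top)]
    if workers > 1:
        chunks = [
            (seq, Sstar, model, validate, xs[w::workers]) for w in range(workers)
        ]
        with ProcessPoolExecutor(max_workers=workers) as pool:
            parts = list(pool.map(_eval_chunk, chunks))
        vals = [None] * top
        for w, part in enumerate(parts):
            for offset, v in enumerate(part):
                vals[w + offset * workers] = v
    else:
        ctx = _EvalContext(seq, Sstar, model, validate=validate)
        vals = [ctx.evaluate(x) for x in xs]
    values = np.empty(m, dtype=np.complex128)
    values[:top] = vals
    for j in range(top, m):
        values[j] = np.conj(values[m - j])
    return ComplexEvaluation(m=m, values=values, Z=float(values[0].real))
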