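"""Free-energy models for secondary structures.

Two models are provided:

* :class:`NussinovModel` -- energy proportional to the number of base
  pairs (``epsilon`` kcal/mol per pair, default -1).  The empty
  structure has energy 0.
* :class:`TurnerModel` -- a loop-decomposition nearest-neighbor model
  (hairpins, stacks, bulges, internal loops, affine multiloops) driven
  by a compact bundled parameter table.  The exterior loop contributes
  nothing.  Dangles, coaxial stacking and special hairpin bonuses are
  out of scope; the model is a self-consistent nearest-neighbor
  instance, not a bit-compatible reproduction of any published table
  dialect.

Energies are in kcal/mol throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .rna_core import (
    DEFAULT_RULE,
    BasePairRule,
    RnaSequence,
    SecondaryStructure,
    StructureError,
)

__all__ = [
    "ThermoConstants",
    "NussinovModel",
    "TurnerModel",
    "TurnerParams",
    "nussinov_energy",
    "boltzmann_factor",
    "turner_energy",
    "loop_decompose",
    "Loop",
    "PAIR_TYPES",
    "MAX_INTERIOR_LOOP",
]

R_KCAL = 0.0019872  # gas constant, kcal/(mol K)
T_DEFAULT = 310.15  # 37 C

#: pair-type order used for the stack table
PAIR_TYPES = ("AU", "CG", "GC", "UA", "GU", "UG")

#: largest interior (bulge + internal) loop size entered in the partition DP
MAX_INTERIOR_LOOP = 30


@dataclass(frozen=True)
class ThermoConstants:
    R: float = R_KCAL
    T: float = T_DEFAULT

    @property
    def RT(self) -> float:
        return self.R * self.T


def boltzmann_factor(E: float, thermo: ThermoConstants) -> float:
    """``exp(-E / RT)``."""
    return math.exp(-E / thermo.RT)


def nussinov_energy(S: SecondaryStructure, epsilon: float = -1.0) -> float:
    """Energy of a structure in the per-pair model: ``epsilon * |pairs|``."""
    return epsilon * len(S.pairs)


@dataclass(frozen=True)
class NussinovModel:
    """Per-base-pair energy model (Nussinov-Jacobson)."""

    epsilon: float = -1.0
    thermo: ThermoConstants = ThermoConstants()
    rule: BasePairRule = DEFAULT_RULE

    name = "nussinov"

    @property
    def RT(self) -> float:
        return self.thermo.RT

    def energy(self, seq: RnaSequence, S: SecondaryStructure) -> float:
        return nussinov_energy(S, self.epsilon)


# -- Turner-style model ----------------------------------------------------


class TurnerParams:
    """Parameter table for the nearest-neighbor model.

    Parsed from a plain-text key/value file; see the bundled
    ``data/turner_params.txt`` for the format.  Loop-length tables are
    extrapolated beyond their largest tabulated size with the
    Jacobson-Stockmayer form ``dG(n) = dG(n_max) + js_coef * ln(n / n_max)``.
    """

    def __init__(self, text: str):
        self.stack: dict[tuple[str, str], float] = {}
        self._hairpin: dict[int, float] = {}
        self._bulge: dict[int, float] = {}
        self._internal: dict[int, float] = {}
        self.scalars: dict[str, float] = {}
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tok = line.split()
            if tok[0] == "stack":
                self.stack[(tok[1], tok[2])] = float(tok[3])
            elif tok[0] in ("hairpin", "bulge", "internal"):
                getattr(self, "_" + tok[0])[int(tok[1])] = float(tok[2])
            else:
                self.scalars[tok[0]] = float(tok[1])
        for key in ("ml_a", "ml_b", "ml_c", "ninio", "ninio_max",
                    "terminal_au_hairpin", "js_coef"):
            if key not in self.scalars:
                raise ValueError(f"parameter table missing {key!r}")

    @classmethod
    def bundled(cls) -> "TurnerParams":
        text = (
            resources.files("fftbor").joinpath("data/turner_params.txt").read_text()
        )
        return cls(text)

    @classmethod
    def from_file(cls, path) -> "TurnerParams":
        return cls(open(path).read())

    def _length_term(self, table: dict[int, float], size: int) -> float:
        if size in table:
            return table[size]
        nmax = max(table)
        if size < min(table):
            raise ValueError(f"loop size {size} below tabulated minimum")
        return table[nmax] + self.scalars["js_coef"] * math.log(size / nmax)

    def hairpin(self, size: int) -> float:
        return self._length_term(self._hairpin, size)

    def bulge(self, size: int) -> float:
        return self._length_term(self._bulge, size)

    def internal(self, n1: int, n2: int) -> float:
        base = self._length_term(self._internal, n1 + n2)
        asym = min(
            self.scalars["ninio_max"], self.scalars["ninio"] * abs(n1 - n2)
        )
        return base + asym


@dataclass(frozen=True)
class Loop:
    """One loop of the unique loop decomposition of a structure."""

    kind: str  # hairpin | stack | bulge | internal | multiloop | exterior
    closing: tuple[int, int] | None
    branches: tuple  # directly enclosed pairs
    unpaired: int  # unpaired nucleotides inside the loop


def loop_decompose(S: SecondaryStructure) -> list[Loop]:
    """The unique loop decomposition of a structure.

    Every pair closes exactly one loop; the exterior face is reported
    once (with ``closing=None``).
    """
    partner = S.partner()

    def children(i: int, j: int) -> list[tuple[int, int]]:
        out = []
        k = i
        while k <= j:
            h = partner.get(k)
            if h is not None and h > k:
                out.append((k, h))
                k = h + 1
            else:
                k += 1
        return out

    loops = []
    ext = children(1, S.n)
    loops.append(
        Loop("exterior", None, tuple(ext), S.n - sum(h - k + 1 for k, h in ext))
    )
    stack_ = list(ext)
    while stack_:
        i, j = stack_.pop()
        inner = children(i + 1, j - 1)
        stack_.extend(inner)
        unpaired = (j - i - 1) - sum(h - k + 1 for k, h in inner)
        if not inner:
            kind = "hairpin"
        elif len(inner) == 1:
            k, h = inner[0]
            n1, n2 = k - i - 1, j - h - 1
            kind = "stack" if n1 == n2 == 0 else ("bulge" if 0 in (n1, n2) else "internal")
        else:
            kind = "multiloop"
        loops.append(Loop(kind, (i, j), tuple(inner), unpaired))
    return loops


def _pair_symbol(seq: RnaSequence, i: int, j: int) -> str:
    return seq[i] + seq[j]


def turner_energy(
    seq: RnaSequence, S: SecondaryStructure, params: TurnerParams
) -> float:
    """Free energy of ``S`` as the sum of its loop free energies."""
    bad = [p for p in S.pairs if _pair_symbol(seq, *p) not in PAIR_TYPES]
    if bad:
        i, j = sorted(bad)[0]
        raise StructureError(
            f"pair ({i},{j}) {seq[i]}-{seq[j]} not admissible in the Turner model"
        )
    total = 0.0
    for loop in loop_decompose(S):
        if loop.kind == "exterior":
            continue
        i, j = loop.closing
        if loop.kind == "hairpin":
            total += params.hairpin(j - i - 1)
            if _pair_symbol(seq, i, j) not in ("CG", "GC"):
                total += params.scalars["terminal_au_hairpin"]
        elif loop.kind == "stack":
            k, h = loop.branches[0]
            total += params.stack[(_pair_symbol(seq, i, j), _pair_symbol(seq, k, h))]
        elif loop.kind == "bulge":
            total += params.bulge(loop.unpaired)
        elif loop.kind == "internal":
            k, h = loop.branches[0]
            total += params.internal(k - i - 1, j - h - 1)
        else:  # multiloop
            total += (
                params.scalars["ml_a"]
                + params.scalars["ml_b"] * len(loop.branches)
                + params.scalars["ml_c"] * loop.unpaired
            )
    return total


@dataclass(frozen=True)
class TurnerModel:
    """Nearest-neighbor loop-based energy model."""

    params: TurnerParams = field(default_factory=TurnerParams.bundled)
    thermo: ThermoConstants = ThermoConstants()
    rule: BasePairRule = DEFAULT_RULE

    name = "turner"

    @property
    def RT(self) -> float:
        return self.thermo.RT

    def energy(self, seq: RnaSequence, S: SecondaryStructure) -> float:
        return turner_energy(seq, S, self.params)
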