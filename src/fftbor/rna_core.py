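"""Sequences, secondary structures and base-pair distance.

Coordinates are 1-based and intervals are closed throughout the public
API, matching the conventional notation of the RNA folding literature.

A secondary structure on a sequence of length ``n`` is a set of base
pairs ``(i, j)`` with ``1 <= i < j <= n`` such that every position is
involved in at most one pair, pairs never cross (no pseudoknots), and
every hairpin loop contains at least ``theta`` unpaired nucleotides
(``j - i > theta``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = [
    "RnaSequence",
    "SecondaryStructure",
    "BasePairRule",
    "DEFAULT_RULE",
    "StructureError",
    "parse_dot_bracket",
    "bp_distance",
    "max_distance_bound",
    "validate_compatibility",
    "read_fasta",
    "read_vienna",
]

DEFAULT_THETA = 3

_VALID = set("ACGU")


class StructureError(ValueError):
    """Raised for malformed sequences, structures or dot-bracket strings."""


@dataclass(frozen=True)
class RnaSequence:
    """A validated RNA sequence.

    Input may contain lowercase letters and ``T``; both are normalized
    (uppercased, ``T`` -> ``U``).  Any other character is rejected.
    """

    residues: str
    id: str = "seq"

    def __post_init__(self) -> None:
        normalized = self.residues.upper().replace("T", "U")
        bad = [(k + 1, c) for k, c in enumerate(normalized) if c not in _VALID]
        if bad:
            pos, c = bad[0]
            raise StructureError(
                f"invalid residue {c!r} at position {pos} in sequence {self.id!r}"
            )
        if not normalized:
            raise StructureError("empty sequence")
        object.__setattr__(self, "residues", normalized)

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, i: int) -> str:
        """1-based residue access."""
        if not 1 <= i <= len(self):
            raise IndexError(f"position {i} outside [1, {len(self)}]")
        return self.residues[i - 1]

    def __str__(self) -> str:
        return self.residues


@dataclass(frozen=True)
class BasePairRule:
    """The set of admissible (unordered) nucleotide pairs.

    The default is the six Watson-Crick and wobble pairs
    AU/UA, CG/GC, GU/UG.
    """

    allowed: frozenset = frozenset({("A", "U"), ("C", "G"), ("G", "U")})

    def admits(self, a: str, b: str) -> bool:
        return (a, b) in self.allowed or (b, a) in self.allowed


DEFAULT_RULE = BasePairRule()


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free set of base pairs on positions ``1..n``."""

    pairs: frozenset
    n: int
    theta: int = DEFAULT_THETA

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", frozenset(tuple(p) for p in self.pairs))
        seen: dict[int, tuple] = {}
        for i, j in self.pairs:
            if not (1 <= i < j <= self.n):
                raise StructureError(f"pair ({i},{j}) outside 1..{self.n}")
            if j - i <= self.theta:
                raise StructureError(
                    f"pair ({i},{j}) violates the minimum hairpin size theta={self.theta}"
                )
            for k in (i, j):
                if k in seen:
                    raise StructureError(
                        f"position {k} occurs in both {seen[k]} and ({i},{j})"
                    )
                seen[k] = (i, j)
        ordered = sorted(self.pairs)
        for a in range(len(ordered)):
            i, j = ordered[a]
            for k, l in ordered[a + 1 :]:
                if k >= j:
                    break
                if i < k < j < l:
                    raise StructureError(
                        f"crossing pairs ({i},{j}) and ({k},{l}) (pseudoknot)"
                    )

    # -- rendering ---------------------------------------------------------

    def to_dot_bracket(self) -> str:
        chars = ["."] * self.n
        for i, j in self.pairs:
            chars[i - 1] = "("
            chars[j - 1] = ")"
        return "".join(chars)

    def __str__(self) -> str:
        return self.to_dot_bracket()

    def __len__(self) -> int:
        return len(self.pairs)

    # -- operations --------------------------------------------------------

    def restrict(self, i: int, j: int) -> "SecondaryStructure":
        """Pairs of the structure lying entirely within the closed interval [i, j]."""
        if not (1 <= i <= j <= self.n):
            raise StructureError(f"interval [{i},{j}] outside 1..{self.n}")
        kept = frozenset((x, y) for x, y in self.pairs if i <= x < y <= j)
        return SecondaryStructure(kept, self.n, self.theta)

    def partner(self) -> dict[int, int]:
        """Map each paired position to its partner."""
        out: dict[int, int] = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out


def empty_structure(n: int, theta: int = DEFAULT_THETA) -> SecondaryStructure:
    return SecondaryStructure(frozenset(), n, theta)


def parse_dot_bracket(
    text: str, theta: int = DEFAULT_THETA
) -> SecondaryStructure:
    """Parse a dot-bracket string into a :class:`SecondaryStructure`.

    Raises :class:`StructureError` naming the offending position for
    stray characters or unbalanced parentheses.
    """
    stack: list[int] = []
    pairs = set()
    for pos, c in enumerate(text, start=1):
        if c == ".":
            continue
        if c == "(":
            stack.append(pos)
        elif c == ")":
            if not stack:
                raise StructureError(f"unmatched ')' at position {pos}")
            pairs.add((stack.pop(), pos))
        else:
            raise StructureError(f"invalid character {c!r} at position {pos}")
    if stack:
        raise StructureError(f"unmatched '(' at position {stack[-1]}")
    return SecondaryStructure(frozenset(pairs), len(text), theta)


def bp_distance(S: SecondaryStructure, T: SecondaryStructure) -> int:
    """Base-pair distance: the number of pairs not common to both structures."""
    if S.n != T.n:
        raise StructureError(f"length mismatch: {S.n} vs {T.n}")
    return len(S.pairs.symmetric_difference(T.pairs))


def max_distance_bound(
    Sstar: SecondaryStructure, n: int | None = None, theta: int | None = None
) -> int:
    """Upper bound on the base-pair distance from ``Sstar`` to any structure.

    No structure on ``n`` nucleotides holds more than ``(n - theta) // 2``
    pairs, and the distance never exceeds ``|S| + |S*|``, so every
    reachable distance is at most ``|S*| + (n - theta) // 2``.
    """
    n = Sstar.n if n is None else n
    theta = Sstar.theta if theta is None else theta
    return len(Sstar.pairs) + max(0, (n - theta) // 2)


def validate_compatibility(
    seq: RnaSequence,
    S: SecondaryStructure,
    rule: BasePairRule = DEFAULT_RULE,
) -> list[tuple[int, int, str, str]]:
    """List every pair of ``S`` whose nucleotides the pairing rule rejects.

    An empty report means the structure is compatible with the sequence.
    """
    if S.n != len(seq):
        raise StructureError(f"length mismatch: structure {S.n}, sequence {len(seq)}")
    bad = []
    for i, j in sorted(S.pairs):
        if not rule.admits(seq[i], seq[j]):
            bad.append((i, j, seq[i], seq[j]))
    return bad


# -- file readers ----------------------------------------------------------


def read_fasta(path, record_id: str | None = None) -> RnaSequence:
    """Read one record from a FASTA file (the first unless ``record_id`` given)."""
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fasta"):
        if record_id is None or rec.id == record_id:
            return RnaSequence(str(rec.seq), id=rec.id)
    raise StructureError(
        f"no FASTA record {'found' if record_id is None else record_id!r} in {path}"
    )


def read_vienna(path, theta: int = DEFAULT_THETA):
    """Read the conventional three-line layout: '>' header, sequence, structure.

    The header line is optional.  Returns ``(RnaSequence, SecondaryStructure)``.
    """
    lines = [ln.strip() for ln in open(path) if ln.strip()]
    if lines and lines[0].startswith(">"):
        name, lines = lines[0][1:].strip() or "seq", lines[1:]
    else:
        name = "seq"
    if len(lines) < 2:
        raise StructureError(f"{path}: expected sequence and structure lines")
    seq = RnaSequence(lines[0], id=name)
    struct = parse_dot_bracket(lines[1], theta=theta)
    if struct.n != len(seq):
        raise StructureError(
            f"{path}: structure length {struct.n} != sequence length {len(seq)}"
        )
    return seq, struct
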