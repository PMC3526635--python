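"""Synthetic sequences and the sequence-randomization control.

All generators take explicit integer seeds and draw from a local
``numpy.random.Generator``; there is no global random state anywhere in
the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rna_core import RnaSequence, SecondaryStructure, StructureError

__all__ = [
    "GeneratorConfig",
    "random_rna",
    "random_structure",
    "dinucleotide_shuffle",
    "embed_hairpin",
    "pearson",
    "TPP_APTAMER_97",
    "TPP_APTAMER_99",
]

NUCLEOTIDES = ("A", "C", "G", "U")
_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}

#: Two thiamine-pyrophosphate riboswitch aptamers from the Rfam RF00059
#: seed alignment, used as realistic fixed inputs for profile statistics
#: and shuffle controls.
TPP_APTAMER_97 = RnaSequence(
    "ACCUGACGCUAGGGGUGUUGGUGAAUUCACCGACUGAGAAUAACCCUUUG"
    "AACCUGAUAGAGAUAAUGCUCGCGCAGGGAAGCAAGAAUAGAAAGAU",
    id="BX842649.1/277414-277318",
)
TPP_APTAMER_99 = RnaSequence(
    "UAUAAGUCCAAGGGGUGCCAAUUGGCUGAGAUGGUUUUAACCAAUCCCUU"
    "UGAACCUGAUCCGGUUAAUACCGGCGUAGGAAUGGAUUUUCUCUACAGC",
    id="AACY022101973.1/389-487",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Seeded random-sequence configuration (uniform composition by default)."""

    seed: int
    length: int
    composition: tuple = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if self.length < 1:
            raise StructureError("length must be >= 1")
        if abs(sum(self.composition) - 1.0) > 1e-9:
            raise StructureError("composition probabilities must sum to 1")


def random_rna(cfg: GeneratorConfig) -> RnaSequence:
    """An i.i.d. random sequence (0th-order model), deterministic per seed."""
    rng = np.random.default_rng(cfg.seed)
    draw = rng.choice(len(NUCLEOTIDES), size=cfg.length, p=list(cfg.composition))
    return RnaSequence(
        "".join(NUCLEOTIDES[k] for k in draw), id=f"random-{cfg.seed}"
    )


def random_structure(
    seq: RnaSequence, seed: int, theta: int = 3, rule=None
) -> SecondaryStructure:
    """A structure drawn uniformly from the enumerated ensemble of ``seq``.

    Enumeration-backed, so only usable at desk scale; intended for test
    references.
    """
    from .oracle import enumerate_structures
    from .rna_core import DEFAULT_RULE

    rule = rule if rule is not None else DEFAULT_RULE
    enum = enumerate_structures(seq, theta=theta, rule=rule)
    rng = np.random.default_rng(seed)
    return enum.structures[int(rng.integers(len(enum.structures)))]


def dinucleotide_shuffle(seq: RnaSequence, seed: int) -> RnaSequence:
    """Altschul-Erikson shuffle preserving the exact dinucleotide multiset.

    The sequence is viewed as an Eulerian path in the multigraph whose
    edges are its dinucleotides.  A random last-edge arborescence toward
    the final nucleotide is drawn (rejection sampling), the remaining
    out-edges are permuted, and the path is rewalked.  First and last
    nucleotides are invariant; output is deterministic given the seed.
    """
    s = seq.residues
    n = len(s)
    if n < 2:
        raise StructureError("dinucleotide shuffle needs n >= 2")
    if len(set(s)) == 1 or n == 2:
        return RnaSequence(s, id=f"{seq.id}|dishuffle-{seed}")
    rng = np.random.default_rng(seed)
    out_edges: dict[str, list[str]] = {}
    for a, b in zip(s, s[1:]):
        out_edges.setdefault(a, []).append(b)
    last = s[-1]
    vertices = [v for v in out_edges if v != last]

    while True:  # draw last edges until they form an arborescence toward `last`
        last_edge = {u: out_edges[u][int(rng.integers(len(out_edges[u])))]
                     for u in vertices}
        ok = True
        for u in vertices:
            seen = {u}
            v = last_edge[u]
            while v != last:
                if v in seen or v not in last_edge:
                    ok = False
                    break
                seen.add(v)
                v = last_edge[v]
            if not ok:
                break
        if ok:
            break

    ordered: dict[str, list[str]] = {}
    for u, edges in out_edges.items():
        pool = list(edges)
        if u != last:
            pool.remove(last_edge[u])
        perm = [pool[k] for k in rng.permutation(len(pool))]
        if u != last:
            perm.append(last_edge[u])
        ordered[u] = perm

    walk = [s[0]]
    cursor = {u: 0 for u in ordered}
    v = s[0]
    for _ in range(n - 1):
        nxt = ordered[v][cursor[v]]
        cursor[v] += 1
        walk.append(nxt)
        v = nxt
    return RnaSequence("".join(walk), id=f"{seq.id}|dishuffle-{seed}")


def embed_hairpin(
    cfg: GeneratorConfig, stem: int, loop: int, offset: int, theta: int = 3
):
    """Splice a perfect complementary stem-loop into a random background.

    Returns ``(sequence, target)`` where ``target`` is the hairpin's
    dot-bracket structure on the window ``[offset, offset + 2*stem +
    loop - 1]`` — the synthetic analogue of a structured element hidden
    in a genomic region, for exercising :func:`window_scan`.  The
    element is designed the way a structured positive control is: stem
    pairs are G-C/C-G (an A-U-only stem of this length would melt at
    37 C) and the loop is poly-A, which cannot pair against a G/C stem,
    so the hairpin has a unique register instead of slipped variants.
    """
    if loop < theta:
        raise StructureError(f"loop {loop} below the hairpin minimum theta={theta}")
    L = 2 * stem + loop
    if offset < 1 or offset + L - 1 > cfg.length:
        raise StructureError(
            f"hairpin window [{offset},{offset + L - 1}] outside 1..{cfg.length}"
        )
    rng = np.random.default_rng(cfg.seed)
    background = rng.choice(len(NUCLEOTIDES), size=cfg.length,
                            p=list(cfg.composition))
    chars = [NUCLEOTIDES[k] for k in background]
    five = [("G", "C")[int(k)] for k in rng.integers(0, 2, size=stem)]
    loop_part = ["A"] * loop
    three = [_COMPLEMENT[c] for c in reversed(five)]
    chars[offset - 1 : offset - 1 + L] = five + loop_part + three
    sequence = RnaSequence("".join(chars), id=f"hairpin-bg-{cfg.seed}")
    pairs = frozenset((k + 1, L - k) for k in range(stem))
    target = SecondaryStructure(pairs, L, theta)
    return sequence, target


def pearson(xs, ys) -> float:
    """Product-moment correlation of two equal-length vectors."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if len(xs) != len(ys) or len(xs) < 3:
        raise StructureError("pearson needs equal-length vectors with n >= 3")
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise StructureError("pearson undefined for zero-variance input")
    return float(np.corrcoef(xs, ys)[0, 1])
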