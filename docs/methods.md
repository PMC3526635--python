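# Methods

## Model

A secondary structure on an RNA sequence of length *n* is a set of base
pairs (i, j), 1 ≤ i < j ≤ n, such that each position pairs at most once,
no two pairs cross (pseudoknot-free), and every hairpin encloses at least
θ unpaired nucleotides (j − i > θ; default θ = 3).  Pairs are restricted
to the six Watson–Crick and wobble combinations AU/UA, CG/GC, GU/UG.
Base-pair distance d(S, T) is the size of the symmetric difference of the
two pair sets.  For a fixed reference S\*, the quantity of interest is
the distribution p(k) = Z_k/Z, where Z_k sums Boltzmann factors
e^(−E(S)/RT) over structures at distance exactly k and Z is the full
partition function.  Every reachable distance satisfies
k ≤ |S\*| + ⌊(n − θ)/2⌋ < n, since a structure holds at most
⌊(n − θ)/2⌋ pairs and d(S, S\*) ≤ |S| + |S\*|.

## The distance polynomial and its evaluation

Ẑ(x) = Σ_k Z_k x^k is a polynomial of degree < n.  Expanding it
symbolically costs an extra factor of n in time and space, so the package
instead evaluates Ẑ at fixed complex points by an interval dynamic
program in which every table entry is a scalar.  Entry (i, j) tracks the
distance to the *restriction* of S\* to [i, j].  Whenever a decomposition
step confines all further pairs to sub-intervals R_1…R_m of [i, j] and
introduces the pair set Q (empty or one pair), the distance gains

    delta = |Q \ S*| + |S*_[i,j]| − |Q ∩ S*| − Σ_k |S*_[R_k]|,

i.e. one for a novel pair plus one for every reference pair made
unrepresentable by the split; an introduced pair that belongs to S\*
costs nothing.  delta ≥ 0 always, and the pre-computed table
P[i, j] = |S\*_[i,j]| makes each delta an O(1) lookup.

For the per-pair (Nussinov–Jacobson) model the recursion is the classical
two-case split — position j unpaired, or paired to l — decorated with
x^delta factors.  For the nearest-neighbor model the same rule decorates
a McCaskill-style decomposition with three matrices (closed-pair ZB,
multiloop fragment ZM, single-branch ZM1) plus an exterior vector; loop
energies are hairpin(size) [+ closing penalty for non-GC pairs],
stack(outer, inner), bulge(size), internal(size, asymmetry), and an
affine multiloop a + b·branches + c·unpaired.  Interior loops are capped
at 30 unpaired nucleotides in the partition DP, the standard practice;
the single-structure energy evaluator prices larger loops by
Jacobson–Stockmayer extrapolation instead.  One evaluation point costs
O(n³) time and O(n²) space; the quadratic tables are reused across
points.  The inner loops are vectorized along anti-diagonals, with
x-powers looked up from precomputed tables indexed by the integer arrays
P.

## Coefficient recovery

The polynomial is evaluated at the m-th roots of unity ω^j (m defaults to
n, which always exceeds the degree bound).  Because the coefficients are
real, Ẑ(ω^(m−j)) = conj(Ẑ(ω^j)), so only ⌊m/2⌋+1 dynamic programs run;
the rest are filled by conjugation.  The normalized values Ẑ(ω^j)/Z —
all on the unit disc — are passed through the inverse DFT
(`numpy.fft.fft/m`), whose output is p(k) directly.  Interpolating the
*unnormalized* polynomial is numerically hopeless because Z grows
exponentially in n; normalizing first is the package's (and the
method's) stability mechanism.  Lagrange interpolation and Gaussian
elimination back-ends are deliberately not provided.

Recovered coefficients are validated before use: the largest imaginary
residual must be ≤ 1e−6 and the coefficient sum within 1e−6 of 1,
otherwise a `NumericalIntegrityError` is raised (such violations indicate
a defect, not round-off — observed residuals are ~1e−15).  Negative
round-off smaller in magnitude than 10^(−digits) is clamped to zero; the
vector is renormalized only if the clamped mass exceeds 10^(−digits).
Output probabilities are reported to `digits` decimal places (default 6);
full-precision values are retained internally, and all statistics
(mean, sd, cv) are computed from the full-precision vector.

The recovery's accuracy is *absolute*, not relative: each coefficient of
the normalized polynomial is obtained to roughly machine epsilon times
the number of evaluation points (~1e−15 in practice), so probabilities
are exact to many more than the reported decimal places, but a
coefficient smaller than that floor (e.g. p(0) for a reference whose
free energy is tens of kcal/mol above the ensemble) carries no relative
precision.  This is inherent to fixed-precision DFT recovery; the
package reports decimal places, matching that precision model.

## Ground truth and cross-checks

Three independent routes are compared on seeded random instances:
exhaustive enumeration (complete by the unpaired-or-paired-to-l case
split; feasible to n ≈ 30), the classical integer-indexed recursion that
convolves coefficient vectors over split points (per-pair model), and the
roots-of-unity pipeline.  Observed pairwise total-variation distances are
~1e−15 against test tolerances of 1e−8 (per-pair) and 1e−6
(nearest-neighbor).  Additional identities exercised on every instance:
Σ p(k) = 1 before truncation; p(k) ≈ 0 beyond the distance bound;
p(0)·Z = e^(−E(S\*)/RT) (the reference is its own only 0-neighbor); and
Ẑ(1) equals a deliberately independent scalar McCaskill implementation
without distance bookkeeping to 1e−10 relative error up to n = 60.

## Parameters

| parameter | default | meaning |
|---|---|---|
| θ | 3 | minimum unpaired nucleotides in a hairpin |
| ε | −1 kcal/mol | per-pair energy, Nussinov model |
| R | 0.0019872 kcal/(mol·K) | gas constant |
| T | 310.15 K | temperature (37 °C) |
| m | n | number of roots of unity |
| digits | 6 | reported decimal places |
| interior-loop cap | 30 | largest bulge+internal size in the DP |

The bundled nearest-neighbor table (`data/turner_params.txt`) carries
Turner-99-like stack energies for the six pair types, loop-length tables
with Jacobson–Stockmayer extrapolation beyond the largest tabulated size,
a Ninio-style asymmetry penalty, and the affine multiloop model.  Dangles,
coaxial stacking and special hairpin bonuses are omitted.  The table is a
self-consistent nearest-neighbor instance — the same energy function
drives the DP, the enumeration oracle and the MFE folder — and makes no
claim of bit-compatibility with any published parameter dialect; every
correctness statement in the test suite is model-internal.  `--param-file`
substitutes a user table in the same plain-text format.

## Synthetic data

`random_rna` draws i.i.d. nucleotides (uniform composition by default),
matching the 0th-order random-sequence benchmark conditions.
`dinucleotide_shuffle` implements the Altschul–Erikson algorithm
(last-edge arborescence over the dinucleotide multigraph, rejection-
sampled, then a permuted Eulerian walk), preserving the exact
dinucleotide multiset and both terminal nucleotides; degenerate inputs
(homopolymers, n = 2) return the input unchanged.

`embed_hairpin` splices a perfect stem-loop into a random background for
the moving-window localization experiment.  The element is designed the
way a wet-lab positive control would be: stem pairs are drawn from
G-C/C-G, because a 5-bp A/U stem melts at 37 °C and an unstable "element"
cannot be localized by any method; the loop is poly-A, which cannot pair
against a G/C stem, so the hairpin has a unique pairing register rather
than a family of slipped variants.  The generator emulates a single
structured element in otherwise unstructured sequence; it does not
emulate multi-domain structures, sequence composition bias, or elements
whose stability rivals the detection threshold, so the localization test
demonstrates sensitivity to clearly-folded elements, not a detection
limit.

Two thiamine-pyrophosphate riboswitch aptamers from the Rfam RF00059 seed
alignment (97 nt and 99 nt) are bundled as fixed realistic inputs for the
shuffle control and for ensemble pair-count statistics.

## Scope of the test suite

Correctness tolerances are enumerated above.  Problem sizes: oracle
comparisons use n ∈ [8, 25] (per-pair) and [8, 20] (nearest-neighbor),
where exhaustive enumeration is exact ground truth; the partition-function
cross-check runs to n = 60; scan localization uses 100 replicates of a
120-nt background; the acceptance script reproduces the same quantities
at moderately reduced replicate counts.  The pipeline itself has no such
limits — the bundled ~100-nt aptamer profiles run in seconds to minutes —
but tolerances quoted here are only *verified* at the stated sizes.

## Known limitations

* No pseudoknots, modified nucleotides, or alignment-level consensus
  structures.
* The nearest-neighbor model is a compact dialect (no dangles, coaxial
  stacks, or tetraloop bonuses); absolute free energies will differ from
  full Turner-2004 implementations, though all internal identities hold
  under any parameter table supplied in the same format.
* The method recovers only the probabilities p(k); it cannot produce the
  minimum-energy structure within a distance class, nor sample structures
  from a distance class.
* Bimodality of profiles is not auto-detected; scans and prefix profiles
  are emitted raw for visual or downstream analysis.
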