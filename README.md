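# fftbor

Boltzmann distance profiles of RNA secondary-structure ensembles.

Given an RNA sequence **s** and a fixed reference secondary structure
*S\**, this package computes the probabilities

&nbsp;&nbsp;&nbsp;&nbsp;*p(k) = Z<sub>k</sub> / Z*

that a structure drawn from the Boltzmann ensemble of **s** lies at base-pair
distance *k* from *S\**, where *Z<sub>k</sub>* is the sum of Boltzmann factors
e<sup>−E(S)/RT</sup> over structures *S* with *d(S, S\*) = k* and
*Z = Σ<sub>k</sub> Z<sub>k</sub>* is the partition function.  The vector
*p(0), p(1), …* is a one-dimensional projection of the energy landscape
around *S\**: a second peak away from *k = 0* flags a competing metastable
structure, which is the signature of a conformational switch such as a
riboswitch expression platform.

Computing every *Z<sub>k</sub>* directly costs *O(n⁵)* time and *O(n³)*
space.  Instead, the package treats

&nbsp;&nbsp;&nbsp;&nbsp;*Ẑ(x) = Σ<sub>k</sub> Z<sub>k</sub> x<sup>k</sup>*

as a polynomial of degree < *n*, evaluates *Ẑ* at the *m*-th complex roots
of unity by an *O(n³)*-time, *O(n²)*-space dynamic program per point, and
recovers the coefficients of *Ẑ(x)/Z* — the probabilities themselves — with
the inverse discrete Fourier transform: *O(n⁴)* time, *O(n²)* space in
total.  Normalizing by *Z* before the transform keeps all inputs on the unit
scale, which is what makes the recovery numerically stable; because the
coefficients are real, values at conjugate roots are conjugate, and only
⌊m/2⌋+1 evaluations are run.

Two energy models are provided: the Nussinov–Jacobson per-pair model
(ε kcal/mol per pair) and a nearest-neighbor (Turner-style) loop model with
hairpin/stack/bulge/internal/multiloop terms.  An exhaustive enumeration
oracle and the classical integer-*k* recursion provide independent ground
truth at small *n*.

## Worked example

The sequence `GAAAC` admits exactly two structures: the empty one and the
single pair (1,5).  With the per-pair model at ε = −1, RT = 1, the pair
carries Boltzmann weight *e*, so *p(0) = 1/(1+e) ≈ 0.268941* and
*p(1) = e/(1+e) ≈ 0.731059* relative to the empty reference:

```sh
$ fftbor --quiet --seq GAAAC --struct "....." --model nussinov \
    --temperature 503.2189 --epsilon -1
# sequence: seq
# reference: .....
# model: nussinov
# theta: 3
# RT: 0.9999965980800001
# Z: 3.7182910758835517
# distance_bound: 1
# max_imag_residual: 0.0
# digits: 6
k	p_k
0	0.268941
1	0.731059
```

(`--temperature 503.2189` sets RT = R·T = 1 for hand-checkable numbers;
the default is 37 °C.)  Choosing the reference `(...)` instead swaps the two
probabilities.  Subcommands `scan` (moving-window expected distance to a
target structure), `prefix` (profiles of all prefixes against their own MFE
structures), `oracle-compare`, `shuffle` (Altschul–Erikson dinucleotide
shuffle) and `random` cover the application workflows; see `fftbor --help`.

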