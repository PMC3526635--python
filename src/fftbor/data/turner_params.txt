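# Nearest-neighbor free-energy parameters, kcal/mol at 37 C.
# version 1 -- compact table: stacks for the six admissible pair types,
# loop-length tables with Jacobson-Stockmayer extrapolation beyond the
# largest tabulated size, affine multiloop model.  Dangles, coaxial
# stacking and special hairpin bonuses are intentionally absent.
#
# stack <outer 5'i-3'j pair> <inner pair> <dG>
stack AU AU -0.9
stack AU CG -2.2
stack AU GC -2.1
stack AU UA -1.1
stack AU GU -0.6
stack AU UG -1.4
stack CG AU -2.1
stack CG CG -3.3
stack CG GC -2.4
stack CG UA -2.1
stack CG GU -1.4
stack CG UG -2.1
stack GC AU -2.4
stack GC CG -3.4
stack GC GC -3.3
stack GC UA -2.2
stack GC GU -1.5
stack GC UG -2.5
stack UA AU -1.3
stack UA CG -2.4
stack UA GC -2.1
stack UA UA -0.9
stack UA GU -1.0
stack UA UG -1.3
stack GU AU -1.3
stack GU CG -2.5
stack GU GC -2.1
stack GU UA -1.4
stack GU GU -0.5
stack GU UG 1.3
stack UG AU -1.0
stack UG CG -1.5
stack UG GC -1.4
stack UG UA -0.6
stack UG GU 0.3
stack UG UG -0.5
# hairpin <loop size> <dG>
hairpin 3 5.4
hairpin 4 5.6
hairpin 5 5.7
hairpin 6 5.4
hairpin 7 6.0
hairpin 8 5.5
hairpin 9 6.4
# bulge <loop size> <dG>
bulge 1 3.8
bulge 2 2.8
bulge 3 3.2
bulge 4 3.6
bulge 5 4.0
bulge 6 4.4
# internal <total unpaired (both sides)> <dG>
internal 2 1.5
internal 3 1.6
internal 4 1.7
internal 5 2.0
internal 6 2.0
internal 7 2.3
internal 8 2.5
internal 9 2.6
# multiloop affine model: a + b * branches + c * unpaired
ml_a 3.4
ml_b 0.4
ml_c 0.0
# internal-loop asymmetry penalty per unit |n1 - n2|, capped
ninio 0.5
ninio_max 3.0
# penalty for a hairpin closed by a non-CG/GC pair
terminal_au_hairpin 0.5
# Jacobson-Stockmayer extrapolation coefficient (1.75 * R * 310.15)
js_coef 1.07856
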