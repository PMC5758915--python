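# Default nearest-neighbor free-energy parameters (kcal/mol, 37 C scale).
# Simplified model: Watson-Crick/wobble stack increments, logarithmic
# hairpin and internal/bulge loop penalties, linear multibranch term.
# Stack keys: outer pair (i,j) then inner pair (i+1, j-1), 5'->3' strand
# letters on each pair.

[stacks]
AU AU -0.9
AU UA -1.1
AU GC -2.2
AU CG -2.1
AU GU -0.6
AU UG -1.4
UA AU -1.3
UA UA -0.9
UA GC -2.4
UA CG -2.1
UA GU -1.0
UA UG -1.3
GC AU -2.1
GC UA -2.2
GC GC -3.3
GC CG -3.4
GC GU -1.5
GC UG -2.5
CG AU -2.1
CG UA -2.4
CG GC -3.3
CG CG -3.3
CG GU -2.1
CG UG -2.1
GU AU -1.4
GU UA -1.3
GU GC -2.5
GU CG -2.1
GU GU -0.5
GU UG -0.4
UG AU -0.6
UG UA -1.0
UG GC -1.5
UG CG -2.1
UG GU 0.3
UG UG -0.5

[hairpin]
base 5.4
log_coeff 1.08

[internal]
base 3.2
log_coeff 1.08

[multibranch]
offset 3.4
per_branch 0.4
per_unpaired 0.1

[general]
min_hairpin 3
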