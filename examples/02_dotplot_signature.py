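"""The dot-matrix signature of a block-order flip.

Plotting ancestral (X) against derivative (Y), a circular-intermediate
duplication shows two parallel slope-+1 diagonals with offsets of opposite
sign, because the two block halves swap order without changing strand.  A
plain copy shows a single main diagonal and an inversion shows slope -1.
"""

import numpy as np

from cdip import dot_matrix, classify_pattern, render_dotplot

rng = np.random.default_rng(7)
rand = lambda n: "".join(rng.choice(list("ACGT"), size=n))

ab, cd = rand(3_000), rand(2_000)
ancestral = ab + cd
derivative = cd + ab  # the circle opened between B and C

matrix = dot_matrix(ancestral, derivative, k=16)
call = classify_pattern(matrix)
offsets = sorted(r.y_start - r.x_start for r in call.runs_used)
print(f"pattern: {call.label}; run offsets {offsets} "
      f"(one +|CD| = +{len(cd)}, one -|AB| = -{len(ab)})")
print(f"axis coverage: x {call.coverage_x:.2f}, y {call.coverage_y:.2f}")

render_dotplot(matrix, "flip_dotplot.png")
print("wrote flip_dotplot.png — the two parallel slanted lines are the flip signature")
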