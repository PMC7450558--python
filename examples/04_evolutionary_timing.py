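"""Polarize a duplication pair and date it on the primate ladder.

The locus present in more outgroup species is the ancestral copy; the
duplication age is bracketed by the nearest species lacking the derivative
(e.g. absent from chimpanzee outward means human-specific).
"""

from cdip import make_presence_table, polarize, closest_without_derivative

for branch in ("chimpanzee", "gorilla", "marmoset"):
    table = make_presence_table(branch, unknown_rate=0.0)
    pol = polarize(table)
    origin = closest_without_derivative(table)
    age = {"chimpanzee": "human-specific",
           "gorilla": "human-chimp ancestor",
           "marmoset": "old/new-world monkey ancestor"}[branch]
    print(f"derivative absent from {origin} outward -> {age} "
          f"(ancestral = locus {pol['ancestral']})")

# Unknown entries (assembly gaps) are skipped, never read as absence:
sparse = make_presence_table("gibbon", unknown_rate=0.1, seed=3)
print("with 10% unknowns:", closest_without_derivative(sparse, derivative_locus=2))
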