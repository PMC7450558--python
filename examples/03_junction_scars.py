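"""Resolve breakpoint junctions at single-nucleotide level.

Each junction read (derivative sequence spanning a breakpoint) is split
between its left and right references by minimizing mismatches plus gap
penalties.  The scar vocabulary: blunt join, 1-2 bp junctional
microhomology, short untemplated insertion, or flank deletion — the repair
signatures of NHEJ / MMBIR-like mechanisms.
"""

from cdip import Scar, simulate_junction, resolve_junction

cases = {
    "blunt (directly adjacent nucleotides)": Scar(),
    "2 bp junctional microhomology": Scar(mh=2),
    "1 nt untemplated insertion": Scar(ins="G"),
    "13 bp flank deletion": Scar(del_left=13),
}

for label, scar in cases.items():
    junction, truth = simulate_junction(scar, flank=150, divergence=0.01, seed=11)
    resolved = resolve_junction(junction)
    print(f"{label}:")
    print(f"  resolved as {resolved.scar_class}: mh={resolved.mh_len} "
          f"ins={resolved.ins_seq!r} del_left={resolved.del_left_bp} "
          f"del_right={resolved.del_right_bp} "
          f"(flank mismatches from divergence: {resolved.alignment_mismatches})")
# Exact recovery of the drawn scar shows the split-point optimization can
# read back the repair signature despite 1% post-duplication divergence.
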