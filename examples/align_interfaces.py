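"""Align pairs of synthetic interfaces and interpret the PC-score.

Generates a seeded interface, compares it against itself, against a
rigidly moved copy, and against an unrelated interface, printing the
score components for each comparison.
"""

import pcalign as pc

iface = pc.generate_synthetic_interface(pc.FixtureSpec(n_per_fragment=20, seed=1))
print(f"interface: {iface.id} with {iface.n_a}+{iface.n_b} residues")


def report(label, result):
    print(f"{label:>12}: PC-score {result.pc:.4f} (raw {result.pc_raw:.4f}, "
          f"f_c {result.f_c:.3f}), {result.l_ali} pairs aligned, "
          f"coverage {result.coverage:.2f}, RMSD {result.rmsd:.4f} A")


# identical interfaces score exactly 1 - the normalization anchor
report("self", pc.align_and_score(iface, iface))

# a rigid motion changes nothing the score can see: the pipeline recovers
# the transform and the score stays at 1
moved, truth = pc.apply_random_rigid(iface, seed=7)
result = pc.align_and_score(iface, moved)
report("rigid copy", result)
ang, shift = result.transform.distance_to(truth.inverse())
print(f"              recovered transform within {ang:.2e} deg / {shift:.2e} A")

# an unrelated interface of the same size lands near the random
# background (PC-score ~0.3-0.4): geometry can always be partially
# matched, but contacts and chemistry do not line up
other = pc.generate_synthetic_interface(pc.FixtureSpec(n_per_fragment=20, seed=99))
report("unrelated", pc.align_and_score(iface, other))
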