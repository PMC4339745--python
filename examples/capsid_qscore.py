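"""Q-score: comparing interfaces formed by copies of one protein.

In icosahedral capsids with T > 1, chemically identical subunits form
several distinct ("quasi-equivalent") interfaces.  Because both partners
share one sequence, each interface reduces to an N x N contact map over
residue positions, and two interfaces compare through the normalized
inner product of their maps.
"""

import numpy as np

import pcalign as pc
from pcalign.qscore import CapsidContactMap

# a small synthetic dimer stands in for one inter-subunit interface
cplx = pc.make_synthetic_complex(n_per_chain=12, seed=2)
a = pc.capsid_contact_map(cplx, "A", "B")
print(f"contact map: {a.n}x{a.n}, {int(a.map.sum())} contacts")

# identical interfaces -> Q = 1
print(f"Q(identical)  = {pc.q_score(a, a):.3f}")

# a slightly different interaction mode: shift some contacts
rng = np.random.default_rng(5)
m = a.map.copy()
occupied = np.argwhere(m)
for i, j in occupied[: len(occupied) // 2]:
    m[i, j] = False
    m[(i + 3) % a.n, (j + 3) % a.n] = True
b = CapsidContactMap(a.n, m)
print(f"Q(perturbed)  = {pc.q_score(a, b):.3f}   # half the contacts moved")

# no shared contacts -> Q = 0
c = CapsidContactMap(a.n, ~a.map & (rng.random((a.n, a.n)) < 0.1))
print(f"Q(disjoint)   = {pc.q_score(a, c):.3f}")
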