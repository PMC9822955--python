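"""Add-While-Truncate construction of a complete-basis-set (CBS) limit.

Starting from H2 in 6-31G**, each cycle (i) runs a short RT-TDHF
propagation and removes shells that are unimportant on both indicators,
(ii) appends one even-tempered diffuse function to every surviving
l-channel (alpha_{k+1} = alpha_k^2 / alpha_{k-1}), and (iii) checks the
smallest overlap eigenvalue |lambda|_min. The loop stops when the basis
reaches overcompleteness (|lambda|_min < epsilon, newest high-l diffuse
shells pruned, one confirming run) or a fixed point.
"""

import numpy as np

from aotrunc import add_while_truncate, load_basis
from aotrunc.cbs import RTParams
from aotrunc.geometry import MolecularGeometry

h2 = MolecularGeometry(("H", "H"), np.array([[0, 0, -0.7], [0, 0, 0.7]]))
result = add_while_truncate(
    h2, load_basis("6-31G**"),
    xthr=0.1, epsilon=1e-6,
    rt_params=RTParams(n_steps=100, dt=0.2, kappa=(0, 0, 1e-3)),
)

print(f"termination: {result.termination} after {len(result.cycles)} cycles")
for c in result.cycles:
    print(
        f"  cycle {c.index}: {c.composition}  N_AO={c.n_ao:3d}  "
        f"deleted={c.n_deleted}  added={c.added or '-'}  "
        f"removed={c.removed or '-'}  min|eig S|={c.min_eig:.2e}"
    )
print(
    f"final min |eig S| = {result.final_min_eig:.2e} vs epsilon = "
    f"{result.epsilon:.0e}; the final basis is the epsilon-complete set "
    "for this spectrum calculation."
)
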