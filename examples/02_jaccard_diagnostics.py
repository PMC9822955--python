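"""Jaccard diagnostics of the two truncation criteria across thresholds.

J(x^thr) compares the deletion sets proposed by x^DC alone and x^IP alone.
For the H2 dimer, the unpolarized bases (6-31G, 6-31++G) contain no jointly
redundant functions: both sets stay empty and J = 0 up to large thresholds.
The polarized bases agree perfectly on the p_x/p_y functions at small
thresholds (J = 1) and disagree only where p_z and the diffuse s straddle
the threshold.
"""

import numpy as np

from aotrunc import (
    compute_integrals,
    indicators_from_trace,
    jaccard_curve,
    load_basis,
    make_h2_dimer,
    propagate,
    scf_rhf,
)
from aotrunc.rtp import PulseSpec

geom = make_h2_dimer()
grid = np.arange(0.01, 1.0001, 0.01)

for name in ("6-31G", "6-31G**", "6-31++G", "6-31++G**"):
    ints = compute_integrals(geom, load_basis(name))
    scf = scf_rhf(geom, ints=ints)
    trace = propagate(scf, ints, PulseSpec.along("z", 1e-3), 100, 0.2)
    xdc, xip = indicators_from_trace(trace, ints.S)
    J = jaccard_curve(xdc, xip, grid)
    print(
        f"{name:10s} N_AO={ints.n_ao:2d}  J(0.05)={J[4]:.2f}  "
        f"J(0.5)={J[49]:.2f}  min J={J.min():.2f}  max J={J.max():.2f}"
    )
print(
    "\nJ = 0 means the two criteria propose disjoint (here: empty) deletion "
    "sets; J = 1 means they agree exactly."
)
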