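"""Compute the two truncation indicators for the H2 dimer in 6-31G**.

A 100-step delta-pulse RT-TDHF run (1% of a production propagation)
yields per-AO x^DC (density-contribution variation) and x^IP
(MO-coefficient variation). Functions below the threshold on BOTH
indicators are truncation candidates: here the eight p_x/p_y polarization
functions, which cannot couple to a z-polarized pulse.
"""

from aotrunc import (
    compute_integrals,
    export_map,
    indicators_from_trace,
    load_basis,
    make_h2_dimer,
    propagate,
    scf_rhf,
    select_truncation,
)
from aotrunc.rtp import PulseSpec

geom = make_h2_dimer()          # two H2, bonds along z, 6 Bohr apart in x
basis = load_basis("6-31G**")   # 2s1p per H -> 20 AO functions

ints = compute_integrals(geom, basis)
scf = scf_rhf(geom, ints=ints)
print(f"RHF energy: {scf.energy:.8f} Hartree ({ints.n_ao} AOs)")

trace = propagate(scf, ints, PulseSpec.along("z", 1e-3), 100, 0.2)
xdc, xip = indicators_from_trace(trace, ints.S)
report = select_truncation(xdc, xip, xthr=0.1, labels=ints.labels)

print(export_map(report)[["label", "xdc", "xip", "kept"]].to_string(index=False))
print(
    f"\n{report.n_deleted} of {report.n_ao} functions fall below "
    f"x^thr = {report.xthr} on both indicators and can be removed; "
    "they are the p_x/p_y functions whose transitions a z pulse cannot drive."
)
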