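"""Shared fixtures: the computationally heavy pieces (integrals, SCF,
indicator propagations) are session-scoped so the suite builds each of
them exactly once."""

from __future__ import annotations

import numpy as np
import pytest

from aotrunc import (
    compute_integrals,
    indicators_from_trace,
    load_basis,
    make_h2_dimer,
    propagate,
    scf_rhf,
)
from aotrunc.basis import AOBasisSet, BasisShell
from aotrunc.geometry import MolecularGeometry
from aotrunc.rtp import PulseSpec


@pytest.fixture(scope="session")
def h2_dimer():
    return make_h2_dimer()


@pytest.fixture(scope="session")
def minimal_h_basis():
    """One normalized s primitive (alpha = 1) per H atom."""
    return AOBasisSet("min-s", {"H": (BasisShell("H", 0, (1.0,), (1.0,)),)})


@pytest.fixture(scope="session")
def h2_monomer():
    return MolecularGeometry(
        ("H", "H"), np.array([[0.0, 0.0, -0.7], [0.0, 0.0, 0.7]])
    )


@pytest.fixture(scope="session")
def h2_631g_system(h2_monomer):
    """Small workhorse system: H2 monomer in 6-31G (4 AOs)."""
    ints = compute_integrals(h2_monomer, load_basis("6-31G"))
    scf = scf_rhf(h2_monomer, ints=ints)
    return h2_monomer, ints, scf


@pytest.fixture(scope="session")
def indicator_runs(h2_dimer):
    """The four H2-dimer indicator propagations of the study conditions:
    z-polarized delta pulse (1e-3 a.u.), 100 ETRS steps at dt = 0.2 a.u."""
    pulse = PulseSpec.along("z", 1e-3)
    out = {}
    for name in ("6-31G", "6-31G**", "6-31++G", "6-31++G**"):
        ints = compute_integrals(h2_dimer, load_basis(name))
        scf = scf_rhf(h2_dimer, ints=ints)
        trace = propagate(scf, ints, pulse, 100, 0.2, record="orbitals")
        xdc, xip = indicators_from_trace(trace, ints.S)
        out[name] = {
            "ints": ints, "scf": scf, "trace": trace,
            "xdc": xdc, "xip": xip, "labels": ints.labels,
        }
    return out
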