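"""Restricted Hartree-Fock ground state and the time-dependent Fock build.

The Fock builder accepts complex Hermitian densities, as required by the
real-time propagation layer: F[P] = Hcore + J[P] - K[P]/2 with the
exchange contraction K_mn = sum_ls P_ls (ml|sn) (chemist-order ERIs).
A caller-supplied Fock builder can be passed to the propagation layer
instead, so a different mean-field backend could be plugged in; only the
Hartree-Fock build is implemented and tested here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import AOBasisSet
from .geometry import MolecularGeometry
from .integrals import IntegralSet, compute_integrals


class SCFConvergenceError(RuntimeError):
    pass


@dataclass
class SCFResult:
    """Converged restricted closed-shell ground state."""

    C: np.ndarray            # (N_AO, N_MO) real MO coefficients
    mo_energy: np.ndarray
    occupations: np.ndarray  # f_i: 2 for occupied, 0 for virtual
    energy: float            # total energy (Hartree), nuclear repulsion included
    converged: bool
    n_iter: int

    @property
    def n_occ(self) -> int:
        return int(np.sum(self.occupations > 0))

    def density(self) -> np.ndarray:
        """AO density P = C f C^dagger."""
        return (self.C * self.occupations[None, :]) @ self.C.conj().T


def coulomb(P: np.ndarray, eri: np.ndarray) -> np.ndarray:
    return np.einsum("mnls,ls->mn", eri, P, optimize=True)


def exchange(P: np.ndarray, eri: np.ndarray) -> np.ndarray:
    # K_mn = sum_ls P_ls <ms|ln> = sum_ls P_ls (ml|sn)
    return np.einsum("mlsn,ls->mn", eri, P, optimize=True)


def build_fock(P: np.ndarray, ints: IntegralSet) -> np.ndarray:
    """Hartree-Fock matrix for a (possibly complex) Hermitian density."""
    if P.shape != ints.S.shape:
        raise ValueError(f"density shape {P.shape} != overlap {ints.S.shape}")
    if ints.eri is None:
        raise ValueError("IntegralSet was built without two-electron integrals")
    jm, km = ints.jk_matrices()
    n = ints.n_ao
    p = P.reshape(n * n)
    J = (jm @ p).reshape(n, n)
    K = (km @ p).reshape(n, n)
    return ints.hcore + J - 0.5 * K


def hf_energy(P: np.ndarray, F: np.ndarray, ints: IntegralSet) -> float:
    """Total HF energy 0.5 Tr[P (Hcore + F)] + E_nuc (real part)."""
    e_elec = 0.5 * np.einsum("mn,nm->", P, ints.hcore + F)
    return float(np.real(e_elec)) + ints.enuc


def scf_rhf(
    geom: MolecularGeometry,
    basis: AOBasisSet | None = None,
    ints: IntegralSet | None = None,
    conv_tol: float = 1e-10,
    max_iter: int = 200,
    diis_size: int = 8,
) -> SCFResult:
    """Converge the restricted HF ground state with DIIS acceleration.

    Convergence is on the Frobenius norm of the density change between
    iterations (default 1e-10).
    """
    if ints is None:
        if basis is None:
            raise ValueError("either basis or ints must be given")
        ints = compute_integrals(geom, basis)
    geom.require_closed_shell()
    n_occ = geom.n_electrons // 2
    N = ints.n_ao
    if n_occ > N:
        raise ValueError(f"{geom.n_electrons} electrons need more than {N} AOs")

    X, _ = ints.lowdin()

    def diag(F):
        Fo = X @ F @ X
        eps, Co = np.linalg.eigh(Fo)
        return eps, X @ Co

    occ = np.zeros(N)
    occ[:n_occ] = 2.0
    eps, C = diag(ints.hcore)
    P = (C * occ[None, :]) @ C.T

    errs: list[np.ndarray] = []
    focks: list[np.ndarray] = []
    delta = np.inf
    for it in range(1, max_iter + 1):
        F = build_fock(P, ints)
        # DIIS on the orthogonalized gradient FPS - SPF
        err = X @ (F @ P @ ints.S - ints.S @ P @ F) @ X
        errs.append(err)
        focks.append(F)
        if len(errs) > diis_size:
            errs.pop(0)
            focks.pop(0)
        if len(errs) > 1:
            m = len(errs)
            B = -np.ones((m + 1, m + 1))
            B[m, m] = 0.0
            for i in range(m):
                for j in range(m):
                    B[i, j] = np.real(np.vdot(errs[i], errs[j]))
            rhs = np.zeros(m + 1)
            rhs[m] = -1.0
            try:
                w = np.linalg.solve(B, rhs)[:m]
                F = sum(wi * Fi for wi, Fi in zip(w, focks))
            except np.linalg.LinAlgError:
                pass
        eps, C = diag(F)
        P_new = (C * occ[None, :]) @ C.T
        delta = float(np.linalg.norm(P_new - P))
        P = P_new
        if delta < conv_tol:
            F = build_fock(P, ints)
            eps, C = diag(F)
            P = (C * occ[None, :]) @ C.T
            return SCFResult(
                C=C, mo_energy=eps, occupations=occ,
                energy=hf_energy(P, F, ints), converged=True, n_iter=it,
            )
    raise SCFConvergenceError(
        f"SCF not converged in {max_iter} iterations (last ||dP|| = {delta:.3e})"
    )
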