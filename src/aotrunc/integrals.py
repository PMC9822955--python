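"""One- and two-electron integrals over contracted spherical Gaussians.

McMurchie-Davidson scheme: Cartesian Gaussian products are expanded in
Hermite Gaussians, Coulomb integrals reduce to Boys-function recursions,
and Cartesian blocks are contracted to real-spherical-harmonic AOs.
Every contracted AO is normalized to unit self-overlap at the end, so the
matrices refer to the conventional unit-normalized spherical AO basis.

This module is the only place the package touches integral numerics;
everything downstream consumes the :class:`IntegralSet` contract.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import hyp1f1

from .basis import AOBasisSet, AOFunctionLabel, expand, m_values
from .geometry import MolecularGeometry


class OvercompletenessWarning(UserWarning):
    """Overlap matrix close to singular: the basis is (nearly) linearly
    dependent; carried minimum |eigenvalue| in the message."""


class IntegralError(ValueError):
    pass


# ---------------------------------------------------------------------------
# low-level pieces

def boys(n: int, x: np.ndarray | float) -> np.ndarray | float:
    """Boys function F_n(x) via the confluent hypergeometric identity."""
    return hyp1f1(n + 0.5, n + 1.5, -np.asarray(x, dtype=float)) / (2 * n + 1)


def cart_components(l: int) -> list[tuple[int, int, int]]:
    return [
        (lx, ly, l - lx - ly)
        for lx in range(l, -1, -1)
        for ly in range(l - lx, -1, -1)
    ]


def _primitive_norm(alpha: float, l: int) -> float:
    # radial norm shared by all members of a solid-harmonic shell
    dfact = 1.0
    for k in range(2 * l - 1, 0, -2):
        dfact *= k
    return (2 * alpha / math.pi) ** 0.75 * (4 * alpha) ** (l / 2.0) / math.sqrt(dfact)


def _e_table(la: int, lb: int, a: float, b: float, ax: float, bx: float) -> np.ndarray:
    """Hermite expansion coefficients E[i, j, t] for one Cartesian direction,
    i <= la, j <= lb, t <= i + j."""
    p = a + b
    mu = a * b / p
    xab = ax - bx
    px = (a * ax + b * bx) / p
    xpa, xpb = px - ax, px - bx
    E = np.zeros((la + 1, lb + 1, la + lb + 2))
    E[0, 0, 0] = math.exp(-mu * xab * xab)
    for i in range(la):
        for t in range(i + 2):
            E[i + 1, 0, t] = (
                (E[i, 0, t - 1] / (2 * p) if t > 0 else 0.0)
                + xpa * E[i, 0, t]
                + (t + 1) * E[i, 0, t + 1]
            )
    for j in range(lb):
        for i in range(la + 1):
            for t in range(i + j + 2):
                E[i, j + 1, t] = (
                    (E[i, j, t - 1] / (2 * p) if t > 0 else 0.0)
                    + xpb * E[i, j, t]
                    + (t + 1) * E[i, j, t + 1]
                )
    return E


def _hermite_coulomb(tmax: int, umax: int, vmax: int, p: float, pc: np.ndarray) -> np.ndarray:
    """Hermite Coulomb integrals R^0_{tuv}(p, PC) as an array."""
    L = tmax + umax + vmax
    x = p * float(pc @ pc)
    F = np.array([boys(n, x) for n in range(L + 1)], dtype=float)
    memo: dict[tuple[int, int, int, int], float] = {}

    def R(t: int, u: int, v: int, n: int) -> float:
        if t < 0 or u < 0 or v < 0:
            return 0.0
        key = (t, u, v, n)
        if key in memo:
            return memo[key]
        if t == u == v == 0:
            val = (-2.0 * p) ** n * F[n]
        elif t > 0:
            val = (t - 1) * R(t - 2, u, v, n + 1) + pc[0] * R(t - 1, u, v, n + 1)
        elif u > 0:
            val = (u - 1) * R(t, u - 2, v, n + 1) + pc[1] * R(t, u - 1, v, n + 1)
        else:
            val = (v - 1) * R(t, u, v - 2, n + 1) + pc[2] * R(t, u, v - 1, n + 1)
        memo[key] = val
        return val

    out = np.empty((tmax + 1, umax + 1, vmax + 1))
    for t in range(tmax + 1):
        for u in range(umax + 1):
            for v in range(vmax + 1):
                out[t, u, v] = R(t, u, v, 0)
    return out


# ---------------------------------------------------------------------------
# real solid harmonics (Cartesian polynomial expansion, built by recursion)

def _poly_mul_linear(poly: dict, axis: int, scale: float) -> dict:
    out: dict[tuple[int, int, int], float] = {}
    for mono, c in poly.items():
        key = list(mono)
        key[axis] += 1
        out[tuple(key)] = out.get(tuple(key), 0.0) + c * scale
    return out


def _poly_add(*polys) -> dict:
    out: dict[tuple[int, int, int], float] = {}
    for poly in polys:
        for mono, c in poly.items():
            out[mono] = out.get(mono, 0.0) + c
    return {k: v for k, v in out.items() if abs(v) > 1e-300}


def _poly_scale(poly: dict, s: float) -> dict:
    return {k: v * s for k, v in poly.items()}


def _poly_mul_r2(poly: dict) -> dict:
    return _poly_add(
        _poly_mul_linear(_poly_mul_linear(poly, 0, 1.0), 0, 1.0),
        _poly_mul_linear(_poly_mul_linear(poly, 1, 1.0), 1, 1.0),
        _poly_mul_linear(_poly_mul_linear(poly, 2, 1.0), 2, 1.0),
    )


def _solid_harmonics_up_to(lmax: int) -> list[dict[int, dict]]:
    """tables[l][m] = {(lx,ly,lz): coeff} for real solid harmonics."""
    tables: list[dict[int, dict]] = [{0: {(0, 0, 0): 1.0}}]
    for l in range(lmax):
        cur, prev = tables[l], tables[l - 1] if l >= 1 else None
        nxt: dict[int, dict] = {}
        diag = math.sqrt((2.0 if l == 0 else 1.0) * (2 * l + 1) / (2 * l + 2))
        s_ll = cur[l]
        s_lml = cur[-l] if l > 0 else {}
        nxt[l + 1] = _poly_scale(
            _poly_add(_poly_mul_linear(s_ll, 0, 1.0),
                      _poly_scale(_poly_mul_linear(s_lml, 1, 1.0), -1.0)),
            diag,
        )
        nxt[-(l + 1)] = _poly_scale(
            _poly_add(_poly_mul_linear(s_ll, 1, 1.0),
                      _poly_mul_linear(s_lml, 0, 1.0)),
            diag,
        )
        for m in range(-l, l + 1):
            num = _poly_scale(_poly_mul_linear(cur[m], 2, 1.0), float(2 * l + 1))
            fac = math.sqrt(float((l + m) * (l - m)))
            if fac != 0.0 and prev is not None:
                num = _poly_add(num, _poly_scale(_poly_mul_r2(prev[m]), -fac))
            nxt[m] = _poly_scale(
                num, 1.0 / math.sqrt(float((l + 1 + m) * (l + 1 - m)))
            )
        tables.append(nxt)
    return tables


def spherical_transform(l: int) -> np.ndarray:
    """Matrix (2l+1, n_cart) mapping Cartesian monomial Gaussians to the
    canonical real-spherical AO order of :func:`aotrunc.basis.m_values`."""
    table = _solid_harmonics_up_to(l)[l]
    carts = cart_components(l)
    T = np.zeros((2 * l + 1, len(carts)))
    for row, m in enumerate(m_values(l)):
        for col, mono in enumerate(carts):
            T[row, col] = table[m].get(mono, 0.0)
    return T


# ---------------------------------------------------------------------------
# shell placement

@dataclass
class _PlacedShell:
    atom: int
    l: int
    center: np.ndarray
    exponents: np.ndarray
    coefs: np.ndarray          # contraction coefficients times primitive norms
    sph_start: int             # offset in the *full* spherical expansion
    active_m: tuple[int, ...]  # kept m components (function-level truncation)


def _place_shells(basis: AOBasisSet, geom: MolecularGeometry):
    placed: list[_PlacedShell] = []
    offset = 0
    for atom, element in enumerate(geom.symbols):
        for sh in basis.shells_for_atom(atom, element):
            exps = np.asarray(sh.exponents)
            coefs = np.asarray(sh.coefficients) * np.array(
                [_primitive_norm(a, sh.l) for a in sh.exponents]
            )
            placed.append(
                _PlacedShell(atom, sh.l, geom.coords[atom], exps, coefs,
                             offset, sh.active_m)
            )
            offset += 2 * sh.l + 1
    return placed, offset


def _active_indices(placed: list[_PlacedShell]) -> np.ndarray:
    idx = []
    for ps in placed:
        idx.extend(ps.sph_start + np.array(ps.active_m, dtype=int))
    return np.array(idx, dtype=int)


# ---------------------------------------------------------------------------
# shell-pair data

class _ShellPair:
    """Primitive-pair expansion data for one shell pair, reused by the
    one-electron builders and as bra/ket in the ERI assembly."""

    __slots__ = ("sa", "sb", "prims", "ncart_a", "ncart_b", "carts_a", "carts_b")

    def __init__(self, sa: _PlacedShell, sb: _PlacedShell):
        self.sa, self.sb = sa, sb
        self.carts_a = cart_components(sa.l)
        self.carts_b = cart_components(sb.l)
        self.ncart_a, self.ncart_b = len(self.carts_a), len(self.carts_b)
        nt = sa.l + sb.l + 1
        self.prims = []
        for ca, a in zip(sa.coefs, sa.exponents):
            for cb, b in zip(sb.coefs, sb.exponents):
                p = a + b
                P = (a * sa.center + b * sb.center) / p
                Ex = _e_table(sa.l, sb.l, a, b, sa.center[0], sb.center[0])
                Ey = _e_table(sa.l, sb.l, a, b, sa.center[1], sb.center[1])
                Ez = _e_table(sa.l, sb.l, a, b, sa.center[2], sb.center[2])
                # Hermite product tensor over Cartesian pairs
                eprod = np.zeros(
                    (self.ncart_a * self.ncart_b, nt, nt, nt)
                )
                for ia, (axl, ayl, azl) in enumerate(self.carts_a):
                    for ib, (bxl, byl, bzl) in enumerate(self.carts_b):
                        row = ia * self.ncart_b + ib
                        ex = Ex[axl, bxl, : axl + bxl + 1]
                        ey = Ey[ayl, byl, : ayl + byl + 1]
                        ez = Ez[azl, bzl, : azl + bzl + 1]
                        eprod[row, : ex.size, : ey.size, : ez.size] = (
                            ex[:, None, None] * ey[None, :, None] * ez[None, None, :]
                        )
                self.prims.append((ca * cb, a, b, p, P, Ex, Ey, Ez, eprod))


# ---------------------------------------------------------------------------
# public containers

@dataclass
class IntegralSet:
    """All AO-basis integrals needed for RT-TDHF on fixed nuclei.

    ``eri`` is stored dense in chemist order: eri[m,n,l,s] = (mn|ls).
    All matrices refer to unit-normalized spherical AOs in the order of
    ``labels``.
    """

    S: np.ndarray
    T: np.ndarray
    V: np.ndarray
    dipole: np.ndarray          # (3, N, N), origin-referenced <mu| r |nu>
    eri: np.ndarray | None
    enuc: float
    labels: list[AOFunctionLabel]
    geom: MolecularGeometry
    basis_name: str = ""
    _lowdin: tuple | None = field(default=None, repr=False, compare=False)
    _jk_cache: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def n_ao(self) -> int:
        return self.S.shape[0]

    @property
    def hcore(self) -> np.ndarray:
        return self.T + self.V

    def min_overlap_eigenvalue(self) -> float:
        return float(np.min(np.abs(np.linalg.eigvalsh(self.S))))

    def lowdin(self) -> tuple[np.ndarray, np.ndarray]:
        """(S^{-1/2}, S^{+1/2}) by symmetric orthogonalization."""
        if self._lowdin is None:
            w, U = np.linalg.eigh(self.S)
            if np.min(w) <= 0:
                raise IntegralError(
                    f"overlap matrix not positive definite (min eig {np.min(w):.3e})"
                )
            X = (U / np.sqrt(w)) @ U.T
            Xi = (U * np.sqrt(w)) @ U.T
            object.__setattr__(self, "_lowdin", (X, Xi))
        return self._lowdin

    def jk_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """Matricized ERI views for fast repeated Fock builds:
        J_mat[(mn),(ls)] = (mn|ls) and K_mat[(mn),(ls)] = (ml|sn)."""
        if self.eri is None:
            raise IntegralError("IntegralSet was built without ERIs")
        if self._jk_cache is None:
            n = self.n_ao
            jm = self.eri.reshape(n * n, n * n)
            km = np.ascontiguousarray(
                self.eri.transpose(0, 3, 1, 2)
            ).reshape(n * n, n * n)
            object.__setattr__(self, "_jk_cache", (jm, km))
        return self._jk_cache


# ---------------------------------------------------------------------------
# assembly

def compute_integrals(
    geom: MolecularGeometry,
    basis: AOBasisSet,
    with_eri: bool = True,
    s_singular_threshold: float = 1e-10,
) -> IntegralSet:
    """Build overlap, kinetic, nuclear-attraction, dipole and (optionally)
    two-electron integrals for ``basis`` on ``geom``.

    Emits :class:`OvercompletenessWarning` when the smallest absolute
    overlap eigenvalue falls below ``s_singular_threshold``.
    """
    placed, n_full = _place_shells(basis, geom)
    labels = expand(basis, geom)
    sph_T = {l: spherical_transform(l) for l in {ps.l for ps in placed}}

    S = np.zeros((n_full, n_full))
    T = np.zeros((n_full, n_full))
    V = np.zeros((n_full, n_full))
    D = np.zeros((3, n_full, n_full))
    zs = geom.atomic_numbers.astype(float)

    pairs: dict[tuple[int, int], _ShellPair] = {}
    n_shell = len(placed)
    for i in range(n_shell):
        for j in range(i + 1):
            pairs[(i, j)] = _ShellPair(placed[i], placed[j])

    sqrt_pi = math.sqrt(math.pi)
    for (i, j), sp in pairs.items():
        sa, sb = sp.sa, sp.sb
        na_c, nb_c = sp.ncart_a, sp.ncart_b
        s_blk = np.zeros((na_c, nb_c))
        t_blk = np.zeros((na_c, nb_c))
        v_blk = np.zeros((na_c, nb_c))
        d_blk = np.zeros((3, na_c, nb_c))
        for coef, a, b, p, P, Ex, Ey, Ez, eprod in sp.prims:
            pref = (math.pi / p) ** 1.5
            # one-dimensional overlap factors (and shifted ones for kinetic)
            sq = sqrt_pi / math.sqrt(p)
            for ia, (axl, ayl, azl) in enumerate(sp.carts_a):
                for ib, (bxl, byl, bzl) in enumerate(sp.carts_b):
                    sx, sy, sz = Ex[axl, bxl, 0], Ey[ayl, byl, 0], Ez[azl, bzl, 0]
                    s_blk[ia, ib] += coef * pref * sx * sy * sz
                    t_blk[ia, ib] += coef * _kinetic_element(
                        sa, sb, a, b, (axl, ayl, azl), (bxl, byl, bzl)
                    )
                    mx = (Ex[axl, bxl, 1] if axl + bxl >= 1 else 0.0) + P[0] * sx
                    my = (Ey[ayl, byl, 1] if ayl + byl >= 1 else 0.0) + P[1] * sy
                    mz = (Ez[azl, bzl, 1] if azl + bzl >= 1 else 0.0) + P[2] * sz
                    d_blk[0, ia, ib] += coef * pref * mx * sy * sz
                    d_blk[1, ia, ib] += coef * pref * sx * my * sz
                    d_blk[2, ia, ib] += coef * pref * sx * sy * mz
            # nuclear attraction over all centers
            nt = sa.l + sb.l
            for atom_idx, (z, C) in enumerate(zip(zs, geom.coords)):
                R = _hermite_coulomb(nt, nt, nt, p, P - C)
                contr = np.einsum("rtuv,tuv->r", eprod, R)
                v_blk -= coef * z * (2 * math.pi / p) * contr.reshape(na_c, nb_c)

        Ta, Tb = sph_T[sa.l], sph_T[sb.l]
        ia0, ib0 = sa.sph_start, sb.sph_start
        na_s, nb_s = Ta.shape[0], Tb.shape[0]
        sl_a, sl_b = slice(ia0, ia0 + na_s), slice(ib0, ib0 + nb_s)
        for M_full, blk in ((S, s_blk), (T, t_blk), (V, v_blk)):
            sph = Ta @ blk @ Tb.T
            M_full[sl_a, sl_b] = sph
            M_full[sl_b, sl_a] = sph.T
        for ax in range(3):
            sph = Ta @ d_blk[ax] @ Tb.T
            D[ax, sl_a, sl_b] = sph
            D[ax, sl_b, sl_a] = sph.T

    eri = _assemble_eri(placed, pairs, sph_T, n_full) if with_eri else None

    # restrict to active functions (partial shells) and renormalize
    act = _active_indices(placed)
    S = S[np.ix_(act, act)]
    T = T[np.ix_(act, act)]
    V = V[np.ix_(act, act)]
    D = D[:, act][:, :, act]
    if eri is not None:
        eri = eri[np.ix_(act, act, act, act)]

    norm = 1.0 / np.sqrt(np.diag(S))
    S = S * norm[:, None] * norm[None, :]
    T = T * norm[:, None] * norm[None, :]
    V = V * norm[:, None] * norm[None, :]
    D = D * norm[None, :, None] * norm[None, None, :]
    if eri is not None:
        eri = np.einsum(
            "m,n,l,s,mnls->mnls", norm, norm, norm, norm, eri, optimize=True
        )

    min_eig = float(np.min(np.abs(np.linalg.eigvalsh(S))))
    if min_eig < s_singular_threshold:
        warnings.warn(
            f"overlap matrix nearly singular: min |eigenvalue| = {min_eig:.3e}",
            OvercompletenessWarning,
            stacklevel=2,
        )

    if len(labels) != S.shape[0]:
        raise IntegralError("label/matrix dimension mismatch")
    return IntegralSet(
        S=S, T=T, V=V, dipole=D, eri=eri,
        enuc=geom.nuclear_repulsion(), labels=labels, geom=geom,
        basis_name=basis.name,
    )


def _kinetic_element(sa, sb, a, b, la3, lb3) -> float:
    """Cartesian kinetic-energy primitive integral via shifted overlaps:
    T = sum_axis K_axis * prod_{other axes} S_axis."""
    s1d = []
    k1d = []
    for ax in range(3):
        la_, lb_ = la3[ax], lb3[ax]
        E = _e_table(la_, lb_ + 2, a, b, sa.center[ax], sb.center[ax])
        p = a + b
        fac = math.sqrt(math.pi / p)
        s = E[la_, lb_, 0] * fac
        s_p2 = E[la_, lb_ + 2, 0] * fac
        s_m2 = E[la_, lb_ - 2, 0] * fac if lb_ >= 2 else 0.0
        k = -2.0 * b * b * s_p2 + b * (2 * lb_ + 1) * s - 0.5 * lb_ * (lb_ - 1) * s_m2
        s1d.append(s)
        k1d.append(k)
    return (
        k1d[0] * s1d[1] * s1d[2]
        + s1d[0] * k1d[1] * s1d[2]
        + s1d[0] * s1d[1] * k1d[2]
    )


def _assemble_eri(placed, pairs, sph_T, n_full) -> np.ndarray:
    """Dense chemist-order ERI tensor (mn|ls) over the full spherical set."""
    eri = np.zeros((n_full, n_full, n_full, n_full))
    pair_keys = list(pairs.keys())
    two_pi_52 = 2.0 * math.pi ** 2.5

    # cache spherical index ranges
    def sph_range(ps: _PlacedShell):
        return np.arange(ps.sph_start, ps.sph_start + 2 * ps.l + 1)

    for ap in range(len(pair_keys)):
        (i, j) = pair_keys[ap]
        bra = pairs[(i, j)]
        for bp in range(ap + 1):
            (k, l) = pair_keys[bp]
            ket = pairs[(k, l)]
            block = _eri_quartet(bra, ket, two_pi_52)
            # spherical transform on all four indices
            Ta, Tb = sph_T[bra.sa.l], sph_T[bra.sb.l]
            Tc, Td = sph_T[ket.sa.l], sph_T[ket.sb.l]
            blk = block.reshape(
                bra.ncart_a, bra.ncart_b, ket.ncart_a, ket.ncart_b
            )
            sph = np.einsum(
                "ai,bj,ck,dl,ijkl->abcd", Ta, Tb, Tc, Td, blk, optimize=True
            )
            ia, ib = sph_range(bra.sa), sph_range(bra.sb)
            ic, id_ = sph_range(ket.sa), sph_range(ket.sb)
            for (p_, q_, r_, s_), t in (
                ((ia, ib, ic, id_), sph),
                ((ib, ia, ic, id_), sph.transpose(1, 0, 2, 3)),
                ((ia, ib, id_, ic), sph.transpose(0, 1, 3, 2)),
                ((ib, ia, id_, ic), sph.transpose(1, 0, 3, 2)),
                ((ic, id_, ia, ib), sph.transpose(2, 3, 0, 1)),
                ((id_, ic, ia, ib), sph.transpose(3, 2, 0, 1)),
                ((ic, id_, ib, ia), sph.transpose(2, 3, 1, 0)),
                ((id_, ic, ib, ia), sph.transpose(3, 2, 1, 0)),
            ):
                eri[np.ix_(p_, q_, r_, s_)] = t
    return eri


def _eri_quartet(bra: _ShellPair, ket: _ShellPair, two_pi_52: float) -> np.ndarray:
    la = bra.sa.l + bra.sb.l
    lc = ket.sa.l + ket.sb.l
    nab = bra.ncart_a * bra.ncart_b
    ncd = ket.ncart_a * ket.ncart_b
    out = np.zeros((nab, ncd))
    nt_b, nt_k = la + 1, lc + 1

    # sign factor (-1)^{tau+nu+phi} applied to the ket Hermite indices
    sgn = np.ones((nt_k, nt_k, nt_k))
    for t in range(nt_k):
        for u in range(nt_k):
            for v in range(nt_k):
                if (t + u + v) % 2:
                    sgn[t, u, v] = -1.0

    tb = np.arange(nt_b)
    tk = np.arange(nt_k)
    idx = tb[:, None] + tk[None, :]  # (nt_b, nt_k)

    for cb, a1, b1, p, P, *_, ebra in bra.prims:
        for ck, a2, b2, q, Q, *_, eket in ket.prims:
            alpha = p * q / (p + q)
            fac = cb * ck * two_pi_52 / (p * q * math.sqrt(p + q))
            R = _hermite_coulomb(la + lc, la + lc, la + lc, alpha, P - Q)
            # M[t,u,v,tau,nu,phi] = (-1)^{tau+nu+phi} R[t+tau, u+nu, v+phi]
            M = R[
                idx[:, None, None, :, None, None],
                idx[None, :, None, None, :, None],
                idx[None, None, :, None, None, :],
            ] * sgn[None, None, None, :, :, :]
            Mm = M.reshape(nt_b ** 3, nt_k ** 3)
            out += fac * (
                ebra.reshape(nab, -1) @ Mm @ eket.reshape(ncd, -1).T
            )
    return out
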