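"""Add-While-Truncate construction of an epsilon-complete basis set.

Each cycle runs a short delta-pulse propagation, truncates the basis at
shell level with the two indicators, then augments every surviving
l-channel with one even-tempered diffuse function (geometric continuation
of the channel's two smallest exponents). Functions deleted in any earlier
cycle are never re-proposed. The loop stops when the smallest absolute
overlap eigenvalue of the augmented basis falls below epsilon — in which
case the newest diffuse shells are removed in order of decreasing angular
momentum until the overcompleteness clears, and one confirming cycle is
run — or when the basis reaches a fixed point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .basis import (
    AOBasisSet,
    BasisShell,
    channel_exponents,
    even_tempered_extend,
    expand,
)
from .geometry import MolecularGeometry
from .indicators import indicators_from_trace, select_truncation
from .integrals import OvercompletenessWarning, compute_integrals
from .rtp import PulseSpec, propagate
from .scf import scf_rhf


class CBSError(RuntimeError):
    pass


@dataclass(frozen=True)
class RTParams:
    """Parameters of the short indicator propagation used in every cycle."""

    n_steps: int = 100
    dt: float = 0.2
    kappa: tuple[float, float, float] = (0.0, 0.0, 1e-3)


@dataclass
class CBSCycle:
    index: int
    composition: dict[str, str]       # element key -> shell composition
    n_ao: int
    n_deleted: int
    added: list[str]                  # human-readable added shells
    removed: list[str]                # shells pruned by the eigenvalue rule
    min_eig: float


@dataclass
class CBSResult:
    cycles: list[CBSCycle]
    final_basis: AOBasisSet
    epsilon: float
    termination: str                  # "eigenvalue" | "fixed_point"
    final_min_eig: float
    deleted_total: int

    def to_json_dict(self) -> dict:
        return {
            "epsilon": self.epsilon,
            "termination": self.termination,
            "final_min_eig": self.final_min_eig,
            "deleted_total": self.deleted_total,
            "cycles": [
                {
                    "index": c.index,
                    "composition": c.composition,
                    "n_ao": c.n_ao,
                    "n_deleted": c.n_deleted,
                    "added": c.added,
                    "removed": c.removed,
                    "min_eig": c.min_eig,
                }
                for c in self.cycles
            ],
        }


def min_overlap_eigenvalue(geom: MolecularGeometry, basis: AOBasisSet) -> float:
    """Smallest absolute eigenvalue of the overlap matrix of ``basis`` on
    ``geom`` (the overcompleteness measure)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", OvercompletenessWarning)
        ints = compute_integrals(geom, basis, with_eri=False)
    return ints.min_overlap_eigenvalue()


def _shell_key(atom: int, sh: BasisShell) -> tuple:
    return (atom, sh.l, tuple(round(a, 10) for a in sh.exponents))


def _shells_by_id(basis: AOBasisSet, geom: MolecularGeometry):
    out = {}
    for atom, element in enumerate(geom.symbols):
        k_count: dict[int, int] = {}
        for sh in basis.shells_for_atom(atom, element):
            k_count[sh.l] = k_count.get(sh.l, 0) + 1
            out[(atom, sh.l, k_count[sh.l])] = sh
    return out


def _composition_map(basis: AOBasisSet, geom: MolecularGeometry) -> dict[str, str]:
    keys = {basis.key_for_atom(a, el) for a, el in enumerate(geom.symbols)}
    return {k: basis.composition(k) for k in sorted(keys)}


def _atoms_for_key(basis: AOBasisSet, geom: MolecularGeometry, key: str):
    return [
        a for a, el in enumerate(geom.symbols)
        if basis.key_for_atom(a, el) == key
    ]


def _run_truncation(geom, basis, xthr, rt, level):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", OvercompletenessWarning)
        ints = compute_integrals(geom, basis)
        scf = scf_rhf(geom, ints=ints)
        trace = propagate(
            scf, ints, PulseSpec(rt.kappa), rt.n_steps, rt.dt, record="orbitals"
        )
    xdc, xip = indicators_from_trace(trace, ints.S)
    labels = ints.labels
    return select_truncation(xdc, xip, xthr, labels, level=level)


def add_while_truncate(
    geom: MolecularGeometry,
    basis: AOBasisSet,
    xthr: float = 0.1,
    epsilon: float = 1e-6,
    rt_params: RTParams | None = None,
    level: str = "shell",
    max_cycles: int = 10,
) -> CBSResult:
    """Iterate truncation and even-tempered diffuse augmentation until the
    overlap-eigenvalue bound ``epsilon`` or a fixed point is reached."""
    if epsilon <= 0:
        raise CBSError("epsilon must be positive")
    rt = rt_params or RTParams()
    from .basis import apply_truncation  # local to avoid cycle at import

    deleted_keys: set[tuple] = set()
    deleted_total = 0
    cycles: list[CBSCycle] = []
    current = basis
    confirming = False

    for cycle in range(1, max_cycles + 1):
        report = _run_truncation(geom, current, xthr, rt, level)
        shells_by_id = _shells_by_id(current, geom)
        deleted_shell_ids = {lab.shell_id for lab in report.deleted}
        for sid in deleted_shell_ids:
            deleted_keys.add(_shell_key(sid[0], shells_by_id[sid]))
        deleted_total += report.n_deleted
        trunc = apply_truncation(current, geom, report.deleted, level=level)

        if confirming:
            final_eig = min_overlap_eigenvalue(geom, trunc)
            cycles.append(CBSCycle(
                index=cycle, composition=_composition_map(trunc, geom),
                n_ao=len(expand(trunc, geom)), n_deleted=report.n_deleted,
                added=[], removed=[], min_eig=final_eig,
            ))
            return CBSResult(
                cycles=cycles, final_basis=trunc, epsilon=epsilon,
                termination="eigenvalue", final_min_eig=final_eig,
                deleted_total=deleted_total,
            )

        # even-tempered diffuse candidates, one per surviving l-channel
        candidates: list[tuple[str, BasisShell]] = []  # (element key, shell)
        for key, shells in trunc.element_shells.items():
            atoms = _atoms_for_key(trunc, geom, key)
            for l in sorted({sh.l for sh in shells}):
                exps = channel_exponents(shells, l)
                if len(set(exps)) < 2:
                    continue
                alpha = even_tempered_extend(exps)
                cand = BasisShell(key.split(".")[0], l, (alpha,), (1.0,))
                if any(
                    (a, l, (round(alpha, 10),)) in deleted_keys for a in atoms
                ):
                    continue
                candidates.append((key, cand))

        def build_aug(cands):
            shells = {k: list(v) for k, v in trunc.element_shells.items()}
            for key, sh in cands:
                shells[key] = shells[key] + [sh]
            return AOBasisSet(
                name=f"{basis.name}-cbs", element_shells={
                    k: tuple(v) for k, v in shells.items()
                },
                atom_keys=trunc.atom_keys,
            )

        aug = build_aug(candidates)
        min_eig = min_overlap_eigenvalue(geom, aug)
        removed: list[str] = []
        if min_eig < epsilon:
            # prune the newest diffuse shells, highest l (then most diffuse)
            # first, until the overcompleteness clears
            order = sorted(
                range(len(candidates)),
                key=lambda i: (-candidates[i][1].l, candidates[i][1].exponents[0]),
            )
            kept = list(candidates)
            for i in order:
                key, sh = candidates[i]
                kept = [c for c in kept if c is not candidates[i]]
                removed.append(f"{key}:{sh.letter}({sh.exponents[0]:.4g})")
                aug = build_aug(kept)
                min_eig = min_overlap_eigenvalue(geom, aug)
                if min_eig >= epsilon:
                    break
            if min_eig < epsilon:
                # even the bare truncated set violates epsilon: stop here
                cycles.append(CBSCycle(
                    index=cycle, composition=_composition_map(trunc, geom),
                    n_ao=len(expand(trunc, geom)),
                    n_deleted=report.n_deleted,
                    added=[], removed=removed, min_eig=min_eig,
                ))
                return CBSResult(
                    cycles=cycles, final_basis=trunc, epsilon=epsilon,
                    termination="eigenvalue", final_min_eig=min_eig,
                    deleted_total=deleted_total,
                )
            confirming = True
            candidates = kept

        added = [
            f"{key}:{sh.letter}({sh.exponents[0]:.4g})" for key, sh in candidates
        ]
        cycles.append(CBSCycle(
            index=cycle, composition=_composition_map(aug, geom),
            n_ao=len(expand(aug, geom)), n_deleted=report.n_deleted,
            added=added, removed=removed, min_eig=min_eig,
        ))

        if len(expand(aug, geom)) == len(expand(current, geom)) and \
                _composition_map(aug, geom) == _composition_map(current, geom) \
                and report.n_deleted == 0 and not candidates:
            return CBSResult(
                cycles=cycles, final_basis=trunc, epsilon=epsilon,
                termination="fixed_point", final_min_eig=min_eig,
                deleted_total=deleted_total,
            )
        current = aug

    raise CBSError(
        f"Add-While-Truncate did not terminate within {max_cycles} cycles"
    )
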