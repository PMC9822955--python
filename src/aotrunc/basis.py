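"""Gaussian-type-orbital basis sets: data model, plain-text file I/O,
AO-function labelling, truncation, and even-tempered diffuse extension.

All basis sets are expanded in real spherical harmonics (5d/7f) for every
family, including Pople sets; the per-shell function count is therefore
always 2l+1 per contracted column. The fixed m-component ordering per
angular momentum is given by :data:`M_NAMES` and shared with the integrals
engine, so per-function indicator vectors are portable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

from .geometry import MolecularGeometry

ANGULAR_LETTERS = "spdfghi"

#: canonical m-component names per angular momentum
M_NAMES: dict[int, tuple[str, ...]] = {
    0: ("s",),
    1: ("p_x", "p_y", "p_z"),
    2: ("d_xy", "d_yz", "d_z2", "d_xz", "d_x2-y2"),
    3: tuple(f"f_{m:+d}" for m in range(-3, 4)),
}
#: the real-solid-harmonic m value behind each name, same order
M_VALUES: dict[int, tuple[int, ...]] = {
    0: (0,),
    1: (1, -1, 0),          # p_x, p_y, p_z
    2: (-2, -1, 0, 1, 2),   # d_xy, d_yz, d_z2, d_xz, d_x2-y2
    3: tuple(range(-3, 4)),
}


def m_names(l: int) -> tuple[str, ...]:
    if l in M_NAMES:
        return M_NAMES[l]
    return tuple(f"{ANGULAR_LETTERS[l]}_{m:+d}" for m in range(-l, l + 1))


def m_values(l: int) -> tuple[int, ...]:
    return M_VALUES.get(l, tuple(range(-l, l + 1)))


class BasisError(ValueError):
    """Basis construction, lookup, or parse failure."""


class BasisParseError(BasisError):
    """Malformed basis-set file; carries a line number where possible."""


@dataclass(frozen=True)
class BasisShell:
    """One segmented contracted shell: shared primitive exponents (Bohr^-2)
    and a single column of contraction coefficients.

    ``m_indices`` selects a subset of the 2l+1 spherical components (indices
    into :func:`m_names`); ``None`` means the full shell. Partial shells
    arise only from function-level truncation and cannot be written to a
    standard basis file.
    """

    element: str
    l: int
    exponents: tuple[float, ...]
    coefficients: tuple[float, ...]
    m_indices: tuple[int, ...] | None = None

    def __post_init__(self):
        if self.l < 0 or self.l >= len(ANGULAR_LETTERS):
            raise BasisError(f"unsupported angular momentum {self.l}")
        if len(self.exponents) != len(self.coefficients):
            raise BasisError("exponents/coefficients length mismatch")
        if not self.exponents:
            raise BasisError("shell must have at least one primitive")
        if any(a <= 0 or not np.isfinite(a) for a in self.exponents):
            raise BasisError("exponents must be strictly positive and finite")
        if any(not np.isfinite(c) for c in self.coefficients):
            raise BasisError("coefficients must be finite")
        if self.m_indices is not None:
            if not all(0 <= i < 2 * self.l + 1 for i in self.m_indices):
                raise BasisError("m_indices out of range for this shell")
            if len(set(self.m_indices)) != len(self.m_indices):
                raise BasisError("duplicate m_indices")

    @property
    def letter(self) -> str:
        return ANGULAR_LETTERS[self.l]

    @property
    def n_functions(self) -> int:
        if self.m_indices is not None:
            return len(self.m_indices)
        return 2 * self.l + 1

    @property
    def active_m(self) -> tuple[int, ...]:
        if self.m_indices is not None:
            return tuple(self.m_indices)
        return tuple(range(2 * self.l + 1))

    @property
    def is_partial(self) -> bool:
        return self.m_indices is not None and len(self.m_indices) < 2 * self.l + 1


@dataclass(frozen=True, order=True)
class AOFunctionLabel:
    """Identity of one spherical AO function in an expanded basis.

    ``k`` is the 1-based shell ordinal within (atom, l) — "2p" means the
    second p-type shell of that atom; ``mu`` is the flat AO index in the
    atom-major, shell-ordinal, m-component order used everywhere.
    """

    mu: int
    atom: int
    element: str
    l: int
    k: int
    m_index: int

    @property
    def m_name(self) -> str:
        return m_names(self.l)[self.m_index]

    @property
    def shell_id(self) -> tuple[int, int, int]:
        """(atom, l, k): the shell this function belongs to."""
        return (self.atom, self.l, self.k)

    def __str__(self) -> str:  # e.g. "H0:2p_x"
        return f"{self.element}{self.atom}:{self.k}{self.m_name}"


@dataclass(frozen=True)
class AOBasisSet:
    """An element-keyed collection of shells, optionally bound to a geometry
    through per-atom keys (used when truncation treats symmetry-inequivalent
    atoms of the same element differently)."""

    name: str
    element_shells: dict[str, tuple[BasisShell, ...]]
    atom_keys: dict[int, str] | None = None
    spherical: bool = field(default=True)

    def __post_init__(self):
        if not self.spherical:
            raise BasisError("only spherical-harmonic (5d/7f) bases supported")
        frozen = {el: tuple(shells) for el, shells in self.element_shells.items()}
        object.__setattr__(self, "element_shells", frozen)

    def key_for_atom(self, atom_index: int, element: str) -> str:
        if self.atom_keys is not None and atom_index in self.atom_keys:
            return self.atom_keys[atom_index]
        return element

    def shells_for_atom(self, atom_index: int, element: str) -> tuple[BasisShell, ...]:
        key = self.key_for_atom(atom_index, element)
        try:
            return self.element_shells[key]
        except KeyError:
            raise BasisError(
                f"basis {self.name!r} has no entry for element {key!r}"
            ) from None

    def composition(self, key: str) -> str:
        """Shell-composition string such as '3s1p' for an element entry,
        counting contracted shells (not primitives) per angular momentum."""
        counts: dict[int, int] = {}
        for sh in self.element_shells[key]:
            counts[sh.l] = counts.get(sh.l, 0) + 1
        return "".join(
            f"{counts[l]}{ANGULAR_LETTERS[l]}" for l in sorted(counts)
        )

    def has_partial_shells(self) -> bool:
        return any(
            sh.is_partial for shells in self.element_shells.values() for sh in shells
        )


# ---------------------------------------------------------------------------
# expansion and counting

def expand(basis: AOBasisSet, geom: MolecularGeometry) -> list[AOFunctionLabel]:
    """Ordered list of AO function labels for ``basis`` on ``geom``:
    atom-major, then shell order within the atom, then m-component order."""
    labels: list[AOFunctionLabel] = []
    mu = 0
    for atom, element in enumerate(geom.symbols):
        shells = basis.shells_for_atom(atom, element)
        k_count: dict[int, int] = {}
        for sh in shells:
            k_count[sh.l] = k_count.get(sh.l, 0) + 1
            k = k_count[sh.l]
            for mi in sh.active_m:
                labels.append(AOFunctionLabel(mu, atom, element, sh.l, k, mi))
                mu += 1
    return labels


_COMP_RE = re.compile(r"(\d+)([a-z])")


def parse_composition(comp: str) -> dict[int, int]:
    """'3s3p1d' -> {0: 3, 1: 3, 2: 1}."""
    comp = comp.strip().lower()
    out: dict[int, int] = {}
    pos = 0
    for match in _COMP_RE.finditer(comp):
        if match.start() != pos:
            raise BasisError(f"malformed composition string {comp!r}")
        pos = match.end()
        count, letter = int(match.group(1)), match.group(2)
        if letter not in ANGULAR_LETTERS:
            raise BasisError(f"unknown angular-momentum letter {letter!r}")
        l = ANGULAR_LETTERS.index(letter)
        out[l] = out.get(l, 0) + count
    if pos != len(comp) or not out:
        raise BasisError(f"malformed composition string {comp!r}")
    return out


def count_functions(composition: dict[str, str], atom_counts: dict[str, int]) -> int:
    """Total spherical AO count for per-element shell compositions.

    ``composition`` maps element -> composition string ('6s4p3d1f');
    ``atom_counts`` maps element -> number of atoms. Each shell of angular
    momentum l contributes 2l+1 functions.
    """
    total = 0
    for element, comp in composition.items():
        per_atom = sum(
            n * (2 * l + 1) for l, n in parse_composition(comp).items()
        )
        total += per_atom * atom_counts.get(element, 0)
    return total


# ---------------------------------------------------------------------------
# even-tempered extension

def even_tempered_extend(shell_or_exponents) -> float:
    """Next diffuse exponent by geometric extrapolation.

    Given the two smallest distinct exponents a_{k-1} > a_k of an l-channel
    (or a single shell), returns a_{k+1} = a_k^2 / a_{k-1} < a_k, i.e. the
    continuation of the even-tempered progression a_k = a * b^k.
    """
    if isinstance(shell_or_exponents, BasisShell):
        exps = shell_or_exponents.exponents
    else:
        exps = tuple(shell_or_exponents)
    distinct = sorted(set(exps))
    if len(distinct) < 2:
        raise BasisError(
            "cannot extrapolate an even-tempered progression from fewer than "
            "two distinct exponents"
        )
    a_k, a_km1 = distinct[0], distinct[1]
    return a_k * a_k / a_km1


def channel_exponents(shells, l: int) -> list[float]:
    """All primitive exponents of angular momentum ``l`` among ``shells``."""
    out: list[float] = []
    for sh in shells:
        if sh.l == l:
            out.extend(sh.exponents)
    return out


# ---------------------------------------------------------------------------
# truncation

def apply_truncation(
    basis: AOBasisSet,
    geom: MolecularGeometry,
    deleted,
    level: str = "function",
) -> AOBasisSet:
    """Return a basis whose expansion on ``geom`` equals the original
    expansion minus ``deleted`` (a set of :class:`AOFunctionLabel`).

    At ``level='shell'`` the deleted set must consist of whole shells. If
    the deletion pattern differs between atoms of the same element, the
    result carries per-atom entries (``atom_keys``) so that each atom class
    keeps its own shell list.
    """
    deleted = set(deleted)
    labels = expand(basis, geom)
    label_set = set(labels)
    if not deleted <= label_set:
        raise BasisError("deleted set contains labels not in the expansion")
    if level not in ("function", "shell"):
        raise BasisError(f"unknown truncation level {level!r}")

    # deleted m-indices per shell id
    by_shell: dict[tuple[int, int, int], set[int]] = {}
    for lab in deleted:
        by_shell.setdefault(lab.shell_id, set()).add(lab.m_index)

    if level == "shell":
        sizes = {
            lab.shell_id: 0 for lab in labels
        }
        for lab in labels:
            sizes[lab.shell_id] += 1
        for sid, ms in by_shell.items():
            if len(ms) != sizes[sid]:
                raise BasisError(
                    f"shell-level truncation requires whole shells; shell "
                    f"{sid} has only {len(ms)}/{sizes[sid]} members deleted"
                )

    # rebuild per-atom shell lists
    per_atom_shells: list[tuple[BasisShell, ...]] = []
    for atom, element in enumerate(geom.symbols):
        shells = basis.shells_for_atom(atom, element)
        k_count: dict[int, int] = {}
        new_shells: list[BasisShell] = []
        for sh in shells:
            k_count[sh.l] = k_count.get(sh.l, 0) + 1
            sid = (atom, sh.l, k_count[sh.l])
            gone = by_shell.get(sid, set())
            keep = tuple(mi for mi in sh.active_m if mi not in gone)
            if not keep:
                continue
            if len(keep) == 2 * sh.l + 1:
                new_shells.append(replace(sh, m_indices=None))
            else:
                new_shells.append(replace(sh, m_indices=keep))
        if not new_shells:
            raise BasisError(
                f"truncation would delete every function of atom {atom} "
                f"({element})"
            )
        per_atom_shells.append(tuple(new_shells))

    # collapse identical atom patterns back onto plain element keys
    element_shells: dict[str, tuple[BasisShell, ...]] = {}
    atom_keys: dict[int, str] = {}
    pattern_key: dict[tuple, str] = {}
    per_element_class: dict[str, int] = {}
    uniform = True
    for element in set(geom.symbols):
        atoms = [a for a, s in enumerate(geom.symbols) if s == element]
        patterns = {tuple(per_atom_shells[a]) for a in atoms}
        if len(patterns) > 1:
            uniform = False
    for atom, element in enumerate(geom.symbols):
        pat = tuple(per_atom_shells[atom])
        if uniform:
            element_shells[element] = pat
            continue
        if pat not in pattern_key:
            per_element_class[element] = per_element_class.get(element, 0) + 1
            key = f"{element}.{per_element_class[element]}"
            pattern_key[pat] = key
            element_shells[key] = pat
        atom_keys[atom] = pattern_key[pat]

    return AOBasisSet(
        name=f"{basis.name}-trunc" if deleted else basis.name,
        element_shells=element_shells,
        atom_keys=atom_keys or None,
    )


# ---------------------------------------------------------------------------
# file I/O: plain-text per-element format (element + angular-momentum letter
# header line, exponent/coefficient rows; composite SP/SPD rows split into
# segmented shells on read)

def parse_basis_text(text: str, name: str = "unnamed") -> AOBasisSet:
    element_shells: dict[str, list[BasisShell]] = {}
    pending: tuple[str, str, list[list[float]]] | None = None

    def flush():
        nonlocal pending
        if pending is None:
            return
        element, letters, rows = pending
        if not rows:
            raise BasisParseError(f"shell {element} {letters} has no primitives")
        ncols = len(rows[0])
        if any(len(r) != ncols for r in rows):
            raise BasisParseError(
                f"ragged coefficient rows in shell {element} {letters}"
            )
        if ncols - 1 < len(letters):
            raise BasisParseError(
                f"shell {element} {letters}: expected {len(letters)} "
                f"coefficient column(s), found {ncols - 1}"
            )
        exps = tuple(r[0] for r in rows)
        width = (ncols - 1) // len(letters)
        for li, letter in enumerate(letters):
            l = ANGULAR_LETTERS.index(letter)
            for col in range(width):
                coeffs = tuple(r[1 + li * width + col] for r in rows)
                if all(c == 0.0 for c in coeffs):
                    continue
                element_shells.setdefault(element, []).append(
                    BasisShell(element, l, exps, coeffs)
                )
        pending = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("BASIS") or upper == "END":
            continue
        parts = line.split()
        try:
            row = [float(p.replace("D", "E").replace("d", "e")) for p in parts]
        except ValueError:
            row = None
        if row is not None:
            if pending is None:
                raise BasisParseError(
                    f"line {lineno}: numeric row before any shell header"
                )
            pending[2].append(row)
            continue
        if len(parts) != 2:
            raise BasisParseError(f"line {lineno}: malformed shell header {line!r}")
        element, letters = parts[0].capitalize(), parts[1].lower()
        if any(ch not in ANGULAR_LETTERS for ch in letters):
            raise BasisParseError(
                f"line {lineno}: unknown angular-momentum letter in {parts[1]!r}"
            )
        flush()
        pending = (element, letters, [])
    flush()
    if not element_shells:
        raise BasisParseError("no shells found in basis text")
    return AOBasisSet(name=name, element_shells={
        el: tuple(shells) for el, shells in element_shells.items()
    })


def parse_basis_file(path) -> AOBasisSet:
    path = Path(path)
    return parse_basis_text(path.read_text(), name=path.stem)


def format_basis(basis: AOBasisSet) -> str:
    """Canonical text form; numbers keep full repr precision so that
    write -> parse is an identity on shells and exponents."""
    if basis.has_partial_shells():
        raise BasisError(
            "cannot write a basis containing partial shells (function-level "
            "truncation); use shell-level truncation for file export"
        )
    lines = [f"# basis set: {basis.name}", "BASIS"]
    for element in sorted(basis.element_shells):
        for sh in basis.element_shells[element]:
            lines.append(f"{element}    {sh.letter.upper()}")
            for a, c in zip(sh.exponents, sh.coefficients):
                lines.append(f"    {a:< .10E}    {c:< .10E}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_basis_file(basis: AOBasisSet, path) -> None:
    Path(path).write_text(format_basis(basis))


# ---------------------------------------------------------------------------
# vendored fixtures

_BUILTIN_ALIASES = {
    "6-31g": "6-31g",
    "6-31g**": "6-31gss",
    "6-31g(d,p)": "6-31gss",
    "6-31++g": "6-31ppg",
    "6-31++g**": "6-31ppgss",
    "tz-synthetic": "tz-synthetic",
}


def available_bases() -> list[str]:
    return sorted(_BUILTIN_ALIASES)


def load_basis(name: str) -> AOBasisSet:
    """Load a vendored basis set by conventional name (e.g. '6-31++G**')."""
    key = name.strip().lower()
    if key not in _BUILTIN_ALIASES:
        raise BasisError(
            f"unknown basis {name!r}; available: {', '.join(available_bases())}"
        )
    fname = _BUILTIN_ALIASES[key] + ".basis"
    text = resources.files("aotrunc.data").joinpath(fname).read_text()
    basis = parse_basis_text(text, name=name.strip())
    return basis
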