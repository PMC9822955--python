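"""End-to-end pipelines behind the command-line interface.

Each pipeline is an ordinary library function taking a :class:`RunConfig`;
the CLI is a thin wrapper. Outputs are deterministic: identical configs
produce identical JSON reports.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import basis as basis_mod
from .basis import apply_truncation, load_basis, parse_basis_file, write_basis_file
from .cbs import RTParams, add_while_truncate
from .geometry import MolecularGeometry, make_h2_dimer, make_h2o_dimer, read_xyz
from .indicators import export_map, indicators_from_trace, select_truncation
from .integrals import compute_integrals
from .rtp import PulseSpec, propagate
from .scf import scf_rhf
from .spectra import dipole_to_spectrum, peak_shift


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline invocation.

    ``geometry`` is either the path of an XYZ file or one of the built-in
    fixtures ('h2_dimer', 'h2o_dimer'); ``basis`` is a vendored basis name
    or the path of a basis file. The indicator run defaults to 1% of the
    full propagation length.
    """

    geometry: str = "h2_dimer"
    geometry_params: dict = field(default_factory=dict)
    basis: str = "6-31G"
    pulse_axis: str = "z"
    kappa: float = 1e-3
    dt: float = 0.2
    steps_full: int = 10000
    steps_indicator: int | None = None   # default: 1% of steps_full
    xthr: float = 0.1
    level: str = "function"
    epsilon: float = 1e-6
    gamma: float = 0.004
    window: tuple[float, float] = (0.5, 20.0)
    outdir: str = "aotrunc-out"
    seed: int = 0   # reserved; the core numerics are deterministic

    @property
    def n_indicator_steps(self) -> int:
        if self.steps_indicator is not None:
            return self.steps_indicator
        return max(1, self.steps_full // 100)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        if "window" in data:
            data["window"] = tuple(data["window"])
        return cls(**data)

    def resolve_geometry(self) -> MolecularGeometry:
        if self.geometry == "h2_dimer":
            return make_h2_dimer(**self.geometry_params)
        if self.geometry == "h2o_dimer":
            return make_h2o_dimer(**self.geometry_params)
        path = Path(self.geometry)
        if not path.exists():
            raise ConfigError(f"geometry {self.geometry!r}: no such fixture or file")
        return read_xyz(path)

    def resolve_basis(self):
        try:
            return load_basis(self.basis)
        except basis_mod.BasisError:
            path = Path(self.basis)
            if not path.exists():
                raise ConfigError(
                    f"basis {self.basis!r}: neither a vendored name nor a file"
                ) from None
            return parse_basis_file(path)

    def pulse(self) -> PulseSpec:
        return PulseSpec.along(self.pulse_axis, self.kappa)


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _provenance(cfg: RunConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    _dump_json(asdict(cfg), outdir / "config.resolved.json")


def _indicator_stage(cfg: RunConfig):
    geom = cfg.resolve_geometry()
    basis = cfg.resolve_basis()
    ints = compute_integrals(geom, basis)
    scf = scf_rhf(geom, ints=ints)
    trace = propagate(
        scf, ints, cfg.pulse(), cfg.n_indicator_steps, cfg.dt, record="orbitals"
    )
    xdc, xip = indicators_from_trace(trace, ints.S)
    report = select_truncation(
        xdc, xip, cfg.xthr, ints.labels, level=cfg.level
    )
    return geom, basis, ints, scf, report


def run_indicators(cfg: RunConfig):
    """Short propagation, indicator computation, truncation selection.

    Writes the indicator report (JSON), the x^DC-x^IP map table (CSV) and,
    when the truncated basis is file-representable, a basis file.
    """
    outdir = Path(cfg.outdir)
    _provenance(cfg, outdir)
    geom, basis, ints, scf, report = _indicator_stage(cfg)
    _dump_json(report.to_json_dict(), outdir / "indicators.json")
    export_map(report).to_csv(outdir / "map.csv", index=False)
    trunc = apply_truncation(basis, geom, report.deleted, level=cfg.level)
    if not trunc.has_partial_shells():
        write_basis_file(trunc, outdir / "truncated.basis")
    return report, trunc


def run_truncate_and_spectrum(cfg: RunConfig):
    """Full-length runs with the original and the truncated basis, their
    spectra, and the matched-peak shift report."""
    outdir = Path(cfg.outdir)
    _provenance(cfg, outdir)
    geom, basis, ints, scf, report = _indicator_stage(cfg)
    trunc = apply_truncation(basis, geom, report.deleted, level=cfg.level)

    def full_run(b, ints_=None):
        ints_ = ints_ or compute_integrals(geom, b)
        scf_ = scf_rhf(geom, ints=ints_)
        trace = propagate(
            scf_, ints_, cfg.pulse(), cfg.steps_full, cfg.dt, record="dipole"
        )
        return dipole_to_spectrum(trace, cfg.pulse().vector, gamma=cfg.gamma)

    spec_full = full_run(basis, ints_=ints)
    spec_trunc = full_run(trunc)
    spec_full.save(outdir / "spectrum_original.dat")
    spec_trunc.save(outdir / "spectrum_truncated.dat")
    shift = peak_shift(spec_full, spec_trunc, cfg.window)
    _dump_json(
        {
            "max_shift_ev": shift["max_shift"],
            "matches": shift["matches"],
            "unmatched_original": shift["unmatched_a"],
            "unmatched_truncated": shift["unmatched_b"],
            "n_ao_original": report.n_ao,
            "n_ao_truncated": report.n_kept,
        },
        outdir / "shift.json",
    )
    return spec_full, spec_trunc, shift


def run_cbs(cfg: RunConfig):
    """Add-While-Truncate loop; writes the cycle log and the final basis."""
    outdir = Path(cfg.outdir)
    _provenance(cfg, outdir)
    geom = cfg.resolve_geometry()
    basis = cfg.resolve_basis()
    result = add_while_truncate(
        geom, basis, xthr=cfg.xthr, epsilon=cfg.epsilon,
        rt_params=RTParams(cfg.n_indicator_steps, cfg.dt,
                           tuple(cfg.pulse().kappa)),
        level="shell",
    )
    _dump_json(result.to_json_dict(), outdir / "cbs.json")
    if not result.final_basis.has_partial_shells():
        write_basis_file(result.final_basis, outdir / "cbs.basis")
    return result


def run_spectrum(cfg: RunConfig):
    """Single full-length run and its spectrum with the configured basis."""
    outdir = Path(cfg.outdir)
    _provenance(cfg, outdir)
    geom = cfg.resolve_geometry()
    basis = cfg.resolve_basis()
    ints = compute_integrals(geom, basis)
    scf = scf_rhf(geom, ints=ints)
    trace = propagate(
        scf, ints, cfg.pulse(), cfg.steps_full, cfg.dt, record="dipole"
    )
    spec = dipole_to_spectrum(trace, cfg.pulse().vector, gamma=cfg.gamma)
    spec.save(Path(cfg.outdir) / "spectrum.dat")
    return spec
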