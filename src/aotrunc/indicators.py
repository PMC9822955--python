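"""Per-AO truncation indicators from a short real-time propagation.

Two dimensionless, unit-mean indicators are computed per basis function:

* x^DC ("density-matrix contribution"): the time standard deviation of the
  Mulliken-style electron count O_mu(t) = (P(t) S)_mu,mu, normalized by its
  mean over all AOs. It measures how much the function's share of the
  time-dependent density fluctuates, which is what survives a Fourier
  transform of the dipole.
* x^IP ("importance for propagation stability"): the summed time standard
  deviation of the MO-coefficient row C_mu,j(t) over all MOs, normalized
  the same way. It measures how much the function participates in the
  propagation itself.

Functions below a threshold x^thr on *both* indicators are truncation
candidates; a Jaccard index between the two candidate sets diagnoses how
much the criteria agree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import AOFunctionLabel
from .rtp import PropagationTrace


class DegenerateTraceError(ValueError):
    """All indicator numerators vanish (e.g. unpulsed, stationary run)."""


def complex_std(series, axis: int = 0) -> np.ndarray | float:
    """Population standard deviation of complex samples:
    sqrt(mean |z - mean(z)|^2). Reduces to the ordinary population standard
    deviation for real input."""
    z = np.asarray(series)
    if z.size == 0:
        raise ValueError("empty series")
    zbar = z.mean(axis=axis, keepdims=True)
    out = np.sqrt(np.mean(np.abs(z - zbar) ** 2, axis=axis))
    return float(out) if np.ndim(out) == 0 else out


def compute_O_series(trace_or_P, S: np.ndarray) -> np.ndarray:
    """Mulliken occupation series O_mu(t_n) = (P(t_n) S)_mu,mu as an
    (n_frames, N_AO) complex array."""
    if isinstance(trace_or_P, PropagationTrace):
        P = trace_or_P.density_series()
    else:
        P = np.asarray(trace_or_P)
    if P.ndim != 3 or P.shape[1] != P.shape[2] or P.shape[1] != S.shape[0]:
        raise ValueError(f"density series {P.shape} inconsistent with S {S.shape}")
    return np.einsum("tmn,nm->tm", P, S, optimize=True)


# a stationary (unpulsed) trace produces numerators at the numerical-noise
# floor (~1e-12); anything below this is not a meaningful variation
_STATIONARY_FLOOR = 1e-9


def _normalize(numer: np.ndarray) -> np.ndarray:
    mean = numer.mean()
    if mean <= _STATIONARY_FLOOR:
        raise DegenerateTraceError(
            "all indicator numerators are at the noise floor: the trace is "
            "stationary (was the pulse applied?)"
        )
    return numer / mean


def compute_xDC(O_series: np.ndarray) -> np.ndarray:
    """Unit-mean density-contribution indicator from an O_mu(t) series."""
    O = np.asarray(O_series)
    if O.shape[0] < 2:
        raise ValueError("need at least two time points")
    return _normalize(complex_std(O, axis=0))


def compute_xIP(trace_or_C) -> np.ndarray:
    """Unit-mean propagation-stability indicator from the C(t) series.

    The per-MO standard deviations are summed over all MOs (occupied and
    virtual alike: the full coefficient matrix enters the propagation).
    """
    if isinstance(trace_or_C, PropagationTrace):
        C = trace_or_C.C
        if C is None:
            raise ValueError("trace was recorded without orbitals")
    else:
        C = np.asarray(trace_or_C)
    if C.ndim != 3 or C.shape[0] < 2:
        raise ValueError("need a (n_frames, N_AO, N_MO) series with >= 2 frames")
    per_mo = complex_std(C, axis=0)          # (N_AO, N_MO)
    return _normalize(per_mo.sum(axis=1))


def jaccard(xdc: np.ndarray, xip: np.ndarray, xthr: float) -> float:
    """Jaccard index |A & B| / |A | B| between the sub-threshold sets
    A = {mu: x^DC < thr} and B = {mu: x^IP < thr}; 0.0 when both are empty."""
    A = np.asarray(xdc) < xthr
    B = np.asarray(xip) < xthr
    union = int(np.sum(A | B))
    if union == 0:
        return 0.0
    return float(np.sum(A & B)) / union


def jaccard_curve(xdc, xip, thresholds) -> np.ndarray:
    return np.array([jaccard(xdc, xip, t) for t in thresholds])


@dataclass
class IndicatorReport:
    """Indicator vectors plus the kept/deleted partition at one threshold."""

    labels: list[AOFunctionLabel]
    xdc: np.ndarray
    xip: np.ndarray
    xthr: float
    level: str
    deleted: set[AOFunctionLabel]
    kept: set[AOFunctionLabel] = field(default_factory=set)

    def __post_init__(self):
        if not self.kept:
            self.kept = set(self.labels) - self.deleted

    @property
    def n_ao(self) -> int:
        return len(self.labels)

    @property
    def n_deleted(self) -> int:
        return len(self.deleted)

    @property
    def n_kept(self) -> int:
        return len(self.kept)

    def jaccard(self) -> float:
        return jaccard(self.xdc, self.xip, self.xthr)

    def to_json_dict(self) -> dict:
        return {
            "xthr": self.xthr,
            "level": self.level,
            "n_ao": self.n_ao,
            "n_deleted": self.n_deleted,
            "labels": [str(l) for l in self.labels],
            "xdc": [float(x) for x in self.xdc],
            "xip": [float(x) for x in self.xip],
            "deleted": sorted(str(l) for l in self.deleted),
        }


def select_truncation(
    xdc: np.ndarray,
    xip: np.ndarray,
    xthr: float,
    labels: list[AOFunctionLabel],
    level: str = "function",
    guard_factor: float = 2.0,
) -> IndicatorReport:
    """Choose the functions to delete at threshold ``xthr``.

    Function level: mu is deleted iff x^DC_mu < thr AND x^IP_mu < thr
    (functions are kept on a strictly-greater criterion, so exact ties are
    deleted). Shell level: a shell survives iff strictly more than half of
    its member functions individually survive; discarding a shell that
    contains a member with x^DC >= guard_factor * xthr triggers a warning,
    since a strong dipole contributor would be lost with it.
    """
    xdc = np.asarray(xdc)
    xip = np.asarray(xip)
    if xthr <= 0:
        raise ValueError("xthr must be positive")
    if not (len(xdc) == len(xip) == len(labels)):
        raise ValueError("indicator vectors and labels must have equal length")
    func_deleted = (xdc <= xthr) & (xip <= xthr)

    if level == "function":
        deleted = {lab for lab, d in zip(labels, func_deleted) if d}
    elif level == "shell":
        members: dict[tuple[int, int, int], list[int]] = {}
        for idx, lab in enumerate(labels):
            members.setdefault(lab.shell_id, []).append(idx)
        deleted = set()
        for sid, idxs in members.items():
            kept_count = sum(1 for i in idxs if not func_deleted[i])
            if kept_count * 2 > len(idxs):
                continue  # majority kept -> whole shell kept
            strong = [i for i in idxs if xdc[i] >= guard_factor * xthr]
            if strong:
                warnings.warn(
                    f"shell {labels[idxs[0]].element}{sid[0]} l={sid[1]} "
                    f"k={sid[2]} is majority-deletable but member "
                    f"{labels[strong[0]]} has x^DC = {xdc[strong[0]]:.3f} >= "
                    f"{guard_factor} * x^thr; check before discarding",
                    stacklevel=2,
                )
            deleted.update(labels[i] for i in idxs)
    else:
        raise ValueError(f"unknown truncation level {level!r}")

    return IndicatorReport(
        labels=list(labels), xdc=xdc, xip=xip, xthr=xthr,
        level=level, deleted=deleted,
    )


def indicators_from_trace(
    trace: PropagationTrace, S: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Convenience: (x^DC, x^IP) from an orbital-recording trace."""
    O = compute_O_series(trace, S)
    return compute_xDC(O), compute_xIP(trace)


def export_map(report: IndicatorReport) -> pd.DataFrame:
    """Tabular form of the x^DC-x^IP map: one row per AO with both
    indicators, their product, ascending ranks on each axis (the axes of
    the map figures), and the kept flag."""
    df = pd.DataFrame(
        {
            "label": [str(l) for l in report.labels],
            "atom": [l.atom for l in report.labels],
            "element": [l.element for l in report.labels],
            "shell": [f"{l.k}{l.m_name}" for l in report.labels],
            "xdc": report.xdc,
            "xip": report.xip,
        }
    )
    df["product"] = df["xdc"] * df["xip"]
    df["rank_dc"] = df["xdc"].rank(method="first").astype(int)
    df["rank_ip"] = df["xip"].rank(method="first").astype(int)
    kept = {str(l) for l in report.kept}
    df["kept"] = df["label"].isin(kept)
    return df


def plot_map(report: IndicatorReport, path=None):
    """Optional x^DC-x^IP map figure (rank-vs-rank squares colored by
    x^DC * x^IP); requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = export_map(report).sort_values("rank_dc")
    fig, ax = plt.subplots(figsize=(5, 5))
    sc = ax.scatter(
        df["rank_dc"], df["rank_ip"], c=df["product"], cmap="viridis",
        marker="s", s=120,
    )
    thr_dc = int(np.sum(report.xdc < report.xthr))
    thr_ip = int(np.sum(report.xip < report.xthr))
    ax.axvline(thr_dc + 0.5, color="red", ls="--", lw=1)
    ax.axhline(thr_ip + 0.5, color="red", ls="--", lw=1)
    ax.set_xlabel("rank by $x^{DC}$")
    ax.set_ylabel("rank by $x^{IP}$")
    fig.colorbar(sc, label="$x^{DC} \\cdot x^{IP}$")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
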