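"""Absorption spectra from the time-dependent dipole of a delta-pulse run.

The induced dipole along the pulse axis is baseline-subtracted, damped with
exp(-gamma t), zero-padded and Fourier transformed; the absorption
intensity is proportional to omega * Im[d(omega)] / |kappa|, which for a
weak impulsive kick is the dipole strength function up to a constant.
A constant dipole (unpulsed run) transforms to an identically zero
spectrum. Comparisons between bases use peak positions, which are
insensitive to the (common) damping and grid choices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .rtp import PropagationTrace

HARTREE_EV = 27.211386245988


class SpectrumError(ValueError):
    pass


@dataclass
class Spectrum:
    """Frequency grid (eV) and absorption intensity (arbitrary units) for
    one pulse polarization."""

    freq_ev: np.ndarray
    intensity: np.ndarray
    gamma: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.freq_ev.shape != self.intensity.shape:
            raise SpectrumError("grid/intensity shape mismatch")
        if np.any(np.diff(self.freq_ev) <= 0):
            raise SpectrumError("frequency grid must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise SpectrumError("non-finite intensity")

    @property
    def grid_spacing(self) -> float:
        return float(self.freq_ev[1] - self.freq_ev[0])

    def window(self, lo: float, hi: float) -> "Spectrum":
        m = (self.freq_ev >= lo) & (self.freq_ev <= hi)
        if not np.any(m):
            raise SpectrumError(f"empty window [{lo}, {hi}] eV")
        return Spectrum(self.freq_ev[m], self.intensity[m], self.gamma,
                        dict(self.metadata))

    def save(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.freq_ev, self.intensity]),
            header="freq_eV  intensity_au",
        )


def dipole_to_spectrum(
    trace: PropagationTrace,
    kappa,
    gamma: float = 0.004,
    padding: int = 4,
) -> Spectrum:
    """Spectrum along the pulse axis from a single-direction delta-pulse run.

    gamma is the exponential damping rate in inverse atomic time units
    (0.004 a.u. gives a line width of roughly 0.1-0.2 eV); padding is the
    zero-padding factor of the discrete Fourier transform.
    """
    k = np.asarray(kappa, dtype=float)
    knorm = float(np.linalg.norm(k))
    if knorm == 0.0:
        raise SpectrumError("kappa = 0: the trace contains no excitation")
    axis = k / knorm
    signal = (trace.dipole - trace.dipole[0]) @ axis
    t = trace.times
    damped = signal * np.exp(-gamma * t)
    n = int(len(damped) * max(1, padding))
    # d(omega) = dt * sum_n d_n exp(+i omega t_n) = dt * conj(rfft(d))_k
    dtil = np.conj(np.fft.rfft(damped, n=n)) * trace.dt
    omega_au = 2.0 * np.pi * np.fft.rfftfreq(n, d=trace.dt)
    intensity = omega_au * np.imag(dtil) / knorm
    return Spectrum(
        freq_ev=omega_au * HARTREE_EV,
        intensity=intensity,
        gamma=gamma,
        metadata={
            "kappa": list(map(float, k)),
            "n_steps": trace.n_steps,
            "dt": trace.dt,
            "basis": trace.metadata.get("basis", ""),
            "padding": padding,
        },
    )


def isotropic_spectrum(spectra: list[Spectrum]) -> Spectrum:
    """Average of the three Cartesian-pulse spectra (same grid required)."""
    if len(spectra) != 3:
        raise SpectrumError("isotropic average needs x, y and z runs")
    grid = spectra[0].freq_ev
    for s in spectra[1:]:
        if s.freq_ev.shape != grid.shape or not np.allclose(s.freq_ev, grid):
            raise SpectrumError("spectra are on different grids")
    inten = np.mean([s.intensity for s in spectra], axis=0)
    return Spectrum(grid.copy(), inten, spectra[0].gamma,
                    {"isotropic": True})


def peak_positions(
    spec: Spectrum,
    window: tuple[float, float],
    min_rel_height: float = 0.02,
) -> list[float]:
    """Local maxima within ``window`` (eV) above min_rel_height times the
    window maximum, ascending."""
    sub = spec.window(*window)
    top = float(np.max(sub.intensity))
    if top <= 0.0:
        return []
    idx, _ = find_peaks(sub.intensity, height=min_rel_height * top)
    return [float(sub.freq_ev[i]) for i in idx]


def peak_shift(
    spec_a: Spectrum,
    spec_b: Spectrum,
    window: tuple[float, float],
    min_rel_height: float = 0.02,
    match_window: float = 1.0,
) -> dict:
    """Greedy nearest-neighbor matching of the two peak lists inside
    ``window``; returns the maximum absolute matched shift (eV) plus the
    matches and any unmatched peaks."""
    peaks_a = peak_positions(spec_a, window, min_rel_height)
    peaks_b = peak_positions(spec_b, window, min_rel_height)
    if not peaks_a and not peaks_b:
        raise SpectrumError("no peaks found in either spectrum")
    remaining = list(peaks_b)
    matches: list[tuple[float, float]] = []
    unmatched_a: list[float] = []
    for pa in peaks_a:
        if not remaining:
            unmatched_a.append(pa)
            continue
        j = int(np.argmin([abs(pb - pa) for pb in remaining]))
        if abs(remaining[j] - pa) <= match_window:
            matches.append((pa, remaining.pop(j)))
        else:
            unmatched_a.append(pa)
    max_shift = max((abs(a - b) for a, b in matches), default=0.0)
    return {
        "max_shift": max_shift,
        "matches": matches,
        "unmatched_a": unmatched_a,
        "unmatched_b": remaining,
    }
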