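"""Spectral prescriptions and analytic spectra of the linear stochastic model.

The model is a multivariate Ornstein-Uhlenbeck (OU) process

    dx/dt = W x + sigma * xi(t),

where ``W`` (units 1/s) is the functional connectivity matrix and ``xi`` is
channel-wise white noise. The channel-averaged power spectrum of this process
is a superposition of Lorentzians: each complex-conjugate eigenvalue pair
``a ± ib`` of ``W`` contributes a spectral peak at frequency ``b / 2π`` Hz
whose half width at half maximum (HWHM) is ``|a| / 2π`` Hz; real eigenvalues
contribute to the non-oscillatory 1/f^2 background.

This module builds eigenvalue prescriptions for five experimental scenarios
(Normal, Entrained, Incomplete, Background, Random) and evaluates the analytic
spectral quantities of a given ``W``: power spectrum, cross-spectrum,
coherence, phase spectrum and log-log spectral slope.

Unit convention: eigenvalues are stored in rad/s; every user-facing frequency
is in Hz with ``f = Im λ / 2π`` and ``hwhm = |Re λ| / 2π``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "GROUPS",
    "SpectralPeak",
    "PrescriptionConfig",
    "SpectrumPrescription",
    "EigenvalueSet",
    "SpectrumCurve",
    "CrossSpectrum",
    "build_prescription",
    "eigenvalues_from_prescription",
    "default_grid",
    "analytic_power_spectrum",
    "lorentzian_spectrum",
    "cross_spectrum",
    "coherence_phase",
    "spectral_slope",
    "find_spectral_peaks",
]

#: The five experimental scenarios.
GROUPS = ("Normal", "Entrained", "Incomplete", "Background", "Random")

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class SpectralPeak:
    """One spectral peak: location and half width at half maximum, both Hz."""

    f_peak: float
    hwhm: float

    def __post_init__(self) -> None:
        if not self.f_peak > 0:
            raise ValueError(f"f_peak must be > 0, got {self.f_peak}")
        if not self.hwhm > 0:
            raise ValueError(f"hwhm must be > 0, got {self.hwhm}")


@dataclass(frozen=True)
class PrescriptionConfig:
    """Parameters from which group prescriptions are generated.

    Attributes
    ----------
    base_freq : float
        Lowest peak frequency of the Normal group (Hz).
    ratio : float
        Constant ratio between consecutive Normal peaks (geometric sequence,
        i.e. evenly spaced on a logarithmic frequency axis).
    n_peaks : int
        Number of peaks in the Normal group.
    hwhm_factor : float
        HWHM of each peak as a fraction of its peak frequency.
    bandwidth_limit : float
        Maximum admissible peak frequency (Hz); the default Normal sequence
        keeps significant power between 0 and 300 Hz.
    entrained_bands : tuple of float
        Peak frequencies of the Entrained group; the defaults, 2.7 and 8.1 Hz,
        are locked at an exact 1:3 ratio, producing cross-frequency
        phase-locking.
    incomplete_removed : int
        How many of the highest-frequency Normal peaks the Incomplete group
        drops (loss of high-frequency rhythms).
    n_nodes : int
        Network size N.
    sigma : float
        Standard deviation of the white-noise drive (signal units / sqrt(s)).
    """

    base_freq: float = 2.0
    ratio: float = 2.6
    n_peaks: int = 6
    hwhm_factor: float = 0.2
    bandwidth_limit: float = 300.0
    entrained_bands: tuple[float, ...] = (2.7, 8.1)
    incomplete_removed: int = 2
    n_nodes: int = 80
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("ratio must be positive")
        if self.base_freq <= 0:
            raise ValueError("base_freq must be positive")
        if self.hwhm_factor <= 0:
            raise ValueError("hwhm_factor must be positive")


@dataclass(frozen=True)
class SpectrumPrescription:
    """Target spectrum: a peak list, a group tag and the network size.

    ``real_eig_bounds`` is the interval (rad/s, negative) from which the real
    eigenvalues — the non-oscillatory background — are drawn uniformly.
    """

    group: str
    peaks: tuple[SpectralPeak, ...]
    n_nodes: int
    real_eig_bounds: tuple[float, float]
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.group == "Background" and self.peaks:
            raise ValueError("Background prescriptions have no peaks")
        if 2 * len(self.peaks) > self.n_nodes:
            raise ValueError(
                f"{len(self.peaks)} peaks need {2 * len(self.peaks)} eigenvalues "
                f"but n_nodes={self.n_nodes}"
            )
        lo, hi = self.real_eig_bounds
        if not (lo <= hi < 0):
            raise ValueError("real_eig_bounds must be a subinterval of (-inf, 0)")

    @property
    def n_real(self) -> int:
        return self.n_nodes - 2 * len(self.peaks)


@dataclass(frozen=True)
class EigenvalueSet:
    """Eigenvalues of a stable drift matrix, closed under conjugation.

    ``complex_pairs`` holds one representative ``a + ib`` (a < 0, b > 0) per
    conjugate pair, in rad/s; ``reals`` holds the negative real eigenvalues.
    """

    complex_pairs: tuple[complex, ...]
    reals: tuple[float, ...]

    def __post_init__(self) -> None:
        for lam in self.complex_pairs:
            if not (lam.real < 0 and lam.imag > 0):
                raise ValueError(f"complex pair representative {lam} must have Re<0, Im>0")
        for lam in self.reals:
            if not lam < 0:
                raise ValueError(f"real eigenvalue {lam} must be negative")

    @property
    def n(self) -> int:
        return 2 * len(self.complex_pairs) + len(self.reals)

    def all_eigenvalues(self) -> np.ndarray:
        """Full spectrum including conjugates, as a complex array."""
        pairs = np.asarray(self.complex_pairs, dtype=complex)
        return np.concatenate([pairs, pairs.conj(), np.asarray(self.reals, dtype=complex)])


@dataclass(frozen=True)
class SpectrumCurve:
    """A power spectrum sampled on a frequency grid (Hz, power >= 0)."""

    frequencies: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        p = np.asarray(self.power, dtype=float)
        if f.ndim != 1 or np.any(np.diff(f) <= 0) or np.any(f <= 0):
            raise ValueError("frequency grid must be strictly increasing and positive")
        if p.shape[-1] != f.shape[0]:
            raise ValueError("power and frequency grids differ in length")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "power", p)


@dataclass(frozen=True)
class CrossSpectrum:
    """Per-frequency N x N complex cross-spectral matrix S(f)."""

    frequencies: np.ndarray
    matrices: np.ndarray  # shape (F, N, N), complex

    @property
    def n_nodes(self) -> int:
        return self.matrices.shape[-1]

    def node_spectra(self) -> SpectrumCurve:
        """Per-node power spectra: the (real) diagonal of S(f), shape (N, F)."""
        diag = np.einsum("fii->fi", self.matrices).real.T
        return SpectrumCurve(self.frequencies, diag)


# ---------------------------------------------------------------------------
# Prescription building
# ---------------------------------------------------------------------------

def _normal_peaks(config: PrescriptionConfig) -> tuple[SpectralPeak, ...]:
    freqs = config.base_freq * config.ratio ** np.arange(config.n_peaks)
    return tuple(SpectralPeak(float(f), float(config.hwhm_factor * f)) for f in freqs)


def _check_bandwidth(peaks: Sequence[SpectralPeak], config: PrescriptionConfig) -> None:
    for p in peaks:
        if p.f_peak > config.bandwidth_limit:
            raise ValueError(
                f"peak at {p.f_peak:g} Hz exceeds the bandwidth limit "
                f"({config.bandwidth_limit:g} Hz)"
            )


def _normal_reference_bounds(config: PrescriptionConfig) -> tuple[float, float]:
    """Bounds for the real eigenvalues: [min, max] of the real parts of the
    Normal group's complex pairs under the same config (rad/s)."""
    res = [-TWO_PI * p.hwhm for p in _normal_peaks(config)]
    return (min(res), max(res))


def build_prescription(
    group: str,
    config: PrescriptionConfig = PrescriptionConfig(),
    seed: int = 0,
) -> SpectrumPrescription:
    """Build the spectral prescription of one of the five scenarios.

    Normal: peak frequencies form a geometric sequence (evenly spaced on a
    logarithmic axis). Entrained: peaks at exact small-integer frequency
    ratios (default 2.7 and 8.1 Hz, ratio 1:3). Incomplete: Normal with the
    top-frequency peaks removed. Background: no peaks at all. Random:
    Normal's peak count with frequencies drawn uniformly on the log-frequency
    axis over Normal's span — a fresh draw per seed.

    All groups reuse the Normal group's real-eigenvalue bounds, so the
    non-oscillatory background is conserved across scenarios.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    normal = _normal_peaks(config)
    bounds = _normal_reference_bounds(config)
    if group == "Normal":
        peaks = normal
    elif group == "Entrained":
        peaks = tuple(
            SpectralPeak(f, config.hwhm_factor * f) for f in sorted(config.entrained_bands)
        )
    elif group == "Incomplete":
        kept = max(1, config.n_peaks - config.incomplete_removed)
        peaks = normal[:kept]
    elif group == "Background":
        peaks = ()
    else:  # Random
        rng = np.random.default_rng(seed)
        lo, hi = np.log(normal[0].f_peak), np.log(normal[-1].f_peak)
        freqs = np.sort(np.exp(rng.uniform(lo, hi, size=config.n_peaks)))
        peaks = tuple(SpectralPeak(f, config.hwhm_factor * f) for f in freqs)
    _check_bandwidth(peaks, config)
    return SpectrumPrescription(
        group=group,
        peaks=peaks,
        n_nodes=config.n_nodes,
        real_eig_bounds=bounds,
        sigma=config.sigma,
        seed=seed,
    )


def eigenvalues_from_prescription(presc: SpectrumPrescription) -> EigenvalueSet:
    """Map a prescription to a full eigenvalue set of size ``n_nodes``.

    Each peak (f, hwhm) becomes a conjugate pair ``-2π·hwhm ± i·2π·f`` rad/s.
    The remaining real eigenvalues are drawn uniformly from
    ``real_eig_bounds`` with the prescription's seed.
    """
    pairs = tuple(complex(-TWO_PI * p.hwhm, TWO_PI * p.f_peak) for p in presc.peaks)
    rng = np.random.default_rng(presc.seed)
    lo, hi = presc.real_eig_bounds
    reals = tuple(float(x) for x in rng.uniform(lo, hi, size=presc.n_real))
    return EigenvalueSet(complex_pairs=pairs, reals=reals)


# ---------------------------------------------------------------------------
# Analytic spectra
# ---------------------------------------------------------------------------

def default_grid(f_min: float = 0.1, f_max: float = 500.0, n: int = 512) -> np.ndarray:
    """Logarithmically spaced frequency grid in Hz."""
    return np.geomspace(f_min, f_max, n)


def _check_stable(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be a square matrix")
    eig = np.linalg.eigvals(W)
    if np.any(eig.real >= 0):
        raise ValueError(
            "W is not stable: an eigenvalue has non-negative real part "
            f"(max Re = {eig.real.max():g})"
        )
    return W


def analytic_power_spectrum(
    W: np.ndarray, sigma: float, grid: np.ndarray | None = None
) -> SpectrumCurve:
    """Channel-averaged analytic power spectrum of the OU process.

    P(f) = (sigma^2 / N) * || (i 2πf I - W)^{-1} ||_F^2, the trace of the
    cross-spectral matrix divided by N.
    """
    W = _check_stable(W)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    n = W.shape[0]
    eye = np.eye(n)
    power = np.empty_like(grid)
    for k, f in enumerate(grid):
        R = np.linalg.inv(1j * TWO_PI * f * eye - W)
        power[k] = (sigma**2 / n) * np.sum(np.abs(R) ** 2)
    return SpectrumCurve(grid, power)


def lorentzian_spectrum(
    eigs: EigenvalueSet | np.ndarray,
    sigma: float,
    grid: np.ndarray | None = None,
    n_nodes: int | None = None,
) -> SpectrumCurve:
    """Sum-of-Lorentzians spectrum built from the eigenvalues alone.

    P(f) = (sigma^2 / N) * sum_k 1 / |i 2πf - λ_k|^2. This equals the
    analytic spectrum of any *normal* matrix with those eigenvalues and is
    used to preview a prescription before the inverse problem is solved.
    """
    if isinstance(eigs, EigenvalueSet):
        lam = eigs.all_eigenvalues()
    else:
        lam = np.asarray(eigs, dtype=complex)
    if np.any(lam.real >= 0):
        raise ValueError("all eigenvalues must have negative real part")
    n = len(lam) if n_nodes is None else n_nodes
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    omega = TWO_PI * grid
    power = (sigma**2 / n) * np.sum(
        1.0 / np.abs(1j * omega[:, None] - lam[None, :]) ** 2, axis=1
    )
    return SpectrumCurve(grid, power)


def cross_spectrum(
    W: np.ndarray, sigma: float, grid: np.ndarray | None = None
) -> CrossSpectrum:
    """Analytic cross-spectral matrix S(f) = sigma^2 R(f) R(f)^† with
    R(f) = (i 2πf I - W)^{-1}.

    S(f) is Hermitian positive semidefinite at every frequency; its diagonal
    holds the per-node power spectra and its mean diagonal is the
    channel-averaged power spectrum.
    """
    W = _check_stable(W)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    n = W.shape[0]
    eye = np.eye(n)
    S = np.empty((len(grid), n, n), dtype=complex)
    for k, f in enumerate(grid):
        R = np.linalg.inv(1j * TWO_PI * f * eye - W)
        S[k] = sigma**2 * (R @ R.conj().T)
    return CrossSpectrum(grid, S)


def coherence_phase(cs: CrossSpectrum) -> tuple[np.ndarray, np.ndarray]:
    """Coherence and phase spectrum from a cross-spectral matrix.

    The coherency is the normalized cross-spectrum
    ``S_ij / sqrt(S_ii S_jj)``; the coherence is its magnitude squared
    (in [0, 1]) and the phase spectrum is its angle (in (-π, π]).
    Pairs with vanishing diagonal power yield NaN.

    Returns
    -------
    (coherence, phase) : arrays of shape (F, N, N)
    """
    S = cs.matrices
    diag = np.einsum("fii->fi", S).real
    denom = np.sqrt(diag[:, :, None] * diag[:, None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        coherency = np.where(denom > 0, S / denom, np.nan + 0j)
    coherence = np.clip(np.abs(coherency) ** 2, 0.0, 1.0)
    phase = np.angle(coherency)
    return coherence, phase


def spectral_slope(curve: SpectrumCurve, f_lo: float, f_hi: float) -> float:
    """Power-law exponent α of the spectral decay P ∝ f^{-α} on a band.

    Least-squares slope of log10 P against log10 f over [f_lo, f_hi],
    returned with the sign convention that a decaying spectrum has α > 0.
    """
    f = curve.frequencies
    mask = (f >= f_lo) & (f <= f_hi)
    if mask.sum() < 3:
        raise ValueError("need at least 3 grid points inside the band")
    p = curve.power[..., mask]
    if p.ndim > 1:
        p = p.mean(axis=0)
    if np.any(p <= 0):
        raise ValueError("power must be strictly positive on the band")
    slope = np.polyfit(np.log10(f[mask]), np.log10(p), 1)[0]
    return float(-slope)


def find_spectral_peaks(
    curve: SpectrumCurve,
    f_lo: float | None = None,
    f_hi: float | None = None,
    min_rel_height: float = 0.0,
) -> np.ndarray:
    """Frequencies of local maxima of a spectrum, refined by quadratic
    interpolation in (log f, log P) around each maximum.

    ``min_rel_height`` discards maxima whose power is below that fraction of
    the tallest local maximum in the band.
    """
    from scipy.signal import argrelmax

    f, p = curve.frequencies, curve.power
    if p.ndim > 1:
        p = p.mean(axis=0)
    mask = np.ones_like(f, dtype=bool)
    if f_lo is not None:
        mask &= f >= f_lo
    if f_hi is not None:
        mask &= f <= f_hi
    fb, pb = f[mask], p[mask]
    idx = argrelmax(pb)[0]
    if idx.size == 0:
        return np.array([])
    keep = pb[idx] >= min_rel_height * pb[idx].max()
    idx = idx[keep]
    peaks = []
    for i in idx:
        if 0 < i < len(fb) - 1:
            # quadratic vertex through the three log-log points
            x = np.log(fb[i - 1 : i + 2])
            y = np.log(pb[i - 1 : i + 2])
            denom = (y[0] - 2 * y[1] + y[2])
            if denom < 0:
                shift = 0.5 * (y[0] - y[2]) / denom
                shift = np.clip(shift, -0.5, 0.5)
                x0 = x[1] + shift * (x[2] - x[0]) / 2.0
                peaks.append(np.exp(x0))
                continue
        peaks.append(fb[i])
    return np.asarray(sorted(peaks))
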