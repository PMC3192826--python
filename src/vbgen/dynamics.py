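"""Forward problem: simulate the OU dynamics and estimate spectra from traces.

Simulation uses the Euler-Maruyama scheme

    x <- x + dt * W x + sqrt(dt) * sigma * eta,

with standard-normal ``eta`` per channel and step, an all-zero initial state
and a discarded burn-in. The drive can optionally be low-pass filtered
("colored") noise with time constant tau, which steepens the high-frequency
spectral drop-off from 1/f^2 to 1/f^4.

Spectral estimation (Welch periodograms, spectrograms) wraps scipy.signal;
``estimate_W_from_timeseries`` recovers the connectivity matrix from recorded
traces by regressing finite-difference derivatives onto the state — the
empirical route to W when only recordings are available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .spectra import SpectrumCurve

__all__ = [
    "NoiseDescriptor",
    "TimeSeriesPanel",
    "simulate",
    "welch_spectrum",
    "spectrogram",
    "estimate_W_from_timeseries",
]


@dataclass(frozen=True)
class NoiseDescriptor:
    """White drive (tau is None) or exponential low-pass drive with time
    constant tau (seconds); sigma in signal units / sqrt(s)."""

    sigma: float = 1.0
    tau: float | None = None


@dataclass(frozen=True)
class TimeSeriesPanel:
    """Simulated multichannel traces: ``data`` is channels x samples."""

    data: np.ndarray
    dt: float
    noise: NoiseDescriptor = NoiseDescriptor()

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if not np.all(np.isfinite(d)):
            raise ValueError("data contains non-finite values")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        object.__setattr__(self, "data", d)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt


def simulate(
    W: np.ndarray,
    sigma: float = 1.0,
    dt: float = 2e-4,
    duration: float = 60.0,
    seed: int = 0,
    noise: str | NoiseDescriptor = "white",
    burn_in: float = 2.0,
) -> TimeSeriesPanel:
    """Integrate dx/dt = W x + sigma * xi numerically (Euler-Maruyama).

    ``noise`` is either "white" or a :class:`NoiseDescriptor` with a low-pass
    time constant tau; the colored drive is white noise passed through a
    one-pole exponential filter and rescaled to unit variance, so the total
    drive power is comparable across the two modes. The step must resolve the
    fastest mode: dt <= 0.1 / rho(W) (spectral radius in rad/s). Deterministic
    for a fixed seed.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    eigs = np.linalg.eigvals(W)
    if np.any(eigs.real >= 0):
        raise ValueError("W must be stable (all eigenvalue real parts < 0)")
    rho = np.abs(eigs).max()
    if dt > 0.1 / rho:
        raise ValueError(
            f"dt={dt:g} too coarse for spectral radius {rho:.3g} rad/s; "
            f"need dt <= {0.1 / rho:.3g}"
        )
    if isinstance(noise, str):
        if noise != "white":
            raise ValueError("noise must be 'white' or a NoiseDescriptor")
        noise = NoiseDescriptor(sigma=sigma)
    elif noise.sigma != sigma:
        noise = NoiseDescriptor(sigma=sigma, tau=noise.tau)

    n_burn = int(round(burn_in / dt))
    n_keep = int(round(duration / dt))
    n_tot = n_burn + n_keep
    rng = np.random.default_rng(seed)
    # propagator pieces reused every step
    A = np.eye(n) + dt * W
    amp = np.sqrt(dt) * sigma

    if noise.tau is not None:
        a = np.exp(-dt / noise.tau)
        # one-pole low-pass scaled back to unit stationary variance
        gain = np.sqrt((1 - a**2))
        eta_state = np.zeros(n)
    x = np.zeros(n)
    out = np.empty((n, n_keep))
    for k in range(n_tot):
        eta = rng.standard_normal(n)
        if noise.tau is not None:
            eta_state = a * eta_state + gain * eta
            eta = eta_state
        x = A @ x + amp * eta
        if k >= n_burn:
            out[:, k - n_burn] = x
    return TimeSeriesPanel(out, dt, noise)


def welch_spectrum(
    panel: TimeSeriesPanel,
    segment_s: float = 2.0,
    overlap: float = 0.5,
) -> tuple[SpectrumCurve, SpectrumCurve]:
    """Welch power spectra of the panel (Hann window).

    Returns ``(per_channel, average)``: per-channel spectra stacked as a
    (N, F) power array, and the channel-averaged spectrum. The record must
    hold at least ~8 segments for a usable average.
    """
    nperseg = int(round(segment_s / panel.dt))
    if nperseg > panel.n_samples:
        raise ValueError("segment longer than the record")
    n_segments = panel.n_samples // max(1, int(nperseg * (1 - overlap)))
    if n_segments < 8:
        raise ValueError(
            f"record too short: only ~{n_segments} Welch segments, need >= 8"
        )
    f, p = signal.welch(
        panel.data,
        fs=1.0 / panel.dt,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)),
        axis=-1,
    )
    # two-sided density convention, to match the analytic OU spectra
    f, p = f[1:], 0.5 * p[:, 1:]  # DC bin dropped (log-frequency plots)
    return SpectrumCurve(f, p), SpectrumCurve(f, p.mean(axis=0))


def spectrogram(
    panel: TimeSeriesPanel,
    channel: int,
    window_s: float = 0.5,
    step_s: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Time-resolved power spectrum (short-time periodograms, Hann window).

    Returns ``(frequencies, times, power)`` with power of shape (F, T).
    """
    nperseg = int(round(window_s / panel.dt))
    if nperseg > panel.n_samples:
        raise ValueError("window longer than the record")
    step = int(round(step_s / panel.dt))
    f, t, p = signal.spectrogram(
        panel.data[channel],
        fs=1.0 / panel.dt,
        window="hann",
        nperseg=nperseg,
        noverlap=max(0, nperseg - step),
    )
    return f, t, p


def estimate_W_from_timeseries(panel: TimeSeriesPanel) -> tuple[np.ndarray, float]:
    """Estimate W by linear regression of the traces' time derivative on the
    traces themselves.

    Forward differences (x(t+dt) - x(t)) / dt are regressed onto x(t) by
    least squares, channel by channel (shared regressor matrix). Returns
    ``(W_hat, sigma_hat)`` where sigma_hat^2 estimates the white-drive
    variance from the regression residuals (the residual of one Euler step
    has variance sigma^2 * dt, i.e. variance sigma^2/dt on the derivative
    scale). Forward differencing biases W_hat at coarse dt by O(dt * W^2).
    """
    X = panel.data[:, :-1].T  # samples x channels
    dX = (panel.data[:, 1:] - panel.data[:, :-1]).T / panel.dt
    n = panel.n_channels
    if X.shape[0] < n**2:
        raise ValueError("record too short: need samples >> channels^2")
    sol, _, rank, _ = np.linalg.lstsq(X, dX, rcond=None)
    if rank < n:
        raise ValueError("rank-deficient regressor matrix")
    W_hat = sol.T
    resid = dX - X @ sol
    sigma_hat = float(np.sqrt(np.mean(resid**2) * panel.dt))
    return W_hat, sigma_hat
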