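"""Closed-form covariance, neural complexity, nodal hierarchy and group tests.

The stationary covariance C of the OU process solves the Lyapunov equation
W C + C Wᵀ = -Q with Q = sigma^2 I. For diagonalizable W = L D L^{-1} it has
the closed form C = L C~ L† with C~_ij = -Q~_ij / (λ_i + conj(λ_j)) and
Q~ = L^{-1} Q L^{-†}; an ill-conditioned eigenvector matrix triggers a direct
Lyapunov solve instead. From C follow the per-channel fluctuation amplitudes
(sqrt of the diagonal) and the Tononi-Sporns-Edelman (TSE) neural complexity,

    C_N = sum_k [ <H(subset of size k)> - (k/N) H(all) ],

with Gaussian entropies H computed from log-determinants of covariance
submatrices — exact subset enumeration for small N, seeded Monte-Carlo subset
sampling otherwise.

Structural summaries are built from W directly: the Total Nodal Strength
(TNS, sum of absolute input and output weights of a node) and its descending
rank define the network hierarchy; removing single nodes and recomputing the
analytic spectrum quantifies each node's contribution to the brain rhythms;
a bootstrap test compares summary statistics between groups of virtual
brains.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .spectra import SpectrumCurve, analytic_power_spectrum, default_grid

__all__ = [
    "HierarchyCurve",
    "RemovalScanResult",
    "BootstrapResult",
    "stationary_covariance",
    "tse_complexity",
    "tns_and_hierarchy",
    "node_removal_scan",
    "bootstrap_mean_diff",
]


def stationary_covariance(
    W: np.ndarray, sigma: float = 1.0, cond_threshold: float = 1e10
) -> np.ndarray:
    """Stationary covariance of dx = W x dt + sigma dξ via the eigenvalue
    closed form, falling back to a direct Lyapunov solve when the eigenvector
    matrix is ill-conditioned.

    The result is symmetric positive semidefinite and satisfies
    W C + C Wᵀ = -sigma^2 I.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    lam, L = np.linalg.eig(W)
    if np.any(lam.real >= 0):
        raise ValueError("W must be stable")
    if np.linalg.cond(L) > cond_threshold:
        warnings.warn(
            "eigenvector matrix ill-conditioned; solving the Lyapunov "
            "equation directly",
            RuntimeWarning,
        )
        C = linalg.solve_continuous_lyapunov(W, -sigma**2 * np.eye(n))
    else:
        Linv = np.linalg.inv(L)
        Qt = sigma**2 * (Linv @ Linv.conj().T)
        Ct = -Qt / (lam[:, None] + lam[None, :].conj())
        C = (L @ Ct @ L.conj().T).real
    return 0.5 * (C + C.T)


def _gaussian_entropy(C_sub: np.ndarray, jitter: float = 1e-12) -> float:
    """Differential entropy of a zero-mean Gaussian with covariance C_sub."""
    k = C_sub.shape[0]
    sign, logdet = np.linalg.slogdet(C_sub)
    if sign <= 0:
        sign, logdet = np.linalg.slogdet(C_sub + jitter * np.eye(k))
        if sign <= 0:
            raise ValueError("covariance submatrix is not positive definite")
    return 0.5 * (k * np.log(2 * np.pi * np.e) + logdet)


def tse_complexity(
    C: np.ndarray,
    mode: str = "auto",
    n_subset_samples: int = 200,
    seed: int = 0,
    with_stderr: bool = False,
) -> float | tuple[float, float]:
    """Tononi-Sporns-Edelman neural complexity of a covariance matrix.

    Subset entropies are averaged exactly over all C(N, k) subsets when
    ``mode='exact'`` (the default for N <= 12 under ``mode='auto'``) or over
    ``n_subset_samples`` random subsets per size otherwise. The measure is
    zero for independent channels (diagonal C), invariant to channel
    permutations and to uniform rescaling of C, and nonnegative up to
    sampling error.

    With ``with_stderr=True`` returns ``(value, stderr)`` where stderr
    propagates the Monte-Carlo subset-sampling error (zero in exact mode).
    """
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    if np.any(np.diag(C) <= 0):
        raise ValueError("covariance diagonal must be strictly positive")
    if mode == "auto":
        mode = "exact" if n <= 12 else "mc"
    H_all = _gaussian_entropy(C)
    rng = np.random.default_rng(seed)
    total, var_total = 0.0, 0.0
    nodes = np.arange(n)
    for k in range(1, n):
        if mode == "exact":
            hs = [
                _gaussian_entropy(C[np.ix_(s, s)])
                for s in itertools.combinations(nodes, k)
            ]
        elif mode == "mc":
            hs = []
            for _ in range(n_subset_samples):
                s = rng.choice(n, size=k, replace=False)
                hs.append(_gaussian_entropy(C[np.ix_(s, s)]))
        else:
            raise ValueError("mode must be 'auto', 'exact' or 'mc'")
        hs = np.asarray(hs)
        total += hs.mean() - (k / n) * H_all
        if mode == "mc":
            var_total += hs.var(ddof=1) / len(hs)
    value = float(total)
    if with_stderr:
        return value, float(np.sqrt(var_total))
    return value


@dataclass(frozen=True)
class HierarchyCurve:
    """Normalized TNS against rank (rank 1 = strongest node).

    ``half_rank`` is the 50th percentile of ranked TNS: the smallest rank k
    such that nodes 1..k account for at least half the total nodal strength.
    A steep curve and a small half_rank signal a pronounced hierarchy.
    """

    normalized_tns: np.ndarray
    half_rank: int


def tns_and_hierarchy(
    W: np.ndarray, C: np.ndarray | None = None, sigma: float = 1.0
) -> tuple[pd.DataFrame, HierarchyCurve]:
    """Per-node strength table and the network's hierarchy curve.

    TNS_i sums the absolute off-diagonal input and output weights of node i
    (self-connections excluded: they are uniformly inhibitory and would mask
    hub structure). Ranks are assigned in descending TNS order. The table
    also holds the total excitatory / inhibitory input (sums of positive /
    |negative| row entries), the net input (row sum) and net output (column
    sum), and the fluctuation SD from the analytic covariance diagonal.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    off = W - np.diag(np.diag(W))
    tns = np.abs(off).sum(axis=1) + np.abs(off).sum(axis=0)
    order = np.argsort(-tns, kind="stable")
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(1, n + 1)
    if C is None:
        C = stationary_covariance(W, sigma)
    table = pd.DataFrame(
        {
            "node": np.arange(n),
            "tns": tns,
            "rank": rank,
            "excitatory_input": np.where(W > 0, W, 0.0).sum(axis=1),
            "inhibitory_input": np.where(W < 0, -W, 0.0).sum(axis=1),
            "net_input": W.sum(axis=1),
            "net_output": W.sum(axis=0),
            "fluctuation_sd": np.sqrt(np.diag(C)),
        }
    )
    sorted_tns = tns[order]
    ref = sorted_tns[0] if sorted_tns[0] > 0 else 1.0
    cum = np.cumsum(sorted_tns)
    half_rank = int(np.searchsorted(cum, 0.5 * cum[-1]) + 1)
    return table, HierarchyCurve(sorted_tns / ref, half_rank)


@dataclass(frozen=True)
class RemovalScanResult:
    """Spectral impact of removing each node in turn.

    ``errors[i]`` is the normalized summed absolute difference between the
    log10 spectra with and without node i; ``corr_rank`` / ``corr_tns`` are
    the Pearson correlations of the error with the removed node's TNS rank
    and TNS. ``unstable[i]`` flags submatrices that lost stability (possible
    for non-normal W; their spectrum is undefined and the error is NaN).
    """

    errors: np.ndarray
    unstable: np.ndarray
    corr_rank: float
    corr_tns: float
    spectra: np.ndarray  # (N, F) perturbed channel-averaged spectra
    baseline: SpectrumCurve


def node_removal_scan(
    W: np.ndarray,
    sigma: float = 1.0,
    grid: np.ndarray | None = None,
    method: str = "pearson",
) -> RemovalScanResult:
    """Delete each node (row and column) and recompute the analytic spectrum.

    error_i = sum_f |log10 P^(i) - log10 P| / sum_f |log10 P|.

    In rhythmic networks the strongest (low-rank) nodes carry the spectral
    peaks, so the error correlates negatively with rank.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if n < 3:
        raise ValueError("need at least 3 nodes")
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    baseline = analytic_power_spectrum(W, sigma, grid)
    logP = np.log10(baseline.power)
    norm = np.abs(logP).sum()
    errors = np.full(n, np.nan)
    unstable = np.zeros(n, dtype=bool)
    spectra = np.full((n, len(grid)), np.nan)
    keep_all = np.arange(n)
    for i in range(n):
        keep = keep_all[keep_all != i]
        Wi = W[np.ix_(keep, keep)]
        if np.any(np.linalg.eigvals(Wi).real >= 0):
            unstable[i] = True
            continue
        Pi = analytic_power_spectrum(Wi, sigma, grid).power
        spectra[i] = Pi
        errors[i] = np.abs(np.log10(Pi) - logP).sum() / norm
    table, _ = tns_and_hierarchy(W, C=np.eye(n))  # covariance not needed here
    ok = ~np.isnan(errors)
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr

    def _corr(x, y):
        if np.ptp(x) == 0 or ok.sum() < 3 or np.ptp(y) <= 1e-12 * np.abs(y).max():
            return float("nan")  # degenerate scan (e.g. isotropic network)
        return float(corr(x, y)[0])

    corr_rank = _corr(table["rank"][ok], errors[ok])
    corr_tns = _corr(table["tns"][ok], errors[ok])
    return RemovalScanResult(errors, unstable, corr_rank, corr_tns, spectra, baseline)


@dataclass(frozen=True)
class BootstrapResult:
    """Observed difference of group means and its bootstrap p-value."""

    observed: float
    p_value: float
    n_iterations: int

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value out of [0, 1]")


def bootstrap_mean_diff(
    values_a,
    values_b,
    n_iter: int = 100_000,
    seed: int = 0,
    alternative: str = "left",
) -> BootstrapResult:
    """Bootstrap test for a difference between two group means.

    Pools both groups, repeatedly re-splits the pool at random into groups of
    the original sizes and accumulates the null distribution of
    mean(a*) - mean(b*). With ``alternative='left'`` the p-value is the
    fraction of null draws at or below the observed difference (the integral
    of the null distribution from the left end up to the observed value);
    ``'two-sided'`` doubles the smaller tail.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if n_iter < 1000:
        warnings.warn("n_iter < 1000 gives a coarse p-value", RuntimeWarning)
    observed = float(a.mean() - b.mean())
    pool = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    null = np.empty(n_iter)
    for i in range(n_iter):
        perm = rng.permutation(pool.size)
        null[i] = pool[perm[: a.size]].mean() - pool[perm[a.size :]].mean()
    left = float(np.mean(null <= observed))
    if alternative == "left":
        p = left
    elif alternative == "two-sided":
        right = float(np.mean(null >= observed))
        p = min(1.0, 2.0 * min(left, right))
    else:
        raise ValueError("alternative must be 'left' or 'two-sided'")
    return BootstrapResult(observed=observed, p_value=p, n_iterations=n_iter)
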