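"""Configuration, file I/O, fixtures and the batch study driver.

The study driver ties the full pipeline together: prescribe a spectrum for
each group, solve the inverse eigenvalue problem for ``n_matrices`` seeds,
derive covariance-based and structural summaries per matrix (fluctuation
amplitudes and their correlations with nodal input, TSE complexity,
hierarchy, node-removal impact), pool the motif censuses per group, and run
bootstrap comparisons between groups. Everything is seeded, so a study is
reproducible from its config alone.

File formats are deliberately plain: matrices and tables as comma-separated
CSV with a header of node ids and 17 significant digits (so write-read-write
round-trips are byte-identical), prescriptions and configs as YAML, and an
optional HDF5 container that bundles a matrix with its provenance.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analytics, motifs
from .iep import ConnectivityMatrix, EntryConstraint, solve_iep
from .spectra import (
    EigenvalueSet,
    PrescriptionConfig,
    SpectralPeak,
    SpectrumCurve,
    SpectrumPrescription,
    build_prescription,
)
from .dynamics import TimeSeriesPanel

__all__ = [
    "StudyConfig",
    "StudyReport",
    "run_group_study",
    "fixture_generator",
    "save_matrix_csv",
    "load_matrix_csv",
    "save_connectivity_h5",
    "load_connectivity_h5",
    "save_panel_csv",
    "load_panel_csv",
    "save_curve_csv",
    "save_prescription",
    "load_prescription",
]

_FMT = "%.17g"  # bit-exact float round-trip


# ---------------------------------------------------------------------------
# Study configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyConfig:
    """Everything needed to reproduce a group study.

    The default scale (16 nodes, 3 matrices per group, 2 peaks) is a desk
    scale chosen so a full five-group study runs in minutes; the study the
    defaults emulate used 80-node networks with 20 matrices per group and
    6 peaks.
    """

    groups: tuple[str, ...] = ("Normal", "Entrained", "Incomplete", "Background", "Random")
    n_matrices: int = 3
    n_nodes: int = 16
    base_freq: float = 2.0
    ratio: float = 2.6
    n_peaks: int = 2
    hwhm_factor: float = 0.2
    bandwidth_limit: float = 300.0
    entrained_bands: tuple[float, ...] = (2.7, 8.1)
    incomplete_removed: int = 1
    sigma: float = 1.0
    zero_fraction: float = 0.35
    iep_rtol: float = 1e-6
    iep_atol: float = 1e-8
    motif_rel_threshold: float = 0.05
    motif_max_nodes: int = 4
    bootstrap_iter: int = 10_000
    seed: int = 0

    def prescription_config(self) -> PrescriptionConfig:
        return PrescriptionConfig(
            base_freq=self.base_freq,
            ratio=self.ratio,
            n_peaks=self.n_peaks,
            hwhm_factor=self.hwhm_factor,
            bandwidth_limit=self.bandwidth_limit,
            entrained_bands=tuple(self.entrained_bands),
            incomplete_removed=self.incomplete_removed,
            n_nodes=self.n_nodes,
            sigma=self.sigma,
        )

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["groups"] = list(d["groups"])
        d["entrained_bands"] = list(d["entrained_bands"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["groups"] = tuple(d["groups"])
        d["entrained_bands"] = tuple(d["entrained_bands"])
        return cls(**d)


@dataclass
class StudyReport:
    """Per-matrix metrics, per-group summaries and pairwise group tests."""

    config: StudyConfig
    metrics: pd.DataFrame
    hierarchy: pd.DataFrame  # group x rank, mean normalized TNS
    motif_censuses: dict[str, pd.DataFrame]
    comparisons: pd.DataFrame
    matrices: dict[tuple[str, int], ConnectivityMatrix] = field(default_factory=dict)

    def save(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.config.to_yaml(out / "config.yaml")
        self.metrics.to_csv(out / "metrics.csv", index=False, float_format=_FMT)
        self.hierarchy.to_csv(out / "hierarchy.csv", index=False, float_format=_FMT)
        self.comparisons.to_csv(out / "comparisons.csv", index=False, float_format=_FMT)
        for group, census in self.motif_censuses.items():
            census.to_csv(out / f"motifs_{group}.csv", index=False, float_format=_FMT)
        for (group, seed), cm in self.matrices.items():
            save_matrix_csv(out / f"W_{group}_{seed}.csv", cm.W)
        summary = {
            "groups": {
                g: {
                    "mean_tse": float(
                        self.metrics.loc[self.metrics.group == g, "tse"].mean()
                    ),
                    "mean_half_rank": float(
                        self.metrics.loc[self.metrics.group == g, "half_rank"].mean()
                    ),
                    "n_converged": int(
                        self.metrics.loc[self.metrics.group == g, "converged"].sum()
                    ),
                }
                for g in self.config.groups
            }
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def run_group_study(config: StudyConfig = StudyConfig()) -> StudyReport:
    """Run the full pipeline for every group and seed in the config.

    A stalled IEP run is recorded (``converged=False``) and the study
    continues. Identical configs produce identical reports.
    """
    pcfg = config.prescription_config()
    rows = []
    hierarchy_rows = []
    censuses: dict[str, list[pd.DataFrame]] = {g: [] for g in config.groups}
    matrices: dict[tuple[str, int], ConnectivityMatrix] = {}
    for group in config.groups:
        for k in range(config.n_matrices):
            seed = config.seed * 1000 + k
            presc = build_prescription(group, pcfg, seed=seed)
            cm = solve_iep(
                presc,
                seed=seed,
                zero_fraction=config.zero_fraction,
                rtol=config.iep_rtol,
                atol=config.iep_atol,
            )
            matrices[(group, seed)] = cm
            C = analytics.stationary_covariance(cm.W, config.sigma)
            table, hier = analytics.tns_and_hierarchy(cm.W, C)
            tse = analytics.tse_complexity(C, seed=seed)
            scan = analytics.node_removal_scan(cm.W, config.sigma)
            hub = motifs.hub_subset(cm.W)
            if hub.size >= 2:
                sa = motifs.signed_adjacency(cm.W, hub, config.motif_rel_threshold)
                censuses[group].append(
                    motifs.motif_census(sa, max_nodes=config.motif_max_nodes)
                )
            sd = table["fluctuation_sd"].to_numpy()
            rows.append(
                {
                    "group": group,
                    "seed": seed,
                    "residual": cm.residual,
                    "converged": cm.converged,
                    "mean_sd": float(sd.mean()),
                    "corr_sd_excitation": _safe_corr(sd, table["excitatory_input"].to_numpy()),
                    "corr_sd_inhibition": _safe_corr(sd, table["inhibitory_input"].to_numpy()),
                    "corr_exc_inh": _safe_corr(
                        table["excitatory_input"].to_numpy(),
                        table["inhibitory_input"].to_numpy(),
                    ),
                    "corr_in_out": _safe_corr(
                        table["net_input"].to_numpy(), table["net_output"].to_numpy()
                    ),
                    "tse": tse,
                    "half_rank": hier.half_rank,
                    "removal_corr_rank": scan.corr_rank,
                    "hub_size": int(hub.size),
                }
            )
            hierarchy_rows.append(
                {"group": group, "seed": seed, **{f"r{r+1}": v for r, v in enumerate(hier.normalized_tns)}}
            )
    metrics = pd.DataFrame(rows)
    hierarchy = (
        pd.DataFrame(hierarchy_rows).drop(columns="seed").groupby("group", sort=False).mean().reset_index()
    )
    group_censuses = {
        g: motifs.combine_censuses(cs) for g, cs in censuses.items() if cs
    }
    comp_rows = []
    for i, ga in enumerate(config.groups):
        for gb in config.groups[i + 1 :]:
            a = metrics.loc[metrics.group == ga, "tse"].to_numpy()
            b = metrics.loc[metrics.group == gb, "tse"].to_numpy()
            res = analytics.bootstrap_mean_diff(
                a, b, n_iter=config.bootstrap_iter, seed=config.seed, alternative="two-sided"
            )
            comp_rows.append(
                {
                    "metric": "tse",
                    "group_a": ga,
                    "group_b": gb,
                    "observed_diff": res.observed,
                    "p_value": res.p_value,
                }
            )
    comparisons = pd.DataFrame(comp_rows)
    return StudyReport(
        config=config,
        metrics=metrics,
        hierarchy=hierarchy,
        motif_censuses=group_censuses,
        comparisons=comparisons,
        matrices=matrices,
    )


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

def fixture_generator(kind: str, seed: int = 0, **params):
    """Small deterministic test objects with documented analytic properties.

    Kinds
    -----
    diagonal : W = -gamma * I (n=4, gamma=1 by default); stationary
        covariance is I / (2 gamma), all channels independent.
    star : one hub reciprocally coupled to all leaves (excitatory out,
        inhibitory back), stabilised by a negative diagonal; the hub has
        maximal TNS.
    cycle : directed single-connection excitatory n-cycle on a negative
        diagonal.
    cycle5_counterbalanced : five nodes in a reciprocal cycle, every
        feedforward connection excitatory with inhibitory feedback —
        exactly one occurrence of the all-EI cyclic motif class.
    two_band : an Entrained prescription with bands at 2.7 and 8.1 Hz
        (eigenvalue imaginary parts 2π·2.7 and 2π·8.1 rad/s).
    reference_panel : a short simulated panel of a diagonal system.
    """
    rng = np.random.default_rng(seed)
    if kind == "diagonal":
        n = params.get("n", 4)
        gamma = params.get("gamma", 1.0)
        return -gamma * np.eye(n)
    if kind == "star":
        n = params.get("n", 6)
        w = params.get("weight", 1.0)
        W = -2.0 * w * np.eye(n)
        W[0, 1:] = -w  # inhibitory feedback into the hub
        W[1:, 0] = w   # excitatory drive from the hub
        return W
    if kind == "cycle":
        n = params.get("n", 5)
        w = params.get("weight", 1.0)
        W = -2.0 * w * np.eye(n)
        for i in range(n):
            W[(i + 1) % n, i] = w
        return W
    if kind == "cycle5_counterbalanced":
        w = params.get("weight", 1.0)
        n = 5
        W = -3.0 * w * np.eye(n)
        for i in range(n):
            W[(i + 1) % n, i] = w    # feedforward excitation
            W[i, (i + 1) % n] = -w   # feedback inhibition
        return W
    if kind == "two_band":
        cfg = PrescriptionConfig(
            n_nodes=params.get("n", 20), entrained_bands=(2.7, 8.1)
        )
        return build_prescription("Entrained", cfg, seed=seed)
    if kind == "reference_panel":
        from .dynamics import simulate

        W = -np.eye(params.get("n", 3))
        return simulate(W, sigma=1.0, dt=1e-3, duration=params.get("duration", 30.0), seed=seed)
    raise ValueError(f"unknown fixture kind {kind!r}")


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def save_matrix_csv(path: str | Path, W: np.ndarray) -> None:
    """Write a matrix as comma-separated CSV with a node-id header row."""
    W = np.atleast_2d(np.asarray(W, dtype=float))
    header = ",".join(f"n{j}" for j in range(W.shape[1]))
    np.savetxt(path, W, fmt=_FMT, delimiter=",", header=header, comments="")


def load_matrix_csv(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)


def save_panel_csv(path: str | Path, panel: TimeSeriesPanel) -> None:
    """Time column plus one column per channel."""
    cols = np.column_stack([panel.times, panel.data.T])
    header = "time_s," + ",".join(f"ch{j}" for j in range(panel.n_channels))
    np.savetxt(path, cols, fmt=_FMT, delimiter=",", header=header, comments="")


def load_panel_csv(path: str | Path) -> TimeSeriesPanel:
    arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    t, data = arr[:, 0], arr[:, 1:].T
    dt = float(t[1] - t[0]) if len(t) > 1 else 1.0
    return TimeSeriesPanel(data, dt)


def save_curve_csv(path: str | Path, curve: SpectrumCurve, label: str = "power") -> None:
    p = np.atleast_2d(curve.power)
    cols = np.column_stack([curve.frequencies, p.T])
    names = [label] if p.shape[0] == 1 else [f"{label}_{j}" for j in range(p.shape[0])]
    header = "frequency_hz," + ",".join(names)
    np.savetxt(path, cols, fmt=_FMT, delimiter=",", header=header, comments="")


def save_prescription(path: str | Path, presc: SpectrumPrescription) -> None:
    d = {
        "group": presc.group,
        "peaks": [{"f_peak": float(p.f_peak), "hwhm": float(p.hwhm)} for p in presc.peaks],
        "n_nodes": presc.n_nodes,
        "real_eig_bounds": [float(b) for b in presc.real_eig_bounds],
        "sigma": presc.sigma,
        "seed": presc.seed,
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_prescription(path: str | Path) -> SpectrumPrescription:
    d = yaml.safe_load(Path(path).read_text())
    return SpectrumPrescription(
        group=d["group"],
        peaks=tuple(SpectralPeak(p["f_peak"], p["hwhm"]) for p in d["peaks"]),
        n_nodes=d["n_nodes"],
        real_eig_bounds=tuple(d["real_eig_bounds"]),
        sigma=d.get("sigma", 1.0),
        seed=d.get("seed", 0),
    )


def save_connectivity_h5(path: str | Path, cm: ConnectivityMatrix) -> None:
    """HDF5 container bundling W with its provenance (seed, group, residual,
    eigenvalues, constraint)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("W", data=cm.W)
        f.create_dataset("complex_pairs", data=np.asarray(cm.eigenvalues.complex_pairs, dtype=complex))
        f.create_dataset("reals", data=np.asarray(cm.eigenvalues.reals))
        f.create_dataset("constraint_rows", data=cm.constraint.rows)
        f.create_dataset("constraint_cols", data=cm.constraint.cols)
        f.create_dataset("constraint_values", data=cm.constraint.values)
        f.create_dataset("residual_trace", data=cm.residual_trace)
        f.attrs["meta"] = json.dumps(
            {
                "group": cm.group,
                "seed": cm.seed,
                "residual": cm.residual,
                "threshold": cm.threshold,
                "converged": bool(cm.converged),
                "flow_time": cm.flow_time,
            }
        )


def load_connectivity_h5(path: str | Path) -> ConnectivityMatrix:
    import h5py

    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["meta"])
        eigs = EigenvalueSet(
            complex_pairs=tuple(complex(z) for z in f["complex_pairs"][()]),
            reals=tuple(float(x) for x in f["reals"][()]),
        )
        con = EntryConstraint(
            rows=f["constraint_rows"][()],
            cols=f["constraint_cols"][()],
            values=f["constraint_values"][()],
        )
        return ConnectivityMatrix(
            W=f["W"][()],
            eigenvalues=eigs,
            constraint=con,
            residual=meta["residual"],
            threshold=meta["threshold"],
            converged=meta["converged"],
            seed=meta["seed"],
            group=meta["group"],
            flow_time=meta["flow_time"],
            residual_trace=f["residual_trace"][()],
        )
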