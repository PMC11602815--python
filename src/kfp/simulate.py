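"""Synthetic isotope-enrichment datasets emulating the KFP protocol.

The simulated experiment: cells at metabolic steady state are switched to
labeled media at t = 0; unlabeled fractions are sampled at 3, 5 or 10
equally spaced time points with 3 technical replicates each, and each
observation is the true solution plus Gaussian noise whose standard
deviation is 2.5, 5 or 10 % of the true value. Noise is *not* clipped to
[0, 1]; observed fractions may stray slightly outside the unit interval,
as raw enrichment measurements do.

Two sampling regimes are supported: ``transient`` places the window over
the decay toward the isotopic steady state, while ``steady_state_only``
starts sampling only after every metabolite is within tolerance of its
steady state — the regime under which turnover rates become invisible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import solve_trajectory
from .enrichment import EnrichmentModel, ParameterSet
from .steady_state import solve_steady_state

__all__ = [
    "EnrichmentDataset",
    "generate_dataset",
    "steady_state_window",
    "transient_horizon",
    "N_REPLICATES",
]

#: technical replicates per (metabolite, time) point
N_REPLICATES = 3

#: standard-deviation floor used when the true value is exactly zero
SD_FLOOR = 1e-6


@dataclass(frozen=True)
class EnrichmentDataset:
    """Tidy table of noisy unlabeled-fraction observations plus metadata.

    ``observations`` has columns ``metabolite``, ``time``, ``replicate``,
    ``unlabeled_fraction``; ``truth`` optionally records the generating
    parameter values.
    """

    observations: pd.DataFrame
    noise_frac: float
    n_timepoints: int
    n_replicates: int
    seed: int
    regime: str
    truth: ParameterSet | None = None

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.observations["time"].unique())

    def to_csv(self, path) -> None:
        """Write observations as CSV and metadata as a JSON sidecar."""
        path = Path(path)
        self.observations.to_csv(path, index=False)
        meta = {
            "noise_frac": self.noise_frac,
            "n_timepoints": self.n_timepoints,
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            "regime": self.regime,
            "truth": dict(self.truth.values) if self.truth is not None else None,
        }
        path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_csv(cls, path) -> "EnrichmentDataset":
        path = Path(path)
        obs = pd.read_csv(path)
        sidecar = path.with_suffix(".meta.json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        truth = meta.get("truth")
        return cls(
            observations=obs,
            noise_frac=float(meta.get("noise_frac", np.nan)),
            n_timepoints=int(meta.get("n_timepoints", obs["time"].nunique())),
            n_replicates=int(meta.get("n_replicates",
                                      obs.groupby(["metabolite", "time"]).size().max())),
            seed=int(meta.get("seed", -1)),
            regime=str(meta.get("regime", "unknown")),
            truth=ParameterSet(truth) if truth else None,
        )


def transient_horizon(model: EnrichmentModel, params: ParameterSet) -> float:
    """Default experiment length: five times the slowest turnover time."""
    K, _, _ = model.numeric(params)
    return 5.0 / float(np.diag(K).min())


def steady_state_window(model: EnrichmentModel, params: ParameterSet,
                        tol: float = 1e-4) -> float:
    """Earliest time at which the trajectory sits within ``tol`` of steady state.

    Scans a coarse grid (out to fifty slowest-turnover times) and returns
    the first grid time where the sup-norm deviation from the steady state
    is at most ``tol``; returns 0 if the initial condition already
    qualifies.
    """
    xss = solve_steady_state(model, params).xbar_ss
    if np.max(np.abs(1.0 - xss)) <= tol:
        return 0.0
    k_min = float(np.diag(model.numeric(params)[0]).min())
    grid = np.linspace(0.0, 50.0 / k_min, 5001)
    traj = solve_trajectory(model, params, grid)
    dev = np.max(np.abs(traj.values - xss[None, :]), axis=1)
    hits = np.flatnonzero(dev <= tol)
    if hits.size == 0:  # pragma: no cover - grid always long enough in practice
        raise RuntimeError("trajectory did not reach steady state on the scan grid")
    return float(grid[hits[0]])


def generate_dataset(model: EnrichmentModel, params: ParameterSet,
                     n_timepoints: int = 10, noise_frac: float = 0.025,
                     regime: str = "transient", seed: int = 0,
                     n_replicates: int = N_REPLICATES,
                     horizon: float | None = None,
                     ss_tol: float = 1e-4) -> EnrichmentDataset:
    """Simulate a noisy enrichment time course.

    ``transient`` spaces ``n_timepoints`` samples equally on ``(0, T]`` with
    ``T = horizon`` (default five slowest turnover times; t = 0 is excluded
    because every fraction is deterministically 1 there). In
    ``steady_state_only`` the same spacing starts at the time the system is
    within ``ss_tol`` of its isotopic steady state. Each observation is
    ``truth + Normal(0, noise_frac * |truth|)``, three replicates per point
    by default, reproducible under ``seed``.
    """
    if regime not in ("transient", "steady_state_only"):
        raise ValueError(f"unknown regime {regime!r}")
    if n_timepoints < 1 or n_replicates < 1:
        raise ValueError("n_timepoints and n_replicates must be positive")
    model.require_admissible(params)
    T = transient_horizon(model, params) if horizon is None else float(horizon)
    if T <= 0:
        raise ValueError("horizon must be positive")
    if regime == "transient":
        times = np.linspace(0.0, T, n_timepoints + 1)[1:]
    else:
        t0 = steady_state_window(model, params, tol=ss_tol)
        times = t0 + np.linspace(0.0, T, n_timepoints + 1)[1:]

    truth_values = solve_trajectory(model, params, times).values
    rng = np.random.default_rng(seed)
    rows = []
    for ti, t in enumerate(times):
        for i, node in enumerate(model.nodes):
            mu = truth_values[ti, i]
            if noise_frac > 0:
                sd = noise_frac * abs(mu)
                if sd == 0.0:
                    sd = SD_FLOOR  # degenerate truth == 0 corner
                obs = mu + rng.normal(0.0, sd, size=n_replicates)
            else:
                obs = np.full(n_replicates, mu)
            for r in range(n_replicates):
                rows.append((node, float(t), r, float(obs[r])))
    df = pd.DataFrame(rows, columns=["metabolite", "time", "replicate",
                                     "unlabeled_fraction"])
    return EnrichmentDataset(observations=df, noise_frac=noise_frac,
                             n_timepoints=n_timepoints, n_replicates=n_replicates,
                             seed=seed, regime=regime, truth=params)
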