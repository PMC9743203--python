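"""First-passage-time sample containers and summary statistics.

The coefficient of variation (COV = std/mean) of the FPT distribution is the
central diagnostic: COV > 1 is a sufficient condition for a small Poisson
reset rate to lower the mean FPT, and broad (COV ≫ 1) distributions are
exactly the ones whose means are dominated by rare, very slow transitions.

Censored trajectories (runs that hit their time budget without passage)
are excluded from every statistic and surfaced loudly: their FPT is only a
lower bound, and silently averaging them would bias the mean downward.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FPTSampleSet",
    "FPTSummary",
    "CensoredSamplesError",
    "summarize",
    "speedup",
    "log_binned_density",
    "last_leg",
]


class CensoredSamplesError(ValueError):
    """An operation that requires fully observed FPTs saw censored ones."""


@dataclass
class FPTSampleSet:
    """First-passage times τ₁..τ_N with protocol provenance.

    Attributes
    ----------
    tau : array of float, ps
        One first-passage time per trajectory (censored rows hold the time
        budget, a lower bound on the true FPT).
    censored : bool array
    protocol_kind : 'none' | 'poisson' | 'sharp'
    rate : float or None, ps⁻¹ — Poisson reset rate (r*) the set was run at.
    period : float or None, ps — sharp reset period.
    resets : int array or None — resets used per trajectory.
    metadata : dict — potential form, seed, temperature, dt, ...
    """

    tau: np.ndarray
    censored: np.ndarray | None = None
    protocol_kind: str = "none"
    rate: float | None = None
    period: float | None = None
    resets: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.tau = np.asarray(self.tau, dtype=float)
        if self.censored is None:
            self.censored = np.zeros(self.tau.shape, dtype=bool)
        self.censored = np.asarray(self.censored, dtype=bool)
        if self.censored.shape != self.tau.shape:
            raise ValueError("censored flags must match tau in shape")
        if np.any(self.tau < 0):
            raise ValueError("first-passage times must be >= 0")
        if self.protocol_kind not in ("none", "poisson", "sharp"):
            raise ValueError(f"unknown protocol {self.protocol_kind!r}")
        if self.protocol_kind == "poisson" and not (self.rate or 0) > 0:
            raise ValueError("poisson provenance requires rate > 0")
        if self.protocol_kind == "sharp" and not (self.period or 0) > 0:
            raise ValueError("sharp provenance requires period > 0")

    @property
    def n(self) -> int:
        return self.tau.size

    @property
    def n_censored(self) -> int:
        return int(np.count_nonzero(self.censored))

    @property
    def observed(self) -> np.ndarray:
        """Uncensored passage times."""
        return self.tau[~self.censored]

    def require_uncensored(self, what: str = "this operation"):
        if self.n_censored:
            raise CensoredSamplesError(
                f"{what} requires fully observed FPTs but {self.n_censored}/"
                f"{self.n} trajectories are censored; re-run with a longer "
                "time budget or a larger reset rate")
        return self


@dataclass(frozen=True)
class FPTSummary:
    """Summary statistics over the uncensored samples of an ensemble."""

    mean: float            # ps
    median: float          # ps
    std: float             # ps, n−1 denominator
    cov: float             # std / mean
    se_mean: float         # std / sqrt(n_used)
    n_used: int
    n_censored: int


def summarize(samples: FPTSampleSet) -> FPTSummary:
    """Mean, median, std (n−1), COV and SE over uncensored samples.

    Censored trajectories are excluded with a warning; fewer than two
    uncensored samples is an error.
    """
    obs = samples.observed
    if obs.size < 2:
        raise ValueError(
            f"need at least 2 uncensored samples, have {obs.size}")
    if samples.n_censored:
        warnings.warn(
            f"{samples.n_censored}/{samples.n} trajectories censored; "
            "excluded from all statistics", stacklevel=2)
    mean = float(np.mean(obs))
    std = float(np.std(obs, ddof=1))
    return FPTSummary(
        mean=mean,
        median=float(np.median(obs)),
        std=std,
        cov=std / mean,
        se_mean=std / math.sqrt(obs.size),
        n_used=int(obs.size),
        n_censored=samples.n_censored,
    )


def speedup(baseline: FPTSummary, reset: FPTSummary) -> tuple[float, float]:
    """Acceleration ratio mean_baseline/mean_reset with first-order SE.

    SE/ratio = sqrt((SE_b/mean_b)² + (SE_r/mean_r)²).
    """
    if baseline.mean <= 0 or reset.mean <= 0:
        raise ValueError("speedup requires positive mean FPTs")
    ratio = baseline.mean / reset.mean
    rel = math.sqrt((baseline.se_mean / baseline.mean) ** 2
                    + (reset.se_mean / reset.mean) ** 2)
    return ratio, ratio * rel


def log_binned_density(samples: FPTSampleSet, n_bins: int = 30):
    """Histogram density on logarithmically spaced bins.

    Returns ``(centers, density, edges)``; density is normalized so that
    Σ density_i · (edge_{i+1} − edge_i) = 1.  Requires strictly positive
    samples and more than one distinct value.
    """
    obs = samples.observed
    if np.any(obs <= 0):
        raise ValueError("log binning requires strictly positive samples")
    lo, hi = float(np.min(obs)), float(np.max(obs))
    if lo == hi:
        raise ValueError("degenerate sample (single distinct value); "
                         "log binning is undefined")
    edges = np.geomspace(lo, hi, n_bins + 1)
    edges[0] *= 1.0 - 1e-12
    edges[-1] *= 1.0 + 1e-12
    counts, edges = np.histogram(obs, bins=edges)
    widths = np.diff(edges)
    density = counts / (obs.size * widths)
    centers = np.sqrt(edges[:-1] * edges[1:])
    return centers, density, edges


def last_leg(record) -> tuple[np.ndarray, np.ndarray]:
    """Trajectory segment from the final reset event to passage.

    `record` is an :class:`~resetfpt.dynamics.FPTRecord` with a recorded
    trajectory.  Returns ``(times, positions)`` covering the window from the
    last reset (or trajectory start if no reset occurred) up to and including
    passage.  Raises if the trajectory never passed or was not recorded.
    """
    if record.trajectory_times is None:
        raise ValueError("record carries no trajectory; enable recording")
    if record.censored:
        raise ValueError("passage was not reached; there is no last leg")
    t = np.asarray(record.trajectory_times)
    x = np.asarray(record.trajectory_positions)
    start = record.reset_times[-1] if len(record.reset_times) else 0.0
    idx = np.nonzero(t >= start * (1.0 - 1e-12))[0]
    # a reset can coincide with a stride frame; keep only the post-reset one
    while idx.size > 1 and np.isclose(t[idx[0]], t[idx[1]]):
        idx = idx[1:]
    return t[idx], x[idx]
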