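"""BRA/SOX2 pole calling on normalized AP profiles and bootstrap
proportion estimates.

Visual pole scoring is replaced here by an explicit, reproducible
criterion: a pole is a maximal run of at least ``min_run`` consecutive
supra-threshold bins of the normalized profile. The fraction of organoids
with a unique pole is reported with a bootstrap standard error and
percentile confidence interval.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .profiles import IntensityProfile


@dataclass
class PoleCall:
    """Pole multiplicity of one organoid's marker profile."""

    n_poles: int
    unique_pole: bool
    pole_positions: list[float]
    organoid_id: str | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.unique_pole != (self.n_poles == 1):
            raise ValueError("unique_pole must equal (n_poles == 1)")


@dataclass
class ProportionEstimate:
    """Fraction estimate with bootstrap uncertainty (percentile CI)."""

    p_hat: float
    n: int
    se_boot: float
    ci_low: float
    ci_high: float
    B: int
    seed: int | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.p_hat <= self.ci_high <= 1.0):
            raise ValueError("percentile CI must bracket p_hat within [0, 1]")
        if self.se_boot < 0:
            raise ValueError("se_boot must be >= 0")


def call_poles(
    profile: IntensityProfile | np.ndarray,
    threshold: float = 0.5,
    min_run: int = 10,
    *,
    organoid_id: str | None = None,
) -> PoleCall:
    """Count marker poles as supra-threshold runs of >= min_run bins.

    Expects a normalized profile (values roughly in [0, 1]); values outside
    [-0.5, 1.5] are flagged with a warning but the call proceeds. Each
    qualifying run anywhere along the axis counts as one pole; run centers
    (mean relative position) are reported.
    """
    if isinstance(profile, IntensityProfile):
        values = profile.values
        positions = profile.positions
        organoid_id = organoid_id or profile.organoid_id
    else:
        values = np.asarray(profile, dtype=float)
        positions = (np.arange(len(values)) + 0.5) / len(values)
    flags: list[str] = []
    if np.any(values < -0.5) or np.any(values > 1.5):
        flags.append("values outside [-0.5, 1.5]: profile may not be normalized")
        warnings.warn(flags[-1])
    above = values > threshold
    # run-length encode
    edges = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
    starts, ends = edges[::2], edges[1::2]
    centers = [
        float(positions[s:e].mean()) for s, e in zip(starts, ends) if e - s >= min_run
    ]
    n = len(centers)
    return PoleCall(
        n_poles=n,
        unique_pole=n == 1,
        pole_positions=centers,
        organoid_id=organoid_id,
        flags=flags,
    )


def bootstrap_proportion(
    outcomes: Sequence[int] | np.ndarray,
    B: int = 1000,
    seed: int | None = None,
    *,
    ci_level: float = 0.95,
    group: str | None = None,
) -> ProportionEstimate:
    """Bootstrap the proportion of successes in a binary outcome list.

    B resamples of size n with replacement; the standard error is the
    standard deviation of the resampled proportions and the CI the
    percentile interval. Fully reproducible under a fixed seed.
    """
    outcomes = np.asarray(outcomes, dtype=float)
    if outcomes.size == 0:
        raise ValueError("empty outcome list")
    if not np.isin(outcomes, (0.0, 1.0)).all():
        raise ValueError("outcomes must be binary (0/1)")
    n = outcomes.size
    p_hat = float(outcomes.mean())
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    p_boot = outcomes[idx].mean(axis=1)
    se = float(p_boot.std(ddof=1)) if B > 1 else 0.0
    alpha = (1.0 - ci_level) / 2.0
    ci_low = float(np.quantile(p_boot, alpha))
    ci_high = float(np.quantile(p_boot, 1.0 - alpha))
    # guard against quantile-interpolation corner cases at tiny n
    ci_low = min(ci_low, p_hat)
    ci_high = max(ci_high, p_hat)
    return ProportionEstimate(
        p_hat=p_hat,
        n=n,
        se_boot=se,
        ci_low=ci_low,
        ci_high=ci_high,
        B=B,
        seed=seed,
        group=group,
    )
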