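"""Nonparametric bootstrap and percentile confidence intervals.

The resampling unit is the subject: whole trajectories (Y, Ā, Z̄, L̄) are
drawn with replacement, and all nuisance models plus the estimator are refitted
on every resample.  Resamples on which estimation fails (singular matrices at
weak instruments, separation) are counted, reported, and excluded from the
percentile computation — never silently dropped from b.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import InferenceError, LongIVError
from .iv_g import estimate_iv_g
from .iv_w import fit_iv_w
from .panel_data import HistorySpec, PanelData

__all__ = [
    "BootstrapResult",
    "bootstrap",
    "percentile_ci",
    "iv_g_estimator",
    "iv_w_estimator",
]


@dataclass
class BootstrapResult:
    """ATE (and per-period β) draws over b subject-level resamples."""

    draws: np.ndarray  # successful ATE draws, length b - n_failed
    beta_draws: np.ndarray = field(repr=False, default=None)  # (b - n_failed, K)
    b: int = 0
    seed: int | None = None
    n_failed: int = 0


def iv_g_estimator(spec: HistorySpec = HistorySpec()) -> Callable[[PanelData], object]:
    """Estimator callable for g-estimation, suitable for :func:`bootstrap`."""

    def fit(panel: PanelData):
        return estimate_iv_g(panel, spec)

    fit.method = "iv_g"
    return fit


def iv_w_estimator(
    spec: HistorySpec = HistorySpec(),
    stabiliser: str = "none",
    trim: bool = False,
    delta_mode: str = "subject",
) -> Callable[[PanelData], object]:
    """Estimator callable for the IV-weighted MSM, suitable for :func:`bootstrap`."""

    def fit(panel: PanelData):
        return fit_iv_w(
            panel, spec=spec, stabiliser=stabiliser, trim=trim, delta_mode=delta_mode
        )

    fit.method = "iv_w"
    return fit


def bootstrap(
    panel: PanelData,
    estimator: Callable[[PanelData], object],
    b: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    max_failure_fraction: float = 0.5,
) -> BootstrapResult:
    """Resample subjects with replacement and refit the estimator b times.

    Reproducible given (seed, b, estimator, panel).  Raises
    :class:`InferenceError` when more than ``max_failure_fraction`` of the
    resamples fail (the estimator is unstable on this dataset).
    """
    if b < 1:
        raise ValueError("b must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = panel.n
    draws: list[float] = []
    betas: list[np.ndarray] = []
    n_failed = 0
    for _ in range(b):
        idx = rng.integers(0, n, size=n)
        try:
            est = estimator(panel.subset(idx))
        except (LongIVError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        draws.append(float(est.ate))
        betas.append(np.asarray(est.beta, dtype=float))
    if n_failed > max_failure_fraction * b:
        raise InferenceError(
            f"{n_failed}/{b} bootstrap resamples failed; estimator unstable "
            "on this dataset"
        )
    return BootstrapResult(
        draws=np.asarray(draws),
        beta_draws=np.asarray(betas) if betas else np.empty((0, panel.K)),
        b=b,
        seed=seed,
        n_failed=n_failed,
    )


def percentile_ci(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Percentile interval from the ordered draws (type-7 interpolation).

    At level 0.95 this is the (2.5th, 97.5th) percentile pair; level 1.0
    returns (min, max).
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("cannot form a confidence interval from zero draws")
    if not 0.0 < level <= 1.0:
        raise ValueError("level must be in (0, 1]")
    tail = (1.0 - level) / 2.0 * 100.0
    lo, hi = np.percentile(draws, [tail, 100.0 - tail])
    return float(lo), float(hi)
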