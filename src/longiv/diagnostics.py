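"""Instrument-strength and weight diagnostics.

Instrument relevance is the only testable IV assumption.  Two measures are
provided: the per-period Pearson correlation between instrument and treatment,
and the Sanderson–Windmeijer conditional F-statistic, which asks how well the
K instruments jointly predict treatment at period t after they have already
been used to predict the remaining treatment periods.  Values below 10 are
flagged as weak (a reported flag, not a hard gate — substantially higher
values may be needed in practice).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DiagnosticsError
from .iv_w import IVWeights, _tukey_fences
from .panel_data import PanelData

__all__ = [
    "StrengthReport",
    "za_correlation",
    "conditional_f",
    "weight_summary",
    "strength_report",
]

WEAK_F_THRESHOLD = 10.0


@dataclass
class StrengthReport:
    """Per-period instrument-strength measures and optional weight summary."""

    za_corr: np.ndarray
    f_sw: np.ndarray
    flag_weak: np.ndarray
    weight_summary: dict | None = field(default=None)

    def to_dict(self) -> dict:
        return {
            "za_correlation": [float(c) for c in self.za_corr],
            "conditional_F": [float(f) for f in self.f_sw],
            "flag_weak": [bool(f) for f in self.flag_weak],
            "weight_summary": self.weight_summary,
        }


def za_correlation(panel: PanelData) -> np.ndarray:
    """Pearson correlation of Z_t and A_t, per period."""
    out = np.empty(panel.K)
    for t in range(panel.K):
        z = panel.Z[:, t].astype(float)
        a = panel.A[:, t].astype(float)
        if z.std() == 0.0 or a.std() == 0.0:
            raise DiagnosticsError(
                f"correlation undefined at period {t + 1}: constant column"
            )
        out[t] = np.corrcoef(z, a)[0, 1]
    return out


def _ols_ssr(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise DiagnosticsError("collinear regressor block in first-stage regression")
    resid = y - X @ coef
    return resid, float(resid @ resid)


def conditional_f(panel: PanelData, exog: np.ndarray | None = None) -> np.ndarray:
    """Sanderson–Windmeijer conditional F-statistic, per treatment period.

    For each t: (i) fit each other treatment period on all K instruments
    (plus exogenous covariates), (ii) partial the fitted values out of A_t by
    OLS, (iii) test the K instruments jointly on the residual, (iv) rescale to
    the conditional numerator degrees of freedom kz − kx + 1 (kz instruments,
    kx endogenous treatment periods).  At K = 1 this reduces exactly to the
    classical first-stage F-statistic.
    """
    n, K = panel.n, panel.K
    Zmat = panel.Z.astype(float)
    Amat = panel.A.astype(float)
    ones = np.ones((n, 1))
    if exog is not None:
        exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if exog.shape[0] != n:
            exog = exog.T
        base = np.hstack([ones, exog])
    else:
        base = ones
    ZX = np.hstack([base, Zmat])
    if np.linalg.matrix_rank(ZX) < ZX.shape[1]:
        raise DiagnosticsError("collinear instrument block")
    q_sw = K - K + 1  # kz - kx + 1 with kz = kx = K
    df_resid = n - ZX.shape[1]
    out = np.empty(K)
    for t in range(K):
        others = [s for s in range(K) if s != t]
        if others:
            fitted = np.empty((n, len(others)))
            for j, s in enumerate(others):
                resid_s, ssr_s = _ols_ssr(ZX, Amat[:, s])
                if ssr_s / n < 1e-12:
                    raise DiagnosticsError(
                        f"treatment period {s + 1} perfectly predicted by the "
                        "instruments; conditional F degenerate (interpret with care)"
                    )
                fitted[:, j] = Amat[:, s] - resid_s
            resid_t, _ = _ols_ssr(np.hstack([base, fitted]), Amat[:, t])
        else:
            resid_t, _ = _ols_ssr(base, Amat[:, t])
        _, ssr_full = _ols_ssr(ZX, resid_t)
        _, ssr_restr = _ols_ssr(base, resid_t)
        if ssr_full / n < 1e-12:
            raise DiagnosticsError(
                f"residual treatment at period {t + 1} perfectly predicted; "
                "conditional F degenerate"
            )
        out[t] = ((ssr_restr - ssr_full) / q_sw) / (ssr_full / df_resid)
    return out


def weight_summary(weights: IVWeights) -> dict:
    """Quartiles, Tukey fences and extreme-value counts of the product weights."""
    w = weights.product
    q1, q3 = np.percentile(w, [25.0, 75.0])
    lo, hi = _tukey_fences(w)
    return {
        "q1": float(q1),
        "q3": float(q3),
        "iqr": float(q3 - q1),
        "fence_lo": lo,
        "fence_hi": hi,
        "n_outside_fences": int(np.sum((w < lo) | (w > hi))),
        "min": float(w.min()),
        "max": float(w.max()),
        "n_instability_flags": int(weights.n_instability_flags),
    }


def strength_report(
    panel: PanelData,
    exog: np.ndarray | None = None,
    weights: IVWeights | None = None,
) -> StrengthReport:
    """Bundle correlation, conditional F and (optionally) weight diagnostics."""
    f_sw = conditional_f(panel, exog)
    return StrengthReport(
        za_corr=za_correlation(panel),
        f_sw=f_sw,
        flag_weak=f_sw < WEAK_F_THRESHOLD,
        weight_summary=None if weights is None else weight_summary(weights),
    )
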