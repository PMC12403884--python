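"""IV-based g-estimation of a structural nested mean model (SNMM).

The SNMM asserts that treatment at period t shifts the conditional mean of the
counterfactual outcome by β_t, identically in treated and untreated subjects
(no current treatment interaction), so the average treatment effect of
sustained treatment is the sum of the β_t.  G-estimation finds the β at which
the counterfactual under no treatment,

    H₁ = Y − Σ_t β_t A_t,

is uncorrelated with the residualised instrument Z_t − E[Z_t | M_t] at every
period.  The estimating equations

    Σ_i H₁ᵢ (Z_tᵢ − Ê[Z_tᵢ | M_tᵢ]) = 0,   t = 1..K,

are linear in β and admit the closed form β̂ = (RᵀA)⁻¹ RᵀY with
R = Z − Ê(Z).  Inference is by nonparametric bootstrap (see
:mod:`longiv.inference`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import WeakInstrumentError
from .nuisance import PmfModel, fit_instrument_model
from .panel_data import HistorySpec, PanelData

__all__ = ["SNMMEstimate", "h1", "estimate_iv_g"]

#: condition number of AᵀR beyond which the solve is refused (weak/degenerate
#: instruments) rather than silently pseudo-inverted
CONDITION_THRESHOLD = 1e12
#: estimating-equation residuals at the solution must not exceed this multiple
#: of ||Y|| (exactness of the linear solve)
EE_TOL = 1e-8


@dataclass
class SNMMEstimate:
    """Fitted SNMM: per-period effects, their sum (the ATE), and diagnostics."""

    beta: np.ndarray
    ate: float
    residual_instruments: np.ndarray = field(repr=False)
    instrument_models: list[PmfModel] = field(repr=False, default_factory=list)
    ee_residuals: np.ndarray | None = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "method": "iv_g",
            "beta": [float(b) for b in self.beta],
            "ate": float(self.ate),
        }


def h1(Y: np.ndarray, A: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Counterfactual-under-no-treatment estimate H₁ = Y − Σ_t β_t A_t."""
    Y = np.asarray(Y, dtype=float)
    A = np.atleast_2d(np.asarray(A, dtype=float))
    beta = np.asarray(beta, dtype=float)
    if A.shape[1] != beta.shape[0]:
        raise ValueError(
            f"beta has length {beta.shape[0]} but A has {A.shape[1]} periods"
        )
    return Y - A @ beta


def estimate_iv_g(
    panel: PanelData,
    spec: HistorySpec = HistorySpec(),
    condition_threshold: float = CONDITION_THRESHOLD,
) -> SNMMEstimate:
    """Closed-form g-estimation of the per-period effects β and the ATE.

    Fits one instrument model P(Z_t | M_t) per period (minimal history by
    default), residualises the instruments, and solves the estimating
    equations exactly.  Raises :class:`WeakInstrumentError` when AᵀR is
    numerically singular, naming the weakest period(s).
    """
    K = panel.K
    models = [fit_instrument_model(panel, t, spec) for t in range(1, K + 1)]
    EZ = np.column_stack([m.fitted for m in models])
    R = panel.Z.astype(float) - EZ
    A = panel.A.astype(float)
    AtR = A.T @ R
    cond = np.linalg.cond(AtR)
    if not np.isfinite(cond) or cond > condition_threshold:
        # the periods with the smallest instrument-treatment residual
        # covariance are the likely culprits
        diag = np.abs(np.diag(AtR)) / panel.n
        weakest = [int(t) + 1 for t in np.argsort(diag)[: max(1, K // 2)]]
        raise WeakInstrumentError(
            f"A'R numerically singular (condition number {cond:.3g}); "
            f"weakest period(s): {weakest}"
        )
    beta = np.linalg.solve(AtR.T, R.T @ panel.Y)
    ee = R.T @ h1(panel.Y, A, beta)
    scale = max(np.linalg.norm(panel.Y), 1.0)
    if np.max(np.abs(ee)) > EE_TOL * scale:
        raise WeakInstrumentError(
            "estimating equations do not vanish at the closed-form solution "
            f"(max residual {np.max(np.abs(ee)):.3g})"
        )
    return SNMMEstimate(
        beta=beta,
        ate=float(beta.sum()),
        residual_instruments=R,
        instrument_models=models,
        ee_residuals=ee,
    )
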