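"""Nuisance regressions: instrument and treatment probability models.

Both estimators need fitted probability mass functions for the instrument,
P(Z_t | M_t), and for the treatment, P(A_t | Z_t, M_t, L̄_t), where
M_t = (Ā_{t-1}, Z̄_{t-1}) is the minimal conditioning history.  All models are
main-effects logistic regressions fitted by Newton–Raphson (IRLS); the solver
is deliberately a small vectorised routine because simulation studies and
bootstrap inference refit these models hundreds of thousands of times.

The compliance difference Δ_t — the shift in the treatment pmf when the
instrument is switched from 0 to 1 — is derived from a fitted treatment model
by predicting under both instrument values and evaluating the pmf at the
observed treatment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .errors import DegenerateFitError, InstabilityWarning
from .panel_data import HistorySpec, PanelData

__all__ = [
    "PmfModel",
    "DeltaEstimate",
    "fit_logistic",
    "fit_instrument_model",
    "fit_treatment_model",
    "fit_reduced_treatment_model",
    "fit_marginal_treatment_model",
    "delta_from_model",
]

#: logistic-fit convergence tolerance (max Newton step size) and iteration cap
LOGIT_TOL = 1e-8
LOGIT_MAXITER = 100
#: |Δ_t| below this triggers an instability warning (feeds IV-W diagnostics)
DELTA_TOL = 1e-6
#: fitted coefficients beyond this magnitude are treated as separation
_COEF_BOUND = 50.0


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = LOGIT_TOL,
    maxiter: int = LOGIT_MAXITER,
) -> np.ndarray:
    """Maximum-likelihood logistic regression via Newton–Raphson.

    Raises :class:`DegenerateFitError` on a constant response, a singular
    information matrix, or (quasi-)separation — by design there is no silent
    penalised fallback, so estimands stay faithful to the stated models.
    """
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise DegenerateFitError(f"constant response (all {int(y[0])})")
    beta = np.zeros(X.shape[1])
    for _ in range(maxiter):
        eta = np.clip(X @ beta, -30.0, 30.0)
        p = expit(eta)
        grad = X.T @ (y - p)
        w = p * (1.0 - p)
        H = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise DegenerateFitError(f"singular information matrix: {exc}") from exc
        if not np.isfinite(step).all():
            raise DegenerateFitError("non-finite Newton step")
        beta += step
        if np.max(np.abs(step)) < tol:
            if np.max(np.abs(beta)) > _COEF_BOUND:
                raise DegenerateFitError(
                    "separation suspected (diverging coefficients)"
                )
            return beta
    raise DegenerateFitError(
        f"no convergence in {maxiter} iterations (possible separation)"
    )


@dataclass
class PmfModel:
    """A fitted per-period logistic probability model.

    ``fitted`` holds P(target = 1 | covariates) for every subject of the panel
    the model was fitted on; ``z_index`` is the design column of the current
    instrument Z_t (None if Z_t is not in the design).
    """

    target: str  # "Z" or "A"
    period: int
    design_cols: list[str]
    coef: np.ndarray
    X: np.ndarray = field(repr=False)
    fitted: np.ndarray = field(repr=False)
    z_index: int | None = None

    def pmf_observed(self, values: np.ndarray) -> np.ndarray:
        """Probability mass at the observed 0/1 values: v*p + (1-v)*(1-p)."""
        v = np.asarray(values, dtype=float)
        return v * self.fitted + (1.0 - v) * (1.0 - self.fitted)

    def predict_with_z(self, z_value: int) -> np.ndarray:
        """P(target = 1) with the current instrument forced to ``z_value``."""
        if self.z_index is None:
            raise ValueError("model does not contain the current instrument Z_t")
        X = self.X.copy()
        X[:, self.z_index] = z_value
        return expit(np.clip(X @ self.coef, -30.0, 30.0))


@dataclass
class DeltaEstimate:
    """Per-subject compliance difference Δ_t evaluated at the observed a_t.

    Δ_t = P_{A_t}(a_t | Z_t=1, ·) − P_{A_t}(a_t | Z_t=0, ·); the sign flips
    when the observed treatment flips.
    """

    period: int
    delta: np.ndarray
    n_unstable: int
    tol: float = DELTA_TOL


def _design(
    panel: PanelData,
    t: int,
    *,
    a_history: bool,
    z_history: bool,
    confounders: tuple[int, ...],
    current_z: bool,
) -> tuple[np.ndarray, list[str], int | None]:
    """Main-effects design matrix at period t (1-based); intercept first.

    Only variables with time index <= t enter; treatment/instrument history is
    strictly earlier than t.
    """
    cols: list[np.ndarray] = [np.ones(panel.n)]
    names = ["const"]
    z_index = None
    if current_z:
        z_index = len(names)
        cols.append(panel.Z[:, t - 1].astype(float))
        names.append(f"Z{t}")
    if a_history:
        for s in range(1, t):
            cols.append(panel.A[:, s - 1].astype(float))
            names.append(f"A{s}")
    if z_history:
        for s in range(1, t):
            cols.append(panel.Z[:, s - 1].astype(float))
            names.append(f"Z{s}")
    for j in confounders:
        if j >= panel.p:
            raise ValueError(f"confounder index {j} out of range (p={panel.p})")
        for s in range(1, t + 1):
            cols.append(panel.L[:, s - 1, j])
            names.append(f"L{s}_{j + 1}")
    return np.column_stack(cols), names, z_index


def _fit(
    panel: PanelData, target: str, t: int, X: np.ndarray, names: list[str],
    z_index: int | None,
) -> PmfModel:
    y = (panel.Z if target == "Z" else panel.A)[:, t - 1].astype(float)
    try:
        coef = fit_logistic(X, y)
    except DegenerateFitError as exc:
        raise DegenerateFitError(f"{target}{t} model: {exc}") from exc
    fitted = expit(np.clip(X @ coef, -30.0, 30.0))
    return PmfModel(
        target=target, period=t, design_cols=names, coef=coef, X=X,
        fitted=fitted, z_index=z_index,
    )


def fit_instrument_model(
    panel: PanelData, t: int, spec: HistorySpec = HistorySpec()
) -> PmfModel:
    """Logistic model of Z_t on the conditioning history M_t.

    With the minimal history at t = 1 this is intercept-only, so the fitted
    probability equals the sample mean of Z_1.
    """
    X, names, _ = _design(
        panel, t,
        a_history=spec.use_treatment_history,
        z_history=spec.use_instrument_history,
        confounders=spec.confounder_subset,
        current_z=False,
    )
    return _fit(panel, "Z", t, X, names, None)


def fit_treatment_model(
    panel: PanelData, t: int, spec: HistorySpec = HistorySpec()
) -> PmfModel:
    """Logistic model of A_t on Z_t (main effect), M_t and the L̄_t subset."""
    X, names, z_index = _design(
        panel, t,
        a_history=spec.use_treatment_history,
        z_history=spec.use_instrument_history,
        confounders=spec.confounder_subset,
        current_z=True,
    )
    return _fit(panel, "A", t, X, names, z_index)


def fit_reduced_treatment_model(panel: PanelData, t: int) -> PmfModel:
    """History-only model A_t ~ Z_t + Ā_{t-1}, for the Delta stabiliser."""
    X, names, z_index = _design(
        panel, t, a_history=True, z_history=False, confounders=(), current_z=True
    )
    return _fit(panel, "A", t, X, names, z_index)


def fit_marginal_treatment_model(panel: PanelData, t: int) -> PmfModel:
    """Treatment-history-only model A_t ~ Ā_{t-1}, for the standard stabiliser."""
    X, names, _ = _design(
        panel, t, a_history=True, z_history=False, confounders=(), current_z=False
    )
    return _fit(panel, "A", t, X, names, None)


def delta_from_model(
    model: PmfModel,
    panel: PanelData,
    t: int,
    tol: float = DELTA_TOL,
    mode: str = "subject",
) -> DeltaEstimate:
    """Compliance difference from a fitted treatment model containing Z_t.

    Predicts P(A_t = 1) with Z_t forced to 1 and to 0, evaluates the pmf at the
    observed a_t, and returns the difference.  ``mode='subject'`` keeps the
    per-subject differences; ``mode='constant'`` averages P(A=1|Z=1) − P(A=1|Z=0)
    over subjects into a single per-period compliance difference before
    applying the observed-treatment sign — appropriate when the compliance
    difference is constant across covariate strata (as in the simulation
    mechanism).  Subjects with |Δ_t| below ``tol`` are counted and reported
    via an :class:`InstabilityWarning`.
    """
    if model.target != "A":
        raise ValueError("delta requires a treatment model")
    if model.z_index is None:
        raise ValueError("treatment model must contain the current instrument Z_t")
    if mode not in ("subject", "constant"):
        raise ValueError(f"unknown delta mode {mode!r}")
    p1 = model.predict_with_z(1)
    p0 = model.predict_with_z(0)
    diff = p1 - p0
    if mode == "constant":
        diff = np.full(panel.n, float(diff.mean()))
    a = panel.A[:, t - 1].astype(float)
    # pmf(a|z=1) - pmf(a|z=0) = (2a-1) * (p1 - p0)
    delta = (2.0 * a - 1.0) * diff
    n_unstable = int(np.sum(np.abs(delta) < tol))
    if n_unstable:
        warnings.warn(
            f"period {t}: |Delta_t| < {tol:g} for {n_unstable} subject(s); "
            "IV weights will be unstable",
            InstabilityWarning,
            stacklevel=2,
        )
    return DeltaEstimate(period=t, delta=delta, n_unstable=n_unstable, tol=tol)
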