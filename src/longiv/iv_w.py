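"""Inverse probability of IV weighting (IV-W) for a marginal structural model.

The MSM E[Y(a)] = β₀ + Σ_t β_t a_t is fitted by re-weighting subjects with

    W̄ᵢ = Π_t W_tᵢ,     W_t = (−1)^{1−Z_t} · P_{Z_t}(Z_t | M_t) · Δ_t,

where Δ_t is the compliance difference evaluated at the observed treatment.
These are signed weights centred around zero — a subject whose treatment
agrees with the instrument's push receives positive weight — so no positivity
constraint applies.  Weight stability degrades as Δ_t approaches zero (weak
instruments); two stabilisers divide W_t by either the marginal treatment
pmf P(A_t | Ā_{t-1}) ("standard") or a history-only compliance difference
("delta"), and Tukey-fence trimming of the product weights is available for
taming a few extreme values.

With h(A) = (1, A) the estimating equations reduce to weighted least squares
with per-subject weight 1/W̄ᵢ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InstabilityWarning, NonConvergenceError
from .nuisance import (
    DELTA_TOL,
    PmfModel,
    delta_from_model,
    fit_instrument_model,
    fit_marginal_treatment_model,
    fit_reduced_treatment_model,
    fit_treatment_model,
)
from .panel_data import HistorySpec, PanelData

__all__ = [
    "IVWeights",
    "MSMEstimate",
    "compute_weights",
    "trim_weights",
    "estimate_iv_w",
    "fit_iv_w",
]

#: condition threshold for the weighted normal matrix
CONDITION_THRESHOLD = 1e12
#: |product weight| below this is treated as numerically zero
PRODUCT_TOL = 1e-10
#: fraction of degenerate product weights beyond which the fit is refused
PRODUCT_DEGENERATE_FRACTION = 0.5


@dataclass
class IVWeights:
    """Per-period and product IV weights with stabilisation/trim metadata."""

    per_period: np.ndarray = field(repr=False)  # n x K, post-stabilisation
    product: np.ndarray = field(repr=False)  # length n
    stabiliser: str = "none"
    trim_bounds: tuple[float, float] | None = None
    n_instability_flags: int = 0

    @property
    def n(self) -> int:
        return self.product.shape[0]

    @property
    def K(self) -> int:
        return self.per_period.shape[1]


@dataclass
class MSMEstimate:
    """Fitted MSM: intercept, per-period effects, ATE = Σβ_t."""

    beta0: float
    beta: np.ndarray
    ate: float
    weights_used: IVWeights | None = field(repr=False, default=None)
    converged: bool = True

    def to_dict(self) -> dict:
        return {
            "method": "iv_w",
            "beta0": float(self.beta0),
            "beta": [float(b) for b in self.beta],
            "ate": float(self.ate),
            "stabiliser": None if self.weights_used is None else self.weights_used.stabiliser,
            "trim_bounds": None
            if self.weights_used is None or self.weights_used.trim_bounds is None
            else [float(b) for b in self.weights_used.trim_bounds],
        }


def compute_weights(
    panel: PanelData,
    instrument_models: list[PmfModel],
    treatment_models: list[PmfModel],
    stabiliser: str = "none",
    tol: float = DELTA_TOL,
    delta_mode: str = "subject",
    known_delta: np.ndarray | None = None,
) -> IVWeights:
    """Signed per-period IV weights and their product.

    ``stabiliser='standard'`` divides W_t by P(A_t | Ā_{t-1});
    ``stabiliser='delta'`` divides by the history-only compliance difference
    Δ_t^Stab from the reduced model A_t ~ Z_t + Ā_{t-1}.  Stabiliser values
    with magnitude below ``tol`` raise a division-instability error.

    ``delta_mode`` selects per-subject or per-period-constant compliance
    differences (see :func:`longiv.nuisance.delta_from_model`); alternatively
    ``known_delta`` plugs in known per-period Δ_t values (length K), a
    sensitivity switch bypassing Δ estimation entirely.
    """
    if stabiliser not in ("none", "standard", "delta"):
        raise ValueError(f"unknown stabiliser {stabiliser!r}")
    K = panel.K
    if len(instrument_models) != K:
        raise ValueError("one instrument model per period required")
    if known_delta is None and (
        treatment_models is None or len(treatment_models) != K
    ):
        raise ValueError("one treatment model per period required")
    if known_delta is not None:
        known_delta = np.asarray(known_delta, dtype=float)
        if known_delta.shape != (K,):
            raise ValueError(f"known_delta must have length {K}")
    per_period = np.empty((panel.n, K))
    n_flags = 0
    for t in range(1, K + 1):
        z = panel.Z[:, t - 1].astype(float)
        a = panel.A[:, t - 1].astype(float)
        pz = instrument_models[t - 1].pmf_observed(z)
        if known_delta is not None:
            delta = (2.0 * a - 1.0) * known_delta[t - 1]
            n_flags += int(np.sum(np.abs(delta) < tol))
        else:
            d = delta_from_model(
                treatment_models[t - 1], panel, t, tol=tol, mode=delta_mode
            )
            n_flags += d.n_unstable
            delta = d.delta
        w = np.where(z == 1.0, 1.0, -1.0) * pz * delta
        if stabiliser == "standard":
            st = fit_marginal_treatment_model(panel, t).pmf_observed(a)
            _check_divisor(st, t, "St_t^Stab", tol)
            w = w / st
        elif stabiliser == "delta":
            # divisor is the success-probability difference P(A_t=1|Z_t=1,hist)
            # - P(A_t=1|Z_t=0,hist), NOT the observed-a pmf difference: dividing
            # by the sign-flipping version would cancel the weight's sign
            # structure and destroy the estimating equations
            rm = fit_reduced_treatment_model(panel, t)
            d_stab = rm.predict_with_z(1) - rm.predict_with_z(0)
            if delta_mode == "constant" and known_delta is None:
                d_stab = np.full(panel.n, float(d_stab.mean()))
            _check_divisor(d_stab, t, "Delta_t^Stab", tol)
            w = w / d_stab
        per_period[:, t - 1] = w
    return IVWeights(
        per_period=per_period,
        product=per_period.prod(axis=1),
        stabiliser=stabiliser,
        n_instability_flags=n_flags,
    )


def _check_divisor(values: np.ndarray, t: int, name: str, tol: float) -> None:
    bad = np.abs(values) < tol
    if bad.any():
        raise NonConvergenceError(
            f"period {t}: |{name}| < {tol:g} for {int(bad.sum())} subject(s); "
            "stabilised weights undefined"
        )


def _tukey_fences(values: np.ndarray) -> tuple[float, float]:
    # type-7 (linear interpolation) quantiles; fences depend on this convention
    q1, q3 = np.percentile(values, [25.0, 75.0])
    iqr = q3 - q1
    return float(q1 - 1.5 * iqr), float(q3 + 1.5 * iqr)


def trim_weights(weights: IVWeights, level: str = "product") -> IVWeights:
    """Cap weights to the Tukey fences [Q1 − 1.5·IQR, Q3 + 1.5·IQR].

    Trimming operates on the product weights by default (the product is what
    enters estimation); ``level='per_period'`` caps each period's weights and
    recomputes the product.  Idempotent: re-trimming leaves weights unchanged.
    """
    if level == "product":
        lo, hi = _tukey_fences(weights.product)
        return IVWeights(
            per_period=weights.per_period,
            product=np.clip(weights.product, lo, hi),
            stabiliser=weights.stabiliser,
            trim_bounds=(lo, hi),
            n_instability_flags=weights.n_instability_flags,
        )
    if level == "per_period":
        per = weights.per_period.copy()
        for t in range(per.shape[1]):
            lo, hi = _tukey_fences(per[:, t])
            per[:, t] = np.clip(per[:, t], lo, hi)
        lo, hi = _tukey_fences(per.prod(axis=1))
        return IVWeights(
            per_period=per,
            product=per.prod(axis=1),
            stabiliser=weights.stabiliser,
            trim_bounds=(lo, hi),
            n_instability_flags=weights.n_instability_flags,
        )
    raise ValueError(f"unknown trim level {level!r}")


def estimate_iv_w(
    panel: PanelData,
    weights: IVWeights,
    condition_threshold: float = CONDITION_THRESHOLD,
    instability_fraction: float = 0.1,
) -> MSMEstimate:
    """Weighted least-squares solve of the MSM with weights 1/W̄ᵢ.

    β̂ = (A'ᵀ D A')⁻¹ A'ᵀ D Y with A' = [1, A] and D = diag(1/W̄ᵢ); the
    weights may be negative.  Raises :class:`NonConvergenceError` on a zero
    weight or a numerically singular normal matrix.
    """
    w = weights.product
    n_zero = int(np.sum(np.abs(w) < PRODUCT_TOL))
    if n_zero:
        raise NonConvergenceError(
            f"{n_zero} product weight(s) numerically zero; WLS undefined"
        )
    d = 1.0 / w
    Ap = np.column_stack([np.ones(panel.n), panel.A.astype(float)])
    M = Ap.T @ (Ap * d[:, None])
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > condition_threshold:
        raise NonConvergenceError(
            f"weighted normal matrix singular (condition number {cond:.3g})"
        )
    coefs = np.linalg.solve(M, Ap.T @ (d * panel.Y))
    if weights.n_instability_flags > instability_fraction * panel.n:
        warnings.warn(
            f"{weights.n_instability_flags} compliance-difference instability "
            "flag(s); the MSM estimate may be unreliable",
            InstabilityWarning,
            stacklevel=2,
        )
    beta = coefs[1:]
    return MSMEstimate(
        beta0=float(coefs[0]),
        beta=beta,
        ate=float(beta.sum()),
        weights_used=weights,
        converged=True,
    )


def fit_iv_w(
    panel: PanelData,
    spec: HistorySpec = HistorySpec(),
    stabiliser: str = "none",
    trim: bool = False,
    instrument_spec: HistorySpec | None = None,
    delta_mode: str = "subject",
    known_delta: np.ndarray | None = None,
) -> MSMEstimate:
    """Full IV-W pipeline: nuisance fits, weights, optional trim, WLS solve.

    The treatment models use ``spec`` (history plus any requested confounder
    columns); the instrument models use the minimal history by default, or
    ``instrument_spec`` when given.
    """
    ispec = instrument_spec if instrument_spec is not None else HistorySpec()
    K = panel.K
    imodels = [fit_instrument_model(panel, t, ispec) for t in range(1, K + 1)]
    tmodels = None
    if known_delta is None:
        tmodels = [fit_treatment_model(panel, t, spec) for t in range(1, K + 1)]
    weights = compute_weights(
        panel, imodels, tmodels, stabiliser=stabiliser,
        delta_mode=delta_mode, known_delta=known_delta,
    )
    if trim:
        weights = trim_weights(weights)
    return estimate_iv_w(panel, weights)
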