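"""Longitudinal panel container, file I/O, QALY outcome and preference-based instruments.

The data model is a complete-case longitudinal panel: ``n`` subjects followed over
``K`` treatment periods, with a binary treatment ``A_t`` and binary instrument
``Z_t`` recorded at each period, optional numeric confounders ``L_t`` (``p``
covariates per period), and a single continuous end-of-study outcome ``Y``
observed after the last treatment period.  Period indexing is 1-based
(treatments at t = 1..K, outcome at T = K+1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PanelData",
    "HistorySpec",
    "PanelFormatError",
    "PanelValidationError",
    "PositivityWarning",
    "read_panel",
    "write_panel",
    "compute_qaly",
    "build_preference_iv",
]

# Time-weights of the four per-phase utility scores entering the QALY over an
# 18-month follow-up: half a year at each interior phase, a quarter year at the
# boundary phases.
QALY_WEIGHTS = np.array([0.25, 0.5, 0.5, 0.25])


class PanelFormatError(ValueError):
    """A panel file does not have the expected layout/header."""


class PanelValidationError(ValueError):
    """Panel values violate an invariant (non-binary A/Z, missing data, ...)."""


class PositivityWarning(UserWarning):
    """A period has no variation in treatment or instrument (positivity at risk)."""


@dataclass
class PanelData:
    """Complete-case longitudinal panel.

    Attributes
    ----------
    Y : (n,) float array — continuous end-of-study outcome.
    A : (n, K) int array — binary treatment per period.
    Z : (n, K) int array — binary instrument per period.
    L : (n, K, p) float array — observed confounders (p may be 0).
    U : optional (n, K) float array — unobserved confounders; simulation truth
        only, never used by estimators.
    ids : (n,) subject identifiers.
    """

    Y: np.ndarray
    A: np.ndarray
    Z: np.ndarray
    L: np.ndarray | None = None
    U: np.ndarray | None = None
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        self.A = np.asarray(self.A)
        self.Z = np.asarray(self.Z)
        if self.Y.ndim != 1:
            raise PanelValidationError("Y must be one-dimensional")
        n = self.Y.shape[0]
        if self.A.ndim != 2 or self.Z.ndim != 2:
            raise PanelValidationError("A and Z must be n x K matrices")
        if self.A.shape[0] != n or self.Z.shape[0] != n:
            raise PanelValidationError("A, Z and Y must agree on subject count")
        if self.A.shape[1] != self.Z.shape[1]:
            raise PanelValidationError("A and Z must agree on period count")
        if self.K < 1:
            raise PanelValidationError("at least one treatment period is required")
        for name, mat in (("A", self.A), ("Z", self.Z)):
            vals = np.asarray(mat, dtype=float)
            if np.isnan(vals).any():
                raise PanelValidationError(f"{name} contains missing values")
            bad = ~np.isin(vals, (0.0, 1.0))
            if bad.any():
                t = int(np.argwhere(bad)[0, 1]) + 1
                raise PanelValidationError(
                    f"non-binary value in {name}{t}: entries must be 0 or 1"
                )
        self.A = self.A.astype(np.int8)
        self.Z = self.Z.astype(np.int8)
        if not np.isfinite(self.Y).all():
            raise PanelValidationError("Y contains missing or non-finite values")
        if self.L is None:
            self.L = np.empty((n, self.K, 0), dtype=float)
        else:
            self.L = np.asarray(self.L, dtype=float)
            if self.L.ndim == 2:  # single covariate supplied as n x K
                self.L = self.L[:, :, None]
            if self.L.shape[:2] != (n, self.K):
                raise PanelValidationError("L must have shape (n, K, p)")
            if not np.isfinite(self.L).all():
                raise PanelValidationError("L contains missing or non-finite values")
        if self.U is not None:
            self.U = np.asarray(self.U, dtype=float)
        if self.ids is None:
            self.ids = np.arange(1, n + 1)
        else:
            self.ids = np.asarray(self.ids)
            if self.ids.shape[0] != n:
                raise PanelValidationError("ids length must equal subject count")
        for name, mat in (("A", self.A), ("Z", self.Z)):
            for t in range(self.K):
                col = mat[:, t]
                if col.min() == col.max():
                    warnings.warn(
                        f"{name}{t + 1} is constant ({int(col[0])}): positivity "
                        "violated in this period",
                        PositivityWarning,
                        stacklevel=2,
                    )

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def K(self) -> int:
        return self.A.shape[1]

    @property
    def p(self) -> int:
        return 0 if self.L is None else self.L.shape[2]

    def subset(self, idx: np.ndarray) -> "PanelData":
        """Row-subset (or resample) the panel; whole subject histories move together."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PositivityWarning)
            return PanelData(
                Y=self.Y[idx],
                A=self.A[idx],
                Z=self.Z[idx],
                L=self.L[idx] if self.p else None,
                U=None if self.U is None else self.U[idx],
                ids=self.ids[idx],
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PanelData):
            return NotImplemented
        return (
            np.array_equal(self.Y, other.Y)
            and np.array_equal(self.A, other.A)
            and np.array_equal(self.Z, other.Z)
            and np.array_equal(self.L, other.L)
            and np.array_equal(self.ids, other.ids)
        )


@dataclass(frozen=True)
class HistorySpec:
    """Which parts of the observed history enter the conditioning set M_t.

    The minimal set is the treatment and instrument history
    (A_1..A_{t-1}, Z_1..Z_{t-1}); ``confounder_subset`` lists indices of L
    columns whose history L_1..L_t is added on top.  At t = 1 the realised
    minimal set is empty (intercept only) unless confounders are requested.
    """

    use_treatment_history: bool = True
    use_instrument_history: bool = True
    confounder_subset: tuple[int, ...] = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_DEFAULT_SCHEMA = {"Y": "Y", "A": "A{t}", "Z": "Z{t}", "L": "L{t}_{j}", "id": "id"}


def _l_name(t: int, j: int, p: int, schema: Mapping[str, str]) -> str:
    # single-covariate panels conventionally use bare L1..LK column names
    if p == 1:
        return schema["L"].format(t=t, j=j).replace("_1", "") if schema["L"] == _DEFAULT_SCHEMA["L"] else schema["L"].format(t=t, j=j)
    return schema["L"].format(t=t, j=j)


def _infer_wide_shape(columns: Sequence[str], schema: Mapping[str, str]) -> tuple[int, int]:
    K = 0
    while schema["A"].format(t=K + 1) in columns:
        K += 1
    if K == 0 or schema["Y"] not in columns:
        raise PanelFormatError(
            "malformed header: expected columns "
            f"{schema['Y']}, {schema['A'].format(t=1)}.., {schema['Z'].format(t=1)}.."
        )
    for t in range(1, K + 1):
        if schema["Z"].format(t=t) not in columns:
            raise PanelFormatError(f"malformed header: missing {schema['Z'].format(t=t)}")
    p = 0
    while (
        schema["L"].format(t=1, j=p + 1) in columns
        or (p == 0 and schema["L"].format(t=1, j=1).replace("_1", "") in columns)
    ):
        p += 1
    return K, p


def read_panel(
    path,
    layout: str = "wide",
    schema: Mapping[str, str] | None = None,
) -> PanelData:
    """Read a panel from a delimited text file.

    ``layout='wide'`` expects one row per subject with columns
    Y, A1..AK, Z1..ZK[, L1_1..LK_p]; ``layout='long'`` expects rows
    (id, period, variable, value) with variables Y, A, Z, L1..Lp and the
    outcome stored at period K+1.  Rows (subjects) with missing required
    values are dropped with a reported count.
    """
    sch = dict(_DEFAULT_SCHEMA)
    if schema:
        sch.update(schema)
    if layout == "wide":
        df = pd.read_csv(path, float_precision="round_trip")
        K, p = _infer_wide_shape(list(df.columns), sch)
        acols = [sch["A"].format(t=t) for t in range(1, K + 1)]
        zcols = [sch["Z"].format(t=t) for t in range(1, K + 1)]
        lcols = [_l_name(t, j, p, sch) for t in range(1, K + 1) for j in range(1, p + 1)]
        need = [sch["Y"], *acols, *zcols, *lcols]
        n_before = len(df)
        df = df.dropna(subset=need)
        if len(df) < n_before:
            warnings.warn(
                f"dropped {n_before - len(df)} row(s) with missing required values",
                UserWarning,
                stacklevel=2,
            )
        ids = df[sch["id"]].to_numpy() if sch["id"] in df.columns else None
        L = None
        if p:
            L = df[lcols].to_numpy(dtype=float).reshape(len(df), K, p)
        return PanelData(
            Y=df[sch["Y"]].to_numpy(dtype=float),
            A=df[acols].to_numpy(),
            Z=df[zcols].to_numpy(),
            L=L,
            ids=ids,
        )
    if layout == "long":
        df = pd.read_csv(path, float_precision="round_trip")
        required = {"id", "period", "variable", "value"}
        if not required.issubset(df.columns):
            raise PanelFormatError(
                f"malformed header: long layout needs columns {sorted(required)}"
            )
        n_before = df["id"].nunique()
        df = df.dropna(subset=["id", "period", "variable", "value"])
        wide = df.pivot_table(
            index="id", columns=["variable", "period"], values="value", aggfunc="first"
        )
        variables = df["variable"].unique()
        K = int(df.loc[df["variable"] == "A", "period"].max())
        lvars = sorted(v for v in variables if v.startswith("L"))
        p = len(lvars)
        cols = [("Y", K + 1)]
        cols += [("A", t) for t in range(1, K + 1)]
        cols += [("Z", t) for t in range(1, K + 1)]
        cols += [(v, t) for t in range(1, K + 1) for v in lvars]
        missing = [c for c in cols if c not in wide.columns]
        if missing:
            raise PanelFormatError(f"malformed long file: missing records {missing[:5]}")
        wide = wide.dropna(subset=cols)
        if len(wide) < n_before:
            warnings.warn(
                f"dropped {n_before - len(wide)} subject(s) with missing required values",
                UserWarning,
                stacklevel=2,
            )
        A = wide[[("A", t) for t in range(1, K + 1)]].to_numpy()
        Z = wide[[("Z", t) for t in range(1, K + 1)]].to_numpy()
        L = None
        if p:
            L = np.stack(
                [wide[[(v, t) for v in lvars]].to_numpy() for t in range(1, K + 1)],
                axis=1,
            )
        return PanelData(
            Y=wide[("Y", K + 1)].to_numpy(dtype=float),
            A=A,
            Z=Z,
            L=L,
            ids=wide.index.to_numpy(),
        )
    raise ValueError(f"unknown layout {layout!r}")


def write_panel(panel: PanelData, path, layout: str = "wide") -> None:
    """Write a panel as UTF-8 comma-delimited text (wide or long layout)."""
    K, p = panel.K, panel.p
    if layout == "wide":
        data = {"id": panel.ids, "Y": panel.Y}
        for t in range(1, K + 1):
            data[f"A{t}"] = panel.A[:, t - 1]
        for t in range(1, K + 1):
            data[f"Z{t}"] = panel.Z[:, t - 1]
        for t in range(1, K + 1):
            for j in range(1, p + 1):
                data[_l_name(t, j, p, _DEFAULT_SCHEMA)] = panel.L[:, t - 1, j - 1]
        pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")
        return
    if layout == "long":
        rows = []
        for i in range(panel.n):
            rows.append((panel.ids[i], K + 1, "Y", panel.Y[i]))
            for t in range(1, K + 1):
                rows.append((panel.ids[i], t, "A", int(panel.A[i, t - 1])))
                rows.append((panel.ids[i], t, "Z", int(panel.Z[i, t - 1])))
                for j in range(1, p + 1):
                    rows.append((panel.ids[i], t, f"L{j}", panel.L[i, t - 1, j - 1]))
        pd.DataFrame(rows, columns=["id", "period", "variable", "value"]).to_csv(
            path, index=False, float_format="%.17g"
        )
        return
    raise ValueError(f"unknown layout {layout!r}")


# ---------------------------------------------------------------------------
# Outcome construction
# ---------------------------------------------------------------------------


def compute_qaly(eq5d) -> np.ndarray:
    """Quality-adjusted life years over an 18-month follow-up.

    Takes four per-phase EQ-5D utility scores per subject and returns
    0.25*s1 + 0.5*s2 + 0.5*s3 + 0.25*s4.  With utilities in [0, 1] the QALY
    lies in [0, 1.5]; 1.5 means the full 18 months in full health.
    """
    scores = np.asarray(eq5d, dtype=float)
    if scores.ndim == 1:
        scores = scores[None, :]
    if scores.ndim != 2 or scores.shape[1] != 4:
        raise ValueError("expected four per-phase utility scores per subject")
    if not np.isfinite(scores).all():
        raise ValueError("utility scores must be finite")
    out = scores @ QALY_WEIGHTS
    return out[0] if np.asarray(eq5d).ndim == 1 else out


# ---------------------------------------------------------------------------
# Preference-based instruments from prescription records
# ---------------------------------------------------------------------------


def build_preference_iv(
    prescriptions: pd.DataFrame,
    patients: pd.DataFrame,
    target_drug,
    method: str = "proportion_median",
    whole_history: bool = True,
) -> tuple[pd.DataFrame, int]:
    """Dichotomised prescriber-preference instrument per patient-period.

    ``prescriptions`` holds records (prescriber_id, phase, drug); ``patients``
    links (patient_id, prescriber_id, phase).  ``method``:

    - ``proportion_median``: IV = 1 iff the prescriber's cumulative proportion
      of target-drug prescriptions (among all drugs) up to the phase strictly
      exceeds the median of all prescribers' proportions in that phase
      (exactly at the median -> 0).
    - ``modal``: IV = 1 iff the target drug is the prescriber's most-prescribed
      drug in history; ties resolve in favour of the target drug.
    - ``last``: IV = 1 iff the prescriber's most recent prescription in history
      is the target drug (within a phase, the later record wins).

    By default the whole prescription history up to and including the phase is
    used; ``whole_history=False`` restricts to the current phase only.
    Patient-periods whose prescriber has no prescriptions in the relevant
    history are excluded and counted (mirroring complete-case handling of
    subjects without prescriber information); returns ``(iv_table, n_missing)``
    where ``iv_table`` has columns patient_id, phase, iv.
    """
    if method not in ("proportion_median", "modal", "last"):
        raise ValueError(f"unknown method {method!r}")
    rx = prescriptions.copy()
    for col in ("prescriber_id", "phase", "drug"):
        if col not in rx.columns:
            raise PanelFormatError(f"prescriptions file missing column {col!r}")
    for col in ("patient_id", "prescriber_id", "phase"):
        if col not in patients.columns:
            raise PanelFormatError(f"patient link file missing column {col!r}")
    rx["is_target"] = (rx["drug"] == target_drug).astype(int)
    rx = rx.reset_index(drop=True)
    rx["order"] = np.arange(len(rx))  # record order breaks within-phase ties for 'last'

    phases = sorted(patients["phase"].unique())
    prescribers = rx["prescriber_id"].unique()
    pref_rows = []
    for phase in phases:
        if whole_history:
            hist = rx[rx["phase"] <= phase]
        else:
            hist = rx[rx["phase"] == phase]
        grouped = hist.groupby("prescriber_id")
        if method == "proportion_median":
            prop = grouped["is_target"].mean()
            # prescribers with no prescriptions in the history are excluded
            # from the median (their preference is undefined in this phase)
            med = float(prop.median()) if len(prop) else np.nan
            iv = (prop > med).astype(int)
        elif method == "modal":
            counts = hist.groupby(["prescriber_id", "drug"]).size().unstack(fill_value=0)
            if target_drug in counts.columns:
                iv = (counts[target_drug] >= counts.max(axis=1)).astype(int)
            else:
                iv = pd.Series(0, index=counts.index)
        else:  # last
            last_rx = grouped.apply(
                lambda g: g.sort_values(["phase", "order"]).iloc[-1]["is_target"],
                include_groups=False,
            )
            iv = last_rx.astype(int)
        for prescriber in prescribers:
            if prescriber in iv.index:
                pref_rows.append((prescriber, phase, int(iv.loc[prescriber])))
    pref = pd.DataFrame(pref_rows, columns=["prescriber_id", "phase", "iv"])
    merged = patients.merge(pref, on=["prescriber_id", "phase"], how="left")
    missing = merged["iv"].isna()
    n_missing = int(missing.sum())
    if n_missing:
        warnings.warn(
            f"excluded {n_missing} patient-period(s) with no linked prescriber history",
            UserWarning,
            stacklevel=2,
        )
    out = merged.loc[~missing, ["patient_id", "phase", "iv"]].reset_index(drop=True)
    out["iv"] = out["iv"].astype(int)
    return out, n_missing
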