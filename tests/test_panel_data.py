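import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from longiv.dgm import DGMParams, simulate
from longiv.panel_data import (
    PanelData,
    PanelFormatError,
    PanelValidationError,
    PositivityWarning,
    build_preference_iv,
    compute_qaly,
    read_panel,
    write_panel,
)


class TestPanelData:
    def test_wide_csv_parse(self, tmp_path):
        path = tmp_path / "panel.csv"
        path.write_text(
            "Y,A1,A2,A3,Z1,Z2,Z3\n"
            "1.5,0,1,0,1,1,0\n2.0,1,1,1,0,1,1\n0.5,0,0,0,0,0,1\n1.0,1,0,1,1,0,0\n"
        )
        panel = read_panel(path, layout="wide")
        assert (panel.n, panel.K, panel.p) == (4, 3, 0)
        assert panel.Y[1] == 2.0 and panel.A[1, 2] == 1

    def test_non_binary_treatment_rejected(self, tmp_path):
        path = tmp_path / "panel.csv"
        path.write_text(
            "Y,A1,A2,A3,Z1,Z2,Z3\n1.5,0,2,0,1,1,0\n2.0,1,1,1,0,1,1\n"
        )
        with pytest.raises(PanelValidationError, match="A2"):
            read_panel(path, layout="wide")

    def test_malformed_header(self, tmp_path):
        path = tmp_path / "panel.csv"
        path.write_text("outcome,treat\n1,0\n")
        with pytest.raises(PanelFormatError):
            read_panel(path, layout="wide")

    @pytest.mark.parametrize("layout", ["wide", "long"])
    def test_round_trip_identity(self, tmp_path, layout):
        panel = simulate(DGMParams(alpha=0.5), n=50, seed=7)
        panel = PanelData(Y=panel.Y, A=panel.A, Z=panel.Z, L=panel.L)  # drop U
        path = tmp_path / f"panel_{layout}.csv"
        write_panel(panel, path, layout=layout)
        back = read_panel(path, layout=layout)
        assert back == panel

    def test_positivity_warning_on_constant_column(self):
        with pytest.warns(PositivityWarning, match="A1"):
            PanelData(
                Y=np.zeros(3),
                A=np.ones((3, 1)),
                Z=np.array([[0], [1], [0]]),
            )

    def test_missing_rows_dropped_with_count(self, tmp_path):
        path = tmp_path / "panel.csv"
        path.write_text(
            "Y,A1,A2,A3,Z1,Z2,Z3\n1.5,0,1,0,1,1,0\n,1,1,1,0,1,1\n"
            "0.5,0,0,0,0,0,1\n1.0,1,0,1,1,0,0\n"
        )
        with pytest.warns(UserWarning, match="dropped 1"):
            panel = read_panel(path, layout="wide")
        assert panel.n == 3


class TestQaly:
    @pytest.mark.parametrize(
        "scores,expected",
        [
            ((1, 1, 1, 1), 1.5),  # full 18 months in full health
            ((0, 0, 0, 0), 0.0),
            ((0.8, 0.6, 0.6, 0.8), 1.0),
        ],
    )
    def test_examples(self, scores, expected):
        assert compute_qaly(scores) == pytest.approx(expected)

    def test_wrong_arity(self):
        with pytest.raises(ValueError):
            compute_qaly([0.5, 0.5, 0.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=4, max_size=4), st.floats(0.1, 2.0))
    def test_linear_and_middle_phase_symmetric(self, s, c):
        base = compute_qaly(s)
        assert compute_qaly([c * x for x in s]) == pytest.approx(c * base, abs=1e-9)
        swapped = [s[0], s[2], s[1], s[3]]
        assert compute_qaly(swapped) == pytest.approx(base, abs=1e-12)

    def test_vectorised(self):
        out = compute_qaly(np.array([[1, 1, 1, 1], [0, 0, 0, 0]]))
        assert np.allclose(out, [1.5, 0.0])


def _rx(rows):
    return pd.DataFrame(rows, columns=["prescriber_id", "phase", "drug"])


def _pat(rows):
    return pd.DataFrame(rows, columns=["patient_id", "prescriber_id", "phase"])


class TestPreferenceIV:
    def test_proportion_above_median(self):
        # doctor d1 prescribed the target 3 of 4 times; d2 and d3 never:
        # the phase median proportion is 0, so d1's 0.75 > median -> IV = 1
        rx = _rx(
            [("d1", 1, "T"), ("d1", 1, "T"), ("d1", 1, "T"), ("d1", 1, "O"),
             ("d2", 1, "O"), ("d3", 1, "O")]
        )
        pats = _pat([("p1", "d1", 1), ("p2", "d2", 1)])
        iv, n_missing = build_preference_iv(rx, pats, target_drug="T")
        assert n_missing == 0
        assert iv.set_index("patient_id")["iv"].to_dict() == {"p1": 1, "p2": 0}

    def test_at_median_is_zero(self):
        # both prescribers at proportion 0.5 == median -> strict inequality -> 0
        rx = _rx([("d1", 1, "T"), ("d1", 1, "O"), ("d2", 1, "T"), ("d2", 1, "O")])
        pats = _pat([("p1", "d1", 1), ("p2", "d2", 1)])
        iv, _ = build_preference_iv(rx, pats, target_drug="T")
        assert set(iv["iv"]) == {0}

    def test_last_prescription_non_target(self):
        rx = _rx([("d1", 1, "T"), ("d1", 2, "O")])
        pats = _pat([("p1", "d1", 2)])
        iv, _ = build_preference_iv(rx, pats, target_drug="T", method="last")
        assert iv["iv"].tolist() == [0]

    def test_modal_tie_goes_to_target(self):
        # two drugs tied at 2 prescriptions each; the documented tie-break
        # awards the target drug, so IV = 1 (the alternative rule would give 0)
        rx = _rx([("d1", 1, "T"), ("d1", 1, "T"), ("d1", 1, "O"), ("d1", 1, "O")])
        pats = _pat([("p1", "d1", 1)])
        iv, _ = build_preference_iv(rx, pats, target_drug="T", method="modal")
        assert iv["iv"].tolist() == [1]

    def test_missing_prescriber_history_excluded(self):
        rx = _rx([("d1", 2, "T")])
        pats = _pat([("p1", "d1", 1), ("p2", "d1", 2)])  # phase 1 precedes any rx
        with pytest.warns(UserWarning, match="excluded 1"):
            iv, n_missing = build_preference_iv(rx, pats, target_drug="T")
        assert n_missing == 1
        assert iv["patient_id"].tolist() == ["p2"]

    def test_whole_history_vs_current_phase(self):
        # d1 prescribed target only in phase 1; by phase 2 whole-history still
        # counts it while the per-phase variant does not
        rx = _rx([("d1", 1, "T"), ("d1", 2, "O"), ("d2", 1, "O"), ("d2", 2, "O")])
        pats = _pat([("p1", "d1", 2)])
        whole, _ = build_preference_iv(rx, pats, target_drug="T", method="modal")
        phase_only, _ = build_preference_iv(
            rx, pats, target_drug="T", method="modal", whole_history=False
        )
        assert whole["iv"].tolist() == [1]
        assert phase_only["iv"].tolist() == [0]

    def test_proportion_median_balance_property(self):
        # with strict inequality at the median, at most half the prescribers
        # (plus ties at the median) can sit above it in any phase
        rng = np.random.default_rng(5)
        rows = []
        for d in range(20):
            for _ in range(rng.integers(1, 8)):
                rows.append((f"d{d}", 1, rng.choice(["T", "O"])))
        rx = _rx(rows)
        pats = _pat([(f"p{d}", f"d{d}", 1) for d in range(20)])
        iv, _ = build_preference_iv(rx, pats, target_drug="T")
        assert iv["iv"].isin([0, 1]).all()
        assert iv["iv"].mean() <= 0.5
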