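import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from vffr.diagnostics import (
    ConfusionTable,
    DiagnosticsError,
    PairedFfr,
    bland_altman,
    confusion_table,
    metrics_report,
    proportion_metrics,
    roc_auc,
    round_half_up,
    spearman_rho,
    wilson_interval,
)


def paired(virtual, invasive, patients=None):
    n = len(virtual)
    patients = patients or [f"P{i}" for i in range(n)]
    return PairedFfr(patients, [f"V{i}" for i in range(n)], np.asarray(virtual), np.asarray(invasive))


# ---------------------------------------------------------------------------
# Wilson intervals
# ---------------------------------------------------------------------------


class TestWilson:
    @pytest.mark.parametrize(
        "x,n",
        [(16, 24), (15, 19), (16, 20), (15, 23), (16, 23), (7, 14), (3, 11), (0, 10), (10, 10)],
    )
    def test_matches_statsmodels_oracle(self, x, n):
        from statsmodels.stats.proportion import proportion_confint

        lo, hi = proportion_confint(x, n, alpha=0.05, method="wilson")
        ci = wilson_interval(x, n)
        assert ci.lower == pytest.approx(100 * lo, abs=2e-3)
        assert ci.upper == pytest.approx(100 * hi, abs=2e-3)

    def test_zero_successes_lower_bound(self):
        ci = wilson_interval(0, 10)
        assert ci.lower == pytest.approx(0.0, abs=1e-9)
        assert ci.estimate == 0.0

    def test_symmetry_at_half(self):
        ci = wilson_interval(7, 14)
        assert ci.lower + ci.upper == pytest.approx(100.0, abs=1e-9)

    @given(st.integers(1, 60))
    @settings(max_examples=40, deadline=None)
    def test_width_shrinks_with_n_at_fixed_p(self, k):
        narrow = wilson_interval(2 * k, 4 * k)
        wide = wilson_interval(k, 2 * k)
        assert narrow.upper - narrow.lower < wide.upper - wide.lower + 1e-12

    @given(st.integers(0, 50), st.integers(1, 50))
    @settings(max_examples=60, deadline=None)
    def test_bounds_bracket_estimate(self, x, n):
        if x > n:
            x, n = n, x
        ci = wilson_interval(x, n)
        assert 0.0 <= ci.lower <= ci.estimate <= ci.upper <= 100.0

    def test_zero_denominator_flagged(self):
        ci = wilson_interval(0, 0)
        assert not ci.defined


# ---------------------------------------------------------------------------
# confusion tables / metrics
# ---------------------------------------------------------------------------


class TestConfusion:
    def test_perfect_agreement(self):
        p = paired([0.7, 0.9, 0.85, 0.6], [0.7, 0.9, 0.85, 0.6])
        t = confusion_table(p)
        assert (t.fp, t.fn) == (0, 0)
        m = proportion_metrics(t)
        assert m["sensitivity"].estimate == 100.0
        assert m["specificity"].estimate == 100.0

    def test_strict_threshold_on_both_sides(self):
        p = paired([0.80, 0.79], [0.80, 0.79])
        t = confusion_table(p)
        assert (t.tp, t.tn, t.fp, t.fn) == (1, 1, 0, 0)

    def test_empty_errors(self):
        with pytest.raises(DiagnosticsError):
            confusion_table(paired([], []))

    def test_per_patient_aggregates_any_rule(self):
        p = paired(
            [0.7, 0.9, 0.9],
            [0.9, 0.7, 0.9],
            patients=["A", "A", "B"],
        )
        t = confusion_table(p, per_patient=True)
        # patient A: virtual positive, invasive positive; B: both negative
        assert (t.tp, t.fp, t.fn, t.tn) == (1, 0, 0, 1)

    def test_negative_count_rejected(self):
        with pytest.raises(DiagnosticsError):
            ConfusionTable(-1, 0, 0, 0)


def build_fixture_cohort(tp, fp, fn, tn, start=0):
    """Deterministic per-vessel pairs realizing an exact 2x2 table."""
    virtual, invasive = [], []
    for _ in range(tp):
        virtual.append(0.70)
        invasive.append(0.72)
    for _ in range(fp):
        virtual.append(0.75)
        invasive.append(0.88)
    for _ in range(fn):
        virtual.append(0.86)
        invasive.append(0.74)
    for _ in range(tn):
        virtual.append(0.90)
        invasive.append(0.92)
    n = len(virtual)
    return PairedFfr(
        [f"P{start + i}" for i in range(n)],
        ["V0"] * n,
        np.array(virtual),
        np.array(invasive),
    )


class TestFixtureTable:
    def test_43_pair_fixture_reproduces_table(self):
        p = build_fixture_cohort(16, 4, 8, 15)
        assert len(p) == 43
        t = confusion_table(p)
        assert (t.tp, t.fp, t.fn, t.tn) == (16, 4, 8, 15)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


class TestRoc:
    def test_perfect_separation(self):
        p = paired([0.5, 0.55, 0.9, 0.95], [0.7, 0.7, 0.9, 0.9])
        assert roc_auc(p).auc == pytest.approx(1.0)

    def test_all_ties(self):
        p = paired([0.8] * 6, [0.7, 0.7, 0.7, 0.9, 0.9, 0.9])
        assert roc_auc(p).auc == pytest.approx(0.5)

    def test_matches_bruteforce_pairwise_oracle(self, rng):
        virtual = np.round(rng.uniform(0.3, 1.0, 20), 2)  # rounding induces ties
        invasive = rng.uniform(0.3, 1.0, 20)
        p = paired(virtual, invasive)
        labels = invasive < 0.80
        scores = 1 - virtual
        pos = scores[labels]
        neg = scores[~labels]
        total = 0.0
        for a, b in itertools.product(pos, neg):
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
        expected = total / (len(pos) * len(neg))
        assert roc_auc(p).auc == pytest.approx(expected, abs=1e-12)

    def test_auc_equals_trapezoid_under_curve(self, rng):
        virtual = np.round(rng.uniform(0.3, 1.0, 30), 2)
        invasive = rng.uniform(0.3, 1.0, 30)
        roc = roc_auc(paired(virtual, invasive))
        assert roc.auc == pytest.approx(float(np.trapezoid(roc.tpr, roc.fpr)), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        virtual = rng.uniform(0.3, 1.0, 25)
        invasive = rng.uniform(0.3, 1.0, 25)
        base = roc_auc(paired(virtual, invasive)).auc
        # strictly increasing map of the virtual values preserves score order
        transformed = 0.1 + 0.9 * (virtual / 1.2) ** 2
        assert roc_auc(paired(transformed, invasive)).auc == pytest.approx(base, abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(DiagnosticsError):
            roc_auc(paired([0.9, 0.95], [0.9, 0.95]))


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------


class TestBlandAltman:
    def test_identical_columns(self):
        ba = bland_altman(paired([0.8, 0.7, 0.9], [0.8, 0.7, 0.9]))
        assert ba["bias"] == 0.0
        assert ba["sd"] == 0.0

    def test_constant_offset(self):
        ba = bland_altman(paired([0.85, 0.75, 0.95], [0.80, 0.70, 0.90]))
        assert ba["bias"] == pytest.approx(0.05)
        assert ba["sd"] == pytest.approx(0.0, abs=1e-12)

    def test_five_row_worked_fixture(self):
        virtual = np.array([0.82, 0.71, 0.93, 0.64, 0.88])
        invasive = np.array([0.80, 0.75, 0.90, 0.70, 0.85])
        diffs = virtual - invasive
        ba = bland_altman(paired(virtual, invasive))
        assert ba["bias"] == pytest.approx(float(np.mean(diffs)))
        assert ba["sd"] == pytest.approx(float(np.std(diffs, ddof=1)))
        assert ba["loa_upper"] == pytest.approx(ba["bias"] + 1.96 * ba["sd"])

    def test_sign_flips_when_columns_swap(self, rng):
        virtual = rng.uniform(0.4, 1.0, 12)
        invasive = rng.uniform(0.4, 1.0, 12)
        a = bland_altman(paired(virtual, invasive))
        b = bland_altman(paired(invasive, virtual))
        assert a["bias"] == pytest.approx(-b["bias"])

    def test_n1_errors(self):
        with pytest.raises(DiagnosticsError):
            bland_altman(paired([0.8], [0.8]))


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------


class TestSpearman:
    def test_monotone_increasing(self):
        assert spearman_rho(paired([0.5, 0.6, 0.7, 0.8], [0.4, 0.5, 0.9, 1.0])) == pytest.approx(1.0)

    def test_reversed(self):
        assert spearman_rho(paired([0.5, 0.6, 0.7], [0.9, 0.8, 0.7])) == pytest.approx(-1.0)

    def test_tie_fixture_matches_midrank_oracle(self):
        virtual = [0.70, 0.70, 0.80, 0.85, 0.90, 0.90]
        invasive = [0.75, 0.65, 0.80, 0.80, 0.95, 0.85]
        # independent oracle: explicit mid-ranks, then Pearson
        def midranks(v):
            v = np.asarray(v)
            out = np.empty(len(v))
            order = np.argsort(v, kind="stable")
            i = 0
            while i < len(v):
                j = i
                while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                    j += 1
                out[order[i : j + 1]] = (i + j) / 2 + 1
                i = j + 1
            return out

        rv, ri = midranks(virtual), midranks(invasive)
        expected = float(
            np.sum((rv - rv.mean()) * (ri - ri.mean()))
            / np.sqrt(np.sum((rv - rv.mean()) ** 2) * np.sum((ri - ri.mean()) ** 2))
        )
        assert spearman_rho(paired(virtual, invasive)) == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy(self, rng):
        virtual = np.round(rng.uniform(0.4, 1.0, 15), 2)
        invasive = np.round(rng.uniform(0.4, 1.0, 15), 2)
        expected = stats.spearmanr(virtual, invasive).statistic
        assert spearman_rho(paired(virtual, invasive)) == pytest.approx(expected, abs=1e-12)

    def test_constant_column_errors(self):
        with pytest.raises(DiagnosticsError):
            spearman_rho(paired([0.8, 0.8, 0.8], [0.7, 0.9, 0.6]))


# ---------------------------------------------------------------------------
# misc
# ---------------------------------------------------------------------------


class TestMisc:
    def test_round_half_up(self):
        assert round_half_up(66.665) == 66.67
        assert round_half_up(66.664) == 66.66
        assert round_half_up(2.5, 0) == 3.0

    def test_values_out_of_domain_rejected(self):
        with pytest.raises(DiagnosticsError):
            paired([1.3], [0.8])
        with pytest.raises(DiagnosticsError):
            paired([0.8], [0.0])

    def test_duplicate_pair_rejected(self):
        with pytest.raises(DiagnosticsError):
            PairedFfr(["A", "A"], ["V0", "V0"], np.array([0.8, 0.9]), np.array([0.8, 0.9]))

    def test_metrics_report_structure(self):
        p = build_fixture_cohort(5, 2, 3, 6)
        rep = metrics_report(p)
        assert rep["per_vessel"]["table"] == {"tp": 5, "fp": 2, "fn": 3, "tn": 6}
        assert set(rep["per_vessel"]["metrics"]) == {"sensitivity", "specificity", "ppv", "npv"}

    def test_csv_roundtrip(self, tmp_path):
        p = build_fixture_cohort(3, 1, 2, 4)
        path = tmp_path / "cohort.csv"
        p.to_csv(path)
        q = PairedFfr.from_csv(path)
        assert np.allclose(p.virtual, q.virtual)
        assert p.patient_id == q.patient_id
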