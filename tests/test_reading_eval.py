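"""Tests for detection-rate, RTPR, IOA and sample-size statistics."""

import numpy as np
import pytest

import petisl
from petisl.errors import InfeasibleError, ValidationError
from petisl.reading import _paired_score_z
from petisl.study import burden_stratum


class TestConsensus:
    def _rec(self, detected, reader, suv=None):
        return petisl.ReadingRecord("L1", reader, "DMI-like", detected, suv)

    def test_unanimity(self):
        flag, _ = petisl.consensus([self._rec(True, "R1"), self._rec(True, "R2")])
        assert flag

    def test_and_vs_or(self):
        records = [self._rec(True, "R1"), self._rec(False, "R2")]
        assert not petisl.consensus(records, rule="and")[0]
        assert petisl.consensus(records, rule="or")[0]

    def test_suv_mean_of_reporting_readers(self):
        records = [
            self._rec(True, "R1", petisl.SUVTriple(4.0, 3.0, 2.0)),
            self._rec(True, "R2", petisl.SUVTriple(6.0, 5.0, 4.0)),
        ]
        _, suv = petisl.consensus(records)
        assert suv.suv_max == pytest.approx(5.0)

    def test_explicit_override_and_warning(self):
        records = [self._rec(False, "R1"), self._rec(False, "R2")]
        with pytest.warns(UserWarning, match="consensus"):
            flag, _ = petisl.consensus(records, explicit=True)
        assert flag

    def test_suv_requires_detection(self):
        with pytest.raises(ValidationError):
            petisl.ReadingRecord("L1", "R1", "DIQ-like", False,
                                 petisl.SUVTriple(4, 3, 2))


class TestNaturalReference:
    def _rec(self, lesion, reader, system, detected=True):
        return petisl.ReadingRecord(lesion, reader, system, detected)

    def test_union_and_dedup(self):
        records = [
            self._rec("L1", "R1", "DIQ-like"),
            self._rec("L2", "R1", "DIQ-like"),
            self._rec("L2", "R2", "DMI-like"),
            self._rec("L3", "R2", "DMI-like"),
        ]
        assert petisl.natural_reference(records) == {"L1", "L2", "L3"}

    def test_empty(self):
        records = [self._rec("L1", "R1", "DIQ-like", detected=False)]
        assert petisl.natural_reference(records) == set()

    def test_order_invariant(self):
        records = [
            self._rec("L1", "R1", "DIQ-like"),
            self._rec("L2", "R2", "DMI-like"),
            self._rec("L1", "R2", "DMI-like"),
        ]
        assert petisl.natural_reference(records) == petisl.natural_reference(
            records[::-1]
        )


class TestDetectionRateAndRTPR:
    def table(self, k_dmi=59, k_diq=33, n=60):
        return petisl.DetectionTable.from_counts(
            n, {"DIQ-like": k_diq, "DMI-like": k_dmi}
        )

    def test_rates(self):
        t = self.table()
        assert petisl.detection_rate(t, "DMI-like") == (59, 60, pytest.approx(0.9833, abs=5e-5))
        assert petisl.detection_rate(t, "DIQ-like")[2] == pytest.approx(0.55)

    def test_zero_detections(self):
        t = self.table(k_dmi=0, k_diq=10)
        assert petisl.detection_rate(t, "DMI-like") == (0, 60, 0.0)

    @pytest.mark.parametrize("k_diq, expected", [(33, 1.79), (29, 2.03)])
    def test_point_estimates(self, k_diq, expected):
        res = petisl.rtpr(self.table(k_diq=k_diq), ci_method="none")
        assert res.rounded() == expected

    def test_identity_ratio(self):
        res = petisl.rtpr(self.table(k_dmi=40, k_diq=40))
        assert res.ratio == pytest.approx(1.0)
        assert res.ci_low < 1.0 < res.ci_high

    def test_katz_ci_closed_form(self):
        """59/60 vs 33/60: Katz SE = sqrt(1/59 - 1/60 + 1/33 - 1/60)."""
        lo, hi = petisl.katz_ci(59, 60, 33, 60)
        assert lo == pytest.approx(1.419, abs=5e-4)
        assert hi == pytest.approx(2.253, abs=5e-4)

    def test_rtpr_of_table_against_itself(self):
        t = self.table(k_dmi=45, k_diq=45)
        assert petisl.rtpr(t, ci_method="none").ratio == 1.0

    def test_infinite_ratio_flagged(self):
        res = petisl.rtpr(self.table(k_dmi=10, k_diq=0))
        assert res.infinite and res.ci_low is None

    def test_method_label_recorded(self):
        res = petisl.rtpr(self.table())
        assert res.method == "paired-score"
        res2 = petisl.rtpr(self.table(), ci_method="katz")
        assert res2.method == "katz-log"


class TestPairedScoreCI:
    TABLE = (20, 10, 5, 25)  # n11, n10, n01, n00

    def test_score_zero_at_mle(self):
        n11, n10, n01, n00 = self.TABLE
        theta_hat = (n11 + n10) / (n11 + n01)
        assert _paired_score_z(theta_hat, *self.TABLE) == pytest.approx(0.0, abs=1e-8)

    def test_restricted_mle_against_grid_oracle(self):
        """SLSQP restricted MLE matches a brute-force grid maximiser."""
        n11, n10, n01, n00 = self.TABLE
        n = sum(self.TABLE)
        theta = 1.5
        best_ll, best = -np.inf, None
        for p11 in np.linspace(1e-6, 0.99, 300):
            for p01 in np.linspace(1e-6, 0.99, 300):
                p10 = theta * (p11 + p01) - p11
                p00 = 1 - p11 - p10 - p01
                if p10 < 0 or p00 < 0:
                    continue
                ll = (n11 * np.log(p11) + n10 * np.log(max(p10, 1e-300))
                      + n01 * np.log(p01) + n00 * np.log(max(p00, 1e-300)))
                if ll > best_ll:
                    best_ll, best = ll, (p10, p01)
        x1, x2 = n11 + n10, n11 + n01
        z_oracle = (x1 - theta * x2) / np.sqrt(n * theta * sum(best))
        assert _paired_score_z(theta, *self.TABLE) == pytest.approx(z_oracle, abs=0.02)

    def test_ci_contains_estimate_and_beats_katz(self):
        n11, n10, n01, n00 = self.TABLE
        n = sum(self.TABLE)
        lo, hi = petisl.paired_ratio_score_ci(*self.TABLE)
        theta_hat = (n11 + n10) / (n11 + n01)
        assert lo < theta_hat < hi
        klo, khi = petisl.katz_ci(n11 + n10, n, n11 + n01, n)
        # positively correlated detections -> paired CI is narrower
        assert (hi - lo) < (khi - klo)


class TestIOA:
    @pytest.mark.parametrize(
        "k, n, pct, lo, hi",
        [
            (53, 60, 88.3, 77.4, 95.2),
            (52, 60, 86.7, 75.4, 94.1),
            (58, 60, 96.7, 88.5, 99.6),
            (56, 60, 93.3, 83.8, 98.2),
        ],
    )
    def test_exact_ci_reproduces_printed_bounds(self, k, n, pct, lo, hi):
        res = petisl.ioa(k, n)
        assert round(res.concordance * 100, 1) == pct
        assert round(res.ci_low * 100, 1) == lo
        assert round(res.ci_high * 100, 1) == hi
        assert res.adequate

    def test_perfect_agreement_boundary(self):
        res = petisl.ioa(60, 60)
        assert res.concordance == 1.0
        assert res.ci_high == pytest.approx(1.0)

    def test_ci_width_shrinks_with_n(self):
        widths = [
            petisl.ioa(int(0.9 * n), n).ci_high - petisl.ioa(int(0.9 * n), n).ci_low
            for n in (20, 60, 200, 1000)
        ]
        assert all(a > b for a, b in zip(widths, widths[1:]))

    def test_guards(self):
        with pytest.raises(ValidationError):
            petisl.ioa(1, 0)
        with pytest.raises(ValidationError):
            petisl.ioa(5, 4)


class TestSampleSize:
    def test_solved_n_power_validated_by_simulation(self):
        """Simulated power at the solved n is within 3% of nominal."""
        res = petisl.sample_size_paired(1.7, 0.20, alpha=0.05, power=0.80)
        assert res.n > 1
        sim = petisl.simulate_mcnemar_power(
            res.n, (res.p11, res.p10, res.p01, res.p00),
            alpha=0.05, n_replicates=4000, seed=7,
        )
        assert sim == pytest.approx(0.80, abs=0.03)

    def test_power_decreases_below_n(self):
        res = petisl.sample_size_paired(1.7, 0.20)
        sim_small = petisl.simulate_mcnemar_power(
            max(res.n - 15, 5), (res.p11, res.p10, res.p01, res.p00),
            n_replicates=4000, seed=7,
        )
        assert sim_small < 0.80

    def test_degenerate_alpha_limit(self):
        """With alpha -> 1 and modest power the requirement collapses."""
        res = petisl.sample_size_paired(1.7, 0.20, alpha=0.999, power=0.5)
        assert res.n == 1

    def test_infeasible_operating_points(self):
        with pytest.raises(InfeasibleError):
            petisl.sample_size_paired(2.0, 0.6)
        with pytest.raises(ValidationError):
            petisl.sample_size_paired(0.9, 0.2)


class TestStrata:
    def test_burden_enumeration(self):
        assert burden_stratum(0) == "M0"
        assert burden_stratum(3) == "OligoM"
        assert burden_stratum(15) == "MultiM"
        with pytest.raises(ValidationError):
            burden_stratum(7)

    def test_stratified_table(self):
        t1 = petisl.DetectionTable.from_counts(
            60, {"DIQ-like": 33, "DMI-like": 59}, bmi_stratum="<=25"
        )
        t2 = petisl.DetectionTable.from_counts(
            60, {"DIQ-like": 29, "DMI-like": 59}, bmi_stratum=">25"
        )
        import pandas as pd

        merged = petisl.DetectionTable(
            df=pd.concat([t1.df, t2.df], ignore_index=True),
            systems=("DIQ-like", "DMI-like"),
        )
        assert petisl.rtpr(merged, ci_method="none", bmi_stratum="<=25").rounded() == 1.79
        assert petisl.rtpr(merged, ci_method="none", bmi_stratum=">25").rounded() == 2.03
        with pytest.raises(ValidationError):
            petisl.detection_rate(merged, "DIQ-like", bmi_stratum="unknown")


class TestReadingSheetEvaluation:
    def test_demo_sheet_reproduces_group_statistics(self):
        sheet = petisl.demo_reading_sheet()
        report = petisl.evaluate_reading_sheet(sheet)
        synth = report["groups"]["synthetic"]
        assert synth["n_lesions"] == 60
        assert synth["detection_rates"]["DMI-like"]["detected"] == 59
        assert synth["detection_rates"]["DIQ-like"]["detected"] == 33
        assert synth["rtpr"]["ratio"] == 1.79
        assert report["ioa"]["DMI-like"]["concordance_pct"] == 88.3
        assert report["ioa"]["DMI-like"]["ci_pct"] == [77.4, 95.2]
        assert report["ioa"]["DIQ-like"]["concordance_pct"] == 86.7
        # TOF system reads hotter -> strictly positive mean RD
        assert synth["rd"]["suv_max"]["mean"] > 0

    def test_or_rule_detects_more(self):
        sheet = petisl.demo_reading_sheet().drop(columns=["consensus"])
        rep_and = petisl.evaluate_reading_sheet(sheet, rule="and")
        rep_or = petisl.evaluate_reading_sheet(sheet, rule="or")
        k_and = rep_and["groups"]["synthetic"]["detection_rates"]["DIQ-like"]["detected"]
        k_or = rep_or["groups"]["synthetic"]["detection_rates"]["DIQ-like"]["detected"]
        assert k_or > k_and
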