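import numpy as np
import pytest

from cvevents.core import Disease, HospitalType
from cvevents.datasets import ADJUDICATION_COUNTS, REVIEW_COUNTS_BY_HOSPITAL
from cvevents.rules import EventKind
from cvevents.validation import (
    AdjudicationRecord,
    CIMethod,
    StratumRule,
    assign_stratum,
    ppv,
    round_half_up,
    stratified_ppv_table,
    unweighted_pooled_ppv,
    weighted_pooled_ppv,
)

from oracles import wald_ci_oracle


class TestPPV:
    @pytest.mark.parametrize(
        "n_true,n_id,want_ppv,want_lo,want_hi",
        [
            (584, 617, 94.7, 92.9, 96.4),
            (51, 121, 42.1, 33.4, 50.9),
            (57, 90, 63.3, 53.4, 73.3),
        ],
    )
    def test_point_estimate_and_wald_interval(self, n_true, n_id, want_ppv, want_lo, want_hi):
        r = ppv(n_true, n_id)
        assert round_half_up(r.ppv_percent) == want_ppv
        assert round_half_up(r.ci_low_percent) == want_lo
        assert round_half_up(r.ci_high_percent) == want_hi

    def test_zero_of_one_is_na(self):
        r = ppv(0, 1)
        assert r.ppv_percent == 0.0 and r.is_na and r.display() == "N/A"

    def test_none_identified_is_na(self):
        r = ppv(0, 0)
        assert r.ppv_percent is None and r.is_na

    def test_perfect_agreement_caps_at_100(self):
        r = ppv(50, 50)
        assert r.ppv_percent == 100.0 and r.ci_high_percent == 100.0

    def test_counts_out_of_order_rejected(self):
        with pytest.raises(ValueError):
            ppv(5, 3)

    def test_scale_free_point_estimate_and_narrowing_ci(self):
        base = ppv(57, 90)
        for k in (2, 5, 10):
            scaled = ppv(57 * k, 90 * k)
            assert scaled.ppv_percent == pytest.approx(base.ppv_percent)
            assert (scaled.ci_high_percent - scaled.ci_low_percent) < (
                base.ci_high_percent - base.ci_low_percent
            )

    def test_wald_matches_hand_computed_interval(self):
        for n_true, n in [(584, 617), (88, 108), (275, 392), (1, 10)]:
            r = ppv(n_true, n)
            lo, hi = wald_ci_oracle(n_true, n)
            assert r.ci_low_percent == pytest.approx(lo, abs=1e-9)
            assert r.ci_high_percent == pytest.approx(hi, abs=1e-9)

    def test_wilson_is_narrower_near_boundary(self):
        wald = ppv(118, 121)
        wilson = ppv(118, 121, method=CIMethod.WILSON)
        assert wilson.ci_high_percent < 100.0
        assert wilson.ci_low_percent < wald.ci_low_percent + 5  # sanity: same scale


class TestAssignStratum:
    def _rec(self, first, highest):
        return AdjudicationRecord(
            "P1", Disease.AMI, EventKind.FIRST, 0, first, highest, True
        )

    def test_first_visit_vs_highest_level(self):
        rec = self._rec(HospitalType.SECONDARY, HospitalType.TERTIARY)
        assert assign_stratum(rec, StratumRule.FIRST_VISIT) == HospitalType.SECONDARY
        assert assign_stratum(rec, StratumRule.HIGHEST_LEVEL) == HospitalType.TERTIARY

    def test_single_hospital_episode_agrees(self):
        rec = self._rec(HospitalType.PRIMARY, HospitalType.PRIMARY)
        assert assign_stratum(rec, StratumRule.FIRST_VISIT) == assign_stratum(
            rec, StratumRule.HIGHEST_LEVEL
        )


class TestPooling:
    def test_unweighted_pool_is_ratio_of_sums(self):
        strata = [
            ppv(*ADJUDICATION_COUNTS[(Disease.AMI, EventKind.FIRST, t)])
            for t in HospitalType
        ]
        pooled = unweighted_pooled_ppv(strata)
        assert pooled.n_adjudicated_true == 974 and pooled.n_identified == 1106
        assert round_half_up(pooled.ppv_percent) == 88.1

    def test_single_stratum_pool_is_identity(self):
        r = ppv(57, 90)
        pooled = unweighted_pooled_ppv([r])
        assert pooled.ppv_percent == pytest.approx(r.ppv_percent)

    def test_empty_strata_pool_is_na(self):
        assert unweighted_pooled_ppv([ppv(0, 0), ppv(0, 0)]).is_na

    def test_weighted_pool_hand_arithmetic(self):
        strata = {
            HospitalType.TERTIARY: ppv(90, 100),
            HospitalType.SECONDARY: ppv(80, 100),
            HospitalType.PRIMARY: ppv(50, 100),
        }
        weights = {
            HospitalType.TERTIARY: 5,
            HospitalType.SECONDARY: 3,
            HospitalType.PRIMARY: 2,
        }
        pooled = weighted_pooled_ppv(strata, weights)
        # (5*90 + 3*80 + 2*50) / 10
        assert pooled.ppv_percent == pytest.approx(79.0)

    def test_equal_weights_give_arithmetic_mean(self):
        strata = {
            HospitalType.TERTIARY: ppv(90, 100),
            HospitalType.SECONDARY: ppv(60, 100),
        }
        pooled = weighted_pooled_ppv(
            strata, {HospitalType.TERTIARY: 1, HospitalType.SECONDARY: 1}
        )
        assert pooled.ppv_percent == pytest.approx(75.0)

    def test_single_positive_weight_degenerates(self):
        strata = {HospitalType.TERTIARY: ppv(90, 100), HospitalType.PRIMARY: ppv(10, 100)}
        pooled = weighted_pooled_ppv(
            strata, {HospitalType.TERTIARY: 4, HospitalType.PRIMARY: 0}
        )
        assert pooled.ppv_percent == pytest.approx(90.0)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            weighted_pooled_ppv(
                {HospitalType.TERTIARY: ppv(9, 10)}, {HospitalType.TERTIARY: 0}
            )

    def test_undefined_stratum_dropped_with_warning(self):
        strata = {HospitalType.TERTIARY: ppv(9, 10), HospitalType.PRIMARY: ppv(0, 0)}
        with pytest.warns(UserWarning, match="undefined"):
            pooled = weighted_pooled_ppv(
                strata, {HospitalType.TERTIARY: 1, HospitalType.PRIMARY: 1}
            )
        assert pooled.ppv_percent == pytest.approx(90.0)

    def test_weighted_pool_bounded_by_strata(self, rng):
        """Pooled value always in [min, max] of the stratum PPVs."""
        for _ in range(200):
            strata, weights = {}, {}
            for t in HospitalType:
                n = int(rng.integers(5, 300))
                k = int(rng.integers(0, n + 1))
                strata[t] = ppv(k, n)
                weights[t] = float(rng.integers(1, 100))
            pooled = weighted_pooled_ppv(strata, weights)
            values = [r.ppv_percent for r in strata.values()]
            assert min(values) - 1e-9 <= pooled.ppv_percent <= max(values) + 1e-9

    def test_published_pooled_values_lie_within_stratum_range(self):
        """Consistency: reported weighted pools fall inside the stratum PPV
        range for each (disease, kind) panel."""
        reported = {
            (Disease.AMI, EventKind.FIRST): (92.0, 92.2),
            (Disease.AMI, EventKind.RECURRENT): (77.8, 78.2),
            (Disease.STROKE, EventKind.FIRST): (88.2, 88.1),
            (Disease.STROKE, EventKind.RECURRENT): (80.8, 81.0),
        }
        for (disease, kind), pooled_values in reported.items():
            strata = [
                ppv(*ADJUDICATION_COUNTS[(disease, kind, t)])
                for t in HospitalType
                if ADJUDICATION_COUNTS[(disease, kind, t)][1] > 1
            ]
            lo = min(r.ppv_percent for r in strata)
            hi = max(r.ppv_percent for r in strata)
            for v in pooled_values:
                assert lo <= v <= hi


class TestStratifiedTable:
    def _records(self):
        recs = []
        i = 0
        for (disease, kind, tier), (n_true, n_id) in ADJUDICATION_COUNTS.items():
            for j in range(n_id):
                recs.append(
                    AdjudicationRecord(
                        f"P{i}", disease, kind, 0, tier, tier, j < n_true
                    )
                )
                i += 1
        return recs

    def test_reproduces_published_panel(self):
        df = stratified_ppv_table(self._records())
        row = df[
            (df.disease == "AMI") & (df.kind == "FIRST") & (df.stratum == "tertiary")
        ].iloc[0]
        assert (row.n_adjudicated_true, row.n_identified) == (584, 617)
        assert row.display == "94.7 (92.9, 96.4)"
        na = df[
            (df.disease == "AMI") & (df.kind == "RECURRENT") & (df.stratum == "primary")
        ].iloc[0]
        assert na.display == "N/A"
        pooled = df[
            (df.disease == "AMI") & (df.kind == "FIRST") & (df.stratum == "pooled")
        ].iloc[0]
        assert pooled.ppv_percent == 88.1

    def test_case_mix_counts_sum_to_reported_totals(self):
        ami = {t: 0 for t in HospitalType}
        stroke = {t: 0 for t in HospitalType}
        for _, tier, n_ami, n_stroke in REVIEW_COUNTS_BY_HOSPITAL:
            ami[tier] += n_ami
            stroke[tier] += n_stroke
        assert sum(ami.values()) + sum(stroke.values()) == 3140


class TestParameterRecovery:
    def test_estimates_cover_configured_ppv(self, rng):
        """Simulated adjudication at a known PPV: estimates near truth and
        the 95% interval covers it most of the time."""
        true_p, n, reps = 0.85, 250, 120
        covered = 0
        est = []
        for _ in range(reps):
            k = int(rng.binomial(n, true_p))
            r = ppv(k, n)
            est.append(r.ppv_percent)
            if r.ci_low_percent <= 100 * true_p <= r.ci_high_percent:
                covered += 1
        assert abs(np.mean(est) - 85.0) < 1.0
        assert covered / reps >= 0.90
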