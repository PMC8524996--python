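"""Metric panel, pooling, ratios, eligibility cascade, cohort summary."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cadeval.classify import CaseOutcome, ImageRecord, LesionTruth, size_bin_of
from cadeval.geometry import BoundingBox
from cadeval.metrics import (
    ConfusionCounts,
    LesionCandidate,
    MetricSet,
    cohort_summary,
    confusion,
    eligibility_filter,
    metric_set,
    pooled_metrics,
    ratio_report,
    round_half_up,
)

STATES = ("TP", "FN", "TN", "FP")


def _outcomes_from_states(states):
    return [
        CaseOutcome(f"i{k}", s, 1 if s == "FP" else 0) for k, s in enumerate(states)
    ]


class TestConfusion:
    def test_perfect_reader(self):
        outs = _outcomes_from_states(["TP"] * 59 + ["TN"] * 253)
        assert confusion(outs) == ConfusionCounts(59, 0, 253, 0)

    def test_all_missed(self):
        assert confusion(_outcomes_from_states(["FN"] * 59)) == ConfusionCounts(
            0, 59, 0, 0
        )

    @given(
        states=st.lists(st.sampled_from(STATES), min_size=1, max_size=200)
    )
    def test_matches_independent_recount(self, states):
        cnt = confusion(_outcomes_from_states(states))
        assert (cnt.tp, cnt.fn, cnt.tn, cnt.fp) == tuple(
            sum(1 for s in states if s == t) for t in STATES
        )
        assert cnt.total == len(states)


class TestMetricSet:
    def test_hand_evaluated_panel(self):
        ms = metric_set(ConfusionCounts(39, 20, 243, 10))
        assert ms.sensitivity == pytest.approx(0.661, abs=5e-4)
        assert ms.specificity == pytest.approx(0.960, abs=5e-4)
        assert ms.accuracy == pytest.approx(0.904, abs=5e-4)
        assert ms.ppv == pytest.approx(0.796, abs=5e-4)
        assert ms.npv == pytest.approx(0.924, abs=5e-4)

    def test_zero_denominator_flags_undefined(self):
        ms = metric_set(ConfusionCounts(0, 0, 10, 0))
        assert ms.sensitivity is None
        assert ms.specificity == 1.0
        assert ms.ppv is None

    def test_all_correct(self):
        ms = metric_set(ConfusionCounts(5, 0, 7, 0))
        assert (
            ms.sensitivity == ms.specificity == ms.accuracy == ms.ppv == ms.npv == 1.0
        )

    def test_empty_total_is_an_error(self):
        with pytest.raises(ValueError):
            metric_set(ConfusionCounts(0, 0, 0, 0))

    @given(states=st.lists(st.sampled_from(STATES), min_size=1, max_size=100))
    def test_accuracy_identity(self, states):
        cnt = confusion(_outcomes_from_states(states))
        ms = metric_set(cnt)
        assert ms.accuracy == pytest.approx((cnt.tp + cnt.tn) / len(states))


class TestPooling:
    def _outcomes(self, states):
        return _outcomes_from_states(states)

    def test_identical_readers_pool_to_the_same_panel(self):
        states = ["TP", "FN", "TN", "FP", "TN"]
        outcomes = {
            (r, a): self._outcomes(states)
            for r in ("r1", "r2")
            for a in ("pre_cad", "post_cad")
        }
        pooled = pooled_metrics(outcomes, {"r1": "g", "r2": "g"})
        assert pooled.overall["pre_cad"] == pooled.per_reader[("r1", "pre_cad")]

    def test_pooled_counts_are_sums(self):
        o1 = self._outcomes(["TP", "TN", "TN"])
        o2 = self._outcomes(["FN", "FP", "TN"])
        outcomes = {
            ("r1", "pre_cad"): o1,
            ("r1", "post_cad"): o1,
            ("r2", "pre_cad"): o2,
            ("r2", "post_cad"): o2,
        }
        pooled = pooled_metrics(outcomes, {"r1": "g", "r2": "g"})
        assert pooled.overall_counts["pre_cad"] == confusion(o1) + confusion(o2)

    def test_mismatched_image_sets_rejected(self):
        outcomes = {
            ("r1", "pre_cad"): self._outcomes(["TP"]),
            ("r1", "post_cad"): self._outcomes(["TP"]),
            ("r2", "pre_cad"): self._outcomes(["TP", "TN"]),
            ("r2", "post_cad"): self._outcomes(["TP", "TN"]),
        }
        with pytest.raises(ValueError, match="image sets"):
            pooled_metrics(outcomes, {"r1": "g", "r2": "g"})

    def test_case_conservation_per_arm(self, default_study):
        from cadeval.evaluate import reader_outcomes

        outs = reader_outcomes(default_study.images, default_study.sessions)
        n_mal = sum(im.label == "malignant" for im in default_study.images)
        n_nor = len(default_study.images) - n_mal
        for key, olist in outs.items():
            cnt = confusion(olist)
            assert cnt.tp + cnt.fn == n_mal, key
            assert cnt.tn + cnt.fp == n_nor, key


class TestRatioReport:
    def test_printed_style_ratios(self):
        pre = MetricSet(0.49, 0.96, 0.87, 0.75, 0.89)
        post = MetricSet(0.60, 0.97, 0.90, 0.81, 0.91)
        ratios = ratio_report(pre, post)
        assert ratios["sensitivity"] == 1.22
        assert ratios["accuracy"] == 1.03
        assert ratios["npv"] == 1.02

    def test_identical_arms_give_unity(self):
        ms = MetricSet(0.5, 0.9, 0.8, 0.7, 0.85)
        assert all(v == 1.00 for v in ratio_report(ms, ms).values())

    def test_undefined_metric_propagates(self):
        pre = MetricSet(None, 0.9, 0.8, 0.7, 0.85)
        post = MetricSet(0.6, 0.9, 0.8, 0.7, 0.85)
        assert ratio_report(pre, post)["sensitivity"] is None

    def test_rounding_is_half_up(self):
        assert round_half_up(1.225, 2) == 1.23
        assert round_half_up(0.115, 2) == 0.12


def _candidates(n_meta, n_mass, n_shape, n_invisible, n_clean):
    cands = []
    k = 0
    for _ in range(n_meta):
        cands.append(LesionCandidate(f"c{k}", True, 20, True, True)); k += 1
    for _ in range(n_mass):
        cands.append(LesionCandidate(f"c{k}", False, 40, True, True)); k += 1
    for _ in range(n_shape):
        cands.append(LesionCandidate(f"c{k}", False, 20, False, True)); k += 1
    for _ in range(n_invisible):
        cands.append(LesionCandidate(f"c{k}", False, 20, True, False)); k += 1
    for _ in range(n_clean):
        cands.append(LesionCandidate(f"c{k}", False, 20, True, True)); k += 1
    return cands


class TestEligibility:
    def test_cascade_counts(self, rng):
        cands = _candidates(8, 44, 4, 7, 59)
        cands = [cands[i] for i in rng.permutation(len(cands))]
        retained, report = eligibility_filter(cands)
        assert report.collected == 122
        assert report.excluded_metastasis == 8
        assert report.excluded_over_30mm == 44
        assert report.excluded_non_nodular == 4
        assert report.excluded_not_visible == 7
        assert report.remaining == len(retained) == 59

    def test_first_failing_criterion_wins(self):
        # metastasis that is also a mass: counted once, as a metastasis
        c = LesionCandidate("x", True, 40, False, False)
        _, report = eligibility_filter([c])
        assert report.excluded_metastasis == 1
        assert report.excluded_over_30mm == 0

    def test_oversize_excluded(self):
        _, report = eligibility_filter([LesionCandidate("x", False, 35, True, True)])
        assert report.excluded_over_30mm == 1

    def test_sub5mm_ggn_counts_as_not_visible(self):
        c = LesionCandidate("x", False, 4, True, True, is_ggn_under_5mm=True)
        _, report = eligibility_filter([c])
        assert report.excluded_not_visible == 1

    def test_empty_input(self):
        retained, report = eligibility_filter([])
        assert retained == [] and report.collected == report.remaining == 0

    @given(
        flags=st.lists(
            st.tuples(st.booleans(), st.floats(5, 60), st.booleans(), st.booleans()),
            max_size=60,
        )
    )
    def test_conservation(self, flags):
        cands = [
            LesionCandidate(f"c{i}", m, s, nod, vis)
            for i, (m, s, nod, vis) in enumerate(flags)
        ]
        retained, report = eligibility_filter(cands)
        total_excluded = (
            report.excluded_metastasis
            + report.excluded_over_30mm
            + report.excluded_non_nodular
            + report.excluded_not_visible
        )
        assert len(retained) + total_excluded == len(cands)


def _cohort(bin_counts, vendors_mal, vendors_nor):
    images = []
    k = 0
    sizes = {"<=10": 8.0, "11-20": 15.0, "21-30": 25.0}
    vm = [v for v, n in vendors_mal.items() for _ in range(n)]
    for bin_name, n in bin_counts.items():
        for _ in range(n):
            image_id = f"M{k:03d}"
            images.append(
                ImageRecord(
                    image_id=image_id,
                    label="malignant",
                    vendor=vm[k],
                    lesion=LesionTruth(
                        image_id=image_id,
                        box=BoundingBox(0, 0, 50, 50),
                        size_mm=sizes[bin_name],
                        size_bin=bin_name,
                        laterality="right",
                        location="upper",
                    ),
                )
            )
            k += 1
    j = 0
    for v, n in vendors_nor.items():
        for _ in range(n):
            images.append(ImageRecord(image_id=f"N{j:03d}", label="normal", vendor=v))
            j += 1
    return images


class TestCohortSummary:
    def test_size_bin_percentages(self):
        images = _cohort(
            {"<=10": 7, "11-20": 33, "21-30": 19},
            {"FUJIFILM": 6, "KONICA": 31, "Philips": 22},
            {"FUJIFILM": 83, "KONICA": 82, "Philips": 88},
        )
        summary = cohort_summary(images)
        assert summary.size_bins["<=10"] == (7, 12)
        assert summary.size_bins["11-20"] == (33, 56)
        assert summary.size_bins["21-30"] == (19, 32)

    def test_vendor_malignant_fraction(self):
        images = _cohort(
            {"11-20": 59},
            {"FUJIFILM": 6, "KONICA": 31, "Philips": 22},
            {"FUJIFILM": 83, "KONICA": 82, "Philips": 88},
        )
        summary = cohort_summary(images)
        assert summary.vendors["FUJIFILM"] == (6, 89, 7)
        assert summary.vendors["KONICA"] == (31, 113, 27)
        assert summary.vendors["Philips"] == (22, 110, 20)

    def test_empty_cohort(self):
        summary = cohort_summary([])
        assert summary.n_images == 0
        assert all(pct is None for _, pct in summary.size_bins.values())

    def test_percentages_sum_to_about_100(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 60))
            bins = rng.multinomial(n, [0.3, 0.4, 0.3])
            images = _cohort(
                dict(zip(("<=10", "11-20", "21-30"), map(int, bins))),
                {"FUJIFILM": n},
                {"KONICA": 5},
            )
            summary = cohort_summary(images)
            total = sum(pct for _, pct in summary.size_bins.values())
            assert abs(total - 100) <= 1
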