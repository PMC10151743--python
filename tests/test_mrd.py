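"""Marker calling, MRD quantification, overlap and tracking."""

import pytest

from dnjstem.evolution import EvolutionCall
from dnjstem.io import DJ, VJ, QcNormalization
from dnjstem.mrd import (MarkerPolicy, call_marker, compare_compartments,
                         cross_patient_specificity, quantify_mrd,
                         track_longitudinal)
from dnjstem.pipeline import AnalysisParams, analyze_sample
from dnjstem.simulate import SimulationConfig, simulate_cohort
from dnjstem.stems import group_by_stem
from dnjstem.validation import strip_anatomy

from conftest import make_clonotype, make_repertoire

QC = QcNormalization(available=True, cells_per_read=0.05)
NO_QC = QcNormalization(available=False)
STABLE = EvolutionCall(call="stable", evidence={}, policy_id="x")
EVOLVING = EvolutionCall(call="evolving", evidence={}, policy_id="x")

SHARED = dict(d_part="GACTACGG", n2="ATCG", j_part="CTAACCATTCGTGT")


def _family_at(percent: float, total: int = 10_000):
    reads = int(round(percent / 100 * total))
    fam_member = make_clonotype("m1", reads=reads, **SHARED)
    filler = make_clonotype("bg", n1="AAAA", n2="GGCC", reads=total - reads,
                            v_call="TVH05", d_part="GACTACGG",
                            j_part="CTAACCATTCGTGT")
    rep = make_repertoire([fam_member, filler])
    fam = [f for f in group_by_stem(rep)
           if f.members[0].clonotype_id == "m1"][0]
    return fam


class TestCallMarker:
    def test_stable_family_over_reads_threshold(self):
        call = call_marker(_family_at(6.2), STABLE, NO_QC)
        assert call.is_marker and call.criteria_fired == {"reads_threshold"}

    def test_evolving_family_at_any_abundance(self):
        call = call_marker(_family_at(0.3), EVOLVING, NO_QC)
        assert call.is_marker and call.criteria_fired == {"evolving"}
        assert call.would_conventional_miss

    def test_stable_below_threshold_without_qc_is_not_marker(self):
        call = call_marker(_family_at(4.9), STABLE, NO_QC)
        assert not call.is_marker

    def test_cells_threshold_fires_with_qc(self):
        call = call_marker(_family_at(2.0), STABLE, QC)
        assert call.is_marker and call.criteria_fired == {"cells_threshold"}

    def test_marker_monotone_in_summed_abundance(self):
        policy = MarkerPolicy()
        was_marker = False
        for pct in [0.5, 2.0, 5.0, 20.0, 60.0]:
            now = call_marker(_family_at(pct), STABLE, QC, policy).is_marker
            assert now or not was_marker
            was_marker = now


class TestQuantifyMrd:
    def _followup(self, member_reads, total=1000):
        members = [make_clonotype(f"m{i}", n1="T" * i, reads=r, **SHARED)
                   for i, r in enumerate(member_reads)]
        filler = make_clonotype("bg", n1="AAAA", n2="GGCC",
                                reads=total - sum(member_reads),
                                d_part="GACTACGG", j_part="CTAACCATTCGTGT")
        return make_repertoire(members + [filler], timepoint="day6"), members

    def test_stem_is_the_sum_of_detected_members(self):
        followup, members = self._followup([20, 5, 1])
        stem = "CGGATCGCTAACCATTCGTGT"
        m = quantify_mrd(stem, followup, NO_QC,
                         diagnostic_top_junction=members[0].junction)
        assert m.stem_percent_reads == pytest.approx(2.6)
        assert m.top_member_percent_reads == pytest.approx(2.0)
        assert m.stem_percent_reads / m.top_member_percent_reads == pytest.approx(1.3)
        assert m.n_members_detected == 3

    def test_absent_stem_is_untraceable_zero(self):
        followup, _ = self._followup([10])
        m = quantify_mrd("TTTTTTTTTTTTTTTTTTTTT", followup, NO_QC)
        assert not m.traceable and m.stem_percent_reads == 0.0

    def test_stem_at_least_top_member_always(self):
        followup, members = self._followup([7, 3, 2, 1])
        stem = "CGGATCGCTAACCATTCGTGT"
        m = quantify_mrd(stem, followup, QC,
                         diagnostic_top_junction=members[0].junction)
        assert m.stem_percent_reads >= m.top_member_percent_reads
        assert m.stem_percent_cells == pytest.approx(m.stem_percent_reads)

    def test_zero_depth_followup_rejected(self):
        followup, _ = self._followup([10])
        followup.clonotypes = []
        with pytest.raises(ValueError, match="zero usable reads"):
            quantify_mrd("ACGT", followup, NO_QC)


def _analyzed(rep, dj=None):
    return analyze_sample(rep, dj, params=AnalysisParams())


class TestCompareCompartments:
    def _bm_pb(self, seed=3):
        data = simulate_cohort(SimulationConfig(seed=seed, n_patients=2,
                                                scenario="bm_pb_pair"))
        pid = "P001"
        bm = _analyzed(strip_anatomy(data.samples[(f"{pid}-BM-day0", VJ)]),
                       strip_anatomy(data.samples[(f"{pid}-BM-day0", DJ)]))
        pb = _analyzed(strip_anatomy(data.samples[(f"{pid}-PB-day0", VJ)]),
                       strip_anatomy(data.samples[(f"{pid}-PB-day0", DJ)]))
        return bm, pb

    def test_identical_samples_overlap_fully(self):
        data = simulate_cohort(SimulationConfig(seed=2, n_patients=1))
        vj = data.samples[("P001-BM-day0", VJ)]
        dj = data.samples[("P001-BM-day0", DJ)]
        bm = _analyzed(strip_anatomy(vj), strip_anatomy(dj))
        pb = _analyzed(strip_anatomy(vj), strip_anatomy(dj))
        overlap = compare_compartments(bm, pb)
        assert not overlap.detectable_both_marker_one
        assert not overlap.one_compartment_only
        assert all(v == pytest.approx(1.0) for v in overlap.member_overlap.values())
        assert all(overlap.evolution_concordant.values())

    def test_subsampled_pb_loses_members_not_abundant_stems(self):
        bm, pb = self._bm_pb()
        overlap = compare_compartments(bm, pb)
        # high-abundance stems stay markers in both compartments
        assert len(overlap.marker_both) >= 1
        if overlap.member_overlap:
            assert min(overlap.member_overlap.values()) < 1.0

    def test_patient_mismatch_rejected(self):
        data = simulate_cohort(SimulationConfig(seed=2, n_patients=2))
        a = _analyzed(strip_anatomy(data.samples[("P001-BM-day0", VJ)]))
        b = _analyzed(strip_anatomy(data.samples[("P002-BM-day0", VJ)]))
        with pytest.raises(ValueError, match="patient mismatch"):
            compare_compartments(a, b)

    def test_category_counts_symmetric_under_swap(self):
        bm, pb = self._bm_pb()
        fwd = compare_compartments(bm, pb)
        rev = compare_compartments(pb, bm)
        assert len(fwd.marker_both) == len(rev.marker_both)
        assert (len(fwd.detectable_both_marker_one)
                + len(fwd.one_compartment_only)) == \
               (len(rev.detectable_both_marker_one)
                + len(rev.one_compartment_only))


class TestTrackLongitudinal:
    def test_killed_top_member_flagged_and_stem_traceable(self):
        from dnjstem.validation import mrd_invariant_check

        result = mrd_invariant_check(2)
        assert result["sum_violations"] == 0
        assert result["killed_total"] > 0
        assert result["killed_ok"] == result["killed_total"]
        assert result["min_ratio"] >= 1.0

    def test_stable_top_produces_no_flags(self):
        diag_members = [make_clonotype("m1", reads=500, **SHARED),
                        make_clonotype("m2", n1="TT", reads=100, **SHARED)]
        filler = make_clonotype("bg", n1="AAAA", n2="GGCC", reads=9400,
                                d_part="GACTACGG", j_part="CTAACCATTCGTGT")
        diag = _analyzed(make_repertoire(diag_members + [filler]))
        fu_members = [make_clonotype("f1", reads=50, **SHARED),
                      make_clonotype("f2", n1="TT", reads=10, **SHARED)]
        fu_filler = make_clonotype("bg2", n1="AAAA", n2="GGCC", reads=940,
                                   d_part="GACTACGG", j_part="CTAACCATTCGTGT")
        followup = make_repertoire(fu_members + [fu_filler], timepoint="day6")
        reports = track_longitudinal(diag, [followup])
        target = [r for r in reports
                  if r.stem_id.endswith("CTAACCATTCGTGT")
                  and "ATCG" in r.stem_id][0]
        assert not target.flags
        assert "report_sum" in target.recommendation_codes

    def test_vanished_stem_untraceable(self):
        diag_members = [make_clonotype("m1", reads=5000, **SHARED)]
        filler = make_clonotype("bg", n1="AAAA", n2="GGCC", reads=5000,
                                d_part="GACTACGG", j_part="CTAACCATTCGTGT")
        diag = _analyzed(make_repertoire(diag_members + [filler]))
        followup = make_repertoire(
            [make_clonotype("bg2", n1="AAAA", n2="GGCC", reads=1000,
                            d_part="GACTACGG", j_part="CTAACCATTCGTGT")],
            timepoint="day6")
        reports = track_longitudinal(diag, [followup])
        target = [r for r in reports if "ATCG" in r.stem_id][0]
        assert "stem_untraceable" in target.flags


class TestCrossPatientSpecificity:
    def test_unique_stems_give_empty_report(self):
        assert cross_patient_specificity(
            {"P1": {"AAAA"}, "P2": {"CCCC"}}) == []

    def test_planted_shared_stem_reported_once(self):
        shared = cross_patient_specificity(
            {"P1": {"AAAA", "GGGG"}, "P2": {"AAAA"}, "P3": {"TTTT"}})
        assert shared == [("AAAA", ["P1", "P2"])]

    def test_default_cohort_has_no_shared_marker_stems(self):
        data = simulate_cohort(SimulationConfig(seed=4, n_patients=6))
        per_patient = {}
        for pid in sorted({s.patient_id for s in data.truth.stems}):
            a = _analyzed(strip_anatomy(data.samples[(f"{pid}-BM-day0", VJ)]),
                          strip_anatomy(data.samples[(f"{pid}-BM-day0", DJ)]))
            per_patient[pid] = set(a.marker_stems(VJ)) | set(a.marker_stems(DJ))
        assert cross_patient_specificity(per_patient) == []
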