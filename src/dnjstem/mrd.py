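"""Marker calling, MRD quantification, compartment overlap and tracking.

A *marker DNJ-stem* is usable as an MRD target when either (i) the
summed abundance of all family members reaches 5% of usable reads or 1%
of cell equivalents, or (ii) the stem shows clonal evolution at *any*
abundance.  Conventional marker screening follows single clonotypes at a
5%-reads threshold; ``would_conventional_miss`` records markers that the
conventional approach would not have reported.

MRD quantification in follow-up samples searches for family members at
any abundance (the noise floor is an evolution-calling device only) by
exact junction-suffix matching against the diagnostic stem, and reports
both the stem-summed abundance and the diagnostic top member's own
abundance; the sum avoids underestimating MRD when the clonotypic
composition shifts under therapy.

Cell-equivalent abundances use the cIT-QC conversion factor.  With the
sample's total cell equivalents taken as usable_reads x cells_per_read,
percentages of cells coincide numerically with percentages of reads; the
cells criterion therefore acts as a 1%-reads floor whenever QC is
available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .evolution import EvolutionCall
from .io import QcNormalization, SampleRepertoire, abundance_percent
from .stems import StemFamily

__all__ = [
    "MarkerPolicy",
    "MarkerCall",
    "MrdMeasurement",
    "TrackingReport",
    "CompartmentOverlap",
    "call_marker",
    "quantify_mrd",
    "compare_compartments",
    "track_longitudinal",
    "cross_patient_specificity",
]

CONVENTIONAL_THRESHOLD = 5.0  # % usable reads, single clonotype


@dataclass(frozen=True)
class MarkerPolicy:
    min_percent_reads: float = 5.0   # summed over the family
    min_percent_cells: float = 1.0   # summed, in cell equivalents
    evolving_at_any_abundance: bool = True

    def __post_init__(self) -> None:
        if self.min_percent_reads <= 0 or self.min_percent_cells <= 0:
            raise ValueError("marker thresholds must be strictly positive")


@dataclass
class MarkerCall:
    stem_id: str
    is_marker: bool
    criteria_fired: Set[str]
    would_conventional_miss: bool


@dataclass
class MrdMeasurement:
    stem_id: str
    timepoint_label: str
    stem_percent_reads: float
    top_member_percent_reads: float
    top_member_id: Optional[str]
    n_members_detected: int
    traceable: bool
    stem_percent_cells: Optional[float] = None


@dataclass
class TrackingReport:
    stem_id: str
    measurements: List[MrdMeasurement]
    flags: Set[str] = field(default_factory=set)
    recommendation_codes: Set[str] = field(default_factory=set)


def call_marker(family: StemFamily, evolution: EvolutionCall,
                qc: QcNormalization, policy: MarkerPolicy = MarkerPolicy()
                ) -> MarkerCall:
    """Marker decision for one stem family.

    Criteria are evaluated on the summed family abundance; the cells
    criterion is skipped when QC normalization is unavailable.
    """
    fired: Set[str] = set()
    if family.total_percent >= policy.min_percent_reads:
        fired.add("reads_threshold")
    if qc.available:
        # %cells == %reads under the usable_reads x cells_per_read denominator
        if family.total_percent >= policy.min_percent_cells:
            fired.add("cells_threshold")
    if policy.evolving_at_any_abundance and evolution.is_evolving:
        fired.add("evolving")
    top_percent = family.total_percent * family.top_member.read_count / family.total_reads
    return MarkerCall(
        stem_id=family.stem_str,
        is_marker=bool(fired),
        criteria_fired=fired,
        would_conventional_miss=bool(fired) and top_percent < CONVENTIONAL_THRESHOLD,
    )


def find_stem_members(stem: str, rep: SampleRepertoire):
    """All clonotypes whose junction ends with the stem (any abundance)."""
    return [c for c in rep.clonotypes if c.junction.endswith(stem)]


def quantify_mrd(stem: str, followup: SampleRepertoire, qc: QcNormalization,
                 diagnostic_top_junction: Optional[str] = None) -> MrdMeasurement:
    """Stem-level and top-member-level MRD in one follow-up sample.

    Members are searched at any abundance.  The diagnostic top member is
    located by exact junction identity; its abundance is 0 when absent.
    """
    if followup.usable_reads <= 0:
        raise ValueError(
            f"{followup.sample_id}: zero usable reads — cannot quantify MRD"
        )
    members = find_stem_members(stem, followup)
    stem_reads = sum(c.read_count for c in members)
    stem_pct = abundance_percent(stem_reads, followup) if stem_reads else 0.0
    top_pct, top_id = 0.0, None
    if diagnostic_top_junction is not None:
        for c in members:
            if c.junction == diagnostic_top_junction:
                top_pct = abundance_percent(c.read_count, followup)
                top_id = c.clonotype_id
                break
    return MrdMeasurement(
        stem_id=stem,
        timepoint_label=followup.meta.timepoint_label,
        stem_percent_reads=stem_pct,
        top_member_percent_reads=top_pct,
        top_member_id=top_id,
        n_members_detected=len(members),
        traceable=len(members) > 0,
        stem_percent_cells=stem_pct if qc.available else None,
    )


# -- compartment comparison ------------------------------------------------

@dataclass
class CompartmentOverlap:
    patient_id: str
    marker_both: List[str]
    detectable_both_marker_one: List[str]
    one_compartment_only: List[str]
    member_overlap: Dict[str, float]          # per stem evolving in both
    evolution_concordant: Dict[str, bool]     # per stem detectable in both


def compare_compartments(bm, pb) -> CompartmentOverlap:
    """Overlap of marker stems and their family members between BM and PB.

    ``bm`` and ``pb`` are :class:`~dnjstem.pipeline.SampleAnalysis`
    objects of the same patient/timepoint.  Member-level overlap (shared
    member junctions over the union) is computed for stems evolving in
    both compartments, searching members at any abundance.
    """
    if bm.patient_id != pb.patient_id:
        raise ValueError(f"patient mismatch: {bm.patient_id} vs {pb.patient_id}")

    marker_both: List[str] = []
    detectable_one: List[str] = []
    only_one: List[str] = []
    member_overlap: Dict[str, float] = {}
    concordant: Dict[str, bool] = {}

    stems = sorted(set(bm.marker_stems()) | set(pb.marker_stems()))
    for stem in stems:
        in_bm = bm.is_marker(stem)
        in_pb = pb.is_marker(stem)
        if in_bm and in_pb:
            marker_both.append(stem)
        else:
            present, absent = (bm, pb) if in_bm else (pb, bm)
            if absent.stem_detectable(stem):
                detectable_one.append(stem)
            else:
                only_one.append(stem)

        rec_bm, rec_pb = bm.get_record(stem), pb.get_record(stem)
        if rec_bm is not None and rec_pb is not None:
            e_bm, e_pb = rec_bm.evolution.is_evolving, rec_pb.evolution.is_evolving
            concordant[stem] = e_bm == e_pb
            if e_bm and e_pb:
                mem_bm = {c.junction for c in find_stem_members(stem, bm.rep)}
                mem_pb = {c.junction for c in find_stem_members(stem, pb.rep)}
                union = mem_bm | mem_pb
                member_overlap[stem] = len(mem_bm & mem_pb) / len(union) if union else 0.0

    return CompartmentOverlap(
        patient_id=bm.patient_id,
        marker_both=marker_both,
        detectable_both_marker_one=detectable_one,
        one_compartment_only=only_one,
        member_overlap=member_overlap,
        evolution_concordant=concordant,
    )


# -- longitudinal tracking -------------------------------------------------

FOLLOW_STEM = "follow_stem_not_member"
FOLLOW_BOTH = "follow_both_libraries"
REPORT_SUM = "report_sum"


def track_longitudinal(diagnostic, followups: Sequence[SampleRepertoire],
                       qcs: Optional[Sequence[QcNormalization]] = None
                       ) -> List[TrackingReport]:
    """Track every diagnostic marker stem across ordered follow-up samples.

    ``diagnostic`` is a :class:`~dnjstem.pipeline.SampleAnalysis`;
    follow-ups are repertoires ordered by time (ordering is taken from
    the caller/metadata, never inferred from labels).
    """
    if not followups:
        raise ValueError("need at least one follow-up sample")
    if qcs is None:
        from .io import normalization_factor
        qcs = [normalization_factor(f) for f in followups]

    reports: List[TrackingReport] = []
    for stem in diagnostic.marker_stems():
        rec = diagnostic.get_record(stem)
        diag_top = rec.family.top_member
        diag_junctions = {c.junction for c in rec.family.members}
        measurements = [
            quantify_mrd(stem, f, qc, diagnostic_top_junction=diag_top.junction)
            for f, qc in zip(followups, qcs)
        ]
        flags: Set[str] = set()
        if all(not m.traceable for m in measurements):
            flags.add("stem_untraceable")
        for m, f in zip(measurements, followups):
            members = find_stem_members(stem, f)
            top_here = next((c for c in members if c.junction == diag_top.junction), None)
            others = [c for c in members if c.junction != diag_top.junction]
            if top_here is None and others:
                flags.add("top_member_vanished")
            if top_here is not None and any(c.read_count > top_here.read_count for c in others):
                flags.add("top_member_displaced")
            if any(c.junction not in diag_junctions for c in members):
                flags.add("new_members_emerged")

        codes: Set[str] = {REPORT_SUM}
        if rec.evolution.is_evolving:
            codes.add(FOLLOW_STEM)
        if rec.family.rooted:
            codes.add(FOLLOW_BOTH)
        reports.append(TrackingReport(stem_id=stem, measurements=measurements,
                                      flags=flags, recommendation_codes=codes))
    return reports


def cross_patient_specificity(patient_marker_stems: Dict[str, Set[str]]
                              ) -> List[Tuple[str, List[str]]]:
    """Marker stems appearing in more than one patient.

    Input maps patient id to its set of marker stem strings; output lists
    (stem, sorted patient ids) for every stem shared by >= 2 patients.
    """
    seen: Dict[str, List[str]] = {}
    for patient, stems in patient_marker_stems.items():
        for s in stems:
            seen.setdefault(s, []).append(patient)
    shared = [(s, sorted(ps)) for s, ps in seen.items() if len(set(ps)) > 1]
    shared.sort()
    return shared
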