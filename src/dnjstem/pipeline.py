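"""End-to-end orchestration: repertoires → stems → calls → reports.

One :class:`SampleAnalysis` holds everything derived from one sample's
two amplicon libraries: the stem families per library, their noise
metrics, evolution calls, mechanism calls (for evolving families),
rooted flags and marker calls.  :func:`analyze_sample` is the single
entry point used by the CLI, the validation harness and the tests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .evolution import (ConsensusPolicy, EvolutionCall, NoisePolicy,
                        analyze_family_noise, call_evolution, FamilyMetrics)
from .io import (DJ, VJ, Clonotype, QcNormalization, SampleMeta,
                 SampleRepertoire, normalization_factor, read_airr_sample,
                 read_metadata, write_reports)
from .locus import LocusCatalog, toy_catalog
from .mechanism import MechanismPolicy, StemMechanismCall, classify_family
from .mrd import MarkerCall, MarkerPolicy, call_marker
from .stats import PatientResult
from .stems import (DecompositionParams, StemFamily, annotate_repertoire,
                    detect_root, group_by_stem)

__all__ = [
    "AnalysisParams",
    "StemRecord",
    "SampleAnalysis",
    "analyze_sample",
    "analyze_cohort_dir",
    "patient_results",
    "run_manifest",
]


@dataclass(frozen=True)
class AnalysisParams:
    """All tunables of the analysis, serializable to one config file."""

    decomposition: DecompositionParams = DecompositionParams()
    noise: NoisePolicy = NoisePolicy()
    consensus: ConsensusPolicy = ConsensusPolicy()
    mechanism: MechanismPolicy = MechanismPolicy()
    marker: MarkerPolicy = MarkerPolicy()

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisParams":
        raw = json.loads(text)
        return cls(
            decomposition=DecompositionParams(**raw.get("decomposition", {})),
            noise=NoisePolicy(**raw.get("noise", {})),
            consensus=ConsensusPolicy(**raw.get("consensus", {})),
            mechanism=MechanismPolicy(**raw.get("mechanism", {})),
            marker=MarkerPolicy(**raw.get("marker", {})),
        )

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


@dataclass
class StemRecord:
    """One stem family with every call attached."""

    family: StemFamily
    kept: List[Clonotype]
    removed: List[Clonotype]
    metrics: FamilyMetrics
    evolution: EvolutionCall
    marker: MarkerCall
    mechanism: Optional[StemMechanismCall] = None


@dataclass
class SampleAnalysis:
    """All per-stem records of one sample (both libraries)."""

    sample_id: str
    patient_id: str
    compartment: str
    timepoint_label: str
    rep: SampleRepertoire                  # the VJ repertoire
    dj_rep: Optional[SampleRepertoire]
    records: Dict[Tuple[str, str], StemRecord]  # (library, stem) -> record
    qc: QcNormalization

    def library_records(self, library: str) -> List[StemRecord]:
        return [r for (lib, _), r in self.records.items() if lib == library]

    def get_record(self, stem: str, library: str = VJ) -> Optional[StemRecord]:
        return self.records.get((library, stem))

    def marker_stems(self, library: str = VJ) -> List[str]:
        return sorted(stem for (lib, stem), r in self.records.items()
                      if lib == library and r.marker.is_marker)

    def is_marker(self, stem: str, library: str = VJ) -> bool:
        r = self.records.get((library, stem))
        return bool(r and r.marker.is_marker)

    def stem_detectable(self, stem: str, library: str = VJ) -> bool:
        rep = self.rep if library == VJ else self.dj_rep
        if rep is None:
            return False
        return any(c.junction.endswith(stem) for c in rep.clonotypes)

    def has_evolving(self) -> bool:
        return any(r.evolution.is_evolving for r in self.records.values())


def _analyze_library(rep: SampleRepertoire, catalog: LocusCatalog,
                     params: AnalysisParams) -> List[StemRecord]:
    annotate_repertoire(rep, catalog, params.decomposition)
    families = group_by_stem(rep)
    qc = normalization_factor(rep)
    records: List[StemRecord] = []
    for fam in families:
        kept, removed, metrics = analyze_family_noise(fam, params.noise, rep)
        evolution = call_evolution(metrics, params.consensus)
        marker = call_marker(fam, evolution, qc, params.marker)
        records.append(StemRecord(family=fam, kept=kept, removed=removed,
                                  metrics=metrics, evolution=evolution,
                                  marker=marker))
    return records


def analyze_sample(vj_rep: SampleRepertoire,
                   dj_rep: Optional[SampleRepertoire],
                   catalog: Optional[LocusCatalog] = None,
                   params: AnalysisParams = AnalysisParams()) -> SampleAnalysis:
    """Full per-sample analysis across both amplicon libraries.

    Decomposes junctions, groups stem families, applies the noise filter
    and evolution consensus per library, flags rooted stems across
    libraries, classifies the mechanism of evolving families (with the
    DJ root as erosion reference where rooted) and calls markers.
    """
    catalog = catalog or toy_catalog()
    vj_records = _analyze_library(vj_rep, catalog, params)
    dj_records = _analyze_library(dj_rep, catalog, params) if dj_rep is not None else []

    detect_root([r.family for r in vj_records], [r.family for r in dj_records])
    dj_by_stem = {r.family.stem_str: r for r in dj_records}

    for rec in vj_records + dj_records:
        if not rec.evolution.is_evolving:
            continue
        dj_root = None
        if rec.family.library == VJ and rec.family.rooted:
            dj_fam = dj_by_stem.get(rec.family.stem_str)
            if dj_fam is not None:
                # most abundant non-tandem DJ member stands in for the root
                plain = [m for m in dj_fam.family.members
                         if m.anatomy is not None and not m.anatomy.is_tandem]
                dj_root = plain[0] if plain else dj_fam.family.top_member
        rec.mechanism = classify_family(
            rec.kept, catalog, params.mechanism, dj_root=dj_root,
            rooted=rec.family.rooted, stem_id=rec.family.stem_str)

    records = {(r.family.library, r.family.stem_str): r
               for r in vj_records + dj_records}
    meta = vj_rep.meta
    return SampleAnalysis(
        sample_id=meta.sample_id, patient_id=meta.patient_id,
        compartment=meta.compartment, timepoint_label=meta.timepoint_label,
        rep=vj_rep, dj_rep=dj_rep, records=records,
        qc=normalization_factor(vj_rep),
    )


def patient_results(analyses: Sequence[SampleAnalysis]) -> List[PatientResult]:
    """Per-patient rollup (diagnostic samples) for the cohort summary."""
    by_patient: Dict[str, List[SampleAnalysis]] = {}
    for a in analyses:
        by_patient.setdefault(a.patient_id, []).append(a)
    out = []
    for patient_id in sorted(by_patient):
        pas = by_patient[patient_id]
        n_markers = 0
        evolving = False
        mech: Dict[str, int] = {}
        for a in pas:
            for rec in a.records.values():
                if rec.marker.is_marker:
                    n_markers += 1
                if rec.evolution.is_evolving:
                    evolving = True
                if rec.mechanism is not None:
                    mech[rec.mechanism.summary] = mech.get(rec.mechanism.summary, 0) + 1
        out.append(PatientResult(patient_id=patient_id, n_marker_stems=n_markers,
                                 has_evolving=evolving,
                                 mechanism_counts=tuple(sorted(mech.items()))))
    return out


# -- file-tree driver ------------------------------------------------------

def load_cohort_dir(dataset_dir: str | Path,
                    use_np_hints: bool = False,
                    catalog: Optional[LocusCatalog] = None
                    ) -> Dict[Tuple[str, str], SampleRepertoire]:
    """Read every sample TSV referenced by a dataset's metadata.tsv."""
    root = Path(dataset_dir)
    meta_path = root / "metadata.tsv"
    if not meta_path.exists():
        from .io import RepertoireError
        raise RepertoireError(f"{root}: no metadata.tsv — not a dataset directory")
    metas = read_metadata(meta_path)
    out: Dict[Tuple[str, str], SampleRepertoire] = {}
    for (sample_id, lib), meta in metas.items():
        tsv = root / f"{sample_id}.{lib}.tsv"
        out[(sample_id, lib)] = read_airr_sample(
            tsv, meta, catalog=catalog, use_np_hints=use_np_hints)
    return out


def analyze_cohort_dir(dataset_dir: str | Path,
                       params: AnalysisParams = AnalysisParams(),
                       catalog: Optional[LocusCatalog] = None,
                       timepoint: Optional[str] = "day0"
                       ) -> List[SampleAnalysis]:
    """Analyze every (optionally: one timepoint's) sample in a dataset dir."""
    catalog = catalog or toy_catalog()
    reps = load_cohort_dir(dataset_dir, catalog=catalog)
    sample_ids = sorted({sid for (sid, _) in reps})
    analyses = []
    for sid in sample_ids:
        vj = reps.get((sid, VJ))
        if vj is None:
            continue
        if timepoint is not None and vj.meta.timepoint_label != timepoint:
            continue
        analyses.append(analyze_sample(vj, reps.get((sid, DJ)), catalog, params))
    return analyses


def stem_report_rows(analysis: SampleAnalysis) -> List[dict]:
    rows = []
    for (lib, stem), rec in sorted(analysis.records.items()):
        rows.append({
            "sample_id": analysis.sample_id,
            "patient_id": analysis.patient_id,
            "library": lib,
            "stem": stem,
            "n_members": len(rec.family.members),
            "n_members_after_filter": rec.metrics.n_members_after_filter,
            "total_reads": rec.family.total_reads,
            "total_percent": rec.family.total_percent,
            "top_member_id": rec.family.top_member.clonotype_id,
            "rooted": rec.family.rooted,
            "call": rec.evolution.call,
            "noise_ratio": rec.metrics.noise_ratio,
            "n_distinct_5prime_genes": rec.metrics.n_distinct_5prime_genes,
            "n_distinct_junction_lengths": rec.metrics.n_distinct_junction_lengths,
            "stem_is_complex": rec.metrics.stem_n_complexity.is_complex,
            "mechanism": rec.mechanism.summary if rec.mechanism else "",
            "is_marker": rec.marker.is_marker,
            "criteria_fired": ",".join(sorted(rec.marker.criteria_fired)),
            "would_conventional_miss": rec.marker.would_conventional_miss,
        })
    return rows


def marker_record(analysis: SampleAnalysis) -> dict:
    return {
        "patient_id": analysis.patient_id,
        "sample_id": analysis.sample_id,
        "marker_stems_vj": analysis.marker_stems(VJ),
        "marker_stems_dj": analysis.marker_stems(DJ),
        "has_evolving": analysis.has_evolving(),
    }


def run_manifest(params: AnalysisParams, seed: Optional[int],
                 input_files: Sequence[Path] = ()) -> dict:
    """Reproducibility manifest: config hash, input hashes, seed, version."""
    from . import __version__

    hashes = {}
    for p in input_files:
        h = hashlib.sha256(Path(p).read_bytes()).hexdigest()[:16]
        hashes[str(p)] = h
    return {
        "artifact_version": __version__,
        "config_hash": params.config_hash,
        "seed": seed,
        "input_hashes": json.dumps(hashes, sort_keys=True),
    }


def write_analysis_reports(analyses: Sequence[SampleAnalysis], out_dir: str | Path,
                           params: AnalysisParams,
                           seed: Optional[int] = None,
                           input_files: Sequence[Path] = ()) -> Dict[str, Path]:
    rows: List[dict] = []
    markers: List[dict] = []
    for a in analyses:
        rows.extend(stem_report_rows(a))
        markers.append(marker_record(a))
    return write_reports(rows, markers, out_dir,
                         run_info=run_manifest(params, seed, input_files))
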