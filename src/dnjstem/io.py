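"""Repertoire I/O: AIRR Rearrangement TSV ingestion, QC spike-in handling
and the usable-read denominator.

A *sample* is one amplicon library (IGH-VJ or IGH-DJ) sequenced from one
material (BM or PB) at one timepoint.  Reads from the cIT-QC spike-in
(central in-tube quality/quantification control) are tallied separately
and excluded from *usable reads*, the denominator of every percentage
abundance downstream.  When both the spike-in read count and the number
of spiked cell equivalents are known, abundances can be converted from
reads to cell equivalents via ``cells_per_read``.

Input dialect: AIRR Rearrangement TSV with the standard columns
``sequence_id, v_call, d_call, j_call, junction, duplicate_count`` plus
the optional columns ``np1, np2, d2_call`` and a boolean ``is_qc`` that
flags spike-in rows (synthetic data labels them explicitly; real data
must be pre-flagged by the caller).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Dict, List, Optional, Sequence

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .stems import JunctionAnatomy

__all__ = [
    "Clonotype",
    "SampleMeta",
    "SampleRepertoire",
    "QcNormalization",
    "LoadReport",
    "RepertoireError",
    "read_airr_sample",
    "write_airr_sample",
    "read_metadata",
    "normalization_factor",
    "abundance_percent",
    "write_reports",
]

VJ = "IGH-VJ"
DJ = "IGH-DJ"
LIBRARIES = (VJ, DJ)

MIN_JUNCTION_LEN = 6

REQUIRED_COLUMNS = ["sequence_id", "v_call", "d_call", "j_call", "junction", "duplicate_count"]
OPTIONAL_COLUMNS = ["np1", "np2", "d2_call", "is_qc"]


class RepertoireError(ValueError):
    """Schema, parse or validation failure on repertoire input."""


@dataclass
class Clonotype:
    """One junction-bearing rearrangement record.

    ``read_count`` is the AIRR ``duplicate_count`` (read level, no UMI
    handling).  ``anatomy`` is filled by junction decomposition.
    """

    clonotype_id: str
    sample_id: str
    library: str
    j_call: str
    junction: str
    read_count: int
    v_call: Optional[str] = None
    d_call: Optional[str] = None
    d2_call: Optional[str] = None
    anatomy: Optional["JunctionAnatomy"] = None

    def __post_init__(self) -> None:
        if self.library not in LIBRARIES:
            raise RepertoireError(f"{self.clonotype_id}: bad library {self.library!r}")
        if self.library == VJ and not self.v_call:
            raise RepertoireError(f"{self.clonotype_id}: IGH-VJ record without v_call")
        if self.library == DJ and self.v_call:
            raise RepertoireError(f"{self.clonotype_id}: IGH-DJ record with v_call")
        if self.library == DJ and not self.d_call:
            raise RepertoireError(f"{self.clonotype_id}: IGH-DJ record without d_call")
        if len(self.junction) < MIN_JUNCTION_LEN:
            raise RepertoireError(f"{self.clonotype_id}: junction shorter than {MIN_JUNCTION_LEN}")
        if self.read_count < 1:
            raise RepertoireError(f"{self.clonotype_id}: read_count must be >= 1")

    @property
    def five_prime_gene(self) -> Optional[str]:
        """The 5'-most gene call: V in the VJ library, (upstream) D in DJ."""
        if self.library == VJ:
            return self.v_call
        return self.d2_call or self.d_call


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    patient_id: str
    compartment: str  # BM | PB
    timepoint_label: str  # e.g. day0, day6, day22
    library: str
    qc_cell_equivalents_input: float = 0.0


@dataclass
class LoadReport:
    n_rows: int = 0
    n_qc_rows: int = 0
    dropped_empty_junction: int = 0
    dropped_short_junction: int = 0
    dropped_invalid: int = 0
    quarantined_decomposition: int = 0
    quarantine_reasons: List[str] = field(default_factory=list)


@dataclass
class SampleRepertoire:
    """All clonotypes of one sample/library plus QC bookkeeping."""

    meta: SampleMeta
    clonotypes: List[Clonotype]
    qc_reads: int = 0
    load_report: LoadReport = field(default_factory=LoadReport)

    def __post_init__(self) -> None:
        ids = [c.clonotype_id for c in self.clonotypes]
        if len(ids) != len(set(ids)):
            raise RepertoireError(
                f"sample {self.meta.sample_id}/{self.meta.library}: duplicate clonotype ids"
            )

    @property
    def sample_id(self) -> str:
        return self.meta.sample_id

    @property
    def library(self) -> str:
        return self.meta.library

    @property
    def usable_reads(self) -> int:
        """Reads with identified junctions after cIT-QC exclusion."""
        return sum(c.read_count for c in self.clonotypes)


@dataclass(frozen=True)
class QcNormalization:
    available: bool
    cells_per_read: Optional[float] = None


def _truthy(x) -> bool:
    return str(x).strip().upper() in {"T", "TRUE", "1", "Y", "YES"}


def read_airr_sample(tsv: str | Path, meta: SampleMeta, *, catalog=None,
                     use_np_hints: bool = False) -> SampleRepertoire:
    """Read one AIRR Rearrangement TSV into a :class:`SampleRepertoire`.

    Rows flagged ``is_qc`` are tallied into ``qc_reads`` and excluded from
    the clonotype list before any junction validation.  Rows with an empty
    junction are dropped and counted in the load report.  With
    ``use_np_hints=True`` and a catalog, junction anatomy is pre-filled
    from the np1/np2 columns where the split is unambiguous.
    """
    try:
        df = pd.read_csv(tsv, sep="\t", dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise RepertoireError(f"{tsv}: missing required columns {missing}")

    report = LoadReport(n_rows=len(df))
    clonotypes: List[Clonotype] = []
    qc_reads = 0
    has_qc = "is_qc" in df.columns
    has_np = "np1" in df.columns and "np2" in df.columns

    for row in df.itertuples(index=False):
        rec = row._asdict()
        try:
            count = int(rec["duplicate_count"])
        except (TypeError, ValueError):
            raise RepertoireError(
                f"{tsv}: non-integer duplicate_count {rec['duplicate_count']!r} "
                f"(sequence_id={rec['sequence_id']!r})"
            )
        if has_qc and _truthy(rec.get("is_qc", "")):
            report.n_qc_rows += 1
            qc_reads += count
            continue
        junction = rec["junction"].strip().upper()
        if not junction:
            report.dropped_empty_junction += 1
            continue
        if len(junction) < MIN_JUNCTION_LEN:
            report.dropped_short_junction += 1
            continue
        try:
            clono = Clonotype(
                clonotype_id=rec["sequence_id"],
                sample_id=meta.sample_id,
                library=meta.library,
                j_call=rec["j_call"],
                junction=junction,
                read_count=count,
                v_call=rec["v_call"] or None,
                d_call=rec["d_call"] or None,
                d2_call=rec.get("d2_call") or None,
            )
        except RepertoireError:
            report.dropped_invalid += 1
            continue
        if use_np_hints and has_np and catalog is not None:
            from .stems import anatomy_from_np_hints

            clono.anatomy = anatomy_from_np_hints(
                clono, rec.get("np1", ""), rec.get("np2", ""), catalog
            )
        clonotypes.append(clono)

    rep = SampleRepertoire(meta=meta, clonotypes=clonotypes, qc_reads=qc_reads,
                           load_report=report)
    if rep.usable_reads == 0:
        raise RepertoireError(
            f"{tsv}: no usable reads (all rows QC or dropped) — empty repertoire"
        )
    return rep


def write_airr_sample(rep: SampleRepertoire, tsv: str | Path) -> None:
    """Write a repertoire back to AIRR Rearrangement TSV (round-trip safe)."""
    rows = []
    for c in rep.clonotypes:
        rows.append({
            "sequence_id": c.clonotype_id,
            "v_call": c.v_call or "",
            "d_call": c.d_call or "",
            "d2_call": c.d2_call or "",
            "j_call": c.j_call,
            "junction": c.junction,
            "duplicate_count": c.read_count,
            "np1": c.anatomy.n1 if c.anatomy else "",
            "np2": c.anatomy.n2 if c.anatomy else "",
            "is_qc": "F",
        })
    if rep.qc_reads > 0:
        rows.append({
            "sequence_id": "cIT-QC",
            "v_call": "", "d_call": "", "d2_call": "", "j_call": "",
            "junction": "ACGTACGT",
            "duplicate_count": rep.qc_reads,
            "np1": "", "np2": "", "is_qc": "T",
        })
    pd.DataFrame(rows).to_csv(tsv, sep="\t", index=False)


METADATA_COLUMNS = ["sample_id", "patient_id", "compartment", "timepoint_label",
                    "library", "qc_cell_equivalents_input"]


def read_metadata(path: str | Path) -> Dict[tuple, SampleMeta]:
    """Read the sidecar sample-metadata TSV, keyed by (sample_id, library)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise RepertoireError(f"{path}: metadata missing columns {missing}")
    out: Dict[tuple, SampleMeta] = {}
    for row in df.itertuples(index=False):
        meta = SampleMeta(
            sample_id=row.sample_id, patient_id=row.patient_id,
            compartment=row.compartment, timepoint_label=row.timepoint_label,
            library=row.library,
            qc_cell_equivalents_input=float(row.qc_cell_equivalents_input or 0),
        )
        key = (meta.sample_id, meta.library)
        if key in out:
            raise RepertoireError(f"{path}: duplicate metadata row for {key}")
        out[key] = meta
    return out


def normalization_factor(rep: SampleRepertoire) -> QcNormalization:
    """Read→cell conversion factor from the cIT-QC spike-in.

    Unavailability (no QC reads, or no spiked cell-equivalent input) is a
    value, not an error.
    """
    qc_in = rep.meta.qc_cell_equivalents_input
    if rep.qc_reads <= 0 or qc_in <= 0:
        return QcNormalization(available=False)
    return QcNormalization(available=True, cells_per_read=qc_in / rep.qc_reads)


def abundance_percent(read_count: int, rep: SampleRepertoire) -> float:
    """Percentage of usable reads (full precision; round only for display)."""
    usable = rep.usable_reads
    if usable <= 0:
        raise ZeroDivisionError("usable_reads is zero")
    return 100.0 * read_count / usable


# -- report writing --------------------------------------------------------

def write_reports(stem_rows: Sequence[dict], marker_records: Sequence[dict],
                  out_dir: str | Path, run_info: Optional[dict] = None) -> Dict[str, Path]:
    """Emit the per-sample stem-family TSV, per-patient marker JSON and run log.

    ``stem_rows`` are flat dicts (one per stem family per sample/library);
    ``marker_records`` are per-patient marker summaries.  Percentages are
    rounded to 2 decimals at this rendering step only.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "stem_families": out / "stem_families.tsv",
        "markers": out / "markers.json",
        "run_log": out / "run_log.txt",
    }
    rows = []
    for r in stem_rows:
        r = dict(r)
        for k, v in r.items():
            if isinstance(v, float):
                r[k] = round(v, 2)
        rows.append(r)
    if rows:
        pd.DataFrame(rows).to_csv(paths["stem_families"], sep="\t", index=False)
    else:
        header = ["sample_id", "library", "stem", "n_members", "total_reads",
                  "total_percent", "rooted", "call", "mechanism", "is_marker"]
        pd.DataFrame(columns=header).to_csv(paths["stem_families"], sep="\t", index=False)
    with open(paths["markers"], "w") as fh:
        json.dump(list(marker_records), fh, indent=1, default=str)
    with open(paths["run_log"], "w") as fh:
        for k, v in (run_info or {}).items():
            fh.write(f"{k}\t{v}\n")
    return paths
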