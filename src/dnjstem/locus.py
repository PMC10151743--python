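"""Germline IGH locus catalog.

Holds the IGHV/IGHD/IGHJ reference segments together with their position
(rank) along the locus.  Locus order matters for two reasons: V_H
replacement proceeds with an *incoming* V that normally lies downstream
(further from the D cluster) of the replaced V, and V/D usage biases in
ongoing recombination are expressed relative to D-proximity.

Rank convention
---------------
* V ranks increase with distance from the D cluster; the most D-proximal
  V (the IGHV6-1 position in the human locus) has rank 1.
* D ranks increase toward the J cluster.
* J ranks follow genomic order.

``is_downstream(incoming, original)`` is therefore a simple rank
inequality: ``rank(incoming) > rank(original)``.

A small fully synthetic toy locus is bundled for simulation and tests
(:func:`toy_catalog`); real IMGT references are user-supplied files and
are never downloaded.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Literal, Tuple

from Bio import SeqIO

__all__ = [
    "GermlineSegment",
    "LocusCatalog",
    "LocusError",
    "load_catalog",
    "toy_catalog",
    "gene_name",
]

SegmentType = Literal["V", "D", "J"]
Functionality = Literal["functional", "ORF", "pseudogene"]

_ALPHABET = set("ACGT")
_FUNCTIONALITIES = {"functional", "ORF", "pseudogene"}

# V_H replacement leaves at most this many nucleotides of the replaced V.
MAX_V_FOOTPRINT = 5


class LocusError(ValueError):
    """Catalog construction or lookup failure."""


def gene_name(call: str) -> str:
    """Strip an allele suffix (``*01`` etc.) from a gene/allele call."""
    return call.split("*", 1)[0]


@dataclass(frozen=True)
class GermlineSegment:
    """One germline V, D or J gene segment.

    ``locus_rank`` is the ordinal position within the segment type (see
    module docstring for orientation conventions).
    """

    name: str
    segment_type: SegmentType
    sequence: str
    locus_rank: int
    functionality: Functionality = "functional"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise LocusError(f"segment {self.name!r}: empty sequence")
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise LocusError(
                f"segment {self.name!r}: non-ACGT characters {sorted(bad)!r}"
            )
        if self.segment_type not in ("V", "D", "J"):
            raise LocusError(f"segment {self.name!r}: bad type {self.segment_type!r}")
        if self.functionality not in _FUNCTIONALITIES:
            raise LocusError(
                f"segment {self.name!r}: bad functionality {self.functionality!r}"
            )


@dataclass
class LocusCatalog:
    """Lookup structure over a set of :class:`GermlineSegment`."""

    segments: Dict[str, GermlineSegment]
    version_tag: str = ""
    _gene_rank: Dict[Tuple[str, str], int] = field(default_factory=dict, repr=False)
    _d_index: Dict[str, str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        types = {s.segment_type for s in self.segments.values()}
        if types != {"V", "D", "J"}:
            missing = {"V", "D", "J"} - types
            raise LocusError(f"catalog must contain V, D and J segments; missing {missing}")
        for stype in "VDJ":
            ranks = [s.locus_rank for s in self.segments.values() if s.segment_type == stype]
            if len(ranks) != len(set(ranks)):
                raise LocusError(f"duplicate locus_rank among {stype} segments")
        # gene-level rank map (allele suffixes stripped); ambiguity across
        # alleles of one gene is resolved by the smallest rank seen.
        for seg in self.segments.values():
            key = (seg.segment_type, gene_name(seg.name))
            if key not in self._gene_rank or seg.locus_rank < self._gene_rank[key]:
                self._gene_rank[key] = seg.locus_rank

    # -- lookup -----------------------------------------------------------

    def get(self, name: str) -> GermlineSegment:
        try:
            return self.segments[name]
        except KeyError:
            raise LocusError(f"unknown segment {name!r}") from None

    def of_type(self, stype: SegmentType) -> List[GermlineSegment]:
        out = [s for s in self.segments.values() if s.segment_type == stype]
        out.sort(key=lambda s: s.locus_rank)
        return out

    def rank(self, stype: SegmentType, call: str) -> int:
        key = (stype, gene_name(call))
        try:
            return self._gene_rank[key]
        except KeyError:
            raise LocusError(f"unknown {stype} gene {call!r}") from None

    # -- locus-order relations -------------------------------------------

    def is_downstream(self, incoming: str, original: str) -> bool:
        """True iff V gene ``incoming`` lies downstream (D-distal) of ``original``.

        Pseudogene and ORF segments are retained in the order and compared
        like any other segment; functionality is a flag, not a filter.
        """
        return self.rank("V", incoming) > self.rank("V", original)

    def v_three_prime_tail(self, v_name: str, k: int) -> str:
        """Last ``k`` nucleotides of a germline V (1 <= k <= 5).

        This is the largest remnant that a V_H replacement can leave of
        the replaced gene.
        """
        if not 1 <= k <= MAX_V_FOOTPRINT:
            raise ValueError(f"k must be in [1, {MAX_V_FOOTPRINT}], got {k}")
        seg = self.get(v_name)
        if seg.segment_type != "V":
            raise LocusError(f"{v_name!r} is not a V segment")
        return seg.sequence[-k:]

    # -- derived indexes --------------------------------------------------

    def d_substring_index(self, min_len: int = 4) -> Dict[str, str]:
        """Map every germline-D substring (length >= min_len) to a D name.

        Where a substring occurs in several D genes the smallest-rank gene
        wins, which makes attribution deterministic.  Used by junction
        decomposition for exact D matching.
        """
        if self._d_index is None:
            index: Dict[str, str] = {}
            for seg in self.of_type("D"):
                s = seg.sequence
                for i in range(len(s)):
                    for j in range(i + min_len, len(s) + 1):
                        index.setdefault(s[i:j], seg.name)
            self._d_index = index
        return self._d_index


def _read_order_table(path: Path) -> Dict[str, Tuple[int, str]]:
    table: Dict[str, Tuple[int, str]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"name", "rank", "functionality"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise LocusError(f"order table {path}: needs columns {sorted(required)}")
        for row in reader:
            name = row["name"].strip()
            if name in table:
                raise LocusError(f"order table {path}: duplicate name {name!r}")
            table[name] = (int(row["rank"]), row["functionality"].strip())
    return table


def _load_fasta(path: Path, stype: SegmentType, order: Dict[str, Tuple[int, str]],
                seen: set) -> Iterable[GermlineSegment]:
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        if name in seen:
            raise LocusError(f"duplicate segment name {name!r}")
        seen.add(name)
        if name not in order:
            raise LocusError(
                f"FASTA record {name!r} ({stype} file {path}) missing from order table"
            )
        rank, functionality = order[name]
        yield GermlineSegment(
            name=name,
            segment_type=stype,
            sequence=str(record.seq).upper(),
            locus_rank=rank,
            functionality=functionality,  # type: ignore[arg-type]
        )


def load_catalog(v_fasta: str | Path, d_fasta: str | Path, j_fasta: str | Path,
                 order_table: str | Path, version_tag: str = "") -> LocusCatalog:
    """Build a :class:`LocusCatalog` from three FASTA files and an order table.

    The order table is a 3-column TSV (``name``, ``rank``, ``functionality``)
    and must cover every FASTA record; records absent from it are rejected.
    """
    for p in (v_fasta, d_fasta, j_fasta, order_table):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    order = _read_order_table(Path(order_table))
    seen: set = set()
    segments: Dict[str, GermlineSegment] = {}
    for path, stype in ((v_fasta, "V"), (d_fasta, "D"), (j_fasta, "J")):
        for seg in _load_fasta(Path(path), stype, order, seen):  # type: ignore[arg-type]
            segments[seg.name] = seg
    return LocusCatalog(segments=segments, version_tag=version_tag)


def toy_catalog() -> LocusCatalog:
    """The bundled synthetic toy locus (12 V, 6 D, 3 J segments).

    Sequences are synthetic (not IMGT) and were generated once with low
    cross-segment similarity so that exact-substring D assignment is
    unambiguous at the default match length.
    """
    root = resources.files("dnjstem.data") / "toy_locus"
    with resources.as_file(root) as base:
        return load_catalog(
            base / "v.fasta", base / "d.fasta", base / "j.fasta",
            base / "order.tsv", version_tag="toy-locus-1",
        )
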