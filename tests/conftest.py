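"""Shared fixtures: catalogs, constructed junctions and repertoires."""

from __future__ import annotations

from typing import List, Optional

import pytest

from dnjstem.io import DJ, VJ, Clonotype, SampleMeta, SampleRepertoire
from dnjstem.locus import LocusCatalog, load_catalog, toy_catalog
from dnjstem.stems import JunctionAnatomy


@pytest.fixture(scope="session")
def catalog() -> LocusCatalog:
    return toy_catalog()


# a hand-sized catalog whose sequences make region boundaries obvious
MINI_V = {"VH-A": "CAGGTGCAGCTGGTGCAGTCTGTGCGAGAG",   # 3' end TGTGCGAGAG
          "VH-B": "CAGGTCACCTTGAAGGAGTCTGCCACGATT"}   # 3' end ...ACGATT
MINI_D = {"DH-A": "GACTAC", "DH-B": "AGTAGTAGCTGCTACTCC"}
MINI_J = {"JH-A": "TTTGACTACTGG", "JH-B": "CTGGGGCCAAGG"}


@pytest.fixture()
def mini_catalog(tmp_path) -> LocusCatalog:
    for name, records in (("v", MINI_V), ("d", MINI_D), ("j", MINI_J)):
        with open(tmp_path / f"{name}.fasta", "w") as fh:
            for rid, seq in records.items():
                fh.write(f">{rid}\n{seq}\n")
    with open(tmp_path / "order.tsv", "w") as fh:
        fh.write("name\trank\tfunctionality\n")
        for i, rid in enumerate([*MINI_V, *MINI_D, *MINI_J]):
            fh.write(f"{rid}\t{i % 2 + 1}\tfunctional\n")
    return load_catalog(tmp_path / "v.fasta", tmp_path / "d.fasta",
                        tmp_path / "j.fasta", tmp_path / "order.tsv")


def make_clonotype(cid: str, *, v_part: str = "TGTGCGAGAG", n1: str = "",
                   d_part: str = "", n2: str = "",
                   j_part: str = "CTAACCATTCGTGT",
                   v_call: Optional[str] = "TVH01",
                   d_call: Optional[str] = None, d2_call: Optional[str] = None,
                   j_call: str = "TJH01", reads: int = 100,
                   library: str = VJ, sample_id: str = "S1",
                   d_upstream_part: str = "", n0: str = "") -> Clonotype:
    """Build a clonotype with a known anatomy and the implied junction."""
    if library == DJ:
        v_part = ""
    anatomy = JunctionAnatomy(v_part=v_part, n1=n1,
                              d_upstream_part=d_upstream_part, n0=n0,
                              d_part=d_part, n2=n2, j_part=j_part)
    return Clonotype(
        clonotype_id=cid, sample_id=sample_id, library=library,
        j_call=j_call, junction=anatomy.junction, read_count=reads,
        v_call=v_call if library == VJ else None,
        d_call=d_call or ("TDH01" if library == DJ else None),
        d2_call=d2_call, anatomy=anatomy,
    )


def make_repertoire(clonotypes: List[Clonotype], sample_id: str = "S1",
                    library: str = VJ, qc_reads: int = 0,
                    qc_cells: float = 0.0, patient_id: str = "PT1",
                    compartment: str = "BM",
                    timepoint: str = "day0") -> SampleRepertoire:
    meta = SampleMeta(sample_id=sample_id, patient_id=patient_id,
                      compartment=compartment, timepoint_label=timepoint,
                      library=library, qc_cell_equivalents_input=qc_cells)
    return SampleRepertoire(meta=meta, clonotypes=clonotypes, qc_reads=qc_reads)
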