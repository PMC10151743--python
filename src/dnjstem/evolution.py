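"""Noise filtering and the evolving/stable consensus call.

A stem family collects everything that shares a junction suffix, so it
mixes true clonally related members with PCR/sequencing-error satellites
of abundant clonotypes and with chance co-occurrences at very low read
counts.  The filter removes, as potential noise, clonotypes highly
similar to the family's most abundant member (same 5' gene, small
junction edit distance) and clonotypes below an absolute (3 reads) or
relative (0.01% of usable reads) abundance floor.

The consensus call then weighs the surviving family's size, its 5'-gene
and junction-length diversity, the fraction of removed members (a noisy
stem), and the stem's N-region complexity (confidence in the stem's
specificity).  The default rule — a family is *evolving* iff it keeps at
least 3 members with at least 2 distinct 5' genes and 2 junction
lengths, no more than half of its members were removed as noise, and its
stem N region is complex (or the family is large) — is one concrete
parameterization; every threshold sits in :class:`ConsensusPolicy`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Tuple

import edlib

from .io import DJ, VJ, Clonotype, SampleRepertoire, abundance_percent
from .locus import gene_name
from .stems import DnjStem, StemFamily

__all__ = [
    "NoisePolicy",
    "ConsensusPolicy",
    "ComplexityScore",
    "FamilyMetrics",
    "EvolutionCall",
    "filter_noise",
    "compute_metrics",
    "call_evolution",
    "levenshtein",
]


def levenshtein(a: str, b: str) -> int:
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


@dataclass(frozen=True)
class NoisePolicy:
    min_reads: int = 3
    min_percent: float = 0.01  # of usable reads
    satellite_max_edit: int = 2
    satellite_same_gene: bool = True

    def __post_init__(self) -> None:
        if self.min_reads < 1 or self.min_percent <= 0:
            raise ValueError("min_reads >= 1 and min_percent > 0 required")


@dataclass(frozen=True)
class ConsensusPolicy:
    """Thresholds of the evolving/stable consensus rule.

    The noise evidence enters softly: ``max_noise_ratio`` bounds the
    total removed fraction only loosely, because genuine recombination
    bursts contain many members below the abundance floor and every
    abundant member carries a PCR/sequencing error cloud — neither is
    evidence against the clonal relatedness of the *surviving* members,
    which never include satellites.  The removal counts are always
    recorded in the evidence; ``max_satellite_ratio`` (off at its
    default of 1.0) can veto families dominated by the top member's
    error cloud where a stricter screen is wanted.
    """

    min_members: int = 3
    min_distinct_5prime_genes: int = 2
    min_distinct_junction_lengths: int = 2
    max_satellite_ratio: float = 1.0
    max_noise_ratio: float = 0.9
    large_family_override: int = 5  # complexity waived at this size


@dataclass(frozen=True)
class ComplexityScore:
    n_region_length: int
    distinct_bases: int

    @property
    def is_complex(self) -> bool:
        return self.n_region_length >= 2 and self.distinct_bases >= 2


@dataclass
class FamilyMetrics:
    n_removed_satellites: int
    n_removed_low_abundance: int
    n_members_after_filter: int
    relative_members: float
    n_distinct_5prime_genes: int
    n_distinct_junction_lengths: int
    stem_n_complexity: ComplexityScore
    noise_ratio: float

    @property
    def satellite_ratio(self) -> float:
        total = self.n_removed_satellites + self.n_removed_low_abundance \
            + self.n_members_after_filter
        return self.n_removed_satellites / total if total else 0.0


@dataclass
class EvolutionCall:
    call: str  # evolving | stable
    evidence: Dict[str, object]
    policy_id: str

    @property
    def is_evolving(self) -> bool:
        return self.call == "evolving"


def filter_noise(family: StemFamily, policy: NoisePolicy,
                 rep: SampleRepertoire) -> Tuple[List[Clonotype], List[Clonotype], Dict[str, int]]:
    """Split a family into kept and removed members.

    The top member is never removed.  A non-top member is a *satellite*
    when it carries the same 5' gene as the top member (if required) and
    its junction is within ``satellite_max_edit`` Levenshtein distance of
    the top junction; independently, members below the read/percent floor
    are removed as low abundance.  Total family reads are conserved
    across the split.
    """
    top = family.top_member
    top_gene = gene_name(top.five_prime_gene) if top.five_prime_gene else None
    kept, removed = [top], []
    counts = {"satellites": 0, "low_abundance": 0}
    for m in family.members[1:]:
        gene = gene_name(m.five_prime_gene) if m.five_prime_gene else None
        same_gene_ok = (not policy.satellite_same_gene) or (gene == top_gene)
        is_satellite = same_gene_ok and levenshtein(m.junction, top.junction) <= policy.satellite_max_edit
        is_low = (m.read_count < policy.min_reads
                  or abundance_percent(m.read_count, rep) < policy.min_percent)
        if is_satellite:
            counts["satellites"] += 1
            removed.append(m)
        elif is_low:
            counts["low_abundance"] += 1
            removed.append(m)
        else:
            kept.append(m)
    return kept, removed, counts


def stem_n_region(stem: DnjStem) -> str:
    """The stem's N-derived portion, on which complexity is scored."""
    if stem.from_n_fallback:
        return stem.d_contribution + stem.n2_contribution
    return stem.n2_contribution


def compute_metrics(kept: List[Clonotype], removed: List[Clonotype],
                    rep: SampleRepertoire, stem: DnjStem) -> FamilyMetrics:
    genes = {gene_name(c.five_prime_gene) for c in kept if c.five_prime_gene}
    lengths = {len(c.junction) for c in kept}
    n_region = stem_n_region(stem)
    n_removed = len(removed)
    total = n_removed + len(kept)
    # the satellite/low-abundance split of `removed` is filled in by
    # analyze_family_noise, which has the filter's reason codes
    return FamilyMetrics(
        n_removed_satellites=0,
        n_removed_low_abundance=0,
        n_members_after_filter=len(kept),
        relative_members=len(kept) / max(1, len(rep.clonotypes)),
        n_distinct_5prime_genes=len(genes),
        n_distinct_junction_lengths=len(lengths),
        stem_n_complexity=ComplexityScore(
            n_region_length=len(n_region),
            distinct_bases=len(set(n_region)),
        ),
        noise_ratio=n_removed / total if total else 0.0,
    )


def analyze_family_noise(family: StemFamily, noise: NoisePolicy,
                         rep: SampleRepertoire) -> Tuple[List[Clonotype], List[Clonotype], FamilyMetrics]:
    """filter_noise + compute_metrics with the removal split filled in."""
    kept, removed, counts = filter_noise(family, noise, rep)
    metrics = compute_metrics(kept, removed, rep, family.stem)
    metrics.n_removed_satellites = counts["satellites"]
    metrics.n_removed_low_abundance = counts["low_abundance"]
    return kept, removed, metrics


def _policy_id(policy: ConsensusPolicy) -> str:
    payload = json.dumps(asdict(policy), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def call_evolution(metrics: FamilyMetrics,
                   policy: ConsensusPolicy = ConsensusPolicy()) -> EvolutionCall:
    """Consensus evolving/stable call from the family metrics.

    Evolving requires, jointly: enough surviving members, 5'-gene and
    junction-length diversity, a bounded noise ratio, and either a
    complex stem N region or a large family.  The evidence dict records
    every consulted value and predicate so calls are auditable.
    """
    cx = metrics.stem_n_complexity
    checks = {
        "n_members_after_filter": metrics.n_members_after_filter,
        "n_members_ok": metrics.n_members_after_filter >= policy.min_members,
        "n_distinct_5prime_genes": metrics.n_distinct_5prime_genes,
        "genes_ok": metrics.n_distinct_5prime_genes >= policy.min_distinct_5prime_genes,
        "n_distinct_junction_lengths": metrics.n_distinct_junction_lengths,
        "lengths_ok": metrics.n_distinct_junction_lengths >= policy.min_distinct_junction_lengths,
        "noise_ratio": metrics.noise_ratio,
        "satellite_ratio": metrics.satellite_ratio,
        "noise_ok": (metrics.noise_ratio <= policy.max_noise_ratio
                     and metrics.satellite_ratio <= policy.max_satellite_ratio),
        "n_region_length": cx.n_region_length,
        "distinct_bases": cx.distinct_bases,
        "is_complex": cx.is_complex,
        "complexity_ok": cx.is_complex
        or metrics.n_members_after_filter >= policy.large_family_override,
        "relative_members": metrics.relative_members,
        "n_removed_satellites": metrics.n_removed_satellites,
        "n_removed_low_abundance": metrics.n_removed_low_abundance,
    }
    evolving = (checks["n_members_ok"] and checks["genes_ok"] and checks["lengths_ok"]
                and checks["noise_ok"] and checks["complexity_ok"])
    return EvolutionCall(
        call="evolving" if evolving else "stable",
        evidence=checks,
        policy_id=_policy_id(policy),
    )
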