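"""Mechanism classification for evolving stem families.

Two recombination programmes drive IGH clonal evolution in BCP-ALL and
leave discriminable signatures inside the junction:

* **V_H replacement** — the V of an existing VDJ is exchanged via a
  cryptic RSS while the DJ assembly is kept.  Signatures: (i) the D
  region's 5' site and the 3' site of the preceding N1 region stay
  stable relative to the abundant *mother* clonotype, and (ii) a remnant
  ("footprint") of up to 5 nt of the replaced V survives inside the new
  N1.  Replacement can run for multiple rounds; the incoming V normally
  lies downstream (D-distal) of the replaced one.
* **D_H/V_H-DJ_H recombination** — a fresh V (or a second D, as a D-D
  tandem fusion) joins an incomplete DJ rearrangement (the *DJ root*).
  Signatures: a completely fresh N1, frequent 5' erosion of the root D,
  and typically a burst of many lowly abundant members.

Classification is per member against a reference (the mother candidate,
i.e. the family's most abundant clonotype, or the DJ root for erosion
checks when the stem is rooted), then summarized per stem by majority;
stems where both mechanism classes carry a substantial share of members
are called *mixed* (observed, but rare, in real data).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Dict, List, Optional, Sequence, Tuple

from .io import DJ, VJ, Clonotype
from .locus import LocusCatalog, LocusError, gene_name
from .stems import StemFamily

__all__ = [
    "MechanismPolicy",
    "MemberMechanism",
    "StemMechanismCall",
    "check_d5_stability",
    "find_vh_footprint",
    "classify_member",
    "classify_family",
    "summarize_stem",
    "mother_candidates",
]

VH_REPLACEMENT = "VH_replacement"
V_TO_DJ = "V_to_DJ"
D_TO_DJ = "D_to_DJ"
UNDETERMINED = "undetermined"
MIXED = "mixed"
DV_TO_DJ = "DV_to_DJ"  # stem-level summary of the recombination class

_RECOMBINATION_CLASS = {V_TO_DJ, D_TO_DJ}


@dataclass(frozen=True)
class MechanismPolicy:
    max_footprint: int = 5
    min_footprint_evidence: int = 2  # length-1 remnants are uninformative
    # when the reference N1 is too short (<2 nt) to test its preservation,
    # the footprint alone carries the replacement evidence and must be longer
    weak_context_footprint: int = 3
    d5_stability_tolerance: int = 1  # nt of erosion absorbed as noise
    mother_abundance_factor: float = 10.0  # x family median
    mixed_fraction: float = 0.2
    allow_upstream_flagged: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.min_footprint_evidence <= self.max_footprint:
            raise ValueError("need 1 <= min_footprint_evidence <= max_footprint")


@dataclass
class MemberMechanism:
    member_id: str
    mechanism: str
    footprint: Optional[str] = None
    footprint_source_v: Optional[str] = None
    upstream_incoming_flag: bool = False


@dataclass
class StemMechanismCall:
    stem_id: str
    summary: str  # VH_replacement | DV_to_DJ | mixed | undetermined
    member_calls: List[MemberMechanism]
    mother_id: Optional[str] = None
    dj_root_present: bool = False


def _observed_erosion(junction: str, ref_d: str, n2: str, j_part: str,
                      window: int) -> Optional[int]:
    """Smallest k such that the junction ends with ref_d[k:] + n2 + j_part.

    This measures D 5' erosion relative to a reference D directly on the
    junction string, which is immune to how the member's own junction
    was decomposed (region boundaries can shift by a nucleotide when N
    bases happen to continue germline).  None when no k within the
    window fits.
    """
    for k in range(min(window, len(ref_d)) + 1):
        if junction.endswith(ref_d[k:] + n2 + j_part):
            return k
    return None


@dataclass
class _StabilityEvidence:
    stable: Optional[bool]       # the check_d5_stability verdict
    erosion: Optional[int]       # observed D erosion vs the reference
    tail_informative: bool       # reference N1 long enough to test
    tail_preserved: Optional[bool]
    prefix: str                  # member junction 5' of the preserved suffix


def _d_extension_chars(ref_d: str, catalog: LocusCatalog) -> set:
    """Germline characters that would extend ref_d by one nt at its 5' end."""
    chars = set()
    for seg in catalog.of_type("D"):
        start = seg.sequence.find(ref_d)
        while start != -1:
            if start > 0:
                chars.add(seg.sequence[start - 1])
            start = seg.sequence.find(ref_d, start + 1)
    return chars


def _stability_evidence(member: Clonotype, reference: Clonotype,
                        tol: int, catalog: Optional[LocusCatalog] = None
                        ) -> Optional[_StabilityEvidence]:
    """Full replacement-signature evidence of a member vs the reference.

    All tests run on the member's raw junction against the reference's
    decomposed regions: stability means the member's junction ends with
    the reference's D + N2 + J suffix (up to ``tol`` nt of D 5' erosion
    and never with *more* germline D than the reference — replacement
    cannot restore eroded D, and the reference D is maximal by
    decomposition, so an extra 5' germline-D character marks a
    less-eroded sibling, not a replacement product), and — where the
    reference N1 offers >= 2 nt — that the reference N1's 3'-most
    min(4, len) nt sit immediately 5' of that suffix (up to ``tol`` nt
    loss, never compared as an empty string).
    """
    ref = reference.anatomy
    if ref is None or member.anatomy is None:
        raise ValueError("both clonotypes need decomposed anatomy")
    if not ref.d_part:
        return None
    erosion = _observed_erosion(member.junction, ref.d_part, ref.n2, ref.j_part,
                                window=max(tol, 6))
    tail = ref.n1[-4:]
    informative = len(tail) >= 2
    if erosion is None:
        return _StabilityEvidence(stable=False, erosion=None,
                                  tail_informative=informative,
                                  tail_preserved=None, prefix="")
    suffix_len = len(ref.d_part) - erosion + len(ref.n2) + len(ref.j_part)
    prefix = member.junction[:len(member.junction) - suffix_len]
    extended = False
    if erosion == 0 and catalog is not None and ref.n1:
        # the maximality argument needs a reference N1 for decomposition
        # to have extended the reference D into; without one, a germline
        # continuation character before the suffix proves nothing
        suffix = ref.d_part + ref.n2 + ref.j_part
        extended = any(member.junction.endswith(c + suffix)
                       for c in _d_extension_chars(ref.d_part, catalog))
    preserved: Optional[bool] = None
    if informative:
        preserved = any(prefix.endswith(tail[k:])
                        for k in range(min(tol, len(tail) - 1) + 1))
    stable = (erosion <= tol and not extended
              and (preserved if informative else True))
    return _StabilityEvidence(stable=stable, erosion=erosion,
                              tail_informative=informative,
                              tail_preserved=preserved, prefix=prefix)


def check_d5_stability(member: Clonotype, reference: Clonotype,
                       tol: int = 1) -> Optional[bool]:
    """Is the member's D 5' site (and the preceding N1 3' site) stable?

    True iff the member's junction retains the reference's D region with
    at most ``tol`` nt of 5' erosion (and everything 3' of it), and the
    3'-most min(4, len) nt of the reference N1 sit immediately 5' of the
    member's D (allowing up to ``tol`` nt loss of that tail).  Returns
    None (an *undetermined* signal, not an error) when the reference has
    no D region.
    """
    ev = _stability_evidence(member, reference, tol)
    return None if ev is None else ev.stable


def find_vh_footprint(member: Clonotype, candidate_replaced_vs: Sequence[str],
                      catalog: LocusCatalog,
                      policy: MechanismPolicy = MechanismPolicy(),
                      region: Optional[str] = None) -> Optional[Tuple[str, str]]:
    """Longest germline-V 3' tail of any candidate found inside the member N1.

    ``region`` overrides the search space (callers pass the junction
    segment between the member's V and the preserved reference suffix,
    which is robust to decomposition boundary shifts); by default the
    member's decomposed N1 is searched.  Candidates are tried in the
    given order (callers order them by family abundance, which resolves
    equal-length ties toward the more abundant mother).  Returns
    (footprint, source V name) or None.
    """
    if region is None:
        if member.anatomy is None:
            raise ValueError("member needs decomposed anatomy")
        region = member.anatomy.n1
    if not region:
        return None
    for k in range(policy.max_footprint, policy.min_footprint_evidence - 1, -1):
        for v in candidate_replaced_vs:
            try:
                tail = catalog.v_three_prime_tail(v, k)
            except (LocusError, ValueError):
                continue
            if tail in region:
                return tail, v
    return None


def mother_candidates(kept_members: Sequence[Clonotype],
                      policy: MechanismPolicy = MechanismPolicy()) -> List[Clonotype]:
    """Abundant mother-clonotype candidates of a filtered family.

    Members at least ``mother_abundance_factor`` times the family median
    read count; the single top member when none qualify.  Input must be
    sorted by read count descending.
    """
    if not kept_members:
        return []
    med = median(m.read_count for m in kept_members)
    out = [m for m in kept_members if m.read_count >= policy.mother_abundance_factor * med]
    return out or [kept_members[0]]


def classify_member(member: Clonotype, reference: Clonotype,
                    candidate_vs: Sequence[str], catalog: LocusCatalog,
                    policy: MechanismPolicy = MechanismPolicy(),
                    root_regions: Optional[Tuple[str, str, str]] = None
                    ) -> MemberMechanism:
    """Mechanism call for one family member against the family reference.

    ``root_regions`` is the (D, N2, J) region triple of the root
    reconstruction — the DJ-library root where the stem is rooted,
    otherwise the family's least-eroded member (see
    :func:`classify_family`).

    Order of evidence: the V_H-replacement signature first (D/N1
    stability, root-consistent erosion, plus a V footprint in the
    junction segment between the member's V and the preserved reference
    suffix; a stronger footprint is demanded when the reference N1 is
    too short to test its preservation), then the DJ-library / D-D
    tandem signature, then the V-DJ burst signature — D 5' erosion
    relative to the root reconstruction, or a fresh N1 where the
    reference N1 is informative.  A burst member may reuse the
    reference's V gene (real bursts heavily reuse the most D-proximal
    V); replacement by definition exchanges it.  An incoming V that is
    *not* downstream of the replaced V is flagged, not vetoed: such
    members exist in real data and may be annotation errors or earlier
    family members.
    """
    mm = MemberMechanism(member_id=member.clonotype_id, mechanism=UNDETERMINED)
    if member.clonotype_id == reference.clonotype_id:
        return mm
    anatomy = member.anatomy
    if anatomy is None:
        raise ValueError("member needs decomposed anatomy")

    tol = policy.d5_stability_tolerance
    ev = _stability_evidence(member, reference, tol, catalog)

    # root-relative D erosion: replacement transmits the mother's D
    # verbatim, so member and reference must sit at the *same* erosion
    # level relative to the root; a differently eroded D marks an
    # independent joining event
    k_mem = k_ref = None
    if root_regions is not None:
        root_d, root_n2, root_jp = root_regions
        k_mem = _observed_erosion(member.junction, root_d, root_n2, root_jp,
                                  window=8)
        k_ref = _observed_erosion(reference.junction, root_d, root_n2, root_jp,
                                  window=8)
    root_consistent = root_regions is None or (k_mem is not None and k_mem == k_ref)

    if member.library == VJ and ev is not None and ev.stable and root_consistent \
            and member.v_call and reference.v_call \
            and gene_name(member.v_call) != gene_name(reference.v_call):
        region = ev.prefix[len(anatomy.v_part):] if ev.prefix else ""
        hit = find_vh_footprint(member, candidate_vs, catalog, policy,
                                region=region)
        required = (policy.min_footprint_evidence if ev.tail_informative
                    else policy.weak_context_footprint)
        if hit is not None and len(hit[0]) >= required:
            footprint, source_v = hit
            try:
                upstream = not catalog.is_downstream(member.v_call, source_v) \
                    and gene_name(member.v_call) != gene_name(source_v)
            except LocusError:
                upstream = False
            mm.mechanism = VH_REPLACEMENT
            mm.footprint = footprint
            mm.footprint_source_v = source_v
            mm.upstream_incoming_flag = upstream
            return mm

    if member.library == DJ:
        mm.mechanism = D_TO_DJ
        return mm
    if anatomy.is_tandem and not (ev is not None and ev.stable):
        # a VJ member with an apparent upstream D *and* a fully preserved
        # reference context is more likely decomposition jitter inside
        # the inherited N1 than a genuine tandem
        mm.mechanism = D_TO_DJ
        return mm

    eroded = False
    if root_regions is not None:
        eroded = k_mem is None or k_mem > 0
    elif ev is not None:
        eroded = ev.erosion is None or ev.erosion > tol
    fresh = ev is not None and ev.tail_preserved is False
    if member.library == VJ and (eroded or fresh):
        mm.mechanism = V_TO_DJ
    return mm


def classify_family(kept_members: Sequence[Clonotype], catalog: LocusCatalog,
                    policy: MechanismPolicy = MechanismPolicy(),
                    dj_root: Optional[Clonotype] = None,
                    rooted: bool = False,
                    stem_id: str = "") -> StemMechanismCall:
    """Classify every kept member of an evolving family and summarize.

    ``kept_members`` must be the noise-filtered members sorted by read
    count descending (the first is the family reference / top member).
    """
    if not kept_members:
        return StemMechanismCall(stem_id=stem_id, summary=UNDETERMINED, member_calls=[])
    mothers = mother_candidates(kept_members, policy)
    reference = mothers[0]
    # root reconstruction for erosion checks: the DJ-library root when
    # rooted, otherwise the least-eroded (longest-D) kept member; its N2
    # and J regions are family-shared by stem identity
    root_regions: Optional[Tuple[str, str, str]] = None
    if dj_root is not None and dj_root.anatomy is not None \
            and dj_root.anatomy.d_part:
        a = dj_root.anatomy
        root_regions = (a.d_part, a.n2, a.j_part)
    else:
        longest = None
        for m in kept_members:
            if m.anatomy is not None and m.anatomy.d_part and (
                    longest is None
                    or len(m.anatomy.d_part) > len(longest.anatomy.d_part)):
                longest = m
        if longest is not None:
            a = longest.anatomy
            root_regions = (a.d_part, a.n2, a.j_part)
    calls: List[MemberMechanism] = []
    for m in kept_members:
        # candidate replaced Vs: abundant mothers plus any more-abundant
        # kept member — supports multi-round replacement chains where the
        # intermediate V is itself not an abundant mother
        cand: List[str] = []
        for c in list(mothers) + [k for k in kept_members if k.read_count > m.read_count]:
            if c.v_call and c.clonotype_id != m.clonotype_id:
                g = c.v_call
                if g not in cand:
                    cand.append(g)
        calls.append(classify_member(m, reference, cand, catalog, policy,
                                     root_regions=root_regions))
    return summarize_stem(calls, rooted=rooted, policy=policy, stem_id=stem_id,
                          mother_id=reference.clonotype_id,
                          dj_root_id=dj_root.clonotype_id if dj_root else None)


def summarize_stem(member_calls: Sequence[MemberMechanism], rooted: bool,
                   policy: MechanismPolicy = MechanismPolicy(),
                   stem_id: str = "", mother_id: Optional[str] = None,
                   dj_root_id: Optional[str] = None) -> StemMechanismCall:
    """Majority mechanism over classified members; *mixed* when both the
    replacement and the recombination class exceed the mixed fraction."""
    classified = [c for c in member_calls if c.mechanism != UNDETERMINED]
    out = StemMechanismCall(stem_id=stem_id, summary=UNDETERMINED,
                            member_calls=list(member_calls),
                            dj_root_present=rooted)
    if not classified:
        return out
    n = len(classified)
    n_vh = sum(1 for c in classified if c.mechanism == VH_REPLACEMENT)
    n_rec = sum(1 for c in classified if c.mechanism in _RECOMBINATION_CLASS)
    if n_vh / n > policy.mixed_fraction and n_rec / n > policy.mixed_fraction:
        out.summary = MIXED
        out.mother_id = mother_id
    elif n_vh > n_rec:
        out.summary = VH_REPLACEMENT
        out.mother_id = mother_id
    else:
        out.summary = DV_TO_DJ
        out.mother_id = dj_root_id if rooted else None
    return out
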