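"""Junction decomposition and DNJ-stem extraction/grouping.

The *DNJ-stem* of a junction is the suffix made of the last at most 3
nucleotides of the D region (or, when no D is identifiable in a VJ
rearrangement, of the N region), any N nucleotides between D and J (N2),
and all J nucleotides.  This suffix is the part of the junction that
stays stable through ongoing D/V-to-DJ recombination and V_H
replacement, so identical stems link clonally related clonotypes into a
*stem family*.

Decomposition model
-------------------
The junction is split left-to-right into V | N1 | [D_upstream | N0] |
D | N2 | J by exact, ungapped germline matching:

* ``j_part`` — the longest common suffix of the junction and the called
  germline J (>= 4 nt; the J 5' end is trimmed during recombination, its
  3' end is conserved through the junction's end).
* ``v_part`` — the longest junction prefix matching the 3'-terminal
  window of the called germline V, allowing 3' trimming of the V.
* ``d_part`` — exact-substring matching against the whole D catalog.
  Among *strong* matches (length >= ``min_d_strong``) the most J-proximal
  one wins; if none is strong, the longest match of length >=
  ``min_d_match`` wins (ties: most J-proximal, then smallest-rank D).
  The J-proximal preference among strong matches keeps decomposition
  consistent across all members of a family (everything 3' of the true D
  is family-shared) and puts the *root* D, not a longer incoming D, into
  the stem of D-D tandem fusions.
* a second disjoint match of length >= ``min_d2_match`` located 5' of
  ``d_part`` becomes ``d_upstream_part`` (D-D tandem); the leftovers are
  the N regions.

All matching is deterministic; identical inputs give identical anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .io import DJ, VJ, Clonotype, SampleRepertoire, abundance_percent
from .locus import LocusCatalog

__all__ = [
    "JunctionAnatomy",
    "DnjStem",
    "StemFamily",
    "DecompositionError",
    "DecompositionParams",
    "decompose_junction",
    "extract_dnj_stem",
    "annotate_repertoire",
    "group_by_stem",
    "detect_root",
    "anatomy_from_np_hints",
]


class DecompositionError(ValueError):
    """Junction cannot be decomposed (record is quarantined upstream)."""


@dataclass(frozen=True)
class DecompositionParams:
    """Exact-match thresholds for region inference.

    min_d_match: shortest catalog-D substring accepted as a D region.
    min_d_strong: matches at least this long are trusted enough that the
        most J-proximal of them is taken over longer, more 5' ones.
    min_d2_match: shortest second (upstream, tandem) D match; higher than
        min_d_match because chance matches in fresh N1 regions are common
        at short lengths while tandem incoming Ds are near full length.
    v_window / max_v_trim: search window at the V 3' end.
    min_j_match: shortest junction/germline-J common suffix.
    """

    min_d_match: int = 5
    min_d_strong: int = 8
    min_d2_match: int = 8
    min_j_match: int = 4
    min_v_match: int = 4
    v_window: int = 14
    max_v_trim: int = 6


@dataclass(frozen=True)
class JunctionAnatomy:
    """Region split of one junction; concatenation restores the junction."""

    v_part: str = ""
    n1: str = ""
    d_upstream_part: str = ""
    n0: str = ""
    d_part: str = ""
    n2: str = ""
    j_part: str = ""

    @property
    def junction(self) -> str:
        return (self.v_part + self.n1 + self.d_upstream_part + self.n0
                + self.d_part + self.n2 + self.j_part)

    @property
    def is_tandem(self) -> bool:
        return bool(self.d_upstream_part)


@dataclass(frozen=True)
class DnjStem:
    """The junction suffix keying a clonal family."""

    stem: str
    d_contribution: str
    n2_contribution: str
    j_contribution: str
    from_n_fallback: bool = False

    def __post_init__(self) -> None:
        assert self.stem == self.d_contribution + self.n2_contribution + self.j_contribution
        assert len(self.d_contribution) <= 3


def _common_suffix_len(a: str, b: str) -> int:
    n = 0
    for x, y in zip(reversed(a), reversed(b)):
        if x != y:
            break
        n += 1
    return n


def _match_v_part(middle: str, v_seq: str, p: DecompositionParams) -> str:
    """Longest junction prefix matching the V 3' window under <=max_v_trim
    3'-trimming; ties resolved toward the least-trimmed alignment."""
    best = 0
    limit = min(len(middle), p.v_window)
    for trim in range(p.max_v_trim + 1):
        end = len(v_seq) - trim
        if end <= 0:
            break
        for k in range(limit, best, -1):
            if end - k < 0:
                continue
            if middle[:k] == v_seq[end - k:end]:
                best = k
                break
    return middle[:best] if best >= p.min_v_match else ""


def _maximal_d_matches(rest: str, index: Dict[str, str], min_len: int,
                       max_len: int) -> List[Tuple[int, int]]:
    """(start, length) of the longest catalog-D match at each start position."""
    out: List[Tuple[int, int]] = []
    n = len(rest)
    for start in range(n - min_len + 1):
        length = 0
        hi = min(max_len, n - start)
        k = min_len
        if rest[start:start + k] not in index:
            continue
        length = k
        while length < hi and rest[start:start + length + 1] in index:
            length += 1
        out.append((start, length))
    return out


def decompose_junction(junction: str, v_call: Optional[str], j_call: str,
                       catalog: LocusCatalog,
                       params: DecompositionParams = DecompositionParams()
                       ) -> JunctionAnatomy:
    """Split a junction into germline-anchored regions (see module docstring).

    Raises :class:`DecompositionError` when no J match of at least
    ``min_j_match`` nt is found; callers quarantine such records.
    """
    junction = junction.upper()
    j_seq = catalog.get(j_call).sequence
    j_len = _common_suffix_len(junction, j_seq)
    j_len = min(j_len, len(junction) - 1)  # never consume the whole junction
    if j_len < params.min_j_match:
        raise DecompositionError(
            f"no J match >= {params.min_j_match} nt for {j_call} in {junction}"
        )
    j_part = junction[len(junction) - j_len:]
    middle = junction[:len(junction) - j_len]

    v_part = ""
    if v_call is not None:
        v_seq = catalog.get(v_call).sequence
        v_part = _match_v_part(middle, v_seq, params)
    rest = middle[len(v_part):]

    index = catalog.d_substring_index(min_len=min(params.min_d_match, params.min_d2_match, 4))
    max_d_len = max(len(s.sequence) for s in catalog.of_type("D"))
    matches = _maximal_d_matches(rest, index, params.min_d_match, max_d_len)

    d_start = d_len = None
    strong = [(s, l) for s, l in matches if l >= params.min_d_strong]
    if strong:
        # most J-proximal end wins; ties toward the longer match
        d_start, d_len = max(strong, key=lambda m: (m[0] + m[1], m[1]))
    elif matches:
        d_start, d_len = max(matches, key=lambda m: (m[1], m[0] + m[1]))

    if d_start is None:
        return JunctionAnatomy(v_part=v_part, n1=rest, j_part=j_part)

    # second, disjoint upstream match (D-D tandem)
    left = rest[:d_start]
    up_start = up_len = None
    if len(left) >= params.min_d2_match:
        lmatches = [(s, l) for s, l in _maximal_d_matches(left, index, params.min_d2_match, max_d_len)
                    if s + l <= len(left)]
        if lmatches:
            up_start, up_len = max(lmatches, key=lambda m: (m[1], m[0] + m[1]))

    if up_start is not None:
        return JunctionAnatomy(
            v_part=v_part,
            n1=left[:up_start],
            d_upstream_part=left[up_start:up_start + up_len],
            n0=left[up_start + up_len:],
            d_part=rest[d_start:d_start + d_len],
            n2=rest[d_start + d_len:],
            j_part=j_part,
        )
    return JunctionAnatomy(
        v_part=v_part, n1=left,
        d_part=rest[d_start:d_start + d_len],
        n2=rest[d_start + d_len:], j_part=j_part,
    )


def extract_dnj_stem(anatomy: JunctionAnatomy) -> DnjStem:
    """DNJ-stem of a decomposed junction.

    Last <=3 D nucleotides (or of the N region when no D was identified —
    the N-fallback of D-less VJ rearrangements), plus N2, plus all J
    nucleotides.
    """
    if not anatomy.j_part:
        raise ValueError("anatomy has an empty j_part")
    if anatomy.d_part:
        d_contrib = anatomy.d_part[-3:]
        fallback = False
    else:
        d_contrib = anatomy.n1[-3:] if anatomy.n1 else ""
        fallback = True
    return DnjStem(
        stem=d_contrib + anatomy.n2 + anatomy.j_part,
        d_contribution=d_contrib,
        n2_contribution=anatomy.n2,
        j_contribution=anatomy.j_part,
        from_n_fallback=fallback,
    )


def anatomy_from_np_hints(clono: Clonotype, np1: str, np2: str,
                          catalog: LocusCatalog,
                          params: DecompositionParams = DecompositionParams()
                          ) -> Optional[JunctionAnatomy]:
    """Pre-fill anatomy from AIRR np1/np2 columns when the split is unambiguous.

    Uses germline-anchored v/j parts and accepts the hint only when the
    remaining middle is exactly np1 + D + np2.  Returns None otherwise.
    """
    np1, np2 = np1.strip().upper(), np2.strip().upper()
    junction = clono.junction
    j_seq = catalog.get(clono.j_call).sequence
    j_len = min(_common_suffix_len(junction, j_seq), len(junction) - 1)
    if j_len < params.min_j_match:
        return None
    middle = junction[:len(junction) - j_len]
    v_part = ""
    if clono.v_call is not None:
        v_part = _match_v_part(middle, catalog.get(clono.v_call).sequence, params)
    rest = middle[len(v_part):]
    if not (rest.startswith(np1) and rest.endswith(np2)):
        return None
    d_part = rest[len(np1):len(rest) - len(np2)] if len(np1) + len(np2) <= len(rest) else None
    if d_part is None:
        return None
    return JunctionAnatomy(v_part=v_part, n1=np1, d_part=d_part, n2=np2,
                           j_part=junction[len(junction) - j_len:])


# -- grouping --------------------------------------------------------------

@dataclass
class StemFamily:
    """All clonotypes of one sample/library sharing a DNJ-stem."""

    stem: DnjStem
    sample_id: str
    library: str
    members: List[Clonotype]
    total_reads: int = 0
    total_percent: float = 0.0
    rooted: bool = False

    @property
    def top_member(self) -> Clonotype:
        return self.members[0]

    @property
    def stem_str(self) -> str:
        return self.stem.stem


def annotate_repertoire(rep: SampleRepertoire, catalog: LocusCatalog,
                        params: DecompositionParams = DecompositionParams()
                        ) -> SampleRepertoire:
    """Decompose every clonotype's junction in place; quarantine failures.

    Records whose junction cannot be anchored to the called J are removed
    from the repertoire and counted (with reasons) in the load report.
    """
    kept: List[Clonotype] = []
    for c in rep.clonotypes:
        if c.anatomy is None:
            try:
                c.anatomy = decompose_junction(c.junction, c.v_call, c.j_call,
                                               catalog, params)
            except DecompositionError as exc:
                rep.load_report.quarantined_decomposition += 1
                rep.load_report.quarantine_reasons.append(f"{c.clonotype_id}: {exc}")
                continue
        kept.append(c)
    rep.clonotypes = kept
    return rep


def _member_order_key(c: Clonotype):
    return (-c.read_count, c.junction)


def group_by_stem(rep: SampleRepertoire) -> List[StemFamily]:
    """Partition a repertoire into stem families by exact stem equality.

    Families are sorted by total reads descending (ties: stem string);
    members by read count descending with a lexicographic junction
    tie-break, so the partition is invariant to input order.
    """
    buckets: Dict[str, List[Clonotype]] = {}
    stems: Dict[str, DnjStem] = {}
    for c in rep.clonotypes:
        if c.anatomy is None:
            raise ValueError(f"{c.clonotype_id}: anatomy missing; run annotate_repertoire first")
        stem = extract_dnj_stem(c.anatomy)
        buckets.setdefault(stem.stem, []).append(c)
        stems.setdefault(stem.stem, stem)
    families: List[StemFamily] = []
    for s, members in buckets.items():
        members.sort(key=_member_order_key)
        total = sum(m.read_count for m in members)
        families.append(StemFamily(
            stem=stems[s], sample_id=rep.sample_id, library=rep.library,
            members=members, total_reads=total,
            total_percent=abundance_percent(total, rep),
        ))
    families.sort(key=lambda f: (-f.total_reads, f.stem_str))
    return families


def detect_root(vj_families: Sequence[StemFamily],
                dj_families: Sequence[StemFamily]) -> None:
    """Flag stems found in both libraries as *rooted* (exact stem equality).

    A rooted VJ stem indicates that the underlying incomplete DJ
    rearrangement (the DJ root) is itself detectable in the IGH-DJ
    library.  The flag is set symmetrically on both families in place.
    """
    dj_by_stem = {f.stem_str: f for f in dj_families}
    for f in vj_families:
        match = dj_by_stem.get(f.stem_str)
        if match is not None:
            f.rooted = True
            match.rooted = True
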