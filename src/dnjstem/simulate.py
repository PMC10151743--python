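"""Synthetic two-library IGH amplicon repertoires with known ground truth.

The generator emulates the statistical structure that the DNJ-stem
analysis assumes in a diagnostic BCP-ALL sample:

* stable leukemic clones (one VDJ rearrangement per stem);
* V-DJ recombination *bursts*: many lowly abundant members sharing one
  DJ root, each with a freshly drawn V (biased toward the most
  D-proximal V gene), a fresh N1 and independent 5' erosion of the root
  D — the root itself usually detectable in the IGH-DJ library;
* multi-round V_H-replacement chains: an abundant mother clonotype whose
  V is successively exchanged for a strictly downstream V, leaving a
  <= 5 nt footprint of the replaced V inside the new N1 while D, N2 and
  J are untouched;
* D-D tandem fusions in the IGH-DJ library (an incoming D, biased toward
  one designated segment, joins 5' of the eroded root D);
* PCR/sequencing-error satellite clonotypes around abundant parents;
* polyclonal background rearrangements filling the remaining depth; and
* cIT-QC spike-in reads for read-to-cell normalization.

All randomness flows through one :class:`numpy.random.Generator`; the
same config and seed give byte-identical output files.

Satellite substitutions are placed only at junction positions 5' of the
stem suffix: an error inside the stem would change the stem itself and
the erroneous read would no longer link to the family (a real
phenomenon, but then it is not a *family* noise problem; see the
methods note for this limitation).  Stems of leukemic clones and of the
polyclonal background are kept globally unique by rejection sampling,
emulating the near-perfect cross-patient specificity of real stems.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .io import (DJ, VJ, Clonotype, SampleMeta, SampleRepertoire,
                 write_airr_sample)
from .locus import LocusCatalog, toy_catalog
from .stems import JunctionAnatomy

__all__ = [
    "SimulationConfig",
    "TruthLabels",
    "StemTruth",
    "CohortData",
    "simulate_rearrangement",
    "simulate_dj_root",
    "simulate_burst",
    "simulate_replacement_chain",
    "simulate_d_dj_tandem",
    "add_satellites_and_noise",
    "simulate_cohort",
    "emit_cohort",
    "noise_fixture",
]

BASES = np.array(list("ACGT"))

# how much of the germline V 3' end enters the junction before trimming
V_JUNCTION_WINDOW = 10

MECH_BURST = "DV_to_DJ"
MECH_REPLACEMENT = "VH_replacement"
MECH_TANDEM = "D_to_DJ"
MECH_MIXED = "mixed"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the default synthetic cohort.

    Defaults describe a dense diagnostic cohort: 25 patients, each with 2
    evolving and 4 stable leukemic stems, 50,000 usable reads per
    library, a leukemic read fraction of 0.8 at diagnosis, and the
    mechanism mix skewed toward ongoing V-DJ recombination as observed
    in BCP-ALL.  Every distribution is exposed here.
    """

    seed: int = 1
    scenario: str = "diagnosis_only"  # | bm_pb_pair | longitudinal
    n_patients: int = 25
    n_evolving_stems_per_patient: int = 2
    n_stable_stems_per_patient: int = 4
    # probabilities of DV_to_DJ, VH_replacement, D_to_DJ, mixed
    mechanism_mix: Tuple[float, float, float, float] = (0.70, 0.22, 0.05, 0.03)
    # burst sizes: burst_size_min + Geometric (mean burst_size_mean), capped
    burst_size_min: int = 4
    burst_size_mean: float = 8.0
    burst_size_max: int = 400
    replacement_rounds_min: int = 2
    replacement_rounds_max: int = 4
    tandem_count_min: int = 3
    tandem_count_max: int = 7
    trim_max: int = 4                # uniform 0..trim_max nt per segment end
    n_mean: float = 4.0              # geometric N-region length, background/N1
    n_max: int = 12
    leukemic_n2_min: int = 2         # leukemic stems carry an informative N2
    leukemic_n2_mean: float = 5.0
    fresh_n_mean: float = 2.0        # fresh N in replacement N1
    v_usage_bias: float = 5.0        # weight for the rank-1 (D-proximal) V in bursts
    d_tandem_bias: float = 5.0       # weight for the designated incoming D in tandems
    footprint_probs: Tuple[float, ...] = (0.10, 0.10, 0.20, 0.25, 0.20, 0.15)
    error_rate: float = 0.002        # per-base substitution (satellite model)
    satellite_mean: float = 2.0      # Poisson per eligible abundant clonotype
    satellite_min_parent_percent: float = 0.5
    depth: int = 50_000              # usable reads per sample/library
    leukemic_fraction: float = 0.8   # of usable reads at diagnosis (VJ library)
    dj_leukemic_fraction: float = 0.4
    n_background_vj: int = 300
    n_background_dj: int = 300
    background_alpha: float = 2.0  # flatter than the leukemic shares
    dirichlet_alpha_stems: float = 1.0
    # every leukemic stem keeps at least this share of the leukemic mass,
    # so that truth-labelled family members are realizable above the
    # analysis noise floor at the configured depth
    min_stem_share: float = 0.02
    dirichlet_alpha_members: float = 1.0
    qc_fraction: float = 0.04        # QC reads as a fraction of depth
    qc_cell_equivalents: float = 100.0
    root_emission_probs: Tuple[Tuple[str, float], ...] = (
        (MECH_BURST, 0.9), (MECH_REPLACEMENT, 0.1),
        (MECH_TANDEM, 1.0), (MECH_MIXED, 0.9), ("stable", 0.3),
    )
    pro_b_fraction: float = 0.2
    # scenario knobs
    pb_subsample: float = 0.1
    followups: Tuple[Tuple[str, float], ...] = (("day6", 0.05), ("day22", 0.005))
    kill_top_member: bool = True     # eradicate the top of the lead evolving stem
    followup_new_members: int = 2    # fresh burst members appearing at the last timepoint

    def validate(self) -> None:
        problems = []
        if abs(sum(self.mechanism_mix) - 1.0) > 1e-9:
            problems.append("mechanism_mix must sum to 1")
        if any(p < 0 for p in self.mechanism_mix):
            problems.append("mechanism_mix probabilities must be >= 0")
        if abs(sum(self.footprint_probs) - 1.0) > 1e-9:
            problems.append("footprint_probs must sum to 1")
        if not 0 < self.leukemic_fraction < 1:
            problems.append("leukemic_fraction must be in (0,1)")
        if self.depth <= 0 or self.n_patients <= 0:
            problems.append("depth and n_patients must be positive")
        if self.scenario not in ("diagnosis_only", "bm_pb_pair", "longitudinal"):
            problems.append(f"unknown scenario {self.scenario!r}")
        if problems:
            raise ValueError("invalid SimulationConfig: " + "; ".join(problems))


# -- elementary draws ------------------------------------------------------

def _geom0(rng: np.random.Generator, mean: float, cap: int) -> int:
    """Geometric on {0,1,...} with the given mean, capped."""
    p = 1.0 / (mean + 1.0)
    return int(min(rng.geometric(p) - 1, cap))


def _nt(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return "".join(BASES[rng.integers(0, 4, n)])


@dataclass
class SimRearrangement:
    """A simulated rearrangement with its generative (true) anatomy."""

    v_call: Optional[str]
    d_call: Optional[str]
    d2_call: Optional[str]
    j_call: str
    v_part: str = ""
    n1: str = ""
    d2_part: str = ""
    n0: str = ""
    d_part: str = ""
    n2: str = ""
    j_part: str = ""

    @property
    def junction(self) -> str:
        return (self.v_part + self.n1 + self.d2_part + self.n0
                + self.d_part + self.n2 + self.j_part)

    @property
    def true_stem(self) -> str:
        d3 = self.d_part[-3:] if self.d_part else self.n1[-3:]
        return d3 + self.n2 + self.j_part

    def true_anatomy(self) -> JunctionAnatomy:
        return JunctionAnatomy(v_part=self.v_part, n1=self.n1,
                               d_upstream_part=self.d2_part, n0=self.n0,
                               d_part=self.d_part, n2=self.n2, j_part=self.j_part)


def _draw_v_region(catalog: LocusCatalog, rng, v_name: str, trim_max: int) -> str:
    seq = catalog.get(v_name).sequence
    trim = int(rng.integers(0, trim_max + 1))
    window = seq[-V_JUNCTION_WINDOW:]
    return window[: len(window) - trim]


def _pick_v(catalog: LocusCatalog, rng, bias_rank1: float = 1.0) -> str:
    vs = catalog.of_type("V")
    w = np.ones(len(vs))
    w[0] = bias_rank1  # vs sorted by rank; rank 1 = most D-proximal
    w /= w.sum()
    return vs[int(rng.choice(len(vs), p=w))].name


def simulate_rearrangement(catalog: LocusCatalog, rng: np.random.Generator,
                           library: str = VJ,
                           config: SimulationConfig = SimulationConfig(),
                           leukemic: bool = False,
                           v_name: Optional[str] = None) -> SimRearrangement:
    """One random V(D)J (or DJ) rearrangement.

    Segment ends are trimmed uniformly on 0..trim_max; N regions are
    geometric-length uniform-base strings.  ``leukemic=True`` draws the
    N2 from the leukemic distribution (minimum length enforced) so the
    resulting stem carries an informative N region.
    """
    ds = catalog.of_type("D")
    js = catalog.of_type("J")
    d = ds[int(rng.integers(0, len(ds)))]
    j = js[int(rng.integers(0, len(js)))]
    t5, t3 = rng.integers(0, config.trim_max + 1, 2)
    d_part = d.sequence[int(t5): len(d.sequence) - int(t3)]
    tj = int(rng.integers(0, config.trim_max + 1))
    j_part = j.sequence[tj:]
    if leukemic:
        # leukemic stems carry an *observably* informative N2: at least 2
        # distinct bases, and the boundary bases must not continue the
        # trimmed D/J germline (an N that mimics germline is, to any
        # observer, germline — and the resulting stem would be borderline)
        forbid_left = d.sequence[len(d.sequence) - int(t3)] if t3 > 0 else None
        forbid_right = j.sequence[tj - 1] if tj > 0 else None
        for _ in range(100):
            n2 = _nt(rng, max(2, config.leukemic_n2_min)
                     + _geom0(rng, config.leukemic_n2_mean - config.leukemic_n2_min,
                              config.n_max - config.leukemic_n2_min))
            if (n2[0] != forbid_left and n2[-1] != forbid_right
                    and len(set(n2)) >= 2):
                break
    else:
        n2 = _nt(rng, _geom0(rng, config.n_mean, config.n_max))
    rearr = SimRearrangement(v_call=None, d_call=d.name, d2_call=None,
                             j_call=j.name, d_part=d_part, n2=n2, j_part=j_part)
    if library == VJ:
        v = v_name or _pick_v(catalog, rng)
        rearr.v_call = v
        rearr.v_part = _draw_v_region(catalog, rng, v, config.trim_max)
        rearr.n1 = _nt(rng, _geom0(rng, config.n_mean, config.n_max))
    return rearr


def simulate_dj_root(catalog: LocusCatalog, rng: np.random.Generator,
                     config: SimulationConfig) -> SimRearrangement:
    """A leukemic incomplete DJ rearrangement (the root of a stem)."""
    return simulate_rearrangement(catalog, rng, library=DJ, config=config,
                                  leukemic=True)


def simulate_burst(root: SimRearrangement, size: int, catalog: LocusCatalog,
                   rng: np.random.Generator,
                   config: SimulationConfig = SimulationConfig()
                   ) -> List[SimRearrangement]:
    """V-DJ recombination burst on a DJ root.

    Every member draws a fresh (rank-1-biased) V and N1 and erodes the
    root D 5' end independently by 0..trim_max nt; the D 3' end, N2 and
    J are copied unchanged, so all members share the root's stem.
    """
    members = []
    for _ in range(size):
        v = _pick_v(catalog, rng, bias_rank1=config.v_usage_bias)
        erosion = int(rng.integers(0, config.trim_max + 1))
        members.append(SimRearrangement(
            v_call=v, d_call=root.d_call, d2_call=None, j_call=root.j_call,
            v_part=_draw_v_region(catalog, rng, v, config.trim_max),
            n1=_nt(rng, _geom0(rng, config.n_mean, config.n_max)),
            d_part=root.d_part[erosion:],
            n2=root.n2, j_part=root.j_part,
        ))
    return members


def simulate_replacement_chain(mother: SimRearrangement, rounds: int,
                               catalog: LocusCatalog, rng: np.random.Generator,
                               config: SimulationConfig = SimulationConfig()
                               ) -> List[Tuple[SimRearrangement, int, str]]:
    """Multi-round V_H replacement of a mother clonotype.

    Each round exchanges the current V for a strictly downstream one and
    rebuilds N1 as fresh N + a footprint of the replaced V (length drawn
    from ``footprint_probs``; 0 = erased) + the surviving old N1.  D, N2
    and J are untouched, so the mother's stem is preserved.  Returns
    (member, planted footprint length, replaced V) per round; the chain
    truncates (logged by shorter output) when no downstream V remains.
    """
    out: List[Tuple[SimRearrangement, int, str]] = []
    current = mother
    v_ranks = {s.name: s.locus_rank for s in catalog.of_type("V")}
    max_rank = max(v_ranks.values())
    for i in range(rounds):
        cur_rank = v_ranks[current.v_call]
        remaining_after = rounds - i - 1
        # keep enough downstream headroom for the remaining rounds so a
        # requested chain length is actually realizable on the locus
        downstream = [n for n, r in v_ranks.items()
                      if r > cur_rank and max_rank - r >= remaining_after]
        if not downstream:
            downstream = [n for n, r in v_ranks.items() if r > cur_rank]
        if not downstream:
            break
        incoming = downstream[int(rng.integers(0, len(downstream)))]
        fp_len = int(rng.choice(len(config.footprint_probs), p=np.array(config.footprint_probs)))
        footprint = catalog.get(current.v_call).sequence[-fp_len:] if fp_len else ""
        member = SimRearrangement(
            v_call=incoming, d_call=current.d_call, d2_call=None,
            j_call=current.j_call,
            v_part=_draw_v_region(catalog, rng, incoming, config.trim_max),
            n1=_nt(rng, _geom0(rng, config.fresh_n_mean, 6)) + footprint + current.n1,
            d_part=current.d_part, n2=current.n2, j_part=current.j_part,
        )
        out.append((member, fp_len, current.v_call))
        current = member
    return out


def simulate_d_dj_tandem(root: SimRearrangement, catalog: LocusCatalog,
                         rng: np.random.Generator,
                         config: SimulationConfig = SimulationConfig()
                         ) -> SimRearrangement:
    """A D-D tandem fusion member in the IGH-DJ library.

    An incoming D (biased toward the designated rank-2 segment, the
    analogue of the real locus's favourite incoming D) joins 5' of the
    possibly eroded root D with a fresh N0; the stem is preserved.
    """
    ds = catalog.of_type("D")
    w = np.ones(len(ds))
    if len(ds) > 1:
        w[1] = config.d_tandem_bias  # designated incoming segment (rank 2)
    w /= w.sum()
    incoming = ds[int(rng.choice(len(ds), p=w))]
    t5, t3 = rng.integers(0, config.trim_max + 1, 2)
    d2_part = incoming.sequence[int(t5): len(incoming.sequence) - int(t3)]
    erosion = int(rng.integers(0, config.trim_max + 1))
    return SimRearrangement(
        v_call=None, d_call=root.d_call, d2_call=incoming.name,
        j_call=root.j_call,
        d2_part=d2_part, n0=_nt(rng, _geom0(rng, config.n_mean, config.n_max)),
        d_part=root.d_part[erosion:], n2=root.n2, j_part=root.j_part,
    )


# -- truth bookkeeping -----------------------------------------------------

@dataclass
class MemberTruth:
    clonotype_id: str
    library: str
    mechanism: str                  # founder | root | V_to_DJ | VH_replacement | D_to_DJ
    footprint_len: int = 0
    replaced_v: Optional[str] = None


@dataclass
class StemTruth:
    stem_id: str
    patient_id: str
    stem: str                       # generative stem string
    evolving: bool
    mechanism: str                  # stable | DV_to_DJ | VH_replacement | D_to_DJ | mixed
    dj_root_emitted: bool = False
    dj_root_id: Optional[str] = None
    mother_id: Optional[str] = None
    members: List[MemberTruth] = field(default_factory=list)
    killed_top_member_id: Optional[str] = None

    def member_ids(self, library: Optional[str] = None) -> List[str]:
        return [m.clonotype_id for m in self.members
                if library is None or m.library == library]


@dataclass
class SatelliteTruth:
    clonotype_id: str
    parent_id: str
    library: str
    n_substitutions: int


@dataclass
class TruthLabels:
    stems: List[StemTruth] = field(default_factory=list)
    satellites: List[SatelliteTruth] = field(default_factory=list)
    immunophenotype: Dict[str, str] = field(default_factory=dict)

    def clonotype_index(self) -> Dict[str, str]:
        """clonotype id -> truth tag (stem_id, 'satellite:<parent>' or set by caller)."""
        idx: Dict[str, str] = {}
        for st in self.stems:
            for m in st.members:
                idx[m.clonotype_id] = st.stem_id
        for sat in self.satellites:
            idx[sat.clonotype_id] = f"satellite:{sat.parent_id}"
        return idx

    def to_json(self) -> str:
        return json.dumps({
            "stems": [asdict(s) for s in self.stems],
            "satellites": [asdict(s) for s in self.satellites],
            "immunophenotype": self.immunophenotype,
        }, indent=1)


@dataclass
class CohortData:
    config: SimulationConfig
    truth: TruthLabels
    # (sample_id, library) -> repertoire; metadata mirrors io.read_metadata
    samples: Dict[Tuple[str, str], SampleRepertoire]
    metadata: List[SampleMeta]

    def sample(self, sample_id: str, library: str) -> SampleRepertoire:
        return self.samples[(sample_id, library)]

    def patient_samples(self, patient_id: str) -> List[SampleRepertoire]:
        return [r for r in self.samples.values() if r.meta.patient_id == patient_id]


# -- patient-level assembly ------------------------------------------------

class _StemRegistry:
    """Global uniqueness of stem strings via rejection sampling."""

    def __init__(self) -> None:
        self.seen: Set[str] = set()

    def admit(self, stem: str) -> bool:
        if stem in self.seen:
            return False
        self.seen.add(stem)
        return True


def _unique_root(catalog, rng, config, registry: _StemRegistry) -> SimRearrangement:
    for _ in range(200):
        root = simulate_dj_root(catalog, rng, config)
        if registry.admit(root.true_stem):
            return root
    raise RuntimeError("could not draw a unique stem in 200 attempts")


def _burst_size(rng, config) -> int:
    extra = _geom0(rng, config.burst_size_mean - config.burst_size_min,
                   config.burst_size_max - config.burst_size_min)
    return config.burst_size_min + extra


@dataclass
class _PatientPlan:
    """Everything needed to emit one patient's samples at any timepoint."""

    patient_id: str
    stems: List[StemTruth]
    vj_members: Dict[str, List[Tuple[str, SimRearrangement, float]]]  # stem_id -> (cid, rearr, weight)
    dj_members: Dict[str, List[Tuple[str, SimRearrangement, float]]]
    stem_weights: Dict[str, float]       # VJ-library stem shares
    dj_stem_weights: Dict[str, float]


def _plan_patient(patient_id: str, catalog: LocusCatalog, rng, config: SimulationConfig,
                  registry: _StemRegistry) -> _PatientPlan:
    mech_names = (MECH_BURST, MECH_REPLACEMENT, MECH_TANDEM, MECH_MIXED)
    root_prob = dict(config.root_emission_probs)
    stems: List[StemTruth] = []
    vj_members: Dict[str, List[Tuple[str, SimRearrangement, float]]] = {}
    dj_members: Dict[str, List[Tuple[str, SimRearrangement, float]]] = {}
    serial = [0]

    def next_id(lib: str) -> str:
        serial[0] += 1
        short = "vj" if lib == VJ else "dj"
        return f"{patient_id}-{short}-{serial[0]:04d}"

    def dirichlet(k: int, alpha: float) -> np.ndarray:
        return rng.dirichlet(np.full(k, alpha)) if k > 1 else np.array([1.0])

    n_stems = config.n_evolving_stems_per_patient + config.n_stable_stems_per_patient
    for s_idx in range(n_stems):
        evolving = s_idx < config.n_evolving_stems_per_patient
        stem_id = f"{patient_id}-S{s_idx + 1}"
        root = _unique_root(catalog, rng, config, registry)
        if evolving:
            mech = mech_names[int(rng.choice(4, p=np.array(config.mechanism_mix)))]
        else:
            mech = "stable"
        truth = StemTruth(stem_id=stem_id, patient_id=patient_id,
                          stem=root.true_stem, evolving=evolving, mechanism=mech)
        vj: List[Tuple[str, SimRearrangement, float]] = []
        dj: List[Tuple[str, SimRearrangement, float]] = []

        def add(lib, rearr, weight, mechanism, fp_len=0, replaced=None):
            cid = next_id(lib)
            (vj if lib == VJ else dj).append((cid, rearr, weight))
            truth.members.append(MemberTruth(clonotype_id=cid, library=lib,
                                             mechanism=mechanism,
                                             footprint_len=fp_len,
                                             replaced_v=replaced))
            return cid

        emit_root = rng.random() < root_prob.get(mech, 0.0) or mech == MECH_TANDEM

        if mech == "stable":
            founder = simulate_rearrangement(catalog, rng, VJ, config, leukemic=False)
            # stable founders sit on the leukemic root: share D/N2/J
            founder.d_call, founder.d_part = root.d_call, root.d_part
            founder.n2, founder.j_part, founder.j_call = root.n2, root.j_part, root.j_call
            add(VJ, founder, 1.0, "founder")
        elif mech == MECH_BURST:
            size = _burst_size(rng, config)
            w = np.sort(dirichlet(size, config.dirichlet_alpha_members))[::-1]
            for i, member in enumerate(simulate_burst(root, size, catalog, rng, config)):
                add(VJ, member, float(w[i]), "V_to_DJ")
        elif mech == MECH_REPLACEMENT:
            mother = simulate_rearrangement(catalog, rng, VJ, config, leukemic=False,
                                            v_name=catalog.of_type("V")[
                                                int(rng.integers(0, max(1, len(catalog.of_type("V")) - 4)))].name)
            mother.d_call, mother.d_part = root.d_call, root.d_part
            mother.n2, mother.j_part, mother.j_call = root.n2, root.j_part, root.j_call
            rounds = int(rng.integers(config.replacement_rounds_min,
                                      config.replacement_rounds_max + 1))
            chain = simulate_replacement_chain(mother, rounds, catalog, rng, config)
            mother_w = 0.55 + 0.25 * rng.random()
            truth.mother_id = add(VJ, mother, mother_w, "founder")
            if chain:
                w = np.sort(dirichlet(len(chain), config.dirichlet_alpha_members))[::-1]
                w = (1.0 - mother_w) * w / w.sum()
                for i, (member, fp_len, replaced) in enumerate(chain):
                    add(VJ, member, float(w[i]), "VH_replacement", fp_len, replaced)
        elif mech == MECH_TANDEM:
            # evolving only in the IGH-DJ library
            n_tandem = int(rng.integers(config.tandem_count_min, config.tandem_count_max + 1))
            w = np.sort(dirichlet(n_tandem, config.dirichlet_alpha_members))[::-1]
            root_w = 0.4
            truth.dj_root_id = add(DJ, root, root_w, "root")
            for i in range(n_tandem):
                member = simulate_d_dj_tandem(root, catalog, rng, config)
                add(DJ, member, float((1 - root_w) * w[i]), "D_to_DJ")
        else:  # mixed: replacement chain and burst on the same stem
            mother = simulate_rearrangement(catalog, rng, VJ, config, leukemic=False,
                                            v_name=catalog.of_type("V")[
                                                int(rng.integers(0, max(1, len(catalog.of_type("V")) - 4)))].name)
            mother.d_call, mother.d_part = root.d_call, root.d_part
            mother.n2, mother.j_part, mother.j_call = root.n2, root.j_part, root.j_call
            chain = simulate_replacement_chain(mother, 2, catalog, rng, config)
            burst = simulate_burst(root, int(rng.integers(3, 6)), catalog, rng, config)
            truth.mother_id = add(VJ, mother, 0.5, "founder")
            n_rest = len(chain) + len(burst)
            w = np.sort(dirichlet(n_rest, config.dirichlet_alpha_members))[::-1]
            w = 0.5 * w / w.sum()
            k = 0
            for member, fp_len, replaced in chain:
                add(VJ, member, float(w[k]), "VH_replacement", fp_len, replaced)
                k += 1
            for member in burst:
                add(VJ, member, float(w[k]), "V_to_DJ")
                k += 1

        if emit_root and mech != MECH_TANDEM:
            truth.dj_root_id = add(DJ, root, 1.0, "root")
        truth.dj_root_emitted = truth.dj_root_id is not None
        stems.append(truth)
        vj_members[stem_id] = vj
        dj_members[stem_id] = dj

    def stem_shares(k: int) -> np.ndarray:
        if k <= 1:
            return np.ones(k)
        shares = rng.dirichlet(np.full(k, config.dirichlet_alpha_stems))
        shares = np.maximum(shares, config.min_stem_share)
        return shares / shares.sum()

    vj_present = [s.stem_id for s in stems if vj_members[s.stem_id]]
    dj_present = [s.stem_id for s in stems if dj_members[s.stem_id]]
    vj_shares = stem_shares(len(vj_present))
    dj_shares = stem_shares(len(dj_present))
    return _PatientPlan(
        patient_id=patient_id, stems=stems,
        vj_members=vj_members, dj_members=dj_members,
        stem_weights={sid: float(w) for sid, w in zip(vj_present, vj_shares)},
        dj_stem_weights={sid: float(w) for sid, w in zip(dj_present, dj_shares)},
    )


def _background_clonotypes(catalog, rng, config, registry: _StemRegistry,
                           library: str, n: int, total_reads: int,
                           sample_id: str, prefix: str) -> List[Clonotype]:
    if total_reads <= 0 or n <= 0:
        return []
    shares = rng.dirichlet(np.full(n, config.background_alpha))
    counts = np.maximum(1, np.round(shares * total_reads).astype(int))
    out = []
    for i in range(n):
        for _ in range(50):
            rearr = simulate_rearrangement(catalog, rng, library, config, leukemic=False)
            if registry.admit(rearr.true_stem):
                break
        c = Clonotype(
            clonotype_id=f"{prefix}-bg{i + 1:04d}",
            sample_id=sample_id, library=library,
            j_call=rearr.j_call, junction=rearr.junction,
            read_count=int(counts[i]),
            v_call=rearr.v_call, d_call=rearr.d_call, d2_call=rearr.d2_call,
            anatomy=rearr.true_anatomy(),
        )
        out.append(c)
    return out


def _satellite_positions(rearr: SimRearrangement) -> List[int]:
    """Junction positions whose substitution provably preserves the stem."""
    if rearr.v_call is not None:
        return list(range(len(rearr.v_part) + len(rearr.n1)))
    # DJ record: 5' part of the (upstream) D / N0 region, keeping any
    # D fragment 3' of the substitution long enough to stay the anchor
    if rearr.d2_part:
        return list(range(len(rearr.d2_part) + len(rearr.n0)))
    L = len(rearr.d_part)
    return list(range(max(0, L - 8)))


def add_satellites_and_noise(clonotypes: List[Clonotype],
                             rearrs: Dict[str, SimRearrangement],
                             rng: np.random.Generator,
                             config: SimulationConfig,
                             usable_target: int) -> List[Tuple[Clonotype, SatelliteTruth]]:
    """PCR/sequencing-error satellites around abundant clonotypes.

    Each clonotype above the parent-abundance floor spawns a Poisson
    number of satellites with 1-2 substitutions at stem-preserving
    junction positions and 1-2 reads (below the noise floor).
    """
    out: List[Tuple[Clonotype, SatelliteTruth]] = []
    floor = config.satellite_min_parent_percent / 100.0 * usable_target
    for parent in clonotypes:
        if parent.read_count < floor or parent.clonotype_id not in rearrs:
            continue
        positions = _satellite_positions(rearrs[parent.clonotype_id])
        if not positions:
            continue
        for k in range(rng.poisson(config.satellite_mean)):
            n_sub = int(rng.integers(1, 3))
            n_sub = min(n_sub, len(positions))
            picked = rng.choice(len(positions), size=n_sub, replace=False)
            junction = list(parent.junction)
            for pi in picked:
                pos = positions[int(pi)]
                alternatives = [b for b in "ACGT" if b != junction[pos]]
                junction[pos] = alternatives[int(rng.integers(0, 3))]
            sat = Clonotype(
                clonotype_id=f"{parent.clonotype_id}-sat{k + 1}",
                sample_id=parent.sample_id, library=parent.library,
                j_call=parent.j_call, junction="".join(junction),
                read_count=int(rng.integers(1, 3)),
                v_call=parent.v_call, d_call=parent.d_call, d2_call=parent.d2_call,
            )
            out.append((sat, SatelliteTruth(
                clonotype_id=sat.clonotype_id, parent_id=parent.clonotype_id,
                library=parent.library, n_substitutions=n_sub,
            )))
    return out


def _emit_sample(plan: _PatientPlan, library: str, catalog, rng,
                 config: SimulationConfig, registry: _StemRegistry,
                 truth: TruthLabels,
                 sample_id: str, compartment: str, timepoint: str,
                 leukemic_fraction: float,
                 weight_override: Optional[Dict[str, float]] = None,
                 with_satellites: bool = True) -> SampleRepertoire:
    """Materialize one sample/library of a patient at a given tumor burden."""
    members = plan.vj_members if library == VJ else plan.dj_members
    stem_w = plan.stem_weights if library == VJ else plan.dj_stem_weights
    frac = leukemic_fraction if library == VJ else min(
        leukemic_fraction * config.dj_leukemic_fraction / config.leukemic_fraction, 0.9)
    leukemic_reads = frac * config.depth
    clonotypes: List[Clonotype] = []
    rearrs: Dict[str, SimRearrangement] = {}
    for stem_id, share in stem_w.items():
        for cid, rearr, w in members[stem_id]:
            eff_w = w
            if weight_override is not None:
                eff_w = weight_override.get(cid, w)
            reads = int(round(eff_w * share * leukemic_reads))
            if timepoint == "day0":
                reads = max(1, reads)  # diagnostic members always detectable
            if reads <= 0:
                continue
            c = Clonotype(clonotype_id=cid, sample_id=sample_id, library=library,
                          j_call=rearr.j_call, junction=rearr.junction,
                          read_count=reads, v_call=rearr.v_call,
                          d_call=rearr.d_call, d2_call=rearr.d2_call,
                          anatomy=rearr.true_anatomy())
            clonotypes.append(c)
            rearrs[cid] = rearr
    n_bg = config.n_background_vj if library == VJ else config.n_background_dj
    bg_reads = config.depth - sum(c.read_count for c in clonotypes)
    clonotypes.extend(_background_clonotypes(
        catalog, rng, config, registry, library, n_bg, bg_reads,
        sample_id, prefix=f"{sample_id}-{'vj' if library == VJ else 'dj'}"))
    if with_satellites:
        for sat, sat_truth in add_satellites_and_noise(
                list(clonotypes), rearrs, rng, config, config.depth):
            clonotypes.append(sat)
            truth.satellites.append(sat_truth)
    meta = SampleMeta(sample_id=sample_id, patient_id=plan.patient_id,
                      compartment=compartment, timepoint_label=timepoint,
                      library=library,
                      qc_cell_equivalents_input=config.qc_cell_equivalents)
    return SampleRepertoire(meta=meta, clonotypes=clonotypes,
                            qc_reads=int(round(config.qc_fraction * config.depth)))


def _thin_repertoire(rep: SampleRepertoire, p: float, rng,
                     sample_id: str, compartment: str) -> SampleRepertoire:
    """Binomial depth-subsampling (e.g. PB drawn shallower than BM)."""
    clonotypes = []
    for c in rep.clonotypes:
        n = int(rng.binomial(c.read_count, p))
        if n > 0:
            clonotypes.append(replace_clonotype(c, sample_id, n))
    meta = SampleMeta(sample_id=sample_id, patient_id=rep.meta.patient_id,
                      compartment=compartment,
                      timepoint_label=rep.meta.timepoint_label,
                      library=rep.meta.library,
                      qc_cell_equivalents_input=rep.meta.qc_cell_equivalents_input)
    return SampleRepertoire(meta=meta, clonotypes=clonotypes,
                            qc_reads=int(rng.binomial(rep.qc_reads, p)))


def replace_clonotype(c: Clonotype, sample_id: str, reads: int) -> Clonotype:
    return Clonotype(clonotype_id=c.clonotype_id, sample_id=sample_id,
                     library=c.library, j_call=c.j_call, junction=c.junction,
                     read_count=reads, v_call=c.v_call, d_call=c.d_call,
                     d2_call=c.d2_call, anatomy=c.anatomy)


def simulate_cohort(config: SimulationConfig) -> CohortData:
    """Generate the full synthetic cohort for the configured scenario."""
    config.validate()
    catalog = toy_catalog()
    rng = np.random.default_rng(config.seed)
    registry = _StemRegistry()
    truth = TruthLabels()
    samples: Dict[Tuple[str, str], SampleRepertoire] = {}
    metadata: List[SampleMeta] = []

    for p_idx in range(config.n_patients):
        patient_id = f"P{p_idx + 1:03d}"
        truth.immunophenotype[patient_id] = (
            "pro-B" if rng.random() < config.pro_b_fraction else "pre-B")
        plan = _plan_patient(patient_id, catalog, rng, config, registry)
        truth.stems.extend(plan.stems)

        diag_id = f"{patient_id}-BM-day0"
        for lib in (VJ, DJ):
            rep = _emit_sample(plan, lib, catalog, rng, config, registry, truth,
                               diag_id, "BM", "day0", config.leukemic_fraction)
            samples[(diag_id, lib)] = rep
            metadata.append(rep.meta)

        if config.scenario == "bm_pb_pair":
            pb_id = f"{patient_id}-PB-day0"
            for lib in (VJ, DJ):
                pb = _thin_repertoire(samples[(diag_id, lib)], config.pb_subsample,
                                      rng, pb_id, "PB")
                samples[(pb_id, lib)] = pb
                metadata.append(pb.meta)

        elif config.scenario == "longitudinal":
            killed: Dict[str, float] = {}
            if config.kill_top_member:
                # eradicate the diagnostic top member of the patient's most
                # abundant evolving VJ stem; siblings persist
                evolving = [s for s in plan.stems
                            if s.evolving and plan.vj_members[s.stem_id]]
                if evolving:
                    lead = max(evolving,
                               key=lambda s: plan.stem_weights.get(s.stem_id, 0.0))
                    mem = plan.vj_members[lead.stem_id]
                    top_cid = max(mem, key=lambda t: t[2])[0]
                    killed[top_cid] = 0.0
                    lead.killed_top_member_id = top_cid
            for label, frac in config.followups:
                fu_id = f"{patient_id}-BM-{label}"
                for lib in (VJ, DJ):
                    override = dict(killed) if lib == VJ else None
                    rep = _emit_sample(plan, lib, catalog, rng, config, registry,
                                       truth, fu_id, "BM", label, frac,
                                       weight_override=override,
                                       with_satellites=False)
                    samples[(fu_id, lib)] = rep
                    metadata.append(rep.meta)

    return CohortData(config=config, truth=truth, samples=samples, metadata=metadata)


def emit_cohort(config: SimulationConfig, out_dir: str | Path) -> CohortData:
    """Generate and write a complete, self-contained dataset.

    Layout: one AIRR TSV per sample/library plus ``metadata.tsv``,
    ``truth.json`` and ``config.json``.  Deterministic per seed.
    """
    data = simulate_cohort(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (sample_id, lib), rep in sorted(data.samples.items()):
        write_airr_sample(rep, out / f"{sample_id}.{lib}.tsv")
    meta_rows = [{
        "sample_id": m.sample_id, "patient_id": m.patient_id,
        "compartment": m.compartment, "timepoint_label": m.timepoint_label,
        "library": m.library,
        "qc_cell_equivalents_input": m.qc_cell_equivalents_input,
    } for m in data.metadata]
    pd.DataFrame(meta_rows).to_csv(out / "metadata.tsv", sep="\t", index=False)
    (out / "truth.json").write_text(data.truth.to_json())
    (out / "config.json").write_text(json.dumps(asdict(data.config), indent=1))
    return data


# -- constructed fixtures --------------------------------------------------

def noise_fixture(seed: int = 1):
    """A single stem family with planted satellites and healthy true members.

    Returns (repertoire, truth) where truth lists the satellite ids and
    the true-member ids: one abundant founder, burst members with
    distinct V genes at comfortable abundance, and satellites of the
    founder at 1-2 reads within edit distance 2.  Used to measure
    noise-filter fidelity.
    """
    config = SimulationConfig(seed=seed)
    catalog = toy_catalog()
    rng = np.random.default_rng(seed)
    registry = _StemRegistry()
    root = _unique_root(catalog, rng, config, registry)
    founder = simulate_rearrangement(catalog, rng, VJ, config)
    founder.d_call, founder.d_part = root.d_call, root.d_part
    founder.n2, founder.j_part, founder.j_call = root.n2, root.j_part, root.j_call
    burst = simulate_burst(root, 6, catalog, rng, config)
    sample_id = "FIX-BM-day0"
    clonotypes = []
    rearrs: Dict[str, SimRearrangement] = {}
    founder_c = Clonotype(clonotype_id="FIX-top", sample_id=sample_id, library=VJ,
                          j_call=founder.j_call, junction=founder.junction,
                          read_count=5000, v_call=founder.v_call,
                          d_call=founder.d_call, anatomy=founder.true_anatomy())
    clonotypes.append(founder_c)
    rearrs["FIX-top"] = founder
    true_members = []
    for i, member in enumerate(burst):
        cid = f"FIX-m{i + 1}"
        clonotypes.append(Clonotype(
            clonotype_id=cid, sample_id=sample_id, library=VJ,
            j_call=member.j_call, junction=member.junction,
            read_count=int(50 + 25 * i), v_call=member.v_call,
            d_call=member.d_call, anatomy=member.true_anatomy()))
        true_members.append(cid)
    meta = SampleMeta(sample_id=sample_id, patient_id="FIX", compartment="BM",
                      timepoint_label="day0", library=VJ,
                      qc_cell_equivalents_input=100.0)
    rep = SampleRepertoire(meta=meta, clonotypes=clonotypes, qc_reads=0)
    sat_cfg = replace(config, satellite_mean=4.0, satellite_min_parent_percent=0.5)
    sats = add_satellites_and_noise(list(clonotypes), rearrs, rng, sat_cfg,
                                    usable_target=rep.usable_reads)
    satellite_ids = []
    for sat, _ in sats:
        rep.clonotypes.append(sat)
        satellite_ids.append(sat.clonotype_id)
    return rep, {"top": "FIX-top", "true_members": true_members,
                 "satellites": satellite_ids}
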