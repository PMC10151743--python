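# Methods

This note documents the models, rules and numerical choices behind
`dnjstem`: what each stage computes, which parameters matter and why
their defaults were chosen, what the synthetic-data generator does and
does not emulate, and the known limitations.

## The DNJ-stem

A rearranged IGH junction is the concatenation
V | N1 | [D_up | N0] | D | N2 | J (tandem parts present only in D–D
fusions). Ongoing D/V-to-DJ recombination replaces everything 5' of the
D (and may erode the D 5' end), while V_H replacement exchanges the V
and rebuilds N1 but leaves the D and everything 3' of it intact. The
junction suffix that survives both — the last at most 3 D nucleotides,
the whole N2, and all J nucleotides — is the *DNJ-stem*. When no D is
identifiable in a VJ rearrangement, the last ≤ 3 nucleotides of the
single N region stand in (the N-fallback). Stems link family members by
exact string identity; no fuzzy matching is attempted, because the stem
is precisely the part of the junction that evolution does not touch.

## Junction decomposition

Decomposition anchors regions by exact, ungapped germline matching:

* **J**: the longest common suffix of the junction and the called
  germline J (minimum `min_j_match` = 4 nt). The J 5' end is trimmed
  during recombination; its 3' end runs through the end of the junction.
* **V**: the longest junction prefix matching the 3'-terminal window
  (14 nt) of the called germline V under up to 6 nt of 3' trimming
  (minimum 4 nt).
* **D**: exact substring matching against the whole D catalog via a
  precomputed substring index. Among *strong* matches
  (≥ `min_d_strong` = 8 nt) the most J-proximal wins; only when no
  strong match exists does the longest match ≥ `min_d_match` = 5 nt win
  (ties: most J-proximal, then the lowest-rank D gene).
* a second disjoint match ≥ `min_d2_match` = 8 nt located 5' of the D
  becomes the upstream D of a tandem fusion.

Two of these choices deserve justification. First, the J-proximal
preference among strong matches (rather than a global longest-match
rule): in a D–D tandem the incoming upstream D is near full length and
frequently *longer* than the eroded root D; a longest-match rule would
put the wrong D into the stem and split the family. Because everything
3' of the true D (N2, J) is shared by all family members, the
J-proximal-strong rule makes the same choice for every member, which is
what family grouping needs. Second, the higher threshold for the
second (tandem) match: chance matches of 5-mers inside fresh N regions
occur at roughly one position in ten, which would flag spurious tandems
constantly, while genuine incoming Ds are near full length (≥ 12 nt in
practice); 8 nt separates the two regimes cleanly.

Region boundaries can shift by a nucleotide when an N base happens to
continue the germline: such shifts are shared within a family (the
relevant flanks are family-identical), so grouping is unaffected, but
per-member decomposed regions are *not* reliable evidence for
member-vs-member comparisons — which is why the mechanism classifier
works on raw junctions against one reference decomposition (below).

## Noise filter and the evolving/stable consensus

Within each family (per sample and library), the filter removes, as
potential noise:

* **satellites** — non-top members with the same 5' gene as the top
  member and junction Levenshtein distance ≤ 2 (PCR/sequencing error
  clouds; true replacement members change the 5' gene and survive);
* **low-abundance members** — below 3 reads or 0.01% of usable reads.

The top member is never removed and family reads are conserved across
the split. The consensus call on the surviving members is *evolving*
iff all of:

| predicate | default | rationale |
|---|---|---|
| members after filter | ≥ 3 | one or two members cannot evidence ongoing recombination |
| distinct 5' genes (V in IGH-VJ, D in IGH-DJ) | ≥ 2 | independent joining events use different genes |
| distinct junction lengths | ≥ 2 | trimming/N-addition variability |
| total removed fraction | ≤ 0.9 | a fully noise-dominated family |
| stem N-region complex, or family ≥ 5 | — | stem specificity |

A stem's N region (N2, or the N-fallback contribution) is *complex*
when it has ≥ 2 nucleotides of ≥ 2 distinct bases; a stem whose
junction is compatible with germline D abutting germline J is a
low-specificity MRD target and gets the stricter family-size demand.
The removal counts are always recorded in the call evidence. A
satellite-cloud veto (`max_satellite_ratio`) exists but is off by
default: satellite counts scale with the number of abundant members
(each carries an error cloud), so a sats-vs-members ratio penalizes
small legitimate families while adding no specificity — satellites
never survive the filter in the first place. Every threshold lives in
`ConsensusPolicy`/`NoisePolicy` and is one config file away
(`dnjstem config show`).

## Mechanism classification

Evolving families are classified per member against a *reference* (the
mother candidate: members ≥ 10× the family median read count, else the
top member) and summarized by majority. All member-side evidence is
evaluated on the member's raw junction against the reference's
decomposed regions, making it immune to per-member boundary jitter:

* **V_H replacement** requires (i) stability — the member's junction
  ends with the reference's D+N2+J suffix with at most
  `d5_stability_tolerance` = 1 nt of D 5' erosion, never with *more*
  germline D (replacement cannot restore eroded D), and with the
  reference N1's 3'-most ≤ 4 nt immediately 5' of that suffix when the
  reference N1 offers ≥ 2 nt to test; (ii) *root-consistent erosion* —
  member and reference sit at the same erosion level relative to the
  root reconstruction (the DJ-library root when the stem is rooted,
  otherwise the family's least-eroded member), since replacement
  transmits the mother's D verbatim; (iii) a different V gene; and
  (iv) a footprint — the 3' tail (5 down to 2 nt) of a candidate
  replaced V found between the member's V and the preserved suffix.
  Candidates are the abundant mothers plus any more-abundant family
  member, which lets multi-round chains attribute each footprint to its
  immediate predecessor. When the reference N1 is too short to test
  (i), the footprint alone carries the evidence and must be ≥ 3 nt
  (`weak_context_footprint`): 2-mers occur by chance in a third of
  fresh N1 regions. An incoming V that is not downstream of its source
  is flagged (`upstream_incoming_flag`), never vetoed — such members
  exist in real data as annotation errors or genuinely earlier members.
* **D-to-DJ**: IGH-DJ-library members, and VJ members with an upstream
  D match — unless their reference context is fully preserved, in which
  case the apparent tandem is more likely a chance match inside the
  inherited N1 and the member stays undetermined.
* **V-to-DJ**: members whose D is eroded relative to the root
  reconstruction, or whose N1 lacks the reference N1 tail where that
  test is informative. Burst members may reuse the reference's V gene —
  real bursts heavily reuse the most D-proximal V — so no V constraint
  applies here.

The stem summary is the majority mechanism over classified members;
*mixed* when both the replacement and the recombination class exceed
20% of classified members (`mixed_fraction`); *undetermined* when
nothing classifies. For replacement stems the mother clonotype id is
reported; for recombination stems the DJ-root id when rooted.

## Markers, MRD and tracking

A stem is a **marker** when the family's summed abundance reaches 5% of
usable reads or 1% of cell equivalents, or when the stem is evolving at
any abundance. Usable reads — reads with identified junctions after
cIT-QC exclusion — are the denominator of every percentage. Cell
equivalents come from the spike-in: `cells_per_read` = spiked cell
equivalents / QC reads. With the sample's total cell equivalents taken
as usable_reads × cells_per_read (the denominator choice adopted here),
percentages of cells equal percentages of reads, so the cells criterion
acts as a 1%-reads floor whenever QC is available; it is skipped when
QC is absent, which is a value, not an error.

Follow-up quantification searches members by exact junction-suffix
match against the diagnostic stem at **any** abundance — the 3-read /
0.01% floor is an evolution-calling device only — and reports both the
stem sum and the diagnostic top member's own abundance. The sum is
never below the top member's value by construction; tracking flags
`top_member_vanished` (top absent while siblings persist),
`top_member_displaced`, `new_members_emerged` and `stem_untraceable`,
and emits the monitoring recommendations: follow the stem rather than a
member (always, for evolving stems), follow both libraries when rooted,
and report the family sum.

## Statistics

Associations between two-level patient attributes and per-patient
outcomes use Fisher's exact test, two-sided by the minimum-likelihood
rule (all tables with the observed margins whose point probability does
not exceed the observed one), delegated to `scipy.stats.fisher_exact`;
a zero-margin table returns p = 1 with a warning. The test suite checks
the implementation against an independent brute-force hypergeometric
enumeration on every table with total ≤ 30. p-values are reported raw;
a Benjamini–Hochberg option exists but is off by default, matching the
single-test usage of the association analyses.

## The synthetic-data generator

`SimulationConfig` defaults define the study conditions of a dense
diagnostic cohort: 25 patients, each with 2 evolving and 4 stable
leukemic stems, 50,000 usable reads per library, leukemic fraction 0.8
at diagnosis (0.4 in the DJ library), and mechanism mix 0.70 / 0.22 /
0.05 / 0.03 for V-DJ bursts / V_H replacement / D-D tandems / mixed
stems. Rearrangements draw uniform 0–4 nt trims per segment end and
geometric N-region lengths (mean 4, cap 12); V usage in bursts is
biased 5× toward the most D-proximal gene and tandem incoming Ds 5×
toward one designated segment. Burst sizes are 4 + Geometric (mean 8,
cap 400); replacement chains run 2–4 rounds with footprint lengths
drawn from a distribution over 0–5 nt (0 = erased, the classifier's
documented blind spot); satellites appear around clonotypes above 0.5%
abundance (Poisson mean 2, 1–2 substitutions, 1–2 reads). Leukemic
stem shares are Dirichlet with a 2% floor — below that, family members
fall under the 3-read/0.01% analysis floor at this depth and an
"evolving" truth label would be unrealizable by any caller. Scenario
presets add a depth-subsampled PB twin (binomial thinning at 0.1) and a
longitudinal day0/day6/day22 series (leukemic fractions 0.05 and 0.005)
in which the top member of each patient's most abundant evolving stem
is eradicated while siblings persist.

Three deliberate idealizations, and what they mean for the tests:

* **Observable-informative N2.** Leukemic stems draw their N2 until it
  has ≥ 2 distinct bases and its boundary bases do not continue the
  trimmed D/J germline: an N that mimics germline is, to any observer,
  germline, and the resulting borderline stem would be indistinguishable
  from a low-specificity one. Real leukemias do produce such borderline
  stems; the pipeline then (correctly, per its own rules) calls them
  stable, so the recovery rates measured here say nothing about that
  margin.
* **Stem-preserving satellites.** Substitutions are placed only 5' of
  the stem suffix. A real error inside the stem creates a *different*
  stem and the read leaves the family — a linking-specificity problem,
  not a family-noise problem, and out of the filter's scope.
* **Globally unique stems.** Leukemic and background stems are kept
  unique by rejection sampling, emulating the near-perfect
  cross-patient specificity observed in practice; collision behaviour
  is therefore untested here.

Passing tests on this generator demonstrate that the rules recover the
structure they were designed for; they do not certify performance on
real repertoires, where primer artefacts, allele-level variation and
sequencing-quality structure (none of which are modelled) add noise.

## Validation harness and problem sizes

`dnjstem.validation` regenerates cohorts, strips the generative
anatomy, runs the real pipeline and scores it against truth labels,
matching truth stems to predicted families by clonotype id (stem
strings can shift by a consistent nucleotide relative to the generative
anatomy, which grouping tolerates but string matching would not). The
default acceptance run uses ten cohort seeds (1,500 truth stems), five
seeds of ≥ 1,000 clonotypes for the stem-definition oracle, 30 origins
× (8 burst + ≤ 4 chain + 3 tandem) members per seed for stem
preservation, and an 8-patient longitudinal scenario for the MRD
invariants; these sizes keep the whole run under a minute per cohort
seed on one CPU while estimating every rate from hundreds of events.

## Known limitations

* The consensus thresholds are one concrete parameterization of a
  procedure whose published description is qualitative; all of them are
  configurable, and cohorts analyzed with different parameterizations
  are not comparable.
* Footprint-less replacement (erased remnants) is undetectable by
  design; such members are reported undetermined rather than guessed.
* Exact stem matching does not tolerate somatic hypermutation inside
  the stem; the intended domain (BCP-ALL precursors) is
  pre-germinal-center.
* Real IMGT references are user-supplied; the bundled locus is
  synthetic and exists for simulation and testing.
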