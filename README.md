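# dnjstem

DNJ-stem analysis of IGH clonal evolution in B-cell precursor acute
lymphoblastic leukemia (BCP-ALL).

## The problem

In BCP-ALL the malignant transformation hits a pro-B or pre-B cell in
which V(D)J recombination machinery may still be active. The leukemic
clone therefore keeps editing its immunoglobulin heavy-chain (IGH)
rearrangement — through ongoing V<sub>H</sub>/D<sub>H</sub>-to-DJ<sub>H</sub>
recombination on an incomplete DJ rearrangement (the *DJ root*) and
through *V<sub>H</sub> replacement*, which exchanges the V of an existing
VDJ via a cryptic recombination signal sequence. Both processes scatter
the leukemic burden over many related clonotypes. Minimal residual
disease (MRD) assays that track a single clonotype's junction can then
underestimate or lose the leukemia entirely.

Both processes leave one part of the junction untouched: its 3' suffix
made of the **last ≤ 3 D nucleotides, the D–J N region (N2), and all J
nucleotides** — the **DNJ-stem**. Clonotypes sharing a stem form a *stem
family*; the family, not any single member, is the durable object to
screen and monitor.

## What the package does

Given AIRR Rearrangement TSV tables from the two EuroClonality-style
amplicon libraries (IGH-VJ and IGH-DJ), `dnjstem`:

1. **decomposes** each junction into V | N1 | [D<sub>up</sub> | N0] | D | N2 | J
   by exact germline anchoring (`dnjstem.stems`);
2. **groups** clonotypes into stem families by exact stem identity and
   flags stems found in both libraries as *rooted* (the DJ root is
   detectable);
3. applies a **noise filter** (satellites of the top member within
   Levenshtein distance 2 and the same 5' gene; members below 3 reads or
   0.01% of usable reads) and a **consensus call** — a family is
   *evolving* when enough filtered members with enough 5'-gene and
   junction-length diversity remain and the stem's N region is complex
   (`dnjstem.evolution`);
4. **classifies the mechanism** of each evolving family: V<sub>H</sub>
   replacement (stable D 5' site and N1 3' site relative to the abundant
   mother clonotype, plus a ≤ 5 nt footprint of the replaced V in the new
   N1) versus D/V-to-DJ recombination (fresh N1, D 5' erosion relative to
   the root, bursts of lowly abundant members), including D–D tandem
   fusions (`dnjstem.mechanism`);
5. calls **marker stems** (family sum ≥ 5% of usable reads or ≥ 1% of
   cell equivalents via the cIT-QC spike-in, or evolving at any
   abundance) and quantifies **stem-based MRD** in follow-up samples as
   the sum over all members found by junction-suffix search at any
   abundance, alongside BM/PB compartment overlap and longitudinal
   tracking (`dnjstem.mrd`);
6. provides cohort summaries and two-sided **Fisher exact** association
   tests between patient attributes and evolution calls
   (`dnjstem.stats`);
7. ships a **ground-truth simulator** (`dnjstem.simulate`) that emulates
   stable clones, V-DJ bursts on shared DJ roots, multi-round
   V<sub>H</sub>-replacement chains with planted footprints, D–D tandems,
   PCR/sequencing-error satellites, polyclonal background and QC
   spike-in reads — used throughout the test suite to validate the
   pipeline against known labels.

## Worked example

```bash
dnjstem simulate --seed 42 --n-patients 2 --out demo/data
dnjstem call demo/data --out demo/calls
```

`demo/calls/stem_families.tsv` then contains one row per stem family per
sample and library; a selection:

```
   sample_id library                  stem  n_members  total_percent  rooted     call      mechanism  is_marker  would_conventional_miss
P001-BM-day0  IGH-VJ     ATAGTGCCCATTCGTGT         10          40.16   False evolving VH_replacement       True                    False
P001-BM-day0  IGH-VJ   ATCCACACAGCTAGAGTCG         15           3.19    True evolving       DV_to_DJ       True                     True
P001-BM-day0  IGH-VJ      TTGTGGGCTAGAGTCG          3           5.13    True   stable            NaN       True                    False
P002-BM-day0  IGH-VJ AAATTAGCTAACCATTCGTGT          1           6.80   False   stable            NaN       True                    False
```

Reading the second row: 15 clonotypes share the stem
`ATCCACACAGCTAGAGTCG`; the family sums to 3.19% of usable reads and is
called *evolving* by V-DJ recombination with its DJ root detectable in
the IGH-DJ library (`rooted`). It is a marker **only** because it
evolves — its most abundant member sits below the conventional 5%
screening threshold (`would_conventional_miss`), so single-clonotype
screening would have ignored this leukemic family entirely. The first
row is a replacement-driven family concentrated in an abundant mother
clonotype (40.16% of reads).

`dnjstem mrd` tracks every diagnostic marker stem across follow-up
samples (stem-summed and top-member MRD per timepoint, with flags such
as `top_member_vanished`), `dnjstem compare` reports BM/PB overlap, and
`dnjstem cohort` writes the cohort summary with optional Fisher
associations. `dnjstem config show` prints every analysis threshold.

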