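"""Replacement-vs-recombination signatures and stem summaries."""

import pytest

from dnjstem.io import DJ, VJ
from dnjstem.mechanism import (MechanismPolicy, MemberMechanism,
                               check_d5_stability, classify_family,
                               classify_member, find_vh_footprint,
                               mother_candidates, summarize_stem)

from conftest import make_clonotype

SHARED = dict(d_part="GCGCGTTTCTACAAAAGTGG", n2="ATCG",
              j_part="CTAACCATTCGTGT")  # TDH01 + informative N2 + TJH01


def mother(n1="TTCC", reads=1000):
    return make_clonotype("mother", v_part="GGCAGTTGGA", n1=n1, reads=reads,
                          v_call="TVH01", d_call="TDH01", **SHARED)


class TestD5Stability:
    def test_identical_d_and_preserved_n1_tail_is_stable(self, catalog):
        member = make_clonotype("m", v_part="GACGGCAC", n1="AGGTTCC", reads=10,
                                v_call="TVH02", d_call="TDH01", **SHARED)
        assert check_d5_stability(member, mother()) is True

    def test_four_nt_erosion_exceeds_tolerance(self):
        member = make_clonotype("m", v_part="GACGGCAC", n1="AGGTTCC", reads=10,
                                v_call="TVH02", d_call="TDH01",
                                d_part=SHARED["d_part"][4:], n2="ATCG",
                                j_part="CTAACCATTCGTGT")
        assert check_d5_stability(member, mother(), tol=1) is False

    def test_one_nt_erosion_with_intact_tail_is_stable(self):
        member = make_clonotype("m", v_part="GACGGCAC", n1="AGGTTCC", reads=10,
                                v_call="TVH02", d_call="TDH01",
                                d_part=SHARED["d_part"][1:], n2="ATCG",
                                j_part="CTAACCATTCGTGT")
        assert check_d5_stability(member, mother(), tol=1) is True

    def test_missing_reference_d_is_undetermined_not_error(self):
        ref = make_clonotype("r", v_part="GGCAGTTGGA", n1="CCGA", reads=100,
                             v_call="TVH01", j_part="CTAACCATTCGTGT")
        member = make_clonotype("m", v_part="GACGGCAC", n1="AG", reads=10,
                                v_call="TVH02", d_call="TDH01", **SHARED)
        assert check_d5_stability(member, ref) is None

    def test_fresh_n1_breaks_stability(self):
        member = make_clonotype("m", v_part="GACGGCAC", n1="AGAGAGA", reads=10,
                                v_call="TVH02", d_call="TDH01", **SHARED)
        assert check_d5_stability(member, mother()) is False


class TestFindVhFootprint:
    def test_tail_substring_found(self, catalog):
        # TVH02 germline ends ...GACGGCAC; plant its 4-nt tail in the N1
        member = make_clonotype("m", v_part="AACCATG", n1="AAGCACT", reads=10,
                                v_call="TVH09", d_call="TDH01", **SHARED)
        hit = find_vh_footprint(member, ["TVH02"], catalog)
        assert hit == ("GCAC", "TVH02")

    def test_no_match_returns_absent(self, catalog):
        member = make_clonotype("m", v_part="AACCATG", n1="TT", reads=10,
                                v_call="TVH09", d_call="TDH01", **SHARED)
        assert find_vh_footprint(member, ["TVH02"], catalog) is None

    def test_longest_tail_wins_then_candidate_order(self, catalog):
        # N1 contains TVH02's 4-nt tail and TVH01's 2-nt tail
        tail4 = catalog.v_three_prime_tail("TVH02", 4)
        tail2 = catalog.v_three_prime_tail("TVH01", 2)
        member = make_clonotype("m", v_part="AACCATG", n1=tail2 + "T" + tail4,
                                reads=10, v_call="TVH09", d_call="TDH01",
                                **SHARED)
        hit = find_vh_footprint(member, ["TVH01", "TVH02"], catalog)
        assert hit == (tail4, "TVH02")
        # exhaustive-equivalent: brute force over all k and candidates
        brute = max(
            ((catalog.v_three_prime_tail(v, k), v)
             for v in ("TVH01", "TVH02") for k in range(2, 6)
             if catalog.v_three_prime_tail(v, k) in member.anatomy.n1),
            key=lambda t: len(t[0]))
        assert len(brute[0]) == len(hit[0])


class TestMotherCandidates:
    def test_abundance_factor_over_median(self):
        members = [mother(reads=5000)] + [
            make_clonotype(f"m{i}", v_part="GACGGCAC", n1="A" * (i + 1),
                           reads=50, v_call="TVH02", d_call="TDH01", **SHARED)
            for i in range(4)]
        cands = mother_candidates(members)
        assert [c.clonotype_id for c in cands] == ["mother"]

    def test_top_member_fallback_when_none_qualify(self):
        members = [make_clonotype(f"m{i}", v_part="GACGGCAC", n1="A" * (i + 1),
                                  reads=100 - i, v_call="TVH02",
                                  d_call="TDH01", **SHARED)
                   for i in range(3)]
        assert mother_candidates(members)[0].clonotype_id == "m0"


class TestClassifyMember:
    def test_replacement_member_with_planted_footprint(self, catalog):
        ref = mother()
        fp = catalog.v_three_prime_tail("TVH01", 4)
        member = make_clonotype("m", v_part="GACGGCAC", n1="GG" + fp + "TTCC",
                                reads=100, v_call="TVH02", d_call="TDH01",
                                **SHARED)
        call = classify_member(member, ref, ["TVH01"], catalog)
        assert call.mechanism == "VH_replacement"
        assert call.footprint == fp
        assert not call.upstream_incoming_flag  # TVH02 is downstream of TVH01

    def test_upstream_incoming_flagged_not_vetoed(self, catalog):
        ref = make_clonotype("mother", v_part="CAACCATG", n1="TTCC", reads=1000,
                             v_call="TVH09", d_call="TDH01", **SHARED)
        fp = catalog.v_three_prime_tail("TVH09", 4)
        member = make_clonotype("m", v_part="GACGGCAC", n1="GG" + fp + "TTCC",
                                reads=100, v_call="TVH02", d_call="TDH01",
                                **SHARED)
        call = classify_member(member, ref, ["TVH09"], catalog)
        assert call.mechanism == "VH_replacement"
        assert call.upstream_incoming_flag  # TVH02 is upstream of TVH09

    def test_burst_member_eroded_and_fresh(self, catalog):
        ref = mother()
        member = make_clonotype("m", v_part="GTAACACGTGTGTCTACT"[-10:],
                                n1="GAGAGA", reads=10, v_call="TVH11",
                                d_call="TDH01", d_part=SHARED["d_part"][3:],
                                n2="ATCG", j_part="CTAACCATTCGTGT")
        call = classify_member(member, ref, ["TVH01"], catalog,
                               root_regions=(SHARED["d_part"], "ATCG",
                                             "CTAACCATTCGTGT"))
        assert call.mechanism == "V_to_DJ"

    def test_dj_library_member_is_d_to_dj(self, catalog):
        member = make_clonotype("m", library=DJ, d_call="TDH01",
                                d2_call="TDH02",
                                d_upstream_part="ACAGAGCAAGGAATGGTCAG",
                                n0="AA", d_part=SHARED["d_part"][2:],
                                n2="ATCG", j_part="CTAACCATTCGTGT", reads=20)
        ref = make_clonotype("root", library=DJ, d_call="TDH01", reads=400,
                             **SHARED)
        call = classify_member(member, ref, [], catalog)
        assert call.mechanism == "D_to_DJ"

    def test_reference_itself_is_undetermined(self, catalog):
        ref = mother()
        assert classify_member(ref, ref, [], catalog).mechanism == "undetermined"


class TestSummarizeStem:
    def _calls(self, mechs):
        return [MemberMechanism(member_id=f"m{i}", mechanism=m)
                for i, m in enumerate(mechs)]

    def test_majority_recombination(self):
        calls = self._calls(["V_to_DJ"] * 9 + ["undetermined"])
        assert summarize_stem(calls, rooted=True).summary == "DV_to_DJ"

    def test_both_mechanisms_above_fraction_is_mixed(self):
        calls = self._calls(["VH_replacement"] * 6 + ["V_to_DJ"] * 5)
        assert summarize_stem(calls, rooted=False).summary == "mixed"

    def test_all_undetermined(self):
        calls = self._calls(["undetermined"] * 3)
        assert summarize_stem(calls, rooted=False).summary == "undetermined"

    def test_replacement_majority_sets_mother(self):
        calls = self._calls(["VH_replacement"] * 4)
        out = summarize_stem(calls, rooted=False, mother_id="mom")
        assert out.summary == "VH_replacement" and out.mother_id == "mom"


class TestClassifyFamilySimulated:
    def test_simulated_chain_recovered(self, catalog):
        import numpy as np
        from dnjstem.simulate import (SimulationConfig,
                                      simulate_rearrangement,
                                      simulate_replacement_chain)
        from dnjstem.stems import decompose_junction

        config = SimulationConfig(seed=4)
        rng = np.random.default_rng(4)
        hits = total = 0
        for _ in range(20):
            mom = simulate_rearrangement(catalog, rng, VJ, config, leukemic=True,
                                         v_name="TVH02")
            chain = simulate_replacement_chain(mom, 3, catalog, rng, config)
            if not any(fp >= 2 for _, fp, _ in chain):
                continue
            members = []
            for i, (rearr, cid) in enumerate(
                    [(mom, "mom")] + [(m, f"c{j}") for j, (m, _, _) in
                                      enumerate(chain)]):
                from dnjstem.io import Clonotype
                members.append(Clonotype(
                    clonotype_id=cid, sample_id="S1", library=VJ,
                    j_call=rearr.j_call, junction=rearr.junction,
                    read_count=1000 >> i, v_call=rearr.v_call,
                    d_call=rearr.d_call,
                    anatomy=decompose_junction(rearr.junction, rearr.v_call,
                                               rearr.j_call, catalog)))
            total += 1
            out = classify_family(members, catalog)
            if out.summary == "VH_replacement":
                hits += 1
        assert total >= 10
        assert hits / total >= 0.9
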