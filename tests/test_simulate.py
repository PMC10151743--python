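"""Synthetic repertoire generator: determinism, anatomy, truth labels."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from dnjstem.io import DJ, VJ
from dnjstem.locus import toy_catalog
from dnjstem.simulate import (SimulationConfig, _StemRegistry, _unique_root,
                              add_satellites_and_noise, emit_cohort,
                              simulate_burst, simulate_cohort,
                              simulate_d_dj_tandem, simulate_rearrangement,
                              simulate_replacement_chain)

CONFIG = SimulationConfig(seed=1)


@pytest.fixture(scope="module")
def catalog():
    return toy_catalog()


class TestSimulateRearrangement:
    def test_same_seed_reproduces_clonotype(self, catalog):
        a = simulate_rearrangement(catalog, np.random.default_rng(1), VJ, CONFIG)
        b = simulate_rearrangement(catalog, np.random.default_rng(1), VJ, CONFIG)
        assert a.junction == b.junction and a.v_call == b.v_call

    def test_zero_trimming_and_zero_n_gives_pure_germline_join(self, catalog):
        config = SimulationConfig(seed=1, trim_max=0, n_mean=1e-9, n_max=0)
        rng = np.random.default_rng(3)
        r = simulate_rearrangement(catalog, rng, VJ, config)
        v = catalog.get(r.v_call).sequence
        d = catalog.get(r.d_call).sequence
        j = catalog.get(r.j_call).sequence
        assert r.junction == v[-10:] + d + j

    def test_n1_length_matches_configured_mean(self, catalog):
        rng = np.random.default_rng(9)
        lengths = [len(simulate_rearrangement(catalog, rng, VJ, CONFIG).n1)
                   for _ in range(10_000)]
        mean = np.mean(lengths)
        se = np.std(lengths) / np.sqrt(len(lengths))
        # analytic mean of the geometric capped at n_max
        q = CONFIG.n_mean / (CONFIG.n_mean + 1)
        expected = sum(q ** j for j in range(1, CONFIG.n_max + 1))
        assert abs(mean - expected) < 3 * se

    def test_leukemic_n2_is_informative(self, catalog):
        rng = np.random.default_rng(2)
        for _ in range(200):
            r = simulate_rearrangement(catalog, rng, DJ, CONFIG, leukemic=True)
            assert len(r.n2) >= 2 and len(set(r.n2)) >= 2


class TestLineagePrimitives:
    def _root(self, seed=5):
        rng = np.random.default_rng(seed)
        return _unique_root(toy_catalog(), rng, CONFIG, _StemRegistry()), rng

    def test_burst_members_share_the_root_stem(self, catalog):
        root, rng = self._root()
        for m in simulate_burst(root, 12, catalog, rng, CONFIG):
            assert m.true_stem == root.true_stem
            assert len(m.d_part) >= len(root.d_part) - CONFIG.trim_max

    def test_burst_draws_multiple_v_genes(self, catalog):
        root, rng = self._root(7)
        members = simulate_burst(root, 12, catalog, rng, CONFIG)
        assert len({m.v_call for m in members}) >= 2

    def test_replacement_chain_ranks_strictly_increase(self, catalog):
        root, rng = self._root(11)
        mother = simulate_rearrangement(catalog, rng, VJ, CONFIG,
                                        v_name="TVH02")
        mother.d_part, mother.n2, mother.j_part = (root.d_part, root.n2,
                                                   root.j_part)
        mother.j_call, mother.d_call = root.j_call, root.d_call
        chain = simulate_replacement_chain(mother, 4, catalog, rng, CONFIG)
        assert len(chain) == 4
        ranks = [catalog.rank("V", mother.v_call)] + [
            catalog.rank("V", m.v_call) for m, _, _ in chain]
        assert all(a < b for a, b in zip(ranks, ranks[1:]))
        for m, _, _ in chain:
            assert m.true_stem == mother.true_stem

    def test_planted_footprint_is_verbatim_in_n1(self, catalog):
        config = SimulationConfig(seed=1, footprint_probs=(0, 0, 0, 0, 1.0, 0))
        root, rng = self._root(13)
        mother = simulate_rearrangement(catalog, rng, VJ, config,
                                        v_name="TVH01")
        mother.d_part, mother.n2, mother.j_part = (root.d_part, root.n2,
                                                   root.j_part)
        mother.j_call, mother.d_call = root.j_call, root.d_call
        chain = simulate_replacement_chain(mother, 2, catalog, rng, config)
        for member, fp_len, replaced in chain:
            assert fp_len == 4
            assert catalog.get(replaced).sequence[-4:] in member.n1

    def test_tandem_biased_toward_designated_incoming_d(self, catalog):
        root, rng = self._root(17)
        designated = catalog.of_type("D")[1].name
        draws = [simulate_d_dj_tandem(root, catalog, rng, CONFIG).d2_call
                 for _ in range(1000)]
        assert sum(d == designated for d in draws) / len(draws) >= 0.45
        for _ in range(50):
            t = simulate_d_dj_tandem(root, catalog, rng, CONFIG)
            assert t.true_stem == root.true_stem


class TestSatellites:
    def test_satellites_close_cheap_and_stem_preserving(self, catalog):
        from dnjstem.evolution import levenshtein
        from dnjstem.io import Clonotype

        rng = np.random.default_rng(21)
        root, _ = (_unique_root(catalog, rng, CONFIG, _StemRegistry()), None)
        founder = simulate_rearrangement(catalog, rng, VJ, CONFIG)
        founder.d_part, founder.n2, founder.j_part = (root.d_part, root.n2,
                                                      root.j_part)
        founder.j_call, founder.d_call = root.j_call, root.d_call
        parent = Clonotype(clonotype_id="p", sample_id="S", library=VJ,
                           j_call=founder.j_call, junction=founder.junction,
                           read_count=5000, v_call=founder.v_call,
                           d_call=founder.d_call)
        out = add_satellites_and_noise(
            [parent], {"p": founder}, rng,
            SimulationConfig(seed=1, satellite_mean=5.0), usable_target=10_000)
        assert out
        for sat, truth in out:
            assert levenshtein(sat.junction, parent.junction) <= 2
            assert sat.read_count < 3
            assert sat.junction.endswith(founder.true_stem)
            assert truth.parent_id == "p"


class TestCohort:
    def test_truth_labels_cover_every_leukemic_clonotype_once(self):
        data = simulate_cohort(SimulationConfig(seed=6, n_patients=3))
        idx = data.truth.clonotype_index()
        seen = set()
        for st in data.truth.stems:
            for m in st.members:
                assert m.clonotype_id not in seen
                seen.add(m.clonotype_id)
        for (sid, lib), rep in data.samples.items():
            for c in rep.clonotypes:
                if "bg" not in c.clonotype_id:
                    assert c.clonotype_id in idx

    def test_configured_stem_counts(self):
        config = SimulationConfig(seed=2, n_patients=4)
        data = simulate_cohort(config)
        evolving = [s for s in data.truth.stems if s.evolving]
        stable = [s for s in data.truth.stems if not s.evolving]
        assert len(evolving) == 4 * config.n_evolving_stems_per_patient
        assert len(stable) == 4 * config.n_stable_stems_per_patient

    def test_emitted_files_are_byte_identical_across_runs(self, tmp_path):
        def tree_hash(d: Path) -> str:
            h = hashlib.sha256()
            for p in sorted(d.rglob("*")):
                if p.is_file():
                    h.update(p.name.encode())
                    h.update(p.read_bytes())
            return h.hexdigest()

        config = SimulationConfig(seed=42, n_patients=2)
        emit_cohort(config, tmp_path / "a")
        emit_cohort(config, tmp_path / "b")
        assert tree_hash(tmp_path / "a") == tree_hash(tmp_path / "b")

    def test_bm_pb_pair_is_a_subsample(self):
        data = simulate_cohort(SimulationConfig(seed=3, n_patients=1,
                                                scenario="bm_pb_pair"))
        bm = {c.clonotype_id: c.read_count
              for c in data.samples[("P001-BM-day0", VJ)].clonotypes}
        pb = data.samples[("P001-PB-day0", VJ)].clonotypes
        assert pb  # something survives thinning
        for c in pb:
            assert c.clonotype_id in bm
            assert c.read_count <= bm[c.clonotype_id]

    def test_longitudinal_kill_preset_records_the_victim(self):
        data = simulate_cohort(SimulationConfig(seed=4, n_patients=2,
                                                scenario="longitudinal"))
        killed = [s for s in data.truth.stems if s.killed_top_member_id]
        assert killed
        for st in killed:
            for label, _ in data.config.followups:
                rep = data.samples[(f"{st.patient_id}-BM-{label}", VJ)]
                ids = {c.clonotype_id for c in rep.clonotypes}
                assert st.killed_top_member_id not in ids

    def test_invalid_config_lists_offending_fields(self):
        with pytest.raises(ValueError, match="mechanism_mix"):
            SimulationConfig(seed=1, mechanism_mix=(0.5, 0.5, 0.5, 0.5)).validate()
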