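"""Simulator contracts: determinism, construction invariants, sampling laws,
and the directional biology at reduced scale."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import clonetrace as ct
from clonetrace.repio import KeyMode, SampleMeta, collapse_by_key, filter_productive, \
    load_repertoire_set, read_rearrangement_table
from clonetrace.simulate import (
    SimConfig,
    sample_repertoire,
    simulate_donor_pool,
    simulate_experiment,
    simulate_recipient,
    write_experiment,
)

from conftest import SMALL_SIM

TINY = SimConfig(n_clones=500, n_syn=1, n_allo=1, depth_lymphoid=800,
                 depth_parenchymal=400, donor_sample_depth=500, allo_fraction=0.02,
                 activated_per_recipient=3, seed=11)


class TestSimConfig:
    def test_validation_lists_offending_fields(self):
        bad = SimConfig(n_clones=10, allo_fraction=2.0, depth_lymphoid=0)
        with pytest.raises(ValueError) as err:
            bad.validate()
        msg = str(err.value)
        assert "n_clones" in msg and "allo_fraction" in msg and "depth_lymphoid" in msg

    def test_depth_by_tissue_class(self):
        cfg = SimConfig()
        assert cfg.depth_for("blood") == cfg.depth_lymphoid
        assert cfg.depth_for("gut") == cfg.depth_parenchymal


class TestDonorPool:
    def test_fixed_seed_reproducible(self):
        p1 = simulate_donor_pool(TINY)
        p2 = simulate_donor_pool(TINY)
        pd.testing.assert_frame_equal(p1.clones, p2.clones)

    def test_zipf_zero_gives_uniform_frequencies(self):
        pool = simulate_donor_pool(SimConfig(n_clones=200, zipf_alpha=0.0, seed=3))
        assert np.allclose(pool.frequency, 1 / 200)

    def test_alloreactive_fraction_and_tail_preference(self):
        cfg = SimConfig(n_clones=5000, allo_fraction=0.01, seed=5)
        pool = simulate_donor_pool(cfg)
        n_allo = pool.clones["alloreactive"].sum()
        assert abs(n_allo - 0.01 * 5000) <= 1
        # rank-proportional sampling pushes the alloreactive set toward the tail
        assert pool.alloreactive_indices.mean() > 5000 / 2

    def test_frequencies_sum_to_one_and_keys_unique(self):
        pool = simulate_donor_pool(TINY)
        assert pool.frequency.sum() == pytest.approx(1.0, abs=1e-12)
        assert pool.clones["cdr3_aa"].is_unique
        assert pool.clones["cdr3_aa"].str.match(r"^C[A-Z]{8,16}F$").all()

    def test_v26_enriched_among_alloreactive(self):
        pool = simulate_donor_pool(SimConfig(n_clones=20000, allo_fraction=0.05, seed=9))
        allo_mask = pool.clones["alloreactive"]
        v26_allo = (pool.clones.loc[allo_mask, "v_gene"] == "V26").mean()
        v26_rest = (pool.clones.loc[~allo_mask, "v_gene"] == "V26").mean()
        assert v26_allo > 3 * v26_rest


class TestSampleRepertoire:
    META = SampleMeta("s", "m1", "syngeneic", "blood", 7)

    def test_total_templates_equals_depth(self):
        pool = simulate_donor_pool(TINY)
        rep = sample_repertoire(pool, 800, self.META, seed=1)
        assert rep.total_templates == 800
        assert rep.key == KeyMode.AA

    def test_uniform_small_pool_fully_covered(self):
        pool = simulate_donor_pool(SimConfig(n_clones=100, zipf_alpha=0.0, seed=2))
        rep = sample_repertoire(pool, 10_000, self.META, seed=4)
        assert rep.n_clones == 100

    def test_law_of_large_numbers(self):
        pool = simulate_donor_pool(SimConfig(n_clones=100, zipf_alpha=1.0, seed=6))
        rep = sample_repertoire(pool, 1_000_000, self.META, seed=8)
        observed = pd.Series(0.0, index=pool.clones["cdr3_aa"])
        freq = rep.clones.set_index("cdr3_aa")["templates"] / rep.total_templates
        observed.loc[freq.index] = freq
        assert np.max(np.abs(observed.to_numpy() - pool.frequency)) < 0.01

    def test_depth_must_be_positive(self):
        pool = simulate_donor_pool(TINY)
        with pytest.raises(ValueError):
            sample_repertoire(pool, 0, self.META, seed=1)


class TestSimulateRecipient:
    def test_unknown_group_rejected(self):
        pool = simulate_donor_pool(TINY)
        with pytest.raises(ValueError):
            simulate_recipient(pool, "xenogeneic", TINY, 1)

    def test_allogeneic_expansion_recorded_in_ground_truth(self):
        pool = simulate_donor_pool(TINY)
        rec = simulate_recipient(pool, "allogeneic", TINY, 2, mouse_id="allo1")
        assert rec.activated_indices.size == 3
        assert set(rec.activated_indices) <= set(pool.alloreactive_indices)
        assert (rec.multipliers > 1).all()
        mass = rec.distribution[rec.activated_indices].sum()
        assert mass > 0.5  # expansion dominates the recipient distribution

    def test_syngeneic_keeps_pool_structure(self):
        pool = simulate_donor_pool(TINY)
        rec = simulate_recipient(pool, "syngeneic", TINY, 3, mouse_id="syn1")
        assert rec.activated_indices.size == 0
        # mild jitter: recipient distribution correlates strongly with the pool
        corr = np.corrcoef(rec.distribution, pool.frequency)[0, 1]
        assert corr > 0.99

    def test_allo_gut_more_clonal_than_syn_gut_over_seeds(self):
        # default study conditions, gut compartment, 3 replicate recipients
        # per group as in the experiment design
        cfg = SimConfig(tissues=("gut",))
        pool = simulate_donor_pool(cfg)
        wins = 0
        n_seeds = 20
        for s in range(n_seeds):
            allo = np.mean([
                ct.clonality(
                    simulate_recipient(pool, "allogeneic", cfg, (1000 + s) * 10 + i, "a")
                    .tissue("gut")
                )
                for i in range(3)
            ])
            syn = np.mean([
                ct.clonality(
                    simulate_recipient(pool, "syngeneic", cfg, (2000 + s) * 10 + i, "s")
                    .tissue("gut")
                )
                for i in range(3)
            ])
            wins += allo > syn
        assert wins >= 0.9 * n_seeds


class TestSimulateExperiment:
    def test_bookkeeping(self, small_experiment):
        cfg = small_experiment.config
        expected = (cfg.n_syn + cfg.n_allo) * len(cfg.tissues) * len(cfg.days) + 1
        assert len(small_experiment.repertoires) == expected
        assert len(small_experiment.manifest) == expected
        assert "donor_graft" in small_experiment.repertoires

    def test_fixed_seed_byte_identical_tables(self, tmp_path):
        d1 = write_experiment(simulate_experiment(TINY), tmp_path / "run1")
        d2 = write_experiment(simulate_experiment(TINY), tmp_path / "run2")
        files1 = sorted(p.name for p in d1.iterdir())
        assert files1 == sorted(p.name for p in d2.iterdir())
        for name in files1:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_two_timepoints_compound_cross_tissue_overlap(self):
        # compounding expansion at day 14 concentrates shared dominants,
        # increasing within-recipient cross-tissue overlap over time
        from itertools import combinations

        from clonetrace.overlap import overlap_metric

        cfg = SimConfig(n_clones=2000, n_syn=1, n_allo=1, depth_lymphoid=2000,
                        depth_parenchymal=1000, donor_sample_depth=1000,
                        allo_fraction=0.01, activated_per_recipient=10,
                        days=(7, 14), seed=13)
        exp = simulate_experiment(cfg)
        allo = exp.repertoires.subset(group="allogeneic")

        def mean_overlap(day):
            samples = list(allo.subset(day=day))
            return np.mean([overlap_metric(a, b) for a, b in combinations(samples, 2)])

        assert mean_overlap(14) > mean_overlap(7)

    def test_emitted_tables_reread_through_repio(self, tmp_path, small_experiment):
        outdir = write_experiment(small_experiment, tmp_path / "exp")
        reps = load_repertoire_set(outdir / "manifest.tsv")
        assert len(reps) == len(small_experiment.repertoires)
        for rep in small_experiment.repertoires:
            back = reps[rep.sample_id]
            assert back.total_templates == rep.total_templates
            assert back.key_set() == rep.key_set()

    def test_nt_and_aa_keys_coincide_on_simulated_data(self, tmp_path, small_experiment):
        outdir = write_experiment(small_experiment, tmp_path / "exp2")
        rep = small_experiment.repertoires.sample_ids[1]
        records = filter_productive(
            read_rearrangement_table(outdir / f"{rep}.tsv", dialect="airr")
        )
        meta = small_experiment.repertoires[rep].meta
        nt = collapse_by_key(records, KeyMode.NT, meta)
        aa = collapse_by_key(records, KeyMode.AA, meta)
        assert nt.n_clones == aa.n_clones
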