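"""Ground-truth recovery and determinism of the synthetic generators."""

import math

import numpy as np
import pandas as pd
import pytest

from mirconverge.consensus import consensus_targets
from mirconverge.screen import select_extremes
from mirconverge.synthetic import (
    PlantedGene,
    SynthConfig,
    gen_ct_table,
    gen_null_binder_sets,
    gen_prediction_calls,
    gen_puncta_pair,
    gen_screen_scores,
    gen_sirna_hits,
    gen_variant_utr,
)


class TestScreenScores:
    def test_cardinality_and_uniqueness(self):
        cfg = SynthConfig(n_mirna=2555, n_gene=100, n_sirna_hits=10, rng_seed=1)
        t = gen_screen_scores(cfg)
        assert len(t) == 2555
        assert t["entity_id"].is_unique
        assert np.isfinite(t["score"]).all()

    def test_planted_shift_lands_in_top_tail(self):
        cfg = SynthConfig(
            n_mirna=2555, n_gene=100, n_sirna_hits=10,
            n_planted_top=25, planted_shift=10.0, rng_seed=2,
        )
        t = gen_screen_scores(cfg)
        sel = select_extremes(t, 0.01)
        assert set(cfg.planted_top_ids()) <= set(sel.top_ids)

    def test_fixed_seed_reproduces_identical_table(self):
        cfg = SynthConfig(n_mirna=500, n_gene=50, n_sirna_hits=5, rng_seed=3)
        a = gen_screen_scores(cfg).to_csv(index=False)
        b = gen_screen_scores(cfg).to_csv(index=False)
        assert a == b

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(n_mirna=2, n_gene=10, n_sirna_hits=1)
        with pytest.raises(ValueError):
            SynthConfig(n_mirna=10, n_gene=10, n_sirna_hits=1, base_call_prob=1.5)


class TestPredictionCalls:
    def test_planted_gene_has_exact_binder_structure(self):
        cfg = SynthConfig(
            n_mirna=300, n_gene=3, n_sirna_hits=1, base_call_prob=0.0,
            planted_genes=(PlantedGene("GENE1", binder_count=100, candidate_overlap=41),),
            rng_seed=4,
        )
        candidates = cfg.mirna_ids[:41]
        calls = gen_prediction_calls(cfg, candidates=candidates)
        binders = consensus_targets(calls, cfg.consensus_min).binder_sets()["GENE1"]
        assert len(binders) == 100
        assert set(candidates) <= binders

    def test_zero_probability_and_no_planting_is_empty(self):
        cfg = SynthConfig(n_mirna=50, n_gene=5, n_sirna_hits=1, base_call_prob=0.0)
        assert len(gen_prediction_calls(cfg)) == 0

    def test_background_consensus_rate_matches_binomial_tail(self):
        """Consensus binder count over background genes ~ n_pairs * P(Bin(K,p) >= min)."""
        cfg = SynthConfig(
            n_mirna=400, n_gene=30, n_sirna_hits=1,
            base_call_prob=0.3, n_algorithms=6, consensus_min=4, rng_seed=5,
        )
        calls = gen_prediction_calls(cfg)
        cmap = consensus_targets(calls, 4)
        p_pair = sum(
            math.comb(6, j) * 0.3 ** j * 0.7 ** (6 - j) for j in range(4, 7)
        )
        n_pairs = 400 * 30
        expected = n_pairs * p_pair
        sd = math.sqrt(n_pairs * p_pair * (1 - p_pair))
        assert abs(len(cmap.pairs) - expected) <= 4 * sd

    def test_overlap_larger_than_candidates_rejected(self):
        cfg = SynthConfig(
            n_mirna=50, n_gene=5, n_sirna_hits=1,
            planted_genes=(PlantedGene("G", 10, 5),),
        )
        with pytest.raises(ValueError, match="candidate_overlap"):
            gen_prediction_calls(cfg, candidates=cfg.mirna_ids[:3])

    def test_fixed_seed_reproduces_identical_calls(self):
        cfg = SynthConfig(
            n_mirna=100, n_gene=10, n_sirna_hits=2, base_call_prob=0.05,
            planted_genes=(PlantedGene("GENE01", 10, 2),), rng_seed=6,
        )
        a = gen_prediction_calls(cfg, cfg.mirna_ids[:5]).calls.to_csv(index=False)
        b = gen_prediction_calls(cfg, cfg.mirna_ids[:5]).calls.to_csv(index=False)
        assert a == b


class TestSirnaHits:
    def test_planted_genes_always_hits(self):
        cfg = SynthConfig(
            n_mirna=20, n_gene=100, n_sirna_hits=30,
            planted_genes=(PlantedGene("GENE001", 5, 0),), rng_seed=7,
        )
        hits = gen_sirna_hits(cfg)
        assert len(hits) == 30 and len(set(hits)) == 30
        assert "GENE001" in hits


class TestVariantUtr:
    MIRNA = __import__("mirconverge.seeds", fromlist=["MiRNASeq"]).MiRNASeq(
        "mir", "UGAGGUAGUAGGUUGUAUAGUU"
    )

    def test_none_mode_differs_at_exactly_one_position(self):
        hap = gen_variant_utr(200, 100, self.MIRNA, planted_allele="none", rng_seed=1)
        diffs = [i for i, (a, b) in enumerate(zip(hap.ref_seq, hap.alt_seq)) if a != b]
        assert diffs == [99]

    def test_long_background_alt_planting_is_clean(self):
        from mirconverge.seeds import compare_alleles, scan_seed_sites

        hap = gen_variant_utr(10_000, 5_000, self.MIRNA, planted_allele="alt", rng_seed=9)
        cmp = compare_alleles(hap, [self.MIRNA])
        assert len(cmp.variant_created) >= 1
        # away from the variant the two alleles agree site-for-site
        ref = {(h.site_type, h.utr_start) for h in scan_seed_sites(hap.ref_seq, self.MIRNA)
               if abs(h.utr_start - 5000) > 8}
        alt = {(h.site_type, h.utr_start) for h in scan_seed_sites(hap.alt_seq, self.MIRNA)
               if abs(h.utr_start - 5000) > 8}
        assert ref == alt

    def test_edge_variant_cannot_be_planted(self):
        with pytest.raises(ValueError, match="second sequence difference"):
            gen_variant_utr(200, 1, self.MIRNA, planted_allele="alt", rng_seed=1)

    def test_fixed_seed_reproduces_identical_haplotype(self):
        a = gen_variant_utr(300, 150, self.MIRNA, "alt", rng_seed=11)
        b = gen_variant_utr(300, 150, self.MIRNA, "alt", rng_seed=11)
        assert (a.ref_seq, a.alt_seq) == (b.ref_seq, b.alt_seq)


class TestPunctaPair:
    def test_partner_counts(self):
        pre, post = gen_puncta_pair(100, 0.37, jitter_sd=0.05,
                                    n_distractor_post=20, rng_seed=3)
        assert len(pre) == 100
        assert len(post) == round(0.37 * 100) + 20

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            gen_puncta_pair(10, 1.2, rng_seed=0)

    def test_crowded_box_warns(self):
        with pytest.warns(UserWarning, match="spacing"):
            gen_puncta_pair(1000, 0.5, box=(5.0, 5.0, 2.0), rng_seed=0)

    def test_fixed_seed_reproduces_identical_clouds(self):
        a = gen_puncta_pair(50, 0.5, rng_seed=13)
        b = gen_puncta_pair(50, 0.5, rng_seed=13)
        assert np.array_equal(a[0].coords, b[0].coords)
        assert np.array_equal(a[1].coords, b[1].coords)


class TestCtTable:
    def test_null_fold_noiseless_gives_unit_rq(self):
        from mirconverge.quant import ddct_relative_quantity

        ct = gen_ct_table(n_per_group=4, group_log2_fold=0.0, noise_sd=0.0, rng_seed=1)
        rq = ddct_relative_quantity(ct, "miR-4504", "RNU48", "CTL")
        assert np.allclose(rq["rq"], 1.0)

    def test_noisy_geometric_mean_recovers_fold(self):
        from mirconverge.quant import ddct_relative_quantity

        n, fold, sd = 30, 1.5, 0.2
        ct = gen_ct_table(n_per_group=n, group_log2_fold=fold, noise_sd=sd, rng_seed=21)
        rq = ddct_relative_quantity(ct, "miR-4504", "RNU48", "CTL")
        case_log2 = np.log2(rq.loc[rq["group"] == "AD", "rq"])
        # log2 RQ_case ~ fold + noise; SE of the mean = 2*sd/sqrt(n)
        se = 2 * sd / math.sqrt(n)
        assert abs(case_log2.mean() - fold) <= 4 * se


class TestNullBinderSets:
    def test_sizes_and_membership(self):
        universe = [f"m{i}" for i in range(100)]
        sets = gen_null_binder_sets(10, 20, universe, rng_seed=2)
        assert len(sets) == 10
        for s in sets.values():
            assert len(s) == 20 and s <= set(universe)
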