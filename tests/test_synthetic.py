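"""Generator behaviour: placement constraints, planted effects, determinism."""
import numpy as np
import pytest

from chiprx.simulate import (
    TruthTable,
    build_genome,
    default_scenario,
    expected_tag_rates,
    simulate_chip_sample,
    simulate_rna_counts,
    simulate_sc_counts,
    truth_from_frame,
    truth_to_frame,
)


class TestBuildGenome:
    def test_constraints_hold(self, small_genome):
        g = small_genome
        assert len({x.gene_id for x in g.gene_annotations}) == 10
        assert len(g.enhancer_annotations) == 5
        genes = g.genes_by_id
        for e in g.enhancer_annotations:
            tss = genes[e.target_gene_id].tss
            # distal: >= 5 kb from its target TSS, clear of the promoter
            assert e.interval.start - tss >= 5_000

    def test_gene_spacing_at_least_10kb(self, small_genome):
        tss = sorted(x.tss for x in small_genome.gene_annotations)
        assert min(np.diff(tss)) >= 10_000

    def test_deterministic_for_fixed_seed(self):
        a = build_genome(1, 1_000_000, 10, 5, 1, seed=1)
        b = build_genome(1, 1_000_000, 10, 5, 1, seed=1)
        assert a.gene_annotations == b.gene_annotations
        assert a.enhancer_annotations == b.enhancer_annotations

    def test_sizing_error_names_constraint(self):
        # 100 genes x 10 kb spacing cannot fit on 50 kb
        with pytest.raises(ValueError, match="spacing"):
            build_genome(1, 50_000, 100, 50, 1, seed=1)

    def test_enhancer_nearest_tss_is_its_target(self, small_genome):
        genes = small_genome.gene_annotations
        for e in small_genome.enhancer_annotations:
            mid = (e.interval.start + e.interval.end) // 2
            nearest = min(genes, key=lambda g: abs(g.tss - mid))
            assert nearest.gene_id == e.target_gene_id


class TestChipSample:
    def test_spike_count_within_3sd_of_design(self, small_genome, neutral_truth):
        depth, s = 100_000, 0.10
        tags = simulate_chip_sample(
            small_genome, neutral_truth, "WT", "H3K4me1", depth=depth,
            spike_fraction=s, seed=2,
        )
        n_spike = sum(t.is_spike for t in tags)
        sd = np.sqrt(depth * s * (1 - s))
        assert abs(n_spike - depth * s) <= 3 * sd

    def test_mean_realized_spike_fraction(self, small_genome, neutral_truth):
        # across 100 simulations the mean fraction is within 0.5% absolute
        fracs = []
        for i in range(100):
            tags = simulate_chip_sample(
                small_genome, neutral_truth, "WT", "H3K4me1", depth=5000,
                spike_fraction=0.10, seed=1000 + i,
            )
            fracs.append(np.mean([t.is_spike for t in tags]))
        assert abs(np.mean(fracs) - 0.10) < 0.005

    def test_identity_case_wt_equals_ko(self, small_genome, neutral_truth):
        # global_depletion = 1, no affected enhancers: identical expectations
        wt = expected_tag_rates(small_genome, neutral_truth, "WT", "H3K4me1", 10**5, 0.1)
        ko = expected_tag_rates(small_genome, neutral_truth, "KO", "H3K4me1", 10**5, 0.1)
        assert wt == ko

    def test_global_depletion_halves_endogenous_not_spike(self, small_genome):
        truth = TruthTable(global_depletion=0.5)
        wt = expected_tag_rates(small_genome, truth, "WT", "H3K4me1", 10**5, 0.1)
        ko = expected_tag_rates(small_genome, truth, "KO", "H3K4me1", 10**5, 0.1)
        assert ko["spike"] == wt["spike"]
        for e in small_genome.enhancer_annotations:
            assert ko[e.enhancer_id] / wt[e.enhancer_id] == pytest.approx(0.5)
        assert ko["background"] / wt["background"] == pytest.approx(0.5)

    def test_per_enhancer_factor_multiplies_global(self, small_genome):
        eid = small_genome.enhancer_annotations[0].enhancer_id
        truth = TruthTable(global_depletion=0.5, affected_enhancers={eid: 0.4})
        wt = expected_tag_rates(small_genome, truth, "WT", "H3K4me1", 10**5, 0.1)
        ko = expected_tag_rates(small_genome, truth, "KO", "H3K4me1", 10**5, 0.1)
        assert ko[eid] / wt[eid] == pytest.approx(0.2)

    def test_ko_kmt2d_emits_background_only(self, small_genome):
        bound = {e.enhancer_id for e in small_genome.enhancer_annotations}
        truth = TruthTable(kmt2d_bound_enhancers=bound)
        wt = expected_tag_rates(small_genome, truth, "WT", "Kmt2d", 10**5, 0.1)
        ko = expected_tag_rates(small_genome, truth, "KO", "Kmt2d", 10**5, 0.1)
        assert set(wt) > set(ko)  # enhancer components absent in KO
        assert set(ko) == {"spike", "background"}

    @pytest.mark.parametrize("genotype, mark", [("HET", "H3K4me1"), ("WT", "H3K9me3")])
    def test_unknown_tokens_rejected(self, small_genome, neutral_truth, genotype, mark):
        with pytest.raises(ValueError, match="unknown"):
            simulate_chip_sample(small_genome, neutral_truth, genotype, mark, depth=100, seed=0)

    def test_deterministic_for_fixed_seed(self, small_genome, neutral_truth):
        a = simulate_chip_sample(small_genome, neutral_truth, "WT", "H3K4me1", depth=2000, seed=7)
        b = simulate_chip_sample(small_genome, neutral_truth, "WT", "H3K4me1", depth=2000, seed=7)
        assert a == b


class TestRnaCounts:
    def test_no_effect_means_equal(self, small_genome, neutral_truth):
        t = simulate_rna_counts(small_genome, neutral_truth, n_reps=100,
                                dispersion=0.0, lib_size=100_000, seed=3)
        wt = t.data.filter(like="WT").mean(axis=1)
        ko = t.data.filter(like="KO").mean(axis=1)
        assert np.allclose(ko / wt, 1.0, atol=0.05)

    def test_planted_factor_scales_ko_mean(self, small_genome):
        gid = small_genome.gene_annotations[0].gene_id
        truth = TruthTable(affected_genes={gid: 0.25})
        t = simulate_rna_counts(small_genome, truth, n_reps=200,
                                dispersion=0.0, lib_size=100_000, seed=4)
        ratio = t.data.loc[gid].filter(like="KO").mean() / t.data.loc[gid].filter(like="WT").mean()
        assert ratio == pytest.approx(0.25, rel=0.08)

    def test_zero_dispersion_is_poisson(self, small_genome, neutral_truth):
        t = simulate_rna_counts(small_genome, neutral_truth, n_reps=500,
                                dispersion=0.0, lib_size=50_000, seed=5)
        wt = t.data.filter(like="WT")
        ratio = wt.var(axis=1) / wt.mean(axis=1)
        assert np.all((ratio > 0.8) & (ratio < 1.25))

    def test_dispersion_inflates_variance(self, small_genome, neutral_truth):
        t = simulate_rna_counts(small_genome, neutral_truth, n_reps=500,
                                dispersion=0.1, lib_size=50_000, seed=5)
        wt = t.data.filter(like="WT")
        assert np.all(wt.var(axis=1) / wt.mean(axis=1) > 2)

    def test_negative_dispersion_rejected(self, small_genome, neutral_truth):
        with pytest.raises(ValueError, match="dispersion"):
            simulate_rna_counts(small_genome, neutral_truth, dispersion=-0.1)


class TestScCounts:
    def test_no_signature_clusters_match(self, small_genome, neutral_truth):
        t, labels = simulate_sc_counts(small_genome, neutral_truth,
                                       n_cells_per_cluster=300, dropout=0.0, seed=6)
        m1 = t.data[labels == "resting"].mean()
        m2 = t.data[labels == "stimulated"].mean()
        assert np.allclose(m2 / m1, 1.0, atol=0.1)

    def test_signature_fold_applies_to_cluster2(self, small_genome):
        gid = small_genome.gene_annotations[0].gene_id
        truth = TruthTable(sc_cluster2_signature={gid: 3.0})
        t, labels = simulate_sc_counts(small_genome, truth,
                                       n_cells_per_cluster=500, dropout=0.0, seed=6)
        ratio = t.data.loc[labels == "stimulated", gid].mean() / t.data.loc[
            labels == "resting", gid].mean()
        assert ratio == pytest.approx(3.0, rel=0.1)

    def test_dropout_thins_to_zeros(self, small_genome, neutral_truth):
        t, _ = simulate_sc_counts(small_genome, neutral_truth,
                                  n_cells_per_cluster=100, dropout=0.9, seed=6)
        assert (t.data.to_numpy() == 0).mean() >= 0.88

    def test_too_few_cells_rejected(self, small_genome, neutral_truth):
        with pytest.raises(ValueError, match="n_cells_per_cluster"):
            simulate_sc_counts(small_genome, neutral_truth, n_cells_per_cluster=2)


class TestTruthTable:
    def test_dual_effect_genes_enumeration(self, small_genome):
        e1, e2, e3 = small_genome.enhancer_annotations[:3]
        truth = TruthTable(
            global_depletion=1.0,
            # e1 passes both arms; e2's gene passes expression only;
            # e3's enhancer passes but its gene expression does not.
            affected_enhancers={e1.enhancer_id: 0.4, e3.enhancer_id: 0.4},
            affected_genes={
                e1.target_gene_id: 0.5,
                e2.target_gene_id: 0.5,
                e3.target_gene_id: 0.8,
            },
        )
        assert truth.dual_effect_genes(small_genome, 1.6) == [e1.target_gene_id]

    def test_global_depletion_counts_toward_enhancer_arm(self, small_genome):
        e1 = small_genome.enhancer_annotations[0]
        truth = TruthTable(
            global_depletion=0.5,
            affected_enhancers={e1.enhancer_id: 0.9},  # net 0.45 <= 1/1.6
            affected_genes={e1.target_gene_id: 0.5},
        )
        assert truth.dual_effect_genes(small_genome, 1.6) == [e1.target_gene_id]

    def test_round_trip_through_frame(self):
        truth = TruthTable(
            global_depletion=0.7,
            affected_enhancers={"e1": 0.4},
            affected_genes={"g1": 0.4},
            kmt2d_bound_enhancers={"e1"},
            sc_cluster2_signature={"g2": 3.0},
        )
        assert truth_from_frame(truth_to_frame(truth)) == truth

    def test_invalid_factors_rejected(self):
        with pytest.raises(ValueError):
            TruthTable(global_depletion=0.0)
        with pytest.raises(ValueError):
            TruthTable(affected_genes={"g1": -1.0})


def test_default_scenario_plants_expected_truth():
    genome, truth = default_scenario(0)
    assert len(genome.gene_annotations) == 1000
    assert len(truth.affected_enhancers) == 100
    assert len(truth.dual_effect_genes(genome)) == 100
    # stratified binding: exactly 60% of affected enhancers are bound
    n_bound_affected = len(set(truth.affected_enhancers) & truth.kmt2d_bound_enhancers)
    assert n_bound_affected == 60
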