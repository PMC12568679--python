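import dataclasses

import numpy as np
import pytest

from enhancerscape.motifs import reverse_complement
from enhancerscape.synthetic_data import (
    SimConfig,
    make_pwm_set,
    simulate_expression_phenotypes,
    simulate_fragments,
    simulate_landscape,
    simulate_sequences_with_motifs,
)


class TestSimulateLandscape:
    def test_deterministic_given_seed(self, small_config, small_truth):
        again = simulate_landscape(small_config)
        assert [dataclasses.astuple(s) for s in again.sites] == [
            dataclasses.astuple(s) for s in small_truth.sites
        ]
        assert again.de_genes == small_truth.de_genes

    def test_distal_fraction_matches_request(self):
        config = SimConfig(
            seed=1, n_sites=1000, fraction_distal=0.5, n_genes=700,
            chrom_length=10_000_000, min_site_spacing=1_500,
        )
        truth = simulate_landscape(config)
        tss = {}
        for g in truth.genes:
            tss.setdefault(g.interval.chrom, []).append(g.tss)
        tss = {c: np.array(v) for c, v in tss.items()}
        distal = sum(
            np.abs(tss[s.interval.chrom] - s.summit).min() > 10_000 for s in truth.sites
        )
        assert 450 <= distal <= 550

    def test_fully_distal_configuration(self):
        config = SimConfig(
            seed=2, n_sites=50, fraction_distal=1.0, n_chroms=1,
            chrom_length=2_000_000, n_genes=40,
        )
        truth = simulate_landscape(config)
        tss = np.array([g.tss for g in truth.genes])
        for s in truth.sites:
            assert np.abs(tss - s.summit).min() > 10_000

    def test_trend_strengths_are_monotone(self, small_truth):
        for s in small_truth.sites:
            l, m, h = s.strengths
            if s.trend == "up":
                assert l <= m <= h and l < h
            elif s.trend == "down":
                assert l >= m >= h and l > h

    def test_overfull_genome_raises(self):
        config = SimConfig(
            seed=0, n_chroms=1, chrom_length=300_000, n_sites=200, n_genes=10
        )
        with pytest.raises(ValueError, match="too small"):
            simulate_landscape(config)


class TestSimulateFragments:
    def test_background_rate_moment_check(self):
        """Zero-strength sites leave pure Poisson background at the configured rate."""
        config = SimConfig(
            seed=3, n_chroms=1, chrom_length=500_000, n_sites=4, n_genes=10,
            trend_strengths={"up": (0, 0, 0), "down": (0, 0, 0), "flat": (0, 0, 0)},
            atac_strength=0.0, background_rate=0.02,
        )
        truth = simulate_landscape(config)
        frag_sets = simulate_fragments(truth, config)
        n = len(frag_sets[0].fragments)
        expected = 0.02 * 500_000
        assert abs(n - expected) <= 3 * np.sqrt(expected)

    def test_strong_site_dominates_coverage(self, small_config, small_truth):
        from enhancerscape.peaks import make_coverage

        config = dataclasses.replace(
            small_config,
            n_sites=1,
            trend_strengths={"up": (50, 50, 50), "down": (50, 50, 50), "flat": (50, 50, 50)},
            reproducible_fraction=1.0,
        )
        truth = simulate_landscape(config)
        site = truth.sites[0]
        for fs in simulate_fragments(truth, config):
            track = make_coverage(fs, 100, truth.genome)[site.interval.chrom]
            top_bin = int(np.argmax(track.counts)) * 100
            assert site.interval.start - 200 <= top_bin <= site.interval.end + 200

    def test_deterministic_given_seed(self, small_config, small_truth):
        a = simulate_fragments(small_truth, small_config)
        b = simulate_fragments(small_truth, small_config)
        assert [(f.chrom, f.start, f.end) for f in a[0].fragments] == [
            (f.chrom, f.start, f.end) for f in b[0].fragments
        ]

    def test_irreproducible_sites_silent_in_second_replicate(self, small_config):
        config = dataclasses.replace(small_config, reproducible_fraction=0.5)
        truth = simulate_landscape(config)
        bad = [s for s in truth.sites if not s.reproducible]
        assert bad
        frag_sets = simulate_fragments(truth, config)
        rep2 = next(fs for fs in frag_sets if fs.sample_id == "H3K27ac_L2")
        site = bad[0]
        inside = sum(
            1 for f in rep2.fragments
            if f.chrom == site.interval.chrom
            and f.start < site.interval.end and site.interval.start < f.end
        )
        # only background-level coverage remains
        bg = config.effective_background_rate * (len(site.interval) + config.fragment_length)
        assert inside <= bg + 4 * np.sqrt(bg) + 1


class TestSimulateSequences:
    def test_planted_consensus_present_in_up_windows(self, small_config, small_truth):
        pwms = make_pwm_set(small_config)
        seqs = simulate_sequences_with_motifs(small_truth, pwms, small_config)
        cons = pwms[0].consensus
        site_by_id = {s.site_id: s for s in small_truth.sites}
        for sid in small_truth.planted_motifs["M_UP"]:
            s = site_by_id[sid]
            window = seqs[s.interval.chrom][s.summit - 110 : s.summit + 110]
            assert cons in window or reverse_complement(cons) in window

    def test_background_gc_content(self):
        config = SimConfig(seed=5, n_chroms=1, chrom_length=1_000_000, n_sites=2,
                           n_genes=10, gc=0.5)
        truth = simulate_landscape(config)
        seqs = simulate_sequences_with_motifs(truth, make_pwm_set(config), config)
        seq = seqs["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.497 <= gc <= 0.503

    def test_unplanted_motif_occurs_at_background_rate(self, small_config, small_truth):
        pwms = make_pwm_set(small_config)
        decoy = pwms[1].consensus
        seqs = simulate_sequences_with_motifs(small_truth, pwms, small_config)
        seq = seqs["chr1"]
        count = seq.count(decoy) + seq.count(reverse_complement(decoy))
        n = 2 * len(seq)  # both strands
        p = 0.25 ** len(decoy)
        assert count <= n * p + 3 * np.sqrt(n * p) + 1


class TestSimulateExpression:
    def test_near_poisson_null_group_means_agree(self, small_truth, small_config):
        config = dataclasses.replace(
            small_config, nb_dispersion=0.0, rna_depth=10_000_000, n_de_genes=0
        )
        truth = dataclasses.replace(small_truth, de_genes={}, trait_links={})
        expr, _ = simulate_expression_phenotypes(truth, config)
        means = expr.counts.T.groupby(lambda s: s[0]).mean().T
        high = means[means.min(axis=1) > 1000]
        ratio = high.max(axis=1) / high.min(axis=1)
        assert (ratio < 1.2).all()

    def test_noise_free_trait_is_perfectly_rank_correlated(self, small_truth, small_config):
        from scipy import stats

        config = dataclasses.replace(small_config, trait_noise_sd=0.0)
        expr, traits = simulate_expression_phenotypes(small_truth, config)
        trait, (gene, direction) = next(iter(small_truth.trait_links.items()))
        rho = stats.spearmanr(
            expr.counts.loc[gene], traits[trait]
        ).statistic
        assert rho == pytest.approx(direction * 1.0)

    def test_deterministic_given_seed(self, small_truth, small_config):
        e1, t1 = simulate_expression_phenotypes(small_truth, small_config)
        e2, t2 = simulate_expression_phenotypes(small_truth, small_config)
        assert e1.counts.equals(e2.counts)
        assert t1.equals(t2)

    def test_de_genes_change_monotonically(self, small_truth, small_config):
        expr, _ = simulate_expression_phenotypes(small_truth, small_config)
        up_genes = [g for g, f in small_truth.de_genes.items() if f[2] > 1]
        means = expr.counts.T.groupby(lambda s: s[0]).mean().T
        frac_up = np.mean([means.loc[g, "H"] > means.loc[g, "L"] for g in up_genes])
        assert frac_up >= 0.9
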