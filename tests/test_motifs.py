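import math

import numpy as np
import pandas as pd
import pytest

from enhancerscape.motifs import (
    PWM,
    cluster_motifs,
    extract_summit_windows,
    hypergeom_upper_tail,
    linkage_to_newick,
    motif_enrichment,
    read_jaspar,
    reverse_complement,
    scan_pwm,
    write_jaspar,
)

from .helpers import make_peak


@pytest.fixture
def sharp_pwm():
    mat = np.full((8, 4), 0.03)
    consensus = "ACGTACGT"
    for i, b in enumerate(consensus):
        mat[i, "ACGT".index(b)] = 0.91
    return PWM("M1", mat)


class TestPWM:
    def test_row_sums_validated(self):
        bad = np.full((6, 4), 0.3)
        with pytest.raises(ValueError, match="sum"):
            PWM("x", bad)

    def test_min_length(self):
        with pytest.raises(ValueError, match="length"):
            PWM("x", np.full((3, 4), 0.25))

    def test_consensus(self, sharp_pwm):
        assert sharp_pwm.consensus == "ACGTACGT"


class TestJasparIO:
    def test_round_trip(self, tmp_path, sharp_pwm):
        path = tmp_path / "m.jaspar"
        write_jaspar([sharp_pwm], path, scale=1000)
        back = read_jaspar(path)
        assert len(back) == 1
        assert back[0].consensus == sharp_pwm.consensus
        assert np.allclose(back[0].matrix, sharp_pwm.matrix, atol=1e-3)


class TestScanPwm:
    def test_planted_consensus_is_hit(self, sharp_pwm, rng):
        flank = "".join(rng.choice(list("ACGT"), 30))
        seq = flank + sharp_pwm.consensus + flank
        hits = scan_pwm(seq, sharp_pwm)
        assert any(h.position == 30 and h.strand == "+" for h in hits)

    def test_reverse_complement_hits_minus_strand(self, sharp_pwm):
        seq = "T" * 20 + reverse_complement(sharp_pwm.consensus) + "T" * 20
        hits = scan_pwm(seq, sharp_pwm)
        assert any(h.position == 20 and h.strand == "-" for h in hits)

    def test_score_matches_per_position_oracle(self, sharp_pwm, rng):
        seq = "".join(rng.choice(list("ACGT"), 40)) + sharp_pwm.consensus
        hits = scan_pwm(seq, sharp_pwm, score_fraction=0.3)
        lo = sharp_pwm.log_odds
        assert any(h.strand == "+" for h in hits)
        for h in hits:
            window = seq[h.position : h.position + len(sharp_pwm)]
            if h.strand == "-":
                window = reverse_complement(window)
            expected = sum(lo[j, "ACGT".index(window[j])] for j in range(len(sharp_pwm)))
            assert h.score == pytest.approx(expected, abs=1e-9)

    def test_mirrored_hits_on_reverse_complement(self, sharp_pwm, rng):
        seq = "".join(rng.choice(list("ACGT"), 60))
        fwd = scan_pwm(seq, sharp_pwm, score_fraction=0.5)
        rev = scan_pwm(reverse_complement(seq), sharp_pwm, score_fraction=0.5)
        n = len(seq) - len(sharp_pwm)
        mirrored = {(n - h.position, "-" if h.strand == "+" else "+") for h in rev}
        assert {(h.position, h.strand) for h in fwd} == mirrored

    def test_short_window_gives_no_hits(self, sharp_pwm):
        assert scan_pwm("ACG", sharp_pwm) == []


class TestExtractSummitWindows:
    def test_window_definition_and_clipping(self):
        genome = {"chr1": "A" * 300 + "CGT" * 100}
        peaks = [
            make_peak("chr1", 100, 300, summit=200, name="mid"),
            make_peak("chr1", 0, 100, summit=50, name="edge"),
        ]
        windows = extract_summit_windows(peaks, genome, flank=100)
        assert len(windows["mid"]) == 200
        assert windows["mid"] == genome["chr1"][100:300]
        assert windows["edge"] == genome["chr1"][0:150]  # clipped at the start

    def test_summit_outside_genome_rejected(self):
        genome = {"chr1": "ACGT" * 10}
        with pytest.raises(ValueError):
            extract_summit_windows([make_peak("chr1", 30, 60, summit=50)], genome)


class TestMotifEnrichment:
    def test_exact_hypergeometric_term(self):
        # N=10, n=4, K=5, k=4 -> C(5,4)C(5,0)/C(10,4) = 5/210
        assert hypergeom_upper_tail(4, 4, 5, 10) == pytest.approx(5 / 210)

    def test_zero_hits_boundary(self, sharp_pwm):
        targets = {f"t{i}": "A" * 30 for i in range(3)}
        background = {f"b{i}": "A" * 30 for i in range(3)}
        pwm = PWM("gg", np.tile(np.array([[0.03, 0.03, 0.91, 0.03]]), (6, 1)))
        (res,) = motif_enrichment(targets, background, [pwm])
        assert res.k == 0 and res.pvalue == 1.0 and res.fold == 0.0

    def test_hypergeometric_matches_enumeration_oracle(self):
        """Exact summation over the tail for all small configurations N <= 30."""
        for N, n, K, k in [(10, 4, 5, 4), (20, 5, 4, 4), (30, 10, 12, 7), (8, 3, 3, 1)]:
            tail = sum(
                math.comb(K, j) * math.comb(N - K, n - j) / math.comb(N, n)
                for j in range(k, min(n, K) + 1)
            )
            assert hypergeom_upper_tail(k, n, K, N) == pytest.approx(tail, rel=1e-12)

    def test_planted_motif_ranks_first_among_decoys(self, rng):
        def cons_pwm(name, consensus):
            mat = np.full((len(consensus), 4), 0.03)
            for i, b in enumerate(consensus):
                mat[i, "ACGT".index(b)] = 0.91
            return PWM(name, mat)

        planted = cons_pwm("planted", "ACGTACGTAC")
        decoys = []
        while len(decoys) < 10:
            cons = "".join(rng.choice(list("ACGT"), 10))
            if cons != planted.consensus:
                decoys.append(cons_pwm(f"d{len(decoys)}", cons))

        def random_seq(n):
            return "".join(rng.choice(list("ACGT"), n))

        targets = {}
        for i in range(100):
            seq = random_seq(200)
            if rng.random() < 0.9:
                pos = int(rng.integers(0, 190))
                seq = seq[:pos] + planted.consensus + seq[pos + 10 :]
            targets[f"t{i}"] = seq
        background = {f"b{i}": random_seq(200) for i in range(300)}
        results = motif_enrichment(targets, background, [planted] + decoys)
        ranked = sorted(results, key=lambda r: r.pvalue)
        assert ranked[0].unit_id == "planted"
        assert ranked[0].qvalue < 1e-6

    def test_overlapping_target_background_rejected(self, sharp_pwm):
        with pytest.raises(ValueError):
            motif_enrichment({"x": "ACGT"}, {"x": "ACGT"}, [sharp_pwm])


class TestClusterMotifs:
    def test_identical_rows_merge_first(self):
        df = pd.DataFrame(
            [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [9.0, 1.0, 4.0]],
            index=["a", "b", "c"],
            columns=["s1", "s2", "s3"],
        )
        z, link, order = cluster_motifs(df)
        assert link[0][2] == pytest.approx(0.0)  # first merge at distance 0
        first = {int(link[0][0]), int(link[0][1])}
        assert first == {0, 1}

    def test_anticorrelated_rows_at_distance_two(self):
        df = pd.DataFrame(
            [[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]], index=["a", "b"], columns=["x", "y", "z"]
        )
        _, link, _ = cluster_motifs(df)
        assert link[0][2] == pytest.approx(2.0)

    def test_zscores_use_sample_sd(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0], [5.0, 5.0, 6.0]], index=["a", "b"],
                          columns=["x", "y", "z"])
        z, _, _ = cluster_motifs(df)
        assert z.loc["a"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_newick_export_contains_all_leaves(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.random((5, 4)), index=list("abcde"))
        _, link, _ = cluster_motifs(df)
        nwk = linkage_to_newick(link, list("abcde"))
        assert nwk.endswith(";") and all(l in nwk for l in "abcde")
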