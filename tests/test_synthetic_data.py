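import warnings

import numpy as np
import pandas as pd
import pytest

from bivalscan import chromatin_state as cs
from bivalscan import genomic_io as gio
from bivalscan import synthetic_data as sd


class TestSimulateTruth:
    def test_determinism(self):
        a = sd.simulate_truth(100, seed=5)
        b = sd.simulate_truth(100, seed=5)
        pd.testing.assert_frame_equal(a.promoters, b.promoters)

    def test_zero_repressed_proportion(self):
        truth = sd.simulate_truth(
            100,
            class_proportions={"BIVALENT": 0.5, "ACTIVE": 0.5, "REPRESSED": 0.0, "LATENT": 0.0},
            seed=5,
        )
        assert not (truth.promoters["true_class"] == "REPRESSED").any()

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            sd.simulate_truth(10, class_proportions={"BIVALENT": 0.5}, seed=0)

    def test_spacing_validated(self):
        with pytest.raises(ValueError, match="spacing"):
            sd.simulate_truth(10, spacing=5000, seed=0)

    def test_promoters_spaced_apart(self):
        truth = sd.simulate_truth(50, seed=6)
        gaps = np.diff(truth.promoters["tss_pos"].to_numpy())
        assert (gaps >= 12000).all()


class TestSimulateReference:
    def test_seed_repeated_identical_fasta_bytes(self):
        a = sd.simulate_reference(n_promoters=40, seed=9)
        b = sd.simulate_reference(n_promoters=40, seed=9)
        assert a.sequence == b.sequence

    def test_cgi_recorded_only_for_cpg_rich(self, small_ref):
        truth = small_ref.truth.promoters
        assert len(small_ref.cgi) == int(truth["cpg_rich"].sum())

    def test_cpg_rich_cores_pass_cgi_thresholds(self, small_ref):
        from bivalscan.cpg import cpg_obs_exp_ratio

        truth = small_ref.truth.promoters
        rich = truth[truth.cpg_rich].head(20)
        for row in rich.itertuples():
            core = small_ref.genome.fetch(
                row.chrom, int(row.tss_pos) - 200, int(row.tss_pos) + 200
            )
            gc = (core.count("G") + core.count("C")) / len(core)
            assert gc > 0.5
            assert cpg_obs_exp_ratio(core) > 0.6

    def test_unplanted_promoters_lack_motifs(self, small_ref):
        from bivalscan.motif import motif_fraction

        truth = small_ref.truth.promoters
        clean = truth[truth.motif == ""].head(30)
        seqs = [
            small_ref.genome.fetch(r.chrom, int(r.tss_pos) - 1000, int(r.tss_pos) + 2000)
            for r in clean.itertuples()
        ]
        assert motif_fraction(seqs, "TCCCC") == 0.0
        assert motif_fraction(seqs, "CGGAA") == 0.0


class TestSimulateChip:
    def test_noiseless_recovery(self):
        truth = sd.simulate_truth(150, seed=13)
        chip = sd.simulate_chip_samples(
            truth, n_samples=4, k4_detect_p=1.0, k27_detect_p=1.0,
            false_positive_rate=0.0, seed=14,
        )
        matrix = cs.build_state_matrix(truth.promoter_regions(), chip.sample_pairs())
        classes = cs.consensus_classify(matrix)
        expected = truth.hc_classes()
        assert all(str(classes[p]) == expected[p] for p in expected)

    def test_determinism(self):
        truth = sd.simulate_truth(60, seed=15)
        a = sd.simulate_chip_samples(truth, n_samples=3, seed=16)
        b = sd.simulate_chip_samples(truth, n_samples=3, seed=16)
        for sa, sb in zip(a.samples, b.samples):
            assert sa.k4_peaks.intervals == sb.k4_peaks.intervals
            assert sa.k27_peaks.intervals == sb.k27_peaks.intervals
            assert sa.depth == sb.depth

    def test_variability_contrast(self):
        # variable per-sample K27 detection vs tight K4 detection
        truth = sd.simulate_truth(2000, seed=17)
        chip = sd.simulate_chip_samples(
            truth, n_samples=10, k4_detect_p=(0.93, 0.99),
            k27_detect_p=(0.4, 0.95), seed=18,
        )
        matrix = cs.build_state_matrix(truth.promoter_regions(), chip.sample_pairs())
        states = matrix.states
        k4_counts = ((states == 1) | (states == 3)).sum(axis=0)
        k27_counts = ((states == 2) | (states == 3)).sum(axis=0)
        k4_rel = 100 * k4_counts.std(ddof=1) / k4_counts.mean()
        k27_rel = 100 * k27_counts.std(ddof=1) / k27_counts.mean()
        assert k4_rel < 10.0
        assert k27_rel > 20.0

    def test_bivalent_k27_stronger_than_repressed(self):
        truth = sd.simulate_truth(500, seed=19)
        chip = sd.simulate_chip_samples(truth, n_samples=1, seed=20)
        cls = truth.promoters.set_index("promoter_id")["true_class"]
        from bivalscan.chromatin_state import promoter_signal_scores

        s = promoter_signal_scores(truth.promoter_regions(), chip.samples[0].k27_peaks)
        series = pd.Series(s)
        biv = series[cls == "BIVALENT"]
        rep = series[cls == "REPRESSED"]
        assert biv[biv > 0].mean() > rep[rep > 0].mean()


class TestSimulateFactors:
    def test_zero_factors(self):
        truth = sd.simulate_truth(20, seed=23)
        assert sd.simulate_factors(truth, n_factors=0, seed=24) == {}

    def test_invalid_odds(self):
        truth = sd.simulate_truth(20, seed=23)
        with pytest.raises(ValueError, match="odds"):
            sd.simulate_factors(
                truth, n_factors=1, class_odds={"BIVALENT": 0.0}, seed=24
            )

    def test_determinism(self):
        truth = sd.simulate_truth(50, seed=25)
        a = sd.simulate_factors(truth, n_factors=3, seed=26)
        b = sd.simulate_factors(truth, n_factors=3, seed=26)
        for name in a:
            assert a[name].intervals == b[name].intervals


class TestSimulateExpression:
    def test_dropout_one_means_all_cells_zero(self):
        truth = sd.simulate_truth(50, seed=27)
        expr = sd.simulate_expression(
            truth,
            dropout_rates={c: 1.0 for c in sd.TRUE_CLASSES},
            n_cells=10,
            seed=28,
        )
        assert (expr.single_cell.to_numpy() == 0).all()

    def test_bulk_ordering(self):
        truth = sd.simulate_truth(600, seed=29)
        expr = sd.simulate_expression(truth, seed=30)
        cls = truth.promoters.set_index("gene_id")["true_class"]
        med = expr.bulk.groupby(cls).median()
        assert med["ACTIVE"] > med["BIVALENT"] > med["LATENT"]

    def test_latent_mostly_silent(self):
        truth = sd.simulate_truth(600, seed=29)
        expr = sd.simulate_expression(truth, seed=30)
        cls = truth.promoters.set_index("gene_id")["true_class"]
        latent = expr.bulk[cls == "LATENT"]
        assert (latent == 0).mean() > 0.7

    def test_invalid_cells(self):
        truth = sd.simulate_truth(10, seed=31)
        with pytest.raises(ValueError):
            sd.simulate_expression(truth, n_cells=0, seed=32)


class TestSimulateOrthologs:
    def test_full_conservation_diagonal(self):
        from bivalscan.cross_species import state_overlap

        truth = sd.simulate_truth(200, seed=33)
        truth_b, pairs = sd.simulate_orthologs(
            truth, conservation_rates={c: 1.0 for c in sd.TRUE_CLASSES}, seed=34
        )
        forward, _ = state_overlap(
            truth.hc_classes(level="gene"), truth_b.hc_classes(level="gene"), pairs
        )
        counts = forward.counts.to_numpy()
        assert (counts == np.diag(np.diag(counts))).all()

    def test_determinism(self):
        truth = sd.simulate_truth(100, seed=35)
        a, pa = sd.simulate_orthologs(truth, seed=36)
        b, pb = sd.simulate_orthologs(truth, seed=36)
        pd.testing.assert_frame_equal(a.promoters, b.promoters)
        assert pa == pb

    def test_pairs_one_to_one(self):
        from bivalscan.cross_species import validate_pairs

        truth = sd.simulate_truth(100, seed=37)
        _, pairs = sd.simulate_orthologs(truth, seed=38)
        validate_pairs(pairs)  # should not raise


class TestFileOutputs:
    def test_generated_files_parse_cleanly(self, tmp_path):
        study = sd.simulate_study(
            seed=39,
            n_promoters=60,
            n_samples_a=2,
            n_samples_b=2,
            n_factors=2,
            n_de_lists=2,
            n_cells=5,
            with_fragments=True,
            out_dir=tmp_path,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            tss = gio.read_tss_annotation(tmp_path / "annotation.gtf")
            assert len(tss) == 60
            cgi = gio.read_bed(tmp_path / "cgi.bed", "ref", "CGI")
            assert cgi.n_rejected == 0
            pairs = pd.read_csv(tmp_path / "chip_a" / "pairs.tsv", sep="\t")
            for row in pairs.itertuples():
                k4 = gio.read_bed(tmp_path / "chip_a" / row.k4_bed, row.sample_id, "k4")
                assert k4.n_rejected == 0
                frag = gio.read_bed(
                    tmp_path / "chip_a" / row.k4_fragments, row.sample_id, "f"
                )
                assert frag.n_rejected == 0
            genome = gio.Genome.from_fasta(tmp_path / "genome.fa")
            assert genome.chrom_length("chrS") == study.reference.truth.chrom_length

    def test_gtf_tss_round_trip(self, tmp_path):
        truth = sd.simulate_truth(50, seed=40)
        sd.write_tss_gtf(truth, tmp_path / "ann.gtf")
        records = gio.read_tss_annotation(tmp_path / "ann.gtf")
        by_id = {r.transcript_id: r for r in records}
        for row in truth.promoters.itertuples():
            rec = by_id[row.promoter_id]
            assert rec.position == int(row.tss_pos)
            assert rec.strand == row.strand
            assert rec.gene_id == row.gene_id

    def test_fasta_round_trips_sequence(self, tmp_path):
        ref = sd.simulate_reference(n_promoters=30, seed=41)
        sd.write_reference(ref, tmp_path)
        genome = gio.Genome.from_fasta(tmp_path / "genome.fa")
        assert genome.fetch("chrS", 0, 500) == ref.sequence[:500]
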