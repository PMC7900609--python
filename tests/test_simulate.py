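"""Generator contracts: determinism, the origin-driven replication program,
Poisson observation statistics, gap monotonicity, the calibrated
antisense/sense expectation, and the recovery evaluator."""

import numpy as np
import pandas as pd
import pytest

import replitx as rx
from replitx import simulate as sim


@pytest.fixture(scope="module")
def small_cfg():
    return rx.SimConfig(n_chrom=1, chrom_length=3_000_000, n_genes=40, seed=3)


@pytest.fixture(scope="module")
def small_sim(small_cfg):
    genome, genes, truth = rx.build_genome(small_cfg, 3)
    return genome, genes, truth


class TestBuildGenome:
    def test_deterministic(self, small_cfg):
        a = rx.build_genome(small_cfg, 3)
        b = rx.build_genome(small_cfg, 3)
        assert a[1] == b[1]
        assert a[2].transcripts.equals(b[2].transcripts)
        for c in a[0].chrom_names:
            np.testing.assert_array_equal(a[2].rep_time[c], b[2].rep_time[c])

    def test_genes_do_not_overlap(self, small_sim):
        _, genes, _ = small_sim
        primaries = rx.dedupe_longest(genes)
        primaries.sort(key=lambda g: (g.chrom, g.start))
        for a, b in zip(primaries, primaries[1:]):
            assert a.chrom != b.chrom or a.end <= b.start

    def test_replication_time_is_origin_propagation(self, small_sim):
        genome, _, truth = small_sim
        cfg = truth.config
        for chrom in genome.chrom_names:
            opos = np.array([p for p, _ in truth.origins[chrom]], dtype=float)
            ot0 = np.array([t for _, t in truth.origins[chrom]])
            centers = np.arange(len(truth.rep_time[chrom])) * cfg.bin_size + cfg.bin_size / 2
            expect = (ot0[:, None] + np.abs(centers - opos[:, None]) / cfg.fork_speed).min(axis=0)
            np.testing.assert_allclose(truth.rep_time[chrom], expect)

    def test_fork_direction_flips_only_at_origins_and_termini(self, small_sim):
        genome, _, truth = small_sim
        for chrom in genome.chrom_names:
            d = truth.fork_dir[chrom]
            flips = np.flatnonzero(np.diff(np.sign(d[d != 0])))
            # number of sign changes = number of origins + termini between them
            n_origins = len(truth.origins[chrom])
            assert len(flips) == 2 * n_origins - 1

    def test_single_origin_geometry(self):
        cfg = rx.SimConfig(n_chrom=1, chrom_length=900_000, n_genes=5,
                           origin_spacing=900_000, origin_jitter=0, seed=0)
        genome, _, truth = rx.build_genome(cfg, 0)
        (opos, t0), = truth.origins["chr1"]
        i = opos // cfg.bin_size
        d = truth.fork_dir["chr1"]
        assert (d[: i - 1] == -1).all() and (d[i + 2 :] == 1).all()
        # time grows linearly with distance on both flanks
        T = truth.rep_time["chr1"]
        assert T[i] == pytest.approx(t0, abs=cfg.bin_size / cfg.fork_speed)
        assert T[i + 100] == pytest.approx(T[i + 200] - 100 * cfg.bin_size / cfg.fork_speed)

    def test_genome_too_small_rejected(self):
        cfg = rx.SimConfig(n_chrom=1, chrom_length=400_000, n_genes=200)
        with pytest.raises(rx.ValidationError):
            rx.build_genome(cfg, 0)

    def test_exon_structure_valid(self, small_sim):
        _, genes, _ = small_sim
        for g in genes:
            assert 2 <= len(g.exons) <= 20


class TestBrduSimulation:
    def test_deterministic(self, small_cfg, small_sim):
        genome, genes, truth = small_sim
        a = rx.simulate_timecourse_brdu(genome, truth, small_cfg, 5)
        b = rx.simulate_timecourse_brdu(genome, truth, small_cfg, 5)
        for l in a.tracks:
            assert a.tracks[l].equal(b.tracks[l])
        assert a.input_track.equal(b.input_track)

    def test_mean_counts_near_target(self, small_cfg, small_sim):
        genome, genes, truth = small_sim
        series = rx.simulate_timecourse_brdu(genome, truth, small_cfg, 5)
        n = sum(genome.n_bins(c, small_cfg.bin_size) for c in genome.chrom_names)
        assert n >= 10_000
        for l, t in series.tracks.items():
            counts = np.concatenate([t.values[c] for c in t.values]) * small_cfg.bin_size
            se = np.sqrt(small_cfg.brdu_reads_per_bin / n)
            assert abs(counts.mean() - small_cfg.brdu_reads_per_bin) < 3 * se * 3

    def test_poisson_dispersion_near_one(self, small_cfg, small_sim):
        genome, genes, truth = small_sim
        series = rx.simulate_timecourse_brdu(genome, truth, small_cfg, 5)
        inp = series.input_track
        counts = np.concatenate([inp.values[c] for c in inp.values]) * small_cfg.bin_size
        dispersion = counts.var() / counts.mean()
        assert 0.9 < dispersion < 1.1

    def test_deeper_gap_lowers_tss_signal(self, small_cfg):
        genome, genes, truth = rx.build_genome(small_cfg, 3)
        t = truth.transcripts
        tx = t[(t.expressed) & (t.gap_depth > 0)].iloc[0]
        gmap = {g.transcript_id: g for g in genes}
        gene = gmap[tx.transcript_id]
        means = []
        for depth in (0.2, 0.5, 0.8):
            truth.transcripts.loc[t.transcript_id == tx.transcript_id, "gap_depth"] = depth
            series = rx.simulate_timecourse_brdu(genome, truth, small_cfg, 9)
            track = series.tracks[tx.true_timepoint]
            w0, w1 = gene.oriented_window(500, 500)
            means.append(track.window_mean(gene.chrom, w0, w1))
        assert means[0] > means[1] > means[2]

    def test_expected_signal_outside_gaps_unaffected_by_gap_depth(self, small_cfg):
        # summed expected signal over time points is gap-independent outside
        # gap windows: compare two simulations differing only in gap depth
        cfg0 = rx.SimConfig(**{**small_cfg.to_dict(), "gap_depth": 0.2,
                               "length_class_weights": tuple(small_cfg.length_class_weights)})
        cfg1 = rx.SimConfig(**{**small_cfg.to_dict(), "gap_depth": 0.8,
                               "length_class_weights": tuple(small_cfg.length_class_weights)})
        g0, genes0, t0 = rx.build_genome(cfg0, 3)
        g1, genes1, t1 = rx.build_genome(cfg1, 3)
        assert genes0 == genes1  # gap depth does not perturb placement
        s0 = rx.simulate_timecourse_brdu(g0, t0, cfg0, 3)
        s1 = rx.simulate_timecourse_brdu(g1, t1, cfg1, 3)
        # intergenic window far from every gene
        gaps_free = (2_900_000, 2_950_000)
        for l in s0.tracks:
            a = s0.tracks[l].window_mean("chr1", *gaps_free)
            b = s1.tracks[l].window_mean("chr1", *gaps_free)
            assert a == pytest.approx(b, rel=0.05)


class TestChrRna:
    def test_shutdown_reduces_intron_signal_at_replication(self, small_cfg, small_sim):
        genome, genes, truth = small_sim
        tracks = rx.simulate_chr_rna(genome, truth, small_cfg, 11, genes=genes)
        t = truth.transcripts.set_index("transcript_id")
        gmap = {g.transcript_id: g for g in genes}
        ratios = []
        for tx, row in t.iterrows():
            if not row.expressed or row.shutdown_applied >= 1 or row.true_timepoint_index < 1:
                continue
            g = gmap[tx]
            labels = list(small_cfg.timepoints)
            during = labels[row.true_timepoint_index]
            before = labels[row.true_timepoint_index - 1]
            a = tracks[during][g.strand].window_mean(g.chrom, g.start, g.end)
            b = tracks[before][g.strand].window_mean(g.chrom, g.start, g.end)
            if b > 0:
                ratios.append(a / b)
        assert np.mean(ratios) == pytest.approx(small_cfg.shutdown_factor, abs=0.03)

    def test_silent_gene_has_zero_track(self, small_cfg, small_sim):
        genome, genes, truth = small_sim
        t = truth.transcripts.set_index("transcript_id")
        silent = [g for g in genes if not t.loc[g.transcript_id, "expressed"]]
        if not silent:
            pytest.skip("no silent gene drawn in this genome")
        tracks = rx.simulate_chr_rna(genome, truth, small_cfg, 11, genes=genes)
        g = silent[0]
        assert tracks["G1/S"][g.strand].window_mass(g.chrom, g.start, g.end) == 0

    def test_antisense_calibration_matches_closed_form(self, small_cfg, small_sim):
        # expected antisense mass upstream = ratio x expected sense mass in
        # the +/-1 kb window; the observed estimate converges to the ratio
        genome, genes, truth = small_sim
        tracks = rx.simulate_chr_rna(genome, truth, small_cfg, 13, genes=genes)
        t = truth.transcripts.set_index("transcript_id")
        pair = tracks["G1/S"]
        vals, targets = [], []
        for g in rx.dedupe_longest(genes):
            row = t.loc[g.transcript_id]
            if not row.expressed:
                continue
            from replitx.transcription import antisense_sense_ratio
            r = antisense_sense_ratio(pair, g)
            if np.isfinite(r):
                vals.append(r)
                targets.append(row.antisense_ratio)
        ratio = np.array(vals) / np.array(targets)
        assert ratio.mean() == pytest.approx(1.0, abs=0.05)


class TestGroseq:
    def test_uniform_pausing_gives_flat_gene(self):
        cfg = rx.SimConfig(n_chrom=1, chrom_length=2_000_000, n_genes=20,
                           pausing_median=1.0, pausing_log_sd=0.0,
                           silent_fraction=0.0, seed=4)
        genome, genes, truth = rx.build_genome(cfg, 4)
        gro = rx.simulate_groseq(genome, truth, cfg, 4)
        from replitx.transcription import compute_p3r2
        vals = [compute_p3r2(gro, g) for g in rx.dedupe_longest(genes)]
        vals = [v for v in vals if np.isfinite(v)]
        assert np.mean(vals) == pytest.approx(1.0, abs=0.05)


class TestEvaluateRecovery:
    def test_oracle_on_itself_is_perfect(self, small_sim):
        genome, genes, truth = small_sim
        t = truth.transcripts
        metrics = pd.DataFrame({
            "transcript_id": t.transcript_id,
            "gene_id": t.gene_id,
            "transcribed": t.expressed,
            "replication_timepoint": t.true_timepoint.replace("", None),
            "directionality": t.true_directionality,
            "shutdown_flag": t.shutdown_applied < 1,
            "shutdown_fc": t.shutdown_applied,
            "recovery_fc": 1.0,
            "p3r2": t.pausing,
            "antisense_sense_ratio": t.antisense_ratio,
            "gap_depth": t.gap_depth,
            "gap_width_bp": t.gap_width_bp,
            "gmids_hotspot": t.hotspot,
        })
        rep = rx.evaluate_recovery(truth, metrics)
        assert rep["directionality_accuracy"] == 1.0
        assert rep["timepoint_match_rate"] == 1.0
        assert rep["shutdown_sensitivity"] == 1.0
        assert rep["shutdown_fpr"] == 0.0
        assert rep["p3r2_rmse"] == 0.0
        assert rep["gap_depth_rmse"] == 0.0
        assert rep["hotspot_sensitivity"] == 1.0
        assert rep["hotspot_fdr"] == 0.0

    def test_random_labels_score_near_chance(self, small_sim):
        genome, genes, truth = small_sim
        t = truth.transcripts
        rng = np.random.default_rng(0)
        classes = ["codirectional", "head_to_head", "transition"]
        # balanced 3-class truth with uniformly random predictions
        truth2 = truth
        n = len(t)
        t2 = t.copy()
        t2["true_directionality"] = [classes[i % 3] for i in range(n)]
        t2["expressed"] = True
        truth2 = sim.SimTruth(truth.genome, truth.config, truth.origins,
                              truth.rep_time, truth.fork_dir, t2)
        metrics = pd.DataFrame({
            "transcript_id": t.transcript_id,
            "gene_id": t.gene_id,
            "transcribed": True,
            "replication_timepoint": t.true_timepoint.replace("", None),
            "directionality": rng.choice(classes, n),
            "shutdown_flag": False, "shutdown_fc": 1.0, "recovery_fc": 1.0,
            "p3r2": 1.0, "antisense_sense_ratio": 1.0,
            "gap_depth": 0.0, "gap_width_bp": 0.0, "gmids_hotspot": False,
        })
        rep = rx.evaluate_recovery(truth2, metrics)
        assert rep["directionality_accuracy"] == pytest.approx(1 / 3, abs=0.15)

    def test_disjoint_gene_sets_rejected(self, small_sim):
        genome, genes, truth = small_sim
        metrics = pd.DataFrame({"transcript_id": ["nope.1"], "gene_id": ["nope"]})
        with pytest.raises(rx.ValidationError):
            rx.evaluate_recovery(truth, metrics)


class TestConfig:
    def test_unknown_key_rejected(self):
        with pytest.raises(rx.ValidationError):
            rx.SimConfig.from_dict({"not_a_knob": 1})

    def test_round_trip(self):
        cfg = rx.SimConfig(n_genes=17, shutdown_factor=0.75)
        assert rx.SimConfig.from_dict(cfg.to_dict()) == cfg

    @pytest.mark.parametrize("field,value", [
        ("shutdown_factor", 0.0), ("shutdown_factor", 1.2),
        ("hotspot_fraction", -0.1), ("sigma_t", 0.0),
        ("length_class_weights", (0.5, 0.5, 0.5, 0.5)),
    ])
    def test_invalid_values_rejected(self, field, value):
        with pytest.raises(rx.ValidationError):
            rx.SimConfig(**{field: value})
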