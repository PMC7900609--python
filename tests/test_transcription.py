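"""Transcription quantification: RPM filter, intron-restricted nascent
levels (with a per-base oracle), shutdown detection, pausing release ratio
and antisense/sense ratios, plus the scale-invariance property."""

import numpy as np
import pandas as pd
import pytest

import replitx as rx
from replitx import transcription as tr


def stranded(genome, plus=1.0, minus=1.0, bin_size=50):
    def mk(v, s):
        t = rx.CoverageTrack.zeros(genome, bin_size, s)
        for c in t.values:
            t.values[c][:] = v
        return t
    return {"+": mk(plus, "+"), "-": mk(minus, "-")}


class TestRpmFilter:
    def test_rpm_definition(self, genome, plus_gene):
        # gene mass fraction 2e-6 of the track -> RPM 2
        tracks = {"t0": stranded(genome, plus=0.0, minus=1.0)}
        track = tracks["t0"]["+"]
        # put all plus-strand mass outside the gene except 2e-6 of it inside
        track.values["chr2"][:] = 1.0
        inside = plus_gene.length  # bp
        outside = genome.length("chr2")
        # density so that gene mass / total = 2e-6
        track.values["chr1"][plus_gene.start // 50 : plus_gene.end // 50] = (
            2e-6 * outside / (inside * (1 - 2e-6))
        )
        df = tr.rpm_and_transcribed_filter(tracks, [plus_gene]).iloc[0]
        assert df["rpm_t0"] == pytest.approx(2.0, rel=1e-6)
        assert df["transcribed"]

    def test_one_low_timepoint_fails_filter(self, genome, plus_gene):
        high = stranded(genome, plus=1.0)
        low = stranded(genome, plus=1.0)
        # dilute the gene's share below 1 RPM at the second time point
        low["+"].values["chr1"][plus_gene.start // 50 : plus_gene.end // 50] = 1e-6
        df = tr.rpm_and_transcribed_filter({"a": high, "b": low}, [plus_gene])
        assert not df.iloc[0]["transcribed"]

    def test_zero_mass_track_rejected(self, genome, plus_gene):
        tracks = {"a": stranded(genome, plus=0.0, minus=0.0)}
        with pytest.raises(rx.ValidationError):
            tr.rpm_and_transcribed_filter(tracks, [plus_gene])


class TestIntronNascent:
    def test_unweighted_mean_across_introns(self, genome, plus_gene):
        pair = stranded(genome, plus=0.0)
        t = pair["+"]
        (i1s, i1e), (i2s, i2e) = plus_gene.introns
        t.values["chr1"][i1s // 50 : i1e // 50] = 2.0
        t.values["chr1"][i2s // 50 : i2e // 50] = 4.0
        t.values["chr2"][:] = 1.0  # background mass elsewhere
        out = tr.intron_nascent_levels({"t0": pair}, [plus_gene])
        rpm = t.to_rpm()
        expect = (rpm.window_mean("chr1", i1s, i1e) + rpm.window_mean("chr1", i2s, i2e)) / 2
        assert out.iloc[0]["nascent_t0"] == pytest.approx(expect, rel=1e-12)
        assert out.iloc[0]["n_introns"] == 2

    def test_uniform_track_equals_body_density(self, genome, plus_gene):
        pair = stranded(genome, plus=3.0)
        out = tr.intron_nascent_levels({"t0": pair}, [plus_gene])
        rpm = pair["+"].to_rpm()
        assert out.iloc[0]["nascent_t0"] == pytest.approx(
            rpm.window_mean("chr1", plus_gene.start, plus_gene.end), rel=1e-12
        )

    def test_matches_per_base_oracle(self, genome, plus_gene, minus_gene):
        rng = np.random.default_rng(5)
        pair = stranded(genome, plus=0.0, minus=0.0)
        for s in pair:
            for c in pair[s].values:
                pair[s].values[c][:] = rng.poisson(6, len(pair[s].values[c]))
        out = tr.intron_nascent_levels({"t0": pair}, [plus_gene, minus_gene])
        for g, row in zip([plus_gene, minus_gene], out.itertuples()):
            rpm = pair[g.strand].to_rpm()
            means = []
            for s, e in g.introns:
                means.append(np.mean([rpm.density_at(g.chrom, x) for x in range(s, e)]))
            assert row.nascent_t0 == pytest.approx(np.mean(means), rel=1e-6)

    def test_exonic_signal_does_not_change_nascent(self, genome, plus_gene):
        pair = stranded(genome, plus=2.0)
        base = tr.intron_nascent_levels({"t0": pair}, [plus_gene])
        boosted = {"+": pair["+"].copy(), "-": pair["-"]}
        for s, e in plus_gene.exons:
            boosted["+"].values["chr1"][s // 50 : e // 50] += 10.0
        out = tr.intron_nascent_levels({"t0": boosted}, [plus_gene])
        # intron densities are untouched; the nascent value changes only by
        # the RPM renormalization factor of the whole track
        r0 = base.iloc[0]["nascent_t0"]
        r1 = out.iloc[0]["nascent_t0"]
        factor = pair["+"].total_mass / boosted["+"].total_mass
        assert r1 == pytest.approx(r0 * factor, rel=1e-12)
        for s, e in plus_gene.introns:
            assert boosted["+"].window_mean("chr1", s, e) == \
                   pair["+"].window_mean("chr1", s, e)

    def test_intronless_gene_undefined(self, genome):
        g = rx.GeneRecord("g", "g.1", "chr1", 1000, 2000, "+", ((1000, 2000),))
        pair = stranded(genome, plus=1.0)
        out = tr.intron_nascent_levels({"t0": pair}, [g])
        assert np.isnan(out.iloc[0]["nascent_t0"])


class TestDetectShutdown:
    labels = ("g1s", "t1", "t2", "t3")

    def _nascent(self, values):
        row = {"transcript_id": "g.1"}
        row.update({f"nascent_{l}": v for l, v in zip(self.labels, values)})
        return pd.DataFrame([row])

    def test_fold_changes_and_flag(self):
        nas = self._nascent((10.0, 8.0, 9.5, 10.0))
        tp = pd.Series({"g.1": "t1"})
        out = tr.detect_shutdown(nas, tp, self.labels).iloc[0]
        assert out["shutdown_fc"] == pytest.approx(0.8)
        assert out["recovery_fc"] == pytest.approx(0.95)
        assert bool(out["shutdown_flag"])

    def test_constant_levels_not_flagged(self):
        nas = self._nascent((5.0, 5.0, 5.0, 5.0))
        out = tr.detect_shutdown(nas, pd.Series({"g.1": "t2"}), self.labels).iloc[0]
        assert out["shutdown_fc"] == pytest.approx(1.0)
        assert not bool(out["shutdown_flag"])

    def test_replication_at_first_label_undefined(self):
        nas = self._nascent((5.0, 5.0, 5.0, 5.0))
        out = tr.detect_shutdown(nas, pd.Series({"g.1": "g1s"}), self.labels).iloc[0]
        assert np.isnan(out["shutdown_fc"])

    def test_zero_prior_level_undefined(self):
        nas = self._nascent((0.0, 5.0, 5.0, 5.0))
        out = tr.detect_shutdown(nas, pd.Series({"g.1": "t1"}), self.labels).iloc[0]
        assert np.isnan(out["shutdown_fc"])

    def test_no_timepoint_undefined(self):
        nas = self._nascent((5.0, 4.0, 5.0, 5.0))
        out = tr.detect_shutdown(nas, pd.Series({"g.1": None}), self.labels).iloc[0]
        assert np.isnan(out["shutdown_fc"]) and pd.isna(out["shutdown_flag"])


class TestP3R2:
    def _gene(self, genome, strand="+", length=5000):
        if strand == "+":
            start, end = 10_000, 10_000 + length
        else:
            start, end = 30_000 - length, 30_000
        return rx.GeneRecord("g", "g.1", "chr1", start, end, strand,
                             ((start, end),))

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_uniform_coverage_is_one(self, genome, strand):
        gro = stranded(genome, plus=2.0, minus=2.0, bin_size=10)
        assert tr.compute_p3r2(gro, self._gene(genome, strand)) == pytest.approx(1.0)

    def test_density_ratio(self, genome):
        g = self._gene(genome, "+")
        gro = stranded(genome, plus=0.0, minus=0.0, bin_size=10)
        arr = gro["+"].values["chr1"]
        w0, w1 = g.oriented_window(50, 300)
        arr[w0 // 10 : w1 // 10] = 10.0
        b0, b1 = g.oriented_window(-300, 1000)
        arr[b0 // 10 : b1 // 10] = 2.0
        assert tr.compute_p3r2(gro, g) == pytest.approx(5.0)

    def test_zero_body_coverage_discarded(self, genome):
        g = self._gene(genome, "+")
        gro = stranded(genome, plus=0.0, minus=0.0, bin_size=10)
        w0, w1 = g.oriented_window(50, 300)
        gro["+"].values["chr1"][w0 // 10 : w1 // 10] = 10.0
        assert np.isnan(tr.compute_p3r2(gro, g))

    def test_short_gene_undefined(self, genome):
        g = self._gene(genome, "+", length=300)
        gro = stranded(genome, plus=1.0, minus=1.0, bin_size=10)
        assert np.isnan(tr.compute_p3r2(gro, g))

    def test_body_window_truncates_at_tts(self, genome):
        # 600 bp gene: body window is [+300, +600) only
        g = self._gene(genome, "+", length=600)
        gro = stranded(genome, plus=0.0, minus=0.0, bin_size=10)
        arr = gro["+"].values["chr1"]
        w0, w1 = g.oriented_window(50, 300)
        arr[w0 // 10 : w1 // 10] = 4.0
        arr[(g.start + 300) // 10 : (g.start + 600) // 10] = 2.0
        arr[(g.start + 600) // 10 : (g.start + 1000) // 10] = 99.0  # past TTS
        assert tr.compute_p3r2(gro, g) == pytest.approx(2.0)


class TestAntisenseSense:
    def test_equal_strands_give_one(self, genome, plus_gene):
        pair = stranded(genome, plus=3.0, minus=3.0)
        assert tr.antisense_sense_ratio(pair, plus_gene) == pytest.approx(1.0)

    def test_threefold_antisense_excess(self, genome, plus_gene):
        pair = stranded(genome, plus=1.0, minus=3.8)
        assert tr.antisense_sense_ratio(pair, plus_gene) == pytest.approx(3.8)

    def test_zero_sense_undefined(self, genome, plus_gene):
        pair = stranded(genome, plus=0.0, minus=1.0)
        assert np.isnan(tr.antisense_sense_ratio(pair, plus_gene))

    def test_minus_strand_uses_plus_as_antisense(self, genome, minus_gene):
        pair = stranded(genome, plus=6.0, minus=2.0)
        assert tr.antisense_sense_ratio(pair, minus_gene) == pytest.approx(3.0)


class TestWindowRatio:
    def test_identity(self, genome, plus_gene, minus_gene, flat_track):
        out = tr.window_ratio_quantify(flat_track, flat_track,
                                       [plus_gene, minus_gene])
        assert np.allclose(out.to_numpy(), 1.0)

    def test_doubling(self, genome, plus_gene, flat_track):
        out = tr.window_ratio_quantify(flat_track.scaled(2.0), flat_track,
                                       [plus_gene])
        assert out.iloc[0] == pytest.approx(2.0)

    def test_zero_denominator_undefined(self, genome, plus_gene, flat_track):
        zero = rx.CoverageTrack.zeros(genome, 50)
        out = tr.window_ratio_quantify(flat_track, zero, [plus_gene])
        assert np.isnan(out.iloc[0])


class TestScaleInvariance:
    """Multiplying any track by a constant leaves every ratio unchanged."""

    def test_p3r2_and_ratios(self, genome, plus_gene):
        rng = np.random.default_rng(9)
        pair = stranded(genome, plus=0.0, minus=0.0, bin_size=10)
        for s in pair:
            pair[s].values["chr1"][:] = rng.poisson(8, len(pair[s].values["chr1"]))
            pair[s].values["chr1"][0] += 1  # ensure nonzero
        scaled = {s: pair[s].scaled(7.3) for s in pair}
        assert tr.compute_p3r2(scaled, plus_gene) == pytest.approx(
            tr.compute_p3r2(pair, plus_gene), rel=1e-12
        )
        assert tr.antisense_sense_ratio(scaled, plus_gene) == pytest.approx(
            tr.antisense_sense_ratio(pair, plus_gene), rel=1e-12
        )

    def test_shutdown_fold_change(self, genome, plus_gene):
        # RPM normalization inside nascent quantification absorbs scaling
        pair = stranded(genome, plus=2.0)
        tracks = {"a": pair, "b": {s: pair[s].scaled(31.0) for s in pair}}
        out = tr.intron_nascent_levels(tracks, [plus_gene])
        assert out.iloc[0]["nascent_a"] == pytest.approx(
            out.iloc[0]["nascent_b"], rel=1e-12
        )
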