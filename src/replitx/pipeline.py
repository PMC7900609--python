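"""End-to-end orchestration: from coverage tracks to the per-transcript
metrics table.

The stages mirror the analysis design: (1) transcribed-gene filtering from
chromatin RNA-seq RPM; (2) replication timing, fork direction and per-gene
replication time point from the BrdU time course; (3) directionality
classification; (4) intron-restricted nascent levels and shutdown
detection; (5) pausing release ratio from GRO-seq-like coverage;
(6) antisense/sense ratio at the last time point; (7) TSS gap metrics on
input-normalized BrdU; (8) G2/M peak calling, S-phase subtraction, and
hotspot gene calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gmids as gmids_mod
from . import metagene as metagene_mod
from . import replication, transcription
from .core_io import (
    CoverageTrack,
    GeneRecord,
    PeakSet,
    TimepointSeries,
    ValidationError,
    logger,
)


@dataclass
class AnalysisParams:
    """Tunable analysis parameters with the pipeline defaults."""

    timing_bin_size: int = 10_000
    timing_smooth_k: int = 5
    timing_floor: float = 0.5
    slope_epsilon: float = 0.01
    uniform_fraction: float = 0.9
    rpm_threshold: float = 1.0
    min_intron_bp: int = 100
    fc_threshold: float = 0.9
    antisense_half_window: int = 1_000
    antisense_upstream_only: bool = False
    gap_half_window: int = 2_500
    gap_step: int = 50
    gap_theta: float = 0.8
    gap_core: int = 1_000
    gap_flank_min: int = 1_500
    gap_smooth_bins: int = 5
    hotspot_window_bp: int = 2_000
    peak_call: gmids_mod.PeakCallConfig = field(default_factory=gmids_mod.PeakCallConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisParams":
        d = dict(d)
        pc = d.pop("peak_call", None)
        known = set(cls.__dataclass_fields__)
        bad = set(d) - known
        if bad:
            raise ValidationError(f"unknown AnalysisParams keys: {sorted(bad)}")
        obj = cls(**d)
        if pc is not None:
            obj.peak_call = gmids_mod.PeakCallConfig(**pc)
        return obj


@dataclass
class PipelineResult:
    """Everything the pipeline computes: the per-transcript metrics table
    plus the timing profile and peak sets for downstream inspection."""

    metrics: pd.DataFrame
    timing_profile: replication.TimingProfile
    s_phase_peaks: dict[str, PeakSet]
    g2m_peaks: PeakSet | None
    gmids_specific: PeakSet | None


def run_pipeline(genes: list[GeneRecord], brdu: TimepointSeries,
                 chr_rna: dict[str, dict[str, CoverageTrack]],
                 groseq: dict[str, CoverageTrack] | None = None,
                 g2m: tuple[CoverageTrack, CoverageTrack] | None = None,
                 params: AnalysisParams | None = None) -> PipelineResult:
    """Run all analysis stages and assemble the per-transcript metrics.

    ``chr_rna`` maps time point label -> strand -> track (all time points,
    G1/S first); ``groseq`` maps strand -> track; ``g2m`` is the
    (sample, input) G2/M BrdU pair. GRO-seq and G2/M stages are skipped
    when their inputs are None.
    """
    if params is None:
        params = AnalysisParams()
    labels = tuple(chr_rna)

    # 1. transcribed filter
    rpm_df = transcription.rpm_and_transcribed_filter(
        chr_rna, genes, rpm_threshold=params.rpm_threshold
    ).set_index("transcript_id")
    transcribed_ids = set(rpm_df.index[rpm_df["transcribed"]])
    transcribed = [g for g in genes if g.transcript_id in transcribed_ids]

    # 2. replication timing / fork direction / per-gene time point
    profile = replication.compute_timing_profile(
        brdu, bin_size=params.timing_bin_size,
        smooth_k=params.timing_smooth_k, floor=params.timing_floor,
    )
    replication.call_fork_direction(profile, epsilon=params.slope_epsilon)
    timepoints = replication.assign_replication_timepoints(genes, brdu)

    # 3. directionality (transcribed genes only)
    directionality = {
        g.transcript_id: replication.classify_directionality(
            g, profile, uniform_fraction=params.uniform_fraction
        )
        for g in transcribed
    }

    # 4. nascent levels and shutdown
    nascent = transcription.intron_nascent_levels(
        chr_rna, transcribed, min_intron_bp=params.min_intron_bp
    )
    shutdown = transcription.detect_shutdown(
        nascent, timepoints, labels, fc_threshold=params.fc_threshold
    ).set_index("transcript_id")

    # 5. pausing release ratio
    p3r2 = {}
    if groseq is not None:
        for g in transcribed:
            p3r2[g.transcript_id] = transcription.compute_p3r2(groseq, g)

    # 6. antisense/sense at the last time point
    as_ratio = {}
    last_pair = chr_rna[labels[-1]]
    for g in transcribed:
        as_ratio[g.transcript_id] = transcription.antisense_sense_ratio(
            last_pair, g, half_window=params.antisense_half_window,
            upstream_only=params.antisense_upstream_only,
        )

    # 7. TSS gap metrics at the gene's replication time point
    gaps = {}
    if brdu.input_track is not None:
        eps = metagene_mod.default_pseudocount(brdu.input_track)
        for g in transcribed:
            tp = timepoints.get(g.transcript_id)
            if tp is None or pd.isna(tp):
                gaps[g.transcript_id] = (np.nan, np.nan)
                continue
            gaps[g.transcript_id] = metagene_mod.gap_metrics(
                brdu.tracks[tp], brdu.input_track, g,
                half_window=params.gap_half_window, step=params.gap_step,
                theta=params.gap_theta, core=params.gap_core,
                flank_min=params.gap_flank_min,
                smooth_bins=params.gap_smooth_bins, eps=eps,
            )

    # 8. G2/M peak calling and hotspot genes
    s_peaks: dict[str, PeakSet] = {}
    g2m_peakset = None
    specific = None
    hotspot_df = None
    if g2m is not None:
        g2m_sample, g2m_input = g2m
        for label in brdu.s_phase_labels:
            s_peaks[label] = gmids_mod.call_peaks(
                brdu.tracks[label], brdu.input_track, params.peak_call
            )
        g2m_peakset = gmids_mod.call_peaks(g2m_sample, g2m_input, params.peak_call)
        specific = gmids_mod.specific_peaks(g2m_peakset, list(s_peaks.values()))
        hotspot_df = gmids_mod.hotspot_genes(
            specific, transcribed, window_bp=params.hotspot_window_bp
        ).set_index("transcript_id")

    # assemble
    rows = []
    for g in genes:
        tx = g.transcript_id
        is_tx = tx in transcribed_ids
        row = dict(
            gene_id=g.gene_id, transcript_id=tx, chrom=g.chrom, start=g.start,
            end=g.end, strand=g.strand, length=g.length, transcribed=is_tx,
            replication_timepoint=timepoints.get(tx),
            directionality=directionality.get(tx, "undefined") if is_tx else "undefined",
            shutdown_flag=shutdown["shutdown_flag"].get(tx, pd.NA),
            shutdown_fc=shutdown["shutdown_fc"].get(tx, np.nan),
            recovery_fc=shutdown["recovery_fc"].get(tx, np.nan),
            p3r2=p3r2.get(tx, np.nan),
            antisense_sense_ratio=as_ratio.get(tx, np.nan),
            gap_depth=gaps.get(tx, (np.nan, np.nan))[0],
            gap_width_bp=gaps.get(tx, (np.nan, np.nan))[1],
            gmids_hotspot=bool(hotspot_df["gmids_hotspot"].get(tx, False))
            if hotspot_df is not None else False,
        )
        for label in labels:
            row[f"rpm_{label}"] = rpm_df.loc[tx, f"rpm_{label}"]
        rows.append(row)
    metrics = pd.DataFrame(rows)
    metrics["shutdown_flag"] = metrics["shutdown_flag"].astype("boolean")

    counts = metrics.loc[metrics.transcribed, "directionality"].value_counts()
    logger.info("pipeline: %d transcripts, %d transcribed; directionality %s",
                len(metrics), int(metrics.transcribed.sum()), counts.to_dict())
    return PipelineResult(metrics, profile, s_peaks, g2m_peakset, specific)


def gene_level(metrics: pd.DataFrame) -> pd.DataFrame:
    """Deduplicate per-transcript metrics to one row per gene_id, keeping
    the longest transcript."""
    idx = metrics.groupby("gene_id")["length"].idxmax()
    return metrics.loc[idx].reset_index(drop=True)
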