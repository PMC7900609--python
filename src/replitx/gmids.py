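"""Poisson local-background peak calling, G-MiDS-specific peak derivation,
and TSS-proximal hotspot gene calling.

The caller tests each bin's count against the most conservative of the
input's genome-wide rate and its local-window rates (1/5/10 kb), scaled to
the sample's sequencing depth — the local-lambda logic of MACS-style
callers, applied to binned coverage. G2/M-specific (G-MiDS) peaks are
G2/M peaks with no overlap (>= 1 bp) against any S-phase peak; hotspot
genes are transcribed genes with a G-MiDS peak within the first 2 kb
downstream of the TSS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core_io import (
    CoverageTrack,
    GeneRecord,
    Peak,
    PeakSet,
    ValidationError,
    logger,
    oriented_window,
)


@dataclass
class PeakCallConfig:
    """Caller parameters: 200 bp bins, raw Poisson p < 1e-5 (no
    multiple-testing correction by default), local background windows of
    1/5/10 kb, peaks merged across gaps of <= merge_gap bins and kept only
    with >= min_peak_bins significant bins."""

    bin_size: int = 200
    p_threshold: float = 1e-5
    local_windows: tuple[int, ...] = (1_000, 5_000, 10_000)
    merge_gap: int = 1
    min_peak_bins: int = 2
    bh_fdr: bool = False  # optional Benjamini-Hochberg mode, off by default

    def __post_init__(self):
        if not (0 < self.p_threshold < 1):
            raise ValidationError("p_threshold must be in (0, 1)")
        if list(self.local_windows) != sorted(self.local_windows):
            raise ValidationError("local windows must be increasing")


def poisson_sf(counts: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Upper-tail Poisson p-value P(X >= count | lambda)."""
    counts = np.asarray(counts)
    return stats.poisson.sf(counts - 1, lam)


def _bin_counts(track: CoverageTrack, bin_size: int) -> dict[str, np.ndarray]:
    re = track.rebin(bin_size)
    return {c: re.values[c] * re.bin_widths(c) for c in track.genome.chrom_names}


def bin_pvalues(sample: CoverageTrack, input_track: CoverageTrack | None,
                config: PeakCallConfig | None = None) -> dict[str, np.ndarray]:
    """Per-bin upper-tail Poisson p-values of ``sample`` against the local
    background model (the caller's significance machinery).

    Per bin, lambda is the maximum of the input's genome-wide mean and its
    means over each centred local window, scaled by the sample/input mass
    ratio; without input, lambda is the sample's own genome-wide rate.
    """
    if config is None:
        config = PeakCallConfig()
    bs = config.bin_size
    s_counts = _bin_counts(sample, bs)
    if input_track is not None:
        if input_track.total_mass <= 0:
            raise ValidationError("input track supplied but has zero mass")
        if input_track.genome != sample.genome:
            raise ValidationError("sample and input on different genomes")
        i_counts = _bin_counts(input_track, bs)
        scale = sample.total_mass / input_track.total_mass
        genome_rate = float(np.mean(np.concatenate([i_counts[c] for c in i_counts])))
    else:
        i_counts = None
        scale = 1.0
        genome_rate = float(np.mean(np.concatenate([s_counts[c] for c in s_counts])))
    out = {}
    for chrom in sample.genome.chrom_names:
        s = np.round(s_counts[chrom])
        lam = np.full(len(s), genome_rate)
        if i_counts is not None:
            for w in config.local_windows:
                k = max(1, w // bs)
                local = ndimage.uniform_filter1d(i_counts[chrom], size=k, mode="nearest")
                np.maximum(lam, local, out=lam)
        p = poisson_sf(s, lam * scale)
        p[s <= 0] = 1.0
        out[chrom] = p
    return out


def call_peaks(sample: CoverageTrack, input_track: CoverageTrack | None,
               config: PeakCallConfig | None = None) -> PeakSet:
    """Enrichment peaks in ``sample`` against ``input_track``.

    Significant bins (:func:`bin_pvalues` < threshold) separated by <=
    merge_gap bins are merged; peaks with fewer than min_peak_bins
    significant bins are discarded. The peak score is -log10 of the minimum
    bin p-value and the summit the midpoint of the most significant bin.
    """
    if config is None:
        config = PeakCallConfig()
    if sample.total_mass <= 0:
        logger.warning("zero-mass sample track: no peaks")
        return PeakSet(sample.genome, [])
    pvals = bin_pvalues(sample, input_track, config)
    peaks: list[Peak] = []
    n_sig_total = 0
    for chrom in sample.genome.chrom_names:
        p = pvals[chrom]
        if config.bh_fdr:
            sig = _bh_reject(p, config.p_threshold)
        else:
            sig = p < config.p_threshold
        n_sig_total += int(sig.sum())
        peaks.extend(_merge_bins(chrom, sig, p, config.bin_size,
                                 sample.genome.length(chrom), config))
    logger.info("call_peaks: %d significant bins -> %d peaks", n_sig_total, len(peaks))
    return PeakSet(sample.genome, peaks)


def _bh_reject(p: np.ndarray, alpha: float) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, n + 1) / n)
    ok = p[order] <= thresh
    k = np.flatnonzero(ok)
    out = np.zeros(n, dtype=bool)
    if len(k):
        out[order[: k[-1] + 1]] = True
    return out


def _merge_bins(chrom: str, sig: np.ndarray, p: np.ndarray, bin_size: int,
                chrom_len: int, config: PeakCallConfig) -> list[Peak]:
    idx = np.flatnonzero(sig)
    if len(idx) == 0:
        return []
    peaks = []
    group_start = idx[0]
    prev = idx[0]
    members = [idx[0]]
    for i in idx[1:].tolist() + [None]:
        if i is not None and i - prev <= config.merge_gap + 1:
            members.append(i)
            prev = i
            continue
        if len(members) >= config.min_peak_bins:
            pvals = p[members]
            best = members[int(np.argmin(pvals))]
            pmin = max(float(pvals.min()), 1e-300)
            start = int(group_start) * bin_size
            end = min((int(prev) + 1) * bin_size, chrom_len)
            summit = best * bin_size + bin_size // 2 - start
            peaks.append(Peak(chrom, start, end, -np.log10(pmin), min(summit, end - start - 1)))
        if i is None:
            break
        group_start = prev = i
        members = [i]
    return peaks


def specific_peaks(g2m_peaks: PeakSet, s_phase_peaksets: list[PeakSet]) -> PeakSet:
    """G2/M peaks with zero >= 1 bp overlap against the union of all
    S-phase peaks; peaks are kept whole or dropped whole."""
    union: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in g2m_peaks.genome.chrom_names:
        starts, ends = [], []
        for ps in s_phase_peaksets:
            for pk in ps.by_chrom().get(chrom, []):
                starts.append(pk.start)
                ends.append(pk.end)
        order = np.argsort(starts) if starts else []
        union[chrom] = (
            np.asarray(starts, dtype=np.int64)[order] if starts else np.empty(0, np.int64),
            np.asarray(ends, dtype=np.int64)[order] if starts else np.empty(0, np.int64),
        )
    kept = [
        pk for pk in g2m_peaks.peaks
        if not _overlaps_any(pk.start, pk.end, *union[pk.chrom])
    ]
    logger.info("specific_peaks: kept %d/%d G2/M peaks", len(kept), len(g2m_peaks))
    return PeakSet(g2m_peaks.genome, kept)


def _overlaps_any(start: int, end: int, starts: np.ndarray, ends: np.ndarray) -> bool:
    if len(starts) == 0:
        return False
    i = int(np.searchsorted(starts, end))  # candidates with start < end
    return bool(np.any(ends[:i] > start))


def hotspot_genes(gmids_peaks: PeakSet, genes: list[GeneRecord], window_bp: int = 2000,
                  symmetric: bool = False) -> pd.DataFrame:
    """Transcripts with a G-MiDS-specific peak within the first
    ``window_bp`` downstream of the TSS (strand-aware; ``symmetric`` tests
    TSS +/- window instead). Returns one row per transcript with the
    hotspot flag and overlapping peak indices; unique genes are obtained by
    deduplicating gene_id (longest transcript)."""
    by_chrom = gmids_peaks.by_chrom()
    arr = {
        c: (
            np.array([p.start for p in pk], dtype=np.int64),
            np.array([p.end for p in pk], dtype=np.int64),
        )
        for c, pk in by_chrom.items()
    }
    rows = []
    for g in genes:
        if symmetric:
            w0, w1 = oriented_window(g.tss, g.strand, window_bp, window_bp)
        else:
            w0, w1 = oriented_window(g.tss, g.strand, 0, window_bp)
        w0 = max(0, w0)
        w1 = min(w1, gmids_peaks.genome.length(g.chrom))
        starts, ends = arr[g.chrom]
        i = int(np.searchsorted(starts, w1))
        hits = np.flatnonzero(ends[:i] > w0).tolist()
        rows.append(
            dict(transcript_id=g.transcript_id, gene_id=g.gene_id,
                 gmids_hotspot=bool(hits), peak_indices=hits)
        )
    df = pd.DataFrame(rows)
    n_tx = int(df.gmids_hotspot.sum())
    n_genes = df.loc[df.gmids_hotspot, "gene_id"].nunique()
    logger.info("hotspot_genes: %d transcripts / %d unique genes", n_tx, n_genes)
    return df
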