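"""Replication timing, fork direction, and transcription/replication
directionality from a BrdU-seq time course.

The timing score of a bin is the signal-weighted mean S-phase time point
index (1 = earliest), computed from RPM-normalized BrdU tracks and smoothed
with a centred moving average. Leading forks travel from timing minima
(initiation regions) toward maxima (termination regions), so the sign of
the local timing slope gives the fork direction: later to the right means
the fork moves rightward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    GeneRecord,
    GenomeModel,
    TimepointSeries,
    ValidationError,
    logger,
)

DIRECTION_RIGHT, DIRECTION_LEFT, DIRECTION_UNDEFINED = 1, -1, 0


@dataclass
class TimingProfile:
    """Per-bin replication timing score and fork direction.

    ``timing``: weighted-mean time point index per bin (NaN where the summed
    RPM is below the floor). ``direction``: int8 per bin, +1 rightward,
    -1 leftward, 0 undefined. Initiation/termination regions are interval
    lists (bp) filled in by :func:`call_fork_direction`.
    """

    genome: GenomeModel
    bin_size: int
    timing: dict[str, np.ndarray]
    direction: dict[str, np.ndarray] = field(default_factory=dict)
    initiation: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    termination: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def defined_mask(self, chrom: str) -> np.ndarray:
        return ~np.isnan(self.timing[chrom])


def _moving_average(x: np.ndarray, k: int) -> np.ndarray:
    """Centred moving average with shrinking windows at the edges;
    NaN-aware (NaNs do not poison neighbours and stay NaN only where the
    whole window is NaN)."""
    if k <= 1:
        return x.copy()
    s = pd.Series(x)
    return s.rolling(window=k, center=True, min_periods=1).mean().to_numpy()


def compute_timing_profile(series: TimepointSeries, bin_size: int = 10_000,
                           smooth_k: int = 5, floor: float = 0.5) -> TimingProfile:
    """Weighted-mean-time point replication timing from BrdU tracks.

    Each S-phase track is rebinned to ``bin_size`` and normalized to RPM;
    the timing score of bin b is sum_t t*f_t(b) / sum_t f_t(b) over S-phase
    indices t = 1..T, smoothed by a centred moving average of ``smooth_k``
    bins. Bins with summed RPM below ``floor`` are undefined.
    """
    labels = series.s_phase_labels
    if len(labels) < 2:
        raise ValidationError("need at least two S-phase tracks")
    rpm = {}
    for label in labels:
        track = series.tracks[label]
        if track.total_mass <= 0:
            logger.warning("all-zero BrdU track %s; timing will be undefined", label)
            rpm[label] = track.rebin(bin_size)
        else:
            rpm[label] = track.rebin(bin_size).to_rpm()
    genome = series.genome
    timing: dict[str, np.ndarray] = {}
    for chrom in genome.chrom_names:
        # f_t(b): per-bin RPM mass (density x bin width)
        widths = rpm[labels[0]].bin_widths(chrom)
        F = np.stack([rpm[l].values[chrom] * widths for l in labels])
        total = F.sum(axis=0)
        t_idx = np.arange(1, len(labels) + 1, dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            score = (t_idx[:, None] * F).sum(axis=0) / total
        low = total < floor
        score[low] = np.nan
        smoothed = _moving_average(score, smooth_k)
        smoothed[low] = np.nan  # smoothing must not resurrect undefined bins
        timing[chrom] = smoothed
        n_def = int(np.sum(~np.isnan(timing[chrom])))
        logger.info("timing %s: %d/%d bins defined", chrom, n_def, len(score))
    return TimingProfile(genome, bin_size, timing)


def call_fork_direction(profile: TimingProfile, epsilon: float = 0.01) -> TimingProfile:
    """Fill fork directions from the timing slope; annotate initiation
    (local timing minima) and termination (local maxima) regions.

    slope(b) is the central difference of the smoothed timing score;
    direction is rightward where slope > epsilon (replication later to the
    right, fork travelling right), leftward where slope < -epsilon, else
    undefined.
    """
    for chrom, score in profile.timing.items():
        n = len(score)
        slope = np.full(n, np.nan)
        if n >= 3:
            slope[1:-1] = (score[2:] - score[:-2]) / 2.0
        d = np.zeros(n, dtype=np.int8)
        with np.errstate(invalid="ignore"):
            d[slope > epsilon] = DIRECTION_RIGHT
            d[slope < -epsilon] = DIRECTION_LEFT
        profile.direction[chrom] = d
        profile.initiation[chrom], profile.termination[chrom] = _extrema_regions(
            d, profile.bin_size, profile.genome.length(chrom)
        )
    return profile


def _extrema_regions(d: np.ndarray, bin_size: int, chrom_len: int):
    """Initiation regions: maximal runs of non-rightward->rightward flips
    (left flank travelling left, right flank travelling right); termination
    regions: the opposite flip. Runs of undefined bins between opposing
    directions are included in the region."""
    initiation, termination = [], []
    idx = np.flatnonzero(d != 0)
    for a, b in zip(idx, idx[1:]):
        if d[a] == d[b]:
            continue
        start, end = int(a) * bin_size, min((int(b) + 1) * bin_size, chrom_len)
        if d[a] == DIRECTION_LEFT and d[b] == DIRECTION_RIGHT:
            initiation.append((start, end))
        else:
            termination.append((start, end))
    return initiation, termination


def assign_gene_replication_timepoint(gene: GeneRecord, series: TimepointSeries) -> str | None:
    """Label of the S-phase time point with the highest mean RPM-normalized
    BrdU density over the gene body; ties go to the earlier time point;
    all-zero genes are undefined (None)."""
    if gene.end > series.genome.length(gene.chrom):
        raise ValidationError(f"{gene.transcript_id} outside genome")
    masses = {l: series.tracks[l].total_mass for l in series.s_phase_labels}
    dens = []
    for label in series.s_phase_labels:
        m = masses[label]
        raw = series.tracks[label].window_mean(gene.chrom, gene.start, gene.end)
        dens.append(raw * 1e6 / m if m > 0 else 0.0)
    return _argmax_timepoint(dens, series.s_phase_labels)


def _argmax_timepoint(densities, labels) -> str | None:
    arr = np.asarray(densities, dtype=float)
    if np.all(arr <= 0):
        return None
    return labels[int(np.argmax(arr))]  # argmax takes the first = earliest tie


def assign_replication_timepoints(genes: list[GeneRecord], series: TimepointSeries) -> pd.Series:
    """Vector version of :func:`assign_gene_replication_timepoint` sharing
    one RPM normalization pass across genes."""
    labels = series.s_phase_labels
    rpm = {l: series.tracks[l].to_rpm() for l in labels}
    out = {}
    for g in genes:
        dens = [rpm[l].window_mean(g.chrom, g.start, g.end) for l in labels]
        out[g.transcript_id] = _argmax_timepoint(dens, labels)
    return pd.Series(out, name="replication_timepoint")


def classify_directionality(gene: GeneRecord, profile: TimingProfile,
                            uniform_fraction: float = 0.9) -> str:
    """Directionality class of a transcribed gene against the fork field.

    Over bins overlapping the gene body with a defined direction, let f be
    the fraction in the majority direction. With f >= uniform_fraction the
    gene is codirectional when the majority fork direction matches the
    transcription direction (+ -> right, - -> left) and head_to_head
    otherwise; with f below the threshold it is a transition gene
    (replication direction changes inside the gene). No defined bins ->
    undefined.
    """
    bs = profile.bin_size
    d = profile.direction[gene.chrom][gene.start // bs : (gene.end - 1) // bs + 1]
    d = d[d != DIRECTION_UNDEFINED]
    if len(d) == 0:
        return "undefined"
    n_right = int((d == DIRECTION_RIGHT).sum())
    n_major = max(n_right, len(d) - n_right)
    if n_major / len(d) < uniform_fraction:
        return "transition"
    major = DIRECTION_RIGHT if n_right * 2 >= len(d) else DIRECTION_LEFT
    tx_dir = DIRECTION_RIGHT if gene.strand == "+" else DIRECTION_LEFT
    return "codirectional" if major == tx_dir else "head_to_head"
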