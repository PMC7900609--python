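"""Anchor-oriented average profiles, input normalization, TSS gap metrics,
anchor stratification, and relative-enrichment profiles.

A metagene profile samples a track at fixed offsets around a set of
anchors (TSSs, TTSs or peak centres), mirroring minus-strand anchors so
that positive positions always point in the direction of transcription.
With an input track, the per-anchor, per-position ratio
``track RPM / (input RPM + eps)`` is formed *before* averaging (per-anchor
normalization), with a pseudocount eps guarding zero-input bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import (
    CoverageTrack,
    GeneRecord,
    Peak,
    TimepointSeries,
    ValidationError,
    logger,
    oriented_window,
)

LENGTH_CLASS_LABELS = ("<5kb", "5-30kb", "30-100kb", ">100kb")
#: closed-left convention: a boundary value belongs to the lower class
LENGTH_CLASS_EDGES = (5_000, 30_000, 100_000)


@dataclass
class MetageneProfile:
    """Average profile around oriented anchors.

    ``positions`` are window-centre offsets in bp (transcription-oriented,
    symmetric about 0); ``mean`` is the per-position unweighted mean over
    anchors; ``semantics`` is ``"density"`` or ``"ratio"``.
    """

    anchor: str
    positions: np.ndarray
    mean: np.ndarray
    n_anchors: int
    semantics: str = "density"
    eps: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": self.positions, "mean": self.mean, "n": self.n_anchors}
        )


def _anchor_tuple(a) -> tuple[str, int, str]:
    """(chrom, anchor bp, strand) from a GeneRecord, Peak, or plain tuple."""
    if isinstance(a, GeneRecord):
        return a.chrom, a.tss, a.strand
    if isinstance(a, Peak):
        return a.chrom, a.start + (a.end - a.start) // 2, "+"
    chrom, pos, strand = a
    return chrom, int(pos), strand


def default_pseudocount(input_track: CoverageTrack) -> float:
    """0.1 x genome-median input RPM density (the ratio regularizer)."""
    rpm = input_track.to_rpm()
    return 0.1 * rpm.median_density()


def metagene_profile(track: CoverageTrack, anchors, half_window: int, step: int,
                     input_track: CoverageTrack | None = None, oriented: bool = True,
                     anchor_label: str = "TSS", eps: float | None = None) -> MetageneProfile:
    """Unweighted average profile of ``track`` around ``anchors``.

    Anchors whose full window falls outside the chromosome are dropped (and
    counted in the log). Positions are window centres at ``step`` spacing
    covering [-half_window, half_window). With ``input_track``, both tracks
    are RPM-normalized and the per-anchor per-position ratio
    ``track/(input+eps)`` is averaged; ``eps`` defaults to 0.1 x the
    genome-median input RPM density.
    """
    if 2 * half_window % step:
        raise ValidationError("step must divide the window size")
    if input_track is not None:
        if eps is None:
            eps = default_pseudocount(input_track)
        track = track.to_rpm()
        input_track = input_track.to_rpm()
        semantics = "ratio"
    else:
        eps = 0.0
        semantics = "density"

    n_pos = 2 * half_window // step
    offsets = -half_window + step * np.arange(n_pos)  # oriented window starts
    positions = offsets + step / 2.0
    total = np.zeros(n_pos)
    used = 0
    dropped = 0
    for a in anchors:
        chrom, pos, strand = _anchor_tuple(a)
        if not oriented:
            strand = "+"
        w0, w1 = oriented_window(pos, strand, half_window, half_window)
        if w0 < 0 or w1 > track.genome.length(chrom):
            dropped += 1
            continue
        vals = _sample_windows(track, chrom, pos, strand, offsets, step)
        if input_track is not None:
            ivals = _sample_windows(input_track, chrom, pos, strand, offsets, step)
            vals = vals / (ivals + eps)
        total += vals
        used += 1
    if used == 0:
        raise ValidationError("no anchors remain after window clipping")
    if dropped:
        logger.info("metagene: dropped %d/%d anchors at chromosome edges",
                    dropped, dropped + used)
    return MetageneProfile(anchor_label, positions, total / used, used, semantics, eps)


def _sample_windows(track: CoverageTrack, chrom: str, pos: int, strand: str,
                    offsets: np.ndarray, step: int) -> np.ndarray:
    """Mean density in each oriented sub-window [offset, offset + step)."""
    out = np.empty(len(offsets))
    for i, off in enumerate(offsets):
        g0, g1 = oriented_window(pos, strand, -int(off), int(off) + step)
        out[i] = track.window_mean(chrom, g0, g1)
    return out


def stratify_anchors(genes: list[GeneRecord], by: str,
                     metrics: pd.DataFrame | None = None,
                     expression_column: str | None = None) -> dict[str, list[GeneRecord]]:
    """Label anchors into the fixed length classes or expression quartiles.

    ``by="length"``: the four classes <5 kb, 5-30 kb, 30-100 kb, >100 kb
    (boundary values go to the lower class). ``by="expression"``: quartiles
    of ``metrics[expression_column]`` (top quartile labelled "75-100%").
    Every gene lands in exactly one group.
    """
    if by == "length":
        groups: dict[str, list[GeneRecord]] = {l: [] for l in LENGTH_CLASS_LABELS}
        for g in genes:
            i = int(np.searchsorted(LENGTH_CLASS_EDGES, g.length, side="left"))
            groups[LENGTH_CLASS_LABELS[i]].append(g)
        return groups
    if by == "expression":
        if metrics is None or expression_column is None:
            raise ValidationError("expression stratification needs metrics and a column")
        vals = metrics.set_index("transcript_id")[expression_column]
        ranks = vals.rank(pct=True, method="first")
        labels = ("0-25%", "25-50%", "50-75%", "75-100%")
        groups = {l: [] for l in labels}
        for g in genes:
            q = min(3, int(ranks[g.transcript_id] * 4 - 1e-9))
            groups[labels[q]].append(g)
        return groups
    raise ValidationError(f"unknown stratification scheme {by!r}")


def gap_metrics(track: CoverageTrack, input_track: CoverageTrack, gene: GeneRecord,
                half_window: int = 2500, step: int = 50, theta: float = 0.8,
                core: int = 1000, flank_min: int = 1500, smooth_bins: int = 5,
                eps: float | None = None) -> tuple[float, float]:
    """Depth and width of the TSS under-replication gap of one gene.

    The oriented per-position sample/input ratio r(x) over TSS +/-
    half_window is divided by the flank baseline B (mean over |x| >=
    flank_min) to give rel(x). The gap centre x* is the argmin over the
    core |x| <= core of rel smoothed by a centred moving average of
    ``smooth_bins`` positions (robust against single-position noise), and
    ``gap_depth = 1 - rel_smooth(x*)``. If rel_smooth(x*) < theta, the gap
    is the maximal contiguous run of *unsmoothed* positions around x* with
    rel < theta (the raw ratio keeps the gap edges crisp, so the run length
    is an unbiased width), ``gap_width_bp`` is its length; otherwise width
    is 0 and depth is max(0, 1 - rel_smooth(x*)). Returns (NaN, NaN) when
    the window leaves the chromosome or the baseline is zero.
    """
    try:
        prof = metagene_profile(track, [gene], half_window, step,
                                input_track=input_track, eps=eps)
    except ValidationError:
        return float("nan"), float("nan")
    r_smooth = _smooth(prof.mean, smooth_bins)
    x = prof.positions
    flank = np.abs(x) >= flank_min
    B = float(r_smooth[flank].mean())
    if B <= 0:
        return float("nan"), float("nan")
    rel_smooth = r_smooth / B
    rel_raw = prof.mean / B
    core_mask = np.abs(x) <= core
    core_idx = np.flatnonzero(core_mask)
    i_star = core_idx[int(np.argmin(rel_smooth[core_mask]))]
    depth = max(0.0, 1.0 - float(rel_smooth[i_star]))
    if rel_smooth[i_star] >= theta:
        return depth, 0.0
    lo = i_star
    while lo > 0 and rel_raw[lo - 1] < theta:
        lo -= 1
    hi = i_star
    while hi + 1 < len(rel_raw) and rel_raw[hi + 1] < theta:
        hi += 1
    return depth, float((hi - lo + 1) * step)


def _smooth(x: np.ndarray, k: int) -> np.ndarray:
    if k <= 1:
        return x
    return pd.Series(x).rolling(k, center=True, min_periods=1).mean().to_numpy()


def relative_enrichment(series: TimepointSeries, anchors, reference_label: str = "earlyS",
                        half_window: int = 2500, step: int = 50,
                        eps: float | None = None) -> dict[str, MetageneProfile]:
    """Per-time point mean RPM profiles expressed relative to a reference
    time point: ratio of mean profile(t) to mean profile(reference) + eps.
    The reference against itself is 1 everywhere (up to eps)."""
    if reference_label not in series.tracks:
        raise ValidationError(f"reference time point {reference_label!r} missing")
    profiles = {}
    for label in series.s_phase_labels:
        track = series.tracks[label]
        if track.total_mass > 0:
            track = track.to_rpm()  # an all-zero time point profiles as zero
        profiles[label] = metagene_profile(track, anchors, half_window, step)
    ref = profiles[reference_label].mean
    if eps is None:
        pos = ref[ref > 0]
        eps = 0.1 * float(np.median(pos)) if len(pos) else 1e-12
    out = {}
    for label, prof in profiles.items():
        out[label] = MetageneProfile(
            prof.anchor, prof.positions, prof.mean / (ref + eps),
            prof.n_anchors, "ratio", eps,
        )
    return out
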