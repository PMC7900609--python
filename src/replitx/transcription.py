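"""Transcription quantification: RPM filtering, intron-restricted nascent
levels, replication-coupled shutdown detection, promoter-proximal pausing
release ratio (P3R2), and antisense/sense ratios.

Nascent transcription is quantified over introns only, because exonic
chromatin RNA-seq signal can come from mature mRNA still bound to
chromatin. The pausing release ratio compares engaged-polymerase density
in the TSS window [-50, +300) with the early gene body [+300, +1000)
(transcription-oriented); higher values mean more promoter-proximal
pausing. All ratios are per-bp densities, so uniform coverage gives
exactly 1 regardless of window lengths.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_io import CoverageTrack, GeneRecord, ValidationError, logger

#: strand-split track pair: {"+": CoverageTrack, "-": CoverageTrack}
StrandPair = dict


def rpm_and_transcribed_filter(tracks: dict[str, StrandPair], genes: list[GeneRecord],
                               rpm_threshold: float = 1.0) -> pd.DataFrame:
    """Per-transcript sense-strand RPM at every time point and the
    transcribed flag (RPM >= threshold at *every* time point).

    ``tracks`` maps time point label -> {strand: CoverageTrack}.
    """
    labels = list(tracks)
    masses = {}
    for label in labels:
        for strand in ("+", "-"):
            m = tracks[label][strand].total_mass
            if m <= 0:
                raise ValidationError(f"zero-mass track {label}/{strand}")
            masses[(label, strand)] = m
    rows = []
    for g in genes:
        rpms = {}
        for label in labels:
            track = tracks[label][g.strand]
            mass = track.window_mass(g.chrom, g.start, g.end)
            rpms[f"rpm_{label}"] = mass * 1e6 / masses[(label, g.strand)]
        rows.append(dict(transcript_id=g.transcript_id, **rpms))
    df = pd.DataFrame(rows).set_index("transcript_id")
    df["transcribed"] = (df >= rpm_threshold).all(axis=1)
    n = int(df["transcribed"].sum())
    logger.info("transcribed filter (RPM >= %g at all %d time points): %d/%d pass",
                rpm_threshold, len(labels), n, len(df))
    if n == 0:
        logger.warning("no transcribed genes; downstream stages will be empty")
    return df.reset_index()


def intron_nascent_levels(tracks: dict[str, StrandPair], genes: list[GeneRecord],
                          min_intron_bp: int = 100) -> pd.DataFrame:
    """Intron-mean nascent signal per transcript and time point.

    Per intron: mean per-bp RPM-normalized sense density; per transcript:
    the unweighted mean across qualifying introns (length >= min_intron_bp).
    Transcripts without qualifying introns get NaN. Columns:
    ``nascent_<label>`` plus ``n_introns``.
    """
    rpm = {
        label: {s: pair[s].to_rpm() for s in ("+", "-")}
        for label, pair in tracks.items()
    }
    rows = []
    for g in genes:
        introns = [iv for iv in g.introns if iv[1] - iv[0] >= min_intron_bp]
        row: dict = dict(transcript_id=g.transcript_id, n_introns=len(introns))
        for label in tracks:
            track = rpm[label][g.strand]
            if not introns:
                row[f"nascent_{label}"] = np.nan
                continue
            means = [track.window_mean(g.chrom, s, e) for s, e in introns]
            row[f"nascent_{label}"] = float(np.mean(means))
        rows.append(row)
    return pd.DataFrame(rows)


def detect_shutdown(nascent: pd.DataFrame, replication_timepoints: pd.Series,
                    labels: tuple[str, ...], fc_threshold: float = 0.9) -> pd.DataFrame:
    """Replication-coupled transcription shutdown calls.

    For a transcript replicated at time point t (with t-1 existing in the
    full label order), ``shutdown_fc = nascent(t)/nascent(t-1)`` and
    ``recovery_fc = nascent(t+1)/nascent(t-1)`` when t+1 exists. The
    shutdown flag is set when the fold change is below ``fc_threshold``.
    Undefined (NaN) when the transcript has no replication time point, no
    prior time point, or zero nascent signal before replication.
    """
    out = []
    label_index = {l: i for i, l in enumerate(labels)}
    for row in nascent.itertuples():
        tx = row.transcript_id
        tp = replication_timepoints.get(tx)
        rec: dict = dict(transcript_id=tx, shutdown_fc=np.nan,
                         recovery_fc=np.nan, shutdown_flag=pd.NA)
        if tp is not None and not pd.isna(tp) and tp in label_index and label_index[tp] >= 1:
            i = label_index[tp]
            before = getattr(row, f"nascent_{labels[i - 1]}".replace("/", "_"), None)
            if before is None:  # label names may contain '/', fetch via dict
                before = nascent.loc[row.Index, f"nascent_{labels[i - 1]}"]
            during = nascent.loc[row.Index, f"nascent_{labels[i]}"]
            if before is not None and np.isfinite(before) and before > 0 and np.isfinite(during):
                rec["shutdown_fc"] = during / before
                rec["shutdown_flag"] = bool(during / before < fc_threshold)
                if i + 1 < len(labels):
                    after = nascent.loc[row.Index, f"nascent_{labels[i + 1]}"]
                    if np.isfinite(after):
                        rec["recovery_fc"] = after / before
        out.append(rec)
    df = pd.DataFrame(out)
    df["shutdown_flag"] = df["shutdown_flag"].astype("boolean")
    return df


def compute_p3r2(groseq: StrandPair, gene: GeneRecord) -> float:
    """Promoter-proximal pausing release ratio, or NaN when undefined.

    Ratio of mean per-bp sense density in the TSS window [-50, +300) to the
    early-body window [+300, +1000) truncated at the TTS (both
    transcription-oriented). Genes of length <= 300 bp, or with zero
    coverage in either window, are discarded (NaN).
    """
    if gene.length <= 300:
        return float("nan")
    track = groseq[gene.strand]
    t0, t1 = _clip(gene.oriented_window(50, 300), track, gene.chrom)
    body_end = min(1000, gene.length)
    b0, b1 = _clip(gene.oriented_window(-300, body_end), track, gene.chrom)
    tss_mean = track.window_mean(gene.chrom, t0, t1)
    body_mean = track.window_mean(gene.chrom, b0, b1)
    if tss_mean <= 0 or body_mean <= 0:
        return float("nan")
    return tss_mean / body_mean


def _clip(window: tuple[int, int], track: CoverageTrack, chrom: str) -> tuple[int, int]:
    L = track.genome.length(chrom)
    return max(0, window[0]), min(L, window[1])


def antisense_sense_ratio(chr_rna: StrandPair, gene: GeneRecord,
                          half_window: int = 1000, upstream_only: bool = False) -> float:
    """Antisense/sense signal ratio around the TSS (default +/- 1 kb,
    symmetric; ``upstream_only`` restricts to [TSS-half_window, TSS)).
    Zero sense signal -> NaN (discarded)."""
    down = 0 if upstream_only else half_window
    w0, w1 = _clip(gene.oriented_window(half_window, down), chr_rna[gene.strand], gene.chrom)
    sense = chr_rna[gene.strand].window_mass(gene.chrom, w0, w1)
    anti_strand = "-" if gene.strand == "+" else "+"
    anti = chr_rna[anti_strand].window_mass(gene.chrom, w0, w1)
    if sense <= 0:
        return float("nan")
    return anti / sense


def window_ratio_quantify(track_a: CoverageTrack, track_b: CoverageTrack,
                          genes: list[GeneRecord], half_window: int = 1000) -> pd.Series:
    """Per-gene ratio of mean densities of two unstranded tracks over the
    TSS +/- half_window window (e.g. a damage mark over its total-histone
    control). Zero denominator -> NaN."""
    if track_a.genome != track_b.genome:
        raise ValidationError("tracks must share a genome")
    out = {}
    for g in genes:
        w0, w1 = _clip(g.oriented_window(half_window, half_window), track_a, g.chrom)
        a = track_a.window_mean(g.chrom, w0, w1)
        b = track_b.window_mean(g.chrom, w0, w1)
        out[g.transcript_id] = a / b if b > 0 else float("nan")
    return pd.Series(out, name="window_ratio")
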