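"""Data model, coordinate conventions, and file I/O.

All coordinates are 0-based half-open (BED convention). A gene on the minus
strand has its TSS at ``end - 1``; every "transcription-oriented" window is
mirrored accordingly, so that a window ``[TSS - u, TSS + d)`` in oriented
coordinates maps to the genomic interval ``[tss + 1 - d, tss + 1 + u)``.

Coverage is stored binned (per-bp *density* per fixed-size bin), never
per-read: read alignment and blacklist filtering are upstream of this
package, which consumes bedGraph tracks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("replitx")

#: Ordered cell-cycle time point labels used throughout. The first label is
#: the G1/S reference (chromatin RNA-seq only); the remaining five are the
#: S-phase labels for which BrdU tracks exist.
DEFAULT_TIMEPOINTS = ("G1/S", "earlyS", "earlyMidS", "midS", "midLateS", "lateSG2")

STRANDS = ("+", "-")


def configure_logging(level: str = "INFO") -> None:
    """Attach a basic stderr handler to the package logger."""
    logging.basicConfig(format="%(asctime)s %(name)s %(levelname)s %(message)s")
    logger.setLevel(level.upper())


class ReplitxError(Exception):
    """Base class for all package errors."""


class ParseError(ReplitxError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ReplitxError):
    """An object violates a data-model invariant."""


# ---------------------------------------------------------------------------
# Genome and gene model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosome names with their lengths in bp."""

    chrom_lengths: tuple[tuple[str, int], ...]

    def __post_init__(self):
        names = [c for c, _ in self.chrom_lengths]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate chromosome names")
        for name, length in self.chrom_lengths:
            if length < 1:
                raise ValidationError(f"chromosome {name} has length {length} < 1")

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "GenomeModel":
        return cls(tuple(d.items()))

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chrom_lengths)

    def length(self, chrom: str) -> int:
        for c, n in self.chrom_lengths:
            if c == chrom:
                return n
        raise KeyError(chrom)

    @property
    def total_length(self) -> int:
        return sum(n for _, n in self.chrom_lengths)

    def n_bins(self, chrom: str, bin_size: int) -> int:
        return -(-self.length(chrom) // bin_size)


@dataclass
class GeneRecord:
    """A stranded gene/transcript model with exon blocks.

    ``exons`` are sorted, disjoint sub-intervals of ``[start, end)``; the
    first exon starts at ``start`` and the last ends at ``end``. Introns are
    the complement of the exons within the gene body.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in STRANDS:
            raise ValidationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if not self.start < self.end:
            raise ValidationError(f"{self.transcript_id}: start >= end")
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: no exons")
        prev_end = None
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValidationError(
                    f"{self.transcript_id}: exon [{s},{e}) outside gene bounds"
                )
            if prev_end is not None and s < prev_end:
                raise ValidationError(f"{self.transcript_id}: exons overlap/unsorted")
            prev_end = e
        if self.exons[0][0] != self.start or self.exons[-1][1] != self.end:
            raise ValidationError(
                f"{self.transcript_id}: exons must span gene start/end"
            )

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        out = []
        for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]):
            if s1 > e0:
                out.append((e0, s1))
        return tuple(out)

    def oriented_window(self, upstream: int, downstream: int) -> tuple[int, int]:
        """Genomic interval for oriented window ``[TSS-upstream, TSS+downstream)``."""
        return oriented_window(self.tss, self.strand, upstream, downstream)


def oriented_window(anchor: int, strand: str, upstream: int, downstream: int) -> tuple[int, int]:
    """Map a transcription-oriented window around ``anchor`` to genomic coords."""
    if strand == "+":
        return anchor - upstream, anchor + downstream
    return anchor + 1 - downstream, anchor + 1 + upstream


def dedupe_longest(genes: list[GeneRecord]) -> list[GeneRecord]:
    """One record per gene_id, keeping the longest transcript (ties: first)."""
    best: dict[str, GeneRecord] = {}
    for g in genes:
        cur = best.get(g.gene_id)
        if cur is None or g.length > cur.length:
            best[g.gene_id] = g
    return list(best.values())


# ---------------------------------------------------------------------------
# Coverage tracks
# ---------------------------------------------------------------------------


@dataclass
class CoverageTrack:
    """Fixed-bin per-chromosome signal, stored as per-bp density.

    ``values[chrom][i]`` is the mean per-bp signal density over bin ``i``;
    the last bin of each chromosome may be partial and covers only the
    remainder of the chromosome, which the mass accounting respects.
    """

    genome: GenomeModel
    bin_size: int
    values: dict[str, np.ndarray]
    strand_tag: str = "unstranded"  # one of {+, -, unstranded}

    def __post_init__(self):
        if self.bin_size < 1:
            raise ValidationError("bin_size must be >= 1")
        for chrom, arr in self.values.items():
            n = self.genome.n_bins(chrom, self.bin_size)
            if len(arr) != n:
                raise ValidationError(
                    f"{chrom}: expected {n} bins, got {len(arr)}"
                )
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValidationError(f"{chrom}: values must be finite and >= 0")

    @classmethod
    def zeros(cls, genome: GenomeModel, bin_size: int, strand_tag: str = "unstranded") -> "CoverageTrack":
        vals = {
            c: np.zeros(genome.n_bins(c, bin_size)) for c in genome.chrom_names
        }
        return cls(genome, bin_size, vals, strand_tag)

    def bin_widths(self, chrom: str) -> np.ndarray:
        n = self.genome.n_bins(chrom, self.bin_size)
        w = np.full(n, float(self.bin_size))
        w[-1] = self.genome.length(chrom) - (n - 1) * self.bin_size
        return w

    @property
    def total_mass(self) -> float:
        return float(
            sum(np.dot(self.values[c], self.bin_widths(c)) for c in self.values)
        )

    def copy(self) -> "CoverageTrack":
        return CoverageTrack(
            self.genome,
            self.bin_size,
            {c: a.copy() for c, a in self.values.items()},
            self.strand_tag,
        )

    def scaled(self, factor: float) -> "CoverageTrack":
        return CoverageTrack(
            self.genome,
            self.bin_size,
            {c: a * factor for c, a in self.values.items()},
            self.strand_tag,
        )

    def to_rpm(self) -> "CoverageTrack":
        """Scale so that total mass is 1e6 ("reads" per million)."""
        m = self.total_mass
        if m <= 0:
            raise ValidationError("cannot RPM-normalize a zero-mass track")
        return self.scaled(1e6 / m)

    def rebin(self, new_bin_size: int) -> "CoverageTrack":
        """Rebin to a coarser bin size (multiple of the current one).

        The new value is the length-weighted mean of constituent fine bins,
        so total mass is conserved.
        """
        if new_bin_size == self.bin_size:
            return self.copy()
        if new_bin_size % self.bin_size or new_bin_size < self.bin_size:
            raise ValidationError(
                "new bin size must be a positive multiple of the current one"
            )
        k = new_bin_size // self.bin_size
        out: dict[str, np.ndarray] = {}
        for chrom, arr in self.values.items():
            widths = self.bin_widths(chrom)
            mass = arr * widths
            n_new = self.genome.n_bins(chrom, new_bin_size)
            pad = n_new * k - len(arr)
            if pad:
                mass = np.concatenate([mass, np.zeros(pad)])
                widths = np.concatenate([widths, np.zeros(pad)])
            new_mass = mass.reshape(n_new, k).sum(axis=1)
            new_widths = widths.reshape(n_new, k).sum(axis=1)
            out[chrom] = new_mass / new_widths
        return CoverageTrack(self.genome, new_bin_size, out, self.strand_tag)

    # -- window queries ----------------------------------------------------

    def window_mass(self, chrom: str, start: int, end: int) -> float:
        """Integral of density over genomic interval ``[start, end)``.

        Partial bins at the window edges contribute proportionally to the
        overlapped length, so this equals the per-base sum of densities.
        """
        L = self.genome.length(chrom)
        if start < 0 or end > L or start >= end:
            raise ValidationError(
                f"window [{start},{end}) invalid for {chrom} (length {L})"
            )
        bs = self.bin_size
        arr = self.values[chrom]
        i0, i1 = start // bs, (end - 1) // bs
        if i0 == i1:
            return float(arr[i0] * (end - start))
        mass = arr[i0] * ((i0 + 1) * bs - start)
        mass += arr[i1] * (end - i1 * bs)
        if i1 > i0 + 1:
            mass += arr[i0 + 1 : i1].sum() * bs
        return float(mass)

    def window_mean(self, chrom: str, start: int, end: int) -> float:
        """Mean per-bp density over ``[start, end)``."""
        return self.window_mass(chrom, start, end) / (end - start)

    def density_at(self, chrom: str, pos: int) -> float:
        """Per-bp density at a single base (the value of its bin)."""
        return float(self.values[chrom][pos // self.bin_size])

    def median_density(self) -> float:
        """Genome-wide median per-bp density (bin-weighted; partial last bins
        counted as whole bins, a negligible approximation)."""
        return float(np.median(np.concatenate([self.values[c] for c in self.values])))

    def equal(self, other: "CoverageTrack") -> bool:
        return (
            self.bin_size == other.bin_size
            and set(self.values) == set(other.values)
            and all(np.array_equal(self.values[c], other.values[c]) for c in self.values)
        )


@dataclass
class TimepointSeries:
    """BrdU coverage per S-phase time point plus a sonicated-input track.

    ``labels`` is the full ordered time point list (including the G1/S
    reference at index 0); BrdU ``tracks`` must exist for every S-phase
    label (index >= 1). All tracks share one genome and bin size.
    """

    labels: tuple[str, ...]
    tracks: dict[str, CoverageTrack]
    input_track: CoverageTrack | None = None

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("timepoint labels must be unique")
        missing = [l for l in self.s_phase_labels if l not in self.tracks]
        if missing:
            raise ValidationError(f"missing BrdU tracks for S-phase labels {missing}")
        ref = next(iter(self.tracks.values()))
        all_tracks = list(self.tracks.values())
        if self.input_track is not None:
            all_tracks.append(self.input_track)
        for t in all_tracks:
            if t.bin_size != ref.bin_size or t.genome is not ref.genome and t.genome != ref.genome:
                raise ValidationError("all tracks must share genome and bin size")

    @property
    def s_phase_labels(self) -> tuple[str, ...]:
        return self.labels[1:]

    @property
    def genome(self) -> GenomeModel:
        return next(iter(self.tracks.values())).genome

    @property
    def bin_size(self) -> int:
        return next(iter(self.tracks.values())).bin_size


# ---------------------------------------------------------------------------
# Peaks
# ---------------------------------------------------------------------------


@dataclass
class Peak:
    chrom: str
    start: int
    end: int
    score: float  # -log10 of the minimum bin p-value
    summit: int  # bp offset of the most enriched bin midpoint, relative to start

    def __post_init__(self):
        if self.start >= self.end:
            raise ValidationError("peak start >= end")
        if not (0 <= self.summit < self.end - self.start):
            raise ValidationError("summit offset outside peak")


@dataclass
class PeakSet:
    """Sorted, non-overlapping scored intervals on one genome."""

    genome: GenomeModel
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self):
        order = {c: i for i, c in enumerate(self.genome.chrom_names)}
        prev: Peak | None = None
        for p in self.peaks:
            if p.chrom not in order:
                raise ValidationError(f"peak on unknown chromosome {p.chrom}")
            if p.end > self.genome.length(p.chrom):
                raise ValidationError("peak beyond chromosome end")
            if prev is not None:
                if (order[p.chrom], p.start) < (order[prev.chrom], prev.start):
                    raise ValidationError("peaks not sorted")
                if p.chrom == prev.chrom and p.start < prev.end:
                    raise ValidationError("overlapping peaks in one set")
            prev = p

    def __len__(self) -> int:
        return len(self.peaks)

    def by_chrom(self) -> dict[str, list[Peak]]:
        out: dict[str, list[Peak]] = {c: [] for c in self.genome.chrom_names}
        for p in self.peaks:
            out[p.chrom].append(p)
        return out


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_annotation(path) -> list[GeneRecord]:
    """Read a BED12 gene annotation into validated :class:`GeneRecord` s.

    The BED ``name`` field carries ``gene_id|transcript_id``; a bare name is
    used for both identifiers. Block offsets are converted to absolute exon
    intervals.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 12:
                raise ParseError(f"{path}: line {lineno}: expected 12 BED fields")
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3]
                strand = fields[5]
                n_blocks = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ParseError(
                    f"{path}: line {lineno}: blockCount does not match block lists"
                )
            exons = tuple(
                (start + off, start + off + size) for off, size in zip(offsets, sizes)
            )
            gene_id, _, tx_id = name.partition("|")
            try:
                records.append(
                    GeneRecord(
                        gene_id=gene_id,
                        transcript_id=tx_id or gene_id,
                        chrom=chrom,
                        start=start,
                        end=end,
                        strand=strand,
                        exons=exons,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from None
    logger.info("read %d transcripts from %s", len(records), path)
    return records


def write_annotation(genes: list[GeneRecord], path) -> None:
    """Write gene records as BED12 (name = ``gene_id|transcript_id``)."""
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offsets = ",".join(str(s - g.start) for s, _ in g.exons)
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        str(g.start),
                        str(g.end),
                        f"{g.gene_id}|{g.transcript_id}",
                        "0",
                        g.strand,
                        str(g.start),
                        str(g.end),
                        "0,0,0",
                        str(len(g.exons)),
                        sizes,
                        offsets,
                    ]
                )
                + "\n"
            )


def read_coverage(path, genome: GenomeModel, bin_size: int, strand_tag: str = "unstranded") -> CoverageTrack:
    """Read a bedGraph into a binned :class:`CoverageTrack`.

    Each bin's value is the length-weighted mean of overlapping bedGraph
    intervals, with absent regions counted as zero. Intervals must be
    non-overlapping per chromosome, non-negative, and within the genome.
    """
    mass = {c: np.zeros(genome.n_bins(c, bin_size)) for c in genome.chrom_names}
    try:
        df = pd.read_csv(
            path,
            sep=r"\s+",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "start", "end", "value"])
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in mass:
            raise ValidationError(f"{path}: unknown chromosome {chrom}")
        L = genome.length(chrom)
        starts = sub["start"].to_numpy(dtype=np.int64)
        ends = sub["end"].to_numpy(dtype=np.int64)
        vals = sub["value"].to_numpy(dtype=float)
        if np.any(vals < 0):
            raise ValidationError(f"{path}: negative coverage value on {chrom}")
        if np.any(starts >= ends) or np.any(starts < 0) or np.any(ends > L):
            raise ValidationError(f"{path}: interval outside {chrom} bounds")
        order = np.argsort(starts, kind="stable")
        if np.any(ends[order][:-1] > starts[order][1:]):
            raise ValidationError(f"{path}: overlapping intervals on {chrom}")
        tgt = mass[chrom]
        i0 = starts // bin_size
        i1 = (ends - 1) // bin_size
        same = i0 == i1
        # intervals fully inside one bin: vectorized
        np.add.at(tgt, i0[same], vals[same] * (ends[same] - starts[same]))
        for s, e, v, a, b in zip(
            starts[~same], ends[~same], vals[~same], i0[~same], i1[~same]
        ):
            tgt[a] += v * ((a + 1) * bin_size - s)
            tgt[b] += v * (e - b * bin_size)
            if b > a + 1:
                tgt[a + 1 : b] += v * bin_size
    track = CoverageTrack.zeros(genome, bin_size, strand_tag)
    for chrom in mass:
        track.values[chrom] = mass[chrom] / track.bin_widths(chrom)
    # bin-aligned intervals fully cover their bins (no other interval can
    # touch them), so assign their value exactly: the mass/width arithmetic
    # above round-trips only to 1 ulp, and a write->read cycle at the
    # native bin size must be the identity
    for chrom, sub in df.groupby("chrom", sort=False):
        L = genome.length(chrom)
        arr = track.values[chrom]
        for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
            if s % bin_size == 0 and (e % bin_size == 0 or e == L):
                arr[s // bin_size : -(-e // bin_size)] = v
    return track


def write_coverage(track: CoverageTrack, path) -> None:
    """Write a track as bedGraph, merging equal-valued adjacent bins and
    omitting zero runs. Values are printed with full float precision so a
    read at the native bin size round-trips exactly."""
    with open(path, "w") as fh:
        for chrom in track.genome.chrom_names:
            arr = track.values.get(chrom)
            if arr is None:
                continue
            L = track.genome.length(chrom)
            bs = track.bin_size
            # run-length encode
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(arr)]])
            for a, b in zip(starts, ends):
                v = arr[a]
                if v == 0:
                    continue
                fh.write(f"{chrom}\t{a * bs}\t{min(b * bs, L)}\t{v:.17g}\n")


def write_peaks(peaks: PeakSet, path) -> None:
    """Write peaks as BED6+1 (score x10 rounded; column 7 = summit offset)."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks.peaks, start=1):
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i}\t"
                f"{round(p.score * 10)}\t.\t{p.summit}\n"
            )


def read_peaks(path, genome: GenomeModel) -> PeakSet:
    """Read peaks written by :func:`write_peaks` (score column is x10)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 7:
                raise ParseError(f"{path}: line {lineno}: expected 7 columns")
            out.append(
                Peak(
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    score=int(f[4]) / 10.0,
                    summit=int(f[6]),
                )
            )
    return PeakSet(genome, out)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_config(path) -> dict:
    """Load a YAML configuration mapping (empty file -> empty dict)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    return cfg


#: Columns of the per-transcript metrics table produced by the pipeline.
GENE_METRICS_COLUMNS = [
    "gene_id",
    "transcript_id",
    "chrom",
    "start",
    "end",
    "strand",
    "length",
    "transcribed",
    "replication_timepoint",
    "directionality",
    "shutdown_flag",
    "shutdown_fc",
    "recovery_fc",
    "p3r2",
    "antisense_sense_ratio",
    "gap_depth",
    "gap_width_bp",
    "gmids_hotspot",
]
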