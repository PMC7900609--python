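"""Synthetic genomes and coverage tracks with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* an origin-driven replication program — origins fire at drawn times and
  forks travel outward at constant speed, giving every bin a continuous
  true replication time and a true fork direction;
* a BrdU pulse per S-phase time point — expected incorporation in a bin
  follows a Gaussian kernel around the bin's true replication time, with
  Poisson observation noise;
* pausing-dependent under-replication gaps centred on the TSS of
  transcribed genes, present at every S-phase time point (TSSs stay
  under-replicated throughout S phase); gaps at hotspot genes never refill
  during S phase, others may refill at the last time point;
* strand-split chromatin RNA-seq with intron-level nascent signal, exonic
  mature-mRNA contamination, a pausing-driven TSS peak, upstream antisense
  transcription, and a transient shutdown (default 20 %) at the time point
  when a gene is replicated;
* GRO-seq-like engaged-polymerase density with a promoter-proximal pausing
  peak whose density ratio to the gene body is the gene's true pausing;
* G2/M BrdU with TSS-restricted gap-filling peaks at hotspot genes.

Everything is deterministic given config + seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core_io import (
    DEFAULT_TIMEPOINTS,
    CoverageTrack,
    GeneRecord,
    GenomeModel,
    TimepointSeries,
    ValidationError,
    dedupe_longest,
    logger,
    oriented_window,
)

# gene length classes (bp): <5 kb, 5-30 kb, 30-100 kb, >100 kb
LENGTH_CLASS_BOUNDS = ((1_500, 5_000), (5_000, 30_000), (30_000, 100_000), (100_000, 300_000))


@dataclass
class SimConfig:
    """Generator parameters. Defaults are the package's study conditions:
    a 2 x 10 Mb genome with 300 genes, a 20 % replication-coupled
    transcription shutdown, ~2 kb TSS gaps at 50 % depth, and antisense/sense
    ratios of 3.8 (hotspot) vs 1.0 (background)."""

    # genome / annotation
    n_chrom: int = 2
    chrom_length: int = 10_000_000
    n_genes: int = 300
    length_class_weights: tuple[float, float, float, float] = (0.35, 0.35, 0.20, 0.10)
    isoform_fraction: float = 0.1  # genes given a second, 3'-truncated transcript
    edge_margin: int = 20_000  # keep genes away from chromosome ends
    bin_size: int = 50  # fine simulation bin (bp)

    # expression / pausing
    expression_log_mean: float = 1.0
    expression_log_sd: float = 0.6
    silent_fraction: float = 0.1
    pausing_median: float = 2.5
    pausing_log_sd: float = 0.4
    pausing_length_corr: float = 0.5  # corr(log pausing, log length)

    # replication program
    origin_spacing: int = 1_000_000
    origin_jitter: int = 100_000
    origin_t0_min: float = 0.5
    origin_t0_max: float = 2.2
    fork_speed: float = 150_000.0  # bp per time point unit
    sigma_t: float = 0.8  # BrdU incorporation kernel width (time point units)
    brdu_background: float = 0.05  # uniform IP background, units of kernel peak

    # TSS gap model
    gap_width: int = 2_000
    gap_depth: float = 0.5
    gap_pausing_slope: float = 0.2  # depth increment per unit of log pausing z-score
    gap_depth_min: float = 0.15
    gap_depth_max: float = 0.85
    refill_probability: float = 0.6  # non-hotspot gaps refilled at the last S time point

    # transcription shutdown / antisense / hotspots
    shutdown_factor: float = 0.8
    shutdown_fraction: float = 0.7
    hotspot_fraction: float = 0.2
    antisense_mean_hotspot: float = 3.8
    antisense_mean_background: float = 1.0
    antisense_log_sd: float = 0.25
    mature_contamination: float = 0.5  # exonic excess over intron level
    chr_tss_peak_coef: float = 1.0  # TSS peak density per unit expression x pausing

    # sequencing depths
    brdu_reads_per_bin: float = 100.0  # per-track mean Poisson count per fine bin
    input_reads_per_bin: float = 100.0
    chr_rna_depth: float = 0.3  # reads per bp per unit expression (intron level)
    groseq_depth: float = 0.4  # reads per bp per unit expression (gene body)
    groseq_bin_size: int = 10  # finer bins: pausing windows are 350/700 bp
    g2m_background: float = 20.0  # background reads per fine bin
    g2m_peak_enrichment: float = 10.0  # hotspot peak density, multiples of background
    g2m_fill_width: int = 1_200  # TSS-centred gap-filling synthesis width (bp)

    # rule used to derive ground-truth directionality classes
    truth_class_bin_size: int = 10_000
    truth_uniform_fraction: float = 0.9

    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    seed: int = 0

    def __post_init__(self):
        w = np.asarray(self.length_class_weights, dtype=float)
        if len(w) != 4 or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValidationError("length_class_weights must be 4 non-negative weights summing to 1")
        if not (0 < self.shutdown_factor <= 1):
            raise ValidationError("shutdown_factor must be in (0, 1]")
        for name in ("silent_fraction", "shutdown_fraction", "hotspot_fraction",
                     "refill_probability", "isoform_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValidationError(f"{name} must be in [0, 1]")
        if not (0 <= self.gap_depth_min <= self.gap_depth_max <= 1):
            raise ValidationError("gap depth bounds must satisfy 0 <= min <= max <= 1")
        if self.sigma_t <= 0 or self.fork_speed <= 0:
            raise ValidationError("sigma_t and fork_speed must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f for f in cls.__dataclass_fields__}
        bad = set(d) - known
        if bad:
            raise ValidationError(f"unknown SimConfig keys: {sorted(bad)}")
        d = dict(d)
        for k in ("length_class_weights", "timepoints"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["length_class_weights"] = list(d["length_class_weights"])
        d["timepoints"] = list(d["timepoints"])
        return d


@dataclass
class SimTruth:
    """Ground truth: per-bin replication program and per-transcript table.

    ``rep_time``/``fork_dir`` are on the fine bin grid (``config.bin_size``);
    fork direction is +1 (rightward), -1 (leftward) or 0 exactly at
    origins/termini. ``transcripts`` has one row per transcript with the
    drawn expression, pausing, shutdown factor, gap geometry, antisense
    ratio, hotspot flag, true replication time point label and true
    directionality class.
    """

    genome: GenomeModel
    config: SimConfig
    origins: dict[str, list[tuple[int, float]]]
    rep_time: dict[str, np.ndarray]
    fork_dir: dict[str, np.ndarray]
    transcripts: pd.DataFrame

    def rep_time_at(self, chrom: str, pos: int) -> float:
        return float(self.rep_time[chrom][pos // self.config.bin_size])

    def coarse_profile(self, bin_size: int) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
        """True replication time and fork direction at a coarser bin size
        (for comparison with an inferred timing profile).

        Time is sampled at the coarse-bin centre. Direction is the common
        direction of the constituent fine bins, or 0 (mixed) for a coarse
        bin that straddles an origin or terminus — such a bin has no single
        fork direction at this resolution.
        """
        times, dirs = {}, {}
        fine = self.config.bin_size
        k = bin_size // fine
        for chrom in self.genome.chrom_names:
            n = self.genome.n_bins(chrom, bin_size)
            centers = (np.arange(n) * bin_size + bin_size // 2).clip(
                max=self.genome.length(chrom) - 1
            )
            times[chrom] = self.rep_time[chrom][centers // fine]
            fd = self.fork_dir[chrom]
            pad = n * k - len(fd)
            if pad:
                fd = np.concatenate([fd, np.zeros(pad, dtype=fd.dtype)])
            grid = fd.reshape(n, k)
            has_pos = (grid > 0).any(axis=1)
            has_neg = (grid < 0).any(axis=1)
            d = np.zeros(n, dtype=np.int8)
            d[has_pos & ~has_neg] = 1
            d[has_neg & ~has_pos] = -1
            dirs[chrom] = d
        return times, dirs


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------


def _draw_gene_length(rng: np.random.Generator, weights) -> int:
    cls = rng.choice(4, p=np.asarray(weights, dtype=float))
    lo, hi = LENGTH_CLASS_BOUNDS[cls]
    return int(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _draw_exons(rng: np.random.Generator, start: int, end: int) -> tuple[tuple[int, int], ...]:
    """2-20 exons spanning [start, end) with all pieces >= ~100 bp."""
    length = end - start
    max_exons = max(2, min(20, length // 400))
    n_exons = int(rng.integers(2, max_exons + 1))
    n_cuts = 2 * n_exons - 2
    # rejection-free: draw sorted interior cut points on a 100 bp lattice
    slots = length // 100 - 1
    if slots < n_cuts:
        n_exons, n_cuts = 2, 2
    picks = rng.choice(np.arange(1, length // 100), size=n_cuts, replace=False)
    cuts = np.sort(picks) * 100 + start
    bounds = [start, *cuts.tolist(), end]
    exons = tuple(
        (bounds[i], bounds[i + 1]) for i in range(0, len(bounds) - 1, 2)
    )
    return exons


def _truncate_transcript(rng: np.random.Generator, g: GeneRecord, tx_id: str) -> GeneRecord | None:
    """A 3'-truncated isoform sharing the TSS (annotation-level duplicate)."""
    new_len = int(g.length * rng.uniform(0.4, 0.7))
    if new_len < 1_000:
        return None
    if g.strand == "+":
        cut = g.start + new_len
        exons = [(s, e) for s, e in g.exons if s < cut]
        exons[-1] = (exons[-1][0], min(exons[-1][1], cut))
        if exons[-1][1] - exons[-1][0] < 50:
            exons.pop()
        if len(exons) < 2:
            return None
        return GeneRecord(g.gene_id, tx_id, g.chrom, g.start, exons[-1][1], "+", tuple(exons))
    cut = g.end - new_len
    exons = [(s, e) for s, e in g.exons if e > cut]
    exons[0] = (max(exons[0][0], cut), exons[0][1])
    if exons[0][1] - exons[0][0] < 50:
        exons.pop(0)
    if len(exons) < 2:
        return None
    return GeneRecord(g.gene_id, tx_id, g.chrom, exons[0][0], g.end, "-", tuple(exons))


def build_genome(config: SimConfig, seed: int | None = None) -> tuple[GenomeModel, list[GeneRecord], SimTruth]:
    """Generate genome, non-overlapping stranded genes, and ground truth.

    Genes never overlap (any strand) and keep a 3 kb clearance so TSS
    windows sample only their own gene's signal; origins are placed with
    the configured spacing and the true replication time of a bin is the
    minimum over origins of firing time + distance / fork speed.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB10]))
    genome = GenomeModel.from_dict(
        {f"chr{i + 1}": config.chrom_length for i in range(config.n_chrom)}
    )

    # --- gene placement: sequential with random inter-gene gaps ------------
    margin = config.edge_margin
    clearance = 5_000  # keeps TSS windows and flank baselines free of neighbours
    lengths = [_draw_gene_length(rng, config.length_class_weights)
               for _ in range(config.n_genes)]
    # greedy split across chromosomes by remaining free capacity
    capacity = {c: config.chrom_length - 2 * margin for c in genome.chrom_names}
    per_chrom: dict[str, list[int]] = {c: [] for c in genome.chrom_names}
    for length in sorted(lengths, reverse=True):
        c = max(capacity, key=capacity.get)
        if capacity[c] < length + clearance:
            raise ValidationError("genome too small to place the requested genes")
        per_chrom[c].append(length)
        capacity[c] -= length + clearance
    genes: list[GeneRecord] = []
    gid_counter = 0
    for chrom in genome.chrom_names:
        chrom_lengths = per_chrom[chrom]
        rng.shuffle(chrom_lengths)
        free = (config.chrom_length - 2 * margin
                - sum(chrom_lengths) - clearance * (len(chrom_lengths) + 1))
        gaps = rng.dirichlet(np.ones(len(chrom_lengths) + 1)) * max(free, 0)
        pos = margin
        for i, length in enumerate(chrom_lengths):
            pos += clearance + int(gaps[i])
            gid_counter += 1
            gid = f"g{gid_counter:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneRecord(gid, f"{gid}.1", chrom, pos, pos + length,
                                    strand, _draw_exons(rng, pos, pos + length)))
            pos += length

    # isoforms: 3'-truncated second transcripts for a fraction of genes
    primaries = list(genes)
    for g in primaries:
        if rng.random() < config.isoform_fraction:
            iso = _truncate_transcript(rng, g, f"{g.gene_id}.2")
            if iso is not None:
                genes.append(iso)
    genes.sort(key=lambda g: (g.chrom, g.start, g.transcript_id))

    # --- replication program ----------------------------------------------
    origins: dict[str, list[tuple[int, float]]] = {}
    for chrom in genome.chrom_names:
        pos = config.origin_spacing // 2
        olist = []
        while pos < config.chrom_length:
            jitter = int(rng.integers(-config.origin_jitter, config.origin_jitter + 1))
            p = int(np.clip(pos + jitter, 1, config.chrom_length - 2))
            t0 = float(rng.uniform(config.origin_t0_min, config.origin_t0_max))
            olist.append((p, t0))
            pos += config.origin_spacing
        origins[chrom] = olist

    rep_time, fork_dir = {}, {}
    bs = config.bin_size
    for chrom in genome.chrom_names:
        n = genome.n_bins(chrom, bs)
        centers = np.arange(n) * bs + bs / 2.0
        opos = np.array([p for p, _ in origins[chrom]], dtype=float)
        ot0 = np.array([t for _, t in origins[chrom]])
        times = ot0[:, None] + np.abs(centers[None, :] - opos[:, None]) / config.fork_speed
        j = np.argmin(times, axis=0)
        tmin = times[j, np.arange(n)]
        rep_time[chrom] = tmin
        d = np.sign(centers - opos[j]).astype(np.int8)
        # termini: where the two earliest origins arrive at ~the same time
        if len(opos) > 1:
            part = np.partition(times, 1, axis=0)
            tie = (part[1] - part[0]) < (bs / config.fork_speed)
            d[tie] = 0
        fork_dir[chrom] = d

    # --- per-gene attributes (drawn per gene_id, shared by isoforms) -------
    uniq = dedupe_longest(genes)
    uniq.sort(key=lambda g: g.gene_id)
    n_u = len(uniq)
    log_len = np.log([g.length for g in uniq])
    z_len = (log_len - log_len.mean()) / max(log_len.std(), 1e-12)
    expression = np.exp(rng.normal(config.expression_log_mean, config.expression_log_sd, n_u))
    expression[rng.random(n_u) < config.silent_fraction] = 0.0
    rho = config.pausing_length_corr
    eps = rng.normal(size=n_u)
    pausing = config.pausing_median * np.exp(
        config.pausing_log_sd * (rho * z_len + np.sqrt(max(0.0, 1 - rho**2)) * eps)
    )

    expressed = expression > 0
    # hotspots: the most promoter-proximally paused transcribed genes, which
    # also carry the deepest gaps (the genes whose TSSs stay under-replicated
    # until G2/M are the longest / most paused ones)
    hotspot = np.zeros(n_u, dtype=bool)
    idx_exp = np.flatnonzero(expressed)
    n_hot = int(round(config.hotspot_fraction * len(idx_exp)))
    if n_hot:
        top = idx_exp[np.argsort(pausing[idx_exp])[-n_hot:]]
        hotspot[top] = True

    shutdown_applied = np.ones(n_u)
    sel = expressed & (rng.random(n_u) < config.shutdown_fraction)
    shutdown_applied[sel] = config.shutdown_factor

    z_pause = (np.log(pausing) - np.log(config.pausing_median)) / max(config.pausing_log_sd, 1e-12)
    gap_depth = np.clip(
        config.gap_depth + config.gap_pausing_slope * z_pause,
        config.gap_depth_min,
        config.gap_depth_max,
    )
    gap_depth[~expressed] = 0.0
    gap_width = np.where(expressed, config.gap_width, 0)

    amean = np.where(hotspot, config.antisense_mean_hotspot, config.antisense_mean_background)
    antisense_ratio = amean * np.exp(
        rng.normal(0.0, config.antisense_log_sd, n_u) - config.antisense_log_sd**2 / 2
    )
    refill = (~hotspot) & expressed & (rng.random(n_u) < config.refill_probability)

    per_gene = {
        g.gene_id: dict(
            expression=expression[i], pausing=pausing[i], expressed=bool(expressed[i]),
            hotspot=bool(hotspot[i]), shutdown_applied=shutdown_applied[i],
            gap_depth=float(gap_depth[i]), gap_width_bp=int(gap_width[i]),
            antisense_ratio=float(antisense_ratio[i]), refilled=bool(refill[i]),
        )
        for i, g in enumerate(uniq)
    }

    # --- truth table (per transcript) --------------------------------------
    s_labels = list(config.timepoints[1:])
    scales = _track_scales(genome, rep_time, config)
    rows = []
    for g in genes:
        attrs = per_gene[g.gene_id]
        tp_kernel, tp_true = _timepoint_truth(g, attrs, rep_time[g.chrom], scales, config)
        rows.append(
            dict(
                transcript_id=g.transcript_id, gene_id=g.gene_id, chrom=g.chrom,
                start=g.start, end=g.end, strand=g.strand, length=g.length,
                **attrs,
                kernel_timepoint_index=tp_kernel,
                true_timepoint=s_labels[tp_true - 1] if attrs["expressed"] else "",
                true_timepoint_index=tp_true if attrs["expressed"] else 0,
            )
        )
    transcripts = pd.DataFrame(rows)

    truth = SimTruth(genome, config, origins, rep_time, fork_dir, transcripts)
    transcripts["true_directionality"] = _true_directionality_classes(truth, genes)
    logger.info(
        "built genome: %d transcripts / %d genes, %d origins, seed=%s",
        len(genes), n_u, sum(len(v) for v in origins.values()), seed,
    )
    return genome, genes, truth


def _kernel(t: float, T: np.ndarray, sigma_t: float) -> np.ndarray:
    return np.exp(-((t - T) ** 2) / (2 * sigma_t**2))


def _track_scales(genome: GenomeModel, rep_time: dict[str, np.ndarray],
                  config: SimConfig) -> np.ndarray:
    """Per-S-time point scale factors applied when each BrdU library is
    brought to the same mean depth (1-based index at position t-1)."""
    n_s = len(config.timepoints) - 1
    means = []
    for t in range(1, n_s + 1):
        tot = nb = 0.0
        for chrom in genome.chrom_names:
            T = rep_time[chrom]
            tot += _kernel(t, T, config.sigma_t).sum() + config.brdu_background * len(T)
            nb += len(T)
        means.append(tot / nb)
    return config.brdu_reads_per_bin / np.asarray(means)


def _timepoint_truth(gene: GeneRecord, attrs: dict, rep_time: np.ndarray,
                     scales: np.ndarray, config: SimConfig) -> tuple[int, int]:
    """True replication time points of a gene (1-based S-phase indices,
    ties broken toward the earlier time point).

    ``tp_kernel`` is the arg-max of the expected depth-scaled BrdU density
    over the gene body without the TSS gap — the time point at which the
    gene body is replicated. ``tp_true`` is the arg-max including the gap
    reduction: the expected outcome of assigning a replication time point
    from the observed tracks. Because the gap scales the signal at every
    S time point, the two almost always coincide.
    """
    bs = config.bin_size
    b0, b1 = gene.start // bs, (gene.end - 1) // bs
    T = rep_time[b0 : b1 + 1]
    n_s = len(scales)
    bg = config.brdu_background
    base = np.array([bg + _kernel(t, T, config.sigma_t).mean()
                     for t in range(1, n_s + 1)])
    tp_kernel = int(np.argmax(scales * base)) + 1
    if not attrs["expressed"] or attrs["gap_depth"] <= 0:
        return tp_kernel, tp_kernel
    half = attrs["gap_width_bp"] // 2
    w0, w1 = oriented_window(gene.tss, gene.strand,
                             half, attrs["gap_width_bp"] - half)
    w0, w1 = max(w0, gene.start), min(w1, gene.end)
    adj = base.copy()
    if w1 > w0:
        Tw = rep_time[w0 // bs : (w1 - 1) // bs + 1]
        frac = (w1 - w0) / gene.length
        for t in range(1, n_s + 1):
            if t == n_s and attrs["refilled"] and not attrs["hotspot"]:
                continue
            win_mean = bg + _kernel(t, Tw, config.sigma_t).mean()
            adj[t - 1] -= attrs["gap_depth"] * frac * win_mean
    tp_true = int(np.argmax(scales * adj)) + 1
    return tp_kernel, tp_true


def _true_directionality_classes(truth: SimTruth, genes: list[GeneRecord]) -> list[str]:
    """Ground-truth directionality class per transcript, derived from the
    true per-bin fork direction with the same majority rule the analysis
    uses (at truth_class_bin_size resolution)."""
    cfg = truth.config
    _, dirs = truth.coarse_profile(cfg.truth_class_bin_size)
    out = []
    for g in genes:
        row = truth.transcripts.loc[truth.transcripts.transcript_id == g.transcript_id]
        if not bool(row.iloc[0]["expressed"]):
            out.append("undefined")
            continue
        b0 = g.start // cfg.truth_class_bin_size
        b1 = (g.end - 1) // cfg.truth_class_bin_size
        d = dirs[g.chrom][b0 : b1 + 1]
        d = d[d != 0]
        if len(d) == 0:
            out.append("undefined")
            continue
        n_right = int((d > 0).sum())
        f = max(n_right, len(d) - n_right) / len(d)
        major = 1 if n_right >= len(d) - n_right else -1
        if f >= cfg.truth_uniform_fraction:
            tx_dir = 1 if g.strand == "+" else -1
            out.append("codirectional" if major == tx_dir else "head_to_head")
        else:
            out.append("transition")
    return out


# ---------------------------------------------------------------------------
# signal field helpers
# ---------------------------------------------------------------------------


def _add_density(arr: np.ndarray, bin_size: int, start: int, end: int, density: float) -> None:
    """Add `density` (per bp) over [start, end), fractional at edge bins."""
    n = len(arr)
    start = max(0, start)
    end = min(end, n * bin_size)
    if start >= end:
        return
    i0, i1 = start // bin_size, (end - 1) // bin_size
    if i0 == i1:
        arr[i0] += density * (end - start) / bin_size
        return
    arr[i0] += density * ((i0 + 1) * bin_size - start) / bin_size
    arr[i1] += density * (end - i1 * bin_size) / bin_size
    if i1 > i0 + 1:
        arr[i0 + 1 : i1] += density


def _apply_factor(arr: np.ndarray, bin_size: int, start: int, end: int, factor: float) -> None:
    """Multiply density by `factor` over [start, end), fractional at edges."""
    n = len(arr)
    start = max(0, start)
    end = min(end, n * bin_size)
    if start >= end or factor == 1.0:
        return
    i0, i1 = start // bin_size, (end - 1) // bin_size
    loss = 1.0 - factor
    if i0 == i1:
        arr[i0] *= 1.0 - loss * (end - start) / bin_size
        return
    arr[i0] *= 1.0 - loss * ((i0 + 1) * bin_size - start) / bin_size
    arr[i1] *= 1.0 - loss * (end - i1 * bin_size) / bin_size
    if i1 > i0 + 1:
        arr[i0 + 1 : i1] *= factor


def _poisson_track(rng: np.random.Generator, genome: GenomeModel, bin_size: int,
                   fields: dict[str, np.ndarray], strand_tag: str = "unstranded") -> CoverageTrack:
    """Observe expected per-bin counts through Poisson noise; store density."""
    vals = {}
    for chrom in genome.chrom_names:
        lam = np.clip(fields[chrom], 0.0, None)
        vals[chrom] = rng.poisson(lam).astype(float) / bin_size
    return CoverageTrack(genome, bin_size, vals, strand_tag)


def _gene_rows(truth: SimTruth) -> pd.DataFrame:
    """One row per unique gene (longest transcript)."""
    tx = truth.transcripts
    idx = tx.groupby("gene_id")["length"].idxmax()
    return tx.loc[idx]


# ---------------------------------------------------------------------------
# track simulators
# ---------------------------------------------------------------------------


def simulate_timecourse_brdu(genome: GenomeModel, truth: SimTruth, config: SimConfig,
                             seed: int) -> TimepointSeries:
    """BrdU-seq for the five S-phase time points plus a uniform input track.

    The expected signal in a bin at S-phase time point t is a small uniform
    background plus ``exp(-(t - T)^2 / (2 sigma_t^2))`` with T the bin's
    true replication time. Within a transcribed gene's TSS gap window the
    signal is multiplied by (1 - gap depth): TSSs stay under-replicated
    throughout S phase, so the reduction applies at every S time point.
    Hotspot gaps never refill during S phase, while a configured fraction
    of other genes has the factor restored at the last S time point. Each
    track is scaled so its mean expected count per bin matches
    ``brdu_reads_per_bin`` and observed through Poisson noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xBD0]))
    bs = config.bin_size
    s_labels = list(config.timepoints[1:])
    genes = _gene_rows(truth)
    tracks: dict[str, CoverageTrack] = {}
    for t_idx, label in enumerate(s_labels, start=1):
        fields = {}
        for chrom in genome.chrom_names:
            T = truth.rep_time[chrom]
            fields[chrom] = config.brdu_background + _kernel(t_idx, T, config.sigma_t)
        last = t_idx == len(s_labels)
        for row in genes.itertuples():
            if not row.expressed or row.gap_depth <= 0:
                continue
            if last and row.refilled and not row.hotspot:
                continue  # gap filled in late S/G2
            half = row.gap_width_bp // 2
            tss = row.start if row.strand == "+" else row.end - 1
            w0, w1 = oriented_window(tss, row.strand, half, row.gap_width_bp - half)
            _apply_factor(fields[row.chrom], bs, w0, w1, 1.0 - row.gap_depth)
        mean_sig = np.mean(np.concatenate([fields[c] for c in genome.chrom_names]))
        scale = config.brdu_reads_per_bin / mean_sig
        tracks[label] = _poisson_track(
            rng, genome, bs, {c: fields[c] * scale for c in fields}
        )
    input_fields = {
        c: np.full(genome.n_bins(c, bs), config.input_reads_per_bin)
        for c in genome.chrom_names
    }
    input_track = _poisson_track(rng, genome, bs, input_fields)
    return TimepointSeries(tuple(config.timepoints), tracks, input_track)


def _field_mass(arr: np.ndarray, bin_size: int, start: int, end: int) -> float:
    """Integral of a density field over [start, end), fractional at edges."""
    i0, i1 = start // bin_size, (end - 1) // bin_size
    if i0 == i1:
        return float(arr[i0] * (end - start))
    m = arr[i0] * ((i0 + 1) * bin_size - start) + arr[i1] * (end - i1 * bin_size)
    return float(m + arr[i0 + 1 : i1].sum() * bin_size)


def simulate_chr_rna(genome: GenomeModel, truth: SimTruth, config: SimConfig, seed: int,
                     genes: list[GeneRecord] | None = None) -> dict[str, dict[str, CoverageTrack]]:
    """Strand-split chromatin RNA-seq per time point.

    At a gene's replication time point all of its signal (sense and its
    TSS antisense) is multiplied by the gene's shutdown factor and restored
    at the next time point. Exon intervals come from ``genes`` when given
    (so the intron/exon structure matches the annotation); otherwise exonic
    contamination is spread over the whole body.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC12A]))
    bs = config.bin_size
    exon_map = {}
    if genes is not None:
        best = {g.transcript_id: g for g in dedupe_longest(genes)}
        exon_map = {g.transcript_id: g.exons for g in best.values()}

    base = _sense_fields_with_exons(genome, truth, config, exon_map)
    gene_rows = _gene_rows(truth)
    out: dict[str, dict[str, CoverageTrack]] = {}
    for t_idx, label in enumerate(config.timepoints):
        fields = {s: {c: a.copy() for c, a in base[s].items()} for s in base}
        for row in gene_rows.itertuples():
            if not row.expressed or row.shutdown_applied >= 1.0:
                continue
            if t_idx != row.true_timepoint_index:  # S labels are indices 1..5
                continue
            tss = row.start if row.strand == "+" else row.end - 1
            a0, a1 = oriented_window(tss, row.strand, 1000, 0)
            _apply_factor(fields[row.strand][row.chrom], bs, row.start, row.end,
                          row.shutdown_applied)
            # the pausing peak extends 50 bp upstream of the gene body
            p0, p1 = oriented_window(tss, row.strand, 50, 0)
            _apply_factor(fields[row.strand][row.chrom], bs, p0, p1, row.shutdown_applied)
            anti = "-" if row.strand == "+" else "+"
            _apply_factor(fields[anti][row.chrom], bs, a0, a1, row.shutdown_applied)
        scale = config.chr_rna_depth * bs
        out[label] = {
            s: _poisson_track(
                rng, genome, bs, {c: fields[s][c] * scale for c in fields[s]}, s
            )
            for s in ("+", "-")
        }
    return out


def _sense_fields_with_exons(genome, truth, config, exon_map):
    bs = config.bin_size
    fields = {
        s: {c: np.zeros(genome.n_bins(c, bs)) for c in genome.chrom_names}
        for s in ("+", "-")
    }
    for row in _gene_rows(truth).itertuples():
        if not row.expressed:
            continue
        arr = fields[row.strand][row.chrom]
        e = row.expression
        _add_density(arr, bs, row.start, row.end, e)
        exons = exon_map.get(row.transcript_id, ((row.start, row.end),))
        for s0, s1 in exons:
            _add_density(arr, bs, s0, s1, e * config.mature_contamination)
        tss = row.start if row.strand == "+" else row.end - 1
        p0, p1 = oriented_window(tss, row.strand, 50, 300)
        _add_density(arr, bs, max(0, p0), p1, e * config.chr_tss_peak_coef * row.pausing)
        w0, w1 = oriented_window(tss, row.strand, 1000, 1000)
        sense_mass = _field_mass(arr, bs, max(0, w0), min(w1, len(arr) * bs))
        a0, a1 = oriented_window(tss, row.strand, 1000, 0)
        anti = fields["-" if row.strand == "+" else "+"][row.chrom]
        _add_density(anti, bs, a0, a1, row.antisense_ratio * sense_mass / 1000.0)
    return fields


def simulate_groseq(genome: GenomeModel, truth: SimTruth, config: SimConfig,
                    seed: int) -> dict[str, CoverageTrack]:
    """Strand-split engaged-polymerase (GRO-seq-like) coverage.

    Sense density is ``pausing * k`` over the TSS window [-50, +300) and
    ``k`` over the gene body [+300, TTS), with ``k`` proportional to
    expression, so the true promoter-proximal pausing release ratio of each
    gene is exactly its drawn pausing value.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x6705]))
    bs = config.groseq_bin_size
    fields = {
        s: {c: np.zeros(genome.n_bins(c, bs)) for c in genome.chrom_names}
        for s in ("+", "-")
    }
    for row in _gene_rows(truth).itertuples():
        if not row.expressed:
            continue
        if row.length <= 300:
            logger.warning("%s shorter than the pausing window; body truncated",
                           row.transcript_id)
        arr = fields[row.strand][row.chrom]
        k = row.expression
        tss = row.start if row.strand == "+" else row.end - 1
        p0, p1 = oriented_window(tss, row.strand, 50, 300)
        _add_density(arr, bs, max(0, p0), p1, row.pausing * k)
        b0, b1 = oriented_window(tss, row.strand, -300, row.length)
        _add_density(arr, bs, max(0, b0), b1, k)
    scale = config.groseq_depth * bs
    return {
        s: _poisson_track(rng, genome, bs, {c: fields[s][c] * scale for c in fields[s]}, s)
        for s in ("+", "-")
    }


def simulate_g2m_brdu(genome: GenomeModel, truth: SimTruth, config: SimConfig,
                      seed: int) -> tuple[CoverageTrack, CoverageTrack]:
    """G2/M BrdU plus its input: uniform background with an added peak of
    ``g2m_peak_enrichment x background`` over the TSS-centred gap-filling
    window (width ``g2m_fill_width``) of hotspot genes — G2/M synthesis
    completes replication across the TSS exactly where the persistent
    S-phase gap was."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x62D]))
    bs = config.bin_size
    bg = config.g2m_background
    fields = {c: np.full(genome.n_bins(c, bs), bg) for c in genome.chrom_names}
    half = config.g2m_fill_width // 2
    for row in _gene_rows(truth).itertuples():
        if not row.hotspot:
            continue
        tss = row.start if row.strand == "+" else row.end - 1
        w0, w1 = oriented_window(tss, row.strand, half, config.g2m_fill_width - half)
        _add_density(fields[row.chrom], bs, w0, w1, config.g2m_peak_enrichment * bg)
    sample = _poisson_track(rng, genome, bs, fields)
    input_fields = {c: np.full(genome.n_bins(c, bs), bg) for c in genome.chrom_names}
    inp = _poisson_track(rng, genome, bs, input_fields)
    return sample, inp


# ---------------------------------------------------------------------------
# recovery evaluation
# ---------------------------------------------------------------------------

DIRECTIONALITY_CLASSES = ("codirectional", "head_to_head", "transition", "undefined")


def evaluate_recovery(truth: SimTruth, metrics: pd.DataFrame) -> dict:
    """Compare pipeline metrics against ground truth.

    Reports the directionality confusion matrix and accuracies, the
    replication-time point exact-match rate, shutdown sensitivity /
    false-positive rate and mean estimated fold change, pausing-ratio and
    gap RMSEs, hotspot sensitivity / FDR, and antisense/sense group means.
    Deterministic given its inputs.
    """
    t = truth.transcripts.set_index("transcript_id")
    m = metrics.set_index("transcript_id")
    if set(t.index) != set(m.index):
        raise ValidationError("truth and metrics cover different transcript sets")
    m = m.reindex(t.index)
    rep: dict = {}

    # directionality (evaluated on transcribed genes with defined truth class)
    td = t["true_directionality"]
    pd_ = m["directionality"].fillna("undefined")
    conf = pd.crosstab(td, pd_, dropna=False).reindex(
        index=DIRECTIONALITY_CLASSES, columns=DIRECTIONALITY_CLASSES, fill_value=0
    )
    rep["directionality_confusion"] = conf
    unam = td.isin(["codirectional", "head_to_head"])
    rep["directionality_accuracy_unambiguous"] = _safe_rate(
        (pd_[unam] == td[unam]).sum(), unam.sum()
    )
    trans = td == "transition"
    rep["transition_recovery"] = _safe_rate((pd_[trans] == "transition").sum(), trans.sum())
    defined = td != "undefined"
    rep["directionality_accuracy"] = _safe_rate((pd_[defined] == td[defined]).sum(), defined.sum())
    rep["n_directionality"] = int(defined.sum())

    # replication time point
    has_tp = (t["true_timepoint"] != "") & m["replication_timepoint"].notna()
    rep["timepoint_match_rate"] = _safe_rate(
        (m.loc[has_tp, "replication_timepoint"] == t.loc[has_tp, "true_timepoint"]).sum(),
        has_tp.sum(),
    )
    rep["n_timepoint"] = int(has_tp.sum())

    # shutdown
    fc = pd.to_numeric(m["shutdown_fc"], errors="coerce")
    flagged = m["shutdown_flag"].fillna(False).astype(bool)
    pos = (t["shutdown_applied"] < 1.0) & fc.notna()
    neg = (t["shutdown_applied"] >= 1.0) & t["expressed"] & fc.notna()
    rep["shutdown_sensitivity"] = _safe_rate(flagged[pos].sum(), pos.sum())
    rep["shutdown_fpr"] = _safe_rate(flagged[neg].sum(), neg.sum())
    rep["shutdown_mean_fc"] = float(fc[pos].mean()) if pos.any() else float("nan")
    rep["n_shutdown_pos"], rep["n_shutdown_neg"] = int(pos.sum()), int(neg.sum())

    # pausing ratio
    p3 = pd.to_numeric(m["p3r2"], errors="coerce")
    ok = p3.notna() & t["expressed"]
    rep["p3r2_rmse"] = _rmse(p3[ok], t.loc[ok, "pausing"])
    rep["p3r2_mean"] = float(p3[ok].mean()) if ok.any() else float("nan")
    rep["n_p3r2"] = int(ok.sum())

    # gap metrics
    gd = pd.to_numeric(m["gap_depth"], errors="coerce")
    gw = pd.to_numeric(m["gap_width_bp"], errors="coerce")
    okg = gd.notna() & t["expressed"] & (t["gap_depth"] > 0)
    rep["gap_depth_rmse"] = _rmse(gd[okg], t.loc[okg, "gap_depth"])
    rep["gap_width_rmse"] = _rmse(gw[okg], t.loc[okg, "gap_width_bp"])
    rep["gap_depth_mean"] = float(gd[okg].mean()) if okg.any() else float("nan")
    rep["gap_width_mean"] = float(gw[okg].mean()) if okg.any() else float("nan")
    rep["n_gap"] = int(okg.sum())

    # hotspots (unique genes)
    gm = m.assign(gene_id=t["gene_id"], hot_true=t["hotspot"]).groupby("gene_id").agg(
        hot_pred=("gmids_hotspot", "any"), hot_true=("hot_true", "any")
    )
    tp_ = int((gm.hot_pred & gm.hot_true).sum())
    fp = int((gm.hot_pred & ~gm.hot_true).sum())
    rep["hotspot_sensitivity"] = _safe_rate(tp_, int(gm.hot_true.sum()))
    rep["hotspot_fdr"] = _safe_rate(fp, tp_ + fp)
    rep["n_hotspot_true"] = int(gm.hot_true.sum())

    # antisense/sense group means
    asr = pd.to_numeric(m["antisense_sense_ratio"], errors="coerce")
    hot = t["hotspot"] & asr.notna()
    bgm = (~t["hotspot"]) & t["expressed"] & asr.notna()
    rep["antisense_mean_hotspot"] = float(asr[hot].mean()) if hot.any() else float("nan")
    rep["antisense_mean_background"] = float(asr[bgm].mean()) if bgm.any() else float("nan")
    return rep


def _safe_rate(num, den) -> float:
    return float(num) / float(den) if den else float("nan")


def _rmse(a: pd.Series, b: pd.Series) -> float:
    if len(a) == 0:
        return 0.0
    d = a.to_numpy(dtype=float) - b.to_numpy(dtype=float)
    return float(np.sqrt(np.mean(d**2)))
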