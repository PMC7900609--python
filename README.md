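# replitx

Analysis of transcription–replication coordination from binned genome
coverage tracks, with a ground-truth synthetic data generator for
validating every stage.

During S phase, DNA replication and RNA polymerase II (RNAPII)
transcription share the same template. Time-resolved BrdU-seq (newly
synthesized DNA per cell-cycle window) combined with chromatin-bound
RNA-seq and GRO-seq makes their interplay measurable: when a gene is
replicated its nascent transcription transiently dips; transcription start
sites (TSSs) of active genes are replicated *late* — an under-replication
gap of roughly 2 kb persists across S phase — and a subset of TSSs is only
duplicated by G2/M DNA synthesis (G-MiDS), once RNAPII leaves the
chromatin. `replitx` implements that whole computational analysis as a
reusable library for anyone working with replication-timing time courses
and strand-split transcription coverage:

* **Replication timing** from an ordered BrdU-seq series: per 10-kb bin,
  the signal-weighted mean time point index
  `score(b) = Σ_t t·f_t(b) / Σ_t f_t(b)` over RPM-normalized S-phase
  tracks, smoothed by a centred moving average. Leading forks run from
  timing minima (initiation) to maxima (termination), so
  `slope > ε ⇒ rightward fork`.
* **Directionality classes**: over a transcribed gene's bins with a
  defined fork direction, majority fraction `f ≥ 0.9` ⇒ *codirectional*
  (fork along transcription) or *head-to-head* (fork against it);
  otherwise *transition* (direction changes inside the gene, e.g. an
  internal origin).
* **Replication time point per gene**: the S-phase track with the highest
  mean RPM density over the gene body (ties to the earlier time point).
* **Nascent transcription and shutdown**: chromatin RNA-seq quantified
  over *introns only* (exonic signal can come from mature mRNA);
  `shutdown_fc = nascent(t)/nascent(t−1)` at the gene's replication time
  point, with a recovery fold change at `t+1`.
* **Promoter-proximal pausing** (P³R²): mean per-bp GRO-seq density in
  `[TSS−50, TSS+300)` over `[TSS+300, TSS+1000)` (transcription-oriented;
  genes with zero coverage in either window are discarded).
* **TSS gap metrics**: input-normalized, TSS-oriented per-position ratio
  relative to its ±(1.5–2.5 kb) flank baseline; the gap is the contiguous
  run below 0.8 around the minimum, reported as depth and width.
* **Peak calling and G-MiDS**: a Poisson local-background caller
  (λ = max of the input's genome-wide and 1/5/10-kb local rates, scaled to
  the sample depth; p < 1e-5, MACS-style). G-MiDS-specific peaks are G2/M
  peaks with zero overlap against all S-phase peaks; *hotspot genes* carry
  such a peak within the first 2 kb downstream of the TSS.

The `simulate` module generates annotation, BrdU/chromatin-RNA/GRO-seq/G2M
tracks from an origin-driven replication program with known per-gene
ground truth (timing, directionality, shutdown factor, pausing, gap
geometry, hotspot status), so every estimator is validated by parameter
recovery. See `docs/methods.md` for the generative model and all defaults.

## Worked example

```python
import replitx as rx

cfg = rx.SimConfig(seed=1)                      # 2 x 10 Mb, 300 genes
genome, genes, truth = rx.build_genome(cfg, seed=1)
brdu = rx.simulate_timecourse_brdu(genome, truth, cfg, seed=1)
chr_rna = rx.simulate_chr_rna(genome, truth, cfg, seed=1, genes=genes)
groseq = rx.simulate_groseq(genome, truth, cfg, seed=1)
g2m = rx.simulate_g2m_brdu(genome, truth, cfg, seed=1)

result = rx.run_pipeline(genes, brdu, chr_rna, groseq, g2m)
m = result.metrics                               # one row per transcript
tx = m[m.transcribed]
print(tx.directionality.value_counts().to_string())
print("mean shutdown fold change:", round(tx.shutdown_fc.mean(), 3))
print("G-MiDS-specific peaks:", len(result.gmids_specific))

report = rx.evaluate_recovery(truth, m)
print("directionality accuracy:", round(report["directionality_accuracy_unambiguous"], 3))
print("hotspot sensitivity:", round(report["hotspot_sensitivity"], 3))
```

prints

```
codirectional    142
head_to_head     128
transition        15
undefined          4
mean shutdown fold change: 0.87
G-MiDS-specific peaks: 54
directionality accuracy: 0.993
hotspot sensitivity: 0.982
```

289 of 313 transcripts pass the RPM ≥ 1 filter; codirectional and
head-to-head genes occur at near-equal frequency with a small transition
class, the mean fold change over all transcribed genes reflects the mix of
shut-down (~0.8) and unaffected (~1.0) genes, and 54 of the 55 simulated
hotspot genes are recovered from the G2/M peak calls with no false
positives.

The same workflow is available from the shell:

```
replitx --seed 1 --out-dir out simulate
replitx --out-dir out timing
replitx --out-dir out evaluate      # writes gene_metrics.tsv + evaluation.json
```

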