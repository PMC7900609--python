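"""Shared fixtures: small hand-built objects for unit tests and one
full-size simulation + pipeline run (seed 1) shared by the recovery tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import replitx as rx

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def genome():
    return rx.GenomeModel.from_dict({"chr1": 100_000, "chr2": 60_000})


@pytest.fixture()
def plus_gene():
    return rx.GeneRecord(
        gene_id="gA", transcript_id="gA.1", chrom="chr1", start=10_000,
        end=30_000, strand="+",
        exons=((10_000, 14_000), (20_000, 24_000), (28_000, 30_000)),
    )


@pytest.fixture()
def minus_gene():
    return rx.GeneRecord(
        gene_id="gB", transcript_id="gB.1", chrom="chr1", start=40_000,
        end=60_000, strand="-",
        exons=((40_000, 44_000), (50_000, 60_000)),
    )


def constant_track(genome, value, bin_size=50, strand="unstranded"):
    t = rx.CoverageTrack.zeros(genome, bin_size, strand)
    for c in t.values:
        t.values[c][:] = value
    return t


@pytest.fixture()
def flat_track(genome):
    return constant_track(genome, 2.0)


# ---------------------------------------------------------------------------
# full default simulation (seed 1), shared across recovery/acceptance tests
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def default_sim():
    cfg = rx.SimConfig(seed=1)
    genome, genes, truth = rx.build_genome(cfg, 1)
    brdu = rx.simulate_timecourse_brdu(genome, truth, cfg, 1)
    chr_rna = rx.simulate_chr_rna(genome, truth, cfg, 1, genes=genes)
    groseq = rx.simulate_groseq(genome, truth, cfg, 1)
    g2m = rx.simulate_g2m_brdu(genome, truth, cfg, 1)
    return dict(config=cfg, genome=genome, genes=genes, truth=truth,
                brdu=brdu, chr_rna=chr_rna, groseq=groseq, g2m=g2m)


@pytest.fixture(scope="session")
def default_result(default_sim):
    return rx.run_pipeline(
        default_sim["genes"], default_sim["brdu"], default_sim["chr_rna"],
        default_sim["groseq"], default_sim["g2m"],
    )


@pytest.fixture(scope="session")
def default_report(default_sim, default_result):
    return rx.evaluate_recovery(default_sim["truth"], default_result.metrics)


def mirror_track(track: rx.CoverageTrack) -> rx.CoverageTrack:
    """Reverse every chromosome of a track (lengths must be bin-multiples)."""
    vals = {}
    for c, a in track.values.items():
        assert track.genome.length(c) % track.bin_size == 0
        vals[c] = a[::-1].copy()
    strand = {"+": "-", "-": "+"}.get(track.strand_tag, track.strand_tag)
    return rx.CoverageTrack(track.genome, track.bin_size, vals, strand)


def mirror_gene(g: rx.GeneRecord, genome: rx.GenomeModel) -> rx.GeneRecord:
    L = genome.length(g.chrom)
    exons = tuple(sorted((L - e, L - s) for s, e in g.exons))
    return rx.GeneRecord(
        gene_id=g.gene_id, transcript_id=g.transcript_id, chrom=g.chrom,
        start=L - g.end, end=L - g.start,
        strand="-" if g.strand == "+" else "+", exons=exons,
    )
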