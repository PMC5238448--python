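"""Shared fixtures: toy annotations built in memory and session-scoped
simulated datasets (all fixtures are generated at test time)."""

from __future__ import annotations

import numpy as np
import pytest

from riboquant import calibration, genome, ingest, simulate
from riboquant.genome import Annotation, GeneModel, GenomicInterval, TranscriptModel


def make_transcript(
    utr5: int = 30,
    codons: int = 40,
    utr3: int = 30,
    strand: str = "+",
    contig: str = "chr1",
    tx_start: int = 100,
    gene_id: str = "gA",
    n_exons: int = 1,
    intron: int = 50,
) -> TranscriptModel:
    return simulate._build_transcript(
        gene_id, contig, strand, tx_start, utr5, 3 * codons, utr3, n_exons, intron
    )


def make_annotation(*transcripts: TranscriptModel) -> Annotation:
    genes: dict[str, GeneModel] = {}
    for t in transcripts:
        genes.setdefault(t.gene_id, GeneModel(gene_id=t.gene_id)).transcripts.append(t)
    return Annotation(genes, stop_codon_in_cds=True)


@pytest.fixture
def toy_transcript() -> TranscriptModel:
    return make_transcript()


@pytest.fixture
def toy_annotation(toy_transcript) -> Annotation:
    return make_annotation(toy_transcript)


# -- session-scoped simulated datasets -----------------------------------

@pytest.fixture(scope="session")
def default_sim(tmp_path_factory):
    """Default small simulation: 5 genes + 3 transgenes, 20k RPFs."""
    cfg = simulate.SimConfig(seed=7)
    return simulate.simulate_dataset(cfg, tmp_path_factory.mktemp("default_sim"))


@pytest.fixture(scope="session")
def default_ann(default_sim):
    return genome.load_annotation(default_sim.annotation_gtf)


@pytest.fixture(scope="session")
def default_profiles(default_sim, default_ann):
    return ingest.build_end_profiles(default_sim.ribo_sam, default_ann)


@pytest.fixture(scope="session")
def default_offsets(default_profiles, default_ann):
    return calibration.estimate_offsets(default_profiles, default_ann)


@pytest.fixture(scope="session")
def default_tracks(default_profiles, default_offsets):
    tracks, _dropped = calibration.apply_offsets(default_profiles, default_offsets)
    return tracks


@pytest.fixture(scope="session")
def quant_sim(tmp_path_factory):
    """Larger simulation for quantification-fidelity checks."""
    cfg = simulate.SimConfig(
        seed=11, n_genes=20, te_sigma=1.0, ribo_depth=60000, rna_depth=60000
    )
    return simulate.simulate_dataset(cfg, tmp_path_factory.mktemp("quant_sim"))


@pytest.fixture(scope="session")
def uniform_sim(tmp_path_factory):
    """Uniform-CDS simulation for metagene checks: flat frame profile, no
    start peak, equal expression/TE, short fixed-length CDSs, high depth."""
    cfg = simulate.SimConfig(
        seed=13,
        n_genes=20,
        cds_codon_range=(50, 50),
        expression_sigma=0.0,
        te_sigma=0.0,
        frame_probs=(1 / 3, 1 / 3, 1 / 3),
        start_peak=1.0,
        ribo_depth=400_000,
        rna_depth=1000,
    )
    return simulate.simulate_dataset(cfg, tmp_path_factory.mktemp("uniform_sim"))


@pytest.fixture(scope="session")
def uniform_tracks(uniform_sim):
    """Calibrated tracks for the uniform simulation, using the simulator's
    true offsets (flat frames leave the data-driven estimator undetermined
    up to +-1 nt; offset estimation itself is covered elsewhere)."""
    ann = genome.load_annotation(uniform_sim.annotation_gtf)
    profiles = ingest.build_end_profiles(uniform_sim.ribo_sam, ann)
    offsets = calibration.OffsetTable(dict(uniform_sim.config.offsets))
    tracks, _ = calibration.apply_offsets(profiles, offsets)
    return ann, tracks
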