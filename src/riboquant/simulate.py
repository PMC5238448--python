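"""Synthetic fixtures with known truth: a toy genome and annotation with
three transgenes, Ribo-Seq/RNA-Seq alignments, category maps, gene sets,
and a two-phase batch-culture series.

Every output is a plain-text file (FASTA, GTF, SAM, TSV, CSV, YAML) and
is byte-reproducible from (config, seed).  Ribosome reads carry a
per-length 5'-end offset to the A site, a configurable frame bias, a
start-codon pile-up used by offset calibration, optional extra 5'UTR
reads on the transgenes, and never any 3'UTR signal.  RNA reads cover
the full spliced transcript uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .genome import GenomicInterval, TranscriptModel, transcript_interval_to_blocks

TRANSGENE_CONTIG = "vector"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class SimConfig:
    """All knobs of the simulator; defaults give the standard small run."""

    seed: int = 42
    # transcriptome
    n_genes: int = 5
    cds_codon_range: tuple[int, int] = (100, 260)
    utr5_length: int = 60
    utr3_length: int = 60
    n_exons: int = 1
    intron_length: int = 80
    expression_sigma: float = 1.0   # lognormal spread of endogenous tpm
    te_sigma: float = 0.5           # lognormal spread of true TE
    transgene_shares: dict[str, float] = field(
        default_factory=lambda: {
            "heavy_chain": 0.10, "light_chain": 0.06, "neo_r": 0.04,
        }
    )
    transgene_cds_codons: dict[str, int] = field(
        default_factory=lambda: {
            "heavy_chain": 160, "light_chain": 120, "neo_r": 100,
        }
    )
    # ribosome reads
    ribo_depth: int = 20000
    length_probs: dict[int, float] = field(
        default_factory=lambda: {28: 0.15, 29: 0.20, 30: 0.30, 31: 0.20, 32: 0.15}
    )
    offsets: dict[int, int] = field(
        default_factory=lambda: {28: 12, 29: 13, 30: 14, 31: 15, 32: 16}
    )
    frame_probs: tuple[float, float, float] = (0.70, 0.15, 0.15)
    start_peak: float = 8.0  # weight multiplier on the first CDS codon
    transgene_utr5_read_fraction: float = 0.08
    # rna reads
    rna_depth: int = 20000
    rna_read_length: int = 40
    # culture
    vcd0_per_ml: float = 0.3e6
    mu_early: float = 0.65
    mu_late: float = 0.12
    phase_boundary_day: float = 4.0
    qp_early: float = 16.0
    qp_late: float = 5.5
    culture_noise: float = 0.03
    n_replicates: int = 3

    def __post_init__(self) -> None:
        for name, probs in (
            ("length_probs", list(self.length_probs.values())),
            ("frame_probs", list(self.frame_probs)),
        ):
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if set(self.offsets) != set(self.length_probs):
            raise ValueError("offsets must cover exactly the read lengths used")
        share = sum(self.transgene_shares.values())
        if not 0 < share < 1:
            raise ValueError("transgene shares must sum to a value in (0, 1)")

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["cds_codon_range"] = list(self.cds_codon_range)
        data["frame_probs"] = list(self.frame_probs)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["cds_codon_range"] = tuple(data["cds_codon_range"])
        data["frame_probs"] = tuple(data["frame_probs"])
        data["length_probs"] = {int(k): v for k, v in data["length_probs"].items()}
        data["offsets"] = {int(k): v for k, v in data["offsets"].items()}
        return cls(**data)


@dataclass
class SimGene:
    gene_id: str
    transcript: TranscriptModel
    true_tpm: float
    true_te: float
    is_transgene: bool


@dataclass
class SimOutput:
    outdir: Path
    config: SimConfig
    genes: list[SimGene]
    genome_fasta: Path
    annotation_gtf: Path
    ribo_sam: Path
    rna_sam: Path
    culture_csv: Path
    category_map_tsv: Path
    gene_sets_gmt: Path
    truth_genes: pd.DataFrame
    truth_reads: pd.DataFrame


# -- layout ---------------------------------------------------------------

def _build_transcript(
    gene_id: str, contig: str, strand: str, tx_start: int,
    utr5: int, cds_len: int, utr3: int, n_exons: int, intron: int,
) -> TranscriptModel:
    """Construct a transcript model at a genomic position, splitting the
    spliced sequence into n_exons blocks separated by fixed introns."""
    total = utr5 + cds_len + utr3
    base = total // n_exons
    parts = [base + (1 if i < total % n_exons else 0) for i in range(n_exons)]
    # transcript 5'->3' exon order; genomic left-to-right order reverses on -
    genomic_parts = parts if strand == "+" else parts[::-1]
    exons = []
    pos = tx_start
    for p in genomic_parts:
        exons.append(GenomicInterval(contig, pos, pos + p, strand))
        pos += p + intron
    t = TranscriptModel(
        transcript_id=f"{gene_id}_t1", gene_id=gene_id, contig=contig,
        strand=strand, exons=tuple(exons),
    )
    blocks = transcript_interval_to_blocks(t, utr5, cds_len)
    cds = tuple(GenomicInterval(contig, s, e, strand) for s, e in blocks)
    return TranscriptModel(
        transcript_id=t.transcript_id, gene_id=gene_id, contig=contig,
        strand=strand, exons=t.exons, cds=cds,
    )


def _layout(config: SimConfig, rng: np.random.Generator) -> list[SimGene]:
    genes: list[SimGene] = []
    lo, hi = config.cds_codon_range
    endo_share = 1.0 - sum(config.transgene_shares.values())
    expr = rng.lognormal(mean=0.0, sigma=config.expression_sigma,
                         size=config.n_genes)
    expr = expr / expr.sum() * endo_share * 1e6

    pos = 200
    for i in range(config.n_genes):
        codons = int(rng.integers(lo, hi + 1))
        strand = "+" if i % 2 == 0 else "-"
        t = _build_transcript(
            f"gene{i + 1:03d}", "chr1", strand, pos,
            config.utr5_length, 3 * codons, config.utr3_length,
            config.n_exons, config.intron_length,
        )
        span = t.exons[-1].end - t.exons[0].start
        pos += span + 200
        te = float(rng.lognormal(mean=0.0, sigma=config.te_sigma))
        genes.append(SimGene(t.gene_id, t, float(expr[i]), te, False))

    pos = 200
    for name in sorted(config.transgene_shares):
        codons = config.transgene_cds_codons[name]
        t = _build_transcript(
            name, TRANSGENE_CONTIG, "+", pos,
            config.utr5_length, 3 * codons, config.utr3_length,
            config.n_exons, config.intron_length,
        )
        span = t.exons[-1].end - t.exons[0].start
        pos += span + 200
        te = float(rng.lognormal(mean=0.0, sigma=config.te_sigma))
        genes.append(
            SimGene(name, t, config.transgene_shares[name] * 1e6, te, True)
        )
    return genes


def validate_layout(genes: Sequence[SimGene]) -> None:
    """Reject layouts where gene loci overlap on a contig."""
    by_contig: dict[str, list[tuple[int, int, str]]] = {}
    for g in genes:
        t = g.transcript
        by_contig.setdefault(t.contig, []).append(
            (t.exons[0].start, t.exons[-1].end, g.gene_id)
        )
    for contig, spans in by_contig.items():
        spans.sort()
        for (s1, e1, g1), (s2, e2, g2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(
                    f"overlapping gene layout on {contig}: {g1} and {g2}"
                )


# -- genome + annotation --------------------------------------------------

def _simulate_genome(
    genes: Sequence[SimGene], rng: np.random.Generator
) -> dict[str, str]:
    lengths: dict[str, int] = {}
    for g in genes:
        t = g.transcript
        lengths[t.contig] = max(lengths.get(t.contig, 0), t.exons[-1].end + 200)
    genome = {
        contig: "".join(rng.choice(list("ACGT"), size=n))
        for contig, n in sorted(lengths.items())
    }
    # stamp start (ATG) and stop (TAA) codons in mRNA sense
    seqs = {c: bytearray(s, "ascii") for c, s in genome.items()}
    for g in genes:
        t = g.transcript
        for tpos, base in list(zip(range(t.cds_start, t.cds_start + 3), "ATG")) + list(
            zip(range(t.cds_end - 3, t.cds_end), "TAA")
        ):
            gpos = t.transcript_to_genomic(tpos)
            if t.strand == "-":
                base = base.translate(_COMPLEMENT)
            seqs[t.contig][gpos] = ord(base)
    return {c: s.decode("ascii") for c, s in seqs.items()}


def _write_fasta(genome: Mapping[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for contig in sorted(genome):
            fh.write(f">{contig}\n")
            seq = genome[contig]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def _write_gtf(genes: Sequence[SimGene], path: Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            t = g.transcript
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}";'

            def line(ftype: str, start0: int, end: int, frame: str = ".") -> str:
                return (
                    f"{t.contig}\triboquant_sim\t{ftype}\t{start0 + 1}\t{end}\t.\t"
                    f"{t.strand}\t{frame}\t{attrs}\n"
                )

            first = t.exons[0].start
            last = t.exons[-1].end
            fh.write(line("transcript", first, last))
            for e in t.exons:
                fh.write(line("exon", e.start, e.end))
            cds_in_tx_order = t.cds if t.strand == "+" else t.cds[::-1]
            cum = 0
            for c in cds_in_tx_order:
                frame = str((3 - cum % 3) % 3)
                fh.write(line("CDS", c.start, c.end, frame))
                cum += len(c)


# -- reads ----------------------------------------------------------------

def _cigar_and_seq(
    t: TranscriptModel, genome: Mapping[str, str], tstart: int, length: int
) -> tuple[int, str, str]:
    """Leftmost genomic position, CIGAR, and reference-forward SEQ for a
    read covering transcript interval [tstart, tstart+length)."""
    blocks = transcript_interval_to_blocks(t, tstart, length)
    cigar = ""
    prev_end = None
    seq_parts = []
    for s, e in blocks:
        if prev_end is not None:
            cigar += f"{s - prev_end}N"
        cigar += f"{e - s}M"
        seq_parts.append(genome[t.contig][s:e])
        prev_end = e
    return blocks[0][0], cigar, "".join(seq_parts)


def _write_sam(
    path: Path, genome: Mapping[str, str],
    records: Sequence[tuple[str, int, str, int, str, str]],
) -> None:
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for contig in sorted(genome):
            fh.write(f"@SQ\tSN:{contig}\tLN:{len(genome[contig])}\n")
        for qname, flag, contig, pos0, cigar, seq in records:
            fh.write(
                f"{qname}\t{flag}\t{contig}\t{pos0 + 1}\t255\t{cigar}\t*\t0\t0\t"
                f"{seq}\t*\n"
            )


def simulate_ribo_reads(
    config: SimConfig,
    genes: Sequence[SimGene],
    genome: Mapping[str, str],
    path: Path,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Write a Ribo-Seq SAM and return the per-read truth table.

    Per-gene read totals are multinomial with weights tpm * te * cds
    length.  Within a gene the A-site codon is uniform over the CDS apart
    from a ``start_peak`` pile-up on the first codon; the within-codon
    position follows ``frame_probs``; the 5' end is placed at A-site
    minus the per-length offset.  Transgenes receive extra reads whose
    A sites fall in the 5'UTR.  No read ever touches the 3'UTR.
    """
    lengths = np.array(sorted(config.length_probs))
    length_p = np.array([config.length_probs[l] for l in lengths])
    max_offset = max(config.offsets.values())

    weights = np.array(
        [g.true_tpm * g.true_te * g.transcript.cds_length for g in genes]
    )
    n_per_gene = rng.multinomial(config.ribo_depth, weights / weights.sum())

    records = []
    truth_rows = []
    read_idx = 0
    for g, n_cds in zip(genes, n_per_gene):
        t = g.transcript
        n_codons = t.cds_length // 3
        codon_w = np.ones(n_codons)
        codon_w[0] = config.start_peak
        codon_w /= codon_w.sum()

        codons = rng.choice(n_codons, size=n_cds, p=codon_w)
        frames = rng.choice(3, size=n_cds, p=np.asarray(config.frame_probs))
        read_lens = rng.choice(lengths, size=n_cds, p=length_p)
        a_sites = t.cds_start + 3 * codons + frames

        n_utr5 = 0
        if g.is_transgene and config.transgene_utr5_read_fraction > 0:
            n_utr5 = int(round(config.transgene_utr5_read_fraction * n_cds))
        if n_utr5:
            utr_a = rng.integers(max_offset, t.cds_start, size=n_utr5)
            utr_lens = rng.choice(lengths, size=n_utr5, p=length_p)
            a_sites = np.concatenate([a_sites, utr_a])
            read_lens = np.concatenate([read_lens, utr_lens])

        kinds = ["cds"] * n_cds + ["utr5"] * n_utr5
        for a, L, kind in zip(a_sites, read_lens, kinds):
            end5 = int(a) - config.offsets[int(L)]
            pos0, cigar, seq = _cigar_and_seq(t, genome, end5, int(L))
            flag = 16 if t.strand == "-" else 0
            qname = f"ribo_{read_idx:07d}"
            records.append((qname, flag, t.contig, pos0, cigar, seq))
            truth_rows.append(
                {
                    "read_id": qname,
                    "gene_id": g.gene_id,
                    "transcript_id": t.transcript_id,
                    "length": int(L),
                    "a_site_tpos": int(a),
                    "kind": kind,
                }
            )
            read_idx += 1

    _write_sam(path, genome, records)
    return pd.DataFrame(truth_rows)


def simulate_rna_reads(
    config: SimConfig,
    genes: Sequence[SimGene],
    genome: Mapping[str, str],
    path: Path,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Write an RNA-Seq SAM (uniform full-transcript coverage) and return
    per-gene truth counts.  Totals are proportional to tpm * length."""
    L = config.rna_read_length
    weights = np.array(
        [g.true_tpm * g.transcript.spliced_length for g in genes]
    )
    n_per_gene = rng.multinomial(config.rna_depth, weights / weights.sum())

    records = []
    rows = []
    read_idx = 0
    for g, n in zip(genes, n_per_gene):
        t = g.transcript
        starts = rng.integers(0, t.spliced_length - L + 1, size=n)
        for s in starts:
            pos0, cigar, seq = _cigar_and_seq(t, genome, int(s), L)
            flag = 16 if t.strand == "-" else 0
            records.append((f"rna_{read_idx:07d}", flag, t.contig, pos0, cigar, seq))
            read_idx += 1
        rows.append({"gene_id": g.gene_id, "rna_reads": int(n)})

    _write_sam(path, genome, records)
    return pd.DataFrame(rows)


# -- culture --------------------------------------------------------------

def simulate_culture(
    config: SimConfig, path: Path, rng: np.random.Generator
) -> pd.DataFrame:
    """Two-phase batch culture, daily sampling days 0-7, 3 replicates.

    Titer accumulates qp * VCD using trapezoids on the daily grid, so a
    noise-free series is exactly linear in (trapezoidal) IVCD within each
    phase and regression recovers qp exactly.
    """
    days = np.arange(0.0, 8.0)
    tb = config.phase_boundary_day
    vcd = np.where(
        days <= tb,
        config.vcd0_per_ml * np.exp(config.mu_early * days),
        config.vcd0_per_ml
        * np.exp(config.mu_early * tb)
        * np.exp(config.mu_late * (days - tb)),
    )
    titer = np.zeros_like(days)
    for k in range(1, len(days)):
        qp = config.qp_early if days[k] <= tb else config.qp_late
        titer[k] = titer[k - 1] + qp * 0.5 * (vcd[k] + vcd[k - 1]) * (
            days[k] - days[k - 1]
        ) * 1e-6

    viability = np.clip(99.0 - 1.5 * days, 80.0, None)
    glucose = np.clip(6.0 - 0.9 * days, 0.0, None)
    lactate = np.where(days <= tb + 1, 0.4 * days, 0.4 * (tb + 1) - 0.2 * (days - tb - 1))

    frames = []
    for rep in range(1, config.n_replicates + 1):
        noise_v = np.exp(rng.normal(0.0, config.culture_noise, size=len(days)))
        noise_t = np.exp(rng.normal(0.0, config.culture_noise, size=len(days)))
        frames.append(
            pd.DataFrame(
                {
                    "replicate": rep,
                    "time_d": days,
                    "vcd_per_ml": vcd * noise_v,
                    "viability_pct": viability,
                    "titer_ug_ml": titer * noise_t,
                    "glucose_g_l": glucose,
                    "lactate_g_l": np.clip(lactate, 0.0, None),
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(path, index=False, float_format="%.6f")
    return df


# -- category map and gene sets ------------------------------------------

CATEGORIES = ("Translation", "Folding", "Metabolism", "Signaling")


def simulate_category_map(
    genes: Sequence[SimGene], path: Path, rng: np.random.Generator,
    unmapped_fraction: float = 0.1,
) -> dict[str, list[tuple[str, str]]]:
    """Gene -> (homolog, category) table; ~30% of mapped endogenous genes
    get two homolog IDs to exercise even allocation."""
    cmap: dict[str, list[tuple[str, str]]] = {}
    homolog_idx = 1
    for g in genes:
        if g.is_transgene:
            cmap[g.gene_id] = [(f"m{homolog_idx:04d}", "Recombinant")]
            homolog_idx += 1
            continue
        if rng.random() < unmapped_fraction:
            continue
        n_homologs = 2 if rng.random() < 0.3 else 1
        entries = []
        for _ in range(n_homologs):
            cat = CATEGORIES[int(rng.integers(len(CATEGORIES)))]
            entries.append((f"m{homolog_idx:04d}", cat))
            homolog_idx += 1
        cmap[g.gene_id] = entries
    with open(path, "w") as fh:
        fh.write("gene_id\thomolog_id\tcategory\n")
        for gene in sorted(cmap):
            for homolog, cat in cmap[gene]:
                fh.write(f"{gene}\t{homolog}\t{cat}\n")
    return cmap


def simulate_gene_sets(
    genes: Sequence[SimGene], path: Path, rng: np.random.Generator,
    n_random_sets: int = 3,
) -> dict[str, list[str]]:
    """A top-expression set plus random sets, written as GMT."""
    ids = [g.gene_id for g in genes]
    by_expr = sorted(genes, key=lambda g: -g.true_tpm)
    top = [g.gene_id for g in by_expr[: max(2, len(genes) // 4)]]
    sets = {"top_expressed": top}
    size = max(2, len(ids) // 4)
    for i in range(n_random_sets):
        members = sorted(rng.choice(ids, size=size, replace=False).tolist())
        sets[f"random_{i + 1}"] = members
    with open(path, "w") as fh:
        for name in sorted(sets):
            fh.write("\t".join([name, "synthetic"] + sets[name]) + "\n")
    return sets


# -- top-level ------------------------------------------------------------

def simulate_transcriptome(
    config: SimConfig, outdir: str | Path
) -> tuple[Path, Path, list[SimGene], dict[str, str]]:
    """Write genome FASTA + GTF; return paths, gene layout, and sequences."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(2)
    genes = _layout(config, np.random.default_rng(seeds[0]))
    validate_layout(genes)
    genome = _simulate_genome(genes, np.random.default_rng(seeds[1]))
    fasta = outdir / "genome.fa"
    gtf = outdir / "annotation.gtf"
    _write_fasta(genome, fasta)
    _write_gtf(genes, gtf)
    return fasta, gtf, genes, genome


def simulate_dataset(config: SimConfig, outdir: str | Path) -> SimOutput:
    """Generate the full fixture set into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta, gtf, genes, genome = simulate_transcriptome(config, outdir)
    seeds = np.random.SeedSequence(config.seed).spawn(8)

    ribo_sam = outdir / "ribo.sam"
    rna_sam = outdir / "rna.sam"
    culture_csv = outdir / "culture.csv"
    cmap_tsv = outdir / "category_map.tsv"
    gmt = outdir / "gene_sets.gmt"

    truth_reads = simulate_ribo_reads(
        config, genes, genome, ribo_sam, np.random.default_rng(seeds[2])
    )
    rna_truth = simulate_rna_reads(
        config, genes, genome, rna_sam, np.random.default_rng(seeds[3])
    )
    simulate_culture(config, culture_csv, np.random.default_rng(seeds[4]))
    simulate_category_map(genes, cmap_tsv, np.random.default_rng(seeds[5]))
    simulate_gene_sets(genes, gmt, np.random.default_rng(seeds[6]))

    per_gene = truth_reads.groupby(["gene_id", "kind"]).size().unstack(fill_value=0)
    truth_genes = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "true_tpm": [g.true_tpm for g in genes],
            "true_te": [g.true_te for g in genes],
            "cds_length": [g.transcript.cds_length for g in genes],
            "tx_length": [g.transcript.spliced_length for g in genes],
            "is_transgene": [g.is_transgene for g in genes],
        }
    )
    truth_genes["ribo_cds_reads"] = [
        int(per_gene["cds"].get(g.gene_id, 0)) if "cds" in per_gene else 0
        for g in genes
    ]
    truth_genes["ribo_utr5_reads"] = [
        int(per_gene["utr5"].get(g.gene_id, 0)) if "utr5" in per_gene else 0
        for g in genes
    ]
    rna_counts = dict(zip(rna_truth["gene_id"], rna_truth["rna_reads"]))
    truth_genes["rna_reads"] = [rna_counts.get(g.gene_id, 0) for g in genes]

    truth_genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    truth_reads.to_csv(outdir / "truth_reads_ribo.tsv", sep="\t", index=False)
    config.to_yaml(outdir / "config.yaml")

    return SimOutput(
        outdir=outdir, config=config, genes=genes,
        genome_fasta=fasta, annotation_gtf=gtf,
        ribo_sam=ribo_sam, rna_sam=rna_sam, culture_csv=culture_csv,
        category_map_tsv=cmap_tsv, gene_sets_gmt=gmt,
        truth_genes=truth_genes, truth_reads=truth_reads,
    )
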