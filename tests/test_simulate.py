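import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from riboquant import calibration, genome, ingest, simulate
from riboquant.bioprocess import EARLY_PHASE, LATE_PHASE, phase_metrics
from riboquant.simulate import SimConfig, SimGene, simulate_dataset

from conftest import make_transcript


def small_config(**overrides):
    defaults = dict(seed=5, n_genes=3, ribo_depth=2000, rna_depth=2000)
    defaults.update(overrides)
    return SimConfig(**defaults)


class TestConfig:
    def test_probs_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimConfig(frame_probs=(0.5, 0.5, 0.5))

    def test_offsets_must_cover_lengths(self):
        with pytest.raises(ValueError):
            SimConfig(length_probs={30: 1.0}, offsets={29: 12})

    def test_yaml_round_trip(self, tmp_path):
        cfg = small_config()
        cfg.to_yaml(tmp_path / "cfg.yaml")
        back = SimConfig.from_yaml(tmp_path / "cfg.yaml")
        assert back == cfg


class TestTranscriptome:
    def test_determinism_byte_identical(self, tmp_path):
        a = simulate_dataset(small_config(), tmp_path / "a")
        b = simulate_dataset(small_config(), tmp_path / "b")
        for name in ("genome.fa", "annotation.gtf", "ribo.sam", "rna.sam",
                     "culture.csv", "truth_genes.tsv", "category_map.tsv",
                     "gene_sets.gmt"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes(), name

    def test_different_seed_differs(self, tmp_path):
        a = simulate_dataset(small_config(seed=5), tmp_path / "a")
        b = simulate_dataset(small_config(seed=6), tmp_path / "b")
        assert (tmp_path / "a" / "ribo.sam").read_bytes() != (
            tmp_path / "b" / "ribo.sam"
        ).read_bytes()

    def test_gene_count_and_cds_divisibility(self, tmp_path):
        out = simulate_dataset(small_config(), tmp_path / "sim")
        ann = genome.load_annotation(out.annotation_gtf)
        assert len(ann.genes) == 3 + 3  # endogenous + transgenes
        for t in ann.representative_transcripts():
            assert t.cds_length % 3 == 0
            assert t.codon_ok

    def test_annotation_round_trips_lengths(self, tmp_path):
        cfg = small_config()
        out = simulate_dataset(cfg, tmp_path / "sim")
        ann = genome.load_annotation(out.annotation_gtf)
        by_id = {g.gene_id: g.transcript for g in out.genes}
        for t in ann.representative_transcripts():
            sim_t = by_id[t.gene_id]
            assert t.spliced_length == sim_t.spliced_length
            assert t.cds_length == sim_t.cds_length
            assert t.utr5_length == sim_t.utr5_length

    def test_multi_exon_mode(self, tmp_path):
        cfg = small_config(n_exons=3)
        out = simulate_dataset(cfg, tmp_path / "sim")
        ann = genome.load_annotation(out.annotation_gtf)
        for t in ann.representative_transcripts():
            assert len(t.exons) == 3

    def test_overlapping_layout_rejected(self):
        t1 = make_transcript(gene_id="g1", tx_start=100)
        t2 = make_transcript(gene_id="g2", tx_start=150)
        genes = [SimGene("g1", t1, 1.0, 1.0, False),
                 SimGene("g2", t2, 1.0, 1.0, False)]
        with pytest.raises(ValueError, match="overlap"):
            simulate.validate_layout(genes)

    def test_start_and_stop_codons_stamped(self, tmp_path):
        out = simulate_dataset(small_config(), tmp_path / "sim")
        seqs = {}
        contig = None
        for line in out.genome_fasta.read_text().splitlines():
            if line.startswith(">"):
                contig = line[1:]
                seqs[contig] = []
            else:
                seqs[contig].append(line)
        seqs = {c: "".join(parts) for c, parts in seqs.items()}
        comp = str.maketrans("ACGT", "TGCA")
        for g in out.genes:
            t = g.transcript
            mrna = []
            for tpos in range(t.cds_start, t.cds_start + 3):
                base = seqs[t.contig][t.transcript_to_genomic(tpos)]
                mrna.append(base.translate(comp) if t.strand == "-" else base)
            assert "".join(mrna) == "ATG"


class TestRiboReads:
    def test_degenerate_frame_model_exact(self, tmp_path):
        cfg = small_config(frame_probs=(1.0, 0.0, 0.0))
        out = simulate_dataset(cfg, tmp_path / "sim")
        ann = genome.load_annotation(out.annotation_gtf)
        profiles = ingest.build_end_profiles(out.ribo_sam, ann)
        offsets = calibration.OffsetTable(dict(cfg.offsets))
        tracks, _ = calibration.apply_offsets(profiles, offsets)
        fp = calibration.pooled_periodicity(tracks, ann)
        assert fp == (1.0, 0.0, 0.0)

    def test_true_offsets_recovered(self, tmp_path):
        cfg = small_config(ribo_depth=5000)
        out = simulate_dataset(cfg, tmp_path / "sim")
        ann = genome.load_annotation(out.annotation_gtf)
        profiles = ingest.build_end_profiles(out.ribo_sam, ann)
        table = calibration.estimate_offsets(profiles, ann)
        assert table.offsets == cfg.offsets

    def test_no_3utr_occupancy(self, tmp_path):
        out = simulate_dataset(small_config(), tmp_path / "sim")
        ann = genome.load_annotation(out.annotation_gtf)
        profiles = ingest.build_end_profiles(out.ribo_sam, ann)
        tracks, _ = calibration.apply_offsets(
            profiles, calibration.OffsetTable(dict(out.config.offsets))
        )
        for t in ann.representative_transcripts():
            assert tracks[t.transcript_id].counts[t.cds_end :].sum() == 0

    def test_truth_table_consistent_with_sam(self, tmp_path):
        out = simulate_dataset(small_config(), tmp_path / "sim")
        n_sam = sum(
            1 for line in out.ribo_sam.read_text().splitlines()
            if not line.startswith("@")
        )
        assert n_sam == len(out.truth_reads)
        per_gene = out.truth_reads.groupby("gene_id").size()
        truth = out.truth_genes.set_index("gene_id")
        for g, n in per_gene.items():
            assert n == truth.loc[g, "ribo_cds_reads"] + truth.loc[g, "ribo_utr5_reads"]

    def test_multi_exon_reads_ingest_cleanly(self, tmp_path):
        cfg = small_config(n_exons=2, ribo_depth=1000)
        out = simulate_dataset(cfg, tmp_path / "sim")
        ann = genome.load_annotation(out.annotation_gtf)
        profiles = ingest.build_end_profiles(out.ribo_sam, ann)
        # spliced alignments keep their ~30 nt length and assign cleanly
        assert profiles.stats.assigned_reads == profiles.stats.retained_reads


class TestRnaReads:
    def _genes(self, tpms):
        genes = []
        for i, tpm in enumerate(tpms):
            t = make_transcript(gene_id=f"g{i}", tx_start=100 + 2000 * i,
                                codons=100)
            t.transcript_id = f"g{i}_t1"
            genes.append(SimGene(f"g{i}", t, tpm, 1.0, False))
        return genes

    def test_single_expressed_gene_gets_all_reads(self, tmp_path):
        cfg = small_config()
        genes = self._genes([1e6, 0.0])
        genome_seq = simulate._simulate_genome(genes, np.random.default_rng(0))
        truth = simulate.simulate_rna_reads(
            cfg, genes, genome_seq, tmp_path / "rna.sam",
            np.random.default_rng(1),
        )
        counts = dict(zip(truth["gene_id"], truth["rna_reads"]))
        assert counts["g0"] == cfg.rna_depth
        assert counts["g1"] == 0

    def test_read_ratio_within_binomial_ci(self, tmp_path):
        cfg = small_config(rna_depth=10000)
        genes = self._genes([800000.0, 200000.0])
        genome_seq = simulate._simulate_genome(genes, np.random.default_rng(0))
        truth = simulate.simulate_rna_reads(
            cfg, genes, genome_seq, tmp_path / "rna.sam",
            np.random.default_rng(2),
        )
        counts = dict(zip(truth["gene_id"], truth["rna_reads"]))
        n = cfg.rna_depth
        lo, hi = sps.binom.interval(0.99, n, 0.8)
        assert lo <= counts["g0"] <= hi

    def test_full_transcript_coverage(self, tmp_path):
        out = simulate_dataset(small_config(rna_depth=20000), tmp_path / "sim")
        ann = genome.load_annotation(out.annotation_gtf)
        profiles = ingest.build_end_profiles(out.rna_sam, ann, length_range=None)
        tracks = calibration.raw_tracks(profiles)
        # 5'UTR sees RNA coverage, unlike the ribosome data
        utr5 = sum(
            tracks[t.transcript_id].counts[: t.cds_start].sum()
            for t in ann.representative_transcripts()
            if t.transcript_id in tracks
        )
        assert utr5 > 0


class TestCulture:
    def test_zero_noise_doubling(self, tmp_path):
        cfg = small_config(mu_early=np.log(2), culture_noise=0.0)
        df = simulate.simulate_culture(
            cfg, tmp_path / "culture.csv", np.random.default_rng(0)
        )
        one = df[df["replicate"] == 1].set_index("time_d")["vcd_per_ml"]
        for day in range(4):
            assert one[day + 1] / one[day] == pytest.approx(2.0)

    def test_zero_noise_qp_recovered_exactly(self, tmp_path):
        cfg = small_config(culture_noise=0.0)
        df = simulate.simulate_culture(
            cfg, tmp_path / "culture.csv", np.random.default_rng(0)
        )
        out = phase_metrics(df, windows=(EARLY_PHASE, LATE_PHASE))
        early = out[out["phase"] == "early"]["qp_pg_per_cell_day"]
        late = out[out["phase"] == "late"]["qp_pg_per_cell_day"]
        assert early.to_numpy() == pytest.approx(cfg.qp_early, rel=1e-9)
        assert late.to_numpy() == pytest.approx(cfg.qp_late, rel=1e-9)

    def test_csv_deterministic(self, tmp_path):
        cfg = small_config()
        simulate.simulate_culture(cfg, tmp_path / "a.csv", np.random.default_rng(3))
        simulate.simulate_culture(cfg, tmp_path / "b.csv", np.random.default_rng(3))
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()


class TestCategoryAndSets:
    def test_category_map_covers_transgenes(self, tmp_path):
        out = simulate_dataset(small_config(), tmp_path / "sim")
        cmap = pd.read_csv(out.category_map_tsv, sep="\t")
        tg = cmap[cmap["gene_id"].isin(["heavy_chain", "light_chain", "neo_r"])]
        assert set(tg["category"]) == {"Recombinant"}

    def test_gene_sets_are_subsets(self, tmp_path):
        out = simulate_dataset(small_config(), tmp_path / "sim")
        from riboquant.stats import read_gmt

        sets = read_gmt(out.gene_sets_gmt)
        ids = {g.gene_id for g in out.genes}
        assert sets
        for members in sets.values():
            assert set(members) <= ids
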