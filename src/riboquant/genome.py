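"""Gene and transcript models built from GTF/GFF3 annotation.

Internal coordinates are 0-based, half-open on the genome; transcript
coordinates are 0-based positions along the spliced mRNA in 5'->3'
orientation (strand-adjusted). GTF/GFF3 input (1-based, closed) is
converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import gffutils

log = logging.getLogger(__name__)

FLAG_CDS_NOT_IN_EXONS = "cds_not_in_exons"
FLAG_CDS_NOT_MULTIPLE_OF_3 = "cds_not_multiple_of_3"


class AnnotationError(ValueError):
    """Raised for unparseable or inconsistent annotation input."""


class UnmappedPositionError(ValueError):
    """Raised when a genomic position does not fall in any exon."""


class NonCodingGeneError(ValueError):
    """Raised when a coding transcript is requested from a non-coding gene."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open stranded interval on a contig."""

    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript with coordinate mapping.

    ``exons`` and ``cds`` are tuples of :class:`GenomicInterval` sorted by
    genomic start; CDS intervals must be contained in exons.  ``flags``
    collects structural problems (e.g. a CDS length not divisible by 3)
    that exclude the transcript from codon-level analyses.
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    cds: tuple[GenomicInterval, ...] = ()
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise AnnotationError(
                    f"overlapping exons in transcript {self.transcript_id}"
                )
        self.exons = exons
        self.cds = tuple(sorted(self.cds, key=lambda c: c.start))
        for c in self.cds:
            if not any(e.start <= c.start and c.end <= e.end for e in exons):
                self.flags.add(FLAG_CDS_NOT_IN_EXONS)
        if self.cds and self.cds_length % 3 != 0:
            self.flags.add(FLAG_CDS_NOT_MULTIPLE_OF_3)

    # -- lengths -------------------------------------------------------
    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(len(c) for c in self.cds)

    @property
    def is_coding(self) -> bool:
        return bool(self.cds) and FLAG_CDS_NOT_IN_EXONS not in self.flags

    @property
    def codon_ok(self) -> bool:
        """True if the transcript may enter codon-level analyses."""
        return self.is_coding and FLAG_CDS_NOT_MULTIPLE_OF_3 not in self.flags

    @property
    def utr5_length(self) -> int:
        """Transcript coordinate of the first CDS nucleotide."""
        if not self.is_coding:
            raise NonCodingGeneError(self.transcript_id)
        if self.strand == "+":
            first = min(c.start for c in self.cds)
            return self.genomic_to_transcript(first)
        first = max(c.end for c in self.cds) - 1
        return self.genomic_to_transcript(first)

    @property
    def utr3_length(self) -> int:
        return self.spliced_length - self.utr5_length - self.cds_length

    @property
    def cds_start(self) -> int:
        """Alias for utr5_length: transcript coord of the CDS start."""
        return self.utr5_length

    @property
    def cds_end(self) -> int:
        """Transcript coord one past the last CDS nucleotide."""
        return self.utr5_length + self.cds_length

    # -- coordinate mapping --------------------------------------------
    def genomic_to_transcript(self, pos: int) -> int:
        offset = 0
        for e in self.exons:
            if e.contains(pos):
                plus = offset + (pos - e.start)
                if self.strand == "+":
                    return plus
                return self.spliced_length - 1 - plus
            offset += len(e)
        raise UnmappedPositionError(
            f"position {pos} not exonic in {self.transcript_id}"
        )

    def transcript_to_genomic(self, tpos: int) -> int:
        if not 0 <= tpos < self.spliced_length:
            raise UnmappedPositionError(
                f"transcript position {tpos} outside {self.transcript_id}"
            )
        plus = tpos if self.strand == "+" else self.spliced_length - 1 - tpos
        for e in self.exons:
            if plus < len(e):
                return e.start + plus
            plus -= len(e)
        raise AssertionError("unreachable")

    def contains_genomic(self, pos: int) -> bool:
        return any(e.contains(pos) for e in self.exons)


def transcript_interval_to_blocks(
    t: TranscriptModel, tstart: int, length: int
) -> list[tuple[int, int]]:
    """Map a transcript-space interval [tstart, tstart+length) to genomic
    blocks, returned sorted by genomic coordinate (as needed for CIGARs)."""
    if length < 1 or tstart < 0 or tstart + length > t.spliced_length:
        raise UnmappedPositionError(
            f"interval [{tstart},{tstart + length}) outside {t.transcript_id}"
        )
    if t.strand == "+":
        a, b = tstart, tstart + length
    else:
        a, b = t.spliced_length - tstart - length, t.spliced_length - tstart
    blocks: list[tuple[int, int]] = []
    offset = 0
    for e in t.exons:
        lo = max(a, offset)
        hi = min(b, offset + len(e))
        if lo < hi:
            blocks.append((e.start + lo - offset, e.start + hi - offset))
        offset += len(e)
    return blocks


@dataclass
class GeneModel:
    """A gene with its transcripts and a representative-transcript rule."""

    gene_id: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    @property
    def is_coding(self) -> bool:
        return any(t.is_coding for t in self.transcripts)

    @property
    def representative(self) -> TranscriptModel:
        return select_representative(self)


def select_representative(gene: GeneModel) -> TranscriptModel:
    """Longest-CDS transcript; ties broken by smallest transcript_id."""
    coding = [t for t in gene.transcripts if t.is_coding]
    if not coding:
        raise NonCodingGeneError(f"gene {gene.gene_id} has no coding transcript")
    return min(coding, key=lambda t: (-t.cds_length, t.transcript_id))


class Annotation:
    """Container for gene models with a per-contig representative index."""

    def __init__(self, genes: dict[str, GeneModel], stop_codon_in_cds: bool | None):
        self.genes = genes
        #: True if CDS features include the stop codon, False if the file
        #: carried separate stop_codon features, None if undeterminable.
        self.stop_codon_in_cds = stop_codon_in_cds
        self._by_contig: dict[str, list[TranscriptModel]] = {}
        for g in genes.values():
            if not g.is_coding:
                continue
            rep = g.representative
            self._by_contig.setdefault(rep.contig, []).append(rep)

    def __len__(self) -> int:
        return len(self.genes)

    def representative_transcripts(self) -> list[TranscriptModel]:
        return [g.representative for g in self.genes.values() if g.is_coding]

    def representatives_on(self, contig: str) -> list[TranscriptModel]:
        return self._by_contig.get(contig, [])

    def transcripts_containing(self, contig: str, pos: int) -> list[TranscriptModel]:
        return [t for t in self.representatives_on(contig) if t.contains_genomic(pos)]


def _validate_lines(path: Path) -> None:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            if len(line.rstrip("\n").split("\t")) != 9:
                raise AnnotationError(f"{path}: unparseable line {i} (expected 9 fields)")


def _feature_ids(db: gffutils.FeatureDB, feat) -> tuple[list[str], str | None]:
    """Return (transcript_ids, gene_id) for an exon/CDS feature in either
    GTF (gene_id/transcript_id attributes) or GFF3 (Parent chain) dialect."""
    attrs = feat.attributes
    if "transcript_id" in attrs:
        return list(attrs["transcript_id"]), attrs.get("gene_id", [None])[0]
    tids = list(attrs.get("Parent", []))
    gene_id = attrs.get("gene_id", [None])[0]
    return tids, gene_id


def load_annotation(path: str | Path) -> Annotation:
    """Parse a GTF or GFF3 file into an :class:`Annotation`.

    Genes with no CDS-bearing transcript are retained but non-coding;
    transcripts whose CDS falls outside their exons are flagged and
    excluded from representative selection.
    """
    path = Path(path)
    _validate_lines(path)
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # pragma: no cover - gffutils raises many types
        raise AnnotationError(f"cannot parse {path}: {exc}") from exc

    raw: dict[str, dict] = {}

    def bucket(tid: str, feat) -> dict:
        entry = raw.setdefault(
            tid,
            {"gene": None, "contig": feat.seqid, "strand": feat.strand,
             "exons": [], "cds": []},
        )
        return entry

    for ftype, key in (("exon", "exons"), ("CDS", "cds")):
        for feat in db.features_of_type(ftype):
            tids, gid = _feature_ids(db, feat)
            if not tids:
                raise AnnotationError(
                    f"{path}: {ftype} feature without transcript_id/Parent"
                )
            for tid in tids:
                entry = bucket(tid, feat)
                if gid is not None:
                    entry["gene"] = gid
                entry[key].append(
                    GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
                )

    # resolve gene ids through transcript-level features (GFF3 Parent chain)
    for ttype in ("mRNA", "transcript"):
        for feat in db.features_of_type(ttype):
            tid = feat.attributes.get("ID", [feat.id])[0]
            if tid in raw and raw[tid]["gene"] is None:
                parent = feat.attributes.get("Parent", [None])[0]
                raw[tid]["gene"] = feat.attributes.get("gene_id", [parent])[0]

    has_stop_features = any(True for _ in db.features_of_type("stop_codon"))

    genes: dict[str, GeneModel] = {}
    for tid, entry in raw.items():
        gid = entry["gene"] or tid
        model = TranscriptModel(
            transcript_id=tid,
            gene_id=gid,
            contig=entry["contig"],
            strand=entry["strand"],
            exons=tuple(entry["exons"]),
            cds=tuple(entry["cds"]),
        )
        if FLAG_CDS_NOT_IN_EXONS in model.flags:
            log.warning("transcript %s: CDS outside exons; excluded", tid)
        genes.setdefault(gid, GeneModel(gene_id=gid)).transcripts.append(model)

    return Annotation(genes, stop_codon_in_cds=None if not has_stop_features else False)


def genomic_to_transcript(pos: int, t: TranscriptModel) -> int:
    """Functional alias for :meth:`TranscriptModel.genomic_to_transcript`."""
    return t.genomic_to_transcript(pos)


def transcript_to_genomic(tpos: int, t: TranscriptModel) -> int:
    return t.transcript_to_genomic(tpos)
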