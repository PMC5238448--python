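"""Alignment ingest: strand-aware ribosome-end assignment and per-length
end profiles along representative transcripts.

The counted end is the ribosome's 5' end in mRNA orientation: the leftmost
aligned base for genes on the + strand and the rightmost aligned base for
genes on the - strand.  The strand of the *gene*, not of the alignment,
governs the rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pysam

from .genome import Annotation, AnnotationError, TranscriptModel

DEFAULT_RPF_LENGTH_RANGE = (25, 35)


@dataclass(frozen=True)
class AlignedRead:
    """Minimal view of an aligned read: reference span plus aligned length.

    ``length`` is the aligned query length excluding soft clips (and
    excluding intron gaps for spliced alignments); for plain ``M``-only
    alignments it equals ``end - start``.
    """

    contig: str
    start: int  # 0-based inclusive leftmost aligned base
    end: int    # exclusive
    length: int

    @classmethod
    def from_pysam(cls, aln: pysam.AlignedSegment) -> "AlignedRead":
        return cls(
            contig=aln.reference_name,
            start=aln.reference_start,
            end=aln.reference_end,
            length=aln.query_alignment_length,
        )


@dataclass
class LibraryStats:
    """Read bookkeeping: retained = assigned + unassigned, exactly."""

    total_input_reads: int = 0
    retained_reads: int = 0
    assigned_reads: int = 0
    unassigned_reads: int = 0
    ambiguous_reads: int = 0  # assigned to >1 overlapping gene
    length_histogram: dict[int, int] = field(default_factory=dict)


class EndProfileSet:
    """Per-(transcript, read length) counts of assigned ribosome ends."""

    def __init__(self, annotation: Annotation):
        self.annotation = annotation
        self._tracks: dict[str, dict[int, np.ndarray]] = {}
        self._lengths: dict[str, int] = {
            t.transcript_id: t.spliced_length
            for t in annotation.representative_transcripts()
        }
        self.stats = LibraryStats()

    def add(self, transcript_id: str, read_length: int, tpos: int) -> None:
        per_len = self._tracks.setdefault(transcript_id, {})
        if read_length not in per_len:
            per_len[read_length] = np.zeros(self._lengths[transcript_id], dtype=np.int64)
        per_len[read_length][tpos] += 1

    def profile(self, transcript_id: str, read_length: int) -> np.ndarray:
        per_len = self._tracks.get(transcript_id, {})
        if read_length in per_len:
            return per_len[read_length]
        return np.zeros(self._lengths[transcript_id], dtype=np.int64)

    def lengths(self) -> list[int]:
        out: set[int] = set()
        for per_len in self._tracks.values():
            out.update(per_len)
        return sorted(out)

    def transcript_ids(self) -> list[str]:
        return sorted(self._tracks)

    def items(self) -> Iterator[tuple[str, int, np.ndarray]]:
        for tid, per_len in self._tracks.items():
            for length, counts in per_len.items():
                yield tid, length, counts

    def total_counts(self) -> int:
        return int(sum(counts.sum() for _, _, counts in self.items()))

    def to_tsv(self, path: str | Path) -> None:
        """Sparse wiggle-like export: transcript, position, length, count."""
        with open(path, "w") as fh:
            fh.write("transcript_id\tposition\tlength\tcount\n")
            for tid, length, counts in sorted(self.items()):
                for pos in np.nonzero(counts)[0]:
                    fh.write(f"{tid}\t{pos}\t{length}\t{counts[pos]}\n")


def assign_ribosome_end(read: AlignedRead, gene_strand: str) -> int:
    """Genomic position of the ribosome's 5' end in mRNA orientation."""
    if gene_strand == "+":
        return read.start
    if gene_strand == "-":
        return read.end - 1
    raise ValueError(f"invalid strand {gene_strand!r}")


def iter_sam(path: str | Path) -> Iterator[AlignedRead]:
    """Yield mapped primary alignments from a SAM/BAM file."""
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            yield AlignedRead.from_pysam(aln)


def build_end_profiles(
    reads: str | Path | Iterable[AlignedRead],
    annotation: Annotation,
    length_range: tuple[int, int] | None = DEFAULT_RPF_LENGTH_RANGE,
) -> EndProfileSet:
    """Count ribosome ends per transcript position and read length.

    Each retained read contributes +1 to the end profile of every gene
    whose representative-transcript exons contain its strand-assigned end;
    reads assigned to more than one gene are tallied as ambiguous.  Pass
    ``length_range=None`` for RNA-Seq (no length filter).
    """
    if not annotation.representative_transcripts():
        raise AnnotationError("annotation contains no coding genes")
    if length_range is not None and length_range[0] > length_range[1]:
        raise ValueError(f"invalid length_range {length_range}")

    if isinstance(reads, (str, Path)):
        reads = iter_sam(reads)

    profiles = EndProfileSet(annotation)
    stats = profiles.stats
    for read in reads:
        stats.total_input_reads += 1
        if length_range is not None and not (
            length_range[0] <= read.length <= length_range[1]
        ):
            continue
        stats.retained_reads += 1
        stats.length_histogram[read.length] = (
            stats.length_histogram.get(read.length, 0) + 1
        )
        hits = 0
        for t in annotation.representatives_on(read.contig):
            end = assign_ribosome_end(read, t.strand)
            if t.contains_genomic(end):
                profiles.add(t.transcript_id, read.length, t.genomic_to_transcript(end))
                hits += 1
        if hits:
            stats.assigned_reads += 1
            if hits > 1:
                stats.ambiguous_reads += 1
        else:
            stats.unassigned_reads += 1

    if stats.retained_reads == 0:
        warnings.warn("no reads retained after length filter", stacklevel=2)
    return profiles
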