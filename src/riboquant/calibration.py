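"""Per-read-length A-site offset calibration and codon periodicity.

The counted 5' end sits a length-dependent distance upstream of the
ribosomal A site.  Offsets are estimated from the pile-up of ends upstream
of annotated start codons, aggregated over representative transcripts:
for each read length the candidate offset maximizing the summed end count
at (start codon - offset) wins, ties going to the smallest candidate.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple

import numpy as np

from .genome import Annotation, TranscriptModel
from .ingest import EndProfileSet

log = logging.getLogger(__name__)

DEFAULT_CANDIDATE_WINDOW = (12, 18)


class CalibrationError(RuntimeError):
    """Raised when offsets cannot be estimated or applied."""


class NoCoverageError(RuntimeError):
    """Raised when a periodicity is requested for a CDS with zero coverage."""


@dataclass
class OffsetTable:
    """Read length -> nt offset from the counted end to the A-site codon."""

    offsets: dict[int, int]
    low_confidence: set[int] = field(default_factory=set)

    def get(self, read_length: int) -> int:
        try:
            return self.offsets[read_length]
        except KeyError:
            raise CalibrationError(
                f"no offset for read length {read_length}"
            ) from None

    def is_confident(self, read_length: int) -> bool:
        return read_length not in self.low_confidence

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("length\toffset\tconfidence\n")
            for length in sorted(self.offsets):
                conf = "low" if length in self.low_confidence else "high"
                fh.write(f"{length}\t{self.offsets[length]}\t{conf}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OffsetTable":
        offsets: dict[int, int] = {}
        low: set[int] = set()
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                length_s, offset_s, conf = line.rstrip("\n").split("\t")
                offsets[int(length_s)] = int(offset_s)
                if conf == "low":
                    low.add(int(length_s))
        return cls(offsets, low)


@dataclass
class OccupancyTrack:
    """Per-nucleotide calibrated ribosome (or RNA) density on a transcript."""

    transcript_id: str
    counts: np.ndarray


class FramePeriodicity(NamedTuple):
    f0: float
    f1: float
    f2: float


def estimate_offsets(
    profiles: EndProfileSet,
    annotation: Annotation,
    candidate_window: tuple[int, int] = DEFAULT_CANDIDATE_WINDOW,
    min_signal: int = 10,
) -> OffsetTable:
    """Estimate one offset per read length from start-codon pile-ups.

    Lengths whose total signal inside the candidate window falls below
    ``min_signal`` inherit the modal offset of the confident lengths and
    are flagged low-confidence.
    """
    lo, hi = candidate_window
    if lo > hi or lo < 0:
        raise ValueError(f"invalid candidate window {candidate_window}")
    reps = [t for t in annotation.representative_transcripts() if t.cds_length > 0]

    offsets: dict[int, int] = {}
    low_confidence: set[int] = set()
    for length in profiles.lengths():
        scores = {d: 0 for d in range(lo, hi + 1)}
        for t in reps:
            counts = profiles.profile(t.transcript_id, length)
            for d in scores:
                pos = t.cds_start - d
                if pos >= 0:
                    scores[d] += int(counts[pos])
        if sum(scores.values()) >= min_signal:
            best = max(scores.values())
            offsets[length] = min(d for d, s in scores.items() if s == best)
        else:
            low_confidence.add(length)

    if not offsets:
        raise CalibrationError("insufficient calibration signal")

    modal = Counter(offsets.values()).most_common()
    top = max(n for _, n in modal)
    fallback = min(off for off, n in modal if n == top)
    for length in low_confidence:
        offsets[length] = fallback
        log.info("read length %d below signal threshold; using modal offset %d",
                 length, fallback)
    return OffsetTable(offsets, low_confidence)


def apply_offsets(
    profiles: EndProfileSet, offsets: OffsetTable
) -> tuple[dict[str, OccupancyTrack], int]:
    """Shift end counts by per-length offsets into A-site occupancy tracks.

    Returns the tracks and the number of end counts shifted past the
    transcript end (dropped and logged).  Mass is conserved up to drops.
    """
    tracks: dict[str, OccupancyTrack] = {}
    dropped = 0
    for tid, length, counts in profiles.items():
        off = offsets.get(length)  # raises CalibrationError if missing
        track = tracks.setdefault(
            tid, OccupancyTrack(tid, np.zeros(len(counts), dtype=np.int64))
        )
        if off == 0:
            track.counts += counts
            continue
        shifted = np.zeros_like(counts)
        if off > 0:
            shifted[off:] = counts[:-off]
            lost = int(counts[-off:].sum())
        else:
            shifted[:off] = counts[-off:]
            lost = int(counts[:-off].sum())
        track.counts += shifted
        dropped += lost
    if dropped:
        log.info("apply_offsets: %d end counts shifted off-transcript", dropped)
    return tracks, dropped


def raw_tracks(profiles: EndProfileSet) -> dict[str, OccupancyTrack]:
    """Uncalibrated tracks: sum of end profiles over read lengths.

    Used for RNA-Seq coverage and for raw-5'-end periodicity.
    """
    zero = OffsetTable({length: 0 for length in profiles.lengths()})
    tracks, _ = apply_offsets(profiles, zero)
    return tracks


def frame_periodicity(track: OccupancyTrack, t: TranscriptModel) -> FramePeriodicity:
    """Fractions of CDS occupancy at codon sub-positions 0/1/2."""
    if not t.codon_ok:
        raise ValueError(f"{t.transcript_id}: CDS length not divisible by 3")
    cds = track.counts[t.cds_start : t.cds_end]
    total = cds.sum()
    if total == 0:
        raise NoCoverageError(f"no CDS coverage on {t.transcript_id}")
    return FramePeriodicity(*(float(cds[k::3].sum()) / float(total) for k in range(3)))


def pooled_periodicity(
    tracks: Mapping[str, OccupancyTrack], annotation: Annotation
) -> FramePeriodicity:
    """Library-wide frame fractions: CDS coverage summed over all
    representative transcripts before dividing."""
    frames = np.zeros(3, dtype=np.int64)
    for t in annotation.representative_transcripts():
        if not t.codon_ok or t.transcript_id not in tracks:
            continue
        cds = tracks[t.transcript_id].counts[t.cds_start : t.cds_end]
        for k in range(3):
            frames[k] += cds[k::3].sum()
    total = frames.sum()
    if total == 0:
        raise NoCoverageError("no CDS coverage in any transcript")
    return FramePeriodicity(*(float(f) / float(total) for f in frames))
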