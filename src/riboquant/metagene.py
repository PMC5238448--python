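"""Normalized ribosome-density profiles anchored at start/stop codons.

Each gene's per-nucleotide coverage is normalized by one third of its
median codon coverage (computed after dropping the first 15 and last 10
codons), so a uniformly covered CDS sits at 1.0.  The cross-gene summary
at each position is the median over genes with sequence at that position;
genes whose UTR is shorter than the window contribute absent values, not
zeros.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import OccupancyTrack
from .genome import Annotation, TranscriptModel

HEAD_CODONS_EXCLUDED = 15
TAIL_CODONS_EXCLUDED = 10

DEFAULT_START_WINDOW = (-30, 60)
DEFAULT_STOP_WINDOW = (-60, 30)


class CdsTooShortError(ValueError):
    """CDS has too few codons for the trimmed median (needs > 25)."""


@dataclass
class MetageneProfile:
    anchor: str                       # "start" or "stop"
    positions: np.ndarray             # nt offsets relative to the anchor
    per_gene: pd.DataFrame            # gene x position, NaN where absent
    summary: pd.Series                # per-position median across genes

    @property
    def n_genes(self) -> int:
        return len(self.per_gene)

    def to_tsv(self, path: str | Path) -> None:
        out = self.per_gene.copy()
        out.loc["__median__"] = self.summary
        out.to_csv(path, sep="\t", index_label="gene_id")


def median_codon_coverage(track: OccupancyTrack, t: TranscriptModel) -> float:
    """Median per-codon coverage over codons 16..N-10 of an N-codon CDS."""
    if not t.codon_ok:
        raise ValueError(f"{t.transcript_id}: CDS not codon-clean")
    n_codons = t.cds_length // 3
    if n_codons <= HEAD_CODONS_EXCLUDED + TAIL_CODONS_EXCLUDED:
        raise CdsTooShortError(
            f"{t.transcript_id}: {n_codons} codons (need > "
            f"{HEAD_CODONS_EXCLUDED + TAIL_CODONS_EXCLUDED})"
        )
    cds = track.counts[t.cds_start : t.cds_end]
    per_codon = cds.reshape(n_codons, 3).sum(axis=1)
    kept = per_codon[HEAD_CODONS_EXCLUDED : n_codons - TAIL_CODONS_EXCLUDED]
    return float(np.median(kept))


def filter_expressed_genes(
    medians_by_gene: Mapping[str, Sequence[float]]
) -> list[str]:
    """Keep genes whose median codon coverage is > 0 in >= 1 replicate."""
    return [g for g, meds in medians_by_gene.items() if meds and max(meds) > 0]


def _anchor_position(t: TranscriptModel, anchor: str) -> int:
    """Transcript coordinate of anchor offset 0.

    start: first nt of the start codon; stop: first nt of the last CDS
    codon (the stop codon when the annotation includes it in the CDS), so
    3'UTR positions begin at offset +3.
    """
    if anchor == "start":
        return t.cds_start
    if anchor == "stop":
        return t.cds_end - 3
    raise ValueError(f"anchor must be 'start' or 'stop', got {anchor!r}")


def metagene_profile(
    tracks: Mapping[str, OccupancyTrack],
    annotation: Annotation,
    anchor: str = "start",
    window: tuple[int, int] | None = None,
    gene_ids: Sequence[str] | None = None,
) -> MetageneProfile:
    """Median-normalized coverage around start or stop codons.

    ``gene_ids`` restricts the profile (e.g. to genes passing
    :func:`filter_expressed_genes`); by default all coding genes with a
    positive median codon coverage and a long-enough CDS contribute.
    """
    if window is None:
        window = DEFAULT_START_WINDOW if anchor == "start" else DEFAULT_STOP_WINDOW
    a, b = window
    positions = np.arange(a, b + 1)

    wanted = set(gene_ids) if gene_ids is not None else None
    rows: dict[str, np.ndarray] = {}
    for t in annotation.representative_transcripts():
        if wanted is not None and t.gene_id not in wanted:
            continue
        if not t.codon_ok or t.transcript_id not in tracks:
            continue
        track = tracks[t.transcript_id]
        try:
            med = median_codon_coverage(track, t)
        except CdsTooShortError:
            continue
        if med <= 0:
            continue
        anchor0 = _anchor_position(t, anchor)
        row = np.full(len(positions), np.nan)
        for i, rel in enumerate(positions):
            p = anchor0 + rel
            if 0 <= p < t.spliced_length:
                row[i] = track.counts[p] / (med / 3.0)
        rows[t.gene_id] = row

    if not rows:
        raise ValueError("no genes eligible for the metagene profile")

    per_gene = pd.DataFrame.from_dict(rows, orient="index", columns=positions)
    summary = per_gene.median(axis=0, skipna=True)
    return MetageneProfile(anchor=anchor, positions=positions,
                           per_gene=per_gene, summary=summary)
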