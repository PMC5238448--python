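"""Gene-level quantification: counts, rpm, tpm, translation efficiency,
and category-level occupancy with even homolog allocation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import OccupancyTrack
from .genome import Annotation, TranscriptModel

UNMAPPED_CATEGORY = "unmapped"


@dataclass
class TranslationEfficiency:
    gene_id: str
    te: float
    defined: bool


def count_gene(
    track: OccupancyTrack, t: TranscriptModel, region: str = "cds"
) -> int:
    """Sum occupancy over the CDS or the full exonic transcript."""
    if region == "cds":
        return int(track.counts[t.cds_start : t.cds_end].sum())
    if region == "exonic":
        return int(track.counts.sum())
    raise ValueError(f"region must be 'cds' or 'exonic', got {region!r}")


def rpm(count: float, library_total: float) -> float:
    """Reads per million: count scaled by the library total."""
    if library_total <= 0:
        raise ValueError("library_total must be > 0")
    return count * 1e6 / library_total


def tpm(
    counts: Mapping[str, float], lengths: Mapping[str, float]
) -> dict[str, float]:
    """Length-normalized abundance summing to 1e6 across genes."""
    rates = {}
    for g, c in counts.items():
        if lengths[g] <= 0:
            raise ValueError(f"non-positive length for {g}")
        rates[g] = c / lengths[g]
    total = sum(rates.values())
    if total == 0:
        warnings.warn("all counts are zero; tpm undefined, returning zeros",
                      stacklevel=2)
        return {g: 0.0 for g in counts}
    return {g: r * 1e6 / total for g, r in rates.items()}


def translation_efficiency(
    ribo_tpm: float, rna_tpm: float, gene_id: str = ""
) -> TranslationEfficiency:
    """Ribo-Seq tpm over RNA-Seq tpm; undefined (flagged) when rna_tpm=0."""
    if rna_tpm == 0:
        return TranslationEfficiency(gene_id, float("nan"), defined=False)
    return TranslationEfficiency(gene_id, ribo_tpm / rna_tpm, defined=True)


def quantify_sample(
    tracks: Mapping[str, OccupancyTrack],
    annotation: Annotation,
    library_total: int,
    sample_id: str,
    assay: str,
) -> pd.DataFrame:
    """Per-gene count/rpm/tpm table for one sample and assay.

    Ribo counts are summed over the CDS and length-normalized by CDS
    length; RNA counts over the full exonic transcript, normalized by
    spliced length.
    """
    if assay not in ("ribo", "rna"):
        raise ValueError(f"assay must be 'ribo' or 'rna', got {assay!r}")
    region = "cds" if assay == "ribo" else "exonic"
    counts: dict[str, int] = {}
    lengths: dict[str, int] = {}
    for t in annotation.representative_transcripts():
        track = tracks.get(t.transcript_id)
        counts[t.gene_id] = count_gene(track, t, region) if track is not None else 0
        lengths[t.gene_id] = t.cds_length if region == "cds" else t.spliced_length
    tpms = tpm(counts, lengths)
    genes = sorted(counts)
    return pd.DataFrame(
        {
            "gene_id": genes,
            "sample_id": sample_id,
            "assay": assay,
            "count": [counts[g] for g in genes],
            "rpm": [rpm(counts[g], library_total) for g in genes],
            "tpm": [tpms[g] for g in genes],
            "length_used": [lengths[g] for g in genes],
        }
    )


def translation_efficiency_table(
    ribo: pd.DataFrame, rna: pd.DataFrame, min_rna_tpm: float = 0.0
) -> pd.DataFrame:
    """Join ribo/rna quantifications into a per-gene TE table.

    Genes with rna tpm <= ``min_rna_tpm`` are flagged undefined rather
    than silently assigned zero.
    """
    r = ribo.set_index("gene_id")["tpm"]
    m = rna.set_index("gene_id")["tpm"]
    genes = sorted(set(r.index) & set(m.index))
    rows = []
    for g in genes:
        defined = m[g] > min_rna_tpm
        rows.append(
            {
                "gene_id": g,
                "ribo_tpm": r[g],
                "rna_tpm": m[g],
                "te": r[g] / m[g] if defined else np.nan,
                "defined": defined,
            }
        )
    return pd.DataFrame(rows)


# -- category occupancy -------------------------------------------------

CategoryMap = Mapping[str, Sequence[tuple[str, str]]]


def read_category_map(path: str | Path) -> dict[str, list[tuple[str, str]]]:
    """3-column TSV (gene_id, homolog_id, category) -> CategoryMap."""
    out: dict[str, list[tuple[str, str]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            gene, homolog, category = line.rstrip("\n").split("\t")
            out.setdefault(gene, []).append((homolog, category))
    return out


def category_occupancy(
    gene_rpm: Mapping[str, float], cmap: CategoryMap
) -> pd.DataFrame:
    """Sum gene rpm by category with even allocation across homolog IDs.

    A gene mapped to k homolog IDs contributes rpm/k to each; genes with
    no mapping accumulate under ``unmapped``.  Total mass is conserved
    exactly.
    """
    totals: dict[str, float] = {}
    for gene, value in gene_rpm.items():
        mapping = cmap.get(gene, [])
        if not mapping:
            totals[UNMAPPED_CATEGORY] = totals.get(UNMAPPED_CATEGORY, 0.0) + value
            continue
        share = value / len(mapping)
        for _homolog, category in mapping:
            totals[category] = totals.get(category, 0.0) + share
    grand = sum(gene_rpm.values())
    rows = [
        {
            "category": cat,
            "rpm_total": val,
            "percent": (val / grand * 100.0) if grand > 0 else 0.0,
        }
        for cat, val in sorted(totals.items(), key=lambda kv: -kv[1])
    ]
    return pd.DataFrame(rows)
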