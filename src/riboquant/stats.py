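"""Statistical layer: fold changes, t-tests, TE-deviation test, BH FDR,
weighted pre-ranked running-sum enrichment with a permutation null, and
delta-delta-Ct fold changes."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class FoldChangeRecord:
    gene_id: str
    mean_a: float
    mean_b: float
    log2fc: float
    pseudocount: float


@dataclass
class TTestResult:
    statistic: float
    pvalue: float
    degenerate: bool = False


@dataclass
class EnrichmentResult:
    set_id: str
    es: float
    p_perm: float
    n_permutations: int
    seed: int | None
    size: int
    fdr: float | None = None


DEFAULT_PSEUDOCOUNT = 0.5


def log2_fold_change(
    mean_a: float, mean_b: float, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> float:
    """log2((b + eps) / (a + eps)); the pseudocount guards zeros."""
    return math.log2((mean_b + pseudocount) / (mean_a + pseudocount))


def fold_changes(
    means_a: Mapping[str, float],
    means_b: Mapping[str, float],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    genes = sorted(set(means_a) & set(means_b))
    return pd.DataFrame(
        [
            {
                "gene_id": g,
                "mean_a": means_a[g],
                "mean_b": means_b[g],
                "log2fc": log2_fold_change(means_a[g], means_b[g], pseudocount),
                "pseudocount": pseudocount,
            }
            for g in genes
        ]
    )


def category_ttest(
    a: Sequence[float], b: Sequence[float], equal_var: bool = True
) -> TTestResult:
    """Two-sample two-tailed Student's t-test (Welch via equal_var=False).

    Degenerate zero-variance inputs are flagged: equal means give p=1,
    different means p=0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return TTestResult(0.0, 1.0, degenerate=True)
        return TTestResult(math.inf if b.mean() > a.mean() else -math.inf,
                           0.0, degenerate=True)
    stat, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(float(stat), float(p))


def te_deviation_test(
    te_gene: float, endogenous_log2_te: Sequence[float]
) -> float:
    """Two-tailed p for one gene's TE against the endogenous distribution.

    log2(te) is standardized by the endogenous sample mean and SD and
    referred to a t distribution with n-1 degrees of freedom.
    """
    if te_gene is None or not np.isfinite(te_gene) or te_gene <= 0:
        raise ValueError("te_gene must be a finite positive translation efficiency")
    sample = np.asarray(endogenous_log2_te, dtype=float)
    n = len(sample)
    if n < 30:
        raise ValueError(f"endogenous sample too small ({n} < 30)")
    z = (math.log2(te_gene) - sample.mean()) / sample.std(ddof=1)
    return float(2.0 * sps.t.sf(abs(z), df=n - 1))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return sps.false_discovery_control(p, method="bh")


# -- pre-ranked enrichment ----------------------------------------------

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene sets: set name, description, members (tab-separated)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def _running_sum_es(
    sorted_scores: np.ndarray, hit: np.ndarray, weight: float
) -> float:
    """ES of a weighted Kolmogorov-Smirnov running sum over a ranked list."""
    n = len(sorted_scores)
    n_hit = int(hit.sum())
    w = np.where(hit, np.abs(sorted_scores) ** weight, 0.0)
    w_total = w.sum()
    if w_total == 0:  # all hit scores are zero: fall back to equal weights
        w = hit.astype(float)
        w_total = float(n_hit)
    p_hit = np.cumsum(w) / w_total
    p_miss = np.cumsum(~hit) / (n - n_hit)
    dev = p_hit - p_miss
    return float(dev[np.argmax(np.abs(dev))])


def null_es_distribution(
    scores: Mapping[str, float],
    set_size: int,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
) -> np.ndarray:
    """ES values of random gene sets of a given size (the permutation null)."""
    genes = np.array(sorted(scores, key=lambda g: (-scores[g], g)))
    values = np.array([scores[g] for g in genes], dtype=float)
    if not 0 < set_size < len(genes):
        raise ValueError("set_size must be in (0, n_genes)")
    rng = np.random.default_rng(seed)
    out = np.empty(n_perm)
    for i in range(n_perm):
        hit = np.zeros(len(genes), dtype=bool)
        hit[rng.choice(len(genes), size=set_size, replace=False)] = True
        out[i] = _running_sum_es(values, hit, weight)
    return out


def preranked_enrichment(
    scores: Mapping[str, float],
    gene_set: Sequence[str],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
    set_id: str = "",
) -> EnrichmentResult:
    """Weighted running-sum enrichment of a gene set in a ranked list.

    Genes are ranked by decreasing score; hits step the running sum up in
    proportion to |score|^weight, misses step it down uniformly.  The
    null distribution comes from random gene sets of the same size; the
    two-sided permutation p uses add-one smoothing.
    """
    genes = np.array(sorted(scores, key=lambda g: (-scores[g], g)))
    values = np.array([scores[g] for g in genes], dtype=float)
    members = set(gene_set) & set(genes.tolist())
    if not members or len(members) >= len(genes):
        raise ValueError("gene set must be a non-empty proper subset of the ranking")
    hit = np.isin(genes, sorted(members))
    es = _running_sum_es(values, hit, weight)

    n_hit = len(members)
    null = null_es_distribution(scores, n_hit, weight=weight,
                                n_perm=n_perm, seed=seed)
    p = (1 + int(np.sum(np.abs(null) >= abs(es)))) / (n_perm + 1)
    return EnrichmentResult(
        set_id=set_id, es=es, p_perm=p, n_permutations=n_perm,
        seed=seed, size=n_hit,
    )


def preranked_enrichment_many(
    scores: Mapping[str, float],
    gene_sets: Mapping[str, Sequence[str]],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Run enrichment for several sets and attach BH FDR across sets.

    Sets with no usable overlap with the ranking are skipped with a warning.
    """
    results = []
    for i, (set_id, members) in enumerate(sorted(gene_sets.items())):
        sub_seed = None if seed is None else seed + i
        try:
            results.append(
                preranked_enrichment(scores, members, weight=weight,
                                     n_perm=n_perm, seed=sub_seed, set_id=set_id)
            )
        except ValueError as exc:
            warnings.warn(f"skipping gene set {set_id!r}: {exc}", stacklevel=2)
    df = pd.DataFrame(
        {
            "set_id": [r.set_id for r in results],
            "es": [r.es for r in results],
            "p_perm": [r.p_perm for r in results],
            "size": [r.size for r in results],
        }
    )
    df["fdr"] = bh_fdr(df["p_perm"].to_numpy()) if len(df) else []
    return df


# -- qPCR ----------------------------------------------------------------

def ddct(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative fold change by the delta-delta-Ct method (2^-ddCt)."""
    for ct in (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control):
        if not math.isfinite(ct):
            raise ValueError("all Ct values must be finite")
    delta = (ct_target_treated - ct_ref_treated) - (
        ct_target_control - ct_ref_control
    )
    return 2.0 ** (-delta)


def knockdown_percent(fold: float) -> float:
    """Percent knockdown implied by a relative fold change."""
    return (1.0 - fold) * 100.0
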