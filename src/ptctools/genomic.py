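"""Genome-category classification and enrichment statistics.

A segmentation of the genome scored for enhancer content (an enrichment
p-value and a log2 fold-change per segment, plus a flag for strong 3D
Hi-C interaction) is split into four categories:

* ``PTC``               p <= 0.05, log2FC >= 0, 3D hub — putative
  transcriptional condensate segments;
* ``very_active``       p <= 0.05, log2FC >= 0, no hub;
* ``moderately_active`` p > 0.05, log2FC >= 0;
* ``inactive``          p > 0.05, log2FC < 0.

Segments significantly *depleted* of enhancers (p <= 0.05 with
log2FC < 0) are not covered by the four rules and are flagged
``unclassified_depleted`` rather than silently binned.

On top of the classification the module provides the enrichment
statistics used to characterise the categories: TF-target
observed/expected scores, a rank-based tissue-specificity score in
[0, 1], a permutation (interval-shuffling) SNP-overlap enrichment, and
an upper-tail hypergeometric test for gene-module overlap.

Interval convention: 0-based half-open everywhere; a SNP at position p
overlaps [start, end) iff start <= p < end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError
from .io import GenomicInterval

CATEGORIES = ("PTC", "very_active", "moderately_active", "inactive")
UNCLASSIFIED = "unclassified_depleted"


def classify_segment(enrichment_p: float, log2fc: float, hub_flag: int) -> str:
    """Four-way category of one genomic segment (see module docstring)."""
    if not 0.0 <= enrichment_p <= 1.0:
        raise DataError(f"enrichment p-value must be in [0, 1], got {enrichment_p}")
    if enrichment_p <= 0.05:
        if log2fc >= 0:
            return "PTC" if hub_flag else "very_active"
        return UNCLASSIFIED
    return "moderately_active" if log2fc >= 0 else "inactive"


def classify_segments(segments: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`classify_segment` over a segment table.

    Expects columns ``p``, ``log2fc``, ``hub``.
    """
    p = segments["p"].to_numpy(dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise DataError("enrichment p-values must be in [0, 1]")
    fc = segments["log2fc"].to_numpy(dtype=float)
    hub = segments["hub"].to_numpy().astype(bool)
    out = np.where(
        p <= 0.05,
        np.where(fc >= 0, np.where(hub, "PTC", "very_active"), UNCLASSIFIED),
        np.where(fc >= 0, "moderately_active", "inactive"),
    )
    return pd.Series(out, index=segments.index, name="category")


def tf_target_enrichment(tf_targets: Mapping[str, Iterable[str]],
                         gene_categories: Mapping[str, str] | pd.Series) -> pd.DataFrame:
    """Observed/expected enrichment of each TF's targets in each genome category.

    ``expected = (|targets| / |universe|) * (genes in category)`` and the
    score is ``observed / expected``.  The gene universe is everything in
    ``gene_categories``.  TFs with no targets inside the universe are
    skipped with a warning; a category with zero genes gets a NaN score.
    The category-count-weighted mean score of each TF is exactly 1.
    """
    cats = pd.Series(gene_categories)
    universe = set(cats.index)
    n_genes = len(universe)
    if n_genes == 0:
        raise DataError("empty gene universe")
    cat_counts = cats.value_counts()
    rows = []
    for tf, targets in tf_targets.items():
        targets = set(targets) & universe
        if not targets:
            warnings.warn(f"TF {tf!r} has no targets in the gene universe; skipped")
            continue
        frac = len(targets) / n_genes
        t_cats = cats.loc[list(targets)].value_counts()
        for cat in CATEGORIES:
            n_cat = int(cat_counts.get(cat, 0))
            observed = int(t_cats.get(cat, 0))
            expected = frac * n_cat
            rows.append({
                "tf": tf, "category": cat, "n_category_genes": n_cat,
                "observed": observed, "expected": expected,
                "score": observed / expected if n_cat > 0 else float("nan"),
            })
    return pd.DataFrame(rows)


def rank_matrix(expression: pd.DataFrame,
                tissue_groups: Mapping[str, Sequence[str]] | None = None) -> pd.DataFrame:
    """Gene-by-tissue expression ranks (higher expression = higher rank).

    ``tissue_groups`` maps a tissue name to the expression columns that
    represent it (e.g. several brain regions); ranks of replicate columns
    are averaged after ranking each column.  Ties receive average ranks.
    """
    if tissue_groups is None:
        tissue_groups = {c: [c] for c in expression.columns}
    out = {}
    for tissue, cols in tissue_groups.items():
        ranks = np.column_stack([
            stats.rankdata(expression[c].to_numpy(dtype=float)) for c in cols
        ])
        out[tissue] = ranks.mean(axis=1)
    return pd.DataFrame(out, index=expression.index)


def tissue_specificity_score(ranks: pd.DataFrame, gene: str, focal_tissue: str) -> float:
    """Fraction of non-focal tissues ranking the gene strictly lower than the focal tissue.

    1 means the gene's rank is highest in the focal tissue, 0 lowest.
    Ties count as not lower.
    """
    if focal_tissue not in ranks.columns:
        raise DataError(f"focal tissue {focal_tissue!r} not in rank matrix")
    if gene not in ranks.index:
        raise DataError(f"gene {gene!r} missing from the rank matrix")
    row = ranks.loc[gene]
    if row.isna().any():
        raise DataError(f"gene {gene!r} has missing ranks in some tissue")
    others = row.drop(focal_tissue)
    if others.empty:
        raise DataError("need at least one non-focal tissue")
    return float((others < row[focal_tissue]).sum() / len(others))


def tissue_specificity_scores(ranks: pd.DataFrame, focal_tissue: str) -> pd.Series:
    """Vectorised tissue-specificity score for every gene in the rank matrix."""
    if focal_tissue not in ranks.columns:
        raise DataError(f"focal tissue {focal_tissue!r} not in rank matrix")
    if ranks.isna().any().any():
        raise DataError("rank matrix contains missing values")
    focal = ranks[focal_tissue].to_numpy()[:, None]
    others = ranks.drop(columns=focal_tissue).to_numpy()
    if others.shape[1] == 0:
        raise DataError("need at least one non-focal tissue")
    return pd.Series((others < focal).mean(axis=1), index=ranks.index,
                     name=f"{focal_tissue}_specificity")


def shuffle_intervals(intervals: Sequence[GenomicInterval],
                      chrom_lengths: Mapping[str, int],
                      seed: int | np.random.Generator = 0) -> list[GenomicInterval]:
    """Re-place each interval uniformly at random across the genome, preserving length.

    The target chromosome is drawn with probability proportional to its
    length among chromosomes long enough to host the interval; the start is
    uniform over valid positions.  Shuffled intervals may overlap each other.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in names], dtype=np.int64)
    out = []
    for iv in intervals:
        span = iv.end - iv.start
        ok = lengths >= span
        if not ok.any():
            raise DataError(f"interval of length {span} exceeds every chromosome")
        w = np.where(ok, lengths, 0).astype(float)
        ci = rng.choice(len(names), p=w / w.sum())
        start = int(rng.integers(0, lengths[ci] - span + 1))
        out.append(GenomicInterval(names[ci], start, start + span))
    return out


def _snps_by_chrom(snps: Iterable[tuple[str, int]]) -> dict[str, np.ndarray]:
    by = {}
    for chrom, pos in snps:
        by.setdefault(chrom, []).append(pos)
    return {c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in by.items()}


def count_snp_overlap(intervals: Sequence[GenomicInterval],
                      snps: Iterable[tuple[str, int]] | Mapping[str, np.ndarray]) -> int:
    """Number of SNPs falling inside at least one interval (each SNP counted once)."""
    by = snps if isinstance(snps, Mapping) else _snps_by_chrom(snps)
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    total = 0
    for chrom, ivs in per_chrom.items():
        pos = by.get(chrom)
        if pos is None or pos.size == 0:
            continue
        ivs.sort()
        merged = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            total += int(np.searchsorted(pos, e, side="left")
                         - np.searchsorted(pos, s, side="left"))
    return total


@dataclass(frozen=True)
class PermutationEnrichment:
    """Observed SNP overlap versus the mean overlap of shuffled interval sets."""

    observed: int
    permuted: np.ndarray
    enrichment: float

    @property
    def defined(self) -> bool:
        return bool(np.isfinite(self.enrichment))

    def to_dict(self) -> dict:
        return {"observed": self.observed,
                "permuted": [int(v) for v in self.permuted],
                "enrichment": self.enrichment if self.defined else None}


def snp_overlap_enrichment(intervals: Sequence[GenomicInterval],
                           snps: Iterable[tuple[str, int]],
                           chrom_lengths: Mapping[str, int],
                           n_perm: int = 100,
                           seed: int = 0) -> PermutationEnrichment:
    """Permutation SNP-overlap enrichment for one interval category.

    enrichment = observed overlap / mean overlap over ``n_perm`` random
    re-placements of the intervals.  A zero mean permuted overlap yields an
    undefined (NaN) enrichment rather than an exception.
    """
    if n_perm < 1:
        raise DataError("need at least one permutation")
    by = _snps_by_chrom(snps)
    observed = count_snp_overlap(intervals, by)
    rng = np.random.default_rng(seed)
    permuted = np.array([
        count_snp_overlap(shuffle_intervals(intervals, chrom_lengths, rng), by)
        for _ in range(n_perm)
    ], dtype=np.int64)
    mean_perm = permuted.mean() if permuted.size else 0.0
    if mean_perm > 0:
        enr = observed / mean_perm
    else:
        enr = 0.0 if observed == 0 else float("nan")
    return PermutationEnrichment(observed=observed, permuted=permuted,
                                 enrichment=float(enr))


def module_overlap_test(cluster_genes: Iterable[str], module_genes: Iterable[str],
                        universe_size: int) -> float:
    """Upper-tail hypergeometric probability of at least the observed overlap."""
    cluster = set(cluster_genes)
    module = set(module_genes)
    overlap = len(cluster & module)
    if len(cluster) > universe_size or len(module) > universe_size:
        raise DataError("cluster and module must be subsets of the universe")
    if overlap > min(len(cluster), len(module)):  # pragma: no cover - set algebra
        raise DataError("overlap larger than either set")
    return float(stats.hypergeom.sf(overlap - 1, universe_size, len(module), len(cluster)))
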