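"""PTC-associated gene filtering, membership clustering and Day-0-relative expression.

Genes linked to putative transcriptional condensates (PTCs) at three
transdifferentiation timepoints (Day 0, Day 1, Day 7) are filtered to
protein-coding genes with mean TPM > 1 across the timepoints and an
H3K27ac peak within +/-1000 bp of their promoter (TSS), then clustered
into seven groups by the timepoints at which they belong to a PTC:

(1,1,1) Invariant, (1,0,0) Early, (1,1,0) Early-Intermediate,
(0,1,0) Intermediate, (0,1,1) Intermediate-Late, (0,0,1) Late,
(1,0,1) Early-Late.

Expression dynamics are summarised per gene as variance-stabilised
counts divided by the gene's Day 0 value, after excluding genes whose
counts fall below a floor at any timepoint.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError
from .io import GenomicInterval

TIMEPOINTS = ("d0", "d1", "d7")

MEMBERSHIP_CLUSTERS: dict[tuple[int, int, int], str] = {
    (1, 1, 1): "Invariant",
    (1, 0, 0): "Early",
    (1, 1, 0): "Early-Intermediate",
    (0, 1, 0): "Intermediate",
    (0, 1, 1): "Intermediate-Late",
    (0, 0, 1): "Late",
    (1, 0, 1): "Early-Late",
}


def cluster_membership(d0: int, d1: int, d7: int) -> str:
    """Seven-way cluster label from the per-timepoint PTC membership flags."""
    key = (int(bool(d0)), int(bool(d1)), int(bool(d7)))
    if key == (0, 0, 0):
        raise DataError("gene is not a PTC member at any timepoint")
    return MEMBERSHIP_CLUSTERS[key]


def _peaks_by_chrom(peaks: Iterable[GenomicInterval]) -> dict[str, np.ndarray]:
    by: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by.setdefault(p.chrom, []).append((p.start, p.end))
    return {c: np.array(sorted(v)) for c, v in by.items()}


def has_promoter_peak(chrom: str, tss: int, peaks_by_chrom: Mapping[str, np.ndarray],
                      window: int = 1000) -> bool:
    """True if any peak overlaps the closed window [tss - window, tss + window].

    Peaks are half-open, so a peak starting exactly ``window`` bp downstream
    of the TSS still counts (its first base sits on the window edge).
    """
    ivs = peaks_by_chrom.get(chrom)
    if ivs is None or ivs.size == 0:
        return False
    return bool(np.any((ivs[:, 0] <= tss + window) & (ivs[:, 1] > tss - window)))


def membership_flags(gene_bodies: pd.DataFrame,
                     ptc_segments: Mapping[str, Sequence[GenomicInterval]]) -> pd.DataFrame:
    """Per-timepoint PTC membership by any gene-body/segment overlap.

    ``gene_bodies`` needs columns ``chrom``, ``start``, ``end``;
    ``ptc_segments`` maps a timepoint key (d0/d1/d7) to its PTC intervals.
    """
    out = {}
    for tp, segments in ptc_segments.items():
        by = _peaks_by_chrom(segments)
        flags = []
        for chrom, start, end in zip(gene_bodies["chrom"], gene_bodies["start"],
                                     gene_bodies["end"]):
            ivs = by.get(chrom)
            flags.append(bool(ivs is not None and ivs.size
                              and np.any((ivs[:, 0] < end) & (ivs[:, 1] > start))))
        out[f"ptc_{tp}"] = flags
    return pd.DataFrame(out, index=gene_bodies.index)


def filter_ptc_genes(genes: pd.DataFrame, peaks: Iterable[GenomicInterval],
                     window: int = 1000) -> pd.DataFrame:
    """Apply the PTC gene filters and attach the membership cluster label.

    Keeps genes that are (i) protein-coding, (ii) mean TPM over the three
    timepoints strictly > 1, (iii) have an H3K27ac peak within +/-window bp
    of the TSS, and (iv) belong to a PTC at >= 1 timepoint.  Expects
    columns ``gene``, ``biotype``, ``chrom``, ``tss``, ``tpm_d0/tpm_d1/tpm_d7``
    and ``ptc_d0/ptc_d1/ptc_d7``.  Genes without a TSS are skipped with a
    warning.
    """
    required = {"gene", "biotype", "chrom", "tss"}
    required |= {f"tpm_{t}" for t in TIMEPOINTS} | {f"ptc_{t}" for t in TIMEPOINTS}
    missing = required - set(genes.columns)
    if missing:
        raise DataError(f"gene table missing columns {sorted(missing)}")
    df = genes.copy()
    no_anchor = df["tss"].isna()
    if no_anchor.any():
        warnings.warn(f"{int(no_anchor.sum())} genes without a promoter anchor skipped")
        df = df[~no_anchor]

    by_chrom = _peaks_by_chrom(peaks)
    coding = df["biotype"] == "protein_coding"
    expressed = df[[f"tpm_{t}" for t in TIMEPOINTS]].mean(axis=1) > 1.0
    member = df[[f"ptc_{t}" for t in TIMEPOINTS]].astype(bool).any(axis=1)
    near_peak = pd.Series(
        [has_promoter_peak(c, int(t), by_chrom, window)
         for c, t in zip(df["chrom"], df["tss"])], index=df.index)

    kept = df[coding & expressed & member & near_peak].copy()
    kept["cluster"] = [
        cluster_membership(a, b, c)
        for a, b, c in zip(kept["ptc_d0"], kept["ptc_d1"], kept["ptc_d7"])
    ]
    return kept


def relative_expression_to_day0(counts: pd.DataFrame, floor: float = 1.0) -> pd.DataFrame:
    """Per-gene (D0/D0, D1/D0, D7/D0) ratios of variance-stabilised counts.

    Genes with any timepoint below ``floor`` are excluded (their normalized
    score cannot be computed reliably), as are genes whose Day 0 count is
    zero after the floor filter.
    """
    cols = [f"count_{t}" for t in TIMEPOINTS]
    missing = set(cols) - set(counts.columns)
    if missing:
        raise DataError(f"count table missing columns {sorted(missing)}")
    vals = counts[cols].astype(float)
    keep = (vals.min(axis=1) >= floor) & (vals["count_d0"] > 0)
    kept = vals[keep]
    ratios = kept.div(kept["count_d0"], axis=0)
    ratios.columns = [f"rel_{t}" for t in TIMEPOINTS]
    return ratios
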