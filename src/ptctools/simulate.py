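"""Synthetic-data generators for every pipeline stage.

Three generators emulate the study's inputs so each analysis stage is
testable without any download:

* :func:`gen_expression_dataset` — replicate RT-qPCR-style expression for
  the four two-enhancer genotypes, drawn from one of the three generative
  model families with per-batch scale factors and Gaussian noise that
  scales with the batch factor (so per-batch WT normalization removes the
  batch structure exactly);
* :func:`gen_image_stack` — 3-channel confocal-like z-stacks with
  ellipsoidal nuclei (DAPI plateau), compact in-nucleus FISH spots
  spanning a few slices, and an IF channel with tunable colocalization
  amplitude at the spot centers;
* :func:`gen_genome_fixture` / :func:`gen_ptc_gene_fixture` — a toy
  genome tiled into four-category segments with consistent (p, log2FC,
  hub) triples, planted SNP densities, TF-target networks with a
  category bias, gene-by-tissue expression with a focal-tissue shift,
  and gene annotations with per-timepoint PTC membership.

Every generator is deterministic given its seed and returns ground-truth
tables sufficient to score the downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enhancer_models import GENOTYPES, model_mean
from .exceptions import DataError
from .genomic import CATEGORIES
from .io import GenomicInterval
from .ptc_genes import MEMBERSHIP_CLUSTERS


# ---------------------------------------------------------------------------
# expression-by-genotype tables
# ---------------------------------------------------------------------------

def gen_expression_dataset(model: str = "additive",
                           b0: float = 0.2, b1: float = 0.5, b2: float = 0.3,
                           g: float | None = None, sigma: float = 0.05,
                           reps_per_genotype: int = 6,
                           batch_scales: Mapping[str, float] | None = None,
                           seed: int = 0) -> pd.DataFrame:
    """Replicate expression for all four genotypes under one model family.

    Each replicate is ``mu(x1, x2) * batch_scale + N(0, sigma * batch_scale)``,
    so dividing by the batch WT mean recovers the unit-scale model exactly in
    expectation.  Returns a table with columns batch, replicate, x1, x2,
    expression.
    """
    if sigma < 0:
        raise DataError("noise sigma must be non-negative")
    if reps_per_genotype < 1:
        raise DataError("need at least one replicate per genotype")
    if batch_scales is None:
        batch_scales = {"batch1": 1.0}
    rng = np.random.default_rng(seed)
    rows = []
    for batch, scale in batch_scales.items():
        if scale <= 0:
            raise DataError(f"batch scale for {batch!r} must be positive")
        for x1, x2 in GENOTYPES:
            mu = float(model_mean(model, b0, b1, b2, x1, x2, g))
            noise = rng.normal(0.0, sigma * scale, size=reps_per_genotype)
            for rep in range(reps_per_genotype):
                rows.append({"batch": batch, "replicate": f"rep{rep + 1}",
                             "x1": x1, "x2": x2,
                             "expression": mu * scale + noise[rep]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# microscopy image stacks
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStack:
    """A generated 3-channel stack plus its ground truth."""

    dapi: np.ndarray
    fish: np.ndarray
    if_channel: np.ndarray
    nucleus_labels: np.ndarray       # (Z, H, W) int, planted nucleus masks
    nuclei: pd.DataFrame             # id, cz, cy, cx, rz, ry, rx
    spots: pd.DataFrame              # nucleus_id, z, row, col


def _sample_unit_ball(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    return v * rng.uniform() ** (1.0 / 3.0)


def gen_image_stack(shape: tuple[int, int, int] = (9, 512, 512),
                    n_nuclei: int = 20,
                    nucleus_radius: tuple[float, float] = (20.0, 28.0),
                    nucleus_depth: tuple[float, float] = (2.5, 3.5),
                    spots_per_nucleus: int = 2,
                    spot_amplitude: float = 0.5,
                    spot_sigma: float = 1.5,
                    spot_z_sigma: float = 1.0,
                    min_spot_separation: float = 12.0,
                    dapi_level: float = 0.8,
                    if_background: float = 0.25,
                    coloc_amplitude: float = 0.0,
                    coloc_sigma: float = 2.0,
                    background: float = 0.03,
                    noise_sd: float = 0.05,
                    seed: int = 0,
                    max_tries: int = 20000) -> SyntheticStack:
    """Generate a DAPI/FISH/IF stack with planted nuclei and spots.

    Nuclei are non-overlapping ellipsoids with an intensity plateau in
    DAPI; FISH spots are in-plane Gaussians (sigma ``spot_sigma``) with a
    Gaussian z-profile spanning 2-4 slices, placed well inside the
    nucleus; the IF channel is flat background plus, when
    ``coloc_amplitude`` > 0, a Gaussian of that amplitude at every spot
    center.  All channels carry additive Gaussian noise clipped to [0, 1].
    The spot signal-to-noise ratio is ``spot_amplitude / noise_sd``.
    """
    if noise_sd < 0 or spot_amplitude < 0 or coloc_amplitude < 0:
        raise DataError("amplitudes and noise SD must be non-negative")
    nz, h, w = shape
    rng = np.random.default_rng(seed)

    # --- place non-overlapping nuclei -------------------------------------
    placed = []  # (cz, cy, cx, rz, ry, rx)
    tries = 0
    while len(placed) < n_nuclei:
        tries += 1
        if tries > max_tries:
            raise DataError(f"could not place {n_nuclei} non-overlapping nuclei "
                            f"in a {h}x{w} frame after {max_tries} tries")
        rx = rng.uniform(*nucleus_radius)
        ry = rx * rng.uniform(0.85, 1.15)
        rz = rng.uniform(*nucleus_depth)
        margin = max(rx, ry) + 8.0
        if 2 * margin >= min(h, w):
            raise DataError("nucleus radius too large for the frame")
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        cz = (nz - 1) / 2.0 + rng.uniform(-0.5, 0.5)
        # keep a >= 20 px gap so Otsu segmentation after the 31x31 smoothing
        # brush cannot bridge neighbouring nuclei
        r_eff = max(rx, ry)
        if all(np.hypot(cy - p[1], cx - p[2]) > r_eff + max(p[4], p[5]) + 20.0
               for p in placed):
            placed.append((cz, cy, cx, rz, ry, rx))

    labels = np.zeros(shape, dtype=np.int32)
    zz = np.arange(nz)[:, None, None]
    for nid, (cz, cy, cx, rz, ry, rx) in enumerate(placed, start=1):
        y0, y1 = int(cy - ry) - 1, int(cy + ry) + 2
        x0, x1 = int(cx - rx) - 1, int(cx + rx) + 2
        yy = np.arange(y0, y1)[None, :, None]
        xx = np.arange(x0, x1)[None, None, :]
        inside = (((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2
                  + ((xx - cx) / rx) ** 2) <= 1.0
        sub = labels[:, y0:y1, x0:x1]
        sub[inside] = nid
    nuclei = pd.DataFrame(placed, columns=["cz", "cy", "cx", "rz", "ry", "rx"])
    nuclei.insert(0, "id", np.arange(1, len(placed) + 1))

    # --- plant FISH spots well inside each nucleus ------------------------
    spot_rows = []
    for nid, (cz, cy, cx, rz, ry, rx) in enumerate(placed, start=1):
        centers_here: list[tuple[int, int]] = []
        for _ in range(spots_per_nucleus):
            for _try in range(200):
                u = _sample_unit_ball(rng)
                z = int(round(cz + u[0] * 0.5 * rz))
                r = int(round(cy + u[1] * 0.6 * ry))
                c = int(round(cx + u[2] * 0.6 * rx))
                if not (0 <= z < nz and labels[z, r, c] == nid):
                    continue
                if all(np.hypot(r - pr, c - pc) >= min_spot_separation
                       for pr, pc in centers_here):
                    centers_here.append((r, c))
                    spot_rows.append({"nucleus_id": nid, "z": z, "row": r, "col": c})
                    break
            else:
                raise DataError("could not place a spot inside nucleus "
                                f"{nid}; relax the separation or radius settings")
    spots = pd.DataFrame(spot_rows)

    # --- render channels ---------------------------------------------------
    dapi = background + dapi_level * (labels > 0)
    fish = np.full(shape, background)
    ifc = np.full(shape, if_background)

    def add_gaussians(channel: np.ndarray, amplitude: float, sig: float) -> None:
        if amplitude <= 0:
            return
        reach = int(np.ceil(4 * sig))
        for _, s in spots.iterrows():
            z0, r0, c0 = int(s["z"]), int(s["row"]), int(s["col"])
            rlo, rhi = max(r0 - reach, 0), min(r0 + reach + 1, h)
            clo, chi = max(c0 - reach, 0), min(c0 + reach + 1, w)
            yy = np.arange(rlo, rhi)[:, None]
            xx = np.arange(clo, chi)[None, :]
            plane = np.exp(-((yy - r0) ** 2 + (xx - c0) ** 2) / (2 * sig ** 2))
            for z in range(max(z0 - 2, 0), min(z0 + 3, nz)):
                zfac = np.exp(-((z - z0) ** 2) / (2 * spot_z_sigma ** 2))
                channel[z, rlo:rhi, clo:chi] += amplitude * zfac * plane

    add_gaussians(fish, spot_amplitude, spot_sigma)
    add_gaussians(ifc, coloc_amplitude, coloc_sigma)

    if noise_sd > 0:
        dapi = dapi + rng.normal(0.0, noise_sd, size=shape)
        fish = fish + rng.normal(0.0, noise_sd, size=shape)
        ifc = ifc + rng.normal(0.0, noise_sd, size=shape)
    return SyntheticStack(dapi=np.clip(dapi, 0.0, 1.0), fish=np.clip(fish, 0.0, 1.0),
                          if_channel=np.clip(ifc, 0.0, 1.0), nucleus_labels=labels,
                          nuclei=nuclei, spots=spots)


# ---------------------------------------------------------------------------
# toy genomes
# ---------------------------------------------------------------------------

DEFAULT_CHROM_LENGTHS = {"chr1": 10_000_000, "chr2": 10_000_000, "chr3": 10_000_000}

#: default category mixing proportions (PTC, very_active, moderately_active,
#: inactive): the genome fractions reported for the transdifferentiation system
DEFAULT_MIXING = (0.055, 0.025, 0.178, 0.742)


@dataclass
class GenomeFixture:
    """A toy genome with planted structure and its ground truth."""

    chrom_lengths: dict[str, int]
    segments: pd.DataFrame          # chrom, start, end, p, log2fc, hub, category
    snps: pd.DataFrame              # chrom, pos
    tf_edges: pd.DataFrame          # tf, target
    genes: pd.DataFrame             # gene, chrom, tss, strand, category, focal_shifted
    tissue_expression: pd.DataFrame  # genes x tissues
    focal_tissue: str
    snp_category: str
    snp_density_ratio: float
    tf_bias: float
    tf_bias_category: str

    def category_intervals(self, category: str) -> list[GenomicInterval]:
        sel = self.segments[self.segments["category"] == category]
        return [GenomicInterval(c, int(s), int(e))
                for c, s, e in zip(sel["chrom"], sel["start"], sel["end"])]


def _draw_segment_scores(category: str, rng: np.random.Generator) -> tuple[float, float, int]:
    """(p, log2fc, hub) consistent with one category's classification rule."""
    if category == "PTC":
        return rng.uniform(1e-6, 0.05), rng.uniform(0.0, 2.0), 1
    if category == "very_active":
        return rng.uniform(1e-6, 0.05), rng.uniform(0.0, 2.0), 0
    if category == "moderately_active":
        return rng.uniform(0.05 + 1e-9, 1.0), rng.uniform(0.0, 2.0), 0
    if category == "inactive":
        return rng.uniform(0.05 + 1e-9, 1.0), rng.uniform(-2.0, -1e-6), 0
    raise DataError(f"unknown category {category!r}")


def gen_genome_fixture(chrom_lengths: Mapping[str, int] | None = None,
                       n_segments: int = 200,
                       mixing: Sequence[float] = DEFAULT_MIXING,
                       n_snps: int = 1000,
                       snp_density_ratio: float = 1.0,
                       snp_category: str = "PTC",
                       n_tfs: int = 50,
                       targets_per_tf: int = 50,
                       tf_bias: float = 1.0,
                       tf_bias_category: str = "PTC",
                       n_genes: int = 1000,
                       n_tissues: int = 8,
                       focal_tissue: str = "blood",
                       n_focal_shifted: int = 100,
                       focal_shift: float = 4.0,
                       seed: int = 0) -> GenomeFixture:
    """Generate a toy genome with four-category segments and planted signals.

    ``snp_density_ratio`` r plants SNPs so the expected per-bp SNP density
    inside ``snp_category`` segments is r times the genome-wide average
    density (requires r * coverage <= 1); r = 1 is the uniform null with
    ground-truth enrichment 1.  ``tf_bias`` multiplies the sampling weight
    of genes in ``tf_bias_category`` when drawing TF targets (1 = unbiased,
    ground-truth enrichment 1).  ``n_focal_shifted`` genes get their
    ``focal_tissue`` expression multiplied by ``focal_shift``.
    """
    if chrom_lengths is None:
        chrom_lengths = dict(DEFAULT_CHROM_LENGTHS)
    mixing = np.asarray(mixing, dtype=float)
    if mixing.size != len(CATEGORIES) or np.any(mixing < 0):
        raise DataError("mixing must give one non-negative proportion per category")
    if not np.isclose(mixing.sum(), 1.0):
        raise DataError(f"mixing proportions must sum to 1, got {mixing.sum()}")
    if snp_density_ratio < 0:
        raise DataError("SNP density ratio must be non-negative")
    rng = np.random.default_rng(seed)

    # --- segments tiling the genome ---------------------------------------
    total_len = sum(chrom_lengths.values())
    seg_rows = []
    for chrom, length in chrom_lengths.items():
        n_seg = max(1, round(n_segments * length / total_len))
        cuts = np.sort(rng.choice(np.arange(1, length), size=n_seg - 1, replace=False)) \
            if n_seg > 1 else np.array([], dtype=int)
        bounds = np.concatenate([[0], cuts, [length]])
        for s, e in zip(bounds[:-1], bounds[1:]):
            cat = CATEGORIES[rng.choice(len(CATEGORIES), p=mixing)]
            p, fc, hub = _draw_segment_scores(cat, rng)
            seg_rows.append({"chrom": chrom, "start": int(s), "end": int(e),
                             "p": p, "log2fc": fc, "hub": hub, "category": cat})
    segments = pd.DataFrame(seg_rows)

    # --- SNPs with a planted density inside one category ------------------
    target = segments[segments["category"] == snp_category]
    cov = int((target["end"] - target["start"]).sum())
    coverage = cov / total_len
    p_inside = snp_density_ratio * coverage
    if p_inside > 1.0:
        raise DataError(f"density ratio {snp_density_ratio} with coverage "
                        f"{coverage:.3f} implies an inside probability > 1")
    snp_rows = []
    t_starts = target["start"].to_numpy()
    t_lens = (target["end"] - target["start"]).to_numpy()
    t_chroms = target["chrom"].to_numpy()
    other = segments[segments["category"] != snp_category]
    o_starts = other["start"].to_numpy()
    o_lens = (other["end"] - other["start"]).to_numpy()
    o_chroms = other["chrom"].to_numpy()

    def _uniform_in(starts, lens, chroms):
        offs = rng.integers(0, lens.sum())
        cum = np.cumsum(lens)
        i = int(np.searchsorted(cum, offs, side="right"))
        return chroms[i], int(starts[i] + offs - (cum[i - 1] if i else 0))

    for _ in range(n_snps):
        if cov > 0 and rng.uniform() < p_inside:
            chrom, pos = _uniform_in(t_starts, t_lens, t_chroms)
        else:
            chrom, pos = _uniform_in(o_starts, o_lens, o_chroms)
        snp_rows.append({"chrom": chrom, "pos": pos})
    snps = pd.DataFrame(snp_rows)

    # --- genes assigned to categories by position -------------------------
    gene_rows = []
    seg_by_chrom = {c: g.sort_values("start") for c, g in segments.groupby("chrom")}
    chrom_names = list(chrom_lengths)
    chrom_w = np.array([chrom_lengths[c] for c in chrom_names], dtype=float)
    for i in range(n_genes):
        ci = rng.choice(len(chrom_names), p=chrom_w / chrom_w.sum())
        chrom = chrom_names[ci]
        tss = int(rng.integers(0, chrom_lengths[chrom]))
        segs = seg_by_chrom[chrom]
        j = int(np.searchsorted(segs["start"].to_numpy(), tss, side="right")) - 1
        gene_rows.append({"gene": f"g{i:04d}", "chrom": chrom, "tss": tss,
                          "strand": "+" if rng.uniform() < 0.5 else "-",
                          "category": segs.iloc[j]["category"]})
    genes = pd.DataFrame(gene_rows)
    shifted_idx = rng.choice(n_genes, size=min(n_focal_shifted, n_genes), replace=False)
    genes["focal_shifted"] = False
    genes.loc[shifted_idx, "focal_shifted"] = True

    # --- TF-target network with optional category bias --------------------
    weights = np.where(genes["category"] == tf_bias_category, tf_bias, 1.0)
    weights = weights / weights.sum()
    edge_rows = []
    for t in range(n_tfs):
        targets = rng.choice(n_genes, size=min(targets_per_tf, n_genes),
                             replace=False, p=weights)
        for gi in targets:
            edge_rows.append({"tf": f"tf{t:03d}", "target": genes.iloc[gi]["gene"]})
    tf_edges = pd.DataFrame(edge_rows)

    # --- tissue expression with a focal shift ------------------------------
    tissues = [focal_tissue] + [f"tissue{k}" for k in range(1, n_tissues)]
    base = rng.lognormal(mean=2.0, sigma=1.0, size=n_genes)
    expr = base[:, None] * rng.lognormal(mean=0.0, sigma=0.3,
                                         size=(n_genes, n_tissues))
    expr[genes["focal_shifted"].to_numpy(), 0] *= focal_shift
    tissue_expression = pd.DataFrame(expr, index=genes["gene"], columns=tissues)

    return GenomeFixture(chrom_lengths=dict(chrom_lengths), segments=segments,
                         snps=snps, tf_edges=tf_edges, genes=genes,
                         tissue_expression=tissue_expression,
                         focal_tissue=focal_tissue, snp_category=snp_category,
                         snp_density_ratio=snp_density_ratio, tf_bias=tf_bias,
                         tf_bias_category=tf_bias_category)


# ---------------------------------------------------------------------------
# PTC gene-filtering fixtures
# ---------------------------------------------------------------------------

@dataclass
class PtcGeneFixture:
    """Gene annotation + peaks + expression with known filter outcomes."""

    genes: pd.DataFrame           # annotation, TPMs, counts, membership flags
    peaks: list[GenomicInterval]
    expected_kept: set[str]       # genes passing all four filters, by construction
    expected_clusters: dict[str, str]


def gen_ptc_gene_fixture(n_genes: int = 300,
                         chrom_lengths: Mapping[str, int] | None = None,
                         frac_protein_coding: float = 0.8,
                         frac_expressed: float = 0.8,
                         frac_with_peak: float = 0.8,
                         frac_member: float = 0.85,
                         peak_window: int = 1000,
                         seed: int = 0) -> PtcGeneFixture:
    """Random gene annotations where every filter outcome is planted.

    Each gene independently draws its biotype, whether its mean TPM clears
    the > 1 cutoff, whether an H3K27ac peak is planted near (inside the
    +/-window) or far from its TSS, and its per-timepoint PTC membership
    flags; the expected post-filter gene set and cluster labels follow from
    those draws.
    """
    if chrom_lengths is None:
        chrom_lengths = dict(DEFAULT_CHROM_LENGTHS)
    rng = np.random.default_rng(seed)
    chroms = list(chrom_lengths)
    flag_keys = list(MEMBERSHIP_CLUSTERS)
    rows, peaks = [], []
    expected, clusters = set(), {}
    # TSSs sit on a coarse grid so one gene's planted peak can never fall
    # inside another gene's promoter window
    spacing = 20 * peak_window
    per_chrom = int(np.ceil(n_genes / len(chroms)))
    for c in chroms:
        if per_chrom * spacing + 2 * peak_window >= chrom_lengths[c]:
            raise DataError("too many genes for the chromosome lengths given")
    for i in range(n_genes):
        gene = f"g{i:04d}"
        chrom = chroms[i % len(chroms)]
        tss = (peak_window + 10 + (i // len(chroms)) * spacing
               + int(rng.integers(-peak_window, peak_window)))
        coding = rng.uniform() < frac_protein_coding
        expressed = rng.uniform() < frac_expressed
        tpm = rng.uniform(1.5, 50.0, size=3) if expressed else rng.uniform(0.0, 0.9, size=3)
        member = rng.uniform() < frac_member
        flags = flag_keys[rng.integers(0, len(flag_keys))] if member else (0, 0, 0)
        with_peak = rng.uniform() < frac_with_peak
        if with_peak:
            off = int(rng.integers(-peak_window, peak_window + 1))
            start = max(tss + off, 0)
            peaks.append(GenomicInterval(chrom, start, start + 200))
        counts = rng.uniform(5.0, 15.0, size=3)
        rows.append({
            "gene": gene, "biotype": "protein_coding" if coding else "lncRNA",
            "chrom": chrom, "tss": tss, "strand": "+",
            "tpm_d0": tpm[0], "tpm_d1": tpm[1], "tpm_d7": tpm[2],
            "count_d0": counts[0], "count_d1": counts[1], "count_d7": counts[2],
            "ptc_d0": flags[0], "ptc_d1": flags[1], "ptc_d7": flags[2],
        })
        if coding and expressed and with_peak and member:
            expected.add(gene)
            clusters[gene] = MEMBERSHIP_CLUSTERS[flags]
    return PtcGeneFixture(genes=pd.DataFrame(rows), peaks=peaks,
                          expected_kept=expected, expected_clusters=clusters)
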