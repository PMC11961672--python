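"""DNA-FISH / immunofluorescence colocalization pipeline.

Quantifies whether an IF-stained factor (e.g. the condensate component
BRD4) is enriched at a genomic locus labelled by DNA-FISH, from 3-channel
confocal z-stacks (DAPI / FISH / IF):

1.  nuclei are segmented per slice from the DAPI channel (31x31 Gaussian
    smoothing with sigma 5, Otsu threshold, hole filling);
2.  FISH spots are detected per slice (9x9 Gaussian smoothing with
    sigma 5, fixed intensity cutoff); spots with any pixel outside a
    nucleus are discarded, and nuclei without spots are dropped;
3.  spot centers are refined to the brightest FISH pixel of the region;
4.  nuclei and spots are stitched in 3D (objects on adjacent slices merge
    when their 2D footprints share at least one pixel) so each physical
    spot carries one identifier and is counted once;
5.  50 random centers per nucleus (sampled uniformly with replacement
    from its voxels) provide the background null;
6.  an 11x11 IF-intensity window is read out around every genuine and
    random center; positions outside the nuclear volume or the image are
    zeroed and flagged invalid; per-spot windows are averaged over the
    slices the spot spans;
7.  per-position medians over genuine and random centers give an
    enrichment-ratio map, and FISH/IF pixel pairs from the windows give a
    percentile-binned intensity profile whose monotone association is
    scored by Spearman correlation with a permutation p-value.

All intensities are assumed scaled to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, stats
from skimage.filters import threshold_otsu

from .exceptions import DataError

WINDOW_SIZE = 11

#: 3D connectivity used for stitching: 8-connectivity within a slice, and
#: adjacent slices connected only through the same (row, col) pixel, i.e.
#: objects merge across z iff their 2D footprints overlap by >= 1 pixel.
_STITCH_STRUCTURE = np.array([
    [[0, 0, 0], [0, 1, 0], [0, 0, 0]],
    [[1, 1, 1], [1, 1, 1], [1, 1, 1]],
    [[0, 0, 0], [0, 1, 0], [0, 0, 0]],
], dtype=bool)


def gaussian_brush(image: np.ndarray, size: int, sigma: float) -> np.ndarray:
    """Smooth with a size-by-size truncated, normalised Gaussian kernel.

    The kernel is separable, so this is the outer product of two 1-D
    truncated gaussians of half-width ``size // 2``.
    """
    radius = size // 2
    return ndimage.gaussian_filter(np.asarray(image, dtype=float), sigma=sigma,
                                   truncate=radius / sigma, mode="reflect")


def segment_nuclei_slice(dapi_slice: np.ndarray, size: int = 31,
                         sigma: float = 5.0) -> np.ndarray:
    """Binary nucleus mask for one DAPI slice (smooth, Otsu, fill holes)."""
    img = np.asarray(dapi_slice, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise DataError("expected a nonempty 2D DAPI slice")
    smoothed = gaussian_brush(img, size, sigma)
    if np.ptp(smoothed) == 0:
        warnings.warn("constant DAPI slice: Otsu threshold undefined, empty mask")
        return np.zeros_like(smoothed, dtype=bool)
    mask = smoothed > threshold_otsu(smoothed)
    return ndimage.binary_fill_holes(mask)


def segment_nuclei_stack(dapi_stack: np.ndarray, size: int = 31,
                         sigma: float = 5.0) -> np.ndarray:
    """Per-slice smoothed, stack-globally Otsu-thresholded nucleus masks.

    A single Otsu threshold over the whole smoothed stack keeps slices
    that contain no nuclei (top and bottom of the z-range) empty, which a
    per-slice threshold cannot guarantee.  Holes are filled per slice.
    """
    stack = np.asarray(dapi_stack, dtype=float)
    if stack.ndim != 3:
        raise DataError("expected a (Z, H, W) DAPI stack")
    smoothed = np.stack([gaussian_brush(s, size, sigma) for s in stack])
    if np.ptp(smoothed) == 0:
        warnings.warn("constant DAPI stack: Otsu threshold undefined, empty mask")
        return np.zeros_like(smoothed, dtype=bool)
    mask = smoothed > threshold_otsu(smoothed)
    return np.stack([ndimage.binary_fill_holes(m) for m in mask])


def detect_spots_slice(fish_slice: np.ndarray, threshold: float,
                       nuclei_mask: np.ndarray, size: int = 9,
                       sigma: float = 5.0) -> np.ndarray:
    """Labelled FISH spot regions of one slice, restricted to nuclei.

    Connected components of the smoothed channel above ``threshold`` are
    labelled (8-connectivity); any component with a pixel outside the
    nucleus mask is discarded entirely.
    """
    if not 0.0 < threshold <= 1.0:
        raise DataError(f"spot threshold must lie in (0, 1], got {threshold}")
    img = np.asarray(fish_slice, dtype=float)
    if img.shape != np.asarray(nuclei_mask).shape:
        raise DataError("FISH slice and nucleus mask shapes differ")
    smoothed = gaussian_brush(img, size, sigma)
    binary = smoothed > threshold
    labels, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        return labels
    outside = np.unique(labels[~np.asarray(nuclei_mask, dtype=bool)])
    keep = np.setdiff1d(np.arange(1, n + 1), outside)
    lut = np.zeros(n + 1, dtype=np.int32)
    lut[keep] = np.arange(1, keep.size + 1)
    return lut[labels]


def default_spot_threshold(fish_stack: np.ndarray, size: int = 9,
                           sigma: float = 5.0, n_sd: float = 6.0) -> float:
    """Stand-in for a manually picked cutoff: mean + n_sd * SD of the smoothed channel."""
    smoothed = np.stack([gaussian_brush(s, size, sigma) for s in fish_stack])
    return float(min(smoothed.mean() + n_sd * smoothed.std(), 1.0))


def refine_center(region_mask: np.ndarray, fish_slice: np.ndarray) -> tuple[int, int]:
    """Brightest FISH pixel of a spot region; ties broken lexicographically.

    The moment centroid is computed first and then shifted to the hottest
    pixel, so the returned center is always a pixel of the region.
    """
    coords = np.argwhere(region_mask)
    if coords.size == 0:
        raise DataError("empty spot region")
    # moment centroid (intermediate; the final center is the brightest pixel)
    _centroid = coords.mean(axis=0)
    values = fish_slice[coords[:, 0], coords[:, 1]]
    hottest = coords[values == values.max()]
    idx = np.lexsort((hottest[:, 1], hottest[:, 0]))[0]
    return int(hottest[idx, 0]), int(hottest[idx, 1])


@dataclass
class NucleusVolume:
    """A 3D-stitched nucleus: per-slice masks aggregated into one labelled volume."""

    id: int
    voxels: np.ndarray  # (n, 3) int array of (z, row, col)
    border_contact: bool = False

    @property
    def voxel_count(self) -> int:
        return self.voxels.shape[0]

    @property
    def bounding_box(self) -> tuple[tuple[int, int], ...]:
        lo = self.voxels.min(axis=0)
        hi = self.voxels.max(axis=0)
        return tuple((int(a), int(b) + 1) for a, b in zip(lo, hi))


@dataclass
class FishSpot:
    """One physical FISH spot spanning one or more slices of a nucleus."""

    id: int
    nucleus_id: int
    centers: list[tuple[int, int, int]]  # (z, row, col) per slice
    center_values: list[float] = field(default_factory=list)

    @property
    def z_range(self) -> tuple[int, int]:
        zs = [c[0] for c in self.centers]
        return min(zs), max(zs)

    @property
    def representative_center(self) -> tuple[int, int, int]:
        """Center on the spot's brightest slice."""
        i = int(np.argmax(self.center_values)) if self.center_values else 0
        return self.centers[i]


def stitch_volumes(mask_stack: np.ndarray) -> np.ndarray:
    """3D labelling of per-slice binary masks under the footprint-overlap rule."""
    labels, _ = ndimage.label(np.asarray(mask_stack, dtype=bool),
                              structure=_STITCH_STRUCTURE)
    return labels


def allocate_random_centers(nucleus: NucleusVolume, n: int = 50,
                            seed: int | np.random.Generator = 0) -> np.ndarray:
    """Sample n voxels uniformly with replacement from the nucleus volume."""
    if nucleus.voxel_count == 0:
        raise DataError(f"nucleus {nucleus.id} has no voxels")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, nucleus.voxel_count, size=n)
    return nucleus.voxels[idx]


@dataclass
class WindowMatrix:
    """11x11 intensity window around a center with per-position validity flags.

    Positions outside the nuclear volume or the image carry value 0 and
    flag 0 and are excluded from every downstream aggregate.
    """

    values: np.ndarray
    valid: np.ndarray


def extract_window(image_slice: np.ndarray, center: tuple[int, int],
                   valid_mask: np.ndarray, size: int = WINDOW_SIZE) -> WindowMatrix:
    """Read a size-by-size window centred on ``center`` from one slice.

    ``valid_mask`` is the nucleus footprint on this slice; entries outside
    it (or outside the image) are zeroed and flagged invalid.
    """
    half = size // 2
    h, w = image_slice.shape
    r0, c0 = center
    values = np.zeros((size, size), dtype=float)
    valid = np.zeros((size, size), dtype=bool)
    rr, cc = np.meshgrid(np.arange(r0 - half, r0 + half + 1),
                         np.arange(c0 - half, c0 + half + 1), indexing="ij")
    inside = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    ri, ci = rr[inside], cc[inside]
    ok = np.asarray(valid_mask, dtype=bool)[ri, ci]
    valid[inside] = ok
    vals = np.zeros(ri.shape, dtype=float)
    vals[ok] = np.asarray(image_slice, dtype=float)[ri[ok], ci[ok]]
    values[inside] = vals
    return WindowMatrix(values=values, valid=valid)


def average_windows(windows: Sequence[WindowMatrix]) -> WindowMatrix:
    """Valid-entry-wise mean of a spot's per-slice windows."""
    vals = np.stack([w.values for w in windows])
    valid = np.stack([w.valid for w in windows])
    counts = valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, (vals * valid).sum(axis=0) / np.maximum(counts, 1), 0.0)
    return WindowMatrix(values=mean, valid=counts > 0)


@dataclass
class EnrichmentMap:
    """Median IF window over genuine spots, over random centers, and their ratio.

    Positions with no valid observation are NaN.
    """

    real_median: np.ndarray
    random_median: np.ndarray

    @property
    def ratio(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            r = self.real_median / self.random_median
        r[~np.isfinite(r)] = np.nan
        return r

    def central_ratio(self, radius: int = 1) -> float:
        """Mean enrichment ratio over the central (2*radius+1)^2 positions."""
        half = self.real_median.shape[0] // 2
        sub = self.ratio[half - radius:half + radius + 1,
                         half - radius:half + radius + 1]
        return float(np.nanmean(sub))


def _positionwise_median(windows: Sequence[WindowMatrix]) -> np.ndarray:
    vals = np.stack([w.values for w in windows])
    valid = np.stack([w.valid for w in windows])
    masked = np.where(valid, vals, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN positions
        return np.nanmedian(masked, axis=0)


def aggregate_enrichment(spot_windows: Sequence[WindowMatrix],
                         random_windows: Sequence[WindowMatrix]) -> EnrichmentMap:
    """Per-position medians over genuine spots and random centers."""
    if not spot_windows or not random_windows:
        raise DataError("need at least one genuine and one random window")
    return EnrichmentMap(real_median=_positionwise_median(spot_windows),
                         random_median=_positionwise_median(random_windows))


@dataclass
class BinnedProfile:
    """Percentile-binned FISH-vs-IF intensity profile with a permutation test."""

    bin_medians: np.ndarray
    bin_index: np.ndarray
    spearman_rho: float
    p_value: float
    n_pixels: int


def binned_intensity_profile(fish_values: np.ndarray, if_values: np.ndarray,
                             n_bins: int = 20, n_perm: int = 10000,
                             seed: int = 0) -> BinnedProfile:
    """Median IF per FISH-intensity percentile bin, plus a monotone-association test.

    FISH intensities are split into ``n_bins`` quantile (5%-percentile)
    bins; the association statistic is the Spearman correlation of the
    (bin index, median IF) pairs, with a p-value from ``n_perm`` seeded
    permutations of the IF values against the FISH values.
    """
    fish = np.asarray(fish_values, dtype=float).ravel()
    ifv = np.asarray(if_values, dtype=float).ravel()
    if fish.size != ifv.size:
        raise DataError("FISH and IF pixel vectors differ in length")
    if fish.size < n_bins:
        raise DataError(f"need at least {n_bins} pixel pairs, got {fish.size}")
    if np.ptp(fish) == 0:
        raise DataError("all FISH values identical: percentile binning is degenerate")
    edges = np.quantile(fish, np.linspace(0.0, 1.0, n_bins + 1))
    bins = np.clip(np.searchsorted(edges, fish, side="right") - 1, 0, n_bins - 1)
    groups = [np.flatnonzero(bins == b) for b in range(n_bins)]
    occupied = [b for b in range(n_bins) if groups[b].size]
    if len(occupied) < 3:
        raise DataError("fewer than 3 occupied FISH-intensity bins; profile degenerate")

    def medians(values: np.ndarray) -> np.ndarray:
        return np.array([np.median(values[groups[b]]) for b in occupied])

    obs_med = medians(ifv)
    rho = float(stats.spearmanr(occupied, obs_med).statistic)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(ifv)
        r = stats.spearmanr(occupied, medians(perm)).statistic
        if abs(r) >= abs(rho) - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    full_medians = np.full(n_bins, np.nan)
    full_medians[occupied] = obs_med
    return BinnedProfile(bin_medians=full_medians, bin_index=np.arange(n_bins),
                         spearman_rho=rho, p_value=float(p), n_pixels=fish.size)


@dataclass
class ColocalizationResult:
    """Everything the pipeline produces for one 3-channel stack."""

    threshold: float
    nuclei: list[NucleusVolume]
    spots: list[FishSpot]
    spot_windows: list[WindowMatrix]
    random_windows: list[WindowMatrix]
    enrichment: EnrichmentMap
    profile: BinnedProfile | None

    def summary(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_nuclei": len(self.nuclei),
            "n_spots": len(self.spots),
            "central_enrichment_ratio": self.enrichment.central_ratio(),
            "spearman_rho": None if self.profile is None else self.profile.spearman_rho,
            "p_value": None if self.profile is None else self.profile.p_value,
        }


def analyze_stack(dapi: np.ndarray, fish: np.ndarray, if_channel: np.ndarray,
                  threshold: float | None = None, n_random: int = 50,
                  seed: int = 0, n_perm: int = 10000,
                  compute_profile: bool = True) -> ColocalizationResult:
    """Run the full pipeline (steps 1-7 of the module docstring) on one stack."""
    dapi = np.asarray(dapi, dtype=float)
    fish = np.asarray(fish, dtype=float)
    ifc = np.asarray(if_channel, dtype=float)
    if not dapi.shape == fish.shape == ifc.shape or dapi.ndim != 3:
        raise DataError("DAPI, FISH and IF stacks must share one (Z, H, W) shape")

    nuc_masks = segment_nuclei_stack(dapi)
    if threshold is None:
        threshold = default_spot_threshold(fish)
    spot_slices = np.stack([detect_spots_slice(fish[z], threshold, nuc_masks[z])
                            for z in range(fish.shape[0])])

    nuc_labels = stitch_volumes(nuc_masks)
    spot_labels = stitch_volumes(spot_slices > 0)
    n_spots = int(spot_labels.max())

    spots: list[FishSpot] = []
    for sid in range(1, n_spots + 1):
        centers, values = [], []
        zs = np.unique(np.nonzero(spot_labels == sid)[0])
        for z in zs:
            region = spot_labels[z] == sid
            r, c = refine_center(region, fish[z])
            centers.append((int(z), r, c))
            values.append(float(fish[z, r, c]))
        z0, r0, c0 = centers[int(np.argmax(values))]
        nucleus_id = int(nuc_labels[z0, r0, c0])
        spots.append(FishSpot(id=sid, nucleus_id=nucleus_id, centers=centers,
                              center_values=values))

    kept_nuc_ids = sorted({s.nucleus_id for s in spots if s.nucleus_id > 0})
    spots = [s for s in spots if s.nucleus_id > 0]
    nz, nh, nw = nuc_labels.shape
    nuclei = []
    for nid in kept_nuc_ids:
        voxels = np.argwhere(nuc_labels == nid)
        border = bool((voxels[:, 1].min() == 0) or (voxels[:, 2].min() == 0)
                      or (voxels[:, 1].max() == nh - 1) or (voxels[:, 2].max() == nw - 1))
        nuclei.append(NucleusVolume(id=nid, voxels=voxels, border_contact=border))

    # step 5-6: windows around genuine centers (averaged per spot) and random centers
    spot_if_windows, spot_fish_windows = [], []
    for s in spots:
        per_slice_if, per_slice_fish = [], []
        valid3d = nuc_labels == s.nucleus_id
        for z, r, c in s.centers:
            per_slice_if.append(extract_window(ifc[z], (r, c), valid3d[z]))
            per_slice_fish.append(extract_window(fish[z], (r, c), valid3d[z]))
        spot_if_windows.append(average_windows(per_slice_if))
        spot_fish_windows.append(average_windows(per_slice_fish))

    rng = np.random.default_rng(seed)
    random_windows = []
    for nuc in nuclei:
        valid3d = nuc_labels == nuc.id
        for z, r, c in allocate_random_centers(nuc, n=n_random, seed=rng):
            random_windows.append(extract_window(ifc[z], (r, c), valid3d[z]))

    enrichment = aggregate_enrichment(spot_if_windows, random_windows)

    fish_px, if_px = [], []
    for wf, wi in zip(spot_fish_windows, spot_if_windows):
        both = wf.valid & wi.valid
        fish_px.append(wf.values[both])
        if_px.append(wi.values[both])
    fish_px = np.concatenate(fish_px) if fish_px else np.empty(0)
    if_px = np.concatenate(if_px) if if_px else np.empty(0)
    profile = None
    if compute_profile and fish_px.size >= 20 and np.ptp(fish_px) > 0:
        profile = binned_intensity_profile(fish_px, if_px, n_perm=n_perm,
                                           seed=int(rng.integers(0, 2**31 - 1)))
    return ColocalizationResult(threshold=float(threshold), nuclei=nuclei, spots=spots,
                                spot_windows=spot_if_windows,
                                random_windows=random_windows,
                                enrichment=enrichment, profile=profile)
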