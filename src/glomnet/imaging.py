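"""Glomerulus segmentation and intensity measurement on two-channel images.

Glomeruli appear in granule-cell-layer images as clusters of membrane
(Kv4.2-like) signal surrounding dark central voids, with mossy-fiber
terminal (vGLUT/vGAT-like) signal filling the cluster.  Segmentation
follows a marker-based watershed recipe: (1) sum the two structural
channels and threshold to delimit glomerulus cluster areas; (2) detect the
central voids of the membrane channel with an H-minima transform plus size
filtering; (3) flood the cluster area from the void markers with a
watershed.  Regions flagged in an exclusion list are removed (never added)
for reproducible manual curation.  Per-region tdT/GFP intensities are
normalized by the per-image medians so tables feed the ratio-dispersion
statistics directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.optimize import curve_fit
from scipy.signal import wiener
from skimage import exposure, filters, measure, morphology, segmentation, util


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable segmentation parameters.

    wiener_size : Wiener-filter window (px).
    clahe_clip, clahe_kernel : CLAHE clip limit and tile size (px).
    threshold : scalar threshold on the summed image in [0, 1]; ``None``
        selects an Otsu threshold automatically.
    h_minima : depth of the H-minima transform on the membrane channel
        (fraction of the intensity range), controlling void detection.
    min_marker_area, max_marker_area : size filter (px) on candidate void
        markers.
    min_region_area : regions smaller than this are dropped and reported in
        ``excluded``.
    smooth_sigma : Gaussian pre-smoothing of the membrane channel before the
        H-minima transform (px).
    """

    wiener_size: int = 5
    clahe_clip: float = 0.01
    clahe_kernel: int | None = None
    threshold: float | None = None
    h_minima: float = 0.15
    min_marker_area: int = 1
    max_marker_area: int = 2000
    min_region_area: int = 30
    smooth_sigma: float = 2.0


@dataclass(frozen=True)
class Region:
    region_id: int
    area: int
    centroid: tuple[float, float]


@dataclass(frozen=True)
class SegmentationResult:
    """Integer label image (0 = background) plus per-region bookkeeping."""

    label_image: np.ndarray
    regions: list[Region]
    excluded: list[int] = field(default_factory=list)

    @property
    def n_regions(self) -> int:
        return len(self.regions)


def preprocess(image: np.ndarray, params: SegmentationParams | None = None) -> np.ndarray:
    """Denoise (Wiener) and locally equalize contrast (CLAHE).

    Returns a float image in [0, 1] with the input's shape.
    """
    params = params or SegmentationParams()
    image = np.asarray(image, dtype=float)
    if image.size == 0 or image.ndim != 2:
        raise ValueError("expected a non-empty 2-D single-channel image")
    if np.ptp(image) == 0:  # constant input: nothing to denoise or equalize
        return np.zeros_like(image)
    with np.errstate(invalid="ignore", divide="ignore"):
        den = wiener(image, mysize=params.wiener_size)
    # zero-variance windows yield NaN; fall back to the raw pixel there
    den = np.where(np.isfinite(den), den, image)
    den = np.clip(den, 0, None)
    rng_ = den.max() - den.min()
    if rng_ == 0:
        return np.zeros_like(den)
    den = (den - den.min()) / rng_
    return exposure.equalize_adapthist(
        den, kernel_size=params.clahe_kernel, clip_limit=params.clahe_clip
    )


def segment_glomeruli(
    membrane_channel: np.ndarray,
    terminal_channel: np.ndarray,
    params: SegmentationParams | None = None,
    exclusions: list[int] | None = None,
) -> SegmentationResult:
    """Marker-based watershed segmentation of glomeruli.

    ``membrane_channel`` and ``terminal_channel`` must be preprocessed,
    same-shape 2-D float images.  See the module docstring for the recipe.
    ``exclusions`` lists region ids to drop from the result (reproducible
    manual removal); regions are never added by hand.
    """
    params = params or SegmentationParams()
    mem = np.asarray(membrane_channel, dtype=float)
    term = np.asarray(terminal_channel, dtype=float)
    if mem.shape != term.shape or mem.ndim != 2:
        raise ValueError("channels must be equal-shape 2-D images")

    summed = mem + term
    thr = params.threshold
    if thr is None:
        thr = float(filters.threshold_otsu(summed))
    cluster_area = summed > thr
    cluster_area = morphology.remove_small_holes(cluster_area, max_size=64)
    cluster_area = morphology.remove_small_objects(cluster_area, max_size=params.min_region_area)

    if not cluster_area.any():
        return SegmentationResult(np.zeros(mem.shape, dtype=np.int32), [], [])

    # void detection: minima of the smoothed membrane channel within clusters
    smooth = ndi.gaussian_filter(mem, params.smooth_sigma)
    rng_ = smooth.max() - smooth.min()
    h = params.h_minima * (rng_ if rng_ > 0 else 1.0)
    minima = morphology.h_minima(smooth, h)
    minima &= cluster_area
    markers, _ = ndi.label(minima)
    # size-filter candidate markers
    sizes = np.bincount(markers.ravel())
    bad = (sizes < params.min_marker_area) | (sizes > params.max_marker_area)
    bad[0] = True
    markers[bad[markers]] = 0
    markers, n_markers = ndi.label(markers > 0)
    if n_markers == 0:
        return SegmentationResult(np.zeros(mem.shape, dtype=np.int32), [], [])

    labels = segmentation.watershed(smooth, markers=markers, mask=cluster_area)

    excluded: list[int] = []
    props = measure.regionprops(labels)
    keep = np.zeros(labels.max() + 1, dtype=bool)
    for p in props:
        if p.area < params.min_region_area or (exclusions and p.label in exclusions):
            excluded.append(p.label)
        else:
            keep[p.label] = True
    cleaned = np.where(keep[labels], labels, 0).astype(np.int32)
    cleaned, _, _ = segmentation.relabel_sequential(cleaned)
    regions = [
        Region(p.label, int(p.area), tuple(p.centroid))
        for p in measure.regionprops(cleaned)
    ]
    return SegmentationResult(cleaned.astype(np.int32), regions, excluded)


def region_intensity_table(
    seg: SegmentationResult,
    tdt_channel: np.ndarray,
    gfp_channel: np.ndarray,
    image_id: str | int = 0,
) -> pd.DataFrame:
    """Median-normalized per-region mean intensities and their ratios.

    Each channel's per-region means are divided by the median over all
    regions of the same image, so a typical glomerulus has normalized
    intensity 1 in both channels.  Output schema matches the intensity
    tables of the labeling simulator (columns ``glom_id``, ``d_tdt``,
    ``d_gfp``, ``ratio``, ``image_id``).
    """
    labels = seg.label_image
    if seg.n_regions == 0:
        return pd.DataFrame(columns=["glom_id", "d_tdt", "d_gfp", "ratio", "image_id"])
    ids = np.array([r.region_id for r in seg.regions])
    mean_t = ndi.mean(np.asarray(tdt_channel, dtype=float), labels=labels, index=ids)
    mean_g = ndi.mean(np.asarray(gfp_channel, dtype=float), labels=labels, index=ids)
    d_tdt = mean_t / np.median(mean_t)
    d_gfp = mean_g / np.median(mean_g)
    return pd.DataFrame(
        {
            "glom_id": ids,
            "d_tdt": d_tdt,
            "d_gfp": d_gfp,
            "ratio": d_tdt / d_gfp,
            "image_id": image_id,
        }
    )


def normalized_mf_intensity(
    i_raw: float | np.ndarray,
    i_background: float | np.ndarray,
    i_whole: float | np.ndarray,
) -> float | np.ndarray:
    """Background-subtracted intensity normalized by the whole-layer mean.

    D = (I - IB) / IW, where IB is the background measured in the
    Purkinje-cell layer or white matter and IW the mean over the whole
    granule-cell layer.  Invariant under a common multiplicative rescaling
    of all three inputs.
    """
    i_whole = np.asarray(i_whole, dtype=float)
    if np.any(i_whole <= 0):
        raise ValueError("i_whole must be > 0")
    return (np.asarray(i_raw, dtype=float) - np.asarray(i_background, dtype=float)) / i_whole


class FitFailureError(RuntimeError):
    """Gaussian profile fit did not converge."""


def localize_pf_bundle(
    positions: np.ndarray, intensities: np.ndarray
) -> dict[str, float]:
    """Locate a labeled parallel-fiber bundle in a molecular-layer profile.

    ``positions`` are molecular-layer depths as percentages of the
    PC-soma-to-dendrite-tip span; the profile is fitted with a Gaussian
    (amplitude, center, width, offset) by least squares, and the fitted
    center is the bundle position.  Returns the four fitted parameters.
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if x.size < 5:
        raise ValueError("need >= 5 profile samples")

    def gauss(x, amp, center, width, offset):
        return amp * np.exp(-((x - center) ** 2) / (2 * width**2)) + offset

    offset0 = float(y.min())
    amp0 = float(y.max() - y.min()) or 1.0
    center0 = float(x[np.argmax(y)])
    width0 = max((x.max() - x.min()) / 6, 1e-3)
    try:
        popt, _ = curve_fit(
            gauss, x, y, p0=(amp0, center0, width0, offset0), maxfev=10000
        )
    except RuntimeError as exc:
        raise FitFailureError(
            f"Gaussian fit failed (n={x.size}, p0={(amp0, center0, width0, offset0)})"
        ) from exc
    amp, center, width, offset = popt
    return {
        "amplitude": float(amp),
        "center": float(center),
        "width": float(abs(width)),
        "offset": float(offset),
    }


def read_exclusions(path: str | Path) -> list[int]:
    """Read a plain-text region-id exclusion list (one id per line, # comments)."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(int(line))
    return out
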