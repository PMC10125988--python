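"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the study's imaging data at its native scale: a
211.7 x 211.7 um^2 granule-cell-layer field holding on the order of 3000 GC
somas (a hard-core lattice, since somas cannot overlap), labeled subsets
that are either Bernoulli-random or seeded clusters, per-glomerulus
two-channel intensity tables with a controllable log-scale correlation, and
two-channel glomerulus images with annular membrane signal around dark
central voids plus blob-like terminal signal.  Every generator is driven by
a single seed and returns its ground truth, so downstream estimates can be
scored against what was planted.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .spatial import PointPattern

FIELD_UM = 211.7  # side of one analyzed GCL image, um


@dataclass(frozen=True)
class LatticeConfig:
    n_points: int = 3000
    field_um: float = FIELD_UM
    min_spacing_um: float = 2.5


@dataclass(frozen=True)
class LabelConfig:
    fraction: float = 0.3
    clustering_strength: float = 0.0
    n_cluster_seeds: int = 5
    cluster_bandwidth_um: float = 15.0


@dataclass(frozen=True)
class IntensityConfig:
    n_glomeruli: int = 1000
    rho: float = 0.0
    sigma_log_tdt: float = 0.5
    sigma_log_gfp: float = 0.5


@dataclass(frozen=True)
class ImageConfig:
    size_px: int = 256
    n_glomeruli: int = 30
    radius_px: tuple[float, float] = (8.0, 12.0)
    margin_px: float = 5.0
    noise_sd: float = 0.05
    membrane_level: float = 1.0
    terminal_level: float = 0.8
    void_fraction: float = 0.45
    rho: float = 0.5


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    lattice: LatticeConfig = field(default_factory=LatticeConfig)
    labeling: LabelConfig = field(default_factory=LabelConfig)
    intensity: IntensityConfig = field(default_factory=IntensityConfig)
    images: ImageConfig = field(default_factory=ImageConfig)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


class PackingError(RuntimeError):
    """Requested points/regions cannot be packed into the field."""


def synth_gc_lattice(
    n_points: int = 3000,
    field_um: float = FIELD_UM,
    min_spacing_um: float = 2.5,
    seed: int | None = None,
    max_attempts_factor: int = 200,
) -> PointPattern:
    """Hard-core random soma lattice by sequential adsorption.

    Somas are placed uniformly in the square field, rejecting candidates
    closer than ``min_spacing_um`` to an accepted point.  The minimum
    spacing emulates soma-size exclusion and makes the lattice an irregular
    grid rather than a Poisson scatter.
    """
    if n_points * min_spacing_um**2 >= field_um**2:
        raise PackingError("requested density is not packable at this spacing")
    rng = np.random.default_rng(seed)
    cell = min_spacing_um
    n_cells = int(np.ceil(field_um / cell))
    grid: dict[tuple[int, int], list[int]] = {}
    pts = np.empty((n_points, 2))
    accepted = 0
    attempts = 0
    max_attempts = max_attempts_factor * n_points
    s2 = min_spacing_um**2
    while accepted < n_points:
        if attempts >= max_attempts:
            raise PackingError(
                f"placed only {accepted}/{n_points} points after {attempts} attempts"
            )
        attempts += 1
        p = rng.uniform(0, field_um, size=2)
        ci, cj = int(p[0] // cell), int(p[1] // cell)
        ok = True
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for k in grid.get((ci + di, cj + dj), ()):
                    d = pts[k] - p
                    if d[0] * d[0] + d[1] * d[1] < s2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            pts[accepted] = p
            grid.setdefault((ci, cj), []).append(accepted)
            accepted += 1
    return PointPattern(pts, np.zeros(n_points, dtype=bool))


def synth_labeled_pattern(
    lattice: PointPattern,
    fraction: float,
    clustering_strength: float = 0.0,
    seed: int | None = None,
    n_cluster_seeds: int = 5,
    bandwidth_um: float = 15.0,
) -> np.ndarray:
    """Select a labeled soma subset, optionally clustered around seed points.

    With ``clustering_strength`` 0 this is an independent Bernoulli
    selection at ``fraction``.  For strength s > 0, selection probabilities
    are proportional to 1 + s * exp(-d^2 / (2 bw^2)) where d is the distance
    to the nearest of ``n_cluster_seeds`` uniformly placed cluster centers;
    probabilities are rescaled so the expected selected fraction stays at
    ``fraction`` (clipped at 1).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if clustering_strength < 0:
        raise ValueError("clustering_strength must be >= 0")
    rng = np.random.default_rng(seed)
    coords = lattice.coordinates
    n = coords.shape[0]
    if clustering_strength == 0:
        return rng.random(n) < fraction
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    seeds = rng.uniform(lo, hi, size=(n_cluster_seeds, 2))
    d2 = ((coords[:, None, :] - seeds[None, :, :]) ** 2).sum(-1).min(axis=1)
    w = 1.0 + clustering_strength * np.exp(-d2 / (2 * bandwidth_um**2))
    p = np.clip(fraction * n * w / w.sum(), 0, 1)
    return rng.random(n) < p


def synth_intensity_table(
    n: int,
    rho: float,
    sigmas: tuple[float, float] = (0.5, 0.5),
    seed: int | None = None,
) -> pd.DataFrame:
    """Bivariate-lognormal intensity table with known log-scale correlation.

    log d_tdt and log d_gfp are jointly normal with standard deviations
    ``sigmas`` and correlation ``rho``; each channel is then divided by its
    median so median(d_tdt) = median(d_gfp) = 1, mimicking the per-image
    median normalization of measured intensities.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    if not -1 <= rho <= 1:
        raise ValueError("rho must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    s_t, s_g = sigmas
    cov = [[s_t**2, rho * s_t * s_g], [rho * s_t * s_g, s_g**2]]
    logs = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="cholesky")
    d = np.exp(logs)
    d /= np.median(d, axis=0)
    return pd.DataFrame(
        {
            "glom_id": np.arange(1, n + 1),
            "d_tdt": d[:, 0],
            "d_gfp": d[:, 1],
            "ratio": d[:, 0] / d[:, 1],
        }
    )


@dataclass(frozen=True)
class SyntheticImageSet:
    """Two structural + two fluorophore channels with planted ground truth."""

    membrane: np.ndarray
    terminal: np.ndarray
    tdt: np.ndarray
    gfp: np.ndarray
    labels: np.ndarray  # planted ground-truth label map, 0 = background
    truth: pd.DataFrame  # glom_id, x, y, radius, d_tdt, d_gfp, ratio


def synth_glomerulus_images(
    config: ImageConfig | None = None, seed: int | None = None
) -> SyntheticImageSet:
    """Render a synthetic two-channel glomerulus field.

    Each planted glomerulus is an annulus of membrane signal with a dark
    central void, overlapping a filled terminal blob; tdT/GFP channels are
    the terminal blob scaled by intensities from
    :func:`synth_intensity_table` at the configured channel correlation.
    Images are lightly blurred and carry additive Gaussian noise.  The
    ground-truth label map marks each glomerulus's full disk.
    """
    cfg = config or ImageConfig()
    rng = np.random.default_rng(seed)
    size = cfg.size_px
    r_lo, r_hi = cfg.radius_px
    # dart-throwing placement with pairwise clearance
    centers: list[np.ndarray] = []
    radii: list[float] = []
    attempts = 0
    while len(centers) < cfg.n_glomeruli:
        if attempts > 500 * cfg.n_glomeruli:
            raise PackingError("cannot place glomeruli without overlap")
        attempts += 1
        r = rng.uniform(r_lo, r_hi)
        c = rng.uniform(r + 2, size - r - 2, size=2)
        if all(
            np.hypot(*(c - c2)) >= r + r2 + cfg.margin_px
            for c2, r2 in zip(centers, radii)
        ):
            centers.append(c)
            radii.append(r)
    centers_a = np.asarray(centers)
    radii_a = np.asarray(radii)

    planted = synth_intensity_table(
        max(cfg.n_glomeruli, 10), cfg.rho, seed=rng.integers(2**31)
    ).iloc[: cfg.n_glomeruli]

    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    membrane = np.zeros((size, size))
    terminal = np.zeros((size, size))
    tdt = np.zeros((size, size))
    gfp = np.zeros((size, size))
    labels = np.zeros((size, size), dtype=np.int32)
    for i, (c, r) in enumerate(zip(centers_a, radii_a)):
        dist = np.hypot(yy - c[1], xx - c[0])
        disk = dist <= r
        void = dist <= cfg.void_fraction * r
        ring = disk & ~void
        blob = dist <= 0.8 * r
        membrane[ring] = cfg.membrane_level
        terminal[blob] = cfg.terminal_level
        tdt[blob] = planted["d_tdt"].iloc[i]
        gfp[blob] = planted["d_gfp"].iloc[i]
        labels[disk] = i + 1

    def finish(img: np.ndarray) -> np.ndarray:
        img = ndi.gaussian_filter(img, 1.0)
        img = img + rng.normal(0, cfg.noise_sd, img.shape)
        return np.clip(img, 0, None)

    truth = pd.DataFrame(
        {
            "glom_id": np.arange(1, cfg.n_glomeruli + 1),
            "x": centers_a[:, 0],
            "y": centers_a[:, 1],
            "radius": radii_a,
            "d_tdt": planted["d_tdt"].to_numpy(),
            "d_gfp": planted["d_gfp"].to_numpy(),
            "ratio": planted["ratio"].to_numpy(),
        }
    )
    return SyntheticImageSet(
        membrane=finish(membrane),
        terminal=finish(terminal),
        tdt=finish(tdt),
        gfp=finish(gfp),
        labels=labels,
        truth=truth,
    )


def match_planted_regions(
    truth: pd.DataFrame, centroids: list[tuple[float, float]]
) -> tuple[int, int, int]:
    """Match recovered region centroids to planted glomeruli.

    A recovered centroid (row, col) matches an unclaimed planted glomerulus
    when it falls within that glomerulus's radius.  Returns
    (true_positives, false_positives, false_negatives).
    """
    claimed = np.zeros(len(truth), dtype=bool)
    xy = truth[["x", "y"]].to_numpy()
    radii = truth["radius"].to_numpy()
    tp = fp = 0
    for row, col in centroids:
        d = np.hypot(xy[:, 0] - col, xy[:, 1] - row)
        cand = np.flatnonzero((d <= radii) & ~claimed)
        if cand.size:
            claimed[cand[np.argmin(d[cand])]] = True
            tp += 1
        else:
            fp += 1
    fn = int((~claimed).sum())
    return tp, fp, fn
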