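"""Virtual tdTomato/GFP labeling of GC ID windows and fluorescence emulation.

A labeling scheme marks two blocks of GC IDs as tdT- and GFP-expressing,
mimicking double AAV injections at two postnatal days.  Because the labeled
ID windows shift with injection age, a pair of injections close in time
shares a doubly labeled block at the junction of the two windows.  Labeled
dendrites are counted per glomerulus, and fluorescence-like intensities are
simulated as sums of lognormal per-dendrite weights plus lognormal background
noise, giving per-glomerulus intensity ratios comparable to imaging data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .network import BipartiteNetwork

#: Injection-age ID windows (inclusive), each 30% of the 3000-GC model.
INJECTION_WINDOWS: Mapping[str, tuple[int, int]] = {
    "P7": (1, 900),
    "P8": (351, 1250),
    "P9": (701, 1600),
    "P10": (1051, 1950),
    "P11": (1401, 2200),
    "P12": (1751, 2650),
    "P13": (2101, 3000),
}

#: Distance presets for distinct (non-overlapping) labeling, keyed by
#: (label fraction tag, distance).  30% blocks are 900 IDs, 15% are 450,
#: 5% are 150.
DISTANCE_PRESETS: Mapping[str, tuple[tuple[int, int], tuple[int, int]]] = {
    "near": ((1, 900), (1051, 1950)),
    "far": ((1, 900), (2101, 3000)),
    "near5": ((1, 150), (451, 600)),
    "middle5": ((1, 150), (1601, 1750)),
    "far5": ((1, 150), (2851, 3000)),
    "near15": ((1, 450), (751, 1200)),
    "middle15": ((1, 450), (1651, 2100)),
    "far15": ((1, 450), (2551, 3000)),
}


@dataclass(frozen=True)
class LabelingScheme:
    """ID windows carrying virtual tdT and GFP labels.

    ``tdt_ids`` / ``gfp_ids`` are inclusive (lo, hi) intervals;
    ``overlap_ids`` is their intersection (doubly labeled GCs) or ``None``.
    """

    tdt_ids: tuple[int, int]
    gfp_ids: tuple[int, int]
    name: str = ""

    @property
    def overlap_ids(self) -> tuple[int, int] | None:
        lo = max(self.tdt_ids[0], self.gfp_ids[0])
        hi = min(self.tdt_ids[1], self.gfp_ids[1])
        return (lo, hi) if lo <= hi else None

    @property
    def n_tdt(self) -> int:
        return self.tdt_ids[1] - self.tdt_ids[0] + 1

    @property
    def n_gfp(self) -> int:
        return self.gfp_ids[1] - self.gfp_ids[0] + 1

    @property
    def n_overlap(self) -> int:
        ov = self.overlap_ids
        return 0 if ov is None else ov[1] - ov[0] + 1


@dataclass(frozen=True)
class IntensityModel:
    """Lognormal fluorescence model.

    Parameters are natural-scale mean/sd of the lognormal variables:
    one weight draw per labeled dendrite plus one background-noise draw per
    glomerulus and channel.  All draws are strictly positive, so intensity
    ratios are always finite.
    """

    dendrite_mean: float = 1.0
    dendrite_sd: float = 0.6
    noise_mean: float = 0.3
    noise_sd: float = 0.1


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Underlying normal (mu, sigma) matching natural-scale mean and sd."""
    if mean <= 0:
        raise ValueError("lognormal mean must be > 0")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    return mu, float(np.sqrt(sigma2))


def make_scheme(
    preset_pair: str | tuple[tuple[int, int], tuple[int, int]],
    overlap_fraction: float | None = None,
    n_gc: int = 3000,
) -> LabelingScheme:
    """Build a labeling scheme from a preset name or explicit windows.

    Presets: ``"P7&P12"``-style realistic pairs (windows from
    :data:`INJECTION_WINDOWS`; the natural intersection of the two windows is
    the doubly labeled block), or distance presets ``"near"``, ``"far"``,
    ``"near5"`` ... from :data:`DISTANCE_PRESETS`.

    If ``overlap_fraction`` is given for a realistic pair, the doubly labeled
    block (that fraction of one window's width) is placed straddling the
    junction between the two windows, splitting it evenly, and both window
    widths are preserved so each label still covers its nominal fraction of
    GCs.
    """
    if isinstance(preset_pair, str):
        name = preset_pair
        if preset_pair in DISTANCE_PRESETS:
            tdt, gfp = DISTANCE_PRESETS[preset_pair]
            if overlap_fraction:
                raise ValueError("distance presets are non-overlapping")
            scheme = LabelingScheme(tdt, gfp, name=name)
        else:
            try:
                early, late = preset_pair.replace("x", "&").split("&")
                tdt = INJECTION_WINDOWS[early]
                gfp = INJECTION_WINDOWS[late]
            except (ValueError, KeyError):
                raise KeyError(f"unknown labeling preset {preset_pair!r}") from None
            scheme = LabelingScheme(tdt, gfp, name=name)
            width = tdt[1] - tdt[0] + 1
            c = (
                int(round(overlap_fraction * width))
                if overlap_fraction is not None
                else 0
            )
            if c > 0:
                # junction between end of the former window and start of the later
                j = (tdt[1] + gfp[0]) / 2.0
                ov_lo = int(np.ceil(j - c / 2.0 + 0.5))
                ov_hi = ov_lo + c - 1
                new_tdt = (ov_hi - width + 1, ov_hi)
                new_gfp = (ov_lo, ov_lo + (gfp[1] - gfp[0] + 1) - 1)
                scheme = LabelingScheme(new_tdt, new_gfp, name=name)
    else:
        tdt, gfp = preset_pair
        scheme = LabelingScheme(tuple(tdt), tuple(gfp), name="custom")
    for lo, hi in (scheme.tdt_ids, scheme.gfp_ids):
        if lo < 1 or hi > n_gc:
            raise ValueError(f"label window ({lo}, {hi}) outside 1..{n_gc}")
    return scheme


def count_labeled_dendrites(
    network: BipartiteNetwork, scheme: LabelingScheme
) -> pd.DataFrame:
    """Count tdT- and GFP-positive dendrites in every glomerulus.

    Doubly labeled GCs (IDs in the overlap block) contribute to both counts.
    Returns a DataFrame with columns ``glom_id``, ``n_tdt``, ``n_gfp``
    covering all glomeruli, including empty counts.
    """
    gc = network.gc_ids
    gl = network.glom_ids
    t_lo, t_hi = scheme.tdt_ids
    g_lo, g_hi = scheme.gfp_ids
    is_t = (gc >= t_lo) & (gc <= t_hi)
    is_g = (gc >= g_lo) & (gc <= g_hi)
    n_tdt = np.bincount(gl[is_t], minlength=network.n_glom + 1)[1:]
    n_gfp = np.bincount(gl[is_g], minlength=network.n_glom + 1)[1:]
    return pd.DataFrame(
        {
            "glom_id": np.arange(1, network.n_glom + 1),
            "n_tdt": n_tdt,
            "n_gfp": n_gfp,
        }
    )


def simulate_intensities(
    counts: pd.DataFrame,
    model: IntensityModel | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Turn labeled-dendrite counts into fluorescence-like intensities.

    Per glomerulus and channel the intensity is the sum of ``n`` independent
    lognormal dendrite-weight draws plus one lognormal background-noise draw;
    the ratio column is tdT intensity / GFP intensity.  Degenerate model
    parameters (sd = 0 or mean = 0) collapse to their deterministic values,
    which is useful for closed-form checks.
    """
    model = model or IntensityModel()
    rng = np.random.default_rng(seed)
    n_tdt = counts["n_tdt"].to_numpy()
    n_gfp = counts["n_gfp"].to_numpy()

    def channel(n: np.ndarray) -> np.ndarray:
        total = np.zeros(n.size, dtype=float)
        if model.dendrite_mean > 0:
            if model.dendrite_sd > 0:
                mu, sig = _lognormal_params(model.dendrite_mean, model.dendrite_sd)
                # draw per-dendrite weights for all glomeruli at once
                n_total = int(n.sum())
                w = rng.lognormal(mu, sig, size=n_total)
                idx = np.repeat(np.arange(n.size), n)
                total = np.bincount(idx, weights=w, minlength=n.size)
            else:
                total = n * model.dendrite_mean
        if model.noise_mean > 0:
            if model.noise_sd > 0:
                mu, sig = _lognormal_params(model.noise_mean, model.noise_sd)
                total = total + rng.lognormal(mu, sig, size=n.size)
            else:
                total = total + model.noise_mean
        return total

    d_tdt = channel(n_tdt)
    d_gfp = channel(n_gfp)
    out = counts[["glom_id", "n_tdt", "n_gfp"]].copy()
    out["d_tdt"] = d_tdt
    out["d_gfp"] = d_gfp
    with np.errstate(divide="ignore"):
        out["ratio"] = d_tdt / d_gfp
    return out
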