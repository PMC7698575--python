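"""Yellow-pigment quantification: RGB color box, pixel counts and SDD.

Two per-image statistics summarize yellow skin pigmentation:

1. the number of foreground pixels whose RGB value falls inside an
   inclusive per-channel color box (standardized by total foreground size
   to a *yellow fraction*), and
2. the Standard Distance Deviation (SDD), a spatial dispersion index of
   the yellow pixels, in pixel units: larger SDD means the yellow pixels
   are more scattered over the fish profile.

The default yellow box is the one derived in the source study for
gilthead seabream: R 205-255, G 130-255, B 0-15 (inclusive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .imaging import MaskedImage

__all__ = [
    "ColorRange",
    "PigmentationRecord",
    "FishRecord",
    "SEABREAM_YELLOW",
    "derive_color_range",
    "perturb_range",
    "yellow_mask",
    "quantify",
    "compute_sdd",
    "sample_pixels",
]


@dataclass(frozen=True)
class ColorRange:
    """Inclusive per-channel [lo, hi] bounds defining 'yellow' in RGB space."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self) -> None:
        for c in range(3):
            if not (0 <= self.lo[c] <= self.hi[c] <= 255):
                raise ValueError(
                    f"channel {c}: need 0 <= lo <= hi <= 255, got {self.lo[c]}..{self.hi[c]}"
                )

    def contains(self, rgb: Sequence[int]) -> bool:
        return all(self.lo[c] <= rgb[c] <= self.hi[c] for c in range(3))

    def as_flat(self) -> tuple[int, ...]:
        """Six integers (R_lo, R_hi, G_lo, G_hi, B_lo, B_hi) for configs."""
        return (self.lo[0], self.hi[0], self.lo[1], self.hi[1], self.lo[2], self.hi[2])

    @classmethod
    def from_flat(cls, values: Sequence[int]) -> "ColorRange":
        v = [int(x) for x in values]
        if len(v) != 6:
            raise ValueError("flat color range needs six integers")
        return cls((v[0], v[2], v[4]), (v[1], v[3], v[5]))


#: Yellow box obtained in the source study (5 pixels x 3 images per tank).
SEABREAM_YELLOW = ColorRange(lo=(205, 130, 0), hi=(255, 255, 15))


@dataclass
class PigmentationRecord:
    """Per-image quantification output plus fish metadata."""

    image_id: str
    fish_id: str
    treatment: str
    tank: str
    view: str
    yellow_count: int
    total_foreground: int
    yellow_fraction: float
    sdd: float  # NaN when fewer than 2 yellow pixels

    def __post_init__(self) -> None:
        if self.total_foreground <= 0:
            raise ValueError("total_foreground must be positive")
        if not 0 <= self.yellow_count <= self.total_foreground:
            raise ValueError("yellow_count must be within [0, total_foreground]")


@dataclass
class FishRecord:
    """Growth traits of one fish: total length (cm) and weight (g)."""

    fish_id: str
    treatment: str
    tank: str
    TL: float
    W: float

    def __post_init__(self) -> None:
        if self.TL <= 0 or self.W <= 0:
            raise ValueError("TL and W must be positive")


def derive_color_range(sampled_pixels: Iterable[Sequence[int]]) -> ColorRange:
    """Channelwise min/max over sampled yellow pixels.

    This mirrors the sampling protocol used to obtain the seabream box:
    the lower (upper) bound of each channel is the minimum (maximum)
    observed among the sampled pixels.
    """
    arr = np.asarray(list(sampled_pixels), dtype=int)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] != 3:
        raise ValueError("need at least two RGB samples")
    lo = arr.min(axis=0)
    hi = arr.max(axis=0)
    return ColorRange(tuple(int(x) for x in lo), tuple(int(x) for x in hi))


def perturb_range(
    rng: ColorRange, pct: float, mode: Literal["expand", "shrink"] = "expand"
) -> ColorRange:
    """Move every bound by ``pct`` percent of its own value.

    expand: lo -> floor(lo*(1-p)), hi -> ceil(hi*(1+p));
    shrink: lo -> ceil(lo*(1+p)), hi -> floor(hi*(1-p)).
    Results are clamped to [0, 255] and re-ordered so lo <= hi.
    """
    if abs(pct) > 50:
        raise ValueError("|pct| must be <= 50")
    p = abs(pct) / 100.0
    lo_new, hi_new = [], []
    for c in range(3):
        if mode == "expand":
            lo_c = math.floor(rng.lo[c] * (1 - p))
            hi_c = math.ceil(rng.hi[c] * (1 + p))
        elif mode == "shrink":
            lo_c = math.ceil(rng.lo[c] * (1 + p))
            hi_c = math.floor(rng.hi[c] * (1 - p))
        else:
            raise ValueError(f"unknown mode {mode!r}")
        lo_c = min(max(lo_c, 0), 255)
        hi_c = min(max(hi_c, 0), 255)
        if lo_c > hi_c:
            lo_c, hi_c = hi_c, lo_c
        lo_new.append(lo_c)
        hi_new.append(hi_c)
    return ColorRange(tuple(lo_new), tuple(hi_new))


def yellow_mask(image: MaskedImage, rng: ColorRange) -> np.ndarray:
    """Boolean H x W mask: foreground pixels inside the color box.

    Bounds are inclusive on both ends; background pixels are never
    selected regardless of color.
    """
    px = image.pixels
    lo = np.asarray(rng.lo, dtype=np.uint8)
    hi = np.asarray(rng.hi, dtype=np.uint8)
    in_box = np.all((px >= lo) & (px <= hi), axis=2)
    return in_box & image.mask


def compute_sdd(
    coords: np.ndarray | Sequence[tuple[float, float]],
    method: Literal["centroid", "pairwise"] = "centroid",
    pixel_metric: Literal["euclidean", "cityblock"] = "euclidean",
) -> float:
    """Standard Distance Deviation of a set of pixel coordinates.

    ``centroid`` (default) is the classical GIS standard distance about
    the mean center: sqrt( sum_i[(r_i - rbar)^2 + (c_i - cbar)^2] / n ).
    ``pairwise`` is the population standard deviation of the n(n-1)/2
    inter-point distances (Euclidean by default, city-block optional).

    Fewer than two points make dispersion undefined; NaN is returned
    (never 0, which would fake maximal concentration).
    """
    pts = np.asarray(coords, dtype=float)
    if pts.size == 0 or pts.shape[0] < 2:
        return float("nan")
    if method == "centroid":
        center = pts.mean(axis=0)
        return float(np.sqrt(np.mean(np.sum((pts - center) ** 2, axis=1))))
    if method == "pairwise":
        from scipy.spatial.distance import pdist

        metric = "euclidean" if pixel_metric == "euclidean" else "cityblock"
        d = pdist(pts, metric=metric)
        return float(np.std(d))  # population SD over the distance multiset
    raise ValueError(f"unknown SDD method {method!r}")


def quantify(
    image: MaskedImage,
    rng: ColorRange,
    *,
    fish_id: str = "",
    treatment: str = "",
    tank: str = "",
    sdd_method: Literal["centroid", "pairwise"] = "centroid",
) -> PigmentationRecord:
    """Count in-range pixels, standardize by foreground size, compute SDD."""
    total = image.foreground_count
    if total == 0:
        raise ValueError(f"{image.image_id}: empty foreground")
    ymask = yellow_mask(image, rng)
    count = int(ymask.sum())
    coords = np.argwhere(ymask)
    sdd = compute_sdd(coords, method=sdd_method)
    return PigmentationRecord(
        image_id=image.image_id,
        fish_id=fish_id,
        treatment=treatment,
        tank=tank,
        view=image.view,
        yellow_count=count,
        total_foreground=total,
        yellow_fraction=count / total,
        sdd=sdd,
    )


def sample_pixels(
    image: MaskedImage,
    selector: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> list[tuple[int, int, tuple[int, int, int]]]:
    """Sample ``n`` pixels uniformly from selector∧foreground, with record.

    Programmatic stand-in for the manual protocol of clicking yellow
    pixels on an image: returns (row, col, RGB) triples so the sampling
    is auditable and reproducible from the generator state.
    """
    candidates = np.argwhere(selector & image.mask)
    if len(candidates) == 0:
        raise ValueError(f"{image.image_id}: no pixels available to sample")
    idx = rng.choice(len(candidates), size=min(n, len(candidates)), replace=False)
    out = []
    for i in idx:
        r, c = (int(v) for v in candidates[i])
        out.append((r, c, tuple(int(v) for v in image.pixels[r, c])))
    return out
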