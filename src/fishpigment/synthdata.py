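"""Synthetic fish-image studies with known ground truth.

The original photographs behind the seabream pigmentation study are not
deposited, so every downstream stage is exercised on generated studies
that reproduce the study's statistical structure: 9 dietary treatments x
3 tanks x 18 fish, a frontal and a lateral photograph per fish, yellow
patch area increasing with the dietary carotenoid concentration, a
shared per-tank random effect and per-fish noise.

A generated image is a stylized fish silhouette (ellipse + tail) filled
with gray-brown body tones that lie outside the yellow RGB box, onto
which disk-like yellow patches are painted at view-specific anchor sites
(operculum, pectoral fin, belly for the lateral view; the between-eyes
region for the frontal view). Patch colors are drawn from the interior
of the yellow box, away from its boundaries, emulating the reported
insensitivity of the real data to a +/-5% perturbation of the box.

Everything is reproducible from a single integer seed; each image is
regenerated lazily from a seed derived from (study seed, image index),
so studies never need to be held in memory or on disk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Literal

import numpy as np
import pandas as pd
from skimage.draw import polygon

from .imaging import MaskedImage
from .pigment import SEABREAM_YELLOW, ColorRange, perturb_range

__all__ = [
    "StudyDesign",
    "DoseResponse",
    "GroundTruth",
    "SyntheticStudy",
    "default_design",
    "make_fish_canvas",
    "paint_yellow_patches",
    "generate_study",
    "GROWTH_PRESETS",
]

#: Treatment labels with total dietary carotenoid concentration
#: (mg kg^-1 dry weight) of the nine test diets.
DEFAULT_TREATMENTS: list[tuple[str, float]] = [
    ("CV", 4.6),
    ("H10", 3.5),
    ("H20", 3.5),
    ("H40", 3.5),
    ("P20", 3.3),
    ("P40", 2.4),
    ("H10P30", 2.7),
    ("RC10", 5.4),
    ("MA10", 234.2),
]

#: Per-treatment total length (cm) and weight (g) normal presets
#: (mean, sd) pairs, matching the reported end-of-trial growth.
GROWTH_PRESETS: dict[str, tuple[float, float, float, float]] = {
    "CV": (21.7, 1.0, 177.7, 22.4),
    "H10": (22.5, 1.0, 186.8, 26.9),
    "H20": (23.0, 0.8, 187.5, 22.0),
    "H40": (23.3, 1.0, 192.2, 22.2),
    "P20": (22.9, 0.9, 191.6, 24.3),
    "P40": (23.0, 0.8, 192.3, 23.2),
    "H10P30": (22.0, 0.8, 190.7, 21.6),
    "RC10": (22.3, 0.8, 180.5, 23.9),
    "MA10": (22.2, 0.8, 166.9, 19.8),
}
_GROWTH_FALLBACK = (22.5, 0.9, 185.0, 22.0)

_ANCHORS = {
    # (row, col) in canvas-relative units
    "lateral": [(0.50, 0.28), (0.60, 0.46), (0.70, 0.56)],
    "frontal": [(0.32, 0.50), (0.47, 0.50), (0.63, 0.50)],
}

#: Interior of the yellow box (inside the 5%-shrunk bounds): patch colors
#: stay classified under both the nominal and the perturbed boxes.
PATCH_COLOR_BOX: ColorRange = perturb_range(SEABREAM_YELLOW, 5, "shrink")


@dataclass
class StudyDesign:
    """Treatments, replication and imaging geometry of a synthetic study."""

    treatments: list[tuple[str, float]] = field(
        default_factory=lambda: list(DEFAULT_TREATMENTS)
    )
    tanks_per_treatment: int = 3
    fish_per_tank: int = 18
    views: tuple[str, ...] = ("frontal", "lateral")
    image_size: tuple[int, int] = (256, 256)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tanks_per_treatment < 1 or self.fish_per_tank < 1:
            raise ValueError("tanks and fish counts must be >= 1")
        for label, c in self.treatments:
            if c < 0:
                raise ValueError(f"carotenoid concentration must be >= 0 ({label})")

    @property
    def n_fish(self) -> int:
        return len(self.treatments) * self.tanks_per_treatment * self.fish_per_tank

    @property
    def n_images(self) -> int:
        return self.n_fish * len(self.views)

    @property
    def carotenoids(self) -> dict[str, float]:
        return dict(self.treatments)


def default_design(seed: int = 0, image_size: tuple[int, int] = (256, 256)) -> StudyDesign:
    """The 9 x 3 x 18, two-view study layout with the test-diet carotenoids."""
    return StudyDesign(seed=seed, image_size=image_size)


@dataclass
class DoseResponse:
    """Saturating carotenoid dose-response with tank and individual noise.

    The mean yellow area fraction of view v at dietary carotenoid
    concentration C (mg/kg d.w.) is ``fmax[v] * C / (C + K)``; fmax and
    the half-saturation K are chosen so that low-carotenoid diets
    (~2-5 mg/kg) give small fractions and the microalgae-level diet
    (234 mg/kg) approaches fmax. Per-fish fractions are the view mean
    times a shared log-normal tank intercept (sd ``sigma_tank`` on the
    log scale) times per-fish, per-view log-normal noise (sd
    ``sigma_individual``), clipped to [0, clip_max].
    """

    fmax: dict[str, float] = field(
        default_factory=lambda: {"frontal": 0.17, "lateral": 0.015}
    )
    half_saturation: float = 50.0
    sigma_tank: float = 0.02
    sigma_individual: float = 0.5
    clip_max: float = 0.4

    def mean_fraction(self, view: str, carotenoid: float) -> float:
        return self.fmax[view] * carotenoid / (carotenoid + self.half_saturation)


@dataclass
class GroundTruth:
    """True pigmentation parameters for one generated image."""

    image_id: str
    true_area_fraction: float
    true_count: int
    patch_centers: list[tuple[int, int]]
    dispersion: float


def _fish_silhouette(view: str, size: tuple[int, int]) -> np.ndarray:
    H, W = size
    rr, cc = np.mgrid[0:H, 0:W]
    if view == "lateral":
        cy, cx = 0.50 * H, 0.42 * W
        a, b = 0.27 * H, 0.30 * W
        mask = ((rr - cy) / a) ** 2 + ((cc - cx) / b) ** 2 <= 1.0
        tail_r = [0.35 * H, 0.65 * H, 0.50 * H]
        tail_c = [0.86 * W, 0.86 * W, 0.66 * W]
        tr, tc = polygon(tail_r, tail_c, shape=(H, W))
        mask[tr, tc] = True
    elif view == "frontal":
        cy, cx = 0.50 * H, 0.50 * W
        a, b = 0.38 * H, 0.20 * W
        mask = ((rr - cy) / a) ** 2 + ((cc - cx) / b) ** 2 <= 1.0
    else:
        raise ValueError(f"unknown view {view!r}")
    return mask


def make_fish_canvas(
    view: str,
    size: tuple[int, int] = (256, 256),
    seed=None,
    noise_sigma: float = 5.0,
) -> MaskedImage:
    """Fish-silhouette canvas in out-of-range gray-brown body tones.

    The body palette keeps the red channel far below the yellow box lower
    bound, so no body pixel can be classified yellow even with channel
    noise.
    """
    H, W = size
    if H < 64 or W < 64:
        raise ValueError("canvas must be at least 64x64")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = _fish_silhouette(view, size)

    base = np.array([132.0, 120.0, 104.0])
    img = np.empty((H, W, 3), dtype=float)
    img[:] = base
    # gentle dorsoventral shading
    shade = np.linspace(-8.0, 8.0, H)[:, None, None]
    img = img + shade
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    img = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    img[~mask] = 0
    return MaskedImage(img, mask, view=view, image_id="")


def paint_yellow_patches(
    canvas: MaskedImage,
    area_fraction: float,
    n_patches: int = 3,
    dispersion: float = 15.0,
    seed=None,
    color_box: ColorRange = PATCH_COLOR_BOX,
) -> tuple[MaskedImage, GroundTruth]:
    """Paint disk-like yellow patches totalling a target area fraction.

    Patch centers scatter (sd = ``dispersion`` px) about view-specific
    anchor sites; each patch is grown as the nearest unpainted foreground
    pixels around its center, so the total painted count matches
    ``round(area_fraction * foreground)`` exactly.
    """
    if not 0 <= area_fraction <= 1:
        raise ValueError("area_fraction must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask_area = canvas.foreground_count
    target = int(round(area_fraction * mask_area))
    if target > mask_area:
        raise ValueError("patches cannot fit: target exceeds foreground")
    out = MaskedImage(
        canvas.pixels.copy(), canvas.mask.copy(), view=canvas.view,
        image_id=canvas.image_id,
    )
    if target == 0:
        return out, GroundTruth(canvas.image_id, area_fraction, 0, [], dispersion)
    if target < n_patches:
        n_patches = max(1, target)

    H, W = canvas.shape
    anchors = _ANCHORS[canvas.view]
    coords = np.argwhere(canvas.mask)  # K x 2
    painted = np.zeros(len(coords), dtype=bool)

    quotas = np.full(n_patches, target // n_patches, dtype=int)
    quotas[: target % n_patches] += 1

    centers: list[tuple[int, int]] = []
    px = out.pixels
    lo = np.asarray(color_box.lo)
    hi = np.asarray(color_box.hi)
    for k in range(n_patches):
        ar, ac = anchors[k % len(anchors)]
        center = np.array([ar * H, ac * W]) + rng.normal(0.0, dispersion, size=2)
        # snap the center to the nearest foreground pixel
        d2 = ((coords - center) ** 2).sum(axis=1)
        center = coords[int(np.argmin(d2))]
        centers.append((int(center[0]), int(center[1])))
        order = np.argsort(((coords - center) ** 2).sum(axis=1), kind="stable")
        avail = order[~painted[order]][: quotas[k]]
        painted[avail] = True
        colors = rng.integers(lo, hi + 1, size=(len(avail), 3))
        px[coords[avail, 0], coords[avail, 1]] = colors.astype(np.uint8)

    truth = GroundTruth(
        image_id=canvas.image_id,
        true_area_fraction=area_fraction,
        true_count=int(painted.sum()),
        patch_centers=centers,
        dispersion=dispersion,
    )
    return out, truth


#: Patch-center scatter (px) per view; lateral patches are more spread
#: along the flank than the frontal between-eyes patches.
DEFAULT_DISPERSION = {"lateral": 18.0, "frontal": 10.0}


class SyntheticStudy:
    """A fully parameterized synthetic study with lazy image generation.

    ``fish`` is one row per fish (treatment, tank, replicate, TL, W);
    ``images`` is one row per image with the ground-truth pigmentation.
    :meth:`iter_images` regenerates images deterministically from the
    study seed, so a study is a pure function of its design and
    parameters.
    """

    def __init__(
        self,
        design: StudyDesign,
        dose_response: DoseResponse | None = None,
        growth_model: dict[str, tuple[float, float, float, float]] | None = None,
        noise_sigma: float = 5.0,
        dispersion: dict[str, float] | None = None,
    ):
        self.design = design
        self.dose_response = dose_response or DoseResponse()
        self.growth_model = growth_model or GROWTH_PRESETS
        self.noise_sigma = noise_sigma
        self.dispersion = dispersion or dict(DEFAULT_DISPERSION)
        self._mask_area = {
            v: int(_fish_silhouette(v, design.image_size).sum()) for v in design.views
        }
        self._build_tables()

    def _build_tables(self) -> None:
        d = self.design
        dr = self.dose_response
        rng = np.random.default_rng([d.seed, 0])
        fish_rows, image_rows = [], []
        image_index = 0
        for treatment, carotenoid in d.treatments:
            tl_m, tl_sd, w_m, w_sd = self.growth_model.get(treatment, _GROWTH_FALLBACK)
            for tank_i in range(1, d.tanks_per_treatment + 1):
                tank = f"{treatment}-{tank_i}"
                tank_effect = rng.normal(0.0, dr.sigma_tank)
                for fish_i in range(1, d.fish_per_tank + 1):
                    fish_id = f"{treatment}-t{tank_i}-f{fish_i:02d}"
                    TL = max(1.0, rng.normal(tl_m, tl_sd))
                    W = max(1.0, rng.normal(w_m, w_sd))
                    fish_rows.append(
                        dict(
                            fish_id=fish_id,
                            treatment=treatment,
                            tank=tank,
                            replicate=tank_i,
                            carotenoid=carotenoid,
                            TL=TL,
                            W=W,
                        )
                    )
                    for view in d.views:
                        mean_f = dr.mean_fraction(view, carotenoid)
                        noise = rng.normal(0.0, dr.sigma_individual)
                        frac = mean_f * np.exp(tank_effect + noise)
                        frac = float(np.clip(frac, 0.0, dr.clip_max))
                        true_count = int(round(frac * self._mask_area[view]))
                        image_rows.append(
                            dict(
                                image_id=f"{fish_id}_{view}",
                                image_index=image_index,
                                fish_id=fish_id,
                                treatment=treatment,
                                tank=tank,
                                replicate=tank_i,
                                carotenoid=carotenoid,
                                view=view,
                                true_area_fraction=frac,
                                true_count=true_count,
                                mask_area=self._mask_area[view],
                            )
                        )
                        image_index += 1
        self.fish = pd.DataFrame(fish_rows)
        self.images = pd.DataFrame(image_rows)

    def render_image(self, row: pd.Series) -> MaskedImage:
        """Deterministically regenerate one image from its table row."""
        rng = np.random.default_rng([self.design.seed, 1, int(row["image_index"])])
        canvas = make_fish_canvas(
            row["view"], self.design.image_size, seed=rng, noise_sigma=self.noise_sigma
        )
        canvas.image_id = row["image_id"]
        n_patches = int(rng.integers(2, 4))  # two or three patch sites
        img, truth = paint_yellow_patches(
            canvas,
            row["true_area_fraction"],
            n_patches=n_patches,
            dispersion=self.dispersion[row["view"]],
            seed=rng,
        )
        assert truth.true_count == row["true_count"]
        return img

    def iter_images(self) -> Iterator[tuple[pd.Series, MaskedImage]]:
        for _, row in self.images.iterrows():
            yield row, self.render_image(row)

    def manifest(self) -> dict:
        return {
            "seed": self.design.seed,
            "treatments": self.design.treatments,
            "tanks_per_treatment": self.design.tanks_per_treatment,
            "fish_per_tank": self.design.fish_per_tank,
            "views": list(self.design.views),
            "image_size": list(self.design.image_size),
            "dose_response": asdict(self.dose_response),
            "noise_sigma": self.noise_sigma,
            "dispersion": self.dispersion,
            "n_fish": int(len(self.fish)),
            "n_images": int(len(self.images)),
        }

    def write(self, outdir: str | Path, write_images: bool = True) -> Path:
        """Write design/ground-truth CSVs, manifest and (optionally) PNGs."""
        from PIL import Image

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.fish.to_csv(outdir / "design.csv", index=False)
        truth = self.images.copy()
        if write_images:
            imgdir = outdir / "images"
            imgdir.mkdir(exist_ok=True)
            paths = []
            for row, img in self.iter_images():
                rgba = np.dstack(
                    [img.pixels, np.where(img.mask, 255, 0).astype(np.uint8)]
                )
                path = imgdir / f"{row.image_id}.png"
                Image.fromarray(rgba, mode="RGBA").save(path)
                paths.append(str(path.relative_to(outdir)))
            truth["image_path"] = paths
        truth.to_csv(outdir / "ground_truth.csv", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest(), fh, indent=2, sort_keys=True)
        return outdir


def generate_study(
    design: StudyDesign | None = None,
    dose_response: DoseResponse | None = None,
    growth_model: dict | None = None,
    **kwargs,
) -> SyntheticStudy:
    """Build a synthetic study (images generated lazily on iteration)."""
    return SyntheticStudy(
        design or default_design(), dose_response, growth_model, **kwargs
    )
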