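"""Image loading, foreground masking and ColorChecker-based calibration.

The unit of analysis is a :class:`MaskedImage`: an 8-bit RGB pixel array
plus a boolean foreground mask separating the fish from the background.
Background elimination is expressed as an explicit, deterministic policy
(alpha channel, chroma key, or an external mask file) so that runs are
reproducible.

Color calibration fits an affine map (3x3 matrix + offset) from the 24
measured patches of a photographed ColorChecker chart to the standard
sRGB reference values shipped with the package, by ordinary least squares.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from PIL import Image

__all__ = [
    "MaskedImage",
    "CalibrationChart",
    "ColorTransform",
    "load_image",
    "fit_calibration",
    "apply_calibration",
    "colorchecker_reference",
]

View = Literal["frontal", "lateral"]


class EmptyForegroundError(ValueError):
    """Raised when a background policy leaves no foreground pixel."""


@dataclass
class MaskedImage:
    """8-bit RGB image with a boolean fish-foreground mask.

    Coordinates are row-major, origin top-left, 0-based (row, col).
    """

    pixels: np.ndarray  # H x W x 3, uint8
    mask: np.ndarray  # H x W, bool
    view: View = "lateral"
    image_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"pixels must be HxWx3, got {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if self.mask.shape != self.pixels.shape[:2]:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match image {self.pixels.shape[:2]}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def foreground_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class CalibrationChart:
    """24 index-aligned pairs of measured and reference RGB patch means."""

    measured_patches: np.ndarray  # 24 x 3
    reference_patches: np.ndarray  # 24 x 3

    def __post_init__(self) -> None:
        self.measured_patches = np.asarray(self.measured_patches, dtype=float)
        self.reference_patches = np.asarray(self.reference_patches, dtype=float)
        for arr, label in (
            (self.measured_patches, "measured"),
            (self.reference_patches, "reference"),
        ):
            if arr.shape != (24, 3):
                raise ValueError(f"{label} patches must be 24x3, got {arr.shape}")


@dataclass
class ColorTransform:
    """Affine RGB correction ``y = A @ x + b`` with fit residual RMSE."""

    matrix: np.ndarray  # 3 x 3
    offset: np.ndarray  # 3
    rmse: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.offset = np.asarray(self.offset, dtype=float).reshape(3)

    @classmethod
    def identity(cls) -> "ColorTransform":
        return cls(np.eye(3), np.zeros(3), 0.0)


def colorchecker_reference() -> np.ndarray:
    """Standard ColorChecker 24 patch values in sRGB, as a 24x3 float array."""
    ref = importlib.resources.files("fishpigment.data") / "colorchecker24_srgb.csv"
    rows = []
    with ref.open() as fh:
        next(fh)  # header
        for line in fh:
            parts = line.strip().split(",")
            rows.append([float(parts[2]), float(parts[3]), float(parts[4])])
    out = np.asarray(rows, dtype=float)
    assert out.shape == (24, 3)
    return out


def load_image(
    path: str | Path,
    background_policy: str = "alpha",
    *,
    key_color: tuple[int, int, int] = (0, 255, 0),
    tolerance: int = 10,
    mask_path: str | Path | None = None,
    view: View = "lateral",
    image_id: str | None = None,
) -> MaskedImage:
    """Read an 8-bit PNG/JPEG/TIFF and establish the fish-foreground mask.

    Policies
    --------
    ``alpha``
        foreground where the alpha channel is > 0 (requires RGBA input).
    ``chroma_key``
        foreground where the Chebyshev (max-channel) distance from
        ``key_color`` exceeds ``tolerance``.
    ``external_mask``
        foreground where a single-channel mask file at ``mask_path`` is
        nonzero; dimensions must match the image.

    Raises
    ------
    EmptyForegroundError
        if the policy leaves zero foreground pixels; such an image is not
        admissible for quantification.
    """
    path = Path(path)
    with Image.open(path) as im:
        if background_policy == "alpha":
            if "A" not in im.getbands():
                raise ValueError(f"{path}: policy 'alpha' requires an alpha channel")
            rgba = np.asarray(im.convert("RGBA"))
            pixels = rgba[:, :, :3]
            mask = rgba[:, :, 3] > 0
        elif background_policy == "chroma_key":
            pixels = np.asarray(im.convert("RGB"))
            key = np.asarray(key_color, dtype=int).reshape(1, 1, 3)
            cheb = np.abs(pixels.astype(int) - key).max(axis=2)
            mask = cheb > tolerance
        elif background_policy == "external_mask":
            if mask_path is None:
                raise ValueError("policy 'external_mask' requires mask_path")
            pixels = np.asarray(im.convert("RGB"))
            with Image.open(mask_path) as mk:
                mask_arr = np.asarray(mk.convert("L"))
            if mask_arr.shape != pixels.shape[:2]:
                raise ValueError(
                    f"mask {mask_arr.shape} does not match image {pixels.shape[:2]}"
                )
            mask = mask_arr > 0
        else:
            raise ValueError(f"unknown background policy: {background_policy!r}")

    if not mask.any():
        raise EmptyForegroundError(
            f"{path}: background policy {background_policy!r} left no foreground"
        )
    return MaskedImage(
        pixels=pixels,
        mask=mask,
        view=view,
        image_id=image_id if image_id is not None else path.stem,
    )


def fit_calibration(chart: CalibrationChart) -> ColorTransform:
    """Least-squares affine transform mapping measured -> reference patches.

    Solves ``ref ~= measured @ A.T + b`` over the 24 patch pairs by
    ordinary least squares and reports the residual RMSE over all 72
    channel values.
    """
    X = np.column_stack([chart.measured_patches, np.ones(24)])  # 24 x 4
    if np.linalg.matrix_rank(X) < 4:
        raise np.linalg.LinAlgError(
            "rank-deficient calibration design (measured patches not diverse enough)"
        )
    coefs, *_ = np.linalg.lstsq(X, chart.reference_patches, rcond=None)  # 4 x 3
    A = coefs[:3].T
    b = coefs[3]
    resid = chart.reference_patches - (chart.measured_patches @ A.T + b)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return ColorTransform(A, b, rmse)


def apply_calibration(image: MaskedImage, transform: ColorTransform) -> MaskedImage:
    """Map every pixel through the affine transform.

    Values are rounded half-up and clamped to [0, 255]; the mask is
    unchanged. Rounding before the yellow-range test keeps the pipeline on
    the 0-255 integer scale the range is defined on.
    """
    flat = image.pixels.reshape(-1, 3).astype(float)
    out = flat @ transform.matrix.T + transform.offset
    out = np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)
    return MaskedImage(
        pixels=out.reshape(image.pixels.shape),
        mask=image.mask.copy(),
        view=image.view,
        image_id=image.image_id,
    )
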