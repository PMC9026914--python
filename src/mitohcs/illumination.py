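"""Per-image illumination correction.

Wide-field fluorescence images carry a smooth shading pattern from uneven
lamp illumination and vignetting.  We model it per image as a full quadratic
surface over normalized coordinates and subtract the fitted surface,
clipping at zero (negative fluorescence is meaningless and downstream
thresholds assume non-negative input).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .plate_io import ChannelImage

__all__ = ["IlluminationSurface", "fit_polynomial_surface", "subtract_illumination", "correct_image"]


def _design_matrix(shape: tuple[int, int]) -> np.ndarray:
    """Quadratic design [1, x, y, x^2, y^2, xy] over (x, y) in [0,1]^2.

    x runs along columns, y along rows; a single row or column maps to 0.
    """
    nr, nc = shape
    y = np.linspace(0.0, 1.0, nr) if nr > 1 else np.zeros(1)
    x = np.linspace(0.0, 1.0, nc) if nc > 1 else np.zeros(1)
    X, Y = np.meshgrid(x, y)
    return np.column_stack(
        [np.ones(X.size), X.ravel(), Y.ravel(), X.ravel() ** 2, Y.ravel() ** 2, (X * Y).ravel()]
    )


@dataclass
class IlluminationSurface:
    """Coefficients (a, b, c, d, e, f) of a + b x + c y + d x^2 + e y^2 + f xy."""

    coefficients: np.ndarray
    shape: tuple[int, int]

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        if self.coefficients.shape != (6,):
            raise ValueError("expected 6 surface coefficients")

    def evaluate(self, shape: tuple[int, int] | None = None) -> np.ndarray:
        shape = self.shape if shape is None else shape
        A = _design_matrix(shape)
        return (A @ self.coefficients).reshape(shape)


def fit_polynomial_surface(image: ChannelImage) -> IlluminationSurface:
    """Least-squares quadratic fit of intensity on normalized coordinates.

    Degenerate grids (single row/column) make the design rank-deficient;
    the minimum-norm pseudo-inverse solution is returned with a warning.
    """
    if image.pixels.size < 6:
        raise ValueError("need at least 6 pixels to fit a quadratic surface")
    A = _design_matrix(image.shape)
    coef, _, rank, _ = np.linalg.lstsq(A, image.pixels.ravel(), rcond=None)
    if rank < 6:
        warnings.warn(
            f"rank-deficient illumination fit (rank {rank}); using pseudo-inverse solution",
            stacklevel=2,
        )
    return IlluminationSurface(coef, image.shape)


def subtract_illumination(image: ChannelImage, surface: IlluminationSurface) -> ChannelImage:
    """corrected = max(image - surface, 0), metadata preserved."""
    if surface.shape != image.shape:
        raise ValueError(f"shape mismatch: image {image.shape} vs surface {surface.shape}")
    corrected = np.clip(image.pixels - surface.evaluate(), 0.0, None)
    return image.with_pixels(np.clip(corrected, 0.0, 1.0))


def correct_image(image: ChannelImage) -> ChannelImage:
    """Fit-and-subtract in one step (the per-image correction stage)."""
    return subtract_illumination(image, fit_polynomial_surface(image))
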