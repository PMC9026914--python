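"""Synthetic multi-channel plate generator with ground truth.

Renders Operetta-style fields for all five dyes so that every assay can
be exercised without a microscope:

* **hoechst** — elliptical nuclei;
* **mitoid_red** — a diffuse cell-body haze plus bright anti-aliased
  tubes radiating around each nucleus; with probability equal to the
  ``fragmentation`` parameter a tube is split into short segments;
* **mitopy1** — Gaussian puncta placed on the tubes, count per cell
  drawn Poisson(``puncta_density``);
* **jc10_orange** — aggregate dots on the tubes with amplitude
  proportional to ``polarization``;
* **jc10_green** — diffuse cytoplasmic haze with amplitude proportional
  to 1 - polarization.

A smooth quadratic illumination bias and Poisson–Gaussian noise are
added to every channel.  The same design and seed reproduce the plate
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .plate_io import ChannelImage, FieldImageSet, ImageKey, format_image_filename

__all__ = [
    "CHANNEL_MAP",
    "WellCondition",
    "PlateDesign",
    "CellTruth",
    "FieldGroundTruth",
    "PlateGroundTruth",
    "generate_field",
    "iter_fields",
    "generate_plate",
    "small_test_design",
]

#: Channel index -> dye name, matching the rendered TIFF channel numbers.
CHANNEL_MAP = {1: "hoechst", 2: "mitoid_red", 3: "mitopy1", 4: "jc10_orange", 5: "jc10_green"}


@dataclass(frozen=True)
class WellCondition:
    """One well's plate coordinates and generative condition parameters."""

    row: int
    column: int
    condition: str
    puncta_density: float = 2.0    # mean puncta per cell (H2O2 dose proxy)
    polarization: float = 1.0      # 1 = fully polarized; uncoupler lowers it
    fragmentation: float = 0.0     # per-tube splitting probability

    def __post_init__(self) -> None:
        if not (0 <= self.polarization <= 1 and 0 <= self.fragmentation <= 1):
            raise ValueError("polarization and fragmentation must be in [0, 1]")
        if self.puncta_density < 0:
            raise ValueError("puncta_density must be >= 0")


@dataclass(frozen=True)
class PlateDesign:
    """Plate layout and rendering parameters.

    Defaults emulate the acquisition this pipeline targets: 1080 x 1080
    16-bit fields at 0.299 µm/px with 15–40 cells per field and 60
    fields per well.  Cell geometry (radii in px) scales with the image
    size chosen.
    """

    wells: tuple[WellCondition, ...]
    fields_per_well: int = 60
    cells_per_field: tuple[int, int] = (15, 40)
    image_size: int = 1080
    pixel_size_um: float = 0.299
    bit_depth: int = 16
    nucleus_radius: tuple[float, float] = (18.0, 28.0)
    cell_radius: tuple[float, float] = (45.0, 70.0)
    tubes_per_cell: tuple[int, int] = (5, 9)
    illumination_bias: tuple[float, float, float, float, float, float] = (
        0.02, 0.015, -0.01, -0.015, 0.01, 0.005,
    )
    noise_gaussian: float = 0.004
    noise_poisson_scale: float = 5000.0  # effective full-scale photon count
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fields_per_well < 1 or self.image_size < 32:
            raise ValueError("invalid design")
        if self.cells_per_field[0] > self.cells_per_field[1]:
            raise ValueError("cells_per_field min > max")


def small_test_design(
    wells: tuple[WellCondition, ...],
    fields_per_well: int = 10,
    seed: int = 0,
) -> PlateDesign:
    """A scaled-down design (256-px fields, 4–7 cells) for fast runs."""
    return PlateDesign(
        wells=wells,
        fields_per_well=fields_per_well,
        cells_per_field=(4, 7),
        image_size=256,
        nucleus_radius=(7.0, 10.0),
        cell_radius=(19.0, 26.0),
        tubes_per_cell=(5, 8),
        seed=seed,
    )


@dataclass
class CellTruth:
    cell: int
    center: tuple[float, float]          # row, col
    nucleus_axes: tuple[float, float]
    cell_radius: float
    n_tubes: int
    n_segments: int                      # rendered mitochondrial segments
    n_puncta: int                        # rendered puncta centered in the cell
    polarization: float
    fragmentation: float


@dataclass
class FieldGroundTruth:
    well: tuple[int, int]
    field: int
    condition: str
    cells: list[CellTruth]
    illumination_coefficients: tuple[float, ...]
    n_cells_requested: int

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass
class PlateGroundTruth:
    fields: list[FieldGroundTruth] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.fields:
            for c in f.cells:
                rows.append(
                    dict(
                        row=f.well[0], column=f.well[1], field=f.field,
                        condition=f.condition, cell=c.cell,
                        center_r=c.center[0], center_c=c.center[1],
                        cell_radius=c.cell_radius, n_tubes=c.n_tubes,
                        n_segments=c.n_segments, n_puncta=c.n_puncta,
                        polarization=c.polarization, fragmentation=c.fragmentation,
                    )
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rendering primitives


def _stamp_gaussian(canvas: np.ndarray, r: float, c: float, sigma: float, amplitude: float) -> None:
    """Add an isotropic Gaussian spot in place, truncated at 4 sigma."""
    n = canvas.shape[0]
    half = int(np.ceil(4 * sigma))
    r0, r1 = max(0, int(r) - half), min(n, int(r) + half + 1)
    c0, c1 = max(0, int(c) - half), min(n, int(c) + half + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    canvas[r0:r1, c0:c1] += amplitude * np.exp(
        -((rr - r) ** 2 + (cc - c) ** 2) / (2 * sigma**2)
    )


def _tube_path(
    rng: np.random.Generator,
    center: tuple[float, float],
    start_radius: float,
    end_radius: float,
) -> np.ndarray:
    """Sample points along one gently curving tube radiating from a cell center."""
    theta0 = rng.uniform(0, 2 * np.pi)
    curvature = rng.normal(0.0, 0.35)
    n_pts = 80
    t = np.linspace(0.0, 1.0, n_pts)
    radius = start_radius + t * (end_radius - start_radius)
    theta = theta0 + curvature * t
    rr = center[0] + radius * np.sin(theta)
    cc = center[1] + radius * np.cos(theta)
    return np.column_stack([rr, cc])


def _draw_path(canvas: np.ndarray, pts: np.ndarray, amplitude: float) -> np.ndarray:
    """Rasterize a polyline with bilinear (anti-aliased) point splatting."""
    n = canvas.shape[0]
    # densify so consecutive samples are < 0.5 px apart
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = seg.sum()
    n_samples = max(int(total * 2), 2)
    t = np.linspace(0, 1, n_samples)
    cum = np.concatenate([[0], np.cumsum(seg)]) / max(total, 1e-9)
    rr = np.interp(t, cum, pts[:, 0])
    cc = np.interp(t, cum, pts[:, 1])
    mask = (rr >= 0) & (rr < n - 1) & (cc >= 0) & (cc < n - 1)
    rr, cc = rr[mask], cc[mask]
    stamp = np.zeros_like(canvas)
    r0, c0 = np.floor(rr).astype(int), np.floor(cc).astype(int)
    fr, fc = rr - r0, cc - c0
    np.maximum.at(stamp, (r0, c0), amplitude * (1 - fr) * (1 - fc))
    np.maximum.at(stamp, (r0 + 1, c0), amplitude * fr * (1 - fc))
    np.maximum.at(stamp, (r0, c0 + 1), amplitude * (1 - fr) * fc)
    np.maximum.at(stamp, (r0 + 1, c0 + 1), amplitude * fr * fc)
    np.maximum(canvas, stamp, out=canvas)
    return canvas


def _quadratic_surface(coefficients: tuple[float, ...], n: int) -> np.ndarray:
    a, b, c, d, e, f = coefficients
    x = np.linspace(0, 1, n)
    X, Y = np.meshgrid(x, x)
    return a + b * X + c * Y + d * X**2 + e * Y**2 + f * X * Y


# ---------------------------------------------------------------------------
# field rendering


def _place_cells(
    rng: np.random.Generator, design: PlateDesign, n_cells: int
) -> list[tuple[float, float, float]]:
    """Non-overlapping (row, col, cell_radius) placements with bounded retries."""
    n = design.image_size
    placed: list[tuple[float, float, float]] = []
    attempts = 0
    while len(placed) < n_cells and attempts < n_cells * 60:
        attempts += 1
        radius = rng.uniform(*design.cell_radius)
        margin = radius * 0.6
        r = rng.uniform(margin, n - margin)
        c = rng.uniform(margin, n - margin)
        if all(np.hypot(r - pr, c - pc) > 0.85 * (radius + prad) for pr, pc, prad in placed):
            placed.append((r, c, radius))
    return placed


def generate_field(
    design: PlateDesign, well: WellCondition, field_index: int
) -> tuple[FieldImageSet, FieldGroundTruth]:
    """Render one field of all five channels plus its ground truth."""
    n = design.image_size
    rng = np.random.default_rng(
        [design.seed & 0x7FFFFFFF, well.row, well.column, field_index]
    )
    n_cells_requested = int(rng.integers(design.cells_per_field[0], design.cells_per_field[1] + 1))
    placements = _place_cells(rng, design, n_cells_requested)

    hoechst = np.zeros((n, n))
    mito_tubes = np.zeros((n, n))
    mito_dots = np.zeros((n, n))
    mitopy = np.zeros((n, n))
    orange = np.zeros((n, n))
    green = np.zeros((n, n))
    cell_haze = np.zeros((n, n))

    Y, X = np.mgrid[0:n, 0:n]
    cells: list[CellTruth] = []

    for idx, (cr, cc, cell_rad) in enumerate(placements, start=1):
        ax_r = rng.uniform(*design.nucleus_radius)
        ax_c = rng.uniform(*design.nucleus_radius)
        angle = rng.uniform(0, np.pi)
        ca, sa = np.cos(angle), np.sin(angle)
        dr, dc = Y - cr, X - cc
        u = (dr * ca + dc * sa) / ax_r
        v = (-dr * sa + dc * ca) / ax_c
        nucleus = u**2 + v**2 <= 1.0
        hoechst[nucleus] = np.maximum(hoechst[nucleus], rng.uniform(0.55, 0.7))

        body = dr**2 + dc**2 <= cell_rad**2
        cell_haze[body] = np.maximum(cell_haze[body], 1.0)

        # mitochondrial tubes in the perinuclear-to-periphery annulus
        n_tubes = int(rng.integers(design.tubes_per_cell[0], design.tubes_per_cell[1] + 1))
        start_rad = max(ax_r, ax_c) * 1.1
        tube_pixels: list[np.ndarray] = []
        n_segments = 0
        for _ in range(n_tubes):
            pts = _tube_path(rng, (cr, cc), start_rad, cell_rad * rng.uniform(0.8, 0.95))
            if rng.uniform() < well.fragmentation:
                # fission: the tube collapses into punctate fragments along its path
                n_dots = int(rng.integers(2, 4))
                # spaced picks along the path so fragments stay separate
                picks = np.linspace(5, len(pts) - 6, n_dots).astype(int)
                picks += rng.integers(-4, 5, size=n_dots)
                picks = np.clip(picks, 0, len(pts) - 1)
                for pr, pc in pts[picks]:
                    if 0 <= pr < n and 0 <= pc < n:
                        _stamp_gaussian(mito_dots, pr, pc, sigma=0.8, amplitude=1.0)
                        n_segments += 1
                tube_pixels.append(pts[picks])
            else:
                _draw_path(mito_tubes, pts, amplitude=1.0)
                tube_pixels.append(pts)
                n_segments += 1

        # H2O2 puncta on tubes
        n_puncta = int(rng.poisson(well.puncta_density))
        n_rendered = 0
        if tube_pixels and n_puncta > 0:
            allpts = np.vstack(tube_pixels)
            for _ in range(n_puncta):
                pr, pc = allpts[rng.integers(len(allpts))]
                if 0 <= pr < n and 0 <= pc < n:
                    _stamp_gaussian(mitopy, pr, pc, sigma=2.0, amplitude=rng.uniform(0.45, 0.6))
                    n_rendered += 1

        # JC-10 aggregates on tubes, amplitude follows polarization
        if tube_pixels:
            allpts = np.vstack(tube_pixels)
            n_agg = max(3, n_tubes * 3)
            amp = 0.15 + 0.55 * well.polarization
            for _ in range(n_agg):
                pr, pc = allpts[rng.integers(len(allpts))]
                _stamp_gaussian(orange, pr, pc, sigma=1.3, amplitude=amp * rng.uniform(0.8, 1.2))

        # JC-10 monomer haze over the whole cell, stronger when depolarized
        green_amp = 0.12 + 0.30 * (1.0 - well.polarization)
        green[body] = np.maximum(green[body], green_amp * rng.uniform(0.9, 1.1))

        cells.append(
            CellTruth(
                cell=idx, center=(cr, cc), nucleus_axes=(ax_r, ax_c),
                cell_radius=cell_rad, n_tubes=n_tubes, n_segments=n_segments,
                n_puncta=n_rendered, polarization=well.polarization,
                fragmentation=well.fragmentation,
            )
        )

    # soften edges; tubes keep ~2-3 px width after blur
    hoechst = ndimage.gaussian_filter(hoechst, 1.2)
    # tubes are rendered wider (sigma 1.1) than fission puncta (sigma ~0.9
    # total): intact mitochondria are tubular, fragments punctate and smaller
    mito = (
        ndimage.gaussian_filter(mito_tubes, 1.1) * 1.3
        + ndimage.gaussian_filter(mito_dots, 0.4) * 0.72
    )
    mitopy = ndimage.gaussian_filter(mitopy, 0.5)
    orange = ndimage.gaussian_filter(orange, 0.5)
    green = ndimage.gaussian_filter(green, 2.0)
    haze = ndimage.gaussian_filter(cell_haze, 3.0)
    mito += 0.06 * haze          # out-of-focus cytoplasmic light
    green += 0.02 * haze
    mitopy += 0.015 * haze

    bias = _quadratic_surface(design.illumination_bias, n)
    channels: dict[str, np.ndarray] = {
        "hoechst": hoechst, "mitoid_red": mito, "mitopy1": mitopy,
        "jc10_orange": orange, "jc10_green": green,
    }
    dye_to_channel = {v: k for k, v in CHANNEL_MAP.items()}
    images: dict[str, ChannelImage] = {}
    scale = 2**design.bit_depth - 1
    for dye, raw in channels.items():
        signal = np.clip(raw + 0.02 + bias, 0.0, 1.0)
        noisy = rng.poisson(signal * design.noise_poisson_scale) / design.noise_poisson_scale
        noisy = noisy + rng.normal(0.0, design.noise_gaussian, size=signal.shape)
        quantized = np.round(np.clip(noisy, 0.0, 1.0) * scale) / scale
        key = ImageKey(
            row=well.row, column=well.column, field=field_index,
            time=1, stack=1, channel=dye_to_channel[dye],
        )
        images[dye] = ChannelImage(
            key, quantized, bit_depth=design.bit_depth, pixel_size_um=design.pixel_size_um
        )

    truth = FieldGroundTruth(
        well=(well.row, well.column), field=field_index, condition=well.condition,
        cells=cells, illumination_coefficients=design.illumination_bias,
        n_cells_requested=n_cells_requested,
    )
    return FieldImageSet(well=(well.row, well.column), field=field_index, channels=images), truth


def iter_fields(design: PlateDesign) -> Iterator[tuple[FieldImageSet, FieldGroundTruth]]:
    """Render every field of the plate in deterministic order."""
    for well in design.wells:
        for f in range(1, design.fields_per_well + 1):
            yield generate_field(design, well, f)


def generate_plate(design: PlateDesign, out_dir: str | Path, overwrite: bool = False) -> pd.DataFrame:
    """Write all TIFFs, the ground-truth CSV and a manifest to a directory.

    Returns the manifest (one row per file with its plate coordinates and
    condition).  Refuses to write into a non-empty directory unless
    ``overwrite`` is set.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"output directory not empty: {out_dir} (pass overwrite=True)")

    scale = 2**design.bit_depth - 1
    dtype = np.uint8 if design.bit_depth == 8 else np.uint16
    manifest_rows = []
    truth = PlateGroundTruth()
    for field_set, field_truth in iter_fields(design):
        truth.fields.append(field_truth)
        for dye, im in field_set.channels.items():
            name = format_image_filename(im.key)
            tifffile.imwrite(out_dir / name, np.round(im.pixels * scale).astype(dtype))
            manifest_rows.append(
                dict(
                    filename=name, row=im.key.row, column=im.key.column,
                    field=im.key.field, channel=im.key.channel, dye=dye,
                    condition=field_truth.condition,
                )
            )
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    truth.to_frame().to_csv(out_dir / "truth.csv", index=False)
    return manifest
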