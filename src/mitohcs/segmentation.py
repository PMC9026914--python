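"""Object segmentation: thresholds, nuclei, cells, cytoplasm, filtering.

The segmentation front end shared by all three assays follows the classic
high-content-screening hierarchy:

* **primary objects** — nuclei, from the DNA stain, by global or adaptive
  histogram thresholding (Otsu two/three-class, minimum cross-entropy);
* **secondary objects** — whole cells, grown from each nucleus by
  propagation (seeded shortest-path region growing restricted to the
  above-threshold region of a cytoplasmic channel);
* **tertiary objects** — cytoplasm, the per-cell set difference
  secondary minus primary.

All threshold methods operate on a fixed 256-bin histogram over [0, 1]
so that results are independent of camera bit depth.  Object labels are
positive integers with 0 = background; 8-connectivity throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .plate_io import ChannelImage

__all__ = [
    "N_BINS",
    "ThresholdSpec",
    "LabelMap",
    "compute_threshold",
    "apply_threshold",
    "identify_primary",
    "identify_secondary_propagation",
    "identify_tertiary",
    "measure_objects",
    "filter_objects",
]

N_BINS = 256
_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity structuring element


@dataclass(frozen=True)
class ThresholdSpec:
    """How to turn an intensity image into foreground/background.

    Parameters
    ----------
    scope
        ``"global"`` computes one threshold for the whole image;
        ``"adaptive"`` computes per-window thresholds on a block grid and
        interpolates them to a per-pixel threshold surface.
    method
        ``"otsu2"`` maximizes two-class between-class variance; ``"otsu3"``
        maximizes three-class between-class variance and assigns the middle
        class per ``middle_class``; ``"min_cross_entropy"`` minimizes the
        Li cross-entropy criterion; ``"manual"`` uses ``manual_value``.
    middle_class
        For ``otsu3`` only: whether the middle intensity class counts as
        foreground (keeps dim puncta) or background (suppresses dim debris).
    window
        Adaptive window size in px (odd, >= 3).
    bounds
        (lower, upper) clamp applied to the computed threshold(s).
    """

    scope: Literal["global", "adaptive"] = "global"
    method: Literal["otsu2", "otsu3", "min_cross_entropy", "manual"] = "otsu2"
    middle_class: Literal["foreground", "background"] = "background"
    window: int = 51
    manual_value: float | None = None
    bounds: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.scope not in ("global", "adaptive"):
            raise ValueError(f"unknown scope {self.scope!r}")
        if self.method not in ("otsu2", "otsu3", "min_cross_entropy", "manual"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.bounds[0] > self.bounds[1]:
            raise ValueError("bounds lower > upper")
        if (self.method == "manual") != (self.manual_value is not None):
            raise ValueError("manual_value must be set iff method='manual'")


@dataclass
class LabelMap:
    """Integer-labeled objects on a pixel grid; 0 is background."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer")
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")

    @property
    def n_objects(self) -> int:
        return len(self.label_ids)

    @property
    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def as_mask(self) -> np.ndarray:
        return self.labels > 0

    def relabel(self) -> "LabelMap":
        """Compact labels to 1..n preserving the order of the original ids."""
        ids = self.label_ids
        lut = np.zeros(int(self.labels.max(initial=0)) + 1, dtype=self.labels.dtype)
        lut[ids] = np.arange(1, len(ids) + 1)
        return LabelMap(lut[self.labels])


# ---------------------------------------------------------------------------
# histogram thresholds


def _plateau_mid(indices: np.ndarray) -> int:
    """Middle element of the tied-optimum plateau.

    Histograms with an empty gap between modes make every cut inside the
    gap equally optimal; taking the plateau midpoint places the threshold
    mid-gap instead of hugging one mode.
    """
    return int(indices[len(indices) // 2])


def _histogram(values: np.ndarray) -> np.ndarray:
    return np.bincount(
        np.clip((values * N_BINS).astype(np.int64), 0, N_BINS - 1), minlength=N_BINS
    ).astype(np.float64)


def _otsu2_from_hist(hist: np.ndarray) -> float:
    """Cut maximizing between-class variance; returns the bin-edge threshold."""
    p = hist / hist.sum()
    centers = (np.arange(N_BINS) + 0.5) / N_BINS
    w0 = np.cumsum(p)[:-1]          # weight of bins <= t, for t = 0..254
    w1 = 1.0 - w0
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * w0 - mu[:-1]) ** 2 / (w0 * w1)
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    best = sigma_b.max()
    t = _plateau_mid(np.flatnonzero(sigma_b >= best - 1e-12 * max(abs(best), 1.0)))
    return (t + 1) / N_BINS


def _otsu3_from_hist(hist: np.ndarray, middle_class: str) -> float:
    """Two cuts maximizing three-class between-class variance.

    Returns the effective foreground threshold: the lower cut if the
    middle class counts as foreground, the upper cut otherwise.
    """
    p = hist / hist.sum()
    centers = (np.arange(N_BINS) + 0.5) / N_BINS
    W = np.concatenate([[0.0], np.cumsum(p)])            # W[i] = sum p[:i]
    M = np.concatenate([[0.0], np.cumsum(p * centers)])  # M[i] = sum (p c)[:i]

    # class k spans bins [i, j); between-class variance = sum_k w_k m_k^2 - mu^2,
    # maximized over all cut pairs (t1, t2), vectorized on a (t1, t2) grid.
    t1 = np.arange(1, N_BINS - 1)      # last bin of class 0 is t1 - 1
    t2 = np.arange(2, N_BINS)          # last bin of class 1 is t2 - 1
    T1, T2 = np.meshgrid(t1, t2, indexing="ij")
    valid = T1 < T2

    def cls(lo, hi):
        w = W[hi] - W[lo]
        m = M[hi] - M[lo]
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(w > 0, m**2 / np.maximum(w, 1e-300), 0.0)
        return out

    score = cls(np.zeros_like(T1), T1) + cls(T1, T2) + cls(T2, np.full_like(T2, N_BINS))
    score = np.where(valid, score, -np.inf)
    best = score.max()
    tied = np.argwhere(score >= best - 1e-12 * max(abs(best), 1.0))
    # the relevant cut for the effective threshold takes its plateau midpoint
    if middle_class == "foreground":
        eff = _plateau_mid(np.sort(np.unique(t1[tied[:, 0]])))
    else:
        eff = _plateau_mid(np.sort(np.unique(t2[tied[:, 1]])))
    return eff / N_BINS


def _li_from_hist(hist: np.ndarray) -> float:
    """Minimum-cross-entropy (Li) threshold by exhaustive histogram search."""
    centers = (np.arange(N_BINS) + 0.5) / N_BINS
    w = hist * centers
    Wlow = np.cumsum(hist)[:-1]
    Slow = np.cumsum(w)[:-1]
    Whigh = hist.sum() - Wlow
    Shigh = w.sum() - Slow
    with np.errstate(divide="ignore", invalid="ignore"):
        mu_low = Slow / Wlow
        mu_high = Shigh / Whigh
        eta = -np.where(Slow > 0, Slow * np.log(mu_low), 0.0) - np.where(
            Shigh > 0, Shigh * np.log(mu_high), 0.0
        )
    eta[~np.isfinite(eta)] = np.inf
    best = eta.min()
    t = _plateau_mid(np.flatnonzero(eta <= best + 1e-12 * max(abs(best), 1.0)))
    return (t + 1) / N_BINS


def _threshold_from_values(values: np.ndarray, spec: ThresholdSpec) -> float:
    if spec.method == "manual":
        thr = float(spec.manual_value)  # type: ignore[arg-type]
    else:
        vmin, vmax = float(values.min()), float(values.max())
        if vmax - vmin < 1.0 / N_BINS:
            warnings.warn("degenerate histogram: (near-)constant image", stacklevel=3)
            thr = vmax
        else:
            hist = _histogram(values)
            if spec.method == "otsu2":
                thr = _otsu2_from_hist(hist)
            elif spec.method == "otsu3":
                thr = _otsu3_from_hist(hist, spec.middle_class)
            else:
                thr = _li_from_hist(hist)
    return float(np.clip(thr, *spec.bounds))


def compute_threshold(image: ChannelImage, spec: ThresholdSpec) -> float | np.ndarray:
    """Scalar threshold (global scope) or per-pixel threshold grid (adaptive).

    Foreground is the set of pixels strictly above the threshold.
    """
    if image.pixels.size == 0:
        raise ValueError("empty image")
    if spec.scope == "global":
        return _threshold_from_values(image.pixels.ravel(), spec)

    # adaptive: per-block thresholds on a coarse grid, bilinearly
    # interpolated back to full resolution.  Blocks containing no real
    # foreground would otherwise threshold into the noise floor, so block
    # thresholds are clamped to [0.7, 1.5] x the global threshold.
    nr, nc = image.shape
    w = spec.window
    nbr, nbc = max(1, int(np.ceil(nr / w))), max(1, int(np.ceil(nc / w)))
    coarse = np.empty((nbr, nbc))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-block degenerate histograms are routine
        global_thr = _threshold_from_values(image.pixels.ravel(), spec)
        for i in range(nbr):
            for j in range(nbc):
                block = image.pixels[i * w : (i + 1) * w, j * w : (j + 1) * w]
                if block.max() - block.min() < 1.0 / N_BINS:
                    coarse[i, j] = global_thr  # flat block: fall back to global
                else:
                    coarse[i, j] = _threshold_from_values(block.ravel(), spec)
    coarse = np.clip(coarse, 0.7 * global_thr, 1.5 * global_thr)
    if (nbr, nbc) == (1, 1):
        grid = np.full((nr, nc), coarse[0, 0])
    else:
        zoom = (nr / nbr, nc / nbc)
        grid = ndimage.zoom(coarse, zoom, order=1, mode="nearest", grid_mode=True)
        grid = grid[:nr, :nc]
    return np.clip(grid, *spec.bounds)


def apply_threshold(image: ChannelImage, spec: ThresholdSpec) -> np.ndarray:
    """Boolean foreground mask: pixels strictly above the threshold."""
    thr = compute_threshold(image, spec)
    return image.pixels > thr


# ---------------------------------------------------------------------------
# object identification


def _label(mask: np.ndarray) -> np.ndarray:
    labels, _ = ndimage.label(mask, structure=_EIGHT)
    return labels


def identify_primary(
    image: ChannelImage,
    spec: ThresholdSpec,
    diameter_range: tuple[float, float],
    fill_holes: bool = True,
    exclude_border: bool = False,
) -> LabelMap:
    """Threshold, label connected components, filter by equivalent diameter.

    ``diameter_range`` is (min, max) equivalent diameter in px, inclusive.
    Components touching the image edge are discarded if ``exclude_border``.
    Surviving objects are relabeled 1..n.
    """
    dmin, dmax = diameter_range
    if dmin > dmax:
        raise ValueError("diameter min > max")
    mask = apply_threshold(image, spec)
    if fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    labels = _label(mask)
    n = labels.max()
    if n == 0:
        return LabelMap(labels)
    areas = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    diam = np.sqrt(4.0 * areas / np.pi)
    keep = (diam >= dmin) & (diam <= dmax)
    if exclude_border:
        border = np.zeros_like(labels, dtype=bool)
        border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
        touching = np.unique(labels[border])
        keep[touching[touching > 0] - 1] = False
    lut = np.zeros(n + 1, dtype=labels.dtype)
    lut[1:][keep] = 1
    return LabelMap(lut[labels] * labels).relabel()


_SHIFTS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_STEP_LEN = {s: float(np.hypot(*s)) for s in _SHIFTS}


def identify_secondary_propagation(
    image: ChannelImage,
    seeds: LabelMap,
    spec: ThresholdSpec,
    regularization: float = 0.05,
    max_iter: int | None = None,
) -> LabelMap:
    """Grow each seed into the above-threshold region by propagation.

    Each above-threshold pixel joins the seed reachable at minimal
    accumulated cost, where one step from pixel p to neighbor q costs
    ``|I(p) - I(q)| + regularization * step_length`` (step length 1 for
    axial, sqrt(2) for diagonal moves).  Large regularization therefore
    approaches a geometric nearest-seed partition; small regularization
    lets intensity valleys draw the dividing lines.  Seed pixels always
    belong to their own object, so a seed entirely below the threshold
    yields a secondary object equal to the seed itself (with a warning).

    Shortest-path costs are computed by vectorized label-correcting
    relaxation (Bellman–Ford over the 8-neighbor grid), which converges
    to the exact Dijkstra solution since all step costs are >= 0.
    """
    if regularization < 0:
        raise ValueError("regularization must be >= 0")
    if seeds.shape != image.shape:
        raise ValueError("seed/image shape mismatch")
    if seeds.n_objects == 0:
        raise ValueError("no seeds")
    mask = apply_threshold(image, spec)
    seed_mask = seeds.as_mask()
    for sid in seeds.label_ids:
        if not mask[seeds.labels == sid].any():
            warnings.warn(f"seed {sid} entirely below threshold; object equals seed", stacklevel=2)
    region = mask | seed_mask

    I = image.pixels
    dist = np.full(image.shape, np.inf)
    dist[seed_mask] = 0.0
    labels = np.where(seed_mask, seeds.labels, 0)

    if max_iter is None:
        max_iter = 2 * (image.shape[0] + image.shape[1])

    def shifted(a, dr, dc, fill):
        out = np.full_like(a, fill)
        rs_src = slice(max(0, -dr), a.shape[0] - max(0, dr))
        cs_src = slice(max(0, -dc), a.shape[1] - max(0, dc))
        rs_dst = slice(max(0, dr), a.shape[0] - max(0, -dr))
        cs_dst = slice(max(0, dc), a.shape[1] - max(0, -dc))
        out[rs_dst, cs_dst] = a[rs_src, cs_src]
        return out

    for _ in range(max_iter):
        best = dist.copy()
        best_lab = labels.copy()
        for dr, dc in _SHIFTS:
            nd = shifted(dist, dr, dc, np.inf)
            nl = shifted(labels, dr, dc, 0)
            nI = shifted(I, dr, dc, np.inf)
            cand = nd + np.abs(I - nI) + regularization * _STEP_LEN[(dr, dc)]
            better = region & (cand < best - 1e-12) & (nl > 0)
            best = np.where(better, cand, best)
            best_lab = np.where(better, nl, best_lab)
        changed = best_lab != labels
        improved = best < dist - 1e-12
        if not (changed | improved).any():
            break
        dist, labels = best, best_lab

    labels = np.where(seed_mask, seeds.labels, labels)  # seeds keep their own id
    return LabelMap(labels.astype(seeds.labels.dtype))


def identify_tertiary(secondary: LabelMap, primary: LabelMap) -> LabelMap:
    """Per-label set difference: cytoplasm_i = cell_i minus nucleus_i.

    Labels are matched by id and preserved in the output so that
    per-object area identities hold; primary labels with no matching
    secondary object are skipped with a warning.
    """
    if secondary.shape != primary.shape:
        raise ValueError("shape mismatch")
    sec_ids = set(secondary.label_ids.tolist())
    orphans = [int(i) for i in primary.label_ids if int(i) not in sec_ids]
    if orphans:
        warnings.warn(f"primary labels without matching secondary object skipped: {orphans}",
                      stacklevel=2)
    out = secondary.labels.copy()
    remove = (primary.labels > 0) & (primary.labels == secondary.labels)
    out[remove] = 0
    return LabelMap(out)


# ---------------------------------------------------------------------------
# measurements and filtering


def measure_objects(
    labels: LabelMap,
    channels: Mapping[str, ChannelImage] | None = None,
) -> pd.DataFrame:
    """Per-object features: area, centroid, equivalent diameter, eccentricity,
    border contact, and mean/integrated intensity for each named channel.

    Returns one row per object, indexed by label id.
    """
    from skimage.measure import regionprops_table

    ids = labels.label_ids
    if len(ids) == 0:
        cols = ["area", "centroid_r", "centroid_c", "equivalent_diameter",
                "eccentricity", "touches_border"]
        if channels:
            for name in channels:
                cols += [f"mean_{name}", f"integrated_{name}"]
        return pd.DataFrame(columns=cols, index=pd.Index([], name="label"))

    props = regionprops_table(
        labels.labels,
        properties=("label", "area", "centroid", "equivalent_diameter", "eccentricity"),
    )
    df = pd.DataFrame(props).set_index("label")
    df = df.rename(columns={"centroid-0": "centroid_r", "centroid-1": "centroid_c"})

    border = np.zeros(labels.shape, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    touching = set(np.unique(labels.labels[border]).tolist()) - {0}
    df["touches_border"] = [int(i) in touching for i in df.index]

    if channels:
        for name, im in channels.items():
            means = ndimage.mean(im.pixels, labels.labels, index=df.index.to_numpy())
            df[f"mean_{name}"] = means
            df[f"integrated_{name}"] = means * df["area"].to_numpy()
    return df


def filter_objects(
    labels: LabelMap,
    measurements: pd.DataFrame,
    criteria: Sequence[tuple[str, float, float]] = (),
    drop_border: bool = False,
) -> LabelMap:
    """Remove objects failing any (feature, min, max) criterion.

    Survivors are relabeled 1..n preserving their original order.
    Applying the same criteria twice is a no-op on the surviving set.
    """
    keep = pd.Series(True, index=measurements.index)
    for feature, lo, hi in criteria:
        if feature not in measurements.columns:
            raise KeyError(
                f"unknown feature {feature!r}; available: {sorted(measurements.columns)}"
            )
        keep &= (measurements[feature] >= lo) & (measurements[feature] <= hi)
    if drop_border and "touches_border" in measurements.columns:
        keep &= ~measurements["touches_border"].astype(bool)
    kept_ids = measurements.index[keep].to_numpy()
    lut = np.zeros(int(labels.labels.max(initial=0)) + 1, dtype=labels.labels.dtype)
    lut[kept_ids] = 1
    return LabelMap(lut[labels.labels] * labels.labels).relabel()
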