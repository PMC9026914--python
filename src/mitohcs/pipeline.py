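"""Per-field assay pipelines: raw channels to per-cell metric rows.

Each assay shares the same front end — illumination correction, nucleus
identification, propagation of cells from nuclei on a cytoplasmic
channel, object filtering, cytoplasm by set difference — and then runs
its specific quantification.  Output is one tidy DataFrame row per cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import assay_h2o2, assay_mmp, assay_morphology
from .config import AnalysisConfig
from .illumination import correct_image
from .plate_io import ChannelImage, FieldImageSet
from .segmentation import (
    LabelMap,
    ThresholdSpec,
    identify_primary,
    identify_secondary_propagation,
    identify_tertiary,
    measure_objects,
)

__all__ = ["FieldSegmentation", "segment_field", "analyze_field", "ASSAY_CHANNELS"]

#: Dyes each assay requires.
ASSAY_CHANNELS = {
    "h2o2": ("hoechst", "mitoid_red", "mitopy1"),
    "mmp": ("hoechst", "jc10_orange", "jc10_green"),
    "morphology": ("hoechst", "mitoid_red"),
}


@dataclass
class FieldSegmentation:
    """Shared segmentation products of one field."""

    nuclei: LabelMap
    cells: LabelMap
    cytoplasm: LabelMap


def _corrected(image: ChannelImage, config: AnalysisConfig) -> ChannelImage:
    return correct_image(image) if config.illumination_correction else image


def _filter_matched(
    cells: LabelMap,
    nuclei: LabelMap,
    cell_channel: ChannelImage,
    config: AnalysisConfig,
) -> tuple[LabelMap, LabelMap]:
    """Filter cells by size/shape/border and relabel cells and nuclei together.

    Cell labels equal their seed nucleus labels, so both maps get the same
    label LUT and the correspondence survives the filtering.
    """
    meas = measure_objects(cells, {"cell": cell_channel})
    if meas.empty:
        return cells, nuclei
    keep = (
        (meas["area"] >= config.nucleus_area[0] * 0.5)  # cells are at least half a nucleus
        & (meas["eccentricity"] <= config.max_eccentricity)
    )
    if config.drop_border_cells:
        keep &= ~meas["touches_border"].astype(bool)
    kept_ids = meas.index[keep].to_numpy()
    top = int(max(cells.labels.max(initial=0), nuclei.labels.max(initial=0)))
    lut = np.zeros(top + 1, dtype=cells.labels.dtype)
    lut[kept_ids] = np.arange(1, len(kept_ids) + 1)
    return LabelMap(lut[cells.labels]), LabelMap(lut[nuclei.labels])


def segment_field(
    field_set: FieldImageSet,
    cell_dye: str,
    config: AnalysisConfig,
    dyes: tuple[str, ...] | None = None,
) -> tuple[FieldSegmentation, dict[str, ChannelImage]]:
    """Nuclei, cells and cytoplasm for one field; returns corrected channels too.

    ``dyes`` limits illumination correction to the channels an assay uses.
    """
    wanted = set(dyes) | {"hoechst", cell_dye} if dyes else set(field_set.channels)
    corrected = {
        dye: _corrected(im, config)
        for dye, im in field_set.channels.items()
        if dye in wanted
    }
    hoechst = corrected["hoechst"]
    nuclei = identify_primary(
        hoechst, config.nucleus_spec, config.nucleus_diameter, fill_holes=True
    )
    if nuclei.n_objects == 0:
        empty = LabelMap(np.zeros(hoechst.shape, dtype=np.int32))
        return FieldSegmentation(empty, empty, empty), corrected
    meas = measure_objects(nuclei)
    keep = (meas["area"] >= config.nucleus_area[0]) & (meas["area"] <= config.nucleus_area[1])
    kept_ids = meas.index[keep].to_numpy()
    lut = np.zeros(int(nuclei.labels.max()) + 1, dtype=nuclei.labels.dtype)
    lut[kept_ids] = np.arange(1, len(kept_ids) + 1)
    nuclei = LabelMap(lut[nuclei.labels])
    if nuclei.n_objects == 0:
        empty = LabelMap(np.zeros(hoechst.shape, dtype=np.int32))
        return FieldSegmentation(empty, empty, empty), corrected

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-seed below-threshold warnings are routine
        cells = identify_secondary_propagation(
            corrected[cell_dye], nuclei, config.cell_spec, config.propagation_regularization
        )
    cells, nuclei = _filter_matched(cells, nuclei, corrected[cell_dye], config)
    cytoplasm = identify_tertiary(cells, nuclei)
    return FieldSegmentation(nuclei, cells, cytoplasm), corrected


def _base_row(field_set: FieldImageSet, cell: int) -> dict:
    return dict(row=field_set.well[0], column=field_set.well[1],
                field=field_set.field, cell=cell)


def analyze_field(field_set: FieldImageSet, assay: str, config: AnalysisConfig) -> pd.DataFrame:
    """Run one assay on one field; one row per included cell.

    Raises KeyError naming the missing dyes if the field is incomplete
    for the assay.
    """
    if assay not in ASSAY_CHANNELS:
        raise ValueError(f"unknown assay {assay!r}; choose from {sorted(ASSAY_CHANNELS)}")
    missing = field_set.missing(ASSAY_CHANNELS[assay])
    if missing:
        raise KeyError(f"incomplete field {field_set.well}/{field_set.field}: missing {missing}")
    if assay == "h2o2":
        return _analyze_h2o2(field_set, config)
    if assay == "mmp":
        return _analyze_mmp(field_set, config)
    return _analyze_morphology(field_set, config)


def _analyze_h2o2(field_set: FieldImageSet, config: AnalysisConfig) -> pd.DataFrame:
    seg, corrected = segment_field(field_set, "mitoid_red", config, ASSAY_CHANNELS["h2o2"])
    p = config.h2o2
    enhanced = assay_h2o2.enhance_speckles(corrected["mitopy1"], p.feature_size)
    puncta = assay_h2o2.detect_puncta(enhanced, diameter_range=p.puncta_diameter)
    puncta = assay_h2o2.relate_puncta_to_cells(puncta, seg.cells)
    mito_mask = corrected["mitoid_red"].pixels > _scalar_threshold(
        corrected["mitoid_red"], config.mito_mask_spec
    )
    results, n_excluded = assay_h2o2.mito_h2o2_level(
        puncta, mito_mask, seg.cells, denominator=p.denominator
    )
    rows = [
        {**_base_row(field_set, r.cell), "mito_area": r.mito_area, "coloc_area": r.coloc_area,
         "n_puncta": r.n_puncta, "h2o2_level": r.h2o2_level}
        for r in results
    ]
    df = pd.DataFrame(rows)
    df.attrs["n_excluded"] = n_excluded
    return df


def _analyze_mmp(field_set: FieldImageSet, config: AnalysisConfig) -> pd.DataFrame:
    seg, corrected = segment_field(field_set, "jc10_green", config, ASSAY_CHANNELS["mmp"])
    p = config.mmp
    aggregates = assay_mmp.detect_aggregates(
        corrected["jc10_orange"], diameter_range=p.aggregate_diameter
    )
    results, n_excluded = assay_mmp.mmp_ratio_per_cell(
        aggregates, seg.cells, corrected["jc10_orange"], corrected["jc10_green"],
        cells=seg.cells, monomer_mask_mode=p.monomer_mask_mode,
    )
    rows = [
        {**_base_row(field_set, r.cell), "aggregate_masked_area": r.aggregate_masked_area,
         "monomer_masked_area": r.monomer_masked_area, "mean_orange": r.mean_orange,
         "mean_green": r.mean_green, "mmp_ratio": r.mmp_ratio}
        for r in results
    ]
    df = pd.DataFrame(rows)
    df.attrs["n_excluded"] = n_excluded
    return df


def _analyze_morphology(field_set: FieldImageSet, config: AnalysisConfig) -> pd.DataFrame:
    from scipy import ndimage as ndi

    seg, corrected = segment_field(field_set, "mitoid_red", config, ASSAY_CHANNELS["morphology"])
    p = config.morphology
    enhanced = assay_morphology.enhance_tubeness(corrected["mitoid_red"], p.tubeness_sigma)
    mito = assay_morphology.segment_mitochondria(
        enhanced, manual_floor=p.manual_floor, diameter_range=p.mito_diameter
    )
    skel = assay_morphology.skeletonize_and_measure(mito, seg.cells, config.pixel_size_um)
    per_cell_len = skel.per_cell.set_index("cell") if len(skel.per_cell) else pd.DataFrame()

    if p.granularity_source == "binary":
        gran_source = corrected["mitoid_red"].with_pixels(mito.as_mask().astype(float))
    elif p.granularity_source == "enhanced":
        gran_source = enhanced
    else:
        gran_source = corrected["mitoid_red"]
    rows = []
    slices = ndi.find_objects(seg.cytoplasm.labels)
    for cid in seg.cytoplasm.label_ids:
        sl = slices[cid - 1]
        if sl is None:
            continue
        region = seg.cytoplasm.labels[sl] == cid
        crop = gran_source.with_pixels(gran_source.pixels[sl])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            spectrum = assay_morphology.granularity_spectrum(
                crop, region, subsample=p.granularity_subsample,
                element_size=p.granularity_element_size, length=p.granularity_length,
            )
        frag = assay_morphology.fragmentation_percent(spectrum, p.fragmentation_scales)
        row = _base_row(field_set, int(cid))
        row["fragmentation_percent"] = frag
        if len(per_cell_len) and cid in per_cell_len.index:
            row["n_mitochondria"] = int(per_cell_len.loc[cid, "n_mitochondria"])
            row["mean_length_px"] = per_cell_len.loc[cid, "mean_length_px"]
            row["mean_length_um"] = per_cell_len.loc[cid, "mean_length_um"]
        else:
            row["n_mitochondria"] = 0
            row["mean_length_px"] = np.nan
            row["mean_length_um"] = np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["n_excluded"] = 0
    return df


def _scalar_threshold(image: ChannelImage, spec: ThresholdSpec) -> float:
    from .segmentation import compute_threshold

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        thr = compute_threshold(image, spec)
    return float(np.asarray(thr).mean())
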