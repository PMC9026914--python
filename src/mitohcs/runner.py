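"""End-to-end command execution: simulate / analyze / stats.

Thin orchestration over the library: loads a plate directory, runs an
assay field by field, aggregates, and writes CSV artifacts plus a plain
run log.  Deterministic for a fixed config and seed.
"""

from __future__ import annotations

import datetime
import warnings
from pathlib import Path

import pandas as pd

from .config import AnalysisConfig
from .pipeline import ASSAY_CHANNELS, analyze_field
from .plate_io import group_image_set, load_channel_image
from .stats_report import compare_groups
from .synthetic_plate import PlateDesign, generate_plate

__all__ = ["run_pipeline", "analyze_plate_dir", "METRIC_BY_ASSAY"]

METRIC_BY_ASSAY = {"h2o2": "h2o2_level", "mmp": "mmp_ratio", "morphology": "fragmentation_percent"}


def _log(out_dir: Path, lines: list[str]) -> None:
    stamp = datetime.datetime.now().isoformat(timespec="seconds")
    with open(out_dir / "run.log", "a") as fh:
        for line in lines:
            fh.write(f"{stamp} {line}\n")


def analyze_plate_dir(
    input_dir: str | Path,
    assay: str,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Run one assay over every complete field in a plate directory.

    Conditions are joined from ``manifest.csv`` when present; otherwise
    each well is its own condition (``r<row>c<col>``).  Incomplete fields
    are skipped and counted.
    """
    config = config or AnalysisConfig()
    input_dir = Path(input_dir)
    paths = sorted(input_dir.glob("*.tif"))
    if not paths:
        raise FileNotFoundError(f"no .tif files in {input_dir}")
    images = [load_channel_image(p, config.pixel_size_um) for p in paths]
    fields = group_image_set(images, config.channel_map)

    condition_of: dict[tuple[int, int], str] = {}
    manifest_path = input_dir / "manifest.csv"
    if manifest_path.exists():
        man = pd.read_csv(manifest_path)
        for _, r in man.iterrows():
            condition_of[(int(r["row"]), int(r["column"]))] = str(r["condition"])

    frames = []
    n_skipped = 0
    for fs in fields:
        if fs.missing(ASSAY_CHANNELS[assay]):
            n_skipped += 1
            continue
        df = analyze_field(fs, assay, config)
        if len(df):
            frames.append(df)
    if not frames:
        per_cell = pd.DataFrame()
    else:
        per_cell = pd.concat(frames, ignore_index=True)
        per_cell["condition"] = [
            condition_of.get((r, c), f"r{r}c{c}")
            for r, c in zip(per_cell["row"], per_cell["column"])
        ]
    per_cell.attrs["n_skipped_fields"] = n_skipped
    return per_cell


def run_pipeline(
    command: str,
    out_dir: str | Path,
    input_dir: str | Path | None = None,
    config: AnalysisConfig | None = None,
    design: PlateDesign | None = None,
    metric: str | None = None,
    overwrite: bool = False,
) -> int:
    """Execute one pipeline command and write its artifacts.

    Commands: ``simulate`` (render a synthetic plate from ``design`` into
    ``out_dir``), ``h2o2`` / ``mmp`` / ``morphology`` (analyze the TIFFs
    in ``input_dir``, writing per-cell and per-well CSVs), ``stats``
    (read ``per_cell.csv`` from ``input_dir`` and write condition
    comparisons).  Returns 0 on success; raises on invalid input.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = config or AnalysisConfig()

    if command == "simulate":
        if design is None:
            raise ValueError("simulate requires a plate design")
        manifest = generate_plate(design, out_dir, overwrite=overwrite)
        _log(out_dir, [
            f"simulate: {len(manifest)} images, {len(design.wells)} wells, "
            f"{design.fields_per_well} fields/well, seed {design.seed}",
        ])
        return 0

    if command in METRIC_BY_ASSAY:
        if input_dir is None:
            raise ValueError(f"{command} requires an input directory")
        per_cell = analyze_plate_dir(input_dir, command, config)
        if per_cell.empty:
            raise RuntimeError("no data: no cells quantified in any field")
        per_cell.to_csv(out_dir / "per_cell.csv", index=False)
        m = metric or METRIC_BY_ASSAY[command]
        per_well = (
            per_cell.groupby(["condition", "row", "column"])[m]
            .agg(n="count", mean="mean")
            .reset_index()
        )
        per_well.to_csv(out_dir / "per_well.csv", index=False)
        _log(out_dir, [
            f"{command}: {len(per_cell)} cells, {per_cell.attrs.get('n_skipped_fields', 0)} "
            f"incomplete fields skipped",
            "note: wells are technical replicates of one plate (n=1 per condition "
            "at the plate level); per-well means emitted for well-level inference",
        ])
        return 0

    if command == "stats":
        if input_dir is None:
            raise ValueError("stats requires an input directory with per_cell.csv")
        path = Path(input_dir) / "per_cell.csv"
        per_cell = pd.read_csv(path) if path.exists() else pd.DataFrame()
        if per_cell.empty:
            raise RuntimeError(f"no data in {path}")
        if metric is None:
            candidates = [m for m in METRIC_BY_ASSAY.values() if m in per_cell.columns]
            if not candidates:
                raise ValueError("no known metric column found; pass one explicitly")
            metric = candidates[0]
        groups = {
            str(cond): grp[metric].dropna().to_numpy()
            for cond, grp in per_cell.groupby("condition")
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = compare_groups(groups)
        header = pd.DataFrame(
            [{"test": result.test, "metric": metric, "statistic": result.statistic,
              "p_value": result.p_value, "stars": result.stars}]
        )
        header.to_csv(out_dir / "comparison.csv", index=False)
        result.pairwise.to_csv(out_dir / "comparison_pairwise.csv", index=False)
        _log(out_dir, [f"stats: {result.test} on {metric}, p={result.p_value:.3g}"])
        return 0

    raise ValueError(f"unknown command {command!r}")
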