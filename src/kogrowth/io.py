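"""Readers and writers for the pipeline's plain-text formats.

Annotation TSV
    ``gene  start_bp  end_bp  strand  essential  category`` with 1-based
    inclusive bp coordinates and an optional header comment
    ``#genome_length_kb=<L>``.
Expression TSV
    ``gene  medium  rep1..repN  [mean]``.
Plate-reader CSV (one per plate)
    first column ``time_h``, remaining columns well ids ``A1``..``H12``.
Well-map CSV
    ``plate,well,strain,medium,replicate``; strain ``BLANK`` marks blank
    wells used for the per-plate blank estimate.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataFormatError
from .growth import GrowthCurve

__all__ = [
    "read_annotation",
    "write_annotation",
    "read_expression",
    "write_expression",
    "read_well_map",
    "write_well_map",
    "read_plate_csv",
    "write_plate_csv",
    "write_rate_table",
]

logger = logging.getLogger(__name__)

_ANNOTATION_COLS = ["gene", "start_bp", "end_bp", "strand", "essential", "category"]


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    L = annotation.attrs.get("genome_length_kb")
    out = annotation[_ANNOTATION_COLS].copy()
    out["essential"] = out["essential"].astype(int)
    with open(path, "w") as fh:
        if L is not None:
            fh.write(f"#genome_length_kb={L}\n")
        out.to_csv(fh, sep="\t", index=False)


def read_annotation(path: str | Path, genome_length_kb: int | None = None) -> pd.DataFrame:
    """Validated annotation table; genome length from the header or argument."""
    path = Path(path)
    header_L = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#genome_length_kb="):
            header_L = int(first.split("=", 1)[1])
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    L = genome_length_kb if genome_length_kb is not None else header_L
    if L is None:
        raise DataFormatError(f"{path}: no genome length in header and none supplied")
    missing = set(_ANNOTATION_COLS) - set(df.columns)
    if missing:
        raise DataFormatError(f"{path}: missing columns {sorted(missing)}")
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise DataFormatError(f"{path}: duplicate gene id {dup!r}")
    length_bp = L * 1000
    for col in ("start_bp", "end_bp"):
        vals = df[col]
        if (vals < 1).any() or (vals > length_bp).any():
            raise DataFormatError(f"{path}: {col} outside [1, {length_bp}]")
    df["essential"] = df["essential"].astype(bool)
    df.attrs["genome_length_kb"] = L
    return df


def write_expression(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    rep_cols = [c for c in df.columns if c.startswith("rep")]
    if "gene" not in df.columns or "medium" not in df.columns or not rep_cols:
        raise DataFormatError(f"{path}: expected gene, medium and rep* columns")
    df["mean"] = df[rep_cols].mean(axis=1)
    return df


def write_well_map(well_map: pd.DataFrame, path: str | Path) -> None:
    well_map.to_csv(path, index=False)


def read_well_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"plate", "well", "strain", "medium", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise DataFormatError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_plate_csv(curves: list[GrowthCurve], plate: str, path: str | Path) -> None:
    """Wide per-plate CSV: ``time_h`` plus one raw-OD column per well."""
    plate_curves = [c for c in curves if c.plate == plate]
    if not plate_curves:
        raise DataFormatError(f"no curves for plate {plate!r}")
    times = plate_curves[0].times
    data = {"time_h": times}
    for c in plate_curves:
        if not np.array_equal(c.times, times):
            raise DataFormatError(f"plate {plate!r}: inconsistent time grids")
        data[c.well] = c.od
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6g")


def read_plate_csv(
    path: str | Path, well_map: pd.DataFrame, plate: str | None = None
) -> list[GrowthCurve]:
    """Curves for one plate CSV, blank-corrected via the map's BLANK wells.

    The per-plate blank is the mean t=0 reading of wells mapped to strain
    ``BLANK`` (0 if the plate has none).  Mapped wells missing from the CSV
    are errors; unmapped CSV columns are logged and skipped.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "time_h" not in df.columns:
        raise DataFormatError(f"{path}: first column must be time_h")
    times = df["time_h"].to_numpy(dtype=float)
    if not np.all(np.diff(times) > 0):
        raise DataFormatError(f"{path}: time_h not strictly increasing")
    if plate is None:
        plates = well_map["plate"].unique()
        if len(plates) != 1:
            raise DataFormatError(
                f"{path}: well map covers {len(plates)} plates; pass plate="
            )
        plate = plates[0]
    pmap = well_map[well_map["plate"] == plate]
    well_cols = [c for c in df.columns if c != "time_h"]
    for col in well_cols:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise DataFormatError(f"{path}: non-numeric value in column {col}, row {bad}")
    missing = set(pmap["well"]) - set(well_cols)
    if missing:
        raise DataFormatError(f"{path}: mapped wells absent from CSV: {sorted(missing)}")

    blank_wells = pmap.loc[pmap["strain"] == "BLANK", "well"]
    blank = float(np.mean([df[w].iloc[0] for w in blank_wells])) if len(blank_wells) else 0.0

    curves = []
    mapped_wells = set(pmap["well"])
    unmapped = [c for c in well_cols if c not in mapped_wells]
    if unmapped:
        logger.info("%s: %d unmapped wells skipped", path, len(unmapped))
    for row in pmap.itertuples(index=False):
        if row.strain == "BLANK":
            continue
        curves.append(
            GrowthCurve(
                strain=row.strain,
                medium=row.medium,
                replicate=int(row.replicate),
                plate=plate,
                well=row.well,
                times=times.copy(),
                od=df[row.well].to_numpy(dtype=float),
                blank=blank,
            )
        )
    return curves


def write_rate_table(rate_table: pd.DataFrame, path: str | Path) -> None:
    rate_table.to_csv(path, sep="\t", index=False, float_format="%.6g")
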