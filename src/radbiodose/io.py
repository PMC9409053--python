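"""CSV/TIFF/JSON I/O with unit-suffixed column schemas and run provenance.

All tabular schemas carry units in the column names (dose_Gy, activity_Bq,
time_h) so files cannot be silently misread across MBq/kBq/Gy conventions.
Readers validate required columns and raise :class:`SchemaError` naming the
missing column.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .dsb import ImagePair
from .errors import SchemaError
from .invivo import BiodistributionRow, BiodistributionTable, TumorGrowthSeries
from .survival import ColonyAssayRecord

COLONY_COLUMNS = ("activity_Bq", "dose_Gy", "colonies", "cells_seeded", "replicate")
BIODIST_COLUMNS = ("organ", "time_h", "value", "unit", "n", "sd")
GROWTH_COLUMNS = ("group", "animal_id", "day", "relative_size")
DSB_COLUMNS = ("dose_Gy", "percent_dsb")


def _require_columns(df: pd.DataFrame, required, path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r} "
                              f"(expected {list(required)})")


def read_colony_csv(path) -> list[ColonyAssayRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, COLONY_COLUMNS, path)
    return [
        ColonyAssayRecord(activity_bq=float(r.activity_Bq), dose_gy=float(r.dose_Gy),
                          colonies=int(r.colonies), cells_seeded=int(r.cells_seeded),
                          replicate=str(r.replicate))
        for r in df.itertuples()
    ]


def write_colony_csv(records, path) -> None:
    pd.DataFrame(
        [{"activity_Bq": r.activity_bq, "dose_Gy": r.dose_gy, "colonies": r.colonies,
          "cells_seeded": r.cells_seeded, "replicate": r.replicate} for r in records]
    ).to_csv(path, index=False, float_format="%.17g")


def read_biodistribution_csv(path) -> BiodistributionTable:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, BIODIST_COLUMNS, path)
    rows = tuple(
        BiodistributionRow(organ=str(r.organ), time_h=float(r.time_h),
                           value=float(r.value), unit=str(r.unit), n=int(r.n),
                           sd=float(r.sd))
        for r in df.itertuples()
    )
    return BiodistributionTable(rows=rows)


def write_biodistribution_csv(table: BiodistributionTable, path) -> None:
    pd.DataFrame(
        [{"organ": r.organ, "time_h": r.time_h, "value": r.value, "unit": r.unit,
          "n": r.n, "sd": r.sd} for r in table.rows]
    ).to_csv(path, index=False, float_format="%.17g")


def read_growth_csv(path) -> dict[str, list[TumorGrowthSeries]]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, GROWTH_COLUMNS, path)
    out: dict[str, list[TumorGrowthSeries]] = {}
    for (group, _animal), sub in df.groupby(["group", "animal_id"], sort=True):
        sub = sub.sort_values("day")
        series = TumorGrowthSeries(
            group=str(group),
            day=tuple(float(d) for d in sub["day"]),
            relative_size=tuple(float(s) for s in sub["relative_size"]),
            relative_weight=tuple(float(w) for w in sub["relative_weight"])
            if "relative_weight" in sub.columns else (),
        )
        out.setdefault(str(group), []).append(series)
    return out


def write_growth_csv(series_by_group, path) -> None:
    rows = []
    for group, series_list in series_by_group.items():
        for i, s in enumerate(series_list):
            for j, d in enumerate(s.day):
                row = {"group": group, "animal_id": f"a{i + 1}", "day": d,
                       "relative_size": s.relative_size[j]}
                if s.relative_weight:
                    row["relative_weight"] = s.relative_weight[j]
                rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_dsb_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, DSB_COLUMNS, path)
    return df


def write_dsb_csv(rows, path) -> None:
    """rows: iterable of (dose_Gy, percent_dsb)."""
    pd.DataFrame(rows, columns=list(DSB_COLUMNS)).to_csv(path, index=False, float_format="%.17g")


def write_image_pair(pair: ImagePair, directory, stem: str) -> tuple[Path, Path]:
    """Write ``<stem>_nuc.tif`` / ``<stem>_dmg.tif`` into a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nuc = directory / f"{stem}_nuc.tif"
    dmg = directory / f"{stem}_dmg.tif"
    tifffile.imwrite(nuc, np.asarray(pair.nuclei_channel, dtype=np.float32))
    tifffile.imwrite(dmg, np.asarray(pair.damage_channel, dtype=np.float32))
    return nuc, dmg


def read_image_pair(nuc_path, dmg_path, pixel_size_um: float = 1.0) -> ImagePair:
    return ImagePair(tifffile.imread(nuc_path).astype(float),
                     tifffile.imread(dmg_path).astype(float),
                     pixel_size_um=pixel_size_um)


def package_version() -> str:
    try:
        return version("radbiodose")
    except PackageNotFoundError:
        return "unknown"


def write_provenance(out_dir, subcommand: str, params: dict) -> Path:
    """Machine-readable record of a run: parameters, version, timestamp."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "subcommand": subcommand,
        "parameters": {k: _jsonable(v) for k, v in params.items()},
        "package_version": package_version(),
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(record, indent=2, sort_keys=True))
    return path


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, Path):
        return str(v)
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    return v
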