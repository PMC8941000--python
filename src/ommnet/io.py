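"""Readers and writers for the pipeline's plain-text interchange formats.

All tables are UTF-8 CSV/TSV with headers and decimal points. Matrix
writers prepend a ``#`` comment line stating the row/column orientation;
the matching readers skip such comments.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd

from .metabolomics import FeatureTable
from .network import StandardCurve

OD_COLUMNS = ["strain", "medium", "replicate", "time_h", "od600"]
PH_COLUMNS = ["strain", "medium", "ph_fresh", "ph_sm", "ph_dsm"]
QPCR_COLUMNS = ["strain", "culture_id", "culture_type", "partner", "timepoint_h",
                "replicate"]


def read_od_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    _require(df, OD_COLUMNS, path)
    return df


def read_ph_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    _require(df, ["strain", "medium", "ph_sm"], path)
    return df


def read_feature_table(table_path, meta_path, fresh_label: str = "fresh") -> FeatureTable:
    intensities = pd.read_csv(table_path, sep="\t", index_col=0, comment="#")
    meta = pd.read_csv(meta_path, comment="#").set_index("sample_id")
    return FeatureTable(intensities, meta, fresh_label=fresh_label)


def write_feature_table(table: FeatureTable, table_path, meta_path) -> None:
    table.intensities.to_csv(table_path, sep="\t", index_label="feature_id")
    table.sample_meta.to_csv(meta_path, index_label="sample_id")


def read_qpcr_csv(path, copies: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    value_col = "copies" if copies else "cq"
    _require(df, QPCR_COLUMNS + [value_col], path)
    df["partner"] = df["partner"].fillna("")
    return df


def read_standards_csv(path) -> list[StandardCurve]:
    df = pd.read_csv(path, comment="#")
    _require(df, ["strain", "slope", "intercept"], path)
    return [
        StandardCurve(strain_id=str(r["strain"]), slope=float(r["slope"]),
                      intercept=float(r["intercept"]))
        for _, r in df.iterrows()
    ]


def write_matrix_csv(matrix: pd.DataFrame, path, orientation: str) -> None:
    """Write a labelled matrix with an orientation comment header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# {orientation}\n")
        matrix.to_csv(fh)


def read_matrix_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col=0)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    try:
        import numpy as np

        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
    except ImportError:  # pragma: no cover
        pass
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _require(df: pd.DataFrame, columns: Iterable[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
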