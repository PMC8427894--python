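"""Delimited-text readers and writers.

Interchange format is UTF-8 CSV with a header row and decimal points;
result tables are written as TSV at a fixed precision so a write/read
round-trip is exact.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    AbundanceMatrix,
    EnvMatrix,
    FormatError,
    SiteTable,
    ValidationError,
)

logger = logging.getLogger("memscape")

#: significant digits used when writing result tables; 17 round-trips float64 exactly
TABLE_PRECISION = 17


def read_site_table(path: str | Path) -> SiteTable:
    """Read a site table CSV with columns site_id, x, y, habitat.

    Extra columns (e.g. season or collection metadata) are kept in
    ``SiteTable.metadata``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    required = {"site_id", "x", "y", "habitat"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"site table missing column(s): {sorted(missing)}")
    extra = [c for c in df.columns if c not in required]
    meta = df[["site_id", *extra]].copy() if extra else None
    return SiteTable(
        site_ids=tuple(df["site_id"].astype(str)),
        coords=df[["x", "y"]].to_numpy(dtype=float),
        habitat=tuple(df["habitat"].astype(str)),
        metadata=meta,
    )


def read_abundance_matrix(path: str | Path, sites: SiteTable) -> AbundanceMatrix:
    """Read a site-by-species count CSV (first column site_id, header = species).

    Rows are reordered to the SiteTable order; all-zero species columns are
    dropped with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if df.columns[0] != "site_id":
        raise FormatError("abundance matrix must have 'site_id' as first column")
    df = df.set_index("site_id")
    df.index = df.index.astype(str)
    unknown = set(df.index) - set(sites.site_ids)
    if unknown:
        raise ValidationError(f"abundance rows for unknown site(s): {sorted(unknown)}")
    missing = set(sites.site_ids) - set(df.index)
    if missing:
        raise ValidationError(f"abundance rows missing for site(s): {sorted(missing)}")
    df = df.loc[list(sites.site_ids)]
    values = df.to_numpy()
    if np.any(values < 0):
        raise ValidationError("negative abundance cell(s) in file")
    zero_cols = df.columns[values.sum(axis=0) == 0]
    if len(zero_cols):
        logger.warning(
            "dropping %d all-zero species column(s): %s",
            len(zero_cols),
            list(zero_cols[:5]),
        )
        df = df.drop(columns=zero_cols)
    return AbundanceMatrix(sites=sites, counts=df)


def read_env_matrix(path: str | Path, sites: SiteTable) -> EnvMatrix:
    """Read a site-by-environment CSV (first column site_id), reordered to sites."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if df.columns[0] != "site_id":
        raise FormatError("environment matrix must have 'site_id' as first column")
    df = df.set_index("site_id")
    df.index = df.index.astype(str)
    missing = set(sites.site_ids) - set(df.index)
    if missing:
        raise ValidationError(f"environment rows missing for site(s): {sorted(missing)}")
    df = df.loc[list(sites.site_ids)]
    return EnvMatrix(sites=sites, data=df)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a result table as TSV at the declared fixed precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=f"%.{TABLE_PRECISION}g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_manifest(manifest: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_grid_csv(path: str | Path) -> np.ndarray:
    """Read one gridded layer stored as a plain numeric matrix CSV (no header)."""
    return np.loadtxt(path, delimiter=",", ndmin=2)


def write_grid_csv(layer: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, np.asarray(layer, dtype=float), delimiter=",", fmt=f"%.{TABLE_PRECISION}g")
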