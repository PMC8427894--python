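"""Core data containers for the site-by-species spatial analysis.

Everything downstream is aligned to the :class:`SiteTable` row order: the
abundance matrix, the environment matrix, spatial weight matrices and MEM
bases all index sites identically, so a site permutation bug cannot arise
silently after construction.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "FormatError",
    "SiteTable",
    "AbundanceMatrix",
    "EnvMatrix",
    "PipelineConfig",
    "STUDY_HABITATS",
]

#: Habitat categories of the agricultural-mosaic study design.
STUDY_HABITATS = ("Crop", "Edge", "Oak", "Wasteland")


class ValidationError(ValueError):
    """Input violates a structural invariant (duplicates, negatives, misalignment)."""


class FormatError(ValueError):
    """Input file does not have the expected columns/layout."""


@dataclass(frozen=True)
class SiteTable:
    """Sampling sites with planar coordinates and habitat labels.

    Coordinates are treated as planar throughout; no CRS handling is done.

    Parameters
    ----------
    site_ids : sequence of str
        Unique identifiers, one per site. Order is the canonical site order.
    coords : (n, 2) array
        Planar x/y coordinates.
    habitat : sequence of str
        Habitat label per site.
    metadata : DataFrame, optional
        Per-collection metadata (e.g. season) indexed however the caller likes;
        carried along untouched.
    """

    site_ids: tuple[str, ...]
    coords: np.ndarray
    habitat: tuple[str, ...]
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "site_ids", tuple(str(s) for s in self.site_ids))
        object.__setattr__(self, "habitat", tuple(str(h) for h in self.habitat))
        n = len(self.site_ids)
        if n < 4:
            raise ValidationError(f"need at least 4 sites, got {n}")
        if coords.shape != (n, 2):
            raise ValidationError(f"coords shape {coords.shape} != ({n}, 2)")
        if not np.all(np.isfinite(coords)):
            raise ValidationError("non-finite coordinates")
        if len(self.habitat) != n:
            raise ValidationError("habitat length mismatch")
        if len(set(self.site_ids)) != n:
            dupes = sorted({s for s in self.site_ids if self.site_ids.count(s) > 1})
            raise ValidationError(f"duplicate site_id(s): {dupes}")
        # duplicate coordinates are rejected outright: they break every planar graph
        _, counts = np.unique(coords, axis=0, return_counts=True)
        if np.any(counts > 1):
            raise ValidationError("two or more sites share identical (x, y)")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def habitats(self) -> tuple[str, ...]:
        """Distinct habitat labels in first-appearance order."""
        seen: dict[str, None] = {}
        for h in self.habitat:
            seen.setdefault(h)
        return tuple(seen)

    def index_of(self, site_id: str) -> int:
        return self.site_ids.index(site_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_id": self.site_ids,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "habitat": self.habitat,
            }
        )


@dataclass(frozen=True)
class AbundanceMatrix:
    """Site-by-species count matrix aligned to a :class:`SiteTable`.

    Rows follow the site order of ``sites``; all cells are non-negative
    integers and every row and column has at least one positive cell.
    """

    sites: SiteTable
    counts: pd.DataFrame  # index = site_id, columns = species

    def __post_init__(self) -> None:
        df = self.counts
        if list(df.index) != list(self.sites.site_ids):
            raise ValidationError("abundance rows not aligned to site order")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("non-numeric abundance cells")
        if np.any(values < 0):
            raise ValidationError("negative abundance cell(s)")
        if np.any(values.sum(axis=1) == 0):
            empty = [s for s, t in zip(df.index, values.sum(axis=1)) if t == 0]
            raise ValidationError(f"site(s) with all-zero abundances: {empty}")
        if df.shape[1] < 1 or np.any(values.sum(axis=0) == 0):
            raise ValidationError("species column(s) with all-zero abundances")

    @property
    def values(self) -> np.ndarray:
        return self.counts.to_numpy(dtype=float)

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.counts.columns)

    @property
    def n_species(self) -> int:
        return self.counts.shape[1]

    @property
    def row_totals(self) -> np.ndarray:
        return self.values.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.values.sum(axis=0)

    @property
    def grand_total(self) -> float:
        return float(self.values.sum())


@dataclass(frozen=True)
class EnvMatrix:
    """Site-by-environment matrix aligned to a :class:`SiteTable`.

    Categorical variables enter as indicator columns; after construction the
    matrix has no missing cells.
    """

    sites: SiteTable
    data: pd.DataFrame  # index = site_id, columns = env variable names

    def __post_init__(self) -> None:
        if list(self.data.index) != list(self.sites.site_ids):
            raise ValidationError("environment rows not aligned to site order")
        if self.data.isna().any().any():
            bad = list(self.data.columns[self.data.isna().any()])
            raise ValidationError(f"missing environment cells in {bad}")

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.data.columns)


@dataclass
class PipelineConfig:
    """Configuration for the full spatial-optimisation pipeline.

    One seed drives every stochastic stage through named child generators,
    so a run is reproducible from the manifest alone.
    """

    graphs: Sequence[str] = ("delaunay", "gabriel", "rng1", "rng2")
    weight_style: str = "binary"
    n_perm: int = 999
    seed: int = 0
    n_windows: int = 2
    tsallis_q: float = 0.5
    lda_priors: str = "uniform"
    train_fraction: float = 0.5
    n_axes: int = 2
    out_dir: str = "results"
    #: "sites" permutes site values (default); "mems" permutes within-window MEM identity
    permute: str = "sites"
    rng_betas: Mapping[str, float] = field(default_factory=lambda: {"rng1": 2.0, "rng2": 3.0})

    def __post_init__(self) -> None:
        if self.n_perm < 99:
            raise ValidationError(f"permutations must be >= 99, got {self.n_perm}")
        if self.weight_style not in ("binary", "row_standardised"):
            raise ValidationError(f"unknown weight style {self.weight_style!r}")
        if self.lda_priors not in ("uniform", "frequency"):
            raise ValidationError(f"unknown prior mode {self.lda_priors!r}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValidationError("train_fraction must be in (0, 1)")

    def stage_rng(self, stage: str) -> np.random.Generator:
        """Independent generator for a named stage, derived from the run seed.

        Uses a CRC of the stage name (process-stable, unlike ``hash``) so the
        same config yields byte-identical permutation draws in every run.
        """
        stage_key = zlib.crc32(stage.encode("utf-8")) % (2**31)
        return np.random.default_rng([int(self.seed), stage_key])
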