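"""Environmental variable screening on gridded layers.

Layers live on one shared rectangular grid (plain-matrix CSV in and out;
no CRS handling — coordinates are planar and must already be aligned).
Terrain variables (slope, aspect) derive from an elevation layer by Horn's
8-neighbour finite-difference stencil. Candidate variables are screened by
per-variable binomial GLMs of site presences against uniformly sampled
background points (pseudo-absences): a variable is retained when its slope
is significant at the chosen alpha.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datamodel import EnvMatrix, SiteTable, ValidationError

__all__ = [
    "GridStack",
    "derive_terrain",
    "sample_background",
    "select_variables",
    "extract_at_points",
]

logger = logging.getLogger("memscape")


@dataclass
class GridStack:
    """Named 2-D layers on a shared grid.

    The grid origin is the minimum-x/minimum-y corner; row 0 is the minimum-y
    row. A point maps to cell floor((coord - origin)/cell_size); points on
    the maximum edge belong to the last cell.
    """

    layers: dict[str, np.ndarray] = field(default_factory=dict)
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    kinds: dict[str, str] = field(default_factory=dict)  # continuous | categorical

    def __post_init__(self) -> None:
        shapes = {name: lay.shape for name, lay in self.layers.items()}
        if len(set(shapes.values())) > 1:
            raise ValidationError(f"layers disagree on grid shape: {shapes}")
        if self.cell_size <= 0:
            raise ValidationError("cell size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        if not self.layers:
            raise ValidationError("empty grid stack")
        return next(iter(self.layers.values())).shape

    def add(self, name: str, layer: np.ndarray, kind: str = "continuous") -> None:
        layer = np.asarray(layer, dtype=float)
        if self.layers and layer.shape != self.shape:
            raise ValidationError(f"layer {name!r} shape {layer.shape} != {self.shape}")
        self.layers[name] = layer
        self.kinds[name] = kind

    def bounds(self) -> tuple[float, float, float, float]:
        n_rows, n_cols = self.shape
        x0, y0 = self.origin
        return x0, y0, x0 + n_cols * self.cell_size, y0 + n_rows * self.cell_size

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        n_rows, n_cols = self.shape
        x0, y0, x1, y1 = self.bounds()
        if not (x0 <= x <= x1 and y0 <= y <= y1):
            raise ValidationError(f"point ({x}, {y}) outside grid bounds")
        c = min(int((x - x0) // self.cell_size), n_cols - 1)
        r = min(int((y - y0) // self.cell_size), n_rows - 1)
        return r, c


def derive_terrain(stack: GridStack, elevation: str = "elevation") -> GridStack:
    """Add slope (degrees) and aspect (degrees, 0..360) from the elevation layer.

    Gradients use Horn's 8-neighbour weighted stencil with edge replication.
    Aspect is the downslope compass direction (0 = +y/north, clockwise);
    flat cells get aspect NaN and are flagged in an ``aspect_defined`` layer.
    """
    if elevation not in stack.layers:
        raise ValidationError(f"no {elevation!r} layer in stack")
    z = stack.layers[elevation]
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValidationError("grid must be at least 3x3 for terrain derivation")
    zp = np.pad(z, 1, mode="edge")
    cs = stack.cell_size
    # 8-neighbour Horn stencil; row index grows with y (origin at min-y corner)
    a = zp[2:, :-2]; b = zp[2:, 1:-1]; c = zp[2:, 2:]      # y+1 row
    d = zp[1:-1, :-2]; f = zp[1:-1, 2:]                    # same row
    g = zp[:-2, :-2]; h = zp[:-2, 1:-1]; i = zp[:-2, 2:]   # y-1 row
    dz_dx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * cs)
    dz_dy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8.0 * cs)
    slope = np.degrees(np.arctan(np.hypot(dz_dx, dz_dy)))
    flat = np.hypot(dz_dx, dz_dy) < 1e-12
    # downslope direction: negative gradient; angle measured clockwise from +y
    aspect = np.degrees(np.arctan2(-dz_dx, -dz_dy)) % 360.0
    aspect = np.where(flat, np.nan, aspect)
    stack.add("slope", slope)
    stack.add("aspect", aspect)
    stack.add("aspect_defined", (~flat).astype(float))
    return stack


def sample_background(stack: GridStack, n: int, seed: int = 0) -> np.ndarray:
    """n uniform pseudo-absence points within the grid bounding box."""
    if n < 1:
        raise ValidationError("need at least one background point")
    x0, y0, x1, y1 = stack.bounds()
    rng = np.random.default_rng(seed)
    pts = np.column_stack(
        [rng.uniform(x0, x1, size=n), rng.uniform(y0, y1, size=n)]
    )
    return pts


def extract_at_points(stack: GridStack, points: np.ndarray, variables) -> pd.DataFrame:
    """Grid-exact extraction: each point receives the value of its cell."""
    points = np.asarray(points, dtype=float)
    cells = [stack.cell_of(x, y) for x, y in points]
    out = {}
    for name in variables:
        lay = stack.layers[name]
        out[name] = np.array([lay[r, c] for r, c in cells])
    return pd.DataFrame(out)


def select_variables(
    sites: SiteTable,
    background: np.ndarray,
    stack: GridStack,
    variables,
    alpha: float = 0.05,
    correction: str | None = None,
) -> tuple[list[str], EnvMatrix]:
    """Screen candidate layers by per-variable presence/background GLMs.

    For each variable a binomial GLM (logit link) of presence (site = 1,
    background = 0) on the extracted values is fit; the variable is retained
    when the slope's p-value is below ``alpha``. ``correction="holm"``
    applies a Holm step-down adjustment across the candidate p-values
    (default: none). Complete separation is flagged with a warning and the
    variable retained. The retained site values form the climate block of
    the returned EnvMatrix.
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError("alpha must be in (0, 1)")
    if correction not in (None, "holm"):
        raise ValidationError(f"unknown correction {correction!r}")
    for v in variables:
        if v not in stack.layers:
            raise ValidationError(f"variable {v!r} not in grid stack")
    site_vals = extract_at_points(stack, sites.coords, variables)
    bg_vals = extract_at_points(stack, background, variables)
    y = np.concatenate([np.ones(len(site_vals)), np.zeros(len(bg_vals))])
    pvals: dict[str, float] = {}
    forced: list[str] = []
    for v in variables:
        x = np.concatenate([site_vals[v], bg_vals[v]])
        design = sm.add_constant(x)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.GLM(y, design, family=sm.families.Binomial()).fit()
                p = float(fit.pvalues[1])
                separated = bool(np.any(np.abs(fit.params) > 1e3))
            except Exception:  # perfect separation can abort IRLS outright
                separated, p = True, 0.0
        if separated:
            logger.warning("variable %r shows (near-)complete separation; retained", v)
            forced.append(v)
        else:
            pvals[v] = p
    tested = list(pvals)
    if correction == "holm" and tested:
        from statsmodels.stats.multitest import multipletests

        reject, *_ = multipletests([pvals[v] for v in tested], alpha=alpha, method="holm")
        passing = {v for v, r in zip(tested, reject) if r}
    else:
        passing = {v for v in tested if pvals[v] < alpha}
    selected = [v for v in variables if v in passing or v in forced]
    env = EnvMatrix(
        sites=sites,
        data=pd.DataFrame(
            {v: site_vals[v].to_numpy() for v in selected},
            index=pd.Index(sites.site_ids, name="site_id"),
        ),
    )
    return selected, env
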