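"""Synthetic landscape generator with known spatial ground truth.

Generates the three study inputs — sites with habitat labels, a
site-by-environment matrix, and a site-by-species count matrix — with
controlled broad- and fine-scale spatial structure, so every downstream
stage can be scored against a known truth record.

Structure of the simulated community, per species s and site i:

    log mu_is = broad_effect * bl_s * g_i
              + fine_effect  * fl_s * u_i
              + habitat offset o(h_i, s)
              + evenness term c(h_i) * z_s

where g is a smooth broad-scale gradient (a monotone function of the first
principal direction of the site coordinates, also present verbatim in the
environment matrix as ``env_broad``), u is one designated trailing MEM of a
reference Gabriel-graph basis over the same sites (so the fine-scale truth
is exactly expressible in the detector's basis), bl/fl are per-species
standard-normal loadings, o is a zero-mean normal habitat-by-species
offset, and the optional evenness term concentrates abundance on a few
species in low-diversity habitats. Expected abundances are rescaled per
species so the marginal mean equals ``mean_abundance``; counts are drawn
negative-binomial (Poisson in the overdispersion -> 0 limit).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .connectivity import gabriel_graph, to_weight_matrix
from .datamodel import (
    AbundanceMatrix,
    EnvMatrix,
    STUDY_HABITATS,
    SiteTable,
    ValidationError,
)
from .spatial import MEMBasis, compute_mems

__all__ = [
    "SimulationParams",
    "TruthRecord",
    "SyntheticDataset",
    "generate_sites",
    "generate_environment",
    "generate_community",
    "generate_dataset",
]


class GenerationError(RuntimeError):
    """Generator could not satisfy its constraints within bounded retries."""


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic landscape; defaults emulate the study design.

    23 sites in a bounded extent, four habitat categories, ~300 species,
    negative-binomial counts, a handful of smooth environmental surfaces.
    """

    n_sites: int = 23
    extent: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 10.0), (0.0, 10.0))
    n_species: int = 300
    n_habitats: int = 4
    broad_effect: float = 1.0
    fine_effect: float = 0.0
    mean_abundance: float = 50.0
    overdispersion: float = 0.3
    n_env_vars: int = 5
    env_spatial_range: float = 4.0
    habitat_offset_sd: float = 0.3
    habitat_evenness: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 4:
            raise ValidationError("n_sites must be >= 4")
        if self.n_species < 2:
            raise ValidationError("n_species must be >= 2")
        for name in ("broad_effect", "fine_effect", "overdispersion", "mean_abundance"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0")
        if self.n_habitats < 1 or self.n_habitats > self.n_sites:
            raise ValidationError("need 1 <= n_habitats <= n_sites")
        if self.env_spatial_range <= 0:
            raise ValidationError("env_spatial_range must be positive")

    def habitat_labels(self) -> tuple[str, ...]:
        if self.n_habitats == len(STUDY_HABITATS):
            return STUDY_HABITATS
        return tuple(f"H{k + 1}" for k in range(self.n_habitats))

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass(frozen=True)
class TruthRecord:
    """What was injected, sufficient to score detection of the scale of effect."""

    broad_gradient: np.ndarray  # g, standardised, length n_sites
    fine_mem_index: int  # 1-based index into the reference MEM basis
    reference_graph: str
    broad_loadings: np.ndarray  # per species
    fine_loadings: np.ndarray
    habitat_offsets: pd.DataFrame  # habitat x species
    evenness: dict

    def to_jsonable(self) -> dict:
        return {
            "fine_mem_index": self.fine_mem_index,
            "reference_graph": self.reference_graph,
            "broad_gradient": self.broad_gradient.tolist(),
            "evenness": dict(self.evenness),
        }


@dataclass(frozen=True)
class SyntheticDataset:
    sites: SiteTable
    env: EnvMatrix
    abundance: AbundanceMatrix
    truth: TruthRecord
    mem_basis: MEMBasis
    params: SimulationParams


def _extent_diag(params: SimulationParams) -> float:
    (x0, x1), (y0, y1) = params.extent
    return float(np.hypot(x1 - x0, y1 - y0))


def _all_graphs_connected(coords: np.ndarray) -> bool:
    """True when Delaunay, Gabriel and both relative-neighbour skeletons connect.

    The study's analysis presumes a usable MEM basis under every
    connectivity hypothesis, so the generator emulates that condition; the
    sparsest skeleton (beta=3) is the only one that can realistically fail.
    """
    from .connectivity import relative_neighbour_graph
    from .datamodel import SiteTable

    try:
        sites = SiteTable(
            site_ids=tuple(f"t{i}" for i in range(len(coords))),
            coords=coords,
            habitat=tuple("t" for _ in coords),
        )
        return relative_neighbour_graph(sites, beta=3.0).is_connected
    except Exception:
        return False


def generate_sites(params: SimulationParams) -> SiteTable:
    """Uniform random sites with a minimum-separation constraint and habitats.

    Separation is enforced at 1% of the extent diagonal by rejection
    sampling with bounded retries; layouts whose sparsest study graph
    (relative neighbour, beta=3) is disconnected are redrawn, since every
    downstream stage needs a connected graph under all four hypotheses.
    Habitat labels are assigned by a blocked random draw so every habitat
    has at least one site.
    """
    rng = params.rng(1)
    (x0, x1), (y0, y1) = params.extent
    min_sep = 0.01 * _extent_diag(params)
    coords = None
    for _ in range(50):  # layout retries: all four study graphs must be connected
        pts: list[np.ndarray] = []
        attempts = 0
        max_attempts = 1000 * params.n_sites
        while len(pts) < params.n_sites:
            if attempts >= max_attempts:
                raise GenerationError(
                    f"could not place {params.n_sites} sites at separation {min_sep:g}"
                )
            attempts += 1
            cand = np.array([rng.uniform(x0, x1), rng.uniform(y0, y1)])
            if all(np.hypot(*(cand - p)) >= min_sep for p in pts):
                pts.append(cand)
        candidate = np.array(pts)
        if _all_graphs_connected(candidate):
            coords = candidate
            break
    if coords is None:
        raise GenerationError(
            "no layout with all four connectivity graphs connected within retries"
        )

    labels = params.habitat_labels()
    habitat = np.empty(params.n_sites, dtype=object)
    order = rng.permutation(params.n_sites)
    # blocked draw: two guaranteed sites per habitat when sites permit
    # (group comparisons need >= 2 members per class), else one
    per_habitat = 2 if params.n_sites >= 2 * len(labels) else 1
    block = per_habitat * len(labels)
    for k in range(block):
        habitat[order[k]] = labels[k % len(labels)]
    rest = order[block:]
    habitat[rest] = rng.choice(labels, size=len(rest))
    site_ids = tuple(f"S{i + 1:02d}" for i in range(params.n_sites))
    return SiteTable(site_ids=site_ids, coords=coords, habitat=tuple(habitat))


def broad_gradient(sites: SiteTable) -> np.ndarray:
    """Standardised projection of the site coordinates on their first principal direction."""
    c = sites.coords - sites.coords.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    direction = vt[0]
    if direction[np.argmax(np.abs(direction))] < 0:
        direction = -direction
    g = c @ direction
    return (g - g.mean()) / g.std(ddof=0)


def generate_environment(sites: SiteTable, params: SimulationParams) -> EnvMatrix:
    """Smooth Gaussian-process environmental surfaces sampled at the sites.

    Column ``env_broad`` is exactly the broad spatial gradient (a monotone
    function of the first principal direction); the remaining continuous
    columns are draws from a squared-exponential GP with range
    ``env_spatial_range``; a categorical block (``cover_*`` indicators, one
    level dropped) assigns each site the nearest of three random centres.
    """
    rng = params.rng(2)
    d = np.linalg.norm(sites.coords[:, None, :] - sites.coords[None, :, :], axis=2)
    rho = params.env_spatial_range
    k = np.exp(-(d**2) / (2.0 * rho**2)) + 1e-8 * np.eye(sites.n_sites)
    chol = np.linalg.cholesky(k)
    cols: dict[str, np.ndarray] = {"env_broad": broad_gradient(sites)}
    for j in range(1, params.n_env_vars):
        cols[f"env_{j + 1}"] = chol @ rng.standard_normal(sites.n_sites)
    (x0, x1), (y0, y1) = params.extent
    centres = np.column_stack(
        [rng.uniform(x0, x1, size=3), rng.uniform(y0, y1, size=3)]
    )
    nearest = np.argmin(
        np.linalg.norm(sites.coords[:, None, :] - centres[None, :, :], axis=2), axis=1
    )
    for level in (1, 2):  # level 0 dropped
        cols[f"cover_{level + 1}"] = (nearest == level).astype(float)
    return EnvMatrix(
        sites=sites,
        data=pd.DataFrame(cols, index=pd.Index(sites.site_ids, name="site_id")),
    )


def _negative_binomial(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB draws with variance mu + alpha*mu^2 (Poisson at alpha=0)."""
    if alpha <= 0:
        return rng.poisson(mu)
    size = 1.0 / alpha
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def generate_community(
    sites: SiteTable,
    env: EnvMatrix,
    params: SimulationParams,
    mem_basis: MEMBasis,
) -> tuple[AbundanceMatrix, TruthRecord]:
    """Spatially structured counts plus the truth record of what was injected."""
    if mem_basis.site_ids != sites.site_ids:
        raise ValidationError("MEM basis sites do not match the site table")
    rng = params.rng(3)
    n, s = sites.n_sites, params.n_species
    if "env_broad" in env.variables:
        g = env.data["env_broad"].to_numpy(dtype=float)
        g = (g - g.mean()) / g.std(ddof=0)
    else:
        g = broad_gradient(sites)
    # designated fine-scale MEM: well inside the trailing (fine) window
    fine_idx = max(1, int(round(0.75 * mem_basis.n_vectors)))
    u = mem_basis.vector(fine_idx)
    u = (u - u.mean()) / u.std(ddof=0)

    bl = rng.standard_normal(s)
    fl = rng.standard_normal(s)
    labels = sites.habitats
    offsets = pd.DataFrame(
        rng.normal(0.0, params.habitat_offset_sd, size=(len(labels), s)),
        index=list(labels),
    )
    evenness = dict(params.habitat_evenness or {})
    z = rng.standard_normal(s)

    eta = (
        params.broad_effect * np.outer(g, bl)
        + params.fine_effect * np.outer(u, fl)
    )
    for i, h in enumerate(sites.habitat):
        eta[i] += offsets.loc[h].to_numpy()
        if h in evenness:
            eta[i] += evenness[h] * z
    # per-site softmax scaling: each site's expected total is mean_abundance
    # per species, so relative composition within a site is exp(eta) and the
    # marginal mean of counts equals mean_abundance exactly in expectation
    expo = np.exp(eta - eta.max(axis=1, keepdims=True))
    mu = params.mean_abundance * s * expo / expo.sum(axis=1, keepdims=True)
    counts = _negative_binomial(rng, mu, params.overdispersion)

    species = [f"sp{j + 1:04d}" for j in range(s)]
    df = pd.DataFrame(counts, index=pd.Index(sites.site_ids, name="site_id"), columns=species)
    present = df.sum(axis=0) > 0
    df = df.loc[:, present]
    abundance = AbundanceMatrix(sites=sites, counts=df)
    truth = TruthRecord(
        broad_gradient=g,
        fine_mem_index=fine_idx,
        reference_graph=mem_basis.graph_kind or "gabriel",
        broad_loadings=bl,
        fine_loadings=fl,
        habitat_offsets=offsets,
        evenness=evenness,
    )
    return abundance, truth


def generate_dataset(params: SimulationParams) -> SyntheticDataset:
    """Full synthetic dataset: sites, environment, community and truth.

    The fine-scale signal is expressed in the MEM basis of the Gabriel graph
    over the generated sites (the reference connectivity hypothesis).
    """
    sites = generate_sites(params)
    env = generate_environment(sites, params)
    basis = compute_mems(to_weight_matrix(gabriel_graph(sites), "binary"))
    abundance, truth = generate_community(sites, env, params, basis)
    return SyntheticDataset(
        sites=sites, env=env, abundance=abundance, truth=truth,
        mem_basis=basis, params=params,
    )
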