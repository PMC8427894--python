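"""End-to-end spatial-optimisation pipeline.

Stages: connectivity graphs -> MEM bases -> ordination variable sets
(Y: species axes, F: environment-constrained axes, R: environment-filtered
residual axes) -> smoothed-scalogram permutation tests per graph (the
scalogram table) -> Moran's I Monte-Carlo tests of the per-axis best MEMs
(the Moran table) -> diversity estimation -> MANOVA/LDA comparison of
diversity vs MEM predictors (the discrimination table). All randomness
derives from the single config seed through named per-stage generators.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .connectivity import build_graph, to_weight_matrix
from .datamodel import AbundanceMatrix, EnvMatrix, PipelineConfig, SiteTable
from .discrimination import boxcox_preprocess, lda_fit_predict, manova_wilks
from .diversity import diversity_table
from .io import write_manifest, write_table
from .ordination import chisq_transform, partial_residual_axes, pca_axes, rda_axes
from .spatial import compute_mems, morans_i_test, smoothed_scalogram_test

__all__ = ["PipelineResult", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineResult:
    scalogram_table: pd.DataFrame  # per graph x variable x window: Obs, std-obs, p
    moran_table: pd.DataFrame  # per graph x selected MEM: Obs, Exp, Var, p
    manova_table: pd.DataFrame  # per predictor set: Wilks, F, df, p + univariate rows
    diversity_sites: pd.DataFrame
    diversity_groups: pd.DataFrame
    lda_confusions: dict[str, pd.DataFrame]
    selected_mems: dict[str, list[int]]  # per graph, 1-based MEM indices fed to LDA
    manifest: dict = field(default_factory=dict)


def _ordination_variables(abundance: AbundanceMatrix, env: EnvMatrix, k: int):
    """The six focal site-score vectors of the three ordinations."""
    x = chisq_transform(abundance)
    axes = {
        "Y": pca_axes(x, k=k, role="Y"),
        "F": rda_axes(x, env, k=k),
        "R": partial_residual_axes(x, env, k=k),
    }
    variables: dict[str, np.ndarray] = {}
    for role, ax in axes.items():
        for j in range(ax.k):
            variables[f"{role}{j + 1}"] = ax.site_scores[:, j]
    return axes, variables


def run_pipeline(
    config: PipelineConfig,
    sites: SiteTable,
    abundance: AbundanceMatrix,
    env: EnvMatrix,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run every stage and (optionally) write the result bundle to ``out_dir``."""

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - stage-named abort is the contract
                raise StageError(name, exc) from exc
        return deco

    bases = {}
    weights = {}

    @stage("connectivity")
    def _build():
        for kind in config.graphs:
            graph = build_graph(sites, kind, dict(config.rng_betas))
            weights[kind] = to_weight_matrix(graph, config.weight_style)

    @stage("mem")
    def _mems():
        for kind, w in weights.items():
            bases[kind] = compute_mems(w)

    @stage("ordination")
    def _ord():
        return _ordination_variables(abundance, env, config.n_axes)

    axes, variables = _ord

    scal_rows = []
    moran_rows = []
    selected: dict[str, list[int]] = {}

    @stage("scalogram")
    def _scal():
        for kind, basis in bases.items():
            for var_name, x in variables.items():
                res = smoothed_scalogram_test(
                    x,
                    basis,
                    n_perm=config.n_perm,
                    seed=int(config.stage_rng(f"scalogram:{kind}:{var_name}").integers(2**31)),
                    name=var_name,
                    permute=config.permute,
                )
                for w_idx, w_name in enumerate(res.window_names):
                    obs = res.window_sums[w_idx]
                    std = (obs - res.null_mean[w_idx]) / res.null_sd[w_idx]
                    scal_rows.append(
                        {
                            "graph": kind,
                            "variable": var_name,
                            "window": w_name,
                            "observed_r2": obs,
                            "standardised": std,
                            "p_value": res.p_values[w_idx],
                            "p_max_statistic": res.p_max_statistic,
                        }
                    )

    @stage("moran")
    def _moran():
        for kind, basis in bases.items():
            chosen: list[int] = []
            for var_name, x in variables.items():
                z = x - x.mean()
                r2 = (basis.vectors.T @ z) ** 2 / float(z @ z)
                best = int(np.argmax(r2)) + 1
                if best not in chosen:
                    chosen.append(best)
                    mem = basis.vector(best)
                    res = morans_i_test(
                        mem,
                        weights[kind],
                        n_perm=config.n_perm,
                        seed=int(config.stage_rng(f"moran:{kind}:{best}").integers(2**31)),
                        alternative="two-sided",
                    )
                    moran_rows.append(
                        {
                            "graph": kind,
                            "mem": f"MEM_{best}",
                            "selected_for": var_name,
                            "observed": res.observed,
                            "expectation": res.expectation,
                            "variance": res.variance,
                            "alternative": res.alternative,
                            "p_value": res.p_value,
                        }
                    )
            selected[kind] = chosen

    @stage("diversity")
    def _div():
        return diversity_table(abundance, q=config.tsallis_q, metadata=sites.metadata)

    div = _div

    manova_rows = []
    confusions: dict[str, pd.DataFrame] = {}

    @stage("discriminate")
    def _disc():
        labels = list(sites.habitat)
        ref_graph = config.graphs[0]
        basis = bases[ref_graph]
        # one MEM per ordination role: axis-1 best under the reference graph
        mem_idx: list[int] = []
        for role in ("Y", "F", "R"):
            x = variables[f"{role}1"]
            z = x - x.mean()
            r2 = (basis.vectors.T @ z) ** 2 / float(z @ z)
            best = int(np.argmax(r2)) + 1
            if best not in mem_idx:
                mem_idx.append(best)
        selected[f"{ref_graph}:lda"] = mem_idx
        predictor_sets = {
            "diversity": div["sites"].set_index("site_id")[["S_q", "D_AE"]],
            "mem": pd.DataFrame(
                {f"MEM_{i}": basis.vector(i) for i in mem_idx},
                index=pd.Index(sites.site_ids, name="site_id"),
            ),
        }
        for set_name, raw in predictor_sets.items():
            prep = boxcox_preprocess(raw)
            wres = manova_wilks(prep, labels)
            manova_rows.append(
                {
                    "predictor_set": set_name,
                    "term": "MANOVA",
                    "wilks_lambda": wres.wilks_lambda,
                    "f_value": wres.f_value,
                    "df1": wres.df1,
                    "df2": wres.df2,
                    "p_value": wres.p_value,
                }
            )
            for _, row in wres.univariate.iterrows():
                manova_rows.append(
                    {
                        "predictor_set": set_name,
                        "term": row["predictor"],
                        "df1": row["df"],
                        "df2": row["resid_df"],
                        "sum_sq": row["sum_sq"],
                        "mean_sq": row["mean_sq"],
                        "f_value": row["f_value"],
                        "p_value": row["p_value"],
                    }
                )
            for mode, split in (
                (config.lda_priors, None),
                ("frequency", None),
                ("uniform", config.train_fraction),
            ):
                tag = f"{set_name}_{mode}" + ("_split" if split else "")
                if tag in confusions:
                    continue
                res = lda_fit_predict(
                    prep,
                    labels,
                    priors=mode,
                    split_fraction=split,
                    seed=int(config.stage_rng(f"lda:{tag}").integers(2**31)),
                )
                confusions[tag] = res.confusion

    manifest = {
        "package_version": __version__,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "n_perm": config.n_perm,
        "graphs": list(config.graphs),
        "weight_style": config.weight_style,
        "tsallis_q": config.tsallis_q,
        "lda_priors": config.lda_priors,
        "train_fraction": config.train_fraction,
        "permute": config.permute,
        "n_sites": sites.n_sites,
        "n_species": abundance.n_species,
        "selected_mems": {k: v for k, v in selected.items()},
    }

    result = PipelineResult(
        scalogram_table=pd.DataFrame(scal_rows),
        moran_table=pd.DataFrame(moran_rows),
        manova_table=pd.DataFrame(manova_rows),
        diversity_sites=div["sites"],
        diversity_groups=div["groups"],
        lda_confusions=confusions,
        selected_mems=selected,
        manifest=manifest,
    )

    if out_dir is not None:
        out = Path(out_dir)
        write_table(result.scalogram_table, out / "scalogram_table.tsv")
        write_table(result.moran_table, out / "moran_table.tsv")
        write_table(result.manova_table, out / "manova_table.tsv")
        write_table(result.diversity_sites, out / "diversity_sites.tsv")
        write_table(result.diversity_groups, out / "diversity_groups.tsv")
        for tag, conf in confusions.items():
            write_table(conf.reset_index(names="true_class"), out / f"confusion_{tag}.tsv")
        write_manifest(manifest, out / "manifest.json")
    return result
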