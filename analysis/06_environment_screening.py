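"""Screen gridded environmental layers against background pseudo-absences.

Builds a synthetic grid stack (an elevation surface plus smooth climate
surrogates), derives slope and aspect, samples 1000 uniform background
points, and screens each candidate layer with a per-variable binomial GLM
of site presence vs background. Sites are placed preferentially along the
first climate surface, so that layer (and the terrain it shapes) should be
selected while independent layers are not. Output: results/env_screen/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from memscape.env_selection import (
    GridStack,
    derive_terrain,
    sample_background,
    select_variables,
)
from memscape.datamodel import SiteTable
from memscape.io import write_table

OUT = Path("results/env_screen")
SEED = 1


def smooth_surface(rng, shape, scale=6):
    coarse = rng.standard_normal((shape[0] // scale + 2, shape[1] // scale + 2))
    rows = np.linspace(0, coarse.shape[0] - 1.01, shape[0])
    cols = np.linspace(0, coarse.shape[1] - 1.01, shape[1])
    r0, c0 = np.floor(rows).astype(int), np.floor(cols).astype(int)
    fr, fc = rows - r0, cols - c0
    z = (
        coarse[np.ix_(r0, c0)] * np.outer(1 - fr, 1 - fc)
        + coarse[np.ix_(r0 + 1, c0)] * np.outer(fr, 1 - fc)
        + coarse[np.ix_(r0, c0 + 1)] * np.outer(1 - fr, fc)
        + coarse[np.ix_(r0 + 1, c0 + 1)] * np.outer(fr, fc)
    )
    return (z - z.mean()) / z.std()


def main() -> None:
    rng = np.random.default_rng(SEED)
    shape = (72, 90)
    stack = GridStack(cell_size=1.0)
    stack.add("elevation", 40 * smooth_surface(rng, shape) + 600)
    for j in range(6):
        stack.add(f"clim_{j + 1}", smooth_surface(rng, shape))
    derive_terrain(stack)

    # sites preferentially where clim_1 is high
    clim1 = stack.layers["clim_1"]
    flat = clim1.ravel()
    top = np.argsort(flat)[-200:]
    chosen = rng.choice(top, 23, replace=False)
    r, c = np.unravel_index(chosen, shape)
    coords = np.column_stack([c + rng.uniform(0.2, 0.8, 23), r + rng.uniform(0.2, 0.8, 23)])
    sites = SiteTable(
        site_ids=tuple(f"S{i:02d}" for i in range(23)),
        coords=coords,
        habitat=tuple(["Crop", "Edge", "Oak", "Wasteland"][i % 4] for i in range(23)),
    )

    background = sample_background(stack, 1000, seed=SEED)
    candidates = [f"clim_{j + 1}" for j in range(6)] + ["elevation", "slope"]
    selected, env = select_variables(sites, background, stack, candidates, alpha=0.05)
    OUT.mkdir(parents=True, exist_ok=True)
    write_table(pd.DataFrame({"selected": selected}), OUT / "selected_variables.tsv")
    env.data.to_csv(OUT / "env_matrix.csv")
    print(f"candidates: {candidates}")
    print(f"selected at alpha=0.05: {selected}")
    print("clim_1 (the placement driver) selected:", "clim_1" in selected)


if __name__ == "__main__":
    main()
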