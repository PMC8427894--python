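"""Build the four a-priori connectivity hypotheses over the broad landscape.

Delaunay expresses relatively unrestricted connectivity; Gabriel and the
two relative-neighbour skeletons are increasingly restricted. Reports edge
counts, verifies the nesting RNG(2) within Gabriel within Delaunay, and
writes edge lists and binary weight matrices under results/graphs/.
"""

from pathlib import Path

import pandas as pd

from memscape.connectivity import build_graph, to_weight_matrix
from memscape.io import read_site_table, write_table

DATA = Path("results/data/broad")
OUT = Path("results/graphs")


def main() -> None:
    sites = read_site_table(DATA / "sites.csv")
    OUT.mkdir(parents=True, exist_ok=True)
    edges = {}
    for kind in ("delaunay", "gabriel", "rng1", "rng2"):
        g = build_graph(sites, kind)
        edges[kind] = g.edges
        w = to_weight_matrix(g, "binary")
        write_table(g.edge_frame(), OUT / f"edges_{kind}.tsv")
        pd.DataFrame(w.weights, index=sites.site_ids, columns=sites.site_ids).to_csv(
            OUT / f"weights_{kind}.csv"
        )
        print(f"{kind:9s}: {g.n_edges:3d} edges, connected={g.is_connected}")
    nested = edges["rng1"] <= edges["gabriel"] <= edges["delaunay"]
    print(f"nesting RNG(2) ⊆ Gabriel ⊆ Delaunay: {nested}")


if __name__ == "__main__":
    main()
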