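"""Fuzzy c-means clustering of dose-response profiles.

Averages replicates per (context, dose) condition, standardizes each gene's
profile, partitions the genes into 8 fuzzy clusters, and selects the
down-regulated clusters (centroid falling with dose in the TRC context) at
a membership threshold of 0.2.  Writes centroids, memberships and the
selected gene list to results/clustering/.
"""

import json
from pathlib import Path

import pandas as pd

from retinotarget import build_profiles, fuzzy_cmeans, select_responsive_genes
from retinotarget.clustering import cluster_directions
from retinotarget.io import read_expression

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "clustering"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    matrix = read_expression(ROOT / "data" / "expression.tsv")
    profiles = build_profiles(matrix)
    clustering = fuzzy_cmeans(profiles, c=8, m_fuzzifier=1.25)
    selected = select_responsive_genes(clustering, direction="down")

    centroids = pd.DataFrame(
        clustering.centroids,
        index=[f"cluster_{j+1}" for j in range(clustering.c)],
        columns=profiles.values.columns,
    )
    centroids.index.name = "cluster"
    centroids.to_csv(OUT / "centroids.tsv", sep="\t", float_format="%.10g")
    u = clustering.memberships.copy()
    u.index.name = "gene_id"
    u.to_csv(OUT / "memberships.tsv", sep="\t", float_format="%.10g")
    (OUT / "selected_genes.txt").write_text(
        "".join(f"{g}\n" for g in sorted(selected))
    )
    trends = cluster_directions(clustering)
    summary = {
        "converged": clustering.converged,
        "n_iterations": clustering.n_iter,
        "selected_clusters": clustering.selected_clusters,
        "cluster_trend_trc": {f"cluster_{j+1}": round(float(t), 4)
                              for j, t in enumerate(trends)},
        "n_selected_genes": len(selected),
        "n_zero_variance_skipped": len(profiles.skipped),
    }
    (OUT / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(
        f"{clustering.c} clusters in {clustering.n_iter} iterations; "
        f"down-regulated clusters {clustering.selected_clusters} select "
        f"{len(selected)} genes (membership >= 0.2)"
    )


if __name__ == "__main__":
    main()
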