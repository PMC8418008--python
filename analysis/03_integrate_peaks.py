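"""Filter factor-binding peaks and intersect with the responsive genes.

Retains peaks at M-value >= 0.5 and P < 0.05, assigns them to promoter
windows (2 kb upstream / 0.5 kb downstream of the TSS, strand-oriented),
and keeps the dose-responsive genes backed by at least one retained
promoter peak.  Writes the assigned peak table and candidate list to
results/integration/.
"""

import json
from pathlib import Path

import pandas as pd

from retinotarget import assign_peaks_to_genes, filter_peaks, integrate_candidates
from retinotarget.io import read_genes, read_peaks, write_peaks

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "integration"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    peaks = read_peaks(ROOT / "data" / "peaks.bed")
    genes = read_genes(ROOT / "data" / "genes.tsv")
    responsive = {
        line.strip()
        for line in (ROOT / "clustering" / "selected_genes.txt").read_text().splitlines()
        if line.strip()
    }
    retained = filter_peaks(peaks)
    assigned = assign_peaks_to_genes(retained, genes)
    candidates = integrate_candidates(assigned, responsive)

    write_peaks(
        assigned.assign(assigned_gene=assigned["assigned_gene"].fillna(".")),
        OUT / "filtered_assigned_peaks.bed",
    )
    table = pd.DataFrame(
        sorted((g, candidates.peak_m[g], candidates.n_peaks[g])
               for g in candidates.genes),
        columns=["gene_id", "peak_m", "n_peaks"],
    )
    table.to_csv(OUT / "candidates.tsv", sep="\t", index=False, float_format="%.10g")
    summary = {
        "n_peaks_input": len(peaks),
        "n_peaks_retained": len(retained),
        "n_responsive_genes": len(responsive),
        "n_candidate_genes": len(candidates.genes),
        "n_contributing_peaks": candidates.n_contributing_peaks,
    }
    (OUT / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(
        f"{len(retained)}/{len(peaks)} peaks pass M >= 0.5, P < 0.05; "
        f"{candidates.n_contributing_peaks} promoter peaks back "
        f"{len(candidates.genes)} of {len(responsive)} responsive genes"
    )


if __name__ == "__main__":
    main()
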