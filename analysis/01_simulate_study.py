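"""Generate the synthetic multi-omic study with planted ground truth.

Writes the full input bundle — expression matrix (3 contexts x 3 doses x 3
replicates), factor-binding peaks, pathway catalog, enhancer landscape,
gene annotation and viability plates — to results/data/, plus the planted
truth for later comparison.
"""

import json
from pathlib import Path

from retinotarget import SimulationConfig
from retinotarget import synth
from retinotarget.io import (
    write_enhancers, write_expression, write_genes, write_gmt, write_peaks,
    write_sample_sheet, write_viability,
)
from retinotarget.config import dump_config

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = SimulationConfig(seed=SEED)
    sim = synth.generate_expression(config)
    write_expression(sim.matrix, OUT / "expression.tsv")
    write_sample_sheet(sim.matrix, OUT / "samples.tsv")
    write_genes(synth.generate_gene_annotation(config), OUT / "genes.tsv")
    write_peaks(synth.generate_peaks(config).peaks, OUT / "peaks.bed")
    write_gmt(synth.generate_pathway_catalog(config), OUT / "pathways.gmt")
    enh = synth.generate_enhancer_signal(1000, 50, seed=SEED)
    write_enhancers(enh.regions, OUT / "enhancers.bed")
    doses = [0.31, 0.62, 1.25, 2.5, 5.0, 10.0, 20.0]
    write_viability(
        synth.generate_viability(2.83, 1.5, doses, noise_sd=0.01, seed=SEED),
        OUT / "viability_a.csv",
    )
    write_viability(
        synth.generate_viability(7.0, 1.2, doses, noise_sd=0.01, seed=SEED + 1),
        OUT / "viability_b.csv",
    )
    write_viability(
        synth.generate_combo_viability(
            2.83, 1.5, 7.0, 1.2, ratio_a=0.5, total_doses=doses,
            potency_shift=0.6, noise_sd=0.01, seed=SEED + 2,
        ),
        OUT / "viability_combo.csv",
    )
    dump_config(config, OUT / "config.yaml")
    truth = {
        "driver_gene": sim.truth.driver_gene,
        "companion_genes": list(sim.truth.companion_genes),
        "down_genes": sorted(sim.truth.down_genes),
        "se_truth": sorted(enh.is_super_truth.index[enh.is_super_truth]),
    }
    (OUT / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    print(
        f"simulated {config.n_genes} genes x {config.n_samples} samples; "
        f"driver = {sim.truth.driver_gene} with "
        f"{len(sim.truth.companion_genes)} planted neighbors -> {OUT}"
    )


if __name__ == "__main__":
    main()
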