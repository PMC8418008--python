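"""Concentration-response pharmacology of the simulated plates.

Fits 4PL curves to both single-agent viability plates, recovers their
IC50s, and computes the Chou-Talalay combination index of the fixed-ratio
combination plate at the median effect (fa = 0.5).  Writes fits and CI to
results/pharmacology/.
"""

import json
from pathlib import Path

from retinotarget import combination_index, fit_4pl
from retinotarget.io import read_viability

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "pharmacology"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    single_a = read_viability(ROOT / "data" / "viability_a.csv")
    single_b = read_viability(ROOT / "data" / "viability_b.csv")
    combo = read_viability(ROOT / "data" / "viability_combo.csv")

    fits = {}
    for name, table in (("drug_a", single_a), ("drug_b", single_b)):
        fit = fit_4pl(table)
        fits[name] = {
            "ic50_uM": fit.ic50, "hill": fit.hill, "bottom": fit.bottom,
            "top": fit.top, "residual_sse": fit.residual_sse,
            "converged": fit.converged,
        }
    result = combination_index(single_a, single_b, combo, effect_level=0.5)
    ci_out = {
        "ci": result.ci,
        "effect_level": result.effect_level,
        "dm_a_uM": result.fit_a.dm, "h_a": result.fit_a.h,
        "dm_b_uM": result.fit_b.dm, "h_b": result.fit_b.h,
        "dm_combo_uM": result.fit_combo.dm, "h_combo": result.fit_combo.h,
    }
    (OUT / "fits.json").write_text(json.dumps(fits, indent=2) + "\n")
    (OUT / "combination_index.json").write_text(json.dumps(ci_out, indent=2) + "\n")
    verdict = (
        "synergy" if result.ci < 1 else
        "antagonism" if result.ci > 1 else "additivity"
    )
    print(
        f"IC50: drug A {fits['drug_a']['ic50_uM']:.2f} uM, "
        f"drug B {fits['drug_b']['ic50_uM']:.2f} uM; "
        f"CI at fa=0.5: {result.ci:.2f} ({verdict})"
    )


if __name__ == "__main__":
    main()
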