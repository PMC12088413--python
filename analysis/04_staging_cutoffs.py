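"""Calibrate the three accumulation-level cutoffs on the simulated cohort.

Reads results/cell_table.csv (run 01 first), derives (i) the background
cutoff from simulated somatic/leptotene control levels, (ii) the plateau
cutoff above which no genotype's decay exponent differs from zero, and
(iii) per-genotype late-pachytene cutoffs where prominent-focus means match
the diakinesis crossover means. Writes results/cutoffs.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from meioquant import staging

OUT = Path(__file__).resolve().parents[1] / "results"
DIAKINESIS_MEANS = {"2X": 10.0, "NEO-4X": 22.0, "HYB-4X": 18.0, "EST-4X": 17.0}


def main(seed: int = 1):
    tab = pd.read_csv(OUT / "cell_table.csv")
    cells = tab.rename(columns={"H_true": "accumulation_pct",
                                "asynapsis_true": "asy1_length_um",
                                "n_prominent_true": "n_prominent"})

    rng = np.random.default_rng(seed)
    controls = np.minimum(np.clip(rng.normal(7.0, 2.5, 40), 0.5, None), 12.0)
    bg = staging.background_cutoff(controls)
    kept, excluded, counts = staging.filter_by_cutoff(cells, bg.cutoff_pct)
    print(f"background cutoff {bg.cutoff_pct:.0f}% -> retained {len(kept)}, "
          f"excluded {len(excluded)}")

    plateau = staging.plateau_cutoff(kept)
    print(f"plateau cutoff: {plateau.cutoff_pct} "
          f"(smallest level with all decay exponents flat at alpha=0.05)")

    late = staging.late_pachytene_cutoffs(kept, DIAKINESIS_MEANS)
    late_cuts = {g: r.cutoff_pct for g, r in late.items()}
    print("late-pachytene cutoffs:", late_cuts)

    OUT.mkdir(exist_ok=True)
    (OUT / "cutoffs.json").write_text(json.dumps({
        "background_cutoff_pct": bg.cutoff_pct,
        "n_retained": len(kept),
        "n_excluded": len(excluded),
        "plateau_cutoff_pct": plateau.cutoff_pct,
        "late_pachytene_cutoffs_pct": late_cuts,
    }, indent=1))


if __name__ == "__main__":
    main()
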