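"""Count regressions: meiotic stability, coalignment, synapsis initiation,
and the crossover-asynapsis relationship.

Reads results/cell_table.csv and fits (i) negative-binomial models of
quadrivalent and univalent counts per genotype, (ii) the parallels ~ ASY1
length model on the 30-150 µm coalignment window with prediction at 100 µm,
(iii) the elongated-ZYP1 ~ total ZYP1 length model on early-zygotene cells,
and (iv) the Poisson GLM of crossover foci on asynapsis in late-pachytene
cells. Writes results/count_models.json.
"""

import json
import math
from pathlib import Path

import pandas as pd

from meioquant import infer, staging

OUT = Path(__file__).resolve().parents[1] / "results"
DIAKINESIS_MEANS = {"2X": 10.0, "NEO-4X": 22.0, "HYB-4X": 18.0, "EST-4X": 17.0}


def main():
    tab = pd.read_csv(OUT / "cell_table.csv")
    out = {}

    # metaphase-I stability: quadrivalents and univalents
    for resp in ("n_quadrivalent_true", "n_univalent_true"):
        fit, table = infer.select_family(tab[tab[resp].notna()], [
            dict(label="poisson", response=resp, family="poisson",
                 random_intercept="plant_id"),
            dict(label="negbin", response=resp, family="negbin",
                 random_intercept="plant_id"),
        ])
        means = {g: round(math.exp(fit.coef(f"b0[{g}]")), 2)
                 for g in DIAKINESIS_MEANS}
        print(f"{resp}: family={fit.family} sigma_u={fit.sigma_u:.2f} "
              f"fitted means={means}")
        out[resp] = dict(family=fit.family, means=means, aic=fit.aic,
                         sigma_u=fit.sigma_u)

    # coalignment: parallels ~ ASY1 length on the 30-150 µm window; only
    # genotypes with enough window cells support the prediction at 100 µm
    window = tab[(tab["asynapsis_true"] >= 30) & (tab["asynapsis_true"] <= 150)].copy()
    well_sampled = window["genotype"].value_counts()
    window = window[window["genotype"].isin(well_sampled[well_sampled >= 10].index)]
    window["asy1_per_100um"] = window["asynapsis_true"] / 100.0
    pfit = infer.fit_count_model(window, "n_parallel_true",
                                 covariate="asy1_per_100um", family="negbin")
    pred100 = {g: round(math.exp(pfit.coef(f"b0[{g}]") + pfit.coef(f"b1[{g}]")), 2)
               for g in pd.unique(window["genotype"])}
    print(f"\nparallels at ASY1 = 100 um ({len(window)} window cells): {pred100} "
          f"(lowest: {min(pred100, key=pred100.get)})")
    out["parallels_at_100um"] = pred100

    # synapsis initiation: elongated ZYP1 segments vs total ZYP1 length. The
    # cohort above holds zygotene-to-pachytene cells, so early zygotene is
    # simulated as its own small dataset (as it was imaged separately):
    # total ZYP1 spans 0-40 µm and elongated counts follow the identity-link
    # means, with the established tetraploid elongating faster from fewer
    # initial stretches than the neo-tetraploid.
    import numpy as np

    from meioquant import synthgen

    rng = np.random.default_rng(2)
    frames = []
    for g in synthgen.default_genotypes():
        if g.name not in ("NEO-4X", "EST-4X"):
            continue
        L = rng.uniform(0.0, 40.0, 80)
        frames.append(pd.DataFrame(dict(
            genotype=g.name, zyp1_length_um=L,
            n_elongated=rng.poisson(g.elong_intercept + g.elong_slope * L),
        )))
    early = pd.concat(frames, ignore_index=True)
    efit = infer.fit_count_model(early, "n_elongated",
                                 covariate="zyp1_length_um", family="poisson",
                                 link="identity")
    elong = {g: dict(intercept=round(efit.coef(f"b0[{g}]"), 2),
                     slope=round(efit.coef(f"b1[{g}]"), 3))
             for g in pd.unique(early["genotype"])}
    print("\nelongated-ZYP1 model (identity link, early zygotene):")
    for g, d in elong.items():
        print(f"  {g}: initial {d['intercept']}, +{d['slope']}/um ZYP1")
    slope_contrast = infer.wald_contrasts(
        efit, {"slope NEO - EST": {"b1[NEO-4X]": 1.0, "b1[EST-4X]": -1.0},
               "intercept NEO - EST": {"b0[NEO-4X]": 1.0, "b0[EST-4X]": -1.0}})
    print(slope_contrast.round(4).to_string(index=False))
    out["elongation_model"] = elong

    # crossovers vs asynapsis in late-pachytene cells
    cells = tab.rename(columns={"H_true": "accumulation_pct",
                                "asynapsis_true": "asy1_length_um",
                                "n_prominent_true": "n_prominent"})
    late = staging.late_pachytene_cutoffs(cells, DIAKINESIS_MEANS)
    parts = [cells[(cells["genotype"] == g)
                   & (cells["accumulation_pct"] > r.cutoff_pct)]
             for g, r in late.items()]
    late_cells = pd.concat(parts)
    co = infer.fit_co_asynapsis(late_cells)
    print(f"\ncrossovers ~ asynapsis (Poisson GLM, {len(late_cells)} late cells): "
          f"slope = {co.coef('b1'):.5f} (p = {co.wald_p('b1'):.2e}), "
          f"pseudo-R2 = {infer.pseudo_r2(co)[0]:.3f}")
    out["co_asynapsis"] = dict(slope=co.coef("b1"), p=co.wald_p("b1"),
                               r2=infer.pseudo_r2(co)[0], n=len(late_cells))

    OUT.mkdir(exist_ok=True)
    (OUT / "count_models.json").write_text(json.dumps(out, indent=1))


if __name__ == "__main__":
    main()
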