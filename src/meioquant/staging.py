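"""Cutoff calibration: converting raw HEI10 accumulation levels into
analysable developmental windows.

Three procedures are implemented:

* a background cutoff from somatic/leptotene control cells (levels below it
  are indistinguishable from background and are excluded);
* a plateau cutoff — the smallest accumulation level above which every
  genotype's decay exponent is statistically indistinguishable from zero,
  i.e. cells have reached their asynapsis minimum;
* per-genotype late-pachytene cutoffs — the accumulation level above which
  the mean prominent-focus count most closely matches the genotype's
  diakinesis crossover mean, so that prominent foci can be read as
  crossovers.

Plus the diploid ASY1-length doubling that puts diploid axis measurements on
the tetraploid scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import infer

__all__ = [
    "CutoffResult",
    "background_cutoff",
    "filter_by_cutoff",
    "plateau_cutoff",
    "late_pachytene_cutoffs",
    "normalize_diploid",
]

DEFAULT_GRID = tuple(range(13, 91))  # integer percents


@dataclass
class CutoffResult:
    """A calibrated accumulation-level threshold with its selection trace."""

    cutoff_pct: float | None
    rule: str  # background | plateau | late_pachytene
    trace: pd.DataFrame
    genotype: str = "all"

    def __post_init__(self):
        if self.cutoff_pct is not None and not 0.0 <= self.cutoff_pct <= 100.0:
            raise ValueError("cutoff_pct must lie in [0, 100]")
        if len(self.trace) == 0:
            raise ValueError("trace must be non-empty")
        if self.cutoff_pct is not None and not np.any(
            np.isclose(self.trace["cutoff"], self.cutoff_pct)
        ):
            raise ValueError("cutoff must appear in the trace")


def background_cutoff(control_levels, grid_step: float = 1.0) -> CutoffResult:
    """Detection-confidence cutoff: the control maximum, rounded up to the grid.

    Control cells (somatic or leptotene) carry no true HEI10 signal, so the
    largest accumulation level they register bounds what background alone can
    produce.
    """
    levels = np.asarray(control_levels, dtype=float)
    if levels.size == 0:
        raise ValueError("empty control set")
    mx = float(levels.max())
    cutoff = math.ceil(mx / grid_step - 1e-9) * grid_step
    trace = pd.DataFrame(
        [dict(cutoff=cutoff, statistic="max", value=mx, mean=float(levels.mean()),
              n=int(levels.size))]
    )
    return CutoffResult(cutoff_pct=float(cutoff), rule="background", trace=trace)


def filter_by_cutoff(cells: pd.DataFrame, cutoff: float):
    """Retain analysable cells: accumulation >= cutoff, QC pass, no linear HEI10.

    Returns (retained, excluded) — an exact partition of the input — plus the
    retained/excluded counts per genotype.
    """
    acc = cells["accumulation_pct"].to_numpy(dtype=float)
    qc = cells["qc_pass"].to_numpy(dtype=bool) if "qc_pass" in cells else np.ones(len(cells), bool)
    lin = (
        cells["has_linear_hei10"].to_numpy(dtype=bool)
        if "has_linear_hei10" in cells
        else np.zeros(len(cells), bool)
    )
    keep = (acc >= cutoff) & qc & ~lin
    retained = cells[keep]
    excluded = cells[~keep]
    counts = (
        pd.DataFrame({"genotype": cells["genotype"], "retained": keep})
        .groupby("genotype", sort=False)["retained"]
        .agg(retained="sum", excluded=lambda s: int((~s).sum()))
        .reset_index()
    )
    return retained, excluded, counts


def plateau_cutoff(
    cells: pd.DataFrame,
    alpha: float = 0.05,
    grid=DEFAULT_GRID,
    min_cells_per_genotype: int = 10,
    **decay_kwargs,
) -> CutoffResult:
    """Smallest accumulation level past which synapsis no longer progresses.

    Scanning the grid in ascending order, the decay model is refitted on the
    strict subset of cells with accumulation > c; the first candidate at
    which every genotype's decay-exponent Wald p is >= alpha is returned.
    Candidates whose subsets are too small to fit are skipped and logged in
    the trace. If no candidate satisfies the rule, ``cutoff_pct`` is None.
    """
    rows = []
    chosen = None
    for c in sorted(grid):
        sub = cells[cells["accumulation_pct"] > c]
        per_g = sub.groupby("genotype", sort=False).size()
        if len(sub) == 0 or (per_g < min_cells_per_genotype).any() or \
                set(sub["genotype"]) != set(cells["genotype"]):
            rows.append(dict(cutoff=float(c), status="skipped: too few cells",
                             n_cells=len(sub), min_p=np.nan))
            continue
        try:
            fit = infer.fit_gamma_decay(sub, **decay_kwargs)
        except Exception as err:  # noqa: BLE001 - candidate-level failure is logged
            rows.append(dict(cutoff=float(c), status=f"skipped: {err}",
                             n_cells=len(sub), min_p=np.nan))
            continue
        pvals = fit.slope_pvalues()
        row = dict(cutoff=float(c), status="evaluated", n_cells=len(sub),
                   min_p=min(pvals.values()))
        for g, p in pvals.items():
            row[f"p[{g}]"] = p
        rows.append(row)
        if all(p >= alpha for p in pvals.values()):
            chosen = float(c)
            break
    trace = pd.DataFrame(rows)
    return CutoffResult(cutoff_pct=chosen, rule="plateau", trace=trace)


def late_pachytene_cutoffs(
    cells: pd.DataFrame,
    diakinesis_means: dict[str, float],
    grid=DEFAULT_GRID,
    min_cells: int = 5,
    foci_col: str = "n_prominent",
) -> dict[str, CutoffResult]:
    """Per-genotype accumulation level where foci match diakinesis crossovers.

    For each genotype and candidate c, the mean prominent-focus count over
    cells with accumulation > c is compared with the genotype's diakinesis
    crossover mean; the candidate minimising the absolute distance wins
    (smallest candidate among exact ties). Candidates with fewer than
    ``min_cells`` cells above them are not considered.
    """
    out: dict[str, CutoffResult] = {}
    for g, diak in diakinesis_means.items():
        sub = cells[cells["genotype"] == g]
        if len(sub) < 10:
            raise ValueError(f"genotype {g!r} has fewer than 10 cells")
        rows = []
        for c in sorted(grid):
            above = sub[sub["accumulation_pct"] > c]
            if len(above) < min_cells:
                continue
            m = float(above[foci_col].mean())
            rows.append(dict(cutoff=float(c), mean_foci=m, n_cells=len(above),
                             distance=abs(m - diak)))
        if not rows:
            raise ValueError(
                f"genotype {g!r}: no candidate cutoff retains >= {min_cells} cells"
            )
        trace = pd.DataFrame(rows)
        best = int(np.argmin(trace["distance"].to_numpy()))
        out[g] = CutoffResult(
            cutoff_pct=float(trace["cutoff"].iloc[best]), rule="late_pachytene",
            trace=trace, genotype=g,
        )
    return out


def normalize_diploid(
    cells: pd.DataFrame, diploid_label: str = "2X", factor: float = 2.0,
    column: str = "asy1_length_um",
) -> pd.DataFrame:
    """Scale diploid ASY1 lengths onto the tetraploid axis-content scale.

    Diploids carry half the chromosome complement, so their axis lengths are
    doubled for direct comparison. Guarded by a provenance column so it can
    only be applied once.
    """
    if "diploid_normalized" in cells.columns and cells["diploid_normalized"].any():
        raise ValueError("diploid normalization already applied")
    if diploid_label not in set(cells["genotype"]):
        raise ValueError(f"diploid label {diploid_label!r} not present")
    out = cells.copy()
    m = out["genotype"] == diploid_label
    out.loc[m, column] = out.loc[m, column] * factor
    out["diploid_normalized"] = True
    return out
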