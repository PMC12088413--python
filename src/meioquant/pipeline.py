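"""End-to-end orchestration: stacks or tables -> measurements -> staging ->
models -> report."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import infer, io, quantify, staging

__all__ = ["PipelineConfig", "Report", "run_pipeline", "measurements_table"]

log = logging.getLogger("meioquant")


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    ``input_mode`` is 'table' (per-cell measurement CSV / DataFrame) or
    'stacks' (directory of OME-TIFF stacks). Stage subsets are derived from
    measurements, never from file names.
    """

    input_mode: str = "table"
    input_path: str | None = None
    output_dir: str | None = None
    background_cutoff_pct: float = 12.0
    control_levels: list[float] | None = None
    alpha: float = 0.05
    grid: tuple = staging.DEFAULT_GRID
    diakinesis_means: dict[str, float] | None = None
    diploid_label: str = "2X"
    double_diploid: bool = True
    coalign_window_um: tuple[float, float] = (30.0, 150.0)
    zygotene_max_zyp1_um: float = 40.0
    seed: int = 0
    quantify: quantify.QuantifyConfig = field(default_factory=quantify.QuantifyConfig)

    def __post_init__(self):
        if self.input_mode not in ("table", "stacks"):
            raise ValueError("input_mode must be 'table' or 'stacks'")
        if self.double_diploid and not self.diploid_label:
            raise ValueError("diploid doubling requested without a diploid label")


@dataclass
class Report:
    """Everything a run produced, with an exact exclusion ledger."""

    measurements: pd.DataFrame
    retained: pd.DataFrame
    exclusions: pd.DataFrame  # cell_id/index + reason
    background: staging.CutoffResult
    decay_fit: infer.DecayFit
    onset_predictions: pd.DataFrame
    decay_contrasts: pd.DataFrame
    plateau: staging.CutoffResult | None
    final_asynapsis: pd.DataFrame | None
    late_pachytene: dict[str, staging.CutoffResult] | None
    co_fit: infer.CountFit | None
    parallel_fit: infer.CountFit | None
    config: PipelineConfig | None = None

    def validate_partition(self) -> bool:
        n = len(self.measurements)
        return n == len(self.retained) + len(self.exclusions)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_table(self.measurements, outdir / "measurements.csv")
        io.write_table(self.retained, outdir / "retained_cells.csv")
        io.write_table(self.exclusions, outdir / "exclusion_ledger.csv")
        io.write_table(self.onset_predictions, outdir / "onset_predictions.csv")
        io.write_table(self.decay_contrasts, outdir / "decay_contrasts.csv")
        fits = {
            "decay": _fit_to_dict(self.decay_fit),
            "background_cutoff": self.background.cutoff_pct,
            "plateau_cutoff": None if self.plateau is None else self.plateau.cutoff_pct,
        }
        if self.late_pachytene:
            fits["late_pachytene_cutoffs"] = {
                g: r.cutoff_pct for g, r in self.late_pachytene.items()
            }
        if self.co_fit is not None:
            fits["co_asynapsis"] = _fit_to_dict(self.co_fit)
        if self.parallel_fit is not None:
            fits["parallels"] = _fit_to_dict(self.parallel_fit)
        if self.config is not None:
            cfg = dataclasses.asdict(self.config)
            cfg["quantify"] = dataclasses.asdict(self.config.quantify)
            cfg["grid"] = list(cfg["grid"])
            fits["config"] = cfg
        (outdir / "fits.json").write_text(json.dumps(fits, indent=1, default=_json_default))


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not serializable: {type(o)}")


def _fit_to_dict(fit) -> dict:
    d = {"param_names": list(fit.param_names), "params": np.asarray(fit.params).tolist(),
         "cov": np.asarray(fit.cov).tolist(), "loglik": fit.loglik, "aic": fit.aic,
         "sigma_u": fit.sigma_u}
    for attr in ("shape", "theta", "r2", "r2_marginal", "r2_conditional",
                 "glm_fallback", "zero_replacement", "pearson_dispersion"):
        if hasattr(fit, attr):
            d[attr] = getattr(fit, attr)
    return d


def measurements_table(stacks, config: quantify.QuantifyConfig | None = None) -> pd.DataFrame:
    """Quantify a list of stacks into a per-cell measurement table."""
    rows = []
    for st in stacks:
        m = quantify.quantify_cell(st, config)
        log.info("quantified cell=%s qc=%s acc=%.1f", st.cell_id, m.qc_pass,
                 m.accumulation_pct)
        rows.append(dataclasses.asdict(m))
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, cells: pd.DataFrame | None = None) -> Report:
    """Execute the full analysis and return a :class:`Report`.

    Order of stages: quantification (stacks mode) or table ingest; background
    cutoff (from control cells when provided, else the configured value);
    QC/level filtering into an exclusion ledger; diploid ASY1 doubling; decay
    GLMM with onset predictions and decay-exponent contrasts; plateau search
    and final asynapsis; late-pachytene calibration and the crossover ~
    asynapsis model (when diakinesis means are given); coalignment-geometry
    model on the 30-150 µm ASY1 window.
    """
    if config.input_mode == "stacks":
        stacks = io.read_stacks(config.input_path)
        cells = measurements_table(stacks, config.quantify)
    elif cells is None:
        if not config.input_path:
            raise ValueError("table mode requires cells or input_path")
        cells = io.read_table(config.input_path)
    if len(cells) == 0:
        raise ValueError("empty input: no cells to analyse")
    cells = cells.reset_index(drop=True)
    if "cell_id" not in cells or cells["cell_id"].eq("").all():
        cells = cells.assign(cell_id=[f"cell_{i:04d}" for i in range(len(cells))])

    # --- staging ---------------------------------------------------------
    if config.control_levels:
        background = staging.background_cutoff(config.control_levels)
    else:
        background = staging.CutoffResult(
            cutoff_pct=config.background_cutoff_pct, rule="background",
            trace=pd.DataFrame([dict(cutoff=config.background_cutoff_pct,
                                     statistic="configured", value=np.nan)]),
        )
    retained, excluded, _counts = staging.filter_by_cutoff(cells, background.cutoff_pct)
    reasons = []
    for _, row in excluded.iterrows():
        if "qc_pass" in row and not row.get("qc_pass", True):
            reasons.append(row.get("qc_reason", "") or "qc fail")
        elif row.get("has_linear_hei10", False):
            reasons.append("linear HEI10 signal")
        else:
            reasons.append(f"accumulation below {background.cutoff_pct:g}%")
    exclusions = excluded.assign(reason=reasons)[["cell_id", "reason"]] if len(excluded) \
        else pd.DataFrame(columns=["cell_id", "reason"])

    if config.double_diploid and config.diploid_label in set(retained["genotype"]):
        retained = staging.normalize_diploid(retained, config.diploid_label)

    # --- decay model -----------------------------------------------------
    fit = infer.fit_gamma_decay(retained)
    onset = infer.predict_asynapsis(fit, background.cutoff_pct)
    gts = fit.genotypes
    contrasts = {
        f"b1[{a}] - b1[{b}]": {f"b1[{a}]": 1.0, f"b1[{b}]": -1.0}
        for i, a in enumerate(gts) for b in gts[i + 1:]
    }
    contrasts.update({f"b1[{g}]": {f"b1[{g}]": 1.0} for g in gts})
    decay_contrasts = infer.wald_contrasts(fit, contrasts)

    plateau = staging.plateau_cutoff(retained, alpha=config.alpha, grid=config.grid)
    final_asyn = None
    if plateau.cutoff_pct is not None:
        top = retained[retained["accumulation_pct"] > plateau.cutoff_pct]
        final_asyn = (
            top.groupby("genotype", sort=False)["asy1_length_um"]
            .agg(["mean", "sem", "count"]).reset_index()
        )

    # --- late pachytene + crossover model --------------------------------
    late = None
    co_fit = None
    if config.diakinesis_means:
        late = staging.late_pachytene_cutoffs(
            retained, config.diakinesis_means, grid=config.grid
        )
        parts = []
        for g, res in late.items():
            sub = retained[(retained["genotype"] == g)
                           & (retained["accumulation_pct"] > res.cutoff_pct)]
            parts.append(sub)
        late_cells = pd.concat(parts) if parts else retained.iloc[:0]
        if len(late_cells) >= 3:
            co_fit = infer.fit_co_asynapsis(late_cells)

    # --- coalignment geometry --------------------------------------------
    parallel_fit = None
    if "n_parallel" in retained.columns:
        lo, hi = config.coalign_window_um
        window = retained[(retained["asy1_length_um"] >= lo)
                          & (retained["asy1_length_um"] <= hi)].copy()
        if len(window) >= 20 and (window["n_parallel"] > 0).any():
            window["asy1_per_100um"] = window["asy1_length_um"] / 100.0
            try:
                parallel_fit = infer.fit_count_model(
                    window, response="n_parallel", covariate="asy1_per_100um",
                    family="negbin", link="log",
                    random_intercept="plant_id" if window["plant_id"].nunique() > len(
                        window["genotype"].unique()) else None,
                )
            except (ValueError, RuntimeError) as err:
                log.warning("parallel-geometry model failed: %s", err)

    report = Report(
        measurements=cells, retained=retained, exclusions=exclusions,
        background=background, decay_fit=fit, onset_predictions=onset,
        decay_contrasts=decay_contrasts, plateau=plateau,
        final_asynapsis=final_asyn, late_pachytene=late, co_fit=co_fit,
        parallel_fit=parallel_fit, config=config,
    )
    if not report.validate_partition():
        raise RuntimeError("exclusion ledger does not partition the input cells")
    if config.output_dir:
        report.save(config.output_dir)
    return report
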