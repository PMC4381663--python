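"""Pipeline orchestration: configuration, staged execution and reports.

The pipeline runs standards -> quantify -> colony statistics -> model
selection and writes, per run: a calibration summary, the per-cell
quantification table, a nested-ANOVA table, a per-colony model-selection
report (hypothesis weights, best model, fitted mixture, proportion of
heterogeneous cells), a per-cell classification table and a structured log
recording every QC exclusion.  Inputs are either CSV tables or the bundled
synthetic generator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import betamodels, colonystats, qpcr, synthetic

__all__ = ["RunConfig", "run_pipeline", "PipelineResult"]

FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Flat, YAML-loadable run configuration with study-default constants."""

    mode: str = "synthetic"  # "synthetic" | "csv"
    seed: int = 1
    out_dir: str = "results"
    # csv-mode inputs
    ct_table: str | None = None
    standard_curves: str | None = None
    # synthetic-mode generator knobs
    n_colonies: int = 6
    n_branches_per_colony: int = 3
    n_cells_per_branch: int = 10
    ct_noise_sd: float = 0.15
    include_sybr: bool = True
    # assay constants
    dilution_factor: float = 1000.0
    preamp_gain: float = 2.0**24
    tm_ref: float = 84.5
    # analysis constants
    clamp_policy: str = "fixed-eps"
    clamp_eps: float = 1e-3
    unambiguity_cutoff: float = 0.90
    t_low: float = 0.15
    t_high: float = 0.85
    schema_version: int = 1

    def __post_init__(self) -> None:
        if not 0.5 < self.unambiguity_cutoff < 1.0:
            raise ValueError("unambiguity_cutoff must lie in (0.5, 1)")
        if not 0.0 < self.clamp_eps < 0.05:
            raise ValueError("clamp_eps must lie in (0, 0.05)")
        if self.mode not in ("synthetic", "csv"):
            raise ValueError("mode must be 'synthetic' or 'csv'")
        if self.mode == "csv" and not (self.ct_table and self.standard_curves):
            raise ValueError("csv mode requires ct_table and standard_curves paths")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def synthetic_config(self) -> synthetic.SyntheticColonyConfig:
        return synthetic.SyntheticColonyConfig(
            n_colonies=self.n_colonies,
            n_branches_per_colony=self.n_branches_per_colony,
            n_cells_per_branch=self.n_cells_per_branch,
            population_mix=(
                synthetic.DEFAULT_COLONY_MIXES
                if self.n_colonies == len(synthetic.DEFAULT_COLONY_MIXES)
                else (synthetic.DEFAULT_COLONY_MIXES[0],)
            ),
            ct_noise_sd=self.ct_noise_sd,
            dilution_factor=self.dilution_factor,
            preamp_gain=self.preamp_gain,
            include_sybr=self.include_sybr,
            tm_ref=self.tm_ref,
            seed=self.seed,
        )


@dataclass
class PipelineResult:
    """Bundle of output tables and paths from one pipeline run."""

    out_dir: Path
    curves: dict[str, qpcr.StandardCurve] = field(default_factory=dict)
    cellquant: pd.DataFrame | None = None
    anova: pd.DataFrame | None = None
    model_report: pd.DataFrame | None = None
    classification: pd.DataFrame | None = None
    log_lines: list[str] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)


def _write(df: pd.DataFrame, path: Path, sep: str = ",", index: bool = False) -> None:
    df.to_csv(path, sep=sep, index=index, float_format=FLOAT_FMT, lineterminator="\n")


def stage_simulate(config: RunConfig, out: Path, log: list[str]) -> None:
    """Generate truth, Ct-table and standard-curve CSVs from the synthetic model."""
    syn = config.synthetic_config()
    cells = synthetic.simulate_colonies(syn)
    _write(synthetic.truth_frame(cells), out / "truth.csv")
    _write(synthetic.simulate_ct_tables(cells, syn), out / "ct_table.csv")
    _write(synthetic.simulate_standard_curve_table(syn), out / "standard_curve_wells.csv")
    log.append(f"INFO simulate colonies={syn.n_colonies} cells={len(cells)} seed={syn.seed}")


def stage_standards(config: RunConfig, out: Path, log: list[str]) -> dict[str, qpcr.StandardCurve]:
    """Fit per-assay standard curves and write a calibration summary."""
    path = config.standard_curves if config.mode == "csv" else out / "standard_curve_wells.csv"
    curves = qpcr.read_standard_curve_table(path)
    rows = []
    for assay, c in sorted(curves.items()):
        in_band = 95.0 < c.efficiency_pct < 100.0
        rows.append(
            {
                "assay": assay,
                "slope": c.slope,
                "intercept": c.intercept,
                "r2": c.r2,
                "efficiency_pct": c.efficiency_pct,
                "efficiency_in_band": in_band,
            }
        )
        if not in_band:
            log.append(f"WARN standards assay={assay} efficiency={c.efficiency_pct:.2f}% outside 95-100%")
    _write(pd.DataFrame(rows), out / "standard_curves.tsv", sep="\t")
    return curves


def stage_quantify(
    config: RunConfig, out: Path, curves: dict[str, qpcr.StandardCurve], log: list[str]
) -> pd.DataFrame:
    """Apply QC and per-cell quantification to the Ct table."""
    path = config.ct_table if config.mode == "csv" else out / "ct_table.csv"
    ct = qpcr.read_ct_table(path)
    tm_ref = config.tm_ref if "SYBR" in curves else None
    cq = qpcr.quantify_table(
        ct,
        curves,
        dilution_factor=config.dilution_factor,
        preamp_gain=config.preamp_gain,
        tm_ref=tm_ref,
        log=log,
    )
    _write(cq, out / "cellquant.csv")
    log.append(f"INFO quantify cells={len(cq)}")
    return cq


def stage_stats(config: RunConfig, out: Path, cq: pd.DataFrame, log: list[str],
                errors: list[str]) -> pd.DataFrame | None:
    """Nested ANOVA on arcsine ratios and the copy-number regression."""
    anova = None
    try:
        transformed = colonystats.arcsin_transform(cq["ratio"].to_numpy())
        anova = colonystats.nested_anova(transformed, cq["colony"], cq["branch"])
        _write(anova.reset_index(), out / "anova.tsv", sep="\t")
    except ValueError as exc:
        errors.append(f"anova: {exc}")
        log.append(f"ERROR anova {exc}")
    try:
        fit = colonystats.quadratic_regression(cq["ratio"], cq["c_total"])
        reg = pd.DataFrame(
            [
                {
                    "b0": fit.coef[0],
                    "b1": fit.coef[1],
                    "b2": fit.coef[2],
                    "r2": fit.r2,
                    "f_stat": fit.f_stat,
                    "p": fit.f_pvalue,
                    "n": fit.n,
                }
            ]
        )
        _write(reg, out / "regression.tsv", sep="\t")
    except ValueError as exc:
        errors.append(f"regression: {exc}")
        log.append(f"ERROR regression {exc}")
    return anova


def _format_model(fit: betamodels.HypothesisFit) -> str:
    if fit.spec.name == "H2":
        pi, a1, b1, a2, b2 = fit.params
        return (
            f"{pi:.3f}*Beta({a1:.4g},{b1:.4g})+{1 - pi:.3f}*Beta({a2:.4g},{b2:.4g})"
        )
    a, b = fit.params
    return f"Beta({a:.4g},{b:.4g})"


def stage_fit(
    config: RunConfig, out: Path, cq: pd.DataFrame, log: list[str], errors: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-colony model selection (branches pooled) and cell classification."""
    report_rows, class_rows = [], []
    for colony, grp in cq.groupby("colony", sort=True):
        ratios = grp["ratio"].to_numpy(dtype=float)
        sample = betamodels.RatioSample(str(colony), ratios)
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                result = betamodels.select_model(
                    sample,
                    cutoff=config.unambiguity_cutoff,
                    role_thresholds=(config.t_low, config.t_high),
                    clamp_policy=config.clamp_policy,
                    clamp_eps=config.clamp_eps,
                )
            for w in caught:
                log.append(f"WARN fit colony={colony} {w.message}")
        except ValueError as exc:
            errors.append(f"fit colony {colony}: {exc}")
            log.append(f"ERROR fit colony={colony} {exc}")
            continue
        notes = "; ".join(
            f"{h}: not fitted ({msg})" for h, msg in sorted(result.fit_errors.items())
        )
        best_fit = result.fits[result.best]
        for h, fit in result.fits.items():
            if fit is not None:
                log.append(
                    f"INFO fit colony={colony} hyp={h} loglik={fit.loglik:.6f} "
                    f"aicc={fit.aicc:.6f} starts={fit.n_starts} "
                    f"best_start={np.array2string(fit.best_start, precision=3)} "
                    f"converged={fit.converged}"
                )
        report_rows.append(
            {
                "colony": colony,
                "best": result.best,
                "w_H0": result.weights["H0"],
                "w_H1": result.weights["H1"],
                "w_H2": result.weights["H2"],
                "params_best": _format_model(best_fit),
                "prop_heterogeneous": result.proportion_heterogeneous,
                "unambiguous": result.unambiguous,
                "notes": notes,
            }
        )
        cls = result.classification
        for (_, row), comp, role in zip(
            grp.iterrows(), cls.cell_components, cls.cell_roles
        ):
            class_rows.append(
                {
                    "colony": colony,
                    "branch": row["branch"],
                    "cell": row["cell"],
                    "ratio": row["ratio"],
                    "component": int(comp),
                    "role": role,
                }
            )
    report = pd.DataFrame(
        report_rows,
        columns=[
            "colony", "best", "w_H0", "w_H1", "w_H2", "params_best",
            "prop_heterogeneous", "unambiguous", "notes",
        ],
    )
    classification = pd.DataFrame(
        class_rows, columns=["colony", "branch", "cell", "ratio", "component", "role"]
    )
    _write(report, out / "model_selection.tsv", sep="\t")
    _write(classification, out / "classification.csv")
    return report, classification


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every stage and write the report bundle to ``config.out_dir``.

    A failure in one colony (or one auxiliary analysis) is logged and does
    not abort the remaining colonies; hard failures are collected in
    ``result.errors``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(out_dir=out)
    log = result.log_lines
    if config.mode == "synthetic":
        stage_simulate(config, out, log)
    result.curves = stage_standards(config, out, log)
    result.cellquant = stage_quantify(config, out, result.curves, log)
    if len(result.cellquant) == 0:
        result.errors.append("no cells passed QC")
        log.append("ERROR quantify no cells passed QC")
    else:
        result.anova = stage_stats(config, out, result.cellquant, log, result.errors)
        result.model_report, result.classification = stage_fit(
            config, out, result.cellquant, log, result.errors
        )
    (out / "run.log").write_text("\n".join(log) + "\n")
    return result
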