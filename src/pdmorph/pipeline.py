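"""Orchestration of the three cohort analyses.

* ``run_baseline`` — atrophy distribution at study entry: per-region
  reference normalization, control-derived covariate correction, a
  Lilliefors normality gate, Welch t tests of each patient group against
  controls (Kruskal-Wallis where the gate fails), percent deviations and
  Bonferroni flags.
* ``run_longitudinal`` — atrophy-rate comparison: per-region mixed-model
  fit on normalized values with the piecewise age covariate, the
  slope-equality contrast F-test, and exploratory LOWESS curves per
  group.
* ``run_converters`` — baseline comparison of cognitively normal PD
  patients who later converted to MCI/dementia (cPDN) against stable
  nonconverters (nPDN) and controls: Kruskal-Wallis omnibus per region,
  gated post hoc Welch t pairs, percent deviation between arms, and the
  correlation of pooled PDN values with a cognitive score.

Follow-up visits are used only for converter labelling; the converter
comparison itself is cross-sectional at study entry.  The Bonferroni
family is the set of p-values in one report table unless overridden,
and its size is logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import lowess as _lowess
from .cohort import LongTable, PdmorphError, Region, label_converters
from .group_stats import (
    bonferroni,
    kruskal_wallis,
    lilliefors,
    spearman,
    welch_t,
)
from .lme import ConvergenceError, build_design, contrast_F_test, fit_lme, slope_table
from .normalize import correct_table, normalize_table, percent_deviation

logger = logging.getLogger("pdmorph")

__all__ = ["RunConfig", "run_baseline", "run_longitudinal", "run_converters"]


@dataclass
class RunConfig:
    alpha: float = 0.05
    seed: int = 0
    multiplicity: int | None = None     # Bonferroni family size override
    correction_age_mode: str = "visit"  # 'visit' | 'baseline'
    lme_age_mode: str = "enrollment"    # 'enrollment' | 'visit'
    df_method: str = "satterthwaite"    # 'satterthwaite' | 'residual'
    knot: float = 60.0
    lilliefors_mc: int = 2000
    score_column: str = "cerad_total"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise PdmorphError("alpha must lie in (0, 1)")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _prepare_baseline(table: LongTable, config: RunConfig) -> LongTable:
    normalized, refs = normalize_table(table)
    logger.info("normalization references: %s",
                {k: round(v.cohort_mean, 4) for k, v in refs.items()})
    corrected, models = correct_table(normalized, age_mode=config.correction_age_mode)
    return corrected


def run_baseline(table: LongTable, config: RunConfig | None = None) -> pd.DataFrame:
    """Per-region baseline group comparison against controls."""
    config = config or RunConfig()
    raw_counts = table.baseline()["group"].value_counts()
    for g in ("CTRL", "PDN", "PDCI"):
        if raw_counts.get(g, 0) < 2:
            raise PdmorphError(f"group {g} has fewer than 2 baseline records")
    corrected = _prepare_baseline(table, config)
    base = corrected.baseline()
    groups = {g: base[base["group"] == g] for g in ("CTRL", "PDN", "PDCI")}

    rows = []
    for region in corrected.region_names():
        vals = {g: df[region].dropna().to_numpy() for g, df in groups.items()}
        normal = True
        for g, v in vals.items():
            if len(v) >= 5:
                lt = lilliefors(v, n_mc=config.lilliefors_mc, seed=config.seed)
                if lt.p < config.alpha:
                    normal = False
                    logger.info("%s: Lilliefors failed for %s (p=%.4f); "
                                "using rank test", region, g, lt.p)
        row = {
            "region": region,
            "kind": corrected.regions[region].kind,
            "test": "welch_t" if normal else "kruskal_wallis",
            "n_ctrl": len(vals["CTRL"]),
            "mean_ctrl": vals["CTRL"].mean(),
        }
        for g in ("PDN", "PDCI"):
            gl = g.lower()
            row[f"n_{gl}"] = len(vals[g])
            row[f"mean_{gl}"] = vals[g].mean()
            row[f"delta_pct_{gl}"] = float(
                percent_deviation(vals[g].mean(), vals["CTRL"].mean())
            )
            if normal:
                tr = welch_t(vals[g], vals["CTRL"])
            else:
                tr = kruskal_wallis([vals[g], vals["CTRL"]])
            row[f"stat_{gl}"] = tr.statistic
            row[f"p_{gl}"] = tr.p
        rows.append(row)

    report = pd.DataFrame(rows)
    pcols = ["p_pdn", "p_pdci"]
    m = config.multiplicity or report[pcols].size
    logger.info("baseline report: Bonferroni family size m=%d", m)
    for col in pcols:
        adj, sig = bonferroni(report[col].to_numpy(), m=m, alpha=config.alpha)
        report[col + "_bonferroni"] = adj
        report["significant_" + col.removeprefix("p_")] = sig
    return report


def run_longitudinal(
    table: LongTable,
    config: RunConfig | None = None,
    lowess_out: dict | None = None,
) -> pd.DataFrame:
    """Per-region atrophy-rate report (mixed model + slope contrast).

    Outcomes are reference-normalized (not covariate-corrected: age and
    education enter the mixed model as fixed effects).  Fit failures are
    collected per region and the run continues.  When ``lowess_out`` is
    a dict it receives, per region, the per-group exploratory LOWESS
    curves over age.
    """
    config = config or RunConfig()
    normalized, _ = normalize_table(table)
    outcomes = normalized.region_names() + ["mean_thickness"]

    fits = {}
    units = {r: normalized.regions[r].units for r in normalized.regions}
    units["mean_thickness"] = "mm"
    errors = {}
    for region in outcomes:
        if normalized.df[region].isna().all():
            continue
        try:
            design = build_design(
                normalized, region, transform=config.knot, age_mode=config.lme_age_mode
            )
            fits[region] = fit_lme(design)
            if fits[region].boundary:
                logger.warning("%s: variance component at boundary", region)
        except (ConvergenceError, PdmorphError) as exc:
            errors[region] = str(exc)
            logger.error("%s: %s", region, exc)
        if lowess_out is not None and region in fits:
            curves = {}
            for g in ("CTRL", "PDN", "PDCI"):
                sub = normalized.df[normalized.df["group"] == g]
                sub = sub[sub[region].notna()]
                if len(sub) >= 5:
                    curves[g] = _lowess.lowess_fit(
                        sub["age_at_visit"].to_numpy(), sub[region].to_numpy()
                    )
            lowess_out[region] = curves

    report = slope_table(fits, df_method=config.df_method, alpha=config.alpha, units=units)
    if errors:
        err_rows = pd.DataFrame(
            [{"region": r, "error": msg} for r, msg in errors.items()]
        )
        report = pd.concat([report, err_rows], ignore_index=True)
    return report


def run_converters(
    table: LongTable,
    config: RunConfig | None = None,
    score_column: str | None = None,
) -> pd.DataFrame:
    """Baseline converter-vs-nonconverter comparison per region.

    Requires cognitive status per visit so converters can be labelled;
    the comparison itself uses corrected baseline values only.
    """
    config = config or RunConfig()
    score_column = score_column or config.score_column
    labelled = label_converters(table)
    corrected = _prepare_baseline(labelled, config)
    base = corrected.baseline()

    arms = {
        "CTRL": base[base["group"] == "CTRL"],
        "nPDN": base[base["converter_label"] == "nPDN"],
        "cPDN": base[base["converter_label"] == "cPDN"],
    }
    for name, df in arms.items():
        if len(df) == 0:
            raise PdmorphError(f"converter arm {name} is empty")
    logger.info("converter arms: CTRL=%d nPDN=%d cPDN=%d",
                *(len(arms[a]) for a in ("CTRL", "nPDN", "cPDN")))

    rows = []
    for region in corrected.region_names():
        vals = {a: df[region].dropna().to_numpy() for a, df in arms.items()}
        omnibus = kruskal_wallis([vals["nPDN"], vals["cPDN"], vals["CTRL"]])
        row = {
            "region": region,
            "kind": corrected.regions[region].kind,
            "n_npdn": len(vals["nPDN"]),
            "n_cpdn": len(vals["cPDN"]),
            "mean_npdn": vals["nPDN"].mean(),
            "mean_cpdn": vals["cPDN"].mean(),
            "delta_pct_cpdn_vs_npdn": float(
                percent_deviation(vals["cPDN"].mean(), vals["nPDN"].mean())
            ),
            "H": omnibus.statistic,
            "p_omnibus": omnibus.p,
        }
        # descriptive pairwise arm contrast, reported for every region
        arm_t = welch_t(vals["cPDN"], vals["nPDN"])
        row["t_arms"] = arm_t.statistic
        row["p_arms"] = arm_t.p
        # post hocs only after a significant omnibus
        if omnibus.p < config.alpha:
            for a, b, tag in [
                ("cPDN", "nPDN", "cpdn_vs_npdn"),
                ("cPDN", "CTRL", "cpdn_vs_ctrl"),
                ("nPDN", "CTRL", "npdn_vs_ctrl"),
            ]:
                tr = welch_t(vals[a], vals[b])
                row[f"t_{tag}"] = tr.statistic
                row[f"p_{tag}"] = tr.p
        pooled = base[base["converter_label"].isin(["nPDN", "cPDN"])]
        pooled = pooled[pooled[region].notna() & pooled[score_column].notna()]
        if len(pooled) >= 3:
            try:
                sp = spearman(pooled[region].to_numpy(), pooled[score_column].to_numpy())
                row["spearman_rho_score"] = sp.statistic
                row["p_spearman_score"] = sp.p
            except PdmorphError:
                pass
        rows.append(row)

    report = pd.DataFrame(rows)
    m = config.multiplicity or len(report)
    logger.info("converter report: Bonferroni family size m=%d", m)
    adj, sig = bonferroni(report["p_omnibus"].to_numpy(), m=m, alpha=config.alpha)
    report["p_omnibus_bonferroni"] = adj
    report["significant"] = sig
    return report
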