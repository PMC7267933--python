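"""Synthetic longitudinal cohort generator.

Generates :class:`~pdmorph.cohort.LongTable` cohorts with the statistical
structure the downstream analysis assumes: three groups (healthy controls,
cognitively normal PD, cognitively impaired PD), group-specific linear
time trajectories, a piecewise-linear age effect with a knot near 60
years, per-subject random intercept and slope, residual noise, and a
monotone drop-out schedule matching the observed cumulative retention of
the study cohort (five visits at 0, 1.1, 2.4, 3.2 and 3.9 years).

For every region the outcome follows the same linear mixed-effect
structure the analysis fits:

    y_ij = x_ij' beta + b0_i + b1_i * t_ij + e_ij

with ``x_ij`` the 8-column fixed-effect row (intercept, time, PDN
indicator, time x PDN, PDCI indicator, time x PDCI, age-above-knot at
enrollment, education), ``(b0, b1) ~ N(0, Psi)`` and ``e ~ N(0, s^2)``.
By default the generated region columns live on the reference-normalized
scale (the model's own scale); with ``icv_scaling=True`` volumes are
multiplied by each subject's ICV relative to the population mean (and
thickness regions by the subject's baseline mean thickness), so the
normalization stage has real work to undo.

Drop-out is independent of the outcomes (missing completely at random),
the implicit assumption of the mixed model; an outcome-dependent mode
is available to probe sensitivity and is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import GROUPS, LongTable, Region, SchemaError
from .lme import piecewise_age

__all__ = [
    "RegionSpec",
    "SyntheticConfig",
    "GenerationTruth",
    "default_config",
    "generate_cohort",
    "generate_converter_scenario",
    "TABLE_RETENTION_PD_ALL",
]

#: Cumulative per-visit retention of the pooled PD cohort
#: (counts 172, 129, 54, 34, 9 at visits 0..4).
TABLE_RETENTION_PD_ALL = [1.0, 129 / 172, 54 / 172, 34 / 172, 9 / 172]


@dataclass
class RegionSpec:
    """Generative truth for one region column.

    beta follows the fixed design column order: intercept, time, G1,
    t*G1, G2, t*G2, age-above-knot, education.  random_cov is the 2x2
    covariance of (random intercept, random slope); residual_sd the
    within-visit noise SD, all in the region's own units.
    """

    kind: str
    units: str
    beta: np.ndarray
    random_cov: np.ndarray
    residual_sd: float

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.random_cov = np.asarray(self.random_cov, dtype=float)
        if self.beta.shape != (8,):
            raise SchemaError("beta must be an 8-vector")
        if self.random_cov.shape != (2, 2):
            raise SchemaError("random_cov must be 2x2")
        if not np.allclose(self.random_cov, self.random_cov.T):
            raise SchemaError("random_cov must be symmetric")
        if np.linalg.eigvalsh(self.random_cov).min() < -1e-10:
            raise SchemaError("random_cov must be positive semi-definite")
        if self.residual_sd < 0:
            raise SchemaError("residual_sd must be non-negative")


@dataclass
class SyntheticConfig:
    n_per_group: Mapping[str, int]
    visit_times: list[float]
    retention: Mapping[str, list[float]]  # cumulative, starts at 1.0
    age_mean_sd: Mapping[str, tuple[float, float]]
    education_mean_sd: Mapping[str, tuple[float, float]]
    sex_prob_male: Mapping[str, float]
    icv_mean_sd: tuple[float, float]
    regions: Mapping[str, RegionSpec]
    mean_thickness: RegionSpec
    score_mean_sd: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"CTRL": (98.0, 5.0), "PDN": (95.8, 5.8), "PDCI": (84.1, 11.6)}
    )
    age_knot: float = 60.0
    age_bounds: tuple[float, float] = (45.0, 80.0)
    education_bounds: tuple[float, float] = (7.0, 30.0)
    time_jitter: float = 0.0  # uniform +/- jitter (years) on follow-up times
    icv_scaling: bool = False
    outcome_dependent_dropout: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        times = np.asarray(self.visit_times, dtype=float)
        if times[0] != 0 or np.any(np.diff(times) <= 0):
            raise SchemaError("visit_times must be strictly increasing and start at 0")
        for g in GROUPS:
            ret = np.asarray(self.retention[g], dtype=float)
            if len(ret) != len(times) or ret[0] != 1.0 or np.any(np.diff(ret) > 1e-12):
                raise SchemaError(f"retention[{g}] must be non-increasing, start at 1.0, "
                                  "and match visit_times in length")


@dataclass
class GenerationTruth:
    """Realized latent quantities, reproducible from (config, seed)."""

    config: SyntheticConfig
    seed: int
    random_effects: dict  # region -> {subject_id: (b0, b1)}
    last_visit: dict      # subject_id -> last attended visit index
    converter_arm: dict = field(default_factory=dict)  # subject_id -> nPDN/cPDN


def default_config(seed: int = 0) -> SyntheticConfig:
    """The study conditions: group sizes, covariate distributions,
    visit schedule and cumulative retention of the cohort, and region
    effects giving trajectories like those observed (controls thinning
    ~7.3 um/y in mean cortical thickness, PD-N ~28 um/y, PD-CI ~2 um/y;
    whole-brain volume loss ~5 cm^3/y above age 60)."""
    b = lambda *v: np.asarray(v, dtype=float)
    cov = lambda s0, s1, r=0.0: np.array(
        [[s0 * s0, r * s0 * s1], [r * s0 * s1, s1 * s1]]
    )
    regions = {
        "brain_volume": RegionSpec(
            "volume", "cm3", b(1210, -5.0, -24, 0, -36, 0, -5.0, 0.5), cov(35, 1.5, -0.2), 4.0
        ),
        "gray_matter": RegionSpec(
            "volume", "cm3", b(600, -3.0, -30, 0, -30, 0, -3.0, 0.3), cov(25, 1.0, -0.2), 3.0
        ),
        "hippocampus": RegionSpec(
            "volume", "cm3", b(8.3, -0.02, -0.3, 0, -0.35, 0, -0.03, 0.0), cov(0.5, 0.02), 0.08
        ),
        "midbrain_plane": RegionSpec(
            "area", "mm2", b(460, -1.0, -15, 0, -23, 0, -1.0, 0.0), cov(25, 0.8), 4.0
        ),
        # thickness regions live on the ratio-normalized scale, where the
        # between-subject SD is ~2.4% of the level (global thickness
        # variation is removed by the normalization), well below raw ROI SDs
        "caudal_acc": RegionSpec(
            "thickness", "mm", b(2.55, -0.0073, 0, 0, 0, 0, -0.005, 0.0), cov(0.06, 0.004), 0.03
        ),
        "superior_frontal": RegionSpec(
            "thickness", "mm", b(2.70, -0.0073, 0, 0, 0, 0, -0.005, 0.0), cov(0.06, 0.004), 0.03
        ),
    }
    mean_thickness = RegionSpec(
        "thickness", "mm",
        b(2.50, -0.0073, 0, -0.0207, 0, 0.0053, -0.004, 0.001),
        cov(0.10, 0.005), 0.025,
    )
    return SyntheticConfig(
        n_per_group={"CTRL": 85, "PDN": 80, "PDCI": 92},
        visit_times=[0.0, 1.1, 2.4, 3.2, 3.9],
        retention={
            "CTRL": [1.0, 66 / 85, 37 / 85, 11 / 85, 0.0],
            "PDN": [1.0, 63 / 80, 26 / 80, 16 / 80, 6 / 80],
            "PDCI": [1.0, 66 / 92, 28 / 92, 18 / 92, 3 / 92],
        },
        age_mean_sd={"CTRL": (65.1, 6.7), "PDN": (65.9, 8.3), "PDCI": (68.9, 7.7)},
        education_mean_sd={"CTRL": (16.1, 4.0), "PDN": (13.8, 2.7), "PDCI": (13.0, 2.9)},
        sex_prob_male={"CTRL": 48 / 85, "PDN": 56 / 80, "PDCI": 64 / 92},
        icv_mean_sd=(1459.3, 130.0),
        regions=regions,
        mean_thickness=mean_thickness,
        seed=seed,
    )


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[LongTable, GenerationTruth]:
    """Draw one cohort.  Identical (config, seed) give identical tables.

    Returns the table together with a :class:`GenerationTruth` exposing
    the realized random effects and attendance, which parameter-recovery
    tests compare against.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    times = np.asarray(config.visit_times, dtype=float)
    n_visits = len(times)

    rows = []
    subj_meta = []
    for group in GROUPS:
        n = int(config.n_per_group.get(group, 0))
        if n == 0:
            continue
        am, asd = config.age_mean_sd[group]
        em, esd = config.education_mean_sd[group]
        ages = _truncnorm(rng, am, asd, *config.age_bounds, size=n)
        edus = _truncnorm(rng, em, esd, *config.education_bounds, size=n)
        sexes = np.where(rng.random(n) < config.sex_prob_male[group], "M", "F")
        icvm, icvs = config.icv_mean_sd
        icvs_draw = _truncnorm(rng, icvm, icvs, icvm - 3.5 * icvs, icvm + 3.5 * icvs, size=n)
        sm, ss = config.score_mean_sd[group]
        scores = rng.normal(sm, ss, size=n)
        u_drop = rng.random(n)
        # cognitive status: controls NORMAL; PDN NORMAL; PDCI mostly MCI
        if group == "PDCI":
            statuses = np.where(rng.random(n) < 15 / 92, "DEMENTIA", "MCI")
        else:
            statuses = np.full(n, "NORMAL")
        for i in range(n):
            subj_meta.append(
                dict(
                    subject_id=f"{group}{i:03d}",
                    group=group,
                    sex=sexes[i],
                    education=float(edus[i]),
                    baseline_age=float(ages[i]),
                    icv=float(icvs_draw[i]),
                    score=float(scores[i]),
                    status=statuses[i],
                    u_drop=float(u_drop[i]),
                )
            )

    # latent random effects per region (mean-thickness column included)
    all_specs = dict(config.regions)
    all_specs["mean_thickness"] = config.mean_thickness
    n_subj = len(subj_meta)
    rand_effects: dict[str, dict[str, tuple[float, float]]] = {}
    b_draws = {}
    for name, spec in all_specs.items():
        L = np.linalg.cholesky(spec.random_cov + 1e-14 * np.eye(2))
        bvals = rng.standard_normal((n_subj, 2)) @ L.T
        b_draws[name] = bvals
        rand_effects[name] = {
            subj_meta[i]["subject_id"]: (float(bvals[i, 0]), float(bvals[i, 1]))
            for i in range(n_subj)
        }
    noise = {name: rng.standard_normal((n_subj, n_visits)) for name in all_specs}
    jitter = rng.uniform(-config.time_jitter, config.time_jitter, size=(n_subj, n_visits)) \
        if config.time_jitter > 0 else np.zeros((n_subj, n_visits))

    if config.outcome_dependent_dropout:
        # faster decliners (lower random slope of the first region) drop out earlier
        first = next(iter(all_specs))
        slope_sd = np.sqrt(all_specs[first].random_cov[1, 1]) or 1.0
        z = -b_draws[first][:, 1] / slope_sd
        rho = 0.5
        for i, meta in enumerate(subj_meta):
            w = stats.norm.ppf(min(max(meta["u_drop"], 1e-12), 1 - 1e-12))
            meta["u_drop"] = float(stats.norm.cdf(rho * z[i] + np.sqrt(1 - rho**2) * w))

    last_visit = {}
    for i, meta in enumerate(subj_meta):
        group = meta["group"]
        ret = np.asarray(config.retention[group], dtype=float)
        attended = meta["u_drop"] < ret  # monotone: ret is non-increasing
        last = int(np.max(np.flatnonzero(attended)))
        last_visit[meta["subject_id"]] = last
        g1 = 1.0 if group == "PDN" else 0.0
        g2 = 1.0 if group == "PDCI" else 0.0
        age_tr = piecewise_age(meta["baseline_age"], config.age_knot)
        mt_ref = None  # subject's baseline mean-thickness scale factor
        for j in range(last + 1):
            t = times[j] + (jitter[i, j] if j > 0 else 0.0)
            row = dict(
                subject_id=meta["subject_id"],
                group=group,
                sex=meta["sex"],
                education=meta["education"],
                baseline_age=meta["baseline_age"],
                icv=meta["icv"],
                converter_label="NA",
                visit_index=j,
                time_from_baseline=t,
                age_at_visit=meta["baseline_age"] + t,
                cognitive_status="NORMAL" if group != "PDCI" else meta["status"],
                cerad_total=meta["score"],
            )
            x = np.array([1.0, t, g1, t * g1, g2, t * g2, age_tr, meta["education"]])
            for name, spec in all_specs.items():
                b0, b1 = b_draws[name][i]
                y = x @ spec.beta + b0 + b1 * t + spec.residual_sd * noise[name][i, j]
                if config.icv_scaling and spec.kind in ("volume", "area"):
                    y *= meta["icv"] / config.icv_mean_sd[0]
                row[name if name != "mean_thickness" else "mean_thickness"] = float(y)
            if config.icv_scaling:
                # thickness regions scale with the subject's mean thickness
                # level at baseline (the downstream subject reference)
                if mt_ref is None:
                    mt_ref = row["mean_thickness"] / all_specs["mean_thickness"].beta[0]
                for name, spec in config.regions.items():
                    if spec.kind == "thickness":
                        row[name] = float(row[name] * mt_ref)
            rows.append(row)

    regions = {n: Region(s.kind, s.units) for n, s in config.regions.items()}
    table = LongTable(pd.DataFrame(rows), regions)
    truth = GenerationTruth(
        config=config, seed=seed, random_effects=rand_effects, last_visit=last_visit
    )
    return table, truth


def generate_converter_scenario(
    config: SyntheticConfig,
    thinning_region: str,
    thinning_delta: float,
    conversion_visit: int = 1,
    converter_fraction: float = 26 / 68,
    score_rho: float = 0.0,
    seed: int | None = None,
) -> tuple[LongTable, GenerationTruth]:
    """Cohort in which a fraction of PDN subjects later convert to MCI.

    The converter (cPDN) arm's values in ``thinning_region`` are scaled
    by (1 + thinning_delta) at every visit, so its baseline mean sits at
    that fractional deficit; all other regions are unshifted.  cPDN
    subjects acquire MCI status from ``conversion_visit`` onward, so
    :func:`~pdmorph.cohort.label_converters` recovers the planted arms
    exactly.  With ``score_rho > 0`` the PDN cognitive score is redrawn
    with that target Spearman correlation to the subject's baseline
    value in the thinned region.
    """
    if thinning_region not in config.regions:
        raise SchemaError(f"unknown region {thinning_region!r}")
    if config.regions[thinning_region].kind != "thickness":
        raise SchemaError(f"{thinning_region} is not a thickness region")
    if not (-0.2 < thinning_delta <= 0.0):
        raise SchemaError("thinning_delta must lie in (-0.2, 0]")
    if seed is None:
        seed = config.seed

    table, truth = generate_cohort(config, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    df = table.df

    pdn_ids = sorted(
        sid for sid, last in truth.last_visit.items()
        if sid.startswith("PDN") and last >= conversion_visit
    )
    n_conv = int(round(converter_fraction * len(pdn_ids)))
    conv_ids = set(rng.choice(pdn_ids, size=n_conv, replace=False)) if n_conv else set()
    truth.converter_arm = {
        sid: ("cPDN" if sid in conv_ids else "nPDN") for sid in pdn_ids
    }

    in_conv = df["subject_id"].isin(conv_ids)
    df.loc[in_conv, thinning_region] *= 1.0 + thinning_delta
    converting = in_conv & (df["visit_index"] >= conversion_visit)
    df.loc[converting, "cognitive_status"] = "MCI"

    if score_rho > 0:
        pdn_base = df[(df["visit_index"] == 0) & df["subject_id"].isin(pdn_ids)]
        x = pdn_base[thinning_region].to_numpy()
        z = (x - x.mean()) / x.std()
        # bivariate-normal latent correlation that yields the target Spearman rho
        rho_p = 2 * np.sin(np.pi * score_rho / 6)
        sm, ss = config.score_mean_sd["PDN"]
        new = sm + ss * (rho_p * z + np.sqrt(1 - rho_p**2) * rng.standard_normal(len(z)))
        score_map = dict(zip(pdn_base["subject_id"], new))
        sel = df["subject_id"].isin(score_map)
        df.loc[sel, "cerad_total"] = df.loc[sel, "subject_id"].map(score_map)

    table._validate()
    return table, truth
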