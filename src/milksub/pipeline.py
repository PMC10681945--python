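"""End-to-end analysis runs over a subject/item pair of tables.

Each stage reproduces one standard output family: demographic composition,
beverage and nutrient trends across age, nutrient contributions of caloric
beverages, and the two substitution scenarios. All stages share the same
kept-subject frame (after exclusions) and survey design.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (BeverageCategoryMap, OccasionMap, apply_exclusions,
                       classification_audit, default_category_map,
                       per_subject_category_intake)
from .io import read_items, read_subjects
from .nutrients import NUTRIENT_PANEL, MilkProfile, default_milk_profile
from .substitution import (add_milk_serving_table, flag_meaningful_change,
                           isocaloric_replace, subject_totals)
from .survey import (SurveyDesign, lsmeans_by_age_group, paired_t,
                     percent_change, population_ratio, trend_regression,
                     weighted_mean)

logger = logging.getLogger(__name__)

DEFAULT_AGE_GROUPS: tuple[tuple[int, int], ...] = ((6, 8), (9, 13), (14, 18))
TREND_COVARIATES = ("sex", "ethnicity", "pir_level")
SIGNIFICANCE_LEVEL = 0.01  # paired-t marker threshold for scenario 2


def group_label(lo: int, hi: int) -> str:
    return f"{lo}-{hi}"


def assign_age_groups(age_years, groups=DEFAULT_AGE_GROUPS) -> pd.Categorical:
    """Map integer ages onto ordered age-group labels; groups must partition 6-18."""
    covered: list[int] = []
    for lo, hi in groups:
        covered.extend(range(lo, hi + 1))
    if sorted(covered) != list(range(6, 19)) or len(covered) != len(set(covered)):
        raise ValueError("age groups must partition ages 6-18 without overlap")
    labels = [group_label(lo, hi) for lo, hi in groups]
    age = np.asarray(age_years)
    out = np.empty(len(age), dtype=object)
    for (lo, hi), lab in zip(groups, labels):
        out[(age >= lo) & (age <= hi)] = lab
    return pd.Categorical(out, categories=labels, ordered=True)


@dataclass
class RunConfig:
    """Paths, maps and knobs for an end-to-end run."""

    subjects_path: str | Path | None = None
    items_path: str | Path | None = None
    output_dir: str | Path = "milksub_out"
    category_map: BeverageCategoryMap = dc_field(default_factory=default_category_map)
    occasion_map: OccasionMap = dc_field(default_factory=OccasionMap)
    milk_profile: MilkProfile = dc_field(default_factory=default_milk_profile)
    n_cycles: int = 1
    age_groups: tuple[tuple[int, int], ...] = DEFAULT_AGE_GROUPS
    scope: str = "all_caloric"
    seed: int = 0

    def __post_init__(self) -> None:
        assign_age_groups([6], self.age_groups)  # validates the partition


def _covariates(subjects: pd.DataFrame) -> pd.DataFrame:
    return subjects.loc[:, list(TREND_COVARIATES)]


def _safe_mean(values: np.ndarray, design: SurveyDesign) -> tuple[float, float]:
    """Weighted mean with SE, degrading to a NaN SE on degenerate designs
    (lone-PSU strata) instead of refusing the point estimate."""
    try:
        res = weighted_mean(values, design)
        return res.estimate, res.se
    except ValueError:
        w = design.analysis_weight
        return float(w @ values / w.sum()), float("nan")


def run_demographics(subjects: pd.DataFrame, design: SurveyDesign,
                     age_groups=DEFAULT_AGE_GROUPS) -> pd.DataFrame:
    """Weighted percentage (with SE) of each categorical level by age group."""
    groups = assign_age_groups(subjects["age_years"], age_groups)
    rows = []
    for lab in groups.categories:
        mask = np.asarray(groups == lab)
        if not mask.any():
            continue
        sub_design = design.subset(mask)
        sub = subjects.loc[mask]
        est, se = _safe_mean(sub["age_years"].to_numpy(dtype=float), sub_design)
        rows.append({"variable": "age_years", "level": "mean", "age_group": lab,
                     "estimate": est, "se": se, "n": int(mask.sum())})
        for var in ("sex", "ethnicity", "pir_level", "physical_activity", "weight_status"):
            levels = (sub[var].cat.categories if hasattr(sub[var], "cat")
                      else pd.unique(subjects[var]))
            for level in levels:
                ind = (sub[var].astype(str) == str(level)).to_numpy(dtype=float) * 100.0
                est, se = _safe_mean(ind, sub_design)
                rows.append({"variable": var, "level": str(level), "age_group": lab,
                             "estimate": est, "se": se, "n": int(mask.sum())})
    return pd.DataFrame(rows)


def _trend_table(per_subject: pd.DataFrame, quantities: list[tuple[str, np.ndarray]],
                 subjects: pd.DataFrame, design: SurveyDesign,
                 age_groups) -> pd.DataFrame:
    """LS means by age group + age trend for a list of named outcome vectors."""
    groups = assign_age_groups(subjects["age_years"], age_groups)
    cov = _covariates(subjects)
    age = subjects["age_years"].to_numpy(dtype=float)
    frames = []
    for name, y in quantities:
        table = lsmeans_by_age_group(y, groups, design, cov, quantity=name)
        fit = trend_regression(y, age, design, cov)
        table["beta"] = fit.beta
        table["beta_se"] = fit.se
        table["t"] = fit.t
        table["p"] = fit.p
        first = table["estimate"].iloc[0]
        last = table["estimate"].iloc[-1]
        if first > 0:
            mode = "increase" if last >= first else "decrease"
            pct = percent_change(first, last, mode)
            table["pct_change_6_8_to_14_18"] = pct if mode == "increase" else -pct
        else:
            table["pct_change_6_8_to_14_18"] = np.nan
        frames.append(table)
    return pd.concat(frames, ignore_index=True)


def run_trends(subjects: pd.DataFrame, items: pd.DataFrame, design: SurveyDesign,
               cmap: BeverageCategoryMap | None = None,
               age_groups=DEFAULT_AGE_GROUPS) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Beverage-group gram trends and nutrient trends from caloric beverages.

    Returns two tidy tables: per-group daily grams (LS means by age group,
    trend coefficient, printed-style percent change 6-8 y to 14-18 y), and
    the same layout for each panel nutrient contributed by caloric
    beverages including milk. Total daily energy is included with the
    beverage table for context.
    """
    cmap = cmap or default_category_map()
    intake = per_subject_category_intake(items, subjects["subject_id"], cmap)
    intake = intake.loc[subjects["subject_id"].to_numpy()]
    totals = subject_totals(items, subjects["subject_id"])
    bev_quantities = [("energy_total", totals["energy"].to_numpy())]
    for group in cmap.groups:
        bev_quantities.append((f"{group}_g", intake[(group, "grams")].to_numpy()))
    bev = _trend_table(intake, bev_quantities, subjects, design, age_groups)
    nut_quantities = [(nutrient, intake[("caloric_bev_incl_milk", nutrient)].to_numpy())
                      for nutrient in NUTRIENT_PANEL]
    nut = _trend_table(intake, nut_quantities, subjects, design, age_groups)
    return bev, nut


def run_contributions(subjects: pd.DataFrame, items: pd.DataFrame,
                      design: SurveyDesign,
                      cmap: BeverageCategoryMap | None = None) -> pd.DataFrame:
    """Percent of each nutrient's daily intake contributed by caloric beverages.

    Population-ratio method over all kept subjects pooled across ages, for
    the aggregates including and excluding milk.
    """
    cmap = cmap or default_category_map()
    intake = per_subject_category_intake(items, subjects["subject_id"], cmap)
    intake = intake.loc[subjects["subject_id"].to_numpy()]
    totals = subject_totals(items, subjects["subject_id"])
    rows = []
    for group in ("caloric_bev_incl_milk", "caloric_bev_excl_milk"):
        for nutrient in NUTRIENT_PANEL:
            res = population_ratio(intake[(group, nutrient)].to_numpy(),
                                   totals[nutrient].to_numpy(), design)
            rows.append({"group": group, "nutrient": nutrient,
                         "percent": res.percent, "se": res.se, "n": res.n})
    return pd.DataFrame(rows)


def _model_table(baseline: pd.DataFrame, adjusted: pd.DataFrame,
                 subjects: pd.DataFrame, design: SurveyDesign, age_groups,
                 scenario: str) -> pd.DataFrame:
    groups = assign_age_groups(subjects["age_years"], age_groups)
    cov = _covariates(subjects)
    rows = []
    for nutrient in NUTRIENT_PANEL:
        b = baseline[nutrient].to_numpy()
        a = adjusted[nutrient].to_numpy()
        tb = lsmeans_by_age_group(b, groups, design, cov, quantity=nutrient)
        ta = lsmeans_by_age_group(a, groups, design, cov, quantity=nutrient)
        for (_, rb), (_, ra) in zip(tb.iterrows(), ta.iterrows()):
            row = {"quantity": nutrient, "age_group": rb["age_group"],
                   "baseline": rb["estimate"], "baseline_se": rb["se"],
                   "adjusted": ra["estimate"], "adjusted_se": ra["se"],
                   "n": rb["n"]}
            if scenario == "add":
                change = flag_meaningful_change(rb["estimate"], ra["estimate"])
                row["pct_change"] = change.percent
                row["meaningful_10pct"] = change.meaningful
            else:
                mask = np.asarray(groups == row["age_group"])
                test = paired_t(b[mask], a[mask], design.subset(mask))
                row["mean_diff"] = test.mean_diff
                row["t"] = test.t
                row["p"] = test.p
                row["significant"] = test.p < SIGNIFICANCE_LEVEL
            rows.append(row)
    return pd.DataFrame(rows)


def run_models(subjects: pd.DataFrame, items: pd.DataFrame, design: SurveyDesign,
               profile: MilkProfile | None = None,
               cmap: BeverageCategoryMap | None = None,
               omap: OccasionMap | None = None,
               scope: str = "all_caloric",
               age_groups=DEFAULT_AGE_GROUPS) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Both substitution scenarios as baseline/adjusted LS-mean tables.

    Scenario 1 (add one milk serving) carries the 10%-rule flag per
    nutrient and age group; scenario 2 (isocaloric meal replacement)
    carries design-weighted paired-t markers at p < 0.01.
    """
    profile = profile or default_milk_profile()
    ids = subjects["subject_id"]
    baseline = subject_totals(items, ids)
    added = add_milk_serving_table(baseline, profile)
    table_add = _model_table(added.baseline, added.adjusted, subjects, design,
                             age_groups, scenario="add")
    replaced = isocaloric_replace(items, ids, profile, omap, cmap, scope=scope)
    table_replace = _model_table(replaced.baseline, replaced.adjusted, subjects,
                                 design, age_groups, scenario="replace")
    table_replace["mean_cup_equivalents"] = float(
        weighted_mean(replaced.cup_equivalents.to_numpy(), design).estimate)
    return table_add, table_replace


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_all(config: RunConfig,
            subjects: pd.DataFrame | None = None,
            items: pd.DataFrame | None = None) -> dict[str, pd.DataFrame]:
    """Execute every stage and write CSV outputs plus a run-metadata sidecar.

    Tables may be passed in memory; otherwise they are read from the
    configured paths. Returns the output tables keyed by stage name.
    """
    if subjects is None:
        subjects = read_subjects(config.subjects_path)
    if items is None:
        items = read_items(config.items_path)
    kept, tally = apply_exclusions(subjects)
    logger.info("exclusions: %s; kept %d of %d subjects", tally, len(kept), len(subjects))
    items = items[items["subject_id"].isin(set(kept["subject_id"]))].reset_index(drop=True)
    design = SurveyDesign.from_subjects(kept, n_cycles=config.n_cycles)

    outputs: dict[str, pd.DataFrame] = {}
    outputs["exclusions"] = pd.DataFrame(
        [{"reason": k, "n": v} for k, v in sorted(tally.items())]
        + [{"reason": "kept", "n": len(kept)}])
    outputs["classification_audit"] = classification_audit(items, config.category_map)
    outputs["demographics"] = run_demographics(kept, design, config.age_groups)
    bev, nut = run_trends(kept, items, design, config.category_map, config.age_groups)
    outputs["beverage_trends"] = bev
    outputs["nutrient_trends"] = nut
    outputs["contributions"] = run_contributions(kept, items, design, config.category_map)
    add_tbl, rep_tbl = run_models(kept, items, design, config.milk_profile,
                                  config.category_map, config.occasion_map,
                                  config.scope, config.age_groups)
    outputs["model_add_milk"] = add_tbl
    outputs["model_replace_meals"] = rep_tbl

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in outputs.items():
        _write_csv(df, outdir / f"{name}.csv")
    meta = {
        "package_version": __version__,
        "seed": config.seed,
        "n_cycles": config.n_cycles,
        "scope": config.scope,
        "age_groups": [list(g) for g in config.age_groups],
        "n_subjects_input": int(len(subjects)),
        "n_subjects_kept": int(len(kept)),
        "exclusion_tally": tally,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    }
    meta["config_hash"] = hashlib.sha256(
        json.dumps(meta, sort_keys=True).encode()).hexdigest()
    (outdir / "run_metadata.json").write_text(json.dumps(meta, indent=2) + "\n")
    return outputs
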