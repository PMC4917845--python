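"""Configuration-driven end-to-end orchestration and report generation.

Runs simulate (or load) -> preprocess -> descriptives -> per-age
univariate sex-limitation fits -> gene-by-age moderation fits, writing
CSV tables shaped like the published figures (per-age standardized
components, OS genetic correlations, variance-vs-age curves), a
versioned machine-readable JSON summary, and a log of stage row counts.
Every output is reproducible byte-for-byte from (input, config, seed):
all randomness comes from per-stage streams spawned from the single
global seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import describe as describe_mod
from . import moderation as moderation_mod
from . import preprocess as preprocess_mod
from . import synth, twinmodel
from .twinmodel import ConfigurationError

__all__ = ["RunConfig", "run_pipeline", "sensitivity_with_exclusion", "fit_univariate_by_age"]

SUMMARY_SCHEMA_VERSION = 1
_SUMMARY_REQUIRED_KEYS = ("schema_version", "seed", "stages", "row_counts")

log = logging.getLogger("twinace")


@dataclass
class RunConfig:
    """End-to-end run configuration (YAML/JSON loadable)."""

    seed: int = 0
    outdir: str = "twinace-out"
    input_csv: str | None = None  # measurement table; None -> simulate
    generator: synth.GeneratorConfig | None = None
    stages: tuple[str, ...] = ("describe", "univariate", "moderation")
    age_range: tuple[int, int] = (1, 19)
    regions_include: list[str] | None = None
    exclude_cohorts: list[str] = field(default_factory=list)
    alpha: float = 0.05
    bonferroni_m: int | None = None  # default: number of age groups tested
    z_max: float = 3.5
    min_cohort_n: int = 50
    profile_cis: bool = False  # per-age profile CIs are slow; off by default
    moderation_regions: bool = False

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError(f"alpha must lie in (0, 1), got {self.alpha}")
        lo, hi = self.age_range
        if not (1 <= lo <= hi <= 19):
            raise ConfigurationError(f"age_range must satisfy 1 <= lo <= hi <= 19, got {self.age_range}")
        if self.input_csv is not None and not Path(self.input_csv).exists():
            raise ConfigurationError(f"input_csv path does not exist: {self.input_csv}")
        unknown = set(self.stages) - {"describe", "univariate", "moderation"}
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = raw.pop("generator", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}})
        if gen is not None:
            regions = [synth.RegionSpec(**r) for r in gen.pop("regions", [])]
            cfg.generator = synth.GeneratorConfig(**gen, regions=regions or synth._default_regions())
        if isinstance(cfg.age_range, list):
            cfg.age_range = tuple(cfg.age_range)
        if isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        return cfg


def _spawned_seeds(seed: int, n: int) -> list[int]:
    """Independent per-stage seeds derived from one global seed (< 2**31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def fit_univariate_by_age(
    pairs: pd.DataFrame,
    ages: range,
    alpha: float = 0.05,
    bonferroni_m: int | None = None,
    profile_cis: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-age full sex-limitation fits plus nested-model comparison table.

    Returns (components table with one row per age x sex, model-comparison
    table with the saturated/equal-sexes/scale/drop-C likelihood-ratio
    tests per age, with the equal-environment test Bonferroni-corrected
    across ages).
    """
    comp_rows, test_rows = [], []
    eea_pvals: list[tuple[int, float]] = []
    for age in ages:
        sub = pairs[pairs["age_group"] == age]
        if sub.empty:
            continue
        full = twinmodel.fit_ace_sexlim(sub)
        sat = twinmodel.fit_saturated(sub)
        tests = {"eea": twinmodel.lrt(sat, full)}
        for constraint in ("equal_sexes", "scale", "drop_C"):
            tests[constraint] = twinmodel.lrt(full, twinmodel.fit_submodel(sub, constraint))
        eea_pvals.append((age, tests["eea"].p_value))
        std = full.standardized
        cis: dict[str, tuple[float, float]] = {}
        if profile_cis:
            for q in ("h2_m", "c2_m", "e2_m", "h2_f", "c2_f", "e2_f", "r_gos"):
                cis[q] = twinmodel.profile_ci(full, q)
        for sex, h2, c2, e2 in (
            ("M", std.h2_m, std.c2_m, std.e2_m),
            ("F", std.h2_f, std.c2_f, std.e2_f),
        ):
            row = {
                "age_group": age,
                "sex": sex,
                "h2": h2,
                "c2": c2,
                "e2": e2,
                "r_gos": full.params.r_gos,
                "minus2ll": full.minus2ll,
                "converged": full.converged,
                "n_pairs_total": int(sum(full.n_pairs.values())),
            }
            for q, (lo, hi) in cis.items():
                if q.endswith(f"_{sex.lower()}") or q == "r_gos":
                    row[f"{q.split('_')[0]}_lo" if q != "r_gos" else "r_gos_lo"] = lo
                    row[f"{q.split('_')[0]}_hi" if q != "r_gos" else "r_gos_hi"] = hi
            comp_rows.append(row)
        for name, res in tests.items():
            test_rows.append(
                {
                    "age_group": age,
                    "test": name,
                    "delta_minus2ll": res.delta_minus2ll,
                    "delta_df": res.delta_df,
                    "p_value": res.p_value,
                }
            )
    tests_df = pd.DataFrame(test_rows)
    if eea_pvals:
        m = bonferroni_m if bonferroni_m is not None else len(eea_pvals)
        dec = twinmodel.bonferroni([p for _, p in eea_pvals], m=m, alpha=alpha)
        rejects = dict(zip((a for a, _ in eea_pvals), dec["reject"]))
        tests_df["bonferroni_reject"] = [
            bool(rejects.get(r["age_group"])) if r["test"] == "eea" else None
            for _, r in tests_df.iterrows()
        ]
    return pd.DataFrame(comp_rows), tests_df


def _validate_summary(summary: dict) -> None:
    missing = [k for k in _SUMMARY_REQUIRED_KEYS if k not in summary]
    if missing:
        raise ConfigurationError(f"summary missing required keys: {missing}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write all outputs under ``outdir``.

    Returns the JSON summary as a dict.  Partial outputs are retained on
    stage failure; the raised error names the failing stage.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    seeds = _spawned_seeds(config.seed, 4)
    summary: dict = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "seed": config.seed,
        "stage_seeds": seeds,
        "stages": list(config.stages),
        "row_counts": {},
        "unconverged_fits": 0,
    }
    stage = "load"
    try:
        # ------------------------------------------------------ data
        if config.input_csv is not None:
            raw = pd.read_csv(config.input_csv)
        else:
            gen = config.generator or synth.GeneratorConfig()
            gen = dataclasses.replace(gen, seed=seeds[0])
            stage = "simulate"
            raw = synth.simulate_cohort(gen)
            synth.write_cohort(raw, str(outdir / "simulated_measurements.csv"), gen)
        if config.regions_include is not None:
            raw = raw[raw["region"].isin(config.regions_include)]
        if config.exclude_cohorts:
            raw = raw[~raw["cohort"].isin(config.exclude_cohorts)]
        summary["row_counts"]["raw"] = int(len(raw))
        log.info("stage=%s rows=%d", stage, len(raw))

        # ------------------------------------------------------ preprocess
        stage = "preprocess"
        pairs_uni, rep_uni = preprocess_mod.run_preprocess(
            raw, mode="univariate", z_max=config.z_max, min_cohort_n=config.min_cohort_n
        )
        lo, hi = config.age_range
        pairs_uni = pairs_uni[(pairs_uni["age_group"] >= lo) & (pairs_uni["age_group"] <= hi)]
        summary["row_counts"]["pairs_univariate"] = int(len(pairs_uni))
        summary["preprocess_univariate"] = rep_uni
        log.info("stage=preprocess mode=univariate pairs=%d", len(pairs_uni))

        # ------------------------------------------------------ describe
        if "describe" in config.stages:
            stage = "describe"
            desc = describe_mod.describe_heights(preprocess_mod.assign_age_groups(raw))
            desc.to_csv(outdir / "descriptives.csv", index=False)
            corrs = describe_mod.twin_correlations(pairs_uni, by=["age_group"])
            corrs.to_csv(outdir / "twin_correlations.csv", index=False)
            summary["row_counts"]["descriptives"] = int(len(desc))
            log.info("stage=describe strata=%d", len(desc))

        # ------------------------------------------------------ univariate fits
        if "univariate" in config.stages:
            stage = "univariate"
            comps, tests = fit_univariate_by_age(
                pairs_uni,
                range(lo, hi + 1),
                alpha=config.alpha,
                bonferroni_m=config.bonferroni_m,
                profile_cis=config.profile_cis,
            )
            comps.to_csv(outdir / "components_by_age.csv", index=False)
            tests.to_csv(outdir / "model_tests_by_age.csv", index=False)
            summary["row_counts"]["component_rows"] = int(len(comps))
            summary["unconverged_fits"] += int((~comps["converged"]).sum() // 2) if len(comps) else 0
            log.info("stage=univariate ages=%d unconverged=%d", len(comps) // 2, summary["unconverged_fits"])

        # ------------------------------------------------------ moderation fits
        if "moderation" in config.stages:
            stage = "moderation"
            pairs_mod, rep_mod = preprocess_mod.run_preprocess(
                raw, mode="moderation", z_max=config.z_max, min_cohort_n=config.min_cohort_n
            )
            ss = pairs_mod[pairs_mod["group"] != "OS"]
            ss = ss[(ss["age_group"] >= lo) & (ss["age_group"] <= hi)]
            summary["row_counts"]["pairs_moderation"] = int(len(ss))
            summary["preprocess_moderation"] = rep_mod
            grouping = "sex_region" if config.moderation_regions else "sex"
            free = moderation_mod.fit_moderation(ss, grouping=grouping)
            equal = moderation_mod.fit_moderation(ss, grouping=grouping, equated=True)
            comparison = twinmodel.lrt(free, equal)
            curves = []
            params = free.params if isinstance(free.params, dict) else {"all": free.params}
            for name, p in params.items():
                tab = moderation_mod.variance_curves(p)
                tab.insert(0, "block", name)
                tab["a_peak_age"] = tab.attrs["a_peak_age"]
                curves.append(tab)
            curves_df = pd.concat(curves, ignore_index=True)
            curves_df.to_csv(outdir / "variance_curves.csv", index=False)
            summary["moderation"] = {
                "grouping": grouping,
                "minus2ll_free": free.minus2ll,
                "minus2ll_equated": equal.minus2ll,
                "group_equality_lrt": {
                    "delta_minus2ll": comparison.delta_minus2ll,
                    "delta_df": comparison.delta_df,
                    "p_value": comparison.p_value,
                },
                "a_peak_age": {name: float(moderation_mod.variance_curves(p).attrs["a_peak_age"]) for name, p in params.items()},
            }
            summary["unconverged_fits"] += int(not free.converged) + int(not equal.converged)
            log.info("stage=moderation blocks=%d", len(params))
    except Exception as exc:
        log.error("pipeline failed in stage %s: %s", stage, exc)
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()

    _validate_summary(summary)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    return summary


def sensitivity_with_exclusion(config: RunConfig, cohort_id: str) -> pd.DataFrame:
    """Per-age component estimates with and without one named cohort.

    Runs the univariate per-age fits on the region containing the cohort
    twice (cohort included / excluded) and reports the difference per age
    and sex — the design used to probe a heterogeneous cohort's leverage
    on a region's estimates.
    """
    config.validate()
    if config.input_csv is not None:
        raw = pd.read_csv(config.input_csv)
    else:
        gen = config.generator or synth.GeneratorConfig()
        gen = dataclasses.replace(gen, seed=_spawned_seeds(config.seed, 1)[0])
        raw = synth.simulate_cohort(gen)
    if cohort_id not in set(raw["cohort"]):
        raise ConfigurationError(f"cohort {cohort_id!r} not present in the data")
    region = raw.loc[raw["cohort"] == cohort_id, "region"].iloc[0]
    regional = raw[raw["region"] == region]
    lo, hi = config.age_range

    def fit(tbl: pd.DataFrame) -> pd.DataFrame:
        pairs, _ = preprocess_mod.run_preprocess(
            tbl, mode="univariate", z_max=config.z_max, min_cohort_n=config.min_cohort_n
        )
        comps, _ = fit_univariate_by_age(pairs, range(lo, hi + 1))
        return comps.set_index(["age_group", "sex"])

    with_c = fit(regional)
    without_c = fit(regional[regional["cohort"] != cohort_id])
    joined = with_c.join(without_c, lsuffix="_with", rsuffix="_without", how="inner")
    for comp in ("h2", "c2", "e2"):
        joined[f"d_{comp}"] = joined[f"{comp}_without"] - joined[f"{comp}_with"]
    return joined.reset_index()
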