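"""Twin-cohort height simulator with known genetic/environmental structure.

Generates measurement tables emulating a pooled multinational twin
database on child and adolescent height: 19 one-year age groups (group k
covers ages k +/- 0.5), two sexes, a zygosity mix of ~39% MZ / 34%
same-sex DZ / 27% opposite-sex DZ pairs, and three geographic-cultural
regions (Europe; North-America and Australia; East-Asia) whose
age- and sex-specific height means and SDs default to the published
descriptive table of that database.  Longitudinal repeats, cohort
effects, secular birth-year trends, MZ/DZ mean differences and missing
co-twins are all configurable.

Heights are built from explicit latent draws:

    height = mu(age, sex, region) + trend + cohort + a(age,sex)*A
             + c(age,sex)*C + e(age,sex)*E  [+ measurement error]

with A standard-normal correlated 1.0 within MZ pairs, 0.5 within
same-sex DZ pairs and ``r_gOS`` within opposite-sex pairs; C shared
within a pair; E independent.  A and C persist across a twin's repeated
measurements (genes and family environment do not change), E is redrawn
per occasion.  Because the generating paths are known, every downstream
estimator can be validated against truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .twinmodel import ConfigurationError, SexLimParams

__all__ = [
    "RegionSpec",
    "GeneratorConfig",
    "default_mean_curve",
    "default_path_table",
    "path_table_from_components",
    "simulate_pairs_at_age",
    "simulate_cohort",
    "write_cohort",
]

AGES = tuple(range(1, 20))
SEXES = ("M", "F")
REGIONS = ("Europe", "North-America and Australia", "East-Asia")

# Published descriptive statistics (mean, SD in cm) of height by age, sex
# and region, used as the default calibration of the generator.
_MEAN_SD = {
    ("Europe", "M"): [
        (75.3, 3.3), (87.7, 3.9), (96.8, 4.3), (103.0, 4.9), (112.6, 5.5),
        (118.3, 5.6), (125.3, 6.1), (130.3, 5.8), (135.8, 6.6), (142.1, 6.8),
        (145.6, 7.1), (152.7, 7.9), (159.7, 8.8), (166.0, 9.1), (172.3, 8.8),
        (176.2, 7.4), (178.2, 7.1), (179.6, 6.9), (180.0, 6.9),
    ],
    ("Europe", "F"): [
        (74.1, 3.0), (86.7, 3.8), (95.8, 4.4), (101.8, 4.9), (111.9, 5.6),
        (117.9, 5.3), (124.5, 6.2), (129.5, 5.9), (134.8, 6.8), (141.6, 7.0),
        (145.8, 7.6), (153.7, 8.2), (159.5, 7.4), (162.6, 6.8), (165.5, 6.7),
        (165.4, 6.2), (166.1, 6.3), (167.1, 6.5), (167.2, 6.4),
    ],
    ("North-America and Australia", "M"): [
        (71.6, 8.8), (85.2, 4.7), (96.3, 5.1), (101.4, 6.4), (108.9, 6.5),
        (114.4, 8.4), (121.5, 8.8), (129.6, 7.2), (133.9, 7.4), (139.2, 7.4),
        (144.4, 8.4), (151.8, 8.2), (157.6, 10.1), (165.7, 8.4), (171.3, 8.4),
        (174.9, 7.6), (174.4, 7.5), (173.4, 7.1), (174.9, 7.8),
    ],
    ("North-America and Australia", "F"): [
        (70.3, 9.0), (84.1, 4.8), (95.1, 5.5), (100.1, 6.3), (107.5, 7.0),
        (113.9, 8.0), (120.4, 7.5), (127.6, 8.0), (133.3, 7.5), (138.7, 8.3),
        (145.2, 8.5), (152.9, 7.9), (156.4, 7.6), (161.4, 6.5), (162.6, 6.7),
        (163.9, 6.8), (164.6, 7.0), (164.6, 7.0), (164.4, 6.9),
    ],
    ("East-Asia", "M"): [
        (69.4, 3.7), (83.4, 4.6), (93.4, 3.8), (99.6, 4.6), (106.5, 4.6),
        (112.6, 4.9), (118.1, 5.2), (123.8, 5.2), (129.4, 5.5), (135.2, 6.1),
        (140.5, 6.4), (146.5, 7.1), (154.7, 9.6), (164.2, 7.2), (166.7, 7.3),
        (168.4, 6.1), (171.5, 6.8), (170.7, 5.6), (174.4, 5.3),
    ],
    ("East-Asia", "F"): [
        (67.8, 3.9), (81.9, 4.4), (92.3, 3.6), (98.6, 4.5), (105.5, 4.6),
        (112.3, 4.8), (117.5, 5.0), (123.2, 5.4), (129.0, 5.6), (135.4, 6.5),
        (142.1, 7.0), (147.7, 6.8), (153.5, 6.3), (157.5, 6.0), (157.6, 5.6),
        (158.4, 6.0), (159.3, 5.5), (159.5, 4.8), (158.4, 5.3),
    ],
}

# Default standardized component trajectories: heritability rises from its
# reported infancy value (0.40 boys / 0.38 girls at age 1) to its reported
# adolescent peak (0.83 at 14 in boys / 0.76 at 13 in girls); the unique-
# environment share is held flat at 0.10 (reported range 0.05-0.14) and the
# shared-environment share takes the remainder.
_H2_BY_AGE = {
    "M": [0.40, 0.50, 0.57, 0.62, 0.66, 0.69, 0.71, 0.72, 0.74, 0.75,
          0.76, 0.77, 0.80, 0.83, 0.80, 0.82, 0.78, 0.76, 0.75],
    "F": [0.38, 0.48, 0.55, 0.60, 0.64, 0.67, 0.69, 0.70, 0.72, 0.73,
          0.74, 0.75, 0.76, 0.74, 0.73, 0.72, 0.71, 0.70, 0.70],
}
_E2_FLAT = 0.10


def default_mean_curve() -> pd.DataFrame:
    """Region/sex/age table of mean height and SD (cm), published calibration."""
    rows = [
        {"region": r, "sex": s, "age_group": age, "mean_cm": m, "sd_cm": sd}
        for (r, s), vals in _MEAN_SD.items()
        for age, (m, sd) in zip(AGES, vals)
    ]
    return pd.DataFrame(rows)


def path_table_from_components(
    h2: dict[str, list[float]],
    e2: dict[str, list[float]] | float,
    mean_curve: pd.DataFrame,
) -> pd.DataFrame:
    """Convert standardized components + total SDs into cm-scale path tables.

    a(age,sex,region) = sqrt(h2 * SD^2) and so on; c2 takes the remainder
    1 - h2 - e2.
    """
    out = mean_curve.copy()
    h2_arr = np.array([h2[s][a - 1] for s, a in zip(out["sex"], out["age_group"])])
    if isinstance(e2, dict):
        e2_arr = np.array([e2[s][a - 1] for s, a in zip(out["sex"], out["age_group"])])
    else:
        e2_arr = np.full(len(out), float(e2))
    c2_arr = 1.0 - h2_arr - e2_arr
    if (c2_arr < -1e-9).any():
        raise ConfigurationError("h2 + e2 exceeds 1 somewhere in the path table")
    v = out["sd_cm"].to_numpy() ** 2
    out["a"] = np.sqrt(h2_arr * v)
    out["c"] = np.sqrt(np.clip(c2_arr, 0.0, None) * v)
    out["e"] = np.sqrt(e2_arr * v)
    return out[["region", "sex", "age_group", "a", "c", "e"]]


def default_path_table() -> pd.DataFrame:
    return path_table_from_components(_H2_BY_AGE, _E2_FLAT, default_mean_curve())


@dataclass
class RegionSpec:
    """One geographic-cultural region of the simulated database."""

    name: str
    n_families: int
    n_cohorts: int = 5
    cohort_weights: list[float] | None = None  # default: equal
    zygosity_probs: tuple[float, float, float] = (0.39, 0.34, 0.27)  # MZ, SSDZ, OSDZ
    sex_ratio: float = 0.5  # P(male) for same-sex pairs

    def validate(self) -> None:
        p = np.asarray(self.zygosity_probs, dtype=float)
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"zygosity_probs for region {self.name!r} must be non-negative and sum to 1, got {tuple(p)}"
            )
        if not 0.0 < self.sex_ratio < 1.0:
            raise ConfigurationError(f"sex_ratio for region {self.name!r} must lie in (0, 1)")
        if self.n_families < 0 or self.n_cohorts < 1:
            raise ConfigurationError(f"invalid n_families/n_cohorts for region {self.name!r}")


def _default_regions() -> list[RegionSpec]:
    # Distinct-pair counts per region sized so that, with ~2.1 measurement
    # occasions per pair, paired-measurement totals match the source database
    # (~132k Europe, ~30k North-America and Australia, ~18k East-Asia).
    return [
        RegionSpec("Europe", n_families=62800, n_cohorts=20),
        RegionSpec("North-America and Australia", n_families=14200, n_cohorts=15),
        RegionSpec("East-Asia", n_families=8500, n_cohorts=6),
    ]


@dataclass
class GeneratorConfig:
    """Full configuration of the cohort generator (defaults = calibrated world)."""

    seed: int = 0
    regions: list[RegionSpec] = field(default_factory=_default_regions)
    mean_curve: pd.DataFrame | None = None  # default: published table
    path_table: pd.DataFrame | None = None  # default: component trajectories above
    path_quadratic: dict | None = None  # optional {sex: {a:(p0,p1,p2), c:..., e:...}} on age-10
    dz_mean_shift: float = 0.0  # cm added to DZ (and OS) means
    cohort_effect_sd: float = 0.5  # cm, shared within cohort
    birth_year_range: tuple[int, int] = (1960, 2005)
    birth_year_trend: float = 0.1  # cm per birth year (secular trend)
    r_gos: float = 0.5  # additive-genetic correlation within OS pairs
    measurement_error_sd: float = 0.0  # cm; 0 = folded into e
    repeat_prob: float = 0.5  # P(another measurement occasion), geometric, cap 5
    missing_cotwin_prob: float = 0.0
    assortative_r: float = 0.0  # approximate spousal correlation, robustness only
    age_groups: tuple[int, ...] = AGES

    def validate(self) -> None:
        if not self.regions:
            raise ConfigurationError("regions must be a non-empty list")
        for r in self.regions:
            r.validate()
        if not -1.0 <= self.r_gos <= 1.0:
            raise ConfigurationError(f"r_gos must lie in [-1, 1], got {self.r_gos}")
        for name in ("cohort_effect_sd", "measurement_error_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("repeat_prob", "missing_cotwin_prob"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1)")
        if not -1.0 <= self.assortative_r <= 1.0:
            raise ConfigurationError("assortative_r must lie in [-1, 1]")
        if any(a not in AGES for a in self.age_groups):
            raise ConfigurationError("age_groups must be a subset of 1..19")

    def resolved_mean_curve(self) -> pd.DataFrame:
        return self.mean_curve if self.mean_curve is not None else default_mean_curve()

    def resolved_path_table(self) -> pd.DataFrame:
        if self.path_table is not None:
            tab = self.path_table
        elif self.path_quadratic is not None:
            rows = []
            for region in {r.name for r in self.regions}:
                for s in SEXES:
                    coefs = self.path_quadratic[s]
                    for age in AGES:
                        x = age - 10.0
                        rows.append(
                            {
                                "region": region,
                                "sex": s,
                                "age_group": age,
                                **{
                                    p: coefs[p][0] + coefs[p][1] * x + coefs[p][2] * x * x
                                    for p in ("a", "c", "e")
                                },
                            }
                        )
            tab = pd.DataFrame(rows)
        else:
            tab = default_path_table()
        if (tab[["a", "c", "e"]].to_numpy() < 0).any():
            raise ConfigurationError("path_table contains a negative path value")
        return tab

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("mean_curve", "path_table"):
            if d[key] is not None:
                d[key] = getattr(self, key).to_dict(orient="records")
        return d


# ---------------------------------------------------------------------------
# Pair-level simulator (single age group, explicit truth)
# ---------------------------------------------------------------------------


def simulate_pairs_at_age(
    n_per_group: dict[str, int],
    truth: SexLimParams,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate complete twin pairs of one age group under known paths.

    Latent A, C, E standard normals are drawn with within-pair
    correlations (A: 1.0 MZ, 0.5 same-sex DZ, r_gOS opposite-sex; C: 1.0;
    E: 0) and combined with the sex-specific paths and zygosity-sex means
    of ``truth``.  Returns a paired table with true group labels (columns
    ``group``, ``y1``, ``y2``); OS pairs are male-first.
    """
    truth.validate()
    for g, n in n_per_group.items():
        if n < 0:
            raise ConfigurationError(f"negative pair count for group {g!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frames = []
    group_setup = {
        "MZM": (1.0, "M", "M", truth.mu_mzm, truth.mu_mzm),
        "MZF": (1.0, "F", "F", truth.mu_mzf, truth.mu_mzf),
        "DZM": (0.5, "M", "M", truth.mu_dzm, truth.mu_dzm),
        "DZF": (0.5, "F", "F", truth.mu_dzf, truth.mu_dzf),
        "OS": (truth.r_gos, "M", "F", truth.mu_dzm, truth.mu_dzf),
    }
    for g, n in n_per_group.items():
        if g not in group_setup:
            raise ConfigurationError(f"unknown group {g!r}")
        if n == 0:
            continue
        r_a, s1, s2, mu1, mu2 = group_setup[g]
        z1 = rng.standard_normal(n)
        z2 = rng.standard_normal(n)
        a1 = z1
        a2 = r_a * z1 + np.sqrt(max(1.0 - r_a * r_a, 0.0)) * z2
        c = rng.standard_normal(n)
        e1 = rng.standard_normal(n)
        e2 = rng.standard_normal(n)
        pa1, pc1, pe1 = truth.paths(s1)
        pa2, pc2, pe2 = truth.paths(s2)
        frames.append(
            pd.DataFrame(
                {
                    "group": g,
                    "y1": mu1 + pa1 * a1 + pc1 * c + pe1 * e1,
                    "y2": mu2 + pa2 * a2 + pc2 * c + pe2 * e2,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["group", "y1", "y2"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Cohort-level simulator (full measurement table)
# ---------------------------------------------------------------------------

_MAX_OCCASIONS = 5


def simulate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a full measurement table under ``config``.

    One row per height measurement: columns family_id, twin_order (1|2),
    cohort, region, zygosity (MZ|DZ), sex (M|F), birth_year, exact_age,
    height_cm.  Individuals repeat across age groups per ``repeat_prob``
    (A and C latents persist, E is redrawn); exact age is uniform within
    each one-year bin; birth year is the measurement year minus exact
    age, rounded down.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    mean_curve = config.resolved_mean_curve()
    paths = config.resolved_path_table()
    ages = np.asarray(config.age_groups)
    by_lo, by_hi = config.birth_year_range
    by_mid = 0.5 * (by_lo + by_hi)

    # fast lookup arrays: [region][sex][age-1] -> value
    def lookup(tab: pd.DataFrame, col: str) -> dict[tuple[str, str], np.ndarray]:
        out = {}
        for (region, s), sub in tab.groupby(["region", "sex"]):
            arr = np.full(20, np.nan)
            arr[sub["age_group"].to_numpy()] = sub[col].to_numpy()
            out[(region, s)] = arr
        return out

    mu_of = lookup(mean_curve, "mean_cm")
    a_of = lookup(paths, "a")
    c_of = lookup(paths, "c")
    e_of = lookup(paths, "e")

    frames = []
    fam_offset = 0
    for region in config.regions:
        needed = {(region.name, s) for s in SEXES}
        missing = needed - set(mu_of) | needed - set(a_of)
        if missing:
            raise ConfigurationError(f"mean_curve/path_table missing entries for {sorted(missing)}")
        n = region.n_families
        if n == 0:
            continue
        # family-level structure
        zyg_draw = rng.choice(3, size=n, p=np.asarray(region.zygosity_probs, dtype=float))
        is_mz = zyg_draw == 0
        is_os = zyg_draw == 2
        sex1 = np.where(rng.random(n) < region.sex_ratio, "M", "F")
        sex1 = np.where(is_os, "M", sex1)  # OS: twin 1 male, twin 2 female
        sex2 = np.where(is_os, "F", sex1)
        weights = region.cohort_weights
        if weights is None:
            weights = [1.0] * region.n_cohorts
        w = np.asarray(weights, dtype=float)
        cohort_idx = rng.choice(region.n_cohorts, size=n, p=w / w.sum())
        cohort_names = np.array([f"{region.name[:2].upper()}-C{j:02d}" for j in range(region.n_cohorts)])
        cohort_eff = rng.normal(0.0, config.cohort_effect_sd, size=region.n_cohorts)

        # persistent latents
        r_dz = min(0.5 + 0.5 * config.assortative_r, 1.0)  # approximate assortative-mating inflation
        r_os = min(config.r_gos + 0.5 * config.assortative_r, 1.0)
        r_a = np.where(is_mz, 1.0, np.where(is_os, r_os, r_dz))
        z1 = rng.standard_normal(n)
        z2 = rng.standard_normal(n)
        A1 = z1
        A2 = r_a * z1 + np.sqrt(np.clip(1.0 - r_a * r_a, 0.0, None)) * z2
        C = rng.standard_normal(n)

        # measurement occasions: first age group uniform, extras geometric
        n_occ = np.ones(n, dtype=int)
        if config.repeat_prob > 0:
            # truncated-geometric occasion count: ~2 occasions/pair at the default
            alive = np.ones(n, dtype=bool)
            for _ in range(_MAX_OCCASIONS - 1):
                alive &= (rng.random(n) < config.repeat_prob) & (n_occ < len(ages))
                n_occ += alive
        if config.repeat_prob > 0:
            age_grp = np.concatenate([rng.choice(ages, size=k, replace=False) for k in n_occ])
        else:
            age_grp = rng.choice(ages, size=n)
        fam_idx = np.repeat(np.arange(n), n_occ)
        m = fam_idx.size
        exact_age = age_grp - 0.5 + rng.random(m)
        meas_year_f = rng.uniform(by_lo, by_hi, size=m) + exact_age
        birth_year = np.floor(meas_year_f - exact_age).astype(int)

        sex_idx1 = (sex1[fam_idx] == "F").astype(int)
        sex_idx2 = (sex2[fam_idx] == "F").astype(int)

        def path_vals(table: dict, sex_arr: np.ndarray) -> np.ndarray:
            vals = np.empty(m)
            for k, s in enumerate(SEXES):
                mask = sex_arr == s
                vals[mask] = table[(region.name, s)][age_grp[mask]]
            return vals

        rows = []
        for member, (sex_arr, A) in enumerate(((sex1, A1), (sex2, A2)), start=1):
            sx = sex_arr[fam_idx]
            mu = path_vals(mu_of, sx)
            a = path_vals(a_of, sx)
            cpath = path_vals(c_of, sx)
            e = path_vals(e_of, sx)
            y = (
                mu
                + config.birth_year_trend * (birth_year - by_mid)
                + cohort_eff[cohort_idx[fam_idx]]
                + config.dz_mean_shift * (~is_mz[fam_idx])
                + a * A[fam_idx]
                + cpath * C[fam_idx]
                + e * rng.standard_normal(m)
            )
            if config.measurement_error_sd > 0:
                y = y + rng.normal(0.0, config.measurement_error_sd, size=m)
            rows.append(
                pd.DataFrame(
                    {
                        "family_id": fam_offset + fam_idx,
                        "twin_order": member,
                        "cohort": cohort_names[cohort_idx[fam_idx]],
                        "region": region.name,
                        "zygosity": np.where(is_mz[fam_idx], "MZ", "DZ"),
                        "sex": sx,
                        "birth_year": birth_year,
                        "exact_age": exact_age,
                        "height_cm": y,
                    }
                )
            )
        region_df = pd.concat(rows, ignore_index=True)
        if config.missing_cotwin_prob > 0:
            # drop one co-twin's row per occasion with the configured probability
            occ_key = region_df["family_id"].astype(str) + "@" + region_df["exact_age"].round(6).astype(str)
            uniq = occ_key.unique()
            hit = uniq[rng.random(uniq.size) < config.missing_cotwin_prob]
            drop_member = rng.integers(1, 3, size=hit.size)
            drop = pd.Series(drop_member, index=hit)
            victim = occ_key.map(drop)
            region_df = region_df[~(victim == region_df["twin_order"])].reset_index(drop=True)
        frames.append(region_df)
        fam_offset += n

    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["family_id", "exact_age", "twin_order"], kind="stable").reset_index(drop=True)
    return out


def write_cohort(table: pd.DataFrame, path: str, config: GeneratorConfig | None = None) -> None:
    """Write a measurement table to CSV with a JSON sidecar of the config."""
    table.to_csv(path, index=False)
    if config is not None:
        with open(str(path) + ".json", "w") as fh:
            json.dump(config.to_jsonable(), fh, indent=2, default=str)
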