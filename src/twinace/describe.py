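"""Descriptive statistics and twin correlations that drive model selection.

Twin correlations are the classical pre-modelling diagnostic: rMZ > rDZ
indicates genetic influence, rDZ > rMZ/2 indicates shared environmental
influence, and opposite-sex DZ correlations below the same-sex DZ
correlations indicate sex-specific genetic effects.  Same-sex
correlations use the double-entry Pearson estimator (each pair enters as
(y1, y2) and (y2, y1)), which is invariant to the arbitrary within-pair
ordering; opposite-sex pairs are single-entry with a fixed male-first
order.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .twinmodel import GROUPS

__all__ = ["describe_heights", "twin_correlations", "selection_heuristics"]


def describe_heights(
    table: pd.DataFrame, strata: list[str] = ["age_group", "sex", "region"]
) -> pd.DataFrame:
    """Per-stratum N, mean and SD (denominator n-1) of height.

    Empty strata are omitted; single-record strata report a missing SD.
    """
    strata = [s for s in strata if s in table.columns]
    g = table.groupby(strata, observed=True)["height_cm"]
    out = g.agg(N="count", mean="mean", SD=lambda x: x.std(ddof=1)).reset_index()
    return out[out["N"] > 0].reset_index(drop=True)


def _fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    from scipy.stats import norm

    if n < 4 or abs(r) >= 1.0:
        return (float("nan"), float("nan"))
    z = math.atanh(r)
    se = 1.0 / math.sqrt(n - 3)
    q = norm.ppf(0.5 + level / 2)
    return (math.tanh(z - q * se), math.tanh(z + q * se))


def twin_correlations(
    pairs: pd.DataFrame,
    by: list[str] = ["age_group"],
    min_pairs: int = 3,
    flag_threshold: int = 30,
) -> pd.DataFrame:
    """Within-pair correlations per zygosity-sex group and stratum.

    Same-sex groups: double-entry Pearson; OS: single-entry (male first).
    95% CIs via the Fisher z transform with n_pairs as the effective
    sample size (conservative for double entry).  Groups with fewer than
    ``min_pairs`` pairs report a missing correlation; groups below
    ``flag_threshold`` are flagged low-n.
    """
    by = [c for c in by if c in pairs.columns]
    rows = []
    keys = pairs.groupby(by, observed=True).groups.keys() if by else [()]
    for key in keys:
        key_t = key if isinstance(key, tuple) else (key,)
        sub = pairs
        for col, val in zip(by, key_t):
            sub = sub[sub[col] == val]
        for g in GROUPS:
            gp = sub[sub["group"] == g]
            n = len(gp)
            if n < min_pairs:
                r, ci = float("nan"), (float("nan"), float("nan"))
            else:
                y1 = gp["y1"].to_numpy(dtype=float)
                y2 = gp["y2"].to_numpy(dtype=float)
                if g == "OS":
                    r = float(np.corrcoef(y1, y2)[0, 1])
                else:
                    r = float(np.corrcoef(np.r_[y1, y2], np.r_[y2, y1])[0, 1])
                ci = _fisher_ci(r, n)
            rows.append(
                dict(zip(by, key_t))
                | {
                    "group": g,
                    "r": r,
                    "n_pairs": n,
                    "ci_lo": ci[0],
                    "ci_hi": ci[1],
                    "low_n": n < flag_threshold,
                }
            )
    return pd.DataFrame(rows)


def selection_heuristics(correlations: dict[str, float]) -> dict:
    """Starting-model flags from one stratum's twin correlations.

    genetic: rMZ > rDZ; shared_env: rDZ > rMZ/2 (strict); sex_specific:
    rOS < min(rDZM, rDZF).  ``correlations`` maps group labels to r; rMZ
    and rDZ average the sexes present.  Flags are ``None`` (undetermined)
    when the needed groups are missing.
    """

    def avail(*names: str) -> list[float]:
        return [correlations[n] for n in names if n in correlations and np.isfinite(correlations[n])]

    mz = avail("MZM", "MZF")
    dz = avail("DZM", "DZF")
    r_mz = float(np.mean(mz)) if mz else None
    r_dz = float(np.mean(dz)) if dz else None
    os_vals = avail("OS")
    r_os = os_vals[0] if os_vals else None
    ss_dz = avail("DZM", "DZF")

    genetic = None if r_mz is None or r_dz is None else bool(r_mz > r_dz)
    shared_env = None if r_mz is None or r_dz is None else bool(r_dz > 0.5 * r_mz)
    sex_specific = (
        None
        if r_os is None or len(ss_dz) < 2
        else bool(r_os < min(ss_dz))
    )
    return {
        "genetic": genetic,
        "shared_env": shared_env,
        "sex_specific": sex_specific,
        "r_mz": r_mz,
        "r_dz": r_dz,
        "r_os": r_os,
    }
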