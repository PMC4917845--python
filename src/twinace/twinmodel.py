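"""Univariate ACE sex-limitation twin modelling by maximum likelihood.

The classical twin design decomposes phenotypic variance into additive
genetic (A), common environmental (C) and unique environmental (E)
components by contrasting monozygotic (MZ) pairs, whose additive genetic
values correlate 1.0, with dizygotic (DZ) pairs, whose additive genetic
values correlate 0.5 on average.  C correlates 1.0 within both pair types
and E is uncorrelated.  The sex-limitation extension allows sex-specific
path coefficients (a, c, e per sex) and a free additive-genetic
correlation ``r_gOS`` within opposite-sex pairs; ``r_gOS`` below its null
value 0.5 indicates qualitatively sex-specific genetic effects.

Data enter as complete pairs classified into five zygosity-sex groups
(MZM, MZF, DZM, DZF, OS; OS ordered male-first).  The likelihood is the
product of bivariate-normal densities of the pair vectors under each
group's model-implied mean vector and covariance matrix.  Because the
data are complete, the -2 log-likelihood is evaluated exactly from
per-group sufficient statistics (n, mean vector, scatter matrix); a
per-pair summation path is retained for verification.

Means are parameterized per zygosity and sex (MZ and DZ twins are
allowed different means; OS twins share the DZ means), giving 11 free
parameters in the full model.  Nested submodels (equal components across
sexes, a common-scale model, and C- or A-drop models), a saturated
reference model, likelihood-ratio tests with Bonferroni correction, and
profile-likelihood confidence intervals are provided.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "GROUPS",
    "SexLimParams",
    "StandardizedComponents",
    "FitResult",
    "LRTResult",
    "GroupStats",
    "ConfigurationError",
    "DataError",
    "expected_moments",
    "group_stats",
    "neg2ll",
    "fit_ace_sexlim",
    "fit_saturated",
    "fit_submodel",
    "lrt",
    "bonferroni",
    "profile_ci",
    "falconer",
]

GROUPS = ("MZM", "MZF", "DZM", "DZF", "OS")
_SAME_SEX_GROUPS = ("MZM", "MZF", "DZM", "DZF")
_LOG_2PI = math.log(2.0 * math.pi)


class ConfigurationError(ValueError):
    """Invalid model or generator configuration (names the offending field)."""


class DataError(ValueError):
    """Structurally invalid input data."""


# ---------------------------------------------------------------------------
# Parameters and results
# ---------------------------------------------------------------------------


@dataclass
class SexLimParams:
    """The 11 free parameters of the univariate ACE sex-limitation model.

    Paths are on the phenotype (cm) scale; squared paths are variance
    components.  ``r_gos`` is the additive-genetic correlation within
    opposite-sex pairs (null value 0.5).  MZ and DZ twins have separate
    means per sex; OS twins use the DZ means.
    """

    a_m: float
    c_m: float
    e_m: float
    a_f: float
    c_f: float
    e_f: float
    r_gos: float = 0.5
    mu_mzm: float = 0.0
    mu_dzm: float = 0.0
    mu_mzf: float = 0.0
    mu_dzf: float = 0.0

    def validate(self) -> None:
        if not -1.0 <= self.r_gos <= 1.0:
            raise ConfigurationError(f"r_gos must lie in [-1, 1], got {self.r_gos}")
        for name in ("a_m", "c_m", "e_m", "a_f", "c_f", "e_f"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"path {name} must be >= 0, got {getattr(self, name)}")

    def variance(self, sex: str) -> float:
        a, c, e = self.paths(sex)
        return a * a + c * c + e * e

    def paths(self, sex: str) -> tuple[float, float, float]:
        if sex == "M":
            return self.a_m, self.c_m, self.e_m
        if sex == "F":
            return self.a_f, self.c_f, self.e_f
        raise ConfigurationError(f"sex must be 'M' or 'F', got {sex!r}")


@dataclass
class StandardizedComponents:
    """Standardized variance proportions h2, c2, e2 per sex (sum to 1)."""

    h2_m: float
    c2_m: float
    e2_m: float
    h2_f: float
    c2_f: float
    e2_f: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    @classmethod
    def from_params(cls, p: SexLimParams) -> "StandardizedComponents":
        vm = p.variance("M")
        vf = p.variance("F")
        return cls(
            h2_m=p.a_m**2 / vm,
            c2_m=p.c_m**2 / vm,
            e2_m=p.e_m**2 / vm,
            h2_f=p.a_f**2 / vf,
            c2_f=p.c_f**2 / vf,
            e2_f=p.e_f**2 / vf,
        )


@dataclass
class FitResult:
    """A maximum-likelihood fit: estimates, -2LL, df bookkeeping, diagnostics."""

    model: str
    params: object
    minus2ll: float
    n_free_params: int
    n_pairs: dict[str, int]
    converged: bool
    standardized: StandardizedComponents | None = None
    nests_in: frozenset = frozenset()
    message: str = ""
    _x: np.ndarray | None = field(default=None, repr=False)
    _stats: dict | None = field(default=None, repr=False)


@dataclass
class LRTResult:
    """Likelihood-ratio test between two nested maximum-likelihood fits."""

    delta_minus2ll: float
    delta_df: int
    p_value: float


# ---------------------------------------------------------------------------
# Expected moments and likelihood
# ---------------------------------------------------------------------------


def expected_moments(group: str, params: SexLimParams) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied mean vector and 2x2 covariance for one zygosity-sex group.

    Variances are a^2 + c^2 + e^2 per member's sex.  Within-pair covariance
    is a^2 + c^2 for MZ, 0.5 a^2 + c^2 for same-sex DZ and
    r_gOS * a_m * a_f + c_m * c_f for OS pairs (male listed first).
    """
    p = params
    if group == "MZM":
        v = p.variance("M")
        cov = p.a_m**2 + p.c_m**2
        mu = np.array([p.mu_mzm, p.mu_mzm])
    elif group == "MZF":
        v = p.variance("F")
        cov = p.a_f**2 + p.c_f**2
        mu = np.array([p.mu_mzf, p.mu_mzf])
    elif group == "DZM":
        v = p.variance("M")
        cov = 0.5 * p.a_m**2 + p.c_m**2
        mu = np.array([p.mu_dzm, p.mu_dzm])
    elif group == "DZF":
        v = p.variance("F")
        cov = 0.5 * p.a_f**2 + p.c_f**2
        mu = np.array([p.mu_dzf, p.mu_dzf])
    elif group == "OS":
        cov = p.r_gos * p.a_m * p.a_f + p.c_m * p.c_f
        mu = np.array([p.mu_dzm, p.mu_dzf])
        return mu, np.array([[p.variance("M"), cov], [cov, p.variance("F")]])
    else:
        raise ConfigurationError(f"unknown group {group!r}; expected one of {GROUPS}")
    return mu, np.array([[v, cov], [cov, v]])


@dataclass
class GroupStats:
    """Sufficient statistics of one group's complete pairs."""

    n: int
    ybar: np.ndarray  # (2,)
    scatter: np.ndarray  # (2,2) sum of outer products about ybar


def group_stats(pairs: pd.DataFrame) -> dict[str, GroupStats]:
    """Per-group (n, mean vector, scatter matrix) from a paired table.

    ``pairs`` needs columns ``group``, ``y1``, ``y2``.
    """
    out: dict[str, GroupStats] = {}
    for g, sub in pairs.groupby("group", observed=True):
        y = sub[["y1", "y2"]].to_numpy(dtype=float)
        n = y.shape[0]
        ybar = y.mean(axis=0)
        d = y - ybar
        out[str(g)] = GroupStats(n=n, ybar=ybar, scatter=d.T @ d)
    return out


def _neg2ll_group(mu: np.ndarray, sig: np.ndarray, gs: GroupStats) -> float:
    s11, s12 = sig[0, 0], sig[0, 1]
    s22 = sig[1, 1]
    det = s11 * s22 - s12 * s12
    if det <= 0.0 or s11 <= 0.0 or s22 <= 0.0:
        return math.inf
    S = gs.scatter
    d1 = gs.ybar[0] - mu[0]
    d2 = gs.ybar[1] - mu[1]
    quad = (s22 * S[0, 0] - 2.0 * s12 * S[0, 1] + s11 * S[1, 1]) / det
    mean_quad = gs.n * (s22 * d1 * d1 - 2.0 * s12 * d1 * d2 + s11 * d2 * d2) / det
    return gs.n * (2.0 * _LOG_2PI + math.log(det)) + quad + mean_quad


def _neg2ll_stats(params: SexLimParams, stats_by_group: Mapping[str, GroupStats]) -> float:
    total = 0.0
    for g, gs in stats_by_group.items():
        mu, sig = expected_moments(g, params)
        total += _neg2ll_group(mu, sig, gs)
        if not math.isfinite(total):
            return math.inf
    return total


def _neg2ll_perpair(params: SexLimParams, pairs: pd.DataFrame) -> float:
    total = 0.0
    for g, sub in pairs.groupby("group", observed=True):
        mu, sig = expected_moments(str(g), params)
        s11, s12, s22 = sig[0, 0], sig[0, 1], sig[1, 1]
        det = s11 * s22 - s12 * s12
        if det <= 0.0:
            return math.inf
        d1 = sub["y1"].to_numpy(dtype=float) - mu[0]
        d2 = sub["y2"].to_numpy(dtype=float) - mu[1]
        quad = (s22 * d1 * d1 - 2.0 * s12 * d1 * d2 + s11 * d2 * d2) / det
        total += float(np.sum(2.0 * _LOG_2PI + math.log(det) + quad))
    return total


def neg2ll(params: SexLimParams, pairs: pd.DataFrame | Mapping[str, GroupStats], *, method: str = "suff") -> float:
    """-2 log-likelihood of complete pairs under the sex-limitation model.

    ``method='suff'`` evaluates exactly from per-group sufficient statistics;
    ``method='perpair'`` sums bivariate-normal log-densities pair by pair
    (identical for complete data; kept for verification).  A singular
    expected covariance yields ``+inf`` rather than an exception.
    """
    if isinstance(pairs, Mapping):
        if method == "perpair":
            raise ConfigurationError("per-pair evaluation requires the pair table, not sufficient statistics")
        return _neg2ll_stats(params, pairs)
    if method == "suff":
        return _neg2ll_stats(params, group_stats(pairs))
    if method == "perpair":
        return _neg2ll_perpair(params, pairs)
    raise ConfigurationError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Model specifications (parameter packing)
# ---------------------------------------------------------------------------

# Paths are optimized raw and unbounded (variances are their squares), so no
# boundary constraints are needed; r_gOS is kept in [-1, 1] via tanh.


def _z_to_r(z: float) -> float:
    return math.tanh(z)


def _r_to_z(r: float) -> float:
    r = min(max(r, -0.999), 0.999)
    return math.atanh(r)


@dataclass(frozen=True)
class _ModelSpec:
    name: str
    n_free: int
    unpack: Callable[[np.ndarray], SexLimParams]
    pack: Callable[[SexLimParams], np.ndarray]
    nests_in: frozenset


def _full_spec() -> _ModelSpec:
    def unpack(x: np.ndarray) -> SexLimParams:
        return SexLimParams(x[0], x[1], x[2], x[3], x[4], x[5], _z_to_r(x[6]), x[7], x[8], x[9], x[10])

    def pack(p: SexLimParams) -> np.ndarray:
        return np.array(
            [p.a_m, p.c_m, p.e_m, p.a_f, p.c_f, p.e_f, _r_to_z(p.r_gos), p.mu_mzm, p.mu_dzm, p.mu_mzf, p.mu_dzf]
        )

    return _ModelSpec("ace_sexlim", 11, unpack, pack, frozenset({"saturated"}))


def _equal_sexes_spec() -> _ModelSpec:
    def unpack(x: np.ndarray) -> SexLimParams:
        return SexLimParams(x[0], x[1], x[2], x[0], x[1], x[2], 0.5, x[3], x[4], x[5], x[6])

    def pack(p: SexLimParams) -> np.ndarray:
        return np.array([p.a_m, p.c_m, p.e_m, p.mu_mzm, p.mu_dzm, p.mu_mzf, p.mu_dzf])

    return _ModelSpec("equal_sexes", 7, unpack, pack, frozenset({"saturated", "ace_sexlim", "scale"}))


def _scale_spec() -> _ModelSpec:
    # Female paths are a common multiple of the male paths: the standardized
    # proportions are equal across sexes while total variances may differ.
    def unpack(x: np.ndarray) -> SexLimParams:
        k = math.exp(x[3])
        return SexLimParams(x[0], x[1], x[2], k * x[0], k * x[1], k * x[2], _z_to_r(x[4]), x[5], x[6], x[7], x[8])

    def pack(p: SexLimParams) -> np.ndarray:
        vm = math.sqrt(max(p.variance("M"), 1e-12))
        vf = math.sqrt(max(p.variance("F"), 1e-12))
        return np.array(
            [p.a_m, p.c_m, p.e_m, math.log(vf / vm), _r_to_z(p.r_gos), p.mu_mzm, p.mu_dzm, p.mu_mzf, p.mu_dzf]
        )

    return _ModelSpec("scale", 9, unpack, pack, frozenset({"saturated", "ace_sexlim"}))


def _drop_c_spec() -> _ModelSpec:
    def unpack(x: np.ndarray) -> SexLimParams:
        return SexLimParams(x[0], 0.0, x[1], x[2], 0.0, x[3], _z_to_r(x[4]), x[5], x[6], x[7], x[8])

    def pack(p: SexLimParams) -> np.ndarray:
        return np.array([p.a_m, p.e_m, p.a_f, p.e_f, _r_to_z(p.r_gos), p.mu_mzm, p.mu_dzm, p.mu_mzf, p.mu_dzf])

    return _ModelSpec("drop_C", 9, unpack, pack, frozenset({"saturated", "ace_sexlim"}))


def _drop_a_spec() -> _ModelSpec:
    # With a = 0 the OS genetic correlation is unidentified; it is fixed at 0.5.
    def unpack(x: np.ndarray) -> SexLimParams:
        return SexLimParams(0.0, x[0], x[1], 0.0, x[2], x[3], 0.5, x[4], x[5], x[6], x[7])

    def pack(p: SexLimParams) -> np.ndarray:
        return np.array([p.c_m, p.e_m, p.c_f, p.e_f, p.mu_mzm, p.mu_dzm, p.mu_mzf, p.mu_dzf])

    return _ModelSpec("drop_A", 8, unpack, pack, frozenset({"saturated", "ace_sexlim"}))


_SPECS: dict[str, Callable[[], _ModelSpec]] = {
    "ace_sexlim": _full_spec,
    "equal_sexes": _equal_sexes_spec,
    "scale": _scale_spec,
    "drop_C": _drop_c_spec,
    "drop_A": _drop_a_spec,
}


# ---------------------------------------------------------------------------
# Closed-form starting values
# ---------------------------------------------------------------------------


def falconer(r_mz: float, r_dz: float) -> tuple[float, float, float]:
    """Falconer's closed-form component estimates from twin correlations.

    a2 = 2 (rMZ - rDZ), c2 = 2 rDZ - rMZ, e2 = 1 - rMZ, each clipped to
    [0, 1].  Used for starting values and as an independent cross-check of
    the maximum-likelihood fit on balanced data with no sex differences.
    """
    a2 = min(max(2.0 * (r_mz - r_dz), 0.0), 1.0)
    c2 = min(max(2.0 * r_dz - r_mz, 0.0), 1.0)
    e2 = min(max(1.0 - r_mz, 0.0), 1.0)
    return a2, c2, e2


def _stats_corr(gs: GroupStats) -> float:
    s = gs.scatter
    denom = math.sqrt(max(s[0, 0] * s[1, 1], 1e-300))
    return float(np.clip(s[0, 1] / denom, -0.99, 0.99))


def _falconer_start(stats_by_group: Mapping[str, GroupStats]) -> SexLimParams:
    """Falconer-based starting point from the observed group moments."""

    def sex_start(mz: str, dz: str) -> tuple[float, float, float, float, float]:
        gmz = stats_by_group.get(mz)
        gdz = stats_by_group.get(dz)
        r_mz = _stats_corr(gmz) if gmz is not None and gmz.n > 2 else 0.6
        r_dz = _stats_corr(gdz) if gdz is not None and gdz.n > 2 else 0.4
        variances = [
            g.scatter[i, i] / max(g.n - 1, 1)
            for g in (gmz, gdz)
            if g is not None and g.n > 1
            for i in (0, 1)
        ]
        v = float(np.mean(variances)) if variances else 1.0
        a2, c2, e2 = falconer(r_mz, r_dz)
        # keep all three components away from zero for a usable interior start
        a2, c2, e2 = max(a2, 0.05), max(c2, 0.05), max(e2, 0.05)
        tot = a2 + c2 + e2
        a2, c2, e2 = a2 / tot, c2 / tot, e2 / tot
        mu_mz = float(gmz.ybar.mean()) if gmz is not None else 0.0
        mu_dz = float(gdz.ybar.mean()) if gdz is not None else 0.0
        return math.sqrt(a2 * v), math.sqrt(c2 * v), math.sqrt(e2 * v), mu_mz, mu_dz

    a_m, c_m, e_m, mu_mzm, mu_dzm = sex_start("MZM", "DZM")
    a_f, c_f, e_f, mu_mzf, mu_dzf = sex_start("MZF", "DZF")
    gos = stats_by_group.get("OS")
    if gos is not None:
        mu_dzm = 0.5 * (mu_dzm + float(gos.ybar[0]))
        mu_dzf = 0.5 * (mu_dzf + float(gos.ybar[1]))
    return SexLimParams(a_m, c_m, e_m, a_f, c_f, e_f, 0.5, mu_mzm, mu_dzm, mu_mzf, mu_dzf)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

_DEFAULT_N_RESTARTS = 4
_RESTART_SEED = 20160623  # fixed: restarts must not depend on caller randomness


def _minimize_spec(
    spec: _ModelSpec,
    stats_by_group: Mapping[str, GroupStats],
    x0: np.ndarray,
    n_restarts: int,
) -> tuple[np.ndarray, float, bool, str]:
    def fun(x: np.ndarray) -> float:
        return _neg2ll_stats(spec.unpack(x), stats_by_group)

    rng = np.random.default_rng(_RESTART_SEED)
    scale = np.maximum(np.abs(x0), 1.0)
    best_x, best_f, best_ok, msg = None, math.inf, False, ""
    for k in range(n_restarts + 1):
        xk = x0 if k == 0 else x0 + 0.15 * scale * rng.standard_normal(x0.shape)
        res = optimize.minimize(fun, xk, method="L-BFGS-B", options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-8})
        if res.fun < best_f:
            best_x, best_f, best_ok, msg = res.x, float(res.fun), bool(res.success), str(res.message)
        if best_ok and k >= 1:
            break  # converged optimum confirmed against at least one restart
    return best_x, best_f, best_ok, msg


def _fit(
    pairs: pd.DataFrame | Mapping[str, GroupStats],
    model: str,
    *,
    start: SexLimParams | None = None,
    n_restarts: int = _DEFAULT_N_RESTARTS,
) -> FitResult:
    stats_by_group = pairs if isinstance(pairs, Mapping) else group_stats(pairs)
    if not stats_by_group:
        raise DataError("no pairs to fit")
    spec = _SPECS[model]()
    p0 = start if start is not None else _falconer_start(stats_by_group)
    x0 = spec.pack(p0)
    x, f, ok, msg = _minimize_spec(spec, stats_by_group, x0, n_restarts)
    params = spec.unpack(x)
    # report non-negative paths: the likelihood depends only on squared paths
    params = replace(
        params,
        a_m=abs(params.a_m), c_m=abs(params.c_m), e_m=abs(params.e_m),
        a_f=abs(params.a_f), c_f=abs(params.c_f), e_f=abs(params.e_f),
    )
    return FitResult(
        model=model,
        params=params,
        minus2ll=f,
        n_free_params=spec.n_free,
        n_pairs={g: gs.n for g, gs in stats_by_group.items()},
        converged=ok and math.isfinite(f),
        standardized=StandardizedComponents.from_params(params),
        nests_in=spec.nests_in,
        message=msg,
        _x=x,
        _stats=dict(stats_by_group),
    )


def fit_ace_sexlim(
    pairs: pd.DataFrame | Mapping[str, GroupStats],
    *,
    start: SexLimParams | None = None,
    n_restarts: int = _DEFAULT_N_RESTARTS,
) -> FitResult:
    """Fit the full 11-parameter ACE sex-limitation model.

    Minimizes the exact sufficient-statistic -2LL by multi-start L-BFGS
    from a Falconer-based starting point plus jittered restarts (fixed
    restart seed).  Missing groups are tolerated: the corresponding
    parameters are then informed only by the remaining groups.
    """
    return _fit(pairs, "ace_sexlim", start=start, n_restarts=n_restarts)


def fit_submodel(
    pairs: pd.DataFrame | Mapping[str, GroupStats],
    constraint: str,
    *,
    start: SexLimParams | None = None,
    n_restarts: int = _DEFAULT_N_RESTARTS,
) -> FitResult:
    """Fit a nested submodel: 'equal_sexes', 'scale', 'drop_C' or 'drop_A'."""
    if constraint not in ("equal_sexes", "scale", "drop_C", "drop_A"):
        raise ConfigurationError(f"unknown constraint {constraint!r}")
    return _fit(pairs, constraint, start=start, n_restarts=n_restarts)


def fit_saturated(pairs: pd.DataFrame | Mapping[str, GroupStats]) -> FitResult:
    """Closed-form saturated model: free moments per zygosity-sex group.

    Within same-sex groups the mean and variance are equated across
    co-twins (within-pair order is arbitrary), leaving one mean, one
    variance and one covariance per group; the OS group has sex-specific
    means and variances plus a covariance.  With all five groups present
    this is 17 free parameters.  Estimates are the constrained maximum-
    likelihood moments (n denominator).
    """
    stats_by_group = pairs if isinstance(pairs, Mapping) else group_stats(pairs)
    if not stats_by_group:
        raise DataError("no pairs to fit")
    moments: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    n_free = 0
    total = 0.0
    identifiable = True
    for g, gs in stats_by_group.items():
        if g == "OS":
            mu = gs.ybar.copy()
            sig = gs.scatter / gs.n
            n_free += 5
        else:
            mu_hat = float(gs.ybar.mean())
            d = gs.ybar - mu_hat
            # ML under exchangeability: pooled mean, pooled variance, covariance
            v = 0.5 * (gs.scatter[0, 0] + gs.scatter[1, 1]) / gs.n + 0.5 * (d[0] ** 2 + d[1] ** 2)
            c = gs.scatter[0, 1] / gs.n + d[0] * d[1]
            mu = np.array([mu_hat, mu_hat])
            sig = np.array([[v, c], [c, v]])
            n_free += 3
        if gs.n < 2:
            identifiable = False
        moments[g] = (mu, sig)
        total += _neg2ll_group(mu, sig, gs)
    return FitResult(
        model="saturated",
        params=moments,
        minus2ll=total,
        n_free_params=n_free,
        n_pairs={g: gs.n for g, gs in stats_by_group.items()},
        converged=identifiable and math.isfinite(total),
        message="" if identifiable else "group with fewer than 2 pairs: saturated moments unidentifiable",
        _stats=dict(stats_by_group),
    )


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------


def lrt(full: FitResult, nested: FitResult) -> LRTResult:
    """Likelihood-ratio test of a nested fit against a fuller fit.

    Delta -2LL is clamped at zero (with a warning if meaningfully negative,
    which indicates an optimizer failure); p-value from the chi-square
    upper tail with df equal to the difference in free-parameter counts.
    """
    if full.model not in nested.nests_in and full.model != nested.model:
        raise ConfigurationError(f"model {nested.model!r} is not nested within {full.model!r}")
    delta_df = full.n_free_params - nested.n_free_params
    if full.model != nested.model and delta_df < 1:
        raise ConfigurationError("nested model must have fewer free parameters")
    delta = nested.minus2ll - full.minus2ll
    if delta < -1e-6:
        warnings.warn(
            f"nested model fit better than full ({delta:.3g}); clamping LRT statistic at 0",
            RuntimeWarning,
            stacklevel=2,
        )
    delta = max(delta, 0.0)
    p = 1.0 if delta_df == 0 else float(stats.chi2.sf(delta, delta_df))
    return LRTResult(delta_minus2ll=delta, delta_df=max(delta_df, 0), p_value=p)


def bonferroni(p_values: Sequence[float], m: int | None = None, alpha: float = 0.05) -> dict:
    """Bonferroni-corrected decisions: reject iff p <= alpha / m."""
    p = np.asarray(p_values, dtype=float)
    m_eff = int(m) if m is not None else p.size
    if m_eff < p.size:
        raise ConfigurationError(f"m={m_eff} smaller than number of p-values ({p.size})")
    threshold = alpha / m_eff
    return {"reject": p <= threshold, "threshold": threshold, "m": m_eff, "alpha": alpha}


# ---------------------------------------------------------------------------
# Profile-likelihood confidence intervals
# ---------------------------------------------------------------------------

_PROPORTIONS = ("h2_m", "c2_m", "e2_m", "h2_f", "c2_f", "e2_f")


def _quantity_value(p: SexLimParams, quantity: str) -> float:
    if quantity == "r_gos":
        return p.r_gos
    comp, sex = quantity.split("_")
    a, c, e = p.paths(sex.upper())
    v = a * a + c * c + e * e
    num = {"h2": a * a, "c2": c * c, "e2": e * e}[comp]
    return num / v


def _sigmoid(t: float) -> float:
    return 1.0 / (1.0 + math.exp(-t))


def _profiled_unpack(quantity: str, q: float) -> tuple[Callable[[np.ndarray], SexLimParams], int]:
    """Parameter map with the profiled quantity held fixed at ``q``.

    Proportions are profiled via (log total variance, split of the
    remaining 1-q between the two free components), which stays smooth at
    the q=0 boundary where a raw-path constraint gradient would vanish.
    """
    if quantity == "r_gos":

        def unpack(x: np.ndarray) -> SexLimParams:
            return SexLimParams(x[0], x[1], x[2], x[3], x[4], x[5], q, x[6], x[7], x[8], x[9])

        return unpack, 10

    comp, sex = quantity.split("_")
    order = {"h2": ("h2", "c2", "e2"), "c2": ("c2", "h2", "e2"), "e2": ("e2", "h2", "c2")}[comp]

    def unpack(x: np.ndarray) -> SexLimParams:
        v = math.exp(x[0])
        frac = _sigmoid(x[1])
        props = {order[0]: q, order[1]: (1.0 - q) * frac, order[2]: (1.0 - q) * (1.0 - frac)}
        a = math.sqrt(props["h2"] * v)
        c = math.sqrt(props["c2"] * v)
        e = math.sqrt(props["e2"] * v)
        r = _z_to_r(x[5])
        if sex == "m":
            return SexLimParams(a, c, e, x[2], x[3], x[4], r, x[6], x[7], x[8], x[9])
        return SexLimParams(x[2], x[3], x[4], a, c, e, r, x[6], x[7], x[8], x[9])

    return unpack, 10


def _profiled_start(fit: FitResult, quantity: str) -> np.ndarray:
    p: SexLimParams = fit.params
    mus = [p.mu_mzm, p.mu_dzm, p.mu_mzf, p.mu_dzf]
    if quantity == "r_gos":
        return np.array([p.a_m, p.c_m, p.e_m, p.a_f, p.c_f, p.e_f, *mus])
    comp, sex = quantity.split("_")
    s = sex.upper()
    a, c, e = p.paths(s)
    v = max(a * a + c * c + e * e, 1e-8)
    props = {"h2": a * a / v, "c2": c * c / v, "e2": e * e / v}
    order = {"h2": ("c2", "e2"), "c2": ("h2", "e2"), "e2": ("h2", "c2")}[comp]
    rest = props[order[0]] + props[order[1]]
    frac = props[order[0]] / rest if rest > 1e-10 else 0.5
    t = math.log(frac / (1.0 - frac)) if 0.0 < frac < 1.0 else 0.0
    other = p.paths("F" if s == "M" else "M")
    return np.array([math.log(v), t, *other, _r_to_z(p.r_gos), *mus])


def _profile_neg2ll(fit: FitResult, quantity: str, q: float, x_warm: np.ndarray) -> tuple[float, np.ndarray]:
    unpack, _ = _profiled_unpack(quantity, q)

    def fun(x: np.ndarray) -> float:
        return _neg2ll_stats(unpack(x), fit._stats)

    res = optimize.minimize(fun, x_warm, method="L-BFGS-B", options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-7})
    return float(res.fun), res.x


def profile_ci(fit: FitResult, quantity: str, level: float = 0.95) -> tuple[float, float]:
    """Profile-likelihood confidence interval for a standardized component.

    ``quantity`` is one of h2/c2/e2 per sex (e.g. ``'h2_m'``) or
    ``'r_gos'``.  The bound is where the profiled -2LL exceeds the
    minimum by the chi-square(1) quantile (3.841 at level 0.95), located
    by bisection with re-optimization of all nuisance parameters at each
    probe; intervals are truncated to [0, 1] for proportions and [-1, 1]
    for r_gOS.  Failure to bracket yields a one-sided interval with a
    warning.
    """
    if quantity not in _PROPORTIONS and quantity != "r_gos":
        raise ConfigurationError(f"unknown quantity {quantity!r}")
    if fit.model != "ace_sexlim":
        raise ConfigurationError("profile_ci expects a full ACE sex-limitation fit")
    if fit._stats is None:
        raise ConfigurationError("fit carries no data; refit before profiling")
    threshold = fit.minus2ll + float(stats.chi2.ppf(level, 1))
    lo_dom, hi_dom = (-1.0, 1.0) if quantity == "r_gos" else (0.0, 1.0)
    qhat = float(np.clip(_quantity_value(fit.params, quantity), lo_dom, hi_dom))

    warm0 = _profiled_start(fit, quantity)
    cache: dict[float, float] = {}

    def g(q: float, warm: list[np.ndarray]) -> float:
        if q not in cache:
            val, x = _profile_neg2ll(fit, quantity, q, warm[0])
            warm[0] = x
            cache[q] = max(val, fit.minus2ll) - threshold
        return cache[q]

    def find_bound(direction: int) -> float:
        edge = hi_dom if direction > 0 else lo_dom
        warm = [warm0.copy()]
        step = 0.02 * (hi_dom - lo_dom)
        prev = qhat
        q = qhat
        for _ in range(60):
            q = q + direction * step
            if (direction > 0 and q >= edge) or (direction < 0 and q <= edge):
                if g(edge, warm) <= 0.0:
                    return edge  # truncated at the domain boundary
                q = edge
                break
            if g(q, warm) > 0.0:
                break
            prev = q
            step *= 1.6
        else:  # pragma: no cover - defensive
            warnings.warn(f"profile for {quantity} failed to bracket; one-sided interval", RuntimeWarning)
            return edge
        lo, hi = (prev, q) if direction > 0 else (q, prev)
        warm2 = [warm[0].copy()]

        def h(qq: float) -> float:
            return g(qq, warm2)

        try:
            return float(optimize.brentq(h, lo, hi, xtol=1e-4))
        except ValueError:
            warnings.warn(f"profile for {quantity} failed to bracket; one-sided interval", RuntimeWarning)
            return edge

    lower = find_bound(-1)
    upper = find_bound(+1)
    return (min(lower, qhat), max(upper, qhat))
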