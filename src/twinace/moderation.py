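"""Gene-by-age moderation of twin variance components.

Instead of fitting one ACE model per one-year age group, the path
coefficients are modelled as quadratic functions of (centred) exact age,

    a(x) = a0 + a1*x + a2*x^2,   x = age - 10,

and likewise c(x), e(x), so raw A/C/E variances change smoothly with age
using far fewer parameters.  Means are zygosity-specific quadratics in
the same centred age (two polynomials of three coefficients), giving 15
free parameters per group: 9 path + 6 mean coefficients.  Only same-sex
pairs enter (the size of sex-specific genetic effects varies with age,
which an opposite-sex group would confound), and fits are run per sex,
optionally stratified by region, with equality constraints across groups
tested by likelihood ratio.

Because exact ages vary continuously, the likelihood is evaluated pair
by pair (vectorized): each pair contributes a bivariate-normal density
with its own age-dependent moments; the MZ within-pair covariance is
a(x)^2 + c(x)^2 and the DZ covariance 0.5*a(x)^2 + c(x)^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy import optimize

from .twinmodel import ConfigurationError, DataError, FitResult

__all__ = [
    "AGE_CENTER",
    "ModerationParams",
    "ModerationSpec",
    "moderated_moments",
    "fit_moderation",
    "count_free_params",
    "variance_curves",
]

AGE_CENTER = 10.0
_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class ModerationParams:
    """15 free parameters of one group's quadratic age-moderation model.

    Path coefficients (cm, cm/yr, cm/yr^2 on centred age) for a, c, e;
    mean polynomial coefficients separately for MZ and DZ pairs.
    """

    a0: float
    a1: float = 0.0
    a2: float = 0.0
    c0: float = 0.0
    c1: float = 0.0
    c2: float = 0.0
    e0: float = 1.0
    e1: float = 0.0
    e2: float = 0.0
    m_mz0: float = 0.0
    m_mz1: float = 0.0
    m_mz2: float = 0.0
    m_dz0: float = 0.0
    m_dz1: float = 0.0
    m_dz2: float = 0.0

    def path(self, which: str, age: float | np.ndarray) -> float | np.ndarray:
        x = np.asarray(age, dtype=float) - AGE_CENTER
        p0, p1, p2 = (getattr(self, f"{which}{i}") for i in range(3))
        return p0 + p1 * x + p2 * x * x

    def mean(self, zygosity: str, age: float | np.ndarray) -> float | np.ndarray:
        x = np.asarray(age, dtype=float) - AGE_CENTER
        pre = {"MZ": "m_mz", "DZ": "m_dz"}.get(zygosity)
        if pre is None:
            raise ConfigurationError(f"zygosity must be 'MZ' or 'DZ', got {zygosity!r}")
        p0, p1, p2 = (getattr(self, f"{pre}{i}") for i in range(3))
        return p0 + p1 * x + p2 * x * x

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)])

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "ModerationParams":
        return cls(*v)


def moderated_moments(
    age: float, zygosity: str, params: ModerationParams
) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied mean vector and covariance of a same-sex pair at one age.

    Requesting an opposite-sex group is a usage error: OS pairs are
    excluded from age-moderation analyses.
    """
    if zygosity in ("OS", "OSDZ"):
        raise ConfigurationError("moderation model is defined for same-sex pairs only")
    a = float(params.path("a", age))
    c = float(params.path("c", age))
    e = float(params.path("e", age))
    v = a * a + c * c + e * e
    cov = a * a + c * c if zygosity == "MZ" else 0.5 * a * a + c * c
    mu = float(params.mean(zygosity, age))
    return np.array([mu, mu]), np.array([[v, cov], [cov, v]])


# ---------------------------------------------------------------------------
# Model specification / degrees of freedom
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModerationSpec:
    """A moderation model layout: how many groups share how many parameters."""

    n_groups: int = 1
    equated: bool = False  # one parameter block shared by all groups
    path_order: str = "quadratic"  # 'quadratic' | 'linear' | 'constant'

    def __post_init__(self) -> None:
        if self.path_order not in ("quadratic", "linear", "constant"):
            raise ConfigurationError(f"unknown path_order {self.path_order!r}")
        if self.n_groups < 1:
            raise ConfigurationError("n_groups must be >= 1")

    @property
    def per_block(self) -> int:
        # constant: a0, c0, e0 + one mean per zygosity
        return {"quadratic": 15, "linear": 12, "constant": 5}[self.path_order]

    @property
    def n_blocks(self) -> int:
        return 1 if self.equated else self.n_groups

    def model_name(self) -> str:
        return f"moderation[g={self.n_groups},equated={self.equated},paths={self.path_order}]"

    def nests_in(self) -> frozenset:
        orders = ("constant", "linear", "quadratic")
        fuller = []
        for eq in (True, False):
            for po in orders[orders.index(self.path_order):]:
                s = ModerationSpec(self.n_groups, eq, po)
                if s.n_free > self.n_free or s == self:
                    fuller.append(s.model_name())
        return frozenset(fuller) - {self.model_name()}

    @property
    def n_free(self) -> int:
        return self.n_blocks * self.per_block


def count_free_params(spec: ModerationSpec) -> int:
    """Free-parameter count of a moderation model spec.

    Differences between nested specs give the likelihood-ratio df: e.g.
    equating two sexes' full quadratic blocks costs 15 df, equating three
    regions' blocks 30 df, and dropping the three quadratic path terms of
    one block 3 df.
    """
    return spec.n_free


# ---------------------------------------------------------------------------
# Likelihood and fitting
# ---------------------------------------------------------------------------

_FREE_IDX = {
    "quadratic": list(range(15)),
    "linear": [0, 1, 3, 4, 6, 7, 9, 10, 11, 12, 13, 14],
    "constant": [0, 3, 6, 9, 12],
}


def _block_neg2ll(theta15: np.ndarray, x: np.ndarray, y1: np.ndarray, y2: np.ndarray, mz: np.ndarray) -> float:
    a = theta15[0] + theta15[1] * x + theta15[2] * x * x
    c = theta15[3] + theta15[4] * x + theta15[5] * x * x
    e = theta15[6] + theta15[7] * x + theta15[8] * x * x
    a2, c2, e2 = a * a, c * c, e * e
    v = a2 + c2 + e2
    cov = np.where(mz, a2 + c2, 0.5 * a2 + c2)
    det = v * v - cov * cov
    if not np.all(det > 1e-12):
        return math.inf
    mu = np.where(
        mz,
        theta15[9] + theta15[10] * x + theta15[11] * x * x,
        theta15[12] + theta15[13] * x + theta15[14] * x * x,
    )
    d1 = y1 - mu
    d2 = y2 - mu
    quad = (v * (d1 * d1 + d2 * d2) - 2.0 * cov * d1 * d2) / det
    return float(np.sum(2.0 * _LOG_2PI + np.log(det) + quad))


def _block_start(x: np.ndarray, y1: np.ndarray, y2: np.ndarray, mz: np.ndarray) -> np.ndarray:
    theta = np.zeros(15)
    for pre, mask in ((9, mz), (12, ~mz)):
        if mask.sum() >= 6:
            xs = np.r_[x[mask], x[mask]]
            ys = np.r_[y1[mask], y2[mask]]
            coef = np.polyfit(xs, ys, 2)  # highest power first
            theta[pre: pre + 3] = coef[::-1]
        else:
            theta[pre] = float(np.mean(np.r_[y1[mask], y2[mask]])) if mask.any() else 0.0
    mu_hat = np.where(mz, theta[9] + theta[10] * x + theta[11] * x * x, theta[12] + theta[13] * x + theta[14] * x * x)
    resid = np.r_[y1 - mu_hat, y2 - mu_hat]
    v = max(float(np.var(resid)), 1e-3)
    theta[0] = math.sqrt(0.5 * v)
    theta[3] = math.sqrt(0.3 * v)
    theta[6] = math.sqrt(0.2 * v)
    return theta


def _fit_block(
    pairs: pd.DataFrame, path_order: str, n_restarts: int = 2
) -> tuple[ModerationParams, float, bool]:
    x = pairs["age"].to_numpy(dtype=float) - AGE_CENTER
    y1 = pairs["y1"].to_numpy(dtype=float)
    y2 = pairs["y2"].to_numpy(dtype=float)
    mz = pairs["group"].str.startswith("MZ").to_numpy()
    free = _FREE_IDX[path_order]
    theta0 = _block_start(x, y1, y2, mz)

    def fun(xfree: np.ndarray) -> float:
        theta = np.zeros(15)  # fixed entries of lower-order models are zero
        theta[free] = xfree
        return _block_neg2ll(theta, x, y1, y2, mz)

    rng = np.random.default_rng(47)
    best = None
    x0 = theta0[free]
    scale = np.maximum(np.abs(x0), 0.5)
    for k in range(n_restarts + 1):
        xk = x0 if k == 0 else x0 + 0.1 * scale * rng.standard_normal(x0.shape)
        res = optimize.minimize(fun, xk, method="L-BFGS-B", options={"maxiter": 3000, "ftol": 1e-11, "gtol": 1e-7})
        if best is None or res.fun < best.fun:
            best = res
        if best.success and k >= 1:
            break
    theta = np.zeros(15)
    theta[free] = best.x
    # sign convention: report non-negative intercepts (likelihood is sign-invariant per path)
    for base in (0, 3, 6):
        if theta[base] < 0:
            theta[base: base + 3] *= -1.0
    return ModerationParams.from_vector(theta), float(best.fun), bool(best.success)


def fit_moderation(
    pairs: pd.DataFrame,
    grouping: str = "sex",
    equated: bool = False,
    path_order: str = "quadratic",
    n_restarts: int = 2,
) -> FitResult:
    """Joint ML fit of the age-moderation model over one or more groups.

    ``grouping``: 'pooled' (one block for all same-sex pairs), 'sex'
    (one block per sex) or 'sex_region' (one block per sex x region).
    ``equated=True`` shares a single parameter block across the groups
    (fitted to the stacked data), which is the nested model of the
    group-equality likelihood-ratio test.  ``path_order='linear'`` fixes
    the quadratic path terms at zero; 'constant' also fixes the linear
    terms and all mean slopes (the age-homogeneous model).  Because the
    groups share no parameters unless equated, the joint ML decomposes
    into independent per-block fits whose -2LL values add.
    """
    if "OS" in set(pairs["group"]):
        raise ConfigurationError("moderation accepts same-sex pairs only; drop OS pairs first")
    if pairs.empty:
        raise DataError("no pairs to fit")
    if grouping == "pooled":
        blocks = {"all": pairs}
    elif grouping == "sex":
        blocks = {str(s): sub for s, sub in pairs.groupby("sex", observed=True)}
    elif grouping == "sex_region":
        blocks = {f"{s}/{r}": sub for (s, r), sub in pairs.groupby(["sex", "region"], observed=True)}
    else:
        raise ConfigurationError(f"unknown grouping {grouping!r}")
    spec = ModerationSpec(n_groups=len(blocks), equated=equated, path_order=path_order)
    if equated:
        fit_sets = {"+".join(blocks): pairs}
    else:
        fit_sets = blocks
    params: dict[str, ModerationParams] = {}
    total = 0.0
    ok = True
    for name, sub in fit_sets.items():
        p, m2ll, conv = _fit_block(sub, path_order, n_restarts=n_restarts)
        params[name] = p
        total += m2ll
        ok = ok and conv
    return FitResult(
        model=spec.model_name(),
        params=params if len(params) > 1 else next(iter(params.values())),
        minus2ll=total,
        n_free_params=spec.n_free,
        n_pairs={name: len(sub) for name, sub in blocks.items()},
        converged=ok,
        nests_in=spec.nests_in(),
    )


def variance_curves(params: ModerationParams, ages: np.ndarray | None = None) -> pd.DataFrame:
    """Raw A/C/E variances per age, plus the age of maximum A variance.

    Variances are squared path values, hence non-negative by construction.
    The A-variance peak is located by a 0.01-year grid search over the
    age range (attached as ``DataFrame.attrs['a_peak_age']``).
    """
    if ages is None:
        ages = np.arange(1, 20)
    ages = np.asarray(ages, dtype=float)
    out = pd.DataFrame(
        {
            "age": ages,
            "A_var": np.asarray(params.path("a", ages)) ** 2,
            "C_var": np.asarray(params.path("c", ages)) ** 2,
            "E_var": np.asarray(params.path("e", ages)) ** 2,
        }
    )
    grid = np.arange(ages.min(), ages.max() + 1e-9, 0.01)
    a_var = np.asarray(params.path("a", grid)) ** 2
    out.attrs["a_peak_age"] = float(grid[np.argmax(a_var)])
    return out
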