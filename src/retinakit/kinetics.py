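"""Cone-survival quantification and degeneration kinetics.

Cone densities (cones per 100 µm of outer-nuclear-layer length, measured at
fixed retinal eccentricities) are aggregated per arm and age, fitted with an
exponential decay parametrised log2-linearly,

    density(t) = 2^(a - b t)   <=>   log2 density = a - b t,

by ordinary least squares, and extrapolated to the day the fitted curve
crosses a density threshold θ (default 1 cone/100 µm, i.e. log2 = 0):
x_intercept = (a - log2 θ)/b.  The separation between arms is the difference
of their x-intercepts.

Treatment effects on per-animal log2 survival ratios are quantified by
Hedges' g against a shared control group, with BCa bootstrap confidence
intervals and an unpaired two-sided permutation-t p value
(:func:`shared_control_estimation`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DecayFit",
    "EffectSizeResult",
    "aggregate",
    "fit_decay",
    "intercept_delay",
    "survival_ratio",
    "hedges_g",
    "shared_control_estimation",
]


@dataclass(frozen=True)
class DecayFit:
    """Log2-linear decay fit for one arm, with x-intercept extrapolation."""

    arm: str
    a: float  # log2 density at day 0
    b: float  # decay slope, log2 units/day (> 0 when declining)
    theta: float  # density threshold defining the x-intercept
    x_intercept: float  # day where fitted density = theta; NaN when b <= 0
    r2: float
    n_ages: int

    @property
    def intercept_defined(self) -> bool:
        return np.isfinite(self.x_intercept)

    def predict_density(self, age) -> np.ndarray:
        return 2.0 ** (self.a - self.b * np.asarray(age, dtype=float))


@dataclass(frozen=True)
class EffectSizeResult:
    """Hedges' g vs a shared control with bootstrap CI and permutation p."""

    comparison_label: str
    hedges_g: float
    ci_low: float
    ci_high: float
    n_boot: int
    p_perm: float
    ci_method: str = "bca"


def aggregate(records: pd.DataFrame) -> pd.DataFrame:
    """Mean density ± SEM per (arm, age) over the flat list of measurements.

    All positions from all animals at a stage enter the mean with equal
    weight.  SEM at n = 1 is reported as 0 with a warning.
    """
    if len(records) == 0:
        raise ValueError("records must be nonempty")
    out = []
    for (arm, age), sub in records.groupby(["arm", "age_pn"], sort=True):
        dens = sub["cones_per_100um"].to_numpy(dtype=float)
        n = len(dens)
        if n == 1:
            warnings.warn(f"single measurement at (arm={arm}, age={age}); SEM set to 0", stacklevel=2)
            sem = 0.0
        else:
            sem = float(np.std(dens, ddof=1) / np.sqrt(n))
        out.append((arm, float(age), float(np.mean(dens)), sem, n))
    return pd.DataFrame(out, columns=["arm", "age_pn", "mean_density", "sem", "n"])


def fit_decay(series: pd.DataFrame, arm: str, theta: float = 1.0) -> DecayFit:
    """OLS fit of log2(mean density) on age for one arm; x-intercept at θ.

    Ages with nonpositive mean density are excluded with a warning; a
    non-declining fit (b <= 0) flags the intercept as undefined rather than
    raising.
    """
    sub = series[series["arm"] == arm]
    if len(sub) == 0:
        raise ValueError(f"no data for arm {arm!r}")
    ages = sub["age_pn"].to_numpy(dtype=float)
    dens = sub["mean_density"].to_numpy(dtype=float)
    ok = dens > 0
    if not ok.all():
        warnings.warn(f"excluding {np.sum(~ok)} age(s) with nonpositive mean density", stacklevel=2)
    ages, dens = ages[ok], dens[ok]
    if len(np.unique(ages)) < 2:
        raise ValueError("need >= 2 distinct ages with positive mean density")
    res = stats.linregress(ages, np.log2(dens))
    a = float(res.intercept)
    b = float(-res.slope)
    if b > 0:
        x_int = (a - np.log2(theta)) / b
    else:
        x_int = float("nan")
    return DecayFit(
        arm=arm, a=a, b=b, theta=theta, x_intercept=float(x_int), r2=float(res.rvalue**2), n_ages=len(ages)
    )


def intercept_delay(fit_1: DecayFit, fit_2: DecayFit, signed: bool = False) -> float:
    """Separation in days between two x-intercepts (|x2 − x1|, or signed)."""
    if not (fit_1.intercept_defined and fit_2.intercept_defined):
        raise ValueError("both fits must have a defined x-intercept")
    d = fit_2.x_intercept - fit_1.x_intercept
    return float(d if signed else abs(d))


def survival_ratio(records: pd.DataFrame) -> pd.DataFrame:
    """Per-animal log2(treated density / control density) by age.

    Densities are first averaged over positions (and eyes) within each arm
    of the animal; animals lacking either arm are skipped, and a zero
    control density flags the ratio as undefined (NaN).
    """
    rows = []
    for (animal, age), sub in records.groupby(["animal_id", "age_pn"], sort=True):
        arms = sub.groupby("arm")["cones_per_100um"].mean()
        if not {"treated", "control"}.issubset(arms.index):
            continue
        c = float(arms["control"])
        t = float(arms["treated"])
        if c == 0:
            warnings.warn(f"zero control density for animal {animal}; ratio undefined", stacklevel=2)
            rows.append((animal, float(age), float("nan")))
        else:
            rows.append((animal, float(age), float(np.log2(t / c))))
    if not rows:
        raise ValueError("no animal carries both arms")
    return pd.DataFrame(rows, columns=["animal_id", "age_pn", "log2_ratio"])


def _hedges_j(df: int) -> float:
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def hedges_g(group_a, group_b) -> float:
    """Small-sample-corrected standardized mean difference (b minus a).

    g = J · (mean_b − mean_a)/s_pooled with J = 1 − 3/(4(n_a+n_b−2) − 1).
    Degenerate pooled SD yields 0 for equal means, signed infinity otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / df
    diff = float(np.mean(b) - np.mean(a))
    if sp2 == 0.0:
        return 0.0 if diff == 0.0 else float(np.sign(diff)) * np.inf
    return float(_hedges_j(df) * diff / np.sqrt(sp2))


def _hedges_g_rows(a_mat: np.ndarray, b_mat: np.ndarray) -> np.ndarray:
    """Row-wise Hedges' g for bootstrap matrices (rows = resamples)."""
    na, nb = a_mat.shape[1], b_mat.shape[1]
    df = na + nb - 2
    va = np.var(a_mat, axis=1, ddof=1)
    vb = np.var(b_mat, axis=1, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    diff = b_mat.mean(axis=1) - a_mat.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = _hedges_j(df) * diff / np.sqrt(sp2)
    g[sp2 == 0] = np.where(diff[sp2 == 0] == 0, 0.0, np.sign(diff[sp2 == 0]) * np.inf)
    return g


def _unpaired_t_rows(a_mat: np.ndarray, b_mat: np.ndarray) -> np.ndarray:
    na, nb = a_mat.shape[1], b_mat.shape[1]
    df = na + nb - 2
    sp2 = ((na - 1) * np.var(a_mat, axis=1, ddof=1) + (nb - 1) * np.var(b_mat, axis=1, ddof=1)) / df
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    diff = b_mat.mean(axis=1) - a_mat.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    t[denom == 0] = np.where(diff[denom == 0] == 0, 0.0, np.sign(diff[denom == 0]) * np.inf)
    return t


def _bca_interval(boot: np.ndarray, point: float, jack: np.ndarray, alpha: float):
    """BCa bootstrap CI; falls back to percentile when bias/acceleration degenerate."""
    boot = boot[np.isfinite(boot)]
    if len(boot) == 0:
        return float("nan"), float("nan"), "percentile"
    prop = np.mean(boot < point)
    jm = jack.mean()
    num = np.sum((jm - jack) ** 3)
    den = 6.0 * np.sum((jm - jack) ** 2) ** 1.5
    if prop in (0.0, 1.0) or den == 0.0 or not np.isfinite(point):
        lo, hi = np.quantile(boot, [alpha / 2, 1 - alpha / 2])
        return float(lo), float(hi), "percentile"
    z0 = stats.norm.ppf(prop)
    acc = num / den
    z = stats.norm.ppf([alpha / 2, 1 - alpha / 2])
    adj = stats.norm.cdf(z0 + (z0 + z) / (1 - acc * (z0 + z)))
    lo, hi = np.quantile(boot, adj)
    return float(lo), float(hi), "bca"


def _jackknife_g(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    vals = []
    for i in range(len(a)):
        vals.append(hedges_g(np.delete(a, i), b))
    for j in range(len(b)):
        vals.append(hedges_g(a, np.delete(b, j)))
    return np.asarray(vals)


def shared_control_estimation(
    shared_control,
    test_groups: dict,
    n_boot: int = 5000,
    n_perm: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
) -> list[EffectSizeResult]:
    """Shared-control estimation: Hedges' g per test group vs one control.

    Each group is compared to the common control: the point estimate is
    Hedges' g; the CI comes from ``n_boot`` resamples (both groups resampled
    with replacement, BCa-corrected, percentile fallback); the p value from
    ``n_perm`` label permutations of the unpaired t statistic, two-sided,
    with (b+1)/(n_perm+1) smoothing.
    """
    ctrl = np.asarray(shared_control, dtype=float)
    if len(ctrl) < 2:
        raise ValueError("shared control needs >= 2 values")
    results = []
    for g_idx, (label, values) in enumerate(test_groups.items()):
        grp = np.asarray(values, dtype=float)
        if len(grp) < 2:
            raise ValueError(f"group {label!r} needs >= 2 values")
        rng = np.random.Generator(
            np.random.Philox(np.random.SeedSequence(entropy=seed, spawn_key=(g_idx,)))
        )
        point = hedges_g(ctrl, grp)

        idx_a = rng.integers(0, len(ctrl), size=(n_boot, len(ctrl)))
        idx_b = rng.integers(0, len(grp), size=(n_boot, len(grp)))
        boot = _hedges_g_rows(ctrl[idx_a], grp[idx_b])
        lo, hi, method = _bca_interval(boot, point, _jackknife_g(ctrl, grp), alpha)

        pooled = np.concatenate([ctrl, grp])
        t_obs = abs(_unpaired_t_rows(ctrl[None, :], grp[None, :])[0])
        perm_idx = np.array([rng.permutation(len(pooled)) for _ in range(n_perm)])
        perm_a = pooled[perm_idx[:, : len(ctrl)]]
        perm_b = pooled[perm_idx[:, len(ctrl):]]
        t_perm = np.abs(_unpaired_t_rows(perm_a, perm_b))
        b_count = int(np.sum(t_perm >= t_obs - 1e-12))
        p_perm = (b_count + 1) / (n_perm + 1)

        results.append(
            EffectSizeResult(
                comparison_label=label,
                hedges_g=point,
                ci_low=lo,
                ci_high=hi,
                n_boot=n_boot,
                p_perm=float(p_perm),
                ci_method=method,
            )
        )
    return results
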