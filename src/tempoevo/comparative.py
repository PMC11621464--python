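"""Phylogenetic comparative inference on species tempo traits.

From per-recording rhythm metrics to the three study-level results:

1. *Species tip values* — a linear mixed model per trait (species as
   cell-means fixed effects, colony of origin as a random intercept, REML)
   whose species coefficients become the single per-species value placed at
   the chronogram tips.
2. *Evolutionary rates* — the Brownian-motion rate sigma^2 fit by maximum
   likelihood on mean-standardized tip values, compared between colony and
   individual level by bootstrap resampling of the underlying recordings.
3. *Correlated evolution and disparity* — phylogenetic generalized least
   squares between trait pairs (with an intraspecific-variation sensitivity
   variant), and the sum-of-variances disparity of the two-trait phenospace
   compared between levels by bootstrap.

p-values from bootstrap comparisons are one-sided with a 1/n_boot floor, so
10,000 replicates and zero exceedances report 0.0001.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular
from scipy.optimize import minimize_scalar

from .phylo import Chronogram

__all__ = [
    "BMFit",
    "PGLSFit",
    "RateComparisonResult",
    "SensitivityPGLSResult",
    "DisparityResult",
    "species_tip_values",
    "standardize_traits",
    "fit_bm",
    "bootstrap_rate_comparison",
    "pgls",
    "sensitivity_pgls",
    "disparity_comparison",
    "lme_species_test",
    "summarize_draws",
]


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BMFit:
    """Maximum-likelihood Brownian-motion fit: x ~ N(root * 1, sigma2 * C)."""

    sigma2: float
    root_state: float
    log_likelihood: float
    n: int


@dataclass(frozen=True)
class PGLSFit:
    """Phylogenetic GLS regression of y on x with BM error covariance."""

    slope: float
    intercept: float
    t_statistic: float
    p_value: float
    df: int
    slope_se: float


@dataclass(frozen=True)
class RateComparisonResult:
    """Bootstrap comparison of colony vs individual evolutionary rates."""

    trait: str
    observed_colony: float
    observed_individual: float
    observed_difference: float
    sigma2_colony_draws: np.ndarray
    sigma2_individual_draws: np.ndarray
    p_value: float
    n_boot: int
    seed: int | None

    @property
    def difference_draws(self) -> np.ndarray:
        return self.sigma2_colony_draws - self.sigma2_individual_draws


@dataclass(frozen=True)
class SensitivityPGLSResult:
    """PGLS refit under intraspecific redraws of both variables."""

    slopes: np.ndarray
    t_statistics: np.ndarray
    p_values: np.ndarray
    n_iter: int
    seed: int | None

    @property
    def median_p(self) -> float:
        return float(np.median(self.p_values))

    @property
    def median_slope(self) -> float:
        return float(np.median(self.slopes))


@dataclass(frozen=True)
class DisparityResult:
    """Sum-of-variances disparity of the two-level phenospaces."""

    sum_of_variances_colony: float
    sum_of_variances_individual: float
    colony_draws: np.ndarray
    individual_draws: np.ndarray
    p_value: float
    n_boot: int
    seed: int | None


def summarize_draws(draws: np.ndarray) -> dict[str, float]:
    """Median and 95% interval (2.5/97.5 percentiles) of a bootstrap sample."""
    lo, med, hi = np.percentile(draws, [2.5, 50, 97.5])
    return {"median": float(med), "ci_low": float(lo), "ci_high": float(hi)}


# ---------------------------------------------------------------------------
# species tip values (mixed model)
# ---------------------------------------------------------------------------

def _profile_reml_tips(
    group_n: np.ndarray,
    group_mean: np.ndarray,
    group_ss: np.ndarray,
    group_species: np.ndarray,
    n_species: int,
) -> np.ndarray:
    """Species cell means under a profiled-REML random-intercept model.

    The model is y = mu_species + b_group + e with b ~ N(0, lambda sigma_e^2).
    For fixed variance ratio lambda the GLS species estimate is the
    weight-w_g = n_g / (1 + lambda n_g) average of group means; the REML
    criterion is profiled down to a 1-D search over log lambda. With one
    observation per group (or no residual degrees of freedom) the criterion
    is flat in lambda and the estimate reduces to the plain species mean.
    """
    N = int(group_n.sum())
    p = n_species
    total_ss = float(group_ss.sum())

    def tips_for(lam: float) -> tuple[np.ndarray, float]:
        w = group_n / (1.0 + lam * group_n)
        wsum = np.bincount(group_species, weights=w, minlength=p)
        mu = np.bincount(group_species, weights=w * group_mean, minlength=p) / wsum
        d = group_mean - mu[group_species]
        q = total_ss + float((w * d * d).sum())
        return mu, q

    if N <= p or bool((group_n == 1).all()):
        mu, _ = tips_for(0.0)
        return mu

    def criterion(log_lam: float) -> float:
        lam = math.exp(log_lam)
        w = group_n / (1.0 + lam * group_n)
        wsum = np.bincount(group_species, weights=w, minlength=p)
        mu = np.bincount(group_species, weights=w * group_mean, minlength=p) / wsum
        d = group_mean - mu[group_species]
        q = total_ss + float((w * d * d).sum())
        sigma_e2 = max(q / (N - p), 1e-300)
        return (
            (N - p) * math.log(sigma_e2)
            + float(np.log1p(lam * group_n).sum())
            + float(np.log(wsum).sum())
        )

    res = minimize_scalar(criterion, bounds=(-12.0, 12.0), method="bounded",
                          options={"xatol": 1e-8})
    best_lam = math.exp(res.x)
    # compare against the lambda -> 0 boundary (no colony variance)
    if criterion(-30.0) < res.fun:
        best_lam = 0.0
    mu, _ = tips_for(best_lam)
    return mu


def _group_stats(values: np.ndarray, groups: np.ndarray, species: np.ndarray):
    """Per-group (n, mean, within-SS) with the species index of each group."""
    df = pd.DataFrame({"v": values, "g": groups, "s": species})
    agg = df.groupby("g", sort=True).agg(
        n=("v", "size"), mean=("v", "mean"), ss=("v", lambda x: ((x - x.mean()) ** 2).sum()),
        s=("s", "first"),
    )
    return (
        agg["n"].to_numpy(dtype=float),
        agg["mean"].to_numpy(dtype=float),
        agg["ss"].to_numpy(dtype=float),
        agg["s"].to_numpy(),
    )


def species_tip_values(
    metrics: pd.DataFrame,
    traits: Sequence[str] | None = None,
    species_col: str = "species",
    group_col: str = "colony_id",
) -> pd.DataFrame:
    """Per-species tip values for each trait via the random-intercept LME.

    ``metrics`` holds one row per recording with a species column, a
    grouping column (the colony, or colony of origin for isolated
    individuals) and one column per trait. Species entirely missing a trait
    get NaN there, with a warning. Returns a DataFrame indexed by species.
    """
    if traits is None:
        reserved = {species_col, group_col, "individual_id", "series_id", "level"}
        traits = [c for c in metrics.columns
                  if c not in reserved and pd.api.types.is_numeric_dtype(metrics[c])]
    if not traits:
        raise ValueError("no trait columns found")
    all_species = sorted(metrics[species_col].astype(str).unique())
    out = pd.DataFrame(index=pd.Index(all_species, name="species"),
                       columns=list(traits), dtype=float)
    for trait in traits:
        sub = metrics[[species_col, group_col, trait]].dropna(subset=[trait])
        present = sorted(sub[species_col].astype(str).unique())
        missing = sorted(set(all_species) - set(present))
        if missing:
            warnings.warn(f"trait {trait!r} missing for species {missing}",
                          stacklevel=2)
        sp_index = pd.Categorical(sub[species_col].astype(str),
                                  categories=present).codes
        n, mean, ss, sp = _group_stats(
            sub[trait].to_numpy(dtype=float),
            sub[group_col].astype(str).to_numpy(),
            sp_index,
        )
        tips = _profile_reml_tips(n, mean, ss, sp, len(present))
        out.loc[present, trait] = tips
    return out


def lme_species_test(
    metrics: pd.DataFrame,
    trait: str,
    species_col: str = "species",
    group_col: str = "colony_id",
) -> dict[str, float]:
    """Likelihood-ratio test of the species factor (descriptive only).

    Fits the random-intercept model with and without species fixed effects
    by ML (statsmodels MixedLM) and reports the chi-square LRT.
    """
    import statsmodels.formula.api as smf

    sub = metrics[[species_col, group_col, trait]].dropna().rename(
        columns={species_col: "species", group_col: "grp", trait: "y"}
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = smf.mixedlm("y ~ 0 + C(species)", sub, groups=sub["grp"]).fit(reml=False)
        null = smf.mixedlm("y ~ 1", sub, groups=sub["grp"]).fit(reml=False)
    lr = 2 * (full.llf - null.llf)
    df = sub["species"].nunique() - 1
    return {
        "lr_statistic": float(lr),
        "df": int(df),
        "p_value": float(stats.chi2.sf(max(lr, 0.0), df)),
    }


# ---------------------------------------------------------------------------
# trait standardization
# ---------------------------------------------------------------------------

def standardize_traits(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each trait column by its cross-species mean (mean becomes 1)."""
    out = table.copy()
    for col in out.columns:
        m = out[col].mean(skipna=True)
        if not np.isfinite(m) or m == 0:
            raise ValueError(f"trait {col!r} has zero or undefined mean")
        out[col] = out[col] / m
    return out


# ---------------------------------------------------------------------------
# Brownian-motion rate
# ---------------------------------------------------------------------------

class _BMSolver:
    """Precomputed Cholesky machinery for repeated BM fits on one tree."""

    def __init__(self, tree: Chronogram, order: Sequence[str]):
        C, self.order = tree.vcv(order=order)
        try:
            self.L = np.linalg.cholesky(C)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "phylogenetic covariance is singular (duplicate or zero-length tips?)"
            ) from exc
        self.n = C.shape[0]
        self.u = solve_triangular(self.L, np.ones(self.n), lower=True)
        self.uu = float(self.u @ self.u)
        self.logdet = 2.0 * float(np.log(np.diag(self.L)).sum())

    def fit(self, x: np.ndarray) -> BMFit:
        z = solve_triangular(self.L, x, lower=True)
        root = float(self.u @ z) / self.uu
        r = z - root * self.u
        sigma2 = float(r @ r) / self.n
        if sigma2 > 0:
            ll = -0.5 * (self.n * math.log(2 * math.pi * sigma2)
                         + self.logdet + self.n)
        else:
            ll = math.inf  # degenerate: all whitened residuals are zero
        return BMFit(sigma2=sigma2, root_state=root, log_likelihood=ll, n=self.n)

    def sigma2_many(self, X: np.ndarray) -> np.ndarray:
        """Vectorized sigma^2 for rows of X (replicates x species)."""
        Z = solve_triangular(self.L, X.T, lower=True)  # n x reps
        roots = (self.u @ Z) / self.uu
        R = Z - np.outer(self.u, roots)
        return (R * R).sum(axis=0) / self.n


def fit_bm(tree: Chronogram, tips: Mapping[str, float]) -> BMFit:
    """ML Brownian-motion rate and root state for tip values on a chronogram.

    The tree is pruned to the species present in ``tips``. The rate is the
    standard ML estimate sigma^2 = r' C^-1 r / n (biased by (n-1)/n relative
    to REML), matching the default behavior of the usual comparative tools.
    """
    species = sorted(tips)
    if len(species) < 2:
        raise ValueError("need tip values for at least 2 species")
    sub = tree if set(tree.taxa) == set(species) else tree.prune_to(species)
    solver = _BMSolver(sub, species)
    x = np.array([float(tips[s]) for s in species])
    if not np.all(np.isfinite(x)):
        raise ValueError("tip values must be finite")
    return solver.fit(x)


# ---------------------------------------------------------------------------
# bootstrap rate comparison
# ---------------------------------------------------------------------------

def _species_groups(
    records: pd.DataFrame,
    trait: str,
    unit_col: str,
    species: Sequence[str],
    species_col: str = "species",
    origin_col: str = "colony_id",
) -> list[list[tuple[str, np.ndarray]]]:
    """Per species, the list of resampling units as (origin, values) pairs.

    The resampling unit (a colony with all its recordings, or an isolated
    individual) keeps its colony-of-origin tag so the mixed model can be
    re-fit on each replicate.
    """
    out = []
    for sp in species:
        sub = records[records[species_col].astype(str) == sp]
        units = []
        for uid, g in sub.groupby(sub[unit_col].astype(str), sort=True):
            origin = str(g[origin_col].iloc[0]) if origin_col in g else str(uid)
            units.append((origin, g[trait].to_numpy(dtype=float)))
        if not units:
            raise ValueError(f"species {sp!r} has no records")
        out.append(units)
    return out


def _tips_once(groups: list[list[tuple[str, np.ndarray]]]) -> np.ndarray:
    """Tip values from resampling-unit groups via the profiled-REML model."""
    n_list, mean_list, ss_list, sp_list = [], [], [], []
    for j, units in enumerate(groups):
        merged: dict[str, list[np.ndarray]] = {}
        for origin, vals in units:
            merged.setdefault(origin, []).append(vals)
        for origin, chunks in merged.items():
            v = np.concatenate(chunks)
            n_list.append(v.size)
            mean_list.append(v.mean())
            ss_list.append(((v - v.mean()) ** 2).sum())
            sp_list.append(j)
    return _profile_reml_tips(
        np.array(n_list, dtype=float),
        np.array(mean_list),
        np.array(ss_list),
        np.array(sp_list),
        len(groups),
    )


def _bootstrap_sigma2(
    groups: list[list[tuple[str, np.ndarray]]],
    solver: _BMSolver,
    n_boot: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """sigma^2 draws: resample units within species, re-derive standardized tips."""
    n_sp = len(groups)
    singleton = all(v.size == 1 for units in groups for _, v in units)
    tips = np.empty((n_boot, n_sp))
    if singleton:
        # every unit contributes one value and the mixed model reduces to
        # the species mean, so the whole resampling loop vectorizes
        for j, units in enumerate(groups):
            v = np.array([vals[0] for _, vals in units])
            idx = rng.integers(0, v.size, size=(n_boot, v.size))
            tips[:, j] = v[idx].mean(axis=1)
    else:
        for b in range(n_boot):
            resampled = []
            for units in groups:
                k = len(units)
                idx = rng.integers(0, k, size=k)
                resampled.append([units[i] for i in idx])
            tips[b] = _tips_once(resampled)
    tips = tips / tips.mean(axis=1, keepdims=True)  # standardize per replicate
    return solver.sigma2_many(tips)


def bootstrap_rate_comparison(
    colony_records: pd.DataFrame,
    individual_records: pd.DataFrame,
    tree: Chronogram,
    trait: str,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> RateComparisonResult:
    """Bootstrap test of sigma^2(colony) > sigma^2(individual) for one trait.

    Per replicate, resampling units (colonies with all their recordings at
    colony level; isolated individuals at individual level) are drawn with
    replacement to original counts within each species, tip values are
    recomputed with the mixed model, traits re-standardized by their mean,
    and the BM rate re-fit at each level. The one-sided p-value is the
    proportion of replicates whose rate difference fails to exceed zero,
    floored at 1/n_boot.
    """
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives a very coarse p-value", stacklevel=2)
    species = sorted(set(colony_records["species"].astype(str)))
    sp_ind = set(individual_records["species"].astype(str))
    if sp_ind != set(species):
        raise ValueError(
            "colony and individual tables must cover the same species; "
            f"difference: {sorted(set(species) ^ sp_ind)}"
        )
    sub = tree if set(tree.taxa) == set(species) else tree.prune_to(species)
    solver = _BMSolver(sub, species)
    # identically seeded streams per level: two literally identical record
    # tables then produce identical resamples and a zero difference in
    # every replicate (the levels' values are independent data, so this
    # couples nothing when the tables differ)
    rng_c = np.random.default_rng(seed)
    rng_i = np.random.default_rng(seed)

    groups_c = _species_groups(colony_records, trait, "colony_id", species)
    ind_unit = ("individual_id" if "individual_id" in individual_records
                else "colony_id")
    groups_i = _species_groups(individual_records, trait, ind_unit, species)

    def observed_sigma2(groups):
        tips = _tips_once(groups)
        tips = tips / tips.mean()
        return solver.fit(tips).sigma2

    obs_c = observed_sigma2(groups_c)
    obs_i = observed_sigma2(groups_i)
    draws_c = _bootstrap_sigma2(groups_c, solver, n_boot, rng_c)
    draws_i = _bootstrap_sigma2(groups_i, solver, n_boot, rng_i)
    diff = draws_c - draws_i
    p = max(1, int((diff <= 0).sum())) / n_boot
    return RateComparisonResult(
        trait=trait,
        observed_colony=obs_c,
        observed_individual=obs_i,
        observed_difference=obs_c - obs_i,
        sigma2_colony_draws=draws_c,
        sigma2_individual_draws=draws_i,
        p_value=p,
        n_boot=n_boot,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------------

def _pgls_whitened(Xw: np.ndarray, yw: np.ndarray) -> tuple[float, float, float, float, int]:
    n = yw.size
    XtX = Xw.T @ Xw
    if np.linalg.cond(XtX) > 1e12:
        raise ValueError("singular design: predictor is (phylogenetically) constant")
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yw - Xw @ beta
    df = n - 2
    s2 = float(resid @ resid) / df
    cov = s2 * np.linalg.inv(XtX)
    se = math.sqrt(cov[1, 1])
    return float(beta[1]), float(beta[0]), se, s2, df


def pgls(tree: Chronogram, x: Mapping[str, float], y: Mapping[str, float]) -> PGLSFit:
    """GLS regression of y on x with error covariance proportional to C.

    Both sides are whitened by the Cholesky factor of C (Brownian-motion
    correlation) and fit by OLS; on a star tree with equal branch lengths
    this reduces exactly to ordinary least squares. The slope t-statistic is
    referred to Student's t with n - 2 degrees of freedom, two-sided.
    """
    common = sorted(set(x) & set(y))
    if len(common) < 3:
        raise ValueError("need x and y on at least 3 shared species")
    sub = tree if set(tree.taxa) == set(common) else tree.prune_to(common)
    solver = _BMSolver(sub, common)
    xv = np.array([float(x[s]) for s in common])
    yv = np.array([float(y[s]) for s in common])
    X = np.column_stack([np.ones_like(xv), xv])
    Xw = solve_triangular(solver.L, X, lower=True)
    yw = solve_triangular(solver.L, yv, lower=True)
    slope, intercept, se, _, df = _pgls_whitened(Xw, yw)
    t = slope / se
    p = 2 * stats.t.sf(abs(t), df)
    return PGLSFit(slope=slope, intercept=intercept, t_statistic=t,
                   p_value=float(p), df=df, slope_se=se)


def sensitivity_pgls(
    tree: Chronogram,
    x: Mapping[str, float],
    y: Mapping[str, float],
    x_sd: Mapping[str, float],
    y_sd: Mapping[str, float],
    n_iter: int = 10_000,
    seed: int | None = None,
) -> SensitivityPGLSResult:
    """PGLS under intraspecific uncertainty: redraw tips, refit, summarize.

    Per iteration each species' x and y are drawn from
    Normal(tip value, intraspecific SD) and the PGLS is refit; the
    headline summary is the median p across iterations (the full slope/t/p
    distributions are returned). Zero SDs reproduce the plain PGLS exactly.
    """
    common = sorted(set(x) & set(y))
    if len(common) < 3:
        raise ValueError("need x and y on at least 3 shared species")
    sd_x = np.array([float(x_sd.get(s, 0.0)) for s in common])
    sd_y = np.array([float(y_sd.get(s, 0.0)) for s in common])
    if (sd_x < 0).any() or (sd_y < 0).any():
        raise ValueError("intraspecific SDs must be >= 0")
    sub = tree if set(tree.taxa) == set(common) else tree.prune_to(common)
    solver = _BMSolver(sub, common)
    xv = np.array([float(x[s]) for s in common])
    yv = np.array([float(y[s]) for s in common])
    rng = np.random.default_rng(seed)
    Li = solver.L
    ones_w = solve_triangular(Li, np.ones(len(common)), lower=True)

    slopes = np.empty(n_iter)
    tstats = np.empty(n_iter)
    pvals = np.empty(n_iter)
    for i in range(n_iter):
        xi = xv + sd_x * rng.standard_normal(len(common))
        yi = yv + sd_y * rng.standard_normal(len(common))
        Xw = np.column_stack([ones_w, solve_triangular(Li, xi, lower=True)])
        yw = solve_triangular(Li, yi, lower=True)
        slope, _, se, _, df = _pgls_whitened(Xw, yw)
        t = slope / se
        slopes[i] = slope
        tstats[i] = t
        pvals[i] = 2 * stats.t.sf(abs(t), df)
    return SensitivityPGLSResult(slopes=slopes, t_statistics=tstats,
                                 p_values=pvals, n_iter=n_iter, seed=seed)


# ---------------------------------------------------------------------------
# disparity
# ---------------------------------------------------------------------------

def _as_points(points) -> np.ndarray:
    arr = points.to_numpy(dtype=float) if isinstance(points, pd.DataFrame) \
        else np.asarray(points, dtype=float)
    if arr.ndim != 2:
        raise ValueError("points must be a species x traits matrix")
    return arr


def sum_of_variances(points) -> float:
    """Disparity of a point cloud: sum over axes of the (n-1) variance."""
    arr = _as_points(points)
    return float(arr.var(axis=0, ddof=1).sum())


def disparity_comparison(
    colony_points,
    individual_points,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> DisparityResult:
    """Bootstrap comparison of phenospace disparity between the two levels.

    Axes are jointly standardized (z-score per axis, pooled over both
    levels) so rhythmicity and period contribute comparably; disparity is
    the sum of per-axis variances across species. Species rows are
    resampled with replacement independently within each level; the
    one-sided p-value is the proportion of replicates where colony
    disparity fails to exceed individual disparity, floored at 1/n_boot.
    """
    Pc = _as_points(colony_points)
    Pi = _as_points(individual_points)
    if Pc.shape != Pi.shape:
        raise ValueError("both levels need the same species x traits shape")
    if isinstance(colony_points, pd.DataFrame) and isinstance(individual_points, pd.DataFrame):
        if set(colony_points.index) != set(individual_points.index):
            raise ValueError("both levels must cover the same species")
    n = Pc.shape[0]
    if n < 3:
        raise ValueError("need at least 3 species")
    pooled = np.vstack([Pc, Pi])
    mu = pooled.mean(axis=0)
    sd = pooled.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0  # a constant axis contributes zero disparity either way
    Zc = (Pc - mu) / sd
    Zi = (Pi - mu) / sd

    rng = np.random.default_rng(seed)

    def boot(Z: np.ndarray) -> np.ndarray:
        idx = rng.integers(0, n, size=(n_boot, n))
        draws = Z[idx]  # n_boot x n x axes
        return draws.var(axis=1, ddof=1).sum(axis=1)

    draws_c = boot(Zc)
    draws_i = boot(Zi)
    p = max(1, int((draws_c <= draws_i).sum())) / n_boot
    return DisparityResult(
        sum_of_variances_colony=float(Zc.var(axis=0, ddof=1).sum()),
        sum_of_variances_individual=float(Zi.var(axis=0, ddof=1).sum()),
        colony_draws=draws_c,
        individual_draws=draws_i,
        p_value=p,
        n_boot=n_boot,
        seed=seed,
    )
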