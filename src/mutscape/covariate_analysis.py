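"""Correlations of DNM density with genomic covariates.

Windowed mutation density is correlated with genomic features
(recombination rates, replication timing, chromatin marks, nucleosome
occupancy, transcription, DNase hypersensitivity, GC content).  Because
the features are strongly inter-correlated, the module also provides
principal components of the standardized feature table, forward stepwise
regression with a p-to-enter rule, a quadratic-in-GC correction for
GC-dependent ascertainment, and a two-cohort slope-equality test for a
paternal-age effect on where mutations land.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)


@dataclass
class CovariateTable:
    """Per-window feature values keyed by (chrom, start, end).

    ``features`` is a numeric DataFrame with one row per window, already
    filtered for coverage (no missing values).
    """

    features: pd.DataFrame
    windows: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.features.isna().any().any():
            raise ValueError("features contain missing values; filter windows first")

    @property
    def feature_names(self) -> list:
        return list(self.features.columns)

    def __len__(self) -> int:
        return len(self.features)


def read_covariates(path) -> CovariateTable:
    """Wide TSV keyed by (chrom, start, end); remaining columns are features."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    keys = [c for c in ("chrom", "start", "end") if c in df.columns]
    return CovariateTable(features=df.drop(columns=keys).dropna(),
                          windows=df[keys] if keys else None)


def write_covariates(table: CovariateTable, path) -> None:
    df = table.features
    if table.windows is not None:
        df = pd.concat([table.windows.reset_index(drop=True),
                        df.reset_index(drop=True)], axis=1)
    df.to_csv(path, sep="\t", index=False)


def correlate_features(density, table: CovariateTable) -> pd.DataFrame:
    """Pearson r (and two-sided p via the t transform) of DNM density
    against each feature.  Constant features get NaN and a flag."""
    density = np.asarray(density, dtype=float)
    if density.size < 10:
        raise ValueError("need at least 10 windows")
    rows = []
    for name in table.feature_names:
        x = table.features[name].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            logger.warning("feature %s is constant; correlation undefined", name)
            rows.append({"feature": name, "r": np.nan, "p": np.nan, "constant": True})
            continue
        r, p = stats.pearsonr(density, x)
        rows.append({"feature": name, "r": float(r), "p": float(p), "constant": False})
    return pd.DataFrame(rows)


def feature_pca(table: CovariateTable, exclude=()) -> tuple:
    """PCA of the z-scored feature table.

    Returns (scores, loadings, variance_explained); loadings is a
    DataFrame (features x components).
    """
    names = [n for n in table.feature_names if n not in set(exclude)]
    if len(names) < 2:
        raise ValueError("need at least 2 features after exclusion")
    x = table.features[names].to_numpy(dtype=float)
    if x.shape[0] < len(names):
        raise ValueError("fewer windows than features")
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)
    pca = PCA()
    scores = pca.fit_transform(z)
    loadings = pd.DataFrame(
        pca.components_.T, index=names,
        columns=[f"PC{k + 1}" for k in range(pca.n_components_)])
    return scores, loadings, pca.explained_variance_ratio_


def stepwise_forward(density, table: CovariateTable,
                     p_enter: float = 0.05) -> tuple:
    """Forward stepwise OLS of DNM density on the features.

    At each step the candidate with the smallest partial-F p-value is
    added if p < p_enter (no removal step).  Exact ties break toward the
    lower feature index.  Both density and features are z-scored, so the
    returned coefficients are standardized.

    Returns (selected_names, {name: standardized beta}, r_squared).
    """
    y = np.asarray(density, dtype=float)
    names = table.feature_names
    if len(names) < 2:
        raise ValueError("need at least 2 candidate features")
    ys = (y - y.mean()) / y.std(ddof=0)
    zs = {}
    for n in names:
        x = table.features[n].to_numpy(dtype=float)
        zs[n] = (x - x.mean()) / x.std(ddof=0) if np.ptp(x) > 0 else None

    def rss(columns):
        X = sm.add_constant(np.column_stack([zs[m] for m in columns])
                            if columns else np.empty((ys.size, 0)))
        return float(sm.OLS(ys, X).fit().ssr)

    n_obs = ys.size
    selected: list = []
    rss_current = rss([])
    while True:
        best_name, best_p, best_rss = None, np.inf, None
        for n in names:
            if n in selected or zs[n] is None:
                continue
            rss_new = rss(selected + [n])
            df_resid = n_obs - len(selected) - 2
            if df_resid <= 0 or rss_new <= 0:
                continue
            # partial F for the single added regressor; exact collinearity
            # leaves the RSS unchanged and the candidate is never entered
            f = max(rss_current - rss_new, 0.0) / (rss_new / df_resid)
            p = float(stats.f.sf(f, 1, df_resid))
            if p < best_p:
                best_name, best_p, best_rss = n, p, rss_new
        if best_name is None or not (best_p < p_enter):
            break
        selected.append(best_name)
        rss_current = best_rss
    if not selected:
        return [], {}, 0.0
    X = sm.add_constant(np.column_stack([zs[m] for m in selected]))
    res = sm.OLS(ys, X).fit()
    coefs = {m: float(b) for m, b in zip(selected, res.params[1:])}
    return selected, coefs, float(res.rsquared)


def gc_quadratic_correction(density, gc) -> tuple:
    """Regress density on (GC, GC^2) and return (coefficients, residuals).

    The residuals strip a non-linear GC dependence (e.g. GC-dependent
    variant ascertainment) before correlating with other features.
    Coefficients are (intercept, linear, quadratic).
    """
    density = np.asarray(density, dtype=float)
    gc = np.asarray(gc, dtype=float)
    if np.ptp(gc) == 0:
        raise ValueError("gc is constant")
    X = np.column_stack([np.ones_like(gc), gc, gc ** 2])
    coef, *_ = np.linalg.lstsq(X, density, rcond=None)
    residuals = density - X @ coef
    return coef, residuals


@dataclass
class SlopeEqualityResult:
    slope_young: float
    se_young: float
    slope_old: float
    se_old: float
    p_equal: float


def paternal_age_slope_test(density_young, density_old, covariate) -> SlopeEqualityResult:
    """Test whether DNM density responds to a covariate differently in
    offspring of young vs old fathers.

    Each cohort's density is normalized to mean 1 (so cohort size drops
    out), regressed on the covariate, and the slope difference tested
    with the standard two-slope z statistic.
    """
    dy = np.asarray(density_young, dtype=float)
    do = np.asarray(density_old, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    if dy.sum() <= 0 or do.sum() <= 0:
        raise ValueError("a cohort has zero DNMs")
    ry = stats.linregress(cov, dy / dy.mean())
    ro = stats.linregress(cov, do / do.mean())
    z = (ry.slope - ro.slope) / np.hypot(ry.stderr, ro.stderr)
    return SlopeEqualityResult(
        slope_young=float(ry.slope), se_young=float(ry.stderr),
        slope_old=float(ro.slope), se_old=float(ro.stderr),
        p_equal=float(2 * stats.norm.sf(abs(z))))
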