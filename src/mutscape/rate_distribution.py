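"""Gamma-Poisson (negative binomial) models of windowed mutation counts.

The per-window mutation rate is written as alpha * u_bar, where u_bar is
the genome-wide mean rate per site and alpha is a gamma-distributed
multiplier with mean 1 and shape k.  Counts per window are Poisson with
mean alpha * u_bar * l (l = usable sites, the offset), so marginally the
count in window j is negative binomial with mean u_bar * l_j and shape k.
The coefficient of variation of the rate distribution is CV = 1/sqrt(k);
it is the headline measure of how much the mutation rate varies between
windows.

Following the source analysis, u_bar is fixed to its moment estimate
(total counts / total offset) and only the shape is profiled by maximum
likelihood; a joint fit is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

_LOG_SHAPE_LO, _LOG_SHAPE_HI = np.log(1e-3), np.log(1e6)
_CHI2_95_1DF_HALF = stats.chi2.ppf(0.95, 1) / 2.0  # 1.9207...


@dataclass
class RateDistFit:
    """Fitted gamma-Poisson rate distribution for one set of windows."""

    mean_rate: float          # u_bar, mutations per site (per offset unit)
    shape: float              # gamma shape k
    cv: float                 # 1/sqrt(k)
    cv_ci: tuple              # 95% profile-likelihood interval for CV
    loglik: float
    n_windows: int
    offset_kind: str = "sites"

    @property
    def at_shape_bound(self) -> bool:
        return not (np.exp(_LOG_SHAPE_LO) * 1.01 < self.shape < np.exp(_LOG_SHAPE_HI) * 0.99)


def nb_loglik(counts: np.ndarray, means: np.ndarray, shape: float) -> float:
    """Negative-binomial log likelihood with per-window means and common shape."""
    p = shape / (shape + means)
    return float(stats.nbinom.logpmf(counts, shape, p).sum())


def nb_pmf(count: int, mean: float, shape: float) -> float:
    """NB pmf: the gamma mixture of Poisson(count; mean * alpha)."""
    return float(stats.nbinom.pmf(count, shape, shape / (shape + mean)))


def fit_gamma_poisson(counts, offsets, offset_kind: str = "sites",
                      fix_mean: bool = True) -> RateDistFit:
    """ML fit of the gamma shape given counts and per-window offsets.

    ``fix_mean=True`` (default) fixes u_bar at total/total; otherwise u_bar
    and the shape are maximised jointly.  The 95% CI for the CV is by
    profile likelihood (drop of chi2_{1,0.95}/2 in log likelihood); the
    lower CV limit is truncated at 0 when the profile is monotone up to
    the Poisson limit.
    """
    counts = np.asarray(counts, dtype=float)
    offsets = np.asarray(offsets, dtype=float)
    if counts.size < 2:
        raise ValueError("need at least 2 windows")
    if counts.size != offsets.size:
        raise ValueError("counts and offsets differ in length")
    if not np.all(np.isfinite(offsets)) or np.any(offsets <= 0):
        raise ValueError("offsets must be finite and positive")
    if np.any(counts < 0) or np.any(counts != np.round(counts)):
        raise ValueError("counts must be nonnegative integers")
    total = counts.sum()
    if total < 1:
        raise ValueError("all counts are zero")

    mean_rate = total / offsets.sum()

    def loglik_at(log_shape: float, u: float = mean_rate) -> float:
        return nb_loglik(counts, u * offsets, np.exp(log_shape))

    if fix_mean:
        res = optimize.minimize_scalar(
            lambda ls: -loglik_at(ls), bounds=(_LOG_SHAPE_LO, _LOG_SHAPE_HI),
            method="bounded", options={"xatol": 1e-10})
        log_shape_hat, lmax = res.x, -res.fun
        # the bounded optimizer can stall just inside a bound; snap if better
        for lb in (_LOG_SHAPE_LO, _LOG_SHAPE_HI):
            if loglik_at(lb) >= lmax:
                log_shape_hat, lmax = lb, loglik_at(lb)
    else:
        def nll(theta):
            log_u, log_shape = theta
            return -nb_loglik(counts, np.exp(log_u) * offsets, np.exp(log_shape))
        res = optimize.minimize(nll, x0=[np.log(mean_rate), np.log(10.0)],
                                method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-10})
        mean_rate = float(np.exp(res.x[0]))
        log_shape_hat = float(np.clip(res.x[1], _LOG_SHAPE_LO, _LOG_SHAPE_HI))
        lmax = -res.fun

    shape = float(np.exp(log_shape_hat))
    cv = 1.0 / np.sqrt(shape)
    target = lmax - _CHI2_95_1DF_HALF

    def drop(ls):
        return loglik_at(ls) - target

    # CV is decreasing in shape: upper CV limit from shapes below the MLE.
    if log_shape_hat > _LOG_SHAPE_LO and drop(_LOG_SHAPE_LO) < 0:
        ls = optimize.brentq(drop, _LOG_SHAPE_LO, log_shape_hat, xtol=1e-10)
        cv_hi = 1.0 / np.sqrt(np.exp(ls))
    else:
        cv_hi = 1.0 / np.sqrt(np.exp(_LOG_SHAPE_LO))
    if log_shape_hat < _LOG_SHAPE_HI and drop(_LOG_SHAPE_HI) < 0:
        ls = optimize.brentq(drop, log_shape_hat, _LOG_SHAPE_HI, xtol=1e-10)
        cv_lo = 1.0 / np.sqrt(np.exp(ls))
    else:
        cv_lo = 0.0  # profile monotone: Poisson not rejected

    return RateDistFit(mean_rate=float(mean_rate), shape=shape, cv=float(cv),
                       cv_ci=(float(cv_lo), float(cv_hi)), loglik=float(lmax),
                       n_windows=int(counts.size), offset_kind=offset_kind)


def goodness_of_fit(fit: RateDistFit, counts, offsets,
                    min_expected: float = 5.0) -> tuple[float, int, float]:
    """Chi-square goodness of fit of the fitted NB to the observed counts.

    Windows are binned by their count; expected bin totals come from the
    fitted NB averaged over the per-window offsets.  Bins are merged from
    the upper tail (and the lower end) until every expected count is at
    least ``min_expected``; df = bins - 2 (one for the total, one for the
    estimated shape).
    """
    counts = np.asarray(counts, dtype=int)
    offsets = np.asarray(offsets, dtype=float)
    means = fit.mean_rate * offsets
    cmax = int(counts.max())
    ks = np.arange(cmax + 1)
    p = fit.shape / (fit.shape + means)
    # expected[c] = sum_j P(C_j = c); tail bin holds the remainder
    expected = stats.nbinom.pmf(ks[:, None], fit.shape, p[None, :]).sum(axis=1)
    expected = np.append(expected, counts.size - expected.sum())
    observed = np.append(np.bincount(counts, minlength=cmax + 1), 0)

    # merge adjacent bins until all expected >= min_expected
    merged_obs, merged_exp, acc_o, acc_e = [], [], 0.0, 0.0
    for o, e in zip(observed, expected):
        acc_o += o
        acc_e += e
        if acc_e >= min_expected:
            merged_obs.append(acc_o)
            merged_exp.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0 or acc_o > 0:  # leftover tail: fold into the last bin
        if merged_obs:
            merged_obs[-1] += acc_o
            merged_exp[-1] += acc_e
    if len(merged_obs) < 3:
        raise ValueError("fewer than 3 bins after merging; too little data")
    merged_obs = np.array(merged_obs)
    merged_exp = np.array(merged_exp)
    chi2 = float(((merged_obs - merged_exp) ** 2 / merged_exp).sum())
    df = len(merged_obs) - 2
    return chi2, df, float(stats.chi2.sf(chi2, df))


@dataclass
class ScaleProfile:
    """Fitted CVs across window widths and the log-log scaling slope.

    If all large-scale variation were aggregation of i.i.d. fine-scale
    variation the slope would be -0.5; a shallower slope indicates
    genuine variation at larger scales.
    """

    widths: list
    cvs: list
    slope: float
    slope_se: float
    excluded_widths: list


def cv_scaling(counts_by_width: dict) -> ScaleProfile:
    """Fit the gamma-Poisson model per width and regress log CV on log width.

    ``counts_by_width`` maps window width -> (counts, offsets).  Widths
    whose fitted CV is 0 (shape at its upper bound) are excluded and
    flagged; at least 3 usable widths are required.
    """
    if len(counts_by_width) < 3:
        raise ValueError("need at least 3 widths")
    widths, cvs, excluded = [], [], []
    for width in sorted(counts_by_width):
        counts, offsets = counts_by_width[width]
        fit = fit_gamma_poisson(counts, offsets)
        if fit.cv <= 1.0 / np.sqrt(np.exp(_LOG_SHAPE_HI)) * 1.01:
            excluded.append(width)
            continue
        widths.append(width)
        cvs.append(fit.cv)
    if len(widths) < 3:
        raise ValueError("fewer than 3 widths with nonzero CV")
    reg = stats.linregress(np.log(widths), np.log(cvs))
    return ScaleProfile(widths=widths, cvs=cvs, slope=float(reg.slope),
                        slope_se=float(reg.stderr), excluded_widths=excluded)


def iid_aggregation_profile(seed: int, n_fine: int = 10_000,
                            fine_width: int = 10_000,
                            factors: tuple = (1, 10, 100),
                            cv: float = 0.5,
                            mean_count: float = 100.0) -> ScaleProfile:
    """The null experiment behind the -0.5 scaling expectation.

    Draws i.i.d. gamma rate multipliers (mean 1, coefficient of variation
    ``cv``) for fine windows, forms coarser windows purely by aggregation,
    generates high-mean Poisson counts at every scale, fits the
    gamma-Poisson model per scale and regresses log CV on log width.  When
    all coarse-scale variation is aggregated fine-scale variation the CV
    falls as width^(-1/2).
    """
    rng = np.random.default_rng(seed)
    alpha = rng.gamma(1.0 / cv ** 2, cv ** 2, n_fine)
    counts = rng.poisson(alpha * mean_count)
    by_width = {}
    for m in factors:
        agg = counts.reshape(-1, m).sum(axis=1)
        by_width[fine_width * m] = (agg, np.full(agg.size, float(fine_width * m)))
    return cv_scaling(by_width)


def nested_scale_anova(fine_counts, fine_offsets, group) -> tuple[float, float]:
    """One-way ANOVA of fine-window rates grouped by coarse window.

    Tests whether coarse-scale rate variation exceeds what fine-scale
    variation alone would produce.  ``group`` maps each fine window to a
    coarse-window label.
    """
    rates = np.asarray(fine_counts, dtype=float) / np.asarray(fine_offsets, dtype=float)
    group = np.asarray(group)
    labels, counts_per = np.unique(group, return_counts=True)
    labels = labels[counts_per >= 2]
    if labels.size < 2:
        raise ValueError("need >=2 coarse groups with >=2 fine windows each")
    samples = [rates[group == g] for g in labels]
    if np.ptp(rates) == 0:  # no variation at all: F = 0 by convention
        return 0.0, 1.0
    f, p = stats.f_oneway(*samples)
    return float(f), float(p)
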