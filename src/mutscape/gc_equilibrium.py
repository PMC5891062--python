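"""Base-composition machinery: equilibrium GC content from DNM spectra.

If the S>W mutation rate (strong G:C -> weak A:T) per strong site is
mu*(1 - f_e) and the W>S rate per weak site is mu*f_e, then a window with
current GC content f would, under mutation alone, evolve toward the
equilibrium GC content f_e, and the proportion of GC-changing mutations
that are S>W is

    x(f_e, f) = f(1 - f_e) / [f(1 - f_e) + (1 - f) f_e].

Letting f_e vary across windows as Normal(mean_fe, sigma), the likelihood
of observing i S>W mutations out of n GC-changing mutations in a window
is the truncated-normal mixture of binomials integrated over f_e in
(0, 1).  Maximising the summed log likelihood over (mean_fe, sigma) asks
whether the *pattern* of mutation varies enough across the genome to
generate variation in GC content: a sigma CI touching 0 says it does not.

A second, spectrum-based route estimates the nine category rates in bins
of current GC and evolves a sequence under them to its stationary GC
content, with CpG context re-evaluated as the sequence changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, gammaln, logit, logsumexp

from .windows_io import (CATEGORIES, SW_CATEGORIES, WS_CATEGORIES,
                         WindowCountMatrix)

logger = logging.getLogger(__name__)

_SIGMA_FLOOR = 1e-6
_CHI2_95_1DF_HALF = stats.chi2.ppf(0.95, 1) / 2.0


def expected_sw_fraction(f: float, fe: float) -> float:
    """Expected S>W fraction of GC-changing mutations, x(f_e, f)."""
    if not (0.0 < f < 1.0) or not (0.0 < fe < 1.0):
        raise ValueError("f and fe must be strictly inside (0, 1)")
    return float(_sw_fraction(f, fe))


def _sw_fraction(f, fe):
    num = f * (1.0 - fe)
    return num / (num + (1.0 - f) * fe)


@dataclass(frozen=True)
class SWWindowSummary:
    """Per-window tally: i S>W DNMs out of n GC-changing, at GC content f."""

    i: int
    n: int
    f: float

    def __post_init__(self):
        if not (0 <= self.i <= self.n):
            raise ValueError("need 0 <= i <= n")
        if not (0.0 <= self.f <= 1.0):
            raise ValueError("f outside [0, 1]")


def summarize_sw(matrix: WindowCountMatrix) -> list:
    """SWWindowSummary per window from a 9-category count matrix."""
    sw = matrix.counts[list(SW_CATEGORIES)].sum(axis=1).to_numpy()
    ws = matrix.counts[list(WS_CATEGORIES)].sum(axis=1).to_numpy()
    return [SWWindowSummary(i=int(a), n=int(a + b), f=w.gc_content)
            for a, b, w in zip(sw, ws, matrix.windows)]


@dataclass
class GCEquilibriumFit:
    """ML fit of the distribution of equilibrium GC content across windows."""

    mean_fe: float
    sigma_fe: float
    cis: dict                 # {"mean_fe": (lo, hi), "sigma_fe": (lo, hi)}
    loglik: float
    n_windows: int


class _EqLikelihood:
    """Vectorised total log likelihood over (mean_fe, sigma).

    The inner integral over f_e uses fixed-order Gauss-Legendre nodes on
    (0, 1); the truncated-normal weight is normalised with the same
    nodes, so doubling the order is a direct stability check.
    """

    def __init__(self, i, n, f, n_nodes=200):
        self.i = np.asarray(i, dtype=float)
        self.n = np.asarray(n, dtype=float)
        self.f = np.asarray(f, dtype=float)
        nodes, wts = np.polynomial.legendre.leggauss(n_nodes)
        self.fe_nodes = 0.5 * (nodes + 1.0)
        self.glw = 0.5 * wts
        self.lcoef = (gammaln(self.n + 1) - gammaln(self.i + 1)
                      - gammaln(self.n - self.i + 1))
        # binomial log-likelihood at each (window, node), coefficient-free
        x = _sw_fraction(self.f[:, None], self.fe_nodes[None, :])
        self._logb_nodes = (self.i[:, None] * np.log(x)
                            + (self.n - self.i)[:, None] * np.log1p(-x))

    def __call__(self, mean_fe: float, sigma: float) -> float:
        if not (0.0 < mean_fe < 1.0) or sigma < 0:
            return -np.inf
        if sigma < _SIGMA_FLOOR:
            x = _sw_fraction(self.f, mean_fe)
            return float((self.lcoef + self.i * np.log(x)
                          + (self.n - self.i) * np.log1p(-x)).sum())
        w = stats.norm.pdf(self.fe_nodes, mean_fe, sigma) * self.glw
        z = w.sum()
        if z <= 0:
            return -np.inf
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            ll = logsumexp(self._logb_nodes, b=(w / z)[None, :], axis=1)
        return float((self.lcoef + ll).sum())


def fit_gc_equilibrium(summaries, n_nodes: int = 200, compute_ci: bool = True,
                       sigma_max: float = 0.5) -> GCEquilibriumFit:
    """Maximise the mixture likelihood over (mean_fe, sigma).

    The sigma = 0 boundary (a single genome-wide equilibrium GC) is
    evaluated explicitly; CIs are by profile likelihood, and the sigma
    lower limit is 0 whenever the boundary lies within the 95% drop.
    Windows with n = 0 or degenerate GC are excluded.
    """
    use = [s for s in summaries if s.n > 0 and 0.0 < s.f < 1.0]
    if len(use) < 2:
        raise ValueError("need >=2 windows with GC-changing DNMs and 0 < f < 1")
    if len(use) < len(summaries):
        logger.info("fit_gc_equilibrium excluded %d degenerate windows",
                    len(summaries) - len(use))
    ll = _EqLikelihood([s.i for s in use], [s.n for s in use],
                       [s.f for s in use], n_nodes=n_nodes)

    # sigma = 0 boundary
    res0 = optimize.minimize_scalar(lambda fe: -ll(fe, 0.0),
                                    bounds=(1e-3, 1 - 1e-3), method="bounded",
                                    options={"xatol": 1e-8})
    fe0, l0 = float(res0.x), -float(res0.fun)

    # interior optimum over (logit fe, log sigma)
    def nll(theta):
        return -ll(expit(theta[0]), min(np.exp(theta[1]), sigma_max))

    best = (fe0, 0.0, l0)
    for sigma_start in (0.02, 0.08):
        res = optimize.minimize(nll, x0=[logit(fe0), np.log(sigma_start)],
                                method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-8})
        fe_i = float(expit(res.x[0]))
        s_i = float(min(np.exp(res.x[1]), sigma_max))
        if -res.fun > best[2] + 1e-9:
            best = (fe_i, s_i if s_i >= _SIGMA_FLOOR else 0.0, -float(res.fun))
    mean_fe, sigma_fe, lmax = best
    if not np.isfinite(lmax):
        raise RuntimeError("likelihood did not evaluate finitely; check inputs")

    cis = {"mean_fe": (float("nan"), float("nan")),
           "sigma_fe": (float("nan"), float("nan"))}
    if compute_ci:
        target = lmax - _CHI2_95_1DF_HALF

        def prof_fe(fe):
            r = optimize.minimize_scalar(
                lambda ls: -ll(fe, np.exp(ls)),
                bounds=(np.log(1e-4), np.log(sigma_max)), method="bounded",
                options={"xatol": 1e-4})
            return max(-float(r.fun), ll(fe, 0.0))

        def prof_sigma(sigma):
            r = optimize.minimize_scalar(
                lambda fe: -ll(fe, sigma), bounds=(1e-3, 1 - 1e-3),
                method="bounded", options={"xatol": 1e-6})
            return -float(r.fun)

        cis["mean_fe"] = (_profile_root(prof_fe, mean_fe, target, 1e-3, upper=False),
                          _profile_root(prof_fe, mean_fe, target, 1 - 1e-3, upper=True))
        if prof_sigma(0.0) >= target:
            lo_s = 0.0
        else:
            lo_s = _profile_root(prof_sigma, sigma_fe, target, 0.0, upper=False)
        cis["sigma_fe"] = (lo_s, _profile_root(prof_sigma, sigma_fe, target,
                                               sigma_max, upper=True))

    return GCEquilibriumFit(mean_fe=mean_fe, sigma_fe=sigma_fe, cis=cis,
                            loglik=lmax, n_windows=len(use))


def _profile_root(profile, mle, target, bound, upper: bool) -> float:
    """Root of profile(theta) = target between the MLE and a bound."""
    if profile(bound) >= target:
        return float(bound)
    a, b = (mle, bound) if upper else (bound, mle)
    return float(optimize.brentq(lambda t: profile(t) - target, a, b, xtol=1e-5))


# ---------------------------------------------------------------------------
# Mutation spectrum and sequence evolution


@dataclass
class MutationSpectrum:
    """Per-site rates for the nine mutation categories (arbitrary time unit)."""

    rates: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in CATEGORIES if c not in self.rates]
        if missing:
            raise ValueError(f"missing categories: {missing}")
        finite = [v for v in self.rates.values() if np.isfinite(v)]
        if any(v < 0 for v in finite) or not any(v > 0 for v in finite):
            raise ValueError("rates must be nonnegative with at least one positive")

    def rate(self, category: str) -> float:
        return self.rates[category]


def estimate_spectrum(matrix: WindowCountMatrix, gc_bins) -> dict:
    """Pooled per-category rates for windows grouped by current GC content.

    Returns {(gc_lo, gc_hi): MutationSpectrum}.  A category with zero
    sites in a bin gets rate NaN (undefined, not zero); empty bins are
    dropped with a warning.
    """
    gc_bins = np.asarray(gc_bins, dtype=float)
    gc = np.array([w.gc_content for w in matrix.windows])
    if gc.min() < gc_bins[0] or gc.max() > gc_bins[-1]:
        raise ValueError("gc_bins do not cover the observed GC range")
    which = np.clip(np.digitize(gc, gc_bins) - 1, 0, len(gc_bins) - 2)
    out = {}
    for b in range(len(gc_bins) - 1):
        idx = np.flatnonzero(which == b)
        if idx.size == 0:
            logger.warning("GC bin [%.3f, %.3f) contains no windows; dropped",
                           gc_bins[b], gc_bins[b + 1])
            continue
        rates = {}
        for cat in CATEGORIES:
            dnms = float(matrix.counts[cat].to_numpy()[idx].sum())
            sites = float(matrix.offsets(cat)[idx].sum())
            rates[cat] = dnms / sites if sites > 0 else float("nan")
        vals = np.array(list(rates.values()))
        if not np.any(np.nan_to_num(vals) > 0):
            logger.warning("GC bin [%.3f, %.3f) has no DNMs; dropped",
                           gc_bins[b], gc_bins[b + 1])
            continue
        out[(float(gc_bins[b]), float(gc_bins[b + 1]))] = MutationSpectrum(rates)
    return out


_BASES = "ACGT"
_A, _C, _G, _T = range(4)


def _rate_table(spectrum: MutationSpectrum) -> np.ndarray:
    """rates[context, base, target]: context 0 = non-CpG, 1 = CpG.

    Strand-collapsed: G behaves as C on the other strand, A as T.  NaN
    rates (undefined categories) are treated as 0.
    """
    r = {c: (0.0 if not np.isfinite(v) else float(v))
         for c, v in spectrum.rates.items()}
    tab = np.zeros((2, 4, 4))
    for cpg in (0, 1):
        pre = "CpG_C" if cpg else "C"
        ct = r[f"{pre}>T"]
        ca = r[f"{pre}>A"]
        cg = r["CpG_C>G"] if cpg else r["C<>G"]
        tab[cpg, _C, _T], tab[cpg, _C, _A], tab[cpg, _C, _G] = ct, ca, cg
        tab[cpg, _G, _A], tab[cpg, _G, _T], tab[cpg, _G, _C] = ct, ca, cg
    for cpg in (0, 1):  # weak bases have no CpG context of their own
        tab[cpg, _T, _C] = tab[cpg, _A, _G] = r["T>C"]
        tab[cpg, _T, _G] = tab[cpg, _A, _C] = r["T>G"]
        tab[cpg, _T, _A] = tab[cpg, _A, _T] = r["T<>A"]
    return tab


def evolve_to_equilibrium(spectrum: MutationSpectrum, init, mode: str = "deterministic",
                          seed: int | None = None, tol: float = 1e-4,
                          span: int = 100, max_iter: int = 20000,
                          dt_scale: float = 0.05):
    """Evolve a sequence under the 9-category spectrum to stationary GC.

    ``init`` is a base string, a GC fraction, or a dict of base
    frequencies.  CpG context is re-evaluated as the composition changes.
    The deterministic mode integrates circular dinucleotide frequencies
    (a 16-state composition vector with a Markov closure for the
    trinucleotide context); the stochastic mode mutates a circular
    sequence.  Convergence: the change in (span-averaged) GC across a
    convergence span falls below ``tol`` (the stochastic mode uses a
    noise-floor-aware tolerance and returns a tail average).

    Returns ``(equilibrium_gc, trajectory)``.
    """
    if mode == "deterministic":
        return _evolve_deterministic(spectrum, init, tol, span, max_iter, dt_scale)
    if mode == "stochastic":
        return _evolve_stochastic(spectrum, init, seed, tol, span, max_iter, dt_scale)
    raise ValueError(f"unknown mode {mode!r}")


def _init_composition(init) -> np.ndarray:
    if isinstance(init, str):
        arr = np.frombuffer(init.upper().encode(), dtype="S1")
        p = np.array([(arr == b).mean() for b in (b"A", b"C", b"G", b"T")])
    elif isinstance(init, dict):
        p = np.array([init.get(b, 0.0) for b in _BASES], dtype=float)
    else:
        gc = float(init)
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    if p.sum() <= 0:
        raise ValueError("degenerate initial composition")
    return p / p.sum()


def _evolve_deterministic(spectrum, init, tol, span, max_iter, dt_scale):
    tab = _rate_table(spectrum)
    # R[a, b, c, d]: rate of middle base b -> d between left a and right c
    is_cpg = np.zeros((4, 4, 4), dtype=int)
    is_cpg[:, _C, _G] = 1
    is_cpg[_C, _G, :] = 1
    R = np.where(is_cpg[..., None], tab[1][None, :, None, :], tab[0][None, :, None, :])
    site_rate = R.sum(axis=3)
    dt = dt_scale / site_rate.max()

    if isinstance(init, str) and len(init) >= 2:
        arr = np.frombuffer(init.upper().encode(), dtype="S1")
        idx = np.full(arr.size, -1)
        for k, b in enumerate((b"A", b"C", b"G", b"T")):
            idx[arr == b] = k
        idx = idx[idx >= 0]
        p2 = np.zeros((4, 4))
        np.add.at(p2, (idx, np.roll(idx, -1)), 1.0)
        p2 /= p2.sum()
    else:
        p1 = _init_composition(init)
        p2 = np.outer(p1, p1)

    traj = []
    for step in range(max_iter):
        p1 = p2.sum(axis=1)
        gc = float(p1[_C] + p1[_G])
        traj.append(gc)
        if step >= span and abs(traj[-1] - traj[-1 - span]) < tol:
            return gc, np.array(traj)
        with np.errstate(divide="ignore", invalid="ignore"):
            f3 = p2[:, :, None] * p2[None, :, :] / p1[None, :, None]
        f3 = np.nan_to_num(f3)
        flux = f3[..., None] * R * dt
        p2 = p2.copy()
        p2 -= np.einsum("abcd->ab", flux)
        p2 -= np.einsum("abcd->bc", flux)
        p2 += np.einsum("abcd->ad", flux)
        p2 += np.einsum("abcd->dc", flux)
        p2 = np.clip(p2, 0.0, None)
        p2 /= p2.sum()
    raise RuntimeError(
        f"no convergence in {max_iter} steps; last GC {traj[-1]:.4f}",
        np.array(traj))


def _evolve_stochastic(spectrum, init, seed, tol, span, max_iter, dt_scale,
                       min_length: int = 1000, tail_spans: int = 5):
    rng = np.random.default_rng(seed)
    tab = _rate_table(spectrum)
    if isinstance(init, str):
        if len(init) < min_length:
            raise ValueError(f"stochastic mode needs length >= {min_length}")
        arr = np.frombuffer(init.upper().encode(), dtype="S1")
        seq = np.full(arr.size, -1, dtype=np.int8)
        for k, b in enumerate((b"A", b"C", b"G", b"T")):
            seq[arr == b] = k
        seq = seq[seq >= 0].copy()
    else:
        p1 = _init_composition(init)
        seq = rng.choice(4, size=100_000, p=p1).astype(np.int8)
    n = seq.size
    total = tab.sum(axis=2)               # (2, 4) total rate per (cpg, base)
    cum = np.cumsum(tab, axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cum = np.nan_to_num(cum / total[..., None])
    dt = dt_scale / total.max()
    # stochastic noise floor on span-mean differences
    conv_tol = max(tol, 3.0 * np.sqrt(0.25 / n))

    traj = []
    span_means = []
    converged_at = None  # sweep index where stationarity was detected
    for sweep in range(max_iter):
        cpg = ((seq == _C) & (np.roll(seq, -1) == _G)) | \
              ((seq == _G) & (np.roll(seq, 1) == _C))
        ctx = cpg.astype(np.int8)
        p_mut = total[ctx, seq] * dt
        hit = np.flatnonzero(rng.random(n) < p_mut)
        if hit.size:
            u = rng.random(hit.size)
            targets = (u[:, None] > cum[ctx[hit], seq[hit]]).sum(axis=1)
            seq[hit] = targets.astype(np.int8)
        gc = float(((seq == _C) | (seq == _G)).mean())
        traj.append(gc)
        if converged_at is not None:
            # average freshly generated equilibrium sweeps, not the burn-in
            if sweep - converged_at >= span * tail_spans:
                eq = float(np.mean(traj[converged_at:]))
                return eq, np.array(traj)
            continue
        if (sweep + 1) % span == 0:
            span_means.append(float(np.mean(traj[-span:])))
            if (len(span_means) >= 3
                    and abs(span_means[-1] - span_means[-2]) < conv_tol
                    and abs(span_means[-2] - span_means[-3]) < conv_tol):
                converged_at = sweep
    raise RuntimeError(
        f"no convergence in {max_iter} sweeps; last GC {traj[-1]:.4f}",
        np.array(traj))


# ---------------------------------------------------------------------------
# Mutability-index calibration


def mi_calibration(mi_values, dnm_counts, group_width: int = 10):
    """Calibrate an integer per-site mutability index (MI) to an absolute
    per-site rate.

    Sites are binned into consecutive MI groups of ``group_width``
    starting from the first MI with at least one DNM; within each bin the
    log of (DNMs / sites) is regressed on the site-weighted mean MI.
    Returns ``(intercept, slope, predict)`` where
    ``predict(mi) = exp(intercept + slope * mi)``.
    """
    mi = np.asarray(mi_values)
    dnm = np.asarray(dnm_counts)
    if mi.shape != dnm.shape:
        raise ValueError("mi_values and dnm_counts differ in length")
    if np.all(mi == mi[0]):
        raise ValueError("all MI values identical")
    with_dnm = mi[dnm > 0]
    if with_dnm.size == 0:
        raise ValueError("no DNMs")
    mi0 = int(with_dnm.min())
    keep = mi >= mi0
    bins = (mi[keep] - mi0) // group_width
    xs, ys = [], []
    for b in np.unique(bins):
        m = bins == b
        n_sites = int(m.sum())
        n_dnm = int(dnm[keep][m].sum())
        if n_dnm == 0:
            logger.info("MI bin %d has no DNMs; dropped", int(b))
            continue
        xs.append(float(mi[keep][m].mean()))
        ys.append(np.log(n_dnm / n_sites))
    if len(xs) < 2:
        raise ValueError("fewer than 2 usable MI bins")
    reg = stats.linregress(xs, ys)
    intercept, slope = float(reg.intercept), float(reg.slope)

    def predict(mi_value):
        return np.exp(intercept + slope * np.asarray(mi_value, dtype=float))

    return intercept, slope, predict
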