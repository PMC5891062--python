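"""The normalized-slope test separating GC-biased gene conversion from
selection, ancestral coalescence, and regression artifacts.

Divergence correlates with recombination rate (RR) beyond its effect on
the mutation rate.  The test compares, per mutation class, the slope of
normalized DNM density on normalized RR with the slope of normalized
substitution (or SNP) density on normalized RR:

* gBGC raises the fixation probability of W>S mutations and lowers that
  of S>W in high-recombination regions, so the substitution slope should
  exceed the DNM slope for W>S, fall below it for S>W, and match it for
  GC-conserving changes.
* Linked/direct selection predicts substitution slopes below DNM slopes
  in all classes; variation in ancestral coalescence time predicts the
  opposite; pure regression artifacts predict uniformly shallower
  substitution slopes.

Densities and RR are divided by their means so slopes are comparable
across quantities on different scales; significance is by bootstrapping
windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .windows_io import NEUTRAL_CATEGORIES, SW_CATEGORIES, WS_CATEGORIES

logger = logging.getLogger(__name__)

#: The three strong/weak classes the test runs over.
SLOPE_CLASSES = ("S>W", "W>S", "S<>S&W<>W")

_CLASS_CATEGORIES = {
    "S>W": list(SW_CATEGORIES),
    "W>S": list(WS_CATEGORIES),
    "S<>S&W<>W": list(NEUTRAL_CATEGORIES),
}


@dataclass
class SlopeTestResult:
    category: str                  # one of SLOPE_CLASSES
    slope_dnm: float
    se_dnm: float
    slope_ref: float
    se_ref: float
    prop_boot_dnm_gt_ref: float    # proportion of bootstrap replicates
    n_boot: int
    rr_kind: str = "sex-averaged"
    degenerate: bool = False


def normalized_slope(y, rr) -> tuple[float, float]:
    """OLS slope (and SE) of y/mean(y) on rr/mean(rr).

    Dividing both variables by their means makes slopes comparable
    between quantities on different scales and makes the slope invariant
    to rescaling either input.
    """
    y = np.asarray(y, dtype=float)
    rr = np.asarray(rr, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 windows")
    if y.mean() <= 0 or rr.mean() <= 0:
        raise ValueError("means must be positive for normalization")
    if np.ptp(rr) == 0:
        raise ValueError("recombination rate has zero variance")
    reg = stats.linregress(rr / rr.mean(), y / y.mean())
    return float(reg.slope), float(reg.stderr)


def class_density(counts, site_counts: dict, cls: str) -> np.ndarray:
    """Per-window event density for one strong/weak class.

    S>W events happen at strong sites (CpG + non-CpG strong), W>S at weak
    sites, GC-conserving at all sites.
    """
    total = counts[_CLASS_CATEGORIES[cls]].sum(axis=1).to_numpy(dtype=float)
    denom = {
        "S>W": site_counts["cpg"] + site_counts["strong_noncpg"],
        "W>S": site_counts["weak"],
        "S<>S&W<>W": site_counts["cpg"] + site_counts["strong_noncpg"] + site_counts["weak"],
    }[cls]
    return total / denom


def slope_comparison_test(dnm_counts, ref_counts, site_counts: dict, rr,
                          n_boot: int = 100, seed: int | None = None,
                          rr_kind: str = "sex-averaged") -> list:
    """Per-class normalized slopes of DNM and reference density on RR,
    with the bootstrap proportion of replicates where the DNM slope
    exceeds the reference slope.

    ``dnm_counts`` and ``ref_counts`` are per-window DataFrames with the
    9 category columns on identical windows; ``site_counts`` maps
    {'cpg', 'strong_noncpg', 'weak'} to per-window site arrays.  Windows
    are resampled with replacement (the same resample is used for every
    class and both quantities within a replicate) and both slopes are
    re-normalized within each replicate; exact slope ties count 0.5.
    """
    rr = np.asarray(rr, dtype=float)
    n = rr.size
    if len(dnm_counts) != n or len(ref_counts) != n:
        raise ValueError("all inputs must be on identical windows")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)

    dens = {}
    for cls in SLOPE_CLASSES:
        d_dnm = class_density(dnm_counts, site_counts, cls)
        d_ref = class_density(ref_counts, site_counts, cls)
        dens[cls] = (d_dnm, d_ref)

    results = []
    boot_idx = rng.integers(0, n, size=(n_boot, n))
    for cls in SLOPE_CLASSES:
        d_dnm, d_ref = dens[cls]
        if d_dnm.sum() == 0 or d_ref.sum() == 0:
            logger.warning("class %s has zero total events; skipped", cls)
            results.append(SlopeTestResult(
                category=cls, slope_dnm=float("nan"), se_dnm=float("nan"),
                slope_ref=float("nan"), se_ref=float("nan"),
                prop_boot_dnm_gt_ref=float("nan"), n_boot=n_boot,
                rr_kind=rr_kind, degenerate=True))
            continue
        try:
            s_dnm, se_dnm = normalized_slope(d_dnm, rr)
            s_ref, se_ref = normalized_slope(d_ref, rr)
        except ValueError as exc:
            logger.warning("class %s degenerate: %s", cls, exc)
            results.append(SlopeTestResult(
                category=cls, slope_dnm=float("nan"), se_dnm=float("nan"),
                slope_ref=float("nan"), se_ref=float("nan"),
                prop_boot_dnm_gt_ref=float("nan"), n_boot=n_boot,
                rr_kind=rr_kind, degenerate=True))
            continue
        score = 0.0
        for b in range(n_boot):
            idx = boot_idx[b]
            if np.ptp(rr[idx]) == 0 or d_dnm[idx].sum() == 0 or d_ref[idx].sum() == 0:
                score += 0.5  # uninformative replicate
                continue
            b_dnm, _ = normalized_slope(d_dnm[idx], rr[idx])
            b_ref, _ = normalized_slope(d_ref[idx], rr[idx])
            score += 1.0 if b_dnm > b_ref else (0.5 if b_dnm == b_ref else 0.0)
        results.append(SlopeTestResult(
            category=cls, slope_dnm=s_dnm, se_dnm=se_dnm, slope_ref=s_ref,
            se_ref=se_ref, prop_boot_dnm_gt_ref=score / n_boot,
            n_boot=n_boot, rr_kind=rr_kind))
    return results


def classify_signature(results: list, alpha: float = 0.05) -> str:
    """Decision table over the three classes' bootstrap proportions.

    The proportion is P(DNM slope > reference slope).  gBGC: reference
    above DNM for W>S, below for S>W, no difference for GC-conserving.
    Selection: DNM above reference everywhere.  Ancestral coalescence:
    reference above DNM everywhere.  Regression artifact: all reference
    slopes significantly different and shallower in magnitude.
    """
    by_class = {r.category: r for r in results}
    missing = [c for c in SLOPE_CLASSES if c not in by_class
               or by_class[c].degenerate]
    if missing:
        raise ValueError(f"missing or degenerate classes: {missing}")
    p = {c: by_class[c].prop_boot_dnm_gt_ref for c in SLOPE_CLASSES}
    hi = {c: p[c] >= 1 - alpha for c in SLOPE_CLASSES}   # DNM slope > ref
    lo = {c: p[c] <= alpha for c in SLOPE_CLASSES}       # ref slope > DNM

    if all(hi.values()):
        return "selection"
    if all(lo.values()):
        return "ancestral-coalescence"
    if hi["S>W"] and lo["W>S"] and not hi["S<>S&W<>W"] and not lo["S<>S&W<>W"]:
        return "gBGC"
    shallower = all(abs(by_class[c].slope_ref) < abs(by_class[c].slope_dnm)
                    for c in SLOPE_CLASSES)
    if all(hi[c] or lo[c] for c in SLOPE_CLASSES) and shallower:
        return "regression-artifact"
    return "inconclusive"
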