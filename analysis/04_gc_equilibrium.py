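"""Does variation in the mutation pattern generate variation in GC content?

Two routes, both on the synthetic study (generated with a single
equilibrium GC of 0.32, i.e. no pattern variation):

1. The mixture likelihood over windows of i S>W mutations out of n
   GC-changing ones, maximized over (mean f_e, sigma).  The fitted sigma
   should be small with a 95% CI encompassing 0.
2. The spectrum route: estimate the 9 category rates in bins of current
   GC, evolve a sequence under each bin's spectrum to its stationary GC,
   and ask whether the equilibrium tracks the current GC (it should not).

Also runs the mutability-index calibration regression on synthetic
per-site scores.  Writes results/gc_equilibrium.tsv and
results/gc_equilibrium_fit.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from mutscape.gc_equilibrium import (estimate_spectrum, evolve_to_equilibrium,
                                     fit_gc_equilibrium, mi_calibration,
                                     summarize_sw)
from mutscape.windows_io import read_counts

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def main():
    matrix = read_counts(SCRATCH / "study" / "dnm_counts.tsv")

    fit = fit_gc_equilibrium(summarize_sw(matrix), n_nodes=200)
    print(f"mixture ML: mean f_e = {fit.mean_fe:.3f} "
          f"(95% CI {fit.cis['mean_fe'][0]:.3f}-{fit.cis['mean_fe'][1]:.3f}), "
          f"sigma = {fit.sigma_fe:.4f} "
          f"(95% CI {fit.cis['sigma_fe'][0]:.4f}-{fit.cis['sigma_fe'][1]:.4f})")
    if fit.cis["sigma_fe"][0] == 0.0:
        print("  -> a model with no variation in equilibrium GC fits the data")
    print("  (the mixture model treats all strong sites alike; CpG "
          "hypermutability inflates the S>W fraction, pulling the fitted "
          "mean f_e below the spectrum-based equilibrium of ~0.32 -- the "
          "sigma CI is the robust conclusion, the spectrum route below "
          "handles CpG explicitly)")
    with open(RESULTS / "gc_equilibrium_fit.json", "w") as fh:
        json.dump({"mean_fe": fit.mean_fe, "sigma_fe": fit.sigma_fe,
                   "cis": fit.cis, "loglik": fit.loglik}, fh, indent=1)

    gc = np.array([w.gc_content for w in matrix.windows])
    bins = np.quantile(gc, [0, 0.25, 0.5, 0.75, 1.0])
    bins[-1] += 1e-9
    rows = []
    for (lo, hi), spec in estimate_spectrum(matrix, bins).items():
        eq, _ = evolve_to_equilibrium(spec, (lo + hi) / 2, mode="deterministic")
        rows.append({"gc_lo": lo, "gc_hi": hi, "equilibrium_gc": eq})
        print(f"GC bin [{lo:.3f}, {hi:.3f}): spectrum evolves to "
              f"equilibrium GC {eq:.3f}")
    df = pd.DataFrame(rows)
    r = np.corrcoef((df.gc_lo + df.gc_hi) / 2, df.equilibrium_gc)[0, 1]
    print(f"correlation of equilibrium GC with current GC across bins: "
          f"r = {r:.2f} (no systematic tracking expected)")
    df.to_csv(RESULTS / "gc_equilibrium.tsv", sep="\t", index=False,
              float_format="%.4f")

    # mutability-index calibration on synthetic per-site scores
    rng = np.random.default_rng(3)
    mi = rng.integers(0, 200, size=300_000)
    dnm = rng.poisson(np.exp(-6.0 + 0.01 * mi))
    intercept, slope, _ = mi_calibration(mi, dnm)
    print(f"MI calibration: log(rate) = {intercept:.2f} + {slope:.4f} x MI "
          f"(truth -6.00 + 0.0100 x MI)")
    print(f"wrote {RESULTS / 'gc_equilibrium.tsv'}")


if __name__ == "__main__":
    main()
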