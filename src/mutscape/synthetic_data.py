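"""Synthetic study generator with known ground truth.

Emulates the statistical structure the analysis assumes: a toy genome
whose window GC content varies; gamma-distributed per-window mutation
rate multipliers; a 9-category spectrum with elevated CpG transitions;
substitution and SNP counts derived from the same per-window rates with
an optional recombination-dependent fixation bias (gBGC); and genomic
covariates loaded on the latent log rate.  Every generator records its
truth so closed-loop tests recover known parameters instead of
re-inferring them from data.

The whole study is a pure function of ``SyntheticConfig`` (including its
seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .covariate_analysis import CovariateTable
from .gc_equilibrium import MutationSpectrum
from .windows_io import (CATEGORIES, SITE_CLASS, SW_CATEGORIES, WS_CATEGORIES,
                         GenomeWindow, MutationEvent, WindowCountMatrix,
                         annotate_windows, make_windows)


def default_spectrum() -> MutationSpectrum:
    """A human-like relative spectrum: CpG transitions ~12x the non-CpG
    C>T rate, transitions above transversions elsewhere.  Units are
    arbitrary; generators rescale to the requested totals.  The W>S rates
    are calibrated so the implied equilibrium GC content is ~0.32 at the
    default window composition, consistent with ``fe_mean``."""
    return MutationSpectrum(rates={
        "CpG_C>T": 12.0, "CpG_C>A": 0.8, "CpG_C>G": 0.7,
        "C>T": 1.0, "T>C": 0.615, "C>A": 0.35, "T>G": 0.176,
        "C<>G": 0.35, "T<>A": 0.25,
    })


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic genome and its observables.

    Defaults are desk-scale but keep the statistical regime of large
    trio studies: ~40 DNMs per window (the largest dataset's per-MB
    density), rate-multiplier CV 0.18, window GC ~0.41, equilibrium GC
    0.32 with no variation, ~1.2% divergence and ~3.1% SNP density per
    window.
    """

    n_chroms: int = 2
    chrom_length: int = 2_000_000
    window_width: int = 100_000
    cv_truth: float = 0.18
    mean_dnm_per_window: float = 40.0
    spectrum_truth: MutationSpectrum = field(default_factory=default_spectrum)
    gc_mean: float = 0.41
    gc_sd: float = 0.04
    fe_mean: float = 0.32
    fe_sd: float = 0.0
    bgc_strength: float = 0.0         # B per unit normalized recombination rate
    snp_bgc_scale: float = 0.5        # SNPs see a diluted fixation bias
    mean_sub_per_window: float = 1200.0
    mean_snp_per_window: float = 3100.0
    rr_log_sd: float = 1.0            # lognormal recombination map, mean 1
    covariate_loadings: dict = field(default_factory=lambda: {
        "replication_time": 0.6, "H3K9me3": 0.4, "expression": 0.2,
        "nucleosome_occupancy": 0.0})
    covariate_noise_sd: float = 1.0
    frac_young_fathers: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.cv_truth < 0:
            raise ValueError("cv_truth must be >= 0")
        if not (0 < self.fe_mean < 1):
            raise ValueError("fe_mean must be in (0, 1)")
        if min(self.n_chroms, self.chrom_length, self.window_width) <= 0:
            raise ValueError("lengths must be positive")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside every generated study."""

    alpha: np.ndarray                  # per-window rate multipliers, mean 1
    fe: np.ndarray                     # per-window equilibrium GC
    rr: np.ndarray                     # per-window recombination rate, mean ~1
    fixation_factor: pd.DataFrame | None = None   # per-window per-category

    def to_json(self, path) -> None:
        obj = {"alpha": self.alpha.tolist(), "fe": self.fe.tolist(),
               "rr": self.rr.tolist()}
        if self.fixation_factor is not None:
            obj["fixation_factor"] = self.fixation_factor.to_dict(orient="list")
        with open(path, "w") as fh:
            json.dump(obj, fh)


def generate_genome(config: SyntheticConfig) -> tuple[dict, list]:
    """Random genome and annotated windows.

    Per-window GC targets are drawn around ``gc_mean``; bases are sampled
    i.i.d. at that composition, which makes CpG density consistent with
    dinucleotide sampling.  Deterministic under the config seed.
    """
    rng = config.rng(stream=1)
    lengths = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    windows = make_windows(lengths, config.window_width)
    sequences = {c: [] for c in lengths}
    for w in windows:
        gc = float(np.clip(rng.normal(config.gc_mean, config.gc_sd), 0.05, 0.95))
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        block = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=w.width, p=p)
        sequences[w.chrom].append(block.tobytes().decode())
    sequences = {c: "".join(parts) for c, parts in sequences.items()}
    annotate_windows(windows, sequences)
    return sequences, windows


def synthesize_window_table(config: SyntheticConfig, n_windows: int | None = None) -> list:
    """Windows with site-class counts set from the expected i.i.d. base
    composition, without materialising a sequence.

    Useful for large-replicate closed-loop studies where only counts per
    window matter; ``generate_genome`` is the sequence-level route.
    """
    rng = config.rng(stream=1)
    if n_windows is None:
        n_windows = (config.n_chroms * config.chrom_length) // config.window_width
    width = config.window_width
    windows = []
    for j in range(n_windows):
        gc = float(np.clip(rng.normal(config.gc_mean, config.gc_sd), 0.05, 0.95))
        # under i.i.d. bases a fraction gc^2/2 of sites sit in CG dinucleotides
        # counted from either side
        n_cpg = int(round(width * 2 * (gc / 2) ** 2))
        n_strong = int(round(width * gc)) - n_cpg
        n_weak = width - n_cpg - n_strong
        windows.append(GenomeWindow(
            chrom="chr1", start=j * width, end=(j + 1) * width, n_sites=width,
            n_cpg_sites=n_cpg, n_strong_noncpg=n_strong, n_weak=n_weak,
            gc_content=gc))
    return windows


def generate_rates(config: SyntheticConfig, windows: list) -> SyntheticTruth:
    """Per-window rate multipliers, equilibrium GC, and recombination map."""
    rng = config.rng(stream=2)
    n = len(windows)
    if config.cv_truth > 0:
        shape = 1.0 / config.cv_truth ** 2
        alpha = rng.gamma(shape, 1.0 / shape, size=n)
    else:
        alpha = np.ones(n)
    fe = np.clip(rng.normal(config.fe_mean, config.fe_sd, size=n), 0.01, 0.99) \
        if config.fe_sd > 0 else np.full(n, config.fe_mean)
    s = config.rr_log_sd
    rr = rng.lognormal(-0.5 * s * s, s, size=n)
    return SyntheticTruth(alpha=alpha, fe=fe, rr=rr)


def _site_counts(windows: list) -> dict:
    return {
        "cpg": np.array([w.n_cpg_sites for w in windows], dtype=float),
        "strong_noncpg": np.array([w.n_strong_noncpg for w in windows], dtype=float),
        "weak": np.array([w.n_weak for w in windows], dtype=float),
    }


def category_expectations(config: SyntheticConfig, truth: SyntheticTruth,
                          windows: list, total: float) -> pd.DataFrame:
    """Per-window per-category expected counts summing to ``total``.

    Expectation is alpha_j x category rate x site-class count, with the
    per-window equilibrium GC shifting the S>W / W>S balance: S>W rates
    scale by (1 - fe_j)/(1 - fe_mean) and W>S rates by fe_j/fe_mean, the
    multiplicative form implied by writing the rates as mu(1 - fe) and
    mu fe.
    """
    sites = _site_counts(windows)
    cols = {}
    for cat in CATEGORIES:
        e = truth.alpha * config.spectrum_truth.rate(cat) * sites[SITE_CLASS[cat]]
        if cat in SW_CATEGORIES:
            e = e * (1.0 - truth.fe) / (1.0 - config.fe_mean)
        elif cat in WS_CATEGORIES:
            e = e * truth.fe / config.fe_mean
        cols[cat] = e
    exp = pd.DataFrame(cols)
    return exp * (total / exp.to_numpy().sum())


def generate_dnms(config: SyntheticConfig, truth: SyntheticTruth, windows: list,
                  sequences: dict, n_total: int | None = None,
                  dataset: str = "synthetic") -> tuple[list, WindowCountMatrix]:
    """Poisson DNMs placed uniformly among eligible sites of each class.

    Returns the event list and the realized per-window count matrix.
    """
    rng = config.rng(stream=3)
    if n_total is None:
        n_total = int(round(config.mean_dnm_per_window * len(windows)))
    exp = category_expectations(config, truth, windows, n_total)
    counts = rng.poisson(exp.to_numpy())

    # per-window site indices by class, from the actual sequence
    events = []
    alt_choices = {
        "CpG_C>T": ("C", "T"), "CpG_C>A": ("C", "A"), "CpG_C>G": ("C", "G"),
        "C>T": ("C", "T"), "C>A": ("C", "A"), "C<>G": ("C", "G"),
        "T>C": ("T", "C"), "T>G": ("T", "G"), "T<>A": ("T", "A"),
    }
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for j, w in enumerate(windows):
        seq = sequences[w.chrom][w.start:w.end]
        arr = np.frombuffer(seq.encode(), dtype="S1")
        is_c, is_g = arr == b"C", arr == b"G"
        cpg = np.zeros(arr.size, dtype=bool)
        if arr.size > 1:
            cg = is_c[:-1] & is_g[1:]
            cpg[:-1] |= cg
            cpg[1:] |= cg
        idx_by_class = {
            "cpg": np.flatnonzero(cpg),
            "strong_noncpg": np.flatnonzero((is_c | is_g) & ~cpg),
            "weak": np.flatnonzero((arr == b"A") | (arr == b"T")),
        }
        for k, cat in enumerate(CATEGORIES):
            c = counts[j, k]
            if c == 0:
                continue
            pool = idx_by_class[SITE_CLASS[cat]]
            if pool.size == 0:
                counts[j, k] = 0  # no eligible site; drop (logged by totals)
                continue
            ref_c, alt_c = alt_choices[cat]
            for pos0 in rng.choice(pool, size=c, replace=True):
                base = arr[pos0].decode()
                ref, alt = (ref_c, alt_c) if base == ref_c else (comp[ref_c], comp[alt_c])
                cohort = "young" if rng.random() < config.frac_young_fathers else "old"
                events.append(MutationEvent(
                    chrom=w.chrom, pos=w.start + int(pos0) + 1, ref=ref, alt=alt,
                    dataset=dataset, paternal_age_cohort=cohort))
    if n_total > sum(w.n_sites for w in windows):
        raise ValueError("requested more DNMs than eligible sites")
    matrix = WindowCountMatrix(windows=list(windows),
                               counts=pd.DataFrame(counts, columns=list(CATEGORIES)))
    return events, matrix


def fixation_factor(b: np.ndarray) -> np.ndarray:
    """Diffusion fixation-bias factor 4B / (1 - exp(-4B)), stable at B ~ 0.

    Positive B favours fixation (W>S under gBGC), negative B disfavours
    it; B = 0 gives exactly 1.
    """
    b = np.asarray(b, dtype=float)
    out = np.empty_like(b)
    small = np.abs(b) < 1e-8
    out[small] = 1.0 + 2.0 * b[small]
    x = 4.0 * b[~small]
    out[~small] = x / (-np.expm1(-x))
    return out


def generate_substitutions(config: SyntheticConfig, truth: SyntheticTruth,
                           windows: list, total: float | None = None,
                           bgc_strength: float | None = None,
                           stream: int = 4) -> WindowCountMatrix:
    """Per-window per-category substitution counts: DNM expectations times
    a recombination-dependent fixation factor.

    B(r) = bgc_strength x (rr / mean rr) applies with positive sign to
    W>S categories, negative to S>W, and not at all to GC-conserving
    ones; bgc_strength = 0 reduces every factor to 1.
    """
    rng = config.rng(stream=stream)
    if total is None:
        total = config.mean_sub_per_window * len(windows)
    if bgc_strength is None:
        bgc_strength = config.bgc_strength
    exp = category_expectations(config, truth, windows, total)
    b = bgc_strength * truth.rr / truth.rr.mean()
    factors = {}
    for cat in CATEGORIES:
        if cat in WS_CATEGORIES:
            f = fixation_factor(b)
        elif cat in SW_CATEGORIES:
            f = fixation_factor(-b)
        else:
            f = np.ones_like(b)
        factors[cat] = f
    fdf = pd.DataFrame(factors)
    exp = exp * fdf
    exp = exp * (total / exp.to_numpy().sum())
    truth.fixation_factor = fdf
    counts = rng.poisson(exp.to_numpy())
    return WindowCountMatrix(windows=list(windows),
                             counts=pd.DataFrame(counts, columns=list(CATEGORIES)))


def generate_snps(config: SyntheticConfig, truth: SyntheticTruth,
                  windows: list) -> WindowCountMatrix:
    """SNP counts: same machinery as substitutions with a diluted bias
    (segregating variants have felt gBGC for less time) and its own total."""
    return generate_substitutions(
        config, truth, windows,
        total=config.mean_snp_per_window * len(windows),
        bgc_strength=config.bgc_strength * config.snp_bgc_scale, stream=5)


def generate_covariates(config: SyntheticConfig, truth: SyntheticTruth,
                        windows: list) -> CovariateTable:
    """Features loaded on the standardized latent log rate plus noise,
    with the recombination map as its own column."""
    rng = config.rng(stream=6)
    log_alpha = np.log(truth.alpha) if np.ptp(truth.alpha) > 0 else truth.alpha * 0.0
    z = ((log_alpha - log_alpha.mean()) / log_alpha.std(ddof=0)
         if np.ptp(log_alpha) > 0 else np.zeros_like(log_alpha))
    cols = {}
    for name, loading in config.covariate_loadings.items():
        cols[name] = loading * z + rng.normal(0.0, config.covariate_noise_sd, z.size)
    cols["recombination_rate"] = truth.rr
    cols["gc_content"] = np.array([w.gc_content for w in windows])
    meta = pd.DataFrame({"chrom": [w.chrom for w in windows],
                         "start": [w.start for w in windows],
                         "end": [w.end for w in windows]})
    return CovariateTable(features=pd.DataFrame(cols), windows=meta)


@dataclass
class SyntheticStudy:
    """A complete generated study with its ground truth."""

    config: SyntheticConfig
    sequences: dict
    windows: list
    truth: SyntheticTruth
    events: list
    dnm_counts: WindowCountMatrix
    substitutions: WindowCountMatrix
    snps: WindowCountMatrix
    covariates: CovariateTable

    @property
    def site_counts(self) -> dict:
        return _site_counts(self.windows)


def generate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Run every generator in sequence and return the bundled study."""
    sequences, windows = generate_genome(config)
    truth = generate_rates(config, windows)
    events, dnm_counts = generate_dnms(config, truth, windows, sequences)
    substitutions = generate_substitutions(config, truth, windows)
    snps = generate_snps(config, truth, windows)
    covariates = generate_covariates(config, truth, windows)
    return SyntheticStudy(config=config, sequences=sequences, windows=windows,
                          truth=truth, events=events, dnm_counts=dnm_counts,
                          substitutions=substitutions, snps=snps,
                          covariates=covariates)


def write_study(study: SyntheticStudy, outdir) -> None:
    """Write the study in the formats the pipeline reads (FASTA, VCF/TSV,
    count TSVs, covariate TSV, truth JSON)."""
    from pathlib import Path

    from . import windows_io
    from .covariate_analysis import write_covariates

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    windows_io.write_fasta(study.sequences, outdir / "genome.fa")
    windows_io.write_dnms_vcf(study.events, outdir / "dnms.vcf")
    windows_io.write_dnms_tsv(study.events, outdir / "dnms.tsv")
    windows_io.write_counts(study.dnm_counts, outdir / "dnm_counts.tsv")
    windows_io.write_counts(study.substitutions, outdir / "substitutions.tsv")
    windows_io.write_counts(study.snps, outdir / "snps.tsv")
    write_covariates(study.covariates, outdir / "covariates.tsv")
    study.truth.to_json(outdir / "truth.json")
    with open(outdir / "config.json", "w") as fh:
        cfg = asdict(study.config)
        cfg["spectrum_truth"] = study.config.spectrum_truth.rates
        json.dump(cfg, fh, indent=1)
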