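"""Generate the synthetic study every downstream analysis step consumes.

Writes a toy genome (FASTA), DNM calls (VCF + TSV), windowed DNM /
substitution / SNP count tables, genomic covariates, and the generator's
ground truth to results/study/.  The study emulates the statistical
regime of large trio-sequencing datasets: ~40 DNMs per window, a
rate-multiplier CV of 0.18, CpG-elevated spectrum, equilibrium GC 0.32.
A second study with a recombination-dependent fixation bias switched on
(results/study_bgc/) feeds the biased-gene-conversion slope test.
"""

from pathlib import Path

from mutscape.synthetic_data import SyntheticConfig, generate_study, write_study

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"

BASE = SyntheticConfig(n_chroms=2, chrom_length=2_500_000, window_width=50_000,
                       seed=1)
BGC = SyntheticConfig(n_chroms=2, chrom_length=2_500_000, window_width=20_000,
                      bgc_strength=0.5, seed=2)


def main():
    for name, config in (("study", BASE), ("study_bgc", BGC)):
        study = generate_study(config)
        outdir = ROOT / "scratch" / name
        write_study(study, outdir)
        print(f"{name}: {len(study.windows)} windows of {config.window_width:,} bp, "
              f"{len(study.events)} DNMs, "
              f"{int(study.substitutions.counts.to_numpy().sum())} substitutions, "
              f"bgc_strength={config.bgc_strength} -> {outdir}")


if __name__ == "__main__":
    main()
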