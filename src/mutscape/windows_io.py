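"""Genome windows, mutation categories, and per-window count tabulation.

De novo mutations (DNMs) are classified into nine strand-collapsed
categories.  CpG dinucleotides are hypermutable for C>T (deamination of
methylated cytosine), so mutations at CpG sites form their own three
categories; the remaining six cover non-CpG changes with C or T as the
collapsed reference base.  Because we cannot tell which strand a mutation
occurred on, G>A is counted as C>T, A>G as T>C, and so on; the two
strand-symmetric transversions C>G/G>C and T>A/A>T collapse onto single
categories written ``C<>G`` and ``T<>A``.

Each category has a natural denominator (its site class): CpG categories
use CpG sites, C categories use non-CpG strong (G:C) sites, and T
categories use weak (A:T) sites.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The nine strand-collapsed mutation categories, in canonical order.
CATEGORIES = (
    "CpG_C>T", "CpG_C>A", "CpG_C>G",
    "C>T", "T>C", "C>A", "T>G", "C<>G", "T<>A",
)

#: Site class (denominator) per category.
SITE_CLASS = {
    "CpG_C>T": "cpg", "CpG_C>A": "cpg", "CpG_C>G": "cpg",
    "C>T": "strong_noncpg", "C>A": "strong_noncpg", "C<>G": "strong_noncpg",
    "T>C": "weak", "T>G": "weak", "T<>A": "weak",
}

#: Strong-to-weak categories (lose a G:C pair), weak-to-strong, and
#: GC-conserving ones.  C>G at a CpG is S>S and therefore GC-conserving.
SW_CATEGORIES = ("CpG_C>T", "CpG_C>A", "C>T", "C>A")
WS_CATEGORIES = ("T>C", "T>G")
NEUTRAL_CATEGORIES = ("CpG_C>G", "C<>G", "T<>A")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class GenomeWindow:
    """One half-open genomic interval [start, end) with site-class counts.

    ``n_sites`` counts non-ambiguous bases and is the window length ``l``
    used as the Poisson offset; ``callable_weight`` (summed callable
    trios) replaces it when present.
    """

    chrom: str
    start: int
    end: int
    n_sites: int = 0
    n_cpg_sites: int = 0
    n_strong_noncpg: int = 0
    n_weak: int = 0
    gc_content: float = float("nan")
    covariates: dict = field(default_factory=dict)
    callable_weight: float | None = None
    partial: bool = False

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty window {self.chrom}:{self.start}-{self.end}")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MutationEvent:
    """A single de novo mutation (1-based position, autosomal SNV)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    dataset: str = ""
    paternal_age_cohort: str | None = None

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError("ref == alt")
        if self.ref not in "ACGT" or self.alt not in "ACGT":
            raise ValueError(f"non-ACGT allele {self.ref}>{self.alt}")


@dataclass
class WindowCountMatrix:
    """Per-window per-category DNM counts over an ordered window list."""

    windows: list
    counts: pd.DataFrame  # n_windows x 9, columns = CATEGORIES
    dropped: dict = field(default_factory=dict)

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def site_counts(self, site_class: str) -> np.ndarray:
        attr = {"cpg": "n_cpg_sites", "strong_noncpg": "n_strong_noncpg",
                "weak": "n_weak", "all": "n_sites"}[site_class]
        return np.array([getattr(w, attr) for w in self.windows], dtype=float)

    def offsets(self, category: str | None = None, kind: str = "sites") -> np.ndarray:
        """Denominator per window: the category's site class, or callable weights."""
        if kind == "callable":
            off = np.array([w.callable_weight for w in self.windows], dtype=float)
            if np.any(~np.isfinite(off)):
                raise ValueError("callable offsets requested but not set on all windows")
            return off
        if category is None:
            return self.site_counts("all")
        return self.site_counts(SITE_CLASS[category])


def make_windows(chrom_lengths: dict, width: int) -> list:
    """Tile each chromosome with non-overlapping half-open windows.

    A trailing window shorter than ``width`` is emitted with
    ``partial=True``.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    if not chrom_lengths:
        raise ValueError("empty chromosome map")
    windows = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"non-positive length for {chrom}")
        for start in range(0, length, width):
            end = min(start + width, length)
            windows.append(GenomeWindow(chrom, start, end, partial=(end - start) < width))
    return windows


def classify_mutation(ref: str, alt: str, left: str = "N", right: str = "N") -> str:
    """Strand-collapsed category of a single-base change given its
    reference context.

    A site is CpG-context if it is the C of a CG dinucleotide, or the G
    preceded by C, on the reference.  N context bases are allowed and make
    CpG context impossible.
    """
    ref, alt, left, right = ref.upper(), alt.upper(), left.upper(), right.upper()
    if ref == "N":
        raise ValueError("ref base is N")
    if ref == alt:
        raise ValueError("ref == alt")
    for b in (ref, alt):
        if b not in "ACGT":
            raise ValueError(f"invalid base {b!r}")
    if left not in "ACGTN" or right not in "ACGTN":
        raise ValueError("invalid context base")
    if ref in "GA":  # collapse onto the C/T strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        left, right = _COMPLEMENT[right], _COMPLEMENT[left]
    if ref == "C":
        cpg = right == "G"
        if cpg:
            return f"CpG_C>{alt}"
        return "C<>G" if alt == "G" else f"C>{alt}"
    else:  # ref == "T"
        return "T<>A" if alt == "A" else f"T>{alt}"


def count_context_sites(sequence: str) -> tuple[int, int, int, int]:
    """Count (CpG, non-CpG strong, weak, ambiguous) sites in a sequence.

    Both the C and the G of every CG dinucleotide are CpG sites; in
    ``CGCG`` all four bases are CpG.  N bases are ambiguous and belong to
    no class.
    """
    if not sequence:
        return (0, 0, 0, 0)
    arr = np.frombuffer(sequence.upper().encode(), dtype="S1")
    is_c = arr == b"C"
    is_g = arr == b"G"
    cpg = np.zeros(arr.size, dtype=bool)
    if arr.size > 1:
        cg = is_c[:-1] & is_g[1:]
        cpg[:-1] |= cg
        cpg[1:] |= cg
    strong = is_c | is_g
    weak = (arr == b"A") | (arr == b"T")
    n_cpg = int(cpg.sum())
    n_strong_noncpg = int((strong & ~cpg).sum())
    n_weak = int(weak.sum())
    n_ambiguous = int(arr.size - strong.sum() - n_weak)
    return (n_cpg, n_strong_noncpg, n_weak, n_ambiguous)


def annotate_windows(windows: list, reference: dict) -> list:
    """Fill site-class counts and GC content from reference sequence."""
    for w in windows:
        seq = str(reference[w.chrom][w.start:w.end])
        n_cpg, n_strong, n_weak, _ = count_context_sites(seq)
        w.n_cpg_sites = n_cpg
        w.n_strong_noncpg = n_strong
        w.n_weak = n_weak
        w.n_sites = n_cpg + n_strong + n_weak
        w.gc_content = (n_cpg + n_strong) / w.n_sites if w.n_sites else float("nan")
    return windows


def tabulate_counts(events: list, windows: list, reference: dict,
                    max_mismatch_frac: float = 0.01) -> WindowCountMatrix:
    """Classify each DNM against the reference and assign it to its window.

    Events on unknown chromosomes, at reference N bases, or whose stated
    ref allele disagrees with the reference are dropped and tallied; more
    than ``max_mismatch_frac`` ref-allele disagreement raises.
    """
    by_chrom: dict[str, list] = {}
    for idx, w in enumerate(windows):
        by_chrom.setdefault(w.chrom, []).append((w.start, w.end, idx))
    starts = {c: [t[0] for t in lst] for c, lst in by_chrom.items()}

    counts = np.zeros((len(windows), len(CATEGORIES)), dtype=int)
    cat_index = {c: i for i, c in enumerate(CATEGORIES)}
    dropped = {"unknown_chrom": 0, "no_window": 0, "ref_N": 0, "ref_mismatch": 0}
    n_checked = 0
    for ev in events:
        if ev.chrom not in by_chrom or ev.chrom not in reference:
            dropped["unknown_chrom"] += 1
            continue
        pos0 = ev.pos - 1
        seq = reference[ev.chrom]
        ref_base = str(seq[pos0]).upper()
        left = str(seq[pos0 - 1]).upper() if pos0 > 0 else "N"
        right = str(seq[pos0 + 1]).upper() if pos0 + 1 < len(seq) else "N"
        if ref_base == "N":
            dropped["ref_N"] += 1
            continue
        n_checked += 1
        if ref_base != ev.ref:
            dropped["ref_mismatch"] += 1
            continue
        lst, st = by_chrom[ev.chrom], starts[ev.chrom]
        i = bisect_right(st, pos0) - 1
        if i < 0 or not (lst[i][0] <= pos0 < lst[i][1]):
            dropped["no_window"] += 1
            continue
        counts[lst[i][2], cat_index[classify_mutation(ev.ref, ev.alt, left, right)]] += 1
    if n_checked and dropped["ref_mismatch"] / n_checked > max_mismatch_frac:
        raise ValueError(
            f"{dropped['ref_mismatch']}/{n_checked} events disagree with the "
            "reference allele; check coordinate system or reference build")
    if any(dropped.values()):
        logger.info("tabulate_counts dropped events: %s", dropped)
    return WindowCountMatrix(
        windows=list(windows),
        counts=pd.DataFrame(counts, columns=list(CATEGORIES)),
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# File formats


def read_fasta(path) -> dict:
    """Reference sequences as a dict chrom -> string."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict, path) -> None:
    recs = [SeqRecord(Seq(s), id=c, description="") for c, s in sequences.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_dnms(path) -> list:
    """Read DNMs from a TSV (chrom, pos, ref, alt[, dataset, paternal_age_cohort])
    or an uncompressed VCF (INFO keys DATASET and AGE_COHORT recognised).

    Indel and multi-allelic records are dropped with a logged count.
    """
    path = Path(path)
    events, n_dropped = [], 0
    if path.suffix == ".vcf":
        from cyvcf2 import VCF

        for var in VCF(str(path)):
            if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
                n_dropped += 1
                continue
            events.append(MutationEvent(
                chrom=var.CHROM, pos=var.POS, ref=var.REF, alt=var.ALT[0],
                dataset=var.INFO.get("DATASET") or "",
                paternal_age_cohort=var.INFO.get("AGE_COHORT"),
            ))
    else:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        for row in df.itertuples(index=False):
            if len(row.ref) != 1 or len(row.alt) != 1:
                n_dropped += 1
                continue
            events.append(MutationEvent(
                chrom=str(row.chrom), pos=int(row.pos), ref=row.ref, alt=row.alt,
                dataset=str(getattr(row, "dataset", "") or ""),
                paternal_age_cohort=(getattr(row, "paternal_age_cohort", None) or None),
            ))
    if n_dropped:
        logger.info("read_dnms dropped %d indel/multi-allelic records", n_dropped)
    return events


def write_dnms_vcf(events: list, path) -> None:
    """Write DNMs as a minimal uncompressed VCF."""
    chroms = sorted({e.chrom for e in events})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DATASET,Number=1,Type=String,Description="Source dataset">\n')
        fh.write('##INFO=<ID=AGE_COHORT,Number=1,Type=String,Description="Paternal age cohort">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for e in sorted(events, key=lambda e: (e.chrom, e.pos)):
            info = []
            if e.dataset:
                info.append(f"DATASET={e.dataset}")
            if e.paternal_age_cohort:
                info.append(f"AGE_COHORT={e.paternal_age_cohort}")
            fh.write(f"{e.chrom}\t{e.pos}\t.\t{e.ref}\t{e.alt}\t.\t.\t{';'.join(info) or '.'}\n")


def write_dnms_tsv(events: list, path) -> None:
    pd.DataFrame(
        [{"chrom": e.chrom, "pos": e.pos, "ref": e.ref, "alt": e.alt,
          "dataset": e.dataset, "paternal_age_cohort": e.paternal_age_cohort or ""}
         for e in events]
    ).to_csv(path, sep="\t", index=False)


_WINDOW_COLS = ["chrom", "start", "end", "n_sites", "n_cpg_sites",
                "n_strong_noncpg", "n_weak", "gc_content", "partial"]


def write_counts(matrix: WindowCountMatrix, path) -> None:
    """WindowCountMatrix as a TSV with window metadata + the 9 category columns."""
    meta = pd.DataFrame(
        [{"chrom": w.chrom, "start": w.start, "end": w.end, "n_sites": w.n_sites,
          "n_cpg_sites": w.n_cpg_sites, "n_strong_noncpg": w.n_strong_noncpg,
          "n_weak": w.n_weak, "gc_content": w.gc_content, "partial": int(w.partial)}
         for w in matrix.windows]
    )
    pd.concat([meta, matrix.counts.reset_index(drop=True)], axis=1).to_csv(
        path, sep="\t", index=False)


def read_counts(path) -> WindowCountMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    windows = [
        GenomeWindow(chrom=str(r.chrom), start=int(r.start), end=int(r.end),
                     n_sites=int(r.n_sites), n_cpg_sites=int(r.n_cpg_sites),
                     n_strong_noncpg=int(r.n_strong_noncpg), n_weak=int(r.n_weak),
                     gc_content=float(r.gc_content), partial=bool(r.partial))
        for r in df.itertuples(index=False)
    ]
    return WindowCountMatrix(windows=windows, counts=df[list(CATEGORIES)].astype(int))


def filter_windows(matrix: WindowCountMatrix, min_fraction: float = 0.5,
                   width: int | None = None) -> WindowCountMatrix:
    """Drop windows with fewer than ``min_fraction`` usable sites.

    Mirrors the convention of excluding windows where less than half the
    window has usable data; ``width`` defaults to the modal window width.
    """
    if width is None:
        width = int(np.median([w.width for w in matrix.windows]))
    keep = [i for i, w in enumerate(matrix.windows) if w.n_sites >= min_fraction * width]
    return WindowCountMatrix(
        windows=[matrix.windows[i] for i in keep],
        counts=matrix.counts.iloc[keep].reset_index(drop=True),
        dropped=dict(matrix.dropped),
    )
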