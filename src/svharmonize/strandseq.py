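"""Strand-seq inversion discovery, genotyping and phase classification.

A composite file pools oriented reads from many single cells of one
individual; inside an inverted locus reads align opposite to the reference,
so the non-reference read fraction (read ratio) is ~0 on reference
homozygotes, ~0.5 on heterozygotes and ~1 on inverted homozygotes, with
inverted duplications sitting at depressed intermediate ratios. Discovery
slides a 250-read window and keeps regions whose windows exceed a 15%
non-reference trigger; each locus is genotyped by exact binomial model
comparison against non-reference proportions {b, 0.5, 1-b} with background
b = 2%, and classified (simple hom/het vs complex, with phase for simple
hets) from per-strand H1:H2 haplotype ratios of phased reads.

Composite files follow the DataFrame contract of
:mod:`svharmonize.synthetic` (columns chrom, pos, nonref, hap).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .core import chain_by_ro

HAP_UNTAGGED, HAP_H1, HAP_H2 = 0, 1, 2

GENOTYPES = ("hom_ref", "het", "hom_inv", "untyped")
CLASSES = ("simple_hom", "simple_het", "complex", "unclassified")


class EmptyLocusError(ValueError):
    """Read ratio is undefined for an interval containing no reads."""


@dataclass
class SegmentationParams:
    """Discovery/genotyping thresholds with their published defaults.

    ``window_reads`` is the sliding window size in reads; ``nonref_trigger``
    the non-reference fraction a window must exceed; ``background`` the
    orientation-error level b allowed in the homozygous states;
    ``min_genotype_reads`` / ``min_phased_reads`` the minimum total / phased
    reads to genotype and to define a haplotype ratio; (hap_lo, hap_hi) the
    haplotype-ratio bounds separating "single haplotype" from "both".
    ``window_step`` and the refine_* fields are implementation resolution
    knobs: windows advance by ``window_step`` reads, and candidate boundaries
    are refined with a small ``refine_window``-read scan before trimming to
    the first/last non-reference read. ``reject_alpha``, when set, untypes a
    locus whose best genotype model is rejected by a two-sided exact test.
    """

    window_reads: int = 250
    window_step: int = 50
    nonref_trigger: float = 0.15
    background: float = 0.02
    min_genotype_reads: int = 50
    min_phased_reads: int = 10
    hap_lo: float = 0.25
    hap_hi: float = 0.75
    reject_alpha: float | None = None
    refine_window: int = 25
    refine_trigger: float = 0.25

    def __post_init__(self) -> None:
        if not 0 < self.nonref_trigger < 1:
            raise ValueError("nonref_trigger must be in (0, 1)")
        if not self.hap_lo < self.hap_hi:
            raise ValueError("hap_lo must be < hap_hi")
        if not 0 < self.background < 0.5:
            raise ValueError("background must be in (0, 0.5)")


@dataclass
class CandidateLocus:
    chrom: str
    start: int
    end: int
    n_ref: int
    n_nonref: int

    def __post_init__(self) -> None:
        if self.n_ref < 0 or self.n_nonref < 0:
            raise ValueError("counts must be >= 0")
        if self.n_ref + self.n_nonref == 0:
            raise EmptyLocusError(f"no reads in {self.chrom}:{self.start}-{self.end}")

    @property
    def total(self) -> int:
        return self.n_ref + self.n_nonref

    @property
    def read_ratio(self) -> float:
        return self.n_nonref / self.total

    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class GenotypeResult:
    genotype: str
    loglik: dict[str, float] = field(default_factory=dict)
    pvalues: dict[str, float] = field(default_factory=dict)
    best_model: str | None = None


@dataclass
class GenotypedInversion:
    locus: CandidateLocus
    genotype: str
    hap_ratio_ref_strand: float | None = None
    hap_ratio_nonref_strand: float | None = None
    cls: str = "unclassified"
    phase: str | None = None  # "1/0" (H1 carrier) | "0/1" (H2 carrier)
    reason: str | None = None

    def __post_init__(self) -> None:
        if self.phase is not None and self.cls != "simple_het":
            raise ValueError("phase is defined only for simple_het")

    def interval(self) -> tuple[str, int, int]:
        return self.locus.interval()


def _chrom_arrays(reads: pd.DataFrame, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sub = reads[reads["chrom"] == chrom]
    return (sub["pos"].to_numpy(), sub["nonref"].to_numpy(), sub["hap"].to_numpy())


def compute_read_ratio(reads: pd.DataFrame, chrom: str, start: int, end: int) -> CandidateLocus:
    """Count reads by orientation over a half-open interval."""
    if end <= start:
        raise ValueError("interval must be non-empty")
    pos, nonref, _ = _chrom_arrays(reads, chrom)
    lo, hi = np.searchsorted(pos, [start, end])
    n_nonref = int(nonref[lo:hi].sum())
    return CandidateLocus(chrom, start, end, int(hi - lo) - n_nonref, n_nonref)


def segment_composite(reads: pd.DataFrame, params: SegmentationParams | None = None) -> list[CandidateLocus]:
    """Locate candidate inversion loci by a sliding-window read-ratio scan.

    Windows of ``window_reads`` consecutive reads advance by ``window_step``;
    maximal runs of triggering windows (non-reference fraction above
    ``nonref_trigger``) merge into one candidate. Boundaries are then
    sharpened inside the run with a ``refine_window``-read scan at
    ``refine_trigger`` and trimmed to the first/last non-reference read.
    Chromosomes with fewer than ``window_reads`` reads yield no candidates.
    """
    params = params or SegmentationParams()
    W, step = params.window_reads, params.window_step
    out: list[CandidateLocus] = []
    for chrom in sorted(reads["chrom"].unique()):
        pos, nonref, _ = _chrom_arrays(reads, chrom)
        n = len(pos)
        if n < W:
            continue
        nr = nonref.astype(np.int64)
        csum = np.concatenate([[0], np.cumsum(nr)])
        starts = np.arange(0, n - W + 1, step)
        ratios = (csum[starts + W] - csum[starts]) / W
        trig = ratios > params.nonref_trigger
        runs: list[tuple[int, int]] = []  # read-index spans of merged windows
        for s in starts[trig]:
            if runs and s <= runs[-1][1]:
                runs[-1] = (runs[-1][0], s + W)
            else:
                runs.append((s, s + W))
        for a, b in runs:
            lo, hi = _refine_run(nr, a, b, params)
            idx = np.nonzero(nr[lo:hi])[0]
            if len(idx) == 0:
                continue
            s_idx, e_idx = lo + idx[0], lo + idx[-1]
            n_nonref = int(nr[s_idx : e_idx + 1].sum())
            total = int(e_idx + 1 - s_idx)
            out.append(CandidateLocus(chrom, int(pos[s_idx]), int(pos[e_idx]) + 1, total - n_nonref, n_nonref))
    return out


def _refine_run(nr: np.ndarray, a: int, b: int, params: SegmentationParams) -> tuple[int, int]:
    w2 = params.refine_window
    if b - a < max(w2 + 1, 2):
        return a, b
    sub = nr[a:b]
    c = np.concatenate([[0], np.cumsum(sub)])
    ratios = (c[w2:] - c[:-w2]) / w2
    mask = ratios >= params.refine_trigger
    if not mask.any():
        return a, b
    first = int(np.argmax(mask))
    last = int(len(mask) - 1 - np.argmax(mask[::-1]))
    return a + first, min(b, a + last + w2)


def genotype_locus(
    n_ref: int, n_nonref: int, params: SegmentationParams | None = None, min_reads: int | None = None
) -> GenotypeResult:
    """Genotype a locus by exact-binomial model comparison.

    The observed (n_ref, n_nonref) is scored against three expected
    non-reference proportions {b, 0.5, 1-b} (hom_ref, het, hom_inv), allowing
    a background level b in the homozygous states; the genotype is the model
    of maximal exact binomial likelihood, with a two-sided exact test p-value
    reported against each model. Fewer than ``min_reads`` total reads (the
    module's min_genotype_reads by default) leaves the locus untyped, as does
    rejection of the best model at ``params.reject_alpha`` when enabled.
    """
    params = params or SegmentationParams()
    if n_ref < 0 or n_nonref < 0:
        raise ValueError("counts must be >= 0")
    total = n_ref + n_nonref
    threshold = params.min_genotype_reads if min_reads is None else min_reads
    b = params.background
    models = {"hom_ref": b, "het": 0.5, "hom_inv": 1.0 - b}
    if total < threshold:
        return GenotypeResult("untyped")
    loglik = {name: float(stats.binom.logpmf(n_nonref, total, p)) for name, p in models.items()}
    pvalues = {name: float(stats.binomtest(n_nonref, total, p).pvalue) for name, p in models.items()}
    best = max(models, key=lambda name: (loglik[name], name == "hom_ref", name == "het"))
    genotype = best
    if params.reject_alpha is not None and pvalues[best] < params.reject_alpha:
        genotype = "untyped"
    return GenotypeResult(genotype, loglik, pvalues, best_model=best)


def compute_haplotype_ratios(
    reads: pd.DataFrame, chrom: str, start: int, end: int, params: SegmentationParams | None = None
) -> tuple[float | None, float | None]:
    """Per-strand H1 fraction among phased reads over an interval.

    For each orientation independently, the ratio is #H1 / (#H1 + #H2) among
    haplotagged reads of that orientation; it is undefined (None) with fewer
    than ``min_phased_reads`` tagged reads on that strand.
    """
    params = params or SegmentationParams()
    if end <= start:
        raise ValueError("interval must be non-empty")
    pos, nonref, hap = _chrom_arrays(reads, chrom)
    lo, hi = np.searchsorted(pos, [start, end])
    nonref = nonref[lo:hi]
    hap = hap[lo:hi]
    out: list[float | None] = []
    for strand_mask in (~nonref, nonref):  # reference strand, then non-reference strand
        h1 = int(((hap == HAP_H1) & strand_mask).sum())
        h2 = int(((hap == HAP_H2) & strand_mask).sum())
        out.append(h1 / (h1 + h2) if h1 + h2 >= params.min_phased_reads else None)
    return out[0], out[1]


def classify_inversion(
    genotype: str,
    hap_ratio_ref_strand: float | None,
    hap_ratio_nonref_strand: float | None,
    params: SegmentationParams | None = None,
) -> tuple[str, str | None, str | None]:
    """Classify a genotyped locus from its per-strand haplotype ratios.

    simple_hom: homozygous genotype with both haplotypes on the non-reference
    strand (ratio strictly between hap_lo and hap_hi). simple_het:
    heterozygous with opposite single haplotypes on the two strands (> hap_hi
    on one, < hap_lo on the other); the phase follows the non-reference
    strand (ratio > hap_hi => carrier H1, "1/0"; < hap_lo => H2, "0/1").
    complex (inverted duplication): heterozygous with a single haplotype on
    the non-reference strand but both haplotypes on the reference strand.
    Returns (class, phase, reason); loci matching no signature or missing a
    required ratio are unclassified with a reason code.
    """
    params = params or SegmentationParams()
    lo, hi = params.hap_lo, params.hap_hi
    rr, rn = hap_ratio_ref_strand, hap_ratio_nonref_strand
    if genotype == "untyped":
        return ("unclassified", None, "untyped_genotype")
    if genotype == "hom_ref":
        return ("unclassified", None, "reference_genotype")
    if genotype == "hom_inv":
        if rn is None:
            return ("unclassified", None, "nonref_ratio_undefined")
        if lo < rn < hi:
            return ("simple_hom", None, None)
        return ("unclassified", None, "hom_with_single_haplotype_nonref")
    # heterozygous
    if rn is None:
        return ("unclassified", None, "nonref_ratio_undefined")
    if rr is None:
        return ("unclassified", None, "ref_ratio_undefined")
    if (rr > hi and rn < lo) or (rr < lo and rn > hi):
        return ("simple_het", "1/0" if rn > hi else "0/1", None)
    if (rn < lo or rn > hi) and lo < rr < hi:
        return ("complex", None, None)
    return ("unclassified", None, "no_signature")


def discover_inversions(
    reads: pd.DataFrame, params: SegmentationParams | None = None
) -> list[GenotypedInversion]:
    """Full per-individual discovery: segment, genotype, phase-classify."""
    params = params or SegmentationParams()
    out: list[GenotypedInversion] = []
    for locus in segment_composite(reads, params):
        g = genotype_locus(locus.n_ref, locus.n_nonref, params)
        rr, rn = compute_haplotype_ratios(reads, locus.chrom, locus.start, locus.end, params)
        cls, phase, reason = classify_inversion(g.genotype, rr, rn, params)
        out.append(GenotypedInversion(locus, g.genotype, rr, rn, cls, phase, reason))
    return out


def flag_misorients(
    per_individual: dict[str, list[GenotypedInversion]], ro_min: float = 0.5
) -> list[list[tuple[str, GenotypedInversion]]]:
    """Flag loci homozygous-inverted in every individual (assembly misorients).

    Loci are matched across individuals at >= 50% reciprocal overlap
    (single linkage); a matched locus present in all individuals and
    genotyped hom_inv in each is flagged for removal.
    """
    if len(per_individual) < 2:
        raise ValueError("misorient flagging needs >= 2 individuals")
    entries: list[tuple[str, GenotypedInversion]] = [
        (ind, inv) for ind, invs in sorted(per_individual.items()) for inv in invs
    ]
    if not entries:
        return []
    groups = chain_by_ro([e[1].interval() for e in entries], ro_min, strict=False)
    flagged: list[list[tuple[str, GenotypedInversion]]] = []
    all_individuals = set(per_individual)
    for grp in groups:
        members = [entries[i] for i in grp]
        if {m[0] for m in members} == all_individuals and all(m[1].genotype == "hom_inv" for m in members):
            flagged.append(members)
    return flagged


def remove_flagged(
    per_individual: dict[str, list[GenotypedInversion]],
    flagged: list[list[tuple[str, GenotypedInversion]]],
) -> dict[str, list[GenotypedInversion]]:
    """Drop flagged loci from each individual's callset."""
    drop = {id(inv) for cluster in flagged for _, inv in cluster}
    return {ind: [inv for inv in invs if id(inv) not in drop] for ind, invs in per_individual.items()}
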