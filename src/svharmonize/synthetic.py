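"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the multi-platform trio setting at desk scale: a small
multi-chromosome genome with annotation tracks and phased het SNVs, planted
simple and complex (inverted-duplication) inversions, Strand-seq composite
files of oriented and optionally haplotagged reads, per-caller SV callsets
with platform-specific breakpoint jitter and false positives, and validation
evidence (supporting-read counts, optical-map lengths, coverage profiles).

Every generator is deterministic for a fixed seed and draws from a labeled
RNG substream, so module outputs are independent of call order.

Data contract for composite files: a pandas DataFrame sorted by
(chrom, pos) with columns

    chrom : str          reference chromosome
    pos   : int64        5' position (reads are modeled as points)
    nonref: bool         True when the read aligns opposite to the reference
    hap   : int8         0 = untagged, 1 = H1, 2 = H2

:data:`HAP_LABELS` maps the integer codes to the field's H1/H2/untagged terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import SVCall, derive_rng, merge_intervals, overlap_len
from .validate import SupportEvidence

HAP_UNTAGGED, HAP_H1, HAP_H2 = 0, 1, 2
HAP_LABELS = {HAP_UNTAGGED: "untagged", HAP_H1: "H1", HAP_H2: "H2"}

COMPOSITE_COLUMNS = ["chrom", "pos", "nonref", "hap"]


class CapacityError(ValueError):
    """Raised when the requested events cannot be placed without overlap."""


@dataclass
class GenomeModel:
    """Small stand-in for a reference genome plus annotation context.

    Tracks are 0-based half-open, sorted and merged per chromosome. Het SNV
    positions are strictly increasing per chromosome.
    """

    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    centromere_intervals: dict[str, tuple[int, int]]
    tandem_repeat_track: dict[str, list[tuple[int, int]]]
    segdup_track: dict[str, list[tuple[int, int]]]
    het_snv_positions: dict[str, np.ndarray]

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def validate(self) -> None:
        for chrom in self.chrom_names:
            L = self.chrom_lengths[chrom]
            for track in (self.tandem_repeat_track[chrom], self.segdup_track[chrom]):
                for s, e in track:
                    if not (0 <= s < e <= L):
                        raise ValueError(f"track interval ({s},{e}) outside {chrom}")
            snv = self.het_snv_positions[chrom]
            if len(snv) and not (np.all(np.diff(snv) > 0) and snv[0] >= 0 and snv[-1] < L):
                raise ValueError(f"SNV positions not strictly increasing within {chrom}")


@dataclass
class TruthInversion:
    id: str
    chrom: str
    start: int
    end: int
    genotype: str  # het_H1 | het_H2 | hom
    cls: str  # simple | inverted_duplication
    dup_copy_number: int = 0  # extra direct copies; > 0 iff inverted_duplication

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError("inversion length < 1")
        if (self.dup_copy_number > 0) != (self.cls == "inverted_duplication"):
            raise ValueError("dup_copy_number > 0 iff inverted_duplication")

    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    @property
    def carrier_haps(self) -> tuple[int, ...]:
        return {"hom": (HAP_H1, HAP_H2), "het_H1": (HAP_H1,), "het_H2": (HAP_H2,)}[self.genotype]


@dataclass
class TruthSV:
    id: str
    chrom: str
    start: int
    end: int
    type: str  # DEL | INS
    length: int
    zygosity: str  # het_H1 | het_H2 | hom

    def __post_init__(self) -> None:
        if self.type == "DEL" and self.length != self.end - self.start:
            raise ValueError("DEL length must equal interval length")
        if self.type == "INS" and self.end != self.start:
            raise ValueError("INS interval must be a point anchor")


@dataclass
class CallerProfile:
    """Per-caller error model: sensitivity, breakpoint jitter, false positives.

    ``fp_rate`` is expressed in calls per Mb of genome, ``breakpoint_jitter_sd``
    in bp of centered Gaussian noise applied to each breakpoint independently.
    """

    name: str
    sensitivity: float = 1.0
    fp_rate: float = 0.0
    breakpoint_jitter_sd: float = 0.0
    length_bias: float = 1.0
    detectable_types: tuple[str, ...] = ("DEL", "INS", "DUP", "INV")

    def __post_init__(self) -> None:
        if not 0.0 <= self.sensitivity <= 1.0:
            raise ValueError("sensitivity must be in [0, 1]")
        if self.breakpoint_jitter_sd < 0:
            raise ValueError("jitter sd must be >= 0")


def _random_track(rng: np.random.Generator, length: int, density: float, mean_len: float) -> list[tuple[int, int]]:
    if density <= 0:
        return []
    n = int(round(density * length / mean_len))
    if n == 0:
        return []
    starts = rng.integers(0, length, size=n)
    lens = np.maximum(1, rng.exponential(mean_len, size=n).astype(np.int64))
    ivs = [(int(s), int(min(length, s + l))) for s, l in zip(starts, lens)]
    return merge_intervals(ivs)


def generate_genome_model(
    n_chroms: int,
    chrom_length: int,
    tr_density: float = 0.05,
    snv_spacing_mean: float = 1200.0,
    seed: int = 0,
    segdup_density: float = 0.02,
    centromere_fraction: float = 0.05,
) -> GenomeModel:
    """Build a synthetic genome with centromeres, TR/segdup tracks and SNVs.

    SNV spacing is exponential with the given mean (the trio composite files
    carry phased SNVs at a mean spacing of roughly 1.0-1.5 kb). Tandem-repeat
    intervals cover approximately ``tr_density`` of each chromosome.
    """
    if chrom_length < 10**5:
        raise ValueError("chrom_length must be >= 1e5")
    if not 0 <= tr_density < 0.5:
        raise ValueError("tr_density must be in [0, 0.5)")
    if snv_spacing_mean <= 0 or n_chroms < 1:
        raise ValueError("non-positive genome dimensions")
    rng = derive_rng(seed, "genome_model")
    names = [f"chr{i + 1}" for i in range(n_chroms)]
    lengths = {c: int(chrom_length) for c in names}
    cen_half = centromere_fraction / 2
    centromeres = {
        c: (int(chrom_length * (0.5 - cen_half)), int(chrom_length * (0.5 + cen_half))) for c in names
    }
    tr = {c: _random_track(rng, chrom_length, tr_density, 2000.0) for c in names}
    sd = {c: _random_track(rng, chrom_length, segdup_density, 10000.0) for c in names}
    snvs: dict[str, np.ndarray] = {}
    for c in names:
        n_exp = int(chrom_length / snv_spacing_mean * 1.2) + 10
        gaps = rng.exponential(snv_spacing_mean, size=n_exp)
        pos = np.unique(np.cumsum(gaps).astype(np.int64))
        snvs[c] = pos[pos < chrom_length]
    model = GenomeModel(names, lengths, centromeres, tr, sd, snvs)
    model.validate()
    return model


def plant_inversions(
    genome: GenomeModel,
    n: int,
    size_min: int,
    size_max: int,
    hom_fraction: float,
    complex_fraction: float,
    seed: int = 0,
    min_gap: int = 10_000,
) -> list[TruthInversion]:
    """Plant ``n`` non-overlapping inversions with a log-uniform size law.

    Complex events (inverted duplications) are heterozygous by construction;
    among the rest, the hom draw is conditioned so the overall hom count is
    Binomial(n, hom_fraction). Events avoid centromeres and keep ``min_gap``
    bp between each other (one Strand-seq window span of slack, so adjacent
    events never merge into one candidate for reasons of placement alone).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (1 <= size_min <= size_max):
        raise ValueError("invalid size law")
    if hom_fraction > 1.0 - complex_fraction + 1e-12:
        raise ValueError("hom_fraction must be <= 1 - complex_fraction (complex events are het)")
    rng = derive_rng(seed, "plant_inversions")
    chrom_arr = np.array(genome.chrom_names)
    weights = np.array([genome.chrom_lengths[c] for c in chrom_arr], dtype=float)
    weights /= weights.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chrom_names}
    out: list[TruthInversion] = []
    p_hom_simple = hom_fraction / (1.0 - complex_fraction) if complex_fraction < 1 else 0.0
    max_attempts = 400 * n
    attempts = 0
    for i in range(n):
        size = int(np.exp(rng.uniform(np.log(size_min), np.log(size_max)))) if size_min < size_max else size_min
        size = max(1, size)
        while True:
            attempts += 1
            if attempts > max_attempts:
                raise CapacityError(
                    f"could not place {n} non-overlapping inversions: {n - len(out)} still unplaced "
                    f"after {max_attempts} attempts"
                )
            chrom = str(rng.choice(chrom_arr, p=weights))
            L = genome.chrom_lengths[chrom]
            if size + 2 * min_gap >= L:
                continue
            start = int(rng.integers(min_gap, L - size - min_gap))
            end = start + size
            cs, ce = genome.centromere_intervals[chrom]
            if overlap_len(start - min_gap, end + min_gap, cs, ce) > 0:
                continue
            if any(overlap_len(start - min_gap, end + min_gap, s, e) > 0 for s, e in placed[chrom]):
                continue
            placed[chrom].append((start, end))
            break
        is_complex = rng.random() < complex_fraction
        if is_complex:
            genotype = "het_H1" if rng.random() < 0.5 else "het_H2"
            k = int(rng.choice([1, 2, 3], p=[0.6, 0.3, 0.1]))
            out.append(TruthInversion(f"inv{i}", chrom, start, end, genotype, "inverted_duplication", k))
        else:
            if rng.random() < p_hom_simple:
                genotype = "hom"
            else:
                genotype = "het_H1" if rng.random() < 0.5 else "het_H2"
            out.append(TruthInversion(f"inv{i}", chrom, start, end, genotype, "simple", 0))
    return sorted(out, key=lambda t: (t.chrom, t.start))


def simulate_strandseq_composite(
    genome: GenomeModel,
    truth: list[TruthInversion],
    read_density: float = 50.0,
    orientation_error: float = 0.02,
    haplotag_rate: float = 0.12,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a merged Strand-seq composite file.

    Reads are points sampled per haplotype at ``read_density/2`` reads per kb
    each. A read from a haplotype carrying a simple inversion is non-reference
    inside the event; inside an inverted duplication with ``k`` extra direct
    copies the carrier haplotype yields ``(1+k)``-fold local read density of
    which a ``1/(1+k)`` fraction is non-reference (copy-number reading of the
    depressed read ratios of complex events). Observed orientation is flipped
    with probability ``orientation_error``; each read is haplotagged with its
    haplotype of origin with probability ``haplotag_rate`` (the rate already
    folds in the chance of overlapping a phased het SNV).
    """
    if read_density <= 0:
        raise ValueError("read_density must be > 0")
    if not 0 <= orientation_error < 0.5:
        raise ValueError("orientation_error must be in [0, 0.5)")
    if not 0 <= haplotag_rate <= 1:
        raise ValueError("haplotag_rate must be in [0, 1]")
    rng = derive_rng(seed, "strandseq_composite")
    by_chrom: dict[str, list[TruthInversion]] = {c: [] for c in genome.chrom_names}
    for t in truth:
        by_chrom[t.chrom].append(t)
    frames: list[pd.DataFrame] = []
    for chrom in genome.chrom_names:
        L = genome.chrom_lengths[chrom]
        per_hap_rate = read_density / 2.0 / 1000.0  # reads per bp per haplotype
        for hap in (HAP_H1, HAP_H2):
            n_base = rng.poisson(per_hap_rate * L)
            pos = rng.integers(0, L, size=n_base)
            nonref = np.zeros(n_base, dtype=bool)
            extra_pos: list[np.ndarray] = []
            extra_nonref: list[np.ndarray] = []
            for t in by_chrom[chrom]:
                if hap not in t.carrier_haps:
                    continue
                inside = (pos >= t.start) & (pos < t.end)
                if t.cls == "simple":
                    nonref[inside] = True
                else:
                    k = t.dup_copy_number
                    p_inv = 1.0 / (1.0 + k)
                    nonref[inside] = rng.random(int(inside.sum())) < p_inv
                    n_extra = rng.poisson(per_hap_rate * (t.end - t.start) * k)
                    epos = rng.integers(t.start, t.end, size=n_extra)
                    extra_pos.append(epos)
                    extra_nonref.append(rng.random(n_extra) < p_inv)
            if extra_pos:
                pos = np.concatenate([pos] + extra_pos)
                nonref = np.concatenate([nonref] + extra_nonref)
            n = len(pos)
            if orientation_error > 0:
                flip = rng.random(n) < orientation_error
                nonref = nonref ^ flip
            hapcol = np.where(rng.random(n) < haplotag_rate, np.int8(hap), np.int8(HAP_UNTAGGED))
            frames.append(
                pd.DataFrame(
                    {"chrom": chrom, "pos": pos.astype(np.int64), "nonref": nonref, "hap": hapcol.astype(np.int8)}
                )
            )
    df = pd.concat(frames, ignore_index=True)
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return df


def plant_svs(
    genome: GenomeModel,
    n: int,
    size_min: int = 50,
    size_max: int = 10_000,
    ins_fraction: float = 0.4,
    hom_fraction: float = 0.33,
    seed: int = 0,
    min_gap: int = 2_000,
) -> list[TruthSV]:
    """Plant deletion/insertion truth events for the merging/validation stages."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = derive_rng(seed, "plant_svs")
    chrom_arr = np.array(genome.chrom_names)
    weights = np.array([genome.chrom_lengths[c] for c in chrom_arr], dtype=float)
    weights /= weights.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chrom_names}
    out: list[TruthSV] = []
    attempts, max_attempts = 0, 400 * n
    for i in range(n):
        svtype = "INS" if rng.random() < ins_fraction else "DEL"
        size = int(np.exp(rng.uniform(np.log(size_min), np.log(size_max))))
        while True:
            attempts += 1
            if attempts > max_attempts:
                raise CapacityError(f"could not place {n} SVs: {n - len(out)} unplaced")
            chrom = str(rng.choice(chrom_arr, p=weights))
            L = genome.chrom_lengths[chrom]
            span = size if svtype == "DEL" else 1
            start = int(rng.integers(min_gap, L - span - min_gap))
            end = start + (size if svtype == "DEL" else 0)
            cs, ce = genome.centromere_intervals[chrom]
            if overlap_len(start - min_gap, max(end, start + 1) + min_gap, cs, ce) > 0:
                continue
            if any(overlap_len(start - min_gap, max(end, start + 1) + min_gap, s, e) > 0 for s, e in placed[chrom]):
                continue
            placed[chrom].append((start, max(end, start + 1)))
            break
        if rng.random() < hom_fraction:
            zyg = "hom"
        else:
            zyg = "het_H1" if rng.random() < 0.5 else "het_H2"
        out.append(TruthSV(f"sv{i}", chrom, start, end, svtype, size, zyg))
    return sorted(out, key=lambda t: (t.chrom, t.start))


def _truth_to_call(t, caller: str) -> SVCall:
    if isinstance(t, TruthInversion):
        gt = "hom" if t.genotype == "hom" else "het"
        return SVCall(t.chrom, t.start, t.end, "INV", source=caller, genotype=gt, truth_id=t.id)
    gt = "hom" if t.zygosity == "hom" else "het"
    hap = None if t.zygosity == "hom" else ("H1" if t.zygosity == "het_H1" else "H2")
    return SVCall(t.chrom, t.start, t.end, t.type, source=caller, genotype=gt, length=t.length, truth_id=t.id, haplotype=hap)


def simulate_caller_callsets(
    truth: list,
    profiles: list[CallerProfile],
    genome: GenomeModel,
    seed: int = 0,
) -> dict[str, list[SVCall]]:
    """Per-caller callsets with sensitivity, breakpoint jitter and FPs.

    Each truth event is detected by caller c with probability sensitivity(c);
    detected breakpoints are perturbed by independent centered Gaussian noise
    of sd jitter_sd(c); false positives arrive as Poisson(fp_rate x Mb) with
    log-uniform sizes. Truth linkage is retained on every true call.
    """
    if not profiles:
        raise ValueError("profiles must be non-empty")
    rng = derive_rng(seed, "caller_callsets")
    genome_mb = genome.total_length / 1e6
    out: dict[str, list[SVCall]] = {}
    for prof in profiles:
        calls: list[SVCall] = []
        for t in truth:
            base = _truth_to_call(t, prof.name)
            if base.svtype not in prof.detectable_types:
                continue
            if rng.random() >= prof.sensitivity:
                continue
            call = base
            if prof.breakpoint_jitter_sd > 0:
                j1 = int(round(rng.normal(0, prof.breakpoint_jitter_sd)))
                j2 = int(round(rng.normal(0, prof.breakpoint_jitter_sd)))
                L = genome.chrom_lengths[call.chrom]
                if call.svtype == "INS":
                    p = int(np.clip(call.start + j1, 0, L - 1))
                    call = SVCall(call.chrom, p, p, "INS", source=prof.name, genotype=call.genotype,
                                  length=call.length, truth_id=call.truth_id, haplotype=call.haplotype)
                else:
                    s = int(np.clip(call.start + j1, 0, L - 2))
                    e = int(np.clip(call.end + j2, s + 1, L))
                    call = SVCall(call.chrom, s, e, call.svtype, source=prof.name, genotype=call.genotype,
                                  truth_id=call.truth_id, haplotype=call.haplotype)
            if prof.length_bias != 1.0:
                call.length = max(1, int(round(call.length * prof.length_bias)))
            calls.append(call)
        n_fp = rng.poisson(prof.fp_rate * genome_mb) if prof.fp_rate > 0 else 0
        for j in range(n_fp):
            chrom = str(rng.choice(genome.chrom_names))
            L = genome.chrom_lengths[chrom]
            size = int(np.exp(rng.uniform(np.log(100), np.log(10_000))))
            svtype = str(rng.choice([t for t in prof.detectable_types]))
            start = int(rng.integers(0, max(1, L - size)))
            if svtype == "INS":
                calls.append(SVCall(chrom, start, start, "INS", source=prof.name, genotype="het",
                                    length=size, id=f"{prof.name}_fp{j}"))
            else:
                calls.append(SVCall(chrom, start, start + size, svtype, source=prof.name, genotype="het",
                                    id=f"{prof.name}_fp{j}"))
        for idx, c in enumerate(calls):
            if c.id is None:
                c.id = f"{prof.name}_{idx}"
        out[prof.name] = sorted(calls, key=lambda c: (c.chrom, c.start, c.end))
    return out


def simulate_validation_evidence(
    calls: list[SVCall],
    truth: list[TruthSV],
    support_mean_true: float = 20.0,
    support_mean_false: float = 1.0,
    bng_rel_error_sd: float = 0.05,
    base_depth: float = 40.0,
    seed: int = 0,
    bng_fraction: float = 0.6,
    flank: int = 1000,
) -> dict[str, SupportEvidence]:
    """Per-call validation evidence: read support, optical lengths, coverage.

    True calls (those with truth linkage) draw alt-supporting read counts
    around ``support_mean_true``, false calls around ``support_mean_false``.
    A fraction ``bng_fraction`` of calls receives an optical-map length
    L_BN = L_PB * (1 + N(0, bng_rel_error_sd)). Coverage profiles are per-bp
    Poisson around ``base_depth``; inside a true deletion the depth drops to
    ~0 (hom) or ~base_depth/2 (het).
    """
    if support_mean_true < 0 or support_mean_false < 0:
        raise ValueError("support means must be >= 0")
    rng = derive_rng(seed, "validation_evidence")
    truth_by_id = {t.id: t for t in truth}
    out: dict[str, SupportEvidence] = {}
    for call in calls:
        t = truth_by_id.get(call.truth_id) if call.truth_id else None
        mean = support_mean_true if t is not None else support_mean_false
        alt_support = int(rng.poisson(mean))
        l_bn = None
        if rng.random() < bng_fraction:
            l_bn = max(1, int(round(call.length * (1.0 + rng.normal(0, bng_rel_error_sd)))))
        p_start = max(0, call.start - flank)
        p_end = max(call.end, call.start + 1) + flank
        depth = rng.poisson(base_depth, size=p_end - p_start).astype(np.float64)
        if t is not None and t.type == "DEL":
            s = max(t.start, p_start) - p_start
            e = min(t.end, p_end) - p_start
            if e > s:
                if t.zygosity == "hom":
                    depth[s:e] = rng.poisson(0.2, size=e - s)
                else:
                    depth[s:e] = rng.poisson(base_depth / 2.0, size=e - s)
        out[call.id] = SupportEvidence(
            call_id=call.id,
            alt_support_reads=alt_support,
            bng_length=l_bn,
            depth_profile=depth,
            profile_start=p_start,
        )
    return out
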