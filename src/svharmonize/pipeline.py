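"""End-to-end orchestration: simulate -> discover -> validate -> integrate.

Stages run in dependency order on synthetic inputs with known truth:

1. simulate        genome, planted inversions/SVs, composite file, per-caller
                   and per-platform callsets, validation evidence
2. strandseq       inversion discovery, genotyping, phase classification
3. inversions      cross-platform unification (intersection, re-genotyping,
                   phase support; pericentric/TR filters)
4. consensus       short-read caller consensus, QC labels, NCR combinations
5. merge           haplotype merging, PBRC/f_BN/depth validation, unified
                   long-read callset, filtered IL/BNG, pan-SV integration

Reruns with the same config and seed are bit-identical; the manifest records
the config hash, per-stage record counts and output checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from . import consensus as cns
from . import integrate as integ
from . import io as svio
from . import strandseq as sts
from . import synthetic as syn
from . import validate as val
from .config import PipelineConfig
from .core import derive_rng

logger = logging.getLogger("svharmonize")


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    versions: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)
    output_checksums: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config_hash": self.config_hash,
                    "seed": self.seed,
                    "versions": self.versions,
                    "stage_counts": self.stage_counts,
                    "output_checksums": self.output_checksums,
                },
                fh,
                indent=2,
                sort_keys=True,
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _exclude_track(genome: syn.GenomeModel, telomere_fraction: float = 0.01) -> dict[str, list[tuple[int, int]]]:
    """Centromere plus terminal (telomeric) intervals per chromosome."""
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom in genome.chrom_names:
        L = genome.chrom_lengths[chrom]
        t = int(L * telomere_fraction)
        cen = genome.centromere_intervals[chrom]
        out[chrom] = sorted([(0, t), cen, (L - t, L)])
    return out


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> RunManifest:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    counts: dict[str, int] = {}

    # --- stage 1: simulate ------------------------------------------------
    genome = syn.generate_genome_model(
        config.genome.n_chroms, config.genome.chrom_length,
        config.genome.tr_density, config.genome.snv_spacing_mean, seed=seed,
    )
    inv_cfg = config.inversions
    truth_inv = syn.plant_inversions(
        genome, inv_cfg.n, inv_cfg.size_min, inv_cfg.size_max,
        inv_cfg.hom_fraction, inv_cfg.complex_fraction, seed=seed,
    )
    truth_svs = syn.plant_svs(genome, config.svs.n, config.svs.size_min, config.svs.size_max,
                              config.svs.ins_fraction, config.svs.hom_fraction, seed=seed)
    comp_cfg = config.composite
    composite = syn.simulate_strandseq_composite(
        genome, truth_inv, comp_cfg.read_density, comp_cfg.orientation_error,
        comp_cfg.haplotag_rate, seed=seed,
    )
    inv_platform_sets = syn.simulate_caller_callsets(
        truth_inv, [p.to_profile() for p in config.inv_platforms], genome, seed=seed,
    )
    il_callsets = syn.simulate_caller_callsets(
        truth_svs, [p.to_profile() for p in config.il_callers], genome, seed=seed + 1,
    )
    pb_hap_sets: dict[str, dict[str, list]] = {}
    for m_i, method in enumerate(config.pb_methods):
        per_hap = {}
        for h_i, hap in enumerate(("H1", "H2")):
            sub = [t for t in truth_svs if t.zygosity in ("hom", f"het_{hap}")]
            calls = syn.simulate_caller_callsets(sub, [method.to_profile()], genome,
                                                 seed=seed + 10 + 2 * m_i + h_i)[method.name]
            for c in calls:
                c.haplotype = hap
                c.id = f"{method.name}_{hap}_{c.id}"
            per_hap[hap] = calls
        pb_hap_sets[method.name] = per_hap
    counts["truth_inversions"] = len(truth_inv)
    counts["truth_svs"] = len(truth_svs)
    counts["composite_reads"] = len(composite)

    svio.write_composite(composite, outdir / "composite.tsv")
    svio.write_track(genome.tandem_repeat_track, outdir / "tandem_repeats.bed")
    svio.write_track({c: [genome.centromere_intervals[c]] for c in genome.chrom_names},
                     outdir / "centromeres.bed")
    svio.write_sv_callset(
        [syn._truth_to_call(t, "truth") for t in truth_svs], outdir / "truth_svs.bed", "bed_tsv"
    )

    # --- stage 2: Strand-seq inversion discovery --------------------------
    params = config.segmentation.to_params()
    discovered = sts.discover_inversions(composite, params)
    counts["sts_discovered"] = len(discovered)
    svio.write_inversions(discovered, outdir / "strandseq_inversions.tsv")

    # --- stage 3: inversion unification -----------------------------------
    platform_calls: dict[str, list[integ.PlatformCall]] = {}
    for platform, calls in inv_platform_sets.items():
        platform_calls[platform] = [
            integ.PlatformCall(platform, c.chrom, c.start, c.end, genotype=c.genotype, id=c.id)
            for c in calls
        ]
    platform_calls["StS"] = [
        integ.PlatformCall(
            "StS", inv.locus.chrom, inv.locus.start, inv.locus.end,
            genotype={"hom_inv": "hom", "het": "het"}.get(inv.genotype),
            cls={"complex": "complex", "simple_hom": "simple", "simple_het": "simple"}.get(inv.cls),
            phase=inv.phase,
        )
        for inv in discovered
        if inv.genotype in ("het", "hom_inv")
    ]
    thr = config.thresholds
    inter = integ.intersection_test(platform_calls, thr.ro_min)
    regeno, _, _ = integ.regenotype_test(
        [c for p, calls in sorted(platform_calls.items()) if p != "StS" for c in calls],
        composite, params, min_reads=thr.regenotype_min_reads,
    )
    phase_sup = integ.sts_phase_support(discovered)
    unified_inv = integ.unify_inversions(inter, regeno, phase_sup, genome, thr.ro_min, thr.tr_max)
    counts["unified_inversions"] = len(unified_inv)
    svio.write_unified_inversions(unified_inv, outdir / "unified_inversions.tsv")
    svio.write_unified_inversions(unified_inv, outdir / "unified_inversions.vcf", "vcf",
                                  contig_lengths=dict(genome.chrom_lengths))

    # --- stage 4: short-read caller consensus ------------------------------
    gold = [c for hap in pb_hap_sets["phased_sv"].values() for c in hap if c.truth_id]
    ci_offsets = cns.estimate_breakpoint_ci(il_callsets, gold, thr.ro_min, thr.ci_min_matches,
                                            (-thr.ci_default_halfwidth, thr.ci_default_halfwidth))
    consensus_calls = cns.build_consensus_calls(il_callsets, ci_offsets)
    cns.qc_filter(consensus_calls, _exclude_track(genome), thr.qc_max_len, thr.ro_min)
    counts["consensus_calls"] = len(consensus_calls)
    counts["consensus_pass"] = sum(1 for c in consensus_calls if c.label == "PASS")

    # --- stage 5: haplotype merge, validation, pan-SV ----------------------
    merged_methods: dict[str, val.HaplotypeMergeResult] = {}
    for method, per_hap in pb_hap_sets.items():
        merged_methods[method] = val.merge_haplotypes(
            per_hap["H1"], per_hap["H2"], genome.tandem_repeat_track,
            thr.ro_hap_non_tr, thr.ro_hap_tr, thr.tr_max_cluster,
        )
    phased_dip = merged_methods["phased_sv"].diploid_calls
    mspac_dip = merged_methods["mspac"].diploid_calls
    evidence = syn.simulate_validation_evidence(
        phased_dip + mspac_dip, truth_svs,
        config.evidence.support_mean_true, config.evidence.support_mean_false,
        config.evidence.bng_rel_error_sd, config.evidence.base_depth,
        seed=seed, bng_fraction=config.evidence.bng_fraction,
    )
    bng_profile = syn.CallerProfile("BNG_SV", sensitivity=0.35, fp_rate=0.1,
                                    breakpoint_jitter_sd=300.0, detectable_types=("DEL", "INS"))
    bng_calls = syn.simulate_caller_callsets(truth_svs, [bng_profile], genome, seed=seed + 30)["BNG_SV"]
    bng_evidence = syn.simulate_validation_evidence(
        bng_calls, truth_svs, config.evidence.support_mean_true, config.evidence.support_mean_false,
        config.evidence.bng_rel_error_sd, config.evidence.base_depth, seed=seed + 31,
    )
    pb_unified = val.unify_pb(phased_dip, mspac_dip, evidence, bng_calls,
                              thr.pbrc_unify_min, thr.f_max, thr.mspac_min_dist)
    counts["pb_unified"] = len(pb_unified)
    svio.write_evidence(evidence, outdir / "pb_evidence.tsv")
    svio.write_sv_callset(pb_unified, outdir / "pb_unified.vcf", "vcf",
                          contig_lengths=dict(genome.chrom_lengths))

    pass_calls = [c for c in consensus_calls if c.label == "PASS"]
    il_as_sv = [
        syn.SVCall(c.chrom, c.start, c.end, c.svtype, source="IL",
                   genotype=c.members[0].genotype, id=f"il_{i}",
                   length=max(max(m.length for m in c.members), 1),
                   truth_id=next((m.truth_id for m in c.members if m.truth_id), None))
        for i, c in enumerate(pass_calls)
    ]
    il_evidence = syn.simulate_validation_evidence(
        il_as_sv, truth_svs, config.evidence.support_mean_true, config.evidence.support_mean_false,
        config.evidence.bng_rel_error_sd, config.evidence.base_depth, seed=seed + 32,
    )
    pb_read_calls = [c for hap in pb_hap_sets["mspac"].values() for c in hap]
    il_filtered = [
        c
        for c in il_as_sv
        if val.il_concordance_filter(
            c, pb_assembly_calls=pb_unified, pb_read_calls=pb_read_calls,
            bng_calls=bng_calls, depth_profile=il_evidence[c.id],
            min_concordance=thr.ro_min, max_depth=thr.il_max_depth,
        )
    ]
    bng_filtered = []
    for c in bng_calls:
        if c.svtype == "DEL":
            ev = bng_evidence[c.id]
            if ev.depth_profile is not None and c.span > 0 and len(ev.depth_profile) >= c.span:
                if val.depth_validate_deletion(ev.depth_profile, c.span, thr.depth_max_min_cov):
                    bng_filtered.append(c)
        else:
            bng_filtered.append(c)  # insertions: no depth signal, kept below 15 Mb
    pan = val.build_pan_sv(il_filtered, bng_filtered, pb_unified, min_concordance=thr.ro_min)
    counts["il_filtered"] = len(il_filtered)
    counts["bng_filtered"] = len(bng_filtered)
    counts["pan_sv_records"] = len(pan)
    svio.write_sv_callset([r.representative for r in pan], outdir / "pan_sv.vcf", "vcf",
                          contig_lengths=dict(genome.chrom_lengths))
    summary = val.summarize_pan_sv(pan)
    summary.to_csv(outdir / "pan_sv_summary.tsv", sep="\t", index=False)

    combos = cns.evaluate_combinations(
        il_callsets,
        concordance_oracle=lambda c: val.il_concordance_filter(
            c, pb_assembly_calls=pb_unified, pb_read_calls=pb_read_calls, bng_calls=bng_calls,
            min_concordance=thr.ro_min,
        ),
    )
    with open(outdir / "combinations.tsv", "w") as fh:
        fh.write("callers\tmode\tn_calls\tncr\n")
        for r in combos:
            fh.write(f"{'+'.join(sorted(r.combo))}\t{r.mode}\t{r.n_calls}\t{r.ncr:.4f}\n")
    counts["combinations"] = len(combos)

    manifest = RunManifest(
        config_hash=config.config_hash(),
        seed=seed,
        versions={"svharmonize": __version__},
        stage_counts=counts,
    )
    for p in sorted(outdir.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest.output_checksums[p.name] = _sha256(p)
    manifest.to_json(outdir / "manifest.json")
    logger.info("pipeline complete: %s", counts)
    return manifest
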