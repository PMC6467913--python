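"""Readers and writers for the pipeline's on-disk formats.

Coordinates are 0-based half-open in memory and in all BED/TSV dialects;
conversion to 1-based happens only at the VCF boundary. VCF records use
symbolic alleles (<DEL>, <INS>, <DUP>, <INV>) with SVTYPE/SVLEN/END INFO
keys (SVLEN signed per convention: negative for deletions) and are read
back through pysam.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .core import SVCall
from .integrate import UnifiedInversion
from .strandseq import GenotypedInversion

logger = logging.getLogger("svharmonize")

_ORIENT = {False: "reference", True: "non_reference"}
_ORIENT_BACK = {v: k for k, v in _ORIENT.items()}
_HAP = {0: "untagged", 1: "H1", 2: "H2"}
_HAP_BACK = {v: k for k, v in _HAP.items()}


def write_composite(reads: pd.DataFrame, path: str | Path) -> None:
    """Write a composite file as BED-like TSV (chrom, pos, pos+1, orientation, haplotag)."""
    df = pd.DataFrame(
        {
            "chrom": reads["chrom"],
            "start": reads["pos"],
            "end": reads["pos"] + 1,
            "orientation": reads["nonref"].map(_ORIENT),
            "haplotag": reads["hap"].map(_HAP),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_composite(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].astype(str),
            "pos": df["start"].astype("int64"),
            "nonref": df["orientation"].map(_ORIENT_BACK).astype(bool),
            "hap": df["haplotag"].map(_HAP_BACK).astype("int8"),
        }
    )
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def write_track(track: dict[str, list[tuple[int, int]]], path: str | Path) -> None:
    """Write an annotation track as 3-column BED."""
    with open(path, "w") as fh:
        for chrom in sorted(track):
            for s, e in track[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\n")


def read_track(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, s, e = line.split("\t")[:3]
            out.setdefault(chrom, []).append((int(s), int(e)))
    for chrom in out:
        out[chrom].sort()
    return out


_BED_COLS = ["chrom", "start", "end", "svtype", "length", "source", "genotype", "id", "truth_id", "haplotype"]


def write_sv_callset(
    calls: Sequence[SVCall],
    path: str | Path,
    dialect: str = "bed_tsv",
    contig_lengths: dict[str, int] | None = None,
    sample: str = "SAMPLE",
) -> None:
    """Write SV calls as a BED-like TSV or a minimal VCF 4.2."""
    if dialect == "bed_tsv":
        rows = [
            {
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "svtype": c.svtype,
                "length": c.length,
                "source": c.source,
                "genotype": c.genotype or ".",
                "id": c.id or ".",
                "truth_id": c.truth_id or ".",
                "haplotype": c.haplotype or ".",
            }
            for c in calls
        ]
        pd.DataFrame(rows, columns=_BED_COLS).to_csv(path, sep="\t", index=False)
    elif dialect == "vcf":
        _write_vcf(calls, path, contig_lengths or _infer_contigs(calls), sample)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _infer_contigs(calls: Iterable[SVCall]) -> dict[str, int]:
    out: dict[str, int] = {}
    for c in calls:
        out[c.chrom] = max(out.get(c.chrom, 0), c.end + 1, c.start + abs(c.length or 0) + 1)
    return out


_GT_CODES = {
    "het": (0, 1),
    "hom": (1, 1),
    "1/1": (1, 1),
    "0/1": (0, 1),
    "1/0": (1, 0),
    "hom_inv": (1, 1),
}


def _write_vcf(calls: Sequence[SVCall], path: str | Path, contigs: dict[str, int], sample: str) -> None:
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">')
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">')
    header.add_line('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Signed length of the variant">')
    header.add_line('##INFO=<ID=SOURCE,Number=1,Type=String,Description="Caller or platform of origin">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for alt in ("DEL", "INS", "DUP", "INV"):
        header.add_line(f'##ALT=<ID={alt},Description="{alt} structural variant">')
    for chrom in sorted(contigs):
        header.add_line(f"##contig=<ID={chrom},length={contigs[chrom]}>")
    header.add_sample(sample)
    vcf = pysam.VariantFile(str(path), "w", header=header)
    for i, c in enumerate(sorted(calls, key=lambda x: (x.chrom, x.start, x.end))):
        rec = vcf.new_record(
            contig=c.chrom,
            start=c.start,
            stop=max(c.end, c.start + 1),
            alleles=("N", f"<{c.svtype}>"),
            id=c.id or f"sv{i}",
        )
        rec.info["SVTYPE"] = c.svtype
        rec.info["SVLEN"] = -int(c.length) if c.svtype == "DEL" else int(c.length)
        if c.source:
            rec.info["SOURCE"] = c.source
        gt = _GT_CODES.get(c.genotype or "", (None,))
        rec.samples[sample]["GT"] = gt
        vcf.write(rec)
    vcf.close()


def read_sv_callset(path: str | Path, dialect: str = "bed_tsv") -> list[SVCall]:
    """Read SV calls, normalizing coordinates to 0-based half-open.

    VCF records with inconsistent END vs SVLEN are rejected with a logged
    record-level error (the run continues); BED rows pass through unchanged.
    """
    if dialect == "bed_tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        out = []
        for _, r in df.iterrows():
            out.append(
                SVCall(
                    str(r["chrom"]),
                    int(r["start"]),
                    int(r["end"]),
                    str(r["svtype"]),
                    source="" if r.get("source") in (".", None) or pd.isna(r.get("source")) else str(r["source"]),
                    genotype=None if r.get("genotype") in (".", None) or pd.isna(r.get("genotype")) else str(r["genotype"]),
                    length=int(r["length"]),
                    id=None if r.get("id") in (".", None) or pd.isna(r.get("id")) else str(r["id"]),
                    truth_id=None if r.get("truth_id") in (".", None) or pd.isna(r.get("truth_id")) else str(r["truth_id"]),
                    haplotype=None if r.get("haplotype") in (".", None) or pd.isna(r.get("haplotype")) else str(r["haplotype"]),
                )
            )
        return out
    if dialect != "vcf":
        raise ValueError(f"unknown dialect {dialect!r}")
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for lineno, rec in enumerate(vcf, 1):
            svtype = rec.info.get("SVTYPE")
            if svtype not in ("DEL", "INS", "DUP", "INV"):
                logger.error("%s record %d: missing/unknown SVTYPE; skipped", path, lineno)
                continue
            start = rec.start  # pysam: 0-based
            svlen = rec.info.get("SVLEN")
            if svlen is None:
                end = rec.stop
                length = end - start
            elif svtype == "INS":
                end = start
                length = abs(int(svlen))
            else:
                length = abs(int(svlen))
                end = start + length
                # htslib derives stop from max(END-POS+1, |SVLEN|+1); an END
                # beyond that window means END and SVLEN disagree
                if rec.stop not in (end, end + 1):
                    logger.error(
                        "%s record %d (%s:%d): END inconsistent with SVLEN=%d; skipped",
                        path, lineno, rec.chrom, rec.pos, svlen,
                    )
                    continue
            gt = None
            if rec.samples:
                sample = rec.samples[next(iter(rec.samples))]
                alleles = sample.get("GT")
                if alleles and None not in alleles:
                    if alleles == (1, 1):
                        gt = "hom"
                    elif 1 in alleles:
                        gt = "het"
            out.append(
                SVCall(
                    rec.chrom, start, end, str(svtype),
                    source=str(rec.info["SOURCE"]) if "SOURCE" in rec.info else "",
                    genotype=gt, length=length, id=rec.id,
                )
            )
    return out


_INV_COLS = [
    "chrom", "start", "end", "name", "score", "strand",
    "genotype", "read_ratio", "hap_ratio_ref", "hap_ratio_nonref", "class", "phase",
]


def write_inversions(invs: Sequence[GenotypedInversion], path: str | Path) -> None:
    """Write classified Strand-seq inversions as BED9+-style TSV."""
    rows = []
    for i, inv in enumerate(invs):
        rows.append(
            {
                "chrom": inv.locus.chrom,
                "start": inv.locus.start,
                "end": inv.locus.end,
                "name": f"inv_{i}",
                "score": inv.locus.total,
                "strand": ".",
                "genotype": inv.genotype,
                "read_ratio": round(inv.locus.read_ratio, 4),
                "hap_ratio_ref": "." if inv.hap_ratio_ref_strand is None else round(inv.hap_ratio_ref_strand, 4),
                "hap_ratio_nonref": "." if inv.hap_ratio_nonref_strand is None else round(inv.hap_ratio_nonref_strand, 4),
                "class": inv.cls,
                "phase": inv.phase or ".",
            }
        )
    pd.DataFrame(rows, columns=_INV_COLS).to_csv(path, sep="\t", index=False)


def write_unified_inversions(
    unified: Sequence[UnifiedInversion], path: str | Path, dialect: str = "bed_tsv",
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write unified inversions as TSV or as VCF with InvR/inner INFO keys."""
    if dialect == "bed_tsv":
        rows = [
            {
                "chrom": u.chrom,
                "start": u.invr_start,
                "end": u.invr_end,
                "inner_start": u.inner_start,
                "inner_end": u.inner_end,
                "platforms": ",".join(sorted(u.platforms)),
                "support": ",".join(sorted(u.support_sources)),
                "genotype": u.consensus_genotype,
                "class": u.cls,
            }
            for u in unified
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        return
    header = pysam.VariantHeader()
    for key, typ in (
        ("SVTYPE", "String"), ("END", "Integer"), ("INVR_START", "Integer"), ("INVR_END", "Integer"),
        ("INNER_START", "Integer"), ("INNER_END", "Integer"), ("PLATFORMS", "String"), ("SUPPORT", "String"),
        ("CLASS", "String"),
    ):
        header.add_line(f'##INFO=<ID={key},Number=1,Type={typ},Description="{key}">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##ALT=<ID=INV,Description="Inversion">')
    contigs = contig_lengths or {}
    for u in unified:
        contigs.setdefault(u.chrom, 0)
        contigs[u.chrom] = max(contigs[u.chrom], u.invr_end + 1)
    for chrom in sorted(contigs):
        header.add_line(f"##contig=<ID={chrom},length={contigs[chrom]}>")
    header.add_sample("SAMPLE")
    vcf = pysam.VariantFile(str(path), "w", header=header)
    for i, u in enumerate(sorted(unified, key=lambda x: (x.chrom, x.invr_start))):
        rec = vcf.new_record(contig=u.chrom, start=u.invr_start, stop=u.invr_end,
                             alleles=("N", "<INV>"), id=f"uinv{i}")
        rec.info["SVTYPE"] = "INV"
        rec.info["INVR_START"] = u.invr_start
        rec.info["INVR_END"] = u.invr_end
        rec.info["INNER_START"] = u.inner_start
        rec.info["INNER_END"] = u.inner_end
        rec.info["PLATFORMS"] = ",".join(sorted(u.platforms))
        rec.info["SUPPORT"] = ",".join(sorted(u.support_sources))
        rec.info["CLASS"] = u.cls
        rec.samples["SAMPLE"]["GT"] = {"het": (0, 1), "hom": (1, 1)}.get(u.consensus_genotype, (None,))
        vcf.write(rec)
    vcf.close()


def write_evidence(evidence: dict, path: str | Path) -> None:
    """Write per-call evidence (support count, optical length, mean depth) as TSV."""
    rows = []
    for call_id in sorted(evidence):
        ev = evidence[call_id]
        mean_depth = float(ev.depth_profile.mean()) if ev.depth_profile is not None else float("nan")
        rows.append(
            {
                "call_id": call_id,
                "alt_support": ev.alt_support_reads,
                "bng_length": "." if ev.bng_length is None else ev.bng_length,
                "mean_depth": round(mean_depth, 3),
            }
        )
    pd.DataFrame(rows, columns=["call_id", "alt_support", "bng_length", "mean_depth"]).to_csv(
        path, sep="\t", index=False
    )


def read_evidence(path: str | Path) -> dict:
    from .validate import SupportEvidence

    df = pd.read_csv(path, sep="\t")
    out = {}
    for _, r in df.iterrows():
        bng = None if str(r["bng_length"]) == "." else int(float(r["bng_length"]))
        out[str(r["call_id"])] = SupportEvidence(str(r["call_id"]), int(r["alt_support"]), bng)
    return out
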