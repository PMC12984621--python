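"""Readers and writers for the pipeline's file formats.

Formats are deliberately plain: VCF for germline profiles and variant
annotations (via pysam), matrix-market + sidecar TSVs for antibody counts,
per-layer CSV for genotype matrices, TSV for longitudinal series and
reports, JSON for truth labels and calls.  VCF-facing positions are
1-based; in-memory records keep the same convention, so no conversion is
needed at these boundaries.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import io as spio
from scipy import sparse

from .demux import GermlineProfile
from .ecngs import EcngsSite
from .matrix import AntibodyCounts, CellGenotypeMatrix, VariantRecord
from .synthio import TruthLabels

__all__ = [
    "write_germline_vcf",
    "read_germline_vcf",
    "write_annotation_vcf",
    "read_annotation_vcf",
    "write_genotype_matrix",
    "read_genotype_matrix",
    "write_antibody_mtx",
    "read_antibody_mtx",
    "write_series_tsv",
    "read_series_tsv",
    "write_ecngs_tsv",
    "read_ecngs_tsv",
    "write_truth_json",
    "read_comparator_days_tsv",
]


# ---------------------------------------------------------------------------
# VCF: germline profiles (multi-sample GT) and variant annotations
# ---------------------------------------------------------------------------


def _vcf_header(
    contigs: Sequence[str], samples: Sequence[str] = (), info: bool = False
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig in contigs:
        header.contigs.add(contig)
    if samples:
        header.formats.add("GT", 1, "String", "Genotype")
    if info:
        header.info.add("GENE", 1, "String", "Gene symbol")
        header.info.add("PCHANGE", 1, "String", "Protein change")
        header.info.add("CSQ", 1, "String", "Consequence")
        header.info.add("POPAF", 1, "Float", "Population allele frequency")
        header.info.add("HP_ADJ", 0, "Flag", "Homopolymer adjacent")
        header.info.add("GERMLINE", 0, "Flag", "User-declared germline")
    for sample in samples:
        header.add_sample(sample)
    return header


def write_germline_vcf(profiles: Sequence[GermlineProfile], path: str | Path) -> None:
    """One multi-sample VCF; GT encodes each patient's SNP genotype."""
    if not profiles:
        raise ValueError("no profiles to write")
    loci = profiles[0].loci
    contigs = list(dict.fromkeys(c for c, _, _, _ in loci))
    header = _vcf_header(contigs, samples=[p.patient_id for p in profiles])
    gt_codes = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for i, (chrom, pos, ref, alt) in enumerate(loci):
            rec = vcf.new_record(
                contig=chrom, start=pos - 1, stop=pos, alleles=(ref, alt)
            )
            for p in profiles:
                rec.samples[p.patient_id]["GT"] = gt_codes[int(p.genotypes[i])]
            vcf.write(rec)


def read_germline_vcf(path: str | Path) -> list[GermlineProfile]:
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        loci: list[tuple[str, int, str, str]] = []
        genos: list[list[int]] = [[] for _ in samples]
        for rec in vcf:
            loci.append((rec.contig, rec.pos, rec.ref, rec.alts[0]))
            for i, s in enumerate(samples):
                gt = rec.samples[s]["GT"]
                genos[i].append(sum(1 for a in gt if a == 1))
    return [
        GermlineProfile(patient_id=s, loci=loci, genotypes=np.array(genos[i]))
        for i, s in enumerate(samples)
    ]


def write_annotation_vcf(variants: Sequence[VariantRecord], path: str | Path) -> None:
    contigs = list(dict.fromkeys(v.chrom for v in variants))
    header = _vcf_header(contigs, info=True)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for v in variants:
            rec = vcf.new_record(
                contig=v.chrom, start=v.pos - 1, stop=v.pos, alleles=(v.ref, v.alt)
            )
            if v.gene:
                rec.info["GENE"] = v.gene
            if v.protein_change:
                rec.info["PCHANGE"] = v.protein_change
            rec.info["CSQ"] = v.consequence
            if v.pop_af is not None:
                rec.info["POPAF"] = v.pop_af
            if v.homopolymer_adjacent:
                rec.info["HP_ADJ"] = True
            if v.germline_flag:
                rec.info["GERMLINE"] = True
            vcf.write(rec)


def read_annotation_vcf(path: str | Path) -> list[VariantRecord]:
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            pop_af = float(info["POPAF"]) if "POPAF" in info else None
            out.append(
                VariantRecord(
                    chrom=rec.contig,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    gene=str(info.get("GENE", "") or ""),
                    protein_change=str(info.get("PCHANGE", "") or ""),
                    consequence=str(info.get("CSQ", "missense_variant")),
                    pop_af=round(pop_af, 6) if pop_af is not None else None,
                    homopolymer_adjacent=bool(info.get("HP_ADJ", False)),
                    germline_flag=bool(info.get("GERMLINE", False)),
                )
            )
    return out


# ---------------------------------------------------------------------------
# genotype matrix: one CSV per layer + annotation VCF, in a directory
# ---------------------------------------------------------------------------

_LAYERS = ("genotype", "depth", "gq", "af")


def write_genotype_matrix(matrix: CellGenotypeMatrix, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ids = matrix.variant_ids
    for layer in _LAYERS:
        pd.DataFrame(
            getattr(matrix, layer), index=matrix.barcodes, columns=ids
        ).to_csv(directory / f"{layer}.csv")
    write_annotation_vcf(matrix.variants, directory / "variants.vcf")


def read_genotype_matrix(directory: str | Path) -> CellGenotypeMatrix:
    directory = Path(directory)
    frames = {
        layer: pd.read_csv(directory / f"{layer}.csv", index_col=0)
        for layer in _LAYERS
    }
    variants = read_annotation_vcf(directory / "variants.vcf")
    barcodes = list(frames["genotype"].index.astype(str))
    return CellGenotypeMatrix(
        barcodes=barcodes,
        variants=variants,
        genotype=frames["genotype"].to_numpy(dtype=np.int8),
        depth=frames["depth"].to_numpy(dtype=np.int32),
        gq=frames["gq"].to_numpy(dtype=np.int16),
        af=frames["af"].to_numpy(dtype=np.float32),
    )


# ---------------------------------------------------------------------------
# antibody counts: matrix market + sidecars
# ---------------------------------------------------------------------------


def write_antibody_mtx(antibody: AntibodyCounts, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(directory / "counts.mtx"), sparse.csr_matrix(antibody.counts))
    (directory / "barcodes.tsv").write_text("\n".join(antibody.barcodes) + "\n")
    (directory / "markers.tsv").write_text("\n".join(antibody.markers) + "\n")


def read_antibody_mtx(directory: str | Path) -> AntibodyCounts:
    directory = Path(directory)
    counts = np.asarray(spio.mmread(str(directory / "counts.mtx")).todense())
    barcodes = (directory / "barcodes.tsv").read_text().splitlines()
    markers = (directory / "markers.tsv").read_text().splitlines()
    return AntibodyCounts(barcodes=barcodes, markers=markers, counts=counts.astype(np.int64))


# ---------------------------------------------------------------------------
# longitudinal series, EC-NGS counts, comparator days
# ---------------------------------------------------------------------------


def write_series_tsv(
    rows: Sequence[tuple[int, str, float, int | None, bool]], path: str | Path
) -> None:
    """Columns: day, tissue, vaf_percent, alleles, dna_limited."""
    df = pd.DataFrame(
        rows, columns=["day", "tissue", "vaf_percent", "alleles", "dna_limited"]
    )
    df.to_csv(path, sep="\t", index=False)


def read_series_tsv(path: str | Path) -> pd.DataFrame:
    """Read a measurement series; unsorted days are sorted with a warning."""
    df = pd.read_csv(path, sep="\t")
    if not df["day"].is_monotonic_increasing:
        warnings.warn(f"series {path} has unsorted days; sorting", stacklevel=2)
        df = df.sort_values("day", kind="stable").reset_index(drop=True)
    return df


def write_ecngs_tsv(sites: Sequence[EcngsSite], path: str | Path) -> None:
    pd.DataFrame(
        [
            (
                s.variant,
                s.fwd_supporting,
                s.fwd_total,
                s.rev_supporting,
                s.rev_total,
                s.uao,
                s.posterior,
                s.called,
            )
            for s in sites
        ],
        columns=[
            "variant",
            "fwd_supporting",
            "fwd_total",
            "rev_supporting",
            "rev_total",
            "uao",
            "posterior",
            "called",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_ecngs_tsv(path: str | Path) -> list[EcngsSite]:
    df = pd.read_csv(path, sep="\t")
    return [
        EcngsSite(
            variant=str(r.variant),
            fwd_supporting=int(r.fwd_supporting),
            fwd_total=int(r.fwd_total),
            rev_supporting=int(r.rev_supporting),
            rev_total=int(r.rev_total),
            uao=int(r.uao),
        )
        for r in df.itertuples()
    ]


def read_comparator_days_tsv(path: str | Path) -> dict[str, int | None]:
    """Columns: method, first_positive_day (empty/NA = never positive)."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, int | None] = {}
    for r in df.itertuples():
        day = r.first_positive_day
        out[str(r.method)] = None if pd.isna(day) else int(day)
    return out


def write_truth_json(truth: TruthLabels, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1, sort_keys=True))
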