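"""File formats: phased VCF, sample sheets, truth matrices, pedigree.

VCF is the exchange format for phased genotypes (v4.2, single contig,
``GT`` with ``|`` separators); a tab-separated sample sheet carries the
breed/generation labels the VCF cannot.  The genetic-map position of each
site is preserved in an INFO field (``GM``, Morgans) so a write/read
round trip reproduces the haplotype container exactly.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .haplo import HaploSet, chars_to_codes, codes_to_chars


class VcfFormatError(ValueError):
    """A VCF record violates the phased single-contig biallelic contract."""


def write_sample_sheet(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str})


def write_phased_vcf(haplo: HaploSet, path: str | Path, chrom: str = "1") -> None:
    """Write a phased single-contig VCF v4.2.

    Base-pair positions are synthesized from the genetic map (1 Morgan =
    1 Mb) and must come out strictly increasing.
    """
    pos_bp = np.round(haplo.positions * 1e6).astype(int) + 1
    if np.any(np.diff(pos_bp) <= 0):
        raise VcfFormatError(
            "map positions collide after rounding to base pairs; "
            "positions must be at least 1e-6 Morgans apart"
        )
    samples = haplo.samples["sample_id"].tolist()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={int(pos_bp[-1]) + 1}>\n")
        fh.write(
            '##INFO=<ID=GM,Number=1,Type=Float,Description="Genetic map position in Morgans">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        hap = haplo.haplotypes
        for j in range(haplo.n_loci):
            gts = "\t".join(
                f"{hap[2 * i, j]}|{hap[2 * i + 1, j]}" for i in range(haplo.n_individuals)
            )
            fh.write(
                f"{chrom}\t{pos_bp[j]}\tsnp{j}\tA\tC\t.\tPASS\t"
                f"GM={haplo.positions[j]:.10f}\tGT\t{gts}\n"
            )


def read_phased_vcf(path: str | Path, sample_sheet: str | Path | pd.DataFrame) -> HaploSet:
    """Read a fully phased biallelic VCF into a haplotype container.

    Every genotype must be phased (``|``); unphased or multiallelic
    records are rejected with the offending file line number.
    """
    sheet = (
        sample_sheet
        if isinstance(sample_sheet, pd.DataFrame)
        else read_sample_sheet(sample_sheet)
    )
    vcf = VCF(str(path))
    # count header lines in the file itself; htslib may synthesize extra
    # header records (e.g. FILTER/PASS) that are not physically present
    header_lines = 0
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for line in fh:
            if line.startswith("#"):
                header_lines += 1
            else:
                break
    order = {s: i for i, s in enumerate(vcf.samples)}
    missing = set(sheet["sample_id"]) - set(order)
    if missing:
        raise VcfFormatError(f"sample sheet names absent from VCF: {sorted(missing)}")

    columns: list[np.ndarray] = []
    positions: list[float] = []
    chroms: set[str] = set()
    for k, variant in enumerate(vcf):
        line_no = header_lines + k + 1
        chroms.add(variant.CHROM)
        if len(chroms) > 1:
            raise VcfFormatError(f"line {line_no}: multiple contigs in input")
        if len(variant.ALT) != 1:
            raise VcfFormatError(f"line {line_no}: record is not biallelic")
        gts = variant.genotypes  # [allele_a, allele_b, phased] per sample
        col = np.empty(2 * len(gts), dtype=np.uint8)
        for i, gt in enumerate(gts):
            if len(gt) != 3 or not gt[2]:
                raise VcfFormatError(
                    f"line {line_no}: unphased genotype for sample {vcf.samples[i]!r}"
                )
            a, b = gt[0], gt[1]
            if a not in (0, 1) or b not in (0, 1):
                raise VcfFormatError(
                    f"line {line_no}: missing or non-biallelic allele for "
                    f"sample {vcf.samples[i]!r}"
                )
            col[2 * i], col[2 * i + 1] = a, b
        gm = variant.INFO.get("GM")
        positions.append(float(gm) if gm is not None else (variant.POS - 1) / 1e6)
        columns.append(col)
    if not columns:
        raise VcfFormatError("VCF contains no variant records")

    matrix = np.column_stack(columns)
    # reorder rows to the sample sheet's ordering
    idx = np.array([order[s] for s in sheet["sample_id"]])
    rows = np.column_stack([2 * idx, 2 * idx + 1]).ravel()
    return HaploSet(matrix[rows], np.array(positions), sheet.reset_index(drop=True))


def write_origin_tsv(origin: np.ndarray, path: str | Path, row_ids=None) -> None:
    """True origin matrix as TSV: one row per haplotype, codes E/L."""
    chars = codes_to_chars(np.asarray(origin))
    if row_ids is None:
        row_ids = [f"h{i}" for i in range(chars.shape[0])]
    with open(path, "w") as fh:
        fh.write("haplotype_id\t" + "\t".join(f"snp{j}" for j in range(chars.shape[1])) + "\n")
        for rid, row in zip(row_ids, chars):
            fh.write(str(rid) + "\t" + "\t".join(row) + "\n")


def read_origin_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    codes = chars_to_codes(frame.to_numpy(dtype="<U1"))
    return codes.astype(np.int8), frame.index.astype(str).tolist()


def write_pedigree_csv(pedigree: pd.DataFrame, path: str | Path) -> None:
    pedigree.to_csv(path, index=False)
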