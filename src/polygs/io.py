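"""File-format adapters: CSV tables and biallelic VCF with AD depths.

Dosage matrices, read counts, pedigrees and phenotypes all travel as
plain CSV; genotypic read counts can additionally round-trip through
VCF using the per-sample allelic-depth (AD) field, the form in which
variant callers deliver them.  VCF reading accepts only biallelic SNP
records — multiallelic sites are dropped with a count reported.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from polygs.dosage import MISSING, DosageMatrix, ReadCountTable
from polygs.simpop import Pedigree

logger = logging.getLogger(__name__)

__all__ = [
    "write_dosage_csv",
    "read_dosage_csv",
    "write_read_counts_csv",
    "read_counts_csv",
    "write_pedigree_csv",
    "read_pedigree_csv",
    "write_phenotypes_csv",
    "read_phenotypes_csv",
    "write_relationship_csv",
    "read_relationship_csv",
    "write_vcf",
    "read_vcf",
]


def write_dosage_csv(dosages: DosageMatrix, path) -> None:
    frame = pd.DataFrame(
        dosages.data.astype(np.int64), index=dosages.individuals, columns=dosages.markers
    )
    frame.to_csv(path)


def read_dosage_csv(path, ploidy: int = 4, metadata: pd.DataFrame | None = None) -> DosageMatrix:
    frame = pd.read_csv(path, index_col=0)
    data = frame.to_numpy()
    data = np.where(pd.isna(data), MISSING, data).astype(np.int8)
    return DosageMatrix(
        data,
        pd.Index(frame.index.astype(str)),
        pd.Index(frame.columns.astype(str)),
        ploidy,
        metadata,
    )


def write_read_counts_csv(counts: ReadCountTable, path) -> None:
    counts.to_frame().to_csv(path, index=False)


def read_counts_csv(path) -> ReadCountTable:
    frame = pd.read_csv(path)
    return ReadCountTable.from_frame(frame)


def write_pedigree_csv(pedigree: Pedigree, path) -> None:
    pedigree.records.to_csv(path, index=False)


def read_pedigree_csv(path) -> Pedigree:
    rec = pd.read_csv(path)
    rec["dam"] = rec["dam"].where(pd.notna(rec["dam"]), None)
    rec["sire"] = rec["sire"].where(pd.notna(rec["sire"]), None)
    return Pedigree(rec)


def write_phenotypes_csv(table, path) -> None:
    frame = table.data if hasattr(table, "data") else table
    frame.to_csv(path, index=False)


def read_phenotypes_csv(path):
    from polygs.phenomodel import PhenotypeTable

    return PhenotypeTable(pd.read_csv(path))


def write_relationship_csv(matrix, path) -> None:
    matrix.to_frame().to_csv(path)


def read_relationship_csv(path, provenance: str = "genomic", ploidy: int = 4):
    from polygs.kinship import RelationshipMatrix

    frame = pd.read_csv(path, index_col=0)
    return RelationshipMatrix(
        frame.to_numpy(dtype=float), pd.Index(frame.index.astype(str)), provenance, ploidy
    )


# ---------------------------------------------------------------------------
# VCF


def write_vcf(counts: ReadCountTable, path, ref_allele: str = "A", alt_allele: str = "T") -> None:
    """Write read counts as a biallelic VCF with AD (no GT claims made).

    Marker metadata supplies CHROM/POS when present; otherwise markers
    land consecutively on a synthetic chromosome.
    """
    path = Path(path)
    meta = counts.metadata
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths for the ref and alt alleles">\n'
        )
        chroms = (
            meta["chrom"].unique().tolist() if meta is not None else ["chrSim"]
        )
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        header += list(counts.individuals.astype(str))
        fh.write("\t".join(header) + "\n")
        for j, marker in enumerate(counts.markers):
            if meta is not None:
                chrom = str(meta["chrom"].iloc[j])
                pos = int(meta["pos"].iloc[j])
            else:
                chrom, pos = "chrSim", j + 1
            fields = [chrom, str(pos), str(marker), ref_allele, alt_allele, ".", "PASS", ".", "AD"]
            for i in range(counts.n_individuals):
                fields.append(f"{counts.ref[i, j]},{counts.alt[i, j]}")
            fh.write("\t".join(fields) + "\n")


def read_vcf(path) -> ReadCountTable:
    """Read a biallelic VCF with per-sample AD into a read-count table.

    Multiallelic records are skipped (triallelic exclusion happens at
    ingestion); a missing AD for a sample becomes zero depth.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    refs, alts, markers = [], [], []
    meta_rows = []
    n_dropped = 0
    for record in vcf:
        if len(record.ALT) != 1:
            n_dropped += 1
            continue
        ad = record.format("AD")
        if ad is None:
            n_dropped += 1
            continue
        ad = np.asarray(ad)
        ad = np.where(ad < 0, 0, ad)  # cyvcf2 encodes missing as negative
        refs.append(ad[:, 0])
        alts.append(ad[:, 1])
        name = record.ID if record.ID not in (None, ".") else f"{record.CHROM}_{record.POS}"
        markers.append(name)
        meta_rows.append({"reference": "vcf", "chrom": record.CHROM, "pos": record.POS})
    if n_dropped:
        logger.info("dropped %d non-biallelic or AD-less records", n_dropped)
    if not markers:
        raise ValueError("no usable biallelic AD records in VCF")
    meta = pd.DataFrame(meta_rows, index=pd.Index(markers, name="marker"))
    return ReadCountTable(
        np.column_stack(refs),
        np.column_stack(alts),
        pd.Index(individuals),
        pd.Index(markers),
        meta,
    )
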