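"""Readers and writers for the pipeline's on-disk formats.

VCF 4.2 via pysam (GT/DP/GQ FORMAT fields, MQ INFO field), FASTA via
Biopython, and headered TSV/CSV tables via pandas. Coordinates in every
format are 1-based inclusive; GRM tables are square with matching header
and first-column individual ids.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .consensus import GeneAlignment, ReferenceSet
from .containers import MISSING, Pedigree, VariantTable
from .relatedness import GRM


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Ordered id -> sequence mapping; duplicate record ids are an error."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA record id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(path: str | Path, records: dict[str, str] | list[tuple[str, str]]) -> None:
    items = records.items() if isinstance(records, dict) else records
    seqs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    SeqIO.write(seqs, str(path), "fasta")


def read_alignment(path: str | Path, gene_id: str | None = None) -> GeneAlignment:
    gene = gene_id or Path(path).stem
    return GeneAlignment(gene, list(read_fasta(path).items()))


def read_alignments_dir(directory: str | Path, pattern: str = "*.fasta") -> list[GeneAlignment]:
    paths = sorted(Path(directory).glob(pattern))
    if not paths:
        raise FileNotFoundError(f"no {pattern} alignments under {directory}")
    return [read_alignment(p) for p in paths]


def write_reference(path: str | Path, reference: ReferenceSet) -> None:
    write_fasta(path, reference.sequences)


# ---------------------------------------------------------------- pedigree

def read_pedigree(path: str | Path) -> Pedigree:
    table = pd.read_csv(path, dtype=str).fillna("")
    return Pedigree(table)


def write_pedigree(path: str | Path, pedigree: Pedigree) -> None:
    pedigree.table.to_csv(path, index=False)


# ---------------------------------------------------------------- GRM

def write_grm(path: str | Path, grm: GRM) -> None:
    frame = pd.DataFrame(grm.matrix, index=grm.individual_ids, columns=grm.individual_ids)
    frame.index.name = "individual_id"
    frame.to_csv(path, sep="\t", float_format="%.12g")


def read_grm(path: str | Path, allele_frequency_source: str = "sample", n_loci: int = 0) -> GRM:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if list(frame.index) != list(frame.columns):
        raise ValueError(f"GRM header and first column disagree in {path}")
    return GRM(list(frame.index), frame.to_numpy(dtype=float), allele_frequency_source, n_loci)


# ---------------------------------------------------------------- VCF

def write_vcf(path: str | Path, table: VariantTable) -> None:
    """Write the table as an uncompressed VCF 4.2 file."""
    header = pysam.VariantHeader()
    contigs = dict(table.contigs)
    for chrom in dict.fromkeys(table.loci["chrom"]):
        if chrom not in contigs:
            sub = table.loci[table.loci["chrom"] == chrom]
            contigs[chrom] = int(sub["pos"].max()) + 1000
    for chrom, length in contigs.items():
        header.contigs.add(str(chrom), length=int(length))
    header.add_meta(
        "INFO",
        items=[("ID", "MQ"), ("Number", "1"), ("Type", "Float"),
               ("Description", "RMS mapping quality")],
    )
    header.add_meta(
        "FORMAT",
        items=[("ID", "GT"), ("Number", "1"), ("Type", "String"), ("Description", "Genotype")],
    )
    if table.depth is not None:
        header.add_meta(
            "FORMAT",
            items=[("ID", "DP"), ("Number", "1"), ("Type", "Integer"), ("Description", "Read depth")],
        )
    if table.gq is not None:
        header.add_meta(
            "FORMAT",
            items=[("ID", "GQ"), ("Number", "1"), ("Type", "Integer"),
                   ("Description", "Genotype quality")],
        )
    for iid in table.individual_ids:
        header.add_sample(iid)

    gt_codes = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, locus in enumerate(table.loci.itertuples(index=False)):
            rec = out.new_record(
                contig=str(locus.chrom),
                start=int(locus.pos) - 1,
                alleles=(str(locus.ref), *[str(a) for a in locus.alt]),
            )
            if not np.isnan(locus.mapq):
                rec.info["MQ"] = float(locus.mapq)
            for i, iid in enumerate(table.individual_ids):
                sample = rec.samples[iid]
                sample["GT"] = gt_codes[int(table.codes[i, j])]
                if table.depth is not None and not np.isnan(table.depth[i, j]):
                    sample["DP"] = int(table.depth[i, j])
                if table.gq is not None and not np.isnan(table.gq[i, j]):
                    sample["GQ"] = int(table.gq[i, j])
            out.write(rec)


def read_vcf(path: str | Path) -> VariantTable:
    """Parse a VCF into a VariantTable.

    Genotype codes count non-reference alleles; a genotype with any
    uncalled allele is missing. DP/GQ/MQ annotations absent from the file
    are surfaced as ``None`` (whole field) or NaN (single genotype), never
    as zero.
    """
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot parse VCF {path}: {exc}") from None
    samples = list(vcf.header.samples)
    has_dp = "DP" in vcf.header.formats
    has_gq = "GQ" in vcf.header.formats
    contigs = {name: c.length for name, c in vcf.header.contigs.items() if c.length}

    loci_rows, code_cols, dp_cols, gq_cols = [], [], [], []
    try:
        for line_no, rec in enumerate(vcf, start=1):
            if rec.alts is None:
                continue
            loci_rows.append(
                {
                    "locus_id": f"{rec.chrom}:{rec.pos}",
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": tuple(rec.alts),
                    "mapq": float(rec.info["MQ"]) if "MQ" in rec.info else np.nan,
                }
            )
            codes, dps, gqs = [], [], []
            for s in samples:
                sample = rec.samples[s]
                gt = sample.get("GT", (None,))
                if gt is None or any(a is None for a in gt):
                    codes.append(MISSING)
                else:
                    codes.append(sum(1 for a in gt if a != 0))
                dp = sample.get("DP") if has_dp else None
                gq = sample.get("GQ") if has_gq else None
                dps.append(np.nan if dp is None else float(dp))
                gqs.append(np.nan if gq is None else float(gq))
            code_cols.append(codes)
            dp_cols.append(dps)
            gq_cols.append(gqs)
    except (OSError, ValueError) as exc:
        raise ValueError(f"malformed VCF {path} near record {len(loci_rows) + 1}: {exc}") from None

    loci = pd.DataFrame(loci_rows, columns=["locus_id", "chrom", "pos", "ref", "alt", "mapq"])
    n = len(loci)
    codes = np.array(code_cols, dtype=np.int8).T if n else np.zeros((len(samples), 0), np.int8)
    return VariantTable(
        loci=loci,
        individual_ids=samples,
        codes=codes,
        depth=np.array(dp_cols, dtype=float).T if (has_dp and n) else None,
        gq=np.array(gq_cols, dtype=float).T if (has_gq and n) else None,
        contigs=contigs,
    )


# ---------------------------------------------------------------- tables

_TSV_KWARGS = {"sep": "\t", "index": False, "float_format": "%.12g"}


def write_tsv(path: str | Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, **_TSV_KWARGS)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_provenance(out_dir: str | Path, config: dict, seed: int) -> None:
    """Record the run's configuration and seed next to its outputs."""
    from . import __version__

    payload = {"capkin_version": __version__, "seed": seed, "config": config}
    path = Path(out_dir) / "provenance.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
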