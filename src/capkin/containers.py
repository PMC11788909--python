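"""Core in-memory containers shared across the pipeline.

Genotypes are coded as alternate-allele counts {0, 1, 2}; ``-1`` marks a
missing call. Coordinates are 1-based and inclusive throughout, following
VCF conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

PEDIGREE_COLUMNS = ["individual_id", "family_id", "provenance_id", "mother_id", "father_id"]


@dataclass
class Pedigree:
    """Assignment of individuals to half-sib families nested in provenances.

    One record per sampled individual. Half-sibs share ``mother_id`` and
    carry distinct ``father_id`` values; ``father_id`` may be empty when the
    paternal parent is unknown.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing_cols = [c for c in PEDIGREE_COLUMNS[:3] if c not in self.table.columns]
        if missing_cols:
            raise ValueError(f"pedigree table lacks columns: {missing_cols}")
        for col in PEDIGREE_COLUMNS[3:]:
            if col not in self.table.columns:
                self.table[col] = ""
        ids = self.table["individual_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise ValueError(f"duplicate individual ids in pedigree: {dupes}")
        self.table = self.table.reset_index(drop=True)

    @property
    def individual_ids(self) -> list[str]:
        return list(self.table["individual_id"])

    @property
    def family_ids(self) -> list[str]:
        """Family ids in order of first appearance."""
        return list(dict.fromkeys(self.table["family_id"]))

    def family_of(self) -> dict[str, str]:
        return dict(zip(self.table["individual_id"], self.table["family_id"]))

    def members(self, family_id: str) -> list[str]:
        sub = self.table[self.table["family_id"] == family_id]
        return list(sub["individual_id"])

    def with_assignments(self, assignments: dict[str, str]) -> "Pedigree":
        """Return a copy with some individuals moved to new families."""
        table = self.table.copy()
        mask = table["individual_id"].isin(assignments)
        table.loc[mask, "family_id"] = table.loc[mask, "individual_id"].map(assignments)
        return Pedigree(table)

    def drop(self, individual_ids: list[str]) -> "Pedigree":
        keep = ~self.table["individual_id"].isin(individual_ids)
        return Pedigree(self.table[keep].reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic loci matrix of alternate-allele counts."""

    individual_ids: list[str]
    locus_ids: list[str]
    codes: np.ndarray  # (n_individuals, n_loci), int8; -1 = missing

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.individual_ids), len(self.locus_ids)):
            raise ValueError(
                f"codes shape {self.codes.shape} inconsistent with "
                f"{len(self.individual_ids)} individuals x {len(self.locus_ids)} loci"
            )
        valid = np.isin(self.codes, (MISSING, 0, 1, 2))
        if not valid.all():
            bad = sorted(np.unique(self.codes[~valid]).tolist())
            raise ValueError(f"genotype codes outside {{-1,0,1,2}}: {bad}")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def subset_individuals(self, ids: list[str]) -> "GenotypeMatrix":
        index = {iid: i for i, iid in enumerate(self.individual_ids)}
        unknown = [i for i in ids if i not in index]
        if unknown:
            raise KeyError(f"unknown individuals: {unknown}")
        rows = [index[i] for i in ids]
        return GenotypeMatrix(list(ids), list(self.locus_ids), self.codes[rows])


@dataclass
class VariantTable:
    """VCF-backed view of observed variants.

    ``loci`` holds one row per site with columns ``locus_id``, ``chrom``,
    ``pos`` (1-based), ``ref``, ``alt`` (tuple of alternate alleles) and
    ``mapq`` (site mapping quality, NaN when the annotation is absent).
    ``depth``/``gq`` are per-genotype arrays aligned with ``codes``; ``None``
    when the corresponding FORMAT field is absent from the source, NaN for
    individually missing annotations.
    """

    loci: pd.DataFrame
    individual_ids: list[str]
    codes: np.ndarray  # (n_individuals, n_loci) int8, -1 missing
    depth: np.ndarray | None = None
    gq: np.ndarray | None = None
    contigs: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"locus_id", "chrom", "pos", "ref", "alt"}
        missing_cols = required - set(self.loci.columns)
        if missing_cols:
            raise ValueError(f"loci table lacks columns: {sorted(missing_cols)}")
        if "mapq" not in self.loci.columns:
            self.loci["mapq"] = np.nan
        self.codes = np.asarray(self.codes, dtype=np.int8)
        shape = (len(self.individual_ids), len(self.loci))
        if self.codes.shape != shape:
            raise ValueError(f"codes shape {self.codes.shape}, expected {shape}")
        for name in ("depth", "gq"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != shape:
                    raise ValueError(f"{name} shape {arr.shape}, expected {shape}")
                setattr(self, name, arr)
        self.loci = self.loci.reset_index(drop=True)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def subset_loci(self, keep: np.ndarray) -> "VariantTable":
        """Subset by boolean mask or integer index over loci."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return VariantTable(
            loci=self.loci.iloc[keep].reset_index(drop=True),
            individual_ids=list(self.individual_ids),
            codes=self.codes[:, keep],
            depth=None if self.depth is None else self.depth[:, keep],
            gq=None if self.gq is None else self.gq[:, keep],
            contigs=dict(self.contigs),
        )

    def to_genotype_matrix(self) -> GenotypeMatrix:
        return GenotypeMatrix(
            list(self.individual_ids), list(self.loci["locus_id"]), self.codes.copy()
        )
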