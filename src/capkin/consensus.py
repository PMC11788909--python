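"""Plurality consensus over per-gene multiple sequence alignments.

A species reference is built by taking, for each gene, the column-wise
plurality consensus of the gene's alignment (one aligned sequence per
individual) and concatenating the per-gene consensi into a reference set.
Ambiguity codes in the input are expanded fractionally across their bases
before counting, ties emit the IUPAC code of the tied base set, and columns
whose consensus is a gap can be dropped to yield an ungapped reference
suitable as a mapping or primer-design template.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd

from ._iupac import GAP_SYMBOLS, IUPAC_TO_BASES, ambiguity_code

logger = logging.getLogger(__name__)

DEFAULT_PLURALITY = 0.5
_TOL = 1e-9


@dataclass
class GeneAlignment:
    """A gene's MSA: equal-length sequences over {A,C,G,T,IUPAC,-,N}."""

    gene_id: str
    records: list[tuple[str, str]]  # (individual_id, aligned sequence)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError(f"alignment {self.gene_id} has no records")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise ValueError(f"alignment {self.gene_id} has ragged sequences: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    def column(self, i: int) -> list[str]:
        return [seq[i] for _, seq in self.records]


@dataclass
class ReferenceSet:
    """Ordered (gene_id, consensus) pairs plus a per-gene report."""

    sequences: list[tuple[str, str]]
    report: pd.DataFrame = field(default_factory=pd.DataFrame)

    def as_dict(self) -> dict[str, str]:
        return dict(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)


def column_consensus(column: list[str], plurality_fraction: float = DEFAULT_PLURALITY) -> str:
    """Consensus symbol for one alignment column.

    Each symbol's weight is spread evenly over the bases of its IUPAC set
    (N contributes 1/4 to each base). The most frequent base is returned if
    its weight is at least ``plurality_fraction`` of the non-gap total; ties
    at the top return the ambiguity code of the tied set; a single top base
    short of the plurality threshold yields the ambiguity code over every
    base observed in the column (so the output's base set never exceeds
    what the column contains); an all-gap column yields ``-``.
    """
    if not column:
        raise ValueError("empty column")
    if not 0.0 < plurality_fraction <= 1.0:
        raise ValueError(f"plurality_fraction must be in (0,1], got {plurality_fraction}")
    weights = {b: 0.0 for b in "ACGT"}
    non_gap = 0.0
    for pos, symbol in enumerate(column):
        s = symbol.upper()
        if s in GAP_SYMBOLS:
            continue
        bases = IUPAC_TO_BASES.get(s)
        if bases is None:
            raise ValueError(f"invalid symbol {symbol!r} at record position {pos}")
        share = 1.0 / len(bases)
        for b in bases:
            weights[b] += share
        non_gap += 1.0
    if non_gap == 0.0:
        return "-"
    top = max(weights.values())
    tied = frozenset(b for b, w in weights.items() if w >= top - _TOL)
    if len(tied) > 1:
        return ambiguity_code(tied)
    if top / non_gap + _TOL < plurality_fraction:
        return ambiguity_code(frozenset(b for b, w in weights.items() if w > 0))
    return next(iter(tied))


def gene_consensus(
    alignment: GeneAlignment,
    plurality_fraction: float = DEFAULT_PLURALITY,
    drop_gap_columns: bool = True,
) -> str:
    """Column-wise consensus of one gene alignment."""
    out = []
    for i in range(alignment.length):
        try:
            symbol = column_consensus(alignment.column(i), plurality_fraction)
        except ValueError as exc:
            raise ValueError(f"gene {alignment.gene_id}, column {i + 1}: {exc}") from None
        if symbol == "-" and drop_gap_columns:
            continue
        out.append(symbol)
    return "".join(out)


def build_reference(
    alignments: list[GeneAlignment],
    plurality_fraction: float = DEFAULT_PLURALITY,
    drop_gap_columns: bool = True,
) -> ReferenceSet:
    """Consensus for every gene, preserving input order, with a summary report."""
    seen: set[str] = set()
    for aln in alignments:
        if aln.gene_id in seen:
            raise ValueError(f"duplicate gene_id {aln.gene_id!r}")
        seen.add(aln.gene_id)
    if not alignments:
        warnings.warn("no alignments supplied; reference set is empty", stacklevel=2)
    sequences = []
    rows = []
    for aln in alignments:
        cons = gene_consensus(aln, plurality_fraction, drop_gap_columns)
        sequences.append((aln.gene_id, cons))
        rows.append(
            {
                "gene_id": aln.gene_id,
                "n_sequences": len(aln.records),
                "alignment_length": aln.length,
                "consensus_length": len(cons),
            }
        )
    report = pd.DataFrame(rows, columns=["gene_id", "n_sequences", "alignment_length", "consensus_length"])
    if rows:
        logger.info(
            "built reference: %d genes, mean consensus length %.1f",
            len(rows),
            report["consensus_length"].mean(),
        )
    return ReferenceSet(sequences=sequences, report=report)
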