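"""Relatedness-based pedigree correction.

Two moves, applied in a fixed order:

1. *Exclusion*: an individual whose realized relatedness to every other
   sampled individual falls below ``unrelated_threshold`` is dropped — it
   is unrelated to all material in the study (e.g. a sample mix-up with
   off-pedigree material).
2. *Reassignment*: after exclusions, each remaining individual's mean
   relatedness to every family's other members is computed; it is moved to
   the best-scoring family when that mean clears ``reassign_threshold`` and
   exceeds its own family's mean by at least ``margin``.

Both moves are evaluated in a single pass in individual-id order against
the pedigree as it stood on entry — no cascading re-evaluation — so the
result is a deterministic function of (GRM, pedigree, config). Defaults sit
around the half-sib expectation of 0.25: an individual genuinely belonging
to a half-sib family should show mean relatedness near 0.25 to it, and
near zero to families it does not belong to.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import Pedigree
from .relatedness import GRM, FamilySummary, family_mean_relatedness

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrectionConfig:
    unrelated_threshold: float = 0.1
    reassign_threshold: float = 0.125
    margin: float = 0.1

    def __post_init__(self) -> None:
        if min(self.unrelated_threshold, self.reassign_threshold, self.margin) < 0:
            raise ValueError("thresholds and margin must be non-negative")


@dataclass
class CorrectionResult:
    """Moves made plus before/after family summaries."""

    excluded: list[tuple[str, float]]  # (individual_id, max off-diagonal r)
    reassignments: list[tuple[str, str, str, float]]  # (id, old, new, best mean r)
    pedigree_after: Pedigree
    summary_before: FamilySummary
    summary_after: FamilySummary

    def __post_init__(self) -> None:
        overlap = {i for i, _ in self.excluded} & {r[0] for r in self.reassignments}
        if overlap:
            raise ValueError(f"individuals both excluded and reassigned: {sorted(overlap)}")


def flag_unrelated(grm: GRM, pedigree: Pedigree, config: CorrectionConfig) -> list[tuple[str, float]]:
    """Individuals whose maximum off-diagonal relatedness is below threshold."""
    sub = grm.reorder(pedigree.individual_ids)
    mat = sub.matrix.copy()
    np.fill_diagonal(mat, -np.inf)
    flagged = []
    for i, iid in enumerate(pedigree.individual_ids):
        max_r = float(mat[i].max())
        if max_r < config.unrelated_threshold:
            flagged.append((iid, max_r))
    return flagged


def _family_means(grm_sub: np.ndarray, ids: list[str], pedigree: Pedigree, iid: str) -> dict[str, float]:
    """Mean r from ``iid`` to the *other* members of each family."""
    index = {x: i for i, x in enumerate(ids)}
    i = index[iid]
    means = {}
    for fam in pedigree.family_ids:
        others = [index[m] for m in pedigree.members(fam) if m != iid]
        if others:
            means[fam] = float(grm_sub[i, others].mean())
    return means


def reassign_individuals(
    grm: GRM, pedigree: Pedigree, config: CorrectionConfig
) -> tuple[Pedigree, list[tuple[str, str, str, float]]]:
    """Single-pass reassignment against the entry pedigree.

    Exclusions are expected to have been applied already. An individual in
    a family where it is the only member has no within-family pairs; its
    own-family mean is treated as absent and the margin condition is
    vacuously satisfied. Exact ties between the best foreign family and the
    own family never move (the margin rule) and are logged.
    """
    ids = pedigree.individual_ids
    sub = grm.reorder(ids)
    moves: list[tuple[str, str, str, float]] = []
    fam_of = pedigree.family_of()
    for iid in ids:
        means = _family_means(sub.matrix, ids, pedigree, iid)
        own = fam_of[iid]
        own_mean = means.get(own)
        candidates = {f: m for f, m in means.items() if f != own}
        if not candidates:
            continue
        best_fam = max(sorted(candidates), key=lambda f: candidates[f])
        best = candidates[best_fam]
        if best < config.reassign_threshold:
            continue
        if own_mean is not None:
            if best - own_mean == 0.0:
                logger.info("tie for %s between %s and %s; no move", iid, own, best_fam)
                continue
            if best - own_mean < config.margin:
                continue
        moves.append((iid, own, best_fam, best))
    new_ped = pedigree.with_assignments({iid: new for iid, _, new, _ in moves})
    return new_ped, moves


def correct_pedigree(grm: GRM, pedigree: Pedigree, config: CorrectionConfig | None = None) -> CorrectionResult:
    """Exclusion then reassignment, with before/after family summaries."""
    config = config or CorrectionConfig()
    summary_before = family_mean_relatedness(grm, pedigree)
    excluded = flag_unrelated(grm, pedigree, config)
    kept = pedigree.drop([iid for iid, _ in excluded])
    after, moves = reassign_individuals(grm, kept, config)
    summary_after = family_mean_relatedness(grm, after)
    return CorrectionResult(
        excluded=excluded,
        reassignments=moves,
        pedigree_after=after,
        summary_before=summary_before,
        summary_after=summary_after,
    )


def correction_report(result: CorrectionResult) -> pd.DataFrame:
    """Side-by-side family means before (BPC) and after (APC) correction.

    Families emptied by the moves appear with zero members and undefined
    (NaN) means.
    """
    before = result.summary_before.table.set_index("family_id")
    after = result.summary_after.table.set_index("family_id")
    fams = list(dict.fromkeys(list(before.index) + list(after.index)))
    rows = []
    for fam in fams:
        b = before.loc[fam] if fam in before.index else None
        a = after.loc[fam] if fam in after.index else None
        rows.append(
            {
                "family_id": fam,
                "n_before": 0 if b is None else int(b["n_members"]),
                "mean_r_bpc": np.nan if b is None else b["mean_r"],
                "sd_r_bpc": np.nan if b is None else b["sd_r"],
                "n_after": 0 if a is None else int(a["n_members"]),
                "mean_r_apc": np.nan if a is None else a["mean_r"],
                "sd_r_apc": np.nan if a is None else a["sd_r"],
            }
        )
    return pd.DataFrame(rows)
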