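"""Realized genomic relatedness from SNP genotypes.

The genomic relationship matrix (GRM) follows VanRaden's first method:
with genotype codes M in {0,1,2} and per-locus allele frequencies p,
Z = M - 2p and G = ZZ' / (2 * sum_j p_j (1 - p_j)). Off-diagonal entries
estimate additive relatedness (0.25 expected for half-sibs); the diagonal
is 1 + F. Allele frequencies may come from the sample itself or from an
external panel — with small, related samples the sample-frequency GRM
systematically underestimates within-family relatedness, which is why both
sources are supported.

Family structure is inspected by eigendecomposition of the double-centered
GRM (a PCA on relatedness), nearest-centroid agreement with the pedigree
("grouping similarity"), per-family mean pairwise relatedness, and Pearson
correlation between GRMs from two marker panels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, Pedigree

HALF_SIB_EXPECTED_RELATEDNESS = 0.25


@dataclass
class GRM:
    """Symmetric realized-relatedness matrix with provenance metadata."""

    individual_ids: list[str]
    matrix: np.ndarray
    allele_frequency_source: str  # "sample" or "external"
    n_loci: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.individual_ids)
        if self.matrix.shape != (n, n):
            raise ValueError(f"GRM shape {self.matrix.shape} for {n} individuals")
        if not np.isfinite(self.matrix).all():
            raise ValueError("GRM contains non-finite entries")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("GRM is not symmetric")

    def reorder(self, ids: list[str]) -> "GRM":
        index = {iid: i for i, iid in enumerate(self.individual_ids)}
        unknown = [i for i in ids if i not in index]
        if unknown:
            raise KeyError(f"individuals not in GRM: {unknown}")
        idx = np.array([index[i] for i in ids])
        return GRM(list(ids), self.matrix[np.ix_(idx, idx)], self.allele_frequency_source, self.n_loci)

    def value(self, a: str, b: str) -> float:
        i = self.individual_ids.index(a)
        j = self.individual_ids.index(b)
        return float(self.matrix[i, j])


def allele_frequencies(matrix: GenotypeMatrix) -> np.ndarray:
    """Per-locus alternate-allele frequency p = sum(codes) / (2 * called)."""
    obs = matrix.codes != MISSING
    n = obs.sum(axis=0)
    empty = np.flatnonzero(n == 0)
    if empty.size:
        bad = [matrix.locus_ids[i] for i in empty[:10]]
        raise ValueError(f"loci with no called genotype: {bad}")
    return np.where(obs, matrix.codes, 0).sum(axis=0) / (2.0 * n)


def vanraden_grm(matrix: GenotypeMatrix, freqs: np.ndarray | str = "sample") -> GRM:
    """VanRaden method-1 GRM with a single global denominator.

    Missing codes are imputed to the locus mean 2p before centering. Loci
    fixed under the supplied frequencies (p of 0 or 1) carry no information
    and are excluded from numerator and denominator alike; ``n_loci``
    records how many loci actually contributed.
    """
    if isinstance(freqs, str):
        if freqs != "sample":
            raise ValueError(f"freqs must be an array or 'sample', got {freqs!r}")
        p = allele_frequencies(matrix)
        source = "sample"
    else:
        p = np.asarray(freqs, dtype=float)
        if p.shape != (matrix.n_loci,):
            raise ValueError(f"expected {matrix.n_loci} frequencies, got {p.shape}")
        source = "external"

    informative = (p > 0.0) & (p < 1.0)
    if not informative.any():
        raise ValueError("all loci are monomorphic under the supplied frequencies")
    p = p[informative]
    codes = matrix.codes[:, informative].astype(float)
    codes[matrix.codes[:, informative] == MISSING] = np.nan
    M = np.where(np.isnan(codes), 2.0 * p, codes)
    Z = M - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    G = (Z @ Z.T) / denom
    G = (G + G.T) / 2.0  # enforce exact symmetry against fp round-off
    return GRM(list(matrix.individual_ids), G, source, int(informative.sum()))


def grm_pca(grm: GRM, n_components: int) -> tuple[np.ndarray, np.ndarray]:
    """Principal coordinates of the double-centered GRM.

    Returns ``(coordinates, eigenvalues)`` with columns sorted by
    descending eigenvalue (ties broken by original index); coordinates are
    eigenvectors scaled by sqrt of the non-negative eigenvalues, so their
    Gram matrix reconstructs the centered GRM at full rank.
    """
    n = len(grm.individual_ids)
    if not 0 < n_components < n:
        raise ValueError(f"n_components must be in [1, {n - 1}], got {n_components}")
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ grm.matrix @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(-eigval, kind="stable")
    eigval = eigval[order][:n_components]
    eigvec = eigvec[:, order][:, :n_components]
    coords = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
    return coords, eigval


@dataclass
class FamilySummary:
    """Per-family mean and SD of within-family pairwise relatedness."""

    table: pd.DataFrame  # family_id, n_members, n_pairs, mean_r, sd_r

    def mean_of(self, family_id: str) -> float:
        row = self.table[self.table["family_id"] == family_id]
        if row.empty:
            raise KeyError(f"family {family_id!r} not in summary")
        return float(row["mean_r"].iloc[0])


def family_mean_relatedness(grm: GRM, pedigree: Pedigree, ddof: int = 1) -> FamilySummary:
    """Mean +/- SD over the C(n,2) within-family off-diagonal entries.

    Families with fewer than two members have no pairs; their mean is
    reported as NaN. The SD is the sample SD (``ddof=1``) and 0.0 when only
    a single pair exists.
    """
    index = {iid: i for i, iid in enumerate(grm.individual_ids)}
    unknown = [i for i in pedigree.individual_ids if i not in index]
    if unknown:
        raise KeyError(f"pedigree individuals missing from GRM: {unknown}")
    rows = []
    for fam in pedigree.family_ids:
        members = [index[m] for m in pedigree.members(fam)]
        pair_values = [
            grm.matrix[a, b] for k, a in enumerate(members) for b in members[k + 1 :]
        ]
        values = np.array(pair_values, dtype=float)
        if values.size == 0:
            mean_r, sd_r = np.nan, np.nan
        elif values.size == 1:
            mean_r, sd_r = float(values[0]), 0.0
        else:
            mean_r = float(values.mean())
            sd_r = float(values.std(ddof=ddof))
        rows.append(
            {
                "family_id": fam,
                "n_members": len(members),
                "n_pairs": int(values.size),
                "mean_r": mean_r,
                "sd_r": sd_r,
            }
        )
    return FamilySummary(pd.DataFrame(rows))


def grouping_similarity(
    coordinates: np.ndarray,
    pedigree: Pedigree,
    grm_ids: list[str],
    n_components: int = 2,
) -> tuple[float, dict[str, str]]:
    """Agreement between PCA clustering and the pedigree's families.

    Each individual is assigned to the family whose centroid (over the top
    ``n_components`` coordinates) is nearest in Euclidean distance; the
    similarity is the fraction assigned to their own pedigree family. Ties
    are broken by family id order. This nearest-centroid definition is a
    declared surrogate for visual cluster agreement.
    """
    families = pedigree.family_ids
    if len(families) < 2:
        raise ValueError("grouping similarity needs at least two families")
    coords = np.asarray(coordinates, dtype=float)[:, :n_components]
    index = {iid: i for i, iid in enumerate(grm_ids)}
    centroids = np.vstack(
        [coords[[index[m] for m in pedigree.members(f)]].mean(axis=0) for f in families]
    )
    if np.allclose(coords, coords[0]):
        warnings.warn("degenerate geometry: all coordinates identical", stacklevel=2)
    assignment: dict[str, str] = {}
    hits = 0
    fam_of = pedigree.family_of()
    for iid in pedigree.individual_ids:
        d = np.linalg.norm(centroids - coords[index[iid]], axis=1)
        chosen = families[int(np.argmin(d))]  # argmin keeps first on ties = family id order
        assignment[iid] = chosen
        hits += chosen == fam_of[iid]
    return hits / len(pedigree), assignment


def grm_correlation(grm_a: GRM, grm_b: GRM, include_diagonal: bool = True) -> float:
    """Pearson correlation of two GRMs over the lower triangle.

    The diagonal (self-relatedness) is included by default, matching
    comparisons of relatedness values "including self" between marker
    panels. ``grm_b`` is reordered to ``grm_a``'s individuals.
    """
    if set(grm_a.individual_ids) != set(grm_b.individual_ids):
        raise ValueError("GRMs cover different individual sets")
    b = grm_b.reorder(grm_a.individual_ids)
    k = 0 if include_diagonal else -1
    idx = np.tril_indices(len(grm_a.individual_ids), k=k)
    return float(np.corrcoef(grm_a.matrix[idx], b.matrix[idx])[0, 1])
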