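"""Synthetic half-sib datasets for marker-development pipelines.

Emulates the data structure of a target-capture marker study: half-sib
families (shared mother, per-offspring unrelated fathers) nested in
provenances; biallelic SNPs embedded in gene-like loci; and a noisy
observation layer carrying read depth, genotype quality, genotype error and
missingness on top of a retained ground truth.

All randomness flows from ``SimConfig.seed`` through named substreams, so a
fixed config yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, Pedigree, VariantTable
from ._iupac import ambiguity_code

_STREAMS = {"pedigree": 1, "genotypes": 2, "observation": 3, "sequences": 4, "planting": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, _STREAMS[stream]])))


@dataclass(frozen=True)
class SimConfig:
    """Design of a simulated half-sib study.

    ``families_per_provenance`` accepts a single count or one count per
    provenance (e.g. ``(2, 1, 1)`` for an unbalanced design). Five offspring
    per family matches the common progeny-trial sampling depth. The founder
    minor-allele frequency is drawn uniformly on ``[maf_min, maf_max]`` so
    loci are informative and survive frequency-based filters in the
    noiseless limit. ``provenance_founder_pool`` optionally draws mothers and
    fathers from a finite per-provenance founder pool, inducing background
    relatedness within provenances; the default (``None``) keeps all
    founders unrelated, making the half-sib expectation of 0.25 exact.
    """

    n_provenances: int = 3
    families_per_provenance: int | Sequence[int] = 2
    offspring_per_family: int = 5
    n_genes: int = 100
    gene_length_bp: int = 800
    n_snps: int = 500
    maf_min: float = 0.05
    maf_max: float = 0.5
    genotype_error_rate: float = 0.01
    missing_rate: float = 0.05
    mean_depth: float = 30.0
    depth_dispersion: float = 5.0
    mapq_mean: float = 60.0
    mapq_sd: float = 2.0
    provenance_founder_pool: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_provenances": self.n_provenances,
            "offspring_per_family": self.offspring_per_family,
            "n_genes": self.n_genes,
            "gene_length_bp": self.gene_length_bp,
            "n_snps": self.n_snps,
        }
        for name, value in counts.items():
            if int(value) < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        for name in ("genotype_error_rate", "missing_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {p}")
        if not 0.0 < self.maf_min <= self.maf_max <= 0.5:
            raise ValueError("need 0 < maf_min <= maf_max <= 0.5")
        if self.mean_depth <= 0 or self.depth_dispersion <= 0:
            raise ValueError("mean_depth and depth_dispersion must be positive")
        fams = self.family_counts()
        if len(fams) != self.n_provenances or any(f < 1 for f in fams):
            raise ValueError("families_per_provenance must give >= 1 family per provenance")

    def family_counts(self) -> tuple[int, ...]:
        if isinstance(self.families_per_provenance, (int, np.integer)):
            return (int(self.families_per_provenance),) * self.n_provenances
        return tuple(int(f) for f in self.families_per_provenance)

    @property
    def n_families(self) -> int:
        return sum(self.family_counts())

    @property
    def n_individuals(self) -> int:
        return self.n_families * self.offspring_per_family


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Lay out half-sib families nested in provenances.

    Each family shares one mother; every offspring has its own father
    (optionally drawn from a finite provenance founder pool).
    """
    rng = _rng(config.seed, "pedigree")
    records = []
    fam_counter = 0
    ind_counter = 0
    for p_idx, n_fam in enumerate(config.family_counts()):
        prov = f"P{p_idx + 1:02d}"
        pool = config.provenance_founder_pool
        for _ in range(n_fam):
            fam_counter += 1
            fam = f"F{fam_counter:03d}"
            if pool is None:
                mother = f"{prov}_M{fam_counter:03d}"
            else:
                mother = f"{prov}_FND{rng.integers(pool) + 1:03d}"
            for _ in range(config.offspring_per_family):
                ind_counter += 1
                if pool is None:
                    father = f"{prov}_D{ind_counter:04d}"
                else:
                    father = f"{prov}_FND{rng.integers(pool) + 1:03d}"
                records.append(
                    {
                        "individual_id": f"I{ind_counter:04d}",
                        "family_id": fam,
                        "provenance_id": prov,
                        "mother_id": mother,
                        "father_id": father,
                    }
                )
    return Pedigree(pd.DataFrame.from_records(records))


def _gametes(genotypes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One Mendelian gamete per entry: 0/2 are fixed, heterozygotes coin-flip."""
    coin = rng.integers(0, 2, size=genotypes.shape)
    return np.where(genotypes == 1, coin, (genotypes == 2).astype(np.int64))


def simulate_genotypes(
    pedigree: Pedigree, config: SimConfig, return_parents: bool = False
):
    """Draw founder frequencies and Mendelian offspring genotypes.

    Returns ``(GenotypeMatrix, true_allele_frequencies)``; with
    ``return_parents`` also a dict of founder genotype rows keyed by parent
    id, used to verify Mendelian consistency.
    """
    rng = _rng(config.seed, "genotypes")
    n_loci = config.n_snps
    freqs = rng.uniform(config.maf_min, config.maf_max, size=n_loci)

    parent_ids = list(
        dict.fromkeys(list(pedigree.table["mother_id"]) + list(pedigree.table["father_id"]))
    )
    parents = {pid: rng.binomial(2, freqs).astype(np.int8) for pid in parent_ids}

    codes = np.empty((len(pedigree), n_loci), dtype=np.int8)
    for row_idx, rec in enumerate(pedigree.table.itertuples(index=False)):
        maternal = _gametes(parents[rec.mother_id], rng)
        paternal = _gametes(parents[rec.father_id], rng)
        codes[row_idx] = maternal + paternal

    locus_ids = [f"L{i + 1:05d}" for i in range(n_loci)]
    gm = GenotypeMatrix(pedigree.individual_ids, locus_ids, codes)
    if return_parents:
        return gm, freqs, parents
    return gm, freqs


@dataclass
class GeneSequences:
    """Per-gene templates and per-individual aligned sequences.

    ``snp_map`` has one row per locus: locus_id, gene_id, pos (1-based
    within the gene), ref, alt. ``alignments`` maps gene_id to ordered
    ``(individual_id, sequence)`` pairs; sequences are aligned by
    construction (no indels) and heterozygotes carry IUPAC ambiguity codes.
    """

    templates: dict[str, str]
    snp_map: pd.DataFrame
    alignments: dict[str, list[tuple[str, str]]]


def embed_snps_in_genes(
    genotypes: GenotypeMatrix, config: SimConfig, *, relabel_loci: bool = True
) -> GeneSequences:
    """Place the simulated loci at random positions in random gene templates.

    Loci are assigned to distinct template positions ordered by
    (gene, position); with ``relabel_loci`` the genotype matrix's locus ids
    are rewritten in place to ``gene:pos`` so every downstream artifact
    shares one naming scheme.
    """
    rng = _rng(config.seed, "sequences")
    n_loci = genotypes.n_loci
    total = config.n_genes * config.gene_length_bp
    if n_loci > total:
        raise ValueError(
            f"cannot place {n_loci} SNPs in {config.n_genes} genes x "
            f"{config.gene_length_bp} bp ({total} positions)"
        )
    bases = np.array(list("ACGT"))
    gene_ids = [f"g{g + 1:03d}" for g in range(config.n_genes)]
    templates = {
        gid: "".join(rng.choice(bases, size=config.gene_length_bp)) for gid in gene_ids
    }

    flat = np.sort(rng.choice(total, size=n_loci, replace=False))
    gene_idx = flat // config.gene_length_bp
    pos = flat % config.gene_length_bp + 1  # 1-based within gene

    refs, alts = [], []
    for g, p in zip(gene_idx, pos):
        ref = templates[gene_ids[g]][p - 1]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        refs.append(ref)
        alts.append(alt)

    snp_map = pd.DataFrame(
        {
            "locus_id": [f"{gene_ids[g]}:{p}" for g, p in zip(gene_idx, pos)],
            "gene_id": [gene_ids[g] for g in gene_idx],
            "pos": pos,
            "ref": refs,
            "alt": alts,
        }
    )
    if relabel_loci:
        genotypes.locus_ids = list(snp_map["locus_id"])

    alignments: dict[str, list[tuple[str, str]]] = {}
    for g_i, gid in enumerate(gene_ids):
        in_gene = np.flatnonzero(gene_idx == g_i)
        records = []
        for row, iid in enumerate(genotypes.individual_ids):
            seq = list(templates[gid])
            for j in in_gene:
                code = genotypes.codes[row, j]
                site = pos[j] - 1
                if code == 0:
                    seq[site] = refs[j]
                elif code == 2:
                    seq[site] = alts[j]
                elif code == 1:
                    seq[site] = ambiguity_code({refs[j], alts[j]})
                else:  # missing genotype
                    seq[site] = "N"
            records.append((iid, "".join(seq)))
        alignments[gid] = records
    return GeneSequences(templates=templates, snp_map=snp_map, alignments=alignments)


def _phred_gq(error_rate: float, shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    base = round(-10.0 * np.log10(max(error_rate, 1e-9)))
    gq = min(base, 99) + rng.integers(-2, 3, size=shape)
    return np.clip(gq, 0, 99).astype(float)


def apply_observation_model(
    genotypes: GenotypeMatrix,
    config: SimConfig,
    snp_map: pd.DataFrame | None = None,
) -> VariantTable:
    """Overlay depth, quality, genotype error and missingness on the truth.

    Depth is negative-binomial (mean ``mean_depth``, dispersion
    ``depth_dispersion``); with probability ``genotype_error_rate`` a call is
    flipped to a uniformly chosen different code; calls go missing
    independently with ``missing_rate``. GQ follows a Phred-like map of the
    error rate (jittered +/-2, capped at 99) so it is monotone decreasing in
    the error likelihood; site MapQ is drawn around ``mapq_mean``. The input
    matrix is left untouched and remains the ground truth.
    """
    if (genotypes.codes == MISSING).any():
        raise ValueError("observation model expects a complete ground-truth matrix")
    rng = _rng(config.seed, "observation")
    shape = genotypes.codes.shape
    n_disp = config.depth_dispersion
    depth = rng.negative_binomial(
        n_disp, n_disp / (n_disp + config.mean_depth), size=shape
    ).astype(float)

    observed = genotypes.codes.copy()
    flip = rng.random(shape) < config.genotype_error_rate
    # flip to one of the two other codes, uniformly
    offset = rng.integers(1, 3, size=shape)
    observed[flip] = (observed[flip] + offset[flip]) % 3
    observed[rng.random(shape) < config.missing_rate] = MISSING

    gq = _phred_gq(config.genotype_error_rate, shape, rng)
    if snp_map is None:
        snp_map = pd.DataFrame(
            {
                "locus_id": genotypes.locus_ids,
                "gene_id": "chr1",
                "pos": np.arange(1, genotypes.n_loci + 1),
                "ref": "A",
                "alt": "C",
            }
        )
    mapq = np.clip(np.rint(rng.normal(config.mapq_mean, config.mapq_sd, size=len(snp_map))), 0, 254)
    loci = pd.DataFrame(
        {
            "locus_id": snp_map["locus_id"].to_numpy(),
            "chrom": snp_map["gene_id"].to_numpy(),
            "pos": snp_map["pos"].to_numpy(),
            "ref": snp_map["ref"].to_numpy(),
            "alt": [(a,) for a in snp_map["alt"]],
            "mapq": mapq,
        }
    )
    contigs = {c: config.gene_length_bp for c in dict.fromkeys(loci["chrom"])}
    return VariantTable(
        loci=loci,
        individual_ids=list(genotypes.individual_ids),
        codes=observed,
        depth=depth,
        gq=gq,
        contigs=contigs,
    )


@dataclass
class SimDataset:
    """Everything a downstream test needs, truth included."""

    config: SimConfig
    pedigree: Pedigree
    truth: GenotypeMatrix
    true_freqs: np.ndarray
    sequences: GeneSequences
    observed: VariantTable
    parents: dict[str, np.ndarray] = field(default_factory=dict)


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Run the full generator: pedigree -> genotypes -> sequences -> observation."""
    pedigree = simulate_pedigree(config)
    truth, freqs, parents = simulate_genotypes(pedigree, config, return_parents=True)
    sequences = embed_snps_in_genes(truth, config)
    observed = apply_observation_model(truth, config, snp_map=sequences.snp_map)
    return SimDataset(
        config=config,
        pedigree=pedigree,
        truth=truth,
        true_freqs=freqs,
        sequences=sequences,
        observed=observed,
        parents=parents,
    )


def swap_family_labels(
    pedigree: Pedigree, fraction: float, seed: int
) -> tuple[Pedigree, list[tuple[str, str]]]:
    """Plant label errors by swapping family assignments between pairs.

    Approximately ``fraction`` of individuals end up mislabeled; swaps are
    made between individuals of different families so each swapped
    individual's label is genuinely wrong. Returns the corrupted pedigree
    and the swapped id pairs.
    """
    rng = _rng(seed, "planting")
    n_pairs = int(round(fraction * len(pedigree) / 2))
    ids = pedigree.individual_ids
    fam = pedigree.family_of()
    available = set(ids)
    pairs: list[tuple[str, str]] = []
    order = [ids[i] for i in rng.permutation(len(ids))]
    for a in order:
        if len(pairs) == n_pairs:
            break
        if a not in available:
            continue
        partners = [b for b in order if b in available and b != a and fam[b] != fam[a]]
        if not partners:
            continue
        b = partners[0]
        available.discard(a)
        available.discard(b)
        pairs.append((a, b))
    table = pedigree.table.copy()
    prov_map = dict(zip(table["family_id"], table["provenance_id"]))
    for a, b in pairs:
        table.loc[table["individual_id"] == a, ["family_id", "provenance_id"]] = (
            fam[b],
            prov_map[fam[b]],
        )
        table.loc[table["individual_id"] == b, ["family_id", "provenance_id"]] = (
            fam[a],
            prov_map[fam[a]],
        )
    return Pedigree(table), pairs


def add_unrelated_individuals(
    genotypes: GenotypeMatrix,
    freqs: np.ndarray,
    pedigree: Pedigree,
    n: int,
    seed: int,
) -> tuple[GenotypeMatrix, Pedigree, list[str]]:
    """Plant individuals unrelated to everyone but labeled into real families.

    New genotypes are Hardy-Weinberg draws from the founder frequencies;
    each planted individual is assigned to a randomly chosen existing
    family, emulating sample mix-ups with off-pedigree material.
    """
    rng = _rng(seed, "planting")
    extra = rng.binomial(2, freqs, size=(n, genotypes.n_loci)).astype(np.int8)
    new_ids = [f"U{i + 1:03d}" for i in range(n)]
    gm = GenotypeMatrix(
        genotypes.individual_ids + new_ids,
        list(genotypes.locus_ids),
        np.vstack([genotypes.codes, extra]),
    )
    families = pedigree.family_ids
    prov_map = dict(zip(pedigree.table["family_id"], pedigree.table["provenance_id"]))
    rows = []
    for iid in new_ids:
        fam = families[rng.integers(len(families))]
        rows.append(
            {
                "individual_id": iid,
                "family_id": fam,
                "provenance_id": prov_map[fam],
                "mother_id": "",
                "father_id": "",
            }
        )
    ped = Pedigree(pd.concat([pedigree.table, pd.DataFrame(rows)], ignore_index=True))
    return gm, ped, new_ids


def noiseless(config: SimConfig) -> SimConfig:
    """Copy of a config with the observation noise switched off."""
    return replace(config, genotype_error_rate=0.0, missing_rate=0.0)
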