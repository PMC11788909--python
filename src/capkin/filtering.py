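"""SNP filtering cascade for capture-based variant tables.

Rules are applied in a fixed, documented order:

1. indels                      (drop non-SNP records)
2. multiallelic                (drop records with >1 alternate allele)
3. minor allele frequency      (monomorphic-only in small-sample mode)
4. missingness                 (zero tolerance in small-sample mode)
5. genotype quality            (genotype-level mask, then missingness re-check)
6. site mapping quality
7. mean depth window           [min_factor x mean, max_factor x mean]
8. excess heterozygosity       (optional; cap at the biallelic maximum 0.5)

Depth thresholds are resolved once from the per-locus mean depths of the
input table (before any rule), mirroring a site-level VCFtools-style filter
with thresholds fixed from the observed depth distribution; per-rule removal
counts are therefore defined with respect to this order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import MISSING, VariantTable

#: Theoretical maximum heterozygosity of a biallelic locus in
#: Hardy-Weinberg proportions: max over p of 2p(1-p) = 0.5.
MAX_BIALLELIC_HETEROZYGOSITY = 0.5

RULE_ORDER = [
    "indel",
    "multiallelic",
    "maf",
    "missing",
    "gq",
    "mapq",
    "depth",
    "heterozygosity",
]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the cascade.

    ``small_sample_mode`` reproduces the handling of tiny cohorts (fewer
    than ~10 individuals): the MAF rule drops only monomorphic loci and no
    missing call is tolerated. ``maf_min`` of 0 likewise drops monomorphic
    loci only (uncallable, all-missing loci always fall to the MAF rule). ``het_max`` of ``None`` disables the
    excess-heterozygosity rule; when enabled it defaults to the biallelic
    theoretical maximum. ``min_dp``/``max_dp`` pin the depth window to fixed
    values instead of deriving it from the depth distribution.
    ``gq_site_level`` switches the GQ rule from genotype-level masking to
    dropping any site with a failing genotype.
    """

    drop_indels: bool = True
    drop_multiallelic: bool = True
    maf_min: float = 0.05
    max_missing_fraction: float = 0.1
    gq_min: int = 16
    mapq_min: int = 40
    min_depth_factor: float = 0.5
    max_depth_factor: float = 2.0
    het_max: float | None = None
    small_sample_mode: bool = False
    min_dp: float | None = None
    max_dp: float | None = None
    gq_site_level: bool = False

    def __post_init__(self) -> None:
        for name in ("maf_min", "max_missing_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.min_depth_factor <= 0 or self.max_depth_factor <= 0:
            raise ValueError("depth factors must be positive")
        if self.min_depth_factor >= self.max_depth_factor:
            raise ValueError("min_depth_factor must be < max_depth_factor")
        if self.het_max is not None and not 0.0 <= self.het_max <= 1.0:
            raise ValueError(f"het_max must be in [0,1], got {self.het_max}")


def species_preset(name: str) -> FilterConfig:
    """Named presets for the data-driven per-species tightenings.

    ``tightened_maf02`` raises the MAF cut to 0.2 and enables the
    heterozygosity cap; ``tightened_maf01`` raises the MAF cut to 0.1;
    ``small_sample`` is the five-individual regime.
    """
    presets = {
        "default": FilterConfig(),
        "small_sample": FilterConfig(small_sample_mode=True),
        "tightened_maf02": FilterConfig(maf_min=0.2, het_max=MAX_BIALLELIC_HETEROZYGOSITY),
        "tightened_maf01": FilterConfig(maf_min=0.1),
    }
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    return presets[name]


@dataclass
class FilterReport:
    """Per-rule removal counts in application order."""

    loci_in: int
    removed: dict[str, int]
    loci_out: int
    min_dp: float | None = None
    max_dp: float | None = None
    global_mean_depth: float | None = None

    def __post_init__(self) -> None:
        if self.loci_in - sum(self.removed.values()) != self.loci_out:
            raise ValueError("filter report does not conserve locus counts")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rule": r, "removed": self.removed.get(r, 0)} for r in RULE_ORDER]
        rows.append({"rule": "loci_in", "removed": self.loci_in})
        rows.append({"rule": "loci_out", "removed": self.loci_out})
        return pd.DataFrame(rows)


def _nonmissing_counts(codes: np.ndarray):
    obs = codes != MISSING
    return obs, obs.sum(axis=0)


def minor_allele_frequency(codes: np.ndarray) -> float:
    """MAF of one biallelic locus from its genotype codes."""
    codes = np.asarray(codes)
    obs = codes != MISSING
    n = int(obs.sum())
    if n == 0:
        raise ValueError("all genotypes missing")
    p = codes[obs].sum() / (2.0 * n)
    return float(min(p, 1.0 - p))


def observed_heterozygosity(codes: np.ndarray) -> float:
    """Fraction of non-missing genotypes that are heterozygous."""
    codes = np.asarray(codes)
    obs = codes != MISSING
    n = int(obs.sum())
    if n == 0:
        raise ValueError("all genotypes missing")
    return float((codes[obs] == 1).mean())


def site_mean_depth(table: VariantTable) -> tuple[np.ndarray, float]:
    """Per-locus mean depth over non-missing genotypes, and the global mean.

    The global mean (mean of the per-locus means) anchors the depth window:
    minDP = min_depth_factor x mean, maxDP = max_depth_factor x mean.
    """
    if table.n_loci == 0:
        raise ValueError("empty variant table")
    if table.depth is None:
        raise ValueError("variant table carries no depth annotations")
    obs = table.codes != MISSING
    with np.errstate(invalid="ignore"):
        per_locus = np.where(
            obs.any(axis=0),
            np.nansum(np.where(obs, table.depth, 0.0), axis=0) / obs.sum(axis=0),
            np.nan,
        )
    return per_locus, float(np.nanmean(per_locus))


def _maf_vector(codes: np.ndarray) -> np.ndarray:
    """Vectorised MAF per locus; NaN where every genotype is missing."""
    obs, n = _nonmissing_counts(codes)
    total = np.where(obs, codes, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, total / (2.0 * n), np.nan)
    return np.minimum(p, 1.0 - p)


def apply_filters(table: VariantTable, config: FilterConfig) -> tuple[VariantTable, FilterReport]:
    """Run the cascade and account for every removed locus.

    Loci with no called genotype at all are treated as monomorphic and fall
    to the MAF rule. GQ (by default) masks failing genotypes to missing and
    re-applies the missingness rule, so the returned table may carry more
    missing calls than the input at surviving sites.
    """
    removed = {r: 0 for r in RULE_ORDER}
    loci_in = table.n_loci
    current = table

    min_dp = config.min_dp
    max_dp = config.max_dp
    global_mean = None
    if current.depth is not None and loci_in > 0 and (min_dp is None or max_dp is None):
        _, global_mean = site_mean_depth(current)
        if min_dp is None:
            min_dp = config.min_depth_factor * global_mean
        if max_dp is None:
            max_dp = config.max_depth_factor * global_mean

    def drop(mask_remove: np.ndarray, rule: str) -> None:
        nonlocal current
        removed[rule] = int(mask_remove.sum())
        if removed[rule]:
            current = current.subset_loci(~mask_remove)

    if config.drop_indels and current.n_loci:
        ref_len = current.loci["ref"].str.len().to_numpy()
        alt_len = np.array([max((len(a) for a in alts), default=0) for alts in current.loci["alt"]])
        drop((ref_len > 1) | (alt_len > 1), "indel")

    if config.drop_multiallelic and current.n_loci:
        drop(np.array([len(alts) > 1 for alts in current.loci["alt"]]), "multiallelic")

    if current.n_loci:
        maf = _maf_vector(current.codes)
        if config.small_sample_mode or config.maf_min == 0.0:
            fail = ~(maf > 0)  # monomorphic or uncallable (all-missing)
        else:
            fail = ~(maf >= config.maf_min)
        drop(fail, "maf")

    max_missing = 0.0 if config.small_sample_mode else config.max_missing_fraction
    if current.n_loci:
        frac = (current.codes == MISSING).mean(axis=0)
        drop(frac > max_missing, "missing")

    if current.n_loci and current.gq is not None:
        fail_gq = (current.codes != MISSING) & ~(current.gq > config.gq_min)
        if config.gq_site_level:
            drop(fail_gq.any(axis=0), "gq")
        else:
            codes = current.codes.copy()
            codes[fail_gq] = MISSING
            current = replace(current, codes=codes)
            frac = (current.codes == MISSING).mean(axis=0)
            drop(frac > max_missing, "gq")

    if current.n_loci:
        mapq = current.loci["mapq"].to_numpy(dtype=float)
        has_mapq = ~np.isnan(mapq)
        drop(has_mapq & ~(mapq > config.mapq_min), "mapq")

    if current.n_loci and current.depth is not None and min_dp is not None:
        per_locus, _ = site_mean_depth(current)
        ok = (per_locus >= min_dp) & (per_locus <= max_dp)
        drop(~ok & ~np.isnan(per_locus), "depth")

    if config.het_max is not None and current.n_loci:
        obs, n = _nonmissing_counts(current.codes)
        het = np.where(n > 0, np.where(obs, current.codes == 1, False).sum(axis=0) / np.maximum(n, 1), 0.0)
        drop(het > config.het_max, "heterozygosity")

    report = FilterReport(
        loci_in=loci_in,
        removed=removed,
        loci_out=current.n_loci,
        min_dp=min_dp,
        max_dp=max_dp,
        global_mean_depth=global_mean,
    )
    return current, report
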