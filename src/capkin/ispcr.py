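"""Primer-pair design around SNPs and primersearch-style in-silico PCR.

Design replaces thermodynamic modelling with transparent rules: primer
length 18-24 nt, GC 40-60%, Wallace-rule melting temperature
Tm = 2(A+T) + 4(G+C) inside a window, homopolymer runs of at most 4, and
no known SNP inside either primer footprint. Amplicons span 100-150 bp by
default — short enough for single-read amplicon sequencing of the target
SNP.

Matching is ungapped with an integer mismatch allowance of
floor(primer_length * pct / 100), and IUPAC ambiguity codes in the template
match any compatible primer base without counting a mismatch. Amplimer
enumeration tries both role assignments of the pair (either primer may act
as the forward primer with the other on the reverse strand), collapses
duplicate spans, and caps the product length. All reported coordinates are
1-based and inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._iupac import IUPAC_TO_BASES, reverse_complement

_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_MASK = {code: sum(_BIT[b] for b in bases) for code, bases in IUPAC_TO_BASES.items()}

DEFAULT_MAX_PRODUCT_BP = 5000
DEFAULT_MISMATCH_PCTS = (10.0, 0.0)


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_MASK[b] for b in seq.upper()], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"invalid nucleotide symbol {exc.args[0]!r}") from None


@dataclass(frozen=True)
class PrimerPair:
    """A designed pair; both sequences are written 5'->3'.

    ``amplicon_start``/``amplicon_end`` give the expected product span on
    the design reference gene (1-based, inclusive).
    """

    pair_id: str
    forward: str
    reverse: str
    gene_id: str
    snp_id: str
    amplicon_start: int
    amplicon_end: int

    @property
    def product_length(self) -> int:
        return self.amplicon_end - self.amplicon_start + 1


@dataclass(frozen=True)
class Amplimer:
    """One predicted product: forward hit start to reverse hit end."""

    template_id: str
    start: int  # 1-based position of the forward primer's first base
    end: int  # 1-based position of the reverse primer's last base
    forward_mismatches: int
    reverse_mismatches: int
    orientation: str  # "canonical" (A fwd / B rev) or "swapped"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class PrimerConstraints:
    primer_len_min: int = 18
    primer_len_max: int = 24
    gc_min: float = 40.0
    gc_max: float = 60.0
    amplicon_min: int = 100
    amplicon_max: int = 150
    tm_min: float = 50.0
    tm_max: float = 72.0
    max_homopolymer: int = 4

    def __post_init__(self) -> None:
        if self.primer_len_min > self.primer_len_max:
            raise ValueError("primer_len_min > primer_len_max")
        if self.amplicon_min > self.amplicon_max:
            raise ValueError("amplicon_min > amplicon_max")
        if self.amplicon_min < 2 * self.primer_len_min:
            raise ValueError("amplicon_min too small to fit two primers")


def wallace_tm(seq: str) -> float:
    """Wallace-rule melting temperature 2(A+T) + 4(G+C)."""
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    return 2.0 * (len(s) - gc) + 4.0 * gc


def gc_percent(seq: str) -> float:
    s = seq.upper()
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def max_homopolymer_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def primer_ok(seq: str, constraints: PrimerConstraints) -> bool:
    """Check every sequence-level design rule for one candidate primer."""
    if not constraints.primer_len_min <= len(seq) <= constraints.primer_len_max:
        return False
    if any(b not in "ACGT" for b in seq.upper()):
        return False
    if not constraints.gc_min <= gc_percent(seq) <= constraints.gc_max:
        return False
    if not constraints.tm_min <= wallace_tm(seq) <= constraints.tm_max:
        return False
    return max_homopolymer_run(seq) <= constraints.max_homopolymer


def mismatch_allowance(primer_len: int, max_mismatch_pct: float) -> int:
    """Integer allowance floor(len * pct / 100), primersearch-style."""
    return int(np.floor(primer_len * max_mismatch_pct / 100.0))


def match_sites(
    primer: str, template: str, max_mismatch_pct: float = 0.0
) -> list[tuple[int, int]]:
    """All ungapped forward-strand placements within the mismatch allowance.

    Returns ``(start, mismatches)`` tuples with 1-based start positions, in
    ascending order. Template IUPAC codes match any compatible primer base.
    """
    if not primer or not template:
        raise ValueError("primer and template must be non-empty")
    if len(primer) > len(template):
        return []
    p = _encode(primer)
    t = _encode(template)
    windows = np.lib.stride_tricks.sliding_window_view(t, len(p))
    mismatches = ((windows & p) == 0).sum(axis=1)
    allowed = mismatch_allowance(len(p), max_mismatch_pct)
    hits = np.flatnonzero(mismatches <= allowed)
    return [(int(i) + 1, int(mismatches[i])) for i in hits]


def enumerate_amplimers(
    pair: PrimerPair,
    template: str,
    template_id: str = "template",
    max_mismatch_pct: float = 0.0,
    max_product_bp: int = DEFAULT_MAX_PRODUCT_BP,
) -> list[Amplimer]:
    """Predict every product of the pair on one template sequence.

    A product is a forward-strand hit of one primer followed downstream by
    a reverse-strand hit of the other (the reverse primer is matched
    against the reverse complement with coordinates mapped back). Both role
    assignments are tried; products sharing a span are collapsed, keeping
    the canonical orientation when both produce it.
    """
    length = len(template)
    rc = reverse_complement(template)
    results: dict[tuple[int, int], Amplimer] = {}
    for orientation, (fwd, rev) in (
        ("canonical", (pair.forward, pair.reverse)),
        ("swapped", (pair.reverse, pair.forward)),
    ):
        if max(len(fwd), len(rev)) > length:
            continue
        fwd_hits = match_sites(fwd, template, max_mismatch_pct)
        rev_hits_rc = match_sites(rev, rc, max_mismatch_pct)
        # a hit starting at s' on the reverse complement ends at L - s' + 1
        # on the forward strand
        rev_hits = [(length - s + 1, mm) for s, mm in rev_hits_rc]
        min_len = len(fwd) + len(rev)
        for f_start, f_mm in fwd_hits:
            for r_end, r_mm in rev_hits:
                span = r_end - f_start + 1
                if span < min_len or span > max_product_bp:
                    continue
                key = (f_start, r_end)
                if key in results:
                    continue
                results[key] = Amplimer(
                    template_id=template_id,
                    start=f_start,
                    end=r_end,
                    forward_mismatches=f_mm,
                    reverse_mismatches=r_mm,
                    orientation=orientation,
                )
    return sorted(results.values(), key=lambda a: (a.start, a.end))


def _valid_primer_starts(seq: str, length: int, constraints: PrimerConstraints) -> np.ndarray:
    """Boolean array: can a valid primer of ``length`` start at position i (0-based)?"""
    n = len(seq)
    if n < length:
        return np.zeros(0, dtype=bool)
    s = seq.upper()
    is_acgt = np.array([b in "ACGT" for b in s])
    gc = np.array([b in "GC" for b in s], dtype=int)
    acgt_c = np.concatenate([[0], np.cumsum(is_acgt)])
    gc_c = np.concatenate([[0], np.cumsum(gc)])
    starts = np.arange(n - length + 1)
    all_acgt = (acgt_c[starts + length] - acgt_c[starts]) == length
    gc_count = gc_c[starts + length] - gc_c[starts]
    gc_pct = 100.0 * gc_count / length
    tm = 2.0 * (length - gc_count) + 4.0 * gc_count
    ok = (
        all_acgt
        & (gc_pct >= constraints.gc_min)
        & (gc_pct <= constraints.gc_max)
        & (tm >= constraints.tm_min)
        & (tm <= constraints.tm_max)
    )
    # homopolymer: mark 0-based positions j where s[j-4..j] are all equal;
    # window [i, i+length-1] is bad iff such a j exists with i+4 <= j <= i+length-1
    run = np.ones(n, dtype=int)
    for j in range(1, n):
        if s[j] == s[j - 1]:
            run[j] = run[j - 1] + 1
    bad = (run >= constraints.max_homopolymer + 1).astype(int)
    bad_c = np.concatenate([[0], np.cumsum(bad)])
    lo = starts + constraints.max_homopolymer
    has_bad = (bad_c[starts + length] - bad_c[np.minimum(lo, n)]) > 0
    return ok & ~has_bad


def design_primers(
    reference: dict[str, str],
    snp_map: pd.DataFrame,
    n_pairs: int | None = None,
    constraints: PrimerConstraints | None = None,
    seed: int = 0,
) -> tuple[list[PrimerPair], pd.DataFrame]:
    """Pick SNPs and design one flanking pair per SNP on the reference.

    SNPs are selected at random (seeded) subject to a minimum spacing of
    ``amplicon_max`` between selected SNPs on the same gene, so no two
    panels' products can overlap. At most one pair per SNP; per-SNP failure
    reasons are returned alongside. ``reference`` maps gene_id to the
    consensus sequence used as the design template; ``snp_map`` needs
    columns gene_id, pos, locus_id.
    """
    constraints = constraints or PrimerConstraints()
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 977])))
    missing = sorted(set(snp_map["gene_id"]) - set(reference))
    if missing:
        raise KeyError(f"SNP genes absent from reference: {missing[:10]}")
    for row in snp_map.itertuples(index=False):
        if not 1 <= row.pos <= len(reference[row.gene_id]):
            raise ValueError(f"SNP {row.locus_id} at {row.pos} is off gene {row.gene_id}")

    snp_positions: dict[str, set[int]] = {}
    for row in snp_map.itertuples(index=False):
        snp_positions.setdefault(row.gene_id, set()).add(int(row.pos))

    order = rng.permutation(len(snp_map))
    chosen_per_gene: dict[str, list[int]] = {}
    selected = []
    skipped_spacing = []
    for idx in order:
        row = snp_map.iloc[int(idx)]
        near = chosen_per_gene.get(row["gene_id"], [])
        if any(abs(int(row["pos"]) - q) < constraints.amplicon_max for q in near):
            skipped_spacing.append(row["locus_id"])
            continue
        selected.append(int(idx))
        chosen_per_gene.setdefault(row["gene_id"], []).append(int(row["pos"]))
        if n_pairs is not None and len(selected) == n_pairs:
            break

    pairs: list[PrimerPair] = []
    failures = [{"locus_id": lid, "reason": "spacing to an already selected SNP"}
                for lid in (skipped_spacing if n_pairs is None else [])]
    for idx in selected:
        row = snp_map.iloc[idx]
        gene, pos, lid = row["gene_id"], int(row["pos"]), row["locus_id"]
        pair, reason = _design_for_snp(
            reference[gene], pos, snp_positions[gene], constraints
        )
        if pair is None:
            failures.append({"locus_id": lid, "reason": reason})
            continue
        fwd, rev, a, b = pair
        pairs.append(
            PrimerPair(
                pair_id=f"pp{len(pairs) + 1:04d}",
                forward=fwd,
                reverse=rev,
                gene_id=gene,
                snp_id=lid,
                amplicon_start=a,
                amplicon_end=b,
            )
        )
    return pairs, pd.DataFrame(failures, columns=["locus_id", "reason"])


def _design_for_snp(
    seq: str, snp_pos: int, snp_positions: set[int], constraints: PrimerConstraints
):
    """Deterministic search for the first valid pair bracketing one SNP."""
    n = len(seq)
    if snp_pos - 1 < constraints.primer_len_min or n - snp_pos < constraints.primer_len_min:
        return None, "insufficient flank"
    lengths = range(constraints.primer_len_min, constraints.primer_len_max + 1)
    valid = {L: _valid_primer_starts(seq, L, constraints) for L in lengths}
    snp0 = np.zeros(n, dtype=int)
    for p in snp_positions:
        snp0[p - 1] = 1
    snp_c = np.concatenate([[0], np.cumsum(snp0)])

    def footprint_clean(start0: int, L: int) -> bool:
        return (snp_c[start0 + L] - snp_c[start0]) == 0

    x0 = snp_pos - 1  # 0-based SNP index
    for product in range(constraints.amplicon_min, constraints.amplicon_max + 1):
        for lf in lengths:
            for lr in lengths:
                # forward footprint [a, a+lf-1] strictly before the SNP,
                # reverse footprint [a+product-lr, a+product-1] strictly after
                a_hi = x0 - lf
                a_lo = x0 + 1 - product + lr
                for a in range(max(a_lo, 0), min(a_hi, n - product) + 1):
                    if not (valid[lf].size and valid[lf][a]):
                        continue
                    r_start = a + product - lr
                    if not (valid[lr].size and r_start < valid[lr].size and valid[lr][r_start]):
                        continue
                    if not footprint_clean(a, lf) or not footprint_clean(r_start, lr):
                        continue
                    fwd = seq[a : a + lf]
                    rev = reverse_complement(seq[r_start : r_start + lr])
                    return (fwd, rev, a + 1, a + product), None
    return None, "no primer pair satisfies the constraints"


@dataclass
class IspcrSummary:
    """Amplification and specificity percentages per mismatch setting."""

    table: pd.DataFrame  # template_set, mismatch_pct, pct_with_amplimer, pct_single
    per_pair: pd.DataFrame = field(default_factory=pd.DataFrame)


def summarize(
    pairs: list[PrimerPair],
    template_sets: dict[str, dict[str, str]],
    mismatch_pcts: tuple[float, ...] = DEFAULT_MISMATCH_PCTS,
    max_product_bp: int = DEFAULT_MAX_PRODUCT_BP,
) -> IspcrSummary:
    """Amplimer statistics for each template set and mismatch allowance.

    ``template_sets`` maps a set label (e.g. a species' genome) to its
    sequences. For each setting, reports the percentage of pairs producing
    at least one amplimer anywhere in the set and the percentage producing
    exactly one (the single-copy specificity criterion); a second template
    set yields the cross-species transferability figures.
    """
    if not pairs:
        raise ValueError("no primer pairs to summarize")
    rows = []
    per_pair_rows = []
    for set_label, templates in template_sets.items():
        for pct in mismatch_pcts:
            counts = {}
            for pair in pairs:
                total = 0
                for tid, seq in templates.items():
                    total += len(
                        enumerate_amplimers(pair, seq, tid, pct, max_product_bp)
                    )
                counts[pair.pair_id] = total
                per_pair_rows.append(
                    {
                        "template_set": set_label,
                        "mismatch_pct": pct,
                        "pair_id": pair.pair_id,
                        "n_amplimers": total,
                    }
                )
            n = len(pairs)
            rows.append(
                {
                    "template_set": set_label,
                    "mismatch_pct": pct,
                    "pct_with_amplimer": 100.0 * sum(c >= 1 for c in counts.values()) / n,
                    "pct_single_amplimer": 100.0 * sum(c == 1 for c in counts.values()) / n,
                }
            )
    return IspcrSummary(table=pd.DataFrame(rows), per_pair=pd.DataFrame(per_pair_rows))
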