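"""Primer design constraints and primersearch-style amplimer enumeration."""

import math

import numpy as np
import pandas as pd
import pytest

from capkin import (
    PrimerConstraints,
    PrimerPair,
    design_primers,
    enumerate_amplimers,
    match_sites,
    summarize,
)
from capkin.ispcr import gc_percent, max_homopolymer_run, mismatch_allowance, primer_ok, wallace_tm

# ---- independent oracle: sliding-window matching with its own IUPAC table ----

_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT", "S": "CG",
    "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT", "H": "ACT",
    "V": "ACG", "N": "ACGT",
}
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def oracle_revcomp(seq):
    out = []
    for b in reversed(seq):
        comp = "".join(sorted(_COMP[x] for x in _SETS[b]))
        out.append(next(k for k, v in _SETS.items() if "".join(sorted(v)) == comp))
    return "".join(out)


def oracle_compatible(primer_base, template_base):
    return bool(set(_SETS[primer_base]) & set(_SETS[template_base]))


def oracle_match(primer, template, pct):
    allowed = math.floor(len(primer) * pct / 100.0)
    hits = []
    for s in range(len(template) - len(primer) + 1):
        window = template[s : s + len(primer)]
        mm = sum(1 for a, b in zip(primer, window) if not oracle_compatible(a, b))
        if mm <= allowed:
            hits.append((s + 1, mm))
    return hits


def oracle_amplimers(pair, template, pct, max_product):
    """Naive all-pairs enumeration over both role assignments."""
    spans = {}
    L = len(template)
    for fwd, rev in [(pair.forward, pair.reverse), (pair.reverse, pair.forward)]:
        fwd_hits = oracle_match(fwd, template, pct)
        rev_hits = oracle_match(rev, oracle_revcomp(template), pct)
        for s, _ in fwd_hits:
            for s2, _ in rev_hits:
                end = L - s2 + 1
                span = end - s + 1
                if len(fwd) + len(rev) <= span <= max_product:
                    spans.setdefault((s, end), True)
    return set(spans)


def random_instance(rng, planted=True):
    """A random template plus a primer pair, optionally planted with mutations."""
    length = int(rng.integers(400, 2000))
    template = "".join(rng.choice(list("ACGT"), size=length))
    lf, lr = int(rng.integers(18, 25)), int(rng.integers(18, 25))
    if planted:
        product = int(rng.integers(lf + lr, 200))
        start = int(rng.integers(0, length - product))
        fwd = list(template[start : start + lf])
        seg = template[start + product - lr : start + product]
        rev = list(oracle_revcomp(seg))
        for primer in (fwd, rev):
            for _ in range(int(rng.integers(0, 3))):
                i = int(rng.integers(len(primer)))
                primer[i] = rng.choice([b for b in "ACGT" if b != primer[i]])
        fwd, rev = "".join(fwd), "".join(rev)
    else:
        fwd = "".join(rng.choice(list("ACGT"), size=lf))
        rev = "".join(rng.choice(list("ACGT"), size=lr))
    pair = PrimerPair("pp", fwd, rev, "g", "s", 1, 1 + lf + lr)
    return pair, template


class TestMatchSites:
    def test_exact_substring_found_once(self):
        template = "A" * 50 + "ACGTACGTACGTACGTACGT" + "C" * 30
        hits = match_sites("ACGTACGTACGTACGTACGT", template, 0.0)
        assert (51, 0) in hits

    def test_allowance_contrast_one_substitution(self):
        template = "T" * 40 + "AAAACCCCGGGGTTTTACGC" + "T" * 40
        primer = "AAAACCCCGGGGTTTTACGG"  # one substitution at the 3' end
        assert match_sites(primer, template, 0.0) == []
        assert (41, 1) in match_sites(primer, template, 10.0)  # floor(20*0.1)=2

    def test_duplicate_site_reported_twice(self):
        core = "ACGTACGTACGTACGTAC"
        template = "TT" + core + "GGGG" + core + "TT"
        starts = [s for s, _ in match_sites(core, template, 0.0)]
        assert starts == [3, 3 + len(core) + 4]

    def test_template_iupac_matches_without_penalty(self):
        # N in the template is compatible with every primer base
        assert (3, 0) in match_sites("ACGT", "NNACGTNN", 0.0)
        hits = dict(match_sites("ACGT", "TTRCGTTT", 0.0))
        assert hits.get(3) == 0  # R is compatible with A

    def test_empty_sequences_rejected(self):
        with pytest.raises(ValueError):
            match_sites("", "ACGT")
        with pytest.raises(ValueError):
            match_sites("ACGT", "")

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("pct", [0.0, 10.0])
    def test_matches_sliding_window_oracle(self, seed, pct):
        rng = np.random.default_rng(seed)
        template = "".join(rng.choice(list("ACGTN"), size=300, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        primer = "".join(rng.choice(list("ACGT"), size=int(rng.integers(15, 25))))
        assert match_sites(primer, template, pct) == oracle_match(primer, template, pct)


class TestEnumerateAmplimers:
    @pytest.mark.parametrize("seed", range(25))
    @pytest.mark.parametrize("pct", [0.0, 10.0])
    def test_matches_all_pairs_oracle(self, seed, pct):
        rng = np.random.default_rng(100 + seed)
        pair, template = random_instance(rng, planted=seed % 4 != 3)
        got = {(a.start, a.end) for a in enumerate_amplimers(pair, template, "t", pct)}
        assert got == oracle_amplimers(pair, template, pct, 5000)

    @pytest.mark.parametrize("seed", range(8))
    def test_monotone_in_allowance(self, seed):
        rng = np.random.default_rng(200 + seed)
        pair, template = random_instance(rng)
        spans = {
            pct: {(a.start, a.end) for a in enumerate_amplimers(pair, template, "t", pct)}
            for pct in (0.0, 5.0, 10.0, 15.0)
        }
        assert spans[0.0] <= spans[5.0] <= spans[10.0] <= spans[15.0]

    @pytest.mark.parametrize("seed", range(8))
    def test_strand_symmetry(self, seed):
        rng = np.random.default_rng(300 + seed)
        pair, template = random_instance(rng)
        L = len(template)
        fwd = {(a.start, a.end) for a in enumerate_amplimers(pair, template, "t", 10.0)}
        rc = oracle_revcomp(template)
        swapped = PrimerPair("pp", pair.reverse, pair.forward, "g", "s", 1, 10)
        back = {
            (L - e + 1, L - s + 1)
            for s, e in ((a.start, a.end) for a in enumerate_amplimers(swapped, rc, "t", 10.0))
        }
        assert fwd == back

    def test_missing_reverse_site_gives_no_amplimer(self):
        rng = np.random.default_rng(17)
        template = "".join(rng.choice(list("ACGT"), size=500))
        fwd = template[100:120]
        rev = "A" * 20  # no poly-T run in a random template of this size
        pair = PrimerPair("pp", fwd, rev, "g", "s", 1, 40)
        assert enumerate_amplimers(pair, template, "t", 0.0) == []

    def test_duplicated_gene_copy_yields_two_amplimers(self):
        rng = np.random.default_rng(23)
        gene = "".join(rng.choice(list("ACGT"), size=300))
        template = gene + "TTTT" + gene
        pair = PrimerPair("pp", gene[10:30], oracle_revcomp(gene[130:150]), "g", "s", 11, 150)
        # product cap excludes the long cross-copy product, leaving one per copy
        amps = enumerate_amplimers(pair, template, "t", 0.0, max_product_bp=200)
        assert len(amps) == 2

    def test_amplimer_length_floor(self):
        # overlapping fwd/rev placements shorter than the primer sum are not products
        template = "ACGTACGTACGTACGTACGTACGT"
        pair = PrimerPair("pp", template[:18], oracle_revcomp(template[:18]), "g", "s", 1, 18)
        for amp in enumerate_amplimers(pair, template, "t", 10.0):
            assert amp.length >= 36


class TestDesign:
    def test_constraint_helpers(self):
        assert gc_percent("GGCC") == 100.0
        assert wallace_tm("ACGT") == 2 * 2 + 4 * 2
        assert max_homopolymer_run("AAACCG") == 3
        assert mismatch_allowance(20, 10.0) == 2
        assert mismatch_allowance(19, 10.0) == 1

    def test_designed_pairs_satisfy_every_constraint(self):
        rng = np.random.default_rng(31)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        snp_map = pd.DataFrame(
            {"locus_id": ["s1", "s2"], "gene_id": "g1", "pos": [600, 1400], "ref": "A", "alt": "C"}
        )
        constraints = PrimerConstraints()
        pairs, failures = design_primers({"g1": seq}, snp_map, constraints=constraints, seed=1)
        assert len(pairs) == 2 and failures.empty
        for pair in pairs:
            assert primer_ok(pair.forward, constraints)
            assert primer_ok(pair.reverse, constraints)
            assert constraints.amplicon_min <= pair.product_length <= constraints.amplicon_max
            snp_pos = int(snp_map.set_index("locus_id").loc[pair.snp_id, "pos"])
            assert pair.amplicon_start <= snp_pos <= pair.amplicon_end
            # primer footprints exclude the SNP site
            fwd_end = pair.amplicon_start + len(pair.forward) - 1
            rev_start = pair.amplicon_end - len(pair.reverse) + 1
            assert fwd_end < snp_pos < rev_start
            # the pair amplifies its own design reference uniquely at 0%
            amps = enumerate_amplimers(pair, seq, "g1", 0.0)
            assert len(amps) == 1
            assert (amps[0].start, amps[0].end) == (pair.amplicon_start, pair.amplicon_end)

    def test_snp_near_edge_fails_with_reason(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        snp_map = pd.DataFrame({"locus_id": ["s"], "gene_id": "g", "pos": [10], "ref": "A", "alt": "C"})
        pairs, failures = design_primers({"g": seq}, snp_map, seed=0)
        assert pairs == []
        assert failures["reason"].iloc[0] == "insufficient flank"

    def test_close_snps_only_one_selected(self):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        snp_map = pd.DataFrame(
            {"locus_id": ["s1", "s2"], "gene_id": "g", "pos": [500, 550], "ref": "A", "alt": "C"}
        )
        pairs, _ = design_primers({"g": seq}, snp_map, seed=0)
        assert len(pairs) == 1

    def test_snp_off_reference_is_an_error(self):
        snp_map = pd.DataFrame({"locus_id": ["s"], "gene_id": "g", "pos": [999], "ref": "A", "alt": "C"})
        with pytest.raises(ValueError, match="off gene"):
            design_primers({"g": "ACGT" * 20}, snp_map, seed=0)


class TestSummarize:
    def _planted_pairs(self, rng, template, n):
        pairs = []
        length = len(template)
        for k in range(n):
            lf = lr = 20
            product = 120
            start = int(rng.integers(0, length - product))
            pairs.append(
                PrimerPair(
                    f"pp{k}", template[start : start + lf],
                    oracle_revcomp(template[start + product - lr : start + product]),
                    "g", f"s{k}", start + 1, start + product,
                )
            )
        return pairs

    def test_unique_plants_give_full_percentages(self):
        rng = np.random.default_rng(41)
        template = "".join(rng.choice(list("ACGT"), size=3000))
        pairs = self._planted_pairs(rng, template, 4)
        summary = summarize(pairs, {"ref": {"t": template}}, (0.0,))
        row = summary.table.iloc[0]
        assert row["pct_with_amplimer"] == 100.0
        assert row["pct_single_amplimer"] == 100.0

    def test_deleted_site_drops_one_pair(self):
        rng = np.random.default_rng(43)
        template = "".join(rng.choice(list("ACGT"), size=3000))
        pairs = self._planted_pairs(rng, template, 4)
        # destroy the first pair's forward site
        broken = template[: pairs[0].amplicon_start - 1] + "T" * 20 + template[pairs[0].amplicon_start + 19 :]
        counts = {
            p.pair_id: len(enumerate_amplimers(p, broken, "t", 0.0)) for p in pairs
        }
        if counts[pairs[0].pair_id] == 0 and all(v == 1 for k, v in counts.items() if k != pairs[0].pair_id):
            summary = summarize(pairs, {"ref": {"t": broken}}, (0.0,))
            assert summary.table.iloc[0]["pct_with_amplimer"] == 75.0

    def test_relaxing_allowance_never_decreases_percentages(self):
        rng = np.random.default_rng(47)
        template = "".join(rng.choice(list("ACGT"), size=3000))
        pairs = self._planted_pairs(rng, template, 5)
        summary = summarize(pairs, {"ref": {"t": template}}, (0.0, 10.0))
        t = summary.table.set_index("mismatch_pct")
        assert t.loc[10.0, "pct_with_amplimer"] >= t.loc[0.0, "pct_with_amplimer"]
        # and the structural invariant: single <= any
        assert (summary.table["pct_single_amplimer"] <= summary.table["pct_with_amplimer"]).all()

    def test_empty_pair_list_rejected(self):
        with pytest.raises(ValueError):
            summarize([], {"ref": {}})
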