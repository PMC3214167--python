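"""Synonymous-shuffle null model: usage, reshuffling, metrics, enumeration."""

import math

import numpy as np
import pytest

from gauscan.codon_core import get_code, minus2_codon, translate
from gauscan.gau_locator import extract_gau_region, locate
from gauscan.shuffle_sim import (
    ShuffleReplicate,
    codon_usage,
    enumerate_stop_sites,
    replicate_metrics,
    run_shuffle,
    shuffle_synonymous,
    summarize_replicates,
)
from tests.conftest import random_cds


class TestCodonUsage:
    def test_single_codon_family(self, code_std):
        usage = codon_usage("TTTTTTTTT", code_std)
        assert usage.family("F") == {"TTT": 1.0, "TTC": 0.0}

    def test_families_sum_to_one(self, code_std):
        rng = np.random.default_rng(2)
        usage = codon_usage(random_cds(rng, 200, code_std), code_std)
        for fam in usage.frequencies.values():
            assert sum(fam.values()) == pytest.approx(1.0)

    def test_matches_naive_tally(self, code_std):
        rng = np.random.default_rng(8)
        cds = random_cds(rng, 150, code_std)
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        usage = codon_usage(cds, code_std)
        for aa, fam in usage.frequencies.items():
            total = sum(1 for c in codons if code_std.aa(c) == aa)
            for codon, freq in fam.items():
                assert freq == pytest.approx(codons.count(codon) / total)

    def test_rejects_partial_codon(self, code_std):
        with pytest.raises(ValueError):
            codon_usage("ATGT", code_std)


class TestShuffle:
    def test_single_member_families_unchanged(self, code_std):
        cds = "ATGTGGATGTGGTAA"  # Met/Trp only (single-codon families) + stop
        usage = codon_usage(cds, code_std)
        assert shuffle_synonymous(cds, code_std, usage, seed=5) == cds

    def test_sense_protein_preserved(self, code_std):
        rng = np.random.default_rng(12)
        for _ in range(30):
            cds = random_cds(rng, 60, code_std)
            usage = codon_usage(cds, code_std)
            shuffled = shuffle_synonymous(cds, code_std, usage, seed=int(rng.integers(2**31)))
            assert translate(shuffled, code_std).protein == translate(cds, code_std).protein

    def test_same_seed_same_output(self, code_std):
        rng = np.random.default_rng(1)
        cds = random_cds(rng, 80, code_std)
        usage = codon_usage(cds, code_std)
        assert shuffle_synonymous(cds, code_std, usage, 99) == shuffle_synonymous(cds, code_std, usage, 99)

    def test_altered_fraction_closed_form(self, code_std):
        """With family frequencies p the expected altered fraction is 1 - sum(p^2)."""
        cds = "TTT" * 9 + "TTC" + "TAA"  # Phe usage (0.9, 0.1)
        usage = codon_usage(cds, code_std)
        n_draws, altered = 0, 0
        for seed in range(2000):
            shuffled = shuffle_synonymous(cds, code_std, usage, seed)
            for i in range(0, 30, 3):
                n_draws += 1
                altered += shuffled[i : i + 3] != cds[i : i + 3]
        expected = 1 - (0.9**2 + 0.1**2)
        se = math.sqrt(expected * (1 - expected) / n_draws)
        assert abs(altered / n_draws - expected) < 3 * se


class TestReplicateMetrics:
    def test_identity_replicate(self, planted_vmt, planted_vmt_region, code_vmt):
        rep = replicate_metrics(planted_vmt.cds, planted_vmt.cds, planted_vmt_region, gau_code=code_vmt)
        assert rep.frac_altered_gene == 0.0
        assert rep.frac_altered_gau == 0.0
        assert rep.frac_gau_aa_unchanged == 100.0
        assert rep.gau_stop_count == len(planted_vmt_region.stop_positions)

    def test_single_forced_substitution(self, planted_vmt, planted_vmt_region, code_vmt):
        """One synonymous change inside the region: metrics follow by hand."""
        cds = planted_vmt.cds
        region = planted_vmt_region
        n_codons = len(cds) // 3
        span = range((region.start_nt - 1) // 3, (region.end_nt - 1) // 3 + 1)
        forced = None
        for i in span:
            codon = cds[3 * i : 3 * i + 3]
            for alt in code_vmt.family(code_vmt.aa(codon)):
                if alt != codon:
                    forced = (i, alt)
                    break
            if forced:
                break
        i, alt = forced
        mutated = cds[: 3 * i] + alt + cds[3 * i + 3 :]
        rep = replicate_metrics(cds, mutated, region, gau_code=code_vmt, sense_code=code_vmt)
        assert rep.frac_altered_gene == pytest.approx(100.0 / n_codons)
        assert rep.frac_altered_gau == pytest.approx(100.0 / len(span))
        assert rep.frac_altered_to_aa_change in (0.0, 100.0)
        # consistency: the flag agrees with a direct residue comparison
        changed = rep.frac_gau_aa_unchanged < 100.0
        assert (rep.frac_altered_to_aa_change == 100.0) == changed

    def test_non_preserving_input_rejected(self, planted_vmt, planted_vmt_region, code_vmt):
        bad = "ATG" + planted_vmt.cds[3:]
        if translate(bad, code_vmt).protein != translate(planted_vmt.cds, code_vmt).protein:
            with pytest.raises(ValueError, match="preserve"):
                replicate_metrics(planted_vmt.cds, bad, planted_vmt_region, gau_code=code_vmt, sense_code=code_vmt)


class TestEnumerateStopSites:
    def test_matches_independent_enumeration(self, planted_vmt, planted_vmt_region, code_vmt):
        """Second brute force via the codon-geometry primitive."""
        cds, region = planted_vmt.cds, planted_vmt_region
        sites = enumerate_stop_sites(cds, code_vmt, region, gau_code=code_vmt)
        # oracle: walk sense codons, substitute synonyms, read the two
        # overlapping antisense codons through minus2_codon
        m = len(cds) // 3
        n_frame = m - 1
        j_a = None
        # recover the anchor frame index from the region coordinates
        j_a = (len(cds) - 2 - (region.end_nt - 1)) // 3 + 1
        expected = set()
        for i in range(m - 1):
            codon = cds[3 * i : 3 * i + 3]
            for alt in code_vmt.family(code_vmt.aa(codon)):
                if alt == codon:
                    continue
                variant = cds[: 3 * i] + alt + cds[3 * i + 3 :]
                for k in (i - 1, i):
                    if not 0 <= k < m - 1:
                        continue
                    j = m - 2 - k
                    residue = j - (j_a - 1) + 1
                    if not 1 <= residue <= 101:
                        continue
                    before = code_vmt.aa(minus2_codon(cds, k))
                    after = code_vmt.aa(minus2_codon(variant, k))
                    if after == "*" and before != "*":
                        expected.add(residue)
        assert sites == expected

    def test_no_synonymous_freedom_gives_empty(self, code_std):
        """Met/Trp-only CDS has no synonymous moves, hence no creatable stops."""
        cds = "ATGTGG" * 55  # 110 codons, single-member families throughout
        region = extract_gau_region(cds, code_std, ("-2", 2))
        assert enumerate_stop_sites(cds, code_std, region, gau_code=code_std) == set()

    def test_replicate_stops_bounded_by_enumeration(self, planted_vmt, planted_vmt_region, code_vmt):
        cds, region = planted_vmt.cds, planted_vmt_region
        sites = enumerate_stop_sites(cds, code_vmt, region, gau_code=code_vmt)
        natural = len(region.stop_positions)
        reps, _ = run_shuffle(cds, region, sense_code=code_vmt, gau_code=code_vmt, n_reps=10, seed=4)
        for rep in reps:
            assert rep.gau_stop_count <= natural + len(sites)


def _rep(gene, gau):
    return ShuffleReplicate(
        seed=0,
        frac_altered_gene=gene,
        frac_altered_gau=gau,
        frac_gau_aa_unchanged=80.0,
        frac_altered_to_aa_change=40.0,
        gau_stop_count=10,
    )


class TestSummary:
    def test_balanced_differences_give_t_zero(self):
        reps = [_rep(50, 51), _rep(50, 49), _rep(50, 51), _rep(50, 49)]
        summary = summarize_replicates(reps, natural_gau_stop_count=14)
        assert summary.paired_t == pytest.approx(0.0)
        assert summary.paired_p == pytest.approx(1.0)

    def test_paired_t_matches_closed_form(self):
        """Five paired differences checked against the hand formula."""
        gene = [50.0, 52.0, 48.0, 51.0, 49.0]
        gau = [53.0, 54.0, 49.0, 55.0, 50.0]
        reps = [_rep(g, u) for g, u in zip(gene, gau)]
        diffs = np.array(gau) - np.array(gene)
        t_hand = diffs.mean() / (diffs.std(ddof=1) / math.sqrt(len(diffs)))
        summary = summarize_replicates(reps, natural_gau_stop_count=14)
        assert summary.paired_t == pytest.approx(t_hand)
        from scipy import stats

        assert summary.paired_p == pytest.approx(2 * stats.t.sf(abs(t_hand), 4))

    def test_zero_variance_flagged_degenerate(self):
        reps = [_rep(50, 52)] * 5
        summary = summarize_replicates(reps, natural_gau_stop_count=14)
        assert summary.degenerate
        assert math.isnan(summary.paired_p)

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError):
            summarize_replicates([_rep(1, 2)], natural_gau_stop_count=0)


def test_full_run_reports_all_metrics(planted_vmt, planted_vmt_region, code_vmt):
    reps, summary = run_shuffle(
        planted_vmt.cds, planted_vmt_region, sense_code=code_vmt, gau_code=code_vmt, n_reps=5, seed=2
    )
    assert summary.n_reps == 5
    assert summary.natural_gau_stop_count == len(planted_vmt_region.stop_positions)
    assert 0 <= summary.means["frac_altered_gene"] <= 100
    assert 0 <= summary.means["frac_gau_aa_unchanged"] <= 100
    assert len({r.seed for r in reps}) == 5
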