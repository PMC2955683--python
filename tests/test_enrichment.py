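"""Multiplicity, IUPAC consensus enrichment, and validated-set controls."""

import numpy as np
import pytest

from seedfold.accessibility import AccessibilityScores, RankedTargets
from seedfold.enrichment import (
    IUPACPattern,
    count_seed_matches_relaxed,
    multiplicity_rank_correlation,
    pattern_enrichment,
    resampled_pattern_enrichment,
    validated_set_enrichment,
)
from seedfold.io import reverse_complement
from seedfold.sequence_sites import TargetWindow

from oracles import count_relaxed_bruteforce

SEED = "GAGGUAG"


class TestRelaxedSeedMatching:
    def test_exact_complement_counts_once(self):
        # C-only background offers no G to pair the seed's C... position and
        # cannot reach 6 paired positions outside the planted complement
        seq = "C" * 20 + reverse_complement(SEED) + "C" * 20
        assert count_seed_matches_relaxed(seq, SEED) == count_relaxed_bruteforce(
            seq, SEED
        )
        assert count_seed_matches_relaxed(seq, SEED) == 1

    def test_wobble_variant_counts_as_second_site(self):
        site = reverse_complement(SEED)          # CUACCUC
        wobble = "U" + site[1:]                  # G can wobble-pair U
        seq = "C" * 10 + site + "C" * 10 + wobble + "C" * 10
        assert count_seed_matches_relaxed(seq, SEED) == 2

    def test_poly_a_with_unpairable_seed(self):
        # seed CCCCCCC needs G or (wobble) U in the target; poly-A pairs at 0
        # of 7 positions, far beyond the 1-mismatch allowance
        assert count_seed_matches_relaxed("A" * 50, "CCCCCCC") == 0

    @pytest.mark.parametrize("seed_idx", range(5))
    def test_matches_bruteforce_on_random_sequences(self, seed_idx):
        rng = np.random.default_rng(seed_idx)
        mirna_seed = "".join(rng.choice(list("ACGU"), size=7))
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGU"), size=60))
            assert count_seed_matches_relaxed(seq, mirna_seed) == (
                count_relaxed_bruteforce(seq, mirna_seed)
            )


def _ranked_from(seqs, gas=None):
    gas = gas if gas is not None else [float(i) for i in range(len(seqs))]
    entries = tuple(
        (
            TargetWindow(f"w{i:03d}", f"g{i:03d}", s, 70, 77),
            AccessibilityScores(dg_all=g, dg_masked=g),  # ga == dg_all here
        )
        for i, (s, g) in enumerate(zip(seqs, gas))
    )
    return RankedTargets(entries=entries)


def _random_windows(rng, n):
    site = reverse_complement(SEED)
    out = []
    for _ in range(n):
        chars = list(rng.choice(list("ACGU"), size=147))
        chars[70:77] = list(site)
        out.append("".join(chars))
    return out


class TestMultiplicityCorrelation:
    def test_constant_counts_undefined(self):
        seqs = ["C" * 70 + reverse_complement(SEED) + "C" * 70] * 5
        r = multiplicity_rank_correlation(_ranked_from(seqs), SEED)
        assert np.isnan(r)

    def test_perfectly_increasing_counts(self):
        site = reverse_complement(SEED)
        seqs = [
            ("C" * 20).join([site] * (i + 1)).ljust(147, "C")
            for i in range(5)
        ]
        r = multiplicity_rank_correlation(_ranked_from(seqs), SEED)
        assert r == pytest.approx(1.0)

    def test_independent_multiplicity_uncorrelated(self):
        """Multiplicity planted independently of the ranking: |r| < 0.2 in
        at least 95% of seeded replicates (200 windows each, the generator's
        default list length)."""
        ok = 0
        n_rep = 100
        for s in range(n_rep):
            rng = np.random.default_rng(1000 + s)
            ranked = _ranked_from(_random_windows(rng, 200))
            r = multiplicity_rank_correlation(ranked, SEED)
            if np.isnan(r) or abs(r) < 0.2:
                ok += 1
        assert ok >= 95


class TestIUPACPattern:
    def test_h_excludes_g(self):
        rx = IUPACPattern("UGUAHAUA").to_regex()
        assert rx.search("UGUAUAUA")
        assert rx.search("UGUACAUA")
        assert rx.search("UGUAAAUA")
        assert not rx.search("UGUAGAUA")

    def test_matcher_agrees_with_explicit_expansion(self):
        pat = IUPACPattern("URUAHAUA")
        concrete = set(pat.expand())
        rng = np.random.default_rng(0)
        for _ in range(200):
            s = "".join(rng.choice(list("ACGU"), size=8))
            assert bool(pat.to_regex().fullmatch(s)) == (s in concrete)

    def test_invalid_symbol_rejected(self):
        with pytest.raises(ValueError):
            IUPACPattern("UGUAXAUA")


class TestPatternEnrichment:
    def test_absent_pattern_scores_one(self):
        res = pattern_enrichment(["AAAA", "CCCC", "AACC"], "GGGG")
        assert res.score == 1.0 and res.p_value == 1.0

    def test_planted_top_quartile_enriched(self):
        rng = np.random.default_rng(42)
        motif = "UGUAUAUA"
        seqs = []
        for i in range(100):
            chars = list(rng.choice(list("ACGU"), size=80))
            p_plant = 0.8 if i < 25 else 0.08  # ~10x odds toward the top
            if rng.random() < p_plant:
                pos = int(rng.integers(0, 80 - 8))
                chars[pos : pos + 8] = list(motif)
            seqs.append("".join(chars))
        res = pattern_enrichment(seqs, "UGUAHAUA")
        assert res.p_value <= 1e-3
        rev = pattern_enrichment(seqs[::-1], "UGUAHAUA")
        assert rev.p_value >= res.p_value

    def test_resampled_control_reports_best_p(self):
        rng = np.random.default_rng(5)
        pool = ["".join(rng.choice(list("ACGU"), size=60)) for _ in range(80)]
        best, pvals = resampled_pattern_enrichment(
            pool, "UGUAHAUA", set_size=30, rank_key=lambda s: s.count("G"),
            n_repeats=20, seed=9,
        )
        assert best.p_value == min(pvals)
        assert len(pvals) == 20


class TestValidatedSetEnrichment:
    def test_empty_validated_set_scores_one(self, default_ranked):
        ranked, _ = default_ranked
        res = validated_set_enrichment(ranked, [], "UGUAHAUA")
        assert res.score == 1.0

    def test_match_overlapping_site_excluded(self):
        # the only consensus match sits exactly on the seed site
        site = "UGUAUAUA"
        chars = ["C"] * 147
        chars[70:78] = list(site)
        w = TargetWindow("w0", "g0", "".join(chars), 70, 78)
        ranked = RankedTargets(
            entries=(
                (w, AccessibilityScores(-1.0, 0.0)),
                (
                    TargetWindow("w1", "g1", "C" * 147, 70, 77),
                    AccessibilityScores(0.0, 0.0),
                ),
            )
        )
        with_excl = validated_set_enrichment(ranked, {"g0"}, "UGUAHAUA")
        without = validated_set_enrichment(
            ranked, {"g0"}, "UGUAHAUA", site_exclusion=False
        )
        assert with_excl.b_star == 0 or with_excl.score == 1.0
        assert without.score < 1.0

    def test_shuffled_labels_are_calibrated(self):
        """Exact p-values under a random-label null: super-uniform tail and
        a central median (200 shuffles, N=60, B=12)."""
        rng = np.random.default_rng(8)
        base = [1] * 12 + [0] * 48
        from seedfold.mhg import mhg_test

        ps = []
        for _ in range(200):
            lam = list(base)
            rng.shuffle(lam)
            ps.append(mhg_test(tuple(lam)).p_value)
        ps = np.array(ps)
        assert (ps <= 0.05).mean() <= 0.10   # ~3 sigma above the nominal 5%
        assert 0.25 <= np.median(ps) <= 0.95
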