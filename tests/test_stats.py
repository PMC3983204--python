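"""Enrichment statistics against independent brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

from pdzscan import (
    ClassificationConfig,
    CTerminus,
    ProteinIsoform,
    VariantRecord,
    binomial_enrichment,
    classify_variant,
    fisher_overlap,
    gold_standard_fisher,
    make_designed_pwms,
    mutate_cterm,
    randomized_disruption_fraction,
    score_cterm,
    simulate_proteome,
    simulate_variants,
    sweep_motif_thresholds,
)
from pdzscan.alphabet import AMINO_ACIDS
from pdzscan.proteome import extract_ctermini
from pdzscan.pwm import score_all


# ---------------------------------------------------------------------------
# independent oracles (log-gamma binomial pmf; combinatorial hypergeometric)

def log_binom_pmf(k, n, p):
    if p in (0.0, 1.0):
        return 0.0 if k == (n if p else 0) else -math.inf
    return (
        math.lgamma(n + 1)
        - math.lgamma(k + 1)
        - math.lgamma(n - k + 1)
        + k * math.log(p)
        + (n - k) * math.log1p(-p)
    )


def brute_binom_tail(k, n, p, sidedness):
    pmf = [math.exp(log_binom_pmf(i, n, p)) for i in range(n + 1)]
    if sidedness == "greater":
        return sum(pmf[k:])
    if sidedness == "less":
        return sum(pmf[: k + 1])
    # two-sided: total mass of outcomes no more likely than the observed one
    cut = pmf[k] * (1 + 1e-7)
    return sum(q for q in pmf if q <= cut)


def brute_hypergeom_upper(M, K, N, k):
    """P(X >= k) by direct combinatorial enumeration."""
    total = math.comb(M, N)
    return sum(
        math.comb(K, i) * math.comb(M - K, N - i)
        for i in range(k, min(K, N) + 1)
    ) / total


class TestBinomialEnrichment:
    def test_matches_brute_force_over_random_cases(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            total = int(rng.integers(50, 2000))
            region = int(rng.integers(1, total + 1))
            n_var = int(rng.integers(0, total))
            rate = n_var / total
            k = int(rng.integers(0, min(region, n_var) + 1)) if n_var else 0
            for side in ("greater", "less", "two"):
                res = binomial_enrichment(k, n_var, region, total, side)
                oracle = brute_binom_tail(k, region, rate, side)
                assert res.p_value == pytest.approx(oracle, rel=1e-3, abs=1e-12)
                assert res.expected == pytest.approx(n_var * region / total)

    def test_zero_observed_greater_tail_is_one(self):
        res = binomial_enrichment(0, 1, 1, 2, "greater")
        assert res.p_value == 1.0

    def test_input_guards(self):
        with pytest.raises(ValueError, match="total_aa"):
            binomial_enrichment(1, 1, 1, 0)
        with pytest.raises(ValueError, match="region_aa"):
            binomial_enrichment(1, 1, 5, 4)
        with pytest.raises(ValueError, match="rate"):
            binomial_enrichment(0, 10, 1, 2)
        with pytest.raises(ValueError):
            binomial_enrichment(5, 4, 2, 10)


class TestFisherOverlap:
    def test_enumerated_small_table(self):
        # 2 draws from 10 with 5 marked, both marked: C(5,2)/C(10,2) = 2/9
        res = fisher_overlap(10, 5, 2, 2)
        assert res.p_value == pytest.approx(2 / 9)

    def test_matches_hypergeometric_enumeration_and_fisher(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            M = int(rng.integers(5, 60))
            K = int(rng.integers(0, M + 1))
            N = int(rng.integers(0, M + 1))
            k = int(rng.integers(max(0, K + N - M), min(K, N) + 1))
            res = fisher_overlap(M, K, N, k)
            oracle = brute_hypergeom_upper(M, K, N, k)
            assert res.p_value == pytest.approx(oracle, rel=1e-9, abs=1e-300)
            table = [[k, N - k], [K - k, M - N - K + k]]
            assert res.p_value == pytest.approx(
                fisher_exact(table, alternative="greater")[1], rel=1e-9
            )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError, match="inconsistent counts"):
            fisher_overlap(10, 5, 2, 4)


class TestSweep:
    @pytest.fixture()
    def fixture(self):
        # 10 C-termini of 7 aa; domain scores chosen so exactly 2 exceed -5
        seqs = ["GETWVAA"] * 10
        cts = [CTerminus(f"P{i}", "i1", seqs[i], 1) for i in range(10)]
        scores = np.full((1, 10), -12.0)
        scores[0, 0] = -4.0
        scores[0, 1] = -4.5
        matrix = pd.DataFrame(
            scores, index=["d1"], columns=[c.key for c in cts]
        )
        # 12 nsSNP occurrences, 3 inside the two high-scoring C-termini
        hits = ["P0|i1", "P0|i1", "P1|i1"] + [f"P{i}|i1" for i in range(2, 11 - 2)] + ["P2|i1", "P3|i1"]
        assert len(hits) == 12
        return matrix, cts, hits

    def test_hand_counted_fixture(self, fixture):
        matrix, cts, hits = fixture
        res = sweep_motif_thresholds(matrix, cts, hits, threshold_grid=[-5.0])
        row = res.table.iloc[0]
        assert row.n_motif_ctermini == 2
        assert row.n_variants == 3
        assert row.n_aa == 14
        assert row.ratio == pytest.approx(3 / 14)
        oracle = brute_binom_tail(3, 14, 12 / 70, "less")
        assert row.p_value == pytest.approx(oracle, rel=1e-6)

    def test_threshold_below_minimum_recovers_background(self, fixture):
        matrix, cts, hits = fixture
        res = sweep_motif_thresholds(matrix, cts, hits, threshold_grid=[-20.0])
        row = res.table.iloc[0]
        assert row.n_motif_ctermini == 10
        assert row.ratio == pytest.approx(res.background_rate)
        assert row.p_value > 0.4  # observed equals expectation: no depletion

    def test_threshold_above_maximum_reports_missing(self, fixture):
        matrix, cts, hits = fixture
        res = sweep_motif_thresholds(matrix, cts, hits, threshold_grid=[-1.0])
        row = res.table.iloc[0]
        assert row.n_variants == 0
        assert np.isnan(row.ratio) and np.isnan(row.p_value)

    def test_counts_monotone_in_threshold(self, fixture):
        matrix, cts, hits = fixture
        res = sweep_motif_thresholds(
            matrix, cts, hits, threshold_grid=np.linspace(-15, -2, 40)
        )
        # grid is descending: counts non-decreasing downward
        assert res.table.threshold.is_monotonic_decreasing
        assert res.table.n_variants.is_monotonic_increasing
        assert res.table.n_aa.is_monotonic_increasing

    def test_empty_grid_rejected(self, fixture):
        matrix, cts, hits = fixture
        with pytest.raises(ValueError, match="empty threshold grid"):
            sweep_motif_thresholds(matrix, cts, hits, threshold_grid=[])


class TestRandomization:
    def test_null_mean_matches_exhaustive_substitution_oracle(self):
        # single planted variant: the null is the exact fraction of the 19
        # substitutions crossing both thresholds, enumerable directly
        pwms = make_designed_pwms(n_domains=1, seed=3)
        proteome, truth = simulate_proteome(
            n_proteins=4, motif_fraction=1.0, near_motif_fraction=0.0,
            pwms=pwms, isoform_rate=0.0, seed=3,
            extracellular_fraction=0.0, mito_fraction=0.0,
        )
        variants, truth = simulate_variants(
            proteome, truth, n_disrupt=1, n_create=0, n_neutral=0,
            n_stopgain=0, seed=4,
        )
        (var,) = variants
        config = ClassificationConfig()
        iso = next(i for i in proteome if i.protein_id == var.protein_id)
        ct = extract_ctermini([iso])[0]
        wt_scores = {p.domain_id: score_cterm(p, ct.sequence) for p in pwms}
        crossing = 0
        for alt in AMINO_ACIDS:
            if alt == var.ref_aa:
                continue
            mutated = mutate_cterm(
                ct,
                VariantRecord("x", var.protein_id, var.isoform_id,
                              var.position, var.ref_aa, alt, "missense"),
            )
            mut_scores = {
                p.domain_id: score_cterm(p, mutated.sequence) for p in pwms
            }
            if classify_variant(wt_scores, mut_scores, config).verdict == "disrupts":
                crossing += 1
        exact = crossing / 19

        summary = randomized_disruption_fraction(
            variants, proteome, pwms, config,
            s_max_grid=[config.s_max], n_reps=1000, seed=9,
        )
        se = math.sqrt(exact * (1 - exact) / 1000) if 0 < exact < 1 else 0.0
        assert summary.observed[0] == 1.0  # the planted alt disrupts
        assert abs(summary.null_mean[0] - exact) <= 3 * se + 1e-12

    def test_fixed_seed_is_bitwise_reproducible(self, synthetic_study):
        proteome, variants, truth = synthetic_study
        a = randomized_disruption_fraction(
            variants, proteome, truth.pwms, n_reps=50, seed=123
        )
        b = randomized_disruption_fraction(
            variants, proteome, truth.pwms, n_reps=50, seed=123
        )
        assert np.array_equal(a.null_mean, b.null_mean)
        assert np.array_equal(a.null_sd, b.null_sd)
        assert np.array_equal(a.observed, b.observed)

    def test_zero_variants_give_zero_fractions(self, synthetic_study):
        proteome, _, truth = synthetic_study
        summary = randomized_disruption_fraction(
            [], proteome, truth.pwms, n_reps=10, seed=1
        )
        assert summary.n_variants == 0
        assert (summary.observed == 0).all() and (summary.null_sd == 0).all()

    def test_null_drawn_alts_lie_on_the_null_curve(self):
        # calibration: when observed alternates are themselves uniform draws
        # from the 19 non-identical residues, the observed curve sits within
        # the null band
        rng = np.random.default_rng(17)
        pwms = make_designed_pwms(n_domains=2, seed=21)
        proteome, truth = simulate_proteome(
            n_proteins=30, motif_fraction=0.5, near_motif_fraction=0.0,
            pwms=pwms, isoform_rate=0.0, seed=21,
            extracellular_fraction=0.0, mito_fraction=0.0,
        )
        variants = []
        for k, iso in enumerate(i for i in proteome if i.isoform_id == "i1"):
            n = len(iso.sequence)
            pos = int(n - rng.integers(0, 7))
            ref = iso.sequence[pos - 1]
            alt = ref
            while alt == ref:
                alt = AMINO_ACIDS[int(rng.integers(20))]
            variants.append(
                VariantRecord(f"v{k}", iso.protein_id, iso.isoform_id,
                              pos, ref, alt, "missense")
            )
        summary = randomized_disruption_fraction(
            variants, proteome, pwms, n_reps=400, seed=5
        )
        n = summary.n_variants
        for obs, mean, sd in zip(summary.observed, summary.null_mean, summary.null_sd):
            band = 4 * max(sd, math.sqrt(0.25 / n))
            assert abs(obs - mean) <= band


class TestGoldStandardFisher:
    def test_planted_interactions_enriched(self, synthetic_study):
        proteome, _, truth = synthetic_study
        from pdzscan import filter_compartments

        filtered, _ = filter_compartments(proteome)
        matrix = score_all(truth.pwms, extract_ctermini(filtered))
        gold = [(e["domain_id"], e["protein_id"]) for e in truth.motif_proteins]
        res = gold_standard_fisher(matrix, gold)
        assert res.p_value < 1e-10
        assert res.observed == len(gold)

    def test_no_matching_domains_rejected(self, synthetic_study):
        proteome, _, truth = synthetic_study
        matrix = score_all(truth.pwms, extract_ctermini(proteome[:5]))
        with pytest.raises(ValueError, match="no gold-standard domain"):
            gold_standard_fisher(matrix, [("NOPE", "P0001")])
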