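"""GLMM fitting, permutation inference and multiplicity control."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from nichecompare.diff_abundance import (
    PAIRS,
    bh_adjust,
    build_design,
    aggregate_counts,
    aggregate_and_test,
    differential_abundance,
    pairwise_summary,
    permutation_test,
)
from nichecompare.glmm import GlmmDesign, fit_binomial_glmm_arrays, pairwise_contrasts
from nichecompare.io_model import NICHES, CountTable, TaxonRecord, ValidationError
from nichecompare.preprocess import exclude_low_count_samples
from nichecompare.synthetic_data import SimConfig, simulate_dataset


class TestGlmmFit:
    def test_matches_plain_binomial_regression_when_variances_vanish(self):
        """Data generated without random effects: the mixed fit collapses
        onto the ordinary (no-random-effect) IRLS solution."""
        rng = np.random.default_rng(42)
        n_samp = 238
        niche = rng.integers(0, 4, n_samp)
        design = GlmmDesign(
            niche, rng.integers(0, 14, n_samp), rng.integers(0, 3, n_samp), list(NICHES)
        )
        beta_true = np.array([-3.0, -3.5, -4.0, -2.5])
        totals = rng.integers(5000, 20000, n_samp).astype(float)
        y = rng.binomial(totals.astype(int), expit(beta_true[niche])).astype(float)

        fit = fit_binomial_glmm_arrays(y, totals, design)
        X = np.zeros((n_samp, 4))
        X[np.arange(n_samp), niche] = 1
        oracle = sm.GLM(
            np.column_stack([y, totals - y]), X, family=sm.families.Binomial()
        ).fit()
        assert np.max(np.abs(fit.beta - oracle.params)) < 1e-3
        assert fit.var_dog < 1e-3 and fit.var_day < 1e-3
        assert fit.converged

    def test_two_group_closed_form_odds_ratio(self):
        """30/100 vs 10/100 with no random structure: OR = (30/70)/(10/90)."""
        niche = np.tile([0, 0, 1, 1], 5)
        dog = np.repeat(np.arange(5), 4)
        design = GlmmDesign(niche, dog, np.zeros(20, int), ["a", "b"])
        y = np.where(niche == 0, 6.0, 2.0)
        fit = fit_binomial_glmm_arrays(y, np.full(20, 20.0), design)
        c = pairwise_contrasts(fit)[0]
        assert c["odds_ratio"] == pytest.approx((30 / 70) / (10 / 90), rel=0.01)
        assert c["or_ci_low"] < c["odds_ratio"] < c["or_ci_high"]

    def test_single_niche_input_rejected(self):
        design = GlmmDesign(np.zeros(6, int), np.arange(6) % 2, np.zeros(6, int), ["a"])
        with pytest.raises(ValueError):
            fit_binomial_glmm_arrays(np.ones(6), np.full(6, 10.0), design)

    def test_zero_total_rejected(self):
        design = GlmmDesign(np.array([0, 1]), np.zeros(2, int), np.zeros(2, int), ["a", "b"])
        with pytest.raises(ValueError):
            fit_binomial_glmm_arrays(np.array([1.0, 0.0]), np.array([10.0, 0.0]), design)

    def test_dog_variance_recovery_over_replicates(self):
        """Mean estimated var_dog over 50 simulated datasets with
        sigma_dog = 0.5 lands within 20% of the true 0.25."""
        estimates = []
        for s in range(50):
            cfg = SimConfig(
                n_otus=24,
                seed=1000 + s,
                sigma_dog=0.5,
                sigma_day=0.1,
                dirichlet_concentration={n: 1e6 for n in NICHES},
                niche_profiles={n: np.full(24, 1 / 24) for n in NICHES},
                low_count_samples=0,
                fail_amp={},
                missing_saliva=0,
            )
            ct, samples, _, _ = simulate_dataset(cfg)
            design = build_design(ct, samples)
            fit = fit_binomial_glmm_arrays(
                ct.counts[5].astype(float), ct.column_totals().astype(float), design
            )
            estimates.append(fit.var_dog)
        assert np.mean(estimates) == pytest.approx(0.25, rel=0.20)

    def test_mean_proportion_cis_bracket_the_estimate(self):
        rng = np.random.default_rng(5)
        niche = rng.integers(0, 4, 100)
        design = GlmmDesign(niche, rng.integers(0, 5, 100), rng.integers(0, 3, 100), list(NICHES))
        y = rng.binomial(1000, 0.02, 100).astype(float)
        fit = fit_binomial_glmm_arrays(y, np.full(100, 1000.0), design)
        ci = fit.mean_proportion_ci()
        p = fit.mean_proportions
        assert np.all((ci[:, 0] < p) & (p < ci[:, 1]))
        assert np.all((p > 0) & (p < 1))


class TestAgainstLme4:
    def test_fit_matches_glmer_laplace(self, tmp_path):
        """Independent oracle: lme4::glmer (Laplace) on the same data.

        Fixed effects should agree to ~1e-2 on the logit scale and the
        variance components closely; the only systematic difference is
        this package's weak stabilising ridge on the fixed effects.
        """
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(7)
        n_samp = 120
        niche = rng.integers(0, 4, n_samp)
        dog = rng.integers(0, 10, n_samp)
        day = rng.integers(0, 3, n_samp)
        beta_true = np.array([-3.0, -3.4, -2.6, -3.8])
        b = rng.normal(0, 0.5, 10)
        c = rng.normal(0, 0.2, 3)
        totals = rng.integers(3000, 15000, n_samp)
        y = rng.binomial(totals, expit(beta_true[niche] + b[dog] + c[day]))

        design = GlmmDesign(niche, dog, day, ["n0", "n1", "n2", "n3"])
        fit = fit_binomial_glmm_arrays(y.astype(float), totals.astype(float), design)

        dat = tmp_path / "d.tsv"
        with dat.open("w") as fh:
            fh.write("y\tn\tniche\tdog\tday\n")
            for i in range(n_samp):
                fh.write(f"{y[i]}\t{totals[i]}\tn{niche[i]}\td{dog[i]}\tt{day[i]}\n")
        rcode = (
            'suppressMessages(library(lme4));'
            f'd <- read.delim("{dat}");'
            "m <- glmer(cbind(y, n - y) ~ 0 + niche + (1|dog) + (1|day),"
            " data=d, family=binomial);"
            'cat(fixef(m), "\\n");'
            "vc <- as.data.frame(VarCorr(m));"
            'cat(vc$vcov[vc$grp == "dog"], vc$vcov[vc$grp == "day"], "\\n")'
        )
        proc = subprocess.run(
            ["Rscript", "-e", rcode], capture_output=True, text=True, timeout=300
        )
        if proc.returncode != 0:
            pytest.skip(f"lme4 unavailable: {proc.stderr[-200:]}")
        lines = [ln for ln in proc.stdout.strip().splitlines() if ln.strip()]
        r_beta = np.array([float(v) for v in lines[0].split()])
        r_vd, r_vt = (float(v) for v in lines[1].split())
        assert np.max(np.abs(fit.beta - r_beta)) < 0.01
        assert fit.var_dog == pytest.approx(r_vd, abs=0.01)
        assert fit.var_day == pytest.approx(r_vt, abs=0.01)


def _enumerate_within_dog_labelings(niche, dog):
    """All distinct within-dog rearrangements of the niche labels."""
    dogs = np.unique(dog)
    per_dog = []
    for d in dogs:
        idx = np.flatnonzero(dog == d)
        labels = niche[idx]
        perms = {tuple(p) for p in itertools.permutations(labels)}
        per_dog.append((idx, sorted(perms)))
    combos = itertools.product(*[p for _, p in per_dog])
    for combo in combos:
        out = niche.copy()
        for (idx, _), labels in zip(per_dog, combo):
            out[idx] = labels
        yield out


class TestPermutation:
    def _toy(self):
        # 2 dogs x 2 niches x 2 samples each; one clear difference
        niche = np.array([0, 0, 1, 1, 0, 0, 1, 1])
        dog = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        day = np.zeros(8, int)
        design = GlmmDesign(niche, dog, day, ["a", "b"])
        y = np.array([30.0, 28.0, 12.0, 10.0, 29.0, 31.0, 9.0, 13.0])
        n = np.full(8, 100.0)
        return y, n, design

    def test_monte_carlo_p_matches_exhaustive_enumeration(self):
        """The MC estimate agrees with brute-force enumeration of all 36
        within-dog label arrangements within 2 binomial SEs."""
        y, n, design = self._toy()

        def stat(niche_codes):
            d = GlmmDesign(niche_codes, design.dog_codes, design.day_codes, design.niche_levels)
            fit = fit_binomial_glmm_arrays(y, n, d)
            return abs(pairwise_contrasts(fit)[0]["wald_stat"])

        obs = stat(design.niche_codes)
        all_stats = [
            stat(lbl) for lbl in _enumerate_within_dog_labelings(design.niche_codes, design.dog_codes)
        ]
        exact_p = np.mean([s >= obs - 1e-9 for s in all_stats])

        res = permutation_test(y, n, design, n_perm=400, seed=2)
        mc_p = res["perm_p"][("a", "b")]
        se = np.sqrt(exact_p * (1 - exact_p) / 400)
        assert abs(mc_p - exact_p) <= 2 * se + 1 / 401

    def test_add_one_lower_bound(self):
        y, n, design = self._toy()
        res = permutation_test(y, n, design, n_perm=99, seed=0)
        p = res["perm_p"][("a", "b")]
        assert p >= 1 / 100
        assert 0 < p <= 1

    def test_no_signal_gives_large_p(self):
        y = np.full(8, 20.0)
        n = np.full(8, 100.0)
        niche = np.array([0, 0, 1, 1, 0, 0, 1, 1])
        dog = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        design = GlmmDesign(niche, dog, np.zeros(8, int), ["a", "b"])
        res = permutation_test(y, n, design, n_perm=99, seed=0)
        assert res["perm_p"][("a", "b")] == 1.0

    def test_p_invariant_to_dog_relabeling_up_to_mc_error(self, default_sim):
        ct, samples, _, _ = default_sim
        qc, _ = exclude_low_count_samples(ct, samples)
        design = build_design(qc, samples)
        y = qc.counts[3].astype(float)
        n = qc.column_totals().astype(float)
        res1 = permutation_test(y, n, design, n_perm=199, seed=21)
        # relabel dogs by reversing the code assignment
        relabeled = GlmmDesign(
            design.niche_codes,
            design.dog_codes.max() - design.dog_codes,
            design.day_codes,
            design.niche_levels,
        )
        res2 = permutation_test(y, n, relabeled, n_perm=199, seed=22)
        for pair in res1["perm_p"]:
            p1, p2 = res1["perm_p"][pair], res2["perm_p"][pair]
            se = np.sqrt(max(p1 * (1 - p1), 0.25 / 199) / 199)
            assert abs(p1 - p2) <= 4 * se + 2 / 200

    def test_block_mode_keeps_side_pairs_together(self):
        # 1 dog, 1 occasion: plaque L/R + buccal L/R + tongue + saliva
        niche = np.array([0, 0, 1, 1, 2, 3])
        dog = np.zeros(6, int)
        day = np.zeros(6, int)
        design = GlmmDesign(niche, dog, day, list(NICHES))
        from nichecompare.diff_abundance import _permuted_niche_codes

        rng = np.random.default_rng(0)
        for _ in range(20):
            out = _permuted_niche_codes(design, rng, sides=np.zeros(6))
            # paired units stay paired: first four entries come in equal pairs
            assert out[0] == out[1] and out[2] == out[3]
            assert sorted(out[:4]) in ([0, 0, 1, 1],)
            assert sorted(out[4:]) == [2, 3]


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_degenerate_inputs(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
        assert bh_adjust(np.array([])).size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_matches_manual_step_up_and_is_idempotent(self, pvals):
        p = np.asarray(pvals)
        adj = bh_adjust(p)
        # independent hand implementation of the step-up rule
        m = p.size
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        manual = np.empty(m)
        manual[order] = np.minimum(ranked, 1.0)
        assert np.allclose(adj, manual, atol=1e-12)
        assert np.all(adj >= p - 1e-12)
        assert np.allclose(bh_adjust(adj), bh_adjust(adj))


class TestSummariesAndAggregation:
    def test_all_nonsignificant_counts_zero(self):
        rows = [
            {"unit_id": "u", "niche_pair": pair, "adj_p": 1.0} for pair in PAIRS
        ]
        s = pairwise_summary(pd.DataFrame(rows))
        assert (s == 0).all() and len(s) == 6

    def test_category_counts_are_member_sums(self):
        ct = CountTable(["A", "B", "C"], ["S1", "S2"], np.array([[3, 1], [4, 2], [5, 9]]))
        taxa = [
            TaxonRecord("A", phylum="Firmicutes"),
            TaxonRecord("B", phylum="Firmicutes"),
            TaxonRecord("C", phylum="Bacteroidetes"),
        ]
        agg = aggregate_counts(ct, taxa, "phylum")
        df = agg.to_dataframe()
        assert list(df.loc["Firmicutes"]) == [7, 3]
        assert list(df.loc["Bacteroidetes"]) == [5, 9]

    def test_unknown_categories_are_excluded(self):
        ct = CountTable(["A", "B"], ["S1"], np.array([[3], [4]]))
        taxa = [TaxonRecord("A", gram="positive"), TaxonRecord("B", gram="unknown")]
        agg = aggregate_counts(ct, taxa, "gram")
        assert agg.otu_ids == ["positive"]

    def test_all_unknown_level_errors(self):
        ct = CountTable(["A"], ["S1"], np.array([[3]]))
        with pytest.raises(ValidationError):
            aggregate_counts(ct, [TaxonRecord("A")], "gram")

    def test_plaque_gram_positive_enrichment_detected(self, default_sim):
        """The default profiles put Gram-positive taxa on top in plaque;
        the Gram-level test must flag plaque against every other niche."""
        ct, samples, taxa, _ = default_sim
        qc, _ = exclude_low_count_samples(ct, samples)
        df = aggregate_and_test(qc, taxa, samples, level="gram", n_perm=99, seed=3)
        pos = df[df["unit_id"] == "positive"]
        plaque_pairs = pos[pos["niche_pair"].apply(lambda p: "plaque" in p)]
        assert len(plaque_pairs) == 3
        assert (plaque_pairs["adj_p"] < 0.05).all()
        # and the direction favours plaque
        for row in plaque_pairs.itertuples():
            lo = row.log_odds_diff if row.niche_pair[0] == "plaque" else -row.log_odds_diff
            assert lo > np.log(2)
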