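import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from negconn import (
    ModelSpec,
    SyntheticConfig,
    bh_fdr,
    brain_behavior_fit,
    edgewise_fit,
    fit_lmm,
    gender_balanced_permutation,
    generate_cohort,
    select_model,
    summed_t_map,
)
from negconn.stats import encode_records


def brute_force_bh(p):
    """Independent step-up oracle: q_i = min over j>=rank(i) of p_(j)*m/j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for pos, i in enumerate(order):
        candidates = [p[order[j]] * m / (j + 1) for j in range(pos, m)]
        q[i] = min(1.0, min(candidates))
    return q


class TestBhFdr:
    def test_worked_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.5])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.5])
        assert (q < 0.05).sum() == 3

    def test_all_ones_no_discoveries(self):
        assert (bh_fdr(np.ones(10)) == 1.0).all()

    def test_single_p_unchanged(self):
        assert bh_fdr([0.123]) == pytest.approx([0.123])

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)

    def test_q_dominates_p_and_monotone(self, rng):
        p = rng.uniform(size=100)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


def _single_scan_records(rng, n=80):
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "wave": 1,
            "group": rng.choice(["control", "adhd"], size=n),
            "sex": rng.choice(["M", "F"], size=n),
            "age": rng.uniform(7, 11, size=n),
            "mean_fd": rng.uniform(0.05, 0.2, size=n),
            "avg_neg_conn": rng.normal(-0.28, 0.05, size=n),
        }
    )


class TestFitLmm:
    def test_degenerate_design_equals_ols(self, rng):
        # one scan per subject: GLS weighting is proportional to identity,
        # so fixed effects must match ordinary least squares
        records = _single_scan_records(rng)
        res = fit_lmm(records, "avg_neg_conn", ModelSpec.model1())
        enc = encode_records(records)
        ols = smf.ols("avg_neg_conn ~ adhd + age_c + female + mean_fd", enc).fit()
        for term in res.terms.index:
            assert res.terms.loc[term, "estimate"] == pytest.approx(
                ols.params[term], abs=1e-6
            )

    def test_identity_regression(self, rng):
        records = _single_scan_records(rng)
        records["avg_neg_conn"] = records["mean_fd"] + rng.normal(0, 1e-8, len(records))
        res = fit_lmm(records, "avg_neg_conn", ModelSpec.model1())
        assert res.terms.loc["mean_fd", "estimate"] == pytest.approx(1.0, abs=1e-4)
        assert res.resid_variance < 1e-10

    def test_group_sign_recovery_on_planted_effect(self):
        cfg = SyntheticConfig(seed=2, n_subjects_per_group=120)
        records = generate_cohort(cfg, emit_timeseries=False).records
        res = fit_lmm(records, "avg_neg_conn", ModelSpec.model1())
        # planted ADHD shift toward zero: positive coefficient on the z scale
        assert res.terms.loc["adhd", "estimate"] > 0
        assert res.terms.loc["female", "estimate"] < 0

    def test_parameter_counts_match_model_families(self, small_records):
        for spec, k in ((ModelSpec.model1(), 7), (ModelSpec.model2(), 8), (ModelSpec.model3(), 11)):
            assert fit_lmm(small_records, "avg_neg_conn", spec).df_model == k

    def test_rank_deficient_design_names_aliased_terms(self, rng):
        records = _single_scan_records(rng)
        records["sex"] = "M"  # 'female' column becomes all-zero
        with pytest.raises(ValueError, match="female"):
            fit_lmm(records, "avg_neg_conn", ModelSpec.model1())

    def test_missing_outcome_rejected(self, rng):
        records = _single_scan_records(rng)
        records.loc[0, "avg_neg_conn"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_lmm(records, "avg_neg_conn")


class TestSelectModel:
    def test_single_candidate_returned(self, small_records):
        res = fit_lmm(small_records, "avg_neg_conn", ModelSpec.model1())
        best, table = select_model([res])
        assert best is res and len(table) == 1

    def test_tie_returns_first(self, small_records):
        res = fit_lmm(small_records, "avg_neg_conn", ModelSpec.model1())
        best, _ = select_model([res, res])
        assert best is res

    def test_differing_data_rejected(self, small_records):
        a = fit_lmm(small_records, "avg_neg_conn", ModelSpec.model1())
        b = fit_lmm(small_records.iloc[:-2], "avg_neg_conn", ModelSpec.model1())
        with pytest.raises(ValueError, match="comparable"):
            select_model([a, b])

    def test_main_effects_model_wins_on_main_effects_truth(self):
        # data generated without interactions: the main-effects model should
        # have the lower AIC in the clear majority of replicates
        wins = 0
        n_rep = 20
        for seed in range(n_rep):
            cfg = SyntheticConfig(seed=100 + seed, n_subjects_per_group=60)
            records = generate_cohort(cfg, emit_timeseries=False).records
            fits = [
                fit_lmm(records, "avg_neg_conn", s)
                for s in (ModelSpec.model1(), ModelSpec.model3())
            ]
            best, _ = select_model(fits)
            wins += best.spec.name == "Model1"
        assert wins > n_rep / 2


class TestEdgewise:
    @pytest.fixture
    def edge_setup(self, rng):
        from negconn import ConnectivityMatrix, MaskRule, build_mask
        from negconn.cohort import toy_parcellation

        parc = toy_parcellation()
        z = np.full((parc.n_rois, parc.n_rois), -0.5)
        np.fill_diagonal(z, np.nan)
        mats = [ConnectivityMatrix(z=z.copy()) for _ in range(2)]
        mask = build_mask(mats, parc, rule=MaskRule("threshold", -0.35))
        cfg = SyntheticConfig(seed=8, n_subjects_per_group=40)
        records = generate_cohort(cfg, emit_timeseries=False).records
        edge_z = (
            records["avg_neg_conn"].to_numpy()[:, None]
            + rng.normal(0, 0.05, size=(len(records), mask.n_edges))
        )
        return parc, mask, records, edge_z

    def test_q_dominates_p_per_term(self, edge_setup):
        parc, mask, records, edge_z = edge_setup
        stats = edgewise_fit(edge_z, records, mask)
        assert (stats.table["qvalue"] >= stats.table["pvalue"] - 1e-12).all()
        for term in stats.table["term"].unique():
            sub = stats.for_term(term)
            np.testing.assert_allclose(
                sub["qvalue"], bh_fdr(sub["pvalue"].to_numpy()), atol=1e-12
            )

    def test_summed_t_matches_brute_force(self, edge_setup, rng):
        parc, mask, records, edge_z = edge_setup
        stats = edgewise_fit(edge_z, records, mask)
        for direction, sign in (("negative", -1), ("positive", 1)):
            out = summed_t_map(stats, "adhd", direction, parc.n_rois, p_cut=0.5)
            brute = np.zeros(parc.n_rois)
            sub = stats.for_term("adhd")
            for roi in range(parc.n_rois):
                for _, row in sub.iterrows():
                    if roi + 1 in (row["roi_i"], row["roi_j"]):
                        if row["pvalue"] < 0.5 and np.sign(row["tvalue"]) == sign:
                            brute[roi] += row["tvalue"]
            np.testing.assert_allclose(out, brute, atol=1e-12)

    def test_no_significant_edges_gives_zero_map(self, edge_setup):
        parc, mask, records, edge_z = edge_setup
        stats = edgewise_fit(edge_z, records, mask)
        out = summed_t_map(stats, "adhd", "negative", parc.n_rois, p_cut=1e-30)
        assert (out == 0).all()

    def test_unknown_term_rejected(self, edge_setup):
        parc, mask, records, edge_z = edge_setup
        stats = edgewise_fit(edge_z, records, mask)
        with pytest.raises(KeyError):
            summed_t_map(stats, "nonexistent", "negative", parc.n_rois)


class TestGenderBalancedPermutation:
    def test_full_sample_selection_equals_single_fit(self, small_records):
        adhd = small_records[small_records["group"] == "adhd"]
        select = adhd["sex"].value_counts().to_dict()
        mean_p, dist = gender_balanced_permutation(
            small_records, n_perm=1, select=select, seed=0
        )
        direct = fit_lmm(small_records, "avg_neg_conn", ModelSpec.model1())
        for term in direct.terms.index:
            assert mean_p[term] == pytest.approx(direct.terms.loc[term, "pvalue"], abs=1e-12)

    def test_seed_reproducibility(self, small_records):
        a, _ = gender_balanced_permutation(small_records, n_perm=10, seed=99)
        b, _ = gender_balanced_permutation(small_records, n_perm=10, seed=99)
        pd.testing.assert_series_equal(a, b)

    def test_infeasible_selection_names_shortfall(self, small_records):
        with pytest.raises(ValueError, match="only"):
            gender_balanced_permutation(
                small_records, n_perm=1, select={"F": 10**6}, seed=0
            )

    def test_balancing_weakens_sex_confounded_group_effect(self):
        # group effect entirely carried by the sex imbalance: after
        # balancing, the averaged group p must be larger than the naive one
        cfg = SyntheticConfig(
            seed=21,
            n_subjects_per_group=100,
            delta_group=0.0,
            delta_sex=-0.08,
            male_fraction={"control": 0.5, "adhd": 0.95},
        )
        records = generate_cohort(cfg, emit_timeseries=False).records
        # drop sex from the model so the imbalance can masquerade as group
        spec = ModelSpec(name="no_sex", base_terms=("adhd", "age_c", "mean_fd"))
        naive = fit_lmm(records, "avg_neg_conn", spec)
        mean_p, _ = gender_balanced_permutation(records, spec=spec, n_perm=30, seed=5)
        assert mean_p["adhd"] > naive.terms.loc["adhd", "pvalue"]


@pytest.fixture(scope="module")
def coupled_records():
    cfg = SyntheticConfig(seed=31, n_subjects_per_group=120)
    return generate_cohort(cfg, emit_timeseries=False).records


class TestBrainBehavior:
    def test_coupling_sign_recovered(self, coupled_records):
        # planted b_conn > 0: more negative connectivity -> higher d', i.e.
        # a negative regression coefficient of d' on the metric
        res = brain_behavior_fit(coupled_records, which_dprime="both")
        assert res.terms.loc["avg_neg_conn", "estimate"] < 0
        assert res.terms.loc["avg_neg_conn", "pvalue"] < 0.05

    def test_single_difficulty_signs(self, coupled_records):
        for cond in ("easy", "difficult"):
            res = brain_behavior_fit(coupled_records, which_dprime=cond)
            assert res.terms.loc["avg_neg_conn", "estimate"] < 0

    def test_null_coupling_not_detected(self):
        cfg = SyntheticConfig(seed=17, n_subjects_per_group=80, b_conn=0.0)
        records = generate_cohort(cfg, emit_timeseries=False).records
        res = brain_behavior_fit(records, which_dprime="both")
        assert res.terms.loc["avg_neg_conn", "pvalue"] > 0.01

    def test_equal_condition_slopes_give_null_interaction(self, coupled_records):
        res = brain_behavior_fit(coupled_records, which_dprime="both")
        # both conditions share the same planted slope
        assert res.terms.loc["avg_neg_conn:difficult", "pvalue"] > 0.01
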