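import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import f_oneway
from skbio import DistanceMatrix

from perigut.stratified_permanova import (
    DegenerateTermError,
    PermutationScheme,
    build_full_design,
    gower_center,
    permanova_test,
    permute_complete_design,
    pseudo_f,
    scheme_space_size,
)

from conftest import make_metadata


def euclidean_dm(x, ids=None):
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
    ids = ids or [f"s{i}" for i in range(len(x))]
    return DistanceMatrix(d, ids=ids)


def paired_metadata(n_subjects, ileo, sdd, missing_post=()):
    """Complete paired design over n_subjects with given subject-level factors."""
    rows = []
    for s in range(n_subjects):
        for tp in ("pre", "post"):
            if tp == "post" and s in missing_post:
                continue
            source = "ileostomy_effluent" if (tp == "post" and ileo[s] == "yes") else "faeces"
            rows.append((f"s{s}_{tp}", f"subj{s}", tp, ileo[s], sdd[s], source))
    return make_metadata(rows)


class TestGowerCenter:
    def test_zero_distances_give_zero_matrix(self):
        np.testing.assert_array_equal(gower_center(np.zeros((4, 4))), np.zeros((4, 4)))

    def test_rows_and_columns_sum_to_zero(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(6, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        G = gower_center(d)
        np.testing.assert_allclose(G.sum(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(G.sum(axis=1), 0, atol=1e-10)

    def test_trace_is_univariate_sum_of_squares(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        G = gower_center(euclidean_dm(x))
        assert np.trace(G) == pytest.approx(np.sum((x - x.mean()) ** 2))  # 5.0
        assert np.trace(G) == pytest.approx(5.0)


class TestPseudoF:
    def test_two_group_worked_case_matches_anova(self):
        # x = (0,1,2,3), groups {0,1} vs {2,3}: SSB=4, SSW=1, F=(4/1)/(1/2)=8
        dm = euclidean_dm([0.0, 1.0, 2.0, 3.0])
        design = pd.DataFrame(
            {"sample_id": dm.ids, "sdd": ["no", "no", "yes", "yes"]}
        )
        res = pseudo_f(dm, design, terms=("sdd",))
        t = res.term("sdd")
        assert t.ss == pytest.approx(4.0, abs=1e-8)
        assert res.residual_ss == pytest.approx(1.0, abs=1e-8)
        assert t.pseudo_f == pytest.approx(8.0, abs=1e-8)
        f_ref = f_oneway([0.0, 1.0], [2.0, 3.0]).statistic
        assert t.pseudo_f == pytest.approx(f_ref, abs=1e-8)

    def test_matches_classical_anova_on_random_univariate_data(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=10)
        groups = np.array(["yes"] * 5 + ["no"] * 5)
        design = pd.DataFrame({"sample_id": [f"s{i}" for i in range(10)], "ileostomy": groups})
        res = pseudo_f(euclidean_dm(x), design, terms=("ileostomy",))
        f_ref = f_oneway(x[:5], x[5:]).statistic
        assert res.term("ileostomy").pseudo_f == pytest.approx(f_ref, abs=1e-8)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=8)
        ids = [f"s{i}" for i in range(8)]
        labels = ["yes", "no"] * 4
        design = pd.DataFrame({"sample_id": ids, "sdd": labels})
        res_a = pseudo_f(euclidean_dm(x, ids), design, terms=("sdd",))
        order = rng.permutation(8)
        dm_b = euclidean_dm(x[order], [ids[i] for i in order])
        res_b = pseudo_f(dm_b, design, terms=("sdd",))
        assert res_a.term("sdd").pseudo_f == pytest.approx(res_b.term("sdd").pseudo_f, abs=1e-10)
        assert res_a.term("sdd").ss == pytest.approx(res_b.term("sdd").ss, abs=1e-10)

    def test_identical_groups_give_zero_r_squared(self):
        x = [0.0, 1.0, 0.0, 1.0]
        design = pd.DataFrame({"sample_id": [f"s{i}" for i in range(4)], "sdd": ["yes", "yes", "no", "no"]})
        res = pseudo_f(euclidean_dm(x), design, terms=("sdd",))
        assert np.isfinite(res.term("sdd").pseudo_f)
        assert res.term("sdd").r_squared == pytest.approx(0.0, abs=1e-10)

    def test_ss_additivity_and_r2_normalisation(self, small_cohort):
        from perigut.diversity import pairwise_weighted_unifrac

        dm = pairwise_weighted_unifrac(small_cohort.counts, small_cohort.tree)
        meta = small_cohort.metadata
        design = meta[["sample_id", "timepoint", "ileostomy", "sdd"]]
        res = pseudo_f(dm, design)
        ss_sum = sum(t.ss for t in res.terms) + res.residual_ss
        assert ss_sum == pytest.approx(res.total_ss, abs=1e-8)
        r2_sum = sum(t.r_squared for t in res.terms) + res.residual_ss / res.total_ss
        assert r2_sum == pytest.approx(1.0, abs=1e-10)

    def test_constant_term_raises(self):
        x = [0.0, 1.0, 2.0, 3.0]
        design = pd.DataFrame({"sample_id": [f"s{i}" for i in range(4)], "sdd": ["yes"] * 4})
        with pytest.raises(DegenerateTermError, match="sdd"):
            pseudo_f(euclidean_dm(x), design, terms=("sdd",))


class TestPermuteCompleteDesign:
    def _full(self):
        meta = paired_metadata(
            4, ileo=["yes", "yes", "no", "no"], sdd=["yes", "no", "yes", "no"], missing_post=(2,)
        )
        return build_full_design(meta)

    def test_identity_scheme_is_identity(self):
        full = self._full()
        out = permute_complete_design(full, PermutationScheme.identity(4))
        lhs = out.sort_values(["subject_id", "timepoint"]).reset_index(drop=True)
        rhs = full.sort_values(["subject_id", "timepoint"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(lhs, rhs)

    def test_one_pre_one_post_per_subject_after_any_scheme(self):
        full = self._full()
        rng = np.random.default_rng(0)
        for _ in range(25):
            out = permute_complete_design(full, PermutationScheme.draw(4, rng))
            counts = out.groupby(["subject_id", "timepoint"]).size().unstack()
            assert (counts == 1).all().all()
            cov = out.groupby("subject_id")[["ileostomy", "sdd"]].nunique()
            assert (cov == 1).all().all()

    def test_observed_flags_stay_with_cells(self):
        full = self._full()
        rng = np.random.default_rng(1)
        out = permute_complete_design(full, PermutationScheme.draw(4, rng))
        assert out["observed"].sum() == full["observed"].sum()
        assert set(out.loc[out["observed"], "sample_id"]) == set(
            full.loc[full["observed"], "sample_id"]
        )

    def test_scheme_space_size(self):
        assert scheme_space_size(4) == 384  # 4! * 2^4


class TestPermanovaTest:
    def _four_subject_setup(self, missing_post=()):
        meta = paired_metadata(
            4, ileo=["yes", "yes", "no", "no"], sdd=["yes", "no", "no", "yes"], missing_post=missing_post
        )
        rng = np.random.default_rng(7)
        x = rng.normal(size=len(meta))
        dm = euclidean_dm(x, list(meta["sample_id"]))
        return dm, build_full_design(meta), meta

    def test_exhaustive_matches_brute_force_via_public_ops(self):
        """Engine enumeration equals recomputing pseudo-F through the public
        permute-then-restrict route for every one of the 384 schemes."""
        dm, full, meta = self._four_subject_setup()
        res = permanova_test(dm, full, mode="exhaustive")
        assert res.n_permutations == 384

        f_obs = {t.name: t.pseudo_f for t in res.terms}
        exceed = {t.name: 0 for t in res.terms}
        for perm in itertools.permutations(range(4)):
            for mask in range(16):
                scheme = PermutationScheme(
                    flips=np.array([(mask >> b) & 1 for b in range(4)], dtype=bool),
                    subject_perm=np.array(perm),
                )
                permuted = permute_complete_design(full, scheme)
                obs = permuted[permuted["observed"]]
                design = obs[["sample_id", "timepoint", "ileostomy", "sdd"]]
                ref = pseudo_f(dm, design)
                for t in ref.terms:
                    if t.pseudo_f >= f_obs[t.name] - 1e-12:
                        exceed[t.name] += 1
        for t in res.terms:
            assert t.p_value == pytest.approx(exceed[t.name] / 384, abs=1e-12)

    def test_auto_mode_selects_exhaustive_for_tiny_designs(self):
        dm, full, _ = self._four_subject_setup()
        res = permanova_test(dm, full, mode="auto")
        assert res.method == "exhaustive"

    def test_monte_carlo_within_binomial_ci_of_exhaustive(self):
        dm, full, _ = self._four_subject_setup(missing_post=(3,))
        exact = permanova_test(dm, full, mode="exhaustive")
        mc = permanova_test(dm, full, mode="monte_carlo", n_permutations=10_000, seed=1)
        for name in ("timepoint", "ileostomy", "sdd"):
            p = exact.term(name).p_value
            half_width = 2.576 * np.sqrt(p * (1 - p) / 10_000) + 1 / 10_000
            assert abs(mc.term(name).p_value - p) <= half_width + 1e-12

    def test_p_value_never_zero(self):
        dm, full, _ = self._four_subject_setup()
        res_mc = permanova_test(dm, full, mode="monte_carlo", n_permutations=199, seed=0)
        res_ex = permanova_test(dm, full, mode="exhaustive")
        for res in (res_mc, res_ex):
            assert all(t.p_value > 0 for t in res.terms)

    def test_sample_order_invariance(self):
        dm, full, meta = self._four_subject_setup(missing_post=(1,))
        res_a = permanova_test(dm, full, n_permutations=299, seed=3, mode="monte_carlo")
        order = np.random.default_rng(0).permutation(len(dm.ids))
        ids_b = [dm.ids[i] for i in order]
        dm_b = DistanceMatrix(dm.data[np.ix_(order, order)], ids=ids_b)
        res_b = permanova_test(dm_b, full, n_permutations=299, seed=3, mode="monte_carlo")
        for name in ("timepoint", "ileostomy", "sdd"):
            assert res_a.term(name).pseudo_f == pytest.approx(res_b.term(name).pseudo_f, abs=1e-10)
            assert res_a.term(name).p_value == pytest.approx(res_b.term(name).p_value, abs=1e-12)

    def test_missing_cells_excluded_not_imputed(self):
        dm, full, meta = self._four_subject_setup(missing_post=(0, 2))
        assert full["observed"].sum() == len(dm.ids) == 6
        res = permanova_test(dm, full, mode="exhaustive")
        total_df = sum(t.df for t in res.terms) + res.residual_df
        assert total_df == 6 - 1

    def test_mismatched_samples_rejected(self):
        dm, full, _ = self._four_subject_setup()
        bad = full.copy()
        bad.loc[bad["sample_id"] == "s0_pre", "sample_id"] = "unknown"
        with pytest.raises(ValueError, match="differ"):
            permanova_test(dm, bad, mode="exhaustive")

    def test_constant_observed_term_raises(self):
        meta = paired_metadata(4, ileo=["yes"] * 4, sdd=["yes", "no", "yes", "no"])
        rng = np.random.default_rng(4)
        dm = euclidean_dm(rng.normal(size=len(meta)), list(meta["sample_id"]))
        with pytest.raises(DegenerateTermError, match="ileostomy"):
            permanova_test(dm, build_full_design(meta), mode="monte_carlo", n_permutations=49)

    def test_strong_time_effect_detected_with_correct_ordering(self):
        from perigut.diversity import pairwise_weighted_unifrac
        from perigut.synthetic_cohort import CohortConfig, generate_cohort

        cohort = generate_cohort(
            CohortConfig(n_subjects=60, n_taxa=40, depth=1000, seed=13, p_missing_pre=0.1, p_missing_post=0.2)
        )
        dm = pairwise_weighted_unifrac(cohort.counts, cohort.tree)
        res = permanova_test(
            dm, build_full_design(cohort.metadata), n_permutations=999, seed=0, mode="monte_carlo"
        )
        r2 = {t.name: t.r_squared for t in res.terms}
        assert res.term("timepoint").p_value <= 0.001
        assert r2["timepoint"] > r2["ileostomy"] > r2["sdd"]
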