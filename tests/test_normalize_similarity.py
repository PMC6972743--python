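"""Control-median normalization, Grubbs exclusion, similarity and ranking."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

import sigscreen as ss
from sigscreen.errors import GeneNotFoundError, ProcessingError
from sigscreen.normalize import (
    OUTLIER_FLAG,
    SignatureVector,
    grubbs_critical_value,
    signature_of_gene,
)
from sigscreen.pipeline import PipelineConfig
from sigscreen.simulate import noise_free

from conftest import make_control_dataset


def grubbs_reference(values: np.ndarray, alpha: float) -> int | None:
    """Independent oracle: p-value route of the two-sided Grubbs test.

    Converts the max standardized deviation G into its t statistic
    ``t = sqrt((n-2) G^2 / ((n-1)^2/n - G^2))`` and declares an outlier iff
    the Bonferroni-corrected two-sided tail probability ``2n * P(T > t)``
    falls below alpha.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    sd = x.std(ddof=1)
    if sd == 0:
        return None
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    g = dev[idx] / sd
    denom = (n - 1) ** 2 / n - g**2
    if denom <= 0:
        p = 0.0
    else:
        t = np.sqrt((n - 2) * g**2 / denom)
        p = 2 * n * sps.t.sf(t, n - 2)
    return idx if p < alpha else None


class TestControlMedianNormalize:
    def test_worked_example(self):
        """With a siCont median of 2.0 for a probe, a sample value of 1.0
        normalizes to log2(0.5) = -1."""
        X = np.full((5, 6), 2.0)
        ds = make_control_dataset(X, role="sicont", stage=ss.Stage.normalized_log2)
        df = ds.frame.copy()
        extra = df.iloc[[0]].copy()
        extra["role"] = "sample"
        extra["column"] = 10
        extra["gene_symbol"] = "GX"
        for p in ds.signature_names:
            extra[p] = 1.0
        df = pd.concat([df, extra], ignore_index=True)
        geo = ss.ScreenDataset(frame=df, panel=ds.panel, stage=ss.Stage.geomean)
        out = ss.control_median_normalize(geo, scope="plate")
        sample = out.frame[out.frame["role"] == "sample"]
        assert np.allclose(sample[ds.signature_names], -1.0)
        assert out.stage is ss.Stage.normalized_log2

    def test_sicont_median_is_zero_by_construction(self, demo_result):
        norm = demo_result.normalized
        sic = norm.frame[norm.frame["role"] == "sicont"]
        med = sic.groupby(["plate", "replicate"])[norm.signature_names].median()
        assert np.abs(med.to_numpy()).max() < 1e-9

    def test_matches_direct_formula(self, demo_sim, demo_result):
        geo = demo_result.geomean
        out = ss.control_median_normalize(geo, scope="plate")
        df = geo.frame
        sic = df[df["role"] == "sicont"]
        for probe in geo.signature_names:
            med = sic.groupby(["plate", "replicate"])[probe].median()
            ref = med.reindex(pd.MultiIndex.from_frame(df[["plate", "replicate"]]))
            expected = np.log2(df[probe].to_numpy() / ref.to_numpy())
            assert np.abs(out.frame[probe].to_numpy() - expected).max() < 1e-12

    def test_scope_unit_without_sicont_errors(self, demo_result):
        geo = demo_result.geomean
        df = geo.frame[geo.frame["role"] != "sicont"].reset_index(drop=True)
        broken = geo.with_frame(df)
        with pytest.raises(ProcessingError):
            ss.control_median_normalize(broken, scope="plate")

    def test_housekeeping_carried_through_unchanged(self, demo_result):
        geo = demo_result.geomean
        out = ss.control_median_normalize(geo, scope="plate")
        for hk in geo.housekeeping_names:
            assert np.allclose(out.frame[hk], geo.frame[hk])


class TestGrubbsStep:
    def test_constant_vector_has_no_outlier(self):
        assert ss.grubbs_step(np.full(10, 3.14)) is None

    def test_planted_extreme_value_is_found(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 21)
        x[13] = 100.0
        assert ss.grubbs_step(x, alpha=0.05) == 13

    def test_requires_n_at_least_3(self):
        with pytest.raises(ProcessingError):
            ss.grubbs_step(np.array([1.0, 2.0]))

    def test_agrees_with_pvalue_route_oracle(self):
        """Decision-level equivalence with an independent implementation on
        1,000 seeded random vectors, n in [6, 30], alpha = 0.05; a fraction
        get a planted outlier so both branches are exercised."""
        rng = np.random.default_rng(99)
        mismatches = 0
        for _ in range(1000):
            n = int(rng.integers(6, 31))
            x = rng.normal(0, 1, n)
            if rng.random() < 0.5:
                x[int(rng.integers(n))] += rng.uniform(2, 8)
            if ss.grubbs_step(x, 0.05) != grubbs_reference(x, 0.05):
                mismatches += 1
        assert mismatches == 0

    def test_critical_value_textbook_anchor(self):
        # G_crit(10, 0.05) two-sided is 2.290 to three decimals
        assert grubbs_critical_value(10, 0.05) == pytest.approx(2.290, abs=5e-4)


class TestExcludeControlOutliers:
    def test_group_at_min_n_cannot_lose_wells(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 0.1, (6, 6))
        X[2] += 50.0  # would be an outlier if removal were allowed
        ds = make_control_dataset(X, role="sicont")
        out, decisions = ss.exclude_control_outliers(
            ds, "sicont", group_scope="plate", min_n=6
        )
        assert not out.has_flag(OUTLIER_FLAG).any()
        assert decisions[0].n_final == 6

    def test_planted_far_outlier_in_batch_group_is_flagged(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 0.3, (40, 6))
        X[7] += 25.0
        ds = make_control_dataset(X, role="si_target")
        out, decisions = ss.exclude_control_outliers(
            ds, "si_target", group_scope="batch", min_n=20
        )
        flagged = out.frame[out.has_flag(OUTLIER_FLAG)]
        assert list(flagged["gene_symbol"]) == ["W7"]
        assert decisions[0].n_final >= 20

    def test_identical_signatures_yield_no_removals(self):
        X = np.ones((12, 6))
        ds = make_control_dataset(X, role="sicont")
        out, _ = ss.exclude_control_outliers(ds, "sicont", group_scope="plate", min_n=6)
        assert not out.has_flag(OUTLIER_FLAG).any()

    def test_undersized_group_skipped_with_warning(self):
        X = np.random.default_rng(3).normal(0, 1, (4, 6))
        ds = make_control_dataset(X, role="sicont")
        with pytest.warns(UserWarning, match="skipped"):
            out, decisions = ss.exclude_control_outliers(
                ds, "sicont", group_scope="plate", min_n=6
            )
        assert decisions[0].skipped
        assert not out.has_flag(OUTLIER_FLAG).any()

    def test_min_n_floor_never_violated_across_seeded_groups(self):
        """Across 100 seeded groups of varying size and floor, iterative
        removal never leaves fewer than min_n wells."""
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(6, 41))
            min_n = int(rng.integers(3, 11))
            X = rng.normal(0, 1, (n, 6))
            k = int(rng.integers(0, 4))  # plant up to 3 wild wells
            for i in rng.choice(n, size=min(k, n), replace=False):
                X[i] += rng.uniform(5, 50)
            ds = make_control_dataset(X, role="sicont")
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                out, decisions = ss.exclude_control_outliers(
                    ds, "sicont", group_scope="plate", min_n=min_n
                )
            d = decisions[0]
            if d.skipped:  # undersized at start: nothing may be removed
                assert not d.removed
            else:
                assert d.n_final >= min_n
            assert int(out.has_flag(OUTLIER_FLAG).sum()) == len(d.removed)

    def test_removal_sequence_deterministic(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 0.5, (15, 6))
        X[3] += 10
        X[9] += 7
        ds = make_control_dataset(X, role="sicont")
        _, d1 = ss.exclude_control_outliers(ds, "sicont", "plate", min_n=6)
        _, d2 = ss.exclude_control_outliers(ds, "sicont", "plate", min_n=6)
        assert d1[0].removed == d2[0].removed
        assert d1[0].removed_scalars == pytest.approx(d2[0].removed_scalars)


class TestTargetSignature:
    def test_single_well_is_identity(self):
        X = np.array([[1.0, -2.0, 0.5, 0.0, 3.0, -1.0]])
        ds = make_control_dataset(X, role="si_target")
        t = ss.compute_target_signature(ds, batch_id=1)
        assert t.values == pytest.approx(tuple(X[0]))

    def test_mean_of_two_wells(self):
        X = np.array([[0, 0, 0, 0, 0, 2.0], [2.0, 0, 0, 0, 0, 0]])
        ds = make_control_dataset(X, role="si_target")
        t = ss.compute_target_signature(ds, batch_id=1)
        assert t.values == pytest.approx((1, 0, 0, 0, 0, 1))

    def test_flagged_outliers_excluded_from_mean(self):
        X = np.vstack([np.zeros((5, 6)), np.full((1, 6), 100.0)])
        ds = make_control_dataset(X, role="si_target")
        mask = pd.Series(False, index=ds.frame.index)
        mask.iloc[5] = True
        ds.add_flag(mask, OUTLIER_FLAG)
        t = ss.compute_target_signature(ds, batch_id=1)
        assert t.values == pytest.approx((0,) * 6)

    def test_insufficient_wells_error(self):
        X = np.zeros((3, 6))
        ds = make_control_dataset(X, role="si_target")
        with pytest.raises(ProcessingError):
            ss.compute_target_signature(ds, batch_id=1, min_n=20)


class TestMetrics:
    def test_pythagorean_distance(self):
        assert ss.euclidean_distance([0.0, 0.0], [3.0, 4.0]) == pytest.approx(5.0)

    def test_distance_of_identical_vectors_is_zero(self):
        v = SignatureVector((1.0, 2.0, 3.0, 4.0, 5.0, 6.0), ("a",) * 6)
        assert ss.euclidean_distance(v, v) == 0.0

    def test_metrics_match_direct_formula_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            a, b = rng.normal(0, 1, (2, 6))
            d = ss.euclidean_distance(a, b)
            assert abs(d - np.sqrt(((a - b) ** 2).sum())) < 1e-12
            r = ss.pearson_correlation(a, b)
            am, bm = a - a.mean(), b - b.mean()
            ref = (am @ bm) / np.sqrt((am @ am) * (bm @ bm))
            assert abs(r - ref) < 1e-12

    @given(
        st.lists(st.floats(-50, 50), min_size=6, max_size=6).filter(
            lambda v: max(v) - min(v) > 1e-6
        ),
        st.floats(0.1, 10),
        st.floats(-5, 5),
    )
    def test_pearson_affine_invariance(self, vals, slope, intercept):
        a = np.array(vals)
        assert ss.pearson_correlation(a, slope * a + intercept) == pytest.approx(1.0)
        assert ss.pearson_correlation(a, -slope * a + intercept) == pytest.approx(-1.0)

    def test_constant_vector_gives_nan_not_zero(self):
        r = ss.pearson_correlation([1.0] * 6, [1, 2, 3, 4, 5, 6])
        assert np.isnan(r)

    def test_length_mismatch_raises(self):
        with pytest.raises(ProcessingError):
            ss.euclidean_distance([1.0], [1.0, 2.0])

    @given(st.integers(0, 10_000))
    def test_triangle_inequality_on_random_triples(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = rng.normal(0, 3, (3, 6))
        dab = ss.euclidean_distance(a, b)
        dbc = ss.euclidean_distance(b, c)
        dac = ss.euclidean_distance(a, c)
        assert dac <= dab + dbc + 1e-12


class TestScoreScreen:
    def test_gene_matching_target_ranks_first(self):
        rng = np.random.default_rng(6)
        X = rng.normal(0, 1, (20, 6))
        target = np.array([1.0, -1.0, 2.0, -2.0, 0.5, -0.5])
        X[11] = target
        ds = make_control_dataset(X, role="sample")
        res = ss.score_screen(ds, {1: target}, similarity_scope="batch")
        best = res[res["gene_symbol"] == "W11"].iloc[0]
        assert best["dist_of_avg"] == pytest.approx(0.0)
        assert best["corr_of_avg"] == pytest.approx(1.0)
        assert best["rank_distance"] == 1
        assert best["rank_correlation"] == 1

    def test_noise_free_planted_genes_attain_perfect_correlation(self):
        cfg = noise_free(ss.make_default_config("tiny", seed=8))
        ds, gt = ss.simulate_screen(cfg)
        res = ss.run_pipeline(ds)
        planted = res.similarity[res.similarity["gene_symbol"].isin(gt.planted_symbols)]
        assert np.allclose(planted["corr_of_avg"], 1.0, atol=1e-9)
        assert np.allclose(planted["dist_of_avg"], 0.0, atol=1e-9)

    def test_matches_independent_recomputation_for_sampled_genes(self, demo_result):
        """Spot-check oracle: metrics recomputed probe-by-probe from the
        averaged normalized table for 10 genes."""
        res = demo_result
        sim = res.similarity
        avg = res.normalized_avg.frame
        rng = np.random.default_rng(0)
        genes = rng.choice(sim["gene_symbol"], size=10, replace=False)
        sig = res.normalized_avg.signature_names
        for g in genes:
            row = sim[sim["gene_symbol"] == g].iloc[0]
            well = avg[(avg["gene_symbol"] == g) & (avg["role"] == "sample")]
            x = well[sig].to_numpy()[0]
            t = np.asarray(res.targets[int(row["batch"])].values)
            assert row["dist_of_avg"] == pytest.approx(np.linalg.norm(x - t), abs=1e-10)
            xm, tm = x - x.mean(), t - t.mean()
            ref = (xm @ tm) / np.sqrt((xm @ xm) * (tm @ tm))
            assert row["corr_of_avg"] == pytest.approx(ref, abs=1e-10)

    def test_rank_ties_broken_lexicographically(self):
        X = np.tile(np.array([1.0, -1.0, 0.5, -0.5, 2.0, -2.0]), (3, 1))
        ds = make_control_dataset(X, role="sample")
        res = ss.score_screen(ds, {1: X[0]}, similarity_scope="batch")
        ordered = res.sort_values("rank_distance")["gene_symbol"].tolist()
        assert ordered == sorted(ordered)

    def test_missing_target_errors(self):
        ds = make_control_dataset(np.zeros((3, 6)), role="sample")
        with pytest.raises(ProcessingError, match="target"):
            ss.score_screen(ds, {2: np.zeros(6)}, similarity_scope="batch")

    def test_per_replicate_and_averaged_columns_present(self, demo_result):
        sim = demo_result.similarity
        for rep in ("1", "2", "3"):
            assert f"dist_rep{rep}" in sim and f"corr_rep{rep}" in sim
        assert {"dist_avg_of_metrics", "corr_avg_of_metrics",
                "dist_of_avg", "corr_of_avg"} <= set(sim.columns)
        assert sim["dist_of_avg"].min() >= 0
        assert sim["corr_of_avg"].dropna().between(-1, 1).all()


@pytest.fixture(scope="module")
def screen_scope_result():
    cfg = ss.make_default_config("tiny", seed=9)
    ds, gt = ss.simulate_screen(cfg)
    res = ss.run_pipeline(
        ds, PipelineConfig(normalization_scope="screen", similarity_scope="screen")
    )
    return res, gt


class TestPairwiseGeneSimilarity:
    def test_gene_vs_itself(self, screen_scope_result):
        res, gt = screen_scope_result
        g = gt.genes["gene_symbol"].iloc[0]
        d, r = ss.pairwise_gene_similarity(res.normalized_avg, g, g)
        assert d == pytest.approx(0.0)
        assert r == pytest.approx(1.0)

    def test_symmetry(self, screen_scope_result):
        res, gt = screen_scope_result
        a, b = gt.genes["gene_symbol"].iloc[:2]
        assert ss.pairwise_gene_similarity(res.normalized_avg, a, b) == pytest.approx(
            ss.pairwise_gene_similarity(res.normalized_avg, b, a)
        )

    def test_identical_planted_genes_noise_free(self):
        cfg = noise_free(ss.make_default_config("tiny", seed=10))
        ds, gt = ss.simulate_screen(cfg)
        res = ss.run_pipeline(
            ds, PipelineConfig(normalization_scope="screen", similarity_scope="screen")
        )
        p1, p2 = gt.planted_symbols[:2]
        d, r = ss.pairwise_gene_similarity(res.normalized_avg, p1, p2)
        assert d == pytest.approx(0.0, abs=1e-9)
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_unknown_gene_errors(self, screen_scope_result):
        res, _ = screen_scope_result
        with pytest.raises(GeneNotFoundError):
            signature_of_gene(res.normalized_avg, "NOPE")
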