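"""Region filtering, normalization, panel z-scores, DMR discovery and the
HBD-derived cutoff."""

import numpy as np
import pandas as pd
import pytest

from melanoliq import SimulationConfig
from melanoliq.exceptions import InsufficientPanelError, MelanoliqError
from melanoliq.methylation import (
    HBD,
    PATIENT,
    DMRFinder,
    MethylationScorer,
    RegionCountMatrix,
    call_altered,
    filter_regions,
    find_dmrs,
    genome_wide_score,
    hbd_cutoff,
    lpnpi_qc,
    melanoma_score,
    moderated_ttest,
    normalize_counts,
    pca_top_variable,
    select_high_ctdna,
)
from melanoliq.simulate import simulate_methylation


def toy_matrix(counts: np.ndarray, n_hbd: int) -> RegionCountMatrix:
    n_regions, n_samples = counts.shape
    ids = [f"r{i}" for i in range(n_regions)]
    samples = [f"h{i}" if i < n_hbd else f"p{i}" for i in range(n_samples)]
    regions = pd.DataFrame(
        {"chrom": [(i % 22) + 1 for i in range(n_regions)],
         "start": np.arange(n_regions) * 100,
         "end": np.arange(n_regions) * 100 + 100},
        index=pd.Index(ids, name="region_id"),
    )
    groups = {s: (HBD if s.startswith("h") else PATIENT) for s in samples}
    return RegionCountMatrix(
        regions=regions,
        counts=pd.DataFrame(counts, index=ids, columns=samples),
        groups=groups,
    )


@pytest.mark.parametrize(
    "passing,expected", [(400_000, True), (399_999, False), (1_900_000, True)]
)
def test_lpnpi_qc_boundary(passing, expected):
    assert lpnpi_qc(passing) is expected


class TestFilterRegions:
    def test_completeness_rule(self):
        counts = np.ones((4, 8), dtype=int)
        counts[2, 5:] = 0  # region r2 has data in 5/8 = 62.5% of samples
        m = filter_regions(toy_matrix(counts, n_hbd=3))
        assert list(m.counts.index) == ["r0", "r1", "r3"]

    def test_exactly_75_percent_retained(self):
        counts = np.ones((2, 8), dtype=int)
        counts[1, 6:] = 0  # 6/8 = 75%, inclusive
        m = filter_regions(toy_matrix(counts, n_hbd=3))
        assert list(m.counts.index) == ["r0", "r1"]

    def test_all_complete_identity(self):
        counts = np.arange(1, 33).reshape(4, 8)
        m0 = toy_matrix(counts, n_hbd=3)
        m1 = filter_regions(m0)
        pd.testing.assert_frame_equal(m0.counts, m1.counts)

    def test_hbd_requirement(self):
        counts = np.ones((3, 8), dtype=int)
        counts[1, 0] = 0  # missing in one HBD but present in 7/8 samples
        m = filter_regions(toy_matrix(counts, n_hbd=3))
        assert "r1" not in m.counts.index
        m2 = filter_regions(toy_matrix(counts, n_hbd=3), require_all_hbds=False)
        assert "r1" in m2.counts.index

    def test_nothing_left_is_an_error(self):
        counts = np.zeros((3, 8), dtype=int)
        counts[:, 0] = 1
        with pytest.raises(MelanoliqError):
            filter_regions(toy_matrix(counts, n_hbd=3))


class TestNormalize:
    def test_scale_invariance(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        norm = normalize_counts(counts)
        np.testing.assert_allclose(norm["a"], norm["b"])

    def test_zero_maps_to_zero_and_cpm_unit(self):
        counts = pd.DataFrame({"a": [0, 1, 999_999]})
        norm = normalize_counts(counts)
        assert norm.loc[0, "a"] == 0.0
        # one read in a one-million-read library is 1 CPM -> log2(2) = 1
        assert norm.loc[1, "a"] == pytest.approx(1.0)


class TestRegionZscores:
    def make_scorer(self):
        X = pd.DataFrame(
            {"r0": [1.0, 2.0, 3.0], "r1": [5.0, 5.0, 5.0], "r2": [2.0, 4.0, 6.0]},
            index=["h0", "h1", "h2"],
        )
        return MethylationScorer().fit(X)

    def test_definition(self):
        scorer = self.make_scorer()
        s = pd.DataFrame({"r0": [2.0], "r2": [4.0 + 2 * 2.0]}, index=["new"])
        s.insert(1, "r1", 6.0)
        z = scorer.transform(s[["r0", "r1", "r2"]])
        assert z.loc["new", "r0"] == pytest.approx(0.0)
        assert z.loc["new", "r2"] == pytest.approx(2.0)
        assert "r1" not in z.columns  # zero-SD region excluded

    def test_loo_inflates_extreme_member(self):
        scorer = self.make_scorer()
        member = pd.DataFrame({"r0": [3.0], "r1": [5.0], "r2": [6.0]}, index=["h2"])
        alias = member.rename(index={"h2": "x"})
        z_loo = scorer.transform(member)
        z_full = scorer.transform(alias)
        assert abs(z_loo.loc["h2", "r0"]) > abs(z_full.loc["x", "r0"])

    def test_degenerate_panel(self):
        X = pd.DataFrame({"r0": [1.0, 1.0, 1.0]}, index=["h0", "h1", "h2"])
        with pytest.raises(InsufficientPanelError):
            MethylationScorer().fit(X)


def test_score_sums():
    z = pd.Series({"r0": 0.0, "r1": 1.0, "r2": 2.0})
    assert genome_wide_score(z) == 5.0
    assert genome_wide_score(pd.Series(dtype=float)) == 0.0
    assert melanoma_score(pd.Series({"a": 2.0, "b": -2.0, "c": 1.0}), ["a", "b", "c"]) == 9.0
    with pytest.warns(UserWarning):
        assert melanoma_score(pd.Series({"a": 2.0}), ["a", "missing"]) == 4.0


def test_select_high_ctdna():
    scores = pd.Series({"p1": 2.9, "p2": 3.0, "p3": 11.0})
    assert select_high_ctdna(scores) == ["p2", "p3"]
    with pytest.raises(MelanoliqError):
        select_high_ctdna(pd.Series({"p1": 1.0, "p2": 2.0}))


class TestModeratedT:
    def test_matches_limma_oracle(self):
        """Frozen reference values from the Bioconductor limma eBayes fit on
        the identical matrix (5 vs 4 samples, 60 normal regions)."""
        rng = np.random.default_rng(7)
        a = rng.normal(5.0, 1.0, (5, 60))
        b = rng.normal(5.4, 1.0, (4, 60))
        lfc, t, p, d0, s0 = moderated_ttest(a, b)
        assert d0 == pytest.approx(101.1822562638, rel=1e-6)
        assert s0 == pytest.approx(0.8844062277, rel=1e-6)
        np.testing.assert_allclose(
            t[:6],
            [1.8320394813, 1.0765270963, 0.6866065352,
             2.2256390332, 0.7922322156, 1.3232444988],
            rtol=1e-6,
        )
        np.testing.assert_allclose(
            p[:6],
            [0.0696965363, 0.2840864430, 0.4937997953,
             0.0281124029, 0.4299591010, 0.1885439765],
            rtol=1e-6,
        )

    def test_zero_within_group_variance_is_finite(self, rng):
        """Shrinkage keeps a zero-variance region's t finite and positive."""
        a = np.column_stack([np.array([1.0, 1.0, 1.0])] + [rng.normal(5, 1, 3) for _ in range(30)])
        b = np.column_stack([np.array([5.0, 5.0, 5.0])] + [rng.normal(5, 1, 3) for _ in range(30)])
        _, t, p, _, _ = moderated_ttest(a, b)
        assert np.isfinite(t[0]) and t[0] > 0
        assert p[0] < 0.05

    def test_ordinary_t_fallback_on_degenerate_ensemble(self):
        a = np.ones((3, 5))
        b = np.ones((3, 5)) * 2
        with pytest.warns(UserWarning, match="degenerate"):
            _, t, p, d0, _ = moderated_ttest(a, b)
        assert d0 == 0.0


class TestDMRFinder:
    def test_null_generator_yields_no_dmrs(self, rng):
        cfg = SimulationConfig(seed=33, n_patients=6, dmr_effect=1.0,
                               n_regions=2_000, n_true_dmrs=100)
        mat, _ = simulate_methylation(cfg, np.full(6, 0.4), rng)
        norm = normalize_counts(filter_regions(mat).counts)
        stats = find_dmrs(norm, mat.hbd_ids, mat.patient_ids)
        assert len(stats) == 0

    def test_spiked_dmrs_recovered(self, rng):
        cfg = SimulationConfig(seed=34, n_patients=7)
        mat, true_dmrs = simulate_methylation(cfg, np.random.default_rng(34).uniform(0.3, 0.5, 7), rng)
        fl = filter_regions(mat)
        stats = find_dmrs(normalize_counts(fl.counts), fl.hbd_ids, fl.patient_ids)
        called = set(stats.index)
        assert len(called & set(true_dmrs)) >= 0.8 * len(true_dmrs)
        assert (stats["q"] < 0.1).all()
        assert (stats.loc[stats.index.isin(true_dmrs), "lfc"] > 0).all()

    def test_group_size_requirement(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(4, 10)))
        with pytest.raises(InsufficientPanelError):
            DMRFinder().fit(X, [HBD, HBD, PATIENT, PATIENT])


class TestCutoff:
    def test_zero_sd(self):
        assert hbd_cutoff([4.0] * 9) == 4.0

    def test_closed_form(self):
        # mean 5, SD 2.7386, n=9, t_{0.975,8} = 2.306 -> 7.105
        assert hbd_cutoff(range(1, 10)) == pytest.approx(7.1051, abs=2e-4)

    def test_scale_equivariance(self):
        scores = [1.0, 2.5, 3.0, 4.5, 8.0]
        assert hbd_cutoff([2 * s for s in scores]) == pytest.approx(2 * hbd_cutoff(scores))

    def test_prediction_mode_is_wider(self):
        scores = list(range(1, 10))
        assert hbd_cutoff(scores, mode="prediction") > hbd_cutoff(scores, mode="ci_mean")

    def test_loo_self_classification_under_prediction_cutoff(self):
        """A prediction-interval cutoff fit on leave-one-out HBD scores
        flags at most 1 of 9 healthy donors on null data (median over reps).
        The narrower CI-of-the-mean cutoff flags ~2/9 by construction."""
        counts = []
        for seed in range(15):
            cfg = SimulationConfig(seed=seed, n_patients=3, n_regions=1_000,
                                   n_true_dmrs=50)
            rng = np.random.default_rng(seed)
            mat, true = simulate_methylation(cfg, np.zeros(3), rng)
            norm = normalize_counts(filter_regions(mat).counts)
            sc = MethylationScorer().fit(norm[mat.hbd_ids].T)
            s = sc.score_samples(norm[mat.hbd_ids].T, dmr_regions=true)["dmr_score"]
            counts.append(int((s > hbd_cutoff(s, mode="prediction")).sum()))
        assert np.median(counts) <= 1

    def test_strict_altered_call(self):
        assert call_altered(5.0, 5.0) is False
        assert call_altered(5.0 + 1e-9, 5.0) is True


class TestPCA:
    def test_rank_one_matrix(self):
        v = np.arange(1.0, 9.0)
        norm = pd.DataFrame(np.outer(np.array([1.0, 2.0, 3.0, 0.5]), v),
                            index=[f"r{i}" for i in range(4)],
                            columns=[f"s{i}" for i in range(8)])
        coords, evr = pca_top_variable(norm, fraction=1.0, n_components=2)
        assert evr[0] == pytest.approx(1.0, abs=1e-9)

    def test_uniform_scaling_scales_distances(self, rng):
        norm = pd.DataFrame(rng.normal(size=(30, 10)))
        c1, _ = pca_top_variable(norm, fraction=0.5, n_components=2)
        c2, _ = pca_top_variable(norm * 3.0, fraction=0.5, n_components=2)
        d1 = np.linalg.norm(c1.iloc[0] - c1.iloc[1])
        d2 = np.linalg.norm(c2.iloc[0] - c2.iloc[1])
        assert d2 == pytest.approx(3.0 * d1, rel=1e-9)

    def test_tumor_fraction_separates_groups(self, rng):
        cfg = SimulationConfig(seed=40, n_patients=12, n_regions=2_000, n_true_dmrs=150)
        tfs = np.array([0.0] * 6 + [0.35] * 6)
        mat, _ = simulate_methylation(cfg, tfs, rng)
        norm = normalize_counts(filter_regions(mat).counts)
        coords, _ = pca_top_variable(norm)
        xy = coords[["PC1", "PC2"]].to_numpy()
        null_idx = [i for i, s in enumerate(coords.index)
                    if s.startswith("HBD") or s in {f"patient_{j + 1:02d}" for j in range(6)}]
        high_idx = [i for i in range(len(coords)) if i not in null_idx]
        within = np.mean([np.linalg.norm(xy[i] - xy[j]) for i in null_idx for j in null_idx if i < j])
        between = np.mean([np.linalg.norm(xy[i] - xy[j]) for i in null_idx for j in high_idx])
        assert between > within

    def test_constant_matrix_error(self):
        norm = pd.DataFrame(np.ones((5, 4)))
        with pytest.raises(MelanoliqError):
            pca_top_variable(norm)
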