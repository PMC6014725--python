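"""FWHM fitting, morphometry, persistence, clustering, rank-sum test."""

import itertools

import numpy as np
import pytest

import stedspine as ss
from stedspine import morpho
from stedspine.morpho import (
    PERSISTENT,
    TRANSIENT,
    LineProfile,
    fit_lorentzian,
    lorentzian,
)
from stedspine.scene import TurnoverParams

from conftest import make_spine


class TestLineProfile:
    def test_uniform_image_gives_constant_profile(self):
        img = np.full((32, 32), 7.0)
        prof = ss.extract_line_profile(img, (16, 2), (16, 28), pixel_size_nm=10)
        assert np.allclose(prof.intensities, 7.0)

    def test_out_of_bounds_rejected(self):
        img = np.zeros((16, 16))
        with pytest.raises(ValueError):
            ss.extract_line_profile(img, (8, -2), (8, 10))

    def test_too_short_segment_rejected(self):
        img = np.zeros((16, 16))
        with pytest.raises(ValueError):
            ss.extract_line_profile(img, (8, 5), (8, 7))

    def test_lorentzian_ridge_cross_section(self):
        """Sampling across a synthetic Lorentzian ridge reproduces the
        analytic cross-section within interpolation tolerance."""
        gamma_px = 6.0
        cols = np.arange(64, dtype=float)
        img = np.tile(1.0 / ((cols - 32.0) ** 2 / gamma_px**2 + 1.0), (64, 1))
        prof = ss.extract_line_profile(img, (32, 2), (32, 62), pixel_size_nm=5)
        x_px = prof.positions / 5.0 + 2.0
        expected = 1.0 / ((x_px - 32.0) ** 2 / gamma_px**2 + 1.0)
        assert np.max(np.abs(prof.intensities - expected)) < 0.01

    def test_profile_symmetric_across_rendered_neck(self, sted):
        sp = make_spine(x=3.0)
        scene = ss.DendriteScene(0.35, 6.0, 0, [sp], "d0")
        stack = ss.render_stack(scene, sted, noiseless=True)
        zi = stack.shape[0] // 2
        # profile across the neck (along x) at the neck's mid-height in y
        _, yi, xi = stack.nm_to_index(0.0, 700.0, 3000.0)
        prof = ss.extract_line_profile(stack.data[zi], (yi, xi - 15),
                                       (yi, xi + 15), pixel_size_nm=20)
        y = prof.intensities
        assert np.max(np.abs(y - y[::-1])) < 0.05 * y.max()


class TestLorentzianFit:
    def test_exact_profile_recovered_to_float_precision(self):
        x = np.linspace(0, 600, 121)
        y = lorentzian(x, 5.0, 80.0, 300.0, 73.5)
        fit = fit_lorentzian(LineProfile(x, y))
        assert fit.fwhm == pytest.approx(147.0, abs=1e-6)
        assert fit.center == pytest.approx(300.0, abs=1e-6)
        assert not fit.flagged

    def test_affine_intensity_invariance(self):
        x = np.linspace(0, 600, 121)
        y = lorentzian(x, 2.0, 50.0, 290.0, 60.0)
        f1 = fit_lorentzian(LineProfile(x, y))
        f2 = fit_lorentzian(LineProfile(x, 3.5 * y + 11.0))
        assert f1.fwhm == pytest.approx(f2.fwhm, rel=1e-9)

    def test_gaussian_input_close_to_crossing_oracle(self):
        """Model mismatch on a Gaussian profile stays within 5% of the
        numeric half-max-crossing width."""
        fwhm = 325.0
        sig = fwhm / (2 * np.sqrt(2 * np.log(2)))
        x = np.linspace(-650, 650, 261)  # +-2 FWHM window
        y = np.exp(-(x**2) / (2 * sig**2))
        fit = fit_lorentzian(LineProfile(x + 650, y))
        # crossing oracle on the same samples
        half = y.max() / 2
        above = np.flatnonzero(y >= half)
        crossing = x[above[-1]] - x[above[0]]
        assert fit.fwhm == pytest.approx(crossing, rel=0.05)

    def test_flat_profile_flagged(self):
        x = np.linspace(0, 100, 21)
        fit = fit_lorentzian(LineProfile(x, np.ones_like(x)))
        assert fit.flagged


class TestMeasureSpine:
    def test_sphere_volume_convention(self):
        rec = ss.measure_spine(make_spine(head=0.36))
        assert rec.head_vol_um3 == pytest.approx(np.pi / 6 * 0.36**3)
        assert rec.head_vol_um3 == pytest.approx(0.0244, abs=5e-4)

    def test_head_neck_ratio(self):
        rec = ss.measure_spine(make_spine(head=0.36, neck=0.15))
        assert rec.head_neck_ratio == pytest.approx(2.4)

    def test_undetected_spine_flagged_in_image_mode(self):
        rec = ss.measure_spine(make_spine(azimuth=0.0), mode="image",
                               detected=False)
        assert rec.flagged and np.isnan(rec.neck_fwhm_nm)

    def test_image_mode_neck_fwhm_matches_convolution_oracle(self, sted):
        """The rendered neck width equals the 1-D chord-profile convolution
        oracle within 3%."""
        neck_d = 0.15
        measured = morpho.measure_neck_fwhm(make_spine(neck=neck_d), 0.35, sted)
        # oracle: cylinder chord profile convolved with the lateral PSF
        d_nm = neck_d * 1e3
        sig = sted.lateral_fwhm / (2 * np.sqrt(2 * np.log(2)))
        x = np.arange(-800.0, 800.0, 1.0)
        chord = np.where(np.abs(x) <= d_nm / 2,
                         2 * np.sqrt(np.maximum((d_nm / 2) ** 2 - x**2, 0)), 0)
        g = np.exp(-(x**2) / (2 * sig**2))
        prof = np.convolve(chord, g / g.sum(), "same")
        sel = np.abs(x) <= 4 * sted.lateral_fwhm
        oracle = fit_lorentzian(LineProfile(x[sel] - x[sel][0], prof[sel])).fwhm
        assert measured == pytest.approx(oracle, rel=0.03)


class TestPersistence:
    def _series(self, presence_map):
        """Build a 3-session series with prescribed per-spine presence."""
        scenes = []
        for t in range(3):
            spines = [
                make_spine(x=1.0 + i, spine_id=sid,
                           born=min(sessions))
                for i, (sid, sessions) in enumerate(sorted(presence_map.items()))
                if t in sessions
            ]
            scenes.append(ss.DendriteScene(0.35, 20.0, t, spines, "d0"))
        return ss.SceneSeries(scenes)

    def test_rules(self):
        series = self._series({
            "always": {0, 1, 2},   # persistent, measured at the last session
            "lost": {0, 1},        # lost, measured at last presence
            "blinker": {1},        # new then lost, measured at appearance
            "late": {1, 2},        # new, measured at first appearance
        })
        recs = {r.spine_id: r for r in ss.classify_persistence(series)}
        assert recs["always"].persistence == PERSISTENT
        assert recs["always"].measure_session == 2
        assert recs["lost"].persistence == TRANSIENT
        assert recs["lost"].measure_session == 1
        assert recs["blinker"].persistence == TRANSIENT
        assert recs["blinker"].measure_session == 1
        assert recs["late"].persistence == TRANSIENT
        assert recs["late"].measure_session == 1

    def test_requires_three_sessions(self):
        series = ss.generate_series(n_sessions=4, seed=1,
                                    session_days=(0, 2, 4, 6))
        with pytest.raises(ValueError):
            ss.classify_persistence(series)

    def test_persistent_spines_larger_in_most_seeds(self):
        """Size-dependent turnover makes the >2-day group's median head
        volume exceed the <=2-day group's in at least 95% of seeds."""
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            series = ss.generate_series(dendrite_length=60.0, seed=seed)
            recs = morpho.records_frame(ss.classify_persistence(series))
            med = recs.groupby("persistence")["head_vol_um3"].median()
            wins += med[PERSISTENT] > med[TRANSIENT]
        assert wins >= 0.95 * n_seeds


def naive_ward_merge_sequence(X):
    """O(n^3) Ward agglomeration recomputing cluster variances from scratch.

    At each step merge the pair whose union minimizes the increase in total
    within-cluster sum of squares; returns the merged member sets in order.
    """
    clusters = [frozenset([i]) for i in range(len(X))]

    def ess(members):
        pts = X[list(members)]
        return float(((pts - pts.mean(axis=0)) ** 2).sum())

    sequence = []
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            delta = (ess(clusters[i] | clusters[j])
                     - ess(clusters[i]) - ess(clusters[j]))
            if best is None or delta < best[0] - 1e-12:
                best = (delta, i, j)
        _, i, j = best
        merged = clusters[i] | clusters[j]
        sequence.append(merged)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return sequence


def linkage_merge_sequence(Z, n):
    members = {i: frozenset([i]) for i in range(n)}
    seq = []
    for k, (a, b, _, _) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + k] = merged
        seq.append(merged)
    return seq


class TestClustering:
    def test_two_separated_groups_recovered(self):
        rng = np.random.default_rng(0)
        recs = []
        for i in range(12):
            big = i < 6
            h = (0.6 if big else 0.2) + rng.normal(0, 0.005)
            recs.append(morpho.MorphRecord(
                spine_id=f"s{i}", mean_head_diam_um=h, mean_neck_diam_um=0.1,
                max_head_diam_um=h, length_um=1.0 + rng.normal(0, 0.01),
                head_vol_um3=np.pi / 6 * h**3,
            ))
        result = ss.cluster_spines(recs, k=2)
        assert set(result.labels[:6]) == {2}   # largest heads labelled last
        assert set(result.labels[6:]) == {1}

    @pytest.mark.parametrize("seed", range(20))
    def test_merge_sequence_matches_naive_ward(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        X = rng.normal(size=(n, 3))
        from scipy.cluster import hierarchy
        got = linkage_merge_sequence(hierarchy.linkage(X, method="ward"), n)
        assert got == naive_ward_merge_sequence(X)

    def test_invariant_to_affine_feature_rescaling(self):
        recs = morpho.sample_archetype_records(n_per_class=15, seed=1)
        base = ss.cluster_spines(recs, k=3).labels
        df = morpho.records_frame(recs)
        df["max_head_diam_um"] = df["max_head_diam_um"] * 1e3  # nm now
        df["length_um"] = df["length_um"] * 7.0 + 3.0
        rescaled = ss.cluster_spines(df, k=3).labels
        # standardization removes affine transforms; the positive scaling
        # preserves the head-size ordering used for labels
        assert np.array_equal(base, rescaled)

    def test_archetype_population_mushroom_cluster(self):
        """k=3 on a small/thin/mushroom mixture: the top cluster carries the
        highest head-to-neck ratio and max head diameter."""
        recs = morpho.sample_archetype_records(n_per_class=40, seed=2)
        result = ss.cluster_spines(recs, k=3)
        df = result.features
        by = df.groupby("cluster")[["head_neck_ratio", "max_head_diam_um"]].mean()
        assert by.loc[3, "max_head_diam_um"] == by["max_head_diam_um"].max()
        assert by.loc[3, "head_neck_ratio"] == by["head_neck_ratio"].max()

    def test_zero_variance_feature_named(self):
        recs = [
            morpho.MorphRecord(
                spine_id=f"s{i}", mean_head_diam_um=0.3 + 0.01 * i,
                mean_neck_diam_um=0.1, max_head_diam_um=0.3 + 0.01 * i,
                length_um=1.0, head_vol_um3=0.01,
            )
            for i in range(5)
        ]
        with pytest.raises(ValueError, match="length_um"):
            ss.cluster_spines(recs, k=3)

    def test_too_few_records_rejected(self):
        recs = morpho.sample_archetype_records(n_per_class=1, seed=3)[:2]
        with pytest.raises(ValueError):
            ss.cluster_spines(recs, k=3)

    def test_dendrogram_json_structure(self):
        import json
        recs = morpho.sample_archetype_records(n_per_class=4, seed=4)
        tree = json.loads(ss.cluster_spines(recs, k=3).dendrogram_json())
        assert tree["count"] == 12
        assert len(tree["children"]) == 2


def permutation_rank_sum_p(a, b):
    """Exhaustive two-sided permutation p-value of the rank-sum statistic."""
    pooled = np.concatenate([a, b])
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    na = len(a)
    obs = ranks[:na].sum()
    total = 0
    extreme = 0
    mean = na * (len(pooled) + 1) / 2.0
    for idx in itertools.combinations(range(len(pooled)), na):
        s = ranks[list(idx)].sum()
        total += 1
        if abs(s - mean) >= abs(obs - mean) - 1e-12:
            extreme += 1
    return extreme / total


class TestCompareGroups:
    def test_identical_groups_null(self):
        _, p = ss.compare_groups([1.0, 2.0, 3.0, 4.0], [1.5, 2.5, 3.5, 4.4])
        assert p > 0.5

    def test_fully_separated_small_groups(self):
        _, p = ss.compare_groups([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert p == pytest.approx(0.1, abs=1e-12)  # 2/20 exactly

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        na = int(rng.integers(2, 6))
        nb = int(rng.integers(2, 6))
        a = rng.normal(size=na)
        b = rng.normal(loc=rng.uniform(0, 2), size=nb)
        _, p = ss.compare_groups(a, b)
        assert p == pytest.approx(permutation_rank_sum_p(a, b), abs=1e-9)

    def test_generator_default_volumes_strongly_separated(self):
        """Persistent vs transient head volumes from the default simulator
        separate at p < 1e-4."""
        recs = []
        for seed in range(6):
            series = ss.generate_series(dendrite_length=40.0, seed=seed)
            recs.extend(ss.classify_persistence(series))
        df = morpho.records_frame(recs)
        _, p = ss.compare_groups(
            df.loc[df.persistence == PERSISTENT, "head_vol_um3"],
            df.loc[df.persistence == TRANSIENT, "head_vol_um3"],
        )
        assert p < 1e-4

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            ss.compare_groups([1.0], [2.0, 3.0])


def test_morphology_summary_table():
    recs = morpho.sample_archetype_records(n_per_class=10, seed=5)
    for i, r in enumerate(recs):
        r.persistence = PERSISTENT if i % 2 else TRANSIENT
    table = morpho.summarize_morphology(recs)
    assert set(table.persistence) == {PERSISTENT, TRANSIENT}
    assert (table.q25 <= table["median"]).all()
    assert (table["median"] <= table.q75).all()
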