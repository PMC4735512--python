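"""4C-seq track arithmetic and interval statistics vs naive oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from polyclust.fourc_analysis import (
    DEFAULT_SCHEME,
    FragmentTrack,
    RegionScheme,
    contacts_to_fragment_counts,
    distance_to_nearest_peak,
    flag_changed_windows,
    mask_viewpoint,
    near_far_summary,
    normalize_track,
    partition_contacts,
    peak_overlap_fraction,
    ratio_minus_one,
    smooth_running_mean,
)


def toy_track(values, start=0, length=100, **extra):
    n = len(next(iter(values.values())))
    starts = start + length * np.arange(n)
    frags = pd.DataFrame(
        {"chrom": "chr3R", "start": starts, "end": starts + length}
    )
    return FragmentTrack(frags, {k: np.asarray(v, float) for k, v in values.items()}, **extra)


def toy_scheme(n_frags=100, length=100):
    span = n_frags * length
    return RegionScheme(
        normalization_region=(0, span),
        viewpoint=(0, length),  # first fragment
        near_far_boundary=span // 2,
        bxc_bounds=(0, span),
        neighbourhood_margin=span,
        viewpoint_margin=1,
    )


class TestNormalize:
    def test_scale_factors(self):
        tr = toy_track({"a": [60, 40], "b": [150, 50]})
        scheme = toy_scheme(2)
        out = normalize_track(tr, scheme, total=1e6)
        assert out.counts["a"] == pytest.approx([6e5, 4e5])
        assert out.counts["b"] == pytest.approx([7.5e5, 2.5e5])

    def test_equal_totals_after(self):
        rng = np.random.default_rng(0)
        tr = toy_track({f"s{i}": rng.integers(1, 100, 50) for i in range(4)})
        out = normalize_track(tr, toy_scheme(50))
        totals = [v.sum() for v in out.counts.values()]
        assert np.allclose(totals, totals[0])

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(1)
        vals = rng.integers(0, 50, 30).astype(float)
        out = normalize_track(toy_track({"a": vals}), toy_scheme(30))
        assert (np.argsort(out.counts["a"]) == np.argsort(vals)).all()

    def test_zero_region_reads_rejected(self):
        tr = toy_track({"a": [0.0, 0.0]})
        with pytest.raises(ValueError, match="normalization region"):
            normalize_track(tr, toy_scheme(2))


class TestSmoothing:
    def test_window_of_three(self):
        out = smooth_running_mean(toy_track({"a": [1, 2, 3]}))
        assert out.counts["a"] == pytest.approx([1.5, 2.0, 2.5])

    def test_constant_unchanged(self):
        out = smooth_running_mean(toy_track({"a": [4.0] * 10}))
        assert out.counts["a"] == pytest.approx([4.0] * 10)

    @given(st.integers(0, 10**6))
    @settings(max_examples=25, deadline=None)
    def test_matches_sliding_window_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.random(int(rng.integers(1, 40)))
        out = smooth_running_mean(toy_track({"a": vals}), window=3)
        oracle = [
            np.mean(vals[max(i - 1, 0): i + 2]) for i in range(len(vals))
        ]
        assert out.counts["a"] == pytest.approx(oracle)

    def test_interior_mean_preserved(self):
        # away from the truncated ends, smoothing redistributes but does not
        # create or destroy signal: interior window sums telescope
        rng = np.random.default_rng(5)
        vals = rng.random(50)
        out = smooth_running_mean(toy_track({"a": vals}))
        assert out.counts["a"][1:-1].sum() == pytest.approx(
            vals[1:-1].sum() + (vals[0] - vals[1]) / 3 + (vals[-1] - vals[-2]) / 3
        )


class TestViewpointMask:
    def test_overlap_rules(self):
        scheme = RegionScheme(
            normalization_region=(0, 10000), viewpoint=(1000, 1200),
            near_far_boundary=5000, bxc_bounds=(0, 10000),
            viewpoint_margin=500,
        )
        frags = pd.DataFrame({
            "chrom": "chr3R",
            "start": [300, 600, 1650, 5000],
            "end": [500, 800, 1750, 5100],
        })
        tr = FragmentTrack(frags, {"a": np.ones(4)})
        out = mask_viewpoint(tr, scheme)
        # margin window is [500, 1700): abutting, fully inside, straddling, outside
        assert out.mask.tolist() == [False, True, True, False]


class TestRatio:
    def test_identity_ratio_zero(self):
        t = toy_track({"r1": [1, 2, 3], "r2": [3, 2, 1]})
        out = ratio_minus_one(t, t)
        assert out.counts["ratio"] == pytest.approx([0, 0, 0])

    def test_doubling(self):
        test = toy_track({"r": [2, 4, 6]})
        ctrl = toy_track({"r": [1, 2, 3]})
        assert ratio_minus_one(test, ctrl).counts["ratio"] == pytest.approx([1, 1, 1])

    def test_zero_control_flagged_not_inf(self):
        test = toy_track({"r": [2.0, 2.0]})
        ctrl = toy_track({"r": [1.0, 0.0]})
        out = ratio_minus_one(test, ctrl)
        assert out.mask[1]
        assert np.isnan(out.counts["ratio"][1])

    def test_mismatched_maps_rejected(self):
        with pytest.raises(ValueError, match="fragment map"):
            ratio_minus_one(toy_track({"r": [1, 2]}), toy_track({"r": [1, 2]}, start=5))


class TestNearFar:
    def test_null_means_zero(self):
        rng = np.random.default_rng(0)
        vals = {"r": rng.integers(50, 150, 100).astype(float)}
        t = toy_track(vals)
        ratio = ratio_minus_one(t, t)
        df = near_far_summary({"vp": ratio}, toy_scheme(100))
        assert df["mean_ratio"].abs().max() == 0.0

    def test_planted_far_depletion_detected(self):
        rng = np.random.default_rng(1)
        scheme = toy_scheme(200)
        base = rng.uniform(80, 120, 200)
        test_vals = base * np.where(np.arange(200) >= 100, 1.0, 0.6)
        # viewpoint sits in fragment 0 (far side is >= boundary? near = side
        # of the viewpoint) -- fragments < 100 are the viewpoint side
        test = toy_track({"r": test_vals})
        ctrl = toy_track({"r": base})
        df = near_far_summary({"vp": ratio_minus_one(test, ctrl)}, scheme)
        near = df[df.region == "near"].iloc[0]
        far = df[df.region == "far"].iloc[0]
        assert near["mean_ratio"] == pytest.approx(-0.4, abs=0.01)
        assert far["mean_ratio"] == pytest.approx(0.0, abs=0.01)
        assert far["p_near_vs_far"] < 0.05

    def test_empty_region_rejected(self):
        scheme = toy_scheme(4)
        t = toy_track({"r": [1.0, 1.0, 1.0, 1.0]})
        ratio = ratio_minus_one(t, t)
        ratio.mask[:2] = True  # wipe the near side
        with pytest.raises(ValueError, match="retained"):
            near_far_summary({"vp": ratio}, scheme)


class TestChangedWindows:
    def _tracks(self, factor_by_half):
        base = np.full(100, 50.0)
        test = base * factor_by_half
        return toy_track({"r": test}), toy_track({"r": base})

    @pytest.mark.parametrize(
        "factor, flag",
        [(0.4, "decreased"), (0.6, "unchanged"), (1.4, "unchanged"), (1.6, "increased")],
    )
    def test_threshold_rule(self, factor, flag):
        test, ctrl = self._tracks(factor)
        df = flag_changed_windows(test, ctrl, toy_scheme(100), window_bp=200)
        assert (df["flag"] == flag).all()

    def test_flags_partition_windows(self):
        rng = np.random.default_rng(2)
        test = toy_track({"r": rng.uniform(10, 200, 100)})
        ctrl = toy_track({"r": rng.uniform(10, 200, 100)})
        df = flag_changed_windows(test, ctrl, toy_scheme(100))
        assert set(df["flag"]).issubset({"decreased", "unchanged", "increased"})
        assert len(df) == df["flag"].notna().sum()


class TestPipelineRecovery:
    @pytest.mark.parametrize("seed", range(10))
    def test_decreased_windows_cluster_near_planted_peaks(self, seed):
        """Contact loss planted around binding peaks: windows flagged as
        decreased sit significantly closer to peak centres than unchanged
        windows (one-sided test)."""
        from scipy import stats as sstats

        from polyclust.synthetic_data import FourCGenParams, gen_4c_tracks

        params = FourCGenParams(seed=seed, depletion_factor=0.4,
                                deplete_around_peaks=True)
        track, truth = gen_4c_tracks(params)

        def prep(names):
            sub = track.replace_counts({n: track.counts[n] for n in names})
            return mask_viewpoint(normalize_track(sub))

        test = prep(["PhML_rep1", "PhML_rep2"])
        ctrl = prep(["S2_rep1", "S2_rep2"])
        windows = flag_changed_windows(test, ctrl)
        out, _ = distance_to_nearest_peak(windows, truth["peaks"])
        dec = out[out["flag"] == "decreased"]["distance_bp"].to_numpy()
        unc = out[out["flag"] == "unchanged"]["distance_bp"].to_numpy()
        assert len(dec) >= 2 and len(unc) >= 2
        p = sstats.ttest_ind(dec, unc, alternative="less", equal_var=False).pvalue
        assert p < 0.05


class TestNearestPeak:
    def _windows(self, mids):
        return pd.DataFrame({
            "midpoint": mids,
            "flag": ["decreased" if i % 2 else "unchanged" for i in range(len(mids))],
        })

    def test_simple_distances(self):
        peaks = pd.DataFrame({"start": [1400, 2900], "end": [1600, 3100]})
        out, _ = distance_to_nearest_peak(self._windows([1000.0, 1500.0]), peaks)
        assert out["distance_bp"].tolist() == [500.0, 0.0]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        mids = rng.uniform(0, 10**6, 200)
        centres = rng.uniform(0, 10**6, 37)
        peaks = pd.DataFrame({"start": centres - 50, "end": centres + 50})
        out, _ = distance_to_nearest_peak(self._windows(mids), peaks)
        oracle = np.min(np.abs(mids[:, None] - centres[None, :]), axis=1)
        assert out["distance_bp"].to_numpy() == pytest.approx(oracle)

    def test_empty_peaks_rejected(self):
        with pytest.raises(ValueError):
            distance_to_nearest_peak(self._windows([1.0]), pd.DataFrame({"start": [], "end": []}))


class TestContacts:
    def test_fragment_counts_examples(self):
        frags = pd.DataFrame({"start": [0, 100, 200, 300], "end": [100, 200, 300, 400]})
        contacts = pd.DataFrame({"start": [50, 120], "end": [320, 180]})
        out = contacts_to_fragment_counts(contacts, frags)
        assert out["n_fragments"].tolist() == [4, 1]

    def test_counts_match_naive_oracle(self):
        rng = np.random.default_rng(4)
        starts = np.sort(rng.choice(np.arange(0, 10**5, 50), 300, replace=False))
        frags = pd.DataFrame({"start": starts, "end": starts + rng.integers(10, 50, 300)})
        cs = rng.integers(0, 10**5, 60)
        contacts = pd.DataFrame({"start": cs, "end": cs + rng.integers(10, 5000, 60)})
        out = contacts_to_fragment_counts(contacts, frags)
        naive = [
            int(((frags["start"] < hi) & (frags["end"] > lo)).sum())
            for lo, hi in zip(contacts["start"], contacts["end"])
        ]
        assert out["n_fragments"].tolist() == naive

    def test_partition_rules(self):
        scheme = DEFAULT_SCHEME
        lo, hi = scheme.bxc_bounds
        contacts = pd.DataFrame({
            "start": [hi + 10**6, hi + 3 * 10**6, lo + 1000],
            "end": [hi + 10**6 + 500, hi + 3 * 10**6 + 500, lo + 2000],
        })
        parts = partition_contacts(contacts, scheme)
        assert len(parts["neighbourhood"]) == 1
        assert len(parts["distal"]) == 1
        assert len(parts["inside"]) == 1

    def test_overlap_fraction_extremes(self):
        peaks = pd.DataFrame({"chrom": "chr3R", "start": [100, 500], "end": [200, 600]})
        on = pd.DataFrame({"chrom": "chr3R", "start": [150, 550], "end": [160, 560]})
        off = pd.DataFrame({"chrom": "chrX", "start": [150, 550], "end": [160, 560]})
        assert peak_overlap_fraction(on, peaks) == 1.0
        assert peak_overlap_fraction(off, peaks) == 0.0
        with pytest.raises(ValueError):
            peak_overlap_fraction(on.iloc[:0], peaks)

    def test_overlap_matches_naive_oracle(self):
        rng = np.random.default_rng(6)
        ps = rng.integers(0, 10**5, 40)
        peaks = pd.DataFrame({"start": ps, "end": ps + rng.integers(50, 500, 40)})
        cs = rng.integers(0, 10**5, 80)
        contacts = pd.DataFrame({"start": cs, "end": cs + rng.integers(50, 3000, 80)})
        frac = peak_overlap_fraction(contacts, peaks)
        naive = np.mean([
            bool(((peaks["start"] < hi) & (peaks["end"] > lo)).any())
            for lo, hi in zip(contacts["start"], contacts["end"])
        ])
        assert frac == pytest.approx(naive)
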