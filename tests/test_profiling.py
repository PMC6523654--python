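import itertools

import numpy as np
import pandas as pd
import pytest

from centrotime.errors import ConfigError, PipelineError
from centrotime.genome import GenomeLayout
from centrotime.profiling import (PipelineConfig, RTProfile, autocorrelation,
                                  bin_s_reads, define_g1_windows,
                                  normalize_profile, piecewise_constant_fit,
                                  segment_filter, smooth_profile)
from conftest import make_reads


def profile_from_values(values, midpoints=None, chrom="chr1", stage="raw",
                        seg_id=0):
    values = np.asarray(values, dtype=float)
    mid = np.asarray(midpoints, dtype=float) if midpoints is not None \
        else 1000.0 * np.arange(len(values))
    data = pd.DataFrame({"chrom": chrom, "seg_id": seg_id,
                         "start": mid - 10, "end": mid + 10,
                         "midpoint": mid, "value": values})
    return RTProfile(data=data, stage=stage)


# ---------------------------------------------------------------------------
# window construction
# ---------------------------------------------------------------------------

class TestWindows:
    def test_window_count_formula(self, plain_layout, config):
        """2000 reads in one segment yield floor((2000-200)/100)+1 = 19 windows."""
        reads = make_reads(np.arange(2000) * 100, frag_len=50)
        win = define_g1_windows(reads, plain_layout, config)
        assert len(win) == 19
        assert (win["n_reads"] == 200).all()

    def test_ten_consecutive_windows_span_1100_distinct_reads(self, plain_layout, config):
        """At the default 200-read/100-step geometry, 10 consecutive windows
        jointly cover 200 + 9*100 = 1100 distinct G1 reads."""
        pos = np.sort(np.random.default_rng(0).choice(9_000_000, size=5000,
                                                      replace=False))
        reads = make_reads(pos, frag_len=50)
        win = define_g1_windows(reads, plain_layout, config)
        ten = win.iloc[0:10]
        lo, hi = ten["start"].iloc[0], ten["end"].iloc[9]
        distinct = ((pos >= lo) & (pos < hi)).sum()
        assert distinct == 1100

    def test_underfilled_segment_emits_no_windows(self, plain_layout, config):
        reads = make_reads(np.arange(150) * 10, frag_len=5)
        win = define_g1_windows(reads, plain_layout, config)
        assert win.empty

    def test_consecutive_windows_share_reads_per_window_minus_step(self, plain_layout, config):
        pos = np.sort(np.random.default_rng(1).choice(9_000_000, 1000, replace=False))
        reads = make_reads(pos, frag_len=50)
        win = define_g1_windows(reads, plain_layout, config)
        for i in range(len(win) - 1):
            shared = ((pos >= win["start"].iloc[i + 1]) & (pos < win["end"].iloc[i])).sum()
            assert shared == config.reads_per_window - config.window_step

    def test_gap_break_splits_segments(self, plain_layout, config):
        left = np.arange(300) * 1000                   # 0 .. 0.3 Mb
        right = 5_000_000 + np.arange(300) * 1000      # far side of a >1 Mb desert
        reads = make_reads(np.concatenate([left, right]), frag_len=50)
        win = define_g1_windows(reads, plain_layout, config)
        assert win["seg_id"].nunique() == 2
        # windows never span the gap
        assert not ((win["start"] < 300_000) & (win["end"] > 5_000_000)).any()

    def test_flagged_reads_not_used(self, plain_layout, config):
        reads = make_reads(np.arange(400) * 1000, frag_len=50)
        reads.loc[:199, "is_dup"] = True
        win = define_g1_windows(reads, plain_layout, config)
        assert len(win) == 1  # only 200 usable reads remain


# ---------------------------------------------------------------------------
# S binning
# ---------------------------------------------------------------------------

class TestBinSReads:
    def _windows(self, plain_layout, config, n_reads=2000):
        g1 = make_reads(np.arange(n_reads) * 100, frag_len=50)
        return define_g1_windows(g1, plain_layout, config)

    def test_two_window_toy_ratio(self):
        windows = pd.DataFrame({
            "chrom": "chr1", "seg_id": 0,
            "start": [0, 10_000], "end": [10_000, 20_000],
            "midpoint": [5_000.0, 15_000.0], "n_reads": 200,
            "g1_span_count": 200})
        s = make_reads(np.concatenate([np.linspace(0, 9999, 100).astype(int),
                                       np.linspace(10_000, 19_999, 300).astype(int)]),
                       frag_len=50)
        prof = bin_s_reads(windows, s)
        assert prof.data["value"].tolist() == [0.5, 1.5]

    def test_uniform_s_reads_give_flat_profile(self, plain_layout, config):
        win = self._windows(plain_layout, config)
        s = make_reads(np.arange(0, 200_000, 37), frag_len=50)
        prof = bin_s_reads(win, s)
        assert prof.data["value"].std() < 0.05
        assert prof.data["value"].mean() == pytest.approx(1.0)

    def test_window_with_no_s_reads_is_zero(self, plain_layout, config):
        win = self._windows(plain_layout, config)
        # S reads only in the right half of the G1-covered range
        s = make_reads(np.arange(100_000, 200_000, 10), frag_len=50)
        prof = bin_s_reads(win, s)
        assert prof.data["value"].iloc[0] == 0.0

    def test_no_s_reads_is_an_error(self, plain_layout, config):
        win = self._windows(plain_layout, config)
        s = make_reads([], frag_len=50).iloc[:0]
        with pytest.raises(PipelineError):
            bin_s_reads(win, s)


# ---------------------------------------------------------------------------
# changepoint outlier filter
# ---------------------------------------------------------------------------

def oracle_partition_cost(y, penalty, min_size):
    """Exhaustive minimum of SSE + penalty*pieces over all valid partitions."""
    n = len(y)
    best = np.inf
    positions = range(min_size, n - min_size + 1)
    for k in range(0, n // min_size):
        for cuts in itertools.combinations(positions, k):
            bounds = [0, *cuts, n]
            if any(b - a < min_size for a, b in zip(bounds[:-1], bounds[1:])):
                continue
            sse = sum(((y[a:b] - y[a:b].mean()) ** 2).sum()
                      for a, b in zip(bounds[:-1], bounds[1:]))
            cost = sse + penalty * (len(bounds) - 1)
            best = min(best, cost)
    return best


class TestSegmentFilter:
    def test_flat_profile_keeps_everything(self, config):
        prof = profile_from_values(np.ones(50))
        assert len(segment_filter(prof, config)) == 50

    def test_single_outlier_removed(self, config):
        """Flat profile with one 3.0 window: deviation 2.0 > 3*sqrt(0.04)=0.6,
        and the minimum piece size stops the outlier forming its own piece."""
        values = np.ones(60)
        values[30] = 3.0
        prof = profile_from_values(values)
        out = segment_filter(prof, config)
        assert len(out) == 59
        assert 3.0 not in out.data["value"].to_numpy()

    def test_clean_step_profile_fully_retained(self, config):
        """A clean two-level step (0.8/1.2, 50 windows each) is absorbed by a
        changepoint, so no window deviates from its piece mean."""
        values = np.concatenate([np.full(50, 0.8), np.full(50, 1.2)])
        out = segment_filter(profile_from_values(values), config)
        assert len(out) == 100
        # and the DP really did split: piece means equal the levels
        fit = piecewise_constant_fit(values, config.segmentation_variance,
                                     config.min_piece_size)
        assert set(np.round(fit, 6)) == {0.8, 1.2}

    @pytest.mark.parametrize("seed", range(6))
    def test_dp_matches_exhaustive_partition_oracle(self, seed):
        """The DP cost equals brute-force enumeration over all partitions."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        y = np.round(rng.normal(1, 0.3, n), 3)
        if seed % 2:
            y[: n // 2] += 1.0  # plant a step
        var = 0.04
        min_size = 3
        penalty = 2 * var * np.log(n)
        fit = piecewise_constant_fit(y, var, min_piece_size=min_size)
        # count pieces from fit-value boundaries (means can tie only for
        # identical adjacent levels, which merging never worsens)
        pieces = 1 + int((np.diff(fit) != 0).sum())
        dp_cost = ((y - fit) ** 2).sum() + penalty * pieces
        assert dp_cost == pytest.approx(oracle_partition_cost(y, penalty, min_size),
                                        abs=1e-9)

    def test_short_segment_passes_through(self, config):
        values = np.array([1.0, 5.0, 1.0])  # gross outlier, but only 3 windows
        out = segment_filter(profile_from_values(values), config)
        assert len(out) == 3

    def test_wrong_stage_rejected(self, config):
        prof = profile_from_values(np.ones(10), stage="smoothed")
        with pytest.raises(ConfigError):
            segment_filter(prof, config)


# ---------------------------------------------------------------------------
# smoothing spline
# ---------------------------------------------------------------------------

class TestSmoothing:
    def test_fidelity_weight_one_interpolates(self):
        rng = np.random.default_rng(2)
        y = rng.normal(1, 0.2, 40)
        prof = profile_from_values(y, stage="filtered")
        cfg = PipelineConfig(spline_param=1.0)
        out = smooth_profile(prof, cfg)
        np.testing.assert_allclose(out.data["value"], y, atol=1e-8)

    def test_fidelity_weight_to_zero_gives_least_squares_line(self):
        rng = np.random.default_rng(3)
        x = np.linspace(0, 5e6, 60)
        y = 1 + 2e-7 * x + rng.normal(0, 0.1, 60)
        prof = profile_from_values(y, midpoints=x, stage="filtered")
        out = smooth_profile(prof, PipelineConfig(spline_param=1e-30))
        slope, icept = np.polyfit(x, y, 1)
        np.testing.assert_allclose(out.data["value"], slope * x + icept, atol=1e-6)

    def test_default_smoothing_reduces_noise_on_sinusoid(self, config):
        """Noisy 10 Mb sinusoid: smoothed residual SD against the clean signal
        is strictly below the raw residual SD."""
        rng = np.random.default_rng(4)
        x = np.linspace(0, 10e6, 2000)
        clean = np.sin(2 * np.pi * x / 4e6)
        y = clean + rng.normal(0, 0.2, len(x))
        out = smooth_profile(profile_from_values(y, midpoints=x, stage="filtered"),
                             config)
        assert np.std(out.data["value"] - clean) < np.std(y - clean) * 0.5

    def test_tiny_segment_passes_through(self, config):
        y = np.array([1.0, 2.0, 1.5])
        out = smooth_profile(profile_from_values(y, stage="filtered"), config)
        np.testing.assert_array_equal(out.data["value"], y)

    def test_tied_midpoints_handled(self, config):
        x = np.array([0, 0, 1e5, 2e5, 3e5, 4e5, 5e5])
        y = np.array([1.0, 2.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        out = smooth_profile(profile_from_values(y, midpoints=x, stage="filtered"),
                             config)
        assert np.isfinite(out.data["value"]).all()
        # tied x received a common fitted value
        assert out.data["value"].iloc[0] == out.data["value"].iloc[1]


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

class TestNormalize:
    def test_autosomal_mean_zero_sd_one(self, plain_layout, config):
        rng = np.random.default_rng(5)
        prof = profile_from_values(rng.normal(1, 0.3, 500), stage="smoothed")
        out = normalize_profile(prof, plain_layout, config)
        v = out.data["value"].to_numpy()
        assert abs(v.mean()) < 1e-9
        assert abs(v.std() - 1) < 1e-9

    def test_constant_profile_rejected(self, plain_layout, config):
        prof = profile_from_values(np.ones(50), stage="smoothed")
        with pytest.raises(PipelineError):
            normalize_profile(prof, plain_layout, config)

    def test_already_standardized_unchanged(self, plain_layout, config):
        values = np.tile([-1.0, 1.0], 25)
        prof = profile_from_values(values, stage="smoothed")
        out = normalize_profile(prof, plain_layout, config)
        np.testing.assert_allclose(out.data["value"], values, atol=1e-12)

    def test_idempotent(self, plain_layout, config):
        rng = np.random.default_rng(6)
        prof = profile_from_values(rng.normal(0, 2, 100), stage="smoothed")
        once = normalize_profile(prof, plain_layout, config)
        once.stage = "smoothed"  # re-enter the same operation
        twice = normalize_profile(once, plain_layout, config)
        np.testing.assert_allclose(once.data["value"], twice.data["value"], atol=1e-12)

    def test_sex_chromosomes_transformed_but_not_in_statistics(self, config):
        layout = GenomeLayout(chromosomes=[("chr1", 1_000_000), ("chrX", 1_000_000)])
        rng = np.random.default_rng(7)
        auto = profile_from_values(rng.normal(1, 0.2, 200), chrom="chr1",
                                   stage="smoothed").data
        sex = profile_from_values(rng.normal(5, 0.2, 200), chrom="chrX",
                                  stage="smoothed", seg_id=1).data
        prof = RTProfile(data=pd.concat([auto, sex], ignore_index=True),
                         stage="smoothed")
        out = normalize_profile(prof, layout, config)
        a = out.data[out.data["chrom"] == "chr1"]["value"].to_numpy()
        x = out.data[out.data["chrom"] == "chrX"]["value"].to_numpy()
        assert abs(a.mean()) < 1e-9 and abs(a.std() - 1) < 1e-9
        assert x.mean() > 5  # shifted by the same transform, far off-scale


# ---------------------------------------------------------------------------
# autocorrelation
# ---------------------------------------------------------------------------

class TestAutocorrelation:
    def test_lag_zero_is_one(self):
        rng = np.random.default_rng(8)
        prof = profile_from_values(rng.normal(0, 1, 300), stage="normalized")
        acf = autocorrelation(prof, max_lag=5000, lag_step=1000)
        assert acf["r"].iloc[0] == 1.0

    def test_white_noise_decorrelates(self):
        rng = np.random.default_rng(9)
        n = 10_000
        prof = profile_from_values(rng.normal(0, 1, n),
                                   midpoints=1000.0 * np.arange(n),
                                   stage="normalized")
        acf = autocorrelation(prof, max_lag=5000, lag_step=1000)
        assert (acf["r"].iloc[1:].abs() < 3 / np.sqrt(n) + 0.02).all()

    def test_smooth_truth_acf_decays_to_noise_floor(self):
        """The generated timing landscape is strongly autocorrelated at 1 Mb
        and decorrelated (within sampling noise of zero) beyond a few
        correlation lengths.  Strict ordering of the near-zero long-lag
        estimates is not asserted — they fluctuate around zero on finite
        chromosomes."""
        from centrotime.simulate import build_toy_genome, simulate_rt_truth
        big = build_toy_genome(n_chrom=4, chrom_length=50_000_000,
                               centromere_span=1_000_000)
        truth = simulate_rt_truth(big, n_control_points=100, seed=1)
        frames = []
        for i, chrom in enumerate(big.names):
            sub = truth.chrom_grid(chrom)
            frames.append(profile_from_values(sub["timing"].to_numpy()[::10],
                                              midpoints=sub["pos"].to_numpy()[::10],
                                              chrom=chrom, seg_id=i,
                                              stage="normalized").data)
        prof = RTProfile(data=pd.concat(frames, ignore_index=True),
                         stage="normalized")
        acf = autocorrelation(prof, max_lag=10_000_000, lag_step=1_000_000)
        r = dict(zip(acf["lag"], acf["r"]))
        assert r[1_000_000] > 0.5
        assert r[1_000_000] > r[5_000_000]
        assert abs(r[5_000_000]) < 0.5 and abs(r[10_000_000]) < 0.5
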