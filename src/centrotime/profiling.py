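"""Replication-timing inference from filtered G1 and S read sets.

The recipe: G1 reads define sliding windows of equal read depth (200 reads,
advancing by 100, so consecutive windows share half their reads); S reads are
counted in those windows; outlier windows are removed with a piecewise-constant
changepoint model (noise variance fixed at 0.04 in squared raw-ratio units);
each contiguously covered segment is smoothed with a cubic smoothing spline
(fidelity weight 1e-16, x in bp); the profile is normalized to autosomal
mean 0 / SD 1.  The per-window statistic is the S/G1 count ratio over the
window interval; with every window holding the same 200 G1 reads this is just
the S count up to an affine transform, but the ratio stays unbiased where
tied (repeat-collapsed) coordinates put extra reads inside an interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.interpolate import make_smoothing_spline

from .errors import ConfigError, PipelineError
from .genome import GenomeLayout
from .reads import passing_mask, read1_position

log = logging.getLogger(__name__)

STAGES = ("raw", "filtered", "smoothed", "normalized")


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable constant of the profiling pipeline.

    Defaults are the published recipe: 200-read windows stepping by 100
    (10 consecutive windows span 1100 distinct G1 reads), changepoint noise
    variance 0.04 with a 3-sigma outlier rule, smoothing-spline fidelity
    weight 1e-16 with x in bp, and z-normalization over autosomal windows.
    """

    reads_per_window: int = 200
    window_step: int = 100
    segmentation_variance: float = 0.04
    outlier_k: float = 3.0
    spline_param: float = 1e-16
    gap_break: int = 1_000_000            # bp without usable G1 reads that splits a segment
    high_cov_bin: int = 100_000
    low_cov_bin: int = 500_000
    min_mapq: int = 20
    dedup_mode: str = "paired"
    sex_chroms: tuple[str, ...] = ("chrX", "chrY", "chrM", "X", "Y", "M", "MT")
    centromere_min_density: float = 10.0  # G1 windows per Mb for centromere inclusion
    aggregation_bins: int = 100
    min_filter_windows: int = 5           # segments shorter than this skip outlier filtering
    min_piece_size: int = 5               # smallest changepoint piece, in windows

    def __post_init__(self):
        if not (self.reads_per_window > self.window_step > 0):
            raise ConfigError("need reads_per_window > window_step > 0")
        for name in ("segmentation_variance", "spline_param", "outlier_k",
                     "gap_break", "high_cov_bin", "low_cov_bin",
                     "centromere_min_density", "aggregation_bins"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0 < self.spline_param <= 1:
            raise ConfigError("spline_param is a fidelity weight in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "sex_chroms" in raw:
            raw["sex_chroms"] = tuple(raw["sex_chroms"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["sex_chroms"] = list(self.sex_chroms)
        return d


@dataclass
class RTProfile:
    """Per-window replication-timing values at one pipeline stage.

    ``data`` columns: chrom, seg_id, start, end, midpoint, value.  ``seg_id``
    is the contiguity group a window belongs to (windows never span assembly
    gaps, excluded regions, or read deserts longer than ``gap_break``).
    """

    data: pd.DataFrame
    stage: str

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ConfigError(f"unknown profile stage {self.stage!r}")

    def __len__(self) -> int:
        return len(self.data)

    def values_on(self, chrom: str) -> pd.DataFrame:
        return self.data[self.data["chrom"] == chrom]


# ---------------------------------------------------------------------------
# window construction
# ---------------------------------------------------------------------------

def _segment_breaks(layout: GenomeLayout, chrom: str,
                    exclusion_intervals: pd.DataFrame | None) -> np.ndarray:
    """Midpoints of annotated gaps / excluded regions that must split windows."""
    pieces = [layout.gaps[layout.gaps["chrom"] == chrom]]
    if exclusion_intervals is not None and len(exclusion_intervals):
        pieces.append(exclusion_intervals[exclusion_intervals["chrom"] == chrom])
    brk = pd.concat(pieces, ignore_index=True) if pieces else pd.DataFrame()
    if brk.empty:
        return np.empty(0)
    return np.sort(0.5 * (brk["start"].to_numpy() + brk["end"].to_numpy()))


def define_g1_windows(g1_reads: pd.DataFrame, layout: GenomeLayout,
                      config: PipelineConfig,
                      exclusion_intervals: pd.DataFrame | None = None) -> pd.DataFrame:
    """Build sliding equal-read-depth windows from usable G1 reads.

    Within each contiguity segment, window ``i`` covers usable G1 reads
    ``[i*step, i*step + reads_per_window)``; its start is its first read's
    position, its end is one past its last read's position, and its midpoint
    is the median read position.  Segments that cannot fill a single window
    emit none.  Returns a DataFrame with columns chrom, seg_id, start, end,
    midpoint, n_reads (the defining count) and g1_span_count (usable G1 reads
    actually inside the interval; > n_reads only at tied coordinates).
    """
    rpw, step = config.reads_per_window, config.window_step
    usable = g1_reads.loc[passing_mask(g1_reads)]
    rows = []
    seg_id = 0
    for chrom, _length in layout.chromosomes:
        sub = usable.loc[usable["chrom"] == chrom]
        if sub.empty:
            continue
        pos = np.sort(read1_position(sub))
        breaks = _segment_breaks(layout, chrom, exclusion_intervals)
        region = np.searchsorted(breaks, pos) if len(breaks) else np.zeros(len(pos), dtype=int)
        new_seg = np.diff(pos) > config.gap_break
        new_seg |= np.diff(region) != 0
        seg_starts = np.concatenate([[0], np.flatnonzero(new_seg) + 1, [len(pos)]])
        for a, b in zip(seg_starts[:-1], seg_starts[1:]):
            seg = pos[a:b]
            n = len(seg)
            if n < rpw:
                log.info("segment on %s with %d reads: no windows", chrom, n)
                seg_id += 1
                continue
            for i0 in range(0, n - rpw + 1, step):
                w = seg[i0:i0 + rpw]
                start, end = int(w[0]), int(w[-1]) + 1
                # ties at the interval edges can put extra usable G1 reads
                # inside [start, end); record the actual interval count so the
                # S/G1 ratio stays unbiased where coordinates collapse
                span = int(np.searchsorted(seg, end) - np.searchsorted(seg, start))
                rows.append((chrom, seg_id, start, end, float(np.median(w)), rpw, span))
            seg_id += 1
    return pd.DataFrame(rows, columns=["chrom", "seg_id", "start", "end",
                                       "midpoint", "n_reads", "g1_span_count"])


# ---------------------------------------------------------------------------
# S-read binning
# ---------------------------------------------------------------------------

def bin_s_reads(windows: pd.DataFrame, s_reads: pd.DataFrame) -> RTProfile:
    """S/G1 read-count ratio per G1 window, scaled so the profile has mean 1.

    The denominator is the usable G1 count in the window interval — exactly
    ``reads_per_window`` except where tied coordinates put extra reads inside
    the interval, so up to that constant the value is just the S count.
    Overlapping windows double-count S reads by design (the windows slide).
    """
    if windows.empty:
        raise PipelineError("no G1 windows to bin into")
    usable = s_reads.loc[passing_mask(s_reads)]
    if usable.empty:
        raise PipelineError("no usable S-phase reads")
    counts = np.zeros(len(windows), dtype=float)
    for chrom, sub in usable.groupby("chrom", sort=False):
        pos = np.sort(read1_position(sub))
        sel = windows["chrom"] == chrom
        if not sel.any():
            continue
        lo = np.searchsorted(pos, windows.loc[sel, "start"].to_numpy())
        hi = np.searchsorted(pos, windows.loc[sel, "end"].to_numpy())
        counts[sel.to_numpy()] = hi - lo
    if counts.sum() == 0:
        raise PipelineError("S reads do not overlap any window")
    g1 = (windows["g1_span_count"] if "g1_span_count" in windows
          else windows["n_reads"]).to_numpy(dtype=float)
    ratio = counts / g1
    data = windows[["chrom", "seg_id", "start", "end", "midpoint"]].copy()
    data["value"] = ratio / ratio.mean()
    return RTProfile(data=data.reset_index(drop=True), stage="raw")


# ---------------------------------------------------------------------------
# changepoint outlier filter
# ---------------------------------------------------------------------------

def piecewise_constant_fit(y: np.ndarray, noise_var: float,
                           min_piece_size: int = 5,
                           penalty: float | None = None) -> np.ndarray:
    """Optimal penalized piecewise-constant fit; returns the piece mean per point.

    Minimizes sum of squared residuals + penalty * (number of pieces) by
    dynamic programming over all partitions with pieces of at least
    ``min_piece_size`` points.  The default penalty is ``2 * noise_var *
    log(n)``, the known-variance BIC rate.  The minimum piece size stops
    isolated outliers from claiming a private piece (they must instead stand
    out against their piece's mean).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2 * min_piece_size:
        return np.full(n, y.mean()) if n else y.copy()
    if penalty is None:
        penalty = 2.0 * noise_var * np.log(n)
    cs = np.concatenate([[0.0], np.cumsum(y)])
    css = np.concatenate([[0.0], np.cumsum(y * y)])
    F = np.full(n + 1, np.inf)
    F[0] = 0.0
    prev = np.zeros(n + 1, dtype=int)
    for t in range(min_piece_size, n + 1):
        s = np.arange(0, t - min_piece_size + 1)
        length = t - s
        sse = (css[t] - css[s]) - (cs[t] - cs[s]) ** 2 / length
        total = F[s] + sse + penalty
        j = int(np.argmin(total))
        F[t] = total[j]
        prev[t] = s[j]
    bounds = [n]
    while bounds[-1] > 0:
        bounds.append(int(prev[bounds[-1]]))
    bounds = bounds[::-1]
    fit = np.empty(n)
    for a, b in zip(bounds[:-1], bounds[1:]):
        fit[a:b] = y[a:b].mean()
    return fit


def segment_filter(profile: RTProfile, config: PipelineConfig) -> RTProfile:
    """Drop windows deviating > k*sigma from their changepoint piece mean.

    sigma is the square root of the configured segmentation variance; the fit
    is per contiguity segment.  Segments shorter than ``min_filter_windows``
    pass through unfiltered.
    """
    if profile.stage != "raw":
        raise ConfigError(f"segment_filter expects a raw profile, got {profile.stage}")
    sigma = np.sqrt(config.segmentation_variance)
    keep = np.ones(len(profile.data), dtype=bool)
    for _, idx in profile.data.groupby(["chrom", "seg_id"], sort=False).groups.items():
        y = profile.data.loc[idx, "value"].to_numpy()
        if len(y) < config.min_filter_windows:
            log.warning("segment with %d windows passed through unfiltered", len(y))
            continue
        fit = piecewise_constant_fit(y, config.segmentation_variance,
                                     min_piece_size=config.min_piece_size)
        keep[profile.data.index.get_indexer(idx)] = np.abs(y - fit) <= config.outlier_k * sigma
    data = profile.data.loc[keep].reset_index(drop=True)
    log.info("segment filter removed %d of %d windows", int((~keep).sum()), len(keep))
    return RTProfile(data=data, stage="filtered")


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def smooth_profile(profile: RTProfile, config: PipelineConfig) -> RTProfile:
    """Cubic smoothing spline per segment, evaluated at window midpoints.

    The spline minimizes ``p * sum (y - f(x))^2 + (1 - p) * int f''(x)^2 dx``
    with ``p = spline_param`` and x in bp, i.e. ``lam = (1 - p) / p`` in the
    equivalent single-penalty form.  Tied midpoints are averaged before the
    fit; segments with fewer than 5 distinct midpoints pass through.
    """
    if profile.stage != "filtered":
        raise ConfigError(f"smooth_profile expects a filtered profile, got {profile.stage}")
    p = config.spline_param
    lam = (1.0 - p) / p
    data = profile.data.copy()
    values = data["value"].to_numpy(dtype=float).copy()
    for _, idx in data.groupby(["chrom", "seg_id"], sort=False).groups.items():
        loc = data.index.get_indexer(idx)
        x = data.loc[idx, "midpoint"].to_numpy(dtype=float)
        y = values[loc]
        ux, inv = np.unique(x, return_inverse=True)
        if len(ux) < 5:
            continue
        uy = np.bincount(inv, weights=y) / np.bincount(inv)
        # solve in unit-range x for conditioning; the roughness penalty scales
        # as range^-3 under x -> x/s, so this is the identical functional
        s = ux[-1] - ux[0]
        lam_seg = lam / s ** 3
        if lam_seg > 1e4:
            # the solution differs from the lam -> inf limit by < 1e-6 here,
            # while the banded solver itself degrades; return the exact limit
            slope, intercept = np.polyfit(ux, uy, 1)
            values[loc] = slope * x + intercept
        else:
            spl = make_smoothing_spline(ux / s, uy, lam=lam_seg)
            values[loc] = spl(x / s)
    data["value"] = values
    return RTProfile(data=data, stage="smoothed")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_profile(profile: RTProfile, layout: GenomeLayout,
                      config: PipelineConfig | None = None) -> RTProfile:
    """Z-score against autosomal windows (mean 0, SD 1), applied genome-wide.

    The mean and SD are computed over autosomal windows only, then the same
    affine transform is applied to every window, sex chromosomes included.
    """
    config = config or PipelineConfig()
    data = profile.data.copy()
    auto = ~data["chrom"].isin(config.sex_chroms)
    if not auto.any():
        raise PipelineError("no autosomal windows to normalize against")
    v = data.loc[auto, "value"].to_numpy(dtype=float)
    sd = v.std()
    if sd == 0 or not np.isfinite(sd):
        raise PipelineError("autosomal profile has zero variance; cannot normalize")
    data["value"] = (data["value"] - v.mean()) / sd
    return RTProfile(data=data, stage="normalized")


# ---------------------------------------------------------------------------
# autocorrelation QC
# ---------------------------------------------------------------------------

def autocorrelation(profile: RTProfile, max_lag: int = 10_000_000,
                    lag_step: int = 100_000) -> pd.DataFrame:
    """Autocorrelation of the profile as a function of genomic distance.

    Each segment is resampled onto a uniform ``lag_step`` grid by linear
    interpolation; r(lag) is the Pearson correlation of value pairs separated
    by the lag, pooled over segments.  Returns columns lag, r, n_pairs.
    """
    grids = []
    for _, sub in profile.data.groupby(["chrom", "seg_id"], sort=False):
        x = sub["midpoint"].to_numpy(dtype=float)
        y = sub["value"].to_numpy(dtype=float)
        if len(x) < 2:
            continue
        gx = np.arange(np.ceil(x[0] / lag_step) * lag_step, x[-1] + 1, lag_step)
        if len(gx) >= 2:
            grids.append(np.interp(gx, x, y))
    if not grids:
        raise PipelineError("profile too sparse for autocorrelation")
    longest = max(len(g) for g in grids)
    k_max = min(max_lag // lag_step, longest - 1)
    if k_max < max_lag // lag_step:
        log.warning("max_lag truncated to %d bp (longest segment)", k_max * lag_step)
    rows = []
    for k in range(0, k_max + 1):
        a = np.concatenate([g[:len(g) - k] for g in grids if len(g) > k])
        b = np.concatenate([g[k:] for g in grids if len(g) > k])
        if len(a) < 3:
            break
        if k == 0:
            r = 1.0
        else:
            with np.errstate(invalid="ignore"):
                r = float(np.corrcoef(a, b)[0, 1])
        rows.append({"lag": k * lag_step, "r": r, "n_pairs": len(a)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    """Everything one profiling run produces."""

    windows: pd.DataFrame
    profiles: dict                      # stage name -> RTProfile
    filter_audit: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)

    @property
    def normalized(self) -> RTProfile:
        return self.profiles["normalized"]


def run_pipeline(g1_reads: pd.DataFrame, s_reads: pd.DataFrame,
                 layout: GenomeLayout, config: PipelineConfig | None = None) -> PipelineResult:
    """Filter both read sets, then window / bin / filter / smooth / normalize."""
    from . import reads as rp

    config = config or PipelineConfig()
    audit, counts = {}, {}
    filtered = {}
    for name, rs in (("G1", g1_reads), ("S", s_reads)):
        rs = rp.mark_duplicates(rs, mode=config.dedup_mode)
        rs = rp.filter_poorly_mapped(rs, min_mapq=config.min_mapq)
        rs, high = rp.filter_high_coverage_bins(rs, layout, bin_size=config.high_cov_bin)
        rs, low = rp.filter_low_coverage_bins(rs, layout, bin_size=config.low_cov_bin)
        audit[name] = {"high": high, "low": low}
        counts[name] = {"total": len(rs), "duplicates": int(rs["is_dup"].sum()),
                        "poorly_mapped": int(rs["is_poor"].sum()),
                        "in_excluded": int(rs["in_excluded"].sum()),
                        "passing": int(passing_mask(rs).sum())}
        filtered[name] = rs
    # the exclusion mask is shared between the fractions: a bin untrustworthy
    # in either sample must not contribute to the S/G1 ratio in both
    exclusion = pd.concat([audit[s][t].excluded for s in ("G1", "S")
                           for t in ("high", "low")], ignore_index=True)
    for name in filtered:
        filtered[name] = rp.flag_reads_in_regions(filtered[name],
                                                  exclusion[["chrom", "start", "end"]])
        counts[name]["in_excluded"] = int(filtered[name]["in_excluded"].sum())
        counts[name]["passing"] = int(passing_mask(filtered[name]).sum())
    windows = define_g1_windows(filtered["G1"], layout, config,
                                exclusion_intervals=exclusion)
    raw = bin_s_reads(windows, filtered["S"])
    filt = segment_filter(raw, config)
    smooth = smooth_profile(filt, config)
    norm = normalize_profile(smooth, layout, config)
    return PipelineResult(windows=windows,
                          profiles={"raw": raw, "filtered": filt,
                                    "smoothed": smooth, "normalized": norm},
                          filter_audit=audit, counts=counts)
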