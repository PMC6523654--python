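"""Centromere-level inference on a normalized replication-timing profile.

Covers the inclusion criterion (at least 10 G1-defined windows per megabase on
average), fixed 100-bin aggregation of each centromere with a cross-centromere
mean and min/max envelope, and pericentromere-anchored overlays.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .genome import GenomeLayout
from .profiling import PipelineConfig, RTProfile

log = logging.getLogger(__name__)


@dataclass
class CentromereProfile:
    """One centromere's window support and inclusion decision."""

    chrom: str
    start: int
    end: int
    n_windows: int
    window_density: float       # windows per Mb
    included: bool

    @property
    def length(self) -> int:
        return self.end - self.start


def assess_centromere_coverage(windows: pd.DataFrame, layout: GenomeLayout,
                               config: PipelineConfig | None = None) -> list[CentromereProfile]:
    """Decide, per centromere, whether enough G1 windows landed inside it.

    Membership is by window midpoint; a centromere is included when its
    average window density reaches the configured threshold (default 10
    windows per Mb, i.e. 1100 reads per Mb at the default window geometry).
    Chromosomes without a centromere annotation are skipped with a note.
    """
    config = config or PipelineConfig()
    out = []
    for chrom, _length in layout.chromosomes:
        cen = layout.centromere(chrom)
        if cen is None:
            log.info("no centromere annotated on %s; skipped", chrom)
            continue
        start, end = cen
        mids = windows.loc[windows["chrom"] == chrom, "midpoint"].to_numpy()
        n = int(((mids >= start) & (mids < end)).sum())
        density = n / ((end - start) / 1e6)
        out.append(CentromereProfile(chrom=chrom, start=start, end=end, n_windows=n,
                                     window_density=density,
                                     included=density >= config.centromere_min_density))
    return out


def inclusion_table(profiles: list[CentromereProfile]) -> pd.DataFrame:
    """Per-chromosome inclusion report (the mappability summary table)."""
    return pd.DataFrame([{"chrom": c.chrom, "start": c.start, "end": c.end,
                          "n_windows": c.n_windows,
                          "windows_per_mb": c.window_density,
                          "included": c.included} for c in profiles])


def aggregate_centromere(profile: RTProfile, cen: CentromereProfile,
                         config: PipelineConfig | None = None) -> np.ndarray:
    """Average window values into 100 equal-width bins across one centromere.

    Bin b covers ``[start + b*L/100, start + (b+1)*L/100)``; bins with no
    member window are NaN (missing, never interpolated — interpolation would
    manufacture signal where mappability failed).
    """
    config = config or PipelineConfig()
    if not cen.included:
        raise ConfigError(f"centromere on {cen.chrom} is not included "
                          f"({cen.window_density:.2f} windows/Mb)")
    if profile.stage != "normalized":
        raise ConfigError("aggregation expects a normalized profile")
    nb = config.aggregation_bins
    sub = profile.values_on(cen.chrom)
    mids = sub["midpoint"].to_numpy(dtype=float)
    vals = sub["value"].to_numpy(dtype=float)
    inside = (mids >= cen.start) & (mids < cen.end)
    frac = (mids[inside] - cen.start) / (cen.end - cen.start)
    bins = np.minimum((frac * nb).astype(int), nb - 1)
    agg = np.full(nb, np.nan)
    if inside.any():
        sums = np.bincount(bins, weights=vals[inside], minlength=nb)
        n = np.bincount(bins, minlength=nb)
        agg[n > 0] = sums[n > 0] / n[n > 0]
    return agg


@dataclass
class CentromereAggregate:
    """Per-centromere bin vectors plus the cross-centromere envelope."""

    per_centromere: dict            # chrom -> 100-bin vector (NaN = missing)
    mean: np.ndarray
    min: np.ndarray
    max: np.ndarray


def aggregate_across_centromeres(vectors: dict[str, np.ndarray] | list[np.ndarray]
                                 ) -> CentromereAggregate:
    """Bin-wise mean/min/max over non-missing entries of the input vectors."""
    if isinstance(vectors, dict):
        named = vectors
    else:
        named = {str(i): v for i, v in enumerate(vectors)}
    if not named:
        raise ConfigError("no centromere vectors to aggregate")
    stack = np.vstack(list(named.values()))
    with warnings.catch_warnings():
        # bins missing in every centromere legitimately stay NaN
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
        vmin = np.nanmin(stack, axis=0)
        vmax = np.nanmax(stack, axis=0)
    return CentromereAggregate(per_centromere=dict(named), mean=mean, min=vmin, max=vmax)


def pericentromere_overlay(profile: RTProfile, cen: CentromereProfile, flank: int,
                           layout: GenomeLayout,
                           config: PipelineConfig | None = None) -> pd.DataFrame:
    """Profile in a centromere-anchored frame: flank / rescaled body / flank.

    The frame is ``[-flank, 0)`` bp left of the centromere start (50 bins of
    width flank/50), the centromere body rescaled to [0, 1) in 100 bins, and
    ``[0, flank)`` bp right of the end (50 bins).  Values are means of window
    values per bin; flanks extending past the chromosome end are truncated.
    Returns columns section (left/cen/right), bin, lo, hi (genomic bp), value.
    With ``flank=0`` the result is exactly the 100-bin aggregate.
    """
    config = config or PipelineConfig()
    if not cen.included:
        raise ConfigError(f"centromere on {cen.chrom} is not included")
    if flank < 0:
        raise ConfigError("flank must be non-negative")
    length = layout.lengths[cen.chrom]
    sub = profile.values_on(cen.chrom)
    mids = sub["midpoint"].to_numpy(dtype=float)
    vals = sub["value"].to_numpy(dtype=float)

    def _bin_means(lo_edges, hi_edges):
        out = np.full(len(lo_edges), np.nan)
        for i, (lo, hi) in enumerate(zip(lo_edges, hi_edges)):
            if hi <= lo:
                continue
            sel = (mids >= lo) & (mids < hi)
            if sel.any():
                out[i] = vals[sel].mean()
        return out

    rows = []
    if flank > 0:
        left_lo = cen.start - flank + np.arange(50) * (flank / 50)
        left_hi = left_lo + flank / 50
        trunc = left_lo < 0
        if trunc.any():
            log.info("left flank of %s truncated at chromosome start", cen.chrom)
        left_lo, left_hi = np.clip(left_lo, 0, None), np.clip(left_hi, 0, None)
        for b, (lo, hi, v) in enumerate(zip(left_lo, left_hi, _bin_means(left_lo, left_hi))):
            rows.append(("left", b, lo, hi, v))
    nb = config.aggregation_bins
    cen_lo = cen.start + np.arange(nb) * (cen.length / nb)
    cen_hi = cen_lo + cen.length / nb
    for b, (lo, hi, v) in enumerate(zip(cen_lo, cen_hi, _bin_means(cen_lo, cen_hi))):
        rows.append(("cen", b, lo, hi, v))
    if flank > 0:
        right_lo = cen.end + np.arange(50) * (flank / 50)
        right_hi = right_lo + flank / 50
        if (right_hi > length).any():
            log.info("right flank of %s truncated at chromosome end", cen.chrom)
        right_lo, right_hi = np.clip(right_lo, None, length), np.clip(right_hi, None, length)
        for b, (lo, hi, v) in enumerate(zip(right_lo, right_hi, _bin_means(right_lo, right_hi))):
            rows.append(("right", b, lo, hi, v))
    return pd.DataFrame(rows, columns=["section", "bin", "lo", "hi", "value"])


def average_overlays(overlays: list[pd.DataFrame]) -> pd.DataFrame:
    """Bin-wise nanmean of centromere-anchored overlays (same frame required)."""
    if not overlays:
        raise ConfigError("no overlays to average")
    base = overlays[0][["section", "bin"]].copy()
    stack = np.vstack([o["value"].to_numpy(dtype=float) for o in overlays])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        base["value"] = np.nanmean(stack, axis=0)
    return base
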