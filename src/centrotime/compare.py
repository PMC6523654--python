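"""Cross-sample correlation statistics and matched null controls.

Two samples never share windows (each sample's windows come from its own G1
reads), so profiles are matched by linear interpolation onto a shared uniform
grid (default 10 kb) restricted to loci covered by a profile segment in both
samples.  Correlations are then computed per region: whole chromosomes
excluding the centromere, individual centromeres, or random matched controls
(size-matched intervals, or runs matched on the number of shared grid
points).
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, PipelineError
from .genome import GenomeLayout
from .profiling import RTProfile

log = logging.getLogger(__name__)

GRID_STEP = 10_000
MIN_SHARED = 3

CORR_COLUMNS = ["sample_a", "sample_b", "region_id", "region_class",
                "n_shared_windows", "pearson_r"]


def profile_grid(profile: RTProfile, layout: GenomeLayout,
                 grid_step: int = GRID_STEP) -> dict[str, np.ndarray]:
    """Resample a profile onto a fixed genome grid; NaN where uncovered."""
    grids = {}
    for chrom, length in layout.chromosomes:
        g = np.full(length // grid_step + 1, np.nan)
        sub = profile.values_on(chrom)
        for _, seg in sub.groupby("seg_id", sort=False):
            x = seg["midpoint"].to_numpy(dtype=float)
            y = seg["value"].to_numpy(dtype=float)
            if len(x) < 2:
                continue
            lo = int(np.ceil(x[0] / grid_step))
            hi = int(np.floor(x[-1] / grid_step))
            if hi >= lo:
                g[lo:hi + 1] = np.interp(np.arange(lo, hi + 1) * grid_step, x, y)
        grids[chrom] = g
    return grids


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    with np.errstate(invalid="ignore"):
        return float(np.corrcoef(a, b)[0, 1])


def _region_r(ga: dict, gb: dict, chrom: str, start: float, end: float,
              grid_step: int) -> tuple[float, int]:
    lo = int(np.ceil(start / grid_step))
    hi = int(np.floor(end / grid_step))
    a = ga[chrom][lo:hi + 1]
    b = gb[chrom][lo:hi + 1]
    ok = np.isfinite(a) & np.isfinite(b)
    n = int(ok.sum())
    if n < MIN_SHARED:
        return np.nan, n
    return _pearson(a[ok], b[ok]), n


def pairwise_region_correlation(a: RTProfile, b: RTProfile, regions: pd.DataFrame,
                                class_label: str, layout: GenomeLayout,
                                sample_a: str = "a", sample_b: str = "b",
                                grid_step: int = GRID_STEP) -> pd.DataFrame:
    """Pearson r between two profiles in each region, on the shared grid.

    ``regions`` needs columns chrom/start/end and optionally ``name``.
    Regions with fewer than 3 shared grid points are omitted (logged).
    """
    ga = profile_grid(a, layout, grid_step)
    gb = profile_grid(b, layout, grid_step)
    rows = []
    for i, row in enumerate(regions.itertuples(index=False)):
        r, n = _region_r(ga, gb, row.chrom, row.start, row.end, grid_step)
        rid = getattr(row, "name", f"{row.chrom}:{row.start}-{row.end}")
        if not np.isfinite(r):
            log.info("region %s: only %d shared grid points; omitted", rid, n)
            continue
        rows.append((sample_a, sample_b, rid, class_label, n, r))
    return pd.DataFrame(rows, columns=CORR_COLUMNS)


def chromosome_regions(layout: GenomeLayout, exclude_centromeres: bool = True) -> pd.DataFrame:
    """Whole-chromosome regions; with exclusion, both arms share the region id
    so the correlation pools all non-centromeric windows of the chromosome."""
    rows = []
    for chrom, length in layout.chromosomes:
        cen = layout.centromere(chrom) if exclude_centromeres else None
        if cen is None:
            rows.append({"chrom": chrom, "start": 0, "end": length, "name": chrom})
        else:
            rows.append({"chrom": chrom, "start": 0, "end": cen[0], "name": chrom})
            rows.append({"chrom": chrom, "start": cen[1], "end": length, "name": chrom})
    return pd.DataFrame(rows)


def _pooled_region_r(ga, gb, parts: pd.DataFrame, grid_step: int) -> tuple[float, int]:
    """r over the concatenation of several sub-intervals (e.g. two arms)."""
    avals, bvals = [], []
    for row in parts.itertuples(index=False):
        lo = int(np.ceil(row.start / grid_step))
        hi = int(np.floor(row.end / grid_step))
        avals.append(ga[row.chrom][lo:hi + 1])
        bvals.append(gb[row.chrom][lo:hi + 1])
    a = np.concatenate(avals)
    b = np.concatenate(bvals)
    ok = np.isfinite(a) & np.isfinite(b)
    n = int(ok.sum())
    if n < MIN_SHARED:
        return np.nan, n
    return _pearson(a[ok], b[ok]), n


def correlation_table(profiles: dict[str, RTProfile], layout: GenomeLayout,
                      grid_step: int = GRID_STEP) -> pd.DataFrame:
    """The full cross-sample table: per-chromosome (arms, centromere excluded)
    and per-centromere correlations for every sample pair."""
    grids = {name: profile_grid(p, layout, grid_step) for name, p in profiles.items()}
    chrom_regions = chromosome_regions(layout, exclude_centromeres=True)
    rows = []
    for (na, ga), (nb, gb) in itertools.combinations(grids.items(), 2):
        for chrom_name, parts in chrom_regions.groupby("name", sort=False):
            r, n = _pooled_region_r(ga, gb, parts, grid_step)
            if np.isfinite(r):
                rows.append((na, nb, chrom_name, "chromosome_ex_centromere", n, r))
        for row in layout.centromeres.itertuples(index=False):
            r, n = _region_r(ga, gb, row.chrom, row.start, row.end, grid_step)
            if np.isfinite(r):
                rows.append((na, nb, f"cen_{row.chrom}", "centromere", n, r))
    return pd.DataFrame(rows, columns=CORR_COLUMNS)


# ---------------------------------------------------------------------------
# matched nulls
# ---------------------------------------------------------------------------

def _valid_placements(layout: GenomeLayout, length: int) -> list[tuple[str, int, int]]:
    """Start ranges [lo, hi] for a length-bp interval avoiding centromeres."""
    spans = []
    for chrom, clen in layout.chromosomes:
        cen = layout.centromere(chrom)
        segments = [(0, clen)] if cen is None else [(0, cen[0]), (cen[1], clen)]
        for a, b in segments:
            if b - a >= length:
                spans.append((chrom, a, b - length))
    return spans


def size_matched_null(profiles: dict[str, RTProfile], centromere_lengths: list[int],
                      layout: GenomeLayout, n_draws: int = 1000, seed: int = 0,
                      grid_step: int = GRID_STEP) -> pd.DataFrame:
    """Null correlations from random non-centromeric intervals of matched size.

    Each draw samples, for every requested length, an interval uniformly over
    all valid non-centromeric placements genome-wide and records the pairwise
    correlations there.  Draws with too few shared grid points are redrawn (up
    to 100 times) before being skipped.
    """
    if len(profiles) < 2:
        raise ConfigError("need at least two profiles for a null")
    rng = np.random.default_rng(seed)
    grids = {name: profile_grid(p, layout, grid_step) for name, p in profiles.items()}
    pairs = list(itertools.combinations(grids.items(), 2))
    rows = []
    for d in range(n_draws):
        for length in centromere_lengths:
            spans = _valid_placements(layout, length)
            if not spans:
                raise PipelineError(f"no chromosome can host a {length} bp interval "
                                    "outside a centromere")
            weights = np.array([hi - lo + 1 for _, lo, hi in spans], dtype=float)
            for _attempt in range(100):
                j = rng.choice(len(spans), p=weights / weights.sum())
                chrom, lo, hi = spans[j]
                start = int(rng.integers(lo, hi + 1))
                got = []
                for (na, ga), (nb, gb) in pairs:
                    r, n = _region_r(ga, gb, chrom, start, start + length, grid_step)
                    if np.isfinite(r):
                        got.append((na, nb, f"draw{d}_{chrom}:{start}", "random_matched", n, r))
                if got:
                    rows.extend(got)
                    break
    return pd.DataFrame(rows, columns=CORR_COLUMNS)


def window_count_matched_null(profiles: dict[str, RTProfile],
                              centromere_window_counts: list[int],
                              layout: GenomeLayout, n_draws: int = 1000,
                              seed: int = 0, grid_step: int = GRID_STEP) -> pd.DataFrame:
    """Null correlations from random runs of exactly k shared grid points.

    Controls for the small number of centromeric windows: for each requested
    count k, a contiguous non-centromeric run of exactly k grid points shared
    by the pair is sampled (uniformly over all placements) per draw.
    """
    if len(profiles) < 2:
        raise ConfigError("need at least two profiles for a null")
    rng = np.random.default_rng(seed)
    grids = {name: profile_grid(p, layout, grid_step) for name, p in profiles.items()}
    cen_mask = {}
    for chrom, length in layout.chromosomes:
        m = np.zeros(length // grid_step + 1, dtype=bool)
        cen = layout.centromere(chrom)
        if cen is not None:
            lo = int(np.ceil(cen[0] / grid_step))
            hi = int(np.floor(cen[1] / grid_step))
            m[lo:hi + 1] = True
        cen_mask[chrom] = m
    pairs = list(itertools.combinations(grids.items(), 2))
    rows = []
    for (na, ga), (nb, gb) in pairs:
        runs = []  # (chrom, run start index, run length)
        for chrom in ga:
            ok = np.isfinite(ga[chrom]) & np.isfinite(gb[chrom]) & ~cen_mask[chrom]
            edges = np.diff(np.concatenate([[0], ok.view(np.int8), [0]]))
            for s, e in zip(np.flatnonzero(edges == 1), np.flatnonzero(edges == -1)):
                runs.append((chrom, int(s), int(e - s)))
        for k in centromere_window_counts:
            fits = [(c, s, ln) for c, s, ln in runs if ln >= k]
            if not fits:
                raise PipelineError(f"no shared run of {k} grid points for pair "
                                    f"({na}, {nb})")
            weights = np.array([ln - k + 1 for _, _, ln in fits], dtype=float)
            for d in range(n_draws):
                j = rng.choice(len(fits), p=weights / weights.sum())
                chrom, s, ln = fits[j]
                off = int(rng.integers(0, ln - k + 1))
                a = ga[chrom][s + off:s + off + k]
                b = gb[chrom][s + off:s + off + k]
                rows.append((na, nb, f"draw{d}_k{k}_{chrom}", "random_matched", k,
                             _pearson(a, b)))
    return pd.DataFrame(rows, columns=CORR_COLUMNS)


def compare_distributions(observed: pd.DataFrame, null: pd.DataFrame) -> dict:
    """Two-sample KS test of the observed r-distribution against the null.

    Also reports the SD ratio (observed / null), the headline summary of
    how much broader the centromere correlations are than expected.  Refuses
    with fewer than 5 observations on either side.
    """
    obs = np.asarray(observed["pearson_r"] if "pearson_r" in observed else observed,
                     dtype=float)
    nul = np.asarray(null["pearson_r"] if "pearson_r" in null else null, dtype=float)
    obs, nul = obs[np.isfinite(obs)], nul[np.isfinite(nul)]
    if len(obs) < 5 or len(nul) < 5:
        raise ConfigError("need at least 5 correlations on each side")
    ks = stats.ks_2samp(obs, nul)
    null_sd = nul.std()
    return {"ks_statistic": float(ks.statistic), "p_value": float(ks.pvalue),
            "n_observed": len(obs), "n_null": len(nul),
            "observed_sd": float(obs.std()), "null_sd": float(null_sd),
            "sd_ratio": float(obs.std() / null_sd) if null_sd > 0 else float("inf")}
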