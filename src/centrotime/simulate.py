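"""Synthetic genomes, replication-timing ground truth, and G1/S read sets.

The generator emulates the statistical structure of a sort-seq experiment:

* a G1 fraction sampled uniformly along each chromosome (every locus at the
  same copy number),
* an S fraction whose sampling density is proportional to ``1 + p(x)`` where
  ``p(x)`` in [0, 1] is the expected replicated fraction at locus ``x`` —
  early-replicating loci approach 2x copy number, late ones stay near 1x,
* centromeric repeat arrays that collapse many true fragments onto a small
  set of shared "alignable" read-1 coordinates (with low mapping quality at a
  configurable rate), the phenomenon that makes single-end duplicate marking
  destroy centromeric signal,
* injected PCR and optical duplicates (exact endpoint copies of a source
  fragment).

Every record carries its true origin and an ``artifact_class`` label so the
downstream filters can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.stats import rankdata

from .errors import ConfigError, SizingError
from .genome import GenomeLayout
from .reads import new_read_set

TRUTH_GRID_STEP = 1_000  # bp between ground-truth evaluation points

#: minimum fragment length the generator emits (one read length)
MIN_FRAGMENT = 100


# ---------------------------------------------------------------------------
# toy genome
# ---------------------------------------------------------------------------

def build_toy_genome(n_chrom: int = 2, chrom_length: int = 10_000_000,
                     centromere_span: int = 1_000_000, unit_length: int = 171,
                     n_distinct_units: int = 50, seed: int = 0) -> GenomeLayout:
    """Build a toy genome with one mid-chromosome centromere per chromosome.

    Each centromere is a single repeat array tiled by ``unit_length`` bp units
    of which only ``n_distinct_units`` are distinguishable to an aligner.  The
    layout is fully deterministic; ``seed`` is accepted for interface symmetry
    with the stochastic generators.
    """
    if n_chrom <= 0 or chrom_length <= 0 or centromere_span <= 0 or unit_length <= 0 \
            or n_distinct_units <= 0:
        raise SizingError("all toy-genome dimensions must be positive")
    if centromere_span >= chrom_length:
        raise SizingError(
            f"centromere span {centromere_span} does not fit in chromosome of "
            f"length {chrom_length}")
    chroms = [(f"chr{i + 1}", chrom_length) for i in range(n_chrom)]
    cen_start = (chrom_length - centromere_span) // 2
    n_units = centromere_span // unit_length
    cen_end = cen_start + max(n_units, 1) * unit_length  # truncate to unit multiples
    cen_end = min(cen_end, cen_start + centromere_span)
    cen = pd.DataFrame({"chrom": [c for c, _ in chroms],
                        "start": cen_start, "end": cen_end})
    rep = cen.assign(unit_length=unit_length,
                     n_distinct_units=min(n_distinct_units, max(n_units, 1)))
    return GenomeLayout(chromosomes=chroms, centromeres=cen, repeat_arrays=rep)


# ---------------------------------------------------------------------------
# ground-truth replication timing
# ---------------------------------------------------------------------------

@dataclass
class RTTruth:
    """Ground-truth timing and replicated fraction on a per-chromosome grid.

    ``grid`` has columns ``chrom, pos, timing, p``: ``timing`` is a smooth
    arbitrary-scale signal (higher = earlier replication) and ``p`` is its
    rank-rescaled transform into [p_min, p_max] — the expected excess copy
    fraction in the S-phase sample.
    """

    grid: pd.DataFrame
    p_min: float = 0.05
    p_max: float = 0.95

    def chrom_grid(self, chrom: str) -> pd.DataFrame:
        sub = self.grid[self.grid["chrom"] == chrom]
        if sub.empty:
            raise ConfigError(f"truth has no chromosome {chrom!r}")
        return sub

    def p_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        sub = self.chrom_grid(chrom)
        return np.interp(pos, sub["pos"].to_numpy(), sub["p"].to_numpy())

    def timing_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        sub = self.chrom_grid(chrom)
        return np.interp(pos, sub["pos"].to_numpy(), sub["timing"].to_numpy())


def _rank_rescale(timing: np.ndarray, p_min: float, p_max: float) -> np.ndarray:
    """Monotone map of timing onto [p_min, p_max] via average ranks."""
    n = len(timing)
    if n == 1 or np.ptp(timing) == 0:
        return np.full(n, 0.5 * (p_min + p_max))
    u = (rankdata(timing, method="average") - 1) / (n - 1)
    return p_min + (p_max - p_min) * u


def simulate_rt_truth(layout: GenomeLayout, n_control_points: int = 20,
                      amplitude: float = 1.0, seed: int = 0,
                      p_min: float = 0.05, p_max: float = 0.95,
                      correlation_length: float = 2_000_000.0) -> RTTruth:
    """Draw a smooth, megabase-scale autocorrelated timing landscape.

    Control points are evenly spaced along each chromosome; their values are
    drawn from a stationary Gaussian process with a squared-exponential
    kernel (``correlation_length`` bp, default 2 Mb — the scale over which
    real timing profiles stay strongly autocorrelated), standardized per
    chromosome, scaled by ``amplitude`` and interpolated with a cubic spline.
    ``amplitude=0`` yields a flat landscape.
    """
    if n_control_points < 2:
        raise ConfigError("need at least 2 control points")
    rng = np.random.default_rng(seed)
    frames = []
    for chrom, length in layout.chromosomes:
        xc = np.linspace(0, length, n_control_points)
        d = xc[:, None] - xc[None, :]
        cov = np.exp(-0.5 * (d / correlation_length) ** 2)
        cov += 1e-9 * np.eye(n_control_points)
        gp = np.linalg.cholesky(cov) @ rng.standard_normal(n_control_points)
        sd = gp.std()
        values = amplitude * (gp - gp.mean()) / (sd if sd > 0 else 1.0)
        grid = np.arange(0, length, TRUTH_GRID_STEP)
        timing = CubicSpline(xc, values)(grid)
        frames.append(pd.DataFrame({"chrom": chrom, "pos": grid, "timing": timing}))
    grid = pd.concat(frames, ignore_index=True)
    grid["p"] = _rank_rescale(grid["timing"].to_numpy(), p_min, p_max)
    return RTTruth(grid=grid, p_min=p_min, p_max=p_max)


def resample_centromere_truth(truth: RTTruth, layout: GenomeLayout, seed: int,
                              n_control_points: int = 20, amplitude: float = 1.0) -> RTTruth:
    """Replace the timing landscape inside every centromere with a fresh draw.

    Used to emulate a panel of cell lines sharing chromosome-arm timing while
    their centromeres replicate independently.  ``p`` is recomputed over the
    spliced landscape.
    """
    fresh = simulate_rt_truth(layout, n_control_points=n_control_points,
                              amplitude=amplitude, seed=seed,
                              p_min=truth.p_min, p_max=truth.p_max)
    grid = truth.grid.copy()
    for row in layout.centromeres.itertuples(index=False):
        mask = ((grid["chrom"] == row.chrom) & (grid["pos"] >= row.start)
                & (grid["pos"] < row.end)).to_numpy()
        donor = ((fresh.grid["chrom"] == row.chrom) & (fresh.grid["pos"] >= row.start)
                 & (fresh.grid["pos"] < row.end)).to_numpy()
        grid.loc[mask, "timing"] = fresh.grid.loc[donor, "timing"].to_numpy()
    grid["p"] = _rank_rescale(grid["timing"].to_numpy(), truth.p_min, truth.p_max)
    return RTTruth(grid=grid, p_min=truth.p_min, p_max=truth.p_max)


def truth_recovery_r(profile, truth: RTTruth) -> float:
    """Pearson r between a profile and the standardized replicated fraction.

    The benchmark of the whole pipeline: the inferred profile is compared to
    the z-scored ground-truth ``p`` evaluated at the profile's window
    midpoints (``p``, not raw timing, is what S/G1 read depth measures).
    """
    vals, tv = [], []
    for chrom in profile.data["chrom"].unique():
        sub = profile.values_on(chrom)
        vals.append(sub["value"].to_numpy(dtype=float))
        tv.append(truth.p_at(chrom, sub["midpoint"].to_numpy(dtype=float)))
    v = np.concatenate(vals)
    t = np.concatenate(tv)
    t = (t - t.mean()) / t.std()
    return float(np.corrcoef(v, t)[0, 1])


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _sample_positions(rng, chrom_grid: pd.DataFrame, n: int, phase: str) -> np.ndarray:
    """Draw fragment read-1 5' positions with density 1 (G1) or 1+p (S)."""
    pos = chrom_grid["pos"].to_numpy()
    if phase == "G1":
        return rng.uniform(pos[0], pos[-1] + TRUTH_GRID_STEP, size=n)
    dens = 1.0 + chrom_grid["p"].to_numpy()
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]) * np.diff(pos))])
    u = rng.uniform(0, cdf[-1], size=n)
    return np.interp(u, cdf, pos)


def _collapse_repeats(layout: GenomeLayout, chrom: str, r1: np.ndarray,
                      rng: np.random.Generator, repeat_mapq_low_prob: float,
                      mapq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map read-1 coordinates inside repeat arrays onto their nearest anchor.

    Each array exposes ``n_distinct_units`` alignable anchors spaced evenly
    (unit-aligned) across it; every true fragment is reported at the nearest
    anchor, so fragments from many distinct repeat units share an identical
    read-1 coordinate while their mate coordinates still reflect the true
    fragment length.  Returns (reported r1, collapsed mask).
    """
    reported = r1.copy()
    collapsed = np.zeros(len(r1), dtype=bool)
    arrays = layout.repeat_arrays[layout.repeat_arrays["chrom"] == chrom]
    for row in arrays.itertuples(index=False):
        inside = (r1 >= row.start) & (r1 < row.end)
        if not inside.any():
            continue
        n_units = max((row.end - row.start) // row.unit_length, 1)
        n_anchor = min(row.n_distinct_units, n_units)
        anchor_units = np.unique(np.round(np.linspace(0, n_units - 1, n_anchor)).astype(int))
        anchors = row.start + anchor_units * row.unit_length
        idx = np.clip(np.searchsorted(anchors, r1[inside]), 1, len(anchors) - 1)
        left = anchors[idx - 1]
        right = anchors[idx]
        nearest = np.where(r1[inside] - left <= right - r1[inside], left, right)
        reported[inside] = nearest
        collapsed[inside] = True
        low = rng.random(int(inside.sum())) < repeat_mapq_low_prob
        mapq[np.flatnonzero(inside)[low]] = 0
    return reported, collapsed


def simulate_reads(layout: GenomeLayout, truth: RTTruth, phase: str,
                   n_fragments: int = 1_000_000, fragment_length_mean: int = 400,
                   pcr_dup_rate: float = 0.02, optical_dup_rate: float = 0.01,
                   repeat_mapq_low_prob: float = 0.85, seed: int = 0) -> pd.DataFrame:
    """Simulate one sorted-fraction read set (coordinate-sorted output).

    Returns a read set with the standard columns plus ``origin_pos`` and
    ``artifact_class``.  Fragment counts per chromosome are multinomial with
    weights proportional to total sampling mass (length for G1, integral of
    ``1+p`` for S); fragment lengths are normal with 10% SD, truncated at one
    read length; strands are random.
    """
    if phase not in ("G1", "S"):
        raise ConfigError(f"phase must be 'G1' or 'S', got {phase!r}")
    if n_fragments <= 0:
        raise ConfigError("n_fragments must be positive")
    for r in (pcr_dup_rate, optical_dup_rate, repeat_mapq_low_prob):
        if not 0.0 <= r <= 1.0:
            raise ConfigError("rates must be probabilities in [0, 1]")
    present = set(truth.grid["chrom"].unique())
    missing = [c for c in layout.names if c not in present]
    if missing:
        raise ConfigError(f"truth is missing chromosomes: {missing}")

    rng = np.random.default_rng(seed)
    weights = []
    for chrom, length in layout.chromosomes:
        if phase == "G1":
            weights.append(float(length))
        else:
            sub = truth.chrom_grid(chrom)
            weights.append(float(np.trapezoid(1.0 + sub["p"].to_numpy(),
                                              sub["pos"].to_numpy())))
    weights = np.asarray(weights)
    per_chrom = rng.multinomial(n_fragments, weights / weights.sum())

    parts = []
    for (chrom, length), n in zip(layout.chromosomes, per_chrom):
        if n == 0:
            continue
        sub = truth.chrom_grid(chrom)
        r1_true = np.floor(_sample_positions(rng, sub, n, phase)).astype(np.int64)
        r1_true = np.clip(r1_true, 0, length - 1)
        flen = np.round(rng.normal(fragment_length_mean, 0.1 * fragment_length_mean, n))
        flen = np.maximum(flen, MIN_FRAGMENT).astype(np.int64)
        strand = np.where(rng.random(n) < 0.5, "+", "-")
        mapq = np.full(n, 60, dtype=np.int64)
        r1_rep, collapsed = _collapse_repeats(layout, chrom, r1_true, rng,
                                              repeat_mapq_low_prob, mapq)
        start = np.where(strand == "+", r1_rep, r1_rep - flen)
        start = np.clip(start, 0, None)
        end = np.minimum(start + flen, length)
        start = np.minimum(start, end - 1)
        cls = np.where(collapsed, "repeat_collapsed", "unique")
        parts.append(new_read_set(chrom, start, end, strand, mapq, paired=True,
                                  origin_pos=r1_true, artifact_class=cls))
    base = pd.concat(parts, ignore_index=True)

    dups = []
    for rate, label in [(pcr_dup_rate, "pcr_duplicate"),
                        (optical_dup_rate, "optical_duplicate")]:
        if rate > 0:
            pick = rng.random(len(base)) < rate
            if pick.any():
                d = base.loc[pick].copy()
                d["artifact_class"] = label
                dups.append(d)
    allreads = pd.concat([base] + dups, ignore_index=True)
    order = np.lexsort((allreads["end"].to_numpy(), allreads["start"].to_numpy(),
                        allreads["chrom"].to_numpy()))
    return allreads.iloc[order].reset_index(drop=True)
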