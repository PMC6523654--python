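"""Read-set container and the filtering stack applied before profiling.

A read set is a pandas DataFrame, one row per sequenced fragment (a full pair
in paired-end data, a single read otherwise) with columns:

``chrom``       reference name
``start, end``  fragment span, 0-based half-open, start < end
``strand``      orientation of read 1: ``+`` (5' end at ``start``) or ``-``
                (5' end at ``end``)
``mapq``        mapping quality, 0-60
``paired``      bool; when True the mate's 5' coordinate is the opposite
                fragment endpoint
``is_dup``      flagged as PCR/optical duplicate
``is_poor``     flagged as poorly mapped (below the MAPQ cutoff)
``in_excluded`` read-1 5' coordinate falls in a coverage-excluded bin

Simulated sets carry two extra columns, ``origin_pos`` (true pre-collapse
read-1 coordinate) and ``artifact_class`` (one of ``unique``,
``repeat_collapsed``, ``pcr_duplicate``, ``optical_duplicate``).

The filtering order used by the pipeline is: duplicate marking, then the MAPQ
filter, then the two coverage filters — duplicates must not inflate bin
coverage, and coverage is judged on reads that could actually be used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ModeError
from .genome import GenomeLayout

log = logging.getLogger(__name__)

READ_COLUMNS = ["chrom", "start", "end", "strand", "mapq", "paired",
                "is_dup", "is_poor", "in_excluded"]

FLAG_DEFAULTS = {"is_dup": False, "is_poor": False, "in_excluded": False}


def new_read_set(chrom, start, end, strand, mapq, paired=True, **extra) -> pd.DataFrame:
    """Assemble a read set from per-column arrays, with flags cleared."""
    df = pd.DataFrame({"chrom": chrom, "start": np.asarray(start, dtype=np.int64),
                       "end": np.asarray(end, dtype=np.int64), "strand": strand,
                       "mapq": np.asarray(mapq, dtype=np.int64), "paired": paired})
    for col, default in FLAG_DEFAULTS.items():
        df[col] = default
    for col, values in extra.items():
        df[col] = values
    return df


def read1_position(reads: pd.DataFrame) -> np.ndarray:
    """5' coordinate of read 1 per fragment (start on +, end on -)."""
    return np.where(reads["strand"].to_numpy() == "+",
                    reads["start"].to_numpy(), reads["end"].to_numpy())


def mate_position(reads: pd.DataFrame) -> np.ndarray:
    """5' coordinate of the mate (the opposite fragment endpoint)."""
    return np.where(reads["strand"].to_numpy() == "+",
                    reads["end"].to_numpy(), reads["start"].to_numpy())


def passing_mask(reads: pd.DataFrame) -> np.ndarray:
    """Reads surviving every filter applied so far."""
    return (~reads["is_dup"] & ~reads["is_poor"] & ~reads["in_excluded"]).to_numpy()


# ---------------------------------------------------------------------------
# duplicate marking
# ---------------------------------------------------------------------------

def mark_duplicates(reads: pd.DataFrame, mode: str = "paired") -> pd.DataFrame:
    """Flag PCR/optical duplicate candidates, keeping one survivor per group.

    In ``single`` mode a duplicate group is every set of fragments sharing
    (chrom, read-1 5' coordinate, strand) — all the information single-end
    sequencing retains.  In ``paired`` mode the mate's 5' coordinate joins the
    key, so fragments of different lengths landing on the same repeat-collapsed
    coordinate are *not* confounded with true duplicates.  The survivor is the
    highest-MAPQ record, ties broken by lowest start then end coordinate,
    strand, then input order — so the surviving fragment set is invariant
    under shuffling of the input.  Input row order is preserved.
    """
    if mode not in ("single", "paired"):
        raise ModeError(f"unknown duplicate-marking mode {mode!r}")
    out = reads.copy()
    if out.empty:
        return out
    if mode == "paired" and not reads["paired"].all():
        raise ModeError("paired-mode duplicate marking requires paired records")

    key = pd.DataFrame({
        "chrom": reads["chrom"].to_numpy(),
        "r1": read1_position(reads),
        "strand": reads["strand"].to_numpy(),
    }, index=reads.index)
    if mode == "paired":
        key["mate"] = mate_position(reads)
    key["_mapq"] = -reads["mapq"].to_numpy()
    key["_start"] = reads["start"].to_numpy()
    key["_end"] = reads["end"].to_numpy()
    key["_order"] = np.arange(len(reads))

    ranked = key.sort_values(["_mapq", "_start", "_end", "strand", "_order"],
                             kind="stable")
    group_cols = ["chrom", "r1", "strand"] + (["mate"] if mode == "paired" else [])
    dup = ranked.duplicated(subset=group_cols, keep="first")
    out["is_dup"] = dup.reindex(reads.index).to_numpy()
    return out


# ---------------------------------------------------------------------------
# mapping-quality filter
# ---------------------------------------------------------------------------

def filter_poorly_mapped(reads: pd.DataFrame, min_mapq: int = 20) -> pd.DataFrame:
    """Flag records with ``mapq < min_mapq`` as poorly mapped."""
    out = reads.copy()
    newly = (out["mapq"] < min_mapq) & ~out["is_poor"]
    out["is_poor"] = out["is_poor"] | (out["mapq"] < min_mapq)
    log.info("mapq filter (<%d): %d newly flagged of %d", min_mapq, int(newly.sum()), len(out))
    return out


# ---------------------------------------------------------------------------
# coverage filters
# ---------------------------------------------------------------------------

@dataclass
class CoverageFilterResult:
    """Outcome of one coverage-based region filter."""

    excluded: pd.DataFrame          # chrom, start, end, count of the excluded bins
    threshold: float                # count at the percentile rank used
    bin_size: int
    tail: str                       # "high" or "low"
    bin_counts: pd.DataFrame = field(repr=False, default=None)  # full audit table

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


def _bin_counts(reads: pd.DataFrame, layout: GenomeLayout, bin_size: int) -> pd.DataFrame:
    # coverage is judged on dedup+mapq survivors; prior region exclusion by the
    # other coverage filter does not hide reads from this one
    use = reads.loc[~reads["is_dup"] & ~reads["is_poor"]]
    pos = read1_position(use)
    tab = (pd.DataFrame({"chrom": use["chrom"].to_numpy(), "bin": pos // bin_size})
           .groupby(["chrom", "bin"], sort=True).size().rename("count").reset_index())
    lengths = layout.lengths
    tab["start"] = tab["bin"] * bin_size
    tab["end"] = [min((b + 1) * bin_size, lengths[c]) for c, b in zip(tab["chrom"], tab["bin"])]
    return tab


def _apply_exclusion(reads: pd.DataFrame, excluded: pd.DataFrame, bin_size: int) -> pd.DataFrame:
    out = reads.copy()
    if excluded.empty:
        return out
    bad = set(zip(excluded["chrom"], excluded["start"] // bin_size))
    pos = read1_position(out)
    hit = np.fromiter(((c, b) in bad for c, b in zip(out["chrom"].to_numpy(), pos // bin_size)),
                      dtype=bool, count=len(out))
    out["in_excluded"] = out["in_excluded"].to_numpy() | hit
    return out


def filter_high_coverage_bins(reads: pd.DataFrame, layout: GenomeLayout,
                              bin_size: int = 100_000) -> tuple[pd.DataFrame, CoverageFilterResult]:
    """Exclude the top 1% highest-coverage fixed bins (repeat-collapse guard).

    The threshold is the nearest-rank 99th-percentile count over all non-empty
    bins genome-wide; bins strictly above it are excluded, so an all-tied
    genome excludes nothing.
    """
    return _coverage_filter(reads, layout, bin_size, tail="high")


def filter_low_coverage_bins(reads: pd.DataFrame, layout: GenomeLayout,
                             bin_size: int = 500_000) -> tuple[pd.DataFrame, CoverageFilterResult]:
    """Exclude the bottom 0.5% lowest-coverage fixed bins (mappability guard)."""
    return _coverage_filter(reads, layout, bin_size, tail="low")


def _coverage_filter(reads, layout, bin_size, tail):
    if reads.empty or not (~reads["is_dup"] & ~reads["is_poor"]).any():
        log.warning("coverage filter (%s): no usable reads", tail)
        empty = pd.DataFrame(columns=["chrom", "start", "end", "count"])
        return reads.copy(), CoverageFilterResult(empty, float("nan"), bin_size, tail, empty)
    tab = _bin_counts(reads, layout, bin_size)
    counts = np.sort(tab["count"].to_numpy())
    n = len(counts)
    if tail == "high":
        thr = counts[int(np.ceil(0.99 * n)) - 1]          # nearest-rank 99th pct
        mask = tab["count"] > thr
    else:
        thr = counts[min(int(np.floor(0.005 * n)), n - 1)]  # rank floor(0.005n)+1
        mask = tab["count"] < thr
    excluded = tab.loc[mask, ["chrom", "start", "end", "count"]].reset_index(drop=True)
    out = _apply_exclusion(reads, excluded, bin_size)
    return out, CoverageFilterResult(excluded, float(thr), bin_size, tail, tab)


def flag_reads_in_regions(reads: pd.DataFrame, intervals: pd.DataFrame) -> pd.DataFrame:
    """Set ``in_excluded`` for reads whose read-1 5' coordinate falls in any
    of the given intervals (chrom/start/end).  Used to share one exclusion
    mask between the G1 and S fractions of a sample."""
    out = reads.copy()
    if intervals is None or len(intervals) == 0:
        return out
    pos = read1_position(out)
    hit = np.zeros(len(out), dtype=bool)
    for chrom, sub in intervals.groupby("chrom", sort=False):
        sel = out["chrom"].to_numpy() == chrom
        if not sel.any():
            continue
        starts = np.sort(sub["start"].to_numpy())
        ends = sub.sort_values("start")["end"].to_numpy()
        idx = np.searchsorted(starts, pos[sel], side="right") - 1
        ok = idx >= 0
        inside = np.zeros(int(sel.sum()), dtype=bool)
        inside[ok] = pos[sel][ok] < ends[idx[ok]]
        hit[sel] = inside
    out["in_excluded"] = out["in_excluded"].to_numpy() | hit
    return out


# ---------------------------------------------------------------------------
# region counting
# ---------------------------------------------------------------------------

def count_reads_by_region(reads: pd.DataFrame, regions: pd.DataFrame,
                          which: str = "passing") -> pd.DataFrame:
    """Count reads whose read-1 5' coordinate falls in each region.

    ``which`` selects the records counted: ``all``, ``passing`` (no flags
    set), or ``unflagged_dup`` (not a duplicate; MAPQ/coverage flags ignored).
    Overlapping regions each count a read once.  ``regions`` needs columns
    chrom/start/end and optionally ``name``.
    """
    preds = {
        "all": lambda df: np.ones(len(df), dtype=bool),
        "passing": passing_mask,
        "unflagged_dup": lambda df: (~df["is_dup"]).to_numpy(),
    }
    if callable(which):
        mask = which(reads)
    else:
        mask = preds[which](reads)
    pos = read1_position(reads)
    rows = []
    for i, row in enumerate(regions.itertuples(index=False)):
        inside = (reads["chrom"].to_numpy() == row.chrom) & (pos >= row.start) & (pos < row.end)
        rows.append({"region": getattr(row, "name", f"region_{i}"), "chrom": row.chrom,
                     "start": row.start, "end": row.end, "count": int((inside & mask).sum())})
    return pd.DataFrame(rows)
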