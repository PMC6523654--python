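"""File formats: BEDPE / BED6 read sets, bedGraph profiles, stage tables, SAM.

All coordinates are BED-convention 0-based half-open.  Read records are
fragment-level (see :mod:`centrotime.reads`); BEDPE rows carry the two read
intervals (a fixed 100 bp read length is assumed for interval widths, which
the pipeline never uses — only 5' coordinates matter downstream).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .profiling import RTProfile
from .reads import new_read_set

READ_LEN = 100

BEDPE_COLS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2",
              "name", "score", "strand1", "strand2"]


def write_bedpe(reads: pd.DataFrame, path: str | Path) -> None:
    """Write a paired read set as BEDPE (name column = artifact class if present)."""
    start = reads["start"].to_numpy()
    end = reads["end"].to_numpy()
    plus = reads["strand"].to_numpy() == "+"
    r1s = np.where(plus, start, np.maximum(end - READ_LEN, start))
    r1e = np.where(plus, np.minimum(start + READ_LEN, end), end)
    r2s = np.where(plus, np.maximum(end - READ_LEN, start), start)
    r2e = np.where(plus, end, np.minimum(start + READ_LEN, end))
    name = reads["artifact_class"] if "artifact_class" in reads else "."
    df = pd.DataFrame({"chrom1": reads["chrom"], "start1": r1s, "end1": r1e,
                       "chrom2": reads["chrom"], "start2": r2s, "end2": r2e,
                       "name": name, "score": reads["mapq"],
                       "strand1": reads["strand"],
                       "strand2": np.where(plus, "-", "+")})
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bedpe(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=BEDPE_COLS)
    start = np.minimum(df["start1"], df["start2"]).to_numpy()
    end = np.maximum(df["end1"], df["end2"]).to_numpy()
    extra = {}
    if (df["name"] != ".").any():
        extra["artifact_class"] = df["name"].to_numpy()
    return new_read_set(df["chrom1"].to_numpy(), start, end,
                        df["strand1"].to_numpy(), df["score"].to_numpy(),
                        paired=True, **extra)


def write_bed6(reads: pd.DataFrame, path: str | Path) -> None:
    """Single-end projection: read 1 only, one BED6 row per fragment."""
    start = reads["start"].to_numpy()
    end = reads["end"].to_numpy()
    plus = reads["strand"].to_numpy() == "+"
    r1s = np.where(plus, start, np.maximum(end - READ_LEN, start))
    r1e = np.where(plus, np.minimum(start + READ_LEN, end), end)
    name = reads["artifact_class"] if "artifact_class" in reads else "."
    pd.DataFrame({"chrom": reads["chrom"], "start": r1s, "end": r1e,
                  "name": name, "score": reads["mapq"], "strand": reads["strand"]
                  }).to_csv(path, sep="\t", header=False, index=False)


def read_bed6(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "score", "strand"])
    extra = {}
    if (df["name"] != ".").any():
        extra["artifact_class"] = df["name"].to_numpy()
    return new_read_set(df["chrom"].to_numpy(), df["start"].to_numpy(),
                        df["end"].to_numpy(), df["strand"].to_numpy(),
                        df["score"].to_numpy(), paired=False, **extra)


def read_sam(path: str | Path, min_tlen: int = 0) -> pd.DataFrame:
    """Ingest a coordinate-sorted SAM/BAM into a fragment-level read set.

    Uses the read-1 record of each properly oriented pair (its TLEN spans the
    fragment); unpaired records become single-end fragments of their aligned
    length.  Flagged duplicates/QC failures in the file are ignored — the
    pipeline re-marks duplicates itself.
    """
    import pysam

    rows = {"chrom": [], "start": [], "end": [], "strand": [], "mapq": [], "paired": []}
    with pysam.AlignmentFile(str(path)) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.is_paired:
                if not aln.is_read1 or aln.mate_is_unmapped \
                        or aln.reference_id != aln.next_reference_id:
                    continue
                tlen = aln.template_length
                if abs(tlen) < min_tlen or tlen == 0:
                    continue
                if tlen > 0:
                    start, end = aln.reference_start, aln.reference_start + tlen
                else:
                    end = aln.reference_end
                    start = end + tlen
                strand = "-" if aln.is_reverse else "+"
            else:
                start, end = aln.reference_start, aln.reference_end
                strand = "-" if aln.is_reverse else "+"
            if end <= start:
                continue
            rows["chrom"].append(aln.reference_name)
            rows["start"].append(start)
            rows["end"].append(end)
            rows["strand"].append(strand)
            rows["mapq"].append(aln.mapping_quality)
            rows["paired"].append(aln.is_paired)
    return new_read_set(rows["chrom"], rows["start"], rows["end"], rows["strand"],
                        rows["mapq"], paired=np.asarray(rows["paired"], dtype=bool))


# ---------------------------------------------------------------------------
# profiles and tables
# ---------------------------------------------------------------------------

def write_bedgraph(profile: RTProfile, path: str | Path) -> None:
    profile.data[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False, float_format="%.17g")


def write_profile_table(profiles: dict[str, RTProfile], path: str | Path) -> None:
    """All-stage TSV keyed on window coordinates; NaN where a stage dropped a
    window."""
    base = None
    for stage in ("raw", "filtered", "smoothed", "normalized"):
        if stage not in profiles:
            continue
        d = profiles[stage].data.rename(columns={"value": stage})
        if base is None:
            base = d
        else:
            base = base.merge(d[["chrom", "seg_id", "start", "end", "midpoint", stage]],
                              on=["chrom", "seg_id", "start", "end", "midpoint"],
                              how="left")
    if base is None:
        raise ConfigError("no profile stages to write")
    base.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_profile_table(path: str | Path, stage: str = "normalized") -> RTProfile:
    df = pd.read_csv(path, sep="\t")
    if stage not in df.columns:
        raise ConfigError(f"stage {stage!r} not in {path}")
    data = df[["chrom", "seg_id", "start", "end", "midpoint", stage]].rename(
        columns={stage: "value"}).dropna(subset=["value"]).reset_index(drop=True)
    return RTProfile(data=data, stage=stage)


def write_truth_table(truth, path: str | Path) -> None:
    truth.grid.to_csv(path, sep="\t", index=False, float_format="%.17g")
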