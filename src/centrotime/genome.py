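"""Genome coordinate frame: chromosome sizes, centromeres, gaps, repeat arrays.

All intervals are 0-based, half-open (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import SizingError

INTERVAL_COLS = ["chrom", "start", "end"]
REPEAT_COLS = ["chrom", "start", "end", "unit_length", "n_distinct_units"]


def _empty_intervals(cols=INTERVAL_COLS) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=int if c != "chrom" else object) for c in cols})


@dataclass
class GenomeLayout:
    """Chromosome lengths plus centromere / gap / repeat-array annotation.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    centromeres, gaps
        DataFrames with columns ``chrom, start, end``; at most one centromere
        per chromosome.
    repeat_arrays
        DataFrame with columns ``chrom, start, end, unit_length,
        n_distinct_units``; every array must lie inside a centromere (repeats
        are only modelled where the reference collapses alignments).
    """

    chromosomes: list[tuple[str, int]]
    centromeres: pd.DataFrame = field(default_factory=_empty_intervals)
    gaps: pd.DataFrame = field(default_factory=_empty_intervals)
    repeat_arrays: pd.DataFrame = field(default_factory=lambda: _empty_intervals(REPEAT_COLS))

    def __post_init__(self) -> None:
        self.centromeres = pd.DataFrame(self.centromeres, columns=INTERVAL_COLS).reset_index(drop=True)
        self.gaps = pd.DataFrame(self.gaps, columns=INTERVAL_COLS).reset_index(drop=True)
        self.repeat_arrays = pd.DataFrame(self.repeat_arrays, columns=REPEAT_COLS).reset_index(drop=True)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        lengths = self.lengths
        for name, length in self.chromosomes:
            if length <= 0:
                raise SizingError(f"chromosome {name} has non-positive length {length}")
        for df, label in [(self.centromeres, "centromere"), (self.gaps, "gap"),
                          (self.repeat_arrays, "repeat array")]:
            for row in df.itertuples(index=False):
                if row.chrom not in lengths:
                    raise SizingError(f"{label} on unknown chromosome {row.chrom!r}")
                if not (0 <= row.start < row.end <= lengths[row.chrom]):
                    raise SizingError(
                        f"{label} [{row.start}, {row.end}) outside chromosome "
                        f"{row.chrom} of length {lengths[row.chrom]}")
        if self.centromeres["chrom"].duplicated().any():
            raise SizingError("more than one centromere on a chromosome")
        # repeat arrays must sit inside a centromere
        for row in self.repeat_arrays.itertuples(index=False):
            cen = self.centromere(row.chrom)
            if cen is None or not (cen[0] <= row.start and row.end <= cen[1]):
                raise SizingError(
                    f"repeat array on {row.chrom} [{row.start}, {row.end}) not "
                    "contained in a centromere")

    # -- accessors --------------------------------------------------------
    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    def centromere(self, chrom: str) -> tuple[int, int] | None:
        hit = self.centromeres[self.centromeres["chrom"] == chrom]
        if hit.empty:
            return None
        row = hit.iloc[0]
        return int(row["start"]), int(row["end"])

    def autosomes(self, sex_chroms: tuple[str, ...] = ("chrX", "chrY", "chrM")) -> list[str]:
        return [n for n in self.names if n not in set(sex_chroms)]

    # -- I/O --------------------------------------------------------------
    def write_chrom_sizes(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self.chromosomes:
                fh.write(f"{name}\t{length}\n")

    def write_centromere_bed(self, path: str | Path) -> None:
        write_bed3(self.centromeres, path)

    @classmethod
    def from_files(cls, chrom_sizes: str | Path, centromere_bed: str | Path | None = None,
                   gap_bed: str | Path | None = None) -> "GenomeLayout":
        chroms = []
        with open(chrom_sizes) as fh:
            for line in fh:
                if line.strip():
                    name, length = line.split()[:2]
                    chroms.append((name, int(length)))
        cen = read_bed3(centromere_bed) if centromere_bed else _empty_intervals()
        gaps = read_bed3(gap_bed) if gap_bed else _empty_intervals()
        return cls(chromosomes=chroms, centromeres=cen, gaps=gaps)


def read_bed3(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2],
                     names=INTERVAL_COLS, dtype={"chrom": str, "start": int, "end": int})
    return df


def write_bed3(df: pd.DataFrame, path: str | Path) -> None:
    df[INTERVAL_COLS].to_csv(path, sep="\t", header=False, index=False)
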