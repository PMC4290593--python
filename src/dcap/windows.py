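"""Genome tiling, blacklist filtering, and per-window signal aggregation.

Coordinates are 0-based half-open (BED convention) throughout; signal tracks
are unstranded.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenomeWindows",
    "tile_genome",
    "bin_signal",
    "read_chrom_sizes",
    "read_bed3",
    "bin_bigwig",
    "bin_bedgraph",
]


class GenomeWindows:
    """Sorted, non-overlapping fixed-width genomic tiles.

    Thin wrapper around a DataFrame with columns (chrom, start, end); the last
    window of a chromosome may be shorter than ``width``.
    """

    def __init__(self, df: pd.DataFrame, width: int):
        df = df.reset_index(drop=True)
        self.df = df
        self.width = int(width)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chrom(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def start(self) -> np.ndarray:
        return self.df["start"].to_numpy()

    @property
    def end(self) -> np.ndarray:
        return self.df["end"].to_numpy()

    def chromosome_segments(self) -> list[np.ndarray]:
        """Row-index arrays, one per run of consecutive same-chromosome rows."""
        chrom = self.chrom
        idx = np.arange(len(chrom))
        if len(chrom) == 0:
            return []
        breaks = np.flatnonzero(chrom[1:] != chrom[:-1]) + 1
        return np.split(idx, breaks)

    @classmethod
    def from_regions(cls, regions: pd.DataFrame, width: int = 0) -> "GenomeWindows":
        """Build windows from an explicit region list (e.g. pre-called peaks)."""
        df = regions[["chrom", "start", "end"]].copy()
        df = df.sort_values(["chrom", "start"], kind="stable")
        return cls(df, width or int((df["end"] - df["start"]).median()))


def read_chrom_sizes(path: str | Path) -> pd.DataFrame:
    """Read a two-column (chrom, size) whitespace-delimited file."""
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["chrom", "size"],
                     dtype={"chrom": str})
    return df


def read_bed3(path: str | Path) -> pd.DataFrame:
    """Read the first three columns of a BED file."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={0: str})
    return df


def tile_genome(
    chrom_sizes: pd.DataFrame,
    width: int = 1000,
    blacklist: pd.DataFrame | None = None,
    include_chroms: list[str] | None = None,
) -> GenomeWindows:
    """Tile chromosomes into fixed-width windows, dropping blacklisted ones.

    Parameters
    ----------
    chrom_sizes : DataFrame with columns (chrom, size).
    width : window width in bp.
    blacklist : optional DataFrame with (chrom, start, end); any window
        overlapping a blacklist interval by >= 1 bp is removed.
    include_chroms : optional explicit chromosome include-list (e.g. to drop
        chrY as done for the human analysis).
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    if len(chrom_sizes) == 0:
        raise ValueError("chrom_sizes is empty")
    chroms, starts, ends = [], [], []
    kept_chroms = []
    for _, row in chrom_sizes.iterrows():
        chrom, size = str(row["chrom"]), int(row["size"])
        if include_chroms is not None and chrom not in include_chroms:
            continue
        kept_chroms.append(chrom)
        s = np.arange(0, size, width)
        e = np.minimum(s + width, size)
        chroms.extend([chrom] * len(s))
        starts.append(s)
        ends.append(e)
    df = pd.DataFrame({
        "chrom": chroms,
        "start": np.concatenate(starts) if starts else np.array([], int),
        "end": np.concatenate(ends) if ends else np.array([], int),
    })
    if blacklist is not None and len(blacklist):
        unknown = set(blacklist["chrom"].astype(str)) - set(kept_chroms)
        if unknown:
            warnings.warn(
                f"blacklist intervals on unknown chromosomes ignored: {sorted(unknown)}"
            )
        keep = np.ones(len(df), dtype=bool)
        for chrom, grp in blacklist.groupby("chrom"):
            mask = df["chrom"].to_numpy() == str(chrom)
            if not mask.any():
                continue
            w_start = df.loc[mask, "start"].to_numpy()
            w_end = df.loc[mask, "end"].to_numpy()
            hit = np.zeros(mask.sum(), dtype=bool)
            for bs, be in zip(grp["start"].to_numpy(), grp["end"].to_numpy()):
                hit |= (w_start < be) & (w_end > bs)
            keep[np.flatnonzero(mask)[hit]] = False
        df = df[keep]
    return GenomeWindows(df, width)


def bin_signal(
    intervals: pd.DataFrame,
    windows: GenomeWindows,
    value_col: str = "value",
) -> np.ndarray:
    """Sum per-bp signal mass of a bedGraph-style track over each window.

    Each interval carries a constant per-bp density ``value``; its mass over a
    window is ``value * overlap_bp``, so intervals split across windows
    contribute proportionally to the overlap length.
    """
    out = np.zeros(len(windows))
    if len(intervals) == 0:
        warnings.warn("empty signal track; returning zeros")
        return out
    w_chrom = windows.chrom
    w_start = windows.start
    w_end = windows.end
    any_overlap = False
    for chrom, grp in intervals.groupby("chrom"):
        mask = w_chrom == str(chrom)
        if not mask.any():
            continue
        rows = np.flatnonzero(mask)
        ws, we = w_start[rows], w_end[rows]
        iv_s = grp["start"].to_numpy()
        iv_e = grp["end"].to_numpy()
        iv_v = grp[value_col].to_numpy(dtype=float)
        # windows within a chromosome are sorted: locate overlap span per interval
        lo = np.searchsorted(we, iv_s, side="right")
        hi = np.searchsorted(ws, iv_e, side="left")
        for s, e, v, a, b in zip(iv_s, iv_e, iv_v, lo, hi):
            if b <= a:
                continue
            any_overlap = True
            ov = np.minimum(we[a:b], e) - np.maximum(ws[a:b], s)
            out[rows[a:b]] += v * np.maximum(ov, 0)
    if not any_overlap:
        warnings.warn("signal track does not overlap any window; all zeros")
    return out


def bin_bedgraph(path: str | Path, windows: GenomeWindows) -> np.ndarray:
    """Aggregate a bedGraph file to per-window sums of density mass."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"],
                     dtype={0: str})
    return bin_signal(df, windows)


def bin_bigwig(path: str | Path, windows: GenomeWindows) -> np.ndarray:
    """Aggregate a bigWig file to per-window sums (exact, via pyBigWig)."""
    import pyBigWig

    out = np.zeros(len(windows))
    bw = pyBigWig.open(str(path))
    try:
        chrom_lens = bw.chroms()
        for rows in windows.chromosome_segments():
            chrom = windows.chrom[rows[0]]
            if chrom not in chrom_lens:
                continue
            for i in rows:
                s, e = int(windows.start[i]), int(windows.end[i])
                v = bw.stats(chrom, s, min(e, chrom_lens[chrom]),
                             type="sum", exact=True)[0]
                out[i] = 0.0 if v is None else v
    finally:
        bw.close()
    return out
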