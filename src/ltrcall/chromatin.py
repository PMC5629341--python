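"""Euchromatin/heterochromatin partition from H3K9me2 tile enrichment.

The genome is segmented by smoothing the per-tile enrichment with a moving
average (default 100 tiles of 60 bp), keeping maximal runs of tiles whose
smoothed value exceeds a conservative threshold (default 1.5) and rounding
the run boundaries to the nearest 100 kb. The complement of the resulting
heterochromatin intervals is the euchromatin.

The default reading of the threshold is absolute: smoothed value > 1.5.
An alternative "ratio" mode (raw value > 1.5 x smoothed trend) is available
through :func:`partition_from_raw`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formats_io import GenomicInterval, TileTrack


@dataclass
class ChromatinPartition:
    heterochromatin: list[GenomicInterval]
    euchromatin: list[GenomicInterval]
    provenance: dict = field(default_factory=dict)

    def class_sizes(self) -> tuple[float, float]:
        """(euchromatin Mbp, heterochromatin Mbp)."""
        eu = sum(len(iv) for iv in self.euchromatin) / 1e6
        het = sum(len(iv) for iv in self.heterochromatin) / 1e6
        return eu, het

    def euchromatin_on(self, chrom: str) -> list[GenomicInterval]:
        return [iv for iv in self.euchromatin if iv.chrom == chrom]


def smooth_track(track: TileTrack, window_tiles: int = 100) -> TileTrack:
    """Centered moving average over ``window_tiles`` tiles.

    Windows are truncated at chromosome ends (mean over the available
    tiles), so no edge tile is dropped. ``window_tiles=1`` is the identity;
    a window larger than the chromosome yields the global mean everywhere.
    For an even window the extra tile sits on the right.
    """
    if window_tiles < 1:
        raise ValueError("window must be >= 1")
    out: dict[str, np.ndarray] = {}
    kernel = np.ones(window_tiles)
    for chrom, vals in track.values.items():
        n = len(vals)
        if window_tiles >= n:
            out[chrom] = np.full(n, vals.mean())
            continue
        sums = np.convolve(vals, kernel, mode="same")
        counts = np.convolve(np.ones(n), kernel, mode="same")
        out[chrom] = sums / counts
    return TileTrack(track.tile_width, out)


def _round_half_up(x: int, unit: int) -> int:
    return ((x + unit // 2) // unit) * unit


def partition(smoothed: TileTrack, threshold: float = 1.5, round_to: int = 100_000,
              chrom_lengths: dict[str, int] | None = None) -> ChromatinPartition:
    """Threshold a smoothed track into a chromatin partition.

    Maximal runs of tiles with value > ``threshold`` become heterochromatin;
    each run's bounds are rounded half-up to the nearest multiple of
    ``round_to`` (clipped to the chromosome), zero-length intervals are
    dropped and overlapping rounded intervals merged. The complement is
    euchromatin; the two classes always form a disjoint cover.
    """
    w = smoothed.tile_width
    het: list[GenomicInterval] = []
    eu: list[GenomicInterval] = []
    for chrom, vals in smoothed.values.items():
        L = (chrom_lengths or {}).get(chrom, len(vals) * w)
        above = vals > threshold
        raw_runs: list[tuple[int, int]] = []
        i = 0
        n = len(vals)
        while i < n:
            if above[i]:
                j = i
                while j < n and above[j]:
                    j += 1
                raw_runs.append((i * w, min(j * w, L)))
                i = j
            else:
                i += 1
        rounded: list[list[int]] = []
        for s, e in raw_runs:
            rs = min(max(_round_half_up(s, round_to), 0), L)
            re = min(max(_round_half_up(e, round_to), 0), L)
            if re <= rs:
                continue
            if rounded and rs <= rounded[-1][1]:
                rounded[-1][1] = max(rounded[-1][1], re)
            else:
                rounded.append([rs, re])
        cursor = 0
        for s, e in rounded:
            if s > cursor:
                eu.append(GenomicInterval(chrom, cursor, s))
            het.append(GenomicInterval(chrom, s, e))
            cursor = e
        if cursor < L:
            eu.append(GenomicInterval(chrom, cursor, L))
    return ChromatinPartition(het, eu, provenance={
        "tile_width": w, "threshold": threshold, "round_to": round_to,
    })


def partition_from_raw(track: TileTrack, window_tiles: int = 100, threshold: float = 1.5,
                       round_to: int = 100_000, mode: str = "absolute",
                       chrom_lengths: dict[str, int] | None = None) -> ChromatinPartition:
    """Smooth then partition, in either threshold semantics.

    ``absolute``: smoothed value > threshold (default). ``ratio``: raw value
    > threshold x smoothed trend, i.e. tiles rising above the local trend
    line by the given factor.
    """
    smoothed = smooth_track(track, window_tiles)
    if mode == "absolute":
        part = partition(smoothed, threshold, round_to, chrom_lengths)
    elif mode == "ratio":
        indicator = {
            c: np.where(smoothed.values[c] > 0,
                        track.values[c] / np.maximum(smoothed.values[c], 1e-300),
                        0.0)
            for c in track.values
        }
        part = partition(TileTrack(track.tile_width, indicator), threshold,
                         round_to, chrom_lengths)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    part.provenance["window_tiles"] = window_tiles
    part.provenance["mode"] = mode
    return part


def class_sizes(part: ChromatinPartition) -> tuple[float, float]:
    """(euchromatin Mbp, heterochromatin Mbp) of a partition."""
    return part.class_sizes()


def write_partition_bed(part: ChromatinPartition, path: str) -> None:
    rows = [(iv.chrom, iv.start, iv.end, "heterochromatin") for iv in part.heterochromatin]
    rows += [(iv.chrom, iv.start, iv.end, "euchromatin") for iv in part.euchromatin]
    rows.sort()
    with open(path, "w") as fh:
        for chrom, s, e, name in rows:
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")


def read_partition_bed(path: str) -> ChromatinPartition:
    het, eu = [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, s, e, name = line.split()[:4]
            iv = GenomicInterval(chrom, int(s), int(e))
            (het if name == "heterochromatin" else eu).append(iv)
    return ChromatinPartition(het, eu)
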