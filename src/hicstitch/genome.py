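"""Binned genome coordinate system.

A :class:`GenomeBins` partitions each chromosome into fixed-width bins
(0-based, half-open intervals; the last bin of a chromosome may be short)
and maps between global bin indices and ``(chrom, local_bin)`` pairs.
Global indices run 0..n-1 in chromosome order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenomeBins", "bin_genome", "read_bins", "write_bins"]


@dataclass(frozen=True)
class GenomeBins:
    """Ordered bins over a multi-chromosome genome.

    Parameters
    ----------
    chrom_names
        Chromosome identifiers in genome order.
    chrom_lengths
        Length in base pairs per chromosome, aligned with ``chrom_names``.
    resolution
        Bin width in base pairs.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    resolution: int
    _offsets: tuple[int, ...] = field(init=False, repr=False)
    _counts: tuple[int, ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError(f"resolution must be positive, got {self.resolution}")
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths must align")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        for name, length in zip(self.chrom_names, self.chrom_lengths):
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        counts = tuple(-(-length // self.resolution) for length in self.chrom_lengths)
        offsets = tuple(int(x) for x in np.concatenate([[0], np.cumsum(counts)]))
        object.__setattr__(self, "_counts", counts)
        object.__setattr__(self, "_offsets", offsets)

    # -- sizes ---------------------------------------------------------------

    @property
    def n_bins(self) -> int:
        return self._offsets[-1]

    def chrom_n_bins(self, chrom: str) -> int:
        return self._counts[self._chrom_pos(chrom)]

    def chrom_length(self, chrom: str) -> int:
        return self.chrom_lengths[self._chrom_pos(chrom)]

    def _chrom_pos(self, chrom: str) -> int:
        try:
            return self.chrom_names.index(chrom)
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    # -- index maps ----------------------------------------------------------

    def chrom_offset(self, chrom: str) -> int:
        """Global index of the first bin of ``chrom``."""
        return self._offsets[self._chrom_pos(chrom)]

    def chrom_slice(self, chrom: str) -> slice:
        k = self._chrom_pos(chrom)
        return slice(self._offsets[k], self._offsets[k + 1])

    def global_index(self, chrom: str, local_bin: int) -> int:
        k = self._chrom_pos(chrom)
        if not 0 <= local_bin < self._counts[k]:
            raise IndexError(f"local bin {local_bin} out of range for {chrom!r}")
        return self._offsets[k] + local_bin

    def to_local(self, global_bin: int) -> tuple[str, int]:
        if not 0 <= global_bin < self.n_bins:
            raise IndexError(f"global bin {global_bin} out of range [0, {self.n_bins})")
        k = int(np.searchsorted(self._offsets, global_bin, side="right") - 1)
        return self.chrom_names[k], global_bin - self._offsets[k]

    def bin_interval(self, global_bin: int) -> tuple[str, int, int]:
        """``(chrom, start, end)`` of a bin; the last bin may be short."""
        chrom, local = self.to_local(global_bin)
        length = self.chrom_length(chrom)
        start = local * self.resolution
        return chrom, start, min(start + self.resolution, length)

    # -- tabular views -------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [self.bin_interval(g) for g in range(self.n_bins)]
        frame = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        frame["bin"] = np.arange(self.n_bins)
        return frame

    def __len__(self) -> int:
        return self.n_bins

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeBins):
            return NotImplemented
        return (
            self.chrom_names == other.chrom_names
            and self.chrom_lengths == other.chrom_lengths
            and self.resolution == other.resolution
        )


def bin_genome(chrom_lengths: dict[str, int], resolution: int) -> GenomeBins:
    """Partition a genome into fixed-width bins.

    Each chromosome gets ``ceil(length / resolution)`` bins; the trailing
    partial bin is kept so coverage is complete.

    Parameters
    ----------
    chrom_lengths
        Mapping chromosome name -> length in base pairs (insertion order
        defines genome order).
    resolution
        Bin width in base pairs; must be positive.
    """
    if resolution <= 0:
        raise ValueError(f"resolution must be positive, got {resolution}")
    names = tuple(chrom_lengths)
    lengths = tuple(int(chrom_lengths[c]) for c in names)
    return GenomeBins(names, lengths, int(resolution))


def write_bins(bins: GenomeBins, path) -> None:
    """Write a BED3+index bin table (TSV, no header)."""
    bins.to_frame().to_csv(path, sep="\t", header=False, index=False)


def read_bins(path) -> GenomeBins:
    """Read a bin table written by :func:`write_bins` (4th column optional).

    The bin width is inferred from the intervals; per-chromosome bins must
    be contiguous from 0 with only the final bin allowed to be short.
    """
    frame = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2], names=["chrom", "start", "end"]
    )
    if frame.empty:
        raise ValueError(f"empty bin table: {path}")
    widths = frame["end"] - frame["start"]
    resolution = int(widths.max())
    names: list[str] = []
    lengths: list[int] = []
    for chrom, grp in frame.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        expected = np.arange(len(grp)) * resolution
        if not np.array_equal(starts, expected) or not np.array_equal(
            ends[:-1], starts[1:]
        ):
            raise ValueError(f"bins of chromosome {chrom!r} are not contiguous from 0")
        names.append(str(chrom))
        lengths.append(int(ends[-1]))
    return GenomeBins(tuple(names), tuple(lengths), resolution)
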