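"""Fixed-width genomic bin grids.

A :class:`BinGrid` tiles each chromosome with non-overlapping, 0-based
half-open windows of a fixed width (default 100 kbp, the working resolution
for shallow cfDNA copy-number profiling); the last bin of every chromosome is
truncated to the chromosome end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

DEFAULT_BIN_WIDTH = 100_000

#: GRCh38 primary-assembly chromosome lengths (autosomes + X).  chrY is left
#: out of the default grid: it is excluded from normalization and calling
#: anyway, and cfDNA cohorts of mixed sex make its depth uninterpretable.
GRCH38_CHROM_SIZES: tuple[tuple[str, int], ...] = (
    ("chr1", 248_956_422), ("chr2", 242_193_529), ("chr3", 198_295_559),
    ("chr4", 190_214_555), ("chr5", 181_538_259), ("chr6", 170_805_979),
    ("chr7", 159_345_973), ("chr8", 145_138_636), ("chr9", 138_394_717),
    ("chr10", 133_797_422), ("chr11", 135_086_622), ("chr12", 133_275_309),
    ("chr13", 114_364_328), ("chr14", 107_043_718), ("chr15", 101_991_189),
    ("chr16", 90_338_345), ("chr17", 83_257_441), ("chr18", 80_373_285),
    ("chr19", 58_617_616), ("chr20", 64_444_167), ("chr21", 46_709_983),
    ("chr22", 50_818_468), ("chrX", 156_040_895),
)

#: Chromosome names treated as sex chromosomes regardless of prefix style.
_SEX_NAMES = {"chrX", "X", "chrY", "Y"}
_Y_NAMES = {"chrY", "Y"}


@dataclass(frozen=True)
class BinGrid:
    """A fixed-width partition of a genome into ordered bins.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    bin_width
        Bin width in bp; the last bin of each chromosome is truncated.
    """

    chromosomes: tuple[tuple[str, int], ...]
    bin_width: int = DEFAULT_BIN_WIDTH
    # derived, filled in __post_init__
    bin_chrom: np.ndarray = field(init=False, repr=False, compare=False)
    bin_start: np.ndarray = field(init=False, repr=False, compare=False)
    bin_end: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be a positive integer")
        if not self.chromosomes:
            raise ValueError("grid needs at least one chromosome")
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in grid")
        chrom_idx, starts, ends = [], [], []
        for ci, (name, length) in enumerate(self.chromosomes):
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
            s = np.arange(0, length, self.bin_width, dtype=np.int64)
            e = np.minimum(s + self.bin_width, length)
            chrom_idx.append(np.full(len(s), ci, dtype=np.int32))
            starts.append(s)
            ends.append(e)
        object.__setattr__(self, "bin_chrom", np.concatenate(chrom_idx))
        object.__setattr__(self, "bin_start", np.concatenate(starts))
        object.__setattr__(self, "bin_end", np.concatenate(ends))

    # -- basic accessors ---------------------------------------------------
    @property
    def n_bins(self) -> int:
        return len(self.bin_start)

    @property
    def chrom_names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def chrom_index(self, name: str) -> int:
        try:
            return self.chrom_names.index(name)
        except ValueError:
            raise KeyError(f"chromosome {name!r} not in grid") from None

    def chrom_slice(self, name: str) -> slice:
        """Contiguous slice of bin indices belonging to one chromosome."""
        ci = self.chrom_index(name)
        idx = np.flatnonzero(self.bin_chrom == ci)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def bin_index(self, chrom: str, pos: int) -> int:
        """Bin containing 0-based position ``pos`` on ``chrom``."""
        ci = self.chrom_index(chrom)
        length = self.chromosomes[ci][1]
        if not 0 <= pos < length:
            raise ValueError(f"position {pos} outside {chrom} (length {length})")
        offset = int(np.flatnonzero(self.bin_chrom == ci)[0])
        return offset + pos // self.bin_width

    @property
    def bin_widths(self) -> np.ndarray:
        return self.bin_end - self.bin_start

    @property
    def autosome_mask(self) -> np.ndarray:
        """Boolean per-bin mask, True on autosomal bins."""
        sex = np.array([name in _SEX_NAMES for name, _ in self.chromosomes])
        return ~sex[self.bin_chrom]

    @property
    def chry_mask(self) -> np.ndarray:
        y = np.array([name in _Y_NAMES for name, _ in self.chromosomes])
        return y[self.bin_chrom]

    # -- alternate constructors -------------------------------------------
    @classmethod
    def human(cls, bin_width: int = DEFAULT_BIN_WIDTH) -> "BinGrid":
        """GRCh38 autosomes + chrX at the given bin width."""
        return cls(GRCH38_CHROM_SIZES, bin_width)

    @classmethod
    def from_sizes(
        cls, sizes: Iterable[Sequence], bin_width: int = DEFAULT_BIN_WIDTH
    ) -> "BinGrid":
        return cls(tuple((str(n), int(l)) for n, l in sizes), bin_width)

    @classmethod
    def read_sizes(cls, path, bin_width: int = DEFAULT_BIN_WIDTH) -> "BinGrid":
        """Read a two-column chrom-sizes file (as produced by samtools faidx)."""
        pairs = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.split()
                pairs.append((fields[0], int(fields[1])))
        return cls.from_sizes(pairs, bin_width)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, BinGrid)
            and self.chromosomes == other.chromosomes
            and self.bin_width == other.bin_width
        )

    def __hash__(self) -> int:
        return hash((self.chromosomes, self.bin_width))
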