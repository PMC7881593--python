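"""Per-bin read-count profiles.

Turns aligned reads (SAM/BAM) or pre-binned tab-delimited tables into
:class:`CountProfile` objects, extracts cfDNA fragment-length distributions,
and supports binomial subsampling and profile merging — the depth-level
operations behind shallow-coverage copy-number analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pysam

from .grid import BinGrid

log = logging.getLogger(__name__)

#: Default SAM flag mask: unmapped | secondary | supplementary.
DEFAULT_EXCLUDE_FLAGS = 0x4 | 0x100 | 0x800
#: Exclude MAPQ-0 multi-mappers by default; exposed because mapping artifacts
#: in repetitive regions are the main source of recurrent false CNVs.
DEFAULT_MAPQ_MIN = 1


@dataclass(frozen=True)
class CountProfile:
    """Read counts per bin for one sample."""

    grid: BinGrid
    counts: np.ndarray  # non-negative ints, one per bin
    sample: str = "sample"
    mapq_min: int = DEFAULT_MAPQ_MIN
    duplicates_excluded: bool = False
    exclusions: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (self.grid.n_bins,):
            raise ValueError(
                f"counts length {counts.shape} != grid bins {self.grid.n_bins}"
            )
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())

    def with_counts(self, counts: np.ndarray, **kw) -> "CountProfile":
        return replace(self, counts=counts, exclusions={}, **kw)


@dataclass(frozen=True)
class FragmentLengthSample:
    """cfDNA fragment lengths (bp) with histogram summaries."""

    lengths: np.ndarray

    def __post_init__(self) -> None:
        lengths = np.asarray(self.lengths, dtype=np.int64)
        if lengths.size == 0:
            raise ValueError("no fragment lengths")
        if (lengths < 1).any():
            raise ValueError("fragment lengths must be >= 1 bp")
        object.__setattr__(self, "lengths", lengths)

    @property
    def mode(self) -> int:
        """Most frequent length (smallest on ties)."""
        return int(np.bincount(self.lengths).argmax())

    @property
    def median(self) -> float:
        return float(np.median(self.lengths))

    def histogram(self, max_len: int | None = None) -> np.ndarray:
        m = max_len if max_len is not None else int(self.lengths.max())
        return np.bincount(self.lengths, minlength=m + 1)


# ---------------------------------------------------------------------------
# SAM/BAM ingestion
# ---------------------------------------------------------------------------

def bin_reads(
    alignments,
    grid: BinGrid,
    mapq_min: int = DEFAULT_MAPQ_MIN,
    exclude_flags: int = DEFAULT_EXCLUDE_FLAGS,
    sample: str | None = None,
) -> CountProfile:
    """Count retained primary alignments per bin.

    Each retained alignment increments exactly one bin, chosen by its leftmost
    mapped position. Reads whose flags intersect ``exclude_flags`` (unmapped,
    secondary and supplementary by default) or whose MAPQ falls below
    ``mapq_min`` are excluded and tallied. Reads on chromosomes absent from the
    grid are skipped with a warning.

    Parameters
    ----------
    alignments
        Path to a SAM/BAM file or an open :class:`pysam.AlignmentFile`.
    """
    own = False
    if not isinstance(alignments, pysam.AlignmentFile):
        alignments = pysam.AlignmentFile(str(alignments), check_sq=False)
        own = True
    if sample is None:
        sample = getattr(alignments, "filename", b"sample")
        sample = sample.decode() if isinstance(sample, bytes) else str(sample)

    counts = np.zeros(grid.n_bins, dtype=np.int64)
    excl = {"flag": 0, "mapq": 0, "off_grid": 0}
    chrom_offsets: dict[str, tuple[int, int]] = {}
    for name, _ in grid.chromosomes:
        sl = grid.chrom_slice(name)
        chrom_offsets[name] = (sl.start, sl.stop)
    try:
        for read in alignments.fetch(until_eof=True):
            if read.flag & exclude_flags:
                excl["flag"] += 1
                continue
            if read.mapping_quality < mapq_min:
                excl["mapq"] += 1
                continue
            span = chrom_offsets.get(read.reference_name)
            if span is None:
                excl["off_grid"] += 1
                continue
            idx = span[0] + read.reference_start // grid.bin_width
            if idx >= span[1]:  # position beyond declared chromosome length
                excl["off_grid"] += 1
                continue
            counts[idx] += 1
    finally:
        if own:
            alignments.close()

    if excl["off_grid"]:
        log.warning("bin_reads: skipped %d reads on chromosomes/positions "
                    "outside the grid", excl["off_grid"])
    if counts.sum() == 0:
        log.warning("bin_reads: no reads retained — zero profile")
    return CountProfile(
        grid, counts, sample=sample, mapq_min=mapq_min,
        duplicates_excluded=bool(exclude_flags & 0x400), exclusions=excl,
    )


def fragment_lengths(alignments) -> FragmentLengthSample:
    """Collect fragment lengths from an alignment stream.

    Single-end reads contribute their aligned query length; paired reads
    contribute the absolute template length, once per pair (taken from the
    mate with positive TLEN).
    """
    own = False
    if not isinstance(alignments, pysam.AlignmentFile):
        alignments = pysam.AlignmentFile(str(alignments), check_sq=False)
        own = True
    lengths: list[int] = []
    try:
        for read in alignments.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.is_paired:
                if read.template_length > 0:
                    lengths.append(read.template_length)
            else:
                qlen = read.query_alignment_length or read.infer_query_length()
                if qlen:
                    lengths.append(qlen)
    finally:
        if own:
            alignments.close()
    if not lengths:
        raise ValueError("no usable reads for fragment-length extraction")
    return FragmentLengthSample(np.array(lengths, dtype=np.int64))


# ---------------------------------------------------------------------------
# Profile algebra
# ---------------------------------------------------------------------------

def subsample_profile(
    p: CountProfile, target_reads: int, seed: int | np.random.Generator
) -> CountProfile:
    """Thin a profile to ``target_reads`` expected total by binomial sampling.

    Each bin's count is thinned with retention probability
    ``target_reads / total_reads``, the in-silico equivalent of subsampling
    the underlying read set uniformly at random.
    """
    total = p.total_reads
    if not 0 < target_reads <= total:
        raise ValueError(
            f"target_reads must be in (0, {total}], got {target_reads}"
        )
    if target_reads == total:
        return p.with_counts(p.counts.copy())
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    thinned = rng.binomial(p.counts, target_reads / total)
    return p.with_counts(thinned.astype(np.int64))


def merge_profiles(ps: Sequence[CountProfile]) -> CountProfile:
    """Sum profiles bin-wise (the in-silico merged-BAM control)."""
    if not ps:
        raise ValueError("no profiles to merge")
    first = ps[0]
    for q in ps[1:]:
        if q.grid != first.grid:
            diff = _first_grid_difference(first.grid, q.grid)
            raise ValueError(f"grid mismatch between profiles: {diff}")
        if (q.mapq_min, q.duplicates_excluded) != (
                first.mapq_min, first.duplicates_excluded):
            raise ValueError("profiles were produced with different filters")
    counts = np.sum([q.counts for q in ps], axis=0)
    label = "+".join(q.sample for q in ps)
    return first.with_counts(counts.astype(np.int64), sample=label)


def _first_grid_difference(a: BinGrid, b: BinGrid) -> str:
    if a.bin_width != b.bin_width:
        return f"bin_width {a.bin_width} vs {b.bin_width}"
    for (na, la), (nb, lb) in zip(a.chromosomes, b.chromosomes):
        if (na, la) != (nb, lb):
            return f"chromosome {na}:{la} vs {nb}:{lb}"
    return f"{len(a.chromosomes)} vs {len(b.chromosomes)} chromosomes"


# ---------------------------------------------------------------------------
# Tab-delimited count tables
# ---------------------------------------------------------------------------

def write_count_table(p: CountProfile, path) -> None:
    """Write chrom/start/end/count (0-based half-open) with metadata header."""
    with open(path, "w") as fh:
        fh.write(f"#sample={p.sample}\n")
        fh.write(f"#bin_width={p.grid.bin_width}\n")
        fh.write(f"#mapq_min={p.mapq_min}\n")
        fh.write(f"#duplicates_excluded={int(p.duplicates_excluded)}\n")
        fh.write("chrom\tstart\tend\tcount\n")
        names = p.grid.chrom_names
        for ci, s, e, c in zip(
            p.grid.bin_chrom, p.grid.bin_start, p.grid.bin_end, p.counts
        ):
            fh.write(f"{names[ci]}\t{s}\t{e}\t{c}\n")


def read_count_table(path, grid: BinGrid | None = None) -> CountProfile:
    """Read a count table written by :func:`write_count_table`.

    The grid is reconstructed from the table itself (bin width from the
    header, chromosome lengths from the final bin end) unless one is given.
    """
    meta = {"sample": "sample", "bin_width": None,
            "mapq_min": DEFAULT_MAPQ_MIN, "duplicates_excluded": 0}
    chroms: list[str] = []
    lengths: dict[str, int] = {}
    counts: list[int] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                if key in meta:
                    meta[key] = val
                continue
            if not line or line.startswith("chrom\t"):
                continue
            chrom, start, end, count = line.split("\t")
            if chrom not in lengths:
                chroms.append(chrom)
            lengths[chrom] = max(lengths.get(chrom, 0), int(end))
            counts.append(int(count))
    if not counts:
        raise ValueError(f"empty count table: {path}")
    if grid is None:
        grid = BinGrid.from_sizes(
            [(c, lengths[c]) for c in chroms], int(meta["bin_width"])
        )
    arr = np.array(counts, dtype=np.int64)
    if arr.shape != (grid.n_bins,):
        raise ValueError("count table does not match the grid")
    return CountProfile(
        grid, arr, sample=str(meta["sample"]),
        mapq_min=int(meta["mapq_min"]),
        duplicates_excluded=bool(int(meta["duplicates_excluded"])),
    )
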