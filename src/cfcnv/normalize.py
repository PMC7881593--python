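"""Per-bin log2ratio profiles: nocontrol and paired normalization.

*nocontrol* mode divides each bin's count by the sample's own median
autosomal bin depth — no matched control is needed, but recurrent technical
depth biases survive as apparent CNVs. *paired* mode divides the test
sample's depth-normalized counts by a control's (here typically a merged
healthy-donor profile), cancelling any multiplicative bias the two share.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .counts import CountProfile
from .grid import BinGrid

log = logging.getLogger(__name__)

#: Minimum usable autosomal bins for a meaningful median.
MIN_USABLE_BINS = 100
#: Chromosomes excluded from normalization and downstream calling by default:
#: chrY is both sex-confounded and artifact-rich.
DEFAULT_EXCLUDE_CHROMS = frozenset({"chrY", "Y"})


@dataclass(frozen=True)
class RatioProfile:
    """Per-bin log2ratio values on a grid.

    ``log2ratio`` is NaN wherever ``usable`` is False (zero-count bins,
    excluded chromosomes and truncated chromosome-end bins carry no value).
    chrX bins are usable but flagged
    via ``grid.autosome_mask`` — they are normalized against the autosomal
    median without any sex inference.
    """

    grid: BinGrid
    log2ratio: np.ndarray
    usable: np.ndarray
    mode: str  # "nocontrol" | "paired"
    sample: str = "sample"
    control: str | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.log2ratio, dtype=float)
        u = np.asarray(self.usable, dtype=bool)
        n = self.grid.n_bins
        if r.shape != (n,) or u.shape != (n,):
            raise ValueError("profile arrays must have one entry per bin")
        if not np.isfinite(r[u]).all():
            raise ValueError("log2ratio must be finite on usable bins")
        r = r.copy()
        r[~u] = np.nan
        object.__setattr__(self, "log2ratio", r)
        object.__setattr__(self, "usable", u)

    @property
    def n_usable(self) -> int:
        return int(self.usable.sum())


def _usable_mask(
    counts: np.ndarray, grid: BinGrid, exclude_chroms=DEFAULT_EXCLUDE_CHROMS
) -> np.ndarray:
    excluded = np.array(
        [name in exclude_chroms for name, _ in grid.chromosomes]
    )
    # truncated chromosome-end bins carry proportionally fewer reads and
    # would masquerade as focal losses; they are masked, not rescaled
    full_width = grid.bin_widths == grid.bin_width
    return (counts > 0) & ~excluded[grid.bin_chrom] & full_width


def normalize_nocontrol(
    p: CountProfile, exclude_chroms=DEFAULT_EXCLUDE_CHROMS
) -> RatioProfile:
    """log2 of each bin's count over the median usable autosomal count.

    Zero-count bins are masked rather than pseudo-counted; the median (not
    the mean) keeps the center robust to a large CNV burden, under the
    assumption that most of the genome is copy-neutral.
    """
    grid = p.grid
    usable = _usable_mask(p.counts, grid, exclude_chroms)
    auto_usable = usable & grid.autosome_mask
    if auto_usable.sum() < MIN_USABLE_BINS:
        raise ValueError(
            f"only {int(auto_usable.sum())} usable autosomal bins "
            f"(need >= {MIN_USABLE_BINS})")
    m = float(np.median(p.counts[auto_usable]))
    if m == 0:
        raise ValueError("median usable autosomal count is 0 — profile too sparse")
    r = np.full(grid.n_bins, np.nan)
    r[usable] = np.log2(p.counts[usable] / m)
    return RatioProfile(grid, r, usable, mode="nocontrol", sample=p.sample)


def normalize_paired(
    test: CountProfile, control: CountProfile,
    exclude_chroms=DEFAULT_EXCLUDE_CHROMS, recenter: bool = True,
) -> RatioProfile:
    """log2 of depth-normalized test over depth-normalized control counts.

    ``r_i = log2((t_i / T) / (k_i / K))`` with ``T`` and ``K`` the usable-bin
    totals; bins where either sample has zero count are masked. Any
    multiplicative bias present in both samples cancels exactly — the
    mechanism by which a merged healthy control suppresses recurrent
    artifacts. The usable autosomal median is re-centered to 0 afterwards
    (disable with ``recenter=False``; required for strict antisymmetry).
    """
    if test.grid != control.grid:
        raise ValueError("test and control profiles are on different grids")
    grid = test.grid
    usable = _usable_mask(test.counts, grid, exclude_chroms) & (
        control.counts > 0)
    auto_usable = usable & grid.autosome_mask
    if auto_usable.sum() < MIN_USABLE_BINS:
        raise ValueError(
            f"only {int(auto_usable.sum())} mutually usable autosomal bins "
            f"(need >= {MIN_USABLE_BINS})")
    T = float(test.counts[usable].sum())
    K = float(control.counts[usable].sum())
    r = np.full(grid.n_bins, np.nan)
    r[usable] = np.log2(
        (test.counts[usable] / T) / (control.counts[usable] / K))
    if recenter:
        r[usable] -= np.median(r[auto_usable])
    return RatioProfile(
        grid, r, usable, mode="paired",
        sample=test.sample, control=control.sample,
    )


# ---------------------------------------------------------------------------
# Ratio-table I/O
# ---------------------------------------------------------------------------

def write_ratio_table(r: RatioProfile, path) -> None:
    """chrom, start, end, log2ratio, usable — tab-delimited."""
    names = r.grid.chrom_names
    with open(path, "w") as fh:
        fh.write(f"#sample={r.sample}\n#mode={r.mode}\n")
        if r.control:
            fh.write(f"#control={r.control}\n")
        fh.write(f"#bin_width={r.grid.bin_width}\n")
        fh.write("chrom\tstart\tend\tlog2ratio\tusable\n")
        for ci, s, e, val, u in zip(
            r.grid.bin_chrom, r.grid.bin_start, r.grid.bin_end,
            r.log2ratio, r.usable,
        ):
            v = f"{val:.6f}" if u else "NA"
            fh.write(f"{names[ci]}\t{s}\t{e}\t{v}\t{int(u)}\n")


def read_ratio_table(path, grid: BinGrid | None = None) -> RatioProfile:
    meta = {"sample": "sample", "mode": "nocontrol", "control": None,
            "bin_width": None}
    chroms: list[str] = []
    lengths: dict[str, int] = {}
    vals: list[float] = []
    usable: list[bool] = []
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
            chrom, start, end, val, u = line.split("\t")
            if chrom not in lengths:
                chroms.append(chrom)
            lengths[chrom] = max(lengths.get(chrom, 0), int(end))
            usable.append(bool(int(u)))
            vals.append(float(val) if val != "NA" else np.nan)
    if not vals:
        raise ValueError(f"empty ratio table: {path}")
    if grid is None:
        grid = BinGrid.from_sizes(
            [(c, lengths[c]) for c in chroms], int(meta["bin_width"]))
    return RatioProfile(
        grid, np.array(vals), np.array(usable), mode=str(meta["mode"]),
        sample=str(meta["sample"]), control=meta["control"],
    )
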