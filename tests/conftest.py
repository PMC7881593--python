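"""Shared fixtures and independent oracles for the cfcnv test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from cfcnv import BinGrid, SimConfig, TruthProfile, simulate_counts


@pytest.fixture
def small_grid() -> BinGrid:
    """Two autosomes + chrX, 100-kb bins, chromosome ends bin-aligned."""
    return BinGrid((("chr1", 5_000_000), ("chr2", 3_000_000),
                    ("chrX", 2_000_000)), 100_000)


@pytest.fixture
def medium_grid() -> BinGrid:
    """Enough autosomal bins (500) for normalization preconditions."""
    return BinGrid((("chr1", 30_000_000), ("chr2", 20_000_000),
                    ("chrX", 5_000_000)), 100_000)


@pytest.fixture(scope="session")
def human_grid() -> BinGrid:
    return BinGrid.human()


def neutral_counts(grid: BinGrid, total: int, seed: int):
    """Copy-neutral Poisson profile on a grid."""
    cfg = SimConfig(total_reads=total, seed=seed)
    return simulate_counts(grid, TruthProfile(grid), cfg)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def brute_force_partition(x: np.ndarray, penalty: float, min_bins: int):
    """Exhaustive search over all admissible partitions of a short series.

    Returns ``(cost, [(start, stop), ...])`` minimizing
    ``sum of within-segment squared deviations + penalty * n_segments``,
    ties broken toward fewer segments, then the reversed breakpoint tuple
    (earlier last changepoint first) — the same total order the DP uses.
    """
    n = len(x)
    if n < min_bins:
        seg = [(0, n)]
        return float(((x - x.mean()) ** 2).sum() + penalty), seg
    best_key, best_bounds = None, None
    for k in range(n):
        for bps in itertools.combinations(range(1, n), k):
            bounds = [0, *bps, n]
            if any(b - a < min_bins for a, b in zip(bounds, bounds[1:])):
                continue
            cost = sum(
                float(((x[a:b] - x[a:b].mean()) ** 2).sum())
                for a, b in zip(bounds, bounds[1:])
            ) + penalty * (len(bounds) - 1)
            key = (cost, len(bounds) - 1, tuple(reversed(bps)))
            if best_key is None or key < best_key:
                best_key = key
                best_bounds = list(zip(bounds, bounds[1:]))
    return best_key[0], best_bounds


def midpoint_scan(grid: BinGrid, chrom: str, start: int, end: int):
    """Brute-force list of bin indices whose midpoint lies in an interval."""
    hits = []
    ci = grid.chrom_index(chrom)
    for i in range(grid.n_bins):
        if grid.bin_chrom[i] != ci:
            continue
        mid = (grid.bin_start[i] + grid.bin_end[i]) // 2
        if start <= mid < end:
            hits.append(i)
    return hits
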