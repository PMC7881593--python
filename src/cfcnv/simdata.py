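"""Synthetic shallow-sequencing cohorts with known copy-number truth.

The generator emulates the data a shallow cfDNA sequencing run produces:
per-bin read counts at 2–30 M reads genome-wide with Poisson (optionally
negative-binomial) noise, integer-copy CNV events diluted by the circulating
tumor fraction *f*, multiplicative regional depth biases that can be shared
across the healthy cohort (the recurrent technical artifacts of repetitive
regions), and a bimodal fragment-length distribution with a mononucleosomal
mode near 169 bp and a dinucleosomal shoulder near 320 bp.

The mixing model: a bin of tumor copy number ``c`` observed at tumor fraction
``f`` on a diploid background has expected relative depth ``(2 + f(c-2))/2``,
hence expected ``log2ratio = log2(1 + f(c/2 - 1))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .counts import CountProfile, FragmentLengthSample
from .grid import BinGrid

#: log2ratio floor absorbing the homozygous-deletion singularity (c=0, f=1).
LOG2_FLOOR = -4.0


# ---------------------------------------------------------------------------
# Truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CnvEvent:
    chrom: str
    start: int
    end: int
    copy: int

    def __post_init__(self) -> None:
        if self.copy < 0 or int(self.copy) != self.copy:
            raise ValueError(f"copy number must be a non-negative integer, "
                             f"got {self.copy}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad event interval {self.start}-{self.end}")


@dataclass(frozen=True)
class TruthProfile:
    """True integer copy state: a diploid background plus CNV events."""

    grid: BinGrid
    events: tuple[CnvEvent, ...] = ()
    ploidy: int = 2

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[CnvEvent]] = {}
        for ev in self.events:
            length = self.grid.chrom_lengths.get(ev.chrom)
            if length is None:
                raise ValueError(f"event chromosome {ev.chrom!r} not in grid")
            if ev.end > length:
                raise ValueError(
                    f"event {ev.chrom}:{ev.start}-{ev.end} exceeds "
                    f"chromosome length {length}")
            by_chrom.setdefault(ev.chrom, []).append(ev)
        for chrom, evs in by_chrom.items():
            evs = sorted(evs, key=lambda e: e.start)
            for a, b in zip(evs, evs[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"overlapping events on {chrom}: "
                        f"{a.start}-{a.end} and {b.start}-{b.end}")

    def bin_copy(self) -> np.ndarray:
        """Per-bin integer copy number by the bin-midpoint rule.

        A bin takes an event's copy number iff the bin midpoint falls inside
        the event interval; all other bins carry the background ploidy.
        """
        grid = self.grid
        copy = np.full(grid.n_bins, self.ploidy, dtype=np.int64)
        mid = (grid.bin_start + grid.bin_end) // 2
        for ev in self.events:
            ci = grid.chrom_index(ev.chrom)
            hit = (grid.bin_chrom == ci) & (mid >= ev.start) & (mid < ev.end)
            copy[hit] = ev.copy
        return copy


def make_truth_profile(
    grid: BinGrid, events: Sequence[tuple] | Sequence[CnvEvent],
    ploidy: int = 2,
) -> TruthProfile:
    """Validate and package CNV events into a :class:`TruthProfile`.

    ``events`` are ``(chrom, start_bp, end_bp, copy)`` tuples or
    :class:`CnvEvent` objects; they must lie within the grid and must not
    overlap on a chromosome.
    """
    evs = tuple(
        ev if isinstance(ev, CnvEvent) else CnvEvent(*ev) for ev in events
    )
    return TruthProfile(grid, evs, ploidy=ploidy)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BiasRegion:
    """A multiplicative regional depth bias, optionally cohort-shared."""

    chrom: str
    start: int
    end: int
    factor: float
    shared: bool = True

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError("bias factor must be strictly positive")


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters for one synthetic sample or cohort.

    ``dispersion`` is the negative-binomial overdispersion: bin variance is
    ``mu + dispersion * mu**2`` (0 means Poisson). Fragment parameters place
    the mononucleosomal mode and the dinucleosomal shoulder of the cfDNA
    fragment-length mixture.
    """

    tumor_fraction: float = 0.0
    total_reads: int = 2_000_000
    dispersion: float = 0.0
    bias_regions: tuple[BiasRegion, ...] = ()
    fragment_mode_bp: float = 169.0
    fragment_shoulder_bp: float = 320.0
    shoulder_weight: float = 0.15
    fragment_sigma: float = 0.12
    shoulder_sigma: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must be in [0, 1]")
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0.0 <= self.shoulder_weight <= 1.0:
            raise ValueError("shoulder_weight must be in [0, 1]")
        if self.fragment_mode_bp <= 0 or self.fragment_shoulder_bp <= 0:
            raise ValueError("fragment modes must be positive")
        object.__setattr__(self, "bias_regions", tuple(
            b if isinstance(b, BiasRegion) else BiasRegion(*b)
            for b in self.bias_regions))

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# Expected signal
# ---------------------------------------------------------------------------

def expected_log2ratio(c, f, floor: float = LOG2_FLOOR):
    """Expected log2ratio of a copy-``c`` region at tumor fraction ``f``.

    ``log2((2 + f*(c - 2)) / 2)``, clipped below at ``floor`` so the
    homozygous-deletion limit (c=0, f=1) stays finite.
    """
    c = np.asarray(c, dtype=float)
    f = np.asarray(f, dtype=float)
    if (c < 0).any():
        raise ValueError("copy number must be >= 0")
    if ((f < 0) | (f > 1)).any():
        raise ValueError("tumor fraction must be in [0, 1]")
    mixture = (2.0 + f * (c - 2.0)) / 2.0
    with np.errstate(divide="ignore"):
        r = np.log2(mixture)
    out = np.maximum(r, floor)
    return float(out) if out.ndim == 0 else out


def bias_vector(grid: BinGrid, regions: Sequence[BiasRegion]) -> np.ndarray:
    """Per-bin multiplicative bias from regional factors (midpoint rule)."""
    b = np.ones(grid.n_bins)
    mid = (grid.bin_start + grid.bin_end) // 2
    for reg in regions:
        ci = grid.chrom_index(reg.chrom)
        hit = (grid.bin_chrom == ci) & (mid >= reg.start) & (mid < reg.end)
        b[hit] *= reg.factor
    return b


# ---------------------------------------------------------------------------
# Count simulation
# ---------------------------------------------------------------------------

def expected_bin_means(
    grid: BinGrid, truth: TruthProfile, cfg: SimConfig,
    bias: np.ndarray | None = None,
) -> np.ndarray:
    """Expected per-bin counts; sums exactly to ``cfg.total_reads``."""
    if grid.n_bins == 0:
        raise ValueError("empty grid")
    copy = truth.bin_copy()
    mixture = 2.0 + cfg.tumor_fraction * (copy - 2.0)
    w = grid.bin_widths / grid.bin_widths.sum()
    if bias is None:
        bias = bias_vector(grid, cfg.bias_regions)
    weight = w * bias * mixture
    return cfg.total_reads * weight / weight.sum()


def simulate_counts(
    grid: BinGrid, truth: TruthProfile, cfg: SimConfig,
    rng: np.random.Generator | None = None,
    bias: np.ndarray | None = None,
) -> CountProfile:
    """Draw one sample's per-bin counts from the mixing model.

    Bin means follow ``N * w_i * b_i * (2 + f(c_i - 2)) / Z`` with ``w_i`` the
    bin-width share, ``b_i`` the regional bias and ``Z`` the normalizer; noise
    is Poisson, or negative-binomial when ``cfg.dispersion > 0``.
    """
    if truth.grid != grid:
        raise ValueError("truth profile is on a different grid")
    mu = expected_bin_means(grid, truth, cfg, bias=bias)
    if rng is None:
        rng = cfg.rng()
    if cfg.dispersion == 0:
        counts = rng.poisson(mu)
    else:
        n = 1.0 / cfg.dispersion
        counts = rng.negative_binomial(n, n / (n + mu))
    return CountProfile(grid, counts.astype(np.int64), sample="sim")


def simulate_healthy_cohort(
    grid: BinGrid, n_samples: int, cfg: SimConfig,
) -> list[CountProfile]:
    """Simulate copy-neutral samples sharing the flagged bias regions.

    Bias regions flagged ``shared`` apply the same factor to every sample
    (the recurrent mapping artifacts seen across healthy donors); a
    non-shared region is assigned to exactly one randomly chosen sample, so
    its recurrence count in the cohort is 1.
    """
    if n_samples < 2:
        raise ValueError("a cohort needs at least 2 samples")
    truth = TruthProfile(grid)
    ss = np.random.SeedSequence(cfg.seed)
    assign_rng = np.random.default_rng(ss.spawn(1)[0])
    owner = {
        i: int(assign_rng.integers(n_samples))
        for i, reg in enumerate(cfg.bias_regions) if not reg.shared
    }
    child_seeds = ss.spawn(n_samples)
    profiles = []
    for s in range(n_samples):
        regions = tuple(
            reg for i, reg in enumerate(cfg.bias_regions)
            if reg.shared or owner[i] == s
        )
        bias = bias_vector(grid, regions)
        rng = np.random.default_rng(child_seeds[s])
        prof = simulate_counts(grid, truth, cfg, rng=rng, bias=bias)
        profiles.append(prof.with_counts(prof.counts, sample=f"healthy{s + 1}"))
    return profiles


# ---------------------------------------------------------------------------
# Fragment lengths
# ---------------------------------------------------------------------------

def simulate_fragment_lengths(n: int, cfg: SimConfig) -> FragmentLengthSample:
    """Draw cfDNA fragment lengths from a two-lognormal location mixture.

    Components are parameterized by their modes (mononucleosomal
    ``fragment_mode_bp``, dinucleosomal ``fragment_shoulder_bp``); the
    shoulder receives mixing weight ``shoulder_weight``. A lognormal with
    log-scale sigma ``s`` and mode ``m`` has ``mu = ln(m) + s**2``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = cfg.rng()
    from_shoulder = rng.random(n) < cfg.shoulder_weight
    mu_mono = np.log(cfg.fragment_mode_bp) + cfg.fragment_sigma ** 2
    mu_di = np.log(cfg.fragment_shoulder_bp) + cfg.shoulder_sigma ** 2
    lengths = np.where(
        from_shoulder,
        rng.lognormal(mu_di, cfg.shoulder_sigma, n),
        rng.lognormal(mu_mono, cfg.fragment_sigma, n),
    )
    return FragmentLengthSample(np.maximum(np.rint(lengths), 1).astype(np.int64))


# ---------------------------------------------------------------------------
# Emission: count tables, truth BED, minimal BAM
# ---------------------------------------------------------------------------

def write_truth_bed(truth: TruthProfile, path) -> None:
    """Write events as BED with the copy number in column 5."""
    with open(path, "w") as fh:
        for ev in truth.events:
            fh.write(f"{ev.chrom}\t{ev.start}\t{ev.end}\tcnv\t{ev.copy}\n")


def write_bam(
    profile: CountProfile, path, cfg: SimConfig | None = None,
    rng: np.random.Generator | None = None,
) -> None:
    """Emit a minimal coordinate-sorted BAM realizing a count profile.

    One single-end read per count, placed uniformly within its bin (so the
    leftmost-position binning rule recovers the counts exactly), with length
    drawn from the fragment mixture. Intended for end-to-end I/O tests; the
    count-table path is the default at genome scale.
    """
    import pysam

    cfg = cfg or SimConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    grid = profile.grid
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length in grid.chromosomes],
    }
    n_reads = profile.total_reads
    frag = simulate_fragment_lengths(max(n_reads, 1), cfg) if n_reads else None
    k = 0
    with pysam.AlignmentFile(str(path), "wb", header=header) as out:
        for i in range(grid.n_bins):
            c = int(profile.counts[i])
            if c == 0:
                continue
            lo, hi = int(grid.bin_start[i]), int(grid.bin_end[i])
            pos = np.sort(rng.integers(lo, hi, size=c))
            chrom_len = grid.chromosomes[int(grid.bin_chrom[i])][1]
            for p in pos:
                a = pysam.AlignedSegment()
                a.query_name = f"sim{k}"
                a.flag = 0
                a.reference_id = int(grid.bin_chrom[i])
                a.reference_start = int(p)
                a.mapping_quality = 60
                length = int(min(frag.lengths[k], chrom_len - p))
                a.cigartuples = [(0, max(length, 1))]
                k += 1
                out.write(a)
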