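"""CNV calling: thresholds, recurrent-artifact masking, gene-level tiers.

Segments are promoted to calls when their absolute mean clears the
mode-specific threshold (|log2ratio| >= 0.10 without a control, >= 0.04 in
paired mode, where shared technical biases have already cancelled). Bins
recurrently "altered" across healthy donors are masked as technical
artifacts before calling, and calls are summarized gene-by-gene into the
five-tier amplification/deletion landscape (boundaries at |log2ratio| 0.10
and 0.30).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grid import BinGrid
from .normalize import RatioProfile
from .segment import SegmentSet, bin_level_means, segment_profile

log = logging.getLogger(__name__)

#: Calling threshold on |segment mean| without a matched control; recurrent
#: artifacts reach roughly this magnitude.
NOCONTROL_THRESHOLD = 0.10
#: Calling threshold in paired mode, where shared biases cancel.
PAIRED_THRESHOLD = 0.04
#: |log2ratio| at which a healthy-cohort bin counts as altered.
DEFAULT_ALTER_THRESHOLD = 0.10
#: Minimum number of healthy samples sharing an alteration for masking.
DEFAULT_MIN_RECURRENCE = 2
#: Calls with more than this fraction of masked bins are dropped.
MASKED_CALL_FRACTION = 0.5

TIER_HIGH_AMP = "high_amp"
TIER_LOW_AMP = "low_amp"
TIER_NEUTRAL = "neutral"
TIER_LOW_DEL = "low_del"
TIER_HIGH_DEL = "high_del"
TIER_LOW_BOUND = 0.10
TIER_HIGH_BOUND = 0.30


def default_threshold(mode: str) -> float:
    return PAIRED_THRESHOLD if mode == "paired" else NOCONTROL_THRESHOLD


@dataclass(frozen=True)
class ArtifactMask:
    """Bins recurrently altered across healthy samples."""

    grid: BinGrid
    masked: np.ndarray  # bool per bin
    recurrence: np.ndarray  # int per bin
    samples: tuple[str, ...]
    alter_threshold: float
    min_recurrence: int

    @property
    def n_masked(self) -> int:
        return int(self.masked.sum())


@dataclass(frozen=True)
class CnvCallSet:
    """Thresholded calls with mask provenance."""

    grid: BinGrid
    calls: pd.DataFrame  # chrom,start,end,n_bins,seg_mean,direction,masked_fraction
    mode: str
    threshold: float
    dropped_masked: int = 0

    @property
    def n_calls(self) -> int:
        return len(self.calls)


@dataclass(frozen=True)
class GeneLandscape:
    """Gene x sample log2ratio values and amplification/deletion tiers."""

    values: pd.DataFrame  # genes x samples, float (NaN = no data)
    tiers: pd.DataFrame  # genes x samples, tier strings

    @property
    def gene_counts(self) -> pd.Series:
        """Per-gene number of samples with a non-neutral tier."""
        return (
            self.tiers.isin([TIER_HIGH_AMP, TIER_LOW_AMP,
                             TIER_LOW_DEL, TIER_HIGH_DEL]).sum(axis=1)
        )

    @property
    def sample_counts(self) -> pd.Series:
        """Per-sample number of genes with a non-neutral tier."""
        return (
            self.tiers.isin([TIER_HIGH_AMP, TIER_LOW_AMP,
                             TIER_LOW_DEL, TIER_HIGH_DEL]).sum(axis=0)
        )


# ---------------------------------------------------------------------------
# Artifact mask
# ---------------------------------------------------------------------------

def build_artifact_mask(
    healthy: Sequence[RatioProfile],
    alter_threshold: float = DEFAULT_ALTER_THRESHOLD,
    min_recurrence: int = DEFAULT_MIN_RECURRENCE,
    **segment_kwargs,
) -> ArtifactMask:
    """Mask bins altered in at least ``min_recurrence`` healthy samples.

    Each healthy profile is segmented and a bin counts as altered when the
    absolute value of its bin-level segment mean reaches ``alter_threshold``.
    """
    if len(healthy) < 2:
        raise ValueError("artifact masking needs at least 2 healthy profiles")
    grid = healthy[0].grid
    recurrence = np.zeros(grid.n_bins, dtype=np.int64)
    for p in healthy:
        if p.grid != grid:
            raise ValueError("healthy profiles are on different grids")
        blm = bin_level_means(segment_profile(p, **segment_kwargs))
        altered = np.abs(blm) >= alter_threshold
        recurrence += np.where(np.isnan(blm), False, altered)
    masked = recurrence >= min_recurrence
    return ArtifactMask(
        grid, masked, recurrence, tuple(p.sample for p in healthy),
        alter_threshold, min_recurrence,
    )


# ---------------------------------------------------------------------------
# Calls
# ---------------------------------------------------------------------------

def call_cnvs(
    s: SegmentSet,
    threshold: float | None = None,
    mask: ArtifactMask | None = None,
    min_bins: int = 3,
) -> CnvCallSet:
    """Threshold segments into gain/loss calls, dropping masked artifacts.

    A segment becomes a call when ``|seg_mean| >= threshold`` and it spans at
    least ``min_bins`` bins; segments with more than half their bins inside
    the artifact mask are dropped (and counted) even if above threshold.
    """
    if threshold is None:
        threshold = default_threshold(s.mode)
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    rows = []
    dropped = 0
    for k, row in s.table.iterrows():
        if mask is not None:
            members = np.flatnonzero(s.bin_seg_id == k)
            mf = float(mask.masked[members].mean()) if len(members) else 0.0
        else:
            mf = 0.0
        if abs(row["seg_mean"]) < threshold or row["n_bins"] < min_bins:
            continue
        if mf > MASKED_CALL_FRACTION:
            dropped += 1
            log.info("call: dropped masked segment %s:%d-%d (%.0f%% masked)",
                     row["chrom"], row["start"], row["end"], 100 * mf)
            continue
        rows.append({
            "chrom": row["chrom"], "start": row["start"], "end": row["end"],
            "n_bins": row["n_bins"], "seg_mean": row["seg_mean"],
            "direction": "gain" if row["seg_mean"] > 0 else "loss",
            "masked_fraction": mf,
        })
    calls = pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "n_bins", "seg_mean", "direction",
        "masked_fraction"])
    return CnvCallSet(s.grid, calls, s.mode, threshold, dropped)


def write_calls_bed(c: CnvCallSet, path) -> None:
    """BED + score: chrom, start, end, direction, seg_mean."""
    with open(path, "w") as fh:
        fh.write(f"#mode={c.mode}\n#threshold={c.threshold}\n")
        for _, row in c.calls.iterrows():
            fh.write(f"{row['chrom']}\t{row['start']}\t{row['end']}\t"
                     f"{row['direction']}\t{row['seg_mean']:.4f}\n")


# ---------------------------------------------------------------------------
# Gene landscape
# ---------------------------------------------------------------------------

def tier_of(value: float) -> str:
    """Five-tier classification with boundaries at |log2ratio| 0.10 / 0.30.

    The low tier is inclusive at 0.10 and exclusive at 0.30.
    """
    if np.isnan(value):
        return "no_data"
    if value >= TIER_HIGH_BOUND:
        return TIER_HIGH_AMP
    if value >= TIER_LOW_BOUND:
        return TIER_LOW_AMP
    if value <= -TIER_HIGH_BOUND:
        return TIER_HIGH_DEL
    if value <= -TIER_LOW_BOUND:
        return TIER_LOW_DEL
    return TIER_NEUTRAL


def read_gene_bed(path) -> pd.DataFrame:
    """Read gene regions from BED (chrom, start, end, name)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed BED at line {ln}: "
                                 f"expected >= 3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(
                    f"malformed BED at line {ln}: non-integer coordinates"
                ) from None
            if start >= end or start < 0:
                raise ValueError(f"malformed BED at line {ln}: bad interval")
            name = fields[3] if len(fields) > 3 else f"region_{ln}"
            rows.append({"chrom": fields[0], "start": start, "end": end,
                         "name": name})
    if not rows:
        raise ValueError(f"no gene records in {path}")
    return pd.DataFrame(rows)


def default_gene_bed_path():
    """Path of the bundled lung-cancer gene BED (GRCh38 coordinates)."""
    from importlib.resources import files

    return files("cfcnv.data").joinpath("genes_grch38.bed")


def annotate_genes(
    segments: SegmentSet | Mapping[str, SegmentSet],
    genes: pd.DataFrame | str,
) -> GeneLandscape:
    """Per-gene log2ratio values and tiers for one or more samples.

    A gene's value is the overlap-length-weighted mean of the segment means
    covering it; genes with no usable overlap are reported as no-data.
    ``genes`` may be a BED path or a DataFrame from :func:`read_gene_bed`.
    """
    if not isinstance(genes, pd.DataFrame):
        genes = read_gene_bed(genes)
    if isinstance(segments, SegmentSet):
        segments = {segments.sample: segments}
    values: dict[str, dict[str, float]] = {}
    for label, segset in segments.items():
        col = {}
        tab = segset.table
        for _, g in genes.iterrows():
            sel = tab[tab["chrom"] == g["chrom"]]
            ov = np.minimum(sel["end"], g["end"]) - np.maximum(
                sel["start"], g["start"])
            w = np.maximum(ov, 0).astype(float)
            if w.sum() == 0:
                col[g["name"]] = np.nan
            else:
                col[g["name"]] = float(
                    (w * sel["seg_mean"]).sum() / w.sum())
        values[label] = col
    vals = pd.DataFrame(values).reindex(genes["name"])
    tiers = vals.map(tier_of)
    return GeneLandscape(vals, tiers)


def write_landscape(l: GeneLandscape, path) -> None:
    """Tab-delimited gene x sample matrix of values, tiers alongside."""
    with open(path, "w") as fh:
        combined = l.values.round(4).astype(str) + ":" + l.tiers
        combined.to_csv(fh, sep="\t")
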