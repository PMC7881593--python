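"""Evaluation procedures: concordance, confusion metrics, subsampling, titration.

Implements the benchmarking machinery for shallow CNV profiling: Pearson
correlation and three-state per-bin concordance between two profiles,
confusion-matrix metrics against a binary truth, robustness of results under
read subsampling, and an in-silico tumor-fraction titration that locates the
minimal reliably detected ctDNA fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import simdata
from .call import PAIRED_THRESHOLD, call_cnvs, default_threshold
from .counts import CountProfile, merge_profiles, subsample_profile
from .grid import BinGrid
from .normalize import normalize_nocontrol, normalize_paired
from .segment import bin_level_means, segment_profile
from .simdata import CnvEvent, SimConfig, TruthProfile

log = logging.getLogger(__name__)

MIN_SHARED_BINS = 100
GAIN, NEUTRAL, LOSS = 1, 0, -1


@dataclass(frozen=True)
class EvalReport:
    """Concordance and/or confusion metrics over shared usable bins.

    Undefined ratios (zero denominator) are ``None`` rather than 0.
    """

    n_bins: int
    pearson_r: float | None = None
    concordant_fraction: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    accuracy: float | None = None
    precision: float | None = None
    settings: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {"n_bins": self.n_bins}
        for k in ("pearson_r", "concordant_fraction", "sensitivity",
                  "specificity", "accuracy", "precision"):
            d[k] = getattr(self, k)
        d.update(self.settings)
        return d


@dataclass(frozen=True)
class TitrationResult:
    """Detection outcomes across tumor fractions."""

    table: pd.DataFrame  # columns: tumor_fraction, replicate, detected
    rate_target: float

    @property
    def detection_rates(self) -> pd.Series:
        return self.table.groupby("tumor_fraction")["detected"].mean()

    @property
    def minimal_detected_fraction(self) -> float | None:
        """Smallest fraction whose detection rate reaches the target."""
        rates = self.detection_rates
        ok = rates[rates >= self.rate_target]
        return float(ok.index.min()) if len(ok) else None


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

def three_state(values: np.ndarray, threshold: float) -> np.ndarray:
    """Classify per-bin values as gain (+1) / neutral (0) / loss (-1)."""
    states = np.zeros(len(values), dtype=np.int8)
    states[values >= threshold] = GAIN
    states[values <= -threshold] = LOSS
    return states


def compare_profiles(
    a: np.ndarray, b: np.ndarray, class_threshold: float,
    tolerance: float | None = None,
) -> EvalReport:
    """Pearson correlation and per-bin concordance of two bin-mean vectors.

    A bin is concordant when its three-state classification (gain at
    ``>= class_threshold``, loss at ``<= -class_threshold``, else neutral)
    agrees between the two profiles. If ``tolerance`` is given, a bin is
    instead concordant when ``|a - b| <= tolerance`` (the alternative
    band-based definition; class agreement is the default).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles have different lengths")
    shared = np.isfinite(a) & np.isfinite(b)
    n = int(shared.sum())
    if n < MIN_SHARED_BINS:
        raise ValueError(f"only {n} shared usable bins "
                         f"(need >= {MIN_SHARED_BINS})")
    av, bv = a[shared], b[shared]
    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        r = 1.0 if np.allclose(av, bv) else None
    else:
        r = float(stats.pearsonr(av, bv).statistic)
    if tolerance is not None:
        conc = float(np.mean(np.abs(av - bv) <= tolerance))
    else:
        conc = float(np.mean(
            three_state(av, class_threshold) == three_state(bv, class_threshold)
        ))
    return EvalReport(
        n_bins=n, pearson_r=r, concordant_fraction=conc,
        settings={"class_threshold": class_threshold, "tolerance": tolerance},
    )


# ---------------------------------------------------------------------------
# Confusion metrics
# ---------------------------------------------------------------------------

def classification_metrics(
    test_states: np.ndarray, truth_states: np.ndarray,
) -> EvalReport:
    """Sensitivity/specificity/accuracy/precision of binary altered calls.

    Inputs are per-bin states; non-zero means altered (gains and losses
    collapse onto one positive class, mirroring a truth-set comparison where
    the reference caller defines the positives).
    """
    t = np.asarray(test_states) != 0
    y = np.asarray(truth_states) != 0
    if t.shape != y.shape:
        raise ValueError("state vectors have different lengths")
    tp = int((t & y).sum())
    fn = int((~t & y).sum())
    tn = int((~t & ~y).sum())
    fp = int((t & ~y).sum())

    def ratio(num: int, den: int) -> float | None:
        return num / den if den else None

    return EvalReport(
        n_bins=len(t),
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        accuracy=ratio(tp + tn, len(t)) if len(t) else None,
        precision=ratio(tp, tp + fp),
        settings={"tp": tp, "fn": fn, "tn": tn, "fp": fp},
    )


# ---------------------------------------------------------------------------
# Subsampling robustness
# ---------------------------------------------------------------------------

def _pipeline_bin_means(p: CountProfile, **segment_kwargs) -> np.ndarray:
    return bin_level_means(
        segment_profile(normalize_nocontrol(p), **segment_kwargs))


def subsampling_study(
    p: CountProfile,
    depths: list[int],
    replicates: int = 10,
    seed: int = 0,
    class_threshold: float | None = None,
    **segment_kwargs,
) -> pd.DataFrame:
    """Concordance of subsampled reanalyses against the full-depth result.

    For each depth and replicate the profile is binomially thinned,
    renormalized and resegmented, and its bin-level segment means are
    compared with the full-depth means. Returns one row per (depth,
    replicate) with the comparison metrics.
    """
    if class_threshold is None:
        class_threshold = default_threshold("nocontrol")
    full = _pipeline_bin_means(p, **segment_kwargs)
    rng = np.random.default_rng(seed)
    rows = []
    for depth in depths:
        if depth > p.total_reads:
            raise ValueError(f"depth {depth} exceeds total {p.total_reads}")
        for rep in range(replicates):
            thinned = subsample_profile(p, depth, rng)
            means = _pipeline_bin_means(thinned, **segment_kwargs)
            rep_report = compare_profiles(means, full, class_threshold)
            rows.append({"depth": depth, "replicate": rep,
                         **rep_report.as_dict()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tumor-fraction titration
# ---------------------------------------------------------------------------

def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """min(overlap/len(a), overlap/len(b)) for two half-open intervals."""
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return 0.0
    return min(ov / (a[1] - a[0]), ov / (b[1] - b[0]))


def titrate_tumor_fraction(
    event: CnvEvent | tuple,
    fractions: list[float],
    grid: BinGrid | None = None,
    total_reads: int = 2_000_000,
    n_controls: int = 4,
    control_reads: int = 5_000_000,
    replicates: int = 20,
    seed: int = 0,
    threshold: float = PAIRED_THRESHOLD,
    min_overlap: float = 0.5,
    rate_target: float = 0.9,
    min_bins: int = 3,
    **segment_kwargs,
) -> TitrationResult:
    """In-silico dilution series for one CNV event, paired-mode pipeline.

    For each tumor fraction and replicate, a tumor sample carrying the event
    is simulated at ``total_reads`` together with a merged control built from
    ``n_controls`` copy-neutral samples of ``control_reads`` each; the paired
    profile is segmented and called, and the event counts as detected when a
    sign-correct call reciprocally overlaps it by at least ``min_overlap``.
    """
    if sorted(fractions) != list(fractions):
        raise ValueError("fractions must be sorted ascending")
    if replicates < 10:
        raise ValueError("need at least 10 replicates per fraction")
    if not isinstance(event, CnvEvent):
        event = CnvEvent(*event)
    grid = grid or BinGrid.human()
    want_gain = event.copy > 2
    ss = np.random.SeedSequence(seed)
    rows = []
    for f in fractions:
        truth = TruthProfile(grid, (event,))
        for rep in range(replicates):
            child = ss.spawn(1)[0]
            rng = np.random.default_rng(child)
            tumor_cfg = SimConfig(tumor_fraction=f, total_reads=total_reads,
                                  seed=seed)
            tumor = simdata.simulate_counts(grid, truth, tumor_cfg, rng=rng)
            neutral = TruthProfile(grid)
            ctrl_cfg = SimConfig(total_reads=control_reads, seed=seed)
            controls = [
                simdata.simulate_counts(grid, neutral, ctrl_cfg, rng=rng)
                for _ in range(n_controls)
            ]
            merged = merge_profiles(controls)
            ratio = normalize_paired(tumor, merged)
            segs = segment_profile(ratio, **segment_kwargs)
            calls = call_cnvs(segs, threshold=threshold, min_bins=min_bins)
            detected = False
            for _, c in calls.calls.iterrows():
                if c["chrom"] != event.chrom:
                    continue
                if (c["direction"] == "gain") != want_gain:
                    continue
                ro = reciprocal_overlap(
                    (c["start"], c["end"]), (event.start, event.end))
                if ro >= min_overlap:
                    detected = True
                    break
            rows.append({"tumor_fraction": f, "replicate": rep,
                         "detected": detected})
    return TitrationResult(pd.DataFrame(rows), rate_target)
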