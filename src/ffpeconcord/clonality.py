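"""Clonal/subclonal decomposition of the VAF distribution.

The tumor's clonal population shows up as the dominant cluster in the
variant-allele-frequency (VAF) distribution of high-confidence somatic
variants; subclones appear as clusters at lower VAF, and residual germline
contamination near 0.5.  The procedure is:

1. restrict to *bona fide diploid* variants — consensus (>= 2 caller)
   variants in copy-number-neutral segments of BOTH the FF and the FFPE
   sample, excluding sex chromosomes and mitochondrion, so VAFs need no
   copy-number correction;
2. estimate the VAF density with a Gaussian kernel, the bandwidth chosen by
   cross-validated held-out log-likelihood over a grid spanning
   [0.01, 0.1];
3. cut [0, 1] into intervals at the interior local minima of the density;
4. pick the clonal interval by rule: the interval with the highest-VAF mode
   below a germline cut (default 0.45) holding at least a minimum share of
   the variants (default 10%) — a deterministic stand-in for the visual
   inspection a human analyst would do, with a manual override available;
5. label variants in lower intervals subclonal, those above the clonal
   interval excluded (germline-like), and compare FF vs FFPE concordance
   separately for clonal and subclonal variants.

No purity correction is applied: clonal labels derive from each sample's
own VAF distribution, which makes them purity-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .callset_io import CnStatus, SegmentSet, VariantCall, VariantKey
from .concordance import ConcordanceResult, ConsensusCallSet, concordance_metrics

EXCLUDED_CONTIGS = {"X", "Y", "MT"}

KDE_GRID_POINTS = 512
BANDWIDTH_GRID = tuple(np.geomspace(0.01, 0.1, 10))
CV_FOLDS = 5
#: Bandwidth CV cost is quadratic in n; above this size the CV runs on a
#: deterministic subsample (the selected bandwidth is insensitive to this
#: because the likelihood curve over a 10-point grid is coarse).
CV_MAX_POINTS = 1500


@dataclass
class BonaFideSet:
    """Consensus variants lying in CN-neutral territory of both samples."""

    calls: list[VariantCall]

    def keys(self) -> set[VariantKey]:
        return {c.key for c in self.calls}

    def vafs(self) -> np.ndarray:
        return np.array([c.tumor_vaf for c in self.calls])

    def __len__(self) -> int:
        return len(self.calls)


def diploid_filter(
    consensus: ConsensusCallSet,
    seg_ff: SegmentSet,
    seg_ffpe: SegmentSet,
) -> BonaFideSet:
    """Keep consensus variants neutral in both segmentations, autosomes only.

    Positions not covered by a segment count as non-neutral (conservative:
    unsegmented territory is not admitted as diploid).
    """
    kept: list[VariantCall] = []
    for key in sorted(consensus.keys(), key=lambda k: k.sort_key):
        if key.chrom in EXCLUDED_CONTIGS:
            continue
        if seg_ff.status_at(key.chrom, key.pos) != CnStatus.NEUTRAL:
            continue
        if seg_ffpe.status_at(key.chrom, key.pos) != CnStatus.NEUTRAL:
            continue
        kept.append(consensus.representative_call(key))
    return BonaFideSet(calls=kept)


@dataclass
class VafDensity:
    """Gaussian-KDE estimate of the VAF density on a fixed grid."""

    bandwidth: float
    grid: np.ndarray
    density: np.ndarray
    minima: list[float]  # interior local-minimum VAFs, ascending
    maxima: list[float]  # local-maximum VAFs, ascending

    def __post_init__(self) -> None:
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")


def _local_extrema(grid: np.ndarray, density: np.ndarray) -> tuple[list[float], list[float]]:
    """Extrema by sign changes of the first differences of the grid values.

    Plateaus are attributed to their leftmost point, which keeps detection
    deterministic and stable under grid refinement.  A density that falls
    away from the left edge (or rises into the right edge) contributes a
    boundary maximum there, so minima and maxima always interleave.
    """
    sign = np.sign(np.diff(density))
    minima: list[float] = []
    maxima: list[float] = []
    last_slope = 0
    plateau_start: int | None = None
    for i, s in enumerate(sign):  # s is the slope between grid[i] and grid[i+1]
        if s == 0:
            if plateau_start is None:
                plateau_start = i
            continue
        if last_slope != 0 and s != last_slope:
            idx = plateau_start if plateau_start is not None else i
            if last_slope < 0:
                minima.append(float(grid[idx]))
            else:
                maxima.append(float(grid[idx]))
        last_slope = s
        plateau_start = None
    nonzero = sign[sign != 0]
    if len(nonzero):
        if nonzero[0] < 0:  # falling away from the left edge
            maxima.insert(0, float(grid[0]))
        if nonzero[-1] > 0:  # rising into the right edge
            maxima.append(float(grid[-1]))
    return minima, maxima


def _kde_log_density(x: np.ndarray, data: np.ndarray, bandwidth: float) -> np.ndarray:
    """Log Gaussian-KDE density of ``data`` evaluated at points ``x``."""
    z = (x[:, None] - data[None, :]) / bandwidth
    log_kernel = -0.5 * z * z - np.log(bandwidth * np.sqrt(2.0 * np.pi))
    return logsumexp(log_kernel, axis=1) - np.log(len(data))


def select_bandwidth(
    vafs: np.ndarray,
    bandwidths: Sequence[float] = BANDWIDTH_GRID,
    n_folds: int = CV_FOLDS,
) -> float:
    """Cross-validated bandwidth: maximize mean held-out log-likelihood.

    Folds are assigned by a fixed shuffle so the choice is deterministic;
    ties prefer the smaller bandwidth.  Very large inputs are subsampled
    (deterministically) for the CV only; the final density always uses all
    points.
    """
    rng = np.random.default_rng(0)
    if len(vafs) > CV_MAX_POINTS:
        vafs = rng.choice(vafs, size=CV_MAX_POINTS, replace=False)
    n = len(vafs)
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)
    best_bw = None
    best_ll = -np.inf
    for bw in sorted(bandwidths):
        ll_sum = 0.0
        for f in folds:
            train_mask = np.ones(n, dtype=bool)
            train_mask[f] = False
            ll_sum += _kde_log_density(vafs[f], vafs[train_mask], bw).sum()
        ll = ll_sum / n
        if ll > best_ll:  # strict: ties keep the earlier (smaller) bandwidth
            best_ll, best_bw = ll, bw
    return float(best_bw)


def fit_kde(
    vafs: "np.ndarray | Iterable[float]",
    bandwidth: float | None = None,
) -> VafDensity:
    """Estimate the VAF density with a Gaussian kernel on a 512-point grid.

    Needs at least 10 values with some spread; with ``bandwidth=None`` the
    cross-validation protocol picks one from the standard grid.
    """
    vafs = np.asarray(list(vafs) if not isinstance(vafs, np.ndarray) else vafs, dtype=float)
    if len(vafs) < 10:
        raise ValueError(f"need >= 10 VAFs to estimate a density, got {len(vafs)}")
    if np.any((vafs < 0) | (vafs > 1)):
        raise ValueError("VAFs must lie in [0, 1]")
    if np.ptp(vafs) == 0:
        raise ValueError("all VAFs identical; density unidentifiable")
    if bandwidth is None:
        bandwidth = select_bandwidth(vafs)
    grid = np.linspace(0.0, 1.0, KDE_GRID_POINTS)
    density = np.exp(_kde_log_density(grid, vafs, bandwidth))
    minima, maxima = _local_extrema(grid, density)
    return VafDensity(
        bandwidth=float(bandwidth),
        grid=grid,
        density=density,
        minima=minima,
        maxima=maxima,
    )


def segment_density(d: VafDensity) -> list[tuple[float, float]]:
    """Partition [0, 1] into intervals split at the interior local minima."""
    cuts = [0.0] + list(d.minima) + [1.0]
    return [(cuts[i], cuts[i + 1]) for i in range(len(cuts) - 1)]


@dataclass
class ClonalityResult:
    """Per-variant clonal/subclonal labels and the interval that drove them."""

    labels: dict[VariantKey, str]  # clonal | subclonal | excluded_high
    clonal_interval: tuple[float, float]
    bandwidth: float
    density: VafDensity | None = None

    def keys_with(self, label: str) -> set[VariantKey]:
        return {k for k, v in self.labels.items() if v == label}

    @property
    def clonal_keys(self) -> set[VariantKey]:
        return self.keys_with("clonal")

    @property
    def subclonal_keys(self) -> set[VariantKey]:
        return self.keys_with("subclonal")


def _interval_mode(d: VafDensity, lo: float, hi: float) -> float:
    mask = (d.grid >= lo) & (d.grid <= hi)
    sub = np.where(mask)[0]
    return float(d.grid[sub[np.argmax(d.density[sub])]])


def select_clonal(
    intervals: Sequence[tuple[float, float]],
    calls: "Sequence[VariantCall] | BonaFideSet",
    density: VafDensity,
    germline_cut: float = 0.45,
    min_mass: float = 0.10,
    override_interval: tuple[float, float] | None = None,
) -> ClonalityResult:
    """Label variants clonal / subclonal / excluded_high.

    The clonal interval is the density interval whose mode is the highest
    VAF below ``germline_cut`` while containing at least ``min_mass`` of
    the variants; intervals below it are subclonal, variants above it are
    excluded as germline-like.  ``override_interval`` bypasses the rule
    (the programmatic equivalent of picking the cluster by eye).
    """
    if isinstance(calls, BonaFideSet):
        calls = calls.calls
    vafs = np.array([c.tumor_vaf for c in calls])
    n = len(vafs)
    if n == 0:
        raise ValueError("no variants to label")

    if override_interval is not None:
        clonal_lo, clonal_hi = override_interval
    else:
        candidates = []
        for lo, hi in intervals:
            in_iv = (vafs >= lo) & (vafs < hi) if hi < 1.0 else (vafs >= lo) & (vafs <= hi)
            mass = in_iv.sum() / n
            mode = _interval_mode(density, lo, hi)
            if mode < germline_cut and mass >= min_mass:
                candidates.append((mode, lo, hi))
        if not candidates:
            raise ValueError(
                "no density interval has its mode below the germline cut with "
                f"mass >= {min_mass:.0%}; pass override_interval=(lo, hi) to "
                "select the clonal cluster manually"
            )
        _, clonal_lo, clonal_hi = max(candidates)

    labels: dict[VariantKey, str] = {}
    for c in calls:
        v = c.tumor_vaf
        if v < clonal_lo:
            labels[c.key] = "subclonal"
        elif v > clonal_hi:
            labels[c.key] = "excluded_high"
        else:
            labels[c.key] = "clonal"
    return ClonalityResult(
        labels=labels,
        clonal_interval=(clonal_lo, clonal_hi),
        bandwidth=density.bandwidth,
        density=density,
    )


def label_clonality(
    bona_fide: BonaFideSet,
    germline_cut: float = 0.45,
    min_mass: float = 0.10,
    bandwidth: float | None = None,
    override_interval: tuple[float, float] | None = None,
) -> ClonalityResult:
    """End-to-end: KDE fit, density segmentation, clonal labelling."""
    d = fit_kde(bona_fide.vafs(), bandwidth=bandwidth)
    intervals = segment_density(d)
    return select_clonal(
        intervals,
        bona_fide,
        d,
        germline_cut=germline_cut,
        min_mass=min_mass,
        override_interval=override_interval,
    )


@dataclass
class ClonalConcordance:
    """FF-vs-FFPE concordance split by clonality, plus the label cross-tab.

    A side with no variants of a class leaves that metric undefined
    (``None`` with the flag False) rather than reporting a misleading 0.
    """

    clonal: ConcordanceResult | None
    subclonal: ConcordanceResult | None
    clonal_defined: bool
    subclonal_defined: bool
    cross_tab: pd.DataFrame

    LABELS = ("clonal", "subclonal", "excluded_high")


def clonal_concordance(
    ff: ClonalityResult,
    ffpe: ClonalityResult,
) -> ClonalConcordance:
    """Concordance over clonal and subclonal keys, with a 3x3 FF-vs-FFPE
    label cross-classification of the shared keys."""
    results: dict[str, ConcordanceResult | None] = {}
    defined: dict[str, bool] = {}
    for label in ("clonal", "subclonal"):
        ff_keys = ff.keys_with(label)
        ffpe_keys = ffpe.keys_with(label)
        ok = bool(ff_keys) and bool(ffpe_keys)
        defined[label] = ok
        results[label] = concordance_metrics(ff_keys, ffpe_keys) if ok else None

    labels = ClonalConcordance.LABELS
    shared = set(ff.labels) & set(ffpe.labels)
    tab = pd.DataFrame(0, index=list(labels), columns=list(labels))
    for key in shared:
        tab.loc[ff.labels[key], ffpe.labels[key]] += 1
    tab.index.name = "FF"
    tab.columns.name = "FFPE"
    return ClonalConcordance(
        clonal=results["clonal"],
        subclonal=results["subclonal"],
        clonal_defined=defined["clonal"],
        subclonal_defined=defined["subclonal"],
        cross_tab=tab,
    )
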