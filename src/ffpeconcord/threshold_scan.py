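"""Per-caller significance-threshold optimization on the FFPE sample.

Each caller attaches a significance score to its calls (Strelka2 somatic
EVS, Mutect2 TLOD — higher is more confident; VarScan2 somatic p-value,
Shimmer q-value — lower is more confident).  Because FFPE calls carry
systematically weaker scores than their FF counterparts, a threshold tuned
on the FFPE call set can trade precision against sensitivity in recovering
an FF-derived ground truth.  The scan is an exhaustive grid search
maximizing F1 against that ground truth, which is defined as the union of
FF calls made by at least two callers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .callset_io import CALLER_POLARITY, CALLERS, CallSet, VariantKey
from .concordance import ConcordanceResult, concordance_metrics, consensus

KeySet = set[VariantKey]


@dataclass(frozen=True)
class ThresholdGrid:
    """Inclusive arithmetic grid of candidate thresholds for one caller.

    Grid values are generated by integer index (``lo + i*step``) to avoid
    floating-point accumulation over many steps.
    """

    caller: str
    lo: float
    hi: float
    step: float

    def __post_init__(self) -> None:
        if self.caller not in CALLERS:
            raise ValueError(f"unknown caller {self.caller!r}")
        if not self.lo < self.hi:
            raise ValueError(f"grid needs lo < hi, got [{self.lo}, {self.hi}]")
        if self.step <= 0:
            raise ValueError(f"grid step must be > 0, got {self.step}")

    @property
    def polarity(self) -> str:
        return CALLER_POLARITY[self.caller]

    def values(self) -> list[float]:
        out = []
        i = 0
        # tiny tolerance so an endpoint reached with float error is kept
        while (v := self.lo + i * self.step) <= self.hi + self.step * 1e-9:
            out.append(round(v, 12))
            i += 1
        return out


#: Screening spaces for the threshold optimization, per caller.
_DEFAULT_GRIDS: dict[str, tuple[float, float, float]] = {
    "strelka2": (5.0, 20.0, 0.25),  # somatic EVS
    "mutect2": (0.0, 200.0, 1.0),  # TLOD
    "varscan2": (0.00005, 0.01, 0.00005),  # somatic p-value
    "shimmer": (0.0005, 0.05, 0.0005),  # q-value
}


def default_grid(caller: str) -> ThresholdGrid:
    """The standard screening space for a caller's significance score."""
    if caller not in _DEFAULT_GRIDS:
        raise ValueError(f"unknown caller {caller!r}; expected one of {CALLERS}")
    lo, hi, step = _DEFAULT_GRIDS[caller]
    return ThresholdGrid(caller=caller, lo=lo, hi=hi, step=step)


def apply_threshold(cs: CallSet, t: float) -> KeySet:
    """Keys surviving threshold ``t`` under the caller's score polarity.

    Scores exactly at the threshold are retained (>= for higher-is-better
    scores, <= for lower-is-better).
    """
    if cs.score_polarity == "higher_better":
        return {c.key for c in cs if c.score >= t}
    return {c.key for c in cs if c.score <= t}


@dataclass
class ThresholdScanResult:
    caller: str
    thresholds: list[float]
    results: list[ConcordanceResult]
    best_threshold: float
    best_f1: float

    def best_result(self) -> ConcordanceResult:
        return self.results[self.thresholds.index(self.best_threshold)]

    def as_rows(self) -> list[dict[str, float]]:
        return [
            {"threshold": t, **r.as_row()}
            for t, r in zip(self.thresholds, self.results)
        ]


def scan(
    ffpe_cs: CallSet,
    ground_truth: "CallSet | KeySet",
    grid: ThresholdGrid | None = None,
) -> ThresholdScanResult:
    """Exhaustive F1-maximizing threshold search over a grid.

    Evaluates the FFPE call set against the ground truth at every grid
    point; ties in best F1 are broken toward the more stringent threshold
    (larger for higher-is-better scores, smaller for lower-is-better),
    which is deterministic and conservative.
    """
    if grid is None:
        grid = default_grid(ffpe_cs.caller)
    if grid.caller != ffpe_cs.caller:
        raise ValueError(f"grid caller {grid.caller!r} != call set caller {ffpe_cs.caller!r}")
    gt = ground_truth.keys() if isinstance(ground_truth, CallSet) else set(ground_truth)
    if not gt:
        raise ValueError("empty ground truth")
    thresholds = grid.values()
    if not thresholds:
        raise ValueError("empty threshold grid")

    results = [concordance_metrics(gt, apply_threshold(ffpe_cs, t)) for t in thresholds]
    higher_better = grid.polarity == "higher_better"

    best_i = 0
    for i in range(1, len(thresholds)):
        f1, best_f1 = results[i].f1, results[best_i].f1
        if f1 > best_f1:
            best_i = i
        elif f1 == best_f1:
            # stringency: larger t for higher_better (later grid point),
            # smaller t for lower_better (earlier grid point — keep best_i)
            if higher_better:
                best_i = i
    return ThresholdScanResult(
        caller=ffpe_cs.caller,
        thresholds=thresholds,
        results=results,
        best_threshold=thresholds[best_i],
        best_f1=results[best_i].f1,
    )


def build_ground_truth(ff_callsets: Sequence[CallSet], k: int = 2) -> KeySet:
    """The gold standard: FF-sample variants called by at least ``k``
    (default two) distinct callers."""
    if len(ff_callsets) < 2:
        raise ValueError("need at least two FF call sets to build a consensus ground truth")
    return consensus(ff_callsets, k=k).keys()
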