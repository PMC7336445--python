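"""Concordance between FF and FFPE somatic call sets.

The FF (fresh-frozen) call set is used as the gold standard: sensitivity is
the fraction of FF variants recovered in the FFPE sample, precision the
fraction of FFPE calls present in FF, and F1 their harmonic mean.  Variants
match iff they share chromosome, position, reference and alternate allele.

Also builds "at-least-k" ensemble consensus call sets across callers, and
provides the two call-level filters the analysis uses: the germline-leak
filter (keep only calls with zero VAF in the matched normal) and the
top-fraction filter (keep a caller's most significant quantile).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .callset_io import CallSet, SampleType, VariantCall, VariantKey

KeySet = set[VariantKey]


def _as_keys(x: "CallSet | Iterable[VariantKey]") -> KeySet:
    if isinstance(x, CallSet):
        return x.keys()
    return set(x)


@dataclass(frozen=True)
class ConcordanceResult:
    """FF/FFPE/overlap counts with sensitivity, precision and F1.

    All ratios are computed from the raw counts; zero denominators yield 0
    so batch reports never fail on empty call sets.
    """

    n_ff: int
    n_ffpe: int
    n_overlap: int

    def __post_init__(self) -> None:
        if self.n_overlap > min(self.n_ff, self.n_ffpe):
            raise ValueError(
                f"overlap {self.n_overlap} exceeds min(FF={self.n_ff}, FFPE={self.n_ffpe})"
            )

    @property
    def sensitivity(self) -> float:
        return self.n_overlap / self.n_ff if self.n_ff else 0.0

    @property
    def precision(self) -> float:
        return self.n_overlap / self.n_ffpe if self.n_ffpe else 0.0

    @property
    def f1(self) -> float:
        denom = self.n_ff + self.n_ffpe
        return 2 * self.n_overlap / denom if denom else 0.0

    def as_row(self) -> dict[str, float]:
        return {
            "FF": self.n_ff,
            "FFPE": self.n_ffpe,
            "Overlap": self.n_overlap,
            "Sensitivity": round(self.sensitivity, 4),
            "Precision": round(self.precision, 4),
            "F1": round(self.f1, 4),
        }


def match_keys(a: "CallSet | Iterable[VariantKey]", b: "CallSet | Iterable[VariantKey]") -> KeySet:
    """Keys present in both inputs (equality on chrom, pos, ref, alt)."""
    return _as_keys(a) & _as_keys(b)


def concordance_metrics(
    ff_keys: "CallSet | Iterable[VariantKey]",
    ffpe_keys: "CallSet | Iterable[VariantKey]",
) -> ConcordanceResult:
    """Concordance of an FFPE call set against the FF gold standard."""
    ff = _as_keys(ff_keys)
    ffpe = _as_keys(ffpe_keys)
    return ConcordanceResult(n_ff=len(ff), n_ffpe=len(ffpe), n_overlap=len(ff & ffpe))


@dataclass
class ConsensusCallSet:
    """Variants supported by at least ``k`` distinct callers on one sample.

    Per key the supporting caller set and each supporter's call payload are
    retained; a representative tumor VAF is the median of the supporting
    callers' VAFs.
    """

    k: int
    sample_type: SampleType
    support: dict[VariantKey, dict[str, VariantCall]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        bad = [k for k, s in self.support.items() if len(s) < self.k]
        if bad:
            raise ValueError(f"{len(bad)} keys have support < k={self.k}")

    def keys(self) -> KeySet:
        return set(self.support)

    def __len__(self) -> int:
        return len(self.support)

    def representative_vaf(self, key: VariantKey) -> float:
        return median(c.tumor_vaf for c in self.support[key].values())

    def representative_call(self, key: VariantKey) -> VariantCall:
        """A supporter's call carrying the median tumor VAF (context kept
        from any supporter that has one)."""
        supporters = sorted(self.support[key].values(), key=lambda c: c.tumor_vaf)
        mid = supporters[(len(supporters) - 1) // 2]
        context = next((c.context for c in supporters if c.context is not None), None)
        return VariantCall(
            key=key,
            tumor_vaf=self.representative_vaf(key),
            normal_vaf=mid.normal_vaf,
            tumor_depth=mid.tumor_depth,
            score=mid.score,
            context=context,
        )


def consensus(callsets: Sequence[CallSet], k: int) -> ConsensusCallSet:
    """Build the at-least-``k`` consensus of several callers on one sample.

    ``k=1`` is the union of the input key sets and ``k = #callers`` their
    intersection.
    """
    if not callsets:
        raise ValueError("need at least one call set")
    sample_types = {cs.sample_type for cs in callsets}
    if len(sample_types) > 1:
        raise ValueError(f"mixed sample types in consensus inputs: {sample_types}")
    if not (1 <= k <= len(callsets)):
        raise ValueError(f"k={k} out of range for {len(callsets)} call sets")
    callers = [cs.caller for cs in callsets]
    if len(set(callers)) != len(callers):
        raise ValueError(f"duplicate callers in consensus inputs: {callers}")

    support: dict[VariantKey, dict[str, VariantCall]] = {}
    for cs in callsets:
        for call in cs:
            support.setdefault(call.key, {})[cs.caller] = call
    kept = {key: sup for key, sup in support.items() if len(sup) >= k}
    return ConsensusCallSet(k=k, sample_type=callsets[0].sample_type, support=kept)


def germline_leak_filter(cs: CallSet) -> CallSet:
    """Keep only calls with zero VAF in the matched normal sample.

    Used to remove putative germline calls that leak into a caller's
    somatic output (observed for Shimmer); somatic variants should be
    absent from the normal.
    """
    return cs.replace_calls(c for c in cs if c.normal_vaf == 0.0)


def top_fraction(cs: CallSet, q: float) -> CallSet:
    """Keep a caller's ``ceil(q*n)`` most significant calls.

    Significance order follows the caller's score polarity; score ties at
    the cutoff are resolved by keeping every tied call, which makes the
    selection deterministic and input-order independent.
    """
    if not (0.0 < q <= 1.0):
        raise ValueError(f"q must be in (0, 1], got {q}")
    n = len(cs)
    if n == 0 or q == 1.0:
        return cs.replace_calls(cs.calls)
    n_keep = math.ceil(q * n)
    higher_better = cs.score_polarity == "higher_better"
    ranked = sorted(cs.calls, key=lambda c: c.score, reverse=higher_better)
    cutoff = ranked[n_keep - 1].score
    if higher_better:
        kept = [c for c in cs.calls if c.score >= cutoff]
    else:
        kept = [c for c in cs.calls if c.score <= cutoff]
    return cs.replace_calls(kept)


def pairwise_caller_overlap(callsets: Sequence[CallSet]) -> pd.DataFrame:
    """Concordance of every caller pair on the same sample.

    Returns a long-form DataFrame with one row per ordered pair; overlap
    counts are symmetric and the diagonal has F1 = 1 (for non-empty sets).
    """
    if len(callsets) < 2:
        raise ValueError("need at least two call sets")
    sample_types = {cs.sample_type for cs in callsets}
    if len(sample_types) > 1:
        raise ValueError(f"mixed sample types: {sample_types}")
    rows = []
    for a in callsets:
        for b in callsets:
            res = concordance_metrics(a.keys(), b.keys())
            rows.append({"caller_a": a.caller, "caller_b": b.caller, **res.as_row()})
    return pd.DataFrame(rows)


def concordance_table(
    named_pairs: Mapping[str, tuple["CallSet | Iterable[VariantKey]", "CallSet | Iterable[VariantKey]"]],
) -> pd.DataFrame:
    """Tabulate concordance for named (FF, FFPE) pairs, one row each."""
    rows = []
    for name, (ff, ffpe) in named_pairs.items():
        rows.append({"strategy": name, **concordance_metrics(ff, ffpe).as_row()})
    return pd.DataFrame(rows)
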