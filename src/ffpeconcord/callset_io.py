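"""Reading and writing somatic call sets and copy-number segment files.

Normalizes the output dialects of four somatic SNV callers (Strelka2,
Mutect2, VarScan2, Shimmer) into a common in-memory model: a
:class:`CallSet` of :class:`VariantCall` records keyed by
(chrom, pos, ref, alt), each carrying a uniformly recomputed tumor/normal
variant allele frequency (VAF) and the caller's significance score with an
explicit polarity.  Copy-number segments are read from GATK-style SEG files
into a :class:`SegmentSet` with a discrete amplified/deleted/neutral status.

Conventions
-----------
* Chromosome labels are normalized: no ``chr`` prefix, mitochondrion is
  ``MT``.
* VCF positions are 1-based; SEG intervals are 1-based inclusive.
* Only single-nucleotide variants are kept; indels and MNVs are skipped
  (with a logged count) and multiallelic records are decomposed into one
  call per alternate allele.
* VAF is recomputed from allele depths as alt reads / total reads, the same
  way for every caller, because the callers' own VAF definitions differ
  slightly and a uniform definition makes cross-caller comparison
  well-defined.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import pysam

logger = logging.getLogger("ffpeconcord")

BASES = ("A", "C", "G", "T")

#: Ordered known-contig set (human-style naming after normalization).
KNOWN_CONTIGS: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y", "MT")
_CONTIG_RANK = {c: i for i, c in enumerate(KNOWN_CONTIGS)}

CALLERS = ("strelka2", "mutect2", "varscan2", "shimmer")

#: Per-caller significance-score field (INFO tag) and polarity.
#: Strelka2 and Mutect2 scores grow with confidence; VarScan2's somatic
#: p-value and Shimmer's q-value shrink with confidence.
CALLER_SCORE_FIELDS: dict[str, str] = {
    "strelka2": "SomaticEVS",
    "mutect2": "TLOD",
    "varscan2": "SPV",
    "shimmer": "QVAL",
}

CALLER_POLARITY: dict[str, str] = {
    "strelka2": "higher_better",
    "mutect2": "higher_better",
    "varscan2": "lower_better",
    "shimmer": "lower_better",
}

# Pipeline-owned INFO tags used by write_callset so that exact float VAFs
# survive a write/read round trip (integer allele depths cannot encode an
# arbitrary fraction).
_TVAF_TAG = "TVAF"
_NVAF_TAG = "NVAF"
_CONTEXT_TAG = "TNC"


class SampleType(str, Enum):
    FF = "FF"
    FFPE = "FFPE"


class CnStatus(str, Enum):
    AMPLIFIED = "amplified"
    DELETED = "deleted"
    NEUTRAL = "neutral"


def normalize_chrom(label: str) -> str:
    """Normalize a chromosome label: strip ``chr``, map ``M`` to ``MT``.

    Idempotent.  Raises ``ValueError`` for labels outside the known-contig
    set after normalization.
    """
    if not label:
        raise ValueError("empty chromosome label")
    out = label[3:] if label.lower().startswith("chr") else label
    if out in ("M", "m"):
        out = "MT"
    out = out.upper() if out in ("x", "y", "mt", "Mt", "mT") else out
    if out not in _CONTIG_RANK:
        raise ValueError(f"unknown contig after normalization: {label!r} -> {out!r}")
    return out


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a somatic SNV across call sets.

    Equality on (chrom, pos, ref, alt): two call sets contain "the same"
    variant iff it sits at an identical chromosomal position with identical
    reference and alternate alleles.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.chrom not in _CONTIG_RANK:
            raise ValueError(f"unknown contig {self.chrom!r}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"ref/alt must be single bases, got {self.ref!r}>{self.alt!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) is not a variant")

    @property
    def sort_key(self) -> tuple[int, int, str, str]:
        return (_CONTIG_RANK[self.chrom], self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class VariantCall:
    """One caller's somatic SNV call with uniform VAFs and a score."""

    key: VariantKey
    tumor_vaf: float
    normal_vaf: float
    tumor_depth: int
    score: float
    context: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.tumor_vaf <= 1.0):
            raise ValueError(f"tumor_vaf out of [0,1]: {self.tumor_vaf}")
        if not (0.0 <= self.normal_vaf <= 1.0):
            raise ValueError(f"normal_vaf out of [0,1]: {self.normal_vaf}")
        if self.tumor_depth < 0:
            raise ValueError(f"tumor_depth < 0: {self.tumor_depth}")
        if self.context is not None:
            ctx = self.context
            if len(ctx) != 3 or any(b not in BASES for b in ctx):
                raise ValueError(f"context must be a 3-mer over ACGT, got {ctx!r}")
            if ctx[1] != self.key.ref:
                raise ValueError(
                    f"context middle base {ctx[1]} != ref {self.key.ref} at {self.key}"
                )


@dataclass
class CallSet:
    """One caller's somatic calls on one sample (FF or FFPE)."""

    caller: str
    sample_type: SampleType
    calls: list[VariantCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.caller not in CALLERS:
            raise ValueError(f"unknown caller {self.caller!r}; expected one of {CALLERS}")
        if not isinstance(self.sample_type, SampleType):
            self.sample_type = SampleType(self.sample_type)
        seen: set[VariantKey] = set()
        for c in self.calls:
            if c.key in seen:
                raise ValueError(f"duplicate VariantKey in CallSet: {c.key}")
            seen.add(c.key)

    @property
    def score_polarity(self) -> str:
        return CALLER_POLARITY[self.caller]

    def keys(self) -> set[VariantKey]:
        return {c.key for c in self.calls}

    def by_key(self) -> dict[VariantKey, VariantCall]:
        return {c.key: c for c in self.calls}

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self) -> Iterator[VariantCall]:
        return iter(self.calls)

    def sorted_calls(self) -> list[VariantCall]:
        return sorted(self.calls, key=lambda c: c.key.sort_key)

    def replace_calls(self, calls: Iterable[VariantCall]) -> "CallSet":
        return CallSet(caller=self.caller, sample_type=self.sample_type, calls=list(calls))


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    cn_status: CnStatus

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start > end: {self}")
        if self.chrom not in _CONTIG_RANK:
            raise ValueError(f"unknown contig {self.chrom!r}")

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class SegmentSet:
    """Copy-number segments with amplified/deleted/neutral status.

    Segments on the same chromosome must not overlap; positions not covered
    by any segment have *no* status (downstream filters treat them as
    non-neutral).
    """

    segments: list[Segment]

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[Segment]] = {}
        for s in self.segments:
            by_chrom.setdefault(s.chrom, []).append(s)
        for chrom, segs in by_chrom.items():
            segs.sort(key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start <= a.end:
                    raise ValueError(f"overlapping segments on {chrom}: {a} / {b}")
        self._index = {c: sorted(v, key=lambda s: s.start) for c, v in by_chrom.items()}

    def __len__(self) -> int:
        return len(self.segments)

    def status_at(self, chrom: str, pos: int) -> CnStatus | None:
        """CN status at a position, or None if no segment covers it."""
        import bisect

        segs = self._index.get(chrom)
        if not segs:
            return None
        i = bisect.bisect_right([s.start for s in segs], pos) - 1
        if i >= 0 and pos <= segs[i].end:
            return segs[i].cn_status
        return None


# ---------------------------------------------------------------------------
# VCF reading


def _sample_roles(
    sample_names: Sequence[str],
    tumor_sample: str | None,
    normal_sample: str | None,
) -> tuple[str, str]:
    """Resolve (tumor, normal) sample column names.

    Explicit names win; otherwise TUMOR/NORMAL-style names are matched
    case-insensitively; otherwise a two-sample VCF is assumed to be ordered
    (normal, tumor), the common convention of paired somatic callers.
    """
    names = list(sample_names)
    if tumor_sample is not None and normal_sample is not None:
        for n in (tumor_sample, normal_sample):
            if n not in names:
                raise ValueError(f"sample {n!r} not in VCF samples {names}")
        return tumor_sample, normal_sample
    lowered = {n.lower(): n for n in names}
    tum = next((lowered[k] for k in lowered if "tumor" in k or "tumour" in k), None)
    nrm = next((lowered[k] for k in lowered if "normal" in k or "blood" in k), None)
    if tum and nrm:
        return tum, nrm
    if len(names) == 2:
        return names[1], names[0]
    raise ValueError(
        f"cannot identify tumor/normal columns among samples {names}; "
        "pass tumor_sample=/normal_sample="
    )


def _allele_depths(sample: Mapping, ref: str, alt: str) -> tuple[int, int] | None:
    """(alt reads, total reads) from a VCF sample record, or None.

    Understands the ``AD`` convention (ref then alts) and the Strelka2 SNV
    tier-1 convention (``AU``/``CU``/``GU``/``TU`` per-base counts).
    """
    ad = sample.get("AD")
    if ad is not None and not all(v is None for v in ad):
        vals = [int(v) for v in ad if v is not None]
        if len(vals) >= 2:
            return vals[1], sum(vals)
    tier = {}
    for b in BASES:
        v = sample.get(f"{b}U")
        if v is None:
            return None
        tier[b] = int(v[0]) if isinstance(v, (tuple, list)) else int(v)
    total = sum(tier.values())
    return tier[alt], total


def _extract_score(record: pysam.VariantRecord, field_name: str, alt_index: int) -> float:
    info = record.info
    if field_name not in info:
        raise ValueError(
            f"record {record.chrom}:{record.pos} lacks required score field "
            f"INFO/{field_name}"
        )
    val = info[field_name]
    if isinstance(val, (tuple, list)):
        # Number=A fields (e.g. Mutect2 TLOD) carry one value per alt.
        val = val[alt_index] if alt_index < len(val) else val[0]
    return float(val)


def read_caller_vcf(
    path: str | Path,
    caller: str,
    *,
    score_field: str | None = None,
    tumor_sample: str | None = None,
    normal_sample: str | None = None,
) -> CallSet:
    """Read one caller's somatic VCF into a normalized :class:`CallSet`.

    Only SNV records are kept (after decomposing multiallelic records into
    one call per single-base alternate allele); the caller's significance
    score is pulled from its dialect's INFO field (overridable via
    ``score_field``), and tumor/normal VAFs are recomputed uniformly from
    allele depths.  Files written by :func:`write_callset` carry exact VAFs
    in pipeline-owned INFO tags, which take precedence.

    The sample type (FF/FFPE) is taken from a ``##sample_type=`` header
    line when present, else defaults to FF; callers may override by
    constructing a new CallSet.
    """
    if caller not in CALLERS:
        raise ValueError(f"unknown caller {caller!r}; expected one of {CALLERS}")
    fld = score_field or CALLER_SCORE_FIELDS[caller]
    path = str(path)
    vf = pysam.VariantFile(path)
    sample_type = SampleType.FF
    for rec in vf.header.records:
        if rec.key == "sample_type" and rec.value in ("FF", "FFPE"):
            sample_type = SampleType(rec.value)
    samples = list(vf.header.samples)
    tum = nrm = None
    if samples:
        tum, nrm = _sample_roles(samples, tumor_sample, normal_sample)

    calls: dict[VariantKey, VariantCall] = {}
    n_skipped_non_snv = 0
    n_dup = 0
    missing_normal_warned = False
    for rec in vf:
        chrom = normalize_chrom(rec.chrom)
        ref = rec.ref
        alts = rec.alts or ()
        for alt_index, alt in enumerate(alts):
            if ref is None or alt is None or len(ref) != 1 or len(alt) != 1:
                n_skipped_non_snv += 1
                continue
            if ref not in BASES or alt not in BASES:
                n_skipped_non_snv += 1
                continue
            key = VariantKey(chrom=chrom, pos=rec.pos, ref=ref, alt=alt)
            score = _extract_score(rec, fld, alt_index)

            tumor_vaf = 0.0
            tumor_depth = 0
            normal_vaf = 0.0
            if tum is not None:
                depths = _allele_depths(rec.samples[tum], ref, alt)
                if depths is not None:
                    alt_n, tot = depths
                    tumor_depth = tot
                    tumor_vaf = alt_n / tot if tot > 0 else 0.0
            if nrm is not None:
                depths = _allele_depths(rec.samples[nrm], ref, alt)
                if depths is not None:
                    alt_n, tot = depths
                    normal_vaf = alt_n / tot if tot > 0 else 0.0
                elif not missing_normal_warned:
                    logger.warning(
                        "%s: normal sample carries no allele depths; normal_vaf "
                        "recorded as 0",
                        path,
                    )
                    missing_normal_warned = True
            # Exact-VAF override tags (our own writer's dialect).
            if _TVAF_TAG in rec.info:
                v = rec.info[_TVAF_TAG]
                tumor_vaf = float(v[alt_index] if isinstance(v, tuple) else v)
            if _NVAF_TAG in rec.info:
                v = rec.info[_NVAF_TAG]
                normal_vaf = float(v[alt_index] if isinstance(v, tuple) else v)

            context = None
            if _CONTEXT_TAG in rec.info:
                raw = rec.info[_CONTEXT_TAG]
                context = str(raw[alt_index] if isinstance(raw, tuple) else raw)
                if context == ".":
                    context = None

            call = VariantCall(
                key=key,
                tumor_vaf=min(1.0, max(0.0, tumor_vaf)),
                normal_vaf=min(1.0, max(0.0, normal_vaf)),
                tumor_depth=tumor_depth,
                score=score,
                context=context,
            )
            if key in calls:
                n_dup += 1
                continue
            calls[key] = call
    vf.close()
    if n_skipped_non_snv:
        logger.info("%s: skipped %d non-SNV allele records", path, n_skipped_non_snv)
    if n_dup:
        logger.warning("%s: dropped %d duplicate-key records (first kept)", path, n_dup)
    return CallSet(caller=caller, sample_type=sample_type, calls=list(calls.values()))


# ---------------------------------------------------------------------------
# VCF writing


def _build_header(cs: CallSet) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line("##source=ffpeconcord")
    header.add_line(f"##caller={cs.caller}")
    header.add_line(f"##sample_type={cs.sample_type.value}")
    for contig in KNOWN_CONTIGS:
        header.add_line(f"##contig=<ID={contig}>")
    fld = CALLER_SCORE_FIELDS[cs.caller]
    header.add_line(
        f'##INFO=<ID={fld},Number=1,Type=Float,Description="Caller significance score">'
    )
    header.add_line(
        f'##INFO=<ID={_TVAF_TAG},Number=1,Type=Float,Description="Exact tumor VAF">'
    )
    header.add_line(
        f'##INFO=<ID={_NVAF_TAG},Number=1,Type=Float,Description="Exact normal VAF">'
    )
    header.add_line(
        f'##INFO=<ID={_CONTEXT_TAG},Number=1,Type=String,'
        'Description="Trinucleotide reference context">'
    )
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">')
    header.add_sample("NORMAL")
    header.add_sample("TUMOR")
    return header


def write_callset(cs: CallSet, path: str | Path) -> Path:
    """Write a CallSet as an uncompressed VCF; round-trips through
    :func:`read_caller_vcf` on (key, tumor_vaf, normal_vaf, score)."""
    path = Path(path)
    header = _build_header(cs)
    fld = CALLER_SCORE_FIELDS[cs.caller]
    out = pysam.VariantFile(str(path), "w", header=header)
    # Assume ~30x normal coverage purely for integer AD rendering; exact
    # values travel in the float INFO tags.
    for call in cs.sorted_calls():
        rec = out.new_record(
            contig=call.key.chrom,
            start=call.key.pos - 1,
            alleles=(call.key.ref, call.key.alt),
        )
        rec.info[fld] = round(call.score, 6)
        rec.info[_TVAF_TAG] = round(call.tumor_vaf, 6)
        rec.info[_NVAF_TAG] = round(call.normal_vaf, 6)
        if call.context is not None:
            rec.info[_CONTEXT_TAG] = call.context
        t_alt = int(round(call.tumor_vaf * call.tumor_depth))
        rec.samples["TUMOR"]["AD"] = (call.tumor_depth - t_alt, t_alt)
        rec.samples["TUMOR"]["DP"] = call.tumor_depth
        n_depth = 30
        n_alt = int(round(call.normal_vaf * n_depth))
        rec.samples["NORMAL"]["AD"] = (n_depth - n_alt, n_alt)
        rec.samples["NORMAL"]["DP"] = n_depth
        out.write(rec)
    out.close()
    return path


# ---------------------------------------------------------------------------
# SEG reading

_STATUS_ALIASES = {
    "+": CnStatus.AMPLIFIED,
    "-": CnStatus.DELETED,
    "0": CnStatus.NEUTRAL,
    "amplified": CnStatus.AMPLIFIED,
    "deleted": CnStatus.DELETED,
    "neutral": CnStatus.NEUTRAL,
    "gain": CnStatus.AMPLIFIED,
    "loss": CnStatus.DELETED,
}

_CHROM_COLS = ("chrom", "chromosome", "contig", "chr")
_START_COLS = ("start", "loc.start", "loc_start")
_END_COLS = ("end", "stop", "loc.end", "loc_end")
_STATUS_COLS = ("status", "cn_status", "call")
_RATIO_COLS = ("log2", "log2_copy_ratio", "mean_log2_copy_ratio", "seg.mean", "seg_mean")


def _find_col(columns: Sequence[str], candidates: Sequence[str]) -> str | None:
    lowered = {c.lower(): c for c in columns}
    for cand in candidates:
        if cand in lowered:
            return lowered[cand]
    return None


def read_segments(path: str | Path, *, neutral_log2_threshold: float = 0.1) -> SegmentSet:
    """Read a GATK-style SEG file (tab-delimited, ``@``-comment and header
    lines tolerated) into a :class:`SegmentSet`.

    Status comes either from an explicit status column (``+``/``-``/``0`` or
    words) or from a log2 copy-ratio column via a symmetric threshold:
    neutral iff |log2 ratio| <= ``neutral_log2_threshold``.
    """
    df = pd.read_csv(path, sep="\t", comment="@", dtype=str)
    cols = list(df.columns)
    c_chrom = _find_col(cols, _CHROM_COLS)
    c_start = _find_col(cols, _START_COLS)
    c_end = _find_col(cols, _END_COLS)
    if c_chrom is None or c_start is None or c_end is None:
        raise ValueError(f"{path}: need chrom/start/end columns, got {cols}")
    c_status = _find_col(cols, _STATUS_COLS)
    c_ratio = _find_col(cols, _RATIO_COLS)
    if c_status is None and c_ratio is None:
        raise ValueError(f"{path}: need a status or log2 copy-ratio column, got {cols}")

    segments: list[Segment] = []
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        row_d = dict(zip(cols, row))
        try:
            chrom = normalize_chrom(str(row_d[c_chrom]))
            start = int(row_d[c_start])
            end = int(row_d[c_end])
            if c_status is not None:
                raw = str(row_d[c_status]).strip().lower()
                if raw not in _STATUS_ALIASES:
                    raise ValueError(f"unknown CN status {row_d[c_status]!r}")
                status = _STATUS_ALIASES[raw]
            else:
                ratio = float(row_d[c_ratio])
                if math.isnan(ratio):
                    raise ValueError("NaN log2 ratio")
                if abs(ratio) <= neutral_log2_threshold:
                    status = CnStatus.NEUTRAL
                elif ratio > 0:
                    status = CnStatus.AMPLIFIED
                else:
                    status = CnStatus.DELETED
            segments.append(Segment(chrom=chrom, start=start, end=end, cn_status=status))
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}: unparsable SEG row at line {line_no}: {exc}") from exc
    return SegmentSet(segments=segments)


def write_segments(seg: SegmentSet, path: str | Path) -> Path:
    """Write a SegmentSet as a tab-delimited SEG file with a status column."""
    path = Path(path)
    rows = sorted(seg.segments, key=lambda s: (_CONTIG_RANK[s.chrom], s.start))
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstatus\n")
        for s in rows:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.cn_status.value}\n")
    return path
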