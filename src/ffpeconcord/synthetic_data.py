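"""Synthetic matched FF/FFPE multi-caller somatic call sets.

Generates call sets, copy-number segments, signature catalogues and a truth
table with the statistical structure the concordance analysis assumes, so
every pipeline stage is testable without access-restricted patient data.

What is emulated
----------------
* A clonal variant cluster at VAF ~0.25 in the fresh-frozen (FF) sample
  whose VAF shrinks multiplicatively in the FFPE sample (default factor
  0.47, putting the FFPE clonal median near 0.11), a subclonal cluster at
  VAF ~0.05, and germline variants leaking in near VAF 0.5 with positive
  VAF in the matched normal.
* Four caller error models (Strelka2, Mutect2, VarScan2, Shimmer style):
  detection probability logistic in the true VAF, caller-specific false
  positives at low VAF, a significance score that grows monotonically with
  the observed VAF plus noise (on the p/q scale for the lower-is-better
  callers), and — for the Shimmer model — germline variants leaking into
  the somatic output.
* FFPE-specific C>T-heavy artefact variants, absent from the FF sample,
  with trinucleotide contexts drawn from an artefact signature.
* Copy-number segmentations: long neutral FF segments, and an FFPE
  segmentation additionally broken by short spurious non-neutral fragments.

Variant positions are uniform over two synthetic 10 Mb contigs — small
enough for fast tests, large enough that independent false positives
essentially never collide between callers.  Everything is driven by one
integer seed; identical configuration and seed give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .callset_io import (
    CALLER_POLARITY,
    CALLERS,
    CallSet,
    CnStatus,
    Segment,
    SegmentSet,
    SampleType,
    VariantCall,
    VariantKey,
    write_callset,
    write_segments,
)
from .mutational_profiles import (
    MUTATION_TYPES,
    SignatureMatrix,
    cosine_similarity,
    write_signature_matrix,
)

#: Synthetic genome: two autosome-style contigs of 10 Mb each.
CONTIGS: dict[str, int] = {"1": 10_000_000, "2": 10_000_000}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Indices of the 16 C>T classes within the 96-type layout.
CT_TYPE_INDICES = tuple(i for i, t in enumerate(MUTATION_TYPES) if "[C>T]" in t)


@dataclass
class CallerModel:
    """Call-set-level error model for one emulated caller.

    ``sens_midpoint``/``sens_slope`` parameterize the logistic detection
    probability in the true VAF; ``fp_count`` false positives are injected
    per sample (inflated in FFPE); the score is ``offset + scale * vaf``
    plus Gaussian noise, exponentiated to a p/q-value for lower-is-better
    callers.  ``germline_leak_rate`` is the probability that a germline
    variant appears in the somatic output; ``artefact_affinity`` thins
    which FFPE artefacts a caller is even exposed to, making artefacts
    mostly caller-private.
    """

    sens_midpoint: float
    sens_slope: float
    fp_count: int
    score_offset: float
    score_scale: float
    score_noise_sd: float
    germline_leak_rate: float = 0.0
    artefact_affinity: float = 0.5

    def detection_prob(self, vaf: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.sens_slope * (vaf - self.sens_midpoint)))


def _default_caller_models() -> dict[str, CallerModel]:
    # Score scales put FF clonal-cluster scores near the observed per-caller
    # averages (EVS ~17, TLOD ~50, somatic p ~2e-3, q ~1e-2).
    return {
        "strelka2": CallerModel(
            sens_midpoint=0.03, sens_slope=35.0, fp_count=1000,
            score_offset=5.0, score_scale=50.0, score_noise_sd=1.5,
        ),
        "mutect2": CallerModel(
            sens_midpoint=0.035, sens_slope=30.0, fp_count=1700,
            score_offset=0.0, score_scale=200.0, score_noise_sd=8.0,
        ),
        "varscan2": CallerModel(
            sens_midpoint=0.12, sens_slope=25.0, fp_count=600,
            score_offset=1.6, score_scale=4.0, score_noise_sd=0.4,
        ),
        "shimmer": CallerModel(
            sens_midpoint=0.06, sens_slope=25.0, fp_count=900,
            score_offset=1.3, score_scale=3.0, score_noise_sd=0.4,
            germline_leak_rate=0.9,
        ),
    }


@dataclass
class ArtefactModel:
    """FFPE-only artefact variants with C>T-dominated contexts."""

    n_artefacts: int = 500
    vaf_mean: float = 0.08
    vaf_sd: float = 0.02
    artefact_signature: np.ndarray | None = None  # 96-vector; default built later


@dataclass
class SegmentModel:
    """Copy-number segmentation: neutral FF, fragmented FFPE."""

    n_ffpe_only_fragments: int = 5
    fragment_length: int = 50_000


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic matched FF/FFPE experiment."""

    seed: int = 0
    n_clonal: int = 3000
    n_subclonal: int = 800
    n_germline_leak: int = 300
    clonal_vaf_ff: float = 0.25
    subclonal_vaf: float = 0.05
    ffpe_vaf_shrink: float = 0.47
    vaf_sd: float = 0.04
    subclonal_vaf_sd: float = 0.015
    ffpe_vaf_noise_sd: float = 0.01
    coverage_mean: float = 100.0
    ffpe_coverage_dispersion: float = 1.5
    ffpe_fp_factor: float = 1.5
    caller_models: dict[str, CallerModel] = field(default_factory=_default_caller_models)
    ffpe_artefact: ArtefactModel = field(default_factory=ArtefactModel)
    segment_model: SegmentModel = field(default_factory=SegmentModel)
    n_signatures: int = 4
    n_artefact_signatures: int = 1

    def __post_init__(self) -> None:
        for name in ("n_clonal", "n_subclonal", "n_germline_leak"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 < self.ffpe_vaf_shrink <= 1.0):
            raise ValueError(f"ffpe_vaf_shrink must be in (0, 1], got {self.ffpe_vaf_shrink}")
        for name in ("clonal_vaf_ff", "subclonal_vaf"):
            if not (0.0 < getattr(self, name) < 1.0):
                raise ValueError(f"{name} must be in (0, 1)")
        unknown = set(self.caller_models) - set(CALLERS)
        if unknown:
            raise ValueError(f"unknown callers in caller_models: {sorted(unknown)}")


@dataclass
class TruthTable:
    """Ground-truth variants: origin, true VAFs, 96-class and context.

    Origins: ``clonal``, ``subclonal``, ``germline`` (present in both
    samples, positive normal VAF), ``ffpe_artefact`` (FFPE only).
    Per-caller false positives are private to each emulated call set and
    appear in the bundle-level truth TSV with origin ``caller_fp``.
    """

    df: pd.DataFrame

    COLUMNS = (
        "chrom", "pos", "ref", "alt", "origin",
        "vaf_ff", "vaf_ffpe", "normal_vaf", "mutation_type", "context",
    )

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"truth table lacks columns {sorted(missing)}")
        dup = self.df.duplicated(subset=["chrom", "pos", "ref", "alt"]).sum()
        if dup:
            raise ValueError(f"{dup} duplicate variant keys in truth table")

    def __len__(self) -> int:
        return len(self.df)

    def keys(self, origin: str | None = None) -> set[VariantKey]:
        df = self.df if origin is None else self.df[self.df["origin"] == origin]
        return {
            VariantKey(chrom=r.chrom, pos=int(r.pos), ref=r.ref, alt=r.alt)
            for r in df.itertuples(index=False)
        }

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        out = self.df.copy()
        for col in ("vaf_ff", "vaf_ffpe", "normal_vaf"):
            out[col] = out[col].map(lambda v: f"{v:.6f}")
        out.to_csv(path, sep="\t", index=False)
        return path


def _draw_positions(rng: np.random.Generator, n: int, taken: set[tuple[str, int]]) -> list[tuple[str, int]]:
    """Uniform unique positions over the synthetic contigs (no collisions)."""
    contig_names = list(CONTIGS)
    sizes = np.array([CONTIGS[c] for c in contig_names], dtype=float)
    total = sizes.sum()
    if n > total - len(taken):
        raise ValueError(f"contig space too small for {n} additional variants")
    out: list[tuple[str, int]] = []
    while len(out) < n:
        k = n - len(out)
        chroms = rng.choice(len(contig_names), size=k, p=sizes / total)
        positions = rng.integers(1, sizes[chroms].astype(int) + 1)
        for ci, pos in zip(chroms, positions):
            loc = (contig_names[ci], int(pos))
            if loc not in taken:
                taken.add(loc)
                out.append(loc)
    return out


def _type_to_variant(rng: np.random.Generator, type_idx: int) -> tuple[str, str, str]:
    """(ref, alt, context) realizing a 96-class, on a random strand."""
    label = MUTATION_TYPES[type_idx]  # e.g. "A[C>T]G"
    five, ref, alt, three = label[0], label[2], label[4], label[6]
    context = five + ref + three
    if rng.random() < 0.5:  # present on the purine strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        context = "".join(_COMPLEMENT[b] for b in reversed(context))
    return ref, alt, context


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, size: int,
               lo: float = 0.005, hi: float = 0.995) -> np.ndarray:
    return np.clip(rng.normal(mean, sd, size=size), lo, hi)


def make_signature_matrix(
    K: int,
    artefact_count: int,
    seed: int,
    max_retries: int = 50,
) -> SignatureMatrix:
    """Random column-stochastic 96 x K catalogue with separated columns.

    Artefact columns put ~80% of their mass on the 16 C>T classes (the FFPE
    deamination fingerprint); all pairwise cosines are kept below 0.9 so
    NNLS decompositions are well-conditioned.
    """
    if K < 2:
        raise ValueError("need K >= 2 signatures")
    if not (0 <= artefact_count < K):
        raise ValueError("need 0 <= artefact_count < K")
    rng = np.random.default_rng(seed)
    ct = np.array(CT_TYPE_INDICES)
    for _ in range(max_retries):
        cols = []
        for j in range(K):
            if j < artefact_count:
                col = np.zeros(96)
                col[ct] = rng.dirichlet(np.full(len(ct), 0.6)) * 0.8
                rest = np.setdiff1d(np.arange(96), ct)
                col[rest] = rng.dirichlet(np.full(len(rest), 0.3)) * 0.2
            else:
                col = rng.dirichlet(np.full(96, 0.3))
            cols.append(col)
        M = np.column_stack(cols)
        M /= M.sum(axis=0, keepdims=True)
        ok = all(
            cosine_similarity(M[:, i], M[:, j]) < 0.9
            for i in range(K)
            for j in range(i + 1, K)
        )
        if ok:
            ids = [f"SBS_ART{j + 1}" if j < artefact_count else f"SBS_SYN{j + 1}"
                   for j in range(K)]
            return SignatureMatrix(
                matrix=M, ids=ids, artefact_ids=set(ids[:artefact_count])
            )
    raise RuntimeError(f"could not build {K} signatures with pairwise cosine < 0.9")


def simulate_truth(
    cfg: SimulationConfig,
    signatures: SignatureMatrix | None = None,
) -> TruthTable:
    """Draw the ground-truth variant catalogue for one synthetic tumor.

    Clonal FF VAFs are Normal(clonal_vaf_ff, vaf_sd) truncated to (0, 1);
    FFPE VAFs are the FF VAFs scaled by ``ffpe_vaf_shrink`` plus noise.
    Subclonal variants behave analogously at ``subclonal_vaf``.  Germline
    leak variants sit near VAF 0.5 in both tumor samples and carry positive
    normal VAF.  FFPE artefacts exist only in the FFPE sample, at low VAF,
    with 96-classes drawn from the artefact signature; all other variants
    draw their class from a uniform mixture of the non-artefact signatures.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    if signatures is None:
        signatures = make_signature_matrix(
            cfg.n_signatures, cfg.n_artefact_signatures, seed=cfg.seed
        )
    mask = signatures.artefact_mask()
    if cfg.ffpe_artefact.artefact_signature is not None:
        artefact_sig = np.asarray(cfg.ffpe_artefact.artefact_signature, dtype=float)
    elif mask.any():
        artefact_sig = signatures.matrix[:, mask].mean(axis=1)
    else:
        artefact_sig = np.zeros(96)
        artefact_sig[list(CT_TYPE_INDICES)] = 1.0 / len(CT_TYPE_INDICES)
    background_sig = signatures.matrix[:, ~mask].mean(axis=1)
    artefact_sig = artefact_sig / artefact_sig.sum()
    background_sig = background_sig / background_sig.sum()

    n_art = cfg.ffpe_artefact.n_artefacts
    sections = (
        ("clonal", cfg.n_clonal, background_sig),
        ("subclonal", cfg.n_subclonal, background_sig),
        ("germline", cfg.n_germline_leak, background_sig),
        ("ffpe_artefact", n_art, artefact_sig),
    )
    taken: set[tuple[str, int]] = set()
    rows: list[dict] = []
    for origin, n, sig in sections:
        if n == 0:
            continue
        locs = _draw_positions(rng, n, taken)
        types = rng.choice(96, size=n, p=sig)
        if origin == "clonal":
            vaf_ff = _truncnorm(rng, cfg.clonal_vaf_ff, cfg.vaf_sd, n)
            vaf_ffpe = np.clip(
                vaf_ff * cfg.ffpe_vaf_shrink + rng.normal(0, cfg.ffpe_vaf_noise_sd, n),
                0.005, 0.995,
            )
            normal_vaf = np.zeros(n)
        elif origin == "subclonal":
            vaf_ff = _truncnorm(rng, cfg.subclonal_vaf, cfg.subclonal_vaf_sd, n)
            vaf_ffpe = np.clip(
                vaf_ff * cfg.ffpe_vaf_shrink + rng.normal(0, cfg.ffpe_vaf_noise_sd, n),
                0.005, 0.995,
            )
            normal_vaf = np.zeros(n)
        elif origin == "germline":
            vaf_ff = _truncnorm(rng, 0.5, 0.05, n)
            vaf_ffpe = _truncnorm(rng, 0.5, 0.05, n)
            normal_vaf = _truncnorm(rng, 0.5, 0.05, n, lo=0.05)
        else:  # ffpe_artefact
            vaf_ff = np.zeros(n)
            vaf_ffpe = _truncnorm(
                rng, cfg.ffpe_artefact.vaf_mean, cfg.ffpe_artefact.vaf_sd, n, lo=0.02
            )
            normal_vaf = np.zeros(n)
        for i, (chrom, pos) in enumerate(locs):
            ref, alt, context = _type_to_variant(rng, int(types[i]))
            rows.append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "origin": origin,
                    "vaf_ff": float(vaf_ff[i]),
                    "vaf_ffpe": float(vaf_ffpe[i]),
                    "normal_vaf": float(normal_vaf[i]),
                    "mutation_type": MUTATION_TYPES[int(types[i])],
                    "context": context,
                }
            )
    df = pd.DataFrame(rows, columns=list(TruthTable.COLUMNS))
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return TruthTable(df=df)


def _observe_vaf(
    rng: np.random.Generator,
    true_vaf: float,
    coverage_mean: float,
    dispersion: float,
) -> tuple[float, int]:
    """Sequencing-level observation: depth ~ (over)dispersed Poisson,
    alt reads ~ Binomial(depth, true VAF); at least one supporting read."""
    lam = coverage_mean
    if dispersion > 1.0:
        lam = rng.gamma(shape=coverage_mean / (dispersion - 1.0),
                        scale=(dispersion - 1.0))
    depth = max(int(rng.poisson(lam)), 10)
    alt = int(rng.binomial(depth, true_vaf))
    alt = max(alt, 1)
    return alt / depth, depth


def _score_from_vaf(
    rng: np.random.Generator, model: CallerModel, caller: str, obs_vaf: float
) -> float:
    raw = model.score_offset + model.score_scale * obs_vaf + rng.normal(0, model.score_noise_sd)
    if CALLER_POLARITY[caller] == "higher_better":
        return max(raw, 0.0)
    return float(np.clip(10.0 ** (-raw), 1e-12, 0.05))


def emulate_caller(
    truth: TruthTable,
    caller: str,
    model: CallerModel,
    sample_type: SampleType,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[CallSet, pd.DataFrame]:
    """One caller's somatic output on one sample.

    Returns the call set plus a frame of the caller's private false
    positives (origin ``caller_fp``).  Detection of a true variant is an
    independent Bernoulli draw with logistic-in-VAF probability; germline
    variants are only emitted at the model's leak rate; FFPE artefacts are
    further thinned by the caller's artefact affinity.
    """
    is_ffpe = sample_type == SampleType.FFPE
    vaf_col = "vaf_ffpe" if is_ffpe else "vaf_ff"
    dispersion = cfg.ffpe_coverage_dispersion if is_ffpe else 1.0
    calls: list[VariantCall] = []
    for row in truth.df.itertuples(index=False):
        true_vaf = getattr(row, vaf_col)
        if true_vaf <= 0:
            continue
        if row.origin == "germline":
            p = model.germline_leak_rate
        else:
            p = float(model.detection_prob(np.array([true_vaf]))[0])
            if row.origin == "ffpe_artefact":
                p *= model.artefact_affinity
        if rng.random() >= p:
            continue
        obs_vaf, depth = _observe_vaf(rng, true_vaf, cfg.coverage_mean, dispersion)
        calls.append(
            VariantCall(
                key=VariantKey(chrom=row.chrom, pos=int(row.pos), ref=row.ref, alt=row.alt),
                tumor_vaf=obs_vaf,
                normal_vaf=float(row.normal_vaf),
                tumor_depth=depth,
                score=_score_from_vaf(rng, model, caller, obs_vaf),
                context=row.context,
            )
        )

    # caller-private false positives at low VAF
    n_fp = int(round(model.fp_count * (cfg.ffpe_fp_factor if is_ffpe else 1.0)))
    taken = {(r.chrom, int(r.pos)) for r in truth.df.itertuples(index=False)}
    taken |= {(c.key.chrom, c.key.pos) for c in calls}
    fp_locs = _draw_positions(rng, n_fp, taken)
    fp_types = rng.choice(96, size=n_fp)
    fp_rows = []
    for (chrom, pos), t in zip(fp_locs, fp_types):
        ref, alt, context = _type_to_variant(rng, int(t))
        true_vaf = float(np.clip(rng.exponential(0.03) + 0.01, 0.01, 0.3))
        obs_vaf, depth = _observe_vaf(rng, true_vaf, cfg.coverage_mean, dispersion)
        calls.append(
            VariantCall(
                key=VariantKey(chrom=chrom, pos=pos, ref=ref, alt=alt),
                tumor_vaf=obs_vaf,
                normal_vaf=0.0,
                tumor_depth=depth,
                score=_score_from_vaf(rng, model, caller, obs_vaf),
                context=context,
            )
        )
        fp_rows.append(
            {
                "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                "origin": "caller_fp",
                "vaf_ff": 0.0 if is_ffpe else true_vaf,
                "vaf_ffpe": true_vaf if is_ffpe else 0.0,
                "normal_vaf": 0.0,
                "mutation_type": MUTATION_TYPES[int(t)],
                "context": context,
                "caller": caller,
                "sample_type": sample_type.value,
            }
        )
    cs = CallSet(caller=caller, sample_type=sample_type, calls=calls)
    return cs, pd.DataFrame(fp_rows)


def emulate_segments(
    cfg: SimulationConfig,
    sample_type: SampleType,
    rng: np.random.Generator,
) -> SegmentSet:
    """Copy-number segmentation for one sample.

    FF: one long neutral segment per contig.  FFPE: the same neutral
    backbone interrupted by short spurious amplified/deleted fragments
    (``n_ffpe_only_fragments`` of them), mimicking fragmentation artefacts.
    """
    segments: list[Segment] = []
    if sample_type == SampleType.FF or cfg.segment_model.n_ffpe_only_fragments == 0:
        for chrom, size in CONTIGS.items():
            segments.append(Segment(chrom=chrom, start=1, end=size, cn_status=CnStatus.NEUTRAL))
        return SegmentSet(segments=segments)

    n_frag = cfg.segment_model.n_ffpe_only_fragments
    frag_len = cfg.segment_model.fragment_length
    contig_names = list(CONTIGS)
    frags: dict[str, list[tuple[int, int, CnStatus]]] = {c: [] for c in contig_names}
    attempts = 0
    placed = 0
    while placed < n_frag and attempts < 1000:
        attempts += 1
        chrom = contig_names[int(rng.integers(len(contig_names)))]
        size = CONTIGS[chrom]
        start = int(rng.integers(1, size - frag_len))
        end = start + frag_len - 1
        if any(s <= end and start <= e for s, e, _ in frags[chrom]):
            continue
        status = CnStatus.AMPLIFIED if rng.random() < 0.7 else CnStatus.DELETED
        frags[chrom].append((start, end, status))
        placed += 1
    if placed < n_frag:
        raise RuntimeError("could not place FFPE CN fragments without overlap")

    for chrom, size in CONTIGS.items():
        cursor = 1
        for start, end, status in sorted(frags[chrom]):
            if cursor < start:
                segments.append(
                    Segment(chrom=chrom, start=cursor, end=start - 1, cn_status=CnStatus.NEUTRAL)
                )
            segments.append(Segment(chrom=chrom, start=start, end=end, cn_status=status))
            cursor = end + 1
        if cursor <= size:
            segments.append(Segment(chrom=chrom, start=cursor, end=size, cn_status=CnStatus.NEUTRAL))
    return SegmentSet(segments=segments)


@dataclass
class SyntheticBundle:
    """Everything one synthetic study produces, in memory."""

    config: SimulationConfig
    truth: TruthTable
    callsets: dict[tuple[str, str], CallSet]  # (sample_type, caller) -> CallSet
    seg_ff: SegmentSet
    seg_ffpe: SegmentSet
    signatures: SignatureMatrix
    fp_table: pd.DataFrame

    def callsets_for(self, sample_type: "SampleType | str") -> list[CallSet]:
        st = SampleType(sample_type).value
        return [self.callsets[(st, c)] for c in CALLERS if (st, c) in self.callsets]

    def full_truth_df(self) -> pd.DataFrame:
        """Truth rows plus per-caller false positives (origin caller_fp)."""
        base = self.truth.df.copy()
        base["caller"] = ""
        base["sample_type"] = ""
        if len(self.fp_table):
            return pd.concat([base, self.fp_table], ignore_index=True)
        return base


def simulate_bundle(cfg: SimulationConfig) -> SyntheticBundle:
    """Run the whole generator: signatures, truth, call sets, segments."""
    signatures = make_signature_matrix(
        cfg.n_signatures, cfg.n_artefact_signatures, seed=cfg.seed
    )
    truth = simulate_truth(cfg, signatures=signatures)
    callsets: dict[tuple[str, str], CallSet] = {}
    fp_frames = []
    for si, sample_type in enumerate((SampleType.FF, SampleType.FFPE)):
        for ci, caller in enumerate(CALLERS):
            if caller not in cfg.caller_models:
                continue
            rng = np.random.default_rng([cfg.seed, 100 + si, ci])
            cs, fp = emulate_caller(
                truth, caller, cfg.caller_models[caller], sample_type, cfg, rng
            )
            callsets[(sample_type.value, caller)] = cs
            fp_frames.append(fp)
    seg_ff = emulate_segments(cfg, SampleType.FF, np.random.default_rng([cfg.seed, 200]))
    seg_ffpe = emulate_segments(cfg, SampleType.FFPE, np.random.default_rng([cfg.seed, 201]))
    fp_table = pd.concat([f for f in fp_frames if len(f)], ignore_index=True) \
        if fp_frames else pd.DataFrame()
    return SyntheticBundle(
        config=cfg,
        truth=truth,
        callsets=callsets,
        seg_ff=seg_ff,
        seg_ffpe=seg_ffpe,
        signatures=signatures,
        fp_table=fp_table,
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle to disk: per-caller VCFs, SEG files, signature TSV
    and truth TSV.  Deterministic: same config and seed, same bytes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for (sample_type, caller), cs in sorted(bundle.callsets.items()):
        p = outdir / f"{sample_type.lower()}_{caller}.vcf"
        write_callset(cs, p)
        paths[f"vcf_{sample_type.lower()}_{caller}"] = p
    paths["seg_ff"] = write_segments(bundle.seg_ff, outdir / "ff.seg")
    paths["seg_ffpe"] = write_segments(bundle.seg_ffpe, outdir / "ffpe.seg")
    paths["signatures"] = write_signature_matrix(bundle.signatures, outdir / "signatures.tsv")
    truth_path = outdir / "truth.tsv"
    full = bundle.full_truth_df().copy()
    for col in ("vaf_ff", "vaf_ffpe", "normal_vaf"):
        full[col] = full[col].map(lambda v: f"{v:.6f}")
    full.to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    return paths
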