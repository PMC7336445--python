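"""96-type trinucleotide mutational profiles and signature decomposition.

A sample's mutational profile counts its somatic SNVs over the 96 single
base substitution (SBS) classes: the six pyrimidine-reference substitutions
(C>A, C>G, C>T, T>A, T>C, T>G) crossed with the 5' and 3' flanking bases.
Variants with a purine reference (A or G) are reverse-complemented onto the
pyrimidine strand before classification, so a variant and its reverse
complement map to the same class.

Profiles are compared by cosine similarity and decomposed into a fixed
catalogue of signature profiles (COSMIC SBS layout) by non-negative least
squares (NNLS); the exposure mass landing on signatures flagged as
sequencing artefacts quantifies how artefact-ridden a call set is.  Fits
whose reconstruction has cosine similarity below 0.9 with the original
profile are flagged unreliable.

The 96-class ordering is the conventional COSMIC lexicographic layout:
substitution (C>A, C>G, C>T, T>A, T>C, T>G), then 5' base (A, C, G, T),
then 3' base (A, C, G, T); labels look like ``A[C>A]T``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .callset_io import BASES, VariantCall, VariantKey

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Fixed ordering of the 96 SBS classes.
MUTATION_TYPES: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)
_TYPE_INDEX = {t: i for i, t in enumerate(MUTATION_TYPES)}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def classify_mutation(key: VariantKey, context: str) -> str:
    """Map an SNV plus its trinucleotide context to one of the 96 classes.

    ``context`` is the reference 3-mer centered on the variant; its middle
    base must equal the reference allele.  Purine-reference variants are
    reverse-complemented first.
    """
    if len(context) != 3 or any(b not in BASES for b in context):
        raise ValueError(f"context must be a 3-mer over ACGT, got {context!r}")
    if context[1] != key.ref:
        raise ValueError(f"context middle base {context[1]} != ref {key.ref}")
    ref, alt, ctx = key.ref, key.alt, context
    if ref in ("A", "G"):
        ref, alt, ctx = _COMPLEMENT[ref], _COMPLEMENT[alt], _revcomp(ctx)
    return f"{ctx[0]}[{ref}>{alt}]{ctx[2]}"


@dataclass
class MutationalProfile:
    """Counts over the 96 SBS trinucleotide classes, in fixed order."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError(f"profile must have 96 entries, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("profile counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def normalized(self) -> np.ndarray:
        """Counts as frequencies summing to 1 (zeros if the profile is empty)."""
        t = self.total
        return self.counts / t if t > 0 else self.counts.copy()

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(MUTATION_TYPES), name="count")


def build_profile(
    calls: Iterable[VariantCall],
    reference: "object | None" = None,
) -> MutationalProfile:
    """Count calls into the 96 classes using each call's context.

    Calls lacking a stored context get one from ``reference`` (any mapping
    of contig name to sequence supporting slicing, e.g. a pyfaidx.Fasta);
    with neither, a hard error is raised.
    """
    counts = np.zeros(96)
    for call in calls:
        ctx = call.context
        if ctx is None:
            if reference is None:
                raise ValueError(
                    f"call {call.key} has no trinucleotide context and no reference "
                    "FASTA was provided"
                )
            ctx = lookup_context(reference, call.key)
        counts[_TYPE_INDEX[classify_mutation(call.key, ctx)]] += 1
    return MutationalProfile(counts=counts)


def lookup_context(reference, key: VariantKey) -> str:
    """Fetch the reference 3-mer centered on a 1-based variant position."""
    seq = str(reference[key.chrom][key.pos - 2 : key.pos + 1]).upper()
    if len(seq) != 3:
        raise ValueError(f"cannot extract 3-mer context at {key.chrom}:{key.pos}")
    if seq[1] != key.ref:
        raise ValueError(
            f"reference base {seq[1]} at {key.chrom}:{key.pos} != variant ref {key.ref}"
        )
    return seq


def cosine_similarity(p: "MutationalProfile | np.ndarray", q: "MutationalProfile | np.ndarray") -> float:
    """Cosine of two 96-vectors; both must be non-zero."""
    a = p.counts if isinstance(p, MutationalProfile) else np.asarray(p, dtype=float)
    b = q.counts if isinstance(q, MutationalProfile) else np.asarray(q, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero profile")
    return float(np.dot(a, b) / (na * nb))


@dataclass
class SignatureMatrix:
    """A 96 x K catalogue of column-stochastic signature profiles.

    ``artefact_ids`` flags the columns that represent sequencing artefacts
    rather than biological mutational processes.
    """

    matrix: np.ndarray
    ids: list[str]
    artefact_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 96:
            raise ValueError(f"signature matrix must be 96 x K, got {self.matrix.shape}")
        if self.matrix.shape[1] != len(self.ids):
            raise ValueError("number of ids must match number of columns")
        if np.any(self.matrix < 0):
            raise ValueError("signature entries must be non-negative")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError(f"signature columns must sum to 1 (got sums {sums})")
        unknown = set(self.artefact_ids) - set(self.ids)
        if unknown:
            raise ValueError(f"artefact ids not in catalogue: {sorted(unknown)}")
        self.artefact_ids = set(self.artefact_ids)

    @property
    def n_signatures(self) -> int:
        return self.matrix.shape[1]

    def artefact_mask(self) -> np.ndarray:
        return np.array([sid in self.artefact_ids for sid in self.ids])


def read_signature_matrix(
    path: str | Path,
    artefact_ids: Iterable[str] = (),
) -> SignatureMatrix:
    """Read a tab-delimited signature catalogue (COSMIC v3 file layout).

    First column: 96 type labels like ``A[C>A]A``; remaining columns: one
    signature each.  Rows may appear in any order; they are realigned to
    the canonical class ordering.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(MUTATION_TYPES) - set(df.index)
    if missing:
        raise ValueError(f"{path}: signature file lacks {len(missing)} mutation types")
    df = df.loc[list(MUTATION_TYPES)]
    return SignatureMatrix(
        matrix=df.to_numpy(dtype=float),
        ids=[str(c) for c in df.columns],
        artefact_ids=set(artefact_ids),
    )


def write_signature_matrix(S: SignatureMatrix, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(S.matrix, index=list(MUTATION_TYPES), columns=S.ids)
    df.index.name = "Type"
    df.to_csv(path, sep="\t", float_format="%.8f")
    return path


#: Reconstruction-quality gate below which artefact estimates are flagged.
RELIABLE_COSINE = 0.9


@dataclass
class SignatureFit:
    """NNLS decomposition of one profile into a signature catalogue."""

    exposures: np.ndarray
    reconstruction: np.ndarray
    recon_cosine: float
    artefact_fraction: float
    reliable: bool
    ids: list[str]

    def exposure_series(self) -> pd.Series:
        return pd.Series(self.exposures, index=self.ids, name="exposure")


def fit_signatures(p: MutationalProfile, S: SignatureMatrix) -> SignatureFit:
    """Decompose a profile into non-negative signature exposures.

    Solves ``min ||p - S e||_2 s.t. e >= 0`` on the count scale; exposures
    are therefore in mutation-count units.  The artefact fraction is the
    share of total exposure mass on artefact-flagged signatures.
    """
    if p.total <= 0:
        raise ValueError("cannot fit signatures to an empty profile")
    exposures, _ = nnls(S.matrix, p.counts)
    reconstruction = S.matrix @ exposures
    recon_cos = cosine_similarity(reconstruction, p.counts) if reconstruction.any() else 0.0
    total = exposures.sum()
    mask = S.artefact_mask()
    artefact_fraction = float(exposures[mask].sum() / total) if total > 0 else 0.0
    return SignatureFit(
        exposures=exposures,
        reconstruction=reconstruction,
        recon_cosine=recon_cos,
        artefact_fraction=artefact_fraction,
        reliable=recon_cos >= RELIABLE_COSINE,
        ids=list(S.ids),
    )


def artefact_fraction_report(
    fits: Mapping[str, SignatureFit],
) -> pd.DataFrame:
    """Tabulate artefact fractions per sample/strategy.

    Entries whose reconstruction cosine is below the reliability gate are
    flagged so readers know the estimate may be untrustworthy.
    """
    rows = []
    for name, fit in fits.items():
        rows.append(
            {
                "name": name,
                "artefact_fraction": round(fit.artefact_fraction, 4),
                "recon_cosine": round(fit.recon_cosine, 4),
                "reliable": fit.reliable,
            }
        )
    return pd.DataFrame(rows)
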