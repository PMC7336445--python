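"""Shared fixtures: hand-built call sets, VCF text helpers, small synthetic bundles."""

from __future__ import annotations

import textwrap
from pathlib import Path

import pytest

from ffpeconcord import (
    CallSet,
    SampleType,
    SimulationConfig,
    VariantCall,
    VariantKey,
    simulate_bundle,
)
from ffpeconcord.synthetic_data import ArtefactModel, SegmentModel


def make_key(pos: int, chrom: str = "1", ref: str = "C", alt: str = "T") -> VariantKey:
    return VariantKey(chrom=chrom, pos=pos, ref=ref, alt=alt)


def make_call(
    pos: int,
    chrom: str = "1",
    ref: str = "C",
    alt: str = "T",
    tumor_vaf: float = 0.25,
    normal_vaf: float = 0.0,
    tumor_depth: int = 100,
    score: float = 10.0,
    context: str | None = None,
) -> VariantCall:
    return VariantCall(
        key=make_key(pos, chrom, ref, alt),
        tumor_vaf=tumor_vaf,
        normal_vaf=normal_vaf,
        tumor_depth=tumor_depth,
        score=score,
        context=context,
    )


def make_callset(
    calls,
    caller: str = "strelka2",
    sample_type: SampleType = SampleType.FF,
) -> CallSet:
    return CallSet(caller=caller, sample_type=sample_type, calls=list(calls))


def write_vcf_text(path: Path, body: str, info_lines: str = "", samples: str = "") -> Path:
    """Render a minimal VCF 4.2 file for reader tests."""
    format_cols = ""
    if samples:
        format_cols = "\tFORMAT\t" + samples.replace(",", "\t")
    header = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=1>\n##contig=<ID=2>\n##contig=<ID=7>\n"
        + info_lines
        + '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n'
        + '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n'
        + f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO{format_cols}\n"
    )
    path.write_text(header + textwrap.dedent(body))
    return path


#: Small but structurally complete study: every origin class populated,
#: four emulated callers, fragmented FFPE segments.
SMALL_CONFIG = dict(
    n_clonal=400,
    n_subclonal=120,
    n_germline_leak=60,
    ffpe_artefact=ArtefactModel(n_artefacts=80),
    segment_model=SegmentModel(n_ffpe_only_fragments=3),
)


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    kwargs = dict(SMALL_CONFIG)
    kwargs.update(overrides)
    cfg = SimulationConfig(seed=seed, **kwargs)
    # scale caller false positives down with the variant count
    for model in cfg.caller_models.values():
        model.fp_count = max(20, model.fp_count // 8)
    return cfg


@pytest.fixture(scope="session")
def small_bundle():
    """One deterministic small synthetic study, shared across tests."""
    return simulate_bundle(small_config(seed=11))


@pytest.fixture(scope="session")
def default_bundle():
    """One study at the default (paper-scale) generator settings."""
    return simulate_bundle(SimulationConfig(seed=5))
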