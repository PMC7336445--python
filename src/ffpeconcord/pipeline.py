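"""Full-analysis orchestration: from per-caller VCFs to a report bundle.

Runs, in order: per-caller FF-vs-FFPE concordance, pairwise caller overlap,
FF ground-truth construction (at-least-two consensus), per-caller
significance-threshold scans, at-least-k ensemble strategies, mutational
profiles with cosine similarity and artefact-signature fractions, and the
diploid-filtered clonal/subclonal concordance.  Each stage writes one TSV;
a JSON manifest records the configuration snapshot, input digests, package
version and output paths so every reported number is traceable.

Ratios in the TSVs are printed at 4 decimal places for table-to-table
comparability; full-precision values live in the machine-readable manifest
companion where relevant.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .callset_io import (
    CALLERS,
    CallSet,
    SampleType,
    SegmentSet,
    read_caller_vcf,
    read_segments,
)
from .clonality import clonal_concordance, diploid_filter, label_clonality, segment_density
from .concordance import (
    concordance_metrics,
    consensus,
    germline_leak_filter,
    pairwise_caller_overlap,
)
from .mutational_profiles import (
    build_profile,
    cosine_similarity,
    fit_signatures,
    read_signature_matrix,
)
from .threshold_scan import build_ground_truth, default_grid, scan

_CONFIG_DEFAULTS: dict[str, Any] = {
    "k": 2,
    "shimmer_germline_filter": True,
    "germline_filter_all_callers": False,
    "neutral_log2_threshold": 0.1,
    "germline_cut": 0.45,
    "min_mass": 0.10,
    "top_fraction_q": 0.25,
    "seed": 0,
    "signatures": None,
    "artefact_ids": None,
    "reference_fasta": None,
    "seg_ff": None,
    "seg_ffpe": None,
    "score_fields": {},
}
_REQUIRED_KEYS = ("vcf_ff", "vcf_ffpe")
_KNOWN_KEYS = set(_CONFIG_DEFAULTS) | set(_REQUIRED_KEYS)


def validate_config(config: Mapping[str, Any]) -> dict[str, Any]:
    """Fill defaults, reject unknown keys, and sanity-check ranges.

    ``vcf_ff`` and ``vcf_ffpe`` map caller name to VCF path and are
    required; segment files and a signature matrix are optional (their
    stages are skipped when absent).
    """
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in _REQUIRED_KEYS:
        if key not in config or not config[key]:
            raise ValueError(f"config must provide {key} (caller -> VCF path)")
    out = dict(_CONFIG_DEFAULTS)
    out.update(config)
    for side in _REQUIRED_KEYS:
        bad = set(out[side]) - set(CALLERS)
        if bad:
            raise ValueError(f"{side}: unknown callers {sorted(bad)}")
    n_callers = len(out["vcf_ffpe"])
    if not (1 <= int(out["k"]) <= n_callers):
        raise ValueError(f"k={out['k']} out of range for {n_callers} callers")
    if not (0.0 < out["min_mass"] < 1.0) or not (0.0 < out["germline_cut"] <= 1.0):
        raise ValueError("min_mass must be in (0,1) and germline_cut in (0,1]")
    return out


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    version: str
    config: dict[str, Any]
    input_digests: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        return path


def _check_report_consistency(df: pd.DataFrame) -> None:
    """Every F1 column entry must equal the F1 recomputed from the same
    row's count columns (guards against report-assembly slips)."""
    for row in df.itertuples(index=False):
        n_ff, n_ffpe, n_ov = int(row.FF), int(row.FFPE), int(row.Overlap)
        f1 = 2 * n_ov / (n_ff + n_ffpe) if (n_ff + n_ffpe) else 0.0
        if abs(round(f1, 4) - float(row.F1)) > 5e-5:
            raise AssertionError(
                f"internal inconsistency: F1 {row.F1} != count-derived {round(f1, 4)}"
            )


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_all(config: Mapping[str, Any], outdir: str | Path) -> RunManifest:
    """Execute the full FF-vs-FFPE analysis and write one TSV per stage."""
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=__version__, config={
        k: (str(v) if isinstance(v, Path) else v) for k, v in cfg.items()
        if k not in ("vcf_ff", "vcf_ffpe")
    })
    manifest.config["vcf_ff"] = {c: str(p) for c, p in cfg["vcf_ff"].items()}
    manifest.config["vcf_ffpe"] = {c: str(p) for c, p in cfg["vcf_ffpe"].items()}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        manifest.outputs[name] = str(path)

    # ---- load inputs -----------------------------------------------------
    stage = "load_inputs"
    try:
        ff: dict[str, CallSet] = {}
        ffpe: dict[str, CallSet] = {}
        for side, store, st in (("vcf_ff", ff, SampleType.FF), ("vcf_ffpe", ffpe, SampleType.FFPE)):
            for caller, path in cfg[side].items():
                cs = read_caller_vcf(
                    path, caller, score_field=cfg["score_fields"].get(caller)
                )
                store[caller] = CallSet(caller=caller, sample_type=st, calls=cs.calls)
                manifest.input_digests[f"{side}:{caller}"] = _sha256(path)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(stage, exc) from exc

    # ---- stage 1: per-caller FF vs FFPE concordance ----------------------
    stage = "per_caller_concordance"
    try:
        rows = []
        for caller in CALLERS:
            if caller in ff and caller in ffpe:
                res = concordance_metrics(ff[caller].keys(), ffpe[caller].keys())
                rows.append({"caller": caller, **res.as_row()})
        df = pd.DataFrame(rows)
        _check_report_consistency(df)
        emit(stage, df)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage 2: pairwise caller overlap --------------------------------
    stage = "pairwise_overlap"
    try:
        frames = []
        for name, store in (("FF", ff), ("FFPE", ffpe)):
            if len(store) >= 2:
                sub = pairwise_caller_overlap(list(store.values()))
                sub.insert(0, "sample", name)
                frames.append(sub)
        emit(stage, pd.concat(frames, ignore_index=True))
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- germline-leak remediation (default: Shimmer only) ---------------
    stage = "germline_filter"
    try:
        def remediate(store: dict[str, CallSet]) -> dict[str, CallSet]:
            out = {}
            for caller, cs in store.items():
                apply = cfg["germline_filter_all_callers"] or (
                    caller == "shimmer" and cfg["shimmer_germline_filter"]
                )
                out[caller] = germline_leak_filter(cs) if apply else cs
            return out

        ff_f = remediate(ff)
        ffpe_f = remediate(ffpe)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage 3: ground truth (FF at-least-2 consensus) -----------------
    stage = "ground_truth"
    try:
        gt = build_ground_truth(list(ff_f.values()), k=2)
        manifest.notes.append(f"ground truth size: {len(gt)}")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage 4: per-caller threshold scans -----------------------------
    stage = "threshold_scan"
    try:
        rows = []
        for caller in CALLERS:
            if caller not in ffpe_f:
                continue
            result = scan(ffpe_f[caller], gt, default_grid(caller))
            best = result.best_result()
            rows.append(
                {"caller": caller, "best_threshold": result.best_threshold, **best.as_row()}
            )
            detail = pd.DataFrame(result.as_rows())
            emit(f"threshold_scan_{caller}", detail)
        df = pd.DataFrame(rows)
        _check_report_consistency(df)
        emit(stage, df)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage 5: at-least-k strategies ----------------------------------
    stage = "strategies"
    try:
        ffpe_sets = list(ffpe_f.values())
        rows = []
        consensus_by_k = {}
        for k in range(1, len(ffpe_sets) + 1):
            cons = consensus(ffpe_sets, k=k)
            consensus_by_k[k] = cons
            res = concordance_metrics(gt, cons.keys())
            rows.append({"strategy": f"at_least_{k}", **res.as_row()})
        df = pd.DataFrame(rows)
        _check_report_consistency(df)
        emit(stage, df)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage 6: mutational profiles + artefact fractions ---------------
    stage = "profiles"
    signatures = None
    try:
        reference = None
        if cfg["reference_fasta"]:
            import pyfaidx

            reference = pyfaidx.Fasta(str(cfg["reference_fasta"]))
        if cfg["signatures"]:
            signatures = read_signature_matrix(
                cfg["signatures"], artefact_ids=cfg["artefact_ids"] or ()
            )
        rows = []
        have_context = all(
            any(c.context for c in cs) for cs in (*ff_f.values(), *ffpe_f.values())
        ) or reference is not None
        if have_context:
            k_cons = int(cfg["k"])
            ff_cons = consensus(list(ff_f.values()), k=k_cons)
            ff_union = consensus(list(ff_f.values()), k=1)
            ffpe_cons = consensus_by_k.get(k_cons) or consensus(ffpe_sets, k=k_cons)
            ffpe_union = consensus_by_k.get(1) or consensus(ffpe_sets, k=1)
            named = {}
            for caller in CALLERS:
                if caller in ff_f and caller in ffpe_f:
                    named[f"{caller}"] = (ff_f[caller].calls, ffpe_f[caller].calls)
            named[f"at_least_{cfg['k']}"] = (
                [ff_cons.representative_call(k) for k in ff_cons.keys()],
                [ffpe_cons.representative_call(k) for k in ffpe_cons.keys()],
            )
            named["union"] = (
                [ff_union.representative_call(k) for k in ff_union.keys()],
                [ffpe_union.representative_call(k) for k in ffpe_union.keys()],
            )
            for name, (ff_calls, ffpe_calls) in named.items():
                p_ff = build_profile(ff_calls, reference)
                p_ffpe = build_profile(ffpe_calls, reference)
                row: dict[str, Any] = {"strategy": name}
                row["cosine_ff_ffpe"] = (
                    round(cosine_similarity(p_ff, p_ffpe), 4)
                    if p_ff.total and p_ffpe.total
                    else float("nan")
                )
                if signatures is not None:
                    for label, prof in (("ff", p_ff), ("ffpe", p_ffpe)):
                        fit = fit_signatures(prof, signatures)
                        row[f"artefact_fraction_{label}"] = round(fit.artefact_fraction, 4)
                        row[f"reliable_{label}"] = fit.reliable
                rows.append(row)
            emit(stage, pd.DataFrame(rows))
        else:
            manifest.notes.append(
                "profiles stage skipped: no trinucleotide contexts and no reference FASTA"
            )
        if signatures is None:
            manifest.notes.append("signature fitting skipped: no signature matrix configured")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage 7: clonality ----------------------------------------------
    stage = "clonality"
    try:
        if cfg["seg_ff"] and cfg["seg_ffpe"]:
            seg_ff = read_segments(cfg["seg_ff"], neutral_log2_threshold=cfg["neutral_log2_threshold"])
            seg_ffpe = read_segments(cfg["seg_ffpe"], neutral_log2_threshold=cfg["neutral_log2_threshold"])
            manifest.input_digests["seg_ff"] = _sha256(cfg["seg_ff"])
            manifest.input_digests["seg_ffpe"] = _sha256(cfg["seg_ffpe"])
            k_cons = max(int(cfg["k"]), 2)
            results = {}
            label_rows = []
            density_rows = []
            for name, store in (("FF", ff_f), ("FFPE", ffpe_f)):
                cons = consensus(list(store.values()), k=k_cons)
                bona = diploid_filter(cons, seg_ff, seg_ffpe)
                res = label_clonality(
                    bona,
                    germline_cut=cfg["germline_cut"],
                    min_mass=cfg["min_mass"],
                )
                results[name] = res
                for call in bona.calls:
                    label_rows.append(
                        {
                            "sample": name,
                            "chrom": call.key.chrom,
                            "pos": call.key.pos,
                            "ref": call.key.ref,
                            "alt": call.key.alt,
                            "vaf": round(call.tumor_vaf, 6),
                            "label": res.labels[call.key],
                        }
                    )
                d = res.density
                for g, y in zip(d.grid, d.density):
                    density_rows.append({"sample": name, "vaf": round(float(g), 6),
                                         "density": round(float(y), 6)})
            cc = clonal_concordance(results["FF"], results["FFPE"])
            rows = []
            for label, res, defined in (
                ("clonal", cc.clonal, cc.clonal_defined),
                ("subclonal", cc.subclonal, cc.subclonal_defined),
            ):
                if defined:
                    rows.append({"clonality": label, "defined": True, **res.as_row()})
                else:
                    rows.append({
                        "clonality": label, "defined": False,
                        "FF": len(results["FF"].keys_with(label)),
                        "FFPE": len(results["FFPE"].keys_with(label)),
                        "Overlap": 0, "Sensitivity": float("nan"),
                        "Precision": float("nan"), "F1": float("nan"),
                    })
            emit(stage, pd.DataFrame(rows))
            emit("clonality_labels", pd.DataFrame(label_rows))
            emit("clonality_density", pd.DataFrame(density_rows))
            cross = cc.cross_tab.reset_index()
            emit("clonality_cross_tab", cross)
        else:
            manifest.notes.append("clonality stage skipped: no segment files configured")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    manifest.write(outdir / "manifest.json")
    manifest.outputs["manifest"] = str(outdir / "manifest.json")
    return manifest
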