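"""End-to-end pipeline assembly: config validation, stage execution, manifest.

A run is described by a nested config (typically loaded from YAML): either a
``synthetic`` block (generator parameters) or an ``inputs`` block (paths to
an expression matrix, response annotation, probe annotation and segment
table), a ``contrast`` block, per-stage parameter blocks and a ``stages``
list. Every random stage derives its stream from the single top-level
``seed``. No stage mutates its inputs on disk; all artifacts land in
``out_dir`` together with a JSON manifest recording the package version, the
fully resolved config and a SHA-256 digest per output file, so a rerun with
the same config and seed reproduces identical digests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import yaml

from . import __version__
from .cna import compare_groups, filter_comparisons, regionize, write_comparisons
from .diffexpr import filter_de, probe_de, write_de
from .discovery import discover_signature, evaluate_signature
from .integration import carrier_contrast, fraction_deregulated
from .io import (
    make_contrast,
    read_expression,
    read_probe_annotation,
    read_response_annotation,
    read_segments,
    write_expression,
    write_response_annotation,
    write_segments,
)
from .preprocess import quantile_normalize
from .synthetic import ConfigError, PlantedRegion, SyntheticConfig, generate_cohort

ALL_STAGES = ("simulate", "normalize", "de", "discover", "evaluate", "cnacompare", "integrate")

_ALLOWED_KEYS = {
    None: {"seed", "synthetic", "inputs", "contrast", "discovery", "evaluate",
           "cna", "integration", "de", "stages"},
    "synthetic": {"n_samples", "class_proportions", "n_probes", "n_informative",
                  "mean_shift", "within_class_sd", "class_cov_distortion",
                  "baseline_range", "cna_regions", "dosage_effect", "coupled_events",
                  "noise_segments_per_sample", "positive_category"},
    "inputs": {"expression", "expression_format", "response", "probes", "segments"},
    "contrast": {"positive", "negative"},
    "de": {"p_threshold", "gene_list", "equal_var"},
    "discovery": {"prefilter_m", "top_k", "max_size", "metric", "priors"},
    "evaluate": {"k", "n_repeats", "stratified"},
    "cna": {"preset", "p_threshold", "diff_threshold_pct", "fdr_scope"},
    "integration": {"p_threshold", "direction", "by_gene"},
}


def validate_config(config: dict) -> dict:
    """Reject unknown keys early, naming the offender."""
    for section, allowed in _ALLOWED_KEYS.items():
        block = config if section is None else config.get(section, {})
        if not isinstance(block, dict):
            continue
        unknown = set(block) - allowed
        if unknown:
            where = "top level" if section is None else f"section '{section}'"
            raise ConfigError(f"unknown config key(s) {sorted(unknown)} at {where}")
    bad_stages = set(config.get("stages", [])) - set(ALL_STAGES)
    if bad_stages:
        raise ConfigError(f"unknown stage(s) {sorted(bad_stages)}; allowed: {list(ALL_STAGES)}")
    if "synthetic" not in config and "inputs" not in config:
        raise ConfigError("config needs a 'synthetic' or an 'inputs' section")
    return config


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _synthetic_config(block: dict, seed: int) -> SyntheticConfig:
    block = dict(block)
    if "cna_regions" in block:
        block["cna_regions"] = tuple(
            PlantedRegion(**{**r, "member_genes": tuple(r.get("member_genes", ()))})
            if isinstance(r, dict) else r
            for r in block["cna_regions"]
        )
    if "baseline_range" in block:
        block["baseline_range"] = tuple(block["baseline_range"])
    if "coupled_events" in block:
        block["coupled_events"] = tuple(block["coupled_events"])
    return SyntheticConfig(seed=seed, **block)


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute the requested stages and return the manifest (also written to
    ``out_dir/manifest.json``)."""
    validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = tuple(config.get("stages", ALL_STAGES))
    artifacts: dict[str, Path] = {}
    report: dict = {}

    # --- inputs ---------------------------------------------------------
    truth = annotation = segments = None
    if "synthetic" in config and ("simulate" in stages or "inputs" not in config):
        syn = _synthetic_config(config.get("synthetic", {}), seed)
        cohort = generate_cohort(syn)
        matrix, labels = cohort.expression, cohort.labels
        annotation, segments, truth = cohort.annotation, cohort.segments, cohort.truth
        if "simulate" in stages:
            write_expression(matrix, out / "expression.tsv")
            write_response_annotation(labels, out / "response.csv")
            write_segments(segments, out / "segments.tsv")
            annotation.rename_axis("probe_id").to_csv(out / "probes.csv")
            artifacts.update(
                expression=out / "expression.tsv", response=out / "response.csv",
                segments=out / "segments.tsv", probes=out / "probes.csv",
            )
            report["truth"] = {
                "informative_probes": list(truth.informative_probe_ids),
                "bayes_accuracy": truth.bayes_accuracy,
            }
    else:
        inputs = config["inputs"]
        matrix = read_expression(
            inputs["expression"], format=inputs.get("expression_format", "tsv")
        )
        labels = read_response_annotation(inputs["response"])
        annotation = read_probe_annotation(inputs["probes"]) if "probes" in inputs else None
        segments = read_segments(inputs["segments"]) if "segments" in inputs else None

    cblock = config.get("contrast", {"positive": ["CR"], "negative": ["nCR", "VGPR", "PR", "SD"]})
    contrast = make_contrast(labels, cblock["positive"], cblock["negative"])
    report["contrast"] = {
        contrast.name_positive: contrast.n_positive,
        contrast.name_negative: contrast.n_negative,
    }

    # --- stages ---------------------------------------------------------
    if "normalize" in stages:
        matrix = quantile_normalize(matrix)
        write_expression(matrix, out / "expression_normalized.tsv")
        artifacts["expression_normalized"] = out / "expression_normalized.tsv"

    if "de" in stages:
        de_block = config.get("de", {})
        results = probe_de(matrix, contrast, annotation=annotation,
                           equal_var=de_block.get("equal_var", False))
        kept = filter_de(results, p_threshold=de_block.get("p_threshold", 0.05),
                         gene_list=de_block.get("gene_list"))
        write_de(kept, out / "de_significant.tsv")
        artifacts["de_significant"] = out / "de_significant.tsv"
        report["de"] = {"n_tested": len(results), "n_significant": len(kept)}

    signature = None
    if "discover" in stages:
        d = config.get("discovery", {})
        pairs, candidates, signature = discover_signature(
            matrix, contrast, prefilter_m=d.get("prefilter_m", "auto"),
            top_k=d.get("top_k", 50), max_size=d.get("max_size", 10),
            metric=d.get("metric", "balanced"), priors=d.get("priors", "equal"),
        )
        top_k = d.get("top_k", 50)
        with open(out / "ranked_pairs.tsv", "w") as fh:
            fh.write("probe_a\tprobe_b\ttp\tfp\ttn\tfn\tscore\n")
            for ps in pairs[: max(top_k, 200)]:
                fh.write(f"{ps.probes[0]}\t{ps.probes[1]}\t{ps.tp}\t{ps.fp}"
                         f"\t{ps.tn}\t{ps.fn}\t{ps.score:.6f}\n")
        artifacts["ranked_pairs"] = out / "ranked_pairs.tsv"
        with open(out / "signature.json", "w") as fh:
            json.dump({"probes": list(signature.probes),
                       "provenance": signature.provenance,
                       "n_candidates": len(candidates)}, fh, indent=2)
        artifacts["signature"] = out / "signature.json"
        report["signature"] = list(signature.probes)

    if "evaluate" in stages:
        if signature is None:
            raise ConfigError("'evaluate' requires the 'discover' stage")
        e = config.get("evaluate", {})
        cv = evaluate_signature(
            matrix, contrast, signature, k=e.get("k", 3),
            n_repeats=e.get("n_repeats", 1000),
            stratified=e.get("stratified", True), seed=seed,
        )
        with open(out / "cv_report.json", "w") as fh:
            json.dump(cv.to_dict(), fh, indent=2)
        artifacts["cv_report"] = out / "cv_report.json"
        report["cv"] = cv.summary()

    comparisons = call_matrix = None
    if "cnacompare" in stages:
        if segments is None:
            raise ConfigError("'cnacompare' requires a segment table")
        c = config.get("cna", {})
        call_matrix = regionize(segments, labels.index)
        comparisons = compare_groups(call_matrix, contrast,
                                     fdr_scope=c.get("fdr_scope", "joint"))
        kept = filter_comparisons(
            comparisons, p_threshold=c.get("p_threshold"),
            diff_threshold_pct=c.get("diff_threshold_pct"),
            preset=c.get("preset", "broad" if "p_threshold" not in c else None),
        )
        write_comparisons(kept, out / "cna_comparisons.tsv",
                          probe_annotation=annotation)
        artifacts["cna_comparisons"] = out / "cna_comparisons.tsv"
        report["cna"] = {"n_regions": len(comparisons), "n_significant": len(kept)}

    if "integrate" in stages:
        if comparisons is None:
            raise ConfigError("'integrate' requires the 'cnacompare' stage")
        if annotation is None:
            raise ConfigError("'integrate' requires a probe annotation")
        ib = config.get("integration", {})
        kept = filter_comparisons(
            comparisons, preset=config.get("cna", {}).get("preset", "broad")
        )
        rows = []
        for r in kept:
            idx = call_matrix.regions.index[
                (call_matrix.regions["chrom"] == r.chrom)
                & (call_matrix.regions["start"] == r.start)
                & (call_matrix.regions["end"] == r.end)
                & (call_matrix.regions["event"] == r.event)
            ][0]
            try:
                de = carrier_contrast(matrix, idx, call_matrix, contrast, annotation)
            except ValueError:
                continue
            frac = fraction_deregulated(
                de, p_threshold=ib.get("p_threshold", 0.05),
                direction=ib.get("direction", "down"),
                by_gene=ib.get("by_gene", True),
            )
            rows.append({
                "region": f"{r.chrom}:{r.start}-{r.end}", "event": r.event,
                "n_genes": len(de),
                "fraction_down": frac.fraction_direction,
                "fraction_significant": frac.fraction_significant,
            })
        with open(out / "integration.json", "w") as fh:
            json.dump(rows, fh, indent=2)
        artifacts["integration"] = out / "integration.json"
        report["integration"] = rows

    manifest = {
        "package": "mmresponse",
        "version": __version__,
        "seed": seed,
        "stages": list(stages),
        "config": _jsonable(config),
        "report": report,
        "digests": {name: _sha256(path) for name, path in sorted(artifacts.items())},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, PlantedRegion):
        return _jsonable(asdict(obj))
    if isinstance(obj, Path):
        return str(obj)
    return obj
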