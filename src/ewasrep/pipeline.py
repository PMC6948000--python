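"""End-to-end orchestration: simulate -> qc -> cells -> ewas -> compare -> report.

A run is driven by a plain dictionary config (typically loaded from YAML or
JSON), validated up front with all violations reported at once.  Every stage
writes TSV/JSON outputs into the run directory, and a manifest records the
config hash, seeds and output checksums so reruns can be verified
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from ewasrep import io as eio
from ewasrep.cells import default_cell_reference, estimate_cell_fractions
from ewasrep.concordance import (
    compare_associations,
    effect_size_regression,
    summarize_trait,
)
from ewasrep.ewas import ModelSpec, estimate_surrogates, fit_ewas, genomewide_hits
from ewasrep.qc import apply_qc, qc_filter
from ewasrep.synthetic import (
    SyntheticConfig,
    generate_cohort,
    generate_detection_matrix,
    generate_reference_summary,
)
from ewasrep.varpower import PowerSpec, bonferroni_threshold, probe_power, round_sig

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "cells", "ewas", "compare", "power", "report")

DEFAULT_CONFIG = {
    "seed": 0,
    "stages": {stage: True for stage in STAGES},
    "synthetic": {},
    "model": {
        "trait": "alcohol",
        "orientation": "methylation_outcome",
        "covariates": ["age", "bmi", "cell_counts"],
        "exposure_coding": "continuous",
        "n_surrogates": 0,
        "trait_transform": "identity",
    },
    "qc": {"p_threshold": 0.01, "max_fail_fraction": 0.05},
    "ci_level": 0.95,
    "genomewide_threshold": 9.4e-8,
    "power": {"alpha_family": 0.05, "m_tests": 530_639, "delta": 0.05, "target": 0.80},
    "inputs": {},
}


def load_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        return yaml.safe_load(text)
    return json.loads(text)


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def validate_config(config: dict) -> list[str]:
    """Collect every schema violation; an empty list means valid."""
    errors: list[str] = []
    known = set(DEFAULT_CONFIG)
    for key in config:
        if key not in known:
            errors.append(f"unknown config key {key!r}")
    stages = config.get("stages", {})
    for stage in stages:
        if stage not in STAGES:
            errors.append(f"unknown stage {stage!r}")
    level = config.get("ci_level", 0.95)
    if not 0 < level < 1:
        errors.append(f"ci_level must lie in (0, 1); got {level}")
    threshold = config.get("genomewide_threshold", 9.4e-8)
    if not 0 < threshold <= 1:
        errors.append(f"genomewide_threshold must lie in (0, 1]; got {threshold}")
    try:
        SyntheticConfig.from_dict(config.get("synthetic", {})).validate()
    except (TypeError, ValueError) as exc:
        errors.append(f"synthetic: {exc}")
    try:
        ModelSpec(**config.get("model", DEFAULT_CONFIG["model"]))
    except (TypeError, ValueError) as exc:
        errors.append(f"model: {exc}")
    if not stages.get("simulate", True):
        inputs = config.get("inputs", {})
        if stages.get("compare", True) and not (
            inputs.get("local_summary") and inputs.get("reference_summary")
        ):
            errors.append(
                "compare without simulate requires inputs.local_summary and "
                "inputs.reference_summary"
            )
    return errors


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def replication_report(summaries: list) -> dict:
    """Pool per-trait concordance summaries into one overall partition."""
    if not summaries:
        raise ValueError("at least one trait summary is required")
    n = sum(s.n_tests for s in summaries)
    n_overlap = sum(s.n_overlap for s in summaries)
    n_consistent = sum(s.n_consistent for s in summaries)
    n_opposite = sum(s.n_opposite for s in summaries)
    per_trait = [
        {
            "trait": s.trait,
            "ancestry": s.ancestry,
            "n_tests": s.n_tests,
            "n_overlap": s.n_overlap,
            "n_consistent": s.n_consistent,
            "n_opposite": s.n_opposite,
            "pct_overlap": s.pct_overlap,
            "slope": s.slope,
        }
        for s in summaries
    ]
    return {
        "n_tests": n,
        "n_overlap": n_overlap,
        "n_consistent": n_consistent,
        "n_opposite": n_opposite,
        "frac_overlap": n_overlap / n,
        "frac_consistent": n_consistent / n,
        "frac_opposite": n_opposite / n,
        "per_trait": per_trait,
    }


def run_pipeline(config: dict, out_dir: str | Path) -> Path:
    """Run the enabled stages and write all outputs plus a manifest.

    Returns the run directory.  Rerunning with an identical config
    reproduces byte-identical numeric outputs.
    """
    config = _merge(DEFAULT_CONFIG, config)
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config:\n  - " + "\n  - ".join(errors))

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = config["stages"]
    seed = int(config["seed"])
    written: list[Path] = []

    syn_cfg = SyntheticConfig.from_dict(
        {**config["synthetic"], "seed": config["synthetic"].get("seed", seed)}
    )
    meth = pheno = truth = reference = local_summary = None
    stage_name = "setup"

    try:
        stage_name = "simulate"
        if stages.get("simulate", True):
            logger.info("stage simulate: %d probes x %d samples", syn_cfg.n_probes, syn_cfg.n_samples)
            meth, pheno, truth = generate_cohort(syn_cfg)
            reference = generate_reference_summary(truth, syn_cfg)
            det = generate_detection_matrix(syn_cfg)
            eio.write_matrix(meth, out / "methylation.tsv")
            eio.write_phenotypes(pheno, out / "phenotypes.tsv")
            eio.write_truth(truth, out / "truth.tsv")
            eio.write_summary_table(reference, out / "reference_summary.tsv")
            eio.write_matrix(det, out / "detection.tsv")
            (out / "synthetic_config.json").write_text(syn_cfg.to_json() + "\n")
            written += [
                out / "methylation.tsv",
                out / "phenotypes.tsv",
                out / "truth.tsv",
                out / "reference_summary.tsv",
                out / "detection.tsv",
                out / "synthetic_config.json",
            ]
        else:
            inputs = config["inputs"]
            if inputs.get("methylation"):
                meth = eio.read_matrix(inputs["methylation"])
            if inputs.get("phenotypes"):
                pheno = eio.read_phenotypes(inputs["phenotypes"])
            if inputs.get("reference_summary"):
                reference = eio.read_summary_table(inputs["reference_summary"])
            if inputs.get("local_summary"):
                local_summary = eio.read_summary_table(inputs["local_summary"])

        stage_name = "qc"
        if stages.get("qc", True) and meth is not None:
            det_path = out / "detection.tsv"
            det = eio.read_matrix(det_path) if det_path.exists() else None
            if config["inputs"].get("detection"):
                det = eio.read_matrix(config["inputs"]["detection"])
            if det is not None:
                report = qc_filter(det, **config["qc"])
                meth = apply_qc(meth, report)
                (out / "qc_report.json").write_text(report.to_json() + "\n")
                written.append(out / "qc_report.json")
                logger.info(
                    "stage qc: excluded %d samples, %d probes",
                    len(report.excluded_samples),
                    len(report.excluded_probes),
                )

        stage_name = "cells"
        if stages.get("cells", True) and meth is not None:
            ref = default_cell_reference()
            shared = ref.index.intersection(meth.index)
            if len(shared) >= ref.shape[1]:
                fractions = estimate_cell_fractions(meth, ref)
                fractions.to_csv(out / "cell_fractions.tsv", sep="\t")
                written.append(out / "cell_fractions.tsv")
                logger.info("stage cells: estimated fractions on %d shared probes", len(shared))
            else:
                logger.info("stage cells: skipped (no reference probes in matrix)")

        stage_name = "ewas"
        if stages.get("ewas", True) and meth is not None and pheno is not None:
            spec = ModelSpec(**config["model"])
            surrogates = None
            if spec.n_surrogates != 0:
                surrogates = estimate_surrogates(meth, pheno, spec, seed=seed)
                surrogates.vectors.to_csv(out / "surrogates.tsv", sep="\t")
                written.append(out / "surrogates.tsv")
            local_summary = fit_ewas(
                meth, pheno, spec, surrogates, ci_level=config["ci_level"]
            )
            eio.write_summary_table(local_summary, out / "local_summary.tsv")
            hits = genomewide_hits(local_summary, config["genomewide_threshold"])
            eio.write_summary_table(hits, out / "genomewide_hits.tsv")
            written += [out / "local_summary.tsv", out / "genomewide_hits.tsv"]
            logger.info("stage ewas: %d probes fitted, %d hits", len(local_summary), len(hits))

        summaries = []
        stage_name = "compare"
        if stages.get("compare", True) and local_summary is not None and reference is not None:
            result = compare_associations(local_summary, reference, level=config["ci_level"])
            result.records.to_csv(out / "comparison_records.tsv", sep="\t", index=False)
            regression = effect_size_regression(local_summary, reference)
            summary = summarize_trait(result.records)
            summaries.append(summary)
            eio.write_json(
                {
                    "trait": summary.trait,
                    "ancestry": summary.ancestry,
                    "n_tests": summary.n_tests,
                    "n_overlap": summary.n_overlap,
                    "n_consistent": summary.n_consistent,
                    "n_opposite": summary.n_opposite,
                    "slope": regression.slope,
                    "slope_se": regression.se,
                    "slope_p": regression.p,
                    "r_squared": regression.r_squared,
                    "y_axis": regression.y_axis,
                },
                out / "concordance_summary.json",
            )
            # plot-data table: x/y effects with the class colour semantics
            plot = result.records[
                ["probe_id", "local_effect", "ref_effect", "direction_class"]
            ].copy()
            plot["color"] = plot["direction_class"].map(
                {"overlap": "green", "consistent_nonoverlap": "yellow", "opposite": "red"}
            )
            plot.to_csv(out / "plot_data.tsv", sep="\t", index=False)
            written += [
                out / "comparison_records.tsv",
                out / "concordance_summary.json",
                out / "plot_data.tsv",
            ]
            logger.info(
                "stage compare: %d tests, %d overlap", summary.n_tests, summary.n_overlap
            )

        stage_name = "power"
        if stages.get("power", True):
            pw_cfg = config["power"]
            threshold = bonferroni_threshold(pw_cfg["alpha_family"], pw_cfg["m_tests"])
            if meth is not None:
                sds = meth.to_numpy().std(axis=1, ddof=1)
                n_samples = meth.shape[1]
            else:
                sds = np.asarray([0.05])
                n_samples = syn_cfg.n_samples
            spec_pw = PowerSpec(
                alpha_family=pw_cfg["alpha_family"],
                m_tests=pw_cfg["m_tests"],
                delta=pw_cfg["delta"],
                n=n_samples,
                probe_sd=sds,
            )
            result_pw = probe_power(spec_pw, threshold, target=pw_cfg["target"])
            eio.write_json(
                {
                    "per_test_threshold": threshold,
                    "per_test_threshold_display": round_sig(threshold, 2),
                    "fraction_at_target": result_pw.fraction_at_target,
                    "target": result_pw.target,
                    "n_probes": int(len(np.atleast_1d(result_pw.power))),
                },
                out / "power.json",
            )
            written.append(out / "power.json")

        stage_name = "report"
        if stages.get("report", True) and summaries:
            eio.write_json(replication_report(summaries), out / "replication_report.json")
            written.append(out / "replication_report.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage_name!r} failed: {exc}") from exc

    manifest = {
        "config_hash": _config_hash(config),
        "seed": seed,
        "synthetic_seed": syn_cfg.seed,
        "stages": {s: bool(stages.get(s, True)) for s in STAGES},
        "outputs": {p.name: _checksum(p) for p in written},
        "version": "0.1.0",
    }
    eio.write_json(manifest, out / "manifest.json")
    return out
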