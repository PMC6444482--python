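"""End-to-end experiment orchestration.

A single YAML config drives simulate -> qc -> annotate -> scan -> cv for a
requested list of prediction models; every run directory receives the
artifacts plus a manifest (config snapshot, per-stage seeds, file digests,
timings, version) so reruns with the same config reproduce identical
outputs.  Per-stage seeds are derived from the master seed by fixed
offsets so each stage is independently reproducible.
"""

from __future__ import annotations

import hashlib
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotate import partition_snps
from .data import align_phenotypes, read_phenotypes, write_phenotypes
from .evaluate import (
    CVResult,
    McmcConfig,
    ModelSpec,
    evaluate_model,
    kfold_split,
    random_snp_baseline,
)
from .qc import dedupe_records, filter_snps
from .scan import DominanceScan
from .simulate import SimulationConfig, simulate_dataset

log = logging.getLogger(__name__)

STAGE_SEED_OFFSETS = {"simulate": 0, "scan": 11, "folds": 23, "mcmc": 37, "random": 53}

_ALLOWED_SECTIONS = {
    "out_dir",
    "seed",
    "simulation",
    "qc",
    "scan",
    "mcmc",
    "cv",
    "models",
    "write_genotypes",
}

KNOWN_MODEL_LABELS = (
    "Base",
    "Base+5SNP",
    "Intergenic+Functional",
    "Intergenic+5SNP+Functional",
)


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        cfg = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh)
    unknown = set(cfg) - _ALLOWED_SECTIONS
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    if "out_dir" not in cfg:
        raise ValueError("config must set out_dir")
    cfg.setdefault("seed", 0)
    cfg.setdefault("simulation", {})
    cfg.setdefault("qc", {})
    cfg.setdefault("scan", {"alpha": 0.05})
    cfg.setdefault("mcmc", {})
    cfg.setdefault("cv", {"k": 5, "n_repeats": 2})
    cfg.setdefault("models", ["Base"])
    cfg.setdefault("write_genotypes", False)
    for label in cfg["models"]:
        if label not in KNOWN_MODEL_LABELS and not label.startswith(
            ("class:", "random:")
        ):
            raise ValueError(f"unknown model label {label!r}")
    return cfg


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def _build_specs(labels, partition, selected) -> list[ModelSpec]:
    specs = []
    for label in labels:
        if label.startswith("random:"):
            continue  # handled separately
        if label == "Base":
            specs.append(ModelSpec("Base"))
        elif label == "Base+5SNP":
            specs.append(
                ModelSpec(
                    "Base+5SNP", fixed_marker_ids=tuple(selected)
                )
            )
        elif label in ("Intergenic+Functional", "Intergenic+5SNP+Functional"):
            sets = {
                cls: list(partition.ids_in(cls))
                for cls in partition.class_of.unique()
                if len(partition.ids_in(cls)) >= 2
            }
            fixed = tuple(selected) if "5SNP" in label else ()
            specs.append(ModelSpec(label, kernel_snp_sets=sets, fixed_marker_ids=fixed))
        elif label.startswith("class:"):
            cls = label.split(":", 1)[1]
            ids = list(partition.ids_in(cls))
            if len(ids) < 2:
                raise ValueError(f"class {cls!r} has fewer than 2 SNPs")
            specs.append(ModelSpec(label, kernel_snp_sets={cls: ids}))
    return specs


def run_experiment(config) -> Path:
    """Execute the configured stages; returns the run directory."""
    cfg = load_config(config)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    master = int(cfg["seed"])
    timings = {}
    outputs = {}
    manifest = {
        "version": __version__,
        "config": cfg,
        "seeds": {
            stage: master + off for stage, off in STAGE_SEED_OFFSETS.items()
        },
        "status": "running",
    }

    try:
        t0 = time.perf_counter()
        sim_cfg = SimulationConfig(
            **{**cfg["simulation"], "seed": master + STAGE_SEED_OFFSETS["simulate"]}
        )
        genotypes, gene_models, pheno_raw, truth = simulate_dataset(sim_cfg)
        gene_models.write(out)
        write_phenotypes(pheno_raw, out / "phenotypes_raw.tsv")
        truth.write(out / "true_parameters.tsv")
        if cfg["write_genotypes"]:
            genotypes.to_tsv(out / "genotypes.tsv")
            genotypes.to_plink(out / "genotypes")
        timings["simulate"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        qc_res = filter_snps(genotypes, **cfg["qc"])
        genotypes = qc_res.genotypes
        qc_res.report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        pheno = dedupe_records(read_phenotypes(out / "phenotypes_raw.tsv"))
        write_phenotypes(pheno, out / "phenotypes.tsv")
        timings["qc"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        partition = partition_snps(
            genotypes, gene_models.genes, gene_models.effect_labels
        )
        partition.to_tsv(out / "snp_classes.tsv")
        timings["annotate"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        y, X, _ = align_phenotypes(genotypes, pheno)
        scan_fit = DominanceScan(y, X, genotypes).fit(
            alpha=cfg["scan"].get("alpha", 0.05)
        )
        scan_fit.to_tsv(out / "scan.tsv")
        (out / "scan_summary.txt").write_text(scan_fit.summary() + "\n")
        timings["scan"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        mcmc = McmcConfig(
            **{**cfg["mcmc"], "seed": master + STAGE_SEED_OFFSETS["mcmc"]}
        )
        folds = kfold_split(
            genotypes.sample_ids,
            k=cfg["cv"].get("k", 5),
            n_repeats=cfg["cv"].get("n_repeats", 2),
            seed=master + STAGE_SEED_OFFSETS["folds"],
        )
        cache: dict = {}
        frames = []
        for spec in _build_specs(cfg["models"], partition, scan_fit.selected):
            res = evaluate_model(spec, genotypes, y, X, folds, mcmc, cache)
            frames.append(res.estimates)
        for label in cfg["models"]:
            if label.startswith("random:"):
                size = int(label.split(":", 1)[1])
                res = random_snp_baseline(
                    genotypes,
                    y,
                    X,
                    class_size=size,
                    n_samplings=cfg["cv"].get("n_samplings", 1),
                    folds=folds,
                    mcmc=mcmc,
                    seed=master + STAGE_SEED_OFFSETS["random"],
                    label=label,
                )
                frames.append(res.estimates.drop(columns="sampling"))
        if frames:
            cv_all = CVResult(pd.concat(frames, ignore_index=True))
            cv_all.estimates.to_csv(out / "cv_estimates.tsv", sep="\t", index=False)
            cv_all.summary().to_csv(out / "cv_summary.tsv", sep="\t", index=False)
        timings["cv"] = time.perf_counter() - t0
        manifest["status"] = "ok"
    except Exception as exc:  # partial outputs stay; manifest records failure
        manifest["status"] = f"failed: {exc}"
        raise
    finally:
        for f in sorted(out.glob("*.tsv")) + sorted(out.glob("*.bed")):
            outputs[f.name] = _digest(f)
        manifest["outputs"] = outputs
        manifest["timings_sec"] = {k: round(v, 3) for k, v in timings.items()}
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
    return out
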