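"""Config-driven orchestration of the full lipidomics analysis.

A run is described by one YAML/dict config: either paths to per-mode
intensity tables plus sample metadata, or a ``simulate`` block for the
synthetic generator; a list of pairwise comparisons (selector A,
selector B, thresholds); and options for the multivariate stages.  The
run writes a deterministic artifact bundle — class-composition and
charge-profile CSVs, a dendrogram in Newick, one differential CSV,
summary JSON and membrane-index JSON per comparison, optional PLS-DA
and biomarker reports — along with a provenance record (input hashes,
thresholds, seed, package version).

Selectors are validated before any computation; a stage failure after
that is logged and the completed artifacts are retained.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

import lipidome
from lipidome.differential import differential_table, subclass_composition, summarize_counts
from lipidome.membrane_metrics import charge_profile, membrane_indices
from lipidome.multivariate import plsda, rf_biomarker_mccv, ward_cluster
from lipidome.preprocess import (
    IntensityMatrix,
    log2_median_normalize,
    merge_modes,
    read_intensity_table,
    read_sample_metadata,
    total_intensity_normalize,
)
from lipidome.synthetic import (
    PlantedEffect,
    SyntheticConfig,
    simulate_lipidome,
    write_tables,
)

__all__ = ["RunConfig", "RunResult", "load_config", "run"]

log = logging.getLogger("lipidome")


@dataclass
class RunConfig:
    output_dir: str = "lipidome_out"
    seed: int = 0
    inputs: dict | None = None  # negative/positive/metadata paths
    simulate: dict | None = None  # SyntheticConfig fields
    comparisons: list[dict] = field(default_factory=list)
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise ValueError("config needs exactly one of 'inputs' or 'simulate'")
        for comp in self.comparisons:
            for key in ("a", "b"):
                if key not in comp:
                    raise ValueError(f"comparison missing selector {key!r}: {comp}")
            for thr in ("p_threshold", "fc_threshold"):
                if thr in comp and comp[thr] <= 0:
                    raise ValueError(f"{thr} must be positive in {comp}")


@dataclass
class RunResult:
    manifest: dict[str, Path]
    errors: list[str]

    @property
    def ok(self) -> bool:
        return not self.errors


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig(**raw)


def _load_matrix(cfg: RunConfig, outdir: Path) -> IntensityMatrix:
    if cfg.simulate is not None:
        sim = dict(cfg.simulate)
        sim.setdefault("seed", cfg.seed)
        effects = [
            PlantedEffect(**e) if isinstance(e, dict) else e
            for e in sim.pop("planted_effects", [])
        ]
        matrix, truth = simulate_lipidome(
            SyntheticConfig(planted_effects=effects, **sim)
        )
        write_tables(matrix, truth, outdir / "simulated_input")
        return matrix
    meta = read_sample_metadata(cfg.inputs["metadata"]) if cfg.inputs.get("metadata") else None
    neg = read_intensity_table(cfg.inputs["negative"], "negative", sample_meta=meta)
    pos = read_intensity_table(cfg.inputs["positive"], "positive", sample_meta=meta)
    return merge_modes(neg, pos)


def _hash_inputs(cfg: RunConfig) -> dict[str, str]:
    hashes = {}
    if cfg.inputs:
        for key, path in cfg.inputs.items():
            if path and Path(path).exists():
                hashes[key] = hashlib.sha256(Path(path).read_bytes()).hexdigest()
    hashes["config"] = hashlib.sha256(
        json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str).encode()
    ).hexdigest()
    return hashes


def _stage(name: str, errors: list[str]):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                log.error("stage %s: FAILED after %.2fs: %s", name, dt, exc)
                errors.append(f"{name}: {exc}")
                return True  # retain completed stages, record failure
            log.info("stage %s: done in %.2fs", name, dt)
            return False

    return _Timer()


def run(cfg: RunConfig) -> RunResult:
    """Execute the configured analysis; returns the artifact manifest."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}
    errors: list[str] = []

    raw = _load_matrix(cfg, outdir)

    # fail fast on unresolvable selectors, before any computation
    for comp in cfg.comparisons:
        raw.select_samples(comp["a"])
        raw.select_samples(comp["b"])

    opts = cfg.options
    with _stage("composition", errors):
        total = total_intensity_normalize(raw)
        species = total.species()
        comp_rows = total.values.copy()
        comp_rows["subclass"] = [
            species[l].subclass if species[l] else "unclassified"
            for l in total.lipid_ids
        ]
        path = outdir / "class_composition.csv"
        comp_rows.groupby("subclass").sum().to_csv(path)
        manifest["class_composition"] = path

        profile = charge_profile(total, basis=opts.get("charge_basis", "fig8_classes_only"))
        path = outdir / "charge_profile.csv"
        profile.fractions.to_csv(path)
        manifest["charge_profile"] = path

    with _stage("normalize", errors):
        logm = log2_median_normalize(raw, zero_policy=opts.get("zero_policy", "error"))

    with _stage("cluster", errors):
        tree = ward_cluster(logm)
        path = outdir / "dendrogram.nwk"
        path.write_text(tree.to_newick() + "\n")
        manifest["dendrogram"] = path

    for comp in cfg.comparisons:
        name = comp.get("name") or f"{comp['a']}_vs_{comp['b']}"
        name = "".join(c if c.isalnum() or c in "-_" else "_" for c in str(name))
        with _stage(f"differential[{name}]", errors):
            table = differential_table(
                logm,
                comp["a"],
                comp["b"],
                p_threshold=comp.get("p_threshold", 0.05),
                fc_threshold=comp.get("fc_threshold", 1.5),
                label_a=str(comp["a"]),
                label_b=str(comp["b"]),
                convention=opts.get("fc_convention", "B_over_A"),
            )
            path = outdir / f"differential_{name}.csv"
            out = table.table.copy()
            out["neg_log10_p"] = [
                float("nan") if p != p else (300.0 if p == 0 else -math.log10(p))
                for p in out["p_value"]
            ]
            out.to_csv(path)
            manifest[f"differential_{name}"] = path

            summary = summarize_counts(table, detected_total=len(table.table))
            tally = subclass_composition(table)
            spath = outdir / f"summary_{name}.json"
            spath.write_text(
                json.dumps(
                    {
                        "comparison": name,
                        "thresholds": [table.p_threshold, table.fc_threshold],
                        "convention": table.convention,
                        **dataclasses.asdict(summary),
                        "class_counts": tally.class_counts,
                        "charge_counts": tally.charge_counts,
                    },
                    indent=2,
                )
            )
            manifest[f"summary_{name}"] = spath

            sig = list(table.significant.index)
            if sig:
                samples = raw.select_samples(comp["a"]) + raw.select_samples(comp["b"])
                idx = membrane_indices(
                    raw, sig, samples=samples,
                    subset_description=f"differential lipids, {name}",
                )
                ipath = outdir / f"indices_{name}.json"
                ipath.write_text(json.dumps(dataclasses.asdict(idx), indent=2))
                manifest[f"indices_{name}"] = ipath

    bm = opts.get("biomarker")
    if bm:
        with _stage("biomarker", errors):
            labels = raw.sample_meta[bm["labels_field"]]
            report = rf_biomarker_mccv(
                logm,
                labels,
                panel_sizes=tuple(bm.get("panel_sizes", (5, 10, 15, 25))),
                n_rounds=bm.get("n_rounds", 100),
                seed=bm.get("seed", cfg.seed),
                panel_size=bm.get("panel_size", 15),
                n_trees=bm.get("n_trees", 500),
            )
            rpath = outdir / "biomarker_ranking.csv"
            report.ranking.to_csv(rpath, index=False)
            manifest["biomarker_ranking"] = rpath
            jpath = outdir / "biomarker_report.json"
            jpath.write_text(
                json.dumps(
                    {
                        "selected_panel": report.selected_panel,
                        "panel_size": report.panel_size,
                        "panel_auc": {
                            str(k): v for k, v in report.panel_auc.items()
                        },
                        "full_model_auc": report.full_model_auc,
                        "accuracy": report.accuracy,
                        "n_rounds": report.n_rounds,
                        "n_trees": report.n_trees,
                        "seed": report.seed,
                    },
                    indent=2,
                )
            )
            manifest["biomarker_report"] = jpath

        pls = bm.get("plsda", True)
        if pls:
            with _stage("plsda", errors):
                report = plsda(logm, raw.sample_meta[bm["labels_field"]])
                ppath = outdir / "plsda_report.json"
                ppath.write_text(
                    json.dumps(
                        {
                            "n_components": report.n_components,
                            "accuracy": report.accuracy,
                            "r2": report.r2,
                            "q2": report.q2,
                            "classes": report.classes,
                            "scores": report.scores.round(6).to_dict(orient="index"),
                        },
                        indent=2,
                    )
                )
                manifest["plsda_report"] = ppath

    prov = outdir / "provenance.json"
    prov.write_text(
        json.dumps(
            {
                "package": "lipidome",
                "version": lipidome.__version__,
                "seed": cfg.seed,
                "inputs": _hash_inputs(cfg),
                "comparisons": cfg.comparisons,
                "options": cfg.options,
                "artifacts": {k: str(v) for k, v in manifest.items()},
                "errors": errors,
            },
            indent=2,
            default=str,
        )
    )
    manifest["provenance"] = prov
    return RunResult(manifest=manifest, errors=errors)
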