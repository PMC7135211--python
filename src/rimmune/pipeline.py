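"""End-to-end orchestration: simulate -> extract -> score -> train -> evaluate.

A single YAML config drives all stages; per-stage seeds are derived
from one master seed by hashing, so a run is reproducible from a single
number.  Every stage writes plain-text artifacts (CSV/TSV/GMT/NIfTI)
and the run emits a manifest JSON with the config hash, stage seeds,
catalog census, file checksums and timings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import roc_curve

from rimmune import expression as expr_mod
from rimmune.immune import dichotomize, score_matrix
from rimmune.modeling import (
    MODEL_ROSTER,
    bootstrap632_evaluate_roster,
    evaluate_on_test,
    lda_group_means,
    preprocess_fit,
    preprocess_transform,
    select_final_model,
    _build_model,
)
from rimmune.phantoms import PhantomConfig, generate_cohort, write_cohort
from rimmune.radiomics import default_catalog, extract_table
from rimmune.radiomics.extract import write_feature_table

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "RunManifest", "run_all", "make_report", "stage_seed"]

#: demo configuration: a small paired train/test cohort with strong coupling
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "cohorts": {
        "train": {"n_samples": 60, "coupling_beta": 45.0},
        "test": {"n_samples": 40, "coupling_beta": 45.0},
    },
    "phantom": {},  # overrides shared by both cohorts (grid, spacing, noise, ...)
    "expression": {"n_genes": 2000, "genes_per_set": 20, "base_noise": 1.0, "effect_size": 2.0},
    "scoring": {"alpha": 0.25, "normalize": True},
    "targets": ["th2"],
    "extraction": {"rim_depth_mm": 2.0, "levels": 32},
    "modeling": {"B": 25, "k_neighbors": 5},
    "write_volumes": False,
}

TARGET_SET = {"th1": "Th1_cells", "th2": "Th2_cells", "ctl": "Cytotoxic_cells"}


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a stage-scoped seed (< 2^31) from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class RunManifest:
    config_hash: str
    seeds: dict
    census: dict
    files: dict  # path -> sha256
    timings_s: dict
    selected_model: dict
    out_dir: str

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base.get(k, {}), v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(config: str | Path | dict | None) -> dict:
    if config is None:
        return json.loads(json.dumps(DEFAULT_CONFIG))
    if isinstance(config, dict):
        return _merge(DEFAULT_CONFIG, config)
    with open(config) as fh:
        return _merge(DEFAULT_CONFIG, yaml.safe_load(fh) or {})


def run_all(config: str | Path | dict | None, out_dir: str | Path) -> RunManifest:
    """Execute the full pipeline and write the run manifest.

    Stages run in order with stage-scoped seeds; any stage error aborts
    with the stage name (and sample id where applicable) in the message.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_text = json.dumps(cfg, sort_keys=True)
    seeds = {s: stage_seed(int(cfg["seed"]), s) for s in
             ("simulate", "expression", "extract", "score", "train")}
    catalog = default_catalog()
    files: dict[str, str] = {}
    timings: dict[str, float] = {}

    def _register(path: Path) -> None:
        files[str(path.relative_to(out))] = _sha256(path)

    # ---- simulate -------------------------------------------------------
    t0 = time.time()
    cohorts: dict[str, dict] = {}
    try:
        for name, cdef in cfg["cohorts"].items():
            pconf_kwargs = _merge(cfg.get("phantom", {}), {k: v for k, v in cdef.items()})
            pconf_kwargs.setdefault("seed", seeds["simulate"] + (0 if name == "train" else 1))
            for key in ("grid_shape", "spacing_mm"):
                if key in pconf_kwargs:
                    pconf_kwargs[key] = tuple(pconf_kwargs[key])
            pconf = PhantomConfig(**pconf_kwargs)
            states, rois = generate_cohort(pconf)
            cohorts[name] = {"config": pconf, "states": states, "rois": rois}
            if cfg.get("write_volumes"):
                manifest = write_cohort(out / f"cohort_{name}", states, rois)
                _register(manifest)
            latents = pd.DataFrame(
                [(s.sample_id, s.th1_level, s.th2_level, s.ctl_level) for s in states],
                columns=["sample_id", "th1_level", "th2_level", "ctl_level"],
            ).set_index("sample_id")
            path = out / f"latents_{name}.csv"
            latents.to_csv(path)
            _register(path)
            cohorts[name]["latents"] = latents
    except Exception as e:
        raise RuntimeError(f"stage 'simulate' failed: {e}") from e
    timings["simulate"] = time.time() - t0

    # ---- expression -----------------------------------------------------
    t0 = time.time()
    try:
        ecfg = cfg["expression"]
        gene_sets = expr_mod.make_immune_gene_sets(
            n_genes=ecfg["n_genes"], genes_per_set=ecfg["genes_per_set"], seed=seeds["expression"]
        )
        gmt_path = out / "immune_sets.gmt"
        expr_mod.write_gmt(gene_sets, gmt_path)
        _register(gmt_path)
        for i, (name, c) in enumerate(cohorts.items()):
            mat = expr_mod.generate_expression(
                c["states"],
                gene_sets,
                base_noise=ecfg["base_noise"],
                effect_size=ecfg["effect_size"],
                n_genes=ecfg["n_genes"],
                seed=seeds["expression"] + 1 + i,
            )
            path = out / f"expression_{name}.tsv"
            expr_mod.write_expression_tsv(mat, path)
            _register(path)
            c["expression"] = mat
    except Exception as e:
        raise RuntimeError(f"stage 'expression' failed: {e}") from e
    timings["expression"] = time.time() - t0

    # ---- extract --------------------------------------------------------
    t0 = time.time()
    xcfg = cfg["extraction"]
    for name, c in cohorts.items():
        try:
            rois = {s.sample_id: r for s, r in zip(c["states"], c["rois"])}
            table = extract_table(
                rois,
                catalog=catalog,
                seed=seeds["extract"],
                rim_depth_mm=xcfg["rim_depth_mm"],
                levels=xcfg["levels"],
            )
        except Exception as e:
            raise RuntimeError(f"stage 'extract' failed on cohort {name!r}: {e}") from e
        path = out / f"features_{name}.csv"
        write_feature_table(table, path, catalog=catalog, seed=seeds["extract"])
        _register(path)
        _register(path.with_suffix(".json"))
        c["features"] = table
    timings["extract"] = time.time() - t0

    # ---- score ----------------------------------------------------------
    t0 = time.time()
    scfg = cfg["scoring"]
    try:
        for name, c in cohorts.items():
            scores = score_matrix(
                c["expression"], gene_sets, alpha=scfg["alpha"], normalize=scfg["normalize"]
            )
            path = out / f"ssgsea_{name}.csv"
            scores.to_csv(path, index_label="sample_id")
            _register(path)
            c["scores"] = scores
            c["labels"] = {}
            label_rows = []
            for target in cfg["targets"]:
                lab = dichotomize(scores[TARGET_SET[target]], cohort_id=name, target=target)
                c["labels"][target] = lab
                for sid, lv in lab.labels.items():
                    label_rows.append((sid, target, lv, lab.cutoff, name))
            path = out / f"labels_{name}.csv"
            pd.DataFrame(
                label_rows, columns=["sample_id", "target", "label", "cutoff", "cohort"]
            ).to_csv(path, index=False)
            _register(path)
    except Exception as e:
        raise RuntimeError(f"stage 'score' failed: {e}") from e
    timings["score"] = time.time() - t0

    # ---- train + evaluate ----------------------------------------------
    t0 = time.time()
    mcfg = cfg["modeling"]
    train = cohorts["train"]
    test = cohorts.get("test")
    selected_info: dict = {}
    try:
        for target in cfg["targets"]:
            y_tr = train["labels"][target].binary.loc[train["features"].index].to_numpy()
            estimates = bootstrap632_evaluate_roster(
                MODEL_ROSTER,
                train["features"],
                y_tr,
                B=mcfg["B"],
                seed=seeds["train"],
                k_neighbors=mcfg["k_neighbors"],
            )
            rows = sorted(estimates.values(), key=lambda e: -e.auc)
            df = pd.DataFrame(
                [
                    {
                        "AUC": e.auc, "Sens": e.sens, "Spec": e.spec,
                        "AUCSD": e.auc_sd, "SensSD": e.sens_sd, "SpecSD": e.spec_sd,
                        "Model": e.model,
                    }
                    for e in rows
                ]
            )
            path = out / f"training_{target}.csv"
            df.to_csv(path, index=False)
            _register(path)

            final = select_final_model(list(estimates.values()))
            selected_info[target] = {
                "model": final.name,
                "train_auc_632": estimates[final.name].auc,
            }

            if test is not None:
                y_te = test["labels"][target].binary.loc[test["features"].index].to_numpy()
                res = evaluate_on_test(
                    final, train["features"], y_tr, test["features"], y_te,
                    seed=seeds["train"], k_neighbors=mcfg["k_neighbors"],
                )
                selected_info[target].update({"test_" + k: v for k, v in res.items()})
                path = out / f"test_{target}.csv"
                pd.DataFrame(
                    [{"Model": final.name, "AUC": res["auc"], "p_value": res["p_value"]}]
                ).to_csv(path, index=False)
                _register(path)

                # ROC points of the final model on the held-out cohort
                state = preprocess_fit(train["features"], k_neighbors=mcfg["k_neighbors"])
                est = _build_model(
                    final.name, final.grid[0] if final.grid else {}, seed=seeds["train"]
                ).fit(preprocess_transform(state, train["features"]), y_tr)
                sc = est.decision_function(preprocess_transform(state, test["features"]))
                fpr, tpr, thr = roc_curve(y_te, sc)
                path = out / f"roc_{target}_{final.name}.csv"
                pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}).to_csv(path, index=False)
                _register(path)

            # standardized group means of the signature rim predictors
            predictors = [
                "skewness_total", "skewness_outer", "kurtosis_total",
                "variance_deltaS", "glcm_imc1_d1",
            ]
            report = lda_group_means(
                train["features"], y_tr, predictors, k_neighbors=mcfg["k_neighbors"]
            )
            path = out / f"group_means_{target}.csv"
            report.table.to_csv(path, index_label="group")
            _register(path)
    except Exception as e:
        raise RuntimeError(f"stage 'train' failed: {e}") from e
    timings["train"] = time.time() - t0

    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_text.encode()).hexdigest(),
        seeds=seeds,
        census=catalog.census(),
        files=files,
        timings_s={k: round(v, 3) for k, v in timings.items()},
        selected_model=selected_info,
        out_dir=str(out),
    )
    manifest.save(out / "manifest.json")
    return manifest


def make_report(manifest: RunManifest | str | Path) -> Path:
    """Render the run's tables into one human-readable markdown summary."""
    if not isinstance(manifest, RunManifest):
        payload = json.loads(Path(manifest).read_text())
        manifest = RunManifest(**payload)
    out = Path(manifest.out_dir)
    lines = ["# Pipeline run summary", ""]
    lines.append(f"- config hash: `{manifest.config_hash[:12]}`")
    lines.append(f"- catalog census: {manifest.census} (total {sum(manifest.census.values())})")
    for target, info in manifest.selected_model.items():
        lines.append(f"- target `{target}`: selected model **{info['model']}**, "
                     f"0.632-bootstrap AUC {info['train_auc_632']:.3f}"
                     + (f", test AUC {info['test_auc']:.3f} (p={info['test_p_value']:.4f})"
                        if "test_auc" in info else ""))
    lines.append("")
    for name in sorted(manifest.files):
        if name.startswith(("training_", "test_", "group_means_")) and name.endswith(".csv"):
            lines.append(f"## {name}")
            lines.append("")
            lines.append(Path(out / name).read_text().strip())
            lines.append("")
    path = out / "summary.md"
    path.write_text("\n".join(lines))
    return path
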