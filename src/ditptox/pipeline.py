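"""Config-driven workflow tying the stages together.

A run directory is populated stage by stage — dataset summary, feature
block manifest, CV results table, external-validation table (with a
consensus row), AD coverage table, alert report and a machine-readable
run manifest (config hash + seed + package versions). Every stage writes
plain CSV/JSON artifacts and can re-read the previous stage's output from
disk, so partial reruns work; ``run_pipeline`` executes them all in order.
Identical config + seed reproduces byte-identical outputs.
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

from . import dataset_io, featurization, model_grid
from .applicability_domain import ad_coverage, fit_ad
from .evaluation import auc_score, classification_metrics, confusion_from_predictions
from .featurization import FeatureBlock, combine_blocks, load_feature_table
from .preprocessing import apply_preprocessor, fit_preprocessor
from .structural_alerts import mine_alerts
from .synthetic_data import SyntheticSpec, generate_feature_dataset

logger = logging.getLogger("ditptox")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(ValueError):
    pass


@dataclass
class RunConfig:
    """Everything a run needs; see the README for a worked example.

    ``synthetic`` (SyntheticSpec kwargs) and ``dataset`` (CSV path) are
    mutually exclusive inputs. ``blocks`` lists feature blocks to compute
    or import for real datasets, e.g.
    ``{"name": "PubChem", "source": "fingerprint", "family": "PubChem"}``,
    ``{"name": "RDMD", "source": "descriptors", "set_name": "RDMD"}``,
    ``{"name": "KRFP", "source": "file", "path": ..., "kind": "binary"}``.
    """

    output_dir: str = "ditptox_run"
    seed: int = 0
    dataset: str | None = None
    column_map: dict | None = None
    synthetic: dict | None = None
    blocks: list = field(default_factory=list)
    split: dict = field(default_factory=lambda: {"train_fraction": 0.8})
    grid: dict = field(default_factory=dict)
    top_n: int = 5
    smote: bool = True
    ad: dict = field(default_factory=lambda: {"percentile": 0.95, "method": "nn"})
    alerts: dict = field(default_factory=lambda: {"min_occurrences": 7})

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)

    def validate(self) -> None:
        if (self.dataset is None) == (self.synthetic is None):
            raise PipelineError("exactly one of 'dataset' or 'synthetic' required")
        known = (
            {"FRAG", "DESC"} if self.synthetic is not None
            else {b["name"] for b in self.blocks}
        )
        for rep in self.grid.get("representations", []):
            unknown = [n for n in rep if n not in known]
            if unknown:
                raise PipelineError(
                    f"unknown block name(s) {unknown} in representation {rep}"
                )
        alert_block = self.alerts.get("block")
        if alert_block is not None and alert_block not in known:
            raise PipelineError(f"unknown alert block {alert_block!r}")

    def content_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


# --------------------------------------------------------------------------
# artifact helpers
# --------------------------------------------------------------------------


def _write_block(block: FeatureBlock, outdir: Path) -> dict:
    path = outdir / "blocks" / f"{block.name}.csv"
    path.parent.mkdir(parents=True, exist_ok=True)
    block.to_csv(path)
    return {"name": block.name, "kind": block.kind, "d": block.n_features,
            "path": str(path.relative_to(outdir))}


def load_blocks(outdir) -> dict[str, FeatureBlock]:
    """Re-read the feature blocks a previous stage wrote to disk."""
    outdir = Path(outdir)
    manifest = json.loads((outdir / "feature_manifest.json").read_text())
    blocks = {}
    for entry in manifest["blocks"]:
        blocks[entry["name"]] = load_feature_table(
            outdir / entry["path"], entry["kind"], entry["name"]
        )
    return blocks


def _split_dataset(cfg: RunConfig, ds: dataset_io.LabeledDataset):
    split = dict(cfg.split)
    pcc = split.get("per_class_counts")
    if pcc is not None:
        pcc = {int(k): v for k, v in pcc.items()}
    return dataset_io.stratified_split(
        ds,
        train_fraction=split.get("train_fraction", 0.8),
        seed=split.get("seed", cfg.seed),
        per_class_counts=pcc,
    )


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------


def stage_data(cfg: RunConfig, outdir: Path):
    """Load or simulate the dataset and materialize every feature block."""
    blocks: dict[str, FeatureBlock] = {}
    ground_truth = None
    if cfg.synthetic is not None:
        spec = SyntheticSpec(**{**cfg.synthetic, "seed": cfg.synthetic.get("seed", cfg.seed)})
        ds, frag, desc, ground_truth = generate_feature_dataset(spec)
        blocks = {"FRAG": frag, "DESC": desc}
        dataset_io.write_dataset(ds, outdir / "dataset.csv")
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(
                {k: v for k, v in ground_truth.items() if k != "true_labels"},
                fh, indent=2,
            )
        summary = dataset_io.dataset_summary(ds, compute_properties=False)
    else:
        ds = dataset_io.read_dataset(cfg.dataset, column_map=cfg.column_map)
        if ds.rejected:
            logger.warning("rejected %d rows with unparseable SMILES", len(ds.rejected))
        for bspec in cfg.blocks:
            source = bspec.get("source", "fingerprint")
            name = bspec["name"]
            if source == "fingerprint":
                blk = featurization.compute_fingerprint(
                    ds, bspec.get("family", name),
                    **{k: v for k, v in bspec.items()
                       if k not in ("name", "source", "family")},
                )
            elif source == "descriptors":
                blk = featurization.compute_descriptors(
                    ds, bspec.get("set_name", name),
                    drop_proprietary=bspec.get("drop_proprietary", False),
                )
            elif source == "file":
                blk = load_feature_table(
                    bspec["path"], bspec.get("kind", "binary"), name,
                    row_ids=ds.ids,
                )
            elif source == "smarts":
                blk = featurization.smarts_catalog_block(
                    ds, bspec["patterns"], name
                )
            else:
                raise PipelineError(f"unknown block source {source!r}")
            blk.name = name
            blocks[name] = blk
        summary = dataset_io.dataset_summary(ds)

    dataset_io.summary_to_json(summary, outdir / "dataset_summary.json")
    manifest = {"blocks": [_write_block(b, outdir) for b in blocks.values()]}
    (outdir / "feature_manifest.json").write_text(json.dumps(manifest, indent=2))
    return ds, blocks, ground_truth


def stage_train(cfg: RunConfig, outdir: Path, ds, blocks):
    """Split, run the CV grid on the training set, rank, save finalists."""
    train_ds, ext_ds = _split_dataset(cfg, ds)
    (outdir / "split.json").write_text(
        json.dumps({"train_ids": train_ds.ids, "external_ids": ext_ds.ids}, indent=2)
    )
    train_blocks = {n: b.reorder(train_ds.ids) for n, b in blocks.items()}

    grid_cfg = dict(cfg.grid)
    grid_cfg.setdefault("seed", cfg.seed)
    if "representations" not in grid_cfg:
        grid_cfg["blocks"] = train_blocks
    candidates = model_grid.build_grid(grid_cfg)
    folds = cfg.grid.get("folds", 5)
    repeats = cfg.grid.get("repeats", 10)

    results = []
    for spec, combo in candidates:
        results.append(
            model_grid.run_repeated_cv(
                train_ds.labels, train_blocks, combo, spec,
                folds=folds, repeats=repeats, seed=cfg.seed, smote=cfg.smote,
            )
        )
    rows = [r.summary() for r in results]
    pd.DataFrame(rows).to_csv(outdir / "cv_results.csv", index=False)

    top = model_grid.select_top(results, n=cfg.top_n)
    (outdir / "selected_models.json").write_text(
        json.dumps(
            [
                {
                    "algorithm": r.spec.algorithm,
                    "params": r.spec.params,
                    "combo": list(r.feature_combo),
                    "AUC_mean": r.mean("AUC"),
                }
                for r in top
            ],
            indent=2,
        )
    )
    return train_ds, ext_ds, results, top


def _external_row(label, y_true, scores, y_pred) -> dict:
    cm = confusion_from_predictions(y_true, y_pred)
    ms = classification_metrics(cm)
    r = ms.rounded()
    return {
        "model": label,
        "SE_pct": r["SE_pct"], "SP_pct": r["SP_pct"], "ACC_pct": r["ACC_pct"],
        "MCC": r["MCC"], "AUC": round(auc_score(y_true, scores), 3),
    }


def stage_validate(cfg: RunConfig, outdir: Path, train_ds, ext_ds, blocks, top):
    """External validation of the finalists plus the consensus average."""
    train_blocks = {n: b.reorder(train_ds.ids) for n, b in blocks.items()}
    ext_blocks = {n: b.reorder(ext_ds.ids) for n, b in blocks.items()}
    rows, score_vectors = [], []
    for r in top:
        scores, preds = model_grid.fit_and_predict_external(
            train_ds.labels, train_blocks, ext_blocks, r.feature_combo, r.spec,
            smote=cfg.smote,
        )
        score_vectors.append(scores)
        rows.append(_external_row(r.label, ext_ds.labels, scores, preds))
    if len(score_vectors) >= 2:
        cscores, cpreds = model_grid.consensus_predict(score_vectors)
        rows.append(_external_row("consensus", ext_ds.labels, cscores, cpreds))
    pd.DataFrame(rows).to_csv(outdir / "external_validation.csv", index=False)
    return rows, score_vectors


def stage_ad(cfg: RunConfig, outdir: Path, train_ds, ext_ds, blocks, top):
    """AD of the best model's feature space; coverage of both sets."""
    combo = top[0].feature_combo
    train_block = combine_blocks([blocks[n].reorder(train_ds.ids) for n in combo])
    ext_block = combine_blocks([blocks[n].reorder(ext_ds.ids) for n in combo])
    state = fit_preprocessor(train_block)
    X_train = apply_preprocessor(state, train_block).matrix
    X_ext = apply_preprocessor(state, ext_block).matrix
    model = fit_ad(
        X_train,
        percentile=cfg.ad.get("percentile", 0.95),
        method=cfg.ad.get("method", "nn"),
    )
    rows = []
    for set_name, X, y in (
        ("training", X_train, train_ds.labels),
        ("external", X_ext, ext_ds.labels),
    ):
        rep = ad_coverage(model, X, labels=y)
        rows.append(
            {
                "set": set_name,
                "inside_pos": rep["per_class"]["inside_pos"],
                "inside_neg": rep["per_class"]["inside_neg"],
                "outside_pos": rep["per_class"]["outside_pos"],
                "outside_neg": rep["per_class"]["outside_neg"],
                "coverage_pct": rep["coverage_pct"],
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "ad_coverage.csv", index=False)
    return rows


def stage_alerts(cfg: RunConfig, outdir: Path, ds, blocks):
    """Mine structural alerts on the configured binary block (full dataset
    by default; 'training_only' restricts to the training rows)."""
    acfg = dict(cfg.alerts)
    name = acfg.get("block")
    if name is None:
        binaries = [n for n, b in blocks.items() if b.kind == "binary"]
        if not binaries:
            return None
        name = binaries[0]
    block = blocks[name].reorder(ds.ids)
    labels = ds.labels
    if acfg.get("training_only"):
        train_ids = set(
            json.loads((outdir / "split.json").read_text())["train_ids"]
        )
        keep = [i for i, rid in enumerate(ds.ids) if rid in train_ids]
        block = block.subset_rows(keep)
        labels = labels[keep]
    report = mine_alerts(
        block, labels,
        min_occurrences=acfg.get("min_occurrences", 7),
        top_n=acfg.get("top_n"),
    )
    report.to_csv(outdir / "alerts.csv")
    return report


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute every stage and return the populated run directory."""
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    timings = {}

    ds, blocks, _ = stage_data(cfg, outdir)
    timings["data"] = round(time.time() - t0, 2)

    t = time.time()
    train_ds, ext_ds, results, top = stage_train(cfg, outdir, ds, blocks)
    timings["train"] = round(time.time() - t, 2)

    t = time.time()
    stage_validate(cfg, outdir, train_ds, ext_ds, blocks, top)
    timings["validate"] = round(time.time() - t, 2)

    t = time.time()
    stage_ad(cfg, outdir, train_ds, ext_ds, blocks, top)
    timings["ad"] = round(time.time() - t, 2)

    t = time.time()
    stage_alerts(cfg, outdir, ds, blocks)
    timings["alerts"] = round(time.time() - t, 2)

    import rdkit
    import sklearn

    manifest = {
        "config": asdict(cfg),
        "config_hash": cfg.content_hash(),
        "seed": cfg.seed,
        "versions": {
            "ditptox": _version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
            "rdkit": rdkit.__version__,
        },
        "timings_s": timings,
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def _version() -> str:
    from . import __version__

    return __version__
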