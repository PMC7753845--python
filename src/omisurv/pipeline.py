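"""End-to-end orchestration: simulate/ingest -> preprocess -> autoencode ->
screen -> cluster -> evaluate -> cross-validated classification, with every
intermediate persisted and a JSON run report.

All randomness derives from one global seed by stage-keyed seed-sequence
spawning, so a rerun of the same config is byte-identical (timestamps
aside).  Log-rank p-values across the 10 CV combinations are aggregated by
geometric mean.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import autoencoder as ae
from .classify import (
    DEFAULT_TOP_N,
    anova_rank,
    fit_label_classifier,
    harmonize_external,
    make_cv_partitions,
    predict_labels,
)
from .containers import ClinicalTable, OmicsMatrix, RiskLabels, StackedMatrix
from .metrics import evaluate_labels
from .preprocess import preprocess_block, stack_unit_norm
from .subtype import assign_risk_groups, choose_k, cox_screen
from .synthetic import SyntheticConfig, generate_cohort

logger = logging.getLogger(__name__)

_STAGE_KEYS = ("simulate", "autoencoder", "cluster", "cv", "classify")


@dataclass
class RunConfig:
    """Configuration for one full pipeline run."""

    outdir: str = "omisurv_run"
    synthetic: SyntheticConfig | None = None
    rna_path: str | None = None
    mirna_path: str | None = None
    methylation_path: str | None = None
    clinical_path: str | None = None
    autoencoder: ae.AutoencoderConfig | None = None
    screen_alpha: float = 0.05
    k_range: tuple[int, int] = (2, 6)
    n_folds: int = 5
    train_folds: int = 3
    top_n: dict = field(default_factory=lambda: dict(DEFAULT_TOP_N))
    seed: int = 0
    run_cv_classification: bool = True
    single_omics_ablation: bool = False

    def stage_seed(self, stage: str) -> int:
        idx = _STAGE_KEYS.index(stage)
        ss = np.random.SeedSequence(self.seed).spawn(len(_STAGE_KEYS))[idx]
        return int(ss.generate_state(1)[0] % (2**31 - 1))


def _load_inputs(cfg: RunConfig):
    if cfg.synthetic is not None:
        syn = cfg.synthetic
        blocks, clinical, truth = generate_cohort(syn)
        return blocks, clinical, truth
    missing = [n for n, p in (("rna", cfg.rna_path), ("mirna", cfg.mirna_path),
                              ("methylation", cfg.methylation_path),
                              ("clinical", cfg.clinical_path)) if p is None]
    if missing:
        raise ValueError(f"config is missing input paths for: {', '.join(missing)}")
    blocks = {
        "rna": OmicsMatrix.from_tsv(cfg.rna_path, "rna"),
        "mirna": OmicsMatrix.from_tsv(cfg.mirna_path, "mirna"),
        "methylation": OmicsMatrix.from_tsv(cfg.methylation_path, "methylation"),
    }
    clinical = ClinicalTable.from_tsv(cfg.clinical_path)
    return blocks, clinical, None


def _geo_mean(values: list[float]) -> float:
    arr = np.asarray(values, dtype=float)
    arr = np.clip(arr, 1e-300, None)
    return float(np.exp(np.mean(np.log(arr))))


def _cv_classification(
    blocks: dict[str, OmicsMatrix],
    clinical: ClinicalTable,
    labels: RiskLabels,
    cfg: RunConfig,
    use_blocks: list[str],
) -> dict:
    """ANOVA top-N + SVM label transfer over all train/test fold combinations."""
    part = make_cv_partitions(
        clinical.sample_ids, n_folds=cfg.n_folds, train_folds=cfg.train_folds,
        seed=cfg.stage_seed("cv"),
    )
    per_combo = []
    for idx in range(len(part.combinations)):
        train_ids, test_ids = part.split(idx)
        train_labels = labels.subset(train_ids)
        feats = {}
        for name in use_blocks:
            block = blocks[name]
            ranking = anova_rank(
                block.values.loc[train_ids], train_labels,
                top_n=cfg.top_n[name], log_transform=(name in ("rna", "mirna")),
            )
            feats[name] = ranking.top_features
        cols = [c for name in use_blocks for c in feats[name]]
        all_vals = pd.concat([blocks[n].values for n in use_blocks], axis=1)
        if all_vals.columns.has_duplicates:
            raise ValueError("feature IDs collide across blocks")
        Xtr = all_vals.loc[train_ids, cols]
        Xte = all_vals.loc[test_ids, cols]
        model = fit_label_classifier(Xtr, train_labels, seed=cfg.stage_seed("classify"))
        combo = {"combination": idx, "n_train": len(train_ids), "n_test": len(test_ids)}
        for split, ids, X in (("train", train_ids, Xtr), ("test", test_ids, Xte)):
            pred = predict_labels(model, X)
            clin = clinical.subset(ids)
            if pred.n_groups == 2:
                combo[split] = evaluate_labels(clin, pred).to_dict()
            else:
                combo[split] = {"error": "single predicted class"}
        per_combo.append(combo)
    summary = {}
    for split in ("train", "test"):
        ok = [c[split] for c in per_combo if "error" not in c[split]]
        if ok:
            summary[split] = {
                "logrank_p_geomean": _geo_mean([r["logrank_p"] for r in ok]),
                "c_index_mean": float(np.mean([r["c_index"] for r in ok])),
                "c_index_sd": float(np.std([r["c_index"] for r in ok])),
                "brier_mean": float(np.mean([r["brier"] for r in ok])),
                "n_evaluable": len(ok),
            }
    return {"combinations": per_combo, "summary": summary}


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute the whole pipeline and return (and persist) the run report."""
    cfg = config
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "stages": []}

    def stage(name: str):
        logger.info("pipeline stage: %s", name)
        report["stages"].append(name)

    try:
        stage("ingest")
        blocks, clinical, truth = _load_inputs(cfg)
        for name, b in blocks.items():
            b.to_tsv(outdir / f"raw_{name}.tsv")
        clinical.to_tsv(outdir / "clinical.tsv")
        if truth is not None:
            truth.to_tsv(outdir / "ground_truth.tsv")

        stage("preprocess")
        clean = {name: preprocess_block(b) for name, b in blocks.items()}
        stacked = stack_unit_norm([clean["rna"], clean["mirna"], clean["methylation"]])
        common = stacked.sample_ids
        clinical = clinical.subset(common)
        stacked.to_tsv(outdir / "stacked.tsv")
        report["n_samples"] = int(stacked.n_samples)
        report["n_stacked_features"] = int(stacked.n_features)

        stage("train_autoencoder")
        ae_cfg = cfg.autoencoder or ae.AutoencoderConfig(seed=cfg.stage_seed("autoencoder"))
        model = ae.train(stacked, ae_cfg)
        model.save(outdir / "autoencoder.pkl")
        report["loss_trace"] = model.loss_trace

        stage("transform")
        latent = ae.transform(model, stacked)
        latent.to_csv(outdir / "latent.tsv", sep="\t", index_label="sample_id")
        report["n_latent_features"] = int(latent.shape[1])

        stage("cox_screen")
        screen = cox_screen(latent, clinical, alpha=cfg.screen_alpha)
        screen.to_tsv(outdir / "screen.tsv")
        report["n_selected_features"] = screen.n_selected
        if screen.n_selected == 0:
            raise ValueError("Cox screen selected no latent features")
        selected = latent[screen.selected_features]

        stage("cluster")
        k, k_table = choose_k(
            selected, k_range=range(cfg.k_range[0], cfg.k_range[1] + 1),
            seed=cfg.stage_seed("cluster"),
        )
        labels = assign_risk_groups(selected, clinical, k=k, seed=cfg.stage_seed("cluster"))
        labels.to_tsv(outdir / "labels.tsv")
        report["chosen_k"] = int(k)
        report["k_selection"] = k_table.to_dict(orient="index")

        stage("evaluate")
        if labels.n_groups == 2:
            report["full_cohort"] = evaluate_labels(clinical, labels).to_dict()
        if truth is not None:
            from sklearn.metrics import adjusted_rand_score

            report["ari_vs_truth"] = float(
                adjusted_rand_score(
                    truth.true_group.loc[common].to_numpy(),
                    labels.labels.loc[common].to_numpy(),
                )
            )

        if cfg.run_cv_classification and labels.n_groups == 2:
            stage("cv_classification")
            report["cv"] = _cv_classification(
                clean, clinical, labels, cfg, ["rna", "mirna", "methylation"]
            )
            if cfg.single_omics_ablation:
                stage("single_omics_ablation")
                report["ablation"] = {
                    name: _cv_classification(clean, clinical, labels, cfg, [name])
                    for name in ("rna", "mirna", "methylation")
                }
    except Exception as err:
        failed_at = report["stages"][-1] if report["stages"] else "setup"
        report["failed_stage"] = failed_at
        report["error"] = str(err)
        (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
        raise RuntimeError(f"pipeline failed at stage {failed_at!r}: {err}") from err

    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
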