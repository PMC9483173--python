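"""End-to-end orchestration: training pipeline and batch/single prediction.

``run_training_pipeline`` executes the full chain
curate -> descriptors -> split -> select -> (SMOTE) -> tune/train -> AD ->
evaluate, writing model bundles, a metrics table, and a reproducibility
manifest.  ``predict`` loads bundles and produces the per-compound report:
one column per member model, the consensus call (which may abstain), the
mean probability score, and the applicability-domain flag.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from hergml import curation
from hergml.applicability_domain import fit_ad, in_domain_mask
from hergml.balancing import smote
from hergml.descriptors import DescriptorMatrix, compute_descriptors, normalize, prune_descriptors
from hergml.evaluation import ABSTAIN, metric_report
from hergml.feature_selection import select_features
from hergml.modeling import (
    ConsensusModel,
    TrainedModelBundle,
    consensus_predict,
    predict_labels,
    predict_proba,
    tune_and_train,
)
from hergml.splitting import maxmin_split

logger = logging.getLogger(__name__)

DEFAULT_ALGORITHMS = [
    {"algorithm": "BRF", "smote": False},
    {"algorithm": "KNN", "smote": True},
    {"algorithm": "SVM", "smote": True},
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineResult:
    out_dir: Path
    bundles: list[TrainedModelBundle]
    consensus: Optional[ConsensusModel]
    metrics: pd.DataFrame
    selection: object
    manifest: dict


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_training_pipeline(config: dict, out_dir) -> PipelineResult:
    """Execute the training workflow described by ``config``.

    Required keys: ``input_table`` (activity export path) or ``records``
    (in-memory list), ``threshold`` (5 or 6), ``seed``.  Optional:
    ``algorithms`` (list of {algorithm, smote}), ``fraction`` (default 0.8),
    ``column_map``, ``selection`` (kwargs for the feature selector),
    ``search_spaces``, ``consensus_size`` (default 2).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    threshold = int(config["threshold"])
    seed = int(config.get("seed", 0))
    rng = np.random.default_rng(seed)
    stage_seeds = {s: int(rng.integers(2**31 - 1))
                   for s in ("split", "select", "smote", "train")}
    label_col = f"label_t{threshold}"

    # -- curate ------------------------------------------------------------
    stage = "curate"
    try:
        if "records" in config:
            records = config["records"]
        else:
            records, _ = curation.read_activity_table(
                config["input_table"], column_map=config.get("column_map")
            )
        compounds, rejection_log = curation.curate(records)
        curated = curation.compounds_to_frame(compounds)
        curated.to_csv(out / "curated.csv", index=False)
        rejection_log.to_csv(out / "rejections.csv", index=False)
        logger.info("curate: %d compounds, %d rejections", len(curated), len(rejection_log))
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- descriptors -------------------------------------------------------
    stage = "descriptors"
    try:
        matrix, dropped = compute_descriptors(curated["canonical_smiles"].tolist())
        pruned, removed = prune_descriptors(matrix)
        labels = curated.set_index("canonical_smiles")[label_col]
        labels = labels.loc[pruned.compound_ids]
        logger.info("descriptors: %d kept of %d (%d compounds dropped)",
                    len(pruned.descriptor_names), len(matrix.descriptor_names), len(dropped))
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- split -------------------------------------------------------------
    stage = "split"
    try:
        split = maxmin_split(
            pruned.compound_ids, labels.tolist(),
            fraction=float(config.get("fraction", 0.8)),
        )
        pd.DataFrame(
            {"compound_id": split.train_ids + split.valid_ids,
             "subset": ["TS"] * len(split.train_ids) + ["VS"] * len(split.valid_ids)}
        ).to_csv(out / "split.csv", index=False)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- normalize + select (training set only) ----------------------------
    stage = "select"
    try:
        ts = pruned.take_rows(split.train_ids)
        vs = pruned.take_rows(split.valid_ids)
        ts_norm = normalize(ts)
        vs_norm = normalize(vs, stats=ts_norm.norm_stats)
        y_ts = labels.loc[split.train_ids].to_numpy()
        y_vs = labels.loc[split.valid_ids].to_numpy()
        selection = select_features(
            ts_norm.values, y_ts, ts_norm.descriptor_names,
            seed=stage_seeds["select"], **config.get("selection", {}),
        )
        features = selection.prediction_kept
        (out / "selection.json").write_text(json.dumps({
            "ranked": selection.ranked_features,
            "threshold_kept": selection.threshold_kept,
            "interpretation_kept": selection.interpretation_kept,
            "prediction_kept": selection.prediction_kept,
        }, indent=2))
        logger.info("select: %d features kept", len(features))
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- train + AD + evaluate ---------------------------------------------
    stage = "train"
    bundles: list[TrainedModelBundle] = []
    metric_rows: list[dict] = []
    try:
        ts_sel = ts_norm.subset(features)
        vs_sel = vs_norm.subset(features)
        ad = fit_ad(ts_sel.values)  # real (pre-SMOTE) training rows only
        vs_in = in_domain_mask(ad, vs_sel.values)
        for spec_entry in config.get("algorithms", DEFAULT_ALGORITHMS):
            algo = spec_entry["algorithm"]
            use_smote = bool(spec_entry.get("smote", False))
            X_fit, y_fit = ts_sel.values, y_ts
            if use_smote:
                aug = smote(X_fit, y_fit, seed=stage_seeds["smote"])
                X_fit, y_fit = aug.X, aug.y
            bundle = tune_and_train(
                algo, X_fit, y_fit,
                search_space=(config.get("search_spaces") or {}).get(algo),
                budget=config.get("budget"),
                seed=stage_seeds["train"],
                threshold=threshold,
                selected_features=features,
                norm_stats=ts_norm.norm_stats.loc[features],
                smote_used=use_smote,
            )
            bundle.ad = ad
            name = ("S" if use_smote else "") + algo
            bundle.save(out / "bundles" / name)
            bundles.append(bundle)
            rep = metric_report(
                list(y_vs[vs_in]),
                list(predict_labels(bundle, vs_sel.values[vs_in])),
                scores=predict_proba(bundle, vs_sel.values[vs_in]),
                n_out_of_domain=int((~vs_in).sum()),
            )
            metric_rows.append({"model": name, "dataset": "VS", **rep.as_row()})
            logger.info("train %s: VS BA=%.3f", name, rep.BA)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- consensus ----------------------------------------------------------
    stage = "consensus"
    consensus = None
    try:
        if len(bundles) >= 2:
            ranked = sorted(
                zip(bundles, metric_rows),
                key=lambda br: (br[1]["BA"], br[1]["AUC"]),
                reverse=True,
            )
            k = int(config.get("consensus_size", 2))
            members = [b for b, _ in ranked[:k]]
            consensus = ConsensusModel(members=members)
            labels_c, scores_c = consensus_predict(
                consensus, [vs_sel.values[vs_in]] * len(members)
            )
            keep = labels_c != ABSTAIN
            rep = metric_report(
                list(np.asarray(y_vs[vs_in])[keep]),
                list(labels_c[keep]),
                scores=scores_c[keep],
                n_abstained=int((~keep).sum()),
                n_out_of_domain=int((~vs_in).sum()),
            )
            member_names = "+".join(
                ("S" if b.smote_used else "") + b.algorithm_id for b in members
            )
            metric_rows.append({"model": f"consensus({member_names})", "dataset": "VS",
                                **rep.as_row()})
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    metrics = pd.DataFrame(metric_rows)
    metrics.to_csv(out / "metrics.csv", index=False)
    manifest = {
        "config_hash": _config_hash({k: v for k, v in config.items() if k != "records"}),
        "threshold": threshold,
        "seed": seed,
        "stage_seeds": stage_seeds,
        "n_curated": int(len(curated)),
        "n_train": len(split.train_ids),
        "n_valid": len(split.valid_ids),
        "n_features_selected": len(features),
        "training_class_counts": {
            str(c): int(n) for c, n in zip(*np.unique(y_ts, return_counts=True))
        },
        "post_balance_class_counts": {
            str(c): int(n) for c, n in zip(*np.unique(y_fit, return_counts=True))
        },
        "models": [
            ("S" if b.smote_used else "") + b.algorithm_id for b in bundles
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return PipelineResult(
        out_dir=out, bundles=bundles, consensus=consensus,
        metrics=metrics, selection=selection, manifest=manifest,
    )


def predict(
    smiles: Sequence[str] | str,
    bundle_dirs: Sequence,
    descriptor_csv: Optional[str] = None,
) -> pd.DataFrame:
    """Per-compound prediction report from saved bundles.

    Accepts a single SMILES or a list.  Rows that fail standardization or
    descriptor computation are flagged (all model columns empty) but kept,
    so the report has exactly one row per input.  With ``descriptor_csv``
    given, descriptors are read from that file (compound id = input SMILES)
    instead of being computed.
    """
    single = isinstance(smiles, str)
    smiles_list = [smiles] if single else list(smiles)
    bundles = [TrainedModelBundle.load(d) for d in bundle_dirs]
    if not bundles:
        raise ValueError("at least one bundle directory required")
    threshold = bundles[0].threshold

    canonical: list[Optional[str]] = []
    flags: list[str] = []
    for smi in smiles_list:
        try:
            canonical.append(curation.standardize_structure(smi))
            flags.append("")
        except curation.StructureRejected as exc:
            canonical.append(None)
            flags.append(exc.reason)

    ok = [c for c in canonical if c is not None]
    if descriptor_csv is not None:
        matrix = DescriptorMatrix.read_csv(descriptor_csv)
    elif ok:
        matrix, dropped = compute_descriptors(ok)
        for d in dropped:
            i = canonical.index(d)
            canonical[i], flags[i] = None, "descriptor-failure"
    else:
        matrix = None

    rows = []
    member_names = [("S" if b.smote_used else "") + b.algorithm_id for b in bundles]
    consensus = ConsensusModel(members=bundles) if len(bundles) >= 2 else None
    for smi, can, flag in zip(smiles_list, canonical, flags):
        row = {"input_smiles": smi, "canonical_smiles": can, "flag": flag,
               "threshold": threshold}
        if can is None or matrix is None or can not in matrix.compound_ids:
            for n in member_names:
                row[n] = ""
            row.update({"consensus": "", "consensus_score": np.nan,
                        "applicability_domain": ""})
            rows.append(row)
            continue
        per_member_X = []
        for b in bundles:
            sub = matrix.take_rows([can]).subset(b.selected_features)
            per_member_X.append(normalize(sub, stats=b.norm_stats).values)
        calls = [predict_labels(b, X)[0] for b, X in zip(bundles, per_member_X)]
        for n, c in zip(member_names, calls):
            row[n] = c
        if consensus is not None:
            lab, score = consensus_predict(consensus, per_member_X)
            row["consensus"] = lab[0]
            row["consensus_score"] = float(score[0])
        else:
            row["consensus"] = calls[0]
            row["consensus_score"] = float(predict_proba(bundles[0], per_member_X[0])[0])
        in_ad = all(
            b.ad is None or in_domain_mask(b.ad, X)[0]
            for b, X in zip(bundles, per_member_X)
        )
        row["applicability_domain"] = bool(in_ad)
        rows.append(row)
    return pd.DataFrame(rows)
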