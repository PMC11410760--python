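"""Experiment orchestration: phantoms -> degrade -> pretext -> transfer ->
ensembles -> metrics -> significance -> explanations.

Stages run in a fixed dependency order. Each stage records, in a JSON
manifest, the hash of its effective configuration (its own parameters and
seed plus the hashes of its upstream stages) and the content hashes of its
output files. A re-run with an unchanged configuration skips completed
stages; changing one stage's parameters re-runs that stage and everything
downstream of it.

The "baseline" classifier in this pipeline is the random-initialization
variant: externally pretrained weights (the ImageNet baseline) are accepted
via ``stages.transfer.external_ckpt`` but are never downloaded.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pretextnet import clf_metrics, ensembles, phantom, pretext, scorecam, stats
from pretextnet import transfer as transfer_mod
from pretextnet.core_io import (
    GrayImage,
    RunConfig,
    get_logger,
    load_image,
    read_label_table,
    save_image,
)
from pretextnet.degrade import BlurSpec, NoiseSpec, degrade_dataset
from pretextnet.phantom import Cohort
from pretextnet.sharp_unet import Restorer, build_restorer, load_checkpoint
from pretextnet.transfer import Classifier, ClassifierTrainConfig

__all__ = ["PipelineManifest", "run_pipeline", "STAGE_ORDER", "STAGE_DEPS"]

STAGE_ORDER = (
    "phantom",
    "degrade",
    "pretext",
    "transfer",
    "ensembles",
    "metrics",
    "stats",
    "scorecam",
)
STAGE_DEPS = {
    "phantom": (),
    "degrade": ("phantom",),
    "pretext": ("degrade",),
    "transfer": ("pretext",),
    "ensembles": ("transfer",),
    "metrics": ("ensembles",),
    "stats": ("metrics",),
    "scorecam": ("transfer",),
}


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class PipelineManifest:
    stages: dict[str, dict] = field(default_factory=dict)
    executed: list[str] = field(default_factory=list)

    def save(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump({"stages": self.stages}, fh, indent=2)

    @classmethod
    def load(cls, path: Path) -> "PipelineManifest":
        if not path.exists():
            return cls()
        with open(path) as fh:
            raw = json.load(fh)
        return cls(stages=raw.get("stages", {}))


def _stage_hash(name: str, config: RunConfig, upstream_hashes: list[str]) -> str:
    payload = json.dumps(
        {
            "stage": name,
            "params": config.stage_params(name),
            "seed": config.stage_params(name).get("seed", config.stage_seed(name)),
            "image_size": list(config.image_size),
            "upstream": upstream_hashes,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()


def _load_cohort(workdir: Path) -> Cohort:
    records = read_label_table(workdir / "phantom" / "labels.csv")
    images = {
        r.image_id: load_image(workdir / "phantom" / "images" / f"{r.image_id}.png")
        for r in records
    }
    boxes: dict[str, list[tuple[int, int, int, int]]] = {}
    box_path = workdir / "phantom" / "truth_boxes.csv"
    if box_path.exists():
        for row in pd.read_csv(box_path).itertuples(index=False):
            boxes.setdefault(row.image_id, []).append(
                (row.row_min, row.col_min, row.row_max, row.col_max)
            )
    return Cohort(records, images, boxes)


def _seed(config: RunConfig, stage: str) -> int:
    return int(config.stage_params(stage).get("seed", config.stage_seed(stage)))


# ---------------------------------------------------------------------------
# stage implementations


def _run_phantom(config: RunConfig, workdir: Path) -> None:
    p = config.stage_params("phantom")
    cohort = phantom.generate_cohort(
        n=int(p.get("n", 60)),
        prevalence=float(p.get("prevalence", 0.5)),
        seed=_seed(config, "phantom"),
        size=config.image_size,
    )
    cohort = phantom.patient_split(cohort, seed=_seed(config, "phantom"))
    phantom.write_cohort(cohort, workdir / "phantom")


def _run_degrade(config: RunConfig, workdir: Path) -> None:
    cohort = _load_cohort(workdir)
    seed = _seed(config, "degrade")
    out_dir = workdir / "degrade"
    out_dir.mkdir(parents=True, exist_ok=True)
    items = sorted(cohort.images.items())
    manifest_rows = []
    for mode, spec in (
        ("noise", NoiseSpec(seed=seed)),
        ("blur", BlurSpec(seed=seed)),
    ):
        mode_dir = out_dir / mode
        mode_dir.mkdir(exist_ok=True)
        for sample in degrade_dataset(items, mode, spec):
            save_image(sample.degraded, mode_dir / f"{sample.image_id}.png")
            manifest_rows.append((sample.image_id, mode, sample.applied_parameter))
    pd.DataFrame(
        manifest_rows, columns=["image_id", "mode", "applied_parameter"]
    ).to_csv(out_dir / "manifest.csv", index=False)


def _paired_samples(workdir: Path, cohort: Cohort, mode: str, split: str):
    from pretextnet.degrade import PairedSample

    manifest = pd.read_csv(workdir / "degrade" / "manifest.csv")
    params = {
        row.image_id: row.applied_parameter
        for row in manifest[manifest["mode"] == mode].itertuples(index=False)
    }
    pairs = []
    for rec in cohort.records:
        if rec.split != split:
            continue
        degraded = load_image(workdir / "degrade" / mode / f"{rec.image_id}.png")
        pairs.append(
            PairedSample(
                degraded=degraded,
                clean=cohort.images[rec.image_id],
                applied_parameter=float(params[rec.image_id]),
                image_id=rec.image_id,
                mode=mode,
            )
        )
    return pairs


def _pretext_config(config: RunConfig) -> pretext.PretextTrainConfig:
    p = config.stage_params("pretext")
    return pretext.PretextTrainConfig(
        max_epochs=int(p.get("max_epochs", 10)),
        batch_size=int(p.get("batch_size", 8)),
        seed=_seed(config, "pretext"),
    )


def _run_pretext(config: RunConfig, workdir: Path) -> None:
    cohort = _load_cohort(workdir)
    p = config.stage_params("pretext")
    width = float(p.get("width_multiplier", 0.125))
    out_dir = workdir / "pretext"
    out_dir.mkdir(parents=True, exist_ok=True)
    tcfg = _pretext_config(config)
    for mode in ("noise", "blur"):
        train_pairs = _paired_samples(workdir, cohort, mode, "train")
        val_pairs = _paired_samples(workdir, cohort, mode, "val")
        model = build_restorer(
            config.image_size, width_multiplier=width, seed=tcfg.seed
        )
        best, history = pretext.train_pretext(model, train_pairs, val_pairs, tcfg)
        model.load_state_dict(best)
        model.save(out_dir / f"restorer_{mode}.npz")
        pd.DataFrame(
            {
                "train_loss": history.train_loss,
                "val_loss": history.val_loss,
                "lr": history.lr,
                "val_ssim": history.val_ssim,
                "val_psnr": history.val_psnr,
            }
        ).to_csv(out_dir / f"history_{mode}.csv", index=False)


def _classifier_config(config: RunConfig) -> ClassifierTrainConfig:
    p = config.stage_params("transfer")
    return ClassifierTrainConfig(
        max_epochs=int(p.get("max_epochs", 8)),
        batch_size=int(p.get("batch_size", 8)),
        seed=_seed(config, "transfer"),
    )


_INIT_BY_MODE = {"denoise": "noise", "deblur": "blur"}


def _run_transfer(config: RunConfig, workdir: Path) -> None:
    cohort = _load_cohort(workdir)
    p = config.stage_params("transfer")
    width = float(config.stage_params("pretext").get("width_multiplier", 0.125))
    out_dir = workdir / "transfer"
    out_dir.mkdir(parents=True, exist_ok=True)
    tcfg = _classifier_config(config)
    for init in ("denoise", "deblur", "baseline"):
        if init in _INIT_BY_MODE:
            restorer = Restorer.load(
                workdir / "pretext" / f"restorer_{_INIT_BY_MODE[init]}.npz"
            )
            encoder = transfer_mod.truncate_encoder(restorer)
            source = f"{init}_pretext"
        else:
            external = p.get("external_ckpt")
            if external:
                _, state = load_checkpoint(external)
                restorer = build_restorer(config.image_size, width, seed=tcfg.seed)
                restorer.load_state_dict(state)
                encoder = transfer_mod.truncate_encoder(restorer)
                source = "external_pretrained"
            else:
                encoder = transfer_mod.truncate_encoder(
                    build_restorer(config.image_size, width, seed=tcfg.seed + 1)
                )
                source = "random"
        clf = transfer_mod.build_classifier(encoder, init_source=source, seed=tcfg.seed)
        best, _ = transfer_mod.fine_tune(clf, cohort, tcfg)
        clf.load_state_dict(best)
        clf.save(out_dir / f"classifier_{init}.npz")
        for split in ("val", "test"):
            df = transfer_mod.predict_cohort(clf, cohort, split)
            df.to_csv(out_dir / f"pred_{init}_{split}.csv", index=False)


def _read_pred_set(workdir: Path, names: list[str], split: str) -> ensembles.PredictionSet:
    dfs = [
        pd.read_csv(workdir / "transfer" / f"pred_{n}_{split}.csv").sort_values(
            "image_id"
        )
        for n in names
    ]
    probs = np.stack([df[["p_normal", "p_abnormal"]].to_numpy() for df in dfs])
    logits = np.stack(
        [df[["logit_normal", "logit_abnormal"]].to_numpy() for df in dfs]
    )
    return ensembles.PredictionSet(
        model_names=names, probs=probs, logits=logits, labels=dfs[0]["label"].to_numpy()
    )


def _run_ensembles(config: RunConfig, workdir: Path) -> None:
    cohort = _load_cohort(workdir)
    out_dir = workdir / "ensembles"
    out_dir.mkdir(parents=True, exist_ok=True)
    members = ["denoise", "deblur"]
    val_set = _read_pred_set(workdir, members, "val")
    test_set = _read_pred_set(workdir, members, "test")

    sa_probs = ensembles.simple_average(test_set)
    weights = ensembles.fit_slsqp_weights(val_set)
    wa_probs = ensembles.apply_weights(test_set, weights)

    clfs = [
        Classifier.load(workdir / "transfer" / f"classifier_{m}.npz") for m in members
    ]
    af = ensembles.build_af_ensemble(clfs, seed=_seed(config, "ensembles"))
    tcfg = _classifier_config(config)
    best, _ = ensembles.train_af_ensemble(af, cohort, tcfg)
    af.load_state_dict(best)
    test_ids = sorted(r.image_id for r in cohort.records if r.split == "test")
    x_test = np.stack([cohort.images[i].pixels for i in test_ids]).astype(np.float32)
    af_probs = af.forward(x_test[:, None])

    labels = test_set.labels
    for name, probs in (("sa", sa_probs), ("slsqp", wa_probs), ("af", af_probs)):
        pd.DataFrame(
            {
                "image_id": test_ids,
                "p_normal": probs[:, 0],
                "p_abnormal": probs[:, 1],
                "label": labels,
            }
        ).to_csv(out_dir / f"pred_{name}_test.csv", index=False)
    with open(out_dir / "fusion_report.json", "w") as fh:
        json.dump(
            {
                "slsqp_weights": weights.w.tolist(),
                "af_gamma": float(af.gamma.value),
            },
            fh,
            indent=2,
        )


_MODEL_PRED_FILES = {
    "baseline": ("transfer", "pred_baseline_test.csv"),
    "den_p": ("transfer", "pred_denoise_test.csv"),
    "deb_p": ("transfer", "pred_deblur_test.csv"),
    "sa": ("ensembles", "pred_sa_test.csv"),
    "slsqp_wa": ("ensembles", "pred_slsqp_test.csv"),
    "af": ("ensembles", "pred_af_test.csv"),
}


def _metric_row(counts: clf_metrics.ConfusionCounts) -> dict:
    """Full metric row; undefined metrics become NaN instead of aborting the
    whole report (a degenerate desk-scale model must not sink the pipeline)."""
    try:
        report = clf_metrics.compute_metrics(counts)
        return {
            "balanced_accuracy": report.balanced_accuracy,
            "sensitivity": report.sensitivity,
            "specificity": report.specificity,
            "f_score": report.f_score,
            "mcc": report.mcc,
            "kappa": report.kappa,
            "youden": report.youden,
        }
    except clf_metrics.UndefinedMetricError:
        tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
        sens = tp / (tp + fn) if tp + fn else np.nan
        spec = tn / (tn + fp) if tn + fp else np.nan
        return {
            "balanced_accuracy": clf_metrics.balanced_accuracy(sens, spec),
            "sensitivity": sens,
            "specificity": spec,
            "f_score": 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else np.nan,
            "mcc": np.nan,
            "kappa": np.nan,
            "youden": clf_metrics.youden_index(sens, spec),
        }


def _run_metrics(config: RunConfig, workdir: Path) -> None:
    out_dir = workdir / "metrics"
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for model, (stage_dir, fname) in _MODEL_PRED_FILES.items():
        df = pd.read_csv(workdir / stage_dir / fname)
        counts = clf_metrics.confusion(
            df[["p_normal", "p_abnormal"]].to_numpy(), df["label"].to_numpy()
        )
        rows.append(
            {"model": model, **_metric_row(counts), "tp": counts.tp, "fp": counts.fp,
             "tn": counts.tn, "fn": counts.fn}
        )
    pd.DataFrame(rows).to_csv(out_dir / "metrics.csv", index=False)


def _run_stats(config: RunConfig, workdir: Path) -> None:
    out_dir = workdir / "stats"
    out_dir.mkdir(parents=True, exist_ok=True)
    metrics = pd.read_csv(workdir / "metrics" / "metrics.csv")
    estimates = {
        row.model: stats.estimate_sensitivity(int(row.tp), int(row.fn))
        for row in metrics.itertuples(index=False)
    }
    panel = stats.pairwise_panel(estimates)
    panel.to_csv(out_dir / "comparisons.csv", index=False)


def _run_scorecam(config: RunConfig, workdir: Path) -> None:
    cohort = _load_cohort(workdir)
    out_dir = workdir / "scorecam"
    out_dir.mkdir(parents=True, exist_ok=True)
    clf = Classifier.load(workdir / "transfer" / "classifier_denoise.npz")
    limit = int(config.stage_params("scorecam").get("max_images", 5))
    rows = []
    done = 0
    for rec in cohort.records:
        if rec.split != "test" or rec.label != 1 or done >= limit:
            continue
        amap = scorecam.score_cam(clf, cohort.images[rec.image_id], target_class=1)
        try:
            box = scorecam.map_to_bbox(amap)
        except scorecam.EmptyBoxError:
            continue
        best_iou = max(
            scorecam.box_iou(box, scorecam.BoundingBox(*tb))
            for tb in cohort.truth_boxes[rec.image_id]
        )
        save_image(GrayImage(amap.values), out_dir / f"map_{rec.image_id}.png")
        rows.append(
            {
                "image_id": rec.image_id,
                "row_min": box.row_min,
                "col_min": box.col_min,
                "row_max": box.row_max,
                "col_max": box.col_max,
                "iou_vs_truth": best_iou,
            }
        )
        done += 1
    pd.DataFrame(rows).to_csv(out_dir / "boxes.csv", index=False)


_STAGE_FN = {
    "phantom": _run_phantom,
    "degrade": _run_degrade,
    "pretext": _run_pretext,
    "transfer": _run_transfer,
    "ensembles": _run_ensembles,
    "metrics": _run_metrics,
    "stats": _run_stats,
    "scorecam": _run_scorecam,
}


def run_pipeline(
    config: RunConfig,
    workdir: str | Path,
    stages: list[str] | None = None,
) -> PipelineManifest:
    """Run (or resume) the experiment; returns the manifest with the list of
    stages actually executed this call."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    log = get_logger()
    requested = set(stages) if stages is not None else set(STAGE_ORDER)
    unknown = requested - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    manifest_path = workdir / "manifest.json"
    manifest = PipelineManifest.load(manifest_path)
    hashes: dict[str, str] = {}

    for name in STAGE_ORDER:
        deps = STAGE_DEPS[name]
        upstream = [hashes.get(d, "") for d in deps]
        stage_hash = _stage_hash(name, config, upstream)
        hashes[name] = stage_hash
        if name not in requested:
            continue
        for d in deps:
            if d not in manifest.stages:
                raise RuntimeError(
                    f"stage {name!r} requires {d!r}, which has not been run"
                )
        record = manifest.stages.get(name)
        up_to_date = (
            record is not None
            and record.get("config_hash") == stage_hash
            and all(
                Path(workdir, rel).exists()
                and _sha256_file(Path(workdir, rel)) == digest
                for rel, digest in record.get("outputs", {}).items()
            )
        )
        if up_to_date:
            log.info("stage %s up to date, skipping", name)
            continue
        log.info("stage %s running (seed %d)", name, _seed(config, name))
        before = _snapshot(workdir, name)
        _STAGE_FN[name](config, workdir)
        after = _snapshot(workdir, name)
        manifest.stages[name] = {
            "config_hash": stage_hash,
            "seed": _seed(config, name),
            "params": config.stage_params(name),
            "inputs": list(deps),
            "outputs": after,
        }
        manifest.executed.append(name)
        manifest.save(manifest_path)
        del before
    manifest.save(manifest_path)
    return manifest


def _snapshot(workdir: Path, stage: str) -> dict[str, str]:
    stage_dir = workdir / stage
    if not stage_dir.exists():
        return {}
    return {
        str(p.relative_to(workdir)): _sha256_file(p)
        for p in sorted(stage_dir.rglob("*"))
        if p.is_file()
    }
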