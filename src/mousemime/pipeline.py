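"""End-to-end orchestration: synth → preprocess → split → train →
evaluate → gradcam → measure → statespace.

The desk-scale experiment (:func:`run_synthetic_experiment`) is the
library entry point used by the CLI, the test suite and the
reproduction script: it generates a balanced synthetic dataset, applies
the masking/compositing/resizing contract, trains the tiny fire-module
classifier for 110 iterations, and evaluates sensitivity/specificity on
the held-out test split. :func:`run_pipeline` wraps the same stages
into an on-disk run directory with a manifest and a ``repro.json``.

A single global seed fans out to per-stage child seeds through
:func:`mousemime.dataset_builder.child_seed`, so one integer reproduces
every artifact in single-threaded mode.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from mousemime import evaluation, gradcam as gc, morphometry, statespace
from mousemime.dataset_builder import (
    augment,
    balance_classes,
    child_seed,
    split_holdout,
)
from mousemime.errors import DetectionError, StageError
from mousemime.nn import (
    Model,
    ModelSpec,
    TrainConfig,
    build_model,
    images_to_batch,
    recalibrate_batchnorm,
    tiny_train_config,
    train,
)
from mousemime.preprocess import composite, detect_subject, resize_for_net
from mousemime.synthetic_faces import (
    STATES,
    SceneConfig,
    generate_dataset,
    tiny_profile,
)

log = logging.getLogger("mousemime")

LABEL_TO_INT = {s: i for i, s in enumerate(STATES)}


def preprocess_records(records, side: int | None = None):
    """Mask, composite and (optionally) resize every record; frames
    where detection fails are excluded, mirroring the exclusion of
    unusable sequences."""
    out = []
    for rec in records:
        try:
            mask = detect_subject(rec)
        except DetectionError:
            log.warning("excluding frame %s: no subject detected", rec.id)
            continue
        rec2 = composite(rec, mask)
        if side is not None:
            rec2 = resize_for_net(rec2, side)
        out.append(rec2)
    return out


def make_augment_fn(max_shift: int, flip_axis: str = "horizontal"):
    """Batch transform for training: per-image flip/translate on uint8
    NHWC frames, then normalization to NCHW floats."""
    def fn(batch_nhwc: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        aug = np.stack([augment(im, rng, max_shift=max_shift,
                                flip_axis=flip_axis) for im in batch_nhwc])
        return images_to_batch(aug)
    return fn


@dataclass
class ExperimentResult:
    """Everything the downstream analyses need from one run."""

    records: list
    split: object
    model: Model
    history: object
    test_indices: np.ndarray
    test_probs: np.ndarray
    cm: evaluation.ConfusionMatrix
    metrics: dict
    seed: int

    def test_records(self):
        return [self.records[i] for i in self.test_indices]


def run_synthetic_experiment(n_per_state: int = 300, seed: int = 0,
                             scene: SceneConfig | None = None,
                             train_cfg: TrainConfig | None = None,
                             max_shift: int | None = None,
                             records=None) -> ExperimentResult:
    """Generate → preprocess → split → train → evaluate, at desk scale.

    Defaults: 64-px tiny scene profile, tiny fire-module model, batch
    64, 110 SGD iterations. ``max_shift`` defaults to the 227-px
    convention (30 px) scaled to the scene size. Pre-generated
    ``records`` may be supplied to share a dataset across seeds.
    """
    scene = scene or tiny_profile()
    if records is None:
        records = generate_dataset(n_per_state, scene,
                                   seed=child_seed(seed, "synth"))
    processed = preprocess_records(records, side=scene.size)
    labels = np.array([r.label for r in processed])
    keep = balance_classes(labels, seed=child_seed(seed, "balance"),
                           classes=STATES)
    processed = [processed[i] for i in keep]
    labels = labels[keep]
    split = split_holdout(np.arange(len(processed)), labels,
                          seed=child_seed(seed, "split"))
    images = np.stack([r.image for r in processed])
    y = np.array([LABEL_TO_INT[l] for l in labels])

    if max_shift is None:
        max_shift = max(1, int(round(30 * scene.size / 227)))
    train_cfg = train_cfg or tiny_train_config(seed=child_seed(seed, "train"))
    spec = ModelSpec.tiny() if scene.size == 64 else \
        ModelSpec.v11(in_side=scene.size)
    model = build_model(spec, seed=child_seed(seed, "init"))
    history = train(
        model,
        images[split.train], y[split.train],
        images_to_batch(images[split.validation]), y[split.validation],
        cfg=train_cfg,
        augment_fn=make_augment_fn(max_shift),
    )
    # refresh BN statistics with the final weights on un-augmented data
    recalibrate_batchnorm(model, images_to_batch(images[split.train]))

    test_x = images_to_batch(images[split.test])
    probs = model.predict_proba(test_x)
    pred = probs.argmax(axis=1)
    cm = evaluation.confusion(labels[split.test],
                              np.array(STATES)[pred], classes=STATES)
    metrics = {
        "accuracy": cm.accuracy,
        "per_class": evaluation.sensitivity_specificity(cm),
    }
    return ExperimentResult(records=processed, split=split, model=model,
                            history=history, test_indices=split.test,
                            test_probs=probs, cm=cm, metrics=metrics,
                            seed=seed)


def gradcam_localization(result: ExperimentResult, state: str = "tail_pinch",
                         parts: tuple[str, ...] = ("ear", "mouth"),
                         n_images: int = 20, threshold: float = 0.5,
                         layer: str | None = None) -> dict:
    """Fraction of thresholded Grad-CAM mass falling inside the
    ground-truth masks of the state-deformed parts, averaged over test
    images of that state, against those parts' area fraction."""
    ci = LABEL_TO_INT[state]
    recs = [r for r in result.test_records() if r.label == state][:n_images]
    fracs, areas = [], []
    for rec in recs:
        x = images_to_batch([rec])
        hm = gc.gradcam(result.model, x, ci, layer=layer, image_id=rec.id)
        union = np.zeros(rec.image.shape[:2], dtype=bool)
        for p in parts:
            union |= rec.masks[p]
        fracs.append(hm.mass_fraction_in(union, threshold=threshold))
        areas.append(union.mean())
    return {"state": state, "n_images": len(recs),
            "mass_fraction": float(np.mean(fracs)),
            "area_fraction": float(np.mean(areas))}


def morphometry_statespace(records) -> dict:
    """Measure the ten parameters, z-score, embed with 3-PC PCA and
    summarize state separation."""
    table = morphometry.measurement_table(records)
    X = table[list(morphometry.PARAMETER_NAMES)].to_numpy(dtype=float)
    labels = table["label"].to_numpy()
    ok = ~np.isnan(X).any(axis=1)
    X, labels = X[ok], labels[ok]
    Z, stats = statespace.zscore(X)
    emb = statespace.pca3(Z)
    sil_pca = statespace.separation_score(emb.scores, labels)
    kept_names = [n for n, k in zip(morphometry.PARAMETER_NAMES, stats.kept) if k]
    sil_single = {name: statespace.separation_score(Z[:, j], labels)
                  for j, name in enumerate(kept_names)}
    return {"table": table, "Z": Z, "labels": labels, "embedding": emb,
            "stats": stats, "silhouette_pca": sil_pca,
            "silhouette_single": sil_single,
            "total_variance": statespace.total_variance(Z)}


# ----------------------------------------------------------------- run dirs


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    seed: int = 0
    outdir: str = "runs/run0"
    n_per_state: int = 300
    profile: str = "tiny"  # tiny (64 px) | default (256 px scene)
    stages: tuple[str, ...] = ("synth", "preprocess", "split", "train",
                               "evaluate", "gradcam", "measure", "statespace")
    gradcam_k: int = 5

    def scene(self) -> SceneConfig:
        return tiny_profile() if self.profile == "tiny" else SceneConfig()


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the configured stages into a run directory.

    Emits a manifest of every artifact plus ``repro.json`` (seed,
    package and platform versions). A stage failure aborts with the
    stage name; artifacts of completed stages are retained.
    """
    import pandas as pd

    import mousemime

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, list[str]] = {}
    timings: dict[str, float] = {}

    def record_artifacts(stage: str, *paths: Path):
        manifest.setdefault(stage, []).extend(str(p.relative_to(outdir))
                                              for p in paths)

    result = None
    analysis = None
    try:
        if {"synth", "preprocess", "split", "train", "evaluate"} & set(cfg.stages):
            t0 = time.time()
            result = run_synthetic_experiment(cfg.n_per_state, seed=cfg.seed,
                                              scene=cfg.scene())
            timings["train"] = time.time() - t0
            split_rows = []
            for name, idx in (("train", result.split.train),
                              ("validation", result.split.validation),
                              ("test", result.split.test)):
                for i in idx:
                    split_rows.append({"image": result.records[i].id,
                                       "label": result.records[i].label,
                                       "partition": name})
            p = outdir / "split.csv"
            pd.DataFrame(split_rows).to_csv(p, index=False)
            record_artifacts("split", p)
            p = outdir / "history.csv"
            result.history.to_dataframe().to_csv(p, index=False)
            record_artifacts("train", p)
            result.model.save(outdir / "weights")
            record_artifacts("train", outdir / "weights.npz",
                             outdir / "weights.json")
            p = outdir / "confusion.csv"
            result.cm.to_dataframe().to_csv(p)
            record_artifacts("evaluate", p)
            p = outdir / "metrics.json"
            with open(p, "w") as fh:
                json.dump(result.metrics, fh, indent=1)
            record_artifacts("evaluate", p)

        if "gradcam" in cfg.stages and result is not None:
            t0 = time.time()
            test_recs = result.test_records()
            x = images_to_batch(test_recs)
            rgb = np.stack([r.image for r in test_recs])
            ids = [r.id for r in test_recs]
            gdir = outdir / "gradcam"
            gc.top_k_overlays(result.model, x, rgb, ids, STATES,
                              k=cfg.gradcam_k, outdir=gdir)
            record_artifacts("gradcam", *sorted(gdir.glob("*.png")))
            timings["gradcam"] = time.time() - t0

        if {"measure", "statespace"} & set(cfg.stages):
            t0 = time.time()
            scene = cfg.scene()
            records = generate_dataset(cfg.n_per_state, scene,
                                       seed=child_seed(cfg.seed, "synth"))
            analysis = morphometry_statespace(records)
            p = outdir / "morphometry.csv"
            analysis["table"].to_csv(p)
            record_artifacts("measure", p)
            if "statespace" in cfg.stages:
                emb = analysis["embedding"]
                p1 = outdir / "pc_scores.csv"
                pd.DataFrame(emb.scores,
                             columns=[f"PC{i+1}" for i in
                                      range(emb.scores.shape[1])]) \
                    .assign(label=analysis["labels"]).to_csv(p1, index=False)
                p2 = outdir / "embedding.json"
                with open(p2, "w") as fh:
                    json.dump({
                        "loadings": emb.loadings.tolist(),
                        "explained_variance_fraction":
                            emb.explained_variance_fraction.tolist(),
                        "silhouette_pca": analysis["silhouette_pca"],
                        "silhouette_single": analysis["silhouette_single"],
                    }, fh, indent=1)
                p3 = outdir / "statespace.png"
                _scatter3d(emb.scores, analysis["labels"], p3)
                record_artifacts("statespace", p1, p2, p3)
            timings["measure"] = time.time() - t0
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        stage = "unknown"
        for s in cfg.stages:
            if s not in manifest:
                stage = s
                break
        _write_manifest(outdir, cfg, manifest, timings)
        raise StageError(stage, str(exc)) from exc

    _write_manifest(outdir, cfg, manifest, timings)
    with open(outdir / "repro.json", "w") as fh:
        json.dump({"seed": cfg.seed,
                   "stage_seeds": {s: child_seed(cfg.seed, s)
                                   for s in ("synth", "balance", "split",
                                             "train", "init")},
                   "mousemime": mousemime.__version__,
                   "numpy": np.__version__,
                   "python": platform.python_version()}, fh, indent=1)
    return outdir


def _write_manifest(outdir: Path, cfg: RunConfig, manifest: dict,
                    timings: dict) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump({"config": {**cfg.__dict__, "stages": list(cfg.stages)},
                   "artifacts": manifest,
                   "timings_s": {k: round(v, 2) for k, v in timings.items()}},
                  fh, indent=1)


def _scatter3d(scores: np.ndarray, labels, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    for state, color in zip(STATES, ("tab:gray", "tab:red", "tab:blue")):
        sel = np.asarray(labels) == state
        k = scores.shape[1]
        coords = [scores[sel, i] for i in range(min(3, k))]
        while len(coords) < 3:
            coords.append(np.zeros(sel.sum()))
        ax.scatter(*coords, s=6, alpha=0.6, label=state, color=color)
    ax.set_xlabel("PC1"), ax.set_ylabel("PC2"), ax.set_zlabel("PC3")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
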