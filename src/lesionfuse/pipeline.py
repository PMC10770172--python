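"""End-to-end orchestration of the double-deck flow.

Stages: deck-one train/predict -> confidence triage into retained vs BSC ->
hair removal on BSC samples -> class-balancing augmentation -> deck-two
training -> bottleneck extraction -> ABCDE + flag feature extraction ->
fusion -> the seven tabular classifiers with metrics and the flag ablation.

Retained (easy) samples keep the deck-one prediction; BSC samples take the
fused-feature prediction of the configured final classifier; the merged
ledger combines both for the headline metrics.  All stage seeds derive from
the master seed via ``numpy.random.SeedSequence`` spawning, so a run is
fully reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize

from . import abcde, classify, deck_one, fflag, fusion, hair, synthetic
from .augment import AugmentSpec, balance_dataset
from .errors import LesionFuseError

log = logging.getLogger("lesionfuse")


@dataclass
class PipelineConfig:
    n_samples: int = 300
    malignant_fraction: float = 0.5
    hairy_fraction: float = 0.4
    signal: str = "full"
    image_size: tuple = (96, 96)
    deck_input_size: int = 32
    deck_one_epochs: int = 10
    deck_two_epochs: int = 10
    batch_size: int = 40
    learning_rate: float = 0.001
    bsc_threshold: float = deck_one.BSC_THRESHOLD
    hair_config: hair.HairRemovalConfig = field(default_factory=hair.HairRemovalConfig)
    augment: AugmentSpec = field(default_factory=AugmentSpec)
    fusion_mode: str = "extended"
    classifiers: tuple = classify.CLASSIFIER_NAMES
    final_classifier: str = "xgboost"
    train_fraction: float = 0.7
    seed: int = 0
    manifest: str | None = None  # load instead of generating when set

    def stage_seeds(self):
        state = np.random.SeedSequence(self.seed).generate_state(8)
        names = ("data", "split", "deck_one", "augment", "deck_two",
                 "classify", "ablation", "misc")
        return {k: int(v % 2**31) for k, v in zip(names, state)}


def _resize_batch(samples, size):
    return np.stack([
        resize(s.image, (size, size, 3), anti_aliasing=True, preserve_range=True) / 255.0
        for s in samples
    ])


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute every stage, write artefacts under ``out_dir``, return the report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    report: dict = {"config_seed": config.seed, "stages": {}}

    def stage(name):
        log.info("stage: %s", name)
        report["stages"][name] = "ok"
        return name

    try:
        stage("data")
        if config.manifest:
            samples = synthetic.read_manifest(config.manifest)
        else:
            samples = synthetic.generate_dataset(
                config.n_samples, config.malignant_fraction, config.hairy_fraction,
                seed=seeds["data"], image_size=config.image_size, signal=config.signal,
            )
        by_id = {s.sample_id: s for s in samples}

        stage("split")
        train, test = classify.split_train_test(samples, config.train_fraction,
                                                seed=seeds["split"])
        pd.DataFrame({"image_name": [s.sample_id for s in train],
                      "target": [s.label for s in train]}).to_csv(out / "train.csv", index=False)
        pd.DataFrame({"image_name": [s.sample_id for s in test],
                      "target": [s.label for s in test]}).to_csv(out / "test.csv", index=False)

        stage("deck_one")
        model1 = deck_one.build_baseline_cnn(config.deck_input_size, seed=seeds["deck_one"])
        small_train = _resize_batch(train, config.deck_input_size)
        history = deck_one.train_baseline(
            model1, train, epochs=config.deck_one_epochs, batch_size=config.batch_size,
            learning_rate=config.learning_rate, seed=seeds["deck_one"], images=small_train,
        )
        (out / "deck_one_loss.json").write_text(json.dumps(history))
        records = deck_one.predict_records(model1, samples,
                                           images=_resize_batch(samples, config.deck_input_size))
        deck_one.write_records_csv(records, out / "confidence.csv")

        stage("bsc")
        partition = deck_one.segregate_bsc(records, j=config.bsc_threshold)
        pd.DataFrame({"image_name": partition.retained}).to_csv(out / "retained.csv", index=False)
        pd.DataFrame({"image_name": partition.bsc}).to_csv(out / "bsc.csv", index=False)
        bsc_samples = [by_id[i] for i in partition.bsc]

        stage("hair_removal")
        cleaned = {}
        for s in bsc_samples:
            img, _mask = hair.remove_hair(s.image, config.hair_config)
            cleaned[s.sample_id] = dataclasses.replace(s, image=img)

        test_ids = {s.sample_id for s in test}
        bsc_train = [cleaned[i] for i in partition.bsc if i not in test_ids]
        bsc_test = [cleaned[i] for i in partition.bsc if i in test_ids]

        stage("augment")
        balanced = balance_dataset(bsc_train,
                                   dataclasses.replace(config.augment, seed=seeds["augment"]))

        stage("deck_two")
        model2 = fusion.build_deck_two_cnn(config.deck_input_size, seed=seeds["deck_two"])
        fusion.train_deck_two(model2, balanced, epochs=config.deck_two_epochs,
                              batch_size=config.batch_size,
                              learning_rate=config.learning_rate, seed=seeds["deck_two"],
                              images=_resize_batch(balanced, config.deck_input_size))

        stage("features")
        feature_samples = bsc_train + bsc_test
        bn = fusion.extract_bottleneck(
            model2, _resize_batch(feature_samples, config.deck_input_size))
        vectors, ids, labels = [], [], []
        for i, s in enumerate(feature_samples):
            seg = abcde.segment_lesion(s.image)
            feats = abcde.compute_abcde(s.image, seg)
            flags = fflag.flag_features_from_segmentation(s.image, seg)
            vectors.append(fusion.fuse_features(bn[i], feats, flags, mode=config.fusion_mode))
            ids.append(s.sample_id)
            labels.append(s.label)
        table = fusion.feature_table(ids, vectors, labels)
        fusion.write_feature_csv(table, out / "features.csv")

        stage("classify")
        train_rows = table["sample_id"].isin([s.sample_id for s in bsc_train]).to_numpy()
        feat_cols = [c for c in table.columns if c not in ("sample_id", "label")]
        clinical = [c for c in feat_cols if not c.startswith("bn_")]
        scaler = classify.ClinicalScaler(clinical).fit(table[train_rows])
        scaled = scaler.transform(table)
        x = scaled[feat_cols].to_numpy(dtype=float)
        y = table["label"].to_numpy(dtype=int)
        per_classifier = {}
        bsc_pred = {}
        for name in config.classifiers:
            cfg = classify.ClassifierConfig(name=name, seed=seeds["classify"])
            model = classify.make_classifier(cfg)
            model.fit(x[train_rows], y[train_rows])
            if (~train_rows).any():
                pred = model.predict(x[~train_rows])
                proba = model.predict_proba(x[~train_rows])[:, 1]
                rep = classify.evaluate_metrics(pred, y[~train_rows])
                if len(set(y[~train_rows].tolist())) == 2:
                    rep.roc_points, rep.auc = classify.roc_auc(proba, y[~train_rows])
                per_classifier[name] = rep.as_dict()
                if name == config.final_classifier:
                    for sid, p in zip(table["sample_id"][~train_rows], pred):
                        bsc_pred[sid] = int(p)
            else:
                per_classifier[name] = None
        report["per_classifier"] = per_classifier

        stage("ablation")
        if config.fusion_mode == "extended" and (~train_rows).any():
            ablation = classify.flag_ablation(table, seed=seeds["ablation"],
                                              train_fraction=config.train_fraction)
            report["ablation"] = ablation.to_dict(orient="records")
            ablation.to_csv(out / "ablation.csv", index=False)
        else:
            report["ablation"] = None

        stage("merge")
        rec_by_id = {r.sample_id: r for r in records}
        merged_pred, merged_truth = [], []
        for s in test:
            if s.sample_id in bsc_pred:
                merged_pred.append(bsc_pred[s.sample_id])
            else:
                merged_pred.append(rec_by_id[s.sample_id].predicted)
            merged_truth.append(s.label)
        if merged_pred:
            report["merged"] = classify.evaluate_metrics(merged_pred, merged_truth).as_dict()
        else:
            report["merged"] = None
        report["counts"] = {"n": len(samples), "retained": len(partition.retained),
                            "bsc": len(partition.bsc), "train": len(train), "test": len(test)}
    except LesionFuseError as exc:
        failed = [k for k, v in report["stages"].items() if v == "ok"]
        report["stages"][failed[-1] if failed else "start"] = f"failed: {exc}"
        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
        raise

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
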