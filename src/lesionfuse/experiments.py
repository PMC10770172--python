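"""Canned study-scale experiments on synthetic data.

These are the reproducible desk-scale studies the package ships: each one
generates its own inputs from a seed, runs the relevant stages, and returns
plain numbers.  They are shared by the test suite and the acceptance script
so that every reported quantity is recomputed from scratch.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize
from sklearn.model_selection import train_test_split

from . import abcde, classify, fflag, fusion, hair, nn
from .synthetic import LesionSpec, generate_dataset, generate_lesion


def _resize_batch(samples, size):
    return np.stack([
        resize(s.image.astype(float) / 255.0, (size, size, 3), anti_aliasing=True)
        for s in samples
    ])


def hair_removal_study(n: int = 100, seed: int = 0,
                       config: hair.HairRemovalConfig | None = None) -> dict:
    """Paired hairy / hair-free comparison over ``n`` seeded lesions.

    Returns the fraction of lesions where inpainting moved the image closer
    (mean absolute error) to the hair-free original, the mean MAE before and
    after, and whether locality held (pixels outside the detected mask are
    bit-identical in every case).
    """
    if config is None:
        config = hair.HairRemovalConfig()
    rng = np.random.default_rng(seed)
    improved = 0
    mae_before, mae_after = [], []
    locality_ok = True
    for _ in range(n):
        spec = LesionSpec(
            seed=int(rng.integers(2**31)),
            hair_count=int(rng.integers(6, 14)),
            hair_thickness=float(rng.uniform(1.0, 3.0)),
            n_tones=int(rng.integers(2, 4)),
            border_wave_amplitude=float(rng.uniform(0.0, 2.0)),
            bwv_fraction=float(rng.uniform(0.0, 0.3)),
        )
        s = generate_lesion(spec)
        cleaned, mask = hair.remove_hair(s.image, config)
        ref = s.ground_truth.hair_free.astype(float)
        before = np.abs(s.image.astype(float) - ref).mean()
        after = np.abs(cleaned.astype(float) - ref).mean()
        improved += after < before
        mae_before.append(before)
        mae_after.append(after)
        outside = ~mask.mask
        locality_ok &= bool(np.array_equal(cleaned[outside], s.image[outside]))
    return {
        "n": n,
        "improved_fraction": improved / n,
        "mae_hairy": float(np.mean(mae_before)),
        "mae_cleaned": float(np.mean(mae_after)),
        "locality_ok": locality_ok,
    }


def bwv_recovery_study(n: int = 50, seed: int = 0) -> dict:
    """Regression of S_Flag1 on the generator's bwv_fraction over ``n`` lesions.

    Fractions sweep 0.1..0.9; a slope near 1 means the veil detector recovers
    the planted veil area almost exactly.
    """
    rng = np.random.default_rng(seed)
    fracs = np.linspace(0.1, 0.9, n)
    measured = []
    for f in fracs:
        s = generate_lesion(LesionSpec(seed=int(rng.integers(2**31)),
                                       bwv_fraction=float(f),
                                       n_tones=int(rng.integers(1, 4))))
        flags = fflag.flag_features(s.image, s.ground_truth.lesion_mask)
        measured.append(flags.S_Flag1)
    slope, intercept = np.polyfit(fracs, measured, 1)
    return {"n": n, "slope": float(slope), "intercept": float(intercept)}


def flag_ablation_study(n: int = 600, seed: int = 0, *, epochs: int = 3,
                        deck_input: int = 32, image_size: tuple = (64, 64)) -> dict:
    """End-to-end flag ablation on a BWV-informative synthetic dataset.

    Generates ``n`` samples whose only label signal is a subtle blue-white
    veil, trains the deck-two CNN briefly on the training split, fuses
    bottleneck + clinical + flag features, and runs the with/without-flag
    specificity ablation across all seven classifiers.
    """
    samples = generate_dataset(n, seed=seed, hairy_fraction=0.0,
                               image_size=image_size, signal="bwv_only")
    imgs = _resize_batch(samples, deck_input)
    labels = np.array([s.label for s in samples])
    tr, _te = train_test_split(np.arange(n), train_size=0.7, stratify=labels,
                               random_state=seed)
    model = fusion.build_deck_two_cnn(deck_input, seed=seed)
    nn.train(model, imgs[tr], labels[tr], epochs=epochs, batch_size=40,
             learning_rate=0.001, seed=seed, optimizer="adamax")
    bn = fusion.extract_bottleneck(model, imgs)
    vectors, ids = [], []
    for i, s in enumerate(samples):
        seg = abcde.segment_lesion(s.image)
        feats = abcde.compute_abcde(s.image, seg)
        flags = fflag.flag_features_from_segmentation(s.image, seg)
        vectors.append(fusion.fuse_features(bn[i], feats, flags, mode="extended"))
        ids.append(s.sample_id)
    table = fusion.feature_table(ids, vectors, labels)
    ablation = classify.flag_ablation(table, seed=seed)
    deltas = ablation["delta"]
    return {
        "n": n,
        "table": ablation,
        "n_improved": int((deltas > 0).sum()),
        "mean_delta": float(deltas.mean()),
    }
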