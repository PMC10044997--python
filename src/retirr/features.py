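"""Per-eye feature assembly: splits, axial-length-stratified folds, and the
fold-wise PVD-reference normalization.

Eyes are split 2/3:1/3 into training and testing (stratified by diagnosis;
retinal-tear eyes form a separate second validation set).  Within the
training set, eyes are sorted by axial length inside each diagnostic group
and dealt into 5 folds block-by-block with fresh random permutations, which
balances both diagnosis and axial length across folds.  Each training eye's
spectrum bins are expressed as differences from the mean spectrum of PVD
eyes in the *other* folds; test eyes are referenced against all training
PVD eyes (training-only data, avoiding leakage).  The resulting vector has
126 entries: 4 x 30 bin differences (up, down, temporal, nasal), the four
detrend curvatures in the same order, axial length, and age.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import GAZES, N_SPECTRUM_BINS, EyeRecord, feature_names

logger = logging.getLogger(__name__)

FEATURE_NAMES = feature_names()


def split_train_test(
    eyes: list[EyeRecord], test_fraction: float = 1.0 / 3.0, seed: int = 0
) -> None:
    """Assign ``split`` labels in place: train/test for PVD+RD, "tear" aside."""
    rng = np.random.default_rng(seed)
    for eye in eyes:
        if eye.diagnosis == "tear":
            eye.split = "tear"
    for group in ("PVD", "RD"):
        members = [e for e in eyes if e.diagnosis == group]
        idx = rng.permutation(len(members))
        n_test = int(round(test_fraction * len(members)))
        test_ids = {members[i].eye_id for i in idx[:n_test]}
        for e in members:
            e.split = "test" if e.eye_id in test_ids else "train"


def allocate_folds(eyes: list[EyeRecord], k: int = 5, seed: int = 0) -> dict[str, int]:
    """Deal eyes into k folds, stratified by diagnosis and axial length.

    Within each diagnostic group, eyes sorted by axial length are assigned
    fold labels block-by-block: each consecutive block of k eyes receives a
    fresh random permutation of {1..k}; the remaining n mod k eyes go to
    that many distinct random folds.  Sets ``eye.fold`` and returns
    eye_id -> fold.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    out: dict[str, int] = {}
    groups = sorted({e.diagnosis for e in eyes})
    for group in groups:
        members = sorted(
            (e for e in eyes if e.diagnosis == group), key=lambda e: e.axial_length_mm
        )
        if not members:
            raise ValueError(f"group {group!r} is empty")
        if len(members) < k:
            logger.warning(
                "group %s has %d eyes for %d folds; some folds will be empty",
                group, len(members), k,
            )
        n_full, rem = divmod(len(members), k)
        labels: list[int] = []
        for _ in range(n_full):
            labels.extend(rng.permutation(k) + 1)
        if rem:
            labels.extend(rng.choice(k, size=rem, replace=False) + 1)
        for eye, lab in zip(members, labels):
            eye.fold = int(lab)
            out[eye.eye_id] = int(lab)
    return out


def _pvd_bin_matrix(eyes: list[EyeRecord], gaze: str) -> np.ndarray:
    return np.array([e.spectra[gaze].bins for e in eyes])


def pvd_reference(eyes: list[EyeRecord], target_fold: int | None) -> dict[str, np.ndarray]:
    """Per-gaze mean 30-bin spectrum over PVD eyes outside ``target_fold``.

    With ``target_fold=None`` the mean runs over all (training) PVD eyes —
    the reference applied to test-set eyes.
    """
    pool = [
        e for e in eyes
        if e.diagnosis == "PVD" and e.complete and (target_fold is None or e.fold != target_fold)
    ]
    if not pool:
        raise ValueError(f"no out-of-fold PVD eyes available for fold {target_fold}")
    return {g: _pvd_bin_matrix(pool, g).mean(axis=0) for g in GAZES}


def build_feature_vector(eye: EyeRecord, reference: dict[str, np.ndarray]) -> np.ndarray:
    """The 126-entry candidate feature vector for one eye.

    Order: up/down/temporal/nasal bin differences (eye bin − reference bin),
    then the four curvatures in the same gaze order, axial length, age.
    Curvature, axial length and age are entered raw (the reference
    subtraction applies to irregularity only).
    """
    missing = [g for g in GAZES if g not in eye.spectra]
    if missing:
        raise ValueError(f"eye {eye.eye_id} is missing gaze regions: {missing}")
    parts = [eye.spectra[g].bins - reference[g] for g in GAZES]
    parts.append(np.array([eye.spectra[g].curvature for g in GAZES]))
    parts.append(np.array([eye.axial_length_mm, eye.age_years]))
    vec = np.concatenate(parts)
    assert vec.shape == (4 * N_SPECTRUM_BINS + 6,)
    if not np.all(np.isfinite(vec)):
        raise ValueError(f"non-finite feature values for eye {eye.eye_id}")
    return vec


def build_feature_matrices(
    eyes: list[EyeRecord], k: int = 5, fold_seed: int = 0
) -> dict[str, np.ndarray]:
    """Folds, references and matrices for a split cohort.

    Expects ``split`` labels already assigned and spectra attached.  Training
    eyes are referenced out-of-fold; test and tear eyes against all training
    PVD eyes.  Returns X/y per split (labels: PVD -> 1, RD -> 2) plus eye ids.
    """
    train = [e for e in eyes if e.split == "train" and e.complete]
    test = [e for e in eyes if e.split == "test" and e.complete]
    tear = [e for e in eyes if e.split == "tear" and e.complete]
    allocate_folds(train, k=k, seed=fold_seed)
    refs = {f: pvd_reference(train, f) for f in sorted({e.fold for e in train})}
    global_ref = pvd_reference(train, None)
    X_train = np.array([build_feature_vector(e, refs[e.fold]) for e in train])
    y_train = np.array([1 if e.diagnosis == "PVD" else 2 for e in train])
    out = {
        "X_train": X_train,
        "y_train": y_train,
        "train_ids": np.array([e.eye_id for e in train]),
    }
    for name, rows in (("test", test), ("tear", tear)):
        if rows:
            out[f"X_{name}"] = np.array([build_feature_vector(e, global_ref) for e in rows])
            out[f"y_{name}"] = np.array([1 if e.diagnosis == "PVD" else 2 for e in rows])
            out[f"{name}_ids"] = np.array([e.eye_id for e in rows])
        else:
            out[f"X_{name}"] = np.empty((0, len(FEATURE_NAMES)))
            out[f"y_{name}"] = np.empty(0, dtype=int)
            out[f"{name}_ids"] = np.empty(0, dtype=object)
    return out
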