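"""Two-class random-forest pixel classification of STED images.

Each pixel is described by multi-scale filter responses (smoothed
intensity, edge and texture descriptors at sigmas from 0.3 to 3.5 px) and
classified as background or tight-junction strand by a random forest,
yielding a probability map that is thresholded into a binary strand mask.
A classifier-free Otsu fallback (:func:`threshold_segment`) is provided
for bootstrapping annotations and for testing.

Annotations are sparse label images with the convention
0 = unlabeled, 1 = background, 2 = strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
from scipy import ndimage as ndi
from skimage.feature import (hessian_matrix, hessian_matrix_eigvals,
                             structure_tensor, structure_tensor_eigenvalues)
from skimage.morphology import remove_small_objects
from sklearn.ensemble import RandomForestClassifier

from .preprocess import otsu_integer_threshold
from .types import ImageChannel, JunctionMask, StrandMask

DEFAULT_SIGMAS = (0.3, 0.7, 1.0, 1.6, 3.5)
SIGMA_RANGE = (0.3, 3.5)
FEATURE_TYPES = (
    "gaussian",
    "gradient_magnitude",
    "laplacian",
    "structure_tensor_max_eig",
    "hessian_eig_high",
    "hessian_eig_low",
)
LABEL_BACKGROUND = 1
LABEL_STRAND = 2

MODEL_FORMAT_VERSION = 1


@dataclass
class FeatureStack:
    """Per-pixel feature vectors for one image: shape (H, W, n_features)."""

    features: np.ndarray
    sigmas: tuple[float, ...]
    feature_names: tuple[str, ...]

    @property
    def n_features(self) -> int:
        return self.features.shape[-1]

    def flat(self) -> np.ndarray:
        return self.features.reshape(-1, self.n_features)


@dataclass
class PixelClassifier:
    """Trained two-class forest plus the feature configuration it expects."""

    model: RandomForestClassifier
    sigmas: tuple[float, ...]
    feature_names: tuple[str, ...]
    n_trees: int
    seed: int
    oob_accuracy: float | None = None
    class_labels: tuple[str, str] = ("background", "tight_junction")


def compute_features(img: ImageChannel | np.ndarray,
                     sigmas: tuple[float, ...] = DEFAULT_SIGMAS,
                     allow_out_of_range: bool = False) -> FeatureStack:
    """Multi-scale filter bank: 6 feature types per sigma.

    Per sigma: Gaussian-smoothed intensity, Gaussian gradient magnitude,
    Laplacian-of-Gaussian, the larger structure-tensor eigenvalue, and both
    Hessian eigenvalues. Boundaries are handled by reflection.
    """
    if len(sigmas) == 0:
        raise ValueError("need at least one sigma")
    lo, hi = SIGMA_RANGE
    if not allow_out_of_range:
        bad = [s for s in sigmas if not lo <= s <= hi]
        if bad:
            raise ValueError(
                f"sigmas {bad} outside the supported range [{lo}, {hi}] "
                "(pass allow_out_of_range=True to override)"
            )
    pixels = img.pixels if isinstance(img, ImageChannel) else np.asarray(img)
    x = pixels.astype(np.float64)
    planes: list[np.ndarray] = []
    names: list[str] = []
    for s in sigmas:
        planes.append(ndi.gaussian_filter(x, s, mode="reflect"))
        planes.append(ndi.gaussian_gradient_magnitude(x, s, mode="reflect"))
        planes.append(ndi.gaussian_laplace(x, s, mode="reflect"))
        st = structure_tensor(x, sigma=s, mode="reflect", order="rc")
        planes.append(structure_tensor_eigenvalues(st)[0])
        hm = hessian_matrix(x, sigma=s, mode="reflect", order="rc",
                            use_gaussian_derivatives=True)
        ev = hessian_matrix_eigvals(hm)
        planes.append(ev[0])
        planes.append(ev[1])
        names.extend(f"{name}_s{s:g}" for name in FEATURE_TYPES)
    return FeatureStack(np.stack(planes, axis=-1), tuple(sigmas), tuple(names))


def _gather_training_set(stacks, annotations):
    xs, ys = [], []
    for stack, ann in zip(stacks, annotations):
        ann = np.asarray(ann)
        if ann.shape != stack.features.shape[:2]:
            raise ValueError("annotation grid does not match the feature stack")
        sel = ann > 0
        xs.append(stack.flat()[sel.ravel()])
        ys.append(ann[sel])
    return np.concatenate(xs), np.concatenate(ys)


def train_classifier(stacks: list[FeatureStack], annotations: list[np.ndarray],
                     n_trees: int = 100, seed: int = 0) -> PixelClassifier:
    """Fit the two-class forest on sparsely annotated feature stacks.

    Raises ``ValueError`` when the annotations do not contain both classes;
    warns when a class has fewer than 50 labeled pixels. Training is
    reproducible given the seed; out-of-bag accuracy is reported.
    """
    X, y = _gather_training_set(stacks, annotations)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(
            f"annotations contain only class {classes.tolist()}; need both "
            f"background ({LABEL_BACKGROUND}) and strand ({LABEL_STRAND}) labels"
        )
    for cls in classes:
        n = int((y == cls).sum())
        if n < 50:
            warnings.warn(f"only {n} labeled pixels for class {cls}; "
                          "at least 50 per class are recommended", stacklevel=2)
    model = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                   n_jobs=1, oob_score=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # oob on tiny sets
        model.fit(X, y)
    oob = float(model.oob_score_) if hasattr(model, "oob_score_") else None
    ref = stacks[0]
    return PixelClassifier(model=model, sigmas=ref.sigmas,
                           feature_names=ref.feature_names,
                           n_trees=n_trees, seed=seed, oob_accuracy=oob)


def predict_probability(img: ImageChannel | np.ndarray, clf: PixelClassifier,
                        stack: FeatureStack | None = None) -> np.ndarray:
    """Per-pixel P(strand) map in [0, 1].

    Features are recomputed with the classifier's own configuration unless
    a precomputed stack is supplied, in which case its configuration must
    match the training configuration exactly.
    """
    if stack is None:
        stack = compute_features(img, clf.sigmas, allow_out_of_range=True)
    elif stack.sigmas != clf.sigmas or stack.feature_names != clf.feature_names:
        raise ValueError("feature configuration does not match the trained classifier")
    proba = clf.model.predict_proba(stack.flat())
    col = list(clf.model.classes_).index(LABEL_STRAND)
    return proba[:, col].reshape(stack.features.shape[:2])


def binarize(prob_map: np.ndarray, prob_threshold: float = 0.5,
             min_object_px: int = 4, mask: JunctionMask | None = None,
             pixel_size_nm: float = 20.0) -> StrandMask:
    """Threshold a probability map into a strand mask.

    Pixels with P >= threshold are kept, intersected with the junction mask
    when given, and connected objects (8-connectivity) smaller than
    ``min_object_px`` are removed.
    """
    if not 0.0 < prob_threshold < 1.0:
        raise ValueError("prob_threshold must lie in (0, 1)")
    binary = np.asarray(prob_map) >= prob_threshold
    if mask is not None:
        if mask.shape != binary.shape:
            raise ValueError("junction mask grid does not match the probability map")
        binary &= mask.pixels
        pixel_size_nm = mask.pixel_size_nm
    if min_object_px > 1:
        binary = remove_small_objects(binary, max_size=min_object_px - 1, connectivity=2)
    return StrandMask(binary, pixel_size_nm, prob_threshold=prob_threshold,
                      min_object_px=min_object_px)


def threshold_segment(img: ImageChannel, mask: JunctionMask | None = None,
                      min_object_px: int = 4) -> StrandMask:
    """Classifier-free fallback: Otsu threshold within the junction mask.

    Useful for bootstrapping annotations and as a baseline. Applies the
    same post-filtering as :func:`binarize`.
    """
    pixels = np.asarray(img.pixels)
    region = mask.pixels if mask is not None else np.ones(pixels.shape, bool)
    vals = pixels[region]
    if vals.size == 0 or vals.min() == vals.max():
        raise ValueError("Otsu threshold undefined for a constant (or empty) region")
    if np.issubdtype(pixels.dtype, np.integer):
        thr = otsu_integer_threshold(vals)
    else:
        from skimage.filters import threshold_otsu
        thr = threshold_otsu(vals)
    binary = (pixels > thr) & region
    if min_object_px > 1:
        binary = remove_small_objects(binary, max_size=min_object_px - 1, connectivity=2)
    return StrandMask(binary, img.pixel_size_nm, min_object_px=min_object_px)


def labels_from_truth(truth_mask: np.ndarray, n_per_class: int = 5000,
                      seed: int = 0, positive_dilation: np.ndarray | None = None,
                      ) -> np.ndarray:
    """Fabricate a sparse annotation image from synthetic ground truth.

    Subsamples ``n_per_class`` strand pixels (label 2) and background
    pixels (label 1). When ``positive_dilation`` is given (e.g. the
    PSF-matched apparent strand mask), strand labels are drawn from it and
    background labels from outside it, mimicking how an annotator labels
    the visible ridge rather than the sub-resolution centreline.
    """
    rng = np.random.default_rng(seed)
    truth_mask = np.asarray(truth_mask, bool)
    pos_region = truth_mask if positive_dilation is None else np.asarray(positive_dilation, bool)
    labels = np.zeros(truth_mask.shape, np.uint8)
    pos = np.flatnonzero(pos_region)
    neg = np.flatnonzero(~pos_region)
    take_pos = rng.choice(pos, size=min(n_per_class, pos.size), replace=False)
    take_neg = rng.choice(neg, size=min(n_per_class, neg.size), replace=False)
    labels.ravel()[take_pos] = LABEL_STRAND
    labels.ravel()[take_neg] = LABEL_BACKGROUND
    return labels


def save_classifier(clf: PixelClassifier, path) -> None:
    """Serialize a classifier with its feature configuration and seed."""
    joblib.dump({
        "format_version": MODEL_FORMAT_VERSION,
        "model": clf.model,
        "sigmas": clf.sigmas,
        "feature_names": clf.feature_names,
        "n_trees": clf.n_trees,
        "seed": clf.seed,
        "oob_accuracy": clf.oob_accuracy,
    }, path)


def load_classifier(path) -> PixelClassifier:
    blob = joblib.load(path)
    if blob.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {blob.get('format_version')}")
    return PixelClassifier(model=blob["model"], sigmas=tuple(blob["sigmas"]),
                           feature_names=tuple(blob["feature_names"]),
                           n_trees=blob["n_trees"], seed=blob["seed"],
                           oob_accuracy=blob["oob_accuracy"])
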