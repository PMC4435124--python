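"""Berry-color classification by linear discriminant analysis.

Per-berry mean RGB values are aggregated to one mean per image; the
image-level (R, G, B) triple is the predictor vector for a five-class LDA
(1=black, 2=red, 3=rose, 4=grey, 5=green). LDA here is the classical
pooled-covariance Gaussian rule: class means mu_k, one shared covariance
Sigma estimated within classes with divisor (N - K), priors pi_k equal to
class frequencies, and discriminants

    delta_k(x) = x' Sigma^-1 mu_k - 1/2 mu_k' Sigma^-1 mu_k + ln pi_k,

with posteriors the softmax of the delta_k and ties broken toward the
lower class code. Evaluation is leave-one-out cross-validation summarised
as a confusion matrix with rows = predicted class and columns = real
(visually assessed) class, printed in the order black, green, grey, red,
rose.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .berry_detection import BerryDetection
from .synthetic_scene import CLASS_NAMES

# printed class order used for confusion matrices and reports
PRINTED_ORDER = ["black", "green", "grey", "red", "rose"]
PRINTED_CODES = [1, 5, 4, 2, 3]

RIDGE_SCALE = 1e-6
COND_LIMIT = 1e10

# Reference leave-out confusion counts for a 500-image field validation set
# of visually assessed berry color classes (rows = predicted, columns =
# real, both in PRINTED_ORDER). Kept as a replay fixture for the accuracy
# arithmetic; column sums give the per-class reference counts
# (202 black, 200 green, 39 grey, 37 red, 22 rose).
FIELD_REFERENCE_CONFUSION = np.array(
    [
        [197, 7, 2, 5, 3],
        [5, 178, 7, 0, 0],
        [0, 15, 28, 2, 3],
        [0, 0, 1, 26, 13],
        [0, 0, 1, 4, 3],
    ],
    dtype=int,
)
FIELD_REFERENCE_CLASS_COUNTS = {1: 202, 5: 200, 4: 39, 2: 37, 3: 22}


class LdaFitError(ValueError):
    """LDA preconditions violated (names the offending class when known)."""


class NoBerriesError(ValueError):
    """Image excluded from color analysis: no detected berries."""


class UndefinedAccuracyError(ValueError):
    """Per-class accuracy undefined: empty reference column."""


@dataclass(frozen=True)
class ColorSample:
    """One image's mean berry RGB with an optional visual class label."""

    image_id: str
    mean_rgb: tuple[float, float, float]
    true_class: int | None = None


@dataclass(frozen=True)
class ColorClassModel:
    """Fitted LDA: ordered class codes, means, pooled covariance, priors."""

    classes: tuple[int, ...]
    class_means: np.ndarray  # (K, 3)
    pooled_covariance: np.ndarray  # (3, 3)
    priors: np.ndarray  # (K,)


@dataclass
class ConfusionMatrix:
    """Counts with rows = predicted class, columns = real class."""

    classes: tuple[int, ...]  # class codes, in printed order
    counts: np.ndarray

    def column_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def class_index(self, class_code: int) -> int:
        try:
            return self.classes.index(int(class_code))
        except ValueError:
            raise KeyError(f"class {class_code} not in confusion matrix") from None


def aggregate_image_color(detections: list[BerryDetection]) -> np.ndarray:
    """Unweighted channel-wise mean RGB over all berries of one image."""
    if not detections:
        raise NoBerriesError("no berries detected; image excluded from color analysis")
    return np.mean([d.mean_rgb for d in detections], axis=0)


# --------------------------------------------------------------------------
# Model fit and prediction
# --------------------------------------------------------------------------


def fit_lda(samples: list[ColorSample]) -> ColorClassModel:
    labelled = [s for s in samples if s.true_class is not None]
    X = np.array([s.mean_rgb for s in labelled], dtype=float)
    y = np.array([s.true_class for s in labelled], dtype=int)
    classes = tuple(sorted(set(y.tolist())))
    if len(classes) < 2:
        raise LdaFitError(f"need >= 2 classes, got {classes}")
    if len(y) <= X.shape[1]:
        raise LdaFitError(f"need more samples ({len(y)}) than dimensions ({X.shape[1]})")
    means = np.empty((len(classes), X.shape[1]))
    scatter = np.zeros((X.shape[1], X.shape[1]))
    for i, c in enumerate(classes):
        xc = X[y == c]
        if len(xc) < 2:
            raise LdaFitError(
                f"class {c} ({CLASS_NAMES.get(c, '?')}) has {len(xc)} sample(s); need >= 2"
            )
        means[i] = xc.mean(axis=0)
        dev = xc - means[i]
        scatter += dev.T @ dev
    cov = scatter / (len(y) - len(classes))
    tr = float(np.trace(cov))
    if tr <= 0 or np.linalg.cond(cov) > COND_LIMIT:
        cov = cov + RIDGE_SCALE * (tr / cov.shape[0] if tr > 0 else 1.0) * np.eye(
            cov.shape[0]
        )
    priors = np.array([(y == c).mean() for c in classes])
    return ColorClassModel(classes, means, cov, priors)


def lda_discriminants(model: ColorClassModel, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, float)
    siw = np.linalg.solve(model.pooled_covariance, model.class_means.T)  # (3, K)
    return x @ siw - 0.5 * np.sum(model.class_means.T * siw, axis=0) + np.log(
        model.priors
    )


def predict_lda(model: ColorClassModel, x: np.ndarray) -> tuple[int, np.ndarray]:
    """Predicted class code and per-class posteriors (softmax of deltas).

    Ties break toward the lower class code; ``model.classes`` is sorted
    ascending, so the first argmax wins.
    """
    x = np.asarray(x, float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"non-finite predictor vector {x}")
    delta = lda_discriminants(model, x)
    e = np.exp(delta - delta.max())
    return int(model.classes[int(np.argmax(delta))]), e / e.sum()


# --------------------------------------------------------------------------
# Cross-validation and accuracy
# --------------------------------------------------------------------------


def _confusion_from_pairs(
    true_codes: np.ndarray, pred_codes: np.ndarray
) -> ConfusionMatrix:
    present = set(true_codes.tolist()) | set(pred_codes.tolist())
    codes = tuple(c for c in PRINTED_CODES if c in present) + tuple(
        sorted(present - set(PRINTED_CODES))
    )
    idx = {c: i for i, c in enumerate(codes)}
    counts = np.zeros((len(codes), len(codes)), dtype=int)
    for t, p in zip(true_codes, pred_codes):
        counts[idx[p], idx[t]] += 1
    return ConfusionMatrix(classes=codes, counts=counts)


def cross_validate(
    samples: list[ColorSample],
    scheme: str = "loo",
    k: int = 5,
    seed: int | None = None,
) -> ConfusionMatrix:
    """Cross-validated confusion matrix (rows predicted, columns real).

    Leave-one-out by default (deterministic). ``scheme="kfold"`` uses k
    folds shuffled by a mandatory ``seed``. A training fold that loses a
    class entirely simply trains without it (that class cannot be
    predicted in the fold); it never crashes.
    """
    labelled = [s for s in samples if s.true_class is not None]
    n = len(labelled)
    if scheme == "loo":
        folds = [[i] for i in range(n)]
    elif scheme == "kfold":
        if seed is None:
            raise ValueError("kfold scheme requires a seed")
        order = np.random.default_rng(seed).permutation(n)
        folds = [order[i::k].tolist() for i in range(k)]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    true_codes, pred_codes = [], []
    for fold in folds:
        hold = set(fold)
        train = [s for i, s in enumerate(labelled) if i not in hold]
        # a fold may lose a class (entirely, or below the 2-sample fit
        # minimum): that fold trains without it and cannot predict it
        tally: dict[int, int] = {}
        for s in train:
            tally[s.true_class] = tally.get(s.true_class, 0) + 1
        train = [s for s in train if tally[s.true_class] >= 2]
        model = fit_lda(train)
        for i in fold:
            x = np.asarray(labelled[i].mean_rgb, float)
            pred_codes.append(predict_lda(model, x)[0])
            true_codes.append(labelled[i].true_class)
    return _confusion_from_pairs(np.array(true_codes), np.array(pred_codes))


def class_accuracy(cm: ConfusionMatrix, class_code: int) -> int:
    """Per-class accuracy as an integer percent, truncated toward zero.

    100 * diagonal / column-sum for the class's column (real class), with
    the fractional part discarded — the convention consistent with printed
    pairs like 197/202 -> 97 and 28/39 -> 71.
    """
    i = cm.class_index(class_code)
    col = int(cm.counts[:, i].sum())
    if col == 0:
        raise UndefinedAccuracyError(f"no reference samples for class {class_code}")
    return int(100 * int(cm.counts[i, i]) // col)


def field_reference_matrix() -> ConfusionMatrix:
    """The 500-image field validation confusion counts as a ConfusionMatrix."""
    return ConfusionMatrix(classes=tuple(PRINTED_CODES), counts=FIELD_REFERENCE_CONFUSION.copy())


# --------------------------------------------------------------------------
# TSV I/O and reports
# --------------------------------------------------------------------------

SAMPLE_COLUMNS = ["image_id", "mean_R", "mean_G", "mean_B", "true_class"]


def write_samples_tsv(path: str | Path, samples: list[ColorSample]) -> None:
    rows = [
        {
            "image_id": s.image_id,
            "mean_R": s.mean_rgb[0],
            "mean_G": s.mean_rgb[1],
            "mean_B": s.mean_rgb[2],
            "true_class": "" if s.true_class is None else s.true_class,
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=SAMPLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_samples_tsv(path: str | Path) -> list[ColorSample]:
    df = pd.read_csv(path, sep="\t", dtype={"image_id": str})
    out = []
    for row in df.itertuples():
        tc = getattr(row, "true_class", None)
        tc = None if tc is None or pd.isna(tc) else int(tc)
        out.append(
            ColorSample(
                image_id=str(row.image_id),
                mean_rgb=(float(row.mean_R), float(row.mean_G), float(row.mean_B)),
                true_class=tc,
            )
        )
    return out


def write_confusion_tsv(path: str | Path, cm: ConfusionMatrix) -> None:
    names = [CLASS_NAMES[c] for c in cm.classes]
    df = pd.DataFrame(cm.counts, index=names, columns=names)
    df.index.name = "predicted\\real"
    df.to_csv(path, sep="\t")


def accuracy_report(cm: ConfusionMatrix) -> str:
    """Plain-text per-class report: reference count, correct, truncated %."""
    lines = ["class\tn_reference\tn_correct\taccuracy_pct"]
    for c in cm.classes:
        i = cm.class_index(c)
        col = int(cm.counts[:, i].sum())
        correct = int(cm.counts[i, i])
        pct = str(class_accuracy(cm, c)) if col else "NA"
        lines.append(f"{CLASS_NAMES.get(c, c)}\t{col}\t{correct}\t{pct}")
    return "\n".join(lines) + "\n"
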