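"""Classification and statistics for donor-level fingerprint cohorts.

Fisher linear discriminant with equal priors and pooled covariance,
diagnostic-test metrics, pooled-variance two-tailed t tests with a
pairwise p-value matrix, covariance confidence ellipses (with numeric
overlap area), blind-validation bookkeeping, and the log-log power-law
exponent fit used for small-angle scattering curves.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "Cohort",
    "LdaModel",
    "ConfusionCounts",
    "Ellipse",
    "PowerLawFit",
    "lda_fit",
    "classify",
    "metrics",
    "student_t",
    "pairwise_pvalue_matrix",
    "confidence_ellipse",
    "ellipse_overlap_area",
    "blind_validation",
    "powerlaw_exponent",
]

NEGATIVE_CLASS = "NOP"


@dataclass
class Cohort:
    """Donor-level 2-D fingerprints with class labels.

    One point per donor; replicates must be averaged beforehand.
    """

    points: np.ndarray          # (n, 2)
    labels: np.ndarray          # (n,) class names
    donor_ids: np.ndarray       # (n,)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.donor_ids = np.asarray(self.donor_ids, dtype=object)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be (n, 2)")
        if len(self.labels) != len(self.points) or len(self.donor_ids) != len(
            self.points
        ):
            raise ValueError("labels/donor_ids length mismatch")
        if len(set(self.donor_ids)) != len(self.donor_ids):
            raise ValueError("duplicate donor_ids (average replicates first)")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))

    def subset(self, class_names) -> "Cohort":
        mask = np.isin(self.labels, list(class_names))
        return Cohort(self.points[mask], self.labels[mask], self.donor_ids[mask])

    def feature(self, index: int, class_name: str) -> np.ndarray:
        return self.points[self.labels == class_name, index]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "donor_id": self.donor_ids,
                "class": self.labels,
                "starting_position_mm": self.points[:, 0],
                "levitating_area": self.points[:, 1],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Cohort":
        return cls(
            points=df[["starting_position_mm", "levitating_area"]].to_numpy(),
            labels=df["class"].to_numpy(),
            donor_ids=df["donor_id"].to_numpy(),
        )


@dataclass(frozen=True)
class LdaModel:
    """Fisher discriminant: decision boundary is the line w.x = threshold."""

    weight_vector: np.ndarray
    threshold: float
    negative_class: str
    positive_class: str
    class_means: dict = field(compare=False, default_factory=dict)
    pooled_covariance: np.ndarray | None = field(compare=False, default=None)

    def decision_values(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.weight_vector - self.threshold

    def digest(self) -> str:
        payload = np.concatenate([self.weight_vector, [self.threshold]])
        return hashlib.sha256(payload.tobytes()).hexdigest()[:16]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion table; the negative class is the healthy reference."""

    true_negative: int
    false_positive: int
    false_negative: int
    true_positive: int

    def __post_init__(self) -> None:
        for name in ("true_negative", "false_positive", "false_negative", "true_positive"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total(self) -> int:
        return (
            self.true_negative
            + self.false_positive
            + self.false_negative
            + self.true_positive
        )


def lda_fit(
    cohort: Cohort,
    positive_class: str,
    negative_class: str = NEGATIVE_CLASS,
) -> LdaModel:
    """Fisher LDA between the negative reference and one disease class.

    w = Sigma_pooled^-1 (mu_pos - mu_neg); the threshold sits at the
    midpoint of the projected class means (equal priors).  A singular
    pooled covariance is ridge-regularized with eps = 1e-8 * trace.
    """
    x0 = cohort.points[cohort.labels == negative_class]
    x1 = cohort.points[cohort.labels == positive_class]
    if len(x0) < 2 or len(x1) < 2:
        raise ValueError("each class needs >= 2 donors")
    mu0, mu1 = x0.mean(axis=0), x1.mean(axis=0)
    s0 = np.cov(x0, rowvar=False, ddof=1) * (len(x0) - 1)
    s1 = np.cov(x1, rowvar=False, ddof=1) * (len(x1) - 1)
    pooled = (s0 + s1) / (len(x0) + len(x1) - 2)
    try:
        w = np.linalg.solve(pooled, mu1 - mu0)
        if not np.all(np.isfinite(w)) or np.linalg.cond(pooled) > 1e12:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        eps = 1e-8 * np.trace(pooled)
        if eps <= 0:
            eps = 1e-12
        warnings.warn("singular pooled covariance; ridge-regularized", stacklevel=2)
        pooled = pooled + eps * np.eye(2)
        w = np.linalg.solve(pooled, mu1 - mu0)
    threshold = float(w @ (mu0 + mu1) / 2.0)
    return LdaModel(
        weight_vector=w,
        threshold=threshold,
        negative_class=negative_class,
        positive_class=positive_class,
        class_means={negative_class: mu0, positive_class: mu1},
        pooled_covariance=pooled,
    )


def classify(model: LdaModel, points: np.ndarray, true_labels=None):
    """Assign classes by the sign of w.x - threshold.

    Returns predicted labels; when ``true_labels`` is given, also a
    :class:`ConfusionCounts` tallied against them.
    """
    dv = model.decision_values(points)
    predicted = np.where(dv > 0, model.positive_class, model.negative_class)
    if true_labels is None:
        return predicted
    true_labels = np.asarray(true_labels, dtype=object)
    is_pos = true_labels == model.positive_class
    is_neg = true_labels == model.negative_class
    if not np.all(is_pos | is_neg):
        extra = sorted(set(true_labels) - {model.positive_class, model.negative_class})
        raise ValueError(f"labels outside model classes: {extra}")
    pred_pos = predicted == model.positive_class
    counts = ConfusionCounts(
        true_negative=int(np.sum(is_neg & ~pred_pos)),
        false_positive=int(np.sum(is_neg & pred_pos)),
        false_negative=int(np.sum(is_pos & ~pred_pos)),
        true_positive=int(np.sum(is_pos & pred_pos)),
    )
    return predicted, counts


def metrics(confusion: ConfusionCounts) -> dict:
    """Diagnostic-test metrics as proportions in [0, 1].

    specificity = TN / (TN + FP), sensitivity = TP / (TP + FN),
    accuracy = (TN + TP) / total.  A zero denominator yields ``None``
    for that metric rather than NaN.
    """
    tn, fp = confusion.true_negative, confusion.false_positive
    fn, tp = confusion.false_negative, confusion.true_positive

    def ratio(num, den):
        return num / den if den > 0 else None

    return {
        "specificity": ratio(tn, tn + fp),
        "sensitivity": ratio(tp, tp + fn),
        "accuracy": ratio(tn + tp, confusion.total),
    }


def student_t(group_a, group_b) -> dict:
    """Two-sample pooled-variance two-tailed Student's t test.

    Returns ``{"t": ..., "p": ..., "dof": ...}``.  Degenerate inputs
    (zero pooled variance) give p = 1 for equal means and p = 0
    otherwise, with a ``degenerate`` flag.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs >= 2 values")
    dof = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / dof
    dmean = a.mean() - b.mean()
    if sp2 == 0.0:
        if dmean == 0.0:
            return {"t": 0.0, "p": 1.0, "dof": dof, "degenerate": True}
        return {
            "t": np.inf if dmean > 0 else -np.inf,
            "p": 0.0,
            "dof": dof,
            "degenerate": True,
        }
    t = dmean / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * sps.t.sf(abs(t), dof)
    return {"t": float(t), "p": float(p), "dof": dof, "degenerate": False}


def pairwise_pvalue_matrix(
    cohort: Cohort, feature_index: int = 0, bonferroni: bool = False
) -> pd.DataFrame:
    """Symmetric matrix of t-test p-values over all class pairs.

    Diagonal entries are 1 by convention.  Raw p-values by default;
    ``bonferroni`` multiplies by the number of pairs (capped at 1).
    """
    classes = cohort.classes
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    n_pairs = len(classes) * (len(classes) - 1) // 2
    mat = pd.DataFrame(np.ones((len(classes), len(classes))), index=classes, columns=classes)
    for i, ci in enumerate(classes):
        for cj in classes[i + 1 :]:
            res = student_t(
                cohort.feature(feature_index, ci), cohort.feature(feature_index, cj)
            )
            p = min(res["p"] * n_pairs, 1.0) if bonferroni else res["p"]
            mat.loc[ci, cj] = p
            mat.loc[cj, ci] = p
    return mat


@dataclass(frozen=True)
class Ellipse:
    """Covariance confidence ellipse: center, semi-axes, orientation (rad)."""

    center: np.ndarray
    semi_axes: np.ndarray       # (major, minor)
    orientation: float          # angle of the major axis vs x, in (-pi/2, pi/2]
    level: float
    degenerate: bool = False


def confidence_ellipse(points: np.ndarray, level: float = 0.95) -> Ellipse:
    """Mean-centered covariance ellipse at the chi-square(2) quantile.

    Semi-axes are sqrt(eigenvalue * chi2_quantile); a rank-deficient
    covariance is flagged degenerate (line segment).
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 3:
        raise ValueError("need >= 3 points")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    center = points.mean(axis=0)
    cov = np.cov(points, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    q = sps.chi2.ppf(level, df=2)
    degenerate = bool(evals[-1] <= 1e-12 * max(evals[0], 1.0))
    semi = np.sqrt(np.clip(evals, 0.0, None) * q)
    major = evecs[:, 0]
    angle = float(np.arctan2(major[1], major[0]))
    if angle <= -np.pi / 2:
        angle += np.pi
    elif angle > np.pi / 2:
        angle -= np.pi
    return Ellipse(
        center=center,
        semi_axes=semi,
        orientation=angle,
        level=level,
        degenerate=degenerate,
    )


def _ellipse_polygon(e: Ellipse, resolution: int = 256):
    from shapely.geometry import Polygon

    t = np.linspace(0, 2 * np.pi, resolution, endpoint=False)
    xy = np.stack([e.semi_axes[0] * np.cos(t), e.semi_axes[1] * np.sin(t)])
    c, s = np.cos(e.orientation), np.sin(e.orientation)
    rot = np.array([[c, -s], [s, c]])
    pts = (rot @ xy).T + e.center
    return Polygon(pts)


def ellipse_overlap_area(a: Ellipse, b: Ellipse, resolution: int = 512) -> float:
    """Numeric intersection area of two confidence ellipses."""
    pa = _ellipse_polygon(a, resolution)
    pb = _ellipse_polygon(b, resolution)
    return float(pa.intersection(pb).area)


def blind_validation(
    model: LdaModel,
    holdout: Cohort,
    training_donor_ids,
) -> dict:
    """Classify a held-out cohort, enforcing donor disjointness.

    Returns metrics plus a provenance record binding the model digest
    to a digest of the holdout data.
    """
    overlap = set(training_donor_ids) & set(holdout.donor_ids)
    if overlap:
        raise ValueError(f"holdout overlaps training donors: {sorted(overlap)}")
    _, counts = classify(model, holdout.points, holdout.labels)
    m = metrics(counts)
    holdout_digest = hashlib.sha256(
        holdout.points.tobytes()
        + json.dumps(sorted(map(str, holdout.donor_ids))).encode()
    ).hexdigest()[:16]
    return {
        "metrics": m,
        "confusion": counts,
        "provenance": {"model": model.digest(), "holdout": holdout_digest},
    }


@dataclass(frozen=True)
class PowerLawFit:
    exponent: float             # D in I(q) ~ q^-D
    stderr: float
    intercept: float


def powerlaw_exponent(q, intensity) -> PowerLawFit:
    """Power-law exponent from a least-squares line in log-log space.

    Fits log I = log A - D log q and returns D (the negated slope) with
    its standard error.
    """
    q = np.asarray(q, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if len(q) < 5:
        raise ValueError("need >= 5 points")
    if np.any(q <= 0) or np.any(intensity <= 0):
        raise ValueError("q and intensities must be positive")
    res = sps.linregress(np.log(q), np.log(intensity))
    return PowerLawFit(
        exponent=float(-res.slope),
        stderr=float(res.stderr),
        intercept=float(res.intercept),
    )
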