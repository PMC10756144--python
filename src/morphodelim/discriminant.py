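"""Confirmatory analysis: two-class LDA, cross-validation, and numeric keys.

The species hypothesis produced by the exploratory stage is tested with a
Fisher linear discriminant on individual specimens, validated by
leave-one-out cross-validation (each specimen classified by a model fitted
without it).  Unplaced specimens — typically name-bearing types — are run as
*wild-cards*: excluded from all fitting and classified post hoc with
Gaussian pooled-covariance posterior probabilities.  Backward stepwise
character reduction produces compact numeric identification keys; the two
published keys (the three-character worker key D3 and the two-character gyne
key) are packaged with their printed coefficients and class score ranges.

Score convention for fitted functions: the discriminant direction
w = S_pooled^-1 (mu_pos - mu_neg) is rescaled to unit pooled within-class
score SD and offset so the two class score means are symmetric about zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import CharacterSystem, MorphRecord, MorphometryError
from .clustering import as_frame

__all__ = [
    "DiscriminantFunction",
    "ConfusionMatrix",
    "fit_lda",
    "score",
    "loo_crossvalidate",
    "wildcard_classify",
    "backward_stepwise",
    "published_keys",
]

_COMMON_ALIASES = {"CWB": "CW", "CLYD": "CLSPD"}


@dataclass
class DiscriminantFunction:
    """A linear score Σ coef_i · x_i + offset separating two classes.

    ``units`` gives the measurement units the coefficients expect ("um" or
    "mm"); the evaluator converts from the caller's units automatically.
    ``class_stats`` maps each class label to its score mean, observed range
    and sample size where known.
    """

    name: str
    characters: list[str]
    coefficients: np.ndarray
    offset: float
    units: str = "um"
    class_pos: Optional[str] = None
    class_neg: Optional[str] = None
    class_stats: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.characters) != self.coefficients.size:
            raise MorphometryError("coefficient/character length mismatch")
        if self.units not in ("um", "mm"):
            raise MorphometryError(f"unknown units {self.units!r}")

    def evaluate(
        self,
        values: MorphRecord | Mapping[str, float],
        units: Optional[str] = None,
        system: Optional[CharacterSystem] = None,
    ) -> float:
        return score(self, values, units=units, system=system)

    def classify(self, values, units: Optional[str] = None, system=None) -> str:
        s = self.evaluate(values, units=units, system=system)
        return self.class_pos if s >= 0 else self.class_neg

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "name": self.name,
            "characters": self.characters,
            "coefficients": self.coefficients.tolist(),
            "offset": self.offset,
            "units": self.units,
            "class_pos": self.class_pos,
            "class_neg": self.class_neg,
            "class_stats": self.class_stats,
            "metadata": self.metadata,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "DiscriminantFunction":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(text)
        return cls(
            name=d["name"], characters=list(d["characters"]),
            coefficients=np.array(d["coefficients"], float), offset=d["offset"],
            units=d["units"], class_pos=d.get("class_pos"),
            class_neg=d.get("class_neg"), class_stats=d.get("class_stats", {}),
            metadata=d.get("metadata", {}),
        )


@dataclass
class ConfusionMatrix:
    """Class-by-class LOO counts: rows = true class, columns = predicted."""

    counts: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def n_per_class(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def percent_correct(self) -> pd.Series:
        diag = pd.Series(np.diag(self.counts), index=self.counts.index)
        return (100.0 * diag / self.n_per_class).round(1)

    @property
    def overall_accuracy(self) -> float:
        return float(np.diag(self.counts).sum() / self.counts.to_numpy().sum())


# ---------------------------------------------------------------------------


def _prep(X, labels) -> tuple[pd.DataFrame, pd.Series]:
    frame = as_frame(X)
    if isinstance(labels, Mapping):
        y = pd.Series({str(k): v for k, v in labels.items()})
        missing = [i for i in frame.index if str(i) not in y.index]
        if missing:
            raise MorphometryError(f"items without labels: {missing[:5]}")
        y = y.loc[[str(i) for i in frame.index]]
        y.index = frame.index
    else:
        y = pd.Series(list(labels), index=frame.index)
    classes = sorted(y.unique())
    if len(classes) != 2:
        raise MorphometryError(f"two-class LDA requires exactly 2 classes, got {classes}")
    return frame, y


def _pooled(
    X: np.ndarray, y: np.ndarray, classes: Sequence[str]
) -> tuple[dict[str, np.ndarray], np.ndarray, dict[str, int]]:
    mus, ns = {}, {}
    p = X.shape[1]
    S = np.zeros((p, p))
    for c in classes:
        sub = X[y == c]
        ns[c] = sub.shape[0]
        mus[c] = sub.mean(axis=0)
        S += (sub - mus[c]).T @ (sub - mus[c])
    dof = sum(ns.values()) - len(classes)
    if dof <= 0:
        raise MorphometryError("not enough items to estimate the pooled covariance")
    return mus, S / dof, ns


def fit_lda(
    X,
    labels,
    priors: str = "equal",
    positive_class: Optional[str] = None,
    name: str = "fitted",
) -> DiscriminantFunction:
    """Fisher two-class LDA with unit pooled within-class score SD.

    The direction is w = S_pooled^-1 (mu_pos − mu_neg); the offset puts the
    two class score means symmetric about zero.  By default the
    lexicographically first class label scores positive; override with
    ``positive_class``.
    """
    frame, y = _prep(X, labels)
    classes = sorted(y.unique())
    if positive_class is None:
        positive_class = classes[0]
    if positive_class not in classes:
        raise MorphometryError(f"positive_class {positive_class!r} not among {classes}")
    negative_class = [c for c in classes if c != positive_class][0]
    Xa, ya = frame.to_numpy(float), y.to_numpy()
    p = Xa.shape[1]
    for c in classes:
        if (ya == c).sum() < p + 1:
            raise MorphometryError(
                f"class {c!r} has {(ya == c).sum()} items; needs >= {p + 1} "
                f"for {p} characters — reduce the character set"
            )
    mus, S, ns = _pooled(Xa, ya, classes)
    diff = mus[positive_class] - mus[negative_class]
    try:
        w = np.linalg.solve(S, diff)
    except np.linalg.LinAlgError as exc:
        raise MorphometryError(
            "pooled within-class covariance is singular; reduce the character set"
        ) from exc
    s2 = float(w @ S @ w)
    degenerate = s2 <= 0 or not np.isfinite(s2) or np.allclose(diff, 0)
    if not degenerate:
        w = w / np.sqrt(s2)
    offset = -float(w @ (mus[positive_class] + mus[negative_class]) / 2.0)
    scores = Xa @ w + offset
    stats = {}
    for c in classes:
        sc = scores[ya == c]
        stats[c] = {
            "mean": float(sc.mean()), "sd": float(sc.std(ddof=1)) if sc.size > 1 else 0.0,
            "range": [float(sc.min()), float(sc.max())], "n": int(ns[c]),
        }
    return DiscriminantFunction(
        name=name, characters=list(map(str, frame.columns)), coefficients=w,
        offset=offset, units="um", class_pos=positive_class, class_neg=negative_class,
        class_stats=stats,
        metadata={"priors": priors, "degenerate": bool(degenerate),
                  "pooled_score_sd": 1.0 if not degenerate else 0.0},
    )


def _lookup(values, char: str, system: Optional[CharacterSystem]) -> float:
    if isinstance(values, MorphRecord):
        return values.get(char, system)
    if char in values:
        return float(values[char])
    for a, b in _COMMON_ALIASES.items():
        if char == a and b in values:
            return float(values[b])
        if char == b and a in values:
            return float(values[a])
    raise MorphometryError(f"missing character {char!r} for discriminant score")


def score(
    f: DiscriminantFunction,
    values: MorphRecord | Mapping[str, float],
    units: Optional[str] = None,
    system: Optional[CharacterSystem] = None,
) -> float:
    """Evaluate Σ coef_i · x_i + offset, converting units if needed.

    ``units`` names the units of ``values``; a MorphRecord is always µm
    (the storage convention), a plain mapping defaults to the key's units.
    """
    if units is None:
        units = "um" if isinstance(values, MorphRecord) else f.units
    factor = 1.0
    if units == "um" and f.units == "mm":
        factor = 1e-3
    elif units == "mm" and f.units == "um":
        factor = 1e3
    x = np.array([_lookup(values, c, system) for c in f.characters]) * factor
    return float(f.coefficients @ x + f.offset)


def loo_crossvalidate(X, labels, priors: str = "equal") -> ConfusionMatrix:
    """Leave-one-out CV: each item classified by an LDA fitted without it."""
    frame, y = _prep(X, labels)
    classes = sorted(y.unique())
    preds = {}
    skipped = []
    for item in frame.index:
        rest = frame.drop(index=item)
        yrest = y.drop(index=item)
        try:
            post = _posteriors(
                rest.to_numpy(float), yrest.to_numpy(), classes,
                frame.loc[[item]].to_numpy(float), priors,
            )
        except MorphometryError as exc:
            skipped.append((str(item), str(exc)))
            continue
        preds[item] = classes[int(np.argmax(post[0]))]
    counts = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for item, pred in preds.items():
        counts.loc[y[item], pred] += 1
    return ConfusionMatrix(
        counts=counts,
        metadata={"priors": priors, "skipped_folds": skipped,
                  "predictions": {str(k): v for k, v in preds.items()}},
    )


def _posteriors(
    Xtr: np.ndarray, ytr: np.ndarray, classes: Sequence[str],
    Q: np.ndarray, priors: str,
) -> np.ndarray:
    mus, S, ns = _pooled(Xtr, ytr, classes)
    try:
        Sinv = np.linalg.inv(S)
    except np.linalg.LinAlgError as exc:
        raise MorphometryError("singular pooled covariance") from exc
    n_total = sum(ns.values())
    logp = np.empty((Q.shape[0], len(classes)))
    for j, c in enumerate(classes):
        prior = 0.5 if priors == "equal" else ns[c] / n_total
        d = Q - mus[c]
        logp[:, j] = -0.5 * np.einsum("ij,jk,ik->i", d, Sinv, d) + np.log(prior)
    logp -= logp.max(axis=1, keepdims=True)
    post = np.exp(logp)
    return post / post.sum(axis=1, keepdims=True)


def wildcard_classify(
    X_labeled, labels, queries, priors: str = "equal"
) -> pd.DataFrame:
    """Posterior class probabilities for queries excluded from fitting.

    Gaussian class-conditional densities with the pooled within-class
    covariance; probabilities sum to 1 per query.  A query whose id is also
    present in the training set is rejected (it would not be a wild-card).
    """
    frame, y = _prep(X_labeled, labels)
    qframe = as_frame(queries)
    overlap = set(map(str, frame.index)) & set(map(str, qframe.index))
    if overlap:
        raise MorphometryError(
            f"query item(s) also present in training data: {sorted(overlap)[:5]}"
        )
    missing = [c for c in frame.columns if c not in qframe.columns]
    if missing:
        raise MorphometryError(f"queries lack character(s) {missing}")
    classes = sorted(y.unique())
    post = _posteriors(
        frame.to_numpy(float), y.to_numpy(), classes,
        qframe[frame.columns].to_numpy(float), priors,
    )
    return pd.DataFrame(post, index=qframe.index, columns=classes)


def backward_stepwise(
    X, labels, target_k: int, priors: str = "equal",
    positive_class: Optional[str] = None,
) -> DiscriminantFunction:
    """Backward character elimination maximizing LOO accuracy.

    At each step the character whose removal gives the highest leave-one-out
    accuracy is dropped (ties broken by the smallest absolute standardized
    coefficient in the current fit), until ``target_k`` characters remain.
    The returned function carries the selection trace in its metadata.
    """
    frame, y = _prep(X, labels)
    chars = list(frame.columns)
    if not 1 <= target_k <= len(chars):
        raise MorphometryError(f"target_k must be in [1, {len(chars)}]")
    trace = []
    while len(chars) > target_k:
        current = fit_lda(frame[chars], y, priors=priors,
                          positive_class=positive_class)
        sds = frame[chars].std(ddof=1).to_numpy()
        std_coef = np.abs(current.coefficients * sds)
        best = None  # (accuracy, -std_coef_rank, char)
        for i, c in enumerate(chars):
            remaining = [x for x in chars if x != c]
            acc = loo_crossvalidate(frame[remaining], y, priors=priors).overall_accuracy
            key = (acc, -std_coef[i])
            if best is None or key > best[0]:
                best = (key, c)
        removed = best[1]
        trace.append({"removed": removed, "loo_accuracy": best[0][0],
                      "n_remaining": len(chars) - 1})
        chars = [c for c in chars if c != removed]
    final = fit_lda(frame[chars], y, priors=priors, positive_class=positive_class,
                    name=f"stepwise_k{target_k}")
    final.metadata["selection_trace"] = trace
    final.metadata["loo_accuracy"] = loo_crossvalidate(
        frame[chars], y, priors=priors
    ).overall_accuracy
    return final


def published_keys() -> list[DiscriminantFunction]:
    """The packaged numeric identification keys with printed constants.

    * ``D3`` — worker key on ML, CWB, CLYW (µm):
      0.060·ML − 0.047·CWB − 0.125·CLYW − 4.582; positive scores indicate
      *S. fugax* (individual means ±1.713).
    * ``gyne_key`` — gyne key on CW, CLSPD (mm):
      35.24·CW − 58.91·CLSPD − 22.59; positive scores indicate *S. fugax*.
    """
    d3 = DiscriminantFunction(
        name="D3",
        characters=["ML", "CWB", "CLYW"],
        coefficients=np.array([0.060, -0.047, -0.125]),
        offset=-4.582,
        units="um",
        class_pos="fugax",
        class_neg="juliae",
        class_stats={
            "fugax": {"mean": 1.713, "range": [-1.722, 4.954], "n": 137},
            "juliae": {"mean": -1.713, "range": [-4.698, 0.454], "n": 62},
        },
        metadata={
            "origin": "published",
            "level": "individual",
            "nest_sample_stats": {
                "fugax": {"mean": 1.776, "range": [0.931, 3.374], "n": 33},
                "juliae": {"mean": -1.678, "range": [-3.477, 0.010], "n": 17},
            },
        },
    )
    gyne = DiscriminantFunction(
        name="gyne_key",
        characters=["CW", "CLSPD"],
        coefficients=np.array([35.24, -58.91]),
        offset=-22.59,
        units="mm",
        class_pos="fugax",
        class_neg="juliae",
        class_stats={
            "fugax": {"range": [0.47, 4.32], "n": 32},
            "juliae": {"range": [-2.73, -0.47], "n": 12},
        },
        metadata={"origin": "published", "level": "individual"},
    )
    return [d3, gyne]
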