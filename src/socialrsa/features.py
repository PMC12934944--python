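"""Non-neural representation sources: ratings, one-hot judgments, model exports.

Behavioral representations summarize how raters categorized each video's
social interaction as friendly, neutral, or adversarial: the per-video
rating counts are normalized to proportions, which preserves the ambiguity
of split judgments.  Post-scan single-subject judgments are one-hot
vectors.  Candidate computational models (e.g. a bottom-up graph network
or a generative inverse planner) enter the pipeline as opaque per-video
feature vectors loaded from delimited text.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "RepresentationSet",
    "EmptyRatingError",
    "rating_representation",
    "rating_representation_set",
    "onehot_representation",
    "onehot_representation_set",
    "load_representations",
    "save_representations",
]

#: fixed category order for all rating-derived representations
CATEGORIES: tuple[str, str, str] = ("friendly", "neutral", "adversarial")


class EmptyRatingError(ValueError):
    """All rating counts are zero for a video."""


@dataclass(frozen=True)
class RepresentationSet:
    """Ordered condition labels with one feature vector per condition."""

    labels: tuple[str, ...]
    vectors: np.ndarray

    def __post_init__(self) -> None:
        vectors = np.asarray(self.vectors, dtype=float)
        object.__setattr__(self, "vectors", vectors)
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        if vectors.ndim != 2:
            raise ValueError("representation vectors must form a 2-D matrix")
        if vectors.shape[0] != len(self.labels):
            raise ValueError("label count does not match number of vectors")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("condition labels must be unique")

    @property
    def n_conditions(self) -> int:
        return len(self.labels)

    @property
    def n_features(self) -> int:
        return self.vectors.shape[1]

    def subset(self, indices) -> "RepresentationSet":
        indices = np.asarray(indices, dtype=int)
        return RepresentationSet(
            tuple(self.labels[i] for i in indices), self.vectors[indices]
        )


def rating_representation(counts) -> np.ndarray:
    """Normalize (friendly, neutral, adversarial) counts to proportions.

    Example: counts (8, 0, 2) -> (0.8, 0.0, 0.2).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (len(CATEGORIES),):
        raise ValueError(f"expected {len(CATEGORIES)} category counts")
    if np.any(counts < 0) or not np.all(counts == np.floor(counts)):
        raise ValueError("rating counts must be non-negative integers")
    total = counts.sum()
    if total == 0:
        raise EmptyRatingError("all rating counts are zero")
    return counts / total


def rating_representation_set(table: pd.DataFrame) -> RepresentationSet:
    """Build proportion representations from a counts table.

    The table has one row per video; the first column (or the index) holds
    the video label and the remaining columns are counts in the fixed
    category order.
    """
    df = table.copy()
    if not set(CATEGORIES).issubset(df.columns):
        raise ValueError(f"counts table must have columns {CATEGORIES}")
    labels = tuple(map(str, df.index)) if df.index.name or not isinstance(
        df.index, pd.RangeIndex
    ) else tuple(map(str, df.iloc[:, 0]))
    if isinstance(df.index, pd.RangeIndex) and "video" in df.columns:
        labels = tuple(map(str, df["video"]))
    vectors = np.stack(
        [rating_representation(row) for row in df[list(CATEGORIES)].to_numpy()]
    )
    return RepresentationSet(labels, vectors)


def onehot_representation(label: str) -> np.ndarray:
    """One-hot vector for a single categorical judgment."""
    if label not in CATEGORIES:
        raise ValueError(
            f"unknown category {label!r}; expected one of {CATEGORIES}"
        )
    vec = np.zeros(len(CATEGORIES))
    vec[CATEGORIES.index(label)] = 1.0
    return vec


def onehot_representation_set(labels, judgments) -> RepresentationSet:
    """One-hot representations for per-video categorical judgments."""
    vectors = np.stack([onehot_representation(j) for j in judgments])
    return RepresentationSet(tuple(labels), vectors)


def load_representations(path, sep: str = "\t") -> RepresentationSet:
    """Read a delimited table: one row per condition, first column = label."""
    rows: list[tuple[str, list[float]]] = []
    with open(path) as fh:
        header = fh.readline()
        if not header:
            raise ValueError(f"{path}: empty representation file")
        width = None
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split(sep)
            if width is None:
                width = len(parts)
            elif len(parts) != width:
                raise ValueError(
                    f"{path}:{lineno}: ragged row ({len(parts)} fields, "
                    f"expected {width})"
                )
            try:
                values = [float(v) for v in parts[1:]]
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: {err}") from None
            rows.append((parts[0], values))
    labels = [r[0] for r in rows]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise ValueError(f"{path}: duplicate condition labels {sorted(dupes)}")
    return RepresentationSet(tuple(labels), np.array([r[1] for r in rows]))


def save_representations(reps: RepresentationSet, path, sep: str = "\t") -> None:
    df = pd.DataFrame(
        reps.vectors,
        index=list(reps.labels),
        columns=[f"f{k}" for k in range(reps.n_features)],
    )
    df.index.name = "condition"
    df.to_csv(path, sep=sep)
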