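"""Representational dissimilarity matrices and rank-based comparisons.

The central currency of the pipeline is the RDM: a symmetric
condition-by-condition matrix of correlation distances (1 - Pearson r,
hence values in [0, 2]) with a zero diagonal.  RDMs from different sources
(neural patterns, model embeddings, behavioral ratings) are compared by
Spearman rank correlation of their strictly-upper-triangle vectors; a
model's *unique* contribution is measured by the semi-partial (part)
Spearman correlation, where the predictor RDM is residualized on the
competing model RDMs while the target (neural) RDM is left intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RDM",
    "RDMVector",
    "RSAStatistic",
    "DegenerateRepresentationError",
    "representation_rdm",
    "correlation_distance_matrix",
    "rdm_vector",
    "rdm_from_vector",
    "pair_index",
    "spearman_rsa",
    "semipartial_spearman",
    "variance_partition",
    "save_rdm",
    "load_rdm",
]

#: numerical tolerance for symmetry and the [0, 2] distance bounds
_TOL = 1e-9


class DegenerateRepresentationError(ValueError):
    """A feature vector or pattern has zero variance, so 1 - Pearson is undefined."""


@dataclass(frozen=True)
class RDM:
    """Symmetric correlation-distance matrix over labelled conditions."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        n = len(self.labels)
        if values.shape != (n, n):
            raise ValueError(
                f"RDM values have shape {values.shape}, expected ({n}, {n}) "
                f"for {n} labels"
            )
        if len(set(self.labels)) != n:
            raise ValueError("RDM labels must be unique")
        if not np.all(np.isfinite(values)):
            raise ValueError("RDM contains non-finite entries")
        if np.abs(np.diag(values)).max(initial=0.0) > _TOL:
            raise ValueError("RDM diagonal must be zero")
        if n and np.abs(values - values.T).max() > _TOL:
            raise ValueError("RDM must be symmetric within tolerance")
        if n and (values.min() < -_TOL or values.max() > 2.0 + _TOL):
            raise ValueError(
                "RDM entries outside [0, 2]: not a correlation distance"
            )
        # canonicalize: exact symmetry and an exactly-zero diagonal
        sym = (values + values.T) / 2.0
        np.fill_diagonal(sym, 0.0)
        object.__setattr__(self, "values", sym)

    @property
    def n_conditions(self) -> int:
        return len(self.labels)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_long(self) -> pd.DataFrame:
        """Long-format table with one row per unordered condition pair."""
        idx = pair_index(self.n_conditions)
        return pd.DataFrame(
            {
                "cond_i": [self.labels[i] for i, _ in idx],
                "cond_j": [self.labels[j] for _, j in idx],
                "dissimilarity": [self.values[i, j] for i, j in idx],
            }
        )


@dataclass(frozen=True)
class RDMVector:
    """Strictly-upper-triangle entries of an RDM in row-major pair order.

    The canonical vector form used for every RDM comparison; the pair order
    ``(0,1), (0,2), ..., (0,n-1), (1,2), ...`` is fixed so that permutation
    tests and oracles agree exactly.
    """

    entries: np.ndarray
    pair_index: tuple[tuple[int, int], ...]
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "entries", np.asarray(self.entries, dtype=float)
        )
        if self.entries.ndim != 1:
            raise ValueError("RDMVector entries must be one-dimensional")
        if len(self.entries) != len(self.pair_index):
            raise ValueError("entries and pair_index length mismatch")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class RSAStatistic:
    """A (semi-partial) Spearman RSA statistic."""

    rho: float
    kind: str  # "full" | "semipartial"
    controlled: tuple[str, ...] = ()
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("full", "semipartial"):
            raise ValueError(f"unknown RSA statistic kind {self.kind!r}")
        if self.kind == "full" and self.controlled:
            raise ValueError("full correlation cannot list controls")
        if not -1.0 - 1e-9 <= self.rho <= 1.0 + 1e-9:
            raise ValueError(f"|rho| > 1: {self.rho}")


def pair_index(n: int) -> tuple[tuple[int, int], ...]:
    """Row-major strictly-upper-triangle pair order for ``n`` conditions."""
    return tuple((i, j) for i in range(n) for j in range(i + 1, n))


def correlation_distance_matrix(vectors: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between the rows of ``vectors``."""
    vectors = np.asarray(vectors, dtype=float)
    sd = vectors.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise DegenerateRepresentationError(
            f"zero-variance feature vector(s) at row(s) {bad.tolist()}"
        )
    d = 1.0 - np.corrcoef(vectors)
    return np.clip(d, 0.0, 2.0)


def representation_rdm(reps) -> RDM:
    """Correlation-distance RDM over a representation set.

    ``reps`` provides ordered ``labels`` and a ``vectors`` matrix with one
    feature vector per condition (any object with those attributes works).
    Entry (i, j) is ``1 - Pearson(vec_i, vec_j)``.
    """
    labels = tuple(reps.labels)
    vectors = np.asarray(reps.vectors, dtype=float)
    if vectors.ndim != 2:
        raise ValueError("representation vectors must form a 2-D matrix")
    if len(labels) != vectors.shape[0]:
        raise ValueError("label count does not match number of vectors")
    if len(labels) < 3:
        raise ValueError("need at least 3 conditions to build an RDM")
    if vectors.shape[1] < 2:
        raise ValueError("feature vectors need at least 2 entries")
    sd = vectors.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise DegenerateRepresentationError(
            "zero-variance representation for condition(s): "
            + ", ".join(labels[i] for i in bad)
        )
    return RDM(labels, correlation_distance_matrix(vectors))


def rdm_vector(rdm: RDM) -> RDMVector:
    """Vectorize an RDM into its canonical strictly-upper-triangle form."""
    idx = pair_index(rdm.n_conditions)
    entries = np.array([rdm.values[i, j] for i, j in idx])
    return RDMVector(entries=entries, pair_index=idx, labels=rdm.labels)


def rdm_from_vector(vec: RDMVector) -> RDM:
    """Inverse of :func:`rdm_vector`; the round-trip is exact."""
    if not vec.pair_index:
        raise ValueError("cannot rebuild an RDM from an empty vector")
    n = max(j for _, j in vec.pair_index) + 1
    if vec.pair_index != pair_index(n):
        raise ValueError("pair_index is not the canonical row-major order")
    values = np.zeros((n, n))
    for (i, j), d in zip(vec.pair_index, vec.entries):
        values[i, j] = values[j, i] = d
    labels = vec.labels if len(vec.labels) == n else tuple(map(str, range(n)))
    return RDM(labels, values)


def _as_entries(v) -> np.ndarray:
    return v.entries if isinstance(v, RDMVector) else np.asarray(v, float)


def spearman_rsa(a, b) -> RSAStatistic:
    """Spearman rank correlation between two RDM vectors (average ranks for ties)."""
    x, y = _as_entries(a), _as_entries(b)
    if x.shape != y.shape:
        raise ValueError("RDM vectors have different lengths")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs for a rank correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant RDM vector: Spearman correlation undefined")
    rho = stats.spearmanr(x, y).statistic
    return RSAStatistic(rho=float(rho), kind="full")


def semipartial_spearman(target, predictor, controls=None,
                         control_names: tuple[str, ...] | None = None) -> RSAStatistic:
    """Unique rank correlation of ``predictor`` with ``target`` given ``controls``.

    All vectors are rank-transformed (average ranks for ties); the predictor
    ranks are residualized on an intercept plus the control ranks by least
    squares; the returned rho is the Pearson correlation between the target
    ranks and the predictor residuals.  The target is *not* residualized
    (part correlation, not partial).  With no controls this reduces exactly
    to the full Spearman correlation.
    """
    controls = list(controls or [])
    y = _as_entries(target)
    x = _as_entries(predictor)
    if not controls:
        return spearman_rsa(y, x)
    names = tuple(control_names) if control_names is not None else tuple(
        f"control_{k}" for k in range(len(controls))
    )
    if len(names) != len(controls):
        raise ValueError("control_names length mismatch")
    cmat = np.column_stack([_as_entries(c) for c in controls])
    if len(y) != len(x) or cmat.shape[0] != len(y):
        raise ValueError("RDM vectors have different lengths")
    ry = stats.rankdata(y)
    rx = stats.rankdata(x)
    rc = np.apply_along_axis(stats.rankdata, 0, cmat)
    design = np.column_stack([np.ones(len(rx)), rc])
    beta, *_ = np.linalg.lstsq(design, rx, rcond=None)
    resid = rx - design @ beta
    if resid.std() <= len(rx) * np.finfo(float).eps * rx.std():
        raise np.linalg.LinAlgError(
            "controls are collinear with the predictor: residual is zero"
        )
    rho = np.corrcoef(ry, resid)[0, 1]
    return RSAStatistic(rho=float(rho), kind="semipartial", controlled=names)


def variance_partition(neural, models: dict) -> list[RSAStatistic]:
    """Unique (semi-partial) contribution of each named model RDM vector.

    For every model, its vector is residualized on all *other* models'
    vectors; results follow the input order.
    """
    names = list(models)
    if len(names) != len(set(names)):
        raise ValueError("duplicate model names")
    if len(names) < 2:
        raise ValueError("variance partitioning needs at least 2 models")
    out = []
    for name in names:
        others = [n for n in names if n != name]
        stat = semipartial_spearman(
            neural, models[name],
            [models[n] for n in others], control_names=tuple(others),
        )
        out.append(RSAStatistic(stat.rho, stat.kind, stat.controlled, name=name))
    return out


def save_rdm(rdm: RDM, path, long: bool = False) -> None:
    """Write an RDM as delimited text (square with labels, or long format)."""
    if long:
        rdm.to_long().to_csv(path, sep="\t", index=False)
    else:
        rdm.to_dataframe().to_csv(path, sep="\t")


def load_rdm(path) -> RDM:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("RDM file row and column labels disagree")
    return RDM(tuple(map(str, df.index)), df.to_numpy(dtype=float))
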