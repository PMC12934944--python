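"""Group-level statistics: sign-flip permutation tests, FDR, ANOVA.

Group inference on per-subject RSA statistics uses a nonparametric
signed (sign-flip) permutation test of the group mean: under the null the
sign of each subject's statistic is exchangeable, so the null distribution
is built from random (or, when affordable, fully enumerated) sign
patterns.  The observed pattern is counted in the null, which keeps every
p-value strictly positive and the test valid.  P-values are corrected with
Benjamini-Hochberg FDR and converted to signed z-statistics for mapping.
Time-resolved model profiles are compared with a two-way within-subject
ANOVA (model x time window), each effect tested against its own
subject-by-effect error term with uncorrected degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupResult",
    "signed_permutation_test",
    "signed_permutation_test_matrix",
    "fdr_bh",
    "p_to_z",
    "paired_model_comparison",
    "rm_anova_2way",
]


@dataclass(frozen=True)
class GroupResult:
    """Outcome of a sign-flip permutation test on per-subject statistics."""

    values: np.ndarray
    mean: float
    p: float
    z: float
    tail: str  # "one" | "two"
    n_perm: int  # permutations actually used (2^n when exhaustive)
    exact: bool  # full sign enumeration
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.p <= 1.0:
            raise ValueError(f"invalid p-value {self.p}")


def _sign_matrix(n: int) -> np.ndarray:
    """All 2^n sign patterns, one row each."""
    bits = np.arange(2**n, dtype=np.int64)[:, None] >> np.arange(n)[None, :]
    return 1.0 - 2.0 * (bits & 1)


def signed_permutation_test(values, tail: str = "two", n_perm: int = 5000,
                            seed: int | None = None) -> GroupResult:
    """Sign-flip permutation test of the group mean against zero.

    When ``2^n_subjects <= n_perm`` the full sign enumeration is used and
    the p-value is exact; otherwise ``n_perm`` seeded random sign patterns
    are drawn and the observed pattern is added to the null count.
    ``tail='one'`` tests mean > 0; ``tail='two'`` uses |mean|.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise ValueError("need a 1-D vector of >= 2 subject values")
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n = len(values)
    obs = values.mean()
    if np.all(values == 0):
        warnings.warn("all subject values are zero: degenerate null, p = 1")
        return GroupResult(values, 0.0, 1.0, 0.0, tail, n_perm, False, seed)
    exact = 2**n <= n_perm
    if exact:
        null = _sign_matrix(n) @ values / n
        total = 2**n
        if tail == "two":
            count = int(np.sum(np.abs(null) >= abs(obs) - 1e-12))
        else:
            count = int(np.sum(null >= obs - 1e-12))
        p = count / total
        used = total
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        null = signs @ values / n
        if tail == "two":
            count = int(np.sum(np.abs(null) >= abs(obs) - 1e-12))
        else:
            count = int(np.sum(null >= obs - 1e-12))
        p = (count + 1) / (n_perm + 1)  # observed pattern included
        used = n_perm
    z = p_to_z(p, effect_sign=np.sign(obs) or 1.0, tail=tail)
    return GroupResult(values, float(obs), float(p), float(z), tail, used,
                       exact, seed)


def signed_permutation_test_matrix(values: np.ndarray, tail: str = "two",
                                   n_perm: int = 5000,
                                   seed: int | None = None):
    """Vectorized sign-flip test over many variables sharing subjects.

    ``values`` is (n_subjects, n_variables); the *same* sign patterns are
    applied across variables (as in a voxelwise searchlight map).  Returns
    ``(mean, p)`` arrays of length n_variables.
    """
    values = np.asarray(values, dtype=float)
    n, _ = values.shape
    obs = values.mean(axis=0)
    exact = 2**n <= n_perm
    if exact:
        signs = _sign_matrix(n)
        null = signs @ values / n
        total = signs.shape[0]
        extra = 0
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        null = signs @ values / n
        total = n_perm + 1
        extra = 1
    if tail == "two":
        count = np.sum(np.abs(null) >= np.abs(obs)[None, :] - 1e-12, axis=0)
    else:
        count = np.sum(null >= obs[None, :] - 1e-12, axis=0)
    p = (count + extra) / total
    return obs, p


def fdr_bh(pvalues, alpha: float = 0.05):
    """Benjamini-Hochberg step-up FDR: (reject flags, adjusted p-values)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((pvalues <= 0) | (pvalues > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, p_adj, _, _ = multipletests(pvalues, alpha=alpha, method="fdr_bh")
    return reject, p_adj


def p_to_z(p: float, effect_sign: float = 1.0, tail: str = "two") -> float:
    """Convert a permutation p-value to a signed normal z-statistic."""
    if not 0.0 < p <= 1.0:
        raise ValueError("p must lie in (0, 1]")
    if tail == "two":
        return float(stats.norm.isf(p / 2.0) * (1.0 if effect_sign >= 0 else -1.0))
    if tail == "one":
        return float(stats.norm.isf(p))
    raise ValueError("tail must be 'one' or 'two'")


def paired_model_comparison(values_a, values_b, n_perm: int = 5000,
                            seed: int | None = None) -> GroupResult:
    """Two-tailed sign-flip test on paired per-subject differences A - B."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired value vectors must have equal length")
    return signed_permutation_test(a - b, tail="two", n_perm=n_perm, seed=seed)


def rm_anova_2way(values: np.ndarray,
                  factor_names: tuple[str, str] = ("model", "window")
                  ) -> pd.DataFrame:
    """Two-way fully within-subject ANOVA on an (n_subjects, a, b) grid.

    Each effect is tested against its own subject-by-effect interaction
    error term; no sphericity correction is applied.  Returns a table with
    one row per effect: sum of squares, numerator/denominator df, F, p.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 3:
        raise ValueError("values must be (n_subjects, levels_a, levels_b)")
    if np.any(~np.isfinite(y)):
        raise ValueError("incomplete design: non-finite cells")
    n, a, b = y.shape
    if n < 2 or a < 2 or b < 2:
        raise ValueError("need >= 2 subjects and >= 2 levels per factor")
    mu = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_a = n * b * np.sum((m_a - mu) ** 2)
    ss_b = n * a * np.sum((m_b - mu) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + mu) ** 2)
    ss_as = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + mu) ** 2)
    ss_bs = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + mu) ** 2)
    resid = (
        y
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - mu
    )
    ss_abs = np.sum(resid**2)

    rows = []
    for name, ss, df1, ss_err, df2 in [
        (factor_names[0], ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        (factor_names[1], ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        (f"{factor_names[0]}:{factor_names[1]}", ss_ab, (a - 1) * (b - 1),
         ss_abs, (a - 1) * (b - 1) * (n - 1)),
    ]:
        ms = ss / df1
        ms_err = ss_err / df2
        f = ms / ms_err if ms_err > 0 else (0.0 if ss == 0 else np.inf)
        p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
        rows.append(
            {"effect": name, "ss": ss, "ss_error": ss_err, "df1": df1,
             "df2": df2, "F": float(f), "p": p}
        )
    return pd.DataFrame(rows)
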