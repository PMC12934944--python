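"""Stimulus-subset selection by random sampling under decorrelation criteria.

Picks a fixed-size subset of candidate videos so that (i) the two
candidate models' RDMs are weakly correlated on the subset, (ii) and
(iii) each model's RDM is strongly correlated with the behavioral-ratings
RDM, and (iv) the three interaction categories are balanced.  The
procedure is the published one: many iterations of uniform sampling
without replacement, scoring each draw and keeping the best feasible one.
Criteria (i)-(iii) combine linearly (configurable weights); balance is a
hard constraint.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import RepresentationSet
from .rdm import DegenerateRepresentationError, rdm_vector, representation_rdm, spearman_rsa

__all__ = ["SelectionCriteria", "SubsetResult", "subset_score", "select_subset"]


@dataclass(frozen=True)
class SelectionCriteria:
    """Subset size, sampling effort, criterion weights, balance tolerance.

    ``weights`` are (w_decorrelate, w_modelA_behavior, w_modelB_behavior):
    the composite score is
    ``w2 * r(A, beh) + w3 * r(B, beh) - w1 * r(A, B)``.
    ``balance_tol`` caps max - min category count in a feasible subset.
    """

    n_select: int = 50
    n_iter: int = 1000
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    balance_tol: int = 4
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_select < 4:
            raise ValueError("subset size must be >= 4 (non-degenerate RDMs)")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if any(w < 0 for w in self.weights) or not any(self.weights):
            raise ValueError("weights must be >= 0 and not all zero")
        if self.balance_tol < 0:
            raise ValueError("balance tolerance must be >= 0")


@dataclass(frozen=True)
class SubsetResult:
    """A selected subset with its achieved inter-RDM correlations."""

    indices: tuple[int, ...]
    r_ab: float  # modelA vs modelB
    r_a_beh: float  # modelA vs behavior
    r_b_beh: float  # modelB vs behavior
    category_counts: dict[str, int]
    score: float

    def __post_init__(self) -> None:
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("subset indices must be unique")


def _subset_correlations(subset, reps: dict[str, RepresentationSet]):
    vecs = {}
    for name in ("modelA", "modelB", "behavior"):
        vecs[name] = rdm_vector(representation_rdm(reps[name].subset(subset)))
    r_ab = spearman_rsa(vecs["modelA"], vecs["modelB"]).rho
    r_a = spearman_rsa(vecs["modelA"], vecs["behavior"]).rho
    r_b = spearman_rsa(vecs["modelB"], vecs["behavior"]).rho
    return r_ab, r_a, r_b


def _balanced(subset, categories, tol: int) -> tuple[bool, dict[str, int]]:
    counts = Counter(categories[i] for i in subset)
    values = list(counts.values())
    # a category absent from the subset counts as zero
    n_cats = len(set(categories))
    values += [0] * (n_cats - len(values))
    return max(values) - min(values) <= tol, dict(counts)


def subset_score(subset, reps: dict[str, RepresentationSet], categories,
                 criteria: SelectionCriteria):
    """Composite score and components for one candidate subset.

    Returns ``(score, components)`` where components is a dict with the
    three correlations, the category counts, and a feasibility flag
    (balance is a hard constraint: infeasible subsets get score -inf).
    """
    subset = tuple(int(i) for i in subset)
    if len(subset) < 4:
        raise ValueError("subset too small for non-degenerate RDMs")
    ok, counts = _balanced(subset, categories, criteria.balance_tol)
    w1, w2, w3 = criteria.weights
    try:
        r_ab, r_a, r_b = _subset_correlations(subset, reps)
    except (DegenerateRepresentationError, ValueError) as err:
        return float("-inf"), {
            "feasible": False, "reason": str(err), "counts": counts,
            "r_ab": np.nan, "r_a_beh": np.nan, "r_b_beh": np.nan,
        }
    score = w2 * r_a + w3 * r_b - w1 * r_ab
    components = {
        "feasible": ok, "reason": "" if ok else "unbalanced categories",
        "counts": counts, "r_ab": r_ab, "r_a_beh": r_a, "r_b_beh": r_b,
    }
    return (score if ok else float("-inf")), components


def select_subset(reps: dict[str, RepresentationSet], categories,
                  criteria: SelectionCriteria,
                  return_audit: bool = False):
    """Sample ``n_iter`` subsets and return the best feasible one.

    ``categories`` assigns each pool condition its interaction category.
    With ``return_audit`` a tidy table of every sampled subset's component
    correlations is returned alongside the result.
    """
    pool = reps["modelA"].n_conditions
    for name in ("modelB", "behavior"):
        if reps[name].n_conditions != pool:
            raise ValueError("representation sets differ in pool size")
    categories = list(categories)
    if len(categories) != pool:
        raise ValueError("category labels must cover the candidate pool")
    if criteria.n_select > pool:
        raise ValueError("subset size exceeds candidate pool")
    rng = np.random.default_rng(criteria.seed)
    best: SubsetResult | None = None
    audit_rows = []
    failures: Counter = Counter()
    for it in range(criteria.n_iter):
        subset = np.sort(rng.choice(pool, size=criteria.n_select, replace=False))
        score, comp = subset_score(subset, reps, categories, criteria)
        audit_rows.append(
            {"iteration": it, "score": score, "feasible": comp["feasible"],
             "r_ab": comp["r_ab"], "r_a_beh": comp["r_a_beh"],
             "r_b_beh": comp["r_b_beh"],
             "indices": ",".join(map(str, subset))}
        )
        if not comp["feasible"]:
            failures[comp["reason"]] += 1
            continue
        if best is None or score > best.score:
            best = SubsetResult(
                indices=tuple(int(i) for i in subset),
                r_ab=comp["r_ab"], r_a_beh=comp["r_a_beh"],
                r_b_beh=comp["r_b_beh"],
                category_counts=comp["counts"], score=score,
            )
    if best is None:
        raise RuntimeError(
            "no feasible subset found in "
            f"{criteria.n_iter} iterations; constraint failures: {dict(failures)}"
        )
    if return_audit:
        return best, pd.DataFrame(audit_rows)
    return best
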