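"""Hierarchy evaluation: EC, AC, AP/AR and F.

Four complementary views of how well an inferred hierarchy matches a
reference:

* **Edge Correctness (EC)** — the fraction of reference parent→child
  edges (direction included) that also appear in the inferred hierarchy.
  Strict and local: terms one extra hop apart score zero.
* **Ancestor Correctness (AC)** — the mean, over terms present in both
  hierarchies, of the Jaccard index between the term's proper-ancestor
  sets in the two hierarchies.  Terms that are roots in both (no
  ancestors anywhere) are excluded.
* **Ancestor Precision / Recall (AP/AR)** — per term x,
  HP(x) = |A_ref(x) ∩ A_inf(x)| / |A_inf(x)| and
  HR(x) = |A_ref(x) ∩ A_inf(x)| / |A_ref(x)|; AP and AR are the means of
  HP and HR over shared terms where the respective denominator is
  non-zero.  Unlike EC/AC, AP penalises surplus inferred ancestors.
* **F** — the harmonic mean of AP and AR (macro-F; 0 when AP + AR = 0).
  Per-term F values are also available via :func:`per_term_scores`.

All metrics compare on the intersection of the two node universes; terms
present in only one hierarchy are logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .exceptions import DomainError, LookupError_
from .reference import Hierarchy, ancestors

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationReport",
    "edge_correctness",
    "ancestor_jaccard",
    "ancestor_correctness",
    "ancestor_precision_recall",
    "per_term_scores",
    "evaluate",
]


@dataclass
class EvaluationReport:
    ec: float
    ac: float
    ap: float
    ar: float
    f: float
    n_shared_terms: int
    n_ref_edges: int

    def as_dict(self) -> dict:
        return {
            "ec": self.ec,
            "ac": self.ac,
            "ap": self.ap,
            "ar": self.ar,
            "f": self.f,
            "n_shared_terms": self.n_shared_terms,
            "n_ref_edges": self.n_ref_edges,
        }


def edge_correctness(ref: Hierarchy, inf: Hierarchy) -> float:
    """Fraction of reference edges present, with direction, in ``inf``."""
    ref_edges = ref.edges
    if not ref_edges:
        raise DomainError("reference hierarchy has no edges")
    return len(ref_edges & inf.edges) / len(ref_edges)


def ancestor_jaccard(ref: Hierarchy, inf: Hierarchy, x: str) -> float | None:
    """Jaccard index of x's proper-ancestor sets in the two hierarchies.

    Returns ``None`` (excluded from averages) when x is a root in both —
    the ratio 0/0 is undefined, not a score.
    """
    if x not in ref or x not in inf:
        raise LookupError_(f"term {x!r} missing from one of the hierarchies")
    a_ref, a_inf = ancestors(ref, x), ancestors(inf, x)
    if not a_ref and not a_inf:
        return None
    return len(a_ref & a_inf) / len(a_ref | a_inf)


def ancestor_correctness(ref: Hierarchy, inf: Hierarchy) -> float:
    """Mean ancestor Jaccard over shared, not-doubly-root terms."""
    shared = ref.nodes & inf.nodes
    scores = [
        aj for x in shared if (aj := ancestor_jaccard(ref, inf, x)) is not None
    ]
    if not scores:
        raise DomainError(
            "no shared term with ancestors in either hierarchy"
        )
    return sum(scores) / len(scores)


def per_term_scores(
    ref: Hierarchy, inf: Hierarchy
) -> dict[str, tuple[float | None, float | None, float | None]]:
    """Per shared term: (HP, HR, F); entries are None where undefined.

    HP is undefined for terms with no inferred ancestors, HR for terms
    with no reference ancestors, and F wherever either is undefined or
    HP + HR = 0.
    """
    out: dict[str, tuple[float | None, float | None, float | None]] = {}
    for x in sorted(ref.nodes & inf.nodes):
        a_ref, a_inf = ancestors(ref, x), ancestors(inf, x)
        common = len(a_ref & a_inf)
        hp = common / len(a_inf) if a_inf else None
        hr = common / len(a_ref) if a_ref else None
        if hp is None or hr is None or hp + hr == 0:
            f = None
        else:
            f = 2 * hp * hr / (hp + hr)
        out[x] = (hp, hr, f)
    return out


def ancestor_precision_recall(
    ref: Hierarchy, inf: Hierarchy
) -> tuple[float, float, float]:
    """(AP, AR, F): mean HP, mean HR over shared terms, and macro-F."""
    scores = per_term_scores(ref, inf)
    hps = [hp for hp, _, _ in scores.values() if hp is not None]
    hrs = [hr for _, hr, _ in scores.values() if hr is not None]
    if not hps or not hrs:
        raise DomainError(
            "no shared term with a non-empty ancestor set on the "
            "required side"
        )
    ap = sum(hps) / len(hps)
    ar = sum(hrs) / len(hrs)
    f = 2 * ap * ar / (ap + ar) if ap + ar > 0 else 0.0
    return ap, ar, f


def evaluate(ref: Hierarchy, inf: Hierarchy) -> EvaluationReport:
    """All four metrics for one (reference, inferred) pair."""
    shared = ref.nodes & inf.nodes
    if not shared:
        raise DomainError("the hierarchies share no terms")
    only_ref = ref.nodes - inf.nodes
    only_inf = inf.nodes - ref.nodes
    if only_ref or only_inf:
        logger.info(
            "evaluate: %d terms only in reference, %d only in inferred",
            len(only_ref), len(only_inf),
        )
    ec = edge_correctness(ref, inf)
    ac = ancestor_correctness(ref, inf)
    ap, ar, f = ancestor_precision_recall(ref, inf)
    report = EvaluationReport(
        ec=ec, ac=ac, ap=ap, ar=ar, f=f,
        n_shared_terms=len(shared),
        n_ref_edges=len(ref.edges),
    )
    logger.info(
        "evaluate: EC=%.3f AC=%.3f AP=%.3f AR=%.3f F=%.3f",
        ec, ac, ap, ar, f,
    )
    return report
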