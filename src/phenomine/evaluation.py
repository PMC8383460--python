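"""Strict and soft evaluation of association sets against a gold standard.

*Strict* comparison ignores ontology semantics: a predicted (disease,
phenotype) pair is a true positive only if exactly that pair is in the gold
standard.  *Soft* comparison first closes both prediction and gold under
phenotype-ancestor addition (per disease) and then compares the closures, so
predicting a child of a gold phenotype (or vice versa) is credited at the
shared ancestor levels.

Precision, recall and F-score follow from the confusion counts; reports
round to 2 decimals only at presentation time, raw values are retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import UndefinedMetricError, UnknownClassError
from .npmi import AssociationScore, threshold_profile
from .ontology import OntologyGraph

__all__ = [
    "ConfusionCounts",
    "EvaluationReport",
    "RankSweepResult",
    "compare_strict",
    "compare_soft",
    "close_pairs",
    "prf",
    "evaluate",
    "corrected_counts",
    "rank_sweep",
    "coverage_stats",
    "union_from_sizes",
]

Pair = tuple[str, str]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def predicted_total(self) -> int:
        return self.tp + self.fp

    @property
    def gold_total(self) -> int:
        return self.tp + self.fn


@dataclass(frozen=True)
class EvaluationReport:
    mode: str  # strict | soft
    counts: ConfusionCounts
    precision: float
    recall: float
    f_score: float

    def rounded(self, ndigits: int = 2) -> tuple[float, float, float]:
        return (round(self.precision, ndigits), round(self.recall, ndigits), round(self.f_score, ndigits))


def compare_strict(pred: Iterable[Pair], gold: Iterable[Pair]) -> ConfusionCounts:
    """Exact-pair set comparison: tp = |pred ∩ gold|, fp = |pred \\ gold|, fn = |gold \\ pred|."""
    pred, gold = set(pred), set(gold)
    return ConfusionCounts(tp=len(pred & gold), fp=len(pred - gold), fn=len(gold - pred))


def close_pairs(pairs: Iterable[Pair], g_pheno: OntologyGraph) -> set[Pair]:
    """Close (disease, phenotype) pairs under phenotype-ancestor addition."""
    closed: set[Pair] = set()
    for disease, phenotype in pairs:
        if phenotype not in g_pheno:
            raise UnknownClassError(f"phenotype {phenotype!r} not in ontology")
        for anc in g_pheno.ancestors(phenotype, include_self=True):
            closed.add((disease, anc))
    return closed


def compare_soft(
    pred: Iterable[Pair], gold: Iterable[Pair], g_pheno: OntologyGraph
) -> ConfusionCounts:
    """Strict comparison of the ancestor closures of prediction and gold."""
    return compare_strict(close_pairs(pred, g_pheno), close_pairs(gold, g_pheno))


def prf(c: ConfusionCounts) -> tuple[float, float, float]:
    """(precision, recall, F1) from confusion counts.

    Undefined when either the prediction or the gold set is empty.
    """
    if c.predicted_total == 0 or c.gold_total == 0:
        raise UndefinedMetricError("precision/recall undefined on empty prediction or gold")
    precision = c.tp / c.predicted_total
    recall = c.tp / c.gold_total
    f_score = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f_score


def evaluate(
    pred: Iterable[Pair],
    gold: Iterable[Pair],
    mode: str = "strict",
    g_pheno: OntologyGraph | None = None,
) -> EvaluationReport:
    if mode == "strict":
        counts = compare_strict(pred, gold)
    elif mode == "soft":
        if g_pheno is None:
            raise ValueError("soft mode requires the phenotype ontology")
        counts = compare_soft(pred, gold, g_pheno)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    precision, recall, f_score = prf(counts)
    return EvaluationReport(mode, counts, precision, recall, f_score)


def corrected_counts(c: ConfusionCounts, n_fp_to_tp: int) -> ConfusionCounts:
    """Error-analysis correction: relabel a reviewed subset of fp as tp.

    The subset size is caller-supplied (from manual review); it is never
    inferred.  False negatives are unchanged.
    """
    if not 0 <= n_fp_to_tp <= c.fp:
        raise ValueError(f"cannot relabel {n_fp_to_tp} of {c.fp} false positives")
    return ConfusionCounts(tp=c.tp + n_fp_to_tp, fp=c.fp - n_fp_to_tp, fn=c.fn)


@dataclass(frozen=True)
class RankSweepResult:
    reports: tuple[tuple[int, EvaluationReport], ...]  # (k, report), k strictly increasing
    best_k: int  # argmax F-score, smallest k on ties

    @property
    def best_report(self) -> EvaluationReport:
        return dict(self.reports)[self.best_k]


def rank_sweep(
    scores: Sequence[AssociationScore],
    gold: Iterable[Pair],
    mode: str,
    k_grid: Sequence[int],
    g_pheno: OntologyGraph | None = None,
) -> RankSweepResult:
    """Evaluate rank-thresholded profiles over a grid of cutoffs k.

    For each k: keep phenotypes of rank <= k per disease, compare against the
    gold standard under the given mode, and report P/R/F; the sweep also
    reports the F-maximising k.
    """
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    ks = sorted(set(int(k) for k in k_grid))
    gold = set(gold)
    reports: list[tuple[int, EvaluationReport]] = []
    for k in ks:
        profile = threshold_profile(scores, k)
        pred = {(c, d) for c, ds in profile.items() for d in ds}
        reports.append((k, evaluate(pred, gold, mode=mode, g_pheno=g_pheno)))
    best_k = max(reports, key=lambda kr: (kr[1].f_score, -kr[0]))[0]
    return RankSweepResult(reports=tuple(reports), best_k=best_k)


def coverage_stats(sets: Mapping[str, set[str]], universe_size: int) -> dict:
    """Overlap/union accounting for named disease-id sets against a universe.

    Reports per-set sizes, pairwise intersections, the union size and the
    union as a whole-number percentage of the universe.
    """
    names = sorted(sets)
    union: set[str] = set().union(*sets.values()) if sets else set()
    if universe_size < len(union):
        raise ValueError("universe smaller than the union of its subsets")
    report = {
        "sizes": {n: len(sets[n]) for n in names},
        "pairwise_intersections": {
            f"{a}&{b}": len(sets[a] & sets[b])
            for i, a in enumerate(names)
            for b in names[i + 1 :]
        },
        "union": len(union),
        "universe": universe_size,
        "union_pct": round(100 * len(union) / universe_size) if universe_size else 0,
    }
    return report


def union_from_sizes(size_a: int, size_b: int, overlap: int, universe_size: int) -> tuple[int, int]:
    """Inclusion-exclusion on reported set sizes: (union, whole-percent of universe)."""
    union = size_a + size_b - overlap
    if not 0 <= overlap <= min(size_a, size_b) or union > universe_size:
        raise ValueError("inconsistent set sizes")
    return union, round(100 * union / universe_size)
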