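"""Normalized pointwise mutual information scoring of disease-phenotype pairs.

For classes C (disease) and D (phenotype), with abstract counts over the
restricted corpus,

    npmi(C, D) = log( n_CD * n_tot / (n_C * n_D) ) / ( -log(n_CD / n_tot) )

lies in [-1, 1]: -1 when the pair never co-occurs (limit convention), 0 at
exact independence, +1 when the pair co-occurs in every abstract of the
corpus (the denominator vanishes; +1 by convention).  The natural log is
used; NPMI is base-invariant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import groupby
from pathlib import Path
from typing import Iterable

from .errors import InconsistentCountsError, InvalidThresholdError
from .mining import CooccurrenceCounts

__all__ = ["AssociationScore", "npmi", "score_all", "threshold_profile", "write_scores", "read_scores"]


@dataclass(frozen=True)
class AssociationScore:
    """A scored disease-phenotype association with its per-disease rank."""

    disease_id: str
    phenotype_id: str
    npmi: float
    rank: int


def npmi(counts: CooccurrenceCounts, disease_id: str, phenotype_id: str) -> float:
    """NPMI of one pair from co-occurrence counts; see module docstring."""
    n_tot = counts.n_tot
    n_c = counts.n_disease.get(disease_id, 0)
    n_d = counts.n_phenotype.get(phenotype_id, 0)
    n_cd = counts.n_pair.get((disease_id, phenotype_id), 0)
    if n_tot <= 0:
        raise InconsistentCountsError("n_tot must be positive")
    if n_cd > min(n_c, n_d):
        raise InconsistentCountsError(
            f"joint count {n_cd} exceeds a marginal ({n_c}, {n_d}) for ({disease_id!r}, {phenotype_id!r})"
        )
    if n_cd == 0:
        return -1.0
    if n_cd == n_tot:
        return 1.0
    return math.log(n_cd * n_tot / (n_c * n_d)) / -math.log(n_cd / n_tot)


def score_all(counts: CooccurrenceCounts, positive_only: bool = True) -> list[AssociationScore]:
    """Score every observed pair (n_CD >= 1) and assign per-disease ranks.

    With ``positive_only`` (the default pipeline behaviour) only strictly
    positive scores are kept.  Within a disease, phenotypes are ranked by
    descending NPMI, ties broken by lexicographic phenotype id; ranks are
    1..k without gaps.
    """
    scored: list[tuple[str, str, float]] = [
        (c, d, npmi(counts, c, d)) for (c, d) in counts.n_pair
    ]
    if positive_only:
        scored = [t for t in scored if t[2] > 0.0]
    scored.sort(key=lambda t: (t[0], -t[2], t[1]))
    out: list[AssociationScore] = []
    for _, group in groupby(scored, key=lambda t: t[0]):
        for rank, (c, d, value) in enumerate(group, 1):
            out.append(AssociationScore(c, d, value, rank))
    return out


def threshold_profile(scores: Iterable[AssociationScore], k: int) -> dict[str, set[str]]:
    """Per-disease phenotype profile keeping ranks <= k.

    Diseases with fewer than ``k`` scored phenotypes keep all of them.
    """
    if k < 1:
        raise InvalidThresholdError(f"rank threshold must be >= 1, got {k}")
    profile: dict[str, set[str]] = {}
    for s in scores:
        if s.rank <= k:
            profile.setdefault(s.disease_id, set()).add(s.phenotype_id)
    return profile


def write_scores(scores: Iterable[AssociationScore], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("disease_id\tphenotype_id\tnpmi\trank\n")
        for s in scores:
            fh.write(f"{s.disease_id}\t{s.phenotype_id}\t{s.npmi:.10g}\t{s.rank}\n")


def read_scores(path: str | Path) -> list[AssociationScore]:
    out = []
    with Path(path).open(encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("disease_id"):
            raise ValueError(f"{path}: missing scores header")
        for line in fh:
            if line.strip():
                c, d, v, r = line.rstrip("\n").split("\t")
                out.append(AssociationScore(c, d, float(v), int(r)))
    return out
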