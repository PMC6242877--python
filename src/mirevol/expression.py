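"""Tissue-specificity statistics for miRNA orthogroups.

Orthogroups are profiled across four tissues (brain, heart, kidney,
testis).  An orthogroup counts as expressed in a tissue when its read
count summed over species reaches the presence threshold (default 1
read); the specificity category for a focal tissue is then determined by
how many *additional* tissues show expression: 0 → tissue-specific,
1 → plus1, 2 → plus2, 3 → all-tissues.  Novel-vs-known differences in
those proportions are tested with a pooled two-proportion z-test; overlap
of target-gene sets with external gene lists uses the upper-tail
hypergeometric test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import math

from scipy import stats

from .dollo import GainLossReconstruction
from .tree import DatedTree

TISSUES = ("brain", "heart", "kidney", "testis")
CATEGORIES = ("not_expressed", "tissue_specific", "plus1", "plus2", "all_tissues")


@dataclass
class ExpressionTable:
    """Read counts per (orthogroup, species, tissue)."""

    counts: dict[tuple[str, str, str], int] = field(default_factory=dict)
    tissues: tuple[str, ...] = TISSUES
    presence_threshold: int = 1

    def add(self, og_id: str, species: str, tissue: str, reads: int) -> None:
        if tissue not in self.tissues:
            raise ValueError(f"unknown tissue {tissue!r}")
        if reads < 0:
            raise ValueError("read counts must be >= 0")
        key = (og_id, species, tissue)
        self.counts[key] = self.counts.get(key, 0) + reads

    def og_ids(self) -> list[str]:
        return sorted({og for og, _, _ in self.counts})

    def tissue_total(self, og_id: str, tissue: str) -> int:
        return sum(
            v for (og, _sp, t), v in self.counts.items()
            if og == og_id and t == tissue
        )

    def expressed_tissues(self, og_id: str) -> set[str]:
        return {
            t for t in self.tissues
            if self.tissue_total(og_id, t) >= self.presence_threshold
        }


@dataclass
class SpecificityClass:
    og_id: str
    tissue: str
    category: str


def classify_specificity(
    table: ExpressionTable, og_id: str, tissue: str
) -> SpecificityClass:
    """Specificity category of an orthogroup for one focal tissue."""
    if tissue not in table.tissues:
        raise ValueError(f"unknown tissue {tissue!r}")
    expressed = table.expressed_tissues(og_id)
    if tissue not in expressed:
        cat = "not_expressed"
    else:
        extra = len(expressed) - 1
        cat = ("tissue_specific", "plus1", "plus2", "all_tissues")[extra]
    return SpecificityClass(og_id=og_id, tissue=tissue, category=cat)


def proportion_ztest(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z-test, two-sided.

    Returns ``(z, p)``; z is positive when group 1's proportion is larger.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("successes must satisfy 0 <= k <= n")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0
    z = (p1 - p2) / se
    p = 2 * stats.norm.sf(abs(z))
    return z, p


def branch_restriction(
    tree: DatedTree,
    reconstruction: GainLossReconstruction,
    specificity: Mapping[str, SpecificityClass],
) -> dict[str, float | None]:
    """Per-branch fraction of tissue-specific orthogroups among gains.

    For each branch, among orthogroups gained there whose focal-tissue
    category is not ``not_expressed``, the fraction classified
    ``tissue_specific``; branches with no qualifying gains report None.
    """
    per_branch: dict[str, list[str]] = {b: [] for b in tree.branch_labels()}
    for og, branch in reconstruction.gain_branch.items():
        per_branch.setdefault(branch, []).append(og)
    out: dict[str, float | None] = {}
    for branch, ogs in per_branch.items():
        qualifying = [
            specificity[og].category
            for og in ogs
            if og in specificity and specificity[og].category != "not_expressed"
        ]
        if not qualifying:
            out[branch] = None
        else:
            out[branch] = sum(
                1 for c in qualifying if c == "tissue_specific"
            ) / len(qualifying)
    return out


def hypergeometric_overlap(
    set_a: set[str], set_b: set[str], background: set[str]
) -> tuple[int, float, float, float]:
    """Upper-tail hypergeometric overlap test of two gene sets.

    Returns ``(k, expected, fold, p_upper)`` with
    ``expected = |A| |B| / N`` and ``p_upper = P(X >= k)`` for
    ``X ~ Hypergeom(N, |A|, |B|)``.
    """
    stray = (set_a | set_b) - background
    if stray:
        raise ValueError(
            f"sets must be subsets of the background; offenders: "
            f"{', '.join(sorted(stray))}"
        )
    N, K, n = len(background), len(set_a), len(set_b)
    k = len(set_a & set_b)
    expected = K * n / N if N else 0.0
    fold = k / expected if expected else 0.0
    p_upper = float(stats.hypergeom.sf(k - 1, N, K, n))
    return k, expected, fold, min(p_upper, 1.0)


def specificity_counts(
    table: ExpressionTable, og_ids: Sequence[str], tissue: str
) -> dict[str, int]:
    """Category histogram over ``og_ids`` for one focal tissue."""
    counts = {c: 0 for c in CATEGORIES}
    for og in og_ids:
        counts[classify_specificity(table, og, tissue).category] += 1
    return counts
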