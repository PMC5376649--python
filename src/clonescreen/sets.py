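"""Cross-screen overlap, curated-list intersection and exact hypergeometric
overlap testing on user-supplied gene sets.

The upper-tail hypergeometric p-value is computed by exact integer
summation of binomial coefficients, so small-universe results agree with
draw-by-draw enumeration to machine precision.  Gene symbols are matched
exactly after upper-casing; no alias resolution is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb
from typing import Iterable

import pandas as pd

from .exceptions import ValidationError


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (upper-cased)."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} is empty")
        object.__setattr__(
            self, "members", frozenset(m.upper() for m in self.members)
        )

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class OverlapResult:
    """Hypergeometric overlap of a hit list with an annotation set."""

    set_name: str
    universe_size: int  # N
    n_hits: int         # n (draws)
    set_size: int       # K (successes in the universe)
    overlap: int        # k (successes drawn)
    fold_enrichment: float
    p: float            # upper-tail P(X >= k)

    def __str__(self) -> str:
        return (
            f"{self.set_name}: k={self.overlap}/{self.n_hits} hits in set "
            f"(K={self.set_size}, N={self.universe_size}), "
            f"fold={self.fold_enrichment:.2f}, p={self.p:.3g}"
        )


@dataclass(frozen=True)
class VennResult:
    """Two-way overlap of hit lists from two screens."""

    unique_a: frozenset[str]
    unique_b: frozenset[str]
    shared: frozenset[str]

    @property
    def n_unique_a(self) -> int:
        return len(self.unique_a)

    @property
    def n_unique_b(self) -> int:
        return len(self.unique_b)

    @property
    def n_shared(self) -> int:
        return len(self.shared)


def _hit_genes(calls: pd.DataFrame, class_filter: str | Iterable[str]) -> set[str]:
    if isinstance(class_filter, str):
        wanted = (
            {"enriched", "depleted"} if class_filter == "hits" else {class_filter}
        )
    else:
        wanted = set(class_filter)
    return {
        g.upper() for g in calls.index[calls["call"].isin(wanted)]
    }


def intersect_hits(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    class_filter: str = "depleted",
) -> VennResult:
    """Venn decomposition of the genes of one class across two screens.

    ``class_filter`` is "depleted", "enriched", "unchanged" or "hits"
    (enriched or depleted).
    """
    a = _hit_genes(calls_a, class_filter)
    b = _hit_genes(calls_b, class_filter)
    return VennResult(
        unique_a=frozenset(a - b),
        unique_b=frozenset(b - a),
        shared=frozenset(a & b),
    )


def hypergeom_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Exact upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    Integer-arithmetic summation; exact up to the final float division.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("require 0 <= K <= N and 0 <= n <= N")
    if k <= max(0, n + K - N):
        return 1.0
    num = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(n, K) + 1))
    return num / comb(N, n)


def hypergeom_test(
    hits: Iterable[str],
    annotation: GeneSet,
    universe: Iterable[str],
) -> OverlapResult:
    """Test whether ``hits`` over-represent ``annotation`` within ``universe``.

    The annotation is first restricted to the universe (K = |set ∩ universe|);
    a disjoint annotation yields K = 0 and p = 1 with a warning.
    """
    uni = {g.upper() for g in universe}
    hit = {g.upper() for g in hits}
    if not uni:
        raise ValidationError("universe is empty")
    if not hit:
        raise ValidationError("hit list is empty")
    if not hit <= uni:
        raise ValidationError(
            f"hits outside the universe: {sorted(hit - uni)[:5]}"
        )
    in_universe = annotation.members & uni
    N, K, n = len(uni), len(in_universe), len(hit)
    k = len(hit & in_universe)
    if K == 0:
        warnings.warn(
            f"annotation {annotation.name!r} is disjoint from the universe",
            stacklevel=2,
        )
        return OverlapResult(annotation.name, N, n, 0, 0, float("nan"), 1.0)
    fold = (k / n) / (K / N)
    return OverlapResult(annotation.name, N, n, K, k, fold, hypergeom_pvalue(N, K, n, k))


def annotate_gene_list(
    calls: pd.DataFrame, components: GeneSet | Iterable[str]
) -> pd.DataFrame:
    """Annotate each gene of a curated component list with its screen call.

    Used for colouring network diagrams: each component gene gets its call
    class and average log2FC (A); genes absent from the screened library are
    marked "not present".  ``components`` may be a :class:`GeneSet` or any
    iterable of symbols (possibly empty, yielding an empty table).
    """
    members = (
        components.members
        if isinstance(components, GeneSet)
        else {g.upper() for g in components}
    )
    idx_upper = pd.Index([g.upper() for g in calls.index])
    lut = calls.set_axis(idx_upper)
    rows = []
    for gene in sorted(members):
        if gene in lut.index:
            rows.append(
                {
                    "gene_symbol": gene,
                    "call": lut.loc[gene, "call"],
                    "A": lut.loc[gene, "A"],
                }
            )
        else:
            rows.append({"gene_symbol": gene, "call": "not present", "A": float("nan")})
    return pd.DataFrame(rows, columns=["gene_symbol", "call", "A"]).set_index(
        "gene_symbol"
    )
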