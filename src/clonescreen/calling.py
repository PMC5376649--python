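"""Gene-level hit calling: aggregate per-hairpin statistics into
enriched / depleted / unchanged calls, rank hits and summarize classes.

A gene is a hit only when enough of its hairpins move significantly, in the
same direction, and far enough on average: with S the set of its significant
hairpins, the gene is *unchanged* (reason ``no_significant``) when
|S| < min_significant, *unchanged/ambiguous* when the significant hairpins
disagree in sign, *unchanged/below_cutoff* when |mean log2FC over S| is
below the cutoff, and otherwise *depleted* (candidate positive growth
regulator) or *enriched* (candidate negative growth regulator) by the sign
of that mean.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ValidationError

CLASSES = ("enriched", "depleted", "unchanged")
UNCHANGED_REASONS = ("none", "no_significant", "below_cutoff", "ambiguous")

#: Directional reading of each hit class in a dropout screen.
CLASS_SEMANTICS = {
    "depleted": "candidate positive growth regulator",
    "enriched": "candidate negative growth regulator",
    "unchanged": "no call",
}


def call_genes(
    stats: pd.DataFrame,
    alpha: float = 0.05,
    lfc_cutoff: float = 0.7,
    min_significant: int = 2,
) -> pd.DataFrame:
    """Partition all genes into enriched / depleted / unchanged calls.

    ``stats`` is the per-hairpin table from :func:`clonescreen.stats.score_shrnas`
    (needs columns gene_symbol, log2fc_mean, p).  Significance is
    re-evaluated at ``alpha`` (on p_adj when present, matching the scoring
    choice).  Returns one row per gene with columns n_shrnas,
    n_significant, call ("class"), unchanged_reason, A (mean log2FC over
    significant hairpins; NaN when there are none) and rank_score (=|A|).
    """
    if lfc_cutoff < 0:
        raise ValueError("lfc_cutoff must be non-negative")
    if min_significant < 1:
        raise ValueError("min_significant must be >= 1")
    for col in ("gene_symbol", "log2fc_mean", "p"):
        if col not in stats.columns:
            raise ValidationError(f"stats table lacks required column {col!r}")

    pcol = "p_adj" if "p_adj" in stats.columns else "p"
    sig = stats[pcol] <= alpha

    rows = []
    for gene, grp in stats.groupby("gene_symbol", sort=False):
        s = grp.loc[sig.reindex(grp.index)]
        n_sig = len(s)
        A = float(s["log2fc_mean"].mean()) if n_sig else np.nan
        if n_sig < min_significant:
            call, reason = "unchanged", "no_significant"
        elif (s["log2fc_mean"] > 0).any() and (s["log2fc_mean"] < 0).any():
            call, reason = "unchanged", "ambiguous"
        elif abs(A) < lfc_cutoff:
            call, reason = "unchanged", "below_cutoff"
        elif A < 0:
            call, reason = "depleted", "none"
        else:
            call, reason = "enriched", "none"
        rows.append(
            {
                "gene_symbol": gene,
                "n_shrnas": len(grp),
                "n_significant": n_sig,
                "call": call,
                "unchanged_reason": reason,
                "A": A,
                "rank_score": abs(A) if np.isfinite(A) else np.nan,
            }
        )
    calls = pd.DataFrame(rows).set_index("gene_symbol")
    return calls


def rank_hits(calls: pd.DataFrame, direction: str) -> pd.DataFrame:
    """Hits of one class ordered by |A| desc, then n_significant desc,
    then gene symbol.

    ``direction`` is "depleted" or "enriched".  An empty class yields an
    empty frame.
    """
    if direction not in ("depleted", "enriched"):
        raise ValueError("direction must be 'depleted' or 'enriched'")
    sub = calls[calls["call"] == direction].copy()
    if sub.empty:
        return sub
    sub = sub.reset_index().sort_values(
        by=["rank_score", "n_significant", "gene_symbol"],
        ascending=[False, False, True],
    ).set_index("gene_symbol")
    sub["rank"] = np.arange(1, len(sub) + 1)
    return sub


def classify_summary(calls: pd.DataFrame) -> dict:
    """Counts per class and per unchanged reason; hits = enriched + depleted."""
    by_class = calls["call"].value_counts().to_dict()
    by_reason = (
        calls.loc[calls["call"] == "unchanged", "unchanged_reason"]
        .value_counts()
        .to_dict()
    )
    summary = {
        "n_genes": int(len(calls)),
        "enriched": int(by_class.get("enriched", 0)),
        "depleted": int(by_class.get("depleted", 0)),
        "unchanged": int(by_class.get("unchanged", 0)),
        "unchanged_no_significant": int(by_reason.get("no_significant", 0)),
        "unchanged_below_cutoff": int(by_reason.get("below_cutoff", 0)),
        "unchanged_ambiguous": int(by_reason.get("ambiguous", 0)),
    }
    summary["hits"] = summary["enriched"] + summary["depleted"]
    return summary
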