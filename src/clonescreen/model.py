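"""Model/results interface over the dropout-screen pipeline.

:class:`DropoutScreen` holds the data of one screen (count matrix, library
annotation, normalization settings); :meth:`DropoutScreen.fit` runs
normalization → per-hairpin scoring → gene calling and returns a
:class:`ScreenResults` carrying the hairpin statistics, the gene-level
calls, ranking and summary tables, recovery scoring against simulated
truth, and diagnostic plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import calling, stats
from .exceptions import ConfigurationError
from .io import CountMatrix, LibraryAnnotation, load_count_matrix, read_library
from .simulate import SimTruth, evaluate_calls


class DropoutScreen:
    """A pooled shRNA dropout screen: counts at t=0 and t=14 plus library.

    Parameters
    ----------
    counts
        shRNA x sample count matrix with its sample sheet.
    library
        shRNA -> gene/barcode annotation covering the matrix rows.
    screen
        Which screen label of the sample sheet to analyse; defaults to the
        only screen present (required when the sheet holds several).
    pseudocount
        CPM pseudocount applied after per-million scaling (must be > 0 so
        fully dropped-out hairpins stay finite in log-ratio space).
    pairing
        Optional explicit mapping of t14 sample_id -> t0 sample_id;
        default pairs replicates by index.
    center
        Median-center log2 fold changes per replicate (default True).
        Counts are compositional, so strong enrichment of a few hairpins
        shifts every raw log2 ratio by a common offset; centering pins the
        growth-neutral bulk at zero so the gene-level fold-change cutoff
        means what it says.
    """

    def __init__(
        self,
        counts: CountMatrix,
        library: LibraryAnnotation,
        screen: str | None = None,
        pseudocount: float = 1.0,
        pairing: Mapping[str, str] | None = None,
        center: bool = True,
    ) -> None:
        if pseudocount <= 0:
            raise ConfigurationError("pseudocount must be > 0 for log fold changes")
        screens = counts.samples.screens
        if screen is None:
            if len(screens) != 1:
                raise ConfigurationError(
                    f"sample sheet holds screens {screens}; pass screen=..."
                )
            screen = screens[0]
        elif screen not in screens:
            raise ConfigurationError(f"screen {screen!r} not in sample sheet {screens}")
        self.counts = counts
        self.library = library
        self.screen = screen
        self.pseudocount = pseudocount
        self.pairing = pairing
        self.center = center

    @classmethod
    def from_tsv(
        cls,
        counts_path: str | Path,
        samples_path: str | Path,
        library_path: str | Path,
        **kwargs,
    ) -> "DropoutScreen":
        """Build a model directly from the three TSV artefacts."""
        library = read_library(library_path)
        counts = load_count_matrix(counts_path, samples_path, library)
        return cls(counts, library, **kwargs)

    # -- pipeline pieces exposed for inspection -----------------------------

    def normalized(self) -> pd.DataFrame:
        return stats.normalize_cpm(self.counts, self.pseudocount)

    def log2fc(self) -> pd.DataFrame:
        lfc = stats.compute_log2fc(
            self.normalized(), self.counts.samples, self.screen, self.pairing
        )
        return stats.median_center(lfc) if self.center else lfc

    def fit(
        self,
        alpha: float = 0.05,
        lfc_cutoff: float = 0.7,
        min_significant: int = 2,
        adjust_pvalues: bool = False,
    ) -> "ScreenResults":
        """Run the full pipeline and return results.

        alpha is the per-hairpin significance level, ``lfc_cutoff`` the
        minimum |mean log2FC over significant hairpins| for a gene-level
        hit, ``min_significant`` the minimum number of significant
        hairpins per hit gene.
        """
        shrna_stats = stats.score_shrnas(
            self.log2fc(), self.library, alpha=alpha, adjust=adjust_pvalues
        )
        gene_calls = calling.call_genes(
            shrna_stats,
            alpha=alpha,
            lfc_cutoff=lfc_cutoff,
            min_significant=min_significant,
        )
        return ScreenResults(
            model=self,
            shrna_stats=shrna_stats,
            gene_calls=gene_calls,
            params={
                "alpha": alpha,
                "lfc_cutoff": lfc_cutoff,
                "min_significant": min_significant,
                "adjust_pvalues": adjust_pvalues,
                "pseudocount": self.pseudocount,
            },
        )


@dataclass
class ScreenResults:
    """Fitted screen: per-hairpin statistics and gene-level calls."""

    model: DropoutScreen
    shrna_stats: pd.DataFrame
    gene_calls: pd.DataFrame
    params: dict = field(default_factory=dict)

    # -- tables --------------------------------------------------------------

    def rank_hits(self, direction: str = "depleted") -> pd.DataFrame:
        """Ranked hit genes of one direction (|A| desc, ties by support)."""
        return calling.rank_hits(self.gene_calls, direction)

    def class_counts(self) -> dict:
        return calling.classify_summary(self.gene_calls)

    def summary(self) -> str:
        """Plain-text overview in the spirit of a model-fit summary table."""
        c = self.class_counts()
        p = self.params
        frac_sig = float(self.shrna_stats["significant"].mean())
        lines = [
            "Pooled shRNA dropout screen",
            "=" * 60,
            f"screen:            {self.model.screen}",
            f"shRNAs:            {len(self.shrna_stats)}",
            f"genes:             {c['n_genes']}",
            f"replicates:        {sum(col.startswith('log2fc_') for col in self.shrna_stats.columns) - 1}",
            f"alpha:             {p.get('alpha')}"
            + ("  (BH-adjusted)" if p.get("adjust_pvalues") else ""),
            f"lfc cutoff:        {p.get('lfc_cutoff')}",
            f"min significant:   {p.get('min_significant')}",
            "-" * 60,
            f"significant shRNAs: {int(self.shrna_stats['significant'].sum())} "
            f"({100 * frac_sig:.2f}%)",
            f"depleted genes:     {c['depleted']}  (candidate positive growth regulators)",
            f"enriched genes:     {c['enriched']}  (candidate negative growth regulators)",
            f"unchanged genes:    {c['unchanged']}  "
            f"[no significant: {c['unchanged_no_significant']}, "
            f"below cutoff: {c['unchanged_below_cutoff']}, "
            f"ambiguous: {c['unchanged_ambiguous']}]",
            f"total hits:         {c['hits']}",
            "=" * 60,
        ]
        return "\n".join(lines)

    # -- evaluation ----------------------------------------------------------

    def evaluate(self, truth: SimTruth) -> dict:
        """Recovery metrics against planted simulation truth."""
        return evaluate_calls(self.gene_calls, truth)

    # -- plotting ------------------------------------------------------------

    def plot_volcano(self, ax=None, eps: float = 1e-300):
        """Hairpin-level volcano plot: mean log2FC vs -log10 p, hit genes'
        hairpins highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        st = self.shrna_stats
        hit_genes = set(
            self.gene_calls.index[self.gene_calls["call"] != "unchanged"]
        )
        in_hit = st["gene_symbol"].isin(hit_genes)
        neglogp = -np.log10(np.maximum(st["p"], eps))
        ax.scatter(
            st.loc[~in_hit, "log2fc_mean"], neglogp[~in_hit],
            s=4, c="0.7", label="other", rasterized=True,
        )
        ax.scatter(
            st.loc[in_hit, "log2fc_mean"], neglogp[in_hit],
            s=6, c="crimson", label="hit-gene hairpins", rasterized=True,
        )
        ax.set_xlabel("mean log2 fold change (t14 / t0)")
        ax.set_ylabel("-log10 p")
        ax.legend(frameon=False, fontsize=8)
        return ax

    def plot_class_pie(self, ax=None):
        """Pie chart of gene classes (hits vs unchanged reasons)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        c = self.class_counts()
        labels = [
            "depleted", "enriched",
            "unchanged\n(no significant)", "unchanged\n(below cutoff)",
            "unchanged\n(ambiguous)",
        ]
        sizes = [
            c["depleted"], c["enriched"],
            c["unchanged_no_significant"], c["unchanged_below_cutoff"],
            c["unchanged_ambiguous"],
        ]
        keep = [(l, s) for l, s in zip(labels, sizes) if s > 0]
        if keep:
            ax.pie([s for _, s in keep], labels=[l for l, _ in keep],
                   autopct="%1.0f%%", textprops={"fontsize": 8})
        return ax
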