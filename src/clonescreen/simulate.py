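"""Truth-labelled synthetic pooled-screen generator and recovery scoring.

The generative model mirrors a 14-day dropout screen.  Each gene g is
planted as neutral, depleted or enriched with fitness coefficient s_g
(s<0 depleted, s>0 enriched); each hairpin i carries an efficacy
e_i ∈ [0,1] drawn from an inert/Beta mixture (an inert hairpin has e=0 and
no phenotype even when its gene is a hit).  Initial library representation
is log-normal; over d population doublings a hairpin's lineage grows by
w_i = 2^{d·(1 + e_i·s_g(i))}, so relative to the neutral bulk its expected
log2 fold change is d·e_i·s_g(i).  Sequencing is multinomial per sample
(optionally Dirichlet-multinomial for overdispersion): t=0 replicates
resample the initial proportions q, t=14 replicates the grown proportions
q' ∝ q·w.  One seed drives library construction, truth assignment and
per-sample sampling through deterministically derived sub-streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError
from .io import BARCODE_LENGTH, CountMatrix, LibraryAnnotation, SampleSheet

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study-design parameters of a simulated dropout screen.

    Defaults emulate a genome-scale screen scaled to 2,000 genes: 5-6
    hairpins per gene, 10% of genes planted as depleted with |s| >= 0.5,
    a 20% inert-hairpin rate with active efficacies ~ Beta(5,2), 7
    population doublings over the 14-day culture, two replicate screens
    and 5e6 reads per sample.
    """

    n_genes: int = 2000
    shrnas_per_gene: tuple[int, ...] = (5, 6)  # sampled uniformly per gene
    frac_depleted: float = 0.10
    frac_enriched: float = 0.05
    effect_location: float = 0.5   # minimum |s| of a planted gene
    effect_scale: float = 0.25     # exponential tail of |s| beyond the minimum
    inert_prob: float = 0.2
    efficacy_a: float = 5.0
    efficacy_b: float = 2.0
    library_sigma: float = 0.2     # log-normal spread of initial representation
    doublings: float = 7.0
    reads_per_sample: int = 5_000_000
    n_replicates: int = 2
    overdispersion: float | None = None  # Dirichlet concentration scale; None = multinomial
    screen_name: str = "SIM"
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.reads_per_sample < 1 or self.n_replicates < 1:
            raise ConfigurationError("n_genes, reads_per_sample, n_replicates must be >= 1")
        if not all(k >= 1 for k in self.shrnas_per_gene):
            raise ConfigurationError("shrnas_per_gene entries must be >= 1")
        probs = (self.frac_depleted, self.frac_enriched, self.inert_prob)
        if any(not 0 <= p <= 1 for p in probs):
            raise ConfigurationError("fractions/probabilities must lie in [0, 1]")
        if self.frac_depleted + self.frac_enriched > 1:
            raise ConfigurationError("frac_depleted + frac_enriched must be <= 1")
        if self.doublings < 0 or self.library_sigma < 0:
            raise ConfigurationError("doublings and library_sigma must be >= 0")
        if self.overdispersion is not None and self.overdispersion <= 0:
            raise ConfigurationError("overdispersion concentration must be > 0")
        if self.n_genes * max(self.shrnas_per_gene) > 4 ** BARCODE_LENGTH:
            raise ConfigurationError("library larger than the 18-mer barcode space")


@dataclass
class SimTruth:
    """Planted ground truth: per-gene class/fitness and per-hairpin efficacy."""

    genes: pd.DataFrame   # index gene_symbol; columns: class, s
    shrnas: pd.DataFrame  # index shrna_id; columns: gene_symbol, efficacy

    def __post_init__(self) -> None:
        g = self.genes
        neutral_bad = (g["class"] == "neutral") & (g["s"] != 0)
        sign_bad = ((g["class"] == "depleted") & (g["s"] >= 0)) | (
            (g["class"] == "enriched") & (g["s"] <= 0)
        )
        if neutral_bad.any() or sign_bad.any():
            raise ValidationError("gene class inconsistent with sign of fitness s")


def _random_barcodes(n: int, rng: np.random.Generator) -> np.ndarray:
    """n distinct random 18-mers."""
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        batch = rng.integers(0, 4, size=(n - len(out), BARCODE_LENGTH))
        for row in batch:
            bc = "".join(_BASES[row])
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
    return np.array(out)


def simulate_screen(
    config: SimConfig,
) -> tuple[LibraryAnnotation, CountMatrix, SimTruth]:
    """Generate a truth-labelled (library, counts, truth) triple.

    Deterministic given ``config.seed``: library construction, truth
    assignment and every sample's sequencing draw use sub-streams spawned
    from one seed sequence.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    n_samples = 2 * config.n_replicates
    streams = ss.spawn(3 + n_samples)
    rng_lib = np.random.default_rng(streams[0])
    rng_truth = np.random.default_rng(streams[1])
    rng_repr = np.random.default_rng(streams[2])

    # --- library: genes, hairpins, barcodes
    genes = np.array([f"G{i + 1:05d}" for i in range(config.n_genes)])
    per_gene = rng_lib.choice(config.shrnas_per_gene, size=config.n_genes)
    gene_of_shrna = np.repeat(genes, per_gene)
    n_shrnas = int(per_gene.sum())
    within = np.concatenate([np.arange(1, k + 1) for k in per_gene])
    shrna_ids = np.array(
        [f"{g}_sh{j}" for g, j in zip(gene_of_shrna, within)]
    )
    barcodes = _random_barcodes(n_shrnas, rng_lib)
    library = LibraryAnnotation(
        pd.DataFrame(
            {"shrna_id": shrna_ids, "gene_symbol": gene_of_shrna, "barcode": barcodes}
        )
    )

    # --- truth: gene classes and fitness, hairpin efficacies
    n_dep = int(round(config.frac_depleted * config.n_genes))
    n_enr = int(round(config.frac_enriched * config.n_genes))
    classes = np.array(["neutral"] * config.n_genes, dtype=object)
    order = rng_truth.permutation(config.n_genes)
    classes[order[:n_dep]] = "depleted"
    classes[order[n_dep : n_dep + n_enr]] = "enriched"
    magnitude = config.effect_location + rng_truth.exponential(
        config.effect_scale, size=config.n_genes
    )
    s = np.where(classes == "depleted", -magnitude, 0.0) + np.where(
        classes == "enriched", magnitude, 0.0
    )
    efficacy = np.where(
        rng_truth.random(n_shrnas) < config.inert_prob,
        0.0,
        rng_truth.beta(config.efficacy_a, config.efficacy_b, size=n_shrnas),
    )
    truth = SimTruth(
        genes=pd.DataFrame({"class": classes, "s": s}, index=pd.Index(genes, name="gene_symbol")),
        shrnas=pd.DataFrame(
            {"gene_symbol": gene_of_shrna, "efficacy": efficacy},
            index=pd.Index(shrna_ids, name="shrna_id"),
        ),
    )

    # --- abundances: initial log-normal representation, clonal growth
    q0 = rng_repr.lognormal(mean=0.0, sigma=config.library_sigma, size=n_shrnas)
    q0 = q0 / q0.sum()
    s_of_shrna = truth.genes["s"].to_numpy()[
        np.searchsorted(genes, gene_of_shrna)
    ]
    growth = 2.0 ** (config.doublings * (1.0 + efficacy * s_of_shrna))
    q14 = q0 * growth
    q14 = q14 / q14.sum()

    # --- sequencing: one sub-stream per sample
    sample_rows = []
    columns = {}
    stream_i = 3
    for tp, q in (("t0", q0), ("t14", q14)):
        for rep in range(1, config.n_replicates + 1):
            sid = f"{config.screen_name}_{tp}_r{rep}"
            rng_s = np.random.default_rng(streams[stream_i])
            stream_i += 1
            p = q
            if config.overdispersion is not None:
                p = rng_s.dirichlet(config.overdispersion * q)
            columns[sid] = rng_s.multinomial(config.reads_per_sample, p)
            sample_rows.append(
                {
                    "sample_id": sid,
                    "screen": config.screen_name,
                    "timepoint": tp,
                    "replicate": rep,
                }
            )
    counts = CountMatrix(
        pd.DataFrame(columns, index=pd.Index(shrna_ids, name="shrna_id")),
        SampleSheet(pd.DataFrame(sample_rows)),
    )
    return library, counts, truth


def evaluate_calls(calls: pd.DataFrame, truth: SimTruth) -> dict:
    """Score gene calls against planted truth.

    Returns sensitivities per planted class, the false-positive rate among
    neutral genes (neutral genes called enriched or depleted), the
    empirical FDR of the hit list (hits whose planted class does not match
    the called direction) and the 3x3 confusion table.
    """
    truth_cls = truth.genes["class"]
    if set(calls.index) != set(truth_cls.index):
        raise ValidationError("calls and truth cover different gene sets")
    called = calls["call"].reindex(truth_cls.index)
    # map call classes onto truth vocabulary
    called = called.replace({"unchanged": "neutral"})

    confusion = pd.crosstab(truth_cls, called, dropna=False).reindex(
        index=["neutral", "depleted", "enriched"],
        columns=["neutral", "depleted", "enriched"],
        fill_value=0,
    )

    def _sens(cls: str) -> float:
        planted = truth_cls == cls
        if not planted.any():
            return float("nan")
        return float((called[planted] == cls).mean())

    neutral = truth_cls == "neutral"
    fpr = float((called[neutral] != "neutral").mean()) if neutral.any() else float("nan")
    is_hit = called.isin(["depleted", "enriched"])
    n_hits = int(is_hit.sum())
    false_hits = int((called[is_hit] != truth_cls[is_hit]).sum())
    return {
        "sensitivity_depleted": _sens("depleted"),
        "sensitivity_enriched": _sens("enriched"),
        "fpr_neutral": fpr,
        "n_hits": n_hits,
        "fdr_hits": false_hits / n_hits if n_hits else 0.0,
        "confusion": confusion,
    }
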