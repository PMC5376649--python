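"""Per-hairpin statistics: CPM normalization, paired log2 fold changes
between t=0 and t=14, and robust-z significance against the library-wide
empirical null.

The significance construction assumes that the vast majority of hairpins are
growth-neutral, so the bulk of the per-replicate log2FC distribution is a
valid empirical null: each hairpin is scored as a robust z against the
within-replicate median/MAD, z-scores are Stouffer-combined across
replicates, and a two-sided normal p-value is attached.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ConfigurationError, ValidationError
from .io import CountMatrix, LibraryAnnotation, SampleSheet

MAD_SCALE = 1.4826  # consistency factor: MAD -> sigma under normality


def normalize_cpm(matrix: CountMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """Counts-per-million per sample, plus a pseudocount on every cell.

    Each column is scaled to sum to 1e6 *before* the pseudocount is added;
    a pseudocount > 0 makes downstream log-ratios finite for fully
    dropped-out hairpins.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    sums = matrix.column_sums()
    zero = sums[sums == 0]
    if not zero.empty:
        raise ValidationError(f"sample {zero.index[0]!r} has zero total counts")
    return matrix.counts / sums * 1e6 + pseudocount


def pair_samples(
    samples: SampleSheet,
    screen: str,
    pairing: Mapping[str, str] | None = None,
) -> list[tuple[str, str, str]]:
    """Pair each t14 sample of a screen with a t0 sample.

    Default pairing is by replicate index; an explicit ``pairing``
    (t14 sample_id -> t0 sample_id) overrides.  Returns tuples
    (label, t0_sample, t14_sample) ordered by replicate.
    """
    t0 = samples.samples_for(screen, "t0")
    t14 = samples.samples_for(screen, "t14")
    if t0.empty or t14.empty:
        raise ConfigurationError(f"screen {screen!r} lacks t0 or t14 samples")
    pairs = []
    if pairing is not None:
        t0_ids = set(t0["sample_id"])
        for _, row in t14.sort_values("replicate").iterrows():
            sid = row["sample_id"]
            if sid not in pairing:
                raise ConfigurationError(f"t14 sample {sid!r} is unpaired")
            ref = pairing[sid]
            if ref not in t0_ids:
                raise ConfigurationError(
                    f"pairing of {sid!r} points to {ref!r}, not a t0 sample of {screen!r}"
                )
            pairs.append((f"{screen}:r{row['replicate']}", ref, sid))
        return pairs
    t0_by_rep = t0.set_index("replicate")["sample_id"]
    for _, row in t14.sort_values("replicate").iterrows():
        rep = row["replicate"]
        if rep not in t0_by_rep.index:
            raise ConfigurationError(
                f"t14 sample {row['sample_id']!r} (replicate {rep}) has no "
                f"matching t0 replicate in screen {screen!r}"
            )
        pairs.append((f"{screen}:r{rep}", t0_by_rep.loc[rep], row["sample_id"]))
    return pairs


def compute_log2fc(
    normalized: pd.DataFrame,
    samples: SampleSheet,
    screen: str,
    pairing: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-hairpin, per-replicate log2(t14 / t0) on normalized abundances.

    ``normalized`` must come from :func:`normalize_cpm` with a positive
    pseudocount so that no cell is zero.
    """
    if (normalized <= 0).any().any():
        raise ValidationError(
            "normalized matrix contains non-positive cells; "
            "use a positive pseudocount before computing log ratios"
        )
    pairs = pair_samples(samples, screen, pairing)
    out = {}
    for label, s0, s14 in pairs:
        out[label] = np.log2(normalized[s14] / normalized[s0])
    return pd.DataFrame(out, index=normalized.index)


def median_center(log2fc: pd.DataFrame) -> pd.DataFrame:
    """Subtract each replicate's library-wide median log2FC.

    Pooled-screen read counts are compositional: strong enrichment of a few
    hairpins depresses every other hairpin's raw log2 ratio by a common
    offset.  Centering each replicate at its median (the growth-neutral
    bulk) removes that offset so that fold-change magnitudes — not just
    ranks — are comparable across screens.  The robust-z significance score
    is invariant to this shift; gene-level cutoff calls are not.
    """
    return log2fc - log2fc.median(axis=0)


def score_shrnas(
    log2fc: pd.DataFrame,
    library: LibraryAnnotation,
    alpha: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """Robust-z score each hairpin against the library-wide empirical null.

    Per replicate r: ``z_ir = (lfc_ir - median_r) / (1.4826 * MAD_r)`` with
    median/MAD taken over all hairpins of that replicate.  Combined
    ``z_i = sum_r z_ir / sqrt(R)`` (Stouffer), ``p_i = 2 * (1 - Phi(|z_i|))``.
    With ``adjust=True`` significance is based on Benjamini-Hochberg
    adjusted p-values instead of raw ones.

    Returns a DataFrame indexed by shrna_id with columns gene_symbol, one
    ``log2fc_<label>`` per replicate, log2fc_mean, z, p (and p_adj when
    requested) and the boolean ``significant``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if log2fc.shape[1] < 1:
        raise ConfigurationError("at least one replicate is required")

    z_parts = []
    for col in log2fc.columns:
        vals = log2fc[col].to_numpy(float)
        med = np.median(vals)
        mad = np.median(np.abs(vals - med))
        if mad == 0:
            raise ValidationError(
                f"replicate {col!r} has zero MAD (degenerate fold-change "
                "distribution); consider excluding it"
            )
        z_parts.append((vals - med) / (MAD_SCALE * mad))
    z = np.sum(z_parts, axis=0) / np.sqrt(len(z_parts))
    p = 2.0 * sps.norm.sf(np.abs(z))

    gene = library.gene_of().reindex(log2fc.index)
    if gene.isna().any():
        missing = log2fc.index[gene.isna()]
        raise ValidationError(
            f"shRNA(s) absent from library annotation: {list(missing[:5])}"
        )

    out = pd.DataFrame(index=log2fc.index)
    out["gene_symbol"] = gene
    for col in log2fc.columns:
        out[f"log2fc_{col}"] = log2fc[col]
    out["log2fc_mean"] = log2fc.mean(axis=1)
    out["z"] = z
    out["p"] = p
    if adjust:
        out["p_adj"] = sps.false_discovery_control(p, method="bh")
        out["significant"] = out["p_adj"] <= alpha
    else:
        out["significant"] = out["p"] <= alpha
    out.index.name = "shrna_id"
    return out
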