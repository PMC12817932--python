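"""Per-taxon normalization of community RNA-seq counts.

In a mixed community the read counts of each organism rise and fall with that
organism's relative abundance and with the sample's library size, so raw
counts of genes from two different taxa correlate strongly even when their
regulation is unrelated. The remedy used here is to treat each taxon as its
own RNA-seq experiment: low-expression genes are removed, trimmed mean of
M-values (TMM) scaling factors are computed per taxon over the samples where
the taxon is present, expression is expressed as per-taxon CPM, and a
hyperbolic arcsine transform stabilizes the variance.

TMM follows the Robinson–Oshlack definition as implemented in edgeR: the
reference sample is the column whose upper-quartile of library-scaled counts
is closest to the mean upper-quartile; per gene, M is the log2 ratio of
library-scaled proportions against the reference and A the average log2
proportion; genes with a zero in either column are excluded; the M values are
doubly trimmed (30% on M, 5% on A) and averaged with inverse asymptotic
variance weights; the factor is 2 to that mean. Factors are rescaled to
geometric mean 1.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import CountMatrix, NormalizedMatrix

__all__ = [
    "filter_low_expression",
    "taxon_presence",
    "tmm_factors",
    "normalize_per_taxon",
    "arcsinh_transform",
]


def filter_low_expression(
    cm: CountMatrix, min_count: int = 10, min_sample_frac: float = 0.5
) -> tuple[CountMatrix, list[str]]:
    """Remove genes without ``min_count`` reads in enough samples.

    A gene is kept iff the number of samples with count >= ``min_count`` is at
    least ``ceil(min_sample_frac * n_samples)``; the denominator is all
    samples, regardless of taxon presence. Returns the filtered matrix and
    the removed gene ids (input order).
    """
    n_samples = cm.counts.shape[1]
    needed = math.ceil(min_sample_frac * n_samples)
    ok = (cm.counts.to_numpy() >= min_count).sum(axis=1) >= needed
    kept = cm.genes[ok]
    removed = list(cm.genes[~ok])
    return cm.subset_genes(kept), removed


def taxon_presence(cm: CountMatrix, min_species_reads: int = 1000) -> pd.DataFrame:
    """Taxon × sample boolean presence matrix.

    A taxon counts as present in a sample when its total assigned reads reach
    ``min_species_reads``; below that its expression estimates are treated as
    missing rather than zero (low-abundance organisms drop out of the
    analysis, they do not fake silence).
    """
    totals = cm.counts.groupby(cm.gene_taxon).sum()
    presence = totals >= min_species_reads
    return presence.reindex(cm.taxa)


def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref_sample: str | None = None,
    weighted: bool = True,
) -> tuple[pd.Series, list[str]]:
    """TMM scaling factors for the columns of one taxon's count sub-matrix.

    Returns ``(factors, warnings)``; factors have geometric mean 1. A sample
    that shares no expressed gene with the reference gets factor 1 and a
    warning record instead of an error.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if (lib == 0).any():
        bad = counts.columns[lib == 0][0]
        raise ValueError(f"sample {bad!r} has zero library size")

    if ref_sample is None:
        # reference: upper-quartile of library-scaled counts closest to mean
        f75 = np.array([np.quantile(x[:, j] / lib[j], 0.75) for j in range(x.shape[1])])
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = counts.columns.get_loc(ref_sample)

    warnings: list[str] = []
    logf = np.zeros(x.shape[1])
    ref = x[:, ref_idx]
    for j in range(x.shape[1]):
        if j == ref_idx:
            continue
        obs = x[:, j]
        keep = (obs > 0) & (ref > 0)
        if not keep.any():
            warnings.append(
                f"sample {counts.columns[j]!r} shares no expressed gene with the "
                f"reference {counts.columns[ref_idx]!r}; factor set to 1"
            )
            continue
        p_obs = obs[keep] / lib[j]
        p_ref = ref[keep] / lib[ref_idx]
        m = np.log2(p_obs / p_ref)
        a = 0.5 * np.log2(p_obs * p_ref)
        if np.max(np.abs(m)) < 1e-6:  # identical proportions
            continue
        n = m.size
        lo_m = math.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rank_m = rankdata(m)
        rank_a = rankdata(a)
        kept = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not kept.any():
            warnings.append(
                f"sample {counts.columns[j]!r}: trimming removed every gene; "
                "factor set to 1"
            )
            continue
        if weighted:
            # asymptotic variance of M (delta method on binomial proportions)
            var = (lib[j] - obs[keep]) / (lib[j] * obs[keep]) + (
                lib[ref_idx] - ref[keep]
            ) / (lib[ref_idx] * ref[keep])
            logf[j] = np.sum(m[kept] / var[kept]) / np.sum(1.0 / var[kept])
        else:
            logf[j] = m[kept].mean()

    factors = 2.0 ** logf
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor"), warnings


def normalize_per_taxon(
    cm: CountMatrix,
    min_species_reads: int = 1000,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> NormalizedMatrix:
    """Normalize every taxon's sub-matrix independently to per-taxon CPM.

    For each taxon, TMM factors are computed over the samples where the taxon
    is present (total assigned reads >= ``min_species_reads``); the normalized
    value is ``count / (taxon library size * factor) * 1e6``. Samples where
    the taxon is absent are NaN. Taxa present in fewer than two samples are
    dropped with a warning.
    """
    presence = taxon_presence(cm, min_species_reads=min_species_reads)
    samples = cm.sample_ids
    values = pd.DataFrame(np.nan, index=cm.genes, columns=samples, dtype=float)
    factors = pd.DataFrame(np.nan, index=presence.index, columns=samples)
    lib_sizes = pd.DataFrame(0.0, index=presence.index, columns=samples)
    warnings: list[str] = []
    dropped: list[str] = []

    for taxon in cm.taxa:
        sub = cm.taxon_counts(taxon)
        lib_sizes.loc[taxon] = sub.sum(axis=0).astype(float)
        present_cols = samples[presence.loc[taxon].to_numpy()]
        if len(present_cols) < 2:
            dropped.append(taxon)
            warnings.append(
                f"taxon {taxon!r} present in {len(present_cols)} sample(s); dropped"
            )
            continue
        sub_present = sub[present_cols]
        f, w = tmm_factors(sub_present, trim_m=trim_m, trim_a=trim_a)
        warnings.extend(w)
        factors.loc[taxon, present_cols] = f
        eff_lib = sub_present.sum(axis=0).to_numpy(dtype=float) * f.to_numpy()
        values.loc[sub.index, present_cols] = (
            sub_present.to_numpy(dtype=float) / eff_lib * 1e6
        )

    keep_genes = ~cm.gene_taxon.isin(dropped)
    return NormalizedMatrix(
        values=values.loc[keep_genes.to_numpy()],
        factors=factors,
        lib_sizes=lib_sizes,
        presence=presence,
        gene_taxon=cm.gene_taxon[keep_genes.to_numpy()],
        removed_genes=[],
        dropped_taxa=dropped,
        warnings=warnings,
    )


def arcsinh_transform(values):
    """Variance-stabilizing hyperbolic arcsine, x -> ln(x + sqrt(x^2 + 1)).

    Defined at zero (0 -> 0), odd, strictly increasing; missing values stay
    missing. Accepts scalars, arrays, Series, or DataFrames.
    """
    return np.arcsinh(values)
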