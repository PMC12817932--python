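"""Independent reference implementations used only as test oracles.

Everything here is coded directly from the defining formulas, separately
from the package's implementations, so the two can disagree when one of
them is wrong.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def tmm_oracle(counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05):
    """Robinson–Oshlack TMM factors, written from the published formulas.

    Reference column: upper quartile of counts/library closest to the mean
    upper quartile. Per sample: M and A over genes positive in both columns,
    double trim by rank on M (fraction ``trim_m``) and A (``trim_a``),
    inverse-variance weighted mean of the kept M values, factor 2**mean,
    all factors divided by their geometric mean.
    """
    x = counts.to_numpy(dtype=float)
    n_genes, n_samples = x.shape
    lib = x.sum(axis=0)
    uq = np.array([np.quantile(x[:, j] / lib[j], 0.75) for j in range(n_samples)])
    ref = int(np.abs(uq - uq.mean()).argmin())

    log2f = []
    for j in range(n_samples):
        if j == ref:
            log2f.append(0.0)
            continue
        both = (x[:, j] > 0) & (x[:, ref] > 0)
        if not both.any():
            log2f.append(0.0)
            continue
        yk = x[both, j] / lib[j]
        yr = x[both, ref] / lib[ref]
        # ratio form so that exact M ties (proportional count pairs) stay
        # exact ties in floating point, as in the tested implementation
        m = np.log2(yk / yr)
        a = 0.5 * np.log2(yk * yr)
        if np.abs(m).max() < 1e-6:
            log2f.append(0.0)
            continue
        n = m.size
        rank_m = pd.Series(m).rank().to_numpy()
        rank_a = pd.Series(a).rank().to_numpy()
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        keep = (
            (rank_m >= lo_m) & (rank_m <= hi_m)
            & (rank_a >= lo_a) & (rank_a <= hi_a)
        )
        if not keep.any():
            log2f.append(0.0)
            continue
        w = 1.0 / (
            (lib[j] - x[both, j]) / (lib[j] * x[both, j])
            + (lib[ref] - x[both, ref]) / (lib[ref] * x[both, ref])
        )
        log2f.append(float((m[keep] * w[keep]).sum() / w[keep].sum()))
    f = np.power(2.0, log2f)
    f = f / np.exp(np.log(f).mean())
    return pd.Series(f, index=counts.columns)


def pearson_oracle(x, y) -> float:
    """Textbook covariance-formula Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    sxy = (x * y).sum() - x.sum() * y.sum() / n
    sxx = (x**2).sum() - x.sum() ** 2 / n
    syy = (y**2).sum() - y.sum() ** 2 / n
    return sxy / np.sqrt(sxx * syy)


def fisher_mean_oracle(r_values) -> float:
    """Direct formula: tanh(mean(atanh(r)))."""
    z = [0.5 * np.log((1 + r) / (1 - r)) for r in r_values]
    m = sum(z) / len(z)
    return (np.exp(2 * m) - 1) / (np.exp(2 * m) + 1)


def eigengene_oracle(counts: pd.DataFrame):
    """First PC sample scores via eigendecomposition of the sample covariance
    of scaled log2 counts (no SVD), unit norm, sign by mean-profile match."""
    x = np.log2(counts.to_numpy(dtype=float) + 1.0)
    sd = x.std(axis=1, ddof=1)
    x = x[sd > 0]
    z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
    gram = z.T @ z  # sample × sample
    vals, vecs = np.linalg.eigh(gram)
    e = vecs[:, -1]
    if np.corrcoef(e, z.mean(axis=0))[0, 1] < 0:
        e = -e
    return e / np.linalg.norm(e)
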