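"""Statistical procedures over correlation sets.

The central test asks whether the correlations observed for one metabolic
module (e.g. all cross-species pairs of a carbohydrate-degradation module)
have a mean that is shifted relative to what exchangeable draws from a pool
of comparable correlation values would give. The null distribution is built
by bootstrap resampling: repeatedly drawing sets of the observed size, with
replacement, from the pool, and recording the mean. Two one-sided empirical
p-values are reported with the +1 finite-sample correction,
``p = (1 + #{null >= observed}) / (B + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ModuleExpressionMatrix
from .errors import XcoexError
from .network import FeatureTable, correlate, discrepancy_filter

__all__ = [
    "BootstrapResult",
    "bootstrap_mean_shift",
    "benjamini_hochberg",
    "MatchedModuleSet",
    "matched_module_correlations",
    "tail_fraction",
    "rank_partner",
]


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (optional; raw p is the default
    reporting convention for the bootstrap tests)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(adjusted, 0, 1)
    return out


@dataclass
class BootstrapResult:
    observed_mean: float
    pool_size: int
    set_size: int
    iterations: int
    seed: int
    p_high: float
    p_low: float
    null_mean: float
    null_sd: float


def bootstrap_mean_shift(
    observed, pool, iterations: int = 50_000, seed: int = 0
) -> BootstrapResult:
    """Bootstrap test for a mean shift of ``observed`` against ``pool``.

    Draws ``iterations`` sets of ``len(observed)`` values with replacement
    from ``pool``; ``p_high`` is the +1-corrected fraction of null means at
    or above the observed mean, ``p_low`` the analogue for at-or-below.
    Deterministic given ``seed`` and invariant to pool ordering (the pool is
    sorted before sampling).
    """
    observed = np.asarray(observed, dtype=float)
    pool = np.sort(np.asarray(pool, dtype=float))
    if observed.size < 1:
        raise XcoexError("observed set is empty")
    if pool.size < 1:
        raise XcoexError("pool is empty")
    if iterations < 1:
        raise XcoexError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    m = observed.size
    obs_mean = float(observed.mean())
    # chunked so iterations × set size never allocates more than ~8M draws
    chunk = max(1, int(8_000_000 // max(m, 1)))
    ge = le = 0
    total = 0
    s1 = s2 = 0.0
    while total < iterations:
        b = min(chunk, iterations - total)
        means = rng.choice(pool, size=(b, m), replace=True).mean(axis=1)
        ge += int((means >= obs_mean).sum())
        le += int((means <= obs_mean).sum())
        s1 += float(means.sum())
        s2 += float((means**2).sum())
        total += b
    null_mean = s1 / iterations
    null_var = max(s2 / iterations - null_mean**2, 0.0)
    return BootstrapResult(
        observed_mean=obs_mean,
        pool_size=int(pool.size),
        set_size=int(m),
        iterations=int(iterations),
        seed=int(seed),
        p_high=(1 + ge) / (iterations + 1),
        p_low=(1 + le) / (iterations + 1),
        null_mean=null_mean,
        null_sd=float(np.sqrt(null_var)),
    )


@dataclass
class MatchedModuleSet:
    """Cross-species correlations between equivalent modules of different taxa."""

    module_id: str
    values: list[float] = field(default_factory=list)
    taxon_pairs: list[tuple[str, str]] = field(default_factory=list)
    n_taxa: int = 0
    reason: str | None = None


def matched_module_correlations(
    module_expr: ModuleExpressionMatrix,
    module_id: str,
    presence: pd.DataFrame,
    min_shared: int = 5,
    discrepancy: float = 0.3,
) -> MatchedModuleSet:
    """All unordered taxon-pair correlations of one module's profiles.

    Only taxa carrying the module (post-coverage-filter) contribute; the
    Pearson–Spearman discrepancy filter is applied before values are
    collected. The number of carrying taxa is reported for panel bookkeeping.
    """
    idx = module_expr.values.index
    carriers = [t for t, m in idx if m == module_id]
    result = MatchedModuleSet(module_id=module_id, n_taxa=len(carriers))
    if len(carriers) < 2:
        result.reason = f"module {module_id!r} expressed in {len(carriers)} taxa"
        return result
    sub = module_expr.values.loc[[(t, module_id) for t in carriers]]
    features = FeatureTable(
        values=pd.DataFrame(
            sub.to_numpy(),
            index=pd.MultiIndex.from_arrays(
                [carriers, ["module"] * len(carriers), [module_id] * len(carriers)],
                names=["taxon", "kind", "feature"],
            ),
            columns=sub.columns,
        ),
        presence=presence,
    )
    edges = discrepancy_filter(
        correlate(features, min_shared=min_shared, include_within=False),
        max_gap=discrepancy,
    )
    for _, row in edges[edges["removed_by"] == "none"].iterrows():
        result.values.append(float(row["r"]))
        result.taxon_pairs.append((row["taxon_a"], row["taxon_b"]))
    return result


def tail_fraction(
    edges: pd.DataFrame, threshold: float = 0.8, exclude_taxon_pairs=()
) -> tuple[float, int]:
    """Fraction and count of cross-species edges with |r| > threshold.

    ``exclude_taxon_pairs`` is a list of unordered taxon pairs to drop before
    counting (e.g. a species pair whose globally parallel regulation would
    dominate the tail).
    """
    cross = edges[edges["cross_species"] & np.isfinite(edges["r"])]
    if exclude_taxon_pairs:
        excluded = {frozenset(p) for p in exclude_taxon_pairs}
        keep = [
            frozenset((a, b)) not in excluded
            for a, b in zip(cross["taxon_a"], cross["taxon_b"])
        ]
        cross = cross[keep]
    if len(cross) == 0:
        return 0.0, 0
    count = int((cross["r"].abs() > threshold).sum())
    return count / len(cross), count


def rank_partner(
    focal_feature: str, edges: pd.DataFrame, by: str = "r"
) -> pd.DataFrame:
    """Rank candidate partners of one feature by correlation.

    ``by='r'`` sorts descending on r (positive screens); ``by='abs'`` on
    |r|. Ties are broken by shared sample count, then by partner label.
    Returns the candidate rows with ``partner`` and ``rank`` columns.
    """
    if by not in {"r", "abs"}:
        raise XcoexError(f"unknown ranking key {by!r}")
    hits = edges[
        (edges["feature_a"] == focal_feature) | (edges["feature_b"] == focal_feature)
    ].copy()
    hits["partner"] = np.where(
        hits["feature_a"] == focal_feature, hits["feature_b"], hits["feature_a"]
    )
    hits["partner_taxon"] = np.where(
        hits["feature_a"] == focal_feature, hits["taxon_b"], hits["taxon_a"]
    )
    key = hits["r"].abs() if by == "abs" else hits["r"]
    hits = hits.assign(_key=key).sort_values(
        by=["_key", "n_shared", "partner"], ascending=[False, False, True]
    ).drop(columns="_key")
    hits["rank"] = np.arange(1, len(hits) + 1)
    return hits.reset_index(drop=True)
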