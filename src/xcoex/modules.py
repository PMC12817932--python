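"""KO-level aggregation and taxon-stratified metabolic module scoring.

Gene-level expression is first collapsed to KEGG Orthology (KO) terms: within
each taxon the normalized (pre-arcsinh) values of all genes annotated with a
KO are summed and the arcsinh transform is applied to the sum. Modules — an
ordered list of reaction steps, each realizable by alternative KOs or KO
complexes — are then scored per taxon:

* the abundance of a complex is the minimum over its members (absent KOs
  count as 0);
* the abundance of a step is the maximum over its alternatives;
* a step is *detected* when at least one alternative has every complex
  member present in the KO matrix (presence, not a value threshold);
* coverage = detected steps / total steps; modules below the minimum
  coverage are not emitted;
* the module score per sample is the median (default estimator) over the
  detected steps' abundances. Undetected steps are excluded, not zero-filled.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import (
    KOMatrix,
    ModuleDatabase,
    ModuleDefinition,
    ModuleExpressionMatrix,
    NormalizedMatrix,
)
from .errors import ConfigError

__all__ = ["aggregate_ko", "score_modules", "shared_ko_fraction"]


def aggregate_ko(norm: NormalizedMatrix, gene_kos: dict) -> KOMatrix:
    """Sum normalized gene values per (taxon, KO), then arcsinh.

    ``gene_kos`` maps gene id → iterable of KO ids; a gene with several KOs
    contributes its full value to each of them. KOs with no expressed gene in
    a taxon are absent from the result. Samples where the taxon is absent
    stay missing.
    """
    rows: dict[tuple[str, str], np.ndarray] = {}
    values = norm.values
    for gene_id, kos in gene_kos.items():
        if gene_id not in values.index or not kos:
            continue
        taxon = norm.gene_taxon[gene_id]
        vec = values.loc[gene_id].to_numpy(dtype=float)
        for ko in kos:
            key = (taxon, ko)
            if key in rows:
                rows[key] = rows[key] + vec
            else:
                rows[key] = vec.copy()
    if not rows:
        empty = pd.DataFrame(
            index=pd.MultiIndex.from_arrays([[], []], names=["taxon", "ko"]),
            columns=values.columns,
            dtype=float,
        )
        return KOMatrix(values=empty)
    index = pd.MultiIndex.from_tuples(sorted(rows), names=["taxon", "ko"])
    data = np.vstack([rows[key] for key in index])
    return KOMatrix(values=pd.DataFrame(np.arcsinh(data), index=index, columns=values.columns))


def _score_module(
    mod: ModuleDefinition, ko_values: pd.DataFrame, present: frozenset[str]
) -> tuple[np.ndarray, tuple[bool, ...]]:
    """Per-sample step abundances (detected steps only stacked) + detection."""
    n_samples = ko_values.shape[1]
    zeros = np.zeros(n_samples)
    detected: list[bool] = []
    step_rows: list[np.ndarray] = []
    for step in mod.steps:
        det = any(alt <= present for alt in step)
        detected.append(det)
        if not det:
            continue
        alt_values = []
        for alt in step:
            member_rows = [
                ko_values.loc[ko].to_numpy(dtype=float) if ko in present else zeros
                for ko in alt
            ]
            alt_values.append(np.min(member_rows, axis=0))
        step_rows.append(np.max(alt_values, axis=0))
    stacked = np.vstack(step_rows) if step_rows else np.empty((0, n_samples))
    return stacked, tuple(detected)


def score_modules(
    ko: KOMatrix,
    db: ModuleDatabase,
    min_coverage: float = 0.5,
    estimator: str = "median",
) -> ModuleExpressionMatrix:
    """Score every (taxon, module) pair; emit rows with coverage >= threshold."""
    if estimator not in {"median", "mean"}:
        raise ConfigError(f"unknown score estimator {estimator!r}")
    reducer = np.nanmedian if estimator == "median" else np.nanmean

    taxa = ko.values.index.get_level_values("taxon").unique()
    out_rows: list[tuple[str, str]] = []
    out_values: list[np.ndarray] = []
    coverages: list[float] = []
    steps_detected: dict[tuple[str, str], tuple[bool, ...]] = {}
    for taxon in taxa:
        ko_values = ko.values.xs(taxon, level="taxon")
        present = frozenset(ko_values.index)
        for mod in db:
            stacked, detected = _score_module(mod, ko_values, present)
            coverage = sum(detected) / mod.n_steps
            # a module with no detected step has no defined score, whatever
            # the coverage threshold
            if coverage < min_coverage or not any(detected):
                continue
            import warnings as _warnings

            with _warnings.catch_warnings():
                # absent-taxon samples are all-NaN columns; the NaN result is
                # exactly what "missing" should propagate to
                _warnings.simplefilter("ignore", RuntimeWarning)
                score = reducer(stacked, axis=0)
            out_rows.append((taxon, mod.module_id))
            out_values.append(score)
            coverages.append(coverage)
            steps_detected[(taxon, mod.module_id)] = detected
    index = pd.MultiIndex.from_tuples(
        out_rows or [], names=["taxon", "module_id"]
    )
    values = pd.DataFrame(
        np.vstack(out_values) if out_values else np.empty((0, ko.values.shape[1])),
        index=index,
        columns=ko.values.columns,
    )
    coverage = pd.Series(coverages, index=index, name="coverage", dtype=float)
    return ModuleExpressionMatrix(
        values=values, coverage=coverage, steps_detected=steps_detected
    )


def shared_ko_fraction(a: ModuleDefinition, b: ModuleDefinition) -> float:
    """Jaccard index of the two modules' full KO sets.

    Within-species edges between modules that share KOs are artificially
    inflated; this fraction lets consumers flag or exclude them.
    """
    union = a.kos | b.kos
    if not union:
        return 0.0
    return len(a.kos & b.kos) / len(union)
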