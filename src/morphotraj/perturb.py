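"""Perturbation statistics on projected cell states.

Once treated cells are projected onto the reference trajectory and
assigned a lineage label (Progenitor / Hepatocyte / Biliary), compound
effects on cell fate are quantified three ways:

* lineage composition per treatment and replicate (fractions, mean +- SD);
* a chi-square goodness-of-fit test of each treatment's composition
  against the differentiated-control reference distribution;
* a rank-sum comparison of pseudotime distributions along a chosen lineage
  (preceded by a Shapiro-Wilk normality check, whose result is reported
  alongside rather than used to switch tests — the rank-sum test is valid
  either way and keeps the analysis uniform).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LINEAGE_LABELS",
    "CompositionTest",
    "PseudotimeComparison",
    "summarize_composition",
    "chisq_statistic",
    "chisq_vs_reference",
    "compare_pseudotime",
]

LINEAGE_LABELS = ["Progenitor", "Hepatocyte", "Biliary"]


def summarize_composition(
    states: pd.DataFrame,
    treatment_col: str = "treatment",
    replicate_col: str = "replicate",
    label_col: str = "label",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lineage composition per treatment and replicate.

    Returns ``(per_replicate, per_treatment)``: counts and fractions over
    the three lineage labels for every (treatment, replicate), plus the
    mean +- SD of the fractions across replicates per treatment.
    """
    rows = []
    for (trt, rep), block in states.groupby([treatment_col, replicate_col]):
        n = len(block)
        if n == 0:
            raise ValueError(f"replicate {rep} of {trt} has zero cells")
        counts = block[label_col].value_counts()
        row = {"treatment": trt, "replicate": rep, "n_cells": n}
        for lab in LINEAGE_LABELS:
            c = int(counts.get(lab, 0))
            row[f"count_{lab}"] = c
            row[f"frac_{lab}"] = c / n
        rows.append(row)
    per_rep = pd.DataFrame(rows)
    agg = {}
    for lab in LINEAGE_LABELS:
        agg[f"frac_{lab}_mean"] = (f"frac_{lab}", "mean")
        agg[f"frac_{lab}_sd"] = (f"frac_{lab}", lambda v: v.std(ddof=1) if len(v) > 1 else 0.0)
    per_trt = per_rep.groupby("treatment").agg(
        n_replicates=("replicate", "nunique"), **agg
    ).reset_index()
    return per_rep, per_trt


@dataclass
class CompositionTest:
    """Chi-square goodness-of-fit of observed lineage counts vs a reference."""

    statistic: float
    df: int
    p_value: float
    observed: np.ndarray
    expected: np.ndarray
    categories: list[str]
    reference: str = "differentiated_control"
    dropped_categories: list[str] = field(default_factory=list)


def chisq_statistic(observed: np.ndarray, expected: np.ndarray) -> float:
    """Pearson goodness-of-fit statistic sum((O - E)^2 / E)."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    return float(((observed - expected) ** 2 / expected).sum())


def chisq_vs_reference(
    observed_counts,
    reference_fractions,
    categories: list[str] | None = None,
    reference: str = "differentiated_control",
) -> CompositionTest:
    """Test a lineage composition against reference fractions.

    Expected counts are reference fractions times the observed total;
    categories whose expectation is zero are dropped with a warning.
    Degrees of freedom = (categories with nonzero expectation) - 1; the
    p-value is the upper tail of the chi-square distribution.
    """
    observed = np.asarray(observed_counts, dtype=float)
    ref = np.asarray(reference_fractions, dtype=float)
    if observed.sum() <= 0:
        raise ValueError("observed composition has zero total count")
    if categories is None:
        categories = [f"cat{i}" for i in range(len(observed))]
    ref = ref / ref.sum()
    expected = ref * observed.sum()
    nonzero = expected > 0
    dropped = [c for c, keep in zip(categories, nonzero) if not keep]
    if dropped:
        warnings.warn(f"dropping zero-expectation categories: {dropped}")
        if observed[~nonzero].sum() > 0:
            warnings.warn("observed counts present in zero-expectation categories")
    obs, exp = observed[nonzero], expected[nonzero]
    stat = chisq_statistic(obs, exp)
    dof = int(nonzero.sum()) - 1
    p = float(stats.chi2.sf(stat, dof)) if dof > 0 else float("nan")
    return CompositionTest(
        statistic=stat,
        df=dof,
        p_value=p,
        observed=obs,
        expected=exp,
        categories=[c for c, keep in zip(categories, nonzero) if keep],
        reference=reference,
        dropped_categories=dropped,
    )


@dataclass
class PseudotimeComparison:
    """Rank-sum comparison of two pseudotime samples with normality context."""

    statistic: float
    p_value: float
    median_a: float
    median_b: float
    n_a: int
    n_b: int
    shapiro_p_a: float
    shapiro_p_b: float
    normal_a: bool
    normal_b: bool
    lineage: str
    density: pd.DataFrame | None = None


def _shapiro_p(x: np.ndarray, cap: int, seed: int) -> float:
    if len(x) > cap:
        rng = np.random.default_rng(seed)
        x = rng.choice(x, size=cap, replace=False)
    if np.ptp(x) == 0:
        return 0.0  # degenerate sample: certainly not normal
    return float(stats.shapiro(x).pvalue)


def compare_pseudotime(
    group_a,
    group_b,
    lineage: str = "Hepatocyte",
    alpha_normality: float = 0.05,
    normality_cap: int = 5000,
    seed: int = 0,
    n_density_bins: int = 50,
) -> PseudotimeComparison:
    """Wilcoxon rank-sum (Mann-Whitney) test between two pseudotime samples.

    Normality is assessed per group with Shapiro-Wilk (on a subsample of at
    most ``normality_cap`` cells) and reported; the rank-sum test is applied
    regardless.  A shared-grid density summary of both groups is attached
    for lineage-progression plots.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 10 or len(b) < 10:
        raise ValueError("each group needs at least 10 cells")
    sp_a = _shapiro_p(a, normality_cap, seed)
    sp_b = _shapiro_p(b, normality_cap, seed + 1)
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    edges = np.linspace(lo, hi if hi > lo else lo + 1.0, n_density_bins + 1)
    dens_a, _ = np.histogram(a, bins=edges, density=True)
    dens_b, _ = np.histogram(b, bins=edges, density=True)
    density = pd.DataFrame(
        {"pseudotime": 0.5 * (edges[:-1] + edges[1:]), "density_a": dens_a, "density_b": dens_b}
    )
    return PseudotimeComparison(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        n_a=len(a),
        n_b=len(b),
        shapiro_p_a=sp_a,
        shapiro_p_b=sp_b,
        normal_a=sp_a >= alpha_normality,
        normal_b=sp_b >= alpha_normality,
        lineage=lineage,
        density=density,
    )
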