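"""Differential expression versus methylation component.

Consumes per-gene differential-expression summaries (group means and raw
p-values from an upstream count model), applies Benjamini-Hochberg FDR
control, and relates expression flexibility to the LOW/HIGH CpG O/E
components: enrichment of significant genes in the HIGH component at a
ladder of adjusted-p cutoffs (one-sided Fisher), quantile trends of effect
magnitude against CpG O/E, Spearman rank correlation, and expression-level
contrasts (Welch t-test between components, one-way ANOVA across CpG O/E
quantiles).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .mixture_model import ComponentSplit

__all__ = [
    "EnrichmentRow",
    "bh_adjust",
    "effect_size",
    "load_de_table",
    "component_enrichment_table",
    "quantile_trend",
    "spearman",
    "component_expression_contrast",
]


@dataclass(frozen=True)
class EnrichmentRow:
    effect_name: str
    cutoff: float
    low_sig: int
    low_not: int
    high_sig: int
    high_not: int
    p: float


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def effect_size(mean_a: float, mean_b: float) -> float:
    """Log expression ratio ln(mean_a / mean_b) between two conditions."""
    if mean_a <= 0 or mean_b <= 0:
        raise ValueError("effect size requires positive group means")
    return math.log(mean_a / mean_b)


def load_de_table(path: str | Path) -> pd.DataFrame:
    """Read a DE results TSV (gene_id, mean_a, mean_b, pvalue [, padj]).

    Adds ``effect`` = ln(mean_a/mean_b) (NaN when either mean is zero; such
    genes are kept for significance-based analyses but drop out of
    effect-magnitude analyses) and ``padj`` by BH adjustment when the file
    does not already provide it.
    """
    frame = pd.read_csv(path, sep="\t")
    required = {"gene_id", "mean_a", "mean_b", "pvalue"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return finalize_de_table(frame)


def finalize_de_table(frame: pd.DataFrame) -> pd.DataFrame:
    frame = frame.copy()
    a = frame["mean_a"].to_numpy(dtype=float)
    b = frame["mean_b"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        effect = np.where((a > 0) & (b > 0), np.log(np.divide(a, b,
                          out=np.ones_like(a), where=b > 0)), np.nan)
    frame["effect"] = effect
    if "padj" not in frame.columns:
        frame["padj"] = bh_adjust(frame["pvalue"].to_numpy())
    return frame


def component_enrichment_table(
    de: pd.DataFrame,
    split: ComponentSplit,
    cutoffs: Sequence[float] = (0.1, 0.05, 0.01, 0.001),
    effect_name: str = "Environment",
) -> list[EnrichmentRow]:
    """Enrichment of significant DE genes in the HIGH component.

    For each adjusted-p cutoff, genes with ``padj < cutoff`` (strict) are
    significant; the one-sided Fisher exact p is the hypergeometric upper
    tail on the count of significant HIGH genes given the table margins.
    """
    if any(not (0 < c < 1) for c in cutoffs):
        raise ValueError("cutoffs must lie in (0, 1)")
    labels = split.labels
    sub = de[de["gene_id"].isin(labels)]
    if sub.empty:
        raise ValueError("no DE genes carry a component label")
    is_high = sub["gene_id"].map(labels).to_numpy() == "HIGH"
    padj = sub["padj"].to_numpy(dtype=float)
    rows = []
    for cutoff in cutoffs:
        sig = padj < cutoff
        hs = int(np.sum(sig & is_high))
        hn = int(np.sum(~sig & is_high))
        ls = int(np.sum(sig & ~is_high))
        ln_ = int(np.sum(~sig & ~is_high))
        p = stats.fisher_exact([[hs, hn], [ls, ln_]], alternative="greater")[1]
        rows.append(EnrichmentRow(effect_name, cutoff, ls, ln_, hs, hn, float(p)))
    return rows


def enrichment_to_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


def quantile_trend(
    x: pd.Series,
    y: pd.Series,
    n_quantiles: int,
) -> pd.DataFrame:
    """Bin genes into contiguous near-equal quantiles of x and summarize y.

    ``x`` and ``y`` are aligned Series indexed by gene id (typically CpG
    O/E and an expression metric).  Genes are sorted by x with ties broken
    by gene id; the first ``n mod q`` quantiles take the extra gene.
    Returns a frame of (quantile, count, mean_x, mean_y, se_y).
    """
    x, y = x.align(y, join="inner")
    n = len(x)
    if n_quantiles < 2:
        raise ValueError("n_quantiles must be >= 2")
    if n_quantiles > n:
        raise ValueError(f"n_quantiles={n_quantiles} exceeds gene count {n}")
    # primary key x, secondary gene id: deterministic under ties
    order = pd.DataFrame({"x": x, "y": y}).reset_index(names="gene_id") \
        .sort_values(by=["x", "gene_id"], kind="mergesort")
    base, extra = divmod(n, n_quantiles)
    sizes = [base + 1] * extra + [base] * (n_quantiles - extra)
    bounds = np.cumsum([0] + sizes)
    rows = []
    xv = order["x"].to_numpy(dtype=float)
    yv = order["y"].to_numpy(dtype=float)
    for q in range(n_quantiles):
        xs = xv[bounds[q]:bounds[q + 1]]
        ys = yv[bounds[q]:bounds[q + 1]]
        se = float(ys.std(ddof=1) / math.sqrt(ys.size)) if ys.size > 1 else 0.0
        rows.append({"quantile": q + 1, "count": int(ys.size),
                     "mean_x": float(xs.mean()), "mean_y": float(ys.mean()),
                     "se_y": se})
    return pd.DataFrame(rows)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties, t-approximation p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need aligned vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def component_expression_contrast(
    mean_expression: pd.Series,
    split: ComponentSplit,
    cpg_oe: Mapping[str, float] | pd.Series | None = None,
    n_quantiles: int = 25,
    log_scale: bool = False,
) -> dict[str, float]:
    """Expression-level contrasts between methylation components.

    Welch's unequal-variance t-test compares per-gene mean expression
    between LOW and HIGH genes; when ``cpg_oe`` is given, a one-way ANOVA
    tests variation of mean expression across ``n_quantiles`` CpG O/E
    quantiles.  ``log_scale`` applies ln(x) before testing.
    """
    labels = split.labels
    expr = mean_expression[mean_expression.index.isin(labels)].astype(float)
    if log_scale:
        if (expr <= 0).any():
            raise ValueError("log scale requires positive expression values")
        expr = np.log(expr)
    lab = expr.index.map(labels)
    low = expr[lab == "LOW"].to_numpy()
    high = expr[lab == "HIGH"].to_numpy()
    if low.size < 2 or high.size < 2:
        raise ValueError("each component needs at least 2 genes")
    t, tp = stats.ttest_ind(low, high, equal_var=False)
    out = {"welch_t": float(t), "welch_p": float(tp),
           "n_low": int(low.size), "n_high": int(high.size)}
    if cpg_oe is not None:
        cpg = pd.Series(cpg_oe, dtype=float)
        trend = quantile_trend(cpg, expr, n_quantiles)
        # rebuild the per-quantile groups for the ANOVA
        aligned = pd.DataFrame({"x": cpg, "y": expr}).dropna() \
            .reset_index(names="gene_id") \
            .sort_values(by=["x", "gene_id"], kind="mergesort")
        counts = trend["count"].to_numpy()
        bounds = np.cumsum(np.concatenate([[0], counts]))
        groups = [aligned["y"].to_numpy()[bounds[i]:bounds[i + 1]]
                  for i in range(len(counts))]
        f, fp = stats.f_oneway(*groups)
        out.update({"anova_f": float(f), "anova_p": float(fp)})
    return out
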