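"""Per-GO-term CpG O/E summaries and component enrichment tests.

Each biological-process term is summarized by the mean and standard error
of CpG O/E over its annotated genes and tested, with one-sided Fisher's
exact tests, for over-representation of its genes in the LOW or HIGH
methylation component relative to all other labeled genes.  Terms with too
few annotated genes are excluded rather than tested.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mixture_model import ComponentSplit

__all__ = [
    "TermSummary",
    "ExcludedTerm",
    "load_annotations",
    "term_summaries",
    "anova_across_terms",
    "reduced_term_summary",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TermSummary:
    term: str
    n_genes: int
    mean_cpg_oe: float
    se: float
    n_low: int
    n_high: int
    p_low: float
    p_high: float
    direction: str  # LOW, HIGH or NONE


@dataclass(frozen=True)
class ExcludedTerm:
    term: str
    n_genes: int
    reason: str


def load_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read a gene -> GO-terms table (TSV, ';'-separated term lists).

    Genes with an empty term list are dropped with a warning; duplicate
    gene rows have their term sets unioned.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene_id", "go_terms"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    table: dict[str, set[str]] = {}
    for gene, cell in zip(frame["gene_id"], frame["go_terms"]):
        terms = {t.strip() for t in str(cell).split(";") if t.strip()} \
            if pd.notna(cell) else set()
        if not terms:
            logger.warning("gene %s has no GO terms; dropped", gene)
            continue
        table.setdefault(gene, set()).update(terms)
    return table


def _one_summary(
    term: str,
    genes: Sequence[str],
    cpg_oe: Mapping[str, float],
    labels: Mapping[str, str],
    background_low: int,
    background_high: int,
    alpha: float,
) -> TermSummary:
    values = np.array([cpg_oe[g] for g in genes], dtype=float)
    n = values.size
    mean = float(values.mean())
    se = float(values.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    n_low = sum(1 for g in genes if labels[g] == "LOW")
    n_high = n - n_low
    # 2x2: [term vs not-term] x [LOW vs HIGH]; one-sided per direction
    out_low = background_low - n_low
    out_high = background_high - n_high
    p_low = stats.fisher_exact([[n_low, n_high], [out_low, out_high]],
                               alternative="greater")[1]
    p_high = stats.fisher_exact([[n_high, n_low], [out_high, out_low]],
                                alternative="greater")[1]
    if min(p_low, p_high) < alpha:
        direction = "LOW" if p_low <= p_high else "HIGH"
    else:
        direction = "NONE"
    return TermSummary(term=term, n_genes=n, mean_cpg_oe=mean, se=se,
                       n_low=n_low, n_high=n_high,
                       p_low=float(p_low), p_high=float(p_high),
                       direction=direction)


def _analysis_genes(annotations: Mapping[str, set[str]],
                    cpg_oe: Mapping[str, float],
                    labels: Mapping[str, str]) -> dict[str, set[str]]:
    """Restrict the annotation table to genes present in the labeled set."""
    return {g: t for g, t in annotations.items() if g in cpg_oe and g in labels}


def term_summaries(
    cpg_oe: Mapping[str, float],
    split: ComponentSplit,
    annotations: Mapping[str, set[str]],
    term_list: Sequence[str],
    min_genes: int = 20,
    alpha: float = 0.05,
) -> tuple[list[TermSummary], list[ExcludedTerm]]:
    """Summaries and enrichment tests for a list of GO terms.

    ``cpg_oe`` maps gene id -> CpG O/E for the PASS genes; the component
    background is every labeled gene with a CpG O/E value, whether or not
    it carries the term.  Terms with fewer than ``min_genes`` annotated
    genes are returned in the excluded list.
    """
    if not term_list:
        raise ValueError("term_list must be non-empty")
    anno = _analysis_genes(annotations, cpg_oe, split.labels)
    labels = split.labels
    background = [g for g in cpg_oe if g in labels]
    bg_low = sum(1 for g in background if labels[g] == "LOW")
    bg_high = len(background) - bg_low

    summaries: list[TermSummary] = []
    excluded: list[ExcludedTerm] = []
    for term in term_list:
        genes = sorted(g for g, terms in anno.items() if term in terms)
        if len(genes) < min_genes:
            excluded.append(ExcludedTerm(term, len(genes),
                                         f"fewer than {min_genes} genes"))
            continue
        summaries.append(_one_summary(term, genes, cpg_oe, labels,
                                      bg_low, bg_high, alpha))
    return summaries, excluded


def anova_across_terms(
    cpg_oe: Mapping[str, float],
    annotations: Mapping[str, set[str]],
    term_list: Sequence[str],
) -> tuple[float, float]:
    """One-way fixed-effects ANOVA of CpG O/E with GO term as the factor.

    A gene annotated to several terms contributes one observation per term
    (the grouping is by annotation, not by gene).
    """
    groups = []
    for term in term_list:
        vals = [cpg_oe[g] for g, terms in annotations.items()
                if term in terms and g in cpg_oe]
        if len(vals) >= 2:
            groups.append(np.asarray(vals, dtype=float))
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 terms with >= 2 genes each")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def reduced_term_summary(
    cpg_oe: Mapping[str, float],
    split: ComponentSplit,
    annotations: Mapping[str, set[str]],
    parent_term: str,
    removed_subterms: Sequence[str],
    min_genes: int = 20,
    alpha: float = 0.05,
) -> TermSummary | ExcludedTerm:
    """Summary of a parent term after removing nested sub-term gene sets.

    Used to ask whether a heterogeneous category (e.g. stress response)
    remains component-enriched once genes of specific sub-processes (e.g.
    response to oxidative stress) are taken out.
    """
    anno = _analysis_genes(annotations, cpg_oe, split.labels)
    all_terms = set().union(*anno.values()) if anno else set()
    for t in [parent_term, *removed_subterms]:
        if t not in all_terms:
            raise ValueError(f"term {t!r} not present in the annotation table")
    parent = {g for g, terms in anno.items() if parent_term in terms}
    removed = {g for g, terms in anno.items()
               if terms & set(removed_subterms)}
    kept = sorted(parent - removed)
    if len(kept) < min_genes:
        return ExcludedTerm(parent_term, len(kept),
                            f"fewer than {min_genes} genes after reduction")
    labels = split.labels
    background = [g for g in cpg_oe if g in labels]
    bg_low = sum(1 for g in background if labels[g] == "LOW")
    bg_high = len(background) - bg_low
    return _one_summary(f"{parent_term} (reduced)", kept, cpg_oe, labels,
                        bg_low, bg_high, alpha)


def summaries_to_frame(summaries: Sequence[TermSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])
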