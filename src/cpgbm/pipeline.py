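"""End-to-end convenience wrapper: profiles -> mixture -> split -> association."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .dinucleotide_metrics import (CodingSequence, compute_profiles,
                                   pass_frame)
from .expression_association import (component_enrichment_table,
                                     component_expression_contrast,
                                     enrichment_to_frame, finalize_de_table,
                                     quantile_trend, spearman)
from .mixture_model import (assign_components, component_intersection,
                            fit_gmm, select_k)

__all__ = ["run_pipeline"]


def run_pipeline(
    records: Sequence[CodingSequence],
    de_table: pd.DataFrame | None = None,
    seed: int = 0,
    window_length: int = 1000,
    min_length: int = 300,
    n_restarts: int = 10,
    k_max: int | None = None,
    cutoffs: Sequence[float] = (0.1, 0.05, 0.01, 0.001),
    effect_name: str = "Environment",
) -> dict:
    """Run the core analysis chain and return a result bundle.

    Computes dinucleotide profiles, fits the two-component mixture to CpG
    O/E of PASS genes, splits genes at the density intersection, and — when
    a DE table is supplied — computes the HIGH-component enrichment ladder,
    the Spearman correlation of |effect| with CpG O/E, and the
    expression-level contrasts.  ``k_max`` additionally records a BIC trace.
    """
    profiles = compute_profiles(records, window_length=window_length,
                                min_length=min_length)
    passed = pass_frame(profiles)
    values = passed["cpg_oe"].to_numpy()
    fit = fit_gmm(values, k=2, n_restarts=n_restarts, seed=seed)
    threshold = component_intersection(fit)
    split = assign_components(dict(zip(passed.index, values)), threshold)
    out = {
        "profiles": profiles,
        "pass_frame": passed,
        "fit": fit,
        "threshold": threshold,
        "split": split,
    }
    if k_max is not None:
        out["bic_trace"] = select_k(values, k_max=k_max,
                                    n_restarts=n_restarts, seed=seed)
    if de_table is not None:
        de = finalize_de_table(de_table)
        rows = component_enrichment_table(de, split, cutoffs=cutoffs,
                                          effect_name=effect_name)
        out["enrichment"] = enrichment_to_frame(rows)
        labeled = de[de["gene_id"].isin(split.labels)].dropna(subset=["effect"])
        cpg = passed.loc[labeled["gene_id"], "cpg_oe"]
        rho, rho_p = spearman(cpg.to_numpy(),
                              labeled["effect"].abs().to_numpy())
        out["spearman_rho"], out["spearman_p"] = rho, rho_p
        mean_expr = pd.Series(
            ((labeled["mean_a"] + labeled["mean_b"]) / 2).to_numpy(),
            index=labeled["gene_id"])
        cpg_map = passed["cpg_oe"].to_dict()
        out["contrast"] = component_expression_contrast(
            mean_expr, split, cpg_oe={g: cpg_map[g] for g in mean_expr.index})
        out["quantile_trend"] = quantile_trend(
            pd.Series(cpg.to_numpy(), index=labeled["gene_id"]),
            pd.Series(labeled["effect"].abs().to_numpy(),
                      index=labeled["gene_id"]),
            n_quantiles=min(25, max(2, len(labeled) // 2)),
        )
    return out
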