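"""Ground-truthed synthetic inputs for the CpG O/E pipeline.

The generator emulates the evolutionary signature the analysis relies on:
coding sequences start as i.i.d. draws from a base composition and are then
subjected to class-specific CpG -> TpG conversion, the sequence-level
footprint of deamination of methylated cytosines.  A HYPER class (strong
germline methylation, high conversion rate) and a HYPO class (weak
methylation, low rate) yield a bimodal CpG O/E distribution with an
anti-correlated TpG O/E, while GpC O/E stays unimodal.  Differential
expression tables are generated with the significant genes biased toward
the HYPO (high-CpG) class, and GO annotation tables with configurable
class bias per term.

Everything is deterministic given the config seed; the three generators
use independent seeded streams so tables can be regenerated separately.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .dinucleotide_metrics import CodingSequence

__all__ = [
    "SyntheticConfig",
    "TermSpec",
    "default_terms",
    "generate_sequences",
    "generate_de_table",
    "generate_annotations",
    "write_fasta",
    "load_config",
]

_LETTERS = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters of the generator.

    ``d_hyper``/``d_hypo`` are per-CpG conversion probabilities (the chance
    that the C of a CpG has been replaced by T); ``p_de_*`` are per-gene
    probabilities of true differential expression, biased toward the HYPO
    class; DE p-values are drawn from Beta(``de_p_shape``, 1), null
    p-values from Uniform(0, 1).
    """

    n_genes: int = 12_000
    pi_hyper: float = 0.45
    d_hyper: float = 0.7
    d_hypo: float = 0.2
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    length_range: tuple[int, int] = (300, 2000)
    p_de_hyper: float = 0.01
    p_de_hypo: float = 0.03
    de_effect_sd: float = 1.0
    null_effect_sd: float = 0.2
    de_p_shape: float = 0.05
    expr_log_mean: float = 3.0
    expr_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not 0 < self.pi_hyper < 1:
            raise ValueError("pi_hyper must lie in (0, 1)")
        if not (0 <= self.d_hypo < self.d_hyper <= 1):
            raise ValueError("require 0 <= d_hypo < d_hyper <= 1")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9 or min(self.base_freqs) < 0:
            raise ValueError("base_freqs must be probabilities summing to 1")
        lo, hi = self.length_range
        if lo < 300 or hi < lo:
            raise ValueError("length_range must be ordered with minimum >= 300")
        for name in ("p_de_hyper", "p_de_hypo"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not self.de_effect_sd > self.null_effect_sd > 0:
            raise ValueError("require de_effect_sd > null_effect_sd > 0")
        if not 0 < self.de_p_shape <= 1:
            raise ValueError("de_p_shape must lie in (0, 1]")

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class TermSpec:
    """One synthetic GO term: size and optional methylation-class bias.

    ``frac_hyper`` is the target fraction of the term's genes drawn from
    the HYPER class; ``None`` samples uniformly from all genes (null term).
    """

    name: str
    size: int
    frac_hyper: float | None = None


def default_terms() -> list[TermSpec]:
    """A panel mirroring housekeeping vs dynamically regulated processes.

    Housekeeping-like terms draw mostly from the HYPER (low-CpG) class,
    dynamic terms mostly from the HYPO class; one null term and one
    undersized term (excluded downstream) complete the panel.
    """
    return [
        TermSpec("translation", 300, 0.80),
        TermSpec("ribosome_biogenesis", 120, 0.80),
        TermSpec("RNA_metabolism", 400, 0.75),
        TermSpec("DNA_metabolism", 200, 0.75),
        TermSpec("cell_cycle_and_proliferation", 250, 0.70),
        TermSpec("cell_organization_and_biogenesis", 350, 0.70),
        TermSpec("signal_transduction", 400, 0.20),
        TermSpec("cell_cell_signaling", 150, 0.20),
        TermSpec("developmental_processes", 350, 0.20),
        TermSpec("cell_adhesion", 120, 0.25),
        TermSpec("defense_response", 150, 0.25),
        TermSpec("regulation_of_response_to_stimulus", 100, 0.30),
        TermSpec("stress_response", 450, 0.50),
        TermSpec("transport", 300, None),
        TermSpec("protein_metabolism", 11, None),
    ]


def _gene_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"gene_{i + 1:0{width}d}" for i in range(n)]


def generate_sequences(
    config: SyntheticConfig,
) -> tuple[list[CodingSequence], pd.DataFrame]:
    """Simulate coding sequences under class-specific CpG depletion.

    Per gene: class ~ Bernoulli(pi_hyper); length uniform over
    ``length_range``; bases i.i.d. from ``base_freqs``; every CpG
    dinucleotide then has its C replaced by T with the class conversion
    probability.  A conversion can create an upstream TpG but never a new
    CpG, so one vectorized pass over all CpG sites is exact.

    Returns the records and a truth frame (gene_id, meth_class, length).
    """
    rng = np.random.default_rng([0, config.seed])
    n = config.n_genes
    ids = _gene_ids(n)
    is_hyper = rng.random(n) < config.pi_hyper
    lo, hi = config.length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    total = int(lengths.sum())
    # inverse-CDF draw; much faster than rng.choice for ~1e7 bases
    cdf = np.cumsum(config.base_freqs)
    flat = np.searchsorted(cdf, rng.random(total), side="right").astype(np.uint8)
    np.minimum(flat, 3, out=flat)  # guard float round-off at the top edge

    gene_of = np.repeat(np.arange(n), lengths)
    within_gene = gene_of[:-1] == gene_of[1:]
    cpg_site = (flat[:-1] == 1) & (flat[1:] == 2) & within_gene
    d_site = np.where(is_hyper[gene_of[:-1]], config.d_hyper, config.d_hypo)
    convert = cpg_site & (rng.random(total - 1) < d_site)
    flat[:-1][convert] = 3  # C -> T

    letters = _LETTERS[flat].tobytes()
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    records = [
        CodingSequence(ids[i],
                       letters[offsets[i]:offsets[i + 1]].decode("ascii"))
        for i in range(n)
    ]
    truth = pd.DataFrame({
        "gene_id": ids,
        "meth_class": np.where(is_hyper, "HYPER", "HYPO"),
        "length": lengths.astype(int),
    })
    return records, truth


def generate_de_table(
    config: SyntheticConfig,
    truth: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a two-condition DE results table with HYPO-biased calls.

    Returns (de_table, truth) where the DE table has the input schema of
    the expression module (gene_id, mean_a, mean_b, pvalue) and the truth
    frame gains ``is_de`` and ``true_effect`` columns.
    """
    rng = np.random.default_rng([1, config.seed])
    is_hyper = truth["meth_class"].to_numpy() == "HYPER"
    n = len(truth)
    p_de = np.where(is_hyper, config.p_de_hyper, config.p_de_hypo)
    is_de = rng.random(n) < p_de
    effect_sd = np.where(is_de, config.de_effect_sd, config.null_effect_sd)
    true_effect = rng.normal(0.0, 1.0, size=n) * effect_sd
    pvalue = np.where(
        is_de,
        rng.beta(config.de_p_shape, 1.0, size=n),
        rng.random(n),
    )
    mean_b = rng.lognormal(config.expr_log_mean, config.expr_log_sd, size=n)
    mean_a = mean_b * np.exp(true_effect)
    de = pd.DataFrame({
        "gene_id": truth["gene_id"],
        "mean_a": mean_a,
        "mean_b": mean_b,
        "pvalue": pvalue,
    })
    truth = truth.copy()
    truth["is_de"] = is_de
    truth["true_effect"] = true_effect
    return de, truth


def generate_annotations(
    config: SyntheticConfig,
    truth: pd.DataFrame,
    terms: Sequence[TermSpec] | None = None,
) -> dict[str, set[str]]:
    """Sample a gene -> GO-terms table with per-term class bias."""
    if terms is None:
        terms = default_terms()
    rng = np.random.default_rng([2, config.seed])
    ids = truth["gene_id"].to_numpy()
    hyper_ids = ids[truth["meth_class"].to_numpy() == "HYPER"]
    hypo_ids = ids[truth["meth_class"].to_numpy() == "HYPO"]
    table: dict[str, set[str]] = {}
    for spec in terms:
        if spec.size > len(ids):
            raise ValueError(f"term {spec.name!r} larger than the gene set")
        if spec.frac_hyper is None:
            chosen = rng.choice(ids, size=spec.size, replace=False)
        else:
            n_hyper = min(round(spec.size * spec.frac_hyper), len(hyper_ids))
            n_hypo = spec.size - n_hyper
            if n_hypo > len(hypo_ids):
                raise ValueError(f"term {spec.name!r} exceeds the HYPO class")
            chosen = np.concatenate([
                rng.choice(hyper_ids, size=n_hyper, replace=False),
                rng.choice(hypo_ids, size=n_hypo, replace=False),
            ])
        for g in chosen:
            table.setdefault(str(g), set()).add(spec.name)
    return table


def write_fasta(records: Sequence[CodingSequence], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.gene_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def write_annotations(table: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tgo_terms\n")
        for gene in sorted(table):
            fh.write(f"{gene}\t{';'.join(sorted(table[gene]))}\n")


def load_config(path: str | Path) -> SyntheticConfig:
    """Read a YAML config whose keys mirror SyntheticConfig field names."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = SyntheticConfig.__dataclass_fields__
    unknown = set(raw) - set(known)
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    for key in ("base_freqs", "length_range"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return SyntheticConfig(**raw)
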