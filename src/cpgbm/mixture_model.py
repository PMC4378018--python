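"""Univariate Gaussian mixture fitting, BIC selection and density-intersection
classification of CpG O/E values.

Genes in invertebrate genomes with gene body methylation typically show a
bimodal CpG O/E distribution: a low mode of historically hypermethylated
genes and a high mode near 1 of weakly methylated genes.  The model here is
a k-component unequal-variance univariate Gaussian mixture fitted by EM
with seeded multi-start initialization.  Model order is compared with
BIC = p*ln(n) - 2*loglik (lower is better, p = 3k-1), but classification
always uses the two-component fit for comparability with prior gene body
methylation studies.  The LOW/HIGH split point is the interior intersection
of the two weighted component densities, solved in closed form.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dinucleotide_metrics import DinucleotideProfile, ProfileStatus

__all__ = [
    "MixtureFit",
    "ComponentSplit",
    "SigmaCollapseError",
    "fit_gmm",
    "select_k",
    "component_intersection",
    "assign_components",
]

_LOG2PI = math.log(2.0 * math.pi)
_SIGMA_FLOOR = 1e-6


class SigmaCollapseError(RuntimeError):
    """All EM restarts degenerated to a near-zero component variance."""


@dataclass(frozen=True)
class MixtureFit:
    """Parameters and diagnostics of a fitted k-component Gaussian mixture.

    Components are sorted by ascending mean.  ``loglik_trace`` records the
    log-likelihood at every EM iteration of the winning restart (it is
    non-decreasing; EM guarantees ascent).
    """

    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    bic: float
    n: int
    converged: bool
    n_iter: int
    loglik_trace: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loglik": self.loglik,
            "bic": self.bic,
            "n": self.n,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }


@dataclass(frozen=True)
class ComponentSplit:
    """Classification threshold and per-gene LOW/HIGH component labels.

    LOW (CpG O/E below the threshold) is the putatively hypermethylated
    component; HIGH (at or above) the putatively hypomethylated one.
    """

    threshold: float
    labels: dict[str, str]

    @property
    def n_low(self) -> int:
        return sum(1 for v in self.labels.values() if v == "LOW")

    @property
    def n_high(self) -> int:
        return sum(1 for v in self.labels.values() if v == "HIGH")

    def to_frame(self, cpg_oe: Mapping[str, float] | None = None) -> pd.DataFrame:
        genes = sorted(self.labels)
        frame = pd.DataFrame({"gene_id": genes,
                              "component": [self.labels[g] for g in genes]})
        if cpg_oe is not None:
            frame.insert(1, "cpg_oe", [cpg_oe[g] for g in genes])
        return frame


def _log_weighted_pdf(x: np.ndarray, w: np.ndarray, mu: np.ndarray,
                      sd: np.ndarray) -> np.ndarray:
    # (n, k) matrix of log(w_j * phi(x_i; mu_j, sd_j))
    z = (x[:, None] - mu[None, :]) / sd[None, :]
    return np.log(w)[None, :] - np.log(sd)[None, :] - 0.5 * (z * z + _LOG2PI)


def _em_run(x: np.ndarray, w: np.ndarray, mu: np.ndarray, sd: np.ndarray,
            tol: float, max_iter: int):
    n = x.size
    trace = []
    prev_ll = -np.inf
    converged = False
    for it in range(1, max_iter + 1):
        logp = _log_weighted_pdf(x, w, mu, sd)
        m = logp.max(axis=1)
        lse = m + np.log(np.exp(logp - m[:, None]).sum(axis=1))
        ll = float(lse.sum())
        trace.append(ll)
        if ll - prev_ll < tol and it > 1:
            converged = True
            break
        prev_ll = ll
        resp = np.exp(logp - lse[:, None])
        nk = resp.sum(axis=0)
        w = nk / n
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sd = np.sqrt(var)
        if np.any(sd < _SIGMA_FLOOR):
            raise SigmaCollapseError("component standard deviation collapsed")
    return w, mu, sd, trace[-1], np.asarray(trace), converged, len(trace)


def fit_gmm(
    values: Sequence[float] | np.ndarray,
    k: int,
    tol: float = 1e-8,
    max_iter: int = 2000,
    n_restarts: int = 10,
    seed: int = 0,
) -> MixtureFit:
    """Fit a k-component unequal-variance univariate Gaussian mixture by EM.

    Restart 0 initializes component means at evenly spaced sample quantiles
    (25th/75th percentiles for k = 2); later restarts perturb those means
    with seeded Gaussian noise.  All restarts start from equal weights and
    the sample SD.  The restart with the highest log-likelihood wins.
    Convergence is declared when the log-likelihood improves by less than
    ``tol`` between iterations.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 10 * k:
        raise ValueError(f"need at least {10 * k} observations for k={k}, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    n = x.size
    sample_sd = float(x.std())
    if sample_sd < _SIGMA_FLOOR:
        raise SigmaCollapseError("all observations are (nearly) identical")

    quantiles = np.quantile(x, (2 * np.arange(k) + 1) / (2 * k))
    rng = np.random.default_rng(seed)
    best = None
    n_collapsed = 0
    for r in range(max(1, n_restarts)):
        mu0 = quantiles.copy()
        if r > 0:
            mu0 = mu0 + rng.normal(0.0, 0.25 * sample_sd, size=k)
        w0 = np.full(k, 1.0 / k)
        sd0 = np.full(k, sample_sd)
        try:
            result = _em_run(x, w0, mu0, sd0, tol, max_iter)
        except SigmaCollapseError:
            n_collapsed += 1
            continue
        if best is None or result[3] > best[3]:
            best = result
    if best is None:
        raise SigmaCollapseError(
            f"all {n_collapsed} EM restarts collapsed to a degenerate component"
        )
    w, mu, sd, ll, trace, converged, n_iter = best
    order = np.argsort(mu)
    w, mu, sd = w[order], mu[order], sd[order]
    p = 3 * k - 1
    bic = p * math.log(n) - 2.0 * ll
    return MixtureFit(k=k, weights=w, means=mu, sds=sd, loglik=ll, bic=bic,
                      n=n, converged=converged, n_iter=n_iter, loglik_trace=trace)


def select_k(
    values: Sequence[float] | np.ndarray,
    k_max: int = 5,
    tol: float = 1e-8,
    max_iter: int = 2000,
    n_restarts: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """BIC trace over k = 1..k_max (diagnostic; classification uses k = 2).

    Returns a frame of (k, loglik, bic, converged) sorted by k; the row
    with the lowest BIC marks the preferred model order.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    rows = []
    for k in range(1, k_max + 1):
        fit = fit_gmm(values, k, tol=tol, max_iter=max_iter,
                      n_restarts=n_restarts, seed=seed)
        rows.append({"k": k, "loglik": fit.loglik, "bic": fit.bic,
                     "converged": fit.converged})
    return pd.DataFrame(rows)


def component_intersection(fit: MixtureFit) -> float:
    """Interior crossing point of the two weighted component densities.

    Solves w1*phi(x; mu1, sd1) = w2*phi(x; mu2, sd2) for x in (mu1, mu2)
    via the quadratic obtained by equating log-densities.  With unequal
    variances the quadratic has two roots; only the one between the means
    where the density difference changes sign from component 1 to
    component 2 is the classification boundary.
    """
    if fit.k != 2:
        raise ValueError("component_intersection requires a two-component fit")
    (w1, w2), (m1, m2), (s1, s2) = fit.weights, fit.means, fit.sds
    if not m1 < m2:
        raise ValueError("component means must be distinct and ascending")

    a = 1.0 / (2 * s2 * s2) - 1.0 / (2 * s1 * s1)
    b = m1 / (s1 * s1) - m2 / (s2 * s2)
    c = (m2 * m2) / (2 * s2 * s2) - (m1 * m1) / (2 * s1 * s1) \
        + math.log(w1 / w2) + math.log(s2 / s1)

    if abs(a) < 1e-14:  # equal variances: the quadratic degenerates to a line
        roots = [] if abs(b) < 1e-14 else [-c / b]
    else:
        disc = b * b - 4 * a * c
        if disc < 0:
            roots = []
        else:
            sq = math.sqrt(disc)
            roots = [(-b + sq) / (2 * a), (-b - sq) / (2 * a)]
    interior = sorted(r for r in roots if m1 < r < m2)
    if not interior:
        raise ValueError(
            "no density intersection between the component means; inspect the "
            "fit, or fall back to the midpoint explicitly if appropriate"
        )
    if len(interior) > 1:
        # keep the root where the sign of (w1*phi1 - w2*phi2) flips + -> -
        def diff(x: float) -> float:
            z1, z2 = (x - m1) / s1, (x - m2) / s2
            return (math.log(w1) - math.log(s1) - 0.5 * z1 * z1) - \
                   (math.log(w2) - math.log(s2) - 0.5 * z2 * z2)

        eps = 1e-9 * (m2 - m1)
        interior = [r for r in interior if diff(r - eps) > 0 > diff(r + eps)] or interior
    return float(interior[0])


def assign_components(
    profiles: Sequence[DinucleotideProfile] | Mapping[str, float],
    threshold: float,
) -> ComponentSplit:
    """Label each PASS gene LOW (cpg_oe < threshold) or HIGH (>= threshold)."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if isinstance(profiles, Mapping):
        items = profiles.items()
    else:
        items = ((p.gene_id, p.cpg_oe) for p in profiles
                 if p.status == ProfileStatus.PASS)
    labels = {g: ("LOW" if v < threshold else "HIGH") for g, v in items}
    return ComponentSplit(threshold=float(threshold), labels=labels)


def write_fit_report(fit: MixtureFit, split: ComponentSplit, path: str | Path) -> None:
    report = fit.to_dict()
    report.update({"threshold": split.threshold,
                   "n_low": split.n_low, "n_high": split.n_high})
    Path(path).write_text(json.dumps(report, indent=2) + "\n")
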