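"""Supervised maximum-likelihood ancestry estimation.

Given fixed reference allele frequencies p_kj, each individual's ancestry
vector q maximizes

    l(q) = sum_j [ g_j ln(theta_j) + (2 - g_j) ln(1 - theta_j) ],
    theta_j = sum_k q_k p_kj,

over the simplex, with missing genotypes skipped.  The maximizer is found
by EM-style multiplicative updates

    q_k <- q_k / (2 M) * sum_j [ g_j p_kj / theta_j
                                 + (2 - g_j)(1 - p_kj) / (1 - theta_j) ],

which keep q on the simplex and never decrease l.  Frequencies are clamped
to [eps, 1 - eps] so the likelihood stays finite at fixed or lost alleles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .freqs import AlleleFrequencyTable
from .io import MISSING, GenotypeMatrix

FREQ_EPS = 1e-6


@dataclass
class ReferencePanelFreqs:
    """K reference populations x M SNPs frequency matrix with a designation
    of which references count as European dairy."""

    freq: pd.DataFrame  # index snp_id, columns reference populations
    dairy_populations: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.freq.shape[1] < 2:
            raise ValueError("need at least two reference populations")
        unknown = set(self.dairy_populations) - set(self.freq.columns)
        if unknown:
            raise ValueError(f"dairy designation not among references: {sorted(unknown)}")
        vals = self.freq.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError("reference frequencies must be defined at every SNP")
        if vals.min() < -1e-12 or vals.max() > 1 + 1e-12:
            raise ValueError("reference frequencies must lie in [0, 1]")
        self.dairy_populations = tuple(self.dairy_populations)

    @classmethod
    def from_table(
        cls,
        freqs: AlleleFrequencyTable,
        populations: Sequence[str],
        dairy_populations: Sequence[str],
    ) -> "ReferencePanelFreqs":
        return cls(
            freq=freqs.freq[list(populations)].copy(),
            dairy_populations=tuple(dairy_populations),
        )

    @property
    def populations(self) -> list[str]:
        return list(self.freq.columns)

    def subset(self, snp_ids: Sequence[str]) -> "ReferencePanelFreqs":
        return ReferencePanelFreqs(
            freq=self.freq.loc[list(snp_ids)].copy(),
            dairy_populations=self.dairy_populations,
        )


@dataclass
class AncestryEstimate:
    q: pd.DataFrame  # index sample_id, columns reference populations
    loglik: pd.Series
    n_iter: pd.Series
    converged: pd.Series
    total_dairy: pd.Series

    def to_tsv(self, path: str | Path) -> None:
        out = self.q.copy()
        out["total_dairy"] = self.total_dairy
        out["loglik"] = self.loglik
        out["n_iter"] = self.n_iter
        out["converged"] = self.converged
        out.rename_axis("sample_id").to_csv(path, sep="\t")


def estimate_admixture_supervised(
    g: GenotypeMatrix,
    refs: ReferencePanelFreqs,
    tol: float = 1e-7,
    max_iter: int = 2000,
    return_trace: bool = False,
) -> AncestryEstimate | tuple[AncestryEstimate, np.ndarray]:
    """Per-individual supervised ancestry estimates.

    Initialization is uniform (deterministic).  Convergence is a relative
    log-likelihood change below ``tol``.  If the reference populations are
    indistinguishable (identical frequency rows), the likelihood is flat in
    q; the uniform initialization is returned with ``converged`` False.

    With ``return_trace`` the per-iteration log-likelihood matrix
    (iterations x individuals) is returned alongside, for monotonicity
    checks.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    ref_ids = refs.freq.index.tolist()
    if g.snp_ids != ref_ids:
        if set(g.snp_ids) != set(ref_ids):
            raise ValueError("SNP sets of genotypes and references differ")
        refs = refs.subset(g.snp_ids)

    pops = refs.populations
    K = len(pops)
    P = np.clip(refs.freq.to_numpy(dtype=float), FREQ_EPS, 1.0 - FREQ_EPS)  # M x K
    n, M = g.dosage.shape
    W = (g.dosage != MISSING).astype(float)
    G = np.where(g.dosage == MISSING, 0, g.dosage).astype(float)
    WG = W * G
    WG2 = W * (2.0 - G)
    m_called = W.sum(axis=1)

    flat = bool(np.all(P.max(axis=1) - P.min(axis=1) < 1e-12))

    Q = np.full((n, K), 1.0 / K)

    def loglik_of(Q_: np.ndarray) -> np.ndarray:
        theta = Q_ @ P.T
        np.clip(theta, FREQ_EPS / 2, 1.0 - FREQ_EPS / 2, out=theta)
        return (WG * np.log(theta) + WG2 * np.log1p(-theta)).sum(axis=1)

    ll = loglik_of(Q)
    if not np.isfinite(ll[m_called > 0]).all():
        raise FloatingPointError("non-finite log-likelihood after clamping")
    trace = [ll.copy()]
    n_iter = np.zeros(n, dtype=int)
    converged = np.zeros(n, dtype=bool)
    # individuals with no called genotype have a flat likelihood: keep uniform
    converged[m_called == 0] = True

    if flat or M == 0:
        est = _package(g, pops, Q, ll, n_iter, converged, refs.dairy_populations)
        return (est, np.array(trace)) if return_trace else est

    one_minus_P = 1.0 - P
    denom = np.maximum(2.0 * m_called, 1.0)
    active = np.flatnonzero(~converged)
    for it in range(1, max_iter + 1):
        if active.size == 0:
            break
        Qa = Q[active]
        theta = Qa @ P.T
        np.clip(theta, FREQ_EPS / 2, 1.0 - FREQ_EPS / 2, out=theta)
        A = (WG[active] / theta) @ P
        B = (WG2[active] / (1.0 - theta)) @ one_minus_P
        Qa = Qa * (A + B) / denom[active, None]
        # renormalize against accumulated round-off
        Qa /= np.maximum(Qa.sum(axis=1, keepdims=True), 1e-300)
        theta = Qa @ P.T
        np.clip(theta, FREQ_EPS / 2, 1.0 - FREQ_EPS / 2, out=theta)
        ll_new = (
            WG[active] * np.log(theta) + WG2[active] * np.log1p(-theta)
        ).sum(axis=1)
        rel_change = np.abs(ll_new - ll[active]) / (np.abs(ll[active]) + 1e-12)
        Q[active] = Qa
        ll[active] = ll_new
        trace.append(ll.copy())
        done = rel_change < tol
        n_iter[active[done]] = it
        converged[active[done]] = True
        active = active[~done]
    n_iter[~converged] = max_iter

    est = _package(g, pops, Q, ll, n_iter, converged, refs.dairy_populations)
    return (est, np.array(trace)) if return_trace else est


def _package(
    g: GenotypeMatrix,
    pops: list[str],
    Q: np.ndarray,
    ll: np.ndarray,
    n_iter: np.ndarray,
    converged: np.ndarray,
    dairy: tuple[str, ...],
) -> AncestryEstimate:
    index = pd.Index(g.sample_ids, name="sample_id")
    q = pd.DataFrame(Q, index=index, columns=pops)
    est = AncestryEstimate(
        q=q,
        loglik=pd.Series(ll, index=index),
        n_iter=pd.Series(n_iter, index=index),
        converged=pd.Series(converged, index=index),
        total_dairy=pd.Series(0.0, index=index),
    )
    est.total_dairy = total_dairy_proportion(est, dairy)
    return est


def total_dairy_proportion(
    est: AncestryEstimate, dairy_populations: Sequence[str]
) -> pd.Series:
    """Sum of the designated (European dairy) ancestry components."""
    dairy = list(dairy_populations)
    if not dairy:
        raise ValueError("dairy designation is empty")
    unknown = set(dairy) - set(est.q.columns)
    if unknown:
        raise KeyError(f"designated populations absent from estimate: {sorted(unknown)}")
    return est.q[dairy].sum(axis=1)


def accuracy_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson correlation between panel-based and baseline
    estimates, computed from the product-moment formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = (dx * dx).sum()
    syy = (dy * dy).sum()
    if sxx == 0.0 or syy == 0.0:
        raise ValueError("correlation undefined: zero variance")
    r = (dx * dy).sum() / np.sqrt(sxx * syy)
    return float(r * r)
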