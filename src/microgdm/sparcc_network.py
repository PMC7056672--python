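"""Compositionally aware correlation inference and network construction.

Basis correlations are inferred from log-ratio variances of Dirichlet
composition resamples, with iterative exclusion of strongly correlated
pairs, then summarized as the median over resamples. Pseudo p-values come
from column-permuted bootstrap resamples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import OtuTable, ValidationError

__all__ = [
    "SparccResult",
    "NetworkEdge",
    "sparcc_correlations",
    "sparcc_pvalues",
    "build_network",
]


@dataclass
class SparccResult:
    feature_ids: list
    corr: np.ndarray
    pvals: np.ndarray | None = None
    n_iterations: int = 0
    n_resamples: int = 0
    flagged_features: list = field(default_factory=list)


@dataclass
class NetworkEdge:
    feature_a: str
    feature_b: str
    rho: float
    p: float
    sign: str  # co-occurring | co-excluding


def _dirichlet_composition(counts: np.ndarray, rng: np.random.Generator,
                           pseudocount: float = 1.0) -> np.ndarray:
    g = rng.standard_gamma(counts + pseudocount)
    return g / g.sum(axis=1, keepdims=True)


def _variation_matrix(comp: np.ndarray) -> np.ndarray:
    logc = np.log(comp)
    v = logc.var(axis=0, ddof=1)
    c = np.cov(logc, rowvar=False)
    return v[:, None] + v[None, :] - 2.0 * c


def _basis_correlations(t: np.ndarray, exclusion_threshold: float,
                        max_excluded_fraction: float,
                        n_iterations: int) -> tuple[np.ndarray, list[int]]:
    """Solve the sparsity-assumption linear system for basis variances,
    iteratively excluding the strongest pair, and return correlations plus
    any features excluded from too many pairs."""
    p = t.shape[0]
    m = np.full((p, p), 1.0)
    np.fill_diagonal(m, p - 2.0)
    excluded = np.zeros((p, p), dtype=bool)
    max_excluded = int(max_excluded_fraction * p * (p - 1) / 2)
    flagged: list[int] = []

    def solve() -> np.ndarray:
        tvec = np.where(excluded, 0.0, t).sum(axis=1)
        omega = np.linalg.solve(m, tvec)
        omega = np.maximum(omega, 1e-12)
        denom = 2.0 * np.sqrt(np.outer(omega, omega))
        rho = (omega[:, None] + omega[None, :] - t) / denom
        np.fill_diagonal(rho, 1.0)
        return np.clip(rho, -1.0, 1.0)

    rho = solve()
    for _ in range(min(n_iterations, max_excluded)):
        masked = np.abs(rho)
        masked[excluded] = 0.0
        np.fill_diagonal(masked, 0.0)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= exclusion_threshold:
            break
        excluded[i, j] = excluded[j, i] = True
        m[i, i] -= 1.0
        m[j, j] -= 1.0
        m[i, j] = m[j, i] = 0.0
        # a feature excluded from nearly all its pairs leaves the system
        for kk in (i, j):
            if excluded[kk].sum() >= p - 2 and kk not in flagged:
                flagged.append(kk)
        if np.linalg.cond(m) > 1e12:
            break
        rho = solve()
    return rho, flagged


def sparcc_correlations(table: OtuTable, n_iterations: int = 20,
                        exclusion_threshold: float = 0.1,
                        max_excluded_fraction: float = 0.3,
                        n_dirichlet_resamples: int = 20,
                        seed: int = 0) -> SparccResult:
    """Median basis-correlation matrix over Dirichlet composition resamples."""
    if table.n_features < 4:
        raise ValidationError("need at least 4 features to solve basis variances")
    rng = np.random.default_rng(seed)
    p = table.n_features
    mats = np.empty((n_dirichlet_resamples, p, p))
    flagged: set[int] = set()
    for r in range(n_dirichlet_resamples):
        comp = _dirichlet_composition(table.counts, rng)
        t = _variation_matrix(comp)
        rho, fl = _basis_correlations(
            t, exclusion_threshold, max_excluded_fraction, n_iterations
        )
        flagged.update(fl)
        mats[r] = rho
    corr = np.median(mats, axis=0)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    for k in flagged:
        corr[k, :] = np.nan
        corr[:, k] = np.nan
        corr[k, k] = 1.0
    return SparccResult(
        feature_ids=list(table.feature_ids), corr=corr,
        n_iterations=n_iterations, n_resamples=n_dirichlet_resamples,
        flagged_features=[table.feature_ids[k] for k in sorted(flagged)],
    )


def sparcc_pvalues(table: OtuTable, observed: SparccResult,
                   n_bootstraps: int = 100, seed: int = 0,
                   n_dirichlet_resamples: int = 5) -> SparccResult:
    """Two-sided pseudo p-values from column-permuted bootstrap resamples.

    p = (1 + #{|r_null| >= |r_obs|}) / (1 + n_bootstraps).
    """
    if list(observed.feature_ids) != list(table.feature_ids):
        raise ValidationError("observed result does not match the table")
    if n_bootstraps < 20:
        raise ValidationError("n_bootstraps must be >= 20")
    rng = np.random.default_rng(seed)
    n, p = table.counts.shape
    exceed = np.zeros((p, p))
    obs_abs = np.abs(observed.corr)
    for _ in range(n_bootstraps):
        rows = rng.integers(0, n, size=n)
        boot = table.counts[rows]
        # independent column permutations break all true associations
        null = np.empty_like(boot)
        for j in range(p):
            null[:, j] = boot[rng.permutation(n), j]
        null_tab = OtuTable(
            [f"b{i}" for i in range(n)], list(table.feature_ids), null
        )
        r = sparcc_correlations(
            null_tab, n_iterations=observed.n_iterations,
            n_dirichlet_resamples=n_dirichlet_resamples,
            seed=int(rng.integers(0, 2**31)),
        )
        exceed += np.abs(r.corr) >= obs_abs
    pvals = (1.0 + exceed) / (1.0 + n_bootstraps)
    pvals = (pvals + pvals.T) / 2.0
    np.fill_diagonal(pvals, np.nan)
    return SparccResult(
        feature_ids=list(observed.feature_ids), corr=observed.corr,
        pvals=pvals, n_iterations=observed.n_iterations,
        n_resamples=observed.n_resamples,
        flagged_features=list(observed.flagged_features),
    )


def build_network(result: SparccResult, rho_cutoff: float = 0.3,
                  p_cutoff: float = 0.05) -> list[NetworkEdge]:
    """Edges where |rho| >= rho_cutoff and p < p_cutoff."""
    if result.pvals is None:
        raise ValidationError("result has no p-values; run sparcc_pvalues first")
    edges = []
    p = len(result.feature_ids)
    for i in range(p):
        for j in range(i + 1, p):
            rho = result.corr[i, j]
            pv = result.pvals[i, j]
            if np.isnan(rho) or np.isnan(pv):
                continue
            if abs(rho) >= rho_cutoff and pv < p_cutoff:
                edges.append(NetworkEdge(
                    feature_a=result.feature_ids[i],
                    feature_b=result.feature_ids[j],
                    rho=float(rho), p=float(pv),
                    sign="co-occurring" if rho > 0 else "co-excluding",
                ))
    return edges
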