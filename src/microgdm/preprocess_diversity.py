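"""OTU filtering, rarefaction, rank aggregation, and alpha diversity.

Alpha indices follow the QIIME-style conventions: Shannon in bits,
Simpson = 1 - sum(p^2), Dominance = sum(p^2), Heip's evenness
(2^H - 1)/(S - 1), Chao1 with bias-corrected fallback, and ACE with the
standard rare/abundant cut at 10 reads.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import ttest_ind

from .io_formats import OtuTable, TaxonomyMap, RANKS, ValidationError

__all__ = [
    "AlphaDiversityRecord",
    "filter_rare_otus",
    "rarefy",
    "aggregate_to_rank",
    "alpha_indices",
    "alpha_table",
    "compare_alpha",
    "rarefaction_curve",
]

log = logging.getLogger(__name__)

ALPHA_INDEX_NAMES = (
    "observed", "chao1", "ace", "shannon", "simpson", "heip_e", "dominance",
)

ACE_RARE_THRESHOLD = 10


@dataclass
class AlphaDiversityRecord:
    sample_id: str
    observed: int
    chao1: float
    ace: float  # NaN when undefined (C_ace = 0)
    shannon: float  # bits
    simpson: float
    heip_e: float  # NaN when observed <= 1
    dominance: float


def filter_rare_otus(table: OtuTable, min_fraction: float = 0.00005):
    """Drop features whose total count is strictly below
    ``min_fraction`` x grand total. Returns (filtered table, removed ids)."""
    if not 0 <= min_fraction < 1:
        raise ValueError("min_fraction must be in [0, 1)")
    totals = table.counts.sum(axis=0)
    grand = totals.sum()
    threshold = min_fraction * grand
    if min_fraction == 0:
        keep = np.ones(len(totals), dtype=bool)
    else:
        # strict "<" removal: totals exactly at the threshold are retained
        keep = (totals >= threshold) & (totals > 0)
    removed = [f for f, k in zip(table.feature_ids, keep) if not k]
    kept = [f for f, k in zip(table.feature_ids, keep) if k]
    return table.select_features(kept), removed


def rarefy(table: OtuTable, depth: int = 36000, seed: int = 0) -> OtuTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` reads are dropped with a warning.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    depths = table.depths()
    keep = depths >= depth
    if not keep.any():
        raise ValueError(f"all {table.n_samples} samples are below depth {depth}")
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        log.warning("rarefy: dropping %d sample(s) below depth %d: %s",
                    len(dropped), depth, ", ".join(dropped[:5]))
    rows = []
    ids = []
    for i, sid in enumerate(table.sample_ids):
        if not keep[i]:
            continue
        if depths[i] == depth:
            rows.append(table.counts[i].copy())
        else:
            rows.append(rng.multivariate_hypergeometric(table.counts[i], depth))
        ids.append(sid)
    return OtuTable(ids, list(table.feature_ids), np.array(rows, dtype=np.int64))


def aggregate_to_rank(table: OtuTable, taxonomy: TaxonomyMap, rank: str) -> OtuTable:
    """Sum counts over features sharing the lineage prefix at ``rank``.

    Features with an unassigned name at ``rank`` are pooled into
    ``unassigned@<rank>``.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    taxonomy.check_covers(table)
    groups: dict[str, list[int]] = {}
    for j, fid in enumerate(table.feature_ids):
        name = taxonomy.name_at(fid, rank)
        label = name if name else f"unassigned@{rank}"
        groups.setdefault(label, []).append(j)
    labels = list(groups)
    counts = np.zeros((table.n_samples, len(labels)), dtype=np.int64)
    for k, label in enumerate(labels):
        counts[:, k] = table.counts[:, groups[label]].sum(axis=1)
    return OtuTable(list(table.sample_ids), labels, counts)


def alpha_indices(counts, sample_id: str = "") -> AlphaDiversityRecord:
    """All seven alpha-diversity indices for one sample's count vector."""
    c = np.asarray(counts, dtype=np.int64)
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("all-zero count vector")
    n = int(c.sum())
    s_obs = int(c.size)
    p = c / n

    shannon = float(-(p * np.log2(p)).sum())
    dominance = float((p * p).sum())
    simpson = 1.0 - dominance
    heip_e = (2.0**shannon - 1.0) / (s_obs - 1) if s_obs > 1 else float("nan")

    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if f2 > 0:
        chao1 = s_obs + f1 * f1 / (2.0 * f2)
    else:
        chao1 = s_obs + f1 * (f1 - 1) / 2.0

    rare = c[c <= ACE_RARE_THRESHOLD]
    s_abund = int((c > ACE_RARE_THRESHOLD).sum())
    s_rare = int(rare.size)
    n_rare = int(rare.sum())
    if s_rare == 0:
        ace = float(s_abund)
    else:
        c_ace = 1.0 - f1 / n_rare
        if c_ace <= 0:
            ace = float("nan")  # undefined: all rare reads are singletons
        else:
            ks = np.arange(1, ACE_RARE_THRESHOLD + 1)
            fk = np.array([(c == k).sum() for k in ks])
            gamma2 = max(
                (s_rare / c_ace)
                * (ks * (ks - 1) * fk).sum()
                / (n_rare * (n_rare - 1))
                - 1.0,
                0.0,
            ) if n_rare > 1 else 0.0
            ace = s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2

    return AlphaDiversityRecord(
        sample_id=sample_id, observed=s_obs, chao1=float(chao1), ace=float(ace),
        shannon=shannon, simpson=float(simpson), heip_e=float(heip_e),
        dominance=dominance,
    )


def alpha_table(table: OtuTable) -> pd.DataFrame:
    """Per-sample alpha indices as a data frame indexed by sample id."""
    recs = [alpha_indices(table.counts[i], sid)
            for i, sid in enumerate(table.sample_ids)]
    return pd.DataFrame(
        {name: [getattr(r, name) for r in recs] for name in ALPHA_INDEX_NAMES},
        index=pd.Index([r.sample_id for r in recs], name="#SampleID"),
    )


def compare_alpha(alpha: pd.DataFrame, groups) -> pd.DataFrame:
    """Welch two-sided t-test per index between the two groups.

    ``groups`` is aligned with ``alpha``'s rows. Returns one row per index
    with group means, t, and p.
    """
    groups = np.asarray(groups)
    levels = sorted(set(groups))
    if len(levels) != 2:
        raise ValidationError(f"expected exactly two groups, got {levels}")
    a_mask = groups == levels[0]
    if a_mask.sum() < 2 or (~a_mask).sum() < 2:
        raise ValidationError("each group needs at least two samples")
    rows = []
    for name in alpha.columns:
        va = alpha.loc[a_mask, name].dropna().to_numpy(dtype=float)
        vb = alpha.loc[~a_mask, name].dropna().to_numpy(dtype=float)
        if np.allclose(va.var(), 0) and np.allclose(vb.var(), 0) and np.isclose(
            va.mean(), vb.mean()
        ):
            t, pval = 0.0, 1.0
        else:
            t, pval = ttest_ind(va, vb, equal_var=False)
        rows.append({
            "index": name,
            f"mean_{levels[0]}": va.mean(),
            f"mean_{levels[1]}": vb.mean(),
            "t": float(t),
            "p": float(pval),
            "higher_in": levels[0] if va.mean() >= vb.mean() else levels[1],
        })
    return pd.DataFrame(rows).set_index("index")


def _expected_observed(counts: np.ndarray, depth: int) -> float:
    """Analytic E[# features observed] when subsampling ``depth`` reads
    without replacement (hypergeometric expectation)."""
    c = counts[counts > 0]
    n = int(c.sum())
    if depth > n:
        raise ValueError("depth exceeds sample total")
    # P(feature absent) = C(N - c_i, d) / C(N, d)
    lognum = gammaln(n - c + 1) + gammaln(n - depth + 1)
    logden = gammaln(n - c - depth + 1) + gammaln(n + 1)
    with np.errstate(invalid="ignore"):
        p_absent = np.where(n - c >= depth, np.exp(lognum - logden), 0.0)
    return float((1.0 - p_absent).sum())


def rarefaction_curve(table: OtuTable, depths, reps: int = 0,
                      seed: int = 0) -> pd.DataFrame:
    """Mean observed-feature count per sample at each depth.

    ``reps = 0`` uses the exact hypergeometric expectation; ``reps > 0``
    averages over Monte-Carlo subsamples instead.
    """
    depths = list(depths)
    if any(b <= a for a, b in zip(depths, depths[1:])):
        raise ValueError("depths must be strictly ascending")
    rng = np.random.default_rng(seed)
    out = np.full((table.n_samples, len(depths)), np.nan)
    for i in range(table.n_samples):
        c = table.counts[i]
        total = int(c.sum())
        for k, d in enumerate(depths):
            if d > total:
                continue
            if reps <= 0:
                out[i, k] = _expected_observed(c, d)
            else:
                obs = [
                    int((rng.multivariate_hypergeometric(c, d) > 0).sum())
                    for _ in range(reps)
                ]
                out[i, k] = float(np.mean(obs))
    return pd.DataFrame(out, index=pd.Index(table.sample_ids, name="#SampleID"),
                        columns=depths)
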