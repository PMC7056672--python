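"""Spearman rank correlation between feature abundances and clinical indices."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .io_formats import OtuTable, SampleMetadata, ValidationError

__all__ = ["CorrelationCell", "spearman", "correlation_grid"]


@dataclass
class CorrelationCell:
    feature_id: str
    index_name: str
    rho: float  # NaN when undefined (constant input)
    p: float
    q: float
    n_used: int


def spearman(x, y) -> tuple[float, float]:
    """Tie-corrected Spearman rho (Pearson on mid-ranks) with a two-sided
    t-approximation p. NaN pairs are removed pairwise; a constant vector
    yields (nan, nan)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 4:
        raise ValidationError(
            f"need >= 4 complete pairs, got {len(x)}"
        )
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    res = scipy.stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def correlation_grid(table: OtuTable, metadata: SampleMetadata,
                     feature_ids=None, index_names=None) -> pd.DataFrame:
    """All (feature, clinical index) Spearman cells, pairwise-complete.

    Features are correlated on relative abundance. Returns a long-format
    frame with unadjusted p and Benjamini-Hochberg q side by side;
    undefined cells are kept with NaN rho and flagged via n_used.
    """
    feature_ids = list(feature_ids) if feature_ids is not None else list(
        table.feature_ids
    )
    index_names = list(index_names) if index_names is not None else list(
        metadata.clinical_columns
    )
    shared = [s for s in table.sample_ids if s in set(metadata.sample_ids)]
    if not shared:
        raise ValidationError("no overlapping samples between table and metadata")
    sub = table.select_samples(shared)
    rel = sub.relative_abundance()
    clin = metadata.frame.loc[shared]

    rows = []
    for fid in feature_ids:
        j = sub.feature_ids.index(fid)
        x = rel[:, j]
        for cname in index_names:
            y = clin[cname].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            n_used = int(ok.sum())
            try:
                rho, p = spearman(x, y)
            except ValidationError:
                rho, p = float("nan"), float("nan")
            rows.append({"feature": fid, "index": cname, "rho": rho, "p": p,
                         "n_used": n_used})
    df = pd.DataFrame(rows)
    valid = df["p"].notna()
    q = np.full(len(df), np.nan)
    if valid.any():
        q[valid.to_numpy()] = scipy.stats.false_discovery_control(
            df.loc[valid, "p"].to_numpy(), method="bh"
        )
    df["q"] = q
    return df[["feature", "index", "rho", "p", "q", "n_used"]]
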