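"""Two-group differential-abundance effect sizes.

A Kruskal-Wallis screen followed by a bootstrapped linear-discriminant
effect size on per-million-scaled abundances, with the conventional
log10-score scale where a cutoff of 2 separates signal from noise.
Works on any sample x feature abundance table (taxa or pathways).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .io_formats import OtuTable, ValidationError

__all__ = [
    "EffectSizeResult",
    "kruskal_wallis",
    "lda_effect_size",
    "lefse",
    "scale_per_million",
]

PER_MILLION = 1e6


@dataclass
class EffectSizeResult:
    feature_id: str
    kw_p: float
    lda_score: float
    enriched_group: str
    significant: bool


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p for two groups.

    All-identical values return (0, 1) by convention.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValidationError(f"expected two groups, got {list(levels)}")
    a = values[groups == levels[0]]
    b = values[groups == levels[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both groups must be non-empty")
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = scipy.stats.kruskal(a, b)
    return float(h), float(p)


def scale_per_million(matrix: np.ndarray) -> np.ndarray:
    """Scale each row (sample) to sum to 1e6."""
    m = np.asarray(matrix, dtype=float)
    rowsum = m.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(rowsum > 0, m / rowsum * PER_MILLION, 0.0)


def _lda_direction(x: np.ndarray, y: np.ndarray, ridge: float = 1e-6) -> np.ndarray:
    m1 = x[y].mean(axis=0)
    m0 = x[~y].mean(axis=0)
    x1 = x[y] - m1
    x0 = x[~y] - m0
    s = (x1.T @ x1 + x0.T @ x0) / (len(y) - 2)
    tr = np.trace(s)
    s = s + ridge * (tr if tr > 0 else 1.0) * np.eye(s.shape[0])
    return np.linalg.solve(s, m1 - m0)


def lda_effect_size(matrix: np.ndarray, groups, n_boot: int = 30,
                    subsample_fraction: float = 2 / 3,
                    seed: int = 0) -> np.ndarray:
    """Per-feature bootstrapped LDA effect score (log10 scale).

    ``matrix`` must already be per-million scaled. Per bootstrap round a
    two-class discriminant is fitted on a class-stratified subsample; the
    per-feature effect is |(w_f * (m1_f - m0_f) + (m1_f - m0_f)) / 2|, and
    the score is log10(max(mean effect, 1)) so null features sit near 0.
    """
    x = np.asarray(matrix, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValidationError(f"expected two groups, got {list(levels)}")
    y = groups == levels[1]  # second level = "positive" for direction only
    rng = np.random.default_rng(seed)
    idx1 = np.flatnonzero(y)
    idx0 = np.flatnonzero(~y)
    k1 = max(int(round(len(idx1) * subsample_fraction)), 2)
    k0 = max(int(round(len(idx0) * subsample_fraction)), 2)
    effects = np.zeros((n_boot, x.shape[1]))
    # scale w so the projected class separation has unit-free magnitude
    for b in range(n_boot):
        take = np.concatenate([
            rng.choice(idx1, size=k1, replace=False),
            rng.choice(idx0, size=k0, replace=False),
        ])
        xs, ys = x[take], y[take]
        if xs[ys].shape[0] < 2 or xs[~ys].shape[0] < 2:
            continue
        w = _lda_direction(xs, ys)
        wn = np.linalg.norm(w)
        if wn > 0:
            w = w / wn
        dmeans = xs[ys].mean(axis=0) - xs[~ys].mean(axis=0)
        effects[b] = np.abs(0.5 * (w * dmeans + dmeans))
    mean_effect = effects.mean(axis=0)
    return np.log10(np.maximum(mean_effect, 1.0))


def lefse(table: OtuTable, groups, p_cutoff: float = 0.05,
          lda_cutoff: float = 2.0, n_boot: int = 30,
          subsample_fraction: float = 2 / 3,
          seed: int = 0) -> list[EffectSizeResult]:
    """KW screen then LDA effect size; both cutoffs set ``significant``.

    Returns one record per feature that passed the screen, sorted by
    descending |lda_score|. Enrichment direction is the group with the
    higher mean per-million abundance.
    """
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValidationError(f"expected two groups, got {list(levels)}")
    if table.n_features == 0:
        return []
    scaled = scale_per_million(table.counts)
    kw = np.array([kruskal_wallis(scaled[:, j], groups)
                   for j in range(table.n_features)])
    passed = np.flatnonzero(kw[:, 1] < p_cutoff)
    if len(passed) == 0:
        return []
    scores = lda_effect_size(scaled[:, passed], groups, n_boot=n_boot,
                             subsample_fraction=subsample_fraction, seed=seed)
    mask1 = groups == levels[1]
    results = []
    for pos, j in enumerate(passed):
        m1 = scaled[mask1, j].mean()
        m0 = scaled[~mask1, j].mean()
        enriched = str(levels[1]) if m1 >= m0 else str(levels[0])
        score = float(scores[pos])
        results.append(EffectSizeResult(
            feature_id=table.feature_ids[j],
            kw_p=float(kw[j, 1]),
            lda_score=score,
            enriched_group=enriched,
            significant=bool(kw[j, 1] < p_cutoff and score >= lda_cutoff),
        ))
    results.sort(key=lambda r: -abs(r.lda_score))
    return results
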