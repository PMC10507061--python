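"""Scoring estimator decisions and literature-review proportions.

A fitted grid is scored into a rate table: per design cell and method, the
proportion of replicates whose 95% interval excluded zero.  When the true
correlation r is 0 this proportion is the false-positive rate; when r > 0
it is statistical power.  Uncertainty is summarized by two-tailed 95%
percentile bootstrap intervals over replicates (1000 resamples).

:func:`review_proportions` computes, for a coded literature-review table,
the proportion of articles per review arm that contain at least one
analysis accounting for non-independence, overall and split by control
category, with the same bootstrap intervals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["compute_rates", "bootstrap_ci", "review_proportions",
           "REVIEW_CATEGORIES"]

CELL_KEYS = ["sigma_source", "lambda", "rho", "r", "method"]

REVIEW_CATEGORIES = ["any_control", "region_fe", "distance",
                     "cultural_history", "other"]


def bootstrap_ci(successes, B: int = 1000, seed: int = 0,
                 alpha: float = 0.05) -> tuple[float, float]:
    """Two-tailed percentile bootstrap interval for a proportion of flags."""
    flags = np.asarray(successes, dtype=float)
    if flags.size == 0:
        raise ValueError("need at least one flag")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, flags.size, size=(B, flags.size))
    props = flags[idx].mean(axis=1)
    lo, hi = np.quantile(props, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def compute_rates(fits: pd.DataFrame, B: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Aggregate a tidy table of fits into FPR/power rates per cell × method.

    ``fits`` needs columns sigma_source, lambda, rho, r, method,
    excludes_zero (and optionally ``cell``, whose rows must agree on r).
    Rows are labelled ``fpr`` when r = 0 and ``power`` otherwise.  Fit order
    never matters: this is a pure aggregation.
    """
    need = set(CELL_KEYS) | {"excludes_zero"}
    missing = need - set(fits.columns)
    if missing:
        raise ValueError(f"fits table missing columns: {sorted(missing)}")
    if "cell" in fits.columns:
        mixed = fits.groupby("cell")["r"].nunique()
        bad = mixed[mixed > 1].index.tolist()
        if bad:
            raise ValueError(f"cells mix different r values: {bad}")
    rows = []
    grouped = fits.groupby(CELL_KEYS, sort=True)
    for gi, (key, grp) in enumerate(grouped):
        flags = grp["excludes_zero"].to_numpy(bool)
        lo, hi = bootstrap_ci(flags, B=B,
                              seed=np.random.SeedSequence(seed, spawn_key=(gi,))
                              .generate_state(1)[0])
        rec = dict(zip(CELL_KEYS, key))
        rec.update(n_reps=len(flags), rate=float(flags.mean()),
                   ci_low=lo, ci_high=hi,
                   kind="fpr" if rec["r"] == 0 else "power")
        rows.append(rec)
    return pd.DataFrame(rows)


def review_proportions(review: pd.DataFrame, B: int = 1000,
                       seed: int = 0) -> pd.DataFrame:
    """Per-arm proportions of articles with each non-independence control.

    ``review`` has one row per article with a review ``arm`` column
    (e.g. "economic development" / "cultural values") and boolean flag
    columns ``any_control``, ``region_fe``, ``distance``,
    ``cultural_history``, ``other``.  Returns one row per arm × category
    with the raw proportion and a percentile bootstrap interval.
    """
    if "arm" not in review.columns:
        raise ValueError("review table needs an 'arm' column")
    cats = [c for c in REVIEW_CATEGORIES if c in review.columns]
    if not cats:
        raise ValueError(f"review table has none of {REVIEW_CATEGORIES}")
    rows = []
    for ai, (arm, grp) in enumerate(sorted(review.groupby("arm"))):
        if len(grp) == 0:
            raise ValueError(f"review arm {arm!r} has no articles")
        for ci, cat in enumerate(cats):
            flags = grp[cat].to_numpy(bool)
            lo, hi = bootstrap_ci(
                flags, B=B,
                seed=np.random.SeedSequence(seed, spawn_key=(ai, ci))
                .generate_state(1)[0])
            rows.append({"arm": arm, "category": cat, "n_articles": len(flags),
                         "proportion": float(flags.mean()),
                         "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)
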