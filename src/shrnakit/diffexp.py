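"""Paired differential expression with fold-change thresholds.

Samples are paired across conditions by shared time point.  Per feature, a
classical paired t-test is run on log2 expression differences across pairs
(two-sided, n_pairs - 1 degrees of freedom), while the fold change is the
ratio of mean *linear* expression between conditions, reported signed:
r for r >= 1 and -1/r otherwise, so that a threshold "|FC| > 1.1" applies
symmetrically to up- and down-regulation.  A feature is called
differentially expressed when p < p_thresh and |FC| > fc_thresh, both
strict.  With three time points the test has two degrees of freedom — an
honest but weak test; no moderation is applied, and no multiple-testing
correction by default (Benjamini-Hochberg is available behind a flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DesignError
from .ncounter import NormalizedMatrix

__all__ = [
    "PairedDesign",
    "paired_t_test",
    "fold_change",
    "call_de",
    "run_diffexp",
    "de_summary",
]


@dataclass(frozen=True)
class PairedDesign:
    """Two conditions and their time-point-matched sample pairs."""

    condition_a: str
    condition_b: str
    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self):
        if len(self.pairs) < 2:
            raise DesignError("a paired design needs >= 2 pairs")
        flat = [s for pair in self.pairs for s in pair]
        if len(set(flat)) != len(flat):
            raise DesignError("each sample may appear in at most one pair")

    @classmethod
    def from_metadata(
        cls, meta: pd.DataFrame, condition_a: str, condition_b: str,
        pair_key: str = "pair_id",
    ) -> "PairedDesign":
        """Build pairs by matching ``pair_key`` (default: shared time point)."""
        for cond in (condition_a, condition_b):
            if cond not in set(meta["condition"]):
                raise DesignError(f"condition '{cond}' not present in metadata")
        a = meta[meta["condition"] == condition_a]
        b = meta[meta["condition"] == condition_b]
        pairs = []
        for key, rows_a in a.groupby(pair_key, sort=True):
            rows_b = b[b[pair_key] == key]
            if len(rows_a) == 1 and len(rows_b) == 1:
                pairs.append((rows_a.index[0], rows_b.index[0]))
            elif len(rows_b) > 1 or len(rows_a) > 1:
                raise DesignError(f"pair key '{key}' is not unique within a condition")
        return cls(condition_a, condition_b, tuple(pairs))

    @property
    def a_samples(self) -> list[str]:
        return [p[0] for p in self.pairs]

    @property
    def b_samples(self) -> list[str]:
        return [p[1] for p in self.pairs]


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Classical paired t on differences b - a; two-sided p, df = n - 1.

    All-zero differences give (nan, nan): the statistic is undefined and
    such features are never called differentially expressed.  Zero-variance
    differences with a nonzero mean (an exactly reproducible shift, e.g.
    noise-free data) give the statistic's limit (+/-inf, 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DesignError("paired t-test needs two equal-length 1-d value lists")
    if len(a) < 2:
        raise DesignError("paired t-test needs >= 2 pairs")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise DesignError("paired t-test requires finite values")
    d = b - a
    if np.std(d) == 0:
        if d[0] == 0:
            return (np.nan, np.nan)
        return (np.inf * np.sign(d[0]), 0.0)
    res = stats.ttest_rel(b, a)
    return (float(res.statistic), float(res.pvalue))


def fold_change(mean_a: float, mean_b: float, pseudocount: float = 0.0) -> float:
    """Signed linear fold change between two non-negative means.

    r = (mean_b + pseudocount) / (mean_a + pseudocount); returns r if
    r >= 1 else -1/r, so |fc| >= 1 always.  Both means zero (with zero
    pseudocount) is undefined and returns nan.
    """
    if mean_a < 0 or mean_b < 0:
        raise ConfigError("means", "fold change requires non-negative means")
    ma, mb = mean_a + pseudocount, mean_b + pseudocount
    if ma == 0 and mb == 0:
        return np.nan
    if ma == 0:
        return np.inf
    if mb == 0:
        return -np.inf
    r = mb / ma
    return float(r) if r >= 1 else float(-1.0 / r)


def call_de(
    results: pd.DataFrame,
    p_thresh: float,
    fc_thresh: float,
    bh: bool = False,
) -> pd.DataFrame:
    """Flag differential expression with strict thresholds, as printed:
    p < p_thresh and |FC| > fc_thresh.

    Undefined p (nan) is treated as 1 and never called.  With ``bh=True``
    the p column is Benjamini-Hochberg adjusted first (column ``p_adj``).
    """
    if p_thresh <= 0:
        raise ConfigError("p_thresh", "must be > 0")
    if fc_thresh < 1:
        raise ConfigError("fc_thresh", "must be >= 1")
    out = results.copy()
    p = out["p"].to_numpy(dtype=float)
    if bh:
        finite = np.isfinite(p)
        adj = np.full_like(p, np.nan)
        if finite.any():
            adj[finite] = stats.false_discovery_control(p[finite], method="bh")
        out["p_adj"] = adj
        p = adj
    p_eff = np.where(np.isfinite(p), p, 1.0)
    fc = out["fc"].to_numpy(dtype=float)
    fc_ok = np.isfinite(fc) & (np.abs(fc) > fc_thresh)
    out["is_de"] = (p_eff < p_thresh) & fc_ok
    out["direction"] = np.where(
        out["is_de"] & (fc > 0), "up", np.where(out["is_de"] & (fc < 0), "down", "")
    )
    return out


def de_summary(results: pd.DataFrame) -> dict:
    """Counts of tested/DE/up/down features for a called result table."""
    n_up = int((results["direction"] == "up").sum())
    n_down = int((results["direction"] == "down").sum())
    return {
        "n_tested": int(len(results)),
        "n_de": int(results["is_de"].sum()),
        "n_up": n_up,
        "n_down": n_down,
    }


def run_diffexp(
    data: NormalizedMatrix | pd.DataFrame,
    design: PairedDesign,
    p_thresh: float = 0.05,
    fc_thresh: float = 1.1,
    fc_mode: str = "ratio_of_means",
    fc_pseudocount: float = 0.0,
    log_pseudocount: float = 1.0,
    bh: bool = False,
) -> pd.DataFrame:
    """Per-feature paired DE between design.condition_a and condition_b.

    The t-test runs on log2 values (log2(x + log_pseudocount) when a plain
    linear matrix is given); the fold change on linear means across the
    paired samples (``fc_mode='mean_of_ratios'`` averages per-pair ratios
    instead).  Rows are ordered by feature id.  Positive fc means higher in
    condition_b.
    """
    if isinstance(data, NormalizedMatrix):
        linear, log2v = data.values, data.log2_values
    else:
        linear = data.astype(float)
        log2v = np.log2(linear + log_pseudocount)
    missing = [
        s for s in (*design.a_samples, *design.b_samples) if s not in linear.columns
    ]
    if missing:
        raise DesignError(f"design samples missing from matrix: {missing}")
    if fc_mode not in ("ratio_of_means", "mean_of_ratios"):
        raise ConfigError("fc_mode", f"unknown mode '{fc_mode}'")

    a_cols, b_cols = design.a_samples, design.b_samples
    la = log2v[a_cols].to_numpy()
    lb = log2v[b_cols].to_numpy()
    diffs = lb - la
    zero_var = diffs.std(axis=1) == 0
    all_zero = zero_var & (diffs[:, 0] == 0)
    exact_shift = zero_var & (diffs[:, 0] != 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns on zero-variance rows
        res = stats.ttest_rel(lb, la, axis=1)
    t = np.where(zero_var, np.nan, res.statistic)
    p = np.where(zero_var, np.nan, res.pvalue)
    with np.errstate(invalid="ignore"):
        t = np.where(exact_shift, np.inf * np.sign(diffs[:, 0]), t)
    p = np.where(exact_shift, 0.0, p)
    t = np.where(all_zero, np.nan, t)
    p = np.where(all_zero, np.nan, p)

    mean_a = linear[a_cols].mean(axis=1).to_numpy()
    mean_b = linear[b_cols].mean(axis=1).to_numpy()
    if fc_mode == "ratio_of_means":
        fc = np.array(
            [fold_change(ma, mb, fc_pseudocount) for ma, mb in zip(mean_a, mean_b)]
        )
    else:
        ratios = (linear[b_cols].to_numpy() + fc_pseudocount) / (
            linear[a_cols].to_numpy() + fc_pseudocount
        )
        r = ratios.mean(axis=1)
        fc = np.where(r >= 1, r, -1.0 / r)

    out = pd.DataFrame(
        {
            "feature_id": linear.index,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fc": fc,
            "t": t,
            "p": p,
        }
    ).sort_values("feature_id", kind="stable").set_index("feature_id")
    return call_de(out, p_thresh, fc_thresh, bh=bh)
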