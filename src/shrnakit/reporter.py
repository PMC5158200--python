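"""Reporter-assay scoring: luciferase ratios, flow composite score, qPCR.

Three readouts of promoter activity are scored here.

Luciferase: per-condition mean RLU divided by a reference condition's mean,
with a delta-method standard error.  Ratios chain: activity relative to an
untransfected control, divided by the control-relative activity of a
reference transfection (e.g. the CRX/NRL condition), equals the activity
relative to that reference exactly.

Flow cytometry: a positivity threshold is an empirical quantile of an
untransfected control's intensity distribution; a sample's composite score
is (percent positive) x (median intensity of positive events), reported as
a ratio to the control sample's score.

qPCR: standard delta-delta-Ct relative quantification against a reference
gene and calibrator sample, assuming a configurable amplification
efficiency (default 2, one doubling per cycle).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, ShrnakitError

__all__ = [
    "FlowEvents",
    "RelativeActivity",
    "FlowScore",
    "relative_activity",
    "double_relative_activity",
    "flow_threshold",
    "flow_reporter_score",
    "qpcr_relative",
]


@dataclass
class FlowEvents:
    """Per-event fluorescence intensities for one sample."""

    intensities: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1:
            raise ConfigError("intensities", "must be a 1-d event vector")
        if (self.intensities < 0).any():
            raise ConfigError("intensities", "must be non-negative")

    @property
    def n_events(self) -> int:
        return len(self.intensities)


@dataclass(frozen=True)
class RelativeActivity:
    """A ratio of mean reporter activities with its propagated SE."""

    ratio: float
    se: float
    condition: str
    reference: str
    n_condition: int
    n_reference: int


def _condition_stats(table: pd.DataFrame, condition: str, day=None):
    rows = table[table["condition"] == condition]
    if day is not None:
        rows = rows[rows["day"] == day]
    if rows.empty:
        raise ShrnakitError(f"no wells for condition '{condition}'"
                            + (f" on day {day}" if day is not None else ""))
    vals = rows["rlu"].to_numpy(dtype=float)
    mean = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return mean, se, len(vals)


def relative_activity(
    table: pd.DataFrame,
    condition: str,
    reference_condition: str,
    day=None,
) -> RelativeActivity:
    """Mean RLU of ``condition`` over mean RLU of ``reference_condition``.

    Day strata are never pooled: if the table spans several days, ``day``
    must select one.  The SE of the ratio is propagated from the two
    replicate SEs by the delta method.
    """
    if day is None and table["day"].nunique() > 1:
        raise ShrnakitError(
            "table spans multiple days; pass `day` (day strata are not pooled)"
        )
    m_c, se_c, n_c = _condition_stats(table, condition, day)
    m_r, se_r, n_r = _condition_stats(table, reference_condition, day)
    if m_r == 0:
        raise ShrnakitError(f"reference condition '{reference_condition}' has mean 0")
    ratio = m_c / m_r
    se = abs(ratio) * np.sqrt((se_c / m_c) ** 2 + (se_r / m_r) ** 2) if m_c else se_c / m_r
    return RelativeActivity(
        ratio=float(ratio), se=float(se),
        condition=condition, reference=reference_condition,
        n_condition=n_c, n_reference=n_r,
    )


def double_relative_activity(
    table: pd.DataFrame,
    condition: str,
    control_condition: str,
    reference_condition: str,
    day=None,
) -> tuple[RelativeActivity, RelativeActivity]:
    """Activity vs the plate control and, chained, vs a reference condition.

    Returns (vs_control, vs_reference); by construction
    vs_reference.ratio == vs_control.ratio / vs_control(reference).ratio.
    """
    vs_control = relative_activity(table, condition, control_condition, day=day)
    vs_reference = relative_activity(table, condition, reference_condition, day=day)
    return vs_control, vs_reference


def flow_threshold(control: FlowEvents, quantile: float = 0.999) -> float:
    """Positivity threshold: empirical quantile of the control distribution.

    The default 0.999 admits ~0.1% of untransfected control events as
    false positives.  Requires >= 100 control events.
    """
    if not 0 < quantile <= 1:
        raise ConfigError("quantile", "must be in (0, 1]")
    if control.n_events < 100:
        raise ShrnakitError(
            f"control has {control.n_events} events; >= 100 required for a threshold"
        )
    return float(np.quantile(control.intensities, quantile))


@dataclass(frozen=True)
class FlowScore:
    """Composite reporter score: percent positive x median positive intensity."""

    percent_positive: float
    median_positive: float
    score: float
    relative: float | None = None
    no_positive_events: bool = False


def flow_reporter_score(
    sample: FlowEvents,
    threshold: float,
    control_score: float | None = None,
) -> FlowScore:
    """Score a sample against a positivity threshold.

    percent_positive = 100 x fraction of events strictly above threshold;
    median_positive = median intensity among those events (even counts
    average the two central order statistics).  ``score`` multiplies the
    two; with ``control_score`` the ratio to the control is filled in.
    A sample with no positive events scores 0 and is flagged.
    """
    if control_score is not None and control_score <= 0:
        raise ConfigError("control_score", "must be > 0")
    pos = sample.intensities[sample.intensities > threshold]
    if len(pos) == 0:
        rel = 0.0 if control_score is not None else None
        return FlowScore(0.0, 0.0, 0.0, relative=rel, no_positive_events=True)
    percent = 100.0 * len(pos) / sample.n_events
    median = float(np.median(pos))
    score = percent * median
    rel = score / control_score if control_score is not None else None
    return FlowScore(percent, median, score, relative=rel)


def qpcr_relative(
    table: pd.DataFrame,
    target_gene: str,
    sample: str,
    calibrator_sample: str,
    reference_gene: str = "GAPDH",
    efficiency: float = 2.0,
) -> float:
    """Delta-delta-Ct relative expression of ``target_gene``.

    relative = efficiency ** -((Ct_t - Ct_ref)_sample - (Ct_t - Ct_ref)_calibrator)

    Replicate Cts are averaged per (sample, gene).  Missing combinations
    raise an error naming the sample and gene.
    """
    if efficiency <= 1:
        raise ConfigError("efficiency", "must be > 1")

    def mean_ct(samp: str, gene: str) -> float:
        rows = table[(table["sample"] == samp) & (table["gene"] == gene)]
        if rows.empty:
            raise ShrnakitError(f"no Ct for gene '{gene}' in sample '{samp}'")
        cts = rows["ct"].to_numpy(dtype=float)
        if not np.isfinite(cts).all():
            raise ShrnakitError(f"non-finite Ct for gene '{gene}' in sample '{samp}'")
        return float(cts.mean())

    d_sample = mean_ct(sample, target_gene) - mean_ct(sample, reference_gene)
    d_cal = mean_ct(calibrator_sample, target_gene) - mean_ct(calibrator_sample, reference_gene)
    return float(efficiency ** -(d_sample - d_cal))
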