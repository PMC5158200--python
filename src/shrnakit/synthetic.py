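"""Synthetic assay data with known ground truth.

Every input the analysis consumes can be generated here with the statistical
structure the methods assume: hybridization count matrices with positive
spike-in controls and a linear count response, reporter plates with
condition-specific fold effects, flow-cytometry event mixtures with a positive
subpopulation, and qPCR Ct tables with a reference gene.  Planted parameters
(abundances, fold changes, fractions, relative expressions) are retained so
that downstream estimators can be checked against the generative truth; with
all noise switched off every estimator recovers its planted parameter exactly.

The noise model is multiplicative lognormal throughout: counts and light
units are positive and right-skewed, and a lognormal factor with unit mean
keeps the zero-noise limit exact.  ``noise_cv`` is the coefficient of
variation of that factor.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .ncounter import CountMatrix
from .reporter import FlowEvents

__all__ = [
    "SimConfig",
    "simulate_ncounter",
    "simulate_reporter_plate",
    "simulate_flow_events",
    "simulate_qpcr",
    "spike_names",
]

DEFAULT_TIMEPOINTS = ("15h", "24h", "48h")
DEFAULT_CONDITIONS = ("crxnrl", "crxnrl_sh49", "crxnrl_sh50")


def spike_names(n: int) -> list[str]:
    """Positive-control names POS_B, POS_C, ... (POS_A/POS_F excluded by default)."""
    letters = string.ascii_uppercase[1 : 1 + n]  # start at B
    return [f"POS_{c}" for c in letters]


def _unit_lognormal(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Lognormal multiplicative noise with mean exactly 1; cv=0 gives ones."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


@dataclass(frozen=True)
class SimConfig:
    """Design of a simulated hybridization-count experiment.

    Defaults mirror the profiling design this package targets: 541 miRNA
    features observed in HEK293 cells, three transfection conditions
    (CRX/NRL alone and with one of two shRNAs) at 15, 24 and 48 h, and four
    positive spike-ins POS_B..POS_E on a 4-fold dilution ladder.

    Parameters
    ----------
    n_mirnas : number of miRNA features.
    n_spikeins : number of positive-control rows (named POS_B..).
    spike_concs : nominal spike concentrations, strictly decreasing,
        arbitrary concentration units.
    hyb_slope : counts per concentration unit per sample.
    hyb_background : additive count background per sample.
    noise_cv : coefficient of variation of the per-cell lognormal noise.
    sample_cv : CV of the per-sample hybridization-efficiency factor that
        jointly scales slope and background (makes global normalization
        non-trivial); ``None`` means "use noise_cv".
    conditions, timepoints : sample grid labels; samples sharing a timepoint
        across conditions are paired.
    planted_fc : feature id -> (condition, linear fold change) applied to
        that feature's abundance in that condition; a tuple of such pairs
        plants the feature in several conditions.
    abundances : per-miRNA true abundances (concentration units); ``None``
        draws them log-uniformly from ``abundance_range``.
    round_counts : round simulated counts to non-negative integers.
    seed : random seed; equal seeds give bit-identical output.
    """

    n_mirnas: int = 541
    n_spikeins: int = 4
    spike_concs: tuple[float, ...] = (32.0, 8.0, 2.0, 0.5)
    hyb_slope: float = 200.0
    hyb_background: float = 20.0
    noise_cv: float = 0.1
    sample_cv: float | None = None
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    planted_fc: Mapping[str, tuple[str, float]] = field(default_factory=dict)
    abundances: tuple[float, ...] | None = None
    abundance_range: tuple[float, float] = (2.0, 200.0)
    round_counts: bool = True
    seed: int = 0

    def feature_ids(self) -> list[str]:
        return [f"mir{i + 1:04d}" for i in range(self.n_mirnas)]

    def planted_items(self):
        """Yield (feature, condition, fold) triples, flattening multi-condition
        plantings."""
        for feat, spec in self.planted_fc.items():
            entries = [spec] if spec and isinstance(spec[0], str) else list(spec)
            for cond, fold in entries:
                yield feat, cond, float(fold)

    def validate(self) -> None:
        if self.n_mirnas < 1:
            raise ConfigError("n_mirnas", "must be >= 1")
        if self.n_spikeins < 3:
            raise ConfigError("n_spikeins", "need >= 3 spike-ins for a fit")
        concs = np.asarray(self.spike_concs, dtype=float)
        if len(concs) != self.n_spikeins:
            raise ConfigError("spike_concs", "length must equal n_spikeins")
        if not np.all(concs > 0):
            raise ConfigError("spike_concs", "must be strictly positive")
        if not np.all(np.diff(concs) < 0):
            raise ConfigError("spike_concs", "must be strictly decreasing")
        if self.hyb_slope <= 0:
            raise ConfigError("hyb_slope", "must be > 0")
        if self.hyb_background < 0:
            raise ConfigError("hyb_background", "must be >= 0")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv", "must be >= 0")
        if self.sample_cv is not None and self.sample_cv < 0:
            raise ConfigError("sample_cv", "must be >= 0")
        if not self.conditions or len(set(self.conditions)) != len(self.conditions):
            raise ConfigError("conditions", "must be non-empty and unique")
        if not self.timepoints or len(set(self.timepoints)) != len(self.timepoints):
            raise ConfigError("timepoints", "must be non-empty and unique")
        features = set(self.feature_ids())
        for feat, cond, fold in self.planted_items():
            if feat not in features:
                raise ConfigError("planted_fc", f"unknown feature '{feat}'")
            if cond not in self.conditions:
                raise ConfigError("planted_fc", f"unknown condition '{cond}'")
            if not fold > 0:
                raise ConfigError("planted_fc", f"fold for '{feat}' must be > 0")
        if self.abundances is not None:
            ab = np.asarray(self.abundances, dtype=float)
            if len(ab) != self.n_mirnas:
                raise ConfigError("abundances", "length must equal n_mirnas")
            if not np.all(ab > 0):
                raise ConfigError("abundances", "must be strictly positive")
        lo, hi = self.abundance_range
        if not (0 < lo < hi):
            raise ConfigError("abundance_range", "need 0 < low < high")


def simulate_ncounter(config: SimConfig) -> CountMatrix:
    """Simulate a raw hybridization count matrix with spike-in controls.

    One row per miRNA and per spike-in; one column per (condition x
    timepoint) sample.  Each sample carries its own hybridization-efficiency
    factor that scales slope and background jointly; counts follow

        count = background_s + slope_s * level * noise

    where ``level`` is the nominal spike concentration for control rows and
    the (possibly fold-changed) miRNA abundance otherwise.  The planted
    per-sample abundances are kept on the returned matrix
    (``true_abundance``) for oracle checks.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    features = config.feature_ids()
    spikes = spike_names(config.n_spikeins)
    samples = [f"{c}_{t}" for c in config.conditions for t in config.timepoints]
    meta = pd.DataFrame(
        {
            "sample_id": samples,
            "condition": [c for c in config.conditions for _ in config.timepoints],
            "timepoint": [t for _ in config.conditions for t in config.timepoints],
        }
    ).set_index("sample_id")
    # samples sharing a timepoint across conditions are paired
    meta["pair_id"] = meta["timepoint"]

    if config.abundances is not None:
        base = np.asarray(config.abundances, dtype=float)
    else:
        lo, hi = config.abundance_range
        base = 10 ** rng.uniform(np.log10(lo), np.log10(hi), config.n_mirnas)

    # per-sample abundance with planted fold changes
    abundance = pd.DataFrame(
        np.tile(base[:, None], (1, len(samples))), index=features, columns=samples
    )
    for feat, cond, fold in config.planted_items():
        cols = meta.index[meta["condition"] == cond]
        abundance.loc[feat, cols] *= fold

    sample_cv = config.noise_cv if config.sample_cv is None else config.sample_cv
    efficiency = _unit_lognormal(rng, sample_cv, len(samples))
    slope_s = config.hyb_slope * efficiency
    bg_s = config.hyb_background * efficiency

    levels = np.vstack([np.asarray(config.spike_concs)[:, None] * np.ones(len(samples)),
                        abundance.to_numpy()])
    noise = _unit_lognormal(rng, config.noise_cv, levels.shape)
    counts = bg_s[None, :] + slope_s[None, :] * levels * noise
    if config.round_counts:
        counts = np.rint(counts)
    counts = np.clip(counts, 0, None)

    counts_df = pd.DataFrame(counts, index=spikes + features, columns=samples)
    if config.round_counts:
        counts_df = counts_df.astype(np.int64)
    return CountMatrix(counts=counts_df, meta=meta, true_abundance=abundance)


def simulate_reporter_plate(
    effects: Mapping[str, float],
    control_rlu: float = 1.0,
    noise_cv: float = 0.1,
    n_wells: int = 3,
    seed: int = 0,
    days: Sequence[int] = (1, 2),
    control_label: str = "control",
) -> pd.DataFrame:
    """Simulate a luciferase reporter plate.

    Per-well RLU = control_rlu * fold(condition) * lognormal noise.  A
    ``control`` condition with fold 1 is always present.  Returns a tidy
    table (well_id, condition, day, replicate, rlu).
    """
    if control_rlu <= 0:
        raise ConfigError("control_rlu", "must be > 0")
    if n_wells < 1:
        raise ConfigError("n_wells", "must be >= 1")
    if noise_cv < 0:
        raise ConfigError("noise_cv", "must be >= 0")
    folds = dict(effects)
    folds.setdefault(control_label, 1.0)
    for cond, fold in folds.items():
        if not fold > 0:
            raise ConfigError("effects", f"fold for '{cond}' must be > 0")

    rng = np.random.default_rng(seed)
    rows = []
    well = 0
    for day in days:
        for cond, fold in folds.items():
            eps = _unit_lognormal(rng, noise_cv, n_wells)
            for rep in range(n_wells):
                rows.append(
                    {
                        "well_id": f"W{well:03d}",
                        "condition": cond,
                        "day": day,
                        "replicate": rep + 1,
                        "rlu": control_rlu * fold * eps[rep],
                    }
                )
                well += 1
    return pd.DataFrame(rows)


def simulate_flow_events(
    n_events: int,
    frac_positive: float,
    pos_median: float,
    neg_median: float,
    seed: int = 0,
    neg_sigma: float = 0.4,
    pos_sigma: float = 0.4,
    label: str = "sample",
) -> FlowEvents:
    """Simulate per-event fluorescence as a two-component lognormal mixture.

    Each event is positive with probability ``frac_positive``; component
    medians are ``pos_median``/``neg_median`` (lognormal location = log
    median).  Event count is exactly ``n_events``.
    """
    if n_events < 1:
        raise ConfigError("n_events", "must be >= 1")
    if not 0 <= frac_positive <= 1:
        raise ConfigError("frac_positive", "must be in [0, 1]")
    if not (pos_median > neg_median > 0):
        raise ConfigError("pos_median", "need pos_median > neg_median > 0")

    rng = np.random.default_rng(seed)
    is_pos = rng.random(n_events) < frac_positive
    log_med = np.where(is_pos, np.log(pos_median), np.log(neg_median))
    sigma = np.where(is_pos, pos_sigma, neg_sigma)
    intensities = np.exp(rng.normal(log_med, sigma))
    return FlowEvents(intensities=intensities, label=label)


def simulate_qpcr(
    true_rel_expr: Mapping[str, float],
    ref_ct: float = 20.0,
    efficiency: float = 2.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 3,
    reference_gene: str = "GAPDH",
    sample: str = "treated",
    calibrator: str = "calibrator",
) -> pd.DataFrame:
    """Simulate a qPCR Ct table for one test sample against a calibrator.

    In the calibrator every target amplifies like the reference
    (Ct = ref_ct); in the test sample a gene with relative expression ``r``
    comes up ``log_efficiency(r)`` cycles earlier:

        Ct_target = ref_ct - log(r) / log(efficiency) + noise

    Returns a tidy table (sample, gene, replicate, ct) containing the
    reference gene in both samples.
    """
    if efficiency <= 1:
        raise ConfigError("efficiency", "must be > 1")
    if noise_sd < 0:
        raise ConfigError("noise_sd", "must be >= 0")
    for gene, r in true_rel_expr.items():
        if not r > 0:
            raise ConfigError("true_rel_expr", f"expression for '{gene}' must be > 0")

    rng = np.random.default_rng(seed)
    rows = []
    for samp in (calibrator, sample):
        for gene in [reference_gene, *true_rel_expr]:
            if samp == sample and gene in true_rel_expr:
                ct = ref_ct - np.log(true_rel_expr[gene]) / np.log(efficiency)
            else:
                ct = ref_ct
            for rep in range(n_replicates):
                noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                rows.append(
                    {"sample": samp, "gene": gene, "replicate": rep + 1, "ct": ct + noise}
                )
    return pd.DataFrame(rows)
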