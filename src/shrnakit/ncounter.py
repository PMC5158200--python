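"""Hybridization-count calibration via positive spike-in controls.

Digital hybridization counters include synthetic positive-control RNAs
(POS_B..POS_E here) at known, strictly decreasing nominal concentrations.
An ordinary least-squares line of raw counts on concentration gives each
sample a hybridization efficiency (slope, counts per concentration unit)
and a background signal B.  Each miRNA's raw count R_i is then converted
to a normalized expression

    E_i = (R_i - B) / slope

in concentration units, clipped at zero, with log2(E_i + pseudocount)
carried alongside for downstream statistics.  In the default linear-space
calibration B is the line's fitted background (its value at zero
concentration) and E_i is the calibrated concentration estimate; the
fitted signal at the POS_B concentration is reported for QC.  In the
log-space variant the regression runs on log2 counts vs log2
concentrations, B is the fitted log2 signal at POS_B, and E_i is log2
expression relative to POS_B.  A final global normalization
rescales every sample so its mean over all miRNAs equals the grand mean
across samples.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateFitError, ParseError, ShrnakitError

__all__ = [
    "CountMatrix",
    "SpikeInFit",
    "NormalizedMatrix",
    "read_counts",
    "write_counts",
    "write_rcc",
    "fit_spikein_response",
    "fit_all_samples",
    "fit_report",
    "normalize_spikein",
    "global_normalize",
]

SPIKE_PATTERN = r"^POS_"


@dataclass
class CountMatrix:
    """Raw counts (features x samples) with per-sample metadata.

    ``counts`` is indexed by feature id (spike-ins prefixed ``POS_``) with
    one column per sample; ``meta`` is indexed by sample id with columns
    ``condition``, ``timepoint`` and ``pair_id``.  ``true_abundance`` holds
    the generative truth when the matrix came from the simulator.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    true_abundance: pd.DataFrame | None = None
    spike_pattern: str = SPIKE_PATTERN

    def __post_init__(self):
        c = self.counts
        if c.index.has_duplicates:
            dupes = c.index[c.index.duplicated()].tolist()
            raise ParseError(f"duplicate feature ids: {dupes}")
        if c.columns.has_duplicates:
            dupes = c.columns[c.columns.duplicated()].tolist()
            raise ParseError(f"duplicate sample ids: {dupes}")
        arr = c.to_numpy()
        if np.isnan(arr.astype(float)).any():
            raise ParseError("count matrix contains missing cells")
        if (arr < 0).any():
            f, s = np.argwhere(arr < 0)[0]
            raise ParseError(
                f"negative count at feature '{c.index[f]}', sample '{c.columns[s]}'"
            )
        missing = [s for s in c.columns if s not in self.meta.index]
        if missing:
            raise ParseError(f"samples missing from metadata: {missing}")
        for col in ("condition", "timepoint"):
            if col not in self.meta.columns:
                raise ParseError(f"metadata lacks required column '{col}'")
            if self.meta.loc[list(c.columns), col].isna().any():
                raise ParseError(f"metadata column '{col}' has missing labels")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def spike_mask(self) -> pd.Series:
        return self.counts.index.str.contains(self.spike_pattern, regex=True)

    @property
    def spike_ids(self) -> list[str]:
        """Spike-in feature ids, sorted (POS_B, POS_C, ... matches a
        decreasing concentration ladder)."""
        return sorted(self.counts.index[self.spike_mask])

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.counts.index[~self.spike_mask])


@dataclass(frozen=True)
class SpikeInFit:
    """Linear response of one sample's positive controls.

    slope: counts per concentration unit (log2 counts per log2 concentration
        unit for a log-space fit); must be > 0.
    B: the signal subtracted by the normalization formula.  In linear space
        this is the calibration line's fitted background (its value at zero
        concentration), so that (R - B)/slope is the calibrated concentration
        estimate; in log space it is the fitted log2 signal at the POS_B
        concentration, so the normalized value is log2 expression relative
        to POS_B.
    pos_b_signal: fitted linear-response signal at the POS_B concentration
        (reported for QC in either space).
    r2: coefficient of determination of the fit.
    """

    sample_id: str
    slope: float
    B: float
    pos_b_signal: float
    r2: float
    log_space: bool = False

    def __post_init__(self):
        if self.slope <= 0:
            raise DegenerateFitError(
                f"sample '{self.sample_id}': non-positive slope {self.slope}"
            )
        if not self.log_space and self.B < 0:
            raise DegenerateFitError(f"sample '{self.sample_id}': negative B {self.B}")


@dataclass
class NormalizedMatrix:
    """Spike-in-normalized expression (concentration units, linear scale)."""

    values: pd.DataFrame
    log2_values: pd.DataFrame = field(repr=False, default=None)
    meta: pd.DataFrame | None = None
    pseudocount: float = 1.0

    def __post_init__(self):
        if self.log2_values is None:
            self.log2_values = np.log2(self.values + self.pseudocount)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# I/O

def read_counts(path, meta_path=None, fmt: str = "csv",
                meta: pd.DataFrame | None = None) -> CountMatrix:
    """Read a count matrix from CSV/TSV or a directory of minimal RCC files.

    CSV layout: first column = feature id, header row = sample ids.  The RCC
    dialect reads only the ``<CodeSummary>`` count section of each ``*.RCC``
    file in the directory (one file per sample; sample id = file stem).
    Metadata comes from ``meta_path`` (CSV with sample_id, condition,
    timepoint, pair_id) or a pre-built frame.
    """
    path = Path(path)
    if fmt == "csv":
        sep = "\t" if path.suffix in (".tsv", ".txt") else ","
        try:
            counts = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise ParseError(f"could not parse '{path}': {exc}") from exc
    elif fmt == "rcc":
        counts = _read_rcc_dir(path)
    else:
        raise ParseError(f"unknown format '{fmt}' (expected 'csv' or 'rcc')")

    if meta is None:
        if meta_path is None:
            raise ParseError("sample metadata required (meta_path or meta)")
        meta = pd.read_csv(meta_path).set_index("sample_id")
    return CountMatrix(counts=counts, meta=meta)


def _read_rcc_dir(directory: Path) -> pd.DataFrame:
    files = sorted(Path(directory).glob("*.RCC"))
    if not files:
        raise ParseError(f"no .RCC files in '{directory}'")
    cols = {}
    for f in files:
        cols[f.stem] = _read_rcc_codesummary(f)
    return pd.DataFrame(cols)


def _read_rcc_codesummary(path: Path) -> pd.Series:
    """Parse the Name,Count pairs of one RCC file's CodeSummary section."""
    text = Path(path).read_text()
    m = re.search(r"<CodeSummary>\n(.*?)</CodeSummary>", text, re.S)
    if not m:
        raise ParseError(f"'{path}': no <CodeSummary> section")
    names, counts = [], []
    lines = [ln for ln in m.group(1).strip().splitlines() if ln.strip()]
    for i, line in enumerate(lines):
        parts = line.split(",")
        if i == 0 and parts[0].strip().lower() == "name":
            continue  # header line
        if len(parts) != 2:
            raise ParseError(f"'{path}' line {i + 1}: expected 'Name,Count'")
        name, count = parts[0].strip(), parts[1].strip()
        try:
            value = int(count)
        except ValueError as exc:
            raise ParseError(f"'{path}' line {i + 1}: bad count '{count}'") from exc
        if value < 0:
            raise ParseError(f"'{path}' line {i + 1}: negative count for '{name}'")
        names.append(name)
        counts.append(value)
    return pd.Series(counts, index=names, dtype=np.int64)


def write_counts(m: CountMatrix, counts_path, meta_path) -> None:
    """Write counts CSV (feature id first column) and sample-metadata CSV."""
    m.counts.to_csv(counts_path, index_label="feature_id")
    m.meta.to_csv(meta_path, index_label="sample_id")


def write_rcc(m: CountMatrix, directory) -> None:
    """Write one minimal RCC file per sample (CodeSummary section only)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for sample in m.sample_ids:
        lines = ["<CodeSummary>", "Name,Count"]
        for feat, count in m.counts[sample].items():
            lines.append(f"{feat},{int(count)}")
        lines.append("</CodeSummary>")
        (directory / f"{sample}.RCC").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Spike-in calibration

def fit_spikein_response(
    counts: Sequence[float],
    concs: Sequence[float],
    sample_id: str = "",
    log_space: bool = False,
) -> SpikeInFit:
    """OLS fit of one sample's spike-in counts on nominal concentration.

    ``concs`` must be strictly decreasing (POS_B first).  In the default
    linear space the subtracted signal B is the line's fitted background
    (value at zero concentration); the fitted signal at the POS_B
    concentration is reported alongside.  With ``log_space=True`` both
    counts and concentrations are log2-transformed before the regression
    and B is the fitted log2 signal at POS_B, making the normalized value
    log2 expression relative to POS_B.
    """
    y = np.asarray(counts, dtype=float)
    x = np.asarray(concs, dtype=float)
    if len(x) != len(y):
        raise DegenerateFitError("counts and concs differ in length")
    if len(x) < 3 or len(np.unique(x)) < 3:
        raise DegenerateFitError("need >= 3 spike-ins with distinct concentrations")
    if not np.all(x > 0) or not np.all(np.diff(x) < 0):
        raise DegenerateFitError("concentrations must be positive, strictly decreasing")
    if log_space:
        if np.any(y <= 0):
            raise DegenerateFitError("log-space fit requires positive counts")
        x, y = np.log2(x), np.log2(y)

    res = stats.linregress(x, y)
    slope, intercept = res.slope, res.intercept
    if not np.isfinite(slope) or slope <= 0:
        raise DegenerateFitError(
            f"sample '{sample_id}': degenerate spike-in response (slope={slope:.4g})"
        )
    pos_b = intercept + slope * x[0]  # fitted signal at the POS_B concentration
    b = pos_b if log_space else max(intercept, 0.0)
    return SpikeInFit(
        sample_id=sample_id,
        slope=float(slope),
        B=float(b),
        pos_b_signal=float(pos_b),
        r2=float(res.rvalue**2),
        log_space=log_space,
    )


def fit_all_samples(
    m: CountMatrix,
    spike_concs: Sequence[float],
    log_space: bool = False,
) -> dict[str, SpikeInFit]:
    """Fit the spike-in response of every sample.

    ``spike_concs`` is given in the order of the sorted spike-in ids
    (POS_B, POS_C, ...), i.e. strictly decreasing down the ladder.
    """
    spikes = m.spike_ids
    if len(spikes) != len(spike_concs):
        raise DegenerateFitError(
            f"{len(spikes)} spike-in rows but {len(spike_concs)} concentrations"
        )
    return {
        s: fit_spikein_response(
            m.counts.loc[spikes, s], spike_concs, sample_id=s, log_space=log_space
        )
        for s in m.sample_ids
    }


def fit_report(fits: Mapping[str, SpikeInFit]) -> pd.DataFrame:
    """Tabular calibration report (sample_id, slope, B, r2)."""
    return pd.DataFrame(
        [
            {
                "sample_id": f.sample_id,
                "slope": f.slope,
                "B": f.B,
                "pos_b_signal": f.pos_b_signal,
                "r2": f.r2,
            }
            for f in fits.values()
        ]
    ).set_index("sample_id")


# ---------------------------------------------------------------------------
# Normalization

def normalize_spikein(
    m: CountMatrix,
    fits: Mapping[str, SpikeInFit],
    pseudocount: float = 1.0,
) -> NormalizedMatrix:
    """Apply E_i = (R_i - B) / slope per sample; spike-in rows are dropped.

    Negative normalized values are clipped to 0; ``log2_values`` holds
    log2(E_i + pseudocount).
    """
    missing = [s for s in m.sample_ids if s not in fits]
    if missing:
        raise ShrnakitError(f"no spike-in fit for samples: {missing}")
    raw = m.counts.loc[m.mirna_ids].astype(float)
    values = {}
    for s in m.sample_ids:
        fit = fits[s]
        r = np.log2(raw[s] + pseudocount) if fit.log_space else raw[s]
        values[s] = (r - fit.B) / fit.slope
    df = pd.DataFrame(values).clip(lower=0.0)
    meta = m.meta.loc[m.sample_ids]
    return NormalizedMatrix(values=df, meta=meta, pseudocount=pseudocount)


def global_normalize(nm: NormalizedMatrix) -> NormalizedMatrix:
    """Rescale each sample so its mean over all miRNAs equals the grand mean.

    The grand mean of the input is preserved; a sample whose values are all
    zero cannot be rescaled and raises.
    """
    if nm.values.shape[0] < 1 or nm.values.shape[1] < 2:
        raise ShrnakitError("global normalization needs >= 1 feature and >= 2 samples")
    sample_means = nm.values.mean(axis=0)
    zero = sample_means[sample_means == 0]
    if len(zero):
        raise ShrnakitError(
            f"cannot rescale all-zero samples: {list(zero.index)}"
        )
    grand = float(sample_means.mean())
    scaled = nm.values * (grand / sample_means)
    return NormalizedMatrix(values=scaled, meta=nm.meta, pseudocount=nm.pseudocount)
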