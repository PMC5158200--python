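"""Integration of differential-expression results across assays.

Combines DE sets from the miRNA and gene arms of the pipeline: exact set
overlaps with direction concordance, intersection of DE genes with the
predicted targets of DE miRNAs (annotating consistency with miRNA-mediated
repression), gene-family over-representation by the upper-tail
hypergeometric test, and plain coefficients of determination (R^2) for
correlating assay readouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, ShrnakitError

__all__ = [
    "FeatureSet",
    "TargetMap",
    "FamilyAnnotation",
    "OverlapResult",
    "EnrichmentResult",
    "set_overlap",
    "target_intersect",
    "family_enrichment",
    "r_squared",
    "summarize_deg_table",
    "read_target_map",
    "read_family_annotation",
]


@dataclass(frozen=True)
class FeatureSet:
    """A labelled set of feature ids with optional up/down directions."""

    label: str
    members: frozenset[str]
    directions: Mapping[str, str] | None = None

    @classmethod
    def from_de_table(cls, results: pd.DataFrame, label: str) -> "FeatureSet":
        """DE features of a called result table; direction from the fc sign."""
        de = results[results["is_de"]]
        directions = {
            feat: ("up" if fc > 0 else "down") for feat, fc in de["fc"].items()
        }
        return cls(label=label, members=frozenset(de.index), directions=directions)

    def direction(self, feature: str) -> str | None:
        if self.directions is None:
            return None
        return self.directions.get(feature)


@dataclass(frozen=True)
class TargetMap:
    """miRNA id -> set of predicted target gene ids."""

    targets: Mapping[str, frozenset[str]]
    source: str = ""

    def __post_init__(self):
        if any(not m for m in self.targets):
            raise ConfigError("targets", "empty miRNA keys are not allowed")

    def __getitem__(self, mirna: str) -> frozenset[str]:
        return self.targets.get(mirna, frozenset())


@dataclass(frozen=True)
class FamilyAnnotation:
    """gene id -> family label over a background universe of annotated genes."""

    families: Mapping[str, str]
    background_size: int | None = None

    @property
    def background(self) -> int:
        return len(self.families) if self.background_size is None else self.background_size

    def family_size(self, label: str) -> int:
        n = sum(1 for fam in self.families.values() if fam == label)
        if n == 0:
            raise ShrnakitError(f"family '{label}' absent from annotation")
        return n


@dataclass(frozen=True)
class OverlapResult:
    members: frozenset[str]
    size: int
    concordant: int | None = None
    discordant: int | None = None


def set_overlap(a: FeatureSet, b: FeatureSet) -> OverlapResult:
    """Exact intersection of two feature sets.

    When both sets carry directions, counts members whose direction agrees
    (concordant) or disagrees (discordant) between the two sets.
    """
    inter = frozenset(a.members & b.members)
    concordant = discordant = None
    if a.directions is not None and b.directions is not None:
        concordant = sum(1 for f in inter if a.direction(f) == b.direction(f))
        discordant = len(inter) - concordant
    return OverlapResult(inter, len(inter), concordant, discordant)


def target_intersect(
    de_mirnas: FeatureSet,
    tmap: TargetMap,
    de_genes: FeatureSet,
) -> pd.DataFrame:
    """All (miRNA, gene) pairs with the miRNA DE, the gene DE, and the gene a
    predicted target of the miRNA.

    Each pair is annotated with both directions and whether they are
    consistent with miRNA-mediated repression (miRNA down and target up,
    or miRNA up and target down).
    """
    rows = []
    for mirna in sorted(de_mirnas.members):
        for gene in sorted(tmap[mirna] & de_genes.members):
            d_m = de_mirnas.direction(mirna)
            d_g = de_genes.direction(gene)
            consistent = (
                None
                if d_m is None or d_g is None
                else (d_m == "down") != (d_g == "down")
            )
            rows.append(
                {
                    "mirna": mirna,
                    "gene": gene,
                    "mirna_direction": d_m,
                    "gene_direction": d_g,
                    "repression_consistent": consistent,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "mirna", "gene", "mirna_direction", "gene_direction",
            "repression_consistent",
        ],
    )


@dataclass(frozen=True)
class EnrichmentResult:
    family: str
    k: int
    n: int
    percent: float
    p: float
    background: int
    family_size: int
    members: frozenset[str] = field(default=frozenset())


def round_percent(k: int, n: int) -> float:
    """100*k/n rounded half-up to two decimals (7/320 -> 2.19)."""
    pct = Decimal(100) * Decimal(k) / Decimal(n)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def family_enrichment(
    de_genes: FeatureSet,
    fam: FamilyAnnotation,
    family_label: str,
) -> EnrichmentResult:
    """Over-representation of a gene family in a DE gene list.

    k = family members among the n DE genes; percent = 100k/n to two
    decimals (half-up); p = upper-tail hypergeometric P(X >= k) drawing n
    genes from a background of ``fam.background`` genes of which
    ``family_size`` belong to the family.
    """
    n = len(de_genes.members)
    if n == 0:
        raise ShrnakitError("DE gene list is empty")
    family_size = fam.family_size(family_label)
    if fam.background < n:
        raise ConfigError("background_size", "background smaller than the DE list")
    members = frozenset(
        g for g in de_genes.members if fam.families.get(g) == family_label
    )
    k = len(members)
    p = float(stats.hypergeom.sf(k - 1, fam.background, family_size, n))
    return EnrichmentResult(
        family=family_label, k=k, n=n, percent=round_percent(k, n), p=p,
        background=fam.background, family_size=family_size, members=members,
    )


def r_squared(x, y) -> float:
    """Coefficient of determination: squared Pearson correlation of x and y.

    Returns nan (undefined) when either input is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigError("x", "x and y must be equal-length 1-d vectors")
    if len(x) < 3:
        raise ConfigError("x", "need >= 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    r, _ = stats.pearsonr(x, y)
    return float(r**2)


# ---------------------------------------------------------------------------
# Tabular inputs

def summarize_deg_table(df: pd.DataFrame, fc_col: str = "fc") -> dict:
    """Row and direction counts of a DEG table under the signed-FC convention
    (fc > 0 up, fc < 0 down)."""
    fc = df[fc_col].to_numpy(dtype=float)
    return {
        "n_rows": int(len(df)),
        "n_up": int((fc > 0).sum()),
        "n_down": int((fc < 0).sum()),
    }


def read_target_map(path, source: str = "") -> TargetMap:
    """Two-column TSV (mirna, gene) -> TargetMap."""
    df = pd.read_csv(path, sep="\t")
    if not {"mirna", "gene"} <= set(df.columns):
        raise ShrnakitError(f"'{path}': expected columns mirna, gene")
    grouped = {
        m: frozenset(sub["gene"]) for m, sub in df.groupby("mirna", sort=True)
    }
    return TargetMap(targets=grouped, source=source or str(path))


def read_family_annotation(path, background_size: int | None = None) -> FamilyAnnotation:
    """Two-column TSV (gene, family) -> FamilyAnnotation."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "family"} <= set(df.columns):
        raise ShrnakitError(f"'{path}': expected columns gene, family")
    return FamilyAnnotation(
        families=dict(zip(df["gene"], df["family"])), background_size=background_size
    )
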