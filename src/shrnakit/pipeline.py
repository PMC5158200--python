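"""End-to-end synthetic pipeline: simulate -> normalize -> DE -> integrate.

The default run emulates the study design this package quantifies: a
profiling experiment of 541 miRNAs under three transfection conditions
(CRX/NRL control plus two shRNA co-transfections) at three time points,
normalized against spike-in controls and tested pairwise (p < 0.05,
|FC| > 1.1); a summarized gene-expression experiment under two conditions
at two time points tested at (p < 0.1, |FC| > 1.25); and an integration
stage intersecting the DE sets, a miRNA target map, and a gene-family
annotation.  The planted effects mirror the structure of the reported
results: 50 affected miRNAs of which 2 are shared (down in both shRNA
conditions), and a DE gene list containing a down-regulated 7-gene histone
family, 3 of which are targets of the first shared miRNA.

Every output file carries the seed and a hash of the configuration, and a
rerun with the same configuration reproduces identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import diffexp, integration, ncounter, synthetic
from .errors import ConfigError, ShrnakitError

__all__ = [
    "RunConfig",
    "PipelineError",
    "run_pipeline",
    "default_mirna_planting",
    "default_gene_planting",
]


class PipelineError(ShrnakitError):
    """A stage of the end-to-end pipeline failed; names the stage."""

log = logging.getLogger("shrnakit")

HISTONE_GENES = (
    "HIST1H4C", "HIST1H4E", "HIST1H4I", "HIST1H2AE", "HIST1H2BJ",
    "HIST1H2BK", "HIST2H2AB",
)
MIR760_LIKE = "mir0001"  # shared, down in both shRNA conditions; targets histones
MIR452_LIKE = "mir0007"  # down in sh49 only; mixed-direction targets
MIR452_TARGETS = ("ST8SIA2", "ZNF532", "CCNT2", "MXD1", "PKN2", "RANBP9", "SKP1")


def default_mirna_planting(fold: float = 2.0) -> dict:
    """Planted miRNA effects: 4 up / 13 down for sh49, 14 up / 21 down for
    sh50, with mir0001 and mir0002 down in both (50 distinct features)."""
    down, up = 1.0 / fold, fold
    planted: dict = {
        "mir0001": (("crxnrl_sh49", down), ("crxnrl_sh50", down)),
        "mir0002": (("crxnrl_sh49", down), ("crxnrl_sh50", down)),
    }
    for i in range(3, 7):  # 4 up in sh49
        planted[f"mir{i:04d}"] = ("crxnrl_sh49", up)
    for i in range(7, 18):  # 11 more down in sh49 (13 total with shared)
        planted[f"mir{i:04d}"] = ("crxnrl_sh49", down)
    for i in range(18, 32):  # 14 up in sh50
        planted[f"mir{i:04d}"] = ("crxnrl_sh50", up)
    for i in range(32, 51):  # 19 more down in sh50 (21 total with shared)
        planted[f"mir{i:04d}"] = ("crxnrl_sh50", down)
    return planted


def default_gene_planting(n_genes: int, fold: float = 2.0) -> tuple[list[str], dict]:
    """Gene universe and planted effects for the expression arm.

    The first ids are named genes (7 histones, down; the mir0007-like
    targets with their reported directions); generic planted genes pad the
    DE list.  Returns (gene_ids, planted_fc).
    """
    named = list(HISTONE_GENES) + list(MIR452_TARGETS)
    generic = [f"gene{i + 1:04d}" for i in range(n_genes - len(named))]
    gene_ids = named + generic
    down, up = 1.0 / fold, fold
    planted: dict = {g: ("crxnrl_sh49", down) for g in HISTONE_GENES}
    planted["ST8SIA2"] = ("crxnrl_sh49", up)
    planted["ZNF532"] = ("crxnrl_sh49", up)
    for g in ("CCNT2", "MXD1", "PKN2", "RANBP9", "SKP1"):
        planted[g] = ("crxnrl_sh49", down)
    for g in generic[:20]:
        planted[g] = ("crxnrl_sh49", down)
    for g in generic[20:30]:
        planted[g] = ("crxnrl_sh49", up)
    return gene_ids, planted


@dataclass(frozen=True)
class RunConfig:
    """Parameters of a full pipeline run."""

    seed: int = 42
    out_dir: str | None = None
    n_mirnas: int = 541
    n_genes: int = 1000
    noise_cv: float = 0.05
    planted_fold: float = 2.0
    spike_concs: tuple[float, ...] = (32.0, 8.0, 2.0, 0.5)
    hyb_slope: float = 200.0
    hyb_background: float = 20.0
    mirna_p: float = 0.05
    mirna_fc: float = 1.1
    gene_p: float = 0.1
    gene_fc: float = 1.25
    log_level: str = "INFO"

    def validate(self) -> None:
        for name in ("mirna_p", "gene_p"):
            if not 0 < getattr(self, name) <= 1:
                raise ConfigError(name, "must be in (0, 1]")
        for name in ("mirna_fc", "gene_fc"):
            if getattr(self, name) < 1:
                raise ConfigError(name, "fold-change threshold must be >= 1")
        if self.planted_fold <= 1:
            raise ConfigError("planted_fold", "must be > 1")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv", "must be >= 0")
        if self.seed < 0 or self.seed >= 2**30:
            raise ConfigError("seed", "must be in [0, 2^30)")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "spike_concs" in raw:
            raw["spike_concs"] = tuple(raw["spike_concs"])
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output path and logging
        verbosity excluded: they do not affect the computation)."""
        payload = asdict(self)
        payload.pop("out_dir")
        payload.pop("log_level")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _provenance_line(config: RunConfig) -> str:
    return f"# shrnakit config_hash={config.config_hash()} seed={config.seed}"


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig, **to_csv_kw) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_line(config) + "\n")
        df.to_csv(fh, **to_csv_kw)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthetic pipeline and return the machine report.

    Stages: simulate miRNA counts -> spike-in + global normalization ->
    paired DE per shRNA condition -> simulate gene expression -> gene DE ->
    integration (DE-set overlap, miRNA-target intersection, family
    enrichment).  With ``config.out_dir`` set, writes provenance-stamped
    CSV/JSON outputs.  Any stage error propagates annotated with the stage
    name.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    report: dict = {
        # out_dir / log_level are run environment, not configuration of the
        # computation; keeping them out makes reports from identical
        # configurations byte-identical
        "config": {
            k: v for k, v in asdict(config).items()
            if k not in ("out_dir", "log_level")
        },
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }

    stage = "simulate-mirna"
    try:
        sim = synthetic.SimConfig(
            n_mirnas=config.n_mirnas,
            spike_concs=config.spike_concs,
            hyb_slope=config.hyb_slope,
            hyb_background=config.hyb_background,
            noise_cv=config.noise_cv,
            planted_fc=default_mirna_planting(config.planted_fold),
            seed=config.seed,
        )
        counts = synthetic.simulate_ncounter(sim)
        log.info("simulated %d features x %d samples", *counts.counts.shape)

        stage = "normalize"
        fits = ncounter.fit_all_samples(counts, config.spike_concs)
        nm = ncounter.global_normalize(
            ncounter.normalize_spikein(counts, fits)
        )

        stage = "diffexp-mirna"
        de_mirna = {}
        for cond in ("crxnrl_sh49", "crxnrl_sh50"):
            design = diffexp.PairedDesign.from_metadata(nm.meta, "crxnrl", cond)
            de_mirna[cond] = diffexp.run_diffexp(
                nm, design, p_thresh=config.mirna_p, fc_thresh=config.mirna_fc
            )

        stage = "simulate-genes"
        gene_ids, gene_planted = default_gene_planting(
            config.n_genes, config.planted_fold
        )
        gene_sim = synthetic.SimConfig(
            n_mirnas=config.n_genes,
            spike_concs=config.spike_concs,
            hyb_slope=config.hyb_slope,
            hyb_background=config.hyb_background,
            noise_cv=config.noise_cv,
            conditions=("crxnrl", "crxnrl_sh49"),
            timepoints=("15h", "48h"),
            planted_fc=_positional_planting(gene_ids, gene_planted),
            seed=config.seed + 1000,
        )
        gene_counts = _rename_features(
            synthetic.simulate_ncounter(gene_sim),
            dict(zip(gene_sim.feature_ids(), gene_ids)),
        )

        stage = "diffexp-genes"
        gfits = ncounter.fit_all_samples(gene_counts, config.spike_concs)
        gnm = ncounter.global_normalize(
            ncounter.normalize_spikein(gene_counts, gfits)
        )
        gdesign = diffexp.PairedDesign.from_metadata(gnm.meta, "crxnrl", "crxnrl_sh49")
        de_genes = diffexp.run_diffexp(
            gnm, gdesign, p_thresh=config.gene_p, fc_thresh=config.gene_fc
        )

        stage = "integrate"
        set49 = integration.FeatureSet.from_de_table(de_mirna["crxnrl_sh49"], "sh49")
        set50 = integration.FeatureSet.from_de_table(de_mirna["crxnrl_sh50"], "sh50")
        overlap = integration.set_overlap(set49, set50)
        gene_set = integration.FeatureSet.from_de_table(de_genes, "sh49_genes")
        tmap = integration.TargetMap(
            targets={
                MIR760_LIKE: frozenset(("HIST1H2AE", "HIST1H2BJ", "HIST2H2AB", "gene0500")),
                MIR452_LIKE: frozenset(MIR452_TARGETS),
            },
            source="synthetic",
        )
        pairs = integration.target_intersect(set49, tmap, gene_set)
        fam = integration.FamilyAnnotation(
            families={g: ("histone" if g in HISTONE_GENES else "other") for g in gene_ids}
        )
        enrich = integration.family_enrichment(gene_set, fam, "histone")
    except Exception as exc:
        raise PipelineError(f"[stage {stage}] {exc}") from exc

    report["mirna"] = {
        cond: diffexp.de_summary(df) for cond, df in de_mirna.items()
    }
    report["genes"] = diffexp.de_summary(de_genes)
    report["integration"] = {
        "overlap_size": overlap.size,
        "overlap_members": sorted(overlap.members),
        "overlap_concordant": overlap.concordant,
        "overlap_discordant": overlap.discordant,
        "target_pairs": int(len(pairs)),
        "family": enrich.family,
        "family_k": enrich.k,
        "family_n": enrich.n,
        "family_percent": enrich.percent,
        "family_p": enrich.p,
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_csv(ncounter.fit_report(fits), out / "spikein_fits.csv", config)
        _write_csv(nm.values, out / "mirna_normalized.csv", config,
                   index_label="feature_id")
        for cond, df in de_mirna.items():
            _write_csv(df, out / f"de_mirna_{cond}.csv", config)
        _write_csv(de_genes, out / "de_genes_crxnrl_sh49.csv", config)
        _write_csv(pairs, out / "mirna_target_pairs.csv", config, index=False)
        report_text = json.dumps(report, indent=2, sort_keys=True, default=str)
        (out / "report.json").write_text(report_text + "\n")
        log.info("wrote pipeline outputs to %s", out)
    return report


def _positional_planting(ids: list[str], planted: dict) -> dict:
    """Translate a planted map keyed by domain gene names onto the
    simulator's positional feature ids (ids[i] <-> mir{i+1:04d})."""
    positional = {name: f"mir{i + 1:04d}" for i, name in enumerate(ids)}
    return {positional[g]: spec for g, spec in planted.items()}


def _rename_features(m: ncounter.CountMatrix, mapping: dict) -> ncounter.CountMatrix:
    """Relabel the simulator's positional feature ids with domain names
    (spike-in rows are untouched)."""
    return ncounter.CountMatrix(
        counts=m.counts.rename(index=mapping),
        meta=m.meta,
        true_abundance=(
            None if m.true_abundance is None else m.true_abundance.rename(index=mapping)
        ),
        spike_pattern=m.spike_pattern,
    )
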