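"""End-to-end orchestration: config, staged execution, manifest writing.

The pipeline runs detection -> paired differential expression on both arms
-> pair matching -> concordance / discordance / DEGP mining, with optional
atlas-enrichment and panel-screening stages when those inputs are supplied.
All tabular outputs are TSV, summaries are JSON, and a manifest records the
configuration hash and seed so identical configs reproduce identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .integration import (
    concordance_table,
    degp_intersect,
    discordant_pairs,
    fold_change_correlation,
    match_pairs,
)
from .proteome_de import (
    SpectralCountMatrix,
    compute_nsaf,
    filter_detected_proteins,
    normalize_spc,
    paired_lm_de,
)
from .rnaseq_de import (
    CountMatrix,
    FpkmMatrix,
    SampleDesign,
    compute_cpm,
    detect_expressed_genes,
    nb_paired_de,
    tmm_factors,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Flat key-value pipeline configuration.

    Threshold defaults are the study-standard values: CPM > 0.25 in at
    least 25% of samples for mRNA detection, SpC >= 2 in at least 4 samples
    for protein detection, fold-change gates 1.5 / 0.67 at FDR < 0.05,
    discordance screening at raw p < 0.10, 10-DEGP GSEA windows, and
    10,000 sampling-null trials.
    """

    counts: str = ""
    fpkm: str = ""
    fpkm_ci: str = ""
    spc: str = ""
    design: str = ""
    id_map: str = ""
    out_dir: str = "results"
    seed: int = 0
    cpm_threshold: float = 0.25
    min_fraction: float = 0.25
    fc_up: float = 1.5
    fc_down: float = 0.67
    alpha: float = 0.05
    discordance_p: float = 0.10
    min_spc: int = 2
    min_samples: int = 4
    window_size: int = 10
    n_trials: int = 10_000

    def __post_init__(self) -> None:
        for name in (
            "cpm_threshold", "min_fraction", "fc_up", "fc_down", "alpha",
            "discordance_p", "min_spc", "min_samples", "window_size", "n_trials",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_inputs(config: PipelineConfig):
    counts = CountMatrix.from_tsv(config.counts)
    design = SampleDesign.from_tsv(config.design)
    spc = SpectralCountMatrix.from_tsv(config.spc)
    id_map = pd.read_csv(config.id_map, sep="\t", dtype=str)
    if config.fpkm:
        fpkm_df = pd.read_csv(config.fpkm, sep="\t", index_col=0)
        if config.fpkm_ci:
            ci_df = pd.read_csv(config.fpkm_ci, sep="\t", index_col=0)
            fpkm = FpkmMatrix(fpkm_df, ci_df)
        else:
            fpkm = FpkmMatrix.with_approximate_ci(fpkm_df, counts.counts)
    else:
        fpkm = FpkmMatrix.with_approximate_ci(compute_cpm(counts), counts.counts)
    return counts, fpkm, spc, design, id_map


def run_pipeline(config: PipelineConfig) -> dict:
    """Run detection, both DE arms, pair matching and integration stages.

    Writes every stage output under ``config.out_dir`` along with a
    ``manifest.json`` recording the configuration, its hash, the seed and
    the package version.  Returns the in-memory results keyed by stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts, fpkm, spc, design, id_map = _load_inputs(config)

    detected = detect_expressed_genes(
        counts, fpkm, min_fraction=config.min_fraction,
        cpm_threshold=config.cpm_threshold,
    )
    detected_counts = CountMatrix(counts.counts.loc[detected])
    factors = tmm_factors(detected_counts)
    mrna_de = nb_paired_de(
        detected_counts, design, factors,
        fc_up=config.fc_up, fc_down=config.fc_down, alpha=config.alpha,
    )
    mrna_de.to_csv(out / "mrna_de.tsv", sep="\t", index=False)

    spc_f = filter_detected_proteins(
        spc, min_spc=config.min_spc, min_samples=config.min_samples
    )
    norm = normalize_spc(spc_f)
    nsaf = compute_nsaf(spc_f)
    nsaf.to_csv(out / "nsaf.tsv", sep="\t", index_label="protein_id")
    protein_de = paired_lm_de(
        norm, design, fc_up=config.fc_up, fc_down=config.fc_down, alpha=config.alpha
    )
    protein_de.to_csv(out / "protein_de.tsv", sep="\t", index=False)

    pairs, unmatched = match_pairs(mrna_de, protein_de, id_map)
    pairs.to_csv(out / "pairs.tsv", sep="\t", index=False)
    unmatched.to_csv(out / "unmatched.tsv", sep="\t", index=False)

    report = fold_change_correlation(pairs)
    conc = concordance_table(pairs)
    down_up, up_down = discordant_pairs(pairs, p_threshold=config.discordance_p)
    down_up.to_csv(out / "discordant_mrna_down_protein_up.tsv", sep="\t", index=False)
    up_down.to_csv(out / "discordant_mrna_up_protein_down.tsv", sep="\t", index=False)
    degps = degp_intersect(pairs)
    degps.to_csv(out / "degp.tsv", sep="\t", index=False)

    summary = {
        "n_genes_detected": len(detected),
        "n_proteins_detected": int(spc_f.spc.shape[0]),
        "n_pairs": int(len(pairs)),
        "fold_change_spearman": report.r_s,
        "concordance_observed": conc.observed.tolist(),
        "concordance_residuals": conc.residuals.tolist(),
        "n_zero_fc_excluded": conc.n_zero_excluded,
        "n_degs": int((mrna_de["de_class"] != "unchanged").sum()),
        "n_degs_up": int((mrna_de["de_class"] == "increased").sum()),
        "n_degs_down": int((mrna_de["de_class"] == "decreased").sum()),
        "n_deps": int((protein_de["de_class"] != "unchanged").sum()),
        "n_deps_up": int((protein_de["de_class"] == "increased").sum()),
        "n_deps_down": int((protein_de["de_class"] == "decreased").sum()),
        "n_degps": int(len(degps)),
        "n_discordant_mrna_down_protein_up": int(len(down_up)),
        "n_discordant_mrna_up_protein_down": int(len(up_down)),
    }
    (out / "concordance.json").write_text(json.dumps(summary, indent=2))

    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "outputs": sorted(
            {p.name for p in out.iterdir() if p.is_file()} | {"manifest.json"}
        ),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return {
        "mrna_de": mrna_de,
        "protein_de": protein_de,
        "pairs": pairs,
        "correlation": report,
        "concordance": conc,
        "discordant": (down_up, up_down),
        "degps": degps,
        "summary": summary,
    }
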