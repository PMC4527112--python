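"""Synthetic paired-cohort, atlas and disease-panel generators with ground truth.

The cohort generator emulates the structure of a paired lesional (PP) /
uninvolved (PN) skin study: negative-binomial RNA-seq counts with shared
per-patient effects, planted gene fold changes, and spectral counts coupled
to mRNA abundance through a per-protein translation factor.  mRNA and
protein log fold changes of mapped pairs are drawn from a bivariate
Gaussian with a configurable correlation (the "coupling"), mirroring the
moderate transcriptome-proteome correspondence (r ~ 0.4-0.6) reported for
human tissue.  A planted "translation block" of proteins is discordant by
construction - mRNA down, protein up - and planted protein-only spikes
are biased toward increases, echoing the excess of elevated proteins seen
in lesional skin.

Every generator takes an explicit seed, draws from named substreams, and
emits a ground-truth record sufficient to score recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas_enrichment import AtlasMatrix
from .gsea_screen import OrderedGeneList
from .rnaseq_de import CountMatrix, FpkmMatrix, SampleDesign
from .proteome_de import SpectralCountMatrix

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_atlas",
    "simulate_disease_panel",
]


def _substream(seed: int, label: str) -> np.random.Generator:
    """Independent generator derived from the top-level seed and a stage label."""
    digest = sum((i + 1) * b for i, b in enumerate(label.encode())) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), digest]))


@dataclass(kw_only=True)
class CohortSpec:
    """Parameters of a simulated paired PP/PN cohort.

    Defaults are desk scale (2,000 genes, 600 mapped proteins, 14 patients)
    with NB dispersion 0.1, log-normal patient effects shared between a
    patient's two samples, an mRNA-protein log-FC coupling of 0.4, and a
    40-protein discordant translation block.
    """

    seed: int
    n_patients: int = 14
    n_genes: int = 2000
    n_proteins_mapped: int = 600
    coupling_rho: float = 0.4
    frac_deg_up: float = 0.10
    frac_deg_down: float = 0.10
    deg_fold_change: float = 4.0
    frac_dep_up: float = 0.05
    frac_dep_down: float = 0.01
    dep_fold_change: float = 3.0
    translation_block_size: int = 40
    dispersion: float = 0.06
    patient_sd: float = 0.4
    gene_lfc_sd: float = 1.0
    protein_lfc_sd: float = 0.7
    read_depth: float = 2e6
    spc_per_protein: float = 30.0
    depth_cv: float = 0.15

    def __post_init__(self) -> None:
        if self.frac_deg_up + self.frac_deg_down > 1:
            raise ValueError("DEG fractions must sum to at most 1")
        if not -1 <= self.coupling_rho <= 1:
            raise ValueError("coupling_rho must lie in [-1, 1]")
        if self.translation_block_size > self.n_proteins_mapped:
            raise ValueError("translation block larger than the mapped proteome")
        if self.n_proteins_mapped > self.n_genes:
            raise ValueError("cannot map more proteins than genes")
        if self.dispersion < 0 or self.patient_sd < 0:
            raise ValueError("dispersion and patient_sd must be non-negative")


@dataclass
class GroundTruth:
    """Planted per-feature effects and memberships of one simulated cohort."""

    genes: pd.DataFrame  # gene_id, true_log2_fc, deg_up, deg_down, mapped
    proteins: pd.DataFrame  # protein_id, gene_id, true_log2_fc, translation_block


@dataclass
class SimulatedCohort:
    counts: CountMatrix
    fpkm: FpkmMatrix
    spc: SpectralCountMatrix
    design: SampleDesign
    id_map: pd.DataFrame
    truth: GroundTruth


def _make_design(n_patients: int) -> SampleDesign:
    rows = []
    for i in range(1, n_patients + 1):
        pat = f"PT{i:02d}"
        rows.append({"sample_id": f"{pat}_PN", "patient": pat, "condition": "PN"})
        rows.append({"sample_id": f"{pat}_PP", "patient": pat, "condition": "PP"})
    return SampleDesign(pd.DataFrame(rows))


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Simulate a paired PP/PN cohort with coupled mRNA and protein arms.

    Gene baselines are log-normal; counts are Gamma-Poisson (NB) around
    baseline x patient effect x condition fold change.  Mapped pairs draw
    (mRNA, protein) log2 fold changes from a bivariate Gaussian with
    correlation ``coupling_rho``; planted DEGs (fold change
    ``deg_fold_change`` up or down) are placed on unmapped genes first and
    spill over onto mapped pairs concordantly only if the unmapped pool is
    exhausted.  Translation-block proteins are overridden to mRNA fold
    change 0.7 and protein fold change 1.8.  Spectral counts are Poisson
    around mRNA-proportional expected abundance times a log-normal
    per-protein translation factor.
    """
    design = _make_design(spec.n_patients)
    n_s = 2 * spec.n_patients
    gene_ids = [f"G{i + 1:05d}" for i in range(spec.n_genes)]

    rng_fc = _substream(spec.seed, "fold_changes")
    rng_counts = _substream(spec.seed, "counts")
    rng_prot = _substream(spec.seed, "proteins")
    rng_struct = _substream(spec.seed, "structure")

    # --- choose mapped genes and planted memberships -----------------------
    mapped_idx = np.sort(
        rng_struct.choice(spec.n_genes, size=spec.n_proteins_mapped, replace=False)
    )
    mapped_mask = np.zeros(spec.n_genes, dtype=bool)
    mapped_mask[mapped_idx] = True

    n_up = int(round(spec.frac_deg_up * spec.n_genes))
    n_down = int(round(spec.frac_deg_down * spec.n_genes))
    unmapped_pool = np.where(~mapped_mask)[0]
    rng_struct.shuffle(unmapped_pool)
    spill = max(0, n_up + n_down - unmapped_pool.size)
    mapped_pool = rng_struct.permutation(mapped_idx)[:spill]
    pool = np.concatenate([unmapped_pool, mapped_pool])
    deg_up_idx = pool[:n_up]
    deg_down_idx = pool[n_up : n_up + n_down]

    # --- log2 fold changes -------------------------------------------------
    # Mapped pairs share a bivariate-Gaussian copula: the protein component
    # follows the standardized gene component with correlation rho.  The
    # per-arm spreads differ (transcript shifts are wider than protein
    # shifts), which leaves rank correlation untouched but keeps the bulk of
    # the proteome inside the fold-change gates after total-count
    # normalization.
    gene_lfc = np.zeros(spec.n_genes)
    protein_lfc_by_gene = np.zeros(spec.n_genes)
    if spec.n_proteins_mapped:
        # coupling_rho is a rank (Spearman) correlation; the Gaussian copula
        # needs the matching Pearson value 2 sin(pi * rho_s / 6)
        rho = 2.0 * np.sin(np.pi * spec.coupling_rho / 6.0)
        z_g = rng_fc.normal(size=spec.n_proteins_mapped)
        z_p = rho * z_g + np.sqrt(
            max(0.0, 1.0 - rho**2)
        ) * rng_fc.normal(size=spec.n_proteins_mapped)
        gene_lfc[mapped_idx] = z_g * spec.gene_lfc_sd
        protein_lfc_by_gene[mapped_idx] = z_p * spec.protein_lfc_sd
    spike = np.log2(spec.deg_fold_change)
    gene_lfc[deg_up_idx] += spike
    gene_lfc[deg_down_idx] -= spike
    # concordant transmission for any DEG spilling onto a mapped pair
    protein_lfc_by_gene[np.intersect1d(deg_up_idx, mapped_idx)] += spike
    protein_lfc_by_gene[np.intersect1d(deg_down_idx, mapped_idx)] -= spike

    block_genes = np.array([], dtype=int)
    if spec.translation_block_size:
        eligible = np.setdiff1d(mapped_idx, np.concatenate([deg_up_idx, deg_down_idx]))
        block_genes = np.sort(
            rng_struct.choice(eligible, size=spec.translation_block_size, replace=False)
        )
        gene_lfc[block_genes] = np.log2(0.7)
        protein_lfc_by_gene[block_genes] = np.log2(1.8)

    # --- RNA-seq counts ----------------------------------------------------
    base_weight = rng_counts.lognormal(mean=0.0, sigma=1.0, size=spec.n_genes)
    base_weight /= base_weight.sum()
    depth = spec.read_depth * rng_counts.lognormal(
        mean=0.0, sigma=spec.depth_cv, size=n_s
    )
    patient_effect = rng_counts.normal(
        0.0, spec.patient_sd, size=(spec.n_genes, spec.n_patients)
    )
    is_pp = np.array([c == "PP" for c in design.samples["condition"]])
    pat_of_sample = np.repeat(np.arange(spec.n_patients), 2)
    mean_rel = (
        base_weight[:, None]
        * np.exp(patient_effect[:, pat_of_sample])
        * np.where(is_pp[None, :], 2.0 ** gene_lfc[:, None], 1.0)
    )
    mu = mean_rel * depth[None, :]
    if spec.dispersion > 0:
        lam = rng_counts.gamma(
            shape=1.0 / spec.dispersion, scale=spec.dispersion * mu
        )
    else:
        lam = mu
    counts = rng_counts.poisson(lam).astype(np.int64)
    count_df = pd.DataFrame(counts, index=gene_ids, columns=design.sample_ids)
    count_mat = CountMatrix(count_df)

    lengths_kb = rng_counts.lognormal(mean=np.log(2.0), sigma=0.6, size=spec.n_genes)
    lib = count_df.sum(axis=0).to_numpy(dtype=float)
    fpkm_vals = counts / (lib[None, :] / 1e6) / lengths_kb[:, None]
    fpkm_df = pd.DataFrame(fpkm_vals, index=gene_ids, columns=design.sample_ids)
    fpkm = FpkmMatrix.with_approximate_ci(fpkm_df, count_df)

    # --- spectral counts ---------------------------------------------------
    protein_ids = [f"PR_{gene_ids[g]}" for g in mapped_idx]
    translation_factor = rng_prot.lognormal(mean=0.0, sigma=0.5, size=spec.n_proteins_mapped)
    prot_weight = base_weight[mapped_idx] * translation_factor
    prot_weight /= prot_weight.sum()
    p_lfc = protein_lfc_by_gene[mapped_idx].copy()

    # Protein-only differential-abundance spikes, biased up (increased DEPs
    # outnumber decreased ones in lesional skin) and placed on low-abundance
    # proteins - as immune-infiltrate proteins are - so they barely perturb
    # the compositional total that spectral-count normalization divides by.
    n_dep_up = int(round(spec.frac_dep_up * spec.n_proteins_mapped))
    n_dep_down = int(round(spec.frac_dep_down * spec.n_proteins_mapped))
    dep_up_pos = np.array([], dtype=int)
    dep_down_pos = np.array([], dtype=int)
    if n_dep_up + n_dep_down:
        in_block = np.isin(mapped_idx, block_genes)
        spiked = np.isin(mapped_idx, np.concatenate([deg_up_idx, deg_down_idx]))
        low = prot_weight <= np.median(prot_weight)
        eligible_pos = np.where(low & ~in_block & ~spiked)[0]
        chosen = rng_struct.choice(
            eligible_pos, size=min(n_dep_up + n_dep_down, eligible_pos.size),
            replace=False,
        )
        dep_up_pos = chosen[:n_dep_up]
        dep_down_pos = chosen[n_dep_up:]
        p_spike = np.log2(spec.dep_fold_change)
        p_lfc[dep_up_pos] += p_spike
        p_lfc[dep_down_pos] -= p_spike
    prot_mean = (
        prot_weight[:, None]
        * np.exp(patient_effect[mapped_idx][:, pat_of_sample])
        * np.where(is_pp[None, :], 2.0 ** p_lfc[:, None], 1.0)
        * spec.spc_per_protein * spec.n_proteins_mapped
    )
    spc_counts = rng_prot.poisson(prot_mean).astype(np.int64)
    mw = rng_prot.lognormal(mean=np.log(50.0), sigma=0.5, size=spec.n_proteins_mapped)
    spc = SpectralCountMatrix(
        pd.DataFrame(spc_counts, index=protein_ids, columns=design.sample_ids),
        pd.Series(mw, index=protein_ids, name="molecular_weight_kda"),
    )

    id_map = pd.DataFrame(
        {"gene_id": [gene_ids[g] for g in mapped_idx], "protein_id": protein_ids}
    )

    block_mask = np.zeros(spec.n_genes, dtype=bool)
    block_mask[block_genes] = True
    genes_truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "true_log2_fc": gene_lfc,
            "deg_up": np.isin(np.arange(spec.n_genes), deg_up_idx),
            "deg_down": np.isin(np.arange(spec.n_genes), deg_down_idx),
            "mapped": mapped_mask,
            "translation_block": block_mask,
        }
    )
    n_p = spec.n_proteins_mapped
    proteins_truth = pd.DataFrame(
        {
            "protein_id": protein_ids,
            "gene_id": [gene_ids[g] for g in mapped_idx],
            "true_log2_fc": p_lfc,
            "dep_up": np.isin(np.arange(n_p), dep_up_pos),
            "dep_down": np.isin(np.arange(n_p), dep_down_pos),
            "translation_block": block_mask[mapped_idx],
            "degp": np.isin(mapped_idx, np.concatenate([deg_up_idx, deg_down_idx])),
        }
    )
    truth = GroundTruth(genes=genes_truth, proteins=proteins_truth)
    return SimulatedCohort(
        counts=count_mat, fpkm=fpkm, spc=spc, design=design, id_map=id_map, truth=truth
    )


# ---------------------------------------------------------------------------


def simulate_atlas(
    n_proteins: int,
    contexts,
    n_specific_per_context: int,
    effect: float,
    seed: int,
    n_replicates: int = 3,
) -> tuple[AtlasMatrix, pd.DataFrame]:
    """Simulate a proteome atlas with planted context-specific proteins.

    ``contexts`` is a list of context names (or an int for generic names).
    Each context receives ``n_specific_per_context`` planted proteins whose
    abundance in that context is multiplied by ``effect``; every context
    has ``n_replicates`` replicate columns.  Returns the atlas plus a
    truth table mapping proteins to their planted context (empty string =
    background).
    """
    if isinstance(contexts, int):
        contexts = [f"ctx{i + 1}" for i in range(contexts)]
    contexts = list(contexts)
    if n_specific_per_context * len(contexts) > n_proteins:
        raise ValueError("too many planted proteins for the atlas size")
    rng = _substream(seed, "atlas")
    protein_ids = [f"AP{i + 1:05d}" for i in range(n_proteins)]
    base = rng.lognormal(mean=np.log(10.0), sigma=1.0, size=n_proteins)
    cols = {}
    planted = np.full(n_proteins, "", dtype=object)
    order = rng.permutation(n_proteins)
    for ci, ctx in enumerate(contexts):
        idx = order[ci * n_specific_per_context : (ci + 1) * n_specific_per_context]
        planted[idx] = ctx
    for ctx in contexts:
        mult = np.where(planted == ctx, effect, 1.0)
        for r in range(1, n_replicates + 1):
            noise = rng.lognormal(mean=0.0, sigma=0.25, size=n_proteins)
            cols[f"{ctx}__rep{r}"] = base * mult * noise
    atlas = AtlasMatrix(pd.DataFrame(cols, index=protein_ids))
    truth = pd.DataFrame({"protein_id": protein_ids, "planted_context": planted})
    return atlas, truth


# ---------------------------------------------------------------------------


@dataclass
class PanelSim:
    """A simulated disease panel plus an induction target list and truth."""

    panel: dict
    induction_list: OrderedGeneList
    truth: pd.DataFrame  # gene_id, target_fraction (NaN for non-DEGP genes)


def simulate_disease_panel(
    n_diseases: int,
    n_genes: int,
    degp_ids,
    seed: int,
    specificity_gradient: float = 0.0,
    mask_drop_prob: float = 0.2,
    responder_p_scale: float = 1e-4,
    gene_ids=None,
) -> PanelSim:
    """Simulate ordered gene lists for a panel of two-group disease comparisons.

    Every DEGP gene receives a target specificity fraction drawn uniformly
    on [0, 1]; in each disease it is a responder (strongly significant,
    increased) with that probability.  Platform masks drop each gene from
    each disease with probability ``mask_drop_prob``.  Non-responders carry
    null scores (uniform p, random sign).

    ``specificity_gradient`` > 0 additionally produces an induction target
    list in which a DEGP's score falls linearly with its target fraction -
    the most disease-specific DEGPs are the most induced - for exercising
    the stratified GSEA trend.  With the gradient at 0 the induction list
    is null.
    """
    rng = _substream(seed, "panel")
    if gene_ids is None:
        gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    gene_ids = list(gene_ids)
    if len(gene_ids) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")
    degp_ids = list(degp_ids)
    if not set(degp_ids) <= set(gene_ids):
        raise ValueError("degp_ids must be a subset of the gene universe")

    fractions = pd.Series(rng.uniform(0.0, 1.0, size=len(degp_ids)), index=degp_ids)
    panel = {}
    is_degp = np.isin(gene_ids, degp_ids)
    frac_vec = fractions.reindex(gene_ids).to_numpy()
    for d in range(n_diseases):
        assayed = rng.uniform(size=n_genes) >= mask_drop_prob
        p_null = rng.uniform(size=n_genes)
        signs = rng.choice([-1.0, 1.0], size=n_genes)
        responds = is_degp & (rng.uniform(size=n_genes) < np.nan_to_num(frac_vec))
        p = np.where(responds, rng.uniform(size=n_genes) * responder_p_scale, p_null)
        signs = np.where(responds, 1.0, signs)
        score = -np.log10(np.clip(p, 1e-300, 1.0)) * signs
        table = pd.DataFrame(
            {"gene_id": gene_ids, "signed_score": score, "assayed": assayed}
        )
        panel[f"disease{d + 1:02d}"] = OrderedGeneList(
            table, metadata={"dataset": f"disease{d + 1:02d}", "contrast": "lesional_vs_normal"}
        )

    null_p = rng.uniform(size=n_genes)
    null_sign = rng.choice([-1.0, 1.0], size=n_genes)
    score = -np.log10(np.clip(null_p, 1e-300, 1.0)) * null_sign
    if specificity_gradient > 0:
        boost = specificity_gradient * (1.0 - np.nan_to_num(frac_vec))
        score = np.where(is_degp, boost + rng.normal(0.0, 1.0, size=n_genes), score)
    induction = OrderedGeneList(
        pd.DataFrame({"gene_id": gene_ids, "signed_score": score, "assayed": True}),
        metadata={"dataset": "induction", "contrast": "treated_vs_control"},
    )
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "target_fraction": frac_vec}
    )
    return PanelSim(panel=panel, induction_list=induction, truth=truth)
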