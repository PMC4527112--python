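"""Matching mRNA-protein pairs and mining concordance, discordance and DEGPs.

A pair table joins the mRNA and protein differential-expression tables
through a one-to-one gene/protein identifier map.  From the table the
module derives: the Spearman correlation of log fold changes across pairs
(globally, per patient, and stratified by abundance), the 2x2
sign-concordance contingency table with Pearson residuals, the sets of
discordant pairs (mRNA down / protein up and the mirror set, both at raw
p < 0.10 by default), and the DEGP intersection - pairs whose mRNA and
protein calls are significant and share direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats_core import DEClass, pearson_residuals, spearman

__all__ = [
    "match_pairs",
    "fold_change_correlation",
    "concordance_table",
    "discordant_pairs",
    "degp_intersect",
    "CorrelationReport",
    "ConcordanceResult",
]


def match_pairs(
    mrna_de: pd.DataFrame,
    protein_de: pd.DataFrame,
    id_map: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inner-join the two DE tables through a gene<->protein map.

    ``id_map`` must have columns ``gene_id`` and ``protein_id`` and be
    one-to-one on both sides.  Returns ``(pairs, unmatched)``: the pair
    table carries every DE column from both arms with ``mrna_``/
    ``protein_`` prefixes; ``unmatched`` lists features that failed to pair
    and why.
    """
    for col in ("gene_id", "protein_id"):
        if col not in id_map.columns:
            raise ValueError(f"id_map needs a {col!r} column")
        dups = id_map[col][id_map[col].duplicated()].unique().tolist()
        if dups:
            raise ValueError(f"duplicate mappings on {col}: {dups}")

    mrna = mrna_de.add_prefix("mrna_").rename(columns={"mrna_feature_id": "gene_id"})
    prot = protein_de.add_prefix("protein_").rename(
        columns={"protein_feature_id": "protein_id"}
    )
    pairs = id_map.merge(mrna, on="gene_id", how="inner").merge(
        prot, on="protein_id", how="inner"
    )
    pairs.insert(0, "pair_id", pairs["gene_id"] + "|" + pairs["protein_id"])

    unmatched = []
    mapped_genes = set(id_map["gene_id"])
    mapped_prots = set(id_map["protein_id"])
    paired_genes = set(pairs["gene_id"])
    paired_prots = set(pairs["protein_id"])
    for g in mrna_de["feature_id"]:
        if g not in mapped_genes:
            unmatched.append((g, "gene", "not in id map"))
        elif g not in paired_genes:
            unmatched.append((g, "gene", "mapped protein not in protein table"))
    for p in protein_de["feature_id"]:
        if p not in mapped_prots:
            unmatched.append((p, "protein", "not in id map"))
        elif p not in paired_prots:
            unmatched.append((p, "protein", "mapped gene not in mRNA table"))
    unmatched_df = pd.DataFrame(unmatched, columns=["feature_id", "arm", "reason"])
    return pairs, unmatched_df


@dataclass
class CorrelationReport:
    """Spearman correlations of mRNA vs protein log fold changes."""

    r_s: float
    n_pairs: int
    per_patient: pd.Series | None = None
    by_abundance: dict = field(default_factory=dict)


def fold_change_correlation(
    pairs: pd.DataFrame,
    mrna_patient_lfc: pd.DataFrame | None = None,
    protein_patient_lfc: pd.DataFrame | None = None,
) -> CorrelationReport:
    """Correlate mRNA and protein log fold changes across matched pairs.

    Always reports the global Spearman r_s.  When per-patient log-FC
    matrices (pairs x patients, indexed like ``pairs['pair_id']``) are
    supplied, also reports one r_s per patient.  Abundance-stratified
    correlations split pairs into protein-abundance tertiles.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    x = pairs["mrna_log_fc"].to_numpy()
    y = pairs["protein_log_fc"].to_numpy()
    r = spearman(x, y)

    per_patient = None
    if mrna_patient_lfc is not None and protein_patient_lfc is not None:
        common = mrna_patient_lfc.columns.intersection(protein_patient_lfc.columns)
        vals = {}
        for pat in common:
            a = mrna_patient_lfc.loc[pairs["pair_id"], pat].to_numpy()
            b = protein_patient_lfc.loc[pairs["pair_id"], pat].to_numpy()
            vals[pat] = spearman(a, b)
        per_patient = pd.Series(vals, name="r_s")

    by_abundance = {}
    if "protein_mean_abundance" in pairs.columns and len(pairs) >= 9:
        tertiles = pd.qcut(
            pairs["protein_mean_abundance"], 3, labels=["low", "mid", "high"],
            duplicates="drop",
        )
        for level in ("low", "high"):
            mask = (tertiles == level).to_numpy()
            if mask.sum() >= 3:
                by_abundance[level] = spearman(x[mask], y[mask])
    return CorrelationReport(r_s=r, n_pairs=len(pairs), per_patient=per_patient,
                             by_abundance=by_abundance)


@dataclass
class ConcordanceResult:
    """Sign-concordance 2x2 table of matched pairs with Pearson residuals."""

    observed: np.ndarray  # rows: mRNA up/down; cols: protein up/down
    residuals: np.ndarray
    n_zero_excluded: int
    row_labels: tuple = ("mrna_up", "mrna_down")
    col_labels: tuple = ("protein_up", "protein_down")


def concordance_table(pairs: pd.DataFrame) -> ConcordanceResult:
    """Cross-classify pairs by the sign of their mRNA and protein log FC.

    Pairs with a log fold change of exactly zero on either arm carry no
    direction and are excluded (their count is reported).  Pearson
    residuals against the independence expectation quantify over- and
    under-abundance of each sign combination.
    """
    mx = pairs["mrna_log_fc"].to_numpy()
    px = pairs["protein_log_fc"].to_numpy()
    nonzero = (mx != 0) & (px != 0)
    n_excluded = int((~nonzero).sum())
    mx, px = mx[nonzero], px[nonzero]
    if mx.size == 0:
        raise ValueError("no pairs with nonzero fold changes on both arms")
    observed = np.array(
        [
            [np.sum((mx > 0) & (px > 0)), np.sum((mx > 0) & (px < 0))],
            [np.sum((mx < 0) & (px > 0)), np.sum((mx < 0) & (px < 0))],
        ],
        dtype=float,
    )
    residuals = pearson_residuals(observed)
    return ConcordanceResult(observed=observed, residuals=residuals,
                             n_zero_excluded=n_excluded)


def discordant_pairs(
    pairs: pd.DataFrame,
    p_threshold: float = 0.10,
    use_fdr: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairs whose mRNA and protein shift in opposite directions.

    Set 1: mRNA decreased (negative log FC, p below threshold) while the
    protein is increased (positive log FC, p below threshold) - the
    pattern of the translation machinery in lesional skin.  Set 2 is the
    mirror image.  Raw p-values gate membership by default; ``use_fdr``
    switches the gate to BH-adjusted values.
    """
    pcol_m = "mrna_fdr" if use_fdr else "mrna_raw_p"
    pcol_p = "protein_fdr" if use_fdr else "protein_raw_p"
    sig = (pairs[pcol_m] < p_threshold) & (pairs[pcol_p] < p_threshold)
    down_up = pairs[sig & (pairs["mrna_log_fc"] < 0) & (pairs["protein_log_fc"] > 0)]
    up_down = pairs[sig & (pairs["mrna_log_fc"] > 0) & (pairs["protein_log_fc"] < 0)]
    return down_up.reset_index(drop=True), up_down.reset_index(drop=True)


def degp_intersect(pairs: pd.DataFrame) -> pd.DataFrame:
    """Pairs significant and same-direction on both arms (DEGPs).

    A pair qualifies when the mRNA and protein classifications agree and
    neither is 'unchanged'.  The result records the shared direction and is
    sorted by protein fold change, descending.
    """
    same = pairs["mrna_de_class"] == pairs["protein_de_class"]
    called = pairs["mrna_de_class"] != DEClass.UNCHANGED.value
    degps = pairs[same & called].copy()
    degps["direction"] = degps["mrna_de_class"]
    return degps.sort_values(
        "protein_fold_change", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
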