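"""Spectral-count proteomics: detection filtering, normalization, NSAF, paired DE.

Relative protein abundance is carried by normalized spectral counts
(total-count scaling to the mean sample total); absolute abundance by the
normalized spectral abundance factor, NSAF = (SpC/MW) / sum(SpC/MW) within
each sample.  Differential abundance between paired PP and PN biopsies is
assessed with an ordinary least-squares model on normalized spectral counts
with patient and sample-type covariates; the two-sided t-test on the
sample-type coefficient gives the raw p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .rnaseq_de import SampleDesign, make_de_table

__all__ = [
    "SpectralCountMatrix",
    "filter_detected_proteins",
    "normalize_spc",
    "compute_nsaf",
    "paired_lm_de",
]


@dataclass
class SpectralCountMatrix:
    """Proteins x samples spectral counts plus per-protein molecular weight (kDa)."""

    spc: pd.DataFrame
    molecular_weight_kda: pd.Series
    keratin_contaminant: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.spc.index.has_duplicates or self.spc.columns.has_duplicates:
            raise ValueError("protein and sample identifiers must be unique")
        vals = self.spc.to_numpy()
        if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
            raise ValueError("spectral counts must be non-negative integers")
        mw = self.molecular_weight_kda.reindex(self.spc.index)
        if mw.isna().any() or (mw <= 0).any():
            raise ValueError("every protein needs a positive molecular weight")
        self.molecular_weight_kda = mw
        if self.keratin_contaminant is None:
            self.keratin_contaminant = pd.Series(False, index=self.spc.index)
        else:
            self.keratin_contaminant = self.keratin_contaminant.reindex(
                self.spc.index, fill_value=False
            )

    @property
    def protein_ids(self) -> pd.Index:
        return self.spc.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.spc.columns

    def subset(self, protein_ids) -> "SpectralCountMatrix":
        return SpectralCountMatrix(
            self.spc.loc[protein_ids],
            self.molecular_weight_kda.loc[protein_ids],
            self.keratin_contaminant.loc[protein_ids],
        )

    @classmethod
    def from_tsv(cls, path) -> "SpectralCountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if "molecular_weight_kda" not in df.columns:
            raise ValueError("expected a molecular_weight_kda column")
        mw = df.pop("molecular_weight_kda")
        keratin = None
        if "keratin_contaminant" in df.columns:
            keratin = df.pop("keratin_contaminant").astype(bool)
        return cls(df.astype(int), mw, keratin)

    def to_tsv(self, path) -> None:
        out = self.spc.copy()
        out.insert(0, "molecular_weight_kda", self.molecular_weight_kda)
        out.insert(1, "keratin_contaminant", self.keratin_contaminant)
        out.to_csv(path, sep="\t", index_label="protein_id")


def filter_detected_proteins(
    spc: SpectralCountMatrix,
    min_spc: int = 2,
    min_samples: int = 4,
) -> SpectralCountMatrix:
    """Keep proteins with SpC >= ``min_spc`` (i.e. SpC > 1) in >= ``min_samples`` samples.

    Keratin contaminants are retained (they are genuinely abundant in skin
    biopsies); the ``keratin_contaminant`` flag travels with the matrix so
    downstream consumers may exclude them explicitly.
    """
    hits = (spc.spc.to_numpy() >= min_spc).sum(axis=1)
    keep = spc.protein_ids[hits >= min_samples]
    return spc.subset(keep)


def normalize_spc(spc: SpectralCountMatrix) -> pd.DataFrame:
    """Total-count scaling of spectral counts to the mean sample total.

    After normalization every sample column sums to the same total (the
    across-sample mean of raw totals), making spectral counts comparable
    between samples of different depth.
    """
    totals = spc.spc.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"samples with zero total spectral counts: {bad}")
    return spc.spc * totals.mean() / totals


def compute_nsaf(spc: SpectralCountMatrix) -> pd.DataFrame:
    """Normalized spectral abundance factor per protein and sample.

    NSAF = (SpC/MW) / sum_over_proteins(SpC/MW), computed within each
    sample; columns sum to one.
    """
    saf = spc.spc.div(spc.molecular_weight_kda, axis=0)
    totals = saf.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"samples with all-zero spectral counts: {bad}")
    return saf / totals


def paired_lm_de(
    norm_spc: pd.DataFrame,
    design: SampleDesign,
    fc_up: float = 1.5,
    fc_down: float = 0.67,
    alpha: float = 0.05,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Paired least-squares differential abundance on normalized spectral counts.

    Per protein, normalized SpC is regressed on patient dummies plus a
    PP indicator; the raw p-value is the two-sided t-test on the PP
    coefficient.  Fold change is (mean PP + c0)/(mean PN + c0) with
    pseudocount c0 guarding against zero PN means.  FDR by Benjamini-
    Hochberg, classification via the shared increased/decreased/unchanged
    contract.
    """
    if design.n_patients < 2:
        raise ValueError("need at least two patients for a paired fit")
    if list(norm_spc.columns) != design.sample_ids:
        raise ValueError("matrix columns must match the design sample order")
    X, _ = design.design_matrices()
    Y = norm_spc.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("design is saturated: more coefficients than samples")
    xtx_inv = np.linalg.inv(X.T @ X)
    hat = xtx_inv @ X.T
    beta = Y @ hat.T  # proteins x p
    resid = Y - beta @ X.T
    dof = n - p
    sigma2 = np.sum(resid**2, axis=1) / dof
    cond_var = xtx_inv[-1, -1]
    se = np.sqrt(np.maximum(sigma2 * cond_var, 0.0))
    coef = beta[:, -1]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, coef / se, 0.0)
    raw_p = 2.0 * _sps.t.sf(np.abs(tstat), df=dof)
    # zero residual variance: an exact fit is decisive, a constant row is not
    raw_p = np.where(se > 0, raw_p, np.where(coef != 0, 0.0, 1.0))

    is_pp = (design.samples["condition"] == "PP").to_numpy()
    mean_pp = Y[:, is_pp].mean(axis=1)
    mean_pn = Y[:, ~is_pp].mean(axis=1)
    fold = (mean_pp + pseudocount) / (mean_pn + pseudocount)
    log_fc = np.log2(fold)

    return make_de_table(
        norm_spc.index,
        log_fc,
        raw_p,
        mean_abundance=Y.mean(axis=1),
        fc_up=fc_up,
        fc_down=fc_down,
        alpha=alpha,
        extra={"condition_coef": coef},
    )
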