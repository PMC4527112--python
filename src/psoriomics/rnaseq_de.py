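"""Gene-level detection filtering and paired differential expression on counts.

The model is the standard paired negative-binomial workflow for a
lesional/uninvolved (PP/PN) design: raw counts are normalized between
samples with the weighted trimmed mean of M-values (TMM), per-gene NB
dispersions are estimated by maximizing the Cox-Reid adjusted profile
likelihood and smoothed against average log-CPM with a binned-median trend,
and each gene is tested with a likelihood-ratio test comparing the full
log-linear model (patient + condition) against the patient-only reduction.
Fold changes are oriented PP/PN throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from . import _nbglm
from .stats_core import DEClass, bh_adjust, classify_de

__all__ = [
    "CountMatrix",
    "FpkmMatrix",
    "SampleDesign",
    "compute_cpm",
    "detect_expressed_genes",
    "tmm_factors",
    "nb_paired_de",
    "make_de_table",
]

DE_TABLE_COLUMNS = [
    "feature_id",
    "fold_change",
    "log_fc",
    "raw_p",
    "fdr",
    "de_class",
    "mean_abundance",
]


@dataclass
class CountMatrix:
    """Genes x samples matrix of non-negative integer read counts."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates or c.columns.has_duplicates:
            raise ValueError("gene and sample identifiers must be unique")
        vals = c.to_numpy()
        if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be non-negative integers")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class FpkmMatrix:
    """FPKM point estimates with the lower bound of their 95% CI."""

    fpkm: pd.DataFrame
    ci_lower: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.fpkm.index.equals(self.ci_lower.index) or not self.fpkm.columns.equals(
            self.ci_lower.columns
        ):
            raise ValueError("fpkm and ci_lower must share identical axes")
        if (self.ci_lower.to_numpy() - self.fpkm.to_numpy() > 1e-9).any():
            raise ValueError("ci_lower must not exceed fpkm")

    @classmethod
    def with_approximate_ci(cls, fpkm: pd.DataFrame, counts: pd.DataFrame) -> "FpkmMatrix":
        """Build the CI lower bound as fpkm * max(0, 1 - 1.96/sqrt(count + 0.5)).

        A normal-approximation stand-in used when no external CI is
        supplied; documented as such since upstream FPKM estimation is out
        of scope here.
        """
        width = 1.0 - 1.96 / np.sqrt(counts.to_numpy() + 0.5)
        ci = fpkm.to_numpy() * np.maximum(0.0, width)
        return cls(fpkm, pd.DataFrame(ci, index=fpkm.index, columns=fpkm.columns))


@dataclass
class SampleDesign:
    """Paired design: each patient contributes one PP and one PN sample."""

    samples: pd.DataFrame  # columns: sample_id, patient, condition

    def __post_init__(self) -> None:
        required = {"sample_id", "patient", "condition"}
        if not required.issubset(self.samples.columns):
            raise ValueError(f"design needs columns {sorted(required)}")
        if not set(self.samples["condition"]) <= {"PP", "PN"}:
            raise ValueError("condition must be PP or PN")
        per = self.samples.groupby("patient")["condition"].agg(
            lambda s: sorted(s.tolist())
        )
        if not all(v == ["PN", "PP"] for v in per):
            raise ValueError("each patient must have exactly one PP and one PN sample")
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("sample ids must be unique")

    @property
    def n_patients(self) -> int:
        return self.samples["patient"].nunique()

    @property
    def sample_ids(self) -> list:
        return self.samples["sample_id"].tolist()

    def design_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """Full (intercept + patient dummies + condition) and reduced designs."""
        pats = pd.get_dummies(
            self.samples["patient"], drop_first=True, dtype=float
        ).to_numpy()
        cond = (self.samples["condition"] == "PP").to_numpy(dtype=float)[:, None]
        intercept = np.ones((len(self.samples), 1))
        full = np.hstack([intercept, pats, cond])
        reduced = np.hstack([intercept, pats])
        return full, reduced

    @classmethod
    def from_tsv(cls, path) -> "SampleDesign":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def to_tsv(self, path) -> None:
        self.samples.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------


def compute_cpm(counts: CountMatrix) -> pd.DataFrame:
    """Counts per million mapped reads, per sample."""
    lib = counts.library_sizes
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"zero library size for samples: {bad}")
    return counts.counts / lib * 1e6


def detect_expressed_genes(
    counts: CountMatrix,
    fpkm: FpkmMatrix,
    min_fraction: float = 0.25,
    cpm_threshold: float = 0.25,
) -> list:
    """Genes detectably expressed in at least ``min_fraction`` of samples.

    A gene counts as detected in a sample when its CPM exceeds
    ``cpm_threshold`` *and* the lower bound of its 95% FPKM confidence
    interval is above zero; it is retained when detected in at least
    ``ceil(min_fraction * n_samples)`` samples (7 of 28 at cohort scale).
    """
    if not counts.gene_ids.equals(fpkm.fpkm.index) or not counts.sample_ids.equals(
        fpkm.fpkm.columns
    ):
        raise ValueError("count and FPKM matrices are not aligned")
    cpm = compute_cpm(counts)
    detected = (cpm.to_numpy() > cpm_threshold) & (fpkm.ci_lower.to_numpy() > 0)
    need = int(np.ceil(min_fraction * counts.counts.shape[1]))
    keep = detected.sum(axis=1) >= need
    return counts.gene_ids[keep].tolist()


def tmm_factors(
    counts: CountMatrix,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> pd.Series:
    """Weighted trimmed mean of M-values normalization factors.

    The reference sample is the one whose 75th percentile of library-size-
    scaled counts is closest to the across-sample mean of those
    percentiles.  For each sample, gene-wise log2 ratios against the
    reference (M) are doubly trimmed -- 30% on M and 5% on average log
    abundance (A) -- and averaged with inverse asymptotic-variance weights.
    Factors are rescaled so that their geometric mean is exactly one.
    """
    mat = counts.counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if counts.counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    scaled = mat / lib
    q75 = np.quantile(scaled, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    ref = mat[:, ref_idx]
    ref_lib = lib[ref_idx]

    factors = np.ones(mat.shape[1])
    for j in range(mat.shape[1]):
        if j == ref_idx:
            continue
        obs = mat[:, j]
        ok = (obs > 0) & (ref > 0)
        if not np.any(ok):
            raise ValueError(
                f"sample {counts.sample_ids[j]!r} shares no nonzero genes with the reference"
            )
        o, r = obs[ok], ref[ok]
        m = np.log2((o / lib[j]) / (r / ref_lib))
        a = 0.5 * np.log2((o / lib[j]) * (r / ref_lib))
        # asymptotic (delta-method) variance of M
        v = (lib[j] - o) / (lib[j] * o) + (ref_lib - r) / (ref_lib * r)
        if np.allclose(m, 0, atol=1e-10):
            continue
        lo_m, hi_m = np.quantile(m, [logratio_trim, 1 - logratio_trim])
        lo_a, hi_a = np.quantile(a, [sum_trim, 1 - sum_trim])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not np.any(keep):
            keep = np.ones_like(m, dtype=bool)
        w = 1.0 / v[keep]
        factors[j] = 2 ** (np.sum(m[keep] * w) / np.sum(w))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.sample_ids, name="norm_factor")


def average_log_cpm(counts: CountMatrix, norm_factors: pd.Series | None = None) -> pd.Series:
    """Per-gene average log2 CPM on effective library sizes (0.5 prior count)."""
    lib = counts.library_sizes.to_numpy(dtype=float)
    if norm_factors is not None:
        lib = lib * norm_factors.reindex(counts.sample_ids).to_numpy()
    cpm = (counts.counts.to_numpy() + 0.5) / lib * 1e6
    return pd.Series(np.log2(cpm).mean(axis=1), index=counts.gene_ids)


def _trend_dispersion(ave_log_cpm: np.ndarray, raw_disp: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Binned-median mean-dispersion trend evaluated at every gene."""
    g = ave_log_cpm.size
    n_bins = max(1, min(n_bins, g // 2)) if g < 2 * n_bins else n_bins
    qs = np.quantile(ave_log_cpm, np.linspace(0, 1, n_bins + 1))
    qs[-1] += 1e-9
    which = np.clip(np.searchsorted(qs, ave_log_cpm, side="right") - 1, 0, n_bins - 1)
    centers, medians = [], []
    for b in range(n_bins):
        mask = which == b
        if np.any(mask):
            centers.append(ave_log_cpm[mask].mean())
            medians.append(np.median(raw_disp[mask]))
    if len(centers) == 1:
        return np.full(g, medians[0])
    order = np.argsort(centers)
    return np.interp(
        ave_log_cpm, np.asarray(centers)[order], np.asarray(medians)[order]
    )


def make_de_table(
    feature_ids,
    log_fc: np.ndarray,
    raw_p: np.ndarray,
    mean_abundance: np.ndarray,
    fc_up: float = 1.5,
    fc_down: float = 0.67,
    alpha: float = 0.05,
    extra: dict | None = None,
) -> pd.DataFrame:
    """Assemble the shared DE-table layout from log2 fold changes and p-values."""
    raw_p = np.clip(np.asarray(raw_p, dtype=float), 0.0, 1.0)
    fdr = bh_adjust(raw_p)
    fold = 2.0 ** np.asarray(log_fc, dtype=float)
    classes = [
        classify_de(fc, q, fc_up=fc_up, fc_down=fc_down, alpha=alpha).value
        for fc, q in zip(fold, fdr)
    ]
    table = pd.DataFrame(
        {
            "feature_id": list(feature_ids),
            "fold_change": fold,
            "log_fc": np.asarray(log_fc, dtype=float),
            "raw_p": raw_p,
            "fdr": fdr,
            "de_class": classes,
            "mean_abundance": np.asarray(mean_abundance, dtype=float),
        }
    )
    for k, v in (extra or {}).items():
        table[k] = v
    return table


def nb_paired_de(
    counts: CountMatrix,
    design: SampleDesign,
    norm_factors: pd.Series | None = None,
    dispersion: float | np.ndarray | None = None,
    fc_up: float = 1.5,
    fc_down: float = 0.67,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired PP-vs-PN differential expression by NB GLM likelihood-ratio test.

    Per gene: the NB dispersion is estimated by maximizing the Cox-Reid
    adjusted profile likelihood on a log-spaced grid and smoothed against
    average log-CPM by a binned-median trend (pass ``dispersion`` to
    override, e.g. 0 for the Poisson special case); a log-link NB GLM with
    offsets log(library size x TMM factor) and covariates patient +
    condition is fitted; the condition effect is tested with a chi-square(1)
    likelihood-ratio test against the patient-only model; p-values are BH
    adjusted.  Fold changes are exp(condition coefficient), i.e. PP/PN.

    Genes whose IRLS fit fails to converge are flagged (``converged``
    column) and assigned p = 1; all-zero genes get fold change 1, p = 1.
    """
    if list(counts.sample_ids) != design.sample_ids:
        raise ValueError("count matrix columns must match the design sample order")
    y = counts.counts.to_numpy(dtype=float)
    lib = counts.library_sizes.to_numpy(dtype=float)
    if norm_factors is None:
        norm_factors = pd.Series(1.0, index=counts.sample_ids)
    eff_lib = lib * norm_factors.reindex(counts.sample_ids).to_numpy(dtype=float)
    offset = np.log(eff_lib)
    full, reduced = design.design_matrices()
    cond_idx = full.shape[1] - 1

    nonzero = y.sum(axis=1) > 0
    yz = y[nonzero]
    ave = average_log_cpm(counts, norm_factors).to_numpy()

    if dispersion is None:
        raw_disp = _nbglm.estimate_dispersion_grid(yz, full, offset)
        disp = _trend_dispersion(ave[nonzero], raw_disp)
    else:
        disp = np.broadcast_to(np.asarray(dispersion, dtype=float), (yz.shape[0],))

    beta_full, mu_full, conv_full = _nbglm.irls_fit(yz, full, offset, disp)
    beta_red, mu_red, conv_red = _nbglm.irls_fit(yz, reduced, offset, disp)
    ll_full = _nbglm.nb_loglik(yz, mu_full, disp)
    ll_red = _nbglm.nb_loglik(yz, mu_red, disp)
    lrt = np.maximum(2.0 * (ll_full - ll_red), 0.0)
    p_nz = _sps.chi2.sf(lrt, df=1)
    conv = conv_full & conv_red
    p_nz = np.where(conv, p_nz, 1.0)
    lfc_nz = beta_full[:, cond_idx] / np.log(2.0)
    lfc_nz = np.where(conv, lfc_nz, lfc_nz)

    log_fc = np.zeros(y.shape[0])
    raw_p = np.ones(y.shape[0])
    converged = np.ones(y.shape[0], dtype=bool)
    log_fc[nonzero] = lfc_nz
    raw_p[nonzero] = p_nz
    converged[nonzero] = conv

    return make_de_table(
        counts.gene_ids,
        log_fc,
        raw_p,
        ave,
        fc_up=fc_up,
        fc_down=fc_down,
        alpha=alpha,
        extra={"converged": converged},
    )
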