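"""Specificity scoring against proteome atlases and enrichment of specific proteins.

An atlas is a proteins x contexts abundance matrix (skin compartments or
cell types, optionally with replicate columns).  The module scores how
specific each protein is to one context (signed -log10 p from a
least-squares contrast of that context against the rest), extracts the
top-k signature proteins per context, and asks whether signature proteins
are shifted in lesional skin: by comparing their mean log fold change to a
sampling null of random protein draws, by correlating a specificity ratio
with fold changes, and by the cumulative-overlap curve of signature members
along a fold-change ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .stats_core import spearman, wilcoxon_rank_sum

__all__ = [
    "AtlasMatrix",
    "SignatureSet",
    "EnrichmentResult",
    "compartment_signed_p",
    "top_signature_proteins",
    "sampling_null_test",
    "specificity_ratio_correlation",
    "cumulative_overlap_curve",
]

_P_FLOOR = 1e-300


@dataclass
class AtlasMatrix:
    """Proteins x contexts abundance matrix; replicate columns allowed.

    Replicates are encoded in the column names as ``context__rep`` (double
    underscore); a column without the suffix is a single-replicate context.
    """

    abundance: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.abundance.to_numpy() < 0).any():
            raise ValueError("atlas abundances must be non-negative")
        if len(self.contexts) < 2:
            raise ValueError("an atlas needs at least two contexts")

    @property
    def protein_ids(self) -> pd.Index:
        return self.abundance.index

    @property
    def column_contexts(self) -> pd.Series:
        return pd.Series(
            [c.split("__")[0] for c in self.abundance.columns],
            index=self.abundance.columns,
        )

    @property
    def contexts(self) -> list:
        seen: dict = {}
        for c in self.column_contexts:
            seen.setdefault(c, None)
        return list(seen)

    def context_columns(self, context: str) -> list:
        cols = [c for c in self.abundance.columns if c.split("__")[0] == context]
        if not cols:
            raise ValueError(f"context {context!r} not in atlas")
        return cols

    @classmethod
    def from_tsv(cls, path) -> "AtlasMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.abundance.to_csv(path, sep="\t", index_label="protein_id")


@dataclass
class SignatureSet:
    """Top-k proteins most specific to one atlas context."""

    context: str
    protein_ids: list
    specificity_scores: pd.Series


@dataclass
class EnrichmentResult:
    """Enrichment statistic and p-value, with the null summary when simulated."""

    statistic: float
    p_value: float
    null_summary: dict | None = None
    seed: int | None = None
    extras: dict = field(default_factory=dict)


def compartment_signed_p(atlas: AtlasMatrix, context: str) -> pd.Series:
    """Signed -log10 p specificity score of each protein for one context.

    With replicate columns the score comes from a least-squares contrast of
    the context columns against all others (equivalently a pooled-variance
    two-group t-test on the context indicator): score = -log10(p) x
    sign(context effect).  A context represented by a single column falls
    back to a rank-based score (context rank minus mean elsewhere rank,
    scaled to the number of columns); the method used is recorded in
    ``Series.attrs['method']``.
    """
    cols = atlas.context_columns(context)
    other = [c for c in atlas.abundance.columns if c not in cols]
    Y = atlas.abundance.to_numpy(dtype=float)
    in_idx = [atlas.abundance.columns.get_loc(c) for c in cols]
    out_idx = [atlas.abundance.columns.get_loc(c) for c in other]
    if len(cols) >= 2 and len(other) >= 2:
        a = Y[:, in_idx]
        b = Y[:, out_idx]
        n1, n2 = a.shape[1], b.shape[1]
        diff = a.mean(axis=1) - b.mean(axis=1)
        ss = (a.var(axis=1, ddof=1) * (n1 - 1) + b.var(axis=1, ddof=1) * (n2 - 1))
        dof = n1 + n2 - 2
        pooled = ss / dof
        se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, diff / se, 0.0)
        p = np.clip(2.0 * _sps.t.sf(np.abs(t), df=dof), _P_FLOOR, 1.0)
        # perfect separation: zero pooled variance with a nonzero contrast
        p = np.where((se == 0) & (diff != 0), _P_FLOOR, p)
        scores = pd.Series(
            -np.log10(p) * np.sign(diff), index=atlas.protein_ids, name="score"
        )
        scores.attrs["method"] = "regression"
        return scores
    ranks = _sps.rankdata(Y, axis=1)
    in_rank = ranks[:, in_idx].mean(axis=1)
    out_rank = ranks[:, out_idx].mean(axis=1)
    scores = pd.Series(
        (in_rank - out_rank) / Y.shape[1], index=atlas.protein_ids, name="score"
    )
    scores.attrs["method"] = "rank"
    return scores


def top_signature_proteins(
    scores: pd.Series, context: str = "", k: int = 12
) -> SignatureSet:
    """The k proteins with the highest signed specificity score.

    Ties are broken by lexical protein id so the signature is deterministic
    across runs; when fewer than k proteins are scored, all of them are
    returned with a warning.
    """
    if len(scores) < k:
        warnings.warn(
            f"only {len(scores)} proteins scored; returning all of them",
            stacklevel=2,
        )
        k = len(scores)
    order = sorted(scores.index, key=lambda pid: (-scores[pid], pid))
    chosen = order[:k]
    return SignatureSet(
        context=context, protein_ids=chosen, specificity_scores=scores.loc[chosen]
    )


def sampling_null_test(
    fold_changes: pd.Series,
    signature: SignatureSet,
    n_trials: int = 10_000,
    seed: int = 0,
) -> EnrichmentResult:
    """Compare the mean log FC of a signature with a random-sampling null.

    The observed statistic is the mean log2 fold change of the signature
    proteins.  The null distribution draws ``len(signature)`` proteins
    without replacement from the fold-change universe ``n_trials`` times;
    the two-sided p-value is (1 + #{|null - null_mean| >= |obs -
    null_mean|}) / (n_trials + 1).
    """
    universe = fold_changes.index
    missing = [p for p in signature.protein_ids if p not in universe]
    if missing:
        raise ValueError(
            f"signature members outside the fold-change universe: {missing}"
        )
    members = list(signature.protein_ids)
    if len(members) == 0:
        raise ValueError("signature is empty")
    log_fc = np.log2(fold_changes.to_numpy(dtype=float))
    obs = float(np.log2(fold_changes.loc[members]).mean())
    k = len(members)
    if k == len(universe):
        return EnrichmentResult(
            statistic=obs,
            p_value=1.0,
            null_summary={"mean": obs, "sd": 0.0, "n_trials": n_trials},
            seed=seed,
        )
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_trials)
    n_univ = len(universe)
    for t in range(n_trials):
        idx = rng.choice(n_univ, size=k, replace=False)
        nulls[t] = log_fc[idx].mean()
    center = nulls.mean()
    p = (1.0 + np.sum(np.abs(nulls - center) >= abs(obs - center))) / (n_trials + 1.0)
    return EnrichmentResult(
        statistic=obs,
        p_value=float(p),
        null_summary={"mean": float(center), "sd": float(nulls.std(ddof=1)),
                      "n_trials": n_trials},
        seed=seed,
    )


def specificity_ratio_correlation(
    atlas: AtlasMatrix,
    context: str,
    fold_changes: pd.Series,
    pseudocount: float = 0.5,
) -> EnrichmentResult:
    """Correlate context-specificity ratios with PP/PN fold changes.

    Specificity of a protein for the context is (mean abundance in context
    + c) / (mean abundance elsewhere + c) with pseudocount c.  The
    statistic is the Spearman correlation between log specificity and log
    fold change over the overlapping proteins; the p-value uses the
    t-approximation for the rank correlation.
    """
    cols = atlas.context_columns(context)
    other = [c for c in atlas.abundance.columns if c not in cols]
    overlap = atlas.protein_ids.intersection(fold_changes.index)
    if len(overlap) < 3:
        raise ValueError("too little overlap between atlas and fold-change universe")
    sub = atlas.abundance.loc[overlap]
    ratio = (sub[cols].mean(axis=1) + pseudocount) / (
        sub[other].mean(axis=1) + pseudocount
    )
    lfc = np.log2(fold_changes.loc[overlap].to_numpy(dtype=float))
    r = spearman(np.log2(ratio.to_numpy()), lfc)
    n = len(overlap)
    t = r * np.sqrt((n - 2) / max(1.0 - r * r, 1e-12))
    p = float(np.clip(2.0 * _sps.t.sf(abs(t), df=n - 2), _P_FLOOR, 1.0))
    return EnrichmentResult(statistic=r, p_value=p, extras={"n": n})


def cumulative_overlap_curve(
    ranked_ids,
    signature_ids,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[np.ndarray, EnrichmentResult]:
    """Cumulative overlap of a signature along a ranked list, with area statistic.

    The curve is C(i) = number of signature members among the top i list
    entries.  The area statistic A = sum_i [C(i) - i*k/N] / N compares the
    curve to the diagonal expected under uniform placement; its maximum is
    k(N-k)/(2N) (all members on top) and it is antisymmetric under list
    reversal.  The p-value comes from permuting member positions uniformly
    (two-sided, +1 smoothed); a Wilcoxon rank-sum p of member vs non-member
    positions is reported alongside.
    """
    ranked = list(ranked_ids)
    n = len(ranked)
    members = set(signature_ids)
    if not members <= set(ranked):
        missing = sorted(members - set(ranked))
        raise ValueError(f"signature members absent from the ranked list: {missing}")
    ind = np.array([1.0 if g in members else 0.0 for g in ranked])
    k = int(ind.sum())
    curve = np.cumsum(ind)
    i = np.arange(1, n + 1)
    area = float(np.sum(curve - i * k / n) / n)

    # under permutation only the member positions matter:
    # sum_i C(i) = sum over member positions s of (n - s + 1)
    rng = np.random.default_rng(seed)
    diag = k * (n + 1) / 2.0
    nulls = np.empty(n_perm)
    for t in range(n_perm):
        pos = rng.choice(n, size=k, replace=False) + 1
        nulls[t] = (np.sum(n - pos + 1) - diag) / n
    p_perm = (1.0 + np.sum(np.abs(nulls) >= abs(area))) / (n_perm + 1.0)

    pos_obs = i[ind == 1]
    pos_rest = i[ind == 0]
    if pos_rest.size:
        _, p_wilcox = wilcoxon_rank_sum(pos_obs, pos_rest)
    else:
        p_wilcox = 1.0
    result = EnrichmentResult(
        statistic=area,
        p_value=float(p_perm),
        null_summary={"mean": float(nulls.mean()), "sd": float(nulls.std(ddof=1)),
                      "n_trials": n_perm},
        seed=seed,
        extras={"wilcoxon_p": float(p_wilcox), "k": k, "n": n},
    )
    return curve, result
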