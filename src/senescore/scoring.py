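"""Composite senescence scores from z-scored log2-CPM expression.

A composite score for a gene set S is the per-sample mean of the z-score
standardized log2-CPM values of the genes in S:

    score_i = (1/G) * sum_{g in S} ( x_gi - mean_g ) / sd_g

with mean/sd taken over the scored samples and the n-1 (sample) SD
denominator.  Higher scores indicate a higher senescence signal.  The
summary score averages over the deduplicated union of the CSP, SIP and SRP
gene lists, not over the three sub-scores.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .containers import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    ScoreTable,
    StandardizedExpression,
)

__all__ = [
    "zscore_genes",
    "build_summary_set",
    "composite_score",
    "overlap_report",
    "score_all",
    "CompositeScorer",
    "ScoringError",
]


class ScoringError(ValueError):
    """Raised when a score cannot be computed as configured."""


def zscore_genes(expr: ExpressionMatrix) -> StandardizedExpression:
    """Center and scale each gene across samples (SD denominator n-1).

    Genes with zero variance are excluded (with reason recorded) rather than
    divided by zero.

    Raises
    ------
    ScoringError
        If fewer than 2 samples are present or every gene is constant.
    """
    if expr.values.shape[1] < 2:
        raise ScoringError("z-scoring requires at least 2 samples")
    arr = expr.values.to_numpy(dtype=float)
    mean = arr.mean(axis=1)
    sd = arr.std(axis=1, ddof=1)
    keep = sd > 0
    excluded = {str(g): "zero variance" for g in expr.gene_ids[~keep]}
    if not keep.any():
        raise ScoringError("all genes have zero variance; nothing to score")
    z = (arr[keep] - mean[keep, None]) / sd[keep, None]
    values = pd.DataFrame(z, index=expr.gene_ids[keep], columns=expr.sample_ids)
    return StandardizedExpression(values=values, excluded_genes=excluded)


def build_summary_set(csp: GeneSet, sip: GeneSet, srp: GeneSet, name: str = "Summary") -> GeneSet:
    """Deduplicated union of the three pathway lists (each gene used once)."""
    for gs, role in ((csp, "CSP"), (sip, "SIP"), (srp, "SRP")):
        if gs.role != role:
            raise ScoringError(f"expected a set with role {role}, got {gs.role!r} ({gs.name})")
    seen: set[str] = set()
    members = []
    for gs in (csp, sip, srp):
        for g in gs.members:
            if g not in seen:
                seen.add(g)
                members.append(g)
    return GeneSet(name=name, members=tuple(members), role="summary")


def composite_score(
    std: StandardizedExpression,
    gene_set: GeneSet,
    missing_policy: str = "error",
) -> tuple[pd.Series, int]:
    """Mean of member z-scores per sample.

    Parameters
    ----------
    std : StandardizedExpression
    gene_set : GeneSet
    missing_policy : {"error", "drop"}
        Under ``"error"`` every member must be present and retained; under
        ``"drop"`` absent/excluded members are skipped and the number of
        genes actually averaged is reported.

    Returns
    -------
    (scores, g_used) : (pandas.Series, int)
    """
    if missing_policy not in ("error", "drop"):
        raise ScoringError(f"unknown missing_policy {missing_policy!r}")
    available = set(map(str, std.gene_ids))
    present = [g for g in gene_set.members if g in available]
    missing = [g for g in gene_set.members if g not in available]
    if missing and missing_policy == "error":
        raise ScoringError(
            f"gene set {gene_set.name!r}: {len(missing)} member(s) missing or "
            f"excluded: {missing[:10]}"
        )
    if not present:
        raise ScoringError(f"gene set {gene_set.name!r}: no members available to average")
    scores = std.values.loc[present].mean(axis=0)
    scores.name = gene_set.name
    return scores, len(present)


def overlap_report(collection: GeneSetCollection) -> pd.DataFrame:
    """Symmetric pairwise intersection counts (diagonal = set sizes)."""
    if len(collection) < 2:
        raise ScoringError("overlap report needs at least 2 sets")
    return collection.overlap_table()


def score_all(
    expr: ExpressionMatrix,
    collection: GeneSetCollection,
    missing_policy: str = "error",
) -> ScoreTable:
    """Z-score once, then compute every configured composite score."""
    std = zscore_genes(expr)
    cols = {}
    g_used = {}
    for gs in collection:
        scores, g = composite_score(std, gs, missing_policy=missing_policy)
        cols[gs.name] = scores
        g_used[gs.name] = g
    values = pd.DataFrame(cols)
    values.index.name = "sample_id"
    return ScoreTable(values=values, g_used=g_used)


class CompositeScorer(TransformerMixin, BaseEstimator):
    """sklearn transformer: log2-CPM expression -> composite score columns.

    Operates in sklearn orientation (rows are samples, columns are genes;
    a DataFrame input must carry gene ids as column names).  ``fit`` learns
    each gene's mean and SD (ddof=1) from the training samples and drops
    zero-variance genes; ``transform`` z-scores against those frozen
    parameters and averages over each configured gene set.

    Parameters
    ----------
    gene_sets : GeneSetCollection or mapping of name -> iterable of gene ids
    missing_policy : {"error", "drop"}, default "error"
    """

    def __init__(self, gene_sets=None, missing_policy: str = "error"):
        self.gene_sets = gene_sets
        self.missing_policy = missing_policy

    def _collection(self) -> GeneSetCollection:
        if isinstance(self.gene_sets, GeneSetCollection):
            return self.gene_sets
        if isinstance(self.gene_sets, dict):
            sets = {
                name: members if isinstance(members, GeneSet)
                else GeneSet(name=name, members=tuple(members))
                for name, members in self.gene_sets.items()
            }
            return GeneSetCollection(sets=sets)
        raise ScoringError("gene_sets must be a GeneSetCollection or a dict")

    def fit(self, X, y=None):
        if not isinstance(X, pd.DataFrame):
            raise ScoringError("CompositeScorer requires a DataFrame with gene ids as columns")
        if X.shape[0] < 2:
            raise ScoringError("z-scoring requires at least 2 samples")
        collection = self._collection()
        arr = X.to_numpy(dtype=float)
        mean = arr.mean(axis=0)
        sd = arr.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.any():
            raise ScoringError("all genes have zero variance; nothing to score")
        self.gene_ids_ = np.asarray(X.columns[keep], dtype=object)
        self.gene_means_ = mean[keep]
        self.gene_sds_ = sd[keep]
        self.excluded_genes_ = {str(g): "zero variance" for g in X.columns[~keep]}
        retained = set(map(str, self.gene_ids_))
        self.members_: dict[str, list[str]] = {}
        self.g_used_: dict[str, int] = {}
        for gs in collection:
            present = [g for g in gs.members if g in retained]
            missing = [g for g in gs.members if g not in retained]
            if missing and self.missing_policy == "error":
                raise ScoringError(
                    f"gene set {gs.name!r}: {len(missing)} member(s) missing or "
                    f"excluded: {missing[:10]}"
                )
            if not present:
                raise ScoringError(f"gene set {gs.name!r}: no members available")
            self.members_[gs.name] = present
            self.g_used_[gs.name] = len(present)
        self._pos = {str(g): i for i, g in enumerate(self.gene_ids_)}
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns)
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "gene_means_")
        if not isinstance(X, pd.DataFrame):
            raise ScoringError("CompositeScorer requires a DataFrame with gene ids as columns")
        sub = X.loc[:, self.gene_ids_].to_numpy(dtype=float)
        z = (sub - self.gene_means_[None, :]) / self.gene_sds_[None, :]
        out = {}
        for name, members in self.members_.items():
            idx = [self._pos[g] for g in members]
            out[name] = z[:, idx].mean(axis=1)
        return pd.DataFrame(out, index=X.index)

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "gene_means_")
        return np.asarray(list(self.members_), dtype=object)
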