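"""Core in-memory containers for the scoring pipeline.

Matrices follow the bulk RNA-seq convention: genes are rows, samples are
columns.  The sklearn-facing estimators in :mod:`senescore.normalization`
and :mod:`senescore.scoring` use the transposed (samples x features)
orientation; conversion happens at that boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """An input violates a structural invariant."""


@dataclass
class CountMatrix:
    """Raw integer read counts, genes x samples.

    Parameters
    ----------
    values : pandas.DataFrame
        Non-negative integer counts with unique gene ids as the index and
        unique sample ids as the columns.  At least 2 genes and 2 samples.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] < 2 or v.shape[1] < 2:
            raise ValidationError(
                f"count matrix must be at least 2 genes x 2 samples, got {v.shape}"
            )
        if v.index.duplicated().any():
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if v.columns.duplicated().any():
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.any(arr < 0):
            g, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at gene {v.index[g]!r}, sample {v.columns[s]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            g, s = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise ValidationError(
                f"non-integer count at gene {v.index[g]!r}, sample {v.columns[s]!r}"
            )
        self.values = v.astype(np.int64)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def lib_sizes(self) -> pd.Series:
        """Per-sample column sums (raw library sizes)."""
        return self.values.sum(axis=0)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class NormFactors:
    """Per-sample RLE scale factors with geometric mean 1.

    ``effective_lib_sizes = lib_sizes * factors`` are the library sizes that
    the CPM computation divides by.
    """

    factors: pd.Series
    lib_sizes: pd.Series

    def __post_init__(self) -> None:
        f = np.asarray(self.factors, dtype=float)
        if not np.all(np.isfinite(f)) or np.any(f <= 0):
            raise ValidationError("norm factors must be finite and positive")
        gm = np.exp(np.mean(np.log(f)))
        if abs(gm - 1.0) > 1e-10:
            raise ValidationError(f"norm factors must have geometric mean 1, got {gm}")

    @property
    def effective_lib_sizes(self) -> pd.Series:
        return self.lib_sizes * self.factors


@dataclass
class ExpressionMatrix:
    """Normalized log2 counts-per-million, genes x samples."""

    values: pd.DataFrame
    prior_count: float = 2.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValidationError("expression values must all be finite")
        if self.prior_count <= 0:
            raise ValidationError("prior_count must be positive")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class StandardizedExpression:
    """Per-gene z-scores across samples (genes x samples).

    ``excluded_genes`` maps gene id -> reason for genes dropped before
    scoring (currently only "zero variance").  SD uses the n-1 denominator.
    """

    values: pd.DataFrame
    excluded_genes: dict[str, str] = field(default_factory=dict)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


VALID_ROLES = ("CSP", "SIP", "SRP", "summary", "SenMayo", "custom")


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered, duplicate-free gene list."""

    name: str
    members: tuple[str, ...]
    role: str = "custom"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} is empty")
        stripped = tuple(str(m).strip() for m in self.members)
        if len(set(stripped)) != len(stripped):
            seen: set[str] = set()
            dups = []
            for m in stripped:
                if m in seen:
                    dups.append(m)
                seen.add(m)
            raise ValidationError(
                f"duplicate members in gene set {self.name!r}: {sorted(set(dups))[:5]}"
            )
        if self.role not in VALID_ROLES:
            raise ValidationError(f"unknown gene-set role {self.role!r}")
        object.__setattr__(self, "members", stripped)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.members)


@dataclass
class GeneSetCollection:
    """Named gene sets with overlap bookkeeping."""

    sets: dict[str, GeneSet]

    def __post_init__(self) -> None:
        for name, gs in self.sets.items():
            if name != gs.name:
                raise ValidationError(f"key {name!r} does not match set name {gs.name!r}")

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets.values())

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def overlap_table(self) -> pd.DataFrame:
        """Symmetric pairwise intersection counts; diagonal = set sizes."""
        names = self.names
        out = pd.DataFrame(0, index=names, columns=names, dtype=int)
        members = {n: set(self.sets[n].members) for n in names}
        for a in names:
            for b in names:
                out.loc[a, b] = len(members[a] & members[b])
        return out


@dataclass
class ScoreTable:
    """Per-sample composite scores, one column per score.

    ``g_used`` records, for each score, how many member genes were actually
    averaged (after exclusions under the ``drop`` policy).
    """

    values: pd.DataFrame
    g_used: dict[str, int] = field(default_factory=dict)

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def score_names(self) -> list[str]:
        return list(self.values.columns)
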