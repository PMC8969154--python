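"""Hepatic-style gene coexpression screen.

Pipeline: filter samples to the non-tumor cohort, build an all-vs-all
correlation matrix, calibrate an empirical null by resampling "virtual"
lists of coefficients from the matrix, summarize the top correlates of a
query gene against the mean +/- k*SD bounds of that null, and test candidate
gene lists for gene-set over-representation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateNullWarning,
    EmptyCohortError,
    InsufficientDataError,
    InvalidConfigError,
    TruncatedResultWarning,
    UnknownGeneError,
    ZeroVarianceWarning,
)
from .omics_stats import bh_adjust

__all__ = [
    "ExpressionMatrix",
    "CorrelationMatrix",
    "CorrelationNull",
    "QueryResult",
    "EnrichmentResult",
    "filter_nontumor",
    "correlation_matrix",
    "resample_null",
    "query_top",
    "enrich",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-sample tumor flags.

    ``values`` is a DataFrame indexed by gene id with sample ids as columns;
    ``sample_meta`` maps every sample id to a boolean ``tumor`` flag.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame  # indexed by sample_id, column "tumor" (bool)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise InvalidConfigError(f"duplicate gene ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise InvalidConfigError(f"duplicate sample ids: {dups}")
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise InvalidConfigError("expression values must all be finite")
        missing = [s for s in self.values.columns if s not in self.sample_meta.index]
        if missing:
            raise InvalidConfigError(f"samples without metadata: {missing}")
        if "tumor" not in self.sample_meta.columns:
            raise InvalidConfigError("sample metadata must carry a 'tumor' column")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class CorrelationMatrix:
    """Symmetric gene-gene correlation matrix with unit diagonal."""

    gene_ids: pd.Index
    r: np.ndarray
    method: str = "pearson"

    def off_diagonal(self) -> np.ndarray:
        """Upper-triangle off-diagonal coefficients (each pair once)."""
        iu = np.triu_indices(self.r.shape[0], k=1)
        return self.r[iu]

    def loc(self, gene: str) -> int:
        idx = self.gene_ids.get_indexer([gene])
        if idx[0] < 0:
            raise UnknownGeneError(gene)
        return int(idx[0])


@dataclass
class CorrelationNull:
    """Empirical null built from B resampled virtual lists of coefficients."""

    B: int
    list_size: int
    k: float
    mean: float
    sd: float
    lower: float
    upper: float
    seed: int
    stat: str = "r"  # {"r", "r2"}: which statistic was pooled


@dataclass
class QueryResult:
    """Top correlates of one query gene, flagged against the null bounds."""

    query_gene: str
    top_n: int
    ranked: list[tuple[str, float, float, bool]]  # (gene_id, r, r2, beyond)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.ranked, columns=["gene_id", "r", "r2", "beyond_threshold"]
        )


@dataclass
class EnrichmentResult:
    set_name: str
    overlap: int
    set_size: int
    list_size: int
    universe_size: int
    p: float
    q: float = field(default=float("nan"))


def filter_nontumor(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Retain only samples whose metadata flags them as non-tumor."""
    keep = [s for s in expr.sample_ids if not bool(expr.sample_meta.loc[s, "tumor"])]
    if not keep:
        raise EmptyCohortError("no non-tumor samples remain after filtering")
    return ExpressionMatrix(
        values=expr.values[keep],
        sample_meta=expr.sample_meta.loc[keep],
    )


def correlation_matrix(
    expr: ExpressionMatrix, method: str = "pearson"
) -> CorrelationMatrix:
    """All-vs-all gene correlation (product-moment or rank-based).

    Zero-variance genes cannot be correlated and are dropped with a warning
    rather than raising: real matrices contain flat probes.
    """
    if method not in ("pearson", "spearman"):
        raise InvalidConfigError(f"unknown correlation method: {method!r}")
    if expr.n_samples < 3:
        raise InsufficientDataError(
            f"need >=3 samples for correlation, got {expr.n_samples}"
        )
    mat = expr.values.to_numpy(dtype=float)
    sd = mat.std(axis=1)
    keep = sd > 0
    if not np.all(keep):
        dropped = expr.gene_ids[~keep].tolist()
        warnings.warn(
            f"dropping {len(dropped)} zero-variance gene(s)", ZeroVarianceWarning
        )
        mat = mat[keep]
    gene_ids = expr.gene_ids[keep]
    if method == "spearman":
        mat = np.apply_along_axis(stats.rankdata, 1, mat)
    r = np.corrcoef(mat)
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(gene_ids=gene_ids, r=r, method=method)


def resample_null(
    corr: CorrelationMatrix,
    B: int = 1000,
    list_size: int = 20,
    seed: int = 0,
    k: float = 2.0,
    stat: str = "r",
) -> CorrelationNull:
    """Build the resampled null for the +/- k*SD significance threshold.

    Draws ``B`` virtual lists of ``list_size`` coefficients from the
    off-diagonal upper triangle (without replacement within a list, with
    replacement across lists), pools all B*list_size draws, and sets bounds
    at ``mean -/+ k*sd`` of the pool.

    ``stat="r"`` pools signed coefficients (default — a two-sided threshold
    needs a signed quantity); ``stat="r2"`` pools squared coefficients,
    preserving a literal r^2 reading.
    """
    if stat not in ("r", "r2"):
        raise InvalidConfigError(f"stat must be 'r' or 'r2', got {stat!r}")
    pool = corr.off_diagonal()
    if stat == "r2":
        pool = pool**2
    if list_size > pool.size:
        raise InvalidConfigError(
            f"list_size={list_size} exceeds {pool.size} off-diagonal entries"
        )
    if B < 1:
        raise InvalidConfigError("B must be >= 1")
    rng = np.random.default_rng(seed)
    draws = np.empty((B, list_size))
    for b in range(B):
        # without replacement within a list; rejection sampling is far
        # cheaper than rng.choice(replace=False) on a pool of ~n^2/2 entries
        idx = rng.integers(0, pool.size, size=list_size)
        while np.unique(idx).size < list_size:
            idx = np.unique(idx)
            idx = np.concatenate(
                [idx, rng.integers(0, pool.size, size=list_size - idx.size)]
            )
        draws[b] = pool[idx]
    pooled = draws.ravel()
    mean = float(pooled.mean())
    sd = float(pooled.std(ddof=1))
    if sd == 0.0:
        warnings.warn(
            "resampled null has zero standard deviation; bounds are degenerate",
            DegenerateNullWarning,
        )
    return CorrelationNull(
        B=B,
        list_size=list_size,
        k=k,
        mean=mean,
        sd=sd,
        lower=mean - k * sd,
        upper=mean + k * sd,
        seed=seed,
        stat=stat,
    )


def query_top(
    corr: CorrelationMatrix,
    query: str,
    null: CorrelationNull,
    top_n: int = 20,
) -> QueryResult:
    """Rank the query gene's correlates by |r| and flag those beyond the null.

    Ties in |r| break lexicographically on gene id. The beyond-threshold flag
    compares the same statistic the null pooled (signed r, or r^2) against
    the null's lower/upper bounds.
    """
    qi = corr.loc(query)
    r_query = corr.r[qi].copy()
    order = [i for i in range(len(corr.gene_ids)) if i != qi]
    order.sort(key=lambda i: (-abs(r_query[i]), str(corr.gene_ids[i])))
    if top_n > len(order):
        warnings.warn(
            f"top_n={top_n} exceeds {len(order)} candidate genes; truncating",
            TruncatedResultWarning,
        )
        top_n = len(order)
    ranked = []
    for i in order[:top_n]:
        r = float(r_query[i])
        val = r * r if null.stat == "r2" else r
        beyond = bool(val < null.lower or val > null.upper)
        ranked.append((str(corr.gene_ids[i]), r, r * r, beyond))
    return QueryResult(query_gene=query, top_n=top_n, ranked=ranked)


def enrich(
    gene_list: set[str],
    gene_sets: dict[str, set[str]],
    universe: set[str],
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of each gene set in ``gene_list``.

    p is the upper tail P(X >= overlap) with the universe as sampling frame;
    q is Benjamini-Hochberg across the tested sets. Results sorted by p.
    """
    if not universe:
        raise InvalidConfigError("universe is empty")
    stray = gene_list - universe
    if stray:
        raise InvalidConfigError(f"gene_list members outside universe: {sorted(stray)[:5]}")
    M = len(universe)
    N = len(gene_list)
    results = []
    for name, members in gene_sets.items():
        members_in = members & universe
        K = len(members_in)
        k_obs = len(gene_list & members_in)
        # upper tail including the observed overlap: P(X >= k_obs)
        p = float(stats.hypergeom.sf(k_obs - 1, M, K, N))
        p = min(max(p, 0.0), 1.0)
        results.append(
            EnrichmentResult(
                set_name=name,
                overlap=k_obs,
                set_size=K,
                list_size=N,
                universe_size=M,
                p=p,
            )
        )
    if results:
        qs = bh_adjust([res.p for res in results])
        for res, q in zip(results, qs):
            res.q = float(q)
    results.sort(key=lambda res: (res.p, res.set_name))
    return results
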