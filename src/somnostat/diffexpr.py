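"""Differential expression: percentile-shift normalization, the dual
parametric / rank-product criterion, and fold-change ranking.

Matrices are log2-scale gene x sample tables with a group label per sample.
A gene is called differentially expressed when its BH-adjusted parametric p
falls below alpha and/or its rank-product percentage of false prediction
falls below the PFP threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import InputError

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_PFP = 0.015
DEFAULT_N_PERM = 100
DEFAULT_TOP_N = 200


@dataclass
class ExpressionMatrix:
    """log2 gene x sample expression values with per-sample group labels."""

    values: pd.DataFrame            # genes (index) x samples (columns)
    groups: pd.Series               # sample -> group label
    tissue: str = ""
    truth: pd.DataFrame | None = None  # planted DE labels, synthetic data only

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups)
        if list(self.groups.index) != list(self.values.columns):
            self.groups.index = self.values.columns
        if self.groups.isna().any():
            raise InputError("every sample needs a group label")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise InputError("expression values must be finite")

    def group_columns(self, label) -> list:
        return list(self.groups.index[self.groups == label])

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#group\t" + "\t".join(map(str, self.groups.to_numpy())) + "\n")
            self.values.to_csv(fh, sep="\t", index_label="gene")

    @classmethod
    def read_tsv(cls, path, tissue: str = "") -> "ExpressionMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[0] != "#group":
                raise InputError("expected a '#group' label line")
            df = pd.read_csv(fh, sep="\t", index_col="gene")
        groups = pd.Series(header[1:], index=df.columns)
        return cls(values=df, groups=groups, tissue=tissue)


def percentile_shift_normalize(matrix, percentile: float = 75.0):
    """Subtract each sample's given intensity percentile (log2 scale).

    After normalization every sample's chosen percentile is exactly zero.
    A linear-scale division variant is equivalent to this subtraction after
    log transform; the subtraction form is the one applied here.
    """
    if not 0 < percentile < 100:
        raise InputError("percentile must lie in (0, 100)")
    if isinstance(matrix, ExpressionMatrix):
        vals = percentile_shift_normalize(matrix.values, percentile)
        return ExpressionMatrix(values=vals, groups=matrix.groups,
                                tissue=matrix.tissue, truth=matrix.truth)
    if isinstance(matrix, pd.DataFrame):
        shift = matrix.quantile(percentile / 100.0, axis=0)
        return matrix.sub(shift, axis=1)
    arr = np.asarray(matrix, dtype=float)
    return arr - np.percentile(arr, percentile, axis=0, keepdims=True)


def _two_group_arrays(matrix: ExpressionMatrix):
    labels = list(dict.fromkeys(matrix.groups.to_numpy()))
    if len(labels) != 2:
        raise InputError(f"rank product needs exactly 2 groups, got {labels}")
    a = matrix.values[matrix.group_columns(labels[0])].to_numpy()
    b = matrix.values[matrix.group_columns(labels[1])].to_numpy()
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise InputError("every group needs >= 2 samples")
    return labels, a, b


def _rank_product_from_ranks(log_ranks: np.ndarray) -> np.ndarray:
    # geometric mean of ranks across comparisons, computed in log space
    return np.exp(log_ranks.mean(axis=1))


def _pairwise_rp(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Up/down rank products over all cross-group sample pairs."""
    n_genes = a.shape[0]
    fc = (a[:, :, None] - b[:, None, :]).reshape(n_genes, -1)
    rp_up = _rank_product_from_ranks(np.log(sps.rankdata(-fc, axis=0)))
    rp_down = _rank_product_from_ranks(np.log(sps.rankdata(fc, axis=0)))
    return rp_up, rp_down


def rank_product(matrix: ExpressionMatrix, n_perm: int = DEFAULT_N_PERM,
                 seed: int = 0, null_model: str = "permute_samples") -> pd.DataFrame:
    """Two-group rank product with permutation-based PFP, both directions.

    For every cross-group sample pair, genes are ranked by the pairwise
    fold change (rank 1 = strongest change in the tested direction); the
    rank product is the geometric mean of those ranks.  For each gene
    PFP = (expected false positives at its RP) / (its position in the
    observed RP ordering), with the null RP distribution pooled over
    ``n_perm`` permutations.

    ``null_model='permute_samples'`` (default) shuffles each gene's values
    across samples and recomputes the rank products, preserving the strong
    dependence between comparisons that share samples.  The textbook
    ``'independent_ranks'`` null draws an independent uniform rank vector
    per comparison; it is only calibrated when comparisons are independent
    (and is what a brute-force enumeration of rank assignments reproduces).
    """
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    labels, a, b = _two_group_arrays(matrix)
    n_genes, n1 = a.shape
    n_comp = n1 * b.shape[1]
    rp_up, rp_down = _pairwise_rp(a, b)

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, n_genes))
    if null_model == "permute_samples":
        pooled = np.concatenate([a, b], axis=1)
        for p in range(n_perm):
            perm = rng.permuted(pooled, axis=1)
            null[p], _ = _pairwise_rp(perm[:, :n1], perm[:, n1:])
    elif null_model == "independent_ranks":
        base = np.log(np.arange(1, n_genes + 1, dtype=float))
        for p in range(n_perm):
            acc = np.zeros(n_genes)
            for _ in range(n_comp):
                acc += base[rng.permutation(n_genes)]
            null[p] = np.exp(acc / n_comp)
    else:
        raise InputError(f"unknown null_model {null_model!r}")
    null_sorted = np.sort(null.ravel())

    def pfp(rp: np.ndarray) -> np.ndarray:
        exp_fp = np.searchsorted(null_sorted, rp, side="right") / n_perm
        pos = sps.rankdata(rp, method="max")  # observed genes at least as extreme
        return exp_fp / pos

    return pd.DataFrame(
        {
            "rp_up": rp_up,
            "rp_down": rp_down,
            "pfp_up": pfp(rp_up),
            "pfp_down": pfp(rp_down),
        },
        index=matrix.values.index,
    )


@dataclass
class DESummary:
    contrast: tuple
    n_de: int
    n_up: int
    n_down: int


def classify_de(
    matrix: ExpressionMatrix,
    alpha: float = DEFAULT_ALPHA,
    pfp_threshold: float = DEFAULT_PFP,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    equal_var: bool = True,
) -> tuple[pd.DataFrame, DESummary]:
    """Dual-criterion differential-expression call on a normalized matrix.

    Two groups are compared with an unpaired t test (pooled variance by
    default, Welch with ``equal_var=False``); more than two with one-way
    ANOVA (rank-product columns are then absent).  Raw p values get a
    Benjamini-Hochberg correction across genes.  A gene is DE when
    BH p < alpha and/or (two groups) PFP < pfp_threshold; direction follows
    the sign of the group-mean difference.
    """
    labels = list(dict.fromkeys(matrix.groups.to_numpy()))
    if len(labels) < 2:
        raise InputError("need >= 2 groups")
    arrays = [matrix.values[matrix.group_columns(l)].to_numpy() for l in labels]
    if len(labels) == 2:
        a, b = arrays
        with np.errstate(divide="ignore", invalid="ignore"):
            t, p = sps.ttest_ind(a, b, axis=1, equal_var=equal_var)
        log2fc = a.mean(axis=1) - b.mean(axis=1)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            _, p = sps.f_oneway(*arrays, axis=1)
        log2fc = arrays[0].mean(axis=1) - arrays[-1].mean(axis=1)
    # degenerate within-group variance -> uninformative parametric p;
    # the rank-product route still applies
    p = np.where(np.isfinite(p), p, 1.0)
    adj_p = multipletests(p, method="fdr_bh")[1]
    res = pd.DataFrame(
        {"log2fc": log2fc, "p": p, "adj_p": adj_p}, index=matrix.values.index
    )
    if len(labels) == 2:
        rp = rank_product(matrix, n_perm=n_perm, seed=seed)
        res = res.join(rp)
        pfp_hit = (rp["pfp_up"] < pfp_threshold) | (rp["pfp_down"] < pfp_threshold)
    else:
        pfp_hit = pd.Series(False, index=res.index)
    res["de"] = (res["adj_p"] < alpha) | pfp_hit
    res["direction"] = np.where(res["log2fc"] >= 0, "up", "down")
    n_up = int((res["de"] & (res["direction"] == "up")).sum())
    n_down = int((res["de"] & (res["direction"] == "down")).sum())
    summary = DESummary(contrast=tuple(labels), n_de=n_up + n_down,
                        n_up=n_up, n_down=n_down)
    return res, summary


def fold_change_ranking(results: pd.DataFrame, top_n: int = DEFAULT_TOP_N) -> pd.DataFrame:
    """DE genes ranked by |log2 fold change|, ties by adjusted p then gene id."""
    de = results[results["de"]].copy()
    if len(de) < top_n:
        log.info("only %d DE genes available for a top-%d ranking", len(de), top_n)
    de["abs_fc"] = de["log2fc"].abs()
    de = de.reset_index(names="gene").sort_values(
        by=["abs_fc", "adj_p", "gene"], ascending=[False, True, True],
        kind="stable",
    )
    return de.head(top_n).set_index("gene")
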