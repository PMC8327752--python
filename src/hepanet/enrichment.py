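"""Gene set enrichment: two-class GSEA, ssGSEA scoring, and immune summaries.

The two-class GSEA statistic is the weighted Kolmogorov-Smirnov running sum:
walking down the ranked list, set members increment the sum by
|metric|^w / (sum of |metric|^w over members) and non-members decrement it by
1/(n - m); the enrichment score (ES) is the signed maximum deviation.
Significance comes from phenotype-label permutation (gene-set permutation as
a small-sample fallback), NES normalizes by the mean |null ES| of the same
sign, and q-values are Benjamini-Hochberg across sets.

ssGSEA scores one sample at a time from within-sample expression ranks with
a rank^alpha weighted ECDF difference, so scores are invariant to any
strictly monotone per-sample transformation of expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix, GeneSet
from .ppi_hub import adjust_pvalues
from .clinical import cox_fit, dichotomize_expression, logrank_test

__all__ = [
    "RankedList",
    "EnrichmentResult",
    "rank_genes",
    "gsea_es",
    "gsea_permutation",
    "ssgsea_scores",
    "immune_correlation",
    "immune_survival_association",
]


@dataclass
class RankedList:
    """Genes ordered by a two-class ranking metric, descending."""

    genes: list[str]
    metric: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != len(set(self.genes)):
            raise ValueError("ranked genes must be unique")
        if np.any(np.diff(self.metric) > 1e-12):
            raise ValueError("metric must be in descending order")


@dataclass
class EnrichmentResult:
    name: str
    es: float
    nes: float
    p: float
    q: float
    leading_edge: list[str]
    size: int


def _metric_values(X: np.ndarray, mask1: np.ndarray, metric: str) -> np.ndarray:
    """Two-class metric per gene, aligned to the rows of X."""
    x1, x2 = X[:, mask1], X[:, ~mask1]
    mu1, mu2 = x1.mean(axis=1), x2.mean(axis=1)
    if metric == "s2n":
        s1 = np.maximum.reduce(
            [x1.std(axis=1, ddof=1), 0.2 * np.abs(mu1), np.full_like(mu1, 1e-8)]
        )
        s2 = np.maximum.reduce(
            [x2.std(axis=1, ddof=1), 0.2 * np.abs(mu2), np.full_like(mu2, 1e-8)]
        )
        return (mu1 - mu2) / (s1 + s2)
    if metric == "t":
        return stats.ttest_ind(x1, x2, axis=1, equal_var=False).statistic
    if metric == "log2fc":
        return mu1 - mu2
    raise ValueError(f"unknown metric {metric!r}")


def rank_genes(
    expr: ExpressionMatrix,
    group_labels: np.ndarray,
    metric: str = "s2n",
) -> RankedList:
    """Rank genes by a two-class differential metric, descending.

    ``s2n`` is the signal-to-noise ratio (mu1 - mu2)/(s1 + s2) with each
    group SD floored at 0.2 |mu| (and a small absolute floor); ``t`` is the
    Welch t statistic; ``log2fc`` the mean difference of the (log-scale)
    input.  Each group needs >= 3 samples; group 1 is the first label
    encountered.
    """
    labels = np.asarray(group_labels)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError("need exactly two groups")
    m1 = labels == uniq[0]
    if m1.sum() < 3 or (~m1).sum() < 3:
        raise ValueError("each group needs at least 3 samples")
    vals = _metric_values(expr.values, m1, metric)
    order = np.argsort(-vals, kind="stable")
    return RankedList([expr.gene_ids[i] for i in order], vals[order])


def _es_from_order(metric: np.ndarray, in_set: np.ndarray, w: float) -> tuple[float, int]:
    """ES and extremum position for one ranked list (boolean membership mask)."""
    n = len(metric)
    m = int(in_set.sum())
    if m == 0 or m == n:
        raise ValueError("gene set must hit a strict subset of the ranked list")
    weights = np.abs(metric) ** w if w != 0 else np.ones(n)
    hit_total = weights[in_set].sum()
    if hit_total == 0:
        weights = np.ones(n)
        hit_total = float(m)
    step = np.where(in_set, weights / hit_total, -1.0 / (n - m))
    running = np.cumsum(step)
    pos = int(np.argmax(np.abs(running)))
    return float(running[pos]), pos


def gsea_es(ranked: RankedList, gene_set: GeneSet, weight_exponent: float = 1.0) -> tuple[float, int]:
    """Weighted KS enrichment score for one gene set on one ranked list."""
    members = set(gene_set.genes)
    in_set = np.fromiter(
        (g in members for g in ranked.genes), dtype=bool, count=len(ranked.genes)
    )
    if not in_set.any():
        raise ValueError(f"gene set {gene_set.name!r} has no overlap with the ranked list")
    return _es_from_order(np.asarray(ranked.metric, dtype=float), in_set, weight_exponent)


def gsea_permutation(
    expr: ExpressionMatrix,
    group_labels: np.ndarray,
    gene_sets: list[GeneSet],
    n_perm: int = 1000,
    seed: int = 0,
    metric: str = "s2n",
    weight_exponent: float = 1.0,
    min_group_for_phenotype: int = 7,
) -> tuple[pd.DataFrame, str]:
    """GSEA with permutation significance; deterministic given the seed.

    Phenotype labels are permuted when both groups have at least
    ``min_group_for_phenotype`` samples; otherwise the fall-back null
    permutes gene-set membership.  Nominal p is the fraction of same-sign
    null ES at least as extreme (+1 pseudo-count so p > 0), NES is ES over
    the mean |null ES| of the same sign, and q is Benjamini-Hochberg across
    sets.  Returns the result table and the permutation scheme used.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    labels = np.asarray(group_labels)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError("need exactly two groups")
    m1 = labels == uniq[0]
    if m1.sum() < 3 or (~m1).sum() < 3:
        raise ValueError("each group needs at least 3 samples")
    X = expr.values
    n_genes = X.shape[0]
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}

    masks: dict[str, np.ndarray] = {}
    for s in gene_sets:
        mask = np.zeros(n_genes, dtype=bool)
        for g in s.genes:
            i = gene_index.get(g)
            if i is not None:
                mask[i] = True
        if mask.any() and not mask.all():
            masks[s.name] = mask
    if not masks:
        raise ValueError("no gene set overlaps the expression matrix")

    scheme = "phenotype" if min(m1.sum(), (~m1).sum()) >= min_group_for_phenotype else "gene_set"

    vals = _metric_values(X, m1, metric)
    order = np.argsort(-vals, kind="stable")
    met = vals[order]
    obs = {name: _es_from_order(met, mask[order], weight_exponent) for name, mask in masks.items()}

    null_es = {name: np.empty(n_perm) for name in masks}
    if scheme == "phenotype":
        for b in range(n_perm):
            pm1 = np.zeros(len(labels), dtype=bool)
            pm1[rng.choice(len(labels), size=int(m1.sum()), replace=False)] = True
            pv = _metric_values(X, pm1, metric)
            po = np.argsort(-pv, kind="stable")
            pmet = pv[po]
            for name, mask in masks.items():
                null_es[name][b] = _es_from_order(pmet, mask[po], weight_exponent)[0]
    else:
        for name, mask in masks.items():
            m = int(mask.sum())
            for b in range(n_perm):
                pm = np.zeros(n_genes, dtype=bool)
                pm[rng.choice(n_genes, size=m, replace=False)] = True
                null_es[name][b] = _es_from_order(met, pm[order], weight_exponent)[0]

    rows = []
    ordered_genes = [expr.gene_ids[i] for i in order]
    for s in gene_sets:
        if s.name not in masks:
            continue
        es, pos = obs[s.name]
        mask_ord = masks[s.name][order]
        null = null_es[s.name]
        same = null[null * np.sign(es) >= 0] if es != 0 else null
        if len(same):
            p = (1 + np.sum(np.abs(same) >= abs(es))) / (1 + len(same))
            denom = np.abs(same).mean()
            nes = es / denom if denom > 0 else np.nan
        else:
            p, nes = 1.0 / (1 + n_perm), np.nan
        if es >= 0:
            leading = [ordered_genes[i] for i in range(pos + 1) if mask_ord[i]]
        else:
            leading = [ordered_genes[i] for i in range(pos, n_genes) if mask_ord[i]]
        rows.append(
            {
                "name": s.name,
                "size": int(mask_ord.sum()),
                "es": es,
                "nes": nes,
                "p": float(p),
                "leading_edge": ",".join(leading),
            }
        )
    table = pd.DataFrame(rows)
    table["q"] = adjust_pvalues(list(table["p"]), method="bh")
    table = table.sort_values("p", kind="stable").reset_index(drop=True)
    return table[["name", "size", "es", "nes", "p", "q", "leading_edge"]], scheme


def ssgsea_scores(
    expr: ExpressionMatrix,
    gene_sets: list[GeneSet],
    alpha: float = 0.25,
    normalize: bool = True,
) -> tuple[pd.DataFrame, list[str]]:
    """Single-sample GSEA scores (set x sample), optionally range-normalized.

    Per sample, genes are ranked by expression (rank n for the highest);
    the raw score is the sum over list positions of the difference between
    the rank^alpha-weighted in-set ECDF and the unweighted out-of-set ECDF.
    With ``normalize`` the whole matrix is divided by its score range
    (max - min over all sets and samples).  Sets with fewer than 2 genes
    present in the matrix (or covering the whole matrix) are flagged and
    skipped.
    """
    X = expr.values
    n_genes, n_samp = X.shape
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    flagged: list[str] = []
    usable: list[tuple[str, np.ndarray]] = []
    for s in gene_sets:
        idx = [gene_index[g] for g in s.genes if g in gene_index]
        if len(idx) < 2 or len(idx) >= n_genes:
            flagged.append(s.name)
            continue
        mask = np.zeros(n_genes, dtype=bool)
        mask[idx] = True
        usable.append((s.name, mask))
    if not usable:
        raise ValueError("no gene set has >= 2 genes in the matrix")

    scores = np.empty((len(usable), n_samp))
    for j in range(n_samp):
        order = np.argsort(-X[:, j], kind="stable")  # descending expression
        wts = np.arange(n_genes, 0, -1, dtype=float) ** alpha  # rank n..1 along order
        for si, (_, mask) in enumerate(usable):
            in_ord = mask[order]
            m = int(in_ord.sum())
            cdf_in = np.cumsum(np.where(in_ord, wts, 0.0))
            cdf_in /= cdf_in[-1]
            cdf_out = np.cumsum(~in_ord) / float(n_genes - m)
            scores[si, j] = float(np.sum(cdf_in - cdf_out))
    df = pd.DataFrame(scores, index=[name for name, _ in usable], columns=expr.sample_ids)
    if normalize:
        span = df.to_numpy().max() - df.to_numpy().min()
        if span > 0:
            df = df / span
    return df, flagged


def immune_correlation(scores: pd.DataFrame, gene_values: pd.Series) -> pd.DataFrame:
    """Spearman correlation of each cell-type score with a gene's expression.

    Samples are aligned by id; the table is sorted by rho descending.
    """
    common = [s for s in scores.columns if s in gene_values.index]
    if len(common) < 3:
        raise ValueError("need at least 3 aligned samples")
    gv = gene_values.loc[common].to_numpy(dtype=float)
    rows = []
    for cell in scores.index:
        sv = scores.loc[cell, common].to_numpy(dtype=float)
        if np.all(sv == sv[0]):
            raise ValueError(f"constant score vector for {cell!r}")
        rho, p = stats.spearmanr(sv, gv)
        rows.append({"cell_type": cell, "rho": float(rho), "p": float(p)})
    return (
        pd.DataFrame(rows)
        .sort_values("rho", ascending=False, kind="stable")
        .reset_index(drop=True)
    )


def immune_survival_association(
    scores: pd.DataFrame,
    survival: dict[str, pd.DataFrame] | pd.DataFrame,
) -> pd.DataFrame:
    """Median-split survival summary per cell type and endpoint.

    Each cell-type score is dichotomized at its median; per endpoint the
    log-rank p and the univariate Cox hazard ratio of the high-score group
    are reported (heatmap-ready long table).
    """
    endpoints = {"OS": survival} if isinstance(survival, pd.DataFrame) else dict(survival)
    if not endpoints:
        raise ValueError("no survival endpoint given")
    rows = []
    for ep_name, df in endpoints.items():
        common = [s for s in scores.columns if s in df.index]
        if len(common) < 4:
            raise ValueError(f"endpoint {ep_name!r}: too few aligned samples")
        sub = df.loc[common]
        for cell in scores.index:
            vals = scores.loc[cell, common].to_numpy(dtype=float)
            labels = dichotomize_expression(vals, rule="median")
            if len(set(labels)) < 2:
                raise ValueError(f"degenerate median split for {cell!r}")
            _, lr_p = logrank_test(sub["time"].to_numpy(), sub["event"].to_numpy(), labels)
            fit_df = pd.DataFrame(
                {
                    "time": sub["time"].to_numpy(),
                    "event": sub["event"].to_numpy(),
                    "high": (labels == "high").astype(float),
                }
            )
            res = cox_fit(fit_df, ["high"], mode="univariate")[0]
            rows.append(
                {
                    "endpoint": ep_name,
                    "cell_type": cell,
                    "hr": res.hr,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "cox_p": res.p,
                    "logrank_p": lr_p,
                }
            )
    return pd.DataFrame(rows)
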