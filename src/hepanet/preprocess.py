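"""Sample-correlation quality control and coefficient-of-variation gene filtering.

Mirrors the funnel of a paired tumor/normal microarray study: cluster samples
by Pearson correlation within each tissue class, keep the tightest cluster(s),
retain only subjects whose tumor AND normal samples both survive, then select
high-variability seed genes by coefficient of variation (CV = sd / |mean|).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io_formats import ExpressionMatrix, SampleInfo

__all__ = ["QCReport", "GeneFilterResult", "sample_correlation_matrix",
           "select_consistent_pairs", "cv_filter"]


@dataclass
class QCReport:
    correlation: dict[str, pd.DataFrame]  # tissue -> sample correlation matrix
    clusters: dict[str, pd.Series]  # tissue -> sample cluster id
    retained_samples: list[str]
    retained_subjects: list[str]
    dropped: list[tuple[str, str]] = field(default_factory=list)  # (sample, reason)


@dataclass
class GeneFilterResult:
    cv: pd.Series  # per-gene CV on the scale used
    cutoff: float | None
    top_n: int | None
    retained_genes: list[str]
    excluded_zero_mean: list[str] = field(default_factory=list)


def sample_correlation_matrix(expr: ExpressionMatrix) -> pd.DataFrame:
    """Pairwise Pearson correlation between samples over all genes."""
    X = expr.values
    sd = X.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if len(zero):
        raise ValueError(f"zero-variance sample(s): {[expr.sample_ids[i] for i in zero]}")
    corr = np.corrcoef(X, rowvar=False)
    return pd.DataFrame(corr, index=expr.sample_ids, columns=expr.sample_ids)


def _mean_intra_correlation(corr: pd.DataFrame, members: list[str]) -> float:
    """Cluster tightness score.

    For clusters of >= 2 the mean off-diagonal correlation; a singleton has
    no intra-pair evidence, so it scores as its best correlation to any
    other sample — a near-duplicate sample split off by a forced cluster
    count then survives, while a genuine outlier still falls below the
    margin.
    """
    if len(members) < 2:
        others = [s for s in corr.index if s not in members]
        if not others:
            return -np.inf
        return float(corr.loc[members[0], others].max())
    sub = corr.loc[members, members].to_numpy()
    iu = np.triu_indices(len(members), k=1)
    return float(sub[iu].mean())


def select_consistent_pairs(
    expr: ExpressionMatrix,
    samples: list[SampleInfo],
    tumor_groups: int = 2,
    normal_groups: int = 3,
    keep_margin: float = 0.05,
) -> QCReport:
    """Average-linkage sample QC with paired-sample retention.

    Within each tissue class, samples are clustered on 1 - Pearson
    correlation (average linkage) and cut into the configured number of
    groups.  Clusters whose mean intra-cluster correlation is within
    ``keep_margin`` of the best substantial cluster's are kept (forcing a
    cluster count on clean data splits near-identical groups whose mean
    correlations differ by a few hundredths, while genuine outlier groups
    fall far below the margin).  A subject is retained only if both its
    tumor and its normal sample survive.  The pass is repeated on its own
    output until the retained set is stable, so the operation is idempotent
    by construction.
    """
    report = _select_pass(expr, samples, tumor_groups, normal_groups, keep_margin)
    dropped = list(report.dropped)
    while report.dropped:
        kept = set(report.retained_samples)
        sub_samples = [s for s in samples if s.sample_id in kept]
        nxt = _select_pass(
            expr.subset_samples(report.retained_samples), sub_samples,
            tumor_groups, normal_groups, keep_margin,
        )
        if not nxt.dropped:
            nxt.dropped = dropped
            return nxt
        dropped.extend(nxt.dropped)
        report = nxt
    return report


def _select_pass(
    expr: ExpressionMatrix,
    samples: list[SampleInfo],
    tumor_groups: int = 2,
    normal_groups: int = 3,
    keep_margin: float = 0.05,
) -> QCReport:
    """One retention pass (see select_consistent_pairs)."""
    by_tissue: dict[str, list[SampleInfo]] = {"tumor": [], "normal": []}
    for s in samples:
        by_tissue[s.tissue].append(s)
    n_groups = {"tumor": tumor_groups, "normal": normal_groups}

    corr_by_tissue: dict[str, pd.DataFrame] = {}
    clusters_by_tissue: dict[str, pd.Series] = {}
    surviving: dict[str, set[str]] = {}
    dropped: list[tuple[str, str]] = []
    for tissue, infos in by_tissue.items():
        ids = [s.sample_id for s in infos]
        if not ids:
            surviving[tissue] = set()
            continue
        corr = sample_correlation_matrix(expr.subset_samples(ids))
        corr_by_tissue[tissue] = corr
        if len(ids) < 3:
            clusters_by_tissue[tissue] = pd.Series(1, index=ids)
            surviving[tissue] = set(ids)
            continue
        dist = squareform(np.clip(1.0 - corr.to_numpy(), 0.0, None), checks=False)
        Z = linkage(dist, method="average")
        labels = fcluster(Z, t=n_groups[tissue], criterion="maxclust")
        clusters = pd.Series(labels, index=ids)
        clusters_by_tissue[tissue] = clusters
        stats = []
        for cid in np.unique(labels):
            members = list(clusters.index[clusters == cid])
            stats.append((cid, _mean_intra_correlation(corr, members), len(members)))
        # the reference level comes from the best *substantial* cluster
        # (>= 25% of the tissue's samples): forced splits of clean data
        # produce small clusters whose noisy means must not raise the bar,
        # and singletons never define it.  Equal means -> larger cluster.
        min_sub = max(2, round(0.25 * len(ids)))
        eligible = [t for t in stats if t[2] >= min_sub]
        if not eligible:
            eligible = [t for t in stats if t[2] >= 2] or stats
        best = max(eligible, key=lambda t: (t[1], t[2]))
        keep_ids = {cid for cid, m, _ in stats if m >= best[1] - keep_margin}
        if all(not np.isfinite(m) for _, m, _ in stats):
            keep_ids = {cid for cid, _, _ in stats}  # all singletons: keep all
        kept = set(clusters.index[clusters.isin(keep_ids)])
        for sid in ids:
            if sid not in kept:
                dropped.append((sid, f"{tissue} cluster below best mean correlation"))
        surviving[tissue] = kept

    subj_tumor = {s.subject_id for s in by_tissue["tumor"] if s.sample_id in surviving["tumor"]}
    subj_normal = {s.subject_id for s in by_tissue["normal"] if s.sample_id in surviving["normal"]}
    retained_subjects = sorted(subj_tumor & subj_normal)
    if not retained_subjects:
        raise ValueError("sample QC removed every subject pair")
    retained = [
        s.sample_id for s in samples
        if s.subject_id in set(retained_subjects) and s.sample_id in surviving[s.tissue]
    ]
    for s in samples:
        if s.sample_id in surviving[s.tissue] and s.subject_id not in set(retained_subjects):
            dropped.append((s.sample_id, "partner sample failed QC (pairing rule)"))
    return QCReport(
        correlation=corr_by_tissue,
        clusters=clusters_by_tissue,
        retained_samples=retained,
        retained_subjects=retained_subjects,
        dropped=dropped,
    )


def cv_filter(
    expr: ExpressionMatrix,
    cutoff: float | None = 3.6,
    top_n: int | None = None,
    scale: str = "linear",
) -> GeneFilterResult:
    """Coefficient-of-variation seed-gene selection.

    CV = sd / |mean| per gene across the retained samples.  By default the
    CV is computed on linear-scale intensities (2**x of the log2 input),
    where cutoffs of the order of several units are attainable;
    ``scale="log"`` computes it on the values as provided.  Either a strict
    cutoff (retain CV > cutoff) or a top-N rank rule may be used.
    Genes whose mean is zero have undefined CV and are excluded and logged.
    """
    if scale not in ("linear", "log"):
        raise ValueError(f"unknown scale {scale!r}")
    if (cutoff is None) == (top_n is None):
        raise ValueError("specify exactly one of cutoff / top_n")
    X = expr.values.astype(float)
    if scale == "linear":
        X = np.exp2(X)
    mean = X.mean(axis=1)
    sd = X.std(axis=1, ddof=1)
    genes = np.asarray(expr.gene_ids)
    zero_mean = mean == 0
    cv = np.full(len(genes), np.nan)
    cv[~zero_mean] = sd[~zero_mean] / np.abs(mean[~zero_mean])
    cv_series = pd.Series(cv, index=genes)
    valid = cv_series.dropna()
    if top_n is not None:
        order = valid.sort_values(ascending=False, kind="stable")
        retained = sorted(order.index[: top_n], key=list(genes).index)
    else:
        retained = [g for g in genes if g in valid.index and valid[g] > cutoff]
    return GeneFilterResult(
        cv=cv_series,
        cutoff=cutoff,
        top_n=top_n,
        retained_genes=list(retained),
        excluded_zero_mean=list(genes[zero_mean]),
    )
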