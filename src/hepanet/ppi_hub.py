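"""Hub-gene screening on a protein-interaction network.

For each co-expression gene covered by the interaction network, the screen
counts co-expressed vs other neighbors, tests the neighborhood for
over-representation of co-expression genes with a one-sided Fisher exact
(upper-tail hypergeometric) test, adjusts for multiplicity, and keeps genes
whose co-expressed-neighbor fraction reaches the proportion threshold with an
adjusted p below alpha.

The hypergeometric model: drawing n = c + o neighbors from a network of N
genes containing M co-expression genes, the p-value is P(X >= c).  The
default multiplicity adjustment is the Bonferroni-style m * p with
m = M (the number of covered co-expression genes); Benjamini-Hochberg is
available and recommended for new analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io_formats import PPINetwork

__all__ = [
    "HubCandidate",
    "CoverageStats",
    "map_to_ppi",
    "neighborhood_overlap",
    "fisher_enrichment",
    "adjust_pvalues",
    "compute_candidates",
    "screen_hubs",
    "TABLE_COLUMNS",
]

#: Stable output column order for the screening table.
TABLE_COLUMNS = [
    "gene",
    "n_coexpr_neighbors",
    "n_other_neighbors",
    "n_coexpr_genes",
    "n_network_genes",
    "proportion",
    "fisher_p",
    "adjusted_p",
]


@dataclass(frozen=True)
class HubCandidate:
    """One screening row: counts, proportion, and significance for one gene."""

    gene: str
    c: int  # co-expressed neighbors
    o: int  # other neighbors
    M: int  # co-expression genes covered by the network
    N: int  # total network genes
    fisher_p: float
    adjusted_p: float = float("nan")

    def __post_init__(self) -> None:
        if not (0 <= self.c <= self.M and self.c + self.o <= self.N and self.M <= self.N):
            raise ValueError(f"inconsistent counts for {self.gene}")

    @property
    def degree(self) -> int:
        return self.c + self.o

    @property
    def proportion(self) -> float:
        return self.c / self.degree if self.degree else float("nan")


@dataclass(frozen=True)
class CoverageStats:
    """Network-level coverage of the co-expression gene list."""

    n_network_genes: int
    mean_degree: float
    n_covered: int
    mean_coexpr_neighbors: float


def neighborhood_overlap(gene: str, ppi: PPINetwork, coexpr_set: set[str]) -> tuple[int, int]:
    """(co-expressed, other) neighbor counts; the focal gene never counts itself."""
    if gene not in ppi.nodes:
        raise KeyError(f"gene {gene!r} not in the interaction network")
    neighbors = ppi.neighbors(gene) - {gene}
    c = sum(1 for nb in neighbors if nb in coexpr_set)
    return c, len(neighbors) - c


def map_to_ppi(coexpr_genes: list[str], ppi: PPINetwork) -> CoverageStats:
    """Coverage statistics of the co-expression list on the network."""
    if not coexpr_genes or not ppi.nodes:
        raise ValueError("empty gene list or network")
    covered = [g for g in coexpr_genes if g in ppi.nodes]
    if not covered:
        raise ValueError("no co-expression gene is covered by the network")
    coexpr_set = set(coexpr_genes)
    counts = [neighborhood_overlap(g, ppi, coexpr_set)[0] for g in covered]
    return CoverageStats(
        n_network_genes=len(ppi.nodes),
        mean_degree=ppi.mean_degree(),
        n_covered=len(covered),
        mean_coexpr_neighbors=float(np.mean(counts)),
    )


def fisher_enrichment(c: int, o: int, M: int, N: int) -> float:
    """One-sided enrichment p-value P(X >= c), X ~ Hypergeom(N, M, c + o).

    Equivalent to the one-sided Fisher exact test on the 2x2 table
    [[c, o], [M - c, N - M - o]].
    """
    if not (0 <= c <= M and M <= N and 0 <= o <= N - M):
        raise ValueError(f"inconsistent counts (c={c}, o={o}, M={M}, N={N})")
    return float(hypergeom.sf(c - 1, N, M, c + o))


def adjust_pvalues(p_list: list[float], method: str = "bonferroni", m: int | None = None) -> list[float]:
    """Multiplicity adjustment with an explicit test count ``m``.

    ``bonferroni``: min(1, m * p).  ``bh``: Benjamini-Hochberg step-up with
    m in the numerator (p_(i) * m / i, cumulative-minimum from the largest).
    ``m`` defaults to the list length and may be larger (tests that were
    screened out but still counted).
    """
    p = np.asarray(p_list, dtype=float)
    if len(p) and (p.min() <= 0 or p.max() > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m_eff = len(p) if m is None else int(m)
    if m_eff < len(p):
        raise ValueError("m must be >= number of p-values")
    if method == "bonferroni":
        return list(np.minimum(1.0, m_eff * p))
    if method == "bh":
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m_eff / np.arange(1, len(p) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(p)
        out[order] = np.minimum(1.0, adj)
        return list(out)
    raise ValueError(f"unknown adjustment method {method!r}")


def compute_candidates(
    coexpr_genes: list[str],
    ppi: PPINetwork,
    method: str = "bonferroni",
    m: int | None = None,
) -> list[HubCandidate]:
    """Screening rows for every covered gene with degree >= 1.

    In the default (fidelity) mode the adjustment multiplier is the number
    of covered co-expression genes M, regardless of how many of them have
    degree >= 1; under ``bh`` only the tested genes count.
    """
    coexpr_set = set(coexpr_genes)
    covered = sorted(g for g in coexpr_set if g in ppi.nodes)
    if not covered:
        raise ValueError("no co-expression gene is covered by the network")
    N = len(ppi.nodes)
    M = len(covered)
    rows = []
    for g in covered:
        c, o = neighborhood_overlap(g, ppi, coexpr_set)
        if c + o == 0:
            continue  # isolated node: excluded from screening
        rows.append((g, c, o, fisher_enrichment(c, o, M, N)))
    if m is None:
        m = M if method == "bonferroni" else len(rows)
    adj = adjust_pvalues([r[3] for r in rows], method=method, m=m)
    return [
        HubCandidate(g, c, o, M, N, p, ap)
        for (g, c, o, p), ap in zip(rows, adj)
    ]


def screen_hubs(
    candidates: list[HubCandidate],
    proportion_threshold: float = 0.10,
    alpha: float = 0.05,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the proportion and adjusted-p screening rules.

    Hubs are candidates with co-expressed-neighbor proportion >= the
    threshold AND adjusted p < alpha.  Returns the hub gene list and the
    full candidate table sorted by adjusted p (ties by gene symbol).
    """
    rows = [
        {
            "gene": cand.gene,
            "n_coexpr_neighbors": cand.c,
            "n_other_neighbors": cand.o,
            "n_coexpr_genes": cand.M,
            "n_network_genes": cand.N,
            "proportion": cand.proportion,
            "fisher_p": cand.fisher_p,
            "adjusted_p": cand.adjusted_p,
        }
        for cand in candidates
    ]
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    table["is_hub"] = (table["proportion"] >= proportion_threshold) & (
        table["adjusted_p"] < alpha
    )
    table = table.sort_values(["adjusted_p", "gene"], kind="stable").reset_index(drop=True)
    hubs = list(table.loc[table["is_hub"], "gene"])
    return hubs, table
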