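"""Synthetic data with planted structure for every stage of the pipeline.

The generators emulate the statistical shape of a paired tumor/normal
microarray study: block-correlated expression modules driven by latent
factors whose means shift with the tumor trait, a scale-free protein
interaction graph with designated genes whose neighborhoods are enriched for
co-expression genes, exponential survival with expression-dependent hazards,
and 2x2-structured clinical covariates.  Every generator is a pure function
of its configuration and seed, and returns ground truth for recovery tests.

Seeding uses named substreams derived from one global seed, so each stage can
be regenerated independently and deterministically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import (
    CLINICAL_LEVELS,
    ClinicalTable,
    ExpressionMatrix,
    GeneSet,
    PPINetwork,
    SampleInfo,
    write_clinical,
    write_gene_sets,
)

__all__ = [
    "ModuleSpec",
    "PPISpec",
    "SurvivalSpec",
    "SimulationConfig",
    "GroundTruth",
    "substream",
    "simulate_expression",
    "simulate_ppi",
    "simulate_survival",
    "simulate_clinical_table",
    "simulate_gene_sets",
    "write_dataset",
]


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic named substream of a global seed."""
    h = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return np.random.default_rng(int.from_bytes(h[:8], "little"))


@dataclass(frozen=True)
class ModuleSpec:
    """One planted co-expression module.

    ``rho`` is the within-module gene-gene correlation; ``trait_effect`` is
    the shift (in latent-factor SD units) of the module eigengene mean in
    tumor relative to normal samples.
    """

    size: int
    rho: float = 0.9
    trait_effect: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.rho < 1.0:
            raise ValueError(f"rho must be in (0,1), got {self.rho}")
        if self.size < 1:
            raise ValueError("module size must be >= 1")


@dataclass(frozen=True)
class PPISpec:
    """Scale-free interaction graph with planted enriched neighborhoods.

    ``hub_coexpr_rate`` is the target fraction of co-expressed genes in each
    planted hub's neighborhood; ``hub_extra_degree`` is the number of extra
    edges each planted hub receives to reach that fraction.
    """

    n_nodes: int = 2000
    attachment: int = 3
    n_hubs: int = 4
    hub_coexpr_rate: float = 0.3
    hub_extra_degree: int = 60


@dataclass(frozen=True)
class SurvivalSpec:
    """Exponential survival with hazard h0 * exp(beta * x)."""

    baseline_hazard: float = 0.02  # events per month
    beta: float = float(np.log(2.0))
    censoring_rate: float = 0.3

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring rate must be in [0,1)")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shaped defaults: 54 tumor/normal pairs, three planted modules of
    50 genes at rho=0.9 among 100 background genes."""

    n_subjects: int = 54
    n_genes: int = 250
    modules: tuple[ModuleSpec, ...] = (
        ModuleSpec(50, 0.9, 2.0),
        ModuleSpec(50, 0.9, 1.2),
        ModuleSpec(50, 0.9, 0.8),
    )
    noise_sd: float = 1.0
    baseline_mean: tuple[float, float] = (6.0, 12.0)  # log2 intensity range
    ppi: PPISpec = PPISpec()
    survival: SurvivalSpec = SurvivalSpec()
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(m.size for m in self.modules) > self.n_genes:
            raise ValueError("sum of module sizes exceeds n_genes")


@dataclass
class GroundTruth:
    """What was planted, for recovery tests."""

    module_labels: dict[str, str]  # gene -> "M1", ... ("grey" for background)
    hub_genes: list[str] = field(default_factory=list)
    latent_factors: pd.DataFrame | None = None  # module x sample
    survival_beta: float | None = None

    def module_members(self, label: str) -> list[str]:
        return [g for g, lab in self.module_labels.items() if lab == label]


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, list[SampleInfo], GroundTruth]:
    """Latent-factor module model on a paired tumor/normal design.

    For module m with correlation rho and trait effect d, gene g in sample j:

        x_gj = mu_g + noise_sd * (sqrt(rho) * z_mj + sqrt(1-rho) * eps_gj)

    where z_mj ~ N(d * trait_j, 1) is the module's latent eigengene and
    trait is 1 for tumor, 0 for normal.  Background genes are i.i.d. noise
    around their baseline.  Each subject contributes one tumor and one
    normal sample.
    """
    rng = substream(config.seed, "expression")
    n_sub = config.n_subjects
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    samples: list[SampleInfo] = []
    for i in range(n_sub):
        sid = f"S{i:03d}"
        samples.append(SampleInfo(f"{sid}T", sid, "tumor"))
        samples.append(SampleInfo(f"{sid}N", sid, "normal"))
    trait = np.array([s.trait for s in samples], dtype=float)
    n_samp = len(samples)

    lo, hi = config.baseline_mean
    mu = rng.uniform(lo, hi, size=config.n_genes)
    X = np.empty((config.n_genes, n_samp))
    labels: dict[str, str] = {g: "grey" for g in genes}
    latent_rows = []
    pos = 0
    for m_idx, spec in enumerate(config.modules, start=1):
        z = rng.normal(spec.trait_effect * trait, 1.0)
        latent_rows.append(z)
        eps = rng.normal(size=(spec.size, n_samp))
        block = np.sqrt(spec.rho) * z[None, :] + np.sqrt(1.0 - spec.rho) * eps
        X[pos : pos + spec.size] = config.noise_sd * block
        for g in genes[pos : pos + spec.size]:
            labels[g] = f"M{m_idx}"
        pos += spec.size
    n_bg = config.n_genes - pos
    if n_bg:
        X[pos:] = config.noise_sd * rng.normal(size=(n_bg, n_samp))
    X += mu[:, None]

    data = pd.DataFrame(X, index=genes, columns=[s.sample_id for s in samples])
    latent = pd.DataFrame(
        np.asarray(latent_rows).reshape(len(config.modules), n_samp),
        index=[f"M{i}" for i in range(1, len(config.modules) + 1)],
        columns=data.columns,
    )
    truth = GroundTruth(module_labels=labels, latent_factors=latent,
                        survival_beta=config.survival.beta)
    return ExpressionMatrix(data), samples, truth


# ---------------------------------------------------------------------------
# protein-interaction graph
# ---------------------------------------------------------------------------

def simulate_ppi(config: SimulationConfig, truth: GroundTruth) -> PPINetwork:
    """Preferential-attachment graph with planted enriched hub neighborhoods.

    Expression genes occupy the first nodes of a Barabasi-Albert graph (extra
    nodes are named ``P####``).  Planted hubs are drawn from the first
    module's genes; each receives ``hub_extra_degree`` additional edges of
    which a ``hub_coexpr_rate`` fraction (binomially sampled) go to module
    genes, so the hub's co-expressed-neighbor fraction exceeds a background
    screening threshold.  Setting ``hub_coexpr_rate`` at or below the
    background co-expression fraction yields a null network.
    """
    spec = config.ppi
    rng = substream(config.seed, "ppi")
    genes = [g for g in truth.module_labels]
    if spec.n_nodes < len(genes):
        raise ValueError("ppi n_nodes must cover all expression genes")
    g_nx = nx.barabasi_albert_graph(
        spec.n_nodes, spec.attachment,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    names = genes + [f"P{i:04d}" for i in range(spec.n_nodes - len(genes))]
    # shuffle which integer node gets which name so degree is not tied to
    # gene index (BA arrival order strongly orders degree)
    perm = rng.permutation(spec.n_nodes)
    mapping = {int(node): names[perm[node]] for node in g_nx.nodes}
    g_nx = nx.relabel_nodes(g_nx, mapping)

    coexpr = [g for g, lab in truth.module_labels.items() if lab != "grey"]
    coexpr_set = set(coexpr)
    module1 = truth.module_members("M1")
    if spec.n_hubs > len(module1):
        raise ValueError("hub count exceeds first-module gene count")
    hubs = list(rng.choice(module1, size=spec.n_hubs, replace=False)) if spec.n_hubs else []

    background_rate = len(coexpr_set) / spec.n_nodes
    others = [n for n in names if n not in coexpr_set]
    for hub in hubs:
        if spec.hub_coexpr_rate <= background_rate:
            break  # null network: no planted enrichment
        n_co = int(rng.binomial(spec.hub_extra_degree, spec.hub_coexpr_rate))
        targets_co = [g for g in coexpr if g != hub and not g_nx.has_edge(hub, g)]
        targets_other = [n for n in others if n != hub and not g_nx.has_edge(hub, n)]
        pick_co = rng.choice(targets_co, size=min(n_co, len(targets_co)), replace=False)
        n_other = spec.hub_extra_degree - len(pick_co)
        pick_other = rng.choice(targets_other, size=min(n_other, len(targets_other)), replace=False)
        g_nx.add_edges_from((hub, t) for t in pick_co)
        g_nx.add_edges_from((hub, t) for t in pick_other)
    truth.hub_genes = list(hubs)
    return PPINetwork(g_nx)


# ---------------------------------------------------------------------------
# survival and clinical covariates
# ---------------------------------------------------------------------------

def simulate_survival(
    covariate: Sequence[float] | np.ndarray,
    spec: SurvivalSpec,
    seed: int = 0,
    ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Exponential event times with hazard ``h0 * exp(beta * x)``.

    Censoring is by an independent exponential clock whose rate is chosen so
    that the expected censoring fraction approximates ``censoring_rate``
    (for competing exponentials, P(censored) = mu / (lambda + mu)).
    Returns a data frame with ``time`` (months) and ``event`` columns.
    """
    rng = substream(seed, "survival")
    x = np.asarray(covariate, dtype=float)
    lam = spec.baseline_hazard * np.exp(spec.beta * x)
    t_event = rng.exponential(1.0 / lam)
    if spec.censoring_rate > 0:
        mu = lam.mean() * spec.censoring_rate / (1.0 - spec.censoring_rate)
        t_cens = rng.exponential(1.0 / mu, size=len(x))
    else:
        t_cens = np.full(len(x), np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    idx = list(ids) if ids is not None else [f"P{i:03d}" for i in range(len(x))]
    return pd.DataFrame({"time": time, "event": event, "x": x}, index=idx)


def simulate_clinical_table(
    n: int,
    class_probs: Mapping[str, Mapping[str, float]] | None = None,
    association: Mapping[str, float] | None = None,
    survival: SurvivalSpec | None = None,
    seed: int = 0,
    p_high: float = 0.4,
) -> ClinicalTable:
    """Clinical table with 2x2-structured covariates tied to an expression class.

    Each categorical covariate is binary with the given baseline probability
    of its second level; ``association`` maps covariate name to an odds
    ratio linking the second level to the *high* expression class (OR=1 means
    independence).  Survival times follow ``survival`` with the high class as
    the hazard covariate.  An ``ihc_percent`` column consistent with the
    expression class is included.
    """
    rng = substream(seed, "clinical")
    if class_probs is None:
        class_probs = {
            "age_class": {">50": 0.55},
            "sex": {"male": 0.9},
            "tnm": {"II-IV": 0.3},
            "tumor_size": {">3cm": 0.6},
            "afp": {">300": 0.45},
        }
    association = dict(association or {})
    survival = survival or SurvivalSpec()
    for cov, pr in class_probs.items():
        p = list(pr.values())[0]
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"invalid probability {p} for {cov}")

    high = rng.random(n) < p_high
    cols: dict[str, np.ndarray] = {}
    for cov, pr in class_probs.items():
        level_hi, p = next(iter(pr.items()))
        levels = CLINICAL_LEVELS[cov]
        level_lo = next(l for l in levels if l != level_hi)
        odds = association.get(cov, 1.0)
        base_odds = p / (1.0 - p) if p < 1 else np.inf
        p_vec = np.where(high, base_odds * odds / (1 + base_odds * odds), p)
        draws = rng.random(n) < p_vec
        cols[cov] = np.where(draws, level_hi, level_lo)
    # IHC percent consistent with the class: low < 50, high >= 50
    pct = np.where(high, rng.uniform(50, 100, n), rng.uniform(0, 50, n))
    surv = simulate_survival(high.astype(float), survival,
                             seed=int(rng.integers(0, 2**31 - 1)))
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:03d}" for i in range(n)],
            "time": surv["time"].to_numpy(),
            "event": surv["event"].to_numpy(),
            "expression": np.where(high, "high", "low"),
            "ihc_percent": pct,
            **cols,
        }
    )
    return ClinicalTable(df)


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def simulate_gene_sets(
    truth: GroundTruth,
    n_random: int = 10,
    random_size: int = 20,
    seed: int = 0,
) -> list[GeneSet]:
    """Marker-style GMT: one set per planted module plus random decoys."""
    rng = substream(seed, "genesets")
    genes = list(truth.module_labels)
    sets = []
    for label in sorted({l for l in truth.module_labels.values() if l != "grey"}):
        members = truth.module_members(label)
        sets.append(GeneSet(f"planted_{label}", "planted module marker set", tuple(members)))
    for i in range(n_random):
        members = rng.choice(genes, size=min(random_size, len(genes)), replace=False)
        sets.append(GeneSet(f"random_{i:02d}", "random decoy set", tuple(members)))
    return sets


# ---------------------------------------------------------------------------
# dataset directory
# ---------------------------------------------------------------------------

def write_dataset(config: SimulationConfig, outdir: str | Path) -> dict[str, str]:
    """Emit a complete dataset directory plus a ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr, samples, truth = simulate_expression(config)
    ppi = simulate_ppi(config, truth)
    clin = simulate_clinical_table(config.n_subjects, survival=config.survival,
                                   seed=config.seed)
    sets = simulate_gene_sets(truth, seed=config.seed)

    paths = {
        "expression": str(outdir / "expression.tsv"),
        "samples": str(outdir / "samples.tsv"),
        "ppi": str(outdir / "ppi_edges.tsv"),
        "gene_sets": str(outdir / "gene_sets.gmt"),
        "clinical": str(outdir / "clinical.csv"),
        "truth": str(outdir / "ground_truth.json"),
    }
    expr.data.to_csv(paths["expression"], sep="\t", float_format="%.12g")
    pd.DataFrame(
        [(s.sample_id, s.subject_id, s.tissue) for s in samples],
        columns=["sample_id", "subject_id", "tissue"],
    ).to_csv(paths["samples"], sep="\t", index=False)
    with open(paths["ppi"], "w") as fh:
        for u, v in sorted(map(sorted, ppi.graph.edges())):
            fh.write(f"{u}\t{v}\n")
    write_gene_sets(sets, paths["gene_sets"])
    write_clinical(clin, paths["clinical"])
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "module_labels": truth.module_labels,
                "hub_genes": truth.hub_genes,
                "survival_beta": truth.survival_beta,
            },
            fh,
            indent=1,
        )
    return paths
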