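"""Synthetic three-phase expression data with a planted regulatory network.

The generator emulates the structure of a phase-labelled leukemia expression
study: a genes x samples log2-ratio matrix with three phase groups (chronic,
accelerated, blast; optionally an imatinib-resistant group), phase-dependent
mean shifts on a subset of genes, and a planted hub -> target regulatory layer
in which target genes are noisy linear combinations of their hub regulators.

Every quantity is drawn from a seeded :class:`numpy.random.Generator`, so the
matrix, metadata and ground truth are bit-reproducible from the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import validate_expression, validate_meta

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "make_ground_truth",
    "simulate_expression",
    "simulate_null_matrix",
    "make_annotation_fixture",
]

PHASE_ORDER = ("chronic", "accelerated", "blast")


@dataclass
class SimulationConfig:
    """Study-design parameters of a simulated phase-labelled cohort.

    Group sizes default to the 42 chronic / 17 accelerated / 28 blast design
    of the CML cohort the package targets (87 samples); ``n_resistant`` adds an
    optional imatinib-resistant group (0 or 15 in that cohort).  ``effect_size``
    is the scale of between-phase mean shifts in log2 units and ``noise_sd``
    the within-group standard deviation of the Gaussian measurement noise.
    """

    n_genes: int = 200
    n_hubs: int = 15
    out_degree_range: tuple[int, int] = (3, 10)
    n_chronic: int = 42
    n_accelerated: int = 17
    n_blast: int = 28
    n_resistant: int = 0
    effect_size: float = 1.5
    noise_sd: float = 0.5
    frac_de: float = 0.5
    resistant_frac: float = 0.1
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.n_hubs >= self.n_genes:
            raise ValueError("n_hubs must be smaller than n_genes")
        if self.n_hubs > 0:
            lo, hi = self.out_degree_range
            if lo < 1 or hi < lo:
                raise ValueError("invalid out_degree_range")
            if hi > self.n_genes - self.n_hubs:
                raise ValueError(
                    "out_degree_range upper bound exceeds available non-hub genes"
                )
        for n in (self.n_chronic, self.n_accelerated, self.n_blast):
            if n < 2:
                raise ValueError("each phase group needs at least 2 samples")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        return self

    @property
    def group_sizes(self) -> dict[str, int]:
        sizes = {
            "chronic": self.n_chronic,
            "accelerated": self.n_accelerated,
            "blast": self.n_blast,
        }
        if self.n_resistant:
            sizes["resistant"] = self.n_resistant
        return sizes


@dataclass
class GroundTruth:
    """Planted network, phase effects and noise level of one simulation."""

    gene_ids: list[str]
    edges: pd.DataFrame  # columns regulator, target, weight
    hub_ids: list[str]
    phase_effects: pd.DataFrame  # genes x (chronic, accelerated, blast)
    resistant_shift: pd.Series  # extra per-gene shift of the resistant group
    noise_sd: float
    seed: int

    @property
    def edge_set(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["regulator"], self.edges["target"]))

    def out_degrees(self) -> pd.Series:
        return self.edges.groupby("regulator").size().reindex(
            self.gene_ids, fill_value=0
        )


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def make_ground_truth(cfg: SimulationConfig) -> GroundTruth:
    """Plant a one-layer hub -> target network and per-gene phase effects.

    Hubs are drawn first; each hub gets a target count uniform in
    ``out_degree_range`` and targets drawn uniformly without replacement from
    the non-hub genes (without replacement across hubs too, so every target
    has exactly one regulator).  Edge weights are ±Uniform(0.5, 1.5) with
    random sign.  All hubs and a ``frac_de`` fraction of the unconnected
    genes carry phase effects: mean shifts of magnitude ``effect_size`` x
    Uniform(0.5, 1) with random sign, independent for the accelerated and
    blast phases (the chronic phase is the reference with zero shift);
    connected targets inherit phase structure through their regulators.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_ids(cfg.n_genes)
    hub_idx = np.sort(rng.choice(cfg.n_genes, size=cfg.n_hubs, replace=False))
    hub_set = set(hub_idx.tolist())
    non_hubs = np.array([i for i in range(cfg.n_genes) if i not in hub_set])

    # targets drawn without replacement across the whole network, so every
    # target has exactly one regulator (one-layer, identifiable topology)
    rows = []
    available = rng.permutation(non_hubs).tolist()
    for h in hub_idx:
        k = int(rng.integers(cfg.out_degree_range[0], cfg.out_degree_range[1] + 1))
        if k > len(available):
            raise ValueError(
                "not enough non-hub genes left to assign disjoint target sets; "
                "reduce n_hubs or out_degree_range"
            )
        targets = [available.pop() for _ in range(k)]
        weights = rng.uniform(0.5, 1.5, size=k) * rng.choice([-1.0, 1.0], size=k)
        for t, w in zip(targets, weights):
            rows.append((genes[h], genes[int(t)], float(w)))
    edges = pd.DataFrame(rows, columns=["regulator", "target", "weight"])

    # Phase effects enter the network at its sources: all hubs carry effects,
    # plus a frac_de share of the unconnected genes.  Connected targets
    # inherit phase structure through their regulators (their own-effect term
    # stays zero by default), mirroring how the inference model explains a
    # signature gene's phase behavior by its regulators' expression.
    effects = np.zeros((cfg.n_genes, 3))
    gene_pos = {g: i for i, g in enumerate(genes)}
    target_idx = {gene_pos[t] for t in edges["target"].unique()} if len(edges) else set()
    unconnected = np.array([i for i in non_hubs if i not in target_idx])
    n_extra = int(round(cfg.frac_de * len(unconnected)))
    extra = (rng.choice(unconnected, size=min(n_extra, len(unconnected)),
                        replace=False)
             if len(unconnected) else np.array([], dtype=int))
    affected = np.concatenate([hub_idx, extra]).astype(int)
    for i in affected:
        for col in (1, 2):  # accelerated, blast; chronic is the reference
            mag = cfg.effect_size * rng.uniform(0.5, 1.0)
            effects[i, col] = mag * rng.choice([-1.0, 1.0])

    shift = np.zeros(cfg.n_genes)
    if cfg.n_resistant:
        n_shift = max(1, int(round(cfg.resistant_frac * cfg.n_genes)))
        shifted = rng.choice(cfg.n_genes, size=n_shift, replace=False)
        shift[shifted] = cfg.effect_size * rng.choice([-1.0, 1.0], size=n_shift)

    return GroundTruth(
        gene_ids=genes,
        edges=edges,
        hub_ids=[genes[i] for i in hub_idx],
        phase_effects=pd.DataFrame(effects, index=genes, columns=list(PHASE_ORDER)),
        resistant_shift=pd.Series(shift, index=genes),
        noise_sd=cfg.noise_sd,
        seed=cfg.seed,
    )


def _sample_table(cfg: SimulationConfig) -> pd.DataFrame:
    rows = []
    for phase, n in cfg.group_sizes.items():
        n_bc = (n + 1) // 2
        for i in range(n):
            subtype = "not_applicable"
            if phase == "accelerated":
                subtype = "blast_count" if i < n_bc else "cytogenetic"
            rows.append((f"{phase[:2].upper()}{i + 1:02d}", phase, subtype))
    return pd.DataFrame(rows, columns=["sample_id", "phase", "accelerated_subtype"])


def simulate_expression(
    gt: GroundTruth, cfg: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a log2-ratio matrix from the planted model.

    Hub and unconnected genes are ``phase_effect + N(0, noise_sd^2)``; each
    target gene is the weighted sum of its regulators' expression plus its own
    phase effect and noise.  The resistant group (if any) follows the blast
    phase-effect column plus the planted resistant shift.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1)
    meta = _sample_table(cfg)
    n_genes, n_samples = len(gt.gene_ids), len(meta)

    # per-sample phase-effect column: resistant samples follow the blast column
    effect_cols = meta["phase"].map(
        {"chronic": 0, "accelerated": 1, "blast": 2, "resistant": 2}
    ).to_numpy()
    base = gt.phase_effects.to_numpy()[:, effect_cols]
    if cfg.n_resistant:
        resistant = (meta["phase"] == "resistant").to_numpy()
        base = base + np.outer(gt.resistant_shift.to_numpy(), resistant)

    values = base + rng.normal(0.0, cfg.noise_sd, size=(n_genes, n_samples))

    # propagate hub expression into targets (one-layer topology)
    gene_pos = {g: i for i, g in enumerate(gt.gene_ids)}
    for reg, tgt, w in gt.edges.itertuples(index=False):
        values[gene_pos[tgt]] += w * values[gene_pos[reg]]

    matrix = pd.DataFrame(values, index=gt.gene_ids, columns=meta["sample_id"])
    matrix.columns.name = None
    return validate_expression(matrix), validate_meta(meta, matrix)


def simulate_null_matrix(
    n_genes: int, group_sizes: dict[str, int], seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """i.i.d. N(0,1) matrix with phase labels — a global-null fixture."""
    rng = np.random.default_rng(seed)
    rows = []
    for phase, n in group_sizes.items():
        for i in range(n):
            subtype = "blast_count" if phase == "accelerated" else "not_applicable"
            rows.append((f"{phase[:2].upper()}{i + 1:02d}", phase, subtype))
    meta = pd.DataFrame(rows, columns=["sample_id", "phase", "accelerated_subtype"])
    genes = _gene_ids(n_genes)
    values = rng.standard_normal((n_genes, len(meta)))
    matrix = pd.DataFrame(values, index=genes, columns=meta["sample_id"])
    matrix.columns.name = None
    return matrix, validate_meta(meta, matrix)


def make_annotation_fixture(
    gt: GroundTruth,
    n_categories: int = 10,
    category_size: int = 20,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Category -> gene-set catalog with one planted enriched category.

    The category named ``"planted"`` is a subset of the genes carrying phase
    effects; the remaining categories are drawn uniformly from all genes.
    """
    rng = np.random.default_rng(seed)
    effects = gt.phase_effects
    de_genes = effects.index[(effects != 0).any(axis=1)].to_numpy()
    if len(de_genes) == 0:
        raise ValueError("ground truth has no genes with phase effects")
    size = min(category_size, len(de_genes))
    catalog = {"planted": set(rng.choice(de_genes, size=size, replace=False))}
    all_genes = np.array(gt.gene_ids)
    for i in range(n_categories - 1):
        members = rng.choice(all_genes, size=min(category_size, len(all_genes)),
                             replace=False)
        catalog[f"random_{i + 1}"] = set(members)
    return catalog
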