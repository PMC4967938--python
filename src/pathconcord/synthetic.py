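"""Synthetic two-class expression data with known pathway-level ground truth.

The generator emulates the statistical structure the pipeline assumes in
real microarray data: per-gene baseline intensities on a log2-like scale
(baseline ~ Normal(8, 2)), Gaussian measurement noise with per-gene standard
deviations drawn log-normally, and coherent mean shifts of ±δ·σ_g applied to
all members of designated "regulated" pathways in the case group only. Pairs
of datasets share a controllable fraction ρ of their truly-regulated pathway
sets, giving exact designed profiles against which predictive-value recovery
can be scored.

It does not emulate probe-level structure, batch effects, count data or
correlated genes beyond the planted shifts; the collapse and mapping steps
are exercised with their own fixtures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ExpressionDataset, GeneSetCollection
from .pathway_state import PathwayStateProfile

logger = logging.getLogger("pathconcord")

__all__ = [
    "SimulationDesign",
    "make_gene_sets",
    "simulate_dataset",
    "simulate_model_pair",
    "truth_profile",
]


@dataclass(frozen=True)
class SimulationDesign:
    """Layout and effect parameters for one simulation.

    Defaults give 20 disjoint 30-gene sets over a 1,000-gene universe with
    10 vs 10 samples and a strong, clearly recoverable effect (δ = 2 noise
    SDs shifting every member gene); ``n_up``/``n_down`` regulated sets per
    model and cross-model overlap ρ apply when pairs are generated.
    """

    n_genes: int = 1000
    n_sets: int = 20
    set_size: tuple[int, int] = (30, 30)   # inclusive range
    set_overlap: float = 0.0               # member overlap between adjacent sets
    n_case: int = 10
    n_control: int = 10
    effect_size: float = 2.0               # δ, in units of per-gene noise SD
    noise_log_mean: float = float(np.log(0.5))  # log-normal params of σ_g
    noise_log_sd: float = 0.3
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    n_up: int = 3
    n_down: int = 3
    rho: float = 0.5                       # cross-model overlap fraction
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.rho <= 1:
            raise ValueError("rho must be in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 1 <= self.set_size[0] <= self.set_size[1]:
            raise ValueError("invalid set size range")
        if not 0 <= self.set_overlap < 1:
            raise ValueError("set_overlap must be in [0, 1)")
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need >= 2 samples per class")
        if self.n_up + self.n_down > self.n_sets:
            raise ValueError("more regulated sets than sets")


def _rng(design: SimulationDesign, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([design.rng_seed & 0x7FFFFFFF, *key]))


def gene_universe(design: SimulationDesign) -> list[str]:
    width = len(str(design.n_genes))
    return [f"G{i:0{width}d}" for i in range(1, design.n_genes + 1)]


def make_gene_sets(design: SimulationDesign) -> GeneSetCollection:
    """Sample the gene-set layout: disjoint sets, optionally overlapping.

    With ``set_overlap`` = 0 the sets are pairwise disjoint (error if the
    universe is too small); with a positive fraction each set shares
    ``round(overlap * size)`` members with its predecessor, the rest drawn
    from still-unused genes. Deterministic given the design seed.
    """
    rng = _rng(design, 1)
    universe = gene_universe(design)
    pool = list(universe)
    rng.shuffle(pool)
    sizes = rng.integers(design.set_size[0], design.set_size[1] + 1,
                         size=design.n_sets)
    n_shared = [0] + [int(round(design.set_overlap * s)) for s in sizes[1:]]
    fresh_needed = int(np.sum(sizes) - np.sum(n_shared))
    if fresh_needed > design.n_genes:
        raise ValueError(
            f"layout infeasible: needs {fresh_needed} distinct genes, "
            f"universe has {design.n_genes}")
    sets: dict[str, tuple[str, ...]] = {}
    prev: list[str] = []
    cursor = 0
    width = len(str(design.n_sets))
    for i, size in enumerate(sizes):
        shared = list(rng.choice(prev, size=n_shared[i], replace=False)) \
            if n_shared[i] else []
        fresh = pool[cursor:cursor + size - len(shared)]
        cursor += len(fresh)
        members = sorted(shared + fresh)
        name = f"SET{i + 1:0{width}d}"
        sets[name] = tuple(members)
        prev = members
    return GeneSetCollection(sets=sets,
                             descriptions={k: "synthetic" for k in sets})


def simulate_dataset(design: SimulationDesign, truth: tuple,
                     collection: GeneSetCollection,
                     dataset_id: str = "sim",
                     stream: int = 0) -> tuple[ExpressionDataset, dict]:
    """One two-class dataset with the given regulated sets planted.

    ``truth`` is ``(up_set_names, down_set_names)``. Every member gene of an
    up set gains +δ·σ_g in case samples (down sets −δ·σ_g); a gene in
    several regulated sets is shifted once per direction, so membership in
    both directions cancels (logged). Returns the dataset and a truth record
    with the designed set states and the per-gene shifts applied.
    """
    up_names, down_names = (set(truth[0]), set(truth[1]))
    if up_names & down_names:
        raise ValueError("a set cannot be both up- and down-regulated")
    for name in up_names | down_names:
        if name not in collection:
            raise ValueError(f"unknown set {name!r} in truth")
    rng = _rng(design, 2, stream)
    genes = gene_universe(design)
    n_g = design.n_genes
    n_s = design.n_case + design.n_control
    mu = rng.normal(design.baseline_mean, design.baseline_sd, size=n_g)
    sigma = rng.lognormal(design.noise_log_mean, design.noise_log_sd, size=n_g)
    values = mu[:, None] + rng.normal(0.0, 1.0, size=(n_g, n_s)) * sigma[:, None]

    gene_pos = {g: i for i, g in enumerate(genes)}
    direction = np.zeros(n_g)
    up_genes = {g for s in up_names for g in collection.members(s)}
    down_genes = {g for s in down_names for g in collection.members(s)}
    both = up_genes & down_genes
    if both:
        logger.info("simulate_dataset %s: %d genes in both directions; "
                    "shifts cancel", dataset_id, len(both))
    for g in up_genes - both:
        direction[gene_pos[g]] = 1.0
    for g in down_genes - both:
        direction[gene_pos[g]] = -1.0
    case_cols = slice(design.n_control, n_s)  # controls first, cases after
    values[:, case_cols] += (design.effect_size * direction * sigma)[:, None]

    sample_ids = [f"{dataset_id}_ctrl{i + 1}" for i in range(design.n_control)] \
        + [f"{dataset_id}_case{i + 1}" for i in range(design.n_case)]
    labels = ["control"] * design.n_control + ["case"] * design.n_case
    ds = ExpressionDataset(
        values=pd.DataFrame(values, index=genes, columns=sample_ids),
        phenotype=pd.Series(labels, index=sample_ids),
        case="case", control="control", dataset_id=dataset_id)
    record = dict(up=sorted(up_names), down=sorted(down_names),
                  cancelled_genes=sorted(both))
    return ds, record


def _split_regulated(names: list[str], rng: np.random.Generator,
                     n_up: int, n_down: int):
    picked = list(rng.choice(names, size=n_up + n_down, replace=False))
    return picked[:n_up], picked[n_up:]


def simulate_model_pair(design: SimulationDesign, rho: float | None = None):
    """Two datasets whose truly-regulated sets overlap by the fraction ρ.

    Model A receives ``n_up`` up and ``n_down`` down sets; model B shares
    ``round(ρ·k)`` of each (same direction; a non-integral ρ·k is rounded
    and logged) and draws the remainder from sets unregulated in A (error if
    too few remain). Returns ``(dataset_a, dataset_b, truth_a, truth_b,
    collection)``; the designed profiles are available via
    :func:`truth_profile`.
    """
    if rho is None:
        rho = design.rho
    if not 0 <= rho <= 1:
        raise ValueError("rho must be in [0, 1]")
    collection = make_gene_sets(design)
    rng = _rng(design, 3)
    up_a, down_a = _split_regulated(collection.names, rng,
                                    design.n_up, design.n_down)
    free = [s for s in collection.names if s not in set(up_a) | set(down_a)]

    def pick_b(own: list[str]):
        n_share = rho * len(own)
        if abs(n_share - round(n_share)) > 1e-9:
            logger.info("simulate_model_pair: rho*%d = %.3f rounded to %d",
                        len(own), n_share, round(n_share))
        n_share = int(round(n_share))
        shared = list(rng.choice(own, size=n_share, replace=False))
        return shared, len(own) - n_share

    shared_up, need_up = pick_b(up_a)
    shared_down, need_down = pick_b(down_a)
    if need_up + need_down > len(free):
        raise ValueError(
            f"not enough unregulated sets: need {need_up + need_down}, "
            f"have {len(free)}")
    drawn = list(rng.choice(free, size=need_up + need_down, replace=False))
    up_b = sorted(shared_up + drawn[:need_up])
    down_b = sorted(shared_down + drawn[need_up:])

    ds_a, truth_a = simulate_dataset(design, (up_a, down_a), collection,
                                     dataset_id="modelA", stream=1)
    ds_b, truth_b = simulate_dataset(design, (up_b, down_b), collection,
                                     dataset_id="modelB", stream=2)
    return ds_a, ds_b, truth_a, truth_b, collection


def truth_profile(collection: GeneSetCollection, up, down,
                  dataset_id: str = "truth") -> PathwayStateProfile:
    """Designed three-state profile (NES ±1, q = 0 for regulated sets)."""
    idx = pd.Index(collection.names, name="pathway")
    states = pd.Series("null", index=idx)
    nes = pd.Series(np.nan, index=idx)
    q = pd.Series(np.nan, index=idx)
    for s in up:
        states[s], nes[s], q[s] = "up", 1.0, 0.0
    for s in down:
        states[s], nes[s], q[s] = "down", -1.0, 0.0
    return PathwayStateProfile(dataset_id=dataset_id, states=states,
                               nes=nes, q=q)
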