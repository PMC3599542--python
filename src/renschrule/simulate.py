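"""Synthetic trees, sex-specific trait data and individual-level samples.

The generator emulates the statistical structure of a comparative anuran
body-size dataset with known ground truth:

* a rooted bifurcating tree of ``n_species`` tips (Yule splitting, a
  balanced topology, or user-supplied), with unit or exponential branch
  lengths;
* log10 female snout--vent length evolving by Brownian motion from a
  root value in the anuran-plausible range (default 50 mm);
* log10 male size generated *conditional* on female size through the
  allometric line  log10 M = β·log10 F + c + ε,  ε ~ N(0, residual_sigma²),
  so that ``true_beta`` is exactly the RMA target in the noiseless limit;
* per-species sexual age difference SAD ~ N(age_offset_mean,
  age_offset_sd²) on the log10 scale, optionally fed back into male size
  (``ssd_sad_coupling``) so that SSD and SAD covary;
* individual-level size samples around the species means for the
  species × sex ANOVA.

All draws derive from a single seed via ``numpy.random.SeedSequence``
substreams, so every output is bit-reproducible for a given seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import dendropy
import numpy as np
import pandas as pd

from .phylo import PhyloTree
from .table_io import SpeciesRecord, TraitTable


@dataclass
class SimulationConfig:
    """Knobs of the synthetic comparative dataset.

    Defaults mirror a typical anuran study: 39 species, isometry
    (β = 1), species mean sizes spread around 50 mm SVL, mean adult ages
    of a few years with females slightly older than males, and a
    moderate coupling of SSD to SAD.
    """

    n_species: int = 39
    tree_model: str = "yule"  # yule | balanced
    branch_lengths: str = "unit"  # unit | exponential
    branch_rate: float = 1.0  # rate of the exponential length distribution
    true_beta: float = 1.0  # allometric slope, log10 male on log10 female
    bm_sigma: float = 0.15  # BM rate (log10 size per unit branch length)
    residual_sigma: float = 0.03  # SD of male deviations off the line
    root_log_size: float = math.log10(50.0)  # log10 mm at the root
    mean_log_age: float = math.log10(4.0)  # log10 years, male baseline
    age_sigma: float = 0.15  # SD of log10 male age across species
    age_offset_mean: float = 0.1  # mean SAD (females ~25% older)
    age_offset_sd: float = 0.075  # SD of SAD across species
    ssd_sad_coupling: float = 0.25  # d(SSD)/d(SAD) injected into male size
    ssd_intercept: float = 0.025  # baseline female bias of log10 size
    n_individuals_per_cell: int = 10
    individual_cv: float = 0.05  # CV of individual sizes around the mean
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 3:
            raise ValueError("n_species must be >= 3")
        for name in (
            "bm_sigma",
            "residual_sigma",
            "age_sigma",
            "age_offset_sd",
            "branch_rate",
            "individual_cv",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tree_model not in ("yule", "balanced"):
            raise ValueError(f"unknown tree_model {self.tree_model!r}")
        if self.branch_lengths not in ("unit", "exponential"):
            raise ValueError(f"unknown branch_lengths {self.branch_lengths!r}")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """Latent quantities behind one simulated trait table."""

    true_beta: float
    intercept: float
    ssd_intercept: float
    ssd_sad_coupling: float
    log_female_size: dict[str, float]
    log_male_size: dict[str, float]
    sad: dict[str, float]


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _tip_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"sp{str(i + 1).zfill(width)}" for i in range(n)]


def _branch_length(config: SimulationConfig, rng: np.random.Generator) -> float:
    if config.branch_lengths == "unit":
        return 1.0
    return float(rng.exponential(1.0 / config.branch_rate))


def simulate_tree(config: SimulationConfig) -> PhyloTree:
    """Random rooted bifurcating tree with ``n_species`` named tips.

    ``yule`` grows the tree by splitting a uniformly chosen extant tip
    until the target richness is reached; ``balanced`` recursively halves
    the tip set, giving a maximally balanced shape.  Branch lengths are
    all 1 (``unit``) or iid exponential (``exponential``).  Deterministic
    for a given seed.
    """
    rng = _substreams(config.seed, 4)[0]
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    names = _tip_names(config.n_species)

    def new_leaf() -> dendropy.Node:
        return dendropy.Node()

    if config.tree_model == "balanced":
        def build(k: int) -> dendropy.Node:
            node = dendropy.Node()
            if k == 1:
                return node
            left = build(k // 2)
            right = build(k - k // 2)
            node.add_child(left)
            node.add_child(right)
            return node

        tree.seed_node = build(config.n_species)
    else:  # yule
        root = tree.seed_node
        left, right = new_leaf(), new_leaf()
        root.add_child(left)
        root.add_child(right)
        leaves = [left, right]
        while len(leaves) < config.n_species:
            i = int(rng.integers(len(leaves)))
            node = leaves.pop(i)
            a, b = new_leaf(), new_leaf()
            node.add_child(a)
            node.add_child(b)
            leaves.extend([a, b])

    for name, leaf in zip(names, tree.leaf_node_iter()):
        leaf.taxon = taxa.new_taxon(label=name)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            node.edge.length = None
        else:
            node.edge.length = _branch_length(config, rng)
    return tree


def _iter_preorder_with_parent(
    tree: PhyloTree,
) -> Iterator[tuple[dendropy.Node, dendropy.Node | None]]:
    for node in tree.preorder_node_iter():
        yield node, node.parent_node


def simulate_traits(
    tree: PhyloTree, config: SimulationConfig
) -> tuple[TraitTable, GroundTruth]:
    """Brownian female size plus conditional male size and paired ages.

    Returns sizes in mm and ages in years, together with the latent
    log-scale values and parameters actually used.
    """
    _, rng_bm, rng_male, rng_age = _substreams(config.seed, 4)

    log_f: dict[dendropy.Node, float] = {}
    for node, parent in _iter_preorder_with_parent(tree):
        if parent is None:
            log_f[node] = config.root_log_size
            continue
        bl = node.edge.length if node.edge.length is not None else 1.0
        step = rng_bm.normal(0.0, config.bm_sigma * math.sqrt(bl)) if bl > 0 else 0.0
        log_f[node] = log_f[parent] + step

    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    lf = {leaf.taxon.label: log_f[leaf] for leaf in tree.leaf_node_iter()}

    # intercept keeps male == female size at the root scale, so simulated
    # SVLs stay in a plausible range for any beta
    intercept = (1.0 - config.true_beta) * config.root_log_size
    sad = {name: rng_age.normal(config.age_offset_mean, config.age_offset_sd)
           for name in tips}
    log_male_age = {name: rng_age.normal(config.mean_log_age, config.age_sigma)
                    for name in tips}
    lm = {}
    for name in tips:
        eps = rng_male.normal(0.0, config.residual_sigma)
        lm[name] = (
            config.true_beta * lf[name]
            + intercept
            + eps
            - config.ssd_intercept
            - config.ssd_sad_coupling * sad[name]
        )

    records = []
    for name in tips:
        records.append(
            SpeciesRecord(
                species=name,
                female_size=10.0 ** lf[name],
                male_size=10.0 ** lm[name],
                female_age=10.0 ** (log_male_age[name] + sad[name]),
                male_age=10.0 ** log_male_age[name],
                female_n=config.n_individuals_per_cell,
                male_n=config.n_individuals_per_cell,
            )
        )
    table = TraitTable(records=records, provenance=f"simulated(seed={config.seed})")
    truth = GroundTruth(
        true_beta=config.true_beta,
        intercept=intercept,
        ssd_intercept=config.ssd_intercept,
        ssd_sad_coupling=config.ssd_sad_coupling,
        log_female_size=lf,
        log_male_size=lm,
        sad=sad,
    )
    return table, truth


def simulate_individuals(
    table: TraitTable, config: SimulationConfig
) -> pd.DataFrame:
    """Individual body sizes around each species × sex mean.

    Draws ``n_individuals_per_cell`` sizes per cell from
    N(mean, (cv · mean)²); deterministic for a given seed.
    """
    rng = _substreams(config.seed, 5)[4]
    rows = []
    for rec in table:
        for sex, mean in (("female", rec.female_size), ("male", rec.male_size)):
            draws = rng.normal(
                mean, config.individual_cv * mean, size=config.n_individuals_per_cell
            )
            for value in draws:
                rows.append(
                    {"species": rec.species, "sex": sex, "body_size": float(value)}
                )
    return pd.DataFrame(rows, columns=["species", "sex", "body_size"])
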