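"""Synthetic trees and BGC-style trait tables with known signal.

The generator emulates the statistical structure of genome-collection BGC
surveys: a bifurcating phylogeny of 10^2-10^3 tips, per-class binary
presence with tunable clade-clumping and prevalence, and negative-binomial
counts with genus-level means and overdispersion.  Because the generating
signal is known (random placement, Brownian-threshold, or clades seeded at
a target depth), every downstream statistic can be checked for parameter
recovery without any real data.

One global seed expands into per-stage substreams via
``numpy.random.SeedSequence([seed, stage, index])`` (stage 0 = tree,
stage 1 = binary traits, stage 2 = counts), so each stage is
independently reproducible.
"""

from __future__ import annotations

import json
import random
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .core import Phylogeny, TraitTable
from .signal import brownian_tip_values, threshold_by_prevalence


def _stage_seed(seed: int, stage: int, index: int = 0) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(seed), int(stage), int(index)])


@dataclass
class ClassSpec:
    """Generating recipe for one BGC class."""

    prevalence: float = 0.3
    signal_mode: str = "random"  # random | brownian_threshold | clade_seeded | lambda_bm
    target_depth: float | None = None  # clade_seeded only
    lambda_: float = 1.0  # lambda_bm only
    mean_count: float | dict = 3.0  # scalar or per-genus dict
    theta: float = 2.0  # NB dispersion; > 1e6 means Poisson

    def __post_init__(self):
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must be in (0, 1)")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")


@dataclass
class SimConfig:
    n_tips: int = 256
    tree_model: str = "yule"  # yule | birth_death
    birth: float = 1.0
    death: float = 0.0
    seed: int = 0
    classes: dict = field(default_factory=lambda: {"classA": ClassSpec()})
    n_phyla: int = 2
    n_classes: int = 4
    n_genera: int = 8
    dataset: str = "synthetic"
    clade_noise: float = 0.05


class _Lineage:
    __slots__ = ("blen", "children")

    def __init__(self):
        self.blen = 0.0
        self.children: list[_Lineage] | None = None


def sim_tree(
    n_tips: int,
    model: str = "yule",
    seed: int = 0,
    birth: float = 1.0,
    death: float = 0.0,
) -> Phylogeny:
    """Simulate a bifurcating tree.

    Yule: exponential waiting times at total rate ``birth * k`` with a
    uniformly chosen lineage splitting at each event; a final waiting time
    keeps all pendant branches positive.  Birth-death trees are delegated
    to dendropy's simulator.  The same seed reproduces the identical
    newick string.
    """
    if n_tips < 3:
        raise ValueError("need n_tips >= 3")
    if model == "birth_death":
        if birth <= death:
            raise ValueError("birth rate must exceed death rate")
        dtree = dendropy.model.birthdeath.birth_death_tree(
            birth_rate=birth,
            death_rate=death,
            num_extant_tips=n_tips,
            rng=random.Random(seed),
        )
        for i, leaf in enumerate(dtree.leaf_node_iter()):
            leaf.taxon.label = f"t{i + 1}"
        return Phylogeny.from_dendropy(dtree)
    if model != "yule":
        raise ValueError(f"unknown tree model {model!r}")

    rng = np.random.default_rng(_stage_seed(seed, 0))
    root = _Lineage()
    active = [root]
    while len(active) < n_tips:
        k = len(active)
        t = rng.exponential(1.0 / (birth * k))
        for lin in active:
            lin.blen += t
        i = int(rng.integers(k))
        parent = active[i]
        left, right = _Lineage(), _Lineage()
        parent.children = [left, right]
        active[i : i + 1] = [left, right]
    t = rng.exponential(1.0 / (birth * n_tips))
    for lin in active:
        lin.blen += t

    # flatten to postorder arrays (tips first, in left-to-right order)
    tips: list[_Lineage] = []
    internals: list[_Lineage] = []

    def walk(node: _Lineage):
        if node.children is None:
            tips.append(node)
        else:
            for c in node.children:
                walk(c)
            internals.append(node)

    walk(root)
    order = tips + internals
    index = {id(nd): i for i, nd in enumerate(order)}
    parent = np.full(len(order), -1, dtype=np.int64)
    blen = np.zeros(len(order))
    for nd in order:
        blen[index[id(nd)]] = nd.blen
        if nd.children is not None:
            for c in nd.children:
                parent[index[id(c)]] = index[id(nd)]
    blen[index[id(root)]] = 0.0
    labels = [f"t{i + 1}" for i in range(len(tips))]
    return Phylogeny(parent, blen, labels)


def sim_binary_trait(
    tree: Phylogeny,
    mode: str = "random",
    prevalence: float = 0.3,
    seed: int = 0,
    target_depth: float | None = None,
    noise: float = 0.05,
    lambda_: float = 1.0,
) -> np.ndarray:
    """Binary trait over tips with a chosen generating signal.

    ``random`` places exactly ``round(prevalence * n)`` ones uniformly;
    ``brownian_threshold`` dichotomises a Brownian trait at the same
    prevalence; ``clade_seeded`` fills whole clades whose mean
    root-to-tip depth is closest to ``target_depth`` until the prevalence
    is reached, then flips each tip label with probability ``noise``.
    """
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must be in (0, 1)")
    n = tree.n_tips
    m = int(round(prevalence * n))
    m = min(max(m, 1), n - 1)
    rng = np.random.default_rng(seed)
    if mode == "random":
        trait = np.zeros(n, dtype=np.int64)
        trait[rng.choice(n, size=m, replace=False)] = 1
        return trait
    if mode in ("brownian_threshold", "lambda_bm"):
        x = brownian_tip_values(tree, 1, rng)[:, 0]
        if mode == "lambda_bm" and lambda_ < 1.0:
            # lambda < 1 mixes in an independent tip-specific component
            indep = rng.standard_normal(n) * np.sqrt(tree.depths()[:n])
            x = np.sqrt(lambda_) * x + np.sqrt(1 - lambda_) * indep
        return threshold_by_prevalence(x[:, None], m)[:, 0]
    if mode == "clade_seeded":
        if target_depth is None:
            raise ValueError("clade_seeded requires target_depth")
        nd = tree.mean_node_tip_distance()
        counts = tree.tip_counts()
        cand = sorted(
            (u for u in range(tree.n_tips, tree.n_nodes) if counts[u] >= 2),
            key=lambda u: (abs(nd[u] - target_depth), u),
        )
        trait = np.zeros(n, dtype=np.int64)
        chosen: list[int] = []
        placed = 0
        for u in cand:
            if placed >= m:
                break
            tips = tree.descendant_tips(u)
            if any(trait[t] for t in tips):
                continue  # overlaps / nests with an already seeded clade
            trait[tips] = 1
            chosen.append(u)
            placed += len(tips)
        if placed < m:
            warnings.warn(
                f"clade seeding reached prevalence {placed / n:.3f} < "
                f"{prevalence:.3f}; no disjoint clades left",
                stacklevel=2,
            )
        if noise > 0:
            flip = rng.random(n) < noise
            trait = np.where(flip, 1 - trait, trait)
        if trait.sum() in (0, n):  # noise can degenerate tiny trees
            idx = int(rng.integers(n))
            trait[idx] = 1 - trait[idx]
        return trait
    raise ValueError(f"unknown signal mode {mode!r}")


def assign_taxonomy(
    tree: Phylogeny,
    n_phyla: int = 2,
    n_classes: int = 4,
    n_genera: int = 8,
) -> pd.DataFrame:
    """Map a nested phylum > class > genus taxonomy onto monophyletic clades.

    Each level splits the largest current clade until the requested number
    of groups exists, so genera nest inside classes inside phyla.
    """
    if not (1 <= n_phyla <= n_classes <= n_genera <= tree.n_tips):
        raise ValueError("need 1 <= n_phyla <= n_classes <= n_genera <= n_tips")
    counts = tree.tip_counts()

    def split(nodes: list[int], target: int) -> list[int]:
        nodes = list(nodes)
        while len(nodes) < target:
            internal = [u for u in nodes if u >= tree.n_tips]
            if not internal:
                break
            u = max(internal, key=lambda v: counts[v])
            nodes.remove(u)
            nodes.extend(tree.children[u])
        return sorted(nodes, key=lambda v: min(tree.descendant_tips(v)))

    phyla = split([tree.root], n_phyla)
    classes = split(phyla, n_classes)
    genera = split(classes, n_genera)

    def label_map(nodes: list[int], prefix: str) -> dict[int, str]:
        out = {}
        for i, u in enumerate(nodes):
            for t in tree.descendant_tips(u):
                out[t] = f"{prefix}{i + 1:02d}"
        return out

    pmap = label_map(phyla, "p")
    cmap = label_map(classes, "c")
    gmap = label_map(genera, "g")
    return pd.DataFrame(
        {
            "phylum": [pmap[i] for i in range(tree.n_tips)],
            "class": [cmap[i] for i in range(tree.n_tips)],
            "genus": [gmap[i] for i in range(tree.n_tips)],
        },
        index=list(tree.labels),
    )


def _draw_counts(
    rng: np.random.Generator, mean: np.ndarray, theta: float
) -> np.ndarray:
    if theta > 1e6:
        return rng.poisson(mean)
    p = theta / (theta + mean)
    return rng.negative_binomial(theta, p)


def sim_count_table(
    tree: Phylogeny,
    taxonomy: pd.DataFrame,
    class_specs: dict[str, ClassSpec],
    seed: int = 0,
    dataset: str = "synthetic",
    clade_noise: float = 0.05,
) -> tuple[TraitTable, dict]:
    """Counts table over the tree's tips with per-class known signal.

    Counts are NB(mean_genus, theta) draws multiplied by the binary trait,
    so absent traits are structural zeros.  Returns the table and a truth
    record (per-class mode, prevalence and parameters) for recovery tests.
    """
    genus = taxonomy["genus"].to_numpy()
    data = {}
    truth: dict = {"seed": seed, "dataset": dataset, "classes": {}}
    for i, (name, spec) in enumerate(class_specs.items()):
        tseed = _stage_seed(seed, 1, i)
        trait = sim_binary_trait(
            tree,
            mode=spec.signal_mode,
            prevalence=spec.prevalence,
            seed=tseed,
            target_depth=spec.target_depth,
            noise=clade_noise,
            lambda_=spec.lambda_,
        )
        crng = np.random.default_rng(_stage_seed(seed, 2, i))
        if isinstance(spec.mean_count, dict):
            mean = np.array([spec.mean_count.get(g, 1.0) for g in genus], dtype=float)
        else:
            mean = np.full(tree.n_tips, float(spec.mean_count))
        counts = _draw_counts(crng, mean, spec.theta) * trait
        data[name] = counts
        truth["classes"][name] = {
            "signal_mode": spec.signal_mode,
            "prevalence": spec.prevalence,
            "target_depth": spec.target_depth,
            "theta": spec.theta,
            "realized_prevalence": float(trait.mean()),
        }
    counts_df = pd.DataFrame(data, index=list(tree.labels))
    meta = taxonomy.copy()
    meta.insert(0, "dataset", dataset)
    return TraitTable(counts_df, meta), truth


def simulate(config: SimConfig) -> tuple[Phylogeny, TraitTable, dict]:
    """Run the full generator: tree, taxonomy, counts, truth record."""
    tree = sim_tree(
        config.n_tips,
        model=config.tree_model,
        seed=config.seed,
        birth=config.birth,
        death=config.death,
    )
    taxonomy = assign_taxonomy(
        tree, config.n_phyla, config.n_classes, config.n_genera
    )
    table, truth = sim_count_table(
        tree,
        taxonomy,
        config.classes,
        seed=config.seed,
        dataset=config.dataset,
        clade_noise=config.clade_noise,
    )
    truth["n_tips"] = config.n_tips
    truth["tree_model"] = config.tree_model
    return tree, table, truth


def write_simulation(outdir: str, tree: Phylogeny, table: TraitTable, truth: dict) -> None:
    """Write tree.nwk, counts.tsv, metadata.tsv and truth.json."""
    import os

    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "tree.nwk"), "w") as fh:
        fh.write(tree.to_newick() + "\n")
    table.to_tsv(
        os.path.join(outdir, "counts.tsv"), os.path.join(outdir, "metadata.tsv")
    )
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=2)
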