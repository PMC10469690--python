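"""Genetic depth of trait conservation (consenTRAIT).

For a binary trait over tips, find the *maximal* clades in which at least
``min_fraction`` (default 90%) of descendant tips carry the trait, measure
each clade's depth as the mean path length from the clade root to its
descendant tips, and average those depths into tau_D.  Positive tips
falling outside every qualifying clade are *singletons* and contribute a
constant depth (``singleton_depth``, default 0) when ``count_singletons``
is on.  Larger tau_D means the trait is conserved in deeper clades.

Significance comes from uniform tip-label permutations: conserved traits
give tau_D in the upper tail of the shuffled distribution, so
``p = (1 + #{tau_perm >= tau_obs}) / (n_perm + 1)``.  The full null vector
is kept on the result so the opposite tail is recoverable.

The permutation null is vectorised: one postorder sweep counts positive
tips for all permutation columns at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Phylogeny

_FRAC_TOL = 1e-9  # guards 0.9 * 10 > 9 floating artefacts


@dataclass
class DepthResult:
    trait_name: str
    tau_mean: float
    tau_min: float
    tau_max: float
    clade_depths: np.ndarray
    n_clades: int
    n_singletons: int
    p_value: float
    n_perm: int
    min_fraction: float
    null_taus: np.ndarray | None = None
    #: conventions recorded with the result (depth averaging, tails)
    conventions: dict = field(
        default_factory=lambda: {
            "clade_depth": "mean node-to-tip distance over ALL descendant tips",
            "p_value": "(1 + #{tau_perm >= tau_obs}) / (n_perm + 1)",
        }
    )


def _check_binary(tree: Phylogeny, trait: np.ndarray) -> np.ndarray:
    trait = np.asarray(trait)
    if trait.shape[0] != tree.n_tips:
        raise ValueError("trait length does not match tip count")
    if not np.isin(trait, (0, 1)).all():
        raise ValueError("trait must be binary (0/1)")
    if trait.sum() == 0:
        raise ValueError("tau_D undefined; no positive tips")
    return trait.astype(np.int64)


def positive_clades(
    tree: Phylogeny, trait: np.ndarray, min_fraction: float = 0.9
) -> list[tuple[int, float, int]]:
    """Maximal internal nodes whose positive-tip fraction >= ``min_fraction``.

    Returns ``(node_index, fraction, tip_count)`` triples; qualifying nodes
    nested inside another qualifying node are absorbed by their ancestor.
    Positive tips outside every returned clade are singletons.
    """
    if not (0.0 < min_fraction <= 1.0):
        raise ValueError("min_fraction must be in (0, 1]")
    trait = np.asarray(trait).astype(np.int64)
    counts = tree.tip_counts()
    pos = np.zeros(tree.n_nodes, dtype=np.int64)
    pos[: tree.n_tips] = trait
    for u in range(tree.n_tips, tree.n_nodes):
        pos[u] = sum(pos[c] for c in tree.children[u])
    qualifies = np.zeros(tree.n_nodes, dtype=bool)
    internal = np.arange(tree.n_tips, tree.n_nodes)
    qualifies[internal] = (counts[internal] >= 2) & (
        pos[internal] >= min_fraction * counts[internal] - _FRAC_TOL
    )
    anc = np.zeros(tree.n_nodes, dtype=bool)
    for u in range(tree.n_nodes - 1, tree.n_tips - 1, -1):
        for c in tree.children[u]:
            anc[c] = anc[u] or qualifies[u]
    out = []
    for u in internal:
        if qualifies[u] and not anc[u]:
            out.append((int(u), pos[u] / counts[u], int(counts[u])))
    return out


def _tau_for_columns(
    tree: Phylogeny,
    traits: np.ndarray,
    min_fraction: float,
    count_singletons: bool,
    singleton_depth: float,
    weighted: bool,
    depth_over_positive_only: bool = False,
    singleton_half_branch: bool = False,
) -> np.ndarray:
    """tau_D for each column of an ``(n_tips, k)`` binary matrix.

    Columns with an empty depth set (no clades and singletons not counted,
    or no positive tips) return NaN.
    """
    n_tips, k = traits.shape
    counts = tree.tip_counts()
    depths = tree.depths()
    nd = tree.mean_node_tip_distance()

    pos = np.zeros((tree.n_nodes, k))
    pos[:n_tips] = traits
    if depth_over_positive_only:
        pos_depth_sum = np.zeros((tree.n_nodes, k))
        pos_depth_sum[:n_tips] = traits * depths[:n_tips, None]
    if singleton_half_branch:
        half_blen_sum = np.zeros((tree.n_nodes, k))
        half_blen_sum[:n_tips] = traits * (0.5 * tree.blen[:n_tips, None])
    for u in range(n_tips, tree.n_nodes):
        for c in tree.children[u]:
            pos[u] += pos[c]
            if depth_over_positive_only:
                pos_depth_sum[u] += pos_depth_sum[c]
            if singleton_half_branch:
                half_blen_sum[u] += half_blen_sum[c]

    qualifies = np.zeros((tree.n_nodes, k), dtype=bool)
    for u in range(n_tips, tree.n_nodes):
        if counts[u] >= 2:
            qualifies[u] = pos[u] >= min_fraction * counts[u] - _FRAC_TOL
    anc = np.zeros((tree.n_nodes, k), dtype=bool)
    for u in range(tree.n_nodes - 1, n_tips - 1, -1):
        mask = anc[u] | qualifies[u]
        for c in tree.children[u]:
            anc[c] = mask
    selected = qualifies & ~anc

    if depth_over_positive_only:
        with np.errstate(invalid="ignore", divide="ignore"):
            node_depth = pos_depth_sum / pos - depths[:, None]
        node_depth = np.where(selected, node_depth, 0.0)
    else:
        node_depth = np.where(selected, nd[:, None], 0.0)

    clade_w = (
        counts[:, None] * selected.astype(float)
        if weighted
        else selected.astype(float)
    )
    num = (node_depth * clade_w).sum(axis=0)
    den = clade_w.sum(axis=0)

    total_pos = pos[tree.root]
    covered = np.where(selected, pos, 0.0).sum(axis=0)
    n_single = total_pos - covered
    if count_singletons:
        if singleton_half_branch:
            covered_hb = np.where(selected, half_blen_sum, 0.0).sum(axis=0)
            num += half_blen_sum[tree.root] - covered_hb
        else:
            num += n_single * singleton_depth
        den += n_single  # singleton weight is 1 in both modes
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = num / den
    tau[den == 0] = np.nan
    return tau


def consentrait(
    tree: Phylogeny,
    trait: np.ndarray,
    min_fraction: float = 0.9,
    count_singletons: bool = True,
    singleton_depth: float = 0.0,
    weighted: bool = False,
    n_perm: int = 1000,
    seed: int = 0,
    trait_name: str = "trait",
    depth_over_positive_only: bool = False,
    singleton_half_branch: bool = False,
    keep_null: bool = True,
) -> DepthResult:
    """consenTRAIT tau_D with tip-permutation significance.

    ``depth_over_positive_only`` averages clade depth over positive tips
    only (instead of all descendants); ``singleton_half_branch`` replaces
    the constant singleton depth with half the singleton's terminal branch.
    Both default to off.
    """
    trait = _check_binary(tree, trait)
    rng = np.random.default_rng(seed)
    cols = np.empty((tree.n_tips, 1 + n_perm), dtype=np.int64)
    cols[:, 0] = trait
    for j in range(n_perm):
        cols[:, j + 1] = rng.permutation(trait)
    taus = _tau_for_columns(
        tree,
        cols,
        min_fraction,
        count_singletons,
        singleton_depth,
        weighted,
        depth_over_positive_only,
        singleton_half_branch,
    )
    tau_obs, null = taus[0], taus[1:]

    clades = positive_clades(tree, trait, min_fraction)
    if depth_over_positive_only:
        depths = tree.depths()
        clade_depths = []
        for u, _, _ in clades:
            tips = tree.descendant_tips(u)
            ptips = [t for t in tips if trait[t]]
            clade_depths.append(float(np.mean(depths[ptips]) - depths[u]))
        clade_depths = np.array(clade_depths)
    else:
        nd = tree.mean_node_tip_distance()
        clade_depths = np.array([nd[u] for u, _, _ in clades])
    covered = set()
    for u, _, _ in clades:
        covered.update(tree.descendant_tips(u))
    singles = [t for t in np.flatnonzero(trait) if t not in covered]
    if singleton_half_branch:
        single_depths = [0.5 * tree.blen[t] for t in singles]
    else:
        single_depths = [singleton_depth] * len(singles)

    depth_set = list(clade_depths) + (single_depths if count_singletons else [])
    if depth_set:
        tau_min, tau_max = float(min(depth_set)), float(max(depth_set))
    else:
        tau_min = tau_max = float("nan")

    valid = ~np.isnan(null)
    p = (1 + int((null[valid] >= tau_obs - _FRAC_TOL).sum())) / (n_perm + 1)
    res = DepthResult(
        trait_name=trait_name,
        tau_mean=float(tau_obs),
        tau_min=tau_min,
        tau_max=tau_max,
        clade_depths=clade_depths,
        n_clades=len(clades),
        n_singletons=len(singles),
        p_value=p,
        n_perm=n_perm,
        min_fraction=min_fraction,
        null_taus=null if keep_null else None,
    )
    res.conventions["clade_depth"] = (
        "mean node-to-tip distance over positive tips"
        if depth_over_positive_only
        else "mean node-to-tip distance over ALL descendant tips"
    )
    return res


# ---------------------------------------------------------------------------
# brute-force oracle (tests only)
# ---------------------------------------------------------------------------


def _brute_tau(
    tree: Phylogeny,
    trait: np.ndarray,
    min_fraction: float,
    count_singletons: bool,
    singleton_depth: float,
    weighted: bool,
) -> tuple[float, list[float], int]:
    """Explicit enumeration of every internal node with raw path sums."""
    qualifying = []
    for u in range(tree.n_tips, tree.n_nodes):
        tips = tree.descendant_tips(u)
        if len(tips) < 2:
            continue
        frac = sum(trait[t] for t in tips) / len(tips)
        if frac >= min_fraction - _FRAC_TOL:
            qualifying.append(u)
    qual = set(qualifying)
    maximal = []
    for u in qualifying:
        p = tree.parent[u]
        ancestor_hit = False
        while p != -1:
            if p in qual:
                ancestor_hit = True
                break
            p = tree.parent[p]
        if not ancestor_hit:
            maximal.append(u)

    def path_len(t: int, u: int) -> float:
        total = 0.0
        while t != u:
            total += tree.blen[t]
            t = tree.parent[t]
        return total

    clade_depths, weights, covered = [], [], set()
    for u in maximal:
        tips = tree.descendant_tips(u)
        clade_depths.append(float(np.mean([path_len(t, u) for t in tips])))
        weights.append(len(tips) if weighted else 1.0)
        covered.update(tips)
    singles = [t for t in np.flatnonzero(trait) if t not in covered]
    depths = list(clade_depths)
    if count_singletons:
        depths += [singleton_depth] * len(singles)
        weights += [1.0] * len(singles)
    if not depths:
        return float("nan"), clade_depths, len(singles)
    tau = float(np.average(depths, weights=weights))
    return tau, clade_depths, len(singles)


def consentrait_oracle(
    tree: Phylogeny,
    trait: np.ndarray,
    min_fraction: float = 0.9,
    count_singletons: bool = True,
    singleton_depth: float = 0.0,
    weighted: bool = False,
    n_perm: int = 1000,
    seed: int = 0,
    trait_name: str = "trait",
) -> DepthResult:
    """Same contract as :func:`consentrait`, by exhaustive enumeration.

    Restricted to small trees (<= 14 tips); used as an independent
    cross-check in the test suite.
    """
    if tree.n_tips > 14:
        raise ValueError("oracle restricted to trees with <= 14 tips")
    trait = _check_binary(tree, trait)
    tau_obs, clade_depths, n_single = _brute_tau(
        tree, trait, min_fraction, count_singletons, singleton_depth, weighted
    )
    rng = np.random.default_rng(seed)
    null = np.array(
        [
            _brute_tau(
                tree,
                rng.permutation(trait),
                min_fraction,
                count_singletons,
                singleton_depth,
                weighted,
            )[0]
            for _ in range(n_perm)
        ]
    )
    valid = ~np.isnan(null)
    p = (1 + int((null[valid] >= tau_obs - _FRAC_TOL).sum())) / (n_perm + 1)
    depth_set = list(clade_depths) + (
        [singleton_depth] * n_single if count_singletons else []
    )
    tau_min = float(min(depth_set)) if depth_set else float("nan")
    tau_max = float(max(depth_set)) if depth_set else float("nan")
    return DepthResult(
        trait_name=trait_name,
        tau_mean=tau_obs,
        tau_min=tau_min,
        tau_max=tau_max,
        clade_depths=np.array(clade_depths),
        n_clades=len(clade_depths),
        n_singletons=n_single,
        p_value=p,
        n_perm=n_perm,
        min_fraction=min_fraction,
        null_taus=null,
    )
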