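"""Synthetic trees and efficacy matrices with known clustering structure.

This module is the testing ground for the whole analysis: it simulates a
Yule (pure-birth) species tree partitioned into family-like clades, draws a
"medicinal" subset of tips, and plants per-category communities that are
uniform (null), clade-confined (clustered), or max-min spread
(overdispersed). The planted mode per category is shipped as a truth table
so that recovery by the NRI/NTI machinery can be scored.

Default parameters mirror the structure of a compiled ethnomedicinal study
of a plant order: a pool of several hundred tips in five family-like clades,
roughly a third of tips medicinal, and 15 categories whose prevalences span
~13% to ~79% of the medicinal species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .efficacy_data import CategorySet, EfficacyMatrix, default_categories
from .metrics import CommunitySample
from .treeio import PatristicMatrix, Phylogeny

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "simulate_yule_tree",
    "assign_clades",
    "sample_community",
    "generate_study",
]

MODES = ("null", "clustered", "overdispersed")

#: per-category prevalence among medicinal species, in canonical category
#: order: the printed per-category species counts of the motivating study
#: divided by its 551 medicinal species.
DEFAULT_PREVALENCES = tuple(
    np.array([105, 80, 343, 78, 110, 435, 183, 389, 132, 181, 73, 144, 239, 348, 124])
    / 551.0
)

#: family shares of the medicinal species pool (five species-rich families)
DEFAULT_CLADE_WEIGHTS = (300 / 551, 126 / 551, 69 / 551, 42 / 551, 14 / 551)


@dataclass
class SimConfig:
    """Parameters of one synthetic study.

    Attributes
    ----------
    n_tips : int
        Tips in the species pool (the tree).
    n_clades : int
        Family-like clades cut from the tree (shallowest splits).
    clade_weights : tuple of float
        Target shares of the *medicinal* subset per clade, largest clade
        first; must sum to 1.
    birth_rate : float
        Yule speciation rate (per lineage, per unit time).
    medicinal_fraction : float
        Fraction of tips carrying any medicinal record (matrix rows).
    n_categories : int
    prevalences : tuple of float
        Per-category fraction of medicinal species recorded positive.
    modes : tuple of str
        Per-category generating mode in {"null", "clustered",
        "overdispersed"}.
    clustering_strength : float
        0 = indistinguishable from null, 1 = fully planted.
    seed : int
    """

    n_tips: int = 500
    n_clades: int = 5
    clade_weights: tuple[float, ...] = DEFAULT_CLADE_WEIGHTS
    birth_rate: float = 1.0
    medicinal_fraction: float = 551 / 1519
    n_categories: int = 15
    prevalences: tuple[float, ...] = DEFAULT_PREVALENCES
    modes: tuple[str, ...] = ()
    clustering_strength: float = 1.0
    seed: int = 20220112
    categories: CategorySet | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.modes:
            self.modes = ("null",) * self.n_categories
        if len(self.modes) != self.n_categories:
            raise ValueError("modes length != n_categories")
        if len(self.prevalences) != self.n_categories:
            raise ValueError("prevalences length != n_categories")
        if not all(0 < p < 1 for p in self.prevalences):
            raise ValueError("prevalences must lie in (0, 1)")
        if any(m not in MODES for m in self.modes):
            raise ValueError(f"modes must be in {MODES}")
        if abs(sum(self.clade_weights) - 1.0) > 1e-9:
            raise ValueError("clade weights must sum to 1")
        if len(self.clade_weights) != self.n_clades:
            raise ValueError("clade_weights length != n_clades")
        if not 0 <= self.clustering_strength <= 1:
            raise ValueError("clustering_strength must lie in [0, 1]")
        if self.categories is None:
            if self.n_categories == 15:
                self.categories = default_categories()
            else:
                self.categories = CategorySet(
                    tuple(f"cat_{i + 1:02d}" for i in range(self.n_categories))
                )


def simulate_yule_tree(
    n_tips: int,
    birth_rate: float = 1.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> Phylogeny:
    """Simulate a pure-birth (Yule) tree with ``n_tips`` labelled tips.

    Starting from a single lineage, each of the ``k`` active lineages splits
    at total rate ``k * birth_rate`` (exponential waiting times); the chosen
    lineage is uniform. Simulation stops when ``n_tips`` lineages exist and
    one final waiting interval is appended, so the tree is ultrametric with
    strictly positive terminal branches. Tips are labelled ``t0001`` ...
    in birth order.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    if rng is None:
        rng = np.random.default_rng(seed)

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    birth_time = {id(root): 0.0}
    active = [root]
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        node = active.pop(rng.integers(k))
        node.edge.length = t - birth_time.pop(id(node))
        for _ in range(2):
            child = node.new_child()
            birth_time[id(child)] = t
            active.append(child)
    t += rng.exponential(1.0 / (n_tips * birth_rate))
    width = max(4, len(str(n_tips)))
    for i, node in enumerate(active):
        node.edge.length = t - birth_time[id(node)]
        node.taxon = taxa.new_taxon(label=f"t{i + 1:0{width}d}")
    return Phylogeny(tree)


def assign_clades(tree: Phylogeny, n_clades: int) -> pd.Series:
    """Partition tips into ``n_clades`` family-like groups.

    The groups are the subtrees obtained by repeatedly splitting the
    shallowest current group root, i.e. the ``n_clades`` deepest-coalescing
    clades. Returns a Series mapping tip label -> "clade_1" ... with clades
    numbered by decreasing size.
    """
    if n_clades < 1:
        raise ValueError("n_clades must be >= 1")
    dtree = tree.dendropy_tree
    depth = {id(dtree.seed_node): 0.0}
    for node in dtree.preorder_node_iter():
        if node is not dtree.seed_node:
            depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)
    groups = [dtree.seed_node]
    while len(groups) < n_clades:
        splittable = [g for g in groups if not g.is_leaf()]
        if not splittable:
            break
        node = min(splittable, key=lambda g: depth[id(g)])
        groups.remove(node)
        groups.extend(node.child_nodes())
    tip_sets = [
        sorted(leaf.taxon.label for leaf in g.leaf_iter()) for g in groups
    ]
    tip_sets.sort(key=lambda s: (-len(s), s[0]))
    mapping = {}
    for i, tips in enumerate(tip_sets):
        for lab in tips:
            mapping[lab] = f"clade_{i + 1}"
    return pd.Series(mapping, name="family").loc[list(tree.tip_labels)]


def _clade_nodes_with_size(tree: Phylogeny, pool: set[str]):
    """Internal nodes with their pool-restricted tip sets (root excluded)."""
    dtree = tree.dendropy_tree
    out = []
    for node in dtree.preorder_internal_node_iter():
        if node is dtree.seed_node:
            continue
        tips = [l.taxon.label for l in node.leaf_iter() if l.taxon.label in pool]
        if len(tips) >= 2:
            out.append(tips)
    return out


def _greedy_maxmin(D: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Greedy max-min-distance subset: start from the farthest pair, then
    repeatedly add the point maximising its minimum distance to the set."""
    n = D.shape[0]
    start = np.unravel_index(int(np.argmax(D)), D.shape)
    chosen = [int(start[0]), int(start[1])]
    mind = np.minimum(D[chosen[0]], D[chosen[1]])
    mind[chosen] = -np.inf
    while len(chosen) < k:
        nxt = int(np.argmax(mind))
        chosen.append(nxt)
        mind = np.minimum(mind, D[nxt])
        mind[nxt] = -np.inf
    return np.array(chosen[:k], dtype=np.intp)


def sample_community(
    tree: Phylogeny,
    k: int,
    mode: str = "null",
    strength: float = 1.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    dist: PatristicMatrix | None = None,
    pool: tuple[str, ...] | None = None,
) -> CommunitySample:
    """Draw a k-member community with a known dispersion structure.

    Modes
    -----
    null
        ``k`` tips uniform without replacement.
    clustered
        A random internal clade with at least ``k`` (pool) tips is chosen
        and ``round(strength*k)`` members are drawn inside it, the rest
        uniformly outside; ``strength=1`` confines the community to the
        clade. If no non-root clade is large enough the largest one is used
        and topped up uniformly (logged).
    overdispersed
        ``round(strength*k)`` members by greedy max-min patristic spread,
        the rest uniform.

    ``dist``/``pool`` allow reusing a precomputed distance matrix and
    restricting the eligible tips (e.g. to medicinal species).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be in {MODES}")
    if not 0 <= strength <= 1:
        raise ValueError("strength must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    if dist is None:
        dist = tree.distance_matrix()
    pool_labels = tuple(pool) if pool is not None else dist.labels
    n = len(pool_labels)
    if not 2 <= k < n:
        raise ValueError(f"need 2 <= k < pool size ({k} vs {n})")
    pool_set = set(pool_labels)

    if mode == "null":
        members = rng.choice(n, size=k, replace=False)
        labels = [pool_labels[i] for i in members]
    elif mode == "clustered":
        n_in = int(round(strength * k))
        candidates = [
            tips for tips in _clade_nodes_with_size(tree, pool_set)
            if n_in <= len(tips) < n
        ]
        if not candidates:
            all_clades = [
                t for t in _clade_nodes_with_size(tree, pool_set) if len(t) < n
            ]
            biggest = max(all_clades, key=len) if all_clades else list(pool_labels)
            logger.warning(
                "no clade with >= %d pool tips; using largest (%d) + uniform top-up",
                n_in, len(biggest),
            )
            candidates = [biggest]
            n_in = min(n_in, len(biggest))
        tips = candidates[rng.integers(len(candidates))]
        inside = [tips[i] for i in rng.choice(len(tips), size=n_in, replace=False)]
        outside_pool = [l for l in pool_labels if l not in set(inside)]
        n_out = k - n_in
        outside = [
            outside_pool[i]
            for i in rng.choice(len(outside_pool), size=n_out, replace=False)
        ]
        labels = inside + outside
    else:  # overdispersed
        n_greedy = max(2, int(round(strength * k))) if strength > 0 else 0
        n_greedy = min(n_greedy, k)
        idx_pool = dist.indices_of(pool_labels)
        Dp = dist.d[np.ix_(idx_pool, idx_pool)]
        chosen = list(_greedy_maxmin(Dp, n_greedy, rng)) if n_greedy >= 2 else []
        rest = [i for i in range(n) if i not in set(chosen)]
        extra = rng.choice(len(rest), size=k - len(chosen), replace=False)
        chosen += [rest[i] for i in extra]
        labels = [pool_labels[i] for i in chosen]
    return CommunitySample(tuple(labels), dist)


def generate_study(
    config: SimConfig,
) -> tuple[Phylogeny, EfficacyMatrix, pd.DataFrame]:
    """Generate one full synthetic study.

    Returns the species-pool tree, the medicinal-species efficacy matrix
    (with family-like clade assignments), and a truth table recording each
    category's generating mode, strength and realised community size.
    All-zero rows (medicinal species that drew no category) are given one
    positive in a random null-mode category so every recorded species treats
    something.
    """
    rng = np.random.default_rng(config.seed)
    tree = simulate_yule_tree(config.n_tips, config.birth_rate, rng=rng)
    clades = assign_clades(tree, config.n_clades)
    dist = tree.distance_matrix()

    n_med = int(round(config.medicinal_fraction * config.n_tips))
    n_med = max(4, n_med)
    # medicinal subset per clade, proportional to clade_weights (largest
    # clade paired with largest weight), capped by clade size
    clade_names = sorted(
        clades.unique(), key=lambda c: (-int((clades == c).sum()), c)
    )
    weights = list(config.clade_weights) + [0.0] * (
        len(clade_names) - len(config.clade_weights)
    )
    medicinal: list[str] = []
    targets = {c: w * n_med for c, w in zip(clade_names, weights)}
    remaining = n_med
    for c in clade_names:
        tips = sorted(clades.index[clades == c])
        take = min(len(tips), int(round(targets[c])), remaining)
        take = max(take, 0)
        if take:
            sel = rng.choice(len(tips), size=take, replace=False)
            medicinal.extend(tips[i] for i in sel)
            remaining -= take
    if remaining > 0:  # redistribute shortfall uniformly over unused tips
        unused = sorted(set(tree.tip_labels) - set(medicinal))
        sel = rng.choice(len(unused), size=min(remaining, len(unused)), replace=False)
        medicinal.extend(unused[i] for i in sel)
    medicinal = [l for l in tree.tip_labels if l in set(medicinal)]

    cats = config.categories
    values = pd.DataFrame(
        np.zeros((len(medicinal), len(cats)), dtype=np.int8),
        index=medicinal,
        columns=list(cats),
    )
    truth_rows = []
    for j, (cat, mode, prev) in enumerate(
        zip(cats, config.modes, config.prevalences)
    ):
        k = int(round(prev * len(medicinal)))
        if k < 2:
            raise ValueError(
                f"prevalence {prev} yields community of size {k} < 2 "
                f"for category {cat!r}"
            )
        strength = config.clustering_strength if mode != "null" else 0.0
        comm = sample_community(
            tree, k, mode=mode,
            strength=config.clustering_strength,
            rng=rng, dist=dist, pool=tuple(medicinal),
        )
        values.loc[list(comm.members), cat] = 1
        truth_rows.append(
            {"category": cat, "mode": mode, "strength": strength, "k": k}
        )

    zero = values.sum(axis=1) == 0
    if zero.any():
        null_cats = [c for c, m in zip(cats, config.modes) if m == "null"]
        pick_from = null_cats or list(cats)
        for sp in values.index[zero]:
            values.loc[sp, pick_from[rng.integers(len(pick_from))]] = 1

    matrix = EfficacyMatrix(values, clades.loc[medicinal], cats)
    truth = pd.DataFrame(truth_rows)
    truth["k_realized"] = values.sum(axis=0).to_numpy()
    truth.attrs["seed"] = config.seed
    return tree, matrix, truth
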