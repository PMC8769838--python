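"""Read, write, prune, and measure rooted phylogenies in Newick format.

The in-memory representation wraps a :class:`dendropy.Tree`. Tip labels are
normalised to an underscore form at parse time (``"Coptis chinensis"`` and
``"Coptis_chinensis"`` denote the same tip), because large species-level
supertrees use binomials-with-underscores while tabular data usually carries
spaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "PatristicMatrix",
    "NewickParseError",
    "MissingBranchLengthError",
    "parse_newick",
    "write_newick",
    "prune_to_taxa",
    "patristic_distances",
]


class NewickParseError(ValueError):
    """Malformed Newick input (unbalanced parentheses, duplicate tips, ...)."""


class MissingBranchLengthError(ValueError):
    """A branch length is absent and no unit-length fallback was requested."""


def _normalize_label(label: str) -> str:
    return "_".join(label.strip().split())


@dataclass(frozen=True)
class PatristicMatrix:
    """Symmetric matrix of tip-to-tip path lengths (sums of branch lengths).

    Attributes
    ----------
    labels : tuple of str
        Ordered tip labels; row/column *i* of ``d`` corresponds to
        ``labels[i]``.
    d : numpy.ndarray
        ``(n, n)`` nonnegative array with zero diagonal satisfying the tree
        (four-point implies triangle) metric.
    """

    labels: tuple[str, ...]
    d: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_index", {lab: i for i, lab in enumerate(self.labels)}
        )
        if len(self._index) != len(self.labels):
            raise ValueError("duplicate labels in PatristicMatrix")
        if self.d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")

    @property
    def n(self) -> int:
        return len(self.labels)

    def indices_of(self, labels) -> np.ndarray:
        try:
            return np.array([self._index[lab] for lab in labels], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"label not in pool: {exc.args[0]!r}") from None

    def distance(self, a: str, b: str) -> float:
        return float(self.d[self._index[a], self._index[b]])

    def submatrix(self, labels) -> "PatristicMatrix":
        idx = self.indices_of(labels)
        return PatristicMatrix(tuple(labels), self.d[np.ix_(idx, idx)])


class Phylogeny:
    """A rooted phylogeny with uniquely labelled tips.

    Wraps a dendropy tree; construction validates tip-label uniqueness and
    normalises labels (spaces become underscores). Branch lengths may be
    absent — that is a declared state queried via
    :attr:`has_complete_branch_lengths`, never silently treated as zero.
    """

    def __init__(self, tree: dendropy.Tree):
        tree.is_rooted = True  # first Newick clause is the root
        self._tree = tree
        labels = []
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is None or leaf.taxon.label is None:
                raise NewickParseError("unlabelled tip in tree")
            leaf.taxon.label = _normalize_label(leaf.taxon.label)
            labels.append(leaf.taxon.label)
        seen: set[str] = set()
        dupes = sorted({l for l in labels if l in seen or seen.add(l)})
        if dupes:
            raise NewickParseError(f"duplicate tip labels: {', '.join(dupes)}")
        self._tip_labels = tuple(labels)

    # -- basic structure -------------------------------------------------

    @property
    def tip_labels(self) -> tuple[str, ...]:
        """Tip labels in a stable (postorder-of-parse) order."""
        return self._tip_labels

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    @property
    def has_complete_branch_lengths(self) -> bool:
        """True when every non-root edge carries a length."""
        root = self._tree.seed_node
        return all(
            n.edge.length is not None
            for n in self._tree.preorder_node_iter()
            if n is not root
        )

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def copy(self) -> "Phylogeny":
        return Phylogeny(self._tree.clone(depth=1))

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises several unrelated classes
            raise NewickParseError(str(exc)) from exc
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        with open(path, encoding="utf-8") as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            preserve_spaces=False,
        ).strip() + "\n"

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_newick())

    # -- operations --------------------------------------------------------

    def prune_to(self, keep) -> "Phylogeny":
        """Return the subtree induced by ``keep``.

        Unary nodes created by pruning are suppressed with their branch
        lengths summed, so patristic distances among surviving tips are
        unchanged.
        """
        keep = {_normalize_label(k) for k in keep}
        unknown = sorted(keep - set(self._tip_labels))
        if unknown:
            raise KeyError(
                f"labels not in tree ({len(unknown)}): {', '.join(unknown[:10])}"
            )
        if len(keep) < 2:
            raise ValueError("need at least 2 tips to keep")
        pruned = self._tree.clone(depth=1)
        pruned.retain_taxa_with_labels(sorted(keep))
        return Phylogeny(pruned)

    def distance_matrix(self, unit_branch_lengths: bool = False) -> PatristicMatrix:
        """Patristic (tip-to-tip path length) distances for all tip pairs.

        A single postorder pass fills the matrix: at each internal node the
        cross-child tip blocks are the only pairs whose path crosses that
        node, so every pair is written exactly once.
        """
        if not unit_branch_lengths and not self.has_complete_branch_lengths:
            raise MissingBranchLengthError(
                "tree has edges without branch lengths; pass "
                "unit_branch_lengths=True to assign 1.0 to every edge"
            )
        labels = self._tip_labels
        index = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        D = np.zeros((n, n))
        # per-node: (tip indices below node, their distance to node)
        carry: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                carry[id(node)] = (
                    np.array([index[node.taxon.label]], dtype=np.intp),
                    np.zeros(1),
                )
                continue
            parts = []
            for child in node.child_nodes():
                idx, dist = carry.pop(id(child))
                edge = 1.0 if unit_branch_lengths else child.edge.length
                parts.append((idx, dist + edge))
            for i in range(len(parts)):
                for j in range(i + 1, len(parts)):
                    ia, da = parts[i]
                    ib, db = parts[j]
                    block = da[:, None] + db[None, :]
                    D[np.ix_(ia, ib)] = block
                    D[np.ix_(ib, ia)] = block.T
            carry[id(node)] = (
                np.concatenate([p[0] for p in parts]),
                np.concatenate([p[1] for p in parts]),
            )
        return PatristicMatrix(labels, D)

    def __repr__(self) -> str:
        return f"<Phylogeny with {self.n_tips} tips>"


# ---------------------------------------------------------------------------
# functional façade

def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`."""
    return Phylogeny.from_newick(text)


def write_newick(tree: Phylogeny) -> str:
    """Serialise a :class:`Phylogeny` back to Newick."""
    return tree.to_newick()


def prune_to_taxa(tree: Phylogeny, keep) -> Phylogeny:
    """Prune ``tree`` down to the tips in ``keep`` (distance-preserving)."""
    return tree.prune_to(keep)


def patristic_distances(
    tree: Phylogeny, unit_branch_lengths: bool = False
) -> PatristicMatrix:
    """All pairwise tip-to-tip path-length distances."""
    return tree.distance_matrix(unit_branch_lengths=unit_branch_lengths)
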