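"""iTOL (Interactive Tree of Life) annotation writers.

Two plain-text annotation formats are emitted for upload alongside the
Newick tree: a ``DATASET_BINARY`` block with one ring per disease category
(inner to outer in the canonical category order), and a ``TREE_COLORS``
file painting each family's clade. Output is byte-stable for identical
inputs (no timestamps).
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .efficacy_data import CategorySet, EfficacyMatrix
from .treeio import Phylogeny

logger = logging.getLogger(__name__)

__all__ = [
    "FAMILY_PALETTE",
    "FIELD_COLORS",
    "write_binary_dataset",
    "parse_binary_dataset",
    "write_clade_colors",
]

#: family hues of the motivating figure; others cycle the fallback palette
FAMILY_PALETTE = {
    "Ranunculaceae": "#ffd700",   # yellow
    "Berberidaceae": "#2e8b57",   # green
    "Menispermaceae": "#4169e1",  # blue
    "Lardizabalaceae": "#dc143c", # red
    "Papaveraceae": "#9370db",    # purple
}

_FALLBACK_PALETTE = (
    "#1b9e77", "#d95f02", "#7570b3", "#e7298a", "#66a61e",
    "#e6ab02", "#a6761d", "#666666",
)

#: fixed 15-colour cycle for ring field colours (colour-blind-safe-ish)
FIELD_COLORS = (
    "#332288", "#117733", "#44aa99", "#88ccee", "#ddcc77",
    "#cc6677", "#aa4499", "#882255", "#6699cc", "#661100",
    "#999933", "#888888", "#dd7788", "#225555", "#997700",
)

_BINARY_SHAPE = "2"  # filled circle


def write_binary_dataset(
    matrix: EfficacyMatrix,
    out,
    categories: CategorySet | None = None,
    species: list[str] | None = None,
    label: str = "Therapeutic efficacy",
    absent_as_hidden: bool = True,
) -> Path:
    """Write a DATASET_BINARY annotation with one field per category.

    Presence is coded ``1``; absence is ``-1`` (hidden) by default so the
    rings read as presence marks, or ``0`` (empty shape) when
    ``absent_as_hidden`` is False. ``species`` restricts/orders the data
    lines; species absent from the matrix are skipped with a log message.
    """
    categories = categories or matrix.categories
    if list(categories.ids) != list(matrix.categories.ids):
        raise ValueError("categories do not match the matrix columns")
    absent = "-1" if absent_as_hidden else "0"
    ncat = len(categories)
    colors = [FIELD_COLORS[i % len(FIELD_COLORS)] for i in range(ncat)]
    lines = [
        "DATASET_BINARY",
        "SEPARATOR COMMA",
        f"DATASET_LABEL,{label}",
        "COLOR,#404040",
        "FIELD_SHAPES," + ",".join(_BINARY_SHAPE for _ in range(ncat)),
        "FIELD_LABELS," + ",".join(categories.labels),
        "FIELD_COLORS," + ",".join(colors),
        "DATA",
    ]
    wanted = list(species) if species is not None else list(matrix.species)
    have = set(matrix.species)
    for sp in wanted:
        if sp not in have:
            logger.info("species %s not in matrix; skipped", sp)
            continue
        row = matrix.values.loc[sp]
        cells = ["1" if v else absent for v in row.to_numpy()]
        lines.append(sp + "," + ",".join(cells))
    out = Path(out)
    out.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return out


def parse_binary_dataset(path) -> pd.DataFrame:
    """Read back a DATASET_BINARY file into a 0/1 DataFrame.

    The writer/parser pair round-trips exactly: ``-1``/``0`` both map to 0.
    Field labels become the columns (display labels, not ids).
    """
    labels = None
    rows = {}
    in_data = False
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        if line == "DATA":
            in_data = True
            continue
        if not in_data:
            if line.startswith("FIELD_LABELS,"):
                labels = line.split(",")[1:]
            continue
        parts = line.split(",")
        rows[parts[0]] = [1 if c == "1" else 0 for c in parts[1:]]
    if labels is None:
        raise ValueError("no FIELD_LABELS line found")
    return pd.DataFrame.from_dict(rows, orient="index", columns=labels)


def _family_color(family: str, extra_index: dict) -> str:
    if family in FAMILY_PALETTE:
        return FAMILY_PALETTE[family]
    idx = extra_index.setdefault(family, len(extra_index))
    return _FALLBACK_PALETTE[idx % len(_FALLBACK_PALETTE)]


def _is_monophyletic(
    tree: Phylogeny, tips: set[str], assigned: set[str]
) -> tuple[bool, str]:
    """Check that the MRCA of ``tips`` contains no tip assigned to another
    family (tips with no assignment are allowed inside the span); return
    (flag, 'tipA|tipB' mrca range descriptor)."""
    dtree = tree.dendropy_tree
    taxa = [t for t in dtree.taxon_namespace if t.label in tips]
    mrca = dtree.mrca(taxa=taxa)
    mrca_tips = {l.taxon.label for l in mrca.leaf_iter()}
    spec_tips = sorted(tips)
    ok = (mrca_tips & assigned) <= tips
    return ok, f"{spec_tips[0]}|{spec_tips[-1]}"


def write_clade_colors(
    tree: Phylogeny,
    family_map: pd.Series,
    out,
) -> Path:
    """Write a TREE_COLORS file with one ``range`` line per family clade.

    For a family whose tips are monophyletic in the tree a single range
    line spans the MRCA; otherwise (paraphyly) one range line per tip is
    emitted instead, with a log message.
    """
    fam_map = family_map.dropna()
    covered = [t for t in fam_map.index if t in set(tree.tip_labels)]
    if not covered:
        raise ValueError("family_map covers no tree tip")
    fam_map = fam_map.loc[covered]
    lines = ["TREE_COLORS", "SEPARATOR COMMA", "DATA"]
    extra_index: dict = {}
    assigned = set(fam_map.index)
    for fam in sorted(fam_map.unique()):
        tips = set(fam_map.index[fam_map == fam])
        color = _family_color(fam, extra_index)
        if len(tips) == 1:
            lines.append(f"{next(iter(tips))},range,{color},{fam}")
            continue
        mono, span = _is_monophyletic(tree, tips, assigned)
        if mono:
            lines.append(f"{span},range,{color},{fam}")
        else:
            logger.warning(
                "family %s is not monophyletic in the tree; "
                "emitting %d per-tip range lines", fam, len(tips)
            )
            for tip in sorted(tips):
                lines.append(f"{tip},range,{color},{fam}")
    out = Path(out)
    out.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return out
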