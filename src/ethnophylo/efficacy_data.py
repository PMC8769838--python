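"""Binary species x therapeutic-category matrices and name reconciliation.

An :class:`EfficacyMatrix` codes, for each medicinal species, which of a
fixed set of disease categories it is recorded as treating (1) or not (0).
Each category column thus defines one "community" of species, the unit on
which phylogenetic dispersion is later scored.

Species names from compiled ethnobotanical tables rarely match tree tip
labels verbatim (authority strings, spacing, infraspecific ranks), so this
module also owns the normalisation and matching rules.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .treeio import Phylogeny

logger = logging.getLogger(__name__)

__all__ = [
    "CategorySet",
    "EfficacyMatrix",
    "NameMatchReport",
    "default_categories",
    "read_efficacy_table",
    "normalize_name",
    "match_taxa",
]

#: infraspecific rank tokens recognised during name normalisation
_RANK_TOKENS = {
    "var": "var.",
    "var.": "var.",
    "subsp": "subsp.",
    "subsp.": "subsp.",
    "ssp": "subsp.",
    "ssp.": "subsp.",
    "f": "f.",
    "f.": "f.",
    "subvar": "subvar.",
    "subvar.": "subvar.",
}

_SPECIES_COLUMN_ALIASES = {"species", "name", "taxon", "scientific_name"}
_FAMILY_COLUMN_ALIASES = {"family"}


@dataclass(frozen=True)
class CategorySet:
    """Ordered disease-category identifiers.

    Order is load-bearing: it fixes table row order and the inner-to-outer
    order of the binary rings in tree visualisations.
    """

    ids: tuple[str, ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("category ids must be unique")
        if not self.labels:
            object.__setattr__(self, "labels", self.ids)
        elif len(self.labels) != len(self.ids):
            raise ValueError("labels and ids length mismatch")

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(self.ids)

    def label_of(self, cat_id: str) -> str:
        return self.labels[self.ids.index(cat_id)]


def default_categories() -> CategorySet:
    """The 15 canonical organ-system categories, in ring order."""
    text = resources.files("ethnophylo.data").joinpath("categories.json").read_text()
    defn = json.loads(text)
    return CategorySet(
        ids=tuple(c["id"] for c in defn["categories"]),
        labels=tuple(c["label"] for c in defn["categories"]),
    )


def normalize_name(raw: str) -> str:
    """Normalise a taxon name to the canonical underscore form.

    Genus is capitalised, epithets lower-cased, infraspecific rank tokens
    (``var.``, ``subsp.``, ``f.``) kept with their epithet, and trailing
    authority strings (capitalised tokens or parenthesised basionym authors
    after the epithet) stripped. Idempotent.

    >>> normalize_name("Coptis chinensis Franch.")
    'Coptis_chinensis'
    >>> normalize_name("anemone rivularis var. flore-minore")
    'Anemone_rivularis_var._flore-minore'
    """
    if not isinstance(raw, str):
        raise ValueError("taxon name must be a string")
    tokens = raw.replace("_", " ").split()
    if not tokens:
        raise ValueError("empty taxon name")
    out = [tokens[0][:1].upper() + tokens[0][1:].lower()]
    i = 1
    expect_epithet = True  # next non-rank token is a (lowercase) epithet
    while i < len(tokens):
        tok = tokens[i]
        low = tok.lower()
        if low in _RANK_TOKENS:
            out.append(_RANK_TOKENS[low])
            if i + 1 < len(tokens):
                out.append(tokens[i + 1].lower())
                i += 2
            else:
                i += 1
            expect_epithet = False
            continue
        if expect_epithet:
            out.append(low)
            expect_epithet = False
            i += 1
            continue
        # authority or anything else after the epithet: stop
        break
    return "_".join(out)


def binomial_of(name: str) -> str:
    """Parent binomial of a normalised (possibly infraspecific) name."""
    parts = name.split("_")
    return "_".join(parts[:2]) if len(parts) >= 2 else name


class EfficacyMatrix:
    """Species x category binary table with optional family assignments.

    Parameters
    ----------
    values : pandas.DataFrame
        Index = species names (unique), columns = category ids, entries in
        {0, 1}.
    families : pandas.Series, optional
        Family per species, aligned with ``values.index``.
    """

    def __init__(self, values: pd.DataFrame, families: pd.Series | None = None,
                 categories: CategorySet | None = None):
        vals = values.astype(np.int8)
        bad = ~vals.isin([0, 1]).to_numpy()
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary entry at species {vals.index[r]!r}, "
                f"category {vals.columns[c]!r}"
            )
        if vals.index.duplicated().any():
            raise ValueError("duplicate species after deduplication")
        self.values = vals
        self.categories = categories or CategorySet(tuple(vals.columns))
        if list(self.categories.ids) != list(vals.columns):
            raise ValueError("column order does not match category order")
        if families is not None:
            families = families.reindex(vals.index)
        self.families = families
        zero = vals.sum(axis=1) == 0
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} species with no positive category "
                f"(e.g. {vals.index[zero][0]!r}); a recorded medicinal "
                "species should treat something",
                stacklevel=2,
            )

    # -- structure ---------------------------------------------------------

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def n_species(self) -> int:
        return len(self.values)

    def members_of(self, category: str) -> tuple[str, ...]:
        """Species recorded as treating ``category`` (the community)."""
        col = self.values[category]
        return tuple(col.index[col == 1])

    def column_sums(self) -> pd.Series:
        return self.values.sum(axis=0)

    def row_sums(self) -> pd.Series:
        return self.values.sum(axis=1)

    def restrict(self, species) -> "EfficacyMatrix":
        keep = [s for s in self.values.index if s in set(species)]
        fam = self.families.loc[keep] if self.families is not None else None
        return EfficacyMatrix(self.values.loc[keep], fam, self.categories)

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path) -> None:
        df = self.values.copy()
        if self.families is not None:
            df.insert(0, "family", self.families)
        df.index.name = "species"
        df.to_csv(path)

    def __repr__(self) -> str:
        return (
            f"<EfficacyMatrix {self.n_species} species x "
            f"{len(self.categories)} categories>"
        )


@dataclass
class NameMatchReport:
    """Accounting of species-to-tip matching; every input species appears."""

    matched: list[tuple[str, str]] = field(default_factory=list)
    unmatched: list[str] = field(default_factory=list)
    normalized: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_matched(self) -> int:
        return len(self.matched)

    @property
    def n_unmatched(self) -> int:
        return len(self.unmatched)

    @property
    def n_total(self) -> int:
        return self.n_matched + self.n_unmatched

    def summary(self) -> str:
        lines = [
            f"matched  : {self.n_matched}/{self.n_total}",
            f"unmatched: {self.n_unmatched}",
            f"renamed  : {len(self.normalized)}",
        ]
        for name in self.unmatched[:20]:
            lines.append(f"  missing from tree: {name}")
        if self.n_unmatched > 20:
            lines.append(f"  ... and {self.n_unmatched - 20} more")
        return "\n".join(lines)


def _or_merge(values: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Merge duplicate species rows by elementwise OR (order-independent)."""
    dup = values.index.duplicated(keep=False)
    n_dup = int(values.index[dup].nunique())
    if n_dup == 0:
        return values, 0
    merged = values.groupby(level=0, sort=False).max()
    # groupby(sort=False) keeps first-appearance order
    return merged, n_dup


def read_efficacy_table(
    path,
    categories: CategorySet | None = None,
    truthy: frozenset[str] = frozenset({"1"}),
    falsy: frozenset[str] = frozenset({"0"}),
    sep: str | None = None,
) -> EfficacyMatrix:
    """Read a delimited species x category table into an :class:`EfficacyMatrix`.

    The header must contain a species column (``species``/``name``/``taxon``),
    optionally a ``family`` column, and one column per category id. Duplicate
    species rows are OR-merged with a warning; cells must parse as binary
    under the configured truthy/falsy token sets.
    """
    categories = categories or default_categories()
    df = pd.read_csv(path, sep=sep, dtype=str, engine="python")
    df.columns = [c.strip() for c in df.columns]
    sp_col = next((c for c in df.columns if c.lower() in _SPECIES_COLUMN_ALIASES), None)
    if sp_col is None:
        raise ValueError(f"no species column found among {list(df.columns)}")
    fam_col = next((c for c in df.columns if c.lower() in _FAMILY_COLUMN_ALIASES), None)
    known = {sp_col, fam_col} | set(categories.ids)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise ValueError(f"unknown category column(s): {unknown}")
    missing = [c for c in categories.ids if c not in df.columns]
    if missing:
        raise ValueError(f"missing category column(s): {missing}")

    # whitespace-to-underscore only; case/authority normalisation is the
    # matching step's job (tip labels like "t0001" must survive verbatim)
    def _tidy(s: str) -> str:
        if not str(s).strip():
            raise ValueError("empty species name in table")
        return "_".join(str(s).split())

    species = df[sp_col].map(_tidy)
    vals = pd.DataFrame(index=species)
    for cat in categories.ids:
        col = df[cat].str.strip()
        ok_true = col.isin(truthy)
        ok_false = col.isin(falsy)
        bad = ~(ok_true | ok_false)
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise ValueError(
                f"non-binary cell {col.iloc[row]!r} at row {row + 2}, "
                f"column {cat!r}"
            )
        vals[cat] = ok_true.astype(np.int8).to_numpy()
    merged, n_dup = _or_merge(vals)
    if n_dup:
        warnings.warn(
            f"{n_dup} duplicate species row(s) OR-merged", stacklevel=2
        )
    families = None
    if fam_col is not None:
        fam = pd.Series(df[fam_col].to_numpy(), index=species)
        families = fam.groupby(level=0, sort=False).first()
    return EfficacyMatrix(merged, families, categories)


def match_taxa(
    matrix: EfficacyMatrix,
    tree: Phylogeny,
    fallback_to_species: bool = False,
) -> tuple[EfficacyMatrix, NameMatchReport]:
    """Reconcile matrix species names with tree tips.

    Direct (normalised) matches are kept. With ``fallback_to_species``,
    infraspecific taxa whose exact name is absent are OR-merged into their
    parent binomial when that binomial is a tip; otherwise unmatched species
    are dropped. The report accounts for every input species.
    """
    tips = set(tree.tip_labels)
    report = NameMatchReport()
    rows: dict[str, np.ndarray] = {}
    fams: dict[str, object] = {}
    for sp in matrix.species:
        target = None
        if sp in tips:  # verbatim match wins; normalisation never breaks it
            norm = sp
        else:
            norm = normalize_name(sp)
            if norm != sp:
                report.normalized.append((sp, norm))
        if norm in tips:
            target = norm
        elif fallback_to_species:
            parent = binomial_of(norm)
            if parent != norm and parent in tips:
                target = parent
        if target is None:
            report.unmatched.append(sp)
            continue
        report.matched.append((sp, target))
        row = matrix.values.loc[sp].to_numpy()
        if target in rows:
            rows[target] = np.maximum(rows[target], row)
            logger.info("OR-merged %s into tip %s", sp, target)
        else:
            rows[target] = row
            if matrix.families is not None:
                fams[target] = matrix.families.loc[sp]
    if not rows:
        raise ValueError(
            "no species matched any tree tip — wrong tree or wrong "
            "name normalisation?"
        )
    values = pd.DataFrame.from_dict(rows, orient="index", columns=list(matrix.categories))
    families = pd.Series(fams) if fams else None
    return EfficacyMatrix(values, families, matrix.categories), report
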