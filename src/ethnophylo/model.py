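"""Model/Results interface for phylogenetic dispersion of therapeutic efficacy.

:class:`PhylogeneticDispersionModel` binds a phylogeny to a binary species x
category efficacy matrix within an analysis scope (a plant order, or one
family). ``fit()`` runs the permutation machinery for every category and
returns a :class:`DispersionResults` carrying the per-category NRI/NTI
estimates, their permutation p-values, community sizes and a printable
summary table.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .efficacy_data import EfficacyMatrix, NameMatchReport, match_taxa
from .metrics import CommunitySample, SESResult, ses_metric
from .treeio import PatristicMatrix, Phylogeny

__all__ = [
    "AnalysisScope",
    "PhylogeneticDispersionModel",
    "DispersionResults",
    "DEFAULT_SEED",
    "DEFAULT_RUNS",
]

#: pipeline-wide defaults, fixed and recorded in every manifest
DEFAULT_SEED = 20220112
DEFAULT_RUNS = 999

POOL_POLICIES = ("all_tree_tips", "medicinal_only")


@dataclass(frozen=True)
class AnalysisScope:
    """A named analysis scope: which tips form the null-model pool.

    ``members=None`` means the whole supplied tree. For a family-level
    scope the members are usually the family's species from the efficacy
    matrix; a caller holding the family's complete tip list in the tree may
    supply it instead to widen the pool.
    """

    name: str = "order"
    members: tuple[str, ...] | None = None
    pool_policy: str = "all_tree_tips"

    def __post_init__(self) -> None:
        if self.pool_policy not in POOL_POLICIES:
            raise ValueError(f"pool_policy must be in {POOL_POLICIES}")


def _category_seed(seed: int, scope_name: str, category: str, metric: str):
    """Deterministic per-(scope, category, metric) seed stream."""
    return np.random.SeedSequence(
        entropy=[
            int(seed),
            zlib.crc32(scope_name.encode()) & 0x7FFFFFFF,
            zlib.crc32(category.encode()) & 0x7FFFFFFF,
            0 if metric == "mpd" else 1,
        ]
    )


class PhylogeneticDispersionModel:
    """Per-category phylogenetic dispersion (NRI/NTI) of efficacy data.

    Parameters
    ----------
    tree : Phylogeny
        The reference phylogeny (already pruned to the taxonomic scope of
        the study, e.g. one plant order).
    matrix : EfficacyMatrix
        Binary species x category table; species names are reconciled with
        tree tips on construction (unmatched species are dropped with a
        report).
    scope : AnalysisScope, optional
        Restriction to a named subset (e.g. one family). Default: the
        whole tree.
    fallback_to_species : bool
        Map infraspecific names without their own tip onto the parent
        binomial (OR-merging records) instead of dropping them.
    """

    def __init__(
        self,
        tree: Phylogeny,
        matrix: EfficacyMatrix,
        scope: AnalysisScope | None = None,
        fallback_to_species: bool = False,
    ):
        self.scope = scope or AnalysisScope()
        self.categories = matrix.categories
        matched, report = match_taxa(
            matrix, tree, fallback_to_species=fallback_to_species
        )
        self.match_report: NameMatchReport = report

        if self.scope.members is not None:
            member_set = {m for m in self.scope.members}
            pool_tips = [t for t in tree.tip_labels if t in member_set]
        else:
            pool_tips = list(tree.tip_labels)
        matched = matched.restrict(pool_tips)
        if matched.n_species == 0:
            raise ValueError(f"no matched species inside scope {self.scope.name!r}")
        if self.scope.pool_policy == "medicinal_only":
            pool_tips = [t for t in pool_tips if t in set(matched.species)]
        if len(pool_tips) < 2:
            raise ValueError("pool must contain at least 2 tips")
        self.tree = tree.prune_to(pool_tips) if len(pool_tips) < tree.n_tips else tree
        self.matrix = matched
        self.dist: PatristicMatrix = self.tree.distance_matrix()

    @classmethod
    def from_files(
        cls,
        tree_path,
        matrix_path,
        scope: AnalysisScope | None = None,
        fallback_to_species: bool = False,
    ) -> "PhylogeneticDispersionModel":
        from .efficacy_data import read_efficacy_table

        return cls(
            Phylogeny.from_file(tree_path),
            read_efficacy_table(matrix_path),
            scope=scope,
            fallback_to_species=fallback_to_species,
        )

    @classmethod
    def from_dataframe(
        cls,
        tree: Phylogeny,
        values: pd.DataFrame,
        families: pd.Series | None = None,
        **kwargs,
    ) -> "PhylogeneticDispersionModel":
        return cls(tree, EfficacyMatrix(values, families), **kwargs)

    @property
    def n_pool(self) -> int:
        return self.dist.n

    def community(self, category: str) -> CommunitySample:
        members = tuple(
            m for m in self.matrix.members_of(category)
            if m in set(self.dist.labels)
        )
        return CommunitySample(members, self.dist)

    def fit(
        self, runs: int = DEFAULT_RUNS, seed: int = DEFAULT_SEED
    ) -> "DispersionResults":
        """Compute NRI and NTI with permutation p-values for every category.

        Categories with fewer than two member species in scope get a row of
        NAs with the true count (so every table has all categories); a
        degenerate null (community == pool) likewise yields NA indices.
        """
        rows = []
        details: dict[tuple[str, str], SESResult] = {}
        any_evaluated = False
        for cat in self.categories:
            comm = self.community(cat)
            n = comm.k
            row = {
                "category": cat,
                "NRI": np.nan, "p_NRI": np.nan,
                "NTI": np.nan, "p_NTI": np.nan,
                "n_species": n,
                "NRI_significant": False,
                "NTI_significant": False,
            }
            if n >= 2:
                any_evaluated = True
                for metric, index, pcol in (
                    ("mpd", "NRI", "p_NRI"),
                    ("mntd", "NTI", "p_NTI"),
                ):
                    res = ses_metric(
                        comm, metric=metric, runs=runs,
                        seed=_category_seed(seed, self.scope.name, cat, metric),
                    )
                    details[(cat, metric)] = res
                    if not res.degenerate:
                        row[index] = res.ses
                        row[pcol] = res.p_value
                        row[f"{index}_significant"] = res.significant
            rows.append(row)
        if not any_evaluated:
            raise ValueError(
                "no category had >= 2 member species in this scope"
            )
        table = pd.DataFrame(rows).set_index("category")
        return DispersionResults(self, table, details, runs=runs, seed=seed)


class DispersionResults:
    """Fitted per-category dispersion indices for one analysis scope."""

    def __init__(self, model, summary_table, details, runs, seed):
        self.model = model
        self.summary_table: pd.DataFrame = summary_table
        self.details = details
        self.runs = runs
        self.seed = seed

    @property
    def scope_name(self) -> str:
        return self.model.scope.name

    @property
    def n_pool(self) -> int:
        return self.model.n_pool

    def ses(self, category: str, metric: str) -> SESResult:
        """Full SES detail (obs, null mean/sd, rank) for one cell."""
        return self.details[(category, metric)]

    def summary(self) -> str:
        """Printable per-category table in the standard layout."""
        labels = self.model.categories.labels
        lines = [
            f"Phylogenetic dispersion of therapeutic efficacy "
            f"[scope: {self.scope_name}]",
            f"pool = {self.n_pool} tips, "
            f"{self.model.matrix.n_species} medicinal species, "
            f"runs = {self.runs}, seed = {self.seed}, "
            f"pool policy = {self.model.scope.pool_policy}",
            "",
            f"{'Disease category':<30}{'NRI':>10}{'p':>9}"
            f"{'NTI':>10}{'p':>9}{'N':>6}",
        ]
        for (cat, row), label in zip(self.summary_table.iterrows(), labels):
            def fmt(x, prec):
                return "NA".rjust(prec[0]) if pd.isna(x) else f"{x:>{prec[0]}.{prec[1]}f}"

            star_nri = "*" if row["NRI_significant"] else " "
            star_nti = "*" if row["NTI_significant"] else " "
            lines.append(
                f"{label:<30}{fmt(row['NRI'], (9, 4))}{star_nri}"
                f"{fmt(row['p_NRI'], (8, 3))}{star_nri}"
                f"{fmt(row['NTI'], (9, 4))}{star_nti}"
                f"{fmt(row['p_NTI'], (8, 3))}{star_nti}"
                f"{int(row['n_species']):>6}"
            )
        lines.append("")
        lines.append("* p < 0.05 (one-tailed, lower = clustered)")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.summary_table.to_csv(path)

    def plot(self, ax=None):
        """Horizontal bar chart of NRI and NTI per category."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 6))
        t = self.summary_table
        y = np.arange(len(t))
        ax.barh(y - 0.2, t["NRI"], height=0.38, label="NRI", color="#4477aa")
        ax.barh(y + 0.2, t["NTI"], height=0.38, label="NTI", color="#ee6677")
        ax.set_yticks(y, [self.model.categories.label_of(c) for c in t.index])
        ax.axvline(0.0, color="k", lw=0.8)
        ax.set_xlabel("standardized effect size (positive = clustered)")
        ax.set_title(f"scope: {self.scope_name}")
        ax.legend()
        ax.invert_yaxis()
        return ax

    def __repr__(self) -> str:
        return (
            f"<DispersionResults scope={self.scope_name!r} "
            f"categories={len(self.summary_table)} runs={self.runs}>"
        )
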