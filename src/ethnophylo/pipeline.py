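"""Orchestration of the full study: per-scope dispersion tables, species
counts, multipurpose species, and a reproducibility manifest.

The heavy lifting lives in :mod:`ethnophylo.model`; these functions are the
batch surface used by the command-line tool and by scripted analyses.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .efficacy_data import EfficacyMatrix, NameMatchReport
from .model import (
    DEFAULT_RUNS,
    DEFAULT_SEED,
    AnalysisScope,
    DispersionResults,
    PhylogeneticDispersionModel,
)
from .treeio import Phylogeny

__all__ = [
    "AnalysisScope",
    "StudyResult",
    "run_scope",
    "count_species_per_category",
    "find_multipurpose",
    "run_study",
]


def run_scope(
    tree: Phylogeny,
    matrix: EfficacyMatrix,
    scope: AnalysisScope | None = None,
    runs: int = DEFAULT_RUNS,
    seed: int = DEFAULT_SEED,
    fallback_to_species: bool = False,
) -> DispersionResults:
    """Fit one scope: NRI/NTI with p-values for every category.

    Categories with fewer than two species in scope yield NA rows carrying
    the true count, so the table always has one row per category.
    """
    model = PhylogeneticDispersionModel(
        tree, matrix, scope=scope, fallback_to_species=fallback_to_species
    )
    return model.fit(runs=runs, seed=seed)


def count_species_per_category(
    matrix: EfficacyMatrix, scope_members=None
) -> pd.DataFrame:
    """Species count and percentage per category (columns ``count``, ``pct``).

    Percentages are relative to the number of species in scope, reported to
    one decimal.
    """
    m = matrix if scope_members is None else matrix.restrict(scope_members)
    counts = m.column_sums()
    total = m.n_species
    pct = (counts / total * 100).round(1) if total else counts * np.nan
    return pd.DataFrame({"count": counts.astype(int), "pct": pct})


def find_multipurpose(matrix: EfficacyMatrix, threshold: int = 10) -> pd.DataFrame:
    """Species treating at least ``threshold`` categories, most versatile
    first (ties broken by name); columns ``species``, ``n_categories``."""
    if not 1 <= threshold <= len(matrix.categories):
        raise ValueError(
            f"threshold must lie in [1, {len(matrix.categories)}], got {threshold}"
        )
    sums = matrix.row_sums()
    hits = sums[sums >= threshold]
    out = (
        pd.DataFrame({"species": hits.index, "n_categories": hits.to_numpy()})
        .sort_values(["n_categories", "species"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return out


@dataclass
class StudyResult:
    """Bundle of one full study run (order scope + per-family scopes)."""

    order: DispersionResults
    families: dict[str, DispersionResults]
    multipurpose: pd.DataFrame
    match_report: NameMatchReport
    manifest: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        """Write per-scope CSV tables, the multipurpose table, the manifest
        and a plain-text log under ``outdir``."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.order.to_csv(out / "summary_order.csv")
        for fam, res in self.families.items():
            res.to_csv(out / f"summary_family_{fam}.csv")
        self.multipurpose.to_csv(out / "multipurpose.csv", index=False)
        (out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True) + "\n"
        )
        log_lines = [self.match_report.summary(), "", self.order.summary()]
        for res in self.families.values():
            log_lines += ["", res.summary()]
        (out / "run.log").write_text("\n".join(log_lines) + "\n")


def _digest(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def run_study(
    tree: Phylogeny,
    matrix: EfficacyMatrix,
    runs: int = DEFAULT_RUNS,
    seed: int = DEFAULT_SEED,
    pool_policy: str = "all_tree_tips",
    threshold: int = 10,
    family_scopes: bool = True,
    fallback_to_species: bool = False,
) -> StudyResult:
    """Run the order-level analysis and, when family assignments exist, one
    family-scoped rerun per family with at least two matched species.

    The manifest records seed, runs, versions and input digests; a rerun
    with the same inputs and manifest parameters reproduces every output
    table bitwise.
    """
    order_scope = AnalysisScope(name="order", pool_policy=pool_policy)
    try:
        order = run_scope(
            tree, matrix, order_scope, runs=runs, seed=seed,
            fallback_to_species=fallback_to_species,
        )
    except ValueError as exc:
        raise ValueError(f"[order scope] {exc}") from exc

    families: dict[str, DispersionResults] = {}
    matched = order.model.matrix
    if family_scopes and matched.families is not None:
        for fam in sorted(matched.families.dropna().unique()):
            members = tuple(
                matched.families.index[matched.families == fam]
            )
            if len(members) < 2:
                continue
            scope = AnalysisScope(
                name=f"family:{fam}", members=members, pool_policy=pool_policy
            )
            try:
                families[fam] = run_scope(
                    tree, matrix, scope, runs=runs, seed=seed,
                    fallback_to_species=fallback_to_species,
                )
            except ValueError as exc:
                raise ValueError(f"[family scope {fam}] {exc}") from exc

    multipurpose = find_multipurpose(matched, threshold=threshold)
    manifest = {
        "package": "ethnophylo",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "runs": runs,
        "seed": seed,
        "pool_policy": pool_policy,
        "threshold": threshold,
        "n_tree_tips": tree.n_tips,
        "n_species_input": matrix.n_species,
        "n_species_matched": matched.n_species,
        "tree_sha256": _digest(tree.to_newick().encode()),
        "matrix_sha256": _digest(
            matrix.values.to_csv().encode()
        ),
        "scopes": ["order"] + sorted(families),
    }
    return StudyResult(
        order, families, multipurpose, order.model.match_report, manifest
    )
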