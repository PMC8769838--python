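"""Phylogenetic dispersion metrics: MPD, MNTD, and their standardized
effect sizes (NRI, NTI) under a taxa-label permutation null.

Model
-----
A *community* is a subset of the tips of a reference pool (here: the species
recorded as treating one disease category, inside a pruned order- or
family-level tree). Two distance summaries are scored:

* MPD — mean patristic distance over all unordered pairs of members; basal
  (root-ward) signal.
* MNTD — mean distance from each member to its nearest other member;
  terminal (tip-ward) signal.

The null model shuffles the tip labels of the pool's distance matrix while
holding community size fixed, which is equivalent to drawing ``k`` tips from
the pool uniformly without replacement on each of ``runs`` draws. The
standardized effect size is the sign-flipped z-score

    NRI = -1 x (MPD_obs - mean(MPD_null)) / sd(MPD_null)

(and NTI likewise from MNTD), so positive values mean the community is more
phylogenetically clustered than expected. The one-tailed p-value is the
midrank of the observed value among {obs} U null, divided by (runs + 1);
small p means clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .treeio import PatristicMatrix

__all__ = [
    "CommunitySample",
    "NullDistribution",
    "SESResult",
    "mpd",
    "mntd",
    "ses_metric",
    "p_from_rank",
]

_METRICS = ("mpd", "mntd")

# cap on elements of the (runs, k, k) gather to bound peak memory
_CHUNK_ELEMENTS = 40_000_000


@dataclass(frozen=True)
class CommunitySample:
    """A community (tip subset) evaluated against a reference pool."""

    members: tuple[str, ...]
    pool: PatristicMatrix

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError("duplicate community members")
        self.pool.indices_of(self.members)  # raises on unknown label

    @property
    def k(self) -> int:
        return len(self.members)

    @property
    def indices(self) -> np.ndarray:
        return self.pool.indices_of(self.members)


@dataclass(frozen=True)
class NullDistribution:
    """Metric values under the label-permutation null."""

    values: np.ndarray
    runs: int
    seed: object

    def __post_init__(self) -> None:
        if len(self.values) != self.runs:
            raise ValueError("null length != runs")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite null values")

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        # ddof=1 matches R's sd(), the convention of the reference
        # community-phylogenetics implementations
        return float(np.std(self.values, ddof=1))


@dataclass(frozen=True)
class SESResult:
    """Observed metric, null summary, standardized effect size and p-value.

    ``ses`` is the NRI when ``metric == "mpd"`` and the NTI when
    ``metric == "mntd"``; it is NaN when the null is degenerate
    (``null_sd == 0``, e.g. community == pool).
    """

    metric: str
    obs: float
    null_mean: float
    null_sd: float
    ses: float
    rank: float
    p_value: float
    runs: int
    n_community: int
    n_pool: int
    seed: object
    degenerate: bool

    @property
    def significant(self) -> bool:
        return (not self.degenerate) and self.p_value < 0.05


def _mpd_from_sub(sub: np.ndarray) -> float:
    k = sub.shape[0]
    return float(sub.sum() / (k * (k - 1)))


def _mntd_from_sub(sub: np.ndarray) -> float:
    k = sub.shape[0]
    masked = sub + np.where(np.eye(k, dtype=bool), np.inf, 0.0)
    return float(masked.min(axis=1).mean())


def mpd(community: CommunitySample) -> float:
    """Mean pairwise patristic distance over the community."""
    if community.k < 2:
        raise ValueError("MPD undefined for fewer than 2 members")
    idx = community.indices
    return _mpd_from_sub(community.pool.d[np.ix_(idx, idx)])


def mntd(community: CommunitySample) -> float:
    """Mean distance from each member to its nearest other member."""
    if community.k < 2:
        raise ValueError("MNTD undefined for fewer than 2 members")
    idx = community.indices
    return _mntd_from_sub(community.pool.d[np.ix_(idx, idx)])


def p_from_rank(obs: float, null: NullDistribution | np.ndarray) -> tuple[float, float]:
    """Lower-tail midrank p-value of ``obs`` among {obs} U null.

    rank = (# null < obs) + (ties + 2)/2 where ties = # null == obs;
    p = rank / (runs + 1). Small p means the observed value is unusually
    small relative to the null (phylogenetic clustering).
    """
    values = null.values if isinstance(null, NullDistribution) else np.asarray(null)
    runs = len(values)
    if runs == 0:
        raise ValueError("empty null distribution")
    below = int(np.count_nonzero(values < obs))
    ties = int(np.count_nonzero(values == obs))
    rank = below + (ties + 2) / 2.0
    return rank, rank / (runs + 1)


def _null_values(
    D: np.ndarray,
    k: int,
    runs: int,
    rng: np.random.Generator,
    metric: str,
) -> np.ndarray:
    """Metric values for ``runs`` uniform k-subsets of the pool."""
    n = D.shape[0]
    out = np.empty(runs)
    chunk = max(1, min(runs, _CHUNK_ELEMENTS // (k * k)))
    pos = 0
    while pos < runs:
        m = min(chunk, runs - pos)
        # uniform k-subset per run: first k of a random permutation
        perm = np.argsort(rng.random((m, n)), axis=1)[:, :k]
        sub = D[perm[:, :, None], perm[:, None, :]]
        if metric == "mpd":
            out[pos : pos + m] = sub.sum(axis=(1, 2)) / (k * (k - 1))
        else:
            ar = np.arange(k)
            sub[:, ar, ar] = np.inf
            out[pos : pos + m] = sub.min(axis=2).mean(axis=1)
        pos += m
    return out


def ses_metric(
    community: CommunitySample,
    metric: str = "mpd",
    runs: int = 999,
    seed: int | np.random.SeedSequence | None = None,
    rng: np.random.Generator | None = None,
) -> SESResult:
    """Standardized effect size of MPD or MNTD under the taxa-label null.

    Parameters
    ----------
    community : CommunitySample
        Members and their reference pool.
    metric : {"mpd", "mntd"}
        Which distance summary to standardize (NRI resp. NTI).
    runs : int
        Number of null permutations (999 by default, giving a p-value floor
        of 1/1000).
    seed, rng
        Either an integer/SeedSequence seed or a ready Generator. Identical
        seed and inputs give bitwise-identical results.
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}")
    if runs < 1:
        raise ValueError("runs must be >= 1")
    if community.k < 2:
        raise ValueError("community must have at least 2 members")
    if rng is None:
        rng = np.random.default_rng(seed)
    D = community.pool.d
    idx = community.indices
    sub = D[np.ix_(idx, idx)]
    obs = _mpd_from_sub(sub) if metric == "mpd" else _mntd_from_sub(sub)
    null = NullDistribution(
        _null_values(D, community.k, runs, rng, metric), runs, seed
    )
    null_sd = null.sd
    # summation-order noise makes an exactly-constant null come out at
    # ~1e-16; treat anything below float precision of the mean as degenerate
    degenerate = null_sd <= 1e-12 * max(1.0, abs(null.mean))
    ses = np.nan if degenerate else -1.0 * (obs - null.mean) / null_sd
    rank, p = p_from_rank(obs, null)
    return SESResult(
        metric=metric,
        obs=obs,
        null_mean=null.mean,
        null_sd=null_sd,
        ses=float(ses),
        rank=rank,
        p_value=p,
        runs=runs,
        n_community=community.k,
        n_pool=community.pool.n,
        seed=seed,
        degenerate=degenerate,
    )
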