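"""Long-run simulation to stable community states and their census.

A community is *static* when, over a trailing window of simulated days
(default 100), the sum over genera of the squared per-genus variances falls
below 1e-20. Random starting communities are drawn from a sparse symmetric
Dirichlet (shape 0.2 per genus by default), long runs are extended in
blocks until static, and the resulting stable compositions are grouped into
statuses by Ward hierarchical clustering on Bray-Curtis distance, cutting
the tree at the smallest number of groups whose within-group distances all
stay below a tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .core import (
    FLOOR,
    Composition,
    GenusMismatchError,
    ModelName,
    ModelParams,
    RawState,
    Trajectory,
    simulate,
)

__all__ = [
    "STATIC_WINDOW",
    "STATIC_THRESHOLD",
    "StableStateCensus",
    "random_compositions",
    "is_static",
    "run_to_stability",
    "census",
]

#: Trailing-window length (days) over which staticness is judged.
STATIC_WINDOW = 100
#: Upper bound on the sum of squared per-genus variances of a static window.
STATIC_THRESHOLD = 1e-20


def default_genera(k: int) -> tuple[str, ...]:
    return tuple(f"genus_{i + 1:02d}" for i in range(k))


def random_compositions(
    n: int,
    k: int,
    shape: float = 0.2,
    seed: int = 0,
    genera: Sequence[str] | None = None,
) -> list[Composition]:
    """Draw ``n`` starting communities from a symmetric Dirichlet on the
    k-simplex.

    A small shape (the 0.2 default) produces sparse, few-genus-dominated
    communities, mimicking the spread of real faecal samples. Entries that
    fall below the 1e-6 extinction floor are raised to the floor and the
    vector renormalized, so every draw is a valid model state.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if not shape > 0:
        raise ValueError(f"shape must be > 0, got {shape}")
    labels = tuple(genera) if genera is not None else default_genera(k)
    if len(labels) != k:
        raise ValueError(f"expected {k} genus labels, got {len(labels)}")
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(np.full(k, float(shape)), size=n)
    draws = np.maximum(draws, FLOOR)
    draws /= draws.sum(axis=1, keepdims=True)
    return [Composition(labels, row) for row in draws]


def is_static(
    traj: Trajectory,
    window: int = STATIC_WINDOW,
    threshold: float = STATIC_THRESHOLD,
    per_genus: bool = False,
) -> bool:
    """Decide whether a trajectory has settled over its final ``window`` days.

    The default criterion is ``sum_i var_i**2 < threshold`` where ``var_i``
    is the variance of genus *i* over the last ``window`` days. With
    ``per_genus=True`` the alternative reading ``var_i**2 < threshold`` for
    every genus is applied instead (a weaker condition: the sum bound
    implies the per-genus bound but not conversely).
    """
    if len(traj) < window:
        raise ValueError(
            f"trajectory of {len(traj)} days is shorter than window {window}"
        )
    tail = traj.values[-window:]
    variances = tail.var(axis=0)
    if per_genus:
        return bool(np.all(variances**2 < threshold))
    return bool(np.sum(variances**2) < threshold)


def run_to_stability(
    x0: Composition,
    params: ModelParams,
    initial_days: int = 400,
    extension_block: int = 100,
    max_days: int = 5000,
    window: int = STATIC_WINDOW,
    threshold: float = STATIC_THRESHOLD,
    model: ModelName = "nedn",
) -> tuple[Composition | RawState | None, Trajectory]:
    """Simulate until the community is static, extending the run as needed.

    Simulates ``initial_days`` days, then extends in blocks of
    ``extension_block`` days until the trailing-window criterion is met or
    ``max_days`` is reached. Returns ``(stable_composition, trajectory)``
    when static, ``(None, trajectory)`` otherwise (an unresolved run is a
    value, not an error). A diverged gLV run is unresolved.
    """
    if max_days < initial_days:
        raise ValueError("max_days must be >= initial_days")
    if initial_days < window:
        raise ValueError("initial_days must be >= the staticness window")
    traj = simulate(x0, params, initial_days, model=model)
    while True:
        if not traj.diverged and is_static(traj, window=window, threshold=threshold):
            if model == "nedn":
                return traj.final_composition(), traj
            return RawState(traj.genera, traj.final), traj
        days_left = max_days - (len(traj) - 1)
        if traj.diverged or days_left <= 0:
            return None, traj
        block = min(extension_block, days_left)
        if model == "nedn":
            last: Composition | RawState = Composition(traj.genera, traj.final)
        else:
            last = RawState(traj.genera, traj.final)
        ext = simulate(last, params, block, model=model)
        traj = Trajectory(
            traj.genera,
            np.arange(len(traj) - 1 + len(ext)),
            np.vstack([traj.values[:-1], ext.values]),
            model=model,
            diverged=ext.diverged,
        )


def bray_curtis(u: np.ndarray, v: np.ndarray) -> float:
    """Bray-Curtis dissimilarity sum|u-v| / sum(u+v) between two profiles."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    return float(np.abs(u - v).sum() / (u + v).sum())


@dataclass
class StableStateCensus:
    """Stable states reached from a set of starts, grouped into statuses.

    Statuses are numbered 1, 2, ... in order of descending frequency.
    ``status_labels[s]`` is the status of start ``s`` (0 for unresolved
    starts), ``status_profiles[g]`` the representative (member-mean)
    composition of status ``g+1``, ``frequencies[g]`` how many starts
    reached it, and ``dominant_genus[g]`` the most abundant genus of the
    representative.
    """

    genera: tuple[str, ...]
    starts: list[Composition]
    stable_states: list[Composition | None]
    status_labels: np.ndarray
    status_profiles: list[Composition]
    frequencies: np.ndarray
    dominant_genus: list[str]

    @property
    def n_statuses(self) -> int:
        return len(self.status_profiles)

    @property
    def n_unresolved(self) -> int:
        return sum(s is None for s in self.stable_states)

    def summary_rows(self) -> list[dict]:
        rows = []
        for g in range(self.n_statuses):
            row = {
                "status": g + 1,
                "frequency": int(self.frequencies[g]),
                "dominant_genus": self.dominant_genus[g],
            }
            row.update(self.status_profiles[g].asdict())
            rows.append(row)
        return rows


def _cut_ward_tree(states: np.ndarray, grouping_tol: float) -> np.ndarray:
    """Group near-identical fixed points: Ward tree on Bray-Curtis distance,
    cut at the smallest cluster count whose every group has max within-group
    distance <= grouping_tol. Returns 0-based group index per state."""
    n = states.shape[0]
    if n == 1:
        return np.zeros(1, dtype=int)
    condensed = pdist(states, metric="braycurtis")
    dist = squareform(condensed)
    if condensed.max() <= grouping_tol:
        return np.zeros(n, dtype=int)
    Z = linkage(condensed, method="ward")
    for n_clusters in range(2, n + 1):
        labels = fcluster(Z, t=n_clusters, criterion="maxclust")
        ok = True
        for c in np.unique(labels):
            members = np.flatnonzero(labels == c)
            if members.size > 1 and dist[np.ix_(members, members)].max() > grouping_tol:
                ok = False
                break
        if ok:
            return labels - 1
    return np.arange(n)  # pragma: no cover - loop always terminates at n


def census(
    starts: Sequence[Composition],
    params: ModelParams,
    grouping_tol: float = 0.05,
    initial_days: int = 400,
    extension_block: int = 100,
    max_days: int = 5000,
    window: int = STATIC_WINDOW,
    threshold: float = STATIC_THRESHOLD,
) -> StableStateCensus:
    """Run every start to stability and group the stable states into statuses.

    Each start is simulated independently (see :func:`run_to_stability`);
    resolved stable compositions are clustered by Ward linkage on
    Bray-Curtis distance and the tree is cut at ``grouping_tol``. Statuses
    are reported in descending order of how many starts reached them, each
    labelled by the dominant genus of its representative profile.
    """
    if not starts:
        raise ValueError("census requires at least one start")
    genera = starts[0].genera
    for s in starts:
        if s.genera != genera:
            raise GenusMismatchError("all starts must share one genus ordering")
    if genera != params.genera:
        raise GenusMismatchError("starts and params genus orderings differ")

    stable_states: list[Composition | None] = []
    for x0 in starts:
        stable, _ = run_to_stability(
            x0,
            params,
            initial_days=initial_days,
            extension_block=extension_block,
            max_days=max_days,
            window=window,
            threshold=threshold,
        )
        stable_states.append(stable)

    resolved_idx = [i for i, s in enumerate(stable_states) if s is not None]
    if not resolved_idx:
        raise ValueError("no start reached a stable state within max_days")
    resolved = np.stack([stable_states[i].values for i in resolved_idx])

    raw_groups = _cut_ward_tree(resolved, grouping_tol)
    counts = np.bincount(raw_groups)
    # renumber statuses 1.. by descending frequency (ties: first-seen order)
    order = np.argsort(-counts, kind="stable")
    rank_of = np.empty_like(order)
    rank_of[order] = np.arange(order.size)

    status_labels = np.zeros(len(starts), dtype=int)
    for pos, i in enumerate(resolved_idx):
        status_labels[i] = rank_of[raw_groups[pos]] + 1

    profiles: list[Composition] = []
    dominant: list[str] = []
    frequencies = counts[order]
    for g_old in order:
        members = resolved[raw_groups == g_old]
        mean = members.mean(axis=0)
        profile = Composition(genera, mean)
        profiles.append(profile)
        dominant.append(genera[int(np.argmax(mean))])

    return StableStateCensus(
        genera=genera,
        starts=list(starts),
        stable_states=stable_states,
        status_labels=status_labels,
        status_profiles=profiles,
        frequencies=frequencies,
        dominant_genus=dominant,
    )
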