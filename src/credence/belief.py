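"""Dempster-Shafer credibility engine.

Evidence quality is expressed as a *credibility* in the open interval
(-1, 1): -1 is perfect disbelief, 0 is neutral (total uncertainty) and 1 is
perfect belief.  Each credibility maps onto a basic probability assignment
(mass function) over the frame of discernment Theta = {T, F}, whose focal
elements are {T}, {F} and the uncertain set {T, F}.  Independent pieces of
evidence are merged with Dempster's orthogonal sum; the belief in {T} of the
merged mass is the *combined credibility* reported for a result row, and it
always lies in [0, 1].

The module also houses the score -> credibility machinery: normalisation of
raw source scores onto a "bigger is more significant" axis, partitioning of
the normalised axis with a 1-D Gaussian mixture (model size chosen by BIC),
contiguous re-clustering when the user adds or removes one partition, and the
online learning rule that nudges a source's credibility when the user grades
individual rows.
"""

from __future__ import annotations

import math
import warnings
from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MassFunction",
    "PartitionScheme",
    "TotalConflictError",
    "VACUOUS",
    "assign_group_credibility",
    "assign_score_credibility",
    "combine_masses",
    "combined_credibility",
    "conflict",
    "credibility_to_mass",
    "fit_partitions",
    "normalize_scores",
    "repartition",
    "update_source_credibility",
]

_MASS_TOL = 1e-12
#: credibilities are clamped strictly inside (-1, 1)
CRED_CLAMP = 1.0 - 1e-9
#: p-values of exactly zero are floored here before taking logs
MIN_P = 1e-300


class TotalConflictError(ValueError):
    """Raised when two mass functions are perfectly contradictory.

    This happens only for perfect belief combined with perfect disbelief
    (K^-1 = 0), which the open credibility interval makes unreachable from
    user-assigned scores; surfacing it loudly is safer than silently
    renormalising.
    """


@dataclass(frozen=True)
class MassFunction:
    """Basic probability assignment over {T, F} with uncertainty mass.

    ``m_t`` and ``m_f`` are the masses on the singletons {T} and {F};
    ``m_u`` is the mass on the whole frame {T, F}.  The empty set carries no
    mass and the three components sum to one.
    """

    m_t: float
    m_f: float
    m_u: float

    def __post_init__(self) -> None:
        for v in (self.m_t, self.m_f, self.m_u):
            if v < -_MASS_TOL:
                raise ValueError(f"negative mass {v!r}")
        total = self.m_t + self.m_f + self.m_u
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"masses sum to {total!r}, expected 1")

    def belief_true(self) -> float:
        """Bel({T}) — for a two-element frame this is just m({T})."""
        return self.m_t


#: the vacuous mass function: total uncertainty, identity of the orthogonal sum
VACUOUS = MassFunction(0.0, 0.0, 1.0)


def credibility_to_mass(c: float) -> MassFunction:
    """Map a credibility in (-1, 1) onto a mass function.

    Positive credibility becomes mass on {T}, negative credibility mass on
    {F}; the remainder is uncertainty.  Neutral credibility 0 maps to the
    vacuous mass function.
    """
    if not -1.0 < c < 1.0:
        raise ValueError(f"credibility {c!r} outside the open interval (-1, 1)")
    if c >= 0:
        return MassFunction(c, 0.0, 1.0 - c)
    return MassFunction(0.0, -c, 1.0 + c)


def _conflict_complement(m1: MassFunction, m2: MassFunction) -> float:
    # K^-1 = sum of products whose focal intersection is non-empty
    return 1.0 - (m1.m_t * m2.m_f + m1.m_f * m2.m_t)


def combine_masses(m1: MassFunction, m2: MassFunction) -> MassFunction:
    """Dempster's orthogonal sum m1 (+) m2.

    For each focal element A, the combined mass is the normalised sum of
    products m1(X) * m2(Y) over intersections X ∩ Y = A; products landing on
    the empty set ({T} against {F}) are discarded and the rest renormalised
    by K.  Commutative and associative.
    """
    k_inv = _conflict_complement(m1, m2)
    if k_inv <= 0.0:
        raise TotalConflictError("perfect belief combined with perfect disbelief")
    m_t = (m1.m_t * m2.m_t + m1.m_t * m2.m_u + m1.m_u * m2.m_t) / k_inv
    m_f = (m1.m_f * m2.m_f + m1.m_f * m2.m_u + m1.m_u * m2.m_f) / k_inv
    m_u = (m1.m_u * m2.m_u) / k_inv
    return MassFunction(m_t, m_f, m_u)


def conflict(m1: MassFunction, m2: MassFunction) -> float:
    """log K, the conflict between two basic probability assignments.

    Zero when no mass lands on the empty set; grows without bound as the two
    assignments approach perfect contradiction (returned as ``math.inf``).
    """
    k_inv = _conflict_complement(m1, m2)
    if k_inv <= 0.0:
        return math.inf
    return -math.log(k_inv)


def combined_credibility(credibilities: Iterable[float]) -> float:
    """Fold credibilities through the orthogonal sum; return Bel({T}).

    The result is order-invariant (the orthogonal sum is commutative and
    associative) and always in [0, 1].
    """
    creds = list(credibilities)
    if not creds:
        raise ValueError("need at least one credibility to combine")
    acc = VACUOUS
    for c in creds:
        acc = combine_masses(acc, credibility_to_mass(c))
    return acc.belief_true()


def normalize_scores(
    scores: Sequence[float], kind: str, *, min_p: float = MIN_P
) -> np.ndarray:
    """Convert raw source scores to a nonnegative "bigger is better" scale.

    p-values are mapped to -log10(p) (floored at zero); article counts and
    percent identities are already on such a scale; net expression direction
    scores are taken in absolute value.  A p-value of exactly zero is clamped
    to ``min_p`` with a warning so that the logarithm stays finite.
    """
    arr = np.asarray(scores, dtype=float)
    if kind == "p_value":
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValueError("p-values must lie in [0, 1]")
        if np.any(arr == 0):
            warnings.warn(
                f"p-value of 0 clamped to {min_p:g} before log transform",
                RuntimeWarning,
                stacklevel=2,
            )
            arr = np.where(arr == 0, min_p, arr)
        return np.maximum(-np.log10(arr), 0.0)
    if kind in ("article_count", "percent_identity"):
        if np.any(arr < 0):
            raise ValueError(f"{kind} scores must be nonnegative")
        return arr
    if kind == "expression_net":
        return np.abs(arr)
    if kind == "default":
        # default scores are stand-in p-values
        return np.maximum(-np.log10(np.maximum(arr, min_p)), 0.0)
    raise ValueError(f"unknown score kind {kind!r}")


@dataclass(frozen=True)
class PartitionScheme:
    """Cut points on the normalised score axis plus one credibility per bin.

    ``boundaries`` are strictly increasing; with b cut points there are b+1
    intervals.  A score equal to a boundary belongs to the right-hand
    (higher-score) interval.
    """

    boundaries: tuple[float, ...]
    credibilities: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.credibilities) != len(self.boundaries) + 1:
            raise ValueError(
                "need exactly one credibility per interval "
                f"({len(self.boundaries)} boundaries, "
                f"{len(self.credibilities)} credibilities)"
            )
        if any(b2 <= b1 for b1, b2 in zip(self.boundaries, self.boundaries[1:])):
            raise ValueError("boundaries must be strictly increasing")
        for c in self.credibilities:
            if not -1.0 < c < 1.0:
                raise ValueError(f"interval credibility {c!r} outside (-1, 1)")

    @property
    def k(self) -> int:
        return len(self.credibilities)

    def interval_index(self, score: float) -> int:
        return bisect_right(self.boundaries, score)

    def credibility_for(self, score: float) -> float:
        return self.credibilities[self.interval_index(score)]


def _midpoint_boundaries(sorted_centers: np.ndarray) -> tuple[float, ...]:
    return tuple((sorted_centers[:-1] + sorted_centers[1:]) / 2.0)


def fit_partitions(
    normalized_scores: Sequence[float],
    k: int | str = "auto",
    *,
    k_max: int = 6,
    seed: int = 0,
) -> PartitionScheme:
    """Partition the normalised score axis with a 1-D Gaussian mixture.

    In auto mode, mixtures with 1..k_max components are fit by EM and the
    model size is selected by BIC; boundaries fall at midpoints between
    adjacent component means.  Every interval starts at the neutral-default
    credibility 0.5.  Deterministic for a fixed seed.
    """
    from sklearn.mixture import GaussianMixture

    arr = np.asarray(normalized_scores, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot partition an empty score collection")
    distinct = np.unique(arr)
    if distinct.size == 1:
        return PartitionScheme((), (0.5,))
    x = arr.reshape(-1, 1)

    def _fit(n_comp: int) -> "GaussianMixture":
        return GaussianMixture(
            n_components=n_comp,
            covariance_type="full",
            random_state=seed,
            n_init=3,
            reg_covar=1e-6,
        ).fit(x)

    if k == "auto":
        best, best_bic = None, np.inf
        for n_comp in range(1, min(k_max, distinct.size) + 1):
            gm = _fit(n_comp)
            bic = gm.bic(x)
            if bic < best_bic - 1e-9:
                best, best_bic = gm, bic
        gm = best
    else:
        k = int(k)
        if k < 1:
            raise ValueError("k must be a positive integer")
        if k > distinct.size:
            raise ValueError(
                f"k={k} exceeds the {distinct.size} distinct score values"
            )
        gm = _fit(k)

    centers = np.sort(gm.means_.ravel())
    # numerically coincident means would create empty intervals; collapse them
    keep = np.concatenate(([True], np.diff(centers) > 1e-12))
    centers = centers[keep]
    boundaries = _midpoint_boundaries(centers)
    return PartitionScheme(boundaries, (0.5,) * (len(boundaries) + 1))


def _optimal_contiguous_groups(sorted_vals: np.ndarray, k: int) -> list[int]:
    """Split sorted 1-D values into k contiguous groups minimising the
    within-group sum of squared deviations (exact dynamic program).

    Returns the sizes of the k groups, left to right.
    """
    n = sorted_vals.size
    pref = np.concatenate(([0.0], np.cumsum(sorted_vals)))
    pref2 = np.concatenate(([0.0], np.cumsum(sorted_vals**2)))

    def sse(i: int, j: int) -> float:  # values i..j-1
        s, s2, cnt = pref[j] - pref[i], pref2[j] - pref2[i], j - i
        return s2 - s * s / cnt

    INF = math.inf
    cost = [[INF] * (n + 1) for _ in range(k + 1)]
    cut = [[0] * (n + 1) for _ in range(k + 1)]
    cost[0][0] = 0.0
    for g in range(1, k + 1):
        for j in range(g, n + 1):
            for i in range(g - 1, j):
                c = cost[g - 1][i] + sse(i, j)
                if c < cost[g][j] - 1e-15:
                    cost[g][j], cut[g][j] = c, i
    sizes, j = [], n
    for g in range(k, 0, -1):
        i = cut[g][j]
        sizes.append(j - i)
        j = i
    return sizes[::-1]


def repartition(
    scheme: PartitionScheme, scores: Sequence[float], k_new: int
) -> PartitionScheme:
    """Re-cluster the scores into one more or one fewer contiguous group.

    Mirrors the interactive add/remove-a-divider gesture, so only steps of
    one partition are allowed.  Credibilities of surviving intervals carry
    over by nearest interval midpoint; genuinely new intervals start at 0.5.
    """
    arr = np.sort(np.asarray(scores, dtype=float))
    if arr.size == 0:
        raise ValueError("cannot repartition an empty score collection")
    distinct = np.unique(arr)
    if k_new < 1:
        raise ValueError("k_new must be >= 1")
    if abs(k_new - scheme.k) != 1:
        raise ValueError(
            f"can only add or remove one partition at a time "
            f"(current k={scheme.k}, requested {k_new})"
        )
    if k_new > distinct.size:
        raise ValueError(
            f"k_new={k_new} exceeds the {distinct.size} distinct score values"
        )
    if k_new == 1:
        mid = (arr[0] + arr[-1]) / 2.0
        return PartitionScheme((), (_carry_credibility(scheme, arr, mid),))

    sizes = _optimal_contiguous_groups(arr, k_new)
    edges = np.cumsum(sizes)[:-1]
    boundaries = tuple(
        (arr[e - 1] + arr[e]) / 2.0 for e in edges
    )
    new = PartitionScheme(boundaries, (0.5,) * k_new)
    creds = tuple(
        _carry_credibility(scheme, arr, m) for m in _interval_midpoints(new, arr)
    )
    return PartitionScheme(boundaries, creds)


def _interval_midpoints(scheme: PartitionScheme, sorted_scores: np.ndarray) -> list[float]:
    lo, hi = float(sorted_scores[0]), float(sorted_scores[-1])
    pts = [lo, *scheme.boundaries, hi]
    return [(a + b) / 2.0 for a, b in zip(pts, pts[1:])]


def _carry_credibility(
    old: PartitionScheme, sorted_scores: np.ndarray, midpoint: float
) -> float:
    """Credibility of the old interval whose midpoint is nearest."""
    old_mids = _interval_midpoints(old, sorted_scores)
    dist = [abs(midpoint - m) for m in old_mids]
    return old.credibilities[int(np.argmin(dist))]


def assign_score_credibility(lst, scheme: PartitionScheme, registry=None):
    """Set every entry's score credibility from the partition it falls in.

    The entry's primary (first) evidence item supplies the raw score, which
    is normalised by its own kind; the combined credibility is then
    recomputed.  Scores outside the tiled range simply land in the end
    intervals, which is the documented nearest-interval behaviour.
    Returns the list (modified in place).
    """
    for entry in lst.entries.values():
        ev = entry.evidence[0]
        norm = float(normalize_scores([ev.score_from_source], ev.score_kind)[0])
        entry.credibility.score_credibility = scheme.credibility_for(norm)
    lst.recompute_combined(registry)
    return lst


def assign_group_credibility(results, scheme: PartitionScheme):
    """Set each enrichment group's size-of-group credibility.

    Group sizes play the role of normalised scores: the partition scheme is
    fitted (or hand-set) over the group-size axis, and each group's
    ``group_credibility`` is the credibility of the interval its size falls
    in.  The group's combined belief is then refreshed over (source, score,
    group) masses.  Groups may equally be graded by hand by assigning
    ``credibility.group_credibility`` directly.  Returns the results.
    """
    for res in results:
        cred = res.credibility
        cred.group_credibility = scheme.credibility_for(float(res.group_size))
        parts = [cred.source_credibility, cred.score_credibility, cred.group_credibility]
        cred.combined = combined_credibility(parts)
    return results


def update_source_credibility(
    registry,
    source: str,
    feedback_position: int,
    affected_entry=None,
    lists: Iterable = (),
):
    """Apply one radio-button feedback event to a source's credibility.

    ``feedback_position`` runs 1..5 from strongest agreement to strongest
    disagreement, position 3 being neutral; the source's credibility moves by
    the corresponding learning rate, clamped strictly inside (-1, 1).  The
    graded entry's own score credibility moves by the same rate, and every
    list passed in has its combined credibilities refreshed.
    """
    if not 1 <= feedback_position <= 5:
        raise ValueError("feedback position must be in 1..5")
    if source not in registry.credibilities:
        raise KeyError(f"source {source!r} is not registered")
    rate = registry.learning_rates[feedback_position - 1]
    registry.credibilities[source] = _clamp(registry.get(source) + rate)
    if affected_entry is not None:
        cred = affected_entry.credibility
        cred.score_credibility = _clamp(cred.score_credibility + rate)
    for lst in lists:
        lst.recompute_combined(registry)
    return registry


def _clamp(c: float) -> float:
    return max(-CRED_CLAMP, min(CRED_CLAMP, c))
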