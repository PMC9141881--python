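"""Distinct informative sets, fragmentation values and fragmentation matrices.

Given a paired predictor/feature table, a *distinct informative set* (DIS)
for a feature Y at threshold theta is an irreducible predictor subset S with
I(S;Y) >= theta * H(Y): irreducible means S is not a proper superset of
another qualifying set.  The *fragmentation* of Y is the size of its smallest
DIS (how dispersed the predictive information is), with the sentinel -1 when
even the full predictor pool fails the threshold, and 0 for zero-entropy
features (nothing to predict).

The search enumerates subsets from smallest to largest so it can stop as
soon as a sufficient subset is found, and prunes supersets of already-found
qualifying sets when collecting complete DIS collections.  The power set
grows as 2^m, so pools above a configurable cap are rejected unless
explicitly overridden.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .state_records import PairedTable

__all__ = [
    "SUBSET_CAP",
    "NodeSet",
    "DISCollection",
    "FragmentationMatrix",
    "iter_subsets",
    "find_dis",
    "fragmentation_value",
    "fragmentation_matrix",
    "fragmentation_from_matrix",
    "dis_from_matrix",
]

#: default maximum pool size for exhaustive power-set enumeration (2^16 - 1
#: subsets); larger pools need an explicit override
SUBSET_CAP = 16

#: absolute slack used when comparing shared entropy against theta * H(Y)
THETA_TOL = 1e-9

NodeSet = tuple[str, ...]


class PoolTooLargeError(ValueError):
    """Raised when an exhaustive subset search over the pool is impractical."""


def iter_subsets(
    pool: Sequence[str], cap: int = SUBSET_CAP, allow_large: bool = False
) -> Iterator[NodeSet]:
    """Yield all 2^m - 1 non-empty subsets of ``pool``, smallest first and
    lexicographically (by pool order) within each size.

    The given pool order is the canonical element order of every emitted
    subset, so the stream is deterministic.
    """
    if not pool:
        raise ValueError("pool must be non-empty")
    if len(set(pool)) != len(pool):
        raise ValueError("pool contains duplicate node ids")
    if len(pool) > cap and not allow_large:
        raise PoolTooLargeError(
            f"pool has {len(pool)} nodes (> cap {cap}); exhaustive search over "
            f"2^{len(pool)} subsets is impractical — prune the pool or pass "
            f"allow_large=True"
        )
    for size in range(1, len(pool) + 1):
        yield from itertools.combinations(pool, size)


@dataclass
class DISCollection:
    """All distinct informative sets for one feature at one theta."""

    feature: str
    theta: float
    sets: list[NodeSet]
    feature_entropy: float
    trivially_predicted: bool = False

    @property
    def minimal_size(self) -> int:
        """Size of the smallest DIS, or -1 when no qualifying set exists."""
        if self.trivially_predicted:
            return 0
        return min((len(s) for s in self.sets), default=-1)

    @property
    def necessary_members(self) -> frozenset[str]:
        """Nodes present in every DIS (empty when there are no sets)."""
        if not self.sets:
            return frozenset()
        out = frozenset(self.sets[0])
        for s in self.sets[1:]:
            out &= frozenset(s)
        return out

    @property
    def all_members(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for s in self.sets:
            out |= frozenset(s)
        return out


# ---------------------------------------------------------------------------
# fast subset entropies
#
# Each relevant column is interned to consecutive integer codes once; a
# subset's joint state is then a mixed-radix integer, counted with bincount.
# Entropies are memoized per subset so the DIS search, matrix fill and flow
# labels share work.

class SubsetEntropyCache:
    def __init__(self, table: PairedTable, ids: Sequence[str]):
        self.n = table.n_rows
        self._codes: dict[str, np.ndarray] = {}
        self._alpha: dict[str, int] = {}
        for c in ids:
            col = table.columns([c])[:, 0]
            _, codes = np.unique(col, return_inverse=True)
            self._codes[c] = codes.astype(np.int64)
            self._alpha[c] = int(codes.max()) + 1 if codes.size else 1
        self._memo: dict[frozenset[str], float] = {}

    def entropy(self, ids: Sequence[str]) -> float:
        key = frozenset(ids)
        h = self._memo.get(key)
        if h is not None:
            return h
        radix = 1
        code = np.zeros(self.n, dtype=np.int64)
        for c in sorted(key):
            code = code * self._alpha[c] + self._codes[c]
            radix *= self._alpha[c]
            if radix > 1 << 62:  # pragma: no cover - astronomically wide joint
                raise OverflowError("joint alphabet too large")
        if radix <= 4 * self.n + 64:
            counts = np.bincount(code, minlength=radix)
            counts = counts[counts > 0]
        else:
            _, counts = np.unique(code, return_counts=True)
        p = counts / self.n
        h = float(-np.sum(p * np.log2(p))) if p.size > 1 else 0.0
        self._memo[key] = h
        return h

    def shared(self, subset: Sequence[str], feature: str) -> float:
        """I(subset; feature) in bits, clipped at zero."""
        h_s = self.entropy(subset)
        h_y = self.entropy([feature])
        h_sy = self.entropy(list(subset) + [feature])
        return max(0.0, h_s + h_y - h_sy)


# ---------------------------------------------------------------------------
# DIS search

def find_dis(
    table: PairedTable,
    pool: Sequence[str],
    feature: str,
    theta: float = 1.0,
    cap: int = SUBSET_CAP,
    allow_large: bool = False,
    _cache: SubsetEntropyCache | None = None,
) -> DISCollection:
    """Collect every irreducible predictor subset with I(S;Y) >= theta H(Y).

    Supersets of qualifying sets are pruned during the size-ascending
    enumeration.  Zero-entropy features are trivially predicted: the
    collection is empty and flagged, since there is nothing to explain.
    """
    if not (0.0 <= theta <= 1.0):
        raise ValueError(f"theta must be in [0, 1], got {theta}")
    cache = _cache or SubsetEntropyCache(table, list(pool) + [feature])
    h_y = cache.entropy([feature])
    if h_y <= THETA_TOL:
        return DISCollection(feature, theta, [], h_y, trivially_predicted=True)
    need = theta * h_y - THETA_TOL
    found: list[NodeSet] = []
    found_masks: list[int] = []
    pos = {c: k for k, c in enumerate(pool)}
    for subset in iter_subsets(pool, cap=cap, allow_large=allow_large):
        mask = 0
        for c in subset:
            mask |= 1 << pos[c]
        if any(mask & fm == fm for fm in found_masks):
            continue  # proper superset of a known DIS -> reducible
        if cache.shared(subset, feature) >= need:
            found.append(tuple(subset))
            found_masks.append(mask)
    return DISCollection(feature, theta, found, h_y)


def fragmentation_value(
    table: PairedTable,
    pool: Sequence[str],
    feature: str,
    theta: float = 1.0,
    cap: int = SUBSET_CAP,
    allow_large: bool = False,
    _cache: SubsetEntropyCache | None = None,
) -> int:
    """Size of the smallest DIS for ``feature``; -1 when even the full pool
    fails the threshold; 0 for a zero-entropy feature.

    Stops at the first qualifying size, so typically far fewer than 2^m
    subsets are examined.
    """
    if not (0.0 <= theta <= 1.0):
        raise ValueError(f"theta must be in [0, 1], got {theta}")
    cache = _cache or SubsetEntropyCache(table, list(pool) + [feature])
    h_y = cache.entropy([feature])
    if h_y <= THETA_TOL:
        return 0
    need = theta * h_y - THETA_TOL
    if len(pool) > cap and not allow_large:
        raise PoolTooLargeError(
            f"pool has {len(pool)} nodes (> cap {cap}); pass allow_large=True"
        )
    for size in range(1, len(pool) + 1):
        for subset in itertools.combinations(pool, size):
            if cache.shared(subset, feature) >= need:
                return size
    return -1


# ---------------------------------------------------------------------------
# fragmentation matrices

@dataclass
class FragmentationMatrix:
    """Features x non-empty predictor subsets, filled with shared entropy.

    Columns are ordered by subset size then lexicographically (pool order),
    which makes "the first column reaching theta" a deterministic lookup.
    Zero-entropy features carry normalized cells of 1.0 and are flagged
    ``trivially_predicted``.
    """

    pool: tuple[str, ...]
    features: tuple[str, ...]
    subsets: list[NodeSet]
    raw: np.ndarray          # (n_features, n_subsets) shared entropy in bits
    normalized: np.ndarray   # raw / H(Y), or 1.0 where H(Y) == 0
    feature_entropies: np.ndarray
    trivially_predicted: np.ndarray = field(default=None)  # bool per feature

    def __post_init__(self) -> None:
        if self.trivially_predicted is None:
            self.trivially_predicted = self.feature_entropies <= THETA_TOL

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.features), len(self.subsets))

    def column_labels(self) -> list[str]:
        return ["+".join(s) for s in self.subsets]

    def row(self, feature: str, normalized: bool = True) -> np.ndarray:
        if feature not in self.features:
            raise KeyError(f"unknown feature: {feature!r}")
        i = self.features.index(feature)
        return (self.normalized if normalized else self.raw)[i]

    def to_tsv(self, path: str | Path, normalized: bool = True) -> None:
        import pandas as pd

        values = self.normalized if normalized else self.raw
        pd.DataFrame(
            values, index=list(self.features), columns=self.column_labels()
        ).to_csv(path, sep="\t", index_label="feature")

    def to_json_dict(self, theta: float | None = None) -> dict:
        out = {
            "pool": list(self.pool),
            "features": list(self.features),
            "columns": self.column_labels(),
            "raw_bits": self.raw.tolist(),
            "normalized": self.normalized.tolist(),
            "feature_entropies": self.feature_entropies.tolist(),
            "trivially_predicted": self.trivially_predicted.tolist(),
        }
        if theta is not None:
            out["theta"] = theta
            out["dis"] = {
                f: [list(s) for s in dis_from_matrix(self, f, theta).sets]
                for f in self.features
            }
            out["fragmentation"] = {
                f: fragmentation_from_matrix(self, f, theta) for f in self.features
            }
        return out

    def to_json(self, path: str | Path, theta: float | None = None) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(theta), indent=1))


def fragmentation_matrix(
    table: PairedTable,
    pool: Sequence[str],
    features: Sequence[str],
    normalize: bool = True,
    cap: int = SUBSET_CAP,
    allow_large: bool = False,
) -> FragmentationMatrix:
    """Complete matrix of I(S;Y) for all non-empty subsets S of ``pool``.

    The full-pool column equals H(Y) (normalized: 1.0) for every feature that
    is a deterministic function of the pool.  ``normalize`` only affects which
    view downstream exports default to; both views are stored.
    """
    cache = SubsetEntropyCache(table, list(pool) + list(features))
    subsets = list(iter_subsets(pool, cap=cap, allow_large=allow_large))
    raw = np.zeros((len(features), len(subsets)))
    h = np.array([cache.entropy([f]) for f in features])
    for j, s in enumerate(subsets):
        for i, f in enumerate(features):
            raw[i, j] = cache.shared(s, f)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.where(h[:, None] > THETA_TOL, raw / np.where(h[:, None] > 0, h[:, None], 1.0), 1.0)
    norm = np.clip(norm, 0.0, 1.0)
    return FragmentationMatrix(
        pool=tuple(pool),
        features=tuple(features),
        subsets=subsets,
        raw=raw,
        normalized=norm,
        feature_entropies=h,
    )


def fragmentation_from_matrix(
    matrix: FragmentationMatrix, feature: str, theta: float = 1.0
) -> int:
    """Look up fragmentation as the size of the first (size-then-lex ordered)
    column whose shared entropy reaches theta * H(Y); consistent with
    :func:`fragmentation_value` on the same inputs."""
    if feature not in matrix.features:
        raise KeyError(f"unknown feature: {feature!r}")
    i = matrix.features.index(feature)
    if matrix.trivially_predicted[i]:
        return 0
    need = theta * matrix.feature_entropies[i] - THETA_TOL
    for j, s in enumerate(matrix.subsets):
        if matrix.raw[i, j] >= need:
            return len(s)
    return -1


def dis_from_matrix(
    matrix: FragmentationMatrix, feature: str, theta: float = 1.0
) -> DISCollection:
    """Recover the DIS collection for ``feature`` from a complete matrix by
    filtering qualifying columns and discarding supersets."""
    if feature not in matrix.features:
        raise KeyError(f"unknown feature: {feature!r}")
    i = matrix.features.index(feature)
    h_y = float(matrix.feature_entropies[i])
    if matrix.trivially_predicted[i]:
        return DISCollection(feature, theta, [], h_y, trivially_predicted=True)
    need = theta * h_y - THETA_TOL
    found: list[NodeSet] = []
    for j, s in enumerate(matrix.subsets):
        if matrix.raw[i, j] < need:
            continue
        fs = frozenset(s)
        if any(frozenset(prev) < fs or frozenset(prev) == fs for prev in found):
            continue
        found.append(s)
    return DISCollection(feature, theta, found, h_y)
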