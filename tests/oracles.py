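"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — dict counting, math.log2 loops and
literal power-set filters — and shares no code with the package's own
entropy cache or pruned DIS search, so agreement between the two routes is
meaningful.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter


def entropy_of_rows(rows: list[tuple]) -> float:
    """Plug-in Shannon entropy (bits) of a list of observed states."""
    n = len(rows)
    h = 0.0
    for count in Counter(rows).values():
        p = count / n
        h -= p * math.log2(p)
    return h


def project(rows: list[tuple], idx: tuple[int, ...]) -> list[tuple]:
    return [tuple(r[i] for i in idx) for r in rows]


def joint_entropy(rows: list[tuple], idx: tuple[int, ...]) -> float:
    return entropy_of_rows(project(rows, idx))


def mutual_information(rows, idx_a, idx_b) -> float:
    return (
        joint_entropy(rows, tuple(idx_a))
        + joint_entropy(rows, tuple(idx_b))
        - joint_entropy(rows, tuple(idx_a) + tuple(idx_b))
    )


def co_information(rows, idx_a, idx_b, idx_c) -> float:
    return (
        mutual_information(rows, idx_a, idx_c)
        + mutual_information(rows, idx_b, idx_c)
        - mutual_information(rows, tuple(idx_a) + tuple(idx_b), idx_c)
    )


def brute_force_dis(
    rows: list[tuple],
    pool_idx: list[int],
    y_idx: int,
    theta: float,
    tol: float = 1e-9,
) -> list[tuple[int, ...]]:
    """Exhaustive DIS filter: compute I(S;Y) for every non-empty subset,
    keep those reaching theta*H(Y), then drop proper supersets of other
    qualifying sets.  A zero-entropy Y is trivially predicted: by convention
    it has no DIS (there is nothing to explain), matching the package."""
    h_y = joint_entropy(rows, (y_idx,))
    if h_y <= tol:
        return []
    qualifying = []
    for size in range(1, len(pool_idx) + 1):
        for s in itertools.combinations(pool_idx, size):
            if mutual_information(rows, s, (y_idx,)) >= theta * h_y - tol:
                qualifying.append(s)
    out = []
    for s in qualifying:
        if not any(set(q) < set(s) for q in qualifying):
            out.append(s)
    return out


def brute_force_fragmentation(rows, pool_idx, y_idx, theta, tol=1e-9) -> int:
    h_y = joint_entropy(rows, (y_idx,))
    if h_y <= tol:
        return 0
    dis = brute_force_dis(rows, pool_idx, y_idx, theta, tol)
    return min((len(s) for s in dis), default=-1)
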