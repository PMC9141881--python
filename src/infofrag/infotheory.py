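"""Shannon information measures on maximum-likelihood probability tables.

All quantities are in bits (log base 2) and are plug-in estimates computed
from observed joint-state frequencies — no bias correction is applied, since
the intended inputs are complete phenotypic recordings of deterministic or
near-deterministic networks.

The three-variable Venn decomposition splits the entropies of three variable
sets A, B, C into seven regions (three conditional entropies, three
pairwise-conditional informations and the triple co-information).  The triple
region may be negative; a value of -H on an XOR-style triple is the signature
of one-time-pad encryption, where each variable is the key unlocking the
information shared by the other two.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .state_records import PairedTable, ProbabilityTable, estimate_probabilities

__all__ = [
    "entropy",
    "joint_entropy",
    "mutual_information",
    "co_information",
    "venn3",
    "VennDecomposition3",
]


def entropy(p: ProbabilityTable | Sequence[float]) -> float:
    """Shannon entropy  H(X) = -sum_i p_i log2 p_i  in bits.

    A single-state (certain) table has zero entropy.
    """
    probs = p.probs if isinstance(p, ProbabilityTable) else np.asarray(p, float)
    if probs.size <= 1:
        return 0.0
    return float(-np.sum(probs * np.log2(probs)))


def joint_entropy(table: PairedTable, subset: Sequence[str]) -> float:
    """Entropy of the joint state over ``subset``, treating the listed nodes
    as a single composite variable."""
    return entropy(estimate_probabilities(table, _dedup(subset)))


def mutual_information(
    table: PairedTable, set_a: Sequence[str], set_b: Sequence[str]
) -> float:
    """Shared entropy  I(A;B) = H(A) + H(B) - H(AB).

    Overlapping sets are allowed; the joint AB deduplicates columns, which
    gives the self-information identity I(X;X) = H(X).  The plug-in estimate
    is clipped at zero to absorb floating-point noise.
    """
    if not set_a or not set_b:
        raise ValueError("both variable sets must be non-empty")
    h_a = joint_entropy(table, set_a)
    h_b = joint_entropy(table, set_b)
    h_ab = joint_entropy(table, list(set_a) + list(set_b))
    return max(0.0, h_a + h_b - h_ab)


def co_information(
    table: PairedTable,
    set_a: Sequence[str],
    set_b: Sequence[str],
    set_c: Sequence[str],
) -> float:
    """Three-way co-information  I(A;B;C) = I(A;C) + I(B;C) - I(AB;C).

    Unlike pairwise shared entropy this may be negative: negative values
    signal synergy (XOR / one-time-pad structure).
    """
    i_ac = mutual_information(table, set_a, set_c)
    i_bc = mutual_information(table, set_b, set_c)
    i_ab_c = mutual_information(table, list(set_a) + list(set_b), set_c)
    return i_ac + i_bc - i_ab_c


@dataclass(frozen=True)
class VennDecomposition3:
    """The seven regions of a three-circle entropy Venn diagram."""

    h_a_given_bc: float
    h_b_given_ac: float
    h_c_given_ab: float
    i_ab_given_c: float
    i_ac_given_b: float
    i_bc_given_a: float
    i_abc: float

    def circle(self, which: str) -> tuple[float, float, float, float]:
        """The four region values inside one variable's circle; they sum to
        that variable's entropy."""
        if which == "a":
            return (self.h_a_given_bc, self.i_ab_given_c, self.i_ac_given_b, self.i_abc)
        if which == "b":
            return (self.h_b_given_ac, self.i_ab_given_c, self.i_bc_given_a, self.i_abc)
        if which == "c":
            return (self.h_c_given_ab, self.i_ac_given_b, self.i_bc_given_a, self.i_abc)
        raise ValueError("which must be 'a', 'b' or 'c'")

    def circle_sum(self, which: str) -> float:
        return float(sum(self.circle(which)))


def venn3(
    table: PairedTable,
    set_a: Sequence[str],
    set_b: Sequence[str],
    set_c: Sequence[str],
) -> VennDecomposition3:
    """Three-variable entropy Venn decomposition from joint entropies only."""
    a, b, c = list(set_a), list(set_b), list(set_c)
    h_a = joint_entropy(table, a)
    h_b = joint_entropy(table, b)
    h_c = joint_entropy(table, c)
    h_ab = joint_entropy(table, a + b)
    h_ac = joint_entropy(table, a + c)
    h_bc = joint_entropy(table, b + c)
    h_abc = joint_entropy(table, a + b + c)
    return VennDecomposition3(
        h_a_given_bc=h_abc - h_bc,
        h_b_given_ac=h_abc - h_ac,
        h_c_given_ab=h_abc - h_ab,
        i_ab_given_c=h_ac + h_bc - h_c - h_abc,
        i_ac_given_b=h_ab + h_bc - h_b - h_abc,
        i_bc_given_a=h_ab + h_ac - h_a - h_abc,
        i_abc=h_a + h_b + h_c - h_ab - h_ac - h_bc + h_abc,
    )


def _dedup(ids: Sequence[str]) -> list[str]:
    seen: list[str] = []
    for c in ids:
        if c not in seen:
            seen.append(c)
    return seen
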