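"""Hand-built brains and synthetic tables with known information structure.

These constructions make every analysis stage testable without running
evolution: a shift-register brain whose information is perfectly localized
(every feature has fragmentation 1 and the flow graph is a set of linear
chains), an XOR delay circuit that moves a bit through a one-time-pad
encryption/decryption cycle (fragmentation 2, zero pairwise information,
co-information -1), and random paired tables with planted structure
(independent, copied, or k-node parity features).

The k-node parity feature generalizes the two-node one-time pad: every
strict subset of the parity set carries zero shared entropy with the
feature, which stresses the irreducibility pruning of the DIS search.
"""

from __future__ import annotations

import numpy as np

from .state_records import PairedTable
from .substrates import NBACK_LAYOUT, BrainLayout, MarkovBrain, MarkovGate

__all__ = ["make_copy_chain", "make_xor_delay", "make_random_table"]


def _copy_gate(layout: BrainLayout, src: str, dst: str) -> MarkovGate:
    """2-in/2-out gate that copies one T0 node to one T1 node (both arity
    slots repeat the same node, so no spurious wiring appears)."""
    a = layout.t0_ids.index(src)
    b = layout.t1_ids.index(dst)
    table = np.zeros((4, 2), dtype=np.uint8)
    table[3] = 1  # index (1,1) -> 1; (0,0) -> 0; mixed rows unreachable
    return MarkovGate((a, a), (b, b), table)


def _xor_gate(layout: BrainLayout, src1: str, src2: str, dst: str) -> MarkovGate:
    a1 = layout.t0_ids.index(src1)
    a2 = layout.t0_ids.index(src2)
    b = layout.t1_ids.index(dst)
    table = np.array([[0, 0], [1, 1], [1, 1], [0, 0]], dtype=np.uint8)
    return MarkovGate((a1, a2), (b, b), table)


def make_copy_chain(delays: tuple[int, ...] = (1, 3, 5, 7, 8)) -> MarkovBrain:
    """Shift-register brain solving n-Back perfectly with zero fragmentation.

    The input bit is passed down a memory chain m1 -> m2 -> ... and each
    output taps the memory cell holding exactly its delay, so every feature
    is predicted by a single node and the flow graph is a set of linear
    chains.
    """
    layout = BrainLayout(n_inputs=1, n_outputs=len(delays), n_memory=max(delays))
    gates = [_copy_gate(layout, "i1", "m1")]
    for k in range(2, max(delays) + 1):
        gates.append(_copy_gate(layout, f"m{k - 1}", f"m{k}"))
    for j, d in enumerate(delays):
        gates.append(_copy_gate(layout, f"m{d}", f"o{j + 1}"))
    return MarkovBrain(layout, gates)


def make_xor_delay() -> MarkovBrain:
    """The XOR encryption/decryption delay circuit.

    m6 latches the current input x_t; m2 copies it one step later; m7 stores
    the one-time pad x_{t-2} XOR x_{t-1}; o5 decrypts m7 with the key m2,
    which algebraically reduces to a clean 3-step delay:
    o5(t) = m2 XOR m7 = x_{t-2} XOR (x_{t-3} XOR x_{t-2}) = x_{t-3}.

    Individually m2 and m7 carry zero information about o5 — the DIS for o5
    is the pair {m2, m7} and the triple (m2, m7, o5) shows the one-time-pad
    Venn signature with co-information -1.
    """
    layout = NBACK_LAYOUT
    gates = [
        _copy_gate(layout, "i1", "m6"),
        _copy_gate(layout, "m6", "m2"),
        _xor_gate(layout, "m2", "m6", "m7"),
        _xor_gate(layout, "m2", "m7", "o5"),
    ]
    return MarkovBrain(layout, gates)


def make_random_table(
    n_nodes: int,
    n_rows: int,
    structure: str = "independent",
    seed: int = 0,
) -> PairedTable:
    """Synthetic paired table with a planted feature Y over binary predictors
    x1..xn.

    structure: ``"independent"`` (Y is a fresh random bit), ``"copy"``
    (Y = x1), or ``"parity-k"`` (Y = XOR of the first k predictors; any
    strict subset of them shares no entropy with Y).
    """
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 2, size=(n_rows, n_nodes), dtype=np.uint8)
    if structure == "independent":
        y = rng.integers(0, 2, size=n_rows, dtype=np.uint8)
    elif structure == "copy":
        y = X[:, 0].copy()
    elif structure.startswith("parity-"):
        k = int(structure.split("-", 1)[1])
        if not 1 <= k <= n_nodes:
            raise ValueError(f"parity size {k} outside [1, {n_nodes}]")
        y = np.bitwise_xor.reduce(X[:, :k], axis=1)
    else:
        raise ValueError(f"unknown structure: {structure!r}")
    predictors = tuple(f"x{j + 1}" for j in range(n_nodes))
    data = np.column_stack([X, y])
    return PairedTable(predictors, ("Y",), data)
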