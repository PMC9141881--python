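"""Genome-decoded network substrates: Markov Brains and recurrent networks.

Both substrates map a T0 state (sensor inputs joined with memory-before) to a
T1 state (outputs joined with memory-after) in one synchronous update:

* A *Markov Brain* is a sparse network of logic gates, each reading 2-4 T0
  nodes and writing 2-4 T1 nodes through an arbitrary lookup table; when
  several gates write the same node the results combine by OR.  Gates are
  decoded from a byte genome by scanning for a start codon (a fixed byte
  pair); the bytes following each codon set the gate's arities, wiring and
  truth table.  The concrete gene byte layout here (codon, arity, address and
  table fields) is this package's own frozen convention, chosen so decodes
  are reproducible and unit-testable.

* An *RNNBrain* is a single-layer fully connected recurrent network
  Y_i = tanh(sum_j w_ij X_j + c_i) with genome-decoded weights in [-1, 1]
  and biases in [-3, 3].  Outputs and recurrent memory are discretized
  (<= 0 -> 0, > 0 -> 1) before recording and recurrence, which makes the
  network a finite-state deterministic map and hence analyzable at theta=1.

Updates are batched: a state matrix of shape (batch, n_t0) maps to
(batch, n_t1), so a whole population of task lifetimes advances in a few
vector operations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "START_CODON",
    "BrainLayout",
    "Genome",
    "MarkovGate",
    "MarkovBrain",
    "RNNBrain",
    "Connectome",
    "random_genome",
    "seed_start_codons",
    "decode_markov_brain",
    "decode_rnn",
    "connectome_of",
]

#: start-codon byte pair marking the beginning of a gate gene
START_CODON = (42, 213)

GENOME_MIN, GENOME_MAX = 2000, 20000
GENOME_INIT = 5000

Genome = np.ndarray  # 1-D uint8 array


@dataclass(frozen=True)
class BrainLayout:
    """Node layout shared by both substrates.

    T0 = [inputs..., memory-before...], T1 = [outputs..., memory-after...].
    Node ids are ``i1..``, ``o1..`` and ``m1..`` (memory ids name both the
    before and after view of the same node).
    """

    n_inputs: int
    n_outputs: int
    n_memory: int = 8

    @property
    def n_t0(self) -> int:
        return self.n_inputs + self.n_memory

    @property
    def n_t1(self) -> int:
        return self.n_outputs + self.n_memory

    @property
    def input_ids(self) -> tuple[str, ...]:
        return tuple(f"i{k + 1}" for k in range(self.n_inputs))

    @property
    def output_ids(self) -> tuple[str, ...]:
        return tuple(f"o{k + 1}" for k in range(self.n_outputs))

    @property
    def memory_ids(self) -> tuple[str, ...]:
        return tuple(f"m{k + 1}" for k in range(self.n_memory))

    @property
    def t0_ids(self) -> tuple[str, ...]:
        return self.input_ids + self.memory_ids

    @property
    def t1_ids(self) -> tuple[str, ...]:
        return self.output_ids + self.memory_ids


NBACK_LAYOUT = BrainLayout(n_inputs=1, n_outputs=5, n_memory=8)
BLOCKCATCH_LAYOUT = BrainLayout(n_inputs=4, n_outputs=2, n_memory=8)


def random_genome(rng: np.random.Generator, length: int = GENOME_INIT) -> Genome:
    return rng.integers(0, 256, size=length, dtype=np.uint8)


def save_genome(g: Genome, path: str | Path) -> None:
    """Write a genome as hex text (one long line)."""
    Path(path).write_text(bytes(np.asarray(g, dtype=np.uint8)).hex() + "\n")


def load_genome(path: str | Path) -> Genome:
    return np.frombuffer(bytes.fromhex(Path(path).read_text().strip()), dtype=np.uint8).copy()


def seed_start_codons(g: Genome, n_codons: int = 6) -> Genome:
    """Overwrite ``n_codons`` evenly spaced sites with the start codon so a
    fresh random genome decodes to a workable number of gates."""
    g = g.copy()
    stride = max(len(g) // max(n_codons, 1), 80)
    for k in range(n_codons):
        at = k * stride
        if at + 1 < len(g):
            g[at] = START_CODON[0]
            g[at + 1] = START_CODON[1]
    return g


# ---------------------------------------------------------------------------
# Markov Brains

@dataclass
class MarkovGate:
    in_ids: tuple[int, ...]   # T0 node indices, 2-4 of them
    out_ids: tuple[int, ...]  # T1 node indices, 2-4 of them
    table: np.ndarray         # (2^n_in, n_out) of 0/1

    def __post_init__(self) -> None:
        if not 2 <= len(self.in_ids) <= 4 or not 2 <= len(self.out_ids) <= 4:
            raise ValueError("gate arities must be within [2, 4]")
        self.table = np.asarray(self.table, dtype=np.uint8)
        if self.table.shape != (1 << len(self.in_ids), len(self.out_ids)):
            raise ValueError("lookup table rows must be 2^(#inputs)")


@dataclass
class MarkovBrain:
    layout: BrainLayout
    gates: list[MarkovGate]

    def update(self, t0: np.ndarray) -> np.ndarray:
        """Map T0 states to T1 states; accepts (n_t0,) or (batch, n_t0).

        All T1 nodes default to 0; colliding gate writes are OR'd.  The first
        listed gate input is the most significant bit of the table index.
        """
        single = t0.ndim == 1
        X = np.atleast_2d(np.asarray(t0, dtype=np.uint8))
        if X.shape[1] != self.layout.n_t0:
            raise ValueError(
                f"t0 has width {X.shape[1]}, layout expects {self.layout.n_t0}"
            )
        if X.max(initial=0) > 1:
            raise ValueError("state symbols must be binary")
        Y = np.zeros((X.shape[0], self.layout.n_t1), dtype=np.uint8)
        for gate in self.gates:
            idx = X[:, gate.in_ids[0]].astype(np.intp)
            for a in gate.in_ids[1:]:
                idx = (idx << 1) | X[:, a]
            rows = gate.table[idx]  # (batch, n_out)
            for j, out in enumerate(gate.out_ids):
                Y[:, out] |= rows[:, j]
        return Y[0] if single else Y

    def to_json_dict(self) -> dict:
        return {
            "type": "markov",
            "layout": [self.layout.n_inputs, self.layout.n_outputs, self.layout.n_memory],
            "gates": [
                {
                    "inputs": list(g.in_ids),
                    "outputs": list(g.out_ids),
                    "table": g.table.tolist(),
                }
                for g in self.gates
            ],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=1))

    @staticmethod
    def from_json_dict(d: dict) -> "MarkovBrain":
        layout = BrainLayout(*d["layout"])
        gates = [
            MarkovGate(tuple(g["inputs"]), tuple(g["outputs"]), np.array(g["table"]))
            for g in d["gates"]
        ]
        return MarkovBrain(layout, gates)


def decode_markov_brain(g: Genome, layout: BrainLayout) -> MarkovBrain:
    """Decode one gate per start-codon occurrence; truncated genes at the
    genome end are skipped, so decoding is a total function of the bytes.

    Gene layout after the codon: 1 byte #inputs (mod 3 + 2), 1 byte #outputs
    (mod 3 + 2), 4 bytes of input addresses (mod n_t0), 4 bytes of output
    addresses (mod n_t1) of which the first #inputs / #outputs are used, then
    2^#inputs x #outputs table bytes (mod 2, row-major).
    """
    g = np.asarray(g, dtype=np.uint8)
    gates: list[MarkovGate] = []
    if len(g) < 2:
        return MarkovBrain(layout, gates)
    starts = np.flatnonzero((g[:-1] == START_CODON[0]) & (g[1:] == START_CODON[1]))
    for at in starts:
        p = at + 2
        if p + 10 > len(g):
            continue
        n_in = int(g[p]) % 3 + 2
        n_out = int(g[p + 1]) % 3 + 2
        in_ids = tuple(int(b) % layout.n_t0 for b in g[p + 2 : p + 2 + n_in])
        out_ids = tuple(int(b) % layout.n_t1 for b in g[p + 6 : p + 6 + n_out])
        t_len = (1 << n_in) * n_out
        t_start = p + 10
        if t_start + t_len > len(g):
            continue
        table = (g[t_start : t_start + t_len] % 2).reshape(1 << n_in, n_out)
        gates.append(MarkovGate(in_ids, out_ids, table))
    return MarkovBrain(layout, gates)


# ---------------------------------------------------------------------------
# recurrent networks

@dataclass
class RNNBrain:
    layout: BrainLayout
    weights: np.ndarray  # (n_t1, n_t0) in [-1, 1]
    biases: np.ndarray   # (n_t1,) in [-3, 3]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.biases = np.asarray(self.biases, dtype=float)
        if self.weights.shape != (self.layout.n_t1, self.layout.n_t0):
            raise ValueError("weight matrix shape mismatch")
        if self.biases.shape != (self.layout.n_t1,):
            raise ValueError("bias vector shape mismatch")
        if np.any(np.abs(self.weights) > 1.0) or np.any(np.abs(self.biases) > 3.0):
            raise ValueError("weights must lie in [-1,1], biases in [-3,3]")

    def update(self, t0: np.ndarray) -> np.ndarray:
        """tanh summation units followed by discretization (<=0 -> 0, >0 -> 1)."""
        single = t0.ndim == 1
        X = np.atleast_2d(np.asarray(t0, dtype=float))
        if X.shape[1] != self.layout.n_t0:
            raise ValueError(
                f"t0 has width {X.shape[1]}, layout expects {self.layout.n_t0}"
            )
        Y = np.tanh(X @ self.weights.T + self.biases)
        out = (Y > 0).astype(np.uint8)
        return out[0] if single else out

    def to_json_dict(self) -> dict:
        return {
            "type": "rnn",
            "layout": [self.layout.n_inputs, self.layout.n_outputs, self.layout.n_memory],
            "weights": self.weights.tolist(),
            "biases": self.biases.tolist(),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=1))

    @staticmethod
    def from_json_dict(d: dict) -> "RNNBrain":
        return RNNBrain(
            BrainLayout(*d["layout"]), np.array(d["weights"]), np.array(d["biases"])
        )


def decode_rnn(g: Genome, layout: BrainLayout) -> RNNBrain:
    """Map genome bytes linearly onto (n_t0 + 1) * n_t1 parameters.

    Per T1 node: n_t0 weight bytes then one bias byte.  Byte 0 maps to the
    range minimum, byte 255 to the maximum (weights [-1, 1], biases [-3, 3]).
    The site count is fixed regardless of genome surplus.
    """
    g = np.asarray(g, dtype=np.uint8)
    n, m = layout.n_t0, layout.n_t1
    needed = (n + 1) * m
    if len(g) < needed:
        raise ValueError(
            f"genome too short: {len(g)} bytes, need {needed} for "
            f"({n}+1) x {m} parameters"
        )
    params = g[:needed].astype(float).reshape(m, n + 1) / 255.0
    weights = params[:, :n] * 2.0 - 1.0
    biases = params[:, n] * 6.0 - 3.0
    return RNNBrain(layout, weights, biases)


# ---------------------------------------------------------------------------
# connectomes

@dataclass(frozen=True)
class Connectome:
    """Directed physical links from T0 node ids to T1 node ids.

    A link exists iff some gate reads the source and writes the target
    (Markov) or the corresponding weight is nonzero (RNN).
    """

    links: frozenset[tuple[str, str]]

    def supports(self, source: str, target: str) -> bool:
        return (source, target) in self.links

    def to_json_dict(self) -> dict:
        return {"links": sorted([list(l) for l in self.links])}

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=1))

    @staticmethod
    def from_json_dict(d: dict) -> "Connectome":
        return Connectome(frozenset(tuple(l) for l in d["links"]))

    @staticmethod
    def load(path: str | Path) -> "Connectome":
        return Connectome.from_json_dict(json.loads(Path(path).read_text()))


def connectome_of(brain: MarkovBrain | RNNBrain) -> Connectome:
    """Extract the substrate's wiring as id-level links."""
    layout = brain.layout
    links: set[tuple[str, str]] = set()
    if isinstance(brain, MarkovBrain):
        for gate in brain.gates:
            for a in gate.in_ids:
                for b in gate.out_ids:
                    links.add((layout.t0_ids[a], layout.t1_ids[b]))
    elif isinstance(brain, RNNBrain):
        rows, cols = np.nonzero(brain.weights)
        for r, c in zip(rows, cols):
            links.add((layout.t0_ids[c], layout.t1_ids[r]))
    else:
        raise TypeError(f"unsupported substrate: {type(brain).__name__}")
    return Connectome(frozenset(links))


def load_brain(path: str | Path) -> MarkovBrain | RNNBrain:
    d = json.loads(Path(path).read_text())
    if d.get("type") == "markov":
        return MarkovBrain.from_json_dict(d)
    if d.get("type") == "rnn":
        return RNNBrain.from_json_dict(d)
    raise ValueError(f"unknown brain type in {path}")
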