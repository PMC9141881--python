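"""Discrete multivariate state recordings collected over agent lifetimes.

A :class:`StateRecording` holds, per lifetime, tables of discrete node states
over time for four node groups: sensory inputs (``i*``), motor/readout outputs
(``o*``), recurrent memory (``m*``) and world features (anything else).  Within
one lifetime the input, output and world tables have ``L`` rows (one per
scored update) while the memory table has ``L + 1`` rows: row ``t`` is the
memory state *before* update ``t`` and row ``t + 1`` the state after it, so
the "before" state of an update equals the "after" state of the previous one.

Rows from all lifetimes are pooled (never averaged per lifetime) when joint
probabilities are estimated, and pairing of predictors at ``t-1`` with
features at ``t`` never crosses a lifetime boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NodeSchema",
    "Lifetime",
    "StateRecording",
    "PairedTable",
    "ProbabilityTable",
    "load_recording",
    "save_recording",
    "pair_states",
    "trim_late_lifetime",
    "estimate_probabilities",
]

#: file-format suffix that marks a memory-after column
AFTER_SUFFIX = "_next"


class RecordingError(ValueError):
    """Malformed recording data; message carries lifetime/update location."""


@dataclass(frozen=True)
class NodeSchema:
    """Declares which node ids belong to which group."""

    inputs: tuple[str, ...] = ()
    outputs: tuple[str, ...] = ()
    memory: tuple[str, ...] = ()
    world: tuple[str, ...] = ()

    @staticmethod
    def infer(columns: Sequence[str]) -> "NodeSchema":
        """Infer groups from id prefixes: i*/o*/m* are input/output/memory,
        ``*_next`` columns are the memory-after view, the rest are world
        features."""
        ins, outs, mem, world = [], [], [], []
        for c in columns:
            if c.endswith(AFTER_SUFFIX):
                continue
            if c.startswith("i") and c[1:].isdigit():
                ins.append(c)
            elif c.startswith("o") and c[1:].isdigit():
                outs.append(c)
            elif c.startswith("m") and c[1:].isdigit():
                mem.append(c)
            else:
                world.append(c)
        return NodeSchema(tuple(ins), tuple(outs), tuple(mem), tuple(world))

    @property
    def all_ids(self) -> tuple[str, ...]:
        return self.inputs + self.outputs + self.memory + self.world


@dataclass
class Lifetime:
    """One test episode: L scored updates of synchronized state tables."""

    inputs: np.ndarray   # (L, n_in)
    outputs: np.ndarray  # (L, n_out)
    memory: np.ndarray   # (L + 1, n_mem); row t = before update t
    world: np.ndarray    # (L, n_world)

    def __post_init__(self) -> None:
        L = self.inputs.shape[0]
        if self.outputs.shape[0] != L or self.world.shape[0] != L:
            raise RecordingError(
                f"input/output/world tables must have equal row counts, got "
                f"{L}/{self.outputs.shape[0]}/{self.world.shape[0]}"
            )
        if self.memory.shape[0] != L + 1:
            raise RecordingError(
                f"memory table must have L+1={L + 1} rows, got "
                f"{self.memory.shape[0]}"
            )

    @property
    def n_updates(self) -> int:
        return self.inputs.shape[0]

    @property
    def memory_before(self) -> np.ndarray:
        return self.memory[:-1]

    @property
    def memory_after(self) -> np.ndarray:
        return self.memory[1:]


@dataclass
class StateRecording:
    """Ordered lifetimes plus the node-group declaration."""

    schema: NodeSchema
    lifetimes: list[Lifetime] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return sum(lt.n_updates for lt in self.lifetimes)

    def validate(self) -> None:
        s = self.schema
        for k, lt in enumerate(self.lifetimes):
            widths = (
                (lt.inputs.shape[1], len(s.inputs), "input"),
                (lt.outputs.shape[1], len(s.outputs), "output"),
                (lt.memory.shape[1], len(s.memory), "memory"),
                (lt.world.shape[1], len(s.world), "world"),
            )
            for got, want, name in widths:
                if got != want:
                    raise RecordingError(
                        f"lifetime {k}: {name} table has {got} columns, "
                        f"schema declares {want}"
                    )


# ---------------------------------------------------------------------------
# paired predictor/feature tables

@dataclass
class PairedTable:
    """Rows of joint states: predictor nodes at t-1 joined with feature
    nodes at t.

    Column ids may be qualified to break ties when the same node id occurs
    on both sides: ``"m2@t-1"`` (predictor view) or ``"m2@t"`` (feature
    view).  Unqualified ids are accepted whenever they are unambiguous.
    """

    predictor_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]
    data: np.ndarray  # (n_rows, n_pred + n_feat) integer symbols

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.shape[1] != len(
            self.predictor_ids
        ) + len(self.feature_ids):
            raise ValueError("data shape does not match declared columns")

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    def column_index(self, node_id: str) -> int:
        """Resolve a (possibly qualified) node id to a data column."""
        if node_id.endswith("@t-1"):
            bare = node_id[:-4]
            if bare in self.predictor_ids:
                return self.predictor_ids.index(bare)
            raise KeyError(f"unknown predictor node id: {bare!r}")
        if node_id.endswith("@t"):
            bare = node_id[:-2]
            if bare in self.feature_ids:
                return len(self.predictor_ids) + self.feature_ids.index(bare)
            raise KeyError(f"unknown feature node id: {bare!r}")
        in_pred = node_id in self.predictor_ids
        in_feat = node_id in self.feature_ids
        if in_pred and in_feat:
            raise KeyError(
                f"node id {node_id!r} is ambiguous; qualify with @t-1 or @t"
            )
        if in_pred:
            return self.predictor_ids.index(node_id)
        if in_feat:
            return len(self.predictor_ids) + self.feature_ids.index(node_id)
        raise KeyError(f"unknown node id: {node_id!r}")

    def columns(self, node_ids: Iterable[str]) -> np.ndarray:
        idx = [self.column_index(c) for c in node_ids]
        return self.data[:, idx]

    def to_frame(self) -> pd.DataFrame:
        cols = list(self.predictor_ids) + [
            f + "@t" if f in self.predictor_ids else f for f in self.feature_ids
        ]
        return pd.DataFrame(self.data, columns=cols)


@dataclass
class ProbabilityTable:
    """Maximum-likelihood joint-state frequencies over observed states only."""

    states: list[tuple]
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if len(self.states) != self.probs.size:
            raise ValueError("states/probs length mismatch")
        if np.any(self.probs <= 0):
            raise ValueError("all probabilities must be positive")
        if abs(self.probs.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")

    @property
    def n(self) -> int:
        return len(self.states)

    @staticmethod
    def from_probs(probs: Sequence[float]) -> "ProbabilityTable":
        """Build a table from bare probabilities (states are anonymous)."""
        return ProbabilityTable([(k,) for k in range(len(probs))], probs)

    @staticmethod
    def from_counts(states: list[tuple], counts: np.ndarray) -> "ProbabilityTable":
        counts = np.asarray(counts, dtype=float)
        return ProbabilityTable(states, counts / counts.sum())


# ---------------------------------------------------------------------------
# operations

def pair_states(
    rec: StateRecording,
    predictors: Sequence[str],
    features: Sequence[str],
) -> PairedTable:
    """Join predictor nodes at t-1 with feature nodes at t, one row per
    scored update per lifetime.

    Predictor ids resolve against the input and memory-before views; feature
    ids against the output, memory-after and world views.  World features
    are recorded at the same alignment as inputs (t-1 relative to outputs at
    t), so all groups share a row index inside a lifetime and pairing never
    crosses lifetimes.
    """
    if not rec.lifetimes:
        raise RecordingError("empty recording")
    s = rec.schema

    def pred_view(lt: Lifetime, node: str) -> np.ndarray:
        if node in s.inputs:
            return lt.inputs[:, s.inputs.index(node)]
        if node in s.memory:
            return lt.memory_before[:, s.memory.index(node)]
        raise KeyError(f"unknown predictor node id: {node!r}")

    def feat_view(lt: Lifetime, node: str) -> np.ndarray:
        if node in s.outputs:
            return lt.outputs[:, s.outputs.index(node)]
        if node in s.memory:
            return lt.memory_after[:, s.memory.index(node)]
        if node in s.world:
            return lt.world[:, s.world.index(node)]
        raise KeyError(f"unknown feature node id: {node!r}")

    blocks = []
    for lt in rec.lifetimes:
        cols = [pred_view(lt, p) for p in predictors]
        cols += [feat_view(lt, f) for f in features]
        blocks.append(np.column_stack(cols))
    data = np.concatenate(blocks, axis=0)
    return PairedTable(tuple(predictors), tuple(features), data)


def trim_late_lifetime(rec: StateRecording, fraction: float) -> StateRecording:
    """Keep only the late-lifetime portion of each lifetime.

    Each lifetime keeps its last ``max(1, round(fraction * L))`` updates
    (round half-up), preserving the memory before/after alignment.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    out = []
    for lt in rec.lifetimes:
        L = lt.n_updates
        keep = max(1, int(np.floor(fraction * L + 0.5)))
        keep = min(keep, L)
        out.append(
            Lifetime(
                inputs=lt.inputs[L - keep :],
                outputs=lt.outputs[L - keep :],
                memory=lt.memory[L - keep :],
                world=lt.world[L - keep :],
            )
        )
    return StateRecording(rec.schema, out)


def estimate_probabilities(
    table: PairedTable, subset: Sequence[str]
) -> ProbabilityTable:
    """ML joint-state frequencies over the projection onto ``subset``.

    Counts the number of times unique joint states are observed; the support
    contains observed states only.
    """
    if not subset:
        raise ValueError("subset must be non-empty")
    if table.n_rows == 0:
        raise ValueError("empty table")
    proj = table.columns(subset)
    uniq, counts = np.unique(proj, axis=0, return_counts=True)
    states = [tuple(row) for row in uniq]
    return ProbabilityTable.from_counts(states, counts)


# ---------------------------------------------------------------------------
# file I/O: TSV/CSV with header  lifetime,update,<node ids...>
# memory-after columns carry the `_next` suffix.

def save_recording(rec: StateRecording, path: str | Path, sep: str = "\t") -> None:
    s = rec.schema
    cols = (
        ["lifetime", "update"]
        + list(s.inputs)
        + list(s.outputs)
        + list(s.memory)
        + [m + AFTER_SUFFIX for m in s.memory]
        + list(s.world)
    )
    rows = []
    for k, lt in enumerate(rec.lifetimes):
        for t in range(lt.n_updates):
            rows.append(
                [k, t]
                + list(lt.inputs[t])
                + list(lt.outputs[t])
                + list(lt.memory_before[t])
                + list(lt.memory_after[t])
                + list(lt.world[t])
            )
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=sep, index=False)


def load_recording(
    path: str | Path, schema: NodeSchema | None = None
) -> StateRecording:
    """Read a recording file; errors report the offending lifetime/update.

    The file is tab- or comma-separated with a ``lifetime,update,...`` header;
    the node group declaration is inferred from column prefixes when not
    given.  The memory before/after chaining (``m(t)_next == m(t+1)``) is
    verified on load.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise RecordingError(f"{path}: malformed file: {exc}") from exc
    for required in ("lifetime", "update"):
        if required not in df.columns:
            raise RecordingError(f"{path}: missing required column {required!r}")
    node_cols = [c for c in df.columns if c not in ("lifetime", "update")]
    if schema is None:
        schema = NodeSchema.infer(node_cols)
    declared = set(schema.all_ids) | {m + AFTER_SUFFIX for m in schema.memory}
    unknown = [c for c in node_cols if c not in declared]
    if unknown:
        raise RecordingError(f"{path}: undeclared node columns: {unknown}")
    missing = [c for c in declared if c not in node_cols]
    if missing:
        raise RecordingError(f"{path}: schema columns absent from file: {missing}")

    lifetimes = []
    for k, grp in df.groupby("lifetime", sort=True):
        grp = grp.sort_values("update")
        upd = grp["update"].to_numpy()
        if not np.array_equal(upd, np.arange(len(upd))):
            raise RecordingError(
                f"{path}: lifetime {k}: update indices are not contiguous "
                f"from 0 (got {upd.tolist()[:5]}...)"
            )
        ins = grp[list(schema.inputs)].to_numpy(dtype=int)
        outs = grp[list(schema.outputs)].to_numpy(dtype=int)
        world = grp[list(schema.world)].to_numpy(dtype=int)
        mem_before = grp[list(schema.memory)].to_numpy(dtype=int)
        mem_after = grp[[m + AFTER_SUFFIX for m in schema.memory]].to_numpy(dtype=int)
        if len(upd) > 1 and not np.array_equal(mem_after[:-1], mem_before[1:]):
            bad = int(
                np.nonzero(np.any(mem_after[:-1] != mem_before[1:], axis=1))[0][0]
            )
            raise RecordingError(
                f"{path}: lifetime {k}, update {bad}: memory-after does not "
                f"match the next update's memory-before"
            )
        memory = (
            np.concatenate([mem_before, mem_after[-1:]], axis=0)
            if len(upd)
            else mem_before
        )
        lifetimes.append(Lifetime(ins, outs, memory, world))
    rec = StateRecording(schema, lifetimes)
    rec.validate()
    return rec
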