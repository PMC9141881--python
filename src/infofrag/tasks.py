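"""Task environments, agent evaluation, fitness and state recording.

Two environments are provided:

* **n-Back** — a memory task: one input bit per update must be echoed on five
  output nodes with delays {1, 3, 5, 7, 8}.  Each evaluation runs 25
  lifetimes of a 33-bit random string; the first 8 updates of each lifetime
  are an unscored warm-up (no state is recorded either) so the maximum delay
  fits in memory before scoring starts.  Fitness is correct answers over
  total answers; random guessing scores 0.5 in expectation.

* **Block Catch** — an active categorical perception task in a 32-high,
  20-wide world with lateral wraparound.  Blocks of sizes {2, 3, 4} fall one
  unit per update while drifting left or right one unit per update; the agent
  is a 6-unit paddle with four upward sensors in the mask ``S S _ _ S S``
  (a central blind spot of width two).  Size-2 blocks and right-moving
  size-3 blocks must be caught, size-4 and left-moving size-3 blocks must be
  avoided; a block is caught iff any part of it overlaps any part of the
  paddle body at landing.  Every (size, direction, start position) combination
  is one lifetime: 3 x 2 x 20 = 120 lifetimes of 31 updates.  Fitness is
  correct decisions / 120.

All lifetimes of an evaluation advance in one batched brain update per time
step, and evaluation is deterministic given (agent, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .state_records import Lifetime, NodeSchema, StateRecording
from .substrates import (
    BLOCKCATCH_LAYOUT,
    NBACK_LAYOUT,
    BrainLayout,
    MarkovBrain,
    RNNBrain,
)

__all__ = [
    "NBackConfig",
    "BlockCatchConfig",
    "EvaluationResult",
    "Agent",
    "BrainAgent",
    "RandomOutputAgent",
    "ConstantOutputAgent",
    "run_nback",
    "run_blockcatch",
    "world_features",
    "WORLD_FEATURE_NAMES",
]


# ---------------------------------------------------------------------------
# agents

class Agent:
    """Batched agent interface: ``step`` maps sensor inputs (batch, n_in) to
    outputs (batch, n_out) while maintaining per-lifetime memory state."""

    layout: BrainLayout

    def reset(self, batch: int) -> None:
        self.memory = np.zeros((batch, self.layout.n_memory), dtype=np.uint8)

    def step(self, inputs: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class BrainAgent(Agent):
    """Wraps a substrate; memory-before/after of the latest step are exposed
    for state recording."""

    def __init__(self, brain: MarkovBrain | RNNBrain):
        self.brain = brain
        self.layout = brain.layout

    def step(self, inputs: np.ndarray) -> np.ndarray:
        self.memory_before = self.memory
        t0 = np.concatenate([inputs.astype(np.uint8), self.memory], axis=1)
        t1 = self.brain.update(t0)
        n_out = self.layout.n_outputs
        self.memory = t1[:, n_out:]
        return t1[:, :n_out]


class RandomOutputAgent(Agent):
    """Emits i.i.d. uniform random output bits, ignoring inputs and memory."""

    def __init__(self, layout: BrainLayout, seed: int = 0):
        self.layout = layout
        self.rng = np.random.default_rng(seed)

    def step(self, inputs: np.ndarray) -> np.ndarray:
        self.memory_before = self.memory
        return self.rng.integers(
            0, 2, size=(inputs.shape[0], self.layout.n_outputs), dtype=np.uint8
        )


class ConstantOutputAgent(Agent):
    """Always emits the same output pattern (default all zeros)."""

    def __init__(self, layout: BrainLayout, pattern: tuple[int, ...] | None = None):
        self.layout = layout
        self.pattern = np.array(
            pattern if pattern is not None else [0] * layout.n_outputs,
            dtype=np.uint8,
        )

    def step(self, inputs: np.ndarray) -> np.ndarray:
        self.memory_before = self.memory
        return np.broadcast_to(self.pattern, (inputs.shape[0], self.pattern.size)).copy()


# ---------------------------------------------------------------------------
# configs and results

@dataclass(frozen=True)
class NBackConfig:
    delays: tuple[int, ...] = (1, 3, 5, 7, 8)
    n_lifetimes: int = 25
    string_length: int = 33
    warmup: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if max(self.delays) > self.warmup:
            raise ValueError("max delay must not exceed the unscored warm-up")
        if self.string_length <= self.warmup:
            raise ValueError("string length must exceed the warm-up")


@dataclass(frozen=True)
class BlockCatchConfig:
    width: int = 20
    height: int = 32
    sizes: tuple[int, ...] = (2, 3, 4)
    directions: tuple[int, ...] = (-1, 1)  # -1 = left, +1 = right
    n_updates: int = 31
    sensor_offsets: tuple[int, ...] = (0, 1, 4, 5)  # mask S S _ _ S S
    body_width: int = 6

    @property
    def n_lifetimes(self) -> int:
        return len(self.sizes) * len(self.directions) * self.width


@dataclass
class EvaluationResult:
    fitness: float
    recording: StateRecording | None
    details: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# n-Back

def run_nback(
    agent: Agent, cfg: NBackConfig = NBackConfig(), record: bool = True
) -> EvaluationResult:
    """Evaluate an agent on n-Back; expects layout 1 input, 5 outputs.

    Scoring and state recording start after the warm-up; expected outputs are
    the input bits delayed by ``cfg.delays`` and are also recorded as world
    features ``e1..`` for matrix construction against expected values.
    ``record=False`` skips recording assembly (for tight evolution loops).
    """
    lay = agent.layout
    if lay.n_inputs != 1 or lay.n_outputs != len(cfg.delays):
        raise ValueError(
            f"layout mismatch: n-Back needs 1 input and {len(cfg.delays)} "
            f"outputs, agent has {lay.n_inputs}/{lay.n_outputs}"
        )
    rng = np.random.default_rng(cfg.seed)
    B, T = cfg.n_lifetimes, cfg.string_length
    bits = rng.integers(0, 2, size=(B, T), dtype=np.uint8)
    agent.reset(B)

    rec_in, rec_out, rec_mb, rec_ma, rec_exp = [], [], [], [], []
    correct = 0
    total = 0
    for t in range(T):
        inputs = bits[:, t : t + 1]
        outputs = agent.step(inputs)
        if t >= cfg.warmup:
            expected = np.column_stack([bits[:, t - d] for d in cfg.delays])
            correct += int(np.sum(outputs == expected))
            total += expected.size
            if record:
                rec_in.append(inputs)
                rec_out.append(outputs)
                rec_mb.append(agent.memory_before)
                rec_ma.append(agent.memory)
                rec_exp.append(expected)

    if not record:
        return EvaluationResult(fitness=correct / total, recording=None)

    schema = NodeSchema(
        inputs=lay.input_ids,
        outputs=lay.output_ids,
        memory=lay.memory_ids,
        world=tuple(f"e{k + 1}" for k in range(len(cfg.delays))),
    )
    lifetimes = []
    for b in range(B):
        mem = np.concatenate(
            [rec_mb[0][b : b + 1], np.stack([ma[b] for ma in rec_ma])], axis=0
        )
        lifetimes.append(
            Lifetime(
                inputs=np.stack([x[b] for x in rec_in]),
                outputs=np.stack([x[b] for x in rec_out]),
                memory=mem,
                world=np.stack([x[b] for x in rec_exp]),
            )
        )
    return EvaluationResult(
        fitness=correct / total, recording=StateRecording(schema, lifetimes)
    )


# ---------------------------------------------------------------------------
# Block Catch

WORLD_FEATURE_NAMES = (
    "catch",        # block is to be caught
    "left",         # block moves left
    "s1", "s2", "s3", "s4",  # size indicators (size 1 is a never-used control)
    "left_catch", "left_avoid", "right_catch", "right_avoid",
)


def world_features(sizes: np.ndarray, directions: np.ndarray) -> np.ndarray:
    """Binary world-feature columns for block lifetimes.

    ``sizes`` and ``directions`` (one entry per lifetime, direction -1 =
    left) expand to 10 indicator columns: to-be-caught, moving-left, four
    size indicators and the four direction x decision conjunctions.  These
    are constant within a lifetime.
    """
    sizes = np.asarray(sizes)
    left = np.asarray(directions) == -1
    catch = (sizes == 2) | ((sizes == 3) & ~left)
    cols = [
        catch,
        left,
        sizes == 1,
        sizes == 2,
        sizes == 3,
        sizes == 4,
        left & catch,
        left & ~catch,
        ~left & catch,
        ~left & ~catch,
    ]
    return np.column_stack(cols).astype(np.uint8)


def run_blockcatch(
    agent: Agent, cfg: BlockCatchConfig = BlockCatchConfig(), record: bool = True
) -> EvaluationResult:
    """Evaluate an agent on Block Catch over all 120 (size, direction,
    start position) lifetimes.

    Within an update the order is: read sensors, update brain, move agent
    (outputs (1,0) -> one unit left, (0,1) -> one unit right, otherwise
    stay), then advance the block one unit down and one unit laterally with
    wraparound.  After ``n_updates`` steps the block is at paddle level and
    the catch/avoid decision is scored by body overlap.
    """
    lay = agent.layout
    if lay.n_inputs != len(cfg.sensor_offsets) or lay.n_outputs != 2:
        raise ValueError(
            f"layout mismatch: Block Catch needs {len(cfg.sensor_offsets)} "
            f"inputs and 2 outputs, agent has {lay.n_inputs}/{lay.n_outputs}"
        )
    combos = [
        (s, d, x)
        for s in cfg.sizes
        for d in cfg.directions
        for x in range(cfg.width)
    ]
    B = len(combos)
    sizes = np.array([c[0] for c in combos])
    dirs = np.array([c[1] for c in combos])
    block_x = np.array([c[2] for c in combos])
    agent_x = np.zeros(B, dtype=int)
    world = world_features(sizes, dirs)
    offsets = np.array(cfg.sensor_offsets)

    agent.reset(B)
    rec_in, rec_out, rec_mb, rec_ma = [], [], [], []
    for _ in range(cfg.n_updates):
        rel = (agent_x[:, None] + offsets[None, :] - block_x[:, None]) % cfg.width
        sensors = (rel < sizes[:, None]).astype(np.uint8)
        outputs = agent.step(sensors)
        if record:
            rec_in.append(sensors)
            rec_out.append(outputs)
            rec_mb.append(agent.memory_before)
            rec_ma.append(agent.memory)
        dx = outputs[:, 1].astype(int) - outputs[:, 0].astype(int)
        agent_x = (agent_x + dx) % cfg.width
        block_x = (block_x + dirs) % cfg.width

    body = np.arange(cfg.body_width)
    rel = (agent_x[:, None] + body[None, :] - block_x[:, None]) % cfg.width
    caught = np.any(rel < sizes[:, None], axis=1)
    should_catch = world[:, 0].astype(bool)
    correct = caught == should_catch
    details = {
        "caught": caught,
        "should_catch": should_catch,
        "correct": correct,
        "sizes": sizes,
        "directions": dirs,
    }
    if not record:
        return EvaluationResult(
            fitness=float(np.mean(correct)), recording=None, details=details
        )

    schema = NodeSchema(
        inputs=lay.input_ids,
        outputs=lay.output_ids,
        memory=lay.memory_ids,
        world=WORLD_FEATURE_NAMES,
    )
    lifetimes = []
    for b in range(B):
        mem = np.concatenate(
            [rec_mb[0][b : b + 1], np.stack([ma[b] for ma in rec_ma])], axis=0
        )
        lifetimes.append(
            Lifetime(
                inputs=np.stack([x[b] for x in rec_in]),
                outputs=np.stack([x[b] for x in rec_out]),
                memory=mem,
                world=np.broadcast_to(world[b], (cfg.n_updates, world.shape[1])).copy(),
            )
        )
    return EvaluationResult(
        fitness=float(np.mean(correct)),
        recording=StateRecording(schema, lifetimes),
        details=details,
    )
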