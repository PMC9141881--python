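from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from infofrag.state_records import Lifetime, NodeSchema, PairedTable, StateRecording

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def xor_table() -> PairedTable:
    """The four equiprobable joint states of two independent uniform bits
    and their XOR."""
    data = np.array([[0, 0, 0], [0, 1, 1], [1, 0, 1], [1, 1, 0]])
    return PairedTable(("A", "B"), ("C",), data)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20220521)


def make_random_recording(
    rng: np.random.Generator,
    n_lifetimes: int = 4,
    n_updates: int = 20,
    n_in: int = 2,
    n_out: int = 2,
    n_mem: int = 3,
    n_world: int = 1,
) -> StateRecording:
    """Unstructured random binary recording for plumbing tests."""
    schema = NodeSchema(
        inputs=tuple(f"i{k+1}" for k in range(n_in)),
        outputs=tuple(f"o{k+1}" for k in range(n_out)),
        memory=tuple(f"m{k+1}" for k in range(n_mem)),
        world=tuple(f"w{k+1}" for k in range(n_world)),
    )
    lifetimes = [
        Lifetime(
            inputs=rng.integers(0, 2, (n_updates, n_in)),
            outputs=rng.integers(0, 2, (n_updates, n_out)),
            memory=rng.integers(0, 2, (n_updates + 1, n_mem)),
            world=rng.integers(0, 2, (n_updates, n_world)),
        )
        for _ in range(n_lifetimes)
    ]
    return StateRecording(schema, lifetimes)
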