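"""Desk-scale complexity-vs-robustness study on the Block Catch task.

Evolves a set of independent replicate populations for a reduced number of
generations, takes each replicate's best final brain, and measures (i) its
information-flow complexity (edge count of the full-lifetime flow graph at
theta = 1) and (ii) its mutational robustness R over 100 mutants.  The
expected qualitative outcome is a negative rank correlation between flow
complexity and robustness: brains with more complex information flow lose
more fitness under mutation.

Replicate generation counts here are deliberately small — the trend is a
sign property of the correlation, not a numeric reproduction of a full-scale
campaign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .evolution import EvolutionConfig, evolve, mutational_robustness
from .flow import build_flow_graph, flow_complexity
from .substrates import BLOCKCATCH_LAYOUT, Genome, decode_markov_brain, decode_rnn
from .tasks import BlockCatchConfig, BrainAgent, run_blockcatch

__all__ = ["StudyResult", "complexity_robustness_study"]


@dataclass
class StudyResult:
    table: pd.DataFrame  # one row per replicate: fitness, complexity, robustness
    spearman_rho: float
    spearman_p: float


def _evaluator(substrate: str, cfg: BlockCatchConfig):
    layout = BLOCKCATCH_LAYOUT
    decode = decode_markov_brain if substrate == "markov" else decode_rnn

    def evaluate(g: Genome) -> float:
        return run_blockcatch(BrainAgent(decode(g, layout)), cfg, record=False).fitness

    return decode, evaluate


def complexity_robustness_study(
    seed: int,
    n_replicates: int = 20,
    generations: int = 25,
    population: int = 100,
    n_mutants: int = 100,
    substrate: str = "markov",
) -> StudyResult:
    """Run the reduced-scale study and correlate complexity with robustness.

    Each replicate gets an independent child stream of ``seed``.  Returns the
    per-replicate table plus the Spearman rank correlation between flow
    complexity and mutational robustness across replicates.
    """
    task_cfg = BlockCatchConfig()
    decode, evaluate = _evaluator(substrate, task_cfg)
    evo_cfg = EvolutionConfig(population=population, generations=generations)
    rows = []
    streams = np.random.SeedSequence(seed).spawn(n_replicates)
    for rep, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        _, lineage = evolve(evaluate, evo_cfg, rng, markov=substrate == "markov")
        best_i, best_fit = lineage.best_final()
        genome = lineage.genomes[-1][best_i]
        brain = decode(genome, BLOCKCATCH_LAYOUT)
        rec = run_blockcatch(BrainAgent(brain), task_cfg).recording
        graph = build_flow_graph(rec, theta=1.0)
        rob = mutational_robustness(genome, evaluate, evo_cfg, rng, n_mutants)
        rows.append(
            {
                "replicate": rep,
                "fitness": best_fit,
                "complexity": flow_complexity(graph),
                "robustness": rob.robustness,
            }
        )
    table = pd.DataFrame(rows)
    rho, p = stats.spearmanr(table["complexity"], table["robustness"])
    return StudyResult(table=table, spearman_rho=float(rho), spearman_p=float(p))
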