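"""Genetic algorithm that evolves Markov Brains to solve the two tasks.

The genome is a structured list of gate genes (two input ids, one output
id, four truth-table bits).  Mutation applies per-site point mutations
plus whole-gene duplication/insertion and deletion.  Parent selection is
lexicase by default — each parent is chosen by filtering the population
through the task's trials in a random order, keeping only individuals
that answer each trial correctly — which suits these tasks' plateaued,
test-case-structured fitness landscapes far better than aggregate-score
tournaments (also available via ``selection="tournament"``).  A single
elite (the best aggregate fitness) is carried over unchanged.  Replicate
populations are fully deterministic given (config, master seed):
replicate ``i`` uses the seed ``master_seed * 10007 + i``.

Fitness inside the GA is computed by a bit-parallel evaluator that packs
all trials of a task into the bits of one Python integer per neuron; unit
tests pin it to the scalar task evaluators exactly.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Sequence

from . import tasks
from .markov_brain import Brain, Gene, genome_to_brain

__all__ = [
    "EvolutionConfig",
    "ReplicateResult",
    "TaskPack",
    "build_pack",
    "packed_correct_mask",
    "packed_fitness",
    "random_genome",
    "mutate",
    "evolve",
    "best_brains",
    "brain_for_task",
]

MD_OUTPUTS = (14, 15)
SL_OUTPUTS = (11, 12, 13, 14, 15)
SENSORS = (0, 1)


@dataclass(frozen=True)
class EvolutionConfig:
    """GA parameters.  Rates are probabilities per site / per genome."""

    population_size: int = 100
    generations: int = 2000
    replicates: int = 20
    point_mutation_rate: float = 0.01   # per connection id and per truth-table bit
    insertion_rate: float = 0.05        # per genome: duplicate a random gene
    deletion_rate: float = 0.02         # per genome: delete a random gene
    init_gene_range: tuple[int, int] = (8, 12)
    selection: str = "lexicase"         # or "tournament"
    tournament_size: int = 2
    elitism: int = 1
    n_neurons: int = 16
    early_stop: bool = True             # stop a replicate once fitness 1.0 is reached

    def validate(self) -> None:
        if self.selection not in ("lexicase", "tournament"):
            raise ValueError(f"unknown selection scheme {self.selection!r}")
        for name in ("point_mutation_rate", "insertion_rate", "deletion_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name}={rate} outside [0, 1]")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.tournament_size < 1 or self.elitism < 0:
            raise ValueError("invalid selection parameters")
        lo, hi = self.init_gene_range
        if lo < 0 or hi < lo:
            raise ValueError("invalid init_gene_range")


# ---------------------------------------------------------------------------
# Bit-parallel task evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaskPack:
    """A task compiled for bit-parallel evaluation (one bit per trial)."""

    name: str
    n_trials: int
    n_neurons: int
    step_clamps: tuple[dict[int, int], ...]  # per update: neuron -> trial bitmask
    kind: str                                # "md" or "sl"
    outputs: tuple[int, ...]
    label_masks: tuple[int, ...]             # md: masks for codes 0,1,2; sl: per label
    labels: tuple[int, ...]                  # per-trial label


def build_pack(task: str, n_neurons: int = 16) -> TaskPack:
    """Compile "md" or "sl" (with their default sensors/outputs) to a TaskPack."""
    if task == "md":
        trials, outputs, kind = tasks.md_trials(SENSORS), MD_OUTPUTS, "md"
    elif task == "sl":
        trials, outputs, kind = tasks.sl_trials(sensors=SENSORS), SL_OUTPUTS, "sl"
    else:
        raise ValueError(f"unknown task {task!r}; expected 'md' or 'sl'")
    n_steps = len(trials[0].clamps)
    step_clamps = []
    for k in range(n_steps):
        masks: dict[int, int] = {}
        for t_idx, trial in enumerate(trials):
            for nid, val in trial.clamps[k].items():
                masks.setdefault(nid, 0)
                if val:
                    masks[nid] |= 1 << t_idx
        step_clamps.append(masks)
    labels = tuple(t.label for t in trials)
    if kind == "md":
        label_masks = tuple(
            sum(1 << i for i, lab in enumerate(labels) if lab == code)
            for code in (0, 1, 2)
        )
    else:
        label_masks = tuple(1 << i for i in range(len(trials)))
    return TaskPack(
        name=task,
        n_trials=len(trials),
        n_neurons=n_neurons,
        step_clamps=tuple(step_clamps),
        kind=kind,
        outputs=outputs,
        label_masks=label_masks,
        labels=labels,
    )


def packed_correct_mask(genome: Sequence[Gene], pack: TaskPack) -> int:
    """Bitmask of correctly answered trials (bit t set = trial t correct)."""
    full = (1 << pack.n_trials) - 1
    state = [0] * pack.n_neurons
    for clamp in pack.step_clamps:
        for nid, mask in clamp.items():
            state[nid] = mask
        nxt = [0] * pack.n_neurons
        for a, b, o, t0, t1, t2, t3 in genome:
            sa = state[a]
            sb = state[b]
            r = 0
            if t0:
                r |= ~sa & ~sb
            if t1:
                r |= ~sa & sb
            if t2:
                r |= sa & ~sb
            if t3:
                r |= sa & sb
            nxt[o] |= r & full
        for nid, mask in clamp.items():
            nxt[nid] |= mask
        state = nxt
    if pack.kind == "md":
        s14 = state[pack.outputs[0]]
        s15 = state[pack.outputs[1]]
        code0 = ~(s14 | s15) & full
        code1 = s14 ^ s15
        code2 = s14 & s15
        correct = (
            (code0 & pack.label_masks[0])
            | (code1 & pack.label_masks[1])
            | (code2 & pack.label_masks[2])
        )
    else:
        correct = 0
        for t_idx, label in enumerate(pack.labels):
            ok = state[pack.outputs[label]]
            for j, o in enumerate(pack.outputs):
                if j != label:
                    ok &= ~state[o]
            correct |= ok & (1 << t_idx)
    return correct


def packed_fitness(genome: Sequence[Gene], pack: TaskPack) -> float:
    """Task fitness of a genome, all trials evaluated in parallel bitwise."""
    return packed_correct_mask(genome, pack).bit_count() / pack.n_trials


# ---------------------------------------------------------------------------
# Variation operators
# ---------------------------------------------------------------------------

def _random_gene(rng: random.Random, n_neurons: int) -> Gene:
    return (
        rng.randrange(n_neurons),
        rng.randrange(n_neurons),
        rng.randrange(n_neurons),
        rng.randrange(2),
        rng.randrange(2),
        rng.randrange(2),
        rng.randrange(2),
    )


def random_genome(rng: random.Random, config: EvolutionConfig) -> tuple[Gene, ...]:
    lo, hi = config.init_gene_range
    return tuple(_random_gene(rng, config.n_neurons) for _ in range(rng.randint(lo, hi)))


def mutate(
    genome: Sequence[Gene], config: EvolutionConfig, rng: random.Random
) -> tuple[Gene, ...]:
    """Point mutations on every site, then at most one deletion and one insertion."""
    p = config.point_mutation_rate
    n = config.n_neurons
    out: list[Gene] = []
    for a, b, o, t0, t1, t2, t3 in genome:
        if rng.random() < p:
            a = rng.randrange(n)
        if rng.random() < p:
            b = rng.randrange(n)
        if rng.random() < p:
            o = rng.randrange(n)
        if rng.random() < p:
            t0 ^= 1
        if rng.random() < p:
            t1 ^= 1
        if rng.random() < p:
            t2 ^= 1
        if rng.random() < p:
            t3 ^= 1
        out.append((a, b, o, t0, t1, t2, t3))
    if out and rng.random() < config.deletion_rate:
        del out[rng.randrange(len(out))]
    if rng.random() < config.insertion_rate:
        gene = out[rng.randrange(len(out))] if out else _random_gene(rng, n)
        out.insert(rng.randrange(len(out) + 1), gene)
    return tuple(out)


# ---------------------------------------------------------------------------
# The GA proper
# ---------------------------------------------------------------------------

@dataclass
class ReplicateResult:
    replicate: int
    seed: int
    genome: tuple[Gene, ...]
    fitness: float
    trace: list[float]            # per-generation max fitness (padded after early stop)
    generations_run: int


def _argmax_first(values: Sequence[float]) -> int:
    best_i = 0
    best_v = values[0]
    for i, v in enumerate(values):
        if v > best_v:
            best_i, best_v = i, v
    return best_i


def _mutate_nonclone(
    genome: tuple[Gene, ...], config: EvolutionConfig, rng: random.Random
) -> tuple[Gene, ...]:
    # Clones waste offspring slots (the elite already preserves the parent);
    # retry a few times, but give up if the rates make change unlikely.
    for _ in range(10):
        child = mutate(genome, config, rng)
        if child != genome:
            return child
    return child


def _lexicase_parent(
    popmasks: list[int], trial_order: list[int], n_pop: int, rng: random.Random
) -> int:
    """Index of a lexicase-selected parent.

    ``popmasks[t]`` is the bitset (over population indices) of individuals
    answering trial t correctly.  Trials are applied in random order; a
    trial that would eliminate everyone is skipped.
    """
    rng.shuffle(trial_order)
    cand = (1 << n_pop) - 1
    for t in trial_order:
        narrowed = cand & popmasks[t]
        if narrowed:
            cand = narrowed
            if narrowed & (narrowed - 1) == 0:
                break
    k = rng.randrange(cand.bit_count())
    for _ in range(k):
        cand &= cand - 1
    return (cand & -cand).bit_length() - 1


def _run_replicate(
    pack: TaskPack,
    config: EvolutionConfig,
    rep: int,
    seed: int,
    seed_genomes: Sequence[Sequence[Gene]],
) -> ReplicateResult:
    rng = random.Random(seed)
    n_pop = config.population_size
    pop: list[tuple[Gene, ...]] = [random_genome(rng, config) for _ in range(n_pop)]
    for i, g in enumerate(seed_genomes[:n_pop]):
        pop[i] = tuple(tuple(gene) for gene in g)

    cache: dict[tuple[Gene, ...], int] = {}

    def correct(g: tuple[Gene, ...]) -> int:
        v = cache.get(g)
        if v is None:
            v = packed_correct_mask(g, pack)
            cache[g] = v
        return v

    n_trials = pack.n_trials
    trial_order = list(range(n_trials))
    trace: list[float] = []
    best_i = 0
    masks = [correct(g) for g in pop]
    fits = [m.bit_count() / n_trials for m in masks]
    for gen in range(config.generations):
        best_i = _argmax_first(fits)
        trace.append(fits[best_i])
        if config.early_stop and fits[best_i] >= 1.0:
            break
        if gen == config.generations - 1:
            break
        newpop: list[tuple[Gene, ...]] = [pop[best_i]] if config.elitism else []
        if config.selection == "lexicase":
            popmasks = [0] * n_trials
            for i, m in enumerate(masks):
                for t in range(n_trials):
                    if (m >> t) & 1:
                        popmasks[t] |= 1 << i
            while len(newpop) < n_pop:
                parent = _lexicase_parent(popmasks, trial_order, n_pop, rng)
                newpop.append(_mutate_nonclone(pop[parent], config, rng))
        else:
            while len(newpop) < n_pop:
                contenders = [rng.randrange(n_pop) for _ in range(config.tournament_size)]
                winner = min(contenders, key=lambda i: (-fits[i], i))
                newpop.append(_mutate_nonclone(pop[winner], config, rng))
        pop = newpop
        masks = [correct(g) for g in pop]
        fits = [m.bit_count() / n_trials for m in masks]
    generations_run = len(trace)
    trace += [trace[-1]] * (config.generations - len(trace))
    return ReplicateResult(
        replicate=rep,
        seed=seed,
        genome=pop[best_i],
        fitness=fits[best_i],
        trace=trace,
        generations_run=generations_run,
    )


def evolve(
    task: str | TaskPack,
    config: EvolutionConfig | None = None,
    seed: int = 0,
    seed_genomes: Sequence[Sequence[Gene]] = (),
) -> list[ReplicateResult]:
    """Run ``config.replicates`` independent GA runs; return their champions.

    ``seed_genomes`` (optional) are injected into each initial population,
    e.g. to start from a known circuit.
    """
    config = config or EvolutionConfig()
    config.validate()
    pack = task if isinstance(task, TaskPack) else build_pack(task, config.n_neurons)
    results = []
    for rep in range(config.replicates):
        rep_seed = seed * 10007 + rep
        results.append(_run_replicate(pack, config, rep, rep_seed, seed_genomes))
    return results


def brain_for_task(genome: Sequence[Gene], task: str, n_neurons: int = 16) -> Brain:
    """Decode a genome with the task's designated sensors and outputs."""
    outputs = MD_OUTPUTS if task == "md" else SL_OUTPUTS
    return genome_to_brain(genome, n_neurons=n_neurons, sensory=SENSORS, outputs=outputs)


def best_brains(
    results: Sequence[ReplicateResult], task: str, require_perfect: bool = True
) -> list[Brain]:
    """Decode replicate champions, optionally keeping only perfect-fitness ones."""
    out = []
    for r in results:
        if require_perfect and r.fitness < 1.0:
            continue
        out.append(brain_for_task(r.genome, task))
    return out
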