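"""Tree-based genetic programming for symbolic regression of a target series.

Individuals are expression trees over the candidate columns of a
:class:`~gpdrivers.preprocess.FeatureTable`, real constants and a small set
of protected arithmetic primitives.  Fitness is the root-mean-squared error
(RMSE) between the tree's output and the target over the training years.
The evolutionary loop is generational with single-individual elitism,
tournament selection, subtree crossover and subtree mutation.

Trees are stored as flat prefix (Polish notation) genomes — a list of
nodes, each ``("v", name)``, ``("c", value)`` or ``(op,)`` — which makes
subtree extraction, swapping and stack-based vectorised evaluation cheap.
All primitives are *protected*: they are total over the reals, so every
evolved tree evaluates everywhere (division returns 1 near a zero
denominator, log acts on the absolute value).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GPConfig",
    "Individual",
    "PRIMITIVES",
    "rmse",
    "evaluate",
    "random_individual",
    "select_parent",
    "subtree_crossover",
    "subtree_mutation",
    "evolve",
]

_DIV_EPS = 1e-12


def _padd(a, b):
    return a + b


def _psub(a, b):
    return a - b


def _pmul(a, b):
    return a * b


def _pdiv(a, b):
    # Protected division: 1 wherever |denominator| < 1e-12 (Koza convention).
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        out = a / b
    return np.where(np.abs(b) < _DIV_EPS, 1.0, out)


def _pexp(a):
    with np.errstate(over="ignore"):
        return np.exp(np.clip(a, -700.0, 700.0))


def _plog(a):
    # Protected log: log|a|, and 0 wherever |a| < 1e-12.
    absa = np.abs(a)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log(absa)
    return np.where(absa < _DIV_EPS, 0.0, out)


# symbol -> (arity, vectorised implementation)
PRIMITIVES: dict[str, tuple[int, callable]] = {
    "add": (2, _padd),
    "sub": (2, _psub),
    "mul": (2, _pmul),
    "div": (2, _pdiv),
    "exp": (1, _pexp),
    "log": (1, _plog),
}

DEFAULT_PRIMITIVES = ("add", "sub", "mul", "div")


@dataclass
class GPConfig:
    """Knobs of the evolutionary run.

    ``p_crossover + p_mutation + p_clonation`` must not exceed 1; any
    remainder reproduces a tournament winner unchanged (same effect as
    clonation).  Depth counts tree levels, a single leaf having depth 1.
    """

    population_size: int = 1000
    max_generations: int = 500
    p_crossover: float = 0.8
    p_mutation: float = 0.15
    p_clonation: float = 0.05
    tournament_size: int = 4
    init_depth: tuple[int, int] = (2, 6)
    max_depth: int = 17
    mutation_subtree_depth: int = 4
    primitives: tuple[str, ...] = DEFAULT_PRIMITIVES
    const_range: tuple[float, float] = (-1.0, 1.0)
    stagnation_window: int = 50
    rmse_stop: float = 1e-9

    def __post_init__(self) -> None:
        for p in (self.p_crossover, self.p_mutation, self.p_clonation):
            if not 0.0 <= p <= 1.0:
                raise ValueError("operator probabilities must lie in [0, 1]")
        if self.p_crossover + self.p_mutation + self.p_clonation > 1.0 + 1e-12:
            raise ValueError("crossover + mutation + clonation must be <= 1")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.init_depth[0] < 1 or self.init_depth[0] > self.init_depth[1]:
            raise ValueError("init_depth bounds must satisfy 1 <= lo <= hi")
        if self.max_depth < self.init_depth[1]:
            raise ValueError("max_depth must be >= upper init depth")
        unknown = set(self.primitives) - set(PRIMITIVES)
        if unknown:
            raise ValueError(f"unknown primitives: {sorted(unknown)}")


@dataclass
class Individual:
    """A GP individual: a prefix genome plus cached errors."""

    genome: list[tuple]
    fitness: float | None = None       # training RMSE
    val_error: float | None = None     # RMSE on the held-out fold

    @property
    def size(self) -> int:
        return len(self.genome)

    def depth(self) -> int:
        return genome_depth(self.genome)

    def variables(self) -> set[str]:
        return {node[1] for node in self.genome if node[0] == "v"}

    def copy(self) -> "Individual":
        return Individual(list(self.genome), self.fitness, self.val_error)

    def to_sexpr(self) -> str:
        return genome_to_sexpr(self.genome)

    @classmethod
    def from_sexpr(cls, text: str) -> "Individual":
        return cls(sexpr_to_genome(text))


# ---------------------------------------------------------------------------
# genome utilities

def _node_arity(node: tuple) -> int:
    kind = node[0]
    if kind in ("v", "c"):
        return 0
    return PRIMITIVES[kind][0]


def genome_depth(genome: list[tuple]) -> int:
    """Depth of the prefix-encoded tree; a single leaf has depth 1."""
    depth = 0
    stack = [1]  # children still expected at each open level
    for node in genome:
        depth = max(depth, len(stack))
        stack[-1] -= 1
        ar = _node_arity(node)
        if ar > 0:
            stack.append(ar)
        else:
            while stack and stack[-1] == 0:
                stack.pop()
    return depth


def subtree_slice(genome: list[tuple], start: int) -> slice:
    """Extent of the subtree rooted at position ``start``."""
    need = 1
    i = start
    while need > 0:
        need += _node_arity(genome[i]) - 1
        i += 1
    return slice(start, i)


def node_depths(genome: list[tuple]) -> list[int]:
    """Depth (1-based from the root) of every node in the genome."""
    out = []
    stack = [1]
    for node in genome:
        out.append(len(stack))
        stack[-1] -= 1
        ar = _node_arity(node)
        if ar > 0:
            stack.append(ar)
        else:
            while stack and stack[-1] == 0:
                stack.pop()
    return out


def genome_to_sexpr(genome: list[tuple]) -> str:
    def emit(i: int) -> tuple[str, int]:
        node = genome[i]
        kind = node[0]
        if kind == "v":
            return node[1], i + 1
        if kind == "c":
            return repr(float(node[1])), i + 1
        ar = PRIMITIVES[kind][0]
        parts, j = [kind], i + 1
        for _ in range(ar):
            s, j = emit(j)
            parts.append(s)
        return "(" + " ".join(parts) + ")", j

    text, end = emit(0)
    if end != len(genome):
        raise ValueError("trailing nodes after root subtree")
    return text


def sexpr_to_genome(text: str) -> list[tuple]:
    tokens = text.replace("(", " ( ").replace(")", " ) ").split()

    def parse(pos: int) -> tuple[list[tuple], int]:
        tok = tokens[pos]
        if tok == "(":
            op = tokens[pos + 1]
            if op not in PRIMITIVES:
                raise ValueError(f"unknown primitive {op!r}")
            ar = PRIMITIVES[op][0]
            genome, j = [(op,)], pos + 2
            for _ in range(ar):
                sub, j = parse(j)
                genome.extend(sub)
            if tokens[j] != ")":
                raise ValueError("malformed s-expression")
            return genome, j + 1
        try:
            return [("c", float(tok))], pos + 1
        except ValueError:
            return [("v", tok)], pos + 1

    genome, end = parse(0)
    if end != len(tokens):
        raise ValueError("trailing tokens in s-expression")
    return genome


# ---------------------------------------------------------------------------
# evaluation and fitness

def eval_genome(genome: list[tuple], columns: dict[str, np.ndarray]) -> np.ndarray:
    """Vectorised stack evaluation of a prefix genome over aligned arrays."""
    n = len(next(iter(columns.values()))) if columns else 1
    stack: list[np.ndarray] = []
    for node in reversed(genome):
        kind = node[0]
        if kind == "v":
            try:
                stack.append(columns[node[1]])
            except KeyError:
                raise KeyError(f"unknown variable reference {node[1]!r}") from None
        elif kind == "c":
            stack.append(np.full(n, node[1]))
        else:
            ar, fn = PRIMITIVES[kind]
            if ar == 1:
                stack.append(fn(stack.pop()))
            else:
                a = stack.pop()
                b = stack.pop()
                stack.append(fn(a, b))
    if len(stack) != 1:
        raise ValueError("malformed genome")
    return np.asarray(stack[0], dtype=float)


def evaluate(individual: Individual, table, years=None) -> np.ndarray:
    """Evaluate an individual over a FeatureTable at the given years.

    A year where any referenced variable is missing yields NaN.  ``years``
    defaults to the full year index of the table.
    """
    if years is None:
        sel = np.ones(len(table.data), dtype=bool)
    else:
        sel = table.data.index.isin(list(years))
    n = int(sel.sum())
    cols = {
        name: table.data[name].to_numpy(dtype=float)[sel]
        for name in individual.variables()
    }
    if not cols:  # constant tree: broadcast a scalar evaluation
        value = float(eval_genome(individual.genome, {"_": np.empty(1)})[0])
        return np.full(n, value)
    return eval_genome(individual.genome, cols)


def rmse(predicted: np.ndarray, observed: np.ndarray) -> float:
    """RMSE over indices where both prediction and observation are finite."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed must have equal length")
    mask = np.isfinite(predicted) & np.isfinite(observed)
    if not mask.any():
        raise ValueError("no usable (non-missing) index for RMSE")
    diff = predicted[mask] - observed[mask]
    return float(np.sqrt(np.mean(diff * diff)))


# ---------------------------------------------------------------------------
# random construction

def _random_terminal(variables: list[str], config: GPConfig, rng) -> tuple:
    # Uniform over variables plus one ephemeral-random-constant slot.
    k = rng.integers(0, len(variables) + 1)
    if k == len(variables):
        lo, hi = config.const_range
        return ("c", float(rng.uniform(lo, hi)))
    return ("v", variables[k])


def _grow(variables, config, rng, depth, full) -> list[tuple]:
    """Recursive grow/full construction down to the given residual depth."""
    if depth <= 1:
        return [_random_terminal(variables, config, rng)]
    if not full and rng.random() < 0.3:
        return [_random_terminal(variables, config, rng)]
    op = config.primitives[rng.integers(0, len(config.primitives))]
    genome = [(op,)]
    for _ in range(PRIMITIVES[op][0]):
        genome.extend(_grow(variables, config, rng, depth - 1, full))
    return genome


def random_individual(
    variables: list[str], config: GPConfig, rng, depth: int | None = None,
    full: bool | None = None,
) -> Individual:
    """Ramped half-and-half random tree between the init depth bounds."""
    if not variables and not config.primitives:
        raise ValueError("need at least one variable or primitive")
    if not variables:
        raise ValueError("empty variable set")
    lo, hi = config.init_depth
    if depth is None:
        depth = int(rng.integers(lo, hi + 1))
    if full is None:
        full = bool(rng.random() < 0.5)
    return Individual(_grow(variables, config, rng, depth, full))


# ---------------------------------------------------------------------------
# variation operators

def _fitness_key(ind: Individual) -> tuple[float, int]:
    f = ind.fitness
    if f is None or not np.isfinite(f):
        f = np.inf
    return (f, ind.size)


def select_parent(population: list[Individual], tournament_size: int, rng) -> Individual:
    """Tournament selection: lowest training RMSE wins, ties to smaller trees."""
    if not population:
        raise ValueError("empty population")
    k = min(tournament_size, len(population))
    idx = rng.choice(len(population), size=k, replace=False)
    best_key = None
    best: list[Individual] = []
    for i in idx:
        key = _fitness_key(population[i])
        if best_key is None or key < best_key:
            best_key, best = key, [population[i]]
        elif key == best_key:
            best.append(population[i])
    return best[0] if len(best) == 1 else best[rng.integers(0, len(best))]


def subtree_crossover(
    a: Individual, b: Individual, rng, max_depth: int = 17
) -> tuple[Individual, Individual]:
    """Swap uniformly chosen subtrees; offspring over the depth cap revert
    to their parent.  Parents are left unmodified."""
    ga, gb = a.genome, b.genome
    ia = int(rng.integers(0, len(ga)))
    ib = int(rng.integers(0, len(gb)))
    sa, sb = subtree_slice(ga, ia), subtree_slice(gb, ib)
    child_a = ga[: sa.start] + gb[sb] + ga[sa.stop :]
    child_b = gb[: sb.start] + ga[sa] + gb[sb.stop :]
    out_a = Individual(child_a) if genome_depth(child_a) <= max_depth else a.copy()
    out_b = Individual(child_b) if genome_depth(child_b) <= max_depth else b.copy()
    return out_a, out_b


def subtree_mutation(
    a: Individual, variables: list[str], config: GPConfig, rng
) -> Individual:
    """Replace a uniformly chosen node's subtree with a fresh random subtree,
    respecting the hard depth cap."""
    g = a.genome
    i = int(rng.integers(0, len(g)))
    s = subtree_slice(g, i)
    pos_depth = node_depths(g)[i]
    allowed = max(1, config.max_depth - pos_depth + 1)
    new_depth = int(rng.integers(1, min(config.mutation_subtree_depth, allowed) + 1))
    fresh = _grow(variables, config, rng, new_depth, full=False)
    return Individual(g[: s.start] + fresh + g[s.stop :])


# ---------------------------------------------------------------------------
# evolutionary loop

def _score(ind: Individual, columns: dict[str, np.ndarray], target: np.ndarray) -> float:
    pred = eval_genome(ind.genome, columns)
    try:
        return rmse(pred, target)
    except ValueError:
        return float("inf")


def evolve(
    table,
    train_years,
    config: GPConfig,
    rng,
) -> tuple[Individual, list[float], list[Individual]]:
    """Run one GP evolution against the table's target over the training years.

    Returns the best individual (by training RMSE), the best-so-far fitness
    history per generation, and the final population.  The loop is elitist
    (the single best survives unchanged), so the history is non-increasing.
    Stops at ``max_generations``, when the best training RMSE drops below
    ``rmse_stop``, or when it has not improved for ``stagnation_window``
    generations.
    """
    sel = table.data.index.isin(list(train_years))
    target = table.target.to_numpy(dtype=float)[sel]
    if np.isfinite(target).sum() < 2:
        raise ValueError("need at least 2 usable training years")
    variables = list(table.data.columns)
    columns = {v: table.data[v].to_numpy(dtype=float)[sel] for v in variables}

    lo, hi = config.init_depth
    population: list[Individual] = []
    for i in range(config.population_size):
        depth = lo + (i % (hi - lo + 1))
        ind = random_individual(variables, config, rng, depth=depth, full=bool(i % 2))
        ind.fitness = _score(ind, columns, target)
        population.append(ind)

    best = min(population, key=_fitness_key)
    history = [best.fitness]
    stagnant = 0
    p_cx, p_mut, p_clone = config.p_crossover, config.p_mutation, config.p_clonation

    for _gen in range(1, config.max_generations):
        if best.fitness < config.rmse_stop or stagnant >= config.stagnation_window:
            break
        new_pop = [best.copy()]  # elitism of 1
        while len(new_pop) < config.population_size:
            r = rng.random()
            if r < p_cx:
                pa = select_parent(population, config.tournament_size, rng)
                pb = select_parent(population, config.tournament_size, rng)
                ca, cb = subtree_crossover(pa, pb, rng, config.max_depth)
                new_pop.append(ca)
                if len(new_pop) < config.population_size:
                    new_pop.append(cb)
            elif r < p_cx + p_mut:
                pa = select_parent(population, config.tournament_size, rng)
                new_pop.append(subtree_mutation(pa, variables, config, rng))
            else:  # clonation / plain reproduction
                pa = select_parent(population, config.tournament_size, rng)
                new_pop.append(pa.copy())
        for ind in new_pop:
            if ind.fitness is None:
                ind.fitness = _score(ind, columns, target)
        population = new_pop
        gen_best = min(population, key=_fitness_key)
        if _fitness_key(gen_best) < _fitness_key(best):
            best = gen_best
            stagnant = 0
        else:
            stagnant += 1
        history.append(best.fitness)

    return best, history, population
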