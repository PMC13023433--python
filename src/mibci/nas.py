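"""Multi-objective neural architecture search (NSGA-II).

The search space covers five architectural genes — BiLSTM hidden size,
Transformer depth, attention heads, patch size (stride fixed at p/2 for
50% overlap), and embedding dimension — 3^5 = 243 raw combinations.
Candidates are compared on three objectives: classification error on a
proxy split, a deterministic MAC-count latency surrogate, and trainable
parameter count.  Survival follows NSGA-II rank + crowding; the weighted
scalar fitness ``λ1·error + λ2·latency + λ3·params`` (min–max normalized)
is used for logging and tie-breaking only.

A genome with an embedding dimension not divisible by the head count is
repaired by resampling the head gene; with head set {2, 4, 6} and
embedding set {64, 128, 256} this removes h = 6, so the reachable space
has 162 valid points — small enough that exhaustive enumeration
(:func:`enumerate_search_space`) serves as a global oracle in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np

from ._seeds import derive_seed, rng_for
from .model import ModelConfig, count_parameters, estimate_macs
from .preprocessing import TrialSet

__all__ = [
    "Genome",
    "Objectives",
    "NASConfig",
    "GENE_SPACE",
    "sample_genome",
    "mutate",
    "crossover",
    "genome_to_config",
    "evaluate_candidate",
    "analytic_objectives",
    "scalar_fitness",
    "search_space_bounds",
    "fast_non_dominated_sort",
    "crowding_distance",
    "pareto_filter",
    "enumerate_search_space",
    "nsga2_search",
]

GENE_SPACE = {
    "lstm_hidden": (64, 128, 256),
    "tf_layers": (1, 2, 3),
    "n_heads": (2, 4, 6),
    "patch_size": (16, 20, 24),
    "embed_dim": (64, 128, 256),
}


@dataclass(frozen=True)
class Genome:
    lstm_hidden: int = 128
    tf_layers: int = 2
    n_heads: int = 4
    patch_size: int = 24
    embed_dim: int = 128

    def __post_init__(self):
        for gene, values in GENE_SPACE.items():
            if getattr(self, gene) not in values:
                raise ValueError(f"{gene}={getattr(self, gene)} outside {values}")

    @property
    def stride(self) -> int:
        return self.patch_size // 2

    @property
    def valid(self) -> bool:
        return self.embed_dim % self.n_heads == 0

    def genes(self) -> tuple:
        return tuple(getattr(self, g) for g in GENE_SPACE)


@dataclass(frozen=True)
class Objectives:
    error: float
    latency: float
    params: float

    def __post_init__(self):
        if min(self.error, self.latency, self.params) < 0:
            raise ValueError("objectives must be nonnegative")

    def as_tuple(self) -> tuple:
        return (self.error, self.latency, self.params)


@dataclass(frozen=True)
class NASConfig:
    population: int = 20
    generations: int = 10
    mutation_p: float = 0.2
    crossover_p: float = 0.8
    proxy_epochs: int = 10
    proxy_subject_fraction: float = 0.8
    weights: tuple = (0.6, 0.3, 0.1)
    seed: int = 0

    def __post_init__(self):
        for p in (self.mutation_p, self.crossover_p):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("objective weights must sum to 1")


def _repair(genome: Genome, rng) -> Genome:
    """Resample the head gene until the embedding dimension divides."""
    while genome.embed_dim % genome.n_heads != 0:
        genome = dc_replace(
            genome, n_heads=int(rng.choice(GENE_SPACE["n_heads"]))
        )
    return genome


def sample_genome(seed: int) -> Genome:
    rng = np.random.default_rng(seed)
    g = Genome(**{k: int(rng.choice(v)) for k, v in GENE_SPACE.items()})
    return _repair(g, rng)


def mutate(genome: Genome, p_mut: float, seed: int) -> Genome:
    """Per-gene resampling with probability ``p_mut``, then repair."""
    rng = np.random.default_rng(seed)
    values = {}
    for gene, space in GENE_SPACE.items():
        if rng.random() < p_mut:
            values[gene] = int(rng.choice(space))
        else:
            values[gene] = getattr(genome, gene)
    return _repair(Genome(**values), rng)


def crossover(g1: Genome, g2: Genome, p_x: float, seed: int):
    """Uniform per-gene exchange, applied with probability ``p_x``."""
    rng = np.random.default_rng(seed)
    a, b = dict(zip(GENE_SPACE, g1.genes())), dict(zip(GENE_SPACE, g2.genes()))
    if rng.random() < p_x:
        for gene in GENE_SPACE:
            if rng.random() < 0.5:
                a[gene], b[gene] = b[gene], a[gene]
    return _repair(Genome(**a), rng), _repair(Genome(**b), rng)


def genome_to_config(genome: Genome, base: ModelConfig | None = None) -> ModelConfig:
    base = base or ModelConfig()
    return dc_replace(
        base,
        lstm_hidden=genome.lstm_hidden,
        tf_layers=genome.tf_layers,
        n_heads=genome.n_heads,
        patch_size=genome.patch_size,
        stride=genome.stride,
        embed_dim=genome.embed_dim,
        ff_dim=2 * genome.embed_dim,
    )


def enumerate_search_space(base: ModelConfig | None = None):
    """All valid genomes (embedding divisible by heads) — the global oracle."""
    import itertools

    out = []
    for genes in itertools.product(*GENE_SPACE.values()):
        g = Genome(**dict(zip(GENE_SPACE, genes)))
        if g.valid:
            out.append(g)
    return out


def analytic_objectives(genome: Genome, base: ModelConfig | None = None,
                        error_fn=None) -> Objectives:
    """Closed-form objectives: MAC latency surrogate + parameter count.

    ``error_fn(genome) -> float`` supplies the error term (defaults to 0);
    tests use a constructed convex error with a known Pareto set.
    """
    cfg = genome_to_config(genome, base)
    return Objectives(
        error=float(error_fn(genome)) if error_fn else 0.0,
        latency=float(estimate_macs(cfg).total),
        params=float(count_parameters(cfg).total),
    )


def evaluate_candidate(genome: Genome, proxy: TrialSet, cfg: NASConfig,
                       base: ModelConfig | None = None,
                       train_cfg=None) -> Objectives:
    """Short proxy training: error = 1 − held-out proxy accuracy."""
    from .training import TrainConfig, evaluate, stratified_split, train_supervised
    from .model import CBTNet

    if len(proxy) == 0:
        raise ValueError("empty proxy set")
    if not genome.valid:
        raise ValueError(f"invalid genome {genome}")
    model_cfg = genome_to_config(genome, base)
    train_cfg = train_cfg or TrainConfig()
    tr_idx, te_idx = stratified_split(proxy, 0.8, derive_seed(cfg.seed, "proxy"))
    tr2, val = stratified_split(proxy.subset(tr_idx), 0.8,
                                derive_seed(cfg.seed, "proxy-val"))
    model = CBTNet(model_cfg, seed=derive_seed(cfg.seed, "cand", *genome.genes()))
    fit_cfg = dc_replace(
        train_cfg,
        max_epochs=cfg.proxy_epochs,
        early_stop_patience=min(train_cfg.early_stop_patience, cfg.proxy_epochs),
        seed=derive_seed(cfg.seed, "cand-fit", *genome.genes()),
    )
    model, _ = train_supervised(model, proxy.subset(tr_idx[tr2]),
                                proxy.subset(tr_idx[val]), fit_cfg)
    acc = evaluate(model, proxy.subset(te_idx)).accuracy
    return Objectives(
        error=1.0 - acc,
        latency=float(estimate_macs(model_cfg).total),
        params=float(count_parameters(model_cfg).total),
    )


def search_space_bounds(base: ModelConfig | None = None) -> dict:
    """(min, max) of the latency and params objectives over the space."""
    lat, par = [], []
    for g in enumerate_search_space(base):
        cfg = genome_to_config(g, base)
        lat.append(estimate_macs(cfg).total)
        par.append(count_parameters(cfg).total)
    return {"latency": (float(min(lat)), float(max(lat))),
            "params": (float(min(par)), float(max(par)))}


def scalar_fitness(obj: Objectives, weights=(0.6, 0.3, 0.1),
                   bounds: dict | None = None) -> float:
    """Weighted scalar score with min–max normalized latency and params."""
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    bounds = bounds or search_space_bounds()

    def norm(value, key):
        lo, hi = bounds[key]
        return (value - lo) / (hi - lo) if hi > lo else 0.0

    l1, l2, l3 = weights
    return float(
        l1 * obj.error
        + l2 * norm(obj.latency, "latency")
        + l3 * norm(obj.params, "params")
    )


# ---------------------------------------------------------------------------
# NSGA-II machinery
# ---------------------------------------------------------------------------

def _dominates(a: tuple, b: tuple) -> bool:
    return all(x <= y for x, y in zip(a, b)) and any(x < y for x, y in zip(a, b))


def pareto_filter(objs) -> list:
    """Brute-force O(n²) nondominated indices (test oracle and final pass)."""
    objs = [tuple(o) for o in objs]
    return [
        i for i, a in enumerate(objs)
        if not any(_dominates(b, a) for j, b in enumerate(objs) if j != i)
    ]


def fast_non_dominated_sort(objs) -> list:
    """NSGA-II fronts: list of index lists, best (rank 0) first."""
    objs = [tuple(o) for o in objs]
    n = len(objs)
    dominated_by = [[] for _ in range(n)]
    dom_count = [0] * n
    fronts = [[]]
    for i in range(n):
        for j in range(i + 1, n):
            if _dominates(objs[i], objs[j]):
                dominated_by[i].append(j)
                dom_count[j] += 1
            elif _dominates(objs[j], objs[i]):
                dominated_by[j].append(i)
                dom_count[i] += 1
    for i in range(n):
        if dom_count[i] == 0:
            fronts[0].append(i)
    k = 0
    while fronts[k]:
        nxt = []
        for i in fronts[k]:
            for j in dominated_by[i]:
                dom_count[j] -= 1
                if dom_count[j] == 0:
                    nxt.append(j)
        fronts.append(nxt)
        k += 1
    return fronts[:-1]


def crowding_distance(objs) -> np.ndarray:
    """Crowding distance of each member within one front."""
    objs = np.asarray([tuple(o) for o in objs], dtype=float)
    n, m = objs.shape
    dist = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for k in range(m):
        order = np.argsort(objs[:, k])
        lo, hi = objs[order[0], k], objs[order[-1], k]
        dist[order[0]] = dist[order[-1]] = np.inf
        if hi > lo:
            gaps = (objs[order[2:], k] - objs[order[:-2], k]) / (hi - lo)
            dist[order[1:-1]] += gaps
    return dist


def _rank_and_crowding(objs):
    fronts = fast_non_dominated_sort(objs)
    rank = np.empty(len(objs), dtype=int)
    crowd = np.empty(len(objs))
    for r, front in enumerate(fronts):
        rank[front] = r
        crowd[front] = crowding_distance([objs[i] for i in front])
    return rank, crowd, fronts


def nsga2_search(cfg: NASConfig, proxy: TrialSet | None = None,
                 evaluator=None, base: ModelConfig | None = None):
    """Generational NSGA-II over the architecture space.

    ``evaluator(genome) -> Objectives`` overrides proxy training (used
    with analytic objectives in tests and for cheap surrogate searches).
    Evaluations are cached per genome; the returned front is the
    nondominated subset of every genome ever evaluated.
    """
    if evaluator is None:
        if proxy is None:
            raise ValueError("either a proxy trial set or an evaluator is required")

        def evaluator(g):  # noqa: F811 - deliberate binding
            return evaluate_candidate(g, proxy, cfg, base)

    cache: dict[Genome, Objectives] = {}
    stats = {"evaluations": 0, "cache_hits": 0}

    def measure(g: Genome) -> Objectives:
        if g in cache:
            stats["cache_hits"] += 1
        else:
            cache[g] = evaluator(g)
            stats["evaluations"] += 1
        return cache[g]

    rng = rng_for(cfg.seed, "nsga2")
    pop = [sample_genome(derive_seed(cfg.seed, "init", i))
           for i in range(cfg.population)]
    objs = [measure(g).as_tuple() for g in pop]
    history = []

    for gen in range(cfg.generations):
        rank, crowd, _ = _rank_and_crowding(objs)

        def tournament():
            i, j = rng.integers(0, len(pop), size=2)
            if rank[i] < rank[j]:
                return pop[i]
            if rank[j] < rank[i]:
                return pop[j]
            return pop[i] if crowd[i] >= crowd[j] else pop[j]

        children = []
        while len(children) < cfg.population:
            c1, c2 = crossover(
                tournament(), tournament(), cfg.crossover_p,
                derive_seed(cfg.seed, "x", gen, len(children)),
            )
            c1 = mutate(c1, cfg.mutation_p, derive_seed(cfg.seed, "m", gen, len(children)))
            c2 = mutate(c2, cfg.mutation_p, derive_seed(cfg.seed, "m", gen, len(children) + 1))
            children.extend([c1, c2])
        children = children[: cfg.population]

        merged = pop + children
        merged_objs = objs + [measure(g).as_tuple() for g in children]
        rank2, crowd2, fronts = _rank_and_crowding(merged_objs)
        survivors = []
        for front in fronts:
            if len(survivors) + len(front) <= cfg.population:
                survivors.extend(front)
            else:
                front = sorted(front, key=lambda i: -crowd2[i])
                survivors.extend(front[: cfg.population - len(survivors)])
                break
        pop = [merged[i] for i in survivors]
        objs = [merged_objs[i] for i in survivors]
        history.append({
            "generation": gen,
            "front0_size": int((rank2 == 0).sum()),
            "evaluations": stats["evaluations"],
            "cache_hits": stats["cache_hits"],
        })

    # final nondominated set over everything evaluated
    all_genomes = list(cache.keys())
    all_objs = [cache[g].as_tuple() for g in all_genomes]
    front_idx = pareto_filter(all_objs)
    front = [(all_genomes[i], cache[all_genomes[i]]) for i in front_idx]
    return front, history
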