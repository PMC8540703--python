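"""NSGA-II search over the 96-coefficient index space, plus the two
published simplification procedures.

A chromosome is a real vector of 96 genes in [0, 10]: the first 48 are the
numerator coefficients C_ij, the last 48 the denominator coefficients K_ij,
each half laid out band-major, channel-minor (delta F3, delta F4, ...,
alpha2 O2).  Fitness is the two-objective (O1, O2) score of
:mod:`~drowsyindex.objectives`, both minimized.

The search machinery is the standard elitist NSGA-II: fast non-dominated
sorting, crowding distance, binary tournament on (rank, crowding),
simulated-binary crossover and polynomial mutation on real genes.  On top
of it sit the population post-processing steps used to distil a compact index out of
a final population:

* coefficient_frequency_analysis — per-band counts of "large" genes across
  the front, used to decide which bands to discard;
* freeze_and_research — re-run the search with the discarded bands' genes
  pinned to zero (halving the space when 4 of 8 bands are kept);
* select_final_solution — floor every gene and pick the candidate with the
  most zeros (ties by O1, then O2);
* brute_force_binary_index — exhaustive 0/1-coefficient search with a
  bounded number of addends over a caller-restricted feature subset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .band_features import BAND_NAMES, CHANNELS, FeatureTable
from .objectives import WIN_SIZE, ObjectiveValues, evaluate_solution
from .ratio_indices import IndexSpec

__all__ = [
    "N_GENES",
    "GENE_LOW",
    "GENE_HIGH",
    "SearchConfig",
    "ParetoFront",
    "decode",
    "encode",
    "nsga2_search",
    "coefficient_frequency_analysis",
    "freeze_and_research",
    "select_final_solution",
    "brute_force_binary_index",
    "is_mutually_nondominated",
]

N_GENES = 2 * len(BAND_NAMES) * len(CHANNELS)  # 96
GENE_LOW, GENE_HIGH = 0.0, 10.0

#: Objectives assigned to a chromosome whose denominator is identically
#: zero when strict evaluation is requested.
_INFEASIBLE = (np.inf, np.inf)


@dataclass
class SearchConfig:
    """NSGA-II settings.

    The full-scale profile (population 100, 107 generations) matches the
    published run; ``reduced()`` gives a small profile for quick
    experiments and tests.  Crossover/mutation are simulated-binary
    crossover (per-pair probability ``crossover_prob``, distribution index
    ``eta_crossover``) and polynomial mutation (per-gene probability
    ``mutation_prob``, index ``eta_mutation``) — conventional real-coded
    defaults, configurable.
    """

    population_size: int = 100
    generations: int = 107
    crossover_prob: float = 0.9
    eta_crossover: float = 15.0
    mutation_prob: float = 1.0 / N_GENES
    eta_mutation: float = 20.0
    seed: int = 0
    win_size: int = WIN_SIZE
    clamp: bool = True
    compat_printed_scan: bool = False
    compat_printed_moved_zero: bool = False

    def __post_init__(self) -> None:
        if self.population_size < 4 or self.population_size % 2:
            raise ValueError("population_size must be even and >= 4")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")

    @classmethod
    def reduced(cls, seed: int = 0, **kw) -> "SearchConfig":
        """Small-scale profile (population 40, 40 generations)."""
        kw.setdefault("population_size", 40)
        kw.setdefault("generations", 40)
        return cls(seed=seed, **kw)


@dataclass
class ParetoFront:
    """Final non-dominated set: gene matrix plus objective pairs."""

    genes: np.ndarray                      # (n_solutions, 96)
    objectives: list[ObjectiveValues]
    config: SearchConfig | None = None
    frozen_mask: np.ndarray | None = None

    def __len__(self) -> int:
        return self.genes.shape[0]

    def objective_array(self) -> np.ndarray:
        return np.array([o.astuple() for o in self.objectives])

    def specs(self) -> list[IndexSpec]:
        return [decode(g) for g in self.genes]

    def to_json(self) -> str:
        return json.dumps({
            "genes": self.genes.tolist(),
            "objectives": [o.astuple() for o in self.objectives],
        })


def decode(genes: np.ndarray, name: str = "") -> IndexSpec:
    """Gene vector -> IndexSpec (C from genes[:48], K from genes[48:])."""
    genes = np.asarray(genes, dtype=float)
    if genes.shape != (N_GENES,):
        raise ValueError(f"chromosome must have {N_GENES} genes")
    half = N_GENES // 2
    shape = (len(BAND_NAMES), len(CHANNELS))
    return IndexSpec(C=genes[:half].reshape(shape),
                     K=genes[half:].reshape(shape), name=name)


def encode(spec: IndexSpec) -> np.ndarray:
    """IndexSpec -> gene vector; inverse of :func:`decode`."""
    return np.concatenate([spec.C.ravel(), spec.K.ravel()])


# ---------------------------------------------------------------------------
# NSGA-II machinery


def _dominates(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return (a[0] <= b[0] and a[1] <= b[1]) and (a[0] < b[0] or a[1] < b[1])


def fast_non_dominated_sort(obj: np.ndarray) -> list[np.ndarray]:
    """Partition solutions into fronts F1, F2, ... (minimization)."""
    n = obj.shape[0]
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    n_dominating = np.zeros(n, dtype=int)
    for p in range(n):
        for q in range(p + 1, n):
            if _dominates(tuple(obj[p]), tuple(obj[q])):
                dominated_by[p].append(q)
                n_dominating[q] += 1
            elif _dominates(tuple(obj[q]), tuple(obj[p])):
                dominated_by[q].append(p)
                n_dominating[p] += 1
    fronts = []
    current = np.flatnonzero(n_dominating == 0)
    while current.size:
        fronts.append(current)
        nxt = []
        for p in current:
            for q in dominated_by[p]:
                n_dominating[q] -= 1
                if n_dominating[q] == 0:
                    nxt.append(q)
        current = np.array(sorted(nxt), dtype=int)
    return fronts


def crowding_distance(obj: np.ndarray) -> np.ndarray:
    """Crowding distance within one front (boundary points get inf)."""
    n = obj.shape[0]
    dist = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for m in range(obj.shape[1]):
        order = np.argsort(obj[:, m], kind="stable")
        span = obj[order[-1], m] - obj[order[0], m]
        dist[order[0]] = dist[order[-1]] = np.inf
        if span <= 0:
            continue
        dist[order[1:-1]] += (obj[order[2:], m] - obj[order[:-2], m]) / span
    return dist


def _sbx_crossover(p1, p2, rng, prob, eta):
    c1, c2 = p1.copy(), p2.copy()
    if rng.random() > prob:
        return c1, c2
    for i in range(len(p1)):
        if rng.random() > 0.5 or p1[i] == p2[i]:
            continue
        lo, hi = sorted((p1[i], p2[i]))
        u = rng.random()
        beta = (2 * u) ** (1 / (eta + 1)) if u <= 0.5 else \
            (1 / (2 * (1 - u))) ** (1 / (eta + 1))
        v1 = 0.5 * ((1 + beta) * lo + (1 - beta) * hi)
        v2 = 0.5 * ((1 - beta) * lo + (1 + beta) * hi)
        c1[i] = np.clip(v1, GENE_LOW, GENE_HIGH)
        c2[i] = np.clip(v2, GENE_LOW, GENE_HIGH)
    return c1, c2


def _polynomial_mutation(x, rng, prob, eta):
    y = x.copy()
    for i in range(len(x)):
        if rng.random() > prob:
            continue
        u = rng.random()
        if u < 0.5:
            delta = (2 * u) ** (1 / (eta + 1)) - 1
        else:
            delta = 1 - (2 * (1 - u)) ** (1 / (eta + 1))
        y[i] = np.clip(x[i] + delta * (GENE_HIGH - GENE_LOW),
                       GENE_LOW, GENE_HIGH)
    return y


def _evaluate_population(genes, fragments, config) -> list[ObjectiveValues]:
    out = []
    for g in genes:
        if not np.any(g[N_GENES // 2:] > 0):
            out.append(ObjectiveValues(*_INFEASIBLE))
            continue
        spec = decode(g)
        out.append(evaluate_solution(
            spec, fragments, win_size=config.win_size, clamp=config.clamp,
            compat_printed_scan=config.compat_printed_scan,
            compat_printed_moved_zero=config.compat_printed_moved_zero,
        ))
    return out


def _tournament(rng, rank, crowd):
    n = len(rank)
    a, b = rng.integers(n), rng.integers(n)
    if rank[a] < rank[b]:
        return a
    if rank[b] < rank[a]:
        return b
    return a if crowd[a] >= crowd[b] else b


def _rank_and_crowd(obj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    fronts = fast_non_dominated_sort(obj)
    rank = np.empty(obj.shape[0], dtype=int)
    crowd = np.empty(obj.shape[0])
    for r, fr in enumerate(fronts):
        rank[fr] = r
        crowd[fr] = crowding_distance(obj[fr])
    return rank, crowd


def nsga2_search(
    fragments: list[FeatureTable],
    config: SearchConfig,
    frozen_mask: np.ndarray | None = None,
    checkpoint_path: str | None = None,
) -> ParetoFront:
    """Run the elitist two-objective search; reproducible from the seed.

    ``frozen_mask`` marks genes pinned to 0 throughout (band pruning).
    With ``checkpoint_path`` set, one JSON line per generation (population
    genes + objectives) is appended for diagnostics/resume.
    """
    if not fragments:
        raise ValueError("need at least one training fragment")
    if frozen_mask is None:
        frozen_mask = np.zeros(N_GENES, dtype=bool)
    frozen_mask = np.asarray(frozen_mask, dtype=bool)
    rng = np.random.default_rng(config.seed)
    npop = config.population_size

    pop = rng.uniform(GENE_LOW, GENE_HIGH, size=(npop, N_GENES))
    pop[:, frozen_mask] = 0.0
    obj_list = _evaluate_population(pop, fragments, config)
    obj = np.array([o.astuple() for o in obj_list])
    if not np.any(np.isfinite(obj).all(axis=1)):
        raise RuntimeError(
            "entire initial population infeasible (degenerate denominators)"
        )

    ckpt = open(checkpoint_path, "a") if checkpoint_path else None
    try:
        for gen in range(config.generations):
            rank, crowd = _rank_and_crowd(obj)
            children = np.empty_like(pop)
            for k in range(0, npop, 2):
                i = _tournament(rng, rank, crowd)
                j = _tournament(rng, rank, crowd)
                c1, c2 = _sbx_crossover(pop[i], pop[j], rng,
                                        config.crossover_prob,
                                        config.eta_crossover)
                c1 = _polynomial_mutation(c1, rng, config.mutation_prob,
                                          config.eta_mutation)
                c2 = _polynomial_mutation(c2, rng, config.mutation_prob,
                                          config.eta_mutation)
                children[k], children[k + 1] = c1, c2
            children[:, frozen_mask] = 0.0
            child_obj_list = _evaluate_population(children, fragments, config)

            all_genes = np.vstack([pop, children])
            all_obj_list = obj_list + child_obj_list
            all_obj = np.array([o.astuple() for o in all_obj_list])
            fronts = fast_non_dominated_sort(all_obj)
            chosen: list[int] = []
            for fr in fronts:
                if len(chosen) + len(fr) <= npop:
                    chosen.extend(fr.tolist())
                else:
                    cd = crowding_distance(all_obj[fr])
                    order = np.argsort(-cd, kind="stable")
                    chosen.extend(fr[order[: npop - len(chosen)]].tolist())
                    break
            pop = all_genes[chosen]
            obj_list = [all_obj_list[i] for i in chosen]
            obj = all_obj[chosen]
            if ckpt is not None:
                ckpt.write(json.dumps({
                    "generation": gen,
                    "objectives": obj.tolist(),
                    "genes": pop.tolist(),
                }) + "\n")
    finally:
        if ckpt is not None:
            ckpt.close()

    first = fast_non_dominated_sort(obj)[0]
    # drop exact duplicates of (genes) to keep the front tidy
    genes = pop[first]
    objs = [obj_list[i] for i in first]
    _, uniq = np.unique(genes.round(12), axis=0, return_index=True)
    uniq = np.sort(uniq)
    return ParetoFront(genes=genes[uniq], objectives=[objs[i] for i in uniq],
                       config=config, frozen_mask=frozen_mask)


def is_mutually_nondominated(objectives: np.ndarray) -> bool:
    """O(n^2) check that no solution dominates another."""
    n = objectives.shape[0]
    for i in range(n):
        for j in range(n):
            if i != j and _dominates(tuple(objectives[i]),
                                     tuple(objectives[j])):
                return False
    return True


# ---------------------------------------------------------------------------
# Population analysis and simplification


def band_gene_indices(band: str) -> np.ndarray:
    """Gene positions (both C and K halves) belonging to one band."""
    i = BAND_NAMES.index(band)
    nch = len(CHANNELS)
    c_part = np.arange(i * nch, (i + 1) * nch)
    return np.concatenate([c_part, c_part + N_GENES // 2])


def coefficient_frequency_analysis(
    front: ParetoFront, large_threshold: float = 5.0
) -> list[tuple[str, int]]:
    """Count large genes per band across the front; descending ranking.

    A gene counts when its value is >= ``large_threshold`` (default: the
    midpoint of the gene range).  Ties keep the fixed band order.
    """
    if len(front) == 0:
        raise ValueError("empty front")
    counts = {}
    for band in BAND_NAMES:
        idx = band_gene_indices(band)
        counts[band] = int(np.sum(front.genes[:, idx] >= large_threshold))
    return sorted(counts.items(), key=lambda kv: -kv[1])


def frozen_mask_for_bands(bands_to_keep: list[str]) -> np.ndarray:
    if not bands_to_keep:
        raise ValueError("must keep at least one band")
    unknown = set(bands_to_keep) - set(BAND_NAMES)
    if unknown:
        raise ValueError(f"unknown bands: {sorted(unknown)}")
    mask = np.zeros(N_GENES, dtype=bool)
    for band in BAND_NAMES:
        if band not in bands_to_keep:
            mask[band_gene_indices(band)] = True
    return mask


def freeze_and_research(
    fragments: list[FeatureTable],
    config: SearchConfig,
    bands_to_keep: list[str],
    checkpoint_path: str | None = None,
) -> ParetoFront:
    """Pin the excluded bands' genes to zero and re-run the search.

    Keeping 4 of the 8 bands leaves 48 free genes — half the space.
    """
    mask = frozen_mask_for_bands(bands_to_keep)
    return nsga2_search(fragments, config, frozen_mask=mask,
                        checkpoint_path=checkpoint_path)


def select_final_solution(front: ParetoFront) -> IndexSpec:
    """Floor all genes and pick the sparsest candidate.

    Candidates are ranked lexicographically by (number of zero
    coefficients, descending; O1 ascending; O2 ascending).  A candidate
    whose floored denominator is all zero is discarded; if every candidate
    is discarded a selection error is raised.  The ranking is independent
    of the order solutions appear in the front.
    """
    if len(front) == 0:
        raise ValueError("empty front")
    candidates = []
    for g, o in zip(front.genes, front.objectives):
        floored = np.floor(g)
        if not np.any(floored[N_GENES // 2:] > 0):
            continue
        n_zero = int(np.sum(floored == 0))
        candidates.append((-n_zero, o.O1, o.O2, tuple(floored)))
    if not candidates:
        raise RuntimeError("flooring left no candidate with a valid denominator")
    candidates.sort()
    best = np.array(candidates[0][3])
    spec = decode(best, name="selected")
    return spec


def brute_force_binary_index(
    fragments: list[FeatureTable],
    max_addends: int = 5,
    positions: list[tuple[str, str, str]] | None = None,
    win_size: int = WIN_SIZE,
    clamp: bool = True,
) -> IndexSpec:
    """Exhaustive 0/1-coefficient search with at most ``max_addends`` terms.

    ``positions`` lists the admissible terms as ("C"|"K", band, channel);
    restricting it (e.g. to the bands surviving frequency analysis) keeps
    the enumeration tractable.  Every split with >= 1 numerator and >= 1
    denominator term and total terms <= max_addends is scored with
    (O1, O2); the lexicographic minimum wins (first-found on exact ties).
    """
    if max_addends < 2:
        raise ValueError("max_addends must be >= 2 (one term each side)")
    if positions is None:
        positions = [(side, b, ch) for side in ("C", "K")
                     for b in BAND_NAMES for ch in CHANNELS]
    c_positions = [(b, ch) for side, b, ch in positions if side == "C"]
    k_positions = [(b, ch) for side, b, ch in positions if side == "K"]
    if not c_positions or not k_positions:
        raise ValueError("positions must allow both numerator and denominator")

    best: tuple | None = None
    best_spec: IndexSpec | None = None
    for n_c in range(1, max_addends):
        for n_k in range(1, max_addends - n_c + 1):
            for c_terms in combinations(c_positions, n_c):
                for k_terms in combinations(k_positions, n_k):
                    C = np.zeros((len(BAND_NAMES), len(CHANNELS)))
                    K = np.zeros_like(C)
                    for b, ch in c_terms:
                        C[BAND_NAMES.index(b), CHANNELS.index(ch)] = 1.0
                    for b, ch in k_terms:
                        K[BAND_NAMES.index(b), CHANNELS.index(ch)] = 1.0
                    spec = IndexSpec(C=C, K=K, name="brute")
                    o = evaluate_solution(spec, fragments, win_size=win_size,
                                          clamp=clamp)
                    key = (o.O1, o.O2)
                    if best is None or key < best:
                        best = key
                        best_spec = spec
    if best_spec is None:
        raise RuntimeError("empty feasible set")
    best_spec.name = "brute-force"
    return best_spec
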