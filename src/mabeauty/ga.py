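"""Prior-constrained multi-objective genetic algorithm for feature selection.

A chromosome is a binary inclusion mask over the 135 features.  Three
mechanisms inject medical-aesthetic prior knowledge:

* prior-informed initialization — every chromosome starts with the 20
  clinically mandated (MA) genes switched on, and each remaining gene drawn
  Bernoulli(p) with p = 0.6;
* directional mutation — per-gene bit flips exempt the protected prior
  genes, which stay at 1 throughout evolution;
* a scalarized dual-criterion fitness F(x) = alpha * PC(x) + beta * (1 - S/N)
  maximizing predictive correlation while rewarding sparsity, with
  alpha = 0.999, beta = 0.001.

PC(x) is the wrapper criterion: mean held-out Pearson correlation of a
ridge regressor trained on the selected columns under k-fold cross-validation
with a fixed fold seed.  The evolutionary loop is tournament selection
(size 3), uniform crossover (probability 0.8), bit-flip mutation
(default rate 1/N per gene), and single-elitism replacement, which makes the
best-so-far fitness trace non-decreasing.  Runs are bit-reproducible given
the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .errors import ConfigError

N_GENES_DEFAULT = 135


@dataclass
class GAConfig:
    """Evolutionary run parameters (defaults follow the published settings)."""

    population_size: int = 200
    generations: int = 200
    alpha: float = 0.999
    beta: float = 0.001
    crossover_prob: float = 0.8
    tournament_size: int = 3
    init_prob: float = 0.6
    mutation_prob: float | None = None  # None -> 1/n_genes per gene
    elitism: int = 1
    rng_seed: int = 0

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ConfigError("alpha and beta must be non-negative")
        for name in ("crossover_prob", "init_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.mutation_prob is not None and not 0.0 <= self.mutation_prob <= 1.0:
            raise ConfigError(f"mutation_prob must lie in [0, 1], got {self.mutation_prob}")
        if self.population_size < 1 or self.generations < 0:
            raise ConfigError("population_size must be >= 1 and generations >= 0")
        if self.tournament_size < 1:
            raise ConfigError("tournament_size must be >= 1")

    def effective_mutation_prob(self, n_genes: int) -> float:
        return self.mutation_prob if self.mutation_prob is not None else 1.0 / n_genes


@dataclass
class Chromosome:
    """Binary feature-inclusion mask with a protected prior index set."""

    genes: np.ndarray
    prior_set: frozenset[int] = frozenset()

    def __post_init__(self):
        self.genes = np.asarray(self.genes, dtype=bool)
        self.prior_set = frozenset(int(i) for i in self.prior_set)
        self.validate()

    def validate(self) -> None:
        if self.genes.ndim != 1:
            raise ValueError("genes must be a 1-D binary vector")
        for i in self.prior_set:
            if not 0 <= i < self.genes.size:
                raise ValueError(f"prior index {i} out of range")
        if self.prior_set and not self.genes[list(self.prior_set)].all():
            raise ValueError("prior genes must all be 1")
        if not self.genes.any():
            raise ValueError("at least one gene must be selected")

    @property
    def selected_count(self) -> int:
        return int(self.genes.sum())

    def selected_indices(self) -> np.ndarray:
        return np.flatnonzero(self.genes)


@dataclass
class GAResult:
    """Outcome of one evolutionary run."""

    best_chromosome: Chromosome
    best_fitness: float
    best_pc: float
    trace: np.ndarray              # best-so-far fitness, length generations + 1
    selected_count: int
    evaluations_used: int
    invariant_violations: int = 0
    mean_fitness_trace: np.ndarray = field(default_factory=lambda: np.array([]))

    def selected_indices(self) -> np.ndarray:
        return self.best_chromosome.selected_indices()


# ---------------------------------------------------------------------------
# wrapper evaluator
# ---------------------------------------------------------------------------

class SubsetEvaluator:
    """Cross-validated ridge Pearson correlation for a feature subset.

    Per-fold Gram matrices of the standardized full design are precomputed
    once, so evaluating a subset only slices the Gram matrix and solves a
    |subset| x |subset| ridge system per fold — fast enough for the tens of
    thousands of evaluations a full GA run performs.  Results are memoized
    by gene mask.
    """

    def __init__(self, X, y, n_folds: int = 5, ridge_alpha: float = 1.0,
                 fold_seed: int = 0):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("feature table and scores are not aligned")
        if X.shape[0] < 2 * n_folds:
            raise ValueError("too few faces for the requested fold count")
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        self.X = (X - mu) / sd
        self.y = y
        self.n, self.n_features = X.shape
        self.ridge_alpha = float(ridge_alpha)
        rng = np.random.default_rng(fold_seed)
        perm = rng.permutation(self.n)
        self.folds = [np.sort(f) for f in np.array_split(perm, n_folds)]
        self._fold_cache = []
        for test_idx in self.folds:
            mask = np.ones(self.n, dtype=bool)
            mask[test_idx] = False
            Xtr, ytr = self.X[mask], self.y[mask]
            mtr = Xtr.mean(axis=0)
            Xc = Xtr - mtr
            self._fold_cache.append({
                "gram": Xc.T @ Xc,
                "xty": Xc.T @ (ytr - ytr.mean()),
                "mtr": mtr,
                "ybar": ytr.mean(),
                "Xte": self.X[test_idx],
                "yte": self.y[test_idx],
            })
        self._memo: dict[bytes, float] = {}
        self.evaluations = 0

    def __call__(self, genes: np.ndarray) -> float:
        genes = np.asarray(genes, dtype=bool)
        key = genes.tobytes()
        cached = self._memo.get(key)
        if cached is not None:
            return cached
        idx = np.flatnonzero(genes)
        if idx.size == 0:
            raise ValueError("cannot evaluate an empty feature subset")
        pcs = []
        lam = self.ridge_alpha
        eye = lam * np.eye(idx.size)
        for f in self._fold_cache:
            G = f["gram"][np.ix_(idx, idx)] + eye
            try:
                w = cho_solve(cho_factor(G, lower=True, check_finite=False),
                              f["xty"][idx], check_finite=False)
            except np.linalg.LinAlgError:
                w = np.linalg.lstsq(G, f["xty"][idx], rcond=None)[0]
            pred = (f["Xte"][:, idx] - f["mtr"][idx]) @ w + f["ybar"]
            pcs.append(_safe_pearson(pred, f["yte"]))
        pc = float(np.mean(pcs))
        self._memo[key] = pc
        self.evaluations += 1
        return pc


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    da = a - a.mean()
    db = b - b.mean()
    denom = np.sqrt((da @ da) * (db @ db))
    if denom <= 0.0:
        warnings.warn("constant predictions in a CV fold; PC counted as 0",
                      stacklevel=2)
        return 0.0
    return float((da @ db) / denom)


def pc_evaluator(chromosome: Chromosome | np.ndarray, features, scores,
                 cfg: GAConfig | None = None, n_folds: int = 5,
                 ridge_alpha: float = 1.0, fold_seed: int = 0) -> float:
    """One-shot subset performance PC(x); see :class:`SubsetEvaluator`."""
    genes = chromosome.genes if isinstance(chromosome, Chromosome) else chromosome
    ev = SubsetEvaluator(features, scores, n_folds=n_folds,
                         ridge_alpha=ridge_alpha, fold_seed=fold_seed)
    return ev(genes)


# ---------------------------------------------------------------------------
# operators
# ---------------------------------------------------------------------------

def fitness(pc: float, selected_count: int, n_genes: int, cfg: GAConfig) -> float:
    """Scalarized dual-criterion fitness alpha*PC + beta*(1 - S/N)."""
    return cfg.alpha * pc + cfg.beta * (1.0 - selected_count / n_genes)


def initialize_population(cfg: GAConfig, prior_set: Sequence[int],
                          rng: np.random.Generator,
                          n_genes: int = N_GENES_DEFAULT) -> np.ndarray:
    """Prior-informed population: prior genes forced to 1, rest Bernoulli(p)."""
    prior = np.asarray(sorted(set(int(i) for i in prior_set)), dtype=int)
    if prior.size and (prior.min() < 0 or prior.max() >= n_genes):
        raise ConfigError("prior set indices out of gene range")
    pop = rng.random((cfg.population_size, n_genes)) < cfg.init_prob
    if prior.size:
        pop[:, prior] = True
    # guard: a chromosome must select something
    empty = ~pop.any(axis=1)
    if empty.any():
        fill = rng.integers(0, n_genes, size=int(empty.sum()))
        pop[np.flatnonzero(empty), fill] = True
    return pop


def mutate(genes: np.ndarray, prior_mask: np.ndarray, p_m: float,
           rng: np.random.Generator) -> np.ndarray:
    """Directional bit-flip mutation: non-prior genes flip w.p. p_m, prior stay 1."""
    flips = (rng.random(genes.size) < p_m) & ~prior_mask
    out = genes ^ flips
    out[prior_mask] = True
    if not out.any():
        out[int(rng.integers(0, genes.size))] = True
    return out


def crossover(a: np.ndarray, b: np.ndarray, prior_mask: np.ndarray,
              cfg: GAConfig, rng: np.random.Generator
              ) -> tuple[np.ndarray, np.ndarray]:
    """Uniform crossover of non-prior genes with probability crossover_prob."""
    if a.size != b.size:
        raise ValueError("parents must have equal gene length")
    if rng.random() >= cfg.crossover_prob:
        return a.copy(), b.copy()
    swap = (rng.random(a.size) < 0.5) & ~prior_mask
    c1, c2 = a.copy(), b.copy()
    c1[swap], c2[swap] = b[swap], a[swap]
    c1[prior_mask] = True
    c2[prior_mask] = True
    return c1, c2


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------

def run_ga(features, scores, cfg: GAConfig,
           prior_set: Sequence[int] = (),
           evaluator: Callable[[np.ndarray], float] | None = None,
           n_genes: int | None = None) -> GAResult:
    """Evolve a feature subset; tournament -> crossover -> mutation -> elitism.

    `evaluator` maps a boolean gene mask to PC(x) in [-1, 1]; by default a
    :class:`SubsetEvaluator` is built from `features`/`scores`.  Passing an
    empty `prior_set` degrades gracefully to an unconstrained GA.
    """
    if evaluator is None:
        evaluator = SubsetEvaluator(features, scores, fold_seed=cfg.rng_seed)
    if n_genes is None:
        n_genes = (np.asarray(features).shape[1] if features is not None
                   else N_GENES_DEFAULT)
    prior = np.asarray(sorted(set(int(i) for i in prior_set)), dtype=int)
    prior_mask = np.zeros(n_genes, dtype=bool)
    prior_mask[prior] = True
    p_m = cfg.effective_mutation_prob(n_genes)
    rng = np.random.default_rng(cfg.rng_seed)

    pop = initialize_population(cfg, prior, rng, n_genes)
    violations = 0

    def score_pop(pop: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pcs = np.array([evaluator(ind) for ind in pop])
        fits = cfg.alpha * pcs + cfg.beta * (1.0 - pop.sum(axis=1) / n_genes)
        if not np.all(np.isfinite(fits)):
            bad = int(np.flatnonzero(~np.isfinite(fits))[0])
            raise RuntimeError(
                "non-finite fitness for chromosome "
                f"{np.flatnonzero(pop[bad]).tolist()}"
            )
        return pcs, fits

    pcs, fits = score_pop(pop)
    best_i = int(np.argmax(fits))
    best_genes, best_fit, best_pc = pop[best_i].copy(), float(fits[best_i]), float(pcs[best_i])
    trace = [best_fit]
    mean_trace = [float(fits.mean())]

    for _ in range(cfg.generations):
        order = np.argsort(fits)[::-1]
        elites = [pop[i].copy() for i in order[:cfg.elitism]]
        children: list[np.ndarray] = list(elites)
        while len(children) < cfg.population_size:
            pi = _tournament(fits, cfg.tournament_size, rng)
            pj = _tournament(fits, cfg.tournament_size, rng)
            c1, c2 = crossover(pop[pi], pop[pj], prior_mask, cfg, rng)
            children.append(mutate(c1, prior_mask, p_m, rng))
            if len(children) < cfg.population_size:
                children.append(mutate(c2, prior_mask, p_m, rng))
        pop = np.array(children[:cfg.population_size])
        if prior.size and not pop[:, prior].all():
            violations += 1  # defensive; operators re-impose prior genes
            pop[:, prior] = True
        pcs, fits = score_pop(pop)
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_genes, best_fit = pop[gen_best].copy(), float(fits[gen_best])
            best_pc = float(pcs[gen_best])
        trace.append(best_fit)
        mean_trace.append(float(fits.mean()))

    chromo = Chromosome(best_genes, frozenset(int(i) for i in prior))
    evaluations = getattr(evaluator, "evaluations", None)
    if evaluations is None:
        evaluations = (cfg.generations + 1) * cfg.population_size
    return GAResult(
        best_chromosome=chromo,
        best_fitness=best_fit,
        best_pc=best_pc,
        trace=np.asarray(trace),
        selected_count=chromo.selected_count,
        evaluations_used=int(evaluations),
        invariant_violations=violations,
        mean_fitness_trace=np.asarray(mean_trace),
    )


def _tournament(fits: np.ndarray, k: int, rng: np.random.Generator) -> int:
    contenders = rng.integers(0, fits.size, size=k)
    return int(contenders[np.argmax(fits[contenders])])


def exhaustive_best(evaluator: Callable[[np.ndarray], float], n_genes: int,
                    cfg: GAConfig) -> tuple[np.ndarray, float]:
    """Brute-force the fitness landscape over all 2^n - 1 non-empty subsets.

    Tractable only for toy gene counts; used as an oracle for the GA.
    """
    if n_genes > 20:
        raise ValueError("exhaustive search is only meant for toy problems")
    best_genes, best_fit = None, -np.inf
    for code in range(1, 2 ** n_genes):
        genes = np.array([(code >> i) & 1 for i in range(n_genes)], dtype=bool)
        f = fitness(evaluator(genes), int(genes.sum()), n_genes, cfg)
        if f > best_fit:
            best_genes, best_fit = genes, f
    return best_genes, float(best_fit)
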