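"""Spread selection by quantum and classical genetic search.

The quantum genetic algorithm (QGA) encodes one candidate spread as a
chromosome of m qubits, each a probability-amplitude pair (alpha, beta) with
alpha^2 + beta^2 = 1.  Every generation each chromosome is *measured* into a
definite bitstring, the bitstring is decoded to a spread on [lo, hi], the
fitness (validation mean squared error, Eq.-style F = (1/P) sum (pn_d' -
pn_o')^2 on the normalized scale) is evaluated, the elitist best-ever
solution is updated, and every qubit is steered toward the best solution's
bit by a 2x2 rotation gate.  A plain binary GA with tournament selection,
one-point crossover and bit-flip mutation serves as the classical baseline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import grnn as grnn_mod
from . import rbf as rbf_mod
from .preprocess import SplitDataset

__all__ = [
    "QubitChromosome",
    "QGAConfig",
    "GAConfig",
    "RotationPolicy",
    "OptimizationTrace",
    "init_population",
    "measure",
    "decode",
    "fitness",
    "rotate",
    "run_qga",
    "run_ga",
    "optimize_spread",
    "SpreadOptimizationResult",
]

logger = logging.getLogger(__name__)

_AMP_TOL = 1e-12  # |alpha| or |beta| below this counts as a collapsed qubit


@dataclass(frozen=True)
class QubitChromosome:
    """m probability-amplitude pairs; alpha_i^2 is P(bit_i = 0)."""

    alpha: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        if self.alpha.shape != self.beta.shape:
            raise ValueError("alpha and beta must have equal length")
        norms = self.alpha**2 + self.beta**2
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("amplitude pairs must satisfy alpha^2 + beta^2 = 1")

    @property
    def m(self) -> int:
        return self.alpha.size


@dataclass(frozen=True)
class RotationPolicy:
    """Rotation-gate magnitude keyed on (own bit, best bit, own-better flag).

    The default steers by a fixed 0.05*pi whenever the measured bit differs
    from the elitist best's bit, regardless of which individual is fitter;
    the full eight-entry table is overridable.
    """

    table: dict[tuple[int, int, bool], float] = field(default_factory=dict)
    delta: float = 0.05 * math.pi

    def angle(self, x_bit: int, b_bit: int, own_better: bool) -> float:
        key = (int(x_bit), int(b_bit), bool(own_better))
        if key in self.table:
            return self.table[key]
        return 0.0 if x_bit == b_bit else self.delta


@dataclass(frozen=True)
class QGAConfig:
    """Quantum GA settings; bounds default to the spread search range [0.1, 10]."""

    n: int = 20
    m: int = 20
    lo: float = 0.1
    hi: float = 10.0
    max_generations: int = 50
    stall_generations: int = 10
    policy: RotationPolicy = field(default_factory=RotationPolicy)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("population size must be >= 2")
        if self.m < 4:
            raise ValueError("bit length must be >= 4")
        if not self.lo < self.hi:
            raise ValueError("lo must be < hi")


@dataclass(frozen=True)
class GAConfig:
    """Classical binary GA settings on the same encoding."""

    n: int = 20
    m: int = 20
    lo: float = 0.1
    hi: float = 10.0
    max_generations: int = 50
    stall_generations: int = 10
    crossover_rate: float = 0.8
    mutation_rate: float | None = None  # None -> 1/m
    tournament_size: int = 2
    elite: int = 1
    seed: int = 0


@dataclass
class OptimizationTrace:
    """Per-generation elitist record (non-increasing best fitness)."""

    best_fitness: list[float] = field(default_factory=list)
    best_value: list[float] = field(default_factory=list)
    evaluations: int = 0
    final_population: list[QubitChromosome] | None = None

    def append(self, f: float, v: float) -> None:
        self.best_fitness.append(f)
        self.best_value.append(v)

    @property
    def generations(self) -> int:
        return len(self.best_fitness)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "generation": np.arange(1, self.generations + 1),
                "best_fitness": self.best_fitness,
                "best_spread": self.best_value,
            }
        )


def init_population(n: int, m: int) -> list[QubitChromosome]:
    """Fresh chromosomes with every gene at (1/sqrt2, 1/sqrt2): all 2^m
    basis states equally probable."""
    if n < 1 or m < 1:
        raise ValueError("n and m must be >= 1")
    a = np.full(m, 1.0 / math.sqrt(2.0))
    return [QubitChromosome(a.copy(), a.copy()) for _ in range(n)]


def measure(chromosome: QubitChromosome, rng: np.random.Generator) -> np.ndarray:
    """Collapse each qubit: draw r in [0, 1); bit = 1 iff r > alpha^2."""
    r = rng.random(chromosome.m)
    return (r > chromosome.alpha**2).astype(np.int8)


def decode(bits, lo: float, hi: float) -> float:
    """Map a bitstring (MSB first) to the uniform grid on [lo, hi]."""
    bits = np.asarray(bits, dtype=np.int64)
    m = bits.size
    if m == 0:
        raise ValueError("empty bitstring")
    value = 0
    for b in bits:
        value = (value << 1) | int(b)
    return lo + value / (2**m - 1) * (hi - lo)


def fitness(measured, predicted) -> float:
    """Mean squared difference F = (1/P) sum (measured - predicted)^2."""
    measured = np.asarray(measured, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if measured.size == 0:
        raise ValueError("empty vectors")
    if measured.shape != predicted.shape:
        raise ValueError("length mismatch")
    return float(np.mean((measured - predicted) ** 2))


def _rotation_sign(alpha: float, beta: float, target_bit: int) -> float:
    """Direction that grows the probability of ``target_bit``.

    Rotation by theta maps (alpha, beta) = (cos phi, sin phi) to angle
    phi + theta; beta^2 grows toward 1 as phi -> pi/2 and shrinks toward 0
    as phi -> 0.  A qubit already collapsed onto the target gets sign 0.
    """
    prod = alpha * beta
    if target_bit == 1:
        if abs(alpha) < _AMP_TOL:
            return 0.0  # already certain to measure 1
        if abs(beta) < _AMP_TOL:
            return 1.0  # degenerate: either direction leaves beta^2 symmetric
        return 1.0 if prod > 0 else -1.0
    if abs(beta) < _AMP_TOL:
        return 0.0  # already certain to measure 0
    if abs(alpha) < _AMP_TOL:
        return 1.0
    return -1.0 if prod > 0 else 1.0


def rotate(
    chromosome: QubitChromosome,
    its_bits,
    best_bits,
    f_curr: float,
    f_best: float,
    policy: RotationPolicy = RotationPolicy(),
) -> QubitChromosome:
    """Apply the quantum rotation gate gene by gene, steering toward the
    elitist best individual's bits.  Norm is conserved exactly (orthogonal
    update)."""
    its_bits = np.asarray(its_bits, dtype=np.int64)
    best_bits = np.asarray(best_bits, dtype=np.int64)
    if its_bits.size != chromosome.m or best_bits.size != chromosome.m:
        raise ValueError("bit length mismatch")
    own_better = f_curr < f_best
    alpha = chromosome.alpha.copy()
    beta = chromosome.beta.copy()
    for i in range(chromosome.m):
        dtheta = policy.angle(its_bits[i], best_bits[i], own_better)
        if dtheta == 0.0:
            continue
        s = _rotation_sign(alpha[i], beta[i], int(best_bits[i]))
        if s == 0.0:
            continue
        theta = s * dtheta
        c, sn = math.cos(theta), math.sin(theta)
        a, b = alpha[i], beta[i]
        alpha[i] = c * a - sn * b
        beta[i] = sn * a + c * b
    return QubitChromosome(alpha, beta)


def run_qga(objective, config: QGAConfig = QGAConfig()):
    """Minimize ``objective`` over [lo, hi] with the quantum GA.

    Returns ``(best_value, best_fitness, trace)``.  The elitist target is
    replaced only by a strictly smaller fitness; candidates whose objective
    is non-finite are discarded with a warning.
    """
    rng = np.random.default_rng(config.seed)
    population = init_population(config.n, config.m)
    best_bits: np.ndarray | None = None
    best_value = math.nan
    best_f = math.inf
    trace = OptimizationTrace()
    stall = 0
    for _gen in range(config.max_generations):
        measured = [measure(ch, rng) for ch in population]
        fitnesses: list[float] = []
        improved = False
        for bits in measured:
            value = decode(bits, config.lo, config.hi)
            f = float(objective(value))
            trace.evaluations += 1
            if not math.isfinite(f):
                logger.warning("objective returned non-finite fitness at %g; discarded", value)
                fitnesses.append(math.inf)
                continue
            fitnesses.append(f)
            if f < best_f:
                best_f, best_value, best_bits = f, value, bits.copy()
                improved = True
        if best_bits is None:
            raise RuntimeError("no finite fitness in the first generation")
        trace.append(best_f, best_value)
        stall = 0 if improved else stall + 1
        if stall >= config.stall_generations:
            break
        population = [
            rotate(ch, bits, best_bits, f, best_f, config.policy)
            for ch, bits, f in zip(population, measured, fitnesses)
        ]
    trace.final_population = population
    return best_value, best_f, trace


def run_ga(objective, config: GAConfig = GAConfig()):
    """Classical binary GA baseline on the same encoding.

    Tournament selection, one-point crossover, bit-flip mutation, one elite
    copied unchanged; same elitist bookkeeping and stopping rule as the QGA.
    """
    rng = np.random.default_rng(config.seed)
    mut = config.mutation_rate if config.mutation_rate is not None else 1.0 / config.m
    pop = rng.integers(0, 2, size=(config.n, config.m), dtype=np.int8)
    best_bits: np.ndarray | None = None
    best_value = math.nan
    best_f = math.inf
    trace = OptimizationTrace()
    stall = 0

    def evaluate(bits: np.ndarray) -> float:
        value = decode(bits, config.lo, config.hi)
        f = float(objective(value))
        trace.evaluations += 1
        if not math.isfinite(f):
            logger.warning("objective returned non-finite fitness at %g; discarded", value)
            return math.inf
        return f

    for _gen in range(config.max_generations):
        fs = np.array([evaluate(pop[i]) for i in range(config.n)])
        gen_best = int(np.argmin(fs))
        improved = fs[gen_best] < best_f
        if improved:
            best_f = float(fs[gen_best])
            best_bits = pop[gen_best].copy()
            best_value = decode(best_bits, config.lo, config.hi)
        if best_bits is None:
            raise RuntimeError("no finite fitness in the first generation")
        trace.append(best_f, best_value)
        stall = 0 if improved else stall + 1
        if stall >= config.stall_generations:
            break
        children = [best_bits.copy() for _ in range(min(config.elite, config.n))]
        while len(children) < config.n:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, config.n, size=config.tournament_size)
                parents.append(pop[contenders[np.argmin(fs[contenders])]].copy())
            p1, p2 = parents
            if rng.random() < config.crossover_rate and config.m > 1:
                cut = int(rng.integers(1, config.m))
                p1 = np.concatenate([p1[:cut], p2[cut:]])
            flip = rng.random(config.m) < mut
            p1[flip] ^= 1
            children.append(p1)
        pop = np.array(children[: config.n], dtype=np.int8)
    return best_value, best_f, trace


@dataclass(frozen=True)
class SpreadOptimizationResult:
    """Final model refit at the selected spread, plus the search record."""

    model: object  # RBFModel or GRNNModel
    spread: float
    fitness: float
    trace: OptimizationTrace | None


def _make_objective(dataset: SplitDataset, model_family: str, model_config, fitness_on: str):
    Xtr = dataset.norm.normalize_inputs(dataset.X_train)
    ytr = np.asarray(dataset.norm.normalize(dataset.y_train, "pn"))
    if fitness_on == "validation":
        Xev = dataset.norm.normalize_inputs(dataset.X_verify)
        yev = np.asarray(dataset.norm.normalize(dataset.y_verify, "pn"))
    elif fitness_on == "train":
        Xev, yev = Xtr, ytr
    else:
        raise ValueError("fitness_on must be 'validation' or 'train'")
    cache: dict[float, float] = {}

    if model_family == "rbf":
        base = model_config if model_config is not None else rbf_mod.RBFConfig()

        def objective(spread: float) -> float:
            if spread in cache:
                return cache[spread]
            cfg = replace(base, spread=float(spread))
            model = rbf_mod.train(Xtr, ytr, cfg)
            phi = rbf_mod.activations(Xev, model.centers, model.widths)
            if model.bias:
                phi = np.column_stack([phi, np.ones(phi.shape[0])])
            f = fitness(yev, phi @ model.weights)
            cache[spread] = f
            return f

        def refit(spread: float):
            cfg = replace(base, spread=float(spread))
            return rbf_mod.train(Xtr, ytr, cfg, norm=dataset.norm)

    elif model_family == "grnn":
        def objective(spread: float) -> float:
            if spread in cache:
                return cache[spread]
            model = grnn_mod.grnn_train(Xtr, ytr, spread)
            f = fitness(yev, grnn_mod.kernel_weights(model, Xev) @ model.y)
            cache[spread] = f
            return f

        def refit(spread: float):
            return grnn_mod.grnn_train(Xtr, ytr, spread, norm=dataset.norm)

    else:
        raise ValueError("model_family must be 'rbf' or 'grnn'")
    return objective, refit


def optimize_spread(
    dataset: SplitDataset,
    model_family: str = "rbf",
    optimizer: str = "qga",
    model_config=None,
    opt_config=None,
    fitness_on: str = "validation",
    default_spread: float = 1.0,
) -> SpreadOptimizationResult:
    """Select the spread for an RBF or GRNN model and refit at the optimum.

    The objective maps a candidate spread to the mean squared error of the
    model (trained on the training set at that spread) on the verification
    set, both on the normalized scale.  ``optimizer="none"`` skips the search
    and uses ``default_spread`` (or the numeric spread in ``model_config``).
    """
    objective, refit = _make_objective(dataset, model_family, model_config, fitness_on)
    if optimizer == "none":
        spread = default_spread
        if model_family == "rbf" and model_config is not None and not isinstance(
            model_config.spread, str
        ):
            spread = float(model_config.spread)
        return SpreadOptimizationResult(refit(spread), spread, objective(spread), None)
    if optimizer == "qga":
        cfg = opt_config if opt_config is not None else QGAConfig()
        best_value, best_f, trace = run_qga(objective, cfg)
    elif optimizer == "ga":
        cfg = opt_config if opt_config is not None else GAConfig()
        best_value, best_f, trace = run_ga(objective, cfg)
    else:
        raise ValueError("optimizer must be 'qga', 'ga' or 'none'")
    return SpreadOptimizationResult(refit(best_value), best_value, best_f, trace)
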