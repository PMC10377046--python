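"""Synthetic expression data with network-structured covariance and sub-graph signal.

The generator emulates a disease-classification study on a gene network:

1. a scale-free feature graph (preferential attachment, kernel degree**0.5);
2. feature covariance decaying with hop distance, ``Sigma_ij = base ** D_ij``
   (base 0.8), so neighboring genes are strongly correlated;
3. mean-zero multivariate Gaussian expression ``x_i ~ N(0, Sigma)``;
4. a connected set S of p0 "true predictors" grown from one or two high-degree
   core nodes by attenuated frontier expansion;
5. signed uniform coefficients beta on S and binary outcomes through a logistic
   or absolute link.

Everything is reproducible from (config, seed): each stage draws from an
independent substream spawned from the config seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

from .graph import (
    FeatureGraph,
    generate_ba_graph,
    k_hop_neighborhood,
    shortest_path_matrix,
)

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "GenerationError",
    "build_covariance",
    "sample_expression",
    "find_potential_cores",
    "select_true_predictors",
    "draw_coefficients",
    "generate_outcome",
    "simulate_dataset",
]

logger = logging.getLogger(__name__)


class GenerationError(RuntimeError):
    """A simulation stage could not satisfy its contract (e.g. too few reachable nodes)."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated dataset.

    Defaults reproduce the study conditions: 4000 features, 500 samples, decay
    base 0.8, scale-free graph with attachment exponent 0.5, one core, logistic
    link, and a true-predictor count in the studied 30..210 range.
    """

    p: int = 4000
    n: int = 500
    power: float = 0.5
    edges_per_new_node: int = 1
    cov_base: float = 0.8
    p0: int = 90
    n_cores: Literal[1, 2] = 1
    link: Literal["logistic", "absolute"] = "logistic"
    m0: int = 10
    attenuation: float = 0.8
    drop_threshold: float = 0.1
    neg_prob: float = 0.5
    beta0: float = 0.0
    beta_lo: float = 0.1
    beta_hi: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p0 < self.p:
            raise ValueError(f"p0 must be in (0, p), got p0={self.p0}, p={self.p}")
        if self.n_cores not in (1, 2):
            raise ValueError(f"n_cores must be 1 or 2, got {self.n_cores}")
        if not 0 < self.cov_base < 1:
            raise ValueError(f"cov_base must be in (0,1), got {self.cov_base}")
        if self.m0 < 1:
            raise ValueError(f"m0 must be >= 1, got {self.m0}")
        if not 0 < self.attenuation <= 1:
            raise ValueError(f"attenuation must be in (0,1], got {self.attenuation}")
        if self.link not in ("logistic", "absolute"):
            raise ValueError(f"unknown link {self.link!r}")


@dataclass(frozen=True)
class SimulatedDataset:
    """One simulated study: expression, labels, ground truth and its generating graph."""

    X: np.ndarray  # n x p expression matrix
    y: np.ndarray  # n binary labels in {0,1}
    S: np.ndarray  # sorted true-predictor indices, |S| = p0
    beta: np.ndarray  # signed coefficients aligned to S
    graph: FeatureGraph
    config: SimulationConfig

    @property
    def true_indicator(self) -> np.ndarray:
        """0/1 vector of length p marking the true predictors (for ranking metrics)."""
        ind = np.zeros(self.config.p, dtype=np.int8)
        ind[self.S] = 1
        return ind


def build_covariance(D: np.ndarray, base: float = 0.8) -> np.ndarray:
    """Distance-decay covariance ``Sigma_ij = base ** D_ij``.

    The diagonal is exactly 1 (distance zero); unreachable pairs (``inf``
    distance) get covariance 0, the natural limit of the decay.
    """
    if not 0 < base < 1:
        raise ValueError(f"base must be in (0,1), got {base}")
    D = np.asarray(D, dtype=np.float64)
    with np.errstate(over="ignore"):
        sigma = np.power(base, D)
    sigma[np.isinf(D)] = 0.0
    np.fill_diagonal(sigma, 1.0)
    return sigma


def sample_expression(
    sigma: np.ndarray, n: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Draw ``n`` i.i.d. mean-zero Gaussian rows with covariance ``sigma``.

    Uses a Cholesky factor; if the factorization fails (covariance numerically
    indefinite, possible on graphs with cycles) a small diagonal jitter is added
    once, with a log message. A second failure raises.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = np.asarray(sigma, dtype=np.float64)
    p = sigma.shape[0]
    try:
        L = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        jitter = 1e-8 * float(np.mean(np.diag(sigma)))
        logger.warning("covariance not positive definite; adding diagonal jitter %g", jitter)
        try:
            L = np.linalg.cholesky(sigma + jitter * np.eye(p))
        except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological input
            raise np.linalg.LinAlgError(
                f"covariance factorization failed even after jitter {jitter:g}; "
                f"min eigenvalue {np.linalg.eigvalsh(sigma).min():g}"
            ) from exc
    z = rng.standard_normal((n, p))
    return z @ L.T


def find_potential_cores(g: FeatureGraph, drop_threshold: float = 0.1) -> set[int]:
    """High-degree candidate cores via a change point in the degree sequence.

    Degrees are sorted descending d_1 >= d_2 >= ...; a three-step rolling mean
    ``dbar_t = (d_t + d_{t-1} + d_{t-2}) / 3`` smooths the sequence, and the
    change point is the first t whose relative drop ``(d_{t-1} - d_t) / dbar_t``
    exceeds ``drop_threshold``. All nodes with degree strictly greater than the
    change-point degree are candidates. If no drop exceeds the threshold (e.g.
    a regular graph), the nodes at or above the 99th degree percentile are used
    instead (logged).
    """
    if g.node_count < 3:
        raise ValueError(f"need at least 3 nodes, got {g.node_count}")
    deg = g.degrees()
    d = np.sort(deg)[::-1].astype(np.float64)
    cutoff = None
    for t in range(2, len(d)):
        dbar = (d[t] + d[t - 1] + d[t - 2]) / 3.0
        if dbar <= 0:
            break
        if (d[t - 1] - d[t]) / dbar > drop_threshold:
            cutoff = d[t]
            break
    if cutoff is None:
        cutoff = float(np.percentile(deg, 99))
        logger.info("no degree change point found; falling back to 99th percentile (%g)", cutoff)
        cores = np.flatnonzero(deg >= cutoff)
    else:
        cores = np.flatnonzero(deg > cutoff)
    return set(int(i) for i in cores)


def _grow_from_core(
    g: FeatureGraph,
    seed_nodes: set[int],
    occupied: set[int],
    target: int,
    m0: int,
    attenuation: float,
    rng: np.random.Generator,
) -> set[int]:
    """One attenuated-frontier expansion round sequence from a single core."""
    grown = set(seed_nodes)
    m = m0
    while len(grown) < target:
        frontier = sorted(
            {nb for v in grown for nb in g.neighbors(v)} - grown - occupied
        )
        if not frontier:
            break
        take = min(m, len(frontier), target - len(grown))
        picked = rng.choice(len(frontier), size=take, replace=False)
        grown.update(frontier[int(i)] for i in picked)
        m = max(1, math.floor(m * attenuation))
    return grown


def select_true_predictors(
    g: FeatureGraph,
    cores: set[int],
    n_cores: Literal[1, 2] = 1,
    p0: int = 90,
    m0: int = 10,
    attenuation: float = 0.8,
    seed: int | np.random.Generator = 0,
    min_core_distance: int = 4,
) -> np.ndarray:
    """Grow the true-predictor set S from 1 or 2 randomly chosen core nodes.

    Growth proceeds in rounds: up to ``m`` uniformly sampled frontier neighbors
    join per round, and ``m`` decays by ``attenuation`` (floored at 1) so the
    sub-graph does not become a dense ball around the core. With two cores the
    seeds must be at graph distance >= ``min_core_distance`` and each grows
    toward half of ``p0`` (the larger half to the first core), alternating; if
    one side's frontier exhausts, the other absorbs the remainder.

    Returns the sorted index array S with ``len(S) == p0``.
    """
    if not cores:
        raise GenerationError("empty core candidate set")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    core_list = sorted(cores)

    if n_cores == 1:
        core = int(core_list[rng.integers(len(core_list))])
        S = _grow_from_core(g, {core}, set(), p0, m0, attenuation, rng)
        if len(S) < p0:
            raise GenerationError(
                f"component around core {core} yielded only {len(S)} of {p0} predictors"
            )
        return np.array(sorted(S), dtype=np.int64)

    # two cores: pick a random candidate pair at distance >= min_core_distance
    order = rng.permutation(len(core_list))
    pair = None
    for ii in range(len(order)):
        a = core_list[order[ii]]
        near = k_hop_neighborhood(g, a, min_core_distance - 1)
        far = [core_list[j] for j in order[ii + 1 :] if core_list[j] not in near]
        if far:
            pair = (a, int(far[0]))
            break
    if pair is None:
        raise GenerationError(
            f"no pair of core candidates at distance >= {min_core_distance}"
        )
    targets = (math.ceil(p0 / 2), math.floor(p0 / 2))
    sets: list[set[int]] = [{pair[0]}, {pair[1]}]
    ms = [m0, m0]
    stalled = [False, False]
    while sum(len(s) for s in sets) < p0:
        progressed = False
        for side in (0, 1):
            deficit = p0 - sum(len(s) for s in sets)
            if deficit <= 0:
                break
            want = targets[side] - len(sets[side])
            if stalled[1 - side]:
                want = deficit  # absorb the stalled side's remainder
            want = min(want, deficit)
            if want <= 0 or stalled[side]:
                continue
            frontier = sorted(
                {nb for v in sets[side] for nb in g.neighbors(v)}
                - sets[side]
                - sets[1 - side]
            )
            if not frontier:
                stalled[side] = True
                logger.info(
                    "core %d frontier exhausted at size %d", pair[side], len(sets[side])
                )
                continue
            take = min(ms[side], len(frontier), want)
            picked = rng.choice(len(frontier), size=take, replace=False)
            sets[side].update(frontier[int(i)] for i in picked)
            ms[side] = max(1, math.floor(ms[side] * attenuation))
            progressed = True
        if not progressed:
            break
    S = sets[0] | sets[1]
    if len(S) < p0:
        raise GenerationError(
            f"two-core growth reached only {len(S)} of {p0} predictors "
            f"(cores {pair[0]}, {pair[1]})"
        )
    return np.array(sorted(S), dtype=np.int64)


def draw_coefficients(
    p0: int,
    lo: float = 0.1,
    hi: float = 0.8,
    neg_prob: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Signed effect sizes: |beta_j| ~ U[lo, hi], sign flipped with prob ``neg_prob``."""
    if p0 < 1:
        raise ValueError(f"p0 must be >= 1, got {p0}")
    if not 0 <= neg_prob <= 1:
        raise ValueError(f"neg_prob must be in [0,1], got {neg_prob}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    beta = rng.uniform(lo, hi, size=p0)
    signs = np.where(rng.random(p0) < neg_prob, -1.0, 1.0)
    return beta * signs


def generate_outcome(
    X: np.ndarray,
    S: Sequence[int],
    beta: np.ndarray,
    beta0: float = 0.0,
    link: Literal["logistic", "absolute"] = "logistic",
    absolute_threshold: Literal["median", "fixed"] = "median",
) -> np.ndarray:
    """Binary labels from the linear predictor ``z_i = x_{i,S} . beta + beta0``.

    logistic
        ``P_i = 1 / (exp(z_i) + 1)`` and ``y_i = 1`` iff ``P_i > 0.5``
        (equivalently ``z_i < 0``; the boundary z=0 labels 0).
    absolute
        ``P_i = |z_i - mean(z)| + 0.5``. Since this exceeds 0.5 for almost every
        sample, a fixed 0.5 cutoff would label everything 1; by default the
        cutoff is the sample median of P (balanced classes). Pass
        ``absolute_threshold="fixed"`` for the literal 0.5 rule.
    """
    S = np.asarray(S, dtype=np.int64)
    beta = np.asarray(beta, dtype=np.float64)
    if beta.shape != (len(S),):
        raise ValueError(f"beta length {beta.shape} does not match |S|={len(S)}")
    z = X[:, S] @ beta + beta0
    if link == "logistic":
        prob = 1.0 / (np.exp(np.clip(z, -500, 500)) + 1.0)
        return (prob > 0.5).astype(np.int8)
    if link == "absolute":
        prob = np.abs(z - z.mean()) + 0.5
        cut = float(np.median(prob)) if absolute_threshold == "median" else 0.5
        return (prob > cut).astype(np.int8)
    raise ValueError(f"unknown link {link!r}")


def simulate_dataset(config: SimulationConfig | None = None, **overrides) -> SimulatedDataset:
    """Run the full generation pipeline; bitwise reproducible from (config, seed).

    Stages: graph -> distances -> covariance -> expression -> cores -> predictor
    growth -> coefficients -> outcome. Keyword overrides are applied to the
    config (e.g. ``simulate_dataset(p=200, p0=30, seed=7)``).
    """
    config = replace(config or SimulationConfig(), **overrides)
    ss = np.random.SeedSequence(config.seed)
    rng_graph, rng_expr, rng_grow, rng_beta = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    graph = generate_ba_graph(
        config.p, power=config.power, edges_per_new_node=config.edges_per_new_node,
        seed=rng_graph,
    )
    D = shortest_path_matrix(graph)
    sigma = build_covariance(D, base=config.cov_base)
    X = sample_expression(sigma, config.n, seed=rng_expr)
    cores = find_potential_cores(graph, drop_threshold=config.drop_threshold)
    S = select_true_predictors(
        graph, cores, n_cores=config.n_cores, p0=config.p0,
        m0=config.m0, attenuation=config.attenuation, seed=rng_grow,
    )
    beta = draw_coefficients(
        config.p0, lo=config.beta_lo, hi=config.beta_hi,
        neg_prob=config.neg_prob, seed=rng_beta,
    )
    y = generate_outcome(X, S, beta, beta0=config.beta0, link=config.link)
    return SimulatedDataset(X=X, y=y, S=S, beta=beta, graph=graph, config=config)
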