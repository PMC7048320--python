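"""Closed-form and semi-analytic estimators for conjunctive codes.

Contains the union-bound error estimate (full distance-spectrum sum and its
nearest-neighbor approximation), the single-feature error estimate, the
total-energy model (spiking cost ``eps * V`` plus one maintenance unit per
neuron), optimal-order selection under neuron-pool or total-energy budgets,
the plug-in mutual-information estimator, and the rate-distortion bound for
a uniform discrete source under symbol-error distortion.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, log2, sqrt

import numpy as np
from scipy.special import ndtr

from .codes import (
    CodeSpec,
    StimulusSpace,
    count_at_distance,
    distance_ratio,
    feature_neighbors as _feature_neighbor_count,
    min_distance,
    neighbors_at_min_distance,
    pairwise_distance,
    population_size,
    representation_energy,
)

#: Default spiking-cost ratio (energy per unit of representation energy,
#: relative to per-neuron maintenance cost); experimental estimates put it
#: around 10 to 100.  Relative code ordering is independent of this value.
DEFAULT_EPSILON = 50.0


def q_function(y):
    """Standard-normal upper-tail probability ``Q(y) = P(Z > y)``.

    Uses the complementary error-function path so values far below 1e-6
    remain accurate.
    """
    return ndtr(-np.asarray(y, dtype=float))


def _energy_for_variant(K: int, n: int, O: int, variant: str) -> float:
    space = StimulusSpace(K, n)
    return representation_energy(space, CodeSpec(O, energy_variant=variant))


def ube_error(
    K: int,
    n: int,
    O: int,
    snr,
    mode: str = "full_sum",
    energy_variant: str = "squared_distance",
) -> np.ndarray | float:
    """Union-bound estimate of the decoding error rate at population SNR.

    ``full_sum`` sums tail probabilities over the whole distance spectrum:
    ``sum_v N_all(v) * Q(d(K, O, v) * sqrt(snr / P) / 2)``; this upper-bounds
    the true ML error rate.  ``nearest_only`` keeps the minimum-distance term
    alone, ``N_min * Q(Delta * sqrt(snr / P) / 2)``, which for the
    squared-distance energy variant reduces to
    ``N_min * Q(sqrt(snr * O / (2K)))``.

    ``energy_variant`` selects the representation energy ``P`` that relates
    SNR to distances; use the variant the simulation under comparison used.
    Accepts a scalar or array ``snr``.
    """
    snr = np.asarray(snr, dtype=float)
    if (snr < 0).any():
        raise ValueError("snr must be nonnegative")
    if mode not in ("full_sum", "nearest_only"):
        raise ValueError("mode must be 'full_sum' or 'nearest_only'")
    space = StimulusSpace(K, n)
    p = _energy_for_variant(K, n, O, energy_variant)
    scale = np.sqrt(snr / p) / 2.0
    if mode == "nearest_only":
        n_min = neighbors_at_min_distance(space, O)
        pe = n_min * q_function(min_distance(K, O) * scale)
    else:
        pe = np.zeros_like(snr, dtype=float)
        for v in range(1, K + 1):
            pe += count_at_distance(space, v) * q_function(
                pairwise_distance(K, O, v) * scale
            )
    return float(pe) if pe.ndim == 0 else pe


def feature_error(K: int, n: int, O: int, snr) -> np.ndarray | float:
    """Union-bound estimate of the single-feature decoding error rate.

    ``N_f * Q(sqrt(snr * O / (2K)))`` where ``N_f`` counts minimum-distance
    neighbors with a wrong value of the queried feature: ``n - 1`` for
    ``O < K`` and ``(n - 1) * n**(K-1)`` for the full-order code.
    """
    snr = np.asarray(snr, dtype=float)
    if (snr < 0).any():
        raise ValueError("snr must be nonnegative")
    space = StimulusSpace(K, n)
    n_f = _feature_neighbor_count(space, O)
    pe = n_f * q_function(np.sqrt(snr * O / (2.0 * K)))
    return float(pe) if pe.ndim == 0 else pe


@dataclass(frozen=True)
class EnergyBudget:
    """Allocation of a total energy budget ``E`` to one code.

    ``E = eps * V + D``: spiking cost ``eps`` per unit of representation
    energy ``V`` plus one maintenance unit per neuron.  Feasible only when
    ``E > D``; then ``V = (E - D) / eps`` and the post-transform squared
    minimum distance is ``delta2 = (2 O / (K eps)) * (E - D)``.
    """

    total_energy: float
    epsilon: float
    order: int
    population: int
    feasible: bool
    representation_energy: float
    delta_sq: float


def allocate_energy(
    E: float,
    epsilon: float,
    K: int,
    n: int,
    O: int,
    rf_width: int = 1,
    population: int | None = None,
) -> EnergyBudget:
    """Split total energy ``E`` between maintenance and spiking for one code.

    ``population`` overrides the formula population size (used for RF codes
    whose constructive unit count differs from the closed form).  An
    infeasible budget (``E <= D``) is flagged, not raised.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if population is None:
        population = population_size(StimulusSpace(K, n), CodeSpec(O, rf_width))
    feasible = E > population
    if not feasible:
        return EnergyBudget(E, epsilon, O, population, False, 0.0, 0.0)
    V = (E - population) / epsilon
    delta_sq = distance_ratio(K, O) * V
    return EnergyBudget(E, epsilon, O, population, True, V, delta_sq)


def transition_energy(K: int, n: int, O: int) -> float:
    """Total energy at which the order ``O + 1`` code overtakes order ``O``.

    ``E = (nK - (n + 1) O) * C(K, O) * n**O``; at this budget the two codes
    reach identical post-transform minimum distance.
    """
    if not (1 <= O < K):
        raise ValueError(f"requires 1 <= O < K, got O={O}, K={K}")
    return float((n * K - (n + 1) * O) * comb(K, O) * n**O)


def mixed_beats_pure(K: int, n: int) -> float:
    """Energy above which some mixed code (O > 1) beats the pure code:
    ``n**2 K**2 - n**2 K - n K`` (equal to ``transition_energy(K, n, 1)``)."""
    if K < 2:
        raise ValueError("requires K >= 2")
    return float(n**2 * K**2 - n**2 * K - n * K)


@dataclass(frozen=True)
class OptimalOrder:
    """Best code order under a resource constraint, with the achieved
    post-transform minimum distance (0 when nothing is feasible)."""

    order: int | None
    delta: float
    feasible: bool


def optimal_order(
    K: int,
    n: int,
    *,
    neuron_pool: int | None = None,
    total_energy: float | None = None,
    epsilon: float = DEFAULT_EPSILON,
) -> OptimalOrder:
    """Best order under a fixed neuron pool or a fixed total-energy budget.

    ``neuron_pool``: the largest ``O`` with ``D_O <= N`` (highest order the
    pool can implement; it also maximizes minimum distance at fixed spiking
    energy).  ``total_energy``: the ``O`` maximizing ``delta**2`` under the
    total-energy split, ties to the lower order.
    """
    if (neuron_pool is None) == (total_energy is None):
        raise ValueError("specify exactly one of neuron_pool or total_energy")
    space = StimulusSpace(K, n)
    if neuron_pool is not None:
        feasible = [
            O
            for O in range(1, K + 1)
            if population_size(space, CodeSpec(O)) <= neuron_pool
        ]
        if not feasible:
            return OptimalOrder(None, 0.0, False)
        best = max(feasible)
        return OptimalOrder(best, min_distance(K, best), True)

    best_order, best_delta_sq = None, -np.inf
    for O in range(1, K + 1):
        budget = allocate_energy(total_energy, epsilon, K, n, O)
        if budget.feasible and budget.delta_sq > best_delta_sq + 1e-12:
            best_order, best_delta_sq = O, budget.delta_sq
    if best_order is None:
        return OptimalOrder(None, 0.0, False)
    return OptimalOrder(best_order, sqrt(best_delta_sq), True)


def mutual_information(confusion: np.ndarray) -> float:
    """Plug-in estimate of I(X; Xhat) in bits from a confusion-count matrix."""
    c = np.asarray(confusion, dtype=float)
    if (c < 0).any():
        raise ValueError("confusion counts must be nonnegative")
    total = c.sum()
    if total <= 0:
        raise ValueError("confusion matrix is all zero")
    joint = c / total
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    ratio = joint[mask] / (px @ py)[mask]
    return float((joint[mask] * np.log2(ratio)).sum())


def rate_distortion_bound(M: int, distortion) -> np.ndarray | float:
    """Minimum information rate (bits) needed to achieve symbol-error
    probability ``distortion`` for a uniform source over ``M`` symbols.

    ``R(D) = log2 M - H_b(D) - D log2(M - 1)`` on ``0 <= D <= 1 - 1/M``;
    ``R(0) = log2 M`` and ``R(1 - 1/M) = 0``.  Any code whose decoder attains
    error probability D must carry at least ``R(D)`` bits about the stimulus.
    """
    if M < 2:
        raise ValueError("M must be >= 2")
    d = np.asarray(distortion, dtype=float)
    if (d < 0).any() or (d > 1.0 - 1.0 / M + 1e-12).any():
        raise ValueError("distortion must lie in [0, 1 - 1/M]")
    with np.errstate(divide="ignore", invalid="ignore"):
        hb = -np.where(d > 0, d * np.log2(np.where(d > 0, d, 1.0)), 0.0) - np.where(
            d < 1, (1 - d) * np.log2(np.where(d < 1, 1 - d, 1.0)), 0.0
        )
    r = log2(M) - hb - d * log2(M - 1)
    r = np.maximum(r, 0.0)
    return float(r) if r.ndim == 0 else r


@dataclass(frozen=True)
class AnalyticReport:
    """Closed-form summary of one code plus a union-bound error curve."""

    K: int
    n: int
    order: int
    rf_width: int
    population: int
    representation_energy: float
    min_distance: float
    delta: float
    distance_spectrum: dict
    neighbor_counts: dict
    snr_grid: np.ndarray
    ube_full: np.ndarray
    ube_nearest: np.ndarray

    def to_dict(self) -> dict:
        d = {
            "K": self.K,
            "n": self.n,
            "order": self.order,
            "rf_width": self.rf_width,
            "population": self.population,
            "representation_energy": self.representation_energy,
            "min_distance": self.min_distance,
            "delta": self.delta,
            "distance_spectrum": self.distance_spectrum,
            "neighbor_counts": self.neighbor_counts,
            "snr_grid": self.snr_grid.tolist(),
            "ube_full": self.ube_full.tolist(),
            "ube_nearest": self.ube_nearest.tolist(),
        }
        return d


def analytic_report(
    K: int,
    n: int,
    O: int,
    rf_width: int = 1,
    target_energy: float | None = None,
    snr_grid=None,
) -> AnalyticReport:
    """All closed-form code metrics, reproducible from the parameters alone.

    Analytic reports use the squared-distance energy variant (the variant in
    the closed forms); ``target_energy`` sets the post-transform energy ``V``
    used to report ``delta = sqrt(V / P) * Delta``.
    """
    space = StimulusSpace(K, n)
    spec = CodeSpec(O, rf_width, energy_variant="squared_distance")
    if snr_grid is None:
        snr_grid = np.linspace(1.0, 25.0, 25)
    snr_grid = np.asarray(snr_grid, dtype=float)
    p = representation_energy(space, spec)
    delta = min_distance(K, O)
    if target_energy is not None:
        delta *= sqrt(target_energy / p)
    return AnalyticReport(
        K=K,
        n=n,
        order=O,
        rf_width=rf_width,
        population=population_size(space, spec),
        representation_energy=p,
        min_distance=min_distance(K, O),
        delta=delta,
        distance_spectrum={v: pairwise_distance(K, O, v) for v in range(1, K + 1)},
        neighbor_counts={
            "all_by_v": {v: count_at_distance(space, v) for v in range(1, K + 1)},
            "min_distance": neighbors_at_min_distance(space, O),
            "feature": _feature_neighbor_count(space, O),
        },
        snr_grid=snr_grid,
        ube_full=np.asarray(ube_error(K, n, O, snr_grid, "full_sum")),
        ube_nearest=np.asarray(ube_error(K, n, O, snr_grid, "nearest_only")),
    )
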