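"""Receptive-field (RF) generalizations of the conjunctive codes.

With RF width ``s > 1`` a unit responds when each of its ``O`` features falls
inside a contiguous value interval of length ``s`` rather than at a point.
Intervals tile each feature axis at ``s`` distinct lattice offsets (boundary
intervals truncated); within one feature subset, units pair intervals across
features at a common offset, so every stimulus activates exactly one unit per
(subset, offset) — ``C(K, O) * s`` in total — and the joint activity of the
``s`` overlapping units per subset localizes the stimulus exactly.

Widening RFs raises representation energy linearly and shrinks the required
population roughly as ``1 / s**(O-1)`` while leaving minimum distance
unchanged; its behavioral effect is to make decoding errors land on nearby
stimuli, trading a higher error rate for a lower mean squared error.

A continuous-stimulus variant discretizes each feature axis into the lattice
cells induced by the RF overlap and measures MSE in continuous feature units.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import sqrt

import numpy as np
import pandas as pd

from .channel import ChannelConfig, ml_decode, simulate, transmit
from .codes import (
    Codebook,
    CodeSpec,
    StimulusSpace,
    Unit,
    build_codebook,
    population_size,
)
from .analytics import allocate_energy
from .errors import UnsupportedGeometryError


@dataclass(frozen=True)
class RFCodebook(Codebook):
    """Codebook with interval (RF) tuning.

    ``formula_population`` is the closed-form unit count
    ``C(K, O) * s * (n/s + 1)**O``; the constructive truncated-lattice count
    ``n_units`` can be smaller, and the two are reported side by side rather
    than forced to agree.
    """

    formula_population: int = 0

    @property
    def population_discrepancy(self) -> int:
        return self.formula_population - self.n_units


def _axis_intervals(n: int, width: int, offset: int) -> list[tuple[int, int]]:
    """Inclusive intervals of length ``width`` tiling ``0..n-1`` at ``offset``,
    with truncated boundary intervals."""
    intervals = []
    if offset > 0:
        intervals.append((0, offset - 1))
    start = offset
    while start < n:
        intervals.append((start, min(start + width, n) - 1))
        start += width
    return intervals


def build_rf_codebook(space: StimulusSpace, spec: CodeSpec) -> RFCodebook:
    """Construct the interval codebook for ``spec.rf_width > 1``.

    Requires the RF width to divide ``n``.  Every stimulus activates exactly
    ``C(K, O) * s`` units and all codewords are distinct.
    """
    spec.validate_for(space)
    s = spec.rf_width
    if s == 1:
        base = build_codebook(space, spec)
        return RFCodebook(
            space=space,
            spec=spec,
            words=base.words,
            units=base.units,
            formula_population=population_size(space, spec),
        )
    K, n = space.n_features, space.n_values
    if n % s != 0:
        raise UnsupportedGeometryError(f"rf_width {s} must divide n = {n}")

    units: list[Unit] = []
    for subset in itertools.combinations(range(K), spec.order):
        for offset in range(s):
            axis = _axis_intervals(n, s, offset)
            for combo in itertools.product(axis, repeat=spec.order):
                units.append(Unit(features=subset, values=tuple(combo), offset=offset))

    stimuli = space.stimuli()
    words = np.zeros((space.n_stimuli, len(units)), dtype=np.uint8)
    for k, u in enumerate(units):
        active = np.ones(space.n_stimuli, dtype=bool)
        for f, (lo, hi) in zip(u.features, u.values):
            col = stimuli[:, f]
            active &= (col >= lo) & (col <= hi)
        words[:, k] = active
    return RFCodebook(
        space=space,
        spec=spec,
        words=words,
        units=tuple(units),
        formula_population=population_size(space, spec),
    )


def rf_sweep(
    space: StimulusSpace,
    orders,
    rf_widths,
    total_energy: float,
    epsilon: float,
    n_trials: int,
    seed: int | None = None,
    energy_variant: str = "variance",
) -> tuple[pd.DataFrame, dict]:
    """Simulate every (order, RF width) configuration at a fixed total energy.

    Each configuration gets ``V = (E - D) / eps`` of representation energy
    (``D`` the constructive unit count) and is transmitted through Gaussian
    noise of unit variance, so the population SNR equals ``V``.  Infeasible
    configurations (``E <= D``) are flagged in the output, not fatal.

    Returns a tidy DataFrame and a dict of the full Monte-Carlo results
    keyed by ``(order, rf_width)`` (for error-magnitude CDFs).
    """
    K, n = space.n_features, space.n_values
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    children = ss.spawn(len(list(orders)) * len(list(rf_widths)))
    rows, results = [], {}
    for i, (O, s) in enumerate(itertools.product(orders, rf_widths)):
        spec = CodeSpec(O, s, energy_variant=energy_variant)
        try:
            codebook = build_rf_codebook(space, spec)
        except UnsupportedGeometryError:
            rows.append(
                {"order": O, "rf_width": s, "E": total_energy, "feasible": False}
            )
            continue
        budget = allocate_energy(
            total_energy, epsilon, K, n, O, s, population=codebook.n_units
        )
        row = {
            "order": O,
            "rf_width": s,
            "E": total_energy,
            "population": codebook.n_units,
            "population_formula": codebook.formula_population,
            "feasible": budget.feasible,
        }
        if budget.feasible:
            V = budget.representation_energy
            rng = np.random.default_rng(children[i])
            res = simulate(
                space,
                spec,
                ChannelConfig(noise="gaussian"),
                n_trials,
                seed=seed,
                snr=V,
                target_energy=V,
                codebook=codebook,
                rng=rng,
            )
            results[(O, s)] = res
            row.update(
                V=V,
                snr=V,
                pe=res.pe,
                pe_se=res.pe_se,
                mse=res.mse,
                mse_se=res.mse_se,
            )
        rows.append(row)
    return pd.DataFrame(rows), results


@dataclass(frozen=True)
class ContinuousCodeConfig:
    """A conjunctive RF code over continuous periodic features on [0, 1).

    Each feature axis carries a lattice of ``n_cells`` decode cells; RF
    centers sit at every cell (no gaps), and an RF spans ``rf_cells``
    consecutive cells, i.e. a continuous width of ``rf_cells / n_cells``.
    Features are periodic (wrap-around), so every stimulus activates exactly
    ``C(K, O) * rf_cells**O`` units and representation energy is uniform.
    ``tuning`` is ``boxcar`` (cell membership, the default) or ``gaussian``
    (graded response with standard deviation half the RF width).
    """

    n_features: int
    order: int
    n_cells: int
    rf_cells: int = 1
    tuning: str = "boxcar"

    def __post_init__(self) -> None:
        if not (1 <= self.order <= self.n_features):
            raise ValueError("order must satisfy 1 <= O <= K")
        if self.n_cells < 2:
            raise ValueError("n_cells must be >= 2")
        if not (1 <= self.rf_cells < self.n_cells):
            raise ValueError("rf_cells must satisfy 1 <= rf_cells < n_cells")
        if self.tuning not in ("boxcar", "gaussian"):
            raise ValueError("tuning must be 'boxcar' or 'gaussian'")

    @property
    def rf_width(self) -> float:
        """Continuous RF width as a fraction of the feature range."""
        return self.rf_cells / self.n_cells


@dataclass(frozen=True)
class ContinuousResult:
    """MSE (continuous feature units, circular metric) and cell error rate."""

    mse: float
    mse_se: float
    pe_cell: float
    n_trials: int
    seed: int | None
    config: ContinuousCodeConfig
    snr: float | None
    target_energy: float | None


def _continuous_units(config: ContinuousCodeConfig):
    """Sliding-window units: (feature subset, start-cell combination)."""
    subsets = list(itertools.combinations(range(config.n_features), config.order))
    starts = list(itertools.product(range(config.n_cells), repeat=config.order))
    return subsets, starts


def _continuous_words(config: ContinuousCodeConfig) -> np.ndarray:
    """Binary codeword matrix over the grid of cells, ``(n_cells**K, D)``.

    Unit (A, c) is active for a cell x iff ``(x_f - c_f) mod n_cells <
    rf_cells`` for every feature f in A.
    """
    n, s = config.n_cells, config.rf_cells
    space = StimulusSpace(config.n_features, n)
    cells = space.stimuli()
    subsets, starts = _continuous_units(config)
    words = np.zeros((cells.shape[0], len(subsets) * len(starts)), dtype=np.uint8)
    k = 0
    for subset in subsets:
        for c in starts:
            active = np.ones(cells.shape[0], dtype=bool)
            for f, cf in zip(subset, c):
                active &= (cells[:, f] - cf) % n < s
            words[:, k] = active
            k += 1
    return words


def _continuous_activity(
    x: np.ndarray, config: ContinuousCodeConfig
) -> np.ndarray:
    """Unit responses to continuous stimuli ``x`` in [0, 1)^K."""
    n, s = config.n_cells, config.rf_cells
    subsets, starts = _continuous_units(config)
    act = np.zeros((x.shape[0], len(subsets) * len(starts)), dtype=float)
    if config.tuning == "boxcar":
        cells = np.minimum((x * n).astype(int), n - 1)
        k = 0
        for subset in subsets:
            for c in starts:
                inside = np.ones(x.shape[0], dtype=bool)
                for f, cf in zip(subset, c):
                    inside &= (cells[:, f] - cf) % n < s
                act[:, k] = inside
                k += 1
        return act
    sd = config.rf_width / 2.0
    k = 0
    for subset in subsets:
        for c in starts:
            sq = np.zeros(x.shape[0])
            for f, cf in zip(subset, c):
                center = ((cf + s / 2.0) % n) / n
                d = np.abs(x[:, f] - center)
                d = np.minimum(d, 1.0 - d)
                sq += d**2
            act[:, k] = np.exp(-sq / (2.0 * sd**2))
            k += 1
    return act


def continuous_simulate(
    config: ContinuousCodeConfig,
    snr: float,
    n_trials: int,
    seed: int | None = None,
    *,
    target_energy: float | None = None,
) -> ContinuousResult:
    """Monte-Carlo MSE of a continuous-feature RF code under Gaussian noise.

    Stimuli are drawn uniformly from [0, 1)^K, encoded by RF tuning,
    rescaled to representation energy ``target_energy`` (default: the code's
    own activity energy), transmitted with noise variance ``V / snr``, and
    ML-decoded on the grid of cell centers.  MSE sums squared circular
    feature errors in continuous units; with no noise it is limited only by
    grid resolution.  Widening RFs makes neighboring codewords share more
    active units, which at matched energy shrinks their separation — MSE
    grows with RF width, the opposite of the discrete-stimulus tradeoff.
    """
    words = _continuous_words(config)
    p = float((words.astype(float) ** 2).sum(axis=1).mean())
    V = p if target_energy is None else float(target_energy)
    H = sqrt(V / p)
    clean = H * words.astype(float)
    channel = ChannelConfig(noise="gaussian", sigma2=V / snr)

    rng = np.random.default_rng(seed)
    K, n = config.n_features, config.n_cells
    space = StimulusSpace(K, n)
    centers = (space.stimuli() + 0.5) / n

    sq_sum = sq_sumsq = 0.0
    n_wrong = 0
    chunk = 2048
    for start in range(0, n_trials, chunk):
        T = min(chunk, n_trials - start)
        x = rng.random((T, K))
        act = _continuous_activity(x, config)
        noisy = transmit(H * act, channel, rng)
        decoded, _ = ml_decode(noisy, clean, channel)
        d = np.abs(centers[decoded] - x)
        d = np.minimum(d, 1.0 - d)
        sq = (d**2).sum(axis=1)
        sq_sum += sq.sum()
        sq_sumsq += (sq**2).sum()
        true_cells = np.minimum((x * n).astype(int), n - 1)
        true_idx = _cell_indices(space, true_cells)
        n_wrong += int((decoded != true_idx).sum())

    mse = sq_sum / n_trials
    var = max(sq_sumsq / n_trials - mse**2, 0.0)
    return ContinuousResult(
        mse=float(mse),
        mse_se=float(sqrt(var / n_trials)),
        pe_cell=n_wrong / n_trials,
        n_trials=n_trials,
        seed=seed,
        config=config,
        snr=snr,
        target_energy=V,
    )


def _cell_indices(space: StimulusSpace, cells: np.ndarray) -> np.ndarray:
    weights = space.n_values ** np.arange(space.n_features - 1, -1, -1)
    return cells @ weights
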