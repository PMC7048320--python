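"""Conjunctive population codes over discrete multi-feature stimulus spaces.

A stimulus has ``K`` discrete features, each taking one of ``n`` values, so
there are ``M = n**K`` stimuli.  A code of order ``O`` assigns one binary
coding unit ("neuron") to every combination of ``O`` features and every joint
value assignment of those features; a unit fires (1) exactly when the stimulus
matches its value combination on its feature subset.  ``O = 1`` is a pure
(single-feature) code, ``O = K`` is the fully conjunctive one-hot code.

Closed-form properties of these codes — population size, representation
energy, the pairwise-distance spectrum, minimum distance, and neighbor
counts — are exposed as module functions; :class:`Codebook` provides the
explicit stimulus-by-unit binary matrix and brute-force counterparts.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from math import comb, sqrt
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidStimulusError, UnsupportedGeometryError

ENERGY_VARIANTS = ("squared_distance", "variance", "sum_of_spikes")


@dataclass(frozen=True)
class StimulusSpace:
    """A grid of ``K`` discrete features, each taking ``n`` values.

    Feature values are 0-based integer indices ``0 .. n - 1``.
    """

    n_features: int
    n_values: int

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.n_values < 2:
            raise ValueError("n_values must be >= 2")

    @property
    def n_stimuli(self) -> int:
        """Total number of stimuli, ``M = n**K``."""
        return self.n_values**self.n_features

    def stimuli(self) -> np.ndarray:
        """All stimuli as an ``(M, K)`` integer array in lexicographic order.

        The first feature is the most significant digit: stimulus ``i`` is the
        base-``n`` expansion of ``i``.
        """
        K, n = self.n_features, self.n_values
        grids = np.indices((n,) * K).reshape(K, -1).T
        return np.ascontiguousarray(grids)

    def index_of(self, stimulus: Sequence[int]) -> int:
        """Position of ``stimulus`` in the :meth:`stimuli` enumeration."""
        s = self.validate(stimulus)
        n = self.n_values
        weights = n ** np.arange(self.n_features - 1, -1, -1)
        return int(s @ weights)

    def validate(self, stimulus: Sequence[int]) -> np.ndarray:
        """Return ``stimulus`` as an int array, or raise :class:`InvalidStimulusError`."""
        s = np.asarray(stimulus, dtype=int)
        if s.shape != (self.n_features,):
            raise InvalidStimulusError(
                f"expected {self.n_features} feature values, got shape {s.shape}"
            )
        if (s < 0).any() or (s >= self.n_values).any():
            raise InvalidStimulusError(
                f"feature values must lie in [0, {self.n_values - 1}]: {s.tolist()}"
            )
        return s


@dataclass(frozen=True)
class CodeSpec:
    """Parameters of a conjunctive code: order, RF width, and energy variant.

    ``energy_variant`` selects how representation energy is accounted:
    ``squared_distance`` (squared norm of the codeword), ``variance``
    (per-unit activity variance summed over the population, the default used
    in simulations because it slightly favors low-order codes), or
    ``sum_of_spikes`` (plain active-unit count).
    """

    order: int
    rf_width: int = 1
    energy_variant: str = "variance"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.rf_width < 1:
            raise ValueError("rf_width must be >= 1")
        if self.energy_variant not in ENERGY_VARIANTS:
            raise ValueError(f"energy_variant must be one of {ENERGY_VARIANTS}")

    def validate_for(self, space: StimulusSpace) -> None:
        if self.order > space.n_features:
            raise ValueError(
                f"order {self.order} exceeds feature count {space.n_features}"
            )
        if self.rf_width > space.n_values:
            raise ValueError(
                f"rf_width {self.rf_width} exceeds values per feature {space.n_values}"
            )
        if space.n_values % self.rf_width != 0:
            raise UnsupportedGeometryError(
                f"rf_width {self.rf_width} must divide n = {space.n_values}"
            )


@dataclass(frozen=True)
class Unit:
    """One coding unit: a feature subset and the value(s) it indicates.

    ``values[i]`` is either a single value index (point tuning) or an
    inclusive ``(lo, hi)`` interval (receptive-field tuning) for feature
    ``features[i]``.  ``offset`` records the RF lattice offset, if any.
    """

    features: tuple[int, ...]
    values: tuple
    offset: int | None = None

    def is_active(self, stimulus: np.ndarray) -> bool:
        for f, v in zip(self.features, self.values):
            x = stimulus[f]
            if isinstance(v, tuple):
                lo, hi = v
                if not (lo <= x <= hi):
                    return False
            elif x != v:
                return False
        return True


@dataclass(frozen=True)
class Codebook:
    """A binary stimulus -> codeword map for one conjunctive code.

    ``words`` is the ``(M, D)`` binary matrix whose row ``i`` is the codeword
    of the ``i``-th stimulus in :meth:`StimulusSpace.stimuli` order.
    """

    space: StimulusSpace
    spec: CodeSpec
    words: np.ndarray
    units: tuple[Unit, ...] = field(repr=False)

    @property
    def n_units(self) -> int:
        return self.words.shape[1]

    def encode(self, stimulus: Sequence[int]) -> np.ndarray:
        """Codeword of ``stimulus`` (validates the stimulus first)."""
        idx = self.space.index_of(stimulus)
        return self.words[idx]

    def pairwise_distances(self) -> np.ndarray:
        """Full ``(M, M)`` matrix of Euclidean distances between codewords."""
        from scipy.spatial.distance import pdist, squareform

        return squareform(pdist(self.words.astype(float)))

    def min_distance(self) -> float:
        """Smallest Euclidean distance between any two distinct codewords."""
        d = self.pairwise_distances()
        m = d.shape[0]
        return float(d[~np.eye(m, dtype=bool)].min())

    def to_frame(self) -> pd.DataFrame:
        """Codebook as a DataFrame: rows labeled by stimulus, columns by unit."""
        stim_labels = ["-".join(map(str, s)) for s in self.space.stimuli()]
        unit_labels = [_unit_label(u) for u in self.units]
        return pd.DataFrame(self.words, index=stim_labels, columns=unit_labels)

    def metadata(self) -> dict:
        """JSON-serializable record of the code's parameters and closed forms."""
        K, n = self.space.n_features, self.space.n_values
        O = self.spec.order
        return {
            "K": K,
            "n": n,
            "order": O,
            "rf_width": self.spec.rf_width,
            "energy_variant": self.spec.energy_variant,
            "n_units": self.n_units,
            "population_size_formula": population_size(self.space, self.spec),
            "representation_energy": empirical_representation_energy(
                self, self.spec.energy_variant
            ),
            "min_distance": min_distance(K, O),
        }

    def to_json(self) -> str:
        return json.dumps(self.metadata(), indent=2)


def _unit_label(u: Unit) -> str:
    parts = []
    for f, v in zip(u.features, u.values):
        if isinstance(v, tuple):
            parts.append(f"f{f}:{v[0]}..{v[1]}")
        else:
            parts.append(f"f{f}={v}")
    label = "&".join(parts)
    if u.offset is not None:
        label += f"@{u.offset}"
    return label


def _value_combinations(
    features: Sequence[int], n: int, value_order: str
) -> Iterable[tuple[int, ...]]:
    O = len(features)
    if value_order == "lex":
        # last listed feature varies fastest
        yield from itertools.product(range(n), repeat=O)
    elif value_order == "colex":
        # first listed feature varies fastest
        for combo in itertools.product(range(n), repeat=O):
            yield combo[::-1]
    else:
        raise ValueError("value_order must be 'lex' or 'colex'")


def build_codebook(
    space: StimulusSpace,
    spec: CodeSpec,
    *,
    feature_subsets: Sequence[Sequence[int]] | None = None,
    value_order: str = "lex",
) -> Codebook:
    """Construct the codebook for ``spec`` over ``space``.

    By default units are ordered by feature subset (lexicographic over
    subsets of ``[0, K)``) and, within a subset, by value combination in
    lexicographic order.  ``feature_subsets`` and ``value_order`` override
    the layout; the geometry of the code is invariant to both.

    Codes with ``rf_width > 1`` are dispatched to
    :func:`mixedcodes.rf.build_rf_codebook`.
    """
    spec.validate_for(space)
    if spec.rf_width > 1:
        from .rf import build_rf_codebook

        return build_rf_codebook(space, spec)

    K, n = space.n_features, space.n_values
    if feature_subsets is None:
        feature_subsets = list(itertools.combinations(range(K), spec.order))
    else:
        feature_subsets = [tuple(a) for a in feature_subsets]
        for a in feature_subsets:
            if len(a) != spec.order or not all(0 <= f < K for f in a):
                raise ValueError(f"invalid feature subset {a} for order {spec.order}")

    units: list[Unit] = []
    for subset in feature_subsets:
        for combo in _value_combinations(subset, n, value_order):
            units.append(Unit(features=tuple(subset), values=tuple(combo)))

    stimuli = space.stimuli()
    words = np.zeros((space.n_stimuli, len(units)), dtype=np.uint8)
    for k, u in enumerate(units):
        cols = stimuli[:, list(u.features)]
        words[:, k] = (cols == np.asarray(u.values)).all(axis=1)
    return Codebook(space=space, spec=spec, words=words, units=tuple(units))


def encode(codebook: Codebook, stimulus: Sequence[int]) -> np.ndarray:
    """Binary codeword of ``stimulus`` under ``codebook``."""
    return codebook.encode(stimulus)


# ---------------------------------------------------------------------------
# closed-form code properties
# ---------------------------------------------------------------------------


def population_size(space: StimulusSpace, spec: CodeSpec) -> int:
    """Number of coding units, ``D_O``.

    For point tuning (``rf_width == 1``) this is ``C(K, O) * n**O``: one unit
    per feature subset and value combination.  For wider RFs with ``O > 1``
    the formula value ``C(K, O) * s * (n/s + 1)**O`` is returned (``s`` the RF
    width); for ``O = 1`` RF width does not change the population size.  Note
    the RF formula is an idealization — the constructive truncated-lattice
    codebook built by :func:`mixedcodes.rf.build_rf_codebook` can use fewer
    units; it records its own count.
    """
    spec.validate_for(space)
    K, n, O, s = space.n_features, space.n_values, spec.order, spec.rf_width
    if s == 1 or O == 1:
        return comb(K, O) * n**O
    return comb(K, O) * s * (n // s + 1) ** O


def representation_energy(space: StimulusSpace, spec: CodeSpec) -> float:
    """Representation energy ``P_O`` under the spec's energy variant.

    * ``squared_distance``: squared norm of each codeword, ``C(K, O) * s``.
    * ``variance``: summed per-unit activity variance over the stimulus set;
      ``C(K, O) * (1 - n**-O)`` for point tuning, computed from the
      constructive codebook for RF codes.
    * ``sum_of_spikes``: active-unit count per stimulus, ``C(K, O) * s``
      (identical to ``squared_distance`` for binary codewords).
    """
    spec.validate_for(space)
    K, n, O, s = space.n_features, space.n_values, spec.order, spec.rf_width
    if spec.energy_variant in ("squared_distance", "sum_of_spikes"):
        return float(comb(K, O) * s)
    if s == 1:
        return comb(K, O) * (1.0 - float(n) ** (-O))
    return empirical_representation_energy(build_codebook(space, spec), "variance")


def empirical_representation_energy(codebook: Codebook, variant: str) -> float:
    """Representation energy measured directly from the codeword matrix."""
    w = codebook.words.astype(float)
    if variant == "squared_distance":
        return float((w**2).sum(axis=1).mean())
    if variant == "sum_of_spikes":
        return float(w.sum(axis=1).mean())
    if variant == "variance":
        return float(((w**2).mean(axis=0) - w.mean(axis=0) ** 2).sum())
    raise ValueError(f"unknown energy variant {variant!r}")


def pairwise_distance(K: int, O: int, v: int) -> float:
    """Euclidean distance ``d(K, O, v)`` between codewords of two stimuli
    differing in exactly ``v`` of ``K`` features, for an order-``O`` code.

    Each feature subset containing ``i >= 1`` of the differing features
    contributes two disagreeing units; there are ``C(v, i) * C(K-v, O-i)``
    such subsets, giving ``sqrt(2 * sum_i C(v, i) * C(K-v, O-i))``.
    """
    if not (1 <= O <= K):
        raise ValueError(f"order must satisfy 1 <= O <= K, got O={O}, K={K}")
    if not (1 <= v <= K):
        raise ValueError(f"v must satisfy 1 <= v <= K, got v={v}")
    total = sum(comb(v, i) * comb(K - v, O - i) for i in range(1, min(v, O) + 1))
    return sqrt(2.0 * total)


def min_distance(K: int, O: int) -> float:
    """Minimum distance ``Delta_O = sqrt(2 * C(K-1, O-1))``.

    The minimum of the distance spectrum is attained by stimulus pairs
    differing in a single feature.
    """
    if not (1 <= O <= K):
        raise ValueError(f"order must satisfy 1 <= O <= K, got O={O}, K={K}")
    return sqrt(2.0 * comb(K - 1, O - 1))


def distance_ratio(K: int, O: int) -> float:
    """Squared minimum distance per unit representation energy: exactly ``2O/K``.

    Uses the squared-distance energy variant with point tuning; the ratio is
    invariant to any valid linear transform.
    """
    if not (1 <= O <= K):
        raise ValueError(f"order must satisfy 1 <= O <= K, got O={O}, K={K}")
    return 2.0 * O / K


def count_at_distance(space: StimulusSpace, v: int) -> int:
    """Number of stimuli differing from a given one in exactly ``v`` features,
    ``N_all(v) = C(K, v) * (n - 1)**v``.  Sums over ``v`` to ``M - 1``."""
    K, n = space.n_features, space.n_values
    if not (1 <= v <= K):
        raise ValueError(f"v must satisfy 1 <= v <= K, got v={v}")
    return comb(K, v) * (n - 1) ** v


def neighbors_at_min_distance(space: StimulusSpace, O: int) -> int:
    """Number of codewords at minimum distance from any given codeword.

    ``K * (n - 1)`` for ``O < K`` (only single-feature changes attain the
    minimum); for the full-order code every other stimulus is at minimum
    distance, ``n**K - 1``.
    """
    K, n = space.n_features, space.n_values
    if not (1 <= O <= K):
        raise ValueError(f"order must satisfy 1 <= O <= K, got O={O}")
    if O < K:
        return K * (n - 1)
    return n**K - 1


def feature_neighbors(space: StimulusSpace, O: int) -> int:
    """Minimum-distance neighbors whose value differs on one queried feature.

    ``n - 1`` for ``O < K``; ``(n - 1) * n**(K-1)`` for the full-order code
    (every stimulus with a different value of the queried feature).
    """
    K, n = space.n_features, space.n_values
    if not (1 <= O <= K):
        raise ValueError(f"order must satisfy 1 <= O <= K, got O={O}")
    if O < K:
        return n - 1
    return (n - 1) * n ** (K - 1)


def hamming_distance(a: Sequence[int], b: Sequence[int]) -> int:
    """Number of coordinates at which two codewords (or stimuli) differ."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return int((a != b).sum())
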