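"""Noisy-channel transmission and maximum-likelihood decoding.

A stimulus is encoded (optionally after input noise corrupts the stimulus or
its pure-code bit representation), passed through a linear transform, and
transmitted through one of three output-noise models:

* ``gaussian`` — additive i.i.d. normal noise of variance ``sigma2`` per
  response dimension; SNR is defined at the population level as
  ``V / sigma2`` where ``V`` is the post-transform representation energy.
* ``poisson`` — spike counts drawn with mean equal to each dimension's
  (nonnegative) activity; dimensions with zero activity emit exactly zero.
* ``poisson_baseline`` — Poisson with mean ``activity + r_spont``; the
  Poisson SNR is ``V / r_spont``.

Decoding is maximum likelihood over the clean transformed codebook: nearest
Euclidean codeword under Gaussian noise, Poisson log-likelihood otherwise.
Ties break to the lowest stimulus index and are counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt

import numpy as np

from .codes import (
    Codebook,
    CodeSpec,
    StimulusSpace,
    build_codebook,
    empirical_representation_energy,
)
from .errors import InvalidConfigurationError
from .transform import LinearTransform, apply_transform, make_transform

_DECODE_CHUNK = 2048
_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class ChannelConfig:
    """Noise model for one transmission channel."""

    noise: str = "gaussian"  # gaussian | poisson | poisson_baseline
    sigma2: float | None = None
    r_spont: float | None = None
    input_noise: str = "none"  # none | local | bitflip
    p_shift: float = 0.0
    p_flip: float = 0.0
    bitflip_pipeline: str = "direct"  # direct | nearest

    def __post_init__(self) -> None:
        if self.noise not in ("gaussian", "poisson", "poisson_baseline"):
            raise InvalidConfigurationError(f"unknown noise model {self.noise!r}")
        if self.noise == "gaussian" and self.sigma2 is not None and self.sigma2 <= 0:
            raise InvalidConfigurationError("sigma2 must be positive")
        if self.noise == "poisson_baseline" and (
            self.r_spont is not None and self.r_spont <= 0
        ):
            raise InvalidConfigurationError("r_spont must be positive")
        if self.input_noise not in ("none", "local", "bitflip"):
            raise InvalidConfigurationError(
                f"unknown input noise model {self.input_noise!r}"
            )
        if not (0.0 <= self.p_shift <= 1.0 and 0.0 <= self.p_flip <= 1.0):
            raise InvalidConfigurationError("noise probabilities must lie in [0, 1]")
        if self.bitflip_pipeline not in ("direct", "nearest"):
            raise InvalidConfigurationError(
                f"unknown bitflip pipeline {self.bitflip_pipeline!r}"
            )


@dataclass(frozen=True)
class MonteCarloResult:
    """Decoding-performance estimates from one Monte-Carlo run."""

    pe: float
    pe_se: float
    mse: float
    mse_se: float
    pe_feature: np.ndarray
    confusion: np.ndarray = field(repr=False)
    n_trials: int
    seed: int | None
    n_ties: int
    snr: float | None
    target_energy: float | None
    feature_metric: str = "linear"

    def squared_error_distribution(self) -> tuple[np.ndarray, np.ndarray]:
        """Empirical CDF of squared feature-space errors, from the confusion
        matrix: returns (sorted distinct squared errors, cumulative probs)."""
        m = self.confusion.shape[0]
        K = self.pe_feature.shape[0]
        n = round(m ** (1.0 / K))
        space = StimulusSpace(K, n)
        stimuli = space.stimuli()
        sq = _squared_feature_errors(stimuli, self.feature_metric)
        weights = self.confusion.astype(float).ravel()
        order = np.argsort(sq.ravel())
        vals, w = sq.ravel()[order], weights[order]
        uniq, starts = np.unique(vals, return_index=True)
        sums = np.add.reduceat(w, starts)
        return uniq, np.cumsum(sums) / w.sum()

    def summary(self) -> dict:
        return {
            "pe": self.pe,
            "pe_se": self.pe_se,
            "mse": self.mse,
            "mse_se": self.mse_se,
            "pe_feature": self.pe_feature.tolist(),
            "n_trials": self.n_trials,
            "n_ties": self.n_ties,
            "seed": self.seed,
            "snr": self.snr,
            "target_energy": self.target_energy,
        }


def _squared_feature_errors(stimuli: np.ndarray, metric: str) -> np.ndarray:
    """(M, M) matrix of squared feature-space distances between stimuli."""
    diff = np.abs(stimuli[:, None, :] - stimuli[None, :, :])
    if metric == "circular":
        n = int(stimuli.max()) + 1
        diff = np.minimum(diff, n - diff)
    elif metric != "linear":
        raise ValueError(f"unknown feature metric {metric!r}")
    return (diff.astype(float) ** 2).sum(axis=2)


def transmit(
    codewords: np.ndarray, config: ChannelConfig, rng: np.random.Generator
) -> np.ndarray:
    """Pass (transformed) codewords through the output-noise model."""
    c = np.asarray(codewords, dtype=float)
    if config.noise == "gaussian":
        if config.sigma2 is None:
            raise InvalidConfigurationError("gaussian noise requires sigma2")
        return c + rng.normal(0.0, sqrt(config.sigma2), size=c.shape)
    if (c < 0).any():
        raise InvalidConfigurationError("Poisson rates must be nonnegative")
    if config.noise == "poisson":
        return rng.poisson(c).astype(float)
    if config.r_spont is None:
        raise InvalidConfigurationError("poisson_baseline requires r_spont")
    return rng.poisson(c + config.r_spont).astype(float)


def perturb_input(
    stimuli: np.ndarray,
    space: StimulusSpace,
    config: ChannelConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Local input noise: each feature independently shifts to an adjacent
    value with total probability ``p_shift``.

    Interior values move up or down with probability ``p_shift / 2`` each;
    values at the ends of the range keep total shift probability ``p_shift``
    but move only inward (the outward mass is renormalized onto the inward
    move).
    """
    s = np.asarray(stimuli, dtype=int)
    squeeze = s.ndim == 1
    s = np.atleast_2d(s).copy()
    if config.input_noise != "local" or config.p_shift == 0.0:
        return s[0] if squeeze else s
    n = space.n_values
    move = rng.random(s.shape) < config.p_shift
    step = np.where(rng.random(s.shape) < 0.5, -1, 1)
    step = np.where(s == 0, 1, step)
    step = np.where(s == n - 1, -1, step)
    s[move] += step[move]
    return s[0] if squeeze else s


def _bitflip_bits(
    stimuli: np.ndarray, space: StimulusSpace, p_flip: float, rng: np.random.Generator
) -> np.ndarray:
    """One-hot (pure-code) bit representation of stimuli with i.i.d. bit flips."""
    T = stimuli.shape[0]
    K, n = space.n_features, space.n_values
    bits = np.zeros((T, K * n), dtype=bool)
    cols = stimuli + n * np.arange(K)
    bits[np.arange(T)[:, None], cols] = True
    flips = rng.random(bits.shape) < p_flip
    return bits ^ flips


def _nearest_stimuli(bits: np.ndarray, space: StimulusSpace) -> np.ndarray:
    """Clean corrupted pure-code bits to the nearest valid stimulus.

    Per feature block the nearest one-hot pattern maximizes the bit at the
    chosen value; ties break to the lowest value index.
    """
    T = bits.shape[0]
    K, n = space.n_features, space.n_values
    blocks = bits.reshape(T, K, n)
    return blocks.argmax(axis=2)


def _direct_activity(bits: np.ndarray, codebook: Codebook) -> np.ndarray:
    """Feed corrupted pure-code bits through the conjunctive indicator units.

    Unit ``(A, v)`` is active iff every input bit ``(f, v_f)`` for ``f`` in
    ``A`` is set.  Requires point-tuned units.
    """
    n = codebook.space.n_values
    T = bits.shape[0]
    act = np.ones((T, codebook.n_units), dtype=np.uint8)
    for k, u in enumerate(codebook.units):
        for f, v in zip(u.features, u.values):
            if isinstance(v, tuple):
                raise InvalidConfigurationError(
                    "direct bitflip pipeline requires point-tuned units"
                )
            act[:, k] &= bits[:, f * n + v]
    return act


def ml_decode(
    responses: np.ndarray,
    codewords: np.ndarray,
    config: ChannelConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood decoding of ``responses`` against ``codewords``.

    Returns ``(indices, tie_flags)``.  Under Gaussian noise the ML estimate
    is the codeword at minimum Euclidean distance; under Poisson models the
    log-likelihood ``sum_i r_i log(lam_i) - lam_i`` is maximized, with
    zero-rate dimensions contributing 0 when the count is 0 and -inf
    otherwise.  Ties go to the lowest stimulus index.
    """
    r = np.atleast_2d(np.asarray(responses, dtype=float))
    c = np.asarray(codewords, dtype=float)
    if c.size == 0:
        raise ValueError("codebook is empty")

    if config.noise == "gaussian":
        # squared distance up to the common ||r||^2 term
        scores = -2.0 * r @ c.T + (c**2).sum(axis=1)
        best = scores.argmin(axis=1)
        two = np.partition(scores, 1, axis=1)[:, :2] if c.shape[0] > 1 else None
    else:
        lam = c if config.noise == "poisson" else c + (config.r_spont or 0.0)
        if (lam < 0).any():
            raise InvalidConfigurationError("Poisson rates must be nonnegative")
        with np.errstate(divide="ignore"):
            log_lam = np.where(lam > 0, np.log(np.where(lam > 0, lam, 1.0)), -1e30)
        scores = -(r @ log_lam.T) + lam.sum(axis=1)  # negated log-likelihood
        best = scores.argmin(axis=1)
        two = np.partition(scores, 1, axis=1)[:, :2] if c.shape[0] > 1 else None

    if two is None:
        ties = np.zeros(r.shape[0], dtype=bool)
    else:
        scale = np.maximum(np.abs(two).max(axis=1), 1.0)
        ties = (two[:, 1] - two[:, 0]) <= _TIE_RTOL * scale
    return best, ties


def simulate(
    space: StimulusSpace,
    spec: CodeSpec,
    config: ChannelConfig,
    n_trials: int,
    seed: int | None = None,
    *,
    snr: float | None = None,
    target_energy: float | None = None,
    transform: LinearTransform | None = None,
    codebook: Codebook | None = None,
    feature_metric: str = "linear",
    rng: np.random.Generator | None = None,
) -> MonteCarloResult:
    """Monte-Carlo estimate of decoding performance for one code.

    Stimuli are presented uniformly at random (performance is independent of
    the stimulus distribution by the symmetry of the codes), encoded,
    transformed, transmitted, and ML-decoded.  Returns the overall error rate
    PE with its binomial standard error, the mean squared feature-space error
    (MSE), per-feature error rates, and the full confusion matrix.

    Energy accounting: the code's representation energy ``P`` (under
    ``spec.energy_variant``) is rescaled to ``target_energy`` ``V`` by an
    identity-proportional transform unless an explicit ``transform`` is
    given.  For Gaussian noise ``sigma2 = V / snr``; for Poisson-with-
    baseline noise ``r_spont = V / snr``; pure Poisson noise is parametrized
    by ``V`` alone.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if codebook is None:
        codebook = build_codebook(space, spec)
    M = space.n_stimuli
    K = space.n_features
    words = codebook.words
    p_energy = empirical_representation_energy(codebook, spec.energy_variant)

    if transform is not None:
        V = transform.column_norm**2 * p_energy
        if target_energy is not None and not np.isclose(V, target_energy):
            raise InvalidConfigurationError(
                "explicit transform is inconsistent with target_energy"
            )
    else:
        V = p_energy if target_energy is None else float(target_energy)

    config = _resolve_noise(config, V, snr)

    if transform is None:
        transform = make_transform(
            codebook.n_units, codebook.n_units, V, p_energy, "identity_scaled"
        )
    clean = apply_transform(transform, words)

    if rng is None:
        rng = np.random.default_rng(seed)
    stimuli = space.stimuli()
    confusion = np.zeros((M, M), dtype=np.int64)
    n_ties = 0

    for start in range(0, n_trials, _DECODE_CHUNK):
        T = min(_DECODE_CHUNK, n_trials - start)
        true_idx = rng.integers(0, M, size=T)
        act_idx, activity = _input_stage(stimuli, true_idx, space, codebook, config, rng)
        if activity is None:
            sent = clean[act_idx]
        else:
            sent = apply_transform(transform, activity)
        noisy = transmit(sent, config, rng)
        decoded, ties = ml_decode(noisy, clean, config)
        n_ties += int(ties.sum())
        np.add.at(confusion, (true_idx, decoded), 1)

    return _result_from_confusion(
        space, confusion, n_trials, seed, n_ties, snr, V, feature_metric
    )


def _resolve_noise(config: ChannelConfig, V: float, snr: float | None) -> ChannelConfig:
    """Fill in sigma2 / r_spont from the population SNR convention."""
    from dataclasses import replace

    if config.noise == "gaussian" and config.sigma2 is None:
        if snr is None:
            raise InvalidConfigurationError("gaussian noise requires snr or sigma2")
        return replace(config, sigma2=V / snr)
    if config.noise == "poisson_baseline" and config.r_spont is None:
        if snr is None:
            raise InvalidConfigurationError(
                "poisson_baseline noise requires snr or r_spont"
            )
        return replace(config, r_spont=V / snr)
    return config


def _input_stage(
    stimuli: np.ndarray,
    true_idx: np.ndarray,
    space: StimulusSpace,
    codebook: Codebook,
    config: ChannelConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Apply input noise; return (effective stimulus indices, activity or None).

    When the activity pattern is a valid codeword row the row index is
    returned (second element None); the direct bitflip pipeline can produce
    arbitrary activity patterns, returned explicitly.
    """
    if config.input_noise == "none":
        return true_idx, None
    if config.input_noise == "local":
        perturbed = perturb_input(stimuli[true_idx], space, config, rng)
        return _stimulus_indices(space, perturbed), None
    bits = _bitflip_bits(stimuli[true_idx], space, config.p_flip, rng)
    if config.bitflip_pipeline == "nearest":
        cleaned = _nearest_stimuli(bits, space)
        return _stimulus_indices(space, cleaned), None
    return true_idx, _direct_activity(bits, codebook)


def _stimulus_indices(space: StimulusSpace, stimuli: np.ndarray) -> np.ndarray:
    n, K = space.n_values, space.n_features
    weights = n ** np.arange(K - 1, -1, -1)
    return np.asarray(stimuli, dtype=np.int64) @ weights


def _result_from_confusion(
    space: StimulusSpace,
    confusion: np.ndarray,
    n_trials: int,
    seed: int | None,
    n_ties: int,
    snr: float | None,
    target_energy: float | None,
    feature_metric: str,
) -> MonteCarloResult:
    stimuli = space.stimuli()
    total = confusion.sum()
    correct = np.trace(confusion)
    pe = 1.0 - correct / total
    pe_se = sqrt(max(pe * (1.0 - pe), 0.0) / total)

    sq = _squared_feature_errors(stimuli, feature_metric)
    weights = confusion.astype(float)
    per_trial_sq = (weights * sq).sum() / total
    second_moment = (weights * sq**2).sum() / total
    mse_se = sqrt(max(second_moment - per_trial_sq**2, 0.0) / total)

    K = space.n_features
    pe_feature = np.empty(K)
    for f in range(K):
        mismatch = stimuli[:, f][:, None] != stimuli[:, f][None, :]
        pe_feature[f] = (weights * mismatch).sum() / total

    return MonteCarloResult(
        pe=float(pe),
        pe_se=float(pe_se),
        mse=float(per_trial_sq),
        mse_se=float(mse_se),
        pe_feature=pe_feature,
        confusion=confusion,
        n_trials=n_trials,
        seed=seed,
        n_ties=n_ties,
        snr=snr,
        target_energy=target_energy,
        feature_metric=feature_metric,
    )
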