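"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from mixedcodes import CodeSpec, StimulusSpace, build_codebook


@pytest.fixture(scope="session")
def small_spaces():
    """All (K, n) pairs with K <= 4, n <= 4 used for exhaustive checks."""
    return [StimulusSpace(K, n) for K in (1, 2, 3, 4) for n in (2, 3, 4)]


def brute_force_distances(space, order):
    """(M, M) Euclidean distance matrix computed from scratch.

    Independent of the library's codeword machinery: units are enumerated
    directly as (feature subset, value combination) indicator products.
    """
    K, n = space.n_features, space.n_values
    stimuli = list(itertools.product(range(n), repeat=K))
    subsets = list(itertools.combinations(range(K), order))
    words = []
    for s in stimuli:
        row = []
        for A in subsets:
            for vals in itertools.product(range(n), repeat=order):
                row.append(1.0 if all(s[f] == v for f, v in zip(A, vals)) else 0.0)
        words.append(row)
    w = np.asarray(words)
    diff = w[:, None, :] - w[None, :, :]
    return np.sqrt((diff**2).sum(axis=2)), np.asarray(stimuli)


def blahut_arimoto_point(M, slope, n_iter=500):
    """One point on the rate-distortion curve of a uniform M-ary source
    under symbol-error (Hamming) distortion, via Blahut-Arimoto.

    ``slope < 0`` is the Lagrange parameter trading rate against
    distortion; returns the (distortion, rate-in-bits) point it selects.
    """
    p = np.full(M, 1.0 / M)
    d = 1.0 - np.eye(M)
    a = np.exp(slope * d)
    q = np.full(M, 1.0 / M)
    for _ in range(n_iter):
        denom = a @ q
        q = q * (p / denom) @ a
        q /= q.sum()
    denom = a @ q
    w = a * q[None, :] / denom[:, None]  # conditional p(y|x)
    joint = p[:, None] * w
    distortion = float((joint * d).sum())
    py = joint.sum(axis=0)
    mask = joint > 0
    rate = float(
        (joint[mask] * np.log2(joint[mask] / (p[:, None] * py[None, :])[mask])).sum()
    )
    return distortion, rate


@pytest.fixture(scope="session")
def worked_space():
    return StimulusSpace(3, 2)


@pytest.fixture(scope="session")
def k3n5_codebooks():
    space = StimulusSpace(3, 5)
    return {O: build_codebook(space, CodeSpec(O)) for O in (1, 2, 3)}
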