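"""Linear transforms that rescale, rotate, or embed codewords.

A transform ``beta`` maps the ``D``-dimensional binary codeword space into an
``N``-dimensional response space (``N >= D``) subject to four constraints:

1. ``N >= D`` — the embedding cannot lose dimensions;
2. ``pinv(beta) @ beta = I`` — the map is invertible on the code subspace;
3. every column of ``beta`` has the same vector length ``H``;
4. cross-products of distinct columns average to zero.

Under these constraints the transform scales every pairwise codeword distance
by exactly ``H`` and sets the representation energy to ``V = H**2 * P``, where
``P`` is the energy of the untransformed code.  Choosing ``H = sqrt(V / P)``
therefore gives codes of different orders the same energy ``V`` without
altering their relative geometry — the ratio ``delta**2 / V`` equals
``Delta**2 / P = 2O/K`` for every valid transform.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np

from .errors import EmbeddingError

STYLES = ("identity_scaled", "random_rotation", "random_embedding", "gaussian")


@dataclass(frozen=True)
class LinearTransform:
    """An ``(N, D)`` matrix with uniform column length ``H``."""

    matrix: np.ndarray
    column_norm: float
    target_energy: float
    style: str
    seed: int | None = None

    @property
    def n_out(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_in(self) -> int:
        return self.matrix.shape[1]


def make_transform(
    n_dims: int,
    n_out: int,
    target_energy: float,
    source_energy: float,
    style: str = "identity_scaled",
    seed: int | None = None,
) -> LinearTransform:
    """Build a transform from ``n_dims`` codeword dimensions to ``n_out``
    response dimensions with representation energy ``target_energy``.

    ``source_energy`` is the energy ``P`` of the untransformed code; the
    column length is ``H = sqrt(target_energy / source_energy)``.

    Styles: ``identity_scaled`` (H times the identity, padded with zero rows;
    the default used in simulations), ``random_rotation`` (random orthogonal
    frame, requires ``n_out == n_dims``), ``random_embedding`` (random
    orthonormal frame into a larger space), and ``gaussian`` (i.i.d. normal
    entries with columns rescaled to length H exactly — constraint 2 then
    holds only approximately at finite N).
    """
    if n_out < n_dims:
        raise EmbeddingError(f"n_out ({n_out}) must be >= n_dims ({n_dims})")
    if target_energy <= 0 or source_energy <= 0:
        raise ValueError("energies must be positive")
    if style not in STYLES:
        raise ValueError(f"style must be one of {STYLES}")
    if style == "random_rotation" and n_out != n_dims:
        raise ValueError("random_rotation requires n_out == n_dims")

    H = sqrt(target_energy / source_energy)
    rng = np.random.default_rng(seed)

    if style == "identity_scaled":
        beta = np.zeros((n_out, n_dims))
        beta[:n_dims, :n_dims] = np.eye(n_dims)
    elif style in ("random_rotation", "random_embedding"):
        g = rng.standard_normal((n_out, n_dims))
        q, r = np.linalg.qr(g)
        # fix the sign convention so the frame is a deterministic function of g
        q *= np.sign(np.diag(r))
        beta = q
    else:  # gaussian
        beta = rng.standard_normal((n_out, n_dims)) / sqrt(n_out)
        beta /= np.linalg.norm(beta, axis=0, keepdims=True)

    return LinearTransform(
        matrix=H * beta,
        column_norm=H,
        target_energy=target_energy,
        style=style,
        seed=seed,
    )


def apply_transform(transform: LinearTransform, words: np.ndarray) -> np.ndarray:
    """Transformed codeword matrix ``words @ beta.T``.

    ``words`` has shape ``(M, D)``; the result has shape ``(M, N)``.  Every
    pairwise distance is scaled by ``H`` and every squared codeword norm by
    ``H**2`` (exactly for orthonormal styles, approximately for ``gaussian``).
    """
    words = np.asarray(words, dtype=float)
    if words.shape[1] != transform.n_in:
        raise ValueError(
            f"codebook width {words.shape[1]} does not match transform "
            f"input dimension {transform.n_in}"
        )
    return words @ transform.matrix.T


def verify_transform(
    transform: LinearTransform,
    source_energy: float | None = None,
    rtol: float = 1e-8,
) -> dict:
    """Check the four transform constraints; return pass/fail with residuals.

    Constraint 2 (pseudoinverse identity) and 3 (uniform column length) are
    deterministic and checked at relative tolerance ``rtol``.  Constraint 4
    is a sampled property: the mean off-diagonal entry of ``beta.T @ beta``
    must be within three standard errors of zero.  If ``source_energy`` is
    given, the energy law ``H**2 * P == V`` is checked as well.
    """
    beta = transform.matrix
    H = transform.column_norm
    report: dict[str, dict] = {}

    n_out, n_in = beta.shape
    report["n_out_ge_n_in"] = {"passed": n_out >= n_in, "residual": float(n_in - n_out)}

    gram = beta.T @ beta
    ident_resid = float(np.abs(np.linalg.pinv(beta) @ beta - np.eye(n_in)).max())
    report["pseudoinverse_identity"] = {
        "passed": ident_resid <= rtol * max(1.0, H**2),
        "residual": ident_resid,
    }

    norms = np.linalg.norm(beta, axis=0)
    norm_resid = float(np.abs(norms - H).max())
    report["uniform_column_norm"] = {
        "passed": norm_resid <= rtol * max(1.0, H),
        "residual": norm_resid,
    }

    off = gram[~np.eye(n_in, dtype=bool)]
    if off.size:
        mean = float(off.mean())
        se = float(off.std(ddof=1) / np.sqrt(off.size)) if off.size > 1 else 0.0
        tol = max(3.0 * se, rtol * H**2)
        report["zero_mean_cross_products"] = {
            "passed": abs(mean) <= tol,
            "residual": mean,
        }
    else:
        report["zero_mean_cross_products"] = {"passed": True, "residual": 0.0}

    if source_energy is not None:
        resid = float(abs(H**2 * source_energy - transform.target_energy))
        report["energy_law"] = {
            "passed": resid <= rtol * max(1.0, transform.target_energy),
            "residual": resid,
        }

    report["all_passed"] = all(
        v["passed"] for k, v in report.items() if isinstance(v, dict)
    )
    return report
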