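"""Per-variant priors and conditional probability paths.

Four interchangeable flow formulations for categorical modalities:

* ``CONTINUOUS`` — ordinary flow matching in R^D from a Gaussian prior to
  one-hot vertices; the discreteness of the data is ignored.
* ``SIMPLEX`` — linear flow constrained to the probability simplex, from the
  uniform simplex prior to one-hot vertices.
* ``DIRICHLET`` — Dirichlet conditional paths Dir(1 + beta(t) * e_{x1}) with
  the conditional vector field built from the derivative of the regularized
  incomplete beta function.
* ``CTMC`` — discrete-state flow: every token starts in a MASK state and
  jumps to its data class; the time-t conditional law is a mixture
  (1 - t) * delta_mask + t * delta_{x1}.

Positions always use ``EUCLIDEAN``: a centered Gaussian prior with a linear
interpolant. All paths are sampleable simulation-free at any t in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Union

import numpy as np
from scipy.special import betainc
from scipy.stats import beta as _beta_dist

__all__ = [
    "VariantId",
    "ModalityState",
    "PathSample",
    "CATEGORICAL_VARIANTS",
    "sample_prior",
    "sample_conditional_path",
    "conditional_vector_field",
    "beta_schedule",
    "beta_schedule_derivative",
    "dirichlet_coefficient",
    "project_to_simplex",
]

BETA_MAX_DEFAULT = 100.0
BETA_EPS = 1e-3
# ceiling on the Dirichlet flow coefficient; keeps Euler steps finite near
# simplex vertices where the beta density underflows
DIRICHLET_C_MAX = 500.0


class VariantId(str, Enum):
    CONTINUOUS = "continuous"
    SIMPLEX = "simplex"
    DIRICHLET = "dirichlet"
    CTMC = "ctmc"
    EUCLIDEAN = "euclidean"


CATEGORICAL_VARIANTS = (
    VariantId.CONTINUOUS,
    VariantId.SIMPLEX,
    VariantId.DIRICHLET,
    VariantId.CTMC,
)


@dataclass
class ModalityState:
    """Time-t state of one modality: indices (CTMC) xor vectors (continuous)."""

    indices: Optional[np.ndarray] = None  # (n,) int
    vectors: Optional[np.ndarray] = None  # (n, D) float

    def __post_init__(self) -> None:
        if (self.indices is None) == (self.vectors is None):
            raise ValueError("exactly one of indices/vectors must be populated")
        if self.indices is not None:
            self.indices = np.asarray(self.indices, dtype=int).reshape(-1)
        else:
            self.vectors = np.asarray(self.vectors, dtype=float)
            if self.vectors.ndim != 2:
                raise ValueError("vectors must be a 2-D (n, D) array")

    @property
    def n(self) -> int:
        return self.indices.shape[0] if self.indices is not None else self.vectors.shape[0]

    def copy(self) -> "ModalityState":
        if self.indices is not None:
            return ModalityState(indices=self.indices.copy())
        return ModalityState(vectors=self.vectors.copy())


@dataclass
class PathSample:
    t: float
    x_t: ModalityState
    x0: ModalityState
    x1: ModalityState


def as_rng(seed: Union[int, np.random.Generator, None]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def onehot_rows(indices: np.ndarray, size: int) -> np.ndarray:
    indices = np.asarray(indices, dtype=int)
    if np.any((indices < 0) | (indices >= size)):
        raise ValueError("index out of range for one-hot encoding")
    out = np.zeros((indices.shape[0], size), dtype=float)
    out[np.arange(indices.shape[0]), indices] = 1.0
    return out


def _x1_indices(x1: ModalityState, size: int) -> np.ndarray:
    """Endpoint as class indices; vectors must be exactly one-hot."""
    if x1.indices is not None:
        idx = x1.indices
    else:
        v = x1.vectors
        idx = np.argmax(v, axis=1)
        if not np.allclose(v, onehot_rows(idx, v.shape[1])):
            raise ValueError("data endpoint must be one-hot")
    if np.any((idx < 0) | (idx >= size)):
        raise ValueError("endpoint index out of vocabulary range")
    return idx


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------


def sample_prior(
    variant: VariantId,
    n: int,
    size: int,
    rng: Union[int, np.random.Generator, None] = None,
) -> ModalityState:
    """Draw n i.i.d. prior states for one modality.

    ``size`` is the number of real classes D (categorical variants) or the
    spatial dimension (EUCLIDEAN). The CTMC prior is deterministic: every
    token starts in the MASK state at index D.
    """
    variant = VariantId(variant)
    rng = as_rng(rng)
    if variant in (VariantId.CONTINUOUS,):
        if size < 2:
            raise ValueError("categorical variants need at least 2 classes")
        return ModalityState(vectors=rng.standard_normal((n, size)))
    if variant in (VariantId.SIMPLEX, VariantId.DIRICHLET):
        if size < 2:
            raise ValueError("categorical variants need at least 2 classes")
        return ModalityState(vectors=rng.dirichlet(np.ones(size), size=n))
    if variant is VariantId.CTMC:
        if size < 2:
            raise ValueError("categorical variants need at least 2 classes")
        return ModalityState(indices=np.full(n, size, dtype=int))
    if variant is VariantId.EUCLIDEAN:
        x = rng.standard_normal((n, size))
        return ModalityState(vectors=x - x.mean(axis=0, keepdims=True))
    raise ValueError(f"unknown variant {variant!r}")


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------


def beta_schedule(t: float, beta_max: float = BETA_MAX_DEFAULT, eps: float = BETA_EPS) -> float:
    """Dirichlet concentration schedule: monotone, beta(0)=0, beta(1)=beta_max."""
    t = float(t)
    return float(min(beta_max, beta_max * t / (1.0 - t + eps)))


def beta_schedule_derivative(
    t: float, beta_max: float = BETA_MAX_DEFAULT, eps: float = BETA_EPS
) -> float:
    t = float(t)
    if beta_max * t / (1.0 - t + eps) >= beta_max:
        return 0.0
    return float(beta_max * (1.0 + eps) / (1.0 - t + eps) ** 2)


# ---------------------------------------------------------------------------
# conditional paths
# ---------------------------------------------------------------------------


def sample_conditional_path(
    variant: VariantId,
    x0: Optional[ModalityState],
    x1: ModalityState,
    t: float,
    rng: Union[int, np.random.Generator, None] = None,
    beta_max: float = BETA_MAX_DEFAULT,
    mask_index: Optional[int] = None,
) -> ModalityState:
    """Sample x_t ~ p_t(. | x0, x1) for one modality, simulation-free.

    ``x0`` is required for the linear-interpolant variants (CONTINUOUS,
    SIMPLEX, EUCLIDEAN) and ignored by CTMC and DIRICHLET, whose conditional
    laws depend only on x1. For CTMC the mask class is taken from ``x0``
    (the mask prior) or from ``mask_index``.
    """
    variant = VariantId(variant)
    t = float(t)
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"t={t} outside [0, 1]")
    rng = as_rng(rng)

    if variant in (VariantId.CONTINUOUS, VariantId.SIMPLEX, VariantId.EUCLIDEAN):
        if x0 is None or x0.vectors is None:
            raise ValueError(f"{variant.value} path requires a vector-valued x0")
        if variant is VariantId.EUCLIDEAN:
            target = np.asarray(x1.vectors, dtype=float)
        else:
            idx = _x1_indices(x1, x0.vectors.shape[1])
            target = onehot_rows(idx, x0.vectors.shape[1])
        return ModalityState(vectors=(1.0 - t) * x0.vectors + t * target)

    if variant is VariantId.CTMC:
        if mask_index is None:
            if x0 is not None and x0.indices is not None:
                mask_index = int(x0.indices[0])
            else:
                raise ValueError("CTMC path needs mask_index (or the mask prior as x0)")
        idx1 = _x1_indices(x1, mask_index)
        keep = rng.random(idx1.shape[0]) < t
        out = np.where(keep, idx1, mask_index)
        return ModalityState(indices=out)

    if variant is VariantId.DIRICHLET:
        if x1.vectors is not None:
            size = x1.vectors.shape[1]
        else:
            if x0 is None or x0.vectors is None:
                raise ValueError("DIRICHLET needs vocabulary size from x0 or one-hot x1")
            size = x0.vectors.shape[1]
        idx1 = _x1_indices(x1, size)
        beta_t = beta_schedule(t, beta_max)
        alpha = np.ones((idx1.shape[0], size))
        alpha[np.arange(idx1.shape[0]), idx1] += beta_t
        draws = np.stack([rng.dirichlet(a) for a in alpha])
        return ModalityState(vectors=draws)

    raise ValueError(f"unknown variant {variant!r}")


# ---------------------------------------------------------------------------
# vector fields
# ---------------------------------------------------------------------------


def dirichlet_coefficient(
    x_i: np.ndarray,
    t: float,
    n_classes: int,
    beta_max: float = BETA_MAX_DEFAULT,
) -> np.ndarray:
    """Scalar coefficient C(x_i, t) of the Dirichlet conditional flow.

    Derived from conservation of the Beta(1 + beta(t), D - 1) marginal CDF
    along trajectories:

        C = -beta'(t) * d/d_beta I_{x_i}(1 + beta, D - 1)
            / [ f_Beta(x_i; 1 + beta, D - 1) * (1 - x_i) ]

    with I the regularized incomplete beta function. The beta-derivative is
    evaluated by central finite differences; C is clamped to
    [0, DIRICHLET_C_MAX] for numerical safety near the simplex vertices.
    """
    x_i = np.asarray(x_i, dtype=float)
    b = beta_schedule(t, beta_max)
    b_dot = beta_schedule_derivative(t, beta_max)
    if b_dot == 0.0:
        return np.zeros_like(x_i)
    a, bb = 1.0 + b, float(n_classes - 1)
    h = 1e-4 * (1.0 + b)
    xi = np.clip(x_i, 1e-12, 1.0 - 1e-12)
    dI_db = (betainc(a + h, bb, xi) - betainc(a - h, bb, xi)) / (2.0 * h)
    dens = _beta_dist.pdf(xi, a, bb) * (1.0 - xi)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = -b_dot * dI_db / dens
    c = np.where(np.isfinite(c), c, DIRICHLET_C_MAX)
    return np.clip(c, 0.0, DIRICHLET_C_MAX)


def conditional_vector_field(
    variant: VariantId,
    x_t: ModalityState,
    x1_hat: np.ndarray,
    t: float,
    beta_max: float = BETA_MAX_DEFAULT,
) -> np.ndarray:
    """Velocity field at (x_t, t) given the denoiser's endpoint estimate.

    ``x1_hat`` is an (n, D) array: a point estimate for CONTINUOUS, SIMPLEX
    and EUCLIDEAN, or a per-row class distribution p_hat(x1 = i) for
    DIRICHLET (where the field is the p_hat-weighted mixture of conditional
    fields, tangent to the simplex).
    """
    variant = VariantId(variant)
    t = float(t)
    if t >= 1.0:
        raise ValueError("vector field is singular at t >= 1")
    if x_t.vectors is None:
        raise ValueError("vector field requires a vector-valued state (not CTMC)")
    x = x_t.vectors
    x1_hat = np.asarray(x1_hat, dtype=float)
    if x1_hat.shape != x.shape:
        raise ValueError(f"x1_hat shape {x1_hat.shape} != state shape {x.shape}")

    if variant in (VariantId.CONTINUOUS, VariantId.SIMPLEX, VariantId.EUCLIDEAN):
        return (x1_hat - x) / (1.0 - t)

    if variant is VariantId.DIRICHLET:
        n_classes = x.shape[1]
        c = dirichlet_coefficient(x, t, n_classes, beta_max)  # (n, D): C(x_i, t)
        w = x1_hat * c  # p_hat_i * C_i
        # sum_i p_i C_i (e_i - x) = w - x * sum_i w_i
        return w - x * w.sum(axis=1, keepdims=True)

    raise ValueError(f"no continuous vector field for variant {variant!r}")


def project_to_simplex(v: np.ndarray, tol: float = 0.0) -> np.ndarray:
    """Clip tiny negatives and renormalize rows to sum to 1."""
    v = np.clip(v, tol, None)
    s = v.sum(axis=1, keepdims=True)
    s[s == 0.0] = 1.0
    return v / s
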