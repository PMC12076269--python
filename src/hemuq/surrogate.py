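"""Non-intrusive polynomial chaos expansion (NIPCE) surrogate of device MIH.

Evaluating the MIH volume integral on a large flow field for every one of
10,000 posterior parameter draws is wasteful; a polynomial surrogate makes
the propagation essentially free.  The construction is standard NIPCE:

1. each uncertain input (a truncated log-normal posterior fit) is
   standardised to a germ z in [-1, 1] by an affine map of its truncated
   support, so the surrogate is a polynomial in the raw parameters —
   which is the space where the damage-model response is smooth.  Because
   the coefficients are found by regression (not spectral projection), the
   fitted polynomial is independent of the basis weight; the Legendre
   basis is used for its conditioning on [-1, 1];
2. a training design combines Latin-hypercube samples of the truncated
   input laws (default 200) with the 2^d corner combinations of the
   truncation bounds;
3. MIH is evaluated directly on the design and the total-degree <= order
   (default 4) expansion is fitted by ordinary least squares.

The surrogate is validated against the direct volume integral on fresh
draws from the same input distributions.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numpy.polynomial import legendre
from scipy.stats import qmc

from .fields import StressVolumeField, mih
from .model import LogNormalFit
from .powerlaw import PowerLawParams

__all__ = [
    "TrainingDesign",
    "SurrogateModel",
    "build_training_design",
    "train_surrogate",
    "evaluate_surrogate",
    "validate_surrogate",
    "train_mih_surrogate",
    "sample_truncated",
    "total_degree_indices",
]


def total_degree_indices(d: int, order: int) -> list[tuple[int, ...]]:
    """All d-tuples of non-negative degrees with sum <= order.

    Count equals C(order + d, d) — e.g. 15 terms for d = 2, order = 4.
    """
    return [
        idx
        for idx in itertools.product(range(order + 1), repeat=d)
        if sum(idx) <= order
    ]


def _trunc_cdf(fit: LogNormalFit, x: np.ndarray) -> np.ndarray:
    dist = fit.frozen()
    p_lo, p_hi = dist.cdf(fit.trunc_low), dist.cdf(fit.trunc_high)
    return (dist.cdf(x) - p_lo) / (p_hi - p_lo)


def _trunc_ppf(fit: LogNormalFit, u: np.ndarray) -> np.ndarray:
    dist = fit.frozen()
    p_lo, p_hi = dist.cdf(fit.trunc_low), dist.cdf(fit.trunc_high)
    return dist.ppf(p_lo + np.asarray(u) * (p_hi - p_lo))


def sample_truncated(
    fits: dict[str, LogNormalFit], n: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Draw n samples per parameter from the fitted law, resampling any draw
    outside the truncation bounds (the draws are independent across
    parameters)."""
    out = {}
    for name, fit in fits.items():
        dist = fit.frozen()
        x = dist.rvs(size=n, random_state=rng)
        bad = (x < fit.trunc_low) | (x > fit.trunc_high)
        while np.any(bad):
            x[bad] = dist.rvs(size=int(bad.sum()), random_state=rng)
            bad = (x < fit.trunc_low) | (x > fit.trunc_high)
        out[name] = x
    return out


@dataclass
class TrainingDesign:
    """LHS-plus-corners design over truncated log-normal inputs.

    ``points`` has shape ``(n_lhs + 2^d, d)`` in raw parameter space;
    ``lhs_u`` holds the underlying (0,1) Latin-hypercube coordinates of the
    first ``n_lhs`` rows (one point per equal-probability stratum per
    marginal).
    """

    names: tuple[str, ...]
    fits: dict[str, LogNormalFit]
    points: np.ndarray
    lhs_u: np.ndarray
    n_lhs: int
    seed: int

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def d(self) -> int:
        return len(self.names)


def build_training_design(
    fits: dict[str, LogNormalFit], n_lhs: int = 200, seed: int = 0
) -> TrainingDesign:
    """Latin-hypercube design mapped through the truncated inverse CDFs,
    augmented with all 2^d combinations of the truncation bounds."""
    names = tuple(fits)
    d = len(names)
    if d < 1:
        raise ValueError("need at least one input distribution")
    if n_lhs < d:
        raise ValueError("n_lhs must be >= number of parameters")
    sampler = qmc.LatinHypercube(d=d, seed=seed)
    u = sampler.random(n_lhs)
    pts = np.column_stack(
        [_trunc_ppf(fits[name], u[:, j]) for j, name in enumerate(names)]
    )
    corners = np.array(
        list(
            itertools.product(
                *[(fits[name].trunc_low, fits[name].trunc_high) for name in names]
            )
        )
    )
    return TrainingDesign(
        names=names,
        fits=dict(fits),
        points=np.vstack([pts, corners]),
        lhs_u=u,
        n_lhs=n_lhs,
        seed=seed,
    )


@dataclass
class SurrogateModel:
    """Trained polynomial-chaos map from free parameters to MIH.

    ``coefficients[k]`` multiplies the product-Legendre term with degrees
    ``indices[k]`` on the germ z in [-1, 1]^d obtained by affinely
    standardising each input over its truncation bounds.  ``fixed_params``
    carries any
    power-law parameters held constant (e.g. the optimised C) so the full
    parameter triple can be reconstructed downstream.
    """

    names: tuple[str, ...]
    fits: dict[str, LogNormalFit]
    order: int
    indices: list[tuple[int, ...]]
    coefficients: np.ndarray
    condition_label: str = ""
    fixed_params: dict[str, float] = field(default_factory=dict)
    validation: dict = field(default_factory=dict)

    @property
    def d(self) -> int:
        return len(self.names)

    def to_germ(self, points: np.ndarray, warn_extrapolation: bool = True
                ) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        z = np.empty_like(points)
        outside = False
        for j, name in enumerate(self.names):
            fit = self.fits[name]
            x = points[:, j]
            if np.any((x < fit.trunc_low) | (x > fit.trunc_high)):
                outside = True
            z[:, j] = (
                2.0 * (x - fit.trunc_low) / (fit.trunc_high - fit.trunc_low) - 1.0
            )
        if outside and warn_extrapolation:
            warnings.warn(
                "surrogate evaluated outside its truncation bounds "
                "(extrapolation)", stacklevel=2
            )
        return z


def _design_matrix(z: np.ndarray, indices: list[tuple[int, ...]]) -> np.ndarray:
    n, d = z.shape
    order = max(max(idx) for idx in indices)
    # per-dimension Legendre Vandermonde, shape (n, order+1)
    V = [legendre.legvander(z[:, j], order) for j in range(d)]
    cols = np.empty((n, len(indices)))
    for k, idx in enumerate(indices):
        col = np.ones(n)
        for j, deg in enumerate(idx):
            if deg:
                col = col * V[j][:, deg]
        cols[:, k] = col
    return cols


def train_surrogate(
    design: TrainingDesign, responses: np.ndarray, order: int = 4,
    condition_label: str = "", fixed_params: Optional[dict] = None,
) -> SurrogateModel:
    """Fit the Legendre expansion coefficients by ordinary least squares."""
    responses = np.asarray(responses, dtype=float).ravel()
    if responses.shape[0] != design.n_points:
        raise ValueError("one response per design point required")
    if not np.all(np.isfinite(responses)):
        raise ValueError("responses must be finite")
    if order < 1:
        raise ValueError("order must be >= 1")
    indices = total_degree_indices(design.d, order)
    if design.n_points < len(indices):
        raise ValueError(
            f"design has {design.n_points} points but the order-{order} basis "
            f"has {len(indices)} terms"
        )
    model = SurrogateModel(
        names=design.names,
        fits=design.fits,
        order=order,
        indices=indices,
        coefficients=np.zeros(len(indices)),
        condition_label=condition_label,
        fixed_params=dict(fixed_params or {}),
    )
    z = model.to_germ(design.points, warn_extrapolation=False)
    Phi = _design_matrix(z, indices)
    rank = np.linalg.matrix_rank(Phi)
    if rank < len(indices):
        raise ValueError(
            f"rank-deficient training design: rank {rank} < {len(indices)} "
            "basis terms; add design points or lower the order"
        )
    coeffs, *_ = np.linalg.lstsq(Phi, responses, rcond=None)
    model.coefficients = coeffs
    fitted = Phi @ coeffs
    denom = np.maximum(np.abs(responses), np.finfo(float).tiny)
    model.validation["train_max_rel_error"] = float(
        np.max(np.abs(fitted - responses) / denom)
    )
    return model


def evaluate_surrogate(model: SurrogateModel, params) -> np.ndarray | float:
    """Evaluate the surrogate at one point (dict or 1-d) or a batch (2-d).

    Points outside the truncation bounds are evaluated anyway but flagged
    with an extrapolation warning.
    """
    if isinstance(params, dict):
        pts = np.array([[params[name] for name in model.names]])
        scalar = True
    else:
        pts = np.asarray(params, dtype=float)
        scalar = pts.ndim == 1
        pts = np.atleast_2d(pts)
    z = model.to_germ(pts)
    out = _design_matrix(z, model.indices) @ model.coefficients
    return float(out[0]) if scalar else out


def validate_surrogate(
    model: SurrogateModel,
    field_: StressVolumeField,
    n_test: int = 50,
    seed: int = 0,
) -> tuple[float, float]:
    """Max and mean relative surrogate error versus the direct MIH integral
    on fresh seeded draws from the input distributions."""
    rng = np.random.default_rng(seed)
    draws = sample_truncated(model.fits, n_test, rng)
    pts = np.column_stack([draws[name] for name in model.names])
    approx = evaluate_surrogate(model, pts)
    exact = np.array(
        [mih(field_, _assemble_params(model, pts[i])) for i in range(n_test)]
    )
    rel = np.abs(approx - exact) / np.abs(exact)
    model.validation["max_rel_error"] = float(rel.max())
    model.validation["mean_rel_error"] = float(rel.mean())
    model.validation["n_test"] = int(n_test)
    return float(rel.max()), float(rel.mean())


def _assemble_params(model: SurrogateModel, point: np.ndarray) -> PowerLawParams:
    vals = dict(model.fixed_params)
    vals.update({name: float(x) for name, x in zip(model.names, point)})
    return PowerLawParams(
        c_coeff=vals["C"], alpha=vals["alpha"], beta=vals["beta"]
    )


def train_mih_surrogate(
    fits: dict[str, LogNormalFit],
    field_: StressVolumeField,
    fixed_params: Optional[dict] = None,
    order: int = 4,
    n_lhs: int = 200,
    seed: int = 0,
    n_test: int = 50,
) -> SurrogateModel:
    """End-to-end: design, direct MIH responses, training and validation
    for one flow condition."""
    design = build_training_design(fits, n_lhs=n_lhs, seed=seed)
    fixed = dict(fixed_params or {})
    responses = np.empty(design.n_points)
    for i in range(design.n_points):
        vals = dict(fixed)
        vals.update(
            {name: float(x) for name, x in zip(design.names, design.points[i])}
        )
        params = PowerLawParams(vals["C"], vals["alpha"], vals["beta"])
        responses[i] = mih(field_, params)
    model = train_surrogate(
        design, responses, order=order,
        condition_label=field_.condition_label, fixed_params=fixed,
    )
    validate_surrogate(model, field_, n_test=n_test, seed=seed + 1)
    return model
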