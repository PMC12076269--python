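"""Synthetic calibration data and device-field fixtures with known truth.

Two generators live here:

* :func:`generate_couette_dataset` emulates a Couette shearing-device
  calibration campaign — a grid of shear stresses (default spanning
  50–320 Pa) and exposure times (default 0.039–1.48 s) with replicated HI
  measurements produced by the power-law model plus configurable noise.
  Because the generating parameters are known, every downstream stage
  (grid search, MCMC recovery, C-optimisation) can be validated against
  ground truth.

* :func:`generate_stress_volume_field` and
  :func:`generate_velocity_gradient_field` build discretised device-domain
  fixtures (per-cell scalar shear stress or velocity-gradient tensor, plus
  volumes and a flow rate) that stand in for CFD flow solutions of a
  centrifugal blood pump.  Only the (stress, volume, Q) histogram matters
  for the MIH volume integral, so no geometry or adjacency is generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datasets import ShearDataset, ShearRecord
from .fields import StressVolumeField, VelocityGradientField
from .powerlaw import REFERENCE_PARAMS, PowerLawParams, predict_hi

__all__ = [
    "NoiseSpec",
    "CouetteDesign",
    "FieldSpec",
    "GradientFieldSpec",
    "generate_couette_dataset",
    "generate_stress_volume_field",
    "generate_velocity_gradient_field",
    "default_condition_specs",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model for synthetic HI observations.

    ``kind`` is one of ``"none"``, ``"student_t"`` (scale ``sigma``, dof
    ``nu``) or ``"normal"`` (scale ``sigma``).  Draws that would make HI
    negative are resampled, i.e. the nominal law is slightly truncated at
    the physical bound HI >= 0.
    """

    kind: str = "student_t"
    sigma: float = 0.1
    nu: float = 30.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "student_t", "normal"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.kind == "student_t" and self.nu <= 0:
            raise ValueError("nu must be > 0 for student_t noise")

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "none" or self.sigma == 0:
            return np.zeros(size)
        if self.kind == "normal":
            return rng.normal(0.0, self.sigma, size)
        return self.sigma * rng.standard_t(self.nu, size)


@dataclass(frozen=True)
class CouetteDesign:
    """Design of a synthetic Couette calibration campaign.

    Defaults follow the calibration envelope of the shear experiments the
    model is meant for: 6 log-spaced stress levels spanning 50–320 Pa,
    6 log-spaced exposure times spanning 0.039–1.48 s, n = 3 replicates
    per operating point, generated from the deterministic reference
    parameter set.
    """

    tau_values: tuple = tuple(np.geomspace(50.0, 320.0, 6))
    t_values: tuple = tuple(np.geomspace(0.039, 1.48, 6))
    n_reps: int = 3
    true_params: PowerLawParams = REFERENCE_PARAMS
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if len(self.tau_values) == 0 or len(self.t_values) == 0:
            raise ValueError("tau_values and t_values must be non-empty")

    def noiseless(self) -> "CouetteDesign":
        return replace(self, noise=NoiseSpec(kind="none"))


def generate_couette_dataset(design: CouetteDesign) -> ShearDataset:
    """Generate a replicated (tau, t, HI) dataset from a known truth.

    One record per (tau, t, replicate) in row-major order over
    (tau, t, rep).  HI = C*tau^beta*t^alpha + noise, with negative draws
    resampled so HI >= 0.  Identical seeds give identical datasets.
    """
    rng = np.random.default_rng(design.seed)
    records = []
    for tau in design.tau_values:
        for t in design.t_values:
            mu = predict_hi(design.true_params, tau, t)
            for _ in range(design.n_reps):
                hi = mu + design.noise.draw(rng, 1)[0]
                while hi < 0:  # physical truncation at zero hemolysis
                    hi = mu + design.noise.draw(rng, 1)[0]
                records.append(ShearRecord(float(tau), float(t), float(hi)))
    label = (
        f"synthetic-couette(C={design.true_params.c_coeff:g}, "
        f"alpha={design.true_params.alpha:g}, beta={design.true_params.beta:g}, "
        f"noise={design.noise.kind}, seed={design.seed})"
    )
    return ShearDataset(records=records, label=label)


@dataclass(frozen=True)
class FieldSpec:
    """Spec for a synthetic per-cell (stress, volume) device field.

    ``stress_model`` is ``("uniform", tau0)`` or
    ``("lognormal", log_mean, log_sd)`` where the lognormal parameters act
    on ln(stress/Pa).  Cell volumes are drawn uniformly and rescaled so
    they sum exactly to ``total_volume``.
    """

    n_cells: int = 2000
    total_volume: float = 1.0e-4  # m^3 (order of a benchmark pump loop domain)
    flow_rate_q: float = 1.0e-4  # m^3/s (= 6 L/min)
    stress_model: tuple = ("lognormal", np.log(30.0), 0.8)
    seed: int = 0
    condition_label: str = "condition1"

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.total_volume <= 0 or self.flow_rate_q <= 0:
            raise ValueError("total_volume and flow_rate_q must be > 0")
        kind = self.stress_model[0]
        if kind == "uniform":
            if len(self.stress_model) != 2 or self.stress_model[1] < 0:
                raise ValueError("uniform stress model needs one value >= 0")
        elif kind == "lognormal":
            if len(self.stress_model) != 3 or self.stress_model[2] <= 0:
                raise ValueError("lognormal stress model needs (log_mean, log_sd>0)")
        else:
            raise ValueError(f"unknown stress model {kind!r}")


def generate_stress_volume_field(spec: FieldSpec) -> StressVolumeField:
    """Generate a seeded per-cell stress/volume histogram for one condition."""
    rng = np.random.default_rng(spec.seed)
    kind = spec.stress_model[0]
    if kind == "uniform":
        sss = np.full(spec.n_cells, float(spec.stress_model[1]))
    else:
        _, log_mean, log_sd = spec.stress_model
        sss = np.exp(rng.normal(log_mean, log_sd, spec.n_cells))
    raw = rng.uniform(0.5, 1.5, spec.n_cells)
    volumes = raw * (spec.total_volume / raw.sum())
    return StressVolumeField(
        sss=sss,
        volumes=volumes,
        flow_rate_q=spec.flow_rate_q,
        condition_label=spec.condition_label,
    )


def default_condition_specs(seed: int = 0) -> list[FieldSpec]:
    """Six labelled condition presets in two flow-rate regimes.

    Emulates, qualitatively, a benchmark-pump campaign run at a lower and a
    higher rotational speed: conditions 1 and 4 use the low-speed regime
    (lower stress scale), the rest the high-speed regime.  Flow rates vary
    across conditions within each regime.
    """
    low = dict(log_mean=np.log(18.0), log_sd=0.7)
    high = dict(log_mean=np.log(45.0), log_sd=0.9)
    q_lpm = {1: 6.0, 2: 6.0, 3: 4.0, 4: 2.5, 5: 6.0, 6: 7.0}
    regimes = {1: low, 2: high, 3: high, 4: low, 5: high, 6: high}
    specs = []
    for i in range(1, 7):
        r = regimes[i]
        specs.append(
            FieldSpec(
                n_cells=2000,
                total_volume=1.0e-4,
                flow_rate_q=q_lpm[i] / 60.0e3,  # L/min -> m^3/s
                stress_model=("lognormal", r["log_mean"], r["log_sd"]),
                seed=seed + i,
                condition_label=f"condition{i}",
            )
        )
    return specs


@dataclass(frozen=True)
class GradientFieldSpec:
    """Spec for a synthetic per-cell velocity-gradient tensor field.

    ``preset`` is one of ``("pure_shear", gamma_dot)``,
    ``("rigid_rotation", omega)``, ``("uniaxial", a)`` or
    ``("random", scale)``; the analytic presets fill every cell with the
    same canonical tensor so the scalar-shear-stress reduction has a known
    closed form (eta*gamma_dot, 0 and sqrt(2)*eta*a respectively).
    """

    n_cells: int = 100
    viscosity: float = 3.5e-3  # Pa s, whole-blood dynamic viscosity
    total_volume: float = 1.0e-4  # m^3
    preset: tuple = ("random", 100.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.viscosity <= 0:
            raise ValueError("viscosity must be > 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


def generate_velocity_gradient_field(spec: GradientFieldSpec) -> VelocityGradientField:
    """Generate per-cell velocity-gradient tensors with known analytic cases."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells
    grads = np.zeros((n, 3, 3))
    kind, value = spec.preset[0], float(spec.preset[1])
    if kind == "pure_shear":
        grads[:, 0, 1] = value  # du/dy = gamma_dot
    elif kind == "rigid_rotation":
        grads[:, 0, 1] = value  # du/dy = omega
        grads[:, 1, 0] = -value  # dv/dx = -omega
    elif kind == "uniaxial":
        grads[:, 0, 0] = value  # du/dx = a
    elif kind == "random":
        grads = rng.normal(0.0, value, (n, 3, 3))
    else:
        raise ValueError(f"unknown gradient preset {kind!r}")
    raw = rng.uniform(0.5, 1.5, n)
    volumes = raw * (spec.total_volume / raw.sum())
    return VelocityGradientField(
        gradients=grads, viscosity=spec.viscosity, volumes=volumes
    )
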