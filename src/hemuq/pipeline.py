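"""End-to-end orchestration of the probabilistic hemolysis workflow.

``run_full_pipeline`` composes the stages — simulate (or load) calibration
data, Bayesian fit, optional fixed-C optimisation, truncated log-normal
posterior fits, per-condition surrogate training, forward propagation and
model comparison — under one master seed, writing every artifact plus a
provenance log into an output directory.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, Field

from . import io as hio
from .model import HemolysisModel, PriorSpec, SamplerConfig
from .optimize_c import COptConfig, optimize_fixed_c
from .powerlaw import REFERENCE_PARAMS, PowerLawParams
from .propagate import compare_models, propagate, rih_distributions
from .synthetic import (
    CouetteDesign,
    NoiseSpec,
    default_condition_specs,
    generate_couette_dataset,
    generate_stress_volume_field,
)
from .surrogate import train_mih_surrogate

__all__ = ["RunConfig", "run_full_pipeline"]

log = logging.getLogger("hemuq")


class DesignBlock(BaseModel):
    n_tau: int = 6
    n_t: int = 6
    n_reps: int = 3
    noise_kind: str = "student_t"
    noise_sigma: float = 0.1
    noise_nu: float = 30.0


class SamplerBlock(BaseModel):
    n_chains: int = 4
    n_draws: int = 2000
    n_tune: int = 1000
    target_accept: float = 0.95
    n_walkers: int = 32


class COptBlock(BaseModel):
    enabled: bool = False
    c_low: float = 1e-6
    c_high: float = 1e-3
    n_iterations: int = 100
    n_initial: int = 10
    inner_chains: int = 2
    inner_draws: int = 1000
    inner_tune: int = 300


class SurrogateBlock(BaseModel):
    order: int = 4
    n_lhs: int = 200
    n_test: int = 50


class PropagationBlock(BaseModel):
    n_forward: int = 10000
    reference: str = "condition5"


class RunConfig(BaseModel):
    """Schema-validated configuration of a full pipeline run."""

    seed: int = 0
    data_csv: Optional[str] = None  # load instead of simulate when given
    fixed_c: Optional[float] = None  # fixed C when the optimiser is off
    design: DesignBlock = Field(default_factory=DesignBlock)
    priors: dict = Field(default_factory=dict)
    sampler: SamplerBlock = Field(default_factory=SamplerBlock)
    copt: COptBlock = Field(default_factory=COptBlock)
    surrogate: SurrogateBlock = Field(default_factory=SurrogateBlock)
    propagation: PropagationBlock = Field(default_factory=PropagationBlock)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(raw)


def _stage(name):
    log.info("stage: %s", name)
    return name


def run_full_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the full workflow; returns a summary dict (also written as
    ``summary.json`` in ``outdir``).

    Stage seeds derive from the master seed by fixed offsets.  Any stage
    failure raises with the stage name; artifacts written so far persist.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    seed = int(config.seed)
    summary: dict = {"seed": seed, "stages": []}
    stage = "init"
    try:
        stage = _stage("data")
        if config.data_csv:
            dataset = hio.read_shear_dataset(config.data_csv)
        else:
            d = config.design
            import numpy as np

            design = CouetteDesign(
                tau_values=tuple(np.geomspace(50.0, 320.0, d.n_tau)),
                t_values=tuple(np.geomspace(0.039, 1.48, d.n_t)),
                n_reps=d.n_reps,
                noise=NoiseSpec(kind=d.noise_kind, sigma=d.noise_sigma,
                                nu=d.noise_nu),
                seed=seed + 11,
            )
            dataset = generate_couette_dataset(design)
        hio.write_shear_dataset(dataset, outdir / "data.csv")
        summary["n_records"] = len(dataset)
        summary["stages"].append(stage)

        stage = _stage("optimize_c" if config.copt.enabled else "fix_c")
        if config.copt.enabled:
            copt_cfg = COptConfig(
                bounds=(config.copt.c_low, config.copt.c_high),
                n_iterations=config.copt.n_iterations,
                n_initial=config.copt.n_initial,
                inner_sampler=SamplerConfig(
                    n_chains=config.copt.inner_chains,
                    n_draws=config.copt.inner_draws,
                    n_tune=config.copt.inner_tune,
                    n_walkers=24,
                ),
                seed=seed + 23,
            )
            copt = optimize_fixed_c(dataset, cfg=copt_cfg)
            c_fixed = copt.c_opt
            (outdir / "copt.json").write_text(json.dumps({
                "c_opt": copt.c_opt,
                "best_objective": copt.best_objective,
                "trace": copt.objective_trace,
                **copt.metadata,
            }, indent=1))
        else:
            c_fixed = (
                config.fixed_c if config.fixed_c is not None
                else REFERENCE_PARAMS.c_coeff
            )
        summary["c_fixed"] = c_fixed
        summary["stages"].append(stage)

        stage = _stage("mcmc_fit")
        priors = PriorSpec(**config.priors).fix_c(c_fixed)
        s = config.sampler
        cfg = SamplerConfig(
            n_chains=s.n_chains, n_draws=s.n_draws, n_tune=s.n_tune,
            target_accept=s.target_accept, n_walkers=s.n_walkers,
            seed=seed + 37,
        )
        results = HemolysisModel(dataset, priors=priors).fit(cfg)
        hio.write_posterior(results, outdir / "posterior")
        summary["posterior_summary"] = json.loads(
            results.posterior_summary().to_json(orient="index")
        )
        summary["r_hat"] = results.gelman_rubin() if cfg.n_chains >= 2 else None
        summary["stages"].append(stage)

        stage = _stage("lognormal_fits")
        fits = {
            name: results.fit_truncated_lognormal(name)
            for name in ("alpha", "beta")
        }
        hio.write_lognormal_fits(fits, outdir / "fits.json")
        summary["stages"].append(stage)

        stage = _stage("fields_and_surrogates")
        specs = default_condition_specs(seed=seed + 41)
        fields = {}
        surrogates = {}
        fields_dir = outdir / "fields"
        fields_dir.mkdir(exist_ok=True)
        for spec in specs:
            f = generate_stress_volume_field(spec)
            fields[f.condition_label] = f
            hio.write_stress_volume_field(f, fields_dir / f"{f.condition_label}.json")
            surrogates[f.condition_label] = train_mih_surrogate(
                fits, f, fixed_params={"C": c_fixed},
                order=config.surrogate.order, n_lhs=config.surrogate.n_lhs,
                seed=seed + 43, n_test=config.surrogate.n_test,
            )
        summary["surrogate_max_rel_error"] = {
            k: sm.validation["max_rel_error"] for k, sm in surrogates.items()
        }
        summary["stages"].append(stage)

        stage = _stage("propagation")
        mih_dists = propagate(
            fits, surrogates, n_forward=config.propagation.n_forward,
            seed=seed + 53,
        )
        ref = config.propagation.reference
        rih_dists = rih_distributions(mih_dists, reference=ref)
        uq_dir = outdir / "uq"
        uq_dir.mkdir(exist_ok=True)
        import pandas as pd

        for label, dist in rih_dists.items():
            pd.DataFrame({"rih": dist.samples}).to_csv(
                uq_dir / f"{label}.csv", index=False
            )
        det_params = PowerLawParams(
            c_coeff=c_fixed,
            alpha=REFERENCE_PARAMS.alpha,
            beta=REFERENCE_PARAMS.beta,
        )
        table = compare_models(rih_dists, det_params, fields, reference=ref)
        table.to_csv(outdir / "comparison.csv")
        summary["comparison"] = json.loads(table.to_json(orient="index"))
        summary["stages"].append(stage)

        summary["config"] = json.loads(config.model_dump_json())
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1,
                                                        sort_keys=True))
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
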