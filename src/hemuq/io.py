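"""Readers and writers for the package's interchange formats.

All formats are plain text: CSV for tabular data (comma separator, '.'
decimal, UTF-8, header required), JSON for structured artifacts, and a
compressed numpy archive plus JSON sidecar for dense SSE landscapes.
Every writer produces files its reader accepts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import CSV_COLUMNS, ShearDataset, ShearRecord
from .fields import StressVolumeField, VelocityGradientField
from .model import HemolysisResults, LogNormalFit
from .powerlaw import GridConfig, PerCMin, PowerLawParams, SSELandscape

__all__ = [
    "read_shear_dataset",
    "write_shear_dataset",
    "read_stress_volume_field",
    "write_stress_volume_field",
    "read_velocity_gradient_field",
    "write_velocity_gradient_field",
    "write_landscape",
    "read_landscape",
    "write_posterior",
    "read_posterior_draws",
    "write_lognormal_fits",
    "read_lognormal_fits",
    "write_params",
    "read_params",
]

GRADIENT_KEYS = (
    "du_dx", "du_dy", "du_dz",
    "dv_dx", "dv_dy", "dv_dz",
    "dw_dx", "dw_dy", "dw_dz",
)


class ValidationError(ValueError):
    """Raised when an input file fails validation; names the offending row."""


def read_shear_dataset(path, label: str | None = None) -> ShearDataset:
    """Read a `tau_pa,t_s,hi` CSV, validating every row.

    Malformed or out-of-range rows raise :class:`ValidationError` naming the
    1-based data row number.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: no records (empty file)") from None
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise ValidationError(f"{path}: no records")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        vals = [getattr(row, c) for c in CSV_COLUMNS]
        try:
            nums = [float(v) for v in vals]
            if not np.isfinite(nums).all():
                raise ValueError("non-finite value")
            records.append(ShearRecord(*nums))
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: invalid row {i}: {exc}") from None
    return ShearDataset(records=records, label=label if label is not None else path.stem)


def write_shear_dataset(dataset: ShearDataset, path) -> None:
    dataset.to_frame().to_csv(path, index=False)


def write_stress_volume_field(field: StressVolumeField, path) -> None:
    payload = {
        "condition_label": field.condition_label,
        "flow_rate_q_m3s": field.flow_rate_q,
        "cells": [
            {"sss_pa": float(s), "volume_m3": float(v)}
            for s, v in zip(field.sss, field.volumes)
        ],
    }
    Path(path).write_text(json.dumps(payload))


def read_stress_volume_field(path) -> StressVolumeField:
    payload = json.loads(Path(path).read_text())
    cells = payload["cells"]
    return StressVolumeField(
        sss=np.array([c["sss_pa"] for c in cells]),
        volumes=np.array([c["volume_m3"] for c in cells]),
        flow_rate_q=float(payload["flow_rate_q_m3s"]),
        condition_label=payload.get("condition_label", ""),
    )


def write_velocity_gradient_field(field: VelocityGradientField, path) -> None:
    cells = []
    for i in range(field.n_cells):
        g = field.gradients[i].ravel()
        cell = {k: float(v) for k, v in zip(GRADIENT_KEYS, g)}
        cell["volume_m3"] = float(field.volumes[i])
        cells.append(cell)
    payload = {"viscosity_pas": field.viscosity, "cells": cells}
    Path(path).write_text(json.dumps(payload))


def read_velocity_gradient_field(path) -> VelocityGradientField:
    payload = json.loads(Path(path).read_text())
    cells = payload["cells"]
    grads = np.array(
        [[c[k] for k in GRADIENT_KEYS] for c in cells]
    ).reshape(-1, 3, 3)
    return VelocityGradientField(
        gradients=grads,
        viscosity=float(payload["viscosity_pas"]),
        volumes=np.array([c["volume_m3"] for c in cells]),
    )


def write_landscape(landscape: SSELandscape, outdir) -> None:
    """Dense SSE array (npz) plus JSON sidecar with axes and minima."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(outdir / "sse.npz", sse=landscape.sse)
    gp, gs = landscape.global_min
    sidecar = {
        "c_values": landscape.axes.c_values.tolist(),
        "alpha_values": landscape.axes.alpha_values.tolist(),
        "beta_values": landscape.axes.beta_values.tolist(),
        "global_min": {"params": gp.as_dict(), "sse": gs},
        "per_c_min": [
            {"c": e.c, "sse": e.sse, "alpha": e.alpha, "beta": e.beta}
            for e in landscape.per_c_min
        ],
    }
    (outdir / "landscape.json").write_text(json.dumps(sidecar, indent=1))


def read_landscape(outdir) -> SSELandscape:
    outdir = Path(outdir)
    sidecar = json.loads((outdir / "landscape.json").read_text())
    sse = np.load(outdir / "sse.npz")["sse"]
    grid = GridConfig(
        c_values=np.array(sidecar["c_values"]),
        alpha_values=np.array(sidecar["alpha_values"]),
        beta_values=np.array(sidecar["beta_values"]),
    )
    gm = sidecar["global_min"]
    params = PowerLawParams(
        gm["params"]["C"], gm["params"]["alpha"], gm["params"]["beta"]
    )
    per_c = [
        PerCMin(c=e["c"], sse=e["sse"], alpha=e["alpha"], beta=e["beta"])
        for e in sidecar["per_c_min"]
    ]
    return SSELandscape(
        axes=grid, sse=sse, global_min=(params, gm["sse"]), per_c_min=per_c
    )


def write_posterior(results: HemolysisResults, outdir) -> None:
    """One CSV per parameter (columns = chains) plus metadata/summary JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, arr in results.draws.items():
        cols = {f"chain{j}": arr[j] for j in range(arr.shape[0])}
        pd.DataFrame(cols).to_csv(outdir / f"{name}.csv", index=False)
    meta = results.metadata
    summary = results.posterior_summary()
    payload = {
        "parameters": list(results.draws),
        "n_chains": results.n_chains,
        "n_draws": results.n_draws,
        "dataset_label": meta.get("dataset_label", ""),
        "sampler": meta.get("sampler", ""),
        "acceptance_fractions": meta.get("acceptance_fractions", []),
        "warnings": meta.get("warnings", []),
        "summary": {
            name: {k: float(summary.loc[name, k]) for k in ("median", "q05", "q95")}
            for name in summary.index
        },
    }
    if results.n_chains >= 2:
        payload["r_hat"] = results.gelman_rubin()
        payload["correlations"] = (
            results.correlations().to_dict() if len(results.draws) >= 2 else {}
        )
    (outdir / "posterior.json").write_text(json.dumps(payload, indent=1))


def read_posterior_draws(outdir) -> dict[str, np.ndarray]:
    outdir = Path(outdir)
    payload = json.loads((outdir / "posterior.json").read_text())
    draws = {}
    for name in payload["parameters"]:
        df = pd.read_csv(outdir / f"{name}.csv")
        draws[name] = df.to_numpy().T  # (chains, draws)
    return draws


def write_lognormal_fits(fits: dict[str, LogNormalFit], path) -> None:
    payload = {
        name: {
            "shape": f.shape,
            "scale": f.scale,
            "location": f.location,
            "trunc_low": f.trunc_low,
            "trunc_high": f.trunc_high,
        }
        for name, f in fits.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_lognormal_fits(path) -> dict[str, LogNormalFit]:
    payload = json.loads(Path(path).read_text())
    return {
        name: LogNormalFit(
            shape=d["shape"], scale=d["scale"],
            trunc_low=d["trunc_low"], trunc_high=d["trunc_high"],
        )
        for name, d in payload.items()
    }


def write_params(params: PowerLawParams, path) -> None:
    Path(path).write_text(json.dumps(params.as_dict(), indent=1))


def read_params(path) -> PowerLawParams:
    d = json.loads(Path(path).read_text())
    return PowerLawParams(c_coeff=d["C"], alpha=d["alpha"], beta=d["beta"])
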