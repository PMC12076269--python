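"""Containers for replicated shear-exposure hemolysis experiments.

A calibration experiment exposes blood to a controlled scalar shear stress
``tau`` (Pa) for an exposure time ``t`` (s) — typically in a Couette shearing
device — and records the resulting hemolysis index ``HI`` (dimensionless).
Replicates at the same operating point are stored as separate records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ShearRecord", "ShearDataset"]

#: canonical CSV column order: shear stress [Pa], exposure time [s], HI [-]
CSV_COLUMNS = ("tau_pa", "t_s", "hi")


@dataclass(frozen=True)
class ShearRecord:
    """One observation: shear stress [Pa], exposure time [s], hemolysis index."""

    tau: float
    t_exp: float
    hi: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.tau, self.t_exp, self.hi]).all():
            raise ValueError("ShearRecord fields must be finite")
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0 Pa, got {self.tau}")
        if self.t_exp <= 0:
            raise ValueError(f"t_exp must be > 0 s, got {self.t_exp}")
        if self.hi < 0:
            raise ValueError(f"hi must be >= 0, got {self.hi}")


@dataclass
class ShearDataset:
    """Ordered collection of :class:`ShearRecord` with a provenance label.

    Duplicate ``(tau, t_exp)`` pairs are allowed and expected: they are the
    replicates whose scatter the probabilistic model is built to capture.
    """

    records: list[ShearRecord]
    label: str = ""
    _arrays: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.records) == 0:
            raise ValueError("ShearDataset must contain at least one record")
        self.records = [
            r if isinstance(r, ShearRecord) else ShearRecord(*r) for r in self.records
        ]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def tau(self) -> np.ndarray:
        """Shear stresses [Pa], shape ``(n,)``."""
        return self._cached("tau", lambda: np.array([r.tau for r in self.records]))

    @property
    def t_exp(self) -> np.ndarray:
        """Exposure times [s], shape ``(n,)``."""
        return self._cached("t_exp", lambda: np.array([r.t_exp for r in self.records]))

    @property
    def hi(self) -> np.ndarray:
        """Observed hemolysis indices, shape ``(n,)``."""
        return self._cached("hi", lambda: np.array([r.hi for r in self.records]))

    def _cached(self, key, build):
        if key not in self._arrays:
            self._arrays[key] = build()
        return self._arrays[key]

    def to_frame(self) -> pd.DataFrame:
        """Return the dataset as a DataFrame with columns ``tau_pa,t_s,hi``."""
        return pd.DataFrame(
            {"tau_pa": self.tau, "t_s": self.t_exp, "hi": self.hi}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label: str = "") -> "ShearDataset":
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        records = [
            ShearRecord(float(r.tau_pa), float(r.t_s), float(r.hi))
            for r in df.itertuples(index=False)
        ]
        return cls(records=records, label=label)
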