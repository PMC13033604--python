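"""Kinetic, radiosensitivity and housekeeping parameters of the model.

The calibrated subset mirrors the quantities estimated against the bilateral
tumor-growth experiment: intrinsic tumor growth and implant size, phagocytic
rate constants for viable and dead tumor cells, debris clearance, naive
CD8+ T-cell proliferation, linear-quadratic radiosensitivities for tumor
cells and for lymph-node immune cells, and the two treatment-dependent
parameters (naive-to-effector activation ``k_tn`` and effector cytolytic
rate ``k_rc1``) which carry separate values for control versus
radiotherapy-treated arms.  Everything else (immune turnover, suppression
coefficients, packing density) is held fixed across arms.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path

#: Parameter identifiers exposed to the one-at-a-time sensitivity sweeps.
#: ``k_tn`` and ``k_rc1`` denote the treatment-arm pair as a unit.
FITTED_PARAMETERS: tuple[str, ...] = (
    "lg_tumor",
    "vi_tumor0_mm3",
    "clear_c_dead",
    "ac_dc",
    "ac_m1",
    "ac_dead_dc",
    "ac_dead_m1",
    "k_prol_tn",
    "a_c",
    "b_c",
    "a_im",
    "b_im",
    "k_tn",
    "k_rc1",
)

#: Scalar layout used by the calibration vector (group pairs unrolled).
FITTED_VECTOR_NAMES: tuple[str, ...] = (
    "lg_tumor",
    "vi_tumor0_mm3",
    "clear_c_dead",
    "ac_dc",
    "ac_m1",
    "ac_dead_dc",
    "ac_dead_m1",
    "k_prol_tn",
    "a_c",
    "b_c",
    "a_im",
    "b_im",
    "k_tn_control",
    "k_tn_rt",
    "k_rc1_control",
    "k_rc1_rt",
)

UNITS: dict[str, str] = {
    "lg_tumor": "1/day",
    "vi_tumor0_mm3": "mm^3",
    "clear_c_dead": "1/day",
    "ac_dc": "mL/cell/day",
    "ac_m1": "mL/cell/day",
    "ac_dead_dc": "mL/cell/day",
    "ac_dead_m1": "mL/cell/day",
    "k_prol_tn": "1/day",
    "a_c": "1/Gy",
    "b_c": "1/Gy^2",
    "a_im": "1/Gy",
    "b_im": "1/Gy^2",
    "k_tn_control": "mL/cell/day",
    "k_tn_rt": "mL/cell/day",
    "k_rc1_control": "mL/cell/day",
    "k_rc1_rt": "mL/cell/day",
    "tn0": "cells",
    "s_treg": "mL/cell",
    "s_m2": "mL/cell",
    "v_cell_mm3": "mm^3/cell",
    "n_exp": "dimensionless",
}

_TRAFFICKING = ("DC", "M1", "M2", "TREG", "TE1", "APC")


@dataclass(frozen=True)
class ParameterSet:
    # -- calibrated, shared across treatment arms -------------------------
    lg_tumor: float            # intrinsic tumor growth rate, 1/day
    vi_tumor0_mm3: float       # initial (implant) tumor volume, mm^3
    clear_c_dead: float        # dead-cell/debris clearance, 1/day
    ac_dc: float               # phagocytosis of viable cells by DC+APC
    ac_m1: float               # phagocytosis of viable cells by M1
    ac_dead_dc: float          # phagocytosis of debris by DC+APC
    ac_dead_m1: float          # phagocytosis of debris by M1
    k_prol_tn: float           # naive CD8+ regeneration, 1/day
    a_c: float                 # tumor-cell LQ alpha, 1/Gy
    b_c: float                 # tumor-cell LQ beta, 1/Gy^2
    a_im: float                # LN immune-cell LQ alpha, 1/Gy
    b_im: float                # LN immune-cell LQ beta, 1/Gy^2
    # -- calibrated, treatment-arm dependent ------------------------------
    k_tn_control: float        # naive->effector activation, control arm
    k_tn_rt: float             # naive->effector activation, RT-treated arms
    k_rc1_control: float       # effector cytolytic rate, control arm
    k_rc1_rt: float            # effector cytolytic rate, RT-treated arms
    # -- fixed auxiliary constants ----------------------------------------
    tn0: float = 1.0e6         # baseline naive CD8+ pool in lymph nodes
    s_treg: float = 1.0e-7     # Treg suppression coefficient (per cells/mL)
    s_m2: float = 1.0e-7       # M2 suppression coefficient (per cells/mL)
    v_cell_mm3: float = 1.0e-6  # packed single-cell volume
    n_exp: float = 1.0         # effector expansion per activated naive cell
    source_rates: dict = field(
        default_factory=dict
    )                          # cells/day entering venous blood, per species
    death_rates: dict = field(
        default_factory=dict
    )                          # first-order death, 1/day, per species

    def __post_init__(self) -> None:
        for name in FITTED_VECTOR_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.vi_tumor0_mm3 <= 0:
            raise ValueError("vi_tumor0_mm3 must be positive")
        if self.tn0 <= 0:
            raise ValueError("tn0 must be positive")
        missing = [s for s in _TRAFFICKING if s not in self.death_rates]
        if missing:
            raise ValueError(f"death_rates missing species: {missing}")

    # -- group resolution --------------------------------------------------
    def k_tn(self, group: str) -> float:
        return self.k_tn_control if _is_control(group) else self.k_tn_rt

    def k_rc1(self, group: str) -> float:
        return self.k_rc1_control if _is_control(group) else self.k_rc1_rt

    # -- functional helpers ------------------------------------------------
    def with_updates(self, **updates) -> "ParameterSet":
        return dataclasses.replace(self, **updates)

    def scaled(self, param_id: str, multiplier: float) -> "ParameterSet":
        """Return a copy with one fitted parameter scaled by ``multiplier``.

        For the arm-dependent pairs (``k_tn``, ``k_rc1``) both arm values are
        scaled together, so the perturbation acts on whichever value the
        simulated protocol selects.
        """
        if multiplier <= 0:
            raise ValueError("multiplier must be positive")
        if param_id in ("k_tn", "k_rc1"):
            return self.with_updates(**{
                f"{param_id}_control": getattr(self, f"{param_id}_control") * multiplier,
                f"{param_id}_rt": getattr(self, f"{param_id}_rt") * multiplier,
            })
        if param_id not in FITTED_VECTOR_NAMES:
            raise KeyError(f"unknown fitted parameter: {param_id!r}")
        return self.with_updates(**{param_id: getattr(self, param_id) * multiplier})

    def fitted_vector(self) -> list[float]:
        return [float(getattr(self, n)) for n in FITTED_VECTOR_NAMES]

    def with_fitted_vector(self, values) -> "ParameterSet":
        if len(values) != len(FITTED_VECTOR_NAMES):
            raise ValueError("fitted vector has wrong length")
        return self.with_updates(
            **{n: float(v) for n, v in zip(FITTED_VECTOR_NAMES, values)}
        )

    # -- serialization -----------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "units": UNITS,
            "values": {
                n: getattr(self, n)
                for n in FITTED_VECTOR_NAMES
                + ("tn0", "s_treg", "s_m2", "v_cell_mm3", "n_exp")
            },
            "source_rates": self.source_rates,
            "death_rates": self.death_rates,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ParameterSet":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        return cls(
            **payload["values"],
            source_rates=payload["source_rates"],
            death_rates=payload["death_rates"],
        )

    @classmethod
    def default(cls) -> "ParameterSet":
        """Shipped default parameterization (murine bilateral-flank setting)."""
        path = Path(
            importlib.resources.files("abscopal") / "data" / "default_parameters.json"
        )
        return cls.from_json(path)


def _is_control(group: str) -> bool:
    g = str(group).upper().replace("-", "_").replace("+", "_").replace(" ", "")
    return g in ("CONTROL", "CTRL")
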