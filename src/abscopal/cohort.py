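"""Synthetic tumor-growth cohorts emulating the bilateral-flank experiment.

The generator reproduces the statistical structure of the calibration
dataset: three treatment arms (control, local-tumor radiotherapy, and
local-tumor plus lymph-node radiotherapy), eight mice per arm, two tumors
per mouse, measurements every two to three days out to day 24.  Biological
variability enters as per-mouse log-normal perturbations of the intrinsic
growth rate and implant size; measurement error is multiplicative
log-normal on volumes (errors scale with tumor size and volumes stay
positive).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import TumorGrowthDataset
from .engine import simulate
from .parameters import ParameterSet
from .physiology import CompartmentId, PhysiologyTable
from .radiotherapy import build_protocol

#: Default measurement schedule: every 3 days to day 24 plus the treatment
#: day (day 10).
DEFAULT_MEASUREMENT_DAYS: tuple[float, ...] = (
    0.0, 3.0, 6.0, 9.0, 10.0, 12.0, 15.0, 18.0, 21.0, 24.0
)

_TUMORS = {"T1": CompartmentId.TUMOR1, "T2": CompartmentId.TUMOR2}


@dataclass
class CohortConfig:
    groups: tuple[str, ...] = ("CONTROL", "T1_RT", "T1_RT_LN_RT")
    n_per_group: int = 8
    measurement_days: tuple[float, ...] = DEFAULT_MEASUREMENT_DAYS
    noise_sigma: float = 0.20          # log-normal sd of measurement error
    mouse_sigma: float = 0.15          # log-normal sd on lg_tumor, vi_tumor0
    seed: int = 0
    true_params: ParameterSet = field(default_factory=ParameterSet.default)
    horizon_days: float = 24.0
    rtol: float = 1.0e-6

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("need at least one mouse per group")
        if self.noise_sigma < 0 or self.mouse_sigma < 0:
            raise ValueError("noise levels must be non-negative")
        if max(self.measurement_days) > self.horizon_days:
            raise ValueError("measurement days must lie within the horizon")


def generate_cohort(
    config: CohortConfig, physiology: PhysiologyTable | None = None
) -> tuple[TumorGrowthDataset, dict]:
    """Simulate a cohort and return (dataset, truth sidecar).

    Each mouse carries its own draw of (lg_tumor, vi_tumor0); both tumors
    are simulated under the mouse's arm protocol, sampled at the
    measurement schedule, and perturbed with multiplicative noise.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    days = np.asarray(sorted(config.measurement_days), dtype=float)
    rows = []
    subject_draws = {}
    for group in config.groups:
        protocol = build_protocol(group)
        for i in range(config.n_per_group):
            subject = f"{group}_m{i+1:02d}"
            lg = config.true_params.lg_tumor * float(
                np.exp(rng.normal(0.0, config.mouse_sigma))
            )
            vi0 = config.true_params.vi_tumor0_mm3 * float(
                np.exp(rng.normal(0.0, config.mouse_sigma))
            )
            subject_draws[subject] = {"lg_tumor": lg, "vi_tumor0_mm3": vi0}
            params_i = config.true_params.with_updates(
                lg_tumor=lg, vi_tumor0_mm3=vi0
            )
            try:
                tr = simulate(
                    params_i,
                    protocol,
                    config.horizon_days,
                    rtol=config.rtol,
                    physiology=physiology,
                )
            except Exception as exc:
                raise RuntimeError(
                    f"simulation failed for subject {subject} "
                    f"(lg_tumor={lg:.4g}, vi_tumor0={vi0:.4g} mm^3): {exc}"
                ) from exc
            for tumor_id, comp in _TUMORS.items():
                clean = np.interp(days, tr.times, tr.tumor_volume_series(comp))
                noise = np.exp(rng.normal(0.0, config.noise_sigma, size=days.size))
                observed = np.maximum(clean * noise, 1e-6)
                for d, v in zip(days, observed):
                    rows.append(
                        {
                            "subject": subject,
                            "group": group,
                            "tumor": tumor_id,
                            "day": float(d),
                            "volume_mm3": float(v),
                        }
                    )
    dataset = TumorGrowthDataset(pd.DataFrame(rows))
    truth = {
        "seed": config.seed,
        "noise_sigma": config.noise_sigma,
        "mouse_sigma": config.mouse_sigma,
        "true_params": json.loads(config.true_params.to_json()),
        "subject_draws": subject_draws,
    }
    return dataset, truth


def write_cohort(
    dataset: TumorGrowthDataset, truth: dict, path: str | Path
) -> None:
    """CSV cohort plus JSON truth sidecar (``<stem>.truth.json``)."""
    path = Path(path)
    dataset.to_csv(path)
    path.with_suffix(".truth.json").write_text(json.dumps(truth, indent=2))


def read_cohort(path: str | Path) -> tuple[TumorGrowthDataset, dict | None]:
    """Load a cohort CSV (and its truth sidecar when present)."""
    path = Path(path)
    dataset = TumorGrowthDataset.from_csv(path)
    sidecar = path.with_suffix(".truth.json")
    truth = json.loads(sidecar.read_text()) if sidecar.exists() else None
    return dataset, truth
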