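"""Whole-body compartment network for immune-cell trafficking.

The body is represented as a physiologically based pharmacokinetic (PBPK)
network: ten organs plus two subcutaneous tumors, each split into a vascular
and an interstitial sub-compartment, joined by two well-mixed blood pools
(arterial, venous) in the standard series arrangement (venous blood -> lungs
-> arterial blood -> systemic tissues -> venous blood).  Lymph drains every
tissue's interstitium into the lymph-node interstitium; the lymph-node
efferent returns to venous blood.

All volumes are in mL, plasma/lymph flows in mL/day, transport rate
constants in 1/day.  Tumor volumes elsewhere in the package are quoted in
mm^3 (1 mm^3 = 1e-3 mL).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd
import yaml


class SpeciesId(str, Enum):
    """The nine cell populations tracked by the model."""

    DC = "DC"          # dendritic cells
    M1 = "M1"          # pro-inflammatory macrophages
    M2 = "M2"          # anti-inflammatory macrophages
    TREG = "TREG"      # regulatory T cells
    TN = "TN"          # naive CD8+ T cells (lymph nodes only)
    TE1 = "TE1"        # effector CD8+ T cells
    APC = "APC"        # antigen-presenting cells (matured DC / M1)
    TV = "TV"          # viable tumor cells (tumors only)
    TD = "TD"          # dead tumor cells / debris (tumors only)


#: Species that circulate through blood and lymph.
TRAFFICKING_SPECIES: tuple[SpeciesId, ...] = (
    SpeciesId.DC,
    SpeciesId.M1,
    SpeciesId.M2,
    SpeciesId.TREG,
    SpeciesId.TE1,
    SpeciesId.APC,
)


class CompartmentId(str, Enum):
    LUNGS = "LUNGS"
    LIVER = "LIVER"
    GI = "GI"
    SPLEEN = "SPLEEN"
    HEART = "HEART"
    KIDNEYS = "KIDNEYS"
    SKIN = "SKIN"
    MUSCLE = "MUSCLE"
    BONE = "BONE"
    LYMPH_NODES = "LYMPH_NODES"
    TUMOR1 = "TUMOR1"
    TUMOR2 = "TUMOR2"
    ARTERIAL_BLOOD = "ARTERIAL_BLOOD"
    VENOUS_BLOOD = "VENOUS_BLOOD"


#: Compartments carrying vascular + interstitial sub-compartments.
TISSUE_COMPARTMENTS: tuple[CompartmentId, ...] = (
    CompartmentId.LUNGS,
    CompartmentId.LIVER,
    CompartmentId.GI,
    CompartmentId.SPLEEN,
    CompartmentId.HEART,
    CompartmentId.KIDNEYS,
    CompartmentId.SKIN,
    CompartmentId.MUSCLE,
    CompartmentId.BONE,
    CompartmentId.LYMPH_NODES,
    CompartmentId.TUMOR1,
    CompartmentId.TUMOR2,
)

#: Systemic tissues: everything perfused from arterial blood (lungs are in
#: series between the venous and arterial pools and are not in this set).
SYSTEMIC_TISSUES: tuple[CompartmentId, ...] = tuple(
    c for c in TISSUE_COMPARTMENTS if c is not CompartmentId.LUNGS
)

TUMOR_COMPARTMENTS: tuple[CompartmentId, ...] = (
    CompartmentId.TUMOR1,
    CompartmentId.TUMOR2,
)

BLOOD_COMPARTMENTS: tuple[CompartmentId, ...] = (
    CompartmentId.ARTERIAL_BLOOD,
    CompartmentId.VENOUS_BLOOD,
)

_COMPARTMENT_COLUMNS = [
    "compartment",
    "total_volume_ml",
    "vascular_ml",
    "interstitial_ml",
    "plasma_flow_ml_day",
    "lymph_flow_ml_day",
]
_TRANSPORT_COLUMNS = [
    "species",
    "compartment",
    "extravasation_per_day",
    "lymph_exit_per_day",
]


@dataclass
class PhysiologyTable:
    """Compartment volumes/flows plus per-(species, tissue) transport rates.

    ``compartments`` has one row per :class:`CompartmentId`;
    ``transport`` one row per (trafficking species, tissue compartment).
    """

    compartments: pd.DataFrame
    transport: pd.DataFrame
    species_profile: str = "mouse"
    _comp_index: dict = field(default_factory=dict, repr=False)
    _trans_index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._comp_index = {
            r.compartment: r for r in self.compartments.itertuples(index=False)
        }
        self._trans_index = {
            (r.species, r.compartment): r
            for r in self.transport.itertuples(index=False)
        }

    # -- lookups -----------------------------------------------------------
    def compartment(self, comp: CompartmentId):
        return self._comp_index[comp.value]

    def plasma_flow(self, comp: CompartmentId) -> float:
        return float(self.compartment(comp).plasma_flow_ml_day)

    def lymph_flow(self, comp: CompartmentId) -> float:
        return float(self.compartment(comp).lymph_flow_ml_day)

    def vascular_volume(self, comp: CompartmentId) -> float:
        return float(self.compartment(comp).vascular_ml)

    def interstitial_volume(self, comp: CompartmentId) -> float:
        return float(self.compartment(comp).interstitial_ml)

    def extravasation(self, sp: SpeciesId, comp: CompartmentId) -> float:
        return float(self._trans_index[(sp.value, comp.value)].extravasation_per_day)

    def lymph_exit(self, sp: SpeciesId, comp: CompartmentId) -> float:
        return float(self._trans_index[(sp.value, comp.value)].lymph_exit_per_day)

    @property
    def total_systemic_plasma_flow(self) -> float:
        return float(
            sum(self.plasma_flow(c) for c in SYSTEMIC_TISSUES)
        )

    @property
    def ln_afferent_lymph_flow(self) -> float:
        """Total lymph drained into the lymph nodes (all tissues except LN)."""
        return float(
            sum(
                self.lymph_flow(c)
                for c in TISSUE_COMPARTMENTS
                if c is not CompartmentId.LYMPH_NODES
            )
        )

    # -- serialization -----------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        comp = self.compartments.copy()
        comp.insert(0, "record", "compartment")
        trans = self.transport.copy()
        trans.insert(0, "record", "transport")
        merged = pd.concat([comp, trans], ignore_index=True)
        merged.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, species_profile: str = "mouse") -> "PhysiologyTable":
        raw = pd.read_csv(path)
        comp = (
            raw[raw["record"] == "compartment"][_COMPARTMENT_COLUMNS]
            .reset_index(drop=True)
        )
        trans = (
            raw[raw["record"] == "transport"][_TRANSPORT_COLUMNS]
            .reset_index(drop=True)
        )
        for col in _COMPARTMENT_COLUMNS[1:]:
            comp[col] = comp[col].astype(float)
        for col in _TRANSPORT_COLUMNS[2:]:
            trans[col] = trans[col].astype(float)
        return cls(compartments=comp, transport=trans, species_profile=species_profile)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhysiologyTable":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        comp = pd.DataFrame(cfg["compartments"])[_COMPARTMENT_COLUMNS]
        trans = pd.DataFrame(cfg["transport"])[_TRANSPORT_COLUMNS]
        return cls(
            compartments=comp,
            transport=trans,
            species_profile=cfg.get("species_profile", "mouse"),
        )


def _default_table_path() -> Path:
    return Path(
        importlib.resources.files("abscopal") / "data" / "mouse_physiology.csv"
    )


def build_default_physiology(species_profile: str = "mouse") -> PhysiologyTable:
    """Load the shipped, validated murine physiology table.

    Organ volumes and plasma flows are standard mouse PBPK reference values;
    vascular/interstitial sub-volumes use fixed fractions of organ volume
    (7% / 20%); lymph flows are 0.2% of plasma flow.  Tumor rows hold
    reference sub-volumes for the nominal implant size; the dynamics module
    rescales them with the instantaneous tumor volume.
    """
    if species_profile != "mouse":
        raise ValueError(f"unsupported species profile: {species_profile!r}")
    table = PhysiologyTable.from_csv(_default_table_path(), species_profile)
    report = validate_physiology(table)
    if report:
        raise RuntimeError(f"shipped physiology table is inconsistent: {report}")
    return table


def validate_physiology(table: PhysiologyTable) -> list[str]:
    """Return a list of violated invariants (empty iff the table is valid)."""
    problems: list[str] = []
    seen = set(table.compartments["compartment"])
    expected = {c.value for c in CompartmentId}
    missing = expected - seen
    if missing:
        problems.append(f"missing compartments: {sorted(missing)}")
    extra = seen - expected
    if extra:
        problems.append(f"unknown compartments: {sorted(extra)}")

    for row in table.compartments.itertuples(index=False):
        is_blood = row.compartment in {c.value for c in BLOOD_COMPARTMENTS}
        for fieldname in ("total_volume_ml", "vascular_ml"):
            if getattr(row, fieldname) <= 0:
                problems.append(
                    f"{row.compartment}: {fieldname} must be > 0 "
                    f"(got {getattr(row, fieldname)})"
                )
        if is_blood:
            if row.interstitial_ml != 0:
                problems.append(
                    f"{row.compartment}: blood pools have no interstitium"
                )
        elif row.interstitial_ml <= 0:
            problems.append(f"{row.compartment}: interstitial_ml must be > 0")
        if row.vascular_ml + row.interstitial_ml > row.total_volume_ml * (1 + 1e-9):
            problems.append(
                f"{row.compartment}: sub-volumes exceed total volume"
            )
        if not is_blood:
            if row.plasma_flow_ml_day <= 0:
                problems.append(f"{row.compartment}: plasma_flow_ml_day must be > 0")
            if row.lymph_flow_ml_day < 0:
                problems.append(f"{row.compartment}: lymph_flow_ml_day negative")

    if not missing:
        # Plasma balance: lungs carry total venous return; arterial outflow
        # equals the sum of systemic tissue flows.
        q_sys = table.total_systemic_plasma_flow
        q_lungs = table.plasma_flow(CompartmentId.LUNGS)
        l_lungs = table.lymph_flow(CompartmentId.LUNGS)
        resid = q_lungs - (q_sys + l_lungs)
        if abs(resid) > 1e-9 * max(q_lungs, 1.0):
            problems.append(
                "plasma imbalance: lungs flow must equal systemic flow + lung "
                f"lymph (residual {resid:.6g} mL/day)"
            )

    # Transport completeness for every (trafficking species, tissue) pair.
    pairs = {
        (r.species, r.compartment) for r in table.transport.itertuples(index=False)
    }
    for sp in TRAFFICKING_SPECIES:
        for comp in TISSUE_COMPARTMENTS:
            if (sp.value, comp.value) not in pairs:
                problems.append(f"missing transport row for ({sp.value}, {comp.value})")
    for r in table.transport.itertuples(index=False):
        if r.extravasation_per_day < 0 or r.lymph_exit_per_day < 0:
            problems.append(
                f"negative transport constant for ({r.species}, {r.compartment})"
            )
    return problems
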