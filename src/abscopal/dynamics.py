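"""Coupled tumor-immune ODE right-hand side on the PBPK scaffold.

State layout
------------
For each of the six trafficking species (DC, M1, M2, TREG, TE1, APC) the
state holds, in order: arterial blood, venous blood, then for each tissue
compartment (fixed :data:`~abscopal.physiology.TISSUE_COMPARTMENTS` order)
a vascular and an interstitial entry -- 26 slots per species.  The tail of
the vector holds the confined species: naive CD8+ T cells in the lymph-node
interstitium (TN) and viable/dead tumor cells per tumor (TV1, TD1, TV2,
TD2).  All entries are absolute cell counts.

Dynamics
--------
Transport is linear in counts: vascular balance ``Q_i (C_art - C_vasc,i)``,
extravasation and lymph exit as first-order rate constants, lymph collected
by the lymph-node interstitium whose efferent feeds venous blood, and lungs
in series between the venous and arterial pools.  Interactions follow
mass-action bilinear kinetics with a saturating suppression denominator for
cytolysis and logistic regeneration of the naive pool; they act only in the
tumor interstitia and the lymph nodes.  Tumor vascular/interstitial
sub-volumes scale with the instantaneous tumor volume (7% / 50% of V(t),
floored at 1 mm^3) so concentrations dilute as tumors grow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ParameterSet
from .physiology import (
    BLOOD_COMPARTMENTS,
    CompartmentId,
    PhysiologyTable,
    SYSTEMIC_TISSUES,
    TISSUE_COMPARTMENTS,
    TRAFFICKING_SPECIES,
    TUMOR_COMPARTMENTS,
    SpeciesId,
)

#: Tumor sub-volume fractions of instantaneous tumor volume.
TUMOR_INTERSTITIAL_FRACTION = 0.50
TUMOR_VASCULAR_FRACTION = 0.07
#: Floor on the volume used for concentrations/flows, mm^3 (numerical guard
#: for regressed tumors).
TUMOR_VOLUME_FLOOR_MM3 = 1.0

_SLOTS_PER_SPECIES = 2 + 2 * len(TISSUE_COMPARTMENTS)  # 26


class StateLayout:
    """Fixed index map from (species, compartment, sub-compartment) to the
    flat state vector; pack/unpack round-trips exactly."""

    def __init__(self) -> None:
        self._index: dict[tuple[str, str, str], int] = {}
        pos = 0
        for sp in TRAFFICKING_SPECIES:
            self._index[(sp.value, CompartmentId.ARTERIAL_BLOOD.value, "vascular")] = pos
            self._index[(sp.value, CompartmentId.VENOUS_BLOOD.value, "vascular")] = pos + 1
            pos += 2
            for comp in TISSUE_COMPARTMENTS:
                self._index[(sp.value, comp.value, "vascular")] = pos
                self._index[(sp.value, comp.value, "interstitial")] = pos + 1
                pos += 2
        self.tn = pos
        self._index[(SpeciesId.TN.value, CompartmentId.LYMPH_NODES.value, "interstitial")] = pos
        pos += 1
        self.tv = {}
        self.td = {}
        for comp in TUMOR_COMPARTMENTS:
            self._index[(SpeciesId.TV.value, comp.value, "interstitial")] = pos
            self.tv[comp] = pos
            self._index[(SpeciesId.TD.value, comp.value, "interstitial")] = pos + 1
            self.td[comp] = pos + 1
            pos += 2
        self.size = pos

    def index(self, sp: SpeciesId, comp: CompartmentId, sub: str = "vascular") -> int:
        return self._index[(sp.value, comp.value, sub)]

    def species_slots(self, sp: SpeciesId) -> np.ndarray:
        """All state indices belonging to one trafficking species."""
        i = TRAFFICKING_SPECIES.index(sp)
        return np.arange(i * _SLOTS_PER_SPECIES, (i + 1) * _SLOTS_PER_SPECIES)

    def labels(self) -> list[tuple[str, str, str]]:
        out = [None] * self.size
        for key, i in self._index.items():
            out[i] = key
        return out

    def pack(self, values: dict[tuple[str, str, str], float]) -> np.ndarray:
        x = np.zeros(self.size)
        for key, v in values.items():
            x[self._index[key]] = v
        return x

    def unpack(self, x: np.ndarray) -> dict[tuple[str, str, str], float]:
        return {key: float(x[i]) for key, i in self._index.items()}


LAYOUT = StateLayout()


# ---------------------------------------------------------------------------
# Interaction kernel (swappable closed forms)
# ---------------------------------------------------------------------------

def tumor_volume(tv: float, td: float, v_cell_mm3: float) -> float:
    """Tumor volume in mm^3 from viable + dead cell counts."""
    if tv < 0 or td < 0:
        raise ValueError("cell counts must be non-negative")
    return (tv + td) * v_cell_mm3


def cytolysis_rate(
    te1_conc: float,
    tv: float,
    k_rc1: float,
    treg_conc: float,
    m2_conc: float,
    s_treg: float,
    s_m2: float,
) -> float:
    """Effector-T-cell killing of viable tumor cells, suppressed by Tregs
    and M2 macrophages (cells/day; removed from TV, added to TD)."""
    if min(te1_conc, tv, treg_conc, m2_conc) < 0:
        raise ValueError("inputs must be non-negative")
    return k_rc1 * te1_conc * tv / (1.0 + s_treg * treg_conc + s_m2 * m2_conc)


def phagocytosis_rates(
    dc: float,
    apc: float,
    m1: float,
    tv: float,
    td: float,
    params: ParameterSet,
    interstitial_ml: float,
) -> dict[str, float]:
    """Phagocytic removal of viable/dead tumor cells and the matching
    DC->APC and M1->APC maturation fluxes (all in cells/day).

    One phagocytic encounter removes one tumor cell and matures one
    phagocyte, so removal and conversion fluxes balance by construction;
    APCs phagocytose with the DC rate constants.
    """
    if interstitial_ml <= 0:
        raise ValueError("interstitial volume must be positive")
    if min(dc, apc, m1, tv, td) < 0:
        raise ValueError("inputs must be non-negative")
    v = interstitial_ml
    dcapc_conc = (dc + apc) / v
    m1_conc = m1 / v
    tv_conc = tv / v
    td_conc = td / v
    return {
        "tv_removal": (params.ac_dc * dcapc_conc + params.ac_m1 * m1_conc) * tv,
        "td_removal": (params.ac_dead_dc * dcapc_conc + params.ac_dead_m1 * m1_conc) * td,
        "dc_to_apc": dc * (params.ac_dc * tv_conc + params.ac_dead_dc * td_conc),
        "m1_to_apc": m1 * (params.ac_m1 * tv_conc + params.ac_dead_m1 * td_conc),
    }


def ln_priming_rates(
    tn: float,
    apc_ln_conc: float,
    params: ParameterSet,
    group: str = "control",
) -> dict[str, float]:
    """Naive-pool regeneration, APC-driven activation, and effector output
    in the lymph nodes (cells/day)."""
    if params.tn0 <= 0:
        raise ValueError("tn0 must be positive")
    if min(tn, apc_ln_conc) < 0:
        raise ValueError("inputs must be non-negative")
    regen = params.k_prol_tn * tn * (1.0 - tn / params.tn0)
    activation = params.k_tn(group) * apc_ln_conc * tn
    return {
        "tn_regen": regen,
        "tn_activation": activation,
        "te1_production": params.n_exp * activation,
    }


def debris_clearance(td: float, clear_c_dead: float) -> float:
    """First-order removal of dead-cell debris (leaves the system)."""
    if td < 0:
        raise ValueError("Td must be non-negative")
    return clear_c_dead * td


# ---------------------------------------------------------------------------
# Assembled system
# ---------------------------------------------------------------------------

def tumor_subvolumes_ml(volume_mm3: float) -> tuple[float, float]:
    """(vascular, interstitial) sub-volumes in mL for a tumor of given size."""
    v_eff = max(volume_mm3, TUMOR_VOLUME_FLOOR_MM3) * 1.0e-3
    return TUMOR_VASCULAR_FRACTION * v_eff, TUMOR_INTERSTITIAL_FRACTION * v_eff


@dataclass
class QspSystem:
    """Right-hand side of the coupled ODE system for one treatment arm.

    The linear part (transport, birth, death) is pre-assembled into a
    constant matrix/vector; tumor vascular efflux (volume-dependent), the
    tumor interaction terms and lymph-node priming are added per call.
    Switches allow tests to isolate transport from sources/sinks.
    """

    params: ParameterSet
    physiology: PhysiologyTable
    group: str = "control"
    enable_transport: bool = True
    enable_sources: bool = True
    enable_deaths: bool = True
    enable_interactions: bool = True

    def __post_init__(self) -> None:
        self.layout = LAYOUT
        self._build_linear_part()

    # -- linear assembly ---------------------------------------------------
    def _build_linear_part(self) -> None:
        lay = self.layout
        phys = self.physiology
        n = lay.size
        A = np.zeros((n, n))
        b = np.zeros(n)
        v_art = phys.vascular_volume(CompartmentId.ARTERIAL_BLOOD)
        v_ven = phys.vascular_volume(CompartmentId.VENOUS_BLOOD)
        q_lungs = phys.plasma_flow(CompartmentId.LUNGS)
        v_lungs = phys.vascular_volume(CompartmentId.LUNGS)

        self._tumor_q = {c: phys.plasma_flow(c) for c in TUMOR_COMPARTMENTS}
        self._tumor_vasc_idx = {}

        for sp in TRAFFICKING_SPECIES:
            i_art = lay.index(sp, CompartmentId.ARTERIAL_BLOOD)
            i_ven = lay.index(sp, CompartmentId.VENOUS_BLOOD)
            i_lnint = lay.index(sp, CompartmentId.LYMPH_NODES, "interstitial")
            if self.enable_transport:
                # venous -> lungs -> arterial series path
                i_lv = lay.index(sp, CompartmentId.LUNGS, "vascular")
                i_li = lay.index(sp, CompartmentId.LUNGS, "interstitial")
                A[i_ven, i_ven] -= q_lungs / v_ven
                A[i_lv, i_ven] += q_lungs / v_ven
                A[i_lv, i_lv] -= q_lungs / v_lungs
                A[i_art, i_lv] += q_lungs / v_lungs
                kex = phys.extravasation(sp, CompartmentId.LUNGS)
                klym = phys.lymph_exit(sp, CompartmentId.LUNGS)
                A[i_lv, i_lv] -= kex
                A[i_li, i_lv] += kex
                A[i_li, i_li] -= klym
                A[i_lnint, i_li] += klym
                for comp in SYSTEMIC_TISSUES:
                    q = phys.plasma_flow(comp)
                    i_v = lay.index(sp, comp, "vascular")
                    i_i = lay.index(sp, comp, "interstitial")
                    A[i_art, i_art] -= q / v_art
                    A[i_v, i_art] += q / v_art
                    if comp in TUMOR_COMPARTMENTS:
                        # vascular efflux uses the dynamic tumor volume
                        self._tumor_vasc_idx.setdefault(comp, {})[sp] = i_v
                    else:
                        v_v = phys.vascular_volume(comp)
                        A[i_v, i_v] -= q / v_v
                        A[i_ven, i_v] += q / v_v
                    kex = phys.extravasation(sp, comp)
                    klym = phys.lymph_exit(sp, comp)
                    A[i_v, i_v] -= kex
                    A[i_i, i_v] += kex
                    A[i_i, i_i] -= klym
                    if comp is CompartmentId.LYMPH_NODES:
                        A[i_ven, i_i] += klym  # LN efferent lymph -> venous
                    else:
                        A[i_lnint, i_i] += klym
            if self.enable_deaths:
                d = float(self.params.death_rates[sp.value])
                slots = lay.species_slots(sp)
                A[slots, slots] -= d
            if self.enable_sources:
                b[i_ven] += float(self.params.source_rates.get(sp.value, 0.0))
        self._A = A
        self._b = b
        # cache frequently used indices
        self._i_ven = {
            sp: lay.index(sp, CompartmentId.VENOUS_BLOOD) for sp in TRAFFICKING_SPECIES
        }
        self._ln_int_vol = phys.interstitial_volume(CompartmentId.LYMPH_NODES)
        self._i_apc_ln = lay.index(SpeciesId.APC, CompartmentId.LYMPH_NODES, "interstitial")
        self._tumor_int_idx = {
            comp: {
                sp: lay.index(sp, comp, "interstitial")
                for sp in TRAFFICKING_SPECIES
            }
            for comp in TUMOR_COMPARTMENTS
        }
        # vectorized index blocks for the hot path
        self._i_te1_ln = lay.index(
            SpeciesId.TE1, CompartmentId.LYMPH_NODES, "interstitial"
        )
        self._ven_idx = np.array(
            [self._i_ven[sp] for sp in TRAFFICKING_SPECIES]
        )
        self._tumor_blocks = []
        for comp in TUMOR_COMPARTMENTS:
            idx = self._tumor_int_idx[comp]
            self._tumor_blocks.append(
                {
                    "comp": comp,
                    "q": self._tumor_q[comp],
                    "vasc_idx": np.array(
                        [
                            self._tumor_vasc_idx.get(comp, {}).get(sp, -1)
                            for sp in TRAFFICKING_SPECIES
                        ]
                    ),
                    "i_tv": lay.tv[comp],
                    "i_td": lay.td[comp],
                    "i_dc": idx[SpeciesId.DC],
                    "i_apc": idx[SpeciesId.APC],
                    "i_m1": idx[SpeciesId.M1],
                    "i_m2": idx[SpeciesId.M2],
                    "i_treg": idx[SpeciesId.TREG],
                    "i_te1": idx[SpeciesId.TE1],
                }
            )

    # -- right-hand side ---------------------------------------------------
    def rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        """Fast RHS used by the integrator (tolerant of tiny solver
        undershoot: interaction terms see counts clamped at zero)."""
        return self._A @ x + self._b + self._nonlinear(t, x)

    def _nonlinear(self, t: float, x: np.ndarray) -> np.ndarray:
        """Volume-dependent tumor vascular efflux, tumor interactions, and
        lymph-node priming (everything outside the constant linear part).

        Inlined form of the kernel functions (``cytolysis_rate``,
        ``phagocytosis_rates``, ``ln_priming_rates``, ``debris_clearance``)
        for the integrator hot path; equivalence is asserted by test.
        """
        dx = np.zeros_like(x)
        p = self.params
        v_cell = p.v_cell_mm3
        k_rc1 = p.k_rc1(self.group)

        for blk in self._tumor_blocks:
            tv = x[blk["i_tv"]]
            td = x[blk["i_td"]]
            if tv < 0.0:
                tv = 0.0
            if td < 0.0:
                td = 0.0
            v_eff = (tv + td) * v_cell
            if v_eff < TUMOR_VOLUME_FLOOR_MM3:
                v_eff = TUMOR_VOLUME_FLOOR_MM3
            v_eff *= 1.0e-3
            v_vasc = TUMOR_VASCULAR_FRACTION * v_eff
            v_int = TUMOR_INTERSTITIAL_FRACTION * v_eff

            if self.enable_transport:
                vi = blk["vasc_idx"]
                eff = (blk["q"] / v_vasc) * x[vi]
                dx[vi] -= eff
                dx[self._ven_idx] += eff

            if self.enable_interactions:
                dc = max(x[blk["i_dc"]], 0.0)
                apc = max(x[blk["i_apc"]], 0.0)
                m1 = max(x[blk["i_m1"]], 0.0)
                m2 = max(x[blk["i_m2"]], 0.0)
                treg = max(x[blk["i_treg"]], 0.0)
                te1 = max(x[blk["i_te1"]], 0.0)

                cyt = (
                    k_rc1 * (te1 / v_int) * tv
                    / (1.0 + p.s_treg * treg / v_int + p.s_m2 * m2 / v_int)
                )
                dcapc_conc = (dc + apc) / v_int
                m1_conc = m1 / v_int
                tv_removal = (p.ac_dc * dcapc_conc + p.ac_m1 * m1_conc) * tv
                td_removal = (p.ac_dead_dc * dcapc_conc + p.ac_dead_m1 * m1_conc) * td
                dc_to_apc = dc * (p.ac_dc * tv + p.ac_dead_dc * td) / v_int
                m1_to_apc = m1 * (p.ac_m1 * tv + p.ac_dead_m1 * td) / v_int

                dx[blk["i_tv"]] += p.lg_tumor * tv - cyt - tv_removal
                dx[blk["i_td"]] += cyt - td_removal - p.clear_c_dead * td
                dx[blk["i_dc"]] -= dc_to_apc
                dx[blk["i_m1"]] -= m1_to_apc
                dx[blk["i_apc"]] += dc_to_apc + m1_to_apc

        if self.enable_interactions:
            tn = max(x[self.layout.tn], 0.0)
            apc_ln_conc = max(x[self._i_apc_ln], 0.0) / self._ln_int_vol
            activation = p.k_tn(self.group) * apc_ln_conc * tn
            dx[self.layout.tn] += (
                p.k_prol_tn * tn * (1.0 - tn / p.tn0) - activation
            )
            dx[self._i_te1_ln] += p.n_exp * activation
        return dx

    def _active_columns(self) -> np.ndarray:
        """State indices the nonlinear part depends on (Jacobian support)."""
        lay = self.layout
        cols = {lay.tn, self._i_apc_ln}
        for comp in TUMOR_COMPARTMENTS:
            cols.add(lay.tv[comp])
            cols.add(lay.td[comp])
            cols.update(self._tumor_int_idx[comp].values())
            if self.enable_transport:
                cols.update(self._tumor_vasc_idx.get(comp, {}).values())
        return np.array(sorted(cols))

    def jac(self, t: float, x: np.ndarray) -> np.ndarray:
        """Jacobian: exact constant linear part plus forward-difference
        corrections on the columns the nonlinear terms touch."""
        J = self._A.copy()
        if not (self.enable_transport or self.enable_interactions):
            return J
        cols = self._cols if hasattr(self, "_cols") else None
        if cols is None:
            cols = self._active_columns()
            self._cols = cols
        g0 = self._nonlinear(t, x)
        for j in cols:
            h = 1e-6 * max(abs(x[j]), 1.0)
            xp = x.copy()
            xp[j] += h
            J[:, j] += (self._nonlinear(t, xp) - g0) / h
        return J

    # -- initial conditions ------------------------------------------------
    def equilibrium_state(self) -> np.ndarray:
        """Tumor-free immune steady state with tumor beds at the implant
        reference volume; TN at its baseline TN0, tumors empty.

        With TV = TD = 0 the trafficking dynamics are linear, so the steady
        state solves ``A' x = -b`` exactly (A' includes tumor vascular
        efflux at the reference volume).
        """
        lay = self.layout
        A = self._A.copy()
        if self.enable_transport:
            v_vasc, _ = tumor_subvolumes_ml(self.params.vi_tumor0_mm3)
            for comp in TUMOR_COMPARTMENTS:
                q = self._tumor_q[comp]
                for sp, i_v in self._tumor_vasc_idx[comp].items():
                    A[i_v, i_v] -= q / v_vasc
                    A[self._i_ven[sp], i_v] += q / v_vasc
        x = np.zeros(lay.size)
        ntraf = len(TRAFFICKING_SPECIES) * _SLOTS_PER_SPECIES
        if self.enable_sources and self.enable_deaths:
            block = A[:ntraf, :ntraf]
            x[:ntraf] = np.linalg.solve(block, -self._b[:ntraf])
            x[:ntraf] = np.clip(x[:ntraf], 0.0, None)
        x[lay.tn] = self.params.tn0
        return x

    def initial_state(self) -> np.ndarray:
        """Immune steady state with the implant placed in both tumors."""
        x = self.equilibrium_state()
        tv0 = self.params.vi_tumor0_mm3 / self.params.v_cell_mm3
        for comp in TUMOR_COMPARTMENTS:
            x[self.layout.tv[comp]] = tv0
        return x


def assemble_rhs(
    t: float,
    state: np.ndarray,
    params: ParameterSet,
    physiology: PhysiologyTable,
    group: str = "control",
) -> np.ndarray:
    """Validated single-call RHS evaluation.

    Raises on NaN or negative state entries, naming the offending index.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (LAYOUT.size,):
        raise ValueError(f"state must have length {LAYOUT.size}")
    bad = np.where(~np.isfinite(state) | (state < 0))[0]
    if bad.size:
        label = LAYOUT.labels()[bad[0]]
        raise ValueError(
            f"invalid state entry at index {bad[0]} {label}: {state[bad[0]]}"
        )
    system = QspSystem(params=params, physiology=physiology, group=group)
    return system.rhs(t, state)
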