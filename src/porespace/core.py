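"""Volume and porosity bookkeeping for the three-class pore-space model.

A soil layer is represented by partial volumes: mineral and organic solids,
a static *textural* pore volume inherent to the particle packing, and
dynamic *structural* pore volumes split over three size classes bounded at
equivalent diameters of 30 and 100 um (micropores < 30 um, mesopores
30-100 um, macropores > 100 um).  Micropores and mesopores together form
the soil matrix; macropores are the remainder.  Volumes, not porosities,
are the canonical state: all porosities, the bulk density and the layer
thickness are derived quantities, so the additivity identities

    phi = phi_mat + phi_mac = phi_t + phi_s

hold by construction.  Units are cm-g-year throughout the package; public
helpers convert from the customary field units (kg/ha, t/ha, per day).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

__all__ = [
    "DAYS_PER_YEAR",
    "PoreSpaceState",
    "PorosityProfile",
    "textural_volumes",
    "porosities",
    "state_from_porosities",
    "per_day_to_per_year",
    "biomass_areal_to_volumetric",
    "production_areal_to_volumetric",
]

#: Calendar convention used for every per-day -> per-year conversion.
DAYS_PER_YEAR = 365.0

#: Relative tolerance below which a negative volume is treated as ODE
#: round-off and clamped to zero rather than raised as an error.
NEGATIVE_VOLUME_RTOL = 1e-9


def _clamp_volume(v: float, v_total: float, name: str) -> float:
    """Clamp round-off negatives to 0; genuinely negative volumes raise."""
    if v >= 0.0:
        return v
    if v > -NEGATIVE_VOLUME_RTOL * max(v_total, 1.0):
        return 0.0
    raise ValueError(f"{name} is negative ({v:g}) beyond round-off tolerance")


@dataclass
class PoreSpaceState:
    """Partial-volume state of one homogeneous soil layer.

    Parameters
    ----------
    A_xs:
        Nominal cross-sectional area [cm^2].
    V_s_mineral, V_s_organic:
        Mineral and organic solid volumes [cm^3].  Organic solids default
        to zero; the slot exists so that SOM volume change can act as a
        pore-change agent.
    V_p_textural:
        Static textural pore volume [cm^3]; constant once set.
    V_ps_mic, V_ps_mes:
        Structural micropore and mesopore volumes [cm^3].
    V_mac:
        Macropore volume [cm^3] (all macropores are structural).
    f_t_mic:
        Fraction of the textural pore volume in the micropore class [-].
    """

    A_xs: float = 1.0
    V_s_mineral: float = 0.0
    V_s_organic: float = 0.0
    V_p_textural: float = 0.0
    V_ps_mic: float = 0.0
    V_ps_mes: float = 0.0
    V_mac: float = 0.0
    f_t_mic: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_t_mic <= 1.0:
            raise ValueError(f"f_t_mic must lie in [0, 1], got {self.f_t_mic}")
        if self.A_xs <= 0.0:
            raise ValueError("A_xs must be positive")
        vt = (self.V_s_mineral + self.V_s_organic + self.V_p_textural
              + self.V_ps_mic + self.V_ps_mes + self.V_mac)
        for name in ("V_s_mineral", "V_s_organic", "V_p_textural",
                     "V_ps_mic", "V_ps_mes", "V_mac"):
            setattr(self, name, _clamp_volume(getattr(self, name), vt, name))

    @property
    def V_s(self) -> float:
        """Total solid volume [cm^3]."""
        return self.V_s_mineral + self.V_s_organic

    @property
    def V_t(self) -> float:
        """Total layer volume [cm^3] (recomputed, never stored)."""
        return (self.V_s + self.V_p_textural
                + self.V_ps_mic + self.V_ps_mes + self.V_mac)

    @property
    def V_pt_mic(self) -> float:
        """Textural micropore volume [cm^3]."""
        return self.f_t_mic * self.V_p_textural

    @property
    def V_pt_mes(self) -> float:
        """Textural mesopore volume [cm^3]."""
        return (1.0 - self.f_t_mic) * self.V_p_textural

    @property
    def V_mic(self) -> float:
        return self.V_ps_mic + self.V_pt_mic

    @property
    def V_mes(self) -> float:
        return self.V_ps_mes + self.V_pt_mes

    @property
    def V_mat(self) -> float:
        """Matrix pore volume (micropores + mesopores) [cm^3]."""
        return self.V_mic + self.V_mes

    def copy(self, **changes) -> "PoreSpaceState":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PoreSpaceState":
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class PorosityProfile:
    """Derived porosities, bulk density and layer thickness of a state."""

    phi: float                 # total porosity [cm^3/cm^3]
    phi_t: float               # textural porosity
    phi_s: float               # structural porosity
    phi_mat: float             # matrix porosity (micro + meso)
    phi_mac: float             # macroporosity
    phi_mic: float             # microporosity (< 30 um)
    phi_mes: float             # mesoporosity (30-100 um)
    phi_t_mic: float           # textural micropores
    phi_t_mes: float           # textural mesopores
    phi_s_mic: float           # structural micropores
    phi_s_mes: float           # structural mesopores
    bulk_density: float        # gamma_b = gamma_s * (1 - phi) [g/cm^3]
    layer_thickness: float     # V_t / A_xs [cm]

    def to_dict(self) -> dict:
        return asdict(self)


def per_day_to_per_year(rate_per_day: float) -> float:
    """Convert a per-day rate to per-year (365 days/yr convention)."""
    return rate_per_day * DAYS_PER_YEAR


def biomass_areal_to_volumetric(kg_per_ha: float, depth_cm: float) -> float:
    """Areal biomass [kg/ha] over a layer [cm] -> concentration [g/cm^3].

    1 kg/ha = 1e3 g / 1e8 cm^2 = 1e-5 g/cm^2.  E.g. 655 kg/ha over
    0-30 cm is 2.1833e-4 g/cm^3 (= 218.33 g/m^3).
    """
    if depth_cm <= 0.0:
        raise ValueError("depth_cm must be positive")
    return kg_per_ha * 1e-5 / depth_cm


def production_areal_to_volumetric(t_per_ha_yr: float, fraction_to_soil: float,
                                   depth_cm: float) -> float:
    """Above-ground production [t/ha/yr] -> root input rate [g cm^-3 yr^-1].

    1 t/ha = 1e6 g / 1e8 cm^2 = 0.01 g/cm^2; a fraction of it enters the
    soil as roots, spread over ``depth_cm``.  E.g. 30% of 10 t/ha/yr over
    a 25 cm layer is 0.0012 g cm^-3 yr^-1.
    """
    if depth_cm <= 0.0:
        raise ValueError("depth_cm must be positive")
    if not 0.0 <= fraction_to_soil <= 1.0:
        raise ValueError("fraction_to_soil must lie in [0, 1]")
    return t_per_ha_yr * 0.01 * fraction_to_soil / depth_cm


def textural_volumes(phi_min: float, dz_min: float, A_xs: float = 1.0
                     ) -> tuple[float, float]:
    """Static textural pore and mineral solid volumes of a layer.

    Both derive from the user-defined minimum matrix porosity ``phi_min``
    and minimum layer thickness ``dz_min`` of the purely mineral soil
    (no organic matter, no structural pores)::

        V_p_textural = phi_min * dz_min * A_xs
        V_s_mineral  = V_p_textural * (1/phi_min - 1)

    Returns
    -------
    (V_p_textural, V_s_mineral) in cm^3; both constant thereafter.
    """
    if not 0.0 < phi_min < 1.0:
        raise ValueError(f"phi_min must lie in (0, 1), got {phi_min}")
    if dz_min <= 0.0:
        raise ValueError("dz_min must be positive")
    if A_xs <= 0.0:
        raise ValueError("A_xs must be positive")
    v_pt = phi_min * dz_min * A_xs
    v_sm = v_pt * (1.0 / phi_min - 1.0)
    return v_pt, v_sm


def porosities(state: PoreSpaceState, gamma_s: float) -> PorosityProfile:
    """Derive all porosities, bulk density and thickness from a state.

    ``gamma_s`` is the soil particle density [g/cm^3]; the bulk density
    follows as ``gamma_b = gamma_s * (1 - phi)``.
    """
    if gamma_s <= 0.0:
        raise ValueError("gamma_s must be positive")
    vt = state.V_t
    if vt <= 0.0:
        raise ValueError("total volume is zero; porosities undefined")
    phi_mic = state.V_mic / vt
    phi_mes = state.V_mes / vt
    phi_mac = state.V_mac / vt
    phi_mat = phi_mic + phi_mes
    phi = phi_mat + phi_mac
    phi_t = state.V_p_textural / vt
    phi_s = (state.V_ps_mic + state.V_ps_mes + state.V_mac) / vt
    return PorosityProfile(
        phi=phi, phi_t=phi_t, phi_s=phi_s,
        phi_mat=phi_mat, phi_mac=phi_mac,
        phi_mic=phi_mic, phi_mes=phi_mes,
        phi_t_mic=state.V_pt_mic / vt, phi_t_mes=state.V_pt_mes / vt,
        phi_s_mic=state.V_ps_mic / vt, phi_s_mes=state.V_ps_mes / vt,
        bulk_density=gamma_s * (1.0 - phi),
        layer_thickness=vt / state.A_xs,
    )


def state_from_porosities(phi_mic: float, phi_mes: float, phi_mac: float,
                          phi_min: float, f_t_mic: float,
                          dz: float, A_xs: float = 1.0) -> PoreSpaceState:
    """Build a partial-volume state matching target class porosities.

    Follows the model convention that the textural porosity of the layer
    equals ``phi_min`` (the matrix porosity of the closest particle
    packing) at the reference volume ``dz * A_xs``; structural volumes
    absorb whatever each class porosity holds beyond its textural share.
    Round-trips with :func:`porosities` to machine precision.
    """
    phi = phi_mic + phi_mes + phi_mac
    if not 0.0 <= phi < 1.0:
        raise ValueError(f"total porosity {phi:g} outside [0, 1)")
    if phi_min > phi_mic + phi_mes + 1e-9:
        raise ValueError("phi_min exceeds the matrix porosity; no valid state")
    v_t = dz * A_xs
    v_s = (1.0 - phi) * v_t
    v_pt = phi_min * v_t

    def _floor(raw: float) -> float:
        # absorb round-off-scale deficits only; larger ones mean the
        # textural share exceeds the class total and must raise below
        return 0.0 if -2e-9 * v_t < raw < 0.0 else raw

    state = PoreSpaceState(
        A_xs=A_xs,
        V_s_mineral=v_s,
        V_s_organic=0.0,
        V_p_textural=v_pt,
        V_ps_mic=_floor(phi_mic * v_t - f_t_mic * v_pt),
        V_ps_mes=_floor(phi_mes * v_t - (1.0 - f_t_mic) * v_pt),
        V_mac=phi_mac * v_t,
        f_t_mic=f_t_mic,
    )
    return state
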