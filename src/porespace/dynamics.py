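"""Biologically driven pore-space dynamics.

Three layers of machinery, in the order the method runs:

1. *Pore-change factors*: every structure-forming agent (root growth and
   decay, earthworm ingestion and casting, microbial OM turnover,
   swell/shrink) changes structural pore volume in each size class as a
   linear function of the change in solid volume it causes,
   dV_ps(i)/dt = sum_j f_ij dV_s(j)/dt.  A process whose three factors
   sum to -1 conserves total soil volume.

2. *Steady-flux regime*: with casting and root biomass at steady state
   (E_c = E_i, R_g = R_d) the total porosity is constant but root turnover
   and bioturbation redistribute pore space between classes; the three
   class porosities follow an ODE system with a closed-form fixed point.

3. *Surface-casting regime*: on bare soil a fraction f_surf of the casts
   is deposited at the surface; the factor sum then exceeds -1, total soil
   volume (layer thickness) grows, and bulk density falls.  f_surf rises
   linearly as macroporosity drops below a threshold phi_mac_c, which is
   what lets a compacted soil recover.

Void ratios: eps = phi_mat/(1-phi) is the matrix void ratio of the soil,
eps_casts that of freshly egested casts.  At steady state on bare soil the
matrix void ratio equals eps_casts exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .core import (DAYS_PER_YEAR, PoreSpaceState, PorosityProfile,
                   porosities, state_from_porosities)

__all__ = [
    "RootParams", "WormParams", "ShrinkageParams", "PoreChangeFactors",
    "Trajectory", "InfeasibleSteadyStateError",
    "solids_rate", "table3_factors", "pore_change_step",
    "swell_shrink_step", "steady_flux_rates", "steady_state",
    "turnover_rate", "surface_cast_fraction", "bioturbation_volume_rates",
    "integrate", "time_to_equilibrium", "NOT_REACHED",
]

#: Marker returned by :func:`time_to_equilibrium` when the trajectory
#: never enters the tolerance band.
NOT_REACHED = math.inf


class InfeasibleSteadyStateError(ValueError):
    """Raised when the closed-form steady state has a negative porosity.

    The steady-state matrix porosity can turn negative when root-driven
    macropore production outpaces what bioturbation can refill — a
    physically impossible configuration that the closed form admits on
    paper but which realistic parameter values do not produce.
    """


# ---------------------------------------------------------------------------
# Parameter containers


@dataclass
class RootParams:
    """Root turnover parameters.

    Only the product ``B_r * tau_r`` (the steady-state root production
    rate, g cm^-3 yr^-1) enters the steady-flux equations; ``R_g`` and
    ``R_d`` may be set independently for transient solids budgets and
    default to that product.
    """

    B_r: float = 0.0        # root biomass [g/cm^3]
    tau_r: float = 0.0      # root turnover rate [1/yr]
    gamma_r: float = 1.2    # root tissue density [g/cm^3]
    f_r_c: float = 0.2      # coarse-root fraction [-]
    R_g: float | None = None   # growth rate [g cm^-3 yr^-1]
    R_d: float | None = None   # decay rate [g cm^-3 yr^-1]

    def __post_init__(self) -> None:
        if min(self.B_r, self.tau_r, self.gamma_r) < 0:
            raise ValueError("root parameters must be non-negative")
        if not 0.0 <= self.f_r_c <= 1.0:
            raise ValueError("f_r_c must lie in [0, 1]")
        if self.R_g is None:
            self.R_g = self.B_r * self.tau_r
        if self.R_d is None:
            self.R_d = self.B_r * self.tau_r

    @property
    def production(self) -> float:
        """Steady-state root production B_r * tau_r [g cm^-3 yr^-1]."""
        return self.B_r * self.tau_r

    @classmethod
    def from_production(cls, R_g: float, gamma_r: float = 1.2,
                        f_r_c: float = 0.2) -> "RootParams":
        """Build from the production rate alone (B_r * tau_r = R_g)."""
        return cls(B_r=R_g, tau_r=1.0, gamma_r=gamma_r, f_r_c=f_r_c)


@dataclass
class WormParams:
    """Earthworm bioturbation parameters.

    The soil-mass turnover can be given directly (``tau_s``, 1/yr) or as
    ingestion rate times biomass concentration (``I_r`` in g soil per g
    biomass per *year*, ``E_bio`` in g/cm^3), in which case
    tau_s = I_r * E_bio / gamma_b at the current bulk density.
    """

    eps_casts: float = 0.6        # cast void ratio [-]
    f_casts_mic: float = 0.8      # micropore fraction of cast pore space [-]
    tau_s: float | None = None    # soil mass turnover [1/yr]
    I_r: float | None = None      # ingestion rate [g g^-1 yr^-1]
    E_bio: float | None = None    # earthworm biomass [g/cm^3]
    phi_mac_c: float | None = None  # surface-casting threshold [cm^3/cm^3]
    E_c: float | None = None      # in-soil casting rate [g cm^-3 yr^-1]
    E_i: float | None = None      # ingestion rate [g cm^-3 yr^-1]

    def __post_init__(self) -> None:
        if self.eps_casts < 0:
            raise ValueError("eps_casts must be non-negative")
        if not 0.0 <= self.f_casts_mic <= 1.0:
            raise ValueError("f_casts_mic must lie in [0, 1]")
        if self.tau_s is None and (self.I_r is None or self.E_bio is None):
            raise ValueError("provide tau_s, or I_r together with E_bio")

    def tau_s_at(self, gamma_b: float) -> float:
        """Turnover rate at bulk density ``gamma_b`` [1/yr]."""
        if self.tau_s is not None:
            return self.tau_s
        return turnover_rate(self.I_r, self.E_bio, gamma_b)


@dataclass(frozen=True)
class ShrinkageParams:
    """Swell/shrink coupling: slope of the shrinkage characteristic."""

    f_slope: float       # d(matrix pore volume)/d(water volume), in [0, 1]
    V_w: float = 0.0     # soil water volume [cm^3]

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_slope <= 1.0:
            raise ValueError("f_slope must lie in [0, 1]")


@dataclass(frozen=True)
class PoreChangeFactors:
    """Per-process pore-change factor triples, ordered (f_mac, f_mes, f_mic).

    Units: m^3 pore created (+) or destroyed (-) per m^3 solid-volume
    change by the process.  Volume-conserving processes have triples
    summing to -1.
    """

    root_growth: tuple[float, float, float]
    root_decay: tuple[float, float, float]
    worm_casting: tuple[float, float, float]
    worm_ingestion: tuple[float, float, float]
    som_turnover: tuple[float, float, float] | None = None
    shrinkage: tuple[float, float, float] | None = None

    def as_dict(self) -> dict[str, tuple[float, float, float]]:
        d = asdict(self)
        return {k: v for k, v in d.items() if v is not None}


# ---------------------------------------------------------------------------
# Elementary rates and factor tables


def solids_rate(roots: RootParams, worms: WormParams, V_t: float,
                gamma_s: float) -> float:
    """Net rate of solid-volume change [cm^3/yr].

    dV_s/dt = V_t * [ (R_g - R_d)/gamma_r + (E_c - E_i)/gamma_s ].
    Root growth/decay moves root tissue (density gamma_r); earthworm
    casting/ingestion moves mineral soil (particle density gamma_s).
    """
    if roots.gamma_r <= 0 or gamma_s <= 0:
        raise ValueError("densities must be positive")
    e_c = worms.E_c if worms.E_c is not None else 0.0
    e_i = worms.E_i if worms.E_i is not None else 0.0
    return V_t * ((roots.R_g - roots.R_d) / roots.gamma_r
                  + (e_c - e_i) / gamma_s)


def _structural_shares(phi_s_mes: float, phi_s_mic: float,
                       f_t_mic: float) -> tuple[float, float]:
    """(s_mes, s_mic) shares of the structural matrix pore space.

    When the structural matrix pools are exhausted the shares are taken
    from the textural partition instead (what remains to be ingested).
    """
    tot = phi_s_mes + phi_s_mic
    if tot < 1e-12:
        return 1.0 - f_t_mic, f_t_mic
    return phi_s_mes / tot, phi_s_mic / tot


def table3_factors(phi_s_mes: float, phi_s_mic: float, eps: float,
                   worms: WormParams, roots: RootParams,
                   f_t_mic: float = 1.0) -> PoreChangeFactors:
    """Pore-change factor triples for the four root/earthworm processes.

    Conventions (each triple ordered mac, mes, mic; each sums to -1):

    * root growth compresses structural meso- and micropores in
      proportion to their volumes and never enters macropores;
    * root decay opens macropores (coarse roots) and mesopores (fine);
    * casting fills macropores and creates cast pore space split between
      micro- and mesopores by ``f_casts_mic``;
    * ingestion removes matrix (solids plus its void ratio eps of pores,
      pro-rata over the structural pools) and leaves a macropore.
    """
    s_mes, s_mic = _structural_shares(phi_s_mes, phi_s_mic, f_t_mic)
    e_c = worms.eps_casts
    f_cm = worms.f_casts_mic
    return PoreChangeFactors(
        root_growth=(0.0, -s_mes, -s_mic),
        root_decay=(-roots.f_r_c, roots.f_r_c - 1.0, 0.0),
        worm_casting=(-(1.0 + e_c), (1.0 - f_cm) * e_c, f_cm * e_c),
        worm_ingestion=(-(1.0 + eps), s_mes * eps, s_mic * eps),
    )


def pore_change_step(dV_s_by_agent: dict[str, float],
                     factors: PoreChangeFactors
                     ) -> tuple[float, float, float, float]:
    """Structural pore-volume changes for given solid-volume changes.

    ``dV_s_by_agent`` maps process names (fields of
    :class:`PoreChangeFactors`) to solid-volume changes [cm^3].  Returns
    ``(dV_ps_mic, dV_ps_mes, dV_mac, dV_t)`` where the total-volume
    change includes the solids themselves.
    """
    table = factors.as_dict()
    d_mac = d_mes = d_mic = 0.0
    for agent, dvs in dV_s_by_agent.items():
        if agent not in table:
            raise KeyError(f"unknown agent {agent!r}; factors defined for "
                           f"{sorted(table)}")
        f_mac, f_mes, f_mic = table[agent]
        d_mac += f_mac * dvs
        d_mes += f_mes * dvs
        d_mic += f_mic * dvs
    dv_solids = sum(dV_s_by_agent.values())
    return d_mic, d_mes, d_mac, d_mic + d_mes + d_mac + dv_solids


def swell_shrink_step(dV_w: float, p: ShrinkageParams) -> float:
    """Matrix pore-volume change from a water-volume change [cm^3].

    dV_mat = f_slope * dV_w: the slope of the shrinkage characteristic
    maps water loss to matrix shrinkage; solids are unchanged.
    """
    return p.f_slope * dV_w


# ---------------------------------------------------------------------------
# Steady-flux regime (constant total volume)


def steady_flux_rates(profile: PorosityProfile, roots: RootParams,
                      worms: WormParams, gamma_s: float
                      ) -> tuple[float, float, float]:
    """Class-porosity rates (d phi_mac, d phi_s_mes, d phi_s_mic)/dt [1/yr].

    Valid in the constant-volume regime (E_c = E_i, R_g = R_d).  The
    three rates sum to zero: pore space is only redistributed.
    """
    phi = profile.phi
    eps = profile.phi_mat / (1.0 - phi)
    gamma_b = gamma_s * (1.0 - phi)
    a = roots.production / roots.gamma_r
    w = gamma_b * worms.tau_s_at(gamma_b) / gamma_s
    s_mes, s_mic = _structural_shares(profile.phi_s_mes, profile.phi_s_mic,
                                      profile.phi_t_mic / max(profile.phi_t, 1e-300))
    e_c, f_cm = worms.eps_casts, worms.f_casts_mic
    d_mac = roots.f_r_c * a + (eps - e_c) * w
    d_mes = (1.0 - roots.f_r_c - s_mes) * a + ((1.0 - f_cm) * e_c - s_mes * eps) * w
    d_mic = -s_mic * a + (f_cm * e_c - s_mic * eps) * w
    return d_mac, d_mes, d_mic


def steady_state(roots: RootParams, worms: WormParams, phi: float,
                 phi_min: float, f_t_mic: float, gamma_s: float,
                 dz: float = 1.0) -> PorosityProfile:
    """Closed-form steady state of the steady-flux system.

    Setting the class-porosity rates to zero gives the equilibrium matrix
    void ratio

        eps* = eps_casts - f_r_c * (B_r tau_r / gamma_r) / W,
        W = gamma_b * tau_s / gamma_s,

    hence phi_mat* = eps* (1 - phi), phi_mac* = phi - phi_mat*, and the
    structural micropore porosity

        phi_s_mic* = (phi_mat* - phi_min) * f_casts_mic * eps_casts * W
                     / (A + W eps*),   A = B_r tau_r / gamma_r,

    which reduces to (phi_mat* - phi_min) * f_casts_mic on bare soil.
    On bare soil (B_r = 0) the matrix void ratio equals the cast void
    ratio exactly.

    Raises
    ------
    InfeasibleSteadyStateError
        If the implied matrix porosity is non-positive (root macropore
        production exceeding what bioturbation refills) or any class
        porosity falls outside physical bounds.
    """
    if not 0.0 < phi < 1.0:
        raise ValueError("phi must lie in (0, 1)")
    gamma_b = gamma_s * (1.0 - phi)
    a = roots.production / roots.gamma_r
    w = gamma_b * worms.tau_s_at(gamma_b) / gamma_s
    if w <= 0.0:
        raise ValueError("steady state requires a positive bioturbation flux")
    eps_star = worms.eps_casts - roots.f_r_c * a / w
    phi_mat = eps_star * (1.0 - phi)
    if phi_mat <= 0.0:
        raise InfeasibleSteadyStateError(
            f"steady-state matrix porosity {phi_mat:g} <= 0: root-driven "
            "macropore production exceeds bioturbation refill")
    if phi_mat > phi:
        raise InfeasibleSteadyStateError(
            f"steady-state matrix porosity {phi_mat:g} exceeds total "
            f"porosity {phi:g}")
    phi_s_mic = ((phi_mat - phi_min) * worms.f_casts_mic * worms.eps_casts
                 * w / (a + w * eps_star))
    phi_mic = phi_s_mic + f_t_mic * phi_min
    phi_mes = phi_mat - phi_mic
    phi_mac = phi - phi_mat
    if phi_mes < -1e-12 or phi_mic < 0.0:
        raise InfeasibleSteadyStateError(
            f"steady-state class porosities infeasible "
            f"(phi_mic={phi_mic:g}, phi_mes={phi_mes:g})")
    state = state_from_porosities(phi_mic, max(phi_mes, 0.0), phi_mac,
                                  phi_min, f_t_mic, dz=dz)
    return porosities(state, gamma_s)


# ---------------------------------------------------------------------------
# Surface-casting (recovery) regime


def turnover_rate(I_r: float, E_bio: float, gamma_b: float) -> float:
    """Soil-mass turnover by earthworms, tau_s = I_r * E_bio / gamma_b.

    ``I_r`` in g soil per g biomass per year, ``E_bio`` in g biomass per
    cm^3 soil, ``gamma_b`` in g/cm^3; result in 1/yr.
    """
    if gamma_b <= 0.0:
        raise ValueError("gamma_b must be positive")
    return I_r * E_bio / gamma_b


def surface_cast_fraction(phi_mac: float, phi_mac_c: float) -> float:
    """Fraction of casts deposited at the soil surface.

    f_surf = max(0, 1 - phi_mac/phi_mac_c): casting shifts to the surface
    as macroporosity drops below the threshold phi_mac_c, i.e. when the
    soil is too compact to cast into.
    """
    if phi_mac_c <= 0.0:
        raise ValueError("phi_mac_c must be positive")
    return max(0.0, 1.0 - phi_mac / phi_mac_c)


def bioturbation_volume_rates(state: PoreSpaceState, worms: WormParams,
                              gamma_s: float
                              ) -> tuple[float, float, float, float]:
    """Pore-volume rates under bioturbation with surface casting [cm^3/yr].

    Returns ``(dV_mac, dV_ps_mes, dV_ps_mic, dV_t)/dt``.  With the solid
    mass flux Q = V_t * I_r * E_bio / gamma_s [cm^3 solids/yr]:

        dV_mac    = Q [ eps - eps_casts + f_surf (1 + eps_casts) ]
        dV_ps_mes = Q [ (1 - f_casts_mic) eps_casts - s_mes eps ]
        dV_ps_mic = Q [ f_casts_mic eps_casts - s_mic eps ]
        dV_t      = Q f_surf (1 + eps_casts)

    Solids are unchanged (ingestion and egestion balance); total volume
    grows only by the surface-cast share.
    """
    prof = porosities(state, gamma_s)
    q = state.V_t * worms.tau_s_at(prof.bulk_density) * prof.bulk_density / gamma_s
    eps = state.V_mat / state.V_s  # = phi_mat / (1 - phi)
    if worms.phi_mac_c is not None:
        f_surf = surface_cast_fraction(prof.phi_mac, worms.phi_mac_c)
    else:
        f_surf = 0.0
    s_mes, s_mic = _structural_shares(state.V_ps_mes, state.V_ps_mic,
                                      state.f_t_mic)
    e_c, f_cm = worms.eps_casts, worms.f_casts_mic
    dv_mac = q * (eps - e_c + f_surf * (1.0 + e_c))
    dv_mes = q * ((1.0 - f_cm) * e_c - s_mes * eps)
    dv_mic = q * (f_cm * e_c - s_mic * eps)
    dv_t = q * f_surf * (1.0 + e_c)
    return dv_mac, dv_mes, dv_mic, dv_t


# ---------------------------------------------------------------------------
# Time integration


@dataclass
class Trajectory:
    """Simulated time course of the layer state."""

    times: np.ndarray
    states: list[PoreSpaceState]
    profiles: list[PorosityProfile]
    f_surf: np.ndarray | None = None

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, (t, p) in enumerate(zip(self.times, self.profiles)):
            rows.append({
                "time": t, "phi_mac": p.phi_mac, "phi_mes": p.phi_mes,
                "phi_mic": p.phi_mic, "phi_mat": p.phi_mat, "phi": p.phi,
                "bulk_density": p.bulk_density,
                "layer_thickness": p.layer_thickness,
                "f_surf": float(self.f_surf[i]) if self.f_surf is not None
                          else float("nan"),
            })
        return pd.DataFrame(rows)


def integrate(initial: PoreSpaceState, roots: RootParams | None,
              worms: WormParams, gamma_s: float, t_end: float,
              mode: str = "steady_flux", n_out: int = 201,
              t_eval: np.ndarray | None = None,
              max_step: float = 0.05, rtol: float = 1e-10,
              atol: float = 1e-12) -> Trajectory:
    """Integrate the pore-space dynamics and return a trajectory.

    ``mode="steady_flux"`` solves the constant-volume class-porosity
    system (roots plus worms, no surface casting); ``mode="recovery"``
    solves the surface-casting volume system on bare soil (roots ignored,
    total worm biomass conserved as the layer grows, so the solid flux
    V_t * I_r * E_bio is constant in time).

    Adaptive Runge-Kutta (RK45) with a 0.05 yr step cap; porosity
    invariants hold at every output because states are rebuilt from
    volumes.
    """
    if t_end <= 0.0:
        raise ValueError("t_end must be positive")
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, n_out)
    t_eval = np.asarray(t_eval, dtype=float)
    if roots is None:
        roots = RootParams()

    v_t0 = initial.V_t
    v_pt = initial.V_p_textural
    f_t_mic = initial.f_t_mic
    v_s = initial.V_s

    if mode == "steady_flux":
        prof0 = porosities(initial, gamma_s)
        gamma_b = gamma_s * (1.0 - prof0.phi)
        tau_s = worms.tau_s_at(gamma_b)
        a = roots.production / roots.gamma_r
        w = gamma_b * tau_s / gamma_s
        phi = prof0.phi  # constant in this regime
        e_c, f_cm, f_rc = worms.eps_casts, worms.f_casts_mic, roots.f_r_c

        def rhs(t, y):
            phi_mac, phi_s_mes, phi_s_mic = y
            phi_mat = phi - phi_mac
            eps_now = phi_mat / (1.0 - phi)
            s_mes, s_mic = _structural_shares(phi_s_mes, phi_s_mic, f_t_mic)
            d_mac = f_rc * a + (eps_now - e_c) * w
            d_mes = ((1.0 - f_rc - s_mes) * a
                     + ((1.0 - f_cm) * e_c - s_mes * eps_now) * w)
            d_mic = (-s_mic * a
                     + (f_cm * e_c - s_mic * eps_now) * w)
            return (d_mac, d_mes, d_mic)

        y0 = (prof0.phi_mac, prof0.phi_s_mes, prof0.phi_s_mic)
        sol = solve_ivp(rhs, (0.0, t_end), y0, t_eval=t_eval, method="RK45",
                        max_step=max_step, rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"integration failed: {sol.message}")
        states, profs = [], []
        for phi_mac, phi_s_mes, phi_s_mic in sol.y.T:
            st = initial.copy(V_mac=phi_mac * v_t0,
                              V_ps_mes=phi_s_mes * v_t0,
                              V_ps_mic=phi_s_mic * v_t0)
            states.append(st)
            profs.append(porosities(st, gamma_s))
        return Trajectory(times=sol.t, states=states, profiles=profs)

    if mode == "recovery":
        # Solid ingestion flux is constant: worm biomass is conserved as
        # the layer grows, so V_t(t) * E_bio(t) = V_t0 * E_bio0.
        prof0 = porosities(initial, gamma_s)
        if worms.I_r is not None and worms.E_bio is not None:
            q = v_t0 * worms.I_r * worms.E_bio / gamma_s
        else:
            q = v_t0 * worms.tau_s * prof0.bulk_density / gamma_s
        e_c, f_cm = worms.eps_casts, worms.f_casts_mic
        phi_mac_c = worms.phi_mac_c

        def rhs(t, y):
            v_mac, v_ps_mes, v_ps_mic = y
            v_total = v_s + v_pt + v_mac + v_ps_mes + v_ps_mic
            eps = (v_ps_mes + v_ps_mic + v_pt) / v_s
            f_surf = (surface_cast_fraction(v_mac / v_total, phi_mac_c)
                      if phi_mac_c is not None else 0.0)
            s_mes, s_mic = _structural_shares(v_ps_mes, v_ps_mic, f_t_mic)
            dv_mac = q * (eps - e_c + f_surf * (1.0 + e_c))
            dv_mes = q * ((1.0 - f_cm) * e_c - s_mes * eps)
            dv_mic = q * (f_cm * e_c - s_mic * eps)
            return (dv_mac, dv_mes, dv_mic)

        y0 = (initial.V_mac, initial.V_ps_mes, initial.V_ps_mic)
        sol = solve_ivp(rhs, (0.0, t_end), y0, t_eval=t_eval, method="RK45",
                        max_step=max_step, rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"integration failed: {sol.message}")
        states, profs, fs = [], [], []
        for v_mac, v_ps_mes, v_ps_mic in sol.y.T:
            st = initial.copy(V_mac=v_mac, V_ps_mes=v_ps_mes,
                              V_ps_mic=v_ps_mic)
            p = porosities(st, gamma_s)
            states.append(st)
            profs.append(p)
            fs.append(surface_cast_fraction(p.phi_mac, phi_mac_c)
                      if phi_mac_c is not None else 0.0)
        return Trajectory(times=sol.t, states=states, profiles=profs,
                          f_surf=np.asarray(fs))

    raise ValueError(f"unknown mode {mode!r}; use 'steady_flux' or 'recovery'")


def time_to_equilibrium(traj: Trajectory, target: PorosityProfile | float,
                        rel_tol: float = 0.05) -> float:
    """First time the macroporosity is within ``rel_tol`` of its target.

    ``target`` may be a steady-state profile or a plain macroporosity
    value.  Returns :data:`NOT_REACHED` (inf) if the band is never
    entered.
    """
    phi_mac_star = target.phi_mac if isinstance(target, PorosityProfile) \
        else float(target)
    band = rel_tol * abs(phi_mac_star)
    for t, p in zip(traj.times, traj.profiles):
        if abs(p.phi_mac - phi_mac_star) <= band:
            return float(t)
    return NOT_REACHED
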