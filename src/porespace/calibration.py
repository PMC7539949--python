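"""Compaction-recovery calibration against field observations.

The forward model is the surface-casting bioturbation system on bare
soil; the observables are bulk density, total porosity and the water
contents at pressure heads of -30 and -100 cm, which under the pore-class
bounds (30 and 100 um) map to the matrix porosity and the microporosity
respectively.  Observed series from a compacted plot are first normalized
by the control plot (ratio of the initial to the current control value)
to strip out trends unrelated to compaction recovery.

Four parameters are estimated: the earthworm soil ingestion rate I_r
[g soil / g biomass / day], the cast void ratio eps_casts, the micropore
fraction of cast pore space f_casts_mic, and the macroporosity threshold
phi_mac_c below which casting shifts to the soil surface.  Estimation
uses Powell's derivative-free conjugate-direction method (the forward
model is only piecewise smooth through the max() in the surface-casting
rule) restarted from many random points within bounds to assess
uniqueness of the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .core import (PoreSpaceState, per_day_to_per_year, porosities,
                   state_from_porosities)
from .dynamics import WormParams, _structural_shares, surface_cast_fraction

__all__ = [
    "ObservationSeries", "FixedParams", "CalibrationResult",
    "DEFAULT_BOUNDS", "normalize_to_control", "observables",
    "simulate_recovery_observables", "objective", "calibrate",
    "initial_state_from_observation",
    "read_observations_csv", "write_observations_csv",
]

OBSERVABLE_NAMES = ("bulk_density", "porosity", "theta_30", "theta_100")

#: Default calibration bounds: generous envelopes around field-plausible
#: values (I_r in g soil g^-1 biomass day^-1).
DEFAULT_BOUNDS = {
    "I_r": (1e-3, 10.0),
    "eps_casts": (1e-3, 2.0),
    "f_casts_mic": (0.0, 1.0),
    "phi_mac_c": (1e-4, 0.2),
}


@dataclass
class ObservationSeries:
    """Timestamped soil-physical observations for one plot."""

    times: np.ndarray          # years since compaction
    bulk_density: np.ndarray   # g/cm^3
    porosity: np.ndarray       # cm^3/cm^3
    theta_30: np.ndarray       # water content at -30 cm
    theta_100: np.ndarray      # water content at -100 cm
    plot: str = "compacted"
    sd: dict[str, np.ndarray] | None = None   # optional per-variable std

    def __post_init__(self) -> None:
        for name in ("times",) + OBSERVABLE_NAMES:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.times.size
        for name in OBSERVABLE_NAMES:
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length mismatch with times")
        if np.any(np.diff(self.times) < 0):
            # accept rows in any order; store sorted by time
            order = np.argsort(self.times, kind="stable")
            for name in ("times",) + OBSERVABLE_NAMES:
                setattr(self, name, getattr(self, name)[order])
            if self.sd:
                self.sd = {k: np.asarray(v)[order]
                           for k, v in self.sd.items()}
        if np.any(self.theta_30 > self.porosity + 1e-9) or \
           np.any(self.theta_100 > self.porosity + 1e-9):
            raise ValueError("water contents must not exceed total porosity")

    def values(self, name: str) -> np.ndarray:
        return getattr(self, name)


@dataclass(frozen=True)
class FixedParams:
    """Quantities held fixed during calibration."""

    E_bio: float               # earthworm biomass [g/cm^3]
    gamma_s: float = 2.56      # particle density [g/cm^3]
    phi_min: float = 0.35      # minimum matrix porosity [cm^3/cm^3]
    f_t_mic: float = 0.966     # micropore fraction of textural pores [-]
    dz: float = 30.0           # layer thickness [cm]


@dataclass
class CalibrationResult:
    """Best fit plus the full multi-restart table."""

    I_r: float                 # g soil g^-1 biomass day^-1
    eps_casts: float
    f_casts_mic: float
    phi_mac_c: float
    objective: float
    restarts: pd.DataFrame     # start/end parameters and objective per restart
    n_restarts: int
    seed: int | None

    def params(self) -> dict[str, float]:
        return {"I_r": self.I_r, "eps_casts": self.eps_casts,
                "f_casts_mic": self.f_casts_mic,
                "phi_mac_c": self.phi_mac_c}


# ---------------------------------------------------------------------------
# Pre-processing and observable mapping


def normalize_to_control(compacted: ObservationSeries,
                         control: ObservationSeries,
                         time_tol: float = 0.05) -> ObservationSeries:
    """Remove control-plot trends from a compacted series.

    Each compacted value v_c(t) is replaced by
    v_c(t) * v_ctrl(0) / v_ctrl(t), per variable independently, using the
    control observation nearest in time (within ``time_tol`` years).
    Idempotent only when the control is constant in time.
    """
    idx = []
    for t in compacted.times:
        j = int(np.argmin(np.abs(control.times - t)))
        if abs(control.times[j] - t) > time_tol:
            missing = [float(t) for t in compacted.times
                       if np.min(np.abs(control.times - t)) > time_tol]
            raise ValueError(
                f"no control observation within {time_tol} yr of times "
                f"{missing}")
        idx.append(j)
    out = {}
    for name in OBSERVABLE_NAMES:
        ctrl = control.values(name)
        if np.any(ctrl[idx] == 0.0):
            raise ValueError(f"control {name} contains zeros; cannot "
                             "normalize by ratio")
        out[name] = compacted.values(name) * ctrl[0] / ctrl[idx]
    return ObservationSeries(times=compacted.times.copy(), plot=compacted.plot,
                             sd=compacted.sd, **out)


def observables(state: PoreSpaceState, gamma_s: float
                ) -> tuple[float, float, float, float]:
    """(bulk_density, porosity, theta_30, theta_100) of a layer state.

    At -100 cm only pores < 30 um (micropores) hold water; at -30 cm the
    macropores (> 100 um) have drained but the matrix is full, so
    theta_30 equals the matrix porosity.
    """
    p = porosities(state, gamma_s)
    return p.bulk_density, p.phi, p.phi_mat, p.phi_mic


def initial_state_from_observation(obs: ObservationSeries,
                                   fixed: FixedParams) -> PoreSpaceState:
    """Layer state matching the first observation row.

    phi_mic = theta_100(0), phi_mes = theta_30(0) - theta_100(0),
    phi_mac = porosity(0) - theta_30(0).  Class porosities that fall
    below their textural floor (possible through measurement noise) are
    raised to it, i.e. the corresponding structural pool starts empty.
    """
    phi_mic = max(float(obs.theta_100[0]), fixed.f_t_mic * fixed.phi_min)
    phi_mes = max(float(obs.theta_30[0] - obs.theta_100[0]),
                  (1.0 - fixed.f_t_mic) * fixed.phi_min)
    phi_mac = max(float(obs.porosity[0] - obs.theta_30[0]), 0.0)
    return state_from_porosities(phi_mic, phi_mes, phi_mac, fixed.phi_min,
                                 fixed.f_t_mic, dz=fixed.dz)


# ---------------------------------------------------------------------------
# Fast forward model (fixed-step RK4 on the three pore volumes)


def simulate_recovery_observables(initial: PoreSpaceState, worms: WormParams,
                                  gamma_s: float, times: np.ndarray,
                                  dt: float = 0.005) -> np.ndarray:
    """Forward-simulate and return observables at the requested times.

    Fixed-step classical RK4 on (V_mac, V_ps_mes, V_ps_mic) with solids,
    textural pores and total worm biomass constant (the solid ingestion
    flux Q = V_t * I_r * E_bio is then constant in time).  Cross-checked
    in the test suite against the adaptive integrator; dt = 0.005 yr is
    far inside the asymptotic regime for this smooth, slow system.

    Returns an array of shape (len(times), 4) ordered
    (bulk_density, porosity, theta_30, theta_100).
    """
    times = np.asarray(times, dtype=float)
    v_s = initial.V_s
    v_pt = initial.V_p_textural
    f_t_mic = initial.f_t_mic
    v_pt_mic = initial.V_pt_mic
    v_pt_mes = initial.V_pt_mes
    prof0 = porosities(initial, gamma_s)
    if worms.I_r is not None and worms.E_bio is not None:
        q = initial.V_t * worms.I_r * worms.E_bio / gamma_s
    else:
        q = initial.V_t * worms.tau_s * prof0.bulk_density / gamma_s
    e_c = worms.eps_casts
    f_cm = worms.f_casts_mic
    phi_mac_c = worms.phi_mac_c

    def rhs(v_mac, v_mes, v_mic):
        v_t = v_s + v_pt + v_mac + v_mes + v_mic
        eps = (v_mes + v_mic + v_pt) / v_s
        if phi_mac_c is not None:
            f_surf = 1.0 - v_mac / (v_t * phi_mac_c)
            if f_surf < 0.0:
                f_surf = 0.0
        else:
            f_surf = 0.0
        tot = v_mes + v_mic
        if tot < 1e-12:
            s_mes, s_mic = 1.0 - f_t_mic, f_t_mic
        else:
            s_mes, s_mic = v_mes / tot, v_mic / tot
        return (q * (eps - e_c + f_surf * (1.0 + e_c)),
                q * ((1.0 - f_cm) * e_c - s_mes * eps),
                q * (f_cm * e_c - s_mic * eps))

    y = [initial.V_mac, initial.V_ps_mes, initial.V_ps_mic]
    t = 0.0
    out = np.empty((times.size, 4))
    order = np.argsort(times)
    for k in order:
        t_target = times[k]
        while t < t_target - 1e-12:
            h = min(dt, t_target - t)
            k1 = rhs(*y)
            k2 = rhs(y[0] + 0.5 * h * k1[0], y[1] + 0.5 * h * k1[1],
                     y[2] + 0.5 * h * k1[2])
            k3 = rhs(y[0] + 0.5 * h * k2[0], y[1] + 0.5 * h * k2[1],
                     y[2] + 0.5 * h * k2[2])
            k4 = rhs(y[0] + h * k3[0], y[1] + h * k3[1], y[2] + h * k3[2])
            y = [y[i] + h / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
                 for i in range(3)]
            t += h
        v_mac, v_mes, v_mic = y
        if min(v_mac, v_mes, v_mic) < -1e-9:
            raise FloatingPointError("pore volume went negative in forward run")
        v_t = v_s + v_pt + v_mac + v_mes + v_mic
        phi = (v_mac + v_mes + v_mic + v_pt) / v_t
        phi_mic = (v_mic + v_pt_mic) / v_t
        phi_mat = (v_mic + v_mes + v_pt) / v_t
        out[k] = (gamma_s * (1.0 - phi), phi, phi_mat, phi_mic)
    return out


# ---------------------------------------------------------------------------
# Objective and Powell multi-start


def _worms_from_params(params, fixed: FixedParams) -> WormParams:
    i_r, eps_casts, f_cm, phi_mac_c = params
    return WormParams(eps_casts=eps_casts, f_casts_mic=f_cm,
                      I_r=per_day_to_per_year(i_r), E_bio=fixed.E_bio,
                      phi_mac_c=phi_mac_c)


def _weights(obs: ObservationSeries) -> dict[str, float]:
    """Per-variable standardization: observed std, falling back to range.

    Prevents bulk density (~1.5 g/cm^3) from dominating porosity
    residuals (~0.05 cm^3/cm^3) in the least-squares objective.
    """
    w = {}
    for name in OBSERVABLE_NAMES:
        if obs.sd is not None and name in obs.sd:
            s = float(np.mean(obs.sd[name]))
        else:
            v = obs.values(name)
            s = float(v.max() - v.min())
        w[name] = s if s > 1e-12 else 1.0
    return w


def objective(params, fixed: FixedParams, initial: PoreSpaceState,
              obs: ObservationSeries, dt: float = 0.005,
              penalty: float = 1e12) -> float:
    """Standardized sum-of-squares misfit of the forward model.

    ``params`` is (I_r [g/g/day], eps_casts, f_casts_mic, phi_mac_c).
    Each observable's residuals are divided by its observed standard
    deviation (or range when no std is supplied).  Infeasible forward
    runs return a large finite penalty so Powell can step away.
    """
    i_r, eps_casts, f_cm, phi_mac_c = params
    if i_r <= 0 or eps_casts <= 0 or phi_mac_c <= 0 or not 0 <= f_cm <= 1:
        return penalty
    worms = _worms_from_params(params, fixed)
    try:
        sim = simulate_recovery_observables(initial, worms, fixed.gamma_s,
                                            obs.times, dt=dt)
    except (FloatingPointError, ValueError, ZeroDivisionError):
        return penalty
    w = _weights(obs)
    sse = 0.0
    for j, name in enumerate(OBSERVABLE_NAMES):
        r = (sim[:, j] - obs.values(name)) / w[name]
        sse += float(np.dot(r, r))
    return sse


def calibrate(obs: ObservationSeries, fixed: FixedParams,
              initial: PoreSpaceState | None = None,
              bounds: dict[str, tuple[float, float]] | None = None,
              n_restarts: int = 100, seed: int | None = None,
              dt: float = 0.01, maxfev: int = 2000,
              xtol: float = 1e-7, ftol: float = 1e-9) -> CalibrationResult:
    """Multi-start Powell estimation of the four recovery parameters.

    Runs Powell's derivative-free minimizer from ``n_restarts`` starting
    points drawn uniformly within ``bounds`` (seeded) and returns the
    best solution together with the full restart table, whose spread is
    the uniqueness/identifiability diagnostic.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    if initial is None:
        initial = initial_state_from_observation(obs, fixed)
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    names = ("I_r", "eps_casts", "f_casts_mic", "phi_mac_c")
    lo = np.array([b[k][0] for k in names])
    hi = np.array([b[k][1] for k in names])
    rng = np.random.default_rng(seed)

    rows = []
    best_x, best_f = None, np.inf
    for i in range(n_restarts):
        x0 = lo + (hi - lo) * rng.uniform(size=4)
        res = minimize(objective, x0,
                       args=(fixed, initial, obs, dt),
                       method="Powell",
                       bounds=list(zip(lo, hi)),
                       options={"xtol": xtol, "ftol": ftol,
                                "maxfev": maxfev})
        row = {"restart": i, "objective": float(res.fun),
               "converged": bool(res.success)}
        row.update({f"start_{k}": x0[j] for j, k in enumerate(names)})
        row.update({f"end_{k}": float(res.x[j]) for j, k in enumerate(names)})
        rows.append(row)
        if res.fun < best_f:
            best_f, best_x = float(res.fun), np.asarray(res.x)
    if best_x is None:
        raise RuntimeError("all calibration restarts failed")
    table = pd.DataFrame(rows)
    return CalibrationResult(
        I_r=float(best_x[0]), eps_casts=float(best_x[1]),
        f_casts_mic=float(best_x[2]), phi_mac_c=float(best_x[3]),
        objective=best_f, restarts=table, n_restarts=n_restarts, seed=seed)


# ---------------------------------------------------------------------------
# I/O


def read_observations_csv(path) -> dict[str, ObservationSeries]:
    """Read observation series keyed by plot label.

    Expected columns: time_yr, plot, bulk_density, porosity, theta_30,
    theta_100, optionally sd_<variable>.
    """
    df = pd.read_csv(path, comment="#")
    required = {"time_yr", "plot"} | set(OBSERVABLE_NAMES)
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"observations CSV missing columns {sorted(missing)}")
    out = {}
    for plot, g in df.groupby("plot", sort=False):
        g = g.sort_values("time_yr")
        sd = {name: g[f"sd_{name}"].to_numpy()
              for name in OBSERVABLE_NAMES if f"sd_{name}" in g.columns}
        out[str(plot)] = ObservationSeries(
            times=g["time_yr"].to_numpy(),
            bulk_density=g["bulk_density"].to_numpy(),
            porosity=g["porosity"].to_numpy(),
            theta_30=g["theta_30"].to_numpy(),
            theta_100=g["theta_100"].to_numpy(),
            plot=str(plot), sd=sd or None)
    return out


def write_observations_csv(series: list[ObservationSeries], path,
                           metadata: dict | None = None) -> None:
    rows = []
    for s in series:
        for i, t in enumerate(s.times):
            row = {"time_yr": t, "plot": s.plot}
            for name in OBSERVABLE_NAMES:
                row[name] = s.values(name)[i]
            if s.sd:
                for name, arr in s.sd.items():
                    row[f"sd_{name}"] = np.asarray(arr)[i]
            rows.append(row)
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        pd.DataFrame(rows).to_csv(fh, index=False)
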