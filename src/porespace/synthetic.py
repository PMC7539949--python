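"""Synthetic fixtures with known ground truth.

Two generators, mirroring the two kinds of field input the package
consumes:

* ``gen_retention`` draws noisy replicate water-retention curves from
  known van Genuchten parameters at a configurable ladder of measurement
  pressure heads (emulating replicate core samples per treatment, with an
  optional water excess at the wettest head standing in for macropore
  storage that the matrix curve cannot represent);

* ``gen_recovery`` forward-simulates the surface-casting bioturbation
  model from known parameters, samples the observables at given times,
  adds truncated Gaussian noise, and optionally emits a drifting control
  series so that control normalization can be exercised.

Both are deterministic given (spec, seed); CSV output carries the
generating truth in '#'-prefixed metadata lines and a JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .calibration import (OBSERVABLE_NAMES, FixedParams, ObservationSeries,
                          simulate_recovery_observables,
                          write_observations_csv)
from .core import PoreSpaceState, per_day_to_per_year, state_from_porosities
from .dynamics import WormParams
from .retention import RetentionCurve, RetentionParams, vg_theta, \
    write_retention_csv

__all__ = ["DEFAULT_PSI_LADDER", "RetentionSpec", "RecoverySpec",
           "gen_retention", "gen_recovery"]

#: Default measurement pressure heads [cm]: a free-drainage point at
#: -2.5 cm plus a ladder spanning field capacity to near wilting point.
DEFAULT_PSI_LADDER = (-2.5, -10.0, -30.0, -60.0, -100.0, -300.0,
                      -1000.0, -15000.0)


@dataclass
class RetentionSpec:
    """Ground truth for synthetic replicate retention curves."""

    params: dict[str, RetentionParams]      # per-group true VG parameters
    n_replicates: int = 12
    noise_std: float = 0.01                 # on theta [cm^3/cm^3]
    psi_ladder: tuple = DEFAULT_PSI_LADDER
    sat_excess: float = 0.0                 # extra theta at the wettest head
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_std < 0:
            raise ValueError("noise_std must be non-negative")


@dataclass
class RecoverySpec:
    """Ground truth for a synthetic compaction-recovery series."""

    I_r: float = 2.79                 # g soil g^-1 biomass day^-1
    eps_casts: float = 0.714
    f_casts_mic: float = 0.845
    phi_mac_c: float = 0.057
    fixed: FixedParams = field(
        default_factory=lambda: FixedParams(E_bio=2.1833e-4))
    # initial porosities right after compaction
    phi_mic0: float = 0.345
    phi_mes0: float = 0.012
    phi_mac0: float = 0.005
    times: tuple = tuple(np.round(np.arange(0.0, 4.01, 0.5), 3))
    noise_std: dict = field(default_factory=dict)  # per observable
    control_drift: float = 1.0        # multiplicative drift of control BD/yr
    seed: int = 0

    def worms(self) -> WormParams:
        return WormParams(eps_casts=self.eps_casts,
                          f_casts_mic=self.f_casts_mic,
                          I_r=per_day_to_per_year(self.I_r),
                          E_bio=self.fixed.E_bio,
                          phi_mac_c=self.phi_mac_c)

    def initial_state(self) -> PoreSpaceState:
        return state_from_porosities(self.phi_mic0, self.phi_mes0,
                                     self.phi_mac0, self.fixed.phi_min,
                                     self.fixed.f_t_mic, dz=self.fixed.dz)

    def truth(self) -> dict:
        return {"I_r": self.I_r, "eps_casts": self.eps_casts,
                "f_casts_mic": self.f_casts_mic,
                "phi_mac_c": self.phi_mac_c, "seed": self.seed}


def gen_retention(spec: RetentionSpec, path=None, truth_path=None
                  ) -> list[RetentionCurve]:
    """Generate noisy replicate retention curves from known parameters.

    Each replicate evaluates the VG curve at the measurement ladder and
    adds independent Gaussian noise truncated to [0, 1]; the wettest head
    optionally carries a saturation excess emulating macropore water.
    Labels are "<group>/r<k>".  Deterministic given (spec, spec.seed).
    """
    rng = np.random.default_rng(spec.seed)
    psi = np.asarray(spec.psi_ladder, dtype=float)
    wettest = np.argmax(psi)
    curves = []
    for group, p in spec.params.items():
        clean = np.asarray(vg_theta(psi, p), dtype=float)
        clean = clean + 0.0
        clean[wettest] += spec.sat_excess
        for r in range(spec.n_replicates):
            theta = clean + rng.normal(0.0, spec.noise_std, size=psi.size) \
                if spec.noise_std > 0 else clean.copy()
            np.clip(theta, 0.0, 1.0, out=theta)
            label = f"{group}/r{r}" if spec.n_replicates > 1 else group
            curves.append(RetentionCurve(psi.copy(), theta, label=label))
    if path is not None:
        meta = {"generator": "gen_retention", "seed": spec.seed,
                "noise_std": spec.noise_std,
                "n_replicates": spec.n_replicates}
        write_retention_csv(curves, path, metadata=meta)
    if truth_path is not None:
        truth = {g: asdict(p) for g, p in spec.params.items()}
        truth["seed"] = spec.seed
        with open(truth_path, "w") as fh:
            json.dump(truth, fh, indent=2)
    return curves


def gen_recovery(spec: RecoverySpec, path=None, truth_path=None
                 ) -> tuple[ObservationSeries, ObservationSeries]:
    """Generate a synthetic compaction-recovery observation series.

    Forward-simulates the surface-casting model from the spec's initial
    state, maps states through the observable stack (bulk density,
    porosity, theta at -30 and -100 cm), adds truncated Gaussian noise,
    and builds a control series that is constant except for an optional
    multiplicative drift (``control_drift`` per year) applied to every
    variable — normalizing by such a control restores the compacted
    trend exactly in the noiseless case.

    Returns (compacted, control).
    """
    rng = np.random.default_rng(spec.seed)
    times = np.asarray(spec.times, dtype=float)
    initial = spec.initial_state()
    sim = simulate_recovery_observables(initial, spec.worms(),
                                        spec.fixed.gamma_s, times)
    # ordering holds pre-noise: theta_100 <= theta_30 <= porosity
    assert np.all(sim[:, 3] <= sim[:, 2] + 1e-12)
    assert np.all(sim[:, 2] <= sim[:, 1] + 1e-12)

    drift = spec.control_drift ** times

    def noisy(clean: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        out = {}
        for name in OBSERVABLE_NAMES:
            v = clean[name] * drift
            s = spec.noise_std.get(name, 0.0)
            if s > 0:
                v = v + rng.normal(0.0, s, size=v.size)
            out[name] = np.clip(v, 1e-6, None)
        # noise must not break the physical ordering theta_100 <= theta_30
        # <= porosity that real measurements obey
        out["theta_30"] = np.minimum(out["theta_30"], out["porosity"])
        out["theta_100"] = np.minimum(out["theta_100"], out["theta_30"])
        return out

    data = noisy({name: sim[:, j]
                  for j, name in enumerate(OBSERVABLE_NAMES)})
    sd = {name: np.full(times.size, s)
          for name, s in spec.noise_std.items() if s > 0} or None
    compacted = ObservationSeries(times=times, plot="compacted", sd=sd, **data)

    ctrl0 = {"bulk_density": 1.45, "porosity": 0.43,
             "theta_30": 0.40, "theta_100": 0.36}
    ctrl = noisy({name: np.full(times.size, ctrl0[name])
                  for name in OBSERVABLE_NAMES})
    control = ObservationSeries(times=times, plot="control", **ctrl)

    if path is not None:
        meta = {"generator": "gen_recovery", "seed": spec.seed,
                **{f"true_{k}": v for k, v in spec.truth().items()
                   if k != "seed"}}
        write_observations_csv([compacted, control], path, metadata=meta)
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            json.dump(spec.truth(), fh, indent=2)
    return compacted, control
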