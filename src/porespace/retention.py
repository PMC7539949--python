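"""Dynamic van Genuchten water retention linked to the pore-class model.

The matrix water retention curve is the van Genuchten form with zero
residual water content,

    theta(psi) = phi_mat * [1 + (alpha*|psi|)^n]^(1/n - 1),

where the shape parameter ``n`` is held constant (texture-controlled)
while ``alpha`` follows the evolving pore-size distribution: given the
micropore and matrix porosities and the pressure head ``psi_mic_mes``
separating micropores from mesopores, ``alpha`` is fixed by requiring
theta(psi_mic_mes) = phi_mic.  Macropores lie outside the curve and are
tracked volumetrically only.

The module also fits measured curves (several samples jointly, one shared
``n``), partitions fitted matrix porosity into the pore-class table, and
converts pressure heads to equivalent pore diameters by the capillary
rule d[um] = 3000 / |psi[cm]| (so -100 cm <-> 30 um, -30 cm <-> 100 um).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "CAPILLARY_CONSTANT",
    "RetentionParams",
    "RetentionCurve",
    "PoreClassRow",
    "SharedNFit",
    "vg_theta",
    "alpha_from_pools",
    "psi_to_diameter",
    "diameter_to_psi",
    "fit_shared_n",
    "pool_curves",
    "classify_pores",
    "ksat_ratio",
    "read_retention_csv",
    "write_retention_csv",
]

#: Capillary constant [um * cm] in d = C/|psi|; reproduces both class
#: bounds: 30 um at -100 cm and 100 um at -30 cm.
CAPILLARY_CONSTANT = 3000.0


@dataclass(frozen=True)
class RetentionParams:
    """Unimodal van Genuchten parameters (zero residual water content)."""

    phi_mat: float   # saturated matrix water content [cm^3/cm^3]
    alpha: float     # shape parameter [1/cm]; the dynamic one
    n: float         # shape parameter [-]; texture-fixed, > 1

    def __post_init__(self) -> None:
        if not 0.0 < self.phi_mat < 1.0:
            raise ValueError(f"phi_mat must lie in (0, 1), got {self.phi_mat}")
        if self.alpha < 0.0:
            raise ValueError("alpha must be non-negative")
        if self.n <= 1.0:
            raise ValueError("n must exceed 1")


@dataclass
class RetentionCurve:
    """Measured retention points for one sample or treatment."""

    psi: np.ndarray      # pressure heads [cm], <= 0
    theta: np.ndarray    # water contents [cm^3/cm^3]
    label: str = ""

    def __post_init__(self) -> None:
        self.psi = np.asarray(self.psi, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.psi.shape != self.theta.shape:
            raise ValueError("psi and theta must have equal length")
        if np.any(self.psi > 0.0):
            raise ValueError("pressure heads must be <= 0")
        if np.any((self.theta < 0.0) | (self.theta > 1.0)):
            raise ValueError("water contents must lie in [0, 1]")
        order = np.argsort(-self.psi)  # decreasing psi (wet to dry)
        self.psi = self.psi[order]
        self.theta = self.theta[order]


def vg_theta(psi, p: RetentionParams):
    """Water content at pressure head ``psi`` [cm, <= 0].  Vectorized."""
    psi = np.asarray(psi, dtype=float)
    if np.any(psi > 0.0):
        raise ValueError("psi must be <= 0 (unsaturated or saturated)")
    m = 1.0 / p.n - 1.0
    out = p.phi_mat * (1.0 + (p.alpha * np.abs(psi)) ** p.n) ** m
    return out if out.ndim else float(out)


def alpha_from_pools(phi_mic: float, phi_mat: float, n: float,
                     psi_mic_mes: float = -100.0) -> float:
    """van Genuchten ``alpha`` consistent with the current pore pools.

    Solves theta(psi_mic_mes) = phi_mic for alpha in closed form::

        alpha = [ (phi_mic/phi_mat)^(-n/(n-1)) - 1 ]^(1/n) / |psi_mic_mes|

    With no mesopores (phi_mic == phi_mat) the result is 0.
    """
    if not 0.0 < phi_mic <= phi_mat:
        raise ValueError(
            f"need 0 < phi_mic <= phi_mat, got {phi_mic} vs {phi_mat}")
    if n <= 1.0:
        raise ValueError("n must exceed 1")
    if psi_mic_mes >= 0.0:
        raise ValueError("psi_mic_mes must be negative")
    ratio = phi_mic / phi_mat
    bracket = ratio ** (-n / (n - 1.0)) - 1.0
    return bracket ** (1.0 / n) / abs(psi_mic_mes)


def psi_to_diameter(psi: float) -> float:
    """Equivalent pore diameter [um] for pressure head ``psi`` [cm, < 0]."""
    if psi >= 0.0:
        raise ValueError("psi must be negative")
    return CAPILLARY_CONSTANT / abs(psi)


def diameter_to_psi(d_um: float) -> float:
    """Pressure head [cm] at which pores of diameter ``d_um`` [um] drain."""
    if d_um <= 0.0:
        raise ValueError("diameter must be positive")
    return -CAPILLARY_CONSTANT / d_um


# ---------------------------------------------------------------------------
# Shared-n fitting


@dataclass
class SharedNFit:
    """Result of a joint shared-n fit over several retention curves."""

    params: list[RetentionParams]   # per-curve (phi_mat, alpha, n)
    n: float                        # the shared n
    rmse: list[float]               # per-curve root-mean-square residual
    labels: list[str]
    n_was_fitted: bool
    cost: float


def _pack_residuals(x, curves, n_fixed):
    """Concatenated residuals; x = per-curve (phi_mat, log_alpha) [+ n]."""
    k = len(curves)
    n = n_fixed if n_fixed is not None else x[2 * k]
    res = []
    for i, c in enumerate(curves):
        phi_mat, log_alpha = x[2 * i], x[2 * i + 1]
        p = RetentionParams(phi_mat=phi_mat, alpha=np.exp(log_alpha), n=n)
        res.append(vg_theta(c.psi, p) - c.theta)
    return np.concatenate(res)


def fit_shared_n(curves: Sequence[RetentionCurve],
                 exclude_psi: Sequence[float] = (-2.5,),
                 n_fixed: float | None = None,
                 n_starts: int = 10) -> SharedNFit:
    """Jointly fit the VG curve to several samples with one shared ``n``.

    Each curve gets its own (phi_mat, alpha); ``n`` is common to all and
    either fixed (``n_fixed``) or estimated.  Points whose pressure head
    matches an entry of ``exclude_psi`` (tolerance 1e-6 cm) are dropped
    before fitting — by default the -2.5 cm free-drainage points, whose
    water content includes macropore storage outside the matrix curve.

    alpha is fitted on a log scale with multi-starts log-spaced over
    [1e-4, 1] 1/cm, because the least-squares surface is multimodal in
    alpha.  Returns per-curve parameters, the shared n and per-curve RMSE.
    """
    if len(curves) == 0:
        raise ValueError("need at least one retention curve")
    exclude = np.asarray(list(exclude_psi), dtype=float)
    kept: list[RetentionCurve] = []
    for c in curves:
        if exclude.size:
            mask = ~np.any(np.abs(c.psi[:, None] - exclude[None, :]) < 1e-6,
                           axis=1)
        else:
            mask = np.ones(c.psi.size, dtype=bool)
        if mask.sum() < 3:
            raise ValueError(
                f"curve {c.label!r}: fewer than 3 points retained after "
                f"excluding psi in {list(exclude)}")
        kept.append(RetentionCurve(c.psi[mask], c.theta[mask], c.label))

    k = len(kept)
    lo = np.concatenate([np.repeat([[1e-3, np.log(1e-6)]], k, axis=0).ravel(),
                         [] if n_fixed is not None else [1.001]])
    hi = np.concatenate([np.repeat([[0.999, np.log(10.0)]], k, axis=0).ravel(),
                         [] if n_fixed is not None else [10.0]])

    best = None
    for log_alpha0 in np.log(np.logspace(-4, 0, n_starts)):
        x0 = []
        for c in kept:
            x0.extend([float(c.theta.max()), log_alpha0])
        if n_fixed is None:
            x0.append(1.2)
        x0 = np.clip(np.asarray(x0), lo + 1e-12, hi - 1e-12)
        sol = least_squares(_pack_residuals, x0, bounds=(lo, hi),
                            args=(kept, n_fixed), method="trf",
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success and best.cost > 1e-6:
        raise RuntimeError(f"shared-n fit failed to converge: {best}")

    n = n_fixed if n_fixed is not None else float(best.x[2 * k])
    params, rmse = [], []
    for i, c in enumerate(kept):
        p = RetentionParams(phi_mat=float(best.x[2 * i]),
                            alpha=float(np.exp(best.x[2 * i + 1])), n=n)
        params.append(p)
        rmse.append(float(np.sqrt(np.mean((vg_theta(c.psi, p) - c.theta) ** 2))))
    return SharedNFit(params=params, n=n, rmse=rmse,
                      labels=[c.label for c in kept],
                      n_was_fitted=n_fixed is None, cost=float(best.cost))


# ---------------------------------------------------------------------------
# Pore-class partitioning


@dataclass(frozen=True)
class PoreClassRow:
    """One row of the pore-class table [cm^3/cm^3].

    Textural entries come from (phi_min, f_t_mic); totals from the fitted
    curve evaluated at the micropore/mesopore boundary; structural entries
    are total minus textural, class by class.  Macroporosity is zero for
    matrix-only fits.
    """

    label: str
    phi_t_mic: float
    phi_t_mes: float
    phi_t: float
    phi_s_mic: float
    phi_s_mes: float
    phi_s: float
    phi_mic: float
    phi_mes: float
    phi_mat: float

    def to_dict(self) -> dict:
        return asdict(self)


def pool_curves(curves: Sequence[RetentionCurve], label: str = "pooled",
                how: str = "pool") -> RetentionCurve:
    """Combine replicate curves of one treatment into a single curve.

    ``how="pool"`` concatenates all points (the stricter default: every
    replicate point carries its own residual); ``how="mean"`` averages
    water contents over replicates measured at the same heads.
    """
    if how == "pool":
        psi = np.concatenate([c.psi for c in curves])
        theta = np.concatenate([c.theta for c in curves])
        return RetentionCurve(psi, theta, label=label)
    if how == "mean":
        ref = curves[0].psi
        for c in curves[1:]:
            if not np.allclose(c.psi, ref):
                raise ValueError("mean pooling needs identical heads")
        theta = np.mean([c.theta for c in curves], axis=0)
        return RetentionCurve(ref.copy(), theta, label=label)
    raise ValueError(f"unknown pooling mode {how!r}")


def classify_pores(fit: RetentionParams, psi_mic_mes: float = -100.0,
                   phi_min: float = 0.3, f_t_mic: float = 1.0,
                   label: str = "") -> PoreClassRow:
    """Partition a fitted matrix curve into the pore-class table row."""
    if phi_min > fit.phi_mat:
        raise ValueError("phi_min exceeds fitted phi_mat")
    phi_mic = float(vg_theta(psi_mic_mes, fit))
    phi_mes = fit.phi_mat - phi_mic
    phi_t_mic = f_t_mic * phi_min
    phi_t_mes = (1.0 - f_t_mic) * phi_min
    phi_s_mic = phi_mic - phi_t_mic
    phi_s_mes = phi_mes - phi_t_mes
    for name, v in (("micropore", phi_s_mic), ("mesopore", phi_s_mes)):
        if v < -1e-9:
            raise ValueError(
                f"textural {name} porosity exceeds the class total "
                f"(structural {name} = {v:g} < 0)")
    return PoreClassRow(
        label=label,
        phi_t_mic=phi_t_mic, phi_t_mes=phi_t_mes, phi_t=phi_min,
        phi_s_mic=max(phi_s_mic, 0.0), phi_s_mes=max(phi_s_mes, 0.0),
        phi_s=fit.phi_mat - phi_min,
        phi_mic=phi_mic, phi_mes=phi_mes, phi_mat=fit.phi_mat,
    )


def ksat_ratio(alpha_1: float, alpha_2: float) -> float:
    """Capillary-bundle estimate of Ksat_1/Ksat_2 = (alpha_1/alpha_2)^2."""
    if alpha_2 == 0.0:
        raise ValueError("alpha_2 must be non-zero")
    return (alpha_1 / alpha_2) ** 2


# ---------------------------------------------------------------------------
# I/O


def read_retention_csv(path) -> list[RetentionCurve]:
    """Read curves from CSV with columns (label, psi_cm, theta)."""
    df = pd.read_csv(path, comment="#")
    required = {"label", "psi_cm", "theta"}
    if not required.issubset(df.columns):
        raise ValueError(f"retention CSV needs columns {sorted(required)}")
    return [RetentionCurve(g["psi_cm"].to_numpy(), g["theta"].to_numpy(),
                           label=str(lab))
            for lab, g in df.groupby("label", sort=False)]


def write_retention_csv(curves: Sequence[RetentionCurve], path,
                        metadata: dict | None = None) -> None:
    """Write curves as CSV, optional '#'-prefixed metadata header."""
    rows = [{"label": c.label, "psi_cm": p, "theta": t}
            for c in curves for p, t in zip(c.psi, c.theta)]
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        pd.DataFrame(rows).to_csv(fh, index=False)
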