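"""ThetaPlanes: piecewise-planar approximation of the transfer surface.

The firing-rate surface nu(I_s, I_d) of the two-compartment neuron splits
into three regions: silent (below rheobase), a low-rate passive region
where the dendritic Ca2+ channel stays closed, and a high-rate active
region after Ca activation.  Each firing region is approximated by a plane

    nu_i(I_s, I_d) = a_i I_s + b_i I_d + d_i,          i in {-, +},

fitted by ordinary least squares over Boolean masks: M+ marks Ca-active
points, M- the inactive points firing above nu_low.  The region boundary
is a straight line I_d = theta_m_H I_s + theta_q_H fitted to the lowest
active I_d per I_s column; the rheobase line is the zero locus of the
low-rate plane.  The assembled transfer function is

    nu_F = Theta(I_d - rheobase) (1 - Theta(I_d - boundary)) nu_-
         + Theta(I_d - boundary) nu_+,

with the Heaviside convention Theta(0) = 1 (boundaries belong to the
active side).  Points with I_s > I_th are excluded from all fits to avoid
edge-of-domain non-linearities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
from sklearn.linear_model import LinearRegression

from .protocols import TransferSurface

__all__ = [
    "ThetaPlanesModel",
    "FitError",
    "compute_masks",
    "fit_planes",
    "fit_boundary_and_rheobase",
    "fit_thetaplanes",
    "evaluate",
    "fit_report",
    "DEFAULT_NU_LOW",
]

DEFAULT_NU_LOW = 10.0       # Hz; low-rate precision matters little below this


class FitError(ValueError):
    """Degenerate mask or undefined geometric element."""


@dataclass
class ThetaPlanesModel:
    """Ten parameters defining the piecewise-planar transfer function."""

    a_plus: float           # Hz/pA
    b_plus: float           # Hz/pA
    d_plus: float           # Hz
    a_minus: float
    b_minus: float
    d_minus: float
    theta_m_H: float        # boundary line slope (dimensionless)
    theta_q_H: float        # boundary line offset (pA)
    theta_m_rho: float      # rheobase line slope
    theta_q_rho: float      # rheobase line offset (pA)
    nu_low: float = DEFAULT_NU_LOW
    I_th: float = np.inf    # pA, exclusion band edge used during fitting

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(asdict(self), f, indent=1)

    @classmethod
    def from_json(cls, path) -> "ThetaPlanesModel":
        with open(path) as f:
            return cls(**json.load(f))


def compute_masks(surface: TransferSurface, nu_low: float = DEFAULT_NU_LOW,
                  I_th: float = np.inf):
    """Boolean masks (M_plus, M_minus) over the surface grid.

    M_plus marks Ca-active points, M_minus inactive points with rate above
    nu_low; both exclude the band I_s > I_th.
    """
    keep = surface.Is_grid[:, None] <= I_th
    M_plus = surface.ca_active & keep
    M_minus = (~surface.ca_active) & (surface.rate > nu_low) & keep
    return M_plus, M_minus


def fit_planes(surface: TransferSurface, mask: np.ndarray):
    """OLS plane fit of the rate over masked points.

    Returns ``((a, b, d), residual_report)`` with max and RMS residuals in
    Hz.  Raises :class:`FitError` for fewer than 3 points or a collinear
    point set.
    """
    II_s, II_d = np.meshgrid(surface.Is_grid, surface.Id_grid, indexing="ij")
    X = np.column_stack([II_s[mask], II_d[mask]])
    y = surface.rate[mask]
    if X.shape[0] < 3:
        raise FitError(f"mask has {X.shape[0]} points; need >= 3")
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < 2:
        raise FitError("masked points are collinear; plane fit is degenerate")
    reg = LinearRegression().fit(X, y)
    a, b = float(reg.coef_[0]), float(reg.coef_[1])
    d = float(reg.intercept_)
    resid = y - reg.predict(X)
    report = {"n": int(X.shape[0]),
              "max_abs_err": float(np.max(np.abs(resid))),
              "rms_err": float(np.sqrt(np.mean(resid ** 2)))}
    return (a, b, d), report


def fit_boundary_and_rheobase(surface: TransferSurface, masks,
                              minus_plane) -> dict:
    """Boundary line (lowest active I_d per I_s column, OLS) and rheobase.

    The rheobase line is the zero locus of the fitted low-rate plane:
    ``I_d = -(a_minus I_s + d_minus)/b_minus``.  Columns without active
    points are skipped, never imputed.
    """
    M_plus, _ = masks
    a_m, b_m, d_m = minus_plane
    xs, ys = [], []
    for i, Is in enumerate(surface.Is_grid):
        col = np.flatnonzero(M_plus[i])
        if col.size:
            xs.append(Is)
            ys.append(surface.Id_grid[col[0]])
    if len(xs) < 2:
        raise FitError("fewer than 2 boundary points; boundary line undefined")
    coef = np.polyfit(xs, ys, 1)
    if b_m == 0:
        raise FitError("b_minus = 0: rheobase line undefined")
    return {
        "theta_m_H": float(coef[0]), "theta_q_H": float(coef[1]),
        "theta_m_rho": float(-a_m / b_m), "theta_q_rho": float(-d_m / b_m),
    }


def fit_thetaplanes(surface: TransferSurface, nu_low: float = DEFAULT_NU_LOW,
                    I_th: float = np.inf) -> ThetaPlanesModel:
    """Full pipeline: masks, two plane fits, boundary and rheobase lines."""
    masks = compute_masks(surface, nu_low, I_th)
    plus, _ = fit_planes(surface, masks[0])
    minus, _ = fit_planes(surface, masks[1])
    lines = fit_boundary_and_rheobase(surface, masks, minus)
    return ThetaPlanesModel(
        a_plus=plus[0], b_plus=plus[1], d_plus=plus[2],
        a_minus=minus[0], b_minus=minus[1], d_minus=minus[2],
        nu_low=nu_low, I_th=float(I_th), **lines,
    )


def _heaviside(x):
    """Heaviside with Theta(0) = 1 (closed on the active side)."""
    return np.where(np.asarray(x, float) >= 0.0, 1.0, 0.0)


def evaluate(model: ThetaPlanesModel, I_s, I_d):
    """The ThetaPlanes transfer function nu_F(I_s, I_d) in Hz.

    Pure and total: defined for every current pair, including outside the
    fitted domain.
    """
    I_s = np.asarray(I_s, float)
    I_d = np.asarray(I_d, float)
    nu_plus = model.a_plus * I_s + model.b_plus * I_d + model.d_plus
    nu_minus = model.a_minus * I_s + model.b_minus * I_d + model.d_minus
    th_H = _heaviside(I_d - (model.theta_m_H * I_s + model.theta_q_H))
    th_rho = _heaviside(I_d - (model.theta_m_rho * I_s + model.theta_q_rho))
    out = th_rho * (1.0 - th_H) * nu_minus + th_H * nu_plus
    if out.ndim == 0:
        return float(out)
    return out


def fit_report(surface: TransferSurface, model: ThetaPlanesModel) -> dict:
    """Max/RMS error (Hz) between the fit and the surface, per region.

    Reported over M_plus, M_minus and their union; the exclusion band
    I_s > I_th is omitted, matching the fitted domain.  Each region is
    compared against its own plane (the region membership comes from the
    masks, not from the fitted boundary line, so boundary-cell
    misclassification does not inflate the plane errors).
    """
    masks = compute_masks(surface, model.nu_low, model.I_th)
    II_s, II_d = np.meshgrid(surface.Is_grid, surface.Id_grid, indexing="ij")
    pred_plus = model.a_plus * II_s + model.b_plus * II_d + model.d_plus
    pred_minus = model.a_minus * II_s + model.b_minus * II_d + model.d_minus
    err_grid = np.where(masks[0], pred_plus - surface.rate,
                        pred_minus - surface.rate)
    out = {}
    for name, m in (("plus", masks[0]), ("minus", masks[1]),
                    ("overall", masks[0] | masks[1])):
        if not np.any(m):
            out[name] = {"n": 0, "max_abs_err": 0.0, "rms_err": 0.0}
            continue
        err = err_grid[m]
        out[name] = {"n": int(m.sum()),
                     "max_abs_err": float(np.max(np.abs(err))),
                     "rms_err": float(np.sqrt(np.mean(err ** 2)))}
    return out
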