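"""Deterministic fixture generators used by tests and examples.

Each generator writes small plain-text files together with the exact
quantities an independent check needs (closed-form responses, known plane
coefficients, seeded spike trains), so no binary data ever ships with the
package.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .model import Compartment, build_tree
from .protocols import TransferSurface
from .thetaplanes import ThetaPlanesModel, evaluate
from .io import write_surface_csv, write_spikes, write_tree

__all__ = ["generate_fixture", "planar_surface", "passive_tree", "poisson_trains"]


def planar_surface(Is_max: float = 600.0, Id_max: float = 1000.0,
                   step: float = 50.0,
                   model: ThetaPlanesModel | None = None) -> tuple:
    """Exactly piecewise-planar surface generated from a known model.

    Returns ``(surface, model)``; the activation mask is the Heaviside
    boundary mask of the model, so refitting must recover all parameters.
    """
    if model is None:
        model = ThetaPlanesModel(
            a_plus=0.05, b_plus=0.08, d_plus=3.0,
            a_minus=0.04, b_minus=0.02, d_minus=-8.0,
            theta_m_H=-0.5, theta_q_H=600.0,
            theta_m_rho=-2.0, theta_q_rho=400.0,
            nu_low=10.0, I_th=np.inf)
    Is = np.arange(0.0, Is_max + step / 2, step)
    Id = np.arange(0.0, Id_max + step / 2, step)
    II_s, II_d = np.meshgrid(Is, Id, indexing="ij")
    rate = np.maximum(evaluate(model, II_s, II_d), 0.0)
    active = II_d >= model.theta_m_H * II_s + model.theta_q_H
    return TransferSurface(Is_grid=Is, Id_grid=Id, rate=rate,
                           ca_active=active), model


def passive_tree(n: int = 2, seed: int = 0):
    """Random passive tree (chain topology for n<=3, random parents above)."""
    rng = np.random.default_rng(seed)
    comps = [Compartment(id=0, parent=None, C_m=float(rng.uniform(100, 300)),
                         g_L=float(rng.uniform(5, 20)), E_L=-70.0)]
    for i in range(1, n):
        parent = i - 1 if n <= 3 else int(rng.integers(0, i))
        comps.append(Compartment(id=i, parent=parent,
                                 C_m=float(rng.uniform(50, 200)),
                                 g_L=float(rng.uniform(2, 10)), E_L=-70.0,
                                 g_C=float(rng.uniform(2, 15))))
    return build_tree(comps)


def poisson_trains(rate_hz: float, T_ms: float, n_units: int, seed: int = 0):
    """Seeded homogeneous Poisson spike trains; returns (times, units)."""
    rng = np.random.default_rng(seed)
    times, units = [], []
    for u in range(n_units):
        t = 0.0
        while True:
            t += rng.exponential(1000.0 / rate_hz)
            if t >= T_ms:
                break
            times.append(t)
            units.append(u)
    order = np.argsort(times, kind="stable")
    return np.asarray(times)[order], np.asarray(units, int)[order]


def generate_fixture(kind: str, out_dir, seed: int = 0, **params) -> list:
    """Write a named fixture into ``out_dir``; returns the created paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    created = []
    if kind == "planar_surface":
        surface, model = planar_surface(**params)
        write_surface_csv(surface, out / "surface.csv")
        model.to_json(out / "thetaplanes_true.json")
        created += [out / "surface.csv", out / "thetaplanes_true.json"]
    elif kind == "passive_tree":
        tree = passive_tree(params.get("n", 2), seed)
        write_tree(tree, out / "passive_tree.json")
        created.append(out / "passive_tree.json")
    elif kind == "poisson_trains":
        t, u = poisson_trains(params.get("rate_hz", 20.0),
                              params.get("T_ms", 1000.0),
                              params.get("n_units", 5), seed)
        write_spikes(out / "spikes.gdf", t, u)
        created.append(out / "spikes.gdf")
    elif kind == "toy_network":
        spec = {"N_exc": params.get("N_exc", 40), "N_inh": params.get("N_inh", 10),
                "g_ratio": 5.0, "K": params.get("K", 25), "J_exc": 0.02,
                "delay": 1.5, "noise_rate": 8000.0, "noise_weight": 0.02,
                "duration": 1000.0, "seed": seed}
        with open(out / "network.json", "w") as f:
            json.dump(spec, f, indent=1)
        created.append(out / "network.json")
    else:
        raise ValueError(f"unknown fixture kind '{kind}'")
    return created
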