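"""Reading and writing the package's plain-text formats.

Genomes and tree layouts travel as JSON or YAML (keys are the exact
parameter names, units fixed: pF, nS, mV, ms, pA, mM); transfer surfaces
as long-format CSV (I_s, I_d, rate, ca_active); spike trains as
two-column text (t_ms, unit_id), GDF-like; voltage/state recordings as
CSV with a time column.  All parsers reject malformed input with
line/field context instead of silently coercing.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .model import (
    AdExMechanism,
    CaHotzoneMechanism,
    Compartment,
    CompartmentTree,
    ConfigurationError,
    Genome,
    build_tree,
    genome_from_dict,
    genome_to_dict,
)
from .channels import ReceptorSpec
from .protocols import TransferSurface
from .solver import SimulationResult

__all__ = [
    "ParseError",
    "read_genome", "write_genome",
    "tree_from_config", "tree_to_config", "read_tree", "write_tree",
    "read_surface_csv", "write_surface_csv",
    "read_spikes", "write_spikes",
    "write_result_csv",
    "write_manifest",
]


class ParseError(ValueError):
    """Malformed input file; the message names the file and offending field."""


def _load_structured(path) -> dict:
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix in (".yaml", ".yml"):
            return yaml.safe_load(text)
        return json.loads(text)
    except Exception as e:
        raise ParseError(f"{path}: cannot parse: {e}") from e


def _dump_structured(obj, path) -> None:
    path = Path(path)
    with open(path, "w") as f:
        if path.suffix in (".yaml", ".yml"):
            yaml.safe_dump(obj, f, sort_keys=False)
        else:
            json.dump(obj, f, indent=1)


def read_genome(path) -> Genome:
    d = _load_structured(path)
    if not isinstance(d, dict):
        raise ParseError(f"{path}: expected a mapping at top level")
    try:
        return genome_from_dict(d)
    except ConfigurationError as e:
        raise ParseError(f"{path}: {e}") from e


def write_genome(genome: Genome, path) -> None:
    _dump_structured(genome_to_dict(genome), path)


_CHANNEL_TYPES = {"AdEx": AdExMechanism, "CaHotzone": CaHotzoneMechanism}


def tree_from_config(config: dict, source: str = "<config>") -> CompartmentTree:
    """Build an arbitrary compartment tree from a plain-dict layout.

    ``config["compartments"]`` is a list of mappings with the
    :class:`~caadex.model.Compartment` fields; channels are given as
    ``{"type": "AdEx"|"CaHotzone", ...params}`` and receptors with the
    :class:`~caadex.channels.ReceptorSpec` fields.
    """
    if "compartments" not in config:
        raise ParseError(f"{source}: missing 'compartments' list")
    comps = []
    for i, entry in enumerate(config["compartments"]):
        entry = dict(entry)
        channels = []
        for ch in entry.pop("channels", []):
            ch = dict(ch)
            kind = ch.pop("type", None)
            if kind not in _CHANNEL_TYPES:
                raise ParseError(f"{source}: compartment {i}: unknown channel "
                                 f"type '{kind}'")
            try:
                channels.append(_CHANNEL_TYPES[kind](**ch))
            except (TypeError, ConfigurationError) as e:
                raise ParseError(f"{source}: compartment {i}: {e}") from e
        receptors = []
        for rc in entry.pop("receptors", []):
            try:
                receptors.append(ReceptorSpec(**rc))
            except (TypeError, ConfigurationError) as e:
                raise ParseError(f"{source}: compartment {i}: {e}") from e
        try:
            comps.append(Compartment(channels=channels, receptors=receptors, **entry))
        except (TypeError, ConfigurationError) as e:
            raise ParseError(f"{source}: compartment {i}: {e}") from e
    return build_tree(comps)


def tree_to_config(tree: CompartmentTree) -> dict:
    out = []
    for c in tree.compartments:
        d = {"id": c.id, "parent": c.parent, "C_m": c.C_m, "g_L": c.g_L,
             "E_L": c.E_L, "g_C": c.g_C}
        chs = []
        for ch in c.channels:
            kind = next(k for k, t in _CHANNEL_TYPES.items() if isinstance(ch, t))
            chs.append({"type": kind, **asdict(ch)})
        if chs:
            d["channels"] = chs
        if c.receptors:
            d["receptors"] = [asdict(r) for r in c.receptors]
        out.append(d)
    return {"compartments": out}


def read_tree(path) -> CompartmentTree:
    return tree_from_config(_load_structured(path), source=str(path))


def write_tree(tree: CompartmentTree, path) -> None:
    _dump_structured(tree_to_config(tree), path)


def write_surface_csv(surface: TransferSurface, path) -> None:
    """Long-format CSV: one row per grid point (I_s, I_d, rate, ca_active)."""
    II_s, II_d = np.meshgrid(surface.Is_grid, surface.Id_grid, indexing="ij")
    df = pd.DataFrame({
        "I_s": II_s.ravel(), "I_d": II_d.ravel(),
        "rate": surface.rate.ravel(),
        "ca_active": surface.ca_active.ravel().astype(int),
    })
    df.to_csv(path, index=False)


def read_surface_csv(path) -> TransferSurface:
    """Parse a long-format surface CSV; row order does not matter."""
    try:
        df = pd.read_csv(path)
    except Exception as e:
        raise ParseError(f"{path}: {e}") from e
    for col in ("I_s", "I_d", "rate", "ca_active"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column '{col}'")
    Is = np.unique(df["I_s"].to_numpy(float))
    Id = np.unique(df["I_d"].to_numpy(float))
    if len(df) != len(Is) * len(Id):
        raise ParseError(f"{path}: rows do not form a complete I_s x I_d grid")
    rate = np.full((len(Is), len(Id)), np.nan)
    act = np.zeros((len(Is), len(Id)), bool)
    i_idx = np.searchsorted(Is, df["I_s"].to_numpy(float))
    j_idx = np.searchsorted(Id, df["I_d"].to_numpy(float))
    rate[i_idx, j_idx] = df["rate"].to_numpy(float)
    act[i_idx, j_idx] = df["ca_active"].to_numpy() != 0
    if np.any(np.isnan(rate)):
        raise ParseError(f"{path}: duplicate or missing grid points")
    return TransferSurface(Is_grid=Is, Id_grid=Id, rate=rate, ca_active=act)


def write_spikes(path, times: Sequence[float], units: Sequence[int]) -> None:
    """Two-column text (t_ms, unit_id), times non-decreasing."""
    with open(path, "w") as f:
        f.write("# t_ms unit_id\n")
        for t, u in zip(times, units):
            f.write(f"{t:.6g} {int(u)}\n")


def read_spikes(path):
    """Parse a GDF-like spike file; non-monotone times are rejected."""
    times, units = [], []
    with open(path) as f:
        for ln, line in enumerate(f, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(f"{path}:{ln}: expected 2 columns, got {len(parts)}")
            try:
                t = float(parts[0])
                u = int(parts[1])
            except ValueError as e:
                raise ParseError(f"{path}:{ln}: {e}") from e
            if times and t < times[-1]:
                raise ParseError(f"{path}:{ln}: spike times must be non-decreasing "
                                 f"({t} after {times[-1]})")
            times.append(t)
            units.append(u)
    return np.asarray(times), np.asarray(units)


def write_result_csv(result: SimulationResult, path) -> None:
    """Recorded traces as CSV (t_ms, V per compartment, Ca, gating, w)."""
    if result.voltages is None:
        raise ConfigurationError("result has no recordings to write")
    cols = {"t_ms": result.times}
    for i in range(result.voltages.shape[1]):
        cols[f"V_{i}_mV"] = result.voltages[:, i]
    if result.calcium is not None:
        cols["Ca_mM"] = result.calcium
    if result.gating is not None:
        for k, v in result.gating.items():
            cols[k] = v
    if result.w is not None:
        cols["w"] = result.w
    pd.DataFrame(cols).to_csv(path, index=False)


def write_manifest(out_dir, command: str, config_paths: Sequence = (),
                   seeds: Sequence = (), outputs: Sequence = ()) -> Path:
    """One manifest per CLI run: command, config hashes, seeds, outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    hashes = {}
    for p in config_paths:
        p = Path(p)
        hashes[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()
    from . import __version__
    manifest = {
        "command": command,
        "config_sha256": hashes,
        "seeds": list(seeds),
        "version": __version__,
        "outputs": [str(o) for o in outputs],
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as f:
        json.dump(manifest, f, indent=1)
    return path
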