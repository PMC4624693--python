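"""File formats: topology JSON, extended-XYZ trajectories, record tables.

Everything is plain text: topologies (with titration-site definitions)
serialize to JSON, trajectories to extended XYZ with the box and time in
the comment line, and state-energy record streams to CSV with one column
per state/subsystem quantity.  Output files carry provenance metadata
(seed, config hash) where the format allows a comment.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np
import pandas as pd

from .dynamics import SubsystemState
from .nonbonded import NonbondedParams
from .topology import TitrationSite, Topology

__all__ = [
    "topology_to_dict", "topology_from_dict",
    "save_system", "load_system",
    "write_trajectory", "read_trajectory",
    "records_to_frame", "frame_to_samples",
    "write_records", "read_records",
    "config_hash",
]


def config_hash(config) -> str:
    """Short stable hash of a RunConfig for provenance lines."""
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


# ---------------------------------------------------------------------------
# topology / system JSON

def topology_to_dict(topology: Topology) -> dict:
    return {
        "masses": topology.masses.tolist(),
        "type_labels": list(topology.type_labels),
        "charge_sets": topology.charge_sets.tolist(),
        "solute_mask": topology.solute_mask.astype(int).tolist(),
        "constraints": topology.constraints.tolist(),
        "constraint_lengths": topology.constraint_lengths.tolist(),
        "molecule_ids": topology.molecule_ids.tolist(),
    }


def topology_from_dict(data: dict) -> Topology:
    return Topology(
        masses=np.asarray(data["masses"], dtype=float),
        type_labels=list(data["type_labels"]),
        charge_sets=np.asarray(data["charge_sets"], dtype=float),
        solute_mask=np.asarray(data["solute_mask"], dtype=bool),
        constraints=np.asarray(data["constraints"], dtype=int).reshape(-1, 2),
        constraint_lengths=np.asarray(data["constraint_lengths"], dtype=float),
        molecule_ids=np.asarray(data["molecule_ids"], dtype=int),
    )


def _site_to_dict(site: TitrationSite) -> dict:
    return {
        "site_id": site.site_id,
        "atom_indices": site.atom_indices.tolist(),
        "protonated_charges": site.protonated_charges.tolist(),
        "deprotonated_charges": site.deprotonated_charges.tolist(),
        "pka_ref": site.pka_ref,
        "delta_g_ref": site.delta_g_ref,
        "x_deprotonated": site.x_deprotonated,
        "explicit": site.explicit,
        "dummy_atom": site.dummy_atom,
    }


def _site_from_dict(d: dict) -> TitrationSite:
    return TitrationSite(
        site_id=d["site_id"],
        atom_indices=np.asarray(d["atom_indices"], dtype=int),
        protonated_charges=np.asarray(d["protonated_charges"], dtype=float),
        deprotonated_charges=np.asarray(d["deprotonated_charges"], dtype=float),
        pka_ref=float(d["pka_ref"]), delta_g_ref=float(d["delta_g_ref"]),
        x_deprotonated=float(d.get("x_deprotonated", 0.5)),
        explicit=bool(d.get("explicit", True)),
        dummy_atom=d.get("dummy_atom"),
    )


def save_system(spec, path) -> None:
    """Serialize a ToySystemSpec (topology + coordinates + parameters)."""
    data = {
        "topology": topology_to_dict(spec.topology),
        "positions": spec.positions.tolist(),
        "box": spec.box.tolist(),
        "cutoff": spec.params.cutoff,
        "coulomb_constant": spec.params.coulomb_constant,
        "lj_params": [[list(k), list(v)] for k, v in spec.params.lj_params.items()],
        "exclusions": sorted(p for p in spec.params.exclusions if p[0] < p[1]),
        "sites": [_site_to_dict(s) for s in spec.sites],
        "base_charges": None if spec.base_charges is None
        else np.asarray(spec.base_charges).tolist(),
        "note": spec.note,
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


def load_system(path):
    from .toys import ToySystemSpec
    with open(path) as fh:
        data = json.load(fh)
    params = NonbondedParams(
        cutoff=float(data["cutoff"]),
        coulomb_constant=float(data["coulomb_constant"]),
        lj_params={tuple(k): tuple(v) for k, v in data["lj_params"]},
        exclusions={tuple(p) for p in data["exclusions"]},
    )
    return ToySystemSpec(
        topology=topology_from_dict(data["topology"]),
        positions=np.asarray(data["positions"], dtype=float),
        box=np.asarray(data["box"], dtype=float),
        params=params,
        sites=[_site_from_dict(d) for d in data["sites"]],
        base_charges=None if data.get("base_charges") is None
        else np.asarray(data["base_charges"], dtype=float),
        note=data.get("note", ""),
    )


# ---------------------------------------------------------------------------
# extended XYZ trajectories

def write_trajectory(frames, path, labels=None, precision: int = 6) -> None:
    """Write SubsystemState frames as extended XYZ.

    The comment line carries the box and time:
    ``box=Lx,Ly,Lz time=<fs>``.  All frames must share the atom count.
    """
    frames = list(frames)
    if frames:
        n0 = frames[0].positions.shape[0]
        if any(f.positions.shape[0] != n0 for f in frames):
            raise ValueError("all frames must share the atom count")
    with open(path, "w") as fh:
        for f in frames:
            n = f.positions.shape[0]
            fh.write(f"{n}\n")
            bx = ",".join(f"{v:.{precision}f}" for v in f.box)
            fh.write(f"box={bx} time={f.time:.{precision}f}\n")
            labs = labels if labels is not None else ["X"] * n
            for lab, p, v in zip(labs, f.positions, f.velocities):
                row = " ".join(f"{c:.{precision}f}" for c in (*p, *v))
                fh.write(f"{lab} {row}\n")


def read_trajectory(path):
    """Read frames written by :func:`write_trajectory`."""
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i])
        header = dict(tok.split("=", 1) for tok in lines[i + 1].split())
        box = np.array([float(v) for v in header["box"].split(",")])
        time = float(header.get("time", 0.0))
        pos = np.empty((n, 3))
        vel = np.zeros((n, 3))
        for a in range(n):
            parts = lines[i + 2 + a].split()
            pos[a] = [float(x) for x in parts[1:4]]
            if len(parts) >= 7:
                vel[a] = [float(x) for x in parts[4:7]]
        frames.append(SubsystemState(pos, vel, box, time))
        i += 2 + n
    return frames


# ---------------------------------------------------------------------------
# record tables

def records_to_frame(records) -> pd.DataFrame:
    """Flatten a StateEnergyRecord stream into a tidy table."""
    rows = []
    for r in records:
        row = {"step": r.step, "time": r.time}
        n = r.e_solute.shape[0]
        for j in range(n):
            for i in range(n):
                row[f"e_solute_{j}_{i}"] = r.e_solute[j, i]
        for j, v in enumerate(r.e_solvent):
            row[f"e_solvent_{j}"] = v
        for j, v in enumerate(r.weights):
            row[f"weight_{j}"] = v
        for i, v in enumerate(r.fractions):
            row[f"fraction_{i}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_samples(frame: pd.DataFrame):
    """Rebuild FreeEnergySamples from a record table."""
    from .free_energy import FreeEnergySamples
    e_cols = sorted((c for c in frame.columns if c.startswith("e_solute_")),
                    key=lambda c: tuple(int(t) for t in c.split("_")[2:]))
    x_cols = sorted((c for c in frame.columns if c.startswith("fraction_")),
                    key=lambda c: int(c.rsplit("_", 1)[1]))
    n = len(x_cols)
    e = frame[e_cols].to_numpy().reshape(-1, n, n)
    return FreeEnergySamples(e, frame[x_cols].to_numpy())


def write_records(records, path, metadata: dict | None = None) -> None:
    frame = records_to_frame(records)
    with open(path, "w") as fh:
        if metadata:
            meta = " ".join(f"{k}={v}" for k, v in sorted(metadata.items()))
            fh.write(f"# {meta}\n")
        frame.to_csv(fh, index=False)


def read_records(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
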