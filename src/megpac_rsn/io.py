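"""Serialization: HDF5 containers for series/maps, CSV/JSON for statistics.

Recordings, PAC maps, megPAC series and RSN sets live in hierarchical HDF5
containers (one group per subject x condition, attributes carrying fs /
condition / subject_id). Statistical outputs are mirrored as tidy CSV tables
and a JSON summary. Vertex indexing is 0-based everywhere.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .mesh import CorticalMesh
from .pac import MegPACSeries, PACMap
from .rsn import ReductionPlan, RSNSet
from .simulate import SourceRecording

__all__ = [
    "write_recordings",
    "read_recordings",
    "write_pacmaps",
    "read_pacmaps",
    "pacmap_to_csv",
    "write_megpac",
    "read_megpac",
    "write_rsnset",
    "read_rsnset",
    "rsn_map_to_csv",
    "RunManifest",
]


def array_digest(*arrays: np.ndarray) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# recordings


def write_recordings(path: str | Path, recordings: dict) -> None:
    """Write {condition: {subject_id: SourceRecording}} to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "megpac-rsn recordings v1; 0-based vertex indexing"
        for cond, subjects in recordings.items():
            for subj, rec in subjects.items():
                g = f.create_group(f"recordings/{cond}/{subj}")
                g.create_dataset("data", data=rec.data)
                g.attrs["fs"] = rec.fs
                g.attrs["condition"] = rec.condition
                g.attrs["subject_id"] = rec.subject_id


def read_recordings(path: str | Path,
                    mesh: CorticalMesh | None = None) -> dict:
    """Read and validate a recordings container.

    Validates required attributes, finiteness, and (if a mesh is given) that
    row counts match the mesh vertex count.
    """
    out: dict[str, dict] = {}
    with h5py.File(path, "r") as f:
        if "recordings" not in f:
            raise ValueError(f"{path}: no 'recordings' group")
        for cond, cgroup in f["recordings"].items():
            out[cond] = {}
            for subj, g in cgroup.items():
                name = f"recordings/{cond}/{subj}"
                for attr in ("fs", "condition", "subject_id"):
                    if attr not in g.attrs:
                        raise ValueError(
                            f"{path}: group {name} missing attribute {attr!r}"
                        )
                data = g["data"][()]
                if not np.all(np.isfinite(data)):
                    raise ValueError(f"{path}: non-finite data in {name}")
                if mesh is not None and data.shape[0] != mesh.n_vertices:
                    raise ValueError(
                        f"{path}: {name} has {data.shape[0]} rows but the "
                        f"mesh has {mesh.n_vertices} vertices"
                    )
                out[cond][subj] = SourceRecording(
                    subject_id=str(g.attrs["subject_id"]),
                    condition=str(g.attrs["condition"]),
                    data=data,
                    fs=float(g.attrs["fs"]),
                )
    return out


# ---------------------------------------------------------------------------
# PAC maps / megPAC / RSN sets


def write_pacmaps(path: str | Path, pacmaps: dict) -> None:
    """Write {condition: {subject: PACMap}}."""
    with h5py.File(path, "w") as f:
        for cond, subjects in pacmaps.items():
            for subj, pm in subjects.items():
                g = f.create_group(f"pac/{cond}/{subj}")
                g.create_dataset("phase_freq", data=pm.phase_freq)
                g.create_dataset("amp_freq", data=pm.amp_freq)
                g.create_dataset("pac", data=pm.pac)


def read_pacmaps(path: str | Path) -> dict:
    out: dict[str, dict] = {}
    with h5py.File(path, "r") as f:
        for cond, cgroup in f["pac"].items():
            out[cond] = {
                subj: PACMap(g["phase_freq"][()], g["amp_freq"][()],
                             g["pac"][()])
                for subj, g in cgroup.items()
            }
    return out


def pacmap_to_csv(path: str | Path, pacmap: PACMap) -> None:
    pd.DataFrame({
        "vertex": np.arange(pacmap.pac.size),
        "f_phi": pacmap.phase_freq,
        "f_a": pacmap.amp_freq,
        "pac": pacmap.pac,
    }).to_csv(path, index=False)


def write_megpac(path: str | Path, megpac: dict) -> None:
    """Write {condition: {subject: (V, n) array}} megPAC series at 10 Hz."""
    with h5py.File(path, "w") as f:
        for cond, subjects in megpac.items():
            for subj, series in subjects.items():
                data = series.data if isinstance(series, MegPACSeries) else series
                rate = series.rate if isinstance(series, MegPACSeries) else 10.0
                g = f.create_group(f"megpac/{cond}/{subj}")
                g.create_dataset("data", data=data)
                g.attrs["rate"] = rate


def read_megpac(path: str | Path) -> dict:
    out: dict[str, dict] = {}
    with h5py.File(path, "r") as f:
        for cond, cgroup in f["megpac"].items():
            out[cond] = {
                subj: MegPACSeries(g["data"][()], float(g.attrs["rate"]), ())
                for subj, g in cgroup.items()
            }
    return out


def write_rsnset(path: str | Path, rsns_by_condition: dict) -> None:
    with h5py.File(path, "w") as f:
        for cond, rsns in rsns_by_condition.items():
            g = f.create_group(f"rsn/{cond}")
            g.create_dataset("modes", data=rsns.modes)
            g.create_dataset("singular_values", data=rsns.singular_values)
            g.create_dataset("subset_indices",
                             data=rsns.subset_used.subset_indices)
            g.create_dataset("subset_modes", data=rsns.subset_modes)
            g.attrs["subset_method"] = rsns.subset_used.method


def read_rsnset(path: str | Path) -> dict:
    out = {}
    with h5py.File(path, "r") as f:
        for cond, g in f["rsn"].items():
            idx = g["subset_indices"][()]
            plan = ReductionPlan(idx, str(g.attrs["subset_method"]), len(idx))
            out[cond] = RSNSet(g["modes"][()], g["singular_values"][()],
                               plan, g["subset_modes"][()])
    return out


def rsn_map_to_csv(path: str | Path, map_values: np.ndarray) -> None:
    """Surface overlay table (vertex_id, value), 0-based."""
    pd.DataFrame({
        "vertex_id": np.arange(len(map_values)),
        "value": np.asarray(map_values, float),
    }).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# named vertex maps (reference / template / healthy-control) and matched runs


def write_named_maps(path: str | Path, maps: dict) -> None:
    """Write {name: (V,) map} (e.g. ground-truth or template networks)."""
    with h5py.File(path, "w") as f:
        for name, values in maps.items():
            f.create_dataset(f"maps/{name}", data=np.asarray(values, float))


def read_named_maps(path: str | Path) -> dict:
    with h5py.File(path, "r") as f:
        return {name: ds[()] for name, ds in f["maps"].items()}


def write_matched(path: str | Path, matched: dict) -> None:
    """Write {condition: {network: [MatchedRun]}}."""
    with h5py.File(path, "w") as f:
        for cond, nets in matched.items():
            for net, runs in nets.items():
                g = f.create_group(f"matched/{cond}/{net}")
                g.create_dataset("maps", data=np.vstack([r.map for r in runs]))
                g.create_dataset("phi", data=[r.phi for r in runs])
                g.create_dataset("mode_index",
                                 data=[r.mode_index for r in runs])
                g.create_dataset("valid", data=[r.valid for r in runs])
                g.create_dataset(
                    "left_out",
                    data=np.array([r.left_out for r in runs], dtype="S"),
                )


def read_matched(path: str | Path) -> dict:
    from .stats import MatchedRun

    out: dict[str, dict] = {}
    with h5py.File(path, "r") as f:
        for cond, cgroup in f["matched"].items():
            out[cond] = {}
            for net, g in cgroup.items():
                left = [s.decode() for s in g["left_out"][()]]
                out[cond][net] = [
                    MatchedRun(left[i], int(g["mode_index"][i]),
                               float(g["phi"][i]), g["maps"][i],
                               bool(g["valid"][i]))
                    for i in range(len(left))
                ]
    return out


def write_runfreq(path: str | Path, run_freq_maps: dict) -> None:
    """Write {condition: {left_out: (V,) phase-frequency map}}."""
    with h5py.File(path, "w") as f:
        for cond, runs in run_freq_maps.items():
            for left_out, fmap in runs.items():
                f.create_dataset(f"runfreq/{cond}/{left_out}", data=fmap)


def read_runfreq(path: str | Path) -> dict:
    with h5py.File(path, "r") as f:
        return {
            cond: {lo: ds[()] for lo, ds in cgroup.items()}
            for cond, cgroup in f["runfreq"].items()
        }


# ---------------------------------------------------------------------------
# run manifest


@dataclass
class RunManifest:
    """Everything needed to re-run a pipeline invocation bit-identically."""

    config: dict
    seed: int
    code_version: str
    input_digests: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    created: str = field(
        default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S")
    )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         default=str))

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
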