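"""File formats: spectral-density tables, the HDF5 result container,
flat-text exports, and an optional line-broadening cache.

Spectral densities are two-column delimited text (frequency cm^-1, J cm^-1)
with '#' comments.  Results go into one HDF5 file:

    /populations            (site x time) ensemble-mean populations
    /populations_t          time grid (fs)
    /dissipation/accumulated  (site x snapshot x frequency), cm^-1 per cm^-1
    /dissipation/total        (snapshot x frequency)
    /dissipation/omega        mode frequency grid (cm^-1)
    /dissipation/snapshots    snapshot times (fs)
    /meta                   config echo (YAML), units, labels, seed

Every array also has a flat TSV mirror via :func:`export_text`.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .bath import SpectralDensity
from .constants import PhysicalConstants
from .lineshape import LineBroadening

__all__ = [
    "load_spectral_density",
    "write_result",
    "read_result",
    "export_text",
    "load_cached_lineshape",
    "store_cached_lineshape",
]

UNITS = {"frequency": "cm^-1", "energy": "cm^-1", "time": "fs", "dissipation": "cm^-1 per cm^-1"}


def load_spectral_density(path: str | Path, label: str = "") -> SpectralDensity:
    """Read a two-column (omega, J) table; '#' lines are comments."""
    data = np.loadtxt(path, comments="#")
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (frequency, J)")
    return SpectralDensity(data[:, 0], data[:, 1], label or Path(path).stem)


def write_result(path: str | Path, result) -> None:
    """Serialize a SimulationResult into the HDF5 container."""
    ens = result.ensemble
    field = ens.mean_field
    with h5py.File(path, "w") as h5:
        h5.create_dataset("populations", data=ens.mean_populations)
        h5.create_dataset("populations_t", data=ens.t_grid)
        grp = h5.create_group("dissipation")
        grp.create_dataset("accumulated", data=field.E_acc)
        grp.create_dataset("total", data=field.E_tot)
        grp.create_dataset("omega", data=field.omega_grid)
        grp.create_dataset("snapshots", data=field.snapshot_times)
        h5.create_dataset("scalar/site_dissipation", data=ens.scalar_site_energy)
        h5.create_dataset("scalar/site_dissipation_stderr", data=ens.scalar_site_stderr)
        meta = h5.create_group("meta")
        meta.attrs["config"] = yaml.safe_dump(result.config.to_dict())
        meta.attrs["units"] = json.dumps(UNITS)
        meta.attrs["labels"] = json.dumps(list(result.labels))
        meta.attrs["seed"] = result.config.seed
        meta.attrs["n_realizations"] = ens.n_effective
        meta.attrs["site_energies_cm1"] = result.site_energies
        meta.attrs["warnings"] = json.dumps(list(result.warnings))
        meta.attrs["validation"] = json.dumps(result.validation)


def read_result(path: str | Path) -> dict:
    """Load the container back into plain arrays and metadata."""
    out: dict = {}
    with h5py.File(path, "r") as h5:
        out["populations"] = h5["populations"][...]
        out["populations_t"] = h5["populations_t"][...]
        out["accumulated"] = h5["dissipation/accumulated"][...]
        out["total"] = h5["dissipation/total"][...]
        out["omega"] = h5["dissipation/omega"][...]
        out["snapshots"] = h5["dissipation/snapshots"][...]
        out["labels"] = json.loads(h5["meta"].attrs["labels"])
        out["config"] = yaml.safe_load(h5["meta"].attrs["config"])
        out["units"] = json.loads(h5["meta"].attrs["units"])
    return out


def export_text(result, out_dir: str | Path) -> list[Path]:
    """Write flat TSV mirrors of every container array; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ens = result.ensemble
    field = ens.mean_field
    written = []

    pop_path = out_dir / "populations.tsv"
    header = "t_fs\t" + "\t".join(result.labels)
    np.savetxt(
        pop_path,
        np.column_stack([ens.t_grid, ens.mean_populations.T]),
        delimiter="\t",
        header=header,
        comments="# ",
    )
    written.append(pop_path)

    for s, t_snap in enumerate(field.snapshot_times):
        snap_path = out_dir / f"dissipation_{int(round(t_snap))}fs.tsv"
        cols = [field.omega_grid] + [field.E_acc[a, s] for a in range(len(result.labels))]
        cols.append(field.E_tot[s])
        header = "omega_cm1\t" + "\t".join(result.labels) + "\ttotal"
        np.savetxt(snap_path, np.column_stack(cols), delimiter="\t", header=header, comments="# ")
        written.append(snap_path)
    return written


# ------------------------------------------------------------- lineshape cache

def _lineshape_key(J: SpectralDensity, consts: PhysicalConstants, t_grid: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(J.omega.tobytes())
    h.update(J.values.tobytes())
    h.update(np.array([consts.temperature, consts.hbar, consts.kB]).tobytes())
    h.update(np.array([t_grid[0], t_grid[-1], t_grid.size], dtype=float).tobytes())
    return h.hexdigest()


def load_cached_lineshape(
    cache_path: str | Path,
    J: SpectralDensity,
    consts: PhysicalConstants,
    t_grid: np.ndarray,
) -> LineBroadening | None:
    """Return the cached g(t) for this density/temperature/grid, if present."""
    cache_path = Path(cache_path)
    if not cache_path.exists():
        return None
    key = _lineshape_key(J, consts, t_grid)
    with h5py.File(cache_path, "r") as h5:
        if key not in h5:
            return None
        grp = h5[key]
        return LineBroadening(grp["t_grid"][...], grp["g_values"][...], grp.attrs["lambda_total"])


def store_cached_lineshape(
    cache_path: str | Path,
    J: SpectralDensity,
    consts: PhysicalConstants,
    g: LineBroadening,
) -> None:
    key = _lineshape_key(J, consts, g.t_grid)
    with h5py.File(cache_path, "a") as h5:
        if key in h5:
            return
        grp = h5.create_group(key)
        grp.create_dataset("t_grid", data=g.t_grid)
        grp.create_dataset("g_values", data=g.g_values)
        grp.attrs["lambda_total"] = g.lambda_total
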