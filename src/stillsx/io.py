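"""Plain-text dialects for geometry, observations, merged tables and config.

Everything users exchange with the pipeline is diffable text: a line-based
panel-geometry grammar, whitespace-delimited observation and merged
reflection tables, and a YAML run configuration with strict key checking.
Images use HDF5 (one data set per panel) since they are bulky arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .detector import DetectorGeometry, Panel
from .merging import OBSERVATION_COLUMNS

__all__ = [
    "read_geometry",
    "write_geometry",
    "read_observations",
    "write_observations",
    "read_stream",
    "write_stream",
    "read_merged",
    "write_merged",
    "read_images",
    "write_images",
    "RunConfig",
    "read_config",
]


class GeometryError(ValueError):
    pass


# ---------------------------------------------------------------------------
# geometry dialect
#
# Line grammar (one statement per line, '#' starts a comment):
#   panel <name>
#   fs <x> <y> <z>        lab displacement per fast-scan pixel (m)
#   ss <x> <y> <z>        lab displacement per slow-scan pixel (m)
#   corner <x> <y> <z>    lab position of the (0,0) pixel corner (m)
#   size <n_fs> <n_ss>
#   gain <g>
# Statements apply to the most recent 'panel'.
# ---------------------------------------------------------------------------

def read_geometry(path) -> DetectorGeometry:
    panels = []
    cur: dict | None = None

    def finish():
        if cur is None:
            return
        missing = {"fs", "ss", "corner", "size"} - cur.keys()
        if missing:
            raise GeometryError(
                f"panel {cur.get('name')!r}: missing {sorted(missing)}"
            )
        D = np.column_stack([cur["fs"], cur["ss"]])
        panels.append(
            Panel(D=D, origin_o=cur["corner"], n_fs=cur["size"][0],
                  n_ss=cur["size"][1], gain_g=cur.get("gain", 1.0),
                  name=cur["name"])
        )

    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tok = line.split()
        key, args = tok[0], tok[1:]
        try:
            if key == "panel":
                finish()
                cur = {"name": args[0]}
            elif cur is None:
                raise GeometryError(f"{key!r} before any 'panel' statement")
            elif key in ("fs", "ss", "corner"):
                cur[key] = np.array([float(a) for a in args], dtype=float)
                if cur[key].size != 3:
                    raise GeometryError(f"{key} needs three components")
            elif key == "size":
                cur["size"] = (int(args[0]), int(args[1]))
            elif key == "gain":
                cur["gain"] = float(args[0])
            else:
                raise GeometryError(f"unknown key {key!r}")
        except (IndexError, ValueError) as err:
            raise GeometryError(f"{path}, line {ln}: {err}") from err
    finish()
    if not panels:
        raise GeometryError(f"{path}: no panels defined")
    return DetectorGeometry(tuple(panels))


def write_geometry(detector: DetectorGeometry, path) -> None:
    out = []
    for p in detector:
        out.append(f"panel {p.name}")
        out.append("fs " + " ".join(repr(float(v)) for v in p.D[:, 0]))
        out.append("ss " + " ".join(repr(float(v)) for v in p.D[:, 1]))
        out.append("corner " + " ".join(repr(float(v)) for v in p.origin_o))
        out.append(f"size {p.n_fs} {p.n_ss}")
        out.append(f"gain {float(p.gain_g)!r}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# observation and merged tables (whitespace-delimited with a header line)
# ---------------------------------------------------------------------------

def read_observations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", float_precision="round_trip")
    missing = [c for c in ("crystal_id", "h", "k", "l", "I", "sigma") if c not in df]
    if missing:
        raise ValueError(f"{path}: observation table lacks columns {missing}")
    return df


def write_observations(df: pd.DataFrame, path) -> None:
    cols = [c for c in OBSERVATION_COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in OBSERVATION_COLUMNS
    ]
    df[cols].to_csv(path, sep=" ", index=False)


# ---------------------------------------------------------------------------
# simplified indexed-stills stream
#
# One text file carrying, per still, the indexed reciprocal cell and the
# integrated reflections.  Line grammar ('#' starts a comment):
#   chunk <crystal_id>
#   cell <9 floats>          reciprocal cell matrix, row-major, nm^-1
#   refl <h> <k> <l> <I> <sigma> [<panel> <fs> <ss>]
#   end
# ---------------------------------------------------------------------------

def read_stream(path):
    """Parse a simplified indexed-stills stream.

    Returns ``(observations, cells)``: the standard observation table plus
    a dict of reciprocal cell matrices keyed by crystal id, ready to seed
    :func:`stillsx.merging.merge`.
    """
    rows = []
    cells: dict = {}
    cid = None
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tok = line.split()
        key, args = tok[0], tok[1:]
        try:
            if key == "chunk":
                cid = int(args[0])
            elif key == "end":
                cid = None
            elif cid is None:
                raise ValueError(f"{key!r} outside a chunk")
            elif key == "cell":
                if len(args) != 9:
                    raise ValueError("cell needs nine components")
                cells[cid] = np.array([float(a) for a in args]).reshape(3, 3)
            elif key == "refl":
                panel = args[5] if len(args) > 5 else "panel0"
                fs = float(args[6]) if len(args) > 6 else 0.0
                ss = float(args[7]) if len(args) > 7 else 0.0
                rows.append((cid, int(args[0]), int(args[1]), int(args[2]),
                             float(args[3]), float(args[4]), panel, fs, ss))
            else:
                raise ValueError(f"unknown key {key!r}")
        except (IndexError, ValueError) as err:
            raise ValueError(f"{path}, line {ln}: {err}") from err
    df = pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)
    missing = sorted(set(df["crystal_id"]) - set(cells))
    if missing:
        raise ValueError(f"{path}: chunks without a cell statement: {missing[:10]}")
    return df, cells


def write_stream(observations: pd.DataFrame, cells: dict, path) -> None:
    out = []
    for cid, sub in observations.groupby("crystal_id", sort=True):
        out.append(f"chunk {int(cid)}")
        out.append("cell " + " ".join(repr(float(v)) for v in
                                      np.asarray(cells[cid]).ravel()))
        for r in sub.itertuples(index=False):
            out.append(f"refl {int(r.h)} {int(r.k)} {int(r.l)} {r.I!r} {r.sigma!r} "
                       f"{r.panel} {r.fs!r} {r.ss!r}")
        out.append("end")
    Path(path).write_text("\n".join(out) + "\n")


def read_merged(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=r"\s+", float_precision="round_trip")


def write_merged(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep=" ", index=False)


# ---------------------------------------------------------------------------
# images (HDF5, one data set per panel)
# ---------------------------------------------------------------------------

def write_images(images: dict, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        for name, arr in images.items():
            f.create_dataset(name, data=np.asarray(arr, dtype=float))


def read_images(path) -> dict:
    import h5py

    out = {}
    with h5py.File(path, "r") as f:
        for name in f:
            out[name] = f[name][()]
    return out


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Structured configuration of a pipeline run (YAML on disk).

    Unknown keys are rejected by name so typos fail loudly.
    """

    # beam
    wavelength: float | None = None  # nm; alternative to nu0
    nu0: float | None = None
    bandwidth: float = 0.0
    divergence: float = 0.0
    polarization: float = 0.0
    pol_normal: tuple = (0.0, 1.0, 0.0)
    flux: float = 1.0
    # crystal defaults
    cell_edge: float = 10.0
    shape_sigma: float = 2e-3
    mosaicity: float = 1e-3
    strain: float = 1e-3
    # cutoffs
    sigma_cutoff: float = 3.0
    d_min: float = 0.8
    sigma_ellipse: float = 4.0
    # optimizer
    max_outer: int = 8
    tol: float = 1e-6
    # error model / outliers
    alpha: float = 1.0
    beta: float = 1e-4
    epsilon: float = 1.0 / 16.0
    gamma: float | None = None
    # misc
    seed: int = 0
    verbosity: int = 1

    def beam(self):
        from .beam import BeamModel

        nu0 = self.nu0 if self.nu0 is not None else (
            1.0 / self.wavelength if self.wavelength else None
        )
        if nu0 is None:
            raise ValueError("config must set either nu0 or wavelength")
        return BeamModel(
            nu0=nu0, bandwidth=self.bandwidth, divergence=self.divergence,
            polarization_p=self.polarization, pol_normal=np.asarray(self.pol_normal),
            flux=self.flux,
        )


def read_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"{path}: unknown config keys {unknown}")
    return RunConfig(**raw)
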