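"""Trajectory and path-collection I/O.

Frames travel as element symbols plus Cartesian coordinates in Å, the
format written by most ab initio MD engines.  Labeled collections of
paths (reactive / unreactive) are described by a plain CSV manifest so
that the output of any path-sampling or segmentation step can be fed to
the analysis without a bespoke directory layout.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Frame",
    "PathRecord",
    "XYZParseError",
    "ManifestError",
    "read_xyz",
    "write_xyz",
    "load_path_collection",
    "write_manifest",
]

# Element symbols accepted in XYZ input.  "X" is the conventional dummy /
# marker element used for visualization.
_PERIODIC = {
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr", "Y", "Zr",
    "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe", "Cs", "Ba", "X",
}

VALID_LABELS = ("reactive", "unreactive", "unlabeled")


class XYZParseError(ValueError):
    """Raised when an XYZ file violates the multi-frame layout."""


class ManifestError(ValueError):
    """Raised when a path-collection manifest is malformed."""


@dataclass
class Frame:
    """One time step: element symbols and coordinates (Å).

    Velocities, when present in the input, are stored but never enter
    the default feature set.
    """

    elements: tuple[str, ...]
    coords: np.ndarray  # (M, 3) float, Å
    velocities: np.ndarray | None = None  # (M, 3) float, optional
    time_index: int = 0

    def __post_init__(self) -> None:
        self.elements = tuple(self.elements)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (M, 3), got {self.coords.shape}")
        if len(self.elements) != self.coords.shape[0]:
            raise ValueError(
                f"{len(self.elements)} elements but {self.coords.shape[0]} coordinate rows"
            )
        if self.coords.shape[0] < 1:
            raise ValueError("a frame needs at least one atom")
        bad = sorted(set(self.elements) - _PERIODIC)
        if bad:
            raise ValueError(f"unknown element symbols: {bad}")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.coords.shape:
                raise ValueError("velocities must match coords shape")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass
class PathRecord:
    """An ordered frame sequence with a reactive/unreactive label.

    ``generation_order`` is the sampling-time ordinal of the path within
    its collection; downstream block averaging relies on it.
    """

    frames: list[Frame]
    label: str
    path_id: str
    generation_order: int
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise ValueError(
                f"label {self.label!r} not in {VALID_LABELS}"
            )
        if not self.frames:
            raise ValueError(f"path {self.path_id!r} has no frames")
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        ref = sorted(self.frames[0].elements)
        for fr in self.frames[1:]:
            if sorted(fr.elements) != ref:
                raise ValueError(
                    f"path {self.path_id!r}: frames do not share one element multiset"
                )


def read_xyz(file) -> list[Frame]:
    """Read a multi-frame XYZ file into a list of :class:`Frame`.

    Lines with seven numeric columns are read as ``x y z vx vy vz``; the
    trailing three are stored as velocities.
    """
    path = Path(file)
    with open(path) as fh:
        lines = fh.read().splitlines()
    frames: list[Frame] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():  # tolerate trailing blank lines
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise XYZParseError(
                f"{path}: frame {len(frames)}: expected atom count, got {lines[i]!r}"
            ) from None
        body = lines[i + 2 : i + 2 + n]
        if i + 1 >= len(lines) or len(body) < n or any(not ln.strip() for ln in body):
            raise XYZParseError(
                f"{path}: frame {len(frames)}: count line says {n} atoms "
                f"but only {sum(bool(ln.strip()) for ln in body)} atom lines follow"
            )
        elements, coords, vels = [], [], []
        for ln in body:
            parts = ln.split()
            if len(parts) not in (4, 7):
                raise XYZParseError(
                    f"{path}: frame {len(frames)}: bad atom line {ln!r}"
                )
            sym = parts[0]
            if sym not in _PERIODIC:
                raise XYZParseError(
                    f"{path}: frame {len(frames)}: unknown element {sym!r}"
                )
            elements.append(sym)
            coords.append([float(x) for x in parts[1:4]])
            if len(parts) == 7:
                vels.append([float(x) for x in parts[4:7]])
        if vels and len(vels) != n:
            raise XYZParseError(
                f"{path}: frame {len(frames)}: velocities on some atom lines only"
            )
        frames.append(
            Frame(
                elements=tuple(elements),
                coords=np.array(coords),
                velocities=np.array(vels) if vels else None,
                time_index=len(frames),
            )
        )
        i += 2 + n
    return frames


def write_xyz(frames: Sequence[Frame], file) -> None:
    """Write frames as standard multi-frame XYZ (6 decimal places).

    The comment line carries the frame's ``time_index`` so a round trip
    preserves frame identity.
    """
    if not frames:
        raise ValueError("write_xyz requires at least one frame")
    buf = io.StringIO()
    for fr in frames:
        buf.write(f"{fr.n_atoms}\n")
        buf.write(f"time_index={fr.time_index}\n")
        for k, sym in enumerate(fr.elements):
            x, y, z = fr.coords[k]
            line = f"{sym} {x:.6f} {y:.6f} {z:.6f}"
            if fr.velocities is not None:
                vx, vy, vz = fr.velocities[k]
                line += f" {vx:.6f} {vy:.6f} {vz:.6f}"
            buf.write(line + "\n")
    Path(file).write_text(buf.getvalue())


def load_path_collection(manifest) -> list[PathRecord]:
    """Load a labeled path collection from a CSV manifest.

    Columns: ``path_id, xyz_file, label, generation_order[, weight]``.
    ``xyz_file`` is resolved relative to the manifest's directory.
    """
    manifest = Path(manifest)
    df = pd.read_csv(manifest, dtype={"path_id": str})
    required = {"path_id", "xyz_file", "label", "generation_order"}
    missing = required - set(df.columns)
    if missing:
        raise ManifestError(f"{manifest}: missing columns {sorted(missing)}")
    if df["path_id"].duplicated().any():
        dupes = df.loc[df["path_id"].duplicated(), "path_id"].tolist()
        raise ManifestError(f"{manifest}: duplicate path_id {dupes}")
    if df["generation_order"].duplicated().any():
        raise ManifestError(f"{manifest}: generation_order values must be unique")
    records: list[PathRecord] = []
    for row_no, row in enumerate(df.itertuples(index=False)):
        if row.label not in VALID_LABELS:
            raise ManifestError(
                f"{manifest}: row {row_no}: label {row.label!r} "
                f"not in {VALID_LABELS}"
            )
        xyz = manifest.parent / str(row.xyz_file)
        if not xyz.exists():
            raise ManifestError(f"{manifest}: row {row_no}: missing file {xyz}")
        weight = float(getattr(row, "weight", 1.0)) if "weight" in df.columns else 1.0
        records.append(
            PathRecord(
                frames=read_xyz(xyz),
                label=str(row.label),
                path_id=str(row.path_id),
                generation_order=int(row.generation_order),
                weight=weight,
            )
        )
    return records


def write_manifest(records: Iterable[PathRecord], out_dir, manifest_name: str = "manifest.csv") -> Path:
    """Write each record's trajectory plus a manifest CSV into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        fname = f"{rec.path_id}.xyz"
        write_xyz(rec.frames, out_dir / fname)
        rows.append(
            {
                "path_id": rec.path_id,
                "xyz_file": fname,
                "label": rec.label,
                "generation_order": rec.generation_order,
                "weight": rec.weight,
            }
        )
    path = out_dir / manifest_name
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
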