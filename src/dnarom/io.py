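"""File formats and run configuration.

Plain-text formats throughout: dense matrices with a one-line header,
whitespace-delimited partition/base-pair maps, CSV I-V tables with a JSON
metadata sidecar, PGM/PNG images, and flat YAML run configs.  Matrix and
I-V round-trips are lossless at 17 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .basis import AtomicBasisSystem
from .transport import IVTable

__all__ = [
    "FormatError",
    "read_matrix",
    "write_matrix",
    "read_partition",
    "read_basepairs",
    "read_basis_system",
    "read_iv",
    "write_iv",
    "read_image",
    "write_pgm",
    "RunConfig",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


# ------------------------------------------------------------------ matrices


def write_matrix(path, M: np.ndarray, units: str = "eV") -> None:
    """Write a dense real matrix with a ``# rows cols units`` header."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError("matrix must be 2-D")
    with open(path, "w") as fh:
        fh.write(f"# {M.shape[0]} {M.shape[1]} {units}\n")
        np.savetxt(fh, M, fmt="%.17g")


def read_matrix(path) -> tuple[np.ndarray, str]:
    """Read a matrix written by :func:`write_matrix`; returns (M, units)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise FormatError(f"{path.name}: missing '# rows cols units' header")
        parts = header[1:].split()
        if len(parts) < 3:
            raise FormatError(f"{path.name}: malformed header {header!r}")
        try:
            rows, cols = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise FormatError(f"{path.name}: non-integer dimensions in header") from exc
        units = " ".join(parts[2:])
        try:
            M = np.loadtxt(fh, ndmin=2)
        except ValueError as exc:
            raise FormatError(f"{path.name}: unparsable matrix body ({exc})") from exc
    if M.shape != (rows, cols):
        raise FormatError(
            f"{path.name}: header says {rows}x{cols}, body is {M.shape[0]}x{M.shape[1]}"
        )
    if not np.isfinite(M).all():
        bad = np.argwhere(~np.isfinite(M))[0]
        raise FormatError(f"{path.name}: non-finite entry at row {bad[0]}, col {bad[1]}")
    return M, units


def read_partition(path) -> list[tuple[str, int, int]]:
    """Partition file: one ``name start end`` line per nucleotide.

    Indices are 0-based, half-open, in strand order.
    """
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#")[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 3:
            raise FormatError(f"partition line {ln}: expected 'name start end'")
        try:
            out.append((parts[0], int(parts[1]), int(parts[2])))
        except ValueError as exc:
            raise FormatError(f"partition line {ln}: non-integer range") from exc
    if not out:
        raise FormatError("partition file is empty")
    return out


def read_basepairs(path) -> list[tuple[int, int, int]]:
    """Base-pair file: one ``pair_index nuc_a nuc_b`` line per pair."""
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#")[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 3:
            raise FormatError(f"base-pair line {ln}: expected 'pair nuc_a nuc_b'")
        try:
            out.append((int(parts[0]), int(parts[1]), int(parts[2])))
        except ValueError as exc:
            raise FormatError(f"base-pair line {ln}: non-integer field") from exc
    if not out:
        raise FormatError("base-pair file is empty")
    return out


def read_basis_system(
    fock_path, overlap_path, partition_path, basepair_path
) -> AtomicBasisSystem:
    """Assemble an :class:`AtomicBasisSystem` from its four input files."""
    F, _ = read_matrix(fock_path)
    S, _ = read_matrix(overlap_path)
    part = read_partition(partition_path)
    pairs = sorted(read_basepairs(basepair_path))
    return AtomicBasisSystem(
        F=F,
        S=S,
        partition=[(start, stop) for _, start, stop in part],
        basepair_groups=[(a, b) for _, a, b in pairs],
    )


# ---------------------------------------------------------------- I-V tables


def write_iv(path, table: IVTable) -> None:
    """CSV (``bias_V, delta_eV, current_A``) plus a JSON metadata sidecar."""
    path = Path(path)
    bias, delta = np.meshgrid(table.bias_grid, table.delta_grid, indexing="ij")
    df = pd.DataFrame(
        {
            "bias_V": bias.ravel(),
            "delta_eV": delta.ravel(),
            "current_A": table.current.ravel(),
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "species": table.species,
        "e_f_anchor_eV": table.e_f_anchor,
        "bias_grid_V": [float(v) for v in table.bias_grid],
        "delta_grid_eV": [float(d) for d in table.delta_grid],
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=1)
    )


def read_iv(path) -> IVTable:
    """Read an I-V table written by :func:`write_iv` (bit-stable round trip)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise FormatError(f"{path.name}: unreadable CSV ({exc})") from exc
    for col in ("bias_V", "delta_eV", "current_A"):
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing column {col!r}")
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        species = meta.get("species", "")
        anchor = float(meta.get("e_f_anchor_eV", 0.0))
    else:
        species, anchor = "", 0.0
    bias_grid = np.unique(df["bias_V"].to_numpy())
    delta_grid = np.unique(df["delta_eV"].to_numpy())
    if len(df) != bias_grid.size * delta_grid.size:
        raise FormatError(f"{path.name}: table is not a complete bias x delta grid")
    current = (
        df.sort_values(["bias_V", "delta_eV"])["current_A"]
        .to_numpy()
        .reshape(bias_grid.size, delta_grid.size)
    )
    return IVTable(
        species=species,
        bias_grid=bias_grid,
        delta_grid=delta_grid,
        current=current,
        e_f_anchor=anchor,
    )


# -------------------------------------------------------------------- images


def read_image(path) -> np.ndarray:
    """Read a PGM (ASCII or binary) or grayscale PNG into a float array.

    Values are scaled to [0, 1]; RGB inputs are converted to luminance.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            mode = im.mode
            arr = np.asarray(im.convert("F"), dtype=float)
    except Exception as exc:
        raise FormatError(f"{path.name}: unreadable image ({exc})") from exc
    # PIL "F" conversion of 8/16-bit images keeps the original integer scale
    maxval = 65535.0 if mode in ("I", "I;16", "I;16B") else 255.0
    return arr / maxval


def write_pgm(path, image: np.ndarray, maxval: int = 65535) -> None:
    """Write a float image in [0, 1] as a binary PGM (P5)."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    q = np.round(arr * maxval).astype(">u2" if maxval > 255 else "u1")
    with open(path, "wb") as fh:
        fh.write(f"P5\n{arr.shape[1]} {arr.shape[0]}\n{maxval}\n".encode())
        fh.write(q.tobytes())


# -------------------------------------------------------------------- config


class RunConfig:
    """Flat key-value configuration with strict key checking.

    Known keys and their defaults live in :attr:`DEFAULTS`; unknown keys in
    a file or override set are rejected.  Every run should write the
    resolved configuration next to its outputs (:meth:`dump`).
    """

    DEFAULTS: dict = {
        # geometry / device
        "m": 64,
        "n": 64,
        "r_int_ohm": 1e4,
        "v_in": 1.0,
        "solver": "kirchhoff",
        "tol": 1e-6,
        # transport
        "gamma_contact_ev": 1.0,
        "gamma_probe_ev": 0.010,
        "kt_ev": 0.0259,
        "energy_step_ev": 1e-3,
        "bias_max_v": 1.0,
        "bias_step_v": 0.05,
        "delta_max_ev": 0.25,
        "delta_step_ev": 0.025,
        # monte carlo / storage
        "n_sims": 100,
        "delta_max": 0.1,
        "sampling_mode": "per_cell",
        "p_one": 0.5,
        "n_images": 50,
        "image_size": 128,
        "seed": 0,
        # output
        "out_dir": "dnarom_out",
        "log_level": "INFO",
    }

    def __init__(self, **overrides):
        unknown = set(overrides) - set(self.DEFAULTS)
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        self._values = {**self.DEFAULTS, **overrides}

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise FormatError("config file must be a flat key-value mapping")
        return cls(**data)

    def __getitem__(self, key):
        return self._values[key]

    def updated(self, **overrides) -> "RunConfig":
        merged = {**self._values}
        unknown = set(overrides) - set(self.DEFAULTS)
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        merged.update({k: v for k, v in overrides.items() if v is not None})
        return RunConfig(**merged)

    def as_dict(self) -> dict:
        return dict(self._values)

    def dump(self, path) -> None:
        """Write the resolved configuration (reproducibility record)."""
        Path(path).write_text(yaml.safe_dump(self._values, sort_keys=True))
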