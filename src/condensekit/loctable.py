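"""Localization tables: the tabular output of single-molecule fitting.

A :class:`LocalizationTable` wraps a :class:`pandas.DataFrame` holding one
row per fitted blink event.  Mandatory columns follow the common SMLM
convention so third-party tables can be ingested:

``frame``      acquisition frame index
``x``, ``y``   sub-pixel coordinates, in camera pixels (x = column, y = row)
``photons``    fitted photon count
``sx``, ``sy`` fitted PSF widths (pixels)
``precision_nm``  estimated localization uncertainty

Extra columns are carried along unchanged.  Physical coordinates are
derived via ``pixel_size_nm``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

MANDATORY_COLUMNS = ("frame", "x", "y", "photons", "sx", "sy", "precision_nm")


class SchemaError(ValueError):
    """Raised when a localization file lacks mandatory columns."""


@dataclass
class LocalizationTable:
    """Per-event localization records with pixel-size metadata."""

    df: pd.DataFrame
    pixel_size_nm: float = 130.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in MANDATORY_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"localization table missing columns: {missing}")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def x(self) -> np.ndarray:
        return self.df["x"].to_numpy(float)

    @property
    def y(self) -> np.ndarray:
        return self.df["y"].to_numpy(float)

    @property
    def x_nm(self) -> np.ndarray:
        return self.x * self.pixel_size_nm

    @property
    def y_nm(self) -> np.ndarray:
        return self.y * self.pixel_size_nm

    @property
    def xy_nm(self) -> np.ndarray:
        """(n, 2) array of (x, y) positions in nm."""
        return np.column_stack([self.x_nm, self.y_nm])

    @classmethod
    def empty(cls, pixel_size_nm: float = 130.0) -> "LocalizationTable":
        df = pd.DataFrame({c: pd.Series(dtype=float) for c in MANDATORY_COLUMNS})
        df["frame"] = df["frame"].astype(np.int64)
        return cls(df, pixel_size_nm=pixel_size_nm)

    @classmethod
    def from_arrays(
        cls,
        *,
        frame,
        x,
        y,
        photons,
        sx,
        sy,
        precision_nm,
        pixel_size_nm: float = 130.0,
        **extra,
    ) -> "LocalizationTable":
        df = pd.DataFrame(
            {
                "frame": np.asarray(frame, dtype=np.int64),
                "x": np.asarray(x, dtype=float),
                "y": np.asarray(y, dtype=float),
                "photons": np.asarray(photons, dtype=float),
                "sx": np.asarray(sx, dtype=float),
                "sy": np.asarray(sy, dtype=float),
                "precision_nm": np.asarray(precision_nm, dtype=float),
            }
        )
        for k, v in extra.items():
            df[k] = v
        return cls(df, pixel_size_nm=pixel_size_nm)


def write_locs(table: LocalizationTable, path) -> None:
    """Write a localization table to CSV or HDF5 (by file extension).

    The HDF5 dialect stores a single ``locs`` compound dataset plus a
    ``pixel_size_nm`` attribute; the CSV dialect stores the pixel size in a
    leading ``#`` metadata line.  Both round-trip losslessly.
    """
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        rec = table.df.to_records(index=False)
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("locs", data=rec)
            ds.attrs["pixel_size_nm"] = table.pixel_size_nm
            for k, v in table.meta.items():
                ds.attrs[k] = v
    else:
        with open(path, "w") as f:
            f.write(f"# pixel_size_nm={table.pixel_size_nm!r}\n")
            table.df.to_csv(f, index=False)


def read_locs(path, pixel_size_nm: float | None = None) -> LocalizationTable:
    """Read a localization table written by :func:`write_locs`.

    Raises :class:`SchemaError` if mandatory columns are absent.
    """
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "r") as f:
            if "locs" not in f:
                raise SchemaError(f"{path}: no 'locs' dataset")
            ds = f["locs"]
            df = pd.DataFrame.from_records(ds[()])
            px = float(ds.attrs.get("pixel_size_nm", pixel_size_nm or 130.0))
            meta = {
                k: v for k, v in ds.attrs.items() if k != "pixel_size_nm"
            }
    else:
        px = pixel_size_nm or 130.0
        meta = {}
        with open(path) as f:
            first = f.readline()
            if first.startswith("#"):
                for item in first.lstrip("#").strip().split(","):
                    k, _, v = item.partition("=")
                    if k.strip() == "pixel_size_nm":
                        px = float(v)
                    else:
                        meta[k.strip()] = v
                df = pd.read_csv(f)
            else:
                f.seek(0)
                df = pd.read_csv(f)
    if "frame" in df.columns:
        df["frame"] = df["frame"].astype(np.int64)
    return LocalizationTable(df, pixel_size_nm=px, meta=meta)
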