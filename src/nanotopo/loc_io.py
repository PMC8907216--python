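"""Reading, validating and writing single-molecule localization tables.

A localization table holds one row per fitted emitter appearance with, at
minimum, lateral position (nm), acquisition frame index and the fitted photon
intensity (the fixed-width Gaussian fit intensity ``I_fit``). Tables may in
addition carry an axial coordinate ``z`` once one has been assigned.

Two input dialects are supported:

``csv``
    Plain comma-separated values with a header naming at least
    ``x_nm, y_nm, frame, intensity`` (``z_nm`` optional). This is the
    canonical interchange format of the package.
``rapidstorm_text``
    Whitespace-separated values preceded by a single XML-like comment header
    from which the column semantics are parsed (attributes ``Position-0-0``,
    ``Position-1-0``, ``ImageNumber-0-0``, ``Amplitude-0-0``).

All coordinates are nanometers internally.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Localization",
    "LocalizationTable",
    "FormatError",
    "read_localizations",
    "write_localizations",
    "validate_table",
]

#: canonical column order of the CSV dialect
CSV_COLUMNS = ("x_nm", "y_nm", "frame", "intensity_photons")
CSV_Z_COLUMN = "z_nm"

# accepted aliases for the mandatory CSV columns, lowercased
_CSV_ALIASES = {
    "x_nm": ("x_nm", "x", "x [nm]", "position-0-0"),
    "y_nm": ("y_nm", "y", "y [nm]", "position-1-0"),
    "frame": ("frame", "imagenumber", "t"),
    "intensity_photons": ("intensity_photons", "intensity", "photons", "amplitude"),
}
_CSV_Z_ALIASES = ("z_nm", "z", "z [nm]")


class FormatError(ValueError):
    """A localization file does not conform to its declared dialect."""


@dataclass(frozen=True)
class Localization:
    """One fitted emitter appearance."""

    frame: int
    x: float
    y: float
    intensity: float
    z: float | None = None
    channel: str = "transmitted"


@dataclass
class LocalizationTable:
    """An ordered collection of localizations of one channel.

    The backing store is a :class:`pandas.DataFrame` with columns
    ``frame`` (int), ``x``, ``y`` (nm), ``intensity`` (photons) and
    optionally ``z`` (nm). Row order is preserved by every operation in
    this module.
    """

    df: pd.DataFrame
    channel: str = "transmitted"
    units: str = "nm"
    provenance: str = ""

    def __post_init__(self) -> None:
        required = {"frame", "x", "y", "intensity"}
        missing = required - set(self.df.columns)
        if missing:
            raise FormatError(f"localization table lacks columns: {sorted(missing)}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def has_z(self) -> bool:
        return "z" in self.df.columns

    def sort_by_frame(self) -> "LocalizationTable":
        """Return a copy sorted by frame; order within a frame is stable."""
        return LocalizationTable(
            self.df.sort_values("frame", kind="stable").reset_index(drop=True),
            channel=self.channel, units=self.units, provenance=self.provenance,
        )

    @classmethod
    def from_arrays(cls, frame, x, y, intensity, z=None, **kw) -> "LocalizationTable":
        data = {
            "frame": np.asarray(frame, dtype=np.int64),
            "x": np.asarray(x, dtype=float),
            "y": np.asarray(y, dtype=float),
            "intensity": np.asarray(intensity, dtype=float),
        }
        if z is not None:
            data["z"] = np.asarray(z, dtype=float)
        return cls(pd.DataFrame(data), **kw)


def _resolve_csv_columns(header: list[str], path: str) -> dict[str, str]:
    lower = {c.strip().lower(): c for c in header}
    mapping: dict[str, str] = {}
    for canonical, aliases in _CSV_ALIASES.items():
        for alias in aliases:
            if alias in lower:
                mapping[canonical] = lower[alias]
                break
        else:
            raise FormatError(
                f"{path}: missing mandatory column '{canonical}' "
                f"(accepted names: {', '.join(aliases)})"
            )
    for alias in _CSV_Z_ALIASES:
        if alias in lower:
            mapping[CSV_Z_COLUMN] = lower[alias]
            break
    return mapping


def _read_csv(path: str) -> pd.DataFrame:
    try:
        raw = pd.read_csv(path, dtype=str, comment=None)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file without header") from None
    mapping = _resolve_csv_columns(list(raw.columns), path)
    out = {}
    for canonical, source in mapping.items():
        col = pd.to_numeric(raw[source], errors="coerce")
        bad = col.isna() & raw[source].notna()
        if bad.any():
            # +2: header line plus 1-based numbering
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise FormatError(
                f"{path}: non-numeric value {raw[source][bad].iloc[0]!r} "
                f"in column '{source}' on line {line}"
            )
        if col.isna().any():
            line = int(np.flatnonzero(col.isna().to_numpy())[0]) + 2
            raise FormatError(f"{path}: missing value in column '{source}' on line {line}")
        out[canonical] = col.to_numpy(dtype=float)
    df = pd.DataFrame({
        "frame": out["frame"].astype(np.int64),
        "x": out["x_nm"],
        "y": out["y_nm"],
        "intensity": out["intensity_photons"],
    })
    if CSV_Z_COLUMN in out:
        df["z"] = out[CSV_Z_COLUMN]
    return df


_RS_FIELD = re.compile(r"<field\b[^>]*>")
_RS_ATTR = re.compile(r'(\w+)="([^"]*)"')

# rapidSTORM header identifier -> canonical column
_RS_SEMANTICS = {
    "Position-0-0": "x",
    "Position-1-0": "y",
    "ImageNumber-0-0": "frame",
    "Amplitude-0-0": "intensity",
}


def _read_rapidstorm(path: str) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise FormatError(f"{path}: rapidSTORM header comment missing")
        columns: list[str | None] = []
        for m in _RS_FIELD.finditer(header):
            attrs = dict(_RS_ATTR.findall(m.group(0)))
            ident = attrs.get("identifier", "")
            columns.append(_RS_SEMANTICS.get(ident))
        for canonical in ("x", "y", "frame", "intensity"):
            if canonical not in columns:
                raise FormatError(
                    f"{path}: header lacks a field for '{canonical}' "
                    f"(identifiers {list(_RS_SEMANTICS)})"
                )
        rows = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < len(columns):
                raise FormatError(f"{path}: line {lineno} has {len(parts)} fields, "
                                  f"expected {len(columns)}")
            rec = {}
            for name, token in zip(columns, parts):
                if name is None:
                    continue  # unknown extra column
                try:
                    rec[name] = float(token)
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric value {token!r} on line {lineno}"
                    ) from None
            rows.append(rec)
    df = pd.DataFrame(rows, columns=["frame", "x", "y", "intensity"])
    if df.empty:
        df = pd.DataFrame({"frame": [], "x": [], "y": [], "intensity": []})
    df["frame"] = df["frame"].astype(np.int64)
    return df


def read_localizations(path, dialect: str = "csv", channel: str = "transmitted",
                       pixel_size: float | None = None) -> LocalizationTable:
    """Read a localization table.

    Parameters
    ----------
    path : str or path-like
        Input file.
    dialect : {"csv", "rapidstorm_text"}
        File format; see the module docstring.
    channel : str
        Channel label stored on the table ("transmitted" or "reflected").
    pixel_size : float, optional
        If given, lateral coordinates in the file are taken to be in camera
        pixels and are multiplied by this factor (nm/pixel). By default
        coordinates are assumed to be in nm already.
    """
    path = str(path)
    if dialect == "csv":
        df = _read_csv(path)
    elif dialect == "rapidstorm_text":
        df = _read_rapidstorm(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if pixel_size is not None:
        df["x"] *= pixel_size
        df["y"] *= pixel_size
    if (df["frame"] < 0).any():
        raise FormatError(f"{path}: negative frame index")
    return LocalizationTable(df, channel=channel, provenance=f"{dialect}:{path}")


def write_localizations(table: LocalizationTable, path, dialect: str = "csv") -> None:
    """Write a table as CSV with columns x_nm,y_nm,frame,intensity_photons[,z_nm].

    Numeric fields round-trip through :func:`read_localizations` to at least
    six significant digits (the writer emits full ``repr`` precision).
    """
    if dialect != "csv":
        raise ValueError(f"unsupported output dialect {dialect!r}")
    out = pd.DataFrame({
        "x_nm": table.df["x"],
        "y_nm": table.df["y"],
        "frame": table.df["frame"],
        "intensity_photons": table.df["intensity"],
    })
    if table.has_z:
        out["z_nm"] = table.df["z"]
    out.to_csv(path, index=False, float_format="%.10g")


@dataclass
class ValidationReport:
    n_input: int
    n_kept: int

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_kept


def validate_table(table: LocalizationTable, min_intensity: float = 500.0,
                   ) -> tuple[LocalizationTable, ValidationReport]:
    """Apply the lower photon threshold (default 500 photons).

    Removes records with intensity below ``min_intensity`` or non-finite
    coordinates/intensity; order of surviving records is preserved. Returns
    the filtered table and a report with the number removed. Idempotent.
    """
    if min_intensity < 0:
        raise ValueError("min_intensity must be >= 0")
    df = table.df
    finite = np.isfinite(df["x"]) & np.isfinite(df["y"]) & np.isfinite(df["intensity"])
    keep = finite & (df["intensity"] >= min_intensity)
    kept = LocalizationTable(df[keep].reset_index(drop=True), channel=table.channel,
                             units=table.units, provenance=table.provenance)
    return kept, ValidationReport(n_input=len(df), n_kept=len(kept))
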