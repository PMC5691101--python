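"""Reading and writing spectrum traces and cohort tables.

Two text dialects are supported:

* a minimal JCAMP-DX subset (``##TITLE``, ``##XUNITS=GAUSS``,
  ``##NPOINTS``, ``##FIRSTX``, ``##LASTX``, ``##XYDATA=(X++(Y..Y))``)
  with acquisition settings as vendor-agnostic ``##$KEY=`` records;
* a two-column CSV with a ``#``-commented ``key: value`` metadata
  header. A CSV carrying only an intensity column is accepted when the
  header states centre field, sweep width and point count, from which
  the field axis is reconstructed.

Units are fixed (gauss, seconds, milliwatt) and never inferred. Writers
emit deterministic bytes for a given trace, and every writer/reader pair
is a lossless round trip for finite values.
"""

from __future__ import annotations

import io
import os

import numpy as np
import pandas as pd

from .acquisition import AcquisitionSettings, SpectrumTrace
from .errors import ParseError, ValidationError
from .simulate import COHORT_COLUMNS

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_cohort_table",
    "write_cohort_table",
]

_FMT = "%.17g"  # full double precision, deterministic

# (settings attribute, metadata key, parser)
_SETTINGS_KEYS = [
    ("centre_field", "centre_field_G", float),
    ("sweep_width", "sweep_width_G", float),
    ("n_points", "n_points", int),
    ("sweep_time", "sweep_time_s", float),
    ("time_constant", "time_constant_s", float),
    ("modulation_amplitude", "modulation_amplitude_G", float),
    ("microwave_power", "microwave_power_mW", float),
    ("n_averages", "n_averages", int),
    ("gradient", "gradient_G_per_cm", float),
    ("rng_seed", "rng_seed", int),
]

# Metadata a reader may silently default (recorded in provenance when it does).
_NON_ESSENTIAL = {
    "sweep_time_s",
    "time_constant_s",
    "modulation_amplitude_G",
    "microwave_power_mW",
    "n_averages",
    "gradient_G_per_cm",
    "rng_seed",
}


def _settings_from_metadata(
    meta: dict[str, str], n_points_data: int
) -> tuple[AcquisitionSettings, list[str]]:
    defaults = AcquisitionSettings()
    kwargs = {}
    defaulted: list[str] = []
    for attr, key, cast in _SETTINGS_KEYS:
        if key in meta:
            kwargs[attr] = cast(float(meta[key])) if cast is int else cast(meta[key])
        else:
            if key not in _NON_ESSENTIAL and key != "n_points":
                raise ParseError(f"missing required metadata key '{key}'")
            kwargs[attr] = getattr(defaults, attr)
            defaulted.append(key)
    kwargs["n_points"] = n_points_data
    return AcquisitionSettings(**kwargs), defaulted


def _finite_or_raise(values: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(values)):
        raise ValidationError(f"{what} contains NaN or Inf; refusing to write")


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def _write_csv(trace: SpectrumTrace, fh: io.TextIOBase) -> None:
    fh.write("# format_version: 1\n")
    for attr, key, _ in _SETTINGS_KEYS:
        value = getattr(trace.settings, attr)
        text = str(value) if isinstance(value, int) else _FMT % value
        fh.write(f"# {key}: {text}\n")
    for k in sorted(trace.provenance):
        fh.write(f"# prov_{k}: {trace.provenance[k]}\n")
    fh.write("field_G,intensity\n")
    for x, y in zip(trace.field, trace.intensity):
        fh.write(f"{_FMT % x},{_FMT % y}\n")


def _read_csv(lines: list[str], path: str) -> SpectrumTrace:
    meta: dict[str, str] = {}
    prov: dict[str, str] = {}
    data_x: list[float] = []
    data_y: list[float] = []
    intensity_only = False
    in_data = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                key, value = key.strip(), value.strip()
                if key.startswith("prov_"):
                    prov[key[5:]] = value
                else:
                    meta[key] = value
            continue
        if not in_data:
            in_data = True
            cols = [c.strip() for c in line.split(",")]
            if cols and not _is_number(cols[0]):  # header row
                intensity_only = len(cols) == 1
                continue
            intensity_only = len(cols) == 1
            # fall through: first data row without header
        parts = [c.strip() for c in line.split(",")]
        try:
            if intensity_only:
                data_y.append(float(parts[0]))
            else:
                data_x.append(float(parts[0]))
                data_y.append(float(parts[1]))
        except (ValueError, IndexError) as exc:
            raise ParseError(f"malformed CSV data row in {path}: {line!r}",
                             lineno) from exc
    if not data_y:
        raise ParseError(f"no data rows found in {path}")
    settings, defaulted = _settings_from_metadata(meta, len(data_y))
    if data_x:
        field = np.array(data_x)
    else:
        field = settings.field_axis
        prov["field_axis"] = "reconstructed from metadata"
    if defaulted:
        prov["defaulted_metadata"] = ",".join(defaulted)
    trace = SpectrumTrace(field, np.array(data_y), settings, prov)
    return trace


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# JCAMP-DX subset
# ---------------------------------------------------------------------------

def _write_jcampdx(trace: SpectrumTrace, fh: io.TextIOBase) -> None:
    s = trace.settings
    fh.write("##TITLE=EPR spectrum\n")
    fh.write("##JCAMP-DX=4.24\n")
    fh.write("##DATA TYPE=EPR SPECTRUM\n")
    fh.write("##XUNITS=GAUSS\n")
    fh.write("##YUNITS=ARBITRARY UNITS\n")
    fh.write(f"##NPOINTS={s.n_points}\n")
    fh.write(f"##FIRSTX={_FMT % trace.field[0]}\n")
    fh.write(f"##LASTX={_FMT % trace.field[-1]}\n")
    for attr, key, _ in _SETTINGS_KEYS:
        value = getattr(s, attr)
        text = str(value) if isinstance(value, int) else _FMT % value
        fh.write(f"##${key.upper()}={text}\n")
    for k in sorted(trace.provenance):
        fh.write(f"##$PROV_{k}={trace.provenance[k]}\n")
    fh.write("##XYDATA=(X++(Y..Y))\n")
    for x, y in zip(trace.field, trace.intensity):
        fh.write(f"{_FMT % x} {_FMT % y}\n")
    fh.write("##END=\n")


def _read_jcampdx(lines: list[str], path: str) -> SpectrumTrace:
    meta: dict[str, str] = {}
    prov: dict[str, str] = {}
    data_x: list[float] = []
    data_y: list[float] = []
    in_data = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            if line.startswith("##END"):
                break
            key, _, value = line[2:].partition("=")
            key, value = key.strip(), value.strip()
            if key.startswith("$PROV_"):
                prov[key[6:]] = value
            elif key.startswith("$"):
                meta[key[1:].lower()] = value
            elif key.upper() == "XYDATA":
                in_data = True
            else:
                meta[key.upper()] = value
            continue
        if in_data:
            parts = line.split()
            try:
                x = float(parts[0])
                ys = [float(p) for p in parts[1:]]
                if not ys:
                    raise ValueError("x without y")
            except (ValueError, IndexError) as exc:
                raise ParseError(
                    f"malformed XYDATA row in {path}: {line!r}", lineno
                ) from exc
            data_x.append(x)
            data_y.extend(ys)
        else:
            raise ParseError(f"unexpected content outside records in {path}: "
                             f"{line!r}", lineno)
    if not data_y:
        raise ParseError(f"no XYDATA found in {path}")
    # ##$ keys are case-insensitive; map them back to the canonical names
    canonical = {key.lower(): key for _, key, _ in _SETTINGS_KEYS}
    smeta = {
        canonical[k.lower()]: v for k, v in meta.items() if k.lower() in canonical
    }
    settings, defaulted = _settings_from_metadata(smeta, len(data_y))
    if len(data_x) == len(data_y):
        field = np.array(data_x)
    else:
        first = float(meta.get("FIRSTX", settings.field_axis[0]))
        last = float(meta.get("LASTX", settings.field_axis[-1]))
        field = np.linspace(first, last, len(data_y))
        prov["field_axis"] = "reconstructed from FIRSTX/LASTX"
    if defaulted:
        prov["defaulted_metadata"] = ",".join(defaulted)
    return SpectrumTrace(field, np.array(data_y), settings, prov)


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def write_spectrum(trace: SpectrumTrace, path: str | os.PathLike,
                   dialect: str = "csv") -> None:
    """Write a trace to ``path`` in the given dialect (``csv``/``jcampdx``).

    Byte output is deterministic for a fixed trace and dialect.
    NaN/Inf intensities are rejected.
    """
    _finite_or_raise(trace.field, "field axis")
    _finite_or_raise(trace.intensity, "intensity")
    if dialect not in ("csv", "jcampdx"):
        raise ValidationError(f"unknown dialect: {dialect!r}")
    with open(path, "w", newline="\n") as fh:
        if dialect == "csv":
            _write_csv(trace, fh)
        else:
            _write_jcampdx(trace, fh)


def read_spectrum(path: str | os.PathLike) -> SpectrumTrace:
    """Read a spectrum file (JCAMP-DX subset or commented CSV).

    The dialect is sniffed from the first record. Missing non-essential
    metadata is filled with package defaults and flagged in provenance;
    a missing field axis is reconstructed from the stated sweep window.
    """
    with open(path) as fh:
        lines = fh.readlines()
    if not lines:
        raise ParseError(f"empty file: {path}")
    text_path = os.fspath(path)
    if lines[0].lstrip().startswith("##"):
        return _read_jcampdx(lines, text_path)
    return _read_csv(lines, text_path)


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

def write_cohort_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a cohort truth/result table as plain CSV (stable column order)."""
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"cohort table missing columns: {missing}")
    extra = [c for c in table.columns if c not in COHORT_COLUMNS]
    table[COHORT_COLUMNS + extra].to_csv(path, index=False, lineterminator="\n")


def read_cohort_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a cohort CSV, validating the documented column set."""
    table = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ParseError(f"cohort table {os.fspath(path)} missing columns: {missing}")
    return table
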