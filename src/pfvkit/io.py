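"""Voltammogram file I/O.

Dialect: UTF-8 text, ``# key: value`` header lines, then a column header row
``potential_V,current_A`` followed by comma-separated point-decimal numbers.
Mandatory header keys: ``scan_rate_V_per_s`` and ``temperature_K`` (or
``temperature_C``).  Unknown header keys are preserved verbatim so that
simulation ground truth round-trips through files.
"""
from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Union

import numpy as np

from .constants import CELSIUS_OFFSET
from .errors import FormatError
from .types import Voltammogram

__all__ = ["read_voltammogram", "write_voltammogram"]


def _parse_float(text: str, where: str) -> float:
    if ";" in text or ("," in text):
        raise FormatError(
            f"{where}: {text!r} — only point-decimal numbers and comma column "
            "separators are accepted (comma decimals / semicolons are not)")
    try:
        return float(text)
    except ValueError as exc:
        raise FormatError(f"{where}: cannot parse {text!r} as a number") from exc


def read_voltammogram(path: Union[str, Path]) -> Voltammogram:
    """Read a voltammogram file in the package dialect.

    Raises :class:`~pfvkit.errors.FormatError` naming the offending key or
    line when the file does not conform.
    """
    path = Path(path)
    meta: dict = {}
    potentials, currents = [], []
    with open(path, "r", encoding="utf-8") as fh:
        header_seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" not in body:
                    raise FormatError(f"{path}:{lineno}: malformed header line {line!r}")
                key, value = body.split(":", 1)
                meta[key.strip()] = value.strip()
                continue
            if not header_seen:
                cols = [c.strip() for c in line.split(",")]
                if cols != ["potential_V", "current_A"]:
                    raise FormatError(
                        f"{path}:{lineno}: expected column header "
                        f"'potential_V,current_A', got {line!r}")
                header_seen = True
                continue
            fields = line.split(",")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 comma-separated columns, got "
                    f"{len(fields)} — check for comma decimals (point decimal required)")
            potentials.append(_parse_float(fields[0].strip(), f"{path}:{lineno}"))
            currents.append(_parse_float(fields[1].strip(), f"{path}:{lineno}"))

    if "scan_rate_V_per_s" not in meta:
        raise FormatError(f"{path}: missing mandatory header key 'scan_rate_V_per_s'")
    if "temperature_K" not in meta and "temperature_C" not in meta:
        raise FormatError(f"{path}: missing mandatory header key 'temperature_K'")
    scan_rate = _parse_float(meta["scan_rate_V_per_s"], "scan_rate_V_per_s")
    if "temperature_K" in meta:
        temperature = _parse_float(meta["temperature_K"], "temperature_K")
    else:
        temperature = _parse_float(meta["temperature_C"], "temperature_C") + CELSIUS_OFFSET

    area = meta.get("electrode_area_cm2")
    area = _parse_float(area, "electrode_area_cm2") if area is not None else None
    n_electrons = int(meta.get("n_electrons", 1))

    extra = {}
    for key, value in meta.items():
        if key in {"scan_rate_V_per_s", "temperature_K", "temperature_C",
                   "electrode_area_cm2", "n_electrons"}:
            continue
        if key == "segment_split_index":
            extra[key] = int(value)
        else:
            try:
                extra[key] = float(value)
            except ValueError:
                extra[key] = value

    return Voltammogram(potential=np.array(potentials), current=np.array(currents),
                        scan_rate=scan_rate, temperature=temperature,
                        electrode_area=area, n_electrons=n_electrons,
                        metadata=extra)


def write_voltammogram(vg: Voltammogram, path: Union[str, Path]) -> None:
    """Write a voltammogram in the package dialect (12 significant digits)."""
    buf = _io.StringIO()
    buf.write(f"# scan_rate_V_per_s: {vg.scan_rate:.12g}\n")
    buf.write(f"# temperature_K: {vg.temperature:.12g}\n")
    if vg.electrode_area is not None:
        buf.write(f"# electrode_area_cm2: {vg.electrode_area:.12g}\n")
    buf.write(f"# n_electrons: {vg.n_electrons}\n")
    for key, value in vg.metadata.items():
        if isinstance(value, float):
            buf.write(f"# {key}: {value:.12g}\n")
        else:
            buf.write(f"# {key}: {value}\n")
    buf.write("potential_V,current_A\n")
    for e, i in zip(vg.potential, vg.current):
        buf.write(f"{e:.12g},{i:.12g}\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")
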