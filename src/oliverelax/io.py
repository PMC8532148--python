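"""File formats, spectral-region catalog and region integration.

Decay curves and dispersion profiles travel as plain-text files: a CSV
dialect with ``# key: value`` metadata lines before the column header,
a whitespace-delimited legacy twin, and a JSON mirror of the same
schema.  Frequencies are stored in MHz and delays in seconds.
Proprietary instrument formats are deliberately not parsed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .decay import DecayCurve
from .dispersion import DispersionProfile

__all__ = [
    "SpectralRegion",
    "REGION_CATALOG",
    "MOST_INTENSE_REGION_100MHZ",
    "ParseError",
    "read_decay",
    "write_decay",
    "read_dispersion",
    "write_dispersion",
    "integrate_region",
]


class ParseError(ValueError):
    """File parse failure carrying the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


@dataclass(frozen=True)
class SpectralRegion:
    """A chemical-shift window with its proton-group assignment.

    ``proton_class`` coarsely classifies the protons (CH, CH2 or CH3);
    the CH and CH2 classes are the ones averaged into high-field NMRD
    supplement points.
    """

    ppm_lo: float
    ppm_hi: float
    assignment: str
    attribution: str
    proton_class: str

    def __post_init__(self) -> None:
        if not self.ppm_lo < self.ppm_hi:
            raise ValueError("ppm_lo must be < ppm_hi")

    @property
    def center(self) -> float:
        return 0.5 * (self.ppm_lo + self.ppm_hi)


#: The ten proton signals of an olive-oil spectrum at 400 MHz, ordered
#: by descending chemical shift.  Single-shift signals are given
#: non-overlapping integration windows around their nominal position.
REGION_CATALOG: tuple[SpectralRegion, ...] = (
    SpectralRegion(5.2, 5.5, "-CH=CH-", "all unsaturated fatty acids", "CH"),
    SpectralRegion(5.0, 5.2, "CH-OCOR", "triacylglycerols", "CH"),
    SpectralRegion(4.0, 4.3, "CH2-OCOR", "triacylglycerols", "CH2"),
    SpectralRegion(2.6, 2.8, "CH=CH-CH2-CH=CH", "linoleic and linolenic chains", "CH2"),
    SpectralRegion(2.2, 2.4, "CH2-COOH", "all acyl chains", "CH2"),
    SpectralRegion(1.9, 2.1, "CH2-CH=CH", "all unsaturated fatty acids", "CH2"),
    SpectralRegion(1.5, 1.7, "CH2-CH2-COOH", "all acyl chains", "CH2"),
    SpectralRegion(0.96, 1.45, "-(CH2)n-", "all acyl chains", "CH2"),
    SpectralRegion(0.86, 0.96, "CH=CH-CH2-CH3", "linolenic acid", "CH3"),
    SpectralRegion(0.74, 0.86, "CH2-CH2-CH2-CH3", "all acyl chains except linolenyl", "CH3"),
)

#: Broad window integrated for single-field screening at 100 MHz (the
#: most intense, partially overlapped aliphatic signal).
MOST_INTENSE_REGION_100MHZ = SpectralRegion(
    0.0, 2.5, "aliphatic envelope", "acyl chains (CH2/CH3 superposition)", "CH2"
)


# ---------------------------------------------------------------------------
# decay-curve files

_SEQ_ALIASES = {
    "inversion_recovery": "inversion_recovery",
    "ir": "inversion_recovery",
    "cpmg": "cpmg",
    "spin_echo": "spin_echo",
    "se": "spin_echo",
}


def _fmt(x: float) -> str:
    return repr(float(x))


def write_decay(curve: DecayCurve, path: str | Path, dialect: str = "csv") -> None:
    """Write a decay curve; dialects: csv, whitespace, json."""
    path = Path(path)
    if dialect == "json":
        doc = {
            "format": "oliverelax-decay",
            "sample_id": curve.sample_id,
            "sequence": curve.sequence_kind,
            "larmor_mhz": curve.larmor_mhz,
            "temperature_c": curve.temperature_c,
            "delay_s": curve.delays.tolist(),
            "signal": curve.magnetization.tolist(),
        }
        if curve.sigma is not None:
            doc["sigma"] = curve.sigma.tolist()
        path.write_text(json.dumps(doc, indent=1))
        return
    if dialect not in ("csv", "whitespace"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = "," if dialect == "csv" else "\t"
    cols = ["delay_s", "signal"] + (["sigma"] if curve.sigma is not None else [])
    lines = [
        "# oliverelax decay v1",
        f"# sample_id: {curve.sample_id}",
        f"# sequence: {curve.sequence_kind}",
        f"# larmor_mhz: {_fmt(curve.larmor_mhz)}",
    ]
    if curve.temperature_c is not None:
        lines.append(f"# temperature_c: {_fmt(curve.temperature_c)}")
    lines.append(sep.join(cols))
    for i in range(len(curve)):
        row = [_fmt(curve.delays[i]), _fmt(curve.magnetization[i])]
        if curve.sigma is not None:
            row.append(_fmt(curve.sigma[i]))
        lines.append(sep.join(row))
    path.write_text("\n".join(lines) + "\n")


def _read_tabular(path: Path, sep: str | None):
    """Parse metadata header + numeric table, tracking line numbers."""
    meta: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[list[float]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
            continue
        fields = [f.strip() for f in (line.split(sep) if sep else line.split())]
        if header is None:
            header = fields
            continue
        try:
            rows.append([float(f) for f in fields])
        except ValueError as exc:
            raise ParseError(f"non-numeric value: {exc}", lineno) from None
        if len(fields) != len(header):
            raise ParseError(
                f"expected {len(header)} columns, got {len(fields)}", lineno
            )
    if header is None or not rows:
        raise ParseError("no data table found in file")
    return meta, header, np.asarray(rows, dtype=float)


def read_decay(path: str | Path, dialect: str = "auto") -> DecayCurve:
    """Read a decay curve written by :func:`write_decay`.

    ``dialect="auto"`` infers json from the suffix and falls back to
    delimited text (comma or whitespace detected per file).
    """
    path = Path(path)
    if dialect == "auto":
        dialect = "json" if path.suffix.lower() == ".json" else "text"
    if dialect == "json":
        doc = json.loads(path.read_text())
        for key in ("sequence", "larmor_mhz", "delay_s", "signal"):
            if key not in doc:
                raise ParseError(f"missing key {key!r} in JSON document")
        return _build_curve(
            {
                "sample_id": doc.get("sample_id", ""),
                "sequence": str(doc["sequence"]),
                "larmor_mhz": str(doc["larmor_mhz"]),
                "temperature_c": (
                    str(doc["temperature_c"])
                    if doc.get("temperature_c") is not None
                    else None
                ),
            },
            ["delay_s", "signal"] + (["sigma"] if "sigma" in doc else []),
            np.column_stack(
                [doc["delay_s"], doc["signal"]]
                + ([doc["sigma"]] if "sigma" in doc else [])
            ),
        )
    sep = "," if dialect == "csv" else None if dialect == "whitespace" else None
    if dialect == "text":
        head = path.read_text()
        sep = "," if "," in head.split("\n", 6)[-1] or "," in head else None
    meta, header, data = _read_tabular(path, sep)
    return _build_curve(meta, header, data)


def _build_curve(meta, header, data) -> DecayCurve:
    for col in ("delay_s", "signal"):
        if col not in header:
            raise ParseError(f"missing column {col!r}")
    seq_raw = meta.get("sequence", "").lower()
    if seq_raw not in _SEQ_ALIASES:
        raise ParseError(f"unknown sequence kind {meta.get('sequence')!r}")
    if "larmor_mhz" not in meta:
        raise ParseError("missing metadata key 'larmor_mhz'")
    delays = data[:, header.index("delay_s")]
    signal = data[:, header.index("signal")]
    if np.any(np.diff(delays) <= 0):
        raise ParseError("delays must be strictly increasing")
    sigma = data[:, header.index("sigma")] if "sigma" in header else None
    t = meta.get("temperature_c")
    return DecayCurve(
        delays=delays,
        magnetization=signal,
        sigma=sigma,
        sequence_kind=_SEQ_ALIASES[seq_raw],
        larmor_mhz=float(meta["larmor_mhz"]),
        sample_id=meta.get("sample_id", ""),
        temperature_c=float(t) if t not in (None, "") else None,
    )


# ---------------------------------------------------------------------------
# dispersion-profile files

def write_dispersion(
    profile: DispersionProfile, path: str | Path, dialect: str = "csv"
) -> None:
    path = Path(path)
    if dialect == "json":
        doc = {
            "format": "oliverelax-dispersion",
            "sample_id": profile.sample_id,
            "component": profile.component_label,
            "freq_mhz": profile.freqs_mhz.tolist(),
            "r1_per_s": profile.r1.tolist(),
        }
        if profile.r1_err is not None:
            doc["r1_err_per_s"] = profile.r1_err.tolist()
        path.write_text(json.dumps(doc, indent=1))
        return
    sep = "," if dialect == "csv" else "\t"
    cols = ["freq_mhz", "r1_per_s"] + (
        ["r1_err_per_s"] if profile.r1_err is not None else []
    )
    lines = [
        "# oliverelax dispersion v1",
        f"# sample_id: {profile.sample_id}",
        f"# component: {profile.component_label}",
        sep.join(cols),
    ]
    for i in range(len(profile)):
        row = [_fmt(profile.freqs_mhz[i]), _fmt(profile.r1[i])]
        if profile.r1_err is not None:
            row.append(_fmt(profile.r1_err[i]))
        lines.append(sep.join(row))
    path.write_text("\n".join(lines) + "\n")


def read_dispersion(path: str | Path) -> DispersionProfile:
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = json.loads(path.read_text())
        for key in ("freq_mhz", "r1_per_s"):
            if key not in doc:
                raise ParseError(f"missing key {key!r} in JSON document")
        return DispersionProfile(
            freqs_mhz=np.asarray(doc["freq_mhz"], dtype=float),
            r1=np.asarray(doc["r1_per_s"], dtype=float),
            r1_err=(
                np.asarray(doc["r1_err_per_s"], dtype=float)
                if "r1_err_per_s" in doc
                else None
            ),
            component_label=doc.get("component", "a"),
            sample_id=doc.get("sample_id", ""),
        )
    head = path.read_text()
    sep = "," if "," in head else None
    meta, header, data = _read_tabular(path, sep)
    for col in ("freq_mhz", "r1_per_s"):
        if col not in header:
            raise ParseError(f"missing column {col!r}")
    return DispersionProfile(
        freqs_mhz=data[:, header.index("freq_mhz")],
        r1=data[:, header.index("r1_per_s")],
        r1_err=(
            data[:, header.index("r1_err_per_s")]
            if "r1_err_per_s" in header
            else None
        ),
        component_label=meta.get("component", "a"),
        sample_id=meta.get("sample_id", ""),
    )


# ---------------------------------------------------------------------------
# spectra

def integrate_region(spectrum: pd.DataFrame, region: SpectralRegion) -> float:
    """Trapezoidal integral of a spectrum over one chemical-shift window.

    ``spectrum`` must have increasing ``ppm`` and ``intensity`` columns
    covering the region; the intensity is linearly interpolated at the
    window boundaries.
    """
    ppm = np.asarray(spectrum["ppm"], dtype=float)
    intensity = np.asarray(spectrum["intensity"], dtype=float)
    if np.any(np.diff(ppm) <= 0):
        raise ValueError("spectrum ppm axis must be strictly increasing")
    if region.ppm_lo < ppm[0] or region.ppm_hi > ppm[-1]:
        raise ValueError(
            f"region [{region.ppm_lo}, {region.ppm_hi}] ppm outside spectrum "
            f"span [{ppm[0]}, {ppm[-1]}]"
        )
    inside = (ppm > region.ppm_lo) & (ppm < region.ppm_hi)
    xs = np.concatenate(([region.ppm_lo], ppm[inside], [region.ppm_hi]))
    ys = np.concatenate(
        (
            [np.interp(region.ppm_lo, ppm, intensity)],
            intensity[inside],
            [np.interp(region.ppm_hi, ppm, intensity)],
        )
    )
    if math.isnan(ys[0]) or math.isnan(ys[-1]):
        raise ValueError("spectrum does not cover the region boundaries")
    return float(np.trapezoid(ys, xs))
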