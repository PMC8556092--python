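"""Depth-ionization curve I/O, peak finding and effective-point extraction.

The measurement this module supports: a plane-parallel reference chamber and
a cylindrical test chamber each record a Bragg curve (reading vs. depth in a
water phantom).  Each curve's raw peak position is converted to a
water-equivalent depth by adding the item-by-item WET chain of everything
upstream of the chamber's point of measurement (tank wall, clearances,
windows).  The difference between the two corrected peak depths is the
effective-point shift of the cylindrical chamber; divided by its cavity
radius ``r`` it gives the shift ratio reported per (energy, field size).

Conventions: depth 0 at the phantom entrance-window inner surface, depths in
mm increasing downstream; a positive shift ratio means the effective point
lies upstream of the chamber centre (serialized with a leading minus sign).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .chambers import ChamberSpec

__all__ = [
    "DepthIonizationCurve",
    "BeamSetup",
    "CurveParseError",
    "read_curve",
    "write_curve",
    "normalize_to_peak",
    "find_peak_depth",
    "corrected_peak_depth",
    "peff_shift",
    "shift_table",
    "resample_monotone",
]


class CurveParseError(ValueError):
    """Raised when a depth-ionization file fails validation."""


@dataclass(frozen=True)
class DepthIonizationCurve:
    """Ordered (depth, reading) samples with acquisition metadata.

    Depths are strictly increasing, readings non-negative; at least five
    samples are required for any peak analysis to be meaningful.
    """

    depth_mm: np.ndarray
    reading: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = np.asarray(self.depth_mm, float)
        v = np.asarray(self.reading, float)
        object.__setattr__(self, "depth_mm", d)
        object.__setattr__(self, "reading", v)
        if d.ndim != 1 or v.shape != d.shape:
            raise CurveParseError("depth and reading must be 1-D and equal length")
        if d.size < 5:
            raise CurveParseError(f"need >= 5 samples, got {d.size}")
        if not np.all(np.diff(d) > 0):
            bad = int(np.flatnonzero(np.diff(d) <= 0)[0]) + 2
            raise CurveParseError(f"depths not strictly increasing at row {bad}")
        if np.any(v < 0):
            bad = int(np.flatnonzero(v < 0)[0]) + 1
            raise CurveParseError(f"negative reading at row {bad}")

    def __len__(self) -> int:
        return int(self.depth_mm.size)


@dataclass(frozen=True)
class BeamSetup:
    """Item-by-item WET chain from the nozzle to a chamber's measuring point.

    ``chain`` entries are ``(label, physical_mm, wet_mm)``;
    ``raw_position_offset_mm`` is the stage coordinate of the point of
    measurement at zero nominal depth.
    """

    chain: tuple[tuple[str, float, float], ...] = ()
    raw_position_offset_mm: float = 0.0
    chamber: ChamberSpec | None = None

    def __post_init__(self) -> None:
        for label, phys, wet in self.chain:
            if wet < 0:
                raise ValueError(f"chain entry {label!r} has negative WET {wet}")

    @property
    def chain_wet_mm(self) -> float:
        return float(sum(wet for _, _, wet in self.chain))

    @classmethod
    def from_yaml(cls, path, chamber: ChamberSpec | None = None) -> "BeamSetup":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        chain = tuple(
            (e["label"], float(e.get("physical_mm", 0.0)), float(e["wet_mm"]))
            for e in raw.get("chain", [])
        )
        return cls(
            chain=chain,
            raw_position_offset_mm=float(raw.get("raw_position_offset_mm", 0.0)),
            chamber=chamber,
        )


# ---------------------------------------------------------------------------
# I/O


def read_curve(path_or_buffer, dialect: str | None = None) -> DepthIonizationCurve:
    """Read a two-column delimited curve file.

    Accepts comma-, tab- or whitespace-separated columns ``depth_mm,reading``
    with an optional header row and ``# key=value`` metadata lines.
    Validation failures name the offending row.
    """
    if hasattr(path_or_buffer, "read"):
        lines = path_or_buffer.read().splitlines()
        source = "<buffer>"
    else:
        with open(path_or_buffer, encoding="utf-8") as fh:
            lines = fh.read().splitlines()
        source = str(path_or_buffer)

    metadata: dict = {}
    depths: list[float] = []
    readings: list[float] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                metadata[key.strip()] = _coerce(val.strip())
            continue
        sep = dialect or ("," if "," in line else "\t" if "\t" in line else None)
        parts = [p for p in line.replace(sep or " ", " ").split() if p] if sep != "," \
            else [p.strip() for p in line.split(",")]
        if len(parts) != 2:
            raise CurveParseError(f"{source}:{lineno}: expected 2 columns, got {len(parts)}")
        try:
            d, v = float(parts[0]), float(parts[1])
        except ValueError:
            if depths or lineno > 1:
                if depths:
                    raise CurveParseError(f"{source}:{lineno}: non-numeric row {parts}") from None
            continue  # header row
        if depths and d == depths[-1]:
            raise CurveParseError(f"{source}:{lineno}: repeated depth {d} mm")
        depths.append(d)
        readings.append(v)

    order = np.argsort(depths, kind="stable")
    d_arr = np.asarray(depths, float)[order]
    v_arr = np.asarray(readings, float)[order]
    if d_arr.size and np.any(np.diff(d_arr) == 0):
        dup = d_arr[np.flatnonzero(np.diff(d_arr) == 0)[0]]
        raise CurveParseError(f"{source}: repeated depth {dup} mm")
    if d_arr.size < 5:
        raise CurveParseError(f"{source}: need >= 5 data rows, got {d_arr.size}")
    if np.any(v_arr < 0):
        row = int(np.flatnonzero(v_arr < 0)[0]) + 1
        raise CurveParseError(f"{source}: negative reading (data row {row})")
    return DepthIonizationCurve(d_arr, v_arr, metadata)


def _coerce(val: str):
    for cast in (int, float):
        try:
            return cast(val)
        except ValueError:
            pass
    return val


def write_curve(curve: DepthIonizationCurve, path_or_buffer, sep: str = ",") -> None:
    """Write a curve in the dialect :func:`read_curve` accepts (round-trips)."""
    buf = io.StringIO()
    for key, val in curve.metadata.items():
        buf.write(f"# {key}={val}\n")
    buf.write(f"depth_mm{sep}reading\n")
    for d, v in zip(curve.depth_mm, curve.reading):
        buf.write(f"{float(d)!r}{sep}{float(v)!r}\n")
    text = buf.getvalue()
    if hasattr(path_or_buffer, "write"):
        path_or_buffer.write(text)
    else:
        with open(path_or_buffer, "w", encoding="utf-8") as fh:
            fh.write(text)


# ---------------------------------------------------------------------------
# analysis


def normalize_to_peak(curve: DepthIonizationCurve) -> DepthIonizationCurve:
    """Scale readings so the maximum sample equals 1.0 (idempotent)."""
    peak = float(curve.reading.max(initial=0.0))
    if peak <= 0:
        raise ValueError("cannot normalize a curve with no positive reading")
    meta = dict(curve.metadata)
    meta["normalized"] = True
    return DepthIonizationCurve(curve.depth_mm, curve.reading / peak, meta)


def find_peak_depth(curve: DepthIonizationCurve, window_mm: float = 2.0) -> float:
    """Bragg-peak depth: vertex of a parabola fitted around the maximum.

    The maximum sample (ties broken toward smaller depth) anchors a
    least-squares quadratic fit over samples within ``window_mm`` of it; the
    vertex abscissa is returned.  Exact for any symmetric peak sampled
    symmetrically about its centre.  A maximum at either end of the sampled
    range raises (extend the scan range).
    """
    d, v = curve.depth_mm, curve.reading
    imax = int(np.argmax(v))  # argmax returns the first (smallest-depth) tie
    if imax in (0, len(d) - 1):
        raise ValueError(
            "peak at the boundary of the sampled range; extend the depth scan"
        )
    mask = np.abs(d - d[imax]) <= window_mm
    if mask.sum() < 3:
        mask = np.zeros_like(mask)
        mask[imax - 1 : imax + 2] = True
    x, y = d[mask] - d[imax], v[mask]
    a, b, _ = np.polyfit(x, y, 2)
    if a >= 0:  # degenerate (flat/noisy window): fall back to the sample
        return float(d[imax])
    vertex = -b / (2.0 * a)
    # keep the vertex inside the fit window; outside means the window caught
    # an asymmetric shoulder
    vertex = float(np.clip(vertex, x.min(), x.max()))
    return float(d[imax] + vertex)


def corrected_peak_depth(
    curve: DepthIonizationCurve,
    setup: BeamSetup,
    window_mm: float = 2.0,
) -> float:
    """Water-equivalent peak depth: raw peak + the setup's WET chain."""
    return find_peak_depth(curve, window_mm) + setup.chain_wet_mm


def peff_shift(reference_depth: float, test_depth: float, r: float) -> tuple[float, float]:
    """Effective-point shift between corrected peak depths.

    Returns ``(shift_mm, ratio)`` with ``shift = test - reference`` and
    ``ratio = shift / r``.  A positive ratio means the cylindrical chamber's
    effective point lies upstream of its centre (reported with a leading
    minus sign in serialized tables).
    """
    if r <= 0:
        raise ValueError("cavity radius must be > 0")
    shift = test_depth - reference_depth
    return shift, shift / r


@dataclass(frozen=True)
class CurvePair:
    """One replicate measurement: reference + test curve for a condition."""

    energy_mev_u: float
    field_cm: float
    reference: DepthIonizationCurve
    test: DepthIonizationCurve
    reference_setup: BeamSetup = BeamSetup()
    test_setup: BeamSetup = BeamSetup()


def shift_table(
    curve_pairs: Iterable[CurvePair],
    chamber: ChamberSpec,
    window_mm: float = 2.0,
) -> pd.DataFrame:
    """Shift-ratio summary per (energy, field size) cell.

    For each pair the corrected peak depths are extracted and the shift
    ratio computed with the chamber's inner radius; replicates within a cell
    are summarized as mean +/- sample standard deviation (NaN for a single
    replicate).
    """
    if chamber.inner_radius_mm is None:
        raise ValueError("shift_table needs a cylindrical chamber with inner_radius_mm")
    r = chamber.inner_radius_mm
    rows = []
    for pair in curve_pairs:
        ref_depth = corrected_peak_depth(pair.reference, pair.reference_setup, window_mm)
        test_depth = corrected_peak_depth(pair.test, pair.test_setup, window_mm)
        shift, ratio = peff_shift(ref_depth, test_depth, r)
        rows.append(
            {
                "energy_mev_u": pair.energy_mev_u,
                "field_cm": pair.field_cm,
                "shift_mm": shift,
                "ratio": ratio,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["energy_mev_u", "field_cm", "n", "ratio_mean", "ratio_sd"]
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["energy_mev_u", "field_cm"], as_index=False)
        .agg(n=("ratio", "size"), ratio_mean=("ratio", "mean"), ratio_sd=("ratio", "std"))
        .sort_values(["field_cm", "energy_mev_u"], ignore_index=True)
    )
    return out


def resample_monotone(
    curve: DepthIonizationCurve, new_depths: Sequence[float]
) -> DepthIonizationCurve:
    """Resample with monotone piecewise-cubic (PCHIP) interpolation.

    Intended for overlay plotting only; peak finding always runs on the raw
    samples.
    """
    from scipy.interpolate import PchipInterpolator

    nd = np.asarray(new_depths, float)
    interp = PchipInterpolator(curve.depth_mm, curve.reading)
    meta = dict(curve.metadata)
    meta["resampled"] = True
    return DepthIonizationCurve(nd, np.clip(interp(nd), 0.0, None), meta)
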