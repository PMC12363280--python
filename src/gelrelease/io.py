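"""CSV readers and writers for release-kinetics data.

All files are plain UTF-8 CSV with a mandatory header row, ``.`` as the
decimal separator, times in hours and masses in µg.  Scalar metadata
(e.g. the initial loading) travels in ``# key: value`` comment lines
before the header.  Two release-data schemas are supported:

* curve mode: ``time_h, cumulative_percent`` (or ``cumulative_mass_ug``),
  metadata ``m_initial_ug``;
* supernatant mode: ``time_h, replicate_id, mass_ug``, metadata
  ``m_initial_ug``.

Malformed rows are reported with their 1-based file line numbers.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import ReleaseCurve, SupernatantSeries
from .exceptions import ParseError
from .perfusion import CalibrationRecord, FractionSeries

__all__ = [
    "read_release_csv",
    "write_release_csv",
    "write_supernatants_csv",
    "read_calibration_csv",
    "write_calibration_csv",
    "read_fractions_csv",
    "write_fractions_csv",
    "write_profiles_csv",
]


def _read_with_metadata(path):
    """Split leading '# key: value' lines from the CSV body."""
    path = Path(path)
    meta = {}
    lines = path.read_text(encoding="utf-8").splitlines()
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        body_start += 1
        stripped = line.lstrip("#").strip()
        if ":" in stripped:
            key, _, value = stripped.partition(":")
            meta[key.strip()] = value.strip()
    body = "\n".join(lines[body_start:])
    if not body.strip():
        raise ParseError(f"{path}: no data rows")
    try:
        df = pd.read_csv(_io.StringIO(body), float_precision="round_trip")
    except Exception as exc:
        raise ParseError(f"{path}: not parseable as CSV: {exc}") from exc
    # 1-based file line of each dataframe row (metadata + header + 1)
    df.index = np.arange(body_start + 2, body_start + 2 + len(df))
    return df, meta


def _require_numeric(df, columns, path):
    bad_lines = []
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad_lines.extend(df.index[coerced.isna() & df[col].notna()].tolist())
        bad_lines.extend(df.index[df[col].isna()].tolist())
        df[col] = coerced
    if bad_lines:
        raise ParseError(
            f"{path}: non-numeric or missing values in lines {sorted(set(bad_lines))}"
        )


def read_release_csv(path) -> "ReleaseCurve | list[SupernatantSeries]":
    """Read a release CSV; the header decides the schema.

    Returns a :class:`ReleaseCurve` (curve mode) or a list of
    :class:`SupernatantSeries`, one per replicate (supernatant mode).
    """
    df, meta = _read_with_metadata(path)
    cols = set(df.columns)
    m_initial = float(meta.get("m_initial_ug", "nan"))

    if {"time_h", "replicate_id", "mass_ug"} <= cols:
        _require_numeric(df, ["time_h", "mass_ug"], path)
        if np.isnan(m_initial):
            raise ParseError(f"{path}: supernatant mode needs '# m_initial_ug:' metadata")
        neg = df.index[df["mass_ug"] < 0].tolist()
        if neg:
            raise ParseError(f"{path}: negative mass in lines {neg}")
        series = []
        for _, group in df.groupby("replicate_id", sort=True):
            t = group["time_h"].to_numpy(float)
            if np.any(np.diff(t) <= 0):
                bad = group.index[1:][np.diff(t) <= 0].tolist()
                raise ParseError(f"{path}: non-monotone times at lines {bad}")
            series.append(
                SupernatantSeries(
                    times=t, masses=group["mass_ug"].to_numpy(float), m_initial=m_initial
                )
            )
        return series

    if "time_h" in cols and ({"cumulative_percent"} & cols or {"cumulative_mass_ug"} & cols):
        value_col = "cumulative_mass_ug" if "cumulative_mass_ug" in cols else "cumulative_percent"
        _require_numeric(df, ["time_h", value_col], path)
        neg = df.index[df[value_col] < 0].tolist()
        if neg:
            raise ParseError(f"{path}: negative release in lines {neg}")
        t = df["time_h"].to_numpy(float)
        if np.any(np.diff(t) < 0):
            bad = df.index[1:][np.diff(t) < 0].tolist()
            raise ParseError(f"{path}: non-monotone times at lines {bad}")
        if value_col == "cumulative_mass_ug":
            if np.isnan(m_initial):
                raise ParseError(f"{path}: mass-valued curve needs '# m_initial_ug:' metadata")
            mass = df[value_col].to_numpy(float)
        else:
            if np.isnan(m_initial):
                m_initial = 1.0  # percent-only: absolute scale arbitrary
            mass = df[value_col].to_numpy(float) / 100.0 * m_initial
        return ReleaseCurve(times=t, cumulative_mass=mass, m_infinity=m_initial)

    raise ParseError(
        f"{path}: header {sorted(cols)} matches neither the curve schema "
        "(time_h, cumulative_percent|cumulative_mass_ug) nor the supernatant schema "
        "(time_h, replicate_id, mass_ug)"
    )


def write_release_csv(curve: ReleaseCurve, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# m_initial_ug: {curve.m_infinity!r}\n")
        pd.DataFrame(
            {
                "time_h": curve.times,
                "cumulative_mass_ug": curve.cumulative_mass,
                "cumulative_percent": curve.cumulative_percent,
            }
        ).to_csv(fh, index=False, float_format="%.17g")


def write_supernatants_csv(series_list, path) -> None:
    series_list = list(series_list)
    path = Path(path)
    frames = [
        pd.DataFrame({"time_h": s.times, "replicate_id": i, "mass_ug": s.masses})
        for i, s in enumerate(series_list)
    ]
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# m_initial_ug: {series_list[0].m_initial!r}\n")
        pd.concat(frames)[["time_h", "replicate_id", "mass_ug"]].to_csv(
            fh, index=False, float_format="%.17g"
        )


def read_calibration_csv(path) -> list:
    """Read pump-calibration records: rpm, mass_g, temperature_c, minutes."""
    df, _ = _read_with_metadata(path)
    required = ["rpm", "mass_g", "temperature_c", "minutes"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    _require_numeric(df, required, path)
    return [
        CalibrationRecord(
            rpm=row.rpm, mass_g=row.mass_g, temperature_c=row.temperature_c, minutes=row.minutes
        )
        for row in df.itertuples()
    ]


def write_calibration_csv(records, path) -> None:
    pd.DataFrame(
        [
            {"rpm": r.rpm, "mass_g": r.mass_g, "temperature_c": r.temperature_c,
             "minutes": r.minutes}
            for r in records
        ]
    ).to_csv(path, index=False, float_format="%.17g")


def read_fractions_csv(path) -> FractionSeries:
    """Read a fraction-collector series: bin_index, time_h, mass_ug with
    flow/loading metadata in the header comments."""
    df, meta = _read_with_metadata(path)
    required = ["bin_index", "time_h", "mass_ug"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    _require_numeric(df, required, path)
    for key in ("flow_ul_min", "m_initial_ug"):
        if key not in meta:
            raise ParseError(f"{path}: missing '# {key}:' metadata")
    df = df.sort_values("bin_index")
    return FractionSeries(
        flow_rate=float(meta["flow_ul_min"]),
        fraction_masses=df["mass_ug"].to_numpy(float),
        m_initial=float(meta["m_initial_ug"]),
        interval_h=float(meta.get("interval_h", 2.0)),
        dead_volume_ul=float(meta.get("dead_volume_ul", 0.0)),
    )


def write_fractions_csv(series: FractionSeries, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# flow_ul_min: {series.flow_rate!r}\n")
        fh.write(f"# m_initial_ug: {series.m_initial!r}\n")
        fh.write(f"# interval_h: {series.interval_h!r}\n")
        fh.write(f"# dead_volume_ul: {series.dead_volume_ul!r}\n")
        pd.DataFrame(
            {
                "bin_index": np.arange(series.fraction_masses.size),
                "time_h": series.times,
                "mass_ug": series.fraction_masses,
            }
        ).to_csv(fh, index=False, float_format="%.17g")


def write_profiles_csv(profiles, directory) -> list:
    """One ``z_m, c`` file per observation time; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for p in profiles:
        out = directory / f"profile_t{p.t / 3600.0:09.3f}h.csv"
        pd.DataFrame({"z_m": p.z, "c": p.c}).to_csv(out, index=False, float_format="%.17g")
        paths.append(out)
    return paths
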