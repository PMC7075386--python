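"""Reading and writing dose-rate profiles and run configurations.

Profile CSV format::

    # facility=elder-6mv
    # energy_mv=6
    # f0_cm2=1600
    # d0_cgy_min=600
    # b_xs=0.027
    # d_w_m=4.5
    # h_m=3.6
    d_s_m,rate_nSv_per_s[,sigma_nSv_per_s]
    6.0,4.1
    ...

Metadata travels as ``# key=value`` comment lines so a profile file is
self-contained for calibration.  Values round-trip to 12 significant
digits.  Run configurations are flat-sectioned JSON mirroring the
domain types; unknown keys are rejected.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import DoseProfile, ProfileMetadata
from .dose import CalibrationConstant, DEFAULT_K, RoofShield, Scenario
from .physics import BeamSpec, VaultGeometry

__all__ = [
    "ProfileParseError",
    "ConfigError",
    "read_profile_csv",
    "write_profile_csv",
    "RunConfig",
    "load_config",
]

_COLUMNS = ("d_s_m", "rate_nSv_per_s")
_SIGMA_COLUMN = "sigma_nSv_per_s"
_NUMERIC_META = ("energy_mv", "f0_cm2", "d0_cgy_min", "b_xs", "d_w_m", "h_m")


class ProfileParseError(ValueError):
    """Malformed profile CSV; carries the offending line number when known."""


class ConfigError(ValueError):
    """Malformed run configuration."""


def write_profile_csv(profile: DoseProfile, path: str | Path) -> None:
    """Write a profile, metadata as ``# key=value`` header comments."""
    lines: list[str] = []
    if profile.metadata is not None:
        m = profile.metadata
        lines.append(f"# facility={m.facility}")
        for key in _NUMERIC_META:
            lines.append(f"# {key}={getattr(m, key)!r}")
    cols = {"d_s_m": profile.d_s, "rate_nSv_per_s": profile.values}
    if profile.sigma is not None:
        cols[_SIGMA_COLUMN] = profile.sigma
    buf = io.StringIO()
    pd.DataFrame(cols).to_csv(buf, index=False, float_format="%.12g")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else "") + buf.getvalue())


def read_profile_csv(path: str | Path) -> DoseProfile:
    """Read a profile CSV, enforcing strictly increasing distances.

    Parse failures name the 1-based line number of the offending row.
    """
    path = Path(path)
    text = path.read_text()
    meta_raw: dict[str, str] = {}
    data_lines: list[str] = []
    line_numbers: list[int] = []  # 1-based file line per data row (incl. header)
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta_raw[key.strip()] = val.strip()
            continue
        data_lines.append(line)
        line_numbers.append(lineno)

    if not data_lines:
        raise ProfileParseError(f"{path}: no data rows found")
    header = [c.strip() for c in data_lines[0].split(",")]
    for col in _COLUMNS:
        if col not in header:
            raise ProfileParseError(
                f"{path} line {line_numbers[0]}: missing required column {col!r} "
                f"(header was {header})"
            )

    try:
        df = pd.read_csv(io.StringIO("\n".join(data_lines)))
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ProfileParseError(f"{path}: {exc}") from exc

    for col in _COLUMNS:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ProfileParseError(
                f"{path} line {line_numbers[bad[0] + 1]}: non-numeric value in column {col!r}"
            )

    d = df["d_s_m"].to_numpy(dtype=float)
    drops = np.nonzero(np.diff(d) <= 0)[0]
    if len(drops):
        i = int(drops[0]) + 1  # row index of the offending (non-increasing) point
        raise ProfileParseError(
            f"{path} line {line_numbers[i + 1]}: distances must be strictly increasing "
            f"(d_s={d[i]} after {d[i - 1]})"
        )

    metadata = None
    if "facility" in meta_raw and all(k in meta_raw for k in _NUMERIC_META):
        metadata = ProfileMetadata(
            facility=meta_raw["facility"],
            **{k: float(meta_raw[k]) for k in _NUMERIC_META},
        )

    sigma = df[_SIGMA_COLUMN].to_numpy(dtype=float) if _SIGMA_COLUMN in df.columns else None
    return DoseProfile(
        d_s=d,
        values=df["rate_nSv_per_s"].to_numpy(dtype=float),
        sigma=sigma,
        metadata=metadata,
    )


@dataclass(frozen=True)
class RunConfig:
    """Validated bundle of everything a prediction run needs."""

    geometry: VaultGeometry
    beam: BeamSpec
    roof: RoofShield
    scenario: Scenario | None = None
    k: CalibrationConstant | None = None

    def resolve_k(self) -> CalibrationConstant:
        """Explicit k override, else the fitted default for the beam MV."""
        if self.k is not None:
            return self.k
        mv = int(round(self.beam.nominal_mv))
        if mv not in DEFAULT_K:
            raise ConfigError(
                f"no default calibration constant for {self.beam.nominal_mv} MV; "
                f"defaults exist for {sorted(DEFAULT_K)} — supply 'k' in the config"
            )
        return DEFAULT_K[mv]


def _section(raw: dict, name: str, allowed: dict[str, str], required: set[str]) -> dict:
    """Extract one config section, mapping JSON keys to constructor kwargs."""
    sec = raw.get(name)
    if sec is None:
        if required:
            raise ConfigError(f"config is missing required section {name!r}")
        return {}
    if not isinstance(sec, dict):
        raise ConfigError(f"config section {name!r} must be an object")
    unknown = set(sec) - set(allowed)
    if unknown:
        raise ConfigError(f"unknown keys in config section {name!r}: {sorted(unknown)}")
    missing = required - set(sec)
    if missing:
        raise ConfigError(f"config section {name!r} is missing keys: {sorted(missing)}")
    return {allowed[k]: v for k, v in sec.items()}


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON run configuration.

    Sections: ``geometry`` (d_w, h, optional d_i; meters), ``beam``
    (mv, f0, d0; cm^2, cGy/min), ``roof`` (b_xs), optional ``scenario``
    (w, u, t, w_h, p, wall_type) and optional scalar ``k`` (nSv/s).
    Unknown sections or keys are rejected.
    """
    raw = json.loads(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a JSON object")
    known_sections = {"geometry", "beam", "roof", "scenario", "k"}
    unknown = set(raw) - known_sections
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")

    try:
        geometry = VaultGeometry(
            **_section(raw, "geometry", {"d_w": "d_w", "h": "h", "d_i": "d_i"}, {"d_w", "h"})
        )
        beam = BeamSpec(
            **_section(
                raw,
                "beam",
                {"mv": "nominal_mv", "f0": "field_area_f0", "d0": "dose_rate_d0", "a": "field_side_a"},
                {"mv", "f0", "d0"},
            )
        )
        roof = RoofShield(**_section(raw, "roof", {"b_xs": "b_xs"}, {"b_xs"}))
        scenario = None
        if "scenario" in raw:
            scenario = Scenario(
                **_section(
                    raw,
                    "scenario",
                    {
                        "w": "workload_w",
                        "u": "use_factor_u",
                        "t": "occupancy_t",
                        "w_h": "hourly_workload_wh",
                        "p": "wall_design_goal_p",
                        "wall_type": "wall_type",
                    },
                    {"w", "u", "t"},
                )
            )
        k = None
        if "k" in raw:
            if not isinstance(raw["k"], (int, float)):
                raise ConfigError("config key 'k' must be a number (nSv/s)")
            k = CalibrationConstant(float(raw["k"]))
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid config value: {exc}") from exc
    return RunConfig(geometry=geometry, beam=beam, roof=roof, scenario=scenario, k=k)
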