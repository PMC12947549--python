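"""CSV readers/writers, TOML configuration, and run manifests.

Units are fixed and never inferred — molar, Pa, rad/s, s, N, K — and
the CSV headers carry them to prevent silent mis-scaling:

* frequency sweep:     omega_rad_s, G_prime_Pa, G_double_prime_Pa
* stress relaxation:   time_s, G_Pa
* modulus titration:   conc_M, G_Pa
* prediction output:   conc_M, ka_app, p, nu_e_M, mu_M, g_affine_Pa,
                       g_phantom_Pa, g_normalized [, band_low, band_high]
"""

from __future__ import annotations

import datetime as _dt
import tomllib
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .binding import BindingSystem, NetworkSpec
from .elasticity import ElasticityPrediction, PredictionBand
from .errors import ParseError
from .inverse import TitrationTable
from .relaxation import FrequencySweep, StressRelaxationCurve

SWEEP_COLUMNS = ("omega_rad_s", "G_prime_Pa", "G_double_prime_Pa")
RELAXATION_COLUMNS = ("time_s", "G_Pa")
TITRATION_COLUMNS = ("conc_M", "G_Pa")


def _read_validated(path: str | Path, columns: Sequence[str],
                    positive: Sequence[str] = (),
                    increasing: str | None = None) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: cannot read CSV ({exc})") from exc
    for col in columns:
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    df = df[list(columns)]
    for col in columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna()]
        if len(bad):
            raise ParseError(
                f"{path}: non-numeric value in column {col!r} at data row "
                f"{int(bad[0]) + 1}")
        df[col] = vals.astype(float)
    for col in positive:
        neg = df.index[df[col] < 0]
        if len(neg):
            raise ParseError(
                f"{path}: negative value in column {col!r} at data row "
                f"{int(neg[0]) + 1}")
    if increasing is not None:
        diffs = np.diff(df[increasing].to_numpy())
        if np.any(diffs <= 0):
            row = int(np.flatnonzero(diffs <= 0)[0]) + 2
            raise ParseError(
                f"{path}: column {increasing!r} must be strictly increasing; "
                f"violation at data row {row}")
    return df


def read_sweep(path: str | Path) -> FrequencySweep:
    """Read a frequency-sweep CSV into a :class:`FrequencySweep`."""
    df = _read_validated(path, SWEEP_COLUMNS,
                         positive=SWEEP_COLUMNS, increasing="omega_rad_s")
    if np.any(df["omega_rad_s"] <= 0):
        row = int(df.index[df["omega_rad_s"] <= 0][0]) + 1
        raise ParseError(f"{path}: omega_rad_s must be > 0 (data row {row})")
    return FrequencySweep(omega=df["omega_rad_s"].to_numpy(),
                          g_storage=df["G_prime_Pa"].to_numpy(),
                          g_loss=df["G_double_prime_Pa"].to_numpy())


def read_relaxation(path: str | Path, g0: float | None = None,
                    ) -> StressRelaxationCurve:
    """Read a stress-relaxation CSV into a :class:`StressRelaxationCurve`."""
    df = _read_validated(path, RELAXATION_COLUMNS,
                         positive=RELAXATION_COLUMNS, increasing="time_s")
    return StressRelaxationCurve(time=df["time_s"].to_numpy(),
                                 g_t=df["G_Pa"].to_numpy(), g0=g0)


def read_titration(path: str | Path, g_uninhibited: float | None = None,
                   ) -> TitrationTable:
    """Read a modulus-titration CSV into a :class:`TitrationTable`."""
    df = _read_validated(path, TITRATION_COLUMNS, positive=TITRATION_COLUMNS)
    return TitrationTable(conc=df["conc_M"].to_numpy(),
                          g_measured=df["G_Pa"].to_numpy(),
                          g_uninhibited=g_uninhibited)


def write_sweep(sweep: FrequencySweep, path: str | Path) -> None:
    pd.DataFrame({"omega_rad_s": sweep.omega, "G_prime_Pa": sweep.g_storage,
                  "G_double_prime_Pa": sweep.g_loss}).to_csv(path, index=False)


def write_relaxation(curve: StressRelaxationCurve, path: str | Path) -> None:
    pd.DataFrame({"time_s": curve.time,
                  "G_Pa": curve.g_t}).to_csv(path, index=False)


def write_titration(table: TitrationTable, path: str | Path) -> None:
    pd.DataFrame({"conc_M": table.conc,
                  "G_Pa": table.g_measured}).to_csv(path, index=False)


def predictions_to_frame(preds: Sequence[ElasticityPrediction],
                         band: PredictionBand | None = None) -> pd.DataFrame:
    """Tidy per-concentration output of the forward chain."""
    df = pd.DataFrame({
        "conc_M": [p.conc_c for p in preds],
        "ka_app": [p.ka_app for p in preds],
        "p": [p.p for p in preds],
        "is_gel": [p.is_gel for p in preds],
        "nu_e_M": [p.nu_e for p in preds],
        "mu_M": [p.mu for p in preds],
        "g_affine_Pa": [p.g_affine for p in preds],
        "g_phantom_Pa": [p.g_phantom for p in preds],
        "g_normalized": [p.g_normalized for p in preds],
    })
    if band is not None:
        df["band_low"] = band.low
        df["band_high"] = band.high
    return df


def load_config(path: str | Path) -> tuple[BindingSystem, NetworkSpec]:
    """Load [binding] and [network] sections from a TOML config.

    Keys: [binding] ka_xl, ka_xl_sd, ka_c, ka_c_sd, conc_c (all optional
    but ka_xl); [network] n_xl_molar, functionality, temperature_K.
    """
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    try:
        b = cfg.get("binding", {})
        binding = BindingSystem(
            ka_xl=float(b["ka_xl"]),
            ka_c=float(b.get("ka_c", 0.0)),
            conc_c=float(b.get("conc_c", 0.0)),
            ka_xl_sd=float(b.get("ka_xl_sd", 0.0)),
            ka_c_sd=float(b.get("ka_c_sd", 0.0)),
        )
        n = cfg.get("network", {})
        network = NetworkSpec(
            n_xl=float(n["n_xl_molar"]),
            functionality=int(n.get("functionality", 4)),
            temperature=float(n.get("temperature_K", 298.15)),
        )
    except KeyError as exc:
        raise ParseError(f"{path}: missing required config key {exc}") from exc
    return binding, network


def write_manifest(path: str | Path, command: str, params: dict,
                   seed: int | None = None) -> None:
    """Plain-text key-value run manifest accompanying every CLI output."""
    lines = [
        f"command = {command}",
        f"package_version = {__version__}",
        f"timestamp_utc = {_dt.datetime.now(_dt.timezone.utc).isoformat()}",
    ]
    if seed is not None:
        lines.append(f"seed = {seed}")
    for key, value in sorted(params.items()):
        lines.append(f"{key} = {value}")
    Path(path).write_text("\n".join(lines) + "\n")
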