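"""Reading and writing the delimited-text experiment tables.

All tables are plain CSV with an optional block of ``#`` comment lines at
the top; trace files carry their metadata in ``# key: value`` comments.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .adsorption import InhibitionPoint
from .constants import BET_SSA, H0_SQRT_COM
from .dft import EnergyRecord
from .errors import ValidationError
from .kinetics import DissolutionRun, RatePoint, TitrationTrace, relative_undersaturation

__all__ = [
    "read_runs_csv",
    "read_inhibition_csv",
    "read_trace_csv",
    "read_energies_csv",
]


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", skip_blank_lines=True)


def read_runs_csv(path, h0_sqrt: float = H0_SQRT_COM) -> list[DissolutionRun]:
    """Dissolution runs from a CSV with columns
    ``t_ca_molar, sigma (optional), rate, seed_mg, rpm, inhibitor_molar, label``.

    If ``sigma`` is absent it is computed from ``t_ca_molar`` as
    (H₀^{1/2} − T_Ca)/H₀^{1/2} with the configured solubility.  Rows are
    grouped by ``label`` into one run each.
    """
    df = _read_csv(path)
    required = {"t_ca_molar", "rate"}
    if missing := required - set(df.columns):
        raise ValidationError(f"runs CSV missing columns: {sorted(missing)}")
    if "sigma" not in df.columns or df["sigma"].isna().all():
        df["sigma"] = [
            relative_undersaturation(t, h0_sqrt) for t in df["t_ca_molar"]
        ]
    if "label" not in df.columns:
        df["label"] = "control"
    runs = []
    for label, grp in df.groupby("label", sort=False):
        points = [
            RatePoint(
                sigma=float(row["sigma"]),
                rate=float(row["rate"]),
                t_ca=float(row["t_ca_molar"]),
                seed_mass=float(row.get("seed_mg", 10.0)) if "seed_mg" in df.columns else 10.0,
                stirring=float(row.get("rpm", 300.0)) if "rpm" in df.columns else 300.0,
                inhibitor_conc=float(row.get("inhibitor_molar", 0.0))
                if "inhibitor_molar" in df.columns else 0.0,
            )
            for _, row in grp.iterrows()
        ]
        runs.append(DissolutionRun(points=points, label=str(label)))
    return runs


def read_inhibition_csv(path) -> tuple[float, list[InhibitionPoint]]:
    """Inhibition series from a CSV with columns ``inhibitor_molar, rate``.

    The control rate R₀ is the row with ``inhibitor_molar == 0`` (exactly one
    required).  Returns ``(r0, points)``.
    """
    df = _read_csv(path)
    if missing := {"inhibitor_molar", "rate"} - set(df.columns):
        raise ValidationError(f"inhibition CSV missing columns: {sorted(missing)}")
    control = df[df["inhibitor_molar"] == 0]
    if len(control) != 1:
        raise ValidationError(
            "inhibition CSV must contain exactly one control row (inhibitor_molar = 0)"
        )
    r0 = float(control["rate"].iloc[0])
    points = [
        InhibitionPoint(
            conc=float(row["inhibitor_molar"]),
            rate_inhibited=float(row["rate"]),
            rate_control=r0,
        )
        for _, row in df[df["inhibitor_molar"] > 0].iterrows()
    ]
    return r0, points


def read_trace_csv(path) -> TitrationTrace:
    """Titration trace: ``# key: value`` metadata then ``time_min, volume_cm3``.

    Required metadata: ``titrant_conc_molar``, ``seed_mg``; optional
    ``ssa_m2_per_g`` (defaults to the BET value).
    """
    meta: dict[str, float] = {}
    body_lines = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if ":" in stripped:
                key, _, val = stripped.partition(":")
                try:
                    meta[key.strip()] = float(val)
                except ValueError:
                    pass
        elif line.strip():
            body_lines.append(line)
    for key in ("titrant_conc_molar", "seed_mg"):
        if key not in meta:
            raise ValidationError(f"trace CSV missing '# {key}:' metadata")
    df = pd.read_csv(_io.StringIO("\n".join(body_lines)))
    if missing := {"time_min", "volume_cm3"} - set(df.columns):
        raise ValidationError(f"trace CSV missing columns: {sorted(missing)}")
    return TitrationTrace(
        times=np.asarray(df["time_min"], dtype=float),
        titrant_volume=np.asarray(df["volume_cm3"], dtype=float),
        titrant_conc=meta["titrant_conc_molar"],
        seed_mass=meta["seed_mg"],
        specific_surface_area=meta.get("ssa_m2_per_g", BET_SSA),
    )


def read_energies_csv(path) -> dict[str, EnergyRecord]:
    """Energy records from ``label, e_total_ev[, e_homo_ev, e_lumo_ev, e_gap_ev]``."""
    df = _read_csv(path)
    if "label" not in df.columns:
        raise ValidationError("energies CSV missing 'label' column")

    def _opt(row, col):
        if col in df.columns and pd.notna(row.get(col)):
            return float(row[col])
        return None

    records = {}
    for _, row in df.iterrows():
        rec = EnergyRecord(
            label=str(row["label"]),
            e_total=_opt(row, "e_total_ev"),
            e_homo=_opt(row, "e_homo_ev"),
            e_lumo=_opt(row, "e_lumo_ev"),
            e_gap=_opt(row, "e_gap_ev"),
        )
        records[rec.label] = rec
    return records
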