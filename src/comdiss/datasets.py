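"""Packaged reference tables and their loaders.

The CSVs under ``comdiss/data`` transcribe the published dissolution and
inhibition experiment tables (corrections applied to derived columns are
documented in each file's header comments).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .adsorption import InhibitionPoint
from .dft import EnergyRecord
from .errors import ValidationError
from .kinetics import DissolutionRun, RatePoint

__all__ = [
    "load_dissolution_table",
    "load_dissolution_runs",
    "load_inhibition_table",
    "load_inhibition_points",
    "load_energies",
    "data_path",
]


def data_path(name: str):
    """Traversable path to a packaged data file."""
    return resources.files("comdiss") / "data" / name


def _read(name: str) -> pd.DataFrame:
    with resources.as_file(data_path(name)) as p:
        return pd.read_csv(p, comment="#")


def load_dissolution_table() -> pd.DataFrame:
    """The dissolution experiment table as a DataFrame (molar units)."""
    return _read("table3_dissolution.csv")


def load_dissolution_runs() -> tuple[DissolutionRun, DissolutionRun]:
    """(control, additive) runs built from the packaged dissolution table.

    σ for each point is the published two-figure value divided by 100; the
    kinetics layer can always recompute it from ``t_ca`` and H₀^{1/2}.
    """
    df = load_dissolution_table()
    runs = []
    for col, label in (("rate_control", "control"), ("rate_additive", "additive")):
        points = [
            RatePoint(
                sigma=float(row["sigma_printed_x100"]) / 100.0,
                rate=float(row[col]),
                t_ca=float(row["t_ca_molar"]),
                seed_mass=float(row["seed_mg"]),
                stirring=float(row["rpm"]),
            )
            for _, row in df.iterrows()
        ]
        runs.append(DissolutionRun(points=points, label=label))
    return runs[0], runs[1]


def load_inhibition_table() -> pd.DataFrame:
    """Inhibition series incl. the control row and the printed % column."""
    return _read("inhibition.csv")


def load_inhibition_points() -> tuple[float, list[InhibitionPoint]]:
    """(control rate R₀, inhibition points) from the packaged table."""
    df = load_inhibition_table()
    control = df[df["inhibitor_molar"] == 0]
    if len(control) != 1:
        raise ValidationError("packaged inhibition table lost its control row")
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


def load_energies() -> dict[str, EnergyRecord]:
    """Published total energies / gaps of caffeine, CaOx and their complex."""
    df = _read("dft_energies.csv")

    def _opt(row, col):
        val = row.get(col)
        return float(val) if pd.notna(val) else None

    return {
        str(row["label"]): EnergyRecord(
            label=str(row["label"]),
            e_total=_opt(row, "e_total_ev"),
            e_homo=_opt(row, "e_homo_ev"),
            e_lumo=_opt(row, "e_lumo_ev"),
            e_gap=_opt(row, "e_gap_ev"),
        )
        for _, row in df.iterrows()
    }
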