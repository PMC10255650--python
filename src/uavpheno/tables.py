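"""CSV round-trip of plot-trait and spectra tables.

Column layout is documented in ``docs/data_dictionary.md``.  Plot tables
carry one row per field plot; spectra tables one row per sample (plot or
bare soil) with band columns named ``b<center-nm>``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .sensors import band_column
from .simulate import PlotRecord, SpectralSample

PLOT_KEY_COLUMNS = ["plot_id", "trial_id", "genotype_id", "replicate"]
SPECTRA_KEY_COLUMNS = ["sample_id", "plot_id", "sensor", "mission", "is_soil"]


def plots_to_frame(plots: Sequence[PlotRecord]) -> pd.DataFrame:
    rows = []
    for p in plots:
        row = {"plot_id": p.plot_id, "trial_id": p.trial_id,
               "genotype_id": p.genotype_id, "replicate": p.replicate}
        row.update(p.traits)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_plots(df: pd.DataFrame) -> list[PlotRecord]:
    _require(df, PLOT_KEY_COLUMNS, "plot table")
    trait_cols = [c for c in df.columns if c not in PLOT_KEY_COLUMNS]
    return [
        PlotRecord(
            plot_id=str(r["plot_id"]), trial_id=str(r["trial_id"]),
            genotype_id=str(r["genotype_id"]), replicate=int(r["replicate"]),
            traits={c: float(r[c]) for c in trait_cols},
        )
        for _, r in df.iterrows()
    ]


def spectra_to_frame(samples: Sequence[SpectralSample]) -> pd.DataFrame:
    rows = []
    for s in samples:
        row = {"sample_id": s.sample_id, "plot_id": s.plot_id or "",
               "sensor": s.sensor, "mission": s.mission,
               "is_soil": bool(s.is_soil)}
        for center, val in s.reflectance.items():
            row[band_column(center)] = val
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_spectra(df: pd.DataFrame) -> list[SpectralSample]:
    _require(df, SPECTRA_KEY_COLUMNS, "spectra table")
    band_cols = [c for c in df.columns if c.startswith("b")
                 and c[1:].isdigit()]
    out = []
    for _, r in df.iterrows():
        pid = str(r["plot_id"]) if str(r["plot_id"]) else None
        out.append(SpectralSample(
            sample_id=str(r["sample_id"]), plot_id=pid,
            sensor=str(r["sensor"]), mission=str(r["mission"]),
            reflectance={float(c[1:]): float(r[c]) for c in band_cols},
            is_soil=bool(r["is_soil"]),
        ))
    return out


def write_plot_table(plots: Sequence[PlotRecord] | pd.DataFrame,
                     path: str | Path) -> None:
    df = plots if isinstance(plots, pd.DataFrame) else plots_to_frame(plots)
    _require(df, PLOT_KEY_COLUMNS, "plot table")
    df.to_csv(path, index=False)


def read_plot_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, PLOT_KEY_COLUMNS, "plot table")
    return df


def write_spectra_table(samples: Sequence[SpectralSample] | pd.DataFrame,
                        path: str | Path) -> None:
    df = (samples if isinstance(samples, pd.DataFrame)
          else spectra_to_frame(samples))
    _require(df, SPECTRA_KEY_COLUMNS, "spectra table")
    df.to_csv(path, index=False)


def read_spectra_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=True)
    _require(df, SPECTRA_KEY_COLUMNS, "spectra table")
    df["plot_id"] = df["plot_id"].fillna("")
    return df


def _require(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing mandatory column(s): {missing}")
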