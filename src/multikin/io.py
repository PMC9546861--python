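"""Tables, units, configuration and protocol arithmetic.

All concentrations are molar in memory; every CSV dialect stores
concentrations in nanomolar in a column whose name ends in ``_nM``.
Dialects:

* library CSV:        id, valency, epitope_seq, e, o1, o2, o3, tokens
* trace CSV (long):   trace_id, spot_role, phase, time_s, signal, conc_nM
* dose-response CSV:  conc_nM, f_norm, replicate
* spot CSV:           spot_id, side, condition_id, conc_nM, intensity, background
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .types import PeptideArchitecture, SensorTrace

logger = logging.getLogger("multikin")

NM_PER_M = 1e9

LIBRARY_COLUMNS = ["id", "valency", "epitope_seq", "e", "o1", "o2", "o3", "tokens"]
TRACE_COLUMNS = ["trace_id", "spot_role", "phase", "time_s", "signal", "conc_nM"]
DOSE_RESPONSE_COLUMNS = ["conc_nM", "f_norm", "replicate"]
SPOT_COLUMNS = ["spot_id", "side", "condition_id", "conc_nM", "intensity", "background"]


def to_nM(conc_M) -> np.ndarray | float:
    return np.multiply(conc_M, NM_PER_M)


def to_M(conc_nM) -> np.ndarray | float:
    return np.divide(conc_nM, NM_PER_M)


class TableFormatError(ValueError):
    """A CSV did not match its documented dialect."""


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise TableFormatError(f"{what}: missing columns {missing}")


def _require_numeric(df: pd.DataFrame, cols: list[str], what: str) -> None:
    for c in cols:
        bad = pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()
        if bad.any():
            # +2: 1-based data rows below the header line
            lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()
            raise TableFormatError(
                f"{what}: non-numeric values in column {c!r} at line(s) {lines[:5]}"
            )


# ---------------------------------------------------------------------------
# Protocol arithmetic
# ---------------------------------------------------------------------------

def dilution_series(
    top: float, n_points: int, factor: float = 2.0, post_mix: int = 1
) -> np.ndarray:
    """Serial dilution concentrations, highest first (molar).

    ``top`` is the pre-dilution stock; each step divides by ``factor``;
    ``post_mix=2`` models mixing each dilution with an equal volume of a
    second component (e.g. the target complex), halving every concentration.
    A 16-point 1:1 series from a 2 mM stock with post-mix thus runs from
    1 mM down to 30.52 nM.
    """
    if top <= 0:
        raise ValueError("top concentration must be positive")
    if n_points < 1:
        raise ValueError("need at least one point")
    if factor <= 1:
        raise ValueError("dilution factor must exceed 1")
    if post_mix not in (1, 2):
        raise ValueError("post_mix must be 1 or 2")
    return top / post_mix / factor ** np.arange(n_points, dtype=float)


def protein_consumption(
    mass_per_assay: dict[str, float], reference_method: str
) -> dict[str, float]:
    """Fold-ratio of protein consumed by each method relative to a reference.

    Masses are per-peptide protein consumption (µg); ratios are rounded to
    one decimal place, matching how such comparisons are quoted.
    """
    if reference_method not in mass_per_assay:
        raise KeyError(f"reference method {reference_method!r} not in table")
    if any(m <= 0 for m in mass_per_assay.values()):
        raise ValueError("masses must be positive")
    ref = mass_per_assay[reference_method]
    return {
        method: round(mass / ref, 1)
        for method, mass in mass_per_assay.items()
        if method != reference_method
    }


# ---------------------------------------------------------------------------
# Library I/O
# ---------------------------------------------------------------------------

def library_to_frame(library: list[PeptideArchitecture]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [a.id for a in library],
            "valency": [a.valency for a in library],
            "epitope_seq": [a.epitope_seq for a in library],
            "e": [a.epitope_length for a in library],
            "o1": [a.linker_lengths[0] for a in library],
            "o2": [a.linker_lengths[1] for a in library],
            "o3": [a.linker_lengths[2] for a in library],
            "tokens": [a.token_string for a in library],
        }
    )


def write_library_csv(library: list[PeptideArchitecture], path) -> None:
    library_to_frame(library).to_csv(path, index=False)


def read_library_csv(path) -> list[PeptideArchitecture]:
    df = pd.read_csv(path, keep_default_na=False)
    _require_columns(df, LIBRARY_COLUMNS, f"library CSV {path}")
    _require_numeric(df, ["valency", "e", "o1", "o2", "o3"], f"library CSV {path}")
    return [
        PeptideArchitecture(
            id=str(r.id),
            valency=int(r.valency),
            epitope_seq=str(r.epitope_seq),
            linker_lengths=(int(r.o1), int(r.o2), int(r.o3)),
            token_string=str(r.tokens),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Trace I/O (long format)
# ---------------------------------------------------------------------------

def traces_to_frame(traces: dict[str, SensorTrace] | list[SensorTrace]) -> pd.DataFrame:
    if isinstance(traces, dict):
        traces = list(traces.values())
    parts = []
    for tr in traces:
        parts.append(
            pd.DataFrame(
                {
                    "trace_id": tr.trace_id,
                    "spot_role": tr.spot_role,
                    "phase": tr.phase,
                    "time_s": tr.time,
                    "signal": tr.signal,
                    "conc_nM": to_nM(tr.analyte_conc),
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def write_trace_csv(traces, path) -> None:
    traces_to_frame(traces).to_csv(path, index=False)


def read_trace_csv(path) -> list[SensorTrace]:
    df = pd.read_csv(path)
    _require_columns(df, TRACE_COLUMNS, f"trace CSV {path}")
    _require_numeric(df, ["time_s", "signal", "conc_nM"], f"trace CSV {path}")
    out = []
    for (tid, role), g in df.groupby(["trace_id", "spot_role"], sort=False):
        g = g.sort_values("time_s")
        out.append(
            SensorTrace(
                time=g["time_s"].to_numpy(),
                signal=g["signal"].to_numpy(),
                phase=g["phase"].to_numpy(),
                analyte_conc=float(to_M(g["conc_nM"].iloc[0])),
                spot_role=str(role),
                trace_id=str(tid),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Dose-response and spot-table I/O
# ---------------------------------------------------------------------------

def write_dose_response_csv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    if "conc_M" in out.columns:
        out["conc_nM"] = to_nM(out.pop("conc_M"))
    out.to_csv(path, index=False)


def read_dose_response_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["conc_nM", "f_norm"], f"dose-response CSV {path}")
    _require_numeric(df, ["conc_nM", "f_norm"], f"dose-response CSV {path}")
    df["conc_M"] = to_M(df["conc_nM"])
    return df


def write_spot_csv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    if "conc_M" in out.columns:
        out["conc_nM"] = to_nM(out.pop("conc_M"))
    out.to_csv(path, index=False)


def read_spot_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, SPOT_COLUMNS, f"spot CSV {path}")
    _require_numeric(df, ["conc_nM", "intensity", "background"], f"spot CSV {path}")
    df["conc_M"] = to_M(df["conc_nM"])
    return df


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Seed plus per-stage parameter blocks; round-trips losslessly as JSON."""

    seed: int = 0
    units: str = "nM"
    paths: dict[str, str] = field(default_factory=dict)
    synth: dict = field(default_factory=dict)
    kinetics: dict = field(default_factory=dict)
    competition: dict = field(default_factory=dict)
    microarray: dict = field(default_factory=dict)
    ml: dict = field(default_factory=dict)
    resource_masses_ug: dict[str, float] = field(
        default_factory=lambda: {"FPS": 0.64, "BLI": 18.25, "ITC": 182.4, "TRIC": 0.29}
    )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_json(Path(path).read_text())

    def log_resolved(self, stage: str) -> None:
        block = getattr(self, stage, {})
        logger.info(
            "stage=%s seed=%d params=%s", stage, self.seed, json.dumps(block, sort_keys=True)
        )
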