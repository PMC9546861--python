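"""Synthetic multivalent-peptide libraries and raw-data simulators.

Generates combinatorial dimer/tetramer/octamer architectures with planted
ground-truth 1:1 kinetics, then simulates every raw data type the analysis
stages consume:

* real-time biosensor (FPS) traces — single-exponential association /
  dissociation with reference and blank channels, linear drift and additive
  Gaussian noise;
* displacement (TRIC-style) dose-response plates — generated from the exact
  three-species competitive equilibrium, not from a logistic, so Hill-fit +
  K_i conversion is a genuine round-trip;
* microarray spot-intensity tables with internal left/right duplicates,
  local background and a no-competitor condition.

The planted-kinetics rule reproduces the qualitative structure observed for
avidity-engineered binders: affinity gains are driven primarily by on-rates
(spread >= 100-fold across a default library) while off-rates stay within a
5-fold band, and K_D decreases with valency and epitope length.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd

from .competition import bound_tracer_fraction
from .io import dilution_series
from .types import (
    CompetitionSetup,
    GroundTruthKinetics,
    PeptideArchitecture,
    SensorTrace,
    TOKEN_CAPACITY,
    TokenCapacityError,
)

__all__ = [
    "DEFAULT_RULE_PARAMS",
    "DEFAULT_EPITOPE_LENGTHS",
    "DEFAULT_LINKER_GRID",
    "generate_library",
    "default_library",
    "plant_kinetics",
    "simulate_fps_trace",
    "simulate_tric_plate",
    "simulate_microarray",
]

# Synthetic epitope context: the FSIVG core motif of the receptor-derived
# binding epitope, embedded in invented flanking residues so that epitope
# length changes the amino-acid composition.  The flanks are synthetic
# sequence, not the natural receptor sequence.
_CORE = "FSIVG"
_LEFT_FLANK = "TNRAD"   # used right-to-left when extending to the N side
_RIGHT_FLANK = "SPKRE"  # used left-to-right when extending to the C side

DEFAULT_VALENCIES = (2, 4, 8)
DEFAULT_EPITOPE_LENGTHS = (5, 6, 7, 8)
# 9 linker specs (J = branching linker, O = PEG spacer): O-runs delimited by
# J give the per-tier PEG counts (o1, o2, o3); here the 3 x 3 grid of
# o1, o2 in {0, 1, 2}.
DEFAULT_LINKER_GRID = (
    "J", "OJ", "OOJ", "JO", "OJO", "OOJO", "JOO", "OJOO", "OOJOO",
)

#: Planted-kinetics rule.  k_on (M^-1 s^-1) and k_off (s^-1) are products of
#: a base rate, a valency multiplier, an epitope-length power law (e/5)^exp,
#: a small per-token linker effect on k_on, and bounded log-uniform jitter.
DEFAULT_RULE_PARAMS: dict = {
    "base_k_on": 2e3,
    "base_k_off": 2e-3,
    "k_on_valency": {1: 0.5, 2: 1.0, 4: 8.0, 8: 60.0},
    "k_off_valency": {1: 2.2, 2: 1.8, 4: 1.0, 8: 0.55},
    "k_on_epitope_exp": 2.0,
    "k_off_epitope_exp": -0.3,
    "k_on_per_O": 1.06,
    "k_on_per_J": 0.97,
    "jitter_log_k_on": 0.15,
    "jitter_log_k_off": 0.08,
}


def _epitope_for_length(e: int) -> str:
    """Epitope of length e >= 5 with the FSIVG core centred."""
    if e < len(_CORE):
        raise ValueError(f"epitope length must be >= {len(_CORE)}, got {e}")
    extra = e - len(_CORE)
    n_right = (extra + 1) // 2
    n_left = extra // 2
    if n_left > len(_LEFT_FLANK) or n_right > len(_RIGHT_FLANK):
        raise ValueError(f"epitope length {e} exceeds the synthetic context")
    left = _LEFT_FLANK[len(_LEFT_FLANK) - n_left:] if n_left else ""
    return left + _CORE + _RIGHT_FLANK[:n_right]


def _tiers_from_tokens(tokens: str) -> tuple[int, int, int]:
    """PEG counts per branching tier: O's between successive J tokens."""
    tiers = tokens.split("J")[:3]
    counts = [t.count("O") for t in tiers] + [0, 0, 0]
    return counts[0], counts[1], counts[2]


def _build_token_string(valency: int, o1: int, o2: int, o3: int) -> str:
    """Assemble the linker build string for a valency.

    One J (branching linker) per branching tier beyond the first, with the
    tier's PEG spacers in front of it: a dimer uses only o1, a tetramer
    o1-J-o2, an octamer o1-J-o2-J-o3.  Valency is therefore implicit in the
    token string, as it is in the synthesized compounds.
    """
    parts = ["O" * o1]
    if valency >= 4:
        parts += ["J", "O" * o2]
    if valency >= 8:
        parts += ["J", "O" * o3]
    return "".join(parts)


def generate_library(
    n_per_valency: int = 1,
    epitope_lengths=DEFAULT_EPITOPE_LENGTHS,
    linker_grid=DEFAULT_LINKER_GRID,
    seed: int = 0,
    valencies=DEFAULT_VALENCIES,
) -> list[PeptideArchitecture]:
    """Full combinatorial library: valencies x epitope lengths x linker grid.

    Each linker-grid entry is a spec string over {J, O} whose O-runs give the
    per-tier PEG counts; the stored token string is rebuilt per valency (see
    :func:`_build_token_string`), so higher valencies carry longer build
    strings.  ``n_per_valency`` adds replicate copies of each combination
    (identical architecture, distinct id) for replicate-aggregation
    workflows.  Deterministic for a fixed seed; ids are unique.
    """
    if n_per_valency < 1:
        raise ValueError("n_per_valency must be >= 1")
    for tok in linker_grid:
        if len(tok) > TOKEN_CAPACITY:
            raise TokenCapacityError(
                f"linker token string {tok!r} exceeds capacity {TOKEN_CAPACITY}"
            )
    library = []
    for v in valencies:
        for e in epitope_lengths:
            for gi, tok in enumerate(linker_grid):
                o1, o2, o3 = _tiers_from_tokens(tok)
                if v < 8:
                    o3 = 0
                if v < 4:
                    o2 = 0
                build = _build_token_string(v, o1, o2, o3)
                for r in range(n_per_valency):
                    pid = f"v{v}_e{e}_g{gi}"
                    if n_per_valency > 1:
                        pid += f"_r{r}"
                    if len(build) > TOKEN_CAPACITY:
                        raise TokenCapacityError(
                            f"architecture {pid!r}: build string {build!r} "
                            f"exceeds capacity {TOKEN_CAPACITY}"
                        )
                    library.append(
                        PeptideArchitecture(
                            id=pid,
                            valency=v,
                            epitope_seq=_epitope_for_length(e),
                            linker_lengths=(o1, o2, o3),
                            token_string=build,
                        )
                    )
    return library


def default_library(seed: int = 0) -> list[PeptideArchitecture]:
    """The default 3 x 4 x 9 = 108-compound study library."""
    return generate_library(seed=seed)


def _arch_rng(seed: int, arch_id: str) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(arch_id.encode())])


def plant_kinetics(
    arch: PeptideArchitecture,
    rule_params: dict | None = None,
    seed: int = 0,
) -> GroundTruthKinetics:
    """Assign ground-truth (k_on, k_off) to an architecture by rule.

    Across the default library the rule guarantees >= 100-fold k_on spread
    and <= 5-fold k_off spread, with K_D monotone decreasing (in expectation)
    in valency and epitope length.
    """
    p = {**DEFAULT_RULE_PARAMS, **(rule_params or {})}
    if p["base_k_on"] <= 0 or p["base_k_off"] <= 0:
        raise ValueError("base rates must be strictly positive")
    e_rel = arch.epitope_length / 5.0
    n_O = arch.token_string.count("O")
    n_J = arch.token_string.count("J")
    k_on = (
        p["base_k_on"]
        * p["k_on_valency"][arch.valency]
        * e_rel ** p["k_on_epitope_exp"]
        * p["k_on_per_O"] ** n_O
        * p["k_on_per_J"] ** n_J
    )
    k_off = (
        p["base_k_off"]
        * p["k_off_valency"][arch.valency]
        * e_rel ** p["k_off_epitope_exp"]
    )
    rng = _arch_rng(seed, arch.id)
    k_on *= np.exp(rng.uniform(-p["jitter_log_k_on"], p["jitter_log_k_on"]))
    k_off *= np.exp(rng.uniform(-p["jitter_log_k_off"], p["jitter_log_k_off"]))
    return GroundTruthKinetics(k_on=float(k_on), k_off=float(k_off))


# ---------------------------------------------------------------------------
# FPS trace simulator
# ---------------------------------------------------------------------------

def simulate_fps_trace(
    gt: GroundTruthKinetics,
    conc: float,
    t_assoc: float = 300.0,
    t_dissoc: float = 600.0,
    amplitude: float = 100.0,
    noise_sd: float = 0.0,
    drift: float = 0.0,
    seed: int = 0,
    dt: float = 1.0,
    t_baseline: float = 30.0,
    beta: float = 0.0,
    c_ref: float = 1e-6,
    trace_id: str = "",
) -> dict[str, SensorTrace]:
    """Simulate one concentration's measurement/reference/blank channel set.

    Forward model (1:1 single-exponential): during association
    S(t) = A * C/(C + K_D) * (1 - exp(-(k_on*C + k_off) t)), during
    dissociation S(t) = S_end * exp(-k_off t).  Reference and blank channels
    carry only drift and noise.  ``beta`` switches on a phenomenological
    concentration-dependent apparent on-rate, k_on,app = k_on (C/c_ref)^beta
    (off by default — the clean 1:1 model).
    """
    if conc < 0:
        raise ValueError("analyte concentration must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise SD must be non-negative")
    if min(t_assoc, t_dissoc, t_baseline) < 0 or dt <= 0:
        raise ValueError("times must be non-negative and dt positive")

    n_base = int(round(t_baseline / dt))
    n_assoc = int(round(t_assoc / dt))
    n_diss = int(round(t_dissoc / dt))
    time = np.arange(n_base + n_assoc + n_diss, dtype=float) * dt
    phase = np.array(
        ["baseline"] * n_base + ["association"] * n_assoc + ["dissociation"] * n_diss,
        dtype=object,
    )

    binding = np.zeros_like(time)
    if conc > 0:
        k_on_app = gt.k_on * (conc / c_ref) ** beta if beta else gt.k_on
        k_obs = k_on_app * conc + gt.k_off
        a_eq = amplitude * conc / (conc + gt.K_D)
        t_a = np.arange(n_assoc, dtype=float) * dt
        assoc = a_eq * (1.0 - np.exp(-k_obs * t_a))
        s_end = a_eq * (1.0 - np.exp(-k_obs * n_assoc * dt))
        t_d = np.arange(n_diss, dtype=float) * dt
        diss = s_end * np.exp(-gt.k_off * t_d)
        binding[n_base : n_base + n_assoc] = assoc
        binding[n_base + n_assoc :] = diss

    rng = np.random.default_rng(seed)
    trend = drift * time

    def channel(role: str, with_binding: bool, c: float) -> SensorTrace:
        noise = rng.normal(0.0, noise_sd, size=time.size) if noise_sd > 0 else 0.0
        sig = (binding if with_binding else 0.0) + trend + noise
        return SensorTrace(
            time=time.copy(),
            signal=np.asarray(sig, dtype=float)
            if np.ndim(sig)
            else np.full_like(time, sig),
            phase=phase.copy(),
            analyte_conc=c,
            spot_role=role,
            trace_id=f"{trace_id}:{role}" if trace_id else role,
        )

    return {
        "measurement": channel("measurement", True, conc),
        "reference": channel("reference", False, conc),
        "blank_measurement": channel("blank_measurement", False, 0.0),
        "blank_reference": channel("blank_reference", False, 0.0),
    }


# ---------------------------------------------------------------------------
# Displacement-plate simulator
# ---------------------------------------------------------------------------

def simulate_tric_plate(
    setup: CompetitionSetup,
    K_i: float,
    top_conc: float = 1e-3,
    n_points: int = 16,
    seed: int = 0,
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    f_free: float = 850.0,
    f_bound: float = 900.0,
) -> pd.DataFrame:
    """Simulate a serial-dilution displacement plate (F_norm vs competitor).

    Competitor concentrations follow top_conc / 2^k, k = 0..n_points-1
    (final in-assay concentrations).  The noiseless response is an affine map
    of the exact ternary-equilibrium bound-tracer fraction, so it is
    monotone in competitor concentration but not exactly logistic.
    Returns a frame with columns conc_M, f_norm, replicate.
    """
    if K_i <= 0:
        raise ValueError("K_i must be strictly positive")
    if n_points < 4:
        raise ValueError("need at least 4 dilution points")
    concs = dilution_series(top_conc, n_points)
    bf = np.array([bound_tracer_fraction(setup, c, K_i) for c in concs])
    clean = f_free + (f_bound - f_free) * bf
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        noise = rng.normal(0.0, noise_sd, size=concs.size) if noise_sd > 0 else 0.0
        rows.append(
            pd.DataFrame(
                {"conc_M": concs, "f_norm": clean + noise, "replicate": rep}
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Microarray simulator
# ---------------------------------------------------------------------------

def simulate_microarray(
    spots: int,
    competitor_concs,
    IC50: float,
    seed: int = 0,
    noise_sd: float = 0.0,
    base_intensity: float = 5e4,
    background: float = 2e3,
    hill: float = 1.0,
    competitor_id: str = "competitor",
) -> pd.DataFrame:
    """Simulate duplicate-spot intensities under competitor neutralization.

    Every spot appears on both duplicate sides (left/right) for every
    condition; a no-competitor condition (conc 0) is always included.  The
    expected specific signal decays logistically in log competitor
    concentration with midpoint ``IC50``; the recorded intensity adds a local
    background (also reported per spot) and Gaussian noise.
    """
    if IC50 <= 0:
        raise ValueError("IC50 must be strictly positive")
    if spots < 1:
        raise ValueError("need at least one spot")
    concs = [0.0] + sorted(float(c) for c in competitor_concs if c > 0)
    rng = np.random.default_rng(seed)
    spot_base = base_intensity * np.exp(rng.normal(0.0, 0.2, size=spots))
    rows = []
    for ci, conc in enumerate(concs):
        occupancy = 1.0 if conc == 0 else 1.0 / (1.0 + (conc / IC50) ** hill)
        for s in range(spots):
            expected = spot_base[s] * occupancy
            for side in ("left", "right"):
                noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                rows.append(
                    {
                        "spot_id": f"spot{s:02d}",
                        "side": side,
                        "condition_id": f"{competitor_id}_c{ci:02d}",
                        "conc_M": conc,
                        "intensity": max(expected + background + noise, 0.0),
                        "background": background,
                    }
                )
    return pd.DataFrame(rows)
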