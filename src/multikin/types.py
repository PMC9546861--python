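"""Shared domain types for the multivalent-binding pipeline.

Concentrations are molar everywhere inside the package; CSV I/O converts
to/from nanomolar (see :mod:`multikin.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical amino-acid alphabet, alphabetical one-letter codes.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Linker building-block alphabet: J = branching linker unit, O = PEG spacer.
TOKEN_ALPHABET = "JO"

#: Maximum token-string length the one-hot linker encoding can hold.
TOKEN_CAPACITY = 7

#: Allowed valencies (epitopes per compound).
VALENCIES = (1, 2, 4, 8)

#: Trace phases in their mandatory order.
PHASES = ("baseline", "association", "dissociation")

#: Roles a sensor spot/run can play in double referencing.
SPOT_ROLES = ("measurement", "reference", "blank_measurement", "blank_reference")


class TokenCapacityError(ValueError):
    """Token string longer than the one-hot encoding capacity."""


@dataclass(frozen=True)
class PeptideArchitecture:
    """One combinatorial multimer: valency, epitope and linker layout.

    ``token_string`` spells the linker build outward-in over {J, O}; the PEG
    counts ``o1..o3`` are the number of O (spacer) units per branching tier,
    tiers being delimited by J (branch) tokens.  o2 is only meaningful for
    valency >= 4 and o3 only for octamers.
    """

    id: str
    valency: int
    epitope_seq: str
    linker_lengths: tuple[int, int, int] = (0, 0, 0)
    token_string: str = ""

    def __post_init__(self) -> None:
        if self.valency not in VALENCIES:
            raise ValueError(f"valency must be one of {VALENCIES}, got {self.valency}")
        if len(self.token_string) > TOKEN_CAPACITY:
            raise TokenCapacityError(
                f"architecture {self.id!r}: token string {self.token_string!r} "
                f"exceeds capacity {TOKEN_CAPACITY}"
            )
        bad = set(self.token_string) - set(TOKEN_ALPHABET)
        if bad:
            raise ValueError(f"architecture {self.id!r}: tokens {bad} not in {{J, O}}")
        bad_aa = set(self.epitope_seq) - set(AA_ALPHABET)
        if bad_aa:
            raise ValueError(f"architecture {self.id!r}: residues {bad_aa} not canonical")
        if any(o < 0 for o in self.linker_lengths):
            raise ValueError(f"architecture {self.id!r}: negative linker length")

    @property
    def epitope_length(self) -> int:
        return len(self.epitope_seq)


@dataclass(frozen=True)
class GroundTruthKinetics:
    """Planted 1:1 rate constants; K_D is defined as k_off / k_on."""

    k_on: float  # M^-1 s^-1
    k_off: float  # s^-1

    def __post_init__(self) -> None:
        if not (self.k_on > 0 and self.k_off > 0):
            raise ValueError("rate constants must be strictly positive")

    @property
    def K_D(self) -> float:
        return self.k_off / self.k_on


@dataclass
class SensorTrace:
    """One time-resolved fluorescence record.

    Phases must be contiguous and ordered baseline -> association ->
    dissociation (any may be absent).  ``time`` is the global experiment
    clock in seconds; phase-local time is obtained with
    :meth:`phase_time`, which restarts at 0 at each phase boundary
    (half-open intervals).
    """

    time: np.ndarray
    signal: np.ndarray
    phase: np.ndarray
    analyte_conc: float = 0.0  # molar; 0 for blanks
    spot_role: str = "measurement"
    trace_id: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        if not (len(self.time) == len(self.signal) == len(self.phase)):
            raise ValueError("time, signal and phase must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.analyte_conc < 0:
            raise ValueError("analyte concentration must be non-negative")
        if self.spot_role not in SPOT_ROLES:
            raise ValueError(f"spot_role must be one of {SPOT_ROLES}")
        seen = [p for p, _ in _runs(self.phase)]
        if len(seen) != len(set(seen)):
            raise ValueError("phases must be contiguous blocks")
        order = [p for p in PHASES if p in seen]
        if seen != order:
            raise ValueError(f"phases must be ordered {PHASES}, got {seen}")

    def phase_mask(self, name: str) -> np.ndarray:
        return np.asarray(self.phase == name)

    def phase_time(self, name: str) -> np.ndarray:
        """Time within a phase, measured from the phase's first sample."""
        t = self.time[self.phase_mask(name)]
        return t - t[0] if len(t) else t

    def phase_signal(self, name: str) -> np.ndarray:
        return self.signal[self.phase_mask(name)]

    def same_grid(self, other: "SensorTrace") -> bool:
        return np.array_equal(self.time, other.time) and np.array_equal(
            self.phase, other.phase
        )


def _runs(seq) -> list[tuple[object, int]]:
    """Run-length encode a sequence: [(value, count), ...]."""
    out: list[tuple[object, int]] = []
    for v in seq:
        if out and out[-1][0] == v:
            out[-1] = (v, out[-1][1] + 1)
        else:
            out.append((v, 1))
    return out


@dataclass(frozen=True)
class CompetitionSetup:
    """Fixed concentrations of a displacement assay.

    T_t : total target protein (M); C_t : total fluorescent tracer (M);
    K_D_tracer : tracer-target dissociation constant (M).
    """

    T_t: float
    C_t: float
    K_D_tracer: float

    def __post_init__(self) -> None:
        if not (self.T_t > 0 and self.C_t > 0 and self.K_D_tracer > 0):
            raise ValueError("all competition-setup concentrations must be > 0")


@dataclass
class KineticFit:
    """Result of a (global) single-exponential fit across concentrations."""

    k_on: float  # M^-1 s^-1
    k_off: float  # s^-1
    amplitudes: dict[float, float] = field(default_factory=dict)  # conc -> a.u.
    association_level: float = float("nan")
    se_k_on: float = 0.0
    se_k_off: float = 0.0
    rss: float = 0.0
    n_curves: int = 0
    flag: str | None = None  # None | "not_determinable" | "koff_upper_bound"

    @property
    def K_D(self) -> float:
        return self.k_off / self.k_on

    @property
    def determinable(self) -> bool:
        return self.flag != "not_determinable"

    @property
    def kd_is_bound(self) -> bool:
        """True when k_off is not resolved and K_D is only an upper bound."""
        return self.flag == "koff_upper_bound"


@dataclass
class HillFit:
    """Four-parameter logistic fit of a dose-response in log10 concentration.

    ``top`` is the response plateau at vanishing, ``bottom`` at saturating
    concentration; for a displacement curve top >= bottom.
    """

    ec50: float  # M
    hill_slope: float
    top: float
    bottom: float
    se_ec50: float = 0.0
    se_hill: float = 0.0
    se_top: float = 0.0
    se_bottom: float = 0.0
    rss: float = 0.0
    flag: str | None = None  # None | "ec50_at_edge" | "no_transition"

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("EC50 must be positive")

    def predict(self, conc) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        return self.bottom + (self.top - self.bottom) / (
            1.0 + (conc / self.ec50) ** self.hill_slope
        )
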