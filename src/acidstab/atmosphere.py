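"""Cloud-droplet sulfuric-acid concentration from temperature and humidity.

The acid concentration of a droplet in equilibrium with the water vapor
around it follows an empirical relation between water vapor pressure over
sulfuric acid, acid concentration, and temperature:

    P = (ln(ppH2O) - 15.988 - 42.2/T) / (0.053346 - 84.03/T)

with P in weight percent, ppH2O in mmHg, and T in kelvin.  Values above 100
denote fuming acid (oleum) and are returned as-is.

Note on the functional form: the two temperature terms are reciprocal
(42.2/T and 84.03/T).  A multiplicative reading (42.2*T) collapses P to a
constant near 0.5 regardless of input; the reciprocal reading yields
cloud-plausible 70-110% concentrations with the correct sign behavior
(drier air => stronger acid).  The form is isolated in
:func:`acid_wt_pct` / :func:`ppH2O_forward`.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from acidstab.kinetics import Condition

_A = 15.988
_B = 42.2
_C = 0.053346
_D = 84.03


def acid_wt_pct(ppH2O: float, T: float) -> float:
    """Acid concentration (wt %) of a droplet in equilibrium with water vapor.

    Parameters: ``ppH2O`` in mmHg (> 0), ``T`` in kelvin (> 0).
    Strictly decreasing in ppH2O at fixed T.
    """
    if not ppH2O > 0:
        raise ValueError(f"ppH2O must be > 0 mmHg, got {ppH2O}")
    if not T > 0:
        raise ValueError(f"temperature must be > 0 K, got {T}")
    denom = _C - _D / T
    if abs(denom) < 1e-9:
        raise ValueError(f"degenerate denominator at T={T} K")
    return (math.log(ppH2O) - _A - _B / T) / denom


def ppH2O_forward(P: float, T: float) -> float:
    """Water partial pressure (mmHg) over acid of concentration P wt % at T kelvin.

    Algebraic inverse of :func:`acid_wt_pct`; exact round-trip.
    """
    if not T > 0:
        raise ValueError(f"temperature must be > 0 K, got {T}")
    return math.exp(_A + _B / T + P * (_C - _D / T))


@dataclass(frozen=True)
class AtmosphericLevel:
    """One altitude sample with its derived acid concentration."""

    altitude_km: float
    temperature_K: float
    ppH2O_mmHg: float
    acid_wt_pct: float

    @property
    def condition(self) -> Condition:
        return Condition(acid_wt_pct=self.acid_wt_pct, temperature=self.temperature_K)


class AtmosphereProfile:
    """Altitude-ordered sequence of annotated levels.

    Queries between levels interpolate temperature and ln(ppH2O) linearly in
    altitude and recompute the acid concentration from the interpolated
    inputs, so the equilibrium relation holds at every queried altitude.
    """

    def __init__(self, levels: Sequence[AtmosphericLevel]):
        if len(levels) == 0:
            raise ValueError("profile must contain at least one level")
        alts = [lv.altitude_km for lv in levels]
        if any(b - a <= 0 for a, b in zip(alts, alts[1:])):
            raise ValueError("altitudes must be strictly increasing")
        self.levels = list(levels)

    def __len__(self) -> int:
        return len(self.levels)

    def __iter__(self):
        return iter(self.levels)

    @property
    def altitudes(self) -> np.ndarray:
        return np.array([lv.altitude_km for lv in self.levels])

    def at(self, altitude_km: float) -> AtmosphericLevel:
        """Level at an arbitrary altitude inside the profile span."""
        alts = self.altitudes
        if altitude_km < alts[0] or altitude_km > alts[-1]:
            raise ValueError(
                f"altitude {altitude_km} km outside profile span "
                f"[{alts[0]}, {alts[-1]}] km"
            )
        T = float(np.interp(altitude_km, alts, [lv.temperature_K for lv in self.levels]))
        ln_pp = float(
            np.interp(altitude_km, alts, [math.log(lv.ppH2O_mmHg) for lv in self.levels])
        )
        pp = math.exp(ln_pp)
        return AtmosphericLevel(
            altitude_km=float(altitude_km),
            temperature_K=T,
            ppH2O_mmHg=pp,
            acid_wt_pct=acid_wt_pct(pp, T),
        )

    def conditions(self) -> list[Condition]:
        return [lv.condition for lv in self.levels]


def build_profile(levels: Sequence[tuple[float, float, float]]) -> AtmosphereProfile:
    """Annotate (altitude_km, T_kelvin, ppH2O_mmHg) triples with acid wt %."""
    annotated = [
        AtmosphericLevel(
            altitude_km=float(alt),
            temperature_K=float(T),
            ppH2O_mmHg=float(pp),
            acid_wt_pct=acid_wt_pct(pp, T),
        )
        for alt, T, pp in levels
    ]
    return AtmosphereProfile(annotated)


def load_profile(path: str | Path) -> AtmosphereProfile:
    """Load a profile CSV with header altitude_km,temperature_K,ppH2O_mmHg."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"altitude_km", "temperature_K", "ppH2O_mmHg"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"{path}: profile must have columns {sorted(required)}")
        triples = [
            (float(r["altitude_km"]), float(r["temperature_K"]), float(r["ppH2O_mmHg"]))
            for r in reader
        ]
    return build_profile(triples)


def save_profile(profile: AtmosphereProfile, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["altitude_km", "temperature_K", "ppH2O_mmHg", "acid_wt_pct"])
        for lv in profile:
            writer.writerow(
                [lv.altitude_km, lv.temperature_K, repr(lv.ppH2O_mmHg), lv.acid_wt_pct]
            )
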