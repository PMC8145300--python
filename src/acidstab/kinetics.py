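"""Rate-constant grids over (acid wt%, temperature) and half-life models.

Rates are pseudo-first-order: with a vast excess of acid the disappearance of
a solute is exponential in time and its half-life is concentration
independent.  Grids store ln k (k in s^-1) on an acid-percent x kelvin mesh
and are interpolated bilinearly in (wt%, 1/T): Arrhenius-like in temperature
and log-linear in acidity.  Queries outside the grid clamp to the nearest
edge and carry an ``extrapolated`` flag -- the empirical data are sparse at
low temperature, so extrapolating the trend would overstate what is known.

The model is order-of-magnitude only; comparisons downstream should be made
on log10 values.

The multi-copy correction :func:`half_life_multi` implements
``t = -ln(1 - 0.5**N) / k`` exactly as printed in its source.  The printed
form is typographically ambiguous between ``0.5**N`` and ``0.5**(1/N)``; the
``0.5**N`` reading is used because it reduces to the single-copy law at
N = 1 and shortens the half-life as copies are added.  The reading is
isolated here so it can be swapped.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from numbers import Integral
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

LN2 = math.log(2.0)


@dataclass(frozen=True)
class Condition:
    """Acid concentration (wt %; >100 denotes oleum) and temperature (K)."""

    acid_wt_pct: float
    temperature: float

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")
        if self.acid_wt_pct < 0:
            raise ValueError(f"acid_wt_pct must be >= 0, got {self.acid_wt_pct}")


@dataclass(frozen=True)
class RateQuery:
    """Result of a grid interpolation."""

    k: float
    ln_k: float
    extrapolated: bool


@dataclass
class RateGrid:
    """ln-rate-constant matrix for one functional group.

    ``ln_k[i, j]`` is the natural log of k (s^-1) at ``wt_levels[i]`` percent
    acid and ``T_levels[j]`` kelvin.
    """

    group_id: str
    wt_levels: np.ndarray
    T_levels: np.ndarray
    ln_k: np.ndarray
    provenance: str = "synthetic"  # measured | interpolated | synthetic

    def __post_init__(self) -> None:
        self.wt_levels = np.asarray(self.wt_levels, dtype=float)
        self.T_levels = np.asarray(self.T_levels, dtype=float)
        self.ln_k = np.asarray(self.ln_k, dtype=float)
        if self.wt_levels.ndim != 1 or self.T_levels.ndim != 1:
            raise ValueError(f"grid {self.group_id!r}: level arrays must be 1-D")
        if self.ln_k.shape != (self.wt_levels.size, self.T_levels.size):
            raise ValueError(
                f"grid {self.group_id!r}: ln_k shape {self.ln_k.shape} != "
                f"({self.wt_levels.size}, {self.T_levels.size})"
            )
        for name, lv in (("wt_levels", self.wt_levels), ("T_levels", self.T_levels)):
            if lv.size == 0:
                raise ValueError(f"grid {self.group_id!r}: empty {name}")
            if np.any(np.diff(lv) <= 0):
                raise ValueError(f"grid {self.group_id!r}: {name} must be strictly ascending")
        if not np.all(np.isfinite(self.ln_k)):
            raise ValueError(f"grid {self.group_id!r}: non-finite ln_k")


def _bracket(levels: np.ndarray, x: float) -> tuple[int, int, float, bool]:
    """Bracketing indices and weight for 1-D linear interpolation with clamping."""
    if x <= levels[0]:
        return 0, 0, 0.0, x < levels[0]
    if x >= levels[-1]:
        n = levels.size - 1
        return n, n, 0.0, x > levels[-1]
    hi = int(np.searchsorted(levels, x, side="right"))
    lo = hi - 1
    w = (x - levels[lo]) / (levels[hi] - levels[lo])
    return lo, hi, float(w), False


def rate_at(grid: RateGrid, cond: Condition) -> RateQuery:
    """Bilinear interpolation of ln k in (acid wt%, 1/T); clamp-with-flag outside."""
    i0, i1, wi, clamp_w = _bracket(grid.wt_levels, cond.acid_wt_pct)
    j0, j1, _, clamp_t = _bracket(grid.T_levels, cond.temperature)
    if j0 == j1:
        wj = 0.0
    else:
        t0, t1 = grid.T_levels[j0], grid.T_levels[j1]
        # linear in 1/T between the bracketing temperature nodes
        wj = (1.0 / cond.temperature - 1.0 / t0) / (1.0 / t1 - 1.0 / t0)
    lnk = (
        (1 - wi) * (1 - wj) * grid.ln_k[i0, j0]
        + (1 - wi) * wj * grid.ln_k[i0, j1]
        + wi * (1 - wj) * grid.ln_k[i1, j0]
        + wi * wj * grid.ln_k[i1, j1]
    )
    return RateQuery(k=math.exp(lnk), ln_k=float(lnk), extrapolated=clamp_w or clamp_t)


def half_life_single(k: float, zero_ok: bool = False) -> float:
    """First-order half-life t = ln 2 / k (seconds, k in s^-1)."""
    if k == 0 and zero_ok:
        return math.inf
    if k <= 0:
        raise ValueError(f"rate constant must be > 0, got {k}")
    return LN2 / k


def half_life_multi(k: float, n_copies: int) -> float:
    """Half-life of a molecule bearing ``n_copies`` of one reactive group.

    ``t = -ln(1 - 0.5**N) / k``; reduces to :func:`half_life_single` at N = 1
    and is strictly decreasing in N.
    """
    if not isinstance(n_copies, Integral) or isinstance(n_copies, bool):
        raise ValueError(f"copy count must be an integer, got {n_copies!r}")
    if n_copies < 1:
        raise ValueError(f"copy count must be >= 1, got {n_copies}")
    if k <= 0:
        raise ValueError(f"rate constant must be > 0, got {k}")
    return -math.log1p(-(0.5 ** int(n_copies))) / k


def validate_grid(grid: RateGrid) -> list[str]:
    """Warnings for physically suspect grids.

    Rates must never decrease with temperature; acid-axis non-monotonicity is
    legitimate (rates generally, but not always, increase with concentration)
    and is not warned.
    """
    warnings = []
    dT = np.diff(grid.ln_k, axis=1)
    if np.any(dT < -1e-12):
        rows = np.unique(np.where(dT < -1e-12)[0])
        for i in rows:
            warnings.append(
                f"grid {grid.group_id!r}: ln_k decreases with temperature at "
                f"acid_wt_pct={grid.wt_levels[i]:g}"
            )
    return warnings


class RateLibrary:
    """Mapping of group_id -> RateGrid."""

    def __init__(self, grids: Iterable[RateGrid] = ()):
        self._grids: dict[str, RateGrid] = {}
        for g in grids:
            self.add(g)

    def add(self, grid: RateGrid) -> None:
        if grid.group_id in self._grids:
            raise ValueError(f"duplicate grid for group {grid.group_id!r}")
        self._grids[grid.group_id] = grid

    def get(self, group_id: str) -> RateGrid | None:
        return self._grids.get(group_id)

    def __contains__(self, group_id: str) -> bool:
        return group_id in self._grids

    def __len__(self) -> int:
        return len(self._grids)

    def __iter__(self) -> Iterator[RateGrid]:
        return iter(self._grids.values())

    def validate(self) -> list[str]:
        out: list[str] = []
        for g in self:
            out.extend(validate_grid(g))
        return out


def load_rates(path: str | Path) -> RateLibrary:
    """Load a long-format rate table (group_id,acid_wt_pct,temperature_K,ln_k[,provenance])."""
    cells: dict[str, dict[tuple[float, float], float]] = {}
    prov: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"group_id", "acid_wt_pct", "temperature_K", "ln_k"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"{path}: rate table must have columns {sorted(required)}")
        for row in reader:
            gid = row["group_id"]
            cells.setdefault(gid, {})[
                (float(row["acid_wt_pct"]), float(row["temperature_K"]))
            ] = float(row["ln_k"])
            prov[gid] = row.get("provenance", "") or "measured"
    grids = []
    for gid, vals in cells.items():
        wts = sorted({w for w, _ in vals})
        Ts = sorted({t for _, t in vals})
        lnk = np.full((len(wts), len(Ts)), np.nan)
        for (w, t), v in vals.items():
            lnk[wts.index(w), Ts.index(t)] = v
        if np.any(np.isnan(lnk)):
            raise ValueError(f"{path}: incomplete grid for group {gid!r}")
        grids.append(RateGrid(gid, np.array(wts), np.array(Ts), lnk, provenance=prov[gid]))
    return RateLibrary(grids)


def save_rates(library: RateLibrary, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["group_id", "acid_wt_pct", "temperature_K", "ln_k", "provenance"])
        for grid in library:
            for i, w in enumerate(grid.wt_levels):
                for j, t in enumerate(grid.T_levels):
                    writer.writerow(
                        [grid.group_id, repr(float(w)), repr(float(t)),
                         repr(float(grid.ln_k[i, j])), grid.provenance]
                    )
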