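"""Per-molecule, per-altitude half-lives and dataset-level stability summaries.

A molecule breaks down at the rate of its fastest-reacting functional group:
its half-life is the minimum over matched groups of the multi-copy half-life
at the queried condition.  Molecules matching no registered group, or whose
matched groups all lack rate data, yield ``no_prediction`` and are excluded
from every average and fraction (exclusion counts are always reported).

"Average half-life" defaults to the geometric mean: half-lives span many
orders of magnitude and an arithmetic mean would be dominated by single
outliers.  The arithmetic mean is available via ``kind="arithmetic"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from acidstab.atmosphere import AtmosphereProfile
from acidstab.fg_registry import MatchResult
from acidstab.kinetics import Condition, RateLibrary, half_life_multi, rate_at

#: half-life thresholds (s) used throughout the summaries
DEFAULT_THRESHOLDS: tuple[float, ...] = (1.0, 1e3, 1e6, 1e8)

#: stability band edges (s) and labels: <1 s, 1-1e3 s, 1e3-1e6 s, 1e6-1e8 s, >1e8 s
BAND_EDGES: tuple[float, ...] = (1.0, 1e3, 1e6, 1e8)
BAND_LABELS: tuple[str, ...] = ("<1s", "1-1e3s", "1e3-1e6s", "1e6-1e8s", ">1e8s")


def band_for(half_life_s: float) -> str:
    """Stability band containing a half-life (upper edges inclusive)."""
    if not half_life_s > 0:
        raise ValueError(f"half-life must be > 0, got {half_life_s}")
    for edge, label in zip(BAND_EDGES, BAND_LABELS):
        if half_life_s < edge:
            return label
    return BAND_LABELS[-1]


@dataclass(frozen=True)
class StabilityResult:
    """Half-life of one molecule at one condition (or ``no_prediction``)."""

    molecule_id: str
    altitude_km: float | None
    half_life_s: float | None
    limiting_group: str | None
    limiting_n: int | None
    band: str | None
    status: str  # "ok" | "no_prediction"
    extrapolated: bool = False

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def molecule_half_life(
    match: MatchResult,
    rates: RateLibrary,
    cond: Condition,
    altitude_km: float | None = None,
) -> StabilityResult:
    """Fastest-group half-life of one molecule at one condition.

    For every matched group with a rate grid, compute the multi-copy
    half-life; the molecule's half-life is the minimum and the limiting group
    is the argmin.
    """
    best: tuple[float, str, int] | None = None
    extrapolated = False
    for a in match.assignments:
        grid = rates.get(a.group_id)
        if grid is None:
            continue
        q = rate_at(grid, cond)
        t = half_life_multi(q.k, a.n_copies)
        if best is None or t < best[0]:
            best = (t, a.group_id, a.n_copies)
            extrapolated = q.extrapolated
    if best is None:
        return StabilityResult(
            molecule_id=match.molecule_id,
            altitude_km=altitude_km,
            half_life_s=None,
            limiting_group=None,
            limiting_n=None,
            band=None,
            status="no_prediction",
        )
    t, gid, n = best
    return StabilityResult(
        molecule_id=match.molecule_id,
        altitude_km=altitude_km,
        half_life_s=t,
        limiting_group=gid,
        limiting_n=n,
        band=band_for(t),
        status="ok",
        extrapolated=extrapolated,
    )


def profile_stability(
    matches: Sequence[MatchResult],
    rates: RateLibrary,
    profile: AtmosphereProfile,
) -> list[StabilityResult]:
    """One result per (molecule, profile level); deterministic given inputs."""
    results = []
    for level in profile:
        cond = level.condition
        for m in matches:
            results.append(
                molecule_half_life(m, rates, cond, altitude_km=level.altitude_km)
            )
    return results


def _by_altitude(results: Iterable[StabilityResult]) -> dict[float, list[StabilityResult]]:
    out: dict[float, list[StabilityResult]] = {}
    for r in results:
        if r.altitude_km is None:
            raise ValueError("result without altitude in a per-altitude aggregate")
        out.setdefault(r.altitude_km, []).append(r)
    return dict(sorted(out.items()))


def fraction_stable(
    results: Iterable[StabilityResult],
    threshold_s: float,
    altitude_min_km: float = 62.0,
) -> float:
    """Mean over qualifying levels of the matched fraction with t >= threshold.

    Levels at or above ``altitude_min_km`` qualify; ``no_prediction``
    molecules are excluded from numerator and denominator; the per-level
    fractions are averaged unweighted.
    """
    per_level = []
    for alt, rs in _by_altitude(results).items():
        if alt < altitude_min_km:
            continue
        matched = [r for r in rs if r.ok]
        if not matched:
            continue
        per_level.append(
            sum(1 for r in matched if r.half_life_s >= threshold_s) / len(matched)
        )
    if not per_level:
        raise ValueError(
            f"no qualifying levels at altitude >= {altitude_min_km} km with matched molecules"
        )
    return float(np.mean(per_level))


def mean_half_life(
    results: Iterable[StabilityResult],
    altitude_km: float,
    kind: str = "geometric",
) -> float:
    """Average half-life of matched molecules at one level (geometric default)."""
    rs = [
        r for r in results
        if r.ok and r.altitude_km is not None and r.altitude_km == altitude_km
    ]
    if not rs:
        raise ValueError(f"no matched molecules at altitude {altitude_km} km")
    ts = np.array([r.half_life_s for r in rs])
    if kind == "geometric":
        return float(np.exp(np.mean(np.log(ts))))
    if kind == "arithmetic":
        return float(np.mean(ts))
    raise ValueError(f"unknown mean kind {kind!r}")


def band_histogram(
    results: Iterable[StabilityResult],
) -> dict[tuple[float, str], tuple[int, float]]:
    """Per (altitude, band): (count, ln count).  Empty cells are absent."""
    out: dict[tuple[float, str], int] = {}
    for alt, rs in _by_altitude(results).items():
        for r in rs:
            if r.ok:
                key = (alt, r.band)
                out[key] = out.get(key, 0) + 1
    return {k: (c, math.log(c)) for k, c in out.items()}


@dataclass
class DatasetSummary:
    """Per-altitude aggregates over one dataset's stability results."""

    per_altitude: pd.DataFrame  # indexed by altitude_km
    band_counts: pd.DataFrame   # altitude_km x band
    thresholds: tuple[float, ...]


def summarize(
    results: Sequence[StabilityResult],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    mean_kind: str = "geometric",
) -> DatasetSummary:
    """Dataset-level summary: counts, mean half-life, stable fractions, bands."""
    rows = []
    band_rows = []
    for alt, rs in _by_altitude(results).items():
        matched = [r for r in rs if r.ok]
        row: dict = {
            "altitude_km": alt,
            "n_matched": len(matched),
            "n_no_prediction": len(rs) - len(matched),
        }
        if matched:
            row["mean_half_life_s"] = mean_half_life(rs, alt, kind=mean_kind)
            for thr in thresholds:
                row[f"frac_ge_{thr:g}s"] = (
                    sum(1 for r in matched if r.half_life_s >= thr) / len(matched)
                )
        rows.append(row)
        counts = {label: 0 for label in BAND_LABELS}
        for r in matched:
            counts[r.band] += 1
        band_rows.append({"altitude_km": alt, **counts})
    per_altitude = pd.DataFrame(rows).set_index("altitude_km")
    band_counts = pd.DataFrame(band_rows).set_index("altitude_km")
    return DatasetSummary(
        per_altitude=per_altitude,
        band_counts=band_counts,
        thresholds=tuple(thresholds),
    )


def results_to_frame(results: Sequence[StabilityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "molecule_id": [r.molecule_id for r in results],
            "altitude_km": [r.altitude_km for r in results],
            "half_life_s": [r.half_life_s for r in results],
            "limiting_group": [r.limiting_group for r in results],
            "limiting_N": [r.limiting_n for r in results],
            "band": [r.band for r in results],
            "status": [r.status for r in results],
            "extrapolated": [r.extrapolated for r in results],
        }
    )


def save_results(results: Sequence[StabilityResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, index=False)


def load_results(path: str | Path) -> list[StabilityResult]:
    frame = pd.read_csv(path)
    out = []
    for row in frame.itertuples(index=False):
        ok = row.status == "ok"
        out.append(
            StabilityResult(
                molecule_id=str(row.molecule_id),
                altitude_km=None if pd.isna(row.altitude_km) else float(row.altitude_km),
                half_life_s=float(row.half_life_s) if ok else None,
                limiting_group=str(row.limiting_group) if ok else None,
                limiting_n=int(row.limiting_N) if ok else None,
                band=str(row.band) if ok else None,
                status=str(row.status),
                extrapolated=bool(row.extrapolated),
            )
        )
    return out
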