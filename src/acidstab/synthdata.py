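"""Seeded synthetic fixtures with exact ground truth.

Three generators make the whole pipeline testable without any external
download: rate grids with a known log-linear functional form, molecule sets
assembled from fragment templates with planted functional-group content, and
a cooling, drying model atmosphere with an optional high-altitude humidity
dip.

The synthetic rate law is ``ln k(W, T) = a + b (W - W0) + c (1/T0 - 1/T)``
with ``c > 0``, so rates always increase with temperature (acid slopes may
have either sign).  Because the law is affine in (W, 1/T) -- the same
coordinates the interpolator uses -- grid queries reproduce it exactly at
any in-grid condition, which is what makes planted half-lives recoverable
to machine precision.  This form is a test harness, not a claim about real
acid kinetics; every grid carries ``provenance="synthetic"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from acidstab.atmosphere import AtmosphereProfile, build_profile, ppH2O_forward
from acidstab.chem_io import MoleculeRecord, parse_molecule
from acidstab.kinetics import LN2, RateGrid, RateLibrary


@dataclass(frozen=True)
class GroupKinetics:
    """Synthetic rate-law parameters for one group.

    ``ref_half_life_s`` fixes the baseline: a = ln(ln 2 / ref_half_life) so a
    single-copy molecule of this group has exactly that half-life at the
    reference condition.  ``acid_slope`` is per percent (sign-free);
    ``inv_T_coeff`` (kelvin) must be positive.
    """

    ref_half_life_s: float
    acid_slope: float
    inv_T_coeff: float

    def ln_k(self, wt: float, T: float, ref_wt: float, ref_T: float) -> float:
        a = math.log(LN2 / self.ref_half_life_s)
        return a + self.acid_slope * (wt - ref_wt) + self.inv_T_coeff * (1.0 / ref_T - 1.0 / T)


#: fragment templates per group: every template contains exactly one copy of
#: exactly one registered default group (or none, for the unreactive fillers)
FRAGMENT_TEMPLATES: dict[str | None, tuple[str, ...]] = {
    "amine": ("CN", "CCN", "CCCN", "CNC", "CC(C)N", "CCCCN", "CCNC"),
    "ester": ("COC(C)=O", "CCOC(C)=O", "COC(CC)=O", "CCOC(CC)=O", "CCCOC(C)=O"),
    "alcohol": ("CO", "CCO", "CCCO", "CC(C)O", "CCCCO", "CC(C)CO"),
    None: ("C", "CC", "CCC", "CCCC", "CC(C)C", "CCCCC", "CC(C)CC"),
}


@dataclass(frozen=True)
class SynthSpec:
    """Knobs for all three generators; identical seed => identical outputs."""

    seed: int = 0
    # rate-grid plan
    ref_wt: float = 85.0
    ref_T: float = 280.0
    wt_levels: tuple[float, ...] = (60.0, 75.0, 90.0, 105.0, 120.0)
    T_levels: tuple[float, ...] = (170.0, 220.0, 270.0, 320.0, 370.0, 420.0)
    groups: Mapping[str, GroupKinetics] = field(
        default_factory=lambda: {
            # planted stable group: half-life >> 1e8 s everywhere in the cloud span
            "amine": GroupKinetics(ref_half_life_s=1e12, acid_slope=0.20, inv_T_coeff=5000.0),
            # planted fast group: seconds or less
            "ester": GroupKinetics(ref_half_life_s=1e-2, acid_slope=0.20, inv_T_coeff=5000.0),
            # planted intermediate group
            "alcohol": GroupKinetics(ref_half_life_s=1e3, acid_slope=0.20, inv_T_coeff=5000.0),
        }
    )
    # molecule plan: fractions of the whole set bearing each group; the
    # remainder (1 - sum - no_group_fraction must be 0) has no reactive group
    planted_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"amine": 0.25, "ester": 0.45, "alcohol": 0.30}
    )
    no_group_fraction: float = 0.0
    # atmosphere plan
    alt_min_km: float = 45.0
    alt_max_km: float = 70.0
    n_levels: int = 26
    T_bottom_K: float = 370.0
    lapse_K_per_km: float = 4.4
    acid_bottom_pct: float = 102.0
    acid_min_pct: float = 77.0
    acid_min_alt_km: float = 66.0
    dip: bool = True
    dip_amplitude_pct: float = 8.0

    def __post_init__(self) -> None:
        for gid, gk in self.groups.items():
            if gk.inv_T_coeff <= 0:
                raise ValueError(
                    f"group {gid!r}: inv_T_coeff must be > 0 (rates must increase with T)"
                )
        fracs = dict(self.planted_fractions)
        if any(f < 0 or f > 1 for f in fracs.values()):
            raise ValueError("planted fractions must lie in [0, 1]")
        total = sum(fracs.values()) + self.no_group_fraction
        if total > 1 + 1e-9:
            raise ValueError(f"planted fractions + no_group_fraction sum to {total} > 1")
        unknown = set(fracs) - set(self.groups)
        if unknown:
            raise ValueError(f"planted groups without kinetics: {sorted(unknown)}")


def gen_rate_grids(spec: SynthSpec) -> RateLibrary:
    """Rate library evaluating the synthetic law on the declared grid."""
    grids = []
    for gid, gk in spec.groups.items():
        lnk = np.array(
            [
                [gk.ln_k(w, t, spec.ref_wt, spec.ref_T) for t in spec.T_levels]
                for w in spec.wt_levels
            ]
        )
        grids.append(
            RateGrid(
                group_id=gid,
                wt_levels=np.array(spec.wt_levels),
                T_levels=np.array(spec.T_levels),
                ln_k=lnk,
                provenance="synthetic",
            )
        )
    return RateLibrary(grids)


def _largest_remainder(fractions: Sequence[float], n: int) -> list[int]:
    """Integer apportionment of n by fractions (sums to round(n * sum))."""
    exact = [f * n for f in fractions]
    counts = [int(math.floor(e)) for e in exact]
    short = int(round(sum(exact))) - sum(counts)
    order = sorted(range(len(exact)), key=lambda i: exact[i] - counts[i], reverse=True)
    for i in order[:short]:
        counts[i] += 1
    return counts


@dataclass
class SyntheticDataset:
    """Molecule records plus exact planted ground truth."""

    records: list[MoleculeRecord]
    planted_group: dict[str, str | None]  # molecule id -> group id (None = no group)

    def planted_counts(self) -> dict[str | None, int]:
        out: dict[str | None, int] = {}
        for g in self.planted_group.values():
            out[g] = out.get(g, 0) + 1
        return out


def gen_molecule_set(spec: SynthSpec, n: int) -> SyntheticDataset:
    """n valid molecules with exactly the planted group composition.

    Counts per category follow largest-remainder rounding of the planted
    fractions (the leftover after planted + no-group categories is assigned
    no reactive group).  Template choice is seeded and deterministic.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    categories: list[str | None] = list(spec.planted_fractions)
    fractions = [spec.planted_fractions[g] for g in categories]
    leftover = 1.0 - sum(fractions) - spec.no_group_fraction
    categories.append(None)
    fractions.append(spec.no_group_fraction + leftover)
    counts = _largest_remainder(fractions, n)
    for cat, cnt in zip(categories, counts):
        if cnt > 0 and cat not in FRAGMENT_TEMPLATES:
            raise ValueError(f"no fragment templates for group {cat!r}")
    rng = np.random.default_rng(spec.seed)
    records: list[MoleculeRecord] = []
    planted: dict[str, str | None] = {}
    idx = 0
    for cat, cnt in zip(categories, counts):
        templates = FRAGMENT_TEMPLATES.get(cat, ())
        for _ in range(cnt):
            idx += 1
            smiles = templates[int(rng.integers(len(templates)))]
            mol_id = f"syn-{idx:04d}"
            rec = parse_molecule(smiles, mol_id=mol_id)
            if not rec.ok:  # templates are hand-written; this is a bug guard
                raise RuntimeError(f"template {smiles!r} failed to parse: {rec.reason}")
            records.append(rec)
            planted[mol_id] = cat
    return SyntheticDataset(records=records, planted_group=planted)


def gen_atmosphere(spec: SynthSpec) -> AtmosphereProfile:
    """Model atmosphere: linear cooling, drying with altitude, optional top dip.

    The acid concentration declines linearly from ``acid_bottom_pct`` to
    ``acid_min_pct`` at ``acid_min_alt_km``; with ``dip`` enabled a quadratic
    bump above that altitude produces a local acid maximum at the top of the
    span (the steep top-of-cloud humidity decline).  Water partial pressure
    at each level is back-computed from the target acid concentration, so the
    equilibrium relation holds exactly and ln(ppH2O) decreases with altitude.
    """
    alts = np.linspace(spec.alt_min_km, spec.alt_max_km, spec.n_levels)
    levels = []
    for alt in alts:
        T = spec.T_bottom_K - spec.lapse_K_per_km * (alt - spec.alt_min_km)
        span = spec.acid_min_alt_km - spec.alt_min_km
        drop = spec.acid_bottom_pct - spec.acid_min_pct
        acid = spec.acid_bottom_pct - drop * min(alt - spec.alt_min_km, span) / span
        if spec.dip and alt > spec.acid_min_alt_km:
            rel = (alt - spec.acid_min_alt_km) / (spec.alt_max_km - spec.acid_min_alt_km)
            acid += spec.dip_amplitude_pct * rel**2
        pp = ppH2O_forward(acid, T)
        levels.append((float(alt), float(T), pp))
    return build_profile(levels)
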