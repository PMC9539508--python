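"""Biomass, relative growth rate, focal filtering and trait completion.

Aboveground biomass is estimated from stem diameter through power-law
allometric equations of the form ``ln B = a + b ln D`` (B in kg, D in cm),
resolved per species where an equation exists and per life-form (here: genus)
otherwise.  Relative growth rate is the log biomass accumulated per year of
planting age, ``RGR = ln(B) / t`` in kg kg^-1 yr^-1, which assumes zero mass
at planting.  Very small plants (< 0.1 kg) are unlikely to date from the
original planting and are excluded from the focal set, though they remain as
neighbors.  Species mean traits (SLA, wood density, maximum height) missing
for non-focal neighbor species are interpolated as the mean of congeneric
species found in plots within a fixed radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AllometryTable",
    "synthetic_allometry",
    "estimate_biomass",
    "invert_biomass",
    "compute_rgr",
    "filter_focals",
    "interpolate_traits",
    "TRAIT_COLUMNS",
]

TRAIT_COLUMNS = ("sla", "wood_density", "max_height")

_EARTH_RADIUS_KM = 6371.0088


class AllometryError(KeyError):
    """No allometric equation resolves for a plant."""


@dataclass
class AllometryTable:
    """A lookup of ``ln B = a + b ln D`` coefficients.

    Each row of ``table`` has columns ``key`` (species name or life-form /
    genus label), ``measure_height_cm`` (10, 50 or 130), ``a`` (log-kg
    intercept) and ``b`` (dimensionless slope, > 0).  Species-level entries
    take precedence over life-form entries.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"key", "measure_height_cm", "a", "b"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"allometry table missing columns: {sorted(missing)}")
        if (self.table["b"] <= 0).any():
            raise ValueError("allometric slope b must be positive")
        self._index = {
            (str(k), int(h)): (float(a), float(b))
            for k, h, a, b in self.table[["key", "measure_height_cm", "a", "b"]].itertuples(index=False)
        }

    @classmethod
    def from_csv(cls, path) -> "AllometryTable":
        return cls(pd.read_csv(path))

    def resolve(self, species: str, lifeform: str, measure_height_cm: int) -> tuple[float, float]:
        """Return (a, b), preferring the species entry over the life-form one."""
        h = int(measure_height_cm)
        for key in (species, lifeform):
            hit = self._index.get((str(key), h))
            if hit is not None:
                return hit
        raise AllometryError(
            f"no allometric equation for species={species!r} or lifeform={lifeform!r} "
            f"at measurement height {h} cm"
        )


def lifeform_key(genus) -> np.ndarray | str:
    """Life-form fallback label for the shipped coefficient table.

    The two focal genera have their own life-form entries; every other
    woody genus resolves to the generic ``"other"`` life form.
    """
    g = np.asarray(genus, dtype=object)
    out = np.where(np.isin(g, ("Acacia", "Eucalyptus")), g, "other")
    return out.item() if out.ndim == 0 else out


def synthetic_allometry() -> AllometryTable:
    """A small life-form level coefficient table used by the simulator and tests.

    Coefficients are in the realistic range for woody plants: biomass scales
    roughly with D^2.3-D^2.5, and a plant of 5 cm diameter at 130 cm weighs a
    few kilograms.  These are synthetic stand-ins for a published equation
    library, which is supplied by the user in real analyses.
    """
    rows = []
    for genus, a, b in [("Acacia", -2.35, 2.42), ("Eucalyptus", -2.20, 2.47), ("other", -2.50, 2.40)]:
        for h, da in [(130, 0.0), (50, -0.25), (10, -0.55)]:
            # lower measurement heights read larger diameters for the same mass
            rows.append({"key": genus, "measure_height_cm": h, "a": a + da, "b": b})
    return AllometryTable(pd.DataFrame(rows))


def estimate_biomass(diameter_cm, species, lifeform, measure_height_cm, table: AllometryTable):
    """Aboveground biomass (kg) from stem diameter (cm).

    Evaluates ``exp(a + b ln D)`` with coefficients resolved from ``table``.
    Accepts scalars or aligned array-likes; strictly increasing in diameter.
    """
    d = np.asarray(diameter_cm, dtype=float)
    if np.any(~np.isfinite(d)) or np.any(d <= 0):
        raise ValueError("diameters must be positive and finite")
    scalar = d.ndim == 0
    d = np.atleast_1d(d)
    species = np.atleast_1d(np.asarray(species, dtype=object))
    lifeform = np.atleast_1d(np.asarray(lifeform, dtype=object))
    heights = np.atleast_1d(np.asarray(measure_height_cm))
    species, lifeform, heights = (
        np.broadcast_to(x, d.shape) for x in (species, lifeform, heights)
    )
    ab = np.empty((d.size, 2))
    for i, (sp, lf, h) in enumerate(zip(species, lifeform, heights)):
        ab[i] = table.resolve(sp, lf, h)
    out = np.exp(ab[:, 0] + ab[:, 1] * np.log(d))
    return float(out[0]) if scalar else out


def invert_biomass(biomass_kg, species, lifeform, measure_height_cm, table: AllometryTable):
    """Diameter (cm) implied by a biomass under the same allometry: D = exp((ln B - a)/b)."""
    b_kg = np.asarray(biomass_kg, dtype=float)
    if np.any(b_kg <= 0):
        raise ValueError("biomass must be positive")
    scalar = b_kg.ndim == 0
    b_kg = np.atleast_1d(b_kg)
    species = np.broadcast_to(np.atleast_1d(np.asarray(species, dtype=object)), b_kg.shape)
    lifeform = np.broadcast_to(np.atleast_1d(np.asarray(lifeform, dtype=object)), b_kg.shape)
    heights = np.broadcast_to(np.atleast_1d(np.asarray(measure_height_cm)), b_kg.shape)
    out = np.empty_like(b_kg)
    for i, (bk, sp, lf, h) in enumerate(zip(b_kg, species, lifeform, heights)):
        a, slope = table.resolve(sp, lf, h)
        out[i] = np.exp((np.log(bk) - a) / slope)
    return float(out[0]) if scalar else out


def compute_rgr(biomass_kg, age_yr):
    """Relative growth rate ln(B)/t in kg kg^-1 yr^-1 (natural log, B in kg).

    Negative for sub-kilogram plants; undefined for non-positive biomass or age.
    """
    b = np.asarray(biomass_kg, dtype=float)
    t = np.asarray(age_yr, dtype=float)
    if np.any(b <= 0):
        raise ValueError("biomass must be positive")
    if np.any(t <= 0):
        raise ValueError("age must be positive")
    out = np.log(b) / t
    return float(out) if out.ndim == 0 else out


def filter_focals(plants: pd.DataFrame, min_biomass_kg: float = 0.1) -> tuple[pd.DataFrame, int]:
    """Drop focal plants with biomass strictly below ``min_biomass_kg``.

    ``plants`` must carry boolean ``is_focal`` and numeric ``biomass_kg``
    columns.  Excluded plants stay in the table (they still count as
    neighbors) but lose focal status.  Returns the updated table and the
    number of exclusions.
    """
    plants = plants.copy()
    small = plants["is_focal"] & (plants["biomass_kg"] < min_biomass_kg)
    plants.loc[small, "is_focal"] = False
    return plants, int(small.sum())


def _haversine_km(lon1, lat1, lon2, lat2):
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


@dataclass
class InterpolationReport:
    """Trait coverage before/after congener interpolation."""

    coverage_before: dict = field(default_factory=dict)
    coverage_after: dict = field(default_factory=dict)
    unresolved: pd.DataFrame | None = None  # (species, trait) pairs still missing

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"trait": t, "coverage_before": self.coverage_before[t], "coverage_after": self.coverage_after[t]}
            for t in self.coverage_before
        ]
        return pd.DataFrame(rows)


def interpolate_traits(
    traits: pd.DataFrame,
    plant_locations: pd.DataFrame,
    radius_km: float = 50.0,
) -> tuple[pd.DataFrame, InterpolationReport]:
    """Fill missing species mean traits with nearby congeners' means.

    For each species with a missing trait, the replacement is the mean of
    that trait over congeneric species (same ``genus``) that occur in any
    plot within ``radius_km`` (great-circle) of any plot holding the target
    species.  Species means are averaged, not individual measurements.

    Parameters
    ----------
    traits
        One row per species: ``species, genus, sla, wood_density, max_height``
        (NaN = missing) and optional ``<trait>_provenance`` columns.
    plant_locations
        One row per (species, plot) occurrence with ``species, lon, lat``.
    radius_km
        Congener search radius.

    Measured values are never altered; a species with no congener in radius
    keeps its NaN and is listed in the report.  Idempotent on complete tables.
    """
    out = traits.copy()
    for t in TRAIT_COLUMNS:
        col = f"{t}_provenance"
        if col not in out.columns:
            out[col] = np.where(out[t].notna(), "measured", "missing")
    occ = plant_locations.drop_duplicates(subset=["species", "lon", "lat"])
    locs = {sp: g[["lon", "lat"]].to_numpy() for sp, g in occ.groupby("species")}

    report = InterpolationReport()
    for t in TRAIT_COLUMNS:
        report.coverage_before[t] = float(out[t].notna().mean())

    unresolved = []
    filled = {}
    for idx, row in out[out[list(TRAIT_COLUMNS)].isna().any(axis=1)].iterrows():
        sp, genus = row["species"], row["genus"]
        own = locs.get(sp)
        if own is None:
            unresolved.extend({"species": sp, "trait": t} for t in TRAIT_COLUMNS if pd.isna(row[t]))
            continue
        congeners = out[(out["genus"] == genus) & (out["species"] != sp)]
        near = []
        for _, c in congeners.iterrows():
            cl = locs.get(c["species"])
            if cl is None:
                continue
            d = _haversine_km(
                own[:, 0][:, None], own[:, 1][:, None], cl[None, :, 0], cl[None, :, 1]
            )
            if d.min() <= radius_km:
                near.append(c)
        near = pd.DataFrame(near)
        for t in TRAIT_COLUMNS:
            if not pd.isna(row[t]):
                continue
            vals = near[t].dropna() if len(near) else pd.Series(dtype=float)
            # only measured congener values feed interpolation, never chained fills
            if len(near):
                vals = near.loc[near[f"{t}_provenance"] == "measured", t].dropna()
            if len(vals):
                filled[(idx, t)] = float(vals.mean())
            else:
                unresolved.append({"species": sp, "trait": t})
    for (idx, t), v in filled.items():
        out.loc[idx, t] = v
        out.loc[idx, f"{t}_provenance"] = "interpolated"

    for t in TRAIT_COLUMNS:
        report.coverage_after[t] = float(out[t].notna().mean())
    report.unresolved = pd.DataFrame(unresolved, columns=["species", "trait"])
    return out, report
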