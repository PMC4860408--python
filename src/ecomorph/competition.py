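"""Assemblage competition scoring for co-occurring canid species.

For a focal specimen the three indices count, among the canid species
recorded at its locality (the focal excluded), the fraction sharing its
diet category, the fraction sharing its habitat category, and the fraction
whose body-size difference falls inside the interspecific-killing window.
BSD = (Mb_l − Mb_s)/Mb_l with Mb_l the larger mass; the killing criterion
tests whether arcsin(√BSD), expressed in a configurable angle unit, lies
strictly inside a configurable window (default: degrees divided by ten,
window 2–5.4, i.e. 20°–54°).  The unit of the published window is
ambiguous, so both the unit and the window are explicit parameters; a
``"ratio"`` unit bypasses the transform and tests the raw mass ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

DEFAULT_WINDOW = (2.0, 5.4)
DEFAULT_ANGLE_UNIT = "deg10"
ANGLE_UNITS = ("deg10", "deg", "rad", "ratio")

DIET_CATEGORIES = ("omnivore", "hypercarnivore", "insectivore")
HABITAT_CATEGORIES = ("open", "forest")


@dataclass(frozen=True)
class CompetitionProfile:
    """Per-focal-specimen overlap fractions, each in [0, 1]."""

    diet_overlap: float
    habitat_overlap: float
    killing: float

    def as_array(self) -> np.ndarray:
        return np.array([self.diet_overlap, self.habitat_overlap, self.killing])


def load_traits(path=None) -> pd.DataFrame:
    """Species trait table (species, mass_kg, diet, habitat).

    Without a path, the shipped default table for the eight South-American
    canids is loaded.  Masses are single representative literature values
    (kg); diet and habitat use a small controlled vocabulary.
    """
    if path is None:
        ref = resources.files("ecomorph.data").joinpath("canid_traits_default.csv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = {"species", "mass_kg", "diet", "habitat"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"traits table missing columns: {sorted(missing)}")
    if (df["mass_kg"] <= 0).any():
        raise ValueError("non-positive body mass in traits table")
    return df.set_index("species", drop=False)


def bsd(mass_a: float, mass_b: float) -> float:
    """Body size difference (Mb_l − Mb_s)/Mb_l; symmetric in its inputs."""
    if mass_a <= 0 or mass_b <= 0:
        raise ValueError("body masses must be positive")
    large, small = max(mass_a, mass_b), min(mass_a, mass_b)
    return (large - small) / large


def killing_potential(
    mass_a: float,
    mass_b: float,
    window: tuple[float, float] = DEFAULT_WINDOW,
    angle_unit: str = DEFAULT_ANGLE_UNIT,
) -> bool:
    """Is this species pair inside the interspecific-killing window?

    θ = arcsin(√BSD) in the configured unit; the window is open at both
    ends (θ exactly on a bound does not qualify).  Unit ``"ratio"``
    compares the raw larger/smaller mass ratio against the window instead.
    """
    low, high = window
    if not low < high:
        raise ValueError("window must satisfy low < high")
    if angle_unit not in ANGLE_UNITS:
        raise ValueError(f"angle_unit must be one of {ANGLE_UNITS}")
    if angle_unit == "ratio":
        theta = max(mass_a, mass_b) / min(mass_a, mass_b)
        if min(mass_a, mass_b) <= 0:
            raise ValueError("body masses must be positive")
    else:
        theta = math.asin(math.sqrt(bsd(mass_a, mass_b)))
        if angle_unit in ("deg", "deg10"):
            theta = math.degrees(theta)
        if angle_unit == "deg10":
            theta /= 10.0
    return low < theta < high


def competition_profile(
    focal: str,
    present,
    traits: pd.DataFrame | None = None,
    window: tuple[float, float] = DEFAULT_WINDOW,
    angle_unit: str = DEFAULT_ANGLE_UNIT,
) -> CompetitionProfile:
    """Diet / habitat / killing overlap fractions for one focal species.

    Each component is the count of qualifying co-occurring species divided
    by the number of co-occurring species at the locality (the focal is
    excluded automatically; duplicates collapse — set semantics).  An
    empty assemblage yields all zeros.
    """
    if traits is None:
        traits = load_traits()
    known = set(traits.index)
    if focal not in known:
        raise KeyError(f"unknown focal species {focal!r}")
    others = sorted({s for s in present if s != focal})
    for s in others:
        if s not in known:
            raise KeyError(f"unknown species in presence list: {s!r}")
    if not others:
        return CompetitionProfile(0.0, 0.0, 0.0)
    frow = traits.loc[focal]
    n = len(others)
    diet = sum(traits.loc[s, "diet"] == frow["diet"] for s in others) / n
    habitat = sum(traits.loc[s, "habitat"] == frow["habitat"] for s in others) / n
    kill = (
        sum(
            killing_potential(
                frow["mass_kg"], traits.loc[s, "mass_kg"], window, angle_unit
            )
            for s in others
        )
        / n
    )
    return CompetitionProfile(float(diet), float(habitat), float(kill))


def competition_block(
    species,
    locality_ids,
    presence: dict[str, set] | pd.DataFrame,
    traits: pd.DataFrame | None = None,
    window: tuple[float, float] = DEFAULT_WINDOW,
    angle_unit: str = DEFAULT_ANGLE_UNIT,
) -> pd.DataFrame:
    """Per-record competition block, row-aligned with a shape sample.

    ``presence`` maps locality id → set of species recorded there (or is a
    long-format DataFrame with ``locality_id`` and ``species`` columns).
    Rows keep the order of the inputs so the block can be fed directly to
    PLS or variation partitioning.
    """
    if traits is None:
        traits = load_traits()
    if isinstance(presence, pd.DataFrame):
        presence = {
            loc: set(grp["species"]) for loc, grp in presence.groupby("locality_id")
        }
    rows = []
    for sp, loc in zip(species, locality_ids):
        if loc not in presence:
            raise KeyError(f"locality {loc!r} has no species presence list")
        prof = competition_profile(
            sp, presence[loc], traits=traits, window=window, angle_unit=angle_unit
        )
        rows.append(prof.as_array())
    return pd.DataFrame(
        np.array(rows).reshape(-1, 3),
        columns=["diet_overlap", "habitat_overlap", "killing"],
    )
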