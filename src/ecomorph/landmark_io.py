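"""Reading, writing and aggregation of 2-D landmark data.

Landmark configurations travel in TPS files (the tpsDig convention:
``LM=<k>`` followed by ``k`` whitespace-separated ``x y`` lines, then
optional ``ID=``, ``SCALE=`` and ``IMAGE=`` lines).  Specimen metadata
(species, sex, locality, coordinates) lives in a sidecar CSV joined on
specimen id.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_SEX = ("F", "M", "unknown")

METADATA_COLUMNS = [
    "specimen_id",
    "species",
    "sex",
    "locality_id",
    "latitude",
    "longitude",
]


class TPSFormatError(ValueError):
    """Raised for malformed TPS records (bad LM counts, non-numeric points)."""


@dataclass
class LandmarkConfiguration:
    """One specimen: labelled 2-D landmarks plus collection metadata.

    ``coords`` are in millimetres once ``scale`` (mm per pixel) has been
    applied by the reader; a missing scale means the file already stores mm.
    """

    specimen_id: str
    coords: np.ndarray  # (k, 2) float
    species: str = ""
    sex: str = "unknown"
    locality_id: str = ""
    latitude: float = np.nan
    longitude: float = np.nan
    scale: float | None = None
    image: str | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError(
                f"coords for {self.specimen_id!r} must be (k, 2), "
                f"got {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates in {self.specimen_id!r}")
        if self.scale is not None and not self.scale > 0:
            raise ValueError(f"scale must be > 0, got {self.scale}")
        if self.sex not in VALID_SEX:
            raise ValueError(f"sex must be one of {VALID_SEX}, got {self.sex!r}")

    @property
    def k(self) -> int:
        return self.coords.shape[0]


@dataclass
class SpecimenTable:
    """A homogeneous collection of landmark configurations (shared k)."""

    configurations: list[LandmarkConfiguration] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.specimen_id for c in self.configurations]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate specimen ids: {dupes}")
        ks = {c.k for c in self.configurations}
        if len(ks) > 1:
            raise ValueError(f"inconsistent landmark counts: {sorted(ks)}")
        unlabelled = sum(1 for c in self.configurations if not c.species)
        if unlabelled:
            warnings.warn(
                f"{unlabelled} specimen(s) have no species label "
                "(join a metadata table before analysis)",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.configurations)

    def __iter__(self):
        return iter(self.configurations)

    @property
    def landmark_count(self) -> int:
        if not self.configurations:
            raise ValueError("empty specimen table")
        return self.configurations[0].k

    def coords_array(self) -> np.ndarray:
        """Stacked (n, k, 2) coordinate array in specimen order."""
        return np.stack([c.coords for c in self.configurations])

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "specimen_id": [c.specimen_id for c in self.configurations],
                "species": [c.species for c in self.configurations],
                "sex": [c.sex for c in self.configurations],
                "locality_id": [c.locality_id for c in self.configurations],
                "latitude": [c.latitude for c in self.configurations],
                "longitude": [c.longitude for c in self.configurations],
            }
        )


def _parse_tps_records(text: str, source: str) -> list[dict]:
    records: list[dict] = []
    current: dict | None = None
    points_left = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("LM="):
            if current is not None:
                records.append(current)
            try:
                k = int(line.split("=", 1)[1])
            except ValueError as exc:
                raise TPSFormatError(
                    f"{source}:{lineno}: bad LM count {line!r}"
                ) from exc
            current = {"k": k, "points": [], "id": None, "scale": None, "image": None}
            points_left = k
        elif current is None:
            raise TPSFormatError(f"{source}:{lineno}: data before first LM= line")
        elif upper.startswith("ID="):
            current["id"] = line.split("=", 1)[1].strip()
        elif upper.startswith("SCALE="):
            try:
                current["scale"] = float(line.split("=", 1)[1])
            except ValueError as exc:
                raise TPSFormatError(
                    f"{source}:{lineno}: non-numeric SCALE {line!r}"
                ) from exc
        elif upper.startswith("IMAGE="):
            current["image"] = line.split("=", 1)[1].strip()
        elif "=" in line and not line[0].isdigit() and line[0] not in "+-.":
            # unknown KEY=value lines are tolerated and ignored
            continue
        else:
            if points_left <= 0:
                raise TPSFormatError(
                    f"{source}:{lineno}: extra coordinate line {line!r}"
                )
            parts = line.split()
            if len(parts) != 2:
                raise TPSFormatError(
                    f"{source}:{lineno}: expected 'x y', got {line!r}"
                )
            try:
                current["points"].append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise TPSFormatError(
                    f"{source}:{lineno}: non-numeric coordinate {line!r}"
                ) from exc
            points_left -= 1
    if current is not None:
        records.append(current)
    return records


def read_tps(path, metadata=None) -> SpecimenTable:
    """Read a TPS file (optionally joining a metadata CSV) into a table.

    Coordinates are multiplied by ``SCALE=`` when present, so the returned
    configurations are in physical units.  All records must share a single
    landmark count; a record that disagrees raises :class:`TPSFormatError`
    naming it.  Metadata rows whose ``specimen_id`` matches no TPS record
    are reported with a warning.
    """
    path = Path(path)
    records = _parse_tps_records(path.read_text(), str(path))
    if not records:
        raise TPSFormatError(f"{path}: no TPS records found")
    k0 = records[0]["k"]
    meta_df = None
    if metadata is not None:
        meta_df = pd.read_csv(metadata, dtype={"specimen_id": str})
        missing = set(METADATA_COLUMNS) - set(meta_df.columns)
        if missing:
            raise ValueError(f"metadata CSV missing columns: {sorted(missing)}")
        meta_df = meta_df.set_index("specimen_id")

    configs: list[LandmarkConfiguration] = []
    matched_ids: set[str] = set()
    for i, rec in enumerate(records):
        rec_id = rec["id"] if rec["id"] is not None else f"record_{i + 1}"
        if rec["k"] != k0:
            raise TPSFormatError(
                f"{path}: record {rec_id!r} has LM={rec['k']}, expected {k0}"
            )
        if len(rec["points"]) != rec["k"]:
            raise TPSFormatError(
                f"{path}: record {rec_id!r} has {len(rec['points'])} points, "
                f"LM={rec['k']}"
            )
        coords = np.asarray(rec["points"], dtype=float)
        if rec["scale"] is not None:
            coords = coords * rec["scale"]
        kwargs: dict = {}
        if meta_df is not None and rec_id in meta_df.index:
            row = meta_df.loc[rec_id]
            sex = row["sex"]
            kwargs = {
                "species": str(row["species"]),
                "sex": sex if sex in VALID_SEX else "unknown",
                "locality_id": str(row["locality_id"]),
                "latitude": float(row["latitude"]),
                "longitude": float(row["longitude"]),
            }
            matched_ids.add(rec_id)
        configs.append(
            LandmarkConfiguration(
                specimen_id=rec_id,
                coords=coords,
                scale=rec["scale"],
                image=rec["image"],
                **kwargs,
            )
        )
    if meta_df is not None:
        unmatched = sorted(set(meta_df.index) - matched_ids)
        if unmatched:
            warnings.warn(
                f"{len(unmatched)} metadata rows matched no TPS record: "
                f"{unmatched[:5]}{'...' if len(unmatched) > 5 else ''}",
                stacklevel=2,
            )
    return SpecimenTable(configs)


def write_tps(table: SpecimenTable, path, precision: int = 10) -> None:
    """Write a specimen table as a TPS file (coordinates already in mm).

    Scale factors are not re-applied on write: coordinates are emitted as
    stored, so a write/read round trip is the identity.
    """
    buf = io.StringIO()
    for c in table:
        buf.write(f"LM={c.k}\n")
        for x, y in c.coords:
            buf.write(f"{x:.{precision}g} {y:.{precision}g}\n")
        if c.image is not None:
            buf.write(f"IMAGE={c.image}\n")
        buf.write(f"ID={c.specimen_id}\n")
    Path(path).write_text(buf.getvalue())


def write_metadata(table: SpecimenTable, path) -> None:
    table.metadata_frame().to_csv(path, index=False)


def aggregate_means(sample, keys: Sequence[str]):
    """Average a GPA-aligned sample over unique key combinations.

    Shape averaging is the arithmetic mean of the aligned coordinates;
    size averaging is the arithmetic mean of lnCS (so the group "size" is
    the geometric-mean centroid size).  Records with ``sex == "unknown"``
    are dropped when ``sex`` is among the grouping keys and retained
    otherwise — locality-level analyses keep every specimen while
    sex-factor models only see sexed ones.
    """
    from .procrustes import ShapeSample  # deferred: avoid import cycle

    keys = list(keys)
    allowed = {"locality_id", "sex", "species"}
    bad = set(keys) - allowed
    if bad:
        raise ValueError(f"grouping keys must be within {allowed}, got {bad}")
    if not keys:
        raise ValueError("at least one grouping key required")
    if len(sample) == 0:
        raise ValueError("empty sample")

    meta = sample.metadata.reset_index(drop=True)
    mask = np.ones(len(meta), dtype=bool)
    if "sex" in keys:
        mask = (meta["sex"] != "unknown").to_numpy()
        if not mask.any():
            raise ValueError("no sexed specimens to aggregate over")
    idx = np.flatnonzero(mask)
    sub = meta.loc[idx]

    grouped = sub.groupby(keys, sort=True, dropna=False)
    aligned_rows = []
    lncs_rows = []
    meta_rows = []
    for key_vals, grp in grouped:
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        rows = grp.index.to_numpy()
        aligned_rows.append(sample.aligned[rows].mean(axis=0))
        lncs_rows.append(sample.lnCS[rows].mean())
        rec = {
            "specimen_id": "|".join(str(v) for v in key_vals),
            "species": grp["species"].iloc[0] if "species" in keys else (
                grp["species"].iloc[0] if grp["species"].nunique() == 1 else "mixed"
            ),
            "sex": key_vals[keys.index("sex")] if "sex" in keys else "unknown",
            "locality_id": key_vals[keys.index("locality_id")]
            if "locality_id" in keys
            else "",
            "latitude": grp["latitude"].mean(),
            "longitude": grp["longitude"].mean(),
            "group_size": len(rows),
        }
        for key, val in zip(keys, key_vals):
            rec[key] = val
        meta_rows.append(rec)

    aligned = np.stack(aligned_rows)
    lncs = np.asarray(lncs_rows)
    return ShapeSample(
        aligned=aligned,
        centroid_sizes=np.exp(lncs),
        mean_shape=sample.mean_shape.copy(),
        metadata=pd.DataFrame(meta_rows),
        converged=sample.converged,
    )
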