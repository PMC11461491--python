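"""41-zone corneal epithelial-thickness map topology and I/O.

The anterior-segment OCT epithelial thickness (ET) map covers a 7-mm
diameter disc summarised as 41 zonal mean thicknesses: one central disc
surrounded by five concentric annuli, each split into eight octant
sectors.  Sectors are named by anatomical direction in right-eye (OD)
convention: S superior, N nasal, I inferior, T temporal, plus the four
oblique octants SN, NI, TI (inferior-temporal) and TS.  Left-eye (OS)
maps are mirrored across the vertical meridian so that "temporal" refers
to the same anatomical direction in both eyes.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "SECTORS",
    "ZoneId",
    "ZoneGrid",
    "ETMap",
    "EyeRecord",
    "Cohort",
    "build_zone_grid",
    "canonicalize",
    "read_cohort_csv",
    "write_cohort_csv",
]

#: Octant labels in angular order, clockwise from superior (OD convention).
SECTORS: tuple[str, ...] = ("S", "SN", "N", "NI", "I", "TI", "T", "TS")

#: Mirror across the vertical (superior-inferior) meridian: nasal <-> temporal.
MIRROR_SECTOR: dict[str, str] = {
    "S": "S", "I": "I", "N": "T", "T": "N", "SN": "TS", "TS": "SN", "NI": "TI", "TI": "NI",
}

#: Plausible zonal mean ET range (µm); values outside trigger a warning only.
ET_PLAUSIBLE_RANGE = (20.0, 120.0)

N_ZONES = 41
N_RINGS = 6  # ring 0 = central disc, rings 1..5 = annuli


@dataclass(frozen=True, order=True)
class ZoneId:
    """One zone of the 41-zone map: a ring index and an octant sector.

    Ring 0 is the central disc and carries no sector.  Ring 1 is the
    paracentral ring whose zones are aliased with a leading ``c`` (so the
    paracentral inferior and inferior-temporal zones are ``cI`` and
    ``cTI``); rings 2-5 are aliased ``r2S`` ... ``r5TS``.
    """

    ring: int
    sector: str | None = None

    def __post_init__(self) -> None:
        if self.ring == 0:
            if self.sector is not None:
                raise ValueError("central zone (ring 0) has no sector")
        elif not (1 <= self.ring <= 5):
            raise ValueError(f"ring must be in 0..5, got {self.ring}")
        elif self.sector not in SECTORS:
            raise ValueError(f"unknown sector {self.sector!r}")

    @property
    def alias(self) -> str:
        if self.ring == 0:
            return "C"
        if self.ring == 1:
            return f"c{self.sector}"
        return f"r{self.ring}{self.sector}"

    def mirrored(self) -> "ZoneId":
        """The zone this one maps to under nasal/temporal mirroring."""
        if self.ring == 0:
            return self
        return ZoneId(self.ring, MIRROR_SECTOR[self.sector])

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.alias


def _zone_from_alias(alias: str) -> ZoneId:
    if alias == "C":
        return ZoneId(0)
    if alias.startswith("c"):
        return ZoneId(1, alias[1:])
    if alias.startswith("r") and len(alias) >= 3:
        return ZoneId(int(alias[1]), alias[2:])
    raise ValueError(f"unknown zone alias {alias!r}")


class ZoneGrid:
    """The 41-zone map topology: zone order, adjacency and geometry.

    Adjacency follows edge-sharing: two zones are neighbours iff they
    share a boundary arc (adjacent rings, same sector; the central disc
    borders all eight paracentral sectors) or a radial segment (same
    ring, angularly adjacent sectors).  Corner contact between
    diagonally-offset zones does not count unless ``adjacency_mode`` is
    ``"edge+corner"``.

    Parameters
    ----------
    adjacency_mode : {"edge", "edge+corner"}
        Neighbourhood rule; ``"edge"`` is the default reading of
        "neighbouring zones".
    ring_radii : sequence of 6 floats, optional
        Outer radii (mm) of the central disc and the five annuli.
        Affects rendering and simulated gradients only, never the
        difference statistics.
    """

    def __init__(
        self,
        adjacency_mode: str = "edge",
        ring_radii: Iterable[float] | None = None,
    ) -> None:
        if adjacency_mode not in ("edge", "edge+corner"):
            raise ValueError(f"unknown adjacency mode {adjacency_mode!r}")
        self.adjacency_mode = adjacency_mode
        if ring_radii is None:
            # central disc of 0.7 mm then 5 equal annuli out to 3.5 mm
            ring_radii = [0.7 + 2.8 * k / 5 for k in range(6)]
        self.ring_radii = tuple(float(r) for r in ring_radii)
        if len(self.ring_radii) != N_RINGS or any(
            b <= a for a, b in zip(self.ring_radii, self.ring_radii[1:])
        ):
            raise ValueError("ring_radii must be 6 strictly increasing radii")
        self.outer_diameter = 2.0 * self.ring_radii[-1]

        zones: list[ZoneId] = [ZoneId(0)]
        for ring in range(1, 6):
            zones.extend(ZoneId(ring, s) for s in SECTORS)
        self.zones: tuple[ZoneId, ...] = tuple(zones)
        self.aliases: tuple[str, ...] = tuple(z.alias for z in self.zones)
        self._index = {z: i for i, z in enumerate(self.zones)}
        self._index.update({z.alias: i for i, z in enumerate(self.zones)})

        self.adjacency: dict[ZoneId, frozenset[ZoneId]] = self._build_adjacency()
        A = np.zeros((N_ZONES, N_ZONES), dtype=bool)
        for z, nbrs in self.adjacency.items():
            for nb in nbrs:
                A[self._index[z], self._index[nb]] = True
        self.adjacency_matrix = A
        self.degrees = A.sum(axis=1)

    def _build_adjacency(self) -> dict[ZoneId, frozenset[ZoneId]]:
        adj: dict[ZoneId, set[ZoneId]] = {z: set() for z in self.zones}

        def link(a: ZoneId, b: ZoneId) -> None:
            adj[a].add(b)
            adj[b].add(a)

        center = ZoneId(0)
        for s in SECTORS:
            link(center, ZoneId(1, s))
        for ring in range(1, 6):
            for i, s in enumerate(SECTORS):
                z = ZoneId(ring, s)
                link(z, ZoneId(ring, SECTORS[(i + 1) % 8]))  # angular neighbour
                if ring < 5:
                    link(z, ZoneId(ring + 1, s))  # radial neighbour
                    if self.adjacency_mode == "edge+corner":
                        link(z, ZoneId(ring + 1, SECTORS[(i + 1) % 8]))
                        link(z, ZoneId(ring + 1, SECTORS[(i - 1) % 8]))
        return {z: frozenset(n) for z, n in adj.items()}

    # -- lookups ---------------------------------------------------------
    def index(self, zone: ZoneId | str) -> int:
        return self._index[zone]

    def zone(self, alias: str) -> ZoneId:
        return self.zones[self._index[alias]]

    def neighbors(self, zone: ZoneId | str) -> frozenset[ZoneId]:
        return self.adjacency[self.zones[self._index[zone]]]

    def sector_aliases(self, sector: str) -> list[str]:
        """Aliases of the five annular zones in one octant (rings 1-5)."""
        return [z.alias for z in self.zones if z.sector == sector]

    # -- geometry (rendering / simulation only) --------------------------
    def zone_centers(self) -> pd.DataFrame:
        """Polar and Cartesian zone centres (mm), +x temporal, +y superior."""
        # +x temporal, +y superior (right-eye convention): S at 90°,
        # N at 180°, I at 270°, T at 0°
        sector_angle = {s: math.radians(90.0 + 45.0 * i) for i, s in enumerate(SECTORS)}
        rows = []
        for z in self.zones:
            if z.ring == 0:
                r, theta = 0.0, 0.0
            else:
                inner = self.ring_radii[z.ring - 1]
                outer = self.ring_radii[z.ring]
                r = 0.5 * (inner + outer)
                theta = sector_angle[z.sector]
            rows.append((z.alias, r, theta, r * math.cos(theta), r * math.sin(theta)))
        return pd.DataFrame(
            rows, columns=["alias", "radius", "angle", "x", "y"]
        ).set_index("alias")

    def to_json(self) -> str:
        """Grid export (zones + adjacency lists) for documentation."""
        payload = {
            "outer_diameter_mm": self.outer_diameter,
            "ring_radii_mm": list(self.ring_radii),
            "adjacency_mode": self.adjacency_mode,
            "zones": [
                {
                    "alias": z.alias,
                    "ring": z.ring,
                    "sector": z.sector,
                    "neighbors": sorted(n.alias for n in self.adjacency[z]),
                }
                for z in self.zones
            ],
        }
        return json.dumps(payload, indent=2)

    def __len__(self) -> int:
        return N_ZONES

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ZoneGrid)
            and self.adjacency_mode == other.adjacency_mode
            and self.ring_radii == other.ring_radii
        )


def build_zone_grid(
    adjacency_mode: str = "edge", ring_radii: Iterable[float] | None = None
) -> ZoneGrid:
    """Construct the canonical 41-zone, 7-mm grid (deterministic)."""
    return ZoneGrid(adjacency_mode=adjacency_mode, ring_radii=ring_radii)


@dataclass
class ETMap:
    """One epithelial-thickness measurement of one eye.

    ``values`` holds the 41 zonal mean thicknesses in µm, indexed by zone
    alias in grid order.  ``canonical`` is True once the map has been
    laterality-normalised to the right-eye convention.
    """

    subject_id: str
    eye: str
    values: pd.Series
    measurement_index: int = 1
    canonical: bool = False

    def __post_init__(self) -> None:
        if self.eye not in ("OD", "OS"):
            raise ValueError(f"laterality must be OD or OS, got {self.eye!r}")
        if self.measurement_index < 1:
            raise ValueError("measurement_index must be >= 1")
        vals = pd.Series(self.values, dtype=float)
        if len(vals) != N_ZONES:
            raise ValueError(f"expected {N_ZONES} zonal values, got {len(vals)}")
        if not np.isfinite(vals.to_numpy()).all():
            raise ValueError("zonal ET values must be finite")
        if (vals <= 0).any():
            raise ValueError("zonal ET values must be strictly positive")
        lo, hi = ET_PLAUSIBLE_RANGE
        if ((vals < lo) | (vals > hi)).any():
            warnings.warn(
                f"zonal ET values outside plausible range [{lo}, {hi}] µm",
                stacklevel=2,
            )
        self.values = vals

    def __getitem__(self, alias: str) -> float:
        return float(self.values[alias])

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy()


def canonicalize(etmap: ETMap, grid: ZoneGrid) -> ETMap:
    """Normalise an ET map to right-eye (OD) anatomical orientation.

    OD maps are returned value-identical with ``canonical=True``; OS maps
    are mirrored across the vertical meridian (N<->T, SN<->TS, NI<->TI)
    so that sector labels refer to the same anatomical directions in both
    eyes.  Mirroring is an involution on the underlying geometry.
    """
    if etmap.canonical:
        warnings.warn("map is already canonical; returning unchanged", stacklevel=2)
        return etmap
    if etmap.eye == "OD":
        return replace(etmap, values=etmap.values.copy(), canonical=True)
    mirrored = pd.Series(
        {z.alias: etmap.values[z.mirrored().alias] for z in grid.zones},
        dtype=float,
    ).reindex(list(grid.aliases))
    return replace(etmap, values=mirrored, canonical=True)


@dataclass
class EyeRecord:
    """An eye with its group label, repeated measurements and tomography.

    Group labels are exogenous, assigned upstream from Scheimpflug
    tomography: ``KC_significant`` (BAD-D >= 2.69), ``KC_fellow_normal``
    (tomographically normal fellow eye of a keratoconus patient, BAD-D
    < 1.65 and Belin ABCD stage 0), or ``healthy``.
    """

    subject_id: str
    eye: str
    group: str
    measurements: list[ETMap] = field(default_factory=list)
    bad_d: float | None = None
    abcd: tuple[float, float, float] | None = None

    GROUPS = ("KC_significant", "KC_fellow_normal", "healthy")

    def __post_init__(self) -> None:
        if self.group not in self.GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        for m in self.measurements:
            if (m.subject_id, m.eye) != (self.subject_id, self.eye):
                raise ValueError("measurement subject/eye mismatch")

    @property
    def n_repeats(self) -> int:
        return len(self.measurements)

    def is_keratoconus(self) -> bool:
        return self.group != "healthy"


class Cohort:
    """An ordered collection of eyes (``EyeRecord``) under one grid."""

    def __init__(self, eyes: Iterable[EyeRecord], grid: ZoneGrid | None = None):
        self.eyes: list[EyeRecord] = list(eyes)
        self.grid = grid if grid is not None else build_zone_grid()
        keys = [(e.subject_id, e.eye) for e in self.eyes]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (subject_id, eye) records in cohort")

    def __len__(self) -> int:
        return len(self.eyes)

    def __iter__(self):
        return iter(self.eyes)

    def groups(self) -> list[str]:
        return sorted({e.group for e in self.eyes})

    def subset(self, groups: Iterable[str]) -> "Cohort":
        groups = set(groups)
        return Cohort([e for e in self.eyes if e.group in groups], self.grid)

    def canonicalized(self) -> "Cohort":
        """Cohort with every measurement laterality-normalised."""
        eyes = []
        for e in self.eyes:
            ms = [
                m if m.canonical else canonicalize(m, self.grid)
                for m in e.measurements
            ]
            eyes.append(replace(e, measurements=ms))
        return Cohort(eyes, self.grid)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.eyes:
            for m in e.measurements:
                row: dict[str, object] = {
                    "subject_id": e.subject_id,
                    "eye": e.eye,
                    "group": e.group,
                    "measurement_index": m.measurement_index,
                    "canonical": int(m.canonical),
                }
                if e.bad_d is not None:
                    row["bad_d"] = e.bad_d
                if e.abcd is not None:
                    row["abcd_a"], row["abcd_b"], row["abcd_c"] = e.abcd
                row.update(m.values.to_dict())
                rows.append(row)
        return pd.DataFrame(rows)


_META_COLS = ("subject_id", "eye", "group", "measurement_index")
_OPTIONAL_COLS = ("bad_d", "abcd_a", "abcd_b", "abcd_c", "canonical")


def write_cohort_csv(cohort: Cohort, path) -> None:
    """Write a cohort in the zone-column CSV dialect (UTF-8, ``.`` decimal)."""
    frame = cohort.to_frame()
    zone_cols = [a for a in cohort.grid.aliases]
    meta = [c for c in (*_META_COLS, *_OPTIONAL_COLS) if c in frame.columns]
    # %.17g round-trips IEEE doubles exactly
    frame[meta + zone_cols].to_csv(path, index=False, float_format="%.17g")


def read_cohort_csv(path, grid: ZoneGrid | None = None) -> Cohort:
    """Read a cohort CSV: one row per measurement, one column per zone.

    Required columns: subject_id, eye, group, measurement_index and the
    41 zone aliases.  Optional: bad_d, abcd_a/b/c, canonical.  Unknown or
    missing zone columns, malformed laterality, non-numeric zonal values
    and duplicate (subject, eye, measurement_index) rows are rejected.
    """
    grid = grid if grid is not None else build_zone_grid()
    frame = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    missing_meta = [c for c in _META_COLS if c not in frame.columns]
    if missing_meta:
        raise ValueError(f"missing required columns: {missing_meta}")
    known = set(_META_COLS) | set(_OPTIONAL_COLS) | set(grid.aliases)
    unknown = [c for c in frame.columns if c not in known]
    if unknown:
        raise ValueError(f"unknown columns: {unknown}")
    missing_zones = [a for a in grid.aliases if a not in frame.columns]
    if missing_zones:
        raise ValueError(f"missing zone columns: {missing_zones}")
    bad_eye = sorted(set(frame["eye"]) - {"OD", "OS"})
    if bad_eye:
        raise ValueError(f"malformed laterality value(s): {bad_eye}")
    dup = frame.duplicated(subset=["subject_id", "eye", "measurement_index"])
    if dup.any():
        dups = frame.loc[dup, ["subject_id", "eye", "measurement_index"]]
        raise ValueError(
            f"duplicate (subject, eye, measurement_index) rows:\n{dups}"
        )
    zone_block = frame[list(grid.aliases)]
    try:
        zone_block = zone_block.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric zonal ET value: {exc}") from exc

    eyes: list[EyeRecord] = []
    for (subject, eye), rows in frame.groupby(["subject_id", "eye"], sort=False):
        groups = rows["group"].unique()
        if len(groups) != 1:
            raise ValueError(f"inconsistent group labels for {subject}/{eye}")
        measurements = []
        for _, row in rows.sort_values("measurement_index").iterrows():
            measurements.append(
                ETMap(
                    subject_id=str(subject),
                    eye=str(eye),
                    measurement_index=int(row["measurement_index"]),
                    values=zone_block.loc[row.name].reindex(list(grid.aliases)),
                    canonical=bool(row.get("canonical", 0)),
                )
            )
        bad_d = rows.iloc[0].get("bad_d")
        abcd_vals = [rows.iloc[0].get(c) for c in ("abcd_a", "abcd_b", "abcd_c")]
        eyes.append(
            EyeRecord(
                subject_id=str(subject),
                eye=str(eye),
                group=str(groups[0]),
                measurements=measurements,
                bad_d=None if bad_d is None or pd.isna(bad_d) else float(bad_d),
                abcd=(
                    None
                    if any(v is None or pd.isna(v) for v in abcd_vals)
                    else tuple(float(v) for v in abcd_vals)
                ),
            )
        )
    return Cohort(eyes, grid)
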