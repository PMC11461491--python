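"""Synthetic zonal epithelial-thickness cohorts.

Emulates the statistical structure the screening analysis assumes so
that both study stages can be exercised end-to-end without patient
data:

* healthy maps — a smooth surface around a ~53 µm baseline, thinner
  superiorly and temporally (by 5.9 µm and 1.3 µm at a 3-mm radius,
  the normal eyelid-related gradient), plus a per-eye level offset and
  independent zonal measurement noise (SD 0.6 µm by default);
* keratoconic maps — the healthy surface plus a severity-scaled
  localized depression (the cone, a raised-cosine kernel centred
  between the paracentral inferior and inferior-temporal zones by
  default) surrounded by a severity-scaled annular thickening;
* cohorts — eyes grouped as tomographically significant keratoconus,
  tomographically normal fellow eyes, and healthy controls, with
  repeated measurements per eye and BAD-D / Belin ABCD indices coupled
  to severity and truncated to the group-defining ranges.

Severity is expressed in µm of epithelial thinning at the cone apex;
severity 0 reproduces the healthy model exactly.  Zonal noise is drawn
independently per zone; spatial noise correlation of real maps is not
modelled.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .zonemap import Cohort, ETMap, EyeRecord, ZoneGrid, build_zone_grid

__all__ = [
    "GeneratorConfig",
    "synth_healthy_map",
    "synth_keratoconus_map",
    "simulate_cohort",
    "development_config",
    "validation_config",
]


class GeneratorConfig(BaseModel):
    """Configuration of the synthetic zonal-ET cohort generator.

    All thickness quantities are in µm and all lengths in mm.  The
    defaults encode the study conditions: 21 eyes per group with three
    repeated measurements (the validation design), a 0.6 µm zonal
    measurement noise, the healthy superior/temporal thinning gradient
    referenced at a 3-mm radius, and group severity distributions that
    are strictly ordered (healthy = 0 < fellow < significant).
    """

    # cohort composition
    n_significant: int = Field(21, ge=0)
    n_fellow: int = Field(21, ge=0)
    n_healthy: int = Field(21, ge=0)
    repeats: int = Field(3, ge=1)

    # healthy surface
    baseline_et: float = Field(53.0, gt=0, description="central ET level")
    superior_thinning: float = Field(
        5.9, ge=0, description="S-minus-I thinning magnitude at the reference radius"
    )
    temporal_thinning: float = Field(
        1.3, ge=0, description="T-minus-N thinning magnitude at the reference radius"
    )
    gradient_reference_radius: float = Field(3.0, gt=0)
    gradient_inner_radius: float = Field(
        1.26,
        ge=0,
        description="radius where the peripheral S/T thinning ramp starts "
        "(default: outer boundary of the paracentral ring)",
    )

    # cone model
    cone_zones: tuple[str, ...] = Field(
        ("cI", "cTI"),
        description="paracentral zone(s) the cone is centred on/between",
    )
    cone_sigma: float = Field(0.9, gt=0, description="raised-cosine half-width")
    depth_per_severity: float = Field(1.0, gt=0)
    annulus_radius: float = Field(1.6, gt=0)
    annulus_width: float = Field(0.7, gt=0)
    annulus_ratio: float = Field(
        0.2, ge=0, description="annular thickening peak relative to cone depth"
    )

    # severity distributions (uniform low/high per group, µm at cone apex)
    severity_significant: tuple[float, float] = (4.0, 12.0)
    severity_fellow: tuple[float, float] = (0.5, 2.5)
    severity_healthy: tuple[float, float] = (0.0, 0.0)

    # noise model
    zonal_noise_sd: float = Field(0.6, ge=0)
    eye_offset_sd: float = Field(1.5, ge=0, description="between-eye level SD")

    # tomography-index coupling (consumed only by correlation analyses)
    badd_intercept: float = 1.0
    badd_slope: float = 0.7
    badd_noise_sd: float = Field(0.3, ge=0)
    abcd_slope: float = 0.3

    seed: int | None = None

    @model_validator(mode="after")
    def _check_ranges(self) -> "GeneratorConfig":
        for name in ("severity_significant", "severity_fellow", "severity_healthy"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} must satisfy 0 <= low <= high")
        if len(self.cone_zones) not in (1, 2):
            raise ValueError("cone_zones must name one zone or an adjacent pair")
        return self


def _cone_center(cfg: GeneratorConfig, grid: ZoneGrid) -> tuple[float, float]:
    centers = grid.zone_centers()
    pts = centers.loc[list(cfg.cone_zones), ["x", "y"]].to_numpy()
    return tuple(pts.mean(axis=0))


def _raised_cosine(u: np.ndarray) -> np.ndarray:
    out = np.where(np.abs(u) <= 1.0, 0.5 * (1.0 + np.cos(np.pi * u)), 0.0)
    return out


def _surface(cfg: GeneratorConfig, grid: ZoneGrid, severity: float) -> np.ndarray:
    """Deterministic (noise-free) canonical zonal surface for one severity."""
    centers = grid.zone_centers()
    x = centers["x"].to_numpy()  # +x temporal
    y = centers["y"].to_numpy()  # +y superior
    r = np.hypot(x, y)
    # peripheral eyelid-related thinning: a radial ramp starting at the
    # paracentral boundary, reaching the configured S-I / T-N offsets at
    # the reference radius; central and paracentral zones stay level.
    r_ref = cfg.gradient_reference_radius
    r0 = cfg.gradient_inner_radius
    with np.errstate(invalid="ignore", divide="ignore"):
        ramp = np.where(r > 0, np.maximum(0.0, (r - r0) / (r_ref - r0)) / r, 0.0)
    surf = (
        cfg.baseline_et
        - cfg.superior_thinning / 2.0 * ramp * y
        - cfg.temporal_thinning / 2.0 * ramp * x
    )
    if severity > 0:
        cx, cy = _cone_center(cfg, grid)
        d = np.hypot(x - cx, y - cy)
        depth = severity * cfg.depth_per_severity
        surf = surf - depth * _raised_cosine(d / cfg.cone_sigma)
        surf = surf + depth * cfg.annulus_ratio * _raised_cosine(
            (d - cfg.annulus_radius) / cfg.annulus_width
        )
    return surf


def _measurement(
    cfg: GeneratorConfig,
    grid: ZoneGrid,
    severity: float,
    eye_offset: float,
    rng: np.random.Generator,
    subject_id: str,
    eye: str,
    measurement_index: int,
) -> ETMap:
    vals = _surface(cfg, grid, severity) + eye_offset
    vals = vals + rng.normal(0.0, cfg.zonal_noise_sd, size=len(grid))
    series = pd.Series(vals, index=list(grid.aliases))
    canonical_map = ETMap(
        subject_id=subject_id,
        eye=eye,
        measurement_index=measurement_index,
        values=series,
        canonical=True,
    )
    if eye == "OD":
        return canonical_map
    # encode as raw left-eye data: mirror back to device orientation
    mirrored = pd.Series(
        {z.alias: series[z.mirrored().alias] for z in grid.zones}
    ).reindex(list(grid.aliases))
    return ETMap(
        subject_id=subject_id,
        eye=eye,
        measurement_index=measurement_index,
        values=mirrored,
        canonical=False,
    )


def synth_healthy_map(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    grid: ZoneGrid | None = None,
    subject_id: str = "H000",
    eye: str = "OD",
    measurement_index: int = 1,
) -> ETMap:
    """One healthy measurement: smooth gradient surface + offset + noise."""
    return synth_keratoconus_map(
        cfg, 0.0, rng, grid, subject_id=subject_id, eye=eye,
        measurement_index=measurement_index,
    )


def synth_keratoconus_map(
    cfg: GeneratorConfig,
    severity: float,
    rng: np.random.Generator,
    grid: ZoneGrid | None = None,
    subject_id: str = "K000",
    eye: str = "OD",
    measurement_index: int = 1,
) -> ETMap:
    """One keratoconic measurement at a given cone severity (µm).

    Severity 0 reduces exactly to the healthy model under the same
    random stream.
    """
    if severity < 0:
        raise ValueError("severity must be >= 0")
    grid = grid if grid is not None else build_zone_grid()
    eye_offset = rng.normal(0.0, cfg.eye_offset_sd)
    return _measurement(
        cfg, grid, severity, eye_offset, rng, subject_id, eye, measurement_index
    )


def _tomography(
    cfg: GeneratorConfig, group: str, severity: float, rng: np.random.Generator
) -> tuple[float, tuple[float, float, float]]:
    raw = cfg.badd_intercept + cfg.badd_slope * severity + rng.normal(
        0.0, cfg.badd_noise_sd
    )
    if group == "KC_significant":
        bad_d = max(2.69, raw)
        abcd = tuple(
            max(0.0, cfg.abcd_slope * severity + rng.normal(0.0, 0.2))
            for _ in range(3)
        )
    else:  # fellow / healthy: tomographically normal, ABCD stage 0
        bad_d = min(1.64, max(0.0, raw))
        abcd = (0.0, 0.0, 0.0)
    return float(bad_d), abcd


_GROUP_PREFIX = {"KC_significant": "S", "KC_fellow_normal": "F", "healthy": "H"}


def simulate_cohort(
    cfg: GeneratorConfig,
    rng: np.random.Generator | int | None = None,
    grid: ZoneGrid | None = None,
) -> Cohort:
    """Simulate a full cohort under the configured study conditions.

    Randomness contract: a single root seed (the ``rng`` argument or
    ``cfg.seed``) spawns one child stream per eye, so cohorts are
    reproducible eye-by-eye regardless of group sizes elsewhere.
    Left-eye records carry raw (device-orientation) values and are
    canonicalized downstream.
    """
    grid = grid if grid is not None else build_zone_grid()
    if isinstance(rng, np.random.Generator):
        root = rng.bit_generator.seed_seq
    else:
        seed = rng if rng is not None else cfg.seed
        root = np.random.SeedSequence(seed)
    plan = [
        ("KC_significant", cfg.n_significant, cfg.severity_significant),
        ("KC_fellow_normal", cfg.n_fellow, cfg.severity_fellow),
        ("healthy", cfg.n_healthy, cfg.severity_healthy),
    ]
    n_total = sum(n for _, n, _ in plan)
    streams = root.spawn(n_total)
    eyes: list[EyeRecord] = []
    k = 0
    for group, n, (lo, hi) in plan:
        prefix = _GROUP_PREFIX[group]
        for i in range(n):
            erng = np.random.default_rng(streams[k])
            k += 1
            subject = f"{prefix}{i + 1:03d}"
            eye = "OD" if (i % 2 == 0) else "OS"
            severity = float(erng.uniform(lo, hi)) if hi > 0 else 0.0
            eye_offset = erng.normal(0.0, cfg.eye_offset_sd)
            measurements = [
                _measurement(cfg, grid, severity, eye_offset, erng, subject, eye, j + 1)
                for j in range(cfg.repeats)
            ]
            bad_d, abcd = _tomography(cfg, group, severity, erng)
            eyes.append(
                EyeRecord(
                    subject_id=subject,
                    eye=eye,
                    group=group,
                    measurements=measurements,
                    bad_d=bad_d,
                    abcd=abcd,
                )
            )
    return Cohort(eyes, grid)


def development_config(**overrides) -> GeneratorConfig:
    """Development-stage conditions: 86 keratoconus vs 40 healthy eyes,
    one measurement per eye.  The bilateral-ectasia inclusion rule admits
    milder disease than the validation-stage "significant" group, so the
    severity spectrum starts lower."""
    base = dict(
        n_significant=86,
        n_fellow=0,
        n_healthy=40,
        repeats=1,
        severity_significant=(1.5, 12.0),
    )
    base.update(overrides)
    return GeneratorConfig(**base)


def validation_config(**overrides) -> GeneratorConfig:
    """Validation-stage conditions: 21 eyes per group, three repeats."""
    return GeneratorConfig(**overrides)
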