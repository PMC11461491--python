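"""Two-stage screening-parameter analysis (development and validation).

The study design has two stages.  In the *development* stage, per-zone
inter-zonal ET difference maps of keratoconus and healthy eyes are
screened by ROC analysis; the two most discriminative zones define the
localized parameter, and two-sided cut-offs (a screening cut-off with
sensitivity >= 95% and a confirmation cut-off with specificity >= 95%)
are derived for the localized and global parameters.  In the
*validation* stage, the frozen parameters and cut-offs are applied to
an independent cohort of tomographically significant keratoconus eyes,
tomographically normal fellow eyes, and healthy controls: group medians
are compared by Mann-Whitney U tests (Bonferroni-adjusted alpha 0.0125
for the four prespecified comparisons), sensitivity/specificity at the
fixed cut-offs and ROC AUCs (with DeLong CIs) are reported for the new
parameters and five baseline ET descriptors, and measurement
repeatability is summarised by intra-subject SDs.

Both stages follow the model/results idiom: construct an analysis
object from a cohort, call ``fit()``, and read estimates, uncertainties
and ``summary()`` off the returned results object.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .parameters import (
    compute_parameters,
    global_parameter,
    inferior_temporal_parameter,
    interzonal_differences,
)
from .stats import (
    HIGHER,
    LOWER,
    CutoffPair,
    GroupComparison,
    ROCResult,
    compare_groups,
    derive_cutoffs,
    repeatability,
    roc_analysis,
    select_top_zones,
    spearman,
)
from .zonemap import Cohort, ETMap

__all__ = [
    "DevelopmentAnalysis",
    "DevelopmentResults",
    "ValidationAnalysis",
    "ValidationResults",
    "run_development",
    "run_validation",
    "score_cohort",
]

#: Baseline comparator parameters and the direction treated as disease-like.
BASELINE_DIRECTIONS: dict[str, str] = {
    "mean_et": LOWER,
    "sd_et": HIGHER,
    "min_et": LOWER,
    "max_et": HIGHER,
    "inferior_superior": LOWER,
}

_VALIDATION_COMPARISONS = [
    ("KC_significant", "healthy"),
    ("KC_fellow_normal", "healthy"),
]


def _config_hash(config: Mapping) -> str:
    payload = json.dumps(config, sort_keys=True, default=str)
    return hashlib.md5(payload.encode()).hexdigest()[:12]


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def score_cohort(cohort: Cohort, localized_zones=("cI", "cTI")) -> pd.DataFrame:
    """Per-measurement screening parameters for every eye in a cohort.

    Returns one row per measurement with the localized and global
    inter-zonal difference parameters and the baseline descriptors.
    """
    cohort = cohort.canonicalized()
    rows = []
    for eye in cohort:
        for m in eye.measurements:
            p = compute_parameters(m, cohort.grid, localized_zones)
            rows.append(
                {
                    "subject_id": eye.subject_id,
                    "eye": eye.eye,
                    "group": eye.group,
                    "measurement_index": m.measurement_index,
                    **p.as_series().to_dict(),
                }
            )
    return pd.DataFrame(rows)


def _per_eye_parameters(
    cohort: Cohort, localized_zones: Sequence[str]
) -> pd.DataFrame:
    """Per-eye parameters averaged over the repeated measurements.

    The parameter is computed on each measurement and the per-eye mean
    of those values is used (not the parameter of the mean map); the
    difference between the two orderings is logged for transparency.
    """
    scored = score_cohort(cohort, localized_zones)
    per_eye = (
        scored.drop(columns="measurement_index")
        .groupby(["subject_id", "eye", "group"], sort=False)
        .mean()
        .reset_index()
    )
    # parameter of the per-eye mean map, for the order-of-operations check
    diffs = []
    for eye in cohort.canonicalized():
        mean_map = np.mean([m.to_numpy() for m in eye.measurements], axis=0)
        mm = ETMap(
            subject_id=eye.subject_id,
            eye=eye.eye,
            values=pd.Series(mean_map, index=list(cohort.grid.aliases)),
            canonical=True,
        )
        d = interzonal_differences(mm, cohort.grid)
        diffs.append(inferior_temporal_parameter(d, localized_zones))
    delta = float(
        np.max(np.abs(per_eye["inferior_temporal"].to_numpy() - np.array(diffs)))
    )
    per_eye.attrs["max_abs_order_difference"] = delta
    return per_eye


# ---------------------------------------------------------------------------
# Development stage
# ---------------------------------------------------------------------------

@dataclass
class DevelopmentResults:
    """Fitted development-stage results: zone selection, ROC, cut-offs."""

    per_zone_diff_auc: pd.Series
    per_zone_et_auc: pd.Series
    selected_zones: list[str]
    parameter_rocs: dict[str, ROCResult]
    cutoffs: dict[str, CutoffPair]
    correlations: pd.DataFrame | None
    n_disease: int
    n_healthy: int
    scores: pd.DataFrame = field(repr=False)
    config: dict = field(default_factory=dict)

    @property
    def stage(self) -> str:
        return "development"

    def to_dict(self) -> dict:
        cut = {
            name: {
                "lower": c.lower,
                "upper": c.upper,
                "lower_sens": c.lower_sens,
                "lower_spec": c.lower_spec,
                "upper_sens": c.upper_sens,
                "upper_spec": c.upper_spec,
            }
            for name, c in self.cutoffs.items()
        }
        rocs = {
            name: {"auc": r.auc, "ci95": list(r.ci95), "direction": r.direction}
            for name, r in self.parameter_rocs.items()
        }
        return _jsonable(
            {
                "stage": self.stage,
                "package_version": __version__,
                "config": self.config,
                "config_hash": _config_hash(self.config),
                "n_disease": self.n_disease,
                "n_healthy": self.n_healthy,
                "per_zone_diff_auc": self.per_zone_diff_auc,
                "per_zone_et_auc": self.per_zone_et_auc,
                "selected_zones": self.selected_zones,
                "parameter_rocs": rocs,
                "cutoffs": cut,
                "correlations": (
                    None
                    if self.correlations is None
                    else self.correlations.to_dict(orient="index")
                ),
            }
        )

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    def summary(self) -> str:
        lines = [
            "Development stage",
            "=" * 60,
            f"eyes: {self.n_disease} keratoconus / {self.n_healthy} healthy",
            f"selected zones (largest per-zone AUC): {', '.join(self.selected_zones)}",
            "",
            f"{'parameter':<22}{'AUC':>7}{'95% CI':>18}",
        ]
        for name, r in self.parameter_rocs.items():
            lines.append(
                f"{name:<22}{r.auc:>7.3f}   [{r.ci95[0]:.3f}, {r.ci95[1]:.3f}]"
            )
        lines.append("")
        lines.append(
            f"{'parameter':<22}{'cut-off':>9}{'sens':>8}{'spec':>8}"
        )
        for name, c in self.cutoffs.items():
            if c.lower is not None:
                lines.append(
                    f"{name + ' (screening)':<22}{c.lower:>9.3f}"
                    f"{100 * c.lower_sens:>7.1f}%{100 * c.lower_spec:>7.1f}%"
                )
            if c.upper is not None:
                lines.append(
                    f"{name + ' (confirm)':<22}{c.upper:>9.3f}"
                    f"{100 * c.upper_sens:>7.1f}%{100 * c.upper_spec:>7.1f}%"
                )
        if self.correlations is not None:
            lines.append("")
            lines.append("Spearman correlation with tomographic indices:")
            lines.append(self.correlations.round(3).to_string())
        return "\n".join(lines)


class DevelopmentAnalysis:
    """Development-stage model: zone selection and cut-off derivation.

    Parameters
    ----------
    cohort : Cohort
        Eyes with keratoconus (any ``KC_*`` group) and healthy controls;
        one measurement per eye is used (the first, with a warning if
        more are present).
    k : int
        Number of top zones defining the localized parameter.
    sens_target, spec_target : float
        Floors for the screening and confirmation cut-offs.
    ci_method : {"delong", "bootstrap"}
        AUC confidence-interval method.
    """

    def __init__(
        self,
        cohort: Cohort,
        k: int = 2,
        sens_target: float = 0.95,
        spec_target: float = 0.95,
        ci_method: str = "delong",
    ) -> None:
        groups = set(e.group for e in cohort)
        if "healthy" not in groups or not (groups - {"healthy"}):
            raise ValueError(
                "development requires healthy controls and keratoconus eyes"
            )
        self.cohort = cohort
        self.k = k
        self.sens_target = sens_target
        self.spec_target = spec_target
        self.ci_method = ci_method

    def fit(self) -> DevelopmentResults:
        cohort = self.cohort.canonicalized()
        grid = cohort.grid
        maps, labels, records = [], [], []
        multi = 0
        for eye in cohort:
            if eye.n_repeats > 1:
                multi += 1
            maps.append(eye.measurements[0])
            labels.append(0 if eye.group == "healthy" else 1)
            records.append(eye)
        if multi:
            warnings.warn(
                f"{multi} eye(s) have repeated measurements; the development "
                "stage uses the first measurement of each eye"
            )
        labels = np.asarray(labels)
        diffmaps = [interzonal_differences(m, grid) for m in maps]

        top, per_zone_auc = select_top_zones(diffmaps, labels, grid, k=self.k)
        selected = [z.alias for z in top]
        et_mat = np.stack([m.to_numpy() for m in maps])
        per_zone_et_auc = pd.Series(
            [
                roc_analysis(et_mat[:, j], labels, direction=LOWER).auc
                for j in range(et_mat.shape[1])
            ],
            index=list(grid.aliases),
            name="auc",
        )

        scores = pd.DataFrame(
            {
                "subject_id": [e.subject_id for e in records],
                "eye": [e.eye for e in records],
                "group": [e.group for e in records],
                "label": labels,
                "localized": [
                    inferior_temporal_parameter(d, selected) for d in diffmaps
                ],
                "global": [global_parameter(d) for d in diffmaps],
                "bad_d": [e.bad_d for e in records],
                "abcd_a": [None if e.abcd is None else e.abcd[0] for e in records],
                "abcd_b": [None if e.abcd is None else e.abcd[1] for e in records],
                "abcd_c": [None if e.abcd is None else e.abcd[2] for e in records],
            }
        )

        rocs: dict[str, ROCResult] = {}
        cuts: dict[str, CutoffPair] = {}
        for name in ("localized", "global"):
            r = roc_analysis(
                scores[name], labels, direction=HIGHER, ci_method=self.ci_method
            )
            rocs[name] = r
            cuts[name] = derive_cutoffs(r, self.sens_target, self.spec_target)

        corr = None
        if scores["bad_d"].notna().all():
            rows = {}
            for name in ("localized", "global"):
                entry = {}
                for idx in ("bad_d", "abcd_a", "abcd_b", "abcd_c"):
                    if scores[idx].notna().all():
                        col = scores[idx].astype(float)
                        if col.nunique() > 1:
                            rho, p = spearman(scores[name], col)
                            entry[f"rho_{idx}"] = rho
                            entry[f"p_{idx}"] = p
                rows[name] = entry
            corr = pd.DataFrame(rows).T
        else:
            warnings.warn(
                "tomographic indices missing; correlation section skipped"
            )

        return DevelopmentResults(
            per_zone_diff_auc=per_zone_auc,
            per_zone_et_auc=per_zone_et_auc,
            selected_zones=selected,
            parameter_rocs=rocs,
            cutoffs=cuts,
            correlations=corr,
            n_disease=int(labels.sum()),
            n_healthy=int((1 - labels).sum()),
            scores=scores,
            config={
                "k": self.k,
                "sens_target": self.sens_target,
                "spec_target": self.spec_target,
                "ci_method": self.ci_method,
                "adjacency_mode": grid.adjacency_mode,
            },
        )


# ---------------------------------------------------------------------------
# Validation stage
# ---------------------------------------------------------------------------

@dataclass
class ValidationResults:
    """Fitted validation-stage results under frozen cut-offs."""

    group_medians: pd.DataFrame
    comparisons: list[GroupComparison]
    fixed_cutoff_performance: pd.DataFrame
    auc_table: pd.DataFrame
    repeatability_table: pd.DataFrame | None
    per_eye: pd.DataFrame = field(repr=False)
    config: dict = field(default_factory=dict)

    @property
    def stage(self) -> str:
        return "validation"

    def to_dict(self) -> dict:
        return _jsonable(
            {
                "stage": self.stage,
                "package_version": __version__,
                "config": self.config,
                "config_hash": _config_hash(self.config),
                "group_medians": self.group_medians.to_dict(orient="index"),
                "comparisons": [
                    {
                        "groups": [c.group_a, c.group_b],
                        "n": [c.n_a, c.n_b],
                        "U": c.u_statistic,
                        "p": c.p_value,
                        "alpha_adjusted": c.alpha_adjusted,
                        "significant": c.significant,
                        "method": c.method,
                    }
                    for c in self.comparisons
                ],
                "fixed_cutoff_performance": self.fixed_cutoff_performance.to_dict(
                    orient="records"
                ),
                "auc_table": self.auc_table.to_dict(orient="records"),
                "repeatability": (
                    None
                    if self.repeatability_table is None
                    else self.repeatability_table.to_dict(orient="records")
                ),
            }
        )

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    def summary(self) -> str:
        lines = [
            "Validation stage",
            "=" * 60,
            "Group medians (IQR), µm:",
            self.group_medians.round(2).to_string(),
            "",
            "Mann-Whitney U comparisons "
            f"(adjusted alpha {self.comparisons[0].alpha_adjusted:g}):",
        ]
        for c in self.comparisons:
            mark = "*" if c.significant else " "
            lines.append(
                f"  {c.group_a:<18} vs {c.group_b:<10} p = {c.p_value:.4g} {mark}"
            )
        lines += ["", "Fixed-cut-off performance (%):"]
        tab = self.fixed_cutoff_performance.copy()
        tab[["sensitivity", "specificity"]] = (
            100 * tab[["sensitivity", "specificity"]]
        ).round(1)
        lines.append(tab.to_string(index=False))
        lines += ["", "ROC AUC (95% CI) per parameter and contrast:"]
        lines.append(self.auc_table.round(3).to_string(index=False))
        if self.repeatability_table is not None:
            lines += ["", "Repeatability: intra-subject SD, median (IQR) µm:"]
            lines.append(self.repeatability_table.round(3).to_string(index=False))
        return "\n".join(lines)


class ValidationAnalysis:
    """Validation-stage model: frozen cut-offs applied to a new cohort.

    Parameters
    ----------
    cohort : Cohort
        Must contain the three groups (significant keratoconus,
        tomographically normal fellow eyes, healthy controls).
    cutoffs : mapping
        ``{"localized": CutoffPair, "global": CutoffPair}`` from the
        development stage (or explicit values).
    localized_zones : sequence of zone aliases defining the localized
        parameter (frozen at development).
    """

    def __init__(
        self,
        cohort: Cohort,
        cutoffs: Mapping[str, CutoffPair],
        localized_zones: Sequence[str] = ("cI", "cTI"),
        ci_method: str = "delong",
        iqr_method: str = "linear",
    ) -> None:
        missing = set(("KC_significant", "KC_fellow_normal", "healthy")) - set(
            e.group for e in cohort
        )
        if missing:
            raise ValueError(f"validation cohort lacks group(s): {sorted(missing)}")
        self.cohort = cohort
        self.cutoffs = dict(cutoffs)
        self.localized_zones = tuple(localized_zones)
        self.ci_method = ci_method
        self.iqr_method = iqr_method

    def fit(self) -> ValidationResults:
        cohort = self.cohort.canonicalized()
        per_eye = _per_eye_parameters(cohort, self.localized_zones)
        per_eye = per_eye.rename(columns={"inferior_temporal": "localized"})
        params = ["localized", "global_mean"]
        display = {"localized": "localized", "global_mean": "global"}

        med_rows = {}
        for name in params:
            row = {}
            for group in ("KC_significant", "KC_fellow_normal", "healthy"):
                vals = per_eye.loc[per_eye["group"] == group, name].to_numpy()
                q1, q3 = np.quantile(vals, [0.25, 0.75], method=self.iqr_method)
                row[f"{group}_median"] = float(np.median(vals))
                row[f"{group}_iqr"] = float(q3 - q1)
            med_rows[display[name]] = row
        group_medians = pd.DataFrame(med_rows).T

        by_group = {
            g: per_eye.loc[per_eye["group"] == g]
            for g in ("KC_significant", "KC_fellow_normal", "healthy")
        }
        comparisons = []
        for name in params:
            comparisons.extend(
                compare_groups(
                    {g: df[name].to_numpy() for g, df in by_group.items()},
                    _VALIDATION_COMPARISONS,
                    family_size=4,
                )
            )

        cut_rows = []
        for name in params:
            pair = self.cutoffs.get(display[name]) or self.cutoffs.get(name)
            if pair is None:
                continue
            for which, cut in (("screening", pair.lower), ("confirmation", pair.upper)):
                if cut is None:
                    continue
                healthy = by_group["healthy"][name].to_numpy()
                specificity = float(np.mean(healthy < cut))
                for group in ("KC_significant", "KC_fellow_normal"):
                    vals = by_group[group][name].to_numpy()
                    cut_rows.append(
                        {
                            "parameter": display[name],
                            "cutoff_kind": which,
                            "cutoff": cut,
                            "target_group": group,
                            "sensitivity": float(np.mean(vals >= cut)),
                            "specificity": specificity,
                        }
                    )
        cutoff_perf = pd.DataFrame(cut_rows)

        auc_rows = []
        directions = {"localized": HIGHER, "global_mean": HIGHER, **BASELINE_DIRECTIONS}
        for name, direction in directions.items():
            for group in ("KC_significant", "KC_fellow_normal"):
                sub = per_eye[per_eye["group"].isin([group, "healthy"])]
                y = (sub["group"] == group).astype(int).to_numpy()
                r = roc_analysis(
                    sub[name].to_numpy(), y, direction=direction,
                    ci_method=self.ci_method,
                )
                auc_rows.append(
                    {
                        "parameter": display.get(name, name),
                        "contrast": f"{group}_vs_healthy",
                        "direction": direction,
                        "auc": r.auc,
                        "ci_low": r.ci95[0],
                        "ci_high": r.ci95[1],
                    }
                )
        auc_table = pd.DataFrame(auc_rows)

        repeat_table = self._repeatability(cohort)

        return ValidationResults(
            group_medians=group_medians,
            comparisons=comparisons,
            fixed_cutoff_performance=cutoff_perf,
            auc_table=auc_table,
            repeatability_table=repeat_table,
            per_eye=per_eye,
            config={
                "localized_zones": list(self.localized_zones),
                "cutoffs": {
                    k: {"lower": v.lower, "upper": v.upper}
                    for k, v in self.cutoffs.items()
                },
                "ci_method": self.ci_method,
                "iqr_method": self.iqr_method,
                "order_of_operations_max_abs_difference": per_eye.attrs.get(
                    "max_abs_order_difference"
                ),
            },
        )

    def _repeatability(self, cohort: Cohort) -> pd.DataFrame | None:
        if all(e.n_repeats < 2 for e in cohort):
            warnings.warn(
                "no eye has repeated measurements; repeatability section omitted"
            )
            return None
        grid = cohort.grid
        rows = []

        def param_fn(name):
            if name == "localized":
                return lambda m: inferior_temporal_parameter(
                    interzonal_differences(m, grid), self.localized_zones
                )
            return lambda m: global_parameter(interzonal_differences(m, grid))

        for name in ("localized", "global"):
            for group in ("KC_significant", "KC_fellow_normal", "healthy"):
                eyes = [e for e in cohort if e.group == group and e.n_repeats >= 2]
                if not eyes:
                    continue
                rep = repeatability(eyes, param_fn(name), self.iqr_method)
                rows.append(
                    {
                        "quantity": name,
                        "group": group,
                        "median_sd": rep.median,
                        "iqr_sd": rep.iqr,
                        "pooled_sd": rep.pooled_sd,
                    }
                )
        # zonal ET repeatability pooled over all zones and eyes
        eyes = [e for e in cohort if e.n_repeats >= 2]
        zonal_sds = []
        for alias in grid.aliases:
            rep = repeatability(eyes, lambda m, a=alias: m[a], self.iqr_method)
            zonal_sds.append(rep.per_eye_sd.to_numpy())
        all_sds = np.concatenate(zonal_sds)
        q1, q3 = np.quantile(all_sds, [0.25, 0.75], method=self.iqr_method)
        rows.append(
            {
                "quantity": "zonal_et",
                "group": "all",
                "median_sd": float(np.median(all_sds)),
                "iqr_sd": float(q3 - q1),
                "pooled_sd": float(np.sqrt(np.mean(all_sds**2))),
            }
        )
        return pd.DataFrame(rows)


def run_development(cohort: Cohort, **config) -> DevelopmentResults:
    """Functional wrapper: fit the development stage on a cohort."""
    return DevelopmentAnalysis(cohort, **config).fit()


def run_validation(
    cohort: Cohort, cutoffs: Mapping[str, CutoffPair], **config
) -> ValidationResults:
    """Functional wrapper: fit the validation stage under frozen cut-offs."""
    return ValidationAnalysis(cohort, cutoffs, **config).fit()
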