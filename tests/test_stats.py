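"""ROC, cut-off, Mann-Whitney, Spearman and repeatability vs oracles."""

import itertools
import subprocess
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import epizone as ez
from epizone.stats import HIGHER, LOWER, _candidate_thresholds

from conftest import make_map


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def concordance_auc(scores, labels):
    """AUC as the Mann-Whitney concordance probability (ties count 1/2)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def exact_mw_pvalue(a, b):
    """Two-sided exact Mann-Whitney p by full enumeration of assignments."""
    combined = list(a) + list(b)
    n1 = len(a)

    def u_stat(idx):
        xs = [combined[i] for i in idx]
        ys = [combined[i] for i in range(len(combined)) if i not in idx]
        return sum(1 for x in xs for y in ys if x > y)

    u_obs = sum(1 for x in a for y in b if x > y)
    us = [u_stat(set(c)) for c in
          itertools.combinations(range(len(combined)), n1)]
    us = np.array(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return min(1.0, 2 * min(p_le, p_ge))


def spearman_midrank_oracle(x, y):
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def cutoff_scan_oracle(scores, labels, sens_target, spec_target):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    u = np.unique(scores)
    cands = (u[:-1] + u[1:]) / 2
    lower = upper = None
    for t in sorted(cands, reverse=True):  # largest t with sens >= target
        if np.mean(pos >= t) >= sens_target:
            lower = t
            break
    for t in sorted(cands):  # smallest t with spec >= target
        if np.mean(neg < t) >= spec_target:
            upper = t
            break
    if lower is not None and upper is not None and lower > upper:
        lower, upper = upper, lower  # overlapping floors: ordered pair
    return lower, upper


# ---------------------------------------------------------------------------
# ROC analysis
# ---------------------------------------------------------------------------

class TestROC:
    def test_perfect_separation(self):
        r = ez.roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0

    def test_no_discrimination_degenerate(self):
        with pytest.warns(UserWarning, match="identical"):
            r = ez.roc_analysis([5.0] * 8, [0, 1] * 4)
        assert r.auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            ez.roc_analysis([1, 2, 3], [1, 1, 1])

    def test_toy_tied_set_vs_pair_enumeration(self):
        scores = [1.0, 2.0, 3.0, 4.0, 5.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0, 11.0]
        labels = [0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1, 0]
        r = ez.roc_analysis(scores, labels)
        assert r.auc == pytest.approx(concordance_auc(scores, labels))

    def test_trapezoid_equals_concordance_on_random_instances(self, rng):
        for _ in range(200):
            n = rng.integers(6, 30)
            scores = rng.integers(0, 10, size=n).astype(float)  # force ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            r = ez.roc_analysis(scores, labels)
            assert r.auc == pytest.approx(concordance_auc(scores, labels))

    def test_direction_negation_identity(self, rng):
        for _ in range(50):
            scores = rng.normal(size=20)
            labels = np.r_[np.ones(10, int), np.zeros(10, int)]
            a_low = ez.roc_analysis(scores, labels, direction=LOWER).auc
            a_neg = ez.roc_analysis(-scores, labels, direction=HIGHER).auc
            assert a_low == pytest.approx(a_neg)

    def test_curve_monotonicity(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        r = ez.roc_analysis(scores, labels)
        assert np.all(np.diff(r.sensitivity) <= 0)
        assert np.all(np.diff(r.specificity) >= 0)

    def test_ci_clipped_and_ordered(self, rng):
        for _ in range(50):
            scores = rng.normal(size=24)
            labels = np.r_[np.ones(12, int), np.zeros(12, int)]
            r = ez.roc_analysis(scores, labels)
            lo, hi = r.ci95
            assert 0.0 <= lo <= r.auc <= hi <= 1.0

    def test_delong_matches_proc_reference(self):
        """DeLong AUC CI agrees with R pROC ci.auc(method='delong')."""
        pos = [2.1, 3.4, 3.4, 4.0, 5.2, 2.8, 3.9, 4.4]
        neg = [1.0, 2.1, 2.5, 3.0, 2.2, 1.8, 2.9, 3.3, 2.6, 1.4]
        scores = np.array(pos + neg)
        labels = np.array([1] * len(pos) + [0] * len(neg))
        r = ez.roc_analysis(scores, labels)
        script = (
            "suppressMessages(library(pROC));"
            f"resp <- c({','.join(str(l) for l in labels)});"
            f"pred <- c({','.join(str(s) for s in scores)});"
            "r <- roc(resp, pred, quiet=TRUE, direction='<');"
            "ci <- ci.auc(r, method='delong');"
            "cat(sprintf('%.10f %.10f %.10f', ci[2], ci[1], ci[3]))"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        auc_ref, lo_ref, hi_ref = map(float, out.stdout.split())
        assert r.auc == pytest.approx(auc_ref, abs=1e-9)
        assert r.ci95[0] == pytest.approx(lo_ref, abs=1e-6)
        assert r.ci95[1] == pytest.approx(hi_ref, abs=1e-6)

    def test_bootstrap_ci_contains_point_estimate(self, rng):
        scores = rng.normal(size=30) + np.r_[np.ones(15), np.zeros(15)]
        labels = np.r_[np.ones(15, int), np.zeros(15, int)]
        r = ez.roc_analysis(scores, labels, ci_method="bootstrap", n_boot=300,
                            rng=rng)
        assert 0.0 <= r.ci95[0] <= r.ci95[1] <= 1.0


# ---------------------------------------------------------------------------
# zone selection
# ---------------------------------------------------------------------------

class TestSelectTopZones:
    def _diffmaps(self, grid, rng, n, hot=None, bump=0.0):
        out = []
        for _ in range(n):
            vals = rng.uniform(0.5, 1.0, size=41)
            d = pd.Series(vals, index=list(grid.aliases))
            if hot:
                d[list(hot)] += bump
            out.append(ez.DiffMap(d))
        return out

    def test_recovers_seeded_zones(self, grid, rng):
        healthy = self._diffmaps(grid, rng, 20)
        disease = self._diffmaps(grid, rng, 20, hot=("cI", "cTI"), bump=3.0)
        zones, aucs = ez.select_top_zones(
            healthy + disease, [0] * 20 + [1] * 20, grid, k=2
        )
        assert {z.alias for z in zones} == {"cI", "cTI"}
        assert aucs["cI"] == 1.0

    def test_k_equals_all_zones_sorted(self, grid, rng):
        maps = self._diffmaps(grid, rng, 16)
        labels = [0, 1] * 8
        zones, aucs = ez.select_top_zones(maps, labels, grid, k=41)
        vals = [aucs[z.alias] for z in zones]
        assert len(zones) == 41
        assert vals == sorted(vals, reverse=True)

    def test_k_too_large_rejected(self, grid, rng):
        maps = self._diffmaps(grid, rng, 4)
        with pytest.raises(ValueError):
            ez.select_top_zones(maps, [0, 0, 1, 1], grid, k=42)

    def test_null_labels_give_chance_level_aucs(self, grid, rng):
        maps = self._diffmaps(grid, rng, 60)
        labels = rng.permutation([0] * 30 + [1] * 30)
        _, aucs = ez.select_top_zones(maps, labels, grid, k=2)
        assert 0.35 < aucs.mean() < 0.65


# ---------------------------------------------------------------------------
# cut-offs
# ---------------------------------------------------------------------------

class TestDeriveCutoffs:
    def test_perfect_separation_midpoint(self):
        r = ez.roc_analysis([1, 2, 3, 7, 8, 9], [0, 0, 0, 1, 1, 1])
        c = ez.derive_cutoffs(r)
        assert c.lower == c.upper == pytest.approx(5.0)
        assert c.lower_sens == c.lower_spec == 1.0

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(100):
            scores = np.round(rng.normal(size=20), 1)
            labels = np.r_[np.ones(10, int), np.zeros(10, int)]
            scores[:10] += rng.uniform(0, 2)
            if np.ptp(scores) == 0:
                continue
            r = ez.roc_analysis(scores, labels)
            with pytest.warns(UserWarning) if _unattainable(r) else _nullcontext():
                c = ez.derive_cutoffs(r, 0.9, 0.9)
            lo, hi = cutoff_scan_oracle(r.scores, r.labels, 0.9, 0.9)
            assert c.lower == (None if lo is None else pytest.approx(lo))
            assert c.upper == (None if hi is None else pytest.approx(hi))

    def test_floors_honoured(self, rng):
        for _ in range(100):
            scores = rng.normal(size=24)
            scores[:12] += 1.0
            labels = np.r_[np.ones(12, int), np.zeros(12, int)]
            r = ez.roc_analysis(scores, labels)
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                c = ez.derive_cutoffs(r, 0.95, 0.95)
            if c.lower is not None:
                assert c.lower_sens >= 0.95
            if c.upper is not None:
                assert c.upper_spec >= 0.95

    def test_zero_sensitivity_target_selects_most_specific_threshold(self):
        # a zero sensitivity floor admits every threshold; the sens-driven
        # rule picks the maximal (most specific) one, which the ordered
        # pair then reports as the upper cut-off
        r = ez.roc_analysis([1, 2, 3, 4, 5, 6], [0, 0, 0, 1, 1, 1])
        c = ez.derive_cutoffs(r, sens_target=0.0)
        assert c.upper == pytest.approx(max(_candidate_thresholds(r.scores)))
        assert c.upper_spec == 1.0
        assert c.lower <= c.upper

    def test_unattainable_target_flagged_absent(self):
        # every candidate keeps at least one healthy eye above it
        scores = [1, 1, 1, 2, 2, 9, 2, 3]
        labels = [0, 0, 0, 0, 0, 0, 1, 1]
        r = ez.roc_analysis(scores, labels)
        with pytest.warns(UserWarning, match="unattainable"):
            c = ez.derive_cutoffs(r, sens_target=0.95, spec_target=1.0)
        assert c.upper is None


def _unattainable(r):
    lo, hi = cutoff_scan_oracle(r.scores, r.labels, 0.9, 0.9)
    return lo is None or hi is None


class _nullcontext:
    def __enter__(self):
        return None

    def __exit__(self, *a):
        return False


# ---------------------------------------------------------------------------
# group comparisons, spearman, repeatability
# ---------------------------------------------------------------------------

class TestCompareGroups:
    def test_bonferroni_alpha(self):
        res = ez.compare_groups(
            {"a": [1, 2, 3], "b": [4, 5, 6]}, [("a", "b")], family_size=4
        )
        assert res[0].alpha_adjusted == pytest.approx(0.0125)
        assert res[0].alpha_adjusted * 4 == 0.05

    def test_separated_triples_exact_p(self):
        res = ez.compare_groups(
            {"a": [1, 2, 3], "b": [4, 5, 6]}, [("a", "b")], family_size=1
        )
        assert res[0].method == "exact"
        assert res[0].p_value == pytest.approx(0.1)

    def test_identical_small_samples_p_one(self):
        # identical samples are fully tied, so the tie-corrected branch
        # applies; no evidence of a location shift whatsoever
        res = ez.compare_groups(
            {"a": [1.0, 5.0, 9.0], "b": [1.0, 5.0, 9.0]},
            [("a", "b")],
            family_size=1,
        )
        assert res[0].p_value == pytest.approx(1.0)

    def test_exact_matches_full_enumeration(self, rng):
        for _ in range(25):
            n1, n2 = rng.integers(3, 7, size=2)
            a = rng.permutation(np.arange(40, dtype=float))[:n1]
            b = rng.permutation(np.arange(40, dtype=float) + 0.5)[:n2]
            res = ez.compare_groups({"a": a, "b": b}, [("a", "b")])
            assert res[0].method == "exact"
            assert res[0].p_value == pytest.approx(exact_mw_pvalue(a, b))

    def test_ties_or_large_samples_use_asymptotic(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(size=30) + 1
        res = ez.compare_groups({"a": a, "b": b}, [("a", "b")])
        assert res[0].method == "asymptotic"
        res = ez.compare_groups({"a": [1, 1, 2], "b": [2, 3, 4]}, [("a", "b")])
        assert res[0].method == "asymptotic"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ez.compare_groups({"a": [], "b": [1]}, [("a", "b")])


class TestSpearman:
    def test_monotone_pairs(self):
        x = [1, 2, 3, 4, 5]
        assert ez.spearman(x, [2, 4, 9, 16, 30])[0] == pytest.approx(1.0)
        assert ez.spearman(x, [30, 16, 9, 4, 2])[0] == pytest.approx(-1.0)

    def test_ties_match_midrank_oracle(self, rng):
        for _ in range(50):
            x = rng.integers(0, 5, size=12).astype(float)
            y = x + rng.integers(0, 3, size=12)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, _ = ez.spearman(x, y)
            assert rho == pytest.approx(spearman_midrank_oracle(x, y))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            ez.spearman([1, 1, 1], [1, 2, 3])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            ez.spearman([1, 2], [3, 4])


class TestRepeatability:
    def _eye(self, grid, sid, values_by_repeat):
        ms = [
            make_map(v, grid, subject=sid, index=i + 1)
            for i, v in enumerate(values_by_repeat)
        ]
        return ez.EyeRecord(sid, "OD", "healthy", ms)

    def test_identical_repeats_zero_sd(self, grid):
        eyes = [self._eye(grid, f"s{i}", [50.0, 50.0, 50.0]) for i in range(4)]
        rep = ez.repeatability(eyes, lambda m: m["C"])
        assert np.all(rep.per_eye_sd == 0.0)
        assert rep.median == 0.0

    def test_known_closed_form(self, grid):
        eyes = [self._eye(grid, "s0", [49.0, 50.0, 51.0])]
        rep = ez.repeatability(eyes, lambda m: m["C"])
        assert rep.per_eye_sd.iloc[0] == pytest.approx(1.0)

    def test_single_measurement_eyes_excluded_with_warning(self, grid):
        eyes = [
            self._eye(grid, "s0", [49.0, 51.0]),
            self._eye(grid, "s1", [50.0]),
        ]
        with pytest.warns(UserWarning, match="fewer than 2"):
            rep = ez.repeatability(eyes, lambda m: m["C"])
        assert len(rep.per_eye_sd) == 1

    def test_all_single_measurement_rejected(self, grid):
        eyes = [self._eye(grid, "s0", [50.0])]
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                ez.repeatability(eyes, lambda m: m["C"])

    def test_iqr_convention_switch(self, grid):
        eyes = [
            self._eye(grid, f"s{i}", [50.0, 50.0 + d])
            for i, d in enumerate([0.1, 0.4, 0.9, 1.6, 2.5])
        ]
        r7 = ez.repeatability(eyes, lambda m: m["C"], iqr_method="linear")
        r6 = ez.repeatability(eyes, lambda m: m["C"], iqr_method="weibull")
        sds = np.sort(r7.per_eye_sd.to_numpy())
        q1_7, q3_7 = np.quantile(sds, [0.25, 0.75], method="linear")
        assert r7.iqr == pytest.approx(q3_7 - q1_7)
        assert r6.iqr > r7.iqr  # type-6 quartiles are wider on 5 points
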