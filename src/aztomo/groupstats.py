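"""Condition-level statistics: aggregation, planned comparisons, CDFs,
and missing-wedge orientation equalization.

Comparisons are restricted to a configured list of planned, orthogonal pairs
(never expanded all-vs-all), with the test chosen by the variable kind:
Student's t for approximately normal continuous values, Kruskal-Wallis for
per-vesicle counts (kept even at two groups), Pearson's chi-squared (no
continuity correction) for frequencies, and Pearson correlation for
associations. All tests are two-tailed; no multiple-testing correction is
applied because the design object itself restricts the comparisons.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SynapseRecord",
    "ComparisonDesign",
    "TestResult",
    "aggregate",
    "compare",
    "compare_counts",
    "significance_stars",
    "cdf_and_inflection",
    "InflectionResult",
    "equalize_orientation",
    "histogram",
]


@dataclasses.dataclass
class SynapseRecord:
    """One synapse: condition, tomogram orientation, and child tables."""

    synapse_id: str
    condition: str
    orientation_deg: float
    az_area_nm2: float | None = None
    vesicles: pd.DataFrame | None = None
    segments: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.orientation_deg <= 90.0:
            raise ValueError("orientation angle must lie in [-90, 90] degrees")

    @property
    def n_proximal(self) -> int:
        if self.vesicles is None or len(self.vesicles) == 0:
            return 0
        return int((self.vesicles["distance_zone"] == "proximal").sum())

    @property
    def surface_concentration_per_um2(self) -> float | None:
        from .morpho import surface_concentration

        if self.az_area_nm2 is None:
            return None
        return surface_concentration(self.n_proximal, self.az_area_nm2)


@dataclasses.dataclass
class ComparisonDesign:
    """Planned, orthogonal pairwise comparisons and the test per variable kind."""

    pairs: list[tuple[str, str]]
    tests: dict[str, str] = dataclasses.field(default_factory=lambda: {
        "continuous": "t",
        "count": "kruskal",
        "frequency": "chi2",
        "association": "pearson",
    })
    two_tailed: bool = True
    welch: bool = False  # Student's t by default; Welch by flag

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate planned pair")


@dataclasses.dataclass
class TestResult:
    variable: str
    group_a: str
    group_b: str
    test: str
    statistic: float
    p_value: float
    stars: str
    n_a: int
    n_b: int
    warning: str = ""


def significance_stars(p: float) -> str:
    """'*' p<0.05, '**' p<0.01, '***' p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def _sem(values: np.ndarray) -> float:
    # SEM undefined for n=1: reported as missing, never as 0
    if len(values) < 2:
        return float("nan")
    return float(np.std(values, ddof=1) / math.sqrt(len(values)))


def aggregate(records: list[SynapseRecord], per_structure: dict[str, tuple[str, str]],
              per_synapse_fractions: dict[str, callable] | None = None) -> pd.DataFrame:
    """Group summaries: pooled per-structure values; per-synapse means for fractions.

    ``per_structure`` maps variable name -> (child table, column); values are
    pooled across synapses within a condition, and the summary is the pooled
    mean with SEM over pooled values. ``per_synapse_fractions`` maps variable
    name -> function(SynapseRecord) -> float; the fraction is computed per
    synapse and the error is the SEM between synapse means.
    """
    rows = []
    by_cond: dict[str, list[SynapseRecord]] = {}
    for rec in records:
        by_cond.setdefault(rec.condition, []).append(rec)
    for cond, recs in by_cond.items():
        for var, (table, col) in per_structure.items():
            pooled = []
            for r in recs:
                child = getattr(r, table)
                if child is not None and len(child):
                    pooled.append(np.asarray(child[col], dtype=float))
            vals = np.concatenate(pooled) if pooled else np.array([])
            rows.append({
                "condition": cond, "variable": var, "kind": "pooled",
                "n": len(vals),
                "mean": float(np.mean(vals)) if len(vals) else float("nan"),
                "sem": _sem(vals),
            })
        for var, fn in (per_synapse_fractions or {}).items():
            vals = np.array([fn(r) for r in recs], dtype=float)
            vals = vals[~np.isnan(vals)]
            rows.append({
                "condition": cond, "variable": var, "kind": "per-synapse",
                "n": len(vals),
                "mean": float(np.mean(vals)) if len(vals) else float("nan"),
                "sem": _sem(vals),
            })
    return pd.DataFrame(rows, columns=["condition", "variable", "kind", "n", "mean", "sem"])


# ---------------------------------------------------------------------------
# Planned comparisons
# ---------------------------------------------------------------------------

def compare(variable: str, group_a: str, group_b: str, a, b, kind: str,
            design: ComparisonDesign | None = None) -> TestResult:
    """Two-tailed planned comparison of one variable between two groups.

    ``kind``: 'continuous' (two-sample t), 'count' (Kruskal-Wallis),
    'frequency' (chi-squared on a contingency table; pass rows as a and b),
    'association' (Pearson r; pass paired arrays).
    """
    if design is not None and (group_a, group_b) not in design.pairs \
            and (group_b, group_a) not in design.pairs:
        raise ValueError(f"({group_a}, {group_b}) is not a planned comparison")
    warn = ""
    if kind == "continuous":
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if len(a) == 0 or len(b) == 0:
            raise ValueError("both groups must be nonempty")
        if np.var(a) == 0 and np.var(b) == 0:
            if np.mean(a) == np.mean(b):
                stat, p, warn = 0.0, 1.0, "zero variance in both groups"
            else:
                stat, p, warn = float("inf"), 0.0, "zero variance in both groups"
            warnings.warn("t test on zero-variance groups")
        else:
            welch = design.welch if design is not None else False
            stat, p = stats.ttest_ind(a, b, equal_var=not welch)
        test = "t"
    elif kind == "count":
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if len(a) == 0 or len(b) == 0:
            raise ValueError("both groups must be nonempty")
        if np.all(np.concatenate([a, b]) == np.concatenate([a, b])[0]):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.kruskal(a, b)
        test = "kruskal"
    elif kind == "frequency":
        table = np.asarray([a, b], dtype=float)
        if table.min() < 0 or table.sum(axis=1).min() == 0:
            raise ValueError("contingency rows must be nonnegative and nonempty")
        if table.sum(axis=0).min() == 0:
            # a frequency shared exactly by both groups (all-zero column):
            # no difference to test
            return TestResult(variable, group_a, group_b, "chi2", 0.0, 1.0, "",
                              int(table[0].sum()), int(table[1].sum()),
                              "degenerate contingency (constant frequency)")
        stat, p, _, expected = stats.chi2_contingency(table, correction=False)
        if expected.min() < 1:
            warn = "expected cell < 1"
        elif expected.min() < 5:
            warn = "expected cell < 5"
        test = "chi2"
    elif kind == "association":
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if len(a) != len(b) or len(a) < 3:
            raise ValueError("association needs paired arrays of length >= 3")
        stat, p = stats.pearsonr(a, b)
        test = "pearson"
    else:
        raise ValueError(f"unknown variable kind {kind!r}")
    n_a = int(np.sum(a)) if kind == "frequency" else len(a)
    n_b = int(np.sum(b)) if kind == "frequency" else len(b)
    return TestResult(variable, group_a, group_b, test, float(stat), float(p),
                      significance_stars(float(p)), n_a, n_b, warn)


def compare_counts(variable: str, group_a: str, group_b: str,
                   n_hit_a: int, n_a: int, n_hit_b: int, n_b: int,
                   design: ComparisonDesign | None = None) -> TestResult:
    """Chi-squared comparison of a fraction (hits / totals) between two groups."""
    return compare(variable, group_a, group_b,
                   [n_hit_a, n_a - n_hit_a], [n_hit_b, n_b - n_hit_b],
                   "frequency", design)


# ---------------------------------------------------------------------------
# CDFs and inflection points
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class InflectionResult:
    grid_nm: np.ndarray
    cdf: np.ndarray
    derivative: np.ndarray
    inflections_nm: list[float]   # empty = no inflection (flat derivative)


def cdf_and_inflection(values, bandwidth_nm: float = 1.0,
                       grid_step_nm: float = 0.1) -> InflectionResult:
    """Empirical CDF and the midpoints of its regions of steep increase.

    The ECDF is evaluated on a regular grid, smoothed by a moving average of
    the given bandwidth, and differentiated; a steep region is a maximal
    contiguous run where the derivative exceeds half its maximum. Each
    steep region contributes its midpoint. A near-uniform sample, whose
    derivative stays above half-maximum over most of the range, yields no
    inflection rather than an arbitrary midpoint.
    """
    values = np.sort(np.asarray(values, dtype=float))
    if len(values) < 2:
        raise ValueError("need at least 2 values")
    lo, hi = values[0] - bandwidth_nm, values[-1] + bandwidth_nm
    grid = np.arange(lo, hi + grid_step_nm, grid_step_nm)
    ecdf = np.searchsorted(values, grid, side="right") / len(values)
    win = max(1, int(round(bandwidth_nm / grid_step_nm)))
    kernel = np.ones(win) / win
    smooth = np.convolve(ecdf, kernel, mode="same")
    deriv = np.gradient(smooth, grid)
    steep = deriv > deriv.max() / 2.0
    # contiguous runs
    edges = np.diff(steep.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0] + 1)
    if steep[0]:
        starts.insert(0, 0)
    if steep[-1]:
        ends.append(len(steep))
    runs = list(zip(starts, ends))
    total_steep = sum(e - s for s, e in runs)
    inflections: list[float] = []
    if total_steep * grid_step_nm < 0.5 * (grid[-1] - grid[0]):
        inflections = [float((grid[s] + grid[e - 1]) / 2.0) for s, e in runs]
    return InflectionResult(grid, ecdf, deriv, inflections)


# ---------------------------------------------------------------------------
# Orientation equalization
# ---------------------------------------------------------------------------

def equalize_orientation(groups: dict[str, list[SynapseRecord]],
                         tolerance_deg: float = 5.0) -> list[tuple[str, str]]:
    """Equalize mean tomogram orientation angles across conditions.

    Synapses are removed one at a time, in order from the most extreme angle
    relative to the grand mean (never emptying a group), until every pairwise
    difference of group means is within tolerance. Returns the ordered
    removal list as (condition, synapse_id) pairs; raises if the tolerance is
    unreachable before a group would be emptied. Deterministic and invariant
    to input order (ties broken by synapse id).
    """
    pool = {c: {r.synapse_id: r.orientation_deg for r in recs}
            for c, recs in groups.items()}
    if any(len(v) == 0 for v in pool.values()):
        raise ValueError("empty condition group")
    removals: list[tuple[str, str]] = []
    while True:
        means = {c: np.mean(list(v.values())) for c, v in pool.items()}
        vals = list(means.values())
        spread = max(vals) - min(vals)
        if spread <= tolerance_deg:
            return removals
        grand = np.mean(np.concatenate([list(v.values()) for v in pool.values()]))
        candidates = sorted(
            ((abs(theta - grand), cond, sid)
             for cond, v in pool.items() if len(v) > 1
             for sid, theta in v.items()),
            key=lambda t: (-t[0], t[1], t[2]),
        )
        if not candidates:
            raise ValueError(
                f"orientation tolerance {tolerance_deg} deg unreachable: "
                f"group means {means} with single-synapse groups remaining"
            )
        _, cond, sid = candidates[0]
        del pool[cond][sid]
        removals.append((cond, sid))


# ---------------------------------------------------------------------------
# Histograms
# ---------------------------------------------------------------------------

def histogram(values, bin_edges) -> pd.DataFrame:
    """Counts and normalized probabilities over left-closed bins.

    ``bin_edges`` are inner edges; values below the first edge fall in the
    first bin, values >= the last edge in the overflow bin. Probabilities sum
    to 1 when the input is nonempty.
    """
    values = np.asarray(values, dtype=float)
    edges = np.asarray(bin_edges, dtype=float)
    full = np.concatenate([[-np.inf], edges, [np.inf]])
    idx = np.searchsorted(edges, values, side="right")
    counts = np.bincount(idx, minlength=len(edges) + 1)
    total = counts.sum()
    probs = counts / total if total else np.zeros_like(counts, dtype=float)
    return pd.DataFrame({
        "bin_lo": full[:-1], "bin_hi": full[1:],
        "count": counts, "probability": probs,
    })
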