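"""Binary extrusion classification and cohort comparison statistics.

The cohort-level questions are nonparametric: do the three measurement
methods give systematically different maximal extrusions and locations
(Wilcoxon signed rank pairwise, Friedman across all three), how well do
they rank knees alike (Spearman), and do binary extruded/not-extruded
calls agree between readings (Cohen's kappa)?

The Wilcoxon test is computed from an exact permutation distribution for
n <= 25 pairs (dynamic programming over signed rank sums, which also
handles mid-ranked ties) and by normal approximation with tie correction
above that; Friedman and Spearman delegate to scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import CohortValidationError, DegenerateTestError
from .results import METHODS

#: Conventional absolute threshold for an "extruded" meniscus, mm.
EXTRUSION_THRESHOLD_MM = 3.0


def classify_extruded(
    extrusion_mm: float,
    threshold_mm: float = EXTRUSION_THRESHOLD_MM,
    meniscal_width_mm: float | None = None,
    width_fraction: float = 0.30,
) -> bool:
    """Binary extrusion call: ``extrusion >= 3 mm`` (inclusive boundary).

    The relative criterion (extrusion at least ``width_fraction`` of the
    meniscal width) is applied in addition only when a width is supplied.
    """
    if not math.isfinite(extrusion_mm):
        raise ValueError("extrusion must be finite")
    if extrusion_mm >= threshold_mm:
        return True
    if meniscal_width_mm is not None:
        return extrusion_mm >= width_fraction * meniscal_width_mm
    return False


# ---------------------------------------------------------------------------
# Wilcoxon signed rank


def _signed_rank_distribution(double_ranks: np.ndarray) -> np.ndarray:
    """Counts of each achievable doubled rank-sum over all sign assignments."""
    total = int(double_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in double_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(
    paired_a, paired_b, exact_max_n: int = 25
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed rank test on paired samples.

    Zero differences are dropped; tied absolute differences receive
    mid-ranks.  Returns ``(W_plus, p)`` where ``W_plus`` is the sum of
    ranks of positive differences.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1D sequences")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise DegenerateTestError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        dbl = np.round(2 * ranks).astype(np.int64)
        counts = _signed_rank_distribution(dbl)
        total = counts.sum()
        w2 = int(round(2 * w_plus))
        p_le = counts[: w2 + 1].sum() / total
        p_ge = counts[w2:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        mean = n * (n + 1) / 4.0
        _uniq, t = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - ((t**3 - t).sum()) / 48.0
        z = (w_plus - mean) / math.sqrt(var)
        p = 2.0 * sps.norm.sf(abs(z))
    return w_plus, float(p)


def friedman_test(matrix) -> tuple[float, float]:
    """Friedman rank chi-square over a (blocks x treatments) matrix.

    Mid-ranks for within-block ties; p from the chi-square distribution on
    k - 1 degrees of freedom.  A matrix in which every block is constant
    carries no rank information and returns (0.0, 1.0).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 3 or m.shape[1] < 3:
        raise DegenerateTestError("Friedman test needs at least 3 blocks and 3 treatments")
    if np.all(m == m[:, :1]):
        return 0.0, 1.0
    chi2, p = sps.friedmanchisquare(*(m[:, j] for j in range(m.shape[1])))
    return float(chi2), float(p)


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation (Pearson on mid-ranks) with its p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length samples of at least 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateTestError("correlation undefined for a constant sample")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class KappaResult:
    """Cohen's kappa with its large-sample standard error."""

    kappa: float
    se: float
    p_observed: float
    p_expected: float
    n: int
    undefined: bool = False


def cohen_kappa(ratings_a, ratings_b) -> KappaResult:
    """Chance-corrected agreement between two binary rating vectors.

    Expected agreement uses the marginal products.  When both raters are
    constant and identical (expected agreement 1) kappa is undefined and
    reported as such (NaN).
    """
    a = np.asarray(ratings_a).astype(int)
    b = np.asarray(ratings_b).astype(int)
    if a.shape != b.shape or a.ndim != 1 or len(a) == 0:
        raise ValueError("ratings must be equal-length non-empty 1D sequences")
    n = len(a)
    cats = np.union1d(a, b)
    p_o = float(np.mean(a == b))
    p_e = float(sum(np.mean(a == c) * np.mean(b == c) for c in cats))
    if p_e >= 1.0 - 1e-12:
        return KappaResult(math.nan, math.nan, p_o, p_e, n, undefined=True)
    kappa = (p_o - p_e) / (1.0 - p_e)
    se = math.sqrt(p_o * (1.0 - p_o) / n) / (1.0 - p_e)
    return KappaResult(kappa, se, p_o, p_e, n)


# ---------------------------------------------------------------------------
# cohort analysis

COHORT_COLUMNS = (
    "knee_id",
    "method",
    "max_extrusion_mm",
    "location_ap_mm",
    "location_pct",
    "extruded",
)


def validate_cohort(cohort: pd.DataFrame) -> None:
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise CohortValidationError(f"cohort table lacks columns: {', '.join(missing)}")
    if len(cohort) == 0:
        raise CohortValidationError("cohort table is empty")
    if cohort["max_extrusion_mm"].isna().any():
        bad = cohort.loc[cohort["max_extrusion_mm"].isna(), "knee_id"].tolist()
        raise CohortValidationError(f"missing max_extrusion_mm for knees: {bad}")
    counts = cohort.groupby("knee_id")["method"].apply(lambda s: sorted(set(s)))
    bad = [k for k, methods in counts.items() if methods != sorted(METHODS)]
    if bad:
        raise CohortValidationError(
            f"knees without exactly one row per method: {', '.join(map(str, bad))}"
        )
    dup = cohort.duplicated(subset=["knee_id", "method"])
    if dup.any():
        raise CohortValidationError(
            f"duplicate knee/method rows: {cohort.loc[dup, 'knee_id'].tolist()}"
        )


@dataclass
class StatsReport:
    """All cohort summary statistics and tests, JSON-serialisable."""

    per_method: dict = field(default_factory=dict)
    wilcoxon_location: dict = field(default_factory=dict)
    wilcoxon_extrusion: dict = field(default_factory=dict)
    friedman_extrusion: tuple[float, float] = (math.nan, math.nan)
    friedman_location: tuple[float, float] = (math.nan, math.nan)
    spearman_extrusion: dict = field(default_factory=dict)
    kappa: dict = field(default_factory=dict)
    n_knees: int = 0

    def to_dict(self) -> dict:
        def tup(t):
            return {"statistic": t[0], "p": t[1]}

        return {
            "n_knees": self.n_knees,
            "per_method": self.per_method,
            "wilcoxon_location": {k: tup(v) for k, v in self.wilcoxon_location.items()},
            "wilcoxon_extrusion": {k: tup(v) for k, v in self.wilcoxon_extrusion.items()},
            "friedman_extrusion": tup(self.friedman_extrusion),
            "friedman_location": tup(self.friedman_location),
            "spearman_extrusion": {k: tup(v) for k, v in self.spearman_extrusion.items()},
            "kappa": self.kappa,
        }

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for method, d in self.per_method.items():
            rows.append({"method": method, **d})
        return pd.DataFrame(rows)


def _summaries(values: pd.Series) -> dict:
    v = values.to_numpy(dtype=float)
    return {
        "median": float(np.median(v)),
        "mean": float(np.mean(v)),
        "sd": float(np.std(v, ddof=1)) if len(v) > 1 else math.nan,
    }


def kappa_from_ratings(ratings: pd.DataFrame) -> dict:
    """Intra- and interobserver kappas from a long ratings table.

    Expected columns: ``knee_id``, ``rater``, ``reading``, ``extruded``.
    Intraobserver agreement compares a rater's two readings; interobserver
    agreement compares the two raters' first readings.
    """
    for c in ("knee_id", "rater", "reading", "extruded"):
        if c not in ratings.columns:
            raise CohortValidationError(f"ratings table lacks column {c!r}")
    out: dict = {}
    piv = ratings.pivot_table(
        index="knee_id", columns=["rater", "reading"], values="extruded", aggfunc="first"
    )
    raters = sorted({r for r, _ in piv.columns})
    for rater in raters:
        readings = sorted(rd for r, rd in piv.columns if r == rater)
        if len(readings) >= 2:
            a = piv[(rater, readings[0])].dropna()
            b = piv[(rater, readings[1])].dropna()
            common = a.index.intersection(b.index)
            k = cohen_kappa(a.loc[common], b.loc[common])
            out[f"intraobserver_{rater}"] = {"kappa": k.kappa, "se": k.se, "n": k.n}
    if len(raters) >= 2:
        r0, r1 = raters[:2]
        rd0 = sorted(rd for r, rd in piv.columns if r == r0)[0]
        rd1 = sorted(rd for r, rd in piv.columns if r == r1)[0]
        a = piv[(r0, rd0)].dropna()
        b = piv[(r1, rd1)].dropna()
        common = a.index.intersection(b.index)
        k = cohen_kappa(a.loc[common], b.loc[common])
        out["interobserver"] = {"kappa": k.kappa, "se": k.se, "n": k.n}
    return out


def run_cohort_analysis(
    cohort: pd.DataFrame,
    ratings: pd.DataFrame | None = None,
) -> StatsReport:
    """Compute the full per-method summary and comparison test battery.

    Deterministic given the table: no step draws random numbers.
    """
    validate_cohort(cohort)
    report = StatsReport()
    wide_e = cohort.pivot(index="knee_id", columns="method", values="max_extrusion_mm")
    wide_l = cohort.pivot(index="knee_id", columns="method", values="location_ap_mm")
    report.n_knees = len(wide_e)

    for method in METHODS:
        sub = cohort[cohort["method"] == method]
        report.per_method[method] = {
            **{f"max_extrusion_{k}": v for k, v in _summaries(sub["max_extrusion_mm"]).items()},
            **{f"location_ap_{k}": v for k, v in _summaries(sub["location_ap_mm"]).items()},
            **{f"location_pct_{k}": v for k, v in _summaries(sub["location_pct"]).items()},
            "n_extruded": int(sub["extruded"].astype(bool).sum()),
            "n": int(len(sub)),
        }

    pairs = [(a, b) for i, a in enumerate(METHODS) for b in METHODS[i + 1 :]]
    for a, b in pairs:
        key = f"{a}_vs_{b}"
        try:
            report.wilcoxon_location[key] = wilcoxon_signed_rank(wide_l[a], wide_l[b])
        except DegenerateTestError:
            report.wilcoxon_location[key] = (math.nan, math.nan)
        try:
            report.wilcoxon_extrusion[key] = wilcoxon_signed_rank(wide_e[a], wide_e[b])
        except DegenerateTestError:
            report.wilcoxon_extrusion[key] = (math.nan, math.nan)
        try:
            report.spearman_extrusion[key] = spearman_rho(wide_e[a], wide_e[b])
        except DegenerateTestError:
            report.spearman_extrusion[key] = (math.nan, math.nan)

    if len(wide_e) >= 3:
        report.friedman_extrusion = friedman_test(wide_e[list(METHODS)].to_numpy())
        report.friedman_location = friedman_test(wide_l[list(METHODS)].to_numpy())

    if ratings is not None:
        report.kappa = kappa_from_ratings(ratings)
    return report
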