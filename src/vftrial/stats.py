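"""The trial's statistical battery and report.

All tests are two-sided.  Conventions match the trial's analysis plan:

* normality gating by Shapiro–Wilk at alpha = 0.05, applied to paired
  differences for within-group comparisons;
* Pearson chi-square on 2x2 tables **without** continuity correction;
* Fisher's exact test with the two-sided probability-mass rule (sum of
  hypergeometric probabilities of all tables, at fixed margins, no more
  probable than the observed one);
* Mann–Whitney U with exact enumeration for small samples (both n <= 8)
  and the tie-corrected normal approximation otherwise;
* Wilcoxon signed-rank dropping zero differences (Wilcoxon's rule).

Computations delegate to scipy.stats; this module fixes the variants and
packages results uniformly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

from .scoring import OutcomeRecord

GATE_ALPHA = 0.05
#: Largest per-group n at which Mann-Whitney switches to exact enumeration.
EXACT_MWU_MAX_N = 8


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    test_name: str
    statistic: float
    p_value: float
    n: int
    sidedness: str = "two-sided"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    def as_dict(self) -> dict:
        return {
            "test": self.test_name,
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "p_formatted": format_p(self.p_value),
            "n": int(self.n),
            "sidedness": self.sidedness,
        }


@dataclass(frozen=True)
class ContingencyTable:
    """A 2x2 count table with optional axis labels."""

    counts: tuple[tuple[int, int], tuple[int, int]]
    row_labels: tuple[str, str] = ("row0", "row1")
    col_labels: tuple[str, str] = ("col0", "col1")

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (2, 2):
            raise ValueError("contingency table must be 2x2")
        if (arr < 0).any():
            raise ValueError("contingency table counts must be nonnegative")
        if arr.sum() == 0:
            raise ValueError("contingency table must have a positive total")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=int)


def _as_table(t) -> ContingencyTable:
    if isinstance(t, ContingencyTable):
        return t
    return ContingencyTable(counts=tuple(tuple(int(x) for x in row) for row in t))


def format_p(p: float) -> str:
    """Report-style p-value: 2 decimals with '<.001' and '>.99' conventions."""
    if p < 0.001:
        return "<.001"
    if p > 0.99:
        return ">.99"
    return f"{p:.2f}".lstrip("0")


def shapiro_wilk_gate(
    sample: Sequence[float], alpha: float = GATE_ALPHA
) -> Literal["parametric", "nonparametric"]:
    """Route to a parametric test iff Shapiro-Wilk does not reject normality."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError(f"Shapiro-Wilk needs n >= 3, got n = {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk is undefined for a constant sample")
    p = sps.shapiro(x).pvalue
    return "parametric" if p >= alpha else "nonparametric"


def chi_square_2x2(t) -> TestResult:
    """Pearson chi-square on a 2x2 table, df = 1, no continuity correction."""
    table = _as_table(t)
    arr = table.array
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("chi-square requires positive row and column margins")
    res = sps.chi2_contingency(arr, correction=False)
    return TestResult("pearson_chi2", float(res.statistic), float(res.pvalue),
                      n=int(arr.sum()))


def fisher_exact_2x2(t) -> TestResult:
    """Fisher's exact test, two-sided by the probability-mass rule."""
    table = _as_table(t)
    res = sps.fisher_exact(table.array, alternative="two-sided")
    return TestResult("fisher_exact", float(res.statistic), float(res.pvalue),
                      n=int(table.array.sum()))


def _check_sample(x: np.ndarray, name: str, min_n: int = 2) -> None:
    if x.size < min_n:
        raise ValueError(f"{name}: need n >= {min_n}, got {x.size}")


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U.

    Exact enumeration when both groups have n <= 8 (a permutation method is
    used when ties preclude the closed-form exact distribution); otherwise
    the tie-corrected normal approximation with continuity correction.
    """
    x, y = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    _check_sample(x, "mann_whitney_u group a")
    _check_sample(y, "mann_whitney_u group b")
    if max(x.size, y.size) <= EXACT_MWU_MAX_N:
        has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
        if has_ties:
            # full enumeration: n_resamples exceeds C(16, 8) = 12870
            method = sps.PermutationMethod(n_resamples=15000, rng=0)
        else:
            method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult("mann_whitney_u", float(res.statistic), float(res.pvalue),
                      n=x.size + y.size)


def wilcoxon_signed_rank(
    pre: Sequence[float], post: Sequence[float]
) -> TestResult:
    """Two-sided Wilcoxon signed-rank on post - pre, zero differences dropped."""
    x, y = np.asarray(pre, dtype=float), np.asarray(post, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = y - x
    nonzero = d[d != 0]
    if nonzero.size == 0:
        raise ValueError("Wilcoxon signed-rank undefined: all differences are zero")
    res = sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided")
    return TestResult("wilcoxon_signed_rank", float(res.statistic),
                      float(res.pvalue), n=int(nonzero.size))


def paired_t(pre: Sequence[float], post: Sequence[float]) -> TestResult:
    x, y = np.asarray(pre, dtype=float), np.asarray(post, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    _check_sample(x, "paired_t")
    if np.ptp(y - x) == 0 and (y - x)[0] == 0:
        raise ValueError("paired t undefined: all differences are zero")
    res = sps.ttest_rel(y, x)
    return TestResult("paired_t", float(res.statistic), float(res.pvalue),
                      n=x.size)


def independent_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    x, y = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    _check_sample(x, "independent_t group a")
    _check_sample(y, "independent_t group b")
    res = sps.ttest_ind(x, y)
    return TestResult("independent_t", float(res.statistic), float(res.pvalue),
                      n=x.size + y.size)


# ---------------------------------------------------------------------------
# Trial-level analysis

ARMS = ("NV", "NV-C")


def _within_group(pre: np.ndarray, post: np.ndarray) -> TestResult | None:
    """Pre/post comparison gated on the paired differences."""
    d = post - pre
    if np.ptp(d) == 0 and (d.size == 0 or d[0] == 0):
        return None  # degenerate: no change in any patient
    try:
        gate = shapiro_wilk_gate(d)
    except ValueError:
        gate = "nonparametric"
    if gate == "parametric":
        return paired_t(pre, post)
    return wilcoxon_signed_rank(pre, post)


def _between_group(a: np.ndarray, b: np.ndarray) -> TestResult:
    """Between-arm comparison of deltas, gated on both samples."""
    try:
        gates = {shapiro_wilk_gate(a), shapiro_wilk_gate(b)}
    except ValueError:
        gates = {"nonparametric"}
    if gates == {"parametric"}:
        return independent_t(a, b)
    return mann_whitney_u(a, b)


def analyze_trial(outcomes: Sequence[OutcomeRecord]) -> dict:
    """Run the full outcome battery and return a nested report dict.

    Per region (defective hemifield, whole field):

    * between-arm Mann-Whitney U on improved areas (primary outcome);
    * within-arm pre/post MTD (paired t or Wilcoxon per the normality gate
      on the paired differences);
    * between-arm comparison of MTD changes (independent t or Mann-Whitney
      per the gate on each arm's deltas);
    * responder counts and percentages per arm.
    """
    by_arm = {arm: [o for o in outcomes if o.arm == arm] for arm in ARMS}
    for arm, recs in by_arm.items():
        if len(recs) < 2:
            raise ValueError(f"arm {arm} has fewer than 2 patients")

    report: dict = {"n_per_arm": {arm: len(v) for arm, v in by_arm.items()},
                    "regions": {}}
    for region, area_attr, pre_attr, post_attr, delta_attr, resp_attr in (
        ("hemifield", "improved_area_hemi_deg2", "mtd_pre_hemi",
         "mtd_post_hemi", "mtd_delta_hemi", "responder_hemi"),
        ("whole", "improved_area_whole_deg2", "mtd_pre_whole",
         "mtd_post_whole", "mtd_delta_whole", "responder_whole"),
    ):
        arm_arrays = {
            arm: {
                "area": np.array([getattr(o, area_attr) for o in recs], float),
                "pre": np.array([getattr(o, pre_attr) for o in recs], float),
                "post": np.array([getattr(o, post_attr) for o in recs], float),
                "delta": np.array([getattr(o, delta_attr) for o in recs], float),
                "resp": np.array([getattr(o, resp_attr) for o in recs], bool),
            }
            for arm, recs in by_arm.items()
        }
        a, b = (arm_arrays[arm] for arm in ARMS)
        within = {
            arm: (r.as_dict() if (r := _within_group(v["pre"], v["post"]))
                  else None)
            for arm, v in arm_arrays.items()
        }
        section = {
            "improved_area_between": mann_whitney_u(
                a["area"], b["area"]).as_dict(),
            "mtd_within": within,
            "mtd_delta_between": _between_group(
                a["delta"], b["delta"]).as_dict(),
            "improved_area_mean_deg2": {
                arm: float(v["area"].mean()) for arm, v in arm_arrays.items()
            },
            "mtd_mean": {
                arm: {"pre": float(v["pre"].mean()),
                      "post": float(v["post"].mean()),
                      "delta": float(v["delta"].mean())}
                for arm, v in arm_arrays.items()
            },
            "responders": {
                arm: {
                    "count": int(v["resp"].sum()),
                    "n": int(v["resp"].size),
                    "pct": float(100.0 * v["resp"].mean()),
                }
                for arm, v in arm_arrays.items()
            },
        }
        report["regions"][region] = section
    return report


def flow_summary(
    randomized: tuple[int, int], dropped: tuple[int, int]
) -> dict:
    """Participant-flow arithmetic and the dropout comparison.

    Returns per-arm completed counts, the overall completion percentage
    (one decimal) and the Fisher exact test on dropped-vs-completed by arm.
    """
    randomized = tuple(int(x) for x in randomized)
    dropped = tuple(int(x) for x in dropped)
    if any(x < 0 for x in randomized + dropped):
        raise ValueError("counts must be nonnegative")
    if any(d > r for r, d in zip(randomized, dropped)):
        raise ValueError("dropped cannot exceed randomized")
    completed = tuple(r - d for r, d in zip(randomized, dropped))
    completion_pct = round(100.0 * sum(completed) / sum(randomized), 1)
    dropout_test = fisher_exact_2x2(
        [[dropped[0], completed[0]], [dropped[1], completed[1]]]
    )
    return {
        "randomized": dict(zip(ARMS, randomized)),
        "dropped": dict(zip(ARMS, dropped)),
        "completed": dict(zip(ARMS, completed)),
        "completion_pct": completion_pct,
        "dropout_test": dropout_test.as_dict(),
    }


# ---------------------------------------------------------------------------
# Report rendering


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2)


def report_to_markdown(report: dict) -> str:
    """Render the analyze_trial report as a compact Markdown document."""
    lines = ["# Trial outcome report", ""]
    lines.append("| arm | n |")
    lines.append("|---|---|")
    for arm, n in report["n_per_arm"].items():
        lines.append(f"| {arm} | {n} |")
    for region, sec in report["regions"].items():
        title = ("Defective hemifield" if region == "hemifield"
                 else "Whole field")
        lines += ["", f"## {title}", ""]
        t = sec["improved_area_between"]
        means = sec["improved_area_mean_deg2"]
        mean_txt = ", ".join(f"{arm} {m:.1f}" for arm, m in means.items())
        lines.append(
            f"- Improved area (deg^2): mean {mean_txt}; between-arm "
            f"{t['test']} p = {t['p_formatted']}"
        )
        for arm, res in sec["mtd_within"].items():
            mm = sec["mtd_mean"][arm]
            if res is None:
                lines.append(
                    f"- {arm} MTD pre {mm['pre']:.2f} -> post {mm['post']:.2f} dB:"
                    " no change in any patient (test not applicable)"
                )
            else:
                lines.append(
                    f"- {arm} MTD pre {mm['pre']:.2f} -> post {mm['post']:.2f} dB: "
                    f"{res['test']} p = {res['p_formatted']}"
                )
        t = sec["mtd_delta_between"]
        lines.append(
            f"- MTD change between arms: {t['test']} p = {t['p_formatted']}"
        )
        resp = sec["responders"]
        resp_txt = ", ".join(
            f"{arm} {r['count']}/{r['n']} ({r['pct']:.1f}%)"
            for arm, r in resp.items()
        )
        lines.append(f"- Responders (MTD change > 0): {resp_txt}")
    return "\n".join(lines) + "\n"
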