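"""Decision-tree group comparison: normality gate, transform, test selection.

The procedure implemented here mirrors a common prespecified analysis plan
for small-animal group data:

1. Assess normality of every group with the D'Agostino-Pearson omnibus
   test. If any group fails and all values are positive, retry after a
   natural-log transform; the transform is kept only if it makes every
   group pass.
2. Assess equality of variances: F test (two normal groups), Bartlett
   (three or more normal groups), Brown-Forsythe — the median-centered
   Levene test — for non-normal data.
3. Select the test:

   ========  ==========  =========  ================================
   groups    normal      variances  test
   ========  ==========  =========  ================================
   2         yes         equal      unpaired two-tailed t
   2         yes         unequal    Welch t
   >=3       yes         equal      one-way ANOVA + Holm-Sidak
   >=3       yes         unequal    pairwise Welch t + Holm-Sidak
   >=3       no          equal      Kruskal-Wallis + Dunn
   >=3       no          unequal    permutation tests + Holm-Sidak
   ========  ==========  =========  ================================

   Two non-normal groups (a case the plan leaves open) fall through to the
   same non-normal branches, which degenerate gracefully for k = 2.

Every gate's statistic and p-value is recorded in a decision trace, so the
chosen test is fully replayable from the result object.

Usage follows the model/results idiom::

    model = GroupComparison({"WT": a, "J20": b, "KI": c})
    res = model.fit()
    print(res.summary())
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sst


@dataclass
class StatsConfig:
    """Knobs of the comparison pipeline.

    ``gate_alpha`` is the level of the normality/variance gates (distinct
    from the decision level ``alpha``); ``exact_enumeration_limit`` bounds
    the number of arrangements for which the permutation test enumerates
    exhaustively instead of sampling ``n_permutations`` label shuffles.
    """

    alpha: float = 0.05
    gate_alpha: float = 0.05
    n_permutations: int = 10000
    exact_enumeration_limit: int = 20000
    seed: int = 0
    log_transform_allowed: bool = True
    permutation_statistic: str = "mean_diff"  # mean_diff | welch_t

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1) or not (0 < self.gate_alpha < 1):
            raise ValueError("alpha levels must be in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")


@dataclass
class TestPlan:
    normal: dict[str, bool]
    transform_applied: bool
    variance_equal: bool
    chosen_test: str
    decision_trace: list[dict] = field(default_factory=list)

    @property
    def all_normal(self) -> bool:
        return all(self.normal.values())


@dataclass
class GroupComparisonResult:
    """Outcome of the full decision-tree comparison.

    ``comparisons`` has one row per group pair with the test statistic, the
    raw p-value and the multiplicity-adjusted p-value; ``global_p`` carries
    the omnibus p where the chosen test has one (ANOVA, Kruskal-Wallis).
    """

    plan: TestPlan
    comparisons: pd.DataFrame
    global_p: float | None
    config: StatsConfig
    group_sizes: dict[str, int]

    @property
    def significant(self) -> bool:
        """Family-wise decision: any adjusted pairwise p below alpha."""
        return bool((self.comparisons["p_adjusted"] < self.config.alpha).any())

    def summary(self) -> str:
        lines = [
            "Group comparison (decision-tree selection)",
            "=" * 58,
            f"groups: "
            + ", ".join(f"{g} (n={n})" for g, n in self.group_sizes.items()),
            f"normality: "
            + ", ".join(f"{g}={'yes' if v else 'no'}" for g, v in self.plan.normal.items())
            + (" [log-transformed]" if self.plan.transform_applied else ""),
            f"variances equal: {'yes' if self.plan.variance_equal else 'no'}",
            f"chosen test: {self.plan.chosen_test}",
        ]
        if self.global_p is not None:
            lines.append(f"omnibus p = {self.global_p:.4g}")
        lines.append("-" * 58)
        lines.append(f"{'comparison':<24}{'stat':>10}{'p raw':>12}{'p adj':>12}")
        for r in self.comparisons.itertuples():
            mark = " *" if r.p_adjusted < self.config.alpha else ""
            lines.append(
                f"{r.group_a + ' vs ' + r.group_b:<24}{r.statistic:>10.4g}"
                f"{r.p_raw:>12.4g}{r.p_adjusted:>12.4g}{mark}"
            )
        lines.append("-" * 58)
        lines.append("decision trace:")
        for step in self.plan.decision_trace:
            stat = step.get("statistic")
            p = step.get("p")
            bits = [f"  {step['gate']}: {step['outcome']}"]
            if stat is not None and not (isinstance(stat, float) and math.isnan(stat)):
                bits.append(f"stat={stat:.4g}")
            if p is not None and not (isinstance(p, float) and math.isnan(p)):
                bits.append(f"p={p:.4g}")
            lines.append(" ".join(bits))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# gates
# ---------------------------------------------------------------------------

def _dagostino_p(x: np.ndarray) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return float(sst.normaltest(x).pvalue)
        except ValueError:
            return 0.0  # degenerate (e.g. constant) -> treat as non-normal


def assess_normality(
    samples: Mapping[str, np.ndarray], config: StatsConfig = StatsConfig()
) -> tuple[dict[str, bool], bool, dict[str, np.ndarray], list[dict]]:
    """Per-group D'Agostino-Pearson gate with optional log rescue.

    Returns (per-group verdicts, transform_applied, working samples, trace).
    Groups below the omnibus test's minimum size (n < 8) are declared
    non-normal with a warning, failing toward the robust branches.
    """
    trace: list[dict] = []
    work = {g: np.asarray(v, dtype=float) for g, v in samples.items()}

    def gate(data: Mapping[str, np.ndarray], label: str) -> dict[str, bool]:
        verdict = {}
        for g, x in data.items():
            if len(x) < 8:
                warnings.warn(
                    f"group {g!r} too small for the normality test (n={len(x)} < 8); "
                    "treated as non-normal",
                    stacklevel=3,
                )
                verdict[g] = False
                trace.append(
                    {"gate": f"normality[{g}]{label}", "statistic": float("nan"),
                     "p": float("nan"), "outcome": "too small -> non-normal"}
                )
                continue
            p = _dagostino_p(x)
            verdict[g] = p >= config.gate_alpha
            trace.append(
                {"gate": f"normality[{g}]{label}", "statistic": float("nan"), "p": p,
                 "outcome": "normal" if verdict[g] else "non-normal"}
            )
        return verdict

    verdict = gate(work, "")
    if all(verdict.values()):
        return verdict, False, work, trace

    positive = all((x > 0).all() for x in work.values())
    if config.log_transform_allowed and positive:
        logged = {g: np.log(x) for g, x in work.items()}
        verdict_log = gate(logged, " (log)")
        if all(verdict_log.values()):
            trace.append({"gate": "log-transform", "statistic": None, "p": None,
                          "outcome": "applied (restores normality)"})
            return verdict_log, True, logged, trace
        trace.append({"gate": "log-transform", "statistic": None, "p": None,
                      "outcome": "tried, does not restore normality"})
    elif not positive:
        trace.append({"gate": "log-transform", "statistic": None, "p": None,
                      "outcome": "not attempted (non-positive values)"})
    return verdict, False, work, trace


def assess_variance(
    samples: Mapping[str, np.ndarray],
    normal: bool,
    config: StatsConfig = StatsConfig(),
) -> tuple[bool, dict]:
    """Equality-of-variance gate; returns (equal, trace step).

    Normal data: F test for two groups, Bartlett for three or more.
    Non-normal data: Brown-Forsythe (median-centered Levene). Groups with
    zero variance short-circuit to "unequal" with a warning.
    """
    arrs = [np.asarray(v, dtype=float) for v in samples.values()]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    if any(np.var(a) == 0 for a in arrs):
        warnings.warn("zero-variance group; variances treated as unequal", stacklevel=2)
        return False, {"gate": "variance", "statistic": float("nan"), "p": float("nan"),
                       "outcome": "zero-variance group -> unequal"}
    if normal and len(arrs) == 2:
        f = np.var(arrs[0], ddof=1) / np.var(arrs[1], ddof=1)
        dfn, dfd = len(arrs[0]) - 1, len(arrs[1]) - 1
        cdf = sst.f.cdf(f, dfn, dfd)
        p = 2 * min(cdf, 1 - cdf)
        name = "F test"
        stat = f
    elif normal:
        stat, p = sst.bartlett(*arrs)
        name = "Bartlett"
    else:
        stat, p = sst.levene(*arrs, center="median")
        name = "Brown-Forsythe"
    equal = bool(p >= config.gate_alpha)
    return equal, {"gate": f"variance ({name})", "statistic": float(stat),
                   "p": float(p), "outcome": "equal" if equal else "unequal"}


def select_test(
    samples: Mapping[str, np.ndarray], config: StatsConfig = StatsConfig()
) -> tuple[TestPlan, dict[str, np.ndarray]]:
    """Run both gates and map their outcomes to the test choice.

    Returns the plan plus the working samples (log-transformed when the
    transform was applied).
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    normal, transformed, work, trace = assess_normality(samples, config)
    all_normal = all(normal.values())
    var_equal, var_step = assess_variance(work, all_normal, config)
    trace = trace + [var_step]
    k = len(samples)
    if all_normal and var_equal:
        chosen = "t" if k == 2 else "anova_holm_sidak"
    elif all_normal:
        chosen = "welch_t" if k == 2 else "welch_t_holm_sidak"
    elif var_equal:
        chosen = "kruskal_wallis_dunn"
    else:
        chosen = "permutation_holm_sidak"
    trace.append({"gate": "test selection", "statistic": None, "p": None,
                  "outcome": chosen})
    return (
        TestPlan(
            normal=normal,
            transform_applied=transformed,
            variance_equal=var_equal,
            chosen_test=chosen,
            decision_trace=trace,
        ),
        work,
    )


# ---------------------------------------------------------------------------
# tests and corrections
# ---------------------------------------------------------------------------

def holm_sidak(p_values: Sequence[float]) -> np.ndarray:
    """Step-down Sidak adjustment.

    Sorted ascending, the i-th smallest p (1-based) becomes
    1 - (1 - p)^(m - i + 1); a running maximum enforces monotonicity and
    values are capped at 1 and restored to input order.
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def _perm_stat(a: np.ndarray, b: np.ndarray, kind: str) -> float:
    if kind == "welch_t":
        with np.errstate(divide="ignore", invalid="ignore"):
            t = sst.ttest_ind(a, b, equal_var=False).statistic
        return abs(float(t)) if np.isfinite(t) else 0.0
    return abs(float(a.mean() - b.mean()))


def permutation_test(
    a: Sequence[float], b: Sequence[float], config: StatsConfig = StatsConfig()
) -> float:
    """Two-sided label-permutation p for the difference of group means.

    Exact when the number of distinct arrangements C(n_a + n_b, n_a) is at
    most ``exact_enumeration_limit``; otherwise Monte-Carlo with
    ``n_permutations`` shuffles and the (count + 1) / (N + 1) estimator.
    Ties with the observed statistic count as at least as extreme.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need n >= 2")
    pooled = np.concatenate([a, b])
    na, n = len(a), len(pooled)
    obs = _perm_stat(a, b, config.permutation_statistic)
    tol = 1e-12 * max(1.0, obs)

    if math.comb(n, na) <= config.exact_enumeration_limit:
        count = 0
        total = 0
        idx_all = np.arange(n)
        for comb in itertools.combinations(range(n), na):
            sel = np.zeros(n, dtype=bool)
            sel[list(comb)] = True
            stat = _perm_stat(pooled[sel], pooled[~sel], config.permutation_statistic)
            count += stat >= obs - tol
            total += 1
        return count / total

    rng = np.random.default_rng(config.seed)
    count = 0
    for _ in range(config.n_permutations):
        perm = rng.permutation(pooled)
        count += _perm_stat(perm[:na], perm[na:], config.permutation_statistic) >= obs - tol
    return (count + 1) / (config.n_permutations + 1)


def _dunn_pairwise(samples: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based multiple comparisons after Kruskal-Wallis.

    z statistics on mean pooled ranks with the tie correction; the adjusted
    p multiplies the raw two-sided normal p by the number of comparisons
    (Bonferroni, the convention of Dunn's original procedure), capped at 1.
    """
    labels = list(samples)
    pooled = np.concatenate([samples[g] for g in labels])
    ranks = sst.rankdata(pooled)
    n_tot = len(pooled)
    splits = np.cumsum([len(samples[g]) for g in labels])[:-1]
    group_ranks = dict(zip(labels, np.split(ranks, splits)))
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12 * (n_tot - 1))) if n_tot > 1 else 0.0
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term

    rows = []
    pairs = list(itertools.combinations(labels, 2))
    for ga, gb in pairs:
        ra, rb = group_ranks[ga].mean(), group_ranks[gb].mean()
        se = math.sqrt(var_base * (1 / len(samples[ga]) + 1 / len(samples[gb])))
        z = (ra - rb) / se if se > 0 else 0.0
        p = 2 * sst.norm.sf(abs(z))
        rows.append({"group_a": ga, "group_b": gb, "statistic": z, "p_raw": p})
    df = pd.DataFrame(rows)
    df["p_adjusted"] = np.minimum(df["p_raw"] * len(pairs), 1.0)
    return df


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class GroupComparison:
    """Decision-tree comparison of two or more independent groups.

    Parameters
    ----------
    samples : mapping of group label to 1-D array of per-animal values
    config : StatsConfig
    """

    def __init__(self, samples: Mapping[str, Sequence[float]], config: StatsConfig | None = None):
        if len(samples) < 2:
            raise ValueError("need at least 2 groups")
        self.samples = {str(g): np.asarray(v, dtype=float) for g, v in samples.items()}
        for g, v in self.samples.items():
            if len(v) < 2:
                raise ValueError(f"group {g!r} needs n >= 2")
        self.config = config or StatsConfig()

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        value_col: str = "value",
        group_col: str = "group",
        config: StatsConfig | None = None,
    ) -> "GroupComparison":
        groups = {
            str(g): sub[value_col].to_numpy(dtype=float)
            for g, sub in df.groupby(group_col, sort=False)
        }
        return cls(groups, config)

    def fit(self) -> GroupComparisonResult:
        """Run gates, select the test, execute it with its correction."""
        plan, work = select_test(self.samples, self.config)
        labels = list(work)
        pairs = list(itertools.combinations(labels, 2))
        global_p: float | None = None
        rows = []

        if plan.chosen_test in ("t", "welch_t"):
            a, b = work[labels[0]], work[labels[1]]
            res = sst.ttest_ind(a, b, equal_var=(plan.chosen_test == "t"))
            rows = [{"group_a": labels[0], "group_b": labels[1],
                     "statistic": float(res.statistic), "p_raw": float(res.pvalue)}]
            comp = pd.DataFrame(rows)
            comp["p_adjusted"] = comp["p_raw"]
        elif plan.chosen_test == "anova_holm_sidak":
            global_p = float(sst.f_oneway(*work.values()).pvalue)
            for ga, gb in pairs:
                res = sst.ttest_ind(work[ga], work[gb], equal_var=True)
                rows.append({"group_a": ga, "group_b": gb,
                             "statistic": float(res.statistic), "p_raw": float(res.pvalue)})
            comp = pd.DataFrame(rows)
            comp["p_adjusted"] = holm_sidak(comp["p_raw"])
        elif plan.chosen_test == "welch_t_holm_sidak":
            for ga, gb in pairs:
                res = sst.ttest_ind(work[ga], work[gb], equal_var=False)
                rows.append({"group_a": ga, "group_b": gb,
                             "statistic": float(res.statistic), "p_raw": float(res.pvalue)})
            comp = pd.DataFrame(rows)
            comp["p_adjusted"] = holm_sidak(comp["p_raw"])
        elif plan.chosen_test == "kruskal_wallis_dunn":
            try:
                global_p = float(sst.kruskal(*work.values()).pvalue)
            except ValueError:  # all values identical
                global_p = 1.0
            comp = _dunn_pairwise(work)
        else:  # permutation_holm_sidak
            for ga, gb in pairs:
                p = permutation_test(work[ga], work[gb], self.config)
                delta = float(work[ga].mean() - work[gb].mean())
                rows.append({"group_a": ga, "group_b": gb, "statistic": delta, "p_raw": p})
            comp = pd.DataFrame(rows)
            comp["p_adjusted"] = holm_sidak(comp["p_raw"])

        return GroupComparisonResult(
            plan=plan,
            comparisons=comp,
            global_p=global_p,
            config=self.config,
            group_sizes={g: len(v) for g, v in self.samples.items()},
        )


def run_comparison(
    samples: Mapping[str, Sequence[float]], config: StatsConfig | None = None
) -> GroupComparisonResult:
    """Functional one-shot wrapper around :class:`GroupComparison`."""
    return GroupComparison(samples, config).fit()
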