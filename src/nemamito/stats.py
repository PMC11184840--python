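"""Life-trait and taxonomic-rank association statistics.

The battery mirrors a comparative-mitogenomics design: each genome
characteristic (length, %GC, skews, substitution rates) is tested against
categorical predictors -- life traits (feeding habit, habitat,
reproduction) and taxonomic ranks -- with a tie-corrected Kruskal-Wallis
test, stratified ("blocked") within each clade as well as pooled, with
epsilon-squared effect sizes (H/(n-1), a rank-based variance-explained
analogue), Benjamini-Hochberg FDR adjustment within each metric's test
family, and Dunn rank-sum post-hoc comparisons to localize group
differences.

Blocking is stratification: a separate test within each block level plus an
unblocked pooled test; a block whose predictor is constant (for example a
clade consisting entirely of animal parasites) is retained as a skipped
entry with its reason rather than dropped silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

MIN_GROUP_SIZE = 2


def kruskal_wallis(
    values: Sequence[float], labels: Sequence[str]
) -> tuple[float, int, float, dict[str, int], list[str]]:
    """Tie-corrected Kruskal-Wallis H test over labeled values.

    Missing values (None/NaN) and values with missing labels are dropped;
    groups smaller than :data:`MIN_GROUP_SIZE` after cleaning are dropped
    and reported.  Returns ``(H, df, p, group_ns, dropped_groups)``.  With
    fewer than two eligible groups a ValueError is raised (callers that
    stratify catch it and record the skip).  A fully tied dataset yields
    H = 0 treated as p = 1.
    """
    groups: dict[str, list[float]] = {}
    for v, lab in zip(values, labels):
        if lab is None or v is None:
            continue
        if isinstance(v, float) and math.isnan(v):
            continue
        groups.setdefault(str(lab), []).append(float(v))
    dropped = sorted(g for g, vs in groups.items() if len(vs) < MIN_GROUP_SIZE)
    eligible = {g: vs for g, vs in groups.items() if len(vs) >= MIN_GROUP_SIZE}
    if len(eligible) < 2:
        raise ValueError(
            f"fewer than 2 eligible groups (sizes {dict((g, len(v)) for g, v in groups.items())})"
        )
    samples = [np.asarray(eligible[g]) for g in sorted(eligible)]
    try:
        with np.errstate(invalid="ignore"):
            H, p = sps.kruskal(*samples)
    except ValueError:
        # all values identical: no rank variation
        H, p = 0.0, 1.0
    if math.isnan(H):
        H, p = 0.0, 1.0
    group_ns = {g: len(eligible[g]) for g in sorted(eligible)}
    return float(H), len(eligible) - 1, float(p), group_ns, dropped


def epsilon_squared(H: float, n: int) -> float:
    """Rank epsilon-squared effect size, H/(n-1), clipped to [0, 1]."""
    if n < 2:
        raise ValueError("epsilon_squared needs n >= 2")
    return min(1.0, max(0.0, H / (n - 1)))


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    ps = np.asarray(list(p_values), dtype=float)
    if ps.size == 0:
        return []
    if ((ps < 0) | (ps > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return list(sps.false_discovery_control(ps, method="bh"))


@dataclass
class TraitTest:
    """One (metric, grouping, block) Kruskal-Wallis result."""

    metric: str
    grouping: str
    block: str                      # block level, or "all" for the pooled test
    n: int = 0
    k: int = 0
    H: float | None = None
    df: int | None = None
    p_raw: float | None = None
    p_adj: float | None = None
    epsilon_sq: float | None = None
    group_ns: dict[str, int] = field(default_factory=dict)
    dropped_groups: list[str] = field(default_factory=list)
    skipped_reason: str | None = None


@dataclass(frozen=True)
class DunnResult:
    group_a: str
    group_b: str
    z: float
    p_raw: float
    p_adj: float


def dunn_posthoc(
    values: Sequence[float], labels: Sequence[str], adjust: str = "bh"
) -> list[DunnResult]:
    """Dunn pairwise post-hoc z tests on the joint ranks.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j)) with the
    tie term T = sum(t^3 - t) / (12 (N - 1)); two-sided normal p-values,
    BH-adjusted across pairs (``adjust=None`` skips adjustment).
    """
    clean = [
        (float(v), str(lab))
        for v, lab in zip(values, labels)
        if lab is not None and v is not None
        and not (isinstance(v, float) and math.isnan(v))
    ]
    vals = np.array([v for v, _ in clean])
    labs = [lab for _, lab in clean]
    group_names = sorted(set(labs))
    if len(group_names) < 2:
        raise ValueError("Dunn test needs >= 2 groups")
    N = len(vals)
    ranks = sps.rankdata(vals)
    _, tie_counts = np.unique(vals, return_counts=True)
    T = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (N - 1)))
    mean_rank = {g: ranks[[l == g for l in labs]].mean() for g in group_names}
    n_of = {g: labs.count(g) for g in group_names}
    results = []
    for a, b in combinations(group_names, 2):
        se = math.sqrt((N * (N + 1) / 12.0 - T) * (1.0 / n_of[a] + 1.0 / n_of[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        results.append((a, b, z, min(1.0, p)))
    p_adj = bh_fdr([r[3] for r in results]) if adjust == "bh" else [r[3] for r in results]
    return [
        DunnResult(a, b, z, p, pa)
        for (a, b, z, p), pa in zip(results, p_adj)
    ]


def blocked_tests(
    df: pd.DataFrame,
    metric: str,
    grouping: str,
    block: str | None,
) -> list[TraitTest]:
    """Stratified Kruskal-Wallis tests of one metric against one predictor.

    Runs one test per block level plus the pooled ("all") test.  Rows with
    a missing metric or predictor are excluded per test; ineligible strata
    are retained as skipped entries with the reason.  ``p_adj`` is left
    unset; family-wise FDR is applied by :func:`run_battery`.
    """
    subsets: list[tuple[str, pd.DataFrame]] = [("all", df)]
    if block is not None:
        for level in sorted(df[block].dropna().unique()):
            subsets.append((str(level), df[df[block] == level]))
    out = []
    for name, sub in subsets:
        test = TraitTest(metric=metric, grouping=grouping, block=name)
        try:
            H, dof, p, group_ns, dropped = kruskal_wallis(sub[metric], sub[grouping])
        except ValueError as exc:
            test.skipped_reason = str(exc)
            out.append(test)
            continue
        n = sum(group_ns.values())
        test.n, test.k = n, dof + 1
        test.H, test.df, test.p_raw = H, dof, p
        test.epsilon_sq = epsilon_squared(H, n)
        test.group_ns = group_ns
        test.dropped_groups = dropped
        out.append(test)
    return out


def run_battery(
    df: pd.DataFrame,
    metrics: Sequence[str],
    groupings: Sequence[str],
    block: str | None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full KW battery with per-metric FDR families and Dunn post-hocs.

    The FDR family is {one metric x all groupings x all block levels}; the
    family definition is recorded in the output.  Returns a tidy test table
    and a companion Dunn table (post-hocs run for tests with p_adj < 0.05).
    """
    all_tests: list[TraitTest] = []
    by_metric: dict[str, list[TraitTest]] = {}
    for metric in metrics:
        fam: list[TraitTest] = []
        for grouping in groupings:
            fam.extend(blocked_tests(df, metric, grouping, block))
        ran = [t for t in fam if t.p_raw is not None]
        for t, pa in zip(ran, bh_fdr([t.p_raw for t in ran])):
            t.p_adj = pa
        by_metric[metric] = fam
        all_tests.extend(fam)

    test_rows = []
    dunn_rows = []
    for t in all_tests:
        test_rows.append(
            {
                "metric": t.metric,
                "grouping": t.grouping,
                "block": t.block,
                "n": t.n,
                "k": t.k,
                "H": t.H,
                "df": t.df,
                "p_raw": t.p_raw,
                "p_adj": t.p_adj,
                "epsilon_sq": t.epsilon_sq,
                "group_ns": ";".join(f"{g}={n}" for g, n in t.group_ns.items()),
                "dropped_groups": ";".join(t.dropped_groups),
                "skipped_reason": t.skipped_reason,
                "fdr_family": f"metric={t.metric}",
            }
        )
        if t.p_adj is not None and t.p_adj < 0.05:
            sub = df if t.block == "all" else df[df[block] == t.block]
            try:
                for d in dunn_posthoc(sub[t.metric], sub[t.grouping]):
                    dunn_rows.append(
                        {
                            "metric": t.metric,
                            "grouping": t.grouping,
                            "block": t.block,
                            "group_a": d.group_a,
                            "group_b": d.group_b,
                            "z": d.z,
                            "p_raw": d.p_raw,
                            "p_adj": d.p_adj,
                        }
                    )
            except ValueError:
                pass
    tests_df = pd.DataFrame(
        test_rows,
        columns=[
            "metric", "grouping", "block", "n", "k", "H", "df",
            "p_raw", "p_adj", "epsilon_sq", "group_ns",
            "dropped_groups", "skipped_reason", "fdr_family",
        ],
    )
    dunn_df = pd.DataFrame(
        dunn_rows,
        columns=["metric", "grouping", "block", "group_a", "group_b", "z", "p_raw", "p_adj"],
    )
    return tests_df, dunn_df
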