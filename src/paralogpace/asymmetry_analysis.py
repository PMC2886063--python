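"""Distribution summaries, rank tests, fold-change grouping and
category-proportion tables over a set of gene-trio rate estimates.

The central container is the rate table: one row per trio carrying the
three pairwise dS/omega values (paralog pair A-B; the two ortholog pairs
A-C and B-C), the decomposed branch values for O->A, O->B, O->C, the
slow/fast branch omegas and the omega fold change.  Flagged (saturated /
undefined) cells are excluded from summaries, with exclusion counts logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

FOLD_HIGH_MIN = 3.0    # strictly greater -> high-asymmetry group
FOLD_LOW_MAX = 1.75    # strictly less -> low/no-asymmetry group

RATE_COLUMNS = [
    "query_id",
    "dS_AB", "dS_AC", "dS_BC", "omega_AB", "omega_AC", "omega_BC",
    "dS_OA", "dS_OB", "dS_OC", "omega_OA", "omega_OB", "omega_OC",
    "omega_slow", "omega_fast", "fold_change",
    "slow_branch", "saturated",
]


def rate_table(trio_results: Sequence[Mapping]) -> pd.DataFrame:
    """Flatten :func:`paralogpace.rate_estimator.trio_rates` results into the
    rate table."""
    rows = []
    for res in trio_results:
        br = res["branches"]
        slow = br.slow_branch
        omega_slow = omega_fast = float("nan")
        if slow is not None:
            omega_slow = br.omega_OA if slow == "OA" else br.omega_OB
            omega_fast = br.omega_OB if slow == "OA" else br.omega_OA
        rows.append({
            "query_id": res["query_id"],
            "dS_AB": res["pair_AB"].dS, "dS_AC": res["pair_AC"].dS,
            "dS_BC": res["pair_BC"].dS,
            "omega_AB": res["pair_AB"].omega, "omega_AC": res["pair_AC"].omega,
            "omega_BC": res["pair_BC"].omega,
            "dS_OA": br.dS_OA, "dS_OB": br.dS_OB, "dS_OC": br.dS_OC,
            "omega_OA": br.omega_OA, "omega_OB": br.omega_OB, "omega_OC": br.omega_OC,
            "omega_slow": omega_slow, "omega_fast": omega_fast,
            "fold_change": br.fold_change,
            "slow_branch": slow, "saturated": br.saturated,
        })
    return pd.DataFrame(rows, columns=RATE_COLUMNS)


@dataclass
class TestResult:
    H: float
    p: float
    n_per_group: tuple[int, ...]


def _clean(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    return v[np.isfinite(v)]


def summarize_distributions(table: pd.DataFrame, bins: int = 40) -> dict:
    """Medians (and histogram data) of the Figure-4-style quantities.

    Saturated rows are excluded throughout; all-flagged columns are omitted
    with a warning.
    """
    ok = table[~table["saturated"].astype(bool)]
    n_excluded = len(table) - len(ok)
    if n_excluded:
        logger.info("summaries exclude %d saturated trio(s)", n_excluded)
    quantities = {
        "paralog_dS": ok["dS_AB"],
        "ortholog1_dS": ok["dS_AC"],
        "ortholog2_dS": ok["dS_BC"],
        "ortholog_dS": pd.concat([ok["dS_AC"], ok["dS_BC"]]),
        "paralog_omega": ok["omega_AB"],
        "ortholog1_omega": ok["omega_AC"],
        "ortholog2_omega": ok["omega_BC"],
        "ortholog_omega": pd.concat([ok["omega_AC"], ok["omega_BC"]]),
        "branch_min_dS": np.minimum(ok["dS_OA"], ok["dS_OB"]),
        "branch_max_dS": np.maximum(ok["dS_OA"], ok["dS_OB"]),
        "branch_OA_dS": ok["dS_OA"],
        "branch_OB_dS": ok["dS_OB"],
        "ancestral_dS": ok["dS_OC"],
        "slow_omega": ok["omega_slow"],
        "fast_omega": ok["omega_fast"],
        "ancestral_omega": ok["omega_OC"],
    }
    medians, hists = {}, {}
    for name, vals in quantities.items():
        v = _clean(vals)
        if v.size == 0:
            logger.warning("column %s: no unflagged values; omitted", name)
            continue
        medians[name] = float(np.median(v))
        counts, edges = np.histogram(v, bins=bins)
        hists[name] = {"counts": counts, "bin_edges": edges}
    return {"n_trios": len(ok), "n_excluded": n_excluded,
            "medians": medians, "histograms": hists}


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal–Wallis rank test with tie correction; p from the chi-square
    upper tail with df = k - 1.  All-identical pooled data gives H=0, p=1."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    cleaned = [_clean(g) for g in groups]
    if any(g.size == 0 for g in cleaned):
        raise ValueError("a group has no finite values")
    pooled = np.concatenate(cleaned)
    if np.all(pooled == pooled[0]):
        return TestResult(H=0.0, p=1.0, n_per_group=tuple(len(g) for g in cleaned))
    H, p = stats.kruskal(*cleaned)
    return TestResult(H=float(H), p=float(p), n_per_group=tuple(len(g) for g in cleaned))


def fold_change_groups(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Partition trios by omega fold change between the post-duplication
    branches: high (> 3x), low (< 1.75x), middle (the rest).

    Infinite folds (omega_slow = 0 with omega_fast > 0) count as high;
    fully undefined folds are excluded and logged.
    """
    fold = table["fold_change"]
    defined = ~fold.isna()
    n_undef = int((~defined).sum())
    if n_undef:
        logger.info("fold grouping excludes %d trio(s) with undefined fold", n_undef)
    d = table[defined]
    f = d["fold_change"]
    high = d[(f > FOLD_HIGH_MIN) | np.isinf(f)]
    low = d[f < FOLD_LOW_MAX]
    middle = d[(f >= FOLD_LOW_MAX) & (f <= FOLD_HIGH_MIN)]
    return {"high": high, "low": low, "middle": middle, "n_undefined": n_undef}


def category_proportions(
    groups: Mapping[str, Sequence[str]],
    mapping: Mapping[str, str],
    aliases: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Count and percent of each group's genes per category.

    ``mapping`` takes gene id -> category; unmapped genes count as
    "unannotated".  ``aliases`` optionally collapses categories (e.g. several
    metabolic terms into "other metabolic process").  Percentages are
    count / group total x 100, one decimal.
    """
    aliases = aliases or {}
    rows: dict[str, dict[str, int]] = {}
    totals: dict[str, int] = {}
    for gname, genes in groups.items():
        genes = list(genes)
        if not genes:
            raise ValueError(f"group {gname!r} is empty")
        totals[gname] = len(genes)
        for g in genes:
            cat = mapping.get(g, "unannotated")
            cat = aliases.get(cat, cat)
            rows.setdefault(cat, {})[gname] = rows.setdefault(cat, {}).get(gname, 0) + 1
    out = []
    for cat in sorted(rows, key=lambda c: -sum(rows[c].values())):
        row = {"category": cat}
        for gname in groups:
            cnt = rows[cat].get(gname, 0)
            row[f"{gname}_count"] = cnt
            row[f"{gname}_pct"] = round(100.0 * cnt / totals[gname], 1)
        out.append(row)
    total_row = {"category": "Total"}
    for gname in groups:
        total_row[f"{gname}_count"] = totals[gname]
        total_row[f"{gname}_pct"] = 100.0
    out.append(total_row)
    return pd.DataFrame(out).set_index("category")
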