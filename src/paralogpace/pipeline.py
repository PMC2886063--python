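"""End-to-end drivers: trio file -> pairwise rates -> branch decomposition
-> distribution report."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import asymmetry_analysis as asym
from . import rate_estimator as rates
from .io_formats import GeneTrio, parse_trio_file
from .synthetic_data import TrioSimConfig, simulate_trio_set

logger = logging.getLogger(__name__)


def trios_to_rate_table(trios: Sequence[GeneTrio], method: str = "yn00") -> pd.DataFrame:
    results = [rates.trio_rates(t, method=method) for t in trios]
    return asym.rate_table(results)


def analysis_report(table: pd.DataFrame) -> dict:
    """Distribution medians, rank tests and fold-change group sizes."""
    summary = asym.summarize_distributions(table)
    ok = table[~table["saturated"].astype(bool)]

    def finite(col):
        import numpy as np
        v = ok[col].to_numpy(dtype=float)
        return v[np.isfinite(v)]

    tests = {
        "paralog_vs_ortholog1_omega": asym.kruskal_wallis(
            [finite("omega_AB"), finite("omega_AC")]),
        "paralog_vs_ortholog2_omega": asym.kruskal_wallis(
            [finite("omega_AB"), finite("omega_BC")]),
        "ortholog1_vs_ortholog2_omega": asym.kruskal_wallis(
            [finite("omega_AC"), finite("omega_BC")]),
        "slow_vs_ancestral_omega": asym.kruskal_wallis(
            [finite("omega_slow"), finite("omega_OC")]),
    }
    groups = asym.fold_change_groups(table)
    return {
        "n_trios": len(table),
        "summary": summary,
        "tests": tests,
        "fold_groups": {
            "high": len(groups["high"]), "low": len(groups["low"]),
            "middle": len(groups["middle"]), "undefined": groups["n_undefined"],
        },
        "fold_group_members": {k: list(groups[k]["query_id"]) for k in ("high", "low", "middle")},
    }


def supplement_report(path: str | Path, method: str = "yn00") -> dict:
    """Full analysis of an aligned gene-trio supplement file."""
    trios = parse_trio_file(path)
    table = trios_to_rate_table(trios, method=method)
    report = analysis_report(table)
    report["table"] = table
    return report


def synthetic_study_report(config: TrioSimConfig | None = None,
                           method: str = "yn00") -> dict:
    """Full analysis of a simulated study-scale trio set (the generator's
    defaults mirror the real study's 408 trios and branch medians)."""
    config = config or TrioSimConfig()
    trios, truth = simulate_trio_set(config)
    table = trios_to_rate_table(trios, method=method)
    report = analysis_report(table)
    report["table"] = table
    report["truth"] = truth
    return report
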