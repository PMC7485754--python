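"""Report layouts: baseline balance, utilization, and cost tables.

Mirrors the conventional claims-study presentation: a balance table with
pre- and post-matching standardized differences and significance tests, a
utilization table (counts, odds ratios) and a cost table (adjusted means
and differences), written as CSV plus a human-readable text rendering.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .matching import PROPENSITY_COVARIATES, _design, standardized_mean_differences


def balance_table(covariates: pd.DataFrame, trd: pd.Series,
                  matched_ids: set | None = None) -> pd.DataFrame:
    """Covariate means by arm with SMDs and p-values, pre and post matching."""
    cov = covariates.set_index("patient_id")
    trd = pd.Series(np.asarray(trd, dtype=bool), index=cov.index)

    def summarize(ids=None):
        sub = cov if ids is None else cov.loc[cov.index.isin(ids)]
        lab = trd.loc[sub.index]
        X = _design(sub.reset_index())[PROPENSITY_COVARIATES]
        rows = {}
        for col in X.columns:
            x1, x0 = X[col][lab.to_numpy()], X[col][~lab.to_numpy()]
            binary = set(np.unique(X[col])) <= {0.0, 1.0}
            if binary:
                table = [[x1.sum(), len(x1) - x1.sum()], [x0.sum(), len(x0) - x0.sum()]]
                try:
                    p = stats.chi2_contingency(table)[1]
                except ValueError:
                    p = np.nan
            else:
                p = stats.ttest_ind(x1, x0, equal_var=False).pvalue
            rows[col] = {"mean_trd": x1.mean(), "mean_control": x0.mean(), "p_value": p}
        out = pd.DataFrame(rows).T
        out["smd"] = standardized_mean_differences(sub.reset_index(), lab.to_numpy())
        return out

    pre = summarize().add_suffix("_pre")
    if matched_ids is None:
        return pre.reset_index(names="covariate")
    post = summarize(matched_ids).add_suffix("_post")
    return pre.join(post).reset_index(names="covariate")


def results_table(results: list) -> pd.DataFrame:
    """Flatten ModelResult objects into a tidy report table."""
    return pd.DataFrame([r.to_dict() for r in results])


def render_reports(outdir, balance: pd.DataFrame, utilization: pd.DataFrame,
                   costs: pd.DataFrame) -> list:
    """Write the three report tables as CSV and aligned text; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in (("table1_balance", balance),
                        ("table2_utilization", utilization),
                        ("table3_costs", costs)):
        csv_path = outdir / f"{name}.csv"
        table.to_csv(csv_path, index=False, float_format="%.6g")
        txt_path = outdir / f"{name}.txt"
        txt_path.write_text(
            table.to_string(index=False, float_format=lambda v: f"{v:.4g}") + "\n"
            if len(table) else ",".join(table.columns) + "\n")
        written += [csv_path, txt_path]
    return written
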