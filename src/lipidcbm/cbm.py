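"""Candidate-biomarker discovery across genotype-matched replicate comparisons.

A variable is a candidate biomarker (CBM) when, in at least two
genotype-matched replicate comparisons within one replicate set and one
ionisation mode, it simultaneously (a) clears a Student t-test at the
0.05/sqrt(n) threshold over the tissue's combined variable count and (b) is
selected by sparse PLS-DA on the same two groups.  Direction (up/down in the
second-listed group) must be consistent across the passing comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abundance import AbundanceTable, UNSATURATION_SPLIT
from .design import Comparison, StudyDesign
from .stats import pca_outlier_exclusion, splsda_select, ttest_matrix


def _mean_impute(frame: pd.DataFrame) -> pd.DataFrame:
    """Column-mean imputation; all-missing columns are dropped."""
    arr = frame.to_numpy(dtype=float, copy=True)
    nan = np.isnan(arr)
    if nan.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            col_mean = np.nanmean(arr, axis=0)
        rows, cols = np.where(nan)
        arr[rows, cols] = col_mean[cols]
        keep = ~np.isnan(arr).any(axis=0)
        return pd.DataFrame(arr[:, keep], index=frame.index,
                            columns=frame.columns[keep])
    return frame


@dataclass
class CbmConfig:
    splsda_ncomp: int = 2
    splsda_keepx: int = 10
    exclude_outliers: bool = True
    outlier_confidence: float = 0.95
    require_direction_consistency: bool = True


def run_comparison(values: pd.DataFrame, groups: pd.Series,
                   comparison: Comparison, threshold: float,
                   config: CbmConfig | None = None) -> pd.DataFrame:
    """Per-variable t-tests plus one sPLS-DA for a two-group comparison.

    ``values`` is samples × variables (per-mille abundances or metabolite
    concentrations, NaN = missing); ``groups`` maps the same sample index to
    group ids.  Samples flagged as outliers by PCA (Hotelling T² at 95% on
    two components) are excluded before testing.  Returns one row per
    variable: t, p, direction, passed_bonferroni (p strictly below the
    threshold), splsda_selected, passed_both.
    """
    config = config or CbmConfig()
    mask = groups.isin([comparison.group_a, comparison.group_b])
    sub = values.loc[mask.index[mask]]
    sub_groups = groups.loc[sub.index]

    if config.exclude_outliers and len(sub) >= 4:
        # multivariate steps need a complete matrix: mean-impute per variable
        filled = _mean_impute(sub)
        outliers = pca_outlier_exclusion(filled.to_numpy(), list(filled.index),
                                         config.outlier_confidence)
        if outliers:
            sub = sub.drop(index=outliers)
            sub_groups = sub_groups.drop(index=outliers)

    in_a = sub_groups == comparison.group_a
    in_b = sub_groups == comparison.group_b
    if in_a.sum() < 2 or in_b.sum() < 2:
        raise ValueError(
            f"comparison {comparison.name!r}: a group has <2 samples after "
            "outlier exclusion")

    t, p, diff = ttest_matrix(sub.loc[in_a].to_numpy(dtype=float),
                              sub.loc[in_b].to_numpy(dtype=float))
    direction = np.where(diff > 0, "up", np.where(diff < 0, "down", "zero"))

    filled = _mean_impute(sub)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = splsda_select(
            filled, [("b" if b else "a") for b in in_b.loc[filled.index]],
            n_components=config.splsda_ncomp, keepx=config.splsda_keepx)
    selected = set(model.selected_variables)

    out = pd.DataFrame({
        "t": t, "p": p, "direction": direction,
        "passed_bonferroni": (p < threshold) & ~np.isnan(p),
        "splsda_selected": [v in selected for v in values.columns],
    }, index=values.columns)
    out["passed_both"] = out["passed_bonferroni"] & out["splsda_selected"]
    out.attrs["comparison"] = comparison.name
    out.attrs["threshold"] = threshold
    out.attrs["n_samples"] = int(len(sub))
    return out


def run_replicate_set(abundance: AbundanceTable, design: StudyDesign,
                      replicate_set_id: str, threshold: float,
                      config: CbmConfig | None = None) -> dict[str, pd.DataFrame]:
    """Run every comparison of one replicate set on one abundance table."""
    comparisons = design.replicate_set(replicate_set_id)
    if len(comparisons) < 2:
        raise ValueError(f"replicate set {replicate_set_id!r} needs >=2 comparisons")
    groups = abundance.samples["group_id"]
    return {c.name: run_comparison(abundance.values, groups, c, threshold, config)
            for c in comparisons}


def discover_cbms(results: dict[str, pd.DataFrame],
                  config: CbmConfig | None = None) -> pd.DataFrame:
    """Aggregate per-comparison results into CBM verdicts.

    A variable is a CBM when it passed both tests in at least two
    comparisons, with a consistent direction across the passing comparisons
    (configurable).  Output is sorted by the number of passing comparisons,
    then by the largest absolute t-statistic.
    """
    config = config or CbmConfig()
    if len(results) < 2:
        raise ValueError("CBM discovery needs results from >=2 comparisons")
    names = list(results)
    index = results[names[0]].index
    for n in names[1:]:
        if not results[n].index.equals(index):
            raise ValueError("comparison results cover different variable sets "
                             "(were modes mixed in one call?)")

    rows = []
    for vid in index:
        passed = [n for n in names if bool(results[n].loc[vid, "passed_both"])]
        dirs = {results[n].loc[vid, "direction"] for n in passed}
        consistent = len(dirs) <= 1
        n_passed = len(passed)
        is_cbm = n_passed >= 2 and (consistent or not config.require_direction_consistency)
        direction = ""
        if n_passed and consistent:
            d = results[passed[0]].loc[vid, "direction"]
            direction = {"up": "UP", "down": "DOWN"}.get(d, "")
        ts = [abs(results[n].loc[vid, "t"]) for n in names]
        max_t = float(np.nanmax(ts)) if not all(np.isnan(ts)) else np.nan
        rows.append({"variable_id": vid, "comparisons_passed": ",".join(passed),
                     "n_passed": n_passed, "is_cbm": bool(is_cbm),
                     "direction": direction,
                     "direction_consistent": consistent, "max_abs_t": max_t})
    out = pd.DataFrame(rows).set_index("variable_id")
    return out.sort_values(["n_passed", "max_abs_t"], ascending=[False, False])


def cbm_report(cbms: pd.DataFrame, library, compartment: str,
               isoforms: dict | None = None) -> pd.DataFrame:
    """Typed summary table of CBM verdicts, one row per reported variable.

    Columns mirror a per-species biomarker table: saturation band, lipid
    name, assigned sn-1/sn-2 isoform with its share of total signal, the
    compartment (tissue), the CBM flag and the direction of change.
    """
    by_id = {v.variable_id: v for v in library}
    isoforms = isoforms or {}
    rows = []
    for vid, rec in cbms.iterrows():
        v = by_id.get(vid)
        band = ""
        name = vid
        if v is not None:
            name = v.name
            band = ("4 or more" if v.total_double_bonds >= UNSATURATION_SPLIT
                    else "3 or less")
        iso = isoforms.get(vid) or isoforms.get(name) \
            or {"isoform": "undetermined", "share": np.nan}
        share = iso.get("share", np.nan)
        iso_txt = (f"{iso['isoform']} ({share:.0f}%)"
                   if iso["isoform"] != "undetermined" and share == share
                   else iso["isoform"])
        rows.append({
            "saturation_band": band, "lipid": name, "isoform": iso_txt,
            "compartment": compartment,
            "cbm": "Y" if rec["is_cbm"] else "N",
            "change": rec["direction"] if rec["is_cbm"] else "n/a",
        })
    return pd.DataFrame(rows, columns=["saturation_band", "lipid", "isoform",
                                       "compartment", "cbm", "change"])
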