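"""PUFA-metabolite quantification: weighted calibration, LOD/LOQ censoring,
and CBM discovery on the concentration table.

Each compound carries a 10-level calibration ladder spanning 0.95-500 ng/mL.
Concentration-response curves are fitted by linear regression weighted 1/X
(variance grows with concentration, so low standards would otherwise be
swamped).  LOD is the lowest standard whose signal-to-noise exceeds 3, LOQ
the lowest exceeding 10; back-calculated sample concentrations below the LOQ
are censored (excluded, not imputed).  The quantified metabolites then pass
through the same candidate-biomarker workflow as the lipidomics data, with
the 0.05/sqrt(n) threshold taken over the number of quantified compounds.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cbm import CbmConfig, discover_cbms, run_comparison
from .design import StudyDesign
from .stats import bonferroni_sqrt_threshold

NEVER_DETECTED = ("LxB4", "RvD1", "RvD2", "LtB5", "5-6-DiHETE",
                  "14-15-EET", "11-12-EET")
PANEL_SIZE = 45


def load_panel() -> pd.DataFrame:
    """The packaged 45-compound panel definition, indexed by metabolite."""
    ref = importlib.resources.files("lipidcbm.data") / "pufa_panel.csv"
    with importlib.resources.as_file(ref) as path:
        panel = pd.read_csv(path).set_index("metabolite")
    panel["never_detected"] = panel["never_detected"].astype(bool)
    return panel


def validate_panel(panel: pd.DataFrame) -> None:
    if len(panel) != PANEL_SIZE:
        raise ValueError(f"panel must list {PANEL_SIZE} compounds, got {len(panel)}")
    nd = set(panel.index[panel["never_detected"].astype(bool)])
    if nd != set(NEVER_DETECTED):
        raise ValueError(
            f"never-detected set must be {sorted(NEVER_DETECTED)}, got {sorted(nd)}")


@dataclass
class CalibrationCurve:
    metabolite: str
    concentrations: np.ndarray
    responses: np.ndarray
    slope: float
    intercept: float
    lod: float | None        # ng/mL; None when never reaching S/N > 3
    loq: float | None
    detected: bool = True

    def __post_init__(self) -> None:
        if self.lod is not None and self.loq is not None and self.loq < self.lod:
            raise ValueError("LOQ must be >= LOD")


def fit_calibration(concentrations, responses, metabolite: str = "",
                    snr=None) -> CalibrationCurve:
    """Weighted (1/X) linear regression of response on concentration.

    Minimises sum over standards of (1/X_i) * (y_i - a - b*X_i)^2.  When
    per-level S/N values are supplied, LOD/LOQ are attached via
    :func:`estimate_lod_loq`.
    """
    import statsmodels.api as sm

    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 calibration standards")
    if np.any(x <= 0):
        raise ValueError("standard concentrations must be > 0 (1/X weighting)")
    if np.unique(x).size == 1:
        raise ValueError("standards at a single concentration cannot define a curve")
    model = sm.WLS(y, sm.add_constant(x), weights=1.0 / x).fit()
    intercept, slope = float(model.params[0]), float(model.params[1])
    lod = loq = None
    detected = True
    if snr is not None:
        lod, loq, detected = estimate_lod_loq(x, snr)
    return CalibrationCurve(metabolite, x, y, slope, intercept, lod, loq, detected)


def estimate_lod_loq(concentrations, snr_values):
    """(LOD, LOQ, detected) from the calibration ladder's S/N values.

    LOD is the lowest concentration with S/N strictly above 3, LOQ the lowest
    strictly above 10 (the literal 'lowest qualifying level' rule, applied on
    the ladder sorted by concentration even if S/N is non-monotone).  When no
    level clears S/N 3 the compound is flagged not detected.
    """
    x = np.asarray(concentrations, dtype=float)
    s = np.asarray(snr_values, dtype=float)
    order = np.argsort(x, kind="stable")
    x, s = x[order], s[order]
    lod_idx = np.nonzero(s > 3.0)[0]
    loq_idx = np.nonzero(s > 10.0)[0]
    if lod_idx.size == 0:
        return None, None, False
    lod = float(x[lod_idx[0]])
    loq = float(x[loq_idx[0]]) if loq_idx.size else None
    return lod, loq, True


def quantify(response: float, curve: CalibrationCurve):
    """Back-calculate one concentration; values below the LOQ are censored.

    Returns the concentration in ng/mL, or NaN when censored (below LOQ,
    or the compound never reached its LOD).
    """
    if curve.slope == 0:
        raise ValueError(f"{curve.metabolite}: zero slope, cannot invert")
    if not curve.detected or curve.loq is None:
        return float("nan")
    conc = (float(response) - curve.intercept) / curve.slope
    return conc if conc >= curve.loq else float("nan")


def calibrate_panel(standards: pd.DataFrame,
                    panel: pd.DataFrame) -> dict[str, CalibrationCurve]:
    """Fit one curve per panel compound from a long-format standards table
    (columns: metabolite, concentration, response, snr)."""
    curves = {}
    for met in panel.index:
        sub = standards[standards["metabolite"] == met]
        if sub.empty:
            raise ValueError(f"no calibration standards for {met}")
        curves[met] = fit_calibration(sub["concentration"], sub["response"],
                                      metabolite=met, snr=sub["snr"])
    return curves


def quantify_table(responses: pd.DataFrame,
                   curves: dict[str, CalibrationCurve]) -> pd.DataFrame:
    """Back-calculate a samples × metabolites response table; censored and
    never-detected entries become NaN."""
    meta_cols = [c for c in responses.columns if c not in curves]
    out = responses[meta_cols].copy()
    for met, curve in curves.items():
        if met not in responses.columns:
            continue
        if not curve.detected or curve.loq is None:
            out[met] = np.nan
            continue
        conc = (responses[met].astype(float) - curve.intercept) / curve.slope
        out[met] = conc.where(conc >= curve.loq)
    return out


def metabolite_cbm(concentrations: pd.DataFrame, design: StudyDesign,
                   replicate_set_id: str = "pregnancy",
                   config: CbmConfig | None = None,
                   min_presence: float = 0.5):
    """CBM discovery on a quantified metabolite table.

    ``concentrations`` is samples × metabolites with a ``group_id`` column
    and NaN marking censored values.  Metabolites quantified in fewer than
    ``min_presence`` of the samples are dropped with a warning; the
    remaining count n sets the 0.05/sqrt(n) threshold.  Returns
    ``(cbms, per_comparison_results, threshold)``.
    """
    config = config or CbmConfig()
    groups = concentrations["group_id"]
    values = concentrations.drop(columns=["group_id"])

    frac = values.notna().mean(axis=0)
    dropped = list(values.columns[frac < min_presence])
    if dropped:
        warnings.warn(f"dropping {len(dropped)} metabolite(s) quantified in "
                      f"<{min_presence:.0%} of samples: {dropped}")
        values = values.drop(columns=dropped)
    n_quantified = values.shape[1]
    threshold = bonferroni_sqrt_threshold(n_quantified)

    comparisons = design.replicate_set(replicate_set_id)
    if len(comparisons) < 2:
        raise ValueError("metabolite CBM needs >=2 replicate comparisons")
    results = {c.name: run_comparison(values, groups, c, threshold, config)
               for c in comparisons}
    cbms = discover_cbms(results, config)
    return cbms, results, threshold
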