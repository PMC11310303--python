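"""Signal annotation and the four retention filters of shotgun lipidomics QC.

A peak list is annotated against a theoretical library by accurate mass, then
every annotated variable must pass, in fixed order:

1. **ppm** — mass deviation from the theoretical m/z of at most 9 ppm
   (strictly more than 9 ppm discards);
2. **linearity** — Pearson correlation of intensity with the QC dilution
   factor (0.25/0.50/1.0) strictly above 0.75;
3. **snr** — median biological intensity over the per-variable noise estimate
   of at least 3 (strictly below 3 discards);
4. **presence** — a non-missing signal in at least 50% of biological samples,
   with zeros recoded as not measured.

The retained set is the intersection of the four passes; the recorded
rejection reason is the first failed criterion in the order above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lipids import LipidVariable

FILTER_ORDER = ("ppm", "linearity", "snr", "presence")


@dataclass
class SignalTable:
    """Raw intensity matrix for one ionisation mode.

    ``samples`` is indexed by sample_id with columns group_id / is_qc /
    qc_dilution; ``intensities`` is samples × variables with NaN as the
    missing sentinel; ``noise_level`` is the per-variable instrument noise
    estimate used by the S/N filter.
    """

    mode: str
    samples: pd.DataFrame
    intensities: pd.DataFrame
    noise_level: pd.Series
    library: list[LipidVariable] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.samples.index.equals(self.intensities.index):
            raise ValueError("sample list and intensity rows disagree")
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("intensities must be non-negative where present")
        qc = self.samples["is_qc"].astype(bool)
        if qc.any() and self.samples.loc[qc, "qc_dilution"].isna().any():
            raise ValueError("QC samples must carry a dilution factor")

    @property
    def biological(self) -> pd.DataFrame:
        return self.intensities.loc[~self.samples["is_qc"].astype(bool)]

    @property
    def qc_samples(self) -> pd.DataFrame:
        return self.intensities.loc[self.samples["is_qc"].astype(bool)]

    def subset_variables(self, variable_ids) -> "SignalTable":
        keep = list(variable_ids)
        lib = [v for v in self.library if v.variable_id in set(keep)]
        return SignalTable(self.mode, self.samples,
                           self.intensities[keep], self.noise_level[keep], lib)


def ppm_deviation(observed_mz: float, theoretical_mz: float) -> float:
    return abs(observed_mz - theoretical_mz) / theoretical_mz * 1e6


def annotate_peaks(peaks: pd.DataFrame, library: list[LipidVariable],
                   tolerance_ppm: float = 9.0):
    """Match observed peaks to library entries by minimal |ppm deviation|.

    ``peaks`` has one row per observed peak: an ``mz`` column plus per-sample
    intensity columns.  Each peak is assigned to the library entry minimising
    the absolute ppm deviation; assignments above ``tolerance_ppm`` are
    discarded.  When two peaks claim the same entry the closer wins and the
    other is logged as unassigned.  Returns ``(annotated, report)`` where
    ``annotated`` carries one row per annotated variable and ``report`` the
    per-variable ppm deviation with the ppm pass flag, plus the list of
    unassigned peak indices in ``report.attrs['unassigned_peaks']``.
    """
    if not library:
        raise ValueError("library must be non-empty")
    lib_mz = np.array([v.theoretical_mz for v in library])
    # stable ambiguity resolution: ties in ppm go to the lower theoretical m/z
    order = np.argsort(lib_mz, kind="stable")
    lib_sorted = [library[i] for i in order]
    lib_mz = lib_mz[order]

    assignments: dict[str, tuple[int, float]] = {}
    unassigned: list[int] = []
    for i, mz in enumerate(peaks["mz"].to_numpy(dtype=float)):
        dev = np.abs(mz - lib_mz) / lib_mz * 1e6
        j = int(np.argmin(dev))
        vid = lib_sorted[j].variable_id
        d = float(dev[j])
        if vid in assignments:
            prev_i, prev_d = assignments[vid]
            if d < prev_d:
                unassigned.append(prev_i)
                assignments[vid] = (i, d)
            else:
                unassigned.append(i)
        else:
            assignments[vid] = (i, d)

    rows, kept_vids, kept_peaks = [], [], []
    for v in lib_sorted:
        if v.variable_id not in assignments:
            continue
        i, d = assignments[v.variable_id]
        # 'more than 9 ppm' discards: exactly 9 passes; the relative guard
        # keeps the boundary decision stable against rounding in the ratio
        passed = d <= tolerance_ppm * (1.0 + 1e-9)
        rows.append({"variable_id": v.variable_id, "ppm_deviation": d,
                     "ppm_pass": passed})
        if passed:
            kept_vids.append(v.variable_id)
            kept_peaks.append(i)
    report = pd.DataFrame(rows).set_index("variable_id")
    report.attrs["unassigned_peaks"] = unassigned

    intensity_cols = [c for c in peaks.columns if c != "mz"]
    annotated = peaks.loc[kept_peaks, intensity_cols].copy()
    annotated.index = kept_vids
    return annotated, report


def qc_linearity_filter(intensities, dilutions, threshold: float = 0.75):
    """Pearson correlation of intensity with dilution factor; pass iff r > threshold.

    A zero-variance (flat) response leaves the correlation undefined and
    fails: a flat response is not linearly proportional to concentration.
    """
    x = np.asarray(dilutions, dtype=float)
    y = np.asarray(intensities, dtype=float)
    ok = ~np.isnan(y)
    x, y = x[ok], y[ok]
    if x.size < 3 or np.unique(x).size < 2:
        raise ValueError("need >=3 QC measurements over >=2 distinct dilutions")
    if np.ptp(y) == 0:
        return False, np.nan
    r = float(np.corrcoef(x, y)[0, 1])
    return r > threshold, r


def snr_filter(median_intensity: float, noise_level: float,
               threshold: float = 3.0):
    """Pass iff median biological intensity / noise >= threshold (< discards)."""
    if noise_level <= 0:
        raise ValueError("noise_level must be > 0")
    snr = float(median_intensity / noise_level)
    return snr >= threshold, snr


def presence_filter(values, threshold: float = 0.5):
    """Pass iff the fraction of non-missing biological samples >= threshold.

    Zeros are first recoded as missing (a zero reading means not measured).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one biological sample")
    present = np.sum(~np.isnan(v) & (v != 0.0))
    frac = float(present / v.size)
    return frac >= threshold, frac


@dataclass
class QCConfig:
    tolerance_ppm: float = 9.0
    linearity_threshold: float = 0.75
    snr_threshold: float = 3.0
    presence_threshold: float = 0.5


def run_qc_pipeline(peaks: pd.DataFrame, library: list[LipidVariable],
                    samples: pd.DataFrame, noise_level: pd.Series,
                    mode: str, config: QCConfig | None = None):
    """Annotate peaks and apply the four retention filters in fixed order.

    ``samples`` carries sample metadata (group_id / is_qc / qc_dilution) for
    the intensity columns of ``peaks``.  Returns ``(retained, report)``: a
    :class:`SignalTable` restricted to retained variables and a per-variable
    QC report with every metric, the retained flag and the rejection reason
    (the first failed criterion among ppm, linearity, snr, presence).
    Without QC samples the linearity stage is skipped and a prominent warning
    recorded in ``report.attrs['warnings']``.
    """
    config = config or QCConfig()
    annotated, ppm_report = annotate_peaks(peaks, library, config.tolerance_ppm)

    # annotation loses peaks rejected on mass accuracy; keep them in the report
    intensities = annotated.T  # samples × variables
    intensities = intensities.loc[samples.index]
    is_qc = samples["is_qc"].astype(bool)
    bio = intensities.loc[~is_qc]
    qc = intensities.loc[is_qc]
    dilutions = samples.loc[is_qc, "qc_dilution"].to_numpy(dtype=float)

    warns: list[str] = []
    has_qc = bool(is_qc.any())
    if not has_qc:
        warns.append("NO QC SAMPLES PRESENT: linearity filter skipped for all variables")
        warnings.warn(warns[-1])

    rows = []
    for v in library:
        vid = v.variable_id
        rec = {"variable_id": vid, "ppm_deviation": np.nan, "qc_correlation": np.nan,
               "snr": np.nan, "presence_fraction": np.nan,
               "retained": False, "rejection_reason": ""}
        if vid in ppm_report.index:
            rec["ppm_deviation"] = ppm_report.loc[vid, "ppm_deviation"]
        failures = []
        if vid not in intensities.columns:
            failures.append("ppm")
            rows.append(_finish(rec, failures))
            continue
        if has_qc:
            lin_pass, r = qc_linearity_filter(
                qc[vid].to_numpy(), dilutions, config.linearity_threshold)
            rec["qc_correlation"] = r
            if not lin_pass:
                failures.append("linearity")
        bio_v = bio[vid].to_numpy(dtype=float)
        bio_nonmissing = bio_v[~np.isnan(bio_v) & (bio_v != 0.0)]
        if bio_nonmissing.size:
            snr_pass, snr = snr_filter(
                float(np.median(bio_nonmissing)), float(noise_level[vid]),
                config.snr_threshold)
            rec["snr"] = snr
            if not snr_pass:
                failures.append("snr")
        else:
            failures.append("snr")
        pres_pass, frac = presence_filter(bio_v, config.presence_threshold)
        rec["presence_fraction"] = frac
        if not pres_pass:
            failures.append("presence")
        rows.append(_finish(rec, failures))

    report = pd.DataFrame(rows).set_index("variable_id")
    report.attrs["warnings"] = warns
    report.attrs["unassigned_peaks"] = ppm_report.attrs["unassigned_peaks"]

    retained_ids = list(report.index[report["retained"]])
    retained = SignalTable(
        mode=mode, samples=samples,
        intensities=intensities[retained_ids].astype(float),
        noise_level=noise_level[retained_ids],
        library=[v for v in library if v.variable_id in set(retained_ids)])
    return retained, report


def _finish(rec: dict, failures: list[str]) -> dict:
    ordered = [f for f in FILTER_ORDER if f in failures]
    rec["retained"] = not ordered
    rec["rejection_reason"] = ordered[0] if ordered else ""
    return rec
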