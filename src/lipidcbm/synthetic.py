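"""Synthetic DI-MS lipidomics cohorts and PUFA-metabolite datasets.

The generator emulates the structure of the targeted study — eight mouse
groups in three genotype-matched replicate comparison sets, two ionisation
modes, pooled QC samples at dilutions 0.25/0.50/1.0, log-normal signal
intensities — with a *truth ledger* recording every planted effect and every
decoy, so each downstream stage (QC filters, normalization, CBM discovery,
metabolite quantification) can be tested against known ground truth.

Intensity model
---------------
Biological sample intensities are log-normal: the natural-log intensity of
variable v in sample s is

    ln I = ln(baseline_v) + ln(2) * log2FC_v(group of s) + Normal(0, sigma_log)

with baselines drawn log-uniformly over three decades so the per-mille
normalization is exercised across magnitudes.  QC samples are a shared pooled
sample measured at each dilution factor d with expected intensity
d * baseline_v and small multiplicative noise.

Decoys
------
Each decoy violates exactly one retention criterion, with margin:
``ppm_offset`` peaks are displaced 12-30 ppm from their theoretical mass;
``low_snr`` variables carry a noise estimate putting the median S/N below 2.5;
``high_missingness`` variables are missing in >60% of biological samples;
``nonlinear_qc`` variables respond *inversely* to the QC dilution factor, so
their dilution-intensity correlation is negative and fails any positive
linearity threshold deterministically (a flat response would fail a
correlation gate only stochastically under noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .design import StudyDesign, default_design
from .lipids import LipidVariable, MZ_MAX, MZ_MIN, check_unique_keys, library_frame
from .qc import SignalTable

DECOY_KINDS = ("nonlinear_qc", "ppm_offset", "low_snr", "high_missingness")

# (carbon range, double-bond range) per class: the composition grids from
# which sum compositions are drawn.
CLASS_GRIDS: dict[str, tuple[range, range]] = {
    "PC": (range(28, 45), range(0, 9)),
    "PE": (range(28, 45), range(0, 9)),
    "PC-O": (range(30, 45), range(0, 8)),
    "LPC": (range(14, 25), range(0, 5)),
    "LPE": (range(14, 25), range(0, 5)),
    "LPS": (range(14, 25), range(0, 5)),
    "CL": (range(60, 81), range(2, 13)),
    "TG": (range(44, 63), range(0, 11)),
    "DG": (range(28, 45), range(0, 9)),
    "SM": (range(30, 45), range(0, 4)),
}

# class allocations reproducing the per-mode retained variable counts of the
# targeted liver (141 + 315) and plasma (100 + 212) datasets
LIVER_CLASS_COUNTS = {
    "positive": {"PC": 50, "TG": 40, "DG": 20, "SM": 15, "LPC": 16},
    "negative": {"PC": 80, "PE": 60, "TG": 70, "DG": 30, "SM": 25,
                 "LPC": 20, "LPE": 15, "CL": 15},
}
PLASMA_CLASS_COUNTS = {
    "positive": {"PC": 40, "TG": 30, "DG": 15, "SM": 15},
    "negative": {"PC": 60, "PE": 45, "TG": 45, "DG": 20, "SM": 20,
                 "LPC": 12, "LPE": 10},
}

_MIN_MZ_SPACING = 0.05  # Da within one mode; keeps annotation unambiguous


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the targeted study where it states values (group sizes
    6-8, QC dilutions, variable counts via the presets); dispersion and
    effect sizes are fixed realistic choices documented in the methods note.
    """

    n_per_group: int = 7
    n_variables_per_class: dict = field(
        default_factory=lambda: {m: dict(c) for m, c in LIVER_CLASS_COUNTS.items()}
    )
    sigma_log: float = 0.2          # SD of natural-log intensity, biological samples
    baseline_decades: float = 3.0   # spread of log10 baseline intensities
    qc_dilutions: tuple = (0.25, 0.50, 1.0)
    n_qc_per_dilution: int = 2
    missing_rate: float = 0.02      # baseline sporadic missingness
    sigma_qc: float = 0.05          # multiplicative noise on QC samples
    # planted class-level pregnancy effects (log2 fold change, pregnant side)
    tg_up: float = 0.5
    pc_high_db_up: float = 0.6
    pc_low_db_down: float = -0.6
    # planted species-level CBM effects; names as CLASS(C:DB)
    cbm_species: dict = field(default_factory=lambda: {
        "PC(38:6)": 1.0, "PC(40:6)": 1.0, "PE(40:6)": 1.0,
        "PC(34:2)": -1.0, "PC(36:3)": -1.0,
    })
    # planted maternal-genotype effects (applied to Dlk1-null dams)
    dlk1_species: dict = field(default_factory=lambda: {"PE(38:4)": -0.8})
    decoys_per_kind: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if tuple(sorted(self.qc_dilutions)) != (0.25, 0.50, 1.0):
            raise ValueError("qc_dilutions must be exactly (0.25, 0.50, 1.0)")
        if self.sigma_log <= 0:
            raise ValueError("sigma_log must be > 0")
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be >= 3")


def paper_like_config(tissue: str = "liver", decoys_per_kind: int = 10,
                      seed: int = 0, **overrides) -> GeneratorConfig:
    """Preset matching the study's per-mode retained variable counts.

    Decoy variables are generated *on top* of the per-mode counts (2 per
    decoy kind split over the two modes), so after QC exactly the configured
    clean counts survive: 141 + 315 = 456 for liver, 100 + 212 = 312 for
    plasma.
    """
    counts = {m: dict(c) for m, c in
              {"liver": LIVER_CLASS_COUNTS,
               "plasma": PLASMA_CLASS_COUNTS}[tissue].items()}
    for mode in counts:
        counts[mode]["PC"] += 2 * decoys_per_kind
    return GeneratorConfig(
        n_variables_per_class=counts,
        decoys_per_kind=decoys_per_kind, seed=seed, **overrides)


def null_config(config: GeneratorConfig) -> GeneratorConfig:
    """Same cohort with every planted effect removed (null simulations)."""
    return replace(config, tg_up=0.0, pc_high_db_up=0.0, pc_low_db_down=0.0,
                   cbm_species={}, dlk1_species={})


def planted_cbm_only_config(config: GeneratorConfig,
                            log2fc: float = 1.0) -> GeneratorConfig:
    """Only the named CBM species carry (±log2fc) effects; everything else
    is null.  Used for sensitivity (power) simulations."""
    species = {name: float(np.sign(lfc) * log2fc)
               for name, lfc in config.cbm_species.items()}
    return replace(null_config(config), cbm_species=species)


def fixture_config(seed: int = 0) -> GeneratorConfig:
    """A small 60-variable cohort (6 mice/group) used by the test suite."""
    # Class-wide effects are kept modest, species spikes strong, and the
    # baseline spread tight: per-mille normalization is compositional, so in
    # a 24-variable mode a dominant species or a large total-signal shift
    # would eat into the planted species' relative contrast.
    return GeneratorConfig(
        n_per_group=6,
        baseline_decades=1.5,
        n_variables_per_class={
            # 24 clean variables per mode plus 6 decoys per mode = 60 total
            "positive": {"PC": 16, "TG": 6, "DG": 4, "SM": 4},
            "negative": {"PC": 14, "PE": 8, "TG": 4, "LPC": 4},
        },
        tg_up=0.3, pc_high_db_up=0.2, pc_low_db_down=-0.2,
        cbm_species={"PC(38:6)": 1.5, "PC(40:6)": 1.5, "PE(40:6)": 1.5,
                     "PC(34:2)": -1.5, "PC(36:3)": -1.5},
        decoys_per_kind=3,
        seed=seed,
    )


@dataclass
class SyntheticTruth:
    """Ground-truth ledger: planted effects and decoy labels."""

    effects: dict = field(default_factory=dict)   # variable_id -> {kind: log2fc}
    decoys: dict = field(default_factory=dict)    # variable_id -> decoy kind
    seed: int = 0

    def __post_init__(self) -> None:
        overlap = set(self.effects) & set(self.decoys)
        if overlap:
            raise ValueError(f"variables both planted and decoy: {sorted(overlap)}")
        bad = set(self.decoys.values()) - set(DECOY_KINDS)
        if bad:
            raise ValueError(f"unknown decoy kinds: {sorted(bad)}")

    def frame(self) -> pd.DataFrame:
        rows = []
        for vid, eff in self.effects.items():
            for kind, lfc in eff.items():
                rows.append({"variable_id": vid, "record": "effect",
                             "kind": kind, "log2fc": lfc})
        for vid, kind in self.decoys.items():
            rows.append({"variable_id": vid, "record": "decoy",
                         "kind": kind, "log2fc": 0.0})
        return pd.DataFrame(rows, columns=["variable_id", "record", "kind", "log2fc"])


def _rng(config: GeneratorConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stage])


def build_library(config: GeneratorConfig) -> list[LipidVariable]:
    """Draw a theoretical lipid library per ionisation mode.

    Sum compositions are sampled without replacement from class-typical
    composition grids (species named in ``cbm_species``/``dlk1_species`` are
    force-included so planted effects always exist in the library), and
    theoretical m/z values are placed uniformly on [150, 1200] Da with a
    minimum spacing so accurate-mass annotation is unambiguous.
    """
    rng = _rng(config, 0)
    wanted = {**config.cbm_species, **config.dlk1_species}
    wanted_by_class: dict[str, list[tuple[int, int]]] = {}
    for name in wanted:
        cls, comp = name[:-1].split("(")
        c, db = comp.split(":")
        wanted_by_class.setdefault(cls, []).append((int(c), int(db)))

    library: list[LipidVariable] = []
    for mode, class_counts in config.n_variables_per_class.items():
        if not class_counts:
            raise ValueError("class vocabulary must be non-empty")
        n_mode = sum(class_counts.values())
        mz_values = _spaced_uniform(rng, n_mode)
        i = 0
        for cls in sorted(class_counts):
            count = class_counts[cls]
            crange, dbrange = CLASS_GRIDS[cls]
            grid = [(c, d) for c in crange for d in dbrange]
            if count > len(grid):
                raise ValueError(f"{cls}: requested {count} > grid size {len(grid)}")
            forced = [cd for cd in wanted_by_class.get(cls, []) if cd in grid]
            rest = [cd for cd in grid if cd not in forced]
            take = rng.choice(len(rest), size=max(0, count - len(forced)),
                              replace=False)
            combos = forced[:count] + [rest[j] for j in sorted(take)]
            for c, db in combos:
                library.append(LipidVariable(
                    variable_id=f"{mode[:3]}_{cls}_{c}_{db}",
                    lipid_class=cls, total_carbons=c, total_double_bonds=db,
                    mode=mode, theoretical_mz=float(mz_values[i])))
                i += 1
    check_unique_keys(library)
    return library


def _spaced_uniform(rng: np.random.Generator, n: int) -> np.ndarray:
    """n uniform draws on [150, 1200] with pairwise spacing >= 0.05 Da."""
    out: list[float] = []
    while len(out) < n:
        batch = rng.uniform(MZ_MIN + 1, MZ_MAX - 1, size=n)
        for v in batch:
            if all(abs(v - u) >= _MIN_MZ_SPACING for u in out):
                out.append(float(v))
                if len(out) == n:
                    break
    return np.array(rng.permutation(out))


def make_truth(library: list[LipidVariable], config: GeneratorConfig) -> SyntheticTruth:
    """Plant class- and species-level effects and designate decoys."""
    rng = _rng(config, 1)
    effects: dict[str, dict[str, float]] = {}

    def add(vid: str, kind: str, lfc: float) -> None:
        if lfc != 0.0:
            effects.setdefault(vid, {})[kind] = lfc

    for v in library:
        name = v.name
        if name in config.cbm_species:
            add(v.variable_id, "virgin_vs_pregnant", config.cbm_species[name])
        elif v.lipid_class == "TG":
            add(v.variable_id, "virgin_vs_pregnant", config.tg_up)
        elif v.lipid_class in ("PC", "PE"):
            lfc = (config.pc_high_db_up if v.total_double_bonds >= 4
                   else config.pc_low_db_down)
            add(v.variable_id, "virgin_vs_pregnant", lfc)
        if name in config.dlk1_species:
            add(v.variable_id, "maternal_effect", config.dlk1_species[name])

    decoys: dict[str, str] = {}
    if config.decoys_per_kind > 0:
        protected = set(config.cbm_species) | set(config.dlk1_species)
        modes = list(config.n_variables_per_class)
        # balanced allocation: kind i, replicate j goes to mode (i + j) mod m,
        # so with two modes each mode hosts 2 * decoys_per_kind decoys
        need: dict[str, list[str]] = {m: [] for m in modes}
        for i, kind in enumerate(DECOY_KINDS):
            for j in range(config.decoys_per_kind):
                need[modes[(i + j) % len(modes)]].append(kind)
        for mode in modes:
            eligible = [v.variable_id for v in library
                        if v.mode == mode and v.name not in protected]
            if len(need[mode]) > len(eligible):
                raise ValueError("not enough variables to host the requested decoys")
            chosen = rng.choice(len(eligible), size=len(need[mode]), replace=False)
            for kind, idx in zip(need[mode], sorted(chosen)):
                vid = eligible[idx]
                decoys[vid] = kind
                effects.pop(vid, None)  # decoys carry zero planted effect
    return SyntheticTruth(effects=effects, decoys=decoys, seed=config.seed)


def _group_log2fc(truth_effects: Mapping[str, float], group) -> float:
    """Total planted log2FC applying to one group for one variable."""
    total = 0.0
    for kind, lfc in truth_effects.items():
        if kind == "virgin_vs_pregnant" and group.pregnant:
            total += lfc
        elif kind == "fetal_effect" and group.fetal_dlk1 == "absent":
            total += lfc
        elif kind == "maternal_effect" and group.maternal_genotype == "null":
            total += lfc
    return total


def simulate_cohort(design: StudyDesign, truth: SyntheticTruth,
                    config: GeneratorConfig):
    """Generate per-mode signal tables and observed peak lists.

    Returns ``(tables, peaks, truth)`` where ``tables`` maps mode to a
    :class:`~lipidcbm.qc.SignalTable` (biological + QC samples) and ``peaks``
    maps mode to a peak-list DataFrame (one row per observed peak: observed
    m/z plus per-sample intensities) ready for accurate-mass annotation.
    """
    library = build_library(config)
    by_id = {v.variable_id: v for v in library}
    unknown = (set(truth.effects) | set(truth.decoys)) - set(by_id)
    if unknown:
        raise ValueError(f"truth references variables not in library: {sorted(unknown)}")
    for kind in {k for eff in truth.effects.values() for k in eff}:
        if kind == "virgin_vs_pregnant" and not any(g.pregnant for g in design.groups):
            raise ValueError("effect kind 'virgin_vs_pregnant' but design has no pregnant group")

    rng = _rng(config, 2)
    tables: dict[str, SignalTable] = {}
    peaks: dict[str, pd.DataFrame] = {}
    for mode in config.n_variables_per_class:
        mode_vars = [v for v in library if v.mode == mode]
        vids = [v.variable_id for v in mode_vars]
        p = len(mode_vars)

        bio_ids, bio_groups = [], []
        for g in design.groups:
            for i in range(config.n_per_group):
                bio_ids.append(f"g{g.group_id}_s{i + 1}")
                bio_groups.append(g.group_id)
        qc_ids, qc_dil = [], []
        for d in sorted(config.qc_dilutions):
            for i in range(config.n_qc_per_dilution):
                qc_ids.append(f"qc_{d:g}_{i + 1}")
                qc_dil.append(d)
        n_bio, n_qc = len(bio_ids), len(qc_ids)

        baseline = 10.0 ** rng.uniform(4.0, 4.0 + config.baseline_decades, size=p)
        snr_true = rng.uniform(5.0, 50.0, size=p)
        jitter_ppm = rng.uniform(-5.0, 5.0, size=p)
        for j, v in enumerate(mode_vars):
            kind = truth.decoys.get(v.variable_id)
            if kind == "low_snr":
                snr_true[j] = rng.uniform(1.2, 2.5)
            elif kind == "ppm_offset":
                jitter_ppm[j] = rng.choice([-1.0, 1.0]) * rng.uniform(12.0, 30.0)
        noise_level = baseline / snr_true

        log2fc = np.zeros((n_bio, p))
        for j, v in enumerate(mode_vars):
            eff = truth.effects.get(v.variable_id)
            if not eff:
                continue
            for s, gid in enumerate(bio_groups):
                log2fc[s, j] = _group_log2fc(eff, design.group(gid))
        ln_bio = (np.log(baseline)[None, :] + np.log(2.0) * log2fc
                  + rng.normal(0.0, config.sigma_log, size=(n_bio, p)))
        bio = np.exp(ln_bio)

        miss = rng.random((n_bio, p)) < config.missing_rate
        for j, v in enumerate(mode_vars):
            if truth.decoys.get(v.variable_id) == "high_missingness":
                k = int(np.floor(0.65 * n_bio))
                rows = rng.choice(n_bio, size=k, replace=False)
                miss[rows, j] = True
        bio[miss] = np.nan

        dil = np.array(qc_dil)
        response = dil[:, None] * np.ones((n_qc, p))
        for j, v in enumerate(mode_vars):
            if truth.decoys.get(v.variable_id) == "nonlinear_qc":
                # inverted dilution response: more dilute reads higher
                response[:, j] = 1.3 - 0.6 * dil
        qc = (baseline[None, :] * response
              * np.exp(rng.normal(0.0, config.sigma_qc, size=(n_qc, p))))

        intensities = pd.DataFrame(
            np.vstack([bio, qc]), index=bio_ids + qc_ids, columns=vids)
        samples = pd.DataFrame({
            "sample_id": bio_ids + qc_ids,
            "group_id": bio_groups + [pd.NA] * n_qc,
            "is_qc": [False] * n_bio + [True] * n_qc,
            "qc_dilution": [np.nan] * n_bio + qc_dil,
        }).set_index("sample_id")
        tables[mode] = SignalTable(
            mode=mode, samples=samples, intensities=intensities,
            noise_level=pd.Series(noise_level, index=vids),
            library=mode_vars)

        observed_mz = np.array([v.theoretical_mz for v in mode_vars])
        observed_mz = observed_mz * (1.0 + jitter_ppm * 1e-6)
        peak_df = intensities.T.copy()
        peak_df.insert(0, "mz", observed_mz)
        peaks[mode] = peak_df.reset_index(drop=True)
    return tables, peaks, truth


# --------------------------------------------------------------------------
# PUFA metabolites
# --------------------------------------------------------------------------

CALIBRATION_LADDER = (0.95, 1.95, 3.9, 7.8, 15.6, 31.3, 62.5, 125.0, 250.0, 500.0)


@dataclass
class MetaboliteGeneratorConfig:
    """Conditions for the metabolite panel simulation: a 10-level calibration
    ladder spanning 0.95-500 ng/mL per compound, multiplicative (CV-type)
    response noise, and planted pregnancy effects on selected metabolites."""

    response_cv: float = 0.04
    sigma_log_conc: float = 0.25
    # log2FC planted on pregnant groups; defaults mirror the six ARA-derived
    # pregnancy CBMs of the targeted study
    effects: dict = field(default_factory=lambda: {
        "PGD2": 1.0, "PGE2": 1.0, "PGF2a": 1.0, "TxB2": 1.0,
        "5-HETE": 1.0, "LxA4": 1.0,
    })
    seed: int = 0


def simulate_metabolites(design: StudyDesign, panel: pd.DataFrame,
                         config: MetaboliteGeneratorConfig):
    """Generate calibration standards and sample responses for the panel.

    ``panel`` is the 45-compound definition (see
    :func:`lipidcbm.metabolites.load_panel`); returns
    ``(responses, standards, truth)`` where standards hold per-metabolite
    (concentration, response, snr) ladders and responses is a samples ×
    metabolites DataFrame of instrument responses for biological samples.
    """
    from .metabolites import validate_panel

    validate_panel(panel)
    rng = np.random.default_rng([int(config.seed), 10])
    ladder = np.array(CALIBRATION_LADDER)

    std_rows = []
    slopes, intercepts, noise_floor = {}, {}, {}
    for met, row in panel.iterrows():
        slope = rng.uniform(5.0, 20.0)
        intercept = rng.uniform(0.0, 2.0)
        if row["never_detected"]:
            floor = slope * 1000.0       # even the top standard stays below S/N 3
        else:
            floor = slope * 3.9 / 10.0   # LOQ lands on the 3.9 ng/mL level
        slopes[met], intercepts[met], noise_floor[met] = slope, intercept, floor
        resp = (intercept + slope * ladder) * np.exp(
            rng.normal(0.0, config.response_cv, size=ladder.size))
        snr = slope * ladder / floor
        for c, r_, s_ in zip(ladder, resp, snr):
            std_rows.append({"metabolite": met, "concentration": c,
                             "response": r_, "snr": s_})
    standards = pd.DataFrame(std_rows)

    sample_ids, group_ids = [], []
    n_per = 7
    for g in design.groups:
        for i in range(n_per):
            sample_ids.append(f"g{g.group_id}_m{i + 1}")
            group_ids.append(g.group_id)

    base = {met: 10.0 ** rng.uniform(1.0, 2.0) for met in panel.index}
    resp = np.zeros((len(sample_ids), len(panel.index)))
    truth_conc = {}
    for j, met in enumerate(panel.index):
        lfc = config.effects.get(met, 0.0)
        for s, gid in enumerate(group_ids):
            g = design.group(gid)
            if panel.loc[met, "never_detected"]:
                resp[s, j] = noise_floor[met] * rng.uniform(0.5, 1.0)
                continue
            conc = base[met] * 2.0 ** (lfc if g.pregnant else 0.0)
            conc *= np.exp(rng.normal(0.0, config.sigma_log_conc))
            resp[s, j] = intercepts[met] + slopes[met] * conc
        truth_conc[met] = {"base": base[met], "log2fc": lfc}
    responses = pd.DataFrame(resp, index=sample_ids, columns=list(panel.index))
    responses.insert(0, "group_id", group_ids)
    truth = {"seed": config.seed, "metabolites": truth_conc}
    return responses, standards, truth
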