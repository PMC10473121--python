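"""Synthetic longitudinal matched-pair methylation cohorts with known truth.

The generator emulates the design of a prospective population-based AD
case-control study: ~50 matched case-control pairs, each sampled at up to
three visits spanning roughly 16 years before to 7 years after clinical AD
onset, profiled on an EPIC-style array (beta-values in [0, 1]).

Each CpG belongs to exactly one effect class:

``null``
    cell-mixture baseline plus noise only.
``stable``
    a constant case-minus-control offset of +/- ``effect_size_delta_beta``
    (the signal the longitudinal panel is built to find).
``interaction``
    a case-specific methylation drift over time-to-onset.
``crossover``
    a case-control difference whose sign flips at onset; the panel
    selection rule must exclude these.
``aging``
    methylation drifts with chronological age in everyone.
``clock``
    beta encodes chronological age linearly, so a bundled toy clock can
    track age (the clock-age correlation of the default configuration is
    calibrated to land near 0.75).

Beta-values are built as inverse-logit(logit(cell-mixture baseline) +
pair, subject and residual Gaussian noise), after which effect-class shifts
are applied on the beta scale and the result clipped to [0, 1].  All
randomness flows from a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .containers import BetaMatrix, SAMPLE_SHEET_COLUMNS

CELL_TYPES = ["granulocyte", "cd8t", "cd4t", "nk", "bcell", "monocyte"]

#: mean blood-cell composition used as the generator default
#: (granulocytes 60%, CD8 8%, CD4 14%, NK 6%, B 4%, monocytes 8%)
DEFAULT_CELL_PROPORTIONS = (0.60, 0.08, 0.14, 0.06, 0.04, 0.08)

_CLOCK_TARGET_CORR = 0.755  # midpoint of the clock-age correlation band


@dataclass
class CohortConfig:
    """Parameters of the synthetic longitudinal cohort.

    Defaults reproduce the study conditions the pipeline is designed for:
    50 matched pairs, three visits near (-13, -6, +2) years around onset
    with +/-2 years of uniform jitter truncated to [-16, +7], onset ages
    67-94, stable planted case-control differences of 8% methylation, and
    the six-component mean blood composition above.
    """

    n_pairs: int = 50
    visit_times: tuple[float, ...] = (-13.0, -6.0, 2.0)
    visit_jitter: float = 2.0
    n_cpgs: int = 2000
    n_stable_effect_cpgs: int = 20
    n_interaction_cpgs: int = 10
    n_crossover_cpgs: int = 10
    n_aging_cpgs: int = 30
    n_clock_cpgs: int = 20
    effect_size_delta_beta: float = 0.08
    onset_age_range: tuple[float, float] = (67.0, 94.0)
    cell_mean_proportions: tuple[float, ...] = DEFAULT_CELL_PROPORTIONS
    noise_sd_logit: float = 0.25
    subject_intercept_sd_logit: float = 0.15
    pair_intercept_sd_logit: float = 0.10
    # per-entry detection-failure rate; ~3e-5 reproduces the observed ~0.8%
    # of probes having any missing value across ~230 samples
    missing_rate: float = 3e-5
    n_pairs_no_post_onset: int = 2
    male_fraction: float = 0.18
    apoe_case_rate: float = 0.54
    apoe_control_rate: float = 0.196
    smoker_rate: float = 0.30
    hypo_fraction: float = 0.78  # fraction of planted effects hypomethylated in AD
    n_deconv_cpgs: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_pairs, self.n_cpgs, self.n_stable_effect_cpgs,
            self.n_interaction_cpgs, self.n_crossover_cpgs,
            self.n_aging_cpgs, self.n_clock_cpgs, self.n_pairs_no_post_onset,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        n_effect = (self.n_stable_effect_cpgs + self.n_interaction_cpgs
                    + self.n_crossover_cpgs + self.n_aging_cpgs + self.n_clock_cpgs)
        if n_effect + self.n_deconv_cpgs > self.n_cpgs:
            raise ValueError("effect + deconvolution CpGs exceed n_cpgs")
        if abs(sum(self.cell_mean_proportions) - 1.0) > 1e-9:
            raise ValueError("cell_mean_proportions must sum to 1")
        if not 0 < self.effect_size_delta_beta < 1:
            raise ValueError("effect_size_delta_beta must be in (0, 1)")
        if not all(-16.0 <= t <= 7.0 for t in self.visit_times):
            raise ValueError("visit times must lie within [-16, +7] years")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")

    @property
    def n_celltypes(self) -> int:
        return len(self.cell_mean_proportions)


@dataclass
class DemographicShift:
    """Demographic composition of a cross-sectional external cohort."""

    male_fraction: float = 0.43
    apoe_case_rate: float = 0.77
    apoe_control_rate: float = 0.23
    control_age_range: tuple[float, float] = (65.0, 91.0)
    case_age_range: tuple[float, float] = (66.0, 93.0)


@dataclass
class GroundTruth:
    """Per-CpG and per-sample truth channel for recovery tests."""

    probe_class: pd.Series          # probe -> effect class
    true_delta_beta: pd.Series      # probe -> planted case-control offset
    time_slope: pd.Series           # probe -> planted per-year slope
    cell_proportions: pd.DataFrame  # sample x cell type, rows sum to 1
    onset_age: pd.Series            # subject -> onset age (years)
    reference: pd.DataFrame         # CpG x cell-type reference mean beta
    clock_intercept: pd.Series      # clock probe -> beta at the anchor age
    clock_slope: pd.Series          # clock probe -> beta change per year
    deconv_probes: list[str] = field(default_factory=list)  # discriminating rows
    clock_anchor_age: float = 75.0

    def to_json(self, path) -> None:
        payload = {
            "probe_class": self.probe_class.to_dict(),
            "true_delta_beta": self.true_delta_beta.to_dict(),
            "time_slope": self.time_slope.to_dict(),
            "cell_proportions": self.cell_proportions.to_dict(orient="index"),
            "onset_age": self.onset_age.to_dict(),
            "reference": self.reference.to_dict(orient="index"),
            "clock_intercept": self.clock_intercept.to_dict(),
            "clock_slope": self.clock_slope.to_dict(),
            "clock_anchor_age": self.clock_anchor_age,
        }
        payload["deconv_probes"] = list(self.deconv_probes)
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            probe_class=pd.Series(d["probe_class"]),
            true_delta_beta=pd.Series(d["true_delta_beta"]),
            time_slope=pd.Series(d["time_slope"]),
            cell_proportions=pd.DataFrame.from_dict(d["cell_proportions"],
                                                    orient="index"),
            onset_age=pd.Series(d["onset_age"]),
            reference=pd.DataFrame.from_dict(d["reference"], orient="index"),
            clock_intercept=pd.Series(d["clock_intercept"], dtype=float),
            clock_slope=pd.Series(d["clock_slope"], dtype=float),
            deconv_probes=list(d["deconv_probes"]),
            clock_anchor_age=d["clock_anchor_age"],
        )


def _probe_ids(n: int, rng: np.random.Generator) -> list[str]:
    nums = np.sort(rng.choice(10**8, size=n, replace=False))
    return [f"cg{i:08d}" for i in nums]


def generate_reference_panel(n_cpgs: int, n_celltypes: int = 6,
                             seed: int = 0) -> pd.DataFrame:
    """Cell-type methylation reference for constrained deconvolution.

    A fifth of the rows (at least ``n_celltypes``) are discriminating: one
    cell type is shifted by >= 0.3 relative to the others, which guarantees
    linearly independent columns and identifiable deconvolution.  Remaining
    rows are near-constant across cell types.
    """
    if n_celltypes < 2:
        raise ValueError("need at least 2 cell types")
    if n_cpgs < n_celltypes:
        raise ValueError("need n_cpgs >= n_celltypes")
    rng = np.random.default_rng(seed)
    names = CELL_TYPES[:n_celltypes] if n_celltypes <= len(CELL_TYPES) else (
        CELL_TYPES + [f"cell_{i}" for i in range(len(CELL_TYPES), n_celltypes)]
    )[:n_celltypes]
    probes = _probe_ids(n_cpgs, rng)
    n_disc = max(n_celltypes, n_cpgs // 5)
    ref = np.empty((n_cpgs, n_celltypes))
    base = rng.uniform(0.15, 0.85, size=n_cpgs)
    ref[:] = base[:, None] + rng.normal(0, 0.01, size=ref.shape)
    # one discriminating block per cell type, cycling
    for i in range(n_disc):
        ct = i % n_celltypes
        lo = rng.uniform(0.05, 0.25)
        ref[i, :] = lo + rng.normal(0, 0.01, size=n_celltypes)
        ref[i, ct] = lo + rng.uniform(0.35, 0.6)
    ref = np.clip(ref, 0.0, 1.0)
    return pd.DataFrame(ref, index=probes, columns=names)


def _assign_classes(config: CohortConfig, probes: list[str]) -> pd.Series:
    classes = np.array(["null"] * config.n_cpgs, dtype=object)
    pos = 0
    for name, n in [
        ("stable", config.n_stable_effect_cpgs),
        ("interaction", config.n_interaction_cpgs),
        ("crossover", config.n_crossover_cpgs),
        ("aging", config.n_aging_cpgs),
        ("clock", config.n_clock_cpgs),
    ]:
        classes[pos:pos + n] = name
        pos += n
    return pd.Series(classes, index=probes, name="probe_class")


def clock_cpg_slope(config: CohortConfig) -> float:
    """Per-year beta slope of clock CpGs calibrating the toy clock.

    Derivation: each clock CpG yields the age estimate
    ``(beta - intercept) / slope`` with error sd approximately
    ``E[p(1-p)] * sd_logit_total / slope``; averaging K independent CpGs and
    requiring corr(clock, age) = r against the cohort's age spread gives
    ``slope = E[p(1-p)] * sd_tot / (sd_age * sqrt(1/r^2 - 1) * sqrt(K))``.
    """
    k = max(config.n_clock_cpgs, 1)
    sd_tot = float(np.sqrt(config.noise_sd_logit ** 2
                           + config.subject_intercept_sd_logit ** 2
                           + config.pair_intercept_sd_logit ** 2))
    # clock CpG baselines ~ U(0.3, 0.7): E[p(1-p)] = 1/4 - (E p^2 - 1/4) ...
    mean_pq = 0.25 - (0.4 ** 2) / 12.0 - 0.0  # E[p] = .5 -> E[p(1-p)] = .25 - var
    onset_lo, onset_hi = config.onset_age_range
    var_onset = (onset_hi - onset_lo) ** 2 / 12.0
    vt = np.asarray(config.visit_times, dtype=float)
    var_visits = vt.var() + config.visit_jitter ** 2 / 3.0
    sd_age = float(np.sqrt(var_onset + var_visits))
    r = _CLOCK_TARGET_CORR
    sigma_clock = sd_age * np.sqrt(1.0 / r**2 - 1.0)
    return float(mean_pq * sd_tot / (sigma_clock * np.sqrt(k)))


def _build_subjects(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """One row per blood sample; matched pairs share onset age and schedule."""
    rows = []
    for g in range(config.n_pairs):
        onset = rng.uniform(*config.onset_age_range)
        sex = "M" if rng.random() < config.male_fraction else "F"
        times = np.asarray(config.visit_times) + rng.uniform(
            -config.visit_jitter, config.visit_jitter, size=len(config.visit_times))
        times = np.clip(times, -16.0, 7.0)
        if g < config.n_pairs_no_post_onset:
            times = times[times < 0]
        apoe = (rng.random() < config.apoe_case_rate,
                rng.random() < config.apoe_control_rate)
        for is_case in (1, 0):
            sid = f"S{g:03d}{'A' if is_case else 'C'}"
            # controls inherit the case's onset age for the time axis and
            # sample within +/-0.5 y of the case's visits (matched design)
            offs = 0.0 if is_case else rng.uniform(-0.5, 0.5, size=len(times))
            smoker = int(rng.random() < config.smoker_rate)
            rtl0 = rng.normal(1.0, 0.12)
            rtl_slope = -0.006 - 0.002 * is_case + rng.normal(0, 0.001)
            for v, t in enumerate(np.clip(times + offs, -16.0, 7.0)):
                age = onset + t
                rows.append({
                    "sample_id": f"{sid}_v{v}",
                    "subject_id": sid,
                    "pair_id": f"P{g:03d}",
                    "ad": is_case,
                    "sex": sex,
                    "age": age,
                    "onset_age": onset,
                    "time": t,
                    "apoe_e4": int(apoe[0] if is_case else apoe[1]),
                    "smoker": smoker,
                    "rtl": rtl0 + rtl_slope * t + rng.normal(0, 0.02),
                })
    return pd.DataFrame(rows, columns=SAMPLE_SHEET_COLUMNS)


def _plant_effects(config: CohortConfig, rng: np.random.Generator,
                   probes: list[str], classes: pd.Series):
    """Draw per-CpG effect directions/magnitudes; return truth Series."""
    delta = pd.Series(0.0, index=probes)
    slope = pd.Series(0.0, index=probes)
    sign = lambda: -1.0 if rng.random() < config.hypo_fraction else 1.0
    for p in classes.index[classes == "stable"]:
        delta[p] = sign() * config.effect_size_delta_beta
    for p in classes.index[classes == "interaction"]:
        slope[p] = sign() * config.effect_size_delta_beta / 10.0
    for p in classes.index[classes == "crossover"]:
        delta[p] = sign() * config.effect_size_delta_beta  # pre-onset sign
    for p in classes.index[classes == "aging"]:
        s = 1.0 if rng.random() < 0.86 else -1.0
        slope[p] = s * rng.uniform(0.001, 0.003)
    return delta, slope


def _beta_matrix(config: CohortConfig, rng: np.random.Generator,
                 sheet: pd.DataFrame, probes: list[str], classes: pd.Series,
                 delta: pd.Series, slope: pd.Series, reference: pd.DataFrame,
                 props: pd.DataFrame, clock_int: pd.Series,
                 clock_slope: pd.Series, attenuation: float = 1.0,
                 anchor: float = 75.0) -> np.ndarray:
    """Assemble the beta matrix for a sample sheet with known cell props."""
    n_probes, n_samp = len(probes), len(sheet)
    baseline = reference.to_numpy() @ props.to_numpy().T  # probes x samples
    cls = classes.to_numpy()
    is_clock = cls == "clock"
    if is_clock.any():
        ages = sheet["age"].to_numpy()
        baseline[is_clock, :] = (
            clock_int.to_numpy()[:, None]
            + clock_slope.to_numpy()[:, None] * (ages - anchor)[None, :]
        )
    eps = 1e-4
    lg = logit(np.clip(baseline, eps, 1 - eps))
    pair_codes = pd.Categorical(sheet["pair_id"]).codes
    subj_codes = pd.Categorical(sheet["subject_id"]).codes
    pair_eff = rng.normal(0, config.pair_intercept_sd_logit,
                          size=(n_probes, pair_codes.max() + 1))
    subj_eff = rng.normal(0, config.subject_intercept_sd_logit,
                          size=(n_probes, subj_codes.max() + 1))
    noise = rng.normal(0, config.noise_sd_logit, size=(n_probes, n_samp))
    beta = expit(lg + pair_eff[:, pair_codes] + subj_eff[:, subj_codes] + noise)

    ad = sheet["ad"].to_numpy().astype(float)
    t = sheet["time"].to_numpy()
    age_dev = sheet["age"].to_numpy() - anchor
    d = delta.to_numpy()[:, None] * attenuation
    s = slope.to_numpy()[:, None]
    stable = (cls == "stable")[:, None]
    inter = (cls == "interaction")[:, None]
    cross = (cls == "crossover")[:, None]
    aging = (cls == "aging")[:, None]
    beta = beta + stable * d * ad[None, :]
    beta = beta + inter * s * attenuation * (t * ad)[None, :]
    beta = beta + cross * d * np.where(t[None, :] < 0, 1.0, -1.0) * ad[None, :]
    beta = beta + aging * s * age_dev[None, :]
    return np.clip(beta, 0.0, 1.0)


def _detection_p(config: CohortConfig, rng: np.random.Generator,
                 shape) -> np.ndarray:
    """Detection p-values: good entries < 0.01, failed entries > 0.05."""
    detp = rng.uniform(0.0, 0.01, size=shape)
    failed = rng.random(size=shape) < config.missing_rate
    detp[failed] = rng.uniform(0.051, 0.5, size=int(failed.sum()))
    return detp


def generate_cohort(config: CohortConfig) -> tuple[BetaMatrix, pd.DataFrame, GroundTruth]:
    """Generate the longitudinal matched-pair cohort.

    Returns the beta matrix (with detection-p channel and probe design
    classes), the sample sheet, and the ground truth.  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    probes = _probe_ids(config.n_cpgs, rng)
    classes = _assign_classes(config, probes)

    # reference panel over this cohort's probes: effect-class CpGs are
    # non-discriminating; a dedicated block of null CpGs discriminates
    n_effect = int((classes != "null").sum())
    ref_seed = int(rng.integers(2**31))
    disc_ref = generate_reference_panel(config.n_deconv_cpgs,
                                        config.n_celltypes, seed=ref_seed)
    ref = np.empty((config.n_cpgs, config.n_celltypes))
    base = rng.uniform(0.2, 0.8, size=config.n_cpgs)
    base[classes.to_numpy() == "null"] = np.clip(
        rng.beta(0.4, 0.4, size=int((classes == "null").sum())), 0.02, 0.98)
    ref[:] = base[:, None]
    disc_rows = slice(n_effect, n_effect + config.n_deconv_cpgs)
    ref[disc_rows, :] = disc_ref.to_numpy()
    reference = pd.DataFrame(ref, index=probes,
                             columns=disc_ref.columns)

    delta, slope = _plant_effects(config, rng, probes, classes)

    is_clock = classes == "clock"
    b = clock_cpg_slope(config)
    clock_sign = np.where(rng.random(int(is_clock.sum())) < 0.5, -1.0, 1.0)
    clock_slope = pd.Series(b * clock_sign, index=classes.index[is_clock])
    clock_int = pd.Series(rng.uniform(0.3, 0.7, size=int(is_clock.sum())),
                          index=classes.index[is_clock])

    sheet = _build_subjects(config, rng)
    conc = 200.0
    props = pd.DataFrame(
        rng.dirichlet(np.asarray(config.cell_mean_proportions) * conc,
                      size=len(sheet)),
        index=sheet["sample_id"], columns=reference.columns)

    beta = _beta_matrix(config, rng, sheet, probes, classes, delta, slope,
                        reference, props, clock_int, clock_slope)
    detp = _detection_p(config, rng, beta.shape)

    values = pd.DataFrame(beta, index=probes, columns=sheet["sample_id"])
    detection = pd.DataFrame(detp, index=probes, columns=sheet["sample_id"])
    design = pd.Series(np.where(rng.random(config.n_cpgs) < 0.84, "II", "I"),
                       index=probes, name="design")
    matrix = BetaMatrix(values=values, detection_p=detection, design=design)

    onset = sheet.drop_duplicates("subject_id").set_index("subject_id")["onset_age"]
    truth = GroundTruth(
        probe_class=classes,
        true_delta_beta=delta,
        time_slope=slope,
        cell_proportions=props,
        onset_age=onset,
        reference=reference,
        clock_intercept=clock_int,
        clock_slope=clock_slope,
        deconv_probes=probes[n_effect:n_effect + config.n_deconv_cpgs],
    )
    return matrix, sheet, truth


def generate_external_cohort(config: CohortConfig, truth: GroundTruth,
                             n_controls: int = 324, n_cases: int = 146,
                             shift: DemographicShift | None = None,
                             attenuation: float = 0.5,
                             seed: int | None = None) -> tuple[BetaMatrix, pd.DataFrame]:
    """Cross-sectional external cohort over the same CpG universe.

    One sample per subject; cases are sampled at clinical onset (time 0).
    Planted stable effects are attenuated by ``attenuation`` (default 0.5)
    to emulate partial replication; the demographic ``shift`` applies a
    different sex ratio and APOE e4 enrichment than the discovery cohort.
    """
    if shift is None:
        shift = DemographicShift()
    if len(truth.probe_class) != config.n_cpgs:
        raise ValueError("CpG universe mismatch between config and ground truth")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    rows = []
    for i in range(n_controls + n_cases):
        is_case = int(i >= n_controls)
        age_range = shift.case_age_range if is_case else shift.control_age_range
        age = rng.uniform(*age_range)
        rate = shift.apoe_case_rate if is_case else shift.apoe_control_rate
        rows.append({
            "sample_id": f"X{i:04d}",
            "subject_id": f"X{i:04d}",
            "pair_id": f"XP{i:04d}",
            "ad": is_case,
            "sex": "M" if rng.random() < shift.male_fraction else "F",
            "age": age,
            "onset_age": age if is_case else np.nan,
            "time": 0.0,
            "apoe_e4": int(rng.random() < rate),
            "smoker": int(rng.random() < config.smoker_rate),
            "rtl": rng.normal(1.0, 0.12) - 0.006 * (age - 75.0),
        })
    sheet = pd.DataFrame(rows, columns=SAMPLE_SHEET_COLUMNS)

    probes = list(truth.probe_class.index)
    conc = 200.0
    props = pd.DataFrame(
        rng.dirichlet(np.asarray(config.cell_mean_proportions) * conc,
                      size=len(sheet)),
        index=sheet["sample_id"], columns=truth.reference.columns)
    beta = _beta_matrix(config, rng, sheet, probes, truth.probe_class,
                        truth.true_delta_beta, truth.time_slope,
                        truth.reference, props, truth.clock_intercept,
                        truth.clock_slope, attenuation=attenuation,
                        anchor=truth.clock_anchor_age)
    detp = _detection_p(config, rng, beta.shape)
    values = pd.DataFrame(beta, index=probes, columns=sheet["sample_id"])
    detection = pd.DataFrame(detp, index=probes, columns=sheet["sample_id"])
    design = pd.Series(np.where(rng.random(config.n_cpgs) < 0.84, "II", "I"),
                       index=probes, name="design")
    return BetaMatrix(values=values, detection_p=detection, design=design), sheet
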