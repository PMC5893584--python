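"""Synthetic crossover-study generator with planted time responses.

Generates profile tables with the statistical structure the analysis
pipeline assumes: a two-period crossover (every subject measured at
hours 0-4 under both a vehicle and an alcohol arm), multiplicative
lognormal noise (urinary concentrations are positive and right-skewed,
and the pipeline analyses them on the log scale), subject random
effects shared across arms, creatinine sampled per void to emulate
dilution by water consumption, and optionally the batch/QC/repeat
injection layout of the measurement design.

The normalized concentration of metabolite m for subject s at hour t in
arm a is

    c = baseline_m * exp(u_sm) * response_m(t, a) * exp(eps)

with u_sm ~ N(0, subject_sd), eps ~ N(0, ln gsd_m), and response = 1 in
the vehicle arm and for unaffected metabolites.  Planted responses
interpolate log-linearly between anchor hours (the study design reports
hourly means, so anchors are the natural parameterization):

* ``early_peak`` / ``late_peak`` — rise to ``peak_fc`` at ``peak_time``,
  then decay back toward baseline by the last hour;
* ``persistent_rise`` — rise to ``peak_fc`` at ``peak_time``, then
  plateau;
* ``monotone_decrease`` — steady log-linear decline to ``peak_fc`` < 1
  at the last hour.

:func:`table1_preset` builds the truth object whose 13 affected
metabolites mimic the published reference profile (see
:mod:`uromet.reference`): baselines equal the printed hour-0 means and
peak fold changes equal the printed mean ratios, with noise calibrated
so simulated per-hour coefficients of variation fall in the printed
SD/mean range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import (
    RESERVED_COLUMNS,
    MetaboliteProfileTable,
    StudyDesign,
    ValidationError,
)
from .reference import REFERENCE_PROFILE


class ResponseShape:
    """Planted time-response shapes (string constants)."""

    EARLY_PEAK = "early_peak"
    LATE_PEAK = "late_peak"
    MONOTONE_DECREASE = "monotone_decrease"
    PERSISTENT_RISE = "persistent_rise"

    ALL = (EARLY_PEAK, LATE_PEAK, MONOTONE_DECREASE, PERSISTENT_RISE)


@dataclass(frozen=True)
class EffectDescriptor:
    """One planted effect: shape, hour of peak response, and peak
    multiplicative fold change (< 1 for monotone_decrease).

    ``anchors`` optionally pins the full hourly response (multiplier per
    hour, starting at 1.0 for hour 0); when present it overrides the
    canonical shape curve, with log-linear interpolation between hours.
    Presets use anchors so planted time-courses equal published hourly
    mean ratios rather than a stylized curve through the peak.
    """

    shape: str
    peak_time: int
    peak_fc: float
    anchors: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.shape not in ResponseShape.ALL:
            raise ValidationError(f"unknown response shape {self.shape!r}")
        if self.peak_fc <= 0:
            raise ValidationError("peak_fc must be > 0")
        if self.shape == ResponseShape.MONOTONE_DECREASE and self.peak_fc >= 1:
            raise ValidationError("monotone_decrease requires peak_fc < 1")
        if self.anchors is not None:
            if len(self.anchors) < 2 or self.anchors[0] != 1.0:
                raise ValidationError(
                    "anchors must start at 1.0 (hour 0) and cover >= 2 hours")
            if min(self.anchors) <= 0:
                raise ValidationError("anchors must be positive multipliers")


@dataclass
class SyntheticTruth:
    """Ground truth of a synthetic study: planted effects, baselines and
    noise levels, for recovery scoring after the pipeline has run."""

    affected: dict[str, EffectDescriptor]
    baseline: dict[str, tuple[float, float]]  # metabolite -> (median, gsd)
    subject_sd: float = 0.35
    noise_sd: float = 0.45
    seed: int | None = None

    def __post_init__(self):
        missing = [m for m in self.affected if m not in self.baseline]
        if missing:
            raise ValidationError(
                f"affected metabolite(s) absent from metabolite set: "
                f"{', '.join(missing)}")
        if self.subject_sd < 0 or self.noise_sd < 0:
            raise ValidationError("sds must be non-negative")

    @property
    def metabolites(self) -> list[str]:
        return list(self.baseline)

    def with_noise(self, noise_sd: float, subject_sd: float | None = None
                   ) -> "SyntheticTruth":
        """Copy with new noise levels (per-metabolite gsd refreshed)."""
        base = {m: (med, float(np.exp(noise_sd)))
                for m, (med, _) in self.baseline.items()}
        return SyntheticTruth(
            affected=dict(self.affected), baseline=base,
            subject_sd=self.subject_sd if subject_sd is None else subject_sd,
            noise_sd=noise_sd, seed=self.seed)

    def response(self, metabolite: str, time: float, t_max: int = 4) -> float:
        """Planted multiplicative response of a metabolite at an hour
        (1.0 for unaffected metabolites and in the vehicle arm)."""
        eff = self.affected.get(metabolite)
        if eff is None:
            return 1.0
        return _response_curve(eff, time, t_max)


def _response_curve(eff: EffectDescriptor, t: float, t_max: int) -> float:
    """Log-linear interpolation between the anchor hours of a shape."""
    if eff.anchors is not None:
        hours = np.arange(len(eff.anchors), dtype=float)
        return float(np.exp(np.interp(t, hours, np.log(eff.anchors))))
    log_peak = np.log(eff.peak_fc)
    if eff.shape == ResponseShape.MONOTONE_DECREASE:
        return float(np.exp(log_peak * t / t_max))
    tp = eff.peak_time
    if t <= tp:
        return float(np.exp(log_peak * t / tp)) if tp > 0 else float(np.exp(log_peak))
    if eff.shape == ResponseShape.PERSISTENT_RISE:
        return float(eff.peak_fc)
    # early/late peak: decay back to baseline by the last hour
    if t_max == tp:
        return float(eff.peak_fc)
    frac = (t_max - t) / (t_max - tp)
    return float(np.exp(log_peak * frac))


@dataclass
class GeneratorConfig:
    """Study dimensions and nuisance parameters; the defaults reproduce
    the reference design (12 subjects, 120 metabolites, hours 0-4, two
    interventions)."""

    n_subjects: int = 12
    times: tuple[int, ...] = (0, 1, 2, 3, 4)
    interventions: tuple[str, ...] = ("vehicle", "alcohol")
    include_qc_layout: bool = False
    creatinine_median: float = 10.0   # mmol/L
    creatinine_log_sd: float = 0.35   # void-to-void dilution spread
    qc_noise_sd: float = 0.05         # analytical noise of pooled QC, log scale
    zero_inflation: float = 0.0       # probability a raw value is a non-detect

    def __post_init__(self):
        if not 0 <= self.zero_inflation < 1:
            raise ValidationError("zero_inflation must be in [0, 1)")

    @property
    def design(self) -> StudyDesign:
        return StudyDesign(
            subjects=tuple(f"S{i:02d}" for i in range(1, self.n_subjects + 1)),
            times=self.times, interventions=self.interventions)


#: Injection order of one subject's batch: 25 injections — 11 pooled QC
#: (the first five condition the column), 5 vehicle + 5 alcohol
#: experimental samples in random order, and 2 + 2 repeat injections
#: (alcohol repeats duplicate samples from later in the batch, vehicle
#: repeats samples from earlier).
BATCH_LAYOUT = (
    "Q", "Q", "Q", "Q", "Q", "Q",
    "S_V", "S_V", "S_V", "R_A", "Q",
    "S_V", "S_V", "R_A", "Q",
    "S_A", "S_A", "S_A", "R_V", "Q",
    "S_A", "S_A", "R_V", "Q", "Q",
)


def generate_study(config: GeneratorConfig, truth: SyntheticTruth,
                   seed: int | None = None
                   ) -> tuple[MetaboliteProfileTable, SyntheticTruth]:
    """Generate one raw (umol/L) profile table under the crossover design.

    Fully reproducible under a fixed seed (``seed`` overrides
    ``truth.seed``).  With ``config.include_qc_layout`` each subject's
    batch is emitted in the 25-injection order of :data:`BATCH_LAYOUT`;
    otherwise only the 10 experimental samples per subject are emitted.
    """
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    design = config.design
    metab = truth.metabolites
    n_m = len(metab)
    t_max = max(design.times)

    medians = np.array([truth.baseline[m][0] for m in metab])
    noise = np.array([np.log(truth.baseline[m][1]) for m in metab])
    resp = {arm: np.array([[truth.response(m, t, t_max) if arm == "alcohol"
                            else 1.0 for m in metab] for t in design.times])
            for arm in design.interventions}

    subj_eff = rng.normal(0.0, truth.subject_sd,
                          size=(design.n_subjects, n_m)) if truth.subject_sd > 0 \
        else np.zeros((design.n_subjects, n_m))

    exp_rows = []
    norm_values = {}  # sample_id -> normalized concentration vector
    for si, subj in enumerate(design.subjects):
        for arm in design.interventions:
            for ti, t in enumerate(design.times):
                eps = (rng.normal(0.0, 1.0, n_m) * noise
                       if noise.any() else np.zeros(n_m))
                normalized = medians * np.exp(subj_eff[si]) \
                    * resp[arm][ti] * np.exp(eps)
                cr = float(np.exp(rng.normal(np.log(config.creatinine_median),
                                             config.creatinine_log_sd)))
                sid = f"{subj}_{arm[0].upper()}{t}"
                norm_values[sid] = normalized
                exp_rows.append({
                    "sample_id": sid, "subject_id": subj, "intervention": arm,
                    "time_h": t, "role": "experimental", "batch_id": subj,
                    "injection_order": 0, "creatinine_mmol_per_L": cr,
                    "values": normalized * cr,
                })
    if config.zero_inflation > 0:
        for row in exp_rows:
            mask = rng.random(n_m) < config.zero_inflation
            row["values"] = np.where(mask, 0.0, row["values"])

    pooled = np.mean([norm_values[r["sample_id"]] for r in exp_rows], axis=0)
    pooled_cr = float(np.mean([r["creatinine_mmol_per_L"] for r in exp_rows]))
    by_key = {(r["subject_id"], r["intervention"], r["time_h"]): r
              for r in exp_rows}

    out_rows = []
    if not config.include_qc_layout:
        for si, subj in enumerate(design.subjects):
            order = 0
            for r in exp_rows:
                if r["subject_id"] == subj:
                    order += 1
                    r = dict(r)
                    r["injection_order"] = order
                    out_rows.append(r)
    else:
        for subj in design.subjects:
            veh_times = list(rng.permutation(design.times))
            alc_times = list(rng.permutation(design.times))
            rep_alc = list(rng.choice(design.times, size=2, replace=False))
            rep_veh = list(rng.choice(design.times, size=2, replace=False))
            qc_i = 0
            for order, token in enumerate(BATCH_LAYOUT, start=1):
                if token == "Q":
                    qc_i += 1
                    qc_vals = pooled * np.exp(
                        rng.normal(0.0, config.qc_noise_sd, n_m))
                    out_rows.append({
                        "sample_id": f"{subj}_Q{qc_i:02d}",
                        "subject_id": "POOL", "intervention": "vehicle",
                        "time_h": 0, "role": "qc", "batch_id": subj,
                        "injection_order": order,
                        "creatinine_mmol_per_L": pooled_cr,
                        "values": qc_vals * pooled_cr,
                    })
                elif token in ("S_V", "S_A"):
                    arm = "vehicle" if token == "S_V" else "alcohol"
                    t = (veh_times if arm == "vehicle" else alc_times).pop(0)
                    r = dict(by_key[(subj, arm, int(t))])
                    r["injection_order"] = order
                    out_rows.append(r)
                else:  # R_A / R_V: exact re-injection of an experimental sample
                    arm = "alcohol" if token == "R_A" else "vehicle"
                    t = (rep_alc if arm == "alcohol" else rep_veh).pop(0)
                    orig = by_key[(subj, arm, int(t))]
                    r = dict(orig)
                    r["sample_id"] = f"{orig['sample_id']}_rep"
                    r["role"] = "repeat"
                    r["injection_order"] = order
                    out_rows.append(r)

    frame_rows = []
    for r in out_rows:
        rec = {c: r[c] for c in RESERVED_COLUMNS}
        rec.update(dict(zip(metab, r["values"])))
        frame_rows.append(rec)
    df = pd.DataFrame(frame_rows)
    table = MetaboliteProfileTable(df, normalized=False)
    table.validate(design)
    return table, truth


def table1_preset(n_metabolites: int = 120, *, subject_sd: float = 0.35,
                  noise_sd: float = 0.45,
                  filler_seed: int = 104729) -> SyntheticTruth:
    """Truth object mimicking the reference study's 13 reported effects.

    Affected metabolites take their printed hour-0 means as baseline
    medians; early-peak shapes carry the printed 0-1 h fold change,
    peak-at-2 h and persistent shapes the printed hour-2/hour-0 mean
    ratio, and the monotone decrease the printed hour-4/hour-0 ratio.
    The remaining metabolites are unaffected fillers with baselines
    drawn once from a fixed-seed lognormal (deterministic preset).
    """
    ref = REFERENCE_PROFILE
    shapes = {
        "hippuric acid": (ResponseShape.EARLY_PEAK, 1),
        "lactic acid": (ResponseShape.EARLY_PEAK, 1),
        "fumaric acid": (ResponseShape.EARLY_PEAK, 2),
        "vanillylmandelic acid": (ResponseShape.MONOTONE_DECREASE, 4),
        "2-hydroxybutyric acid": (ResponseShape.EARLY_PEAK, 1),
        "succinic acid": (ResponseShape.EARLY_PEAK, 2),
        "3-hydroxybutyric acid": (ResponseShape.EARLY_PEAK, 1),
        "2-ethylhydracrylic acid": (ResponseShape.EARLY_PEAK, 2),
        "3-hydroxyisobutyric acid": (ResponseShape.EARLY_PEAK, 1),
        "2-hydroxyisobutyric acid": (ResponseShape.EARLY_PEAK, 1),
        "malic acid": (ResponseShape.EARLY_PEAK, 2),
        "N-tiglylglycine": (ResponseShape.PERSISTENT_RISE, 2),
        "2-hydroxyglutaric acid": (ResponseShape.PERSISTENT_RISE, 2),
    }
    gsd = float(np.exp(noise_sd))
    affected, baseline = {}, {}
    for m, (shape, tp) in shapes.items():
        row = ref.loc[m]
        anchors = tuple(float(row[f"mean_{t}"] / row["mean_0"])
                        for t in range(5))
        anchors = (1.0,) + anchors[1:]
        affected[m] = EffectDescriptor(shape=shape, peak_time=tp,
                                       peak_fc=float(anchors[tp]),
                                       anchors=anchors)
        baseline[m] = (float(row["mean_0"]), gsd)
    if n_metabolites < len(shapes):
        raise ValidationError(
            f"preset needs at least {len(shapes)} metabolites")
    filler_rng = np.random.default_rng(filler_seed)
    for i in range(n_metabolites - len(shapes)):
        med = float(np.exp(filler_rng.normal(np.log(5.0), 1.0)))
        baseline[f"oa_{i + 1:03d}"] = (med, gsd)
    return SyntheticTruth(affected=affected, baseline=baseline,
                          subject_sd=subject_sd, noise_sd=noise_sd)


def score_recovery(selected, truth: SyntheticTruth, *,
                   min_abs_fc: float | None = None,
                   at_time: int = 1, t_max: int = 4) -> dict:
    """Recovery of the planted effect set by a selection.

    ``min_abs_fc`` restricts the positives to planted effects whose
    response magnitude at hour ``at_time`` reaches that signed-fold-
    change magnitude (relevant when scoring a contrast at that hour).
    Sensitivity = recovered positives / positives; specificity = true
    negatives / unaffected; false_discoveries = selected but unplanted.
    """
    selected = set(selected)
    universe = set(truth.metabolites)
    stray = selected - universe
    if stray:
        raise ValidationError(
            f"selected metabolite(s) outside the study: {', '.join(sorted(stray))}")
    positives = set()
    for m in truth.affected:
        r = truth.response(m, at_time, t_max)
        mag = r if r >= 1 else 1.0 / r
        if min_abs_fc is None or mag >= min_abs_fc:
            positives.add(m)
    negatives = universe - set(truth.affected)
    tp = selected & positives
    fd = selected - set(truth.affected)
    return {
        "sensitivity": len(tp) / len(positives) if positives else float("nan"),
        "specificity": (len(negatives - selected) / len(negatives)
                        if negatives else float("nan")),
        "false_discoveries": len(fd),
        "n_positives": len(positives),
    }
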