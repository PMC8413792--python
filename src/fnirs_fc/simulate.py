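"""Synthetic fNIRS cohorts with a plantable connectivity structure.

The generator emulates the study protocol end to end: a 48-channel frontal
montage sampled at 3.9 Hz through a 60-s rest followed by six 10-s
finger-tapping stimuli.  Each channel's oxyhemoglobin signal is a latent
multivariate-Gaussian process whose inter-channel correlation matrix is
imposed exactly (via Cholesky factorisation) and switches between a rest
and a task target; deoxyhemoglobin is an anticorrelated copy plus
independent noise.  On top of the latent processes the generator adds
HRF-convolved boxcar responses on contralateral motor channels,
physiological sinusoids (cardiac, respiratory, Mayer waves), white noise,
and Poisson-timed motion spikes, then converts everything to two-wavelength
optical densities through the same forward Beer-Lambert model the analysis
inverts.

The connectivity plan is the experimental ground truth: finger tapping
lowers inter-channel correlations (``task_modulation`` < 0), and sleep
deprivation attenuates that task-related drop (``sd_modulation`` > 0,
applied to task epochs of the after-SD session only).  Per-subject random
effects perturb both modulations, and cognitive-score changes are coupled
linearly to each subject's realised attenuation so that brain-behaviour
correlation analyses can be exercised against a known sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .montage import (
    DEFAULT_FS_HZ, SLEEP_STATES, EventSchedule, Montage, Recording,
    build_default_montage, build_default_schedule, intensity_to_od,
)
from .preprocess import hemoglobin_to_od


# ---------------------------------------------------------------------------
# plan and spec


@dataclass(frozen=True)
class ConnectivityPlan:
    """Target latent correlation structure and its state modulations.

    ``block_assignment`` maps each channel to a community label; channels in
    the same community correlate at ``r_within``, others at ``r_between``.
    ``task_modulation`` is added to every off-diagonal entry during stimulus
    epochs; ``sd_modulation`` is additionally added to task epochs of the
    after-SD session, attenuating the task effect there.
    """

    block_assignment: tuple[int, ...]
    r_within: float = 0.40
    r_between: float = 0.10
    task_modulation: float = -0.25
    sd_modulation: float = 0.15

    def __post_init__(self) -> None:
        for name in ("r_within", "r_between"):
            v = getattr(self, name)
            if not -1.0 < v < 1.0:
                raise ValueError(f"{name}={v} outside (-1, 1)")

    def correlation_target(
        self, in_task: bool, after_sd: bool,
        task_mod: float | None = None, sd_mod: float | None = None,
    ) -> np.ndarray:
        """The (PSD-repaired) latent correlation matrix for one epoch state."""
        task_mod = self.task_modulation if task_mod is None else task_mod
        sd_mod = self.sd_modulation if sd_mod is None else sd_mod
        lab = np.asarray(self.block_assignment)
        r = np.where(lab[:, None] == lab[None, :], self.r_within, self.r_between)
        shift = 0.0
        if in_task:
            shift += task_mod
            if after_sd:
                shift += sd_mod
        r = np.clip(r + shift, -0.95, 0.95).astype(float)
        np.fill_diagonal(r, 1.0)
        return nearest_correlation(r)


def default_block_assignment(montage: Montage, n_blocks: int = 4) -> tuple[int, ...]:
    """Community labels by scalp quadrant (hemisphere x anterior/posterior)."""
    pos = montage.channel_positions()
    y_mid = np.median(pos[:, 1])
    labels = []
    for x, y in pos:
        labels.append((0 if x <= 0 else 1) + 2 * (0 if y > y_mid else 1))
    return tuple(labels)


def nearest_correlation(r: np.ndarray, eig_floor: float = 1e-10) -> np.ndarray:
    """Nearest valid correlation matrix by eigenvalue clipping + rescaling."""
    vals, vecs = np.linalg.eigh((r + r.T) / 2.0)
    if vals.min() >= eig_floor:
        return r
    repaired = (vecs * np.maximum(vals, eig_floor)) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


@dataclass(frozen=True)
class PhysioModel:
    """Amplitudes (uM) and centre frequencies (Hz) of systemic oscillations."""

    cardiac_amp: float = 0.40
    cardiac_hz: float = 1.1
    respiratory_amp: float = 0.30
    respiratory_hz: float = 0.25
    mayer_amp: float = 0.30
    mayer_hz: float = 0.10
    freq_jitter: float = 0.05  # relative sd of per-channel frequency jitter


@dataclass(frozen=True)
class HRFModel:
    """Canonical double-gamma hemodynamic response function parameters."""

    peak_s: float = 6.0
    undershoot_s: float = 16.0
    ratio: float = 1.0 / 6.0
    length_s: float = 30.0

    def kernel(self, fs_hz: float) -> np.ndarray:
        t = np.arange(0.0, self.length_s, 1.0 / fs_hz)
        from scipy.stats import gamma as gamma_dist

        peak = gamma_dist.pdf(t, self.peak_s, scale=1.0)
        under = gamma_dist.pdf(t, self.undershoot_s, scale=1.0)
        h = peak - self.ratio * under
        return h / h.max()


@dataclass(frozen=True)
class SimulationSpec:
    """Everything needed to generate a cohort; study-protocol defaults."""

    n_subjects: int = 10
    seed: int = 0
    fs_hz: float = DEFAULT_FS_HZ
    montage: Montage = field(default_factory=build_default_montage)
    schedule: EventSchedule = field(default_factory=build_default_schedule)
    duration_s: float = 175.0
    physio: PhysioModel = field(default_factory=PhysioModel)
    hrf: HRFModel = field(default_factory=HRFModel)
    connectivity_plan: ConnectivityPlan | None = None
    latent_sd_um: float = 1.0       # sd of the latent HbO processes
    hbr_gamma: float = 1.0 / 3.0    # HbR = -gamma * HbO + noise
    hbr_noise_sd_um: float = 0.10
    response_amp_um: float = 1.0    # peak HbO task response on motor channels
    noise_sd_um: float = 0.20       # white measurement noise
    artifact_rate_per_min: float = 0.5
    artifact_amp_range: tuple[float, float] = (5.0, 20.0)  # x signal sd
    artifact_tau_s: float = 1.0
    subject_jitter_sd: float = 0.05  # sd of per-subject modulation jitter
    pal_slope: float = -40.0         # PAL score change per unit planted delta
    rti_slope: float = 0.0
    rvpa_slope: float = 0.0
    score_noise_sd: float = 1.0
    baseline_intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        for name in ("latent_sd_um", "noise_sd_um", "response_amp_um",
                     "artifact_rate_per_min", "score_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.duration_s < self.schedule.end_s:
            raise ValueError("duration must cover the event schedule")

    def plan(self) -> ConnectivityPlan:
        if self.connectivity_plan is not None:
            if len(self.connectivity_plan.block_assignment) != self.montage.n_channels:
                raise ValueError("connectivity plan does not match montage size")
            return self.connectivity_plan
        return ConnectivityPlan(default_block_assignment(self.montage))

    def to_json(self) -> str:
        """Serialise every scalar/nested parameter; montage and schedule are
        always the packaged defaults when round-tripping through JSON."""
        import dataclasses as dc
        import json

        d = {}
        for f in dc.fields(self):
            v = getattr(self, f.name)
            if f.name in ("montage", "schedule"):
                continue
            if dc.is_dataclass(v):
                d[f.name] = dc.asdict(v)
            elif isinstance(v, tuple):
                d[f.name] = list(v)
            else:
                d[f.name] = v
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationSpec":
        import json

        d = json.loads(text)
        if "physio" in d and isinstance(d["physio"], dict):
            d["physio"] = PhysioModel(**d["physio"])
        if "hrf" in d and isinstance(d["hrf"], dict):
            d["hrf"] = HRFModel(**d["hrf"])
        if d.get("connectivity_plan") is not None:
            p = d["connectivity_plan"]
            p["block_assignment"] = tuple(p["block_assignment"])
            d["connectivity_plan"] = ConnectivityPlan(**p)
        if "artifact_amp_range" in d:
            d["artifact_amp_range"] = tuple(d["artifact_amp_range"])
        known = {f.name for f in __import__("dataclasses").fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation-spec keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class SyntheticCohort:
    """Generated recordings, cognitive scores and the planted ground truth."""

    recordings: list[Recording]
    cognitive_scores: "object"  # pandas.DataFrame: subject_id, visit, PAL, RTI, RVPA
    ground_truth: dict

    def recording(self, subject_id: str, sleep_state: str) -> Recording:
        for rec in self.recordings:
            if rec.subject_id == subject_id and rec.sleep_state == sleep_state:
                return rec
        raise KeyError((subject_id, sleep_state))

    @property
    def subject_ids(self) -> list[str]:
        seen: list[str] = []
        for rec in self.recordings:
            if rec.subject_id not in seen:
                seen.append(rec.subject_id)
        return seen


# ---------------------------------------------------------------------------
# generation


def _subject_effects(spec: SimulationSpec, subject_idx: int) -> dict[str, float]:
    """Per-subject random perturbations of the planted modulations.

    Derived from (seed, subject index) only, so the subject's two sessions
    and the cognitive-score coupling see identical effects.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([int(spec.seed) % (2**31), 1000 + subject_idx])
    )
    plan = spec.plan()
    task_mod = plan.task_modulation + spec.subject_jitter_sd * rng.standard_normal()
    sd_mod = plan.sd_modulation + spec.subject_jitter_sd * rng.standard_normal()
    return {"task_modulation": task_mod, "sd_modulation": sd_mod}


def _task_mask(spec: SimulationSpec, n: int) -> np.ndarray:
    """Boolean per-sample mask: True during any stimulus epoch."""
    t = np.arange(n) / spec.fs_hz
    mask = np.zeros(n, dtype=bool)
    for label, onset, dur in spec.schedule.entries:
        if label.startswith("Stim"):
            mask |= (t >= onset) & (t < onset + dur)
    return mask


def generate_recording(
    spec: SimulationSpec,
    subject_idx: int,
    sleep_state: str,
    rng: np.random.Generator | None = None,
) -> Recording:
    """One synthetic session for one subject and sleep state."""
    if sleep_state not in SLEEP_STATES:
        raise ValueError(f"unknown sleep state {sleep_state!r}")
    after_sd = sleep_state == "after_SD"
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(
            [int(spec.seed) % (2**31), subject_idx, int(after_sd)]
        ))
    plan = spec.plan()
    eff = _subject_effects(spec, subject_idx)
    n = int(np.floor(spec.duration_s * spec.fs_hz))
    n_ch = spec.montage.n_channels
    task = _task_mask(spec, n)

    # latent HbO with exact per-epoch-state correlation structure
    r_rest = plan.correlation_target(
        False, after_sd, task_mod=eff["task_modulation"], sd_mod=eff["sd_modulation"]
    )
    r_task = plan.correlation_target(
        True, after_sd, task_mod=eff["task_modulation"], sd_mod=eff["sd_modulation"]
    )
    z = rng.standard_normal((n, n_ch))
    l_rest = np.linalg.cholesky(r_rest)
    l_task = np.linalg.cholesky(r_task)
    hbo = np.where(task[:, None], z @ l_task.T, z @ l_rest.T) * spec.latent_sd_um
    hbr = -spec.hbr_gamma * hbo + spec.hbr_noise_sd_um * rng.standard_normal((n, n_ch))

    # lateralised task responses: HRF-convolved boxcars on contralateral motor channels
    if spec.response_amp_um > 0:
        kernel = spec.hrf.kernel(spec.fs_hz)
        t = np.arange(n) / spec.fs_hz
        resp = {"left": np.zeros(n), "right": np.zeros(n)}
        stim_len = 0
        for label, onset, dur in spec.schedule.entries:
            if label.startswith("Stim"):
                box = ((t >= onset) & (t < onset + dur)).astype(float)
                resp[spec.schedule.stimulus_hand(label)] += box
                stim_len = max(stim_len, int(np.floor(dur * spec.fs_hz)))
        # scale so one isolated stimulus peaks at response_amp_um
        unit_peak = np.convolve(np.ones(stim_len), kernel).max()
        for hand, series in resp.items():
            drive = np.convolve(series, kernel)[:n] * (spec.response_amp_um / unit_peak)
            contralateral = "right" if hand == "left" else "left"
            for ch in spec.montage.motor_channels(contralateral):
                hbo[:, ch] += drive
                hbr[:, ch] -= spec.hbr_gamma * drive

    # systemic physiology: per-channel random phase, small frequency jitter
    t = np.arange(n) / spec.fs_hz
    for amp, f0 in ((spec.physio.cardiac_amp, spec.physio.cardiac_hz),
                    (spec.physio.respiratory_amp, spec.physio.respiratory_hz),
                    (spec.physio.mayer_amp, spec.physio.mayer_hz)):
        if amp <= 0:
            continue
        freqs = f0 * (1.0 + spec.physio.freq_jitter * rng.standard_normal(n_ch))
        phases = rng.uniform(0, 2 * np.pi, n_ch)
        wave = amp * np.sin(2 * np.pi * freqs[None, :] * t[:, None] + phases[None, :])
        hbo += wave
        hbr += -spec.hbr_gamma * wave

    if spec.noise_sd_um > 0:
        hbo = hbo + spec.noise_sd_um * rng.standard_normal((n, n_ch))
        hbr = hbr + spec.noise_sd_um * rng.standard_normal((n, n_ch))

    od = hemoglobin_to_od(
        hbo, hbr,
        distance_cm=spec.montage.source_detector_distance_cm,
        wavelengths=tuple(float(w) for w in (760.0, 850.0)),
    )

    # motion artifacts: Poisson-timed spikes with exponential tails, in OD
    if spec.artifact_rate_per_min > 0:
        n_spikes = rng.poisson(spec.artifact_rate_per_min * spec.duration_s / 60.0)
        sd_od = od.std(axis=0, keepdims=True)
        for _ in range(n_spikes):
            i0 = int(rng.integers(0, n))
            ch = int(rng.integers(0, n_ch))
            amp = rng.uniform(*spec.artifact_amp_range) * rng.choice([-1.0, 1.0])
            tail = np.exp(-(t[i0:] - t[i0]) / spec.artifact_tau_s)
            od[i0:, ch, :] += amp * sd_od[0, ch, :] * tail[:, None]

    intensity = spec.baseline_intensity * np.power(10.0, -od)
    return Recording(
        montage=spec.montage, fs_hz=spec.fs_hz,
        od=intensity_to_od(intensity), events=spec.schedule,
        subject_id=f"S{subject_idx + 1:02d}", sleep_state=sleep_state,
        raw_intensity=intensity,
    )


def generate_cohort(spec: SimulationSpec) -> SyntheticCohort:
    """Full cohort: two sessions per subject plus coupled cognitive scores."""
    import pandas as pd

    recordings = []
    rows = []
    truth_subjects = {}
    rng_scores = np.random.default_rng(
        np.random.SeedSequence([int(spec.seed) % (2**31), 7777])
    )
    for s in range(spec.n_subjects):
        for state in SLEEP_STATES:
            recordings.append(generate_recording(spec, s, state))
        eff = _subject_effects(spec, s)
        # the subject's planted attenuation of the task effect after SD
        delta_plan = eff["sd_modulation"]
        truth_subjects[f"S{s + 1:02d}"] = {**eff, "delta_plan": delta_plan}
        base = {"PAL": 17.0 + 3.0 * rng_scores.standard_normal(),
                "RTI": 320.0 + 25.0 * rng_scores.standard_normal(),
                "RVPA": 0.91 + 0.03 * rng_scores.standard_normal()}
        change = {
            "PAL": spec.pal_slope * delta_plan
                   + spec.score_noise_sd * rng_scores.standard_normal(),
            "RTI": spec.rti_slope * delta_plan
                   + spec.score_noise_sd * rng_scores.standard_normal(),
            "RVPA": spec.rvpa_slope * delta_plan
                    + 0.01 * spec.score_noise_sd * rng_scores.standard_normal(),
        }
        rows.append({"subject_id": f"S{s + 1:02d}", "visit": 1, **base})
        rows.append({"subject_id": f"S{s + 1:02d}", "visit": 2,
                     **{k: base[k] + change[k] for k in base}})
    plan = spec.plan()
    ground_truth = {
        "plan": plan,
        "subjects": truth_subjects,
        "correlation_targets": {
            (st, sl): plan.correlation_target(st == "task", sl == "after_SD")
            for st in ("rest", "task") for sl in SLEEP_STATES
        },
    }
    return SyntheticCohort(
        recordings=recordings,
        cognitive_scores=pd.DataFrame(rows),
        ground_truth=ground_truth,
    )


def qc_mixed_fixture(seed: int = 42, n_subjects: int = 10) -> SyntheticCohort:
    """Cohort with one deliberately degraded subject for QC-rule testing.

    Subjects 1..n-1 are generated artifact-free with gentle physiology so
    every channel's raw-intensity CV stays below 5%; the last subject's
    intensities get multiplicative noise (15% sd) on 90% of channels,
    pushing their CV above 10% so the session trips the exclusion rule.
    """
    spec = replace(
        SimulationSpec(n_subjects=n_subjects, seed=int(seed)),
        artifact_rate_per_min=0.0,
    )
    cohort = generate_cohort(spec)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 424242]))
    bad_subject = f"S{n_subjects:02d}"
    n_bad = int(round(0.9 * spec.montage.n_channels))
    bad_channels = np.arange(n_bad)
    for i, rec in enumerate(cohort.recordings):
        if rec.subject_id != bad_subject:
            continue
        inten = rec.raw_intensity.copy()
        noise = rng.lognormal(mean=0.0, sigma=0.15,
                              size=(inten.shape[0], n_bad, inten.shape[2]))
        inten[:, bad_channels, :] *= noise
        cohort.recordings[i] = replace(
            rec, raw_intensity=inten, od=intensity_to_od(inten)
        )
    cohort.ground_truth["qc_bad_subject"] = bad_subject
    cohort.ground_truth["qc_bad_channels"] = bad_channels
    return cohort
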