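"""Synthetic marker-trajectory cohorts with retained ground truth.

The generator emulates the study conditions the analysis assumes: a rigid
trunk whose midline markers (CLAV, XP, M-STRN, T1, T10, plus a heel proxy
for event detection) are carried through gait-like and drop-vertical-jump
(DVJ) motion at 240 Hz, corrupted by per-marker soft-tissue sinusoids,
a constant sports-bra displacement of the XP marker in dynamic trials,
isotropic Gaussian measurement noise, marker occlusion episodes and
optional full-marker-set flicker.  Every random draw is seeded and the
noise-free angle series, events and cycle metrics are stored alongside
each trial, so pipeline estimates can always be checked against truth.

Tilt profiles are the simplest smooth shapes matching the reported group
summaries: gait tilt is a sinusoid about a slightly extended mean (ROM a
few degrees), DVJ tilt is a raised-cosine flexion pulse peaking at maximum
descent of the first landing (excursions of roughly 40-50 degrees, larger
in males).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ConfigError
from .events import (DEFAULT_CONTACT_THRESHOLD_MM, CycleAnnotation,
                     detect_dvj_events, max_descent_frame)
from .metrics import TiltMetrics, compute_metrics
from .trial import MarkerTrialSet

DEFAULT_RATE_HZ = 240.0
BOX_HEIGHT_MM = 310.0  # 31 cm plyometric box

#: direction of the sports-bra XP displacement in the trunk frame: mostly
#: superior (along the bra band) with a small anterior lift off the chest
BRA_SHIFT_DIRECTION = np.array([np.sin(np.deg2rad(20.0)), 0.0,
                                np.cos(np.deg2rad(20.0))])

#: reference stature the template box is scaled against
_REFERENCE_HEIGHT_CM = 170.0


# ---------------------------------------------------------------------------
# subject template

@dataclass(frozen=True)
class SubjectTemplate:
    """Local trunk-frame marker coordinates (mm) plus stature and sex."""

    local: dict[str, np.ndarray]
    height_cm: float
    sex: str = "F"

    def __post_init__(self):
        for name in ("CLAV", "XP", "M-STRN", "T1", "T10"):
            if name not in self.local:
                raise ConfigError(f"template lacks marker {name!r}")
        mid = 0.5 * (np.asarray(self.local["CLAV"]) + np.asarray(self.local["XP"]))
        if not np.allclose(self.local["M-STRN"], mid, atol=1e-9):
            raise ConfigError("M-STRN must sit at the CLAV/XP midpoint")
        span = np.ptp([v[2] for v in self.local.values()])
        if span < 100.0:
            raise ConfigError("trunk markers must span >= 100 mm longitudinally")

    @classmethod
    def default(cls, height_cm: float = 168.6, sex: str = "F") -> "SubjectTemplate":
        """Stature-scaled trunk template with an inclined anterior face.

        CLAV/XP anterior (the xiphoid sits further forward than the
        jugular notch, as on a real chest), T1/T10 posterior, 300 mm
        longitudinal span at the reference stature; M-STRN at the CLAV/XP
        midpoint.  Local coordinates are canonicalised so the template's
        anatomical frame is the identity: profile angles are then the
        anatomical trunk angles with no static offset.
        """
        from .models import build_anatomical_frame

        s = height_cm / _REFERENCE_HEIGHT_CM
        raw = {
            "CLAV": np.array([25.0, 0.0, 300.0]) * s,
            "XP": np.array([75.0, 0.0, 0.0]) * s,
            "T1": np.array([-50.0, 0.0, 300.0]) * s,
            "T10": np.array([-50.0, 0.0, 0.0]) * s,
        }
        raw["M-STRN"] = 0.5 * (raw["CLAV"] + raw["XP"])
        basis = build_anatomical_frame(raw)
        local = {name: basis.orientation.T @ (pos - basis.origin)
                 for name, pos in raw.items()}
        return cls(local=local, height_cm=height_cm, sex=sex)


# ---------------------------------------------------------------------------
# motion profiles

@dataclass(frozen=True)
class MotionProfile:
    """Parametric trunk motion for one trial; ground truth is recomputable.

    ``params`` holds the shape parameters; the ``gait``/``dvj``/``static``
    constructors document them.  Angle functions are in degrees, paths in
    mm.
    """

    task: str
    duration_s: float
    params: dict = field(default_factory=dict)

    # -- constructors ------------------------------------------------------
    @classmethod
    def static(cls, duration_s: float = 1.0,
               origin_height_mm: float = 1000.0) -> "MotionProfile":
        return cls("static", duration_s, {"origin_height": origin_height_mm})

    @classmethod
    def gait(cls, mean_tilt_deg: float = -1.68, rom_deg: float = 4.34,
             cycle_s: float = 1.1, obliquity_amp_deg: float = 1.0,
             axial_amp_deg: float = 2.0, speed_mm_s: float = 1200.0,
             bounce_mm: float = 15.0,
             origin_height_mm: float = 1000.0) -> "MotionProfile":
        """Two gait cycles; tilt = mean + (ROM/2) sin(2 pi t / T)."""
        if not (2.0 <= rom_deg <= 8.0):
            raise ConfigError("gait ROM parameter must lie in [2, 8] deg")
        if not (-6.0 <= mean_tilt_deg <= 2.0):
            raise ConfigError("gait mean tilt parameter must lie in [-6, 2] deg")
        return cls("gait", 2 * cycle_s, {
            "mean_tilt": mean_tilt_deg, "rom": rom_deg, "cycle": cycle_s,
            "obliquity_amp": obliquity_amp_deg, "axial_amp": axial_amp_deg,
            "speed": speed_mm_s, "bounce": bounce_mm,
            "origin_height": origin_height_mm,
        })

    @classmethod
    def dvj(cls, peak_flexion_deg: float = 43.94, base_tilt_deg: float = -2.0,
            height_cm: float = 168.6, obliquity_amp_deg: float = 1.0,
            axial_amp_deg: float = 1.0, drop_s: float = 0.3,
            contact_s: float = 0.8,
            origin_height_mm: float = 950.0) -> "MotionProfile":
        """Box drop, first landing, flight: flexion pulse peaks at max descent.

        The box stands one half of the participant's stature from the
        landing target, which fixes the forward travel of the drop.
        """
        if not (20.0 <= peak_flexion_deg <= 70.0):
            raise ConfigError("DVJ flexion excursion must lie in [20, 70] deg")
        t_drop = 0.5
        t_ic = t_drop + drop_s
        t_to = t_ic + contact_s
        return cls("dvj", t_to + 1.4, {
            "peak": peak_flexion_deg, "base": base_tilt_deg,
            "obliquity_amp": obliquity_amp_deg, "axial_amp": axial_amp_deg,
            "t_drop": t_drop, "t_ic": t_ic, "t_to": t_to,
            "forward": 10.0 * height_cm / 2.0,  # half stature, in mm
            "origin_height": origin_height_mm, "dip": 150.0,
        })

    # -- time functions ----------------------------------------------------
    def angles_deg(self, t: np.ndarray) -> np.ndarray:
        """(n, 3) array of [tilt, obliquity, axial] in degrees."""
        t = np.asarray(t, dtype=float)
        p = self.params
        if self.task == "static":
            return np.zeros(t.shape + (3,))
        if self.task == "gait":
            phase = 2 * np.pi * t / p["cycle"]
            tilt = p["mean_tilt"] + 0.5 * p["rom"] * np.sin(phase)
            obliquity = p["obliquity_amp"] * np.sin(phase + 0.5)
            axial = p["axial_amp"] * np.sin(0.5 * phase)
            return np.stack([tilt, obliquity, axial], axis=-1)
        pulse = self._dvj_pulse(t)
        tilt = p["base"] + p["peak"] * pulse
        obliquity = p["obliquity_amp"] * pulse
        axial = p["axial_amp"] * np.sin(2 * np.pi * t / self.duration_s)
        return np.stack([tilt, obliquity, axial], axis=-1)

    def _dvj_pulse(self, t: np.ndarray) -> np.ndarray:
        """Raised-cosine-power window on [t_ic, t_to], peak 1 at the midpoint.

        The fourth power keeps value, slope and curvature zero at the
        window edges: trunk motion stays jerk-limited through landing.
        """
        p = self.params
        mid = 0.5 * (p["t_ic"] + p["t_to"])
        half = 0.5 * (p["t_to"] - p["t_ic"])
        u = (t - mid) / half
        return np.where(np.abs(u) <= 1, np.cos(0.5 * np.pi * u) ** 4, 0.0)

    def origin_mm(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        p = self.params
        z0 = p["origin_height"]
        if self.task == "static":
            out = np.zeros(t.shape + (3,))
            out[..., 2] = z0
            return out
        if self.task == "gait":
            x = p["speed"] * t
            z = z0 + p["bounce"] * np.sin(4 * np.pi * t / p["cycle"])
            return np.stack([x, np.zeros_like(t), z], axis=-1)
        heel = self.heel_height_mm(t)
        x = p["forward"] * self._ramp(t, p["t_drop"], p["t_ic"])
        z = z0 + 0.5 * heel - p["dip"] * self._dvj_pulse(t)
        return np.stack([x, np.zeros_like(t), z], axis=-1)

    @staticmethod
    def _ramp(t, t0, t1):
        # quintic smoothstep: zero velocity and acceleration at both ends
        u = np.clip((t - t0) / (t1 - t0), 0.0, 1.0)
        return u ** 3 * (10.0 + u * (6.0 * u - 15.0))

    def heel_height_mm(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        p = self.params
        if self.task == "static":
            return np.full(t.shape, 25.0)
        if self.task == "gait":
            # swing-phase lift; events come from annotations during gait
            lift = np.sin(np.pi * ((t / p["cycle"]) % 1.0)) ** 2
            return 2.0 + 80.0 * lift
        ground = 2.0
        h = np.full(t.shape, BOX_HEIGHT_MM)
        drop = self._ramp(t, p["t_drop"], p["t_ic"])
        h = BOX_HEIGHT_MM + (ground - BOX_HEIGHT_MM) * drop
        flight_peak = 320.0
        rise = self._ramp(t, p["t_to"], p["t_to"] + 0.35)
        fall = self._ramp(t, p["t_to"] + 0.7, p["t_to"] + 1.05)
        h = h + (flight_peak - ground) * (rise - fall)
        return h

    # -- ground-truth events ----------------------------------------------
    def annotation(self, rate: float) -> CycleAnnotation | None:
        """Noise-free event ground truth at the given sampling rate."""
        n = int(round(self.duration_s * rate))
        t = np.arange(n) / rate
        if self.task == "static":
            return None
        if self.task == "gait":
            p = self.params
            return CycleAnnotation("gait", {
                "heel_strike": 0,
                "toe_off": int(round(0.6 * p["cycle"] * rate)),
                "next_heel_strike": int(round(p["cycle"] * rate)),
            })
        ann = detect_dvj_events(self.heel_height_mm(t), rate,
                                DEFAULT_CONTACT_THRESHOLD_MM)
        md = max_descent_frame(self.origin_mm(t)[:, 2], ann)
        return CycleAnnotation("dvj", {**ann.events, "max_descent": md})


# ---------------------------------------------------------------------------
# artifact model

@dataclass(frozen=True)
class ArtifactConfig:
    """Non-rigid corruption applied on top of the rigid marker placement."""

    sta_amplitude_mm: float = 3.0
    sta_frequency_hz: float = 1.5
    bra_shift_mm: float = 15.0      # superior XP displacement, dynamic trials,
                                    # applied to female templates only
    noise_sigma_mm: float = 0.5
    occlusions: tuple = ()          # (marker, start_frame, n_frames) episodes
    flicker_fraction: float = 0.0   # full-marker-set dropout fraction

    def __post_init__(self):
        for name in ("sta_amplitude_mm", "sta_frequency_hz", "bra_shift_mm",
                     "noise_sigma_mm", "flicker_fraction"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.flicker_fraction > 1:
            raise ConfigError("flicker_fraction must be <= 1")

    @classmethod
    def none(cls) -> "ArtifactConfig":
        """Rigid, noise-free configuration (ground-truth pass-through)."""
        return cls(sta_amplitude_mm=0.0, bra_shift_mm=0.0, noise_sigma_mm=0.0)


@dataclass
class GroundTruth:
    """Noise-free angles, events and cycle metrics for one generated trial."""

    angles_deg: np.ndarray          # (n, 3): tilt, obliquity, axial
    origin_mm: np.ndarray           # (n, 3)
    annotation: CycleAnnotation | None
    metrics: TiltMetrics | None


# ---------------------------------------------------------------------------
# trial and cohort generation

def generate_trial(template: SubjectTemplate, profile: MotionProfile,
                   artifact: ArtifactConfig = ArtifactConfig(),
                   rate: float = DEFAULT_RATE_HZ,
                   rng: np.random.Generator | int | None = 0,
                   ) -> tuple[MarkerTrialSet, GroundTruth]:
    """One trial: rigid placement + soft tissue + bra shift + noise + occlusion."""
    if rate <= 0:
        raise ConfigError("rate must be positive")
    rng = np.random.default_rng(rng)
    n = int(round(profile.duration_s * rate))
    t = np.arange(n) / rate

    angles = profile.angles_deg(t)
    origin = profile.origin_mm(t)
    R = Rotation.from_euler("YXZ", angles, degrees=True).as_matrix()  # (n,3,3)

    local = {k: np.asarray(v, dtype=float) for k, v in template.local.items()}
    if (artifact.bra_shift_mm > 0 and template.sex == "F"
            and profile.task != "static"):
        local["XP"] = local["XP"] + artifact.bra_shift_mm * BRA_SHIFT_DIRECTION

    positions: dict[str, np.ndarray] = {}
    for name, loc in local.items():
        pos = origin + np.einsum("nij,j->ni", R, loc)
        if artifact.sta_amplitude_mm > 0:
            phase = rng.uniform(0, 2 * np.pi)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            wobble = artifact.sta_amplitude_mm * np.sin(
                2 * np.pi * artifact.sta_frequency_hz * t + phase)
            pos = pos + wobble[:, None] * direction[None, :]
        positions[name] = pos

    heel = np.stack([origin[:, 0], np.full(n, 80.0),
                     profile.heel_height_mm(t)], axis=-1)
    positions["HEEL"] = heel

    if artifact.noise_sigma_mm > 0:
        for name in positions:
            positions[name] = positions[name] + rng.normal(
                scale=artifact.noise_sigma_mm, size=(n, 3))

    occluded = {name: np.zeros(n, dtype=bool) for name in positions}
    for marker, start, length in artifact.occlusions:
        if marker not in occluded:
            raise ConfigError(f"occlusion names unknown marker {marker!r}")
        occluded[marker][start:start + length] = True
    if artifact.flicker_fraction > 0:
        n_flick = int(round(artifact.flicker_fraction * n))
        frames = rng.choice(n, size=n_flick, replace=False)
        for name in occluded:
            occluded[name][frames] = True

    trial = MarkerTrialSet(positions=positions, rate=rate, kind=profile.task,
                           sex=template.sex, occluded=occluded)
    annotation = profile.annotation(rate)
    truth_metrics = None
    if annotation is not None:
        truth_metrics = compute_metrics(angles[:, 0], annotation,
                                        origin_height=origin[:, 2])
    truth = GroundTruth(angles_deg=angles, origin_mm=origin,
                        annotation=annotation, metrics=truth_metrics)
    return trial, truth


@dataclass
class Participant:
    subject: str
    sex: str
    height_cm: float
    template: SubjectTemplate
    trials: dict[str, MarkerTrialSet]
    truths: dict[str, GroundTruth]


@dataclass
class Cohort:
    participants: list[Participant]
    seed: int

    def __len__(self) -> int:
        return len(self.participants)

    def by_subject(self) -> dict[str, Participant]:
        return {p.subject: p for p in self.participants}


#: per-sex sampling targets (mean, SD) for trunk-tilt profile parameters
SEX_PROFILE_TARGETS = {
    "F": {"gait_mean": (-1.83, 2.34), "gait_rom": (4.97, 2.05),
          "dvj_peak": (38.30, 11.42), "height": (163.0, 7.0)},
    "M": {"gait_mean": (-1.44, 3.61), "gait_rom": (3.36, 0.47),
          "dvj_peak": (52.81, 13.91), "height": (176.0, 7.0)},
}

FLICKER_FRACTION = 0.30


def generate_cohort(n: int = 20, n_male: int | None = None,
                    tasks: tuple[str, ...] = ("static", "gait", "dvj"),
                    artifact: ArtifactConfig = ArtifactConfig(),
                    seed: int = 0, n_flicker: int = 0,
                    center_dvj_rom: bool = False,
                    rate: float = DEFAULT_RATE_HZ) -> Cohort:
    """Seeded cohort: one static plus the requested dynamic trials per subject.

    Subject templates are stature-scaled; gait and DVJ tilt parameters are
    drawn per sex around the study-level group targets (males flex more in
    the DVJ).  ``n_flicker`` male participants receive 30% full-marker-set
    flicker in their dynamic trials, emulating mis-calibrated capture
    sessions that quality control should reject.  ``center_dvj_rom``
    recentres each sex's DVJ excursion draws so the realised group mean
    equals the target exactly (calibrated-cohort option).
    """
    if n < 1:
        raise ConfigError("cohort size must be >= 1")
    if n_male is None:
        n_male = int(round(n * 9 / 20))  # study split: 9 males of 20 tested
    if not (0 <= n_male <= n):
        raise ConfigError("n_male out of range")
    if n_flicker > n_male:
        raise ConfigError("flicker participants are drawn from the males")

    root = np.random.SeedSequence(seed)
    subject_seeds = root.spawn(n)
    sexes = ["M"] * n_male + ["F"] * (n - n_male)

    # pre-draw DVJ excursions so they can optionally be recentred per sex
    draw_rng = np.random.default_rng(root.spawn(1)[0])
    peaks = np.empty(n)
    for i, sex in enumerate(sexes):
        mu, sd = SEX_PROFILE_TARGETS[sex]["dvj_peak"]
        peaks[i] = draw_rng.normal(mu, sd)
    if center_dvj_rom:
        for sex in ("F", "M"):
            idx = [i for i, s in enumerate(sexes) if s == sex]
            if not idx:
                continue
            target = SEX_PROFILE_TARGETS[sex]["dvj_peak"][0]
            # alternate recentring and clipping until the realised group
            # mean sits on the target within the physiological bounds
            for _ in range(50):
                peaks[idx] += target - peaks[idx].mean()
                peaks[idx] = np.clip(peaks[idx], 20.0, 70.0)
                if abs(peaks[idx].mean() - target) < 1e-9:
                    break
    peaks = np.clip(peaks, 20.0, 70.0)

    participants = []
    for i, sex in enumerate(sexes):
        rng = np.random.default_rng(subject_seeds[i])
        tgt = SEX_PROFILE_TARGETS[sex]
        height = float(np.clip(rng.normal(*tgt["height"]), 150.0, 198.0))
        template = SubjectTemplate.default(height_cm=height, sex=sex)
        gait_mean = float(np.clip(rng.normal(*tgt["gait_mean"]), -6.0, 2.0))
        gait_rom = float(np.clip(rng.normal(*tgt["gait_rom"]), 2.0, 8.0))
        base = float(np.clip(rng.normal(-2.0, 2.0), -6.0, 2.0))

        art = artifact
        if i < n_flicker and sex == "M":
            art = replace(artifact, flicker_fraction=FLICKER_FRACTION)

        profiles = {}
        if "static" in tasks:
            profiles["static"] = MotionProfile.static()
        if "gait" in tasks:
            profiles["gait"] = MotionProfile.gait(
                mean_tilt_deg=gait_mean, rom_deg=gait_rom)
        if "dvj" in tasks:
            profiles["dvj"] = MotionProfile.dvj(
                peak_flexion_deg=float(peaks[i]), base_tilt_deg=base,
                height_cm=height)

        trials, truths = {}, {}
        for kind, profile in profiles.items():
            # static trials carry no soft-tissue artifact, bra shift or flicker
            trial_art = (replace(art, sta_amplitude_mm=0.0,
                                 flicker_fraction=0.0)
                         if kind == "static" else art)
            trial, truth = generate_trial(template, profile, trial_art,
                                          rate=rate, rng=rng)
            trial.subject = f"S{i + 1:02d}"
            trials[kind] = trial
            truths[kind] = truth
        participants.append(Participant(
            subject=f"S{i + 1:02d}", sex=sex, height_cm=height,
            template=template, trials=trials, truths=truths))
    return Cohort(participants=participants, seed=seed)
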