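"""Synthetic EEG cohort generator.

Produces recording cohorts with two independently controllable sources of
structure:

* a class-level spectral effect ("EEG slowing": delta/theta power up,
  alpha/beta down in the dementia groups relative to controls), scaled by
  ``class_effect_scale`` (0 = no class signal at all);
* subject-level spectral fingerprints — per-band log-power offsets and
  per-channel gains drawn once per subject — which make epochs of the same
  subject mutually similar and thereby create the epoch-leakage phenomenon
  that pooled k-fold cross-validation exploits.

Each channel is a mixture of band-limited noises: white noise filtered with
the same zero-phase Butterworth band filters the feature extractor uses,
variance-normalized, and scaled by the subject's per-band amplitude. This
keeps generator and analyzer spectrally consistent, so specified band-power
shares are recoverable from the extracted features. No attempt is made at
physiological realism (no 1/f continuum, no transient artifacts).
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import yaml

from .bands import DEFAULT_BANDS, Band
from .filters import bandpass_sos, filtfilt
from .preprocess import Recording

CLASS_ORDER = ("AD", "FTD", "CN")

# Standard anterior-posterior bipolar chains of the 10-20 system ("double
# banana"): two temporal and two parasagittal four-link chains plus the
# fronto-central midline derivation, for 17 channels. The exact list is
# configuration, not physiology; any ordered name list works.
DEFAULT_MONTAGE_17 = [
    "Fp1-F7", "F7-T3", "T3-T5", "T5-O1",
    "Fp2-F8", "F8-T4", "T4-T6", "T6-O2",
    "Fp1-F3", "F3-C3", "C3-P3", "P3-O1",
    "Fp2-F4", "F4-C4", "C4-P4", "P4-O2",
    "Fz-Cz",
]


@dataclass(frozen=True)
class ClassSpectralProfile:
    """Mean log relative band power for one diagnostic class."""

    class_label: str
    band_log_power: dict[str, float]

    def __post_init__(self) -> None:
        for name, lp in self.band_log_power.items():
            if not np.isfinite(lp):
                raise ValueError(f"non-finite log power for band {name!r}")


def _log_shares(shares: dict[str, float]) -> dict[str, float]:
    total = sum(shares.values())
    return {k: float(np.log(v / total)) for k, v in shares.items()}


# Directionally encodes EEG slowing for the dementia groups: more delta and
# theta, less alpha and beta than controls; FTD intermediate between AD and
# CN. Magnitudes are configurable study parameters, not clinical estimates.
DEFAULT_CLASS_PROFILES: dict[str, ClassSpectralProfile] = {
    "CN": ClassSpectralProfile("CN", _log_shares(
        {"delta": 0.14, "theta": 0.12, "alpha": 0.36, "beta": 0.28, "gamma": 0.10})),
    "AD": ClassSpectralProfile("AD", _log_shares(
        {"delta": 0.32, "theta": 0.26, "alpha": 0.18, "beta": 0.14, "gamma": 0.10})),
    "FTD": ClassSpectralProfile("FTD", _log_shares(
        {"delta": 0.23, "theta": 0.19, "alpha": 0.27, "beta": 0.21, "gamma": 0.10})),
}


@dataclass(frozen=True)
class SubjectProfile:
    """One subject's realized spectral parameters.

    band_log_power already includes the (scaled) class effect and the
    subject fingerprint; channel_gain is a positive per-channel multiplier.
    """

    subject_id: str
    class_label: str
    band_log_power: dict[str, float]
    channel_gain: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.channel_gain) <= 0):
            raise ValueError("channel gains must be positive")

    def band_shares(self, bands: tuple[Band, ...] = DEFAULT_BANDS) -> dict[str, float]:
        """Relative band-power shares implied by the log powers (sum to 1)."""
        powers = np.array([np.exp(self.band_log_power[b.name]) for b in bands])
        shares = powers / powers.sum()
        return {b.name: float(s) for b, s in zip(bands, shares)}


@dataclass
class CohortSpec:
    """Study-design parameters of a synthetic cohort.

    Defaults mirror the emulated clinical study: 10 AD / 10 FTD / 8 CN
    subjects, 500 Hz sampling, 13 min mean recordings for the patient
    groups and 21 min for controls, 17 montaged channels.
    """

    n_per_class: dict[str, int] = field(
        default_factory=lambda: {"AD": 10, "FTD": 10, "CN": 8})
    duration_s: float | dict[str, float] = field(
        default_factory=lambda: {"AD": 780.0, "FTD": 780.0, "CN": 1260.0})
    fs_hz: float = 500.0
    channel_names: list[str] = field(default_factory=lambda: list(DEFAULT_MONTAGE_17))
    sigma_subject: float = 0.4     # SD of per-band log-power fingerprints
    sigma_channel_gain: float = 0.1  # SD of per-channel log gains
    class_effect_scale: float = 1.0  # 0 = no between-class signal
    noise_floor: float = 0.02      # broadband noise power relative to band total
    amplitude_uv: float = 30.0     # overall RMS scale, microvolts
    bands: tuple[Band, ...] = DEFAULT_BANDS
    seed: int = 0

    def __post_init__(self) -> None:
        for cls, n in self.n_per_class.items():
            if n < 1:
                raise ValueError(f"n_per_class[{cls!r}] must be >= 1")
        nyq = self.fs_hz / 2.0
        for b in self.bands:
            if b.high_hz >= nyq:
                raise ValueError(f"band {b.name} [{b.low_hz}, {b.high_hz}) exceeds Nyquist {nyq} Hz")
        if self.noise_floor < 0 or self.sigma_subject < 0:
            raise ValueError("noise_floor and sigma_subject must be non-negative")

    def class_duration_s(self, class_label: str) -> float:
        if isinstance(self.duration_s, dict):
            return float(self.duration_s[class_label])
        return float(self.duration_s)

    @property
    def n_subjects(self) -> int:
        return sum(self.n_per_class.values())

    # -- config-file round trip ------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_per_class": dict(self.n_per_class),
            "duration_s": dict(self.duration_s) if isinstance(self.duration_s, dict) else self.duration_s,
            "fs_hz": self.fs_hz,
            "channel_names": list(self.channel_names),
            "sigma_subject": self.sigma_subject,
            "sigma_channel_gain": self.sigma_channel_gain,
            "class_effect_scale": self.class_effect_scale,
            "noise_floor": self.noise_floor,
            "amplitude_uv": self.amplitude_uv,
            "bands": [{"name": b.name, "low_hz": b.low_hz, "high_hz": b.high_hz} for b in self.bands],
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        if "bands" in d:
            d["bands"] = tuple(Band(**b) for b in d["bands"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _ordered_classes(spec: CohortSpec) -> list[str]:
    known = [c for c in CLASS_ORDER if c in spec.n_per_class]
    extra = [c for c in spec.n_per_class if c not in CLASS_ORDER]
    return known + sorted(extra)


def make_subject_profiles(
    spec: CohortSpec,
    profiles: dict[str, ClassSpectralProfile] | None = None,
) -> list[SubjectProfile]:
    """Draw one SubjectProfile per subject, deterministically from spec.seed.

    Subject log band power = grand mean over the cohort's class profiles
    + class_effect_scale * (class mean - grand mean)
    + Normal(0, sigma_subject^2) per-band fingerprint,
    so class_effect_scale scales only the *between-class* differences and
    at 0 the expected spectrum is identical across classes while subjects
    still differ through their fingerprints.
    """
    if profiles is None:
        profiles = DEFAULT_CLASS_PROFILES
    classes = _ordered_classes(spec)
    missing = [c for c in classes if c not in profiles]
    if missing:
        raise ValueError(f"no spectral profile for class(es) {missing}")

    band_names = [b.name for b in spec.bands]
    class_lp = {
        c: np.array([profiles[c].band_log_power[n] for n in band_names]) for c in classes
    }
    grand = np.mean([class_lp[c] for c in classes], axis=0)

    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 1]))
    out: list[SubjectProfile] = []
    for cls in classes:
        mean_lp = grand + spec.class_effect_scale * (class_lp[cls] - grand)
        for i in range(spec.n_per_class[cls]):
            fingerprint = rng.normal(0.0, spec.sigma_subject, size=len(band_names))
            gains = np.exp(rng.normal(0.0, spec.sigma_channel_gain, size=len(spec.channel_names)))
            out.append(
                SubjectProfile(
                    subject_id=f"{cls}-{i + 1:02d}",
                    class_label=cls,
                    band_log_power={n: float(v) for n, v in zip(band_names, mean_lp + fingerprint)},
                    channel_gain=gains,
                )
            )
    return out


def _subject_seed(spec_seed: int, subject_id: str) -> np.random.SeedSequence:
    # crc32 keys the stream to the subject id, independent of cohort order
    return np.random.SeedSequence([int(spec_seed), 2, zlib.crc32(subject_id.encode())])


def synthesize_recording(profile: SubjectProfile, spec: CohortSpec) -> Recording:
    """Render one subject's multichannel recording from their profile.

    Per channel: sum over bands of sqrt(exp(band_log_power)) x unit-variance
    band-limited noise, times the channel gain, plus a broadband white-noise
    floor with power noise_floor x (total band power). Reproducible given
    (spec.seed, subject_id).
    """
    n_samples = int(round(spec.class_duration_s(profile.class_label) * spec.fs_hz))
    n_ch = len(spec.channel_names)
    rng = np.random.default_rng(_subject_seed(spec.seed, profile.subject_id))

    band_amp = {
        b.name: np.sqrt(np.exp(profile.band_log_power[b.name])) for b in spec.bands
    }
    total_power = sum(a * a for a in band_amp.values())
    noise_sd = np.sqrt(spec.noise_floor * total_power)

    data = np.zeros((n_ch, n_samples))
    for b in spec.bands:
        sos = bandpass_sos(b.low_hz, b.high_hz, spec.fs_hz)
        white = rng.standard_normal((n_ch, n_samples))
        shaped = filtfilt(sos, white)
        shaped /= shaped.std(axis=-1, keepdims=True)
        data += band_amp[b.name] * shaped
    if noise_sd > 0:
        data += noise_sd * rng.standard_normal((n_ch, n_samples))
    data *= profile.channel_gain[:, None] * spec.amplitude_uv

    return Recording(
        subject_id=profile.subject_id,
        class_label=profile.class_label,
        fs_hz=spec.fs_hz,
        channel_names=list(spec.channel_names),
        samples=data.astype(np.float32),
    )


def generate_cohort(
    spec: CohortSpec,
    profiles: dict[str, ClassSpectralProfile] | None = None,
) -> list[Recording]:
    """One recording per subject; ids unique, class labels attached."""
    return [synthesize_recording(p, spec) for p in make_subject_profiles(spec, profiles)]
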