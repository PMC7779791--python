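"""Synthetic TMS-EEG cohort generation.

Generates epoched TMS-evoked potentials (TEPs) for a two-group cohort
(healthy vs. white-matter injury), together with per-subject fractional
anisotropy (FA) tables that share a single latent injury-severity scalar
with the EEG distortion.  Every generator is seeded and reproducible.

Conventions (documented, not physiological ground truth):

* TEP waveforms are sums of Gaussian-windowed component peaks.  The default
  component set (P30, N45, P60, N100, P180) follows standard TEP
  literature and is fully overridable through :class:`SimulationConfig`.
* Injury scales component amplitudes by ``1 - severity * proximity_weight``
  and shifts latencies by ``+severity * 20`` ms.
* The inhibitory (1 Hz) protocol scales amplitudes by an effective
  plasticity factor; injury attenuates the single-vs-inhibitory contrast.
* Background noise is AR(1) (coefficient 0.95) mixed 1:1 in variance with
  white noise — cheap, seedable, spectrally plausible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "ComponentSpec",
    "SimulationConfig",
    "EpochSet",
    "DEFAULT_COMPONENTS",
    "DEFAULT_PROXIMITY_WEIGHTS",
    "DEFAULT_FA_BASELINE",
    "DEFAULT_FA_LOADING",
    "component_waveform",
    "effective_plasticity_factor",
    "simulate_tep_waveform",
    "simulate_fa",
    "simulate_cohort",
]

CONDITIONS = ("single", "inhibitory")

#: Latency shift, in ms, applied to every component at severity 1.
SEVERITY_LATENCY_SHIFT_MS = 20.0

#: Hard clip range for generated FA values.
FA_CLIP = (0.05, 0.95)


@dataclass(frozen=True)
class ComponentSpec:
    """One canonical TEP component peak.

    ``width_ms`` is the Gaussian standard deviation of the peak window.
    """

    label: str
    latency_ms: float
    latency_sd_ms: float
    amplitude_uv: float
    amplitude_sd_uv: float
    width_ms: float


DEFAULT_COMPONENTS: tuple[ComponentSpec, ...] = (
    ComponentSpec("P30", 30.0, 3.0, 3.0, 0.5, 7.0),
    ComponentSpec("N45", 45.0, 3.0, -4.0, 0.6, 8.0),
    ComponentSpec("P60", 60.0, 4.0, 4.5, 0.6, 10.0),
    ComponentSpec("N100", 100.0, 6.0, -6.0, 0.8, 22.0),
    ComponentSpec("P180", 180.0, 8.0, 3.5, 0.6, 40.0),
)

# Stimulation is over left M1: proximal/left hotspots carry the largest
# injury effect, contralateral less, occipital least.
DEFAULT_PROXIMITY_WEIGHTS: dict[str, float] = {
    "parietal_left": 1.0,
    "temporal_left": 0.9,
    "frontal_left": 0.8,
    "parietal_right": 0.7,
    "temporal_right": 0.6,
    "frontal_right": 0.55,
    "occipital_left": 0.5,
    "occipital_right": 0.4,
}

# White-matter ROIs with ICBM-MORI-style names.  Loadings impose a
# proximal/left > distal/right severity gradient on FA.
DEFAULT_FA_BASELINE: dict[str, float] = {
    "corpus_callosum_genu": 0.55,
    "anterior_corona_radiata_L": 0.50,
    "superior_fronto_occipital_fasciculus_L": 0.52,
    "anterior_internal_capsule_L": 0.53,
    "superior_longitudinal_fasciculus_L": 0.50,
    "anterior_corona_radiata_R": 0.50,
    "superior_longitudinal_fasciculus_R": 0.49,
    "posterior_thalamic_radiation_R": 0.54,
    "sagittal_stratum_R": 0.54,
    "middle_cerebellar_peduncle": 0.32,
}
DEFAULT_FA_LOADING: dict[str, float] = {
    "corpus_callosum_genu": 0.18,
    "anterior_corona_radiata_L": 0.16,
    "superior_fronto_occipital_fasciculus_L": 0.15,
    "anterior_internal_capsule_L": 0.13,
    "superior_longitudinal_fasciculus_L": 0.12,
    "anterior_corona_radiata_R": 0.08,
    "superior_longitudinal_fasciculus_R": 0.06,
    "posterior_thalamic_radiation_R": 0.04,
    "sagittal_stratum_R": 0.03,
    "middle_cerebellar_peduncle": 0.01,
}


@dataclass
class SimulationConfig:
    """Cohort-level simulation parameters.  See module docstring."""

    n_healthy: int = 20
    n_injured: int = 20
    epochs_per_condition: int = 60
    sampling_rate: float = 1000.0
    pre_stim_ms: float = 100.0
    post_stim_ms: float = 350.0
    severity_mean: float = 0.6
    severity_sd: float = 0.15
    components: tuple[ComponentSpec, ...] = DEFAULT_COMPONENTS
    noise_sd: float = 2.0
    artifact_rate: float = 0.0
    artifact_amp: float = 300.0
    plasticity_factor_healthy: float = 0.7
    plasticity_attenuation_per_severity: float = 1.0
    fa_baseline: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FA_BASELINE))
    fa_loading: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FA_LOADING))
    fa_noise_sd: float = 0.04
    proximity_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROXIMITY_WEIGHTS))
    seed: int = 0

    def validate(self) -> None:
        if self.n_healthy < 0 or self.n_injured < 0:
            raise ValueError("subject counts must be non-negative")
        if self.n_healthy + self.n_injured == 0:
            raise ValueError("cohort must contain at least one subject")
        if self.epochs_per_condition <= 0:
            raise ValueError("epochs_per_condition must be > 0")
        if self.sampling_rate < 250.0:
            raise ValueError("sampling_rate must be >= 250 Hz")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must be in [0, 1]")
        for roi, b in self.fa_baseline.items():
            if not 0.0 < b < 1.0:
                raise ValueError(f"fa_baseline for {roi!r} must be in (0, 1)")
        for roi, l in self.fa_loading.items():
            if l < 0:
                raise ValueError(f"fa_loading for {roi!r} must be >= 0")
        for comp in self.components:
            if not 0.0 < comp.latency_ms < self.post_stim_ms:
                raise ValueError(
                    f"component {comp.label} latency outside (0, post_stim_ms)")

    def time_axis(self) -> np.ndarray:
        """Epoch time axis in ms, pulse at 0, uniform 1000/fs spacing."""
        step = 1000.0 / self.sampling_rate
        n_pre = int(round(self.pre_stim_ms / step))
        n_post = int(round(self.post_stim_ms / step))
        return np.arange(-n_pre, n_post + 1) * step

    def to_dict(self) -> dict:
        d = asdict(self)
        d["components"] = [asdict(c) for c in self.components]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "components" in d:
            d["components"] = tuple(
                ComponentSpec(**c) for c in d["components"])
        return cls(**d)


@dataclass
class EpochSet:
    """Raw per-electrode epochs for one cohort.

    ``data`` has shape ``(n_subjects, n_conditions, n_electrodes,
    n_epochs, n_times)`` in µV; ``retained`` is a boolean mask over the
    first four axes (all True before rejection).
    """

    data: np.ndarray
    retained: np.ndarray
    subjects: list[str]
    conditions: tuple[str, ...]
    electrodes: list[str]
    times: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        if self.data.shape[:4] != self.retained.shape:
            raise ValueError("retained mask does not match data shape")
        dt = np.diff(self.times)
        if not np.allclose(dt, 1000.0 / self.sampling_rate):
            raise ValueError("time axis must be uniform at 1000/fs ms")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[3]

    def copy(self) -> "EpochSet":
        return EpochSet(self.data.copy(), self.retained.copy(),
                        list(self.subjects), tuple(self.conditions),
                        list(self.electrodes), self.times.copy(),
                        self.sampling_rate)

    def electrode_index(self, label: str) -> int:
        return self.electrodes.index(label)


def component_waveform(times_ms: np.ndarray,
                       components=DEFAULT_COMPONENTS) -> np.ndarray:
    """Deterministic noiseless component sum (the healthy template)."""
    t = np.asarray(times_ms, dtype=float)
    out = np.zeros_like(t)
    for c in components:
        out += c.amplitude_uv * np.exp(
            -0.5 * ((t - c.latency_ms) / c.width_ms) ** 2)
    return out


def effective_plasticity_factor(base_factor: float, severity: float,
                                attenuation: float) -> float:
    """Inhibitory-condition amplitude ratio after injury attenuation.

    Healthy subjects show ``base_factor`` (< 1, i.e. suppression under the
    1 Hz protocol).  Injury flattens the contrast towards 1 at a rate of
    ``attenuation`` per unit severity.
    """
    contrast = (1.0 - base_factor) * max(0.0, 1.0 - attenuation * severity)
    return 1.0 - contrast


def _noise(shape, noise_sd: float, ar_coeff: float,
           rng: np.random.Generator) -> np.ndarray:
    """AR(1)+white mixture with overall standard deviation ``noise_sd``."""
    if noise_sd == 0.0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    drive = rng.standard_normal(shape)
    ar = signal.lfilter([1.0], [1.0, -ar_coeff], drive, axis=-1)
    ar *= np.sqrt(1.0 - ar_coeff**2)  # unit stationary variance
    return noise_sd / np.sqrt(2.0) * (ar + white)


def simulate_tep_waveform(times_ms: np.ndarray,
                          severity: float,
                          condition: str,
                          components=DEFAULT_COMPONENTS,
                          *,
                          proximity_weight: float = 1.0,
                          plasticity_factor: float = 0.7,
                          plasticity_attenuation: float = 1.0,
                          noise_sd: float = 0.0,
                          ar_coeff: float = 0.95,
                          rng: np.random.Generator | None = None,
                          latency_offsets=None,
                          amplitude_offsets=None) -> np.ndarray:
    """Simulate one TEP waveform (µV) on ``times_ms``.

    Injury scales each component amplitude by
    ``1 - severity * proximity_weight`` (floored at 0) and shifts latencies
    by ``severity * 20`` ms.  The inhibitory condition multiplies
    amplitudes by the effective plasticity factor.  ``latency_offsets`` /
    ``amplitude_offsets`` carry per-subject component jitter (one value per
    component); when None they are zero.
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError(f"severity must be in [0, 1], got {severity}")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    t = np.asarray(times_ms, dtype=float)
    n = len(components)
    lat_off = np.zeros(n) if latency_offsets is None else np.asarray(latency_offsets)
    amp_off = np.zeros(n) if amplitude_offsets is None else np.asarray(amplitude_offsets)

    amp_scale = max(0.0, 1.0 - severity * proximity_weight)
    if condition == "inhibitory":
        amp_scale *= effective_plasticity_factor(
            plasticity_factor, severity, plasticity_attenuation)
    lat_shift = severity * SEVERITY_LATENCY_SHIFT_MS

    wave = np.zeros_like(t)
    for i, c in enumerate(components):
        amp = (c.amplitude_uv + amp_off[i]) * amp_scale
        lat = c.latency_ms + lat_off[i] + lat_shift
        wave += amp * np.exp(-0.5 * ((t - lat) / c.width_ms) ** 2)
    if noise_sd > 0.0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        wave = wave + _noise(t.shape, noise_sd, ar_coeff, rng)
    return wave


def simulate_fa(severity_per_subject,
                fa_baseline: dict[str, float],
                fa_loading: dict[str, float],
                fa_noise_sd: float,
                rng: np.random.Generator,
                subjects=None) -> pd.DataFrame:
    """Per-subject per-ROI FA table.

    ``FA[s, roi] = clip(baseline[roi] - loading[roi] * severity[s] + eps,
    0.05, 0.95)`` with ``eps ~ N(0, fa_noise_sd)``.  Returns a wide
    DataFrame (index subject_id, one column per ROI).
    """
    sev = np.asarray(severity_per_subject, dtype=float)
    if np.any((sev < 0) | (sev > 1)):
        raise ValueError("severity values must be in [0, 1]")
    rois = list(fa_baseline)
    for roi in rois:
        if fa_loading.get(roi, 0.0) < 0:
            raise ValueError(f"fa_loading for {roi!r} must be >= 0")
    base = np.array([fa_baseline[r] for r in rois])
    load = np.array([fa_loading.get(r, 0.0) for r in rois])
    eps = (rng.standard_normal((len(sev), len(rois))) * fa_noise_sd
           if fa_noise_sd > 0 else np.zeros((len(sev), len(rois))))
    fa = np.clip(base[None, :] - load[None, :] * sev[:, None] + eps, *FA_CLIP)
    if subjects is None:
        subjects = [f"S{i:03d}" for i in range(len(sev))]
    out = pd.DataFrame(fa, index=pd.Index(subjects, name="subject_id"),
                       columns=rois)
    return out


def _truncated_normal(mean: float, sd: float, size: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Normal(mean, sd) truncated to [0, 1] by resampling."""
    if sd == 0.0:
        return np.full(size, float(np.clip(mean, 0.0, 1.0)))
    out = np.empty(size)
    todo = np.arange(size)
    while todo.size:
        draw = rng.normal(mean, sd, todo.size)
        ok = (draw >= 0.0) & (draw <= 1.0)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def simulate_cohort(config: SimulationConfig, hotspot_map=None):
    """Generate ``(EpochSet, FATable, labels)`` for a full cohort.

    ``labels`` is a Series (index subject_id) with values ``healthy`` /
    ``injured``.  Each injured subject carries a single latent severity
    reused for both EEG distortion and FA generation; the severities are
    stored in ``labels.attrs['severity']``.  Artifact epochs (all
    electrodes of a (subject, condition, epoch) slice) receive a large
    spike with peak amplitude >= ``artifact_amp``.
    """
    from .preprocess import DEFAULT_HOTSPOTS  # avoid import cycle at top

    config.validate()
    if hotspot_map is None:
        hotspot_map = DEFAULT_HOTSPOTS
    rng = np.random.default_rng(config.seed)
    times = config.time_axis()
    n_times = times.size

    subjects = ([f"H{i:03d}" for i in range(config.n_healthy)]
                + [f"I{i:03d}" for i in range(config.n_injured)])
    groups = (["healthy"] * config.n_healthy + ["injured"] * config.n_injured)
    severity = np.concatenate([
        np.zeros(config.n_healthy),
        _truncated_normal(config.severity_mean, config.severity_sd,
                          config.n_injured, rng),
    ])

    electrodes: list[str] = []
    elec_hotspot: list[str] = []
    for hotspot, elecs in hotspot_map.items():
        for e in elecs:
            electrodes.append(e)
            elec_hotspot.append(hotspot)

    n_sub, n_cond = len(subjects), len(CONDITIONS)
    n_elec, n_ep = len(electrodes), config.epochs_per_condition
    data = np.empty((n_sub, n_cond, n_elec, n_ep, n_times))
    n_comp = len(config.components)

    for s in range(n_sub):
        lat_jit = rng.normal(0.0, [c.latency_sd_ms for c in config.components],
                             n_comp)
        amp_jit = rng.normal(0.0, [c.amplitude_sd_uv for c in config.components],
                             n_comp)
        for ci, cond in enumerate(CONDITIONS):
            # one deterministic waveform per hotspot, shared by its electrodes
            hotspot_wave = {}
            for hotspot in hotspot_map:
                w = config.proximity_weights.get(hotspot, 1.0)
                hotspot_wave[hotspot] = simulate_tep_waveform(
                    times, severity[s], cond, config.components,
                    proximity_weight=w,
                    plasticity_factor=config.plasticity_factor_healthy,
                    plasticity_attenuation=config.plasticity_attenuation_per_severity,
                    latency_offsets=lat_jit, amplitude_offsets=amp_jit)
            base = np.stack([hotspot_wave[h] for h in elec_hotspot])
            block = base[:, None, :] + _noise(
                (n_elec, n_ep, n_times), config.noise_sd, 0.95, rng)
            if config.artifact_rate > 0.0:
                bad = rng.random(n_ep) < config.artifact_rate
                for ep in np.nonzero(bad)[0]:
                    centre = rng.uniform(20.0, config.post_stim_ms - 20.0)
                    amp = config.artifact_amp * (1.0 + rng.random())
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                    spike = sign * amp * np.exp(
                        -0.5 * ((times - centre) / 4.0) ** 2)
                    block[:, ep, :] += spike[None, :]
            data[s, ci] = block

    epochs = EpochSet(
        data=data,
        retained=np.ones((n_sub, n_cond, n_elec, n_ep), dtype=bool),
        subjects=subjects,
        conditions=CONDITIONS,
        electrodes=electrodes,
        times=times,
        sampling_rate=config.sampling_rate,
    )
    fa = simulate_fa(severity, config.fa_baseline, config.fa_loading,
                     config.fa_noise_sd, rng, subjects=subjects)
    labels = pd.Series(groups, index=pd.Index(subjects, name="subject_id"),
                       name="group")
    labels.attrs["severity"] = dict(zip(subjects, severity.tolist()))
    return epochs, fa, labels
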