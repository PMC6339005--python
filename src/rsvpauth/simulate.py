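"""Synthetic face-RSVP EEG recordings with class-dependent ERP structure.

The generator emulates the registration/login protocol used for face-evoked
EEG authentication: a participant watches rapid serial visual presentation
(RSVP) streams of face images, 10 images per trial at 300 ms per image, with
exactly one target image (the account owner's face) per trial, organised as
20 blocks of 10 trials.  The EEG response to the target image carries
event-related potentials (N170, N250, P3a, P3b) whose amplitude and latency
depend on whether the face is the viewer's own ("self") or someone else's
("nonself"): self faces evoke markedly larger and earlier P3a/P3b deflections
over parietal electrodes, which is the signal the downstream classifier
exploits.

Each ERP component is a Gaussian bump in time multiplied by a fixed scalp
topography; components are summed and embedded in 1/f (pink) background
noise, per-channel independent plus a common-mode term.  A ``familiarity``
factor in [0, 1] interpolates nonself → self amplitudes/latencies, modelling
an imposter who knows the targeted user (and, reused, slow drift of the
user's own response over time).

All randomness flows through ``numpy.random.Generator``; identical seeds
yield bit-identical recordings.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

#: 16-electrode montage (international 10-20 names) of the emulated amplifier.
CHANNELS_16: tuple[str, ...] = (
    "Fz", "Cz", "P3", "Pz", "P4", "Po7", "Oz", "Po8",
    "C3", "C4", "F3", "F4", "Af7", "Af8", "Cp5", "Cp6",
)

# Quiet padding around the stimulus stream so epochs at the edges of the
# first/last trials stay inside the recording.
_PAD_PRE_MS = 500.0
_PAD_POST_MS = 1500.0

# ERP components are rendered over this span after each target onset.
_KERNEL_SPAN_MS = 1000.0


@dataclass(frozen=True)
class ERPTemplate:
    """One ERP component: a Gaussian time course times a scalp topography.

    Parameters
    ----------
    name
        Component label (e.g. ``"P3b"``).
    latency
        Peak latency for the self-face response, ms after stimulus onset.
    width
        Gaussian SD of the time course, ms.
    amplitude_self, amplitude_nonself
        Peak amplitude (µV, signed) for self-face / non-self-face responses.
    topography
        Per-channel gain in [-1, 1]; the sign of the deflection lives in the
        amplitude, the topography only spreads it over the scalp.
    latency_shift_nonself
        Added to ``latency`` for the non-self response (non-self P3 peaks
        later), ms.
    """

    name: str
    latency: float
    width: float
    amplitude_self: float
    amplitude_nonself: float
    topography: np.ndarray
    latency_shift_nonself: float = 0.0

    def __post_init__(self) -> None:
        topo = np.asarray(self.topography, dtype=float)
        object.__setattr__(self, "topography", topo)
        if self.width <= 0:
            raise ValueError(f"{self.name}: width must be > 0")
        if topo.ndim != 1:
            raise ValueError(f"{self.name}: topography must be a vector")
        if np.any(np.abs(topo) > 1 + 1e-12):
            raise ValueError(f"{self.name}: topography gains must lie in [-1, 1]")
        peak = self.latency + max(0.0, self.latency_shift_nonself)
        if not (0.0 <= self.latency and peak < _KERNEL_SPAN_MS):
            raise ValueError(
                f"{self.name}: component peak must lie inside the 0..{_KERNEL_SPAN_MS:g} ms epoch"
            )

    def effective(self, familiarity: float) -> tuple[float, float]:
        """Amplitude and latency for a response-strength mix.

        ``familiarity=1`` is the genuine self response, ``0`` the naive
        non-self response; intermediate values interpolate both amplitude and
        latency linearly.
        """
        f = float(familiarity)
        amp = self.amplitude_nonself + f * (self.amplitude_self - self.amplitude_nonself)
        lat = self.latency + (1.0 - f) * self.latency_shift_nonself
        return amp, lat

    def waveform(self, t_ms: np.ndarray, familiarity: float) -> np.ndarray:
        """Single-channel time course at times ``t_ms`` (ms post-onset)."""
        amp, lat = self.effective(familiarity)
        return amp * np.exp(-0.5 * ((np.asarray(t_ms, float) - lat) / self.width) ** 2)


@dataclass(frozen=True)
class SimConfig:
    """Recording-session layout and noise model.

    Defaults reproduce the emulated acquisition protocol: 16 channels at
    2400 Hz, 20 blocks × 10 trials, 10 images per trial at 300 ms each (one
    target per trial), hence 200 target events and 3 s per trial.
    """

    n_channels: int = 16
    channel_names: tuple[str, ...] = CHANNELS_16
    fs: float = 2400.0
    n_blocks: int = 20
    trials_per_block: int = 10
    images_per_trial: int = 10
    image_duration: float = 300.0  # ms
    noise_exponent: float = 1.0    # spectral slope: PSD ∝ 1/f^exponent
    noise_rms: float = 10.0        # µV, per independent channel
    common_noise_rms: float = 3.0  # µV, shared across channels
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.n_blocks * self.trials_per_block < 1:
            raise ValueError("at least one trial must be requested")
        if self.images_per_trial < 1 or self.image_duration <= 0:
            raise ValueError("invalid trial layout")
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must equal n_channels")
        if self.noise_rms < 0 or self.common_noise_rms < 0:
            raise ValueError("noise RMS must be >= 0")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def samples_per_image(self) -> int:
        return int(round(self.image_duration * self.fs / 1000.0))

    @property
    def trial_duration_ms(self) -> float:
        return self.images_per_trial * self.image_duration

    def replace(self, **changes) -> "SimConfig":
        return dataclasses.replace(self, **changes)


@dataclass
class ContinuousRecording:
    """Multichannel raw EEG (µV) with a target-event table.

    ``events`` holds ``(sample_index, label)`` pairs, one per target (the
    account owner's face image) onset, with ``label`` in {"self", "nonself"}
    describing the viewer's relationship to that face.
    """

    data: np.ndarray  # channels × samples, µV
    fs: float
    channel_names: tuple[str, ...]
    events: list[tuple[int, str]]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels × samples")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match data rows")
        samples = [s for s, _ in self.events]
        if any(b <= a for a, b in zip(samples, samples[1:])):
            raise ValueError("event sample indices must be strictly increasing")
        if samples and (samples[0] < 0 or samples[-1] >= self.data.shape[1]):
            raise ValueError("event sample indices must lie inside the recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def _topo(channel_names: tuple[str, ...], **gains: float) -> np.ndarray:
    """Build a topography vector from {channel name: gain} pairs."""
    topo = np.zeros(len(channel_names))
    for name, g in gains.items():
        try:
            topo[channel_names.index(name)] = g
        except ValueError as err:
            raise ValueError(f"unknown channel {name!r}") from err
    return topo


def default_templates(channel_names: tuple[str, ...] = CHANNELS_16) -> list[ERPTemplate]:
    """Default face-evoked component set.

    The self/non-self contrast is concentrated on P3a/P3b over parietal
    electrodes (P3, Pz, P4, Po8): self faces evoke a much larger and earlier
    P300 complex, N250 is slightly larger for self, N170 is face-generic.
    Amplitudes are in the single-digit-µV range typical of scalp ERPs.
    """
    return [
        ERPTemplate(
            "N170", latency=170.0, width=25.0,
            amplitude_self=-4.0, amplitude_nonself=-4.0,
            topography=_topo(channel_names, Po7=1.0, Po8=1.0, Oz=0.7, P3=0.3, P4=0.3),
        ),
        ERPTemplate(
            "N250", latency=250.0, width=30.0,
            amplitude_self=-3.5, amplitude_nonself=-3.0,
            latency_shift_nonself=10.0,
            topography=_topo(channel_names, Po7=0.8, Po8=0.8, Oz=0.6, Cp5=0.3, Cp6=0.3),
        ),
        ERPTemplate(
            "P3a", latency=320.0, width=45.0,
            amplitude_self=6.0, amplitude_nonself=2.5,
            latency_shift_nonself=30.0,
            topography=_topo(channel_names, Cz=1.0, Fz=0.6, Pz=0.8, C3=0.4, C4=0.4, P3=0.5, P4=0.5),
        ),
        ERPTemplate(
            "P3b", latency=450.0, width=70.0,
            amplitude_self=7.0, amplitude_nonself=3.0,
            latency_shift_nonself=50.0,
            topography=_topo(channel_names, Pz=1.0, P3=0.9, P4=0.9, Po8=0.6, Po7=0.4,
                             Oz=0.3, Cp5=0.4, Cp6=0.4, Cz=0.5),
        ),
    ]


def null_templates(channel_names: tuple[str, ...] = CHANNELS_16) -> list[ERPTemplate]:
    """Templates with no self/non-self contrast (both classes exchangeable)."""
    return [
        dataclasses.replace(t, amplitude_nonself=t.amplitude_self, latency_shift_nonself=0.0)
        for t in default_templates(channel_names)
    ]


def parietal_effect_templates(channel_names: tuple[str, ...] = CHANNELS_16) -> list[ERPTemplate]:
    """Discriminative signal confined to P3/Pz/P4 within 300–500 ms.

    Used for recovery studies: every other channel and time window carries
    noise only, so a correct model must localise its weights there.  Each
    channel carries its *own* pair of components (latencies at the centres
    of the 300–400 and 400–500 ms analysis windows), so every channel is
    individually informative: with one shared component, two channels
    capture most of the signal-to-noise and excluding the third is
    genuinely optimal, which would invalidate the all-three ground truth.
    """
    templates = []
    for ch, amp in (("P3", 12.0), ("Pz", 13.0), ("P4", 12.0)):
        for tag, latency in (("early", 350.0), ("late", 450.0)):
            templates.append(ERPTemplate(
                f"parietal-{ch}-{tag}", latency=latency, width=30.0,
                amplitude_self=amp, amplitude_nonself=0.0,
                topography=_topo(channel_names, **{ch: 1.0})))
    return templates


def powerlaw_noise(n_channels: int, n_samples: int, exponent: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS noise rows with power spectral density ∝ 1/f^exponent.

    Spectral-shaping construction: white Gaussian Fourier coefficients scaled
    by f^(−exponent/2), inverse-transformed, then normalised to unit RMS per
    channel (so the configured RMS is exact for every realisation).
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (rng.standard_normal((n_channels, freqs.size))
            + 1j * rng.standard_normal((n_channels, freqs.size))) * scale
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    rms = x.std(axis=1, keepdims=True)
    rms[rms == 0] = 1.0
    return x / rms


def _make_timeline(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Target-onset sample indices: one uniformly placed target per trial."""
    positions = rng.integers(0, config.images_per_trial, size=config.n_trials)
    trial_starts = np.arange(config.n_trials) * config.images_per_trial
    pad = int(round(_PAD_PRE_MS * config.fs / 1000.0))
    return pad + (trial_starts + positions) * config.samples_per_image


def _render_kernel(config: SimConfig, templates: list[ERPTemplate],
                   familiarity: float) -> np.ndarray:
    """Channels × samples ERP response following one target onset."""
    n_k = int(round(_KERNEL_SPAN_MS * config.fs / 1000.0))
    t_ms = np.arange(n_k) / config.fs * 1000.0
    kernel = np.zeros((config.n_channels, n_k))
    for tpl in templates:
        kernel += np.outer(tpl.topography, tpl.waveform(t_ms, familiarity))
    return kernel


def generate_recording(
    config: SimConfig,
    templates: list[ERPTemplate] | None = None,
    response_class: str = "self",
    familiarity: float | None = None,
    timeline: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> ContinuousRecording:
    """Simulate one registration/login session.

    Parameters
    ----------
    config
        Session layout and noise model.
    templates
        ERP component set; defaults to :func:`default_templates`.
    response_class
        ``"self"`` for the legitimate user (events labelled ``self``),
        ``"nonself"`` for an imposter watching the user's face sequence.
    familiarity
        Response-strength mix in [0, 1]; defaults to 1 for ``self`` and 0 for
        ``nonself``.  Intermediate values model a non-blind imposter who
        knows the user, or a drifted user response.
    timeline
        Precomputed target-onset samples (to share timing across the user
        and imposter recordings of one account).
    rng
        Random generator; defaults to ``default_rng(config.seed)``.
    """
    if templates is None:
        templates = default_templates(config.channel_names)
    if response_class not in ("self", "nonself"):
        raise ValueError("response_class must be 'self' or 'nonself'")
    for tpl in templates:
        if tpl.topography.size != config.n_channels:
            raise ValueError(
                f"template {tpl.name!r}: topography length {tpl.topography.size} "
                f"!= n_channels {config.n_channels}"
            )
    if familiarity is None:
        familiarity = 1.0 if response_class == "self" else 0.0
    if not 0.0 <= familiarity <= 1.0:
        raise ValueError("familiarity must lie in [0, 1]")

    if rng is None:
        rng = np.random.default_rng(config.seed)
    if timeline is None:
        timeline = _make_timeline(config, rng)
    timeline = np.asarray(timeline, dtype=int)

    n_stream = config.n_trials * config.images_per_trial * config.samples_per_image
    pad_pre = int(round(_PAD_PRE_MS * config.fs / 1000.0))
    pad_post = int(round(_PAD_POST_MS * config.fs / 1000.0))
    n_total = pad_pre + n_stream + pad_post

    data = np.zeros((config.n_channels, n_total))
    if config.noise_rms > 0:
        data += config.noise_rms * powerlaw_noise(
            config.n_channels, n_total, config.noise_exponent, rng)
    if config.common_noise_rms > 0:
        common = powerlaw_noise(1, n_total, config.noise_exponent, rng)
        data += config.common_noise_rms * common

    kernel = _render_kernel(config, templates, familiarity)
    n_k = kernel.shape[1]
    for onset in timeline:
        data[:, onset:onset + n_k] += kernel[:, : n_total - onset]

    events = [(int(s), response_class) for s in timeline]
    return ContinuousRecording(data=data, fs=config.fs,
                               channel_names=tuple(config.channel_names),
                               events=events)


def generate_subject_triplet(
    config: SimConfig,
    templates: list[ERPTemplate] | None = None,
    familiarity: float = 0.3,
) -> tuple[ContinuousRecording, ContinuousRecording, ContinuousRecording]:
    """User + two imposter sessions for one account, sharing stimulus timing.

    Returns ``(user, imposter_blind, imposter_nonblind)``: the user views
    their own face (self response); the blind imposter does not know which
    face is the target (naive non-self response); the non-blind imposter
    knows the user, modelled by interpolating ``familiarity`` of the way from
    the non-self toward the self response.
    """
    ss = np.random.SeedSequence(config.seed)
    r_time, r_user, r_blind, r_non = (np.random.default_rng(s) for s in ss.spawn(4))
    timeline = _make_timeline(config, r_time)
    user = generate_recording(config, templates, "self", None, timeline, r_user)
    blind = generate_recording(config, templates, "nonself", 0.0, timeline, r_blind)
    nonblind = generate_recording(config, templates, "nonself", familiarity, timeline, r_non)
    return user, blind, nonblind
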