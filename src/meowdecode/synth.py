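"""Synthetic meow audio and synthetic listener cohorts.

Real meows are short (roughly 0.5-2 s) harmonic vocalizations whose pitch
contour, harmonic rolloff and amplitude-modulation depth vary with the
emission context: solicitation-type meows tend to have higher, rising F0
contours, while distress meows fall in pitch and carry stronger amplitude
modulation (perceived as roughness).  :func:`synth_meow` renders such a
signal as additive harmonics under a sinusoidal AM envelope plus Gaussian
noise, and :func:`synth_corpus` draws labelled corpora from per-context
parameter distributions.

:func:`synth_cohort` generates survey respondents with the structure the
analysis stages assume: Bernoulli attributes, group-dependent context
classification accuracy, group-dependent empathy levels driven by a shared
latent trait (which also induces positive inter-item correlation, hence a
realistic Cronbach's alpha), and descriptor ratings produced by a single
latent valence factor per context plus independent noise.

Everything is deterministic given the seed carried in the spec; all draws
flow from one `numpy` Generator per call, never from global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .audio import TARGET_RATE, AudioClip
from .survey import (
    CONTEXTS,
    DESCRIPTORS,
    POSITIVE_DESCRIPTORS,
    N_AES_ITEMS,
    N_CES_ITEMS,
    DEFAULT_AES_POLARITY,
    MeowResponse,
    ResponseRecord,
)

NYQUIST = TARGET_RATE / 2.0


# ---------------------------------------------------------------------------
# Audio synthesis

@dataclass(frozen=True)
class MeowSpec:
    """Parameters of one synthetic meow.

    The F0 contour is linear from ``f0_start`` to ``f0_end`` (rising when
    end > start).  Harmonic k is attenuated by ``harmonic_rolloff`` dB per
    octave; harmonics at or above the 4 kHz Nyquist limit are truncated.
    The AM envelope is (1 + depth*sin(2*pi*rate*t)) / (1 + depth), so peak
    amplitude stays constant while modulation depth (and hence roughness)
    varies.  ``noise_snr`` is in dB; ``None`` disables noise.
    """

    f0_start: float = 400.0
    f0_end: float = 500.0
    n_harmonics: int = 8
    harmonic_rolloff: float = 9.0  # dB/octave
    am_rate: float = 100.0  # Hz
    am_depth: float = 0.3  # fraction in [0, 1]
    noise_snr: float | None = 25.0  # dB
    duration: float = 1.0  # seconds
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("f0_start", "f0_end"):
            v = getattr(self, name)
            if not 50.0 < v < 2000.0:
                raise ValueError(f"{name}={v} outside (50, 2000) Hz")
        if not 0.1 < self.duration <= 10.0:
            raise ValueError("duration must be in (0.1, 10] s")
        if not 0.0 <= self.am_depth <= 1.0:
            raise ValueError("am_depth must be in [0, 1]")
        if self.n_harmonics < 1:
            raise ValueError("need at least one harmonic")

    @property
    def f0_max(self) -> float:
        return max(self.f0_start, self.f0_end)

    def effective_harmonics(self) -> int:
        """Harmonic count after Nyquist truncation (k * f0_max < 4 kHz)."""
        k = min(self.n_harmonics, int(np.floor((NYQUIST - 1e-9) / self.f0_max)))
        if k < 1:
            raise ValueError("Nyquist truncation leaves no harmonics")
        return k


_FADE_S = 0.01  # raised-cosine onset/offset, avoids synthesis clicks
_PEAK = 0.85  # headroom below full scale for the harmonic part


def synth_meow(spec: MeowSpec) -> AudioClip:
    """Render one synthetic meow at 8 kHz, samples in [-1, 1)."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * TARGET_RATE))
    t = np.arange(n) / TARGET_RATE
    f_inst = spec.f0_start + (spec.f0_end - spec.f0_start) * t / spec.duration
    phase = 2.0 * np.pi * np.cumsum(f_inst) / TARGET_RATE

    k_max = spec.effective_harmonics()
    wave = np.zeros(n)
    for k in range(1, k_max + 1):
        amp = 10.0 ** (-spec.harmonic_rolloff * np.log2(k) / 20.0)
        wave += amp * np.sin(k * phase)

    env = (1.0 + spec.am_depth * np.sin(2.0 * np.pi * spec.am_rate * t))
    env /= (1.0 + spec.am_depth)
    n_fade = min(int(_FADE_S * TARGET_RATE), n // 4)
    if n_fade > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_fade) / n_fade))
        env[:n_fade] *= ramp
        env[-n_fade:] *= ramp[::-1]
    wave *= env
    peak = np.abs(wave).max()
    if peak > 0:
        wave *= _PEAK / peak

    if spec.noise_snr is not None and np.isfinite(spec.noise_snr):
        p_sig = np.mean(wave ** 2)
        sd = np.sqrt(p_sig / 10.0 ** (spec.noise_snr / 10.0))
        wave = wave + rng.normal(0.0, sd, n)

    wave = np.clip(wave, -1.0, 1.0 - 2.0 ** -15)
    return AudioClip(samples=wave, rate=TARGET_RATE)


@dataclass(frozen=True)
class MeowDistribution:
    """Per-context parameter distribution that :func:`synth_corpus` samples.

    F0 endpoints are Gaussian (mean, sd); AM depth, AM rate and duration
    are uniform over (lo, hi); the remaining spec fields are fixed.
    """

    f0_start: tuple[float, float] = (400.0, 30.0)
    f0_end: tuple[float, float] = (500.0, 30.0)
    am_depth: tuple[float, float] = (0.1, 0.4)
    am_rate: tuple[float, float] = (80.0, 120.0)
    duration: tuple[float, float] = (0.6, 1.5)
    n_harmonics: int = 8
    harmonic_rolloff: float = 9.0
    noise_snr: float | None = 25.0

    def draw(self, rng: np.random.Generator, seed: int) -> MeowSpec:
        def gauss(pair):
            return float(np.clip(rng.normal(*pair), 60.0, 1900.0))

        return MeowSpec(
            f0_start=gauss(self.f0_start),
            f0_end=gauss(self.f0_end),
            am_depth=float(np.clip(rng.uniform(*self.am_depth), 0.0, 1.0)),
            am_rate=float(rng.uniform(*self.am_rate)),
            duration=float(rng.uniform(*self.duration)),
            n_harmonics=self.n_harmonics,
            harmonic_rolloff=self.harmonic_rolloff,
            noise_snr=self.noise_snr,
            seed=seed,
        )


def default_corpus_classes() -> dict[str, MeowDistribution]:
    """Plausible per-context distributions for a three-context corpus.

    Food solicitation: high, rising pitch with light modulation; isolation
    (distress): falling pitch with strong modulation; brushing (relaxed):
    lower, gently rising pitch, nearly unmodulated.  These are plausibility
    choices for a Maine Coon-like voice, not calibrated to any recorded
    corpus.
    """
    return {
        "waiting_for_food": MeowDistribution(
            f0_start=(600.0, 40.0), f0_end=(700.0, 40.0),
            am_depth=(0.1, 0.3)),
        "isolation": MeowDistribution(
            f0_start=(520.0, 40.0), f0_end=(380.0, 40.0),
            am_depth=(0.5, 0.9)),
        "brushing": MeowDistribution(
            f0_start=(340.0, 30.0), f0_end=(420.0, 30.0),
            am_depth=(0.0, 0.15)),
    }


def synth_corpus(class_specs: dict[str, MeowDistribution] | None = None,
                 n_per_class: int = 10,
                 seed: int = 0) -> list[tuple[str, str, AudioClip]]:
    """Draw a labelled corpus: ``n_per_class`` clips per context.

    Returns a list of (clip_id, context, clip) triples, exactly
    ``n_per_class`` per class, in deterministic order.  At least two clips
    per class are required so that a distinct medioid and outlier exist.
    """
    if class_specs is None:
        class_specs = default_corpus_classes()
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2 (medioid + outlier)")
    rng = np.random.default_rng(seed)
    corpus = []
    for ctx in sorted(class_specs):
        dist = class_specs[ctx]
        for i in range(n_per_class):
            clip_seed = int(rng.integers(0, 2 ** 31 - 1))
            spec = dist.draw(rng, clip_seed)
            clip = synth_meow(spec)
            clip_id = f"{ctx}_{i:03d}"
            corpus.append((clip_id, ctx, replace(clip, clip_id=clip_id)))
    return corpus


# ---------------------------------------------------------------------------
# Cohort synthesis

def default_descriptor_signs() -> dict[str, int]:
    """+1 for positive-valence descriptors, -1 for negative ones."""
    return {d: (1 if d in POSITIVE_DESCRIPTORS else -1) for d in DESCRIPTORS}


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters of a synthetic survey cohort.

    Participants fall into two experience groups ("owner"/"nonowner" via
    the cat_owner attribute); classification accuracy and empathy levels
    are group-dependent.  Defaults emulate a 225-respondent online survey:
    a two-thirds-female sample, owners a bit under half, owners both more
    accurate and more empathic, and an outlier recognized roughly half as
    often as the medioid of the same context.  Empathy item means are on
    the 9-point item scale.  Descriptor ratings follow a one-factor model:
    score = round(4 + 3 * valence * sign(descriptor) + noise), clipped to
    1..7, with ``valence_by_context`` the planted latent valences.
    """

    n_participants: int = 225
    p_female: float = 146.0 / 225.0
    p_owner: float = 108.0 / 225.0
    p_grownup: float = 122.0 / 225.0
    p_parent: float = 72.0 / 225.0
    accuracy_by_group_context: dict = field(default_factory=lambda: {
        ("owner", "waiting_for_food"): 0.44,
        ("owner", "isolation"): 0.35,
        ("owner", "brushing"): 0.44,
        ("nonowner", "waiting_for_food"): 0.37,
        ("nonowner", "isolation"): 0.19,
        ("nonowner", "brushing"): 0.22,
    })
    outlier_accuracy_factor: float = 0.55
    aes_group_means: dict = field(default_factory=lambda: {
        "owner": 7.15, "nonowner": 6.8})
    ces_group_means: dict = field(default_factory=lambda: {
        "owner": 6.7, "nonowner": 4.9})
    aes_gender_gap: float = 0.6  # female minus male shift, item scale
    ces_gender_gap: float = 0.7
    aes_trait_sd: float = 0.6  # shared latent empathy trait
    aes_item_sd: float = 1.5
    ces_item_sd: float = 1.6
    valence_by_context: dict = field(default_factory=lambda: {
        "brushing": 0.8, "waiting_for_food": 0.3, "isolation": -0.8})
    descriptor_loading_signs: dict = field(
        default_factory=default_descriptor_signs)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_female", "p_owner", "p_grownup", "p_parent"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")
        for key, p in self.accuracy_by_group_context.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"accuracy for {key} must be in [0, 1]")
        if set(self.descriptor_loading_signs) != set(DESCRIPTORS):
            raise ValueError("descriptor_loading_signs must cover exactly "
                             "the 11 canonical descriptors")
        for v in self.valence_by_context.values():
            if not -1.0 <= v <= 1.0:
                raise ValueError("latent valence must be in [-1, 1]")


def _likert(rng: np.random.Generator, mean: float, sd: float,
            lo: int, hi: int) -> int:
    return int(np.clip(np.round(rng.normal(mean, sd)), lo, hi))


def synth_cohort(spec: CohortSpec) -> list[ResponseRecord]:
    """Generate a synthetic cohort of :class:`ResponseRecord`.

    Attributes are Bernoulli draws.  Context answers are correct with the
    group/context accuracy (times the outlier factor for outlier meows),
    errors spread uniformly over the two wrong contexts.  AES items are
    drawn around the group mean plus a shared latent trait, with
    unempathic items stored on the reversed scale; CES items share the
    trait at reduced weight.  Descriptor scores follow the one-factor
    valence model; the valence answer is "positive" with probability
    (1 + valence)/2.
    """
    rng = np.random.default_rng(spec.seed)
    records = []
    for i in range(spec.n_participants):
        gender = "female" if rng.random() < spec.p_female else "male"
        owner = rng.random() < spec.p_owner
        group = "owner" if owner else "nonowner"
        grownup = rng.random() < spec.p_grownup
        parent = rng.random() < spec.p_parent
        trait = rng.normal(0.0, spec.aes_trait_sd)
        g_shift = (spec.aes_gender_gap / 2.0) * (1 if gender == "female" else -1)

        aes_mu = spec.aes_group_means[group] + g_shift + trait
        aes_items = []
        for j, pol in enumerate(DEFAULT_AES_POLARITY):
            latent = _likert(rng, aes_mu, spec.aes_item_sd, 1, 9)
            aes_items.append(10 - latent if pol == "unempathic" else latent)

        ces_shift = (spec.ces_gender_gap / 2.0) * (1 if gender == "female" else -1)
        ces_mu = spec.ces_group_means[group] + ces_shift + 0.7 * trait
        ces_items = [_likert(rng, ces_mu, spec.ces_item_sd, 1, 9)
                     for _ in range(N_CES_ITEMS)]

        responses = []
        for ctx in CONTEXTS:
            v = spec.valence_by_context.get(ctx, 0.0)
            for variant in ("medioid", "outlier"):
                acc = spec.accuracy_by_group_context[(group, ctx)]
                if variant == "outlier":
                    acc = min(1.0, acc * spec.outlier_accuracy_factor)
                if rng.random() < acc:
                    chosen = ctx
                else:
                    wrong = [c for c in CONTEXTS if c != ctx]
                    chosen = wrong[int(rng.integers(0, 2))]
                valence = "positive" if rng.random() < (1.0 + v) / 2.0 else "negative"
                scores = {
                    d: int(np.clip(np.round(
                        4.0 + 3.0 * v * spec.descriptor_loading_signs[d]
                        + rng.normal(0.0, spec.noise_sd)), 1, 7))
                    for d in DESCRIPTORS
                }
                responses.append(MeowResponse(
                    true_context=ctx, variant=variant, chosen_context=chosen,
                    valence=valence, descriptor_scores=scores))

        records.append(ResponseRecord(
            participant_id=f"p{i:04d}", gender=gender, parent=parent,
            cat_owner=owner, grew_up_with_cats=grownup,
            aes_items=aes_items, ces_items=ces_items, responses=responses))
    return records
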