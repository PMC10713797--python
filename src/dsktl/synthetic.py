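"""Synthetic multi-subject, two-class motor-imagery-like EEG generator.

Real MI-EEG classes differ mainly in their spatial covariance: imagining one
limb suppresses band power over a contralateral channel group (event-related
desynchronization).  The generator emulates exactly that second-order
structure — each class gets a diagonal latent covariance with elevated
variance on its own designated channel pair — and adds cross-subject
distribution shift as a per-subject random linear mixing of the channels,
plus white sensor noise:

    trial = A_m · Σ_c^{1/2} · Z + noise_sd · N,   A_m = I + subject_shift · R_m

with Z, N white Gaussian (ch × Ts) and R_m a fixed random matrix per
subject.  It makes no attempt at realistic spectra, artifacts or
within-session nonstationarity; it exists so every stage of the pipeline is
testable without external recordings.

Seeding uses ``numpy.random.SeedSequence`` spawned per (subject, class), so
adding subjects never changes existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .exceptions import InvalidInputError
from . import spd
from .spd import FeatureSet, TrialSet

__all__ = ["SimConfig", "generate_subjects", "empirical_shift", "append_distractors"]


@dataclass
class SimConfig:
    """Study conditions for the synthetic benchmark.

    Defaults define the standard 4-subject benchmark: 8 channels, 256
    samples per trial, 60 trials per class, a class-contrast variance ratio
    of 1.0 on disjoint channel pairs, subject mixing perturbations of
    magnitude 1.8 and sensor noise of 0.5 — calibrated so that cross-subject
    transfer is hard enough for a no-adaptation classifier to leave clear
    headroom (mean accuracy around 0.72) while the classes remain separable
    within a subject.
    """

    n_subjects: int = 4
    n_trials_per_class: int = 60
    ch: int = 8
    Ts: int = 256
    class_contrast: float = 1.0
    subject_shift: float = 1.8
    noise_sd: float = 0.5
    n_distractor_features: int = 0
    seed: int = 0
    sampling_rate: float = 250.0
    class_channel_pairs: tuple = field(default=((0, 1), (2, 3)))

    def __post_init__(self) -> None:
        if self.ch < 2:
            raise InvalidInputError("ch must be >= 2")
        if self.Ts < 2 * self.ch:
            raise InvalidInputError("Ts must be >= 2*ch for well-posed covariances")
        if self.n_subjects < 1 or self.n_trials_per_class < 1:
            raise InvalidInputError("need >= 1 subject and >= 1 trial per class")
        if min(self.class_contrast, self.subject_shift, self.noise_sd) < 0:
            raise InvalidInputError("contrast/shift/noise must be nonnegative")
        for pair in self.class_channel_pairs:
            if max(pair) >= self.ch:
                raise InvalidInputError("class channel pair outside channel range")

    def to_dict(self) -> dict:
        return asdict(self)


def _class_cov_sqrt(cfg: SimConfig, class_idx: int) -> np.ndarray:
    var = np.ones(cfg.ch)
    for chn in cfg.class_channel_pairs[class_idx]:
        var[chn] += cfg.class_contrast
    return np.sqrt(var)


def generate_subjects(cfg: SimConfig) -> list[TrialSet]:
    """Draw one TrialSet per subject, fully reproducible from ``cfg.seed``."""
    subjects = []
    n_classes = len(cfg.class_channel_pairs)
    for m in range(cfg.n_subjects):
        ss_subject = np.random.SeedSequence([cfg.seed, m])
        rng_mix = np.random.default_rng(ss_subject.spawn(1)[0])
        r_m = rng_mix.standard_normal((cfg.ch, cfg.ch)) / np.sqrt(cfg.ch)
        a_m = np.eye(cfg.ch) + cfg.subject_shift * r_m
        trials = []
        labels = []
        for c in range(n_classes):
            rng_c = np.random.default_rng(np.random.SeedSequence([cfg.seed, m, c + 1]))
            sig_sqrt = _class_cov_sqrt(cfg, c)
            for _ in range(cfg.n_trials_per_class):
                z = rng_c.standard_normal((cfg.ch, cfg.Ts))
                n = rng_c.standard_normal((cfg.ch, cfg.Ts))
                trials.append(a_m @ (sig_sqrt[:, None] * z) + cfg.noise_sd * n)
                labels.append(c + 1)
        subjects.append(
            TrialSet(
                trials=np.stack(trials),
                labels=np.asarray(labels),
                subject_id=f"S{m + 1}",
                sampling_rate=cfg.sampling_rate,
            )
        )
    return subjects


def empirical_shift(subjects: list[TrialSet]) -> float:
    """Mean pairwise Riemannian distance between subjects' mean covariances.

    A scalar summary of cross-subject distribution discrepancy; it grows
    with ``subject_shift`` and shrinks after centroid alignment.
    """
    if len(subjects) < 2:
        raise InvalidInputError("need at least two subjects")
    means = [
        spd.euclidean_mean(spd.trial_covariances(s)) for s in subjects
    ]
    dists = [
        spd.riemannian_distance(means[i], means[j])
        for i in range(len(means))
        for j in range(i + 1, len(means))
    ]
    return float(np.mean(dists))


def append_distractors(
    features: FeatureSet, n_distractors: int, seed: int = 0
) -> FeatureSet:
    """Append pure-noise feature columns carrying no label information."""
    if n_distractors < 0:
        raise InvalidInputError("n_distractors must be nonnegative")
    if n_distractors == 0:
        return features
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD157]))
    noise = rng.standard_normal((features.n, n_distractors))
    return FeatureSet(
        features=np.hstack([features.features, noise]),
        labels=None if features.labels is None else features.labels.copy(),
        domain_tag=features.domain_tag,
    )
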