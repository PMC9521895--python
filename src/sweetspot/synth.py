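"""Synthetic cohorts and audio with known ground truth.

The study's raw participant data are not deposited, so every downstream
stage is exercised on simulated cohorts.  A cohort consists of a liking
matrix (participants x excerpts), a trait table and the generative
ground truth.  Wundt responders rate according to a concave quadratic
response curve

    rating(x) = plateau + b2 * (x - peak)**2 + noise,    b2 < 0,

clipped to the 0-100 visual-analogue scale, where ``x`` is the excerpt's
complexity score and ``peak`` the participant's latent preferred level
of complexity.  Non-Wundt responders follow convex, flat or monotone
linear curves; "straight-liners" answer near the scale midpoint.

A configurable rank correlation couples one trait to the latent peak
through a Gaussian copula applied before the marginal transforms, so the
Spearman correlation between trait and peak is controlled exactly
(rho_pearson_latent = 2 * sin(pi * rho_spearman / 6)).  Trait marginals
are matched to the demographics of the study sample: CAPEp and AQ as
scaled Beta variates on [1, 4] (mean/SD 1.48/0.32 and 2.20/0.38), ACE as
a negative binomial count, mood as a 5-point ordinal, and so on.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .io import LikingMatrix, StimulusTable, TraitTable, load_table1

__all__ = ["CohortConfig", "GroundTruth", "generate_cohort", "generate_audio"]


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    """Shape parameters of a Beta distribution with given mean and sd on (0,1)."""
    nu = mean * (1 - mean) / sd**2 - 1
    if nu <= 0:
        raise ValueError("infeasible Beta mean/sd")
    return mean * nu, (1 - mean) * nu


# marginal targets from the study sample's demographics (Wundt subset)
_CAPEP_AB = _beta_params((1.48 - 1) / 3, 0.32 / 3)
_AQ_AB = _beta_params((2.20 - 1) / 3, 0.38 / 3)
_MOOD_P = np.array([0.01, 0.04, 0.34, 0.55, 0.06])  # mean 3.61


@dataclass(frozen=True)
class CohortConfig:
    """Generative settings for a synthetic cohort.

    Defaults mirror the study conditions: a 321-participant cohort rating
    the packaged 29-excerpt stimulus set, latent preferred complexity
    centred mid-range (mean 5.0, SD 1.8, matching the reported peak
    distribution), curve sharpness -1 +/- 0.3 rating units per squared
    complexity unit, rating noise SD 10 on the 0-100 scale, and a 44%
    share of non-Wundt responders (140 of 321 in the study).
    """

    n_participants: int = 321
    stimulus_table: StimulusTable | None = None
    peak_mean: float = 5.0
    peak_sd: float = 1.8
    sharpness_mean: float = -1.0
    sharpness_sd: float = 0.3
    frac_nonwundt: float = 0.44
    noise_sd: float = 10.0
    trait_peak_rho: float = 0.0
    target_trait: str = "capep"
    frac_straightliners: float = 0.0
    plateau_range: tuple[float, float] = (60.0, 90.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.frac_nonwundt <= 1 and 0 <= self.frac_straightliners <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.sharpness_mean >= 0:
            raise ValueError("sharpness_mean must be negative (concave curves)")
        if not -1 < self.trait_peak_rho < 1:
            raise ValueError("trait_peak_rho must lie in (-1, 1)")


@dataclass(frozen=True)
class GroundTruth:
    """Per-participant generative truth for a synthetic cohort.

    ``df`` columns: ``responder_class`` (wundt / nonwundt / straightliner),
    ``curve`` (wundt / convex / flat / linear / straightliner),
    ``latent_peak`` (NaN when the class has no preferred level),
    ``quad_true`` (generative quadratic coefficient), ``plateau`` and
    ``z_peak`` (the latent normal score behind the peak and the copula).
    """

    df: pd.DataFrame

    @property
    def latent_peaks(self) -> pd.Series:
        return self.df["latent_peak"]

    @property
    def classes(self) -> pd.Series:
        return self.df["responder_class"]


def _truncated_normal_below(
    rng: np.random.Generator, mean: float, sd: float, upper: float, size: int
) -> np.ndarray:
    """Normal draws rejected until all fall at or below ``upper``."""
    out = rng.normal(mean, sd, size)
    bad = out > upper
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out > upper
    return out


def _trait_marginal(name: str, u: np.ndarray) -> np.ndarray:
    """Map uniform scores to a trait's marginal distribution."""
    if name == "capep":
        return 1 + 3 * stats.beta.ppf(u, *_CAPEP_AB)
    if name == "aq":
        return 1 + 3 * stats.beta.ppf(u, *_AQ_AB)
    if name == "ace":
        # mean 1.76, SD 1.58 -> negative binomial (overdispersed count)
        m, v = 1.76, 1.58**2
        r = m**2 / (v - m)
        return stats.nbinom.ppf(u, r, r / (r + m))
    if name == "baisv":
        return np.clip(np.round(stats.norm.ppf(u, 28.87, 5.76)), 0, 49)
    if name == "mood":
        return np.searchsorted(np.cumsum(_MOOD_P), u, side="right") + 1.0
    if name == "training_years":
        return np.round(stats.gamma.ppf(u, 0.55, scale=9.0), 1)
    if name == "daily_listening_h":
        a, b = (0 - 2.3) / 1.4, (4.5 - 2.3) / 1.4
        return np.round(stats.truncnorm.ppf(u, a, b, loc=2.3, scale=1.4), 1)
    raise ValueError(f"unknown trait {name!r}")


_TRAITS = (
    "capep",
    "aq",
    "ace",
    "baisv",
    "mood",
    "training_years",
    "daily_listening_h",
)
_NONWUNDT_CURVES = ("convex", "flat", "linear")


def generate_cohort(
    config: CohortConfig,
) -> tuple[LikingMatrix, TraitTable, GroundTruth]:
    """Simulate a cohort: liking matrix, trait table and ground truth.

    Identical configs (including the seed) yield bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    stimuli = config.stimulus_table if config.stimulus_table is not None else load_table1()
    x = stimuli.complexity.to_numpy()
    lo, hi = stimuli.complexity_range
    n = config.n_participants
    if n < 1:
        raise ValueError("n_participants must be >= 1")

    # responder classes
    u = rng.random(n)
    classes = np.where(
        u < config.frac_straightliners,
        "straightliner",
        np.where(u < config.frac_straightliners + config.frac_nonwundt, "nonwundt", "wundt"),
    )
    curve = classes.astype(object).copy()
    nonwundt_idx = np.flatnonzero(classes == "nonwundt")
    for i, idx in enumerate(nonwundt_idx):  # even split among the three shapes
        curve[idx] = _NONWUNDT_CURVES[i % 3]
    curve[classes == "wundt"] = "wundt"

    # latent peaks and trait coupling (Gaussian copula on z_peak)
    z_peak = rng.standard_normal(n)
    latent_peak = config.peak_mean + config.peak_sd * z_peak
    r_latent = 2 * math.sin(math.pi * config.trait_peak_rho / 6)
    traits = {}
    for name in _TRAITS:
        z = rng.standard_normal(n)
        if name == config.target_trait:
            z = r_latent * z_peak + math.sqrt(1 - r_latent**2) * z
        traits[name] = _trait_marginal(name, stats.norm.cdf(z))

    # response curves
    b2 = np.zeros(n)
    plateau = np.full(n, np.nan)
    mu = np.empty((n, x.size))
    is_w = classes == "wundt"
    n_w = int(is_w.sum())
    if n_w:
        b2w = _truncated_normal_below(
            rng, config.sharpness_mean, config.sharpness_sd, -0.2, n_w
        )
        b2[is_w] = b2w
        plw = rng.uniform(*config.plateau_range, n_w)
        plateau[is_w] = plw
        mu[is_w] = plw[:, None] + b2w[:, None] * (x[None, :] - latent_peak[is_w, None]) ** 2
    for i in np.flatnonzero(~is_w):
        c = curve[i]
        latent_peak[i] = np.nan
        if c == "convex":
            b2[i] = rng.uniform(0.4, 1.0)
            v = rng.uniform(lo, hi)
            mu[i] = rng.uniform(25, 45) + b2[i] * (x - v) ** 2
        elif c == "flat":
            mu[i] = rng.uniform(30, 70)
        elif c == "linear":
            slope = rng.uniform(2, 5) * rng.choice([-1.0, 1.0])
            mu[i] = rng.uniform(40, 60) + slope * (x - (lo + hi) / 2)
        else:  # straightliner: scale midpoint with small jitter
            mu[i] = 50.0
    noise = rng.normal(0.0, 1.0, mu.shape)
    sd = np.where(classes == "straightliner", 1.0, config.noise_sd)
    raw = mu + sd[:, None] * noise
    ratings = np.clip(raw, 0.0, 100.0)
    frac_clipped = float(np.mean(raw != ratings))
    if frac_clipped > 0.5:
        warnings.warn(
            f"{frac_clipped:.0%} of ratings saturated the 0-100 scale; "
            "generative parameters look implausible",
            stacklevel=2,
        )

    pids = [f"p{i + 1:04d}" for i in range(n)]
    liking = LikingMatrix(
        pd.DataFrame(ratings, index=pd.Index(pids, name="participant_id"),
                     columns=stimuli.excerpt_ids),
        stimuli,
    )
    trait_table = TraitTable(
        pd.DataFrame(traits, index=pd.Index(pids, name="participant_id"))
    )
    truth = GroundTruth(
        pd.DataFrame(
            {
                "responder_class": classes,
                "curve": curve,
                "latent_peak": latent_peak,
                "quad_true": b2,
                "plateau": plateau,
                "z_peak": z_peak,
            },
            index=pd.Index(pids, name="participant_id"),
        )
    )
    return liking, trait_table, truth


def generate_audio(
    kind: str,
    duration_s: float = 1.0,
    sample_rate: int = 44100,
    *,
    freq: float = 440.0,
    noise_fraction: float = 0.5,
    amplitude: float = 0.9,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Synthesise a test waveform in [-1, 1].

    ``white_noise`` has spectral flatness near 1, a pure ``sine`` near 0,
    and a ``mixture`` interpolates monotonically in ``noise_fraction``
    (the share of total power carried by the noise component).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if sample_rate < 8000:
        raise ValueError("sample_rate must be >= 8000 Hz")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = int(round(duration_s * sample_rate))
    t = np.arange(m) / sample_rate
    if kind == "white_noise":
        y = rng.standard_normal(m)
    elif kind == "sine":
        y = np.sin(2 * np.pi * freq * t)
    elif kind == "mixture":
        if not 0 <= noise_fraction <= 1:
            raise ValueError("noise_fraction must lie in [0, 1]")
        noise = rng.standard_normal(m)
        sine = np.sqrt(2.0) * np.sin(2 * np.pi * freq * t)  # unit power
        y = math.sqrt(noise_fraction) * noise + math.sqrt(1 - noise_fraction) * sine
    else:
        raise ValueError(f"unsupported audio kind {kind!r}")
    if amplitude == 0:
        return np.zeros(m)
    peak = np.max(np.abs(y))
    return amplitude * y / peak if peak > 0 else y
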