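"""Synthetic behavioral responses and ERP epochs for the paradigm.

Behavioral model
----------------
Ratings and confidence are ordinal 5-point responses generated from a latent
Gaussian cut at -1.5, -0.5, +0.5, +1.5 on the recoded (-2..+2) scale.  The
latent mean is condition-specific, with an independent per-subject random
effect per condition; response times are log-normal with means keyed by
(response category x condition).  Boundary extension enters through the
condition means: identical pairs drift toward "closer" (negative), and the
mismatched pairs are asymmetric, |mean(CW)| < |mean(WC)|.

ERP model
---------
Each epoch is  subject gain x condition template  +  noise, where the template
is a sum of components (Gaussian time course x Gaussian spatial falloff from a
center electrode over unit-sphere chord distance).  The defaults produce the
canonical posterior sequence P1/N1/P2/P3b, a P3b ordered CC = WW < CW < WC at
centro-parietal sites with a right-lateralized WC increment, and a focal
negative WC-vs-CW bump at TP7/P7 around 275 ms.  Noise is Gaussian with AR(1)
temporal correlation and a squared-exponential spatial kernel over montage
distance, which yields the correlated comparison families that make a
max-statistic threshold less severe than Bonferroni.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .design import CONDITIONS
from .epochs import EpochSet, default_times
from .montage import FRONTAL_CHANNELS, Montage

#: Latent cut-points mapping the recoded continuum to the 5 ordinal categories.
CUTPOINTS = np.array([-1.5, -0.5, 0.5, 1.5])


def _discretize(latent: np.ndarray) -> np.ndarray:
    """Latent value -> signed rating in {-2..+2}."""
    return np.digitize(latent, CUTPOINTS) - 2


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------

def _default_rating_means() -> dict[str, float]:
    # Recoded scale: negative = "closer".  Identical pairs show boundary
    # extension (WW reliably, CC weakly); mismatched pairs are asymmetric.
    return {"CC": -0.05, "WW": -0.25, "CW": 0.30, "WC": -0.60}


def _default_confidence_means() -> dict[str, float]:
    # Latent confidence (centered at 0 = raw 3); highest for WC.
    return {"CC": 0.40, "WW": 0.40, "CW": 0.20, "WC": 0.90}


def _default_rt_rating_means() -> dict[str, dict[str, float]]:
    # ms, by response category x condition: "same" fastest; slow CW-"closer".
    return {
        "closer": {"CC": 1600.0, "WW": 1600.0, "CW": 1911.0, "WC": 1620.0},
        "same":   {"CC": 1162.0, "WW": 1129.0, "CW": 1440.0, "WC": 1480.0},
        "wider":  {"CC": 1671.0, "WW": 1672.0, "CW": 1500.0, "WC": 1620.0},
    }


def _default_rt_conf_means() -> dict[str, float]:
    return {"low": 1100.0, "medium": 900.0, "high": 734.0}


@dataclass(frozen=True)
class BehaviorParams:
    rating_mean: dict[str, float] = field(default_factory=_default_rating_means)
    rating_sd: float = 1.0                 # latent within-subject trial SD
    rating_subject_sd: float = 0.15        # per subject x condition random effect
    confidence_mean: dict[str, float] = field(default_factory=_default_confidence_means)
    confidence_sd: float = 1.0
    confidence_subject_sd: float = 0.15
    rt_rating_mean_ms: dict[str, dict[str, float]] = field(
        default_factory=_default_rt_rating_means)
    rt_conf_mean_ms: dict[str, float] = field(default_factory=_default_rt_conf_means)
    rt_sigma: float = 0.30                 # log-normal shape
    rt_subject_sd: float = 0.10            # multiplicative subject effect
    be_asymmetry: bool = True
    seed: int = 0

    def validate(self) -> None:
        missing = set(CONDITIONS) - set(self.rating_mean)
        if missing:
            raise ValueError(f"rating_mean missing conditions {sorted(missing)}")
        if self.rating_sd <= 0 or self.confidence_sd <= 0 or self.rt_sigma <= 0:
            raise ValueError("dispersions must be positive")
        if self.be_asymmetry:
            if not abs(self.rating_mean["CW"]) < abs(self.rating_mean["WC"]):
                raise ValueError("BE asymmetry requires |mean(CW)| < |mean(WC)|")
            if not (self.rating_mean["WW"] < 0 and self.rating_mean["CC"] <= 0):
                raise ValueError("BE requires mean(WW) < 0 and mean(CC) <= 0")

    def null(self) -> "BehaviorParams":
        """Zero-effect variant (all condition means 0, no BE invariants)."""
        zero = {c: 0.0 for c in CONDITIONS}
        return replace(self, rating_mean=zero, confidence_mean=zero,
                       be_asymmetry=False)


def simulate_behavior(design: pd.DataFrame, params: BehaviorParams = BehaviorParams(),
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-trial behavioral table (rating, confidence, response times).

    Ratings and confidence are on the raw 1-5 scale; RTs in ms.  Deterministic
    under a fixed seed / Generator.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    df = design.copy()
    n = len(df)
    subjects = np.sort(df["subject"].unique())
    # Per subject x condition random effects, drawn in a fixed order.
    re_rating = {(s, c): rng.normal(0.0, params.rating_subject_sd)
                 for s in subjects for c in CONDITIONS}
    re_conf = {(s, c): rng.normal(0.0, params.confidence_subject_sd)
               for s in subjects for c in CONDITIONS}
    re_rt = {s: rng.lognormal(0.0, params.rt_subject_sd) for s in subjects}

    mu_rating = np.array([params.rating_mean[c] + re_rating[(s, c)]
                          for s, c in zip(df["subject"], df["condition"])])
    mu_conf = np.array([params.confidence_mean[c] + re_conf[(s, c)]
                        for s, c in zip(df["subject"], df["condition"])])
    signed = _discretize(rng.normal(mu_rating, params.rating_sd, size=n))
    conf_signed = _discretize(rng.normal(mu_conf, params.confidence_sd, size=n))
    df["rating"] = signed + 3
    df["confidence"] = conf_signed + 3

    category = np.where(signed < 0, "closer", np.where(signed > 0, "wider", "same"))
    level = np.where(df["confidence"] <= 2, "low",
                     np.where(df["confidence"] == 3, "medium", "high"))
    mu_rt = np.array([params.rt_rating_mean_ms[cat][c] * re_rt[s]
                      for cat, c, s in zip(category, df["condition"], df["subject"])])
    mu_crt = np.array([params.rt_conf_mean_ms[lv] * re_rt[s]
                       for lv, s in zip(level, df["subject"])])
    sig = params.rt_sigma
    df["rt_rating_ms"] = np.exp(rng.normal(np.log(mu_rt) - sig ** 2 / 2, sig, size=n))
    df["rt_conf_ms"] = np.exp(rng.normal(np.log(mu_crt) - sig ** 2 / 2, sig, size=n))
    return df


# ---------------------------------------------------------------------------
# ERP epochs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Component:
    """One ERP component: Gaussian time course x Gaussian spatial falloff.

    ``plateau_ms`` widens the time course into a flat top: the profile is 1
    within latency +/- plateau_ms and falls off with Gaussian tails of sigma
    ``width_ms`` outside.  With plateau_ms = 0 the profile is a plain
    Gaussian.  ``center`` may name several electrodes; the spatial profile is
    then the maximum of the per-center falloffs, so every named electrode
    carries the full configured amplitude.
    """

    name: str
    latency_ms: float
    width_ms: float            # temporal Gaussian sigma (tail sigma if plateau)
    amplitude_uv: dict[str, float]  # condition -> peak amplitude at the center
    center: str | tuple[str, ...]   # center electrode(s)
    spread: float              # spatial length scale (unit-sphere chord)
    plateau_ms: float = 0.0    # flat-top half-width

    @property
    def centers(self) -> tuple[str, ...]:
        return (self.center,) if isinstance(self.center, str) else self.center

    def validate(self) -> None:
        if self.width_ms <= 0 or self.spread <= 0 or self.plateau_ms < 0:
            raise ValueError(f"component {self.name}: widths must be > 0")

    def time_course(self, times: np.ndarray) -> np.ndarray:
        excess = np.maximum(np.abs(times - self.latency_ms) - self.plateau_ms, 0.0)
        return np.exp(-excess ** 2 / (2.0 * self.width_ms ** 2))


def _default_components() -> tuple[Component, ...]:
    same = {c: 1.0 for c in CONDITIONS}

    def amp(base: float, extra: dict[str, float] | None = None) -> dict[str, float]:
        out = {c: base * same[c] for c in CONDITIONS}
        if extra:
            out.update(extra)
        return out

    return (
        Component("P1", 120.0, 20.0, amp(3.0), "Oz", 0.5),
        Component("N1", 170.0, 22.0, amp(-4.0), "POz", 0.5),
        Component("P2", 250.0, 30.0, amp(3.0), "CPz", 0.5),
        # P3b ordered CC = WW < CW < WC at centro-parietal sites.
        Component("P3b", 530.0, 50.0,
                  {"CC": 4.0, "WW": 4.0, "CW": 5.0, "WC": 6.0}, "Pz", 0.5),
        # Right-lateralized extra WC positivity -> type x laterality interaction.
        Component("P3b_WC_right", 530.0, 50.0,
                  {"CC": 0.0, "WW": 0.0, "CW": 0.0, "WC": 0.6}, "CP2", 0.4),
        # Focal WC-vs-CW negativity at left temporo-parietal sites: full
        # amplitude at both named electrodes across 265-295 ms (flat top),
        # Gaussian falloff outside.
        Component("mismatch_TP7_P7", 280.0, 10.0,
                  {"CC": 0.0, "WW": 0.0, "CW": 0.0, "WC": -1.5},
                  ("TP7", "P7"), 0.35, plateau_ms=15.0),
    )


@dataclass(frozen=True)
class ErpEffectParams:
    components: tuple[Component, ...] = field(default_factory=_default_components)
    #: Per-trial stationary channel SD (microvolts).  Calibrated so that at
    #: the reference design (128 trials/condition) a subject's condition-
    #: difference wave carries ~1 uV of noise per cell after the full
    #: preprocessing chain (baseline correction of temporally correlated noise
    #: inflates post-stimulus SD by ~15%; 7.0 * sqrt(2/128) * 1.146 ~ 1.0).
    noise_sd: float = 7.0
    noise_tau_ms: float = 50.0     # AR(1) correlation time
    spatial_scale: float = 0.4     # squared-exponential kernel length (chord)
    subject_gain_sd: float = 0.10  # SD of the multiplicative subject effect
    seed: int = 0

    def validate(self, montage: Montage) -> None:
        if self.noise_sd < 0 or self.noise_tau_ms <= 0 or self.spatial_scale <= 0:
            raise ValueError("noise parameters must be positive")
        for comp in self.components:
            comp.validate()
            for center in comp.centers:
                if center not in montage:
                    raise KeyError(f"component {comp.name}: unknown channel "
                                   f"{center!r}")

    def rescaled_for_trials(self, n_per_condition: int,
                            reference: int = 128) -> "ErpEffectParams":
        """Scale trial noise so subject-level ERP noise matches the reference
        design (noise_sd * sqrt(n/reference) keeps SD of the per-subject trial
        average constant)."""
        return replace(self, noise_sd=self.noise_sd *
                       np.sqrt(n_per_condition / reference))

    def no_effects(self) -> "ErpEffectParams":
        """Condition-blind variant: all condition amplitudes equalized (global
        null for condition contrasts; components common to all conditions
        are kept)."""
        comps = []
        for c in self.components:
            amps = c.amplitude_uv
            if len(set(amps.values())) > 1:
                mean_amp = float(np.mean(list(amps.values())))
                amps = {k: mean_amp for k in amps}
            comps.append(replace(c, amplitude_uv=amps))
        return replace(self, components=tuple(comps))


def _spatial_weights(montage: Montage, ch_names, centers, spread: float
                     ) -> np.ndarray:
    """Max over centers of the Gaussian falloff in chord distance."""
    pos = montage.positions(ch_names)
    w = np.zeros(len(pos))
    for center in ((centers,) if isinstance(centers, str) else centers):
        d = np.linalg.norm(pos - montage.position(center), axis=1)
        w = np.maximum(w, np.exp(-d ** 2 / (2.0 * spread ** 2)))
    return w


def condition_template(effects: ErpEffectParams, montage: Montage,
                       condition: str, times: np.ndarray,
                       ch_names=None) -> np.ndarray:
    """Noise-free (channels x samples) template for one condition."""
    if ch_names is None:
        ch_names = montage.names
    out = np.zeros((len(ch_names), len(times)))
    for comp in effects.components:
        a = comp.amplitude_uv.get(condition, 0.0)
        if a == 0.0:
            continue
        w = _spatial_weights(montage, ch_names, comp.center, comp.spread)
        out += a * np.outer(w, comp.time_course(times))
    return out


def _correlated_noise(rng: np.random.Generator, n_trials: int, chol: np.ndarray,
                      n_samples: int, sd: float, phi: float) -> np.ndarray:
    """AR(1)-in-time, spatially correlated Gaussian noise, stationary SD `sd`."""
    n_ch = chol.shape[0]
    burn = 100
    white = rng.standard_normal((n_trials, n_ch, n_samples + burn),
                                dtype=np.float32)
    ar = signal.lfilter([1.0], [1.0, -phi], white, axis=-1)[..., burn:]
    ar *= np.sqrt(1.0 - phi ** 2)  # unit stationary variance
    return sd * (chol.astype(ar.dtype) @ ar)


def simulate_subject_epochs(conditions: np.ndarray, effects: ErpEffectParams,
                            montage: Montage, rng: np.random.Generator,
                            subject: int = 0,
                            times: np.ndarray | None = None) -> EpochSet:
    """Simulate one subject's epochs for the given per-trial condition labels."""
    effects.validate(montage)
    if times is None:
        times = default_times()
    sfreq = 1000.0 / (times[1] - times[0])
    ch_names = montage.names
    gain = 1.0 + rng.normal(0.0, effects.subject_gain_sd) if effects.subject_gain_sd else 1.0
    templates = {c: gain * condition_template(effects, montage, c, times)
                 for c in np.unique(conditions)}
    n_trials = len(conditions)
    data = np.empty((n_trials, len(ch_names), len(times)))
    for c, tpl in templates.items():
        data[conditions == c] = tpl
    if effects.noise_sd > 0:
        phi = np.exp(-(1000.0 / sfreq) / effects.noise_tau_ms)
        dist = montage.distances()
        kern = np.exp(-dist ** 2 / (2.0 * effects.spatial_scale ** 2))
        chol = np.linalg.cholesky(kern + 1e-9 * np.eye(len(ch_names)))
        data += _correlated_noise(rng, n_trials, chol, len(times),
                                  effects.noise_sd, phi)
    return EpochSet(data=data, times=times, sfreq=sfreq,
                    conditions=np.asarray(conditions, dtype=object),
                    ch_names=tuple(ch_names),
                    ch_kinds=tuple(montage.kinds), subject=subject)


def iter_subject_epochs(design: pd.DataFrame, effects: ErpEffectParams,
                        montage: Montage, seed: int | None = None):
    """Yield (subject, EpochSet) per subject, memory-light, seed-reproducible."""
    root = np.random.SeedSequence(effects.seed if seed is None else seed)
    subjects = np.sort(design["subject"].unique())
    for subj, ss in zip(subjects, root.spawn(len(subjects))):
        sub = design[design["subject"] == subj].sort_values(["block", "trial"])
        rng = np.random.default_rng(ss)
        yield int(subj), simulate_subject_epochs(
            sub["condition"].to_numpy(), effects, montage, rng, subject=int(subj))


def simulate_erp_epochs(design: pd.DataFrame, effects: ErpEffectParams,
                        montage: Montage, seed: int | None = None
                        ) -> dict[int, EpochSet]:
    """All subjects' epochs as a dict (convenience wrapper; large at full scale)."""
    return dict(iter_subject_epochs(design, effects, montage, seed))


# ---------------------------------------------------------------------------
# Artifacts
# ---------------------------------------------------------------------------

def inject_artifacts(epochs: EpochSet, fraction: float, amplitude_uv: float,
                     seed: int | None = None) -> tuple[EpochSet, list[int]]:
    """Add blink-like transients exceeding the rejection threshold.

    Exactly round(fraction * n_trials) epochs receive a positive Gaussian
    transient (sigma 40 ms, random center within 100-700 ms) with peak
    `amplitude_uv` on the vertical EOG and frontal channels.  Returns the
    contaminated EpochSet and the sorted list of contaminated epoch indices.
    """
    if amplitude_uv <= 75.0:
        raise ValueError("artifact amplitude must exceed the 75 uV rejection "
                         "threshold to be detectable")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    n_bad = int(round(fraction * epochs.n_trials))
    out = epochs.copy()
    if n_bad == 0:
        return out, []
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(epochs.n_trials, size=n_bad, replace=False))
    blink_ch = [c for c in ("VEOGU", "VEOGD") + FRONTAL_CHANNELS
                if c in epochs.ch_names]
    weights = {c: 1.0 if c.startswith("VEOG") else 0.8 for c in blink_ch}
    for i in idx:
        # snap the blink center to the sample grid so the configured peak
        # amplitude is realized exactly
        center = epochs.times[np.argmin(np.abs(epochs.times -
                                               rng.uniform(100.0, 700.0)))]
        tc = np.exp(-(epochs.times - center) ** 2 / (2.0 * 40.0 ** 2))
        for c in blink_ch:
            sign = -1.0 if c == "VEOGD" else 1.0
            out.data[i, epochs.channel_index(c)] += sign * weights[c] * amplitude_uv * tc
    return out, [int(i) for i in idx]
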