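"""Seeded synthetic cohorts: demographics, raw keystroke streams, and linked count outcomes.

No public dataset of home-based tapping sessions with matched cognitive scores
exists, so this module generates complete cohorts end-to-end:

* **Demographics** — age from a truncated normal whose *truncated* mean/SD are
  moment-matched to the configured targets; sex Bernoulli; education from a
  six-level categorical; anxiety/depression scores as rounded, clipped normals.
* **Tapping streams** — each block is a *stationary* lognormal renewal process:
  inter-press intervals are LogNormal(mu, sigma) with mean 1/frequency, and the
  first press is placed at ``U * I_hat`` where ``I_hat`` is drawn from the
  length-biased interval distribution (LogNormal(mu + sigma^2, sigma)).  A
  stationary start makes the expected press count exactly ``duration x
  frequency``, so the frequency feature is unbiased for its configured target
  at any block length.  The lognormal interval choice makes "SD of log
  interval" the literal generator parameter, so the variability feature
  recovers it directly.  Participant-level lognormal random effects (speed via
  a shared z-score across blocks, rhythm, dwell) induce realistic
  between-feature correlation.
* **Cognitive counts** — drawn from a log-link count GLM (negative binomial
  via the gamma-Poisson mixture, or Poisson) whose linear predictor combines
  configured coefficients with *centered* demographics and the participant's
  *realized* motor features; the intercept is the log of the target mean
  count.  Counts are capped at configured task ceilings.
* **Exclusion flags** — configured numbers of cognitively-symptomatic, PD, and
  MS participants (and optionally incomplete protocols) are injected at
  random, independent of everything else, so the downstream filter can be
  exercised at realistic rates.

Each participant consumes an independent random substream keyed by
``(seed, index)``: growing ``n_participants`` never perturbs earlier
participants.  Flag injection uses a cohort-level stream and is the one
quantity that depends on ``n``.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy import optimize, special, stats

from tapcog.keystroke_io import (
    EDUCATION_LEVELS,
    Cohort,
    Hand,
    KeyEvent,
    ParticipantRecord,
    TappingBlock,
    TestType,
    block_duration_s,
)
from tapcog.motor_features import (
    ALTERNATE_TARGETS,
    DEFAULT_ADJACENCY,
    FEATURE_COLUMNS,
    accuracy_score,
    dwell_time,
    feature_column,
    tapping_frequency,
    tapping_variability,
)

_FEATURE_FNS = {
    "freq": tapping_frequency,
    "var": tapping_variability,
    "dwell": dwell_time,
    "acc": accuracy_score,
}

__all__ = [
    "DemographicsParams",
    "TappingParams",
    "OutcomeModel",
    "ExclusionInjection",
    "SimConfig",
    "simulate_demographics",
    "simulate_tapping_session",
    "simulate_cognitive_counts",
    "simulate_cohort",
    "feature_centers",
    "covariate_centers",
]

_FAR_KEYS = ("g", "h", "j", "k", "q", "r")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DemographicsParams:
    """Cohort composition targets (community sample of older adults)."""

    age_mean: float = 65.8
    age_sd: float = 7.37
    age_min: float = 50.0
    age_max: float = 90.0
    p_female: float = 0.731
    education_probs: tuple[float, ...] = (0.042, 0.092, 0.139, 0.494, 0.173, 0.060)
    hads_anxiety_mean: float = 4.28
    hads_anxiety_sd: float = 3.55
    hads_depression_mean: float = 2.90
    hads_depression_sd: float = 2.72
    hads_cap: int = 21


@dataclass(frozen=True)
class TappingParams:
    """Tapping-stream targets per test/hand/block.

    Frequency targets and between-participant SDs follow the observed
    block-level distributions of a large community cohort (single-key blocks
    drift upward 5.54 -> 5.77 presses/s across the four blocks — a warm-up
    trend — and alternate-key rates are 2.17 / 2.00 presses/s for the
    dominant / non-dominant hand).  The log-interval SDs, dwell parameters,
    and wrong-key probabilities have no published reference distribution and
    are plausible conventions (see docs/methods.md).
    """

    single_freq_targets: tuple[float, ...] = (5.54, 5.62, 5.70, 5.77)
    single_freq_sds: tuple[float, ...] = (0.813, 0.839, 0.860, 0.871)
    alt_freq_target_dominant: float = 2.17
    alt_freq_sd_dominant: float = 0.365
    alt_freq_target_nondominant: float = 2.00
    alt_freq_sd_nondominant: float = 0.321
    log_interval_sd_single: float = 0.15
    log_interval_sd_alternate: float = 0.20
    rhythm_sd_log: float = 0.25  # participant multiplier on the log-interval SD
    dwell_median_single_ms: float = 90.0
    dwell_median_alternate_ms: float = 110.0
    dwell_between_sd_log: float = 0.20
    dwell_within_sd_log: float = 0.25
    p_adjacent_single: float = 0.004
    p_other_single: float = 0.002
    p_adjacent_alternate: float = 0.030
    p_other_alternate: float = 0.012
    age_log_freq_slope: float = -0.004  # per year, multiplicative on frequency
    freq_floor: float = 0.8


@dataclass(frozen=True)
class OutcomeModel:
    """Log-link count model for one cognitive score.

    ``coef`` maps covariate/feature names to coefficients applied to *centered*
    predictors; ``mean_count`` is the expected count at the centers (the
    intercept is its log).  ``theta`` is the negative-binomial size (ignored
    for Poisson).  ``cap`` is the task ceiling applied to drawn counts.
    """

    family: str  # "negative_binomial" | "poisson"
    mean_count: float
    theta: float | None = None
    coef: dict[str, float] = field(default_factory=dict)
    cap: int | None = None


def _default_outcomes() -> dict[str, OutcomeModel]:
    edu_grad = {
        "edu_left_school_at_16": -0.05,
        "edu_left_school_17_or_18": -0.10,
        "edu_undergraduate": -0.20,
        "edu_masters": -0.25,
        "edu_phd": -0.30,
    }
    return {
        # episodic memory errors: linked to alternate-key speed and rhythm
        "paltea6": OutcomeModel(
            family="negative_binomial",
            mean_count=4.40,
            theta=1.05,
            cap=22,
            coef={
                "age_years": 0.020,
                "sex_male": 0.05,
                "hads_anxiety": 0.010,
                "hads_depression": 0.020,
                **edu_grad,
                "ak_freq_d": -0.35,
                "ak_var_nd": 2.0,
            },
        ),
        # working-memory between errors: no motor link
        "swmbe6": OutcomeModel(
            family="negative_binomial",
            mean_count=3.22,
            theta=1.35,
            cap=13,
            coef={
                "age_years": 0.025,
                "sex_male": 0.05,
                "hads_anxiety": 0.010,
                "hads_depression": 0.015,
                **edu_grad,
            },
        ),
        # strategy score: mildly linked to late-block single-key speed;
        # Poisson because the observed score is underdispersed (mean > var)
        "swms": OutcomeModel(
            family="poisson",
            mean_count=7.75,
            cap=13,
            coef={
                "age_years": 0.012,
                "hads_anxiety": 0.005,
                "hads_depression": 0.010,
                "edu_undergraduate": -0.05,
                "edu_masters": -0.08,
                "edu_phd": -0.10,
                "sk_freq_b4": -0.12,
            },
        ),
    }


@dataclass(frozen=True)
class ExclusionInjection:
    """How many participants receive each exclusion flag (disjoint sets)."""

    n_symptomatic: int = 74
    n_pd: int = 3
    n_ms: int = 8
    n_incomplete: int = 0


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of a synthetic cohort; the seed determines everything."""

    n_participants: int = 1254
    seed: int = 0
    demographics: DemographicsParams = field(default_factory=DemographicsParams)
    tapping: TappingParams = field(default_factory=TappingParams)
    outcomes: dict[str, OutcomeModel] = field(default_factory=_default_outcomes)
    exclusions: ExclusionInjection = field(default_factory=ExclusionInjection)

    def __post_init__(self):
        d = self.demographics
        if abs(sum(d.education_probs) - 1.0) > 1e-6:
            raise ValueError("education_probs must sum to 1")
        if not (0.0 <= d.p_female <= 1.0):
            raise ValueError("p_female must be in [0, 1]")
        for om in self.outcomes.values():
            if om.family == "negative_binomial" and (om.theta is None or om.theta <= 0):
                raise ValueError("negative_binomial outcomes need theta > 0")
        inj = self.exclusions
        n_flagged = inj.n_symptomatic + inj.n_pd + inj.n_ms + inj.n_incomplete
        if n_flagged > self.n_participants:
            raise ValueError("more exclusion flags than participants")

    def with_updates(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        import json

        d = asdict(self)
        d["outcomes"] = {k: asdict(v) for k, v in self.outcomes.items()}
        # JSON round-trip turns tuples into lists -> YAML/JSON-safe
        return json.loads(json.dumps(d))

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "demographics" in d:
            d["demographics"] = DemographicsParams(**d["demographics"])
        if "tapping" in d:
            t = dict(d["tapping"])
            for key in ("single_freq_targets", "single_freq_sds"):
                if key in t:
                    t[key] = tuple(t[key])
            d["tapping"] = TappingParams(**t)
        if "exclusions" in d:
            d["exclusions"] = ExclusionInjection(**d["exclusions"])
        if "outcomes" in d:
            d["outcomes"] = {
                k: OutcomeModel(**v) for k, v in d["outcomes"].items()
            }
        if "demographics" in d and isinstance(d["demographics"].education_probs, list):
            d["demographics"] = replace(
                d["demographics"],
                education_probs=tuple(d["demographics"].education_probs),
            )
        return cls(**d)


# ---------------------------------------------------------------------------
# centers (for intercept calibration and coefficient bookkeeping)
# ---------------------------------------------------------------------------


def covariate_centers(config: SimConfig) -> dict[str, float]:
    """Expected values of the model covariates under the configured demographics."""
    d = config.demographics
    centers = {
        "age_years": d.age_mean,
        "sex_male": 1.0 - d.p_female,
        "hads_anxiety": d.hads_anxiety_mean,
        "hads_depression": d.hads_depression_mean,
    }
    for level, p in zip(EDUCATION_LEVELS[1:], d.education_probs[1:]):
        centers[f"edu_{level}"] = p
    return centers


def feature_centers(config: SimConfig) -> dict[str, float]:
    """Approximate expected values of the 24 motor features under the config."""
    t = config.tapping
    centers: dict[str, float] = {}
    acc_single = 1.0 + t.p_adjacent_single + 2.0 * t.p_other_single
    acc_alt = 1.0 + t.p_adjacent_alternate + 2.0 * t.p_other_alternate
    dwell_single = t.dwell_median_single_ms * math.exp(t.dwell_within_sd_log**2 / 2)
    dwell_alt = t.dwell_median_alternate_ms * math.exp(t.dwell_within_sd_log**2 / 2)
    for b in (1, 2, 3, 4):
        centers[feature_column(TestType.SINGLE_KEY, "freq", block_index=b)] = (
            t.single_freq_targets[b - 1]
        )
        centers[feature_column(TestType.SINGLE_KEY, "var", block_index=b)] = (
            t.log_interval_sd_single
        )
        centers[feature_column(TestType.SINGLE_KEY, "dwell", block_index=b)] = dwell_single
        centers[feature_column(TestType.SINGLE_KEY, "acc", block_index=b)] = acc_single
    for hand, ftarget in (
        (Hand.DOMINANT, t.alt_freq_target_dominant),
        (Hand.NON_DOMINANT, t.alt_freq_target_nondominant),
    ):
        centers[feature_column(TestType.ALTERNATE_KEY, "freq", hand=hand)] = ftarget
        centers[feature_column(TestType.ALTERNATE_KEY, "var", hand=hand)] = (
            t.log_interval_sd_alternate
        )
        centers[feature_column(TestType.ALTERNATE_KEY, "dwell", hand=hand)] = dwell_alt
        centers[feature_column(TestType.ALTERNATE_KEY, "acc", hand=hand)] = acc_alt
    return centers


def predictor_centers(config: SimConfig) -> dict[str, float]:
    return {**covariate_centers(config), **feature_centers(config)}


# ---------------------------------------------------------------------------
# demographics
# ---------------------------------------------------------------------------


@lru_cache(maxsize=32)
def _truncnorm_parent_params(
    mean: float, sd: float, lo: float, hi: float
) -> tuple[float, float]:
    """Parent (mu, sigma) such that N(mu, sigma) truncated to [lo, hi] has the given moments."""

    def residual(x):
        m, s = x
        a, b = (lo - m) / s, (hi - m) / s
        return [
            stats.truncnorm.mean(a, b, loc=m, scale=s) - mean,
            stats.truncnorm.std(a, b, loc=m, scale=s) - sd,
        ]

    sol = optimize.fsolve(residual, x0=[mean, sd], full_output=False)
    return float(sol[0]), float(sol[1])


def _draw_truncnorm(rng: np.random.Generator, mean, sd, lo, hi) -> float:
    m, s = _truncnorm_parent_params(mean, sd, lo, hi)
    plo, phi = special.ndtr((lo - m) / s), special.ndtr((hi - m) / s)
    u = rng.uniform(plo, phi)
    return m + s * float(special.ndtri(u))


def _draw_hads(rng: np.random.Generator, mean, sd, cap) -> int:
    return int(np.clip(np.rint(rng.normal(mean, sd)), 0, cap))


def simulate_demographics(config: SimConfig, rng: np.random.Generator) -> dict:
    """Draw one participant's demographic scalars from the configured distributions."""
    d = config.demographics
    age = _draw_truncnorm(rng, d.age_mean, d.age_sd, d.age_min, d.age_max)
    sex = "female" if rng.random() < d.p_female else "male"
    education = EDUCATION_LEVELS[rng.choice(len(EDUCATION_LEVELS), p=d.education_probs)]
    anx = _draw_hads(rng, d.hads_anxiety_mean, d.hads_anxiety_sd, d.hads_cap)
    dep = _draw_hads(rng, d.hads_depression_mean, d.hads_depression_sd, d.hads_cap)
    return {
        "age_years": age,
        "sex": sex,
        "education_level": education,
        "hads_anxiety": anx,
        "hads_depression": dep,
    }


# ---------------------------------------------------------------------------
# tapping streams
# ---------------------------------------------------------------------------

_ADJ_LISTS = {k: sorted(v) for k, v in DEFAULT_ADJACENCY.items()}


def _stationary_press_times_ms(
    rng: np.random.Generator, freq: float, sigma: float, duration_ms: int
) -> np.ndarray:
    """Key-down times (int ms) of a stationary lognormal renewal process on [0, T)."""
    mean_interval_s = 1.0 / freq
    mu = math.log(mean_interval_s) - sigma**2 / 2.0
    # length-biased first interval, uniform phase -> exactly stationary
    i_hat = rng.lognormal(mu + sigma**2, sigma)
    first_ms = np.rint(rng.uniform(0.0, 1.0) * i_hat * 1000.0)
    chunks = [np.array([first_ms])]
    total = first_ms
    while total < duration_ms:
        n = int(duration_ms / 1000.0 * freq * 0.8 + 30)
        iv = np.maximum(1.0, np.rint(rng.lognormal(mu, sigma, size=n) * 1000.0))
        chunks.append(iv)
        total += iv.sum()
    times = np.cumsum(np.concatenate(chunks))
    return times[times < duration_ms].astype(np.int64)


def _block_keys(
    rng: np.random.Generator,
    n: int,
    test_type: TestType,
    p_adjacent: float,
    p_other: float,
) -> list[str]:
    if test_type is TestType.SINGLE_KEY:
        expected = ["space"] * n
    else:
        a, b = ALTERNATE_TARGETS
        expected = [a if i % 2 == 0 else b for i in range(n)]
    keys = list(expected)
    u = rng.random(n)
    wrong = np.nonzero(u < p_adjacent + p_other)[0]
    for i in wrong.tolist():
        if u[i] < p_adjacent:
            pool = _ADJ_LISTS[expected[i]]
            keys[i] = pool[rng.integers(len(pool))]
        else:
            keys[i] = _FAR_KEYS[rng.integers(len(_FAR_KEYS))]
    return keys


def _generate_block(
    rng: np.random.Generator,
    test_type: TestType,
    hand: Hand,
    block_index: int,
    freq: float,
    sigma: float,
    dwell_median_ms: float,
    dwell_sigma: float,
    p_adjacent: float,
    p_other: float,
) -> TappingBlock:
    duration_s = block_duration_s(test_type)
    duration_ms = round(duration_s * 1000)
    downs = _stationary_press_times_ms(rng, freq, sigma, duration_ms)
    n = downs.size
    keys = _block_keys(rng, n, test_type, p_adjacent, p_other)
    dwell = np.maximum(1.0, np.rint(rng.lognormal(math.log(dwell_median_ms), dwell_sigma, n)))
    # a key must be released before (or as) the same/next key goes down,
    # and by the end of the block
    caps = np.empty(n)
    caps[:-1] = np.maximum(1, np.diff(downs) - 1)
    if n:
        caps[-1] = duration_ms - downs[-1]
    ups = downs + np.minimum(dwell, caps).astype(np.int64)
    events = [
        KeyEvent(key_label=k, down_ms=d, up_ms=u)
        for k, d, u in zip(keys, downs.tolist(), ups.tolist())
    ]
    return TappingBlock(
        test_type=test_type,
        hand=hand,
        block_index=block_index,
        duration_s=duration_s,
        events=events,
    )


def simulate_tapping_session(
    latents: dict, config: SimConfig, rng: np.random.Generator
) -> list[TappingBlock]:
    """Generate one participant's full protocol (4 single-key + 2 alternate-key blocks).

    ``latents`` must hold ``z_speed`` (standard-normal shared speed score),
    ``rhythm_mult`` and ``dwell_mult`` (mean-one lognormal multipliers), and
    ``age_years``.
    """
    t = config.tapping
    z = latents["z_speed"]
    age_mult = math.exp(t.age_log_freq_slope * (latents["age_years"] - config.demographics.age_mean))
    sigma_single = t.log_interval_sd_single * latents["rhythm_mult"]
    sigma_alt = t.log_interval_sd_alternate * latents["rhythm_mult"]
    blocks = []
    for b in (1, 2, 3, 4):
        freq = (t.single_freq_targets[b - 1] + z * t.single_freq_sds[b - 1]) * age_mult
        blocks.append(
            _generate_block(
                rng,
                TestType.SINGLE_KEY,
                Hand.DOMINANT,
                b,
                max(t.freq_floor, freq),
                sigma_single,
                t.dwell_median_single_ms * latents["dwell_mult"],
                t.dwell_within_sd_log,
                t.p_adjacent_single,
                t.p_other_single,
            )
        )
    for hand, ftarget, fsd in (
        (Hand.DOMINANT, t.alt_freq_target_dominant, t.alt_freq_sd_dominant),
        (Hand.NON_DOMINANT, t.alt_freq_target_nondominant, t.alt_freq_sd_nondominant),
    ):
        freq = (ftarget + z * fsd) * age_mult
        blocks.append(
            _generate_block(
                rng,
                TestType.ALTERNATE_KEY,
                hand,
                1,
                max(t.freq_floor, freq),
                sigma_alt,
                t.dwell_median_alternate_ms * latents["dwell_mult"],
                t.dwell_within_sd_log,
                t.p_adjacent_alternate,
                t.p_other_alternate,
            )
        )
    return blocks


# ---------------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------------


def _predictor_value(name: str, demog: dict, features: dict) -> float:
    if name == "sex_male":
        return 1.0 if demog["sex"] == "male" else 0.0
    if name.startswith("edu_"):
        return 1.0 if demog["education_level"] == name[4:] else 0.0
    if name in demog:
        return float(demog[name])
    return float(features.get(name, math.nan))


def simulate_cognitive_counts(
    features: dict, demog: dict, config: SimConfig, rng: np.random.Generator
) -> dict[str, int]:
    """Draw the three cognitive counts from the configured log-link models.

    Predictors are centered at their configured expectations, so the intercept
    of each model is ``log(mean_count)``.  A missing feature (incomplete
    protocol) contributes zero, i.e. is held at its center.
    """
    centers = predictor_centers(config)
    out = {}
    for outcome, om in config.outcomes.items():
        eta = math.log(om.mean_count)
        for name, beta in om.coef.items():
            x = _predictor_value(name, demog, features)
            if not math.isnan(x):
                eta += beta * (x - centers[name])
        mu = math.exp(eta)
        if om.family == "negative_binomial":
            lam = rng.gamma(shape=om.theta, scale=mu / om.theta)
            y = int(rng.poisson(lam))
        elif om.family == "poisson":
            y = int(rng.poisson(mu))
        else:
            raise ValueError(f"unknown outcome family {om.family!r}")
        if om.cap is not None:
            y = min(y, om.cap)
        out[outcome] = y
    return out


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------


def _participant_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def _cohort_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, 0x7FFFFFFF]))


def _needed_features(config: SimConfig) -> set[str]:
    """Feature columns the configured outcome models actually reference."""
    covs = set(covariate_centers(config))
    needed = set()
    for om in config.outcomes.values():
        needed |= {name for name in om.coef if name not in covs}
    unknown = needed - set(FEATURE_COLUMNS)
    if unknown:
        raise ValueError(f"outcome coefficients reference unknown predictors {sorted(unknown)}")
    return needed


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate the full synthetic cohort (deterministic in ``config.seed``)."""
    import contextlib
    import gc

    @contextlib.contextmanager
    def _gc_paused():
        # event streams are large, flat, and acyclic; pausing the cyclic GC
        # during generation avoids quadratic collector sweeps
        was_enabled = gc.isenabled()
        gc.disable()
        try:
            yield
        finally:
            if was_enabled:
                gc.enable()

    with _gc_paused():
        return _simulate_cohort_inner(config)


def _simulate_cohort_inner(config: SimConfig) -> Cohort:
    t = config.tapping
    needed = _needed_features(config)
    participants: list[ParticipantRecord] = []
    for i in range(config.n_participants):
        rng = _participant_rng(config.seed, i)
        demog = simulate_demographics(config, rng)
        latents = {
            "z_speed": rng.normal(),
            "rhythm_mult": math.exp(rng.normal(0.0, t.rhythm_sd_log) - t.rhythm_sd_log**2 / 2),
            "dwell_mult": math.exp(
                rng.normal(0.0, t.dwell_between_sd_log) - t.dwell_between_sd_log**2 / 2
            ),
            "age_years": demog["age_years"],
        }
        blocks = simulate_tapping_session(latents, config, rng)
        features = {}
        for b in blocks:
            cols = {
                fname: col
                for fname in ("freq", "var", "dwell", "acc")
                if (col := feature_column(b.test_type, fname, hand=b.hand, block_index=b.block_index))
                in needed
            }
            if not cols:
                continue
            for fname, col in cols.items():
                features[col] = _FEATURE_FNS[fname](b)
        counts = simulate_cognitive_counts(features, demog, config, rng)
        participants.append(
            ParticipantRecord(
                participant_id=f"p{i:05d}",
                memory_change=False,
                dementia_dx=False,
                memory_impairment_dx=False,
                pd_dx=False,
                ms_dx=False,
                blocks=blocks,
                **demog,
                **counts,
            )
        )

    _inject_exclusions(participants, config)
    return Cohort(
        participants=participants,
        provenance={
            "source": "synthetic",
            "seed": config.seed,
            "n_participants": config.n_participants,
        },
    )


def _inject_exclusions(participants: list[ParticipantRecord], config: SimConfig) -> None:
    inj = config.exclusions
    n_flagged = inj.n_symptomatic + inj.n_pd + inj.n_ms + inj.n_incomplete
    if n_flagged == 0:
        return
    rng = _cohort_rng(config.seed)
    order = rng.permutation(len(participants))
    pos = 0
    symptom_fields = ("memory_change", "dementia_dx", "memory_impairment_dx")
    for _ in range(inj.n_symptomatic):
        p = participants[order[pos]]
        setattr(p, symptom_fields[rng.integers(3)], True)
        pos += 1
    for _ in range(inj.n_pd):
        participants[order[pos]].pd_dx = True
        pos += 1
    for _ in range(inj.n_ms):
        participants[order[pos]].ms_dx = True
        pos += 1
    for _ in range(inj.n_incomplete):
        p = participants[order[pos]]
        if p.blocks:
            p.blocks = p.blocks[:-1]
        pos += 1
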