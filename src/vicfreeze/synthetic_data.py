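"""Synthetic inputs with known ground truth.

Two generators feed the pipeline:

* Cage audio: broadband background noise plus brief broadband "clatter"
  transients and constant-frequency 22-kHz calls with small frequency
  jitter, 5-ms cosine on/off ramps and lognormal durations, placed at
  non-overlapping random times. Call amplitude is set from a per-call SNR
  against the background power inside the 15-30 kHz analysis band.

* Behavioral cohorts: per-animal, per-bin freezing percentages drawn from
  truncated normals around group targets (four witness groups, two
  demonstrator groups, n = 11-15 per group in the emulated design),
  realized as freezing-bout interval sets; demonstrator freezing escalates
  over shock trials; pair-level call counts follow a negative binomial
  coupled to demonstrator shock-period freezing through a Gaussian copula.

Every artifact is reproducible from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .audio_io import AudioTrack
from .behavior_scoring import BinSchedule, FreezingBoutSeries, percent_freezing

__all__ = [
    "AudioSimSpec",
    "BehaviorSimSpec",
    "GroundTruth",
    "simulate_audio",
    "simulate_cohort",
    "simulate_pre_exposure",
    "realize_bouts",
    "DEFAULT_FREEZING_TARGETS",
    "PRE_EXPOSURE_TARGETS",
]


@dataclass
class AudioSimSpec:
    """Parameters of the synthetic cage recording."""

    duration: float = 60.0
    sample_rate: int = 96_000
    n_calls: int = 10
    call_freq_mean: float = 22_000.0
    call_freq_jitter_sd: float = 300.0
    call_duration_median: float = 0.8
    call_duration_sigma: float = 0.35  # lognormal shape
    call_duration_range: tuple[float, float] = (0.1, 2.5)
    min_gap: float = 0.5
    snr_db: float = 20.0
    background: Literal["white", "pink"] = "white"
    background_level_db: float = -40.0  # RMS re full scale
    transient_rate: float = 2.0  # clatter events per minute
    ramp_s: float = 0.005

    def __post_init__(self) -> None:
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")
        if self.duration <= 0 or self.n_calls < 0:
            raise ValueError("invalid duration or call count")


@dataclass
class GroundTruth:
    """What the generator actually put in, for recovery checks."""

    call_onsets: np.ndarray | None = None
    call_durations: np.ndarray | None = None
    call_freqs: np.ndarray | None = None
    bin_targets: pd.DataFrame | None = None
    coupling_rho: float | None = None
    seed: int | None = None


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Approximate 1/f noise by shaping white noise in the frequency domain."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec /= np.sqrt(f)
    out = np.fft.irfft(spec, n=n)
    return out / out.std()


def _place_intervals(
    durations: np.ndarray, total: float, min_gap: float, rng: np.random.Generator
) -> np.ndarray:
    """Random non-overlapping onsets with at least ``min_gap`` between events
    and a ``min_gap`` margin at both ends. Raises if the events do not fit."""
    n = len(durations)
    occupied = float(durations.sum()) + (n + 1) * min_gap
    slack = total - occupied
    if slack < 0:
        raise ValueError(
            f"{n} events of total {durations.sum():.1f}s with gap {min_gap}s "
            f"do not fit in {total}s"
        )
    extra = rng.dirichlet(np.ones(n + 1)) * slack
    onsets = np.empty(n)
    t = min_gap + extra[0]
    for i in range(n):
        onsets[i] = t
        t += durations[i] + min_gap + extra[i + 1]
    return onsets


def _band_fraction(spec: AudioSimSpec, lo: float = 15_000.0, hi: float = 30_000.0) -> float:
    """Fraction of background power inside the analysis band."""
    nyq = spec.sample_rate / 2
    if spec.background == "white":
        return (hi - lo) / nyq
    # 1/f: power density ~ 1/f integrates to log ratio
    f_min = 20.0
    return float(np.log(hi / lo) / np.log(nyq / f_min))


def simulate_audio(spec: AudioSimSpec, seed: int) -> tuple[AudioTrack, GroundTruth]:
    """Synthesize a cage recording and return it with its ground truth."""
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration * spec.sample_rate))
    bg_rms = 10.0 ** (spec.background_level_db / 20.0)
    if spec.background == "white":
        audio = rng.standard_normal(n) * bg_rms
    else:
        audio = _pink_noise(n, rng) * bg_rms

    # cage clatter: brief broadband bursts, spectrally flat -> low frame SD
    n_trans = rng.poisson(spec.transient_rate * spec.duration / 60.0)
    for _ in range(n_trans):
        dur = rng.uniform(0.005, 0.045)
        ln = int(dur * spec.sample_rate)
        start = rng.integers(0, max(n - ln, 1))
        burst = rng.standard_normal(ln) * bg_rms * 10 ** (rng.uniform(6, 12) / 20)
        ramp = min(ln // 4, int(0.002 * spec.sample_rate))
        if ramp > 0:
            win = np.ones(ln)
            edge = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
            win[:ramp], win[-ramp:] = edge, edge[::-1]
            burst *= win
        audio[start : start + ln] += burst

    durations = np.array([])
    onsets = np.array([])
    freqs = np.array([])
    if spec.n_calls > 0:
        mu = np.log(spec.call_duration_median)
        durations = np.exp(rng.normal(mu, spec.call_duration_sigma, spec.n_calls))
        durations = np.clip(durations, *spec.call_duration_range)
        onsets = _place_intervals(durations, spec.duration, spec.min_gap, rng)
        freqs = spec.call_freq_mean + rng.normal(0, spec.call_freq_jitter_sd, spec.n_calls)

        band_power = bg_rms**2 * _band_fraction(spec)
        amp = np.sqrt(2.0 * band_power * 10.0 ** (spec.snr_db / 10.0))
        ramp_n = int(spec.ramp_s * spec.sample_rate)
        for onset, dur, f in zip(onsets, durations, freqs):
            i0 = int(onset * spec.sample_rate)
            ln = int(dur * spec.sample_rate)
            t = np.arange(ln) / spec.sample_rate
            tone = amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
            if ramp_n > 0 and ln > 2 * ramp_n:
                env = np.ones(ln)
                edge = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
                env[:ramp_n], env[-ramp_n:] = edge, edge[::-1]
                tone *= env
            audio[i0 : i0 + ln] += tone[: n - i0]

    peak = np.max(np.abs(audio)) if n else 0.0
    if peak > 1.0:
        audio /= peak * 1.01
    track = AudioTrack(audio, spec.sample_rate)
    truth = GroundTruth(
        call_onsets=onsets, call_durations=durations, call_freqs=freqs, seed=seed
    )
    return track, truth


# ---------------------------------------------------------------------------
# behavioral cohorts

#: default per-bin freezing targets (%, mean then SEM) for the six groups on
#: the 6-bin test schedule. Witness controls stay near floor, shock witnesses
#: rise only with prior shock experience, demonstrators escalate over trials.
DEFAULT_FREEZING_TARGETS: dict[str, dict[str, Sequence[float]]] = {
    "NcW": {"mean": [2, 3, 3, 3, 3, 3], "sem": [1, 1, 1, 1, 1, 1]},
    "EcW": {"mean": [3, 5, 5, 4, 4, 4], "sem": [1, 2, 2, 1, 1, 1]},
    "NsW": {"mean": [2, 6, 8, 8, 7, 7], "sem": [1, 2, 3, 3, 2, 2]},
    "EsW": {"mean": [4, 25, 30, 32, 30, 30], "sem": [2, 5, 6, 6, 5, 5]},
    "D(NsW)": {"mean": [3, 15, 30, 40, 50, 55], "sem": [1, 4, 6, 7, 7, 7]},
    "D(EsW)": {"mean": [5, 25, 50, 62, 68, 72], "sem": [2, 5, 7, 7, 7, 6]},
}

#: pre-exposure-test targets: mean and SEM of % freezing in the scored
#: 3 minutes for experienced vs naive witnesses (the emulated study prints
#: 36.6 +/- 5.2 vs 1.2 +/- 0.7).
PRE_EXPOSURE_TARGETS = {"experienced": (36.6, 5.2), "naive": (1.2, 0.7)}

#: negative-binomial (mu, size) for pair call counts per shock group; sizes
#: chosen so that zero-count (non-emitting) pairs occur at realistic rates.
DEFAULT_USV_COUNT_PARAMS = {"NsW": (5.0, 0.2), "EsW": (40.0, 0.5)}


@dataclass
class BehaviorSimSpec:
    """Cohort structure and coupling parameters."""

    freezing_targets: Mapping[str, Mapping[str, Sequence[float]]] = field(
        default_factory=lambda: DEFAULT_FREEZING_TARGETS
    )
    n_per_group: int = 12
    usv_coupling_rho: float = 0.6
    usv_count_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: DEFAULT_USV_COUNT_PARAMS
    )
    min_bout_s: float = 1.0

    def __post_init__(self) -> None:
        if abs(self.usv_coupling_rho) > 1:
            raise ValueError("|usv_coupling_rho| must be <= 1")
        if self.n_per_group < 2:
            raise ValueError("need n >= 2 per group")
        for g, t in self.freezing_targets.items():
            m = np.asarray(t["mean"], dtype=float)
            s = np.asarray(t["sem"], dtype=float)
            if np.any((m < 0) | (m > 100)):
                raise ValueError(f"group {g}: means must lie in [0, 100]")
            sd = s * np.sqrt(self.n_per_group)
            # no distribution on [0, 100] has SD above 50 (two-point bound)
            if np.any(sd > 50):
                raise ValueError(f"group {g}: SEM forces mass outside [0, 100]")


def _truncnorm(
    mean: float, sd: float, size: int, rng: np.random.Generator,
    lo: float = 0.0, hi: float = 100.0,
) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def realize_bouts(
    bin_targets: Sequence[float],
    bins: BinSchedule,
    seed: int | np.random.Generator,
    animal_id: str = "animal",
    min_bout_s: float = 1.0,
) -> FreezingBoutSeries:
    """Construct a bout set whose per-bin freezing matches ``bin_targets``.

    Per bin, the target time is split into bouts of at least ``min_bout_s``
    placed at random non-overlapping positions; the realized percentage is
    within 0.5 points of the target. Targets too small to realize with the
    minimum bout length round to the nearer of zero or one minimum bout
    (raising if even that misses by more than 0.5 points).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bouts: list[tuple[float, float]] = []
    for (lo, hi), pct in zip(bins.bins, bin_targets):
        if not 0 <= pct <= 100:
            raise ValueError(f"target {pct} outside [0, 100]")
        length = hi - lo
        target_t = pct / 100.0 * length
        if target_t <= 0:
            continue
        if target_t < min_bout_s:
            err_zero = target_t / length
            err_one = (min_bout_s - target_t) / length
            if min(err_zero, err_one) > 0.005:
                raise ValueError(
                    f"target {pct}% unreachable in a {length}s bin with "
                    f"{min_bout_s}s minimum bouts"
                )
            if err_zero <= err_one:
                continue
            target_t = min_bout_s
        if target_t >= 0.9 * length:
            start = lo + rng.uniform(0, length - target_t)
            bouts.append((start, start + target_t))
            continue
        k = int(max(1, min(target_t // min_bout_s, round(target_t / 5.0))))
        gap = 0.2
        while k > 1 and target_t + (k + 1) * gap > length:
            k -= 1
        per = target_t / k
        onsets = _place_intervals(np.full(k, per), length, gap, rng)
        bouts.extend((lo + o, lo + o + per) for o in onsets)
    bouts.sort()
    return FreezingBoutSeries(animal_id=animal_id, bouts=bouts)


def _copula_counts(
    freezing: np.ndarray,
    groups: Sequence[str],
    spec: BehaviorSimSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Negative-binomial pair counts coupled to freezing via a Gaussian copula.

    Freezing is standardized within each shock group so the copula leaves
    the per-group count marginals untouched; the pooled Pearson correlation
    then combines the within-group coupling with the aligned between-group
    separation of both variables.
    """
    groups = np.asarray(groups)
    z = np.empty(len(freezing))
    for grp in np.unique(groups):
        mask = groups == grp
        f = freezing[mask]
        z[mask] = (f - f.mean()) / max(f.std(), 1e-12)
    rho = spec.usv_coupling_rho
    w = rho * z + np.sqrt(1 - rho**2) * rng.standard_normal(len(z))
    u = stats.norm.cdf(w)
    counts = np.empty(len(z), dtype=int)
    for i, grp in enumerate(groups):
        mu, size = spec.usv_count_params[grp]
        p = size / (size + mu)  # scipy nbinom (n=size, p)
        counts[i] = int(stats.nbinom.ppf(u[i], size, p))
    return counts


def simulate_cohort(
    spec: BehaviorSimSpec, seed: int, bins: BinSchedule | None = None
) -> tuple[pd.DataFrame, dict[str, FreezingBoutSeries], pd.DataFrame, GroundTruth]:
    """Generate a full behavioral cohort.

    Returns a tidy freezing table (animal_id, group, bin, value), the
    realized per-animal bout series on ``bins`` (defaults to a canonical
    6-bin test schedule with shocks at 600/720/900/1020/1200 s), a
    pair-level table of call counts for the two shock groups, and the
    ground truth used.
    """
    from .behavior_scoring import SessionSchedule, build_empathy_bins

    rng = np.random.default_rng(seed)
    if bins is None:
        sched = SessionSchedule(
            session_type="empathy_test",
            baseline_duration=600.0,
            event_onsets=[600.0, 720.0, 900.0, 1020.0, 1200.0],
        )
        bins = build_empathy_bins(sched)
    n_bins = len(bins.bins)

    rows = []
    bout_series: dict[str, FreezingBoutSeries] = {}
    truth_rows = []
    for grp, targets in spec.freezing_targets.items():
        means = np.asarray(targets["mean"], dtype=float)
        sems = np.asarray(targets["sem"], dtype=float)
        if len(means) != n_bins:
            raise ValueError(f"group {grp}: expected {n_bins} bin targets")
        sds = sems * np.sqrt(spec.n_per_group)
        for i in range(spec.n_per_group):
            animal = f"{grp}_{i:02d}"
            vals = np.array(
                [_truncnorm(m, s, 1, rng)[0] for m, s in zip(means, sds)]
            )
            bout_series[animal] = realize_bouts(
                vals, bins, rng, animal_id=animal, min_bout_s=spec.min_bout_s
            )
            realized = percent_freezing(bout_series[animal], bins)
            for lbl, v in zip(bins.labels, realized):
                rows.append({"animal_id": animal, "group": grp, "bin": lbl, "value": v})
            truth_rows.append({"animal_id": animal, "group": grp, **dict(zip(bins.labels, vals))})
    freezing = pd.DataFrame(rows)

    # pair-level call counts, coupled to demonstrator shock-period freezing
    pair_rows = []
    demo_map = {"NsW": "D(NsW)", "EsW": "D(EsW)"}
    demo_freeze, pair_groups, pair_ids = [], [], []
    for wit_grp, demo_grp in demo_map.items():
        if demo_grp not in spec.freezing_targets:
            continue
        for i in range(spec.n_per_group):
            animal = f"{demo_grp}_{i:02d}"
            vals = freezing[freezing["animal_id"] == animal]
            shock = vals[vals["bin"] != bins.labels[0]]["value"].mean()
            demo_freeze.append(shock)
            pair_groups.append(wit_grp)
            pair_ids.append(f"pair_{wit_grp}_{i:02d}")
    usv = pd.DataFrame()
    if demo_freeze:
        demo_freeze = np.asarray(demo_freeze)
        counts = _copula_counts(demo_freeze, pair_groups, spec, rng)
        usv = pd.DataFrame(
            {
                "pair_id": pair_ids,
                "group": pair_groups,
                "usv_count": counts,
                "demonstrator_shock_freezing": demo_freeze,
            }
        )

    truth = GroundTruth(
        bin_targets=pd.DataFrame(truth_rows),
        coupling_rho=spec.usv_coupling_rho,
        seed=seed,
    )
    return freezing, bout_series, usv, truth


def simulate_pre_exposure(
    n_per_group: int, seed: int,
    targets: Mapping[str, tuple[float, float]] = PRE_EXPOSURE_TARGETS,
) -> pd.DataFrame:
    """Pre-exposure-test freezing scores for experienced vs naive witnesses.

    Per-animal scores are truncated normals with SD = SEM * sqrt(n) around
    the group targets.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for grp, (mean, sem) in targets.items():
        sd = sem * np.sqrt(n_per_group)
        vals = _truncnorm(mean, sd, n_per_group, rng)
        rows.extend(
            {"animal_id": f"{grp}_{i:02d}", "group": grp, "value": v}
            for i, v in enumerate(vals)
        )
    return pd.DataFrame(rows)
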