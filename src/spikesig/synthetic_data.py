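"""Synthetic spike trains emulating the four archetypal phenotypes.

Renewal and mixture models chosen to land each phenotype in its qualitative
feature regime with clear margins:

* control - gamma-renewal ISIs, shape 3, mean 12 ms: moderately irregular
  firing near 80 spikes/s.
* ataxia - gamma-renewal, shape 80, mean 12 ms: highly regular firing
  (CV2 well below 0.2), same rate as control.
* dystonia - two-component mixture renewal: with probability 0.85 a fast ISI
  ~ gamma(2, mean 15 ms), otherwise a pause ISI ~ gamma(2, mean 150 ms):
  slow, irregular, pause-rich firing.
* tremor - 10 Hz cycle process: each 100 ms cycle holds a burst of
  1 + Poisson(4) spikes with intra-burst ISIs ~ gamma(5, mean 6 ms), the
  remainder of the cycle silent, cycle onsets jittered +-5 ms: rhythmic
  bursting at the tremor frequency.

Optogenetic stimulation paradigms are modeled as inhomogeneous thinning of a
base Poisson process: the instantaneous rate is r(t) = base_rate * (1 - g*s(t))
where s(t) in [0, 1] is the light waveform (Purkinje-cell stimulation inhibits
nuclei neurons; no rebound dynamics).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core_io import SIGNATURES, CohortTable, SpikeTrain

__all__ = [
    "PhenotypeSpec",
    "ARCHETYPES",
    "CONTRACTS",
    "OptoParadigm",
    "generate_train",
    "generate_archetypal_cohort",
    "opto_modulated_train",
    "generate_accel_trace",
]


@dataclass
class PhenotypeSpec:
    """Generator parameters for one phenotype (defaults per archetype)."""

    phenotype: str
    kind: str                        # "gamma" | "gamma_mixture" | "burst_cycle"
    duration: float = 30.0
    # gamma / gamma_mixture
    shape: float = 3.0
    mean_ms: float = 12.0
    pause_prob: float = 0.0
    pause_shape: float = 2.0
    pause_mean_ms: float = 150.0
    # burst_cycle
    cycle_ms: float = 100.0
    jitter_ms: float = 5.0
    extra_spikes_mean: float = 4.0
    intra_shape: float = 5.0
    intra_mean_ms: float = 6.0

    def __post_init__(self) -> None:
        for name in ("shape", "mean_ms", "pause_shape", "pause_mean_ms",
                     "cycle_ms", "intra_shape", "intra_mean_ms", "duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.pause_prob <= 1.0:
            raise ValueError("pause_prob must be in [0, 1]")


ARCHETYPES: dict[str, PhenotypeSpec] = {
    "control": PhenotypeSpec("control", "gamma", shape=3.0, mean_ms=12.0),
    "ataxia": PhenotypeSpec("ataxia", "gamma", shape=80.0, mean_ms=12.0),
    "dystonia": PhenotypeSpec("dystonia", "gamma_mixture", shape=2.0,
                              mean_ms=15.0, pause_prob=0.15,
                              pause_shape=2.0, pause_mean_ms=150.0),
    "tremor": PhenotypeSpec("tremor", "burst_cycle"),
}

#: Expected feature regimes of the archetype generators (inclusive bounds).
#: Derived from the renewal parameters above (e.g. dystonia skewness: the
#: mixture's median ISI ~ 15 ms against a mean ISI of 35 ms gives ~0.8).
CONTRACTS: dict[str, dict[str, tuple[float, float]]] = {
    "control": {"firing_rate": (60.0, 95.0), "cv2": (0.4, 0.8),
                "skewness": (0.0, 0.25), "isi25": (0.0, 15.0)},
    "ataxia": {"cv2": (0.0, 0.2), "skewness": (-0.1, 0.1)},
    "dystonia": {"skewness": (0.3, 1.0), "isi25": (25.0, 100.0)},
    "tremor": {"skewness": (0.5, 2.0), "isi25": (10.0, 25.0)},
}


def _rng_for(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _renewal_times(draw_isi, duration_s: float, rng, chunk: int = 4096
                   ) -> np.ndarray:
    """Accumulate ISIs (seconds) from ``draw_isi(rng, size)`` until the
    recording ends; the first spike sits one ISI after t = 0."""
    times = []
    t = 0.0
    while t < duration_s:
        ts = t + np.cumsum(draw_isi(rng, chunk))
        times.append(ts)
        t = float(ts[-1])
    ts = np.concatenate(times)
    return ts[ts < duration_s]


def generate_train(spec: PhenotypeSpec | str, seed=0, cell_id: str | None = None,
                   duration: float | None = None) -> SpikeTrain:
    """Generate one 30-s spike train for a phenotype archetype.

    ``spec`` may be a phenotype name (using :data:`ARCHETYPES` defaults) or a
    full :class:`PhenotypeSpec`. Reproducible given ``seed``.
    """
    if isinstance(spec, str):
        if spec not in ARCHETYPES:
            raise KeyError(f"unknown phenotype {spec!r}")
        spec = ARCHETYPES[spec]
    if duration is not None:
        spec = replace(spec, duration=duration)
    rng = _rng_for(seed)
    dur = spec.duration

    if spec.kind == "gamma":
        scale = spec.mean_ms / 1000.0 / spec.shape
        if dur / (spec.mean_ms / 1000.0) < 2:
            raise ValueError("parameters imply fewer than 2 expected spikes")
        ts = _renewal_times(lambda r, n: r.gamma(spec.shape, scale, n), dur, rng)
    elif spec.kind == "gamma_mixture":
        fast_scale = spec.mean_ms / 1000.0 / spec.shape
        pause_scale = spec.pause_mean_ms / 1000.0 / spec.pause_shape

        def draw(r, n):
            fast = r.gamma(spec.shape, fast_scale, n)
            pause = r.gamma(spec.pause_shape, pause_scale, n)
            is_pause = r.random(n) < spec.pause_prob
            return np.where(is_pause, pause, fast)

        mean_isi_s = ((1 - spec.pause_prob) * spec.mean_ms
                      + spec.pause_prob * spec.pause_mean_ms) / 1000.0
        if dur / mean_isi_s < 2:
            raise ValueError("parameters imply fewer than 2 expected spikes")
        ts = _renewal_times(draw, dur, rng)
    elif spec.kind == "burst_cycle":
        cycle_s = spec.cycle_ms / 1000.0
        n_cycles = int(np.floor(dur / cycle_s))
        if n_cycles < 2:
            raise ValueError("parameters imply fewer than 2 expected spikes")
        intra_scale = spec.intra_mean_ms / 1000.0 / spec.intra_shape
        times = []
        for k in range(n_cycles):
            onset = k * cycle_s + rng.uniform(-spec.jitter_ms, spec.jitter_ms) / 1000.0
            n_spk = 1 + rng.poisson(spec.extra_spikes_mean)
            isis = rng.gamma(spec.intra_shape, intra_scale, n_spk - 1)
            times.append(onset + np.concatenate([[0.0], np.cumsum(isis)]))
        ts = np.sort(np.concatenate(times))
        ts = ts[(ts >= 0) & (ts < dur)]
    else:
        raise ValueError(f"unknown generator kind {spec.kind!r}")

    ts = np.unique(ts)
    return SpikeTrain(
        cell_id=cell_id or f"{spec.phenotype}_s{seed}",
        timestamps=ts,
        duration=dur,
        group_label=spec.phenotype,
        metadata={"seed": str(seed), "generator": spec.kind},
    )


def generate_archetypal_cohort(
    n_per_group: dict[str, int] | None = None,
    seed: int = 0,
    duration: float = 30.0,
) -> tuple[CohortTable, list[str]]:
    """Generate a labeled cohort at the reference class sizes.

    Defaults to control 25, ataxia 20, dystonia 20, tremor 20. Each cell uses
    an independent RNG stream derived from ``(seed, cell index)``, recorded in
    the train metadata.
    """
    if n_per_group is None:
        n_per_group = {"control": 25, "ataxia": 20, "dystonia": 20, "tremor": 20}
    for g in n_per_group:
        if g not in ARCHETYPES:
            raise KeyError(f"unknown group {g!r}")
        if n_per_group[g] < 1:
            raise ValueError(f"need n >= 1 for group {g!r}")
    trains, labels = [], []
    cell_index = 0
    for g, n in n_per_group.items():
        for i in range(n):
            cell_seed = np.random.SeedSequence([int(seed), cell_index])
            t = generate_train(ARCHETYPES[g], seed=cell_seed,
                               cell_id=f"{g}_{i:03d}_m{seed}",
                               duration=duration)
            t.metadata["cell_index"] = str(cell_index)
            t.metadata["master_seed"] = str(seed)
            trains.append(t)
            labels.append(g)
            cell_index += 1
    return CohortTable(trains, provenance=f"synthetic archetypal cohort, seed {seed}"), labels


# ---------------------------------------------------------------------------
# Optogenetic stimulation paradigms
# ---------------------------------------------------------------------------

@dataclass
class OptoParadigm:
    """Light-stimulation waveform s(t) in [0, 1] for one paradigm.

    * ``ataxia_stim``: continuous 50 Hz square pulses (10 ms on / 10 ms off).
    * ``dystonia_stim``: blocks of >= 1 s of the 50 Hz pulses, each block
      followed with probability 0.75 by a 250 ms pause in stimulation.
    * ``tremor_stim``: 100 Hz pulses (5 ms on / 5 ms off) amplitude-modulated
      by a 10 Hz sinusoid - per 100 ms cycle, 50 ms of parabolic rise and
      fall of light power followed by 50 ms light off.
    """

    kind: str
    block_s: float = 1.0
    pause_s: float = 0.25
    pause_prob: float = 0.75

    KINDS = ("ataxia_stim", "dystonia_stim", "tremor_stim")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown paradigm {self.kind!r}")

    def waveform(self, t: np.ndarray, rng: np.random.Generator | None = None
                 ) -> np.ndarray:
        """Evaluate s(t) at times ``t`` (seconds).

        The dystonia paradigm's random pause schedule is drawn from ``rng``
        over the span of ``t``.
        """
        t = np.asarray(t, dtype=float)
        if self.kind == "ataxia_stim":
            return (np.mod(t, 0.020) < 0.010).astype(float)
        if self.kind == "tremor_stim":
            pulse = (np.mod(t, 0.010) < 0.005).astype(float)
            tau = np.mod(t, 0.100)
            env = np.where(tau < 0.050, 1.0 - ((tau - 0.025) / 0.025) ** 2, 0.0)
            return pulse * np.clip(env, 0.0, 1.0)
        # dystonia_stim: build the block/pause schedule, then mask pauses.
        if rng is None:
            rng = np.random.default_rng(0)
        t_end = float(t.max()) if t.size else 0.0
        stim_on = np.ones_like(t, dtype=bool)
        clock = self.block_s
        while clock < t_end:
            if rng.random() < self.pause_prob:
                stim_on &= ~((t >= clock) & (t < clock + self.pause_s))
                clock += self.pause_s
            clock += self.block_s
        pulses = (np.mod(t, 0.020) < 0.010).astype(float)
        return pulses * stim_on


def opto_modulated_train(
    base_rate_hz: float = 80.0,
    paradigm: OptoParadigm | str = "tremor_stim",
    gain: float = 0.9,
    duration: float = 30.0,
    seed=0,
    cell_id: str | None = None,
) -> SpikeTrain:
    """Spike train under optogenetic inhibition, by thinning a Poisson process.

    A homogeneous Poisson train at ``base_rate_hz`` is thinned so that the
    instantaneous rate is base_rate * (1 - gain * s(t)). ``gain`` = 0 returns
    the unmodulated base process.
    """
    if isinstance(paradigm, str):
        paradigm = OptoParadigm(paradigm)
    if base_rate_hz <= 0:
        raise ValueError("base_rate_hz must be positive")
    if not 0.0 <= gain <= 1.0:
        raise ValueError("gain must be in [0, 1]")
    rng = _rng_for(seed)
    n = rng.poisson(base_rate_hz * duration)
    ts = np.sort(rng.uniform(0.0, duration, n))
    s = paradigm.waveform(ts, rng=rng)
    keep = rng.random(ts.size) < (1.0 - gain * s)
    ts = np.unique(ts[keep])
    return SpikeTrain(
        cell_id=cell_id or f"{paradigm.kind}_g{gain}_s{seed}",
        timestamps=ts,
        duration=duration,
        group_label=paradigm.kind,
        metadata={"seed": str(seed), "paradigm": paradigm.kind,
                  "gain": str(gain), "base_rate_hz": str(base_rate_hz)},
    )


def generate_accel_trace(
    tremor_hz: float = 10.0,
    amplitude: float = 1.0,
    noise_sd: float = 0.3,
    duration: float = 120.0,
    sampling_rate: float = 500.0,
    seed=0,
):
    """Accelerometer trace: a tremor sinusoid plus white noise (seeded)."""
    from .cohort_stats import AccelTrace

    if tremor_hz >= sampling_rate / 2:
        raise ValueError("tremor frequency aliases: need tremor_hz < rate/2")
    rng = _rng_for(seed)
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    x = amplitude * np.sin(2 * np.pi * tremor_hz * t) + rng.normal(0, noise_sd, n)
    return AccelTrace(samples=x, sampling_rate=sampling_rate)
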