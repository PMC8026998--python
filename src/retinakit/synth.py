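"""Seeded synthetic-data generators for every input the analysis pipeline consumes.

Two tiers of electrophysiology data are generated:

* a *count tier* (:func:`simulate_trial_counts`) that draws windowed spike
  counts directly from Poisson laws — fast, used for statistical acceptance
  checks; and
* a *trace tier* (:func:`simulate_trace`) that renders an inhomogeneous
  Poisson spike train as biphasic waveforms embedded in Gaussian noise at the
  full sampling rate, with ground-truth spike times returned alongside — used
  to exercise filtering and threshold detection end to end.

Cone-survival tables follow a log2-linear decay with multiplicative lognormal
noise, and RNA-seq-like count matrices are negative-binomial with a spiked
differentially-expressed fraction.  Every generator is a pure function of its
parameters and a single integer seed; per-channel / per-gene substreams are
spawned from that seed so that subsets are reproducible independently of how
many channels or genes are requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FlashEpoch",
    "StimulusProtocol",
    "RateModel",
    "SpikeTemplate",
    "DecayModel",
    "PAPER_INTENSITIES",
    "make_protocol",
    "saturating_rate_map",
    "biphasic_template",
    "simulate_trial_counts",
    "simulate_trace",
    "simulate_survival",
    "simulate_counts",
]

#: Flash intensities of the standard stimulation protocol, photons/cm^2/s.
#: The lowest tier is scotopic; the top five are the photopic range.
PAPER_INTENSITIES: tuple[float, ...] = (8.6e12, 5.3e13, 3e14, 8.7e14, 1.6e15, 2.3e15)

#: Window length (s) shared by the ON, OFF and spontaneous counting windows.
WINDOW_S = 0.35


@dataclass(frozen=True)
class FlashEpoch:
    """One light flash: onset time, duration, intensity and repetition index."""

    onset_s: float
    duration_s: float
    intensity: float
    rep_index: int

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class StimulusProtocol:
    """Chronologically ordered, non-overlapping flash epochs.

    ``photopic`` returns the top five intensities (cone-driven range); when
    fewer than five intensities exist, all of them are returned.
    """

    epochs: tuple[FlashEpoch, ...]
    dark_gap_s: float

    @property
    def intensities(self) -> tuple[float, ...]:
        seen: dict[float, None] = {}
        for e in self.epochs:
            seen.setdefault(e.intensity, None)
        return tuple(sorted(seen))

    @property
    def photopic(self) -> tuple[float, ...]:
        ints = self.intensities
        return ints[-5:] if len(ints) > 5 else ints

    @property
    def reps(self) -> int:
        return 1 + max(e.rep_index for e in self.epochs)

    @property
    def flash_duration_s(self) -> float:
        return self.epochs[0].duration_s

    @property
    def total_duration_s(self) -> float:
        last = self.epochs[-1]
        return last.offset_s + self.dark_gap_s

    def epochs_for(self, intensity: float) -> tuple[FlashEpoch, ...]:
        return tuple(e for e in self.epochs if e.intensity == intensity)

    def to_records(self) -> list[dict]:
        return [
            {
                "onset_s": e.onset_s,
                "duration_s": e.duration_s,
                "intensity_photons_cm2_s": e.intensity,
                "rep_index": e.rep_index,
            }
            for e in self.epochs
        ]

    @classmethod
    def from_records(cls, records: list[dict], dark_gap_s: float | None = None) -> "StimulusProtocol":
        epochs = tuple(
            FlashEpoch(
                onset_s=float(r["onset_s"]),
                duration_s=float(r["duration_s"]),
                intensity=float(r["intensity_photons_cm2_s"]),
                rep_index=int(r["rep_index"]),
            )
            for r in records
        )
        if dark_gap_s is None:
            dark_gap_s = epochs[0].onset_s if epochs else 2.0
        return cls(epochs=epochs, dark_gap_s=float(dark_gap_s))


@dataclass(frozen=True)
class RateModel:
    """Generative firing rates (events/s) of one simulated electrode.

    ``on_rate`` / ``off_rate`` map stimulus intensity to the firing rate in
    the ON (during flash) and OFF (after flash) windows; ``spont_rate`` is the
    dark rate.  ``latency_s`` shifts the rate step after flash onset in the
    trace tier.
    """

    spont_rate: float
    on_rate: dict[float, float]
    off_rate: dict[float, float]
    latency_s: float = 0.0

    def __post_init__(self) -> None:
        rates = [self.spont_rate, self.latency_s, *self.on_rate.values(), *self.off_rate.values()]
        arr = np.asarray(rates, dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValueError("rates and latency must be finite and >= 0")

    @classmethod
    def flat(
        cls,
        intensities,
        on_rate: float,
        spont_rate: float,
        off_rate: float | None = None,
        latency_s: float = 0.0,
    ) -> "RateModel":
        """Same ON (and OFF) rate at every intensity — the common test case."""
        off = spont_rate if off_rate is None else off_rate
        return cls(
            spont_rate=spont_rate,
            on_rate={float(i): float(on_rate) for i in intensities},
            off_rate={float(i): float(off) for i in intensities},
            latency_s=latency_s,
        )


def saturating_rate_map(
    intensities,
    r_max: float,
    i_half: float,
    spont_rate: float = 0.0,
    exponent: float = 1.0,
) -> dict[float, float]:
    """Optional Naka–Rushton-style intensity→rate helper.

    rate(I) = spont + r_max * I^n / (I^n + i_half^n).  The generators never
    require it; explicit per-intensity rates are the primary interface.
    """
    out = {}
    for i in intensities:
        drive = float(i) ** exponent
        out[float(i)] = spont_rate + r_max * drive / (drive + float(i_half) ** exponent)
    return out


@dataclass(frozen=True)
class SpikeTemplate:
    """Biphasic spike waveform; peak amplitude in units of the noise SD."""

    waveform: np.ndarray
    duration_s: float

    def __post_init__(self) -> None:
        w = np.asarray(self.waveform, dtype=float)
        if not np.all(np.isfinite(w)):
            raise ValueError("template waveform must be finite")
        if self.duration_s <= 0:
            raise ValueError("template duration must be positive")
        object.__setattr__(self, "waveform", w)

    @property
    def peak_sd(self) -> float:
        return float(np.max(np.abs(self.waveform)))


def biphasic_template(
    sampling_rate: float, amplitude_sd: float = 8.0, duration_s: float = 0.001
) -> SpikeTemplate:
    """Canonical extracellular-like biphasic template.

    Negative trough followed by a smaller positive rebound (first derivative
    of a Gaussian), scaled so the trough depth equals ``amplitude_sd`` noise
    standard deviations.
    """
    n = max(int(round(duration_s * sampling_rate)), 3)
    t = np.linspace(-1.0, 1.0, n)
    w = -t * np.exp(-(t**2) * 4.0)
    w = w / np.max(np.abs(w)) * amplitude_sd
    return SpikeTemplate(waveform=w, duration_s=n / sampling_rate)


@dataclass(frozen=True)
class DecayModel:
    """Log2-linear cone-density decay: density(t) = 2^(a - b t).

    ``a`` is log2 cones/100 µm at day 0, ``b`` the decay slope in log2 units
    per day (positive for a declining arm), ``noise_cv`` the coefficient of
    variation of the multiplicative lognormal noise.
    """

    a: float
    b: float
    noise_cv: float = 0.0
    arm_label: str = "control"

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    def density(self, age) -> np.ndarray:
        return 2.0 ** (self.a - self.b * np.asarray(age, dtype=float))


def make_protocol(
    intensities=PAPER_INTENSITIES,
    reps: int = 20,
    flash_dur: float = WINDOW_S,
    dark_gap: float = 2.0,
) -> StimulusProtocol:
    """Build the flash protocol: ``reps`` flashes per intensity, dark gaps between.

    Flashes are grouped by increasing intensity (all repetitions of one
    intensity before the next), each preceded by ``dark_gap`` seconds of dark,
    starting at t = ``dark_gap``.
    """
    intensities = [float(i) for i in intensities]
    if not intensities:
        raise ValueError("intensities must be nonempty")
    if any(b <= a for a, b in zip(intensities, intensities[1:])):
        raise ValueError("intensities must be strictly increasing")
    if flash_dur <= 0 or dark_gap <= 0:
        raise ValueError("flash_dur and dark_gap must be positive")
    if reps < 1:
        raise ValueError("reps must be >= 1")

    epochs = []
    t = dark_gap
    for inten in intensities:
        for rep in range(reps):
            epochs.append(FlashEpoch(onset_s=t, duration_s=flash_dur, intensity=inten, rep_index=rep))
            t += flash_dur + dark_gap
    return StimulusProtocol(epochs=tuple(epochs), dark_gap_s=dark_gap)


def _channel_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Independent substream per channel; substream i does not depend on n."""
    return [
        np.random.Generator(np.random.Philox(np.random.SeedSequence(entropy=seed, spawn_key=(i,))))
        for i in range(n)
    ]


def simulate_trial_counts(
    protocol: StimulusProtocol,
    rate_model: RateModel,
    n_channels: int,
    seed: int,
) -> pd.DataFrame:
    """Count-tier generator: independent Poisson ON/OFF/spontaneous counts.

    Returns a tidy frame with one row per (channel, intensity, repetition)
    holding ``count_on``, ``count_off`` and ``count_spont``; the counting
    window is the flash duration for all three.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    missing = [i for i in protocol.intensities if i not in rate_model.on_rate]
    if missing:
        raise ValueError(f"rate model lacks intensities {missing}")

    w = protocol.flash_duration_s
    reps = protocol.reps
    intensities = protocol.intensities
    rows = []
    for ch, rng in enumerate(_channel_rngs(seed, n_channels)):
        for inten in intensities:
            lam_on = rate_model.on_rate[inten] * w
            lam_off = rate_model.off_rate[inten] * w
            lam_sp = rate_model.spont_rate * w
            c_on = rng.poisson(lam_on, reps)
            c_off = rng.poisson(lam_off, reps)
            c_sp = rng.poisson(lam_sp, reps)
            for rep in range(reps):
                rows.append((ch, inten, rep, int(c_on[rep]), int(c_off[rep]), int(c_sp[rep])))
    df = pd.DataFrame(
        rows, columns=["channel_id", "intensity", "rep_index", "count_on", "count_off", "count_spont"]
    )
    df.attrs["window_s"] = w
    return df


def _segment_rates(protocol: StimulusProtocol, rate_model: RateModel, duration_s: float):
    """Piecewise-constant rate: spont in dark, ON during flash (after latency),
    OFF rate for one window length after flash offset."""
    bounds = [0.0]
    rates = []
    t = 0.0
    for e in protocol.epochs:
        on_start = min(e.onset_s + rate_model.latency_s, duration_s)
        off_end = min(e.offset_s + e.duration_s, duration_s)
        for start, rate in (
            (t, rate_model.spont_rate),
            (on_start, rate_model.on_rate[e.intensity]),
            (min(e.offset_s, duration_s), rate_model.off_rate[e.intensity]),
        ):
            if start < duration_s:
                rates.append(rate)
                bounds.append(start)
        t = off_end
        if t >= duration_s:
            break
    if t < duration_s:
        rates.append(rate_model.spont_rate)
        bounds.append(t)
    # normalise: bounds[0]=0 start sentinel; build (start, end, rate) triples
    starts = bounds[1:]
    segs = []
    for k, rate in enumerate(rates):
        end = starts[k + 1] if k + 1 < len(starts) else duration_s
        if end > starts[k]:
            segs.append((starts[k], end, rate))
    return segs


def _poisson_times(rng: np.random.Generator, segs, min_isi: float) -> np.ndarray:
    times = []
    for start, end, rate in segs:
        if rate <= 0:
            continue
        n = rng.poisson(rate * (end - start))
        if n:
            times.append(np.sort(rng.uniform(start, end, n)))
    if not times:
        return np.empty(0)
    t = np.sort(np.concatenate(times))
    # enforce refractory separation >= min_isi by dropping too-close events
    keep = []
    last = -np.inf
    for ti in t:
        if ti - last >= min_isi:
            keep.append(ti)
            last = ti
    return np.asarray(keep)


def simulate_trace(
    protocol: StimulusProtocol,
    rate_model: RateModel,
    template: SpikeTemplate,
    noise_sd: float,
    sampling_rate: float = 25000.0,
    duration_s: float | None = None,
    n_channels: int = 1,
    seed: int = 0,
    min_isi: float | None = None,
):
    """Trace-tier generator: spike waveforms in white Gaussian noise.

    Spike times follow an inhomogeneous Poisson process whose rate steps at
    flash boundaries, with a minimum inter-spike interval of ``min_isi``
    (default: the template duration or the standard 1.5 ms detector dead
    time, whichever is longer) so every generated waveform is separable by
    the downstream detector.  Returns
    ``(recording, truth)`` where ``recording`` is an
    :class:`retinakit.mea.RawRecording` and ``truth`` a DataFrame of
    (channel_id, t_s) ground-truth spike times.
    """
    from .mea import RawRecording, default_geometry

    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if min_isi is None:
        min_isi = max(template.duration_s, 0.0015)
    elif min_isi < template.duration_s:
        raise ValueError("min_isi must be >= the template duration")
    if duration_s is None:
        duration_s = protocol.total_duration_s
    n_samples = int(round(duration_s * sampling_rate))
    segs = _segment_rates(protocol, rate_model, duration_s)
    max_rate = max((r for _, _, r in segs), default=0.0)
    if max_rate > 0 and template.duration_s >= 1.0 / max_rate * 10:
        # soft sanity guard only: refractory thinning handles density
        pass

    voltage = np.empty((n_channels, n_samples), dtype=np.float32)
    truth_rows = []
    wav = template.waveform * noise_sd  # template amplitude is in noise-SD units
    for ch, rng in enumerate(_channel_rngs(seed, n_channels)):
        trace = rng.normal(0.0, noise_sd, n_samples)
        times = _poisson_times(rng, segs, min_isi)
        for t_spk in times:
            i0 = int(round(t_spk * sampling_rate))
            i1 = min(i0 + len(wav), n_samples)
            if i0 < n_samples:
                trace[i0:i1] += wav[: i1 - i0]
                truth_rows.append((ch, t_spk))
        voltage[ch] = trace
    truth = pd.DataFrame(truth_rows, columns=["channel_id", "t_s"])
    truth["channel_id"] = truth["channel_id"].astype(int)
    rec = RawRecording(
        voltage=voltage,
        sampling_rate=sampling_rate,
        channel_ids=tuple(range(n_channels)),
        geometry=default_geometry(n_channels),
    )
    return rec, truth


def simulate_survival(
    models,
    ages,
    positions=(-80, -10, 10, 80),
    n_eyes: int = 6,
    seed: int = 0,
) -> pd.DataFrame:
    """Cone-density records: density = 2^(a − b·age) × LogNormal(0, σ).

    σ is set so the lognormal coefficient of variation equals the model's
    ``noise_cv``; all positions share the same expectation (no positional
    gradient by default).  One animal contributes one eye per arm.
    """
    models = list(models)
    if not models:
        raise ValueError("model list must be nonempty")
    ages = list(ages)
    if not ages:
        raise ValueError("ages must be nonempty")
    if n_eyes < 1:
        raise ValueError("n_eyes must be >= 1")

    rows = []
    for m_idx, model in enumerate(models):
        sigma = float(np.sqrt(np.log1p(model.noise_cv**2)))
        rng = np.random.Generator(
            np.random.Philox(np.random.SeedSequence(entropy=seed, spawn_key=(1000 + m_idx,)))
        )
        for age in ages:
            base = float(model.density(age))
            for eye in range(n_eyes):
                # animal id is arm-independent: the same animal carries a
                # treated eye and a contralateral control eye
                animal = f"pn{age:g}_m{eye}"
                for pos in positions:
                    noise = float(rng.lognormal(0.0, sigma)) if sigma > 0 else 1.0
                    rows.append(
                        (animal, model.arm_label, f"eye{eye}", float(age), float(pos), base * noise)
                    )
    return pd.DataFrame(
        rows, columns=["animal_id", "arm", "eye", "age_pn", "position_deg", "cones_per_100um"]
    )


def simulate_counts(
    n_genes: int,
    group_sizes=(3, 3),
    frac_de: float = 0.1,
    effect_log2: float = 2.0,
    dispersion: float = 0.01,
    mean_log_mu: float = 5.0,
    seed: int = 0,
    de_direction: str = "balanced",
):
    """Negative-binomial count matrix with a spiked differential fraction.

    Per-gene base means are lognormal around ``exp(mean_log_mu)``; a
    deterministic ``round(frac_de * n_genes)`` genes (seeded random identity)
    have their group-2 mean multiplied by ``2**(±effect_log2)``.  With
    ``de_direction='balanced'`` (default) the signs are assigned greedily so
    the spiked library mass is conserved — mixed up/down regulation, which
    keeps non-differential genes unshifted on the closed counts-per-million
    scale; ``'single'`` applies ``2**effect_log2`` to every spiked gene.
    Counts are gamma–Poisson draws with Var = µ + dispersion·µ².  Returns
    ``(counts DataFrame genes × samples, group labels, true-DE boolean
    array)``; the per-gene effect signs are in ``counts.attrs['de_sign']``.
    """
    if not 0 <= frac_de <= 1:
        raise ValueError("frac_de must be in [0, 1]")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if len(group_sizes) != 2 or any(g < 2 for g in group_sizes):
        raise ValueError("two groups of >= 2 samples each are required")
    if de_direction not in ("balanced", "single"):
        raise ValueError("de_direction must be 'balanced' or 'single'")

    n1, n2 = int(group_sizes[0]), int(group_sizes[1])
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
    base_mu = np.exp(rng.normal(mean_log_mu, 1.0, n_genes))
    n_de = int(round(frac_de * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    is_de = np.zeros(n_genes, dtype=bool)
    is_de[de_idx] = True

    sign = np.ones(n_genes)
    if de_direction == "balanced":
        # assign each spiked gene the regulation direction that keeps the
        # running library-mass delta closest to zero
        delta = 0.0
        up_f, down_f = 2.0**effect_log2 - 1.0, 2.0**-effect_log2 - 1.0
        for g in de_idx:
            d_up = delta + base_mu[g] * up_f
            d_down = delta + base_mu[g] * down_f
            if abs(d_up) <= abs(d_down):
                delta = d_up
            else:
                sign[g] = -1.0
                delta = d_down

    mu = np.tile(base_mu[:, None], (1, n1 + n2))
    mu[is_de, n1:] *= (2.0 ** (sign[is_de] * effect_log2))[:, None]
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu / shape)
    counts = rng.poisson(lam)

    samples = [f"ctrl_{i+1}" for i in range(n1)] + [f"trt_{i+1}" for i in range(n2)]
    genes = [f"gene_{i:05d}" for i in range(n_genes)]
    df = pd.DataFrame(counts, index=genes, columns=samples)
    df.attrs["de_sign"] = np.where(is_de, sign, 0.0)
    labels = ["control"] * n1 + ["treated"] * n2
    return df, labels, is_de
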