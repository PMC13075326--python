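"""Seeded multi-center synthetic EGM cohort generator.

Real AHRE archives are proprietary, so this module fabricates cohorts with
the same statistical shape: AT/AF the majority class, noise second, far-field
oversensing (FFO) the minority; long-tailed per-patient episode burdens
(median six AT/AF episodes per patient); and center-specific morphology bias
(spike width, dominant noise frequency, relative amplitudes) that the
cross-center ensemble is meant to absorb.

Waveform mechanics per class
----------------------------
SINUS  regular atrial activations at 50-90 bpm (Gaussian-derivative spike
       kernels), each conducted to the ventricle after a 120-200 ms AV delay.
ATAF   atrial rate 180-350 bpm; AF mode uses i.i.d. uniform cycle lengths and
       low-amplitude fibrillatory deflections; ventricular response is a
       thinned, jittered subsample of atrial events.
NOISE  a sinus-like rhythm plus one or more bursts of band-limited 30-60 Hz
       contamination on the atrial channel, with spurious markers inside
       bursts.
FFO    sinus rhythm plus an attenuated far-field R-wave on the ATRIAL channel
       time-locked 0-80 ms after each ventricular activation, double-counting
       atrial markers.

Every episode is emitted in preprocessed form together with a ground-truth
event log (activation times, burst windows, far-field deflections).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import signal as sp_signal

from .episodes import (
    EPISODE_SECONDS,
    FS,
    CohortManifest,
    EpisodeRecord,
    Label,
    preprocess,
)

EventLog = list[tuple[float, str]]


@dataclasses.dataclass
class CenterSpec:
    """One simulated hospital: roster size plus morphology bias knobs.

    Morphology fields default to None and are drawn once per center from the
    cohort seed; set them explicitly to pin a center's bias.
    """

    center_id: str
    n_patients: int
    width_scale: float | None = None      # multiplies spike kernel width
    noise_freq_hz: float | None = None    # dominant contamination frequency
    rel_amp_scale: float | None = None    # scales secondary-component amplitudes


@dataclasses.dataclass
class SimulationConfig:
    """Stated world of the default synthetic cohort.

    Per-patient class burdens follow shifted negative-binomial counts
    (minimum one episode) calibrated to the reported medians: six AT/AF
    episodes per AT/AF patient, five per noise patient, six per FFO patient.
    Noise and FFO are patient-level minorities via their prevalences.
    """

    seed: int = 0
    centers: list[CenterSpec] = dataclasses.field(
        default_factory=lambda: [
            CenterSpec("C1", 36),
            CenterSpec("C2", 30),
            CenterSpec("C3", 24),
            CenterSpec("C4", 12),
            CenterSpec("EXT", 20),
        ]
    )
    # shifted negative binomial: count = 1 + NB(r, p); r=2 centers the
    # median away from the 0.5 CDF boundary while keeping a 1-to-25+ tail
    count_r: int = 2
    ataf_count_p: float = 0.2456          # median 6
    noise_patient_prevalence: float = 0.45
    noise_count_p: float = 0.288          # median 5
    ffo_patient_prevalence: float = 0.15
    ffo_count_p: float = 0.2456           # median 6
    sinus_fraction: float = 0.5           # sinus episodes per AHRE episode
    no_ventricular_fraction: float = 0.05
    hard_mode: bool = False               # narrow inter-class gaps

    def validate(self) -> None:
        if not self.centers:
            raise ValueError("no centers configured")
        if any(c.n_patients < 1 for c in self.centers):
            raise ValueError("every center needs at least one patient")
        for name in ("ataf_count_p", "noise_count_p", "ffo_count_p"):
            p = getattr(self, name)
            if not 0 < p < 1:
                raise ValueError(f"{name} must be in (0,1)")


def _substream(seed: int, *key: int) -> np.random.Generator:
    """Hierarchical substream: stable under adding new centers/patients."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


@dataclasses.dataclass
class _Morphology:
    width_scale: float
    noise_freq_hz: float
    rel_amp_scale: float


def _center_morphology(spec: CenterSpec, rng: np.random.Generator) -> _Morphology:
    return _Morphology(
        width_scale=spec.width_scale if spec.width_scale is not None else rng.uniform(0.8, 1.25),
        noise_freq_hz=spec.noise_freq_hz
        if spec.noise_freq_hz is not None
        else rng.uniform(35.0, 55.0),
        rel_amp_scale=spec.rel_amp_scale
        if spec.rel_amp_scale is not None
        else rng.uniform(0.8, 1.2),
    )


def _spike_kernel(sigma_s: float) -> np.ndarray:
    """Biphasic deflection: first derivative of a Gaussian, peak |.| = 1."""
    half = max(2, int(round(4 * sigma_s * FS)))
    t = np.arange(-half, half + 1) / FS
    k = -t * np.exp(-(t**2) / (2 * sigma_s**2))
    return (k / np.max(np.abs(k))).astype(np.float32)


def _place_spikes(n: int, times: np.ndarray, amps: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    out = np.zeros(n, dtype=np.float32)
    half = (len(kernel) - 1) // 2
    for t, a in zip(times, amps):
        c = int(round(t * FS))
        lo, hi = c - half, c + half + 1
        klo, khi = max(0, -lo), len(kernel) - max(0, hi - n)
        lo, hi = max(0, lo), min(n, hi)
        if lo < hi:
            out[lo:hi] += a * kernel[klo:khi]
    return out


def _periodic_times(rate_bpm: float, jitter: float, rng: np.random.Generator) -> np.ndarray:
    period = 60.0 / rate_bpm
    t = rng.uniform(0, period)
    times = []
    while t < EPISODE_SECONDS:
        times.append(t)
        t += period * (1 + rng.uniform(-jitter, jitter))
    return np.array(times)


def _sinus_base(
    morph: _Morphology, rng: np.random.Generator, n: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Shared sinus machinery: returns (atrial, ventricular, a_times, v_times)."""
    rate = rng.uniform(50.0, 90.0)
    a_times = _periodic_times(rate, 0.02, rng)
    av = rng.uniform(0.12, 0.20)
    v_times = a_times + av + rng.normal(0, 0.005, size=len(a_times))
    v_times = v_times[(v_times >= 0) & (v_times < EPISODE_SECONDS)]
    sigma_a = rng.uniform(0.008, 0.020) * morph.width_scale
    atrial = _place_spikes(n, a_times, rng.normal(1.0, 0.05, len(a_times)), _spike_kernel(sigma_a))
    ventricular = _place_spikes(
        n, v_times, rng.normal(1.0, 0.05, len(v_times)), _spike_kernel(sigma_a * 1.6)
    )
    floor = 0.03 * morph.rel_amp_scale
    atrial += rng.normal(0, floor, n).astype(np.float32)
    ventricular += rng.normal(0, floor, n).astype(np.float32)
    return atrial, ventricular, a_times, v_times


def _band_noise(n: int, f0: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-amplitude band-limited noise centered at f0 (clipped to <62 Hz)."""
    lo = max(1.0, f0 - 6.0)
    hi = min(62.0, f0 + 6.0)
    b, a = sp_signal.butter(4, [lo, hi], btype="band", fs=FS)
    x = sp_signal.lfilter(b, a, rng.standard_normal(n)).astype(np.float32)
    peak = np.max(np.abs(x))
    return x / peak if peak > 0 else x


def simulate_episode(
    label: Label | str,
    center_params: _Morphology | CenterSpec,
    rng: np.random.Generator,
    *,
    episode_id: str = "episode",
    patient_id: str = "patient",
    center_id: str = "center",
    with_ventricular: bool = True,
    hard_mode: bool = False,
) -> tuple[EpisodeRecord, EventLog]:
    """Simulate one preprocessed episode plus its ground-truth event log.

    Event log kinds: ``A`` atrial activation, ``V`` ventricular activation,
    ``FF`` far-field deflection, ``burst_start``/``burst_end`` noise bursts.
    """
    label = Label(label)
    if isinstance(center_params, CenterSpec):
        center_params = _center_morphology(center_params, rng)
    morph = center_params
    n = int(EPISODE_SECONDS * FS)
    events: EventLog = []
    marker_times: list[float] = []
    marker_kinds: list[str] = []

    if label in (Label.SINUS, Label.NOISE, Label.FFO):
        atrial, ventricular, a_times, v_times = _sinus_base(morph, rng, n)
        events += [(float(t), "A") for t in a_times]
        events += [(float(t), "V") for t in v_times]
        v_kind = "Vp" if rng.random() < 0.2 else "Vs"
        marker_times += list(a_times) + list(v_times)
        marker_kinds += ["AS"] * len(a_times) + [v_kind] * len(v_times)

        if label == Label.NOISE:
            burst_amp = rng.uniform(0.25, 0.5) if hard_mode else rng.uniform(0.7, 1.2)
            burst_amp *= morph.rel_amp_scale
            for _ in range(int(rng.integers(1, 4))):
                dur = rng.uniform(0.5, 3.0)
                start = rng.uniform(0, EPISODE_SECONDS - dur)
                s0, s1 = int(start * FS), int((start + dur) * FS)
                env = sp_signal.windows.tukey(s1 - s0, alpha=0.25).astype(np.float32)
                atrial[s0:s1] += burst_amp * env * _band_noise(s1 - s0, morph.noise_freq_hz, rng)
                events += [(start, "burst_start"), (start + dur, "burst_end")]
                # spurious high-rate markers inside the burst
                t = start + rng.exponential(1 / 8)
                while t < start + dur:
                    marker_times.append(t)
                    marker_kinds.append("TA" if rng.random() < 0.5 else "AS")
                    t += rng.exponential(1 / 8)

        if label == Label.FFO:
            lag = rng.uniform(0.0, 0.080)
            rel = rng.uniform(0.15, 0.3) if hard_mode else rng.uniform(0.2, 0.6)
            rel *= morph.rel_amp_scale
            sigma_ff = rng.uniform(0.016, 0.030) * morph.width_scale
            ff_times = v_times + lag
            ff_times = ff_times[ff_times < EPISODE_SECONDS]
            atrial += _place_spikes(
                n, ff_times, np.full(len(ff_times), rel, dtype=np.float32), _spike_kernel(sigma_ff)
            )
            events += [(float(t), "FF") for t in ff_times]
            marker_times += list(ff_times)          # double-counted atrial senses
            marker_kinds += ["AS"] * len(ff_times)

    elif label == Label.ATAF:
        af_mode = rng.random() < 0.6
        if af_mode:
            lo, hi = 60.0 / 350.0, 60.0 / 180.0
            cycles = rng.uniform(lo, hi, size=80)
            a_times = np.cumsum(cycles) + rng.uniform(0, lo)
            a_times = a_times[a_times < EPISODE_SECONDS]
            amps = rng.uniform(0.3, 0.8, len(a_times))
            sigma_a = rng.uniform(0.006, 0.012) * morph.width_scale
        else:  # organized atrial tachycardia
            rate = rng.uniform(180.0, 350.0)
            a_times = _periodic_times(rate, 0.03, rng)
            amps = rng.normal(0.9, 0.08, len(a_times))
            sigma_a = rng.uniform(0.008, 0.016) * morph.width_scale
        atrial = _place_spikes(n, a_times, amps, _spike_kernel(sigma_a))
        floor = 0.03 * morph.rel_amp_scale * (1.5 if af_mode else 1.0)
        atrial += rng.normal(0, floor, n).astype(np.float32)

        # irregular, slower ventricular response: thinned + jittered
        conduct = rng.uniform(0.2, 0.4)
        v_times = []
        last = -1.0
        for t in a_times:
            if rng.random() < conduct:
                vt = t + rng.uniform(0.12, 0.25)
                if vt - last >= 0.35 and vt < EPISODE_SECONDS:
                    v_times.append(vt)
                    last = vt
        v_times = np.array(v_times)
        ventricular = _place_spikes(
            n, v_times, rng.normal(1.0, 0.05, len(v_times)), _spike_kernel(sigma_a * 2.0)
        )
        ventricular += rng.normal(0, 0.03 * morph.rel_amp_scale, n).astype(np.float32)
        events += [(float(t), "A") for t in a_times]
        events += [(float(t), "V") for t in v_times]
        marker_times += list(a_times) + list(v_times)
        marker_kinds += ["TA"] * len(a_times) + ["Vs"] * len(v_times)
    else:  # pragma: no cover - Label() above already rejects unknown names
        raise ValueError(f"unknown label {label}")

    payload = preprocess(
        atrial,
        ventricular if with_ventricular else None,
        marker_times,
        FS,
        marker_kinds,
    )
    record = EpisodeRecord(
        episode_id=episode_id,
        patient_id=patient_id,
        center_id=center_id,
        label=label,
        **payload,
    )
    events.sort()
    return record, events


def _patient_class_counts(cfg: SimulationConfig, rng: np.random.Generator) -> dict[Label, int]:
    counts = {Label.ATAF: 1 + int(rng.negative_binomial(cfg.count_r, cfg.ataf_count_p))}
    if rng.random() < cfg.noise_patient_prevalence:
        counts[Label.NOISE] = 1 + int(rng.negative_binomial(cfg.count_r, cfg.noise_count_p))
    if rng.random() < cfg.ffo_patient_prevalence:
        counts[Label.FFO] = 1 + int(rng.negative_binomial(cfg.count_r, cfg.ffo_count_p))
    return counts


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[CohortManifest, dict[str, EventLog]]:
    """Generate a full multi-center cohort plus per-episode event logs.

    All randomness derives from ``config.seed`` through hierarchical
    per-center / per-patient / per-episode substreams, so cohorts are
    bit-reproducible and stable under appending centers. Sinus pretraining
    episodes are attributed to dedicated sinus-only patients of each center,
    which guarantees they never share a patient with validation or test
    AHREs.
    """
    config.validate()
    episodes: list[EpisodeRecord] = []
    patient_to_center: dict[str, str] = {}
    event_logs: dict[str, EventLog] = {}

    for ci, spec in enumerate(config.centers):
        center_rng = _substream(config.seed, ci)
        morph = _center_morphology(spec, center_rng)
        n_ahre_center = 0
        for pi in range(spec.n_patients):
            pid = f"{spec.center_id}-P{pi:03d}"
            patient_to_center[pid] = spec.center_id
            prng = _substream(config.seed, ci, pi)
            class_counts = _patient_class_counts(config, prng)
            ei = 0
            for label, count in class_counts.items():
                for _ in range(count):
                    erng = _substream(config.seed, ci, pi, ei)
                    with_v = not (
                        label in (Label.ATAF, Label.NOISE)
                        and erng.random() < config.no_ventricular_fraction
                    )
                    eid = f"{pid}-E{ei:03d}"
                    rec, ev = simulate_episode(
                        label,
                        morph,
                        erng,
                        episode_id=eid,
                        patient_id=pid,
                        center_id=spec.center_id,
                        with_ventricular=with_v,
                        hard_mode=config.hard_mode,
                    )
                    episodes.append(rec)
                    event_logs[eid] = ev
                    n_ahre_center += 1
                    ei += 1

        # sinus-only patients for the pretraining pool
        target_sinus = int(round(config.sinus_fraction * n_ahre_center))
        si = 0
        made = 0
        while made < target_sinus:
            pid = f"{spec.center_id}-S{si:03d}"
            patient_to_center[pid] = spec.center_id
            prng = _substream(config.seed, ci, 10_000 + si)
            count = min(1 + int(prng.negative_binomial(1, 0.2)), target_sinus - made)
            for ei in range(count):
                erng = _substream(config.seed, ci, 10_000 + si, ei)
                eid = f"{pid}-E{ei:03d}"
                rec, ev = simulate_episode(
                    Label.SINUS,
                    morph,
                    erng,
                    episode_id=eid,
                    patient_id=pid,
                    center_id=spec.center_id,
                )
                episodes.append(rec)
                event_logs[eid] = ev
            made += count
            si += 1

    if not episodes:
        raise ValueError("configuration produced zero episodes")
    manifest = CohortManifest(episodes, patient_to_center)
    manifest.validate()
    return manifest, event_logs


def save_event_logs(event_logs: dict[str, EventLog], path) -> None:
    """Ground-truth table: episode_id, event_time_s, event_kind (CSV)."""
    import pandas as pd

    rows = [
        {"episode_id": eid, "event_time_s": round(t, 6), "event_kind": kind}
        for eid, ev in event_logs.items()
        for t, kind in ev
    ]
    pd.DataFrame(rows, columns=["episode_id", "event_time_s", "event_kind"]).to_csv(
        path, index=False
    )
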