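"""Synthetic MEA recordings, patch-clamp fixtures, and hierarchical outcome tables.

The patient recordings behind the population results are not publicly
deposited, so this module generates stand-ins with known ground truth that
emulate their statistical structure:

* spatially contiguous ictal-like event (ILE) sources on the 8x8 grid, each a
  smooth electrode weight map times a source trace;
* ILE traces with large-amplitude preictal discharges, an onset segment that is
  either low-voltage fast (LVF: a low-amplitude 10-20 Hz oscillation) or
  hypersynchronous (initial discharges about twice the train amplitude),
  followed by a within-event discharge train at the planted rate;
* isolated interictal-like discharges (IILDs) on their own sources;
* 1/f (pink) plus white background noise per channel;
* baseline / treatment / washout epochs with planted per-epoch effect
  multipliers;
* patch-clamp fixtures (I-V point sets, capacitive transients, holding-current
  trace pairs) with closed-form ground truth;
* patient-nested outcome tables with random intercepts for the mixed-model
  layer.

Default planted rates are the study-scale population means for slices with
activity: 8.9 ILEs per 20 min, 22.6 s mean duration, 3.1 discharges/s within
ILEs, a spatial spread of about 21 electrodes.  All generators are
deterministic given a seed.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ictalmea.errors import ConfigError
from ictalmea.ephys import IVCurve
from ictalmea.mea_io import ElectrodeLayout, Recording


@dataclass
class EventRates:
    """Planted per-source event statistics (per 20-min window where rate-like)."""

    ile_per_20min: float = 8.9
    ile_duration_s: float = 22.6
    discharge_rate_hz: float = 3.1
    iild_rate_hz: float = 0.0
    n_active_electrodes: int = 21

    def __post_init__(self) -> None:
        for name in ("ile_per_20min", "ile_duration_s", "discharge_rate_hz", "iild_rate_hz"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


@dataclass
class EffectMultipliers:
    """Per-epoch multipliers applied to the planted rates (1.0 = no change)."""

    ile_count: float = 1.0
    ile_duration: float = 1.0
    discharge_rate: float = 1.0
    extent: float = 1.0
    iild_rate: float = 1.0


@dataclass
class NoiseConfig:
    """Per-channel background noise: independent pink (1/f) plus white, in uV."""

    pink_sd_uV: float = 8.0
    white_sd_uV: float = 6.0


@dataclass
class RecordingConfig:
    """Everything needed to synthesize one slice recording."""

    fs_hz: float = 10_000.0
    epochs: list[tuple[str, float, float]] = field(default_factory=lambda: [("baseline", 0.0, 1200.0)])
    rates: EventRates = field(default_factory=EventRates)
    effects: dict[str, EffectMultipliers] = field(default_factory=dict)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    n_sources: int = 1
    n_iild_sources: int = 0
    discharge_amp_uV: float = 500.0
    discharge_width_s: float = 0.05
    preictal_amp_factor: float = 2.0
    lvf_fraction: float = 0.56
    lvf_onset_s: float = 2.3
    lvf_osc_hz: float = 15.0
    lvf_osc_amp_uV: float = 15.0
    duration_jitter_frac: float = 0.1
    min_event_gap_s: float = 30.0

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ConfigError("at least one epoch required")
        for _, start, end in self.epochs:
            if end - start <= 0:
                raise ConfigError("epoch durations must be > 0")
        if not 0.0 <= self.lvf_fraction <= 1.0:
            raise ConfigError("lvf_fraction must be in [0, 1]")


@dataclass
class PlantedEvent:
    """Ground-truth record of one planted event."""

    source: int
    kind: str  # ILE | IILD
    epoch: str
    start_s: float
    end_s: float
    discharge_times_s: np.ndarray
    onset_class: str  # LVF | hypersynchronous | unclassified
    preictal_times_s: np.ndarray


@dataclass
class GroundTruth:
    """Planted sources, events, rates, and effects for one synthetic recording."""

    source_maps: list[np.ndarray]
    epoch_maps: dict
    event_times: list[PlantedEvent]
    planted_rates: dict
    effect: dict
    seed: int

    def events_for(self, source: int | None = None, epoch: str | None = None, kind: str | None = None):
        out = self.event_times
        if source is not None:
            out = [e for e in out if e.source == source]
        if epoch is not None:
            out = [e for e in out if e.epoch == epoch]
        if kind is not None:
            out = [e for e in out if e.kind == kind]
        return out


# ---------------------------------------------------------------------------
# spatial maps

_SOURCE_CENTERS = [(2, 2), (5, 5), (2, 5), (5, 2), (4, 3), (3, 4)]


def _grid_adjacency(positions: list[tuple[int, int]]) -> dict[int, list[int]]:
    index = {p: i for i, p in enumerate(positions)}
    adj: dict[int, list[int]] = {i: [] for i in range(len(positions))}
    for p, i in index.items():
        r, c = p
        for q in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if q in index:
                adj[i].append(index[q])
    return adj


def _patch_map(layout: ElectrodeLayout, center: tuple[int, int], n_active: int, rng: np.random.Generator) -> np.ndarray:
    """Contiguous electrode patch grown breadth-first from ``center``.

    Weights fall off smoothly with BFS depth from 1.0 at the centre to 0.25 at
    the rim (all >= the default 0.2 spatial-map threshold), max-normalized.
    """
    positions = layout.recording_positions
    index = {p: i for i, p in enumerate(positions)}
    if center not in index:
        center = min(index, key=lambda p: abs(p[0] - center[0]) + abs(p[1] - center[1]))
    adj = _grid_adjacency(positions)
    n_active = min(n_active, len(positions))
    start = index[center]
    depth = {start: 0}
    order = [start]
    queue = deque([start])
    while queue and len(order) < len(positions):
        cur = queue.popleft()
        neighbours = sorted(adj[cur])
        for nb in neighbours:
            if nb not in depth:
                depth[nb] = depth[cur] + 1
                order.append(nb)
                queue.append(nb)
    chosen = order[:n_active]
    weights = np.zeros(len(positions))
    max_depth = max(depth[i] for i in chosen) if len(chosen) > 1 else 1
    for i in chosen:
        weights[i] = 1.0 - 0.75 * (depth[i] / max(max_depth, 1))
    return weights


# ---------------------------------------------------------------------------
# waveforms and noise

def _discharge_waveform(fs: float, width_s: float) -> np.ndarray:
    """Biphasic sharp transient, main deflection negative, peak amplitude 1."""
    n = max(int(round(width_s * fs)), 4)
    t = np.arange(n) / n
    shape = -np.sin(2 * np.pi * t) * np.hanning(n)
    return shape / np.max(np.abs(shape))


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD 1/f noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    spec *= scale
    out = np.fft.irfft(spec, n=n)
    sd = out.std()
    return out / sd if sd > 0 else out


# ---------------------------------------------------------------------------
# event schedules

def _shifted_exp_isis(rate_hz: float, t_min: float, total_s: float, rng: np.random.Generator) -> np.ndarray:
    """Arrival times of a renewal train with mean rate ``rate_hz`` and a hard
    minimum interval ``t_min`` (shifted-exponential ISIs keep the mean exact)."""
    if rate_hz <= 0:
        return np.array([])
    mean_isi = 1.0 / rate_hz
    if mean_isi <= t_min:
        raise ConfigError(f"rate {rate_hz} Hz incompatible with minimum interval {t_min} s")
    times = []
    t = 0.0
    while True:
        t += t_min + rng.exponential(mean_isi - t_min) if times else 0.0
        if t >= total_s:
            break
        times.append(t)
    return np.asarray(times)


def _schedule_ile_events(
    cfg: RecordingConfig,
    epoch: tuple[str, float, float],
    source: int,
    eff: EffectMultipliers,
    rng: np.random.Generator,
) -> list[PlantedEvent]:
    label, ep_start, ep_end = epoch
    ep_len = ep_end - ep_start
    rate = cfg.rates.ile_per_20min * eff.ile_count
    count = int(round(rate * ep_len / 1200.0))
    if count == 0:
        return []
    mean_dur = cfg.rates.ile_duration_s * eff.ile_duration
    if count * (mean_dur * (1 + cfg.duration_jitter_frac) + cfg.min_event_gap_s) > ep_len:
        raise ConfigError(
            f"epoch '{label}' ({ep_len:.0f} s) cannot hold {count} events of ~{mean_dur:.0f} s "
            f"with {cfg.min_event_gap_s:.0f} s gaps"
        )
    slot = ep_len / count
    events = []
    for k in range(count):
        dur = mean_dur * (1.0 + cfg.duration_jitter_frac * rng.uniform(-1, 1))
        # stagger multiple sources within the slot so their events do not overlap
        frac = (source + 1) / (cfg.n_sources + 1)
        onset = ep_start + slot * (k + frac) - dur / 2 + rng.uniform(-0.03, 0.03) * slot
        onset = float(np.clip(onset, ep_start + 14.0, ep_end - dur - 6.0))
        is_lvf = rng.uniform() < cfg.lvf_fraction
        rate_hz = cfg.rates.discharge_rate_hz * eff.discharge_rate
        if is_lvf:
            train_offset = cfg.lvf_onset_s
            markers = np.array([0.05, 1.0])
            train = train_offset + _shifted_exp_isis(rate_hz, 0.12, dur - train_offset, rng)
            discharges = np.concatenate([markers, train])
            onset_class = "LVF"
        else:
            discharges = _shifted_exp_isis(rate_hz, 0.12, dur, rng)
            onset_class = "hypersynchronous"
        preictal = onset - np.array([12.0, 8.5, 5.0])
        preictal = preictal[preictal >= ep_start + 1.0]
        events.append(
            PlantedEvent(
                source=source,
                kind="ILE",
                epoch=label,
                start_s=onset,
                end_s=onset + dur,
                discharge_times_s=onset + discharges,
                onset_class=onset_class,
                preictal_times_s=preictal,
            )
        )
    # drop preictal discharges that collide with the previous event
    for prev, nxt in zip(events, events[1:]):
        nxt.preictal_times_s = nxt.preictal_times_s[nxt.preictal_times_s >= prev.end_s + 5.0]
    return events


def _schedule_iild_events(
    cfg: RecordingConfig,
    epoch: tuple[str, float, float],
    source: int,
    eff: EffectMultipliers,
    rng: np.random.Generator,
) -> list[PlantedEvent]:
    label, ep_start, ep_end = epoch
    rate = cfg.rates.iild_rate_hz * eff.iild_rate
    if rate <= 0:
        return []
    # a 3 s floor keeps single discharges from chaining into burst-like groups
    times = ep_start + _shifted_exp_isis(rate, 3.0, ep_end - ep_start - 2.0, rng) + 1.0
    half = cfg.discharge_width_s / 2
    return [
        PlantedEvent(
            source=source,
            kind="IILD",
            epoch=label,
            start_s=float(t - half),
            end_s=float(t + half),
            discharge_times_s=np.array([t]),
            onset_class="unclassified",
            preictal_times_s=np.array([]),
        )
        for t in times
    ]


# ---------------------------------------------------------------------------
# recording synthesis

def _render_source_trace(cfg: RecordingConfig, events: list[PlantedEvent], n_samples: int, fs: float,
                         rng: np.random.Generator) -> np.ndarray:
    trace = np.zeros(n_samples)
    wave = _discharge_waveform(fs, cfg.discharge_width_s)
    nw = wave.size
    amp = cfg.discharge_amp_uV

    def add_spike(t: float, a: float) -> None:
        i0 = int(round(t * fs))
        if 0 <= i0 and i0 + nw <= n_samples:
            trace[i0 : i0 + nw] += a * wave

    for ev in events:
        for t in ev.preictal_times_s:
            add_spike(t, amp * cfg.preictal_amp_factor)
        if ev.kind == "ILE" and ev.onset_class == "hypersynchronous":
            for t in ev.discharge_times_s:
                a = amp * 2.0 if (t - ev.start_s) < 2.0 else amp
                add_spike(t, a)
        elif ev.kind == "ILE":  # LVF
            rel = ev.discharge_times_s - ev.start_s
            for t, r in zip(ev.discharge_times_s, rel):
                # onset markers are small threshold-crossing discharges
                a = amp * 0.25 if r < cfg.lvf_onset_s else amp
                add_spike(t, a)
            osc_start = int(round(ev.start_s * fs))
            osc_end = int(round((ev.start_s + cfg.lvf_onset_s - 0.1) * fs))
            osc_end = min(osc_end, n_samples)
            if osc_end > osc_start:
                tt = np.arange(osc_end - osc_start) / fs
                ramp = np.minimum(1.0, tt / 0.2)
                trace[osc_start:osc_end] += cfg.lvf_osc_amp_uV * ramp * np.sin(
                    2 * np.pi * cfg.lvf_osc_hz * tt + rng.uniform(0, 2 * np.pi)
                )
        else:  # IILD
            add_spike(float(ev.discharge_times_s[0] - cfg.discharge_width_s / 2), amp)
    return trace


def generate_recording(config: RecordingConfig, seed: int = 0) -> tuple[Recording, GroundTruth]:
    """Synthesize one MEA recording plus its ground truth.

    The recorded signal is the sum over sources of (electrode map) x (source
    trace) plus per-channel pink+white noise.  Event schedules, onset classes,
    maps, and noise all derive from a single seeded generator, so identical
    (config, seed) pairs give bit-identical recordings.
    """
    rng = np.random.default_rng(seed)
    layout = ElectrodeLayout.default()
    n_ch = layout.n_recording
    t_end = max(end for _, _, end in config.epochs)
    n_samples = int(round(t_end * config.fs_hz))
    fs = config.fs_hz

    effects = {label: config.effects.get(label, EffectMultipliers()) for label, _, _ in config.epochs}

    all_events: list[PlantedEvent] = []
    n_total_sources = config.n_sources + config.n_iild_sources
    source_events: list[list[PlantedEvent]] = [[] for _ in range(n_total_sources)]
    for src in range(config.n_sources):
        for epoch in config.epochs:
            evs = _schedule_ile_events(config, epoch, src, effects[epoch[0]], rng)
            source_events[src].extend(evs)
            all_events.extend(evs)
    for j in range(config.n_iild_sources):
        src = config.n_sources + j
        for epoch in config.epochs:
            evs = _schedule_iild_events(config, epoch, src, effects[epoch[0]], rng)
            source_events[src].extend(evs)
            all_events.extend(evs)

    # per-source, per-epoch spatial maps (extent may change between epochs)
    base_maps: list[np.ndarray] = []
    epoch_maps: dict[tuple[int, str], np.ndarray] = {}
    for src in range(n_total_sources):
        center = _SOURCE_CENTERS[src % len(_SOURCE_CENTERS)]
        n_act = config.rates.n_active_electrodes if src < config.n_sources else max(
            4, config.rates.n_active_electrodes // 2
        )
        base_maps.append(_patch_map(layout, center, n_act, rng))
        for label, _, _ in config.epochs:
            mult = effects[label].extent
            n_eff = int(round(n_act * mult))
            epoch_maps[(src, label)] = (
                base_maps[src]
                if n_eff == n_act
                else _patch_map(layout, center, max(n_eff, 1), rng)
            )

    data = np.zeros((n_ch, n_samples), dtype=np.float32)
    for ch in range(n_ch):
        noise = config.noise.pink_sd_uV * _pink_noise(n_samples, rng)
        noise += config.noise.white_sd_uV * rng.standard_normal(n_samples)
        data[ch] = noise.astype(np.float32)

    for src in range(n_total_sources):
        if not source_events[src]:
            continue
        for label, ep_start, ep_end in config.epochs:
            evs = [e for e in source_events[src] if e.epoch == label]
            if not evs:
                continue
            trace = _render_source_trace(config, evs, n_samples, fs, rng)
            w = epoch_maps[(src, label)]
            i0, i1 = int(round(ep_start * fs)), int(round(ep_end * fs))
            seg = trace[i0:i1]
            active = np.flatnonzero(w)
            for ch in active:
                data[ch, i0:i1] += (w[ch] * seg).astype(np.float32)

    rec = Recording(
        data=data,
        fs_hz=fs,
        layout=layout,
        condition={"mg_mM": 0.0, "k_mM": 6.0, "drug_name": "", "drug_conc_uM": 0.0},
        epochs=list(config.epochs),
    )
    truth = GroundTruth(
        source_maps=base_maps,
        epoch_maps=epoch_maps,
        event_times=sorted(all_events, key=lambda e: (e.source, e.start_s)),
        planted_rates=asdict(config.rates),
        effect={k: asdict(v) for k, v in effects.items()},
        seed=seed,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# patch-clamp fixtures

@dataclass
class PatchConfig:
    """Ground truth for synthetic patch-clamp fixtures."""

    e_true_mV: float = -60.0
    slope_nS: float = 1.0
    iv_noise_sd_pA: float = 0.0
    voltages_mV: tuple = (-80.0, -70.0, -60.0, -50.0, -40.0)
    rs_MOhm: float = 10.0
    cap_pF: float = 150.0
    step_mV: float = -10.0
    fs_hz: float = 10_000.0
    tonic_shift_pA: float = 30.0
    hold_level_pA: float = -200.0
    hold_noise_sd_pA: float = 5.0
    hold_duration_s: float = 12.0
    synaptic_rate_hz: float = 0.0
    synaptic_amp_pA: float = -60.0
    synaptic_tau_s: float = 0.02

    def __post_init__(self) -> None:
        if self.slope_nS <= 0 or self.cap_pF <= 0 or self.rs_MOhm <= 0:
            raise ConfigError("conductance, capacitance, and series resistance must be > 0")


def _holding_trace(level_pA: float, cfg: PatchConfig, rng: np.random.Generator) -> np.ndarray:
    n = int(round(cfg.hold_duration_s * cfg.fs_hz))
    trace = level_pA + cfg.hold_noise_sd_pA * rng.standard_normal(n)
    if cfg.synaptic_rate_hz > 0:
        n_events = rng.poisson(cfg.synaptic_rate_hz * cfg.hold_duration_s)
        kernel_t = np.arange(int(5 * cfg.synaptic_tau_s * cfg.fs_hz)) / cfg.fs_hz
        kernel = cfg.synaptic_amp_pA * np.exp(-kernel_t / cfg.synaptic_tau_s)
        for t0 in rng.uniform(0, cfg.hold_duration_s, size=n_events):
            i0 = int(t0 * cfg.fs_hz)
            i1 = min(i0 + kernel.size, n)
            trace[i0:i1] += kernel[: i1 - i0] * rng.uniform(0.5, 1.5)
    return trace


def generate_patch_fixtures(config: PatchConfig | None = None, seed: int = 0) -> dict:
    """I-V points, an RC capacitive transient, and a holding-current trace pair.

    I-V points follow I = g (V - E_true) + noise; the transient is the ideal
    series-RC response to the configured voltage step (peak dV/Rs, time
    constant Rs*C); the holding traces differ by the planted tonic shift plus
    optional superimposed synaptic-event deflections.
    """
    cfg = config or PatchConfig()
    rng = np.random.default_rng(seed)
    v = np.asarray(cfg.voltages_mV, dtype=float)
    i = cfg.slope_nS * (v - cfg.e_true_mV) + cfg.iv_noise_sd_pA * rng.standard_normal(v.size)
    iv = IVCurve(points=list(zip(v.tolist(), i.tolist())))

    tau_s = cfg.rs_MOhm * cfg.cap_pF * 1e-6  # MOhm * pF = us
    n = max(int(round(10 * tau_s * cfg.fs_hz)), 64)
    t = np.arange(n) / cfg.fs_hz
    i_peak_pA = cfg.step_mV / cfg.rs_MOhm * 1000.0
    transient = i_peak_pA * np.exp(-t / tau_s)

    before = _holding_trace(cfg.hold_level_pA, cfg, rng)
    during = _holding_trace(cfg.hold_level_pA + cfg.tonic_shift_pA, cfg, rng)

    return {
        "iv": iv,
        "transient_pA": transient,
        "holding_before_pA": before,
        "holding_during_pA": during,
        "truth": asdict(cfg),
    }


# ---------------------------------------------------------------------------
# hierarchical outcome tables

def generate_hierarchical_dataset(
    n_patients: int,
    units_per_patient: int,
    true_effect: float,
    between_sd: float,
    within_sd: float,
    alpha: float = 10.0,
    baseline_model: str = "continuous",
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Patient-nested paired outcome table with a planted treatment effect.

    y_ij(period) = alpha + beta * post + b_i + eps_ij with b_i ~ N(0, between_sd^2)
    and eps ~ N(0, within_sd^2).  The baseline covariate of each unit is its
    baseline-period outcome.  Returns the long-format table and a ground-truth
    dict including the closed-form ICC between_sd^2 / (between_sd^2 + within_sd^2).
    """
    if n_patients < 2:
        raise ConfigError("need >= 2 patients")
    if between_sd < 0 or within_sd < 0:
        raise ConfigError("standard deviations must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_patients):
        b_i = rng.normal(0.0, between_sd)
        for u in range(units_per_patient):
            base = alpha + b_i + rng.normal(0.0, within_sd)
            post = alpha + true_effect + b_i + rng.normal(0.0, within_sd)
            unit = f"p{p:03d}_u{u:02d}"
            rows.append((f"p{p:03d}", unit, "baseline", base, base))
            rows.append((f"p{p:03d}", unit, "treatment", post, base))
    df = pd.DataFrame(rows, columns=["patient_id", "unit_id", "period", "outcome", "baseline_covariate"])
    if baseline_model == "binary":
        df["baseline_covariate"] = (df["baseline_covariate"] > 0).astype(float)
    denom = between_sd**2 + within_sd**2
    truth = {
        "beta": true_effect,
        "alpha": alpha,
        "between_sd": between_sd,
        "within_sd": within_sd,
        "icc": between_sd**2 / denom if denom > 0 else 0.0,
        "seed": seed,
    }
    return df, truth
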