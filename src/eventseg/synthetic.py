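"""Generative simulator: multichannel EEG/EOG and behavior with planted effects.

Every downstream analysis in this package is validated by parameter recovery
against this simulator. A session is a continuous 64+4 channel recording at
``sfreq`` Hz containing, per stimulus trial (1.25 s stimulus-onset asynchrony):

* 1/f^beta background noise and common-phase line noise,
* a condition-dependent P300-like evoked deflection (Gaussian bump, default
  peak 350 ms, SD 50 ms) with a parietal spatial profile centered on Pz,
* a community-specific oscillatory "template": amplitude-modulated narrowband
  activity (default 5-7 Hz theta) with a fixed, posterior-weighted channel
  gain pattern per community, keyed to the *displayed* stimulus's community,
* predictive mixing at boundary-node trials: the adjacent community's
  template added with weight alpha(run) = alpha0 + alpha1 * run_length from
  ``mix_onset_s`` onward,
* blink artifacts coupled from the EOG channels into frontal electrodes, and
  rare high-amplitude spikes for artifact-rejection testing.

All injected events are logged in ``SimulatedSession.ground_truth`` so tests
can compare detector output against the generator's bookkeeping. Behavioral
responses (parsing decisions and RTs, rotation-task responses, posttest
answers) are simulated from per-condition rates configured in
:class:`GenerativeSpec`. Default behavioral rates are set to the observed
group means of the paradigm (parse probabilities 18.3/19.0/14.0 % and parse
RTs 690/648/631 ms for novel/learned/nonboundary; rotation hit/false-alarm
rates giving d-prime near 2; posttest accuracy 65.6 %). Neural effect sizes
have no empirical anchors and are chosen for recoverability at small
simulated samples; they are ground truth knobs, not estimates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats

from . import montage
from .graph_sequences import (
    LEARNED,
    NONBOUNDARY,
    NOVEL,
    STIMULUS_DURATION_S,
    CommunityGraph,
    write_events_tsv,
)

CONDITIONS = (NOVEL, LEARNED, NONBOUNDARY)


class GenerativeSpec(BaseModel):
    """All planted-effect parameters of the simulator (the ground truth)."""

    model_config = ConfigDict(extra="forbid")

    # --- recording geometry ---
    sfreq: float = 250.0
    montage_name: str = "biosemi64"

    # --- evoked (P300-like) component, µV at the center electrode ---
    p300_amp: dict[str, float] = Field(
        default_factory=lambda: {NOVEL: 3.0, LEARNED: 5.0, NONBOUNDARY: 2.0}
    )
    p300_latency_s: float = 0.35
    p300_width_s: float = 0.05
    p300_center: str = "Pz"
    p300_sigma_m: float = 0.06

    # --- community oscillatory templates ---
    template_gain: float = 4.0  # µV narrowband amplitude at unit channel gain
    template_band_hz: tuple[float, float] = (5.0, 7.0)
    template_seed: int = 20240 # fixes the per-community channel gain patterns
    item_level_templates: bool = False  # per-node rather than per-community code

    # --- predictive mixing at boundary nodes ---
    predictive_alpha0: float = 0.0
    predictive_alpha1: float = 0.25
    mix_onset_s: float = 0.25
    mix_preboundary: bool = False

    # --- noise and artifacts ---
    noise_beta: float = 1.0
    noise_scale: float = 10.0     # µV RMS broadband background
    line_freq: float = 60.0
    line_amp: float = 1.0         # µV
    blink_rate_hz: float = 0.05
    blink_amp: float = 120.0      # µV at the vertical EOG
    spike_rate: float = 0.02      # per-trial probability
    spike_amp: float = 350.0      # µV, exceeds the ±250 µV rejection criterion

    # --- behavior ---
    parse_prob: dict[str, float] = Field(
        default_factory=lambda: {NOVEL: 0.183, LEARNED: 0.190, NONBOUNDARY: 0.140}
    )
    rt_mean_ms: dict[str, float] = Field(
        default_factory=lambda: {NOVEL: 690.0, LEARNED: 648.0, NONBOUNDARY: 631.0}
    )
    rt_sd_ms: float = 150.0
    rt_min_ms: float = 150.0
    rt_max_ms: float = 1250.0
    rotation_hit: float = 0.85
    rotation_fa: float = 0.15
    rotation_rt_mean_ms: dict[str, float] = Field(
        default_factory=lambda: {LEARNED: 676.0, NONBOUNDARY: 665.0}
    )
    posttest_acc: float = 0.656
    response_mode: Literal["every_trial", "parse_only"] = "every_trial"

    @model_validator(mode="after")
    def _check_invariants(self):
        for name in ("parse_prob",):
            for k, v in getattr(self, name).items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{name}[{k}]={v} outside [0, 1]")
        for name in ("rotation_hit", "rotation_fa", "posttest_acc",
                     "predictive_alpha0", "spike_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("template_gain", "noise_scale", "line_amp", "blink_amp",
                     "spike_amp", "blink_rate_hz", "predictive_alpha1",
                     "p300_width_s", "rt_sd_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (self.template_band_hz[0] < self.template_band_hz[1]):
            raise ValueError("template_band_hz must be (low, high) with low < high")
        for k, v in self.p300_amp.items():
            if v < 0:
                raise ValueError(f"p300_amp[{k}]={v} must be >= 0")
        return self

    def mix_alpha(self, run_length: np.ndarray | float) -> np.ndarray | float:
        """Predictive mixing weight alpha(run), clipped to [0, 1]."""
        return np.clip(
            self.predictive_alpha0 + self.predictive_alpha1 * run_length, 0.0, 1.0
        )

    def community_templates(self, n_patterns: int = 3) -> np.ndarray:
        """Fixed channel-gain patterns, one per community (rows), max gain 1.

        Gains are posterior-weighted (larger at electrodes with y <= 0) so the
        planted spectral structure is strongest over parietal/occipital sites.
        """
        rng = np.random.default_rng(self.template_seed)
        chans = montage.scalp_channels(self.montage_name)
        pos = montage.channel_positions(self.montage_name)
        y = np.array([pos[ch][1] for ch in chans])
        posterior = np.where(y <= 0.0, 1.0, 0.25)
        pats = []
        for _ in range(n_patterns):
            g = posterior * rng.uniform(0.2, 1.0, size=len(chans))
            pats.append(g / g.max())
        return np.asarray(pats)


@dataclass
class SimulatedSession:
    """One simulated participant-session of continuous data plus metadata."""

    data: np.ndarray              # (n_channels, n_samples), µV
    sfreq: float
    ch_names: list[str]
    onsets: np.ndarray            # stimulus-onset sample indices
    trials: pd.DataFrame
    spec: GenerativeSpec
    ground_truth: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def save(self, outdir) -> None:
        """Write the recording as an .npz array container with sidecars."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            out / "continuous.npz",
            data=self.data.astype(np.float32),
            onsets=self.onsets,
        )
        meta = {
            "sfreq": self.sfreq,
            "ch_names": self.ch_names,
            "units": "microvolts",
            "spec": self.spec.model_dump(),
            "ground_truth": _jsonable(self.ground_truth),
        }
        (out / "continuous.json").write_text(json.dumps(meta, indent=1))
        write_events_tsv(self.trials, out / "events.tsv")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# Signal generators
# ---------------------------------------------------------------------------

def one_over_f_noise(
    n_channels: int, n_samples: int, beta: float, scale: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian noise with a 1/f^beta power spectrum, unit-free RMS = scale."""
    if scale == 0 or n_samples == 0:
        return np.zeros((n_channels, n_samples))
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_samples)
    shaping = np.zeros_like(f)
    shaping[1:] = f[1:] ** (-beta / 2.0)
    x = np.fft.irfft(spec * shaping, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd * scale


def narrowband_burst(
    n_samples: int, sfreq: float, band: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Amplitude-modulated narrowband noise, RMS 1 (not a pure sinusoid)."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n_samples, 1.0 / sfreq)
    mask = ((f >= band[0]) & (f <= band[1])).astype(float)
    x = np.fft.irfft(spec * mask, n=n_samples)
    sd = x.std()
    return x / sd if sd > 0 else x


def _blink_waveform(sfreq: float, dur_s: float = 0.3) -> np.ndarray:
    n = max(int(round(dur_s * sfreq)), 3)
    return np.hanning(n)


def preceding_run_length(communities: np.ndarray) -> np.ndarray:
    """Trials spent in one community before each trial.

    For trial i this is the length of the consecutive same-community run
    ending at trial i-1 (0 for the first trial). Boundary-node visits are
    typically still inside their community's run, so for them this counts the
    time already spent in the community before the boundary stimulus appears.
    """
    n = len(communities)
    run = np.zeros(n, dtype=int)
    run_end = np.ones(n, dtype=int)  # run length of the streak ending at i
    for i in range(1, n):
        run_end[i] = run_end[i - 1] + 1 if communities[i] == communities[i - 1] else 1
    run[1:] = run_end[:-1]
    return run


def simulate_session(
    trials: pd.DataFrame,
    spec: GenerativeSpec,
    seed: int | np.random.Generator | None,
    graph: CommunityGraph | None = None,
    pad_s: float = 2.0,
) -> SimulatedSession:
    """Render a labeled trial table into a continuous EEG/EOG recording."""
    rng = np.random.default_rng(seed)
    trials = trials.reset_index(drop=True).copy()
    n_trials = len(trials)
    scalp = montage.scalp_channels(spec.montage_name)
    ch_names = scalp + montage.EOG_CHANNELS
    n_scalp = len(scalp)
    n_ch = len(ch_names)
    sfreq = spec.sfreq
    trial_len = int(round(STIMULUS_DURATION_S * sfreq))
    pad = int(round(pad_s * sfreq))
    n_samples = n_trials * trial_len + 2 * pad
    onsets = pad + np.arange(n_trials) * trial_len

    data = one_over_f_noise(n_ch, n_samples, spec.noise_beta, spec.noise_scale, rng)

    t = np.arange(n_samples) / sfreq
    if spec.line_amp > 0:
        line = spec.line_amp * np.sin(
            2 * np.pi * spec.line_freq * t + rng.uniform(0, 2 * np.pi)
        )
        data[:n_scalp] += line[None, :]

    gt: dict = {}

    # ----- evoked P300-like component -----
    cond = trials["transition_label"].replace("", NONBOUNDARY)
    amps = cond.map(lambda c: spec.p300_amp.get(c, 0.0)).to_numpy(float)
    tt = np.arange(trial_len) / sfreq
    bump = np.exp(-((tt - spec.p300_latency_s) ** 2) / (2 * spec.p300_width_s ** 2))
    topo = montage.spatial_weights(
        spec.p300_center, spec.p300_sigma_m, spec.montage_name
    )
    if np.any(amps != 0):
        for i, a in enumerate(amps):
            if a:
                sl = slice(onsets[i], onsets[i] + trial_len)
                data[:n_scalp, sl] += a * np.outer(topo, bump)
    gt["p300_amp_per_trial"] = amps
    gt["condition_per_trial"] = cond.to_numpy()

    # ----- community templates and predictive mixing -----
    if graph is not None:
        node_to_comm = {n: graph.community(n) for n in graph.nodes}
        stim_to_node = {v: k for k, v in graph.stimulus.items()}
        node_comm = trials["node"].map(node_to_comm).to_numpy()
        stim_comm = trials["stimulus"].map(
            lambda s: node_to_comm[stim_to_node[s]]
        ).to_numpy()
        is_boundary = trials["node"].map(
            lambda n: graph.role(n) == "boundary"
        ).to_numpy()
        adj_comm = trials["node"].map(
            lambda n: node_to_comm[graph.external_neighbor(n)]
            if graph.role(n) == "boundary" else 0
        ).to_numpy()
        run_len = preceding_run_length(node_comm)
        pre_boundary = np.zeros(n_trials, dtype=bool)
        pre_boundary[:-1] = is_boundary[1:] & ~is_boundary[:-1]

        if spec.item_level_templates:
            nodes = list(graph.nodes)
            templates = spec.community_templates(n_patterns=len(nodes))
            node_index = {n: i for i, n in enumerate(nodes)}
            trial_pattern = trials["stimulus"].map(
                lambda s: node_index[stim_to_node[s]]
            ).to_numpy()
            comm_of_pattern = None
        else:
            templates = spec.community_templates()
            trial_pattern = stim_comm - 1
            comm_of_pattern = templates

        alphas = np.zeros(n_trials)
        mix_start = int(round(spec.mix_onset_s * sfreq))
        if spec.template_gain > 0:
            for i in range(n_trials):
                sl = slice(onsets[i], onsets[i] + trial_len)
                burst = narrowband_burst(trial_len, sfreq, spec.template_band_hz, rng)
                data[:n_scalp, sl] += spec.template_gain * np.outer(
                    templates[trial_pattern[i]], burst
                )
                mix_here = (is_boundary[i] or (spec.mix_preboundary and pre_boundary[i]))
                if mix_here and not spec.item_level_templates:
                    a = float(spec.mix_alpha(run_len[i]))
                    if a > 0:
                        target = adj_comm[i] if is_boundary[i] else (
                            node_to_comm[graph.external_neighbor(
                                trials["node"].iloc[i + 1])]
                        )
                        burst2 = narrowband_burst(
                            trial_len, sfreq, spec.template_band_hz, rng
                        )
                        mix = spec.template_gain * np.outer(
                            templates[target - 1], burst2
                        )
                        mix[:, :mix_start] = 0.0
                        data[:n_scalp, sl] += a * mix
                        alphas[i] = a
        gt["alpha_per_trial"] = alphas
        gt["run_length_per_trial"] = run_len
        gt["template_index_per_trial"] = trial_pattern
        gt["templates"] = templates
        gt["is_boundary_node"] = is_boundary
        gt["adjacent_community"] = adj_comm

    # ----- blinks -----
    blink_times: list[float] = []
    if spec.blink_rate_hz > 0 and spec.blink_amp > 0:
        n_blinks = rng.poisson(spec.blink_rate_hz * n_samples / sfreq)
        wave = _blink_waveform(sfreq)
        pos = montage.channel_positions(spec.montage_name)
        frontal = np.array([max(pos[ch][1], 0.0) for ch in scalp])
        frontal = (frontal / frontal.max()) ** 2 * 0.5  # strongest at Fp sites
        veog = [ch_names.index("LVEOG"), ch_names.index("RVEOG")]
        heog = [ch_names.index("LHEOG"), ch_names.index("RHEOG")]
        for _ in range(n_blinks):
            s0 = rng.integers(0, n_samples - len(wave))
            blink_times.append(s0 / sfreq)
            seg = slice(s0, s0 + len(wave))
            for ix in veog:
                data[ix, seg] += spec.blink_amp * wave
            for ix in heog:
                data[ix, seg] += 0.2 * spec.blink_amp * wave
            data[:n_scalp, seg] += spec.blink_amp * np.outer(frontal, wave)
    gt["blink_times_s"] = np.asarray(sorted(blink_times))

    # ----- spikes -----
    spike_trials: list[int] = []
    if spec.spike_rate > 0 and spec.spike_amp > 0:
        hit = rng.random(n_trials) < spec.spike_rate
        pulse = np.hanning(max(int(round(0.03 * sfreq)), 3))
        # spikes land inside the analyzed 0..1 s epoch span so the logged
        # trial indices are recoverable by the epoch-level detector
        span = min(trial_len, int(round(1.0 * sfreq))) - len(pulse)
        for i in np.flatnonzero(hit):
            ch = rng.integers(n_scalp)
            s0 = onsets[i] + rng.integers(0, span)
            sign = 1 if rng.random() < 0.5 else -1
            data[ch, s0 : s0 + len(pulse)] += sign * spec.spike_amp * pulse
            spike_trials.append(int(i))
    gt["spike_trials"] = np.asarray(spike_trials, dtype=int)

    return SimulatedSession(
        data=data,
        sfreq=sfreq,
        ch_names=ch_names,
        onsets=onsets,
        trials=trials,
        spec=spec,
        ground_truth=gt,
    )


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------

def _truncnorm_ms(
    mean: np.ndarray, sd: float, lo: float, hi: float, rng: np.random.Generator
) -> np.ndarray:
    mean = np.asarray(mean, float)
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng)


def simulate_behavior(
    trials: pd.DataFrame,
    spec: GenerativeSpec,
    seed: int | np.random.Generator | None,
) -> pd.DataFrame:
    """Per-trial behavioral responses for an exposure or parsing sequence.

    Parsing phase: a Bernoulli parse decision per trial with a
    condition-specific probability, plus a truncated-normal RT (all trials in
    ``every_trial`` response mode; parse trials only in ``parse_only`` mode).
    Exposure phase: rotation-task responses from hit/false-alarm rates and
    condition-specific RTs.
    """
    rng = np.random.default_rng(seed)
    df = trials.reset_index(drop=True).copy()
    cond = df["transition_label"].replace("", NONBOUNDARY)
    out = pd.DataFrame({"trial_index": df["trial_index"], "condition": cond})
    phase = df["phase"].iloc[0] if len(df) else "parsing"

    if phase == "exposure":
        rotated = df["rotated"].to_numpy(bool)
        p_yes = np.where(rotated, spec.rotation_hit, spec.rotation_fa)
        out["rotated"] = rotated
        out["responded_rotated"] = rng.random(len(df)) < p_yes
        rt_mean = cond.map(
            lambda c: spec.rotation_rt_mean_ms.get(c, spec.rotation_rt_mean_ms[NONBOUNDARY])
        ).to_numpy(float)
        out["rt_ms"] = _truncnorm_ms(
            rt_mean, spec.rt_sd_ms, spec.rt_min_ms, spec.rt_max_ms, rng
        )
        return out

    p = cond.map(lambda c: spec.parse_prob.get(c, 0.0)).to_numpy(float)
    parsed = rng.random(len(df)) < p
    out["parsed"] = parsed
    rt_mean = cond.map(
        lambda c: spec.rt_mean_ms.get(c, spec.rt_mean_ms[NONBOUNDARY])
    ).to_numpy(float)
    rts = _truncnorm_ms(rt_mean, spec.rt_sd_ms, spec.rt_min_ms, spec.rt_max_ms, rng)
    if spec.response_mode == "parse_only":
        rts = np.where(parsed, rts, np.nan)
    out["rt_ms"] = rts
    out["response_mode"] = spec.response_mode
    return out


def simulate_posttest(
    posttest: pd.DataFrame,
    spec: GenerativeSpec,
    seed: int | np.random.Generator | None,
) -> pd.DataFrame:
    """Forced-choice posttest answers at the configured accuracy."""
    rng = np.random.default_rng(seed)
    df = posttest.reset_index(drop=True).copy()
    correct = rng.random(len(df)) < spec.posttest_acc
    df["answer"] = np.where(correct, df["target"], df["lure"])
    df["correct"] = correct
    return df
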