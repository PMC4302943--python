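"""Virtual-subject and virtual-listener simulation of the vowel task.

Emulates the closed-loop experiment end-to-end without hardware: a
subject model produces two-channel muscle-drive trajectories toward each
vowel's required drive pair (minimum-jerk reach from rest, optionally
distorted by co-contraction cross-talk, signal-dependent noise and
tremor); rectified EMG is drawn per millisecond as Poisson counts whose
rate is proportional to the drive; the Bayesian filter recovers drive
estimates; the chosen transform maps them to a formant trace; the
synthesizer renders the 5-s clip; and a noisy nearest-vowel listener
labels it.  A session is the randomized 25-trial protocol (5 trials per
vowel, 5 s each with 2-s breaks) run under one transform.

All randomness flows from a single seed through ``numpy`` SeedSequence
spawning, so identical seeds reproduce identical manifests, visual
errors, and WAV bytes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import bayes_filter as bf
from . import formant_map as fm
from . import synth as sy
from .metrics import ResponseTable, VOWELS

logger = logging.getLogger(__name__)

__all__ = [
    "SubjectModel",
    "SessionConfig",
    "TrialRecord",
    "SessionResult",
    "session_targets",
    "drive_trajectory",
    "poisson_emg",
    "mvc_normalize",
    "run_virtual_session",
    "virtual_listener",
    "run_virtual_listeners",
]


@dataclass(frozen=True)
class SubjectModel:
    """Virtual subject: reach dynamics plus movement-disorder distortions.

    reach_time    : s, time to reach the target drive (minimum-jerk)
    sdn_coeff     : signal-dependent noise; per-sample drive SD = sdn_coeff * drive
    cocontraction : fraction of each channel's drive leaking into the other
    tremor_amp    : amplitude of an oscillatory drive perturbation
    tremor_hz     : tremor frequency, Hz

    The healthy profile has all distortions at zero; the ``cp`` profile
    uses signal-dependent noise 0.3 and co-contraction 0.2, qualitative
    hallmarks of dyskinetic cerebral palsy.
    """

    reach_time: float = 1.0
    sdn_coeff: float = 0.0
    cocontraction: float = 0.0
    tremor_amp: float = 0.0
    tremor_hz: float = 5.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("reach_time", "sdn_coeff", "cocontraction", "tremor_amp", "tremor_hz"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def healthy(cls, **kw) -> "SubjectModel":
        return cls(**kw)

    @classmethod
    def cp(cls, sdn_coeff: float = 0.3, cocontraction: float = 0.2, **kw) -> "SubjectModel":
        return cls(sdn_coeff=sdn_coeff, cocontraction=cocontraction, **kw)


@dataclass(frozen=True)
class SessionConfig:
    """The randomized vowel-generation protocol."""

    n_per_vowel: int = 5
    trial_s: float = 5.0
    break_s: float = 2.0
    transform: str = "cartesian"
    control_hz: int = 1000
    initial_rest_s: float = 0.25  # rest-formant sound opening each clip

    def __post_init__(self) -> None:
        if self.n_per_vowel < 1:
            raise ValueError("n_per_vowel must be >= 1")
        if self.trial_s <= 0 or self.break_s < 0 or self.initial_rest_s < 0:
            raise ValueError("durations must be positive")
        if self.transform not in ("cartesian", "polar"):
            raise ValueError(f"transform must be cartesian|polar, got {self.transform!r}")
        if self.control_hz <= 0:
            raise ValueError("control_hz must be positive")


@dataclass
class TrialRecord:
    """Everything produced by one 5-s trial."""

    index: int
    target_ipa: str
    target_e: tuple[float, float]
    reachable: bool
    drive_true: np.ndarray  # (n, 2) commanded+distorted drive
    drive_est: np.ndarray  # (n, 2) filter output
    trace: fm.FormantTrace  # includes the initial rest segment
    ve_last_second: float | None
    wav_path: str | None = None
    waveform: "sy.Waveform | None" = None


@dataclass
class SessionResult:
    trials: list[TrialRecord]
    manifest: dict

    @property
    def mean_ve(self) -> float:
        ves = [t.ve_last_second for t in self.trials if t.ve_last_second is not None]
        return float(np.mean(ves))


def session_targets(cfg: SessionConfig, seed: int | None = None) -> list[str]:
    """Seeded pseudo-random trial order: each vowel exactly n_per_vowel times."""
    rng = np.random.default_rng(seed)
    base = [v for v in VOWELS for _ in range(cfg.n_per_vowel)]
    return [base[i] for i in rng.permutation(len(base))]


def _min_jerk(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile on [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def drive_trajectory(
    target_e1: float,
    target_e2: float,
    m: SubjectModel,
    cfg: SessionConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Two-channel drive trace for one trial, shape (trial_s*control_hz, 2).

    A minimum-jerk reach from rest (0, 0) to the target over
    ``m.reach_time`` seconds, held for the rest of the trial; distortions
    applied in order: co-contraction mixing, signal-dependent noise,
    tremor; finally clipped to [0, 1].
    """
    if not (0 <= target_e1 <= 1 and 0 <= target_e2 <= 1):
        raise ValueError("targets must lie in [0, 1]")
    if m.reach_time >= cfg.trial_s:
        raise ValueError(
            f"reach_time {m.reach_time} s must be shorter than the trial ({cfg.trial_s} s)"
        )
    if rng is None:
        rng = np.random.default_rng(m.seed)
    n = int(round(cfg.trial_s * cfg.control_hz))
    t = np.arange(n) / cfg.control_hz
    prof = _min_jerk(t / m.reach_time) if m.reach_time > 0 else np.ones(n)
    d = np.column_stack([target_e1 * prof, target_e2 * prof])
    if m.cocontraction > 0:
        clean = d.copy()
        d[:, 0] += m.cocontraction * clean[:, 1]
        d[:, 1] += m.cocontraction * clean[:, 0]
    if m.sdn_coeff > 0:
        d = d + rng.normal(size=d.shape) * (m.sdn_coeff * np.abs(d))
    if m.tremor_amp > 0:
        phases = rng.uniform(0, 2 * np.pi, size=2)
        osc = m.tremor_amp * np.sin(
            2 * np.pi * m.tremor_hz * t[:, None] + phases[None, :]
        )
        d = d + osc
    return np.clip(d, 0.0, 1.0)


def poisson_emg(
    drive: np.ndarray, gain: float = 50.0, rng_or_seed=None
) -> np.ndarray:
    """Rectified, MVC-scaled EMG from a drive trace.

    Per 1-ms sample the event count is Poisson with mean ``gain * drive``;
    the emitted amplitude is ``count / gain`` so the stream has mean equal
    to the drive (and variance drive/gain).
    """
    if gain <= 0:
        raise ValueError(f"gain must be > 0, got {gain}")
    drive = np.asarray(drive, dtype=float)
    if np.any(drive < 0) or np.any(drive > 1):
        raise ValueError("drive must lie in [0, 1]")
    rng = (
        rng_or_seed
        if isinstance(rng_or_seed, np.random.Generator)
        else np.random.default_rng(rng_or_seed)
    )
    return rng.poisson(gain * drive).astype(float) / gain


def mvc_normalize(attempts: list[np.ndarray], window: int = 250) -> float:
    """MVC reference: the highest ``window``-sample (250-ms) mean across attempts."""
    kernel = np.full(window, 1.0 / window)
    best = -np.inf
    for i, a in enumerate(attempts):
        a = np.asarray(a, dtype=float)
        if a.size < window:
            raise ValueError(
                f"attempt {i} has {a.size} samples; need >= {window} (250 ms)"
            )
        means = np.convolve(a, kernel, mode="valid")
        best = max(best, float(means.max()))
    return best


def _required_drives(ipa: str, cfg: SessionConfig, bounds, polar):
    """Target drive pair for a vowel under the session transform."""
    target = next(t for t in fm.default_targets() if t.ipa == ipa)
    if cfg.transform == "cartesian":
        e1, e2 = fm.inverse_cartesian(target.f1_hz, target.f2_hz, bounds)
        return target, (e1, e2), True
    e1, e2 = fm.inverse_polar(target.f1_hz, target.f2_hz, polar)
    reachable = e1 <= 1.0
    return target, (min(e1, 1.0), e2), reachable


def run_virtual_session(
    m: SubjectModel,
    cfg: SessionConfig,
    filter_params: bf.FilterParams | None = None,
    bounds: fm.FormantBounds | None = None,
    polar: fm.PolarParams | None = None,
    synth_cfg: sy.SynthConfig | None = None,
    seed: int | None = None,
    outdir=None,
    render_audio: bool = False,
) -> SessionResult:
    """Run one full randomized session through the whole pipeline.

    Per trial: vowel target → required drive pair (inverse transform) →
    minimum-jerk reach with distortions → Poisson EMG → Bayesian filter →
    transform → formant trace (prefixed by the rest-formant opening
    segment) → visual error; with ``render_audio`` (or ``outdir``) the
    clip is synthesized and written as WAV.  Polar targets outside the
    reachable ellipse are clipped, flagged, and excluded from the VE
    summary.  Deterministic given ``seed``.
    """
    filter_params = filter_params or bf.FilterParams()
    bounds = bounds or fm.default_bounds()
    polar = polar or fm.PolarParams.from_bounds(bounds)
    synth_cfg = synth_cfg or sy.SynthConfig()
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        render_audio = True

    ss = np.random.SeedSequence(seed)
    order_seed, trial_root = ss.spawn(2)
    targets = session_targets(cfg, order_seed.generate_state(1)[0] % (2**31))
    trial_seeds = trial_root.spawn(len(targets))

    rest_f = (
        fm.cartesian_to_formants(0.0, 0.0, bounds)
        if cfg.transform == "cartesian"
        else fm.polar_to_formants(0.0, 0.0, polar)
    )
    n_rest = int(round(cfg.initial_rest_s * cfg.control_hz))
    trials: list[TrialRecord] = []
    for i, ipa in enumerate(targets):
        rng = np.random.default_rng(trial_seeds[i])
        target, (e1, e2), reachable = _required_drives(ipa, cfg, bounds, polar)
        drive = drive_trajectory(e1, e2, m, cfg, rng)
        emg = np.column_stack(
            [poisson_emg(drive[:, k], filter_params.gain, rng) for k in range(2)]
        )
        est = np.column_stack(
            [bf.filter_stream(emg[:, k], filter_params) for k in range(2)]
        )
        if cfg.transform == "cartesian":
            f1, f2 = fm.cartesian_to_formants(est[:, 0], est[:, 1], bounds)
        else:
            f1, f2 = fm.polar_to_formants(est[:, 0], est[:, 1], polar)
        f1 = np.concatenate([np.full(n_rest, rest_f[0]), f1])
        f2 = np.concatenate([np.full(n_rest, rest_f[1]), f2])
        t = np.arange(f1.size) / cfg.control_hz
        trace = fm.FormantTrace(t, f1, f2)
        if reachable:
            task = fm.FormantTrace(t[n_rest:], f1[n_rest:], f2[n_rest:])
            _, ve = fm.visual_error(task, target)
        else:
            ve = None
            logger.warning("trial %d: /%s/ unreachable under polar params", i, ipa)
        rec = TrialRecord(
            index=i,
            target_ipa=ipa,
            target_e=(e1, e2),
            reachable=reachable,
            drive_true=drive,
            drive_est=est,
            trace=trace,
            ve_last_second=ve,
        )
        if render_audio:
            wav = sy.synthesize(trace, synth_cfg)
            if outdir is not None:
                path = outdir / f"trial_{i:02d}.wav"
                sy.write_wav(wav, path)
                rec.wav_path = str(path)
                trace_df = pd.DataFrame(
                    {"time_s": trace.time_s, "f1_hz": trace.f1_hz, "f2_hz": trace.f2_hz}
                )
                trace_df.to_csv(outdir / f"trial_{i:02d}_trace.csv", index=False)
            rec.waveform = wav
        trials.append(rec)

    manifest = {
        "seed": seed,
        "subject": asdict(m),
        "session": asdict(cfg),
        "filter": asdict(filter_params),
        "bounds": asdict(bounds),
        "polar": asdict(polar),
        "synth": asdict(synth_cfg),
        "trials": [
            {
                "index": t.index,
                "target": t.target_ipa,
                "reachable": t.reachable,
                "ve_last_second": t.ve_last_second,
                "wav": Path(t.wav_path).name if t.wav_path else None,
            }
            for t in trials
        ],
    }
    if outdir is not None:
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, ensure_ascii=False)
    return SessionResult(trials, manifest)


def virtual_listener(
    record: TrialRecord,
    noise_hz: float = 50.0,
    rng_or_seed=None,
    targets: list[fm.VowelTarget] | None = None,
    window_s: float = 1.0,
) -> str:
    """Label a trial like a naive listener judging the steady-state sound.

    Takes the mean (F1, F2) over the final second of the trace, perturbs
    it with isotropic Gaussian perceptual noise of SD ``noise_hz``, and
    returns the nearest vowel target by Euclidean distance in Hz (ties
    broken by fixture order).
    """
    if targets is None:
        targets = fm.default_targets()
    trace = record.trace
    t_end = trace.time_s[-1]
    mask = trace.time_s > t_end - window_s + 1e-12
    if mask.sum() * trace.dt < window_s - 1e-9:
        raise ValueError("trial trace must contain >= 1 s of steady segment")
    f1 = float(trace.f1_hz[mask].mean())
    f2 = float(trace.f2_hz[mask].mean())
    rng = (
        rng_or_seed
        if isinstance(rng_or_seed, np.random.Generator)
        else np.random.default_rng(rng_or_seed)
    )
    if noise_hz > 0:
        f1 += rng.normal(0.0, noise_hz)
        f2 += rng.normal(0.0, noise_hz)
    dists = [np.hypot(f1 - t.f1_hz, f2 - t.f2_hz) for t in targets]
    return targets[int(np.argmin(dists))].ipa


def run_virtual_listeners(
    session: SessionResult,
    n_listeners: int = 4,
    noise_hz: float = 50.0,
    seed: int | None = None,
) -> ResponseTable:
    """Independent noisy listeners labelling every trial of a session."""
    rng = np.random.default_rng(seed)
    truth = [t.target_ipa for t in session.trials]
    responses = np.empty((len(truth), n_listeners), dtype=object)
    for j in range(n_listeners):
        for i, rec in enumerate(session.trials):
            responses[i, j] = virtual_listener(rec, noise_hz, rng)
    return ResponseTable(np.asarray(truth, dtype=object), responses)
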