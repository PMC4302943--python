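"""EMG-to-formant mappings, vowel targets, and geometric performance measures.

Two filtered drive signals place a point in the (F1, F2) plane, where the
five common U.S. English vowels are fixed targets (average male formant
frequencies).  Two transforms are supported:

* **Cartesian** — each drive is mapped affinely onto one formant axis,
  ``F = (F_hi - F_lo) * e + F_lo``; the box boundaries are chosen so all
  five vowels are reachable with drives in [0, 1].
* **Polar** — drive 1 sets the magnitude and drive 2 the angle of a
  vector about the box center, ``theta = 2*pi*e2 + pi/2``; at
  (e1, e2) = (1, 0) the vector points toward negative F1.

Producing a vowel is thus a 2-D reaching movement.  The *visual error*
(VE) is the Euclidean distance in Hz between the instantaneous formant
point and the target, summarized as its mean over the last second of a
5-s trial; a scalar performance measure is its reciprocal, p = 1/VE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VowelTarget",
    "FormantBounds",
    "PolarParams",
    "FormantTrace",
    "load_vowel_table",
    "default_targets",
    "default_bounds",
    "cartesian_to_formants",
    "polar_to_formants",
    "inverse_cartesian",
    "inverse_polar",
    "fit_bounds_from_table",
    "table_residuals",
    "required_emg_table",
    "visual_error",
    "performance_change",
]

HIGH_EFFORT_THRESHOLD = 0.60  # drive above this fraction of MVC risks fatigue


@dataclass(frozen=True)
class VowelTarget:
    """One vowel target: IPA label, example word, and its (F1, F2) in Hz."""

    ipa: str
    example_word: str
    f1_hz: float
    f2_hz: float

    def __post_init__(self) -> None:
        if not (0 < self.f1_hz < self.f2_hz):
            raise ValueError(
                f"/{self.ipa}/: need 0 < F1 < F2, got ({self.f1_hz}, {self.f2_hz})"
            )


def load_vowel_table() -> pd.DataFrame:
    """The shipped five-vowel fixture: formants plus the published
    Cartesian and polar drive magnitudes for each vowel."""
    with resources.files("myovowel.data").joinpath("vowel_targets.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        return pd.read_csv(fh)


def default_targets() -> list[VowelTarget]:
    df = load_vowel_table()
    return [
        VowelTarget(r.ipa, r.word, float(r.f1_hz), float(r.f2_hz))
        for r in df.itertuples()
    ]


@dataclass(frozen=True)
class FormantBounds:
    """Boundary frequencies of the Cartesian formant box (Hz)."""

    f1_lo: float
    f1_hi: float
    f2_lo: float
    f2_hi: float

    def __post_init__(self) -> None:
        if not self.f1_lo < self.f1_hi:
            raise ValueError(f"need f1_lo < f1_hi, got {self.f1_lo} >= {self.f1_hi}")
        if not self.f2_lo < self.f2_hi:
            raise ValueError(f"need f2_lo < f2_hi, got {self.f2_lo} >= {self.f2_hi}")

    def contains(self, f1_hz: float, f2_hz: float) -> bool:
        return (self.f1_lo <= f1_hz <= self.f1_hi) and (
            self.f2_lo <= f2_hz <= self.f2_hi
        )

    @property
    def center(self) -> tuple[float, float]:
        return ((self.f1_lo + self.f1_hi) / 2.0, (self.f2_lo + self.f2_hi) / 2.0)


@dataclass(frozen=True)
class PolarParams:
    """Parameters of the polar transform.

    ``k_f1``/``k_f2`` scale the ellipse semi-axes; ``k_f1`` is negative so
    that (e1, e2) = (1, 0) points toward negative F1.  The center defaults
    to the midpoint of the Cartesian box.
    """

    k_f1: float
    k_f2: float
    center_f1: float
    center_f2: float

    def __post_init__(self) -> None:
        if self.k_f1 == 0 or self.k_f2 == 0:
            raise ValueError("scaling factors k_f1, k_f2 must be nonzero")

    @classmethod
    def from_bounds(cls, b: FormantBounds) -> "PolarParams":
        c1, c2 = b.center
        return cls(
            k_f1=-(b.f1_hi - b.f1_lo) / 2.0,
            k_f2=(b.f2_hi - b.f2_lo) / 2.0,
            center_f1=c1,
            center_f2=c2,
        )


def _clip_drives(e1, e2):
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    n_out = int(np.sum((e1 < 0) | (e1 > 1)) + np.sum((e2 < 0) | (e2 > 1)))
    if n_out:
        logger.info("clipped %d out-of-range drive values to [0, 1]", n_out)
    return np.clip(e1, 0.0, 1.0), np.clip(e2, 0.0, 1.0)


def cartesian_to_formants(e1, e2, b: FormantBounds):
    """Affine map from a drive pair to (F1, F2); drives are clipped to [0, 1]."""
    e1, e2 = _clip_drives(e1, e2)
    f1 = (b.f1_hi - b.f1_lo) * e1 + b.f1_lo
    f2 = (b.f2_hi - b.f2_lo) * e2 + b.f2_lo
    return f1, f2


def polar_to_formants(e1, e2, p: PolarParams):
    """Magnitude/angle map: e1 scales the vector, e2 sets its angle."""
    e1, e2 = _clip_drives(e1, e2)
    theta = 2.0 * np.pi * e2 + np.pi / 2.0
    f1 = p.center_f1 + p.k_f1 * e1 * np.sin(theta)
    f2 = p.center_f2 + p.k_f2 * e1 * np.cos(theta)
    return f1, f2


def inverse_cartesian(f1_hz: float, f2_hz: float, b: FormantBounds):
    """Exact inverse of the Cartesian transform for a point inside the box."""
    if not (b.f1_lo <= f1_hz <= b.f1_hi):
        raise ValueError(
            f"F1 = {f1_hz} Hz outside bounds [{b.f1_lo}, {b.f1_hi}]"
        )
    if not (b.f2_lo <= f2_hz <= b.f2_hi):
        raise ValueError(
            f"F2 = {f2_hz} Hz outside bounds [{b.f2_lo}, {b.f2_hi}]"
        )
    e1 = (f1_hz - b.f1_lo) / (b.f1_hi - b.f1_lo)
    e2 = (f2_hz - b.f2_lo) / (b.f2_hi - b.f2_lo)
    return float(e1), float(e2)


def inverse_polar(f1_hz: float, f2_hz: float, p: PolarParams):
    """Invert the polar transform.

    Returns ``(e1, e2)`` with ``e2`` wrapped to [0, 1).  ``e1`` may exceed
    1 when the point lies outside the reachable ellipse; callers decide
    whether that makes the target unreachable.
    """
    d1 = (f1_hz - p.center_f1) / p.k_f1  # e1 * sin(theta)
    d2 = (f2_hz - p.center_f2) / p.k_f2  # e1 * cos(theta)
    e1 = float(np.hypot(d1, d2))
    if e1 == 0.0:
        return 0.0, 0.0
    theta = float(np.arctan2(d1, d2))
    e2 = ((theta - np.pi / 2.0) / (2.0 * np.pi)) % 1.0
    return e1, float(e2)


def fit_bounds_from_table(
    table: pd.DataFrame | None = None, vowels: list[str] | None = None
) -> FormantBounds:
    """Recover the Cartesian boundary frequencies from the vowel fixture.

    Fits a least-squares line ``F = (hi - lo) * e + lo`` through the
    (published drive, formant) pairs of each axis.  ``vowels`` restricts
    the fit to a subset of rows (e.g. the two anchor vowels /i/ and /ɑ/,
    which reproduces every published drive value to two decimals).
    """
    if table is None:
        table = load_vowel_table()
    if vowels is not None:
        table = table[table["ipa"].isin(vowels)]
    if len(table) < 2:
        raise ValueError("need at least 2 vowels to fit boundary frequencies")
    out = []
    for e_col, f_col in (("emg1_cart", "f1_hz"), ("emg2_cart", "f2_hz")):
        e = table[e_col].to_numpy(dtype=float)
        f = table[f_col].to_numpy(dtype=float)
        if np.ptp(e) == 0:
            raise ValueError(f"degenerate fit: all {e_col} values identical")
        slope, lo = np.polyfit(e, f, 1)
        out.append((float(lo), float(lo + slope)))
    (f1_lo, f1_hi), (f2_lo, f2_hi) = out
    return FormantBounds(f1_lo, f1_hi, f2_lo, f2_hi)


def table_residuals(b: FormantBounds, table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-vowel residuals of the published Cartesian drives under ``b``."""
    if table is None:
        table = load_vowel_table()
    rows = []
    for r in table.itertuples():
        e1, e2 = inverse_cartesian(float(r.f1_hz), float(r.f2_hz), b)
        rows.append(
            {
                "ipa": r.ipa,
                "emg1_recon": e1,
                "emg2_recon": e2,
                "resid1": e1 - float(r.emg1_cart),
                "resid2": e2 - float(r.emg2_cart),
            }
        )
    return pd.DataFrame(rows)


def default_bounds() -> FormantBounds:
    """Boundary frequencies fitted to the shipped vowel fixture."""
    return fit_bounds_from_table()


def required_emg_table(
    targets: list[VowelTarget] | None = None,
    b: FormantBounds | None = None,
    p: PolarParams | None = None,
) -> pd.DataFrame:
    """Drive pair required for each vowel under both transforms.

    Flags components above 60% MVC (known to induce fatigue) and polar
    targets outside the reachable ellipse (e1 > 1).
    """
    if targets is None:
        targets = default_targets()
    if b is None:
        b = default_bounds()
    if p is None:
        p = PolarParams.from_bounds(b)
    rows = []
    for t in targets:
        c1, c2 = inverse_cartesian(t.f1_hz, t.f2_hz, b)
        p1, p2 = inverse_polar(t.f1_hz, t.f2_hz, p)
        rows.append(
            {
                "ipa": t.ipa,
                "e1_cart": c1,
                "e2_cart": c2,
                "e1_polar": p1,
                "e2_polar": p2,
                "high_effort_cart": (c1 > HIGH_EFFORT_THRESHOLD)
                or (c2 > HIGH_EFFORT_THRESHOLD),
                "high_effort_polar": (min(p1, 1.0) > HIGH_EFFORT_THRESHOLD)
                or (p2 > HIGH_EFFORT_THRESHOLD),
                "unreachable_polar": p1 > 1.0,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class FormantTrace:
    """Commanded (F1, F2) per control tick at a uniform control rate."""

    time_s: np.ndarray
    f1_hz: np.ndarray
    f2_hz: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.f1_hz = np.asarray(self.f1_hz, dtype=float)
        self.f2_hz = np.asarray(self.f2_hz, dtype=float)
        if not (self.time_s.shape == self.f1_hz.shape == self.f2_hz.shape):
            raise ValueError("time, F1 and F2 must have equal length")
        if self.time_s.size >= 2:
            dt = np.diff(self.time_s)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("trace must be uniformly sampled")

    def __len__(self) -> int:
        return self.time_s.size

    @property
    def dt(self) -> float:
        if len(self) < 2:
            raise ValueError("need >= 2 ticks to infer dt")
        return float(self.time_s[1] - self.time_s[0])

    @classmethod
    def from_drives(cls, e1, e2, transform: str, b=None, p=None, control_hz: float = 1000.0):
        """Build a trace by mapping drive streams through a transform."""
        e1 = np.asarray(e1, dtype=float)
        if transform == "cartesian":
            b = b if b is not None else default_bounds()
            f1, f2 = cartesian_to_formants(e1, e2, b)
        elif transform == "polar":
            if p is None:
                p = PolarParams.from_bounds(b if b is not None else default_bounds())
            f1, f2 = polar_to_formants(e1, e2, p)
        else:
            raise ValueError(f"unknown transform {transform!r}")
        t = np.arange(e1.size) / control_hz
        return cls(t, f1, f2)


def visual_error(trace: FormantTrace, target: VowelTarget, window_s: float = 1.0):
    """Per-tick distance to the target and its mean over the final window.

    ``VE(t) = sqrt((F1(t) - F1_0)^2 + (F2(t) - F2_0)^2)``; the summary is
    the mean over the last ``window_s`` seconds (1 s of a 5-s trial).
    """
    if len(trace) == 0:
        raise ValueError("trace is empty")
    ve = np.hypot(trace.f1_hz - target.f1_hz, trace.f2_hz - target.f2_hz)
    t_end = trace.time_s[-1]
    mask = trace.time_s > t_end - window_s + 1e-12
    if trace.time_s[0] > t_end - window_s:
        logger.warning(
            "trace shorter than %.3g s; averaging over all %d ticks",
            window_s,
            len(trace),
        )
    return ve, float(ve[mask].mean())


def performance_change(ve_healthy: float, ve_patient: float):
    """Relative VE increase and the implied relative performance drop.

    With performance p = 1/VE: ``dVE = (VE2 - VE1)/VE1`` and
    ``dp = dVE / (1 + dVE)``, the fractional decrease in p when VE grows.
    Both are returned as fractions (multiply by 100 for percent).
    """
    if ve_healthy <= 0:
        raise ValueError(f"reference VE must be > 0, got {ve_healthy}")
    if ve_patient <= 0:
        raise ValueError(f"comparison VE must be > 0, got {ve_patient}")
    delta_ve = (ve_patient - ve_healthy) / ve_healthy
    delta_p = delta_ve / (1.0 + delta_ve)
    return float(delta_ve), float(delta_p)
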