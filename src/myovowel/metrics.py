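"""Intelligibility statistics for listener responses.

Each trial has a true (intended) vowel and one forced-choice response per
listener.  Intelligibility is summarized by the fraction of vowels
identified correctly, by Cohen's κ between each listener and an imaginary
perfect listener (chance-corrected agreement with ground truth), and by
Fleiss's κ for agreement among the listeners themselves.  κ values carry
the Landis–Koch qualitative band ("Slight" … "Almost perfect").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats import inter_rater

__all__ = [
    "VOWELS",
    "ResponseTable",
    "KappaResult",
    "fraction_correct",
    "cohens_kappa",
    "fleiss_kappa",
    "landis_koch_label",
    "session_report",
]

VOWELS = ("ɑ", "e", "i", "ɔ", "u")


@dataclass
class ResponseTable:
    """Trials × (true vowel, one response per listener)."""

    true_vowel: np.ndarray
    responses: np.ndarray  # shape (n_trials, n_listeners)
    categories: tuple[str, ...] = VOWELS

    def __post_init__(self) -> None:
        self.true_vowel = np.asarray(self.true_vowel, dtype=object)
        self.responses = np.asarray(self.responses, dtype=object)
        if self.responses.ndim == 1:
            self.responses = self.responses[:, None]
        if self.true_vowel.size == 0:
            raise ValueError("response table needs at least one trial")
        if self.responses.shape[0] != self.true_vowel.size:
            raise ValueError("responses and truth must have equal trial counts")
        cats = set(self.categories)
        bad = (set(self.true_vowel.tolist()) | set(self.responses.ravel().tolist())) - cats
        if bad:
            raise ValueError(f"labels outside the category set: {sorted(bad)}")

    @property
    def n_trials(self) -> int:
        return self.true_vowel.size

    @property
    def n_listeners(self) -> int:
        return self.responses.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, categories=VOWELS) -> "ResponseTable":
        """Columns: ``trial`` (optional), ``true_vowel``, then one per listener."""
        cols = [c for c in df.columns if c not in ("trial", "true_vowel")]
        return cls(df["true_vowel"].to_numpy(), df[cols].to_numpy(), tuple(categories))

    @classmethod
    def from_csv(cls, path, categories=VOWELS) -> "ResponseTable":
        return cls.from_dataframe(pd.read_csv(path), categories)

    def to_dataframe(self) -> pd.DataFrame:
        data = {"trial": np.arange(self.n_trials), "true_vowel": self.true_vowel}
        for j in range(self.n_listeners):
            data[f"listener{j + 1}"] = self.responses[:, j]
        return pd.DataFrame(data)

    def confusion_matrix(self, listener: int) -> pd.DataFrame:
        """Truth (rows) × response (columns) counts over the full category set."""
        self._check_listener(listener)
        cats = list(self.categories)
        cm = pd.crosstab(
            pd.Categorical(self.true_vowel, categories=cats),
            pd.Categorical(self.responses[:, listener], categories=cats),
            dropna=False,
        )
        return cm.reindex(index=cats, columns=cats, fill_value=0)

    def _check_listener(self, listener: int) -> None:
        if not (0 <= listener < self.n_listeners):
            raise IndexError(
                f"listener index {listener} out of range [0, {self.n_listeners})"
            )


@dataclass(frozen=True)
class KappaResult:
    """A κ statistic with its Landis–Koch quality band."""

    kappa: float
    label: str
    p_observed: float | None = None
    p_expected: float | None = None


def landis_koch_label(kappa: float) -> str:
    """Landis–Koch qualitative band for a κ value (κ <= 1).

    Bands are half-open [lo, hi) with the top band closed at 1:
    <0 Poor; [0, .21) Slight; [.21, .41) Fair; [.41, .61) Moderate;
    [.61, .81) Substantial; [.81, 1] Almost perfect.
    """
    if not np.isfinite(kappa):
        return "Undefined"
    if kappa > 1.0 + 1e-12:
        raise ValueError(f"kappa cannot exceed 1, got {kappa}")
    if kappa < 0:
        return "Poor"
    if kappa < 0.21:
        return "Slight"
    if kappa < 0.41:
        return "Fair"
    if kappa < 0.61:
        return "Moderate"
    if kappa < 0.81:
        return "Substantial"
    return "Almost perfect"


def fraction_correct(t: ResponseTable, listener: int = 0) -> float:
    """N_correct / N_total for one listener against the intended vowels."""
    t._check_listener(listener)
    return float(np.mean(t.responses[:, listener] == t.true_vowel))


def cohens_kappa(t: ResponseTable, listener: int = 0) -> KappaResult:
    """Cohen's κ between one listener and the intended vowels.

    κ = (p_o − p_e)/(1 − p_e) with p_e from the marginal products of the
    listener-vs-truth confusion matrix.  Degenerate tables (p_e = 1) give
    κ = NaN with label "Undefined".
    """
    cm = t.confusion_matrix(listener).to_numpy(dtype=float)
    n = cm.sum()
    p_o = float(np.trace(cm) / n)
    p_e = float(np.sum(cm.sum(axis=0) * cm.sum(axis=1)) / n**2)
    if abs(1.0 - p_e) < 1e-12:
        return KappaResult(float("nan"), "Undefined", p_o, p_e)
    res = inter_rater.cohens_kappa(cm, return_results=False)
    return KappaResult(float(res), landis_koch_label(float(res)), p_o, p_e)


def fleiss_kappa(t: ResponseTable) -> KappaResult:
    """Fleiss's κ for agreement among all listeners (>= 2 required)."""
    if t.n_listeners < 2:
        raise ValueError("Fleiss's kappa needs >= 2 raters; use cohens_kappa")
    cats = list(t.categories)
    counts = np.zeros((t.n_trials, len(cats)), dtype=float)
    index = {c: j for j, c in enumerate(cats)}
    for i in range(t.n_trials):
        for r in t.responses[i]:
            counts[i, index[r]] += 1
    k = float(inter_rater.fleiss_kappa(counts, method="fleiss"))
    return KappaResult(k, landis_koch_label(k))


def session_report(t: ResponseTable) -> dict:
    """Per-listener and pooled intelligibility summary.

    Returns per-listener fraction correct and Cohen's κ (with labels),
    their mean and sample SD across listeners, and Fleiss's κ across all
    listeners — the summary printed for each session condition.
    """
    per_listener = []
    kappas = []
    for j in range(t.n_listeners):
        k = cohens_kappa(t, j)
        kappas.append(k.kappa)
        per_listener.append(
            {
                "listener": j + 1,
                "fraction_correct": fraction_correct(t, j),
                "kappa": k.kappa,
                "label": k.label,
            }
        )
    kappas = np.asarray(kappas, dtype=float)
    report = {
        "n_trials": t.n_trials,
        "n_listeners": t.n_listeners,
        "per_listener": per_listener,
        "fraction_correct_mean": float(
            np.mean([r["fraction_correct"] for r in per_listener])
        ),
        "kappa_mean": float(np.nanmean(kappas)),
        "kappa_sd": float(np.nanstd(kappas, ddof=1)) if len(kappas) > 1 else 0.0,
        "kappa_mean_label": landis_koch_label(float(np.nanmean(kappas))),
    }
    if t.n_listeners >= 2:
        fk = fleiss_kappa(t)
        report["fleiss_kappa"] = fk.kappa
        report["fleiss_label"] = fk.label
    return report
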