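"""Evaluation metrics: accuracy, information transfer rate, coefficient
spectra, paired comparisons and data-length sweeps.

The information transfer rate (ITR, bits/min) of an M-class selector with
mean accuracy sigma deciding every T seconds is the Wolpaw formula

    ITR = (60/T) * [log2 M + sigma log2 sigma
                    + (1 - sigma) log2((1 - sigma) / (M - 1))]

with the continuity convention ``0 * log2 0 = 0`` at the endpoints; ITR
is zero exactly at chance level ``sigma = 1/M``.

The module also ships a 42-subject reference benchmark (per-subject
accuracy/ITR pairs for CCA, FBCCA, CAR-USSR and PCA-USSR at T = 2 s,
M = 35) used as a regression fixture for the ITR arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .recognize import ScoreSpectrum, classify, score_epoch
from .signal_model import EEGEpoch

__all__ = [
    "ITRParams",
    "EvaluationReport",
    "compute_itr",
    "accuracy",
    "coefficient_spectrum",
    "paired_comparison",
    "evaluate_method",
    "data_length_sweep",
    "load_reference_benchmark",
    "REFERENCE_SUMMARY",
]


@dataclass(frozen=True)
class ITRParams:
    """Arguments of the ITR formula: accuracy ``sigma`` in [0, 1], class
    count ``m`` >= 2, decision time ``t`` in seconds."""

    sigma: float
    m: int = 35
    t: float = 2.0

    def __post_init__(self) -> None:
        if not 0 <= self.sigma <= 1:
            raise ValueError(f"sigma must lie in [0, 1], got {self.sigma}")
        if self.m < 2:
            raise ValueError(f"need at least 2 classes, got {self.m}")
        if self.t <= 0:
            raise ValueError(f"decision time must be positive, got {self.t}")


def compute_itr(sigma: float | ITRParams, m: int = 35, t: float = 2.0) -> float:
    """Information transfer rate in bits/min (Wolpaw formula).

    Accepts either an :class:`ITRParams` or ``(sigma, m, t)`` directly.
    Finite on the whole closed interval (0*log0 := 0 at the endpoints);
    zero exactly at chance level and non-negative everywhere, being a
    KL divergence against the uniform M-class distribution.
    """
    if isinstance(sigma, ITRParams):
        p = sigma
    else:
        p = ITRParams(sigma=float(sigma), m=m, t=t)
    bits = math.log2(p.m)
    if p.sigma > 0:
        bits += p.sigma * math.log2(p.sigma)
    if p.sigma < 1:
        bits += (1 - p.sigma) * math.log2((1 - p.sigma) / (p.m - 1))
    return 60.0 / p.t * bits


def accuracy(predictions: Sequence[float], truths: Sequence[float]) -> float:
    """Percent of exact frequency matches."""
    if len(predictions) != len(truths):
        raise ValueError(
            f"length mismatch: {len(predictions)} predictions, {len(truths)} truths"
        )
    if not predictions:
        raise ValueError("empty prediction list")
    hits = sum(1 for p, t in zip(predictions, truths) if float(p) == float(t))
    return 100.0 * hits / len(predictions)


def coefficient_spectrum(
    epoch: EEGEpoch,
    method: str = "cca_ussr",
    *,
    low: float = 1.0,
    high: float = 40.0,
    step: float = 0.5,
    k: int = 2,
    **pipeline_kwargs,
) -> ScoreSpectrum:
    """Discriminant spectrum over a dense candidate grid (default
    1-40 Hz at 0.5 Hz: 79 points) using the configured method."""
    n = int(round((high - low) / step)) + 1
    grid = low + step * np.arange(n)
    return score_epoch(epoch, method, candidate_freqs=grid, k=k, **pipeline_kwargs)


def paired_comparison(acc_a: Sequence[float], acc_b: Sequence[float]):
    """Paired two-sided t-test on per-unit accuracies.

    Returns ``(t, p)``.  Identical vectors are a degenerate case with no
    evidence of difference: reported as ``t = 0, p = 1``.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need two 1-D vectors of equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 paired samples")
    d = a - b
    if np.all(d == d[0]):
        if d[0] == 0:
            return 0.0, 1.0
        raise ValueError("zero-variance non-zero differences: t undefined")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


@dataclass(frozen=True)
class EvaluationReport:
    """Classification outcome of one method at one data length."""

    method: str
    length_s: float
    n_trials: int
    accuracy_pct: float
    itr_bits_per_min: float
    predictions: tuple[float, ...]
    truths: tuple[float, ...]
    tie_count: int = 0
    m: int = 35
    seed: int | None = None

    def to_row(self) -> dict:
        return {
            "method": self.method,
            "length_s": self.length_s,
            "n_trials": self.n_trials,
            "accuracy_pct": round(self.accuracy_pct, 2),
            "itr_bits_per_min": round(self.itr_bits_per_min, 2),
            "tie_count": self.tie_count,
        }


def evaluate_method(
    epochs: Sequence[EEGEpoch],
    method: str,
    stimulus_freqs: Sequence[float],
    *,
    length_s: float | None = None,
    k: int = 2,
    seed: int | None = None,
    **pipeline_kwargs,
) -> EvaluationReport:
    """Classify every epoch with one method and summarize accuracy + ITR.

    ``length_s`` truncates each epoch to its first ``length_s`` seconds
    before decoding (stimulus-onset aligned), mirroring online use.
    """
    if not epochs:
        raise ValueError("no epochs to evaluate")
    stimulus_freqs = [float(f) for f in stimulus_freqs]
    preds: list[float] = []
    truths: list[float] = []
    ties = 0
    for ep in epochs:
        if ep.true_freq is None:
            raise ValueError("epoch lacks a true_freq label")
        e = ep if length_s is None else ep.crop(length_s)
        spectrum = score_epoch(e, method, candidate_freqs=stimulus_freqs, k=k, **pipeline_kwargs)
        pred = classify(spectrum, stimulus_freqs)
        preds.append(pred.freq)
        truths.append(float(ep.true_freq))
        ties += int(pred.tie)
    t_used = length_s if length_s is not None else epochs[0].duration
    acc = accuracy(preds, truths)
    return EvaluationReport(
        method=method,
        length_s=float(t_used),
        n_trials=len(epochs),
        accuracy_pct=acc,
        itr_bits_per_min=compute_itr(acc / 100.0, m=len(stimulus_freqs), t=float(t_used)),
        predictions=tuple(preds),
        truths=tuple(truths),
        tie_count=ties,
        m=len(stimulus_freqs),
        seed=seed,
    )


def data_length_sweep(
    epochs: Sequence[EEGEpoch],
    lengths: Sequence[float],
    methods: Sequence[str],
    stimulus_freqs: Sequence[float],
    **pipeline_kwargs,
) -> list[EvaluationReport]:
    """Re-run classification at several truncated data lengths.

    Returns one report per (method, length) in method-major order.
    """
    max_dur = min(ep.duration for ep in epochs)
    bad = [t for t in lengths if t > max_dur + 1e-9]
    if bad:
        raise ValueError(f"lengths {bad} exceed epoch duration {max_dur} s")
    reports = []
    for method in methods:
        for t in lengths:
            reports.append(
                evaluate_method(
                    epochs, method, stimulus_freqs, length_s=float(t), **pipeline_kwargs
                )
            )
    return reports


# ---------------------------------------------------------------------------
# Reference benchmark (42 subjects, T = 2 s, M = 35)

#: Printed per-column summary (mean, sample SD) of the reference benchmark.
REFERENCE_SUMMARY: Mapping[str, Mapping[str, tuple[float, float]]] = {
    "cca": {"accuracy": (61.16, 19.59), "itr": (66.68, 33.48)},
    "fbcca": {"accuracy": (65.99, 11.68), "itr": (74.22, 20.66)},
    "car_ussr": {"accuracy": (52.38, 32.75), "itr": (51.25, 48.71)},
    "pca_ussr": {"accuracy": (54.97, 17.38), "itr": (55.36, 27.32)},
}


def load_reference_benchmark() -> pd.DataFrame:
    """Per-subject accuracy/ITR of four decoders on the 42-subject
    motion-checkerboard benchmark (35 targets, 2 s epochs)."""
    with resources.files("ssvepsr.data").joinpath("benchmark_42subjects.csv").open() as fh:
        return pd.read_csv(fh)
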