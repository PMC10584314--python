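"""Frequency scoring and target classification.

Four families of scorers assign a discriminant value to every candidate
stimulus frequency:

* ``cca_score``   - first canonical correlation between the multichannel
  epoch and the sinusoidal template of each candidate;
* ``fbcca_score`` - filter-bank CCA: the epoch is decomposed into
  sub-bands, CCA is run per band, and squared correlations are combined
  with decaying weights ``w_i = i**(-a) + b``;
* ``psda_score``  - spectral power evaluated exactly at each candidate
  (and optionally its first harmonic) by single-frequency projection,
  never snapped to FFT bins;
* ``ussr_pipeline_score`` - the stochastic-resonance pipeline: reduce the
  epoch to one dimension, pass it through the bistable filter, and score
  the output trajectory by CCA or PSDA.

The predicted target is the stimulus frequency with the maximal score
(ties broken toward the lowest frequency).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from . import dimred
from .preprocess import FilterSpec, bandpass
from .signal_model import EEGEpoch, TemplateBank, make_template_bank, time_axis
from .ussr import USSRParams, ussr_filter

__all__ = [
    "ScoreSpectrum",
    "FBCCAParams",
    "Prediction",
    "fbcca_weight",
    "cca_score",
    "fbcca_score",
    "psda_score",
    "ussr_pipeline_score",
    "score_epoch",
    "classify",
    "METHODS",
]

log = logging.getLogger(__name__)

#: Recognized end-to-end method names (see :func:`score_epoch`).
METHODS = (
    "cca",
    "fbcca",
    "psda",
    "cca_ussr",
    "car_ussr",
    "pca_ussr",
    "mds_ussr",
    "lle_ussr",
)


@dataclass(frozen=True)
class ScoreSpectrum:
    """Per-candidate-frequency discriminant values."""

    freqs: np.ndarray
    scores: np.ndarray
    method: str

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        scores = np.asarray(self.scores, dtype=float)
        if freqs.shape != scores.shape or freqs.ndim != 1:
            raise ValueError("freqs and scores must be matching 1-D arrays")
        if len(freqs) == 0:
            raise ValueError("empty score spectrum")
        if np.any(np.diff(freqs) <= 0):
            raise ValueError("freqs must be ascending and unique")
        if not np.isfinite(scores).all():
            raise ValueError("non-finite scores")
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "scores", scores)

    def score_at(self, f: float) -> float:
        i = int(np.argmin(np.abs(self.freqs - f)))
        if abs(self.freqs[i] - f) > 1e-9:
            raise KeyError(f"frequency {f} Hz not in spectrum")
        return float(self.scores[i])


class Prediction(NamedTuple):
    """Classification outcome: predicted frequency and tie flag."""

    freq: float
    tie: bool


def _default_subbands(n: int, high: float = 40.0) -> tuple[tuple[float, float], ...]:
    # harmonic-progressive bank scaled to the 3-20 Hz stimulus range
    return tuple((3.0 * i, high) for i in range(1, n + 1))


@dataclass(frozen=True)
class FBCCAParams:
    """Filter-bank CCA settings: N sub-bands and weight constants.

    Sub-band ``i`` spans ``subband_edges[i-1]``; its squared canonical
    correlation is weighted by ``i**(-weight_a) + weight_b``.
    """

    n_subbands: int = 5
    weight_a: float = 1.25
    weight_b: float = 0.25
    subband_edges: tuple[tuple[float, float], ...] = field(default=None)  # type: ignore[assignment]
    filter_order: int = 4

    def __post_init__(self) -> None:
        if self.n_subbands < 1:
            raise ValueError("need at least one sub-band")
        if self.weight_b < 0:
            raise ValueError("weights must stay positive")
        edges = self.subband_edges
        if edges is None:
            edges = _default_subbands(self.n_subbands)
        edges = tuple((float(lo), float(hi)) for lo, hi in edges)
        if len(edges) != self.n_subbands:
            raise ValueError(
                f"{len(edges)} edge pairs for {self.n_subbands} sub-bands"
            )
        for lo, hi in edges:
            if not 0 < lo < hi:
                raise ValueError(f"invalid sub-band ({lo}, {hi})")
        object.__setattr__(self, "subband_edges", edges)


def fbcca_weight(i: int, p: FBCCAParams = FBCCAParams()) -> float:
    """Sub-band weight ``i**(-a) + b`` for 1-based sub-band index ``i``."""
    if not 1 <= i <= p.n_subbands:
        raise IndexError(f"sub-band index {i} outside 1..{p.n_subbands}")
    return i ** (-p.weight_a) + p.weight_b


def cca_score(epoch: EEGEpoch, bank: TemplateBank) -> ScoreSpectrum:
    """Canonical correlation against every candidate template."""
    if bank.n_samples != epoch.n_samples:
        raise ValueError("template bank length does not match epoch")
    scores = [dimred.cca_fit(epoch.data, bank[f]).rho for f in bank.freqs]
    return ScoreSpectrum(np.array(bank.freqs), np.array(scores), "cca")


def fbcca_score(
    epoch: EEGEpoch, bank: TemplateBank, p: FBCCAParams = FBCCAParams()
) -> ScoreSpectrum:
    """Filter-bank CCA: weighted sum of squared per-band correlations."""
    if bank.n_samples != epoch.n_samples:
        raise ValueError("template bank length does not match epoch")
    nyq = epoch.fs / 2
    for lo, hi in p.subband_edges:
        if hi >= nyq:
            raise ValueError(f"sub-band ({lo}, {hi}) reaches Nyquist {nyq} Hz")
    scores = np.zeros(len(bank.freqs))
    for i, (lo, hi) in enumerate(p.subband_edges, start=1):
        sub = bandpass(epoch, FilterSpec(lo, hi, order=p.filter_order, zero_phase=True))
        w = fbcca_weight(i, p)
        rhos = np.array([dimred.cca_fit(sub.data, bank[f]).rho for f in bank.freqs])
        scores += w * rhos**2
    return ScoreSpectrum(np.array(bank.freqs), scores, "fbcca")


def _single_freq_power(values: np.ndarray, fs: float, f: float) -> float:
    """Squared magnitude of the discrete-time Fourier sum at exactly ``f``.

    Unnormalized convention: a unit sinusoid over an integer number of
    periods scores ``(n/2)**2``.
    """
    t = time_axis(len(values), fs)
    z = np.exp(-2j * math.pi * f * t) @ values
    return float(abs(z) ** 2)


def psda_score(
    values: np.ndarray,
    fs: float,
    freqs: Sequence[float],
    use_harmonic: bool = True,
) -> ScoreSpectrum:
    """Power-spectral scoring of a one-dimensional signal.

    Evaluates the spectrum exactly at each candidate frequency (the 0.5 Hz
    grid does not align with FFT bins at arbitrary data lengths); with
    ``use_harmonic`` the power at ``2 f`` is added.
    """
    values = np.asarray(values, dtype=float).ravel()
    freqs = np.sort(np.asarray(freqs, dtype=float))
    needed = 2 * freqs[-1] if use_harmonic else freqs[-1]
    if needed >= fs / 2:
        raise ValueError(
            f"candidate (or harmonic) frequency {needed} Hz reaches Nyquist {fs / 2} Hz"
        )
    values = values - values.mean()
    scores = np.array(
        [
            _single_freq_power(values, fs, f)
            + (_single_freq_power(values, fs, 2 * f) if use_harmonic else 0.0)
            for f in freqs
        ]
    )
    return ScoreSpectrum(freqs, scores, "psda")


def _score_trajectory(
    values: np.ndarray,
    fs: float,
    template: np.ndarray,
    f: float,
    scorer: str,
    use_harmonic: bool,
) -> float:
    if scorer == "cca":
        return dimred.cca_fit(values[None, :], template).rho
    if scorer == "psda":
        p = _single_freq_power(values - values.mean(), fs, f)
        if use_harmonic and 2 * f < fs / 2:
            p += _single_freq_power(values - values.mean(), fs, 2 * f)
        return p
    raise ValueError(f"unknown trajectory scorer {scorer!r}")


def ussr_pipeline_score(
    epoch: EEGEpoch,
    bank: TemplateBank,
    reducer: str,
    p: USSRParams = USSRParams(),
    scorer: str = "cca",
    *,
    reference_channel: str = "Oz",
    lle_k: int = 40,
    max_points: int = 2000,
    cca_scope: str = "per_frequency",
    psda_use_harmonic: bool = True,
) -> ScoreSpectrum:
    """Reduce -> stochastic-resonance filter -> score, per candidate.

    For the CAR/PCA/MDS/LLE reducers the epoch is reduced once, filtered
    once, and the output trajectory is scored at every candidate.  For the
    CCA reducer in ``per_frequency`` scope, each candidate gets its own
    projection (fitted against that candidate's template), its own filter
    pass, and is scored at that candidate only - this is what produces a
    candidate-resolved coefficient spectrum.  ``single_best`` scope
    instead reuses the projection of the best plain-CCA candidate.
    """
    reducer = reducer.lower()
    if reducer not in dimred.REDUCERS:
        raise ValueError(f"unknown reducer {reducer!r}; expected one of {dimred.REDUCERS}")
    if bank.n_samples != epoch.n_samples:
        raise ValueError("template bank length does not match epoch")
    method = f"{reducer}_ussr"

    if reducer == "cca" and cca_scope == "per_frequency":
        scores = []
        for f in bank.freqs:
            red = dimred.cca_reduce(epoch, bank, f)
            traj = ussr_filter(red.values, p)
            scores.append(
                _score_trajectory(
                    traj.centred(), epoch.fs, bank[f], f, scorer, psda_use_harmonic
                )
            )
        return ScoreSpectrum(np.array(bank.freqs), np.array(scores), method)

    if reducer == "car":
        red = dimred.car_reduce(epoch, reference_channel)
    elif reducer == "pca":
        red = dimred.pca_reduce(epoch)
    elif reducer == "mds":
        red = dimred.mds_reduce(epoch, max_points=max_points)
    elif reducer == "lle":
        red = dimred.lle_reduce(epoch, K=lle_k, max_points=max_points)
    else:  # cca, single_best scope
        if cca_scope != "single_best":
            raise ValueError(f"unknown cca_scope {cca_scope!r}")
        plain = cca_score(epoch, bank)
        f_best = float(plain.freqs[int(np.argmax(plain.scores))])
        red = dimred.cca_reduce(epoch, bank, f_best)

    traj = ussr_filter(red.values, p)
    out = traj.centred()
    scores = np.array(
        [
            _score_trajectory(out, epoch.fs, bank[f], f, scorer, psda_use_harmonic)
            for f in bank.freqs
        ]
    )
    return ScoreSpectrum(np.array(bank.freqs), scores, method)


def score_epoch(
    epoch: EEGEpoch,
    method: str,
    bank: TemplateBank | None = None,
    *,
    candidate_freqs: Sequence[float] | None = None,
    k: int = 2,
    filter_spec: FilterSpec | None = FilterSpec(),
    ussr_params: USSRParams = USSRParams(),
    fbcca_params: FBCCAParams = FBCCAParams(),
    scorer: str = "cca",
    reference_channel: str = "Oz",
    lle_k: int = 40,
    max_points: int = 2000,
    cca_scope: str = "per_frequency",
    psda_use_harmonic: bool = True,
) -> ScoreSpectrum:
    """Full decoding pipeline for one epoch: band-pass, then the chosen
    scorer.  ``method`` is one of :data:`METHODS`.

    Either pass a prebuilt ``bank`` matching the epoch length or
    ``candidate_freqs`` (a bank with ``k`` harmonics is then built).
    """
    method = method.lower()
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if bank is None:
        if candidate_freqs is None:
            raise ValueError("need either a template bank or candidate_freqs")
        bank = make_template_bank(candidate_freqs, k, epoch.fs, epoch.n_samples)
    filtered = bandpass(epoch, filter_spec) if filter_spec is not None else epoch
    if method == "cca":
        return cca_score(filtered, bank)
    if method == "fbcca":
        return fbcca_score(filtered, bank, fbcca_params)
    if method == "psda":
        return psda_score(
            filtered.channel(reference_channel),
            filtered.fs,
            bank.freqs,
            use_harmonic=psda_use_harmonic,
        )
    reducer = method[: -len("_ussr")]
    return ussr_pipeline_score(
        filtered,
        bank,
        reducer,
        ussr_params,
        scorer,
        reference_channel=reference_channel,
        lle_k=lle_k,
        max_points=max_points,
        cca_scope=cca_scope,
        psda_use_harmonic=psda_use_harmonic,
    )


def classify(spectrum: ScoreSpectrum, stimulus_freqs: Sequence[float]) -> Prediction:
    """Pick the stimulus frequency with maximal score.

    The spectrum may cover a wider grid (e.g. 1-40 Hz); only stimulus
    frequencies compete.  Exact ties go to the lowest frequency and are
    flagged (and logged).
    """
    stimulus_freqs = sorted(float(f) for f in stimulus_freqs)
    if not stimulus_freqs:
        raise ValueError("empty stimulus frequency set")
    scores = np.array([spectrum.score_at(f) for f in stimulus_freqs])
    best = int(np.argmax(scores))  # argmax returns the first (lowest-f) maximum
    tie = bool(np.sum(scores == scores[best]) > 1)
    if tie:
        log.warning(
            "score tie at %.6g; broke toward lowest frequency %.3g Hz",
            scores[best],
            stimulus_freqs[best],
        )
    return Prediction(freq=stimulus_freqs[best], tie=tie)
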