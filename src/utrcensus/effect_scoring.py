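"""Variant-effect aggregation schemes over supplied prediction arrays.

Three adapters turn raw deep-learning model outputs into per-variant
effect scores; none of them runs a network — they consume numeric
predictions produced by a model runner (or by the synthetic generator):

* **transcription effect** (promoter-level models): strand-averaged
  prediction tensors are subset to the CAGE tracks and to the center
  window +/- 2; each track is summed over the windows, shifted by a
  pseudocount of one and log2-transformed; the sequence score is the mean
  over tracks, and the effect is alt minus ref.
* **stability effect** (mRNA half-life ensembles): the score of a
  sequence is the mean prediction over the ensemble's cross-validation
  folds; the effect is alt minus ref.
* **ORF effect** (ribosome-load models): the effect is the predicted
  mean-ribosome-load fold change, reported as log2 ratio by default so
  that the absolute value is symmetric for increases and decreases.

The module also builds the six-channel input track used by the stability
model (one-hot sequence, coding-frame indicator, splice-site indicator)
and annotates variants with conservation scores (max over the reference
span for multi-base variants).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import ConservationTrack, VariantRecord

__all__ = [
    "PredictionTensor",
    "EffectScore",
    "SixChannelTrack",
    "ConservationAnnotation",
    "transcription_effect",
    "stability_effect",
    "orf_effect",
    "build_six_channel_track",
    "phylop_annotate",
]

STRAND_AXIS, WINDOW_AXIS, TRACK_AXIS = 0, 1, 2


@dataclass
class PredictionTensor:
    """Model output for one sequence: (strand, window, track) array.

    ``values`` has shape (2, n_windows, n_tracks) with strand index 0 =
    forward, 1 = reverse. ``center_window`` is metadata supplied by the
    model runner; it is never inferred.
    """

    values: np.ndarray
    center_window: int
    track_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[STRAND_AXIS] != 2:
            raise ValueError(
                f"values must have shape (2, windows, tracks), got {self.values.shape}"
            )
        if not 0 <= self.center_window < self.values.shape[WINDOW_AXIS]:
            raise ValueError("center_window outside the window axis")


@dataclass(frozen=True)
class EffectScore:
    """Per-variant score from one model adapter (raw and absolute)."""

    variant_key: tuple | str
    model: str
    raw: float

    @property
    def abs(self) -> float:
        return abs(self.raw)


@dataclass(frozen=True)
class ConservationAnnotation:
    variant_key: tuple | str
    phylop: float | None  # None when the span is fully uncovered


@dataclass
class SixChannelTrack:
    """Per-nucleotide input track for the mRNA-stability model.

    ``values`` has shape (length, 6): channels 0-3 one-hot A/C/G/T (U),
    channel 4 marks the first base of each codon within the coding
    interval, channel 5 marks splice-site positions. N bases get an
    all-zero one-hot.
    """

    values: np.ndarray
    sequence: str = field(repr=False, default="")


def _sequence_score(
    tensor: PredictionTensor, cage_tracks: Sequence[int], n_windows: int
) -> float:
    half = (n_windows - 1) // 2
    lo = tensor.center_window - half
    hi = tensor.center_window + half + 1
    if lo < 0 or hi > tensor.values.shape[WINDOW_AXIS]:
        raise ValueError(
            f"tensor has too few windows for a {n_windows}-window subset "
            f"around center {tensor.center_window}"
        )
    averaged = tensor.values.mean(axis=STRAND_AXIS)  # (windows, tracks)
    subset = averaged[lo:hi][:, list(cage_tracks)]
    per_track = np.log2(1.0 + subset.sum(axis=0))
    return float(per_track.mean())


def transcription_effect(
    ref: PredictionTensor,
    alt: PredictionTensor,
    cage_tracks: Sequence[int],
    n_windows: int = 5,
    variant_key: tuple | str = "",
    model: str = "transcription",
) -> EffectScore:
    """Aggregate promoter-model predictions into one transcription effect.

    Per sequence: average forward/reverse strands elementwise, subset to
    the center window +/- (n_windows-1)/2 and to ``cage_tracks``, compute
    log2(1 + window-sum) per track, and take the mean over tracks. The
    effect is score(alt) - score(ref).
    """
    if n_windows % 2 == 0 or n_windows < 1:
        raise ValueError("n_windows must be a positive odd integer")
    if len(cage_tracks) == 0:
        raise ValueError("cage_tracks must be non-empty")
    if ref.values.shape != alt.values.shape:
        raise ValueError("ref and alt tensors must share shape")
    raw = _sequence_score(alt, cage_tracks, n_windows) - _sequence_score(
        ref, cage_tracks, n_windows
    )
    return EffectScore(variant_key=variant_key, model=model, raw=raw)


def stability_effect(
    ref_preds: Sequence[float],
    alt_preds: Sequence[float],
    variant_key: tuple | str = "",
    model: str = "stability",
) -> EffectScore:
    """Ensemble-mean difference: mean(alt) - mean(ref) over K fold models."""
    if len(ref_preds) != len(alt_preds):
        raise ValueError(
            f"prediction lists differ in length ({len(ref_preds)} vs {len(alt_preds)})"
        )
    if len(ref_preds) == 0:
        raise ValueError("prediction lists must be non-empty")
    raw = float(np.mean(alt_preds)) - float(np.mean(ref_preds))
    return EffectScore(variant_key=variant_key, model=model, raw=raw)


def orf_effect(
    mrl_ref: float,
    mrl_alt: float,
    scale: str = "log2_ratio",
    variant_key: tuple | str = "",
    model: str = "orf",
) -> EffectScore:
    """Mean-ribosome-load fold change of alt over ref.

    ``scale`` is "log2_ratio" (default; symmetric around zero so the
    absolute value treats load increase and decrease alike) or "ratio".
    """
    if mrl_ref <= 0 or mrl_alt <= 0:
        raise ValueError("mean ribosome loads must be positive")
    if scale == "ratio":
        raw = mrl_alt / mrl_ref
    elif scale == "log2_ratio":
        raw = math.log2(mrl_alt / mrl_ref)
    else:
        raise ValueError(f"scale must be 'ratio' or 'log2_ratio', got {scale!r}")
    return EffectScore(variant_key=variant_key, model=model, raw=raw)


_ONE_HOT = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


def build_six_channel_track(
    sequence: str,
    coding_interval: tuple[int, int] | None = None,
    splice_positions: Sequence[int] = (),
) -> SixChannelTrack:
    """Build the six-channel input track for a transcript sequence.

    ``coding_interval`` is 1-based inclusive in transcript coordinates;
    the frame channel marks the first base of each codon within it.
    ``splice_positions`` are 1-based transcript positions.
    """
    n = len(sequence)
    values = np.zeros((n, 6), dtype=float)
    for i, base in enumerate(sequence.upper()):
        if base == "N":
            continue
        if base not in _ONE_HOT:
            raise ValueError(f"non-ACGTN character {base!r} at position {i + 1}")
        values[i, _ONE_HOT[base]] = 1.0
    if coding_interval is not None:
        cds_start, cds_end = coding_interval
        if not 1 <= cds_start <= cds_end <= n:
            raise ValueError("coding_interval outside sequence bounds")
        values[cds_start - 1 : cds_end : 3, 4] = 1.0
    for pos in splice_positions:
        if not 1 <= pos <= n:
            raise ValueError(f"splice position {pos} outside sequence bounds")
        values[pos - 1, 5] = 1.0
    return SixChannelTrack(values=values, sequence=sequence)


def phylop_annotate(
    variant: VariantRecord, track: ConservationTrack
) -> ConservationAnnotation:
    """Annotate a variant with its conservation score.

    Single-base reference: the score at the variant position. Multi-base
    reference: the maximum score across [pos, pos + len(ref) - 1];
    uncovered positions inside the span are ignored, and a fully
    uncovered span yields ``phylop=None``.
    """
    score = track.max_over(variant.chrom, variant.pos, variant.end)
    return ConservationAnnotation(variant_key=variant.key, phylop=score)
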