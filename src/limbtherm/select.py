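"""Deterministic frame-quality scoring and best-K frame selection.

Clinical thermal videos contain frames where the subject has moved and the
target region is no longer properly presented. Instead of a manual visual
scan, each frame is scored by its centred (Pearson) correlation with the
recording's pixelwise median frame — the median is robust to a minority of
moved frames, so motion-corrupted frames score low — and the K
highest-scoring frames are kept, ties broken towards the earlier frame.
One selection is made per recording and shared by all ROIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import ThermalRecording

__all__ = ["FrameQuality", "score_frames", "select_best_frames", "frame_quality_report"]

DEFAULT_K = 20


@dataclass(frozen=True)
class FrameQuality:
    """Similarity of one frame to the recording's median reference."""

    frame_index: int
    score: float
    accepted: bool = False


def score_frames(recording: ThermalRecording) -> list[FrameQuality]:
    """Centred correlation of every frame with the pixelwise median frame.

    Conventions: a single-frame recording scores 1; a zero-variance frame
    (or reference) scores 0.
    """
    n = len(recording)
    if n == 1:
        return [FrameQuality(frame_index=0, score=1.0)]
    stack = recording.temps_stack()
    ref = np.median(stack, axis=0)
    ref_c = (ref - ref.mean()).ravel()
    ref_norm = np.linalg.norm(ref_c)
    out = []
    for i in range(n):
        x = stack[i]
        x_c = (x - x.mean()).ravel()
        x_norm = np.linalg.norm(x_c)
        if x_norm == 0.0 or ref_norm == 0.0:
            score = 0.0
        else:
            score = float(np.dot(x_c, ref_c) / (x_norm * ref_norm))
        out.append(FrameQuality(frame_index=i, score=score))
    return out


def select_best_frames(recording: ThermalRecording, k: int = DEFAULT_K) -> list[int]:
    """Indices of the ``k`` highest-scoring frames, in ascending index order.

    Ties break towards the lower index. If the recording holds fewer than
    ``k`` frames, all indices are returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    qualities = score_frames(recording)
    n = len(qualities)
    if n < k:
        warnings.warn(
            f"recording has only {n} frames; requested k={k}, keeping all",
            stacklevel=2,
        )
        return list(range(n))
    ranked = sorted(qualities, key=lambda q: (-q.score, q.frame_index))
    return sorted(q.frame_index for q in ranked[:k])


def frame_quality_report(
    recording: ThermalRecording, k: int = DEFAULT_K
) -> list[FrameQuality]:
    """Per-frame scores with the accepted flag set for the selected frames."""
    selected = set(select_best_frames(recording, k))
    return [
        FrameQuality(q.frame_index, q.score, accepted=q.frame_index in selected)
        for q in score_frames(recording)
    ]
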