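"""Convenience chains over the module primitives.

The canonical path from an aligned recording to TAP: artifact-filter the
temperature channel, percentile-normalize all three channels (inverting
temperature, which runs high during rest), and average.
"""

from __future__ import annotations

from .series import (SubjectRecording, TEMPERATURE_ARTIFACT_RULE, filter_artifacts,
                     normalize_percentile)
from .tap import TapSeries, compose_tap

__all__ = ["recording_tap", "normalized_channels"]


def normalized_channels(recording: SubjectRecording, filter_temperature: bool = True):
    """Per-subject normalized (inverted T, A, P) triplet on [0, 1]."""
    temp = recording.temperature
    if filter_temperature:
        temp = filter_artifacts(temp, TEMPERATURE_ARTIFACT_RULE)
    t_inv = normalize_percentile(temp, invert=True)
    a = normalize_percentile(recording.activity)
    p = normalize_percentile(recording.position)
    return t_inv, a, p


def recording_tap(recording: SubjectRecording, filter_temperature: bool = True,
                  missing: str = "propagate") -> TapSeries:
    """Fuse one subject's recording into its TAP series."""
    t_inv, a, p = normalized_channels(recording, filter_temperature)
    return compose_tap(t_inv, a, p, missing=missing)
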