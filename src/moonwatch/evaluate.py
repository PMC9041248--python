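"""Scoring detected transit tracks against simulator ground truth."""

from __future__ import annotations

import math
from dataclasses import dataclass

from .detect import TransitTrack
from .scene import GroundTruthLog, TransitTruth

__all__ = ["MatchResult", "match_tracks"]


@dataclass
class MatchResult:
    n_truth: int
    n_tracks: int
    matches: list[tuple[int, int]]  # (truth index, track index)
    precision: float
    recall: float

    @property
    def n_matched(self) -> int:
        return len(self.matches)


def match_tracks(
    truth: GroundTruthLog | list[TransitTruth],
    tracks: list[TransitTrack],
    max_dist_px: float = 8.0,
    min_visible_frames: int = 1,
) -> MatchResult:
    """Greedy one-to-one matching of tracks to ground-truth transits.

    A (truth, track) pair scores the number of frames where the track's
    detection lies within ``max_dist_px`` of the truth centroid; pairs are
    matched in descending score order.  Precision counts matched tracks
    over all tracks, recall matched truths over visible truths.
    """
    truths = truth.visible_transits(min_visible_frames) if isinstance(
        truth, GroundTruthLog) else truth
    scores = []
    for ti, tr in enumerate(truths):
        pos = {
            f: c for f, c, v in zip(tr.frames, tr.centroids_px, tr.visible) if v
        }
        for ki, track in enumerate(tracks):
            s = 0
            for det in track.detections:
                p = pos.get(det.frame_index)
                if p is not None and math.hypot(
                    det.centroid_px[0] - p[0], det.centroid_px[1] - p[1]
                ) <= max_dist_px:
                    s += 1
            if s > 0:
                scores.append((s, ti, ki))
    scores.sort(reverse=True)
    used_truth: set[int] = set()
    used_track: set[int] = set()
    matches = []
    for s, ti, ki in scores:
        if ti in used_truth or ki in used_track:
            continue
        matches.append((ti, ki))
        used_truth.add(ti)
        used_track.add(ki)
    n_truth, n_tracks = len(truths), len(tracks)
    precision = len(matches) / n_tracks if n_tracks else 1.0
    recall = len(matches) / n_truth if n_truth else 1.0
    return MatchResult(n_truth, n_tracks, matches, precision, recall)
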