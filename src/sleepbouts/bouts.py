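"""Bout segmentation, REM duration split, time binning and NREM latency.

A *bout* (episode) is a maximal run of consecutive epochs scored in the same
vigilance state.  Bout-duration histograms in rodents are strongly
right-skewed with a "spike and slab" structure -- many very short bouts plus
rare long ones -- which is most pronounced for REM sleep; REM bouts are
therefore split at a 4-epoch (16 s) cutoff into short (REMS_S) and long
(REMS_L) classes that downstream statistics treat as distinct states.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .hypnogram import NREM_STATES, SPLIT_STATES, Hypnogram

#: Sentinel bin value for bouts whose onset falls past the analysis window.
OUTSIDE = "outside"

#: Default REM short/long cutoff: bouts of at most 4 epochs (16 s) are short.
REMS_CUTOFF_EPOCHS = 4


@dataclass(frozen=True)
class Bout:
    """A maximal run of identical state: onset, length and wall duration."""

    state: str
    onset_epoch: int
    n_epochs: int
    duration_s: float

    def __post_init__(self) -> None:
        if self.n_epochs < 1:
            raise ValueError("bout must span at least one epoch")


@dataclass(frozen=True)
class LatencyParams:
    """Qualification rule for the first sustained NREM episode.

    An episode must accumulate at least ``min_episode_epochs`` of NREM
    content (45 epochs = 3 min by default) while never being interrupted by
    more than ``max_consecutive_interrupt_epochs`` consecutive non-NREM
    epochs (14) nor by more than ``max_cumulative_interrupt_epochs``
    non-NREM epochs in total (60 epochs = 240 s).  With
    ``episode_length_counts_interruptions`` the 3-min clause is read as wall
    time from episode onset instead of NREM content.
    """

    min_episode_epochs: int = 45
    max_consecutive_interrupt_epochs: int = 14
    max_cumulative_interrupt_epochs: int = 60
    episode_length_counts_interruptions: bool = False

    def __post_init__(self) -> None:
        if min(
            self.min_episode_epochs,
            self.max_consecutive_interrupt_epochs,
            self.max_cumulative_interrupt_epochs,
        ) <= 0:
            raise ValueError("latency parameters must be positive")


def segment_bouts(h: Hypnogram) -> list[Bout]:
    """Run-length encode a hypnogram into its ordered bout sequence."""
    codes = pd.Categorical(h.states).codes
    change = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(codes)]))
    return [
        Bout(
            state=h.states[s],
            onset_epoch=int(s),
            n_epochs=int(e - s),
            duration_s=float((e - s) * h.epoch_seconds),
        )
        for s, e in zip(starts, ends)
    ]


def reclassify_rems(
    bouts: Sequence[Bout], cutoff_epochs: int = REMS_CUTOFF_EPOCHS
) -> list[Bout]:
    """Split raw REMS bouts into REMS_S (<= cutoff epochs) and REMS_L.

    Non-REM bouts pass through unchanged and order is preserved.  Input that
    already contains REMS_S/REMS_L is rejected.
    """
    if any(b.state in ("REMS_S", "REMS_L") for b in bouts):
        raise ValueError("bouts are already REM-reclassified")
    out = []
    for b in bouts:
        if b.state == "REMS":
            label = "REMS_S" if b.n_epochs <= cutoff_epochs else "REMS_L"
            b = Bout(label, b.onset_epoch, b.n_epochs, b.duration_s)
        out.append(b)
    return out


def bin_bouts(
    bouts: Sequence[Bout], bin_epochs: int = 900, n_bins: int = 3
) -> list[int | str]:
    """Assign each bout to a time bin by its ONSET epoch.

    Bin ``k`` covers onsets in ``[k*bin_epochs, (k+1)*bin_epochs)``; onsets at
    or past ``n_bins*bin_epochs`` map to :data:`OUTSIDE`.  A bout spanning a
    bin boundary is counted once, in its onset bin.
    """
    if bin_epochs <= 0 or n_bins <= 0:
        raise ValueError("bin_epochs and n_bins must be positive")
    out: list[int | str] = []
    for b in bouts:
        k = b.onset_epoch // bin_epochs
        out.append(int(k) if k < n_bins else OUTSIDE)
    return out


def nrem_latency(
    h: Hypnogram, params: LatencyParams = LatencyParams()
) -> Optional[float]:
    """Seconds from drug administration to the first qualifying NREM episode.

    Scanning starts at ``h.treatment_epoch``.  A candidate episode begins at
    the first NREM-state epoch (NREM = S1, S2 or IS).  The episode fails the
    moment a consecutive non-NREM run exceeds
    ``params.max_consecutive_interrupt_epochs`` or cumulative non-NREM epochs
    exceed ``params.max_cumulative_interrupt_epochs``; scanning then resumes
    after the run that caused the failure.  The episode qualifies the moment
    its NREM content reaches ``params.min_episode_epochs``, and the latency
    is the episode onset relative to treatment, in seconds.  Returns ``None``
    when no episode qualifies before the end of the recording.
    """
    states = h.states
    n = len(states)
    is_nrem = [s in NREM_STATES for s in states]
    i = h.treatment_epoch
    while i < n:
        while i < n and not is_nrem[i]:
            i += 1
        if i >= n:
            return None
        start = i
        nrem_count = 0
        cum_interrupt = 0
        consec_interrupt = 0
        j = start
        failed = False
        while j < n:
            if is_nrem[j]:
                consec_interrupt = 0
                nrem_count += 1
                content = (
                    j - start + 1
                    if params.episode_length_counts_interruptions
                    else nrem_count
                )
                if content >= params.min_episode_epochs:
                    return float((start - h.treatment_epoch) * h.epoch_seconds)
            else:
                consec_interrupt += 1
                cum_interrupt += 1
                if (
                    consec_interrupt > params.max_consecutive_interrupt_epochs
                    or cum_interrupt > params.max_cumulative_interrupt_epochs
                ):
                    # skip the remainder of the interrupting run, then rescan
                    while j + 1 < n and not is_nrem[j + 1]:
                        j += 1
                    failed = True
                    break
            j += 1
        if not failed:
            return None
        i = j + 1
    return None


def bout_table(
    hypnograms: Iterable[Hypnogram],
    cutoff_epochs: int = REMS_CUTOFF_EPOCHS,
    bin_epochs: int = 900,
    n_bins: int = 3,
) -> pd.DataFrame:
    """Segment, REM-split and bin a whole study into one long bout table.

    Columns: subject_id, treatment, state, onset_epoch, n_epochs,
    duration_s, bin (int bin index or the string ``"outside"``).
    """
    rows = []
    for h in hypnograms:
        bouts = reclassify_rems(segment_bouts(h), cutoff_epochs)
        bins = bin_bouts(bouts, bin_epochs=bin_epochs, n_bins=n_bins)
        for b, k in zip(bouts, bins):
            rows.append(
                (h.subject_id, h.treatment, b.state, b.onset_epoch,
                 b.n_epochs, b.duration_s, k)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id", "treatment", "state", "onset_epoch",
            "n_epochs", "duration_s", "bin",
        ],
    )


def bouts_by_subject(
    hypnograms: Iterable[Hypnogram], cutoff_epochs: int = REMS_CUTOFF_EPOCHS
) -> dict[str, list[Bout]]:
    """Per-subject ordered, REM-reclassified bout sequences (one treatment)."""
    out: dict[str, list[Bout]] = {}
    for h in hypnograms:
        out[h.subject_id] = reclassify_rems(segment_bouts(h), cutoff_epochs)
    return out
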