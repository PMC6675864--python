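"""Epoch-scored hypnograms: the container type and its CSV round-trip.

A hypnogram is the time-ordered sequence of vigilance-state labels assigned
to fixed-length scoring epochs (4 s by default) for one animal under one
treatment.  Six raw states are recognised -- active wake (AW), passive wake
(PW), light and deep slow-wave sleep (S1, S2), intermediate stage (IS) and
REM sleep (REMS) -- plus the two duration-split REM labels (REMS_S, REMS_L)
that downstream bout analysis introduces.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

#: Raw scoring labels, as they come out of epoch-by-epoch sleep staging.
RAW_STATES: tuple[str, ...] = ("AW", "PW", "S1", "S2", "IS", "REMS")

#: Labels after REM bouts have been split by duration into short/long.
SPLIT_STATES: tuple[str, ...] = ("AW", "PW", "S1", "S2", "IS", "REMS_S", "REMS_L")

#: The non-REM sleep superset used by the latency rule.
NREM_STATES: frozenset[str] = frozenset({"S1", "S2", "IS"})

_ALL_STATES = frozenset(RAW_STATES) | frozenset(SPLIT_STATES)

REQUIRED_COLUMNS = ("subject_id", "treatment", "epoch_index", "state")


class HypnogramError(ValueError):
    """Base class for hypnogram I/O and validation failures."""


class FormatError(HypnogramError):
    """The file does not have the expected columns/shape."""


class ValidationError(HypnogramError):
    """The file parses but its content violates hypnogram invariants."""


@dataclass(frozen=True)
class Hypnogram:
    """One subject x treatment recording as a sequence of epoch state codes.

    Parameters
    ----------
    subject_id : str
        Opaque subject identifier.
    treatment : str
        Dose label, e.g. ``"VEH"``, ``"AM5"``, ``"AM10"``.
    states : tuple of str
        One state label per epoch, 0-based; epoch ``i`` covers the half-open
        interval ``[i * epoch_seconds, (i + 1) * epoch_seconds)``.
    epoch_seconds : float
        Scoring epoch length in seconds (default 4).
    treatment_epoch : int
        0-based index of the epoch at which the drug was administered
        (default 0, i.e. the recording starts at injection).
    """

    subject_id: str
    treatment: str
    states: tuple[str, ...] = field(default=())
    epoch_seconds: float = 4.0
    treatment_epoch: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        if len(self.states) < 1:
            raise ValidationError("hypnogram must contain at least one epoch")
        bad = sorted({s for s in self.states if s not in _ALL_STATES})
        if bad:
            raise ValidationError(f"unknown state label(s): {bad}")
        present = set(self.states)
        if "REMS" in present and present & {"REMS_S", "REMS_L"}:
            raise ValidationError(
                "hypnogram mixes raw REMS with reclassified REMS_S/REMS_L"
            )
        if self.epoch_seconds <= 0:
            raise ValidationError("epoch_seconds must be positive")
        if not 0 <= self.treatment_epoch < len(self.states):
            raise ValidationError(
                f"treatment_epoch {self.treatment_epoch} outside "
                f"[0, {len(self.states)})"
            )

    @property
    def n_epochs(self) -> int:
        return len(self.states)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_seconds


def _split_comments(text: str) -> tuple[list[str], str, int]:
    """Separate leading '#' comment lines from the CSV body.

    Returns (comment lines, body, number of lines consumed before the header).
    """
    lines = text.splitlines(keepends=True)
    comments: list[str] = []
    i = 0
    while i < len(lines) and lines[i].lstrip().startswith("#"):
        comments.append(lines[i].strip())
        i += 1
    return comments, "".join(lines[i:]), i


def read_hypnogram(path: str | Path) -> list[Hypnogram]:
    """Read epoch-scored hypnograms from CSV, one per (subject, treatment).

    The file must carry the header columns ``subject_id, treatment,
    epoch_index, state`` (extra columns are ignored, except an optional
    ``treatment_epoch`` column written by :func:`write_hypnogram`).  An
    optional leading comment line ``# epoch_seconds=4`` sets the epoch
    length; 4 s is assumed when absent.  Epoch indices must run 0..n-1
    without gaps or duplicates within each group; state labels are matched
    case-insensitively.

    Returns the groups in file order.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    comments, body, offset = _split_comments(text)

    epoch_seconds = 4.0
    for line in comments:
        m = re.match(r"#\s*epoch_seconds\s*=\s*([0-9.eE+-]+)", line)
        if m:
            epoch_seconds = float(m.group(1))

    if not body.strip():
        return []
    df = pd.read_csv(io.StringIO(body), dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column: {col!r}")
    if df.empty:
        return []

    # 1-based data row numbers in the original file (header + comments offset)
    df["_row"] = df.index + offset + 2

    df["state"] = df["state"].str.strip().str.upper()
    bad = df.loc[~df["state"].isin(_ALL_STATES)]
    if not bad.empty:
        first = bad.iloc[0]
        raise ValidationError(
            f"unknown state label {first['state']!r} at row {first['_row']}"
        )
    try:
        df["epoch_index"] = df["epoch_index"].astype(int)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-integer epoch_index: {exc}") from exc

    out: list[Hypnogram] = []
    for (subject, treatment), grp in df.groupby(
        ["subject_id", "treatment"], sort=False
    ):
        grp = grp.sort_values("epoch_index")
        idx = grp["epoch_index"].to_numpy()
        if len(set(idx)) != len(idx):
            raise ValidationError(
                f"duplicate epoch_index in group ({subject}, {treatment})"
            )
        if idx[0] != 0 or (idx[1:] - idx[:-1] != 1).any():
            raise ValidationError(
                f"non-contiguous epoch_index in group ({subject}, {treatment}): "
                f"expected 0..{len(idx) - 1}"
            )
        treatment_epoch = 0
        if "treatment_epoch" in grp.columns:
            vals = set(grp["treatment_epoch"].astype(str))
            if len(vals) > 1:
                raise ValidationError(
                    f"inconsistent treatment_epoch in group ({subject}, {treatment})"
                )
            treatment_epoch = int(float(vals.pop()))
        out.append(
            Hypnogram(
                subject_id=str(subject),
                treatment=str(treatment),
                states=tuple(grp["state"]),
                epoch_seconds=epoch_seconds,
                treatment_epoch=treatment_epoch,
            )
        )
    return out


def write_hypnogram(hypnograms: Iterable[Hypnogram], path: str | Path) -> None:
    """Write hypnograms to CSV such that :func:`read_hypnogram` round-trips.

    An empty collection yields a header-only file.  All hypnograms in one
    file must share ``epoch_seconds`` (it is file-level metadata).
    """
    hypnograms = list(hypnograms)
    path = Path(path)
    eps = {h.epoch_seconds for h in hypnograms} or {4.0}
    if len(eps) > 1:
        raise ValidationError(
            f"hypnograms in one file must share epoch_seconds, got {sorted(eps)}"
        )
    epoch_seconds = eps.pop()
    eps_repr = (
        str(int(epoch_seconds)) if epoch_seconds == int(epoch_seconds)
        else repr(epoch_seconds)
    )
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# epoch_seconds={eps_repr}\n")
        fh.write("subject_id,treatment,epoch_index,state,treatment_epoch\n")
        for h in hypnograms:
            for i, s in enumerate(h.states):
                fh.write(
                    f"{h.subject_id},{h.treatment},{i},{s},{h.treatment_epoch}\n"
                )


def group_by_treatment(
    hypnograms: Sequence[Hypnogram],
) -> dict[str, dict[str, Hypnogram]]:
    """Index hypnograms as treatment -> subject -> Hypnogram."""
    out: dict[str, dict[str, Hypnogram]] = {}
    for h in hypnograms:
        out.setdefault(h.treatment, {})[h.subject_id] = h
    return out
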