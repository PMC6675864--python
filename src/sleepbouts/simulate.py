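"""Semi-Markov hypnogram simulator.

The generator emulates the statistical structure the analysis assumes for a
rat sleep study: 6 subjects x 3 treatments x 3 h of 4-s epochs, with (i)
right-skewed "spike and slab" dwell-time distributions per state, modelled
as a two-component mixture of shifted-geometric laws; (ii) strongly
non-random state succession through an embedded transition matrix with a
zero diagonal; and (iii) dose- and hour-dependent shifts of the transition
matrix with dwell mixtures shared across treatments -- i.e. the drug
mechanism acts on transition frequencies, not on state durations.  An
optional per-treatment dwell-scaling knob simulates the alternative
duration mechanism for power comparisons.

The default matrices are qualitative mimics of vehicle-like and
antagonist-like traffic (wake-dominated rows under high dose, starved
IS/S2 entries), not estimates of any animal's physiology.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from .hypnogram import RAW_STATES, Hypnogram

_ROW_TOL = 1e-9


@dataclass(frozen=True)
class DwellMixture:
    """Two-component shifted-geometric dwell law for one state.

    With probability ``p_short`` a bout length is drawn from the short
    component, else from the long one; each component is geometric on
    {1, 2, ...} with the given mean in epochs, so every bout lasts at
    least one epoch and the mixture mean is analytic:
    ``p_short * mean_short + (1 - p_short) * mean_long``.
    """

    p_short: float
    mean_short_epochs: float
    mean_long_epochs: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_short <= 1.0:
            raise ValueError("p_short must be in [0, 1]")
        if not 1.0 <= self.mean_short_epochs <= self.mean_long_epochs:
            raise ValueError(
                "need 1 <= mean_short_epochs <= mean_long_epochs"
            )

    @property
    def mean_epochs(self) -> float:
        return (
            self.p_short * self.mean_short_epochs
            + (1.0 - self.p_short) * self.mean_long_epochs
        )

    def sample(self, rng: np.random.Generator, scale: float = 1.0) -> int:
        """Draw one dwell length in epochs (>= 1)."""
        mean = (
            self.mean_short_epochs
            if rng.random() < self.p_short
            else self.mean_long_epochs
        )
        mean = max(1.0, mean * scale)
        # geometric on {1, 2, ...} with success prob 1/mean has mean `mean`
        return int(rng.geometric(1.0 / mean))


@dataclass(frozen=True)
class SimConfig:
    """Full specification of a simulated study.

    ``P[treatment]`` is a list of one K x K embedded transition matrix per
    hour (zero diagonal, rows summing to 1); ``dwell`` maps each raw state
    to its mixture, shared across treatments; ``dwell_scale`` optionally
    rescales dwell means per treatment (default 1 everywhere -- the
    transition-frequency mechanism).  The whole study is a pure function of
    ``seed``.
    """

    states: tuple[str, ...] = RAW_STATES
    treatments: tuple[str, ...] = ("VEH", "AM5", "AM10")
    P: Mapping[str, tuple[np.ndarray, ...]] = field(default_factory=dict)
    dwell: Mapping[str, DwellMixture] = field(default_factory=dict)
    dwell_scale: Mapping[str, float] = field(default_factory=dict)
    n_subjects: int = 6
    n_epochs: int = 2700
    hour_epochs: int = 900
    epoch_seconds: float = 4.0
    initial_state: str = "AW"
    seed: int = 0

    def __post_init__(self) -> None:
        K = len(self.states)
        P = {
            tr: tuple(np.asarray(m, dtype=float) for m in mats)
            for tr, mats in self.P.items()
        }
        object.__setattr__(self, "P", P)
        for tr in self.treatments:
            if tr not in P:
                raise ValueError(f"no transition matrices for treatment {tr!r}")
            for h, m in enumerate(P[tr]):
                if m.shape != (K, K):
                    raise ValueError(
                        f"P[{tr!r}][{h}] must be {K}x{K}, got {m.shape}"
                    )
                if np.abs(np.diag(m)).max() > 0:
                    raise ValueError(f"P[{tr!r}][{h}] has nonzero diagonal")
                if (m < 0).any():
                    raise ValueError(f"P[{tr!r}][{h}] has negative entries")
                if np.abs(m.sum(axis=1) - 1.0).max() > _ROW_TOL:
                    raise ValueError(f"rows of P[{tr!r}][{h}] must sum to 1")
        for s in self.states:
            if s not in self.dwell:
                raise ValueError(f"no dwell mixture for state {s!r}")
        if self.initial_state not in self.states:
            raise ValueError(f"unknown initial state {self.initial_state!r}")
        if min(self.n_subjects, self.n_epochs, self.hour_epochs) <= 0:
            raise ValueError("study dimensions must be positive")

    @property
    def subjects(self) -> tuple[str, ...]:
        return tuple(f"rat{i + 1}" for i in range(self.n_subjects))

    def n_hours(self, treatment: str) -> int:
        return len(self.P[treatment])

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "states": list(self.states),
            "treatments": list(self.treatments),
            "P": {
                tr: [m.tolist() for m in mats] for tr, mats in self.P.items()
            },
            "dwell": {
                s: {
                    "p_short": d.p_short,
                    "mean_short_epochs": d.mean_short_epochs,
                    "mean_long_epochs": d.mean_long_epochs,
                }
                for s, d in self.dwell.items()
            },
            "dwell_scale": dict(self.dwell_scale),
            "n_subjects": self.n_subjects,
            "n_epochs": self.n_epochs,
            "hour_epochs": self.hour_epochs,
            "epoch_seconds": self.epoch_seconds,
            "initial_state": self.initial_state,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(
            states=tuple(d["states"]),
            treatments=tuple(d["treatments"]),
            P={tr: tuple(np.asarray(m) for m in mats) for tr, mats in d["P"].items()},
            dwell={s: DwellMixture(**v) for s, v in d["dwell"].items()},
            dwell_scale=dict(d.get("dwell_scale", {})),
            n_subjects=int(d["n_subjects"]),
            n_epochs=int(d["n_epochs"]),
            hour_epochs=int(d["hour_epochs"]),
            epoch_seconds=float(d["epoch_seconds"]),
            initial_state=str(d.get("initial_state", "AW")),
            seed=int(d["seed"]),
        )

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "SimConfig":
        p = Path(source)
        text = p.read_text(encoding="utf-8") if p.exists() else str(source)
        return cls.from_dict(yaml.safe_load(text))


def tilt_matrix(
    P: np.ndarray,
    states: Sequence[str],
    col_factors: Mapping[str, float],
) -> np.ndarray:
    """Multiply destination-state columns by factors and renormalize rows.

    The diagonal stays zero.  This is the knob used to construct dose
    effects (e.g. tripling all traffic into AW while starving IS and S2)
    and planted effects in tests.
    """
    out = np.asarray(P, dtype=float).copy()
    for s, f in col_factors.items():
        out[:, list(states).index(s)] *= f
    np.fill_diagonal(out, 0.0)
    rowsum = out.sum(axis=1, keepdims=True)
    if (rowsum == 0).any():
        raise ValueError("a row lost all mass under the tilt")
    return out / rowsum


def _vehicle_hour_matrices() -> list[np.ndarray]:
    # state order: AW, PW, S1, S2, IS, REMS
    base = np.array(
        [
            #  AW    PW    S1    S2    IS   REMS
            [0.00, 0.70, 0.25, 0.02, 0.01, 0.02],  # AW
            [0.50, 0.00, 0.45, 0.02, 0.01, 0.02],  # PW
            [0.15, 0.30, 0.00, 0.50, 0.03, 0.02],  # S1
            [0.05, 0.10, 0.35, 0.00, 0.30, 0.20],  # S2
            [0.05, 0.05, 0.15, 0.25, 0.00, 0.50],  # IS
            [0.25, 0.20, 0.10, 0.05, 0.40, 0.00],  # REMS
        ]
    )
    # circadian drift across the passive phase: wake traffic relaxes, sleep
    # and REM/IS returns pick up in hours 2-3
    h2 = tilt_matrix(base, RAW_STATES, {"AW": 0.8, "S2": 1.3, "REMS": 1.3})
    h3 = tilt_matrix(base, RAW_STATES, {"AW": 0.7, "PW": 0.9, "S2": 1.5, "IS": 1.2, "REMS": 1.5})
    return [base, h2, h3]


def default_config(seed: int = 20190726) -> SimConfig:
    """A fully specified 3-treatment x 3-hour study configuration.

    Vehicle traffic routes AW<->PW<->S1->S2 with S2->IS->REMS returns and a
    mild circadian drift over the three hours; the 5 mg/kg-like treatment
    tilts all rows moderately toward AW while starving IS and REMS; the
    10 mg/kg-like treatment does so strongly and additionally starves S2.
    Dwell mixtures are shared across treatments (spike-and-slab per state),
    so any treatment contrast in the output comes from transition
    frequencies alone.
    """
    veh = _vehicle_hour_matrices()
    am5 = [
        tilt_matrix(m, RAW_STATES, {"AW": 1.8, "IS": 0.4, "REMS": 0.5})
        for m in veh
    ]
    am10 = [
        tilt_matrix(
            m, RAW_STATES, {"AW": 3.0, "PW": 1.2, "S2": 0.35, "IS": 0.25, "REMS": 0.35}
        )
        for m in veh
    ]
    dwell = {
        # p_short, short mean, long mean (epochs of 4 s)
        "AW": DwellMixture(0.60, 2.0, 40.0),
        "PW": DwellMixture(0.60, 2.0, 15.0),
        "S1": DwellMixture(0.50, 2.0, 10.0),
        "S2": DwellMixture(0.45, 3.0, 30.0),
        "IS": DwellMixture(0.70, 2.0, 6.0),
        "REMS": DwellMixture(0.55, 2.0, 22.0),
    }
    return SimConfig(
        P={"VEH": tuple(veh), "AM5": tuple(am5), "AM10": tuple(am10)},
        dwell=dwell,
        seed=seed,
    )


def derive_seed(seed: int, subject: str, treatment: str) -> int:
    """Deterministic per-hypnogram seed: CRC32 of 'seed:subject:treatment'."""
    return zlib.crc32(f"{seed}:{subject}:{treatment}".encode()) & 0x7FFFFFFF


def simulate_hypnogram(
    cfg: SimConfig,
    subject: str,
    treatment: str,
    seed: Optional[int] = None,
) -> Hypnogram:
    """Simulate one subject x treatment recording.

    Alternating draws: the next state comes from the current hour's
    transition-matrix row, the dwell length from the state's mixture; the
    sequence is concatenated until ``n_epochs`` is reached (final bout
    truncated).  The hour regime is selected by the epoch at which each
    transition occurs; a bout begun under one regime keeps its drawn dwell.
    """
    if treatment not in cfg.P:
        raise ValueError(f"unknown treatment {treatment!r}")
    if seed is None:
        seed = derive_seed(cfg.seed, subject, treatment)
    rng = np.random.default_rng(seed)
    scale = float(cfg.dwell_scale.get(treatment, 1.0))
    mats = cfg.P[treatment]
    n_hours = len(mats)
    idx = {s: i for i, s in enumerate(cfg.states)}

    states: list[str] = []
    current = cfg.initial_state
    pos = 0
    while pos < cfg.n_epochs:
        dwell = cfg.dwell[current].sample(rng, scale=scale)
        take = min(dwell, cfg.n_epochs - pos)
        states.extend([current] * take)
        pos += take
        if pos >= cfg.n_epochs:
            break
        hour = min(pos // cfg.hour_epochs, n_hours - 1)
        row = mats[hour][idx[current]]
        current = cfg.states[rng.choice(len(cfg.states), p=row)]
    return Hypnogram(
        subject_id=subject,
        treatment=treatment,
        states=tuple(states),
        epoch_seconds=cfg.epoch_seconds,
        treatment_epoch=0,
    )


def simulate_study(cfg: SimConfig) -> list[Hypnogram]:
    """Simulate the full study: every subject under every treatment."""
    return [
        simulate_hypnogram(cfg, subject, treatment)
        for treatment in cfg.treatments
        for subject in cfg.subjects
    ]


def sample_transitions(
    P: np.ndarray,
    states: Sequence[str],
    n_transitions: int,
    rng: np.random.Generator,
    initial_state: Optional[str] = None,
) -> np.ndarray:
    """Observed K x K transition counts from one run of the embedded chain.

    Dwell times are irrelevant to succession statistics, so this samples
    the embedded (jump) chain directly; useful for calibration and power
    studies of the z-statistics.
    """
    P = np.asarray(P, dtype=float)
    K = len(states)
    current = (
        list(states).index(initial_state)
        if initial_state is not None
        else int(rng.integers(K))
    )
    O = np.zeros((K, K), dtype=int)
    # pre-draw uniforms and invert each row's CDF step by step
    cdfs = np.cumsum(P, axis=1)
    u = rng.random(n_transitions)
    for k in range(n_transitions):
        nxt = int(np.searchsorted(cdfs[current], u[k], side="right"))
        nxt = min(nxt, K - 1)
        O[current, nxt] += 1
        current = nxt
    return O
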