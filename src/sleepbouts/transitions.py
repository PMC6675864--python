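"""Transition heatmaps: cross-tabulated bout successions and z-statistics.

For each pair of consecutive bouts within a subject, the succession
state_i -> state_j is tallied into a K x K contingency table with a
structurally zero diagonal (a bout is by definition followed by a bout of a
different state).  Under the "no preference" null the transition
probabilities factorise into the product of the row and column marginals;
the standardized difference between observed and expected cell values --
the z-statistic familiar from categorical data analysis -- measures how
strongly each specific succession is preferred (z > 0) or inhibited
(z < 0), with |z| > 2 the conventional significance rule of thumb.  Cells
with fewer than five observations, and the diagonal, are masked as not
estimable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .bouts import Bout
from .hypnogram import SPLIT_STATES


@dataclass(frozen=True)
class TransitionTable:
    """K x K observed bout-transition counts with derived null quantities.

    ``O[i, j]`` counts transitions from ``states[i]`` to ``states[j]``.
    ``Z`` and ``mask`` are filled by :func:`z_statistics` and
    :func:`apply_mask`; until then they are ``None``.
    """

    states: tuple[str, ...]
    O: np.ndarray
    Z: Optional[np.ndarray] = None
    mask: Optional[np.ndarray] = None
    method: Optional[str] = None

    def __post_init__(self) -> None:
        O = np.asarray(self.O, dtype=int)
        K = len(self.states)
        if O.shape != (K, K):
            raise ValueError(f"O must be {K}x{K}, got {O.shape}")
        if (O < 0).any():
            raise ValueError("observed counts must be non-negative")
        if np.diag(O).any():
            raise ValueError("diagonal of O must be structurally zero")
        object.__setattr__(self, "O", O)

    @property
    def N(self) -> int:
        """Total number of transitions."""
        return int(self.O.sum())

    @property
    def R(self) -> np.ndarray:
        """Row marginals (transitions leaving each state)."""
        return self.O.sum(axis=1)

    @property
    def C(self) -> np.ndarray:
        """Column marginals (transitions entering each state)."""
        return self.O.sum(axis=0)

    @property
    def E(self) -> np.ndarray:
        """Expected counts R_i C_j / N under row/column independence."""
        if self.N == 0:
            raise ValueError("empty table")
        return np.outer(self.R, self.C) / self.N

    @property
    def p_obs(self) -> np.ndarray:
        """Observed transition probabilities O / N."""
        if self.N == 0:
            raise ValueError("empty table")
        return self.O / self.N

    @property
    def p_exp(self) -> np.ndarray:
        """Expected probabilities p_i. * p_.j under independence."""
        return self.E / self.N


def cross_tabulate(
    bouts_by_subject: Mapping[str, Sequence[Bout]],
    states: Sequence[str] = SPLIT_STATES,
    bin_index: Optional[int] = None,
    bin_epochs: int = 900,
) -> TransitionTable:
    """Tally bout successions, pooled over subjects, into a TransitionTable.

    Consecutive bout pairs are taken within each subject only.  A
    transition belongs to the time bin containing the ONSET of the
    successor bout; with ``bin_index=None`` all transitions are kept.
    """
    states = tuple(states)
    index = {s: i for i, s in enumerate(states)}
    O = np.zeros((len(states), len(states)), dtype=int)
    for bouts in bouts_by_subject.values():
        for prev, nxt in zip(bouts, bouts[1:]):
            if bin_index is not None and (
                nxt.onset_epoch // bin_epochs != bin_index
            ):
                continue
            try:
                O[index[prev.state], index[nxt.state]] += 1
            except KeyError as exc:
                raise ValueError(f"state {exc} not in table state list") from exc
    return TransitionTable(states=states, O=O)


def z_statistics(
    t: TransitionTable,
    method: str = "pearson",
    on: str = "counts",
) -> TransitionTable:
    """Standardized observed-vs-expected residuals for every cell.

    ``pearson``: z_ij = (O_ij - E_ij) / sqrt(E_ij).  ``adjusted`` divides
    further by sqrt((1 - R_i/N)(1 - C_j/N)), the haberman-style variance
    correction.  Expected counts use the naive independence product over
    the full table including the structurally-zero diagonal.  ``on``
    chooses the count scale (default; the |z| > 2 rule presumes it) or the
    probability scale, which rescales z by 1/sqrt(N).  Cells with E = 0
    are left NaN.
    """
    if method not in ("pearson", "adjusted"):
        raise ValueError(f"unknown method {method!r}")
    if on not in ("counts", "probabilities"):
        raise ValueError(f"unknown scale {on!r}")
    if t.N == 0:
        raise ValueError("empty table")
    E = t.E
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = (t.O - E) / np.sqrt(E)
        if method == "adjusted":
            adj = np.sqrt(
                np.outer(1.0 - t.R / t.N, 1.0 - t.C / t.N)
            )
            Z = Z / adj
    Z[E == 0] = np.nan
    if on == "probabilities":
        Z = Z / np.sqrt(t.N)
    return replace(t, Z=Z, method=f"{method}/{on}")


def apply_mask(
    t: TransitionTable,
    min_count: int = 5,
    on_expected: bool = False,
) -> TransitionTable:
    """Mask the diagonal and low-count cells as not estimable.

    By default a cell is masked when its OBSERVED count is below
    ``min_count`` (fewer than five observations by default); with
    ``on_expected`` the rule is applied to the expected count instead.
    Masked cells carry no z value.
    """
    K = len(t.states)
    mask = np.eye(K, dtype=bool)
    if min_count > 0:
        low = (t.E if on_expected else t.O) < min_count
        mask |= low
    Z = t.Z
    if Z is not None:
        Z = Z.copy()
        Z[mask] = np.nan
    return replace(t, Z=Z, mask=mask)


def transition_frame(t: TransitionTable) -> pd.DataFrame:
    """Long-format view: from_state, to_state, observed, expected, z, masked."""
    K = len(t.states)
    E = t.E if t.N > 0 else np.zeros((K, K))
    mask = t.mask if t.mask is not None else np.zeros((K, K), dtype=bool)
    Z = t.Z if t.Z is not None else np.full((K, K), np.nan)
    rows = []
    for i, a in enumerate(t.states):
        for j, b in enumerate(t.states):
            rows.append(
                {
                    "from_state": a,
                    "to_state": b,
                    "observed": int(t.O[i, j]),
                    "expected": float(E[i, j]),
                    "z": float(Z[i, j]),
                    "masked": bool(mask[i, j]),
                }
            )
    return pd.DataFrame(rows)


def _render_panel(ax, t: TransitionTable, vmax: float, cmap):
    Z = t.Z if t.Z is not None else np.full((len(t.states),) * 2, np.nan)
    data = np.ma.masked_invalid(Z)
    if t.mask is not None:
        data = np.ma.masked_where(t.mask, data)
    im = ax.imshow(
        data, cmap=cmap, vmin=-vmax, vmax=vmax, aspect="equal",
        interpolation="nearest",
    )
    ax.set_xticks(range(len(t.states)), t.states, rotation=90, fontsize=7)
    ax.set_yticks(range(len(t.states)), t.states, fontsize=7)
    ax.set_xlabel("next state", fontsize=8)
    ax.set_ylabel("current state", fontsize=8)
    return im


def _diverging_cmap():
    import matplotlib

    cmap = matplotlib.colormaps["RdBu_r"].copy()
    cmap.set_bad("0.4")  # gray tiles for not-estimable cells
    return cmap


def heatmap_export(
    t: TransitionTable,
    csv_path: str | Path | None = None,
    image_paths: Sequence[str | Path] = (),
    vmax: Optional[float] = None,
    title: Optional[str] = None,
) -> pd.DataFrame:
    """Write the long-format transition CSV and render the heatmap.

    The colormap is diverging and symmetric about zero (limits +-``vmax``,
    defaulting to the largest unmasked |z|, or 2 if none); masked cells are
    gray.  Rows are the current state (Y axis), columns the next state
    (X axis).  Image format follows each path's extension (png/svg).
    """
    if t.Z is None or t.mask is None:
        raise ValueError("fill Z (z_statistics) and mask (apply_mask) first")
    frame = transition_frame(t)
    if csv_path is not None:
        # %.17g round-trips float64 exactly
        frame.to_csv(csv_path, index=False, float_format="%.17g")
    if image_paths:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if vmax is None:
            finite = np.abs(t.Z[~t.mask & np.isfinite(t.Z)])
            vmax = float(finite.max()) if finite.size else 2.0
        fig, ax = plt.subplots(figsize=(4, 3.5))
        im = _render_panel(ax, t, vmax, _diverging_cmap())
        fig.colorbar(im, ax=ax, label="z")
        if title:
            ax.set_title(title, fontsize=9)
        fig.tight_layout()
        for p in image_paths:
            fig.savefig(p, dpi=150)
        plt.close(fig)
    return frame


def heatmap_grid(
    bouts_by_treatment: Mapping[str, Mapping[str, Sequence[Bout]]],
    treatments: Optional[Sequence[str]] = None,
    n_bins: int = 3,
    bin_epochs: int = 900,
    states: Sequence[str] = SPLIT_STATES,
    method: str = "pearson",
    min_count: int = 5,
    out_dir: str | Path | None = None,
    figure_name: str = "transition_grid",
) -> dict[tuple[str, int], TransitionTable]:
    """One transition table and heatmap panel per (treatment, time bin).

    Transitions are pooled over subjects within each panel.  All panels
    share the state ordering and a common symmetric color scale set by the
    largest unmasked |z| across the grid.  With ``out_dir`` set, one CSV
    per panel and a composite PNG+SVG figure are written.
    """
    if treatments is None:
        treatments = list(bouts_by_treatment)
    tables: dict[tuple[str, int], TransitionTable] = {}
    for tr in treatments:
        per_subject = bouts_by_treatment.get(tr, {})
        for b in range(n_bins):
            t = cross_tabulate(
                per_subject, states=states, bin_index=b, bin_epochs=bin_epochs
            )
            if t.N > 0:
                t = z_statistics(t, method=method)
            else:
                t = replace(t, Z=np.full((len(t.states),) * 2, np.nan))
            tables[(tr, b)] = apply_mask(t, min_count=min_count)

    if out_dir is not None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        vmax = 2.0
        for t in tables.values():
            if t.Z is not None:
                finite = np.abs(t.Z[~t.mask & np.isfinite(t.Z)])
                if finite.size:
                    vmax = max(vmax, float(finite.max()))
        cmap = _diverging_cmap()
        fig, axes = plt.subplots(
            len(treatments), n_bins,
            figsize=(3.2 * n_bins, 3.0 * len(treatments)),
            squeeze=False,
        )
        im = None
        for r, tr in enumerate(treatments):
            for b in range(n_bins):
                t = tables[(tr, b)]
                transition_frame(t).to_csv(
                    out_dir / f"transitions_{tr}_h{b + 1}.csv",
                    index=False, float_format="%.17g",
                )
                im = _render_panel(axes[r][b], t, vmax, cmap)
                axes[r][b].set_title(f"{tr}, hour {b + 1}", fontsize=9)
        if im is not None:
            fig.colorbar(im, ax=axes, label="z", shrink=0.6)
        for ext in ("png", "svg"):
            fig.savefig(out_dir / f"{figure_name}.{ext}", dpi=150)
        plt.close(fig)
    return tables
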