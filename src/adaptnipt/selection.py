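"""Adaptive reference-sample selection by stepped GC/RF window expansion.

For a test sample and a target chromosome, candidate reference subsets are
the panel samples falling inside a rectangular window centred on the test
sample's chromosome GC content (GC axis) and on its *fitted* reads fraction
from the full-panel regression (RF axis; the fitted value is used because a
trisomic sample's observed fraction is inflated and would drag the window
toward high-fraction references).  The window half-widths are expanded on a
stepped grid — multiples of a GC unit (default 0.001) up to a preset
maximum (default 0.02), and of an RF unit (default 0.00005) up to a maximum
(default 0.001) — and, among windows holding at least a minimum number of
reference samples, the one with the smallest coefficient of variation is
selected as the reference set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .gc_correction import ChromosomeProfile, PanelProfiles
from .scoring import RegressionFit, panel_cv, predicted_rf

logger = logging.getLogger(__name__)


@dataclass
class SelectionParams:
    """Stepping units, maxima and the minimum usable panel size."""

    gc_unit: float = 0.001
    rf_unit: float = 0.00005
    gc_max: float = 0.02
    rf_max: float = 0.001
    min_panel: int = 30

    def __post_init__(self) -> None:
        if not (0 < self.gc_unit <= self.gc_max):
            raise ValueError("need 0 < gc_unit <= gc_max")
        if not (0 < self.rf_unit <= self.rf_max):
            raise ValueError("need 0 < rf_unit <= rf_max")

    def gc_steps(self) -> np.ndarray:
        n = int(round(self.gc_max / self.gc_unit))
        return self.gc_unit * np.arange(1, n + 1)

    def rf_steps(self) -> np.ndarray:
        n = int(round(self.rf_max / self.rf_unit))
        return self.rf_unit * np.arange(1, n + 1)


@dataclass
class SelectionWindow:
    """One candidate (GC +/- g, RF +/- r) window over the panel."""

    gc_center: float
    rf_center: float
    g: float
    r: float
    member_mask: np.ndarray
    member_ids: list[str]
    cv: float  # nan when fewer than 2 members

    @property
    def n(self) -> int:
        return len(self.member_ids)


@dataclass
class SelectionGrid:
    windows: list[SelectionWindow]
    chosen: int | None          # index into windows; None => fallback
    fallback: SelectionWindow | None = None

    @property
    def chosen_window(self) -> SelectionWindow:
        if self.chosen is None:
            assert self.fallback is not None
            return self.fallback
        return self.windows[self.chosen]


def select_window(
    test: ChromosomeProfile,
    panel: PanelProfiles,
    chrom: int,
    g: float,
    r: float,
    fit: RegressionFit,
) -> SelectionWindow:
    """Panel members within GC +/- g of the test sample and RF +/- r of its
    fitted reads fraction.  ``g``/``r`` may be infinite (baseline: whole
    panel).  The test profile must be on the panel-normalised rf scale.
    """
    j = panel.col(chrom)
    gc_center = float(test.gc[test.col(chrom)])
    rf_center = predicted_rf(fit, gc_center)
    mask = (np.abs(panel.gc[:, j] - gc_center) <= g) & (
        np.abs(panel.rf[:, j] - rf_center) <= r
    )
    ids = [sid for sid, m in zip(panel.sample_ids, mask) if m]
    cv = panel_cv(panel, chrom, mask) if mask.sum() >= 2 else math.nan
    return SelectionWindow(gc_center, rf_center, float(g), float(r), mask, ids, cv)


def expand_and_choose(
    test: ChromosomeProfile,
    panel: PanelProfiles,
    chrom: int,
    params: SelectionParams,
    fit: RegressionFit,
) -> SelectionGrid:
    """Evaluate the full (g, r) step grid and pick the CV-optimal window.

    Among windows with at least ``params.min_panel`` members the minimal-CV
    window wins, with a one-standard-error rule: any window whose CV lies
    within one standard error of the minimum (SE of a CV estimate from n
    samples is about cv/sqrt(2n)) counts as tied with it, and ties resolve
    toward larger membership, then smaller g, then smaller r.  Without the
    SE allowance the minimum over many nested candidate subsets is a
    noise-biased underestimate of the selected panel's true spread, which
    would systematically inflate downstream z scores.  If no window reaches
    the minimum size, the full panel is used as a logged fallback.
    """
    j = panel.col(chrom)
    gc_center = float(test.gc[test.col(chrom)])
    rf_center = predicted_rf(fit, gc_center)
    gc_dist = np.abs(panel.gc[:, j] - gc_center)
    rf_dist = np.abs(panel.rf[:, j] - rf_center)
    rf_col = panel.rf[:, j]

    windows: list[SelectionWindow] = []
    candidates: list[int] = []
    for g in params.gc_steps():
        in_g = gc_dist <= g
        for r in params.rf_steps():
            mask = in_g & (rf_dist <= r)
            n = int(mask.sum())
            if n >= 2:
                vals = rf_col[mask]
                cv = float(vals.std(ddof=1) / vals.mean())
            else:
                cv = math.nan
            ids = [sid for sid, m in zip(panel.sample_ids, mask) if m]
            windows.append(
                SelectionWindow(gc_center, rf_center, float(g), float(r), mask, ids, cv)
            )
            if n >= params.min_panel and not math.isnan(cv):
                candidates.append(len(windows) - 1)

    best_idx: int | None = None
    if candidates:
        i_min = min(candidates, key=lambda i: windows[i].cv)
        w_min = windows[i_min]
        threshold = w_min.cv * (1.0 + 1.0 / math.sqrt(2.0 * w_min.n))
        best_idx = min(
            (i for i in candidates if windows[i].cv <= threshold),
            key=lambda i: (-windows[i].n, windows[i].g, windows[i].r),
        )

    if best_idx is None:
        logger.warning(
            "chromosome %s: no window reached min_panel=%d; falling back to "
            "the full panel (n=%d)",
            chrom,
            params.min_panel,
            len(panel),
        )
        fallback = select_window(test, panel, chrom, math.inf, math.inf, fit)
        return SelectionGrid(windows, None, fallback)
    return SelectionGrid(windows, best_idx)


def grid_dump(grid: SelectionGrid) -> "np.ndarray":
    """(g, r, n, cv, chosen) rows for plotting CV-vs-window bar charts."""
    rows = []
    for i, w in enumerate(grid.windows):
        rows.append((w.g, w.r, w.n, w.cv, 1.0 if i == grid.chosen else 0.0))
    return np.array(rows)


# ---------------------------------------------------------------------------
# Grouping of positive samples for panel-building evaluation


def group_positives_by_gc_region(
    samples: list[ChromosomeProfile], chrom: int, width: float = 0.01
) -> dict[float, list[ChromosomeProfile]]:
    """Bucket samples into GC-content regions of the given width.

    A sample with chromosome GC g goes to region floor(g / width) * width
    (e.g. 0.424 -> 0.42); values exactly on a boundary go to the region they
    open.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    groups: dict[float, list[ChromosomeProfile]] = {}
    for p in samples:
        g = float(p.gc[p.col(chrom)])
        region = math.floor(g / width + 1e-9) * width
        groups.setdefault(round(region, 10), []).append(p)
    return groups


def choose_representative(group: list[ChromosomeProfile], chrom: int) -> str:
    """Representative sample of a GC region group.

    More than two samples: the one with the (lower-)median GC content.  Two
    samples: the lexicographically smallest id (a deterministic stand-in for
    an arbitrary choice).  One sample: itself.
    """
    if not group:
        raise ValueError("empty group")
    if len(group) == 1:
        return group[0].sample_id
    if len(group) == 2:
        return min(p.sample_id for p in group)
    ordered = sorted(group, key=lambda p: (float(p.gc[p.col(chrom)]), p.sample_id))
    return ordered[(len(ordered) - 1) // 2].sample_id
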