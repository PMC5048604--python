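"""Classification thresholds and end-to-end pipeline orchestration.

The single-cutoff scheme calls a sample positive when z > 3 (reads fraction
above the reference 99.9th percentile, one tailed).  The dual-cutoff scheme
calls z < 2 negative and z > 4 positive, with the band in between reported
as a gray zone (retest / confirmatory testing), the less aggressive rule
some laboratories prefer.  Boundary values resolve to the less severe
category (the inequalities are strict).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .gc_correction import (
    ChromosomeProfile,
    PanelProfiles,
    chromosome_profile,
    loess_correct,
    normalize_panel,
    normalize_test,
)
from .io import AneuploidyCall, BinnedCounts, filter_reference_eligible
from .scoring import (
    DEFAULT_MODERATION_DF,
    RegressionFit,
    fit_regression,
    moderated_z,
    panel_cv,
    z_score,
)
from .selection import SelectionParams, expand_and_choose

logger = logging.getLogger(__name__)

NEGATIVE = "negative"
GRAY_ZONE = "gray_zone"
POSITIVE = "positive"


@dataclass
class ThresholdScheme:
    mode: str = "single"
    z_positive: float | None = None
    z_negative: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("single", "dual"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if self.z_positive is None:
            self.z_positive = 3.0 if self.mode == "single" else 4.0
        if self.mode == "dual":
            if self.z_negative is None:
                self.z_negative = 2.0
            if not self.z_negative < self.z_positive:
                raise ValueError("dual scheme needs z_negative < z_positive")


def classify(z: float, scheme: ThresholdScheme) -> str:
    if math.isnan(z):
        raise ValueError("cannot classify NaN z score")
    if scheme.mode == "single":
        return POSITIVE if z > scheme.z_positive else NEGATIVE
    if z > scheme.z_positive:
        return POSITIVE
    if z < scheme.z_negative:
        return NEGATIVE
    return GRAY_ZONE


# ---------------------------------------------------------------------------
# Reference panel model


class ReferencePanelModel:
    """A normalised reference panel with its full-panel regression fits.

    Built once from euploid reference profiles; scores any number of test
    samples, each with its own adaptively selected reference subset and a
    refit of the regression on that subset.
    """

    def __init__(
        self,
        panel: PanelProfiles,
        s: np.ndarray,
        fits: dict[int, RegressionFit],
        targets: tuple[int, ...],
    ):
        self.panel = panel
        self.s = s
        self.fits = fits
        self.targets = targets

    @classmethod
    def build(
        cls, profiles: list[ChromosomeProfile], targets: tuple[int, ...] = (13, 18, 21)
    ) -> "ReferencePanelModel":
        panel, s = normalize_panel(profiles)
        fits = {c: fit_regression(panel, c) for c in targets}
        return cls(panel, s, fits, targets)

    def normalize(self, profile: ChromosomeProfile) -> ChromosomeProfile:
        return normalize_test(profile, self.s)

    def baseline_z(self, profile: ChromosomeProfile, chrom: int) -> float:
        """z against the full panel (no adaptive selection).

        ``profile`` is on the raw rf scale; normalisation is applied here.
        """
        return z_score(self.normalize(profile), self.fits[chrom], chrom)

    def adaptive_z(
        self,
        profile: ChromosomeProfile,
        chrom: int,
        params: SelectionParams,
        moderation_df: float = DEFAULT_MODERATION_DF,
    ) -> tuple[float, int, float]:
        """(z, panel_size, panel_cv) using the CV-optimal reference window.

        The regression is refitted on the selected members; the residual
        variance is moderated toward the full-panel fit (see
        :func:`adaptnipt.scoring.moderated_z`).
        """
        test = self.normalize(profile)
        grid = expand_and_choose(test, self.panel, chrom, params, self.fits[chrom])
        window = grid.chosen_window
        refit = fit_regression(self.panel, chrom, window.member_mask)
        z = moderated_z(test, refit, self.fits[chrom], chrom, moderation_df)
        return z, window.n, window.cv

    def score(
        self,
        profile: ChromosomeProfile,
        params: SelectionParams,
        scheme: ThresholdScheme,
        moderation_df: float = DEFAULT_MODERATION_DF,
    ) -> list[AneuploidyCall]:
        calls = []
        for chrom in self.targets:
            z, n, cv = self.adaptive_z(profile, chrom, params, moderation_df)
            calls.append(
                AneuploidyCall(
                    sample_id=profile.sample_id,
                    chrom=chrom,
                    z=z,
                    panel_size=n,
                    panel_cv=cv,
                    classification=classify(z, scheme),
                )
            )
        return calls

    def statistics(self) -> pd.DataFrame:
        rows = [
            {
                "chrom": c,
                "n": len(self.panel),
                "cv": panel_cv(self.panel, c),
                "alpha": self.fits[c].alpha,
                "beta": self.fits[c].beta,
                "resid_sd": self.fits[c].resid_sd,
            }
            for c in self.targets
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# End-to-end pipeline


def _profile_sample(
    counts: BinnedCounts, bins: pd.DataFrame, cfg: PipelineConfig
) -> ChromosomeProfile:
    corrected = loess_correct(
        counts,
        bins,
        span=cfg.loess.span,
        clamp_floor=cfg.loess.clamp_floor,
        min_usable_bins=cfg.loess.min_usable_bins,
    )
    return chromosome_profile(corrected, bins, counts.sample_id, counts.counts)


def build_panel_model(
    panel_counts: list[BinnedCounts],
    bins: pd.DataFrame,
    manifest: pd.DataFrame,
    cfg: PipelineConfig | None = None,
) -> ReferencePanelModel:
    """Eligibility-filter, correct and profile the reference cohort."""
    cfg = cfg or PipelineConfig()
    eligible = set(filter_reference_eligible(manifest))
    kept = [bc for bc in panel_counts if bc.sample_id in eligible]
    logger.info(
        "stage=eligibility n_in=%d n_out=%d", len(panel_counts), len(kept)
    )
    if len(kept) < 2:
        raise ValueError("fewer than 2 eligible reference samples")
    profiles = [_profile_sample(bc, bins, cfg) for bc in kept]
    logger.info("stage=profile n_in=%d n_out=%d", len(kept), len(profiles))
    return ReferencePanelModel.build(profiles, cfg.targets)


def run_pipeline(
    panel_counts: list[BinnedCounts],
    test_counts: list[BinnedCounts],
    bins: pd.DataFrame,
    manifest: pd.DataFrame,
    cfg: PipelineConfig | None = None,
) -> tuple[list[AneuploidyCall], pd.DataFrame]:
    """Full run: panel build, adaptive selection, scoring, classification.

    Returns the calls (one per test sample per target chromosome) and the
    full-panel statistics table (reported even when there are no tests).
    """
    cfg = cfg or PipelineConfig()
    model = build_panel_model(panel_counts, bins, manifest, cfg)
    scheme = ThresholdScheme(
        cfg.calling.mode, cfg.calling.z_positive, cfg.calling.z_negative
    )
    params = cfg.selection
    calls: list[AneuploidyCall] = []
    for bc in test_counts:
        profile = _profile_sample(bc, bins, cfg)
        calls.extend(
            model.score(profile, params, scheme, cfg.scoring.moderation_df)
        )
    logger.info("stage=score n_in=%d n_out=%d", len(test_counts), len(calls))
    return calls, model.statistics()
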