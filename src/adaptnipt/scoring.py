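"""Per-chromosome regression of reads fraction on GC content and z-scoring.

Across a reference panel, a chromosome's normalised reads fraction rf is
regressed on the per-sample GC content of that chromosome, rf = a + b*gc + e
(ordinary least squares).  A test sample's residual against the fitted line,
standardised by the panel residual mean and sample standard deviation, is
the aneuploidy z score: z > 3 corresponds to a reads fraction above the
99.9th percentile of the reference distribution under normality.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .gc_correction import ChromosomeProfile, PanelProfiles

logger = logging.getLogger(__name__)

DEFAULT_MIN_PANEL_SIZE = 30
DEFAULT_OUTLIER_THRESHOLD = 3.0
DEFAULT_MODERATION_DF = 60


class DegeneratePanelError(ValueError):
    pass


@dataclass
class RegressionFit:
    chrom: int
    alpha: float
    beta: float
    residuals: np.ndarray
    resid_mean: float
    resid_sd: float   # sample sd (ddof=1)
    n: int


@dataclass
class PanelStatistics:
    chrom: int
    cv: float
    n: int


def fit_regression(
    panel: PanelProfiles, chrom: int, members: np.ndarray | None = None
) -> RegressionFit:
    """OLS of normalised rf on per-sample GC for one chromosome.

    ``members`` optionally restricts the fit to a subset of panel rows
    (boolean mask or index array), used when refitting on an adaptively
    selected reference set.
    """
    j = panel.col(chrom)
    gc = panel.gc[:, j]
    rf = panel.rf[:, j]
    if members is not None:
        gc = gc[members]
        rf = rf[members]
    n = len(gc)
    if n < 3:
        raise DegeneratePanelError(f"chromosome {chrom}: n={n} < 3 for regression")
    gc_c = gc - gc.mean()
    sxx = float(gc_c @ gc_c)
    if sxx < 1e-18:
        raise DegeneratePanelError(
            f"chromosome {chrom}: degenerate GC spread in regression panel"
        )
    beta = float(gc_c @ (rf - rf.mean())) / sxx
    alpha = float(rf.mean() - beta * gc.mean())
    resid = rf - (alpha + beta * gc)
    return RegressionFit(
        chrom=chrom,
        alpha=alpha,
        beta=beta,
        residuals=resid,
        resid_mean=float(resid.mean()),
        resid_sd=float(resid.std(ddof=1)),
        n=n,
    )


def predicted_rf(fit: RegressionFit, gc: float) -> float:
    """Fitted reads fraction a + b*gc — the RF centre for window selection."""
    return fit.alpha + fit.beta * gc


def z_score(test: ChromosomeProfile, fit: RegressionFit, chrom: int) -> float:
    """Standardised residual of a (panel-normalised) test sample."""
    if fit.resid_sd <= 0:
        raise DegeneratePanelError(
            f"chromosome {chrom}: zero residual spread in reference panel"
        )
    j = test.col(chrom)
    r = test.rf[j] - predicted_rf(fit, test.gc[j])
    return float((r - fit.resid_mean) / fit.resid_sd)


def moderated_z(
    test: ChromosomeProfile,
    fit: RegressionFit,
    prior_fit: RegressionFit,
    chrom: int,
    prior_df: float = DEFAULT_MODERATION_DF,
) -> float:
    """z score with empirical-Bayes moderated residual variance.

    When ``fit`` comes from a small adaptively selected subset, its residual
    sd is a noisy — and, being the CV-minimising window, a downward-biased —
    estimate of the subset's true spread.  The residual variance is
    therefore shrunk toward the full-panel fit's residual variance with
    ``prior_df`` prior degrees of freedom (as in moderated t statistics).
    When the subset IS the full panel the two variances coincide and this
    reduces exactly to :func:`z_score`.
    """
    if prior_df <= 0:
        return z_score(test, fit, chrom)
    df = fit.n - 2
    s2 = (df * fit.resid_sd**2 + prior_df * prior_fit.resid_sd**2) / (df + prior_df)
    if s2 <= 0:
        raise DegeneratePanelError(f"chromosome {chrom}: zero moderated variance")
    j = test.col(chrom)
    r = test.rf[j] - predicted_rf(fit, test.gc[j])
    return float((r - fit.resid_mean) / np.sqrt(s2))


def panel_cv(
    panel: PanelProfiles, chrom: int, members: np.ndarray | None = None
) -> float:
    """Coefficient of variation (sample sd / mean) of normalised rf."""
    j = panel.col(chrom)
    rf = panel.rf[:, j]
    if members is not None:
        rf = rf[members]
    if len(rf) < 2:
        raise DegeneratePanelError(f"chromosome {chrom}: CV needs >= 2 samples")
    mean = float(rf.mean())
    if mean <= 0:
        raise DegeneratePanelError(f"chromosome {chrom}: non-positive mean rf")
    return float(rf.std(ddof=1)) / mean


def panel_statistics(panel: PanelProfiles, chrom: int) -> PanelStatistics:
    return PanelStatistics(chrom=chrom, cv=panel_cv(panel, chrom), n=len(panel))


def flag_outliers(
    panel: PanelProfiles, threshold: float = DEFAULT_OUTLIER_THRESHOLD
) -> list[str]:
    """Flag panel samples with extreme reads fractions on any autosome.

    A sample is flagged when its robust z score — (rf - median) / (1.4826 *
    MAD) — exceeds ``threshold`` in absolute value for at least one
    chromosome.  The criterion is this package's own; chromosomes with zero
    MAD are skipped with a warning.
    """
    if len(panel) < 10:
        raise DegeneratePanelError("outlier flagging needs >= 10 samples")
    flagged = np.zeros(len(panel), dtype=bool)
    for j, chrom in enumerate(panel.chroms):
        rf = panel.rf[:, j]
        med = np.median(rf)
        mad = np.median(np.abs(rf - med))
        if mad <= 0:
            warnings.warn(f"chromosome {chrom}: zero MAD, skipped", stacklevel=2)
            continue
        rz = np.abs(rf - med) / (1.4826 * mad)
        flagged |= rz > threshold
    return [sid for sid, f in zip(panel.sample_ids, flagged) if f]
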