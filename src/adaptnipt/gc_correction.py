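"""Bin-level GC-bias correction and per-chromosome aggregation.

The depth-vs-GC bias of a sample is modelled with LOESS over usable bins and
removed multiplicatively: each bin count is rescaled by the ratio of the
sample's global mean count to the LOESS prediction at the bin's GC.  The
corrected counts are summed per autosome into RC, turned into reads
fractions Rf (each chromosome's share of autosomal reads) and normalised
across the reference panel column-wise, so every chromosome's normalised
fractions sum to 1 over the panel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import BinnedCounts, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_SPAN = 0.3
DEFAULT_CLAMP_FLOOR = 0.01
DEFAULT_MIN_USABLE_BINS = 100


@dataclass
class LoessFit:
    """Degree-1 LOESS fit of bin count on bin GC for one sample."""

    span: float
    gc_grid: np.ndarray      # unique sorted gc of fitted points
    predictions: np.ndarray  # LOESS prediction at gc_grid
    global_mean: float       # mean usable-bin count M

    def predict(self, gc: np.ndarray) -> np.ndarray:
        return np.interp(gc, self.gc_grid, self.predictions)


def fit_loess(
    counts: np.ndarray, gc: np.ndarray, span: float = DEFAULT_SPAN
) -> LoessFit:
    """Fit count-vs-GC LOESS (local linear, fraction ``span``)."""
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    # delta collapses near-duplicate gc values; 1% of the range keeps the
    # fit smooth while making run time near-linear in the number of bins.
    delta = 0.01 * float(np.ptp(gc))
    fitted = lowess(counts, gc, frac=span, it=1, delta=delta, return_sorted=True)
    xs, idx = np.unique(fitted[:, 0], return_index=True)
    return LoessFit(
        span=span,
        gc_grid=xs,
        predictions=fitted[idx, 1],
        global_mean=float(np.mean(counts)),
    )


def loess_correct(
    counts: BinnedCounts,
    bins: pd.DataFrame,
    span: float = DEFAULT_SPAN,
    clamp_floor: float = DEFAULT_CLAMP_FLOOR,
    min_usable_bins: int = DEFAULT_MIN_USABLE_BINS,
) -> np.ndarray:
    """Return GC-corrected per-bin counts for one sample.

    For each usable bin b: corrected_b = count_b * M / max(L(gc_b),
    clamp_floor * M), with L the sample's LOESS fit and M its mean usable-bin
    count.  Unusable bins get 0.  If the usable bins have (numerically) no GC
    spread the correction is refused and raw counts are passed through with a
    warning.
    """
    usable = bins["usable"].to_numpy()
    raw = np.asarray(counts.counts, dtype=float)
    if len(raw) != len(bins):
        raise ValidationError(
            f"{counts.sample_id}: {len(raw)} counts for {len(bins)} bins"
        )
    n_informative = int(np.count_nonzero(usable & (raw > 0)))
    if n_informative < min_usable_bins:
        raise ValidationError(
            f"{counts.sample_id}: only {n_informative} usable non-zero bins "
            f"(need >= {min_usable_bins})"
        )
    gc = bins["gc"].to_numpy()[usable]
    x = raw[usable]
    out = np.zeros_like(raw)
    if np.ptp(gc) < 1e-9:
        warnings.warn(
            f"{counts.sample_id}: degenerate GC spread, correction skipped",
            stacklevel=2,
        )
        out[usable] = x
        return out
    fit = fit_loess(x, gc, span=span)
    pred = np.maximum(fit.predict(gc), clamp_floor * fit.global_mean)
    out[usable] = x * fit.global_mean / pred
    return out


# ---------------------------------------------------------------------------
# Chromosome profiles


@dataclass
class ChromosomeProfile:
    """Per-autosome summary of one sample.

    ``rf`` holds reads fractions on either the raw (sums to 1) or the
    panel-normalised scale, depending on provenance; ``gc`` is the
    raw-count-weighted mean bin GC of each chromosome, a proxy for the GC
    content of the reads mapped to it.
    """

    sample_id: str
    chroms: np.ndarray  # sorted autosome labels present in the bin table
    rc: np.ndarray
    rf: np.ndarray
    gc: np.ndarray

    def col(self, chrom: int) -> int:
        idx = np.searchsorted(self.chroms, chrom)
        if idx >= len(self.chroms) or self.chroms[idx] != chrom:
            raise KeyError(f"chromosome {chrom} not in profile")
        return int(idx)


def chromosome_profile(
    corrected: np.ndarray,
    bins: pd.DataFrame,
    sample_id: str,
    raw_counts: np.ndarray | None = None,
) -> ChromosomeProfile:
    """Aggregate corrected bin counts into per-chromosome RC, Rf and GC.

    GC per chromosome is the count-weighted mean bin GC using the *raw*
    counts when given (the reads as sequenced carry the sample's GC
    character; correction deliberately flattens it), falling back to the
    corrected counts.
    """
    chrom_arr = bins["chrom"].to_numpy()
    gc_arr = bins["gc"].to_numpy()
    usable = bins["usable"].to_numpy()
    weights = np.asarray(raw_counts if raw_counts is not None else corrected, dtype=float)

    chroms = np.unique(chrom_arr)
    rc = np.zeros(len(chroms))
    gc = np.zeros(len(chroms))
    for k, c in enumerate(chroms):
        m = (chrom_arr == c) & usable
        rc[k] = corrected[m].sum()
        w = weights[m]
        wsum = w.sum()
        gc[k] = float(np.average(gc_arr[m], weights=w)) if wsum > 0 else float(
            gc_arr[m].mean()
        )
    total = rc.sum()
    if total <= 0:
        raise ValidationError(f"{sample_id}: zero total corrected count")
    return ChromosomeProfile(sample_id, chroms, rc, rc / total, gc)


class PanelProfiles:
    """Column-aligned matrix view over a set of ChromosomeProfiles."""

    def __init__(self, profiles: list[ChromosomeProfile]):
        if not profiles:
            raise ValueError("empty profile list")
        chroms = profiles[0].chroms
        for p in profiles[1:]:
            if not np.array_equal(p.chroms, chroms):
                raise ValueError("profiles cover different chromosome sets")
        self.chroms = chroms
        self.sample_ids = [p.sample_id for p in profiles]
        self.rf = np.vstack([p.rf for p in profiles])
        self.gc = np.vstack([p.gc for p in profiles])
        self.rc = np.vstack([p.rc for p in profiles])

    def __len__(self) -> int:
        return len(self.sample_ids)

    def col(self, chrom: int) -> int:
        idx = np.searchsorted(self.chroms, chrom)
        if idx >= len(self.chroms) or self.chroms[idx] != chrom:
            raise KeyError(f"chromosome {chrom} not in panel")
        return int(idx)

    def profile(self, i: int) -> ChromosomeProfile:
        return ChromosomeProfile(
            self.sample_ids[i], self.chroms, self.rc[i], self.rf[i], self.gc[i]
        )


def normalize_panel(
    profiles: list[ChromosomeProfile],
) -> tuple[PanelProfiles, np.ndarray]:
    """Normalise reads fractions column-wise over the panel.

    Each chromosome's fractions are divided by their sum over the N panel
    samples (so normalised columns sum to 1).  Returns the normalised panel
    and the column-sum vector S, which puts later test samples on the same
    scale.
    """
    if len(profiles) < 2:
        raise ValidationError("panel normalisation needs >= 2 samples")
    panel = PanelProfiles(profiles)
    s = panel.rf.sum(axis=0)
    if (s <= 0).any():
        bad = panel.chroms[s <= 0]
        raise ValidationError(f"zero column sum for chromosomes {bad.tolist()}")
    norm = PanelProfiles.__new__(PanelProfiles)
    norm.chroms = panel.chroms
    norm.sample_ids = panel.sample_ids
    norm.rf = panel.rf / s
    norm.gc = panel.gc
    norm.rc = panel.rc
    return norm, s


def normalize_test(profile: ChromosomeProfile, s: np.ndarray) -> ChromosomeProfile:
    """Scale a test sample's reads fractions by the panel's column sums."""
    return ChromosomeProfile(
        profile.sample_id, profile.chroms, profile.rc, profile.rf / s, profile.gc
    )
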