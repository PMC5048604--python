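"""Synthetic cfDNA cohort generator.

Emulates the statistical structure the scoring method assumes: a fixed toy
genome of 20 kb-capped bins whose per-chromosome counts are proportional to
hg19 chromosome lengths; per-sample unimodal depth-vs-GC bias curves; a
per-sample GC "tilt" that moves the count-weighted GC content of every
chromosome (calibrated so per-chromosome GC contents stay inside a
configured envelope, 0.40-0.51 by default); a chromosome-level coupling
between a sample's GC tilt and its reads fractions, which is what makes a
GC-heterogeneous reference panel inflate the chromosome-21 coefficient of
variation and is the failure mode adaptive reference selection corrects;
negative-binomial count noise; and trisomic samples whose target-chromosome
intensity is multiplied by (1 + f/2) for fetal fraction f, halved again for
a twin-diluted pregnancy.

The generator is seed-reproducible and is the package's test fixture
factory: no external data is required anywhere in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import BinnedCounts

logger = logging.getLogger(__name__)

# hg19 chromosome lengths (Mb) and GC fractions, autosomes 1..22.
_CHROM_LENGTH_MB = np.array(
    [249.25, 243.20, 198.02, 191.15, 180.92, 171.12, 159.14, 146.36, 141.21,
     135.53, 135.01, 133.85, 115.17, 107.35, 102.53, 90.35, 81.20, 78.08,
     59.13, 63.03, 48.13, 51.30]
)
_CHROM_GC = np.array(
    [0.417, 0.402, 0.397, 0.382, 0.395, 0.396, 0.407, 0.401, 0.413, 0.415,
     0.415, 0.408, 0.385, 0.408, 0.422, 0.447, 0.455, 0.398, 0.483, 0.441,
     0.408, 0.479]
)


@dataclass
class SimulationConfig:
    """Cohort-level simulation settings.

    ``depth`` is mean unique reads per sample; ``dispersion`` is the
    negative-binomial excess-variance parameter (per-bin variance
    mu + dispersion * mu^2; 0 gives Poisson).  ``gc_rf_slope`` and
    ``gc_rf_curvature`` set the linear and quadratic components of the
    chromosome-level coupling between a sample's GC tilt and its reads
    fractions; the quadratic part is what a panel-wide linear regression
    cannot remove.  ``subpop_tilts`` (fractions of the calibrated tilt
    range) switches on a GC-stratified panel.
    """

    n_panel: int = 396
    n_bins: int = 5000
    depth: float = 3.3e6
    depth_cv: float = 0.1
    dispersion: float = 2e-4
    gc_envelope: tuple[float, float] = (0.40, 0.51)
    envelope_margin: float = 0.004
    bin_gc_spread: float = 0.11
    tilt_range_fraction: float = 0.8
    unusable_fraction: float = 0.01
    bias_amplitude: tuple[float, float] = (0.2, 0.8)
    bias_mode: tuple[float, float] = (0.40, 0.48)
    bias_concentration: float = 20.0
    gc_rf_slope: float = 0.01
    gc_rf_curvature: float = 0.0
    subpop_tilts: tuple[float, ...] | None = None   # fractions of tilt range
    subpop_sd: float = 0.12
    trisomy_spec: tuple[tuple[int, float, bool], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 22 * 3:
            raise ValueError("n_bins too small for 22 autosomes")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        for chrom, f, _twin in self.trisomy_spec:
            if chrom not in range(1, 23):
                raise ValueError(f"trisomy chromosome {chrom} not an autosome")
            if not 0 <= f <= 0.5:
                raise ValueError(f"fetal fraction {f} outside [0, 0.5]")


class CohortSimulator:
    """Genome plus sampling machinery for one simulated study."""

    def __init__(self, cfg: SimulationConfig):
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self._build_genome()
        self._calibrate_tilt()

    # -- genome -------------------------------------------------------------

    def _build_genome(self) -> None:
        cfg = self.cfg
        # bins per chromosome proportional to hg19 lengths, >= 3 each
        share = _CHROM_LENGTH_MB / _CHROM_LENGTH_MB.sum()
        nb = np.maximum(3, np.round(share * cfg.n_bins).astype(int))
        lo, hi = cfg.gc_envelope
        margin = cfg.envelope_margin
        # chromosome mean GC: hg19 ranking affinely compressed so the
        # envelope leaves room for the per-sample tilt on both sides
        span = hi - lo - 6.5 * margin
        mu = lo + 3 * margin + (
            (_CHROM_GC - _CHROM_GC.min()) / np.ptp(_CHROM_GC)
        ) * span * 0.8
        self.chrom_mu = mu
        self.chrom_dev = (mu - mu.mean()) / mu.std()
        # per-chromosome GC-response loading: how strongly a sample's GC
        # bias state shifts this chromosome's reads fraction.  Partly the
        # chromosome's mean-GC deviation, partly idiosyncratic fine-scale
        # composition that bin-level GC (and hence bin-level correction)
        # cannot see — the component that makes a GC-heterogeneous panel
        # genuinely heterogeneous in reads fraction.
        load = 0.45 * self.chrom_dev + np.where(np.arange(1, 23) % 2 == 1, 1.0, -1.0)
        self.chrom_load = (load - load.mean()) / load.std()

        chrom_col, gc_col, start_col, end_col = [], [], [], []
        for j, (n, m) in enumerate(zip(nb, mu), start=1):
            dev = cfg.bin_gc_spread * (2 * self.rng.beta(2.0, 2.0, size=n) - 1)
            dev -= dev.mean()  # realized chromosome mean GC equals the design
            gc_col.append(np.clip(m + dev, 0.25, 0.65))
            chrom_col.append(np.full(n, j))
            starts = np.arange(n) * 20_000
            start_col.append(starts)
            end_col.append(starts + 20_000)
        chrom = np.concatenate(chrom_col)
        gc = np.concatenate(gc_col)
        usable = self.rng.random(len(chrom)) >= cfg.unusable_fraction
        self.bins = pd.DataFrame(
            {
                "chrom": chrom.astype(int),
                "start": np.concatenate(start_col),
                "end": np.concatenate(end_col),
                "gc": gc,
                "usable": usable,
            }
        )
        self.chrom_idx = chrom.astype(int) - 1
        # mild mappability-like variation of bin efficiency
        self.weights = np.exp(self.rng.normal(0.0, 0.1, size=len(chrom)))
        # within-chromosome gc variance drives the tilt scaling
        resid = gc - mu[self.chrom_idx]
        self.gc_var = float(np.var(resid))
        self.gc_anchor = 0.45

    def _tilt_factor(self, tilt: float) -> np.ndarray:
        gc = self.bins["gc"].to_numpy()
        return np.exp(tilt * (gc - self.gc_anchor) / self.gc_var)

    def _weighted_gc(self, chrom: int, tilt: float) -> float:
        m = self.chrom_idx == chrom - 1
        w = self.weights[m] * self._tilt_factor(tilt)[m]
        return float(np.average(self.bins["gc"].to_numpy()[m], weights=w))

    def _calibrate_tilt(self) -> None:
        """Solve the tilt range so all per-chromosome GC contents stay in
        the configured envelope (with a safety margin for the random bias
        shapes)."""
        lo, hi = self.cfg.gc_envelope
        margin = self.cfg.envelope_margin
        jmin = int(np.argmin(self.chrom_mu)) + 1
        jmax = int(np.argmax(self.chrom_mu)) + 1
        if not (lo + margin < self.chrom_mu.min() and self.chrom_mu.max() < hi - margin):
            raise ValueError("GC envelope infeasible for the generated genome")
        try:
            self.tilt_lo = optimize.brentq(
                lambda a: self._weighted_gc(jmin, a) - (lo + margin), -0.5, 0.1
            )
            self.tilt_hi = optimize.brentq(
                lambda a: self._weighted_gc(jmax, a) - (hi - margin), -0.1, 0.5
            )
        except ValueError as exc:
            raise ValueError(
                "GC envelope calibration failed; genome too small or envelope "
                "too tight"
            ) from exc
        if self.tilt_lo >= self.tilt_hi:
            raise ValueError("GC envelope leaves no feasible tilt range")
        # samples use an inner fraction of the feasible range: the envelope
        # extremes are occupied by the extreme chromosomes, not by every
        # sample's bias curve
        frac = self.cfg.tilt_range_fraction
        self.tilt_lo *= frac
        self.tilt_hi *= frac
        self.tilt_scale = 0.5 * (self.tilt_hi - self.tilt_lo)

    # -- per-sample machinery ----------------------------------------------

    def _bias_shape(self, mode: float, amplitude: float) -> np.ndarray:
        conc = self.cfg.bias_concentration
        a = 1 + mode * conc
        b = 1 + (1 - mode) * conc
        gc = self.bins["gc"].to_numpy()
        pdf = stats.beta.pdf(gc, a, b)
        peak = stats.beta.pdf(mode, a, b)
        return (1 - amplitude) + amplitude * pdf / peak

    def _chrom_coupling(self, tilt: float) -> np.ndarray:
        """Per-chromosome reads-fraction multiplier tied to the GC tilt."""
        cfg = self.cfg
        t = tilt / self.tilt_scale
        log_e = (cfg.gc_rf_slope * t + cfg.gc_rf_curvature * (t * t - 1.0)) * self.chrom_load
        return np.exp(log_e)

    def draw_tilt(self, subpop: int | None = None) -> float:
        if subpop is None:
            return float(self.rng.uniform(self.tilt_lo, self.tilt_hi))
        center = self.cfg.subpop_tilts[subpop] * self.tilt_scale
        t = self.rng.normal(center, self.cfg.subpop_sd * self.tilt_scale)
        return float(np.clip(t, self.tilt_lo, self.tilt_hi))

    def expected_fractions(
        self, tilt: float, trisomy: tuple[int, float] | None = None
    ) -> np.ndarray:
        """Latent post-correction reads fractions for a given tilt (the
        bin-level bias divides out; the chromosome coupling does not)."""
        w_chrom = np.bincount(self.chrom_idx, weights=self.weights, minlength=22)
        lam = w_chrom * self._chrom_coupling(tilt)
        if trisomy is not None:
            chrom, f = trisomy
            lam[chrom - 1] *= 1 + f / 2
        return lam / lam.sum()

    def sample(
        self,
        sample_id: str,
        trisomy: tuple[int, float] | None = None,
        twin: bool = False,
        tilt: float | None = None,
        subpop: int | None = None,
    ) -> BinnedCounts:
        """Draw one sample's binned counts.

        ``trisomy`` is (chromosome, fetal fraction); the effective fraction
        is halved for a twin pregnancy (the unaffected co-twin dilutes the
        signal by about 50%).
        """
        cfg = self.cfg
        rng = self.rng
        if tilt is None:
            tilt = self.draw_tilt(subpop)
        mode = rng.uniform(*cfg.bias_mode)
        amplitude = rng.uniform(*cfg.bias_amplitude)
        bias = self._bias_shape(mode, amplitude) * self._tilt_factor(tilt)
        p = self.weights * bias * self._chrom_coupling(tilt)[self.chrom_idx]
        p = p / p.sum()
        if trisomy is not None:
            chrom, f = trisomy
            f_eff = f / 2 if twin else f
            p = p.copy()
            p[self.chrom_idx == chrom - 1] *= 1 + f_eff / 2
        depth = cfg.depth * np.exp(rng.normal(0.0, cfg.depth_cv))
        lam = depth * p
        if cfg.dispersion > 0:
            lam = rng.gamma(1.0 / cfg.dispersion, cfg.dispersion * lam)
        counts = rng.poisson(lam)
        return BinnedCounts(sample_id, counts)


def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, list[BinnedCounts], pd.DataFrame]:
    """Generate (bins, counts, manifest) for a euploid panel plus any
    trisomic samples listed in ``cfg.trisomy_spec``."""
    sim = CohortSimulator(cfg)
    counts: list[BinnedCounts] = []
    rows = []
    for i in range(cfg.n_panel):
        sid = f"R{i + 1:04d}"
        counts.append(sim.sample(sid))
        rows.append((sid, "euploid", False, False))
    for k, (chrom, f, twin) in enumerate(cfg.trisomy_spec):
        sid = f"A{k + 1:03d}"
        counts.append(sim.sample(sid, trisomy=(chrom, f), twin=twin))
        rows.append((sid, f"T{chrom}", twin, False))
    manifest = pd.DataFrame(rows, columns=["sample_id", "karyotype", "twin", "outlier"])
    return sim.bins, counts, manifest


def stratified_config(cfg: SimulationConfig) -> SimulationConfig:
    """The effective configuration of a GC-stratified panel: two
    subpopulations (asymmetric around the tilt-range centre) and a
    nonlinear GC-to-reads-fraction coupling, unless the caller set them."""
    if cfg.subpop_tilts is None:
        cfg = replace(cfg, subpop_tilts=(-0.5, 0.8), gc_rf_curvature=0.02)
    return cfg


def simulate_gc_stratified_panel(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, list[BinnedCounts], pd.DataFrame]:
    """Generate a panel with >= 2 GC subpopulations.

    The full-panel chromosome-21 CV of the latent reads fractions is
    verified at generation time to exceed every within-subpopulation CV;
    infeasible settings raise.  The returned manifest carries a ``subpop``
    column.
    """
    cfg = stratified_config(cfg)
    if len(cfg.subpop_tilts) < 2:
        raise ValueError("need >= 2 subpopulations")
    sim = CohortSimulator(cfg)
    gc_sep = abs(
        sim._weighted_gc(21, cfg.subpop_tilts[0] * sim.tilt_scale)
        - sim._weighted_gc(21, cfg.subpop_tilts[1] * sim.tilt_scale)
    )
    if gc_sep < 2 * 0.001:
        raise ValueError(
            f"subpopulation GC separation {gc_sep:.4f} below 2 GC units"
        )
    n_sub = len(cfg.subpop_tilts)
    counts: list[BinnedCounts] = []
    rows = []
    tilts: list[float] = []
    for i in range(cfg.n_panel):
        sub = i % n_sub
        tilt = sim.draw_tilt(sub)
        tilts.append(tilt)
        sid = f"R{i + 1:04d}"
        counts.append(sim.sample(sid, tilt=tilt))
        rows.append((sid, "euploid", False, False, sub))
    for k, (chrom, f, twin) in enumerate(cfg.trisomy_spec):
        sub = k % n_sub
        sid = f"A{k + 1:03d}"
        counts.append(sim.sample(sid, trisomy=(chrom, f), twin=twin, subpop=sub))
        rows.append((sid, f"T{chrom}", twin, False, sub))
    manifest = pd.DataFrame(
        rows, columns=["sample_id", "karyotype", "twin", "outlier", "subpop"]
    )

    # generation-time construction check on the latent fractions
    latent21 = np.array([sim.expected_fractions(t)[20] for t in tilts])
    subs = manifest["subpop"].to_numpy()[: cfg.n_panel]
    full_cv = latent21.std(ddof=1) / latent21.mean()
    sub_cvs = [
        latent21[subs == s].std(ddof=1) / latent21[subs == s].mean()
        for s in range(n_sub)
    ]
    if full_cv <= max(sub_cvs):
        raise ValueError(
            f"stratification ineffective: full CV {full_cv:.4g} <= "
            f"subpopulation CVs {max(sub_cvs):.4g}"
        )
    return sim.bins, counts, manifest
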