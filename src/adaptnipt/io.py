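"""Domain types and readers/writers for bins, counts, manifests and reports.

All genomic coordinates are 0-based, half-open.  Only autosomes (1-22) are
carried through the pipeline; rows for other chromosomes are dropped on read
with a logged count.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AUTOSOMES = tuple(range(1, 23))
MAX_BIN_SIZE = 20_000

BIN_COLUMNS = ["chrom", "start", "end", "gc", "usable"]

KARYOTYPES = ("euploid", "T21", "T18", "T13", "other_aneuploidy")


class FormatError(ValueError):
    """Malformed input file (structure, not values)."""


class ValidationError(ValueError):
    """Well-formed input with invalid values."""


def _parse_chrom(label: object) -> int | None:
    """Return autosome number for a chromosome label, None if not an autosome."""
    s = str(label)
    s = re.sub(r"^chr", "", s, flags=re.IGNORECASE)
    if s.isdigit() and 1 <= int(s) <= 22:
        return int(s)
    return None


# ---------------------------------------------------------------------------
# Bin definitions


def read_bins(path: str | Path) -> pd.DataFrame:
    """Read a BED-like bin definition file.

    Columns (no header): chrom, start, end, gc[, usable].  Rows for
    non-autosomal chromosomes are dropped (count logged).  Returns a
    DataFrame with columns ``chrom`` (int 1-22), ``start``, ``end``
    (0-based half-open), ``gc`` and boolean ``usable``, sorted by
    (chrom, start).

    Raises
    ------
    FormatError
        On overlapping bins within a chromosome.
    ValidationError
        On gc outside [0, 1] or bin size above 20 kb.
    """
    raw = pd.read_csv(path, sep="\t", header=None, comment="#")
    if raw.shape[1] < 4:
        raise FormatError(f"{path}: expected >= 4 tab-separated columns")
    raw = raw.iloc[:, :5] if raw.shape[1] >= 5 else raw.iloc[:, :4]
    raw.columns = BIN_COLUMNS[: raw.shape[1]]
    if "usable" not in raw.columns:
        raw["usable"] = True

    chroms = raw["chrom"].map(_parse_chrom)
    dropped = int(chroms.isna().sum())
    if dropped:
        logger.info("read_bins: dropped %d non-autosomal bin rows", dropped)
    bins = raw.loc[chroms.notna()].copy()
    bins["chrom"] = chroms[chroms.notna()].astype(int)
    bins["start"] = bins["start"].astype(int)
    bins["end"] = bins["end"].astype(int)
    bins["gc"] = bins["gc"].astype(float)
    bins["usable"] = bins["usable"].astype(bool)
    bins = bins.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    validate_bins(bins)
    return bins


def validate_bins(bins: pd.DataFrame) -> None:
    sizes = bins["end"] - bins["start"]
    if (sizes <= 0).any():
        raise ValidationError("bin with end <= start")
    if (sizes > MAX_BIN_SIZE).any():
        bad = bins.loc[sizes > MAX_BIN_SIZE].iloc[0]
        raise ValidationError(
            f"bin {bad.chrom}:{bad.start}-{bad.end} exceeds {MAX_BIN_SIZE} bp"
        )
    if ((bins["gc"] < 0) | (bins["gc"] > 1)).any():
        raise ValidationError("bin gc outside [0, 1]")
    for chrom, grp in bins.groupby("chrom"):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if (starts[1:] < ends[:-1]).any():
            raise FormatError(f"overlapping bins on chromosome {chrom}")


def write_bins(bins: pd.DataFrame, path: str | Path) -> None:
    bins.loc[:, BIN_COLUMNS].assign(usable=bins["usable"].astype(int)).to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# Binned counts


@dataclass
class BinnedCounts:
    """Per-bin unique-read counts for one sample, aligned to a bin table."""

    sample_id: str
    counts: np.ndarray  # int, len == n_bins

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValidationError(f"{self.sample_id}: negative counts")


def read_counts(path: str | Path, bins: pd.DataFrame, sample_id: str | None = None) -> BinnedCounts:
    """Read a counts TSV and align it to ``bins``.

    Two layouts are accepted: keyed ``chrom<TAB>start<TAB>count`` with no
    header, or a single column whose header names the sample.  Missing bins
    are filled with 0 (count logged); keyed rows that match no bin are an
    error; duplicated keys are an error.
    """
    path = Path(path)
    first = path.read_text().splitlines()
    if not first:
        raise FormatError(f"{path}: empty counts file")
    ncol = len(first[0].split("\t"))

    if ncol == 1:
        header = first[0].strip()
        values = first[1:]
        try:
            counts = np.array([int(v) for v in values])
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer count") from exc
        if len(counts) != len(bins):
            raise FormatError(
                f"{path}: {len(counts)} counts for {len(bins)} bins"
            )
        return BinnedCounts(sample_id or header, counts)

    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "count"])
    chroms = df["chrom"].map(_parse_chrom)
    n_other = int(chroms.isna().sum())
    if n_other:
        logger.info("read_counts %s: dropped %d non-autosomal rows", path, n_other)
    df = df.loc[chroms.notna()].copy()
    df["chrom"] = chroms[chroms.notna()].astype(int)
    key = list(zip(df["chrom"], df["start"].astype(int)))
    if len(set(key)) != len(key):
        raise FormatError(f"{path}: duplicated (chrom, start) rows")
    index = {(c, s): i for i, (c, s) in enumerate(zip(bins["chrom"], bins["start"]))}
    counts = np.zeros(len(bins), dtype=np.int64)
    seen = 0
    for (k, cnt) in zip(key, df["count"].astype(int)):
        if k not in index:
            raise FormatError(f"{path}: count row {k} matches no bin")
        counts[index[k]] = cnt
        seen += 1
    if seen < len(bins):
        logger.info("read_counts %s: %d bins missing, filled with 0", path, len(bins) - seen)
    return BinnedCounts(sample_id or path.stem, counts)


def write_counts(bc: BinnedCounts, bins: pd.DataFrame, path: str | Path) -> None:
    pd.DataFrame(
        {"chrom": bins["chrom"], "start": bins["start"], "count": bc.counts}
    ).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Cohort manifest


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest TSV (header: sample_id karyotype twin outlier)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "karyotype", "twin", "outlier"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: manifest missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample_ids in manifest")
    bad = set(df["karyotype"]) - set(KARYOTYPES)
    if bad:
        raise ValidationError(f"{path}: unknown karyotypes {sorted(bad)}")
    df["twin"] = df["twin"].astype(bool)
    df["outlier"] = df["outlier"].astype(bool)
    return df


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    out = manifest.copy()
    out["twin"] = out["twin"].astype(int)
    out["outlier"] = out["outlier"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def filter_reference_eligible(manifest: pd.DataFrame) -> list[str]:
    """Sample ids usable as reference: euploid, singleton, not an outlier.

    Exclusion categories may overlap; a sample failing several criteria is
    excluded once (set union).
    """
    ok = (
        (manifest["karyotype"] == "euploid")
        & ~manifest["twin"]
        & ~manifest["outlier"]
    )
    return manifest.loc[ok, "sample_id"].tolist()


def example_manifest() -> pd.DataFrame:
    """Bundled 447-sample high-risk screening cohort manifest.

    Composition: 13 T21 fetuses (3 of them twin pregnancies), one T18 (twin),
    one T13, two XXY (recorded as other_aneuploidy), 29 additional euploid
    twin pregnancies, and 5 euploid singleton outliers; the remaining 396
    samples are reference-eligible euploid singletons.
    """
    rows: list[tuple[str, str, bool, bool]] = []
    i = 0

    def add(karyotype: str, twin: bool, outlier: bool, n: int = 1) -> None:
        nonlocal i
        for _ in range(n):
            i += 1
            rows.append((f"S{i:03d}", karyotype, twin, outlier))

    add("T21", twin=True, outlier=False, n=3)
    add("T21", twin=False, outlier=False, n=10)
    add("T18", twin=True, outlier=False, n=1)
    add("T13", twin=False, outlier=False, n=1)
    add("other_aneuploidy", twin=False, outlier=False, n=2)
    add("euploid", twin=True, outlier=False, n=29)
    add("euploid", twin=False, outlier=True, n=5)
    add("euploid", twin=False, outlier=False, n=447 - i)
    return pd.DataFrame(rows, columns=["sample_id", "karyotype", "twin", "outlier"])


# ---------------------------------------------------------------------------
# Calls / report


@dataclass
class AneuploidyCall:
    """One scored (sample, target chromosome) pair."""

    sample_id: str
    chrom: int
    z: float
    panel_size: int
    panel_cv: float
    classification: str


REPORT_COLUMNS = ["sample_id", "chrom", "z", "panel_size", "panel_cv", "classification"]


def write_report(calls: Sequence[AneuploidyCall], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (c.sample_id, c.chrom, c.z, c.panel_size, c.panel_cv, c.classification)
            for c in calls
        ],
        columns=REPORT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_report(path: str | Path) -> list[AneuploidyCall]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if list(df.columns) != REPORT_COLUMNS:
        raise FormatError(f"{path}: unexpected report columns {list(df.columns)}")
    return [
        AneuploidyCall(
            sample_id=r.sample_id,
            chrom=int(r.chrom),
            z=float(r.z),
            panel_size=int(r.panel_size),
            panel_cv=float(r.panel_cv),
            classification=str(r.classification),
        )
        for r in df.itertuples()
    ]
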