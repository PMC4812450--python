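"""Bin-based detection of runs of homozygosity and diversity outside them.

The genome is tiled into adjacent, non-overlapping 10-kb bins.  Per sample,
heterozygous SNPs are counted into bins and the count is scaled up from the
number of covered sites to the full bin length (the coverage correction for
missing data): ``scaled = raw * bin_size / covered_sites``.  Bins with fewer
than 1,000 covered sites (<10% of the bin) and bins on sex chromosomes are
excluded.  A run of homozygosity (ROH) is a maximal run of at least twenty
consecutive retained bins each with a scaled SNP count strictly below 0.33
of the genomic average; any non-retained bin terminates a run.  Nucleotide
diversity (π, here: scaled SNPs per 10-kb bin) is the mean over retained
bins outside all ROHs.

The genomic average is computed genome-wide per individual over all
retained bins, ROH bins included — the average is defined before any ROH
exists; excluding ROH bins would make the threshold circular.

Long ROHs indicate recent consanguineous mating; short ROHs older
inbreeding, since recombination and mutation break runs down over time.
ROHs are classified into length categories (default edges 0.2, 0.5, 1, 2,
5 Mb, half-open ``[lo, hi)``) to separate the two signals.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .vcf_io import GT_HET, VariantTable

DEFAULT_BIN_SIZE = 10_000
DEFAULT_MIN_BINS = 20
DEFAULT_FRAC = 0.33
DEFAULT_MIN_COVERED = 1_000
DEFAULT_SEX_CHROMS = ("X", "Y")
DEFAULT_CATEGORY_EDGES_MB = (0.2, 0.5, 1.0, 2.0, 5.0)

ROH_COLUMNS = ["chrom", "start", "end", "n_bins", "length"]


def bin_genome(
    table: VariantTable,
    sample: str,
    chrom_lengths: Mapping[str, int],
    coverage: pd.DataFrame | None = None,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> pd.DataFrame:
    """Tile chromosomes into bins and count one sample's heterozygous SNPs.

    ``coverage``, if given, holds per-bin covered-site counts (columns
    ``chrom, start, covered_sites``); bins absent from it count as
    uncovered.  Without it every position is treated as covered.

    Returns a bin track: ``chrom, start, end, covered_sites,
    raw_snp_count, scaled_snp_count (NaN), retained (True)``.
    """
    frames = []
    for chrom, length in chrom_lengths.items():
        n_bins = int(math.ceil(length / bin_size))
        starts = np.arange(n_bins, dtype=np.int64) * bin_size
        ends = np.minimum(starts + bin_size, length)
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    track = pd.concat(frames, ignore_index=True)

    if coverage is None:
        track["covered_sites"] = track["end"] - track["start"]
    else:
        cov = coverage[["chrom", "start", "covered_sites"]]
        track = track.merge(cov, on=["chrom", "start"], how="left")
        track["covered_sites"] = track["covered_sites"].fillna(0).astype(np.int64)
    if (track["covered_sites"] > track["end"] - track["start"]).any():
        raise ValueError("covered_sites exceeds bin length")

    track["raw_snp_count"] = 0
    het = table.df.loc[table.gt(sample) == GT_HET, ["chrom", "pos"]]
    for chrom, sub in het.groupby("chrom", sort=False):
        if chrom not in chrom_lengths:
            raise ValueError(f"site on chromosome {chrom!r} absent from chrom_lengths")
        if (sub["pos"] > chrom_lengths[chrom]).any():
            bad = int(sub.loc[sub["pos"] > chrom_lengths[chrom], "pos"].iloc[0])
            raise ValueError(f"site {chrom}:{bad} beyond chromosome length {chrom_lengths[chrom]}")
        idx = (sub["pos"].to_numpy() - 1) // bin_size
        counts = np.bincount(idx, minlength=int(math.ceil(chrom_lengths[chrom] / bin_size)))
        mask = track["chrom"] == chrom
        track.loc[mask, "raw_snp_count"] = counts
    track["scaled_snp_count"] = np.nan
    track["retained"] = True
    return track


def scale_bins(track: pd.DataFrame, bin_size: int = DEFAULT_BIN_SIZE) -> pd.DataFrame:
    """Scale raw SNP counts up from covered sites to the full bin length."""
    out = track.copy()
    cov = out["covered_sites"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["scaled_snp_count"] = np.where(cov > 0, out["raw_snp_count"] * bin_size / cov, np.nan)
    out.loc[cov <= 0, "retained"] = False
    return out


def filter_bins(
    track: pd.DataFrame,
    sex_chroms: Iterable[str] = DEFAULT_SEX_CHROMS,
    min_covered: int = DEFAULT_MIN_COVERED,
) -> pd.DataFrame:
    """Retain autosomal bins with at least ``min_covered`` covered sites."""
    out = track.copy()
    sex = set(sex_chroms)
    out["retained"] = (out["covered_sites"] >= min_covered) & ~out["chrom"].isin(sex)
    return out


def genomic_average(track: pd.DataFrame) -> float:
    """Mean scaled SNP count over retained bins (ROH bins included)."""
    vals = track.loc[track["retained"], "scaled_snp_count"]
    if len(vals) == 0:
        raise ValueError("no retained bins: cannot compute genomic average")
    return float(vals.mean())


def call_rohs(
    track: pd.DataFrame,
    genomic_avg: float | None = None,
    min_bins: int = DEFAULT_MIN_BINS,
    frac: float = DEFAULT_FRAC,
    max_gap_bins: int = 0,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> pd.DataFrame:
    """Call ROHs: runs of ≥ ``min_bins`` consecutive retained low-SNP bins.

    A bin qualifies when retained and ``scaled_snp_count < frac *
    genomic_avg`` (strict).  A non-retained or non-qualifying bin
    terminates a run; with ``max_gap_bins > 0`` qualifying runs on the
    same chromosome separated by at most that many bins are merged
    (``n_bins`` still counts only qualifying bins).

    Returns a frame with columns ``chrom, start, end, n_bins, length``.
    """
    if genomic_avg is None:
        genomic_avg = genomic_average(track)
    if genomic_avg <= 0:
        raise ValueError("genomic average must be positive to call ROHs")
    cutoff = frac * genomic_avg

    segs: list[dict] = []
    for chrom, sub in track.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        qual = (
            sub["retained"].to_numpy()
            & (sub["scaled_snp_count"].to_numpy() < cutoff)
        )
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        runs: list[tuple[int, int]] = []  # [first_idx, last_idx]
        i = 0
        n = len(sub)
        while i < n:
            if qual[i]:
                j = i
                while j + 1 < n and qual[j + 1]:
                    j += 1
                runs.append((i, j))
                i = j + 1
            else:
                i += 1
        if max_gap_bins > 0 and runs:
            merged = [list(runs[0])]
            for a, b in runs[1:]:
                if a - merged[-1][1] - 1 <= max_gap_bins:
                    merged[-1][1] = b
                else:
                    merged.append([a, b])
            runs = [(a, b) for a, b in merged]
        for a, b in runs:
            n_qual = int(qual[a : b + 1].sum())
            if n_qual >= min_bins:
                segs.append(
                    {
                        "chrom": chrom,
                        "start": int(starts[a]),
                        "end": int(ends[b]),
                        "n_bins": n_qual,
                        "length": int(ends[b] - starts[a]),
                    }
                )
    return pd.DataFrame(segs, columns=ROH_COLUMNS)


def _category_labels(edges_mb: tuple[float, ...]) -> list[str]:
    labels = [f"{lo:g}-{hi:g}" for lo, hi in zip(edges_mb, edges_mb[1:])]
    labels.append(f">={edges_mb[-1]:g}")
    return labels


def classify_lengths(
    rohs: pd.DataFrame,
    edges_mb: tuple[float, ...] = DEFAULT_CATEGORY_EDGES_MB,
    strict: bool = True,
) -> pd.DataFrame:
    """Assign each ROH to a half-open ``[lo, hi)`` length category (Mb).

    Returns per-category ``n_rohs`` and ``total_bp``, covering every
    category even when empty.  A ROH shorter than the smallest edge is an
    error (cannot occur with the default 20-bin minimum); with
    ``strict=False`` such ROHs fall into an extra ``<lo`` category
    instead, for runs configured with a smaller bin minimum.
    """
    labels = _category_labels(edges_mb)
    bounds = [e * 1e6 for e in edges_mb] + [np.inf]
    if len(rohs) and (rohs["length"] < bounds[0]).any():
        if strict:
            raise ValueError(f"ROH shorter than the smallest category edge {edges_mb[0]} Mb")
        labels = [f"<{edges_mb[0]:g}"] + labels
        bounds = [0.0] + bounds
    out = pd.DataFrame({"category": labels, "n_rohs": 0, "total_bp": 0}).set_index("category")
    if len(rohs):
        cats = pd.cut(rohs["length"], bins=bounds, labels=labels, right=False)
        grouped = rohs.groupby(cats, observed=False)["length"].agg(["count", "sum"])
        out["n_rohs"] = grouped["count"]
        out["total_bp"] = grouped["sum"]
    return out.astype({"n_rohs": int, "total_bp": int})


def _outside_mask(track: pd.DataFrame, rohs: pd.DataFrame) -> np.ndarray:
    """Boolean mask of track bins lying outside every ROH."""
    outside = np.ones(len(track), dtype=bool)
    for r in rohs.itertuples(index=False):
        inside = (
            (track["chrom"] == r.chrom)
            & (track["start"] >= r.start)
            & (track["start"] < r.end)
        )
        outside &= ~inside.to_numpy()
    return outside


def diversity_outside(track: pd.DataFrame, rohs: pd.DataFrame) -> float:
    """π: mean scaled SNP count over retained bins outside all ROHs."""
    mask = track["retained"].to_numpy() & _outside_mask(track, rohs)
    if not mask.any():
        raise ValueError("every retained bin lies inside a ROH; diversity undefined")
    return float(track.loc[mask, "scaled_snp_count"].mean())


@dataclass
class DiversitySummary:
    """Per-sample ROH and diversity summary."""

    sample: str
    n_rohs: int
    mean_roh_length_kb: float  # NaN when no ROHs
    pi: float
    genome_fraction_in_roh: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.genome_fraction_in_roh.values())
        if self.genome_fraction_in_roh and not (-1e-9 <= total <= 1 + 1e-9):
            raise ValueError("genome fractions must lie in [0, 1] and sum to <= 1")


def summarize_sample(
    sample: str,
    track: pd.DataFrame,
    rohs: pd.DataFrame,
    edges_mb: tuple[float, ...] = DEFAULT_CATEGORY_EDGES_MB,
) -> DiversitySummary:
    """Bundle ROH count, mean length, π and per-category genome fractions."""
    genome_bp = int((track["end"] - track["start"]).sum())
    cats = classify_lengths(rohs, edges_mb, strict=False)
    fractions = (cats["total_bp"] / genome_bp).to_dict() if genome_bp else {}
    return DiversitySummary(
        sample=sample,
        n_rohs=int(len(rohs)),
        mean_roh_length_kb=float(rohs["length"].mean() / 1e3) if len(rohs) else float("nan"),
        pi=diversity_outside(track, rohs),
        genome_fraction_in_roh=fractions,
    )


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention used for reported means)."""
    scale = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)


def summarize_cohort(
    summaries: pd.DataFrame,
    group_map: Mapping[str, str],
    metrics: tuple[str, ...] = ("n_rohs", "mean_roh_length_kb", "pi"),
) -> pd.DataFrame:
    """Per-group (and overall) mean and sample SD of summary metrics.

    ``summaries`` needs a ``sample`` column plus the metric columns; every
    sample must be mapped to a group.  The overall row is labelled
    ``all``.  SD is reported as NaN for single-sample groups.
    """
    df = summaries.copy()
    missing = [s for s in df["sample"] if s not in group_map]
    if missing:
        raise ValueError(f"samples without a group: {missing}")
    df["group"] = df["sample"].map(group_map)
    if (df.groupby("group").size() == 0).any():
        raise ValueError("empty group")

    rows = []
    for group, sub in [("all", df)] + list(df.groupby("group")):
        if len(sub) == 0:
            raise ValueError(f"empty group {group!r}")
        row: dict[str, float | str | int] = {"group": group, "n_samples": len(sub)}
        for m in metrics:
            row[f"{m}_mean"] = float(sub[m].mean())
            row[f"{m}_sd"] = float(sub[m].std(ddof=1)) if len(sub) > 1 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


def write_roh_bed(rohs: pd.DataFrame, path) -> None:
    """ROHs as BED (0-based half-open) with an n_bins column."""
    rohs[["chrom", "start", "end", "n_bins"]].to_csv(path, sep="\t", header=False, index=False)
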