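"""Synthetic genomes, coverage tracks, cohorts and pedigrees with known truth.

Every downstream stage of the pipeline has a generator here that plants a
known answer:

* :func:`simulate_individual` emits one diploid genome's heterozygous sites
  as a Poisson process — rate ``het_rate_per_bin`` (λ, SNPs per 10-kb bin)
  outside planted autozygous tracts and ``tract_residual_factor``·λ (ε·λ)
  inside them — together with a per-bin covered-sites track and per-site
  read depths.  The planted tracts are the truth for ROH-recovery tests;
  λ is the truth for diversity-recovery tests.  The default λ of 12
  matches the heterozygosity scale of a severely bottlenecked wild pig
  population; ε defaults to 0 (fully autozygous tracts).
* :func:`simulate_cohort` builds a two-island cohort with exact planted
  counts of shared and island-private variants, each passing the minor-
  allele-count ≥ 2 rule, so the partitioning stage must recover the counts
  exactly.
* :func:`simulate_pedigree` emits studbook-format pedigrees for textbook
  mating designs whose focal individual has a known inbreeding coefficient.

Depth model: per-site depth is Poisson(``mean_depth``); a "covered" site is
one whose depth falls inside the depth-filter window.  The per-bin covered
count is therefore Binomial(bin_size, p) with p the Poisson window mass —
drawn directly at bin granularity.  A dropout bin has its covered count
(and the depths of variants inside it) forced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .vcf_io import GT_HET, GT_HOM_ALT, GT_HOM_REF, VariantTable

_BASES = np.array(list("ACGT"))

DEFAULT_BIN_SIZE = 10_000


@dataclass(frozen=True)
class SimConfig:
    """Configuration for a single-genome simulation.

    Parameters
    ----------
    chrom_lengths
        Chromosome name → length in bp.
    het_rate_per_bin
        λ: expected heterozygous SNPs per 10-kb bin outside tracts.
    tract_residual_factor
        ε ∈ [0, 1): fraction of λ remaining inside planted tracts.
    planted_tracts
        Autozygous tracts as (chrom, start, end), 0-based half-open;
        must lie within chromosome bounds and not overlap.
    mean_depth
        Expected reads per site (Poisson mean).
    dropout_prob
        Per-bin probability of total coverage loss.
    depth_lower, depth_upper
        Depth-window factors defining a "covered" site, matching the
        variant depth filter.
    """

    chrom_lengths: dict[str, int]
    het_rate_per_bin: float = 12.0
    tract_residual_factor: float = 0.0
    planted_tracts: tuple[tuple[str, int, int], ...] = ()
    mean_depth: float = 10.0
    dropout_prob: float = 0.0
    depth_lower: float = 0.5
    depth_upper: float = 2.0
    bin_size: int = DEFAULT_BIN_SIZE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.het_rate_per_bin <= 0:
            raise ValueError("het_rate_per_bin must be > 0")
        if not (0 <= self.tract_residual_factor < 1):
            raise ValueError("tract_residual_factor must be in [0, 1)")
        if not (0 <= self.dropout_prob <= 1):
            raise ValueError("dropout_prob must be in [0, 1]")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.planted_tracts:
            if chrom not in self.chrom_lengths:
                raise ValueError(f"tract on unknown chromosome {chrom!r}")
            if not (0 <= start < end <= self.chrom_lengths[chrom]):
                raise ValueError(f"tract ({chrom}, {start}, {end}) outside chromosome bounds")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, tracts in by_chrom.items():
            tracts.sort()
            for (s1, e1), (s2, e2) in zip(tracts, tracts[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping tracts on {chrom}: ({s1},{e1}) and ({s2},{e2})")


@dataclass
class SimTruth:
    """Ground truth emitted alongside simulated data."""

    planted_tracts: tuple[tuple[str, int, int], ...] = ()
    site_categories: pd.Series | None = None  # pos-indexed: shared / <island>_private


def _coverage_probability(cfg: SimConfig) -> float:
    """P(Poisson(mean_depth) inside the inclusive depth window)."""
    lo = int(np.ceil(cfg.depth_lower * cfg.mean_depth))
    hi = int(np.floor(cfg.depth_upper * cfg.mean_depth))
    return float(stats.poisson.cdf(hi, cfg.mean_depth) - stats.poisson.cdf(lo - 1, cfg.mean_depth))


def _chrom_segments(cfg: SimConfig, chrom: str) -> list[tuple[int, int, bool]]:
    """Partition a chromosome into (start, end, in_tract) segments."""
    length = cfg.chrom_lengths[chrom]
    tracts = sorted((s, e) for c, s, e in cfg.planted_tracts if c == chrom)
    segs: list[tuple[int, int, bool]] = []
    cursor = 0
    for s, e in tracts:
        if s > cursor:
            segs.append((cursor, s, False))
        segs.append((s, e, True))
        cursor = e
    if cursor < length:
        segs.append((cursor, length, False))
    return segs


def simulate_individual(
    config: SimConfig,
    seed: int | None = None,
    sample_name: str = "indiv1",
) -> tuple[VariantTable, pd.DataFrame, SimTruth]:
    """Simulate one genome: heterozygous sites, coverage track, truth.

    Returns
    -------
    variants
        Single-sample :class:`VariantTable` of heterozygous sites with
        per-site read depths.
    coverage
        Per-bin covered-site counts: columns ``chrom, start, end,
        covered_sites``.
    truth
        The planted tracts.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    p_cov = _coverage_probability(config)
    bs = config.bin_size
    rate_bp = config.het_rate_per_bin / bs

    chroms: list[str] = []
    positions: list[np.ndarray] = []
    cov_frames: list[pd.DataFrame] = []

    for chrom, length in config.chrom_lengths.items():
        pos_parts = []
        for s, e, in_tract in _chrom_segments(config, chrom):
            rate = rate_bp * (config.tract_residual_factor if in_tract else 1.0)
            n = rng.poisson(rate * (e - s))
            if n:
                # 1-based positions inside (s, e]
                pos_parts.append(rng.integers(s + 1, e + 1, size=n))
        pos = np.unique(np.concatenate(pos_parts)) if pos_parts else np.empty(0, dtype=np.int64)
        chroms.extend([chrom] * len(pos))
        positions.append(pos)

        n_bins = int(np.ceil(length / bs))
        starts = np.arange(n_bins, dtype=np.int64) * bs
        ends = np.minimum(starts + bs, length)
        covered = rng.binomial(ends - starts, p_cov)
        dropout = rng.random(n_bins) < config.dropout_prob
        covered[dropout] = 0
        cov_frames.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends, "covered_sites": covered, "_dropout": dropout}
            )
        )

    coverage = pd.concat(cov_frames, ignore_index=True) if cov_frames else pd.DataFrame(
        columns=["chrom", "start", "end", "covered_sites", "_dropout"]
    )
    pos_all = np.concatenate(positions) if positions else np.empty(0, dtype=np.int64)
    n_sites = len(pos_all)

    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    depths = rng.poisson(config.mean_depth, size=n_sites).astype(np.int32)

    # zero out depths of variants falling into dropout bins
    dropout_keys = {
        (c, s)
        for c, s, drop in zip(coverage["chrom"], coverage["start"], coverage["_dropout"])
        if drop
    }
    if dropout_keys and n_sites:
        bin_start = ((pos_all - 1) // bs) * bs
        in_dropout = np.fromiter(
            ((c, b) in dropout_keys for c, b in zip(chroms, bin_start)), dtype=bool, count=n_sites
        )
        depths[in_dropout] = 0

    variants = VariantTable.from_records(
        chrom=chroms,
        pos=pos_all,
        ref=_BASES[ref_idx],
        alt=_BASES[alt_idx],
        genotypes={sample_name: np.full(n_sites, GT_HET, dtype=np.int8)},
        depths={sample_name: depths},
    )
    coverage = coverage.drop(columns="_dropout")
    return variants, coverage, SimTruth(planted_tracts=tuple(config.planted_tracts))


def simulate_cohort(
    n_panay: int,
    n_negros: int,
    n_shared: int,
    n_panay_private: int,
    n_negros_private: int,
    seed: int = 0,
    chrom: str = "1",
    spacing: int = 100,
    mean_depth: float = 10.0,
    island_names: tuple[str, str] = ("panay", "negros"),
) -> tuple[VariantTable, dict[str, str], SimTruth]:
    """Simulate a two-island cohort with exact planted variant categories.

    Every emitted site is biallelic, not a fixed difference, and passes
    MAC ≥ 2: a shared site carries the minor allele as one heterozygote on
    each island; a private site carries it as two heterozygotes (or one
    homozygote when the island has a single sample) on its island only.

    Returns the multi-sample table, the sample→island map, and the truth
    category per site.
    """
    for name, v in [
        ("n_shared", n_shared),
        ("n_panay_private", n_panay_private),
        ("n_negros_private", n_negros_private),
    ]:
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    if n_panay < 1 or n_negros < 1:
        raise ValueError("each island needs at least one sample")

    isl_a, isl_b = island_names
    samples_a = [f"{isl_a}_{i + 1}" for i in range(n_panay)]
    samples_b = [f"{isl_b}_{i + 1}" for i in range(n_negros)]
    samples = samples_a + samples_b
    island_map = {s: isl_a for s in samples_a} | {s: isl_b for s in samples_b}

    rng = np.random.default_rng(seed)
    total = n_shared + n_panay_private + n_negros_private
    categories = np.array(
        ["shared"] * n_shared
        + [f"{isl_a}_private"] * n_panay_private
        + [f"{isl_b}_private"] * n_negros_private
    )
    rng.shuffle(categories)

    pos = (np.arange(total, dtype=np.int64) + 1) * spacing
    gt = np.zeros((total, len(samples)), dtype=np.int8)
    idx_a = np.arange(n_panay)
    idx_b = np.arange(n_panay, n_panay + n_negros)

    for i, cat in enumerate(categories):
        if cat == "shared":
            gt[i, rng.choice(idx_a)] = GT_HET
            gt[i, rng.choice(idx_b)] = GT_HET
        else:
            idx = idx_a if cat == f"{isl_a}_private" else idx_b
            if len(idx) >= 2:
                a, b = rng.choice(idx, size=2, replace=False)
                gt[i, a] = GT_HET
                gt[i, b] = GT_HET
            else:
                gt[i, idx[0]] = GT_HOM_ALT

    ref_idx = rng.integers(0, 4, size=total)
    alt_idx = (ref_idx + rng.integers(1, 4, size=total)) % 4
    # constant in-window depth: planted counts must survive depth filtering
    depths = np.full((total, len(samples)), int(round(mean_depth)), dtype=np.int32)

    variants = VariantTable.from_records(
        chrom=[chrom] * total,
        pos=pos,
        ref=_BASES[ref_idx],
        alt=_BASES[alt_idx],
        genotypes={s: gt[:, j] for j, s in enumerate(samples)},
        depths={s: depths[:, j] for j, s in enumerate(samples)},
    )
    truth = SimTruth(site_categories=pd.Series(categories, index=pos, name="category"))
    return variants, island_map, truth


PEDIGREE_DESIGNS = ("full_sib", "half_sib", "first_cousin", "outbred")

_WILD = "WILD"


def simulate_pedigree(design: str, seed: int = 0) -> tuple[pd.DataFrame, str]:
    """Studbook-format pedigree for a textbook mating design.

    The focal (last) individual has the textbook inbreeding coefficient:
    0.25 for full-sib mating, 0.125 for half-sib, 0.0625 for first-cousin,
    0 for outbred.  Birth dates advance five years per generation so the
    pedigree also exercises generation-time estimation.

    Returns (studbook table, focal individual id).
    """
    del seed  # designs are fixed; accepted for interface symmetry

    def row(i, sire, dam, year):
        return {"id": i, "sire": sire, "dam": dam, "birth_date": f"{year}-06-01", "origin": "sim"}

    if design == "full_sib":
        rows = [
            row("F1", _WILD, _WILD, 2000),
            row("F2", _WILD, _WILD, 2000),
            row("S1", "F1", "F2", 2005),
            row("S2", "F1", "F2", 2005),
            row("X", "S1", "S2", 2010),
        ]
    elif design == "half_sib":
        rows = [
            row("F1", _WILD, _WILD, 2000),
            row("F2", _WILD, _WILD, 2000),
            row("F3", _WILD, _WILD, 2000),
            row("S1", "F1", "F2", 2005),
            row("S2", "F1", "F3", 2005),
            row("X", "S1", "S2", 2010),
        ]
    elif design == "first_cousin":
        rows = [
            row("F1", _WILD, _WILD, 2000),
            row("F2", _WILD, _WILD, 2000),
            row("F3", _WILD, _WILD, 2000),
            row("F4", _WILD, _WILD, 2000),
            row("S1", "F1", "F2", 2005),
            row("S2", "F1", "F2", 2005),
            row("C1", "S1", "F3", 2010),
            row("C2", "S2", "F4", 2010),
            row("X", "C1", "C2", 2015),
        ]
    elif design == "outbred":
        rows = [
            row("F1", _WILD, _WILD, 2000),
            row("F2", _WILD, _WILD, 2000),
            row("X", "F1", "F2", 2005),
        ]
    else:
        raise ValueError(f"unknown pedigree design {design!r}; expected one of {PEDIGREE_DESIGNS}")
    return pd.DataFrame(rows), "X"


def write_truth_bed(truth: SimTruth, path) -> None:
    """Write planted tracts as BED (0-based, half-open)."""
    with open(path, "w") as fh:
        for chrom, start, end in truth.planted_tracts:
            fh.write(f"{chrom}\t{start}\t{end}\n")
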