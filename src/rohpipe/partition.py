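"""Shared vs. island-private variant partitioning with consequence classes.

For a small two-island cohort, the fraction of variation private to one
island measures how recently the populations split: a recent split leaves
most variants shared.  Sites first pass two cleaning rules: fixed
differences against the reference species (every non-missing genotype
homozygous for the same allele) are removed as uninformative within the
study species, and sites with a cohort minor-allele count below 2
(singleton haplotypes) are removed as likely spurious calls.  The minor
allele is determined from cohort haplotype counts (het = 1 haplotype,
hom = 2); an exact tie treats the alt allele as minor.  A surviving site
is private to an island when every carrier of its minor allele belongs to
that island, and shared otherwise.

Consequence classes come from a precomputed annotation table (variant
effect prediction is upstream): synonymous, nonsynonymous tolerated
(SIFT ≥ 0.05) and nonsynonymous not-tolerated (SIFT < 0.05).  SIFT scores
run from 1 ("tolerated") to 0 ("deleterious").  The heterozygous-to-
homozygous ratio of genotype observations per class is a purging
diagnostic: deleterious recessives surviving mostly as heterozygotes
inflate the ratio in the not-tolerated class.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
import pandas as pd

from .vcf_io import GT_HET, GT_HOM_ALT, GT_HOM_REF, VariantTable

DEFAULT_MAC = 2
DEFAULT_SIFT_THRESHOLD = 0.05

CLASS_ALL = "all"
CLASS_SYN = "synonymous"
CLASS_TOL = "nonsyn_tolerated"
CLASS_NOT_TOL = "nonsyn_not_tolerated"
PARTITION_CLASSES = (CLASS_ALL, CLASS_SYN, CLASS_TOL, CLASS_NOT_TOL)


def allele_counts(table: VariantTable) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (ref, alt) haplotype counts over non-missing genotypes."""
    gm = table.gt_matrix()
    het = gm == GT_HET
    alt = het.sum(axis=1) + 2 * (gm == GT_HOM_ALT).sum(axis=1)
    ref = het.sum(axis=1) + 2 * (gm == GT_HOM_REF).sum(axis=1)
    return ref.astype(np.int64), alt.astype(np.int64)


def remove_fixed_differences(table: VariantTable) -> VariantTable:
    """Drop sites invariant in the cohort (all hom-alt, i.e. fixed against
    the reference species, or all hom-ref)."""
    ref, alt = allele_counts(table)
    keep = (ref > 0) & (alt > 0)
    return VariantTable(table.df.loc[keep].reset_index(drop=True), list(table.samples))


def minor_allele(table: VariantTable) -> tuple[np.ndarray, np.ndarray]:
    """Per-site minor-allele count and a flag for 'minor allele is alt'.

    Ties (equal haplotype counts) treat alt as minor.
    """
    ref, alt = allele_counts(table)
    minor_is_alt = alt <= ref
    return np.where(minor_is_alt, alt, ref), minor_is_alt


def mac_filter(table: VariantTable, min_count: int = DEFAULT_MAC) -> VariantTable:
    """Drop sites whose cohort minor-allele count is below ``min_count``."""
    mac, _ = minor_allele(table)
    keep = mac >= min_count
    return VariantTable(table.df.loc[keep].reset_index(drop=True), list(table.samples))


def partition_by_island(
    table: VariantTable, island_map: Mapping[str, str]
) -> tuple[pd.Series, dict[str, int]]:
    """Classify each site as shared or ``<island>_private``.

    A site is private to an island when all carriers of its minor allele
    are that island's samples.  Missing genotypes contribute nothing and
    cannot make a site private on their own.  Returns the per-site
    category series (aligned to the table) and category counts, with all
    categories present (zero-filled).
    """
    unmapped = [s for s in table.samples if s not in island_map]
    if unmapped:
        raise ValueError(f"samples without an island assignment: {unmapped}")
    islands = sorted(set(island_map[s] for s in table.samples))
    sample_island = np.array([island_map[s] for s in table.samples])

    _, minor_is_alt = minor_allele(table)
    gm = table.gt_matrix()
    carries_alt = (gm == GT_HET) | (gm == GT_HOM_ALT)
    carries_ref = (gm == GT_HET) | (gm == GT_HOM_REF)
    carriers = np.where(minor_is_alt[:, None], carries_alt, carries_ref)

    cats = []
    for i in range(table.n_sites):
        isl = set(sample_island[carriers[i]])
        if len(isl) == 0:
            raise ValueError(
                f"site {table.df['chrom'].iat[i]}:{table.df['pos'].iat[i]} has no minor-allele "
                "carriers; apply remove_fixed_differences/mac_filter first"
            )
        cats.append(f"{isl.pop()}_private" if len(isl) == 1 else "shared")
    categories = pd.Series(cats, index=table.df.index, name="category")
    counts = {"shared": 0, **{f"{i}_private": 0 for i in islands}}
    counts.update(categories.value_counts().to_dict())
    return categories, counts


def classify_sift(
    annotations: pd.DataFrame, threshold: float = DEFAULT_SIFT_THRESHOLD
) -> pd.Series:
    """Consequence class per annotated site.

    ``annotations`` columns: ``chrom, pos, consequence`` and
    ``sift_score`` (nonsynonymous only).  Nonsynonymous sites with a SIFT
    score strictly below ``threshold`` are not-tolerated; at or above it,
    tolerated.  A score exactly at the threshold is therefore tolerated.
    """
    cons = annotations["consequence"]
    sift = annotations.get("sift_score", pd.Series(np.nan, index=annotations.index))
    nonsyn = cons == "nonsynonymous"
    valid = sift.dropna()
    if ((valid < 0) | (valid > 1)).any():
        raise ValueError("SIFT scores must lie in [0, 1]")
    if (sift.notna() & ~nonsyn).any():
        raise ValueError("SIFT scores are defined for nonsynonymous sites only")
    if (nonsyn & sift.isna()).any():
        raise ValueError("nonsynonymous sites require a SIFT score")
    out = pd.Series("other", index=annotations.index, name="class")
    out[cons == "synonymous"] = CLASS_SYN
    out[nonsyn & (sift < threshold)] = CLASS_NOT_TOL
    out[nonsyn & (sift >= threshold)] = CLASS_TOL
    return out


def partition_table(
    table: VariantTable,
    island_map: Mapping[str, str],
    annotations: pd.DataFrame | None = None,
    sift_threshold: float = DEFAULT_SIFT_THRESHOLD,
) -> pd.DataFrame:
    """Counts of shared / island-private sites per consequence class.

    Rows: all sites, synonymous, nonsynonymous tolerated, nonsynonymous
    not-tolerated.  Columns: shared and one ``<island>_private`` per
    island.  Annotated classes cover only sites present in
    ``annotations``; unannotated sites count toward the ``all`` row only.
    """
    categories, counts = partition_by_island(table, island_map)
    columns = list(counts)
    out = pd.DataFrame(0, index=list(PARTITION_CLASSES), columns=columns, dtype=int)
    for cat, n in counts.items():
        out.loc[CLASS_ALL, cat] = n

    if annotations is not None and len(annotations):
        classes = classify_sift(annotations, sift_threshold)
        ann = annotations[["chrom", "pos"]].copy()
        ann["class"] = classes
        sites = table.df[["chrom", "pos"]].copy()
        sites["category"] = categories
        joined = sites.merge(ann, on=["chrom", "pos"], how="inner")
        for cls in (CLASS_SYN, CLASS_TOL, CLASS_NOT_TOL):
            sub = joined.loc[joined["class"] == cls, "category"].value_counts()
            for cat, n in sub.items():
                out.loc[cls, cat] = int(n)
    return out


def het_hom_ratio(
    table: VariantTable, site_classes: pd.Series | None = None
) -> pd.DataFrame:
    """Het/hom-alt genotype-observation counts and ratio, per class.

    ``site_classes`` aligns to the table rows; without it a single
    ``all`` class is used.  The ratio is NaN with ``undefined=True`` when
    no hom-alt observation exists.
    """
    gm = table.gt_matrix()
    het = (gm == GT_HET).sum(axis=1)
    hom = (gm == GT_HOM_ALT).sum(axis=1)
    classes = (
        site_classes
        if site_classes is not None
        else pd.Series(CLASS_ALL, index=table.df.index)
    )
    rows = []
    for cls, idx in classes.groupby(classes).groups.items():
        loc = classes.index.get_indexer(idx)
        n_het, n_hom = int(het[loc].sum()), int(hom[loc].sum())
        rows.append(
            {
                "class": cls,
                "n_het": n_het,
                "n_hom_alt": n_hom,
                "ratio": n_het / n_hom if n_hom else float("nan"),
                "undefined": n_hom == 0,
            }
        )
    return pd.DataFrame(rows).set_index("class")
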