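"""Variant-table container and VCF input/output with depth-window filtering.

The canonical in-memory object is :class:`VariantTable`: one row per site,
with per-sample genotype codes (0 = hom-ref, 1 = het, 2 = hom-alt,
-1 = missing) and per-sample read depths (-1 = missing).  All downstream
stages (ROH calling, variant partitioning, distance matrices) consume this
table.

Site-level filters implemented here follow the processing used for
low-coverage resequencing of small cohorts: a per-sample read-depth window
of 0.5–2.0 times that sample's mean depth (discarding unreliable
low-coverage calls and likely copy-number/collapsed-repeat artefacts at
high coverage), and restriction to biallelic sites that are variant within
the cohort.  Depth filtering *masks* the genotype of the offending sample
rather than dropping the whole record, because each sample has its own
depth window.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GT_MISSING = -1
GT_HOM_REF = 0
GT_HET = 1
GT_HOM_ALT = 2

# cyvcf2 gt_types codes: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
_CYVCF2_GT_MAP = np.array([GT_HOM_REF, GT_HET, GT_MISSING, GT_HOM_ALT], dtype=np.int8)


class VcfFormatError(ValueError):
    """Raised for records that violate the expected VCF layout."""


@dataclass
class VariantTable:
    """Multi-sample site table.

    ``df`` has columns ``chrom, pos, ref, alt, multiallelic`` plus, for each
    sample ``s``, ``gt_<s>`` (int8 genotype code) and ``dp_<s>`` (int32 read
    depth, -1 when missing).  ``pos`` is 1-based, as in VCF.
    """

    df: pd.DataFrame
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.df) and (self.df["pos"] < 1).any():
            raise ValueError("positions must be 1-based (pos >= 1)")

    @property
    def n_sites(self) -> int:
        return len(self.df)

    def gt(self, sample: str) -> np.ndarray:
        return self.df[f"gt_{sample}"].to_numpy()

    def dp(self, sample: str) -> np.ndarray:
        return self.df[f"dp_{sample}"].to_numpy()

    def gt_matrix(self) -> np.ndarray:
        """Genotype codes as an (n_sites, n_samples) array."""
        if not self.samples:
            return np.zeros((self.n_sites, 0), dtype=np.int8)
        return self.df[[f"gt_{s}" for s in self.samples]].to_numpy(dtype=np.int8)

    def copy(self) -> "VariantTable":
        return VariantTable(self.df.copy(), list(self.samples))

    @classmethod
    def from_records(
        cls,
        chrom: Iterable[str],
        pos: Iterable[int],
        ref: Iterable[str],
        alt: Iterable[str],
        genotypes: Mapping[str, Iterable[int]],
        depths: Mapping[str, Iterable[int]] | None = None,
        multiallelic: Iterable[bool] | None = None,
    ) -> "VariantTable":
        samples = list(genotypes)
        df = pd.DataFrame({"chrom": list(chrom), "pos": list(pos), "ref": list(ref), "alt": list(alt)})
        df["multiallelic"] = list(multiallelic) if multiallelic is not None else False
        for s in samples:
            df[f"gt_{s}"] = np.asarray(list(genotypes[s]), dtype=np.int8)
            if depths is not None and s in depths:
                df[f"dp_{s}"] = np.asarray(list(depths[s]), dtype=np.int32)
            else:
                df[f"dp_{s}"] = np.int32(-1)
        return cls(df, samples)


def read_vcf(path: str | Path) -> VariantTable:
    """Read a VCF (v4.x, plain or bgzipped) into a :class:`VariantTable`.

    Streaming and order-preserving.  Multi-allelic records are kept but
    flagged (``multiallelic``) for removal by :func:`select_biallelic`.
    Records without a GT FORMAT field, and records htslib cannot parse,
    raise :class:`VcfFormatError` naming the offending record.
    """
    import cyvcf2

    vcf = cyvcf2.VCF(str(path))
    samples = list(vcf.samples)
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    multi: list[bool] = []
    gts: list[np.ndarray] = []
    dps: list[np.ndarray] = []
    record_no = 0
    try:
        for var in vcf:
            record_no += 1
            if "GT" not in var.FORMAT:
                raise VcfFormatError(f"record {record_no} ({var.CHROM}:{var.POS}): no GT field")
            chroms.append(var.CHROM)
            poss.append(var.POS)
            refs.append(var.REF)
            alts.append(",".join(var.ALT) if var.ALT else ".")
            multi.append(len(var.ALT) > 1)
            gts.append(_CYVCF2_GT_MAP[np.asarray(var.gt_types, dtype=np.int64)])
            fmt_dp = var.format("DP") if "DP" in var.FORMAT else None
            if fmt_dp is None:
                dps.append(np.full(len(samples), -1, dtype=np.int32))
            else:
                d = np.asarray(fmt_dp, dtype=np.int64).reshape(len(samples))
                d[d < 0] = -1
                dps.append(d.astype(np.int32))
    except VcfFormatError:
        raise
    except Exception as exc:  # htslib parse failure
        raise VcfFormatError(f"malformed VCF record {record_no + 1} in {path}: {exc}") from exc

    df = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts, "multiallelic": multi})
    if len(df) == 0:
        df = pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "multiallelic"])
    gt_arr = (
        np.stack(gts) if gts else np.zeros((0, len(samples)), dtype=np.int8)
    )
    dp_arr = (
        np.stack(dps) if dps else np.zeros((0, len(samples)), dtype=np.int32)
    )
    for i, s in enumerate(samples):
        df[f"gt_{s}"] = gt_arr[:, i]
        df[f"dp_{s}"] = dp_arr[:, i]
    return VariantTable(df, samples)


_GT_STR = {GT_HOM_REF: "0/0", GT_HET: "0/1", GT_HOM_ALT: "1/1", GT_MISSING: "./."}


def write_vcf(
    table: VariantTable,
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write a VariantTable as VCF v4.2 with GT and DP FORMAT fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rohpipe\n")
        if contig_lengths:
            for chrom, length in contig_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(table.samples) + "\n")
        gt_cols = [f"gt_{s}" for s in table.samples]
        dp_cols = [f"dp_{s}" for s in table.samples]
        for row in table.df.itertuples(index=False):
            rowd = row._asdict()
            fields = [
                str(rowd["chrom"]),
                str(rowd["pos"]),
                ".",
                rowd["ref"],
                rowd["alt"],
                ".",
                "PASS",
                ".",
                "GT:DP",
            ]
            for gc, dc in zip(gt_cols, dp_cols):
                dp = rowd[dc]
                dp_s = "." if dp < 0 else str(dp)
                fields.append(f"{_GT_STR[rowd[gc]]}:{dp_s}")
            fh.write("\t".join(fields) + "\n")


@dataclass
class DepthFilterConfig:
    """Per-sample depth window: keep depths in [lower*mean, upper*mean]."""

    lower_factor: float = 0.5
    upper_factor: float = 2.0
    mean_depths: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if not (0 < self.lower_factor < self.upper_factor):
            raise ValueError("require 0 < lower_factor < upper_factor")

    def bounds(self, sample: str) -> tuple[float, float]:
        if self.mean_depths is None or sample not in self.mean_depths:
            raise ValueError(f"no mean depth available for sample {sample!r}")
        m = self.mean_depths[sample]
        return self.lower_factor * m, self.upper_factor * m


def mean_depth(table: VariantTable, sample: str) -> float:
    """Arithmetic mean of non-missing per-site depths for one sample."""
    dp = table.dp(sample)
    dp = dp[dp >= 0]
    if dp.size == 0:
        raise ValueError(f"no depth data for sample {sample!r}")
    return float(dp.mean())


def filter_depth(
    table: VariantTable,
    config: DepthFilterConfig | None = None,
    samples: Iterable[str] | None = None,
) -> VariantTable:
    """Mask genotypes whose site depth lies outside the sample's window.

    Bounds are inclusive at both ends (a mean of 10 keeps depths 5 and 20).
    Masking sets the genotype code to missing; depths are preserved, so the
    operation is idempotent.  Sites with missing depth are masked too — an
    unknown depth cannot be shown to lie inside the window.
    """
    out = table.copy()
    if config is None:
        config = DepthFilterConfig()
    if config.mean_depths is None:
        config = DepthFilterConfig(
            config.lower_factor,
            config.upper_factor,
            {s: mean_depth(table, s) for s in table.samples},
        )
    for s in samples if samples is not None else table.samples:
        lo, hi = config.bounds(s)
        dp = out.dp(s)
        bad = (dp < lo) | (dp > hi) | (dp < 0)
        col = out.df[f"gt_{s}"].to_numpy().copy()
        col[bad] = GT_MISSING
        out.df[f"gt_{s}"] = col
    return out


def select_biallelic(table: VariantTable) -> VariantTable:
    """Keep sites with exactly one alt allele and ≥1 non-reference genotype."""
    gm = table.gt_matrix()
    has_nonref = ((gm == GT_HET) | (gm == GT_HOM_ALT)).any(axis=1)
    keep = (~table.df["multiallelic"].to_numpy()) & has_nonref
    return VariantTable(table.df.loc[keep].reset_index(drop=True), list(table.samples))
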