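"""End-to-end orchestration: filter → bin → ROH → diversity → partition →
tree → pedigree, from one configuration.

Every threshold of the analysis lives in :class:`RunConfig` with the
published defaults (10-kb bins, ≥20 bins per ROH, 0.33× genomic-average
cutoff, 0.5–2.0× depth window, ≥1,000 covered sites per bin, MAC ≥ 2) and
is echoed into the run log, so a run is fully reproducible from its config
file.  Identical config + seed yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import partition as part
from . import pedigree as ped_mod
from . import phylo, roh, vcf_io


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    vcf: str
    out_dir: str
    coverage: str | None = None
    islands: str | None = None
    annotations: str | None = None
    studbook: str | None = None
    bin_size: int = roh.DEFAULT_BIN_SIZE
    min_bins: int = roh.DEFAULT_MIN_BINS
    frac: float = roh.DEFAULT_FRAC
    max_gap_bins: int = 0
    depth_lower: float = 0.5
    depth_upper: float = 2.0
    min_covered: int = roh.DEFAULT_MIN_COVERED
    mac: int = part.DEFAULT_MAC
    sift_threshold: float = part.DEFAULT_SIFT_THRESHOLD
    sex_chroms: tuple[str, ...] = roh.DEFAULT_SEX_CHROMS
    category_edges_mb: tuple[float, ...] = roh.DEFAULT_CATEGORY_EDGES_MB
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bin_size", "min_bins", "frac", "depth_lower", "depth_upper", "min_covered", "mac"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("sex_chroms", "category_edges_mb"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _chrom_lengths_from_vcf(path: str) -> dict[str, int]:
    import cyvcf2

    vcf = cyvcf2.VCF(str(path))
    lengths = dict(zip(vcf.seqnames, vcf.seqlens))
    return {c: int(n) for c, n in lengths.items() if n > 0}


def _read_coverage(path: str) -> pd.DataFrame:
    cov = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "covered_sites"}
    if not required <= set(cov.columns):
        raise ValueError(f"coverage file needs columns {sorted(required)}")
    cov["chrom"] = cov["chrom"].astype(str)
    return cov


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full analysis; returns a map of output name → path."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    log_lines = ["rohpipe run", "parameters:"]
    for key, val in asdict(config).items():
        log_lines.append(f"  {key}: {val}")

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(name, exc) from exc

        return wrap

    # --- read + filter ---
    table = stage("read_vcf")(vcf_io.read_vcf, config.vcf)
    chrom_lengths = _chrom_lengths_from_vcf(config.vcf)
    if not chrom_lengths:
        bs = config.bin_size
        chrom_lengths = {
            str(c): int(-(-int(sub["pos"].max()) // bs) * bs)
            for c, sub in table.df.groupby("chrom", sort=False)
        }
    dcfg = vcf_io.DepthFilterConfig(config.depth_lower, config.depth_upper)
    filtered = stage("filter_depth")(vcf_io.filter_depth, table, dcfg)
    filtered = stage("select_biallelic")(vcf_io.select_biallelic, filtered)
    outputs["filtered_vcf"] = out_dir / "filtered.vcf"
    vcf_io.write_vcf(filtered, outputs["filtered_vcf"], chrom_lengths)
    log_lines.append(f"sites read: {table.n_sites}; after filters: {filtered.n_sites}")

    coverage = _read_coverage(config.coverage) if config.coverage else None
    if coverage is not None and "sample" not in coverage.columns:
        coverage_by_sample = {s: coverage for s in table.samples}
    elif coverage is not None:
        coverage_by_sample = {s: g.drop(columns="sample") for s, g in coverage.groupby("sample")}
    else:
        coverage_by_sample = {s: None for s in table.samples}

    # --- per-sample ROH + diversity ---
    summaries = []
    for sample in table.samples:
        track = stage("bin_genome")(
            roh.bin_genome, filtered, sample, chrom_lengths,
            coverage_by_sample.get(sample), config.bin_size,
        )
        track = roh.scale_bins(track, config.bin_size)
        track = roh.filter_bins(track, config.sex_chroms, config.min_covered)
        rohs = stage("call_rohs")(
            roh.call_rohs, track, None, config.min_bins, config.frac,
            config.max_gap_bins, config.bin_size,
        )
        bed = out_dir / f"roh_{sample}.bed"
        roh.write_roh_bed(rohs, bed)
        outputs[f"roh_bed_{sample}"] = bed
        bins_path = out_dir / f"bins_{sample}.tsv"
        track.to_csv(bins_path, sep="\t", index=False, float_format="%.6g")
        outputs[f"bins_{sample}"] = bins_path
        summary = stage("summarize")(roh.summarize_sample, sample, track, rohs, config.category_edges_mb)
        row = {
            "sample": sample,
            "n_rohs": summary.n_rohs,
            "mean_roh_length_kb": summary.mean_roh_length_kb,
            "pi": summary.pi,
        }
        row.update({f"frac_roh_{k}": v for k, v in summary.genome_fraction_in_roh.items()})
        summaries.append(row)
    summary_df = pd.DataFrame(summaries)
    outputs["sample_summary"] = out_dir / "sample_summary.tsv"
    summary_df.to_csv(outputs["sample_summary"], sep="\t", index=False, float_format="%.6g")

    island_map = None
    if config.islands:
        imap = pd.read_csv(config.islands, sep="\t")
        island_map = dict(zip(imap["sample"].astype(str), imap["island"].astype(str)))
        group_summary = stage("summarize_cohort")(roh.summarize_cohort, summary_df, island_map)
        outputs["group_summary"] = out_dir / "group_summary.tsv"
        group_summary.to_csv(outputs["group_summary"], sep="\t", float_format="%.6g")

    # --- partition ---
    if island_map is not None:
        clean = stage("remove_fixed_differences")(part.remove_fixed_differences, filtered)
        clean = stage("mac_filter")(part.mac_filter, clean, config.mac)
        annotations = (
            pd.read_csv(config.annotations, sep="\t") if config.annotations else None
        )
        ptable = stage("partition")(
            part.partition_table, clean, island_map, annotations, config.sift_threshold
        )
        outputs["partition"] = out_dir / "partition.tsv"
        ptable.to_csv(outputs["partition"], sep="\t")
        if annotations is not None:
            classes = part.classify_sift(annotations, config.sift_threshold)
            ann = annotations[["chrom", "pos"]].copy()
            ann["class"] = classes
            joined = clean.df[["chrom", "pos"]].reset_index().merge(ann, on=["chrom", "pos"])
            site_classes = pd.Series(joined["class"].values, index=joined["index"].values)
            hh = part.het_hom_ratio(
                vcf_io.VariantTable(clean.df.loc[site_classes.index], clean.samples),
                site_classes,
            )
            outputs["het_hom"] = out_dir / "het_hom.tsv"
            hh.to_csv(outputs["het_hom"], sep="\t", float_format="%.6g")

    # --- tree ---
    if len(table.samples) >= 3:
        dist, counts = stage("distance_matrix")(phylo.distance_matrix, filtered)
        outputs["distances"] = out_dir / "distances.tsv"
        dist.to_csv(outputs["distances"], sep="\t", float_format="%.10g")
        tree = stage("neighbor_joining")(phylo.neighbor_joining, dist)
        tree = stage("midpoint_root")(phylo.midpoint_root, tree)
        outputs["tree"] = out_dir / "tree.nwk"
        outputs["tree"].write_text(phylo.to_newick(tree) + "\n")

    # --- pedigree ---
    if config.studbook:
        ped = stage("read_studbook")(ped_mod.read_studbook, config.studbook)
        f_series = stage("inbreeding")(ped_mod.inbreeding, ped)
        outputs["inbreeding"] = out_dir / "inbreeding.tsv"
        f_series.rename_axis("id").to_csv(outputs["inbreeding"], sep="\t")
        kin = ped_mod.kinship(ped)
        outputs["kinship"] = out_dir / "kinship.tsv"
        kin.to_csv(outputs["kinship"], sep="\t", float_format="%.10g")
        try:
            gt_years = ped_mod.generation_time(ped)
            log_lines.append(f"generation_time_years: {gt_years:.4g}")
        except ValueError:
            log_lines.append("generation_time_years: undatable")

    outputs["log"] = out_dir / "run_log.txt"
    outputs["log"].write_text("\n".join(log_lines) + "\n")
    return outputs
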