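"""End-to-end orchestration: scan -> call -> classify -> enrich -> LADs ->
lineage (-> intactness), with a flat key-value config, a run log and a
summary JSON carrying every headline count.

Outputs in ``outdir``:

* ``regions.bed`` / ``regions.tsv`` - called arrays with density, context,
  contained genes and LAD status per region,
* ``windows.bedgraph`` - the window coverage track,
* ``enrichment.json`` - one record per family pattern,
* ``lads.tsv``, ``lineage.tsv``, ``intactness.tsv``,
* ``summary.json`` - all headline counts (byte-identical across runs with
  the same config and seed),
* ``run_log.txt`` - the effective merged configuration and stage list.

Any stage failure aborts with :class:`PipelineError` naming the stage;
whatever was computed is written to ``outdir/quarantine/``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .enrichment import classify_context, cluster_enrichment
from .intactness import ElementSpec, assess_fasta, write_intactness_tsv
from .io import (
    LADCollection,
    read_chrom_sizes,
    read_genes,
    read_repeats,
    region_id,
    write_region_report,
)
from .lads import lad_overlap
from .lineage import LineageMap, lineage_stratify
from .scan import ScanParams, call_arrays, window_scan

__all__ = ["PipelineConfig", "PipelineError", "PipelineResult", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    repeats: Path
    genome: Path
    outdir: Path
    dialect: str = "ucsc_rmsk"
    genes: Path | None = None
    lads: dict[str, Path] = field(default_factory=dict)
    lineage_map: Path | None = None
    fasta: Path | None = None
    preset: str = "line_array"
    window: int | None = None
    step: int | None = None
    min_density: float | None = None
    min_length: int | None = None
    family_patterns: tuple[str, ...] = ("^Olfr", "^Vmn")
    n_random: int = 500
    min_lad_overlap: int = 10_000
    seed: int | None = None
    element_spec: ElementSpec = field(default_factory=ElementSpec)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Flat key-value config file; keyword overrides win."""
        with open(path, "rt", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a flat mapping")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        lads = raw.get("lads") or {}
        if isinstance(lads, list):  # ["label=path", ...]
            lads = dict(item.split("=", 1) for item in lads)
        kwargs = dict(
            repeats=Path(raw["repeats"]),
            genome=Path(raw["genome"]),
            outdir=Path(raw["outdir"]),
            dialect=raw.get("dialect", "ucsc_rmsk"),
            genes=Path(raw["genes"]) if raw.get("genes") else None,
            lads={k: Path(v) for k, v in lads.items()},
            lineage_map=Path(raw["lineage_map"]) if raw.get("lineage_map") else None,
            fasta=Path(raw["fasta"]) if raw.get("fasta") else None,
            preset=raw.get("preset", "line_array"),
            window=raw.get("window"),
            step=raw.get("step"),
            min_density=raw.get("min_density"),
            min_length=raw.get("min_length"),
            family_patterns=tuple(raw.get("family_patterns", ("^Olfr", "^Vmn"))),
            n_random=int(raw.get("n_random", 500)),
            min_lad_overlap=int(raw.get("min_lad_overlap", 10_000)),
            seed=raw.get("seed"),
        )
        return cls(**kwargs)

    def scan_params(self) -> ScanParams:
        overrides = {
            k: v
            for k, v in (
                ("window", self.window),
                ("step", self.step),
                ("min_density", self.min_density),
                ("min_length", self.min_length),
            )
            if v is not None
        }
        return ScanParams.preset(self.preset, **overrides)

    def echo(self) -> dict:
        return {
            "repeats": str(self.repeats),
            "dialect": self.dialect,
            "genome": str(self.genome),
            "genes": str(self.genes) if self.genes else None,
            "lads": {k: str(v) for k, v in self.lads.items()},
            "lineage_map": str(self.lineage_map) if self.lineage_map else None,
            "fasta": str(self.fasta) if self.fasta else None,
            "preset": self.preset,
            "window": self.window,
            "step": self.step,
            "min_density": self.min_density,
            "min_length": self.min_length,
            "family_patterns": list(self.family_patterns),
            "n_random": self.n_random,
            "min_lad_overlap": self.min_lad_overlap,
            "seed": self.seed,
            "outdir": str(self.outdir),
        }


@dataclass
class PipelineResult:
    regions: list
    windows: list
    context_report: object | None
    enrichment: dict
    lad_summary: object | None
    lineage_table: object | None
    intactness: list | None
    summary: dict
    outdir: Path


def _write_summary(summary: dict, path: Path) -> None:
    with open(path, "wt", encoding="ascii") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.scan_params()

    regions: list = []
    windows: list = []
    context_report = None
    enrichment: dict = {}
    lad_records = None
    lad_summary = None
    lineage_table = None
    intact_reports = None
    summary: dict = {"parameters": config.echo()}
    stage = "load-inputs"
    try:
        for label, p in (
            ("repeats", config.repeats),
            ("genome", config.genome),
            ("genes", config.genes),
            ("fasta", config.fasta),
            ("lineage_map", config.lineage_map),
            *((f"lads[{k}]", v) for k, v in config.lads.items()),
        ):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{label} file not found: {p}")
        genome = read_chrom_sizes(config.genome)
        repeats = read_repeats(config.repeats, config.dialect, genome)
        genes = read_genes(config.genes, genome) if config.genes else None
        lads = (
            LADCollection.from_bed_files(config.lads, genome) if config.lads else None
        )
        lmap = (
            LineageMap.from_tsv(config.lineage_map)
            if config.lineage_map
            else LineageMap.default_mouse()
        )

        stage = "scan"
        windows = window_scan(repeats, genome, params)

        stage = "call"
        regions = call_arrays(windows, params, repeats=repeats)
        summary["n_windows"] = len(windows)
        summary["n_regions"] = len(regions)
        per_chrom: dict[str, int] = {}
        for r in regions:
            per_chrom[r.chrom] = per_chrom.get(r.chrom, 0) + 1
        summary["regions_per_chrom"] = per_chrom
        summary["total_array_bp"] = sum(r.length for r in regions)

        if genes is not None:
            stage = "classify"
            context_report = classify_context(regions, genes)
            for r, rec in zip(regions, context_report.records):
                r.context = rec.label
                r.contained_genes = rec.contained_genes
            summary["context"] = {
                label.name: context_report.counts[label]
                for label in context_report.counts
            }
            summary["contains_genes_count"] = context_report.contains_genes_count

            if regions and config.family_patterns:
                stage = "enrich"
                if config.seed is None:
                    raise ValueError("a seed is required for the enrichment stage")
                for i, pattern in enumerate(config.family_patterns):
                    try:
                        res = cluster_enrichment(
                            regions,
                            genes,
                            pattern,
                            genome,
                            n_random=config.n_random,
                            seed=int(config.seed) + i,
                        )
                    except ValueError as exc:
                        if "matches no gene name" in str(exc):
                            continue  # family absent from this annotation set
                        raise
                    enrichment[pattern] = res.to_dict()
                summary["enrichment"] = enrichment

        if lads is not None:
            stage = "lads"
            lad_records, lad_summary = lad_overlap(
                regions, lads, min_overlap=config.min_lad_overlap
            )
            by_id = {rec.region_id: rec for rec in lad_records}
            for r in regions:
                r.lad_status = by_id[region_id(r)].status
            summary["lads"] = {
                "n_regions": lad_summary.n_regions,
                "n_any": lad_summary.n_any,
                "n_constitutive": lad_summary.n_constitutive,
                "n_facultative": lad_summary.n_facultative,
                "n_none": lad_summary.n_none,
            }

        stage = "lineage"
        lineage_table = lineage_stratify(repeats, regions, lmap)
        summary["lineage"] = {
            "lineages": list(lineage_table.lineages),
            "genomewide": lineage_table.genomewide,
            "within_arrays": lineage_table.within_arrays,
            "outside_arrays": lineage_table.outside_arrays,
            "unassigned_genomewide": lineage_table.unassigned_genomewide,
            "unassigned_within": lineage_table.unassigned_within,
        }

        if config.fasta is not None:
            stage = "intact"
            intact_reports = assess_fasta(config.fasta, config.element_spec)
            summary["intactness"] = {
                "n_elements": len(intact_reports),
                "n_full_length": sum(r.is_full_length for r in intact_reports),
                "n_orf1_ok": sum(r.orf1_ok for r in intact_reports),
                "n_orf2_ok": sum(r.orf2_ok for r in intact_reports),
                "n_polya_ok": sum(r.polya_ok for r in intact_reports),
                "n_intact": sum(r.is_intact for r in intact_reports),
            }

        stage = "write-outputs"
        _write_outputs(
            outdir, config, params, windows, regions, enrichment,
            lad_records, lineage_table, intact_reports, summary,
        )
    except Exception as exc:
        qdir = outdir / "quarantine"
        qdir.mkdir(parents=True, exist_ok=True)
        try:
            _write_outputs(
                qdir, config, params, windows, regions, enrichment,
                lad_records, lineage_table, intact_reports, summary,
            )
        except Exception:
            pass  # quarantine is best effort
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc

    return PipelineResult(
        regions=regions,
        windows=windows,
        context_report=context_report,
        enrichment=enrichment,
        lad_summary=lad_summary,
        lineage_table=lineage_table,
        intactness=intact_reports,
        summary=summary,
        outdir=outdir,
    )


def _write_outputs(
    outdir: Path, config, params, windows, regions, enrichment,
    lad_records, lineage_table, intact_reports, summary,
) -> None:
    write_region_report(regions, outdir / "regions.bed", outdir / "regions.tsv")
    with open(outdir / "windows.bedgraph", "wt", encoding="ascii") as fh:
        for w in windows:
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.fraction:.6f}\n")
    if enrichment:
        with open(outdir / "enrichment.json", "wt", encoding="ascii") as fh:
            json.dump(enrichment, fh, indent=2, sort_keys=True)
            fh.write("\n")
    if lad_records is not None:
        with open(outdir / "lads.tsv", "wt", encoding="ascii") as fh:
            fh.write("region\tstatus\tcell_types\n")
            for rec in lad_records:
                fh.write(
                    f"{rec.region_id}\t{rec.status.name}\t"
                    f"{','.join(rec.overlapping_cell_types) or 'none'}\n"
                )
    if lineage_table is not None:
        lineage_table.to_tsv(outdir / "lineage.tsv")
    if intact_reports is not None:
        write_intactness_tsv(intact_reports, outdir / "intactness.tsv")
    _write_summary(summary, outdir / "summary.json")
    with open(outdir / "run_log.txt", "wt", encoding="ascii") as fh:
        fh.write("effective configuration:\n")
        for key, val in sorted(config.echo().items()):
            fh.write(f"  {key} = {val}\n")
        fh.write(
            f"scan parameters: window={params.window} step={params.step} "
            f"min_density={params.min_density} min_length={params.min_length}\n"
        )
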