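"""End-to-end orchestration: count -> genotype -> allelic imbalance ->
PSI -> per-sample report, from a single declarative config.

The report row mirrors a per-sample summary table: heterozygous-site
count, imbalance verdict with pooled fraction, percent skipping, and a
tumor-specific flag when a matched normal is present.  Everything is
deterministic given the config (no timestamps in outputs), so a rerun is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .ase import (
    BALANCED,
    IMBALANCED,
    AllelicImbalanceModel,
    compare_tumor_normal,
)
from .counts import count_alleles, read_counts_tsv, write_counts_tsv
from .gene_model import GeneModel, Snv, snvs_from_tsv, snvs_from_vcf
from .genotype import genotype_region
from .psi import JunctionCounts, compute_psi, extract_junction_counts

REPORT_COLUMNS = [
    "sample",
    "n_het_sites",
    "imbalance_verdict",
    "pooled_alt_fraction",
    "psi_percent",
    "normal_verdict",
    "tumor_specific_ase",
    "error",
]


@dataclass
class Thresholds:
    """All tunable thresholds of the pipeline, surfaced in one place."""

    min_base_quality: int = 20
    min_mapping_quality: int = 20
    het_low: float = 0.2
    het_high: float = 0.8
    min_dna_depth: int = 14
    genotype_alpha: float = 0.001
    hom_cut: float = 0.02
    ase_alpha: float = 0.05
    effect_floor: float = 0.15
    min_rna_depth: int = 10
    min_overhang: int = 6
    min_junction_total: int = 10

    @classmethod
    def from_dict(cls, d: dict[str, Any] | None) -> "Thresholds":
        return cls(**(d or {}))


@dataclass
class SampleReport:
    """One row of the final classification table."""

    sample: str
    n_het_sites: int = 0
    imbalance_verdict: str = ""
    pooled_alt_fraction: float | None = None
    psi_percent: float | None = None
    normal_verdict: str | None = None
    tumor_specific_ase: bool | None = None
    error: str | None = None
    provenance: dict[str, Any] = field(default_factory=dict)


def _file_hash(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def _load_model(cfg: dict[str, Any]) -> GeneModel:
    mcfg = cfg["gene_model"]
    if "bed" in mcfg:
        snvs: tuple[Snv, ...] = ()
        if "snv_vcf" in mcfg:
            snvs = snvs_from_vcf(mcfg["snv_vcf"])
        elif "snv_tsv" in mcfg:
            snvs = snvs_from_tsv(mcfg["snv_tsv"])
        return GeneModel.from_bed(mcfg["bed"], int(mcfg["cassette_index"]), snvs)
    return GeneModel(
        contig=mcfg["contig"],
        exons=tuple(tuple(e) for e in mcfg["exons"]),
        cassette_index=int(mcfg["cassette_index"]),
        snvs=tuple(
            Snv(int(s["pos_1based"]) - 1, s["ref"], s["alt"])
            for s in mcfg.get("snvs", [])
        ),
    )


def _material_counts(
    entry: dict[str, Any], model: GeneModel, th: Thresholds, material: str, label: str
):
    """Load or compute allele counts for one material of one sample."""
    if "counts" in entry:
        recs = read_counts_tsv(entry["counts"])
        for r in recs:
            r.material = material
            r.sample = label
        return recs, {f"{material.lower()}_counts": _file_hash(entry["counts"])}
    if "bam" in entry:
        recs = count_alleles(
            entry["bam"],
            model.snvs,
            contig=model.contig,
            min_base_quality=th.min_base_quality,
            min_mapping_quality=th.min_mapping_quality,
            sample=label,
            material=material,
        )
        return recs, {f"{material.lower()}_bam": _file_hash(entry["bam"])}
    raise ValueError(f"sample {label}: {material} entry needs 'counts' or 'bam'")


def _junctions(entry: dict[str, Any], model: GeneModel, th: Thresholds, label: str):
    if "junctions" in entry:
        j = entry["junctions"]
        if isinstance(j, str):
            j = json.loads(Path(j).read_text())
        return JunctionCounts(
            inclusion_upstream=int(j["inclusion_upstream"]),
            inclusion_downstream=int(j["inclusion_downstream"]),
            exclusion=int(j["exclusion"]),
            sample=label,
        )
    if "bam" in entry:
        return extract_junction_counts(
            entry["bam"], model, min_overhang=th.min_overhang,
            min_mapping_quality=th.min_mapping_quality, sample=label,
        )
    raise ValueError(f"sample {label}: rna entry needs 'junctions' or 'bam'")


def _analyze_one(
    label: str,
    dna_entry: dict[str, Any],
    rna_entry: dict[str, Any],
    model: GeneModel,
    th: Thresholds,
    out_dir: Path,
    log: list[str],
):
    """count -> genotype -> imbalance fit for one sample; returns the
    fitted results plus het calls."""
    dna_counts, prov = _material_counts(dna_entry, model, th, "DNA", label)
    write_counts_tsv(dna_counts, out_dir / f"{label}.dna_counts.tsv")
    log.append(f"{label}\tcount_dna\tsites={len(dna_counts)}\t{prov}")

    calls = genotype_region(
        dna_counts,
        het_window=(th.het_low, th.het_high),
        min_depth=th.min_dna_depth,
        alpha=th.genotype_alpha,
        hom_cut=th.hom_cut,
        het_vcf=out_dir / f"{label}.het.vcf",
        sample=label,
    )
    het = [z for z in calls if z.is_het]
    log.append(f"{label}\tgenotype\thet={len(het)}/{len(calls)}")

    rna_counts, prov_r = _material_counts(rna_entry, model, th, "RNA", label)
    write_counts_tsv(rna_counts, out_dir / f"{label}.rna_counts.tsv")
    log.append(f"{label}\tcount_rna\tsites={len(rna_counts)}\t{prov_r}")

    fit = AllelicImbalanceModel(
        het,
        rna_counts,
        alpha=th.ase_alpha,
        effect_floor=th.effect_floor,
        min_depth=th.min_rna_depth,
        sample=label,
    ).fit()
    fit.to_tsv(out_dir / f"{label}.ase.tsv")
    fit.to_json(out_dir / f"{label}.ase.json")
    log.append(
        f"{label}\tase\tverdict={fit.sample_summary.verdict}"
        f"\tpooled={fit.sample_summary.pooled_alt_fraction}"
    )
    return fit, het


def run_pipeline(config: str | Path | dict[str, Any]) -> list[SampleReport]:
    """Run the full analysis for every sample in the config and write the
    classification table.

    Config keys: ``out_dir``, ``gene_model`` (inline or ``bed`` +
    ``snv_vcf``/``snv_tsv`` + ``cassette_index``), optional ``thresholds``,
    and ``samples``: a list of ``{label, dna: {...}, rna: {...},
    normal: {dna: {...}, rna: {...}}}`` where each material entry names
    either a ``counts``/``junctions`` table or a ``bam``.  A failure in one
    sample is recorded in its row and does not abort the others.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    try:
        out_dir = Path(config["out_dir"])
        out_dir.mkdir(parents=True, exist_ok=True)
        model = _load_model(config)
        th = Thresholds.from_dict(config.get("thresholds"))
        samples = config["samples"]
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"malformed config: {exc}") from exc

    reports: list[SampleReport] = []
    log: list[str] = []
    for scfg in samples:
        label = scfg.get("label", f"sample{len(reports)}")
        rep = SampleReport(sample=label)
        rep.provenance = {
            "version": __version__,
            "thresholds": dataclasses.asdict(th),
            "seed": config.get("seed"),
        }
        try:
            fit, het = _analyze_one(
                label, scfg["dna"], scfg["rna"], model, th, out_dir, log
            )
            junc = _junctions(scfg["rna"], model, th, label)
            psi = compute_psi(junc, min_total=th.min_junction_total)
            log.append(f"{label}\tpsi\tpsi={psi.psi_skip}")

            rep.n_het_sites = len(het)
            rep.imbalance_verdict = fit.sample_summary.verdict
            rep.pooled_alt_fraction = fit.sample_summary.pooled_alt_fraction
            rep.psi_percent = psi.percent

            if "normal" in scfg:
                nfit, _ = _analyze_one(
                    f"{label}.normal", scfg["normal"]["dna"], scfg["normal"]["rna"],
                    model, th, out_dir, log,
                )
                contrast = compare_tumor_normal(
                    fit.per_site, nfit.per_site,
                    fit.sample_summary, nfit.sample_summary,
                )
                rep.normal_verdict = nfit.sample_summary.verdict
                rep.tumor_specific_ase = contrast.tumor_specific_ase
                log.append(
                    f"{label}\tcontrast\ttumor_specific={contrast.tumor_specific_ase}"
                )
        except Exception as exc:  # per-sample failure is recorded, not fatal
            rep.error = f"{type(exc).__name__}: {exc}"
            log.append(f"{label}\terror\t{rep.error}")
        reports.append(rep)

    _write_report(reports, out_dir)
    (out_dir / "pipeline.log").write_text("\n".join(log) + "\n")
    return reports


def _write_report(reports: list[SampleReport], out_dir: Path) -> None:
    rows = []
    for r in reports:
        rows.append(
            {
                "sample": r.sample,
                "n_het_sites": r.n_het_sites,
                "imbalance_verdict": r.imbalance_verdict,
                "pooled_alt_fraction": r.pooled_alt_fraction,
                "psi_percent": r.psi_percent,
                "normal_verdict": r.normal_verdict,
                "tumor_specific_ase": r.tumor_specific_ase,
                "error": r.error,
            }
        )
    pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(
        out_dir / "report.tsv", sep="\t", index=False
    )
    for r in reports:
        payload = dataclasses.asdict(r)
        (out_dir / f"{r.sample}.report.json").write_text(
            json.dumps(payload, indent=2, default=str) + "\n"
        )
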