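"""End-to-end pipeline runner: simulate/ingest -> QC -> analyze -> report.

One declarative config drives every stage; all randomness derives from the
config's seeds, and a rerun with the same config produces byte-identical
outputs (the manifest records input checksums and seeds, never wall time).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np
import yaml

from . import diversity as div
from .callset import summarize_callset
from .enrichment import (DEFAULT_BIN_ERROR_RATES, bin_by_af, class_contrast,
                         correct_counts, enrichment_table)
from .errors import ConfigError
from .panel import SamplePanel
from .regions import TargetRegions
from .sharing import DownsampleSpec, downsampled_sharing
from .simulate import (CohortDataset, CoverageModel, PopulationSpec,
                       SimulationConfig, corrupt_genotypes, simulate_cohort)
from .validation import genotype_accuracy
from .vcfio import mark_known, read_known_sites, read_vcf

log = logging.getLogger("exonpop")


def simulation_config_from_dict(d: Mapping[str, Any]) -> SimulationConfig:
    """Build a SimulationConfig from plain YAML-style data."""
    kwargs: dict[str, Any] = dict(d)
    if "populations" in kwargs:
        kwargs["populations"] = tuple(
            PopulationSpec(str(p[0]), str(p[1]), int(p[2]))
            for p in kwargs["populations"])
    if "coverage" in kwargs:
        kwargs["coverage"] = CoverageModel(**kwargs["coverage"])
    for key in ("site_classes", "selected_classes"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return SimulationConfig(**kwargs)


@dataclass
class PipelineConfig:
    """Declarative pipeline configuration.

    Either ``simulate`` (a SimulationConfig mapping) or ``vcf`` + ``panel``
    must be provided; ``targets``, ``known_sites``, ``sharing``, ``afs`` and
    ``enrichment`` sections tune the analysis stages.
    """
    output_dir: str = "exonpop_out"
    seed: int = 0
    simulate: Optional[Mapping[str, Any]] = None
    vcf: Optional[str] = None
    panel: Optional[str] = None
    targets: Optional[str] = None
    known_sites: Optional[str] = None
    afs_project_to: int = 100
    sharing: Mapping[str, Any] = field(default_factory=dict)
    enrichment: Mapping[str, Any] = field(default_factory=dict)
    validation_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def validate(self) -> None:
        if self.simulate is None and (self.vcf is None or self.panel is None):
            raise ConfigError("either 'simulate' or 'vcf'+'panel' is required")
        for name in ("vcf", "panel", "targets", "known_sites"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name}: path {p!r} does not exist")
        if self.afs_project_to < 2:
            raise ConfigError("afs_project_to must be >= 2")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in dependency order; returns the manifest.

    Stage outputs land under ``config.output_dir``; the manifest
    (manifest.json) lists every output with its checksum plus the seeds
    used. Stage failures abort with the stage name in the message.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"seed": config.seed, "stages": {}}
    outputs: dict[str, Path] = {}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            manifest["stages"][name] = "ok"
        return deco

    state: dict[str, Any] = {}

    @stage("inputs")
    def _inputs():
        if config.simulate is not None:
            sim = dict(config.simulate)
            sim.setdefault("seed", config.seed)
            simconf = simulation_config_from_dict(sim)
            cohort = simulate_cohort(simconf)
            paths = cohort.write(outdir / "cohort")
            outputs.update({f"cohort_{k}": v for k, v in paths.items()})
            state["cohort"] = cohort
            state["sites"] = cohort.sites
            state["panel"] = cohort.panel
            state["targets"] = cohort.targets
            manifest["simulation_seed"] = simconf.seed
        else:
            panel = SamplePanel.from_tsv(config.panel)
            sites = read_vcf(config.vcf, panel)
            state["panel"] = panel
            state["sites"] = sites
            state["targets"] = (TargetRegions.from_bed(config.targets)
                                if config.targets else None)
            manifest["input_checksums"] = {
                "vcf": _sha256(Path(config.vcf)),
                "panel": _sha256(Path(config.panel)),
            }
        if config.known_sites:
            mark_known(state["sites"], read_known_sites(config.known_sites))

    @stage("summary")
    def _summary():
        summary = summarize_callset([s for s in state["sites"] if s.is_snp])
        path = outdir / "callset_summary.tsv"
        summary.to_series().to_csv(path, sep="\t", header=False)
        outputs["callset_summary"] = path

    @stage("afs")
    def _afs():
        sites = [s for s in state["sites"] if s.is_snp]
        polarized = any(s.ancestral is not None for s in sites)
        afs = div.build_afs(sites, polarize=polarized)
        m = min(config.afs_project_to, afs.n)
        projected = div.project_afs(afs, m)
        path = outdir / "afs.tsv"
        with open(path, "w") as fh:
            fh.write("bin\tcount\tprojected_bin\tprojected_count\n")
            for i in range(max(afs.n, m) + 1):
                a = f"{afs.counts[i]:.6g}" if i <= afs.n else ""
                b = f"{projected.counts[i]:.6g}" if i <= m else ""
                fh.write(f"{i if i <= afs.n else ''}\t{a}\t"
                         f"{i if i <= m else ''}\t{b}\n")
        outputs["afs"] = path
        state["afs"] = afs
        fracs = div.fraction_in_bins(sites)
        path = outdir / "af_fractions.tsv"
        with open(path, "w") as fh:
            fh.write("bin\tfraction\tknown_fraction\n")
            for label, row in fracs.items():
                fh.write(f"{label}\t{row['fraction']:.6g}\t"
                         f"{row['known_fraction']:.6g}\n")
        outputs["af_fractions"] = path

    @stage("diversity")
    def _diversity():
        sites = [s for s in state["sites"] if s.is_snp]
        targets = state["targets"]
        denom = targets.total_length if targets is not None else None
        classes = sorted({s.site_class for s in sites if s.site_class})
        path = outdir / "diversity.tsv"
        with open(path, "w") as fh:
            fh.write("site_class\tn_sites\twatterson_theta\t"
                     "het_per_base_x1e4\n")
            for cls in ["all"] + classes:
                sub = sites if cls == "all" else [
                    s for s in sites if s.site_class == cls]
                seg = [s for s in sub if 0 < s.alt_count() < s.chrom_count()]
                n = max((s.chrom_count() for s in sub), default=2)
                theta = div.watterson_theta(len(seg), n)
                het = (div.per_base_het(sub, denom) * 1e4
                       if denom else float("nan"))
                fh.write(f"{cls}\t{len(sub)}\t{theta:.6g}\t{het:.6g}\n")
        outputs["diversity"] = path

    @stage("sharing")
    def _sharing():
        sites = [s for s in state["sites"] if s.is_snp]
        panel: SamplePanel = state["panel"]
        opts = dict(config.sharing)
        m = opts.get("m") or {p: 2 * panel.n_samples(p)
                              for p in panel.populations}
        spec = DownsampleSpec(m={k: int(v) for k, v in m.items()},
                              method=opts.get("method", "auto"),
                              replicates=int(opts.get("replicates", 2000)),
                              seed=config.seed)
        est = downsampled_sharing(
            sites, spec, panel,
            bootstrap_reps=int(opts.get("bootstrap", 200)), seed=config.seed)
        path = outdir / "sharing.tsv"
        est.to_frame().to_csv(path, sep="\t", index=False,
                              float_format="%.6g")
        outputs["sharing"] = path

    @stage("enrichment")
    def _enrichment():
        sites = [s for s in state["sites"] if s.is_snp and s.site_class]
        if not sites:
            return
        rates = tuple(config.enrichment.get("error_rates",
                                            DEFAULT_BIN_ERROR_RATES))
        binned = bin_by_af(sites, error_rates=rates)
        corrected = correct_counts(binned)
        path = outdir / "enrichment.tsv"
        enrichment_table(binned, corrected).to_csv(
            path, sep="\t", index=False, float_format="%.6g")
        outputs["enrichment"] = path
        contrasts = []
        classes = list(binned.classes)
        base = config.enrichment.get("baseline_class", "silent")
        if base in classes:
            for other in classes:
                if other == base:
                    continue
                for corr in (False, True):
                    r = class_contrast(corrected if corr else binned,
                                       base, other, corrected=False)
                    contrasts.append({
                        "baseline": base, "class": other,
                        "corrected": corr, "chi2": r.statistic,
                        "pvalue": r.pvalue,
                        "low_fraction_baseline": r.low_fraction_a,
                        "low_fraction_class": r.low_fraction_b,
                    })
        if contrasts:
            import pandas as pd
            path = outdir / "contrasts.tsv"
            pd.DataFrame(contrasts).to_csv(path, sep="\t", index=False,
                                           float_format="%.6g")
            outputs["contrasts"] = path

    @stage("validation")
    def _validation():
        cohort: Optional[CohortDataset] = state.get("cohort")
        if cohort is None:
            return
        _, table = corrupt_genotypes(cohort, seed=config.validation_seed)
        acc = genotype_accuracy(table)
        path = outdir / "validation.tsv"
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            for cls, v in acc.per_class.items():
                fh.write(f"accuracy_{cls}\t{v:.4g}\n")
            fh.write(f"accuracy_overall\t{acc.overall:.4g}\n")
            fh.write(f"variant_fdr\t{acc.variant_fdr:.4g}\n")
            fh.write(f"missed_variant_rate\t{acc.missed_variant_rate:.4g}\n")
            fh.write(f"n_compared\t{acc.n_compared}\n")
        outputs["validation"] = path
        manifest["validation_seed"] = config.validation_seed

    manifest["outputs"] = {k: {"path": str(v), "sha256": _sha256(v)}
                           for k, v in sorted(outputs.items())}
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
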