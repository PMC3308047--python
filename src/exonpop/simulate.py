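"""Synthetic multi-population exome cohorts with known ground truth.

The generator emulates the structure of a multi-center exon-capture study:
seven population panels in three continental groups, a neutral 1/x-shaped
ancestral allele-frequency density with an excess-rare skew applied to
selected (amino-acid-changing) site classes, Balding–Nichols divergence
between continents and populations, and per-target/per-sample coverage
heterogeneity. It exists so that every downstream statistic in this package
can be tested against configured truth without any external data.

Model
-----
Ancestral (derived-allele) frequencies are drawn from the standing neutral
density proportional to 1/x, truncated to (1/(2*N_e), 1) where ``N_e`` is an
effective population size: one new mutation in a population of N_e diploids.
Under this density the expected unfolded sample spectrum is theta/i per
derived-allele-count bin, and Watterson's theta computed downstream recovers
the configured theta. Population structure follows a two-level
Balding–Nichols model (continent around the ancestral frequency, population
around the continent frequency), each level using F = fst/2, so the total
frequency variance is fst*(1 - fst/4) ~ fst. Genotypes are binomial draws of
two chromosomes per sample.
"""

from __future__ import annotations


from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._utils import (STREAM_COHORT, STREAM_CORRUPT, STREAM_DEPTHS, substream)
from .errors import ConfigError
from .panel import SamplePanel
from .regions import TargetRegions
from .sites import HET, HOM_ALT, VariantSite
from .validation import AssayTable

#: Panel layout of the study conditions: (population, continent, samples).
EXON_PILOT_PANEL: tuple[tuple[str, str, int], ...] = (
    ("YRI", "Africa", 112),
    ("LWK", "Africa", 108),
    ("CHB", "Asia", 109),
    ("CHD", "Asia", 107),
    ("JPT", "Asia", 105),
    ("CEU", "Europe", 90),
    ("TSI", "Europe", 66),
)

GENOTYPE_CLASSES = ("hom_ref", "het", "hom_alt")

#: Default per-genotype-class miscall rates, set to the complement of the
#: per-class genotype accuracies a deep-coverage exome validation series
#: reports (hom-ref 99.9%, het 97.0%, hom-alt 92.3%). Miscalled hets drop to
#: hom-ref (allele dropout); miscalled homozygotes move one dosage step.
DEFAULT_ERROR_RATES: dict[str, dict[str, float]] = {
    "hom_ref": {"het": 0.001},
    "het": {"hom_ref": 0.030},
    "hom_alt": {"het": 0.077},
}


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    continent: str
    n_samples: int


@dataclass(frozen=True)
class CoverageModel:
    """Two-factor read-depth model: depth = mean * target_effect * sample_effect.

    ``target_sigma`` is the standard deviation of the log-normal per-target
    effect (mean 1), shared across samples so target-to-target variance is
    reproducible; ``sample_cv`` is the coefficient of variation of the
    gamma-distributed per-sample scale (mean 1).
    """
    mean_depth: float = 48.0
    target_sigma: float = 0.7
    sample_cv: float = 0.3


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs for the synthetic cohort generator.

    Exactly one of ``n_sites`` (fixed count of sample-polymorphic sites per
    class) or ``theta`` (per-class scaled diversity; the number of simulated
    sites is then Poisson(theta * ln(2*N_e)) and sites monomorphic in the
    realized sample are retained) drives each functional class. Scalars apply
    to every class in ``site_classes``.
    """
    populations: tuple[PopulationSpec, ...] = tuple(
        PopulationSpec(*p) for p in EXON_PILOT_PANEL)
    site_classes: tuple[str, ...] = ("silent", "missense", "nonsense")
    n_sites: Optional[int | Mapping[str, int]] = None
    theta: Optional[float | Mapping[str, float]] = None
    selected_classes: tuple[str, ...] = ("missense", "nonsense")
    selection_skew: float = 0.5
    fst: float = 0.08
    effective_size: int = 10_000
    coverage: CoverageModel = CoverageModel()
    genotype_error_rates: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ERROR_RATES.items()})
    transition_prob: float = 0.78
    n_targets: Optional[int] = None
    target_length: int = 180
    seed: int = 0

    #: Sample-polymorphic site counts roughly matching the composition of a
    #: ~12.7k-SNP exome call set (used when neither n_sites nor theta is set).
    _DEFAULT_N_SITES = {"silent": 5500, "missense": 6900, "nonsense": 350}

    def class_plan(self) -> dict[str, tuple[str, float]]:
        """Per-class driver: class -> ("n_sites"|"theta", value)."""
        if self.n_sites is not None and self.theta is not None:
            raise ConfigError("n_sites and theta are mutually exclusive")
        if self.theta is not None:
            if isinstance(self.theta, Mapping):
                return {c: ("theta", float(v)) for c, v in self.theta.items()}
            return {c: ("theta", float(self.theta)) for c in self.site_classes}
        n = self.n_sites if self.n_sites is not None else self._DEFAULT_N_SITES
        if isinstance(n, Mapping):
            return {c: ("n_sites", int(v)) for c, v in n.items()}
        return {c: ("n_sites", int(n)) for c in self.site_classes}

    def validate(self) -> None:
        for p in self.populations:
            if p.n_samples < 1:
                raise ConfigError(f"populations: {p.name} has n_samples < 1")
        if not 0.0 <= self.fst < 1.0:
            raise ConfigError(f"fst must be in [0, 1), got {self.fst}")
        if not 0.0 < self.selection_skew <= 1.0:
            raise ConfigError(
                f"selection_skew must be in (0, 1], got {self.selection_skew}")
        if self.coverage.mean_depth <= 0:
            raise ConfigError("coverage.mean_depth must be > 0")
        if self.coverage.target_sigma < 0:
            raise ConfigError("coverage.target_sigma must be >= 0")
        if self.coverage.sample_cv < 0:
            raise ConfigError("coverage.sample_cv must be >= 0")
        if self.effective_size < 1:
            raise ConfigError("effective_size must be >= 1")
        if not 0.0 <= self.transition_prob <= 1.0:
            raise ConfigError("transition_prob must be in [0, 1]")
        if self.target_length < 1:
            raise ConfigError("target_length must be >= 1")
        for cls, (mode, value) in self.class_plan().items():
            if value < 0 or not np.isfinite(value):
                raise ConfigError(f"{mode}[{cls}] must be non-negative")
        _validate_rates(self.genotype_error_rates)

    def make_panel(self) -> SamplePanel:
        s2p: dict[str, str] = {}
        p2c: dict[str, str] = {}
        for p in self.populations:
            p2c[p.name] = p.continent
            for i in range(p.n_samples):
                s2p[f"{p.name}{i:04d}"] = p.name
        return SamplePanel(s2p, p2c)


def _validate_rates(rates: Mapping[str, Mapping[str, float]]) -> None:
    for true_cls, row in rates.items():
        if true_cls not in GENOTYPE_CLASSES:
            raise ConfigError(f"genotype_error_rates: unknown class {true_cls!r}")
        total = 0.0
        for called, p in row.items():
            if called not in GENOTYPE_CLASSES or called == true_cls:
                raise ConfigError(
                    f"genotype_error_rates[{true_cls}]: bad target {called!r}")
            if not 0.0 <= p <= 1.0:
                raise ConfigError(
                    f"genotype_error_rates[{true_cls}][{called}] not in [0, 1]")
            total += p
        if total > 1.0:
            raise ConfigError(
                f"genotype_error_rates[{true_cls}] rates sum to {total} > 1")


@dataclass
class CohortDataset:
    """A simulated (or corrupted) cohort: sites, matrices, panel, and truth.

    ``genotypes`` is (n_sites, n_samples) of alternate-allele dosages;
    ``depths`` has the same shape. Each VariantSite's per-sample arrays are
    views into these matrices. ``truth`` records the ancestral and
    per-population allele frequencies each site was generated from.
    """
    sites: list[VariantSite]
    genotypes: np.ndarray
    depths: np.ndarray
    panel: SamplePanel
    truth: pd.DataFrame
    targets: TargetRegions
    config: Optional[SimulationConfig] = None

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.panel)

    def validate(self) -> None:
        if self.genotypes.shape != (self.n_sites, self.n_samples):
            raise ValueError("genotype matrix shape disagrees with sites/panel")
        if self.depths.shape != self.genotypes.shape:
            raise ValueError("depth matrix shape disagrees with genotypes")
        if (self.depths < 0).any():
            raise ValueError("negative read depths")

    def equals(self, other: "CohortDataset") -> bool:
        return (self.panel == other.panel
                and np.array_equal(self.genotypes, other.genotypes)
                and np.array_equal(self.depths, other.depths)
                and len(self.sites) == len(other.sites)
                and all(a.key == b.key and a.site_class == b.site_class
                        and a.known == b.known
                        for a, b in zip(self.sites, other.sites))
                and self.truth.equals(other.truth))

    def write(self, outdir) -> dict[str, Path]:
        """Write VCF + BED + panel + truth under ``outdir``; return the paths."""
        from .vcfio import write_vcf
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "cohort.vcf",
            "targets": outdir / "targets.bed",
            "panel": outdir / "panel.tsv",
            "truth": outdir / "truth.tsv",
        }
        contigs = {c: max(end for chrom, _, end in self.targets if chrom == c)
                   + 1000 for c in self.targets.chromosomes}
        write_vcf(self.sites, self.panel.samples, paths["vcf"],
                  contigs=contigs, depths=self.depths)
        self.targets.to_bed(paths["targets"])
        self.panel.to_tsv(paths["panel"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False,
                          float_format="%.8g")
        return paths


# ---------------------------------------------------------------------------
# frequency model
# ---------------------------------------------------------------------------

def _draw_loglinear(rng: np.random.Generator, n: int, floor: float) -> np.ndarray:
    """Draw from the density proportional to 1/x on (floor, 1)."""
    u = rng.random(n)
    return floor ** (1.0 - u)


def _balding_nichols(rng: np.random.Generator, p: np.ndarray,
                     f: float) -> np.ndarray:
    """Beta draw with mean p and variance p(1-p)f; degenerate at f=0 or p in {0,1}."""
    if f <= 0.0:
        return p.copy()
    out = p.copy()
    interior = (p > 0.0) & (p < 1.0)
    if interior.any():
        scale = (1.0 - f) / f
        a = p[interior] * scale
        b = (1.0 - p[interior]) * scale
        out[interior] = rng.beta(a, b)
    return out


def _population_frequencies(rng: np.random.Generator, anc: np.ndarray,
                            config: SimulationConfig) -> np.ndarray:
    """(n_sites, n_pops) per-population frequencies, two-level divergence."""
    f_level = config.fst / 2.0
    pops = config.populations
    continents = list(dict.fromkeys(p.continent for p in pops))
    cont_freq = {c: _balding_nichols(rng, anc, f_level) for c in continents}
    cols = [ _balding_nichols(rng, cont_freq[p.continent], f_level)
             for p in pops ]
    return np.column_stack(cols)


def _genotype_block(rng: np.random.Generator, pop_freq: np.ndarray,
                    pop_sizes: Sequence[int]) -> np.ndarray:
    """(n_sites, n_samples) dosage draws, samples grouped by population."""
    blocks = []
    for j, n in enumerate(pop_sizes):
        pf = np.repeat(pop_freq[:, j:j + 1], n, axis=1)
        blocks.append(rng.binomial(2, pf).astype(np.int8))
    return np.concatenate(blocks, axis=1)


def _coverage_effects(rng: np.random.Generator, cov: CoverageModel,
                      n_targets: int, n_samples: int
                      ) -> tuple[np.ndarray, np.ndarray]:
    if cov.target_sigma > 0:
        t = rng.lognormal(-0.5 * cov.target_sigma ** 2, cov.target_sigma,
                          n_targets)
    else:
        t = np.ones(n_targets)
    if cov.sample_cv > 0:
        shape = 1.0 / cov.sample_cv ** 2
        s = rng.gamma(shape, 1.0 / shape, n_samples)
    else:
        s = np.ones(n_samples)
    return t, s


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig) -> CohortDataset:
    """Generate a cohort under the configured study conditions.

    Deterministic under ``config.seed``: identical configs yield
    byte-identical datasets.
    """
    config.validate()
    rng = substream(config.seed, STREAM_COHORT)
    panel = config.make_panel()
    pop_sizes = [p.n_samples for p in config.populations]
    n_samples = sum(pop_sizes)
    n_chrom = 2 * n_samples
    floor = 1.0 / (2.0 * config.effective_size)

    anc_all: list[np.ndarray] = []
    pop_all: list[np.ndarray] = []
    geno_all: list[np.ndarray] = []
    class_all: list[np.ndarray] = []

    for cls, (mode, value) in config.class_plan().items():
        skew = config.selection_skew if cls in config.selected_classes else 1.0
        if mode == "theta":
            n_draw = int(rng.poisson(value * np.log(1.0 / floor)))
            anc = _draw_loglinear(rng, n_draw, floor)
            anc = np.clip(anc * skew, floor, 1.0)
            pop_freq = _population_frequencies(rng, anc, config)
            geno = _genotype_block(rng, pop_freq, pop_sizes)
        else:
            target = int(value)
            kept_a, kept_p, kept_g = [], [], []
            have = 0
            while have < target:
                batch = max(2 * (target - have), 512)
                a = _draw_loglinear(rng, batch, floor)
                a = np.clip(a * skew, floor, 1.0)
                pf = _population_frequencies(rng, a, config)
                g = _genotype_block(rng, pf, pop_sizes)
                ac = g.sum(axis=1)
                keep = (ac > 0) & (ac < n_chrom)
                kept_a.append(a[keep])
                kept_p.append(pf[keep])
                kept_g.append(g[keep])
                have += int(keep.sum())
            anc = np.concatenate(kept_a)[:target]
            pop_freq = np.concatenate(kept_p)[:target]
            geno = np.concatenate(kept_g)[:target]
        anc_all.append(anc)
        pop_all.append(pop_freq)
        geno_all.append(geno)
        class_all.append(np.full(len(anc), cls, dtype=object))

    anc = np.concatenate(anc_all)
    pop_freq = np.concatenate(pop_all)
    G = np.concatenate(geno_all) if geno_all else np.empty((0, n_samples), np.int8)
    classes = np.concatenate(class_all)
    n_total = len(anc)

    # --- genomic layout: capture targets on one synthetic chromosome -----
    if config.n_targets is not None:
        n_targets = config.n_targets
    else:
        # ~1% variant density per targeted base, the order seen in exome data
        n_targets = max(32, int(np.ceil(n_total / 0.009 / config.target_length)))
    total_bases = n_targets * config.target_length
    if n_total > total_bases:
        raise ConfigError(
            f"n_targets: {n_targets} targets of {config.target_length} bp "
            f"cannot hold {n_total} sites")
    gap = max(60, config.target_length // 2)
    starts = np.arange(n_targets, dtype=np.int64) * (config.target_length + gap)
    targets = TargetRegions(("1", int(s), int(s + config.target_length))
                            for s in starts)
    base_idx = rng.choice(total_bases, size=n_total, replace=False)
    t_idx = base_idx // config.target_length
    pos0 = starts[t_idx] + base_idx % config.target_length

    order = np.argsort(pos0, kind="stable")
    pos0, t_idx = pos0[order], t_idx[order]
    anc, pop_freq, classes = anc[order], pop_freq[order], classes[order]
    G = np.ascontiguousarray(G[order])

    # --- alleles: random ref base, transition-biased alt -----------------
    bases = np.array(list("ACGT"))
    transition = {"A": "G", "G": "A", "C": "T", "T": "C"}
    transversions = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
    ref = bases[rng.integers(0, 4, n_total)]
    is_ts = rng.random(n_total) < config.transition_prob
    tv_pick = rng.integers(0, 2, n_total)
    alt = np.array([transition[r] if ts else transversions[r][k]
                    for r, ts, k in zip(ref, is_ts, tv_pick)], dtype=object)

    # --- coverage, qualities, per-sample depths --------------------------
    t_eff, s_eff = _coverage_effects(rng, config.coverage, n_targets, n_samples)
    lam = config.coverage.mean_depth * t_eff[t_idx][:, None] * s_eff[None, :]
    D = np.rint(lam).astype(np.int32)

    quality = np.clip(rng.normal(60.0, 10.0, n_total), 30.0, None)
    qd = quality / 8.0
    GQ = rng.integers(20, 100, size=(n_total, n_samples), dtype=np.int32)
    alt_d = np.zeros_like(D)
    het_mask = G == HET
    alt_d[het_mask] = rng.binomial(D[het_mask], 0.5)
    alt_d[G == HOM_ALT] = D[G == HOM_ALT]
    ref_d = D - alt_d

    af = G.sum(axis=1) / n_chrom
    p_known = np.where(af > 0.1, 0.9, np.where(af > 0.01, 0.55, 0.25))
    known = rng.random(n_total) < p_known

    sites = [VariantSite(
        chrom="1", pos=int(pos0[i]) + 1, ref=str(ref[i]), alt=str(alt[i]),
        quality=float(quality[i]), qd=float(qd[i]),
        genotypes=G[i], genotype_quals=GQ[i],
        ref_depths=ref_d[i], alt_depths=alt_d[i],
        ancestral=str(ref[i]), known=bool(known[i]),
        site_class=str(classes[i]), info={"target": int(t_idx[i])},
    ) for i in range(n_total)]

    truth = pd.DataFrame({
        "chrom": "1",
        "pos": pos0 + 1,
        "site_class": classes.astype(str),
        "ancestral_freq": anc,
        **{f"freq_{p.name}": pop_freq[:, j]
           for j, p in enumerate(config.populations)},
    })
    ds = CohortDataset(sites, G, D, panel, truth, targets, config)
    ds.validate()
    return ds


def simulate_depths(config: SimulationConfig, n_targets: int) -> np.ndarray:
    """(n_targets, n_samples) read-depth matrix from the two-factor model.

    Per-target effects are shared across samples; per-sample scales are
    shared across targets. With both variances zero the matrix is constant
    at the configured mean depth.
    """
    if n_targets < 1:
        raise ConfigError("n_targets must be >= 1")
    config.validate()
    rng = substream(config.seed, STREAM_DEPTHS)
    n_samples = sum(p.n_samples for p in config.populations)
    t_eff, s_eff = _coverage_effects(rng, config.coverage, n_targets, n_samples)
    lam = config.coverage.mean_depth * t_eff[:, None] * s_eff[None, :]
    return np.rint(lam).astype(np.int32)


def corrupt_genotypes(dataset: CohortDataset,
                      rates: Optional[Mapping[str, Mapping[str, float]]] = None,
                      seed: int = 0) -> tuple[CohortDataset, AssayTable]:
    """Miscall genotypes at per-class rates; return the corrupted cohort and
    the 3x3 called-vs-true contingency table.

    ``rates[true_class][called_class]`` is the probability a genotype of
    ``true_class`` is reported as ``called_class``. Missing genotypes are
    left untouched. Deterministic under ``seed``.
    """
    if rates is None:
        rates = (dataset.config.genotype_error_rates
                 if dataset.config is not None else DEFAULT_ERROR_RATES)
    _validate_rates(rates)
    rng = substream(seed, STREAM_CORRUPT)
    G = dataset.genotypes.copy()
    table = np.zeros((3, 3), dtype=np.int64)
    for t, true_cls in enumerate(GENOTYPE_CLASSES):
        mask = dataset.genotypes == t
        n = int(mask.sum())
        if n == 0:
            continue
        row = rates.get(true_cls, {})
        targets = [GENOTYPE_CLASSES.index(c) for c in row]
        probs = np.array([row[c] for c in row])
        u = rng.random(n)
        called = np.full(n, t, dtype=np.int8)
        edges = np.concatenate(([0.0], np.cumsum(probs)))
        for j, tgt in enumerate(targets):
            called[(u >= edges[j]) & (u < edges[j + 1])] = tgt
        G[mask] = called
        for c in range(3):
            table[c, t] += int((called == c).sum())

    new_sites = [replace(s, genotypes=G[i], info=dict(s.info))
                 for i, s in enumerate(dataset.sites)]
    corrupted = CohortDataset(new_sites, G, dataset.depths, dataset.panel,
                              dataset.truth, dataset.targets, dataset.config)
    return corrupted, AssayTable(genotype_counts=table)
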