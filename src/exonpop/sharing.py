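"""Cross-population minor-allele sharing.

The sharing statistic asks: if two minor alleles are sampled at random
without replacement among all minor alleles at a site, what is the
probability they come from the same population, from different populations
on the same continent, or from different continents? With per-population
minor-allele counts c_p (C = sum c_p >= 2) the three probabilities are exact
combinatorics:

    P(same population)  = sum_p c_p (c_p - 1) / (C (C - 1))
    P(same continent)   = sum_{cont} S_cont (S_cont - 1) / (C (C - 1)) - P(same pop)
    P(diff continents)  = 1 - sum_{cont} S_cont (S_cont - 1) / (C (C - 1))

The panmictic expectation substitutes sample sizes for allele counts and is
independent of allele frequency. Unequal panel sizes are equalized by
down-sampling each population to m_p chromosomes with independent
hypergeometric reductions; per allele-frequency bin the estimate averages
the conditional sharing over sites, weighting each site by the probability
it retains at least two minor alleles after down-sampling. Singletons cannot
be shared and are dropped. Confidence intervals are percentile bootstrap
over variant sites.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import hypergeom

from ._utils import STREAM_BOOTSTRAP, STREAM_SHARING_MC, substream
from .errors import ConfigError, DomainError, UndefinedResultError
from .panel import SamplePanel
from .sites import VariantSite

CATEGORIES = ("same_population", "same_continent", "different_continents")
DEFAULT_BIN_EDGES = (0.01, 0.1)
DEFAULT_BIN_LABELS = ("<0.01", "0.01-0.1", "0.1-0.5")


def _sharing_from_counts(counts: Mapping[str, float],
                         panel: SamplePanel) -> tuple[float, float, float]:
    C = float(sum(counts.values()))
    if C < 2:
        raise DomainError("sharing undefined for fewer than two minor alleles "
                          "(singletons cannot be shared)")
    denom = C * (C - 1.0)
    same_pop = sum(c * (c - 1.0) for c in counts.values()) / denom
    cont_sums: dict[str, float] = {}
    for pop, c in counts.items():
        cont = panel.continent_of(pop)
        cont_sums[cont] = cont_sums.get(cont, 0.0) + c
    within_cont = sum(s * (s - 1.0) for s in cont_sums.values()) / denom
    return (same_pop, within_cont - same_pop, 1.0 - within_cont)


def site_sharing(minor_counts: Mapping[str, int],
                 panel: SamplePanel) -> tuple[float, float, float]:
    """Exact sharing probabilities from per-population minor-allele counts."""
    return _sharing_from_counts(minor_counts, panel)


def panmictic_expectation(sizes: Mapping[str, int],
                          panel: SamplePanel) -> tuple[float, float, float]:
    """Expected sharing in a panmictic population with the given per-population
    chromosome counts; a property of sample sizes only."""
    return _sharing_from_counts(sizes, panel)


@dataclass(frozen=True)
class DownsampleSpec:
    """Per-population target chromosome counts and enumeration strategy.

    ``method`` is "auto" (exact enumeration when the total minor count is at
    most ``exact_max_total``, Monte Carlo otherwise), "exact", or
    "monte-carlo". Monte-Carlo sampling is deterministic under ``seed``.
    """
    m: Mapping[str, int]
    method: str = "auto"
    replicates: int = 10_000
    seed: int = 0
    exact_max_total: int = 12

    def validate(self, panel: SamplePanel) -> None:
        if self.method not in ("auto", "exact", "monte-carlo"):
            raise ConfigError(f"unknown down-sampling method {self.method!r}")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        for pop, mp in self.m.items():
            if mp < 0:
                raise ConfigError(f"m[{pop}] must be >= 0")
            if mp > 2 * panel.n_samples(pop):
                raise ConfigError(
                    f"m[{pop}] = {mp} exceeds the {2 * panel.n_samples(pop)} "
                    f"available chromosomes")


@dataclass
class SharingEstimate:
    """Per-AF-bin sharing probabilities with bootstrap CIs.

    ``estimates[b, k]`` is category k of CATEGORIES in bin b; rows sum to 1.
    ``mc_se`` carries Monte-Carlo standard errors when down-sampling was
    sampled rather than enumerated.
    """
    bins: tuple[str, ...]
    estimates: np.ndarray
    n_sites: np.ndarray
    ci_low: Optional[np.ndarray] = None
    ci_high: Optional[np.ndarray] = None
    mc_se: Optional[np.ndarray] = None

    def to_frame(self):
        import pandas as pd
        rows = []
        for b, label in enumerate(self.bins):
            for k, cat in enumerate(CATEGORIES):
                rows.append({
                    "bin": label, "category": cat,
                    "estimate": self.estimates[b, k],
                    "ci_low": self.ci_low[b, k] if self.ci_low is not None else np.nan,
                    "ci_high": self.ci_high[b, k] if self.ci_high is not None else np.nan,
                    "n_sites": int(self.n_sites[b]),
                })
        return pd.DataFrame(rows)


def _site_terms_exact(counts: list[int], chroms: list[int], ms: list[int],
                      cont_idx: np.ndarray, n_cont: int
                      ) -> tuple[float, np.ndarray]:
    """(weight P(D>=2), E[1{D>=2} * sharing vector]) by joint enumeration."""
    supports = []
    pmfs = []
    for c, n, m in zip(counts, chroms, ms):
        lo = max(0, m - (n - c))
        hi = min(c, m)
        d = np.arange(lo, hi + 1)
        supports.append(d)
        pmfs.append(hypergeom.pmf(d, n, c, m))
    w = 0.0
    num = np.zeros(3)
    for combo in itertools.product(*(range(len(s)) for s in supports)):
        prob = 1.0
        for k, idx in enumerate(combo):
            prob *= pmfs[k][idx]
        if prob == 0.0:
            continue
        d = np.array([supports[k][idx] for k, idx in enumerate(combo)],
                     dtype=float)
        D = d.sum()
        if D < 2:
            continue
        w += prob
        denom = D * (D - 1.0)
        same_pop = float((d * (d - 1.0)).sum()) / denom
        s_cont = np.bincount(cont_idx, weights=d, minlength=n_cont)
        within = float((s_cont * (s_cont - 1.0)).sum()) / denom
        num += prob * np.array([same_pop, within - same_pop, 1.0 - within])
    return w, num


def _site_terms_mc(rng: np.random.Generator, counts: np.ndarray,
                   chroms: np.ndarray, ms: np.ndarray, cont_idx: np.ndarray,
                   n_cont: int, reps: int
                   ) -> tuple[float, np.ndarray, np.ndarray, float]:
    """Monte-Carlo (weight, numerator, numerator variance-of-mean, weight var)."""
    d = np.empty((reps, len(counts)))
    for k, (c, n, m) in enumerate(zip(counts, chroms, ms)):
        if c == 0 or m == 0:
            d[:, k] = 0.0
        else:
            d[:, k] = rng.hypergeometric(c, n - c, m, size=reps)
    D = d.sum(axis=1)
    ok = D >= 2
    vec = np.zeros((reps, 3))
    if ok.any():
        denom = D[ok] * (D[ok] - 1.0)
        same_pop = (d[ok] * (d[ok] - 1.0)).sum(axis=1) / denom
        s_cont = np.zeros((int(ok.sum()), n_cont))
        for k in range(len(counts)):
            s_cont[:, cont_idx[k]] += d[ok, k]
        within = (s_cont * (s_cont - 1.0)).sum(axis=1) / denom
        vec[ok, 0] = same_pop
        vec[ok, 1] = within - same_pop
        vec[ok, 2] = 1.0 - within
    w = float(ok.mean())
    num = vec.mean(axis=0)
    num_var = vec.var(axis=0, ddof=1) / reps if reps > 1 else np.zeros(3)
    w_var = float(np.var(ok.astype(float), ddof=1) / reps) if reps > 1 else 0.0
    return w, num, num_var, w_var


def _af_bin(f: float, edges: Sequence[float]) -> int:
    # [0, e1) | [e1, e2] | (e2, 0.5]; boundary values go to the middle bin
    if f < edges[0]:
        return 0
    if f <= edges[1]:
        return 1
    return 2


def downsampled_sharing(sites: Sequence[VariantSite], spec: DownsampleSpec,
                        panel: SamplePanel,
                        edges: Sequence[float] = DEFAULT_BIN_EDGES,
                        bin_labels: Sequence[str] = DEFAULT_BIN_LABELS,
                        bootstrap_reps: int = 0, ci_level: float = 0.95,
                        seed: int = 0) -> SharingEstimate:
    """Down-sampled, AF-binned sharing estimate over variant sites.

    Per site, minor counts are reduced to the spec's chromosome counts by
    independent hypergeometric draws (enumerated exactly for small total
    minor counts); the per-bin estimate is sum_s E[1{D_s>=2} sharing_s] /
    sum_s P(D_s>=2). Minor alleles are labelled by global frequency across
    all included samples, fixed before down-sampling. Sites that are
    singletons in the full data are dropped. ``bootstrap_reps`` > 0 adds
    percentile bootstrap CIs over sites.
    """
    spec.validate(panel)
    pops = panel.populations
    cont_of = {p: panel.continent_of(p) for p in pops}
    continents = list(dict.fromkeys(cont_of.values()))
    cont_idx = np.array([continents.index(cont_of[p]) for p in pops])
    ms_by_pop = {p: int(spec.m.get(p, 2 * panel.n_samples(p))) for p in pops}
    rng = substream(spec.seed, STREAM_SHARING_MC)

    n_bins = len(bin_labels)
    per_bin_sites: list[list[tuple[float, np.ndarray, np.ndarray, float]]] = [
        [] for _ in range(n_bins)]
    for site in sites:
        counts_map, chroms_map = site.minor_counts_by_population(panel)
        counts = np.array([counts_map[p] for p in pops])
        chroms = np.array([chroms_map[p] for p in pops])
        C = int(counts.sum())
        if C < 2:
            continue  # singletons cannot be shared
        ms = np.array([ms_by_pop[p] for p in pops])
        if (ms > chroms).any():
            bad = pops[int(np.argmax(ms > chroms))]
            raise ConfigError(
                f"m[{bad}] exceeds the chromosomes called at "
                f"{site.chrom}:{site.pos}")
        b = _af_bin(site.minor_freq(), edges)
        if np.array_equal(ms, chroms):
            # degenerate hypergeometric: the full sample is kept
            w, num = 1.0, np.asarray(
                _sharing_from_counts(dict(zip(pops, counts.tolist())), panel))
            per_bin_sites[b].append((w, num, np.zeros(3), 0.0))
        elif spec.method == "exact" or (spec.method == "auto"
                                        and C <= spec.exact_max_total):
            w, num = _site_terms_exact(counts.tolist(), chroms.tolist(),
                                       ms.tolist(), cont_idx, len(continents))
            per_bin_sites[b].append((w, num, np.zeros(3), 0.0))
        else:
            w, num, nv, wv = _site_terms_mc(rng, counts, chroms, ms, cont_idx,
                                            len(continents), spec.replicates)
            per_bin_sites[b].append((w, num, nv, wv))

    estimates = np.full((n_bins, 3), np.nan)
    mc_se = np.zeros((n_bins, 3))
    n_sites_arr = np.zeros(n_bins, dtype=int)
    ws: list[np.ndarray] = []
    nums: list[np.ndarray] = []
    any_mc = False
    for b in range(n_bins):
        terms = per_bin_sites[b]
        n_sites_arr[b] = len(terms)
        if not terms:
            ws.append(np.zeros(0))
            nums.append(np.zeros((0, 3)))
            continue
        w = np.array([t[0] for t in terms])
        num = np.vstack([t[1] for t in terms])
        ws.append(w)
        nums.append(num)
        W = w.sum()
        estimates[b] = num.sum(axis=0) / W
        nvar = np.vstack([t[2] for t in terms]).sum(axis=0)
        wvar = sum(t[3] for t in terms)
        if nvar.any() or wvar:
            any_mc = True
            # delta method for the ratio sum(num)/sum(w), independent sites
            r = estimates[b]
            mc_se[b] = np.sqrt(np.maximum(nvar + r ** 2 * wvar, 0.0)) / W

    ci_low = ci_high = None
    if bootstrap_reps > 0:
        ci_low = np.full((n_bins, 3), np.nan)
        ci_high = np.full((n_bins, 3), np.nan)
        brng = substream(seed, STREAM_BOOTSTRAP)
        alpha = 100.0 * (1.0 - ci_level) / 2.0
        for b in range(n_bins):
            n = len(ws[b])
            if n < 2:
                continue
            idx = brng.integers(0, n, size=(bootstrap_reps, n))
            w_b = ws[b][idx].sum(axis=1)
            num_b = nums[b][idx].sum(axis=1)
            est_b = num_b / w_b[:, None]
            ci_low[b] = np.percentile(est_b, alpha, axis=0)
            ci_high[b] = np.percentile(est_b, 100.0 - alpha, axis=0)

    return SharingEstimate(tuple(bin_labels), estimates, n_sites_arr,
                           ci_low, ci_high, mc_se if any_mc else None)


def bootstrap_ci(sites: Sequence, estimator: Callable[[Sequence], np.ndarray],
                 B: int = 1000, seed: int = 0, level: float = 0.95
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Generic percentile bootstrap over variant sites.

    ``estimator`` maps a site list to a statistic vector. Deterministic
    under ``seed``; requires at least two sites and B >= 100.
    """
    sites = list(sites)
    if len(sites) < 2:
        raise UndefinedResultError("bootstrap needs at least two sites")
    if B < 100:
        raise ConfigError("B must be >= 100")
    rng = substream(seed, STREAM_BOOTSTRAP)
    stats = []
    for _ in range(B):
        idx = rng.integers(0, len(sites), size=len(sites))
        stats.append(np.asarray(estimator([sites[i] for i in idx]), dtype=float))
    stats = np.vstack(stats)
    alpha = 100.0 * (1.0 - level) / 2.0
    return (np.percentile(stats, alpha, axis=0),
            np.percentile(stats, 100.0 - alpha, axis=0))
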