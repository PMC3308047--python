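"""Shared fixtures: tiny panels, site factories, and small cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from exonpop import PopulationSpec, SamplePanel, SimulationConfig, VariantSite


@pytest.fixture
def panel3():
    """Three populations on two continents, two samples each."""
    s2p = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C", "c2": "C"}
    return SamplePanel(s2p, {"A": "Africa", "B": "Africa", "C": "Europe"})


@pytest.fixture
def site_factory():
    def make(pos=100, ref="A", alt="G", genotypes=(0, 1, 2), quality=None,
             qd=None, gq=None, ref_depths=None, alt_depths=None,
             ancestral=None, known=False, site_class=None, chrom="1"):
        g = np.asarray(genotypes, dtype=np.int8)
        def arr(x):
            return None if x is None else np.asarray(x)
        return VariantSite(chrom=chrom, pos=pos, ref=ref, alt=alt,
                           quality=quality, qd=qd, genotypes=g,
                           genotype_quals=arr(gq), ref_depths=arr(ref_depths),
                           alt_depths=arr(alt_depths), ancestral=ancestral,
                           known=known, site_class=site_class)
    return make


def small_config(**overrides) -> SimulationConfig:
    defaults = dict(
        populations=(PopulationSpec("POP1", "Africa", 12),
                     PopulationSpec("POP2", "Africa", 12),
                     PopulationSpec("POP3", "Europe", 12)),
        n_sites=150,
        fst=0.05,
        seed=11,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture
def small_cohort():
    from exonpop import simulate_cohort
    return simulate_cohort(small_config())
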