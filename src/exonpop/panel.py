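"""Sample panels: sample -> population -> continental group.

A panel is the total map from every sample to its population code and from
every population to its continent, mirroring the seven-population /
three-continent layout of multi-population exome studies.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import PanelError


class SamplePanel:
    """Immutable sample -> population -> continent assignment.

    Parameters
    ----------
    sample_to_pop:
        Mapping from sample identifier to population code. Iteration order
        fixes the sample index used by genotype matrices.
    pop_to_continent:
        Mapping from population code to continental group. Every population
        referenced by ``sample_to_pop`` must appear here.
    """

    def __init__(self, sample_to_pop: Mapping[str, str],
                 pop_to_continent: Mapping[str, str]):
        self._sample_to_pop = dict(sample_to_pop)
        self._pop_to_continent = dict(pop_to_continent)
        missing = {p for p in self._sample_to_pop.values()
                   if p not in self._pop_to_continent}
        if missing:
            raise PanelError(f"populations without a continent: {sorted(missing)}")
        self.samples: list[str] = list(self._sample_to_pop)
        self.populations: list[str] = sorted({*self._sample_to_pop.values()},
                                             key=list(self._pop_to_continent).index)
        self.continents: list[str] = []
        for pop in self.populations:
            cont = self._pop_to_continent[pop]
            if cont not in self.continents:
                self.continents.append(cont)
        self._index = {s: i for i, s in enumerate(self.samples)}

    # -- lookups ---------------------------------------------------------
    def population_of(self, sample: str) -> str:
        try:
            return self._sample_to_pop[sample]
        except KeyError:
            raise PanelError(f"sample {sample!r} not in panel") from None

    def continent_of(self, population: str) -> str:
        try:
            return self._pop_to_continent[population]
        except KeyError:
            raise PanelError(f"population {population!r} not in panel") from None

    def samples_in(self, population: str) -> list[str]:
        return [s for s, p in self._sample_to_pop.items() if p == population]

    def index_of(self, sample: str) -> int:
        return self._index[sample]

    def indices_by_population(self) -> dict[str, np.ndarray]:
        """Population code -> array of sample column indices."""
        out: dict[str, list[int]] = {p: [] for p in self.populations}
        for i, s in enumerate(self.samples):
            out[self._sample_to_pop[s]].append(i)
        return {p: np.asarray(ix, dtype=int) for p, ix in out.items()}

    def n_samples(self, population: str | None = None) -> int:
        if population is None:
            return len(self.samples)
        return len(self.samples_in(population))

    def __len__(self) -> int:
        return len(self.samples)

    def __contains__(self, sample: str) -> bool:
        return sample in self._sample_to_pop

    def __eq__(self, other) -> bool:
        return (isinstance(other, SamplePanel)
                and self._sample_to_pop == other._sample_to_pop
                and self._pop_to_continent == other._pop_to_continent)

    def subset(self, samples: Iterable[str]) -> "SamplePanel":
        samples = list(samples)
        for s in samples:
            if s not in self._sample_to_pop:
                raise PanelError(f"sample {s!r} not in panel")
        return SamplePanel({s: self._sample_to_pop[s] for s in samples},
                           self._pop_to_continent)

    # -- I/O -------------------------------------------------------------
    @classmethod
    def from_tsv(cls, path) -> "SamplePanel":
        """Read a 3-column tab-separated panel (sample, population, continent)."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        expected = ["sample", "population", "continent"]
        if list(df.columns[:3]) != expected:
            # headerless files are accepted as positional columns
            df = pd.read_csv(path, sep="\t", dtype=str, header=None,
                             names=expected)
        s2p = dict(zip(df["sample"], df["population"]))
        p2c = dict(zip(df["population"], df["continent"]))
        return cls(s2p, p2c)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame({
            "sample": self.samples,
            "population": [self._sample_to_pop[s] for s in self.samples],
            "continent": [self._pop_to_continent[self._sample_to_pop[s]]
                          for s in self.samples],
        })
        df.to_csv(path, sep="\t", index=False)
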