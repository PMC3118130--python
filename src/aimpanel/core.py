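"""Core in-memory containers shared by every stage of the pipeline.

Two objects move through the whole analysis:

* :class:`FrequencyPanel` — a populations × loci matrix of reference-allele
  frequencies together with the diploid sample sizes the frequencies were
  estimated from.
* :class:`GenotypeTable` — individuals × loci reference-allele dosages
  (0/1/2, NaN = missing) with the true population label of each individual.

Both are thin frozen wrappers over numpy arrays: loci are opaque string
identifiers (no genomic coordinates are ever used), and the reference
allele "A" is simply whichever allele the frequencies count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["FrequencyPanel", "GenotypeTable"]


def _as_str_tuple(xs: Sequence) -> tuple[str, ...]:
    return tuple(str(x) for x in xs)


@dataclass(frozen=True)
class FrequencyPanel:
    """Reference-allele frequencies per population.

    Parameters
    ----------
    populations
        Ordered population identifiers (rows of ``freq``).
    loci
        Ordered locus identifiers (columns of ``freq``).
    freq
        ``(K, L)`` array, ``freq[i, j]`` = frequency of the reference allele
        at locus ``j`` in population ``i``; all values in ``[0, 1]``.
    n
        ``(K,)`` integer array of diploid sample sizes used to estimate the
        frequencies; every ``n[i] >= 1``.
    """

    populations: tuple[str, ...]
    loci: tuple[str, ...]
    freq: np.ndarray
    n: np.ndarray

    def __init__(self, populations, loci, freq, n):
        object.__setattr__(self, "populations", _as_str_tuple(populations))
        object.__setattr__(self, "loci", _as_str_tuple(loci))
        object.__setattr__(self, "freq", np.asarray(freq, dtype=float))
        object.__setattr__(self, "n", np.asarray(n, dtype=int))
        self._validate()

    def _validate(self) -> None:
        K, L = len(self.populations), len(self.loci)
        if self.freq.shape != (K, L):
            raise ValueError(
                f"freq has shape {self.freq.shape}, expected ({K}, {L})"
            )
        if len(set(self.populations)) != K:
            raise ValueError("duplicate population identifiers")
        if len(set(self.loci)) != L:
            raise ValueError("duplicate locus identifiers")
        if self.n.shape != (K,):
            raise ValueError(f"n has shape {self.n.shape}, expected ({K},)")
        if np.any(self.n < 1):
            raise ValueError("per-population sample sizes must be >= 1")
        if not np.all(np.isfinite(self.freq)):
            raise ValueError("frequencies must be finite")
        if np.any((self.freq < 0) | (self.freq > 1)):
            bad = np.argwhere((self.freq < 0) | (self.freq > 1))[0]
            raise ValueError(
                "frequency outside [0, 1] at population "
                f"{self.populations[bad[0]]!r}, locus {self.loci[bad[1]]!r}"
            )

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def pop_index(self, population: str) -> int:
        try:
            return self.populations.index(population)
        except ValueError:
            raise KeyError(f"unknown population {population!r}") from None

    def locus_indices(self, loci: Sequence[str]) -> np.ndarray:
        pos = {l: j for j, l in enumerate(self.loci)}
        try:
            return np.array([pos[l] for l in loci], dtype=int)
        except KeyError as e:
            raise KeyError(f"locus {e.args[0]!r} not in panel") from None

    def subset_loci(self, loci: Sequence[str]) -> "FrequencyPanel":
        idx = self.locus_indices(loci)
        return FrequencyPanel(self.populations, [self.loci[j] for j in idx],
                              self.freq[:, idx], self.n)

    def subset_populations(self, populations: Sequence[str]) -> "FrequencyPanel":
        idx = [self.pop_index(p) for p in populations]
        return FrequencyPanel([self.populations[i] for i in idx], self.loci,
                              self.freq[idx, :], self.n[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.freq, index=list(self.populations),
                            columns=list(self.loci))


@dataclass(frozen=True)
class GenotypeTable:
    """Diploid reference-allele dosages with known population labels.

    ``dosage[i, j]`` counts copies of the reference allele (0, 1 or 2) for
    individual ``i`` at locus ``j``; missing calls are ``NaN``.
    """

    individuals: tuple[str, ...]
    loci: tuple[str, ...]
    dosage: np.ndarray
    true_pop: tuple[str, ...]

    def __init__(self, individuals, loci, dosage, true_pop):
        object.__setattr__(self, "individuals", _as_str_tuple(individuals))
        object.__setattr__(self, "loci", _as_str_tuple(loci))
        object.__setattr__(self, "dosage", np.asarray(dosage, dtype=float))
        object.__setattr__(self, "true_pop", _as_str_tuple(true_pop))
        self._validate()

    def _validate(self) -> None:
        N, L = len(self.individuals), len(self.loci)
        if self.dosage.shape != (N, L):
            raise ValueError(
                f"dosage has shape {self.dosage.shape}, expected ({N}, {L})"
            )
        if len(self.true_pop) != N:
            raise ValueError("true_pop length does not match individuals")
        if len(set(self.individuals)) != N:
            raise ValueError("duplicate individual identifiers")
        if len(set(self.loci)) != L:
            raise ValueError("duplicate locus identifiers")
        vals = self.dosage[~np.isnan(self.dosage)]
        if not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = sorted(set(vals[~np.isin(vals, (0.0, 1.0, 2.0))]))
            raise ValueError(f"dosage values outside {{0,1,2,missing}}: {bad}")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def populations(self) -> tuple[str, ...]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.true_pop:
            seen.setdefault(p, None)
        return tuple(seen)

    def locus_indices(self, loci: Sequence[str]) -> np.ndarray:
        pos = {l: j for j, l in enumerate(self.loci)}
        try:
            return np.array([pos[l] for l in loci], dtype=int)
        except KeyError as e:
            raise KeyError(f"locus {e.args[0]!r} not in genotype table") from None

    def subset_loci(self, loci: Sequence[str]) -> "GenotypeTable":
        idx = self.locus_indices(loci)
        return GenotypeTable(self.individuals, [self.loci[j] for j in idx],
                             self.dosage[:, idx], self.true_pop)

    def subset_individuals(self, individuals: Sequence[str]) -> "GenotypeTable":
        pos = {ind: i for i, ind in enumerate(self.individuals)}
        idx = [pos[i] for i in individuals]
        return GenotypeTable([self.individuals[i] for i in idx], self.loci,
                             self.dosage[idx, :],
                             [self.true_pop[i] for i in idx])

    def members(self, population: str) -> tuple[str, ...]:
        return tuple(ind for ind, p in zip(self.individuals, self.true_pop)
                     if p == population)

    def relabel(self, mapping: dict[str, str]) -> "GenotypeTable":
        """Rewrite population labels through ``mapping`` (identity elsewhere)."""
        return GenotypeTable(self.individuals, self.loci, self.dosage,
                             [mapping.get(p, p) for p in self.true_pop])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.dosage, index=list(self.individuals),
                          columns=list(self.loci))
        df.insert(0, "population", list(self.true_pop))
        return df
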