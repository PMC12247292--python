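"""Shared containers: phased haplotype sets and breed-origin codes.

Breed-origin codes are small signed integers so that call matrices and
truth matrices share one dtype:

* ``LOCAL = 0``   -- allele descends from a local (indigenous) founder
* ``EXOTIC = 1``  -- allele descends from an exotic founder
* ``MISSING = -1`` -- no breed origin assigned
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LOCAL: int = 0
EXOTIC: int = 1
MISSING: int = -1

#: single-character codes used in text output (calls TSV, truth matrix)
CODE_TO_CHAR = {LOCAL: "L", EXOTIC: "E", MISSING: "M"}
CHAR_TO_CODE = {v: k for k, v in CODE_TO_CHAR.items()}


@dataclass
class HaploSet:
    """A phased biallelic haplotype panel on one chromosome.

    Parameters
    ----------
    haplotypes:
        ``(2n, m)`` uint8 matrix of 0/1 alleles.  Rows ``2i`` and ``2i+1``
        are the two haplotypes of individual ``i``.
    positions:
        Genetic-map position of each locus in Morgans, strictly increasing.
    samples:
        One row per individual with at least the columns
        ``sample_id``, ``population`` and ``generation``.
    """

    haplotypes: np.ndarray
    positions: np.ndarray
    samples: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.haplotypes = np.ascontiguousarray(self.haplotypes, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D matrix")
        if self.haplotypes.shape[0] % 2 != 0:
            raise ValueError("haplotype matrix must have an even number of rows")
        if self.haplotypes.shape[1] != self.positions.shape[0]:
            raise ValueError(
                f"{self.haplotypes.shape[1]} loci in matrix but "
                f"{self.positions.shape[0]} map positions"
            )
        if np.any((self.haplotypes != 0) & (self.haplotypes != 1)):
            raise ValueError("haplotype entries must be 0 or 1")
        if self.positions.size > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("map positions must be strictly increasing")
        if len(self.samples) * 2 != self.haplotypes.shape[0]:
            raise ValueError(
                f"{len(self.samples)} samples for {self.haplotypes.shape[0]} haplotype rows"
            )
        for col in ("sample_id", "population", "generation"):
            if col not in self.samples.columns:
                raise ValueError(f"sample sheet lacks required column {col!r}")

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[1]

    def individual(self, i: int) -> np.ndarray:
        """The ``(2, m)`` haplotype pair of individual ``i`` (a view)."""
        return self.haplotypes[2 * i : 2 * i + 2]

    def subset(self, individual_idx: np.ndarray) -> "HaploSet":
        """Restrict to the given individuals (by 0-based index)."""
        idx = np.asarray(individual_idx, dtype=int)
        rows = np.column_stack([2 * idx, 2 * idx + 1]).ravel()
        return HaploSet(
            haplotypes=self.haplotypes[rows].copy(),
            positions=self.positions,
            samples=self.samples.iloc[idx].reset_index(drop=True),
        )


def codes_to_chars(codes: np.ndarray) -> np.ndarray:
    """Map an integer code array to the L/E/M character alphabet."""
    out = np.full(codes.shape, "?", dtype="<U1")
    for code, char in CODE_TO_CHAR.items():
        out[codes == code] = char
    if np.any(out == "?"):
        raise ValueError("array contains values outside {LOCAL, EXOTIC, MISSING}")
    return out


def chars_to_codes(chars: np.ndarray) -> np.ndarray:
    """Inverse of :func:`codes_to_chars`."""
    chars = np.asarray(chars, dtype="<U1")
    out = np.full(chars.shape, 99, dtype=np.int8)
    for char, code in CHAR_TO_CODE.items():
        out[chars == char] = code
    if np.any(out == 99):
        raise ValueError("array contains characters outside {L, E, M}")
    return out
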