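"""Core windows and the switch-error model for imperfect phasing.

A *core* is a window of consecutive SNP loci treated as one haplotype
unit.  Each core length is applied in two modes: plain tiling from locus
0, and *offset* tiling where the first window is shortened to half a core
so all subsequent boundaries shift forward by 50% of the core length.
Terminal partial windows are kept, so every scheme covers each locus
exactly once.

Phased input defaults to the true simulated haplotypes; the switch-error
injector flips the maternal/paternal assignment from a heterozygous locus
onward with a given per-site probability, the classic model of
statistical-phasing error, leaving genotypes untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .haplo import HaploSet

DEFAULT_CORE_LENGTHS = (100, 120, 140, 160, 180, 200, 220, 240, 260, 280)


@dataclass(frozen=True)
class Core:
    """Half-open window ``[start, stop)`` of locus indices."""

    start: int
    stop: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.stop:
            raise ValueError(f"invalid core bounds [{self.start}, {self.stop})")

    @property
    def width(self) -> int:
        return self.stop - self.start


def make_cores(n_loci: int, core_length: int, offset: bool = False) -> list[Core]:
    """Tile ``[0, n_loci)`` with cores of the given length.

    Without offset the windows start at 0, ``L``, ``2L``, ...; with offset
    the first window is ``[0, L//2)`` and full windows follow.  A final
    partial window absorbs the remainder in either mode.
    """
    if core_length <= 0:
        raise ValueError("core_length must be positive")
    if core_length > n_loci:
        raise ValueError(f"core_length {core_length} exceeds {n_loci} loci")
    first_stop = core_length // 2 if offset else core_length
    stop = min(first_stop, n_loci)
    cores = [Core(0, stop)]
    while stop < n_loci:
        nxt = min(stop + core_length, n_loci)
        cores.append(Core(stop, nxt))
        stop = nxt
    return cores


@dataclass(frozen=True)
class PhasingScheme:
    """The grid of windowing scenarios applied to one dataset."""

    core_lengths: tuple[int, ...] = DEFAULT_CORE_LENGTHS
    offset_modes: tuple[bool, ...] = (False, True)
    switch_error_rate: float = 0.0

    def __post_init__(self) -> None:
        if any(length <= 0 for length in self.core_lengths):
            raise ValueError("core lengths must be positive")
        if not 0 <= self.switch_error_rate <= 1:
            raise ValueError("switch_error_rate must lie in [0, 1]")

    def scenarios(self) -> list[tuple[int, bool]]:
        """All (core_length, offset) pairs, offset-minor order."""
        return [(length, off) for length in self.core_lengths for off in self.offset_modes]


def inject_switch_errors(
    haplo: np.ndarray | HaploSet, rate: float, rng: np.random.Generator
) -> np.ndarray | HaploSet:
    """Corrupt phase with independent switch errors at heterozygous sites.

    At each heterozygous locus of each individual, with probability
    ``rate``, the maternal/paternal assignment is flipped from that locus
    to the end of the chromosome.  Per-locus genotypes are preserved by
    construction.  Returns the same container type it was given.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must lie in [0, 1]")
    if isinstance(haplo, HaploSet):
        flipped = inject_switch_errors(haplo.haplotypes, rate, rng)
        return HaploSet(flipped, haplo.positions, haplo.samples.copy())
    hap = np.asarray(haplo, dtype=np.uint8)
    if rate == 0:
        return hap.copy()
    mat, pat = hap[0::2], hap[1::2]
    het = mat != pat
    switches = het & (rng.random(mat.shape) < rate)
    # a switch toggles the swapped/unswapped state from its locus onward
    state = np.cumsum(switches, axis=1) % 2 == 1
    out = hap.copy()
    out[0::2] = np.where(state, pat, mat)
    out[1::2] = np.where(state, mat, pat)
    return out


def cores_to_frame(n_loci: int, scheme: PhasingScheme) -> pd.DataFrame:
    """Serializable audit table of every core in every scenario."""
    rows = []
    for length, off in scheme.scenarios():
        for k, core in enumerate(make_cores(n_loci, length, off)):
            rows.append(
                {
                    "core_id": k,
                    "start": core.start,
                    "stop": core.stop,
                    "width": core.width,
                    "core_length": length,
                    "mode": "offset" if off else "no_offset",
                }
            )
    return pd.DataFrame(rows)
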