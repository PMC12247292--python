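"""Core-based breed-origin assignment by haplotype-library matching.

For each core window, the unique haplotype sequences observed in each
purebred reference panel form that breed's *haplotype library*.  A
crossbred haplotype is assigned to the breed whose library contains the
entry with the fewest mismatches (Hamming distance) against it; if both
libraries tie on the minimum, the call is missing.  The per-core call is
broadcast to every locus inside the core, giving per-allele calls.

An optional minimum match fraction turns low-quality wins into missing
calls: the winning library must match at least ``min_match_fraction`` of
the core's sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .haplo import EXOTIC, LOCAL, MISSING, HaploSet, codes_to_chars
from .windows import Core, PhasingScheme, make_cores

_CHUNK = 4096  # target rows per distance-matrix block (memory bound)


def _unique_rows(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(unique rows, inverse index, counts) of a 0/1 uint8 matrix.

    Rows are bit-packed before de-duplication, which is much faster than
    ``np.unique(..., axis=0)`` on wide windows and yields the same row set.
    """
    packed = np.packbits(matrix, axis=1)
    view = np.ascontiguousarray(packed).view(
        np.dtype((np.void, packed.shape[1]))
    ).ravel()
    _, first_idx, inverse, counts = np.unique(
        view, return_index=True, return_inverse=True, return_counts=True
    )
    return matrix[first_idx], inverse, counts


@dataclass
class HaplotypeLibrary:
    """Unique haplotypes of one purebred panel within one core."""

    core: Core
    breed: int  # LOCAL or EXOTIC
    entries: np.ndarray  # (u, width) uint8, pairwise distinct
    counts: np.ndarray  # (u,) observation counts

    @property
    def size(self) -> int:
        return len(self.entries)


def build_library(purebred: HaploSet | np.ndarray, core: Core, breed: int = LOCAL) -> HaplotypeLibrary:
    """De-duplicate a purebred panel's haplotypes within a core."""
    hap = purebred.haplotypes if isinstance(purebred, HaploSet) else np.asarray(purebred)
    if hap.shape[0] == 0:
        raise ValueError("cannot build a haplotype library from an empty panel")
    window = np.ascontiguousarray(hap[:, core.start : core.stop], dtype=np.uint8)
    entries, _, counts = _unique_rows(window)
    return HaplotypeLibrary(core=core, breed=breed, entries=entries, counts=counts)


def mismatches(a: np.ndarray, b: np.ndarray) -> int:
    """Hamming distance between two equal-length 0/1 sequences."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"sequence lengths differ: {a.shape} vs {b.shape}")
    return int(np.count_nonzero(a != b))


def _min_mismatch_block(targets: np.ndarray, entries: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Minimum Hamming distance of each target to a library, plus the
    number of library entries attaining it.  Vectorized via the identity
    ``d(a, b) = sum(a) + sum(b) - 2 a.b`` on 0/1 rows."""
    t = targets.astype(np.float32)
    e = entries.astype(np.float32)
    mind = np.empty(len(t), dtype=np.int32)
    nmin = np.empty(len(t), dtype=np.int32)
    e_sums = e.sum(axis=1)
    # cap the distance-matrix block at ~16M float32 cells
    step = max(1, min(_CHUNK, 16_000_000 // max(1, len(entries))))
    for lo in range(0, len(t), step):
        block = t[lo : lo + step]
        d = block.sum(axis=1)[:, None] + e_sums[None, :] - 2.0 * (block @ e.T)
        d = np.rint(d).astype(np.int32)
        bm = d.min(axis=1)
        mind[lo : lo + step] = bm
        nmin[lo : lo + step] = (d == bm[:, None]).sum(axis=1)
    return mind, nmin


def best_match(target: np.ndarray, lib: HaplotypeLibrary) -> tuple[int, int]:
    """(min mismatches over the library, number of entries attaining it)."""
    if lib.size == 0:
        raise ValueError("empty haplotype library")
    target = np.asarray(target, dtype=np.uint8)
    if target.shape != (lib.core.width,):
        raise ValueError(
            f"target length {target.shape} does not match core width {lib.core.width}"
        )
    d = (lib.entries != target).sum(axis=1)
    mind = int(d.min())
    return mind, int((d == mind).sum())


def _calls_from_mismatches(
    m_exotic: np.ndarray,
    m_local: np.ndarray,
    width: int,
    min_match_fraction: float | None,
) -> np.ndarray:
    calls = np.full(m_exotic.shape, MISSING, dtype=np.int8)
    calls[m_exotic < m_local] = EXOTIC
    calls[m_local < m_exotic] = LOCAL
    if min_match_fraction is not None:
        winner_m = np.minimum(m_exotic, m_local)
        ok = 1.0 - winner_m / width >= min_match_fraction - 1e-12
        calls[~ok] = MISSING
    return calls


def assign_core(
    target: np.ndarray,
    lib_exotic: HaplotypeLibrary,
    lib_local: HaplotypeLibrary,
    min_match_fraction: float | None = None,
) -> int:
    """Assign one core haplotype to EXOTIC, LOCAL, or MISSING.

    The breed with the strictly smaller minimum mismatch count wins; an
    exact tie is missing.  With ``min_match_fraction`` set, a winner whose
    best match covers less than that fraction of the core is also missing.
    """
    if lib_exotic.core != lib_local.core:
        raise ValueError(
            f"library cores differ: {lib_exotic.core} vs {lib_local.core}"
        )
    m_e, _ = best_match(target, lib_exotic)
    m_l, _ = best_match(target, lib_local)
    call = _calls_from_mismatches(
        np.array([m_e]), np.array([m_l]), lib_exotic.core.width, min_match_fraction
    )
    return int(call[0])


@dataclass
class ScenarioCalls:
    """Per-core calls of one (core length, offset mode) scenario."""

    cores: list[Core]
    calls: np.ndarray  # (n_haplotypes, n_cores) int8


@dataclass
class AssignmentTensor:
    """Calls for every haplotype x locus x scenario, stored per core.

    Within one scenario every locus of a core carries the core's call, so
    only the ``(n_haplotypes, n_cores)`` matrix is kept per scenario;
    :meth:`expand` broadcasts to per-locus calls on demand.
    """

    n_haplotypes: int
    n_loci: int
    scenarios: dict[tuple[int, bool], ScenarioCalls]
    provenance: dict = field(default_factory=dict)

    def expand(self, core_length: int, offset: bool) -> np.ndarray:
        """Per-locus ``(n_haplotypes, n_loci)`` calls of one scenario."""
        sc = self.scenarios[(core_length, offset)]
        out = np.empty((self.n_haplotypes, self.n_loci), dtype=np.int8)
        for k, core in enumerate(sc.cores):
            out[:, core.start : core.stop] = sc.calls[:, k : k + 1]
        return out

    def vote_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-allele counts of EXOTIC and LOCAL votes across scenarios."""
        n_e = np.zeros((self.n_haplotypes, self.n_loci), dtype=np.int16)
        n_l = np.zeros_like(n_e)
        for key in self.scenarios:
            per_locus = self.expand(*key)
            n_e += per_locus == EXOTIC
            n_l += per_locus == LOCAL
        return n_e, n_l

    @property
    def n_scenarios(self) -> int:
        return len(self.scenarios)

    def to_frame(self) -> pd.DataFrame:
        """Long-format per-allele calls (one row per haplotype x locus x
        scenario); intended for modest problem sizes and file export."""
        parts = []
        for (length, off), _ in self.scenarios.items():
            per_locus = self.expand(length, off)
            hap_idx, locus = np.meshgrid(
                np.arange(self.n_haplotypes), np.arange(self.n_loci), indexing="ij"
            )
            parts.append(
                pd.DataFrame(
                    {
                        "haplotype_row": hap_idx.ravel(),
                        "individual": hap_idx.ravel() // 2,
                        "haplotype": hap_idx.ravel() % 2,
                        "locus": locus.ravel(),
                        "core_length": length,
                        "mode": "offset" if off else "no_offset",
                        "call": codes_to_chars(per_locus.ravel()),
                    }
                )
            )
        frame = pd.concat(parts, ignore_index=True)
        for key, value in self.provenance.items():
            frame[key] = value
        return frame


def _assign_one_core(
    window: np.ndarray,
    lib_exotic: HaplotypeLibrary,
    lib_local: HaplotypeLibrary,
    min_match_fraction: float | None,
) -> np.ndarray:
    """Vectorized per-core assignment of many target haplotypes."""
    uniq, inverse, _ = _unique_rows(window)
    m_e, _ = _min_mismatch_block(uniq, lib_exotic.entries)
    m_l, _ = _min_mismatch_block(uniq, lib_local.entries)
    calls = _calls_from_mismatches(m_e, m_l, window.shape[1], min_match_fraction)
    return calls[inverse]


def assign_all(
    crossbreds: HaploSet | np.ndarray,
    exotic_panel: HaploSet | np.ndarray,
    local_panel: HaploSet | np.ndarray,
    scheme: PhasingScheme,
    min_match_fraction: float | None = None,
    provenance: dict | None = None,
) -> AssignmentTensor:
    """Assign every crossbred haplotype in every windowing scenario."""

    def matrix(x):
        return x.haplotypes if isinstance(x, HaploSet) else np.asarray(x, dtype=np.uint8)

    cross = matrix(crossbreds)
    pan_e = matrix(exotic_panel)
    pan_l = matrix(local_panel)
    n_loci = cross.shape[1]
    if pan_e.shape[1] != n_loci or pan_l.shape[1] != n_loci:
        raise ValueError("crossbreds and purebred panels must share the locus set")

    scenarios: dict[tuple[int, bool], ScenarioCalls] = {}
    for length, off in scheme.scenarios():
        cores = make_cores(n_loci, length, off)
        calls = np.empty((cross.shape[0], len(cores)), dtype=np.int8)
        for k, core in enumerate(cores):
            lib_e = build_library(pan_e, core, EXOTIC)
            lib_l = build_library(pan_l, core, LOCAL)
            window = np.ascontiguousarray(cross[:, core.start : core.stop])
            calls[:, k] = _assign_one_core(window, lib_e, lib_l, min_match_fraction)
        scenarios[(length, off)] = ScenarioCalls(cores, calls)
    return AssignmentTensor(
        n_haplotypes=cross.shape[0],
        n_loci=n_loci,
        scenarios=scenarios,
        provenance=provenance or {},
    )
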