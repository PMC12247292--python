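"""Founder haplotype simulation.

One exotic breed and four more closely related local breeds descend from a
common ancestral cattle population.  The demography is a two-level split
model simulated with ``msprime``: the ancestral population splits into an
exotic branch and an indigenous branch; the indigenous branch later splits
into the four local breeds.  Split depths are calibrated (see
:func:`calibrate_split`) so that the exotic-vs-pooled-local differentiation
matches a target Hudson FST; the shipped defaults were obtained by running
the calibration against a target of 0.09.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import msprime
import numpy as np
import pandas as pd

from .haplo import HaploSet

EXOTIC_POP = "EXOTIC"
LOCAL_POPS = ("LOCAL_1", "LOCAL_2", "LOCAL_3", "LOCAL_4")

#: split depth (generations ago) of the exotic/indigenous divergence that
#: reproduces FST ~ 0.09 between exotic and pooled local founders under the
#: default sizes below; produced by ``calibrate_split(0.09, 0.02, ...)``.
CALIBRATED_SPLIT_EXOTIC = 54.0

#: ratio of the local-breed split depth to the exotic split depth.  Local
#: breeds are far more closely related to each other than to the exotic
#: breed, so their radiation is placed at a quarter of the deep split.
LOCAL_SPLIT_RATIO = 0.25


class InsufficientVariantsError(RuntimeError):
    """Raised when too few segregating sites survive the MAF filter."""


@dataclass
class FounderConfig:
    """Parameters of the founder coalescent simulation.

    Sizes follow the study design: 2500 founder individuals genotyped at
    1000 SNPs on one chromosome, split equally over the exotic breed and
    four local breeds.  Effective sizes reflect modern cattle breeds
    (Ne of a few hundred) below a larger ancestral population.
    """

    n_loci: int = 1000
    n_local_breeds: int = 4
    pop_size: int = 500  # diploid founders sampled per population
    ne_breed: float = 200.0  # effective size of each terminal breed
    ne_indigenous: float = 500.0  # indigenous branch between the two splits
    ne_ancestral: float = 1000.0
    split_depth_exotic: float = CALIBRATED_SPLIT_EXOTIC  # generations ago
    split_depth_local: float = CALIBRATED_SPLIT_EXOTIC * LOCAL_SPLIT_RATIO
    map_length_morgans: float = 1.0
    sequence_length_bp: float = 1.0e6
    mutation_rate: float = 1.2e-6  # per bp per generation; oversupplies SNPs
    maf_min: float = 0.05
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_local_breeds != len(LOCAL_POPS):
            raise ValueError("the split model is defined for exactly 4 local breeds")
        if not 0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must lie in [0, 0.5)")
        if self.split_depth_local > self.split_depth_exotic:
            raise ValueError(
                "split_depth_local must not exceed split_depth_exotic "
                "(local breeds are more closely related than exotic vs local)"
            )
        if self.n_loci <= 0 or self.pop_size <= 0:
            raise ValueError("n_loci and pop_size must be positive")

    @property
    def n_individuals_total(self) -> int:
        return self.pop_size * (1 + self.n_local_breeds)

    @property
    def recombination_rate(self) -> float:
        """Per-bp recombination rate giving ``map_length_morgans`` in total."""
        return self.map_length_morgans / self.sequence_length_bp


@dataclass
class FounderSet:
    """Founder panel plus convenience views by breed."""

    haplo: HaploSet

    @property
    def positions(self) -> np.ndarray:
        return self.haplo.positions

    @property
    def population_labels(self) -> pd.Series:
        return self.haplo.samples["population"]

    def _pop_index(self, pops: tuple[str, ...]) -> np.ndarray:
        return np.flatnonzero(self.population_labels.isin(pops).to_numpy())

    def exotic(self) -> HaploSet:
        return self.haplo.subset(self._pop_index((EXOTIC_POP,)))

    def local_pooled(self) -> HaploSet:
        """All four local breeds pooled into one panel."""
        return self.haplo.subset(self._pop_index(LOCAL_POPS))

    def breed(self, name: str) -> HaploSet:
        return self.haplo.subset(self._pop_index((name,)))


def _demography(cfg: FounderConfig) -> msprime.Demography:
    dem = msprime.Demography()
    dem.add_population(name="ANC", initial_size=cfg.ne_ancestral)
    dem.add_population(name="INDIG", initial_size=cfg.ne_indigenous)
    dem.add_population(name=EXOTIC_POP, initial_size=cfg.ne_breed)
    for name in LOCAL_POPS:
        dem.add_population(name=name, initial_size=cfg.ne_breed)
    # a zero-depth split degenerates to panmixia; msprime requires time > 0,
    # so clamp to a tiny epsilon ordering local strictly before exotic
    t_local = max(cfg.split_depth_local, 1e-9)
    t_exotic = max(cfg.split_depth_exotic, 2e-9)
    if t_exotic <= t_local:
        t_exotic = t_local * (1 + 1e-9) + 1e-12
    dem.add_population_split(time=t_local, derived=list(LOCAL_POPS), ancestral="INDIG")
    dem.add_population_split(time=t_exotic, derived=[EXOTIC_POP, "INDIG"], ancestral="ANC")
    return dem


def simulate_founders(cfg: FounderConfig) -> FounderSet:
    """Simulate the founder panel and ascertain ``cfg.n_loci`` SNPs.

    Sites are kept if biallelic and segregating at pooled minor-allele
    frequency >= ``cfg.maf_min``; the requested number of loci is then
    taken evenly spaced along the chromosome so the marker map stays
    roughly uniform.  The same config (including its seed) always yields a
    bit-identical matrix.
    """
    dem = _demography(cfg)
    samples = {EXOTIC_POP: cfg.pop_size, **{p: cfg.pop_size for p in LOCAL_POPS}}
    # msprime wants strictly positive 32-bit seeds; derive two from cfg.seed
    ss = np.random.SeedSequence(cfg.seed)
    anc_seed, mut_seed = (int(s) % (2**31 - 2) + 1 for s in ss.generate_state(2))
    ts = msprime.sim_ancestry(
        samples=samples,
        demography=dem,
        sequence_length=cfg.sequence_length_bp,
        recombination_rate=cfg.recombination_rate,
        random_seed=anc_seed,
    )
    ts = msprime.sim_mutations(
        ts,
        rate=cfg.mutation_rate,
        random_seed=mut_seed,
        model=msprime.BinaryMutationModel(),
    )
    genotypes = ts.genotype_matrix()  # sites x haplotypes
    if genotypes.size == 0:
        raise InsufficientVariantsError(
            "no segregating sites were produced; raise mutation_rate"
        )
    # the binary mutation model only toggles 0/1, so every site is biallelic;
    # guard anyway so a model change cannot silently corrupt the panel
    biallelic = genotypes.max(axis=1) <= 1
    freq = genotypes.mean(axis=1)
    keep = biallelic & (np.minimum(freq, 1 - freq) >= cfg.maf_min)
    idx = np.flatnonzero(keep)
    if idx.size < cfg.n_loci:
        raise InsufficientVariantsError(
            f"only {idx.size} segregating sites pass the MAF filter but "
            f"{cfg.n_loci} loci were requested; raise mutation_rate / "
            f"sequence_length_bp or lower maf_min"
        )
    sel = idx[np.round(np.linspace(0, idx.size - 1, cfg.n_loci)).astype(int)]
    site_pos = ts.tables.sites.position[sel]
    positions = site_pos * cfg.recombination_rate  # bp -> Morgans
    hap = np.ascontiguousarray(genotypes[sel].T, dtype=np.uint8)

    pops = [EXOTIC_POP] * cfg.pop_size
    for name in LOCAL_POPS:
        pops.extend([name] * cfg.pop_size)
    sheet = pd.DataFrame(
        {
            "sample_id": [f"F{i:05d}" for i in range(cfg.n_individuals_total)],
            "population": pops,
            "generation": "FOUNDER",
        }
    )
    return FounderSet(HaploSet(hap, positions, sheet))


def calibrate_split(
    target_fst: float,
    tolerance: float,
    cfg: FounderConfig,
    *,
    n_replicates: int = 10,
    depth_bounds: tuple[float, float] = (1.0, 400.0),
    max_iter: int = 20,
    seed: int = 2024,
) -> float:
    """Find the exotic split depth whose mean simulated FST hits the target.

    Mean Hudson FST between exotic and pooled local founders is monotone
    increasing in divergence time, so plain bisection over
    ``split_depth_exotic`` suffices; the local split depth is scaled along
    with it (ratio taken from ``cfg``).  The mean is taken over
    ``n_replicates`` independent simulations per candidate depth.

    Returns the calibrated ``split_depth_exotic``.  Raises ``ValueError``
    if the search range does not bracket the target.
    """
    from .metrics import fst  # deferred: metrics imports nothing from here

    if not 0 < target_fst < 1:
        raise ValueError("target_fst must lie in (0, 1)")
    ratio = (
        cfg.split_depth_local / cfg.split_depth_exotic
        if cfg.split_depth_exotic > 0
        else LOCAL_SPLIT_RATIO
    )
    rep_seeds = np.random.SeedSequence(seed).generate_state(n_replicates)

    def mean_fst(depth: float) -> float:
        vals = []
        for s in rep_seeds:
            c = replace(
                cfg,
                split_depth_exotic=depth,
                split_depth_local=depth * ratio,
                seed=int(s) % (2**31 - 1),
            )
            fs = simulate_founders(c)
            vals.append(fst(fs.exotic().haplotypes, fs.local_pooled().haplotypes))
        return float(np.mean(vals))

    lo, hi = depth_bounds
    f_lo, f_hi = mean_fst(lo), mean_fst(hi)
    if not (f_lo <= target_fst <= f_hi):
        raise ValueError(
            f"depth bounds {depth_bounds} do not bracket target FST "
            f"{target_fst} (FST at bounds: {f_lo:.4f}, {f_hi:.4f})"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = mean_fst(mid)
        if abs(f_mid - target_fst) <= tolerance:
            return mid
        if f_mid < target_fst:
            lo = mid
        else:
            hi = mid
    raise RuntimeError(
        f"bisection did not reach |FST - {target_fst}| <= {tolerance} in "
        f"{max_iter} iterations; Monte-Carlo noise may exceed the tolerance "
        f"-- raise n_replicates or tolerance"
    )
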