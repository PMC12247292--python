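"""Stochastic crossbreeding program with per-locus breed-origin tracking.

The program emulates smallholder dairy crossbreeding: local breeds are
pooled and randomly mated for a number of generations, the best cows are
selected on a polygenic trait, and those cows (and subsequently their
crossbred daughters) are mated to newly imported purebred exotic bulls for
several rounds.  Both purebred populations are maintained in parallel.

Every meiosis cuts the parental haplotype pair and its breed-origin pair at
the same recombination breakpoints, so the true founder-breed origin of
each allele copy is known exactly for every crossbred animal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .founders import FounderSet
from .haplo import EXOTIC, LOCAL, HaploSet

FEMALE = 0
MALE = 1


# ---------------------------------------------------------------------------
# trait architecture


@dataclass
class TraitArchitecture:
    """Additive + dominance architecture of the selection trait.

    Dominance effects are parameterized through dominance degrees
    ``delta_i = d_i / |a_i|`` drawn around a small positive mean, the usual
    way mild directional dominance is introduced in breeding simulations.
    """

    qtl_indices: np.ndarray  # locus indices of the QTL
    additive_effects: np.ndarray  # a_i
    dominance_degrees: np.ndarray  # delta_i
    dominance_effects: np.ndarray  # d_i = delta_i * |a_i|
    environmental_variance: float

    def __post_init__(self) -> None:
        n = len(self.qtl_indices)
        for arr in (self.additive_effects, self.dominance_degrees, self.dominance_effects):
            if len(arr) != n:
                raise ValueError("trait effect vectors must all have one entry per QTL")
        if self.environmental_variance < 0:
            raise ValueError("environmental variance must be non-negative")


def sample_trait(
    founders: FounderSet,
    n_qtl: int = 100,
    h2: float = 0.3,
    *,
    dd_mean: float = 0.1,
    dd_var: float = 0.1,
    rng: np.random.Generator | None = None,
) -> TraitArchitecture:
    """Draw a trait and solve the environmental variance for a target h2.

    Additive effects are standard normal; dominance degrees are
    ``Normal(dd_mean, sqrt(dd_var))``.  The environmental variance is set
    from the additive and dominance variances realized in the pooled local
    founder population (linkage equilibrium approximation) so that the
    narrow-sense heritability there equals ``h2``.
    """
    if rng is None:
        rng = np.random.default_rng()
    base = founders.local_pooled()
    if not 0 < h2 < 1:
        raise ValueError("h2 must lie in (0, 1)")
    if n_qtl > base.n_loci:
        raise ValueError("n_qtl cannot exceed the number of loci")
    qtl = np.sort(rng.choice(base.n_loci, size=n_qtl, replace=False))
    a = rng.standard_normal(n_qtl)
    delta = dd_mean + np.sqrt(dd_var) * rng.standard_normal(n_qtl)
    d = delta * np.abs(a)

    p = base.haplotypes[:, qtl].mean(axis=0)
    q = 1 - p
    alpha = a + d * (q - p)  # average allele-substitution effect
    var_a = float(np.sum(2 * p * q * alpha**2))
    var_d = float(np.sum((2 * p * q * d) ** 2))
    if var_a <= 0:
        raise ValueError(
            "zero realized additive variance in the base population; "
            "all QTL are monomorphic there"
        )
    var_e = var_a * (1 - h2) / h2 - var_d
    if var_e < 0:
        raise ValueError(
            f"target h2={h2} unattainable: dominance variance {var_d:.4f} "
            f"exceeds the non-additive budget"
        )
    return TraitArchitecture(qtl, a, delta, d, var_e)


def genetic_value(haplopairs: np.ndarray, arch: TraitArchitecture) -> np.ndarray | float:
    """Total genetic value(s) under the additive+dominance model.

    ``value = sum_i a_i * (x_i - 1) + d_i * [x_i == 1]`` with dosage
    ``x_i in {0, 1, 2}``.  Accepts a single ``(2, m)`` haplotype pair or a
    stacked ``(2n, m)`` matrix; returns a scalar or an ``(n,)`` vector.
    """
    hp = np.asarray(haplopairs)
    single = hp.shape[0] == 2 and hp.ndim == 2
    if hp.ndim != 2 or hp.shape[0] % 2 != 0:
        raise ValueError("haplopairs must be a (2n, m) 0/1 matrix")
    if arch.qtl_indices.size and arch.qtl_indices.max() >= hp.shape[1]:
        raise ValueError("trait architecture refers to loci beyond the matrix")
    x = hp[0::2, arch.qtl_indices].astype(np.int16) + hp[1::2, arch.qtl_indices]
    vals = (x - 1) @ arch.additive_effects + (x == 1) @ arch.dominance_effects
    return float(vals[0]) if single else vals


def phenotype(
    gv: np.ndarray | float, env_var: float, rng: np.random.Generator
) -> np.ndarray | float:
    """Add Normal(0, env_var) environmental noise to genetic values."""
    if env_var < 0:
        raise ValueError("environmental variance must be non-negative")
    gv = np.asarray(gv, dtype=float)
    noise = rng.normal(0.0, np.sqrt(env_var), size=gv.shape)
    out = gv + noise
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# individuals, cohorts, meiosis


@dataclass
class Individual:
    """Single-animal view used by :func:`meiosis` and in tests."""

    id: int
    sex: int  # FEMALE or MALE
    generation_label: str
    haplopair: np.ndarray  # (2, m)
    originpair: np.ndarray  # (2, m) breed codes
    genetic_value: float | None = None
    phenotype: float | None = None


@dataclass
class Cohort:
    """One generation of animals stored as stacked arrays."""

    label: str
    haplo: np.ndarray  # (2n, m) uint8
    origin: np.ndarray  # (2n, m) int8, LOCAL/EXOTIC
    sex: np.ndarray  # (n,)
    ids: np.ndarray  # (n,)
    sire: np.ndarray  # (n,), -1 for founders
    dam: np.ndarray
    genetic_value: np.ndarray | None = None
    phenotype: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.ids)

    def individual(self, i: int) -> Individual:
        return Individual(
            id=int(self.ids[i]),
            sex=int(self.sex[i]),
            generation_label=self.label,
            haplopair=self.haplo[2 * i : 2 * i + 2],
            originpair=self.origin[2 * i : 2 * i + 2],
            genetic_value=None if self.genetic_value is None else float(self.genetic_value[i]),
            phenotype=None if self.phenotype is None else float(self.phenotype[i]),
        )

    def females(self) -> np.ndarray:
        return np.flatnonzero(self.sex == FEMALE)

    def males(self) -> np.ndarray:
        return np.flatnonzero(self.sex == MALE)

    def to_haploset(self, positions: np.ndarray, population: str) -> HaploSet:
        sheet = pd.DataFrame(
            {
                "sample_id": [f"I{i:07d}" for i in self.ids],
                "population": population,
                "generation": self.label,
            }
        )
        return HaploSet(self.haplo, positions, sheet)


def _gamete(
    haplopair: np.ndarray,
    originpair: np.ndarray,
    positions: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One meiosis: haplotype and origin row cut at shared breakpoints.

    Crossover count is Poisson with mean equal to the map length in
    Morgans; breakpoint positions are uniform on the map (no interference).
    """
    map_len = float(positions[-1] - positions[0]) if positions.size else 0.0
    k = rng.poisson(map_len)
    start = rng.integers(2)
    if k == 0:
        return haplopair[start].copy(), originpair[start].copy()
    breaks = np.sort(rng.uniform(positions[0], positions[-1], size=k))
    seg = np.searchsorted(breaks, positions, side="right")
    chrom = (start + seg) & 1
    pick = chrom == 0
    hap = np.where(pick, haplopair[0], haplopair[1])
    orig = np.where(pick, originpair[0], originpair[1])
    return hap.astype(haplopair.dtype), orig.astype(originpair.dtype)


def meiosis(
    parent: Individual, positions: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample one gamete (haplotype row, origin row) from a parent."""
    if parent.haplopair.shape != parent.originpair.shape:
        raise ValueError("haplopair and originpair must have identical shape")
    return _gamete(parent.haplopair, parent.originpair, positions, rng)


def true_exotic_dosage(origin: np.ndarray) -> np.ndarray:
    """Per-individual fraction of allele copies of exotic origin.

    ``origin`` is a ``(2n, m)`` matrix of LOCAL/EXOTIC codes; the result
    has one entry per individual (rows averaged in pairs).
    """
    origin = np.asarray(origin)
    if origin.ndim != 2 or origin.shape[0] % 2 != 0:
        raise ValueError("origin must be a (2n, m) matrix")
    frac = (origin == EXOTIC).mean(axis=1)
    return (frac[0::2] + frac[1::2]) / 2


def select_top_females(cohort: Cohort, n: int) -> np.ndarray:
    """Indices of the ``n`` phenotypically best females (ties by id)."""
    fem = cohort.females()
    if len(fem) < n:
        raise ValueError(f"cohort has {len(fem)} females; cannot select {n}")
    if cohort.phenotype is None:
        raise ValueError("cohort has no phenotypes to select on")
    crit = cohort.phenotype[fem]
    order = np.lexsort((cohort.ids[fem], -crit))
    return fem[order[:n]]


# ---------------------------------------------------------------------------
# program


@dataclass
class ProgramConfig:
    """Parameters of the breeding program."""

    n_premix_generations: int = 10  # random mating among pooled locals
    n_cross_rounds: int = 5
    n_dams: int = 1000  # cows selected / retained per round
    n_bulls: int = 25  # exotic bulls imported per round
    n_offspring: int = 2000  # calves per crossbred cohort (2 per dam)
    n_qtl: int = 100
    h2: float = 0.3
    dd_mean: float = 0.1
    dd_var: float = 0.1
    selection_on: str = "phenotype"  # or "genetic_value"

    def __post_init__(self) -> None:
        if self.n_offspring != 2 * self.n_dams:
            raise ValueError("each dam calves twice: n_offspring must equal 2 * n_dams")
        if self.selection_on not in ("phenotype", "genetic_value"):
            raise ValueError("selection_on must be 'phenotype' or 'genetic_value'")


@dataclass
class ProgramOutput:
    """Everything the assignment stage and the evaluation need."""

    local_purebred: list[Cohort]  # index = generation since founding
    exotic_purebred: list[Cohort]
    crossbred: list[Cohort]  # index r-1 holds CROSSBRED_r
    pedigree: pd.DataFrame  # id, sire, dam, sex, generation
    trait: TraitArchitecture
    positions: np.ndarray

    def truth(self, round_index: int) -> np.ndarray:
        """True origin matrix of crossbred cohort ``round_index`` (1-based)."""
        return self.crossbred[round_index - 1].origin


class _IdCounter:
    def __init__(self) -> None:
        self.next = 0

    def take(self, n: int) -> np.ndarray:
        ids = np.arange(self.next, self.next + n)
        self.next += n
        return ids


def _forced_sexes(n: int, rng: np.random.Generator) -> np.ndarray:
    """Exactly half females, half males, in random order."""
    sexes = np.full(n, MALE, dtype=np.int8)
    sexes[: n // 2] = FEMALE
    rng.shuffle(sexes)
    return sexes


def _founder_cohort(
    haplo: HaploSet, origin_code: int, label: str, ids: _IdCounter, rng: np.random.Generator
) -> Cohort:
    n = haplo.n_individuals
    return Cohort(
        label=label,
        haplo=haplo.haplotypes.copy(),
        origin=np.full(haplo.haplotypes.shape, origin_code, dtype=np.int8),
        sex=_forced_sexes(n, rng),
        ids=ids.take(n),
        sire=np.full(n, -1),
        dam=np.full(n, -1),
    )


def _mate(
    dams: Cohort,
    dam_idx: np.ndarray,
    sires: Cohort,
    sire_idx: np.ndarray,
    positions: np.ndarray,
    label: str,
    ids: _IdCounter,
    rng: np.random.Generator,
) -> Cohort:
    """Produce offspring for given (dam, sire) index pairs (same length)."""
    n = len(dam_idx)
    m = len(positions)
    haplo = np.empty((2 * n, m), dtype=np.uint8)
    origin = np.empty((2 * n, m), dtype=np.int8)
    for j, (di, si) in enumerate(zip(dam_idx, sire_idx)):
        mh, mo = _gamete(
            dams.haplo[2 * di : 2 * di + 2], dams.origin[2 * di : 2 * di + 2], positions, rng
        )
        ph, po = _gamete(
            sires.haplo[2 * si : 2 * si + 2], sires.origin[2 * si : 2 * si + 2], positions, rng
        )
        haplo[2 * j] = mh
        haplo[2 * j + 1] = ph
        origin[2 * j] = mo
        origin[2 * j + 1] = po
    return Cohort(
        label=label,
        haplo=haplo,
        origin=origin,
        sex=_forced_sexes(n, rng),
        ids=ids.take(n),
        sire=sires.ids[sire_idx],
        dam=dams.ids[dam_idx],
    )


def _random_mating(
    parents: Cohort,
    n_offspring: int,
    positions: np.ndarray,
    label: str,
    ids: _IdCounter,
    rng: np.random.Generator,
) -> Cohort:
    fem, mal = parents.females(), parents.males()
    dam_idx = rng.choice(fem, size=n_offspring, replace=True)
    sire_idx = rng.choice(mal, size=n_offspring, replace=True)
    return _mate(parents, dam_idx, parents, sire_idx, positions, label, ids, rng)


def run_program(
    founders: FounderSet,
    cfg: ProgramConfig,
    rng: np.random.Generator,
) -> ProgramOutput:
    """Run the full breeding program on a founder panel.

    Stages: (1) pooled local breeds mate at random for
    ``n_premix_generations``; the exotic breed is propagated in parallel at
    constant size throughout.  (2) The best ``n_dams`` local cows are
    selected on the trait.  (3) For each crossing round, ``n_bulls`` bulls
    are freshly drawn from the contemporary exotic purebred generation and
    mated to the dams (each dam calves twice, sire uniform per mating);
    all female calves become the dams of the next round.
    """
    positions = founders.positions
    ids = _IdCounter()

    local = [_founder_cohort(founders.local_pooled(), LOCAL, "LOCAL_BASE_0", ids, rng)]
    exotic = [_founder_cohort(founders.exotic(), EXOTIC, "EXOTIC_0", ids, rng)]
    pedigree_parts: list[Cohort] = [local[0], exotic[0]]

    total_gens = cfg.n_premix_generations + cfg.n_cross_rounds
    for g in range(1, total_gens + 1):
        exotic.append(
            _random_mating(exotic[-1], exotic[0].n, positions, f"EXOTIC_{g}", ids, rng)
        )
        pedigree_parts.append(exotic[-1])
        if g <= cfg.n_premix_generations:
            local.append(
                _random_mating(local[-1], local[0].n, positions, f"LOCAL_BASE_{g}", ids, rng)
            )
        else:
            local.append(
                _random_mating(local[-1], local[0].n, positions, f"LOCAL_{g}", ids, rng)
            )
        pedigree_parts.append(local[-1])

    # trait and selection of the foundation cows
    trait = sample_trait(
        founders, cfg.n_qtl, cfg.h2, dd_mean=cfg.dd_mean, dd_var=cfg.dd_var, rng=rng
    )
    base = local[cfg.n_premix_generations]
    base.genetic_value = np.asarray(genetic_value(base.haplo, trait))
    base.phenotype = np.asarray(
        phenotype(base.genetic_value, trait.environmental_variance, rng)
    )
    if cfg.selection_on == "genetic_value":
        crit_cohort = Cohort(
            **{**base.__dict__, "phenotype": base.genetic_value}
        )
        dam_idx = select_top_females(crit_cohort, cfg.n_dams)
    else:
        dam_idx = select_top_females(base, cfg.n_dams)

    crossbred: list[Cohort] = []
    dams, dam_pool = base, dam_idx
    for r in range(1, cfg.n_cross_rounds + 1):
        sire_cohort = exotic[cfg.n_premix_generations + r - 1]
        bulls = rng.choice(sire_cohort.males(), size=cfg.n_bulls, replace=False)
        # each dam calves twice; the sire of every mating is drawn uniformly
        dam_seq = np.repeat(dam_pool, 2)
        sire_seq = rng.choice(bulls, size=len(dam_seq), replace=True)
        cohort = _mate(
            dams, dam_seq, sire_cohort, sire_seq, positions, f"CROSSBRED_{r}", ids, rng
        )
        cohort.genetic_value = np.asarray(genetic_value(cohort.haplo, trait))
        cohort.phenotype = np.asarray(
            phenotype(cohort.genetic_value, trait.environmental_variance, rng)
        )
        crossbred.append(cohort)
        pedigree_parts.append(cohort)
        dams, dam_pool = cohort, cohort.females()  # all heifers retained

    pedigree = pd.concat(
        [
            pd.DataFrame(
                {
                    "id": c.ids,
                    "sire": c.sire,
                    "dam": c.dam,
                    "sex": np.where(c.sex == FEMALE, "F", "M"),
                    "generation": c.label,
                }
            )
            for c in pedigree_parts
        ],
        ignore_index=True,
    )
    return ProgramOutput(local, exotic, crossbred, pedigree, trait, positions)
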