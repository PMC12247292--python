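"""Breeding program: trait model, meiosis, selection, origin tracking."""

from dataclasses import replace

import numpy as np
import pytest

from boacall.breeding import (
    FEMALE,
    MALE,
    Cohort,
    Individual,
    genetic_value,
    meiosis,
    phenotype,
    run_program,
    sample_trait,
    select_top_females,
    true_exotic_dosage,
)
from boacall.founders import simulate_founders
from boacall.haplo import EXOTIC, LOCAL

from conftest import tiny_founder_config, tiny_program_config


def arch(qtl, a, d):
    from boacall.breeding import TraitArchitecture

    a = np.asarray(a, dtype=float)
    d = np.asarray(d, dtype=float)
    return TraitArchitecture(
        qtl_indices=np.asarray(qtl),
        additive_effects=a,
        dominance_degrees=np.where(np.abs(a) > 0, d / np.abs(a), 0.0),
        dominance_effects=d,
        environmental_variance=1.0,
    )


# --- genetic value ----------------------------------------------------------


@pytest.mark.parametrize(
    "dosage,expected", [(0, -2.0), (1, 0.5), (2, 2.0)]
)
def test_genetic_value_single_qtl(dosage, expected):
    """a=2, d=0.5: heterozygote scores d, homozygotes score +/-a."""
    hap = np.zeros((2, 3), dtype=np.uint8)
    if dosage >= 1:
        hap[0, 1] = 1
    if dosage == 2:
        hap[1, 1] = 1
    assert genetic_value(hap, arch([1], [2.0], [0.5])) == pytest.approx(expected)


def test_genetic_value_reduces_to_additive_without_dominance():
    rng = np.random.default_rng(0)
    hap = rng.integers(0, 2, size=(8, 20), dtype=np.uint8)
    a = rng.standard_normal(5)
    qtl = [2, 5, 9, 13, 17]
    vals = genetic_value(hap, arch(qtl, a, np.zeros(5)))
    dosage = hap[0::2][:, qtl].astype(int) + hap[1::2][:, qtl]
    np.testing.assert_allclose(vals, (dosage - 1) @ a)


def test_genetic_value_matches_per_locus_summation_oracle():
    rng = np.random.default_rng(3)
    hap = rng.integers(0, 2, size=(6, 30), dtype=np.uint8)
    qtl = sorted(rng.choice(30, 5, replace=False))
    a = rng.standard_normal(5)
    d = rng.standard_normal(5) * 0.3
    vals = genetic_value(hap, arch(qtl, a, d))
    for i in range(3):
        expected = 0.0
        for k, j in enumerate(qtl):
            x = int(hap[2 * i, j]) + int(hap[2 * i + 1, j])
            expected += a[k] * (x - 1) + (d[k] if x == 1 else 0.0)
        assert vals[i] == pytest.approx(expected)


def test_genetic_value_shape_mismatch_raises():
    with pytest.raises(ValueError, match="beyond"):
        genetic_value(np.zeros((2, 3), dtype=np.uint8), arch([10], [1.0], [0.0]))


# --- trait sampling ---------------------------------------------------------


def test_degenerate_dominance_distribution(tiny_founders):
    t = sample_trait(tiny_founders, 10, 0.3, dd_var=0.0, rng=np.random.default_rng(1))
    np.testing.assert_allclose(t.dominance_effects, 0.1 * np.abs(t.additive_effects))


def test_full_locus_set_as_qtl(tiny_founders):
    n = tiny_founders.haplo.n_loci
    t = sample_trait(tiny_founders, n, 0.3, rng=np.random.default_rng(2))
    np.testing.assert_array_equal(t.qtl_indices, np.arange(n))


def test_realized_heritability_near_target(tiny_founders):
    """Genic V_A over realized phenotypic variance ~ 0.3 in the base pop."""
    base = tiny_founders.local_pooled()
    h2s = []
    for s in range(10):
        rng = np.random.default_rng(100 + s)
        t = sample_trait(tiny_founders, 20, 0.3, rng=rng)
        gv = genetic_value(base.haplotypes, t)
        phen = phenotype(gv, t.environmental_variance, rng)
        p = base.haplotypes[:, t.qtl_indices].mean(axis=0)
        alpha = t.additive_effects + t.dominance_effects * (1 - 2 * p)
        var_a = np.sum(2 * p * (1 - p) * alpha**2)
        h2s.append(var_a / np.var(phen))
    assert 0.25 <= np.mean(h2s) <= 0.35


# --- phenotype --------------------------------------------------------------


def test_phenotype_without_noise_is_genetic_value():
    gv = np.array([1.0, -2.0, 0.5])
    np.testing.assert_array_equal(phenotype(gv, 0.0, np.random.default_rng(0)), gv)


def test_phenotype_reproducible_and_unbiased():
    gv = np.random.default_rng(5).normal(0, 2, size=10_000)
    a = phenotype(gv, 1.5, np.random.default_rng(7))
    b = phenotype(gv, 1.5, np.random.default_rng(7))
    np.testing.assert_array_equal(a, b)
    slope = np.polyfit(gv, a, 1)[0]
    se = np.sqrt(1.5 / np.sum((gv - gv.mean()) ** 2))
    assert abs(slope - 1) < 3 * se


# --- meiosis ----------------------------------------------------------------


def _parent(haplopair, originpair):
    return Individual(
        id=0, sex=FEMALE, generation_label="X",
        haplopair=np.asarray(haplopair, dtype=np.uint8),
        originpair=np.asarray(originpair, dtype=np.int8),
    )


def test_meiosis_zero_map_copies_one_chromatid():
    hap = np.array([[0, 0, 0, 0], [1, 1, 1, 1]], dtype=np.uint8)
    orig = np.array([[EXOTIC] * 4, [LOCAL] * 4], dtype=np.int8)
    positions = np.zeros(4)
    g_hap, g_orig = meiosis(_parent(hap, orig), positions, np.random.default_rng(0))
    assert g_hap.tolist() in ([0, 0, 0, 0], [1, 1, 1, 1])
    expected = EXOTIC if g_hap[0] == 0 else LOCAL
    assert set(g_orig) == {expected}


def test_meiosis_origin_cut_at_same_breakpoints_as_haplotype():
    """With distinguishable chromatids the origin row mirrors the haplotype."""
    m = 500
    hap = np.vstack([np.zeros(m, dtype=np.uint8), np.ones(m, dtype=np.uint8)])
    orig = np.vstack([np.full(m, EXOTIC, np.int8), np.full(m, LOCAL, np.int8)])
    positions = np.linspace(0, 1, m)
    rng = np.random.default_rng(13)
    for _ in range(20):
        g_hap, g_orig = meiosis(_parent(hap, orig), positions, rng)
        np.testing.assert_array_equal(
            g_orig, np.where(g_hap == 0, EXOTIC, LOCAL).astype(np.int8)
        )


def test_meiosis_crossover_count_is_poisson_with_map_length_mean():
    m = 1000
    hap = np.vstack([np.zeros(m, dtype=np.uint8), np.ones(m, dtype=np.uint8)])
    orig = np.vstack([np.full(m, EXOTIC, np.int8), np.full(m, LOCAL, np.int8)])
    positions = np.linspace(0, 1, m)
    rng = np.random.default_rng(99)
    parent = _parent(hap, orig)
    switches = 0
    n = 10_000
    for _ in range(n):
        g_hap, _ = meiosis(parent, positions, rng)
        switches += int(np.count_nonzero(np.diff(g_hap)))
    assert 0.97 <= switches / n <= 1.03


# --- selection --------------------------------------------------------------


def _cohort_with_phenotypes(phenos, sexes, ids=None):
    n = len(phenos)
    return Cohort(
        label="T",
        haplo=np.zeros((2 * n, 4), dtype=np.uint8),
        origin=np.zeros((2 * n, 4), dtype=np.int8),
        sex=np.asarray(sexes),
        ids=np.arange(n) if ids is None else np.asarray(ids),
        sire=np.full(n, -1),
        dam=np.full(n, -1),
        phenotype=np.asarray(phenos, dtype=float),
    )


def test_select_all_females_is_identity():
    c = _cohort_with_phenotypes([3.0, 1.0, 2.0], [FEMALE] * 3)
    assert sorted(select_top_females(c, 3)) == [0, 1, 2]


def test_select_single_best_female():
    c = _cohort_with_phenotypes([3.0, 9.0, 2.0, 8.0], [FEMALE, FEMALE, MALE, FEMALE])
    assert select_top_females(c, 1).tolist() == [1]


def test_selection_matches_sort_oracle_with_id_tiebreak():
    rng = np.random.default_rng(8)
    phenos = np.round(rng.normal(size=50), 1)  # rounding forces ties
    c = _cohort_with_phenotypes(phenos, [FEMALE] * 50)
    picked = select_top_females(c, 10)
    oracle = sorted(range(50), key=lambda i: (-phenos[i], i))[:10]
    assert picked.tolist() == oracle


def test_selecting_more_females_than_available_fails():
    c = _cohort_with_phenotypes([1.0, 2.0], [FEMALE, MALE])
    with pytest.raises(ValueError, match="females"):
        select_top_females(c, 2)


# --- whole program ----------------------------------------------------------


def test_program_cohort_structure(tiny_program):
    cfg = tiny_program_config()
    assert len(tiny_program.crossbred) == cfg.n_cross_rounds
    for cohort in tiny_program.crossbred:
        assert cohort.n == cfg.n_offspring
        assert len(cohort.females()) == cfg.n_offspring // 2


def test_f1_has_one_pure_exotic_and_one_pure_local_haplotype(tiny_program):
    f1 = tiny_program.crossbred[0]
    for i in range(f1.n):
        maternal, paternal = f1.origin[2 * i], f1.origin[2 * i + 1]
        assert set(paternal) == {EXOTIC}
        assert set(maternal) == {LOCAL}


def test_true_exotic_dosage_counts_cells():
    rng = np.random.default_rng(1)
    origin = rng.choice([LOCAL, EXOTIC], size=(6, 40)).astype(np.int8)
    frac = true_exotic_dosage(origin)
    for i in range(3):
        expected = (origin[2 * i : 2 * i + 2] == EXOTIC).mean()
        assert frac[i] == pytest.approx(expected)
    assert true_exotic_dosage(np.full((4, 5), EXOTIC, np.int8)).tolist() == [1.0, 1.0]


def test_exotic_dosage_follows_backcross_expectation(tiny_program):
    for g, cohort in enumerate(tiny_program.crossbred, start=1):
        fracs = true_exotic_dosage(cohort.origin)
        expected = 1 - 0.5**g
        se = fracs.std(ddof=1) / np.sqrt(len(fracs))
        assert abs(fracs.mean() - expected) <= max(3 * se, 0.02)


def test_pedigree_closure(tiny_program):
    ped = tiny_program.pedigree
    known = set(ped["id"])
    parents = set(ped["sire"]) | set(ped["dam"])
    parents.discard(-1)
    assert parents <= known


def test_origin_conservation_through_meiosis(tiny_program):
    """Each origin cell of a crossbred equals one parental cell at that locus."""
    dams = tiny_program.crossbred[0]
    off = tiny_program.crossbred[1]
    dam_index = {int(i): k for k, i in enumerate(dams.ids)}
    for i in range(off.n):
        k = dam_index[int(off.dam[i])]
        maternal = off.origin[2 * i]
        d0, d1 = dams.origin[2 * k], dams.origin[2 * k + 1]
        assert np.all((maternal == d0) | (maternal == d1))
        assert set(off.origin[2 * i + 1]) == {EXOTIC}  # sire is purebred exotic


def test_selection_beats_random_choice_on_genetic_value(tiny_founders):
    wins = 0
    for s in range(10):
        rng = np.random.default_rng(400 + s)
        t = sample_trait(tiny_founders, 20, 0.3, rng=rng)
        base = tiny_founders.local_pooled()
        gv = genetic_value(base.haplotypes, t)
        phen = phenotype(gv, t.environmental_variance, rng)
        n = len(gv)
        c = _cohort_with_phenotypes(phen, [FEMALE] * n)
        picked = select_top_females(c, 20)
        random_pick = rng.choice(n, 20, replace=False)
        wins += gv[picked].mean() > gv[random_pick].mean()
    assert wins >= 9
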