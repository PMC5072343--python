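"""EM haplotype-frequency estimation and LD statistics."""

import numpy as np
import pytest

import hornscan as hs
from hornscan.ld import log_likelihood


def table(entries):
    tab = np.zeros((3, 3))
    for (i, j), n in entries.items():
        tab[i, j] = n
    return hs.TwoLocusCounts(tab)


def grid_search_ml(counts, grid=1e-4):
    """Independent brute-force ML oracle.

    Allele margins are preserved by every EM step, so the ML solution lies on
    the one-dimensional family indexed by p_AB; profile the multinomial
    likelihood over that family on a fine grid with explicit class-probability
    formulas.
    """
    c = counts.counts
    n = c.sum()
    pa = (c.sum(axis=1) @ [0, 1, 2]) / (2 * n)   # second-allele freq, locus 1
    pb = (c.sum(axis=0) @ [0, 1, 2]) / (2 * n)
    pA, pB = 1 - pa, 1 - pb
    lo = max(0.0, pA + pB - 1.0)
    hi = min(pA, pB)
    pAB = np.arange(lo, hi + grid / 2, grid)
    pAb = pA - pAB
    paB = pB - pAB
    pab = 1.0 - pAB - pAb - paB
    ok = (pAb > -1e-12) & (paB > -1e-12) & (pab > -1e-12)
    pAB, pAb, paB, pab = (np.clip(x[ok], 0, 1) for x in (pAB, pAb, paB, pab))
    probs = np.stack([  # closed-form class probabilities, one row per grid point
        pAB**2, 2 * pAB * pAb, pAb**2,
        2 * pAB * paB, 2 * (pAB * pab + pAb * paB), 2 * pAb * pab,
        paB**2, 2 * paB * pab, pab**2,
    ], axis=1)
    weights = c.reshape(-1)
    with np.errstate(divide="ignore"):
        ll = np.where(weights > 0,
                      weights * np.log(np.clip(probs, 1e-300, None)), 0.0).sum(axis=1)
    best = int(np.argmax(ll))
    return np.array([pAB[best], pAb[best], paB[best], pab[best]]), float(ll[best])


class TestEmHaplotypes:
    def test_unambiguous_phase(self):
        h = hs.em_haplotypes(table({(0, 0): 4, (2, 2): 4}))
        assert h["AB"] == pytest.approx(0.5, abs=1e-9)
        assert h["ab"] == pytest.approx(0.5, abs=1e-9)
        assert h["Ab"] == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_fixture_matches_grid_oracle(self):
        counts = table({(0, 0): 4, (1, 1): 2, (2, 2): 4})
        h = hs.em_haplotypes(counts)
        oracle, _ = grid_search_ml(counts, grid=1e-3)
        em_r2 = hs.ld_stats(h).r2
        pAB, pAb, paB, pab = oracle
        pA, pB = pAB + pAb, pAB + paB
        oracle_r2 = (pAB - pA * pB) ** 2 / (pA * (1 - pA) * pB * (1 - pB))
        assert em_r2 == pytest.approx(oracle_r2, abs=1e-3)
        assert h["AB"] == pytest.approx(pAB, abs=1e-3)

    def test_independent_loci_give_near_zero_d(self):
        # genotypes sampled as products of marginals, n = 400
        rng = np.random.default_rng(21)
        d1 = rng.binomial(2, 0.3, size=400)
        d2 = rng.binomial(2, 0.6, size=400)
        h = hs.em_haplotypes(hs.TwoLocusCounts.from_dosages(d1, d2))
        s = hs.ld_stats(h)
        # SE(D) ~ sqrt(pA qA pB qB / n)
        se = np.sqrt(0.3 * 0.7 * 0.6 * 0.4 / 400)
        assert abs(s.D) < 2 * se

    def test_log_likelihood_nondecreasing(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            c = hs.TwoLocusCounts(rng.integers(0, 6, size=(3, 3)).astype(float))
            try:
                pa, pb = c.allele_freqs()
                if pa in (0, 1) or pb in (0, 1):
                    continue
            except hs.InputError:
                continue
            lls = []
            # re-run EM step by step via increasing max_iter
            for it in range(1, 15):
                h = hs.em_haplotypes(c, tol=0.0, max_iter=it)
                lls.append(h.log_likelihood)
            assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_allele_label_swap_invariance(self):
        rng = np.random.default_rng(11)
        c = rng.integers(0, 8, size=(3, 3)).astype(float)
        counts = hs.TwoLocusCounts(c)
        swapped = hs.TwoLocusCounts(c[::-1, :].copy())  # swap alleles at locus 1
        s = hs.ld_stats(hs.em_haplotypes(counts))
        s_sw = hs.ld_stats(hs.em_haplotypes(swapped))
        assert s.r2 == pytest.approx(s_sw.r2, abs=1e-8)
        assert abs(s.D_prime) == pytest.approx(abs(s_sw.D_prime), abs=1e-8)
        assert s.D == pytest.approx(-s_sw.D, abs=1e-8)

    def test_monomorphic_locus_rejected(self):
        with pytest.raises(hs.InputError, match="monomorphic"):
            hs.em_haplotypes(table({(0, 0): 5, (0, 2): 5}))

    def test_agrees_with_grid_oracle_on_random_tables(self):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 50:
            hap = rng.dirichlet([1, 1, 1, 1])
            n = int(rng.integers(8, 31))
            draws = rng.choice(4, size=2 * n, p=hap)
            d1 = (draws >= 2).reshape(n, 2).sum(axis=1)
            d2 = (draws % 2).reshape(n, 2).sum(axis=1)
            counts = hs.TwoLocusCounts.from_dosages(d1, d2)
            pa, pb = counts.allele_freqs()
            if pa in (0.0, 1.0) or pb in (0.0, 1.0):
                continue
            em = hs.ld_stats(hs.em_haplotypes(counts))
            oracle, oracle_ll = grid_search_ml(counts)
            pAB, pAb, paB, pab = oracle
            pA, pB = pAB + pAb, pAB + paB
            oracle_r2 = (pAB - pA * pB) ** 2 / (pA * (1 - pA) * pB * (1 - pB))
            assert em.r2 == pytest.approx(oracle_r2, abs=1e-3)
            checked += 1


class TestLdStats:
    def test_complete_ld(self):
        h = hs.HaplotypeFreqs({"AB": 0.5, "Ab": 0.0, "aB": 0.0, "ab": 0.5}, 0.0, 1)
        s = hs.ld_stats(h)
        assert (s.D, s.D_prime, s.r2) == pytest.approx((0.25, 1.0, 1.0))

    def test_equilibrium_has_zero_d(self):
        h = hs.HaplotypeFreqs({"AB": 0.12, "Ab": 0.28, "aB": 0.18, "ab": 0.42}, 0.0, 1)
        s = hs.ld_stats(h)
        assert s.D == pytest.approx(0.0, abs=1e-12)
        assert s.r2 == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_hand_evaluation(self):
        h = hs.HaplotypeFreqs({"AB": 0.4, "Ab": 0.1, "aB": 0.1, "ab": 0.4}, 0.0, 1)
        s = hs.ld_stats(h)
        assert s.D == pytest.approx(0.15)
        assert s.r2 == pytest.approx(0.36)

    def test_fixed_allele_rejected(self):
        h = hs.HaplotypeFreqs({"AB": 0.6, "Ab": 0.4, "aB": 0.0, "ab": 0.0}, 0.0, 1)
        with pytest.raises(hs.InputError):
            hs.ld_stats(h)

    def test_r2_consistent_with_invariant(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            freqs = rng.dirichlet([2, 2, 2, 2])
            h = hs.HaplotypeFreqs(dict(zip(hs.HAPLOTYPES, freqs)), 0.0, 1)
            s = hs.ld_stats(h)
            assert s.r2 == pytest.approx(
                s.D ** 2 / (s.pA * (1 - s.pA) * s.pB * (1 - s.pB)))
            assert abs(s.D_prime) <= 1.0 + 1e-9


class TestGroupedR2:
    def test_printed_group_values_give_published_ratio(self):
        assert hs.r2_ratio(0.635, 0.194) == 3.27

    def test_identical_groups_ratio_one(self):
        panel = hs.synth_breed_panel(hs.BreedCategory.variable, 40, 40, seed=2)
        for rec in panel:
            d = rec.genotypes["ins1780"].count("der")
            # second marker in perfect LD with the insertion
            alleles = tuple(sorted(["A"] * d + ["G"] * (2 - d)))
            rec.genotypes["OAR10_29511510.1"] = hs.Genotype(
                "OAR10_29511510.1", alleles)
        grouping = {"g1": [panel[0].breed], "g2": [panel[0].breed]}
        stats, ratio = hs.grouped_r2(panel, "ins1780", "OAR10_29511510.1",
                                     grouping, allele1="der", allele2="A",
                                     ratio_groups=("g1", "g2"))
        assert ratio == 1.0
        assert stats["g1"].r2 == pytest.approx(1.0)

    def test_monomorphic_group_skipped(self):
        panel = hs.synth_breed_panel(hs.BreedCategory.completely_horned, 10, 10,
                                     seed=1, breed="fixed")
        for rec in panel:
            rec.genotypes["OAR10_29511510.1"] = hs.Genotype(
                "OAR10_29511510.1", ("A", "G"))
        stats, ratio = hs.grouped_r2(panel, "ins1780", "OAR10_29511510.1",
                                     {"fixed": ["fixed"]},
                                     allele1="der", allele2="A",
                                     ratio_groups=("fixed", "fixed"))
        assert stats == {} and ratio is None

    def test_denominator_floor_guard(self):
        assert hs.r2_ratio(0.5, 0.0) == pytest.approx(0.5 / 1e-12)
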