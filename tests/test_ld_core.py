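import itertools
import math

import numpy as np
import pytest

from lrldkit.errors import EmptyTableError, MonomorphicLocusError
from lrldkit.genotype_io import MISSING
from lrldkit.ld_core import (
    HaplotypeFreqs,
    TwoLocusTable,
    chi2_upper_tail_p,
    em_haplotype_freqs,
    ld_from_haplofreqs,
    ld_pair,
    ld_prune,
    two_locus_table,
)
from tests.conftest import make_dataset


def hf(pAB, pAb, paB, pab):
    return HaplotypeFreqs(pAB, pAb, paB, pab, math.nan, 0, True)


def grid_search_mle(counts, coarse=0.01, fine=0.001):
    """Brute-force likelihood grid search over the haplotype simplex.

    Coarse pass at ``coarse`` resolution over (pAB, pAb, paB), then a
    fine pass at ``fine`` resolution in a +/- coarse box around the
    coarse optimum. Independent of the EM implementation.
    """
    counts = np.asarray(counts, dtype=float)

    def loglik_vec(pAB, pAb, paB, pab):
        probs = np.stack(
            [
                pab * pab, 2 * paB * pab, paB * paB,
                2 * pAb * pab, 2 * (pAB * pab + pAb * paB), 2 * pAB * paB,
                pAb * pAb, 2 * pAB * pAb, pAB * pAB,
            ],
            axis=-1,
        )
        flat = counts.ravel()
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(flat > 0, flat * np.log(probs), 0.0)
        terms = np.where((probs <= 0) & (flat > 0), -np.inf, terms)
        return terms.sum(axis=-1)

    def best_on(axes):
        a, b, c = np.meshgrid(*axes, indexing="ij")
        a, b, c = a.ravel(), b.ravel(), c.ravel()
        d = 1.0 - a - b - c
        ok = d >= -1e-12
        a, b, c, d = a[ok], b[ok], c[ok], np.clip(d[ok], 0.0, 1.0)
        ll = loglik_vec(a, b, c, d)
        k = int(np.argmax(ll))
        return a[k], b[k], c[k], d[k]

    step = np.arange(0.0, 1.0 + coarse / 2, coarse)
    p0 = best_on((step, step, step))
    axes = tuple(
        np.clip(np.arange(x - coarse, x + coarse + fine / 2, fine), 0.0, 1.0)
        for x in p0[:3]
    )
    return best_on(axes)


class TestTwoLocusTable:
    def test_all_double_reference(self):
        ds = make_dataset([[0, 0]] * 7)
        t = two_locus_table(ds, "rs1", "rs2")
        assert t.counts[0, 0] == 7 and t.counts.sum() == 7

    def test_missing_excluded(self):
        ds = make_dataset(
            [[0, 0], [1, 1], [2, MISSING], [1, 0], [0, 2], [2, 2]]
        )
        t = two_locus_table(ds, "rs1", "rs2")
        assert t.n_samples == 5

    def test_matches_hand_tally(self, rng):
        calls = rng.integers(-1, 3, size=(50, 2)).astype(np.int8)
        ds = make_dataset(calls)
        t = two_locus_table(ds, "rs1", "rs2")
        for i in range(3):
            for j in range(3):
                expected = sum(
                    1
                    for a, b in calls
                    if a == i and b == j
                )
                assert t.counts[i, j] == expected

    def test_empty_raises(self):
        ds = make_dataset([[0, MISSING], [MISSING, 1]])
        with pytest.raises(EmptyTableError):
            two_locus_table(ds, "rs1", "rs2")


class TestEM:
    def test_no_double_het_equals_gamete_counts(self):
        counts = [[10, 5, 0], [3, 0, 2], [1, 0, 4]]
        t = TwoLocusTable.from_counts(counts)
        h = em_haplotype_freqs(t)
        assert h.converged and h.n_iter == 1
        n = np.asarray(counts)
        denom = 2.0 * n.sum()
        kAB = 2 * n[2, 2] + n[2, 1] + n[1, 2]
        kAb = 2 * n[2, 0] + n[2, 1] + n[1, 0]
        kaB = 2 * n[0, 2] + n[0, 1] + n[1, 2]
        kab = 2 * n[0, 0] + n[0, 1] + n[1, 0]
        assert h.pAB == pytest.approx(kAB / denom)
        assert h.pAb == pytest.approx(kAb / denom)
        assert h.paB == pytest.approx(kaB / denom)
        assert h.pab == pytest.approx(kab / denom)

    def test_perfect_coupling(self):
        t = TwoLocusTable.from_counts([[75, 0, 0], [0, 0, 0], [0, 0, 25]])
        h = em_haplotype_freqs(t)
        assert h.pAB == pytest.approx(0.25)
        assert h.pab == pytest.approx(0.75)
        assert h.pAb == pytest.approx(0.0)
        assert h.paB == pytest.approx(0.0)

    def test_all_double_het_stays_on_ridge(self):
        t = TwoLocusTable.from_counts([[0, 0, 0], [0, 40, 0], [0, 0, 0]])
        h = em_haplotype_freqs(t)
        for f in (h.pAB, h.pAb, h.paB, h.pab):
            assert f == pytest.approx(0.25, abs=1e-9)
        # 0.25^4 is an EM fixed point (the deterministic D=0 resolution of
        # the phase-ambiguity symmetry); the likelihood also has two
        # symmetric global maxima at the D = +/-Dmax corners, which the
        # LE start deliberately does not select
        assert h.loglik == pytest.approx(40 * math.log(0.25))
        g = grid_search_mle(t.counts)
        ll_grid = 40 * math.log(2 * (g[0] * g[3] + g[1] * g[2]))
        assert ll_grid == pytest.approx(40 * math.log(0.5), abs=1e-3)

    def test_monomorphic_raises(self):
        t = TwoLocusTable.from_counts([[5, 3, 2], [0, 0, 0], [0, 0, 0]])
        with pytest.raises(MonomorphicLocusError):
            em_haplotype_freqs(t)

    def test_loglik_monotone_and_sums_to_one(self, rng):
        for _ in range(25):
            freqs = rng.dirichlet(np.ones(4))
            cells = _cell_probs(hf(*freqs))
            counts = rng.multinomial(60, cells.ravel()).reshape(3, 3)
            try:
                trace = []
                h = em_haplotype_freqs(
                    TwoLocusTable.from_counts(counts), trace=trace
                )
            except MonomorphicLocusError:
                continue
            assert sum((h.pAB, h.pAb, h.paB, h.pab)) == pytest.approx(1.0, abs=1e-12)
            diffs = np.diff(trace)
            assert (diffs >= -1e-9).all()

    def test_marginals_match_table(self, rng):
        for _ in range(10):
            counts = rng.multinomial(50, np.ones(9) / 9).reshape(3, 3)
            t = TwoLocusTable.from_counts(counts)
            try:
                h = em_haplotype_freqs(t)
            except MonomorphicLocusError:
                continue
            n = t.counts
            pA = (2 * n[2, :].sum() + n[1, :].sum()) / (2 * t.n_samples)
            pB = (2 * n[:, 2].sum() + n[:, 1].sum()) / (2 * t.n_samples)
            assert h.pA == pytest.approx(pA, abs=1e-9)
            assert h.pB == pytest.approx(pB, abs=1e-9)


def _cell_probs(h):
    """Genotype cell probabilities under random mating, cell (i, j)."""
    hap = np.array([[h.pab, h.paB], [h.pAb, h.pAB]])  # [a_count][b_count]
    cells = np.zeros((3, 3))
    for (a1, b1), (a2, b2) in itertools.product(
        itertools.product(range(2), range(2)), repeat=2
    ):
        cells[a1 + a2, b1 + b2] += hap[a1, b1] * hap[a2, b2]
    return cells


class TestLDFromHaplofreqs:
    def test_independence(self):
        h = hf(0.12, 0.18, 0.28, 0.42)  # pA=0.3, pB=0.4, pAB=pA*pB
        ld = ld_from_haplofreqs(h, 100)
        assert ld.D == pytest.approx(0.0, abs=1e-15)
        assert ld.dprime == 0.0
        assert ld.r2 == pytest.approx(0.0, abs=1e-15)
        assert ld.p == pytest.approx(1.0)

    def test_perfect_coupling_closed_form(self):
        ld = ld_from_haplofreqs(hf(0.25, 0.0, 0.0, 0.75), 100)
        assert ld.D == pytest.approx(0.1875)
        assert ld.dprime == pytest.approx(1.0)
        assert ld.r2 == pytest.approx(1.0)

    def test_apoe_like_absent_tt_haplotype(self):
        # pA=0.14, pB=0.07, pAB=0 -> D' = -1, as for rs429358-rs7412
        h = hf(0.0, 0.14, 0.07, 0.79)
        ld = ld_from_haplofreqs(h, 1000)
        assert ld.dprime == pytest.approx(-1.0)

    def test_chi2_is_2nr2(self):
        h = hf(0.2, 0.2, 0.1, 0.5)
        ld = ld_from_haplofreqs(h, 500)
        assert ld.chi2 == pytest.approx(2 * 500 * ld.r2)

    def test_r2_identity_and_dprime_bound(self, rng):
        for _ in range(50):
            freqs = rng.dirichlet(np.ones(4))
            h = hf(*freqs)
            if min(h.pA, 1 - h.pA, h.pB, 1 - h.pB) < 1e-6:
                continue
            ld = ld_from_haplofreqs(h, 100)
            qA, qB = 1 - h.pA, 1 - h.pB
            assert ld.r2 * (h.pA * qA * h.pB * qB) == pytest.approx(
                ld.D**2, abs=1e-12
            )
            assert abs(ld.dprime) <= 1 + 1e-12
            assert math.copysign(1, ld.dprime) == math.copysign(1, ld.D) or ld.D == 0

    def test_monomorphic_raises(self):
        with pytest.raises(MonomorphicLocusError):
            ld_from_haplofreqs(hf(0.0, 0.0, 0.3, 0.7), 10)


class TestLDPair:
    def test_self_pair_perfect(self, rng):
        g = rng.integers(0, 3, size=100).astype(np.int8)
        ds = make_dataset(np.column_stack([g, g]))
        ld = ld_pair(ds, "rs1", "rs2")
        assert ld.dprime == pytest.approx(1.0)
        assert ld.r2 == pytest.approx(1.0)

    def test_allele_relabel_equivariance(self, rng):
        calls = rng.integers(0, 3, size=(80, 2)).astype(np.int8)
        ds = make_dataset(calls)
        flipped = make_dataset(np.column_stack([2 - calls[:, 0], calls[:, 1]]))
        a = ld_pair(ds, "rs1", "rs2")
        b = ld_pair(flipped, "rs1", "rs2")
        assert b.D == pytest.approx(-a.D, abs=1e-9)
        assert b.dprime == pytest.approx(-a.dprime, abs=1e-6)
        assert b.r2 == pytest.approx(a.r2, abs=1e-9)
        assert b.chi2 == pytest.approx(a.chi2, abs=1e-6)
        assert b.p == pytest.approx(a.p, abs=1e-9)

    def test_simulated_dprime_recovered(self, rng):
        # 200 replicates at n=5000 from known haplotype frequencies
        truth = hf(*_haplofreqs(0.3, 0.3, 0.5))
        true_dp = ld_from_haplofreqs(truth, 1).dprime
        cells = _cell_probs(truth).ravel()
        est = []
        for _ in range(200):
            counts = rng.multinomial(5000, cells).reshape(3, 3)
            h = em_haplotype_freqs(TwoLocusTable.from_counts(counts))
            est.append(ld_from_haplofreqs(h, 5000).dprime)
        est = np.asarray(est)
        # MC SE = replicate SD; the finite-n bias of D'-hat (~0.004 here,
        # O(1/sqrt(n))) rules out a SD/sqrt(R) tolerance on the mean
        assert abs(est.mean() - true_dp) < 3 * est.std(ddof=1)
        assert abs(est.mean() - true_dp) < 0.01


def _haplofreqs(mafA, mafB, dprime):
    from lrldkit.synthetic_data import haplofreqs_from_dprime

    h = haplofreqs_from_dprime(mafA, mafB, dprime)
    return h.pAB, h.pAb, h.paB, h.pab


class TestEMGridOracle:
    @pytest.mark.parametrize("seed", range(20))
    def test_em_matches_grid(self, seed):
        rng = np.random.default_rng(1000 + seed)
        freqs = rng.dirichlet(np.ones(4) * 2)
        counts = rng.multinomial(
            int(rng.integers(20, 61)), _cell_probs(hf(*freqs)).ravel()
        ).reshape(3, 3)
        t = TwoLocusTable.from_counts(counts)
        try:
            h = em_haplotype_freqs(t)
        except MonomorphicLocusError:
            return
        g = grid_search_mle(counts)
        for em_f, grid_f in zip((h.pAB, h.pAb, h.paB, h.pab), g):
            assert abs(em_f - grid_f) <= 2e-3


class TestChi2UpperTail:
    def test_zero_statistic(self):
        assert chi2_upper_tail_p(0.0, 1) == 1.0

    def test_quantile_inversion(self):
        assert chi2_upper_tail_p(3.841459, 1) == pytest.approx(0.05, abs=1e-6)

    def test_monotone_decreasing(self):
        xs = np.linspace(0, 50, 200)
        ps = [chi2_upper_tail_p(x, 1) for x in xs]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            chi2_upper_tail_p(-0.1, 1)


class TestLDPrune:
    def test_independent_markers_all_retained(self, rng):
        calls = rng.integers(0, 3, size=(200, 8)).astype(np.int8)
        ds = make_dataset(calls)
        # independent draws: sample pairwise r2 all << 0.3 at n=200 w.h.p.
        kept = ld_prune(ds, r2_max=0.9)
        assert kept == [m.id for m in ds.markers]

    def test_duplicate_column_pruned(self, rng):
        g = rng.integers(0, 3, size=100).astype(np.int8)
        other = rng.integers(0, 3, size=100).astype(np.int8)
        ds = make_dataset(np.column_stack([g, g, other]))
        kept = ld_prune(ds, r2_max=0.3)
        assert kept == ["rs1", "rs3"]

    def test_matches_greedy_oracle(self, rng):
        base = rng.integers(0, 3, size=(120, 20)).astype(np.int8)
        # correlate some neighbours
        for j in (3, 7, 11):
            copy_mask = rng.random(120) < 0.9
            base[copy_mask, j] = base[copy_mask, j - 1]
        ds = make_dataset(base)

        def oracle(window, step, r2_max):
            removed = set()
            start = 0
            n = ds.n_markers
            while True:
                idx = [j for j in range(start, min(start + window, n))]
                for a in idx:
                    for b in idx:
                        if a < b and a not in removed and b not in removed:
                            try:
                                r2 = ld_pair(
                                    ds, ds.markers[a].id, ds.markers[b].id
                                ).r2
                            except MonomorphicLocusError:
                                continue
                            if r2 > r2_max:
                                removed.add(b)
                if start + window >= n:
                    break
                start += step
            return [m.id for j, m in enumerate(ds.markers) if j not in removed]

        assert ld_prune(ds, 0.3, window_markers=6, step_markers=2) == oracle(6, 2, 0.3)
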