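import math

import numpy as np
import pytest

from paralogpace.io_formats import GeneTrio
from paralogpace.rate_estimator import (
    PairwiseRates, assign_fast_slow, decompose_branches, ng86_pairwise,
    trio_rates, yn00_pairwise,
)
from paralogpace.synthetic_data import TrioSimConfig, TrioSimulator

from ng86_oracle import ng86_brute_force
from conftest import diverged_pair, random_codon_seq


def rates(dn, ds, **kw):
    omega = float("nan") if ds <= 0 else dn / ds
    return PairwiseRates(dN=dn, dS=ds, omega=omega, S_sites=100, N_sites=200,
                         codons_used=100, **kw)


class TestNG86:
    def test_identical_sequences_zero(self, rng):
        s = random_codon_seq(rng, 50)
        r = ng86_pairwise(s, s)
        assert r.dN == r.dS == 0.0
        assert not r.omega_defined
        assert r.S_sites + r.N_sites == pytest.approx(3 * r.codons_used)

    def test_purely_synonymous_differences(self):
        # 60 codons; three third-position synonymous transversions:
        # GGT->GGA (Gly), CCT->CCA (Pro), GTT->GTA (Val)
        base = ["GGT", "CCT", "GTT"] + ["GGC"] * 57
        other = ["GGA", "CCA", "GTA"] + ["GGC"] * 57
        s1, s2 = "".join(base), "".join(other)
        r = ng86_pairwise(s1, s2)
        dn, ds, S, N, n = ng86_brute_force(s1, s2)
        assert r.dN == 0.0
        assert r.dS == pytest.approx(ds, abs=1e-12)
        assert r.S_sites == pytest.approx(S, abs=1e-12)

    def test_purely_nonsynonymous_differences(self):
        s1 = "ATG" + "AAA" * 20   # Lys
        s2 = "ATG" + "GAA" * 20   # Glu (first-position, nonsynonymous)
        r = ng86_pairwise(s1, s2)
        assert r.dS == 0.0
        assert not r.omega_defined

    def test_agrees_with_brute_force_oracle(self, rng):
        for _ in range(50):
            s1 = random_codon_seq(rng, 60)
            s2 = random_codon_seq(rng, 60)
            dn, ds, S, N, n = ng86_brute_force(s1, s2)
            r = ng86_pairwise(s1, s2)
            assert r.codons_used == n
            assert r.S_sites == pytest.approx(S, abs=1e-10)
            assert r.N_sites == pytest.approx(N, abs=1e-10)
            if not math.isnan(ds):
                assert r.dS == pytest.approx(ds, abs=1e-10)
            if not math.isnan(dn):
                assert r.dN == pytest.approx(dn, abs=1e-10)

    def test_symmetric(self, rng):
        s1, s2 = diverged_pair(rng, 80, 40)
        r1, r2 = ng86_pairwise(s1, s2), ng86_pairwise(s2, s1)
        assert r1.dS == r2.dS and r1.dN == r2.dN

    def test_duplication_invariance(self, rng):
        s1, s2 = diverged_pair(rng, 60, 30)
        r1 = ng86_pairwise(s1, s2)
        r2 = ng86_pairwise(s1 + s1, s2 + s2)
        assert r2.dS == pytest.approx(r1.dS, abs=1e-12)
        assert r2.dN == pytest.approx(r1.dN, abs=1e-12)

    def test_gap_and_n_codons_deleted_pairwise(self):
        s1 = "ATGAAA" + "---"
        s2 = "ATGAAG" + "CCC"
        r = ng86_pairwise(s1, s2)
        assert r.codons_used == 2

    def test_all_missing_raises(self):
        with pytest.raises(ValueError):
            ng86_pairwise("---", "ATG")


class TestYN00:
    def test_identical_sequences_zero(self, rng):
        s = random_codon_seq(rng, 50)
        r = yn00_pairwise(s, s)
        assert r.dN == r.dS == 0.0 and not r.omega_defined

    def test_symmetric(self, rng):
        s1, s2 = diverged_pair(rng, 100, 45)
        r1, r2 = yn00_pairwise(s1, s2), yn00_pairwise(s2, s1)
        assert r1.dS == pytest.approx(r2.dS, abs=1e-9)
        assert r1.dN == pytest.approx(r2.dN, abs=1e-9)

    def test_duplication_invariance(self, rng):
        s1, s2 = diverged_pair(rng, 80, 35)
        r1 = yn00_pairwise(s1, s2)
        r2 = yn00_pairwise(s1 + s1, s2 + s2)
        assert r2.dS == pytest.approx(r1.dS, abs=1e-9)
        assert r2.dN == pytest.approx(r1.dN, abs=1e-9)

    def test_site_partition(self, rng):
        s1, s2 = diverged_pair(rng, 90, 40)
        r = yn00_pairwise(s1, s2)
        assert r.S_sites + r.N_sites == pytest.approx(3 * r.codons_used)

    def test_agrees_with_ng86_in_no_bias_limit(self):
        """With kappa = 1 and uniform codon frequencies the two estimators
        should coincide closely at moderate divergence."""
        cfg = TrioSimConfig(
            n_trios=1, n_codons=2000, kappa=1.0,
            branch_dS={"OA": 0.1, "OB": 0.1, "OC": 0.1},
            branch_omega={"OA": 0.3, "OB": 0.3, "OC": 0.3}, seed=5,
        )
        sim = TrioSimulator(cfg)
        rng = np.random.default_rng(5)
        n_ok = 0
        for k in range(20):
            trio, _ = sim.simulate(rng, k)
            y, g = yn00_pairwise(trio.A, trio.B), ng86_pairwise(trio.A, trio.B)
            if abs(y.dS - g.dS) < 0.01 and abs(y.dN - g.dN) < 0.01:
                n_ok += 1
        assert n_ok >= 19

    def test_kappa_recovered_from_biased_data(self):
        cfg = TrioSimConfig(
            n_trios=1, n_codons=4000, kappa=4.0,
            branch_dS={"OA": 0.2, "OB": 0.2, "OC": 0.2},
            branch_omega={"OA": 0.2, "OB": 0.2, "OC": 0.2}, seed=9,
        )
        trio, _ = TrioSimulator(cfg).simulate(np.random.default_rng(9), 0)
        r = yn00_pairwise(trio.A, trio.B)
        assert 2.5 < r.kappa < 6.0


class TestDecomposition:
    def test_paper_style_arithmetic(self):
        br = decompose_branches(rates(0.02, 0.192), rates(0.04, 0.434),
                                rates(0.04, 0.434))
        assert br.dS_OA == pytest.approx(0.096)
        assert br.dS_OB == pytest.approx(0.096)
        assert br.dS_OC == pytest.approx(0.338)

    def test_symmetric_inputs_halved(self):
        br = decompose_branches(rates(0.01, 0.2), rates(0.01, 0.2), rates(0.01, 0.2))
        for v in (br.dS_OA, br.dS_OB, br.dS_OC):
            assert v == pytest.approx(0.1)

    def test_negative_branch_preserved(self):
        br = decompose_branches(rates(0.0, 0.05), rates(0.0, 0.40), rates(0.0, 0.48))
        assert br.dS_OA == pytest.approx(-0.015)
        assert math.isnan(br.omega_OA)  # dS <= 0 -> undefined omega

    def test_additivity_identities_random(self, rng):
        for _ in range(1000):
            ab, ac, bc = rng.random(3)
            nab, nac, nbc = rng.random(3)
            br = decompose_branches(rates(nab, ab), rates(nac, ac), rates(nbc, bc))
            assert abs(br.dS_OA + br.dS_OB - ab) < 1e-12
            assert abs(br.dS_OA + br.dS_OC - ac) < 1e-12
            assert abs(br.dS_OB + br.dS_OC - bc) < 1e-12
            assert abs(br.dN_OA + br.dN_OB - nab) < 1e-12

    def test_saturation_propagates(self):
        sat = rates(0.1, float("nan"))
        sat.saturated = True
        br = decompose_branches(sat, rates(0.01, 0.2), rates(0.01, 0.2))
        assert br.saturated


class TestFastSlow:
    def _branches(self, w_oa, w_ob):
        br = decompose_branches(rates(0.02, 0.2), rates(0.02, 0.3), rates(0.02, 0.3))
        br.omega_OA, br.omega_OB = w_oa, w_ob
        return br

    def test_lower_omega_is_slow(self):
        br = assign_fast_slow(self._branches(0.08, 0.21))
        assert (br.slow_branch, br.fast_branch) == ("OA", "OB")
        assert br.fold_change == pytest.approx(0.21 / 0.08)

    def test_tie_goes_to_oa(self):
        br = assign_fast_slow(self._branches(0.1, 0.1))
        assert br.slow_branch == "OA" and br.fold_change == 1.0

    def test_undefined_omega_propagates(self):
        br = assign_fast_slow(self._branches(0.1, float("nan")))
        assert br.slow_branch is None and math.isnan(br.fold_change)

    def test_zero_slow_gives_infinite_fold(self):
        br = assign_fast_slow(self._branches(0.0, 0.2))
        assert br.fold_change == math.inf


class TestTrioRates:
    def test_complete_deletion_and_additivity(self, small_trio_set):
        _, trios, _ = small_trio_set
        res = trio_rates(trios[0], method="yn00")
        br, ab, ac, bc = (res["branches"], res["pair_AB"], res["pair_AC"],
                          res["pair_BC"])
        assert ab.codons_used == ac.codons_used == bc.codons_used
        assert br.dS_OA + br.dS_OB == pytest.approx(ab.dS, abs=1e-12)
        assert br.dN_OA + br.dN_OC == pytest.approx(ac.dN, abs=1e-12)

    def test_gapped_columns_excluded_for_all_pairs(self):
        trio = GeneTrio(query_id="q", a_id="a", b_id="b", c_id="c",
                        A="ATGAAACCC", B="ATG---CCC", C="ATGAAACCG")
        res = trio_rates(trio, method="ng86")
        assert res["pair_AC"].codons_used == 2  # gap column dropped everywhere
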