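import numpy as np
import pytest
from hypothesis import given, strategies as st

from splicewave.genome import GeneModel, Intron
from splicewave.kinetics import (
    MoleculeState,
    RateSet,
    cleavage_before_splicing_prob,
    cleavage_prob_mc,
    expected_coverage,
    monte_carlo_coverage,
    predicted_cassette_psi,
    simulate_molecules,
    time_to_transcribe,
)


def intronless(L=10000):
    return GeneModel("g", "+", L, exons=[(0, L)], introns=[])


class TestExpectedCoverage:
    def test_linear_ramp_before_wave_reaches_tes(self):
        # exonic position, no polymerase at the TES yet: coverage = sigma*(t - x/v)
        rs = RateSet(sigma=2.0, v=1000.0, s=np.array([]), c=0.5)
        cov = expected_coverage(intronless(), rs, t=5.0, bins=np.array([1000.0]))
        assert cov[0] == pytest.approx(8.0, rel=1e-4)

    def test_no_removal_limit_intron_equals_exon(self, two_intron_gene):
        # s=0 and c -> 0: intronic coverage follows the exonic ramp formula
        rs = RateSet(sigma=1.0, v=1200.0, s=np.array([0.0, 0.0]), c=1e-7)
        bins = np.array([500.0, 1700.0])  # exonic, intronic
        cov = expected_coverage(two_intron_gene, rs, t=4.0, bins=bins)
        expected = 1.0 * (4.0 - bins / 1200.0)
        np.testing.assert_allclose(cov, expected, rtol=1e-4)

    def test_homogeneous_in_sigma(self, two_intron_gene, toy_rates):
        r2 = RateSet(toy_rates.sigma * 2, toy_rates.v, toy_rates.s, toy_rates.c)
        c1 = expected_coverage(two_intron_gene, toy_rates, t=10.0)
        c2 = expected_coverage(two_intron_gene, r2, t=10.0)
        np.testing.assert_allclose(c2, 2 * c1, rtol=1e-12)

    def test_matches_molecule_simulation(self, two_intron_gene, toy_rates):
        n = 100_000
        for t in (4.0, 12.0, 30.0):
            exp = expected_coverage(two_intron_gene, toy_rates, t)
            mc, se = monte_carlo_coverage(two_intron_gene, toy_rates, t, n=n, seed=42)
            slack = 3 * se + 5 * toy_rates.sigma * t / n  # Poisson-tail floor
            assert (np.abs(exp - mc) <= slack).all()

    def test_rejects_bad_inputs(self, two_intron_gene, toy_rates):
        with pytest.raises(ValueError):
            expected_coverage(two_intron_gene, toy_rates, t=0.0)
        with pytest.raises(ValueError):
            expected_coverage(two_intron_gene, toy_rates, t=5.0, bins=np.array([-1.0]))


class TestSimulateMolecules:
    def test_poisson_molecule_count(self, two_intron_gene, toy_rates):
        t = 20.0
        mols = simulate_molecules(two_intron_gene, toy_rates, t, seed=1)
        mean = toy_rates.sigma * t
        assert abs(len(mols) - mean) <= 3 * np.sqrt(mean) + 1

    def test_huge_splicing_rate_splices_all_transcribed(self, two_intron_gene):
        rs = RateSet(sigma=2.0, v=1200.0, s=np.array([1e6, 1e6]), c=0.5)
        mols = simulate_molecules(two_intron_gene, rs, t=30.0, n=500, seed=2)
        for mol in mols:
            for j, intr in enumerate(two_intron_gene.introns):
                if mol.front > intr.end + 1e-9:  # 3'SS transcribed some time ago
                    assert mol.intron_status[j] == MoleculeState.SPLICED

    def test_intron_survival_is_exponential(self):
        # all molecules same age: spawn at ~0, observe at t -> survival e^(-s*a)
        L, s = 2000, 0.4
        m = GeneModel("g", "+", L, exons=[(0, 500), (1500, L)],
                      introns=[Intron(0, 500, 1500, 500)])
        rs = RateSet(sigma=1.0, v=1e5, s=np.array([s]), c=1e-9)
        t = 5.0
        n = 40_000
        # age of the splicing clock ~ t - e3/v ~ t for all molecules with tau~0;
        # use uniform tau but condition on age via the analytic average instead:
        # P(spliced) = (1/t) * int_0^t (1 - e^(-s*(t-u))) du
        mols = simulate_molecules(m, rs, t, n=n, seed=3)
        frac_spliced = np.mean([mol.intron_status[0] == MoleculeState.SPLICED for mol in mols])
        expected = 1 - (1 - np.exp(-s * t)) / (s * t)
        assert abs(frac_spliced - expected) < 3 * np.sqrt(expected * (1 - expected) / n)

    def test_spliced_implies_3ss_transcribed(self, two_intron_gene, toy_rates):
        mols = simulate_molecules(two_intron_gene, toy_rates, t=8.0, n=2000, seed=4)
        for mol in mols:
            for j, intr in enumerate(two_intron_gene.introns):
                if mol.intron_status[j] == MoleculeState.SPLICED:
                    assert mol.front >= intr.end


class TestTimeToTranscribe:
    @pytest.mark.parametrize(
        "length,v,expected", [(3000, 1500.0, 2.0), (1000, 2000.0, 0.5)]
    )
    def test_closed_form(self, length, v, expected):
        intr = Intron(0, 1000, 1000 + length, 500)
        rs = RateSet(sigma=1.0, v=v, s=np.array([0.5]), c=0.5)
        assert time_to_transcribe(intr, rs) == pytest.approx(expected)

    def test_detained_introns_transcribe_faster(self, small_study):
        _, models, truth = small_study
        ttt = {}
        for m in models:
            rs = truth.rates["control"][m.gene_id]
            for intr in m.introns:
                ttt[f"{m.gene_id}:{intr.index}"] = time_to_transcribe(intr, rs)
        import pandas as pd

        s = pd.Series(ttt)
        det = truth.detained
        assert s[det[det].index].median() < s.median()


class TestCleavageBeforeSplicing:
    def test_zero_splicing_rate_gives_one(self):
        intr = Intron(0, 100, 600, 1000)
        rs = RateSet(sigma=1.0, v=1000.0, s=np.array([0.0]), c=0.5)
        assert cleavage_before_splicing_prob(intr, rs) == 1.0

    def test_symmetric_race_with_vanishing_delay(self):
        # d -> 0 and c = s: memoryless race between two equal exponentials
        intr = Intron(0, 100, 600, dist_to_tes=1)
        rs = RateSet(sigma=1.0, v=1e9, s=np.array([0.7]), c=0.7)
        assert cleavage_before_splicing_prob(intr, rs) == pytest.approx(0.5, abs=1e-6)

    def test_closed_form_matches_exponential_race(self):
        s, c, d = 0.2, 1.0, 1.0
        closed = np.exp(-s * d) * c / (c + s)
        mc, se = cleavage_prob_mc(s, c, d, n=1_000_000, seed=5)
        assert abs(closed - mc) <= 3 * se

    @given(
        s=st.floats(0.01, 10.0),
        c=st.floats(0.01, 10.0),
        d_nt=st.integers(1, 20000),
    )
    def test_monotonicity_and_bounds(self, s, c, d_nt):
        rs_lo = RateSet(1.0, 1000.0, np.array([s]), c)
        rs_hi = RateSet(1.0, 1000.0, np.array([s * 2]), c)
        intr = Intron(0, 100, 600, d_nt)
        p = cleavage_before_splicing_prob(intr, rs_lo)
        assert 0.0 < p <= 1.0
        # decreasing in s
        assert cleavage_before_splicing_prob(intr, rs_hi) <= p
        # increasing in c
        rs_c = RateSet(1.0, 1000.0, np.array([s]), c * 2)
        assert cleavage_before_splicing_prob(intr, rs_c) >= p
        # decreasing in d
        closer = Intron(0, 100, 600, max(1, d_nt // 2))
        assert cleavage_before_splicing_prob(closer, rs_lo) >= p


class TestPredictedCassettePsi:
    def test_no_skip_rate_gives_full_inclusion(self):
        assert predicted_cassette_psi(1.0, 1.0, 0.0, dt=2.0) == 1.0

    def test_no_upstream_reduces_to_two_way_race(self):
        assert predicted_cassette_psi(0.0, 0.5, 0.5, dt=7.0) == pytest.approx(0.5)
        assert predicted_cassette_psi(0.0, 1.5, 0.5, dt=0.0) == pytest.approx(0.75)

    def test_symmetric_rates_with_ln2_head_start(self):
        psi = predicted_cassette_psi(1.0, 1.0, 1.0, dt=np.log(2))
        assert psi == pytest.approx(1 - 0.5 / 3)

    def test_closed_form_matches_race_simulation(self):
        n = 400_000
        closed = predicted_cassette_psi(1.0, 1.0, 1.0, dt=np.log(2))
        mc = predicted_cassette_psi(1.0, 1.0, 1.0, dt=np.log(2), mode="mc", n=n, seed=6)
        se = np.sqrt(closed * (1 - closed) / n)
        assert abs(closed - mc) <= 3 * se

    def test_all_rates_zero_undefined(self):
        with pytest.raises(ValueError):
            predicted_cassette_psi(0.0, 0.0, 0.0, dt=1.0)

    @given(
        s_u=st.floats(0.0, 5.0),
        s_d=st.floats(0.0, 5.0),
        s_k=st.floats(0.01, 5.0),
        dt=st.floats(0.0, 5.0),
    )
    def test_monotonicity(self, s_u, s_d, s_k, dt):
        psi = predicted_cassette_psi(s_u, s_d, s_k, dt)
        assert 0.0 <= psi <= 1.0
        assert predicted_cassette_psi(s_u + 1, s_d, s_k, dt) >= psi
        assert predicted_cassette_psi(s_u, s_d + 1, s_k, dt) >= psi
        assert predicted_cassette_psi(s_u, s_d, s_k + 1, dt) <= psi
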