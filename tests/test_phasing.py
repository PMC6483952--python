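"""Multi-locus EM phasing, diplotype posteriors and haplotype selection."""

import numpy as np
import pytest

from haploblup import em_phase_block, phase_blocks, select_frequent_haplotypes
from haploblup.phasing import BlockPhase, PhasedData, carrier_frequency
from haploblup.types import MISSING, HaplotypeAllele, LDBlock


def _pool_genotypes(rng, pool, freqs, n):
    pool = np.asarray(pool, dtype=np.int8)
    draws = rng.choice(len(pool), size=(n, 2), p=freqs)
    return pool[draws[:, 0]] + pool[draws[:, 1]], draws


def test_fully_homozygous_animal_has_certain_phase():
    calls = np.array([[0, 2, 0], [0, 2, 0], [2, 0, 2]], dtype=np.int8)
    phase = em_phase_block(calls)
    for pairs in phase.posteriors:
        assert len(pairs) == 1 and pairs[0][2] == pytest.approx(1.0)
        j, k, _ = pairs[0]
        assert j == k


def test_single_heterozygote_is_phase_unambiguous():
    calls = np.array([[0, 1, 2]] * 4, dtype=np.int8)
    phase = em_phase_block(calls)
    pairs = phase.posteriors[0]
    assert len(pairs) == 1 and pairs[0][2] == pytest.approx(1.0)
    strings = {phase.alleles[pairs[0][0]].allele_string,
               phase.alleles[pairs[0][1]].allele_string}
    assert strings == {"001", "011"}


def test_frequency_recovery_from_known_three_allele_pool():
    """EM frequencies within 3 binomial SE of the generating pool (n=200)."""
    rng = np.random.default_rng(5)
    pool = [[0, 0, 0, 0], [1, 1, 0, 1], [0, 1, 1, 0]]
    truth = {"0000": 0.5, "1101": 0.3, "0110": 0.2}
    calls, _ = _pool_genotypes(rng, pool, list(truth.values()), n=200)
    phase = em_phase_block(calls, tol=1e-10)
    est = {a.allele_string: a.population_frequency for a in phase.alleles}
    for string, f in truth.items():
        se = np.sqrt(f * (1 - f) / 400)  # 2n gametes
        assert abs(est.get(string, 0.0) - f) < 3 * se
    # spurious alleles carry almost no mass
    assert sum(v for k, v in est.items() if k not in truth) < 0.05


def test_log_likelihood_monotone_and_posteriors_normalised():
    rng = np.random.default_rng(8)
    pool = [[0, 0, 0], [1, 1, 0], [0, 1, 1], [1, 0, 1]]
    calls, _ = _pool_genotypes(rng, pool, [0.4, 0.3, 0.2, 0.1], n=120)
    calls[rng.random(calls.shape) < 0.1] = MISSING
    calls = calls[(calls != MISSING).any(axis=1)]
    phase = em_phase_block(calls, tol=1e-10)
    trace = phase.log_likelihood_trace
    assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))
    for pairs in phase.posteriors:
        assert sum(p for _, _, p in pairs) == pytest.approx(1.0, abs=1e-10)


def test_posterior_pairs_reproduce_observed_genotypes():
    rng = np.random.default_rng(3)
    pool = [[0, 0], [1, 1], [0, 1]]
    calls, _ = _pool_genotypes(rng, pool, [0.5, 0.3, 0.2], n=80)
    calls[rng.random(calls.shape) < 0.15] = MISSING
    calls = calls[(calls != MISSING).any(axis=1)]
    phase = em_phase_block(calls)
    strings = [a.allele_string for a in phase.alleles]
    for i, pairs in enumerate(phase.posteriors):
        for j, k, p in pairs:
            if p <= 0:
                continue
            summed = np.array([int(x) for x in strings[j]]) + np.array(
                [int(x) for x in strings[k]]
            )
            observed = calls[i] != MISSING
            assert np.array_equal(summed[observed], calls[i][observed])


def test_unambiguous_data_converges_to_counting_frequencies():
    """No double heterozygotes, no missing: EM equals direct gamete counts."""
    calls = np.array(
        [[0, 0], [0, 0], [2, 2], [1, 0], [0, 1], [2, 1]], dtype=np.int8
    )
    phase = em_phase_block(calls, tol=1e-12)
    est = {a.allele_string: a.population_frequency for a in phase.alleles}
    # gametes by hand: rows (0,0)x2 give four 00; (2,2) gives two 11;
    # (1,0) gives 00+10; (0,1) gives 00+01; (2,1) gives 10+11 -> 12 gametes
    assert est["00"] == pytest.approx(6 / 12, abs=1e-9)
    assert est["11"] == pytest.approx(3 / 12, abs=1e-9)
    assert est["10"] == pytest.approx(2 / 12, abs=1e-9)
    assert est["01"] == pytest.approx(1 / 12, abs=1e-9)


def test_all_missing_animal_gets_population_prior():
    calls = np.array([[2, 2], [0, 0], [MISSING, MISSING]], dtype=np.int8)
    phase = em_phase_block(calls)
    prior = phase.posteriors[2]
    assert sum(p for _, _, p in prior) == pytest.approx(1.0, abs=1e-10)
    freqs = phase.frequencies
    for j, k, p in prior:
        expected = freqs[j] * freqs[k] * (2.0 if j != k else 1.0)
        assert p == pytest.approx(expected, abs=1e-9)


def test_enumeration_cap_reported_via_skip():
    from haploblup.types import GenotypeMatrix

    calls = np.ones((4, 26), dtype=np.int8)  # every site heterozygous
    block = LDBlock("b0", "1", tuple(range(26)))
    g = GenotypeMatrix(
        animal_ids=[f"a{i}" for i in range(4)],
        snp_ids=[f"s{j}" for j in range(26)],
        chromosome=np.array(["1"] * 26, dtype=object),
        position=np.arange(1, 27) * 100,
        calls=calls,
    )
    phased = phase_blocks(g, [block], enumeration_cap=1000)
    assert phased.skipped == ["b0"] and phased.blocks == []


def _manual_phase(posterior_rows, strings, block_id="b0"):
    alleles = [
        HaplotypeAllele(block_id=block_id, allele_string=s, population_frequency=f)
        for s, f in strings
    ]
    return BlockPhase(block_id=block_id, alleles=alleles, posteriors=posterior_rows)


def test_carrier_frequency_counts_confident_carriers():
    strings = [("00", 0.6), ("11", 0.4)]
    posteriors = [[(0, 1, 1.0)]] * 30 + [[(1, 1, 1.0)]] * 0 + [[(0, 0, 1.0)]] * 70
    phase = _manual_phase(posteriors, strings)
    assert carrier_frequency(phase, 1) == pytest.approx(0.30)
    assert carrier_frequency(phase, 0) == pytest.approx(1.0)


def test_absent_allele_has_zero_carrier_frequency():
    phase = _manual_phase([[(0, 0, 1.0)]] * 10, [("00", 1.0), ("11", 0.0)])
    assert carrier_frequency(phase, 1) == 0.0


def test_hardy_weinberg_carrier_frequency():
    """Population frequency p=0.25 with certain phasing: carriers near 2p-p2."""
    rng = np.random.default_rng(4)
    n = 4000
    draws = rng.choice(2, size=(n, 2), p=[0.75, 0.25])
    posteriors = [
        [(int(min(a, b)), int(max(a, b)), 1.0)] for a, b in draws
    ]
    phase = _manual_phase(posteriors, [("0", 0.75), ("1", 0.25)])
    expected = 2 * 0.25 - 0.25**2  # 0.4375
    assert carrier_frequency(phase, 1) == pytest.approx(expected, abs=0.025)


def _phased_single_block(posteriors, strings):
    block = LDBlock("b0", "1", (0, 1))
    phase = _manual_phase(posteriors, strings)
    return PhasedData(
        blocks=[block],
        phases={"b0": phase},
        animal_ids=[f"a{i}" for i in range(len(posteriors))],
    )


def test_selection_threshold_is_strict():
    # carriers: allele0 60%, allele1 30%, allele2 10% -> two kept at 0.25;
    # alleles at exactly the threshold are excluded
    post = (
        [[(0, 0, 1.0)]] * 60
        + [[(1, 1, 1.0)]] * 30
        + [[(2, 2, 1.0)]] * 10
    )
    strings = [("00", 0.5), ("11", 0.3), ("01", 0.2)]
    phased = _phased_single_block(post, strings)
    kept = select_frequent_haplotypes(phased, threshold=0.25)
    assert [h.allele_string for h in kept] == ["00", "11"]
    assert all(h.block_size == 2 for h in kept)

    exact = [[(0, 0, 1.0)]] * 25 + [[(1, 1, 1.0)]] * 25 + [[(2, 2, 1.0)]] * 50
    phased = _phased_single_block(exact, strings)
    kept = select_frequent_haplotypes(phased, threshold=0.25)
    assert [h.allele_string for h in kept] == ["01"]

    assert len(select_frequent_haplotypes(phased, threshold=0.0)) == 3


def test_selection_order_deterministic_with_lexicographic_ties():
    post = [[(0, 1, 1.0)]] * 10  # both alleles carried by everyone
    strings = [("11", 0.5), ("00", 0.5)]
    phased = _phased_single_block(post, strings)
    kept = select_frequent_haplotypes(phased, threshold=0.25)
    assert [h.allele_string for h in kept] == ["00", "11"]


def test_population_basis_switch():
    post = [[(0, 1, 1.0)]] * 10
    strings = [("00", 0.8), ("11", 0.2)]
    phased = _phased_single_block(post, strings)
    kept = select_frequent_haplotypes(phased, threshold=0.25, basis="population")
    assert [h.allele_string for h in kept] == ["00"]


def test_selected_count_per_block_sanity_bound(small_population):
    """Carrier frequency > 25% keeps per-block selections small (<= 7)."""
    from haploblup import apply_qc, build_blocks, inject_missingness

    g = inject_missingness(small_population, 0.02, seed=2)
    filtered, _ = apply_qc(g)
    blocks = build_blocks(filtered, 0.8, 50)
    phased = phase_blocks(filtered, blocks)
    kept = select_frequent_haplotypes(phased)
    per_block: dict[str, int] = {}
    for h in kept:
        per_block[h.block_id] = per_block.get(h.block_id, 0) + 1
    assert per_block and max(per_block.values()) <= 7
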