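"""Jordan-Wigner string tables, expectation inversion, and shot noise.

The symbolic ladder algebra is cross-checked against a dense Kronecker
statevector oracle built independently in conftest.
"""

import numpy as np
import pytest

import rdmcomplete as rc
from rdmcomplete.measurement import (
    PauliString,
    SpinOrbitalRDMView,
    element_string_table,
    pauli_expectation,
    sector_element_labels,
    shot_variance,
)
from conftest import (
    fermionic_expectation_dense,
    ground_state,
    pauli_expectation_dense,
)


class TestQuartetStrings:
    def test_distinct_quartet_gives_eight_strings(self):
        q = rc.pauli_strings_for_quartet(0, 1, 2, 3, 4)
        assert len(q["strings"]) == 8
        for s in q["strings"]:
            assert not s.is_identity
            assert s.y_parity == 0

    def test_z_fill_between_sites(self):
        q = rc.pauli_strings_for_quartet(0, 5, 1, 4, 6)
        for s in q["strings"]:
            # sites 2..3 sit between the pairs and must carry Z fill or I
            assert set(s.letters[2:4]) <= {"Z", "I"}

    def test_number_operator_combination(self):
        # <n_0 n_2> = (1 - <Z_0> - <Z_2> + <Z_0 Z_2>)/4
        c0, tab = element_string_table(0, 2, 2, 0, 4)
        assert c0 == pytest.approx(0.25)
        expect = {"ZIII": -0.25, "IIZI": -0.25, "ZIZI": 0.25}
        assert {str(k): v for k, v in tab.items()} == pytest.approx(expect)

    def test_degenerate_orderings_have_empty_tables(self):
        q = rc.pauli_strings_for_quartet(0, 0, 1, 1, 4)
        # orderings with a repeated creator or annihilator pair vanish
        assert np.count_nonzero(q["identity"]) <= 2

    def test_too_many_distinct_indices_rejected(self):
        with pytest.raises(ValueError):
            rc.pauli_strings_for_quartet(0, 1, 2, 9, 4)


class TestExpectationInversion:
    """Both directions of the string/element linear maps vs the oracle."""

    def test_string_expectations_match_statevector(self, pair_n3):
        psi = ground_state(pair_n3.ints, 1, 1)
        view = SpinOrbitalRDMView(pair_n3.target, pair_n3.target_1rdm)
        plan = rc.build_measurement_plan(pair_n3.target)
        for q in plan.strings:
            ref = pauli_expectation_dense(q.letters, psi)
            assert pauli_expectation(q, view) == pytest.approx(ref,
                                                               abs=1e-10)

    def test_open_shell_string_expectations(self, beh_like):
        psi = ground_state(beh_like.ints, 2, 1)
        view = SpinOrbitalRDMView(beh_like.target, beh_like.target_1rdm)
        plan = rc.build_measurement_plan(beh_like.target)
        rng = np.random.default_rng(0)
        sample = rng.choice(len(plan.strings), size=60, replace=False)
        for t in sample:
            q = plan.strings[t]
            ref = pauli_expectation_dense(q.letters, psi)
            assert pauli_expectation(q, view) == pytest.approx(ref,
                                                               abs=1e-10)

    def test_element_reconstruction_roundtrip(self, beh_like):
        # exact string expectations reassembled through the coefficient
        # tables must return the stored 2-RDM elements
        rdm2 = beh_like.target
        plan = rc.build_measurement_plan(rdm2)
        exact = rc.fermionic_to_pauli_expectations(rdm2,
                                                   beh_like.target_1rdm,
                                                   plan)
        n = rdm2.n_orb
        for (label, a, b), (c0, tab) in plan.element_tables.items():
            val = c0 + sum(c * exact[q] for q, c in tab.items())
            assert val == pytest.approx(
                rdm2.sectors[label].values[a, b], abs=1e-10)

    def test_quartet_coefficients_on_statevector(self, pair_n3):
        # reconstruct fermionic expectations of a quartet from dense string
        # expectations alone
        psi = ground_state(pair_n3.ints, 1, 1)
        n_so = 6
        q = rc.pauli_strings_for_quartet(0, 3, 1, 4, n_so)
        string_ev = {s: pauli_expectation_dense(s.letters, psi)
                     for s in q["strings"]}
        for t, (i, k, l, j) in enumerate(q["orderings"]):
            if i == k or l == j:
                continue
            rec = q["identity"][t] + sum(
                q["coefficients"][s][t] * string_ev[s]
                for s in q["strings"])
            ref = fermionic_expectation_dense(i, k, l, j, psi, n_so)
            assert rec == pytest.approx(ref, abs=1e-10)

    def test_diagonal_state_kills_xy_strings(self):
        # an uncorrelated diagonal 2-RDM has zero expectation for every
        # string that moves particles
        n = 2
        da = np.diag([1.0, 0.0])
        rdm2 = rc.hartree_fock_2rdm(da, da)
        rdm1 = rc.contract_to_1rdm(rdm2)
        plan = rc.build_measurement_plan(rdm2)
        exact = rc.fermionic_to_pauli_expectations(rdm2, rdm1, plan)
        for q, val in exact.items():
            if "X" in q.letters or "Y" in q.letters:
                assert val == pytest.approx(0.0, abs=1e-12)


class TestShotNoise:
    def test_eigenstate_is_deterministic(self):
        rng = np.random.default_rng(0)
        assert rc.sample_pauli(1.0, 7, rng) == 1.0
        assert rc.sample_pauli(-1.0, 7, rng) == -1.0

    def test_variance_formula_at_symmetric_point(self):
        assert shot_variance(0.0, 1) == 1.0

    def test_unbiased_and_variance_matches_binomial(self):
        rng = np.random.default_rng(1)
        reps = 10000
        est = np.array([rc.sample_pauli(0.5, 100, rng)
                        for _ in range(reps)])
        target_var = shot_variance(0.5, 100)
        se = np.sqrt(target_var / reps)
        assert abs(est.mean() - 0.5) < 3 * se
        assert abs(est.var() - target_var) < 0.05 * target_var

    def test_out_of_range_expectation_rejected(self):
        with pytest.raises(ValueError):
            rc.sample_pauli(1.2, 10, np.random.default_rng(0))


class TestSimulateMeasurement:
    def test_large_shot_limit_recovers_rdm(self, pair_n3):
        noisy, _, _ = rc.simulate_measurement(
            pair_n3.target, pair_n3.target_1rdm, None, 10 ** 9, seed=5)
        for label, sec in pair_n3.target.sectors.items():
            assert rc.relative_error(noisy[label].values,
                                     sec.values) < 1e-3

    def test_error_scales_as_inverse_sqrt_shots(self, pair_n3):
        errs = {}
        cache = {}
        for m in (10 ** 3, 10 ** 4, 10 ** 5):
            vals = []
            for s in range(8):
                noisy, _, _ = rc.simulate_measurement(
                    pair_n3.target, pair_n3.target_1rdm, None, m,
                    seed=100 * s + m % 97, expectation_cache=cache)
                vals.append(rc.relative_error(
                    noisy["abab"].values,
                    pair_n3.target.sectors["abab"].values))
            errs[m] = np.median(vals)
        for m in (10 ** 3, 10 ** 4):
            ratio = errs[m] / errs[m * 10]
            assert ratio == pytest.approx(np.sqrt(10), rel=0.3)

    def test_partial_plan_leaves_other_entries_empty(self, pair_n3):
        d = pair_n3.target.sectors["abab"].d
        omega = rc.sample_elements(d, n_sample=5, rng_seed=1)
        noisy, _, plan = rc.simulate_measurement(
            pair_n3.target, pair_n3.target_1rdm, {"abab": omega},
            10 ** 4, seed=2)
        vals = noisy["abab"].values
        filled = {(i, j) for i in range(d) for j in range(d)
                  if not np.isnan(vals[i, j])}
        expected = set()
        for (i, j) in omega.indices:
            expected |= {(i, j), (j, i)}
        assert filled == expected

    def test_estimator_is_unbiased_per_element(self, pair_n3):
        d = pair_n3.target.sectors["abab"].d
        omega = rc.SampleSet(d, ((3, 1),))
        truth = pair_n3.target.sectors["abab"].values[3, 1]
        cache = {}
        vals = []
        for s in range(300):
            noisy, recs, _ = rc.simulate_measurement(
                pair_n3.target, pair_n3.target_1rdm, {"abab": omega},
                200, seed=s, expectation_cache=cache)
            vals.append(noisy["abab"].values[3, 1])
        vals = np.array(vals)
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean() - truth) < 3.5 * se

    def test_strings_deduplicated_across_elements(self, pair_n3):
        plan = rc.build_measurement_plan(pair_n3.target)
        total_refs = sum(len(tab) for _, tab in
                         plan.element_tables.values())
        assert len(plan.strings) < total_refs
        assert len(set(plan.strings)) == len(plan.strings)


class TestCostsAndVariance:
    def test_average_variance_examples(self):
        assert rc.average_variance_per_string([1.0, -1.0]) == 0.0
        assert rc.average_variance_per_string([0.0], shots=1) == 1.0
        assert rc.average_variance_per_string([1.0, 0.0, -1.0, 0.0]) == 0.5

    def test_total_cost_with_switching(self, pair_n3):
        q = rc.pauli_strings_for_quartet(0, 1, 2, 3, 4)
        plan = rc.MeasurementPlan(
            n_spin_orb=4, quartets=[(0, 1, 2, 3)], strings=q["strings"],
            element_tables={}, shots_per_string=100, switch_cost=500)
        # 8 strings: 800 shots + 8 * 500 switches
        assert rc.total_cost(plan) == 4800

    def test_removing_elements_never_increases_cost(self, pair_n3):
        d = pair_n3.target.sectors["abab"].d
        omega = rc.sample_elements(d, n_sample=20, rng_seed=0)
        sub = rc.SampleSet(d, omega.indices[:-5])
        full = rc.build_measurement_plan(pair_n3.target, {"abab": omega},
                                         shots_per_string=10,
                                         switch_cost=3.0)
        smaller = rc.build_measurement_plan(pair_n3.target, {"abab": sub},
                                            shots_per_string=10,
                                            switch_cost=3.0)
        assert rc.total_cost(smaller) <= rc.total_cost(full)

    def test_element_labels_roundtrip(self, beh_like):
        # packed element (a, b) -> spin orbital labels -> stored value
        view = SpinOrbitalRDMView(beh_like.target, beh_like.target_1rdm)
        n = beh_like.target.n_orb
        for label in beh_like.target.sectors:
            d = beh_like.target.sectors[label].d
            for (a, b) in [(0, 0), (d - 1, 0), (d - 1, d - 1)]:
                i, k, l, j = sector_element_labels(label, n, a, b)
                assert view.two_body(i, k, l, j) == pytest.approx(
                    beh_like.target.sectors[label].values[a, b],
                    abs=1e-10)
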