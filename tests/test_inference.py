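"""Potentials, forward-backward decoding and the path-enumeration oracle."""

import numpy as np
import pytest
from conftest import random_model, random_tables, uniform_tables

from coilmrf.features import HydropathyScale
from coilmrf.inference import (
    PotentialTable,
    brute_force_posterior,
    build_potentials,
    forward_backward,
    posterior_oligomer_probs,
    predict_sequence,
)
from coilmrf.model_core import (
    OligomerClass,
    coil_run_lengths,
    enumerate_valid_paths,
)
from coilmrf.sequence_io import ProteinSequence
from coilmrf.training import RegressionModel
from coilmrf.synthetic import SyntheticSpec, sample_dataset

AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_sequence(rng, length):
    return ProteinSequence("s", "".join(AA[i] for i in rng.integers(0, 20, length)))


def _zero_model():
    return RegressionModel(np.zeros(8), np.zeros(8), 0.0, 0.0)


@pytest.fixture(scope="module")
def eisenberg():
    return HydropathyScale.eisenberg_consensus()


class TestBuildPotentials:
    def test_zero_model_gives_zero_potentials(self, space, eisenberg):
        single, pairs = uniform_tables()
        seq = _random_sequence(np.random.default_rng(0), 15)
        pot = build_potentials(seq, _zero_model(), single, pairs, eisenberg, space)
        # uniform tables make the log-prob features nonzero, but with zero
        # coefficients every state's potential vanishes
        np.testing.assert_array_equal(pot.log_psi1, 0.0)

    def test_noncoil_column_is_zero(self, space, eisenberg):
        rng = np.random.default_rng(1)
        single, pairs = random_tables(rng)
        seq = _random_sequence(rng, 20)
        pot = build_potentials(seq, random_model(rng), single, pairs, eisenberg, space)
        np.testing.assert_array_equal(pot.log_psi1[:, 0], 0.0)
        assert np.all(np.isfinite(pot.log_psi1))

    def test_constants_charged_once_per_coil_segment(self, space, eisenberg):
        """With zero coefficients, a path's log-score is the per-class
        constant times its number of coil segments."""
        single, pairs = uniform_tables()
        model = RegressionModel(np.zeros(8), np.zeros(8), -1.5, 2.5)
        seq = _random_sequence(np.random.default_rng(2), 12)
        pot = build_potentials(seq, model, single, pairs, eisenberg, space)
        for path in enumerate_valid_paths(12):
            score = sum(pot.log_psi1[i, space.index[s]] for i, s in enumerate(path))
            n_d = sum(
                1 for s in path if s.is_coil and s.location == 1
                and s.oligomer is OligomerClass.DIMER
            )
            n_t = sum(
                1 for s in path if s.is_coil and s.location == 1
                and s.oligomer is OligomerClass.TRIMER
            )
            assert score == pytest.approx(-1.5 * n_d + 2.5 * n_t, abs=1e-12)

    def test_locality_window(self, space, eisenberg):
        """Potentials at position i depend only on residues i-7..i."""
        rng = np.random.default_rng(3)
        single, pairs = random_tables(rng)
        model = random_model(rng)
        base = "MKQLEDKIEELLSKIYHLENE"
        changed = base[:-1] + "W"  # touch only the final residue
        p1 = build_potentials(ProteinSequence("a", base), model, single, pairs, eisenberg, space)
        p2 = build_potentials(ProteinSequence("b", changed), model, single, pairs, eisenberg, space)
        np.testing.assert_array_equal(
            p1.log_psi1[: len(base) - 1], p2.log_psi1[: len(base) - 1]
        )

    def test_pseudocount_mismatch_rejected(self, space, eisenberg):
        rng = np.random.default_rng(4)
        single, pairs = random_tables(rng)  # pseudocount 1.0
        model = RegressionModel(np.zeros(8), np.zeros(8), 0.0, 0.0, pseudocount=0.5)
        with pytest.raises(ValueError, match="pseudocount"):
            build_potentials(_random_sequence(rng, 10), model, single, pairs, eisenberg, space)


class TestForwardBackward:
    def test_posteriors_normalize(self, space, eisenberg):
        rng = np.random.default_rng(5)
        single, pairs = random_tables(rng)
        seq = _random_sequence(rng, 40)
        pot = build_potentials(seq, random_model(rng), single, pairs, eisenberg, space)
        post = forward_backward(seq, pot, space)
        np.testing.assert_allclose(post.gamma.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(post.gamma >= 0)

    @pytest.mark.parametrize("length", range(1, 9))
    def test_short_sequences_carry_no_coil_mass(self, length, space, eisenberg):
        """No valid path fits a coil into fewer than nine residues."""
        rng = np.random.default_rng(6 + length)
        single, pairs = random_tables(rng)
        seq = _random_sequence(rng, length)
        pot = build_potentials(seq, random_model(rng, 1.0), single, pairs, eisenberg, space)
        post = forward_backward(seq, pot, space)
        coil_mass = post.gamma[:, space.coil_mask].sum()
        assert coil_mass == 0.0

    def test_single_residue_is_noncoil(self, space, eisenberg):
        single, pairs = uniform_tables()
        seq = ProteinSequence("s", "M")
        pot = build_potentials(seq, _zero_model(), single, pairs, eisenberg, space)
        post = brute_force_posterior(seq, pot, space)
        assert post.gamma[0, 0] == 1.0

    def test_gauge_invariance(self, space, eisenberg):
        """Adding a constant to every state's log-potential at one position
        shifts logZ but leaves the posteriors unchanged."""
        rng = np.random.default_rng(20)
        single, pairs = random_tables(rng)
        seq = _random_sequence(rng, 25)
        pot = build_potentials(seq, random_model(rng), single, pairs, eisenberg, space)
        post = forward_backward(seq, pot, space)
        shifted = PotentialTable(pot.log_psi1.copy(), space)
        shifted.log_psi1[10] += 3.7
        post2 = forward_backward(seq, shifted, space)
        np.testing.assert_allclose(post2.gamma, post.gamma, atol=1e-9)
        assert post2.logZ == pytest.approx(post.logZ + 3.7)

    def test_dimer_constant_monotonicity(self, space, eisenberg):
        """Raising c_dimer never lowers any residue's dimer posterior.

        Pointwise monotonicity holds when the sequence hosts at most one
        coil segment (length < 19: two coils need 9 + 1 + 9 residues);
        with several segments, paths carrying more constants can overtake.
        """
        rng = np.random.default_rng(21)
        single, pairs = random_tables(rng)
        seq = _random_sequence(rng, 16)
        model = random_model(rng)
        prev = None
        for bump in (0.0, 1.0, 3.0):
            m = RegressionModel(model.alpha, model.beta, model.c_dimer + bump, model.c_trimer)
            pot = build_potentials(seq, m, single, pairs, eisenberg, space)
            post = forward_backward(seq, pot, space)
            p_dimer = post.gamma[:, space.dimer_mask].sum(axis=1)
            if prev is not None:
                assert np.all(p_dimer >= prev - 1e-12)
            prev = p_dimer

    def test_offset_monotonicity(self, space, eisenberg):
        """Increasing the coil-bias offset never raises any coil posterior
        (single-coil regime; see the c_dimer monotonicity note)."""
        from coilmrf.training import apply_offset

        rng = np.random.default_rng(22)
        single, pairs = random_tables(rng)
        seq = _random_sequence(rng, 16)
        base = random_model(rng)
        prev = None
        for offset in (0.0, 5.0, 20.0):
            pot = build_potentials(
                seq, apply_offset(base, offset), single, pairs, eisenberg, space
            )
            post = forward_backward(seq, pot, space)
            p_coil = post.gamma[:, space.coil_mask].sum(axis=1)
            if prev is not None:
                assert np.all(p_coil <= prev + 1e-12)
            prev = p_coil


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_instances(self, space, eisenberg):
        """Forward-backward equals explicit path summation to 1e-9 on 200
        random (sequence, model) pairs of length <= 12."""
        rng = np.random.default_rng(123)
        for trial in range(200):
            single, pairs = random_tables(rng)
            model = random_model(rng, coef_scale=1.0)
            seq = _random_sequence(rng, int(rng.integers(1, 13)))
            pot = build_potentials(seq, model, single, pairs, eisenberg, space)
            fb = forward_backward(seq, pot, space)
            bf = brute_force_posterior(seq, pot, space)
            np.testing.assert_allclose(fb.gamma, bf.gamma, atol=1e-9, rtol=0)
            assert fb.logZ == pytest.approx(bf.logZ, abs=1e-9)

    def test_coil_mass_is_enumerated_path_fraction(self, space, eisenberg):
        """With zero potentials the posterior is uniform over valid paths,
        so coil mass equals the enumerated coil-path fraction."""
        single, pairs = uniform_tables()
        seq = _random_sequence(np.random.default_rng(9), 9)
        pot = build_potentials(seq, _zero_model(), single, pairs, eisenberg, space)
        post = forward_backward(seq, pot, space)
        paths = enumerate_valid_paths(9)
        frac = np.mean([paths[j][0].is_coil for j in range(len(paths))])
        # position 0: coil mass = fraction of paths whose first state is coil
        assert post.gamma[0, space.coil_mask].sum() == pytest.approx(frac, abs=1e-12)


class TestPosteriorSummaries:
    def test_partition_of_unity(self, space, eisenberg):
        rng = np.random.default_rng(30)
        single, pairs = random_tables(rng)
        seq = _random_sequence(rng, 35)
        pot = build_potentials(seq, random_model(rng), single, pairs, eisenberg, space)
        post = forward_backward(seq, pot, space)
        rows = posterior_oligomer_probs(post, seq)
        p_noncoil = post.gamma[:, 0]
        for i, row in enumerate(rows):
            assert row.p_dimer + row.p_trimer + p_noncoil[i] == pytest.approx(1.0, abs=1e-9)

    def test_all_noncoil_mass_gives_zero_probs(self, space, eisenberg):
        single, pairs = uniform_tables()
        seq = ProteinSequence("s", "MKQL")
        pot = build_potentials(seq, _zero_model(), single, pairs, eisenberg, space)
        post = forward_backward(seq, pot, space)  # length 4: only non-coil paths
        rows = posterior_oligomer_probs(post, seq)
        assert all(r.p_dimer == 0.0 and r.p_trimer == 0.0 and r.best_register == "-" for r in rows)


def test_register_recovery_on_strong_dimer_coils(dataset, tables, full_model, space, eisenberg):
    """On held-in strong dimer coils the arg-max posterior register matches
    the generating register at >= 95% of coil residues."""
    families, _ = dataset
    single, pairs = tables
    matches = total = 0
    for fam, records in families.items():
        if not fam.startswith("dimer"):
            continue
        for rec in records[:3]:
            rows = predict_sequence(rec.sequence, full_model, single, pairs, eisenberg, space)
            (ann,) = rec.annotations
            for off in range(len(ann)):
                total += 1
                matches += rows[ann.start + off].best_register == ann.register[off]
    assert matches / total >= 0.95
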