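import numpy as np
import pytest

from modesign.objectives import (
    CompositeScoreInputs,
    ObjectiveSpec,
    StatePSSM,
    composite_fold_score,
    kabsch_superpose,
    make_batch_evaluator,
    pssm_log_likelihood,
    register_scorer,
    get_scorer,
    surrogate_composite,
    tm_score,
    _tm_d0,
)
from modesign.problem import Candidate, ValidationError
from modesign.synthetic import make_toy_problem
from modesign.runner import run_design
from modesign.moea import RunConfig


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def quaternion_rmsd(a, b):
    """Independent oracle: Horn's closed-form quaternion superposition."""
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    m = b0.T @ a0
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(k)[-1]
    sq = (a0 ** 2).sum() + (b0 ** 2).sum() - 2 * lam
    return np.sqrt(max(sq, 0.0) / a.shape[0])


class TestCompositeScore:
    @pytest.mark.parametrize("inputs,expected", [
        ((1.0, 1.0, 1.0), 1.0),
        ((0.0, 0.7, 0.9), 0.0),
        ((0.8, 0.9, 0.5), 0.36),
    ])
    def test_product_formula(self, inputs, expected):
        assert composite_fold_score(CompositeScoreInputs(*inputs)) == pytest.approx(expected)

    def test_out_of_range_component_rejected(self):
        with pytest.raises(ValidationError):
            CompositeScoreInputs(1.2, 0.5, 0.5)

    def test_monotone_in_each_component(self, rng):
        for _ in range(50):
            base = rng.random(3)
            j = rng.integers(0, 3)
            better = base.copy()
            better[j] = min(1.0, better[j] + rng.random() * (1 - better[j]))
            assert composite_fold_score(CompositeScoreInputs(*better)) >= \
                composite_fold_score(CompositeScoreInputs(*base)) - 1e-15


class TestKabsch:
    def test_identity(self, rng):
        a = rng.normal(size=(10, 3))
        rot, trans, rmsd = kabsch_superpose(a, a)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(rot, np.eye(3), atol=1e-9)

    def test_rigid_invariance(self, rng):
        a = rng.normal(size=(12, 3)) * 5
        rot = random_rotation(rng)
        b = a @ rot.T + np.array([3.0, -2.0, 7.5])
        _, _, rmsd = kabsch_superpose(a, b)
        assert rmsd < 1e-6

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_quaternion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 3))
        _, _, rmsd = kabsch_superpose(a, b)
        assert rmsd == pytest.approx(quaternion_rmsd(a, b), abs=1e-8)

    def test_proper_rotation(self, rng):
        for _ in range(20):
            a = rng.normal(size=(8, 3))
            b = rng.normal(size=(8, 3))
            rot, _, _ = kabsch_superpose(a, b)
            assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_cloud_rejected(self):
        line = np.stack([np.arange(5.0), np.zeros(5), np.zeros(5)], axis=1)
        with pytest.raises(ValidationError):
            kabsch_superpose(line, line)
        with pytest.raises(ValidationError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


def helix_ca(n, rng=None):
    t = np.deg2rad(100.0) * np.arange(n)
    ca = np.stack([2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * np.arange(n)], axis=1)
    if rng is not None:
        ca = ca + rng.normal(scale=0.3, size=ca.shape)
    return ca


class TestTMScore:
    def test_identical_structures(self, rng):
        a = helix_ca(20, rng)
        assert tm_score(a, a) == pytest.approx(1.0, abs=1e-9)

    def test_rigid_invariance(self, rng):
        a = helix_ca(25, rng)
        rot = random_rotation(rng)
        b = a @ rot.T + np.array([10.0, -4.0, 2.0])
        assert tm_score(b, a) == pytest.approx(1.0, abs=1e-6)

    def test_single_displaced_residue_closed_form(self, rng):
        # one residue thrown far away: the optimal superposition aligns the
        # L-1 identical residues exactly, leaving one tiny term
        a = helix_ca(30, rng)
        b = a.copy()
        b[7] += np.array([500.0, 0.0, 0.0])
        L = 30
        d0 = _tm_d0(L)
        d_out = np.linalg.norm(b[7] - a[7])
        closed_form = ((L - 1) + 1.0 / (1.0 + (d_out / d0) ** 2)) / L
        assert tm_score(b, a) == pytest.approx(closed_form, abs=1e-3)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_seed_oracle(self, seed):
        rng = np.random.default_rng(seed)
        L = 16
        a = helix_ca(L, rng)
        b = a + rng.normal(scale=1.5, size=a.shape)

        def oracle(model, ref):
            d0 = _tm_d0(L)

            def score(rot, trans):
                d = np.linalg.norm(model @ rot.T + trans - ref, axis=1)
                return np.mean(1.0 / (1.0 + (d / d0) ** 2)), d

            best = 0.0
            for frag in range(4, L + 1):
                for start in range(L - frag + 1):
                    idx = np.arange(start, start + frag)
                    try:
                        rot, trans, _ = kabsch_superpose(ref[idx], model[idx])
                    except ValidationError:
                        continue
                    sc, d = score(rot, trans)
                    best = max(best, sc)
                    prev = idx
                    for _ in range(30):
                        cutoff = d0 + 1.0
                        keep = np.flatnonzero(d < cutoff)
                        while keep.size < 3:
                            cutoff += 0.5
                            keep = np.flatnonzero(d < cutoff)
                        if np.array_equal(keep, prev):
                            break
                        try:
                            rot, trans, _ = kabsch_superpose(ref[keep], model[keep])
                        except ValidationError:
                            break
                        sc, d = score(rot, trans)
                        best = max(best, sc)
                        prev = keep
            return best

        assert tm_score(b, a) == pytest.approx(oracle(b, a), abs=1e-6)

    def test_value_in_unit_interval(self, rng):
        a = helix_ca(15, rng)
        b = rng.normal(size=(15, 3)) * 20
        s = tm_score(b, a)
        assert 0.0 < s <= 1.0

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError):
            tm_score(helix_ca(10), helix_ca(11))


class TestPSSMScores:
    def _uniform_pssm(self, L=4, A=20):
        alphabet = "ACDEFGHIKLMNPQRSTVWY"[:A]
        probs = np.full((L, A), 1.0 / A)
        return StatePSSM("s", alphabet, probs)

    def test_uniform_pssm_log_likelihood(self):
        pssm = self._uniform_pssm()
        assert pssm_log_likelihood("ACDE", pssm) == pytest.approx(np.log(1 / 20))

    def test_near_one_hot(self):
        eps = 1e-4
        probs = np.full((3, 20), eps / 19)
        probs[:, 0] = 1 - eps
        pssm = StatePSSM("s", "ACDEFGHIKLMNPQRSTVWY", probs)
        assert pssm_log_likelihood("AAA", pssm) == pytest.approx(np.log(1 - eps))

    def test_matches_position_sum_oracle(self, rng):
        probs = rng.dirichlet(np.ones(4), size=5)
        pssm = StatePSSM("s", "ACDE", probs)
        seq = "CADEC"
        expected = np.mean([
            np.log(probs[i, "ACDE".index(ch)]) for i, ch in enumerate(seq)
        ])
        assert pssm_log_likelihood(seq, pssm) == pytest.approx(expected)

    def test_surrogate_composite_range_and_modal(self, rng):
        probs = rng.dirichlet(np.ones(4) * 2, size=6)
        pssm = StatePSSM("s", "ACDE", probs)
        assert surrogate_composite(pssm.modal_sequence(), pssm) == pytest.approx(1.0)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACDE"), size=6))
            v = surrogate_composite(seq, pssm)
            assert 0.0 < v <= 1.0

    def test_surrogate_monotone_in_position_probability(self, rng):
        # improving one position's probability never lowers the score
        probs = rng.dirichlet(np.ones(4), size=3)
        pssm = StatePSSM("s", "ACDE", probs)
        seq = "ACD"
        for j in range(3):
            better = probs.copy()
            ch = "ACDE".index(seq[j])
            # shift mass toward the sequence's residue, keep the max fixed
            worst = better[j].argmin()
            if worst == ch:
                continue
            delta = better[j, worst] / 2
            better[j, ch] += delta
            better[j, worst] -= delta
            if better[j].argmax() != probs[j].argmax():
                continue
            improved = StatePSSM("s", "ACDE", better / better.sum(axis=1, keepdims=True))
            assert surrogate_composite(seq, improved) >= surrogate_composite(seq, pssm) - 1e-12

    def test_all_sequences_finite(self, rng):
        toy = make_toy_problem(seed=9)
        specs = toy.objective_specs()
        for _ in range(200):
            seq = "".join(rng.choice(list(toy.problem.alphabet.symbols),
                                     size=toy.problem.n_designable))
            for spec in specs:
                assert np.isfinite(spec.evaluator(Candidate(seq)))


class TestPluginContracts:
    def test_mock_plugin_runs_end_to_end(self):
        register_scorer("pmpnn_sd_score", lambda seq, structure: 1.5,
                        name="mock_sd")
        fn = get_scorer("mock_sd")
        toy = make_toy_problem(seed=1)
        specs = [
            ObjectiveSpec("plug_a", "alpha", lambda c: float(fn(c.designed_residues, None))),
            ObjectiveSpec("plug_b", "beta", lambda c: 2.0),
        ]
        history = run_design(toy.problem,
                             RunConfig(population_size=10, iterations=2, seed=0),
                             specs)
        assert len(history.records) == 2

    def test_arity_mismatch_rejected_at_registration(self):
        with pytest.raises(ValidationError, match="arity|argument"):
            register_scorer("esm_position_scores", lambda seq, extra: [0.0])

    def test_unknown_contract_rejected(self):
        with pytest.raises(ValidationError):
            register_scorer("not_a_contract", lambda s: 0.0)

    def test_surrogate_plugin_swap_preserves_trajectory(self):
        # two evaluators returning identical values yield identical runs
        toy = make_toy_problem(seed=3)
        pssms = toy.pssms
        specs_a = toy.objective_specs()
        specs_b = [
            ObjectiveSpec("swapped_a", "alpha",
                          lambda c: -surrogate_composite(c, pssms[0])),
            ObjectiveSpec("swapped_b", "beta",
                          lambda c: -surrogate_composite(c, pssms[1])),
        ]
        cfg = lambda: RunConfig(population_size=20, iterations=5, seed=13)
        ha = run_design(toy.problem, cfg(), specs_a)
        hb = run_design(toy.problem, cfg(), specs_b)
        for ra, rb in zip(ha.records, hb.records):
            assert [c.designed_residues for c in ra.population] == \
                   [c.designed_residues for c in rb.population]


class TestBatchEvaluator:
    def test_parallel_map_identical_to_sequential(self):
        from concurrent.futures import ThreadPoolExecutor
        toy = make_toy_problem(seed=4)
        specs = toy.objective_specs()
        seqs = ["".join(s) for s in
                np.random.default_rng(0).choice(list("ACDE"), size=(30, 6))]
        seq_eval = make_batch_evaluator(specs)
        with ThreadPoolExecutor(max_workers=4) as pool:
            par_eval = make_batch_evaluator(specs, map_fn=pool.map)
            assert np.array_equal(seq_eval(seqs), par_eval(seqs))
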