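"""Correlated component analysis and per-subject ISC against independent oracles."""

import numpy as np
import pytest

from eegisc import (
    CorrCA,
    ValidationError,
    assemble_covariances,
    fit_corrca,
    isc_against_group,
    pair_cross_covariance,
    subject_isc,
    topography_similarity,
)


# ---------------------------------------------------------------------------
# independent oracles (explicit loops over the printed definitions)
# ---------------------------------------------------------------------------

def oracle_pair_cov(xk, xl):
    d, t = xk.shape
    xbk = xk.mean(axis=1)
    xbl = xl.mean(axis=1)
    out = np.zeros((d, d))
    for s in range(t):
        out += np.outer(xk[:, s] - xbk, xl[:, s] - xbl)
    return out


def oracle_isc(tensor, v):
    """Brute-force C_ik by explicit loops over subjects and pairs."""
    n = tensor.shape[0]
    r = {(k, l): oracle_pair_cov(tensor[k], tensor[l])
         for k in range(n) for l in range(n)}
    k_comp = v.shape[1]
    c = np.zeros((n, k_comp))
    for k in range(n):
        rbk = sum(r[(k, l)] + r[(l, k)] for l in range(n) if l != k) / (n - 1)
        rwk = sum(r[(k, k)] + r[(l, l)] for l in range(n) if l != k) / (n - 1)
        for i in range(k_comp):
            vi = v[:, i]
            c[k, i] = (vi @ rbk @ vi) / (vi @ rwk @ vi)
    return c


class TestPairCrossCovariance:
    def test_self_pair_is_symmetric_psd(self, rng):
        x = rng.standard_normal((4, 50))
        r = pair_cross_covariance(x, x)
        np.testing.assert_allclose(r, r.T, atol=1e-12)
        assert np.linalg.eigvalsh(r).min() >= -1e-10

    def test_orthogonal_zero_mean_gives_zero(self):
        t = np.arange(100)
        xk = np.sin(2 * np.pi * t / 50)[None, :]
        xl = np.cos(2 * np.pi * t / 50)[None, :]
        r = pair_cross_covariance(xk, xl)
        assert np.abs(r).max() < 1e-10

    def test_toy_matches_hand_summation(self):
        xk = np.array([[1.0, 2.0, 3.0], [0.0, 1.0, 0.0]])
        xl = np.array([[2.0, 0.0, 1.0], [1.0, 1.0, 2.0]])
        np.testing.assert_allclose(
            pair_cross_covariance(xk, xl), oracle_pair_cov(xk, xl), atol=1e-12
        )

    def test_length_mismatch_raises(self, rng):
        with pytest.raises(ValidationError, match="samples"):
            pair_cross_covariance(rng.standard_normal((2, 5)),
                                  rng.standard_normal((2, 6)))


class TestAssembleCovariances:
    def test_identical_subjects_make_rb_equal_rw(self, rng):
        x = rng.standard_normal((3, 100))
        covs = assemble_covariances(np.stack([x] * 5))
        np.testing.assert_allclose(covs.Rb, covs.Rw, atol=1e-8)

    def test_two_subjects_pair_average(self, rng):
        tensor = rng.standard_normal((2, 3, 80))
        covs = assemble_covariances(tensor)
        r12 = pair_cross_covariance(tensor[0], tensor[1])
        np.testing.assert_allclose(covs.Rb, (r12 + r12.T) / 2, atol=1e-10)
        np.testing.assert_allclose(covs.Rb, covs.Rb.T, atol=1e-10)

    def test_matches_double_loop_oracle(self, rng):
        tensor = rng.standard_normal((4, 3, 60))
        covs = assemble_covariances(tensor)
        n = 4
        rb = np.zeros((3, 3))
        rw = np.zeros((3, 3))
        for k in range(n):
            rw += oracle_pair_cov(tensor[k], tensor[k])
            for l in range(n):
                if l != k:
                    rb += oracle_pair_cov(tensor[k], tensor[l])
        np.testing.assert_allclose(covs.Rw, rw / n, atol=1e-10)
        np.testing.assert_allclose(covs.Rb, rb / (n * (n - 1)), atol=1e-10)

    def test_pairwise_transpose_symmetry(self, rng):
        tensor = rng.standard_normal((3, 4, 40))
        covs = assemble_covariances(tensor)
        for k in range(3):
            for l in range(3):
                np.testing.assert_allclose(
                    covs.pair_cov[l, k], covs.pair_cov[k, l].T, atol=1e-10
                )


class TestFitCorrca:
    def test_identical_subjects_give_unit_eigenvalues(self, rng):
        x = rng.standard_normal((5, 400))
        model = CorrCA().fit(np.stack([x] * 4))
        np.testing.assert_allclose(model.eigenvalues_, 1.0, atol=1e-8)

    def test_null_cohort_top_eigenvalue_small(self, rng):
        tensor = rng.standard_normal((10, 8, 2000))
        model = CorrCA().fit(tensor)
        assert model.eigenvalues_[0] < 0.1

    def test_planted_component_recovered(self, rng):
        # one shared source mixed into all subjects at per-channel SNR 1
        n, d, t = 8, 8, 4000
        source = rng.standard_normal(t)
        m = rng.standard_normal(d)
        m /= np.linalg.norm(m)
        tensor = np.stack(
            [np.outer(m, source) + rng.standard_normal((d, t)) for _ in range(n)]
        )
        model = CorrCA().fit(tensor)
        a1 = model.forward_[:, 0]
        cos = abs(a1 @ m) / np.linalg.norm(a1)
        assert cos >= 0.95

    def test_matches_random_search_oracle(self, rng):
        # brute-force maximization of the Rayleigh quotient v'Rb v / v'Rw v
        tensor = rng.standard_normal((6, 3, 300))
        tensor += 0.5 * rng.standard_normal((1, 3, 300))  # some shared signal
        covs = assemble_covariances(tensor)
        model = fit_corrca(covs, k=3)
        v = rng.standard_normal((100_000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        quotients = np.einsum("ni,ij,nj->n", v, covs.Rb, v) / np.einsum(
            "ni,ij,nj->n", v, covs.Rw, v
        )
        best = quotients.max()
        top = model.eigenvalues_[0]
        spread = model.eigenvalues_[0] - model.eigenvalues_[-1]
        assert best <= top + 1e-9  # eigenvalue is the true maximum
        assert top - best <= 0.01 * max(spread, abs(top))

    def test_rank_deficient_rw_warns_and_truncates(self, rng):
        tensor = rng.standard_normal((4, 5, 200))
        tensor[:, 2] = 0.0  # zeroed bad channel for every subject
        with pytest.warns(UserWarning, match="effective rank"):
            model = CorrCA(n_components=5).fit(tensor)
        assert model.projections_.shape[1] == 4
        assert model.rank_used_ == 4

    def test_zeroed_channel_gets_zero_weight(self, rng):
        tensor = rng.standard_normal((4, 5, 500))
        tensor[:, 2] = 0.0
        model = CorrCA(n_components=3).fit(tensor)
        assert np.abs(model.projections_[2]).max() < 1e-10

    def test_projections_unit_norm_sign_fixed(self, rng):
        model = CorrCA().fit(rng.standard_normal((4, 6, 300)))
        norms = np.linalg.norm(model.projections_, axis=0)
        np.testing.assert_allclose(norms, 1.0, atol=1e-12)
        for i in range(model.projections_.shape[1]):
            vi = model.projections_[:, i]
            assert vi[np.argmax(np.abs(vi))] > 0


class TestSubjectIsc:
    def test_identical_subjects_have_unit_isc(self, rng):
        x = rng.standard_normal((4, 300))
        tensor = np.stack([x] * 5)
        model = CorrCA().fit(tensor)
        res = subject_isc(tensor, model)
        np.testing.assert_allclose(res.per_subject_components, 1.0, atol=1e-8)
        np.testing.assert_allclose(res.isc, 3.0, atol=1e-7)

    def test_matches_brute_force_oracle_on_integer_toy(self):
        tensor = np.array(
            [
                [[1, 2, 0, 3, 1], [0, 1, 1, 2, 0]],
                [[2, 1, 1, 0, 2], [1, 0, 2, 1, 1]],
                [[0, 3, 2, 1, 0], [2, 2, 0, 0, 1]],
            ],
            dtype=float,
        )
        model = CorrCA(n_components=2).fit(tensor)
        res = subject_isc(tensor, model)
        expected = oracle_isc(tensor, model.projections_)
        np.testing.assert_allclose(res.per_subject_components, expected, atol=1e-12)
        np.testing.assert_allclose(res.isc, expected.sum(axis=1), atol=1e-12)

    def test_component_correlations_bounded(self, rng):
        tensor = rng.standard_normal((6, 4, 100))
        model = CorrCA().fit(tensor)
        res = subject_isc(tensor, model)
        assert np.all(np.abs(res.per_subject_components) <= 1 + 1e-9)

    def test_covariance_normalization_irrelevant(self, rng):
        # C_ik are ratios: rescaling every covariance by 1/(T-1) changes nothing
        tensor = rng.standard_normal((4, 3, 120))
        model = CorrCA().fit(tensor)
        covs = assemble_covariances(tensor)
        res_raw = subject_isc(tensor, model, covs=covs)
        t = tensor.shape[2]
        scaled = type(covs)(
            pair_cov=covs.pair_cov / (t - 1), Rw=covs.Rw / (t - 1),
            Rb=covs.Rb / (t - 1),
        )
        res_scaled = subject_isc(tensor, model, covs=scaled)
        np.testing.assert_allclose(
            res_raw.per_subject_components, res_scaled.per_subject_components,
            atol=1e-12,
        )

    def test_invariance_to_common_spatial_transform(self, rng):
        # one invertible mixing applied to every subject leaves all C_ik fixed
        tensor = rng.standard_normal((5, 4, 400))
        tensor += 0.5 * rng.standard_normal((1, 4, 400))
        model = CorrCA().fit(tensor)
        base = subject_isc(tensor, model).per_subject_components
        a = rng.standard_normal((4, 4)) + 2 * np.eye(4)
        transformed = np.einsum("de,net->ndt", a, tensor)
        model_t = CorrCA().fit(transformed)
        trans = subject_isc(transformed, model_t).per_subject_components
        np.testing.assert_allclose(trans, base, atol=1e-8)

    def test_null_cohort_isc_within_replicate_band(self, rng):
        # shared-signal-free cohorts: the mean ISC must sit inside the band
        # spanned by independent null replicates (the Rest-condition property)
        def null_mean(seed):
            r = np.random.default_rng(seed)
            tensor = r.standard_normal((12, 6, 1500))
            model = CorrCA().fit(tensor)
            return subject_isc(tensor, model).isc.mean()

        reps = np.array([null_mean(1000 + i) for i in range(20)])
        probe = null_mean(4242)
        band = (reps.mean() - 5 * reps.std(), reps.mean() + 5 * reps.std())
        assert band[0] <= probe <= band[1]
        # and the whole band hugs zero on the ISC scale (|isc| <= 3)
        assert abs(reps.mean()) < 0.05

    def test_isc_monotone_in_shared_gain(self, rng):
        source = rng.standard_normal(1200)
        m = rng.standard_normal(5)
        m /= np.linalg.norm(m)
        noise = rng.standard_normal((6, 5, 1200))
        means = []
        for gain in (0.0, 0.25, 0.5, 1.0):
            tensor = gain * np.outer(m, source)[None] + noise
            model = CorrCA().fit(tensor)
            means.append(subject_isc(tensor, model).isc.mean())
        assert np.all(np.diff(means) > 0)


class TestIscAgainstGroup:
    def test_subject_identical_to_cohort_members(self, rng):
        x = rng.standard_normal((3, 200))
        cohort = np.stack([x] * 4)
        model = CorrCA().fit(cohort)
        c, total = isc_against_group(x, cohort, model)
        np.testing.assert_allclose(c, 1.0, atol=1e-8)

    def test_matches_subject_isc_row(self, rng):
        tensor = rng.standard_normal((5, 4, 300))
        model = CorrCA().fit(tensor)
        full = subject_isc(tensor, model)
        for k in range(5):
            others = np.delete(tensor, k, axis=0)
            c, total = isc_against_group(tensor[k], others, model)
            np.testing.assert_allclose(c, full.per_subject_components[k], atol=1e-12)
            np.testing.assert_allclose(total, full.isc[k], atol=1e-12)

    def test_noise_subject_falls_in_null_band(self, rng):
        source = rng.standard_normal(1000)
        m = rng.standard_normal(4)
        cohort = np.stack(
            [np.outer(m, source) + rng.standard_normal((4, 1000)) for _ in range(6)]
        )
        model = CorrCA().fit(cohort)
        nulls = [
            isc_against_group(rng.standard_normal((4, 1000)), cohort, model)[1]
            for _ in range(20)
        ]
        probe = isc_against_group(rng.standard_normal((4, 1000)), cohort, model)[1]
        lo = np.mean(nulls) - 5 * np.std(nulls)
        hi = np.mean(nulls) + 5 * np.std(nulls)
        assert lo <= probe <= hi
        # structured members score far above that band
        member = isc_against_group(cohort[0], np.stack(cohort[1:]), model)[1]
        assert member > hi


class TestTopographySimilarity:
    def test_self_similarity_is_one(self, rng):
        model = CorrCA().fit(rng.standard_normal((4, 5, 300)))
        np.testing.assert_allclose(topography_similarity(model, model), 1.0,
                                   atol=1e-12)

    def test_orthogonal_forward_models_give_zero(self, rng):
        a = CorrCA().fit(rng.standard_normal((4, 3, 300)))
        b = CorrCA().fit(rng.standard_normal((4, 3, 300)))
        a.forward_ = np.eye(3)[:, [0, 1]]
        b.forward_ = np.eye(3)[:, [2, 0]]
        sims = topography_similarity(a, b)
        np.testing.assert_allclose(sims, 0.0, atol=1e-12)

    def test_split_half_recovery(self, rng):
        # two disjoint halves of one planted-component cohort agree on C1
        n, d, t = 12, 6, 3000
        source = rng.standard_normal(t)
        m = rng.standard_normal(d)
        m /= np.linalg.norm(m)
        tensor = np.stack(
            [np.outer(m, source) + rng.standard_normal((d, t)) for _ in range(n)]
        )
        model_a = CorrCA().fit(tensor[: n // 2])
        model_b = CorrCA().fit(tensor[n // 2:])
        sims = topography_similarity(model_a, model_b)
        assert sims[0] >= 0.9

    def test_zero_forward_vector_flagged_nan(self, rng):
        a = CorrCA().fit(rng.standard_normal((4, 3, 200)))
        b = CorrCA().fit(rng.standard_normal((4, 3, 200)))
        b.forward_ = b.forward_.copy()
        b.forward_[:, 1] = 0.0
        with pytest.warns(UserWarning, match="zero-norm"):
            sims = topography_similarity(a, b)
        assert np.isnan(sims[1]) and not np.isnan(sims[0])
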