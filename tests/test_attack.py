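import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import uaplab as ul
from uaplab.attack import lp_norm, save_perturbation, load_perturbation
from uaplab.exceptions import ConfigurationError, InputError


def _image_set(images):
    return ul.ImageSet(images=np.asarray(images, dtype=float))


class TestZetaToXi:
    def test_l2_mean_norm(self):
        # two 6x6 images with L2 norms 3 (9 ones) and 5 (25 ones)
        a = np.zeros((6, 6, 1)); a.ravel()[:9] = 1.0
        b = np.zeros((6, 6, 1)); b.ravel()[:25] = 1.0
        ref = _image_set([a, b])
        assert ul.zeta_to_xi(0.04, ref, p=2) == pytest.approx(0.04 * 4.0)

    def test_zero_zeta(self):
        ref = _image_set(np.ones((2, 3, 3, 1)))
        assert ul.zeta_to_xi(0.0, ref, p=2) == 0.0

    def test_linf_of_saturated_images(self):
        ref = _image_set(np.ones((4, 3, 3, 1)))
        assert ul.zeta_to_xi(0.08, ref, p="inf") == pytest.approx(0.08)

    def test_empty_reference_rejected(self):
        with pytest.raises(InputError):
            ul.zeta_to_xi(0.1, _image_set(np.zeros((0, 2, 2, 1))), p=2)


class TestProjectLp:
    def test_linf_clip(self):
        np.testing.assert_allclose(ul.project_lp(np.array([0.5, -0.2]), 0.3, "inf"), [0.3, -0.2])

    def test_l2_rescale(self):
        np.testing.assert_allclose(ul.project_lp(np.array([3.0, 4.0]), 1.0, 2), [0.6, 0.8])

    def test_identity_inside_ball(self):
        rho = np.array([0.1, -0.05])
        np.testing.assert_array_equal(ul.project_lp(rho, 0.2, 2), rho)
        np.testing.assert_array_equal(ul.project_lp(rho, 0.2, "inf"), rho)

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(-5, 5), min_size=1, max_size=8),
        st.floats(0.01, 2.0),
        st.sampled_from([2, "inf"]),
    )
    def test_budget_always_satisfied(self, values, xi, p):
        out = ul.project_lp(np.array(values), xi, p)
        assert lp_norm(out, p) <= xi + 1e-9


class TestFgsmStep:
    def test_linf_sign(self):
        np.testing.assert_allclose(ul.fgsm_step(np.array([2.0, -1.0]), 0.1, "inf"), [0.1, -0.1])

    def test_l2_normalized(self):
        np.testing.assert_allclose(ul.fgsm_step(np.array([3.0, 4.0]), 0.1, 2), [0.06, 0.08])

    def test_zero_gradient_zero_step(self):
        np.testing.assert_array_equal(ul.fgsm_step(np.zeros(4), 0.1, 2), np.zeros(4))
        np.testing.assert_array_equal(ul.fgsm_step(np.zeros(4), 0.1, "inf"), np.zeros(4))

    def test_descend_negates(self):
        g = np.array([1.0, -2.0])
        np.testing.assert_allclose(
            ul.fgsm_step(g, 0.2, "inf", "descend"), -ul.fgsm_step(g, 0.2, "inf", "ascend")
        )

    def test_nonfinite_gradient_raises(self):
        with pytest.raises(ul.NumericalError):
            ul.fgsm_step(np.array([np.nan, 1.0]), 0.1, 2)


class TestRandomUap:
    @pytest.mark.parametrize("p", [2, "inf"])
    def test_norm_exact(self, p):
        pert = ul.random_uap((8, 8, 1), xi=0.3, p=p, seed=0)
        assert pert.norm == pytest.approx(0.3, abs=1e-6)
        assert pert.source_tag == "random"

    def test_seeded_determinism(self):
        p1 = ul.random_uap((4, 4, 1), 0.1, 2, seed=9)
        p2 = ul.random_uap((4, 4, 1), 0.1, 2, seed=9)
        np.testing.assert_array_equal(p1.rho, p2.rho)

    def test_directions_cancel(self):
        # Monte-Carlo oracle: the mean of n unit-sphere draws has expected
        # norm ~ xi/sqrt(n); with n=1000 it should be well under 0.1*xi
        xi, n = 1.0, 1000
        draws = np.stack([ul.random_uap((4, 4, 1), xi, 2, seed=s).rho for s in range(n)])
        assert np.linalg.norm(draws.mean(axis=0)) < 0.1 * xi

    def test_invalid_xi(self):
        with pytest.raises(InputError):
            ul.random_uap((2, 2, 1), 0.0, 2, seed=0)


def _softmax(z):
    e = np.exp(z - z.max())
    return e / e.sum()


def _hand_loop(w, b, images, eps, xi, p, seed, i_max=1, target=None):
    """Independent step-by-step simulation of the UAP loop for a linear model."""
    shape = images[0].shape

    def pred(x):
        return int(np.argmax(x.ravel() @ w + b))

    clean = [pred(x) for x in images]
    rho = np.zeros(shape)
    rng = np.random.default_rng(seed)
    for _ in range(i_max):
        for idx in rng.permutation(len(images)):
            adv = np.clip(images[idx] + rho, 0.0, 1.0)
            if target is None:
                if pred(adv) != clean[idx]:
                    continue
                cls, direction = clean[idx], 1.0
            else:
                if pred(adv) == target:
                    continue
                cls, direction = target, -1.0
            probs = _softmax(adv.ravel() @ w + b)
            g = (w @ (probs - np.eye(len(b))[cls])).reshape(shape)
            if p == "inf":
                step = eps * np.sign(g)
            else:
                n = np.linalg.norm(g.ravel())
                step = np.zeros(shape) if n == 0 else eps * g / n
            rho = rho + direction * step
            if p == "inf":
                rho = np.clip(rho, -xi, xi)
            elif np.linalg.norm(rho.ravel()) > xi:
                rho = rho * xi / np.linalg.norm(rho.ravel())
    return rho


class TestNontargetedLoop:
    def test_single_image_single_step_oracle(self, linear_2class):
        x = np.full((1, 1, 1), 0.3)
        X = _image_set([x])
        config = ul.AttackConfig(epsilon=0.05, p="inf", xi=1.0, seed=0)
        pert = ul.generate_uap_nontargeted(linear_2class, X, config)
        w = linear_2class.model.layers[-1].w
        b = linear_2class.model.layers[-1].b
        probs = _softmax(x.ravel() @ w + b)
        g = (w @ (probs - np.eye(2)[0])).reshape(1, 1, 1)
        np.testing.assert_allclose(pert.rho, 0.05 * np.sign(g), atol=1e-12)

    def test_three_image_hand_loop(self, linear_2class):
        rng = np.random.default_rng(5)
        images = [np.full((1, 1, 1), v) for v in (0.2, 0.55, 0.8)]
        X = _image_set(images)
        for p in ("inf", 2):
            for seed in (0, 1):
                config = ul.AttackConfig(epsilon=0.04, p=p, xi=0.1, seed=seed, i_max=2)
                pert = ul.generate_uap_nontargeted(linear_2class, X, config)
                w = linear_2class.model.layers[-1].w
                b = linear_2class.model.layers[-1].b
                expected = _hand_loop(w, b, images, 0.04, 0.1, p, seed, i_max=2)
                np.testing.assert_allclose(pert.rho, expected, atol=1e-10)

    def test_vanishing_epsilon(self, tiny_clf, tiny_data):
        train, _ = tiny_data
        config = ul.AttackConfig(epsilon=1e-8, p="inf", xi=0.1, seed=0)
        pert = ul.generate_uap_nontargeted(tiny_clf, train, config)
        assert pert.norm < 1e-5
        assert ul.fooling_rate(tiny_clf, train, pert) == 0.0
        # nothing fooled: every visit updates, none skipped
        assert pert.log["n_updates"] == len(train)
        assert pert.log["n_skipped"] == 0

    def test_seeded_reproducibility(self, tiny_clf, tiny_data):
        train, _ = tiny_data
        config = ul.AttackConfig(epsilon=0.01, p="inf", zeta=0.05, seed=3)
        p1 = ul.generate_uap_nontargeted(tiny_clf, train, config)
        p2 = ul.generate_uap_nontargeted(tiny_clf, train, config)
        np.testing.assert_array_equal(p1.rho, p2.rho)

    def test_target_class_rejected(self, tiny_clf, tiny_data):
        train, _ = tiny_data
        with pytest.raises(ConfigurationError):
            ul.generate_uap_nontargeted(
                tiny_clf, train, ul.AttackConfig(epsilon=0.1, xi=0.1, target_class=1)
            )

    def test_zeta_relation_recorded(self, tiny_clf, tiny_data):
        train, _ = tiny_data
        config = ul.AttackConfig(epsilon=0.01, p=2, zeta=0.05, seed=0)
        pert = ul.generate_uap_nontargeted(tiny_clf, train, config)
        assert pert.xi == pytest.approx(ul.zeta_to_xi(0.05, train, 2), abs=1e-6)


class TestTargetedLoop:
    def test_already_on_target_no_update(self, linear_2class):
        x = np.full((1, 1, 1), 0.9)  # predicted class 1
        X = _image_set([x])
        config = ul.AttackConfig(epsilon=0.05, p="inf", xi=1.0, seed=0, target_class=1)
        pert = ul.generate_uap_targeted(linear_2class, X, config)
        np.testing.assert_array_equal(pert.rho, 0.0)
        assert pert.log["n_updates"] == 0
        assert pert.log["n_skipped"] == 1

    def test_single_descend_step_oracle(self, linear_2class):
        x = np.full((1, 1, 1), 0.3)  # predicted class 0; target class 1
        X = _image_set([x])
        config = ul.AttackConfig(epsilon=0.05, p="inf", xi=1.0, seed=0, target_class=1)
        pert = ul.generate_uap_targeted(linear_2class, X, config)
        w = linear_2class.model.layers[-1].w
        b = linear_2class.model.layers[-1].b
        probs = _softmax(x.ravel() @ w + b)
        g = (w @ (probs - np.eye(2)[1])).reshape(1, 1, 1)
        np.testing.assert_allclose(pert.rho, -0.05 * np.sign(g), atol=1e-12)

    def test_three_image_hand_loop(self, linear_2class):
        images = [np.full((1, 1, 1), v) for v in (0.2, 0.55, 0.8)]
        X = _image_set(images)
        config = ul.AttackConfig(epsilon=0.04, p="inf", xi=0.08, seed=2, i_max=2, target_class=0)
        pert = ul.generate_uap_targeted(linear_2class, X, config)
        w = linear_2class.model.layers[-1].w
        b = linear_2class.model.layers[-1].b
        expected = _hand_loop(w, b, images, 0.04, 0.08, "inf", 2, i_max=2, target=0)
        np.testing.assert_allclose(pert.rho, expected, atol=1e-10)

    def test_success_rate_not_below_baseline(self, tiny_clf, tiny_data):
        train, test = tiny_data
        config = ul.AttackConfig(epsilon=0.01, p="inf", zeta=0.08, seed=0, target_class=0)
        pert = ul.generate_uap_targeted(tiny_clf, train, config)
        rs, base = ul.success_rate(tiny_clf, train, pert, 0)
        assert rs >= base

    def test_missing_target_rejected(self, tiny_clf, tiny_data):
        train, _ = tiny_data
        with pytest.raises(ConfigurationError):
            ul.generate_uap_targeted(tiny_clf, train, ul.AttackConfig(epsilon=0.1, xi=0.1))

    def test_invalid_target_rejected(self, tiny_clf, tiny_data):
        train, _ = tiny_data
        with pytest.raises(InputError):
            ul.generate_uap_targeted(
                tiny_clf, train, ul.AttackConfig(epsilon=0.1, xi=0.1, target_class=7)
            )


class TestBudgetInvariant:
    @pytest.mark.parametrize("p", [2, "inf"])
    @pytest.mark.parametrize("seed", [0, 1])
    def test_generated_uaps_within_budget(self, tiny_clf, tiny_data, p, seed):
        train, _ = tiny_data
        config = ul.AttackConfig(epsilon=0.02, p=p, zeta=0.05, seed=seed, i_max=2)
        pert = ul.generate_uap_nontargeted(tiny_clf, train, config)
        assert pert.norm <= pert.xi + 1e-6
        tconfig = ul.AttackConfig(epsilon=0.02, p=p, zeta=0.05, seed=seed, target_class=0)
        tpert = ul.generate_uap_targeted(tiny_clf, train, tconfig)
        assert tpert.norm <= tpert.xi + 1e-6

    def test_perturbation_validates_budget(self):
        with pytest.raises(InputError):
            ul.Perturbation(rho=np.ones((2, 2, 1)), p="inf", xi=0.5)


class TestConfigValidation:
    def test_both_zeta_and_xi_rejected(self):
        with pytest.raises(ConfigurationError):
            ul.AttackConfig(epsilon=0.1, zeta=0.04, xi=0.1).validate()

    def test_neither_zeta_nor_xi_rejected(self):
        with pytest.raises(ConfigurationError):
            ul.AttackConfig(epsilon=0.1).validate()

    def test_bad_epsilon(self):
        with pytest.raises(ConfigurationError):
            ul.AttackConfig(epsilon=0.0, xi=0.1).validate()

    def test_bad_norm_order(self):
        with pytest.raises(ConfigurationError):
            ul.AttackConfig(epsilon=0.1, xi=0.1, p=3).validate()


def test_perturbation_roundtrip(tmp_path):
    pert = ul.random_uap((4, 4, 1), 0.2, "inf", seed=1)
    path = tmp_path / "uap.npy"
    save_perturbation(pert, path)
    loaded = load_perturbation(path)
    np.testing.assert_array_equal(loaded.rho, pert.rho)
    assert loaded.p == pert.p
    assert loaded.xi == pert.xi
    assert loaded.source_tag == "random"
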