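"""Product-of-experts fusion, KL, the multimodal ELBO, and early stopping."""

import numpy as np
import pytest

from surgflow._autodiff import Tensor
from surgflow.mvae import (
    EarlyStopping,
    GaussianBelief,
    MVAEConfig,
    MultimodalVAE,
    kl_to_prior,
    mvae_loss,
    poe_combine,
)
from surgflow.simulate import BenchmarkConfig, make_benchmark

# -- beliefs and PoE ---------------------------------------------------------


def test_belief_validation():
    with pytest.raises(ValueError):
        GaussianBelief(np.zeros(3), np.array([1.0, 0.0, 1.0]))
    with pytest.raises(ValueError):
        GaussianBelief(np.array([np.inf]), np.array([1.0]))


def test_poe_prior_only_is_standard_normal():
    q = poe_combine([], include_prior=True)
    assert q.mean == pytest.approx(0.0) and q.var == pytest.approx(1.0)
    with pytest.raises(ValueError):
        poe_combine([], include_prior=False)


def test_poe_symmetric_experts_precisions_add():
    e = GaussianBelief(np.zeros(2), np.ones(2))
    q = poe_combine([e, e], include_prior=True)
    assert np.allclose(q.var, 1 / 3)
    assert np.allclose(q.mean, 0.0)


def test_poe_single_expert_closed_form():
    q = poe_combine([GaussianBelief(np.array([2.0]), np.array([1.0]))])
    assert q.var[0] == pytest.approx(0.5)
    assert q.mean[0] == pytest.approx(1.0)


def test_poe_matches_numeric_density_product_integration():
    """Oracle: multiply Gaussian densities on a 1-D grid and integrate for
    the product's mean and variance."""
    rng = np.random.default_rng(0)
    grid = np.linspace(-20, 20, 200_001)
    for _ in range(10):
        means = rng.normal(0, 2, size=3)
        variances = rng.uniform(0.3, 4.0, size=3)
        experts = [
            GaussianBelief(np.array([m]), np.array([v]))
            for m, v in zip(means, variances)
        ]
        q = poe_combine(experts, include_prior=True)
        dens = np.exp(-0.5 * grid**2)  # prior
        for m, v in zip(means, variances):
            dens = dens * np.exp(-0.5 * (grid - m) ** 2 / v)
        dens /= np.trapezoid(dens, grid)
        mu = np.trapezoid(grid * dens, grid)
        var = np.trapezoid((grid - mu) ** 2 * dens, grid)
        assert q.mean[0] == pytest.approx(mu, abs=1e-4)
        assert q.var[0] == pytest.approx(var, abs=1e-4)


def test_adding_expert_never_increases_variance():
    rng = np.random.default_rng(1)
    experts = [
        GaussianBelief(rng.normal(size=4), rng.uniform(0.2, 3.0, size=4))
        for _ in range(4)
    ]
    prev = poe_combine(experts[:1])
    for k in range(2, 5):
        cur = poe_combine(experts[:k])
        assert np.all(cur.var < prev.var)  # strictly: every expert adds precision
        prev = cur


# -- KL ----------------------------------------------------------------------


def test_kl_closed_form_values():
    assert kl_to_prior(GaussianBelief(np.zeros(5), np.ones(5))) == pytest.approx(0.0)
    assert kl_to_prior(GaussianBelief(np.array([2.0]), np.array([1.0]))) == pytest.approx(2.0)
    rng = np.random.default_rng(2)
    for _ in range(20):
        q = GaussianBelief(rng.normal(size=3), rng.uniform(0.1, 5, size=3))
        assert kl_to_prior(q) >= 0.0


# -- the multimodal loss -----------------------------------------------------


def small_mvae(demos, modalities=("visual", "kin_left", "kin_right"), **kw):
    cfg = MVAEConfig(
        modalities=modalities,
        hidden={m: (16,) for m in modalities},
        z_dim=8,
        lr=1e-3,
        min_epochs=2,
        patience=2,
        max_epochs=4,
        val_fraction=0.34,
        **kw,
    )
    return MultimodalVAE(demos, config=cfg)


@pytest.fixture(scope="module")
def tiny_demos():
    cfg = BenchmarkConfig(n_users=3, trials_per_user=1, t_target=150)
    demos, _ = make_benchmark(cfg, seed=3)
    return demos


def test_single_modality_loss_is_twice_beta_vae(tiny_demos):
    """With M = 1 the objective collapses to unimodal + joint terms over the
    same modality: exactly twice the beta-VAE loss under shared noise."""
    model = small_mvae(tiny_demos, modalities=("visual",))
    rng = np.random.default_rng(0)
    from surgflow.mvae import _MVAENet, _VAR_FLOOR

    net = _MVAENet(model.config, rng)
    x = tiny_demos[0].visual[:32]
    eps = rng.normal(size=(32, 8))
    total, breakdown = mvae_loss(net, {"visual": x}, eps=eps)

    # independent beta-VAE oracle with the same encoder/decoder weights
    mean_t, var_t = net.encoders["visual"](Tensor(x))
    mean, var = mean_t.data, var_t.data
    prec = 1.0 + 1.0 / var  # prior-fused posterior
    q_var = 1.0 / prec
    q_mean = (mean / var) * q_var
    z = q_mean + np.sqrt(q_var) * eps
    recon = net.decoders["visual"](Tensor(z)).data
    nll = np.mean(0.5 * np.sum((x - recon) ** 2, axis=1)) + 0.5 * x.shape[1] * np.log(
        2 * np.pi
    )
    kl = np.mean(np.sum(0.5 * (q_mean**2 + q_var - 1 - np.log(q_var)), axis=1))
    beta_vae = nll + model.config.beta * kl
    assert total.item() == pytest.approx(2 * beta_vae, abs=1e-6)


def test_batched_loss_equals_per_sample_loop(tiny_demos):
    model = small_mvae(tiny_demos)
    rng = np.random.default_rng(1)
    from surgflow.mvae import _MVAENet

    net = _MVAENet(model.config, rng)
    batch = {
        "visual": tiny_demos[0].visual[:8],
        "kin_left": tiny_demos[0].kin_left[:8],
        "kin_right": tiny_demos[0].kin_right[:8],
    }
    eps = rng.normal(size=(8, 8))
    total, _ = mvae_loss(net, batch, eps=eps)
    per_sample = []
    for i in range(8):
        row = {m: batch[m][i : i + 1] for m in batch}
        t_i, _ = mvae_loss(net, row, eps=eps[i : i + 1])
        per_sample.append(t_i.item())
    assert total.item() == pytest.approx(np.mean(per_sample), abs=1e-5)


def test_loss_requires_all_modalities(tiny_demos):
    model = small_mvae(tiny_demos)
    from surgflow.mvae import _MVAENet

    net = _MVAENet(model.config, np.random.default_rng(0))
    with pytest.raises(ValueError, match="missing"):
        mvae_loss(net, {"visual": tiny_demos[0].visual[:4]})


# -- early stopping rule -----------------------------------------------------


def run_stopper(losses, **kw):
    stopper = EarlyStopping(**kw)
    for epoch, loss in enumerate(losses, start=1):
        if stopper.update(epoch, loss):
            return epoch, stopper.best_epoch
    raise AssertionError("sequence exhausted without stopping")


def test_early_stopping_min_epochs_floor():
    # improvements at epochs 1..3 then flat: patience expires at 18 but the
    # floor forces continuation to epoch 25
    losses = [10, 9, 8] + [8] * 400
    stop, best = run_stopper(losses, min_epochs=25, patience=15, max_epochs=300)
    assert (stop, best) == (25, 3)


def test_early_stopping_hard_cap_on_monotone_decrease():
    losses = list(range(400, 0, -1))
    stop, best = run_stopper(losses, min_epochs=25, patience=15, max_epochs=300)
    assert stop == 300 and best == 300


def test_early_stopping_late_improvement_capped():
    # steadily improving through epoch 290, then flat: patience would run to
    # 305 but the cap stops training at 300
    losses = [300.0 - i for i in range(290)] + [100.0] * 100
    stop, best = run_stopper(losses, min_epochs=25, patience=15, max_epochs=300)
    assert stop == 300 and best == 290


def test_early_stopping_patience_in_open_interval():
    # last improvement at epoch 31 (past the floor): stop at 31 + 15 = 46
    losses = [100.0 - i for i in range(31)] + [100.0] * 100
    stop, best = run_stopper(losses, min_epochs=25, patience=15, max_epochs=300)
    assert (stop, best) == (46, 31)


# -- training + inference ----------------------------------------------------


@pytest.fixture(scope="module")
def trained(tiny_demos):
    model = small_mvae(tiny_demos)
    return model.fit(seed=0)


def test_training_respects_stopping_bounds(trained):
    assert 2 <= trained.stopped_epoch <= 4
    assert len(trained.val_history) == trained.stopped_epoch
    assert trained.best_val_loss == pytest.approx(min(trained.val_history))


def test_infer_z_deterministic_and_shaped(trained, tiny_demos):
    d = tiny_demos[0]
    z1 = trained.infer_z(d)
    z2 = trained.infer_z(d)
    assert z1.shape == (d.n_frames, 8)
    assert np.array_equal(z1, z2)
    with pytest.raises(KeyError):
        trained.infer_z(d, modalities=("audio",))
    with pytest.raises(ValueError):
        trained.infer_z(d, modalities=())


def test_subset_posterior_variance_dominates_full(trained, tiny_demos):
    d = tiny_demos[0]
    inputs = {"visual": d.visual, "kin_left": d.kin_left, "kin_right": d.kin_right}
    full = trained.posterior(inputs)
    for m in ("visual", "kin_left", "kin_right"):
        single = trained.posterior(inputs, modalities=(m,))
        assert np.all(full.var <= single.var + 1e-12)


def test_reconstruct_deterministic(trained):
    z = np.random.default_rng(0).normal(size=(5, 8))
    a = trained.reconstruct(z, "kin_left")
    b = trained.reconstruct(z, "kin_left")
    assert np.array_equal(a, b)
    assert a.shape == (5, 8)  # kin_dim of the benchmark
    with pytest.raises(KeyError):
        trained.reconstruct(z, "audio")


def test_trained_reconstruction_beats_mean_predictor(tiny_demos):
    """After training, decoding the fused posterior mean reconstructs each
    modality better than predicting its mean everywhere."""
    cfg = MVAEConfig(
        modalities=("visual", "kin_left", "kin_right"),
        hidden={m: (32,) for m in ("visual", "kin_left", "kin_right")},
        z_dim=16,
        lr=3e-3,
        min_epochs=20,
        patience=10,
        max_epochs=30,
        val_fraction=0.34,
    )
    model = MultimodalVAE(tiny_demos, config=cfg)
    res = model.fit(seed=1)
    d = tiny_demos[0]
    inputs = {"visual": d.visual, "kin_left": d.kin_left, "kin_right": d.kin_right}
    z = res.infer_z(inputs)
    for m in inputs:
        x = inputs[m]
        err = np.mean((res.reconstruct(z, m) - x) ** 2)
        baseline = np.mean((x - x.mean(axis=0)) ** 2)
        assert err < baseline


def test_validation_split_must_leave_training_data():
    cfg = BenchmarkConfig(n_users=1, trials_per_user=1, t_target=150)
    demos, _ = make_benchmark(cfg, seed=0)
    model = small_mvae(demos)
    model.config.val_fraction = 0.99
    with pytest.raises(ValueError, match="validation"):
        model.fit(seed=0)
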