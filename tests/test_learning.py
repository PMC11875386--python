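"""Conductance learning: dataset generation, objectives, gradients, SGD."""

import numpy as np
import pytest

import poregraph as pg
from poregraph.balls import partition_volumes
from poregraph.learning import (
    TrainingConfig,
    TrainingDataset,
    generate_training_data,
    grad_explicit,
    grad_implicit,
    loss_explicit,
    loss_implicit,
    sgd_train,
)


def pngm_forward(theta, x, net, a):
    c = x / net.volumes
    return x - a * (net.theta_laplacian(theta) @ c.T).T


def random_small_net(rng):
    """A connected random ball network with 5-8 balls."""
    n = int(rng.integers(5, 9))
    balls = [pg.Ball((8.0, 8.0, 8.0), float(rng.uniform(2, 3)))]
    while len(balls) < n:
        anchor = balls[int(rng.integers(len(balls)))]
        r = float(rng.uniform(2, 3))
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        center = np.asarray(anchor.center) + rng.uniform(0.4, 0.8) * (anchor.radius + r) * direction
        balls.append(pg.Ball(tuple(center), r))
    return pg.build_ball_network(balls)


@pytest.fixture(scope="module")
def path5_dataset():
    """Self-consistent recovery fixture: 5-ball path, data from known theta*."""
    balls = [pg.Ball((6.0 + 3.2 * k, 6.0, 6.0), 2.2) for k in range(5)]
    net = pg.build_ball_network(balls)
    rng = np.random.default_rng(17)
    theta_star = net.theta * rng.uniform(0.95, 1.05, size=len(net.edges))
    a = pg.coupling(100950.0, 2.0)
    x = rng.random((200, net.q))
    y = pngm_forward(theta_star, x, net, a)
    ds = TrainingDataset(x=x, y=y, dc=100950.0, record_interval=2.0)
    return net, theta_star, ds, a


@pytest.fixture(scope="module")
def tiny_net():
    balls = [pg.Ball((5.0, 6.0, 6.0), 2.5), pg.Ball((8.5, 6.0, 6.0), 2.5)]
    return pg.build_ball_network(balls)


class TestGenerateTrainingData:
    def test_pair_counting(self, tiny_net):
        ds = generate_training_data(
            tiny_net, (14, 12, 12), n_scenarios=1, sim_dt=0.05,
            record_interval=1.0, duration=2.0, seed=0,
        )
        assert len(ds) == 2

    def test_pairs_conserve_mass_and_counting_scales(self, tiny_net):
        ds = generate_training_data(
            tiny_net, (14, 12, 12), n_scenarios=3, sim_dt=0.05,
            record_interval=1.0, duration=3.0, seed=1,
        )
        assert len(ds) == 9
        assert np.allclose(ds.x.sum(axis=1), ds.y.sum(axis=1), rtol=1e-8)
        # generator bookkeeping at the reference experiment's scale:
        # 30 scenarios recorded every 10 s for 1200 s give 3600 pairs
        assert 30 * int(1200 / 10) == 3600

    def test_seeded_reproducibility(self, tiny_net):
        kwargs = dict(n_scenarios=2, sim_dt=0.05, record_interval=1.0, duration=2.0, seed=9)
        a = generate_training_data(tiny_net, (14, 12, 12), **kwargs)
        b = generate_training_data(tiny_net, (14, 12, 12), **kwargs)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)

    def test_mass_mismatch_rejected(self):
        with pytest.raises(ValueError, match="conserve"):
            TrainingDataset(x=np.ones((1, 3)), y=2 * np.ones((1, 3)), dc=1.0, record_interval=1.0)


class TestLosses:
    def test_zero_at_generating_theta(self, path5_dataset):
        net, theta_star, ds, a = path5_dataset
        assert loss_explicit(theta_star, ds.x, ds.y, net, a) <= 1e-20

    def test_two_ball_hand_computed_residual(self):
        net = pg.build_ball_network(
            [pg.Ball((6.0, 6.0, 6.0), 2.0), pg.Ball((9.0, 6.0, 6.0), 2.0)]
        ).with_volumes(np.array([2.0, 4.0]))
        theta = np.array([0.5])
        a, x, y = 0.1, np.array([[1.0, 2.0]]), np.array([[0.8, 2.2]])
        # flux out of ball 0: a*theta*(x0/v0 - x1/v1) = 0.1*0.5*(0.5-0.5) = 0
        # residuals: r = y - x + a*L@c = (-0.2, 0.2); loss = mean(r^2) = 0.04
        assert loss_explicit(theta, x, y, net, a) == pytest.approx(0.04)
        # implicit: c_y = (0.4, 0.55), flux = a*theta*(0.4-0.55) = -0.0075
        # r = x - y - a*L@c_y = (0.2 + 0.0075, -0.2 - 0.0075)
        want = np.mean([(0.2075) ** 2, (-0.2075) ** 2])
        assert loss_implicit(theta, x, y, net, a) == pytest.approx(want)

    def test_zero_theta_reduces_to_identity_scheme(self, path5_dataset):
        net, _, ds, a = path5_dataset
        want = float(np.mean((ds.y - ds.x) ** 2))
        assert loss_explicit(np.zeros(len(net.edges)), ds.x, ds.y, net, a) == pytest.approx(want)


class TestGradients:
    @pytest.mark.parametrize("seed", range(5))
    def test_finite_difference_agreement(self, seed):
        rng = np.random.default_rng(seed)
        net = random_small_net(rng)
        theta = net.theta * rng.uniform(0.5, 1.5, len(net.edges))
        x = rng.random((4, net.q)) * 10
        y = x + rng.normal(scale=0.1, size=x.shape)
        y += (x.sum(axis=1) - y.sum(axis=1))[:, None] / net.q  # restore mass balance
        a = 0.7
        for loss_fn, grad_fn in ((loss_explicit, grad_explicit), (loss_implicit, grad_implicit)):
            g = grad_fn(theta, x, y, net, a)
            h = 1e-6
            fd = np.empty_like(g)
            for e in range(len(theta)):
                tp, tm = theta.copy(), theta.copy()
                tp[e] += h
                tm[e] -= h
                fd[e] = (loss_fn(tp, x, y, net, a) - loss_fn(tm, x, y, net, a)) / (2 * h)
            assert np.abs(g - fd).max() <= 1e-5 * max(np.abs(fd).max(), 1e-12)

    def test_zero_residual_gives_zero_gradient(self, path5_dataset):
        net, theta_star, ds, a = path5_dataset
        g = grad_explicit(theta_star, ds.x, ds.y, net, a)
        assert np.abs(g).max() <= 1e-12

    def test_equal_concentrations_give_zero_gradient(self):
        net = pg.build_ball_network(
            [pg.Ball((6.0, 6.0, 6.0), 2.0), pg.Ball((9.0, 6.0, 6.0), 2.0)]
        )
        v = net.volumes
        x = np.array([v])  # concentration 1 everywhere: no flux, no sensitivity
        y = x.copy()
        for grad_fn in (grad_explicit, grad_implicit):
            assert np.abs(grad_fn(net.theta, x, y, net, 0.5)).max() == 0.0


class TestSGD:
    def test_zero_epochs_returns_initial_theta(self, path5_dataset):
        net, _, ds, _ = path5_dataset
        res = sgd_train(ds, net, TrainingConfig(epochs=0, seed=0))
        assert np.array_equal(res.theta, net.theta)
        assert len(res.probe_loss) == 1

    def test_parameter_recovery_on_path_network(self, path5_dataset):
        """Training on self-consistent data recovers the generating conductances."""
        net, theta_star, ds, a = path5_dataset
        cfg = TrainingConfig(objective="explicit", epochs=1000, seed=2)
        res = sgd_train(ds, net, cfg)
        assert res.probe_loss[0] / res.probe_loss[-1] >= 1e3
        pred = pngm_forward(res.theta, ds.x, net, a)
        rms = np.sqrt(np.mean((pred - ds.y) ** 2))
        assert rms <= 1e-4

    def test_probe_loss_decreases_early(self, path5_dataset):
        net, _, ds, _ = path5_dataset
        res = sgd_train(ds, net, TrainingConfig(objective="explicit", epochs=50, seed=3))
        assert res.probe_loss[50] < res.probe_loss[0]

    def test_learned_theta_keeps_mass_conservation(self, path5_dataset):
        net, _, ds, _ = path5_dataset
        res = sgd_train(ds, net, TrainingConfig(objective="explicit", epochs=100, seed=4))
        assert np.all(res.theta >= 0)
        b = np.linspace(1, 5, net.q)
        out = pg.pngm_explicit_step(b, net, 1000.0, 1.0, theta=res.theta)
        assert out.sum() == pytest.approx(b.sum(), rel=1e-12)

    def test_plateau_stop(self, path5_dataset):
        net, theta_star, ds, _ = path5_dataset
        cfg = TrainingConfig(objective="explicit", epochs=1000, seed=5,
                             plateau_window=50, plateau_tol=1e-10)
        res = sgd_train(ds, net, cfg, theta0=theta_star)  # already at the optimum
        assert res.epochs_run < 1000


class TestResolutionTrend:
    def test_learned_network_tracks_voxel_solution_better_at_higher_resolution(self):
        """Voxelizing the same ball chain at finer resolution improves the
        learned network's agreement with the voxel-graph solution."""
        corrs = []
        for scale in (1.0, 1.5, 2.0):
            balls = [pg.Ball((6.0 * scale + 3.2 * scale * k, 6.0 * scale, 6.0 * scale),
                             2.2 * scale) for k in range(4)]
            dims = (int(24 * scale), int(12 * scale), int(12 * scale))
            net = pg.build_ball_network(balls)
            image = pg.voxelize_balls(balls, dims)
            graph = pg.build_voxel_graph(image)
            lap = pg.laplacian(graph)
            labels = pg.map_voxels_to_balls(graph, balls)
            net_pv = net.with_volumes(partition_volumes(labels, net.q))
            ds = generate_training_data(net, dims, n_scenarios=6, sim_dt=0.05,
                                        record_interval=1.0, duration=20.0, seed=11)
            res = sgd_train(ds, net_pv, TrainingConfig(objective="implicit", epochs=400, seed=2))
            # compare after a diffusion horizon proportional to the geometry scale
            m0 = np.zeros(graph.n)
            m0[graph.node_coords[:, 0] <= np.quantile(graph.node_coords[:, 0], 0.2)] = 1.0
            m0 *= 100.0 / m0.sum()
            n_steps = int(round(40 * scale**2 / 0.05))
            p = pg.DiffusionParams(d=100950.0, dt=0.05)
            m = m0.copy()
            for _ in range(n_steps):
                m = pg.explicit_step(m, lap, p)
            prof_voxel = pg.layer_mass_profile(m, graph, "x")
            b = pg.ball_masses_from_voxels(m0, labels, net.q)
            for _ in range(n_steps):
                b = pg.pngm_explicit_step(b, net_pv, 100950.0, 0.05, theta=res.theta)
            mv = pg.uniform_voxel_masses_from_balls(b, labels, net.q)
            prof_net = pg.layer_mass_profile(mv, graph, "x")
            corrs.append(pg.intercorrelation(prof_voxel, prof_net))
        assert corrs[0] <= corrs[-1]
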