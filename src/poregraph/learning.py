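"""Learning ball-network conductances from voxel-graph diffusion data.

The voxel-graph solver is accurate but expensive; the ball network is cheap
but only as good as its edge conductances.  This module generates training
pairs ``(X_p, Y_p)`` of ball-mass distributions one recording interval apart
(computed on the voxel graph and aggregated to balls) and fits the
conductances by normalized stochastic gradient descent on one of two
objectives:

* explicit objective: squared residual of the forward-Euler ball step
  predicting ``Y_p`` from ``X_p``;
* implicit objective (default): squared residual of the backward-Euler
  relation reconstructing ``X_p`` from ``Y_p``.

Because the learned conductances are geometric quantities, they transfer to
any diffusion coefficient or time step (the scheme only sees the product
``Dc * dt * theta_ij``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .balls import BallNetwork, ball_masses_from_voxels, map_voxels_to_balls, voxelize_balls
from .diffusion import DiffusionParams, explicit_step
from .graph import build_voxel_graph, laplacian
from .synthetic import random_dom_distribution
from .units import coupling

__all__ = [
    "TrainingDataset",
    "TrainingConfig",
    "TrainingResult",
    "generate_training_data",
    "loss_explicit",
    "loss_implicit",
    "grad_explicit",
    "grad_implicit",
    "sgd_train",
]


@dataclass
class TrainingDataset:
    """Pairs of ball-mass distributions separated by one recording interval.

    ``x`` and ``y`` are ``(l, q)`` arrays; row p holds the masses of the q
    balls at a recorded time and ``record_interval`` seconds later.  Diffusion
    conserves mass, so row sums of ``x`` and ``y`` agree.
    """

    x: np.ndarray
    y: np.ndarray
    dc: float               # voxel^2/day used to generate the data
    record_interval: float  # seconds between X and Y
    seed: Optional[int] = None
    n_scenarios: Optional[int] = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.x.shape != self.y.shape or self.x.ndim != 2:
            raise ValueError("x and y must be (l, q) arrays of equal shape")
        sums_x = self.x.sum(axis=1)
        sums_y = self.y.sum(axis=1)
        if len(self.x) and not np.allclose(sums_x, sums_y, rtol=1e-8):
            raise ValueError("each (X, Y) pair must conserve total mass")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def coupling(self) -> float:
        """Dimensionless Dc*dt of the recording interval."""
        return coupling(self.dc, self.record_interval)


@dataclass
class TrainingConfig:
    """Normalized-SGD schedule.

    An "epoch" is one batch update (the convention of the training experiment
    this mirrors), not a pass over the data.  The learning rate starts at
    ``lr`` and is halved every ``lr_halving_period`` epochs.
    """

    objective: str = "implicit"   # "implicit" | "explicit"
    epochs: int = 1000
    batch_size: int = 4
    lr: float = 0.1
    lr_halving_period: int = 10
    seed: int = 0
    project_nonnegative: bool = True
    normalization: str = "sign"   # "sign" (per-coordinate) | "vector" (Euclidean)
    probe_size: int = 4
    plateau_window: Optional[int] = None   # e.g. 50; None disables plateau stop
    plateau_tol: float = 1e-12

    def validate(self) -> None:
        if self.objective not in ("implicit", "explicit"):
            raise ValueError(f"unknown objective {self.objective!r}")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")
        if self.lr <= 0 or self.lr_halving_period < 1:
            raise ValueError("lr must be > 0 and lr_halving_period >= 1")
        if self.normalization not in ("vector", "sign"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


@dataclass
class TrainingResult:
    theta: np.ndarray
    probe_loss: np.ndarray    # length epochs_run + 1; entry 0 is the initial loss
    probe_indices: np.ndarray
    epochs_run: int


def generate_training_data(
    net: BallNetwork,
    dims: tuple[int, int, int],
    n_scenarios: int = 30,
    sim_dt: float = 0.1,
    record_interval: float = 10.0,
    duration: float = 1200.0,
    dc: float = 100950.0,
    seed: int = 0,
    mass_range: tuple[float, float] = (100.0, 1000.0),
) -> TrainingDataset:
    """Generate (X, Y) ball-distribution pairs from voxel-graph diffusion runs.

    Per scenario, a random total mass is drawn and spread randomly over the
    pore voxels of the voxelized ball image; explicit voxel-graph diffusion is
    run with step ``sim_dt`` (seconds) and the state is aggregated to balls
    every ``record_interval`` seconds.  Consecutive recordings form pairs, so
    the dataset holds ``n_scenarios * (recordings - 1)`` entries.
    """
    steps_per_record = int(round(record_interval / sim_dt))
    if abs(steps_per_record * sim_dt - record_interval) > 1e-9 * record_interval:
        raise ValueError("sim_dt must divide record_interval")
    n_records = int(round(duration / record_interval))
    if n_records < 1:
        raise ValueError("duration must cover at least one recording interval")

    image = voxelize_balls(net.balls, dims)
    graph = build_voxel_graph(image)
    lap = laplacian(graph)
    labels = map_voxels_to_balls(graph, net.balls)
    p = DiffusionParams(d=dc, dt=sim_dt)
    rng = np.random.default_rng(seed)

    xs, ys = [], []
    for _ in range(n_scenarios):
        m = random_dom_distribution(graph, mass_range, rng)
        prev = ball_masses_from_voxels(m, labels, net.q)
        for _ in range(n_records):
            for _ in range(steps_per_record):
                m = explicit_step(m, lap, p)
            cur = ball_masses_from_voxels(m, labels, net.q)
            xs.append(prev)
            ys.append(cur)
            prev = cur
    return TrainingDataset(
        x=np.asarray(xs),
        y=np.asarray(ys),
        dc=dc,
        record_interval=record_interval,
        seed=seed,
        n_scenarios=n_scenarios,
    )


def _edge_diffs(arr: np.ndarray, net: BallNetwork) -> np.ndarray:
    """Per-edge concentration differences c_i - c_j for a batch, shape (l, m)."""
    c = arr / net.volumes
    i, j = net.edges.T
    return c[:, i] - c[:, j]


def _residual_explicit(theta, x, y, net, a):
    c = x / net.volumes
    flux = (net.theta_laplacian(theta) @ c.T).T  # (l, q)
    return y - x + a * flux


def _residual_implicit(theta, x, y, net, a):
    c = y / net.volumes
    flux = (net.theta_laplacian(theta) @ c.T).T
    return x - y - a * flux


def loss_explicit(theta: np.ndarray, x: np.ndarray, y: np.ndarray, net: BallNetwork, a: float) -> float:
    """Mean squared residual of the explicit ball step over a batch.

    ``a`` is the dimensionless coupling ``Dc * dt`` of the recording interval.
    Zero iff the explicit scheme with these conductances maps every X to Y.
    """
    r = _residual_explicit(theta, np.atleast_2d(x), np.atleast_2d(y), net, a)
    return float(np.mean(r * r))


def loss_implicit(theta: np.ndarray, x: np.ndarray, y: np.ndarray, net: BallNetwork, a: float) -> float:
    """Mean squared residual of the implicit ball relation over a batch."""
    r = _residual_implicit(theta, np.atleast_2d(x), np.atleast_2d(y), net, a)
    return float(np.mean(r * r))


def grad_explicit(theta: np.ndarray, x: np.ndarray, y: np.ndarray, net: BallNetwork, a: float) -> np.ndarray:
    """Per-edge gradient of :func:`loss_explicit`.

    With theta stored once per undirected edge, the residuals at both
    endpoints depend on theta_ij, giving
    ``(2a/(l q)) sum_p (c_i - c_j)(r_i - r_j)``.
    Matches central finite differences of the loss.
    """
    x = np.atleast_2d(x)
    y = np.atleast_2d(y)
    l, q = x.shape
    r = _residual_explicit(theta, x, y, net, a)
    i, j = net.edges.T
    dc = _edge_diffs(x, net)
    dr = r[:, i] - r[:, j]
    return (2.0 * a / (l * q)) * np.sum(dc * dr, axis=0)


def grad_implicit(theta: np.ndarray, x: np.ndarray, y: np.ndarray, net: BallNetwork, a: float) -> np.ndarray:
    """Per-edge gradient of :func:`loss_implicit` (note the leading minus:
    the implicit residual decreases when theta_ij grows along the gradient
    of the concentration gap)."""
    x = np.atleast_2d(x)
    y = np.atleast_2d(y)
    l, q = x.shape
    r = _residual_implicit(theta, x, y, net, a)
    i, j = net.edges.T
    dc = _edge_diffs(y, net)
    dr = r[:, i] - r[:, j]
    return (-2.0 * a / (l * q)) * np.sum(dc * dr, axis=0)


_LOSSES = {"explicit": loss_explicit, "implicit": loss_implicit}
_GRADS = {"explicit": grad_explicit, "implicit": grad_implicit}


def sgd_train(
    dataset: TrainingDataset,
    net: BallNetwork,
    cfg: TrainingConfig,
    theta0: Optional[np.ndarray] = None,
) -> TrainingResult:
    """Fit conductances by normalized stochastic gradient descent.

    Each epoch samples ``batch_size`` pairs, computes the objective gradient,
    normalizes it and steps by the scheduled learning rate, projecting onto
    nonnegative conductances.  The default normalization is per-coordinate
    (each conductance moves by +-lr, the literal reading of the normalized
    update rule); full-vector Euclidean normalization is available behind the
    flag but converges markedly slower on these objectives.  The loss is
    tracked on a fixed probe batch drawn once from the seed.

    Pass a network whose ``volumes`` are partition-cell volumes (see
    :meth:`~poregraph.balls.BallNetwork.with_volumes`) when the dataset was
    aggregated from voxel masses, so concentrations are consistent between
    the two representations.
    """
    cfg.validate()
    if len(dataset) == 0:
        raise ValueError("training dataset is empty")
    loss_fn = _LOSSES[cfg.objective]
    grad_fn = _GRADS[cfg.objective]
    a = dataset.coupling
    theta = (net.theta if theta0 is None else np.asarray(theta0, dtype=np.float64)).copy()

    rng = np.random.default_rng(cfg.seed)
    n = len(dataset)
    probe = rng.choice(n, size=min(cfg.probe_size, n), replace=False)
    xp, yp = dataset.x[probe], dataset.y[probe]

    history = [loss_fn(theta, xp, yp, net, a)]
    epochs_run = 0
    for epoch in range(cfg.epochs):
        idx = rng.choice(n, size=cfg.batch_size, replace=n < cfg.batch_size)
        g = grad_fn(theta, dataset.x[idx], dataset.y[idx], net, a)
        if cfg.normalization == "vector":
            norm = float(np.linalg.norm(g))
            step = g / norm if norm > 0 else np.zeros_like(g)
        else:
            step = np.sign(g)
        lr = cfg.lr * 0.5 ** (epoch // cfg.lr_halving_period)
        theta = theta - lr * step
        if cfg.project_nonnegative:
            np.maximum(theta, 0.0, out=theta)
        current = loss_fn(theta, xp, yp, net, a)
        if not np.isfinite(current):
            raise FloatingPointError(f"non-finite probe loss at epoch {epoch}")
        history.append(current)
        epochs_run = epoch + 1
        if (
            cfg.plateau_window is not None
            and epochs_run >= cfg.plateau_window
            and abs(history[-1] - history[-1 - cfg.plateau_window]) < cfg.plateau_tol
        ):
            break
    return TrainingResult(
        theta=theta,
        probe_loss=np.asarray(history),
        probe_indices=probe,
        epochs_run=epochs_run,
    )
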