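"""Binary particle swarm optimization over tri-channel selection masks.

Two variants of BPSO search the space of (d, 3) binary masks that decide
which projected feature vectors of each color channel are kept for
reconstruction:

* **traditional** — real-valued velocities; each velocity entry is mapped
  through the sigmoid transfer function and the corresponding position bit
  is resampled as Bernoulli(S(v)).
* **improved** — the cognitive/social random factors r1, r2 are drawn as
  integers in {0, 1}, the updated velocity is quantized with the sign
  function to {-1, 0, 1}, and the position moves additively
  (x <- clamp01(x + v)).  The discrete jump update avoids the purely
  probabilistic bit resampling that makes sigmoid BPSO prone to local
  optima in high-dimensional sparse spaces.

Both variants minimize ``fitness = mean_i sum_c ||X_i^c - Xhat_i^c||_F
+ lambda * k`` where k is the total number of selected components across
the three channels and lambda charges a sparsity penalty per component.

Update order within one iteration (fixed, for reproducibility): for each
particle in index order, draw r1 then r2 (each (d, 3)), update the
velocity, apply the transfer rule (traditional draws one more (d, 3)
uniform block for the bit resampling), evaluate the new position and
update that particle's personal best and, on strict improvement, the
global best immediately (asynchronous gbest, so later particles in the
same sweep see fresh information).  All randomness flows from a single
``numpy`` Generator seeded from the config; no global RNG state is
touched.

In the improved variant the binary position boundary is absorbing: after
``x <- clamp01(x + sgn(v))`` the stored velocity is the step actually
realized, ``x(t+1) - x(t)``.  A component pushed against the clamp
therefore carries zero velocity into the next iteration instead of an
inertia term that would pin it to the wall indefinitely; this keeps the
additive position rule exact where the move is feasible while preserving
the swarm's ability to keep exploring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

from .rgb2dpca import (
    ProjectionBasis,
    ShapeError,
    as_stack,
    frobenius_error,
    reconstruct,
    validate_mask,
)

__all__ = [
    "BPSOConfig",
    "BPSOResult",
    "Particle",
    "fitness",
    "init_swarm",
    "make_fitness",
    "run",
    "sigmoid_transfer",
    "sign_clip",
    "step_improved",
    "step_traditional",
]


@dataclass
class BPSOConfig:
    """Swarm hyperparameters.

    Defaults follow the reference configuration: swarm of 50 particles,
    100 iterations, inertia 1.5, cognitive weight 2, social weight 1,
    sparsity penalty 0.001.
    """

    swarm_size: int = 50
    iterations: int = 100
    inertia: float = 1.5
    cognitive: float = 2.0
    social: float = 1.0
    sparsity: float = 0.001
    variant: Literal["traditional", "improved"] = "improved"
    seed: int = 0
    velocity_init: Literal["random_pm1", "zero"] = "random_pm1"
    fitness_subset: int | None = None

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if min(self.inertia, self.cognitive, self.social) <= 0:
            raise ValueError("inertia, cognitive and social weights must be > 0")
        if self.sparsity < 0:
            raise ValueError("sparsity penalty must be >= 0")
        if self.variant not in ("traditional", "improved"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.velocity_init not in ("random_pm1", "zero"):
            raise ValueError(f"unknown velocity_init {self.velocity_init!r}")


@dataclass
class Particle:
    """One swarm member: binary position, velocity, and personal best."""

    position: np.ndarray  # (d, 3) uint8
    velocity: np.ndarray  # (d, 3) float (traditional) or small ints (improved)
    pbest: np.ndarray  # (d, 3) uint8
    pbest_fitness: float


@dataclass
class BPSOResult:
    """Outcome of a swarm run."""

    gbest: np.ndarray
    gbest_fitness: float
    trace: list[float] = field(default_factory=list)
    evaluations: int = 0


# ---------------------------------------------------------------------------
# fitness
# ---------------------------------------------------------------------------

def fitness(
    mask: np.ndarray,
    stack: np.ndarray,
    basis: ProjectionBasis,
    sparsity: float,
    projections: np.ndarray | None = None,
) -> float:
    """Reconstruction-plus-sparsity objective for one mask.

    Mean over the stack of the summed per-channel Frobenius reconstruction
    errors, plus ``sparsity`` times the number of set bits (counted across
    all three channels).  ``projections`` may carry precomputed ``(N, H, W,
    3)`` projection coefficients to avoid reprojecting per call.
    """
    stack = as_stack(stack)
    mask = validate_mask(mask, basis.dim)
    if projections is None:
        projections = np.einsum("nhwc,wjc->nhjc", stack, basis.vectors)
    total = 0.0
    for img, proj in zip(stack, projections):
        recon = reconstruct(proj, basis, mask)
        _, summed = frobenius_error(img, recon)
        total += summed
    value = total / stack.shape[0] + sparsity * int(mask.sum())
    if not np.isfinite(value):
        raise ValueError("fitness is non-finite")
    return float(value)


def make_fitness(
    stack: np.ndarray,
    basis: ProjectionBasis,
    sparsity: float,
    subset: int | None = None,
) -> Callable[[np.ndarray], float]:
    """Build a fast evaluator equivalent to :func:`fitness`.

    Because the basis columns are orthonormal, the residual of a masked
    reconstruction is the sum of the *excluded* rank-one terms and its
    Frobenius norm is the root-sum of the excluded projection-column
    energies.  Precomputing those energies once per stack reduces each
    evaluation to a masked sum, which is what makes exhaustive enumeration
    and long swarm runs affordable.  ``subset`` restricts evaluation to the
    first n stack images.
    """
    stack = as_stack(stack)
    if subset is not None:
        if subset < 1:
            raise ValueError("fitness_subset must be >= 1")
        stack = stack[:subset]
    proj = np.einsum("nhwc,wjc->nhjc", stack, basis.vectors)
    energies = np.einsum("nhjc,nhjc->njc", proj, proj)  # ||Y_j^c||^2 per image

    def evaluate(mask: np.ndarray) -> float:
        mask = np.asarray(mask)
        excluded = energies * (1 - mask)[np.newaxis, :, :]
        per_channel = np.sqrt(excluded.sum(axis=1))  # (N, 3)
        value = per_channel.sum(axis=1).mean() + sparsity * int(mask.sum())
        if not np.isfinite(value):
            raise ValueError("fitness is non-finite")
        return float(value)

    return evaluate


# ---------------------------------------------------------------------------
# transfer functions
# ---------------------------------------------------------------------------

def sigmoid_transfer(v):
    """Sigmoid transfer S(v) = 1 / (1 + exp(-v)), elementwise, in (0, 1)."""
    v = np.asarray(v, dtype=np.float64)
    if not np.all(np.isfinite(v)):
        raise ValueError("velocity must be finite")
    with np.errstate(over="ignore"):  # exp overflow saturates correctly to 0
        out = 1.0 / (1.0 + np.exp(-v))
    return float(out) if out.ndim == 0 else out


def sign_clip(v):
    """Sign quantization: -1 if v < 0, 0 if v = 0, +1 if v > 0 (elementwise)."""
    v = np.asarray(v, dtype=np.float64)
    if not np.all(np.isfinite(v)):
        raise ValueError("velocity must be finite")
    out = np.sign(v).astype(np.int64)
    return int(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# swarm mechanics
# ---------------------------------------------------------------------------

def init_swarm(
    config: BPSOConfig,
    d: int,
    rng: np.random.Generator | None = None,
    fitness_fn: Callable[[np.ndarray], float] | None = None,
) -> list[Particle]:
    """Create the initial swarm.

    Positions are i.i.d. uniform bits; velocities are i.i.d. uniform over
    {-1, 0, 1} (or all-zero with ``velocity_init='zero'``).  If a fitness
    function is given, personal bests are scored immediately; otherwise
    they carry +inf until first evaluation.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    particles = []
    for _ in range(config.swarm_size):
        position = rng.integers(0, 2, size=(d, 3)).astype(np.uint8)
        if config.velocity_init == "zero":
            velocity = np.zeros((d, 3))
        else:
            velocity = rng.integers(-1, 2, size=(d, 3)).astype(np.float64)
        fit = fitness_fn(position) if fitness_fn is not None else np.inf
        particles.append(
            Particle(
                position=position,
                velocity=velocity,
                pbest=position.copy(),
                pbest_fitness=float(fit),
            )
        )
    return particles


def _velocity_update(
    p: Particle,
    gbest: np.ndarray,
    config: BPSOConfig,
    r1: np.ndarray,
    r2: np.ndarray,
) -> np.ndarray:
    pos = p.position.astype(np.float64)
    return (
        config.inertia * p.velocity
        + config.cognitive * r1 * (p.pbest.astype(np.float64) - pos)
        + config.social * r2 * (gbest.astype(np.float64) - pos)
    )


def step_traditional(
    particles: Sequence[Particle],
    gbest: np.ndarray,
    gbest_fitness: float,
    fitness_fn: Callable[[np.ndarray], float],
    config: BPSOConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, int]:
    """One sigmoid-BPSO iteration; returns (gbest, gbest_fitness, n_evals)."""
    shape = particles[0].position.shape
    for p in particles:
        r1 = rng.uniform(size=shape)
        r2 = rng.uniform(size=shape)
        p.velocity = _velocity_update(p, gbest, config, r1, r2)
        prob = sigmoid_transfer(p.velocity)
        p.position = (rng.uniform(size=shape) < prob).astype(np.uint8)
        fit = fitness_fn(p.position)
        if fit < p.pbest_fitness:
            p.pbest = p.position.copy()
            p.pbest_fitness = fit
            if fit < gbest_fitness:
                gbest = p.position.copy()
                gbest_fitness = fit
    return gbest, gbest_fitness, len(particles)


def step_improved(
    particles: Sequence[Particle],
    gbest: np.ndarray,
    gbest_fitness: float,
    fitness_fn: Callable[[np.ndarray], float],
    config: BPSOConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, int]:
    """One improved-BPSO iteration with integer r-draws and sign-clipped velocity.

    After ``x <- x + sgn(v)`` the position is clamped back to {0, 1}: a bit
    at 1 pushed upward stays 1 and a bit at 0 pushed downward stays 0, the
    only reading under which the additive update keeps positions binary.
    The velocity carried to the next iteration is the realized step
    ``x(t+1) - x(t)`` (absorbing boundary): a clamped component expends
    its velocity at the wall rather than accumulating inertia there.
    """
    shape = particles[0].position.shape
    for p in particles:
        r1 = rng.integers(0, 2, size=shape).astype(np.float64)
        r2 = rng.integers(0, 2, size=shape).astype(np.float64)
        step = sign_clip(_velocity_update(p, gbest, config, r1, r2))
        new_position = np.clip(p.position.astype(np.int64) + step, 0, 1).astype(np.uint8)
        p.velocity = (new_position.astype(np.int64) - p.position.astype(np.int64)).astype(
            np.float64
        )
        p.position = new_position
        fit = fitness_fn(p.position)
        if fit < p.pbest_fitness:
            p.pbest = p.position.copy()
            p.pbest_fitness = fit
            if fit < gbest_fitness:
                gbest = p.position.copy()
                gbest_fitness = fit
    return gbest, gbest_fitness, len(particles)


def _refresh_gbest(
    particles: Sequence[Particle], gbest: np.ndarray, gbest_fitness: float
) -> tuple[np.ndarray, float]:
    # strict improvement only: stable under fitness ties
    for p in particles:
        if p.pbest_fitness < gbest_fitness:
            gbest = p.pbest.copy()
            gbest_fitness = p.pbest_fitness
    return gbest, gbest_fitness


def run(
    stack: np.ndarray,
    basis: ProjectionBasis,
    config: BPSOConfig,
    callback: Callable[[int, Sequence[Particle], np.ndarray, float], None] | None = None,
) -> BPSOResult:
    """Run the configured BPSO variant on a training stack.

    The optional ``callback(iteration, particles, gbest, gbest_fitness)``
    is invoked after every iteration (for tracing or invariant checks).
    Fully reproducible: the result is a pure function of (stack, basis,
    config).
    """
    stack = as_stack(stack)
    if stack.shape[2] != basis.dim:
        raise ShapeError(
            f"stack width {stack.shape[2]} does not match basis dimension {basis.dim}"
        )
    rng = np.random.default_rng(config.seed)
    fitness_fn = make_fitness(stack, basis, config.sparsity, config.fitness_subset)
    particles = init_swarm(config, basis.dim, rng, fitness_fn)

    gbest = particles[0].pbest.copy()
    gbest_fitness = particles[0].pbest_fitness
    gbest, gbest_fitness = _refresh_gbest(particles, gbest, gbest_fitness)

    step = step_improved if config.variant == "improved" else step_traditional
    trace: list[float] = []
    evaluations = 0
    for t in range(config.iterations):
        gbest, gbest_fitness, n_evals = step(
            particles, gbest, gbest_fitness, fitness_fn, config, rng
        )
        evaluations += n_evals
        trace.append(gbest_fitness)
        if callback is not None:
            callback(t, particles, gbest, gbest_fitness)
    return BPSOResult(
        gbest=gbest, gbest_fitness=gbest_fitness, trace=trace, evaluations=evaluations
    )
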