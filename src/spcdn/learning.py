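"""Hebbian dictionary learning for the SPC network.

Training alternates a response phase with a learning step: for each batch of
image patches the network responses are iterated to (near) equilibrium with
the weights frozen, then the weights receive one Hebbian update

    A <- A + eta_a * mean_batch(e s^T),        e = x - A s,

followed by L2 normalization of every column.  The per-batch update (one
weight step per many response iterations) realizes the slow-weight /
fast-response timescale separation the model assumes; column normalization
plays the role of homeostatic synaptic scaling and keeps basis vectors from
growing without bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .homeostasis import HomeostasisSpec
from .network import IterationConfig, SPCNetwork, iterate_batch

__all__ = [
    "TrainingConfig",
    "TrainingReport",
    "hebbian_update",
    "normalize_columns",
    "init_weights",
    "train",
]

#: responses below this fraction of the batch max count as inactive (sparsity)
_SPARSITY_EPS = 1e-3


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the training loop.

    ``eta_a`` is the Hebbian learning rate (applied to the batch-mean outer
    product, so it is batch-size independent); ``n_batches`` counts weight
    updates; the nested ``iteration`` config drives the response phase.
    ``eta_a`` is much larger than the response rate ``iteration.eta_s`` —
    the slow timescale of the weights comes from updating them once per
    batch of fully iterated responses, not from a small rate.
    """

    eta_a: float = 0.2
    n_batches: int = 5000
    batch_size: int = 100
    n_units: int = 64
    patch_edge: int = 16
    seed: int = 0
    iteration: IterationConfig = field(
        default_factory=lambda: IterationConfig(eta_s=0.02, max_iter=400, tol=1e-5)
    )

    def __post_init__(self) -> None:
        if not self.eta_a > 0:
            raise ValueError("eta_a must be > 0")
        if self.n_batches < 0 or self.batch_size < 1 or self.n_units < 1:
            raise ValueError("invalid counts in TrainingConfig")


@dataclass
class TrainingReport:
    """Per-batch telemetry of a training run."""

    mean_reconstruction_error: np.ndarray  # per batch, mean ||e||^2 per patch
    mean_sparsity: np.ndarray  # per batch, fraction of near-zero responses
    final_column_norms: np.ndarray
    clamp_count: int = 0
    nonconverged_batches: int = 0
    rescued_columns: int = 0


def normalize_columns(A: np.ndarray, rng: np.random.Generator | None = None) -> tuple[np.ndarray, int]:
    """Scale every column of A to unit L2 norm.

    A column that has collapsed to zero cannot be normalized; it is
    re-initialized from a random unit-sphere draw (a rare dead-unit rescue
    under nonnegative responses) and counted.  Returns ``(A, n_rescued)``.
    """
    A = np.asarray(A, dtype=float).copy()
    norms = np.linalg.norm(A, axis=0)
    dead = norms == 0.0
    n_rescued = int(np.count_nonzero(dead))
    if n_rescued:
        if rng is None:
            raise ValueError(
                f"{n_rescued} all-zero column(s) and no rng provided for rescue"
            )
        fresh = rng.standard_normal((A.shape[0], n_rescued))
        A[:, dead] = fresh
        norms = np.linalg.norm(A, axis=0)
    return A / norms, n_rescued


def hebbian_update(
    A: np.ndarray,
    e_batch: np.ndarray,
    s_batch: np.ndarray,
    eta_a: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One Hebbian step A + eta_a * mean(e s^T), then column normalization."""
    e_batch = np.atleast_2d(np.asarray(e_batch, dtype=float))
    s_batch = np.atleast_2d(np.asarray(s_batch, dtype=float))
    if e_batch.shape[0] != A.shape[0] or s_batch.shape[0] != A.shape[1]:
        raise ValueError(
            f"dimension mismatch: A {A.shape}, e {e_batch.shape}, s {s_batch.shape}"
        )
    if e_batch.shape[1] != s_batch.shape[1]:
        raise ValueError("error and response batches differ in size")
    B = e_batch.shape[1]
    A_new = A + eta_a * (e_batch @ s_batch.T) / B
    A_new, _ = normalize_columns(A_new, rng)
    return A_new


def init_weights(L: int, M: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded Gaussian initialization with unit-norm columns."""
    A, _ = normalize_columns(rng.standard_normal((L, M)))
    return A


def train(
    stimulus_source,
    tcfg: TrainingConfig,
    hspec: HomeostasisSpec,
    nonnegative: bool = True,
) -> tuple[SPCNetwork, TrainingReport]:
    """Train an SPC network on image patches.

    Parameters
    ----------
    stimulus_source
        Either a callable ``(batch_size, rng) -> L x batch_size array`` or an
        :class:`~spcdn.stimuli.ImageSet`, from which patches are sampled.
    tcfg
        Training hyperparameters; ``tcfg.seed`` drives weight initialization
        and patch sampling, so runs are bit-reproducible.
    hspec
        Homeostasis function shared by all units.
    """
    from .stimuli import ImageSet  # local import to avoid cycle at module load

    L = tcfg.patch_edge**2
    rng = np.random.default_rng(tcfg.seed)

    if isinstance(stimulus_source, ImageSet):
        imset = stimulus_source

        def draw(batch_size: int, rng: np.random.Generator) -> np.ndarray:
            from .stimuli import sample_patches

            return sample_patches(
                imset, tcfg.patch_edge, batch_size, seed=int(rng.integers(2**31))
            )

        source = draw
    else:
        source = stimulus_source

    A = init_weights(L, tcfg.n_units, rng)
    recon_err = np.empty(tcfg.n_batches)
    sparsity = np.empty(tcfg.n_batches)
    clamp_total = 0
    nonconverged = 0
    rescued = 0
    for b in range(tcfg.n_batches):
        X = np.asarray(source(tcfg.batch_size, rng), dtype=float)
        if X.shape[0] != L:
            raise ValueError(f"stimulus source yielded {X.shape[0]}-d patches, expected {L}")
        net = SPCNetwork(A=A, hspec=hspec, nonnegative=nonnegative)
        S, conv, _, clamps = iterate_batch(net, X, tcfg.iteration)
        clamp_total += clamps
        nonconverged += int(np.count_nonzero(~conv))
        E = X - A @ S
        recon_err[b] = float((E**2).sum(axis=0).mean())
        smax = S.max()
        sparsity[b] = (
            float((S <= _SPARSITY_EPS * smax).mean()) if smax > 0 else 1.0
        )
        A = A + tcfg.eta_a * (E @ S.T) / tcfg.batch_size
        A, n_resc = normalize_columns(A, rng)
        rescued += n_resc
    net = SPCNetwork(A=A, hspec=hspec, nonnegative=nonnegative)
    report = TrainingReport(
        mean_reconstruction_error=recon_err,
        mean_sparsity=sparsity,
        final_column_norms=np.linalg.norm(A, axis=0),
        clamp_count=clamp_total,
        nonconverged_batches=nonconverged,
        rescued_columns=rescued,
    )
    return net, report
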