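"""Compressed-sensing benchmark: sparse binary sensing, CS-ResNet, PRD.

A length-N frame x is acquired as y = phi @ x with a sparse binary
measurement matrix phi of shape (M, N); the compression ratio is CR = M/N.
Reconstruction starts from the pseudoinverse lift x0 = pinv(phi) @ y and is
refined by a 1-D residual convolutional network (CS-ResNet): a 16-channel
stem, two residual blocks of six dilated convolutions each
(filters 32/64/128/64/32/16, kernels 7/7/5/5/3/3, dilation 2, ELU, "same"
padding, identity skip), a single-channel head convolution and a fully
connected output layer.  Quality is scored by the percentage RMS distortion

    PRD = 100 * ||x_hat - x||_2 / ||x||_2   (lower is better).

The augmentation benchmark trains the reconstructor on the real training
frames plus growing fractions of generated frames and tabulates mean test
PRD per compression ratio, with "no-augmentation minus augmented"
improvement deltas truncated to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from . import autodiff as ad
from . import nn
from .autodiff import Tensor, backward
from .models import SpecError
from .preprocess import DataError, FrameSet


@dataclass
class MeasurementMatrix:
    """Sparse binary sensing matrix with its precomputed pseudoinverse."""

    phi: np.ndarray
    pinv: np.ndarray
    M: int
    N: int
    ones_per_column: int
    seed: int

    @property
    def cr(self) -> float:
        return self.M / self.N

    def save(self, path) -> None:
        np.savez(path, phi=self.phi, pinv=self.pinv, M=self.M, N=self.N,
                 ones_per_column=self.ones_per_column, seed=self.seed)

    @staticmethod
    def load(path) -> "MeasurementMatrix":
        z = np.load(path)
        return MeasurementMatrix(phi=z["phi"], pinv=z["pinv"], M=int(z["M"]),
                                 N=int(z["N"]), ones_per_column=int(z["ones_per_column"]),
                                 seed=int(z["seed"]))


def build_measurement_matrix(M: int, N: int = 500, ones_per_column: int = 4,
                             seed: int = 0) -> MeasurementMatrix:
    """Each column receives ``ones_per_column`` ones at random distinct rows.

    Rows are drawn from a balanced pool (every row repeated as evenly as
    possible), the standard construction for sparse binary sensing: row
    weights stay near-uniform, and the M = N, one-per-column case yields an
    exact permutation matrix.
    """
    if not 1 <= M <= N:
        raise DataError(f"need 1 <= M <= N, got M={M}, N={N}")
    if not 1 <= ones_per_column <= M:
        raise DataError(f"ones_per_column={ones_per_column} infeasible for M={M}")
    rng = np.random.default_rng(seed)
    k = ones_per_column
    reps = int(np.ceil(k * N / M))
    pool = np.concatenate([rng.permutation(M) for _ in range(reps)])[: k * N]
    assign = pool.reshape(N, k)
    # resolve within-column duplicates by swapping with entries elsewhere
    for _ in range(10 * N):
        dirty = [j for j in range(N) if len(set(assign[j])) < k]
        if not dirty:
            break
        for j in dirty:
            seen: set[int] = set()
            for i in range(k):
                if assign[j, i] in seen:
                    j2, i2 = rng.integers(N), rng.integers(k)
                    assign[j, i], assign[j2, i2] = assign[j2, i2], assign[j, i]
                else:
                    seen.add(assign[j, i])
    else:  # pragma: no cover - fallback for pathological densities
        for j in range(N):
            assign[j] = rng.choice(M, size=k, replace=False)
    phi = np.zeros((M, N))
    for j in range(N):
        phi[assign[j], j] = 1.0
    return MeasurementMatrix(phi=phi, pinv=np.linalg.pinv(phi), M=M, N=N,
                             ones_per_column=ones_per_column, seed=seed)


def compress(x: np.ndarray, mm: MeasurementMatrix) -> np.ndarray:
    """y = phi @ x for a single frame or a (batch, N) matrix."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] != mm.N:
        raise DataError(f"frame length {x.shape[-1]} != N={mm.N}")
    return x @ mm.phi.T


def pseudoinverse_lift(y: np.ndarray, mm: MeasurementMatrix) -> np.ndarray:
    """x0 = pinv(phi) @ y — the linear initial reconstruction."""
    y = np.asarray(y, dtype=np.float64)
    if y.shape[-1] != mm.M:
        raise DataError(f"measurement length {y.shape[-1]} != M={mm.M}")
    return y @ mm.pinv.T


def prd(x, x_hat) -> float:
    """Percentage root-mean-square distortion, 100*||x_hat-x||/||x||."""
    x = np.asarray(x, dtype=np.float64).ravel()
    x_hat = np.asarray(x_hat, dtype=np.float64).ravel()
    if x.shape != x_hat.shape:
        raise DataError("length mismatch")
    nx = np.linalg.norm(x)
    if nx == 0:
        raise DataError("zero reference norm")
    return float(100.0 * np.linalg.norm(x_hat - x) / nx)


def mean_prd(X, X_hat) -> float:
    X, X_hat = np.atleast_2d(X), np.atleast_2d(X_hat)
    return float(np.mean([prd(a, b) for a, b in zip(X, X_hat)]))


# -- CS-ResNet ---------------------------------------------------------------

@dataclass
class CSResNetSpec:
    signal_len: int = 500
    stem_filters: int = 16
    stem_kernel: int = 3
    blocks: int = 2
    block_filters: tuple[int, ...] = (32, 64, 128, 64, 32, 16)
    block_kernels: tuple[int, ...] = (7, 7, 5, 5, 3, 3)
    dilation: int = 2
    head_kernel: int = 3

    def validate(self) -> "CSResNetSpec":
        if len(self.block_filters) != len(self.block_kernels):
            raise SpecError("block_filters and block_kernels lengths differ")
        if self.block_filters[-1] != self.stem_filters:
            raise SpecError(
                "last block filter count must equal stem_filters so the identity "
                "skip addition is well-formed")
        if any(k % 2 == 0 for k in (self.stem_kernel, self.head_kernel) + tuple(self.block_kernels)):
            raise SpecError("kernels must be odd for symmetric same-padding")
        return self


class _ResidualBlock(nn.Module):
    def __init__(self, spec: CSResNetSpec, rng: np.random.Generator):
        super().__init__()
        layers = []
        in_ch = spec.stem_filters
        for f, k in zip(spec.block_filters, spec.block_kernels):
            pad = spec.dilation * (k - 1) // 2
            layers += [nn.Conv1d(in_ch, f, k, rng, stride=1, padding=pad,
                                 dilation=spec.dilation), nn.ELU()]
            in_ch = f
        self.body = nn.Sequential(*layers)

    def forward(self, x: Tensor) -> Tensor:
        return ad.add(self.body(x), x)


class CSResNet(nn.Module):
    """Maps a lifted (batch, N) input to a refined (batch, N) reconstruction."""

    def __init__(self, spec: CSResNetSpec, seed: int = 0):
        super().__init__()
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.stem = nn.Sequential(
            nn.Reshape((1, spec.signal_len)),
            nn.Conv1d(1, spec.stem_filters, spec.stem_kernel, rng,
                      padding=(spec.stem_kernel - 1) // 2),
            nn.ELU(),
        )
        for b in range(spec.blocks):
            setattr(self, f"block{b}", _ResidualBlock(spec, rng))
        out_fc = nn.Dense(spec.signal_len, spec.signal_len, rng)
        # zero-initialized output layer: at init the network is exactly the
        # pseudoinverse-lift baseline (global skip), and training refines it
        out_fc.W.data[:] = 0.0
        self.head = nn.Sequential(
            nn.Conv1d(spec.stem_filters, 1, spec.head_kernel, rng,
                      padding=(spec.head_kernel - 1) // 2),
            nn.Flatten(),
            out_fc,
        )

    def forward(self, x: Tensor) -> Tensor:
        h = self.stem(x)
        for b in range(self.spec.blocks):
            h = getattr(self, f"block{b}")(h)
        return ad.add(self.head(h), x)  # global residual: refine the lift


def build_cs_resnet(spec: CSResNetSpec | None = None, seed: int = 0) -> CSResNet:
    return CSResNet(spec or CSResNetSpec(), seed=seed)


class PlainCNNReconstructor(nn.Module):
    """Synthetic stand-in comparison network: the CS-ResNet stem, one block's
    worth of convolutions without the identity skips, and the same head.
    It is NOT a faithful copy of any previously published reconstructor."""

    def __init__(self, spec: CSResNetSpec, seed: int = 0):
        super().__init__()
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        layers = [nn.Reshape((1, spec.signal_len)),
                  nn.Conv1d(1, spec.stem_filters, spec.stem_kernel, rng,
                            padding=(spec.stem_kernel - 1) // 2), nn.ELU()]
        in_ch = spec.stem_filters
        for f, k in zip(spec.block_filters, spec.block_kernels):
            pad = spec.dilation * (k - 1) // 2
            layers += [nn.Conv1d(in_ch, f, k, rng, padding=pad,
                                 dilation=spec.dilation), nn.ELU()]
            in_ch = f
        layers += [nn.Conv1d(in_ch, 1, spec.head_kernel, rng,
                             padding=(spec.head_kernel - 1) // 2),
                   nn.Flatten(), nn.Dense(spec.signal_len, spec.signal_len, rng)]
        self.net = nn.Sequential(*layers)

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x)


class CSResNetReconstructor(BaseEstimator):
    """Sklearn-style wrapper: fit on frames, predict reconstructions.

    ``fit(X)`` compresses each frame with the measurement matrix, lifts it by
    the pseudoinverse and trains the refiner to regress the original frame
    under mean-squared error (Adam).  ``predict(X)`` runs the full
    compress -> lift -> refine path; ``prd_score(X)`` reports mean PRD.
    """

    def __init__(self, matrix: MeasurementMatrix | None = None,
                 spec: CSResNetSpec | None = None, architecture: str = "resnet",
                 epochs: int = 30, batch_size: int = 64, lr: float = 1e-3,
                 adam_betas: tuple[float, float] = (0.9, 0.999), seed: int = 0):
        self.matrix = matrix
        self.spec = spec
        self.architecture = architecture
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.adam_betas = adam_betas
        self.seed = seed

    def _build(self, signal_len: int) -> nn.Module:
        spec = self.spec or CSResNetSpec(signal_len=signal_len)
        if spec.signal_len != signal_len:
            raise SpecError(f"spec signal_len {spec.signal_len} != data length {signal_len}")
        if self.architecture == "resnet":
            return CSResNet(spec, seed=self.seed)
        if self.architecture == "plain_cnn":
            return PlainCNNReconstructor(spec, seed=self.seed)
        raise SpecError(f"unknown architecture {self.architecture!r}")

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[0] == 0:
            raise DataError("empty training set")
        mm = self.matrix or build_measurement_matrix(X.shape[1] // 2, X.shape[1],
                                                     seed=self.seed)
        if mm.N != X.shape[1]:
            raise DataError(f"matrix N={mm.N} != frame length {X.shape[1]}")
        net = self._build(X.shape[1])
        lifted = pseudoinverse_lift(compress(X, mm), mm)
        rng = np.random.default_rng(self.seed)
        opt = nn.Adam(net.parameters(), self.lr, self.adam_betas)
        n = X.shape[0]
        bs = min(self.batch_size, n)
        history = []
        for _ in range(self.epochs):
            perm = rng.permutation(n)
            losses = []
            for s in range(0, n - bs + 1, bs):
                idx = perm[s:s + bs]
                pred = net(Tensor(lifted[idx]))
                err = ad.add(pred, Tensor(-X[idx]))
                loss = ad.tmean(ad.power(err, 2.0))
                opt.zero_grad()
                backward(loss, net.parameters(), accumulate=True)
                opt.step()
                losses.append(loss.item())
            history.append(float(np.mean(losses)))
        self.network_ = net
        self.matrix_ = mm
        self.loss_history_ = history
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "network_"):
            raise RuntimeError("fit the reconstructor first")
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        lifted = pseudoinverse_lift(compress(X, self.matrix_), self.matrix_)
        with ad.no_grad():
            return self.network_(Tensor(lifted)).data

    def prd_score(self, X) -> float:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        return mean_prd(X, self.predict(X))


# -- augmentation benchmark --------------------------------------------------

def truncate2(x: float) -> float:
    """Truncate (not round) to 2 decimals; the convention used for deltas."""
    return float(np.floor(abs(x) * 100 + 1e-9) / 100 * np.sign(x))


@dataclass
class PRDTable:
    """Mean test PRD per compression ratio and augmentation fraction.

    ``rows`` maps CR (percent) to {fraction -> PRD percent}; fraction 0 is
    the unaugmented baseline.  ``deltas`` holds baseline-minus-augmented
    improvements truncated to two decimals.  ``meta`` records the training
    configuration and sensing density for reproducibility.
    """

    rows: dict[int, dict[int, float]]
    deltas: dict[int, dict[int, float]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def compute_deltas(self) -> "PRDTable":
        self.deltas = {
            cr: {f: truncate2(by_frac[0] - v)
                 for f, v in by_frac.items() if f != 0}
            for cr, by_frac in self.rows.items()
        }
        return self

    def delta_range(self, crs=None) -> tuple[float, float]:
        """(min, max) delta over the given CRs (all CRs by default)."""
        vals = [v for cr, d in self.deltas.items()
                if crs is None or cr in crs for v in d.values()]
        return (min(vals), max(vals))

    def averaged_delta_range(self, crs) -> tuple[float, float]:
        """Range of per-fraction deltas averaged over the given CRs, truncated."""
        fracs = sorted(next(iter(self.deltas.values())).keys())
        means = [float(np.mean([self.rows[cr][0] - self.rows[cr][f] for cr in crs]))
                 for f in fracs]
        return (truncate2(min(means)), truncate2(max(means)))

    def to_frame(self):
        import pandas as pd
        df = pd.DataFrame(self.rows).T.sort_index(ascending=False)
        df.index.name = "cr_percent"
        df.columns = [f"add_{c}pct" if c else "none" for c in df.columns]
        return df


def run_augmentation_benchmark(real_train: FrameSet | np.ndarray,
                               generated: FrameSet | np.ndarray,
                               test: FrameSet | np.ndarray,
                               fractions=(0, 25, 50, 75, 100),
                               cr_grid=(10, 20, 30, 40, 50, 60, 70, 80, 90),
                               spec: CSResNetSpec | None = None,
                               architecture: str = "resnet",
                               epochs: int = 30, batch_size: int = 64,
                               lr: float = 1e-3, ones_per_column: int = 4,
                               seed: int = 0) -> PRDTable:
    """Train a reconstructor per (CR, augmentation fraction) cell and tabulate
    mean test PRD.  Fraction f adds the first f% of the generated pool to the
    real training frames; fraction 0 is the baseline.  Deterministic per seed.
    """
    R = real_train.frames if isinstance(real_train, FrameSet) else np.atleast_2d(real_train)
    G = generated.frames if isinstance(generated, FrameSet) else np.atleast_2d(generated)
    T = test.frames if isinstance(test, FrameSet) else np.atleast_2d(test)
    if T.shape[0] == 0:
        raise DataError("empty test set")
    N = R.shape[1]
    rows: dict[int, dict[int, float]] = {}
    for cr in cr_grid:
        M = max(1, int(round(cr / 100.0 * N)))
        mm = build_measurement_matrix(M, N, ones_per_column=ones_per_column, seed=seed)
        rows[cr] = {}
        for frac in fractions:
            n_add = int(round(frac / 100.0 * G.shape[0]))
            X = np.vstack([R, G[:n_add]]) if n_add else R
            rec = CSResNetReconstructor(matrix=mm, spec=spec, architecture=architecture,
                                        epochs=epochs, batch_size=batch_size, lr=lr,
                                        seed=seed)
            rec.fit(X)
            rows[cr][frac] = rec.prd_score(T)
    table = PRDTable(rows=rows, meta={
        "ones_per_column": ones_per_column, "epochs": epochs, "lr": lr,
        "batch_size": batch_size, "architecture": architecture, "seed": seed,
        "n_real": int(R.shape[0]), "n_generated_pool": int(G.shape[0]),
        "n_test": int(T.shape[0]),
    })
    return table.compute_deltas()
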