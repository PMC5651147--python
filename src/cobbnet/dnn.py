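"""Vertebral-slope regression network.

The network maps a 2500-element patch vector P to a slope in degrees:

    A(P) = b4 + W4 tanh(b3 + W3 tanh(b2 + W2 (W1 (P - b1))))

The first hidden layer is linear and frozen: its 100 weight rows W1 are
the leading eigenvectors of the patch covariance matrix (the PCA basis)
and b1 is the mean patch, so h1 acts as a low-pass dimensionality
reduction.  The two tanh hidden layers (h2, h3) and the linear output
are initialized by layer-wise autoencoder pretraining and then
fine-tuned by mini-batch gradient-descent backpropagation on the
squared slope error.  Labels are kept in degrees throughout so reported
errors are directly interpretable.

The high-level entry points are :class:`SlopeRegression` (the model) and
:class:`SlopeRegressionResults` (the fit); the module-level functions
expose each training stage individually.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg

from .exceptions import DataIntegrityError, ValidationError
from .patches import PATCH_VECTOR_LEN, PatchSet, patch_vector

PCA_COMPONENTS = 100

FORMAT_NAME = "cobbnet-model"
FORMAT_VERSION = 1


@dataclass
class TrainingConfig:
    """Hyperparameters for pretraining and fine-tuning.

    Pretraining uses a learning rate of 0.1 per layer; fine-tuning uses
    plain mini-batch gradient descent.  All randomness flows from
    ``seed``.
    """

    pretrain_learning_rate: float = 0.1
    pretrain_epochs: int = 20
    finetune_learning_rate: float = 0.01
    finetune_epochs: int = 50
    batch_size: int = 128
    seed: int = 0
    h2_size: int = 500
    h3_size: int = 50
    unfreeze_pca: bool = False

    def validate(self) -> None:
        for name in ("pretrain_learning_rate", "finetune_learning_rate"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        for name in ("pretrain_epochs", "finetune_epochs", "batch_size",
                     "h2_size", "h3_size"):
            if int(getattr(self, name)) < 1:
                raise ValidationError(f"{name} must be >= 1")

    def to_dict(self) -> dict:
        return {
            "pretrain_learning_rate": self.pretrain_learning_rate,
            "pretrain_epochs": self.pretrain_epochs,
            "finetune_learning_rate": self.finetune_learning_rate,
            "finetune_epochs": self.finetune_epochs,
            "batch_size": self.batch_size,
            "seed": self.seed,
            "h2_size": self.h2_size,
            "h3_size": self.h3_size,
            "unfreeze_pca": self.unfreeze_pca,
        }


@dataclass
class DNNParameters:
    """All weights and biases of the four-layer slope network.

    Shapes: W1 (100, 2500), b1 (2500,), W2 (h2, 100), b2 (h2,),
    W3 (h3, h2), b3 (h3,), W4 (1, h3), b4 scalar.
    """

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    W3: np.ndarray
    b3: np.ndarray
    W4: np.ndarray
    b4: float
    h2_size: int
    h3_size: int
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        h2, h3 = self.h2_size, self.h3_size
        expected = {
            "W1": (PCA_COMPONENTS, PATCH_VECTOR_LEN),
            "b1": (PATCH_VECTOR_LEN,),
            "W2": (h2, PCA_COMPONENTS),
            "b2": (h2,),
            "W3": (h3, h2),
            "b3": (h3,),
            "W4": (1, h3),
        }
        for name, shape in expected.items():
            got = getattr(self, name).shape
            if got != shape:
                raise ValidationError(
                    f"layer {name}: expected shape {shape}, got {got}"
                )
        gram = self.W1 @ self.W1.T
        if not np.allclose(gram, np.eye(PCA_COMPONENTS), atol=1e-6):
            raise ValidationError("rows of W1 must be orthonormal")


def fit_pca_layer(patches) -> tuple[np.ndarray, np.ndarray]:
    """Fit the frozen first layer: b1 is the mean patch vector and the
    rows of W1 are the top-100 eigenvectors of the patch covariance
    matrix, ordered by descending eigenvalue.

    Accepts a :class:`PatchSet` or an (n, 2500) array; requires at least
    101 patches so the covariance has full rank on the retained subspace.
    """
    X = patches.vectors if isinstance(patches, PatchSet) else np.asarray(patches)
    n, d = X.shape
    if d != PATCH_VECTOR_LEN:
        raise ValidationError(f"patch vectors must have length {PATCH_VECTOR_LEN}")
    if n < PCA_COMPONENTS + 1:
        raise ValidationError(
            f"need at least {PCA_COMPONENTS + 1} patches to fit the PCA "
            f"layer, got {n}"
        )
    b1 = X.mean(axis=0, dtype=np.float64)
    Xc = X.astype(np.float64) - b1
    cov = (Xc.T @ Xc) / (n - 1)
    vals, vecs = scipy.linalg.eigh(
        cov, subset_by_index=[d - PCA_COMPONENTS, d - 1]
    )
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    W1 = vecs.T
    # deterministic sign: largest-magnitude loading positive
    flips = np.sign(W1[np.arange(PCA_COMPONENTS), np.argmax(np.abs(W1), axis=1)])
    W1 = W1 * flips[:, None]
    return W1, b1, vals


def forward(params: DNNParameters, patch) -> float | np.ndarray:
    """Evaluate the slope network on one patch vector or a batch.

    Returns a scalar for a single (2500,) vector, or an (n,) array for an
    (n, 2500) batch, in degrees.
    """
    P = np.asarray(patch, dtype=np.float64)
    single = P.ndim == 1
    if single:
        P = P[None, :]
    if P.shape[1] != params.b1.shape[0]:
        raise ValidationError(
            f"layer W1/b1: patch length {P.shape[1]} != {params.b1.shape[0]}"
        )
    z = (P - params.b1) @ params.W1.T
    h2 = np.tanh(params.b2 + z @ params.W2.T)
    h3 = np.tanh(params.b3 + h2 @ params.W3.T)
    out = params.b4 + h3 @ params.W4.ravel()
    return float(out[0]) if single else out


def _train_autoencoder(X, hidden, lr, epochs, batch_size, rng):
    """One tied-architecture (untied-weight) autoencoder: tanh encoder,
    linear decoder, squared-error loss, plain SGD.  Returns the encoder
    (W, b) and the per-epoch reconstruction loss curve; the decoder is
    discarded."""
    n, d = X.shape
    W = rng.uniform(-1.0, 1.0, size=(hidden, d)) / np.sqrt(d)
    b = np.zeros(hidden)
    V = rng.uniform(-1.0, 1.0, size=(d, hidden)) / np.sqrt(hidden)
    c = np.zeros(d)
    losses = []
    for _ in range(epochs):
        idx = rng.permutation(n)
        total = 0.0
        for start in range(0, n, batch_size):
            sel = idx[start:start + batch_size]
            Xb = X[sel]
            m = len(sel)
            H = np.tanh(b + Xb @ W.T)
            Xhat = c + H @ V.T
            E = Xhat - Xb
            total += 0.5 * float(np.sum(E * E))
            dV = E.T @ H / m
            dc = E.mean(axis=0)
            dH = (E @ V) * (1.0 - H * H)
            dW = dH.T @ Xb / m
            db = dH.mean(axis=0)
            V -= lr * dV
            c -= lr * dc
            W -= lr * dW
            b -= lr * db
        losses.append(total / n)
    return W, b, losses


def pretrain(
    patches: PatchSet,
    config: TrainingConfig | None = None,
    pca: tuple[np.ndarray, np.ndarray] | None = None,
) -> DNNParameters:
    """Initialize the network: PCA first layer, then layer-wise
    autoencoder pretraining of h2 and h3 at the pretraining learning
    rate, and a small random output layer.

    Inside each autoencoder the inputs are standardized per component for
    SGD stability and the learned encoder weights are rescaled back, so
    the initialized network computes the exact four-layer composition on
    raw PCA latents.  Deterministic per ``config.seed``.
    """
    config = config or TrainingConfig()
    config.validate()
    if len(patches) == 0:
        raise ValidationError("cannot pretrain on an empty patch set")
    rng = np.random.default_rng(config.seed)
    if pca is None:
        W1, b1, _ = fit_pca_layer(patches)
    else:
        W1, b1 = pca
    X = patches.vectors.astype(np.float64)
    Z = (X - b1) @ W1.T

    s2 = Z.std(axis=0)
    s2[s2 < 1e-8] = 1.0
    Wa, ba, ae1_losses = _train_autoencoder(
        Z / s2, config.h2_size, config.pretrain_learning_rate,
        config.pretrain_epochs, config.batch_size, rng,
    )
    W2 = Wa / s2[None, :]
    b2 = ba

    H2 = np.tanh(b2 + Z @ W2.T)
    s3 = H2.std(axis=0)
    s3[s3 < 1e-8] = 1.0
    Wb, bb, ae2_losses = _train_autoencoder(
        H2 / s3, config.h3_size, config.pretrain_learning_rate,
        config.pretrain_epochs, config.batch_size, rng,
    )
    W3 = Wb / s3[None, :]
    b3 = bb

    W4 = rng.uniform(-1.0, 1.0, size=(1, config.h3_size)) / np.sqrt(config.h3_size)
    labeled = ~np.isnan(patches.labels)
    b4 = float(patches.labels[labeled].mean()) if labeled.any() else 0.0

    params = DNNParameters(
        W1=W1, b1=b1, W2=W2, b2=b2, W3=W3, b3=b3, W4=W4, b4=b4,
        h2_size=config.h2_size, h3_size=config.h3_size,
        metadata={
            "pretrain": {
                "ae1_loss": ae1_losses,
                "ae2_loss": ae2_losses,
                "config": config.to_dict(),
            }
        },
    )
    params.validate()
    return params


def finetune(
    params: DNNParameters,
    patches: PatchSet,
    config: TrainingConfig | None = None,
) -> DNNParameters:
    """Fine-tune layers 2-4 by mini-batch gradient descent on the mean
    squared slope error (degrees^2), with the PCA layer frozen unless
    ``config.unfreeze_pca``.  Returns a new parameter container holding
    the final-epoch weights and the training-loss curve; deterministic
    per ``config.seed``."""
    config = config or TrainingConfig(
        h2_size=params.h2_size, h3_size=params.h3_size
    )
    config.validate()
    bad = np.flatnonzero(np.isnan(patches.labels))
    if bad.size:
        i = int(bad[0])
        raise ValidationError(
            f"unlabeled patch at index {i} "
            f"(source {patches.source_ids[i]}, vertebra "
            f"{patches.vertebra_indices[i]}); fine-tuning needs labels"
        )
    rng = np.random.default_rng(config.seed + 1)
    X = patches.vectors.astype(np.float64)
    y = patches.labels.astype(np.float64)
    n = len(y)
    W1, b1 = params.W1.copy(), params.b1.copy()
    W2, b2 = params.W2.copy(), params.b2.copy()
    W3, b3 = params.W3.copy(), params.b3.copy()
    W4, b4 = params.W4.copy(), float(params.b4)
    Z = None if config.unfreeze_pca else (X - b1) @ W1.T
    lr = config.finetune_learning_rate
    losses = []
    for _ in range(config.finetune_epochs):
        idx = rng.permutation(n)
        total = 0.0
        for start in range(0, n, config.batch_size):
            sel = idx[start:start + config.batch_size]
            m = len(sel)
            Zb = (X[sel] - b1) @ W1.T if Z is None else Z[sel]
            A2 = np.tanh(b2 + Zb @ W2.T)
            A3 = np.tanh(b3 + A2 @ W3.T)
            pred = b4 + A3 @ W4.ravel()
            err = pred - y[sel]
            total += float(np.sum(err * err))
            d4 = err[:, None]                      # (m, 1)
            dW4 = d4.T @ A3 / m
            db4 = float(d4.mean())
            d3 = (d4 @ W4) * (1.0 - A3 * A3)
            dW3 = d3.T @ A2 / m
            db3 = d3.mean(axis=0)
            d2 = (d3 @ W3) * (1.0 - A2 * A2)
            dW2 = d2.T @ Zb / m
            db2 = d2.mean(axis=0)
            if config.unfreeze_pca:
                dz = d2 @ W2
                dW1 = dz.T @ (X[sel] - b1) / m
                db1 = -(dz @ W1).mean(axis=0)
                W1 -= lr * dW1
                b1 -= lr * db1
            W4 -= lr * dW4
            b4 -= lr * db4
            W3 -= lr * dW3
            b3 -= lr * db3
            W2 -= lr * dW2
            b2 -= lr * db2
        losses.append(total / n)
    metadata = dict(params.metadata)
    metadata["finetune"] = {"mse": losses, "config": config.to_dict()}
    out = DNNParameters(
        W1=W1, b1=b1, W2=W2, b2=b2, W3=W3, b3=b3, W4=W4, b4=b4,
        h2_size=params.h2_size, h3_size=params.h3_size, metadata=metadata,
    )
    if not config.unfreeze_pca:
        out.validate()
    return out


def predict_slope(
    params: DNNParameters, image: np.ndarray, click: tuple[float, float]
) -> float:
    """Predict the slope (degrees) of the vertebra under ``click`` on a
    standardized image: extract the 150x150 window, downsample, evaluate
    the network."""
    return forward(params, patch_vector(image, click))


def save_model(path, params: DNNParameters) -> None:
    """Model container: .npz with arrays W1..W4, b1..b4 and a JSON
    ``header`` holding the format tag, architecture sizes and the
    training metadata."""
    header = json.dumps({
        "format": FORMAT_NAME,
        "version": FORMAT_VERSION,
        "h2_size": params.h2_size,
        "h3_size": params.h3_size,
        "metadata": params.metadata,
    })
    np.savez_compressed(
        path, header=np.array(header),
        W1=params.W1, b1=params.b1, W2=params.W2, b2=params.b2,
        W3=params.W3, b3=params.b3, W4=params.W4,
        b4=np.array([params.b4]),
    )


def load_model(path) -> DNNParameters:
    """Load and validate a model container; corrupted or shape-mismatched
    files are rejected without returning a partial model."""
    try:
        with np.load(path, allow_pickle=False) as z:
            header = json.loads(str(z["header"]))
            if header.get("format") != FORMAT_NAME:
                raise DataIntegrityError(f"{path}: not a cobbnet model container")
            params = DNNParameters(
                W1=z["W1"], b1=z["b1"], W2=z["W2"], b2=z["b2"],
                W3=z["W3"], b3=z["b3"], W4=z["W4"], b4=float(z["b4"][0]),
                h2_size=int(header["h2_size"]),
                h3_size=int(header["h3_size"]),
                metadata=header.get("metadata", {}),
            )
    except (OSError, KeyError, ValueError, zipfile.BadZipFile,
            json.JSONDecodeError) as exc:
        raise DataIntegrityError(f"cannot read model container {path}: {exc}")
    try:
        params.validate()
    except ValidationError as exc:
        raise DataIntegrityError(f"model container {path} inconsistent: {exc}")
    return params


class SlopeRegression:
    """Vertebral-slope regression model over a labeled patch set.

    Parameters
    ----------
    patches : PatchSet
        Labeled training patches (2500-vectors with slope labels in
        degrees).
    config : TrainingConfig, optional
        Architecture sizes and training hyperparameters; defaults match
        the reference protocol (h2=500, h3=50, pretraining rate 0.1).

    Examples
    --------
    >>> model = SlopeRegression(train_patches, TrainingConfig(seed=7))
    >>> res = model.fit()
    >>> res.evaluate(test_patches)["mae"]
    """

    def __init__(self, patches: PatchSet, config: TrainingConfig | None = None):
        patches.validate()
        self.patches = patches
        self.config = config or TrainingConfig()
        self.config.validate()

    @classmethod
    def from_patchset(cls, patches: PatchSet, **config_kwargs) -> "SlopeRegression":
        return cls(patches, TrainingConfig(**config_kwargs))

    def fit(self, do_pretrain: bool = True) -> "SlopeRegressionResults":
        """Fit PCA layer, pretrain the hidden layers, fine-tune, and wrap
        the trained parameters in a results object."""
        W1, b1, eigvals = fit_pca_layer(self.patches)
        if do_pretrain:
            params = pretrain(self.patches, self.config, pca=(W1, b1))
        else:
            rng = np.random.default_rng(self.config.seed)
            h2, h3 = self.config.h2_size, self.config.h3_size
            params = DNNParameters(
                W1=W1, b1=b1,
                W2=rng.uniform(-1, 1, (h2, PCA_COMPONENTS)) / np.sqrt(PCA_COMPONENTS),
                b2=np.zeros(h2),
                W3=rng.uniform(-1, 1, (h3, h2)) / np.sqrt(h2),
                b3=np.zeros(h3),
                W4=rng.uniform(-1, 1, (1, h3)) / np.sqrt(h3),
                b4=float(np.nanmean(self.patches.labels)),
                h2_size=h2, h3_size=h3,
            )
        params = finetune(params, self.patches, self.config)
        params.metadata["pca_explained_variance"] = eigvals[:10].tolist()
        return SlopeRegressionResults(self, params)


class SlopeRegressionResults:
    """A fitted slope network: trained parameters, training curves, and
    prediction/evaluation helpers."""

    def __init__(self, model: SlopeRegression | None, params: DNNParameters):
        self.model = model
        self.params = params

    # -- prediction ---------------------------------------------------
    def predict(self, vectors) -> np.ndarray:
        """Slopes (degrees) for an (n, 2500) array or a PatchSet."""
        X = vectors.vectors if isinstance(vectors, PatchSet) else vectors
        return np.atleast_1d(forward(self.params, X))

    def predict_image(self, image, clicks) -> np.ndarray:
        """Slopes for a list of click coordinates on a standardized image."""
        return np.array(
            [predict_slope(self.params, image, c) for c in clicks]
        )

    def evaluate(self, patches: PatchSet) -> dict:
        """Mean-absolute and RMS slope error against the patch labels."""
        pred = self.predict(patches)
        err = pred - patches.labels
        return {
            "mae": float(np.mean(np.abs(err))),
            "rmse": float(np.sqrt(np.mean(err * err))),
            "n": len(patches),
        }

    # -- diagnostics --------------------------------------------------
    @property
    def training_history(self) -> dict:
        return {
            "pretrain": self.params.metadata.get("pretrain", {}),
            "finetune": self.params.metadata.get("finetune", {}),
        }

    def summary(self) -> str:
        p = self.params
        ft = p.metadata.get("finetune", {})
        mse = ft.get("mse", [])
        lines = [
            "Vertebral Slope Regression Results",
            "=" * 46,
            f"Architecture:      2500 -> 100 (PCA) -> {p.h2_size} -> {p.h3_size} -> 1",
            f"Activations:       linear, tanh, tanh, linear",
            f"Parameters:        {sum(getattr(p, n).size for n in ('W1','b1','W2','b2','W3','b3','W4')) + 1}",
        ]
        cfg = ft.get("config")
        if cfg:
            lines += [
                f"Fine-tune epochs:  {cfg['finetune_epochs']} "
                f"(lr {cfg['finetune_learning_rate']}, batch {cfg['batch_size']})",
            ]
        if mse:
            lines += [
                f"Final train MSE:   {mse[-1]:.4f} deg^2",
                f"Final train RMSE:  {np.sqrt(mse[-1]):.3f} deg",
            ]
        lines.append("=" * 46)
        return "\n".join(lines)

    # -- persistence --------------------------------------------------
    def save(self, path) -> None:
        save_model(path, self.params)

    @classmethod
    def load(cls, path) -> "SlopeRegressionResults":
        return cls(None, load_model(path))
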