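"""Model configuration, training loop and inference for the seq2seq
reconstruction models.

Training follows the standard recipe of this task: Adam on mean-squared
error, 50 epochs, batch size 512, initial learning rate 1e-3 halved
every five epochs (``lr(e) = lr0 * 0.5**floor(e / period)`` with 0-based
epochs), dropout 0.2, weights drawn from N(0, 0.01^2), and a seeded 7:3
train/validation split.  The checkpoint retained is the epoch with the
best validation loss.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .dataset import SimulatedDataset
from .grids import OffsetGrid
from .nn import Adam, SeqModel
from .nn.models import ARCHITECTURES

__all__ = [
    "ModelConfig",
    "TrainingConfig",
    "TrainedModel",
    "build_model",
    "train",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    architecture: str = "tcn_lstm"
    input_len: int = 11
    output_len: int = 101
    hidden_size: int = 128
    num_layers: int = 2
    tcn_channels: int = 64
    tcn_kernel: int = 3
    tcn_dilations: tuple[int, ...] = (1, 2, 4, 8)
    dropout: float = 0.2
    head_mode: str = "sequence"  # "sequence": affine head on the whole
    # hidden sequence; "final": head on the last hidden state only
    tcn_skip_input: bool = True  # tcn_lstm: feed the raw spectrum to the
    # LSTM alongside the TCN features
    include_offsets_channel: bool = False

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; expected one of {ARCHITECTURES}"
            )
        if self.input_len < 1 or self.output_len < 1:
            raise ValueError("input_len and output_len must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    @property
    def n_channels(self) -> int:
        return 2 if self.include_offsets_channel else 1


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 50
    batch_size: int = 512
    lr0: float = 1e-3
    lr_halving_period_epochs: int = 5
    train_fraction: float = 0.7
    weight_init_std: float | str = "scaled"  # float: constant-std normal
    # draw; "scaled": fan-in scaling, std = 1/sqrt(fan_in)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")

    def lr_at_epoch(self, epoch: int) -> float:
        """Learning rate at 0-based ``epoch``: lr0 halved every period."""
        return self.lr0 * 0.5 ** (epoch // self.lr_halving_period_epochs)


def build_model(config: ModelConfig, seed: int = 0, init_std: float | str = "scaled",
                dtype=np.float32,
                sparse_grid: OffsetGrid | None = None,
                dense_grid: OffsetGrid | None = None) -> SeqModel:
    """Instantiate an untrained model; same seed gives identical weights.

    The model's linear bypass is initialized to piecewise-linear
    interpolation between the two offset grids; when they are omitted and
    the lengths match the default protocol, the default grids are used.
    """
    from .grids import dense_default, sparse_default

    if sparse_grid is None and config.input_len == 11:
        sparse_grid = sparse_default()
    if dense_grid is None and config.output_len == 101:
        dense_grid = dense_default()
    interp = None
    if sparse_grid is not None and dense_grid is not None:
        interp = (sparse_grid.offsets_ppm, dense_grid.offsets_ppm)
    return SeqModel(
        architecture=config.architecture,
        input_len=config.input_len,
        output_len=config.output_len,
        n_channels=config.n_channels,
        hidden_size=config.hidden_size,
        num_layers=config.num_layers,
        tcn_channels=config.tcn_channels,
        tcn_kernel=config.tcn_kernel,
        tcn_dilations=tuple(config.tcn_dilations),
        dropout=config.dropout,
        head_mode=config.head_mode,
        tcn_skip_input=config.tcn_skip_input,
        interp_positions=interp,
        seed=seed,
        init_std=init_std,
        dtype=dtype,
    )


@dataclass
class TrainedModel:
    """A trained model bound to the offset grids it was fitted on."""

    model: SeqModel
    model_config: ModelConfig
    training_config: TrainingConfig
    history: dict = field(default_factory=dict)
    sparse_grid: OffsetGrid | None = None
    dense_grid: OffsetGrid | None = None
    best_epoch: int = -1
    train_indices: np.ndarray | None = None
    val_indices: np.ndarray | None = None


def _as_inputs(X: np.ndarray, cfg: ModelConfig, grid: OffsetGrid | None) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim != 2 or X.shape[1] != cfg.input_len:
        raise ValueError(
            f"expected sparse spectra of length {cfg.input_len}, got shape {X.shape}"
        )
    x = X[:, :, None]
    if cfg.include_offsets_channel:
        if grid is None:
            raise ValueError("offsets channel requested but no grid is bound")
        ch = np.broadcast_to(
            (grid.offsets_ppm / np.abs(grid.offsets_ppm).max())[None, :, None],
            x.shape,
        )
        x = np.concatenate([x, ch], axis=2)
    return x


def _mse(model: SeqModel, X: np.ndarray, Y: np.ndarray, batch: int = 4096) -> float:
    tot, cnt = 0.0, 0
    for s in range(0, X.shape[0], batch):
        pred = model.forward(X[s : s + batch], train=False).astype(np.float64)
        tot += float(((pred - Y[s : s + batch]) ** 2).sum())
        cnt += pred.size
    return tot / cnt


def train(model: SeqModel, dataset: SimulatedDataset, tcfg: TrainingConfig,
          mcfg: ModelConfig | None = None, progress: bool = False) -> TrainedModel:
    """Fit ``model`` to a paired dataset and return the best-validation model.

    The dataset is split train:validation by a permutation seeded with
    ``tcfg.seed``; validation rows never contribute gradient updates.
    Per-epoch learning rate, train MSE (average of minibatch losses) and
    validation MSE are recorded in the history.
    """
    if mcfg is None:
        mcfg = ModelConfig(architecture=model.architecture,
                           input_len=model.input_len, output_len=model.output_len,
                           dropout=model.dropout,
                           include_offsets_channel=model.n_channels == 2)
    n = dataset.n
    if n == 0:
        raise ValueError("empty dataset")
    if dataset.sparse_z.shape[1] != mcfg.input_len:
        raise ValueError(
            f"dataset sparse length {dataset.sparse_z.shape[1]} != model input_len {mcfg.input_len}"
        )
    if dataset.dense_z.shape[1] != mcfg.output_len:
        raise ValueError(
            f"dataset dense length {dataset.dense_z.shape[1]} != model output_len {mcfg.output_len}"
        )

    rng = np.random.default_rng(tcfg.seed)
    perm = rng.permutation(n)
    n_train = max(1, int(np.floor(tcfg.train_fraction * n)))
    if n_train == n:
        n_train = n - 1 if n > 1 else n
    tr_idx, va_idx = perm[:n_train], perm[n_train:]

    X = _as_inputs(dataset.sparse_z, mcfg, dataset.sparse_grid).astype(model.dtype)
    Y = dataset.dense_z.astype(model.dtype)
    Xtr, Ytr = X[tr_idx], Y[tr_idx]
    Xva, Yva = X[va_idx], Y[va_idx]

    opt = Adam(model, lr=tcfg.lr0)
    history = {"epoch": [], "lr": [], "train_mse": [], "val_mse": []}
    best_val, best_state, best_epoch = np.inf, model.state_dict(), -1

    epochs_iter = range(tcfg.epochs)
    if progress:
        from tqdm import tqdm

        epochs_iter = tqdm(epochs_iter, desc=f"train {model.architecture}", unit="epoch")
    for epoch in epochs_iter:
        opt.lr = tcfg.lr_at_epoch(epoch)
        order = rng.permutation(n_train)
        losses = []
        for s in range(0, n_train, tcfg.batch_size):
            idx = order[s : s + tcfg.batch_size]
            xb, yb = Xtr[idx], Ytr[idx]
            model.zero_grad()
            pred = model.forward(xb, train=True)
            diff = pred - yb
            losses.append(float(np.mean(diff.astype(np.float64) ** 2)))
            model.backward((2.0 / diff.size) * diff)
            opt.step()
        val = _mse(model, Xva, Yva) if len(va_idx) else float("nan")
        history["epoch"].append(epoch)
        history["lr"].append(opt.lr)
        history["train_mse"].append(float(np.mean(losses)))
        history["val_mse"].append(val)
        if len(va_idx) and val < best_val:
            best_val, best_state, best_epoch = val, model.state_dict(), epoch

    if best_epoch >= 0:
        model.load_state_dict(best_state)
    return TrainedModel(
        model=model, model_config=mcfg, training_config=tcfg, history=history,
        sparse_grid=dataset.sparse_grid, dense_grid=dataset.dense_grid,
        best_epoch=best_epoch, train_indices=tr_idx, val_indices=va_idx,
    )


def predict(tm: TrainedModel, sparse_z: np.ndarray, batch: int = 4096) -> np.ndarray:
    """Reconstruct dense spectra for a batch of sparse spectra.

    Deterministic (dropout disabled); raises if the input length does not
    match the model's bound sparse grid.
    """
    X = _as_inputs(sparse_z, tm.model_config, tm.sparse_grid)
    out = np.empty((X.shape[0], tm.model_config.output_len))
    for s in range(0, X.shape[0], batch):
        out[s : s + batch] = tm.model.forward(X[s : s + batch], train=False)
    if not np.all(np.isfinite(out)):
        raise RuntimeError("non-finite model output")
    return out


def _grid_json(grid: OffsetGrid | None):
    return None if grid is None else list(map(float, grid.offsets_ppm))


def save_checkpoint(tm: TrainedModel, path) -> None:
    """Single-file checkpoint: weights plus both configs and grid metadata."""
    meta = {
        "model_config": asdict(tm.model_config),
        "training_config": asdict(tm.training_config),
        "history": tm.history,
        "best_epoch": tm.best_epoch,
        "sparse_grid": _grid_json(tm.sparse_grid),
        "dense_grid": _grid_json(tm.dense_grid),
    }
    arrays = {f"w__{k}": v for k, v in tm.model.state_dict().items()}
    np.savez(path, metadata_json=np.array(json.dumps(meta)), **arrays)


def load_checkpoint(path) -> TrainedModel:
    with np.load(path, allow_pickle=False) as f:
        meta = json.loads(str(f["metadata_json"]))
        state = {k[3:]: f[k] for k in f.files if k.startswith("w__")}
    mc = meta["model_config"]
    mc["tcn_dilations"] = tuple(mc["tcn_dilations"])
    mcfg = ModelConfig(**mc)
    tcfg = TrainingConfig(**meta["training_config"])
    sparse = OffsetGrid(meta["sparse_grid"]) if meta["sparse_grid"] else None
    dense = OffsetGrid(meta["dense_grid"]) if meta["dense_grid"] else None
    model = build_model(mcfg, seed=tcfg.seed, init_std=tcfg.weight_init_std,
                        sparse_grid=sparse, dense_grid=dense)
    model.load_state_dict(state)
    return TrainedModel(
        model=model, model_config=mcfg, training_config=tcfg,
        history=meta["history"], best_epoch=meta["best_epoch"],
        sparse_grid=sparse, dense_grid=dense,
    )
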