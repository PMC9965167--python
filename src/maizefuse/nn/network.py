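"""Multimodal multi-task convolutional regression network.

One convolutional stream per data modality group: a 3-D stream for the
hyperspectral cube (jointly spatial-spectral kernels), a 2-D stream for the
LiDAR-derived rasters (canopy height and intensity stacked as channels when
both are selected) and a 2-D stream for thermal.  Each stream is a ladder of
convolution (Glorot-uniform weights, zero bias, ReLU) and max-pooling layers
with filter counts doubling 8 → 16 → 32 → 64, closed by global average
pooling to 64 values.  Streams are fused by concatenation and a small fully
connected head (32 units, ReLU, dropout) maps the fused vector to one output
per task.  Training minimizes the unweighted mean of per-task Huber losses
on standardized targets with Adam under an exponentially decaying learning
rate, early-stopping on validation loss.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from ..plot_prep import TraitScaler
from ..synthetic_field import _substream
from .augment import AugmentationSpec, augment_crops, center_crop
from .layers import (
    Adam,
    ConvND,
    Dense,
    Dropout,
    GlobalAvgPool,
    MaxPoolND,
    ReLU,
)
from .losses import multitask_huber

MODALITIES = ("hyperspectral", "lidar_height", "lidar_intensity", "thermal")


@dataclass
class FusionNetSpec:
    """Complete architecture description of the fusion network."""

    modalities: tuple[str, ...] = MODALITIES
    n_tasks: int = 8
    n_layers: int = 4
    filters: tuple[int, ...] = (8, 16, 32, 64)
    kernel3d: tuple[int, int, int] = (7, 3, 3)   # (spectral, rows, cols)
    pool3d: tuple[int, int, int] = (6, 2, 2)
    kernel2d: tuple[int, int] = (3, 3)
    pool2d: tuple[int, int] = (2, 2)
    head_units: int = 32
    dropout: float = 0.5
    padding: str = "same"

    def validate(self) -> None:
        if not self.modalities:
            raise ValueError("at least one modality is required")
        for m in self.modalities:
            if m not in MODALITIES:
                raise ValueError(f"unknown modality {m!r}")
        if self.n_tasks < 1:
            raise ValueError("n_tasks must be >= 1")
        if self.n_layers < 1 or self.n_layers > len(self.filters):
            raise ValueError("n_layers must be within the filter ladder")

    def streams(self) -> list[tuple[str, int, int]]:
        """(stream name, conv dimensionality, input channels) per stream.

        Height and intensity share one 2-D LiDAR stream as channels when
        both are selected, so the full four-modality model has three
        convolutional streams.
        """
        self.validate()
        out: list[tuple[str, int, int]] = []
        if "hyperspectral" in self.modalities:
            out.append(("hyperspectral", 3, 1))
        lidar = [m for m in ("lidar_height", "lidar_intensity") if m in self.modalities]
        if lidar:
            out.append(("lidar", 2, len(lidar)))
        if "thermal" in self.modalities:
            out.append(("thermal", 2, 1))
        return out

    @property
    def fusion_length(self) -> int:
        return self.filters[self.n_layers - 1] * len(self.streams())


def build_network(modalities, n_tasks: int, **overrides) -> FusionNetSpec:
    """Construct the architecture spec for a modality subset."""
    spec = FusionNetSpec(modalities=tuple(modalities), n_tasks=n_tasks, **overrides)
    spec.validate()
    return spec


class FusionNet:
    """The assembled network: per-stream layer stacks plus the fused head.

    Stream weights are drawn from a seed substream that does not depend on
    the head configuration, so mono-task and multi-task builds share
    identical stream initializations for the same seed.
    """

    def __init__(self, spec: FusionNetSpec, seed: int = 0):
        spec.validate()
        self.spec = spec
        rng_streams = _substream(seed, "net-streams")
        rng_head = _substream(seed, "net-head")
        rng_drop = _substream(seed, "net-dropout")

        self.streams: dict[str, list] = {}
        for name, ndim, in_ch in spec.streams():
            layers = []
            cin = in_ch
            kernel = spec.kernel3d if ndim == 3 else spec.kernel2d
            pool = spec.pool3d if ndim == 3 else spec.pool2d
            for li in range(spec.n_layers):
                layers.append(ConvND(ndim, cin, spec.filters[li], kernel,
                                     spec.padding, rng_streams))
                layers.append(ReLU())
                layers.append(MaxPoolND(ndim, pool))
                cin = spec.filters[li]
            layers.append(GlobalAvgPool())
            self.streams[name] = layers

        self.head = [
            Dense(spec.fusion_length, spec.head_units, rng_head),
            ReLU(),
            Dropout(spec.dropout, rng_drop),
            Dense(spec.head_units, spec.n_tasks, rng_head),
        ]

    # -- plumbing ----------------------------------------------------------
    @property
    def params(self) -> list[np.ndarray]:
        out = []
        for layers in self.streams.values():
            for layer in layers:
                out.extend(layer.params)
        for layer in self.head:
            out.extend(layer.params)
        return out

    @property
    def grads(self) -> list[np.ndarray]:
        out = []
        for layers in self.streams.values():
            for layer in layers:
                out.extend(layer.grads)
        for layer in self.head:
            out.extend(layer.grads)
        return out

    def forward(self, inputs: dict[str, np.ndarray], train: bool = False) -> np.ndarray:
        pooled = []
        self._widths = []
        for name, layers in self.streams.items():
            if name not in inputs:
                raise ValueError(f"missing input for stream {name!r}")
            h = inputs[name]
            for layer in layers:
                h = layer.forward(h, train=train)
            pooled.append(h)
            self._widths.append(h.shape[1])
        fused = np.concatenate(pooled, axis=1)
        for layer in self.head:
            fused = layer.forward(fused, train=train)
        return fused

    def backward(self, dout: np.ndarray) -> None:
        d = dout
        for layer in reversed(self.head):
            d = layer.backward(d)
        offset = 0
        for (name, layers), width in zip(self.streams.items(), self._widths):
            dseg = d[:, offset : offset + width]
            offset += width
            for layer in reversed(layers):
                dseg = layer.backward(dseg)

    def state_dict(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params, state):
            p[...] = s


@dataclass
class TrainConfig:
    """Optimization settings for the fusion network."""

    delta: float = 1.0            # Huber threshold on standardized targets
    learning_rate: float = 1e-3   # Adam initial rate
    lr_decay: float = 0.9         # multiplicative decay ...
    decay_every: int = 5          # ... applied every this many epochs
    batch_size: int = 16
    max_epochs: int = 100
    patience: int = 15            # early-stopping epochs without val improvement
    val_fraction: float = 0.2
    n_crops: int = 20
    crop_window: tuple[int, int] | None = None  # None: largest window all chips fit
    seed: int = 0

    def validate(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")


def _stack_modalities(
    crops: list[dict[str, np.ndarray]], streams: list[tuple[str, int, int]],
    modalities: tuple[str, ...],
) -> dict[str, np.ndarray]:
    """Crop dicts -> per-stream batched arrays with network axis layout."""
    out: dict[str, np.ndarray] = {}
    for name, ndim, _ in streams:
        if name == "hyperspectral":
            cube = np.stack([c["hyperspectral"] for c in crops])  # (N, H, W, B)
            out[name] = np.ascontiguousarray(
                np.moveaxis(cube, -1, 1)[..., None], dtype=float
            )  # (N, B, H, W, 1)
        elif name == "lidar":
            chans = [m.split("_")[1] for m in ("lidar_height", "lidar_intensity")
                     if m in modalities]
            out[name] = np.stack(
                [np.stack([c[ch] for ch in chans], axis=-1) for c in crops]
            ).astype(float)
        elif name == "thermal":
            out[name] = np.stack([c["thermal"] for c in crops])[..., None].astype(float)
    return out


class FusionNetRegressor(BaseEstimator, RegressorMixin):
    """Sklearn-style estimator over multimodal plot chips.

    ``fit`` takes ``chips`` — a mapping ``plot_id -> {"hyperspectral":
    (H, W, B), "height": (H, W), "intensity": (H, W), "thermal": (H, W)}``
    (the prepared-plot container) — and a target frame ``y`` (plots x
    traits) in physical units.  Targets are standardized internally on the
    training plots only; ``predict`` inverts the scaling.  Plots never
    straddle the train/validation split: crops are generated per plot after
    splitting, and augmentation applies to training plots only.
    """

    def __init__(
        self,
        modalities: tuple[str, ...] = MODALITIES,
        spec: FusionNetSpec | None = None,
        config: TrainConfig | None = None,
        seed: int = 0,
        verbose: bool = False,
    ):
        self.modalities = modalities
        self.spec = spec
        self.config = config
        self.seed = seed
        self.verbose = verbose

    # -- data plumbing -----------------------------------------------------
    def _chip_to_modal(self, chipset: dict) -> dict[str, np.ndarray]:
        out = {}
        if "hyperspectral" in self.modalities:
            out["hyperspectral"] = np.asarray(chipset["hyperspectral"], dtype=float)
        if "lidar_height" in self.modalities:
            out["height"] = np.asarray(chipset["height"], dtype=float)
        if "lidar_intensity" in self.modalities:
            out["intensity"] = np.asarray(chipset["intensity"], dtype=float)
        if "thermal" in self.modalities:
            out["thermal"] = np.asarray(chipset["thermal"], dtype=float)
        return out

    def _default_window(self, chips: dict) -> tuple[int, int]:
        shapes = [next(iter(self._chip_to_modal(c).values())).shape[:2]
                  for c in chips.values()]
        return (min(s[0] for s in shapes), min(s[1] for s in shapes))

    def _standardize_inputs(self, modal: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        out = {}
        for name, arr in modal.items():
            mu, sd = self._input_stats_[name]
            out[name] = (arr - mu) / sd
        return out

    # -- fit ---------------------------------------------------------------
    def fit(self, chips: dict, y: pd.DataFrame, strata: pd.Series | None = None,
            train_plots=None, val_plots=None):
        cfg = copy.deepcopy(self.config) if self.config is not None else TrainConfig(seed=self.seed)
        cfg.validate()
        plot_ids = list(y.index)
        missing = [p for p in plot_ids if p not in chips]
        if missing:
            raise ValueError(f"chips missing for plots: {missing[:5]} ...")

        rng = _substream(cfg.seed, "fit-split")
        if train_plots is None or val_plots is None:
            ids = np.array(plot_ids)
            groups = (
                [ids[np.asarray(strata.loc[plot_ids]) == s]
                 for s in np.unique(np.asarray(strata.loc[plot_ids]))]
                if strata is not None
                else [ids]
            )
            val_plots, train_plots = [], []
            for g in groups:  # proportional validation share per stratum
                perm = rng.permutation(len(g))
                n_val = max(int(round(cfg.val_fraction * len(g))), 1)
                val_plots.extend(g[perm[:n_val]])
                train_plots.extend(g[perm[n_val:]])
        overlap = set(train_plots) & set(val_plots)
        if overlap:
            raise ValueError(f"plots straddle the split: {sorted(overlap)[:5]}")
        self.train_plots_ = list(train_plots)
        self.val_plots_ = list(val_plots)

        window = cfg.crop_window or self._default_window(chips)
        self.window_ = window

        # per-plot modality chips -> crops (train augmented, val center crop)
        aug = AugmentationSpec(window=window, n_crops=max(cfg.n_crops, 1))
        train_crops, train_rows = [], []
        for i, pid in enumerate(self.train_plots_):
            modal = self._chip_to_modal(chips[pid])
            if cfg.n_crops == 0:
                crops = [center_crop(modal, window)]
            else:
                crops, _ = augment_crops(modal, aug, seed=cfg.seed * 100003 + i)
            train_crops.extend(crops)
            train_rows.extend([pid] * len(crops))
        val_crops = [center_crop(self._chip_to_modal(chips[pid]), window)
                     for pid in self.val_plots_]

        # input standardization per modality (train statistics only)
        self._input_stats_ = {}
        for name in train_crops[0]:
            stacked = np.stack([c[name] for c in train_crops])
            sd = float(stacked.std())
            self._input_stats_[name] = (float(stacked.mean()), sd if sd > 0 else 1.0)
        train_crops = [self._standardize_inputs(c) for c in train_crops]
        val_crops = [self._standardize_inputs(c) for c in val_crops]

        # target standardization (train plots only)
        self.y_columns_ = list(y.columns)
        self.y_scaler_ = TraitScaler().fit(y, fit_rows=self.train_plots_)
        y_std = self.y_scaler_.transform(y)
        y_train = y_std.loc[train_rows].to_numpy()
        y_val = y_std.loc[self.val_plots_].to_numpy()

        spec = self.spec or FusionNetSpec(modalities=tuple(self.modalities),
                                          n_tasks=len(self.y_columns_))
        spec = dataclass_replace(spec, modalities=tuple(self.modalities),
                                 n_tasks=len(self.y_columns_))
        self.spec_ = spec
        self.net_ = FusionNet(spec, seed=cfg.seed)

        streams = spec.streams()
        X_train = _stack_modalities(train_crops, streams, tuple(self.modalities))
        X_val = _stack_modalities(val_crops, streams, tuple(self.modalities))

        opt = Adam(self.net_.params, lr=cfg.learning_rate)
        n_train = len(train_rows)
        shuffle_rng = _substream(cfg.seed, "fit-shuffle")
        best_val = np.inf
        best_state = self.net_.state_dict()
        since_best = 0
        history = []

        for epoch in range(cfg.max_epochs):
            lr = cfg.learning_rate * cfg.lr_decay ** (epoch // cfg.decay_every)
            order = shuffle_rng.permutation(n_train)
            epoch_loss = 0.0
            for start in range(0, n_train, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb = {k: v[idx] for k, v in X_train.items()}
                yb = y_train[idx]
                pred = self.net_.forward(xb, train=True)
                loss, dpred = multitask_huber(yb, pred, cfg.delta)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}: {loss}"
                    )
                self.net_.backward(dpred)
                opt.step(self.net_.grads, lr=lr)
                epoch_loss += loss * len(idx)
            epoch_loss /= n_train

            val_pred = self._forward_batched(X_val)
            val_loss, _ = multitask_huber(y_val, val_pred, cfg.delta)
            history.append({"epoch": epoch, "train_loss": epoch_loss,
                            "val_loss": val_loss, "lr": lr})
            if self.verbose:
                print(f"epoch {epoch:3d}  train {epoch_loss:.4f}  val {val_loss:.4f}")
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_state = self.net_.state_dict()
                since_best = 0
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break

        self.net_.load_state(best_state)
        self.history_ = pd.DataFrame(history)
        self.config_ = cfg
        return self

    def _forward_batched(self, X: dict[str, np.ndarray], batch: int = 64) -> np.ndarray:
        n = len(next(iter(X.values())))
        outs = []
        for start in range(0, n, batch):
            xb = {k: v[start : start + batch] for k, v in X.items()}
            outs.append(self.net_.forward(xb, train=False))
        return np.vstack(outs)

    # -- predict -----------------------------------------------------------
    def predict(self, chips: dict, plot_ids=None, aggregate: str = "center") -> pd.DataFrame:
        """Per-plot predictions in physical units.

        ``aggregate='center'`` (default) uses the deterministic center crop;
        ``'five_crop'`` averages the center and the four corner crops.
        """
        if not hasattr(self, "net_"):
            raise ValueError("FusionNetRegressor is not fitted")
        if aggregate not in ("center", "five_crop"):
            raise ValueError("aggregate must be 'center' or 'five_crop'")
        ids = list(plot_ids) if plot_ids is not None else list(chips.keys())
        wh, ww = self.window_
        preds_std = []
        n_views = 1 if aggregate == "center" else 5
        for view in range(n_views):
            crops = []
            for pid in ids:
                modal = self._chip_to_modal(chips[pid])
                if view == 0:
                    crop = center_crop(modal, self.window_)
                else:
                    crop = {}
                    for name, arr in modal.items():
                        mr, mc = arr.shape[0] - wh, arr.shape[1] - ww
                        if mr < 0 or mc < 0:
                            raise ValueError(f"chip smaller than window for {name}")
                        r = 0 if view in (1, 2) else mr
                        c = 0 if view in (1, 3) else mc
                        crop[name] = arr[r : r + wh, c : c + ww]
                crops.append(self._standardize_inputs(crop))
            X = _stack_modalities(crops, self.spec_.streams(), tuple(self.modalities))
            preds_std.append(self._forward_batched(X))
        pred = self.y_scaler_.inverse_transform_array(np.mean(preds_std, axis=0))
        return pd.DataFrame(pred, index=pd.Index(ids, name="plot_id"),
                            columns=self.y_columns_)


def dataclass_replace(spec: FusionNetSpec, **kw) -> FusionNetSpec:
    import dataclasses

    return dataclasses.replace(spec, **kw)
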