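"""The full dual-channel multi-label ADR predictor.

A drug is encoded four ways — three GIN graph embeddings X^m, X^e, X^c and
the attention-channel feature X^f — concatenated into a width 4*dim drug
representation and mapped by a single linear layer W_pred through a
sigmoid to per-label probabilities:

    P = sigmoid(concat(X^m, X^e, X^c, X^f) @ W_pred)

Training minimizes mean per-label binary cross-entropy with Adam
(learning rate 0.001) and L2 weight decay 0.001, the tuned setting of the
method (heads H=2, dropout 0.5). The GIN encoders are fine-tuned jointly
with everything else by default; a flag freezes them instead.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import featurize as fz
from .autodiff import Adam, Tensor, bce_with_logits, concat
from .errors import (
    ConfigurationError,
    FeaturizationError,
    TrainingDivergenceError,
)
from .featurize import Molecule, MolecularGraph, SubstructureSequence
from .graph_channel import (
    BatchedGraphs,
    GinParams,
    batch_graphs,
    gin_encode_batch,
    init_gin_params,
)
from .sequence_channel import (
    EncoderParams,
    init_encoder_params,
    sequence_encode_batch,
)

CHECKPOINT_SCHEMA_VERSION = 1


@dataclass
class ModelConfig:
    """Hyperparameters of the predictor.

    ``n_heads=2``, ``dropout=0.5``, ``lr=0.001`` and ``weight_decay=0.001``
    are the tuned values; ``dim=300`` (graph embedding width), ``T=5``
    message-passing iterations, ``dim_prime=64`` token-embedding width and
    ``dim_ff=1024`` hidden width are the package defaults for the
    dimensions the method leaves open. Epochs and batch size are training
    run-size choices, exposed here.
    """

    n_labels: int = 4
    dim: int = 300
    T: int = 5
    dim_prime: int = 64
    dim_ff: int = 1024
    n_heads: int = 2
    dropout: float = 0.5
    lr: float = 1e-3
    weight_decay: float = 1e-3
    epochs: int = 100
    batch_size: int = 32
    threshold: float = 0.5
    finetune_gin: bool = True
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        if self.n_labels < 1:
            raise ConfigurationError("n_labels must be >= 1")
        if self.dim_prime % self.n_heads != 0:
            raise ConfigurationError(
                f"dim_prime={self.dim_prime} must be divisible by "
                f"n_heads={self.n_heads}"
            )


@dataclass
class PredictionVector:
    """Per-label probabilities (strictly inside (0,1)) and optional labels."""

    probabilities: np.ndarray
    labels: np.ndarray | None = None


class AdrPredictor:
    """Dual-channel multi-label predictor over molecules."""

    def __init__(self, config: ModelConfig):
        self.config = config
        root = np.random.SeedSequence(config.seed)
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(5)]
        dtype = np.dtype(config.dtype).type
        self.gin_m: GinParams = init_gin_params(
            config.dim, config.T, "m", seed=seeds[0], dtype=dtype
        )
        self.gin_e: GinParams = init_gin_params(
            config.dim, config.T, "e", seed=seeds[1], dtype=dtype
        )
        self.gin_c: GinParams = init_gin_params(
            config.dim, config.T, "c", seed=seeds[2], dtype=dtype
        )
        self.encoder: EncoderParams = init_encoder_params(
            dim_prime=config.dim_prime,
            n_heads=config.n_heads,
            dim_ff=config.dim_ff,
            out_dim=config.dim,
            dropout_rate=config.dropout,
            seed=seeds[3],
            dtype=dtype,
        )
        rng = np.random.default_rng(seeds[4])
        std = np.sqrt(2.0 / (4 * config.dim + config.n_labels))
        self.W_pred = Tensor(
            rng.normal(0.0, std, size=(4 * config.dim, config.n_labels)).astype(dtype),
            requires_grad=True,
        )

    # -- parameters ---------------------------------------------------------
    def parameters(self, include_gin: bool = True) -> list[Tensor]:
        params = [*self.encoder.tensors(), self.W_pred]
        if include_gin:
            for gin in (self.gin_m, self.gin_e, self.gin_c):
                params.extend(gin.tensors())
        return params

    # -- forward ------------------------------------------------------------
    def _forward_features(
        self,
        batch: BatchedGraphs,
        token_ids: np.ndarray,
        training: bool,
        rng: np.random.Generator | None,
    ) -> Tensor:
        xm = gin_encode_batch(batch, self.gin_m)
        xe = gin_encode_batch(batch, self.gin_e)
        xc = gin_encode_batch(batch, self.gin_c)
        xf = sequence_encode_batch(token_ids, self.encoder, training=training, rng=rng)
        fused = concat([xm, xe, xc, xf], axis=1)
        if fused.shape[1] != 4 * self.config.dim:
            raise ConfigurationError(
                f"fused width {fused.shape[1]} != 4*dim={4 * self.config.dim}"
            )
        return fused

    def _forward_logits(
        self,
        batch: BatchedGraphs,
        token_ids: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        return self._forward_features(batch, token_ids, training, rng) @ self.W_pred

    def forward_pairs(
        self,
        pairs: list[tuple[MolecularGraph, SubstructureSequence]],
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Probabilities for featurized molecules, (B, n_labels)."""
        batch = batch_graphs([g for g, _ in pairs])
        tokens = np.stack([s.token_ids() for _, s in pairs])
        logits = self._forward_logits(batch, tokens, training=training, rng=rng)
        return 1.0 / (1.0 + np.exp(-logits.data))

    def forward(self, molecule: Molecule, mode: str = "eval") -> PredictionVector:
        """Predict one molecule. ``eval`` mode is deterministic."""
        if mode not in ("train", "eval"):
            raise ConfigurationError(f"unknown mode {mode!r}")
        try:
            graph = fz.smiles_to_graph(molecule.smiles)
            seq = fz.fp2_hex_sequence(molecule.smiles)
        except FeaturizationError as exc:
            raise FeaturizationError(
                f"molecule {molecule.id!r}: {exc}", smiles=molecule.smiles
            ) from exc
        rng = np.random.default_rng(self.config.seed) if mode == "train" else None
        probs = self.forward_pairs([(graph, seq)], training=mode == "train", rng=rng)
        return PredictionVector(probabilities=probs[0])

    # -- loss ---------------------------------------------------------------
    @staticmethod
    def loss(pred: np.ndarray, truth: np.ndarray) -> float:
        """Mean per-label binary cross-entropy between probabilities and
        binary targets (clipped away from exact 0/1 for finiteness)."""
        p = np.asarray(pred, dtype=float)
        y = np.asarray(truth, dtype=float)
        if p.shape != y.shape:
            raise ConfigurationError(
                f"shape mismatch: predictions {p.shape} vs truth {y.shape}"
            )
        tiny = np.finfo(float).tiny
        p = np.clip(p, tiny, 1.0 - np.finfo(float).epsneg)
        return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())

    # -- training -----------------------------------------------------------
    def fit(
        self,
        pairs: list[tuple[MolecularGraph, SubstructureSequence]],
        labels: np.ndarray,
        epochs: int | None = None,
        batch_size: int | None = None,
        seed: int | None = None,
    ) -> list[float]:
        """Train on featurized molecules; returns per-epoch mean loss.

        Deterministic for a given seed (shuffling and dropout are driven by
        a generator derived from it). Raises
        :class:`TrainingDivergenceError` if the loss goes non-finite.
        """
        if len(pairs) == 0:
            raise ConfigurationError("cannot train on an empty dataset")
        labels = np.asarray(labels, dtype=float)
        if labels.shape != (len(pairs), self.config.n_labels):
            raise ConfigurationError(
                f"labels shape {labels.shape} does not match "
                f"({len(pairs)}, {self.config.n_labels})"
            )
        epochs = self.config.epochs if epochs is None else epochs
        batch_size = self.config.batch_size if batch_size is None else batch_size
        seed = self.config.seed if seed is None else seed
        rng = np.random.default_rng(np.random.SeedSequence([seed, 911]))
        opt = Adam(
            self.parameters(include_gin=self.config.finetune_gin),
            lr=self.config.lr,
            weight_decay=self.config.weight_decay,
        )
        graphs = [g for g, _ in pairs]
        tokens = np.stack([s.token_ids() for _, s in pairs])
        n = len(pairs)
        trajectory: list[float] = []
        for epoch in range(epochs):
            order = rng.permutation(n)
            total, seen = 0.0, 0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                batch = batch_graphs([graphs[i] for i in idx])
                logits = self._forward_logits(
                    batch, tokens[idx], training=True, rng=rng
                )
                loss = bce_with_logits(logits, labels[idx]).mean()
                opt.zero_grad()
                loss.backward()
                opt.step()
                total += float(loss.data) * len(idx)
                seen += len(idx)
            epoch_loss = total / seen
            if not np.isfinite(epoch_loss):
                raise TrainingDivergenceError(
                    f"non-finite training loss at epoch {epoch}", epoch=epoch
                )
            trajectory.append(epoch_loss)
        return trajectory

    def fit_molecules(
        self,
        molecules: list[Molecule],
        labels: np.ndarray,
        **kwargs,
    ) -> list[float]:
        """Featurize (strict policy) then train; convenience wrapper."""
        result = fz.featurize_batch(molecules, on_error="strict")
        return self.fit(result.pairs, labels, **kwargs)

    # -- prediction ---------------------------------------------------------
    def predict_batch(
        self,
        molecules: list[Molecule],
        threshold: float | None = None,
    ) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str]]]:
        """Binary labels (>= threshold rule) and raw probabilities.

        Returns ``(labels, probabilities, skipped)`` where skipped pairs
        molecule ids with the featurization failure reason; successful rows
        keep the input order.
        """
        threshold = self.config.threshold if threshold is None else threshold
        result = fz.featurize_batch(molecules, on_error="skip")
        if result.pairs:
            probs = self.forward_pairs(result.pairs, training=False)
        else:
            probs = np.zeros((0, self.config.n_labels))
        labels = (probs >= threshold).astype(int)
        return labels, probs, result.skipped

    # -- persistence ----------------------------------------------------------
    def save_checkpoint(self, path) -> None:
        """Write all weights plus the full config to a versioned .npz file."""
        meta = {
            "schema_version": CHECKPOINT_SCHEMA_VERSION,
            "config": asdict(self.config),
        }
        arrays = {"W_pred": self.W_pred.data}
        for tag, gin in (("m", self.gin_m), ("e", self.gin_e), ("c", self.gin_c)):
            for t, W in enumerate(gin.Ws):
                arrays[f"gin_{tag}_W_{t}"] = W.data
            arrays[f"gin_{tag}_atom_emb"] = gin.atom_emb.data
            arrays[f"gin_{tag}_chirality_emb"] = gin.chirality_emb.data
            arrays[f"gin_{tag}_bond_type_emb"] = gin.bond_type_emb.data
            arrays[f"gin_{tag}_bond_dir_emb"] = gin.bond_dir_emb.data
        enc = self.encoder
        for name in (
            "embedding",
            "ln1_gamma",
            "ln1_beta",
            "Wq",
            "Wk",
            "Wv",
            "Wo",
            "ln2_gamma",
            "ln2_beta",
            "W_layer1",
            "bn_gamma",
            "bn_beta",
            "W_layer2",
        ):
            arrays[f"enc_{name}"] = getattr(enc, name).data
        arrays["enc_bn_running_mean"] = enc.bn_running_mean
        arrays["enc_bn_running_var"] = enc.bn_running_var
        with open(path, "wb") as f:
            np.savez(
                f,
                meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                **arrays,
            )

    @classmethod
    def load_checkpoint(cls, path, expected_n_labels: int | None = None) -> "AdrPredictor":
        """Rebuild a predictor from a checkpoint, bit-for-bit.

        ``expected_n_labels`` (e.g. a dataset's label count) is validated
        against the stored config when given.
        """
        try:
            with np.load(path) as npz:
                data = {k: npz[k] for k in npz.files}
        except FileNotFoundError:
            raise
        except Exception as exc:
            raise IOError(f"could not read checkpoint {path}: {exc}") from exc
        if "meta" not in data:
            raise ConfigurationError(f"checkpoint {path} lacks a schema header")
        meta = json.loads(bytes(data["meta"]).decode())
        if meta.get("schema_version") != CHECKPOINT_SCHEMA_VERSION:
            raise ConfigurationError(
                f"schema_version mismatch: file has {meta.get('schema_version')}, "
                f"expected {CHECKPOINT_SCHEMA_VERSION}"
            )
        config = ModelConfig(**meta["config"])
        if expected_n_labels is not None and config.n_labels != expected_n_labels:
            raise ConfigurationError(
                f"checkpoint was trained with n_labels={config.n_labels}, "
                f"but {expected_n_labels} labels were expected"
            )
        model = cls(config)

        def load_into(tensor: Tensor, key: str):
            if key not in data:
                raise ConfigurationError(f"checkpoint missing array {key!r}")
            if data[key].shape != tensor.shape:
                raise ConfigurationError(
                    f"checkpoint array {key!r} has shape {data[key].shape}, "
                    f"expected {tensor.shape}"
                )
            tensor.data = data[key]

        load_into(model.W_pred, "W_pred")
        for tag, gin in (("m", model.gin_m), ("e", model.gin_e), ("c", model.gin_c)):
            for t, W in enumerate(gin.Ws):
                load_into(W, f"gin_{tag}_W_{t}")
            load_into(gin.atom_emb, f"gin_{tag}_atom_emb")
            load_into(gin.chirality_emb, f"gin_{tag}_chirality_emb")
            load_into(gin.bond_type_emb, f"gin_{tag}_bond_type_emb")
            load_into(gin.bond_dir_emb, f"gin_{tag}_bond_dir_emb")
        enc = model.encoder
        for name in (
            "embedding",
            "ln1_gamma",
            "ln1_beta",
            "Wq",
            "Wk",
            "Wv",
            "Wo",
            "ln2_gamma",
            "ln2_beta",
            "W_layer1",
            "bn_gamma",
            "bn_beta",
            "W_layer2",
        ):
            load_into(getattr(enc, name), f"enc_{name}")
        if "enc_bn_running_mean" not in data or "enc_bn_running_var" not in data:
            raise ConfigurationError("checkpoint missing batch-norm running stats")
        enc.bn_running_mean = data["enc_bn_running_mean"]
        enc.bn_running_var = data["enc_bn_running_var"]
        return model
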