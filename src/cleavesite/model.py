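"""Training, transfer learning and ensembling of the window classifier.

The classifier is a stack of bidirectional LSTM layers over the 8-residue
window, followed by a dense layer and a single sigmoid output.  Training
uses class-weighted binary cross-entropy (the cleavage class is heavily
underrepresented), early stopping on validation F1, and protein-level
train/test/validation splits so that no protein contributes windows to
two partitions.

Transfer learning initialises a protease-specific model from a generic
model trained on a pooled protease group, freezing the first
bidirectional layer.  The final predictor is an ensemble whose members
differ only in their initialisation/shuffling seed; its score is the
arithmetic mean of the member sigmoid outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import nn
from .core import (
    AnnotationSource,
    CleavageAnnotation,
    ProteinRecord,
    ValidationError,
)
from .encoding import (
    N_FEATURES,
    WINDOW_SIZE,
    FeatureProvider,
    WindowDataset,
    encode_dataset,
)
from .evaluation import ConfusionCounts, f1


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of one classifier.

    The architecture (four bidirectional recurrent layers, one dense
    layer, one sigmoid output; early stopping on validation F1 with
    patience 20; very large epoch cap) follows the published design; the
    width, learning rate and batch size are desk-scale CPU choices and
    are fully exposed here.
    """

    n_bilstm_layers: int = 4
    hidden_units: int = 4
    dense_units: int = 32
    learning_rate: float = 2e-3
    batch_size: int = 512
    max_epochs: int = 10000
    patience: int = 20
    early_stop_min_delta: float = 5e-3
    decision_threshold: float = 0.5
    class_weighting: str = "balanced"  # or "none"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_bilstm_layers", "hidden_units", "dense_units", "batch_size", "max_epochs"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if self.patience < 1:
            raise ValidationError("patience must be >= 1")
        if self.class_weighting not in ("balanced", "none"):
            raise ValidationError("class_weighting must be 'balanced' or 'none'")


@dataclass(frozen=True)
class SplitAssignment:
    """Protein-level partition into train / test / validate."""

    assignment: Mapping[str, str]
    seed: int
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)

    def partition(self, name: str) -> tuple[str, ...]:
        return tuple(pid for pid, part in self.assignment.items() if part == name)

    @property
    def train(self) -> tuple[str, ...]:
        return self.partition("train")

    @property
    def test(self) -> tuple[str, ...]:
        return self.partition("test")

    @property
    def validate(self) -> tuple[str, ...]:
        return self.partition("validate")


def split_proteins(
    protein_ids: Sequence[str],
    seed: int = 0,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
) -> SplitAssignment:
    """Shuffle proteins and assign 70/15/15 train/test/validate partitions.

    Test and validation each receive ``floor(f * n)`` proteins; the
    remainder trains.  Splitting at the protein level guarantees the
    partitions come from independent proteins.
    """
    ids = list(protein_ids)
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate protein ids in split input")
    if len(ids) < 3:
        raise ValidationError(f"need >= 3 proteins to split, got {len(ids)}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValidationError(f"fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    order = list(ids)
    rng.shuffle(order)
    n = len(order)
    n_test = int(np.floor(fractions[1] * n))
    n_val = int(np.floor(fractions[2] * n))
    assignment: dict[str, str] = {}
    for i, pid in enumerate(order):
        if i < n_test:
            assignment[pid] = "test"
        elif i < n_test + n_val:
            assignment[pid] = "validate"
        else:
            assignment[pid] = "train"
    return SplitAssignment(assignment=assignment, seed=seed, fractions=tuple(fractions))


def class_weights(labels: np.ndarray, scheme: str = "balanced") -> dict[int, float]:
    """Per-class weights; balanced scheme gives ``w_c = N / (2 * N_c)``."""
    labels = np.asarray(labels)
    if scheme == "none":
        return {0: 1.0, 1: 1.0}
    if scheme != "balanced":
        raise ValidationError(f"unknown weighting scheme '{scheme}'")
    n = len(labels)
    counts = {c: int((labels == c).sum()) for c in (0, 1)}
    for c, cnt in counts.items():
        if cnt == 0:
            raise ValidationError(f"class {c} absent: cannot balance weights")
    return {c: n / (2.0 * cnt) for c, cnt in counts.items()}


@dataclass
class TrainedModel:
    """One trained classifier with its training history."""

    protease: str
    params: list[dict]
    config: ModelConfig
    provenance: str = "generic"  # or "transferred"
    training_log: pd.DataFrame = field(default_factory=pd.DataFrame)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return nn.predict_proba(self.params, X)

    @property
    def best_val_f1(self) -> float:
        return float(self.training_log["val_f1"].max()) if len(self.training_log) else float("nan")


@dataclass
class EnsembleModel:
    """k independently seeded models; score = mean member sigmoid output."""

    protease: str
    members: list[TrainedModel]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError("ensemble needs at least one member")
        if any(m.protease != self.protease for m in self.members):
            raise ValidationError("ensemble members disagree on protease")

    @property
    def k(self) -> int:
        return len(self.members)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return np.mean([m.predict_proba(X) for m in self.members], axis=0)


def _val_f1(params, X_val, y_val, threshold: float) -> float:
    scores = nn.predict_proba(params, X_val)
    pred = scores >= threshold
    counts = ConfusionCounts(
        tp=int((pred & (y_val == 1)).sum()),
        tn=int((~pred & (y_val == 0)).sum()),
        fp=int((pred & (y_val == 0)).sum()),
        fn=int((~pred & (y_val == 1)).sum()),
    )
    return f1(counts)


def train(
    windows: WindowDataset,
    split: SplitAssignment,
    config: ModelConfig,
    protease: str = "",
    init_params: list[dict] | None = None,
    frozen_layers: int = 0,
    provenance: str = "generic",
) -> TrainedModel:
    """Fit the classifier with early stopping on validation F1.

    Trains on the ``train`` partition, monitors F1 (at the configured
    decision threshold) on the ``validate`` partition, stops once F1 has
    not improved by more than ``early_stop_min_delta`` for ``patience``
    epochs (or at ``max_epochs``), and returns the parameters of the
    best-F1 epoch.  ``init_params`` warm-starts from existing weights;
    the first ``frozen_layers`` bidirectional layers are then excluded
    from updates (transfer learning).  Their activations are constant, so
    they are computed once and cached for the whole fit.
    """
    train_set = windows.for_proteins(split.train)
    val_set = windows.for_proteins(split.validate)
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValidationError("empty train or validation partition")
    y_train = train_set.y.astype(np.int64)
    if len(np.unique(y_train)) < 2:
        raise ValidationError("training set contains a single class")

    weights = class_weights(y_train, config.class_weighting)
    w_train = np.where(y_train == 1, weights[1], weights[0]).astype(np.float32)

    if init_params is not None:
        params = nn.clone_params(init_params)
    else:
        params = nn.init_model(
            input_dim=N_FEATURES,
            n_bilstm_layers=config.n_bilstm_layers,
            hidden_units=config.hidden_units,
            dense_units=config.dense_units,
            seed=config.seed,
        )
    if frozen_layers >= config.n_bilstm_layers:
        raise ValidationError("cannot freeze every recurrent layer")

    X_train = train_set.X
    X_val, y_val = val_set.X, val_set.y.astype(np.int64)

    # Frozen layers never change: run them once, fine-tune the suffix.
    prefix = params[:frozen_layers]
    trainable = params[frozen_layers:]
    if prefix:
        X_train = nn.apply_bilstm_prefix(prefix, X_train)
        X_val = nn.apply_bilstm_prefix(prefix, X_val)

    opt = nn.Adam(trainable, learning_rate=config.learning_rate)
    rng = np.random.default_rng(config.seed)

    best_f1 = -np.inf
    best_params = nn.clone_params(trainable)
    significant_f1 = -np.inf
    last_significant = 0
    log_rows = []
    n = len(X_train)
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            loss, grads = nn.loss_and_grads(
                trainable, X_train[idx], y_train[idx], w_train[idx]
            )
            opt.step(trainable, grads)
            epoch_loss += loss
            n_batches += 1
        val_f1 = _val_f1(trainable, X_val, y_val, config.decision_threshold)
        log_rows.append(
            {"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1), "val_f1": val_f1}
        )
        if val_f1 > best_f1:  # best-epoch weights at any margin
            if val_f1 > significant_f1 + config.early_stop_min_delta:
                significant_f1 = val_f1
                last_significant = epoch
            best_f1 = val_f1
            best_params = nn.clone_params(trainable)
        if epoch - last_significant >= config.patience:
            break

    return TrainedModel(
        protease=protease,
        params=nn.clone_params(prefix) + best_params,
        config=config,
        provenance=provenance,
        training_log=pd.DataFrame(log_rows),
    )


def pool_group_labels(
    proteins: Sequence[ProteinRecord],
    annotations: Iterable[CleavageAnnotation],
    group_proteases: Sequence[str],
    provider: FeatureProvider,
) -> WindowDataset:
    """Windows labelled 1 iff the site is cleaved by *any* group member.

    This is the generic-model training pool: data for a whole protease
    group (e.g. all MMPs) merged at the label level.
    """
    annotations = list(annotations)
    group = set(group_proteases)
    positives = {
        (a.protein_id, a.p1) for a in annotations if a.protease in group
    }
    if not group_proteases:
        raise ValidationError("group must contain at least one protease")
    base = encode_dataset(proteins, annotations, group_proteases[0], provider)
    return base.relabel(positives)


def pretrain_generic(
    group_windows: WindowDataset, split: SplitAssignment, config: ModelConfig, group: str = "generic"
) -> TrainedModel:
    """Train the generic (group-level) model used as a transfer source."""
    return train(group_windows, split, config, protease=group, provenance="generic")


def transfer(
    generic: TrainedModel,
    protease_windows: WindowDataset,
    split: SplitAssignment,
    config: ModelConfig,
    protease: str,
    freeze_layers: int = 1,
) -> TrainedModel:
    """Fine-tune the generic model on protease-specific labels.

    Weights are initialised from the generic model and the first
    ``freeze_layers`` bidirectional layers are frozen: their parameters
    are bit-identical before and after fine-tuning.
    """
    if generic.config.n_bilstm_layers != config.n_bilstm_layers or (
        generic.config.hidden_units != config.hidden_units
        or generic.config.dense_units != config.dense_units
    ):
        raise ValidationError("generic model architecture does not match config")
    if generic.params[0]["fwd"]["Wx"].shape[0] != protease_windows.X.shape[2]:
        raise ValidationError("generic model input dimensionality does not match windows")
    return train(
        protease_windows,
        split,
        config,
        protease=protease,
        init_params=generic.params,
        frozen_layers=freeze_layers,
        provenance="transferred",
    )


def train_ensemble(
    windows: WindowDataset,
    split: SplitAssignment,
    config: ModelConfig,
    protease: str,
    k: int = 5,
    generic: TrainedModel | None = None,
    freeze_layers: int = 1,
) -> EnsembleModel:
    """Train a k-member ensemble (default 5) with seed offsets.

    Members share data and configuration and differ only in seed
    (``config.seed + 0 .. k-1``), which drives initialisation and batch
    shuffling.  When ``generic`` is given every member is produced by
    transfer learning from it.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    members = []
    for i in range(k):
        cfg = replace(config, seed=config.seed + i)
        if generic is not None:
            members.append(
                transfer(generic, windows, split, cfg, protease, freeze_layers=freeze_layers)
            )
        else:
            members.append(train(windows, split, cfg, protease=protease))
    return EnsembleModel(protease=protease, members=members)


def predict(
    ensemble: EnsembleModel, protein: ProteinRecord, provider: FeatureProvider
) -> list[CleavageAnnotation]:
    """Score every candidate site of one protein with the ensemble."""
    if protein.length < 2:
        return []
    dataset = encode_dataset([protein], [], ensemble.protease, provider)
    scores = ensemble.predict_proba(dataset.X)
    return [
        CleavageAnnotation(
            protease=ensemble.protease,
            protein_id=protein.id,
            p1=int(p1),
            source=AnnotationSource.PREDICTION,
            score=float(np.clip(s, 0.0, 1.0)),
        )
        for p1, s in zip(dataset.p1, scores)
    ]


def predict_windows(ensemble: EnsembleModel, windows: WindowDataset) -> np.ndarray:
    """Ensemble scores for an already-encoded window set."""
    return ensemble.predict_proba(windows.X)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def _params_to_flat(params: list[dict]) -> dict[str, np.ndarray]:
    return {f"{li}.{key}" + (f".{k2}" if k2 else ""): arr
            for (li, key, k2), arr in nn._iter_arrays(params)}


def save_ensemble(ensemble: EnsembleModel, out_dir: str | Path) -> None:
    """Write a model directory: config.json, member weights, training logs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = asdict(ensemble.members[0].config)
    meta = {
        "protease": ensemble.protease,
        "k": ensemble.k,
        "config": cfg,
        "provenance": [m.provenance for m in ensemble.members],
    }
    (out / "config.json").write_text(json.dumps(meta, indent=2))
    for i, member in enumerate(ensemble.members):
        np.savez(out / f"member_{i}.npz", **_params_to_flat(member.params))
        member.training_log.to_csv(out / f"training_log_{i}.tsv", sep="\t", index=False)


def load_ensemble(model_dir: str | Path) -> EnsembleModel:
    model_dir = Path(model_dir)
    meta = json.loads((model_dir / "config.json").read_text())
    config = ModelConfig(**meta["config"])
    members = []
    for i in range(meta["k"]):
        flat = dict(np.load(model_dir / f"member_{i}.npz"))
        params = nn.init_model(
            input_dim=N_FEATURES,
            n_bilstm_layers=config.n_bilstm_layers,
            hidden_units=config.hidden_units,
            dense_units=config.dense_units,
            seed=config.seed,
        )
        for (li, key, k2), arr in nn._iter_arrays(params):
            name = f"{li}.{key}" + (f".{k2}" if k2 else "")
            stored = flat[name]
            if stored.shape != arr.shape:
                raise ValidationError(f"{model_dir}: weight {name} has wrong shape")
            arr[...] = stored
        log_path = model_dir / f"training_log_{i}.tsv"
        log = pd.read_csv(log_path, sep="\t") if log_path.exists() else pd.DataFrame()
        members.append(
            TrainedModel(
                protease=meta["protease"],
                params=params,
                config=config,
                provenance=meta["provenance"][i],
                training_log=log,
            )
        )
    return EnsembleModel(protease=meta["protease"], members=members)
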