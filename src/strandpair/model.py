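"""Model/Results interface over the pairing network.

`BetaPairingModel` holds a prepared dataset (feature tensors plus labels);
`fit()` runs the cross-validated training and returns a
`BetaPairingResults` carrying the fold ensemble, the training histories,
the CV-selected probability cutoff and per-fold diagnostics, with
`predict()`, `summary()` and checkpoint `save()`/`load()` attached.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import evaluate_per_protein
from .features import FeatureTensor, assemble_features
from .io import PairingProbMap
from .pairnet import EnsembleModel, ModelConfig, PairNet, TrainConfig, train


def _registry_hash(names) -> str:
    return hashlib.sha1(",".join(names).encode()).hexdigest()[:12]


class BetaPairingModel:
    """Cross-validated beta-beta pairing predictor over a prepared dataset."""

    def __init__(self, tensors, labels, ids=None):
        self.tensors = list(tensors)
        self.labels = list(labels)
        if len(self.tensors) != len(self.labels):
            raise ValueError("tensors and labels differ in length")
        self.ids = list(ids) if ids is not None else [f"p{k}" for k in range(len(self.tensors))]

    @classmethod
    def from_proteins(cls, proteins, groups=None):
        """Build from SyntheticProtein records (or any objects with map_a,
        map_b, ridge_a, ridge_b, profile, labels attributes)."""
        from .features import FEATURE_GROUPS

        groups = groups or FEATURE_GROUPS
        tensors, labels, ids = [], [], []
        for p in proteins:
            tensors.append(assemble_features(p.map_a, p.map_b, p.ridge_a, p.ridge_b,
                                             p.profile, groups=groups))
            labels.append(p.labels)
            ids.append(getattr(p, "protein_id", f"p{len(ids)}"))
        return cls(tensors, labels, ids)

    def fit(self, model_config: ModelConfig | None = None,
            train_config: TrainConfig | None = None) -> "BetaPairingResults":
        model_config = model_config or ModelConfig(
            in_channels=self.tensors[0].n_channels)
        train_config = train_config or TrainConfig()
        ensemble, histories = train(list(zip(self.tensors, self.labels)),
                                    model_config, train_config)
        return BetaPairingResults(model=self, ensemble=ensemble,
                                  histories=histories, train_config=train_config)


@dataclass
class BetaPairingResults:
    """Fitted ensemble plus training diagnostics."""

    model: BetaPairingModel
    ensemble: EnsembleModel
    histories: list
    train_config: TrainConfig

    @property
    def cutoff(self) -> float:
        """Probability cutoff selected by pooled cross-validation F1."""
        return self.ensemble.cutoff

    @property
    def history_frame(self) -> pd.DataFrame:
        rows = [row for fold in self.histories for row in fold]
        return pd.DataFrame(rows)

    @property
    def fold_f1(self) -> list:
        """Best pooled validation F1 reached by each trained fold."""
        return [max((r["val_f1"] for r in fold), default=float("nan"))
                for fold in self.histories if fold]

    def predict(self, features: FeatureTensor) -> PairingProbMap:
        """Mean-of-folds pairing probability map for one protein."""
        return self.ensemble.predict(features)

    def evaluate(self, tensors, labels, ids=None, cutoff: float | None = None) -> pd.DataFrame:
        """Per-protein P/R/F1 table (plus pooled row) at the selected cutoff."""
        preds = [self.predict(t) for t in tensors]
        return evaluate_per_protein(preds, labels, self.cutoff if cutoff is None else cutoff,
                                    ids=ids)

    def summary(self) -> str:
        cfg = self.ensemble.config
        lines = [
            "Beta-beta pairing network: cross-validated fit",
            "=" * 54,
            f"blocks: {cfg.n_blocks}   channels: {cfg.n_channels}   "
            f"RN/CN: {'on' if cfg.use_rncn else 'off'}",
            f"training proteins: {len(self.model.tensors)}   "
            f"folds trained: {len(self.ensemble.models)}/{self.train_config.n_folds}",
            f"learning rate: {self.train_config.learning_rate:g}   "
            f"seed: {self.train_config.seed}",
            f"selected cutoff (pooled CV F1): {self.cutoff:.4f}",
            "-" * 54,
            "fold   epochs   best val F1",
        ]
        for k, fold in enumerate(self.histories_nonempty()):
            best = max(r["val_f1"] for r in fold)
            lines.append(f"{k:>4}   {len(fold):>6}   {best:.4f}")
        return "\n".join(lines)

    def histories_nonempty(self):
        return [h for h in self.histories if h]

    # -- checkpointing -----------------------------------------------------

    def save(self, directory) -> None:
        """Checkpoint: JSON manifest plus one .npz weight file per fold."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        names = self.model.tensors[0].channel_names if self.model.tensors else []
        manifest = {
            "model_config": asdict(self.ensemble.config),
            "train_config": asdict(self.train_config),
            "cutoff": self.cutoff,
            "n_folds_trained": len(self.ensemble.models),
            "channel_registry_hash": _registry_hash(names),
            "histories": self.histories,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
        for k, net in enumerate(self.ensemble.models):
            np.savez(directory / f"fold{k}.npz", **net.params)

    @staticmethod
    def load_ensemble(directory) -> EnsembleModel:
        """Load the fold ensemble saved by :meth:`save`."""
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        cfg = ModelConfig(**manifest["model_config"])
        models = []
        for k in range(manifest["n_folds_trained"]):
            with np.load(directory / f"fold{k}.npz") as data:
                models.append(PairNet(cfg, params={key: data[key] for key in data.files}))
        return EnsembleModel(models=models, config=cfg, cutoff=manifest["cutoff"])
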