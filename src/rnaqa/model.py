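"""Model/Results facade over the scorer, in the style of statsmodels.

``RNAQualityModel`` is built from a labelled decoy dataset (or a manifest
on disk); ``fit()`` runs the training protocol and returns an
``RNAQualityResults`` carrying the fitted parameters, the loss trace,
simple diagnostics and a ``summary()`` table. Scoring new structures and
serialisation hang off the results object.
"""

from __future__ import annotations

import numpy as np

from . import training as tr
from .network import (
    ModelConfig,
    QualityPrediction,
    load_params,
    parameter_count,
    predict,
    save_params,
)


class RNAQualityModel:
    """Per-nucleotide RNA model-quality scorer, specified by an architecture
    config and the dataset it will be fitted to."""

    def __init__(self, dataset: list[tr.TrainingExample],
                 config: ModelConfig | None = None,
                 validation: list[tr.TrainingExample] | None = None):
        self.dataset = dataset
        self.validation = validation
        self.config = config or ModelConfig()

    @classmethod
    def from_manifest(cls, manifest, config: ModelConfig | None = None,
                      validation_fraction: float = 0.0, seed: int = 0):
        """Build from a decoy manifest, optionally holding out whole decoys
        (native-stratified order) for validation."""
        dataset = tr.dataset_from_manifest(manifest)
        if validation_fraction > 0:
            rng = np.random.default_rng(seed)
            idx = rng.permutation(len(dataset))
            n_val = max(1, int(round(validation_fraction * len(dataset))))
            val = [dataset[i] for i in idx[:n_val]]
            trainset = [dataset[i] for i in idx[n_val:]]
            return cls(trainset, config, validation=val)
        return cls(dataset, config)

    def fit(self, train_config: tr.TrainConfig | None = None, log=None) -> "RNAQualityResults":
        tc = train_config or tr.TrainConfig()
        params, trace = tr.train(self.dataset, self.config, tc,
                                 validation=self.validation, log=log)
        return RNAQualityResults(self, params, trace, tc)


class RNAQualityResults:
    """Fitted scorer: parameters, loss trace, diagnostics, prediction."""

    def __init__(self, model: RNAQualityModel, params, trace, train_config):
        self.model = model
        self.config = model.config
        self.params = params
        self.trace = trace
        self.train_config = train_config

    # ---- estimates & diagnostics ---------------------------------------------
    @property
    def final_train_mae(self) -> float:
        return self.trace[-1]["train_mae"]

    @property
    def final_val_mae(self) -> float | None:
        return self.trace[-1].get("val_mae")

    def predict(self, structure) -> QualityPrediction:
        """Score a structure: pNuL per nucleotide and pMoL = mean(pNuL)."""
        return predict(structure, self.params, self.config)

    def predict_dataset(self, dataset: list[tr.TrainingExample]) -> list[dict]:
        """Score each example; returns records with predicted pMoL and the
        true global lDDT, ready for the evaluation metrics."""
        out = []
        for ex in dataset:
            pred = self.predict(ex.decoy)
            out.append({
                "target_id": ex.native_id, "model_id": ex.decoy.id,
                "predicted": pred.pmol, "truth_lddt": ex.truth_global,
                "pnul": pred.pnul, "labels": ex.labels, "mask": ex.mask,
            })
        return out

    def summary(self) -> str:
        c = self.config
        rows = [
            ("IPA layers", c.n_layers), ("attention heads", c.n_heads),
            ("hidden width c", c.hidden), ("query points", c.n_query_points),
            ("value points", c.n_value_points), ("neighbours K", c.K),
            ("parameters", parameter_count(c)),
            ("training examples", len(self.model.dataset)),
            ("epochs", len(self.trace)),
            ("learning rate", self.train_config.learning_rate),
            ("seed", self.train_config.seed),
            ("final train MAE", f"{self.final_train_mae:.4f}"),
        ]
        if self.final_val_mae is not None:
            rows.append(("final val MAE", f"{self.final_val_mae:.4f}"))
        width = max(len(k) for k, _ in rows)
        lines = ["RNA Quality Scorer (locality-aware IPA)", "=" * 44]
        lines += [f"{k:<{width}}  {v}" for k, v in rows]
        return "\n".join(lines)

    # ---- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        save_params(self.params, self.config, path, seed=self.train_config.seed)

    @staticmethod
    def load(path) -> "RNAQualityResults":
        params, config, seed = load_params(path)
        model = RNAQualityModel(dataset=[], config=config)
        tc = tr.TrainConfig(seed=seed if seed is not None else 0)
        return RNAQualityResults(model, params, trace=[{"epoch": 0, "train_mae": float("nan")}],
                                 train_config=tc)
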