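"""The fused fingerprint + graph capsule classifier.

:class:`CarcinogenicityModel` is built from curated molecule records and a
choice of fingerprint family and architecture variant; :meth:`fit` trains
the network and returns a :class:`CarcinogenicityResults` object carrying
the learned parameters, the loss trajectory and prediction/evaluation
methods; :meth:`cross_validate` runs repeated stratified k-fold CV and
returns an aggregated :class:`CrossValidationResults`.

Architecture (the "full" variant): the selected fingerprint vector is
concatenated with the 50-d graph-attention embedding, passed through two
fully connected blocks (Linear -> BatchNorm -> ReLU -> Dropout, 128 units
each), reshaped into 16 input capsules of dimension 8, squashed, and routed
by the self-attention capsule layer into 2 output capsules of dimension 2.
The length of each output capsule is the class score; training minimises
the margin loss with Adam.

Variants: ``full`` (both branches, self-attention routing), ``NA`` (both
branches, 3-iteration dynamic routing), ``OF`` (fingerprint branch only),
``OG`` (graph branch only).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .autodiff import Adam, Parameter, Tensor, concat, dropout_mask
from .capsule import (CapsuleLayer, CapsuleLayerParams, LossConfig,
                      capsule_lengths, margin_loss, squash)
from .chemio import MoleculeRecord
from .feature_selection import SelectionConfig, SelectionMask, fit_selection
from .fingerprints import FeatureMatrix, FINGERPRINT_REGISTRY, featurize_dataset
from .gat import GATEncoder
from .molgraph import MolecularGraph, batch_graphs, mol_to_graph

__all__ = ["TrainConfig", "MetricsReport", "compute_metrics", "predict",
           "CarcinogenicityModel", "CarcinogenicityResults",
           "CrossValidationResults", "VARIANTS"]

VARIANTS = ("full", "NA", "OF", "OG")


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (defaults are the published optimum values)."""

    batch_size: int = 256
    learning_rate: float = 0.001
    weight_decay: float = 0.001
    epochs: int = 100
    dropout: float = 0.2
    fc_units: int = 128
    seed: int = 0

    def __post_init__(self):
        assert min(self.batch_size, self.epochs, self.fc_units) > 0
        assert self.learning_rate > 0 and self.weight_decay >= 0
        assert 0 <= self.dropout < 1


# -- metrics ----------------------------------------------------------------

@dataclass
class MetricsReport:
    """Confusion counts and SE/SP/ACC/AUC for one evaluation."""

    TP: int
    TN: int
    FP: int
    FN: int
    SE: float
    SP: float
    ACC: float
    AUC: float

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def to_series(self) -> pd.Series:
        return pd.Series(asdict(self))


def compute_metrics(labels: np.ndarray, predictions: np.ndarray,
                    scores: np.ndarray) -> MetricsReport:
    """Sensitivity, specificity, accuracy and AUC of binary predictions.

    AUC is the probability that a randomly drawn carcinogen outscores a
    randomly drawn non-carcinogen, with ties counting one half.
    """
    labels = np.asarray(labels).astype(int)
    predictions = np.asarray(predictions).astype(int)
    scores = np.asarray(scores, dtype=float)
    if not (len(labels) == len(predictions) == len(scores)):
        raise ValueError("labels, predictions and scores must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: only one class present")
    tp = int(np.sum((labels == 1) & (predictions == 1)))
    tn = int(np.sum((labels == 0) & (predictions == 0)))
    fp = int(np.sum((labels == 0) & (predictions == 1)))
    fn = int(np.sum((labels == 1) & (predictions == 0)))
    se = tp / (tp + fn)
    sp = tn / (tn + fp)
    acc = (tp + tn) / len(labels)
    auc = float(roc_auc_score(labels, scores))
    return MetricsReport(tp, tn, fp, fn, se, sp, acc, auc)


def predict(lengths: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels and AUC scores from per-class capsule lengths.

    Capsule 0 is the carcinogen class (label 1) and capsule 1 the
    non-carcinogen class; the carcinogen-capsule length is the score. A tie
    in lengths is resolved to non-carcinogen.
    """
    lengths = np.atleast_2d(np.asarray(lengths, dtype=float))
    labels = (lengths[:, 0] > lengths[:, 1]).astype(int)
    return labels, lengths[:, 0]


# -- network building blocks ------------------------------------------------

class _Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (d_in + d_out))
        self.W = Parameter(rng.uniform(-limit, limit, size=(d_in, d_out)))
        self.b = Parameter(np.zeros(d_out))
        self.params = [self.W, self.b]

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class _BatchNorm:
    def __init__(self, d: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))
        self.running_mean = np.zeros(d)
        self.running_var = np.ones(d)
        self.momentum, self.eps = momentum, eps
        self.params = [self.gamma, self.beta]

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = x.mean(axis=0, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=0, keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
            xhat = xc / (var + self.eps).sqrt()
        else:
            xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return xhat * self.gamma + self.beta


class _Network:
    """Fingerprint/graph fusion -> two FC blocks -> capsule head."""

    def __init__(self, d_fp: int, variant: str, config: TrainConfig,
                 rng: np.random.Generator,
                 caps_params: CapsuleLayerParams = CapsuleLayerParams()):
        assert variant in VARIANTS
        self.variant = variant
        self.config = config
        self.caps_params = caps_params
        self.use_fp = variant in ("full", "NA", "OF")
        self.use_graph = variant in ("full", "NA", "OG")
        self.encoder = GATEncoder.init(rng) if self.use_graph else None
        d_in = (d_fp if self.use_fp else 0) + (self.encoder.d_out if self.use_graph else 0)
        if d_in == 0:
            raise ValueError("network has no input branch")
        fc = config.fc_units
        assert fc == caps_params.n_in * caps_params.d_in, \
            "FC width must reshape into the input capsules"
        self.fc1 = _Linear(d_in, fc, rng)
        self.bn1 = _BatchNorm(fc)
        self.fc2 = _Linear(fc, fc, rng)
        self.bn2 = _BatchNorm(fc)
        routing = "dynamic" if variant == "NA" else "self_attention"
        self.capsule = CapsuleLayer(caps_params, rng, routing=routing)

    @property
    def params(self) -> list[Parameter]:
        ps = self.fc1.params + self.bn1.params + self.fc2.params + self.bn2.params
        ps += self.capsule.params
        if self.encoder is not None:
            ps += self.encoder.params
        return ps

    def forward(self, fp: np.ndarray | None, graphs: list[MolecularGraph] | None,
                *, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """Per-class capsule lengths for a batch of molecules."""
        parts: list[Tensor] = []
        if self.use_fp:
            if fp is None:
                raise ValueError(f"variant {self.variant!r} requires fingerprints")
            parts.append(Tensor(fp))
        if self.use_graph:
            if graphs is None:
                raise ValueError(f"variant {self.variant!r} requires molecular graphs")
            batch = batch_graphs(graphs)
            parts.append(self.encoder(batch, training=training, rng=rng))
        x = parts[0] if len(parts) == 1 else concat(parts, axis=1)
        for lin, bn in ((self.fc1, self.bn1), (self.fc2, self.bn2)):
            x = bn(lin(x), training).relu()
            if training and self.config.dropout > 0:
                x = x * dropout_mask(rng, x.shape, self.config.dropout)
        u = squash(x.reshape(-1, self.caps_params.n_in, self.caps_params.d_in))
        v, _state = self.capsule(u)
        return capsule_lengths(v)

    # -- parameter (de)serialisation --

    def get_state(self) -> dict[str, np.ndarray]:
        state = {f"p{i}": p.data for i, p in enumerate(self.params)}
        state["bn1_mean"], state["bn1_var"] = self.bn1.running_mean, self.bn1.running_var
        state["bn2_mean"], state["bn2_var"] = self.bn2.running_mean, self.bn2.running_var
        return state

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params):
            p.data = np.asarray(state[f"p{i}"], dtype=np.float64)
        self.bn1.running_mean = np.asarray(state["bn1_mean"])
        self.bn1.running_var = np.asarray(state["bn1_var"])
        self.bn2.running_mean = np.asarray(state["bn2_mean"])
        self.bn2.running_var = np.asarray(state["bn2_var"])


@dataclass
class _Standardizer:
    """Z-scores count-valued columns with training statistics; bits pass through."""

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, values: np.ndarray) -> "_Standardizer":
        is_count = np.array([not set(np.unique(col)) <= {0.0, 1.0}
                             for col in values.T])
        mean = np.where(is_count, values.mean(axis=0), 0.0)
        std = values.std(axis=0, ddof=0)
        scale = np.where(is_count & (std > 0), std, 1.0)
        return cls(mean, scale)

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (values - self.mean) / self.scale


# -- model / results --------------------------------------------------------

class CarcinogenicityModel:
    """Capsule carcinogenicity classifier built from curated records.

    Parameters
    ----------
    records : curated molecule records (canonical SMILES, binary labels).
    fingerprint : one of the 12 registered fingerprint family names.
    variant : "full", "NA" (dynamic routing), "OF" (fingerprints only) or
        "OG" (graph only).
    config : training hyperparameters.
    selection : thresholds of the variance/correlation feature filters.
    """

    def __init__(self, records: Sequence[MoleculeRecord],
                 fingerprint: str = "CDKExt", variant: str = "full",
                 config: TrainConfig = TrainConfig(),
                 selection: SelectionConfig = SelectionConfig(),
                 loss: LossConfig = LossConfig()):
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}")
        if fingerprint not in FINGERPRINT_REGISTRY:
            raise ValueError(f"unknown fingerprint {fingerprint!r}")
        if len({r.label for r in records}) < 2:
            raise ValueError("dataset must contain both classes")
        self.records = list(records)
        self.fingerprint = fingerprint
        self.variant = variant
        self.config = config
        self.selection = selection
        self.loss = loss
        self.labels = np.array([r.label for r in self.records], dtype=int)
        self._fp_matrix: FeatureMatrix | None = None
        self._graphs: list[MolecularGraph] | None = None

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "CarcinogenicityModel":
        records = [MoleculeRecord(str(r.id), str(r.smiles), int(r.label),
                                  getattr(r, "source", "dataframe"))
                   for r in df.itertuples(index=False)]
        return cls(records, **kwargs)

    # cached featurisation -------------------------------------------------

    @property
    def fp_matrix(self) -> FeatureMatrix:
        if self._fp_matrix is None:
            self._fp_matrix = featurize_dataset(self.records, self.fingerprint)
        return self._fp_matrix

    @property
    def graphs(self) -> list[MolecularGraph]:
        if self._graphs is None:
            self._graphs = [mol_to_graph(r) for r in self.records]
        return self._graphs

    def _needs_fp(self) -> bool:
        return self.variant in ("full", "NA", "OF")

    def _needs_graph(self) -> bool:
        return self.variant in ("full", "NA", "OG")

    # training -------------------------------------------------------------

    def _train_on(self, idx: np.ndarray, seed: int,
                  mask: SelectionMask | None = None,
                  ) -> tuple[_Network, SelectionMask | None, _Standardizer | None, list[float]]:
        cfg = self.config
        ss = np.random.SeedSequence(seed)
        init_rng, run_rng = (np.random.default_rng(c) for c in ss.spawn(2))
        fp = std = None
        d_fp = 0
        if self._needs_fp():
            train_fp = self.fp_matrix.select_columns(range(self.fp_matrix.shape[1]))
            sub = FeatureMatrix(train_fp.values[idx], train_fp.feature_names,
                                [train_fp.molecule_ids[i] for i in idx])
            if mask is None:
                mask = fit_selection(sub, self.selection, fitted_on=self.fingerprint)
            reduced = mask.apply(sub)
            std = _Standardizer.fit(reduced.values)
            fp = std.transform(reduced.values)
            d_fp = fp.shape[1]
        graphs = [self.graphs[i] for i in idx] if self._needs_graph() else None
        labels = self.labels[idx]
        net = _Network(d_fp, self.variant, cfg, init_rng)
        opt = Adam(net.params, lr=cfg.learning_rate,
                   weight_decay=cfg.weight_decay)
        n = len(idx)
        # capsule order: [carcinogen, non-carcinogen]
        onehot = np.column_stack([labels, 1 - labels]).astype(float)
        history: list[float] = []
        for epoch in range(cfg.epochs):
            order = run_rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                b = order[start:start + cfg.batch_size]
                if len(b) < 2:
                    continue  # batchnorm needs at least two rows
                lengths = net.forward(
                    fp[b] if fp is not None else None,
                    [graphs[i] for i in b] if graphs is not None else None,
                    training=True, rng=run_rng)
                loss = margin_loss(lengths, onehot[b], self.loss)
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"training diverged (loss={loss.data}) at epoch {epoch}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            history.append(float(np.mean(losses)))
        return net, mask, std, history

    def fit(self, seed: int | None = None) -> "CarcinogenicityResults":
        """Train on all records; returns the fitted results object."""
        seed = self.config.seed if seed is None else seed
        idx = np.arange(len(self.records))
        net, mask, std, history = self._train_on(idx, seed)
        return CarcinogenicityResults(self, net, mask, std, history, seed)

    # cross-validation -----------------------------------------------------

    def cross_validate(self, k: int = 5, repeats: int = 1,
                       seed: int | None = None,
                       refit_mask_per_fold: bool = True,
                       ) -> "CrossValidationResults":
        """Repeated stratified k-fold CV with per-fold selection refit."""
        if k < 2:
            raise ValueError("k must be >= 2")
        seed = self.config.seed if seed is None else seed
        ss = np.random.SeedSequence(seed)
        global_mask = None
        if not refit_mask_per_fold and self._needs_fp():
            global_mask = fit_selection(self.fp_matrix, self.selection,
                                        fitted_on=self.fingerprint)
        reports: list[MetricsReport] = []
        masks: list[SelectionMask | None] = []
        assignments: list[np.ndarray] = []
        for rep, rep_ss in enumerate(ss.spawn(repeats)):
            states = rep_ss.generate_state(2)
            splitter = StratifiedKFold(n_splits=k, shuffle=True,
                                       random_state=int(states[0] % (2 ** 31)))
            fold_of = np.full(len(self.records), -1)
            for fold, (tr, va) in enumerate(
                    splitter.split(np.zeros(len(self.records)), self.labels)):
                if len(np.unique(self.labels[va])) < 2:
                    raise ValueError("stratification failure: single-class fold")
                fold_of[va] = fold
                train_seed = int((states[1] + fold) % (2 ** 31))
                net, mask, std, _hist = self._train_on(tr, train_seed,
                                                       mask=global_mask)
                rep_metrics = self._evaluate_indices(net, mask, std, va)
                reports.append(rep_metrics)
                masks.append(mask)
            assignments.append(fold_of)
        return CrossValidationResults(self, reports, masks, assignments,
                                      k=k, repeats=repeats, seed=seed)

    def _evaluate_indices(self, net: _Network, mask, std,
                          idx: np.ndarray) -> MetricsReport:
        fp = None
        if self._needs_fp():
            sub = FeatureMatrix(self.fp_matrix.values[idx],
                                self.fp_matrix.feature_names,
                                [self.fp_matrix.molecule_ids[i] for i in idx])
            fp = std.transform(mask.apply(sub).values)
        graphs = [self.graphs[i] for i in idx] if self._needs_graph() else None
        lengths = _forward_in_chunks(net, fp, graphs)
        pred, score = predict(lengths)
        return compute_metrics(self.labels[idx], pred, score)


def _forward_in_chunks(net: _Network, fp, graphs, chunk: int = 512) -> np.ndarray:
    n = len(fp) if fp is not None else len(graphs)
    outs = []
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        outs.append(net.forward(fp[sl] if fp is not None else None,
                                graphs[sl] if graphs is not None else None).data)
    return np.concatenate(outs, axis=0)


class CarcinogenicityResults:
    """Fitted model: learned parameters, loss trajectory, predictions."""

    def __init__(self, model: CarcinogenicityModel, net: _Network,
                 mask: SelectionMask | None, std: _Standardizer | None,
                 loss_history: list[float], seed: int):
        self.model = model
        self._net = net
        self.selection_mask = mask
        self._std = std
        self.loss_history = loss_history
        self.seed = seed

    @property
    def n_selected_features(self) -> int | None:
        return len(self.selection_mask.kept_indices) if self.selection_mask else None

    def _featurize(self, records: Sequence[MoleculeRecord]):
        fp = graphs = None
        if self.model._needs_fp():
            matrix = featurize_dataset(records, self.model.fingerprint)
            fp = self._std.transform(self.selection_mask.apply(matrix).values)
        if self.model._needs_graph():
            graphs = [mol_to_graph(r) for r in records]
        return fp, graphs

    def capsule_lengths(self, records: Sequence[MoleculeRecord]) -> np.ndarray:
        fp, graphs = self._featurize(records)
        return _forward_in_chunks(self._net, fp, graphs)

    def predict(self, records: Sequence[MoleculeRecord]) -> pd.DataFrame:
        """Per-molecule predicted label and carcinogen score."""
        labels, scores = predict(self.capsule_lengths(records))
        return pd.DataFrame({"id": [r.id for r in records],
                             "predicted_label": labels, "score": scores})

    def evaluate(self, records: Sequence[MoleculeRecord]) -> MetricsReport:
        labels, scores = predict(self.capsule_lengths(records))
        truth = np.array([r.label for r in records])
        return compute_metrics(truth, labels, scores)

    def summary(self) -> str:
        lines = [
            "Capsule carcinogenicity classifier",
            "=" * 42,
            f"variant:            {self.model.variant}",
            f"fingerprint:        {self.model.fingerprint}",
            f"n molecules:        {len(self.model.records)}",
            f"selected features:  {self.n_selected_features}",
            f"epochs:             {len(self.loss_history)}",
            f"final margin loss:  {self.loss_history[-1]:.4f}",
            f"seed:               {self.seed}",
        ]
        return "\n".join(lines)

    # checkpointing ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Binary parameter blob (.npz) + JSON sidecar of the run config."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self._net.get_state())
        sidecar = {
            "variant": self.model.variant,
            "fingerprint": self.model.fingerprint,
            "config": asdict(self.model.config),
            "loss_config": asdict(self.model.loss),
            "selection_mask": (json.loads(self.selection_mask.to_json())
                               if self.selection_mask else None),
            "standardizer": ({"mean": self._std.mean.tolist(),
                              "scale": self._std.scale.tolist()}
                             if self._std else None),
            "loss_history": self.loss_history,
            "seed": self.seed,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path,
             records: Sequence[MoleculeRecord]) -> "CarcinogenicityResults":
        """Rebuild a fitted results object from a checkpoint.

        ``records`` re-seeds the model context (e.g. for evaluate());
        the learned parameters come from the checkpoint alone.
        """
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        model = CarcinogenicityModel(
            records, fingerprint=sidecar["fingerprint"],
            variant=sidecar["variant"],
            config=TrainConfig(**sidecar["config"]),
            loss=LossConfig(**sidecar["loss_config"]))
        mask = (SelectionMask(**sidecar["selection_mask"])
                if sidecar["selection_mask"] else None)
        std = (_Standardizer(np.array(sidecar["standardizer"]["mean"]),
                             np.array(sidecar["standardizer"]["scale"]))
               if sidecar["standardizer"] else None)
        rng = np.random.default_rng(0)
        d_fp = len(mask.kept_indices) if mask else 0
        net = _Network(d_fp, sidecar["variant"], model.config, rng)
        with np.load(path.with_suffix(".npz")) as data:
            net.set_state({k: data[k] for k in data.files})
        return cls(model, net, mask, std, sidecar["loss_history"], sidecar["seed"])


class CrossValidationResults:
    """Metrics of every fold evaluation plus mean +/- std aggregations."""

    def __init__(self, model: CarcinogenicityModel,
                 reports: list[MetricsReport],
                 masks: list[SelectionMask | None],
                 fold_assignments: list[np.ndarray],
                 k: int, repeats: int, seed: int):
        self.model = model
        self.reports = reports
        self.masks = masks
        self.fold_assignments = fold_assignments
        self.k, self.repeats, self.seed = k, repeats, seed

    def as_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame([r.to_series() for r in self.reports])
        df.insert(0, "repeat", np.repeat(np.arange(self.repeats), self.k))
        df.insert(1, "fold", np.tile(np.arange(self.k), self.repeats))
        return df

    def aggregate(self, level: str = "fold") -> pd.DataFrame:
        """Mean +/- std over all fold evaluations (``"fold"``) or over
        repeat-level means (``"repeat"``)."""
        df = self.as_dataframe()[["SE", "SP", "ACC", "AUC"]]
        if level == "repeat":
            rep = self.as_dataframe().groupby("repeat")[["SE", "SP", "ACC", "AUC"]].mean()
            return pd.DataFrame({"mean": rep.mean(), "std": rep.std(ddof=0)})
        return pd.DataFrame({"mean": df.mean(), "std": df.std(ddof=0)})

    def summary(self) -> str:
        agg = self.aggregate()
        lines = [
            f"Stratified {self.k}-fold CV x {self.repeats} repeat(s)  "
            f"(variant={self.model.variant}, fingerprint={self.model.fingerprint}, "
            f"n={len(self.model.records)})",
            "-" * 72,
        ]
        for name in ("ACC", "SE", "SP", "AUC"):
            lines.append(f"{name:4s} {agg.loc[name, 'mean']:.3f} "
                         f"± {agg.loc[name, 'std']:.3f}")
        return "\n".join(lines)
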