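"""Mixture of experts for longevity prediction.

Two experts — a discrete Bayesian network over the binned longevity and a
multilayer perceptron on the scaled descriptor — each predict the
restoration longevity; a second, small MLP (2 inputs, 5 hidden neurons)
combines their outputs into the final estimate.  The combiner is trained
on *out-of-fold* expert predictions (stacking): the experts are refitted
on internal folds so the combiner never sees resubstitution outputs,
which would understate the experts' true error.

All quantities crossing the combiner travel in the sigmoid working range
via a single longevity scaler, so the combiner sees its inputs and target
on the same scale; predictions are inverse-scaled back to years and
clamped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bayes_net import BayesNet, DiscreteData, bn_expected_longevity, fit_cpts, learn_structure
from .case_model import Case, CaseEncoder, RESTORATION_TYPES
from .mlp import MLPModel, RangeScaler, mlp_forward, mlp_init, mlp_train


class TrainingSizeError(ValueError):
    """Too few cases to train a mixture; callers fall back to averaging."""


@dataclass
class MixtureConfig:
    min_cases: int = 20
    oof_folds: int = 5
    validation_fraction: float = 0.2
    bn_alpha: float = 0.05
    bn_max_cond: int = 1
    bn_laplace: float = 1.0
    eta: float = 0.1
    mu: float = 0.9
    epochs: int = 200
    patience: int = 15
    combiner_epochs: int = 300


@dataclass
class MixtureModel:
    bn_expert: BayesNet
    mlp_expert: MLPModel
    combiner: MLPModel
    target_scaler: RangeScaler
    cluster_id: int | None = None
    diagnostics: dict = field(default_factory=dict)
    encoder: CaseEncoder | None = None  # reattached by the engine, not serialized

    def to_dict(self) -> dict:
        return {
            "bn_expert": self.bn_expert.to_dict(),
            "mlp_expert": self.mlp_expert.to_dict(),
            "combiner": self.combiner.to_dict(),
            "target_scaler": self.target_scaler.to_dict(),
            "cluster_id": self.cluster_id,
            "diagnostics": self.diagnostics,
        }

    @classmethod
    def from_dict(cls, d: dict, encoder: CaseEncoder | None = None) -> "MixtureModel":
        return cls(
            bn_expert=BayesNet.from_dict(d["bn_expert"]),
            mlp_expert=MLPModel.from_dict(d["mlp_expert"]),
            combiner=MLPModel.from_dict(d["combiner"]),
            target_scaler=RangeScaler.from_dict(d["target_scaler"]),
            cluster_id=d.get("cluster_id"),
            diagnostics=dict(d.get("diagnostics", {})),
            encoder=encoder,
        )


# ---------------------------------------------------------------------------
# Bayesian-network expert
# ---------------------------------------------------------------------------

def _bn_expert_data(cases, encoder: CaseEncoder) -> DiscreteData:
    frame = encoder.encode_frame(cases, target="bn")
    dd = DiscreteData.from_frame(frame)
    types, bins = encoder.bn_solution_columns(cases)
    return dd.with_columns(
        [
            ("restoration_type", types, 2),
            ("longevity_bin", bins, len(encoder.LONGEVITY_BIN_EDGES)),
        ]
    )


def _bn_evidence(case: Case, restoration_type: str, encoder: CaseEncoder) -> dict[str, int]:
    frame = encoder.encode_frame([case], target="bn")
    ev = {name: int(frame.cat[0, j]) for j, name in enumerate(frame.cat_names)}
    ev["restoration_type"] = RESTORATION_TYPES.index(restoration_type)
    return ev


def _bn_expert_predict(bn: BayesNet, case: Case, restoration_type: str, encoder: CaseEncoder) -> float:
    ev = _bn_evidence(case, restoration_type, encoder)
    ev = {k: v for k, v in ev.items() if k in bn.levels}
    return bn_expected_longevity(bn, ev, encoder.LONGEVITY_BIN_EDGES, target="longevity_bin")


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _train_combiner(
    expert_preds: np.ndarray,
    targets_years: np.ndarray,
    scaler: RangeScaler,
    config: MixtureConfig,
    seed: int,
) -> MLPModel:
    """Fit the 2-input combiner on expert predictions, all in working range."""
    X = scaler.transform(expert_preds.reshape(-1, 1)).reshape(expert_preds.shape)
    D = scaler.transform(targets_years.reshape(-1, 1))
    combiner = mlp_init(2, 1, seed=seed)  # 2*2 + 1 = 5 hidden neurons
    mlp_train(
        combiner,
        X,
        D,
        eta=config.eta,
        mu=config.mu,
        epochs=config.combiner_epochs,
        seed=seed,
        early_stop=(0.2, config.patience),
    )
    return combiner


def train_mixture(
    cases, encoder: CaseEncoder, config: MixtureConfig | None = None, seed: int = 0
) -> MixtureModel:
    """Train both experts and the stacking combiner on one cluster's cases."""
    config = config or MixtureConfig()
    cases = list(cases)
    if len(cases) < config.min_cases:
        raise TrainingSizeError(
            f"{len(cases)} cases is below the training floor of {config.min_cases}"
        )
    ss = np.random.SeedSequence(seed)
    seeds = [int(np.random.default_rng(c).integers(0, 2**31 - 1)) for c in ss.spawn(8)]
    rng = np.random.default_rng(seeds[0])

    # held-out validation split for the diagnostics
    perm = rng.permutation(len(cases))
    n_val = max(1, int(round(config.validation_fraction * len(cases))))
    val_cases = [cases[i] for i in perm[:n_val]]
    train_cases = [cases[i] for i in perm[n_val:]]

    longevities = np.array([c.restoration_longevity for c in train_cases])
    types = [c.restoration_type for c in train_cases]
    scaler = RangeScaler.fit(longevities.reshape(-1, 1))

    # one structure for the BN expert, learned on the training split; folds
    # refit only the conditional tables
    bn_data_full = _bn_expert_data(train_cases, encoder)
    bn_struct = learn_structure(bn_data_full, alpha=config.bn_alpha, max_cond=config.bn_max_cond)

    X_mlp = encoder.encode_mlp_with_type(train_cases, types)
    D_mlp = scaler.transform(longevities.reshape(-1, 1))

    # out-of-fold expert predictions for the combiner (stacking)
    n = len(train_cases)
    fold_of = np.arange(n) % config.oof_folds
    fold_of = np.random.default_rng(seeds[1]).permutation(fold_of)
    oof = np.zeros((n, 2))
    for f in range(config.oof_folds):
        tr = np.where(fold_of != f)[0]
        te = np.where(fold_of == f)[0]
        if len(tr) == 0 or len(te) == 0:
            continue
        bn_f = BayesNet(bn_struct.names, dict(bn_struct.levels), bn_struct.dag.copy())
        fit_cpts(bn_f, _bn_expert_data([train_cases[i] for i in tr], encoder), config.bn_laplace)
        for i in te:
            oof[i, 0] = _bn_expert_predict(bn_f, train_cases[i], types[i], encoder)
        mlp_f = mlp_init(X_mlp.shape[1], 1, seed=seeds[2] + f)
        mlp_train(
            mlp_f, X_mlp[tr], D_mlp[tr],
            eta=config.eta, mu=config.mu, epochs=config.epochs,
            seed=seeds[3] + f, early_stop=(0.2, config.patience),
        )
        pred_scaled = mlp_forward(mlp_f, X_mlp[te])
        oof[te, 1] = scaler.inverse(pred_scaled)[:, 0]

    # final experts on the full training split
    bn_expert = BayesNet(bn_struct.names, dict(bn_struct.levels), bn_struct.dag.copy())
    fit_cpts(bn_expert, bn_data_full, config.bn_laplace)
    mlp_expert = mlp_init(X_mlp.shape[1], 1, seed=seeds[4])
    mlp_train(
        mlp_expert, X_mlp, D_mlp,
        eta=config.eta, mu=config.mu, epochs=config.epochs,
        seed=seeds[5], early_stop=(0.2, config.patience),
    )

    combiner = _train_combiner(oof, longevities, scaler, config, seeds[6])

    model = MixtureModel(
        bn_expert=bn_expert,
        mlp_expert=mlp_expert,
        combiner=combiner,
        target_scaler=scaler,
        encoder=encoder,
    )

    # validation diagnostics in years
    if val_cases:
        truth = np.array([c.restoration_longevity for c in val_cases])
        bn_pred = np.array(
            [_bn_expert_predict(bn_expert, c, c.restoration_type, encoder) for c in val_cases]
        )
        Xv = encoder.encode_mlp_with_type(val_cases, [c.restoration_type for c in val_cases])
        mlp_pred = scaler.inverse(mlp_forward(mlp_expert, Xv))[:, 0]
        mix_pred = np.array([mixture_predict(model, c) for c in val_cases])
        model.diagnostics = {
            "n_train": len(train_cases),
            "n_val": len(val_cases),
            "bn_val_mse": float(np.mean((bn_pred - truth) ** 2)),
            "mlp_val_mse": float(np.mean((mlp_pred - truth) ** 2)),
            "mixture_val_mse": float(np.mean((mix_pred - truth) ** 2)),
        }
    return model


def expert_predictions(model: MixtureModel, case: Case, restoration_type: str | None = None) -> tuple[float, float]:
    """(Bayesian-network, MLP) longevity predictions in years."""
    if model.encoder is None:
        raise RuntimeError("mixture model has no encoder attached")
    rtype = restoration_type or case.restoration_type
    bn_pred = _bn_expert_predict(model.bn_expert, case, rtype, model.encoder)
    x = model.encoder.encode_mlp_with_type([case], [rtype])
    mlp_pred = float(model.target_scaler.inverse(mlp_forward(model.mlp_expert, x))[0, 0])
    return bn_pred, mlp_pred


def mixture_predict(model: MixtureModel, case: Case, restoration_type: str | None = None) -> float:
    """Final combined longevity estimate in years (clamped at zero)."""
    if model.combiner is None:
        raise RuntimeError("mixture model is untrained")
    preds = np.array(expert_predictions(model, case, restoration_type))
    x = model.target_scaler.transform(preds.reshape(-1, 1)).reshape(1, 2)
    y_scaled = mlp_forward(model.combiner, x)
    years = float(model.target_scaler.inverse(y_scaled)[0, 0])
    return max(years, 0.0)
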