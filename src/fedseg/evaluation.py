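"""Dice evaluation and the method-comparison harness.

Provides the binary Dice score, per-client evaluation of trained models, the
two reference baselines (FedAvg = the federated loop with the contrastive
weight zeroed and nothing personalized; local-only = isolated per-client
training on a matched gradient-step budget), and hyperparameter sweeps.
Client averages are unweighted arithmetic means.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from ._utils import derive_seed
from .federation import FederationConfig, FederationResult, run_federation
from .losses import LossConfig, supervised_loss_graph
from .nn import Adam, no_grad as nn_no_grad
from .seg_model import NetworkConfig, UNet, build_model
from .synthetic_data import SplitDataset, Sample

__all__ = [
    "EvalReport",
    "dice_score",
    "evaluate_client",
    "evaluate_federated",
    "run_baseline",
    "train_local_only",
    "sweep",
    "run_comparison",
    "desk_benchmark",
]


@dataclass(frozen=True)
class EvalReport:
    """Per-client and average Dice for one method at one round."""

    per_client_dice: dict[int, float]
    average_dice: float
    method_label: str
    round: int

    def to_frame(self, **extra) -> pd.DataFrame:
        rows = [
            {"method": self.method_label, "round": self.round, "client": k,
             "dice": v, **extra}
            for k, v in sorted(self.per_client_dice.items())
        ]
        return pd.DataFrame(rows)


def dice_score(pred_mask: np.ndarray, target_mask: np.ndarray) -> float:
    """Binary Dice overlap 2|A∩B| / (|A|+|B|); two empty masks score 1."""
    pred = np.asarray(pred_mask)
    target = np.asarray(target_mask)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    for arr, label in ((pred, "pred"), (target, "target")):
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"{label} mask must be binary (0/1)")
    total = pred.sum() + target.sum()
    if total == 0:
        return 1.0
    return float(2.0 * np.logical_and(pred, target).sum() / total)


def evaluate_client(model: UNet, samples: list[Sample], threshold: float = 0.5,
                    batch_size: int = 32) -> float:
    """Mean per-sample Dice of thresholded sigmoid predictions (eval mode)."""
    if not samples:
        raise ValueError("empty evaluation split")
    scores = []
    for start in range(0, len(samples), batch_size):
        chunk = samples[start:start + batch_size]
        x = np.stack([np.asarray(s.image, dtype=np.float32) for s in chunk])[:, None]
        with nn_no_grad():
            logits, _ = model.forward(x, train=False)
        pred = (expit(logits.data[:, 0]) >= threshold).astype(np.uint8)
        for p, s in zip(pred, chunk):
            scores.append(dice_score(p, (np.asarray(s.mask) > 0).astype(np.uint8)))
    return float(np.mean(scores))


def evaluate_federated(result: FederationResult, split: str = "test",
                       method_label: str = "contrastive_pfl",
                       threshold: float = 0.5) -> EvalReport:
    """Evaluate each client's final personalized model on its own split."""
    per_client = {
        c.id: evaluate_client(c.model, getattr(c.data, split), threshold=threshold)
        for c in result.clients
    }
    return EvalReport(
        per_client_dice=per_client,
        average_dice=float(np.mean(list(per_client.values()))),
        method_label=method_label,
        round=result.server.round,
    )


def train_local_only(cfg: FederationConfig, datasets: list[SplitDataset],
                     network: NetworkConfig) -> tuple[list[UNet], list[int]]:
    """Isolated per-client training, matched to the federated step budget.

    Each client trains for rounds * local_epochs epochs with the same
    initialization, optimizer, batch-order streams and supervised loss as the
    federated runs, but with no communication and no contrastive term.
    Returns the trained models and the per-client gradient-step counts.
    """
    models = []
    step_counts = []
    for k, data in enumerate(datasets):
        model = build_model(network, seed=derive_seed(cfg.seed, "init"))
        opt = Adam(model.trainable_params(), lr=cfg.learning_rate, betas=cfg.adam_betas)
        n = len(data.train)
        bs = min(cfg.batch_size, n)
        steps = 0
        for t in range(cfg.rounds):
            order_rng = np.random.default_rng(derive_seed(cfg.seed, "batch", t, k))
            aug_rng = np.random.default_rng(derive_seed(cfg.seed, "augment", t, k))
            for _ in range(cfg.local_epochs):
                perm = order_rng.permutation(n)
                for start in range(0, n, bs):
                    idx = perm[start:start + bs]
                    from .federation import _batch_arrays

                    x, y = _batch_arrays(data.train, idx, cfg.augment, aug_rng)
                    logits, _ = model.forward(x, train=True)
                    sup, _, _ = supervised_loss_graph(logits, y, cfg.loss)
                    opt.zero_grad()
                    sup.backward()
                    opt.step()
                    steps += 1
        models.append(model)
        step_counts.append(steps)
    return models, step_counts


def run_baseline(kind: str, cfg: FederationConfig, datasets: list[SplitDataset],
                 network: NetworkConfig, split: str = "test") -> EvalReport:
    """Reference baselines sharing seeds/data with the personalized run.

    ``fedavg``: the federated loop with alpha = 0 and an empty personalized
    partition (pure weighted averaging of everything).
    ``local_only``: per-client training without communication.
    """
    if kind == "fedavg":
        fed_cfg = replace(cfg, partition_patterns=(),
                          loss=replace(cfg.loss, alpha=0.0))
        result = run_federation(fed_cfg, datasets, network, eval_val=False)
        return evaluate_federated(result, split=split, method_label="fedavg")
    if kind == "local_only":
        models, _ = train_local_only(cfg, datasets, network)
        per_client = {
            k: evaluate_client(m, getattr(d, split))
            for k, (m, d) in enumerate(zip(models, datasets))
        }
        return EvalReport(
            per_client_dice=per_client,
            average_dice=float(np.mean(list(per_client.values()))),
            method_label="local_only",
            round=cfg.rounds,
        )
    raise ValueError(f"unknown baseline {kind!r}")


def sweep(parameter: str, values, cfg: FederationConfig,
          datasets: list[SplitDataset], network: NetworkConfig,
          split: str = "test") -> pd.DataFrame:
    """One full federated run per value of alpha / tau / local_epochs."""
    if parameter not in ("alpha", "tau", "local_epochs"):
        raise ValueError(f"unknown sweep parameter {parameter!r}")
    values = list(values)
    if not values:
        raise ValueError("values must be nonempty")
    frames = []
    for value in values:
        if parameter == "local_epochs":
            run_cfg = replace(cfg, local_epochs=int(value))
        else:
            run_cfg = replace(cfg, loss=replace(cfg.loss, **{parameter: float(value)}))
        result = run_federation(run_cfg, datasets, network, eval_val=False)
        report = evaluate_federated(result, split=split)
        frames.append(report.to_frame(**{parameter: value}))
    return pd.concat(frames, ignore_index=True)


def desk_benchmark(seeds=(1, 2, 3), rounds: int = 20, local_epochs: int = 1,
                   image_size: tuple[int, int] = (64, 64),
                   progress: bool = False) -> pd.DataFrame:
    """Desk-scale comparison on the four-site toy fixture.

    For each replicate seed, regenerates the toy4 sites (quantity-skewed
    counts 60/50/30/20 with site-specific intensity profiles), then trains the
    personalized contrastive method, FedAvg, and local-only baselines under
    shared initialization and data-order streams. The training recipe scales
    the reference one down to 20 rounds with a correspondingly larger Adam
    step (1e-3); see the methods note for the rationale.
    """
    from .synthetic_data import AugmentConfig, build_fixture, make_site_dataset

    network = NetworkConfig(in_channels=1, base_channels=8, depth=2,
                            norm_kind="instance")
    frames = []
    iterator = seeds
    if progress:
        from tqdm import tqdm

        iterator = tqdm(list(seeds), desc="replicates")
    for seed in iterator:
        profiles = build_fixture("toy4", base_seed=derive_seed(seed, "data"),
                                 image_size=image_size)
        datasets = [make_site_dataset(p) for p in profiles]
        cfg = FederationConfig(
            rounds=rounds, local_epochs=local_epochs, batch_size=32,
            learning_rate=1e-3, partition_patterns=("norm",),
            loss=LossConfig(mu=1.0, alpha=1.0, tau=0.5), seed=seed,
            augment=AugmentConfig(rotate_deg=10.0, flip_prob=0.5),
        )
        frame = run_comparison(cfg, datasets, network)
        frame["n_k"] = frame["client"].map(
            {k: len(d.train) for k, d in enumerate(datasets)}
        )
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def run_comparison(cfg: FederationConfig, datasets: list[SplitDataset],
                   network: NetworkConfig,
                   methods: tuple[str, ...] = ("contrastive_pfl", "fedavg", "local_only"),
                   split: str = "test") -> pd.DataFrame:
    """Run the personalized method and baselines on shared data/seeds."""
    frames = []
    for method in methods:
        if method == "contrastive_pfl":
            result = run_federation(cfg, datasets, network, eval_val=False)
            report = evaluate_federated(result, split=split)
        else:
            report = run_baseline(method, cfg, datasets, network, split=split)
        frames.append(report.to_frame(seed=cfg.seed))
    return pd.concat(frames, ignore_index=True)
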