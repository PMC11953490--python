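"""Federated orchestration: broadcast, local update, weighted aggregation.

One communication round:

1. the server broadcasts the shared parameter subset to every client;
2. each client runs E local epochs of Adam on the combined objective
   L = L_sup + alpha * L_con, where the contrastive term compares the live
   model's site embedding against frozen snapshots of (a) the received global
   model (positive) and (b) the client's previous-round model (negative);
3. the server replaces the shared parameters with the sample-count-weighted
   average sum_k (n_k / N) * omega_k of the client models.

Personalized parameters (by default all normalization layers) never leave the
client. At round 0 the previous-round snapshot is initialized to the initial
global model, so the contrastive term is the constant beta*ln 2 with zero
gradient and training starts purely supervised.

All randomness (batch order, augmentation) is drawn from streams keyed by
(seed, purpose, round, client), so results are independent of client
processing order and runs are exactly reproducible.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._utils import derive_seed
from .embedding import site_embedding, site_embedding_graph
from .losses import (
    LossConfig,
    beta_weight,
    contrastive_loss_graph,
    supervised_loss_graph,
)
from .nn import Adam, no_grad
from .seg_model import (
    NetworkConfig,
    ParameterPartition,
    ParameterSet,
    UNet,
    build_model,
    partition_parameters,
)
from .synthetic_data import AugmentConfig, Sample, SplitDataset, augment

__all__ = [
    "FederationConfig",
    "ClientState",
    "ServerState",
    "FederationResult",
    "broadcast_shared",
    "client_update",
    "aggregate",
    "run_round",
    "run_federation",
    "write_roundlog_jsonl",
    "write_summary_csv",
    "save_run_state",
    "load_run_state",
]

DEFAULT_PARTITION_PATTERNS = ["norm"]


@dataclass(frozen=True)
class FederationConfig:
    """Federation hyperparameters (defaults follow the reference training
    recipe: Adam(0.9, 0.999), lr 1e-4, batch 32, 200 rounds)."""

    rounds: int = 200
    local_epochs: int = 1
    batch_size: int = 32
    learning_rate: float = 1e-4
    adam_betas: tuple[float, float] = (0.9, 0.999)
    partition_patterns: tuple[str, ...] = ("norm",)
    loss: LossConfig = field(default_factory=LossConfig)
    seed: int = 0
    augment: AugmentConfig | None = None
    embedding_fusion: str = "concat"

    def __post_init__(self):
        if self.rounds < 0:
            raise ValueError("rounds must be >= 0")
        if self.local_epochs < 1:
            raise ValueError("local_epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")


@dataclass
class ClientState:
    """One site's model, data, previous-round cache and optimizer."""

    id: int
    n_k: int
    model: UNet
    prev_params: ParameterSet
    optimizer: Adam
    data: SplitDataset
    beta: float

    @property
    def params(self) -> ParameterSet:
        return self.model.get_parameters()


@dataclass
class ServerState:
    """Round counter plus the shared-parameter aggregate."""

    round: int
    global_params: ParameterSet
    N: int


@dataclass
class FederationResult:
    server: ServerState
    clients: list[ClientState]
    log: list[dict]


def _restrict(params: ParameterSet, names) -> ParameterSet:
    return ParameterSet({n: params[n].copy() for n in sorted(names)})


def broadcast_shared(server: ServerState, client: ClientState,
                     partition: ParameterPartition) -> ClientState:
    """Overwrite the client's shared parameters with the server's."""
    client.model.set_parameters(
        {n: server.global_params[n] for n in sorted(partition.shared_names)}
    )
    return client


def _batch_arrays(samples: list[Sample], idx: np.ndarray,
                  aug_cfg: AugmentConfig | None,
                  aug_rng: np.random.Generator | None) -> tuple[np.ndarray, np.ndarray]:
    chosen = [samples[i] for i in idx]
    if aug_cfg is not None:
        chosen = [augment(s, aug_rng, aug_cfg) for s in chosen]
    x = np.stack([np.asarray(s.image, dtype=np.float32) for s in chosen])[:, None]
    y = np.stack([np.asarray(s.mask, dtype=np.float32) for s in chosen])[:, None]
    return x, y


def client_update(client: ClientState, global_params: ParameterSet,
                  partition: ParameterPartition, cfg: FederationConfig,
                  round_index: int) -> list[dict]:
    """Run E local epochs on the client; returns per-step loss records.

    The positive snapshot merges the received global shared parameters over
    the client's own personalized parameters; the negative snapshot is the
    previous-round local model. Both are frozen (no gradients, evaluation
    mode) for the whole round. ``prev_params`` is refreshed afterwards.
    """
    train = client.data.train
    if not train:
        raise ValueError(f"client {client.id} has an empty training split")
    alpha = cfg.loss.alpha
    model = client.model
    snap_g = snap_b = None
    if alpha > 0:
        merged = {n: client.model.params[n].data.copy() for n in client.model.params}
        for n in partition.shared_names:
            merged[n] = np.asarray(global_params[n]).copy()
        snap_g = UNet(model.config, seed=0)
        snap_g.set_parameters(merged)
        snap_b = UNet(model.config, seed=0)
        snap_b.set_parameters(client.prev_params)

    order_rng = np.random.default_rng(
        derive_seed(cfg.seed, "batch", round_index, client.id)
    )
    aug_rng = np.random.default_rng(
        derive_seed(cfg.seed, "augment", round_index, client.id)
    )
    n = len(train)
    bs = min(cfg.batch_size, n)
    records: list[dict] = []
    for epoch in range(cfg.local_epochs):
        perm = order_rng.permutation(n)
        for start in range(0, n, bs):
            idx = perm[start:start + bs]
            x, y = _batch_arrays(train, idx, cfg.augment, aug_rng)
            logits, rep = model.forward(x, train=True)
            sup, dice, bce = supervised_loss_graph(logits, y, cfg.loss)
            if alpha > 0:
                with no_grad():
                    _, rep_g = snap_g.forward(x, train=False, bridge_only=True)
                    _, rep_b = snap_b.forward(x, train=False, bridge_only=True)
                xi = site_embedding_graph(rep, fusion=cfg.embedding_fusion)
                xi_g = site_embedding(rep_g.data, fusion=cfg.embedding_fusion)
                xi_b = site_embedding(rep_b.data, fusion=cfg.embedding_fusion)
                con = contrastive_loss_graph(xi, xi_g, xi_b, cfg.loss.tau, client.beta)
                total = sup + alpha * con
                con_value = float(con.data)
            else:
                total = sup
                con_value = 0.0
            client.optimizer.zero_grad()
            total.backward()
            client.optimizer.step()
            records.append({
                "epoch": epoch,
                "loss_sup": float(sup.data),
                "loss_dice": float(dice.data),
                "loss_bce": float(bce.data),
                "loss_con": con_value,
                "loss_total": float(total.data),
            })
    client.prev_params = client.model.get_parameters()
    return records


def aggregate(clients: list[ClientState], partition: ParameterPartition,
              N: int) -> ParameterSet:
    """Sample-count-weighted average of the shared parameters only."""
    if N <= 0:
        raise ValueError("N must be positive")
    out = {}
    for name in sorted(partition.shared_names):
        acc = None
        for c in sorted(clients, key=lambda c: c.id):
            arr = c.model.params[name].data
            term = (c.n_k / N) * arr
            acc = term if acc is None else acc + term
        out[name] = acc.astype(clients[0].model.params[name].data.dtype)
    return ParameterSet(out)


def _mean(records: list[dict], key: str) -> float:
    return float(np.mean([r[key] for r in records])) if records else float("nan")


def run_round(server: ServerState, clients: list[ClientState],
              partition: ParameterPartition, cfg: FederationConfig,
              eval_val: bool = True) -> list[dict]:
    """One communication round with full participation; returns log records."""
    from .evaluation import evaluate_client  # local import to avoid a cycle

    t = server.round
    received = server.global_params
    log: list[dict] = []
    for client in sorted(clients, key=lambda c: c.id):
        broadcast_shared(server, client, partition)
        steps = client_update(client, received, partition, cfg, t)
        entry = {
            "round": t,
            "client": client.id,
            "n_k": client.n_k,
            "loss_sup": _mean(steps, "loss_sup"),
            "loss_con": _mean(steps, "loss_con"),
            "loss_total": _mean(steps, "loss_total"),
            "dice_val": float("nan"),
            "steps": steps,
        }
        if eval_val and client.data.val:
            entry["dice_val"] = evaluate_client(client.model, client.data.val)
        log.append(entry)
    server.global_params = aggregate(clients, partition, server.N)
    server.round = t + 1
    return log


def _init_clients(cfg: FederationConfig, datasets: list[SplitDataset],
                  network: NetworkConfig) -> tuple[ServerState, list[ClientState],
                                                   ParameterPartition]:
    init_model = build_model(network, seed=derive_seed(cfg.seed, "init"))
    init_params = init_model.get_parameters()
    partition = partition_parameters(init_params, cfg.partition_patterns)
    N = sum(len(d.train) for d in datasets)
    clients = []
    for k, data in enumerate(datasets):
        model = build_model(network, seed=derive_seed(cfg.seed, "init"))
        model.set_parameters(init_params)
        clients.append(ClientState(
            id=k,
            n_k=len(data.train),
            model=model,
            prev_params=init_params.copy(),
            optimizer=Adam(model.trainable_params(), lr=cfg.learning_rate,
                           betas=cfg.adam_betas),
            data=data,
            beta=beta_weight(len(data.train), N),
        ))
    server = ServerState(round=0, global_params=_restrict(init_params,
                                                          partition.shared_names), N=N)
    return server, clients, partition


def run_federation(cfg: FederationConfig, datasets: list[SplitDataset],
                   network: NetworkConfig, *,
                   state: tuple[ServerState, list[ClientState]] | None = None,
                   eval_val: bool = True,
                   checkpoint_dir=None, checkpoint_every: int = 0,
                   progress: bool = False) -> FederationResult:
    """Run T communication rounds and return final states plus the full log.

    After the last aggregation the shared aggregate is broadcast once more, so
    each client's final personalized model combines the final global shared
    parameters with its own personalized ones.
    """
    if state is None:
        server, clients, partition = _init_clients(cfg, datasets, network)
    else:
        server, clients = state
        partition = partition_parameters(clients[0].model.get_parameters(),
                                         cfg.partition_patterns)
    log: list[dict] = []
    rounds = range(server.round, cfg.rounds)
    if progress:
        from tqdm import tqdm

        rounds = tqdm(rounds, desc="rounds")
    for t in rounds:
        log.extend(run_round(server, clients, partition, cfg, eval_val=eval_val))
        if checkpoint_dir and checkpoint_every and (t + 1) % checkpoint_every == 0:
            save_run_state(checkpoint_dir, server, clients, cfg)
    for client in sorted(clients, key=lambda c: c.id):
        broadcast_shared(server, client, partition)
    return FederationResult(server=server, clients=clients, log=log)


# -- log output -------------------------------------------------------------------


def write_roundlog_jsonl(log: list[dict], path) -> None:
    """One JSON record per (round, client); key order fixed for determinism."""
    keys = ("round", "client", "n_k", "loss_sup", "loss_con", "loss_total", "dice_val")
    with open(path, "w") as fh:
        for entry in log:
            fh.write(json.dumps({k: entry[k] for k in keys}, sort_keys=True))
            fh.write("\n")


def write_summary_csv(log: list[dict], path) -> None:
    """Per-round summary: mean validation Dice plus per-client columns."""
    rounds = sorted({e["round"] for e in log})
    client_ids = sorted({e["client"] for e in log})
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["round", "mean_dice"] + [f"dice_client_{k}" for k in client_ids])
        for t in rounds:
            row = {e["client"]: e["dice_val"] for e in log if e["round"] == t}
            dices = [row.get(k, float("nan")) for k in client_ids]
            writer.writerow([t, float(np.mean(dices))] + dices)


# -- run-state checkpointing (resume support) ---------------------------------------


def save_run_state(directory, server: ServerState, clients: list[ClientState],
                   cfg: FederationConfig) -> None:
    """Persist server round/aggregate and per-client model+optimizer state."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {"round": server.round, "N": server.N, "K": len(clients),
            "config": {**asdict(cfg), "loss": asdict(cfg.loss),
                       "augment": asdict(cfg.augment) if cfg.augment else None}}
    (directory / "state.json").write_text(json.dumps(meta, sort_keys=True, default=list))
    np.savez(directory / f"round_{server.round:04d}_global.npz",
             **{f"g/{k}": v for k, v in server.global_params.items()})
    for c in clients:
        arrays = {f"p/{k}": t.data for k, t in c.model.params.items()}
        arrays.update({f"prev/{k}": v for k, v in c.prev_params.items()})
        arrays.update({f"m/{k}": v for k, v in c.optimizer.m.items()})
        arrays.update({f"v/{k}": v for k, v in c.optimizer.v.items()})
        arrays["adam_t"] = np.array(c.optimizer.t)
        np.savez(directory / f"round_{server.round:04d}_client_{c.id}.npz", **arrays)


def load_run_state(directory, cfg: FederationConfig, datasets: list[SplitDataset],
                   network: NetworkConfig) -> tuple[ServerState, list[ClientState]]:
    """Rebuild (server, clients) from a saved run state for resumption."""
    directory = Path(directory)
    meta = json.loads((directory / "state.json").read_text())
    t, N = meta["round"], meta["N"]
    server_npz = np.load(directory / f"round_{t:04d}_global.npz")
    global_params = ParameterSet(
        {k[2:]: server_npz[k] for k in server_npz.files}
    )
    clients = []
    for k, data in enumerate(datasets):
        model = build_model(network, seed=derive_seed(cfg.seed, "init"))
        with np.load(directory / f"round_{t:04d}_client_{k}.npz") as archive:
            model.set_parameters(
                {key[2:]: archive[key] for key in archive.files if key.startswith("p/")}
            )
            prev = ParameterSet({key[5:]: archive[key] for key in archive.files
                                 if key.startswith("prev/")})
            opt = Adam(model.trainable_params(), lr=cfg.learning_rate,
                       betas=cfg.adam_betas)
            opt.t = int(archive["adam_t"])
            for key in archive.files:
                if key.startswith("m/"):
                    opt.m[key[2:]][...] = archive[key]
                elif key.startswith("v/"):
                    opt.v[key[2:]][...] = archive[key]
        clients.append(ClientState(
            id=k, n_k=len(data.train), model=model, prev_params=prev,
            optimizer=opt, data=data, beta=beta_weight(len(data.train), N),
        ))
    return ServerState(round=t, global_params=global_params, N=N), clients
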