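"""Federation mechanics: broadcast, aggregation algebra, local updates,
round orchestration, the FedAvg reduction, and resumable run state."""

import numpy as np
import pytest

from fedseg import NetworkConfig, build_model, partition_parameters
from fedseg.federation import (
    ClientState,
    FederationConfig,
    ServerState,
    aggregate,
    broadcast_shared,
    client_update,
    load_run_state,
    run_federation,
    run_round,
    save_run_state,
    write_roundlog_jsonl,
)
from fedseg.losses import LossConfig, beta_weight
from fedseg.nn import Adam
from fedseg.seg_model import ParameterSet
from fedseg.synthetic_data import SplitDataset

from conftest import make_tiny_sites

NET = NetworkConfig(in_channels=1, base_channels=2, depth=1, norm_kind="instance")


def make_client(k, data, net=NET, seed=0, lr=1e-3, n_k=None, N=None):
    model = build_model(net, seed=seed)
    n = n_k if n_k is not None else len(data.train)
    return ClientState(
        id=k, n_k=n, model=model, prev_params=model.get_parameters(),
        optimizer=Adam(model.trainable_params(), lr=lr), data=data,
        beta=beta_weight(n, N or n),
    )


def small_cfg(**kw):
    defaults = dict(rounds=2, local_epochs=1, batch_size=8, learning_rate=1e-3,
                    partition_patterns=("norm",), loss=LossConfig(tau=0.5),
                    seed=3)
    defaults.update(kw)
    return FederationConfig(**defaults)


class TestBroadcast:
    def _setup(self, patterns):
        data = make_tiny_sites((6,))[0]
        client = make_client(0, data, seed=1)
        global_model = build_model(NET, seed=2)
        partition = partition_parameters(global_model.get_parameters(), patterns)
        server = ServerState(
            round=0,
            global_params=ParameterSet({
                n: global_model.get_parameters()[n]
                for n in partition.shared_names
            }),
            N=6,
        )
        return server, client, partition, global_model.get_parameters()

    def test_empty_personalized_set_copies_everything(self):
        server, client, partition, global_params = self._setup([])
        broadcast_shared(server, client, partition)
        assert client.params.equals(global_params)

    def test_all_personalized_is_a_no_op(self):
        server, client, partition, _ = self._setup(["*"])
        before = client.params
        broadcast_shared(server, client, partition)
        assert client.params.equals(before)

    def test_mixed_partition_changes_exactly_the_shared_names(self):
        server, client, partition, _ = self._setup(["norm"])
        before = client.params
        broadcast_shared(server, client, partition)
        after = client.params
        changed = {n for n in after if not np.array_equal(before[n], after[n])}
        # every changed name is shared; untouched shared names were already equal
        assert changed <= partition.shared_names
        for n in partition.shared_names:
            np.testing.assert_array_equal(after[n], server.global_params[n])
        for n in partition.personalized_names:
            np.testing.assert_array_equal(after[n], before[n])


class TestAggregate:
    def _clients(self, values, counts):
        data = make_tiny_sites((6, 6))[:len(values)]
        clients = []
        for k, (v, n) in enumerate(zip(values, counts)):
            c = make_client(k, data[k % len(data)], n_k=n, N=sum(counts))
            c.model.set_parameters({
                "head.bias": np.full_like(c.model.params["head.bias"].data, v)
            })
            clients.append(c)
        return clients

    def test_identical_clients_are_a_fixed_point(self):
        clients = self._clients([1.5, 1.5], [3, 9])
        partition = partition_parameters(clients[0].params, [])
        agg = aggregate(clients, partition, N=12)
        assert agg.equals(clients[0].params)

    def test_equal_weights_give_arithmetic_mean(self):
        clients = self._clients([0.0, 4.0], [5, 5])
        partition = partition_parameters(clients[0].params, [])
        agg = aggregate(clients, partition, N=10)
        np.testing.assert_allclose(agg["head.bias"], 2.0)

    def test_proportional_weights_one_to_three(self):
        clients = self._clients([0.0, 4.0], [1, 3])
        partition = partition_parameters(clients[0].params, [])
        agg = aggregate(clients, partition, N=4)
        np.testing.assert_allclose(agg["head.bias"], 3.0, rtol=1e-6)

    def test_convex_combination_bounds_and_personalized_untouched(self, rng):
        clients = self._clients([0.0, 1.0, 2.0], [2, 3, 7])
        for c in clients:  # give every client distinct random weights
            c.model.set_parameters({
                "enc0.conv1.weight": rng.normal(
                    0, 1, c.model.params["enc0.conv1.weight"].shape
                ).astype(np.float32)
            })
        partition = partition_parameters(clients[0].params, ["norm"])
        personalized_before = [
            {n: c.model.params[n].data.tobytes()
             for n in partition.personalized_names}
            for c in clients
        ]
        agg = aggregate(clients, partition, N=12)
        assert set(agg.names) == partition.shared_names
        for name in agg:
            stacked = np.stack([c.model.params[name].data for c in clients])
            assert np.all(agg[name] >= stacked.min(axis=0) - 1e-6)
            assert np.all(agg[name] <= stacked.max(axis=0) + 1e-6)
        for c, before in zip(clients, personalized_before):
            for n, blob in before.items():
                assert c.model.params[n].data.tobytes() == blob

    def test_zero_total_raises(self):
        clients = self._clients([0.0], [1])
        partition = partition_parameters(clients[0].params, [])
        with pytest.raises(ValueError):
            aggregate(clients, partition, N=0)


class TestClientUpdate:
    def test_zero_learning_rate_leaves_parameters_unchanged(self):
        data = make_tiny_sites((6,))[0]
        client = make_client(0, data, lr=0.0)
        cfg = small_cfg(learning_rate=0.0, local_epochs=2)
        partition = partition_parameters(client.params, ["norm"])
        before = client.params
        client_update(client, before, partition, cfg, round_index=0)
        assert client.params.equals(before)

    def test_alpha_zero_total_equals_supervised(self):
        data = make_tiny_sites((6,))[0]
        client = make_client(0, data)
        cfg = small_cfg(loss=LossConfig(alpha=0.0))
        partition = partition_parameters(client.params, ["norm"])
        steps = client_update(client, client.params, partition, cfg, 0)
        for s in steps:
            assert s["loss_total"] == pytest.approx(s["loss_sup"])
            assert s["loss_con"] == 0.0

    def test_one_step_moves_against_finite_difference_gradient(self):
        """A single Adam step decreases each parameter with a clearly positive
        finite-difference gradient and vice versa (Adam's first step is
        -lr * sign(g))."""
        from fedseg.losses import supervised_loss_graph

        data = make_tiny_sites((4,))[0]
        net = NetworkConfig(in_channels=1, base_channels=1, depth=1,
                            norm_kind="none")
        client = make_client(0, data, net=net, lr=1e-4)
        cfg = small_cfg(loss=LossConfig(alpha=0.0), batch_size=16,
                        learning_rate=1e-4)
        partition = partition_parameters(client.params, [])
        before = client.params

        # finite-difference gradient of the (full-batch) supervised loss
        x = np.stack([s.image for s in data.train])[:, None].astype(np.float32)
        y = np.stack([s.mask for s in data.train])[:, None].astype(np.float32)

        def batch_loss():
            logits, _ = client.model.forward(x, train=True)
            sup, _, _ = supervised_loss_graph(logits, y, cfg.loss)
            return float(sup.data)

        name = "head.bias"
        flat = client.model.params[name].data
        eps = 1e-3
        old = flat[0]
        flat[0] = old + eps
        hi = batch_loss()
        flat[0] = old - eps
        lo = batch_loss()
        flat[0] = old
        fd_grad = (hi - lo) / (2 * eps)

        client_update(client, before, partition, cfg, round_index=0)
        moved = client.params[name][0] - before[name][0]
        assert np.sign(moved) == -np.sign(fd_grad)
        assert abs(moved) == pytest.approx(1e-4, rel=0.2)

    def test_empty_training_split_raises(self):
        data = make_tiny_sites((6,))[0]
        empty = SplitDataset(train=[], val=data.val, test=data.test)
        client = make_client(0, data)
        client.data = empty
        cfg = small_cfg()
        partition = partition_parameters(client.params, [])
        with pytest.raises(ValueError, match="empty training split"):
            client_update(client, client.params, partition, cfg, 0)


class TestRounds:
    def test_single_client_empty_partition_global_equals_trained(self):
        datasets = make_tiny_sites((6,))
        cfg = small_cfg(rounds=1, partition_patterns=())
        result = run_federation(cfg, datasets, NET, eval_val=False)
        client_params = result.clients[0].params
        for name in result.server.global_params:
            np.testing.assert_array_equal(result.server.global_params[name],
                                          client_params[name])

    def test_roundlog_is_deterministic_byte_for_byte(self, tmp_path):
        datasets = make_tiny_sites((6, 5))
        paths = []
        for run in range(2):
            cfg = small_cfg(rounds=2)
            result = run_federation(cfg, datasets, NET)
            path = tmp_path / f"log{run}.jsonl"
            write_roundlog_jsonl(result.log, path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    def test_first_round_contrastive_loss_is_beta_ln2_and_inert(self):
        """At t=0 prev == global == local, so the contrastive term equals
        beta*ln2 on every first batch and its gradient cancels exactly: the
        alpha=1 trajectory is bitwise identical to alpha=0 over round 0."""
        datasets = make_tiny_sites((6, 4))
        runs = {}
        for alpha in (1.0, 0.0):
            cfg = small_cfg(rounds=1, loss=LossConfig(alpha=alpha, tau=0.5))
            result = run_federation(cfg, datasets, NET, eval_val=False)
            runs[alpha] = result
        N = sum(len(d.train) for d in datasets)
        for entry in runs[1.0].log:
            beta = beta_weight(entry["n_k"], N)
            first_batch = entry["steps"][0]
            assert first_batch["loss_con"] == pytest.approx(
                beta * np.log(2), abs=1e-6)
        for c1, c0 in zip(runs[1.0].clients, runs[0.0].clients):
            assert c1.params.equals(c0.params)

    def test_prev_params_cache_matches_end_of_round_params(self):
        datasets = make_tiny_sites((6,))
        cfg = small_cfg(rounds=1, partition_patterns=("*",))
        # all-personalized: the final broadcast cannot alter client params,
        # so prev_params must equal the end-of-round parameters exactly
        result = run_federation(cfg, datasets, NET, eval_val=False)
        client = result.clients[0]
        assert client.prev_params.equals(client.params)

    def test_zero_rounds_returns_inputs_unchanged(self):
        datasets = make_tiny_sites((6,))
        cfg = small_cfg(rounds=0)
        result = run_federation(cfg, datasets, NET)
        init = build_model(NET, seed=result.clients[0].model is None or 0)
        assert result.log == []
        assert result.server.round == 0

    def test_doubling_epochs_and_halving_rounds_matches_step_budget(self):
        datasets = make_tiny_sites((6, 5))
        steps = {}
        for rounds, epochs in ((4, 1), (2, 2)):
            cfg = small_cfg(rounds=rounds, local_epochs=epochs)
            result = run_federation(cfg, datasets, NET, eval_val=False)
            steps[(rounds, epochs)] = sum(len(e["steps"]) for e in result.log)
        assert steps[(4, 1)] == steps[(2, 2)]


class TestFedAvgReduction:
    def test_matches_independent_fedavg_loop(self):
        """alpha=0 + empty partition must reproduce a separately coded
        FedAvg loop (broadcast, E epochs of supervised Adam, n_k/N average)
        parameter-for-parameter over 3 rounds."""
        from fedseg._utils import derive_seed
        from fedseg.federation import _batch_arrays
        from fedseg.losses import supervised_loss_graph

        datasets = make_tiny_sites((7, 5))
        seed = 11
        cfg = small_cfg(rounds=3, partition_patterns=(),
                        loss=LossConfig(alpha=0.0), seed=seed, batch_size=4)

        # ---- independent reference loop ----
        init = build_model(NET, seed=derive_seed(seed, "init"))
        global_params = {k: v.copy() for k, v in init.get_parameters().items()}
        N = sum(len(d.train) for d in datasets)
        ref_models = []
        ref_opts = []
        for k, d in enumerate(datasets):
            m = build_model(NET, seed=derive_seed(seed, "init"))
            ref_models.append(m)
            ref_opts.append(Adam(m.trainable_params(), lr=cfg.learning_rate,
                                 betas=cfg.adam_betas))
        trajectory = []
        for t in range(3):
            for k, (m, opt, d) in enumerate(zip(ref_models, ref_opts, datasets)):
                m.set_parameters(global_params)
                order = np.random.default_rng(derive_seed(seed, "batch", t, k))
                n = len(d.train)
                perm = order.permutation(n)
                for start in range(0, n, 4):
                    idx = perm[start:start + 4]
                    x, y = _batch_arrays(d.train, idx, None, None)
                    logits, _ = m.forward(x, train=True)
                    sup, _, _ = supervised_loss_graph(logits, y, cfg.loss)
                    opt.zero_grad()
                    sup.backward()
                    opt.step()
            global_params = {}
            for name in ref_models[0].parameter_names:
                global_params[name] = sum(
                    (len(d.train) / N) * m.params[name].data
                    for m, d in zip(ref_models, datasets)
                ).astype(np.float32)
            trajectory.append({k: v.copy() for k, v in global_params.items()})

        # ---- package run, captured round by round ----
        from fedseg.federation import _init_clients

        server, clients, partition = _init_clients(cfg, datasets, NET)
        for t in range(3):
            run_round(server, clients, partition, cfg, eval_val=False)
            for name, expected in trajectory[t].items():
                np.testing.assert_allclose(
                    server.global_params[name], expected, atol=1e-6,
                    err_msg=f"round {t}, parameter {name}")


class TestRunState:
    def test_resume_reproduces_uninterrupted_trajectory(self, tmp_path):
        datasets = make_tiny_sites((6, 5))
        cfg = small_cfg(rounds=4)
        full = run_federation(cfg, datasets, NET, eval_val=False)

        cfg_half = small_cfg(rounds=2)
        half = run_federation(cfg_half, datasets, NET, eval_val=False)
        save_run_state(tmp_path, half.server, half.clients, cfg_half)
        state = load_run_state(tmp_path, cfg, datasets, NET)
        resumed = run_federation(cfg, datasets, NET, state=state, eval_val=False)

        for name in full.server.global_params:
            np.testing.assert_array_equal(resumed.server.global_params[name],
                                          full.server.global_params[name])
        for cf, cr in zip(full.clients, resumed.clients):
            assert cf.params.equals(cr.params)
            assert cf.prev_params.equals(cr.prev_params)
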