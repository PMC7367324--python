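"""Training engine, experiment protocols, and the CLI surface."""

import numpy as np
import pytest
from click.testing import CliRunner

from biofusion import cli
from biofusion.harness import (ExperimentConfig, build_dataset, evaluate,
                               grid_search_loss_weights, run_fusion_comparison,
                               run_modality_ablation, run_noise_matrix,
                               run_task_comparison, train)
from biofusion.model import MultimodalNet
from biofusion.noise import NoiseSpec
from dataclasses import replace


TINY = dict(n_subjects=4, triplets_per_subject=30, records_per_subject=1,
            images_per_subject=6, epochs=6, patience=3)


@pytest.fixture(scope="module")
def tiny_cfg():
    return ExperimentConfig(seed=3, **TINY)


@pytest.fixture(scope="module")
def tiny_ds(tiny_cfg):
    return build_dataset(tiny_cfg)


class TestTrain:
    def test_separable_toy_problem_loss_decreases_and_fits(self):
        cfg = ExperimentConfig(n_subjects=2, triplets_per_subject=20,
                               records_per_subject=1, images_per_subject=5,
                               epochs=20, patience=20,
                               noise=NoiseSpec.silent(), seed=5)
        ds = build_dataset(cfg)
        model, log = train(cfg, ds)
        joint = log["l_joint"].to_numpy()
        assert np.all(np.diff(joint[:5]) < 0), "loss must fall over first epochs"
        tr = ds.splits.train
        id_p, _ = model.predict(ds.arrays(tr, cfg.modalities))
        assert np.mean(np.argmax(id_p, axis=1) == ds.id_labels[tr]) == 1.0

    def test_single_task_model_lacks_other_head(self, tiny_cfg, tiny_ds):
        cfg = replace(tiny_cfg, tasks=("id",), epochs=1)
        model, _ = train(cfg, tiny_ds)
        assert model.gender_head is None and model.id_head is not None
        cfg = replace(tiny_cfg, tasks=("gender",), epochs=1)
        model, _ = train(cfg, tiny_ds)
        assert model.id_head is None and model.gender_head is not None

    def test_same_seed_identical_rerun(self, tiny_cfg, tiny_ds):
        cfg = replace(tiny_cfg, epochs=3)
        reports = []
        for _ in range(2):
            model, log = train(cfg, tiny_ds)
            rep = evaluate(model, tiny_ds, config=cfg)
            reports.append((rep.id_accuracy, rep.gender_accuracy,
                            log["l_joint"].iloc[-1]))
        assert reports[0] == pytest.approx(reports[1], abs=1e-6)

    def test_leakage_assertion(self, tiny_cfg, tiny_ds):
        import copy

        bad = copy.copy(tiny_ds)
        bad.splits = copy.copy(tiny_ds.splits)
        bad.splits.val = np.concatenate([tiny_ds.splits.val,
                                         tiny_ds.splits.test[:2]])
        with pytest.raises(AssertionError):
            train(tiny_cfg, bad)


class _StubModel:
    """Minimal model stand-in with controllable predictions."""

    def __init__(self, n_classes, mode, seed=0):
        self.n_classes = n_classes
        self.mode = mode
        self.modalities = ("ecg",)
        self.id_head = object()
        self.gender_head = object()
        self._rng = np.random.default_rng(seed)
        self.truth = None

    def predict(self, batch):
        B = len(next(iter(batch.values())))
        if self.mode == "perfect":
            ids, genders = self.truth
            id_p = np.zeros((B, self.n_classes))
            id_p[np.arange(B), ids] = 1.0
            return id_p, genders.astype(float)
        id_p = np.zeros((B, self.n_classes))
        id_p[np.arange(B), self._rng.integers(0, self.n_classes, B)] = 1.0
        return id_p, self._rng.random(B)


class TestEvaluate:
    def test_perfect_oracle_scores_100(self, tiny_ds):
        stub = _StubModel(tiny_ds.n_classes, "perfect")
        te = tiny_ds.splits.test
        stub.truth = (tiny_ds.id_labels[te], tiny_ds.gender_labels[te])
        rep = evaluate(stub, tiny_ds)
        assert rep.id_accuracy == 100.0 and rep.gender_accuracy == 100.0

    def test_uniform_random_near_chance(self, tiny_ds):
        accs = [evaluate(_StubModel(tiny_ds.n_classes, "random", seed=s),
                         tiny_ds).id_accuracy for s in range(40)]
        n = len(tiny_ds.splits.test)
        chance = 100.0 / tiny_ds.n_classes
        sd = 100.0 * np.sqrt((chance / 100) * (1 - chance / 100) / (40 * n))
        assert abs(np.mean(accs) - chance) < 4 * sd

    def test_silent_noise_equals_no_noise(self, tiny_ds):
        stub = _StubModel(tiny_ds.n_classes, "random", seed=1)
        a = evaluate(stub, tiny_ds, noise=NoiseSpec.silent())
        stub2 = _StubModel(tiny_ds.n_classes, "random", seed=1)
        b = evaluate(stub2, tiny_ds, noise=None)
        assert a.id_accuracy == b.id_accuracy

    def test_empty_test_set_rejected(self, tiny_ds):
        stub = _StubModel(tiny_ds.n_classes, "random")
        with pytest.raises(ValueError):
            evaluate(stub, tiny_ds, indices=np.array([], dtype=int))


class TestProtocols:
    def test_modality_ablation_seven_rows(self, tiny_cfg, tiny_ds):
        df = run_modality_ablation(replace(tiny_cfg, epochs=2, patience=1), tiny_ds)
        assert len(df) == 7
        assert df[["ecg", "face", "fingerprint"]].apply(tuple, axis=1).nunique() == 7
        assert df["id_accuracy"].between(0, 100).all()

    def test_task_comparison_rows_and_param_economy(self, tiny_cfg, tiny_ds):
        df = run_task_comparison(replace(tiny_cfg, epochs=2, patience=1), tiny_ds)
        assert list(df["tasks"]) == ["id", "gender", "id+gender"]
        single_sum = df.loc[df.tasks == "id", "n_params"].iat[0] + \
            df.loc[df.tasks == "gender", "n_params"].iat[0]
        multi = df.loc[df.tasks == "id+gender", "n_params"].iat[0]
        assert multi < single_sum

    def test_noise_matrix_cells(self, tiny_cfg, tiny_ds):
        df = run_noise_matrix(replace(tiny_cfg, epochs=2, patience=1), tiny_ds,
                              subsets=(("ecg",), ("ecg", "face", "fingerprint")))
        assert len(df) == 4  # 2 subsets x {clean, noisy}
        assert set(df["noisy"]) == {False, True}

    def test_fusion_comparison_13_rows(self, tiny_cfg, tiny_ds):
        df = run_fusion_comparison(replace(tiny_cfg, epochs=2, patience=1), tiny_ds)
        assert len(df) == 13  # 1 feature-level + 3 rules x 4 weightings
        assert df["id_accuracy"].between(0, 100).all()
        assert df["gender_accuracy"].between(0, 100).all()
        assert (df["level"] == "score").sum() == 12

    def test_grid_search_prefers_id_when_gender_is_noise(self):
        # shuffle gender labels so the gender task carries no signal; with a
        # tight training budget, down-weighting the (learnable) ID task
        # cannot help the validation metric
        cfg = ExperimentConfig(n_subjects=5, triplets_per_subject=40,
                               records_per_subject=1, images_per_subject=8,
                               epochs=4, patience=4,
                               noise=NoiseSpec.silent(), seed=3)
        ds = build_dataset(cfg)
        rng = np.random.default_rng(0)
        ds.gender_labels = rng.permutation(ds.gender_labels)
        lw = grid_search_loss_weights(cfg, ds, grid=[0.1, 0.5, 0.9])
        assert lw.w1 <= 0.5


class TestModelContract:
    def test_multitask_param_count_less_than_sum_of_singles(self):
        both = MultimodalNet(10, tasks=("id", "gender"), seed=0)
        id_only = MultimodalNet(10, tasks=("id",), seed=0)
        g_only = MultimodalNet(10, tasks=("gender",), seed=0)
        assert both.n_params < id_only.n_params + g_only.n_params

    def test_unimodal_fused_input_blocks_masked(self, tiny_ds):
        model = MultimodalNet(tiny_ds.n_classes, modalities=("ecg",), seed=0)
        idx = tiny_ds.splits.test[:4]
        model.forward(tiny_ds.arrays(idx, ("ecg",)), training=False)
        assert model._present == {"ecg": True, "face": False, "fingerprint": False}

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            MultimodalNet(5, modalities=())
        with pytest.raises(ValueError):
            MultimodalNet(5, tasks=("segmentation",))


class TestConfig:
    def test_yaml_roundtrip(self, tiny_cfg):
        text = tiny_cfg.to_yaml()
        back = ExperimentConfig.from_yaml(text)
        assert back == tiny_cfg
        assert back.config_hash() == tiny_cfg.config_hash()

    def test_empty_modalities_rejected(self):
        with pytest.raises(ValueError):
            ExperimentConfig(modalities=())


class TestCli:
    def test_simulate_and_prepare(self, tmp_path):
        runner = CliRunner()
        cfg = ExperimentConfig(n_subjects=2, records_per_subject=1,
                               images_per_subject=1, seed=2)
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(cfg.to_yaml())
        res = runner.invoke(cli.main, ["simulate", "--config", str(cfg_path),
                                       "--out", str(tmp_path / "cohort")])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "cohort/ecg/metadata.csv").exists()
        assert (tmp_path / "cohort/face/F000_0.png").exists()
        res = runner.invoke(cli.main, ["prepare-data", "--config", str(cfg_path),
                                       "--out", str(tmp_path / "ds")])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "ds/subjects.csv").exists()

    def test_fusion_spec_validation(self):
        runner = CliRunner()
        res = runner.invoke(cli.main, ["fusion-spec", "--rule", "product",
                                       "--weights", "0.5,0.25,0.25"])
        assert res.exit_code == 0
        assert '"product"' in res.output
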