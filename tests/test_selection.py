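"""SFFS semantics, the scr selection score, and MDA importance."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from cogload.selection import (
    make_scr_evaluator,
    mda_importance,
    selection_score,
    sffs_select,
)
from cogload.synthetic import generate_feature_table


class TestSelectionScore:
    def test_anchor_values(self):
        assert selection_score(1.0, 1.0) == pytest.approx(2.0)
        assert selection_score(0.0, 0.7) == 0.0
        assert selection_score(0.3, 0.0) == 0.0
        assert selection_score(0.5, 0.5) == pytest.approx(1.0)

    def test_monotone_and_bounded(self):
        grid = np.linspace(0, 1, 21)
        vals = np.array([[selection_score(s, p) for p in grid] for s in grid])
        assert vals.min() >= 0 and vals.max() <= 2
        assert (np.diff(vals, axis=0) >= -1e-12).all()
        assert (np.diff(vals, axis=1) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            selection_score(1.2, 0.5)


def _cheap_evaluator(xall_cols_y):
    """Deterministic separation score: |standardized mean difference| sum."""

    def evaluate(x, y):
        y = np.asarray(y)
        classes = np.unique(y)
        a, b = x[y == classes[0]], x[y == classes[1]]
        sd = np.sqrt((a.var(axis=0) + b.var(axis=0)) / 2 + 1e-12)
        d = np.abs(a.mean(axis=0) - b.mean(axis=0)) / sd
        # diminishing returns for redundant features
        return float(np.sqrt((d**2).sum()))

    return evaluate


class TestSffs:
    def _planted(self, seed, n=120, pool=23, k=3, effect=1.5):
        table, info = generate_feature_table(
            n_per_class=(n, 0, n), n_informative=k, effect_size=effect, seed=seed
        )
        noise = [
            c
            for c in table.columns
            if c not in info + ["task", "scenario", "participant"]
        ][: pool - k]
        return table, info, sorted(info + noise)

    def test_single_candidate_returned(self):
        table, info, _ = self._planted(0)
        res = sffs_select(table, [info[0]], max_size=3, seed=0)
        assert res.selected == [info[0]]

    def test_planted_features_recovered_across_seeds(self):
        """3 informative among 23: SFFS finds all three in >= 9/10 seeds."""
        hits = 0
        for seed in range(10):
            table, info, pool = self._planted(seed)
            res = sffs_select(table, pool, max_size=6, seed=seed)
            hits += set(info) <= set(res.selected)
        assert hits >= 9

    def test_score_trajectory_never_worsens_per_size(self):
        table, info, pool = self._planted(1)
        res = sffs_select(table, pool, max_size=6, seed=1)
        best = {}
        for size, score in res.trajectory:
            assert score >= best.get(size, -np.inf) - 1e-12
            best[size] = max(best.get(size, -np.inf), score)
        assert len(res.selected) == len(set(res.selected))

    def test_matches_exhaustive_search_on_small_pools(self):
        """score(SFFS) >= 0.95 x score(exhaustive) on random 8-pools."""
        rng_master = np.random.default_rng(0)
        evaluator = _cheap_evaluator(None)
        ok = 0
        for trial in range(20):
            seed = int(rng_master.integers(1 << 30))
            rng = np.random.default_rng(seed)
            n = 80
            x = rng.standard_normal((2 * n, 8))
            y = np.repeat(["a", "b"], n)
            betas = rng.uniform(-1, 1, 8) * rng.integers(0, 2, 8)
            x[: n] += 0.5 * betas
            cols = [f"f{i}" for i in range(8)]
            table = pd.DataFrame(x, columns=cols)
            table["task"] = y
            res = sffs_select(table, cols, evaluator=evaluator, max_size=4, seed=seed)
            sffs_score = res.best_score
            exhaustive = max(
                evaluator(x[:, list(sub)], y)
                for k in range(1, 5)
                for sub in combinations(range(8), k)
            )
            ok += sffs_score >= 0.95 * exhaustive
        assert ok == 20

    def test_floating_step_removes_dominated_feature(self):
        """A strong alone but redundant once B and C enter -> A dropped."""
        rng = np.random.default_rng(4)
        n = 400
        b = rng.standard_normal(2 * n)
        c = rng.standard_normal(2 * n)
        y = np.where(np.arange(2 * n) < n, "task", "base")
        b[:n] += 1.0
        c[:n] += 1.0
        a = 0.75 * (b + c) + rng.standard_normal(2 * n) * 0.5
        table = pd.DataFrame({"A": a, "B": b, "C": c})
        table["task"] = y

        def evaluator(x, yy):
            # Mahalanobis separation of the class means: redundancy-aware
            yy = np.asarray(yy)
            cls = np.unique(yy)
            g0, g1 = x[yy == cls[0]], x[yy == cls[1]]
            cov = (np.cov(g0.T) + np.cov(g1.T)) / 2
            cov = np.atleast_2d(cov) + 1e-9 * np.eye(x.shape[1])
            diff = g0.mean(axis=0) - g1.mean(axis=0)
            return float(np.sqrt(diff @ np.linalg.solve(cov, diff)))
        # precondition: A is the best singleton but {B,C} beats any pair with A
        x = {k: table[k].to_numpy()[:, None] for k in "ABC"}
        singles = {k: evaluator(x[k], y) for k in "ABC"}
        assert max(singles, key=singles.get) == "A"
        pair = lambda p, q: evaluator(table[[p, q]].to_numpy(), y)
        assert pair("B", "C") > max(pair("A", "B"), pair("A", "C"))
        res = sffs_select(table, ["A", "B", "C"], evaluator=evaluator, max_size=3, seed=0)
        # the forward path reaches {A, B}; once C enters, the floating
        # backward step discovers that dropping A improves the best pair
        score2, names2 = res.best_per_size[2]
        assert set(names2) == {"B", "C"}
        assert score2 == pytest.approx(evaluator(table[["B", "C"]].to_numpy(), y))
        # exhaustive oracle: no subset containing A beats the A-free best
        best_with_a = max(
            evaluator(table[list(sub)].to_numpy(), y)
            for sub in (["A"], ["A", "B"], ["A", "C"])
        )
        assert score2 > best_with_a

    def test_evaluator_failure_scores_zero_not_crash(self):
        table, info, pool = self._planted(2)

        def flaky(x, y):
            if x.shape[1] >= 2:
                raise RuntimeError("boom")
            return float(np.abs(x.mean()))

        res = sffs_select(table, pool[:4], evaluator=flaky, max_size=3, seed=0)
        assert len(res.selected) >= 1


class TestMda:
    def _table(self, seed, effect=2.0):
        table, info = generate_feature_table(
            n_per_class=(150, 0, 150), n_informative=3, effect_size=effect, seed=seed
        )
        cols = info + [
            c
            for c in table.columns
            if c not in info + ["task", "scenario", "participant"]
        ][:17]
        return table, info, cols

    def test_noise_columns_near_zero_importance(self):
        table, info, cols = self._table(0)
        imp = mda_importance(table, cols, n_repeats=10, seed=0)
        noise = [c for c in cols if c not in info]
        assert np.abs(imp[noise]).max() < 0.05
        assert abs(imp[noise].mean()) < 0.02

    def test_planted_columns_dominate_noise(self):
        wins = 0
        for seed in range(10):
            table, info, cols = self._table(seed)
            imp = mda_importance(table, cols, n_repeats=5, seed=seed)
            noise_max = imp[[c for c in cols if c not in info]].max()
            wins += all(imp[c] > noise_max for c in info)
        assert wins >= 9

    def test_permuting_everything_collapses_to_majority_rate(self):
        from sklearn.ensemble import RandomForestClassifier
        from sklearn.model_selection import train_test_split

        table, info, cols = self._table(3)
        x = table[cols].to_numpy()
        y = (table["task"] == "2-back").to_numpy()
        xtr, xva, ytr, yva = train_test_split(x, y, test_size=0.3, random_state=0)
        rf = RandomForestClassifier(n_estimators=200, random_state=0).fit(xtr, ytr)
        rng = np.random.default_rng(0)
        accs = []
        for _ in range(10):
            xp = np.column_stack([rng.permutation(xva[:, j]) for j in range(xva.shape[1])])
            accs.append(rf.score(xp, yva))
        majority = max(np.mean(yva), 1 - np.mean(yva))
        assert np.mean(accs) == pytest.approx(majority, abs=0.05)

    def test_all_noise_table_importances_average_zero(self):
        table, _ = generate_feature_table(
            n_per_class=(100, 0, 100), n_informative=0, seed=9
        )
        cols = [c for c in table.columns if c.startswith("ECG_")]
        imp = mda_importance(table, cols, n_repeats=5, seed=9)
        assert abs(imp.mean()) < 0.02


def test_svm_scr_evaluator_separates_signal_from_noise():
    table, info = generate_feature_table(
        n_per_class=(100, 0, 100), n_informative=3, effect_size=2.0, seed=0
    )
    ev = make_scr_evaluator(seed=0)
    y = table["task"].to_numpy()
    strong = ev(table[info].to_numpy(), y)
    noise_cols = [c for c in table.columns if c.startswith("RR_")][:3]
    weak = ev(table[noise_cols].to_numpy(), y)
    assert strong > 1.5 > weak
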