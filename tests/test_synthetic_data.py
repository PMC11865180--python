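"""Design generation and observer simulation."""

import numpy as np
import pytest
from scipy import stats

from ensembleyn import synthetic_data as sd
from ensembleyn.descriptives import classify
from ensembleyn.types import FeatureSeries, ObserverParams, OldPair


class TestSeries:
    def test_orientation_levels(self):
        s = sd.make_series("orientation", "rightward")
        assert s.levels == (0.0, 15.0, 30.0, 45.0, 60.0, 75.0, 90.0)

    def test_green_series_matches_packaged_table(self):
        s = sd.make_series("color", "green")
        assert len(s.levels) == 7
        assert s.labels[0] == "#3E6928" and s.labels[-1] == "#9EFE6C"
        assert all(b > a for a, b in zip(s.levels, s.levels[1:]))

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown family"):
            sd.make_series("color", "crimson")


class TestOldPair:
    def test_pair_invariants_and_uniformity(self):
        rng = np.random.default_rng(0)
        lowers = []
        for _ in range(10_000):
            pair = sd.sample_old_pair(sd.make_series("orientation", "leftward"), rng)
            assert pair.upper_index - pair.lower_index == 2
            assert pair.mean_index == pair.lower_index + 1
            lowers.append(pair.lower_index)
        counts = np.bincount(lowers, minlength=6)[1:]
        assert stats.chisquare(counts).pvalue > 1e-3

    def test_seeded_determinism(self):
        s = sd.make_series("orientation", "rightward")
        p1 = sd.sample_old_pair(s, np.random.default_rng(7))
        p2 = sd.sample_old_pair(s, np.random.default_rng(7))
        assert p1 == p2


class TestAssignProbe:
    @pytest.fixture
    def series(self):
        return sd.make_series("orientation", "rightward")

    def test_mean_probe_is_intervening_value(self, series):
        probe = sd.assign_probe("M", OldPair.from_lower(1), series, np.random.default_rng(0))
        assert probe.series_index == 2
        assert (probe.dist_from_mean, probe.dist_from_nearest_old) == (0, 1)

    def test_novel_probe_outside_old_range(self, series):
        rng = np.random.default_rng(0)
        seen = {
            sd.assign_probe("N", OldPair.from_lower(1), series, rng).series_index
            for _ in range(200)
        }
        assert seen == {4, 5, 6, 7}

    def test_novel_probe_excludes_old_and_mean(self, series):
        rng = np.random.default_rng(0)
        seen = {
            sd.assign_probe("N", OldPair.from_lower(3), series, rng).series_index
            for _ in range(200)
        }
        assert seen == {1, 2, 6, 7}

    def test_old_probe_hits_either_old_item(self, series):
        rng = np.random.default_rng(0)
        seen = {
            sd.assign_probe("O", OldPair.from_lower(2), series, rng).series_index
            for _ in range(100)
        }
        assert seen == {2, 4}


class TestSession:
    def test_single_dimension_trial_counts(self):
        trials = sd.generate_session(1, "P01", 5)
        exp = [t for t in trials if not t.practice]
        assert len(exp) == 480
        counts = {c: sum(t.relevant_probe.probe_class == c for t in exp) for c in "MON"}
        assert counts == {"M": 120, "O": 240, "N": 120}
        assert sum(t.practice for t in trials) == 20
        blocks = {t.block for t in exp}
        assert blocks == {1, 2, 3, 4, 5}
        assert sum(t.block == 1 for t in exp) == 96

    def test_family_balance(self):
        exp = [t for t in sd.generate_session(2, "P01", 5) if not t.practice]
        greens = sum(t.relevant_series.family == "green" for t in exp)
        assert greens == 240

    def test_factorial_cell_counts(self):
        exp = [t for t in sd.generate_session(3, "P01", 5) if not t.practice]
        assert len(exp) == 480
        assert all(t.relevant_dimension == "color" for t in exp)
        cells = {}
        for t in exp:
            key = (t.relevant_probe.probe_class, t.irrelevant_probe.probe_class)
            cells[key] = cells.get(key, 0) + 1
        assert all(cells[("O", irr)] == 80 for irr in "MON")
        assert all(cells[(rel, irr)] == 40 for rel in "MN" for irr in "MON")

    def test_seeded_determinism_and_design_invariance(self):
        t1 = sd.generate_session(1, "P01", 99)
        t2 = sd.generate_session(1, "P01", 99)
        assert t1 == t2
        # responses come from a separate stream: the design is identical
        # whichever observer answers it
        avg = sd.simulate_session(1, "P01", ObserverParams(rule="averaging"), 99)
        sim = sd.simulate_session(
            1, "P01", ObserverParams(rule="similarity", kernel=(0.9, 0.5, 0.1)), 99
        )
        assert [r.trial for r in avg] == t1
        assert [r.trial for r in sim] == t1


class TestLayout:
    def test_geometry_constraints(self):
        trial = sd.generate_session(1, "P01", 11)[25]
        lay = sd.generate_layout(trial)
        assert len(lay) == 64
        assert ((lay["x"] ** 2 + lay["y"] ** 2) > sd.BAR_LENGTH**2).all()
        assert lay["x"].abs().le(500).all() and lay["y"].abs().le(400).all()
        vals = lay["orientation"].value_counts()
        assert sorted(vals) == [32, 32]

    def test_two_dimension_crossing_balanced(self):
        trial = sd.generate_session(4, "P01", 11)[30]
        lay = sd.generate_layout(trial)
        combos = lay.groupby(["orientation", "color"]).size()
        assert len(combos) == 4 and (combos == 16).all()

    def test_seeded_determinism(self):
        trial = sd.generate_session(1, "P01", 11)[3]
        l1 = sd.generate_layout(trial, np.random.default_rng(4))
        l2 = sd.generate_layout(trial, np.random.default_rng(4))
        assert l1.equals(l2)


class TestObserver:
    def probe_trial(self, probe_class, lower=1, experiment=1):
        trials = sd.generate_session(experiment, "P", 1)
        for t in trials:
            if (
                t.relevant_probe.probe_class == probe_class
                and t.relevant_old.lower_index == lower
            ):
                return t
        raise AssertionError("no such trial in session")

    def test_similarity_mean_probe_product(self):
        # M probe one step from both old items: p(No) = (1 - g(1))^2
        t = self.probe_trial("M")
        params = ObserverParams(rule="similarity", kernel=(1.0, 0.6, 0.0))
        assert sd.response_probability(t, params) == pytest.approx(0.16)

    def test_similarity_old_probe_product(self):
        # O probe: distance 0 from one old item, 2 from the other
        t = self.probe_trial("O")
        params = ObserverParams(rule="similarity", kernel=(0.95, 0.5, 0.1))
        assert sd.response_probability(t, params) == pytest.approx(0.05 * 0.9)

    def test_averaging_mean_probe(self):
        t = self.probe_trial("M")
        params = ObserverParams(rule="averaging", a=0.2, b=0.0, c=1.0)
        assert sd.response_probability(t, params) == pytest.approx(0.6)

    @pytest.mark.parametrize(
        "params",
        [
            ObserverParams(rule="averaging", a=0.1, b=2.0, c=1.3),
            ObserverParams(rule="averaging", a=0.4, b=-1.0, c=0.5),
        ],
    )
    def test_averaging_monotone_in_dist_from_mean(self, params):
        trials = [t for t in sd.generate_session(1, "P", 3) if not t.practice]
        probs = {}
        for t in trials:
            d = t.relevant_probe.dist_from_mean
            probs.setdefault(d, sd.response_probability(t, params))
        ds = sorted(probs)
        assert all(probs[a] <= probs[b] for a, b in zip(ds, ds[1:]))

    def test_similarity_monotone_in_dist_from_old(self):
        params = ObserverParams(rule="similarity", kernel=(0.9, 0.6, 0.3, 0.1))
        trials = [t for t in sd.generate_session(1, "P", 3) if not t.practice]
        by_d = {}
        for t in trials:
            d = t.relevant_probe.dist_from_nearest_old
            by_d.setdefault(d, []).append(sd.response_probability(t, params))
        ds = sorted(by_d)
        lows = [min(by_d[d]) for d in ds]
        highs = [max(by_d[d]) for d in ds]
        assert all(lows[i + 1] >= highs[i] - 1e-12 for i in range(len(ds) - 1))

    def test_irrelevant_dimension_mixture(self):
        t = self.probe_trial("M", experiment=4)
        base = ObserverParams(rule="averaging", a=0.2, b=0.0, c=1.0, lam=0.0)
        mixed = ObserverParams(rule="averaging", a=0.2, b=0.0, c=1.0, lam=1.0)
        p_rel = sd.response_probability(t, base)
        p_irr = sd.response_probability(t, mixed)
        half = ObserverParams(rule="averaging", a=0.2, b=0.0, c=1.0, lam=0.5)
        assert sd.response_probability(t, half) == pytest.approx((p_rel + p_irr) / 2)

    def test_response_stream_determinism(self):
        params = ObserverParams(rule="averaging", a=0.2, b=2.0, c=1.5)
        r1 = sd.simulate_session(1, "P", params, 123)
        r2 = sd.simulate_session(1, "P", params, 123)
        assert [r.response for r in r1] == [r.response for r in r2]


def test_classify_consistency_on_simulated_table(exp1_avg_table):
    """Scheme consistency: N probes satisfy d_mean = d_old + 1; M probes are
    (0, 1); O probes are (1, 0)."""
    df = exp1_avg_table
    n = df["relevant_probe_class"] == "N"
    assert (
        df.loc[n, "relevant_dist_from_mean"]
        == df.loc[n, "relevant_dist_from_old"] + 1
    ).all()
    m = df["relevant_probe_class"] == "M"
    assert (df.loc[m, "relevant_dist_from_mean"] == 0).all()
    assert (df.loc[m, "relevant_dist_from_old"] == 1).all()
    o = df["relevant_probe_class"] == "O"
    assert (df.loc[o, "relevant_dist_from_mean"] == 1).all()
    assert (df.loc[o, "relevant_dist_from_old"] == 0).all()
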