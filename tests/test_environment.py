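import numpy as np
import pandas as pd
import pytest

from nestnet import (
    ScenarioConfig,
    UndefinedStatisticError,
    build_knn_network,
    nestbox_repeatability,
    simulate_dataset,
    strength_personality_association,
)
from nestnet.environment import _oneway_icc

from conftest import make_network


def _records_personality(assignments):
    """assignments: list of (year, box, bird, sex, score)."""
    recs, pers = [], {}
    for year, box, bird, sex, score in assignments:
        row = {"year": year, "box_id": box, "male_id": None, "female_id": None}
        row[f"{sex}_id"] = bird
        recs.append(row)
        pers[bird] = (sex, score)
    records = pd.DataFrame(recs)
    personality = pd.DataFrame(
        [{"bird_id": b, "sex": s, "score": sc} for b, (s, sc) in pers.items()]
    )
    return records, personality


class TestRepeatability:
    def test_pure_between_box_variance_gives_one(self):
        """Each box always hosts the same score, boxes differ: ICC = 1."""
        rows = []
        for b, score in enumerate([1.0, 5.0, 9.0]):
            for year in (2001, 2002, 2003):
                rows.append((year, f"box{b}", f"m{b}_{year}", "male", score))
        records, personality = _records_personality(rows)
        res = nestbox_repeatability(records, personality, n_subsamples=20, seed=0)
        assert res.estimate == pytest.approx(1.0, abs=1e-9)
        assert res.n_groups == 3

    def test_iid_scores_give_near_zero_icc(self):
        """Scores unrelated to boxes: mean ICC over synthetic datasets < 0.05."""
        rng = np.random.default_rng(1)
        estimates = []
        for _ in range(60):
            rows = []
            i = 0
            for b in range(30):
                for year in (2001, 2002, 2003):
                    rows.append((year, f"box{b}", f"m{i}", "male", float(rng.normal())))
                    i += 1
            records, personality = _records_personality(rows)
            res = nestbox_repeatability(records, personality, n_subsamples=1, seed=int(rng.integers(2**31)))
            estimates.append(res.estimate)
        assert np.mean(estimates) < 0.05

    def test_recovers_known_icc_half(self):
        """Between-box SD equal to residual SD (true ICC 0.5)."""
        rng = np.random.default_rng(2)
        estimates = []
        for _ in range(60):
            rows = []
            i = 0
            for b in range(50):
                mu = rng.normal()
                for year in range(2001, 2007):
                    rows.append((year, f"box{b}", f"m{i}", "male", float(mu + rng.normal())))
                    i += 1
            records, personality = _records_personality(rows)
            res = nestbox_repeatability(records, personality, n_subsamples=1, seed=int(rng.integers(2**31)))
            estimates.append(res.estimate)
        assert np.mean(estimates) == pytest.approx(0.5, abs=0.05)

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        rows = []
        i = 0
        for b in range(20):
            mu = rng.normal()
            for year in (2001, 2002):
                rows.append((year, f"box{b}", f"m{i}", "male", float(mu + rng.normal())))
                i += 1
        records, personality = _records_personality(rows)
        r1 = nestbox_repeatability(records, personality, n_subsamples=10, seed=9)
        personality2 = personality.assign(score=3.0 * personality["score"] - 11.0)
        r2 = nestbox_repeatability(records, personality2, n_subsamples=10, seed=9)
        assert r1.estimate == pytest.approx(r2.estimate, rel=1e-9)

    def test_subsampling_keeps_one_year_per_bird_box(self):
        """A bird reusing one box: the repeat years must not inflate ICC.
        With singleton groups only, ICC is 0 with a warning."""
        rows = [
            (2001, "boxA", "m1", "male", 2.0),
            (2002, "boxA", "m1", "male", 2.0),
            (2003, "boxA", "m1", "male", 2.0),
            (2001, "boxB", "m2", "male", 5.0),
        ]
        records, personality = _records_personality(rows)
        res = nestbox_repeatability(records, personality, n_subsamples=5, seed=1)
        assert res.estimate == 0.0

    def test_interval_orders_and_reproducible(self):
        rng = np.random.default_rng(4)
        rows = []
        i = 0
        for b in range(25):
            mu = rng.normal(scale=0.5)
            for year in range(2001, 2005):
                rows.append((year, f"box{b}", f"m{i}", "male", float(mu + rng.normal())))
                i += 1
        records, personality = _records_personality(rows)
        a = nestbox_repeatability(records, personality, n_subsamples=50, seed=5)
        b = nestbox_repeatability(records, personality, n_subsamples=50, seed=5)
        assert a.interval_low <= a.estimate <= a.interval_high
        assert a.estimate == b.estimate and a.interval_low == b.interval_low

    def test_oneway_icc_truncated_at_zero(self):
        groups = np.array(["a", "a", "b", "b"])
        values = np.array([0.0, 10.0, 5.0, 5.01])  # within >> between
        assert _oneway_icc(groups, values) == 0.0


class TestStrengthAssociation:
    def _nets_with_strength_slope(self, slope, n=40, noise=0.1, seed=0, years=2):
        """Star-free synthetic networks where strength ~= slope*score."""
        rng = np.random.default_rng(seed)
        nets = []
        for y in range(years):
            scores = rng.normal(size=n)
            edges = []
            # chain topology; per-node strength adjusted via self-tuned weights
            nodes = {f"y{y}m{i}": s for i, s in enumerate(scores)}
            names = list(nodes)
            for i in range(n):
                target = slope * scores[i] + rng.normal(scale=noise)
                w = max(target / 2.0, 0.01)  # two incident edges each side
                edges.append((names[i], names[(i + 1) % n], w))
            net = make_network(edges, nodes, directed=False, year=2001 + y)
            nets.append(net)
        return nets

    def test_recovers_constructed_slope(self):
        """Strength built as ~2*score + noise: slope ~= 2 recovered."""
        rng = np.random.default_rng(11)
        nets = []
        for y in (2001, 2002):
            n = 60
            scores = rng.normal(size=n)
            nodes = {f"y{y}m{i}": float(scores[i]) for i in range(n)}
            names = list(nodes)
            edges = []
            for i in range(n):
                # pair each node with a dedicated stub so its strength is
                # exactly its own edge weight
                stub = f"y{y}s{i}"
                nodes[stub] = None
                w = 2.0 * scores[i] + rng.normal(scale=0.05) + 10.0
                edges.append((names[i], stub, w))
            net = make_network(edges, nodes, directed=False, year=y)
            nets.append(net)
        res = strength_personality_association(nets, n_perm=300, seed=3)
        assert res.slope == pytest.approx(2.0, abs=0.05)
        assert res.p_value < 0.01

    def test_constant_strength_null(self):
        rng = np.random.default_rng(12)
        n = 30
        nodes = {f"m{i}": float(rng.normal()) for i in range(n)}
        names = list(nodes)
        edges = [(names[i], names[(i + 1) % n], 1.0) for i in range(n)]
        net = make_network(edges, nodes, directed=False, year=2001)
        res = strength_personality_association([net], n_perm=400, seed=4)
        assert res.slope == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.9

    def test_calibration_under_null(self):
        """Scores independent of position: rejection rate at alpha=0.05
        compatible with the binomial 95% interval over 120 simulations."""
        rng = np.random.default_rng(13)
        rejections = 0
        n_sim = 120
        for _ in range(n_sim):
            cfg = ScenarioConfig(
                n_boxes=80, window=(0, 0, 700, 500), min_spacing=15, n_years=1,
                occupancy=0.6, typed_fraction=1.0, rho=0.0,
                seed=int(rng.integers(2**31)),
            )
            ds = simulate_dataset(cfg)
            year = int(ds.records["year"].iloc[0])
            net = build_knn_network(ds.records, ds.nestboxes, ds.personality, year, "male", k=5)
            res = strength_personality_association(
                [net], n_perm=200, seed=int(rng.integers(2**31))
            )
            rejections += res.p_value <= 0.05
        # exact binomial 95% band for p=0.05, n=120: [2, 11] successes
        assert 1 <= rejections <= 12

    def test_zero_variance_raises(self):
        nodes = {f"m{i}": 1.0 for i in range(12)}
        names = list(nodes)
        edges = [(names[i], names[(i + 1) % 12], 1.0) for i in range(12)]
        net = make_network(edges, nodes, directed=False, year=2001)
        with pytest.raises(UndefinedStatisticError):
            strength_personality_association([net], n_perm=50, seed=0)
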