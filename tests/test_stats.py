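"""Profile aggregation and the mixed repeated-measures ANOVA."""

import numpy as np
import pandas as pd
import pytest

from mfcsholl.errors import ValidationError
from mfcsholl.sholl import ShollProfile
from mfcsholl.stats import (ExperimentSet, aggregate, compare_treatments,
                            median_outermost, mixed_anova)

DISTS = np.arange(100.0, 500.0, 50.0)


def make_profile(counts, chamber_id, side="right", soma=100):
    return ShollProfile(distances_um=DISTS[:len(counts)], intersections=counts,
                        soma_count=soma, side=side, chamber_id=chamber_id)


def poisson_set(rng, mus, n_subjects=5, soma=100):
    """One ExperimentSet with Poisson counts around per-treatment curves."""
    profiles, design = [], {}
    for treat, mu in mus.items():
        for s in range(n_subjects):
            cid = f"{treat}{s}"
            profiles.append(make_profile(rng.poisson(mu), cid, soma=soma))
            design[cid] = treat
    return ExperimentSet(profiles, design)


class TestExperimentSet:
    def test_mismatched_grids_rejected(self):
        p1 = make_profile([5, 4, 3], "a")
        p2 = ShollProfile(distances_um=[100.0, 200.0, 300.0],
                          intersections=[5, 4, 3], soma_count=100,
                          side="right", chamber_id="b")
        with pytest.raises(ValidationError):
            ExperimentSet([p1, p2], {"a": "x", "b": "x"})

    def test_unlabelled_profile_rejected(self):
        with pytest.raises(ValidationError):
            ExperimentSet([make_profile([1, 2], "a")], {"other": "x"})

    def test_per_side_design_overrides_chamber(self):
        pl = make_profile([1, 2], "c", side="left")
        pr = make_profile([3, 4], "c", side="right")
        es = ExperimentSet([pl, pr], {("c", "left"): "ctrl", ("c", "right"): "ngf"})
        assert es.treatment_of(pl) == "ctrl"
        assert es.treatment_of(pr) == "ngf"

    def test_chamber_unit_rejects_split_treatments(self):
        pl = make_profile([1, 2], "c", side="left")
        pr = make_profile([3, 4], "c", side="right")
        es = ExperimentSet([pl, pr], {("c", "left"): "ctrl", ("c", "right"): "ngf"})
        with pytest.raises(ValidationError):
            es.subject_table(unit="chamber")


class TestAggregate:
    def test_single_profile_mean_with_zero_sem(self):
        es = ExperimentSet([make_profile([10, 6], "a")], {"a": "t"})
        with pytest.warns(UserWarning):
            out = aggregate(es)
        np.testing.assert_allclose(out["mean"], [0.10, 0.06])
        np.testing.assert_allclose(out["sem"], [0.0, 0.0])

    def test_two_profile_hand_arithmetic(self):
        es = ExperimentSet([make_profile([20, 10], "a"), make_profile([40, 30], "b")],
                           {"a": "t", "b": "t"})
        out = aggregate(es).sort_values("distance_um")
        np.testing.assert_allclose(out["mean"], [0.3, 0.2])
        np.testing.assert_allclose(out["sem"], [0.1, 0.1])

    def test_order_invariance(self):
        ps = [make_profile([20, 10], "a"), make_profile([40, 30], "b"),
              make_profile([5, 2], "c")]
        design = {k: "t" for k in "abc"}
        out1 = aggregate(ExperimentSet(ps, design))
        out2 = aggregate(ExperimentSet(ps[::-1], design))
        pd.testing.assert_frame_equal(out1.reset_index(drop=True),
                                      out2.reset_index(drop=True))

    def test_replicate_means_near_expectation(self):
        rng = np.random.default_rng(6)
        mu = 30 * np.exp(-DISTS / 250)
        hits = total = 0
        for rep in range(200):
            es = poisson_set(rng, {"t": mu}, n_subjects=5)
            out = aggregate(es).sort_values("distance_um")
            sem = np.maximum(out["sem"].to_numpy(), 1e-9)
            ok = np.abs(out["mean"].to_numpy() - mu / 100) <= 3 * sem
            hits += ok.sum()
            total += ok.size
        assert hits / total >= 0.95


class TestMixedAnova:
    def test_identical_groups_give_null_f(self):
        base = np.array([[0.2, 0.1, 0.05], [0.3, 0.2, 0.1], [0.25, 0.12, 0.07]])
        effects, _ = mixed_anova({"a": base, "b": base.copy()})
        assert effects["treatment"].F == pytest.approx(0.0, abs=1e-12)
        assert effects["treatment"].p == pytest.approx(1.0)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(42)
        rows = []
        groups = {}
        for g, treat in enumerate(["ctrl", "cocktail"]):
            mat = []
            for s in range(5):
                mu = 20 * np.exp(-DISTS / 300) * (1 + 0.5 * g)
                vals = (rng.poisson(mu) + 1) / 100
                mat.append(vals)
                for d, v in zip(DISTS, vals):
                    rows.append({"subj": f"c{g}{s}", "treat": treat,
                                 "dist": d, "val": v})
            groups[treat] = np.array(mat)
        effects, _ = mixed_anova(groups)
        aov = pg.mixed_anova(data=pd.DataFrame(rows), dv="val", within="dist",
                             subject="subj", between="treat").set_index("Source")
        assert effects["treatment"].ss == pytest.approx(aov.loc["treat", "SS"], rel=1e-9)
        assert effects["treatment"].F == pytest.approx(aov.loc["treat", "F"], rel=1e-9)
        assert effects["treatment"].p == pytest.approx(aov.loc["treat", "p_unc"], rel=1e-9)
        assert effects["distance"].ss == pytest.approx(aov.loc["dist", "SS"], rel=1e-9)
        assert effects["distance"].F == pytest.approx(aov.loc["dist", "F"], rel=1e-9)
        assert effects["interaction"].F == pytest.approx(
            aov.loc["Interaction", "F"], rel=1e-9)

    def test_gg_correction_weakens_within_tests(self):
        rng = np.random.default_rng(9)
        es = poisson_set(rng, {"a": 20 * np.exp(-DISTS / 300),
                               "b": 25 * np.exp(-DISTS / 300)})
        res = compare_treatments(es)
        dist = res.effects["distance"]
        assert dist.p_gg >= dist.p
        assert 1.0 / (len(DISTS) - 1) <= res.epsilon_gg <= 1.0
        assert dist.df1_gg == pytest.approx(res.epsilon_gg * dist.df1)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValidationError):
            mixed_anova({"a": np.zeros((1, 4)), "b": np.zeros((3, 4))})
        with pytest.raises(ValidationError):
            mixed_anova({"a": np.zeros((3, 4))})

    def test_permutation_and_parametric_p_rank_agree(self):
        rng = np.random.default_rng(12)
        mu = 20 * np.exp(-DISTS / 300)
        param_p, perm_p = [], []
        # moderate effects keep the p-values above the permutation resolution
        for effect in (1.0, 1.08, 1.16, 1.30):
            A = rng.poisson(mu, size=(6, len(DISTS))) / 100
            B = rng.poisson(effect * mu, size=(6, len(DISTS))) / 100
            effects, _ = mixed_anova({"A": A, "B": B})
            param_p.append(effects["treatment"].p)
            pooled = np.vstack([A, B])
            f_obs = effects["treatment"].F
            hits = 0
            n_perm = 400
            for _ in range(n_perm):
                idx = rng.permutation(12)
                eff_p, _ = mixed_anova({"A": pooled[idx[:6]], "B": pooled[idx[6:]]})
                hits += eff_p["treatment"].F >= f_obs
            perm_p.append((hits + 1) / (n_perm + 1))
        # rank agreement: wherever both p-values differ between two effect
        # sizes, they must order those effect sizes identically
        for i in range(len(param_p)):
            for j in range(i + 1, len(param_p)):
                dp = param_p[i] - param_p[j]
                dq = perm_p[i] - perm_p[j]
                if dp != 0 and dq != 0:
                    assert np.sign(dp) == np.sign(dq)


class TestMedianOutermost:
    def _set(self, outer_counts):
        profiles, design = [], {}
        for i, k in enumerate(outer_counts):
            counts = [5] * k + [0] * (len(DISTS) - k)
            profiles.append(make_profile(counts, f"c{i}"))
            design[f"c{i}"] = "t"
        return ExperimentSet(profiles, design)

    def test_odd_count_median(self):
        # outermost lines at 200, 300, 400 um -> median 300
        es = self._set([3, 5, 7])
        assert median_outermost(es, "t") == 300.0

    def test_even_count_takes_lower_median(self):
        es = self._set([3, 5])  # outermost 200 and 300 um
        assert median_outermost(es, "t") == 200.0

    def test_single_profile_returns_its_own(self):
        es = self._set([4])
        assert median_outermost(es, "t") == 250.0

    def test_all_zero_profiles_undefined(self):
        es = self._set([0, 0])
        with pytest.warns(UserWarning):
            assert median_outermost(es, "t") is None
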