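import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from psyvalid.nomonet import (
    block_average,
    constrained_pair_test,
    correlate_block,
    pairwise_difference_scan,
)


def _mvn_sample(rng, corr, n):
    chol = np.linalg.cholesky(np.asarray(corr))
    return rng.standard_normal((n, len(corr))) @ chol.T


def brute_force_constrained_chi2(x: np.ndarray, grid_steps: int = 0) -> float:
    """Independent oracle: maximize the constrained 3-variable Gaussian
    likelihood by direct search over (r_shared, r_12) and the three SDs,
    without the package's parameterization."""
    n, p = x.shape
    assert p == 3
    s = np.cov(x, rowvar=False, ddof=0)
    sign, logdet_s = np.linalg.slogdet(s)

    def discrepancy(params):
        sd = np.exp(params[:3])
        r12, rc = np.tanh(params[3]), np.tanh(params[4])
        corr = np.array([[1, r12, rc], [r12, 1, rc], [rc, rc, 1]])
        sigma = corr * np.outer(sd, sd)
        sgn, logdet = np.linalg.slogdet(sigma)
        if sgn <= 0:
            return 1e9
        return logdet + np.trace(s @ np.linalg.inv(sigma)) - logdet_s - 3

    d = np.sqrt(np.diag(s))
    r = s / np.outer(d, d)
    start = np.concatenate([np.log(d), [np.arctanh(r[0, 1]),
                                        np.arctanh((r[0, 2] + r[1, 2]) / 2)]])
    best = optimize.minimize(discrepancy, start, method="Nelder-Mead",
                             options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 50000})
    return n * best.fun


class TestCorrelateBlock:
    def test_measure_as_its_own_correlate(self, rng):
        scores = pd.DataFrame(rng.standard_normal((50, 1)), columns=["m"])
        block = correlate_block(scores, scores.rename(columns={"m": "c"}),
                                {"c": "identity"})
        assert block.values.loc["c", "m"] == pytest.approx(1.0)
        assert block.significance(0.01).loc["c", "m"]

    def test_generator_implied_cell(self, rng):
        n = 5000
        latent = rng.standard_normal(n)
        scores = pd.DataFrame({"m": latent})
        correlates = pd.DataFrame(
            {"c": 0.30 * latent + np.sqrt(1 - 0.09) * rng.standard_normal(n)}
        )
        block = correlate_block(scores, correlates, {"c": "personality"})
        assert block.values.loc["c", "m"] == pytest.approx(0.30, abs=0.03)

    def test_small_n_orthogonal_flagged_nonsignificant(self):
        # r = .5 on n = 5: t = 1, p ~ .39 -> "italic" (p >= .01) flag
        scores = pd.DataFrame({"m": [1.0, 2.0, 3.0, 4.0, 5.0]})
        correlates = pd.DataFrame({"c": [2.0, 1.0, 4.0, 3.0, 5.0]})
        block = correlate_block(scores, correlates, {"c": "demography"})
        assert block.p_values.loc["c", "m"] > 0.01
        assert not block.significance(0.01).loc["c", "m"]

    def test_domain_tag_required(self, rng):
        scores = pd.DataFrame(rng.standard_normal((20, 1)), columns=["m"])
        corr = pd.DataFrame(rng.standard_normal((20, 1)), columns=["c"])
        with pytest.raises(ValueError):
            correlate_block(scores, corr, {})


class TestBlockAverage:
    def test_published_personality_columns(self, study1_net, study2_net):
        block1, dom1 = study1_net
        from psyvalid.nomonet import NomologicalBlock

        b1 = NomologicalBlock(
            values=block1, pair_n=block1.notna().astype(int) * 600,
            p_values=block1 * 0.0, domains=dom1,
        )
        avg = block_average(b1, "personality")
        assert round(avg["UCLA_20"], 2) == 0.36
        block2, dom2 = study2_net
        b2 = NomologicalBlock(
            values=block2, pair_n=block2.notna().astype(int) * 1000,
            p_values=block2 * 0.0, domains=dom2,
        )
        assert round(block_average(b2, "personality")["RTLS_Social"], 2) == 0.22

    def test_single_cell_domain(self, rng):
        scores = pd.DataFrame(rng.standard_normal((30, 1)), columns=["m"])
        corr = pd.DataFrame(rng.standard_normal((30, 1)), columns=["c"])
        block = correlate_block(scores, corr, {"c": "solo"})
        avg = block_average(block, "solo")
        assert avg["m"] == pytest.approx(abs(block.values.loc["c", "m"]))

    def test_average_between_min_and_max(self, study1_net):
        block, dom = study1_net
        from psyvalid.nomonet import NomologicalBlock

        b = NomologicalBlock(
            values=block, pair_n=block.notna().astype(int) * 600,
            p_values=block * 0.0, domains=dom,
        )
        for domain in ("demography", "personality", "satisfaction", "network"):
            rows = b.domain_rows(domain).abs()
            avg = block_average(b, domain)
            for m in avg.index:
                assert rows[m].min() - 1e-12 <= avg[m] <= rows[m].max() + 1e-12


class TestConstrainedPairTest:
    def test_exactly_satisfied_constraint(self, rng):
        # y built so its sample correlations with m1 and m2 are equal
        n = 150
        a = rng.standard_normal(n)
        b = 0.4 * a + np.sqrt(1 - 0.16) * rng.standard_normal(n)
        az = (a - a.mean()) / a.std()
        bz = (b - b.mean()) / b.std()
        # noise orthogonalized in-sample so the equality is exact but the
        # joint covariance stays nonsingular
        e = rng.standard_normal(n)
        basis = np.column_stack([np.ones(n), az, bz])
        e = e - basis @ np.linalg.lstsq(basis, e, rcond=None)[0]
        data = pd.DataFrame({"m1": a, "m2": b, "y": az + bz + e})
        r1 = np.corrcoef(data["m1"], data["y"])[0, 1]
        r2 = np.corrcoef(data["m2"], data["y"])[0, 1]
        assert r1 == pytest.approx(r2, abs=1e-12)
        res = constrained_pair_test(data, ("m1", "m2", "y"))
        assert res.chi2_diff <= 1e-6

    def test_agrees_with_brute_force_likelihood(self, rng):
        corr = [[1, 0.5, 0.45], [0.5, 1, 0.15], [0.45, 0.15, 1]]
        x = _mvn_sample(rng, corr, 200)
        data = pd.DataFrame(x, columns=["m1", "m2", "y"])
        res = constrained_pair_test(data, ("m1", "m2", "y"))
        oracle = brute_force_constrained_chi2(x)
        assert res.chi2_diff == pytest.approx(oracle, abs=1e-3)
        assert res.chi2_diff > 1.0  # the fixture has clearly unequal correlations

    def test_affine_rescaling_invariance(self, rng):
        corr = [[1, 0.6, 0.4], [0.6, 1, 0.2], [0.4, 0.2, 1]]
        x = _mvn_sample(rng, corr, 300)
        data = pd.DataFrame(x, columns=["m1", "m2", "y"])
        scaled = data * np.array([3.0, 0.25, 10.0]) + np.array([5.0, -2.0, 100.0])
        a = constrained_pair_test(data, ("m1", "m2", "y")).chi2_diff
        b = constrained_pair_test(scaled, ("m1", "m2", "y")).chi2_diff
        assert a == pytest.approx(b, rel=1e-5, abs=1e-7)

    def test_insufficient_cases_rejected(self, rng):
        data = pd.DataFrame(rng.standard_normal((10, 3)), columns=["m1", "m2", "y"])
        with pytest.raises(ValueError):
            constrained_pair_test(data, ("m1", "m2", "y"))

    def test_batch_scope_matches_triplet_saturated(self, rng):
        # wider scope changes the constrained optimum only slightly; both
        # must stay nonnegative and agree to first order on null-ish data
        corr = np.eye(4) * 0.4 + 0.6
        x = _mvn_sample(rng, corr, 400)
        data = pd.DataFrame(x, columns=["m1", "m2", "m3", "y"])
        tri = constrained_pair_test(data, ("m1", "m2", "y"))
        wide = constrained_pair_test(data, ("m1", "m2", "y"), scope=["m1", "m2", "m3"])
        assert wide.chi2_diff >= -1e-9
        assert wide.chi2_diff == pytest.approx(tri.chi2_diff, abs=0.5)


class TestPairwiseScan:
    def test_single_measure_batch_empty(self, rng):
        scores = pd.DataFrame(rng.standard_normal((60, 2)), columns=["m1", "m2"])
        corrs = pd.DataFrame(rng.standard_normal((60, 1)), columns=["y"])
        out = pairwise_difference_scan(scores, corrs, batches=[["m1"], ["m2"]])
        assert out.empty

    def test_two_measures_reduce_to_single_test(self, rng):
        corr = [[1, 0.5, 0.3], [0.5, 1, 0.3], [0.3, 0.3, 1]]
        x = _mvn_sample(rng, corr, 120)
        scores = pd.DataFrame(x[:, :2], columns=["m1", "m2"])
        corrs = pd.DataFrame(x[:, 2:], columns=["y"])
        out = pairwise_difference_scan(scores, corrs)
        assert len(out) == 1
        direct = constrained_pair_test(
            pd.concat([scores, corrs], axis=1), ("m1", "m2", "y")
        )
        assert out.loc[0, "chi2"] == pytest.approx(direct.chi2_diff, rel=1e-6, abs=1e-9)

    def test_power_against_clearly_unequal_correlations(self, rng):
        n = 2000
        latent = rng.standard_normal(n)
        m1 = 0.5 * latent + np.sqrt(1 - 0.25) * rng.standard_normal(n)
        m2 = 0.2 * latent + np.sqrt(1 - 0.04) * rng.standard_normal(n)
        y = latent
        scores = pd.DataFrame({"m1": m1, "m2": m2})
        corrs = pd.DataFrame({"y": y})
        out = pairwise_difference_scan(scores, corrs, alpha=0.001)
        assert bool(out.loc[0, "significant"])
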