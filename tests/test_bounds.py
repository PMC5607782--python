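"""Closed-form guarantee calculators: local-optimality characterization,
attacker TP and utility-ratio bounds, VC deviation term, set identities."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from greedysanitize import (
    ConfusionCounts,
    FiniteSampleParams,
    GameParams,
    bound_report,
    fs_ratio_bound,
    fs_tp_bound,
    lambda_bound,
    lemma_identities,
    local_optimum_check,
    ratio_bound,
    tp_bound,
)
from greedysanitize.bounds import BoundValidityError


def brute_force_loss(labels: dict, pred_sets: list[dict], params: GameParams) -> float:
    """Publisher loss T(H) computed directly from the set definitions."""
    sens = {k for k, v in labels.items() if v == 1}
    x1 = set()
    for preds in pred_sets:
        x1 |= {k for k, p in preds.items() if p == 1}
    fn = len(sens - x1)
    fp = len(x1 - sens)
    return params.L * fn + params.C * fp


class TestLocalOptimum:
    @pytest.mark.parametrize("tp, fp, lc, expected", [
        (0, 0, 5, True),
        (0, 99, 5, True),
        (3, 6, 5, False),   # 2 < 5
        (3, 6, 2, True),    # 2 >= 2 boundary
    ])
    def test_characterization(self, tp, fp, lc, expected):
        counts = ConfusionCounts(tp=tp, fp=fp, tn=0, fn=0)
        assert local_optimum_check(counts, GameParams(L=lc, C=1)) is expected

    def test_agrees_with_direct_loss_comparison_exhaustive(self):
        """On fully enumerated universes (n <= 4, every labeling, every pair
        of H-union and candidate prediction bitmaps), the TP/FP
        characterization coincides with T(H u h_A) - T(H) >= 0."""
        params = GameParams(L=3, C=1)
        for n in range(1, 5):
            keys = [("d0", i) for i in range(n)]
            for lab_bits, h_bits, a_bits in itertools.product(
                    range(2 ** n), repeat=3):
                labels = {k: (lab_bits >> i) & 1 for i, k in enumerate(keys)}
                preds_H = {k: (h_bits >> i) & 1 for i, k in enumerate(keys)}
                preds_A = {k: (a_bits >> i) & 1 for i, k in enumerate(keys)}
                delta = (brute_force_loss(labels, [preds_H, preds_A], params)
                         - brute_force_loss(labels, [preds_H], params))
                # counts of h_A restricted to P(H)
                p_h = [k for k in keys if preds_H[k] == 0]
                c = ConfusionCounts(
                    tp=sum(1 for k in p_h if labels[k] and preds_A[k]),
                    fp=sum(1 for k in p_h if not labels[k] and preds_A[k]),
                    tn=sum(1 for k in p_h if not labels[k] and not preds_A[k]),
                    fn=sum(1 for k in p_h if labels[k] and not preds_A[k]),
                )
                assert local_optimum_check(c, params) == (delta >= 0)

    def test_agrees_on_random_larger_universes(self):
        """Randomized check up to n = 12 with multi-member H."""
        rng = np.random.default_rng(0)
        params = GameParams(L=5, C=2)
        for _ in range(300):
            n = int(rng.integers(1, 13))
            keys = [("d0", i) for i in range(n)]
            labels = {k: int(rng.random() < 0.4) for k in keys}
            H = [{k: int(rng.random() < 0.3) for k in keys}
                 for _ in range(int(rng.integers(0, 4)))]
            preds_A = {k: int(rng.random() < 0.3) for k in keys}
            delta = (brute_force_loss(labels, H + [preds_A], params)
                     - brute_force_loss(labels, H, params))
            x1 = set()
            for preds in H:
                x1 |= {k for k, p in preds.items() if p == 1}
            p_h = [k for k in keys if k not in x1]
            c = ConfusionCounts(
                tp=sum(1 for k in p_h if labels[k] and preds_A[k]),
                fp=sum(1 for k in p_h if not labels[k] and preds_A[k]),
                tn=sum(1 for k in p_h if not labels[k] and not preds_A[k]),
                fn=sum(1 for k in p_h if labels[k] and not preds_A[k]),
            )
            assert local_optimum_check(c, params) == (delta >= 0)


class TestAsymptoticBounds:
    def test_tp_bound_substitution(self):
        assert tp_bound(GameParams(L=5, C=1), alpha=5 / 26, n=26) == \
            pytest.approx(4.2)

    def test_tp_bound_all_sensitive(self):
        assert tp_bound(GameParams(L=5, C=1), alpha=1.0, n=100) == 0.0

    def test_tp_bound_decreases_in_loss(self):
        vals = [tp_bound(GameParams(L=L, C=1), 0.02, 1000)
                for L in [1, 2, 5, 10, 100]]
        assert vals == sorted(vals, reverse=True)

    def test_ratio_bound_substitution(self):
        assert ratio_bound(GameParams(L=5, C=1), alpha=5 / 26, n=26) == \
            pytest.approx(22 / 6)

    def test_ratio_bound_fixed_point(self):
        # L/C = (1 - alpha) n  =>  bound is exactly 1
        alpha, n = 0.2, 50
        lc = (1 - alpha) * n
        assert ratio_bound(GameParams(L=lc, C=1), alpha, n) == pytest.approx(1.0)

    def test_worked_example_ratio_within_bound(self):
        """The observed 1.1165 ratio respects the bound up to the crossover
        L/C = 22/1.1165 - 1 ~ 18.70, and violates it just beyond."""
        observed = 1898 / 1700
        assert observed <= ratio_bound(GameParams(L=18.7, C=1), 5 / 26, 26)
        assert observed > ratio_bound(GameParams(L=18.8, C=1), 5 / 26, 26)


class TestLambda:
    def test_reference_value(self):
        fsp = FiniteSampleParams(vc_dim=1, delta=0.05, m=10_000)
        assert lambda_bound(fsp) == pytest.approx(0.07819, abs=1e-4)

    def test_decreases_in_sample_size(self):
        for m in [10, 100, 1000, 54321]:
            a = lambda_bound(FiniteSampleParams(1, 0.05, m))
            b = lambda_bound(FiniteSampleParams(1, 0.05, 2 * m))
            assert b < a

    def test_increases_as_delta_shrinks(self):
        a = lambda_bound(FiniteSampleParams(2, 0.1, 1000))
        b = lambda_bound(FiniteSampleParams(2, 0.01, 1000))
        assert b > a

    @pytest.mark.parametrize("kwargs", [
        {"vc_dim": 0}, {"delta": 0.0}, {"delta": 1.0}, {"m": 0}, {"p": 0.0},
    ])
    def test_parameter_validation(self, kwargs):
        with pytest.raises(ValueError):
            FiniteSampleParams(**{"vc_dim": 1, "delta": 0.05, "m": 10, **kwargs})


class TestFiniteSampleBounds:
    def test_tp_substitution(self):
        fsp = FiniteSampleParams(vc_dim=1, delta=0.05, m=100,
                                 p=1, q=1, r=1, s=1)
        val = fs_tp_bound(fsp, GameParams(L=10, C=1), alpha=0.0, n=100,
                          lam=0.5)
        assert val == pytest.approx(200 / 19.5)

    def test_ratio_substitution(self):
        fsp = FiniteSampleParams(vc_dim=1, delta=0.05, m=100,
                                 p=1, q=1, r=1, s=1)
        val = fs_ratio_bound(fsp, GameParams(L=10, C=1), alpha=0.0, n=100,
                             lam=0.5)
        assert val == pytest.approx(202 / 21.5)

    def test_reduces_to_asymptotic_in_the_limit(self):
        """lambda -> 0 with p, s -> inf and q, r -> 1 recovers the
        asymptotic bounds to 1e-9."""
        fsp = FiniteSampleParams(vc_dim=1, delta=0.05, m=100,
                                 p=math.inf, q=1.0, r=1.0, s=math.inf)
        params = GameParams(L=7, C=2)
        assert fs_tp_bound(fsp, params, 0.03, 500, lam=0.0) == pytest.approx(
            tp_bound(params, 0.03, 500), abs=1e-9)
        assert fs_ratio_bound(fsp, params, 0.03, 500, lam=0.0) == pytest.approx(
            ratio_bound(params, 0.03, 500), abs=1e-9)

    def test_finite_sample_bounds_dominate_asymptotic(self):
        """With lambda > 0 and the training-side ratios at their tight
        limits (p -> inf, q = r = 1), a finite published-side slack s makes
        the finite-sample bounds weakly looser than the asymptotic ones."""
        params = GameParams(L=10, C=1)
        fsp = FiniteSampleParams(vc_dim=3, delta=0.05, m=5000,
                                 p=math.inf, q=1.0, r=1.0, s=3.0)
        assert fs_tp_bound(fsp, params, 0.02, 1000) >= \
            tp_bound(params, 0.02, 1000)
        assert fs_ratio_bound(fsp, params, 0.02, 1000) >= \
            ratio_bound(params, 0.02, 1000)

    def test_ratio_bound_decreases_in_loss_ratio(self):
        fsp = FiniteSampleParams(vc_dim=1, delta=0.05, m=10_000,
                                 p=1, q=1, r=1, s=1)
        vals = [fs_ratio_bound(fsp, GameParams(L=lc, C=1), 0.02, 100)
                for lc in [2, 5, 10, 50]]
        assert vals == sorted(vals, reverse=True)

    def test_validity_error_when_lambda_too_large(self):
        fsp = FiniteSampleParams(vc_dim=1, delta=0.05, m=100, p=1, q=1,
                                 r=1, s=1)
        with pytest.raises(BoundValidityError, match="lambda"):
            fs_tp_bound(fsp, GameParams(L=10, C=1), 0.0, 100, lam=25.0)


class TestSetIdentities:
    def test_empty_classifier_set(self):
        """With H empty, FN(H) is the total sensitive count and the identity
        reduces to #sensitive = FN({h}) + TP(h, X)."""
        keys = [("d0", i) for i in range(6)]
        labels = dict(zip(keys, [1, 1, 0, 0, 1, 0]))
        h = dict(zip(keys, [1, 0, 1, 0, 0, 0]))
        assert lemma_identities([], h, labels)

    def test_random_universes_against_set_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(1, 11))
            keys = [("d0", i) for i in range(n)]
            labels = {k: int(rng.random() < 0.5) for k in keys}
            H = [{k: int(rng.random() < 0.4) for k in keys}
                 for _ in range(3)]
            h = {k: int(rng.random() < 0.4) for k in keys}
            assert lemma_identities(H, h, labels)

    def test_idempotent_member(self):
        keys = [("d0", i) for i in range(5)]
        labels = dict(zip(keys, [1, 0, 1, 0, 0]))
        h = dict(zip(keys, [1, 1, 0, 0, 0]))
        assert lemma_identities([h], h, labels)

    def test_universe_mismatch_rejected(self):
        labels = {("d0", 0): 1}
        with pytest.raises(ValueError, match="universe"):
            lemma_identities([], {}, labels)


class TestBoundReport:
    def test_report_flags_and_values(self):
        counts = ConfusionCounts(tp=3, fp=6, tn=15, fn=2)
        params = GameParams(L=5, C=1, B=20)
        fsp = FiniteSampleParams(vc_dim=1, delta=0.05, m=10_000)
        rep = bound_report(counts, params, alpha=5 / 26, n=26, fsp=fsp)
        assert rep.preconditions_met["ranking_condition"]  # 45 >= 12
        assert rep.preconditions_met["surplus_budget"]     # 20 >= 9
        assert rep.preconditions_met["lambda_valid"]
        assert not rep.local_optimum                       # 2 < 5
        assert rep.tp_bound == pytest.approx(4.2)
        assert rep.ratio_bound == pytest.approx(22 / 6)
        assert rep.fs_tp_bound >= rep.tp_bound
        d = rep.to_dict()
        assert d["lambda"] == pytest.approx(lambda_bound(fsp))
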