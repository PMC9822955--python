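import math

import numpy as np
import pytest

from aotrunc import (
    compute_integrals,
    indicators_from_trace,
    load_basis,
    make_h2_dimer,
    propagate,
    scf_rhf,
)
from aotrunc.basis import AOFunctionLabel
from aotrunc.indicators import (
    DegenerateTraceError,
    complex_std,
    compute_O_series,
    compute_xDC,
    compute_xIP,
    export_map,
    jaccard,
    jaccard_curve,
    select_truncation,
)
from aotrunc.rtp import PulseSpec

RNG = np.random.default_rng(42)


def _labels(n):
    return [AOFunctionLabel(mu, mu, "H", 0, 1, 0) for mu in range(n)]


class TestComplexStd:
    def test_constant_is_zero(self):
        assert complex_std([3.0 + 1.0j] * 5) == 0.0

    def test_real_population_std(self):
        assert complex_std([1.0, 3.0]) == pytest.approx(1.0)

    def test_complex_pair(self):
        assert complex_std([1.0, 1.0j]) == pytest.approx(math.sqrt(0.5))

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            complex_std([])


class TestOSeries:
    def test_loop_oracle(self):
        n, T = 6, 4
        A = RNG.normal(size=(n, n))
        S = A @ A.T + n * np.eye(n)  # SPD
        P = RNG.normal(size=(T, n, n)) + 1j * RNG.normal(size=(T, n, n))
        P = P + np.conj(np.swapaxes(P, 1, 2))
        O = compute_O_series(P, S)
        for t in range(T):
            for m in range(n):
                ref = sum(P[t, m, nu] * S[nu, m] for nu in range(n))
                assert O[t, m] == pytest.approx(ref, abs=1e-13)

    def test_sums_to_electron_count(self, indicator_runs):
        run = indicator_runs["6-31G**"]
        O = compute_O_series(run["trace"], run["ints"].S)
        assert np.allclose(O.sum(axis=1).real, 4.0, atol=1e-8)
        assert np.abs(O.sum(axis=1).imag).max() < 1e-8

    def test_mirror_equivalent_atoms_match_at_t0(self, indicator_runs):
        run = indicator_runs["6-31G"]
        O0 = compute_O_series(run["trace"], run["ints"].S)[0]
        labels = run["labels"]
        # atoms 0/2 and 1/3 are mirror images through the yz plane
        for a, b in ((0, 2), (1, 3)):
            for la in labels:
                if la.atom != a:
                    continue
                lb = next(
                    l for l in labels
                    if l.atom == b and l.k == la.k and l.m_index == la.m_index
                    and l.l == la.l
                )
                assert abs(O0[la.mu] - O0[lb.mu]) < 1e-8


class TestIndicators:
    def test_unit_mean_normalization(self, indicator_runs):
        for run in indicator_runs.values():
            assert run["xdc"].mean() == pytest.approx(1.0, abs=1e-10)
            assert run["xip"].mean() == pytest.approx(1.0, abs=1e-10)

    def test_time_constant_contribution_scores_zero(self):
        T, n = 8, 3
        O = RNG.normal(size=(T, n)) + 0j
        O[:, 1] = 0.7  # constant in time
        x = compute_xDC(O)
        assert x[1] == pytest.approx(0.0, abs=1e-12)

    def test_xip_loop_oracle(self):
        T, n, nmo = 5, 4, 3
        C = RNG.normal(size=(T, n, nmo)) + 1j * RNG.normal(size=(T, n, nmo))
        x = compute_xIP(C)
        num = np.zeros(n)
        for m in range(n):
            for j in range(nmo):
                series = C[:, m, j]
                zbar = series.mean()
                num[m] += math.sqrt(np.mean(np.abs(series - zbar) ** 2))
        ref = num / num.mean()
        assert np.allclose(x, ref, atol=1e-12)

    def test_stationary_trace_is_degenerate(self, h2_631g_system):
        _, ints, scf = h2_631g_system
        tr = propagate(scf, ints, PulseSpec((0, 0, 0)), 10, 0.2)
        with pytest.raises(DegenerateTraceError):
            indicators_from_trace(tr, ints.S)

    def test_translation_invariance(self, indicator_runs):
        """Rigidly shifting the molecule by 10 Bohr must leave both
        indicators unchanged (the overlap-based contribution is the
        translation-invariant choice)."""
        run = indicator_runs["6-31G**"]
        geom = make_h2_dimer().translated([10.0, 0.0, 0.0])
        ints = compute_integrals(geom, load_basis("6-31G**"))
        scf = scf_rhf(geom, ints=ints)
        tr = propagate(scf, ints, PulseSpec.along("z", 1e-3), 100, 0.2)
        xdc, xip = indicators_from_trace(tr, ints.S)
        assert np.abs(xdc - run["xdc"]).max() < 1e-6
        assert np.abs(xip - run["xip"]).max() < 1e-6

    def test_trace_length_stability(self, indicator_runs):
        """1x and 10x the standard indicator-run length select the same
        deleted set."""
        run = indicator_runs["6-31G**"]
        long_tr = propagate(
            run["scf"], run["ints"], PulseSpec.along("z", 1e-3), 1000, 0.2
        )
        xdc_l, xip_l = indicators_from_trace(long_tr, run["ints"].S)
        short = select_truncation(run["xdc"], run["xip"], 0.1, run["labels"])
        long_ = select_truncation(xdc_l, xip_l, 0.1, run["labels"])
        assert short.deleted == long_.deleted


class TestSelection:
    def test_all_above_threshold_deletes_nothing(self):
        labels = _labels(4)
        rep = select_truncation(
            np.array([1.0, 2.0, 0.5, 0.9]), np.array([1.1, 0.4, 2.0, 0.8]),
            0.3, labels,
        )
        assert rep.deleted == set()
        assert rep.kept == set(labels)

    def test_tie_at_threshold_is_deleted(self):
        labels = _labels(2)
        rep = select_truncation(
            np.array([0.1, 0.5]), np.array([0.1, 0.5]), 0.1, labels
        )
        assert rep.deleted == {labels[0]}

    def test_joint_criterion(self):
        labels = _labels(3)
        # below on one indicator only -> kept
        rep = select_truncation(
            np.array([0.01, 0.5, 0.01]), np.array([0.5, 0.01, 0.01]),
            0.1, labels,
        )
        assert rep.deleted == {labels[2]}

    def test_shell_majority_rule_keeps_partial_shell(self):
        # one p shell: p_x, p_y kept, p_z deletable -> 2/3 majority keeps it
        labels = [AOFunctionLabel(m, 0, "H", 1, 1, m) for m in range(3)]
        rep = select_truncation(
            np.array([0.5, 0.5, 0.01]), np.array([0.5, 0.5, 0.01]),
            0.1, labels, level="shell",
        )
        assert rep.deleted == set()

    def test_shell_majority_rule_drops_shell(self):
        labels = [AOFunctionLabel(m, 0, "H", 1, 1, m) for m in range(3)]
        rep = select_truncation(
            np.array([0.01, 0.01, 0.5]), np.array([0.01, 0.01, 0.5]),
            0.1, labels, level="shell",
        )
        assert rep.deleted == set(labels)

    def test_guard_warns_on_strong_member(self):
        labels = [AOFunctionLabel(m, 0, "H", 1, 1, m) for m in range(3)]
        with pytest.warns(UserWarning, match="check before discarding"):
            select_truncation(
                np.array([0.01, 0.01, 0.5]), np.array([0.01, 0.01, 0.01]),
                0.1, labels, level="shell",
            )

    def test_monotonic_in_threshold(self, indicator_runs):
        run = indicator_runs["6-31++G**"]
        sizes = [
            select_truncation(
                run["xdc"], run["xip"], t, run["labels"]
            ).n_deleted
            for t in np.arange(0.02, 1.0, 0.02)
        ]
        assert all(b >= a for a, b in zip(sizes, sizes[1:]))


class TestJaccard:
    def test_identical_nonempty_sets(self):
        x = np.array([0.01, 0.02, 5.0])
        assert jaccard(x, x, 0.1) == 1.0

    def test_disjoint_sets(self):
        assert jaccard(
            np.array([0.01, 5.0]), np.array([5.0, 0.01]), 0.1
        ) == 0.0

    def test_empty_sets_define_zero(self):
        assert jaccard(np.array([1.0]), np.array([1.0]), 0.1) == 0.0

    def test_curve_shape(self):
        xdc = np.array([0.05, 2.0])
        xip = np.array([0.05, 2.0])
        J = jaccard_curve(xdc, xip, [0.01, 0.1, 1.0])
        assert list(J) == [0.0, 1.0, 1.0]


class TestMapExport:
    def test_product_rank_and_partition(self, indicator_runs):
        run = indicator_runs["6-31++G**"]
        rep = select_truncation(run["xdc"], run["xip"], 0.1, run["labels"])
        df = export_map(rep)
        assert len(df) == 24
        assert np.allclose(df["product"], df["xdc"] * df["xip"], atol=1e-12)
        assert sorted(df["rank_dc"]) == list(range(1, 25))
        # quadrants at x^thr = 0.1 partition all labels
        q_bl = (df["xdc"] < 0.1) & (df["xip"] < 0.1)
        q_tr = (df["xdc"] >= 0.1) & (df["xip"] >= 0.1)
        q_tl = (df["xdc"] < 0.1) & (df["xip"] >= 0.1)
        q_br = (df["xdc"] >= 0.1) & (df["xip"] < 0.1)
        assert int(q_bl.sum() + q_tr.sum() + q_tl.sum() + q_br.sum()) == 24
        assert (~df["kept"] == q_bl).all()
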