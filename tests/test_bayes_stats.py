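"""Bayes factors: t test vs quadrature oracle, model-space enumeration,
RM-ANOVA integrator consistency, labels, sequential design contracts."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from gazeshift import (chi_square_independence, evidence_label, inclusion_bf,
                       rm_anova_bf, sequential_design, simulate_ratio_table,
                       ttest_bf)
from gazeshift.bayes_stats import EFFECTS, MODEL_SPACE
from gazeshift.synthetic_data import SESSIONS, participant_stream

R = 1.0 / np.sqrt(2.0)


def jzs_oracle(a, b, paired=False, r=R):
    """Independent adaptive-quadrature oracle in effect-size space.

    Integrates the noncentral-t likelihood against the Cauchy prior on the
    standardized effect size — a different parameterization from the
    implementation's g-space integral.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if paired:
        d = a - b
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        nu, n_eff = len(d) - 1, float(len(d))
    else:
        n1, n2 = len(a), len(b)
        nu = n1 + n2 - 2
        sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / nu
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        n_eff = n1 * n2 / (n1 + n2)

    def integrand(delta):
        return stats.nct.pdf(t, nu, delta * np.sqrt(n_eff)) * stats.cauchy.pdf(
            delta, scale=r
        )

    num, _ = integrate.quad(integrand, -np.inf, np.inf, limit=400)
    return num / stats.t.pdf(t, nu)


def test_ttest_bf_matches_quadrature_oracle():
    """g-space and effect-size-space integrals agree to 1e-4 relative."""
    rng = np.random.default_rng(12345)
    for _ in range(100):
        n1, n2 = rng.integers(5, 40, size=2)
        shift = rng.normal(0, 1.5)
        a = rng.normal(0, 1, n1)
        b = rng.normal(shift, 1, n2)
        paired = False
        if rng.uniform() < 0.3:
            n = min(n1, n2)
            a, b, paired = a[:n], b[:n], True
        got = ttest_bf(a, b, paired=paired)
        want = jzs_oracle(a, b, paired=paired)
        assert got == pytest.approx(want, rel=1e-4)


def test_ttest_backends_agree():
    rng = np.random.default_rng(7)
    a, b = rng.normal(0, 1, 18), rng.normal(0.6, 1, 22)
    q = ttest_bf(a, b, method="quad")
    m = ttest_bf(a, b, method="mc", seed=0)
    assert m == pytest.approx(q, rel=1e-4)


def test_ttest_bf_matches_pingouin():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(3)
    a, b = rng.normal(0, 1, 15), rng.normal(0.8, 1, 15)
    t = stats.ttest_ind(a, b).statistic
    want = float(pingouin.bayesfactor_ttest(t, 15, 15, r=R))
    assert ttest_bf(a, b) == pytest.approx(want, rel=1e-6)


@pytest.mark.parametrize("n", [5, 10, 20, 50])
def test_null_data_favors_null(n):
    """t = 0: the point null predicts the data better than the diffuse prior."""
    base = np.linspace(-1, 1, n)
    assert ttest_bf(base + 5.0, base + 5.0, paired=False) < 1.0


def test_large_separation_extreme_evidence():
    base = np.linspace(-1, 1, 15)
    assert ttest_bf(base, base + 5.0 * base.std(ddof=1)) > 100.0


def test_ttest_bf_input_validation():
    with pytest.raises(ValueError, match="at least 3"):
        ttest_bf([1.0, 2.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError, match="zero variance"):
        ttest_bf([1.0, 2.0, 3.0], [0.0, 1.0, 2.0], paired=True)


# ---------------------------------------------------------------------------
# inclusion BF
# ---------------------------------------------------------------------------

def brute_force_inclusion(bf10, effect, scheme):
    """Posterior/prior odds by explicit enumeration over the model space."""
    def higher(m):
        return any(o != effect and effect in o.split(":") for o in m)

    if scheme == "matched":
        if ":" in effect:
            with_m = [m for m in bf10 if effect in m]
            without = [m - {effect} for m in with_m]
        else:
            with_m = [m for m in bf10 if effect in m and not higher(m)]
            without = [m for m in bf10 if effect not in m and not higher(m)]
    else:
        with_m = [m for m in bf10 if effect in m]
        without = [m for m in bf10 if effect not in m]
    post = sum(bf10[m] for m in with_m) / sum(bf10[m] for m in without)
    prior = len(with_m) / len(without)
    return post / prior


@pytest.mark.parametrize("scheme", ["matched", "all"])
@pytest.mark.parametrize("effect", EFFECTS)
def test_inclusion_matches_enumeration(effect, scheme):
    rng = np.random.default_rng(11)
    for _ in range(50):
        bf10 = {m: float(np.exp(rng.normal(0, 3))) for m in MODEL_SPACE}
        bf10[frozenset()] = 1.0
        got = inclusion_bf(bf10, effect, scheme=scheme)
        assert got == pytest.approx(brute_force_inclusion(bf10, effect, scheme),
                                    rel=1e-12)


def test_two_model_space_inclusion_is_bf10():
    bf10 = {frozenset(): 1.0, frozenset({"group"}): 7.3}
    assert inclusion_bf(bf10, "group") == pytest.approx(7.3)


def test_equal_evidence_gives_count_ratio():
    bf10 = {m: 1.0 for m in MODEL_SPACE}
    assert inclusion_bf(bf10, "group", scheme="matched") == pytest.approx(1.0)
    assert inclusion_bf(bf10, "group", scheme="all") == pytest.approx(1.0)


def test_unknown_effect_errors():
    with pytest.raises(ValueError, match="not present"):
        inclusion_bf({frozenset(): 1.0}, "group")


# ---------------------------------------------------------------------------
# chi-square and labels
# ---------------------------------------------------------------------------

def test_chi_square_hand_value():
    """9/6 vs 6/9 split: expected counts 7.5 give X^2 = 4 * (1.5^2/7.5)."""
    assert chi_square_independence([[9, 6], [6, 9]]) == pytest.approx(1.2)


def test_chi_square_perfect_independence():
    assert chi_square_independence([[5, 5], [5, 5]]) == 0.0


def test_chi_square_matches_formula_loop():
    rng = np.random.default_rng(0)
    for _ in range(20):
        obs = rng.integers(1, 30, size=(2, 2)).astype(float)
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        by_hand = ((obs - expected) ** 2 / expected).sum()
        assert chi_square_independence(obs) == pytest.approx(by_hand)


def test_chi_square_zero_margin_errors():
    with pytest.raises(ValueError, match="zero margin"):
        chi_square_independence([[0, 0], [3, 4]])


@pytest.mark.parametrize(
    "bf,label",
    [
        (1.0, "no evidence"),
        (2.0, "anecdotal"),
        (3.7, "substantial"),
        (15.0, "strong"),
        (50.0, "very strong"),
        (2.684e15, "extreme"),
        (1 / 3.7, "substantial"),  # same strength, opposite direction
        (1e-16, "extreme"),
    ],
)
def test_evidence_labels(bf, label):
    assert evidence_label(bf) == label


def test_evidence_label_rejects_nonpositive():
    with pytest.raises(ValueError):
        evidence_label(0.0)


@given(bf=st.floats(min_value=1e-300, max_value=1e300))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_label_total_and_direction_symmetric(bf):
    """Every positive BF gets a label, and BF and 1/BF get the same one."""
    assert evidence_label(bf) in {"no evidence", "anecdotal", "substantial",
                                  "strong", "very strong", "extreme"}
    assert evidence_label(bf) == evidence_label(1.0 / bf)


def test_label_order_preserving_in_log_magnitude():
    order = ["no evidence", "anecdotal", "substantial", "strong", "very strong",
             "extreme"]
    bfs = np.exp(np.linspace(0.0, 6.0, 60))
    ranks = [order.index(evidence_label(b)) for b in bfs]
    assert all(b >= a for a, b in zip(ranks, ranks[1:]))


# ---------------------------------------------------------------------------
# RM-ANOVA
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def cohort():
    return simulate_ratio_table(n_per_group=15, seed=42)


def test_rm_anova_session_effect_dominates(cohort):
    res = rm_anova_bf(cohort, seed=0)
    assert res.bf_inclusion["session"] > 100.0
    assert evidence_label(res.bf_inclusion["session"]) == "extreme"
    assert all(bf > 0 for bf in res.bf10_by_model.values())
    for e in EFFECTS:
        assert res.bf_exclusion[e] == pytest.approx(1 / res.bf_inclusion[e])


def test_rm_anova_deterministic(cohort):
    a = rm_anova_bf(cohort, seed=3)
    b = rm_anova_bf(cohort, seed=3)
    assert a.bf10_by_model == b.bf10_by_model


def test_rm_anova_mc_consistency(cohort):
    """Doubling the sample count moves each log-BF within the stated MC error."""
    a = rm_anova_bf(cohort, mc_samples=2000, seed=1)
    b = rm_anova_bf(cohort, mc_samples=4000, seed=2)
    for m in MODEL_SPACE:
        if not m:
            continue
        diff = abs(np.log(a.bf10_by_model[m]) - np.log(b.bf10_by_model[m]))
        budget = 3.0 * np.hypot(
            np.hypot(a.mc_error_by_model[m], a.mc_error_by_model[frozenset()]),
            np.hypot(b.mc_error_by_model[m], b.mc_error_by_model[frozenset()]),
        )
        assert diff < max(budget, 0.05)


def test_rm_anova_transitivity(cohort):
    """BF(A vs null)/BF(B vs null) equals BF(A vs B) within MC error."""
    res = rm_anova_bf(cohort, seed=4)
    s = frozenset({"session"})
    gs = frozenset({"group", "session"})
    ratio = res.bf10_by_model[gs] / res.bf10_by_model[s]
    direct = np.exp(res.log_marginals[gs] - res.log_marginals[s])
    assert ratio == pytest.approx(direct, rel=1e-9)


def test_rm_anova_rejects_bad_tables(cohort):
    flat = cohort.copy()
    flat["mean_ratio_pct"] = 5.0
    with pytest.raises(ValueError, match="identical"):
        rm_anova_bf(flat, seed=0)
    with pytest.raises(ValueError, match="incomplete"):
        rm_anova_bf(cohort.iloc[:-1], seed=0)
    one_group = cohort[cohort.group == "control"]
    with pytest.raises(ValueError, match="two groups"):
        rm_anova_bf(one_group, seed=0)


def test_null_evidence_grows_with_sample_size():
    """Under a null group effect, median BF01 for group increases with n."""
    medians = []
    for n in (10, 15, 20):
        bf01 = []
        for rep in range(20):
            tab = simulate_ratio_table(n_per_group=n, seed=5000 + rep)
            res = rm_anova_bf(tab, mc_samples=1000, seed=rep)
            bf01.append(1.0 / res.bf10_by_model[frozenset({"group"})])
        medians.append(float(np.median(bf01)))
    assert medians[0] < medians[1] < medians[2]


# ---------------------------------------------------------------------------
# sequential design
# ---------------------------------------------------------------------------

def test_sequential_infinite_threshold_never_stops():
    dec = sequential_design(participant_stream(seed=1), threshold=np.inf,
                            n_max=15, mc_samples=800, seed=0)
    assert not dec.stopped
    assert [n for n, _ in dec.rounds] == [10, 15]


def test_sequential_deterministic():
    a = sequential_design(participant_stream(seed=2), n_max=15,
                          mc_samples=800, seed=5)
    b = sequential_design(participant_stream(seed=2), n_max=15,
                          mc_samples=800, seed=5)
    assert a.stopped == b.stopped and a.stop_round == b.stop_round
    assert [n for n, _ in a.rounds] == [n for n, _ in b.rounds]
    for (_, ra), (_, rb) in zip(a.rounds, b.rounds):
        assert ra.bf10_by_model == rb.bf10_by_model


def test_sequential_exhausted_stream_errors():
    short = list(itertools.islice(participant_stream(seed=0), 6))
    with pytest.raises(ValueError, match="exhausted"):
        sequential_design(iter(short), n_initial=10, seed=0)


def test_sequential_rounds_grow_by_batch():
    dec = sequential_design(participant_stream(seed=3), threshold=np.inf,
                            n_initial=4, batch=3, n_max=10, mc_samples=600,
                            seed=1)
    assert [n for n, _ in dec.rounds] == [4, 7, 10]
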