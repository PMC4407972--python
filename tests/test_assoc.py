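"""Association-test battery: exhaustive permutation oracles, asymptotic
oracles, symmetry and degeneracy behavior."""

import itertools
from math import comb

import numpy as np
import pytest
from scipy import stats

from rvpower import assoc
from rvpower.architecture import DiseaseModel, LocusEffects, \
    default_architecture, sample_locus_effects
from rvpower.assoc import TEST_NAMES, TestSpec
from rvpower.cohort import CohortDataset, sample_cohort
from rvpower.errors import NoQualifyingVariantsError, ParameterError
from rvpower.fixtures import toy_cohort

SPEC = TestSpec(maf_threshold=0.2, n_permutations=2000,
                initial_permutations=2000)


# ---------------------------------------------------------------------------
# independent oracle implementations (straight loops, no shared code)
# ---------------------------------------------------------------------------

def _minor(ds):
    g = ds.genotypes.astype(float)
    flip = g.mean(axis=0) / 2 > 0.5
    g[:, flip] = 2 - g[:, flip]
    return g


def _rare(ds, thr):
    g = _minor(ds)
    maf = g.mean(axis=0) / 2
    return g[:, maf < thr]


def oracle_burden(g, cases):
    return sum(g[i].sum() for i in cases)


def oracle_uniq(g, cases, n):
    controls = [i for i in range(n) if i not in cases]
    total = 0.0
    for v in range(g.shape[1]):
        if sum(g[i, v] for i in controls) == 0:
            total += sum(g[i, v] for i in cases)
    return total


def oracle_frqwgt(g, cases, n):
    controls = [i for i in range(n) if i not in cases]
    nu = len(controls)
    stat = 0.0
    for v in range(g.shape[1]):
        mu = sum(g[i, v] for i in controls)
        q = (mu + 1) / (2 * nu + 2)
        w = 1.0 / np.sqrt(n * q * (1 - q))
        stat += w * sum(g[i, v] for i in cases)
    return stat


def oracle_calpha(g, cases, n):
    p0 = len(cases) / n
    stat = 0.0
    for v in range(g.shape[1]):
        yv = sum(g[i, v] for i in cases)
        nv = g[:, v].sum()
        stat += (yv - nv * p0) ** 2 - nv * p0 * (1 - p0)
    return stat


def oracle_vt(g, maf, cases, n):
    ybar = len(cases) / n
    best = -np.inf
    for thr in np.unique(maf):
        sel = maf <= thr
        s = g[:, sel].sum(axis=1)
        num = sum((1 - ybar) * s[i] for i in cases) \
            + sum((0 - ybar) * s[i] for i in range(n) if i not in cases)
        den = np.sqrt(((s - s.mean()) ** 2).sum())
        if den > 0:
            best = max(best, num / den)
    return best


def oracle_kbac(g, cases, n):
    n_case = len(cases)
    n_ctrl = n - n_case
    patterns = {}
    for i in range(n):
        key = tuple(g[i])
        if any(k > 0 for k in key):
            patterns.setdefault(key, []).append(i)
    stat = 0.0
    for members in patterns.values():
        ng = len(members)
        a = sum(1 for i in members if i in cases)
        w = stats.hypergeom.cdf(a, n, ng, n_case)
        stat += w * (a / n_case - (ng - a) / n_ctrl)
    return stat


ORACLES = {
    "BURDEN": lambda g, maf, cases, n: oracle_burden(g, cases),
    "UNIQ": lambda g, maf, cases, n: oracle_uniq(g, cases, n),
    "FRQWGT": lambda g, maf, cases, n: oracle_frqwgt(g, cases, n),
    "C-ALPHA": lambda g, maf, cases, n: oracle_calpha(g, cases, n),
    "VT": lambda g, maf, cases, n: oracle_vt(g, maf, cases, n),
    "KBAC": lambda g, maf, cases, n: oracle_kbac(g, cases, n),
}

PERM_TESTS = {
    "BURDEN": assoc.test_burden,
    "UNIQ": assoc.test_uniq,
    "FRQWGT": assoc.test_frqwgt,
    "C-ALPHA": assoc.test_calpha,
    "VT": assoc.test_vt,
    "KBAC": assoc.test_kbac,
}


@pytest.mark.parametrize("name", list(PERM_TESTS))
def test_permutation_tests_match_exhaustive_oracle(name, toy):
    """On an 8-individual cohort every permutation test must equal full
    enumeration over all C(8,4) case assignments."""
    res = PERM_TESTS[name](toy, SPEC, seed=0)
    assert res.diagnostics["exhaustive"]

    g = _rare(toy, SPEC.maf_threshold)
    maf = g.mean(axis=0) / 2
    n = 8
    obs = ORACLES[name](g, maf, (0, 1, 2, 3), n)
    vals = [ORACLES[name](g, maf, cases, n)
            for cases in itertools.combinations(range(n), 4)]
    p_oracle = np.mean([v >= obs - 1e-9 * max(1, abs(obs)) for v in vals])
    assert res.p_value == pytest.approx(p_oracle, abs=1e-12)
    assert res.statistic == pytest.approx(obs, rel=1e-9)


def test_fisher_matches_hypergeometric_tail_oracle(toy):
    """Two-sided Fisher's exact equals the minimum-likelihood tail sum over
    the hypergeometric support."""
    res = assoc.test_single_fisher(toy)
    case, ctrl = toy.minor_allele_counts()
    n_case, n_ctrl = toy.n_case, toy.n_control
    for v in range(toy.n_sites):
        a, u = int(case[v]), int(ctrl[v])
        total = a + u
        n1, n2 = 2 * n_case, 2 * n_ctrl
        support = range(max(0, total - n2), min(n1, total) + 1)
        probs = {k: stats.hypergeom.pmf(k, n1 + n2, total, n1)
                 for k in support}
        p_obs = probs[a]
        p_two = sum(pk for pk in probs.values() if pk <= p_obs * (1 + 1e-9))
        assert res.diagnostics["p_per_site"][v] == pytest.approx(
            min(p_two, 1.0), rel=1e-7)
    assert res.p_value == pytest.approx(
        min(res.diagnostics["p_per_site"]), rel=1e-12)


def test_fisher_balanced_table_p_one():
    geno = np.zeros((8, 1), np.uint8)
    geno[[0, 1, 4, 5], 0] = 1
    ds = CohortDataset(geno, np.array([1, 1, 1, 1, 0, 0, 0, 0]),
                       np.array([5]), np.array([True]),
                       np.zeros(1, bool))
    assert assoc.test_single_fisher(ds).p_value == pytest.approx(1.0)


def test_label_swap_symmetry(toy):
    """Two-sided tests report identical p after exchanging case and control
    labels (equal group sizes)."""
    swapped = CohortDataset(toy.genotypes.copy(), 1 - toy.phenotype,
                            toy.positions, toy.exonic, toy.causal_mask)
    # WILCOX-WSS is excluded: its weights are estimated from the control
    # group, which is itself exchanged by the swap.
    for fn in (assoc.test_cmc, assoc.test_calpha,
               assoc.test_skat, assoc.test_single_fisher):
        a = fn(toy, SPEC, seed=1) if fn is not assoc.test_single_fisher \
            else fn(toy)
        b = fn(swapped, SPEC, seed=1) if fn is not assoc.test_single_fisher \
            else fn(swapped)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-9)


def test_cmc_matches_g_test_oracle(toy):
    res = assoc.test_cmc(toy, SPEC)
    g = _rare(toy, SPEC.maf_threshold)
    carrier = (g.sum(axis=1) > 0).astype(int)
    table = np.array([[np.sum((carrier == c) & (toy.phenotype == y))
                       for y in (0, 1)] for c in (0, 1)])
    g2, p, _, _ = stats.chi2_contingency(table, correction=False,
                                         lambda_="log-likelihood")
    assert res.p_value == pytest.approx(p, rel=1e-9)
    assert res.statistic == pytest.approx(g2, rel=1e-9)


def test_cmc_degenerate_predictor_p_one():
    # three rare sites jointly cover every individual: carrier status is
    # constant, so the collapsed predictor carries no information
    geno = np.zeros((6, 3), np.uint8)
    geno[[0, 1], 0] = 1
    geno[[2, 3], 1] = 1
    geno[[4, 5], 2] = 1
    ds = CohortDataset(geno, np.array([1, 1, 1, 0, 0, 0]),
                       np.array([3, 9, 15]), np.ones(3, bool),
                       np.zeros(3, bool))
    res = assoc.test_cmc(ds, TestSpec(maf_threshold=0.4))
    assert res.p_value == 1.0


def test_wss_identical_scores_p_one():
    geno = np.zeros((8, 2), np.uint8)
    geno[:, 0] = 1  # same dosage for everyone at both sites
    geno[:, 1] = 1
    geno[0, 1] = 0  # keep columns polymorphic
    geno[0, 0] = 0
    ds = CohortDataset(geno, np.array([1, 1, 1, 1, 0, 0, 0, 0]),
                       np.array([5, 9]), np.ones(2, bool),
                       np.zeros(2, bool))
    # individual 0 differs; drop it from scoring by filtering to a
    # genuinely constant configuration instead
    geno2 = np.tile([[1, 0]], (8, 1)).astype(np.uint8)
    geno2[4:, 0] = 0
    geno2[4:, 1] = 1
    ds2 = CohortDataset(geno2, np.array([1, 0, 1, 0, 1, 0, 1, 0]),
                        np.arange(2) * 7 + 3, np.ones(2, bool),
                        np.zeros(2, bool))
    res = assoc.test_wss(ds2, TestSpec(maf_threshold=0.5))
    # scores are equal iff the control-estimated weights coincide; here the
    # two sites have equal control frequency, so all scores tie
    assert res.p_value == 1.0


def test_wss_matches_exact_rank_sum_on_tie_free_scores():
    rng = np.random.default_rng(8)
    geno = rng.binomial(1, 0.3, size=(12, 5)).astype(np.uint8)
    geno = geno[:, (geno.sum(0) > 0) & (geno.sum(0) < 12)]
    ds = CohortDataset(geno, np.r_[np.ones(6, int), np.zeros(6, int)],
                       np.arange(geno.shape[1]) * 11 + 2,
                       np.ones(geno.shape[1], bool),
                       np.zeros(geno.shape[1], bool))
    res = assoc.test_wss(ds, TestSpec(maf_threshold=0.5))
    g = _rare(ds, 0.5)
    nu = 6
    q = (g[6:].sum(axis=0) + 1) / (2 * nu + 2)
    w = 1 / np.sqrt(12 * q * (1 - q))
    scores = g @ w
    exact = stats.mannwhitneyu(scores[:6], scores[6:],
                               alternative="two-sided", method="exact")
    assert res.p_value == pytest.approx(exact.pvalue, abs=0.05)


def test_vt_max_over_thresholds_dominates_any_fixed_threshold(toy):
    res = assoc.test_vt(toy, SPEC, seed=0)
    g = _rare(toy, SPEC.maf_threshold)
    maf = g.mean(axis=0) / 2
    y = toy.phenotype.astype(float)
    for thr in np.unique(maf):
        s = g[:, maf <= thr].sum(axis=1)
        den = np.sqrt(((s - s.mean()) ** 2).sum())
        if den > 0:
            z = float((y - y.mean()) @ s) / den
            assert res.statistic >= z - 1e-12


def test_kbac_case_private_pattern_attains_minimum_p():
    geno = np.zeros((8, 1), np.uint8)
    geno[:4, 0] = 1  # one pattern, carried by exactly the four cases
    ds = CohortDataset(geno, np.array([1, 1, 1, 1, 0, 0, 0, 0]),
                       np.array([5]), np.array([True]), np.zeros(1, bool))
    res = assoc.test_kbac(ds, TestSpec(maf_threshold=0.5), seed=0)
    assert res.p_value == pytest.approx(1 / comb(8, 4))


def test_calpha_is_bidirectional():
    """Both a case-skewed and a control-skewed site inflate the statistic
    relative to balanced sites."""
    def stat_of(cols):
        geno = np.zeros((8, len(cols)), np.uint8)
        for j, carriers in enumerate(cols):
            geno[list(carriers), j] = 1
        ds = CohortDataset(geno, np.array([1, 1, 1, 1, 0, 0, 0, 0]),
                           np.arange(len(cols)) * 10 + 1,
                           np.ones(len(cols), bool),
                           np.zeros(len(cols), bool))
        return assoc.test_calpha(ds, TestSpec(maf_threshold=0.5),
                                 seed=0).statistic

    balanced = stat_of([(0, 4), (1, 5)])
    case_skew = stat_of([(0, 1), (1, 5)])
    ctrl_skew = stat_of([(4, 5), (1, 5)])
    assert case_skew > balanced
    assert ctrl_skew > balanced


def test_skat_flat_weights_orders_like_calpha(toy):
    """With flat weights the SKAT statistic differs from the C-alpha
    statistic by a constant over label permutations, so their orderings
    across the 70 assignments coincide."""
    g = _rare(toy, 0.2)
    maf = g.mean(axis=0) / 2
    n = 8
    skat_vals, ca_vals = [], []
    centered = g - g.mean(axis=0, keepdims=True)
    for cases in itertools.combinations(range(n), 4):
        y = np.zeros(n)
        y[list(cases)] = 1
        v = y - y.mean()
        skat_vals.append(float(((centered.T @ v) ** 2).sum()))
        ca_vals.append(oracle_calpha(g, cases, n))
    diff = np.asarray(skat_vals) - np.asarray(ca_vals)
    assert np.allclose(diff, diff[0], atol=1e-9)
    assert np.array_equal(np.argsort(skat_vals), np.argsort(ca_vals))


def test_skat_zero_phenotype_variance_errors(toy):
    ds = CohortDataset(toy.genotypes, np.ones(8, int), toy.positions,
                       toy.exonic, toy.causal_mask)
    with pytest.raises(ParameterError):
        assoc.test_skat(ds, SPEC)


def test_skat_numeric_tail_matches_permutation(midi_panel):
    """The moment-adjusted chi-square-mixture p agrees with the permutation
    p within Monte-Carlo error scale (B = 2000)."""
    spec = TestSpec(n_permutations=4000, initial_permutations=4000)
    for s in range(3):
        eff = sample_locus_effects(midi_panel, default_architecture("ar2"),
                                   0.01, seed=40 + s)
        ds = sample_cohort(midi_panel, eff, n_case=250, n_control=250,
                           seed=50 + s)
        B, v, sigma2, idx = assoc._skat_parts(ds, spec)

        def statfn(Y):
            V = Y - Y.mean(axis=0, keepdims=True)
            U = B.T @ V
            return (U * U).sum(axis=0)

        y = ds.phenotype.astype(float)
        obs = float(statfn(y[:, None])[0])
        p_perm, _, _ = assoc._perm_pvalue(statfn, obs, y,
                                          np.random.default_rng(s), spec)
        p_num = assoc.test_skat(ds, spec).p_value
        # tolerance covers Monte-Carlo noise at B = 4000 plus the residual
        # higher-moment error of the moment-matched mixture tail
        assert p_num == pytest.approx(p_perm, abs=0.04)


def test_skato_degenerate_grids(midi_panel):
    eff = sample_locus_effects(midi_panel, default_architecture("ar2"),
                               0.01, seed=7)
    ds = sample_cohort(midi_panel, eff, n_case=200, n_control=200, seed=8)
    p_skat = assoc.test_skat(ds, TestSpec()).p_value
    p_o0 = assoc.test_skato(ds, TestSpec(rho_grid=(0.0,))).p_value
    assert p_o0 == pytest.approx(p_skat, rel=1e-9)

    res1 = assoc.test_skato(ds, TestSpec(rho_grid=(1.0,)))
    # rho = 1 is the squared weighted-burden score; its p is the two-sided
    # z-test of the burden component
    B, v, sigma2, _ = assoc._skat_parts(ds, TestSpec())
    s = B.sum(axis=1)
    z = float(s @ v) / np.sqrt(sigma2 * float(s @ s))
    assert res1.p_value == pytest.approx(2 * stats.norm.sf(abs(z)), rel=0.05)


def test_skato_bounded_by_min_p_and_bonferroni(midi_panel):
    for s in range(4):
        eff = sample_locus_effects(midi_panel, default_architecture("ar6"),
                                   0.01, seed=60 + s)
        ds = sample_cohort(midi_panel, eff, n_case=200, n_control=200,
                           seed=70 + s)
        res = assoc.test_skato(ds, SPEC)
        t_min = res.diagnostics["min_p"]
        assert t_min <= res.p_value <= min(1.0, len(SPEC.rho_grid) * t_min)


def test_mist_stage_separation(midi_panel):
    """A unidirectional locus loads on the burden stage; a balanced
    bidirectional locus loads on the heterogeneity stage."""
    eff = sample_locus_effects(midi_panel, default_architecture("ar5"),
                               0.02, seed=3)
    ds = sample_cohort(midi_panel, eff, n_case=500, n_control=500, seed=4)
    res = assoc.test_mist(ds, TestSpec())
    assert res.diagnostics["p_burden"] < 0.2

    rng = np.random.default_rng(0)
    n = 600
    geno = np.zeros((n, 8), np.uint8)
    y = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
    for j in range(8):
        # alternate: case-enriched and control-enriched sites, same sizes
        target = np.flatnonzero(y == (j % 2))
        geno[rng.choice(target, 9, replace=False), j] = 1
        other = np.flatnonzero(y != (j % 2))
        geno[rng.choice(other, 2, replace=False), j] = 1
    ds2 = CohortDataset(geno, y, np.arange(8) * 30 + 7, np.ones(8, bool),
                        np.zeros(8, bool))
    res2 = assoc.test_mist(ds2, TestSpec())
    assert res2.diagnostics["p_heterogeneity"] < res2.diagnostics["p_burden"]


def test_mist_null_fisher_statistic_distribution(midi_panel):
    """Under the null the two stage p-values are independent, so the Fisher
    combination follows chi-square with 4 df (KS check, reduced scale)."""
    stats_f = []
    null_eff = LocusEffects([], [], [], 0.0, 0.0)
    for s in range(150):
        ds = sample_cohort(midi_panel, null_eff, n_case=150, n_control=150,
                           seed=9000 + s)
        res = assoc.test_mist(ds, TestSpec())
        stats_f.append(res.statistic)
    _, p = stats.kstest(stats_f, stats.chi2(4).cdf)
    assert p > 0.001


def test_maf_filter_strict_and_permissive(toy):
    maf = toy.maf
    thr = float(np.sort(np.unique(maf))[1])
    kept = assoc.maf_filter(toy, thr)
    assert np.all(maf[kept] < thr)
    assert not np.any(maf[kept] == thr)
    assert assoc.maf_filter(toy, 0.5).size == toy.n_sites


def test_no_qualifying_variants_error(toy):
    with pytest.raises(NoQualifyingVariantsError):
        assoc.test_burden(toy, TestSpec(maf_threshold=1e-6), seed=0)


def test_adaptive_escalation():
    rng = np.random.default_rng(1)
    n = 60
    geno = rng.binomial(1, 0.1, size=(n, 6)).astype(np.uint8)
    y = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
    geno[y == 1, 0] = 1  # overwhelming case burden
    geno[y == 0, 0] = 0
    geno = geno[:, (geno.sum(0) > 0) & (geno.sum(0) < n)]
    ds = CohortDataset(geno, y, np.arange(geno.shape[1]) * 13 + 1,
                       np.ones(geno.shape[1], bool),
                       np.zeros(geno.shape[1], bool))
    spec = TestSpec(maf_threshold=0.5, n_permutations=20_000,
                    initial_permutations=500)
    res = assoc.test_burden(ds, spec, seed=0)
    assert not res.diagnostics["exhaustive"]
    assert res.diagnostics["permutations"] == 20_000
    assert res.p_value <= 10 / 500


def test_battery_rows_reproducible_and_match_individual_calls(toy):
    rows_a = assoc.run_test_battery(toy, SPEC, seed=11)
    rows_b = assoc.run_test_battery(toy, SPEC, seed=11)
    assert len(rows_a) == len(TEST_NAMES)
    for a, b in zip(rows_a, rows_b):
        assert a.test == b.test and a.p_value == b.p_value

    children = np.random.SeedSequence(11).spawn(len(TEST_NAMES))
    for name, child, row in zip(TEST_NAMES, children, rows_a):
        seed = int(child.generate_state(1)[0] % (2**31 - 1))
        solo = assoc.run_test(name, toy, SPEC, seed=seed)
        assert solo.p_value == row.p_value


def test_battery_records_errors_as_missing_rows():
    geno = np.tile([[1], [1], [0], [0]], (2, 1)).astype(np.uint8)
    ds = CohortDataset(geno, np.array([1, 1, 1, 1, 0, 0, 0, 0]),
                       np.array([5]), np.array([True]), np.zeros(1, bool))
    rows = assoc.run_test_battery(ds, TestSpec(maf_threshold=1e-4), seed=0)
    by_name = {r.test: r for r in rows}
    assert np.isnan(by_name["BURDEN"].p_value)
    assert "NoQualifyingVariants" in by_name["BURDEN"].diagnostics["error"]
    assert by_name["SINGLE-FISHER"].p_value > 0  # no MAF filter applied
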