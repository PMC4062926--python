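"""Differential expression, QC outlier flagging, and the concordance rule."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from netprio import concordance, de_anova, pca_outliers
from netprio.expression import DEStudyResult
from netprio.netio import ExpressionStudy
from netprio.synthetic import SyntheticTruth, generate_expression


def make_study(values, n_case, n_control, name="s", covariates=None):
    values = np.asarray(values, dtype=float)
    samples = [f"x{i}" for i in range(n_case + n_control)]
    groups = pd.Series(["case"] * n_case + ["control"] * n_control, index=samples)
    genes = [f"G{i:03d}" for i in range(values.shape[0])]
    cov = None
    if covariates is not None:
        cov = pd.DataFrame(covariates, index=samples)
    return ExpressionStudy(name, genes, samples, values, groups, cov)


def test_identical_groups_give_f_zero_p_one():
    study = make_study(np.ones((3, 8)), 4, 4)
    res = de_anova(study, ("case", "control"))
    assert (res.table["F"] == 0).all()
    assert (res.table["p"] == 1).all()
    assert not res.table["significant"].any()


def test_f_equals_t_squared_for_two_equal_groups():
    rng = np.random.default_rng(0)
    study = make_study(rng.normal(size=(200, 24)), 12, 12)
    res = de_anova(study, ("case", "control"))
    a = study.values[:, :12]
    b = study.values[:, 12:]
    t, p_t = stats.ttest_ind(a, b, axis=1)
    np.testing.assert_allclose(res.table["F"], t**2, rtol=1e-9)
    np.testing.assert_allclose(res.table["p"], p_t, rtol=1e-9)


def test_direction_follows_case_minus_control_mean():
    vals = np.zeros((2, 8))
    vals[0, :4] = 2.0   # up in cases
    vals[1, 4:] = 2.0   # down in cases
    vals += np.random.default_rng(1).normal(0, 0.01, size=vals.shape)
    res = de_anova(make_study(vals, 4, 4), ("case", "control"))
    assert res.table.iloc[0]["direction"] == "up"
    assert res.table.iloc[1]["direction"] == "down"
    assert res.table["significant"].all()


def test_planted_genes_recovered_with_direction():
    """effect 2, noise 1, n=20/20: planted genes flagged with planted direction."""
    genes = [f"G{i:04d}" for i in range(300)]
    module = set(genes[:80])
    truth = SyntheticTruth(module_genes=module, seed_genes=module)
    (study,) = generate_expression(genes, [(20, 20)], 2.0, 1.0, truth, rng_seed=3)
    res = de_anova(study, ("case", "control"))
    up, down = truth.de_genes_per_contrast["C1"]
    hits = 0
    for g in sorted(module):
        row = res.table.loc[g]
        if row["significant"] and row["direction"] == ("up" if g in up else "down"):
            hits += 1
    assert hits / len(module) > 0.99


def test_covariate_residualisation_removes_batch_shift():
    rng = np.random.default_rng(4)
    vals = rng.normal(size=(100, 20))
    # batch confound: second half of each group shifted by +5
    batch = (["b1"] * 5 + ["b2"] * 5) * 2
    vals[:, np.array(batch) == "b2"] += 5.0
    study = make_study(vals, 10, 10, covariates={"batch": batch})
    raw = de_anova(study, ("case", "control"), use_covariates=False)
    adj = de_anova(study, ("case", "control"), use_covariates=True)
    # residualisation must not inflate false positives
    assert adj.table["significant"].mean() <= max(raw.table["significant"].mean(), 0.1)
    ks = stats.kstest(adj.table["p"], "uniform")
    assert ks.pvalue > 0.01


def test_group_too_small_is_error():
    study = make_study(np.zeros((2, 3)), 1, 2)
    with pytest.raises(ValueError, match=">=2 samples"):
        de_anova(study, ("case", "control"))


# --- QC outliers ------------------------------------------------------------

def test_identical_samples_flag_nothing():
    study = make_study(np.ones((10, 6)), 3, 3)
    assert pca_outliers(study) == []


def test_shifted_sample_is_flagged():
    rng = np.random.default_rng(5)
    vals = rng.normal(0, 1.0, size=(200, 12))
    vals[:, 0] += 10.0  # one sample shifted by 10 x noise_sd on all genes
    study = make_study(vals, 6, 6)
    assert pca_outliers(study) == ["x0"]


def test_infinite_threshold_flags_nothing():
    rng = np.random.default_rng(6)
    vals = rng.normal(size=(50, 10))
    vals[:, 0] += 50.0
    study = make_study(vals, 5, 5)
    assert pca_outliers(study, k_sd=math.inf) == []


# --- concordance ------------------------------------------------------------

def _result(name, flags):
    """flags: gene -> (p, direction)"""
    genes = sorted(flags)
    table = pd.DataFrame(
        {
            "F": 1.0,
            "p": [flags[g][0] for g in genes],
            "direction": [flags[g][1] for g in genes],
            "significant": [flags[g][0] <= 0.05 for g in genes],
        },
        index=pd.Index(genes, name="gene"),
    )
    return DEStudyResult(study=name, comparison=("case", "control"), table=table)


def test_three_of_five_rule():
    results = [
        _result(f"s{i}", {"A": (0.01 if i < 3 else 0.5, "up"),
                          "B": (0.01, "up" if i < 2 else "down")})
        for i in range(5)
    ]
    conc = concordance(results, min_support=3)
    assert conc.up == ["A"]          # up in exactly 3 of 5
    assert "B" not in conc.up        # up in 2, down in 3 -> down list
    assert conc.down == ["B"]


def test_mixed_direction_below_support_excluded():
    # up in 2, down in 1, min_support 3 -> nowhere
    results = [
        _result("s0", {"A": (0.01, "up")}),
        _result("s1", {"A": (0.01, "up")}),
        _result("s2", {"A": (0.01, "down")}),
        _result("s3", {"A": (0.5, "up")}),
        _result("s4", {"A": (0.5, "up")}),
    ]
    conc = concordance(results, min_support=3)
    assert conc.up == [] and conc.down == []


def test_both_comparisons_rule():
    results = [_result("s0", {"A": (0.01, "up")}), _result("s1", {"A": (0.02, "up")})]
    conc = concordance(results, min_support=2)
    assert conc.up == ["A"]


def test_conflicting_gene_excluded_and_logged():
    # significant up in 1 comparison, down in another; min_support 1
    results = [_result("s0", {"A": (0.01, "up")}), _result("s1", {"A": (0.01, "down")})]
    conc = concordance(results, min_support=1)
    assert conc.conflicting == ["A"]
    assert conc.up == [] and conc.down == []


def test_raising_min_support_never_grows_support():
    """Directional support (including genes excluded as conflicting) shrinks
    as min_support rises; the plain up/down lists alone are not monotone
    because a gene can leave the conflict state when one direction drops
    below the threshold."""
    rng = np.random.default_rng(7)
    genes = [f"G{i:02d}" for i in range(60)]
    results = [
        _result(
            f"s{j}",
            {g: (float(rng.uniform(0, 0.2)), str(rng.choice(["up", "down"]))) for g in genes},
        )
        for j in range(5)
    ]
    sizes = []
    for m in range(1, 6):
        conc = concordance(results, min_support=m)
        sizes.append((set(conc.up) | set(conc.conflicting),
                      set(conc.down) | set(conc.conflicting)))
    for (u1, d1), (u2, d2) in zip(sizes, sizes[1:]):
        assert u2 <= u1 and d2 <= d1


def test_null_pass_rate_bounded():
    """Global null: pass rate at m of n with per-test alpha stays within the
    binomial bound C(n,m) * (alpha/2)^m per direction (3 SE slack)."""
    genes = [f"G{i:04d}" for i in range(2000)]
    truth = SyntheticTruth()
    studies = generate_expression(genes, [(10, 10)] * 3, 0.0, 1.0, truth, rng_seed=8)
    results = [de_anova(s, ("case", "control")) for s in studies]
    conc = concordance(results, min_support=2)
    rate = (len(conc.up) + len(conc.down)) / len(genes)
    bound = 2 * math.comb(3, 2) * (0.05 / 2) ** 2
    se = math.sqrt(bound * (1 - bound) / len(genes))
    assert rate <= bound + 3 * se


def test_empty_results_rejected():
    with pytest.raises(ValueError):
        concordance([])
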