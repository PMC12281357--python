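"""Percentile subsets, the moderated per-CpG model, DMP calling,
cross-subset consistency and feature-class enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from resilio.dataset import MethylationDataset
from resilio.dmp import (DEFAULT_STEPS, call_dmps, consistency_scan,
                         feature_enrichment, fit_dmp_model, make_subsets,
                         subset_label)
from resilio.preprocessing import beta_to_m, m_to_beta


def _samples_frame(scores_low, scores_high):
    rows = []
    for i, s in enumerate(scores_low):
        rows.append({"sample_id": f"lo{i:03d}", "cdrisc_score": s,
                     "resilience_group": "low"})
    for i, s in enumerate(scores_high):
        rows.append({"sample_id": f"hi{i:03d}", "cdrisc_score": s,
                     "resilience_group": "high"})
    df = pd.DataFrame(rows)
    return df.set_index("sample_id", drop=False).rename_axis(None)


# -- subsets ----------------------------------------------------------------

def test_full_subset_is_identity():
    sam = _samples_frame(range(32, 66), range(77, 101))
    subs = make_subsets(sam, steps=[1.0])
    assert len(subs[0].low_ids) == 34 and len(subs[0].high_ids) == 24
    assert set(subs[0].low_ids) == set(sam.index[sam.resilience_group == "low"])


def test_subsets_match_sorted_selection_oracle():
    rng = np.random.default_rng(11)
    scores_low = rng.uniform(32, 65, 41).round(1)
    scores_high = rng.uniform(77, 100, 83).round(1)
    sam = _samples_frame(scores_low, scores_high)
    subs = make_subsets(sam)
    for sub in subs:
        n_low = math.ceil(sub.q * len(scores_low))
        n_high = math.ceil(sub.q * len(scores_high))
        low = sam[sam.resilience_group == "low"]
        expect_low = low.sort_values(["cdrisc_score", "sample_id"]).head(n_low)
        high = sam[sam.resilience_group == "high"]
        expect_high = high.sort_values(
            ["cdrisc_score", "sample_id"], ascending=[False, True]).head(n_high)
        assert sub.low_ids == expect_low["sample_id"].tolist()
        assert sub.high_ids == expect_high["sample_id"].tolist()


def test_subset_nesting():
    rng = np.random.default_rng(3)
    sam = _samples_frame(rng.uniform(32, 65, 60), rng.uniform(77, 100, 60))
    subs = make_subsets(sam)
    for a, b in zip(subs[:-1], subs[1:]):  # b is more distal than a
        assert set(b.low_ids) <= set(a.low_ids)
        assert set(b.high_ids) <= set(a.high_ids)


def test_tiny_subsets_excluded_with_warning():
    sam = _samples_frame(range(32, 38), range(90, 96))
    with pytest.warns(UserWarning, match="excluded"):
        subs = make_subsets(sam, steps=[1.0, 0.1])
    assert [s.label for s in subs] == ["100%"]


# -- moderated model --------------------------------------------------------

def _flat_dataset(m_matrix, samples):
    probes = [f"cg{i:03d}" for i in range(m_matrix.shape[0])]
    beta = m_to_beta(pd.DataFrame(m_matrix, index=probes,
                                  columns=samples.index))
    manifest = pd.DataFrame({
        "probe_id": probes, "chrom": "chr1",
        "pos": np.arange(1, len(probes) + 1) * 1000,
        "gene": "", "feature_class": "opensea",
        "snp_flag": False, "multihit_flag": False, "sex_chrom_flag": False,
    }, index=probes)
    return MethylationDataset(beta=beta, manifest=manifest, samples=samples)


def test_no_covariate_fit_equals_closed_form_group_difference():
    """With no covariates, the group coefficient is mean(M_low) - mean(M_high)."""
    rng = np.random.default_rng(1)
    sam = _samples_frame([35, 40, 45], [85, 90, 95])
    M = rng.normal(0, 1, size=(20, 6))
    ds = _flat_dataset(M, sam)
    fits = fit_dmp_model(ds, sam.index[:3].tolist(), sam.index[3:].tolist(),
                         covariates=())
    m = beta_to_m(ds.beta)
    expected = m.iloc[:, :3].mean(axis=1) - m.iloc[:, 3:].mean(axis=1)
    np.testing.assert_allclose(fits["coef"], expected, atol=1e-12)


def test_infinite_prior_df_gives_common_variance_t():
    rng = np.random.default_rng(2)
    sam = _samples_frame(range(32, 42), range(85, 95))
    M = rng.normal(0, 1, size=(200, 20))
    ds = _flat_dataset(M, sam)
    low, high = sam.index[:10].tolist(), sam.index[10:].tolist()
    fits = fit_dmp_model(ds, low, high, covariates=(), prior_df=np.inf)
    s0 = math.sqrt(fits.attrs["s0_sq"])
    se = fits.attrs["se_unscaled"]
    np.testing.assert_allclose(fits["t"], fits["coef"] / (s0 * se), atol=1e-12)
    assert np.allclose(fits["s2_post"], fits.attrs["s0_sq"])


def test_moderated_variance_between_s2_and_prior(spiked_filtered):
    filtered, _, _ = spiked_filtered
    sam = filtered.samples
    low = sam.index[sam.resilience_group == "low"][:40].tolist()
    high = sam.index[sam.resilience_group == "high"][:40].tolist()
    fits = fit_dmp_model(filtered, low, high)
    s0 = fits.attrs["s0_sq"]
    lo = np.minimum(fits["s2"], s0) - 1e-12
    hi = np.maximum(fits["s2"], s0) + 1e-12
    assert ((fits["s2_post"] >= lo) & (fits["s2_post"] <= hi)).all()


def test_rank_deficient_covariate_dropped():
    rng = np.random.default_rng(4)
    sam = _samples_frame([35, 40, 45, 50], [85, 88, 90, 95])
    sam["er"] = "pos"  # constant within the subset
    sam["age"] = [50, 60, 55, 62, 48, 59, 61, 66]
    ds = _flat_dataset(rng.normal(0, 1, (10, 8)), sam)
    fits = fit_dmp_model(ds, sam.index[:4].tolist(), sam.index[4:].tolist(),
                         covariates=("age", "er"))
    assert "er" in fits.attrs["dropped_covariates"]


def test_null_pvalues_uniform_small():
    rng = np.random.default_rng(8)
    sam = _samples_frame(rng.uniform(32, 65, 30), rng.uniform(77, 100, 30))
    ds = _flat_dataset(rng.normal(0, 0.7, size=(2000, 60)), sam)
    low = sam.index[sam.resilience_group == "low"].tolist()
    high = sam.index[sam.resilience_group == "high"].tolist()
    fits = fit_dmp_model(ds, low, high, covariates=())
    assert stats.kstest(fits["p_value"], "uniform").pvalue > 0.01


# -- DMP calling ------------------------------------------------------------

@pytest.mark.parametrize("p,lfc,expected", [
    (0.04, 0.6, True),   # passes both gates (hyper)
    (0.04, 0.3, False),  # fails the fold-change gate
    (0.06, 2.0, False),  # fails the p gate
])
def test_dmp_gates(p, lfc, expected):
    fits = pd.DataFrame({"coef": [lfc], "p_value": [p]}, index=["cgX"])
    called = call_dmps(fits)
    assert bool(called["dmp"].iloc[0]) is expected
    if expected:
        assert called["direction"].iloc[0] == "hyper"


# -- consistency ------------------------------------------------------------

def _fake_results(hit_labels, coefs_by_label, subsets):
    out = {}
    for sub in subsets:
        lb = sub.label
        out[lb] = pd.DataFrame({
            "coef": [coefs_by_label[lb]],
            "p_value": [0.01],
            "dmp": [lb in hit_labels],
        }, index=["cg0"])
    return out


def _dummy_subsets():
    rng = np.random.default_rng(0)
    sam = _samples_frame(rng.uniform(32, 65, 60), rng.uniform(77, 100, 60))
    return make_subsets(sam)


@pytest.mark.parametrize("hits,n_expected,run_expected", [
    ({"60%", "50%", "40%"}, 3, 3),
    ({"90%", "40%", "10%"}, 3, 1),
])
def test_consistency_counting(hits, n_expected, run_expected):
    subsets = _dummy_subsets()
    coefs = {s.label: 0.1 for s in subsets}
    res = _fake_results(hits, coefs, subsets)
    cons = consistency_scan(res, subsets)
    assert cons.loc["cg0", "n_hits"] == n_expected
    assert cons.loc["cg0", "max_consecutive_run"] == run_expected


def test_dose_response_stat_is_one_for_monotone_coefficients():
    subsets = _dummy_subsets()
    diffs = np.array([s.score_diff for s in subsets])
    coefs = {s.label: 0.01 * s.score_diff for s in subsets}
    assert (np.diff(diffs) > 0).all()
    res = _fake_results(set(), coefs, subsets)
    cons = consistency_scan(res, subsets)
    assert np.isclose(cons.loc["cg0", "dose_response_stat"], 1.0)


def test_spiked_probes_show_dose_response(spiked_filtered):
    filtered, truth, _ = spiked_filtered
    subsets = make_subsets(filtered.samples)
    called = {
        s.label: call_dmps(fit_dmp_model(filtered, s.low_ids, s.high_ids))
        for s in subsets
    }
    cons = consistency_scan(called, subsets)
    spiked = [p for p in truth.all_spiked_probe_ids if p in cons.index]
    hyper = [p for p in truth.spiked_probes["SPIKE00"] if p in cons.index]
    assert cons.loc[hyper, "dose_response_stat"].median() > 0.8
    assert cons.loc[spiked, "n_hits"].median() >= 5


# -- enrichment -------------------------------------------------------------

def test_enrichment_extreme_and_null(spiked_filtered):
    filtered, _, _ = spiked_filtered
    mf = filtered.manifest
    promoters = mf.index[mf.feature_class == "promoter"][:50]
    enr = feature_enrichment(promoters, mf)
    assert enr.loc["promoter", "p_value"] < 1e-10
    assert enr.loc["promoter", "direction"] == "over"
    rng = np.random.default_rng(6)
    random_set = rng.choice(mf.index, size=200, replace=False)
    enr0 = feature_enrichment(random_set, mf)
    assert enr0["significant"].sum() <= 2  # ~nominal false-positive rate
    with pytest.raises(ValueError):
        feature_enrichment([], mf)
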