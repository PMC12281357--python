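"""QC filter cascade, beta<->M transforms, batch standardisation,
deconvolution and the PCA-covariate scan."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from resilio.dataset import MethylationDataset
from resilio.preprocessing import (adjust_batch, beta_to_m, deconvolve_cells,
                                   filter_probes, m_to_beta,
                                   pca_covariate_scan)
from resilio.synthetic import default_cell_reference, mix_cell_types


def _toy_dataset(n_probes=10, n_samples=20, seed=0):
    rng = np.random.default_rng(seed)
    probes = [f"cg{i:04d}" for i in range(n_probes)]
    samples = [f"s{i:02d}" for i in range(n_samples)]
    beta = pd.DataFrame(rng.uniform(0.1, 0.9, (n_probes, n_samples)),
                        index=probes, columns=samples)
    manifest = pd.DataFrame({
        "probe_id": probes,
        "chrom": "chr1",
        "pos": np.arange(1, n_probes + 1) * 100,
        "gene": "",
        "feature_class": "opensea",
        "snp_flag": False,
        "multihit_flag": False,
        "sex_chrom_flag": False,
    }, index=probes)
    sheet = pd.DataFrame({
        "sample_id": samples,
        "cdrisc_score": rng.uniform(30, 100, n_samples).round(1),
        "resilience_group": (["low", "high"] * n_samples)[:n_samples],
        "age": rng.uniform(40, 80, n_samples).round(1),
        "menstrual": "post",
        "detection_mode": "screening",
        "er": "pos", "pr": "pos", "her2": "neg", "smoking": "never",
        "batch": "b1",
    }, index=samples)
    return beta, manifest, sheet


# -- transforms -------------------------------------------------------------

@pytest.mark.parametrize("beta,m", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)])
def test_beta_to_m_anchor_points(beta, m):
    assert np.isclose(beta_to_m(np.array([beta]))[0], m, atol=1e-12)


@given(st.floats(min_value=1e-3, max_value=1 - 1e-3,
                 allow_nan=False, allow_infinity=False))
@settings(max_examples=100, derandomize=True)
def test_transform_round_trip_identity(b):
    assert abs(m_to_beta(beta_to_m(np.array([b])))[0] - b) < 1e-12


def test_antisymmetry():
    b = np.array([0.1, 0.3, 0.45])
    np.testing.assert_allclose(beta_to_m(b), -beta_to_m(1 - b), atol=1e-12)


# -- filter cascade ---------------------------------------------------------

def test_filter_rules_direct_application():
    beta, manifest, sheet = _toy_dataset()
    # probe 0: detection p .02 in 6% of samples -> removed by rule 1
    det = pd.DataFrame(0.001, index=beta.index, columns=beta.columns)
    det.iloc[0, :2] = 0.02  # 2/20 = 10% > 5%
    # probe 1: <3 beads in 5% of samples -> removed by rule 2
    beads = pd.DataFrame(10, index=beta.index, columns=beta.columns)
    beads.iloc[1, 0] = 1
    manifest.loc["cg0002", "snp_flag"] = True
    manifest.loc["cg0003", "multihit_flag"] = True
    manifest.loc["cg0004", "sex_chrom_flag"] = True
    ds = MethylationDataset(beta=beta, manifest=manifest, samples=sheet,
                            detection_p=det, bead_counts=beads)
    filtered, report = filter_probes(ds)
    removed = set(beta.index) - set(filtered.beta.index)
    assert removed == {"cg0000", "cg0001", "cg0002", "cg0003", "cg0004"}
    counts = report.to_frame().set_index("rule")["probes_removed"]
    assert counts["detection_p"] == 1 and counts["sex_chrom"] == 1


def test_filter_cascade_is_order_stable(spiked_cohort):
    """Survivors equal the intersection of the independent rule predicates."""
    _, ds, _ = spiked_cohort
    filtered, _ = filter_probes(ds)
    det_ok = (ds.detection_p > 0.01).mean(axis=1) <= 0.05
    bead_ok = (ds.bead_counts < 3).mean(axis=1) < 0.05
    cpg_ok = ds.manifest["probe_id"].str.startswith("cg")
    flag_ok = ~(ds.manifest["snp_flag"] | ds.manifest["multihit_flag"]
                | ds.manifest["sex_chrom_flag"])
    expected = ds.beta.index[det_ok & bead_ok & cpg_ok & flag_ok]
    assert set(filtered.beta.index) == set(expected)


def test_sex_chromosome_probes_always_removed(spiked_filtered):
    filtered, _, _ = spiked_filtered
    assert not filtered.manifest["sex_chrom_flag"].any()


# -- batch adjustment -------------------------------------------------------

def test_single_batch_is_noop():
    beta, manifest, sheet = _toy_dataset()
    ds = MethylationDataset(beta=beta, manifest=manifest, samples=sheet)
    adj = adjust_batch(ds)
    np.testing.assert_allclose(adj.beta.to_numpy(), beta.to_numpy(), atol=1e-10)


def test_pure_location_shift_removed_exactly():
    beta, manifest, sheet = _toy_dataset(n_samples=20)
    sheet["batch"] = ["b1"] * 10 + ["b2"] * 10
    m = beta_to_m(beta)
    m.iloc[:, 10:] += 1.0  # batch b2 shifted +1 on M
    ds = MethylationDataset(beta=m_to_beta(m), manifest=manifest, samples=sheet)
    adj = adjust_batch(ds)
    m_adj = beta_to_m(adj.beta)
    diff = m_adj.iloc[:, :10].mean(axis=1) - m_adj.iloc[:, 10:].mean(axis=1)
    assert diff.abs().max() < 1e-10


def test_grand_moments_preserved():
    beta, manifest, sheet = _toy_dataset(n_samples=24, seed=4)
    sheet["batch"] = (["b1"] * 8 + ["b2"] * 8 + ["b3"] * 8)
    ds = MethylationDataset(beta=beta, manifest=manifest, samples=sheet)
    m0 = beta_to_m(ds.beta)
    adj = adjust_batch(ds)
    m1 = beta_to_m(adj.beta)
    np.testing.assert_allclose(m1.mean(axis=1), m0.mean(axis=1), atol=1e-10)
    np.testing.assert_allclose(m1.std(axis=1, ddof=0), m0.std(axis=1, ddof=0),
                               atol=1e-10)


def test_singleton_batch_refused():
    beta, manifest, sheet = _toy_dataset()
    sheet["batch"] = ["solo"] + ["b1"] * (len(sheet) - 1)
    ds = MethylationDataset(beta=beta, manifest=manifest, samples=sheet)
    with pytest.raises(ValueError, match="singleton"):
        adjust_batch(ds)


def test_batch_structure_removed_from_top_pcs():
    """Location+scale batch shifts stop predicting the top PCs."""
    beta, manifest, sheet = _toy_dataset(n_probes=200, n_samples=40, seed=7)
    sheet["batch"] = ["b1"] * 20 + ["b2"] * 20
    m = beta_to_m(beta)
    m.iloc[:, 20:] = 0.8 + 1.4 * m.iloc[:, 20:]
    ds = MethylationDataset(beta=m_to_beta(m), manifest=manifest, samples=sheet)

    def batch_f(d):
        assoc, _ = pca_covariate_scan(d, ["batch"], n_components=2)
        return assoc["batch"].min()

    assert batch_f(ds) < 0.01           # batch dominates before
    assert batch_f(adjust_batch(ds)) > 0.05  # and not after


# -- deconvolution ----------------------------------------------------------

def test_deconvolution_recovers_random_simplex_mixtures():
    ref = default_cell_reference(n_ref_probes=40)
    rng = np.random.default_rng(5)
    frac = pd.DataFrame(rng.dirichlet(np.ones(len(ref.columns)), size=15),
                        index=[f"s{i:02d}" for i in range(15)],
                        columns=ref.columns)
    beta_ref = mix_cell_types(frac, ref)
    beta, manifest, sheet = _toy_dataset(n_probes=40, n_samples=15, seed=2)
    beta_full = beta_ref.set_axis(beta.index, axis=0).set_axis(beta.columns, axis=1)
    ds = MethylationDataset(beta=beta_full, manifest=manifest, samples=sheet)
    ref_local = ref.set_axis(beta.index, axis=0)
    dec = deconvolve_cells(ds, ref_local)
    err = np.abs(dec.fractions.to_numpy() - frac.to_numpy()).max()
    assert err < 1e-6
    assert dec.residual_norm.max() < 1e-6
    np.testing.assert_allclose(dec.fractions.sum(axis=1), 1.0, atol=1e-6)


def test_deconvolution_one_hot_exact(spiked_cohort):
    ref = default_cell_reference(n_ref_probes=30)
    frac = pd.DataFrame(np.eye(len(ref.columns)),
                        index=[f"s{i}" for i in range(len(ref.columns))],
                        columns=ref.columns)
    beta_ref = mix_cell_types(frac, ref)
    beta, manifest, sheet = _toy_dataset(n_probes=30, n_samples=6, seed=3)
    ds = MethylationDataset(
        beta=beta_ref.set_axis(beta.index, axis=0).set_axis(beta.columns, axis=1),
        manifest=manifest, samples=sheet)
    dec = deconvolve_cells(ds, ref.set_axis(beta.index, axis=0))
    for j, ct in enumerate(ref.columns):
        assert dec.fractions.iloc[j][ct] >= 0.999


def test_deconvolution_missing_reference_probes():
    beta, manifest, sheet = _toy_dataset(n_probes=5, n_samples=4)
    ds = MethylationDataset(beta=beta, manifest=manifest, samples=sheet)
    ref = default_cell_reference(n_ref_probes=5)  # alien probe ids
    with pytest.raises(ValueError, match="absent"):
        deconvolve_cells(ds, ref)


# -- PCA scan ---------------------------------------------------------------

def test_pca_scan_self_association_and_variance_shape(null_cohort):
    _, ds, _ = null_cohort
    small = ds.subset_probes(ds.beta.index[:500])
    assoc, varexp = pca_covariate_scan(small, ["age"], n_components=5)
    # inject the PC1 scores as a covariate -> p ~ 0 on PC1
    m = beta_to_m(small.beta).to_numpy().T
    m = m - m.mean(axis=0)
    from sklearn.decomposition import PCA
    pc1 = PCA(n_components=1, random_state=0).fit_transform(m)[:, 0]
    small.samples = small.samples.copy()
    small.samples["pc1_copy"] = pc1
    assoc2, _ = pca_covariate_scan(small, ["pc1_copy"], n_components=3)
    assert assoc2.loc["PC1", "pc1_copy"] < 1e-10
    assert varexp.sum() <= 1.0 + 1e-9
    assert (np.diff(varexp.to_numpy()) <= 1e-12).all()


def test_pca_scan_detects_injected_covariate_effect():
    from resilio.synthetic import SimulationConfig, simulate_dataset
    cfg = SimulationConfig(n_probes=1500, n_samples=80,
                           covariate_effects={"age": 1.2},
                           covariate_affected_fraction=0.3,
                           batch_effects={"b1": (0.0, 1.0)}, seed=21)
    ds, _ = simulate_dataset(cfg)
    assoc, _ = pca_covariate_scan(ds, ["age"], n_components=5)
    assert assoc["age"].min() < 0.05
    rng = np.random.default_rng(0)
    ds.samples = ds.samples.copy()
    ds.samples["age_permuted"] = rng.permutation(ds.samples["age"].to_numpy())
    assoc_p, _ = pca_covariate_scan(ds, ["age_permuted"], n_components=5)
    assert assoc_p["age_permuted"].min() > 0.05 / 5  # no Bonferroni-level hit


def test_constant_covariate_flagged():
    beta, manifest, sheet = _toy_dataset()
    ds = MethylationDataset(beta=beta, manifest=manifest, samples=sheet)
    assoc, _ = pca_covariate_scan(ds, ["er"], n_components=2)  # constant 'pos'
    assert assoc["er"].isna().all()
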