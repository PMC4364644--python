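import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import methwas as mw

settings.register_profile(
    "fixed", derandomize=True, max_examples=40, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fixed")


def make_cohort(beta, detection_p=None, sample_ids=None, probe_ids=None,
                covariates=None):
    """Construct a small MethylationCohort from raw arrays."""
    beta = np.asarray(beta, dtype=float)
    n_probes, n_samples = beta.shape
    probe_ids = probe_ids or [f"cg{i:04d}" for i in range(n_probes)]
    sample_ids = sample_ids or [f"S{i:02d}" for i in range(n_samples)]
    if detection_p is None:
        detection_p = np.full(beta.shape, 1e-7)
    beta_df = pd.DataFrame(beta, index=pd.Index(probe_ids, name="probe_id"),
                           columns=sample_ids)
    det_df = pd.DataFrame(np.asarray(detection_p, float), index=beta_df.index,
                          columns=sample_ids)
    if covariates is None:
        rng = np.random.default_rng(0)
        covariates = pd.DataFrame({
            "G": rng.integers(0, 2, n_samples),
            "T": rng.integers(1, 6, n_samples),
            "B": rng.uniform(4, 10, n_samples),
            "W": (np.arange(n_samples) % 2),
            "S": rng.integers(0, 3, n_samples),
        }, index=pd.Index(sample_ids, name="sample_id"))
    return mw.MethylationCohort(beta_df, det_df, covariates)


def make_annotation(probe_ids, chromosome="chr1", island_name="", hil_class="nonisland",
                    gene="GENE1", **overrides):
    """Uniform annotation frame for constructed cohorts. Column defaults are
    scalars; any value given as a {probe_id: value} dict (including for the
    named columns) is applied as a per-probe override."""
    n = len(probe_ids)
    scalar_defaults = {"chromosome": "chr1", "island_name": "",
                       "hil_class": "nonisland", "closest_tss_gene": "GENE1"}
    named = {"chromosome": chromosome, "island_name": island_name,
             "hil_class": hil_class, "closest_tss_gene": gene}
    for col, val in named.items():
        if isinstance(val, dict):
            overrides.setdefault(col, val)
            named[col] = scalar_defaults[col]
    annot = pd.DataFrame({
        "chromosome": [named["chromosome"]] * n,
        "position": np.arange(1, n + 1) * 1000,
        "island_name": [named["island_name"]] * n,
        "hil_class": [named["hil_class"]] * n,
        "closest_tss_gene": [named["closest_tss_gene"]] * n,
        "distance_to_tss": np.full(n, 100),
        "snp_flag": [False] * n,
        "crossreactive_flag": [False] * n,
    }, index=pd.Index(probe_ids, name="probe_id"))
    for col, mapping in overrides.items():
        for pid, val in mapping.items():
            annot.loc[pid, col] = val
    return annot


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully featured simulated cohort (islands, flags, effects)."""
    cfg = mw.SimulationConfig(n_probes=600, n_samples=30, seed=11,
                              frac_weight_effect=0.02, frac_snp_effect=0.02)
    cohort, annot, truth = mw.simulate_cohort(cfg)
    return cfg, cohort, annot, truth


def inject_shared_gene_effects(cohort, annot, truth, w_effect=2.5, s_effect=2.5):
    """Give one gene a strong weight effect on one probe and a strong genotype
    effect on another, so the dual-contrast intersection must return it.

    Picks two clean free-standing probes sharing a closest-TSS gene; returns
    (modified cohort, gene symbol, probe pair)."""
    clean = annot[
        (annot["island_name"] == "")
        & ~annot["snp_flag"] & ~annot["crossreactive_flag"]
        & ~annot["chromosome"].isin(["chrX", "chrY"])
        & (truth["true_weight_effect"] == 0) & (truth["true_snp_effect"] == 0)
        & cohort.beta.notna().all(axis=1)
        & (cohort.detection_p < 1e-5).all(axis=1)
    ]
    counts = clean.groupby("closest_tss_gene").size()
    gene = counts.index[counts >= 2][0]
    pair = list(clean.index[clean["closest_tss_gene"] == gene][:2])
    beta = cohort.beta.copy()
    m = mw.beta_to_m(beta.loc[pair])
    w = cohort.covariates.loc[beta.columns, "W"].to_numpy(float)
    s = cohort.covariates.loc[beta.columns, "S"].to_numpy(float)
    m.loc[pair[0]] += w_effect * w
    m.loc[pair[1]] += s_effect * s
    beta.loc[pair] = mw.m_to_beta(m).to_numpy()
    beta = beta.where(beta.notna(), np.nan).clip(1e-12, 1 - 1e-12)
    cohort2 = mw.MethylationCohort(beta, cohort.detection_p, cohort.covariates)
    return cohort2, gene, pair
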