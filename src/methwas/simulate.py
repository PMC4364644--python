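"""Synthetic Infinium-like methylation cohorts with known ground truth.

The simulator emulates the data structure the pipeline consumes: a probe x
sample beta matrix drawn from a three-component Beta mixture (unmethylated /
hemimethylated / methylated baseline states), a matching detection p-value
matrix, a probe annotation manifest with CpG-island structure, SNP and
cross-reactivity flags and sex-chromosome probes, and a sample covariate
table modelled on a pediatric obesity cohort (sex, Tanner stage, white-blood-
cell count, weight category, additive risk-allele dose).

Differential effects are injected additively on the M scale, where the linear
model operates, then mapped back to beta-values for storage. The true effect
per probe is returned as a TruthSet so downstream estimates can be scored
against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MethylationCohort
from .errors import ConfigurationError
from .preprocess import beta_to_m, m_to_beta

#: Default Beta-mixture (weight, a, b): mostly-unmethylated promoters, a
#: hemimethylated middle class, and a methylated class, giving the bimodal
#: marginal typical of 27k-style promoter arrays.
DEFAULT_BETA_MIXTURE = ((0.55, 2.0, 18.0), (0.15, 5.0, 5.0), (0.30, 18.0, 2.0))

#: Cohort composition used when n_samples is the 69-child default:
#: 24 obese + 23 normal-weight girls, 11 obese + 11 normal-weight boys.
GIRLS_FRACTION = 47 / 69
GIRLS_OBESE_FRACTION = 24 / 47
BOYS_OBESE_FRACTION = 11 / 22


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Proportions are in [0, 1]; counts positive. The weight- and SNP-effect
    truth sets are disjoint by construction, so their fractions must sum to
    at most 1. ``n_islands=None`` scales the island count with the number of
    island-member probes (about 0.47 islands per member, the 27k-chip ratio).
    """

    n_probes: int = 27578
    n_samples: int = 69
    frac_weight_effect: float = 0.01
    frac_snp_effect: float = 0.01
    effect_size_m: float = 1.5
    frac_island_members: float = 0.42
    n_islands: int | None = None
    frac_snp_probes: float = 0.05
    frac_crossreactive: float = 0.05
    frac_sex_chrom: float = 0.04
    frac_missing: float = 0.01
    detection_fail_rate: float = 0.002
    beta_mixture: tuple = DEFAULT_BETA_MIXTURE
    noise_sd_m: float = 0.5
    tanner_weight_corr: float = 0.3
    risk_allele_freq: float = 0.45
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        for f in ("n_probes", "n_samples"):
            if int(getattr(self, f)) <= 0:
                raise ConfigurationError(f, "must be a positive count")
        for f in ("frac_weight_effect", "frac_snp_effect", "frac_island_members",
                  "frac_snp_probes", "frac_crossreactive", "frac_sex_chrom",
                  "frac_missing", "detection_fail_rate", "risk_allele_freq"):
            v = getattr(self, f)
            if not (0 <= v <= 1):
                raise ConfigurationError(f, f"must lie in [0, 1], got {v}")
        if self.frac_weight_effect + self.frac_snp_effect > 1:
            raise ConfigurationError(
                "frac_weight_effect", "frac_weight_effect + frac_snp_effect must be <= 1")
        if self.noise_sd_m < 0:
            raise ConfigurationError("noise_sd_m", "must be non-negative")
        if not (-1 < self.tanner_weight_corr < 1):
            raise ConfigurationError("tanner_weight_corr", "must lie in (-1, 1)")
        if self.n_islands is not None and self.n_islands <= 0:
            raise ConfigurationError("n_islands", "must be a positive count or None")
        weights = [w for w, _, _ in self.beta_mixture]
        if not math.isclose(sum(weights), 1.0, abs_tol=1e-9):
            raise ConfigurationError("beta_mixture", "component weights must sum to 1")
        if any(a <= 0 or b <= 0 for _, a, b in self.beta_mixture):
            raise ConfigurationError("beta_mixture", "Beta shape parameters must be positive")
        return self

    def resolved_n_islands(self, n_members: int) -> int:
        if self.n_islands is not None:
            return min(self.n_islands, max(n_members, 1))
        return max(1, round(0.47 * n_members)) if n_members else 0


def _simulate_covariates(cfg: SimulationConfig, rng: np.random.Generator,
                         sample_ids: list[str]) -> pd.DataFrame:
    n = cfg.n_samples
    n_girls = round(n * GIRLS_FRACTION)
    n_boys = n - n_girls
    g = np.array([0] * n_girls + [1] * n_boys)
    w = np.zeros(n, dtype=int)
    w[: round(n_girls * GIRLS_OBESE_FRACTION)] = 1
    w[n_girls: n_girls + round(n_boys * BOYS_OBESE_FRACTION)] = 1
    # Tanner stage mildly confounded with weight category via a Gaussian copula
    rho = cfg.tanner_weight_corr
    zw = (w - w.mean()) / max(w.std(), 1e-12)
    latent = rho * zw + math.sqrt(1 - rho ** 2) * rng.standard_normal(n)
    tanner = np.digitize(latent, [-1.2816, -0.5244, 0.5244, 1.2816]) + 1
    wbc = np.exp(rng.normal(math.log(7.0), 0.25, size=n))  # 1e9 cells/L, pediatric range
    snp = rng.binomial(2, cfg.risk_allele_freq, size=n)
    return pd.DataFrame(
        {"G": g, "T": tanner, "B": wbc, "W": w, "S": snp}, index=pd.Index(sample_ids, name="sample_id")
    )


def _simulate_annotation(cfg: SimulationConfig, rng: np.random.Generator,
                         probe_ids: list[str]) -> pd.DataFrame:
    n = cfg.n_probes
    n_sex = round(cfg.frac_sex_chrom * n)
    n_auto = n - n_sex
    n_members = min(round(cfg.frac_island_members * n), n_auto)
    n_islands = cfg.resolved_n_islands(n_members)
    if n_islands > n_members:
        n_islands = n_members

    # contiguous island blocks along the autosomal probe order: distribute the
    # non-member probes into n_islands + 1 gaps, island sizes >= 1
    island_of = np.full(n_auto, -1, dtype=int)
    sizes = np.zeros(0, dtype=int)
    if n_islands > 0:
        sizes = np.ones(n_islands, dtype=int)
        extra = rng.multinomial(n_members - n_islands, np.full(n_islands, 1 / n_islands))
        sizes += extra
        gaps = rng.multinomial(n_auto - n_members, np.full(n_islands + 1, 1 / (n_islands + 1)))
        pos = 0
        for i in range(n_islands):
            pos += gaps[i]
            island_of[pos: pos + sizes[i]] = i
            pos += sizes[i]

    # chromosomes: 22 autosomes in order, boundaries never split an island
    chrom = np.empty(n_auto, dtype=object)
    target = n_auto / 22
    c, count = 1, 0
    for i in range(n_auto):
        if count >= target and c < 22 and (island_of[i] == -1 or (i > 0 and island_of[i] != island_of[i - 1])):
            c += 1
            count = 0
        chrom[i] = f"chr{c}"
        count += 1

    # per-chromosome 1-based positions from random inter-probe gaps
    position = np.zeros(n_auto, dtype=int)
    gaps_bp = rng.integers(200, 5000, size=n_auto)
    last_chrom, run = None, 0
    for i in range(n_auto):
        run = gaps_bp[i] if chrom[i] != last_chrom else run + gaps_bp[i]
        position[i] = run
        last_chrom = chrom[i]

    # genes tile the genome; island members share their island's gene
    gene_idx = np.zeros(n_auto, dtype=int)
    g, since = 0, 0
    for i in range(n_auto):
        new_block = i > 0 and (chrom[i] != chrom[i - 1] or island_of[i] != island_of[i - 1])
        if new_block and (island_of[i] != -1 or island_of[i - 1] != -1 or since >= 3):
            g += 1
            since = 0
        gene_idx[i] = g
        since += 1
    genes = np.array([f"G{k:05d}" for k in gene_idx])

    island_class = (
        rng.choice(["HC", "IC", "ICshore"], size=n_islands, p=[0.5, 0.3, 0.2])
        if n_islands else np.zeros(0, dtype=object)
    )
    island_names = np.empty(n_islands, dtype=object)
    for i in range(n_islands):
        members = np.flatnonzero(island_of == i)
        c_name = chrom[members[0]]
        island_names[i] = (
            f"{c_name}_{island_class[i]}:{position[members].min()}-{position[members].max()}"
        )

    if n_islands:
        hil = np.where(island_of >= 0, island_class[np.maximum(island_of, 0)], "nonisland")
        island_name_col = np.where(island_of >= 0, island_names[np.maximum(island_of, 0)], "")
    else:
        hil = np.full(n_auto, "nonisland", dtype=object)
        island_name_col = np.full(n_auto, "", dtype=object)

    # sex-chromosome probes appended after the autosomes
    sex_chrom = np.array(["chrX"] * (n_sex - n_sex // 3) + ["chrY"] * (n_sex // 3))
    sex_pos = np.cumsum(rng.integers(200, 5000, size=n_sex))
    sex_genes = np.array([f"GS{k:04d}" for k in range(n_sex)])

    annot = pd.DataFrame({
        "chromosome": np.concatenate([chrom, sex_chrom]),
        "position": np.concatenate([position, sex_pos]).astype(int),
        "island_name": np.concatenate([island_name_col, np.full(n_sex, "", dtype=object)]),
        "hil_class": np.concatenate([hil, np.full(n_sex, "nonisland", dtype=object)]),
        "closest_tss_gene": np.concatenate([genes, sex_genes]),
        "distance_to_tss": rng.integers(-1500, 1501, size=n),
        "snp_flag": rng.random(n) < cfg.frac_snp_probes,
        "crossreactive_flag": rng.random(n) < cfg.frac_crossreactive,
    }, index=pd.Index(probe_ids, name="probe_id"))
    return annot


def _simulate_truth(cfg: SimulationConfig, rng: np.random.Generator,
                    annot: pd.DataFrame) -> pd.DataFrame:
    n = cfg.n_probes
    truth = pd.DataFrame(
        {"true_weight_effect": np.zeros(n), "true_snp_effect": np.zeros(n)},
        index=annot.index,
    )
    sex = annot["chromosome"].isin(["chrX", "chrY"]).to_numpy()
    eligible = np.flatnonzero(
        ~sex & ~annot["snp_flag"].to_numpy() & ~annot["crossreactive_flag"].to_numpy()
    )
    n_w = round(cfg.frac_weight_effect * n)
    n_s = round(cfg.frac_snp_effect * n)
    if n_w + n_s > len(eligible):
        raise ConfigurationError(
            "frac_weight_effect", "not enough clean probes to host the requested effects")
    chosen = rng.choice(eligible, size=n_w + n_s, replace=False)
    signs_w = rng.choice([-1.0, 1.0], size=n_w)
    signs_s = rng.choice([-1.0, 1.0], size=n_s)
    truth.iloc[chosen[:n_w], 0] = signs_w * cfg.effect_size_m
    truth.iloc[chosen[n_w:], 1] = signs_s * cfg.effect_size_m
    return truth


def simulate_cohort(cfg: SimulationConfig):
    """Simulate one cohort; returns ``(MethylationCohort, annotation, truth)``.

    Identical config + seed gives bit-identical output. Beta values lie in
    (0, 1); effects are injected on the M scale (weight effect applied to
    obese samples, SNP effect per risk allele) and mapped back to beta.
    Detection p-values are Uniform(0, 1e-6) for passing cells and
    Uniform(0.05, 1) for failing cells, so they fall unambiguously on either
    side of both QC thresholds.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    probe_ids = [f"cg{i:07d}" for i in range(cfg.n_probes)]
    sample_ids = [f"S{i:03d}" for i in range(cfg.n_samples)]

    covariates = _simulate_covariates(cfg, rng, sample_ids)
    annot = _simulate_annotation(cfg, rng, probe_ids)
    truth = _simulate_truth(cfg, rng, annot)

    weights = np.array([w for w, _, _ in cfg.beta_mixture])
    comps = rng.choice(len(weights), size=cfg.n_probes, p=weights)
    a = np.array([a for _, a, _ in cfg.beta_mixture])[comps]
    b = np.array([b for _, _, b in cfg.beta_mixture])[comps]
    base_beta = np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4)
    base_m = beta_to_m(base_beta)

    w_vec = covariates["W"].to_numpy(float)
    s_vec = covariates["S"].to_numpy(float)
    m = (
        base_m[:, None]
        + np.outer(truth["true_weight_effect"].to_numpy(), w_vec)
        + np.outer(truth["true_snp_effect"].to_numpy(), s_vec)
        + rng.normal(0.0, cfg.noise_sd_m, size=(cfg.n_probes, cfg.n_samples))
    )
    beta = m_to_beta(m)
    beta = np.clip(beta, 1e-12, 1 - 1e-12)

    # detection failure is simulated as whole-probe failure (failed probe
    # chemistry affects every sample), so the cell-level exceedance rate is
    # detection_fail_rate while good samples keep a clean detection profile
    det = rng.uniform(0.0, 1e-6, beta.shape)
    null_probes = np.flatnonzero(
        (truth["true_weight_effect"] == 0).to_numpy()
        & (truth["true_snp_effect"] == 0).to_numpy()
    )
    n_fail = min(round(cfg.detection_fail_rate * cfg.n_probes), len(null_probes))
    fail_probes = rng.choice(null_probes, size=n_fail, replace=False)
    det[fail_probes, :] = rng.uniform(0.05, 1.0, (n_fail, cfg.n_samples))

    # a fraction of probes carries one missing beta cell; never a truth probe,
    # so ground-truth effects survive QC
    remaining = np.setdiff1d(null_probes, fail_probes, assume_unique=True)
    n_missing = min(round(cfg.frac_missing * cfg.n_probes), len(remaining))
    if n_missing:
        rows = rng.choice(remaining, size=n_missing, replace=False)
        cols = rng.integers(0, cfg.n_samples, size=n_missing)
        beta[rows, cols] = np.nan

    beta_df = pd.DataFrame(beta, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids)
    det_df = pd.DataFrame(det, index=beta_df.index, columns=sample_ids)
    cohort = MethylationCohort(beta_df, det_df, covariates)
    return cohort, annot, truth


FIXTURE_FILES = ("beta.tsv", "detection_p.tsv", "annotation.tsv", "covariates.tsv")


def write_fixture(cohort: MethylationCohort, annotation: pd.DataFrame, dir_path,
                  truth: pd.DataFrame | None = None) -> dict:
    """Write the TSV inputs consumed by the readers; returns ``{name: Path}``.

    Emits ``beta.tsv``, ``detection_p.tsv`` (probe x sample, empty cells for
    missing), ``annotation.tsv`` (flags as 0/1) and ``covariates.tsv`` (the
    cohort's covariate table); optionally ``truth.tsv``.
    """
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _write(name, frame):
        p = out / name
        frame.to_csv(p, sep="\t", na_rep="", float_format="%.10g")
        paths[name] = p

    _write("beta.tsv", cohort.beta)
    _write("detection_p.tsv", cohort.detection_p)
    ann = annotation.copy()
    for flag in ("snp_flag", "crossreactive_flag"):
        ann[flag] = ann[flag].astype(int)
    _write("annotation.tsv", ann)
    _write("covariates.tsv", cohort.covariates)
    if truth is not None:
        _write("truth.tsv", truth)
    return paths
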