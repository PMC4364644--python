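"""End-to-end pipeline: QC -> M-values -> normalization -> collapsing ->
two moderated models -> top-k tables -> gene intersection.

Model 1 regresses each location's M-value on sex, Tanner stage, weight
category and white-blood-cell count, ranking by the weight-category
coefficient; model 2 adds the additive risk-allele dose and ranks by it.
Candidate genes are those hit by top-k locations of both models.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import io as mio
from .annotate import validate_annotation
from .containers import MethylationCohort
from .diffmeth import ModelSpec, fit_differential, rank_top
from .discover import cross_model_intersect
from .errors import ConfigurationError, PipelineStageError
from .preprocess import QCThresholds, beta_to_m, qc_filter, quantile_normalize
from .annotate import collapse_islands

logger = logging.getLogger(__name__)

OUTPUT_FILES = (
    "qc_report.tsv", "fit_model1.tsv", "fit_model2.tsv",
    "top15_model1.tsv", "top15_model2.tsv", "intersection.tsv", "manifest.json",
)


@dataclass
class PipelineConfig:
    """Paths, thresholds and switches for one pipeline run.

    A seed is mandatory (it seeds any stochastic path and is echoed in the
    manifest); silent clock seeding is refused.
    """

    beta_path: str = ""
    detection_path: str = ""
    annotation_path: str = ""
    covariates_path: str = ""
    output_dir: str = "methwas_out"
    seed: int | None = None
    k: int = 15
    qc: QCThresholds = field(default_factory=QCThresholds)
    robust: bool = True
    max_iter: int = 10000
    exact_gene_match: bool = False
    decimal_comma: bool = False
    verbosity: str = "INFO"

    def validate(self) -> "PipelineConfig":
        if self.seed is None:
            raise ConfigurationError("seed", "a seed is required (no clock seeding)")
        if self.k < 1:
            raise ConfigurationError("k", "must be >= 1")
        self.qc.validate()
        for f in ("beta_path", "detection_path", "annotation_path", "covariates_path"):
            if not getattr(self, f):
                raise ConfigurationError(f, "path is required")
        return self

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        qc_data = data.pop("qc", {})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(sorted(unknown)[0], "unknown configuration key")
        cfg = cls(**data)
        if qc_data:
            cfg.qc = QCThresholds(**qc_data)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def run_pipeline(cfg: PipelineConfig, cohort: MethylationCohort | None = None,
                 annotation: pd.DataFrame | None = None) -> dict:
    """Execute the full chain and write the result bundle to cfg.output_dir.

    Inputs may be passed in memory (cohort + annotation) or read from the
    configured paths. Returns a manifest dict (also written as JSON). On a
    stage failure, partial outputs are kept, a FAILED marker is written, and
    :class:`PipelineStageError` is raised.
    """
    cfg.validate() if cohort is None else None
    if cfg.seed is None:
        raise ConfigurationError("seed", "a seed is required (no clock seeding)")
    logging.basicConfig(level=getattr(logging, str(cfg.verbosity).upper(), logging.INFO))
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": _jsonable(cfg.to_dict()), "seed": cfg.seed, "stages": {}}
    stage = "read_inputs"
    try:
        if cohort is None:
            cohort = mio.read_cohort(cfg.beta_path, cfg.detection_path, cfg.covariates_path)
        if annotation is None:
            annotation = mio.read_annotation(cfg.annotation_path)
        else:
            annotation = validate_annotation(annotation)
        manifest["stages"]["input"] = {
            "probes": cohort.n_probes, "samples": cohort.n_samples}

        stage = "qc"
        filtered, report = qc_filter(cohort, annotation, cfg.qc)
        mio.write_table(report.to_frame().set_index("rule"), out / "qc_report.tsv")
        manifest["stages"]["qc"] = {
            "probes_removed_qc": report.probes_removed_qc,
            "probes_removed_sex": report.probes_removed_sex,
            "probes_retained": report.probes_retained,
            "samples_removed": report.samples_removed,
            "samples_retained": report.samples_retained,
        }

        stage = "normalize"
        m = quantile_normalize(beta_to_m(filtered.beta))

        stage = "collapse"
        m_loc, loc_table = collapse_islands(m, annotation)
        n_islands = int((loc_table["kind"] == "island").sum())
        manifest["stages"]["collapse"] = {
            "sites_in": int(m.shape[0]),
            "islands": n_islands,
            "island_members": int(loc_table.loc[loc_table["kind"] == "island", "n_members"].sum()),
            "locations": int(m_loc.shape[0]),
        }

        stage = "fit_model1"
        spec1 = ModelSpec(robust=cfg.robust, max_iter=cfg.max_iter)
        fits1, prior1 = fit_differential(m_loc, filtered.covariates, spec1)
        mio.write_table(fits1, out / "fit_model1.tsv")

        stage = "fit_model2"
        spec2 = spec1.with_snp()
        fits2, prior2 = fit_differential(m_loc, filtered.covariates, spec2)
        mio.write_table(fits2, out / "fit_model2.tsv")
        manifest["stages"]["fit"] = {
            "model1": {"contrast": spec1.contrast, "prior_d0": _num(prior1.d0),
                       "prior_s02": prior1.s02,
                       "n_not_converged": int((~fits1["converged"]).sum())},
            "model2": {"contrast": spec2.contrast, "prior_d0": _num(prior2.d0),
                       "prior_s02": prior2.s02,
                       "n_not_converged": int((~fits2["converged"]).sum())},
        }

        stage = "rank"
        top1 = rank_top(fits1, k=cfg.k, location_table=loc_table)
        top2 = rank_top(fits2, k=cfg.k, location_table=loc_table)
        mio.write_table(top1.frame, out / "top15_model1.tsv", decimal_comma=cfg.decimal_comma)
        mio.write_table(top2.frame, out / "top15_model2.tsv", decimal_comma=cfg.decimal_comma)

        stage = "discover"
        inter = cross_model_intersect(top1, top2, exact=cfg.exact_gene_match)
        mio.write_table(inter.frame.set_index("gene") if len(inter.frame) else inter.frame,
                        out / "intersection.tsv")
        manifest["stages"]["discover"] = {
            "k": cfg.k, "shared_genes": inter.genes,
            "direction_consistent": inter.frame["direction_consistent"].tolist(),
        }
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        logger.error("pipeline failed at stage %s: %s", stage, exc)
        raise PipelineStageError(stage, str(exc)) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _num(x):
    return "inf" if x == float("inf") else x


def _jsonable(d):
    if isinstance(d, dict):
        return {k: _jsonable(v) for k, v in d.items()}
    if isinstance(d, (list, tuple)):
        return [_jsonable(v) for v in d]
    return d
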