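"""Core in-memory containers shared across pipeline stages.

The pipeline's central object is a :class:`MethylationCohort`: a probe x sample
matrix of beta-values (proportion methylated, in [0, 1]) together with the
matching detection p-value matrix and a per-sample covariate table. Matrices
are plain :class:`pandas.DataFrame` objects with probe IDs as the index and
sample IDs as the columns, matching the tab-separated on-disk layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import MatrixFormatError

#: Covariate column names: G = sex (female=0, male=1), T = Tanner stage (1-5),
#: B = white-blood-cell count (> 0), W = weight category (normal=0, obese=1),
#: S = additive genotype dose of the obesity-risk SNP (TT=0, TC=1, CC=2).
REQUIRED_COVARIATES = ("G", "T", "B", "W")
OPTIONAL_COVARIATES = ("S",)


def validate_covariates(cov: pd.DataFrame, require_snp: bool = False) -> pd.DataFrame:
    """Check covariate table ranges; returns the table unchanged on success."""
    needed = list(REQUIRED_COVARIATES) + (["S"] if require_snp else [])
    missing = [c for c in needed if c not in cov.columns]
    if missing:
        raise MatrixFormatError(f"covariate table is missing columns {missing}")
    checks = {
        "G": lambda v: np.isin(v, (0, 1)),
        "W": lambda v: np.isin(v, (0, 1)),
        "T": lambda v: np.isin(v, (1, 2, 3, 4, 5)),
        "B": lambda v: v > 0,
        "S": lambda v: np.isin(v, (0, 1, 2)),
    }
    for col, ok in checks.items():
        if col not in cov.columns:
            continue
        v = cov[col].to_numpy()
        good = ok(v) | pd.isna(v)
        if not good.all():
            bad = cov.index[~good][0]
            raise MatrixFormatError(
                f"covariate {col!r} out of range for sample {bad!r} (value {cov.loc[bad, col]!r})"
            )
    return cov


@dataclass
class MethylationCohort:
    """Probe x sample beta matrix + detection p matrix + sample covariates."""

    beta: pd.DataFrame
    detection_p: pd.DataFrame
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.beta.index.equals(self.detection_p.index) or not self.beta.columns.equals(
            self.detection_p.columns
        ):
            raise MatrixFormatError("beta and detection_p must share probe and sample labels")
        if self.beta.index.has_duplicates:
            dup = self.beta.index[self.beta.index.duplicated()][0]
            raise MatrixFormatError(f"duplicate probe ID {dup!r}")
        missing = [s for s in self.beta.columns if s not in self.covariates.index]
        if missing:
            raise MatrixFormatError(f"samples missing from covariate table: {missing[:5]}")
        vals = self.beta.to_numpy(float)
        with np.errstate(invalid="ignore"):
            bad = (vals < 0) | (vals > 1)
        if np.nansum(bad):
            i, j = np.argwhere(bad)[0]
            raise MatrixFormatError(
                f"beta value out of [0, 1] at probe {self.beta.index[i]!r}, "
                f"sample {self.beta.columns[j]!r}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns

    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    def subset(self, probes=None, samples=None) -> "MethylationCohort":
        """Return a new cohort restricted to the given probe/sample IDs (order kept)."""
        beta, det = self.beta, self.detection_p
        if probes is not None:
            beta, det = beta.loc[probes], det.loc[probes]
        if samples is not None:
            beta, det = beta[samples], det[samples]
        return MethylationCohort(beta, det, self.covariates)


@dataclass
class RuleRemoval:
    """Entities removed by one QC rule, in application order."""

    rule: str
    entity: str  # "sample" | "probe"
    removed: list = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.removed)


@dataclass
class QCReport:
    """Per-rule removal record for the QC cascade.

    Each entity is attributed to the *first* rule that removes it, so the ID
    lists are disjoint and the counts satisfy
    ``probes_retained = probes_in - probes_removed_qc - probes_removed_sex``.
    """

    probes_in: int
    samples_in: int
    removals: list  # list[RuleRemoval]

    SEX_RULE = "probe_sex_chromosome"

    def _probe_rules(self):
        return [r for r in self.removals if r.entity == "probe"]

    @property
    def probes_removed_qc(self) -> int:
        return sum(r.count for r in self._probe_rules() if r.rule != self.SEX_RULE)

    @property
    def probes_removed_sex(self) -> int:
        return sum(r.count for r in self._probe_rules() if r.rule == self.SEX_RULE)

    @property
    def probes_retained(self) -> int:
        return self.probes_in - self.probes_removed_qc - self.probes_removed_sex

    @property
    def samples_removed(self) -> int:
        return sum(r.count for r in self.removals if r.entity == "sample")

    @property
    def samples_retained(self) -> int:
        return self.samples_in - self.samples_removed

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"rule": r.rule, "entity_type": r.entity, "count": r.count,
             "removed_ids": ";".join(map(str, r.removed))}
            for r in self.removals
        ]
        rows.append({"rule": "total_probes_retained", "entity_type": "probe",
                     "count": self.probes_retained, "removed_ids": ""})
        rows.append({"rule": "total_samples_retained", "entity_type": "sample",
                     "count": self.samples_retained, "removed_ids": ""})
        return pd.DataFrame(rows, columns=["rule", "entity_type", "count", "removed_ids"])

    def log_lines(self) -> list:
        lines = [f"QC input: {self.probes_in} probes, {self.samples_in} samples"]
        for r in self.removals:
            lines.append(f"QC rule {r.rule}: removed {r.count} {r.entity}(s)")
        lines.append(
            f"QC retained {self.probes_retained} probes "
            f"({self.probes_removed_qc} failed QC, {self.probes_removed_sex} on sex chromosomes) "
            f"and {self.samples_retained} samples"
        )
        return lines
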