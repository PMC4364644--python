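"""Dual-contrast gene discovery: intersect two models' top-k tables.

A gene is nominated when a top-k location of the weight-category model and a
top-k location of the genotype model map to the same closest-TSS gene.
Matching is token-based by default: a symbol such as ``CORO7-PAM16`` (a
read-through locus) matches ``CORO7`` because they share the token CORO7.
Direction consistency records whether the two coefficients share sign — the
risk-aligned reading in which, e.g., lower methylation in obese children and
lower methylation per risk allele count as a consistent pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffmeth import RankedTable

#: Gene-field sentinel for locations without an annotated gene; such rows are
#: excluded from the intersection.
NA_GENE = "NA"


def gene_tokens(symbol: str) -> frozenset:
    """Candidate match tokens for a gene symbol: the full symbol plus its
    "-"-separated components. Empty or NA symbols yield an empty set."""
    s = str(symbol).strip()
    if not s or s.upper() in {"NA", "NAN", "NONE"}:
        return frozenset()
    tokens = {s}
    if "-" in s:
        tokens.update(t for t in s.split("-") if t)
    return frozenset(tokens)


@dataclass
class IntersectionResult:
    """Genes shared between two top-k tables.

    ``frame`` has one row per matched location pair with both tables' rows
    and the sign-consistency flag; ``genes`` is the ordered list of distinct
    shared gene labels.
    """

    frame: pd.DataFrame
    genes: list = field(default_factory=list)
    contrast_a: str = ""
    contrast_b: str = ""

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def __len__(self) -> int:
        return len(self.frame)


_EMPTY_COLUMNS = [
    "gene", "location_a", "gene_a", "coefficient_a", "raw_p_a",
    "location_b", "gene_b", "coefficient_b", "raw_p_b", "direction_consistent",
]


def cross_model_intersect(a: RankedTable, b: RankedTable,
                          exact: bool = False) -> IntersectionResult:
    """Intersect two ranked tables at the gene level.

    With ``exact=False`` (default) rows match when their gene token sets
    intersect; with ``exact=True`` only identical symbols match. The shared
    gene label reported for a match is the alphabetically first shared token.
    Empty tables produce an empty result.
    """
    rows = []
    fa, fb = a.frame, b.frame
    for lid_a, row_a in fa.iterrows():
        tok_a = gene_tokens(row_a.get("gene", NA_GENE))
        if not tok_a:
            continue
        for lid_b, row_b in fb.iterrows():
            tok_b = gene_tokens(row_b.get("gene", NA_GENE))
            if not tok_b:
                continue
            if exact:
                shared = {row_a["gene"]} if str(row_a["gene"]) == str(row_b["gene"]) else set()
            else:
                shared = tok_a & tok_b
            if not shared:
                continue
            ca = float(row_a["coefficient"])
            cb = float(row_b["coefficient"])
            rows.append({
                "gene": sorted(shared)[0],
                "location_a": lid_a, "gene_a": row_a["gene"],
                "coefficient_a": ca, "raw_p_a": float(row_a["raw_p"]),
                "location_b": lid_b, "gene_b": row_b["gene"],
                "coefficient_b": cb, "raw_p_b": float(row_b["raw_p"]),
                "direction_consistent": bool(np.sign(ca) == np.sign(cb)),
            })
    frame = pd.DataFrame(rows, columns=_EMPTY_COLUMNS)
    genes = list(dict.fromkeys(frame["gene"])) if len(frame) else []
    return IntersectionResult(frame=frame, genes=genes,
                              contrast_a=a.contrast, contrast_b=b.contrast)
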