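"""Stage-1 screen for "response genes".

A gene qualifies as a *response gene* when it carries at least one
multidimensional genotypic pattern that is characteristic of one outcome
class (frequency >= ``min_characteristic`` with at least ``min_count``
carriers) while being rare in the other class (frequency < ``rarity``,
default 10%).  The screen is run in both directions (responder-characteristic
and non-responder-characteristic patterns both qualify).  Only qualifying
genes enter the downstream neural-net analysis.

No multiple-testing correction is applied at this stage; the implied
false-positive rate of the rule is quantified by null simulation instead
(see the test suite and methods note).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clinical import OutcomeLabels
from .vectors import GeneVectorMatrix, PatternCatalog, pattern_catalog

__all__ = [
    "ScreenParams",
    "ScreenResult",
    "pattern_class_frequencies",
    "screen_gene",
    "screen_cohort",
]


@dataclass
class ScreenParams:
    rarity: float = 0.10
    min_characteristic: float = 0.20
    min_count: int = 5

    def __post_init__(self) -> None:
        if not 0 <= self.rarity <= 1 or not 0 <= self.min_characteristic <= 1:
            raise ValueError("rarity and min_characteristic must be in [0,1]")


@dataclass
class ScreenResult:
    params: ScreenParams
    #: per-gene frame: gene, n_qualifying, response_gene flag
    genes: pd.DataFrame
    #: per qualifying pattern: gene, code, direction, f_target, f_contrast, counts
    qualifying: pd.DataFrame
    target: str = "responder"
    contrast: str = "non_responder"

    @property
    def response_genes(self) -> list[str]:
        return list(self.genes.loc[self.genes["response_gene"], "gene"])


def pattern_class_frequencies(
    catalog: PatternCatalog, target: str, contrast: str
) -> pd.DataFrame:
    """Per-pattern class frequencies from a catalog built with both subgroups.

    Frequencies are class-wise pattern counts divided by the class size among
    subjects with a non-missing vector; they sum to 1 per class.
    """
    for cls in (target, contrast):
        if cls not in catalog.rows.columns:
            raise KeyError(f"catalog for {catalog.gene} lacks subgroup {cls!r}")
        if catalog.subgroup_sizes.get(cls, 0) == 0:
            raise ValueError(f"class {cls!r} is empty after missing-vector removal")
    out = catalog.rows[["code", "count", target, contrast]].copy()
    out = out.rename(columns={target: "n_target", contrast: "n_contrast"})
    out["f_target"] = out["n_target"] / catalog.subgroup_sizes[target]
    out["f_contrast"] = out["n_contrast"] / catalog.subgroup_sizes[contrast]
    return out


def screen_gene(
    catalog: PatternCatalog,
    target: str,
    contrast: str,
    params: ScreenParams | None = None,
) -> pd.DataFrame:
    """Qualifying patterns of one gene, tested in both directions.

    A pattern qualifies in the forward direction when f_contrast < rarity,
    f_target >= min_characteristic and the target carrier count >= min_count;
    the reverse direction swaps the roles ("and vice versa").
    """
    params = params or ScreenParams()
    freq = pattern_class_frequencies(catalog, target, contrast)
    rows = []
    for _, r in freq.iterrows():
        fwd = (
            r["f_contrast"] < params.rarity
            and r["f_target"] >= params.min_characteristic
            and r["n_target"] >= params.min_count
        )
        rev = (
            r["f_target"] < params.rarity
            and r["f_contrast"] >= params.min_characteristic
            and r["n_contrast"] >= params.min_count
        )
        if fwd or rev:
            rows.append(
                {
                    "gene": catalog.gene,
                    "code": int(r["code"]),
                    "direction": "target" if fwd else "contrast",
                    "f_target": r["f_target"],
                    "f_contrast": r["f_contrast"],
                    "n_target": int(r["n_target"]),
                    "n_contrast": int(r["n_contrast"]),
                }
            )
    cols = ["gene", "code", "direction", "f_target", "f_contrast", "n_target", "n_contrast"]
    return pd.DataFrame(rows, columns=cols)


def screen_cohort(
    matrix: GeneVectorMatrix,
    labels: OutcomeLabels,
    params: ScreenParams | None = None,
    target_column: str = "responder",
    subjects: list[str] | None = None,
) -> ScreenResult:
    """Screen every gene for response-characteristic patterns.

    ``subjects`` restricts the screen to a subset (e.g. training folds in the
    fold-honest mode, or the included subsample); default is all subjects with
    a label.  Target class = labels[target_column] is True, contrast = False.
    """
    params = params or ScreenParams()
    pool = subjects if subjects is not None else list(labels.table.index)
    pool = [s for s in pool if s in set(matrix.subjects)]
    flags = labels.table.loc[pool, target_column].astype(bool)
    target_subjects = list(flags.index[flags])
    contrast_subjects = list(flags.index[~flags])
    gene_rows, qual_frames = [], []
    for g in matrix.genes:
        cat = pattern_catalog(
            matrix, g.gene,
            subgroups={"target": target_subjects, "contrast": contrast_subjects},
        )
        if cat.subgroup_sizes.get("target", 0) == 0 or cat.subgroup_sizes.get("contrast", 0) == 0:
            raise ValueError(f"empty class when screening gene {g.gene}")
        qual = screen_gene(cat, "target", "contrast", params)
        gene_rows.append((g.gene, len(qual), len(qual) > 0))
        if len(qual):
            qual_frames.append(qual)
    genes = pd.DataFrame(gene_rows, columns=["gene", "n_qualifying", "response_gene"])
    qualifying = (
        pd.concat(qual_frames, ignore_index=True)
        if qual_frames
        else pd.DataFrame(
            columns=["gene", "code", "direction", "f_target", "f_contrast", "n_target", "n_contrast"]
        )
    )
    return ScreenResult(params=params, genes=genes, qualifying=qualifying,
                        target=target_column, contrast=f"non_{target_column}")
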