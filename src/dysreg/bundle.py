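"""Core in-memory containers: the aligned multi-omics bundle and the gene panel.

An :class:`OmicsBundle` carries sample-by-feature matrices for mRNA expression
(normal and tumour samples; panel genes plus transcription-factor genes),
gene-level copy-number values (tumour samples only, 0 = diploid) and promoter
methylation beta values (tumour only, in [0, 1]), together with sample group
labels, optional stratification metadata and the gene -> repair-pathway map.
All downstream stages consume this one container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, FormatError

#: Canonical repair-pathway labels; arbitrary extra labels are permitted.
REPAIR_PATHWAYS = ("HR", "NER", "BER", "FA", "NHEJ", "MMR")

NORMAL = "normal"
TUMOUR = "tumour"


@dataclass
class GenePanel:
    """A curated gene panel (gene -> pathway labels) plus the candidate TF list.

    Parameters
    ----------
    genes : list of str
        Ordered panel gene identifiers (opaque, case-sensitive).
    pathways : dict of str -> set of str
        Pathway label(s) for every panel gene; each gene needs >= 1 label.
    tf_list : list of str
        Ordered candidate transcription-factor identifiers.
    """

    genes: list[str]
    pathways: dict[str, set[str]]
    tf_list: list[str]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise FormatError("duplicate identifiers in panel gene list")
        if len(set(self.tf_list)) != len(self.tf_list):
            raise FormatError("duplicate identifiers in TF list")
        missing = [g for g in self.genes if not self.pathways.get(g)]
        if missing:
            raise FormatError(
                f"panel genes without a pathway label: {missing[:5]}"
            )

    def subset(self, genes: list[str]) -> "GenePanel":
        keep = set(genes)
        return GenePanel(
            genes=[g for g in self.genes if g in keep],
            pathways={g: set(v) for g, v in self.pathways.items() if g in keep},
            tf_list=list(self.tf_list),
        )


@dataclass
class OmicsBundle:
    """Aligned sample x feature matrices for one cohort.

    ``expression`` holds both normal and tumour samples (rows) over panel and
    TF genes (columns).  ``cna`` and ``dm`` hold tumour samples only, over
    panel genes only.  ``strata`` (optional) holds per-tumour-sample
    categorical covariates such as an ER-status or stage analogue.
    """

    expression: pd.DataFrame
    cna: pd.DataFrame
    dm: pd.DataFrame
    group_labels: pd.Series
    gene_pathways: dict[str, set[str]]
    panel_genes: list[str] = field(default_factory=list)
    tf_genes: list[str] = field(default_factory=list)
    strata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.panel_genes:
            self.panel_genes = list(self.cna.columns)
        if not self.tf_genes:
            self.tf_genes = [
                c for c in self.expression.columns if c not in set(self.panel_genes)
            ]
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        tum = set(self.tumour_samples)
        if not tum:
            raise AlignmentError("bundle has no tumour samples")
        for name, mat in (("cna", self.cna), ("dm", self.dm)):
            if set(mat.index) != tum:
                raise AlignmentError(
                    f"{name} sample axis differs from the tumour sample set"
                )
            if list(mat.columns) != list(self.panel_genes):
                raise AlignmentError(f"{name} gene axis differs from panel genes")
        if not set(self.expression.index) >= tum:
            raise AlignmentError("expression matrix is missing tumour samples")
        dmv = self.dm.to_numpy()
        if dmv.size and (np.nanmin(dmv) < 0 or np.nanmax(dmv) > 1):
            raise FormatError("methylation beta values must lie in [0, 1]")
        unlabelled = [g for g in self.panel_genes if not self.gene_pathways.get(g)]
        if unlabelled:
            raise FormatError(f"panel genes without pathway label: {unlabelled[:5]}")

    # -- convenience ----------------------------------------------------
    @property
    def tumour_samples(self) -> list[str]:
        return list(self.group_labels.index[self.group_labels == TUMOUR])

    @property
    def normal_samples(self) -> list[str]:
        return list(self.group_labels.index[self.group_labels == NORMAL])

    def tumour_expression(self, genes: list[str] | None = None) -> pd.DataFrame:
        cols = genes if genes is not None else list(self.expression.columns)
        return self.expression.loc[self.tumour_samples, cols]

    def restrict_tumour_samples(self, samples: list[str]) -> "OmicsBundle":
        """Return a bundle restricted to a subset of tumour samples (normals kept)."""
        keep = [s for s in self.tumour_samples if s in set(samples)]
        rows = self.normal_samples + keep
        return OmicsBundle(
            expression=self.expression.loc[rows],
            cna=self.cna.loc[keep],
            dm=self.dm.loc[keep],
            group_labels=self.group_labels.loc[rows],
            gene_pathways=self.gene_pathways,
            panel_genes=list(self.panel_genes),
            tf_genes=list(self.tf_genes),
            strata=None if self.strata is None else self.strata.loc[keep],
        )
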