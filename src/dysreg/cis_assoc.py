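"""Per-gene cis association of mRNA with copy number and promoter methylation.

For every differentially expressed panel gene the Spearman correlation of its
tumour mRNA with its own-gene CNA (expected positive, moderate) or promoter
methylation beta (expected negative, weak) is computed, with BH FDR within
each (layer, stratum), per-pathway distribution summaries and a top-k table.
Stratified reruns (e.g. by ER-status or stage analogue) reuse the same code
path; strata below a minimum sample count are skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bundle import GenePanel, OmicsBundle
from .diff_expr import bh_adjust
from .errors import InputError

log = logging.getLogger(__name__)

CNA_LAYER = "CNA"
DM_LAYER = "DM"
ALL_STRATA = "all"


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho (midranks for ties) and its large-sample p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("inputs must be equal-length 1-d vectors")
    if x.size < 3:
        raise InputError("need at least 3 observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise InputError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class CisResult:
    """Association table plus the Figs-1/2-shaped distribution summary and
    the top-k table."""

    table: pd.DataFrame
    pathway_summary: pd.DataFrame
    top: pd.DataFrame


def _layer_matrix(bundle: OmicsBundle, layer: str) -> pd.DataFrame:
    if layer == CNA_LAYER:
        return bundle.cna
    if layer == DM_LAYER:
        return bundle.dm
    raise InputError(f"unknown layer {layer!r}")


def cis_table(
    bundle: OmicsBundle,
    layer: str,
    genes: list[str],
    strata_column: str | None = None,
    min_stratum_size: int = 10,
    top_k: int = 10,
) -> CisResult:
    """Spearman cis association per gene, overall or per stratum.

    ``genes`` is normally the DE gene set from the screening stage.  The
    top-k table sorts by |rho| descending for CNA and by rho ascending
    (most negative first) for methylation.
    """
    strata: dict[str, list[str]] = {ALL_STRATA: bundle.tumour_samples}
    if strata_column is not None:
        if bundle.strata is None or strata_column not in bundle.strata.columns:
            raise InputError(f"bundle has no stratum column {strata_column!r}")
        for value, idx in bundle.strata.groupby(strata_column).groups.items():
            samples = list(idx)
            if len(samples) < min_stratum_size:
                log.warning(
                    "stratum %s=%s has %d samples (<%d); skipped",
                    strata_column, value, len(samples), min_stratum_size,
                )
                continue
            strata[str(value)] = samples

    mat = _layer_matrix(bundle, layer)
    rows = []
    for stratum, samples in strata.items():
        expr = bundle.expression.loc[samples]
        pvals, kept = [], []
        for g in genes:
            rho, p = spearman(expr[g].to_numpy(), mat.loc[samples, g].to_numpy())
            rows.append(
                {"gene": g, "layer": layer, "stratum": stratum, "rho": rho, "p_value": p}
            )
            pvals.append(p)
            kept.append(g)
        fdr = bh_adjust(pvals)
        for r, q in zip(rows[-len(kept):], fdr):
            r["fdr"] = float(q)
    table = pd.DataFrame(rows)

    overall = table[table["stratum"] == ALL_STRATA].set_index("gene")
    summary = _pathway_distribution(overall["rho"], bundle.gene_pathways)
    if layer == CNA_LAYER:
        order = overall["rho"].abs().sort_values(ascending=False)
    else:
        order = overall["rho"].sort_values(ascending=True)
    top = overall.loc[order.index[:top_k]].reset_index()
    return CisResult(table=table, pathway_summary=summary, top=top)


def _pathway_distribution(
    rho: pd.Series, gene_pathways: dict[str, set[str]]
) -> pd.DataFrame:
    """Quartile summary of the per-gene correlations, for all genes and per
    pathway (the content of the distribution figures)."""
    groups: dict[str, list[float]] = {"all": list(rho)}
    for g, r in rho.items():
        for pw in gene_pathways.get(g, set()):
            groups.setdefault(pw, []).append(r)
    rows = []
    for name, vals in groups.items():
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append(
            {"group": name, "n": len(vals), "q1": q1, "median": med, "q3": q3,
             "min": min(vals), "max": max(vals)}
        )
    return pd.DataFrame(rows).set_index("group")


def direction_group_tests(
    cis: pd.DataFrame,
    de_results: pd.DataFrame,
    top_genes: list[str],
) -> dict[str, float]:
    """Two secondary checks: do up- and down-regulated genes differ in their
    methylation correlations (rank-sum), and is the top methylation-correlated
    set enriched for down-regulated genes (Fisher)?  Reported only; nothing
    downstream consumes them."""
    overall = cis[cis["stratum"] == ALL_STRATA].set_index("gene")
    up = [g for g in overall.index if de_results.loc[g, "direction"] == "up"]
    down = [g for g in overall.index if de_results.loc[g, "direction"] == "down"]
    out: dict[str, float] = {}
    if up and down:
        out["wilcoxon_p"] = float(
            stats.ranksums(overall.loc[up, "rho"], overall.loc[down, "rho"]).pvalue
        )
    top_set = set(top_genes)
    in_top_down = sum(1 for g in down if g in top_set)
    in_top_up = sum(1 for g in up if g in top_set)
    table = [
        [in_top_down, len(down) - in_top_down],
        [in_top_up, len(up) - in_top_up],
    ]
    out["fisher_p"] = float(stats.fisher_exact(table)[1])
    return out
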