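"""Master-regulator ranking and ChIP-Seq binding support.

Candidate master regulators are TFs ranked by the number of panel genes they
were selected for.  A predicted (TF, target) pair counts as supported when
the TF has a binding peak whose distance to the target's transcription start
site, on the same chromosome, is at most a threshold (default 100 kb; the
distance is zero when the TSS lies inside the peak interval).
"""

from __future__ import annotations

import logging
import math

import networkx as nx
import pandas as pd

from .bundle import GenePanel
from .errors import InputError

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD_BP = 100_000


def rank_regulators(
    selections: dict[str, set[str]],
    panel: GenePanel,
    top_k: int = 10,
) -> pd.DataFrame:
    """Top-k TFs by target count (descending); ties break lexicographically."""
    if not selections:
        raise InputError("no selections to rank")
    targets: dict[str, set[str]] = {}
    for gene, tfs in selections.items():
        for tf in tfs:
            targets.setdefault(tf, set()).add(gene)
    order = sorted(targets, key=lambda tf: (-len(targets[tf]), tf))
    rows = []
    for rank, tf in enumerate(order[:top_k], start=1):
        by_pathway: dict[str, set[str]] = {}
        for g in targets[tf]:
            for pw in panel.pathways.get(g, {"unannotated"}):
                by_pathway.setdefault(pw, set()).add(g)
        rows.append(
            {
                "tf": tf,
                "rank": rank,
                "n_targets": len(targets[tf]),
                "targets": ";".join(sorted(targets[tf])),
                "targets_by_pathway": {k: sorted(v) for k, v in sorted(by_pathway.items())},
            }
        )
    return pd.DataFrame(rows).set_index("tf")


def regulator_graph(selections: dict[str, set[str]], panel: GenePanel) -> nx.DiGraph:
    """TF -> target digraph with pathway annotations (GraphML-writable)."""
    g = nx.DiGraph()
    for gene, tfs in selections.items():
        g.add_node(gene, kind="gene",
                   pathways=";".join(sorted(panel.pathways.get(gene, set()))))
        for tf in tfs:
            g.add_node(tf, kind="tf")
            g.add_edge(tf, gene)
    return g


def tss_distance(
    peak_start: int, peak_end: int, tss: int, same_chrom: bool = True
) -> float:
    """Distance in bp between a TSS and a peak interval (0-based half-open).

    Zero if the TSS lies inside the peak; infinite across chromosomes.
    """
    if peak_start >= peak_end:
        raise InputError(f"invalid interval [{peak_start}, {peak_end})")
    if not same_chrom:
        return math.inf
    if peak_start <= tss < peak_end:
        return 0.0
    return float(min(abs(tss - peak_start), abs(tss - (peak_end - 1))))


def support_table(
    selections: dict[str, set[str]],
    peaks: pd.DataFrame,
    tss: pd.DataFrame,
    threshold_bp: int = DEFAULT_THRESHOLD_BP,
    mode: str = "interval",
) -> pd.DataFrame:
    """Per-TF binding support of predicted targets, plus a Total row.

    ``peaks`` is a BED-style frame whose ``name`` column carries the TF; TFs
    without any peak record are excluded (with a warning) rather than counted
    as unsupported.  Targets without a TSS record count as unsupported.  A
    pair is supported when the minimum TSS distance over the TF's peaks is
    <= ``threshold_bp``.  ``mode`` measures the distance to the peak interval
    (0 inside, default) or to the peak midpoint (``"summit"``).
    """
    if mode not in ("interval", "summit"):
        raise InputError(f"unknown distance mode {mode!r}")
    peaks_by_tf = {str(tf): sub for tf, sub in peaks.groupby("name")}
    tss_lookup = {r.gene: (r.chrom, int(r.start)) for r in tss.itertuples()}

    predicted: dict[str, list[str]] = {}
    for gene, tfs in selections.items():
        for tf in tfs:
            predicted.setdefault(tf, []).append(gene)
    usable = sorted(t for t in predicted if t in peaks_by_tf)
    for tf in sorted(set(predicted) - set(usable)):
        log.warning("TF %s has predicted targets but no peak data; excluded", tf)
    if not usable:
        raise InputError("no selected TF has peak data")

    rows = []
    tot_pred = tot_supp = 0
    for tf in usable:
        sub = peaks_by_tf[tf]
        n_supp = 0
        for gene in predicted[tf]:
            loc = tss_lookup.get(gene)
            if loc is None:
                log.warning("target %s lacks a TSS record; counted unsupported", gene)
                continue
            chrom, pos = loc
            same = sub[sub["chrom"] == chrom]
            if mode == "summit":
                dmin = min(
                    (abs(pos - (int(r.start) + int(r.end)) // 2)
                     for r in same.itertuples()),
                    default=math.inf,
                )
            else:
                dmin = min(
                    (tss_distance(int(r.start), int(r.end), pos)
                     for r in same.itertuples()),
                    default=math.inf,
                )
            if dmin <= threshold_bp:
                n_supp += 1
        n_pred = len(predicted[tf])
        if n_pred == 0:
            continue
        rows.append(
            {
                "tf": tf,
                "n_predicted": n_pred,
                "n_supported": n_supp,
                "percent": int(round(100.0 * n_supp / n_pred)),
            }
        )
        tot_pred += n_pred
        tot_supp += n_supp
    rows.append(
        {
            "tf": "Total",
            "n_predicted": tot_pred,
            "n_supported": tot_supp,
            "percent": int(round(100.0 * tot_supp / tot_pred)),
        }
    )
    return pd.DataFrame(rows).set_index("tf")
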