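"""Stability selection of transcription factors per dysregulated gene.

For each differentially expressed panel gene: draw ``runs`` cross-validated
lambda values (fold assignment re-randomised each time), fit the constrained
LASSO at every lambda, count for each TF the number of fits in which its
coefficient is nonzero (the selection frequency N), then choose the frequency
cutoff whose induced OLS model (forced-in CNA/DM plus the TFs selected more
than N-tilde times) minimises the mean test MSE over random train/test
subsamples.  TFs above the optimised cutoff are the gene's selected set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bundle import OmicsBundle
from .errors import InputError
from .lasso import PathParams, RegressionDesign, build_design, draw_lambdas, fit_at_lambdas

log = logging.getLogger(__name__)


@dataclass
class SelectionParams:
    """Knobs of the stability-selection procedure.

    ``runs`` lambda draws and ``splits`` train/test subsamples both default
    to 100; reduce them for desk-scale work.  ``train_fraction`` defaults to
    two thirds.
    """

    runs: int = 100
    splits: int = 100
    train_fraction: float = 2.0 / 3.0
    seed: int = 0
    path: PathParams = field(default_factory=PathParams)


@dataclass
class StabilityProfile:
    """Selection frequencies, the MSE-vs-cutoff curve and the selected set."""

    gene: str
    runs: int
    frequency: pd.Series  # per-TF integer in [0, runs]
    cutoff_grid: list[int]
    mse_by_cutoff: dict[int, float]
    optimal_cutoff: int
    selected_tfs: set[str]
    lambdas: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "runs": self.runs,
            "frequency": {k: int(v) for k, v in self.frequency.items() if v > 0},
            "cutoff_grid": list(map(int, self.cutoff_grid)),
            "mse_by_cutoff": {int(k): float(v) for k, v in self.mse_by_cutoff.items()},
            "optimal_cutoff": int(self.optimal_cutoff),
            "selected_tfs": sorted(self.selected_tfs),
            "lambdas": None if self.lambdas is None else list(map(float, self.lambdas)),
        }


def selection_frequencies(
    design: RegressionDesign,
    lambdas: np.ndarray,
    params: PathParams | None = None,
) -> pd.Series:
    """Per-TF count of lambdas at which the TF's coefficient is nonzero."""
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.size == 0:
        raise InputError("need at least one lambda")
    support = fit_at_lambdas(design, lambdas, params)
    freq = support.sum(axis=0).astype(int)
    return pd.Series(freq, index=design.tf_names, name=design.gene)


def _ols_test_mse(X_cols: np.ndarray, y: np.ndarray, tr: np.ndarray, te: np.ndarray) -> float:
    A = np.column_stack([np.ones(tr.sum()), X_cols[tr]])
    coef, *_ = np.linalg.lstsq(A, y[tr], rcond=None)
    pred = np.column_stack([np.ones(te.sum()), X_cols[te]]) @ coef
    return float(np.mean((y[te] - pred) ** 2))


def optimize_frequency_cutoff(
    design: RegressionDesign,
    frequency: pd.Series,
    splits: int = 100,
    train_fraction: float = 2.0 / 3.0,
    seed: int | np.random.Generator = 0,
) -> tuple[int, dict[int, float]]:
    """Pick the selection-frequency cutoff by out-of-sample OLS error.

    Candidate cutoffs are 0 plus the distinct positive observed frequencies
    (together these induce every model an integer cutoff grid could: cutoff 0
    keeps every TF ever selected, the maximum observed frequency keeps none).
    The model for cutoff N-tilde regresses y on (1, CNA, DM, TFs with
    frequency > N-tilde).  Returns the cutoff with minimal mean test MSE over
    the subsampling splits, ties broken toward the larger (more parsimonious)
    cutoff.
    """
    if not 0 < train_fraction < 1:
        raise InputError("train_fraction must lie in (0, 1)")
    freq = frequency.reindex(design.tf_names).fillna(0).astype(int)
    positive = sorted(set(freq[freq > 0]))
    if not positive:
        raise InputError("no TF has a positive selection frequency")
    candidates = [0] + positive
    rng = np.random.default_rng(seed)
    n = design.n
    n_train = int(round(train_fraction * n))
    cols_by_cutoff = {
        c: [design.x_cna, design.x_dm]
        + [design.tf_matrix[:, j] for j, name in enumerate(design.tf_names)
           if freq[name] > c]
        for c in candidates
    }
    X_by_cutoff = {c: np.column_stack(v) for c, v in cols_by_cutoff.items()}

    mse = {c: [] for c in candidates}
    for _ in range(splits):
        perm = rng.permutation(n)
        tr = np.zeros(n, dtype=bool)
        tr[perm[:n_train]] = True
        te = ~tr
        for c in candidates:
            Xc = X_by_cutoff[c]
            if Xc.shape[1] + 1 > n_train:
                continue
            mse[c].append(_ols_test_mse(Xc, design.y, tr, te))

    mse_by_cutoff: dict[int, float] = {}
    for c in candidates:
        if not mse[c]:
            log.warning(
                "gene %s: cutoff %d skipped (model wider than training set)",
                design.gene, c,
            )
            continue
        mse_by_cutoff[c] = float(np.mean(mse[c]))
    if not mse_by_cutoff:
        raise InputError("every candidate cutoff was skipped")
    best = min(mse_by_cutoff.values())
    # ties (to numerical precision) break toward the larger cutoff
    tie = best + 1e-9 * max(best, 1e-300)
    optimal = max(c for c, v in mse_by_cutoff.items() if v <= tie)
    return optimal, mse_by_cutoff


def select_tfs_for_gene(
    bundle: OmicsBundle,
    gene: str,
    params: SelectionParams | None = None,
) -> StabilityProfile:
    """Full stability-selection pipeline for one gene."""
    params = params or SelectionParams()
    design = build_design(bundle, gene)
    ss = np.random.SeedSequence(params.seed)
    rng_lam, rng_cut = (np.random.default_rng(s) for s in ss.spawn(2))
    lambdas = draw_lambdas(design, repeats=params.runs, seed=rng_lam, params=params.path)
    freq = selection_frequencies(design, lambdas, params.path)
    if freq.empty or int(freq.max()) == 0:
        return StabilityProfile(
            gene=gene, runs=params.runs, frequency=freq, cutoff_grid=[],
            mse_by_cutoff={}, optimal_cutoff=0, selected_tfs=set(), lambdas=lambdas,
        )
    optimal, mse_by_cutoff = optimize_frequency_cutoff(
        design, freq, splits=params.splits,
        train_fraction=params.train_fraction, seed=rng_cut,
    )
    selected = {name for name, f in freq.items() if f > optimal}
    return StabilityProfile(
        gene=gene,
        runs=params.runs,
        frequency=freq,
        cutoff_grid=sorted(mse_by_cutoff),
        mse_by_cutoff=mse_by_cutoff,
        optimal_cutoff=optimal,
        selected_tfs=selected,
        lambdas=lambdas,
    )


def gene_selection_seed(global_seed: int, gene: str) -> int:
    """Deterministic per-gene seed independent of scheduling/worker count."""
    h = np.random.SeedSequence(
        [global_seed, int.from_bytes(gene.encode(), "little") % (2**31)]
    )
    return int(h.generate_state(1)[0] % (2**31))


def select_tfs(
    bundle: OmicsBundle,
    genes: list[str],
    params: SelectionParams | None = None,
) -> dict[str, StabilityProfile]:
    """Run stability selection for each gene with per-gene derived seeds."""
    params = params or SelectionParams()
    out: dict[str, StabilityProfile] = {}
    for gene in genes:
        gene_params = replace(params, seed=gene_selection_seed(params.seed, gene))
        out[gene] = select_tfs_for_gene(bundle, gene, gene_params)
    return out


def selections_table(profiles: dict[str, StabilityProfile]) -> pd.DataFrame:
    rows = [
        {
            "gene": g,
            "n_selected": len(p.selected_tfs),
            "optimal_cutoff": p.optimal_cutoff,
            "selected_tfs": ";".join(sorted(p.selected_tfs)),
        }
        for g, p in profiles.items()
    ]
    return pd.DataFrame(rows).set_index("gene")
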