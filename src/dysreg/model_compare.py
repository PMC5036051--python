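"""Four alternative explanatory models per gene, compared out of sample.

Models: DM only; CNA only; CNA + DM; CNA + DM + selected TFs.  Each is an
ordinary least-squares fit on a random two-thirds training split, evaluated
on the held-out third by the Spearman correlation between predicted and
observed mRNA and by the coefficient of determination R^2 (computed about
the test-set mean, so poorly transferring models naturally go negative).
The same seeded split sequence is shared by all four models of a gene, which
makes the comparison paired.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .bundle import OmicsBundle
from .errors import InputError

log = logging.getLogger(__name__)

MODEL_NAMES = ("DM", "CNA", "CNA+DM", "CNA+DM+TFs")


def _model_columns(
    bundle: OmicsBundle, gene: str, selected_tfs: list[str], samples: list[str]
) -> dict[str, np.ndarray]:
    cna = bundle.cna.loc[samples, gene].to_numpy(dtype=float)
    dm = bundle.dm.loc[samples, gene].to_numpy(dtype=float)
    tfs = bundle.expression.loc[samples, selected_tfs].to_numpy(dtype=float)
    return {
        "DM": dm[:, None],
        "CNA": cna[:, None],
        "CNA+DM": np.column_stack([cna, dm]),
        "CNA+DM+TFs": np.column_stack([cna, dm, tfs]),
    }


def evaluate_models(
    bundle: OmicsBundle,
    gene: str,
    selected_tfs: set[str] | list[str],
    repeats: int = 100,
    train_fraction: float = 2.0 / 3.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Per-repeat test-set Spearman and R^2 for the four models of one gene."""
    if not 0 < train_fraction < 1:
        raise InputError("train_fraction must lie in (0, 1)")
    samples = bundle.tumour_samples
    y = bundle.expression.loc[samples, gene].to_numpy(dtype=float)
    tf_cols = sorted(selected_tfs)
    designs = _model_columns(bundle, gene, tf_cols, samples)
    rng = np.random.default_rng(seed)
    n = len(samples)
    n_train = int(round(train_fraction * n))

    rows = []
    skipped = {m: 0 for m in MODEL_NAMES}
    for rep in range(repeats):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        for model in MODEL_NAMES:
            Xm = designs[model]
            A = np.column_stack([np.ones(tr.size), Xm[tr]])
            coef, _, rank, _ = np.linalg.lstsq(A, y[tr], rcond=None)
            if rank < A.shape[1]:
                skipped[model] += 1
                continue
            pred = np.column_stack([np.ones(te.size), Xm[te]]) @ coef
            obs = y[te]
            if np.ptp(pred) == 0:  # degenerate constant prediction
                rho = 0.0
            else:
                rho = float(stats.spearmanr(pred, obs).statistic)
            ss_res = float(np.sum((obs - pred) ** 2))
            ss_tot = float(np.sum((obs - obs.mean()) ** 2))
            rows.append(
                {
                    "gene": gene,
                    "model": model,
                    "repeat": rep,
                    "rho": rho,
                    "r2": 1.0 - ss_res / ss_tot,
                }
            )
    for model, k in skipped.items():
        if k:
            log.warning("gene %s model %s: %d/%d splits rank-deficient, skipped",
                        gene, model, k, repeats)
        if k > 0.2 * repeats:
            raise InputError(
                f"gene {gene} model {model}: >20% of training splits rank-deficient"
            )
    return pd.DataFrame(rows)


def evaluate_all(
    bundle: OmicsBundle,
    selections: dict[str, set[str]],
    repeats: int = 100,
    train_fraction: float = 2.0 / 3.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Evaluate the four models for every gene with a selection."""
    frames = []
    for i, (gene, tfs) in enumerate(sorted(selections.items())):
        gene_seed = np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31)
        frames.append(
            evaluate_models(
                bundle, gene, tfs, repeats=repeats,
                train_fraction=train_fraction, seed=int(gene_seed),
            )
        )
    return pd.concat(frames, ignore_index=True)


def per_gene_means(rows: pd.DataFrame) -> pd.DataFrame:
    """Mean test rho and R^2 per (gene, model) over repeats."""
    return rows.groupby(["gene", "model"])[["rho", "r2"]].mean().reset_index()


def summarize_table(rows: pd.DataFrame) -> pd.DataFrame:
    """Min/median/mean/max across genes of the per-gene mean test Spearman
    and R^2, as rounded percentages — one row per model."""
    if rows.empty:
        raise InputError("no evaluated genes")
    means = per_gene_means(rows)
    out = []
    for model in MODEL_NAMES:
        sub = means[means["model"] == model]
        if sub.empty:
            continue
        row = {"model": model}
        for col, label in (("rho", "spearman_pct"), ("r2", "r2_pct")):
            v = sub[col].to_numpy() * 100.0
            row.update(
                {
                    f"{label}_min": int(round(v.min())),
                    f"{label}_median": int(round(float(np.median(v)))),
                    f"{label}_mean": int(round(v.mean())),
                    f"{label}_max": int(round(v.max())),
                }
            )
        out.append(row)
    return pd.DataFrame(out).set_index("model")
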