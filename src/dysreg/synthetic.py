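"""Synthetic multi-omics cohorts with planted ground truth.

The generator emulates the statistical structure of a tumour/normal breast
cohort profiled at three molecular levels.  Tumour mRNA of each panel gene
``g`` follows the same linear model the inference stages assume::

    y_g = b0_g + delta_g + b_c * CNA_g + b_m * DM_g + sum_k b_gk * TF_k + eps

with a positive, moderate copy-number effect ``b_c``, a weak negative
promoter-methylation effect ``b_m``, a small planted set of regulating
transcription factors per gene, and Gaussian noise.  Normal samples are drawn
from the same model with CNA fixed at 0 (diploid), DM at its normal-tissue
mean, and without the tumour-only mean shifts ``delta_g``.  Every planted
quantity is recorded in a :class:`SyntheticTruth` so recovery can be scored.

Copy-number values are discrete states {-1, 0, +1} x ``cna_scale`` plus a
small Gaussian jitter, mimicking gene-level segmentation values centred on
the diploid state.  Methylation is Beta-distributed per gene, hence in
[0, 1].  TF expression is unit-variance Gaussian; a configurable subset of
TFs receives a tumour mean shift, so TFs themselves can be differentially
expressed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .bundle import NORMAL, TUMOUR, REPAIR_PATHWAYS, GenePanel, OmicsBundle
from .errors import ConfigError


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort dimensions and planted effect sizes.

    Defaults are calibrated so the tumour-expression variance of a typical
    panel gene decomposes as roughly 22% copy number, 3% promoter
    methylation, 49% transcription factors and 26% noise, matching the
    explained-variance profile the inference stages are designed to detect.
    """

    n_tumour: int = 300
    n_normal: int = 100
    n_panel_genes: int = 50
    n_tfs: int = 150
    true_tfs_per_gene: int = 5
    beta_cna: float = 1.5
    beta_dm: float = -1.0
    tf_effect_range: tuple[float, float] = (0.27, 0.35)
    noise_sd: float = 0.51
    cna_state_probs: tuple[float, float, float] = (0.2, 0.6, 0.2)
    cna_scale: float = 0.5
    cna_jitter_sd: float = 0.05
    dm_beta_params: tuple[float, float] = (2.0, 5.0)
    tumour_shift_sd: float = 0.5
    de_fraction: float = 0.9
    de_up_prob: float = 0.7
    tf_shift_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_tumour": self.n_tumour,
            "n_normal": self.n_normal,
            "n_panel_genes": self.n_panel_genes,
            "n_tfs": self.n_tfs,
            "true_tfs_per_gene": self.true_tfs_per_gene,
        }
        for name, v in counts.items():
            if int(v) != v or v < 1:
                raise ConfigError(f"{name} must be an integer >= 1, got {v!r}")
        if self.true_tfs_per_gene > self.n_tfs:
            raise ConfigError("true_tfs_per_gene cannot exceed n_tfs")
        if abs(sum(self.cna_state_probs) - 1.0) > 1e-9 or min(self.cna_state_probs) < 0:
            raise ConfigError("cna_state_probs must be non-negative and sum to 1")
        if self.noise_sd < 0 or self.tumour_shift_sd < 0:
            raise ConfigError("standard deviations must be >= 0")
        lo, hi = self.tf_effect_range
        if lo < 0 or hi < lo:
            raise ConfigError("tf_effect_range must be 0 <= lo <= hi")
        a, b = self.dm_beta_params
        if a <= 0 or b <= 0:
            raise ConfigError("dm_beta_params must be positive shape parameters")
        if not 0 <= self.de_fraction <= 1 or not 0 <= self.tf_shift_fraction <= 1:
            raise ConfigError("fractions must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """Everything the generator planted, for recovery scoring."""

    true_tf_sets: dict[str, set[str]]
    coefficients: dict[tuple[str, str], float]
    de_genes: set[str]
    supported_pairs: set[tuple[str, str]] = field(default_factory=set)

    def to_json(self) -> str:
        payload = {
            "true_tf_sets": {g: sorted(v) for g, v in self.true_tf_sets.items()},
            "coefficients": {f"{g}\t{p}": c for (g, p), c in self.coefficients.items()},
            "de_genes": sorted(self.de_genes),
            "supported_pairs": sorted(list(p) for p in self.supported_pairs),
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(
            true_tf_sets={g: set(v) for g, v in d["true_tf_sets"].items()},
            coefficients={
                tuple(k.split("\t")): v for k, v in d["coefficients"].items()
            },
            de_genes=set(d["de_genes"]),
            supported_pairs={tuple(p) for p in d["supported_pairs"]},
        )


def _gene_names(n: int) -> list[str]:
    return [f"G{i + 1:03d}" for i in range(n)]


def _tf_names(n: int) -> list[str]:
    return [f"TF{i + 1:03d}" for i in range(n)]


def default_panel(config: SyntheticConfig) -> GenePanel:
    """Pathway labels cycle through the six repair pathways; every seventh
    gene carries a second label so multi-pathway counting is exercised."""
    genes = _gene_names(config.n_panel_genes)
    pathways: dict[str, set[str]] = {}
    for i, g in enumerate(genes):
        labels = {REPAIR_PATHWAYS[i % len(REPAIR_PATHWAYS)]}
        if i % 7 == 3:
            labels.add(REPAIR_PATHWAYS[(i + 2) % len(REPAIR_PATHWAYS)])
        pathways[g] = labels
    return GenePanel(genes=genes, pathways=pathways, tf_list=_tf_names(config.n_tfs))


def generate_cohort(config: SyntheticConfig) -> tuple[OmicsBundle, SyntheticTruth]:
    """Draw one cohort; a pure function of ``config`` (same seed, same bytes)."""
    rng = np.random.default_rng(config.seed)
    panel = default_panel(config)
    genes, tfs = panel.genes, panel.tf_list
    nt, nn = config.n_tumour, config.n_normal
    tum_samples = [f"T{i + 1:04d}" for i in range(nt)]
    norm_samples = [f"N{i + 1:04d}" for i in range(nn)]

    # TF expression: unit-variance Gaussian; a subset shifts in tumours.
    n_shift = int(round(config.tf_shift_fraction * config.n_tfs))
    shifted_tfs = rng.choice(config.n_tfs, size=n_shift, replace=False)
    tf_shift = np.zeros(config.n_tfs)
    tf_shift[shifted_tfs] = rng.normal(0.0, config.tumour_shift_sd, size=n_shift)
    tf_norm = rng.normal(0.0, 1.0, size=(nn, config.n_tfs))
    tf_tum = rng.normal(0.0, 1.0, size=(nt, config.n_tfs)) + tf_shift

    # Copy number: discrete loss/neutral/gain states + jitter, tumours only.
    states = rng.choice(
        np.array([-1.0, 0.0, 1.0]), size=(nt, len(genes)), p=config.cna_state_probs
    )
    cna = states * config.cna_scale + rng.normal(
        0.0, config.cna_jitter_sd, size=(nt, len(genes))
    )

    # Promoter methylation: Beta per sample per gene; normals sit at the mean.
    a, b = config.dm_beta_params
    dm = rng.beta(a, b, size=(nt, len(genes)))
    dm_normal_mean = a / (a + b)

    # Planted regulatory structure.
    true_tf_sets: dict[str, set[str]] = {}
    coefficients: dict[tuple[str, str], float] = {}
    beta_tf = np.zeros((config.n_tfs, len(genes)))
    lo, hi = config.tf_effect_range
    for j, g in enumerate(genes):
        idx = rng.choice(config.n_tfs, size=config.true_tfs_per_gene, replace=False)
        mags = rng.uniform(lo, hi, size=config.true_tfs_per_gene)
        signs = rng.choice([-1.0, 1.0], size=config.true_tfs_per_gene)
        beta_tf[idx, j] = mags * signs
        true_tf_sets[g] = {tfs[k] for k in idx}
        for k in idx:
            coefficients[(g, tfs[k])] = beta_tf[k, j]
        coefficients[(g, "CNA")] = config.beta_cna
        coefficients[(g, "DM")] = config.beta_dm

    intercepts = rng.normal(0.0, 0.25, size=len(genes))
    n_de = int(round(config.de_fraction * len(genes)))
    de_idx = rng.choice(len(genes), size=n_de, replace=False)
    delta = np.zeros(len(genes))
    if n_de:
        # shift magnitude scales with tumour_shift_sd (1-3 x, i.e. clearly
        # detectable at the default cohort size without being degenerate)
        mags = rng.uniform(1.0, 3.0, size=n_de) * config.tumour_shift_sd
        signs = np.where(rng.random(n_de) < config.de_up_prob, 1.0, -1.0)
        delta[de_idx] = mags * signs
    de_genes = {genes[j] for j in de_idx if delta[j] != 0.0}
    for j, g in enumerate(genes):
        coefficients[(g, "intercept")] = intercepts[j]
        coefficients[(g, "tumour_shift")] = delta[j]

    # Assemble expression.
    noise_t = rng.normal(0.0, config.noise_sd, size=(nt, len(genes)))
    noise_n = rng.normal(0.0, config.noise_sd, size=(nn, len(genes)))
    expr_tum = (
        intercepts
        + delta
        + config.beta_cna * cna
        + config.beta_dm * dm
        + tf_tum @ beta_tf
        + noise_t
    )
    expr_norm = (
        intercepts
        + config.beta_dm * dm_normal_mean
        + tf_norm @ beta_tf
        + noise_n
    )

    expression = pd.DataFrame(
        np.vstack([np.hstack([expr_norm, tf_norm]), np.hstack([expr_tum, tf_tum])]),
        index=norm_samples + tum_samples,
        columns=genes + tfs,
    )
    group = pd.Series(
        [NORMAL] * nn + [TUMOUR] * nt, index=norm_samples + tum_samples, name="group"
    )
    er = np.where(rng.random(nt) < 0.7, "ER+", "ER-")
    stage = rng.choice(["I", "II", "III"], size=nt, p=[0.25, 0.5, 0.25])
    strata = pd.DataFrame({"er_status": er, "stage": stage}, index=tum_samples)

    bundle = OmicsBundle(
        expression=expression,
        cna=pd.DataFrame(cna, index=tum_samples, columns=genes),
        dm=pd.DataFrame(dm, index=tum_samples, columns=genes),
        group_labels=group,
        gene_pathways=panel.pathways,
        panel_genes=list(genes),
        tf_genes=list(tfs),
        strata=strata,
    )
    truth = SyntheticTruth(
        true_tf_sets=true_tf_sets, coefficients=coefficients, de_genes=de_genes
    )
    return bundle, truth


# ---------------------------------------------------------------------------
# Planted variance bookkeeping
# ---------------------------------------------------------------------------

def cna_variance(config: SyntheticConfig) -> float:
    p_loss, _, p_gain = config.cna_state_probs
    mean = p_gain - p_loss
    var_state = (p_loss + p_gain) - mean**2
    return config.cna_scale**2 * var_state + config.cna_jitter_sd**2


def dm_variance(config: SyntheticConfig) -> float:
    a, b = config.dm_beta_params
    return a * b / ((a + b) ** 2 * (a + b + 1.0))


def planted_variance_fractions(
    truth: SyntheticTruth, config: SyntheticConfig
) -> pd.DataFrame:
    """Per-gene analytic decomposition of tumour-expression variance.

    Assumes independence of CNA, DM and TF expression (true by construction);
    TF expression has unit variance.  ``r2_*`` columns are the population R^2
    of the corresponding explanatory model.
    """
    v_cna = cna_variance(config) * config.beta_cna**2
    v_dm = dm_variance(config) * config.beta_dm**2
    rows = []
    for g, tf_set in truth.true_tf_sets.items():
        v_tf = sum(truth.coefficients[(g, k)] ** 2 for k in tf_set)
        total = v_cna + v_dm + v_tf + config.noise_sd**2
        rows.append(
            {
                "gene": g,
                "var_cna": v_cna,
                "var_dm": v_dm,
                "var_tf": v_tf,
                "var_noise": config.noise_sd**2,
                "r2_dm": v_dm / total,
                "r2_cna": v_cna / total,
                "r2_cna_dm": (v_cna + v_dm) / total,
                "r2_full": (v_cna + v_dm + v_tf) / total,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


# ---------------------------------------------------------------------------
# Binding annotation (peaks + TSS) with planted support
# ---------------------------------------------------------------------------

GENES_PER_CHROM = 50
TSS_SPACING = 1_000_000
PEAK_WIDTH = 200


def gene_tss_map(genes: list[str]) -> pd.DataFrame:
    """Deterministic synthetic gene geography: one chromosome per 50 genes,
    TSS spaced 1 Mb apart (so a 100 kb distance rule is geometrically
    meaningful)."""
    rows = []
    for i, g in enumerate(sorted(genes)):
        chrom = f"chr{i // GENES_PER_CHROM + 1}"
        pos = (i % GENES_PER_CHROM + 1) * TSS_SPACING
        rows.append({"chrom": chrom, "start": pos, "end": pos + 1, "gene": g})
    return pd.DataFrame(rows)


def generate_binding_annotation(
    truth: SyntheticTruth,
    supported_fraction: float,
    threshold_bp: int = 100_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place one peak per planted (TF, target) pair.

    With probability ``supported_fraction`` the peak lands within
    ``threshold_bp`` of the target TSS on the same chromosome; otherwise it is
    placed beyond the threshold or on a decoy chromosome.  The realized
    supported set is written back to ``truth.supported_pairs``.  Returns
    ``(peaks, tss)`` as BED-style frames (0-based half-open intervals).
    """
    if not 0 <= supported_fraction <= 1:
        raise ConfigError("supported_fraction must lie in [0, 1]")
    if not truth.true_tf_sets or all(not v for v in truth.true_tf_sets.values()):
        raise ConfigError("truth has no planted TF-target pairs")
    rng = np.random.default_rng(seed)
    tss = gene_tss_map(list(truth.true_tf_sets))
    tss_lookup = {r.gene: (r.chrom, r.start) for r in tss.itertuples()}

    pairs = sorted(
        (tf, gene) for gene, tf_set in truth.true_tf_sets.items() for tf in tf_set
    )
    peaks = []
    realized: set[tuple[str, str]] = set()
    margin = threshold_bp - PEAK_WIDTH
    for tf, gene in pairs:
        chrom, pos = tss_lookup[gene]
        if rng.random() < supported_fraction:
            offset = int(rng.integers(-margin, margin + 1))
            start = max(0, pos + offset)
            peaks.append((chrom, start, start + PEAK_WIDTH, tf))
            realized.add((tf, gene))
        elif rng.random() < 0.5:
            # same chromosome, comfortably beyond the threshold
            offset = threshold_bp + PEAK_WIDTH + int(rng.integers(10_000, 400_000))
            start = pos + offset
            peaks.append((chrom, start, start + PEAK_WIDTH, tf))
        else:
            start = int(rng.integers(0, 10 * TSS_SPACING))
            peaks.append(("chrU", start, start + PEAK_WIDTH, tf))
    truth.supported_pairs = realized
    peaks_df = pd.DataFrame(peaks, columns=["chrom", "start", "end", "name"])
    peaks_df["score"] = 0
    peaks_df["strand"] = "."
    return peaks_df, tss


def config_to_dict(config: SyntheticConfig) -> dict:
    return asdict(config)
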