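"""Readers/writers for the pipeline's file formats and matrix alignment.

Formats: tab-delimited sample x feature matrices (samples in rows, header row
of feature identifiers), a sample-metadata TSV, a gene-panel TSV (gene,
semicolon-joined pathway labels), a plain-text TF list, BED peaks (0-based
half-open), a BED-like TSS table (chrom, position, position+1, gene) and JSON
for ground truth and alignment reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .bundle import NORMAL, TUMOUR, GenePanel, OmicsBundle
from .errors import AlignmentError, FormatError
from .synthetic import SyntheticTruth


# ---------------------------------------------------------------------------
# Matrices and metadata
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    dups = [h for h in header if h in seen or seen.add(h)]
    if dups:
        raise FormatError(f"duplicate feature identifiers in {path}: {dups[:5]}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise FormatError(f"duplicate sample identifiers in {path}")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_panel(panel_path: str | Path, tf_path: str | Path) -> GenePanel:
    df = pd.read_csv(panel_path, sep="\t", dtype=str)
    if not {"gene", "pathways"} <= set(df.columns):
        raise FormatError("panel TSV needs 'gene' and 'pathways' columns")
    tf_list = [
        line.strip()
        for line in Path(tf_path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    return GenePanel(
        genes=df["gene"].tolist(),
        pathways={r.gene: set(r.pathways.split(";")) for r in df.itertuples()},
        tf_list=tf_list,
    )


def write_panel(panel: GenePanel, panel_path: str | Path, tf_path: str | Path) -> None:
    rows = [
        {"gene": g, "pathways": ";".join(sorted(panel.pathways[g]))}
        for g in panel.genes
    ]
    pd.DataFrame(rows).to_csv(panel_path, sep="\t", index=False)
    Path(tf_path).write_text("\n".join(panel.tf_list) + "\n")


# ---------------------------------------------------------------------------
# Bundle round trip
# ---------------------------------------------------------------------------

@dataclass
class BundlePaths:
    expression: Path
    cna: Path
    dm: Path
    samples: Path

    @classmethod
    def under(cls, outdir: str | Path) -> "BundlePaths":
        d = Path(outdir)
        return cls(
            expression=d / "expression.tsv",
            cna=d / "cna.tsv",
            dm=d / "dm.tsv",
            samples=d / "samples.tsv",
        )


@dataclass
class AlignmentReport:
    """What alignment dropped, mirroring a present-in-all-layers restriction."""

    dropped_genes: list[str] = field(default_factory=list)
    dropped_tumour_samples: list[str] = field(default_factory=list)
    dropped_tfs: list[str] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not (self.dropped_genes or self.dropped_tumour_samples or self.dropped_tfs)

    def to_json(self) -> str:
        return json.dumps(
            {
                "dropped_genes": self.dropped_genes,
                "dropped_tumour_samples": self.dropped_tumour_samples,
                "dropped_tfs": self.dropped_tfs,
            },
            indent=1,
        )


def write_bundle(bundle: OmicsBundle, outdir: str | Path) -> BundlePaths:
    paths = BundlePaths.under(outdir)
    Path(outdir).mkdir(parents=True, exist_ok=True)
    write_matrix(bundle.expression, paths.expression)
    write_matrix(bundle.cna, paths.cna)
    write_matrix(bundle.dm, paths.dm)
    meta = pd.DataFrame({"group": bundle.group_labels})
    if bundle.strata is not None:
        meta = meta.join(bundle.strata)
    meta.index.name = "sample"
    meta.to_csv(paths.samples, sep="\t")
    return paths


def load_bundle(paths: BundlePaths, panel: GenePanel) -> tuple[OmicsBundle, AlignmentReport]:
    """Load matrices and align them onto a shared sample and gene space.

    Tumour-side samples are intersected across expression/CNA/DM; panel genes
    are restricted to those present (and complete) in all three layers, and TF
    genes to those present in the expression matrix.  Dropped identifiers are
    listed in the report.
    """
    expr = read_matrix(paths.expression)
    cna = read_matrix(paths.cna)
    dm = read_matrix(paths.dm)
    meta = pd.read_csv(paths.samples, sep="\t", index_col=0)
    if "group" not in meta.columns:
        raise FormatError("sample metadata needs a 'group' column")
    group = meta["group"]
    bad = set(group.unique()) - {NORMAL, TUMOUR}
    if bad:
        raise FormatError(f"unknown group labels: {sorted(bad)}")

    tumour = [s for s in expr.index if group.get(s) == TUMOUR]
    shared = [s for s in tumour if s in cna.index and s in dm.index]
    if not shared:
        raise AlignmentError("no tumour sample shared across expression/CNA/DM")
    normal = [s for s in expr.index if group.get(s) == NORMAL]

    report = AlignmentReport(
        dropped_tumour_samples=sorted(set(tumour) - set(shared))
    )
    kept_genes = []
    for g in panel.genes:
        present = g in expr.columns and g in cna.columns and g in dm.columns
        complete = False
        if present:
            complete = (
                expr.loc[normal + shared, g].notna().all()
                and cna.loc[shared, g].notna().all()
                and dm.loc[shared, g].notna().all()
            )
        if not present or not complete:
            report.dropped_genes.append(g)
        else:
            kept_genes.append(g)
    kept_tfs = []
    for tf in panel.tf_list:
        if tf in expr.columns and expr.loc[normal + shared, tf].notna().all():
            kept_tfs.append(tf)
        else:
            report.dropped_tfs.append(tf)

    strata_cols = [c for c in meta.columns if c != "group"]
    bundle = OmicsBundle(
        expression=expr.loc[normal + shared, kept_genes + kept_tfs],
        cna=cna.loc[shared, kept_genes],
        dm=dm.loc[shared, kept_genes],
        group_labels=group.loc[normal + shared],
        gene_pathways={g: panel.pathways[g] for g in kept_genes},
        panel_genes=kept_genes,
        tf_genes=kept_tfs,
        strata=meta.loc[shared, strata_cols] if strata_cols else None,
    )
    return bundle, report


# ---------------------------------------------------------------------------
# BED intervals and TSS tables
# ---------------------------------------------------------------------------

_SKIP_PREFIXES = ("track", "browser", "#")


def read_bed_intervals(path: str | Path) -> pd.DataFrame:
    """Parse a BED file (>= 3 columns, 0-based half-open) into a frame with
    chrom/start/end plus name/score/strand when present.  Track, browser and
    comment lines are skipped; ``start >= end`` raises a format error naming
    the offending line."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has <3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise FormatError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "name": parts[3] if len(parts) > 3 else ".",
                    "score": parts[4] if len(parts) > 4 else "0",
                    "strand": parts[5] if len(parts) > 5 else ".",
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"] if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_tss_table(path: str | Path) -> pd.DataFrame:
    """BED-like 4-column TSS table: chrom, position, position+1, gene."""
    bed = read_bed_intervals(path)
    tss = bed.rename(columns={"name": "gene"})[["chrom", "start", "end", "gene"]]
    if (tss["end"] - tss["start"] != 1).any():
        raise FormatError(f"{path}: TSS records must be single-base intervals")
    return tss


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    Path(path).write_text(truth.to_json())


def read_truth(path: str | Path) -> SyntheticTruth:
    return SyntheticTruth.from_json(Path(path).read_text())
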