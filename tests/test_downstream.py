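"""Regulator ranking and binding-support geometry."""

import math

import numpy as np
import pandas as pd
import pytest

from dysreg import (
    GenePanel,
    generate_binding_annotation,
    rank_regulators,
    support_table,
    tss_distance,
)
from dysreg.downstream import regulator_graph
from dysreg.errors import InputError
from dysreg.synthetic import gene_tss_map


def _panel(genes):
    return GenePanel(genes=list(genes),
                     pathways={g: {"HR"} for g in genes},
                     tf_list=["A", "B", "C"])


class TestTssDistance:
    def test_containment_is_zero(self):
        assert tss_distance(1000, 2000, 1500) == 0

    def test_boundary_distance_arithmetic(self):
        # peak starts 100 kb beyond the TSS: distance exactly 100000
        assert tss_distance(200000, 200500, 100000) == 100000

    def test_nearest_edge_used(self):
        assert tss_distance(100, 200, 250) == 51  # vs end-1 = 199
        assert tss_distance(100, 200, 40) == 60

    def test_other_chromosome_is_infinite(self):
        assert math.isinf(tss_distance(0, 10, 5, same_chrom=False))

    def test_malformed_interval_rejected(self):
        with pytest.raises(InputError):
            tss_distance(200, 100, 50)


class TestRanking:
    def test_ordering_by_target_count(self):
        sel = {f"G{i}": {"A"} for i in range(5)}
        sel.update({f"H{i}": {"B"} for i in range(3)})
        ranking = rank_regulators(sel, _panel(list(sel)), top_k=10)
        assert list(ranking.index) == ["A", "B"]
        assert ranking.loc["A", "n_targets"] == 5

    def test_equal_counts_break_lexicographically(self):
        sel = {"G1": {"B", "A"}, "G2": {"A", "B"}}
        ranking = rank_regulators(sel, _panel(["G1", "G2"]), top_k=10)
        assert list(ranking.index) == ["A", "B"]

    def test_top_k_limits_rows(self):
        sel = {f"G{i}": {f"TF{i:02d}"} for i in range(12)}
        ranking = rank_regulators(sel, _panel(list(sel)), top_k=10)
        assert len(ranking) == 10

    def test_stable_under_gene_order_permutation(self):
        sel = {"G1": {"A"}, "G2": {"A", "B"}, "G3": {"B"}, "G4": {"A"}}
        r1 = rank_regulators(sel, _panel(list(sel)), top_k=5)
        r2 = rank_regulators(dict(reversed(list(sel.items()))),
                             _panel(list(sel)), top_k=5)
        pd.testing.assert_frame_equal(r1, r2)

    def test_graph_has_tf_target_edges(self):
        sel = {"G1": {"A"}, "G2": {"A"}}
        g = regulator_graph(sel, _panel(["G1", "G2"]))
        assert g.has_edge("A", "G1") and g.has_edge("A", "G2")


def _geometry(per_tf: dict[str, tuple[int, int]], threshold=100_000):
    """Build selections/peaks/tss realizing given (predicted, supported)
    counts per TF: supported targets get a peak at distance 0, unsupported
    ones a peak on a decoy chromosome."""
    selections: dict[str, set[str]] = {}
    peaks, tss_rows = [], []
    pos = 1_000_000
    for tf, (n_pred, n_supp) in per_tf.items():
        for i in range(n_pred):
            gene = f"{tf}_target{i}"
            selections.setdefault(gene, set()).add(tf)
            tss_rows.append({"chrom": "chr1", "start": pos, "end": pos + 1,
                             "gene": gene})
            if i < n_supp:
                peaks.append({"chrom": "chr1", "start": pos - 50,
                              "end": pos + 150, "name": tf})
            else:
                peaks.append({"chrom": "chrU", "start": pos, "end": pos + 200,
                              "name": tf})
            pos += 1_000_000
    return selections, pd.DataFrame(peaks), pd.DataFrame(tss_rows)


class TestSupportTable:
    def test_per_tf_counts_and_total_percentage(self):
        counts = {"E2F1": (46, 41), "MYC": (12, 10), "TCF7L2": (8, 5),
                  "CTCF": (6, 6), "GATA3": (6, 2), "ZNF217": (2, 1)}
        selections, peaks, tss = _geometry(counts)
        table = support_table(selections, peaks, tss)
        assert table.loc["E2F1", "percent"] == 89
        assert table.loc["Total", "n_predicted"] == 80
        assert table.loc["Total", "n_supported"] == 65
        assert table.loc["Total", "percent"] == 81

    def test_boundary_inclusive_at_threshold(self):
        selections = {"G1": {"A"}}
        tss = pd.DataFrame([{"chrom": "chr1", "start": 100_000, "end": 100_001,
                             "gene": "G1"}])
        peaks = pd.DataFrame([{"chrom": "chr1", "start": 200_000,
                               "end": 200_500, "name": "A"}])
        at = support_table(selections, peaks, tss, threshold_bp=100_000)
        assert at.loc["A", "n_supported"] == 1
        below = support_table(selections, peaks, tss, threshold_bp=99_999)
        assert below.loc["A", "n_supported"] == 0

    def test_summit_mode_measures_to_peak_midpoint(self):
        selections = {"G1": {"A"}}
        tss = pd.DataFrame([{"chrom": "chr1", "start": 100_000, "end": 100_001,
                             "gene": "G1"}])
        peaks = pd.DataFrame([{"chrom": "chr1", "start": 200_000,
                               "end": 200_500, "name": "A"}])
        interval = support_table(selections, peaks, tss, 100_000)
        summit = support_table(selections, peaks, tss, 100_000, mode="summit")
        assert interval.loc["A", "n_supported"] == 1  # edge at exactly 100 kb
        assert summit.loc["A", "n_supported"] == 0    # midpoint at 100,250 bp
        with pytest.raises(InputError):
            support_table(selections, peaks, tss, 100_000, mode="bogus")

    def test_monotone_in_threshold(self, rng):
        selections = {f"G{i}": {"A"} for i in range(30)}
        tss = pd.DataFrame(
            [{"chrom": "chr1", "start": int(p), "end": int(p) + 1, "gene": f"G{i}"}
             for i, p in enumerate(rng.integers(0, 5_000_000, 30))]
        )
        peaks = pd.DataFrame(
            [{"chrom": "chr1", "start": int(p), "end": int(p) + 200, "name": "A"}
             for p in rng.integers(0, 5_000_000, 10)]
        )
        last = -1
        for thr in (1_000, 50_000, 200_000, 2_000_000):
            supported = support_table(selections, peaks, tss, thr).loc["A", "n_supported"]
            assert supported >= last
            last = supported

    def test_tf_without_peaks_excluded(self):
        selections, peaks, tss = _geometry({"A": (3, 2)})
        selections["extra_gene"] = {"B"}  # B has no peak records
        table = support_table(selections, peaks, tss)
        assert "B" not in table.index
        assert table.loc["Total", "n_predicted"] == 3

    def test_target_without_tss_counts_unsupported(self):
        selections, peaks, tss = _geometry({"A": (3, 3)})
        selections["phantom"] = {"A"}
        table = support_table(selections, peaks, tss)
        assert table.loc["A", "n_predicted"] == 4
        assert table.loc["A", "n_supported"] == 3

    def test_no_usable_tf_rejected(self):
        with pytest.raises(InputError):
            support_table({"G1": {"A"}}, pd.DataFrame(columns=["chrom", "start",
                                                               "end", "name"]),
                          pd.DataFrame(columns=["chrom", "start", "end", "gene"]))


def test_synthetic_annotation_consistent_with_support_table(small_cohort):
    """Every pair the generator realized as supported is recovered by the
    distance rule, and no unsupported pair sneaks in (seeded re-execution
    oracle for the annotation geometry)."""
    _, truth = small_cohort
    peaks, tss = generate_binding_annotation(truth, 0.7, seed=77)
    selections = {g: set(s) for g, s in truth.true_tf_sets.items()}
    table = support_table(selections, peaks, tss)
    n_pairs = sum(len(s) for s in selections.values())
    assert table.loc["Total", "n_predicted"] == n_pairs
    assert table.loc["Total", "n_supported"] == len(truth.supported_pairs)


def test_gene_tss_map_spacing():
    tss = gene_tss_map([f"G{i:03d}" for i in range(75)])
    chr1 = tss[tss["chrom"] == "chr1"]
    assert len(chr1) == 50
    assert (np.diff(sorted(chr1["start"])) == 1_000_000).all()
    assert set(tss["chrom"]) == {"chr1", "chr2"}
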