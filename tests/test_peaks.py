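"""Peak filtering, promoter assignment, and candidate integration."""

import numpy as np
import pandas as pd
import pytest

from retinotarget import peaks as pk
from retinotarget.io import PROMOTER, NON_PROMOTER

import oracles


def peak_row(peak_id, start, end, m, p, chrom="chr1", loc=NON_PROMOTER):
    return (chrom, start, end, peak_id, ".", ".", m, p, loc)


def peak_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "peak_id", "score", "strand",
                 "m_value", "p_value", "location_class"],
    )


def gene_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])


def random_peaks(rng, n, chrom="chr1"):
    starts = rng.integers(0, 1_000_000, size=n)
    return peak_frame(
        [
            peak_row(
                f"p{i}", int(s), int(s) + int(rng.integers(100, 500)),
                float(rng.uniform(0, 1.5)), float(rng.uniform(0, 1)), chrom,
            )
            for i, s in enumerate(starts)
        ]
    )


class TestFilter:
    def test_boundary_m_retained_p_strict(self):
        table = peak_frame(
            [
                peak_row("at_m", 0, 100, 0.5, 0.049),    # M boundary -> kept
                peak_row("low_m", 200, 300, 0.49, 0.001),  # below M -> dropped
                peak_row("at_p", 400, 500, 0.9, 0.05),   # P boundary -> dropped
            ]
        )
        kept = set(pk.filter_peaks(table)["peak_id"])
        assert kept == {"at_m"}

    def test_matches_row_by_row_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            table = random_peaks(rng, 200)
            m_min = float(rng.uniform(0.2, 0.8))
            p_max = float(rng.uniform(0.01, 0.2))
            got = list(pk.filter_peaks(table, m_min, p_max)["peak_id"])
            assert got == oracles.filter_peaks_bruteforce(table, m_min, p_max)

    def test_order_preserved(self):
        rng = np.random.default_rng(1)
        table = random_peaks(rng, 50)
        kept = pk.filter_peaks(table)
        assert list(kept.index) == sorted(kept.index)


class TestAssign:
    GENES = gene_frame([("GA", "chr1", 10_000, "+"), ("GB", "chr1", 50_000, "-")])

    def test_peak_in_forward_promoter_window_assigned(self):
        table = peak_frame([peak_row("p1", 10_000 - 100, 10_000 + 50, 1.0, 0.01)])
        out = pk.assign_peaks_to_genes(table, self.GENES, (2000, 500))
        assert out["assigned_gene"].iloc[0] == "GA"
        assert out["location_class"].iloc[0] == PROMOTER

    def test_minus_strand_window_is_mirrored(self):
        # upstream of a minus-strand gene lies to the right of the TSS
        table = peak_frame([peak_row("p1", 50_000 + 1000, 50_000 + 1200, 1.0, 0.01)])
        out = pk.assign_peaks_to_genes(table, self.GENES, (2000, 500))
        assert out["assigned_gene"].iloc[0] == "GB"
        table2 = peak_frame([peak_row("p2", 50_000 - 1500, 50_000 - 1200, 1.0, 0.01)])
        out2 = pk.assign_peaks_to_genes(table2, self.GENES, (2000, 500))
        assert out2["assigned_gene"].iloc[0] is None

    def test_distant_peak_unassigned(self):
        table = peak_frame([peak_row("p1", 110_000, 110_200, 1.0, 0.01)])
        out = pk.assign_peaks_to_genes(table, self.GENES, (2000, 500))
        assert out["assigned_gene"].iloc[0] is None
        assert out["location_class"].iloc[0] == NON_PROMOTER

    def test_nearest_tss_wins_overlapping_promoters(self):
        genes = gene_frame(
            [("GA", "chr1", 10_000, "+"), ("GB", "chr1", 11_000, "+")]
        )
        table = peak_frame([peak_row("p1", 10_400, 10_700, 1.0, 0.01)])
        out = pk.assign_peaks_to_genes(table, genes, (2000, 500))
        # peak center 10550: 550 bp from GA, 450 bp from GB
        assert out["assigned_gene"].iloc[0] == "GB"

    def test_exact_distance_tie_breaks_lexicographically(self):
        genes = gene_frame(
            [("GB", "chr1", 10_000, "+"), ("GA", "chr1", 11_000, "+")]
        )
        table = peak_frame([peak_row("p1", 10_400, 10_600, 1.0, 0.01)])
        out = pk.assign_peaks_to_genes(table, genes, (2000, 2000))
        assert out["assigned_gene"].iloc[0] == "GA"

    def test_unknown_chromosome_rejected(self):
        table = peak_frame([peak_row("p1", 0, 100, 1.0, 0.01, chrom="chrX")])
        with pytest.raises(ValueError, match="chrX"):
            pk.assign_peaks_to_genes(table, self.GENES)

    def test_matches_all_pairs_oracle_on_random_layouts(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            genes = gene_frame(
                [
                    (
                        f"g{i}", "chr1", int(rng.integers(0, 500_000)),
                        "+" if rng.random() < 0.5 else "-",
                    )
                    for i in range(20)
                ]
            )
            table = random_peaks(rng, 50)
            window = (int(rng.integers(500, 5000)), int(rng.integers(100, 2000)))
            out = pk.assign_peaks_to_genes(table, genes, window)
            got = dict(zip(out["peak_id"], out["assigned_gene"]))
            assert got == oracles.assign_peaks_bruteforce(table, genes, window)

    def test_filter_and_assign_commute(self):
        rng = np.random.default_rng(9)
        table = random_peaks(rng, 100)
        genes = gene_frame(
            [(f"g{i}", "chr1", int(rng.integers(0, 1_000_000)), "+") for i in range(20)]
        )
        a = pk.assign_peaks_to_genes(pk.filter_peaks(table), genes)
        b = pk.filter_peaks(pk.assign_peaks_to_genes(table, genes))
        pd.testing.assert_frame_equal(
            a.reset_index(drop=True), b.reset_index(drop=True)
        )

    def test_widening_window_never_loses_candidates(self):
        rng = np.random.default_rng(11)
        table = random_peaks(rng, 100)
        genes = gene_frame(
            [(f"g{i}", "chr1", int(rng.integers(0, 1_000_000)), "+") for i in range(20)]
        )
        responsive = {f"g{i}" for i in range(20)}
        retained = pk.filter_peaks(table)
        small = pk.integrate_candidates(
            pk.assign_peaks_to_genes(retained, genes, (1000, 200)), responsive
        )
        large = pk.integrate_candidates(
            pk.assign_peaks_to_genes(retained, genes, (5000, 1000)), responsive
        )
        assert small.genes <= large.genes


class TestIntegrate:
    def test_evidence_is_max_m_over_peaks(self):
        table = peak_frame(
            [
                peak_row("p1", 0, 100, 0.6, 0.01, loc=PROMOTER),
                peak_row("p2", 200, 300, 0.9, 0.01, loc=PROMOTER),
                peak_row("p3", 400, 500, 0.7, 0.01, loc=PROMOTER),
            ]
        )
        table["assigned_gene"] = "GA"
        cand = pk.integrate_candidates(table, {"GA"})
        assert cand.peak_m["GA"] == 0.9
        assert cand.n_peaks["GA"] == 3

    def test_responsive_gene_without_peak_excluded(self):
        table = peak_frame([peak_row("p1", 0, 100, 0.9, 0.01, loc=PROMOTER)])
        table["assigned_gene"] = "GA"
        cand = pk.integrate_candidates(table, {"GA", "GB"})
        assert cand.genes == {"GA"}

    def test_empty_intersection_warns(self):
        table = peak_frame([peak_row("p1", 0, 100, 0.9, 0.01, loc=PROMOTER)])
        table["assigned_gene"] = "GA"
        with pytest.warns(UserWarning, match="no responsive gene"):
            cand = pk.integrate_candidates(table, {"GZ"})
        assert cand.genes == set()

    def test_candidates_never_exceed_contributing_peaks(self, default_config):
        from retinotarget import synth

        sim = synth.generate_peaks(default_config)
        genes = synth.generate_gene_annotation(default_config)
        retained = pk.filter_peaks(sim.peaks)
        assigned = pk.assign_peaks_to_genes(retained, genes)
        cand = pk.integrate_candidates(
            assigned, set(genes["gene_id"]), require_promoter=True
        )
        assert len(cand.genes) <= cand.n_contributing_peaks

    def test_planted_candidates_recovered(self, default_config):
        from retinotarget import synth
        from retinotarget import clustering as cl

        sim = synth.generate_expression(default_config)
        peaks = synth.generate_peaks(default_config)
        genes = synth.generate_gene_annotation(default_config)
        prof = cl.build_profiles(sim.matrix)
        responsive = cl.select_responsive_genes(cl.fuzzy_cmeans(prof), "down")
        assigned = pk.assign_peaks_to_genes(pk.filter_peaks(peaks.peaks), genes)
        cand = pk.integrate_candidates(assigned, responsive)
        planted = set(peaks.truth.genes_with_passing_promoter_peak)
        assert sim.truth.driver_gene in cand.genes
        assert cand.genes <= planted
        # every planted peak gene that is also responsive must be recovered
        assert cand.genes == planted & responsive
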