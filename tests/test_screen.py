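"""Proteome scan, hypergeometric enrichment and screen summary."""

import itertools
import math

import numpy as np
import pytest

from dppscan import (
    AnnotationRow,
    MotifRuleSet,
    ProteinRecord,
    hypergeom_enrichment,
    scan_proteome,
    summarize_screen,
)


def records_from(seqs):
    return [ProteinRecord(id=f"p{i}", sequence=s) for i, s in enumerate(seqs)]


class TestScan:
    def test_order_and_counts(self):
        outcomes = scan_proteome(records_from(["MAPSXAAA", "MPGLAAAA", "MKKTAAAA"]))
        assert [o.pattern for o in outcomes] == ["P4", "P3", "none"]

    def test_no_hit_proteome(self):
        outcomes = scan_proteome(records_from(["MKKTAAAA"] * 5))
        assert all(o.pattern == "none" for o in outcomes)

    def test_duplicate_sequences_same_outcome(self):
        a, b = scan_proteome(records_from(["MAPSVPAA", "MAPSVPAA"]))
        assert (a.pattern, a.released, a.degron) == (b.pattern, b.released, b.degron)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            scan_proteome([])

    def test_variant_hits_nested(self):
        rng = np.random.default_rng(7)
        seqs = [
            "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=8))
            for _ in range(2000)
        ]
        legend_hits = {
            o.id
            for o in scan_proteome(records_from(seqs), MotifRuleSet.legend())
            if o.pattern != "none"
        }
        text_hits = {
            o.id
            for o in scan_proteome(records_from(seqs), MotifRuleSet.text())
            if o.pattern != "none"
        }
        assert text_hits <= legend_hits


def enumerate_upper_tail(k, K, n, N):
    """Exhaustive oracle: fraction of hit-set placements with >= k in category."""
    hits_with_at_least_k = 0
    total = 0
    for hit_set in itertools.combinations(range(N), n):
        total += 1
        if sum(1 for i in hit_set if i < K) >= k:
            hits_with_at_least_k += 1
    return hits_with_at_least_k / total


class TestHypergeom:
    @pytest.mark.parametrize(
        "k, K, n, N, expected",
        [
            (2, 2, 2, 4, 1 / 6),
            (1, 1, 1, 2, 0.5),
            (0, 3, 2, 10, 1.0),
        ],
    )
    def test_derived_values(self, k, K, n, N, expected):
        assert hypergeom_enrichment(k, K, n, N) == pytest.approx(expected, abs=1e-12)

    def test_matches_enumeration_small(self):
        for N in range(1, 9):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(0, n + K - N), min(K, n) + 1):
                        assert hypergeom_enrichment(k, K, n, N) == pytest.approx(
                            enumerate_upper_tail(k, K, n, N), abs=1e-12
                        )

    def test_monotone_in_k(self):
        values = [hypergeom_enrichment(k, 40, 25, 200) for k in range(0, 26)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_large_population_stable(self):
        p = hypergeom_enrichment(80, 500, 1000, 100000)
        assert 0.0 < p < 1e-50  # strong enrichment, finite and positive

    @pytest.mark.parametrize(
        "k, K, n, N", [(3, 2, 5, 10), (1, 5, 0, 10), (0, 5, 8, 10), (1, 11, 1, 10)]
    )
    def test_inconsistent_counts_error(self, k, K, n, N):
        with pytest.raises(ValueError):
            hypergeom_enrichment(k, K, n, N)


def bh_adjust(pvals):
    """Textbook step-up Benjamini-Hochberg, independent of statsmodels."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        prev = min(prev, pvals[i] * m / rank_from_top)
        adjusted[i] = prev
    return adjusted


class TestSummary:
    def _screen(self, seqs, annotations):
        outcomes = scan_proteome(records_from(seqs))
        return summarize_screen(outcomes, annotations)

    def test_totals_and_crosstab_conservation(self):
        seqs = ["MAPSVPAA", "MPGLAAAA", "MKKTAAAA", "MKKTAAAA"]
        anns = [
            AnnotationRow(id="p0", compartment="IMS", has_n_terminal_mts=False),
            AnnotationRow(id="p1", compartment="IMS", has_n_terminal_mts=True),
            AnnotationRow(id="p2", compartment="matrix", has_n_terminal_mts=True),
            # p3 deliberately unannotated -> counted under "unknown"
        ]
        summary = self._screen(seqs, anns)
        assert summary.n_total == 4
        assert summary.n_hits == summary.n_P3 + summary.n_P4 == 2
        assert int(summary.mts_crosstab.to_numpy().sum()) == 4
        comps = dict(
            zip(summary.by_compartment["category"], summary.by_compartment["n_in_category"])
        )
        assert comps == {"IMS": 2, "matrix": 1, "unknown": 1}
        assert summary.by_compartment["n_in_category"].sum() == summary.n_total
        assert ((summary.by_compartment["p_raw"] >= 0) & (summary.by_compartment["p_raw"] <= 1)).all()

    def test_single_compartment_p_is_one(self):
        seqs = ["MAPSVPAA", "MKKTAAAA", "MKKTAAAA"]
        anns = [
            AnnotationRow(id=f"p{i}", compartment="matrix") for i in range(3)
        ]
        summary = self._screen(seqs, anns)
        assert summary.by_compartment["p_raw"].tolist() == [1.0]

    def test_empty_categories_skipped(self):
        seqs = ["MAPSVPAA"]
        anns = [AnnotationRow(id="p0", compartment="IMS")]
        summary = self._screen(seqs, anns)
        assert set(summary.by_compartment["category"]) == {"IMS"}
        assert summary.by_pathway.empty

    def test_bh_adjustment_matches_textbook(self):
        rng = np.random.default_rng(3)
        seqs = []
        anns = []
        compartments = ["matrix", "IMS", "IMM", "OMM", "membrane"]
        for i in range(300):
            comp = compartments[i % 5]
            hit = rng.random() < (0.5 if comp == "IMS" else 0.05)
            seqs.append("MAPSVPAA" if hit else "MKKTAAAA")
            anns.append(AnnotationRow(id=f"p{i}", compartment=comp))
        summary = self._screen(seqs, anns)
        df = summary.by_compartment
        expected = bh_adjust(df["p_raw"].tolist())
        assert df["p_adjusted"].tolist() == pytest.approx(expected, abs=1e-12)
        best = df.loc[df["p_adjusted"].idxmin(), "category"]
        assert best == "IMS"

    def test_pathway_enrichment(self):
        seqs = []
        anns = []
        for i in range(40):
            in_pathway = i < 10
            seqs.append("MAPSVPAA" if in_pathway else "MKKTAAAA")
            anns.append(
                AnnotationRow(
                    id=f"p{i}",
                    compartment="matrix",
                    pathways=frozenset({"disulfide_relay_substrate"})
                    if in_pathway
                    else frozenset(),
                )
            )
        summary = self._screen(seqs, anns)
        row = summary.by_pathway.iloc[0]
        assert row["category"] == "disulfide_relay_substrate"
        assert row["n_hits_in_category"] == 10
        assert row["p_raw"] == pytest.approx(
            1.0 / math.comb(40, 10), rel=1e-9
        )  # all 10 hits landed in the 10-member pathway

    def test_empty_outcomes_error(self):
        with pytest.raises(ValueError):
            summarize_screen([], [])
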