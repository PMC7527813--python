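"""Proteome-wide motif screen and category enrichment.

Applies the DPP8/9 N-terminal classifier to every protein of an annotated
proteome and summarises the result: hit counts per motif pattern, a 2x2
cross-tabulation of motif hits against the presence of an N-terminal
mitochondrial targeting sequence (MTS), and one-sided hypergeometric
over-representation tests per subcompartment and per pathway label with
Benjamini-Hochberg adjustment within each category family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import AnnotationRow, ProteinRecord
from .rules import MotifRuleSet, ProcessingOutcome, classify_nterm

__all__ = [
    "ScreenSummary",
    "scan_proteome",
    "hypergeom_enrichment",
    "summarize_screen",
]


def scan_proteome(
    records: Sequence[ProteinRecord],
    rules: MotifRuleSet | None = None,
    degron_table: Mapping[str, str] | None = None,
) -> list[ProcessingOutcome]:
    """Classify every protein of a proteome; one outcome per record, order kept.

    Per-record classification errors are collected and re-raised together
    with the offending ids rather than aborting at the first record.
    """
    if not records:
        raise ValueError("scan_proteome requires a non-empty record list")
    if rules is None:
        rules = MotifRuleSet.legend()
    outcomes: list[ProcessingOutcome] = []
    failures: list[str] = []
    for rec in records:
        try:
            outcomes.append(
                classify_nterm(rec.sequence, rules, degron_table, id=rec.id)
            )
        except ValueError as exc:  # collected, reported with ids
            failures.append(f"{rec.id}: {exc}")
    if failures:
        raise ValueError("classification failed for records: " + "; ".join(failures))
    return outcomes


def hypergeom_enrichment(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts category members among the ``n`` motif hits when ``K`` of the
    ``N`` proteins belong to the category and hits are exchangeable
    (sampling without replacement with fixed margins).  Uses the survival
    function of :class:`scipy.stats.hypergeom`, numerically stable for
    proteome sizes up to at least 1e5.
    """
    for name, value in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(value) != value or value < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {value!r}")
    if K > N or n > N:
        raise ValueError(f"category size K={K} and hit count n={n} must not exceed N={N}")
    if k > min(K, n):
        raise ValueError(f"k={k} exceeds min(K={K}, n={n})")
    if k < max(0, n + K - N):
        raise ValueError(f"k={k} below the feasible minimum {max(0, n + K - N)}")
    return float(hypergeom.sf(k - 1, N, K, n))


@dataclass(frozen=True)
class ScreenSummary:
    """Proteome-level summary of one motif-screen run.

    ``by_compartment`` / ``by_pathway`` carry one row per tested category:
    category, K (category size), k (hits in category), p_raw, p_adjusted
    (Benjamini-Hochberg within the family).  ``mts_crosstab`` is the 2x2
    table hit/non-hit x MTS/no-MTS; its cells sum to ``n_total``.
    """

    variant: str
    n_total: int
    n_hits: int
    n_P3: int
    n_P4: int
    by_compartment: pd.DataFrame
    by_pathway: pd.DataFrame
    mts_crosstab: pd.DataFrame
    degron_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_hits != self.n_P3 + self.n_P4:
            raise ValueError("n_hits must equal n_P3 + n_P4")
        if int(self.mts_crosstab.to_numpy().sum()) != self.n_total:
            raise ValueError("mts_crosstab cells must sum to n_total")

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "n_total": self.n_total,
            "n_hits": self.n_hits,
            "n_P3": self.n_P3,
            "n_P4": self.n_P4,
            "by_compartment": self.by_compartment.to_dict(orient="records"),
            "by_pathway": self.by_pathway.to_dict(orient="records"),
            "mts_crosstab": {
                str(row): {str(col): int(v) for col, v in cols.items()}
                for row, cols in self.mts_crosstab.to_dict(orient="index").items()
            },
            "degron_counts": dict(sorted(self.degron_counts.items())),
        }


def _enrichment_frame(
    categories: Mapping[str, tuple[int, int]], n_hits: int, n_total: int
) -> pd.DataFrame:
    """Build the per-category enrichment table with BH adjustment.

    ``categories`` maps label -> (K, k).  Categories with K == 0 are the
    caller's responsibility to drop (they are untestable, not p = 1).
    """
    labels = sorted(categories)
    rows = []
    for label in labels:
        K, k = categories[label]
        rows.append(
            {
                "category": label,
                "n_in_category": K,
                "n_hits_in_category": k,
                "p_raw": hypergeom_enrichment(k, K, n_hits, n_total),
            }
        )
    df = pd.DataFrame(
        rows, columns=["category", "n_in_category", "n_hits_in_category", "p_raw"]
    )
    if len(df):
        df["p_adjusted"] = multipletests(df["p_raw"].to_numpy(), method="fdr_bh")[1]
    else:
        df["p_adjusted"] = pd.Series(dtype=float)
    return df


def summarize_screen(
    outcomes: Sequence[ProcessingOutcome],
    annotations: Sequence[AnnotationRow],
    variant: str = "legend",
) -> ScreenSummary:
    """Summarise scan outcomes against the annotation table.

    Proteins without an annotation row are counted under compartment
    ``unknown`` with no MTS and no pathways, so totals always match the
    scanned FASTA.  Enrichment is one-sided hypergeometric per compartment
    and per pathway label (only categories with at least one member), with
    Benjamini-Hochberg adjustment within compartments and within pathways
    separately; raw p-values are always reported alongside.
    """
    if not outcomes:
        raise ValueError("summarize_screen requires a non-empty outcome list")
    ann_by_id = {a.id: a for a in annotations}
    n_total = len(outcomes)
    hits = [o for o in outcomes if o.pattern != "none"]
    n_hits = len(hits)
    n_p3 = sum(1 for o in outcomes if o.pattern == "P3")
    n_p4 = sum(1 for o in outcomes if o.pattern == "P4")

    comp_counts: dict[str, list[int]] = {}
    path_counts: dict[str, list[int]] = {}
    crosstab = {
        ("hit", "mts"): 0,
        ("hit", "no_mts"): 0,
        ("non_hit", "mts"): 0,
        ("non_hit", "no_mts"): 0,
    }
    degron_counts: dict[str, int] = {}
    for o in outcomes:
        ann = ann_by_id.get(o.id)
        compartment = ann.compartment if ann else "unknown"
        has_mts = ann.has_n_terminal_mts if ann else False
        is_hit = o.pattern != "none"
        entry = comp_counts.setdefault(compartment, [0, 0])
        entry[0] += 1
        entry[1] += int(is_hit)
        if ann:
            for label in ann.pathways:
                pentry = path_counts.setdefault(label, [0, 0])
                pentry[0] += 1
                pentry[1] += int(is_hit)
        crosstab[("hit" if is_hit else "non_hit", "mts" if has_mts else "no_mts")] += 1
        if o.degron is not None:
            degron_counts[o.degron.branch] = degron_counts.get(o.degron.branch, 0) + 1

    by_compartment = _enrichment_frame(
        {c: (K, k) for c, (K, k) in comp_counts.items() if K > 0}, n_hits, n_total
    )
    by_pathway = _enrichment_frame(
        {p: (K, k) for p, (K, k) in path_counts.items() if K > 0}, n_hits, n_total
    )
    mts_crosstab = pd.DataFrame(
        {
            "mts": [crosstab[("hit", "mts")], crosstab[("non_hit", "mts")]],
            "no_mts": [crosstab[("hit", "no_mts")], crosstab[("non_hit", "no_mts")]],
        },
        index=pd.Index(["hit", "non_hit"], name="motif"),
    )
    return ScreenSummary(
        variant=variant,
        n_total=n_total,
        n_hits=n_hits,
        n_P3=n_p3,
        n_P4=n_p4,
        by_compartment=by_compartment,
        by_pathway=by_pathway,
        mts_crosstab=mts_crosstab,
        degron_counts=degron_counts,
    )
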