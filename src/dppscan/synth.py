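"""Synthetic proteomes, annotations and ortholog sets with planted structure.

The proteome generator emulates the input of a mitochondrial motif screen:
N-terminal sequences drawn i.i.d. from a configurable background amino-acid
distribution, a compartment label per protein, and a *planted* fraction of
motif-bearing N-termini that can differ by compartment (and by pathway
membership).  Planted N-termini are forced to a random 4-mer that matches
the default (legend-variant) DPP8/9 motif; accidental motif matches arising
from the background are kept and recorded in the truth table, so the
analytic background match rate stays exact.

The ortholog generator uses a substitution-only model (no indels, so rows
are trivially aligned): each non-motif position is independently replaced by
a background-drawn residue with a per-position substitution probability,
while the four N-terminal (motif) positions are copied intact with a
separately controlled conservation probability and otherwise redrawn from
the background as a block.  The motif-bearing row fraction is therefore a
binomial sample of the conservation probability, up to the tiny accidental
background match rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import AnnotationRow, ProteinRecord
from .rules import CANONICAL_AA, MotifRuleSet, match_motif

__all__ = [
    "CompartmentSpec",
    "PathwaySpec",
    "SyntheticSpec",
    "OrthologSpec",
    "gen_proteome",
    "gen_ortholog_set",
    "accidental_match_probability",
    "legend_motif_fourmers",
]

_AA = np.array(list(CANONICAL_AA))


def _background_vector(
    background_frequencies: Mapping[str, float] | None,
) -> np.ndarray:
    if background_frequencies is None:
        return np.full(20, 1.0 / 20.0)
    vec = np.zeros(20)
    for i, aa in enumerate(CANONICAL_AA):
        vec[i] = float(background_frequencies.get(aa, 0.0))
    if not np.isclose(vec.sum(), 1.0, atol=1e-9):
        raise ValueError(f"background frequencies sum to {vec.sum()}, expected 1")
    if np.any(vec < 0):
        raise ValueError("background frequencies must be non-negative")
    return vec


@dataclass(frozen=True)
class CompartmentSpec:
    """One subcompartment: its proteome share and planted-motif probability."""

    name: str
    proportion: float
    planted_probability: float = 0.0


@dataclass(frozen=True)
class PathwaySpec:
    """One pathway label: membership probability and optional extra planting."""

    name: str
    membership_probability: float
    planted_probability: float = 0.0


# Default compartment mix loosely mirrors curated mitochondrial inventories
# (matrix-dominated, IMS a small minority); no planting by default.
_DEFAULT_COMPARTMENTS = (
    CompartmentSpec("matrix", 0.45),
    CompartmentSpec("IMM", 0.27),
    CompartmentSpec("IMS", 0.08),
    CompartmentSpec("OMM", 0.10),
    CompartmentSpec("membrane", 0.05),
    CompartmentSpec("unknown", 0.05),
)

_DEFAULT_PATHWAYS = (PathwaySpec("disulfide_relay_substrate", 0.04),)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic annotated proteome."""

    n_proteins: int = 1000
    length_range: tuple[int, int] = (60, 400)
    background_frequencies: Mapping[str, float] | None = None
    compartments: tuple[CompartmentSpec, ...] = _DEFAULT_COMPARTMENTS
    pathways: tuple[PathwaySpec, ...] = _DEFAULT_PATHWAYS
    mts_probability: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be positive")
        lo, hi = self.length_range
        if lo < 4:
            raise ValueError("minimum protein length must be >= 4 (motif needs 4 residues)")
        if hi < lo:
            raise ValueError("length_range must be (min, max) with max >= min")
        total = sum(c.proportion for c in self.compartments)
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"compartment proportions sum to {total}, expected 1")
        for c in self.compartments:
            if not 0.0 <= c.planted_probability <= 1.0 or c.proportion < 0:
                raise ValueError(f"invalid compartment spec {c}")
        for p in self.pathways:
            if not 0.0 <= p.membership_probability <= 1.0:
                raise ValueError(f"invalid pathway spec {p}")
            if not 0.0 <= p.planted_probability <= 1.0:
                raise ValueError(f"invalid pathway spec {p}")
        if not 0.0 <= self.mts_probability <= 1.0:
            raise ValueError("mts_probability must be in [0, 1]")


@dataclass(frozen=True)
class OrthologSpec:
    """Parameters of the synthetic ortholog set for one base protein."""

    base_sequence: str
    n_species: int = 11
    substitution_probability: float = 0.1
    motif_conservation_probability: float = 0.9
    background_frequencies: Mapping[str, float] | None = None
    name: str = "synthetic_orthologs"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.base_sequence) < 4:
            raise ValueError("base sequence must have at least 4 residues")
        if self.n_species < 2:
            raise ValueError("need at least 2 species for an alignment")
        if not 0.0 <= self.substitution_probability <= 1.0:
            raise ValueError("substitution_probability must be in [0, 1]")
        if not 0.0 <= self.motif_conservation_probability <= 1.0:
            raise ValueError("motif_conservation_probability must be in [0, 1]")
        object.__setattr__(self, "base_sequence", self.base_sequence.upper())


_LEGEND_FOURMERS: tuple[str, ...] | None = None


def legend_motif_fourmers() -> tuple[str, ...]:
    """All canonical 4-mers matching the legend-variant motif (P3 or P4).

    Constructed directly from the constraint sets: M[^D]P[^P] (361 strings)
    plus MP[^P]x (380 strings); the two sets are disjoint because the direct
    pattern forbids Pro at position 3 while the excision pattern requires it.
    """
    global _LEGEND_FOURMERS
    if _LEGEND_FOURMERS is None:
        non_d = [a for a in CANONICAL_AA if a != "D"]
        non_p = [a for a in CANONICAL_AA if a != "P"]
        p4 = [f"M{y}P{x}" for y in non_d for x in non_p]
        p3 = [f"MP{x}{z}" for x in non_p for z in CANONICAL_AA]
        _LEGEND_FOURMERS = tuple(p4 + p3)
    return _LEGEND_FOURMERS


def accidental_match_probability(
    rules: MotifRuleSet | None = None,
    background_frequencies: Mapping[str, float] | None = None,
) -> float:
    """Closed-form probability that a background-drawn N-terminus matches.

    For i.i.d. residues with background probabilities p(.), the disjoint
    motif patterns give

        P(match) = p(M) * P(pos2 allowed) * p(P) * (1 - p(P))   [excision]
                 + p(M) * p(P) * (1 - p(P))                      [direct]
    """
    if rules is None:
        rules = MotifRuleSet.legend()
    bg = _background_vector(background_frequencies)
    p = dict(zip(CANONICAL_AA, bg))
    pos2_allowed = sum(v for aa, v in p.items() if aa not in rules.pos2_excluded)
    pos_not_p = 1.0 - p["P"]
    return p["M"] * pos2_allowed * p["P"] * pos_not_p + p["M"] * p["P"] * pos_not_p


def gen_proteome(
    spec: SyntheticSpec,
) -> tuple[list[ProteinRecord], list[AnnotationRow], pd.DataFrame]:
    """Generate a synthetic annotated proteome plus its ground-truth table.

    Returns records, annotations and a truth table with one row per protein:
    id, compartment, pathway memberships, planted flag, the pattern of the
    planted 4-mer (empty if unplanted), and the pattern observed on the final
    sequence under the legend rules (accidental background matches included).
    Deterministic for identical spec (the seed lives in the spec).
    """
    rng = np.random.default_rng(spec.seed)
    bg = _background_vector(spec.background_frequencies)
    n = spec.n_proteins
    lo, hi = spec.length_range

    comp_names = [c.name for c in spec.compartments]
    comp_probs = np.array([c.proportion for c in spec.compartments])
    comp_probs = comp_probs / comp_probs.sum()
    comp_planted = {c.name: c.planted_probability for c in spec.compartments}

    compartments = rng.choice(len(comp_names), size=n, p=comp_probs)
    lengths = rng.integers(lo, hi + 1, size=n)
    memberships = {
        pw.name: rng.random(n) < pw.membership_probability for pw in spec.pathways
    }
    mts_flags = rng.random(n) < spec.mts_probability

    # effective planting probability: compartment OR any member pathway plants
    p_eff = np.empty(n)
    for i in range(n):
        keep = 1.0 - comp_planted[comp_names[compartments[i]]]
        for pw in spec.pathways:
            if memberships[pw.name][i]:
                keep *= 1.0 - pw.planted_probability
        p_eff[i] = 1.0 - keep
    planted = rng.random(n) < p_eff

    flat = rng.choice(20, size=int(lengths.sum()), p=bg)
    fourmers = legend_motif_fourmers()
    planted_idx = rng.integers(0, len(fourmers), size=n)

    rules = MotifRuleSet.legend()
    records: list[ProteinRecord] = []
    annotations: list[AnnotationRow] = []
    truth_rows = []
    offset = 0
    width = len(str(n))
    for i in range(n):
        length = int(lengths[i])
        seq = "".join(_AA[flat[offset : offset + length]])
        offset += length
        planted_pattern = ""
        if planted[i]:
            fourmer = fourmers[planted_idx[i]]
            seq = fourmer + seq[4:]
            planted_pattern = match_motif(fourmer, rules)
        pid = f"SYN{i + 1:0{width}d}"
        pathways = frozenset(
            pw.name for pw in spec.pathways if memberships[pw.name][i]
        )
        records.append(ProteinRecord(id=pid, sequence=seq, description=f"{pid} synthetic"))
        annotations.append(
            AnnotationRow(
                id=pid,
                compartment=comp_names[compartments[i]],
                has_n_terminal_mts=bool(mts_flags[i]),
                symbol=pid,
                pathways=pathways,
            )
        )
        truth_rows.append(
            {
                "id": pid,
                "compartment": comp_names[compartments[i]],
                "pathways": ";".join(sorted(pathways)),
                "planted": bool(planted[i]),
                "planted_pattern": planted_pattern,
                "observed_pattern": match_motif(seq, rules),
            }
        )
    truth = pd.DataFrame(truth_rows)
    return records, annotations, truth


def gen_ortholog_set(spec: OrthologSpec):
    """Generate a trivially aligned synthetic ortholog set (substitution only).

    Each species row copies the base sequence; non-motif positions are
    independently replaced by background draws with the substitution
    probability, and the motif block (positions 1-4) is copied intact with
    the motif conservation probability, otherwise redrawn entirely from the
    background.
    """
    from .io import OrthologAlignment  # local import to avoid cycle at import time

    rng = np.random.default_rng(spec.seed)
    bg = _background_vector(spec.background_frequencies)
    base = spec.base_sequence
    tail_len = len(base) - 4
    rows: list[tuple[str, str]] = []
    width = len(str(spec.n_species))
    for s in range(spec.n_species):
        keep_motif = rng.random() < spec.motif_conservation_probability
        if keep_motif:
            head = base[:4]
        else:
            head = "".join(_AA[rng.choice(20, size=4, p=bg)])
        tail_chars = list(base[4:])
        if tail_len:
            mutate = rng.random(tail_len) < spec.substitution_probability
            n_mut = int(mutate.sum())
            if n_mut:
                replacements = _AA[rng.choice(20, size=n_mut, p=bg)]
                for j, pos in enumerate(np.flatnonzero(mutate)):
                    tail_chars[pos] = replacements[j]
        rows.append((f"species_{s + 1:0{width}d}", head + "".join(tail_chars)))
    return OrthologAlignment(name=spec.name, rows=tuple(rows))
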