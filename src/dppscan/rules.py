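"""N-terminal processing rules for cytosolic dipeptidyl peptidases DPP8/9.

DPP8 and DPP9 release a dipeptide from a free protein N-terminus by cleaving
the peptide bond after a proline in position 2.  For a nascent chain that
still carries its initiator methionine there are two routes to a cleavable
substrate:

* direct cleavage of ``M-P-x...`` (the proline is already in position 2), or
* prior excision of the initiator Met by methionine aminopeptidase, which
  exposes ``y-P-x...`` from ``M-y-P-x...`` and puts the proline in position 2.

The recognition motifs used for proteome screening encode exactly these two
routes on the *unprocessed* sequence:

* ``P4``: ``M y P x`` with ``y`` outside an excluded set and ``x != P``
  (Met excision, then dipeptide ``yP`` release; the mature protein starts
  at residue 4);
* ``P3``: ``M P x`` with ``x != P`` (direct ``MP`` release; the mature
  protein starts at residue 3).

Two motif variants are first class because the source screen is described
with two mutually inconsistent exclusion sets for the variable pre-proline
position ``y``: the ``legend`` variant excludes only Asp, the ``text``
variant excludes Asp and Glu.  ``legend`` is the default; every ``text``
match is also a ``legend`` match.

The residue exposed after cleavage (the neo-N-terminus) determines the
protein's fate under the N-degron pathways; :func:`degron_class` maps it to
a pathway branch via an overridable lookup table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "CANONICAL_AA",
    "AMBIGUITY_AA",
    "MotifRuleSet",
    "DegronClass",
    "ProcessingOutcome",
    "DEFAULT_DEGRON_TABLE",
    "DEFAULT_SMALL_RESIDUES",
    "match_motif",
    "classify_nterm",
    "met_excision",
    "degron_class",
]

#: The 20 canonical amino-acid one-letter codes.
CANONICAL_AA: str = "ACDEFGHIKLMNPQRSTVWY"

#: Ambiguity / non-standard letters tolerated in input sequences.  They are
#: retained on ingest but never satisfy a constrained motif position.
AMBIGUITY_AA: frozenset[str] = frozenset("XBZUJO")

_CANONICAL_SET = frozenset(CANONICAL_AA)


@dataclass(frozen=True)
class MotifRuleSet:
    """Constraint sets defining the two DPP8/9 recognition motifs.

    Parameters
    ----------
    variant:
        ``"legend"`` (pre-proline position excludes D only) or ``"text"``
        (excludes D and E).
    pos2_excluded:
        Residues disallowed at position 2 of the 4-residue motif.
    pos4_excluded:
        Residues disallowed at position 4 of the 4-residue motif and, by the
        same post-proline rule, at position 3 of the 3-residue motif.
    """

    variant: str
    pos2_excluded: frozenset[str]
    pos4_excluded: frozenset[str] = frozenset("P")

    VARIANTS = ("legend", "text")

    @classmethod
    def legend(cls) -> "MotifRuleSet":
        """Figure-legend variant: M[^D]P[^P] or MP[^P]."""
        return cls(variant="legend", pos2_excluded=frozenset("D"))

    @classmethod
    def text(cls) -> "MotifRuleSet":
        """Results-text variant: M[^DE]P[^P] or MP[^P]."""
        return cls(variant="text", pos2_excluded=frozenset("DE"))

    @classmethod
    def from_variant(cls, variant: str) -> "MotifRuleSet":
        if variant == "legend":
            return cls.legend()
        if variant == "text":
            return cls.text()
        raise ValueError(
            f"unknown motif variant {variant!r}; expected one of {cls.VARIANTS}"
        )


@dataclass(frozen=True)
class DegronClass:
    """N-degron pathway branch assigned to a neo-N-terminal residue."""

    branch: str
    note: str = ""

    BRANCHES = ("AcN", "ArgN_primary", "ArgN_secondary", "ArgN_tertiary", "stabilizing")


# Default residue -> branch table.  Ser/Thr/Cys/Ala feed the Ac/N-degron
# pathway via N-terminal acetylation; Arg/Lys/His are primary Arg/N-degrons;
# Asp/Glu secondary (arginylation); Asn/Gln tertiary (deamidation to D/E,
# then arginylation).  Gly and Val are placed with the stabilizing residues
# following the observed stabilisation of S4G/S4V neo-termini, even though
# canonical N-acetyltransferase substrate ranges differ; override via the
# ``degron_table`` argument where another convention is wanted.
DEFAULT_DEGRON_TABLE: Mapping[str, str] = {
    **{aa: "AcN" for aa in "STCA"},
    **{aa: "ArgN_primary" for aa in "RKH"},
    **{aa: "ArgN_secondary" for aa in "DE"},
    **{aa: "ArgN_tertiary" for aa in "NQ"},
    **{aa: "stabilizing" for aa in "GVMPILFWY"},
}

_DEGRON_NOTES: Mapping[str, str] = {
    "AcN": "N-terminal acetylation by NatA-type acetyltransferases creates an Ac/N-degron",
    "ArgN_primary": "primary destabilizing residue, direct Arg/N-recognin binding",
    "ArgN_secondary": "secondary destabilizing residue, arginylation by ATE1 precedes recognition",
    "ArgN_tertiary": "tertiary destabilizing residue, deamidation to D/E then arginylation path",
    "stabilizing": "no destabilizing N-degron under the default rules",
}

#: Penultimate residues permitting initiator-Met excision by methionine
#: aminopeptidase (small side chains).
DEFAULT_SMALL_RESIDUES: frozenset[str] = frozenset("ACGPSTV")


def _check_sequence(sequence: str) -> str:
    if not sequence:
        raise ValueError("empty sequence")
    return sequence.upper()


def match_motif(sequence: str, rules: MotifRuleSet) -> str:
    """Match the DPP8/9 recognition motifs at a protein N-terminus.

    Returns ``"P4"`` for the 4-residue motif (Met excision then dipeptide
    release), ``"P3"`` for the 3-residue motif (direct ``MP`` release), or
    ``"none"``.  The two patterns are mutually exclusive: ``P3`` requires a
    non-Pro at position 3 while ``P4`` requires Pro there.  Ambiguity letters
    never satisfy a constrained position.
    """
    seq = _check_sequence(sequence)
    if len(seq) >= 4 and seq[0] == "M" and seq[2] == "P":
        p2, p4 = seq[1], seq[3]
        if (
            p2 in _CANONICAL_SET
            and p2 not in rules.pos2_excluded
            and p4 in _CANONICAL_SET
            and p4 not in rules.pos4_excluded
        ):
            return "P4"
    if len(seq) >= 3 and seq[0] == "M" and seq[1] == "P":
        p3 = seq[2]
        if p3 in _CANONICAL_SET and p3 not in rules.pos4_excluded:
            return "P3"
    return "none"


def degron_class(
    neo_residue: str, degron_table: Mapping[str, str] | None = None
) -> DegronClass:
    """Assign the N-degron pathway branch for a neo-N-terminal residue.

    The branch is determined solely by the residue through the lookup table
    (default :data:`DEFAULT_DEGRON_TABLE`).  Ambiguity letters are rejected.
    """
    table = DEFAULT_DEGRON_TABLE if degron_table is None else degron_table
    residue = neo_residue.upper()
    if len(residue) != 1 or residue not in _CANONICAL_SET:
        raise ValueError(f"not a canonical amino-acid letter: {neo_residue!r}")
    try:
        branch = table[residue]
    except KeyError:
        raise ValueError(f"degron table has no entry for residue {residue!r}") from None
    if branch not in DegronClass.BRANCHES:
        raise ValueError(f"unknown degron branch {branch!r} for residue {residue!r}")
    return DegronClass(branch=branch, note=_DEGRON_NOTES.get(branch, ""))


@dataclass(frozen=True)
class ProcessingOutcome:
    """Predicted N-terminal maturation of one protein.

    ``pattern`` is the matched motif (``none``/``P3``/``P4``); ``route`` the
    maturation route (``none``, ``dpp_direct``, ``map_then_dpp``);
    ``released`` the ordered peptides removed from the N-terminus;
    ``neo_residue``/``neo_prefix`` describe the mature N-terminus; ``degron``
    its N-degron classification.  Non-substrates carry ``None`` downstream
    fields.
    """

    id: str
    pattern: str
    route: str = "none"
    released: tuple[str, ...] = ()
    neo_residue: str | None = None
    neo_prefix: str | None = None
    degron: DegronClass | None = None


def classify_nterm(
    sequence: str,
    rules: MotifRuleSet | None = None,
    degron_table: Mapping[str, str] | None = None,
    id: str = "",
) -> ProcessingOutcome:
    """Classify a protein N-terminus through the full two-step model.

    Composes motif matching, route assignment, released-peptide listing,
    neo-N-terminus extraction and degron lookup.  For ``P4`` the route is
    Met excision followed by dipeptide release (released ``["M", y+"P"]``,
    mature protein starting at residue 4); for ``P3`` it is direct ``MP``
    release (mature protein starting at residue 3).  Pure function of its
    arguments.
    """
    if rules is None:
        rules = MotifRuleSet.legend()
    seq = _check_sequence(sequence)
    pattern = match_motif(seq, rules)
    if pattern == "none":
        return ProcessingOutcome(id=id, pattern="none")
    if pattern == "P4":
        route = "map_then_dpp"
        released = ("M", seq[1:3])
        neo_pos = 3  # 0-based index of residue 4
    else:
        route = "dpp_direct"
        released = (seq[0:2],)
        neo_pos = 2
    neo_residue = seq[neo_pos]
    neo_prefix = seq[neo_pos : neo_pos + 2]
    return ProcessingOutcome(
        id=id,
        pattern=pattern,
        route=route,
        released=released,
        neo_residue=neo_residue,
        neo_prefix=neo_prefix,
        degron=degron_class(neo_residue, degron_table),
    )


def met_excision(
    sequence: str, small_residue_set: Iterable[str] = DEFAULT_SMALL_RESIDUES
) -> tuple[str, bool]:
    """Apply the methionine-aminopeptidase rule to a sequence.

    Removes the initiator Met iff the penultimate residue is in
    ``small_residue_set`` (default A, C, G, P, S, T, V).  Annotation utility
    only: the screen classifies through the motif rules directly, because the
    canonical small-residue set contains Pro and chaining excision into the
    motif would contradict the direct-cleavage pattern.
    """
    seq = _check_sequence(sequence)
    if len(seq) < 2:
        raise ValueError("sequence too short for Met-excision rule (need >= 2 residues)")
    small = frozenset(r.upper() for r in small_residue_set)
    if seq[0] == "M" and seq[1] in small:
        return seq[1:], True
    return seq, False
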