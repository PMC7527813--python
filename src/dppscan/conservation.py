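"""Per-column conservation profiles, logo matrices and motif conservation.

Columns of an ortholog alignment are summarised as residue relative
frequencies over the 20 canonical amino acids.  Gaps (and non-canonical
letters) are excluded from the denominator; the gap fraction is kept
separately, following sequence-logo convention.  Column information content
is measured in bits against the 20-letter uniform maximum,

    I_i = log2(20) - H_i,    H_i = -sum_a f_ai * log2(f_ai),

with no small-sample correction.  An information-mode logo scales each
residue's letter height by its column's information content, so heights sum
per column to I_i; probability mode uses the raw frequencies (matching logos
whose letter sizes show relative residue abundance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .io import OrthologAlignment
from .rules import CANONICAL_AA, MotifRuleSet, match_motif

__all__ = [
    "AlignmentProfile",
    "column_profile",
    "motif_conservation",
    "logo_matrix",
    "profile_table",
    "MAX_INFORMATION_BITS",
]

#: Information ceiling for a 20-letter alphabet, log2(20) bits.
MAX_INFORMATION_BITS: float = math.log2(20)

_AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}


@dataclass(frozen=True)
class AlignmentProfile:
    """Column-wise summary of an ortholog alignment.

    ``frequencies`` is an (n_columns, 20) array over :data:`CANONICAL_AA`;
    each row sums to 1.  ``gap_fraction`` is the per-column fraction of rows
    excluded from the frequency denominator (gaps and non-canonical
    letters).  ``consensus`` takes the most frequent residue per column,
    ties broken alphabetically and recorded in ``tie_columns`` (1-based).
    """

    name: str
    n_sequences: int
    frequencies: np.ndarray
    gap_fraction: np.ndarray
    information_bits: np.ndarray
    consensus: str
    tie_columns: tuple[int, ...]
    pseudocount: float

    @property
    def n_columns(self) -> int:
        return self.frequencies.shape[0]


def column_profile(
    alignment: OrthologAlignment, pseudocount: float = 0.0
) -> AlignmentProfile:
    """Compute per-column residue frequencies and information content.

    ``pseudocount`` is added to every residue count before normalisation
    (default 0: raw abundances).  With pseudocount 0 an all-gap column would
    be undefined; ingest trims those, and any that slip through raise.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    ncol = alignment.n_columns
    counts = np.zeros((ncol, 20), dtype=float)
    gap = np.zeros(ncol, dtype=float)
    for _, seq in alignment.rows:
        for col, letter in enumerate(seq):
            idx = _AA_INDEX.get(letter)
            if idx is None:
                gap[col] += 1.0
            else:
                counts[col, idx] += 1.0
    totals = counts.sum(axis=1) + 20.0 * pseudocount
    if np.any(totals == 0.0):
        bad = int(np.flatnonzero(totals == 0.0)[0]) + 1
        raise ValueError(
            f"alignment {alignment.name!r}: column {bad} has no canonical residues"
        )
    freqs = (counts + pseudocount) / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0.0, freqs * np.log2(freqs), 0.0)
    entropy = -plogp.sum(axis=1)
    information = MAX_INFORMATION_BITS - entropy

    consensus_chars: list[str] = []
    ties: list[int] = []
    for col in range(ncol):
        best = freqs[col].max()
        # alphabetical tie-break: CANONICAL_AA is sorted, argmax takes first
        winners = np.flatnonzero(np.isclose(freqs[col], best, rtol=0.0, atol=1e-12))
        consensus_chars.append(CANONICAL_AA[winners[0]])
        if len(winners) > 1:
            ties.append(col + 1)
    return AlignmentProfile(
        name=alignment.name,
        n_sequences=alignment.n_sequences,
        frequencies=freqs,
        gap_fraction=gap / alignment.n_sequences,
        information_bits=information,
        consensus="".join(consensus_chars),
        tie_columns=tuple(ties),
        pseudocount=float(pseudocount),
    )


def motif_conservation(
    alignment: OrthologAlignment, rules: MotifRuleSet | None = None
) -> float:
    """Fraction of ortholog rows whose ungapped sequence carries the motif.

    Each aligned row is de-gapped and run through :func:`match_motif`; the
    return value is the matched-row fraction in [0, 1].  Invariant to
    gap-only column insertion by construction.
    """
    if rules is None:
        rules = MotifRuleSet.legend()
    sequences = alignment.ungapped_sequences()
    if not sequences:
        raise ValueError("empty alignment")
    short = [lbl for (lbl, _), s in zip(alignment.rows, sequences) if len(s) < 3]
    if short:
        raise ValueError(f"rows too short after de-gapping (< 3 residues): {short}")
    matched = sum(1 for s in sequences if match_motif(s, rules) != "none")
    return matched / len(sequences)


def logo_matrix(profile: AlignmentProfile, mode: str = "information") -> pd.DataFrame:
    """Letter-height table for a sequence logo, one row per column.

    ``probability`` mode returns the frequencies; ``information`` mode scales
    them by the column's information content, so per-column heights sum to
    the column information.  Index is the 1-based alignment column.
    """
    if mode not in ("probability", "information"):
        raise ValueError(f"mode must be 'probability' or 'information', got {mode!r}")
    heights = profile.frequencies.copy()
    if mode == "information":
        heights *= profile.information_bits[:, None]
    return pd.DataFrame(
        heights,
        index=pd.RangeIndex(1, profile.n_columns + 1, name="column"),
        columns=list(CANONICAL_AA),
    )


def profile_table(profile: AlignmentProfile) -> pd.DataFrame:
    """Serializable per-column table: frequencies, gap fraction, information."""
    df = pd.DataFrame(
        profile.frequencies,
        index=pd.RangeIndex(1, profile.n_columns + 1, name="column"),
        columns=list(CANONICAL_AA),
    )
    df["gap_fraction"] = profile.gap_fraction
    df["information_bits"] = profile.information_bits
    df["consensus"] = list(profile.consensus)
    return df


def plot_logo(profile: AlignmentProfile, mode: str = "information", ax=None):
    """Convenience stacked-bar logo rendering (untested, best-effort).

    Letter heights per column are drawn as stacked bars coloured by residue;
    use the exported :func:`logo_matrix` for faithful downstream plotting.
    """
    import matplotlib.pyplot as plt  # local import: plotting is optional

    heights = logo_matrix(profile, mode=mode)
    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, profile.n_columns * 0.4), 3))
    bottoms = np.zeros(profile.n_columns)
    for aa in CANONICAL_AA:
        vals = heights[aa].to_numpy()
        ax.bar(heights.index, vals, bottom=bottoms, label=aa, width=0.8)
        bottoms += vals
    ax.set_xlabel("alignment column")
    ax.set_ylabel("bits" if mode == "information" else "frequency")
    ax.set_title(profile.name)
    return ax
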