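# Methods

## Processing model

The package models two-step N-terminal maturation of cytosolic precursor
proteins. Methionine aminopeptidase (MAP) removes the initiator Met when the
penultimate residue is small (default set {A, C, G, P, S, T, V}); the
cytosolic dipeptidyl peptidases DPP8/9 then cleave after a proline in
position 2 of the resulting N-terminus, releasing one dipeptide. On the
unprocessed sequence the two observable substrate classes are therefore
`M y P x` (excision route, releases Met then `yP`, mature protein starts at
residue 4) and `M P x` (direct route, releases `MP`, mature protein starts
at residue 3), with `x ≠ P` in both — DPP4-family proteases do not cleave a
Pro-Pro bond.

The screen classifies through these motif patterns directly rather than by
chaining a Met-excision simulation into a dipeptidase simulation. The two
formulations are not equivalent: the canonical MAP small-residue set
contains Pro, so a chained model would excise the Met of `MPx…` sequences
and destroy the direct-route substrate the motif describes.
`met_excision` is therefore exposed as a stand-alone annotation utility
only. A single cleavage round is modelled; no iterative removal of
successive dipeptides.

Two motif variants are first-class because the screen's defining exclusion
set for the variable pre-proline position `y` exists in two forms: the
`legend` variant excludes only Asp, the `text` variant Asp and Glu.
`legend` is the default; `text` matches are a strict subset, and the screen
CLI can report both. Ambiguity letters (X, B, Z, U, J, O) are retained in
sequences but never satisfy a constrained motif position; sequences not
starting with Met classify as non-substrates, not as errors.

## Degron table

The neo-N-terminal residue is mapped to an N-degron branch by a pure lookup
(default: S/T/C/A → Ac/N; R/K/H → Arg/N primary; D/E → secondary; N/Q →
tertiary, noting the deamidation step; G, V, M, P, I, L, F, W, Y →
stabilizing). Placing Gly and Val with the stabilizing residues follows the
observed stabilisation of engineered Gly/Val neo-termini on this pathway's
model substrate, although canonical N-acetyltransferase substrate ranges
would admit other assignments; the table is a config-overridable mapping
precisely because this boundary is convention-dependent. N-terminal
acetylation of the mature protein is recorded as the mechanism note of the
Ac/N branch, not predicted per protein.

## Enrichment statistics

Category over-representation among motif hits is tested one-sided with the
hypergeometric upper tail P(X ≥ k) for X ~ Hypergeom(N, K, n) — standard
for 2×2 over-representation with fixed margins; the scipy survival function
is numerically stable to at least N = 10⁵. Benjamini–Hochberg adjustment is
applied within the compartment family and within the pathway family
separately (few, structurally different categories); raw p-values are
always reported alongside. Categories with zero members are skipped rather
than reported as p = 1. Proteins missing from the annotation table are
counted under compartment `unknown` with no MTS and no pathways, so all
totals match the scanned FASTA.

## Conservation math

Alignments are consumed, not computed: conservation math is independent of
the aligner, and alignment construction is out of scope. Per column,
residue frequencies are computed over the 20 canonical letters with gaps
(and non-canonical letters) excluded from the denominator and their
fraction reported separately — the sequence-logo convention for displaying
residue abundance. Information content is I = log₂20 − H bits (base-2
entropy, 20-letter ceiling, no small-sample correction); the default
pseudocount is 0 so that profiles reflect raw abundances, configurable for
downstream scoring. Information-mode logo heights are frequency × column
information and sum per column to I. Consensus ties break alphabetically
and are flagged with their column indices. Duplicate rows count fully —
every species observation contributes; no phylogenetic weighting is
applied. Motif conservation de-gaps each row and reports the matched-row
fraction, which makes it invariant to gap-column insertion.

## Synthetic data generator

`gen_proteome` draws, per protein: a compartment from the configured
proportions; a length uniform on the configured range (default 60–400
residues; the analysis scripts use 30–80 since only the N-terminus enters
the screen); a sequence i.i.d. from the background distribution (default
uniform over 20 letters); an MTS flag (independent Bernoulli, default 0.6 —
roughly the fraction of mitochondrial proteins with a predicted
presequence); and pathway memberships (independent Bernoullis; the default
pathway emulates a small curated substrate list at 4% membership). With the
protein's effective planting probability — compartment and member-pathway
probabilities combined as 1 − ∏(1 − pᵢ) — the first four residues are
overwritten by a 4-mer drawn uniformly from the 741 canonical 4-mers
matching the legend-variant motif. Accidental motif matches in unplanted
proteins are *kept* and recorded in the truth table, so the analytic
background match rate

    P(match) = p(M)·P(y allowed)·p(P)·(1 − p(P)) + p(M)·p(P)·(1 − p(P))

stays exact (≈ 0.46% under the uniform background). One seeded
`numpy.random.Generator` per call; no global state; identical spec ⇒
byte-identical output.

`gen_ortholog_set` uses a substitution-only model (no indels), so rows are
trivially aligned and the conservation math, not the alignment, is under
test. Non-motif positions are independently replaced by background draws
with the substitution probability (a replacement may equal the original, as
in a symmetric substitution process). The motif block (positions 1–4) is
copied intact with the motif-conservation probability and otherwise redrawn
entirely from the background; redrawing the whole block, rather than
applying the per-position substitution rate to it, keeps the matched-row
fraction an unbiased binomial sample of the conservation probability (up to
the ≈ 0.5% accidental match rate) — under per-position substitution the
motif would frequently survive by chance and the parameter would not be
recoverable.

What the generator does **not** emulate: realistic amino-acid composition
(configurable frequencies stand in for it), sequence-length/compartment
correlations, isoform structure, phylogenetic correlation between species,
and indels. Passing tests therefore demonstrate correctness of the
classification, enrichment and conservation machinery under the generative
assumptions, not performance characteristics on real proteomes — on real
data the hit rate depends on the organism's actual N-terminal composition.

## Numerical and design choices

* 1-based residue numbering throughout ("position 2" is the penultimate
  residue to the initiator).
* Screens of real inventories take one sequence per accession as provided
  in the input FASTA; isoform selection is the caller's curation step, and
  no minimum protein length is imposed beyond the motif's own 3–4 residues.
* TSV/JSON outputs only (UTF-8, `\t`, `\n`), byte-stable for identical
  inputs; spreadsheet conversion is a user step on ingest.
* Monte-Carlo calibration (analysis 04, acceptance script) uses 100 seeds ×
  1,000 proteins with short sequences (30–80 residues), sized so the whole
  calibration completes in seconds while the binomial error on recovered
  fractions stays within the 3σ bounds being checked.
* A small stacked-bar logo plot is provided for convenience only; the
  exported logo matrix is the supported output.

## Known limitations

* The motif describes the DPP8/9 *recognition* site; actual processing in
  cells additionally depends on substrate folding, localisation kinetics
  and protease abundance, none of which are modelled.
* DPP8 and DPP9 are treated as sharing one recognition motif; no
  paralog-specific prediction is attempted.
* Acetylation efficiency of Ac/N substrates and degradation kinetics are
  out of scope; the degron class is a qualitative fate label.
* Compartment and pathway labels are consumed as given; the package does
  not predict targeting sequences or curate localisation.
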