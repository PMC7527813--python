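# dppscan

Prediction of N-terminal processing of mitochondrial precursor proteins by
the cytosolic dipeptidyl peptidases DPP8/9, and of its consequence for
protein stability under the N-degron (N-end rule) pathways.

Many proteins of the mitochondrial intermembrane space (IMS) lack an
N-terminal targeting sequence and are imported slowly. While such precursors
dwell in the cytosol, DPP8/9 can clip a dipeptide off their N-terminus —
these proteases cleave the bond after a proline in position 2 — and the
residue this exposes (the *neo-N-terminus*) decides whether the protein is
routed to proteasomal degradation. `dppscan` implements this logic as a
reusable sequence-analysis pipeline for anyone screening an annotated
proteome for candidate DPP8/9 substrates or studying the conservation of
cleavage sites across species.

## The model

A protein with sequence `s₁s₂s₃s₄…` (1-based, initiator Met at position 1)
is a predicted DPP8/9 substrate if its N-terminus matches either
recognition motif:

* **excision route (`P4`)** — `M y P x`: methionine aminopeptidase removes
  the initiator Met (penultimate residue small), DPP8/9 then release the
  dipeptide `yP`; the mature protein starts at `s₄`. Constraints: `y ∉ {D}`
  (*legend* variant) or `y ∉ {D, E}` (*text* variant), `x ≠ P`.
* **direct route (`P3`)** — `M P x` with `x ≠ P`: DPP8/9 release `MP`
  directly; the mature protein starts at `s₃`.

The two patterns are mutually exclusive, every *text* match is a *legend*
match, and ambiguity letters (X, B, Z, U, J, O) never satisfy a constrained
position. The exposed residue is mapped to an N-degron branch
(overridable table): S/T/C/A → Ac/N-degron (acetylation-dependent),
R/K/H → Arg/N primary, D/E → secondary, N/Q → tertiary (deamidation first),
everything else stabilizing.

Proteome screens are summarised with one-sided hypergeometric
over-representation tests per subcompartment and pathway label
(P(X ≥ k) for X ~ Hypergeom(N, K, n)), Benjamini–Hochberg adjusted within
each family. Conservation of cleavage sites is quantified from pre-computed
ortholog alignments as per-column residue frequencies (gaps excluded from
the denominator), column information content I = log₂20 − H in bits, and
the fraction of species whose de-gapped N-terminus still carries the motif.

A synthetic-data module generates annotated proteomes with planted,
compartment-dependent motif probabilities and substitution-only ortholog
sets with a controlled motif-conservation probability, so every stage is
testable with known ground truth.

## Worked example

```sh
$ dppscan classify MAPSVPAA
{
  "pattern": "P4",
  "route": "map_then_dpp",
  "released": ["M", "AP"],
  "neo_residue": "S",
  "neo_prefix": "SV",
  "degron": "AcN"
}
```

This is the N-terminus of human adenylate kinase 2 (AK2): Met excision
yields the `APS-` intermediate, dipeptide release the mature `S-` protein,
and the serine neo-N-terminus routes cytosolic AK2 into the
acetylation-dependent Ac/N-degron pathway — the processing ladder observed
for AK2 in cells. The full pipeline on synthetic data:

```sh
$ python analysis/01_simulate_inputs.py
proteome: 1000 proteins, 59 planted motifs (45/74 in IMS)
$ python analysis/02_screen_proteome.py
[legend] 66/1000 hits (29 via Met excision, 37 direct)
[legend] hits lacking an N-terminal MTS: 23/66
[legend] most enriched compartment: IMS (45/74 hits, adjusted p = 2.88e-41)
[legend] pathway disulfide_relay_substrate: 16/41 hits, adjusted p = 6.04e-10
$ python analysis/03_conservation_profiles.py
ak2_like_high_conservation: 163 species, consensus N-terminus MAPSVPAA-, motif conserved in 94.5% of species, ...
$ python analysis/04_power_analysis.py
planted IMS detected as top compartment in 100/100 seeds; false alarm under uniform planting in 3/100 seeds
```

The screen recovers every planted motif (66 hits = 59 planted + 7
accidental background matches), flags the compartment that actually carries
the planted enrichment, and the conservation profile of the simulated
163-species ortholog set reproduces its generating parameters. To screen
real data, point the CLI at your own files:

```sh
dppscan screen --fasta proteome.fasta --annotations annotations.tsv --variant both --out out/
dppscan logo --alignment orthologs.fasta --mode information --out logo/
```

The annotation TSV needs columns `id`, `compartment`
(matrix/IMS/IMM/OMM/membrane/unknown), `has_n_terminal_mts` and optionally
`symbol` and semicolon-separated `pathways`.

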