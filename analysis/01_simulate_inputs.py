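#!/usr/bin/env python
"""Generate the study inputs: a planted synthetic proteome and ortholog sets.

The proteome has 1,000 proteins with a MitoCarta-like compartment mix and a
planted DPP8/9 motif probability of 0.5 in the IMS (background elsewhere),
emulating the structure the real screen assumes.  Ortholog sets are built
for an AK2-like N-terminus at two conservation levels.  Everything is
written under results/sim/ in the package's standard formats.
"""

from pathlib import Path

from dppscan import (
    CompartmentSpec,
    OrthologSpec,
    PathwaySpec,
    SyntheticSpec,
    gen_ortholog_set,
    gen_proteome,
    write_alignment_fasta,
    write_annotation_table,
    write_fasta,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "sim"

SPEC = SyntheticSpec(
    n_proteins=1000,
    length_range=(30, 80),
    compartments=(
        CompartmentSpec("matrix", 0.45, 0.0),
        CompartmentSpec("IMM", 0.27, 0.0),
        CompartmentSpec("IMS", 0.08, 0.5),
        CompartmentSpec("OMM", 0.10, 0.0),
        CompartmentSpec("membrane", 0.05, 0.0),
        CompartmentSpec("unknown", 0.05, 0.0),
    ),
    pathways=(PathwaySpec("disulfide_relay_substrate", 0.04, 0.5),),
    seed=20200820,
)

ORTHOLOG_SPECS = {
    "ak2_like_high_conservation": OrthologSpec(
        base_sequence="MAPSVPAAEPEYPKGIRAVLLGPPGA",
        n_species=163,
        substitution_probability=0.1,
        motif_conservation_probability=0.95,
        name="ak2_like_high_conservation",
        seed=163,
    ),
    "relay_like_moderate_conservation": OrthologSpec(
        base_sequence="MPGLVDSNPAPPESQEKKPLKPCCAC",
        n_species=11,
        substitution_probability=0.2,
        motif_conservation_probability=0.7,
        name="relay_like_moderate_conservation",
        seed=11,
    ),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    records, annotations, truth = gen_proteome(SPEC)
    write_fasta(records, OUT / "proteome.fasta")
    write_annotation_table(annotations, OUT / "annotations.tsv")
    truth.to_csv(OUT / "truth.tsv", sep="\t", index=False, lineterminator="\n")
    n_planted = int(truth["planted"].sum())
    ims = truth[truth["compartment"] == "IMS"]
    print(
        f"proteome: {len(records)} proteins, {n_planted} planted motifs "
        f"({int(ims['planted'].sum())}/{len(ims)} in IMS)"
    )
    for key, spec in ORTHOLOG_SPECS.items():
        aln = gen_ortholog_set(spec)
        write_alignment_fasta(aln, OUT / f"{key}.fasta")
        print(f"orthologs[{key}]: {aln.n_sequences} species x {aln.n_columns} columns")


if __name__ == "__main__":
    main()
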