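#!/usr/bin/env python
"""Profile the simulated ortholog alignments: logos, consensus, conservation.

For each alignment from 01_simulate_inputs.py, exports the per-column
frequency/information table and the information-mode logo matrix under
results/conservation/, and reports the consensus N-terminus and the fraction
of species whose N-terminus still carries the DPP8/9 motif.
"""

import json
from pathlib import Path

from dppscan import (
    column_profile,
    logo_matrix,
    motif_conservation,
    profile_table,
    read_alignment_fasta,
)

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    out_dir = BASE / "conservation"
    out_dir.mkdir(parents=True, exist_ok=True)
    aln_paths = [p for p in sorted((BASE / "sim").glob("*.fasta")) if p.name != "proteome.fasta"]
    for aln_path in aln_paths:
        alignment = read_alignment_fasta(aln_path)
        profile = column_profile(alignment)
        name = alignment.name
        profile_table(profile).to_csv(out_dir / f"{name}_profile.tsv", sep="\t", lineterminator="\n")
        logo_matrix(profile, mode="information").to_csv(
            out_dir / f"{name}_logo_information.tsv", sep="\t", lineterminator="\n"
        )
        conserved = motif_conservation(alignment)
        meta = {
            "name": name,
            "n_sequences": profile.n_sequences,
            "consensus_nterm": profile.consensus[:8],
            "motif_conservation": conserved,
            "nterm_information_bits": [round(float(b), 3) for b in profile.information_bits[:4]],
        }
        with open(out_dir / f"{name}_summary.json", "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=2)
            fh.write("\n")
        print(
            f"{name}: {profile.n_sequences} species, consensus N-terminus "
            f"{meta['consensus_nterm']}-, motif conserved in {conserved:.1%} of species, "
            f"N-terminal column information {meta['nterm_information_bits']} bits"
        )


if __name__ == "__main__":
    main()
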