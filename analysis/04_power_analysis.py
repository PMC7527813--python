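#!/usr/bin/env python
"""Monte-Carlo calibration of the enrichment screen on planted proteomes.

Over 100 fixed seeds at 1,000 proteins each: (a) with motif planting
probability 0.5 in the IMS only, how often does the screen rank the IMS as
the most enriched compartment (detection power); (b) with planting 0.5 in
every compartment (a true null), how often does any Benjamini-Hochberg
adjusted p-value fall below 0.05 (type-I rate)?  Writes results/power.json.
"""

import json
from pathlib import Path

from dppscan import (
    CompartmentSpec,
    SyntheticSpec,
    gen_proteome,
    scan_proteome,
    summarize_screen,
)

BASE = Path(__file__).resolve().parents[1] / "results"


def spec(p_ims: float, p_other: float, seed: int) -> SyntheticSpec:
    return SyntheticSpec(
        n_proteins=1000,
        length_range=(30, 80),
        compartments=(
            CompartmentSpec("matrix", 0.45, p_other),
            CompartmentSpec("IMM", 0.27, p_other),
            CompartmentSpec("IMS", 0.08, p_ims),
            CompartmentSpec("OMM", 0.10, p_other),
            CompartmentSpec("membrane", 0.05, p_other),
            CompartmentSpec("unknown", 0.05, p_other),
        ),
        pathways=(),
        seed=seed,
    )


def main() -> None:
    detected = 0
    alarms = 0
    for seed in range(100):
        records, annotations, _ = gen_proteome(spec(0.5, 0.0, seed))
        df = summarize_screen(scan_proteome(records), annotations).by_compartment
        detected += int(df.loc[df["p_adjusted"].idxmin(), "category"] == "IMS")

        records, annotations, _ = gen_proteome(spec(0.5, 0.5, seed))
        df = summarize_screen(scan_proteome(records), annotations).by_compartment
        alarms += int((df["p_adjusted"] < 0.05).any())

    payload = {
        "n_seeds": 100,
        "n_proteins": 1000,
        "detection_power_percent": detected,
        "type_i_rate_percent": alarms,
    }
    BASE.mkdir(parents=True, exist_ok=True)
    with open(BASE / "power.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
    print(
        f"planted IMS detected as top compartment in {detected}/100 seeds; "
        f"false alarm under uniform planting in {alarms}/100 seeds"
    )


if __name__ == "__main__":
    main()
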