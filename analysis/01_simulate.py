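#!/usr/bin/env python
"""Build the synthetic six-paralog cohort used by the downstream analyses.

The cohort emulates the ferlin C2-domain situation: six Type-II beta-sandwich
paralogs, five of which carry a conserved helix-rich insertion in the beta6-7
loop (one paralog lacks it, mirroring how single family members can miss a
subdomain), and one of which additionally carries a beta1-2 loop insertion on
the pocket face.  Everything is seeded; PDB + FASTA + ground truth land in
results/sim/.
"""

import json
from pathlib import Path

from c2map import synth
from c2map.structure import write_structure

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"
SEED = 2026

COHORT = {
    # paralog -> loop insertions (length, secondary-structure class)
    "paralog_a": {"b6-7": (30, "helix"), "b1-2": (25, "coil")},
    "paralog_b": {"b6-7": (30, "helix")},
    "paralog_c": {"b6-7": (32, "helix")},
    "paralog_d": {},                      # the family member lacking it
    "paralog_e": {"b6-7": (28, "helix")},
    "paralog_f": {"b6-7": (60, "helix")},  # the long-insertion extreme
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ref, ref_truth = synth.build_sandwich(
        synth.SandwichSpec(seed=SEED, noise_sigma=0.0))
    write_structure(ref, OUT / "reference.pdb")
    (OUT / "reference.truth.json").write_text(json.dumps(
        {"boundary": ref_truth.boundary, "topology": ref_truth.topology}))

    for k, (name, insertions) in enumerate(COHORT.items(), start=1):
        spec = synth.SandwichSpec(seed=SEED + k, noise_sigma=0.1,
                                  insertions=insertions)
        s, truth = synth.build_sandwich(spec)
        write_structure(s, OUT / f"{name}.pdb")
        (OUT / f"{name}.fasta").write_text(f">{name}\n{truth.sequence}\n")
        (OUT / f"{name}.truth.json").write_text(json.dumps({
            "topology": truth.topology,
            "boundary": list(truth.boundary),
            "strands": [list(x) for x in truth.strands],
            "insertions": [[l, ln, list(iv), cls]
                           for l, ln, iv, cls in truth.insertions],
            "ss": truth.ss,
        }, indent=2))
        print(f"{name}: {s.n_residues()} residues, "
              f"insertions {sorted(insertions) or 'none'}")
    print(f"cohort written to {OUT}")


if __name__ == "__main__":
    main()
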