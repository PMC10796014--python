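#!/usr/bin/env python
"""Polymer N-acetylation study: how subsite preferences shape block structure.

N-acetylates polyglucosamine (dp 2000) with the three enzyme presets (nm,
H199K, H199Y), digests snapshots at F_A 0.1–0.5 with the in silico
chitinosanase, and tabulates weight-average block sizes and the oligomeric
fraction against a Bernoulli random control.

Writes results/polymer_blocks.csv (per profile × seed × F_A) and
results/polymer_summary.csv (means per profile × F_A) and prints the
F_A 0.3 cross-enzyme comparison.
"""

from pathlib import Path

from chitosim.workflows import run_polymer_workflow, write_manifest

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table = run_polymer_workflow(
        profiles=["nm", "H199K", "H199Y"],
        dp=2000,
        checkpoints=(0.1, 0.2, 0.3, 0.4, 0.5),
        n_seeds=20,
        seed=1,
    )
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "polymer_blocks.csv", index=False)
    summary = (
        table.groupby(["profile", "fa"])
        [["blockA_w", "blockD_w", "blockA_w_all", "oligomeric_fraction"]]
        .mean()
        .round(3)
    )
    summary.to_csv(OUT / "polymer_summary.csv")
    write_manifest(OUT, {"script": "01_polymer_patterns", "dp": 2000,
                         "n_seeds": 20, "seed": 1})

    at03 = summary.xs(0.3, level="fa")
    print("Weight-average A-block size at F_A 0.3 (all interior fragments):")
    print(at03["blockA_w_all"].sort_values(ascending=False).to_string())
    print("\nOligomeric fraction (DP 2-14 share) at F_A 0.3:")
    print(at03["oligomeric_fraction"].sort_values().to_string())
    print(
        "\nFinding: GlcNAc preference at subsites -2/-1 (nm, stronger in "
        "H199K) builds large A-blocks that resist chitinosanase digestion; "
        "GlcN acceptance at -1 (H199Y) yields near-alternating chains that "
        "digest almost completely into short oligomers."
    )


if __name__ == "__main__":
    main()
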