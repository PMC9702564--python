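#!/usr/bin/env python
"""Generate the synthetic GWAS study: three reproductive-timing exposures
(AAM, ANM, AFB scale), four shared osteoarthritis outcome GWAS tables, a
BMI-like confounder GWAS and the pairwise-LD table, all with known ground
truth.

Writes plain TSVs under results/sim/ that the downstream scripts read back
through the summary-statistics I/O layer, exactly as they would real files.
"""

from pathlib import Path

import pandas as pd

from reprocausal.synth_gwas import simulate_study

SEED = 7
OUT = Path(__file__).resolve().parent.parent / "results" / "sim"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    study = simulate_study(seed=SEED)

    for name, table in {**study.exposures, **study.outcomes}.items():
        table.df.to_csv(OUT / f"{name}.tsv", sep="\t", index=False)
        print(f"{name}: {len(table)} variants -> {name}.tsv")
    study.confounder.df.to_csv(OUT / "BMI.tsv", sep="\t", index=False)
    print(f"BMI: {len(study.confounder)} variants -> BMI.tsv")

    ld_rows = [(a, b, r2) for (a, b), r2 in study.ld._r2.items()]
    pd.DataFrame(ld_rows, columns=["variant_id_a", "variant_id_b", "r2"]).to_csv(
        OUT / "ld.tsv", sep="\t", index=False
    )
    print(f"LD: {len(ld_rows)} pairs -> ld.tsv")

    truth = pd.concat(
        [t.snps.assign(exposure=name) for name, t in study.truths.items()],
        ignore_index=True,
    )
    truth.to_csv(OUT / "truth.tsv", sep="\t", index=False)
    print(f"ground truth: {len(truth)} SNPs -> truth.tsv (seed {SEED})")


if __name__ == "__main__":
    main()
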