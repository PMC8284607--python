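#!/usr/bin/env python
"""96-channel substitution spectra, six-type percentages, the POLE
discriminator, and the observed-vs-expected genomic region distribution.

Consumes the genome, variant tables and GFF3 written by
01_simulate_inputs.py. Writes results/spectrum_{p287r,wt}.tsv,
results/six_type_percentages.tsv and results/region_distribution.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from mutacc.genome_io import read_fasta, read_gff_regions, read_variants
from mutacc.spectrum import (
    build_spectrum,
    pole_discriminator,
    region_distribution,
    six_type_percentages,
    write_spectrum_tsv,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 17) -> None:
    inputs = RESULTS / "inputs"
    if not (inputs / "genome.fa").exists():
        raise SystemExit("run analysis/01_simulate_inputs.py first")
    genome = read_fasta(inputs / "genome.fa")

    six_rows = []
    for strain in ("p287r", "wt"):
        records = read_variants(inputs / f"{strain}_snvs.tsv", "tsv")
        spec = build_spectrum(records, genome)
        write_spectrum_tsv(spec, RESULTS / f"spectrum_{strain}.tsv")
        six = six_type_percentages(spec)
        six_rows.append({"strain": strain, **{k: round(v, 1) for k, v in six.pct.items()}})
        top = spec.to_frame().nlargest(3, "count")
        print(f"{strain}: {spec.n_mutations} SNVs; top channels: "
              + ", ".join(f"{r.channel} ({r.count})" for r in top.itertuples()))
        verdict, report = pole_discriminator(six)
        crit = "; ".join(
            f"{r['type']} {r['value']:.1f}% {'PASS' if r['passed'] else 'fail'}"
            for r in report
        )
        print(f"  POLE discriminator: {crit} -> {'POLE-like' if verdict else 'not POLE-like'}")
    pd.DataFrame(six_rows).to_csv(RESULTS / "six_type_percentages.tsv",
                                  sep="\t", index=False)

    annotation = read_gff_regions(inputs / "regions.gff3", genome)
    records = read_variants(inputs / "p287r_snvs.tsv", "tsv")
    dist = region_distribution(records, annotation)
    dist.to_frame().to_csv(RESULTS / "region_distribution.tsv", sep="\t", index=False)
    print("\nregion distribution of hypermutator SNVs (observed vs expected %):")
    print(dist.to_frame().to_string(index=False, float_format=lambda x: f"{x:.1f}"))


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=17)
    main(ap.parse_args().seed)
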