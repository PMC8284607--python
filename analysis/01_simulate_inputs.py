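#!/usr/bin/env python
"""Generate the synthetic study inputs every later analysis step consumes.

Writes, under results/inputs/:
  * genome.fa               — 200 kb AT-rich (64% A+T) random genome,
                              emulating fission-yeast base composition
  * p287r_snvs.tsv          — 1073 SNVs drawn from the hypermutator-like
                              signature (C>A-in-TCT dominated)
  * wt_snvs.tsv             — 746 SNVs drawn from a flat signature
  * fluctuation_counts.tsv  — mutant colony counts for wt / exonull /
                              P287R-like strains (960 cultures each) at the
                              70x / 14x rate structure
  * regions.gff3            — a toy region annotation covering the genome
"""

import argparse
from pathlib import Path

from mutacc.genome_io import write_fasta, write_variants_tsv
from mutacc.simulate import (
    flat_signature,
    pole_like_signature,
    pombe_like_genome,
    strain_fluctuation_experiments,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"


def main(seed: int = 17) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome = pombe_like_genome(length=200_000, seed=seed)
    write_fasta(genome, OUT / "genome.fa")
    seq = genome["sim_1"]
    at = (seq.count("A") + seq.count("T")) / len(seq)
    print(f"genome: 200 kb, A+T = {100*at:.1f}%")

    from mutacc.simulate import simulate_mutations

    p287r = simulate_mutations(genome, pole_like_signature(), 1073,
                               seed=seed + 1, sample="p287r")
    write_variants_tsv(p287r, OUT / "p287r_snvs.tsv")
    wt = simulate_mutations(genome, flat_signature(), 746,
                            seed=seed + 2, sample="wt")
    write_variants_tsv(wt, OUT / "wt_snvs.tsv")
    print(f"variants: {len(p287r)} hypermutator SNVs, {len(wt)} wild-type-like SNVs")

    exps = strain_fluctuation_experiments(n_cultures=960, epsilon=1.0, seed=seed)
    with open(OUT / "fluctuation_counts.tsv", "w") as fh:
        fh.write("strain\tcount\n")
        for strain, exp in exps.items():
            for c in exp.counts:
                fh.write(f"{strain}\t{c}\n")
    zero = {s: sum(c == 0 for c in e.counts) / len(e.counts) for s, e in exps.items()}
    print("fluctuation cultures per strain: 960; zero-count fraction:",
          {s: round(f, 3) for s, f in zero.items()})

    # toy annotation: alternating CDS (60%), intron (10%), rest intergenic
    with open(OUT / "regions.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        block = 1000
        pos = 1
        while pos + block <= len(seq):
            fh.write(f"sim_1\tsim\tCDS\t{pos}\t{pos + 599}\t.\t+\t.\tID=cds{pos}\n")
            fh.write(f"sim_1\tsim\tintron\t{pos + 600}\t{pos + 699}\t.\t+\t.\tID=int{pos}\n")
            pos += block
        print(f"annotation: {pos // block} CDS/intron blocks written")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=17)
    main(ap.parse_args().seed)
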