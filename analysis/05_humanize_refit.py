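#!/usr/bin/env python
"""Humanization of the yeast-genome spectra and comparison to a signature
catalog: cosine similarities (0.80 "high" threshold), clustering order,
and non-negative exposure refitting.

The catalog here is synthetic (the generating hypermutator-like signature,
humanized, plus Dirichlet-random fillers); a real COSMIC v3.x SBS file is
a drop-in replacement via mutacc.signatures.read_signature_catalog.

Writes results/cosine_similarities.tsv and results/exposures_p287r.tsv.
"""

import argparse
from pathlib import Path

from mutacc.genome_io import read_fasta, read_variants, trinucleotide_frequencies
from mutacc.humanize import humanize_pattern, load_synthetic_human_exome_freqs
from mutacc.signatures import refit_exposures, similarity_matrix
from mutacc.simulate import make_catalog, pole_like_signature
from mutacc.spectrum import Spectrum96, build_spectrum

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 17) -> None:
    inputs = RESULTS / "inputs"
    if not (inputs / "genome.fa").exists():
        raise SystemExit("run analysis/01_simulate_inputs.py first")
    genome = read_fasta(inputs / "genome.fa")
    source = trinucleotide_frequencies(genome)
    target = load_synthetic_human_exome_freqs()

    spectra = {}
    for strain in ("p287r", "wt"):
        records = read_variants(inputs / f"{strain}_snvs.tsv", "tsv")
        spec = build_spectrum(records, genome, normalized=True)
        spectra[strain] = humanize_pattern(spec, source, target)

    generating = humanize_pattern(
        Spectrum96(pole_like_signature(), normalized=True), source, target
    )
    catalog = make_catalog(n_random=5, seed=seed, include={"POLE_like": generating.values})

    res = similarity_matrix(spectra, catalog)
    res.matrix.to_csv(RESULTS / "cosine_similarities.tsv", sep="\t")
    print("cosine similarities (catalog in clustering order):")
    print(res.matrix[list(res.leaf_order)].round(3).to_string())
    for hit in res.best_hits.itertuples():
        flag = "HIGH (>=0.80)" if hit.high else "below threshold"
        print(f"  {hit.spectrum}: best {hit.signature} at {hit.similarity:.2f} [{flag}]")

    exp = refit_exposures(spectra["p287r"], catalog, min_weight=0.01)
    exp.to_frame().to_csv(RESULTS / "exposures_p287r.tsv", sep="\t", index=False)
    pcts = {k: round(float(v), 1) for k, v in exp.as_percentages().items() if v > 0}
    print(f"\nP287R exposure refit (weights >1%): {pcts}; "
          f"reconstruction cosine {exp.residual_cosine:.4f}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=17)
    main(ap.parse_args().seed)
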