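"""Cross-genome "humanization" of mutation spectra.

A 96-channel spectrum observed in one genome reflects both the mutational
process and that genome's trinucleotide composition. Reweighting each
channel by the ratio of target-genome to source-genome frequency of its
flanking trinucleotide, then renormalizing, makes spectra from genomes
with different composition (e.g. the AT-rich fission yeast genome vs the
human exome) directly comparable.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np

from .genome_io import TrinucFrequencies, read_trinuc_table
from .spectrum import CHANNEL_TRINUC_INDEX, Spectrum96

#: Synthetic stand-in for a human-exome trinucleotide frequency table
#: (see file header); a real table is a drop-in replacement.
SYNTHETIC_HUMAN_EXOME_TABLE = "human_exome_trinuc_synthetic.tsv"


def load_synthetic_human_exome_freqs() -> TrinucFrequencies:
    """Load the bundled synthetic exome-like trinucleotide frequency table."""
    with resources.as_file(
        resources.files("mutacc.data").joinpath(SYNTHETIC_HUMAN_EXOME_TABLE)
    ) as path:
        return read_trinuc_table(Path(path))


def _reweight(spectrum: Spectrum96, ratios: np.ndarray) -> Spectrum96:
    values = spectrum.proportions()
    channel_ratio = ratios[CHANNEL_TRINUC_INDEX]
    if np.any((values > 0) & ~np.isfinite(channel_ratio)):
        raise ValueError(
            "zero source/target trinucleotide frequency for a channel with "
            "nonzero mass: correction undefined"
        )
    out = np.where(values > 0, values * channel_ratio, 0.0)
    total = out.sum()
    if total == 0:
        raise ValueError("all-zero spectrum after reweighting")
    return Spectrum96(out / total, normalized=True, n_mutations=spectrum.n_mutations)


def normalize_by_trinuc(
    spectrum: Spectrum96, source_freqs: TrinucFrequencies
) -> Spectrum96:
    """Divide each channel by its context frequency in the source genome
    and renormalize: the composition-free "mutational pattern"."""
    src = source_freqs.as_vector()
    with np.errstate(divide="ignore"):
        ratios = np.where(src > 0, 1.0 / np.where(src > 0, src, 1.0), np.inf)
    return _reweight(spectrum, ratios)


def humanize_pattern(
    spectrum: Spectrum96,
    source_freqs: TrinucFrequencies,
    target_freqs: TrinucFrequencies,
) -> Spectrum96:
    """Rescale each channel by target/source context-frequency ratio and
    renormalize once at the end.

    Equivalent to :func:`normalize_by_trinuc` followed by multiplication
    with the target frequencies (renormalization commutes). Zero channels
    stay zero; a nonzero channel whose context has zero frequency in either
    table is an error.
    """
    src = source_freqs.as_vector()
    tgt = target_freqs.as_vector()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where((src > 0) & (tgt > 0), tgt / np.where(src > 0, src, 1.0), np.inf)
    ratios = np.where((tgt == 0) & (src == 0), np.inf, ratios)
    return _reweight(spectrum, ratios)
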