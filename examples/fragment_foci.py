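"""Locate fragment-pileup foci and classify direct vs nucleosomal binding.

Simulates paired-end fragments around planted foci in two length regimes
(mean 80 bp = direct DNA binding, mean 150 bp = nucleosomal binding),
finds each focus as a local maximum of per-base fragment overlap, and
classifies it by the mean size of covering fragments (<100 bp direct,
>120 bp nucleosomal).
"""

import tempfile
from pathlib import Path

import pandas as pd

from chromswitch import SimulationConfig, find_all_foci
from chromswitch.core_io import read_fragments, read_peaks
from chromswitch.fragment_echo import summarize_modes
from chromswitch.synthetic_data import simulate_fragments

with tempfile.TemporaryDirectory() as tmp:
    cfg = SimulationConfig(seed=3, n_direct_foci=6, n_nucleosomal_foci=6,
                           fragments_per_focus=500)
    paths = simulate_fragments(cfg, Path(tmp))
    fragments = read_fragments(paths["fragments"])
    peaks = read_peaks(paths["peaks"])
    truth = pd.read_csv(paths["truth"], sep="\t")

foci = find_all_foci(fragments, peaks, min_support=50)
print(f"fragments: {len(fragments)}, peaks: {len(peaks)}, foci found: {len(foci)}")
for focus, row in zip(foci, truth.itertuples()):
    print(f"  {focus.chrom}:{focus.position}  n={focus.n_fragments}  "
          f"mean size {focus.mean_fragment_size:6.1f} bp  -> {focus.mode} "
          f"(planted {row.mode}, mu={row.mu:g})")

summary = summarize_modes(foci, dict(zip(truth["name"], truth["mode"])))
print("\nper-group fragment-size summary:")
print(summary[["group", "n_foci", "mean_size", "median_size"]].round(1).to_string(index=False))
# Short protected footprints indicate the TF contacts open DNA directly;
# mononucleosome-sized fragments indicate binding to nucleosomal DNA.
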