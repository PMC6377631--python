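"""Recombination landscape: cM/Mb tracks, hot regions, arm and gene profiles.

Builds windowed cM/Mb maps for both populations, calls hot and
sex-preferred hot regions, normalizes CO positions by chromosome arm, and
profiles CO-to-gene distances against a simulated uniform null.
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]

from gametoco import io as gio
from gametoco.co_landscape import (
    arm_normalize,
    gene_distance_profile,
    genetic_map,
    hot_regions,
)

SYNTH = ROOT / "results" / "synth"
CALLS = ROOT / "results" / "calls"
OUT = ROOT / "results" / "landscape"
OUT.mkdir(parents=True, exist_ok=True)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 20260920
WINDOW = 150_000  # 3 Mb at study scale (1/21 genome)

sizes = gio.read_chrom_table(SYNTH / "chrom_sizes.tsv")
cens = gio.read_chrom_table(SYNTH / "centromeres.tsv")
genes = gio.read_genes_bed(SYNTH / "genes.bed")

tracks = {}
for name in ("female", "male"):
    cos = gio.read_co_calls(CALLS / f"co_calls_{name}.tsv")
    track = genetic_map(cos, sizes, window_bp=WINDOW)
    tracks[name] = (cos, track)
    gio.write_maptrack_bedgraph(track, OUT / f"map_{name}.bedgraph")
    mean_cos = len(cos.calls) / cos.n_samples
    print(f"{name}: total map {track.total_cm:.1f} cM "
          f"(= 50 x {mean_cos:.2f} COs/gamete), "
          f"{track.total_cm / (sum(sizes.values()) / 1e6):.3f} cM/Mb genome-wide")

(f_cos, f_track), (m_cos, m_track) = tracks["female"], tracks["male"]
print(f"female/male map-length ratio: {f_track.total_cm / m_track.total_cm:.2f}")

# the simulated genome carries full-genome CO counts on 1/21 of the
# physical length, so the study-scale 1 cM/Mb hot threshold scales by the
# genome compression factor
HOT = 1.0 * (2_106_000_000 / sum(sizes.values()))
hot = hot_regions(f_track, m_track, hot_cm_per_mb=HOT, fold=2.0)
gio.write_hot_regions_bed(hot, OUT / "hot_regions.bed")
lab = hot.regions["label"].value_counts().to_dict()
print(f"hot regions: {len(hot.regions)} total; "
      f"female-preferred {lab.get('a_preferred', 0)}, "
      f"male-preferred {lab.get('b_preferred', 0)}, shared {lab.get('shared', 0)}")

for name, (cos, track) in tracks.items():
    hot_windows = track.windows[track.windows["cm_per_mb"] > HOT]
    keys = set(map(tuple, hot_windows[["chrom", "start"]].to_numpy()))
    in_hot = 0
    for _, r in cos.calls.iterrows():
        w = (r["chrom"], int(r["midpoint"] // WINDOW) * WINDOW)
        in_hot += w in keys
    print(f"{name}: {len(hot_windows)} hot windows contain "
          f"{100 * in_hot / len(cos.calls):.2f}% of COs")
    arm = arm_normalize(cos, cens, sizes)
    arm.to_csv(OUT / f"arm_positions_{name}.tsv", sep="\t", index=False)
    prof = gene_distance_profile(cos, genes, sizes, n_null=5, seed=SEED,
                                 max_width_bp=10_000)
    pd.DataFrame(dict(observed=prof.observed)).to_csv(
        OUT / f"gene_distance_{name}.tsv", sep="\t", index=False
    )
    print(f"{name}: gene-distance KS stat {prof.ks_statistic:.3f} "
          f"(p = {prof.ks_pvalue:.2e}) over {len(prof.observed)} fine-mapped COs")
print(f"wrote {OUT}")
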