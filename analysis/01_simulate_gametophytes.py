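"""Simulate female- and male-like single-gametophyte populations.

Generates one synthetic maize-like genome model (scaled to desk size) and
two gamete populations driven by the fitted female/male Beam-Film presets,
with residual-heterozygosity and false-short-bin artifacts injected, then
writes genotype matrices, truth sets and genome annotation under
results/synth/.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]

from gametoco import io as gio
from gametoco.presets import ZS_FEMALE, ZS_MALE
from gametoco.synthetic_data import (
    GenomeConfig,
    inject_artifacts,
    make_genome_model,
    simulate_gametes,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 20260920

OUT = ROOT / "results" / "synth"
OUT.mkdir(parents=True, exist_ok=True)

cfg = GenomeConfig(
    n_chromosomes=10,
    total_bp=100_000_000,  # maize-proportional lengths at 1/21 scale
    snp_median_spacing=730.0,  # keeps ~137k SNPs; the study's 73 bp spacing
    genes_per_mb=30.0,  # at full scale would give ~1.4M informative SNPs
)
model = make_genome_model(cfg, seed=SEED)
(OUT / "model.json").write_text(model.to_json() + "\n")
gio.write_genes_bed(model.genes, OUT / "genes.bed")
gio.write_chrom_table(model.chrom_sizes, OUT / "chrom_sizes.tsv")
gio.write_chrom_table(model.centromeres, OUT / "centromeres.tsv")

populations = {
    # female embryo sacs: more input DNA -> higher coverage (40%)
    "female": (ZS_FEMALE, 106, 0.60),
    # male microspores: single-copy MDA -> lower coverage (29%)
    "male": (ZS_MALE, 96, 0.71),
}
for name, (params, n, missing) in populations.items():
    truth, geno = simulate_gametes(model, params, n_gametes=n,
                                   seed=SEED + hash(name) % 1000,
                                   missing_rate=missing)
    geno, truth = inject_artifacts(
        geno, truth,
        shared_segment_samples=6, shared_segment_snps=60,
        false_bin_rate=0.05, false_bin_snps=25,
        seed=SEED + 5,
    )
    gio.write_genotypes(geno, OUT / f"genotypes_{name}.tsv")
    truth.truth.to_csv(OUT / f"truth_{name}.tsv", sep="\t", index=False)
    with open(OUT / f"artifacts_{name}.json", "w") as fh:
        json.dump(truth.artifact_log, fh, indent=2, default=str)
    per_gamete = truth.truth.groupby("gamete").size()
    print(f"{name}: {n} gametes, {len(truth.truth)} true COs "
          f"({per_gamete.mean():.1f} per gamete), "
          f"{len(geno.calls):,} SNP calls, "
          f"{len(truth.artifact_log)} artifact injections")
print(f"wrote {OUT}")
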