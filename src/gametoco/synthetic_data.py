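"""Synthetic single-gametophyte data with known crossover truth.

Generates a maize-like genome model (chromosomes, informative SNPs, genes,
a telomere-inflated genetic<->physical map), simulates gametes whose COs
come from the Beam-Film simulator, renders them as sparse parental SNP
calls with i.i.d. dropout, and optionally injects the two artifact types
the calling pipeline must handle: residual-heterozygosity shared bins and
false short bins.

The default configuration mirrors the study's downstream data structure at
desk scale: 10 chromosomes with maize-proportional lengths (100 Mb total by
default), SNPs at 73 bp median spacing (~1.4M SNPs), ~40% per-sample SNP
coverage (missing rate 0.6), and 100 gametes.  Tests and the analysis
drivers use smaller configurations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bf_sim import BFParams, simulate_bivalents, to_chromatid
from .co_landscape import GenotypeMatrix, MISSING

__all__ = [
    "GenomeConfig",
    "GenomeModel",
    "TruthSet",
    "make_genome_model",
    "simulate_gametes",
    "inject_artifacts",
]

# B73 chromosome lengths (Mb), used as relative proportions
_MAIZE_PROPORTIONS = np.array(
    [307.0, 244.4, 235.7, 247.0, 223.9, 174.0, 182.4, 181.1, 159.8, 150.9]
)


@dataclass
class GenomeConfig:
    n_chromosomes: int = 10
    total_bp: int = 100_000_000
    snp_median_spacing: float = 73.0
    genes_per_mb: float = 30.0
    gene_mean_len: float = 3000.0
    centromere_frac: float = 0.45  # centromere midpoint as fraction of length
    centromere_half_width: float = 0.01  # fraction of chromosome length
    telomere_shape: float = 3.0  # 0 = uniform cM/Mb; larger inflates telomeres
    cm_per_chromosome: float = 100.0

    def chrom_lengths(self) -> np.ndarray:
        props = _MAIZE_PROPORTIONS[: self.n_chromosomes]
        if self.n_chromosomes > len(_MAIZE_PROPORTIONS):
            props = np.resize(_MAIZE_PROPORTIONS, self.n_chromosomes)
        return np.round(props / props.sum() * self.total_bp).astype(np.int64)


@dataclass
class GenomeModel:
    """Chromosomes, SNPs, genes and the genetic<->physical map."""

    chrom_sizes: dict  # chrom -> length bp
    centromeres: dict  # chrom -> (cen_start, cen_end)
    snp_positions: dict  # chrom -> sorted int positions (1-based)
    genes: pd.DataFrame  # chrom, start, end, gene_id
    map_knots: dict  # chrom -> (phys array, genetic-fraction array), monotone
    cm_totals: dict  # chrom -> total cM

    def genetic_to_physical(self, chrom: str, frac) -> np.ndarray:
        """Invert the map: genetic fraction in [0,1] -> physical bp."""
        phys, gen = self.map_knots[chrom]
        return np.interp(np.asarray(frac, dtype=float), gen, phys)

    def physical_to_genetic(self, chrom: str, pos) -> np.ndarray:
        phys, gen = self.map_knots[chrom]
        return np.interp(np.asarray(pos, dtype=float), phys, gen)

    def to_json(self) -> str:
        return json.dumps(
            dict(
                chrom_sizes=self.chrom_sizes,
                centromeres={c: list(v) for c, v in self.centromeres.items()},
                cm_totals=self.cm_totals,
                n_snps={c: int(len(p)) for c, p in self.snp_positions.items()},
                n_genes=int(len(self.genes)),
            ),
            sort_keys=True,
        )


@dataclass
class TruthSet:
    """True CO positions per gamete plus the generating conditions."""

    truth: pd.DataFrame  # gamete, chrom, genetic_frac, pos, co_class
    params: BFParams
    seed: int
    missing_rate: float
    artifact_log: list = field(default_factory=list)


def make_genome_model(config: GenomeConfig | None = None, seed: int = 0) -> GenomeModel:
    """Build a synthetic genome model.

    SNP spacings are exponential with the configured median (median of
    Exp(scale) = scale*ln2); genes are non-overlapping random intervals;
    the genetic map allocates more cM/Mb near telomeres with density
    ``1 + shape*(2x-1)^2`` along the normalized chromosome.
    """
    if config is None:
        config = GenomeConfig()
    if config.n_chromosomes < 1:
        raise ValueError("need >= 1 chromosome")
    lengths = config.chrom_lengths()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))
    chrom_sizes, centromeres, snps, map_knots, cm_totals = {}, {}, {}, {}, {}
    gene_rows = []
    for i, L in enumerate(lengths):
        chrom = f"chr{i + 1}"
        L = int(L)
        chrom_sizes[chrom] = L
        cen_mid = config.centromere_frac * L
        half = config.centromere_half_width * L
        centromeres[chrom] = (int(cen_mid - half), int(cen_mid + half))

        scale = config.snp_median_spacing / np.log(2.0)
        est = int(L / scale * 1.2 + 100)
        gaps = rng.exponential(scale, size=est)
        pos = np.cumsum(gaps)
        while pos[-1] < L:
            more = rng.exponential(scale, size=est // 4 + 10)
            pos = np.concatenate([pos, pos[-1] + np.cumsum(more)])
        pos = pos[pos < L]
        p = np.unique(np.maximum(pos.astype(np.int64), 1))
        if len(p) < 2:
            raise ValueError("infeasible SNP density for chromosome length")
        snps[chrom] = p

        n_genes = max(1, int(config.genes_per_mb * L / 1e6))
        glen = rng.exponential(config.gene_mean_len, size=n_genes).astype(np.int64) + 200
        if glen.sum() * 2 > L:
            raise ValueError("infeasible gene density")
        slack = L - glen.sum()
        gapsg = rng.dirichlet(np.ones(n_genes + 1)) * slack
        starts = (np.cumsum(gapsg[:-1]) + np.concatenate([[0], np.cumsum(glen[:-1])])).astype(np.int64)
        for k in range(n_genes):
            gene_rows.append(
                dict(chrom=chrom, start=int(starts[k]),
                     end=int(starts[k] + glen[k]), gene_id=f"{chrom}_g{k}")
            )

        x = np.linspace(0.0, 1.0, 257)
        dens = 1.0 + config.telomere_shape * (2.0 * x - 1.0) ** 2
        cum = np.concatenate([[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]) * np.diff(x))])
        cum /= cum[-1]
        map_knots[chrom] = (x * L, cum)
        cm_totals[chrom] = float(config.cm_per_chromosome)
    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "gene_id"])
    return GenomeModel(
        chrom_sizes=chrom_sizes,
        centromeres=centromeres,
        snp_positions=snps,
        genes=genes,
        map_knots=map_knots,
        cm_totals=cm_totals,
    )


def simulate_gametes(
    model: GenomeModel,
    params: BFParams,
    n_gametes: int = 100,
    seed: int = 0,
    missing_rate: float = 0.6,
) -> tuple[TruthSet, GenotypeMatrix]:
    """Simulate gametes: one Beam-Film bivalent and one sampled chromatid
    per gamete and chromosome.

    CO genetic fractions map to physical positions through the model's
    map; the gamete genotype alternates parental haplotype across CO
    midpoints, starting from a random parent per (gamete, chromosome); SNP
    calls drop out independently at ``missing_rate`` (dropped calls are
    absent from the output table).
    """
    truth_rows = []
    call_frames = []
    gametes = [f"g{j:03d}" for j in range(n_gametes)]
    for ci, (chrom, snp_pos) in enumerate(model.snp_positions.items()):
        sub = int(np.random.SeedSequence([int(seed), 211, ci]).generate_state(1)[0] % (2**31))
        bset = simulate_bivalents(params, n_gametes, sub)
        chromatids = to_chromatid(bset, sub + 1)
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 307, ci]))
        for j in range(n_gametes):
            frac = np.sort(chromatids.positions[j])
            phys = model.genetic_to_physical(chrom, frac)
            for f, x in zip(frac, phys):
                truth_rows.append(
                    dict(gamete=gametes[j], chrom=chrom,
                         genetic_frac=float(f), pos=float(x), co_class="CO")
                )
            start_parent = rng.integers(0, 2)  # 0 = P1 first
            flips = np.searchsorted(phys, snp_pos)
            alleles = np.where((flips + start_parent) % 2 == 0, "P1", "P2")
            keep = rng.uniform(size=len(snp_pos)) >= missing_rate
            call_frames.append(
                pd.DataFrame(
                    dict(sample=gametes[j], chrom=chrom,
                         pos=snp_pos[keep], allele=alleles[keep])
                )
            )
    calls = (
        pd.concat(call_frames, ignore_index=True)
        if call_frames
        else pd.DataFrame(columns=["sample", "chrom", "pos", "allele"])
    )
    truth = pd.DataFrame(
        truth_rows, columns=["gamete", "chrom", "genetic_frac", "pos", "co_class"]
    )
    return (
        TruthSet(truth=truth, params=params, seed=seed, missing_rate=missing_rate),
        GenotypeMatrix(calls=calls),
    )


def inject_artifacts(
    genotypes: GenotypeMatrix,
    truth: TruthSet,
    shared_segment_samples: int = 0,
    shared_segment_snps: int = 60,
    false_bin_rate: float = 0.0,
    false_bin_snps: int = 25,
    seed: int = 0,
) -> tuple[GenotypeMatrix, TruthSet]:
    """Corrupt genotypes with the two artifact classes.

    * residual heterozygosity: one fixed segment of ``shared_segment_snps``
      consecutive SNPs flips parent in ``shared_segment_samples`` randomly
      chosen samples at identical coordinates;
    * false short bins: per gamete, a Poisson(``false_bin_rate``) number of
      isolated ``false_bin_snps``-SNP opposite-parent runs inserted at
      random sites.

    Every injection is appended to the truth set's artifact log.
    """
    calls = genotypes.calls.copy()
    log = list(truth.artifact_log)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 409]))
    samples = sorted(calls["sample"].unique())
    chroms = sorted(calls["chrom"].unique())

    def flip(mask):
        calls.loc[mask, "allele"] = np.where(
            calls.loc[mask, "allele"] == "P1", "P2", "P1"
        )

    if shared_segment_samples > 0:
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        chrom_pos = np.sort(calls.loc[calls["chrom"] == chrom, "pos"].unique())
        i0 = int(rng.integers(0, max(1, len(chrom_pos) - shared_segment_snps)))
        lo, hi = chrom_pos[i0], chrom_pos[min(i0 + shared_segment_snps - 1, len(chrom_pos) - 1)]
        carriers = rng.choice(samples, size=min(shared_segment_samples, len(samples)),
                              replace=False)
        for s in carriers:
            mask = (
                (calls["sample"] == s)
                & (calls["chrom"] == chrom)
                & calls["pos"].between(lo, hi)
                & (calls["allele"] != MISSING)
            )
            flip(mask)
        log.append(
            dict(event="shared_segment", chrom=chrom, start=int(lo), end=int(hi),
                 samples=sorted(map(str, carriers)))
        )

    if false_bin_rate > 0:
        for s in samples:
            k = rng.poisson(false_bin_rate)
            for _ in range(k):
                for _attempt in range(20):
                    chrom = chroms[int(rng.integers(0, len(chroms)))]
                    g = calls[(calls["sample"] == s) & (calls["chrom"] == chrom)
                              & (calls["allele"] != MISSING)]
                    if len(g) < false_bin_snps + 2:
                        continue
                    i0 = int(rng.integers(0, len(g) - false_bin_snps))
                    sel = g.iloc[i0 : i0 + false_bin_snps]
                    if len(sel["allele"].unique()) != 1:
                        log.append(dict(event="false_bin_redrawn", sample=s,
                                        chrom=chrom))
                        continue
                    flip(sel.index)
                    log.append(
                        dict(event="false_bin", sample=s, chrom=chrom,
                             start=int(sel["pos"].iloc[0]),
                             end=int(sel["pos"].iloc[-1]),
                             n_snps=int(false_bin_snps))
                    )
                    break

    new_truth = TruthSet(
        truth=truth.truth,
        params=truth.params,
        seed=truth.seed,
        missing_rate=truth.missing_rate,
        artifact_log=log,
    )
    return GenotypeMatrix(calls=calls), new_truth
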