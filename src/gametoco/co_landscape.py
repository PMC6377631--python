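"""Crossover calling and landscape analysis from single-gamete genotypes.

A sequenced gamete (microspore or embryo-sac sample) yields sparse parental
SNP calls along each chromosome.  Maximal runs of consecutive same-parent
calls form haplotype *bins*; the junction between two adjacent
opposite-parent bins is a crossover (CO), localised to the interval between
the last supporting SNP of the left bin and the first supporting SNP of the
right bin.  Two artifact filters follow the calling step:

* *shared bins* — bins with (near-)identical boundaries in several samples
  arise from residual heterozygosity of the parents, not from independent
  COs, and are removed in every carrier;
* *short bins* — bins below a physical-length threshold are flagged for
  validation and by default excluded from CO calling.

Downstream, CO calls feed a windowed recombination map (cM/Mb), hot-region
and sex-preferred hot-region calls, chromosome-arm-normalized CO positions,
and a metagene profile of CO-to-gene distances with a simulated null.

Window genetic length follows the convention ``cM = 50 x (CO count /
n_samples)``, which makes the summed map length reproduce the counting
identity `total cM = 50 x mean COs per gamete`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "BinSet",
    "COCalls",
    "MapTrack",
    "HotRegionSet",
    "DistanceProfile",
    "call_bins",
    "filter_bins",
    "call_cos",
    "resolution_stats",
    "genetic_map",
    "hot_regions",
    "arm_normalize",
    "gene_distance_profile",
]

MISSING = "NA"
PARENTS = ("P1", "P2")


@dataclass
class GenotypeMatrix:
    """Long-format parental SNP calls: sample, chrom, pos, allele.

    ``allele`` is ``P1``/``P2``/``NA``; uncovered SNPs may simply be absent.
    Positions are 1-based bp and must be strictly increasing within each
    (sample, chromosome).
    """

    calls: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample", "chrom", "pos", "allele"}
        if not required.issubset(self.calls.columns):
            raise ValueError(f"genotype table needs columns {sorted(required)}")
        bad = ~self.calls["allele"].isin([*PARENTS, MISSING])
        if bad.any():
            raise ValueError(
                f"unknown allele values: {sorted(self.calls.loc[bad, 'allele'].unique())}"
            )
        for (s, c), g in self.calls.groupby(["sample", "chrom"], sort=False):
            d = np.diff(g["pos"].to_numpy())
            if np.any(d <= 0):
                raise ValueError(f"positions not strictly increasing in {s}/{c}")

    @property
    def samples(self) -> list:
        return sorted(self.calls["sample"].unique())


@dataclass
class BinSet:
    """Haplotype bins per sample, with filter flags and a decision log."""

    bins: pd.DataFrame  # sample, chrom, start, end, parent, n_snps,
    # start_idx, end_idx, shared_removed, short_flagged
    log: list = field(default_factory=list)

    def retained(self, drop_short: bool = True) -> pd.DataFrame:
        b = self.bins[~self.bins["shared_removed"]]
        if drop_short:
            b = b[~b["short_flagged"]]
        return b


@dataclass
class COCalls:
    """CO intervals per sample: chrom, start, end, midpoint, width."""

    calls: pd.DataFrame  # sample, chrom, start, end, midpoint, width
    n_samples: int

    def __post_init__(self) -> None:
        if len(self.calls) and (self.calls["start"] >= self.calls["end"]).any():
            raise ValueError("CO interval start must be < end")


@dataclass
class MapTrack:
    """Windowed recombination map: chrom, start, end, n_cos, cm, cm_per_mb."""

    windows: pd.DataFrame
    n_samples: int
    window_bp: int

    @property
    def total_cm(self) -> float:
        return float(self.windows["cm"].sum())


@dataclass
class HotRegionSet:
    """Hot windows with sex-preference labels.

    ``label`` in {"a_preferred", "b_preferred", "shared"} for windows hot in
    at least one track.
    """

    regions: pd.DataFrame  # chrom, start, end, value_a, value_b, hot_a,
    # hot_b, label
    hot_cm_per_mb: float
    fold: float


@dataclass
class DistanceProfile:
    """Metagene-coordinate CO-to-gene distances with simulated null."""

    observed: np.ndarray
    null: np.ndarray  # pooled null distances (n_null sets)
    n_null: int
    ks_statistic: float
    ks_pvalue: float


# ---------------------------------------------------------------------------
# bin calling


def _runs_from_codes(codes: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of equal values; returns (start, stop) index pairs."""
    if len(codes) == 0:
        return []
    change = np.flatnonzero(np.diff(codes) != 0) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [len(codes)]])
    return list(zip(starts, stops))


def call_bins(genotypes: GenotypeMatrix, min_snps: int = 20) -> BinSet:
    """Call parental haplotype bins from sorted SNP calls.

    Missing calls are skipped (they never break a run).  Runs shorter than
    ``min_snps`` are absorbed into their flanks and logged; the surviving
    maximal same-parent runs become bins.  Bin span is the first..last
    supporting SNP; ``n_snps`` counts supporting (same-parent) SNPs only.
    """
    rows = []
    log = []
    # global SNP index per chromosome over the union of observed positions
    union = {
        c: np.sort(g["pos"].unique())
        for c, g in genotypes.calls.groupby("chrom", sort=False)
    }
    for (sample, chrom), g in genotypes.calls.groupby(["sample", "chrom"], sort=False):
        g = g[g["allele"] != MISSING]
        pos = g["pos"].to_numpy()
        codes = np.where(g["allele"].to_numpy() == "P1", 1, 2)
        runs = [(a, b, codes[a]) for a, b in _runs_from_codes(codes)]
        # absorb sub-threshold runs, shortest first, merging same-parent flanks
        while True:
            short = [i for i, (a, b, _) in enumerate(runs) if b - a < min_snps]
            if not short or len(runs) == 1:
                break
            i = min(short, key=lambda i: runs[i][1] - runs[i][0])
            a, b, parent = runs.pop(i)
            log.append(
                dict(event="absorbed_short_run", sample=sample, chrom=chrom,
                     start=int(pos[a]), end=int(pos[b - 1]), n_snps=int(b - a),
                     parent=PARENTS[parent - 1])
            )
            # merge now-adjacent same-parent runs
            j = 0
            while j < len(runs) - 1:
                a0, b0, p0 = runs[j]
                a1, b1, p1 = runs[j + 1]
                if p0 == p1:
                    runs[j] = (a0, b1, p0)
                    runs.pop(j + 1)
                else:
                    j += 1
        for a, b, parent in runs:
            if b - a < min_snps:
                log.append(
                    dict(event="chromosome_below_min_snps", sample=sample,
                         chrom=chrom, n_snps=int(b - a))
                )
                continue
            support = np.flatnonzero(codes[a:b] == parent) + a
            first, last = support[0], support[-1]
            u = union[chrom]
            rows.append(
                dict(
                    sample=sample, chrom=chrom,
                    start=int(pos[first]), end=int(pos[last]),
                    parent=PARENTS[parent - 1],
                    n_snps=int(len(support)),
                    start_idx=int(np.searchsorted(u, pos[first])),
                    end_idx=int(np.searchsorted(u, pos[last])),
                )
            )
    bins = pd.DataFrame(
        rows,
        columns=["sample", "chrom", "start", "end", "parent", "n_snps",
                 "start_idx", "end_idx"],
    )
    bins["shared_removed"] = False
    bins["short_flagged"] = False
    return BinSet(bins=bins, log=log)


def filter_bins(
    bins: BinSet,
    short_bp: int = 1_200_000,
    shared_min_samples: int = 3,
    idx_tol: int = 2,
) -> BinSet:
    """Flag residual-heterozygosity shared bins and short bins.

    Bins whose boundaries match within ``idx_tol`` SNP indices in at least
    ``shared_min_samples`` distinct samples are marked ``shared_removed``
    in every carrier.  Bins spanning fewer than ``short_bp`` base pairs are
    marked ``short_flagged``.  All decisions are appended to the log.
    """
    b = bins.bins.copy()
    log = list(bins.log)
    for chrom, g in b.groupby("chrom", sort=False):
        # residual-heterozygosity artifacts are interior segments; bins
        # anchored at a chromosome end share boundaries trivially across
        # samples and are exempt from shared-bin matching
        max_idx = int(g["end_idx"].max())
        interior = (g["start_idx"] > idx_tol) & (g["end_idx"] < max_idx - idx_tol)
        g = g[interior]
        if len(g) == 0:
            continue
        idx = g.index.to_numpy()
        si = g["start_idx"].to_numpy()
        ei = g["end_idx"].to_numpy()
        n = len(idx)
        # union-find style clustering on boundary proximity
        parent = np.arange(n)

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        order = np.argsort(si, kind="stable")
        for ai in range(n):
            i = order[ai]
            for aj in range(ai + 1, n):
                j = order[aj]
                if si[j] - si[i] > idx_tol:
                    break
                if abs(ei[i] - ei[j]) <= idx_tol:
                    parent[find(i)] = find(j)
        roots = np.array([find(i) for i in range(n)])
        samples = g["sample"].to_numpy()
        for r in np.unique(roots):
            members = np.flatnonzero(roots == r)
            carriers = set(samples[members])
            if len(carriers) >= shared_min_samples:
                b.loc[idx[members], "shared_removed"] = True
                log.append(
                    dict(event="shared_bin_removed", chrom=chrom,
                         n_bins=int(len(members)), n_samples=len(carriers),
                         start=int(b.loc[idx[members[0]], "start"]),
                         end=int(b.loc[idx[members[0]], "end"]))
                )
    short = (b["end"] - b["start"]) < short_bp
    newly = short & ~b["short_flagged"]
    b.loc[short, "short_flagged"] = True
    for _, row in b[newly].iterrows():
        log.append(
            dict(event="short_bin_flagged", sample=row["sample"],
                 chrom=row["chrom"], start=int(row["start"]),
                 end=int(row["end"]), span=int(row["end"] - row["start"]))
        )
    return BinSet(bins=b, log=log)


def call_cos(bins: BinSet, drop_short: bool = True) -> COCalls:
    """Call one CO per junction between adjacent opposite-parent bins.

    Interval start/end are the last/first supporting SNPs of the flanking
    bins; the CO position is the interval midpoint.  After filtering,
    adjacent same-parent bins are merged, never called.
    """
    retained = bins.retained(drop_short=drop_short)
    n_samples = bins.bins["sample"].nunique()
    rows = []
    for (sample, chrom), g in retained.groupby(["sample", "chrom"], sort=False):
        g = g.sort_values("start")
        # merge adjacent same-parent bins left by filtering
        merged = []
        for _, r in g.iterrows():
            if merged and merged[-1]["parent"] == r["parent"]:
                merged[-1]["end"] = r["end"]
                merged[-1]["n_snps"] += r["n_snps"]
            else:
                merged.append(dict(r))
        for left, right in zip(merged[:-1], merged[1:]):
            start, end = left["end"], right["start"]
            rows.append(
                dict(sample=sample, chrom=chrom, start=int(start), end=int(end),
                     midpoint=0.5 * (start + end), width=int(end - start))
            )
    calls = pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "midpoint", "width"]
    )
    return COCalls(calls=calls, n_samples=n_samples)


def resolution_stats(calls: COCalls, cut_bp: int) -> float:
    """Fraction of CO intervals narrower than ``cut_bp``."""
    if len(calls.calls) == 0:
        raise ValueError("no CO calls")
    return float((calls.calls["width"] < cut_bp).mean())


# ---------------------------------------------------------------------------
# landscape


def genetic_map(
    calls: COCalls,
    chrom_sizes: dict,
    window_bp: int = 3_000_000,
    n_samples: int | None = None,
) -> MapTrack:
    """Windowed recombination map.

    Windows tile each chromosome from its start; the trailing partial
    window keeps its actual width.  Window genetic length is
    ``50 * count / n_samples`` cM and cM/Mb divides by the actual window
    size in Mb.
    """
    n = n_samples if n_samples is not None else calls.n_samples
    if n <= 0:
        raise ValueError("population size must be positive")
    for c in calls.calls["chrom"].unique():
        if c not in chrom_sizes:
            raise ValueError(f"missing chromosome size for {c}")
    rows = []
    for chrom, size in chrom_sizes.items():
        edges = np.arange(0, size, window_bp, dtype=int)
        g = calls.calls[calls.calls["chrom"] == chrom]
        mids = g["midpoint"].to_numpy()
        for start in edges:
            end = min(start + window_bp, size)
            cnt = int(np.sum((mids >= start) & (mids < end)))
            mb = (end - start) / 1e6
            cm = 50.0 * cnt / n
            rows.append(
                dict(chrom=chrom, start=int(start), end=int(end), n_cos=cnt,
                     cm=cm, cm_per_mb=cm / mb)
            )
    return MapTrack(windows=pd.DataFrame(rows), n_samples=n, window_bp=window_bp)


def hot_regions(
    track_a: MapTrack,
    track_b: MapTrack,
    hot_cm_per_mb: float = 1.0,
    fold: float = 2.0,
) -> HotRegionSet:
    """Hot windows (> ``hot_cm_per_mb``) and sex-preference labels.

    A window hot in either track is a-preferred when ``value_a >= fold *
    value_b`` (a zero in the other track counts as preferred), b-preferred
    symmetrically, otherwise shared.  Swapping the tracks swaps the labels.
    """
    key = ["chrom", "start", "end"]
    a = track_a.windows[key + ["cm_per_mb"]].rename(columns={"cm_per_mb": "value_a"})
    b = track_b.windows[key + ["cm_per_mb"]].rename(columns={"cm_per_mb": "value_b"})
    if not a[key].reset_index(drop=True).equals(b[key].reset_index(drop=True)):
        raise ValueError("tracks are not on identical windows")
    m = a.merge(b, on=key)
    m["hot_a"] = m["value_a"] > hot_cm_per_mb
    m["hot_b"] = m["value_b"] > hot_cm_per_mb
    m = m[m["hot_a"] | m["hot_b"]].reset_index(drop=True)

    def label(r):
        a_pref = (r["value_a"] >= fold * r["value_b"]) and r["value_a"] > 0
        b_pref = (r["value_b"] >= fold * r["value_a"]) and r["value_b"] > 0
        if a_pref and not b_pref:
            return "a_preferred"
        if b_pref and not a_pref:
            return "b_preferred"
        return "shared"

    m["label"] = m.apply(label, axis=1) if len(m) else pd.Series(dtype=object)
    return HotRegionSet(regions=m, hot_cm_per_mb=hot_cm_per_mb, fold=fold)


def arm_normalize(
    calls: COCalls,
    centromeres: dict,
    chrom_sizes: dict,
    convention: str = "from_telomere",
) -> pd.DataFrame:
    """Normalize CO midpoints by chromosome-arm length.

    ``centromeres`` maps chrom -> (cen_start, cen_end).  Each CO is
    assigned to the arm on its side of the centromere and its position is
    divided by the arm length, measured from the telomere (default) or
    from the centromere (``convention="from_centromere"``).  COs inside the
    centromere interval are flagged and excluded.
    """
    if convention not in ("from_telomere", "from_centromere"):
        raise ValueError(f"unknown convention {convention!r}")
    rows = []
    for _, r in calls.calls.iterrows():
        chrom = r["chrom"]
        cen_start, cen_end = centromeres[chrom]
        size = chrom_sizes[chrom]
        pos = r["midpoint"]
        if cen_start <= pos <= cen_end:
            rows.append(dict(sample=r["sample"], chrom=chrom, midpoint=pos,
                             arm=None, frac=np.nan, in_centromere=True))
            continue
        if pos < cen_start:
            arm, arm_len, from_tel = "short", cen_start, pos
        else:
            arm, arm_len, from_tel = "long", size - cen_end, size - pos
        frac = from_tel / arm_len
        if convention == "from_centromere":
            frac = 1.0 - frac
        rows.append(dict(sample=r["sample"], chrom=chrom, midpoint=pos,
                         arm=arm, frac=float(frac), in_centromere=False))
    return pd.DataFrame(
        rows, columns=["sample", "chrom", "midpoint", "arm", "frac",
                       "in_centromere"]
    )


def _metagene_distance(pos: np.ndarray, chrom: np.ndarray, genes: pd.DataFrame) -> np.ndarray:
    """Signed metagene coordinate of each position to its closest gene.

    0 = gene start, 1 = gene end, inside the gene linearly in between;
    upstream/downstream positions extend the axis below 0 / above 1 with
    the flank rescaled by the same gene's length.
    """
    out = np.empty(len(pos))
    for c in np.unique(chrom):
        gsub = genes[genes["chrom"] == c].sort_values("start")
        if len(gsub) == 0:
            raise ValueError(f"no genes on chromosome {c}")
        starts = gsub["start"].to_numpy(dtype=float)
        ends = gsub["end"].to_numpy(dtype=float)
        sel = chrom == c
        p = pos[sel].astype(float)
        # closest gene by edge distance
        d_start = np.abs(p[:, None] - starts[None, :])
        d_end = np.abs(p[:, None] - ends[None, :])
        inside = (p[:, None] >= starts[None, :]) & (p[:, None] <= ends[None, :])
        dist = np.minimum(d_start, d_end)
        dist[inside] = 0.0
        j = np.argmin(dist, axis=1)
        s, e = starts[j], ends[j]
        length = np.maximum(e - s, 1.0)
        out[sel] = (p - s) / length
    return out


def gene_distance_profile(
    calls: COCalls,
    genes: pd.DataFrame,
    chrom_sizes: dict,
    n_null: int = 5,
    seed: int = 0,
    max_width_bp: int = 10_000,
) -> DistanceProfile:
    """Metagene profile of CO positions versus a uniform null.

    Only COs resolved below ``max_width_bp`` are profiled (wider intervals
    cannot place a CO at gene scale).  ``n_null`` random position sets of
    the same per-chromosome size are drawn uniformly; a two-sided
    Kolmogorov-Smirnov test compares observed and pooled null metagene
    distances.
    """
    if len(genes) == 0:
        raise ValueError("empty gene annotation")
    fine = calls.calls[calls.calls["width"] < max_width_bp]
    if len(fine) == 0:
        raise ValueError("no CO calls resolved below max_width_bp")
    pos = fine["midpoint"].to_numpy()
    chrom = fine["chrom"].to_numpy()
    observed = _metagene_distance(pos, chrom, genes)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 23]))
    null_all = []
    for _ in range(n_null):
        null_pos = np.empty(len(pos))
        for c in np.unique(chrom):
            sel = chrom == c
            null_pos[sel] = rng.uniform(0, chrom_sizes[c], size=int(sel.sum()))
        null_all.append(_metagene_distance(null_pos, chrom, genes))
    null = np.concatenate(null_all)
    ks = stats.ks_2samp(observed, null, alternative="two-sided")
    return DistanceProfile(
        observed=observed,
        null=null,
        n_null=n_null,
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
    )
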