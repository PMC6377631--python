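"""Plain-text serialization: TSV/BED/bedGraph/JSON/YAML round-trips.

All on-disk formats are line-oriented text.  Coordinates in TSV are
1-based inclusive; BED and bedGraph output is 0-based half-open.  CO-set
TSVs carry normalized genetic positions with 6 decimals and deterministic
row order.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bf_sim import BFParams, BivalentCOSet, ChromatidCOSet, CO_CLASSES
from .co_landscape import COCalls, GenotypeMatrix, HotRegionSet, MapTrack

__all__ = [
    "write_co_set",
    "read_co_set",
    "write_genotypes",
    "read_genotypes",
    "write_co_calls",
    "read_co_calls",
    "write_bins_bed",
    "write_maptrack_bedgraph",
    "write_hot_regions_bed",
    "write_chrom_table",
    "read_chrom_table",
    "write_genes_bed",
    "read_genes_bed",
    "load_config",
    "save_config",
    "bf_params_from_config",
    "file_sha256",
    "write_manifest",
]


class ParseError(ValueError):
    def __init__(self, path, line_no, msg):
        super().__init__(f"{path}:{line_no}: {msg}")


def write_co_set(co_set, path) -> None:
    """CO-set TSV: bivalent_id (or chromatid_id) / position / class."""
    if isinstance(co_set, BivalentCOSet):
        id_col, records = "bivalent_id", zip(co_set.positions, co_set.classes)
    elif isinstance(co_set, ChromatidCOSet):
        id_col = "chromatid_id"
        records = ((p, ["CO"] * len(p)) for p in co_set.positions)
    else:
        raise TypeError(type(co_set))
    with open(path, "w") as fh:
        fh.write(f"{id_col}\tposition\tclass\n")
        for i, (pos, cls) in enumerate(records):
            order = np.argsort(pos, kind="stable")
            for j in order:
                fh.write(f"{i}\t{pos[j]:.6f}\t{cls[j]}\n")


def read_co_set(path, level: str = "bivalent"):
    """Read a CO-set TSV back; zero data rows yield a valid empty-sample set."""
    ids, positions, classes = [], [], []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != [header[0], "position"] or len(header) < 3:
            raise ParseError(path, 1, f"bad CO-set header {header}")
        for ln, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ParseError(path, ln, f"expected 3 columns, got {len(parts)}")
            try:
                ids.append(int(parts[0]))
                positions.append(float(parts[1]))
            except ValueError as e:
                raise ParseError(path, ln, str(e)) from None
            classes.append(parts[2])
    n = (max(ids) + 1) if ids else 0
    if level == "chromatid" and n == 0:
        return ChromatidCOSet(positions=[])
    n = max(n, 1)  # a zero-row bivalent TSV is one CO-free bivalent
    pos_lists = [[] for _ in range(n)]
    cls_lists = [[] for _ in range(n)]
    for i, p, c in zip(ids, positions, classes):
        pos_lists[i].append(p)
        cls_lists[i].append(c)
    pos_arr = [np.array(p) for p in pos_lists]
    cls_arr = [np.array(c, dtype=object) for c in cls_lists]
    if level == "chromatid":
        return ChromatidCOSet(positions=[np.sort(p) for p in pos_arr])
    return BivalentCOSet(positions=pos_arr, classes=cls_arr)


def write_genotypes(genotypes: GenotypeMatrix, path) -> None:
    genotypes.calls.to_csv(path, sep="\t", index=False)


def read_genotypes(path) -> GenotypeMatrix:
    df = pd.read_csv(
        path, sep="\t", dtype={"sample": str, "chrom": str, "allele": str},
        keep_default_na=False,
    )
    try:
        df["pos"] = df["pos"].astype(np.int64)
    except (KeyError, ValueError) as e:
        raise ParseError(path, 0, f"bad genotype table: {e}") from None
    return GenotypeMatrix(calls=df)


def write_co_calls(calls: COCalls, path) -> None:
    df = calls.calls.copy()
    df.insert(0, "n_samples", calls.n_samples)
    df.to_csv(path, sep="\t", index=False)


def read_co_calls(path) -> COCalls:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    n = int(df["n_samples"].iloc[0]) if len(df) else 0
    return COCalls(calls=df.drop(columns=["n_samples"]), n_samples=n)


def write_bins_bed(bins, path) -> None:
    """Bins as BED6: name = parent, score = supporting SNP count."""
    with open(path, "w") as fh:
        for _, r in bins.bins.iterrows():
            fh.write(
                f"{r['chrom']}\t{r['start'] - 1}\t{r['end']}\t"
                f"{r['sample']}:{r['parent']}\t{r['n_snps']}\t+\n"
            )


def write_maptrack_bedgraph(track: MapTrack, path) -> None:
    with open(path, "w") as fh:
        fh.write('track type=bedGraph name="cM_per_Mb"\n')
        for _, r in track.windows.iterrows():
            fh.write(f"{r['chrom']}\t{r['start']}\t{r['end']}\t{r['cm_per_mb']:.6f}\n")


def write_hot_regions_bed(hot: HotRegionSet, path) -> None:
    with open(path, "w") as fh:
        for _, r in hot.regions.iterrows():
            fh.write(
                f"{r['chrom']}\t{r['start']}\t{r['end']}\t{r['label']}\t0\t+\n"
            )


def write_chrom_table(table: dict, path) -> None:
    """chrom -> scalar or tuple rows as TSV (sizes, centromeres)."""
    with open(path, "w") as fh:
        first = next(iter(table.values()))
        if np.isscalar(first):
            fh.write("chrom\tlength\n")
            for c, v in table.items():
                fh.write(f"{c}\t{int(v)}\n")
        else:
            fh.write("chrom\tstart\tend\n")
            for c, (a, b) in table.items():
                fh.write(f"{c}\t{int(a)}\t{int(b)}\n")


def read_chrom_table(path) -> dict:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if "length" in df.columns:
        return dict(zip(df["chrom"], df["length"].astype(int)))
    return {r["chrom"]: (int(r["start"]), int(r["end"])) for _, r in df.iterrows()}


def write_genes_bed(genes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for _, r in genes.iterrows():
            fh.write(f"{r['chrom']}\t{r['start']}\t{r['end']}\t{r['gene_id']}\n")


def read_genes_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError(path, ln, "BED needs >= 3 columns")
            try:
                rows.append(
                    dict(chrom=parts[0], start=int(parts[1]), end=int(parts[2]),
                         gene_id=parts[3] if len(parts) > 3 else f"g{ln}")
                )
            except ValueError as e:
                raise ParseError(path, ln, str(e)) from None
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


# ---------------------------------------------------------------------------
# config


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config root must be a mapping: {path}")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def bf_params_from_config(cfg: dict) -> BFParams:
    """Read the flat ``bf:`` section (keys N,E,B,Y,A,Smax,L,M,T2prob)."""
    section = cfg.get("bf", {})
    return BFParams(**{k: float(v) for k, v in section.items()})


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, config: dict, seed: int, inputs: list) -> Path:
    from . import __version__

    out_dir = Path(out_dir)
    manifest = dict(
        package="gametoco",
        version=__version__,
        seed=int(seed),
        config=config,
        inputs={str(p): file_sha256(p) for p in inputs if Path(p).exists()},
    )
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return path
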