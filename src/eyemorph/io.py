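"""Readers and writers for the pipeline's plain-text formats.

Landmarks travel as TSV (specimen_id, group, x1, y1, ..., xk, yk) or
classic TPS files (LM= blocks with coordinate lines and ID=/IMAGE= keys);
phenotypes and genotypes as TSV; pooled SNP counts as a sync-style TSV
(chrom, pos, ref, alt, then one "ref:alt" column per pool) or a minimal
VCF with per-pool AD fields; trees as Newick plus a tip/value trait TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .morpho import LandmarkConfiguration
from .phylo import TraitTree

__all__ = [
    "read_landmark_tsv", "write_landmark_tsv", "read_tps",
    "read_snp_sync", "write_snp_sync", "write_snp_vcf", "read_snp_vcf",
    "read_trait_tree", "write_trait_tree",
]


def write_landmark_tsv(configs, path) -> None:
    rows = []
    for c in configs:
        row = {"specimen_id": c.specimen_id, "group": c.group}
        for i, (x, y) in enumerate(c.coords, start=1):
            row[f"x{i}"] = x
            row[f"y{i}"] = y
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_landmark_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t")
    k = (len(df.columns) - 2) // 2
    out = []
    for _, r in df.iterrows():
        coords = np.array([[r[f"x{i}"], r[f"y{i}"]] for i in range(1, k + 1)])
        out.append(LandmarkConfiguration(
            specimen_id=str(r["specimen_id"]), group=str(r["group"]), coords=coords))
    return out


def read_tps(path, group: str = "") -> list:
    """Classic TPS landmark file: LM=, coordinate lines, ID=/IMAGE= keys."""
    out = []
    coords, spec_id, expect = [], None, 0
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("LM="):
            if coords:
                out.append(LandmarkConfiguration(
                    specimen_id=spec_id or str(len(out)), group=group,
                    coords=np.asarray(coords)))
            expect = int(line.split("=", 1)[1])
            coords, spec_id = [], None
        elif upper.startswith(("ID=", "IMAGE=")):
            if spec_id is None or upper.startswith("ID="):
                spec_id = line.split("=", 1)[1]
        elif "=" not in line:
            x, y = line.split()[:2]
            coords.append([float(x), float(y)])
    if coords:
        out.append(LandmarkConfiguration(
            specimen_id=spec_id or str(len(out)), group=group,
            coords=np.asarray(coords)))
    for c in out:
        if expect and c.coords.shape[0] != expect:
            pass  # trust the coordinates actually present
    return out


# ---------------------------------------------------------------------------
# SNP tables


def _pool_names(df: pd.DataFrame) -> list:
    return sorted({c[:-4] for c in df.columns if c.endswith("_ref")})


def write_snp_sync(snps: pd.DataFrame, path) -> None:
    pools = _pool_names(snps)
    out = snps[["chrom", "pos", "ref", "alt"]].copy()
    for p in pools:
        out[p] = snps[f"{p}_ref"].astype(str) + ":" + snps[f"{p}_alt"].astype(str)
    out.to_csv(path, sep="\t", index=False)


def read_snp_sync(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    out = df[["chrom", "pos", "ref", "alt"]].copy()
    for p in [c for c in df.columns if c not in ("chrom", "pos", "ref", "alt")]:
        counts = df[p].str.split(":", expand=True).astype(int)
        out[f"{p}_ref"] = counts[0]
        out[f"{p}_alt"] = counts[1]
    return out


def write_snp_vcf(snps: pd.DataFrame, path) -> None:
    """Minimal VCF with per-pool allelic-depth (AD) sample fields."""
    pools = _pool_names(snps)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths (ref,alt)">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(pools) + "\n")
        for _, r in snps.iterrows():
            sample_fields = "\t".join(
                f"{int(r[f'{p}_ref'])},{int(r[f'{p}_alt'])}" for p in pools)
            fh.write(f"{r['chrom']}\t{int(r['pos'])}\t.\t{r['ref']}\t{r['alt']}"
                     f"\t.\t.\t.\tAD\t{sample_fields}\n")


def read_snp_vcf(path) -> pd.DataFrame:
    """Read a minimal AD-field VCF back into the count-table layout."""
    rows = []
    pools = []
    for raw in Path(path).read_text().splitlines():
        if raw.startswith("##"):
            continue
        fields = raw.rstrip("\n").split("\t")
        if raw.startswith("#CHROM"):
            pools = fields[9:]
            continue
        row = {"chrom": fields[0], "pos": int(fields[1]),
               "ref": fields[3], "alt": fields[4]}
        fmt = fields[8].split(":")
        ad_idx = fmt.index("AD")
        for p, sample in zip(pools, fields[9:]):
            ref_n, alt_n = sample.split(":")[ad_idx].split(",")[:2]
            row[f"{p}_ref"] = int(ref_n)
            row[f"{p}_alt"] = int(alt_n)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trees


def write_trait_tree(tt: TraitTree, newick_path, trait_path) -> None:
    Path(newick_path).write_text(
        tt.tree.as_string(schema="newick", suppress_rooting=True))
    pd.DataFrame(
        {"tip": list(tt.traits), "value": list(tt.traits.values())}
    ).to_csv(trait_path, sep="\t", index=False)


def read_trait_tree(newick_path, trait_path) -> TraitTree:
    traits = pd.read_csv(trait_path, sep="\t").set_index("tip")["value"].to_dict()
    return TraitTree.from_newick(Path(newick_path).read_text(), traits)
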