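"""Readers and writers for VCF, PED-like pedigree tables, FASTA and BED.

VCF is read with cyvcf2; only biallelic sites are retained and multiallelic
records are dropped with a logged count. Writing uses plain VCF 4.2 text with
GT and DP fields so that outputs round-trip through the reader.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, TrioSet

log = logging.getLogger("gibbonpop")


class VcfError(ValueError):
    pass


class PedigreeError(ValueError):
    pass


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Multiallelic sites are dropped (count logged); positions are converted
    to 0-based. DP is taken from the per-sample FORMAT field when present.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise VcfError(f"cannot open VCF {path!r}: {exc}") from exc
    samples = list(vcf.samples)
    gts, dps, chrom, pos, ref, alt = [], [], [], [], [], []
    n_multi = 0
    has_dp = True
    for i, v in enumerate(vcf):
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        g = np.asarray(v.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        gts.append(g)
        d = None
        if has_dp:
            try:
                d = v.format("DP")
            except KeyError:  # DP absent from the FORMAT header
                has_dp = False
        if d is not None:
            d = np.asarray(d).reshape(-1).astype(np.int32)
            d[d < 0] = 0
        dps.append(d)
        chrom.append(v.CHROM)
        pos.append(v.POS - 1)
        ref.append(v.REF)
        alt.append(v.ALT[0])
    if n_multi:
        log.info("read_vcf: dropped %d multiallelic site(s) from %s", n_multi, path)
    if not gts:
        raise VcfError(f"no biallelic records in {path!r}")
    depth = None
    if all(d is not None for d in dps):
        depth = np.stack(dps, axis=1)
    gm = GenotypeMatrix(
        genotypes=np.stack(gts, axis=1),
        samples=samples,
        chrom=np.asarray(chrom),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(ref),
        alt=np.asarray(alt),
        depth=depth,
    )
    gm.n_multiallelic_dropped = n_multi  # type: ignore[attr-defined]
    return gm


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix as uncompressed VCF 4.2 with GT (and DP)."""
    with_depth = gm.depth is not None
    fmt = "GT:DP" if with_depth else "GT"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if with_depth:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for c in pd.unique(gm.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for j in range(gm.n_sites):
            cells = []
            for i in range(gm.n_individuals):
                gt = _GT_STR[int(gm.genotypes[i, j])]
                if with_depth:
                    gt = f"{gt}:{int(gm.depth[i, j])}"
                cells.append(gt)
            fh.write(
                f"{gm.chrom[j]}\t{int(gm.pos[j]) + 1}\t.\t{gm.ref[j]}\t{gm.alt[j]}"
                f"\t.\tPASS\t.\t{fmt}\t" + "\t".join(cells) + "\n"
            )


PED_COLUMNS = ["family", "id", "father", "mother", "sex"]
PED_MISSING = "0"


def write_ped(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", header=False, index=False, columns=PED_COLUMNS)


def read_pedigree(path: str | Path) -> pd.DataFrame:
    """Read a PED-like table (family, id, father, mother, sex).

    Rejects pedigrees in which an individual is its own ancestor.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
    if df.shape[1] < 5:
        raise PedigreeError(
            f"pedigree table needs >=5 columns (family id father mother sex), got {df.shape[1]}"
        )
    df = df.iloc[:, :5]
    df.columns = PED_COLUMNS
    _check_acyclic(df)
    return df


def _check_acyclic(df: pd.DataFrame) -> None:
    parents = {
        row.id: [p for p in (row.father, row.mother) if p != PED_MISSING]
        for row in df.itertuples()
    }
    WHITE, GREY, BLACK = 0, 1, 2
    state = {i: WHITE for i in parents}
    for start in parents:
        if state[start] != WHITE:
            continue
        stack = [(start, iter(parents[start]))]
        state[start] = GREY
        while stack:
            node, it = stack[-1]
            for nxt in it:
                if nxt not in parents:
                    continue
                if state[nxt] == GREY:
                    raise PedigreeError(f"pedigree cycle involving {nxt!r}")
                if state[nxt] == WHITE:
                    state[nxt] = GREY
                    stack.append((nxt, iter(parents[nxt])))
                    break
            else:
                state[node] = BLACK
                stack.pop()


def extract_trios(ped: pd.DataFrame) -> list[tuple[str, str, str]]:
    """(father, mother, offspring) triples where both parents are present."""
    ids = set(ped["id"])
    trios = []
    for row in ped.itertuples():
        if row.father in ids and row.mother in ids:
            trios.append((row.father, row.mother, row.id))
    return trios


def trios_from_vcf_ped(gm: GenotypeMatrix, ped: pd.DataFrame) -> TrioSet:
    """Assemble a TrioSet from a genotype matrix and a pedigree table."""
    idx = {s: i for i, s in enumerate(gm.samples)}
    triples = [
        t for t in extract_trios(ped) if all(m in idx for m in t)
    ]
    if not triples:
        raise PedigreeError("no complete trios with genotyped members")
    rows = np.array([[idx[f], idx[m], idx[o]] for f, m, o in triples])
    return TrioSet(
        genotypes=gm.genotypes[rows],
        chrom=gm.chrom,
        pos=gm.pos,
        ref=gm.ref,
        alt=gm.alt,
        depth=gm.depth[rows] if gm.depth is not None else None,
        trio_ids=triples,
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED-like gene intervals: chrom, start, end[, name] (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError("BED needs at least chrom/start/end columns")
    cols = ["chrom", "start", "end"] + (["name"] if df.shape[1] > 3 else [])
    df = df.iloc[:, : len(cols)]
    df.columns = cols
    return df
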