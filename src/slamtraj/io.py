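"""Readers and writers for the on-disk formats the pipeline touches.

All genomic coordinates are 0-based half-open internally; VCF and SAM are
1-based and converted at this boundary, BED passes through. TSV output uses
tab separators, '.' decimals and Unix newlines so reruns are byte-identical.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from scipy import sparse
from scipy.io import mmread, mmwrite

from .matrix import LayeredCountMatrix
from .synthetic import ReadSimResult

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


# ---------------------------------------------------------------------------
# TSV helpers
# ---------------------------------------------------------------------------


def write_tsv(df: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format,
              lineterminator="\n")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# MatrixMarket + sidecars
# ---------------------------------------------------------------------------


def write_layered_matrix(matrix: LayeredCountMatrix, out_dir) -> None:
    """Write {layer}.mtx + barcodes.tsv + features.tsv (genes x cells)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, layer in matrix.layers.items():
        coo = sparse.coo_matrix(layer)
        integral = np.allclose(layer, np.round(layer))
        if integral:
            coo = coo.astype(np.int64)
        mmwrite(str(out_dir / f"{name}.mtx"), coo,
                field="integer" if integral else "real")
    (out_dir / "barcodes.tsv").write_text("\n".join(matrix.cells) + "\n")
    (out_dir / "features.tsv").write_text("\n".join(matrix.genes) + "\n")


def _read_mtx_checked(path) -> np.ndarray:
    try:
        mat = mmread(str(path))
    except Exception as exc:
        raise ValueError(f"failed to parse MatrixMarket file {path}: {exc}") from exc
    return np.asarray(mat.todense() if sparse.issparse(mat) else mat, dtype=float)


def read_layered_matrix(in_dir, layers=("nascent", "old", "total")) -> LayeredCountMatrix:
    """Read {layer}.mtx + barcodes.tsv + features.tsv back into memory.

    The "total" layer is recomputed from nascent + old when its file is
    absent. Indices out of the declared dimensions raise an error naming
    the offending entry.
    """
    in_dir = Path(in_dir)
    cells = (in_dir / "barcodes.tsv").read_text().splitlines()
    genes = (in_dir / "features.tsv").read_text().splitlines()
    found: dict[str, np.ndarray] = {}
    for name in layers:
        path = in_dir / f"{name}.mtx"
        if not path.exists():
            if name == "total":
                continue
            raise FileNotFoundError(f"missing layer file {path}")
        data = _validated_mtx(path, len(genes), len(cells))
        found[name] = data
    if "total" not in found and {"nascent", "old"} <= set(found):
        found["total"] = found["nascent"] + found["old"]
    unknown = set(found) - set(layers)
    if unknown:
        raise ValueError(f"unknown layers {sorted(unknown)}; expected {list(layers)}")
    return LayeredCountMatrix(genes=genes, cells=cells, layers=found)


def _validated_mtx(path, n_rows: int, n_cols: int) -> np.ndarray:
    """Parse a coordinate MTX, checking 1-based indices against sidecars."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("%%MatrixMarket matrix coordinate"):
            raise ValueError(f"{path}: unsupported MatrixMarket header {header!r}")
        line = fh.readline()
        while line.startswith("%"):
            line = fh.readline()
        rows, cols, _nnz = (int(x) for x in line.split())
        if (rows, cols) != (n_rows, n_cols):
            raise ValueError(
                f"{path}: declared shape {(rows, cols)} does not match sidecars "
                f"({n_rows} features, {n_cols} barcodes)"
            )
        for lineno, entry in enumerate(fh, start=1):
            if not entry.strip():
                continue
            i, j = entry.split()[:2]
            i, j = int(i), int(j)
            if not (1 <= i <= rows and 1 <= j <= cols):
                raise ValueError(
                    f"{path}: entry {lineno} has out-of-range index ({i}, {j}) "
                    f"for shape {(rows, cols)}"
                )
    return _read_mtx_checked(path)


# ---------------------------------------------------------------------------
# VCF / BED
# ---------------------------------------------------------------------------


def write_minimal_vcf(records: pd.DataFrame, path) -> None:
    """records columns: chrom, pos (0-based, converted to 1-based), id, ref, alt."""
    lines = ["##fileformat=VCFv4.2", "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"]
    for row in records.itertuples(index=False):
        lines.append(
            f"{row.chrom}\t{row.pos + 1}\t{row.id}\t{row.ref}\t{row.alt}\t.\t.\t."
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_bed(coords: pd.DataFrame, path) -> None:
    """columns chrom, start, end, gene_id (+ optional score, strand)."""
    cols = ["chrom", "start", "end", "gene_id"]
    if "strand" in coords.columns:
        out = coords.assign(score=coords.get("score", 0))[cols + ["score", "strand"]]
    else:
        out = coords[cols]
    out.to_csv(path, sep="\t", header=False, index=False, lineterminator="\n")


def read_bed(path) -> pd.DataFrame:
    names = ["chrom", "start", "end", "gene_id", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    if "strand" not in df.columns:
        df["strand"] = "+"
    return df


# ---------------------------------------------------------------------------
# SAM text dialect
# ---------------------------------------------------------------------------


def write_sam(result: ReadSimResult, path, read_length: int | None = None) -> None:
    """Emit the simulated ReadTable as SAM text with CB/UB/GX/MD/NM tags.

    The reference forward strand carries T at simulated T positions of
    plus-strand genes (A for minus-strand genes, by complement); observed
    conversions appear as T->C (A->G) mismatches encoded through SEQ + MD.
    """
    gene_meta = result.gene_table.set_index("gene_id")
    chrom_len: dict[str, int] = {}
    for row in result.gene_table.itertuples(index=False):
        chrom_len[row.chrom] = max(chrom_len.get(row.chrom, 0), int(row.end) + 1000)

    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for chrom in sorted(chrom_len):
        lines.append(f"@SQ\tSN:{chrom}\tLN:{chrom_len[chrom]}")

    for ridx, row in enumerate(result.reads.itertuples(index=False)):
        gene = row.gene_id
        meta = gene_meta.loc[gene]
        t_pos = set(int(p) for p in result.gene_t_positions[gene])
        covered = sorted(int(p) for p in str(row.covered_T).split(",")) if row.covered_T else []
        converted = set(int(p) for p in str(row.converted).split(",")) if row.converted else set()
        other = set(int(p) for p in str(row.other_mismatch).split(",")) if row.other_mismatch else set()
        # the ReadTable stores only evidence positions; the emitted window is
        # the tight span of evidence (a 1-base stub for evidence-free reads)
        all_pos = covered + sorted(other)
        if all_pos:
            w_lo, w_hi = min(all_pos), max(all_pos) + 1
        else:
            w_lo, w_hi = 0, 1
        gene_len = int(meta.end) - int(meta.start)

        # transcript-frame sequences over [w_lo, w_hi)
        ref_seq, obs_seq = [], []
        for p in range(w_lo, w_hi):
            ref = "T" if p in t_pos else "A"
            if p in converted:
                obs = "C"
            elif p in other:
                obs = "G"
            else:
                obs = ref
            ref_seq.append(ref)
            obs_seq.append(obs)
        ref_seq = "".join(ref_seq)
        obs_seq = "".join(obs_seq)

        if meta.strand == "+":
            pos0 = int(meta.start) + w_lo
            fwd_ref, fwd_obs = ref_seq, obs_seq
        else:
            pos0 = int(meta.start) + (gene_len - w_hi)
            fwd_ref = ref_seq.translate(_COMPLEMENT)[::-1]
            fwd_obs = obs_seq.translate(_COMPLEMENT)[::-1]

        md, nm = _md_tag(fwd_ref, fwd_obs)
        flag = 0 if meta.strand == "+" else 16
        lines.append(
            "\t".join(
                [
                    f"read{ridx:08d}",
                    str(flag),
                    str(meta.chrom),
                    str(pos0 + 1),
                    "255",
                    f"{len(fwd_obs)}M",
                    "*",
                    "0",
                    "0",
                    fwd_obs,
                    "*",
                    f"CB:Z:{row.barcode}",
                    f"UB:Z:{row.umi}",
                    f"GX:Z:{gene}",
                    f"NM:i:{nm}",
                    f"MD:Z:{md}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _md_tag(ref: str, obs: str) -> tuple[str, int]:
    parts, run, nm = [], 0, 0
    for r, o in zip(ref, obs):
        if r == o:
            run += 1
        else:
            parts.append(str(run))
            parts.append(r)
            run = 0
            nm += 1
    parts.append(str(run))
    return "".join(parts), nm


def read_sam_dialect(path, gene_coords: pd.DataFrame, max_skip_frac: float = 0.1) -> pd.DataFrame:
    """Parse tagged SAM into a ReadTable (transcribed-strand gene frame).

    Records need CB:Z and UB:Z plus mismatch information via MD:Z (with
    CIGAR/SEQ) or an XC:Z/XT:Z pair. Gene assignment uses the GX:Z tag when
    present, otherwise the record's position against ``gene_coords``.
    Unmapped, secondary and supplementary records are skipped with counts;
    more than ``max_skip_frac`` skipped records is a hard error.
    """
    coords = gene_coords.set_index("gene_id")
    by_chrom: dict[str, list[tuple[int, int, str, str]]] = {}
    for gene, row in coords.iterrows():
        by_chrom.setdefault(str(row.chrom), []).append(
            (int(row.start), int(row.end), str(row.strand), gene)
        )

    rows = []
    n_total = n_skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            n_total += 1
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                n_skipped += 1
                continue
            if not rec.has_tag("CB") or not rec.has_tag("UB"):
                n_skipped += 1
                continue
            gene = rec.get_tag("GX") if rec.has_tag("GX") else None
            if gene is None:
                hits = [
                    g
                    for (s, e, _strand, g) in by_chrom.get(rec.reference_name, [])
                    if s <= rec.reference_start < e
                ]
                if len(hits) != 1:
                    n_skipped += 1
                    continue
                gene = hits[0]
            if gene not in coords.index:
                n_skipped += 1
                continue
            meta = coords.loc[gene]
            gene_len = int(meta.end) - int(meta.start)

            if rec.has_tag("MD"):
                pairs = rec.get_aligned_pairs(matches_only=True, with_seq=True)
                covered_t, converted, other = [], [], []
                qseq = rec.query_sequence
                for qpos, rpos, ref_base in pairs:
                    obs = qseq[qpos].upper()
                    ref = ref_base.upper()
                    local = rpos - int(meta.start)
                    if meta.strand == "-":
                        t_local = gene_len - 1 - local
                        t_ref = ref.translate(_COMPLEMENT)
                        t_obs = obs.translate(_COMPLEMENT)
                    else:
                        t_local = local
                        t_ref, t_obs = ref, obs
                    if t_ref == "T":
                        covered_t.append(t_local)
                        if t_obs == "C":
                            converted.append(t_local)
                        elif t_obs != "T":
                            other.append(t_local)
                    elif t_obs != t_ref:
                        other.append(t_local)
            elif rec.has_tag("XC") or rec.has_tag("XT"):
                covered_t = [int(p) for p in str(rec.get_tag("XT")).split(",") if p]
                converted, other = [], []
                if rec.has_tag("XC"):
                    for item in str(rec.get_tag("XC")).split(","):
                        if not item:
                            continue
                        pos_s, change = item.split(":")
                        ref, alt = change.split(">")
                        if ref.upper() == "T" and alt.upper() == "C":
                            converted.append(int(pos_s))
                        else:
                            other.append(int(pos_s))
            else:
                n_skipped += 1
                continue

            rows.append(
                (
                    rec.get_tag("CB"),
                    rec.get_tag("UB"),
                    gene,
                    ",".join(str(p) for p in sorted(covered_t)),
                    ",".join(str(p) for p in sorted(converted)),
                    ",".join(str(p) for p in sorted(other)),
                )
            )
    if n_total and n_skipped / n_total > max_skip_frac:
        raise ValueError(
            f"{n_skipped}/{n_total} SAM records skipped (> {max_skip_frac:.0%})"
        )
    return pd.DataFrame(
        rows,
        columns=["barcode", "umi", "gene_id", "covered_T", "converted", "other_mismatch"],
    )


def snp_records_from_sim(result: ReadSimResult) -> pd.DataFrame:
    """Translate simulator gene-local SNPs into global VCF-ready records."""
    meta = result.gene_table.set_index("gene_id")
    rows = []
    for i, row in enumerate(result.snps.itertuples(index=False)):
        m = meta.loc[row.gene_id]
        gene_len = int(m.end) - int(m.start)
        if m.strand == "-":
            gpos = int(m.start) + (gene_len - 1 - int(row.pos))
            ref = ("T" if row.ref_is_T else "A").translate(_COMPLEMENT)
            alt = ("C" if row.ref_is_T else "G").translate(_COMPLEMENT)
        else:
            gpos = int(m.start) + int(row.pos)
            ref = "T" if row.ref_is_T else "A"
            alt = "C" if row.ref_is_T else "G"
        rows.append((str(m.chrom), gpos, f"snp{i:06d}", ref, alt))
    return pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
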