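"""Nascent/old RNA classification from T->C conversion evidence.

Per read, usable T positions and conversions are counted while SNP-masked
positions are left out. Reads sharing one (cell barcode, UMI, gene) key are
collapsed into a molecule; positions observed with discordant nucleotides
across overlapping reads are excluded from both counts. A molecule is
called nascent if at least one conversion survives all exclusions, and old
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import LayeredCountMatrix


class DataError(ValueError):
    """Inconsistent read evidence (e.g. conversion outside covered span)."""


@dataclass(frozen=True)
class ReadObservation:
    """Per-read conversion evidence in gene-local transcribed-strand coords."""

    barcode: str
    umi: str
    gene_id: str
    covered_T: frozenset[int]
    converted: frozenset[int]
    other_mismatch: frozenset[int] = frozenset()

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.barcode, self.umi, self.gene_id)


def _parse_positions(text) -> frozenset[int]:
    if text is None or (isinstance(text, float) and np.isnan(text)) or text == "":
        return frozenset()
    return frozenset(int(p) for p in str(text).split(","))


def reads_from_table(table: pd.DataFrame) -> list[ReadObservation]:
    """Build :class:`ReadObservation` records from a ReadTable DataFrame."""
    out = []
    for row in table.itertuples(index=False):
        out.append(
            ReadObservation(
                barcode=row.barcode,
                umi=row.umi,
                gene_id=row.gene_id,
                covered_T=_parse_positions(row.covered_T),
                converted=_parse_positions(row.converted),
                other_mismatch=_parse_positions(row.other_mismatch),
            )
        )
    return out


@dataclass(frozen=True)
class SNPMask:
    """Positions excluded from conversion counting.

    ``entries`` hold (key, position) pairs where the key is a chromosome
    name (frame="genomic", as parsed from VCF) or a gene identifier
    (frame="gene", the frame the classifier operates in).
    """

    entries: frozenset[tuple[str, int]] = frozenset()
    frame: str = "gene"

    def __contains__(self, item: tuple[str, int]) -> bool:
        return item in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def to_gene_frame(self, gene_table: pd.DataFrame) -> "SNPMask":
        """Translate genomic-frame entries to gene-local transcribed coords.

        ``gene_table`` needs columns gene_id, chrom, start, end, strand
        (0-based half-open). Positions outside every gene are dropped.
        Minus-strand genes are flipped so that position 0 is the transcript
        5' end in the same frame the simulator and SAM reader use.
        """
        if self.frame == "gene":
            return self
        out = set()
        for row in gene_table.itertuples(index=False):
            for chrom, pos in self.entries:
                if chrom == row.chrom and row.start <= pos < row.end:
                    if row.strand == "-":
                        local = (row.end - 1) - pos
                    else:
                        local = pos - row.start
                    out.add((row.gene_id, local))
        return SNPMask(entries=frozenset(out), frame="gene")


def parse_snp_mask(vcf_source) -> SNPMask:
    """Parse a minimal VCF into a genomic-frame SNP mask.

    ``vcf_source`` is a path or an iterable of lines. Header lines starting
    with '#' are ignored; POS is converted from 1-based VCF to the internal
    0-based frame. Duplicate records collapse by set semantics.
    """
    if isinstance(vcf_source, (str, bytes)) or hasattr(vcf_source, "__fspath__"):
        with open(vcf_source) as fh:
            lines = fh.readlines()
    else:
        lines = list(vcf_source)
    entries = set()
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"malformed VCF line {lineno}: {line!r}")
        chrom, pos = parts[0], parts[1]
        try:
            pos0 = int(pos) - 1
        except ValueError:
            raise ValueError(f"malformed VCF line {lineno}: non-integer POS {pos!r}")
        if pos0 < 0:
            raise ValueError(f"malformed VCF line {lineno}: POS must be >= 1")
        entries.add((chrom, pos0))
    return SNPMask(entries=frozenset(entries), frame="genomic")


@dataclass
class ConversionProfile:
    """Usable-T and conversion evidence after masking/discordance exclusion."""

    n_T: int
    converted_positions: frozenset[int]
    discarded_positions: frozenset[int] = frozenset()
    other_mismatch_positions: frozenset[int] = frozenset()


@dataclass
class MoleculeCall:
    key: tuple[str, str, str]  # (barcode, umi, gene_id)
    profile: ConversionProfile
    label: str  # "nascent" | "old"
    n_reads: int
    no_T: bool = False


def read_conversion_profile(read: ReadObservation, mask: SNPMask) -> ConversionProfile:
    """Count usable T positions and conversions for one read.

    Masked positions are excluded from both the usable-T count and the
    converted set; non-T->C mismatches are recorded but never counted as
    conversions.
    """
    if mask.frame != "gene":
        raise ValueError("mask must be in gene frame; call to_gene_frame() first")
    if not read.converted <= read.covered_T:
        bad = sorted(read.converted - read.covered_T)
        raise DataError(
            f"converted positions {bad} not among covered T positions for "
            f"read {read.key}"
        )
    masked = frozenset(p for p in read.covered_T if (read.gene_id, p) in mask)
    usable = read.covered_T - masked
    converted = read.converted - masked
    return ConversionProfile(
        n_T=len(usable),
        converted_positions=converted,
        discarded_positions=masked,
        other_mismatch_positions=read.other_mismatch & usable,
    )


def collapse_molecule(reads: list[ReadObservation], mask: SNPMask) -> MoleculeCall:
    """Collapse the reads of one (barcode, UMI, gene) molecule into a call.

    A position observed as converted in at least one read and with a
    different nucleotide in at least one other overlapping read is
    discordant and excluded from both the usable and the converted sets.
    Duplicate identical read records are deduplicated first, so re-fed
    inputs are idempotent.
    """
    if not reads:
        raise ValueError("collapse_molecule requires at least one read")
    if mask.frame != "gene":
        raise ValueError("mask must be in gene frame; call to_gene_frame() first")
    key = reads[0].key
    if any(r.key != key for r in reads):
        raise ValueError(f"reads do not share one (barcode, umi, gene) key: {key}")
    reads = list(dict.fromkeys(reads))  # dedupe, order-preserving

    # status per covered T position per read: C (converted), T (reference),
    # M (other mismatch at a T position)
    status: dict[int, set[str]] = {}
    gene = key[2]
    for r in reads:
        if not r.converted <= r.covered_T:
            bad = sorted(r.converted - r.covered_T)
            raise DataError(f"converted positions {bad} not covered for read {r.key}")
        for p in r.covered_T:
            if (gene, p) in mask:
                continue
            if p in r.converted:
                status.setdefault(p, set()).add("C")
            elif p in r.other_mismatch:
                status.setdefault(p, set()).add("M")
            else:
                status.setdefault(p, set()).add("T")

    discordant = frozenset(p for p, st in status.items() if len(st) > 1)
    converted = frozenset(p for p, st in status.items() if st == {"C"})
    other = frozenset(p for p, st in status.items() if st == {"M"})
    usable = frozenset(status) - discordant
    masked = frozenset(
        p for r in reads for p in r.covered_T if (gene, p) in mask
    )
    profile = ConversionProfile(
        n_T=len(usable),
        converted_positions=converted,
        discarded_positions=discordant | masked,
        other_mismatch_positions=other,
    )
    label = "nascent" if len(converted) >= 1 else "old"
    return MoleculeCall(
        key=key,
        profile=profile,
        label=label,
        n_reads=len(reads),
        no_T=len(usable) == 0,
    )


@dataclass
class CollapseResult:
    calls: list[MoleculeCall]
    audit: pd.DataFrame  # per molecule: key, n_T, n_conv, n_discordant, label, no_T
    discard: pd.DataFrame  # reason, count


def collapse_reads(reads: list[ReadObservation], mask: SNPMask) -> CollapseResult:
    """Group reads by molecule key and collapse each group into a call.

    Reads sharing (barcode, UMI) but mapping to more than one gene cannot
    be assigned a gene row; all their reads are discarded as ambiguous and
    tallied in the discard report.
    """
    by_bc_umi: dict[tuple[str, str], dict[str, list[ReadObservation]]] = {}
    for r in reads:
        by_bc_umi.setdefault((r.barcode, r.umi), {}).setdefault(r.gene_id, []).append(r)

    calls: list[MoleculeCall] = []
    n_ambiguous = 0
    for (_bc, _umi), by_gene in by_bc_umi.items():
        if len(by_gene) > 1:
            n_ambiguous += 1
            continue
        ((_gene, group),) = by_gene.items()
        calls.append(collapse_molecule(group, mask))

    audit = pd.DataFrame(
        {
            "barcode": [c.key[0] for c in calls],
            "umi": [c.key[1] for c in calls],
            "gene_id": [c.key[2] for c in calls],
            "n_T": [c.profile.n_T for c in calls],
            "n_conv": [len(c.profile.converted_positions) for c in calls],
            "n_discordant": [len(c.profile.discarded_positions) for c in calls],
            "n_reads": [c.n_reads for c in calls],
            "label": [c.label for c in calls],
            "no_T": [c.no_T for c in calls],
        }
    )
    discard = pd.DataFrame(
        {"reason": ["gene_ambiguous_umi"], "count": [n_ambiguous]}
    )
    return CollapseResult(calls=calls, audit=audit, discard=discard)


def build_layered_matrix(
    calls,
    cell_list: list[str],
    gene_list: list[str],
    on_unknown: str = "error",
) -> tuple[LayeredCountMatrix, pd.DataFrame]:
    """Tally molecule calls into nascent/old/total gene x cell matrices.

    ``on_unknown`` controls handling of calls referencing a barcode or gene
    missing from the given lists: "error" raises, "drop" counts them in the
    returned discard report.
    """
    if on_unknown not in ("error", "drop"):
        raise ValueError("on_unknown must be 'error' or 'drop'")
    cell_index = {c: i for i, c in enumerate(cell_list)}
    gene_index = {g: i for i, g in enumerate(gene_list)}
    nascent = np.zeros((len(gene_list), len(cell_list)))
    old = np.zeros((len(gene_list), len(cell_list)))
    n_unknown = 0
    for call in calls:
        bc, _umi, gene = call.key
        if bc not in cell_index or gene not in gene_index:
            if on_unknown == "error":
                raise KeyError(f"unknown barcode/gene in call key {call.key}")
            n_unknown += 1
            continue
        g, c = gene_index[gene], cell_index[bc]
        if call.label == "nascent":
            nascent[g, c] += 1
        else:
            old[g, c] += 1
    matrix = LayeredCountMatrix(
        genes=list(gene_list),
        cells=list(cell_list),
        layers={"nascent": nascent, "old": old, "total": nascent + old},
    )
    discard = pd.DataFrame({"reason": ["unknown_barcode_or_gene"], "count": [n_unknown]})
    return matrix, discard


def quantify_reads(
    read_table: pd.DataFrame,
    mask: SNPMask,
    cell_list: list[str] | None = None,
    gene_list: list[str] | None = None,
) -> tuple[LayeredCountMatrix, CollapseResult]:
    """ReadTable -> layered matrix convenience wrapper."""
    reads = reads_from_table(read_table)
    result = collapse_reads(reads, mask)
    if cell_list is None:
        cell_list = sorted({r.barcode for r in reads})
    if gene_list is None:
        gene_list = sorted({r.gene_id for r in reads})
    matrix, _ = build_layered_matrix(result.calls, cell_list, gene_list, on_unknown="drop")
    return matrix, result
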