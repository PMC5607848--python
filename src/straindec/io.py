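"""Tabular and sequence I/O for the strain deconvolution pipeline.

The pipeline's central observable is a table of per-position base counts
(A, C, G, T — fixed alphabetical order) across samples, produced upstream by
pileup-style counting of read mappings. This module parses those tables,
derives mean-coverage summaries and writes inferred haplotype sequences
back out as FASTA.

Positions are 1-based in every file (pileup convention) and 0-based in
memory; the conversion happens only here, at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class ParseError(ValueError):
    """Raised when an input table cannot be parsed."""


@dataclass
class BaseCountTable:
    """Per-position base counts over samples.

    Attributes
    ----------
    ids
        Sequence identifier of each row (contig or gene).
    positions
        0-based position of each row within its sequence.
    counts
        Integer array of shape ``(n_rows, n_samples, 4)`` in A,C,G,T order.
    samples
        Sample names, in file-header order. This order is immutable for the
        whole run.
    """

    ids: np.ndarray
    positions: np.ndarray
    counts: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3 or self.counts.shape[2] != 4:
            raise ValueError("counts must have shape (n_rows, n_samples, 4)")
        if np.any(self.counts < 0):
            raise ValueError("base counts must be non-negative")
        if self.counts.shape[0] != len(self.ids) or self.counts.shape[0] != len(self.positions):
            raise ValueError("ids, positions and counts must agree in length")
        if self.counts.shape[1] != len(self.samples):
            raise ValueError("sample names must match the counts' sample axis")
        # positions unique within each sequence id
        seen: set[tuple] = set()
        for i, p in zip(self.ids, self.positions):
            key = (i, int(p))
            if key in seen:
                raise ValueError(f"duplicate position {p + 1} for sequence {i!r}")
            seen.add(key)

    @property
    def n_rows(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def aggregate_over_samples(self) -> np.ndarray:
        """Total count of each base across all samples, shape (n_rows, 4)."""
        return self.counts.sum(axis=1)

    def subset(self, mask: np.ndarray) -> "BaseCountTable":
        return BaseCountTable(
            self.ids[mask], self.positions[mask], self.counts[mask], list(self.samples)
        )


@dataclass
class CoverageMatrix:
    """Mean coverage of each gene/contig in each sample (reads·bp per bp)."""

    gene_ids: list[str]
    lengths: np.ndarray
    values: np.ndarray  # shape (n_genes, n_samples)
    samples: list[str]

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.lengths < 1):
            raise ValueError("gene lengths must be >= 1")
        if np.any(self.values < 0):
            raise ValueError("coverages must be non-negative")
        if self.values.shape != (len(self.gene_ids), len(self.samples)):
            raise ValueError("coverage matrix shape mismatch")


def read_base_counts(path: str | Path, n_samples: int | None = None) -> BaseCountTable:
    """Read a tab-separated base-count table.

    Expected layout: ``id<TAB>position<TAB><sample>-A ... <sample>-T`` with a
    header row; four columns per sample in A,C,G,T order. ``position`` is
    1-based in the file.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}: empty file, expected a header line")
        cols = header.split("\t")
        if len(cols) < 2 or (len(cols) - 2) % 4 != 0:
            raise ParseError(
                f"{path}: header has {len(cols)} columns; expected id, position "
                "and four base columns per sample"
            )
        n_s = (len(cols) - 2) // 4
        if n_samples is not None and n_s != n_samples:
            raise ParseError(f"{path}: header implies {n_s} samples, expected {n_samples}")
        samples = []
        for s in range(n_s):
            name = cols[2 + 4 * s]
            samples.append(name[:-2] if name.endswith("-A") else name)

        ids, positions, rows = [], [], []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2 + 4 * n_s:
                raise ParseError(
                    f"{path}, line {lineno}: expected {2 + 4 * n_s} fields, got {len(parts)}"
                )
            try:
                pos = int(parts[1])
                vals = [int(v) for v in parts[2:]]
            except ValueError as exc:
                raise ParseError(f"{path}, line {lineno}: non-integer field ({exc})") from None
            if any(v < 0 for v in vals):
                raise ValueError(f"{path}, line {lineno}: negative base count")
            ids.append(parts[0])
            positions.append(pos - 1)
            rows.append(vals)

    counts = (
        np.asarray(rows, dtype=np.int64).reshape(len(rows), n_s, 4)
        if rows
        else np.zeros((0, n_s, 4), dtype=np.int64)
    )
    return BaseCountTable(np.asarray(ids, dtype=object), np.asarray(positions), counts, samples)


def write_base_counts(table: BaseCountTable, path: str | Path) -> None:
    """Write a base-count table in the format read by :func:`read_base_counts`."""
    cols = ["id", "position"]
    for s in table.samples:
        cols.extend(f"{s}-{b}" for b in BASES)
    flat = table.counts.reshape(table.n_rows, -1)
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for i in range(table.n_rows):
            fh.write(
                "\t".join(
                    [str(table.ids[i]), str(int(table.positions[i]) + 1)]
                    + [str(int(v)) for v in flat[i]]
                )
                + "\n"
            )


def read_coverage(path: str | Path) -> CoverageMatrix:
    """Read a gene-coverage TSV: ``gene_id<TAB>length<TAB><sample1> ...``."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise ParseError(f"{path}: expected gene_id, length and >=1 sample column")
    samples = list(df.columns[2:])
    return CoverageMatrix(
        [str(g) for g in df.iloc[:, 0]],
        df.iloc[:, 1].to_numpy(),
        df.iloc[:, 2:].to_numpy(dtype=float),
        samples,
    )


def write_coverage(cov: CoverageMatrix, path: str | Path) -> None:
    df = pd.DataFrame(cov.values, columns=cov.samples)
    df.insert(0, "length", cov.lengths)
    df.insert(0, "gene_id", cov.gene_ids)
    df.to_csv(path, sep="\t", index=False)


def mean_coverage(counts: BaseCountTable, lengths: Mapping[str, int]) -> CoverageMatrix:
    """Mean coverage x_{d,s} = (total bases mapped to d in s) / L_d.

    Every sequence id present in ``counts`` must have a length; ids in
    ``lengths`` without any counted position get coverage 0.
    """
    present = list(dict.fromkeys(counts.ids))  # order of first appearance
    missing = [i for i in present if i not in lengths]
    if missing:
        raise KeyError(f"no length provided for sequence id(s): {missing}")
    gene_ids = present + [g for g in lengths if g not in set(present)]
    idx = {g: k for k, g in enumerate(gene_ids)}
    values = np.zeros((len(gene_ids), counts.n_samples))
    per_row = counts.counts.sum(axis=2)  # (rows, samples)
    for r in range(counts.n_rows):
        values[idx[counts.ids[r]]] += per_row[r]
    lens = np.array([lengths[g] for g in gene_ids], dtype=np.int64)
    values /= lens[:, None]
    return CoverageMatrix(gene_ids, lens, values, list(counts.samples))


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a nucleotide FASTA into an id → sequence map (A,C,G,T,N)."""
    from Bio import SeqIO

    store: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        store[rec.id] = str(rec.seq).upper()
    return store


def write_haplotype_fasta(
    store: Mapping[str, str],
    haplotype_bases: np.ndarray,
    variant_index: Sequence[tuple[str, int]],
    path: str | Path,
    strain_names: Sequence[str] | None = None,
) -> None:
    """Write per-strain sequences with variant positions substituted.

    Parameters
    ----------
    store
        Reference sequences, id → string.
    haplotype_bases
        Integer array (V, G): base index (0..3) of strain g at variant v.
    variant_index
        For each variant v, the ``(sequence_id, 0-based position)`` it maps to.
    """
    haplotype_bases = np.asarray(haplotype_bases)
    V, G = haplotype_bases.shape
    if len(variant_index) != V:
        raise ValueError("variant_index length must equal the number of variants")
    if strain_names is None:
        strain_names = [f"strain_{g}" for g in range(G)]
    for sid, pos in variant_index:
        if sid not in store:
            raise KeyError(f"variant references unknown sequence {sid!r}")
        seq = store[sid]
        if not (0 <= pos < len(seq)):
            raise IndexError(f"variant position {pos + 1} outside sequence {sid!r} (length {len(seq)})")
        if seq[pos] == "N":
            raise ValueError(f"variant at ambiguous reference base N: {sid!r}:{pos + 1}")

    with open(path, "w") as fh:
        for g, name in enumerate(strain_names):
            for sid, seq in store.items():
                chars = list(seq)
                for v, (vid, pos) in enumerate(variant_index):
                    if vid == sid:
                        chars[pos] = BASES[haplotype_bases[v, g]]
                fh.write(f">{name}|{sid}\n{''.join(chars)}\n")
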