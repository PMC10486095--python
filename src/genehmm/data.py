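"""Gene-anchored extraction of binarized tracks and the concatenated file layout.

Coordinates are 0-based, half-open internally.  Genomic start/end are rounded
outward to bin-width multiples (which realizes "round the TSS in the 5'
direction and the TES in the 3' direction" for both strands), a fixed flank is
added on each side, and negative-strand genes are row-reversed so that row 0
of every observation is the 5' flank.

Training input files use the ChromHMM binarized-text dialect: two header
lines (cell type <tab> chromosome, then tab-separated mark names) followed by
one 0/1 row per bin.  Files carry ``E + 1`` columns, the last being the dummy
mark: genes are concatenated head to tail with a single dummy row (all real
marks 0, dummy mark 1) between them and at the start and end of the file.
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GeneInterval",
    "BinarizedChromosome",
    "BinnedGeneObservation",
    "DEFAULT_CHROMS",
    "load_gene_annotation",
    "compute_extended_bins",
    "extract_observation",
    "write_input_files",
    "read_binarized_file",
    "split_concatenated",
    "read_manifest",
]

logger = logging.getLogger(__name__)

DUMMY_MARK = "dummy"

#: chromosomes kept by default: autosomes 1-22 and X, with or without "chr".
DEFAULT_CHROMS = frozenset(
    name for i in list(range(1, 23)) + ["X"] for name in (f"{i}", f"chr{i}")
)


@dataclass(frozen=True)
class GeneInterval:
    """A gene's genomic interval; 0-based, half-open, stranded."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    gene_symbol: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.gene_id}: need 0 <= start < end, "
                             f"got [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand required ('+' or '-'), "
                             f"got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class BinarizedChromosome:
    """Presence/absence calls for one (cell type, chromosome) at fixed bin width."""

    cell_type: str
    chrom: str
    bins: np.ndarray  # (B, E) of {0, 1}
    bin_width: int = 200
    mark_names: list = None

    def __post_init__(self):
        self.bins = np.asarray(self.bins)
        vals = np.unique(self.bins)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("binarized track entries must be 0/1")
        if self.mark_names is None:
            self.mark_names = [f"mark{e}" for e in range(self.bins.shape[1])]

    @property
    def chrom_len(self) -> int:
        return self.bins.shape[0] * self.bin_width


@dataclass
class BinnedGeneObservation:
    """One gene's T x E binary matrix for one cell type, oriented 5' -> 3'."""

    gene: GeneInterval
    cell_type: str
    obs: np.ndarray

    @property
    def T(self) -> int:
        return self.obs.shape[0]


# ---------------------------------------------------------------------------
# gene annotation

def _parse_gtf_attributes(attr: str) -> dict:
    out = {}
    for chunk in attr.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, val = chunk.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def load_gene_annotation(path, fmt: str | None = None,
                         allowed_chroms=DEFAULT_CHROMS) -> list[GeneInterval]:
    """Read gene intervals from a 6-column BED or a gene-level GTF/GFF3.

    GTF input (1-based inclusive) is converted to 0-based half-open.
    Duplicate gene ids are rejected; chromosomes outside ``allowed_chroms``
    (pass ``None`` to disable the filter) are dropped.
    """
    if fmt is None:
        name = str(path).lower()
        fmt = "gtf" if name.endswith((".gtf", ".gff", ".gff3", ".gtf.gz")) else "bed"
    opener = gzip.open if str(path).endswith(".gz") else open
    genes: list[GeneInterval] = []
    seen: set[str] = set()
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if fmt == "bed":
                    if len(fields) < 6:
                        raise ValueError("BED needs 6 columns (chrom, start, end, "
                                         "name, score, strand)")
                    chrom, start, end, name, _, strand = fields[:6]
                    gene = GeneInterval(chrom=chrom, start=int(start), end=int(end),
                                        strand=strand, gene_id=name, gene_symbol=name)
                else:
                    if len(fields) < 9:
                        raise ValueError("GTF needs 9 columns")
                    if fields[2] != "gene":
                        continue
                    attrs = _parse_gtf_attributes(fields[8])
                    gid = attrs.get("gene_id") or attrs.get("ID")
                    if not gid:
                        raise ValueError("gene record without gene_id")
                    gene = GeneInterval(chrom=fields[0], start=int(fields[3]) - 1,
                                        end=int(fields[4]), strand=fields[6],
                                        gene_id=gid,
                                        gene_symbol=attrs.get("gene_name", gid))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if allowed_chroms is not None and gene.chrom not in allowed_chroms:
                continue
            if gene.gene_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene_id {gene.gene_id!r}")
            seen.add(gene.gene_id)
            genes.append(gene)
    return genes


# ---------------------------------------------------------------------------
# binning

def compute_extended_bins(gene: GeneInterval, flank_bp: int = 2000,
                          bin_width: int = 200,
                          chrom_len: int | None = None) -> tuple[int, int, int]:
    """Outward-rounded, flanked, clamped bin span of a gene.

    Returns ``(ext_start, ext_end, T)`` with ``T`` the number of bins covering
    the gene and its flanks.
    """
    if flank_bp <= 0 or bin_width <= 0:
        raise ValueError("flank_bp and bin_width must be positive")
    if flank_bp % bin_width != 0:
        raise ValueError("bin_width must divide flank_bp")
    if chrom_len is not None and gene.start >= chrom_len:
        raise ValueError(f"{gene.gene_id} lies outside its chromosome "
                         f"(start {gene.start} >= length {chrom_len})")
    ext_start = (gene.start // bin_width) * bin_width - flank_bp
    ext_end = -(-gene.end // bin_width) * bin_width + flank_bp
    ext_start = max(ext_start, 0)
    if chrom_len is not None:
        ext_end = min(ext_end, (chrom_len // bin_width) * bin_width)
    T = (ext_end - ext_start) // bin_width
    return ext_start, ext_end, T


def extract_observation(track: BinarizedChromosome, gene: GeneInterval,
                        flank_bp: int = 2000, bin_width: int = 200) -> BinnedGeneObservation:
    """Pull a gene's (flank-extended) rows out of a track, 5' first.

    Negative-strand genes are row-reversed; mark columns are never reordered.
    """
    if track.chrom != gene.chrom:
        raise ValueError(f"track is for {track.chrom}, gene {gene.gene_id} "
                         f"is on {gene.chrom}")
    if track.bin_width != bin_width:
        raise ValueError("track bin width differs from requested bin width")
    ext_start, ext_end, _ = compute_extended_bins(gene, flank_bp, bin_width,
                                                  chrom_len=track.chrom_len)
    if ext_end > track.chrom_len:
        raise ValueError(f"{gene.gene_id}: extended interval [{ext_start}, {ext_end}) "
                         f"exceeds track length {track.chrom_len}")
    rows = track.bins[ext_start // bin_width: ext_end // bin_width]
    if gene.strand == "-":
        rows = rows[::-1]
    return BinnedGeneObservation(gene=gene, cell_type=track.cell_type, obs=rows.copy())


# ---------------------------------------------------------------------------
# concatenated input files

def _input_filename(cell_type: str, chrom: str) -> str:
    return f"{cell_type}_{chrom}_binary.txt"


def write_input_files(genes_by_chrom: dict, tracks: dict, out_dir,
                      flank_bp: int = 2000, bin_width: int = 200,
                      observations: dict | None = None) -> pd.DataFrame:
    """Write one dummy-separated file per (cell type, chromosome).

    ``genes_by_chrom`` maps chromosome -> ordered list of GeneInterval;
    ``tracks`` maps ``(cell_type, chrom)`` -> BinarizedChromosome.  If
    ``observations`` is given (``(cell_type, chrom)`` -> list of T x E
    matrices aligned with the gene list), extraction is skipped and those
    rows are written directly — this is how single-bin (TSS) layouts and
    simulated data reuse the writer.

    Returns the manifest: one row per (file, gene) recording gene order.
    The manifest is also written as ``manifest.tsv`` in ``out_dir``.
    """
    os.makedirs(out_dir, exist_ok=True)
    records = []
    n_files = 0
    cell_types = sorted({ct for (ct, _) in tracks})
    mark_names = None
    for cell_type in cell_types:
        for chrom, genes in genes_by_chrom.items():
            if not genes:
                continue
            key = (cell_type, chrom)
            if key not in tracks:
                raise ValueError(f"no binarized track for cell type {cell_type!r}, "
                                 f"chromosome {chrom!r}")
            track = tracks[key]
            if mark_names is None:
                mark_names = list(track.mark_names)
            elif list(track.mark_names) != mark_names:
                raise ValueError(f"mark order in track {key} differs from the "
                                 "first track; mark columns must be identical "
                                 "across all files")
            E = len(mark_names)
            dummy_row = "\t".join(["0"] * E + ["1"])
            fname = _input_filename(cell_type, chrom)
            fpath = os.path.join(out_dir, fname)
            with open(fpath, "w") as fh:
                fh.write(f"{cell_type}\t{chrom}\n")
                fh.write("\t".join(mark_names + [DUMMY_MARK]) + "\n")
                fh.write(dummy_row + "\n")
                for idx, gene in enumerate(genes):
                    if observations is not None:
                        obs = observations[key][idx]
                    else:
                        obs = extract_observation(track, gene, flank_bp, bin_width).obs
                    for row in np.asarray(obs, dtype=int):
                        fh.write("\t".join(map(str, row)) + "\t0\n")
                    fh.write(dummy_row + "\n")
                    records.append({"file": fname, "cell_type": cell_type,
                                    "chrom": chrom, "index": idx,
                                    "gene_id": gene.gene_id, "n_bins": len(obs)})
            n_files += 1
    manifest = pd.DataFrame.from_records(
        records, columns=["file", "cell_type", "chrom", "index", "gene_id", "n_bins"])
    manifest.to_csv(os.path.join(out_dir, "manifest.tsv"), sep="\t", index=False)
    logger.info("wrote %d input files to %s", n_files, out_dir)
    return manifest


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_binarized_file(path) -> tuple[str, str, list, np.ndarray]:
    """Parse a ChromHMM-dialect binarized file.

    Returns ``(cell_type, chrom, mark_names, matrix)``; the matrix keeps every
    column in the file (including a dummy column if present).
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ValueError(f"{path}: first line must be 'cell_type<TAB>chrom'")
        cell_type, chrom = header[0], header[1]
        mark_names = fh.readline().rstrip("\n").split("\t")
        E = len(mark_names)
        rows = []
        for i, line in enumerate(fh):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != E:
                raise ValueError(f"{path}: row {i} has {len(parts)} columns, "
                                 f"expected {E}")
            for tok in parts:
                if tok not in ("0", "1"):
                    raise ValueError(f"{path}: non-binary token {tok!r} in row {i}")
            rows.append([int(t) for t in parts])
    if not rows:
        logger.warning("%s: empty data section", path)
        return cell_type, chrom, mark_names, np.zeros((0, E), dtype=np.int8)
    return cell_type, chrom, mark_names, np.asarray(rows, dtype=np.int8)


def split_concatenated(matrix: np.ndarray) -> list[np.ndarray]:
    """Split a concatenated file matrix on dummy rows into per-gene blocks.

    The last column is taken as the dummy mark; returned blocks exclude the
    dummy rows and the dummy column, inverting the writer's layout exactly.
    """
    matrix = np.asarray(matrix)
    dummy = matrix[:, -1] == 1
    blocks = []
    start = None
    for i, is_dummy in enumerate(dummy):
        if is_dummy:
            if start is not None and i > start:
                blocks.append(matrix[start:i, :-1])
            start = i + 1
        elif start is None:
            raise ValueError("file does not begin with a dummy row")
    if start is not None and start < len(dummy):
        raise ValueError("file does not end with a dummy row")
    return blocks


def gene_row_ranges(matrix: np.ndarray) -> list[tuple[int, int]]:
    """Half-open row index ranges of each gene block in a concatenated matrix."""
    dummy = np.asarray(matrix)[:, -1] == 1
    ranges = []
    start = None
    for i, is_dummy in enumerate(dummy):
        if is_dummy:
            if start is not None and i > start:
                ranges.append((start, i))
            start = i + 1
    return ranges
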