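"""Reading, merging and quality-filtering paired TCR contig tables and GEx matrices.

Single-cell immune-profiling runs produce two linked outputs per sample: a
``filtered_contig.csv`` table with one row per assembled TCR chain (barcode,
locus, V/J genes, CDR3 junction, UMI support, productivity) and a sparse
gene-expression count matrix in Matrix Market triplet form.  This module
standardizes both, resolves each cell to at most one chain per chain group
(alpha/gamma vs beta/delta), and intersects the modalities into a
:class:`Repertoire` restricted to cells observed in both.
"""

from __future__ import annotations

import csv
import gzip
import io
import logging
import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("tcrfirst")

#: Loci accepted in contig tables; anything else ("Multi", "IGH", ...) is dropped.
VALID_LOCI = ("TRA", "TRB", "TRG", "TRD")

#: Chain-group membership: alpha and gamma chains pair with beta/delta partners.
AG_LOCI = frozenset({"TRA", "TRG"})
BD_LOCI = frozenset({"TRB", "TRD"})

_TRUTHY = {"true", "t", "1", "yes"}

# Column synonyms: 10x filtered_contig headers first, AIRR rearrangement second.
_COLUMN_ALIASES = {
    "barcode": ("barcode", "cell_id"),
    "locus": ("chain", "locus"),
    "v_gene": ("v_gene", "v_call"),
    "j_gene": ("j_gene", "j_call"),
    "cdr3_aa": ("cdr3", "junction_aa"),
    "cdr3_nt": ("cdr3_nt", "junction"),
    "umis": ("umis", "duplicate_count"),
    "productive": ("productive",),
}


class FormatError(ValueError):
    """A required column or structural property of an input file is missing."""


@dataclass(frozen=True)
class ContigRecord:
    """One sequenced TCR chain of one cell."""

    barcode: str
    locus: str
    v_gene: str
    j_gene: str
    cdr3_aa: str
    umis: int = 0
    productive: bool = True
    cdr3_nt: Optional[str] = None

    @property
    def chain_group(self) -> str:
        """``"AG"`` for alpha/gamma chains, ``"BD"`` for beta/delta chains."""
        return "AG" if self.locus in AG_LOCI else "BD"


@dataclass(frozen=True)
class Chain:
    locus: str
    v_gene: str
    j_gene: str
    cdr3_aa: str


@dataclass
class Clonotype:
    """A cell-level paired receptor: up to one resolved chain per chain group."""

    barcode: str
    chain_ag: Optional[Chain] = None
    chain_bd: Optional[Chain] = None
    sample_id: str = ""
    flags: tuple = ()

    def __post_init__(self) -> None:
        if self.chain_ag is None and self.chain_bd is None:
            raise ValueError("clonotype must carry at least one chain")

    @property
    def clone_key(self) -> str:
        """Canonical clone identity: ``Vag.Jag_CDR3ag|Vbd.Jbd_CDR3bd``."""

        def part(c: Optional[Chain]) -> str:
            if c is None:
                return "NA"
            return f"{c.v_gene}.{c.j_gene}_{c.cdr3_aa}"

        return f"{part(self.chain_ag)}|{part(self.chain_bd)}"


@dataclass
class GexMatrix:
    """Cells-by-genes sparse count matrix with aligned barcode/feature lists."""

    barcodes: list
    features: list
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.barcodes), len(self.features)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} inconsistent with "
                f"{len(self.barcodes)} barcodes x {len(self.features)} features"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("count matrix contains negative entries")

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    @property
    def n_genes(self) -> int:
        return len(self.features)


@dataclass
class Repertoire:
    """Clonotype table for one or more samples, optionally linked to a GexMatrix."""

    clonotypes: list = field(default_factory=list)
    samples: dict = field(default_factory=dict)
    gex_link: Optional[GexMatrix] = None

    def __len__(self) -> int:
        return len(self.clonotypes)

    def barcodes(self) -> list:
        return [c.barcode for c in self.clonotypes]

    def for_sample(self, sample_id: str) -> list:
        return [c for c in self.clonotypes if c.sample_id == sample_id]

    def unique_clones(self) -> dict:
        """Map clone_key -> cell count across all clonotypes."""
        out: dict = {}
        for c in self.clonotypes:
            out[c.clone_key] = out.get(c.clone_key, 0) + 1
        return out


# ---------------------------------------------------------------------------
# contig parsing
# ---------------------------------------------------------------------------


def _open_text(path):
    if str(path).endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "r", newline="")


def _resolve_columns(header: Sequence[str]) -> dict:
    mapping = {}
    lower = {h.lower(): h for h in header}
    for canon, aliases in _COLUMN_ALIASES.items():
        for a in aliases:
            if a in lower:
                mapping[canon] = lower[a]
                break
    required = ("barcode", "locus", "v_gene", "j_gene", "cdr3_aa")
    for canon in required:
        if canon not in mapping:
            raise FormatError(
                f"contig table is missing required column '{canon}' "
                f"(accepted headers: {_COLUMN_ALIASES[canon]})"
            )
    return mapping


def parse_contigs(path) -> list:
    """Read a 10x ``filtered_contig.csv`` (or AIRR rearrangement TSV) into records.

    Rows whose chain is not one of TRA/TRB/TRG/TRD (e.g. ``Multi``) are dropped
    and the drop count logged.  The productive flag accepts the usual truthy
    spellings ("True"/"true"/"TRUE"/"T").
    """
    with _open_text(path) as fh:
        sniff = fh.read(4096)
        if not sniff.strip():
            logger.warning("contig file %s is empty", path)
            return []
        delimiter = "\t" if "\t" in sniff.splitlines()[0] else ","
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            logger.warning("contig file %s has no header", path)
            return []
        cols = _resolve_columns(reader.fieldnames)
        records = []
        dropped = 0
        for row in reader:
            locus = (row[cols["locus"]] or "").strip()
            if locus not in VALID_LOCI:
                dropped += 1
                continue
            umis_raw = row.get(cols.get("umis", ""), "") or "0"
            try:
                umis = int(float(umis_raw))
            except ValueError:
                umis = 0
            prod_raw = (row.get(cols.get("productive", ""), "") or "true").strip()
            records.append(
                ContigRecord(
                    barcode=row[cols["barcode"]].strip(),
                    locus=locus,
                    v_gene=(row[cols["v_gene"]] or "").strip(),
                    j_gene=(row[cols["j_gene"]] or "").strip(),
                    cdr3_aa=(row[cols["cdr3_aa"]] or "").strip(),
                    umis=umis,
                    productive=prod_raw.lower() in _TRUTHY,
                    cdr3_nt=(row.get(cols.get("cdr3_nt", ""), None) or None),
                )
            )
    if dropped:
        logger.info("parse_contigs: dropped %d rows with unrecognized locus", dropped)
    return records


def merge_chain_sets(ab: Iterable[ContigRecord], gd: Iterable[ContigRecord]):
    """Concatenate separately delivered alpha/beta and gamma/delta contig files.

    Returns ``(records, dual_lineage_barcodes)``.  When one barcode carries both
    an alpha/beta and a gamma/delta receptor all its contigs are retained and
    the barcode is flagged for downstream resolution.
    """
    ab = list(ab)
    gd = list(gd)
    ab_barcodes = {r.barcode for r in ab}
    gd_barcodes = {r.barcode for r in gd}
    dual = sorted(ab_barcodes & gd_barcodes)
    if dual:
        logger.info("merge_chain_sets: %d dual-lineage barcodes flagged", len(dual))
    return ab + gd, dual


def resolve_cell_chains(
    records: Iterable[ContigRecord],
    dual_lineage: Iterable[str] = (),
    keep_dual: bool = False,
    sample_id: str = "",
):
    """Collapse per-barcode contigs into one Clonotype per cell.

    Only productive contigs are considered.  Within each chain group the contig
    with the highest UMI count wins (ties broken by lexicographically smallest
    CDR3, then V gene, for determinism).  Cells with more than two distinct
    productive contigs in one chain group are excluded as multiplets; dual
    alpha/beta + gamma/delta barcodes are excluded unless ``keep_dual``.

    Returns ``(clonotypes, report)`` where report counts multiplets and
    dual-lineage exclusions.
    """
    dual_set = set(dual_lineage)
    by_barcode: dict = {}
    for r in records:
        if not r.productive or not r.cdr3_aa:
            continue
        by_barcode.setdefault(r.barcode, []).append(r)

    clonotypes = []
    multiplets = 0
    dual_excluded = 0
    for barcode in sorted(by_barcode):
        contigs = by_barcode[barcode]
        flags = []
        if barcode in dual_set:
            if not keep_dual:
                dual_excluded += 1
                continue
            flags.append("dual-lineage")
        groups = {"AG": [], "BD": []}
        for c in contigs:
            groups[c.chain_group].append(c)
        # >2 distinct productive contigs in one group suggests a cell multiplet
        distinct = {
            g: {(c.locus, c.v_gene, c.j_gene, c.cdr3_aa) for c in cs}
            for g, cs in groups.items()
        }
        if any(len(d) > 2 for d in distinct.values()):
            multiplets += 1
            continue

        def best(cs):
            if not cs:
                return None
            top = min(cs, key=lambda c: (-c.umis, c.cdr3_aa, c.v_gene))
            return Chain(top.locus, top.v_gene, top.j_gene, top.cdr3_aa)

        clonotypes.append(
            Clonotype(
                barcode=barcode,
                chain_ag=best(groups["AG"]),
                chain_bd=best(groups["BD"]),
                sample_id=sample_id,
                flags=tuple(flags),
            )
        )
    report = {"multiplets_excluded": multiplets, "dual_lineage_excluded": dual_excluded}
    return clonotypes, report


# ---------------------------------------------------------------------------
# GEx ingestion and modality intersection
# ---------------------------------------------------------------------------

_SUFFIX_RE = re.compile(r"-\d+$")


def _read_lines(path) -> list:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        return [ln.split("\t")[0].strip() if "\t" in ln else ln.strip() for ln in fh if ln.strip()]


def _find(dirpath, stem) -> str:
    for name in (stem, stem + ".gz"):
        p = os.path.join(dirpath, name)
        if os.path.exists(p):
            return p
    raise FormatError(f"{stem}[.gz] not found in {dirpath}")


def read_gex_triplet(dirpath) -> GexMatrix:
    """Read a Matrix Market triplet directory (matrix.mtx + barcodes/features tsv).

    Orientation (genes-by-cells, the 10x convention, vs cells-by-genes) is
    auto-detected from the barcode and feature list lengths; gzipped variants
    are accepted.
    """
    mtx_path = _find(dirpath, "matrix.mtx")
    barcodes = _read_lines(_find(dirpath, "barcodes.tsv"))
    # 10x names the gene list either features.tsv or genes.tsv
    try:
        features = _read_lines(_find(dirpath, "features.tsv"))
    except FormatError:
        features = _read_lines(_find(dirpath, "genes.tsv"))
    try:
        if mtx_path.endswith(".gz"):
            with gzip.open(mtx_path, "rb") as fh:
                mat = scipy.io.mmread(fh)
        else:
            mat = scipy.io.mmread(mtx_path)
    except Exception as exc:  # noqa: BLE001 - normalize parser errors
        raise FormatError(f"cannot parse {mtx_path}: {exc}") from exc
    mat = sp.csr_matrix(mat)
    n_b, n_f = len(barcodes), len(features)
    if mat.shape == (n_b, n_f):
        pass
    elif mat.shape == (n_f, n_b):
        mat = sp.csr_matrix(mat.T)
    else:
        raise FormatError(
            f"matrix shape {mat.shape} matches neither {n_b} barcodes x {n_f} "
            f"features nor its transpose"
        )
    return GexMatrix(barcodes=barcodes, features=features, counts=mat)


def write_gex_triplet(gex: GexMatrix, dirpath) -> None:
    """Write a GexMatrix in the genes-by-cells triplet convention."""
    os.makedirs(dirpath, exist_ok=True)
    scipy.io.mmwrite(os.path.join(dirpath, "matrix.mtx"), sp.coo_matrix(gex.counts.T))
    with open(os.path.join(dirpath, "barcodes.tsv"), "w") as fh:
        fh.write("\n".join(gex.barcodes) + "\n")
    with open(os.path.join(dirpath, "features.tsv"), "w") as fh:
        fh.write("\n".join(gex.features) + "\n")


def build_repertoire(
    clonotypes: Iterable[Clonotype],
    gex: GexMatrix,
    sample_id: str = "",
    strip_suffix: bool = False,
):
    """Restrict to cells with both modalities (TCR clonotype and GEx column).

    With ``strip_suffix`` the trailing ``-<digits>`` barcode dialect marker is
    removed symmetrically on both sides before intersecting.  Returns
    ``(repertoire, report)`` with counts of TCR-only, GEx-only and shared cells.
    Zero overlap raises, pointing at the usual suffix-dialect mismatch.
    """
    clonotypes = list(clonotypes)

    def norm(b: str) -> str:
        return _SUFFIX_RE.sub("", b) if strip_suffix else b

    gex_set = {norm(b) for b in gex.barcodes}
    if len(gex_set) != len(gex.barcodes):
        raise FormatError("GEx barcodes are not unique (after normalization)")
    kept = [c for c in clonotypes if norm(c.barcode) in gex_set]
    report = {
        "tcr_only": len(clonotypes) - len(kept),
        "gex_only": len(gex.barcodes) - len(kept),
        "both": len(kept),
    }
    if clonotypes and not kept:
        raise FormatError(
            "no barcode overlap between TCR and GEx inputs; if the barcodes "
            "differ only by a '-1'-style suffix, retry with strip_suffix=True"
        )
    if sample_id:
        for c in kept:
            c.sample_id = sample_id
    rep = Repertoire(
        clonotypes=kept,
        samples={sample_id: {"id": sample_id}} if sample_id else {},
        gex_link=gex,
    )
    return rep, report


def qc_filter_cells(gex: GexMatrix, min_genes: int = 200, max_mito_frac: float = 0.1) -> GexMatrix:
    """Drop low-quality cells: few detected genes or high mitochondrial fraction.

    Mitochondrial genes are recognized by the ``MT-`` symbol prefix.  Raises if
    every cell is removed (thresholds too strict for the input).
    """
    counts = gex.counts
    detected = np.asarray((counts > 0).sum(axis=1)).ravel()
    totals = np.asarray(counts.sum(axis=1)).ravel()
    mito_idx = [i for i, f in enumerate(gex.features) if f.upper().startswith("MT-")]
    if mito_idx:
        mito = np.asarray(counts[:, mito_idx].sum(axis=1)).ravel()
    else:
        mito = np.zeros(gex.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)
    keep = (detected >= min_genes) & (mito_frac <= max_mito_frac)
    if not keep.any():
        raise ValueError(
            f"qc_filter_cells removed all {gex.n_cells} cells "
            f"(min_genes={min_genes}, max_mito_frac={max_mito_frac}); relax thresholds"
        )
    idx = np.flatnonzero(keep)
    return GexMatrix(
        barcodes=[gex.barcodes[i] for i in idx],
        features=list(gex.features),
        counts=gex.counts[idx],
    )


def write_repertoire_tsv(rep: Repertoire, path) -> None:
    """Write the canonical one-row-per-cell repertoire table."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(
            ["barcode", "sample_id", "clone_key", "locus_ag", "v_ag", "j_ag",
             "cdr3_ag", "locus_bd", "v_bd", "j_bd", "cdr3_bd", "flags"]
        )
        for c in rep.clonotypes:
            ag = c.chain_ag or Chain("", "", "", "")
            bd = c.chain_bd or Chain("", "", "", "")
            w.writerow(
                [c.barcode, c.sample_id, c.clone_key, ag.locus, ag.v_gene, ag.j_gene,
                 ag.cdr3_aa, bd.locus, bd.v_gene, bd.j_gene, bd.cdr3_aa,
                 ";".join(c.flags)]
            )
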