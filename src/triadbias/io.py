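"""Readers and writers for 10x-style matrices and annotation tables.

Internal convention is 0-based indexing with genes as rows and cells as
columns; on-disk MatrixMarket files are 1-based per the standard.
"""

from __future__ import annotations

import gzip
import io as _io
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)


class MatrixFormatError(ValueError):
    """A 10x-style matrix directory is malformed or inconsistent."""


class AnnotationError(ValueError):
    """A cell annotation table is malformed or inconsistent with barcodes."""


@dataclass
class CountMatrix:
    """Sparse gene-by-cell integer count matrix with labels."""

    matrix: sp.csr_matrix
    genes: list[str]
    barcodes: list[str]

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        if self.matrix.shape != (len(self.genes), len(self.barcodes)):
            raise MatrixFormatError(
                f"matrix shape {self.matrix.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


def _find(dirpath: Path, stems: list[str]) -> Path:
    for stem in stems:
        for name in (stem, stem + ".gz"):
            p = dirpath / name
            if p.exists():
                return p
    raise FileNotFoundError(f"none of {stems} (or .gz) found in {dirpath}")


def _open_maybe_gzip(path: Path, mode: str = "rt"):
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_tenx(dirpath: str | Path) -> CountMatrix:
    """Read a 10x-style directory (matrix.mtx, features/genes.tsv, barcodes.tsv).

    Accepts gzipped or plain files and the legacy 2-column ``genes.tsv``
    dialect. Integer counts are preserved exactly.
    """
    dirpath = Path(dirpath)
    mtx_path = _find(dirpath, ["matrix.mtx"])
    feat_path = _find(dirpath, ["features.tsv", "genes.tsv"])
    bc_path = _find(dirpath, ["barcodes.tsv"])

    try:
        with _open_maybe_gzip(mtx_path, "rb") as fh:
            mat = scipy.io.mmread(fh)
    except Exception as exc:  # scipy raises bare ValueError on truncation
        raise MatrixFormatError(f"{mtx_path}: cannot parse MatrixMarket file: {exc}") from exc
    if not sp.issparse(mat):
        raise MatrixFormatError(f"{mtx_path}: expected coordinate (sparse) MTX dialect")

    features = pd.read_csv(feat_path, sep="\t", header=None, dtype=str)
    if features.shape[1] < 2:
        # bare one-column gene list
        features[1] = features[0]
    if features.shape[1] < 3:
        features[2] = "Gene Expression"
    barcodes = pd.read_csv(bc_path, sep="\t", header=None, dtype=str)[0].tolist()
    genes = features[0].tolist()
    if mat.shape != (len(genes), len(barcodes)):
        raise MatrixFormatError(
            f"{dirpath}: matrix is {mat.shape} but found "
            f"{len(genes)} features and {len(barcodes)} barcodes"
        )
    return CountMatrix(sp.csr_matrix(mat.astype(np.int64)), genes, barcodes)


def write_tenx(
    cm: CountMatrix,
    dirpath: str | Path,
    compress: bool = True,
    gene_names: list[str] | None = None,
) -> Path:
    """Write a :class:`CountMatrix` as matrix.mtx + features.tsv + barcodes.tsv.

    Output is byte-deterministic: gzip members are written with mtime=0.
    Round-trips exactly through :func:`read_tenx`.
    """
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if compress else ""

    def _write(name: str, payload: bytes) -> None:
        path = dirpath / (name + suffix)
        if compress:
            with open(path, "wb") as raw:
                with gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0) as gz:
                    gz.write(payload)
        else:
            path.write_bytes(payload)

    buf = _io.BytesIO()
    scipy.io.mmwrite(buf, sp.coo_matrix(cm.matrix), field="integer")
    _write("matrix.mtx", buf.getvalue())

    names = gene_names or cm.genes
    feat = "".join(
        f"{gid}\t{name}\tGene Expression\n" for gid, name in zip(cm.genes, names)
    )
    _write("features.tsv", feat.encode())
    _write("barcodes.tsv", "".join(b + "\n" for b in cm.barcodes).encode())
    return dirpath


def read_annotation(
    path: str | Path,
    barcodes: list[str] | None = None,
) -> pd.DataFrame:
    """Read a cell annotation TSV (``cell_id``, ``cluster``, optional
    ``pseudotime``/``branch``/``segment``).

    Pseudotime values outside [0, 1] are rescaled to rank order with a
    warning. When ``barcodes`` is given, the annotation must cover all of
    them; unknown extra cells are reported and kept.
    """
    path = Path(path)
    ann = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "cluster": str})
    for col in ("cell_id", "cluster"):
        if col not in ann.columns:
            raise AnnotationError(f"{path}: missing required column {col!r}")
    dups = ann["cell_id"][ann["cell_id"].duplicated()]
    if not dups.empty:
        raise AnnotationError(f"{path}: duplicate cell_id values: {sorted(set(dups))[:10]}")
    if "pseudotime" in ann.columns:
        pt = ann["pseudotime"].astype(float)
        finite = pt.dropna()
        if not finite.empty and (finite.min() < 0 or finite.max() > 1):
            logger.warning(
                "%s: pseudotime outside [0,1]; rescaling to rank order", path
            )
            ranks = pt.rank(method="average") - 1
            denom = max(pt.notna().sum() - 1, 1)
            ann["pseudotime"] = ranks / denom
    if barcodes is not None:
        known = set(ann["cell_id"])
        missing = [b for b in barcodes if b not in known]
        if missing:
            raise AnnotationError(
                f"{path}: {len(missing)} barcode(s) missing from annotation: "
                f"{missing[:10]}"
            )
        extra = known.difference(barcodes)
        if extra:
            logger.warning("%s: %d annotated cells not in barcode list", path, len(extra))
    return ann


def read_grouped_tsv(path: str | Path) -> pd.DataFrame:
    """Read a dense gene-by-group expression TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise MatrixFormatError(f"{path}: duplicate gene identifiers in first column")
    return df.astype(float)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    """Write a table as TSV with a stable float format."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")
    return path
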