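"""Chemogenomic matrix container and file formats.

The central object is :class:`ChemGenMatrix`, a compound × gene matrix of
fitness-defect p-values (or transformed scores) with an explicit
present/missing mask. Rows are compounds because the analysis clusters
compounds by their genetic interaction profiles.

Three dialects are supported:

* a plain TSV matrix (header row of gene ids, first column of compound ids,
  missing cells written as ``NA``),
* Cluster-3.0 ``.cdt`` / ``.gtr`` files so a clustering result can be opened
  directly in Java TreeView.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError, StateError

if TYPE_CHECKING:  # pragma: no cover
    from .hierarchy import Dendrogram

log = logging.getLogger(__name__)

MISSING_TOKENS = ("NA", "")

#: Valid transform tags: raw fitness-defect p-values, or -log10 scores.
TRANSFORM_TAGS = ("raw_p", "neglog10")


@dataclass
class ChemGenMatrix:
    """Compound × gene matrix of interaction scores with a missing-value mask.

    Parameters
    ----------
    compound_ids :
        Ordered, unique row identifiers.
    gene_ids :
        Ordered, unique column identifiers.
    values :
        Float matrix of shape ``(len(compound_ids), len(gene_ids))``. Entries
        at masked-out cells are ignored (stored as NaN).
    mask :
        Boolean matrix, ``True`` where a value is present.
    transform_tag :
        ``"raw_p"`` for untransformed p-values (values must lie in [0, 1]) or
        ``"neglog10"`` after a -log10 transform.
    """

    compound_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    transform_tag: str = "raw_p"

    def __post_init__(self) -> None:
        self.compound_ids = [str(c) for c in self.compound_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = ~np.isnan(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        n, g = len(self.compound_ids), len(self.gene_ids)
        if self.values.shape != (n, g):
            raise FormatError(
                f"values shape {self.values.shape} does not match "
                f"{n} compounds x {g} genes"
            )
        if self.mask.shape != self.values.shape:
            raise FormatError("mask shape does not match values shape")
        if len(set(self.compound_ids)) != n:
            raise FormatError("duplicate compound identifiers")
        if len(set(self.gene_ids)) != g:
            raise FormatError("duplicate gene identifiers")
        if self.transform_tag not in TRANSFORM_TAGS:
            raise FormatError(f"unknown transform tag {self.transform_tag!r}")
        present = self.values[self.mask]
        if present.size and not np.all(np.isfinite(present)):
            raise FormatError("non-finite value in a present cell")
        if self.transform_tag == "raw_p" and present.size:
            if present.min() < 0.0 or present.max() > 1.0:
                raise FormatError("raw_p values must lie in [0, 1]")
        # normalise masked cells to NaN so equality semantics are simple
        self.values = np.where(self.mask, self.values, np.nan)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row_index(self, compound_id: str) -> int:
        try:
            return self.compound_ids.index(compound_id)
        except ValueError:
            from .errors import IdentifierError

            raise IdentifierError(f"unknown compound {compound_id!r}") from None

    def to_frame(self) -> pd.DataFrame:
        """Return a DataFrame view (missing cells as NaN)."""
        return pd.DataFrame(
            np.where(self.mask, self.values, np.nan),
            index=pd.Index(self.compound_ids, name="compound"),
            columns=self.gene_ids,
        )


def read_matrix(path: str | Path) -> ChemGenMatrix:
    """Read a compound × gene TSV matrix.

    First row: header whose first cell is a label and remaining cells are
    gene ids. Following rows: compound id then one value per gene. Empty
    cells or ``NA`` are missing. Errors name the offending 1-based line.
    """
    path = Path(path)
    raw_lines = path.read_text(encoding="utf-8").splitlines()
    if not raw_lines:
        raise FormatError(f"{path}: empty file")
    header = raw_lines[0].split("\t")
    ncol = len(header)
    if ncol < 2:
        raise FormatError(f"{path}: line 1: header has no gene columns")
    gene_ids = header[1:]
    if len(set(gene_ids)) != len(gene_ids):
        raise FormatError(f"{path}: line 1: duplicate gene identifier in header")
    for lineno, line in enumerate(raw_lines[1:], start=2):
        nfields = len(line.split("\t"))
        if nfields != ncol:
            raise FormatError(
                f"{path}: line {lineno}: expected {ncol} fields, found {nfields}"
            )
    cells = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        dtype=str,
        na_values=list(MISSING_TOKENS),
        keep_default_na=False,
        skip_blank_lines=False,
    )
    compound_ids = [str(c) for c in cells.index]
    if len(set(compound_ids)) != len(compound_ids):
        raise FormatError(f"{path}: duplicate compound identifier in first column")
    values = cells.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    mask = ~cells.isna().to_numpy()
    bad = mask & np.isnan(values)
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise FormatError(
            f"{path}: line {i + 2}: non-numeric cell {cells.iat[i, j]!r} "
            f"in column {cells.columns[j]!r}"
        )
    return ChemGenMatrix(compound_ids, [str(g) for g in cells.columns], values, mask)


def write_matrix(m: ChemGenMatrix, path: str | Path) -> None:
    """Write ``m`` as TSV (round-trips through :func:`read_matrix`)."""
    df = m.to_frame()
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.12g", lineterminator="\n")


def transform_profiles(
    m: ChemGenMatrix, mode: str, cap: float = 10.0
) -> ChemGenMatrix:
    """Optionally transform raw p-values to capped -log10 scores.

    ``raw_p`` returns the matrix unchanged (the analysis default: the
    original study clustered raw p-values directly). ``neglog10`` maps each
    present p to ``min(-log10(max(p, 10**-cap)), cap)`` — a convenience mode
    that de-emphasises the bulk of non-significant values; note it changes
    which compounds look similar and is therefore never applied silently.
    """
    if mode not in TRANSFORM_TAGS:
        raise StateError(f"unknown transform mode {mode!r}")
    if mode == "raw_p":
        return m
    if m.transform_tag != "raw_p":
        raise StateError("matrix already transformed; refusing to re-transform")
    if cap <= 0:
        raise StateError("cap must be positive")
    floor = 10.0 ** (-cap)
    vals = np.where(m.mask, -np.log10(np.maximum(m.values, floor)), np.nan)
    vals = np.minimum(vals, cap)
    return ChemGenMatrix(
        list(m.compound_ids), list(m.gene_ids), vals, m.mask.copy(), "neglog10"
    )


def _node_ref(ref: int, n: int) -> str:
    """TreeView node naming: leaves GENE{i}X, internal nodes NODE{k}X (1-based)."""
    if ref < n:
        return f"GENE{ref}X"
    return f"NODE{ref - n + 1}X"


def write_cdt_gtr(m: ChemGenMatrix, d: "Dendrogram", basename: str | Path) -> tuple[Path, Path]:
    """Emit Cluster-3.0 compatible ``.cdt`` and ``.gtr`` files.

    The ``.cdt`` lists compounds in dendrogram leaf order with GID keys
    matching the ``.gtr`` leaf references; the ``.gtr`` has one line per
    merge with score ``1 - height/h_max`` so that scores read as similarity
    in [0, 1] (the convention TreeView expects: larger = tighter).
    """
    if list(d.leaf_ids) != list(m.compound_ids):
        raise ConsistencyError(
            "dendrogram leaves do not match matrix compounds (order-sensitive)"
        )
    n = len(m.compound_ids)
    base = Path(basename)
    cdt_path = base.with_suffix(".cdt")
    gtr_path = base.with_suffix(".gtr")

    heights = [mg.height for mg in d.merges]
    h_max = max(heights) if heights else 0.0
    if h_max <= 0.0:
        h_max = 1.0  # all merges at zero height: every score is 1

    with gtr_path.open("w", encoding="utf-8", newline="\n") as fh:
        for k, mg in enumerate(d.merges, start=1):
            score = 1.0 - mg.height / h_max
            fh.write(
                f"NODE{k}X\t{_node_ref(mg.left, n)}\t{_node_ref(mg.right, n)}"
                f"\t{score:.10g}\n"
            )

    with cdt_path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("GID\tUNIQID\tNAME\tGWEIGHT\t" + "\t".join(m.gene_ids) + "\n")
        for i in d.leaf_order():
            cid = m.compound_ids[i]
            row = [
                "" if not m.mask[i, j] else f"{m.values[i, j]:.12g}"
                for j in range(len(m.gene_ids))
            ]
            fh.write(f"GENE{i}X\t{cid}\t{cid}\t1\t" + "\t".join(row) + "\n")
    log.debug("wrote %s and %s", cdt_path, gtr_path)
    return cdt_path, gtr_path
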