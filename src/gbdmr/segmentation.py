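"""Segmentation of coordinate-ordered CpG sites into correlation blocks.

CpGs are ordered by chromosome (natural order: chr1, chr2, ..., chr10,
..., chrX, chrY) and base-pair position.  The Pearson correlation of
every adjacent pair is computed on the beta-value scale, and maximal
runs whose internal adjacent correlations all exceed a threshold
(default 0.5) form multi-CpG blocks; any CpG without a sufficiently
correlated neighbour forms a block by itself.  Blocks never span a
chromosome boundary.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel placed where an adjacent correlation is undefined or must
#: never chain CpGs together (chromosome boundary, zero-variance CpG).
#: It is below -1, hence below any admissible threshold.
CHROM_BOUNDARY = -2.0

ANNOTATION_COLUMNS = ("cpg_id", "chromosome", "position")


def chromosome_sort_key(chrom: str):
    """Natural sort key: chr1 < chr2 < ... < chr10 < ... < chrX < chrY < chrM."""
    name = str(chrom)
    stripped = re.sub(r"^chr", "", name, flags=re.IGNORECASE)
    if stripped.isdigit():
        return (0, int(stripped), "")
    special = {"X": 0, "Y": 1, "M": 2, "MT": 2}
    if stripped.upper() in special:
        return (1, special[stripped.upper()], "")
    return (2, 0, stripped)


def sort_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Sort an annotation table by (chromosome, position, cpg_id).

    The table must have columns ``cpg_id``, ``chromosome``, ``position``
    (the columns of an Illumina 450k/EPIC manifest).  Position ties are
    broken by CpG ID so the order is total and reproducible.
    """
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotation.columns]
    if missing:
        raise ValueError(f"annotation is missing columns {missing}")
    if annotation["cpg_id"].duplicated().any():
        raise ValueError("annotation contains duplicated cpg_id values")
    if (annotation["position"].astype(int) < 1).any():
        raise ValueError("positions must be >= 1 (1-based coordinates)")
    key = annotation["chromosome"].map(chromosome_sort_key)
    order = (
        annotation.assign(_k=key)
        .sort_values(["_k", "position", "cpg_id"], kind="mergesort")
        .drop(columns="_k")
    )
    return order.reset_index(drop=True)


@dataclass
class Block:
    """A maximal run of adjacent, correlated CpGs on one chromosome.

    Coordinates are 1-based inclusive (manifest convention); use
    :func:`blocks_to_bed` for 0-based half-open BED export.
    """

    block_id: int
    cpg_ids: list[str]
    chromosome: str
    start: int
    end: int
    adjacent_correlations: list[float] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.cpg_ids)

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("a block must contain at least one CpG")
        if self.start > self.end:
            raise ValueError("block start must be <= end")
        if len(self.adjacent_correlations) != self.size - 1:
            raise ValueError("need exactly size-1 adjacent correlations")


def adjacent_correlations(beta_matrix: np.ndarray, annotation: pd.DataFrame) -> np.ndarray:
    """Pearson correlation of each adjacent CpG pair.

    Parameters
    ----------
    beta_matrix
        ``(n_samples, m_cpgs)`` array whose columns align with the rows
        of the coordinate-sorted ``annotation``.
    annotation
        Sorted annotation table (see :func:`sort_annotation`).

    Returns
    -------
    ndarray
        Length ``m - 1`` vector; entry ``j`` is the correlation between
        CpG ``j`` and CpG ``j + 1`` over samples where both are present.
        Pairs spanning a chromosome boundary, and pairs involving a
        zero-variance CpG, receive :data:`CHROM_BOUNDARY`.
    """
    B = np.asarray(beta_matrix, dtype=float)
    if B.ndim != 2:
        raise ValueError("beta_matrix must be 2-D (samples x CpGs)")
    n, m = B.shape
    if m != len(annotation):
        raise ValueError("beta_matrix columns do not match annotation rows")
    if n < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    if m < 2:
        return np.empty(0)

    chroms = annotation["chromosome"].to_numpy()
    same_chrom = chroms[:-1] == chroms[1:]
    out = np.full(m - 1, CHROM_BOUNDARY)

    if not np.isnan(B).any():
        centred = B - B.mean(axis=0)
        norms = np.sqrt((centred**2).sum(axis=0))
        num = (centred[:, :-1] * centred[:, 1:]).sum(axis=0)
        den = norms[:-1] * norms[1:]
        with np.errstate(invalid="ignore", divide="ignore"):
            r = num / den
        # relative tolerance: a column of repeated values is constant even
        # when its floating-point mean is off in the last ulp
        tiny = 1e-10 * (np.abs(B).max(axis=0) + 1.0) * np.sqrt(n)
        zero_var = norms < tiny
        degenerate = zero_var[:-1] | zero_var[1:]
        if degenerate.any():
            warnings.warn(
                f"{int(degenerate.sum())} adjacent pair(s) involve a zero-variance "
                "CpG; their correlation is undefined and treated as a break",
                RuntimeWarning,
                stacklevel=2,
            )
        ok = same_chrom & ~degenerate
        out[ok] = np.clip(r[ok], -1.0, 1.0)
        return out

    # pairwise-complete path in the presence of missing values
    for j in np.flatnonzero(same_chrom):
        x, y = B[:, j], B[:, j + 1]
        mask = ~(np.isnan(x) | np.isnan(y))
        if mask.sum() < 3:
            warnings.warn(
                f"fewer than 3 complete sample pairs for CpGs {j} and {j + 1}",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        xs, ys = x[mask], y[mask]
        tiny = 1e-10 * (max(abs(xs).max(), abs(ys).max()) + 1.0)
        if xs.std() < tiny or ys.std() < tiny:
            warnings.warn(
                f"zero-variance CpG in pair ({j}, {j + 1}); correlation undefined",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        out[j] = np.clip(np.corrcoef(xs, ys)[0, 1], -1.0, 1.0)
    return out


def segment_blocks(
    correlations: np.ndarray,
    annotation: pd.DataFrame,
    threshold: float = 0.5,
    max_gap: int | None = None,
) -> list[Block]:
    """Chain CpGs into blocks wherever adjacent correlation exceeds ``threshold``.

    The inequality is strict (``r > threshold``): a tie at exactly the
    threshold breaks the chain.  The returned blocks partition all CpGs,
    so block sizes always sum to ``m``.

    Parameters
    ----------
    correlations
        Output of :func:`adjacent_correlations` (length ``m - 1``).
    annotation
        The same sorted annotation the correlations were computed on.
    threshold
        Correlation threshold in (0, 1); 0.5 by default.
    max_gap
        Optional maximum base-pair gap between chained neighbours; by
        default no distance cap is applied (correlation is the sole
        chaining criterion).
    """
    m = len(annotation)
    if m == 0:
        return []
    corr = np.asarray(correlations, dtype=float)
    if corr.shape != (max(m - 1, 0),):
        raise ValueError("correlations must have length m - 1")

    chroms = annotation["chromosome"].to_numpy()
    positions = annotation["position"].to_numpy().astype(int)
    cpg_ids = annotation["cpg_id"].to_numpy()

    blocks: list[Block] = []
    start = 0
    for j in range(m - 1):
        chain = (
            corr[j] > threshold
            and chroms[j] == chroms[j + 1]
            and (max_gap is None or positions[j + 1] - positions[j] <= max_gap)
        )
        if not chain:
            blocks.append(
                Block(
                    block_id=len(blocks),
                    cpg_ids=list(cpg_ids[start : j + 1]),
                    chromosome=str(chroms[start]),
                    start=int(positions[start]),
                    end=int(positions[j]),
                    adjacent_correlations=[float(c) for c in corr[start:j]],
                )
            )
            start = j + 1
    blocks.append(
        Block(
            block_id=len(blocks),
            cpg_ids=list(cpg_ids[start:m]),
            chromosome=str(chroms[start]),
            start=int(positions[start]),
            end=int(positions[m - 1]),
            adjacent_correlations=[float(c) for c in corr[start : m - 1]],
        )
    )
    return blocks


def read_annotation(path) -> pd.DataFrame:
    """Read a (cpg_id, chromosome, position) table from TSV/CSV."""
    sep = "," if str(path).endswith(".csv") else "\t"
    ann = pd.read_csv(path, sep=sep, dtype={"cpg_id": str, "chromosome": str})
    return sort_annotation(ann)


def blocks_to_bed(blocks: list[Block]) -> pd.DataFrame:
    """Convert blocks to a BED-style frame (0-based half-open)."""
    return pd.DataFrame(
        {
            "chrom": [b.chromosome for b in blocks],
            "chromStart": [b.start - 1 for b in blocks],
            "chromEnd": [b.end for b in blocks],
            "name": [f"block_{b.block_id}" for b in blocks],
            "size": [b.size for b in blocks],
        }
    )
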