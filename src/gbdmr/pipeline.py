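"""End-to-end DMR detection: read, segment, fit, test, adjust, classify.

The pipeline consumes a CpG-by-sample beta-value matrix, a per-sample
phenotype/covariate table and a CpG annotation (manifest) table, clips
beta values away from the boundaries, segments CpGs into correlation
blocks, runs the generalized beta likelihood-ratio test per block,
adjusts p-values across blocks and labels significant blocks as DMRs
(multi-CpG) or DMPs (single CpG).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from statsmodels.stats.multitest import multipletests

from .regression import RegressionData, lrt_block
from .segmentation import (
    Block,
    adjacent_correlations,
    segment_blocks,
    sort_annotation,
)

logger = logging.getLogger(__name__)

#: beta values are clipped into [BETA_CLIP, 1 - BETA_CLIP]; the density
#: is undefined at the boundaries {0, 1}
BETA_CLIP = 1e-6

CORRECTION_METHODS = ("bonferroni", "holm", "bh", "none")


@dataclass
class MethylationDataset:
    """Aligned beta matrix, annotation and phenotype table.

    ``beta``: samples x CpGs DataFrame with values in (0, 1);
    ``annotation``: (cpg_id, chromosome, position) table covering every
    CpG column; ``phenotypes``: per-sample table indexed by sample ID.
    """

    beta: pd.DataFrame
    annotation: pd.DataFrame
    phenotypes: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.beta.index.equals(self.phenotypes.index):
            raise ValueError("beta matrix and phenotype table sample IDs differ")
        missing = set(self.beta.columns) - set(self.annotation["cpg_id"])
        if missing:
            raise ValueError(f"{len(missing)} CpG column(s) lack annotation")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.index)


@dataclass
class DMRResult:
    """One tested block with its test outcome and classification."""

    block_id: int
    chromosome: str
    start: int
    end: int
    cpg_ids: list[str]
    block_size: int
    gamma1_estimate: float
    lrt_statistic: float
    p_value: float
    p_adjusted: float = np.nan
    significant: bool = False
    label: str = "null"          # DMR (significant, L >= 2), DMP (significant, L == 1)
    converged: bool = True


def _read_table(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def read_dataset(beta_path, phenotype_path, annotation_path) -> MethylationDataset:
    """Read and align the three input tables.

    The beta table is CpG-by-sample (manifest orientation) and is
    transposed internally; samples missing from either table are dropped
    with a logged count; beta values are clipped into
    ``[1e-6, 1 - 1e-6]`` with the number of clipped cells logged.
    """
    beta_raw = _read_table(beta_path)
    try:
        beta_raw = beta_raw.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        bad = beta_raw.apply(pd.to_numeric, errors="coerce")
        rows, cols = np.where(bad.isna() & beta_raw.notna())
        where = ", ".join(
            f"(row {beta_raw.index[r]!r}, column {beta_raw.columns[c]!r})"
            for r, c in list(zip(rows, cols))[:5]
        )
        raise ValueError(f"non-numeric beta value(s) at {where}") from exc
    beta = beta_raw.T                      # samples x CpGs

    pheno = _read_table(phenotype_path)
    sep = "," if str(annotation_path).endswith(".csv") else "\t"
    annotation = pd.read_csv(
        annotation_path, sep=sep, dtype={"cpg_id": str, "chromosome": str}
    )

    shared = beta.index.intersection(pheno.index)
    if len(shared) == 0:
        raise ValueError("no overlapping samples between beta matrix and phenotype table")
    dropped = (len(beta) - len(shared)) + (len(pheno) - len(shared))
    if dropped:
        logger.warning("dropped %d sample(s) missing from one of the tables", dropped)
    beta = beta.loc[shared]
    pheno = pheno.loc[shared]

    annotated = beta.columns.intersection(annotation["cpg_id"])
    if len(annotated) < beta.shape[1]:
        logger.warning(
            "dropped %d CpG(s) without annotation", beta.shape[1] - len(annotated)
        )
        beta = beta[annotated]

    values = beta.to_numpy(dtype=float)
    n_clipped = int(((values < BETA_CLIP) | (values > 1.0 - BETA_CLIP)).sum())
    if n_clipped:
        logger.info("clipped %d beta value(s) into [%g, %g]", n_clipped, BETA_CLIP, 1 - BETA_CLIP)
    beta = pd.DataFrame(
        np.clip(values, BETA_CLIP, 1.0 - BETA_CLIP), index=beta.index, columns=beta.columns
    )
    annotation = annotation[annotation["cpg_id"].isin(beta.columns)].reset_index(drop=True)
    return MethylationDataset(beta=beta, annotation=annotation, phenotypes=pheno)


def adjust_pvalues(p, method: str = "bonferroni") -> np.ndarray:
    """Multiple-testing adjustment across blocks.

    ``bonferroni``: ``min(1, p * B)`` with ``B`` the number of
    non-missing tests; ``holm`` and ``bh`` are the standard step
    procedures; ``none`` returns the raw p-values (per-test mode).
    Missing (NaN) entries stay missing and are excluded from ``B``.
    """
    p = np.asarray(p, dtype=float)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in CORRECTION_METHODS:
        raise ValueError(f"unknown correction method {method!r}; choose from {CORRECTION_METHODS}")
    out = np.full_like(p, np.nan)
    if method == "none":
        out[ok] = p[ok]
        return out
    if ok.sum() == 0:
        return out
    if method == "bonferroni":
        out[ok] = np.minimum(1.0, p[ok] * ok.sum())
        return out
    sm_method = {"holm": "holm", "bh": "fdr_bh"}[method]
    out[ok] = multipletests(p[ok], method=sm_method)[1]
    return out


def _build_design(
    phenotypes: pd.DataFrame, phenotype_name: str, covariate_names
) -> np.ndarray:
    cols = [phenotype_name, *covariate_names]
    missing = [c for c in cols if c not in phenotypes.columns]
    if missing:
        raise ValueError(f"phenotype table lacks column(s) {missing}")
    mat = []
    for c in cols:
        v = phenotypes[c]
        if not pd.api.types.is_numeric_dtype(v):
            levels = sorted(v.dropna().unique())
            if len(levels) != 2:
                raise ValueError(
                    f"non-numeric column {c!r} must have exactly 2 levels to be 0/1 coded"
                )
            v = v.map({levels[0]: 0.0, levels[1]: 1.0})
            logger.info("coded %r as 0=%r, 1=%r", c, levels[0], levels[1])
        mat.append(v.to_numpy(dtype=float))
    X = np.column_stack([np.ones(len(phenotypes)), *mat])
    if np.isnan(X).any():
        raise ValueError("missing values in phenotype/covariate columns")
    return X


def _test_block(block: Block, Z: np.ndarray, X: np.ndarray, seed_child) -> DMRResult:
    rng = np.random.default_rng(seed_child)
    converged = True
    try:
        data = RegressionData(Z, X)
        res = lrt_block(data, seed=rng)
        stat, p = res.statistic, res.p_value
        gamma1 = float(res.fit_full.gamma_slopes[0])
        converged = res.fit_full.converged and res.fit_null.converged
    except ValueError as exc:
        logger.warning("block %d failed: %s", block.block_id, exc)
        stat, p, gamma1, converged = np.nan, np.nan, np.nan, False
    return DMRResult(
        block_id=block.block_id,
        chromosome=block.chromosome,
        start=block.start,
        end=block.end,
        cpg_ids=list(block.cpg_ids),
        block_size=block.size,
        gamma1_estimate=gamma1,
        lrt_statistic=stat,
        p_value=p,
        converged=converged,
    )


def run_gbdmr(
    dataset: MethylationDataset,
    phenotype_name: str,
    covariate_names=(),
    threshold: float = 0.5,
    alpha_level: float = 0.05,
    correction: str = "bonferroni",
    seed: int = 0,
    n_threads: int = 1,
    max_gap: int | None = None,
) -> list[DMRResult]:
    """Run the full detector and return one result per block.

    Blocks are pure functions of (block data, block seed), so the result
    is independent of ``n_threads``; the output is sorted by genomic
    position.  Per-block convergence failures are flagged in the result
    (``p_value`` missing) rather than aborting the run.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    annotation = sort_annotation(dataset.annotation)
    beta = dataset.beta[annotation["cpg_id"]]
    B = beta.to_numpy(dtype=float)

    corr = adjacent_correlations(B, annotation)
    blocks = segment_blocks(corr, annotation, threshold=threshold, max_gap=max_gap)
    X = _build_design(dataset.phenotypes, phenotype_name, covariate_names)

    col_of = {c: i for i, c in enumerate(beta.columns)}
    tasks = []
    for block in blocks:
        idx = [col_of[c] for c in block.cpg_ids]
        # independent child seed per block: scheduling cannot change results
        child = np.random.SeedSequence(entropy=seed, spawn_key=(block.block_id,))
        tasks.append((block, B[:, idx], child))

    if n_threads == 1:
        results = [_test_block(b, Z, X, s) for b, Z, s in tasks]
    else:
        results = Parallel(n_jobs=n_threads)(
            delayed(_test_block)(b, Z, X, s) for b, Z, s in tasks
        )

    p_adj = adjust_pvalues([r.p_value for r in results], method=correction)
    for r, pa in zip(results, p_adj):
        r.p_adjusted = float(pa) if np.isfinite(pa) else np.nan
        r.significant = bool(np.isfinite(pa) and pa <= alpha_level)
        r.label = ("DMR" if r.block_size >= 2 else "DMP") if r.significant else "null"
    n_failed = sum(not r.converged for r in results)
    if n_failed:
        logger.warning("%d block fit(s) did not converge", n_failed)
    return results


def results_to_frame(results: list[DMRResult]) -> pd.DataFrame:
    """Flatten results to a tidy table (cpg_ids joined with ';')."""
    return pd.DataFrame(
        {
            "block_id": [r.block_id for r in results],
            "chromosome": [r.chromosome for r in results],
            "start": [r.start for r in results],
            "end": [r.end for r in results],
            "cpg_ids": [";".join(r.cpg_ids) for r in results],
            "block_size": [r.block_size for r in results],
            "gamma1_estimate": [r.gamma1_estimate for r in results],
            "lrt_statistic": [r.lrt_statistic for r in results],
            "p_value": [r.p_value for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "significant": [r.significant for r in results],
            "label": [r.label for r in results],
            "converged": [r.converged for r in results],
        }
    )


def write_results(results: list[DMRResult], path, fmt: str = "tsv") -> None:
    """Write results as TSV (all fields) or BED (0-based half-open).

    The BED score is ``-log10`` of the adjusted p-value, capped at 1000;
    the TSV round-trips bit-exactly through :func:`read_results`.
    """
    if fmt == "tsv":
        results_to_frame(results).to_csv(path, sep="\t", index=False)
    elif fmt == "bed":
        with np.errstate(divide="ignore"):
            scores = [
                min(1000.0, float(-np.log10(r.p_adjusted)))
                if np.isfinite(r.p_adjusted) and r.p_adjusted > 0
                else (1000.0 if r.p_adjusted == 0 else 0.0)
                for r in results
            ]
        bed = pd.DataFrame(
            {
                "chrom": [r.chromosome for r in results],
                "chromStart": [r.start - 1 for r in results],
                "chromEnd": [r.end for r in results],
                "name": [f"block_{r.block_id}" for r in results],
                "score": scores,
            }
        )
        bed.to_csv(path, sep="\t", index=False, header=False)
    else:
        raise ValueError(f"unknown format {fmt!r}; choose 'tsv' or 'bed'")


def read_results(path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_results`.

    The ``label`` column's "null" level must survive the round trip, so
    only empty cells count as missing.
    """
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
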