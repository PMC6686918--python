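"""Population diagnostics on dosage data: short-range LD and PCA.

Linkage disequilibrium is the squared Pearson correlation of dosage
vectors (0..ploidy codes, no phasing) between same-chromosome marker
pairs within a base-pair window, pooled per reference genome; principal
components of the column-centered dosage matrix summarize population
structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from polygs.dosage import MISSING, DosageMatrix

logger = logging.getLogger(__name__)

__all__ = ["LdReport", "ld_r2", "pca_dosage"]


@dataclass
class LdReport:
    """Window-limited pairwise r2 values and per-reference summaries."""

    pairs: pd.DataFrame  # marker1, marker2, reference, chrom, distance_bp, r2
    by_reference: pd.DataFrame  # mean r2, n pairs, p90 per reference
    adjacent_mean: float  # mean r2 over physically adjacent in-window pairs
    n_skipped: int  # zero-variance pairs


def _pair_r2(x: np.ndarray, y: np.ndarray) -> float | None:
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 3:
        return None
    xv = x[ok].astype(float)
    yv = y[ok].astype(float)
    if xv.std() == 0 or yv.std() == 0:
        return None
    r = np.corrcoef(xv, yv)[0, 1]
    return float(r * r)


def ld_r2(
    dosages: DosageMatrix,
    window_bp: int = 1500,
    positions: pd.DataFrame | None = None,
) -> LdReport:
    """Squared dosage correlation for same-chromosome pairs within a window.

    ``positions`` defaults to the matrix's marker metadata (columns
    ``reference``, ``chrom``, ``pos``).  Pairs involving a zero-variance
    marker are skipped with a log entry; missing entries are handled
    pairwise-complete.
    """
    meta = positions if positions is not None else dosages.metadata
    if meta is None:
        raise ValueError("marker positions required (metadata or positions argument)")
    meta = meta.loc[dosages.markers]
    data = dosages.data
    rows = []
    n_skipped = 0
    for (ref, chrom), block in meta.groupby(["reference", "chrom"], sort=False):
        order = block["pos"].sort_values().index
        pos = block.loc[order, "pos"].to_numpy()
        idx = dosages.markers.get_indexer(order)
        for a in range(len(order)):
            for b in range(a + 1, len(order)):
                dist = int(pos[b] - pos[a])
                if dist > window_bp:
                    break
                r2 = _pair_r2(data[:, idx[a]], data[:, idx[b]])
                if r2 is None:
                    logger.info(
                        "skipping pair %s/%s: zero variance or too few complete pairs",
                        order[a], order[b],
                    )
                    n_skipped += 1
                    continue
                rows.append(
                    {
                        "marker1": order[a],
                        "marker2": order[b],
                        "reference": ref,
                        "chrom": chrom,
                        "distance_bp": dist,
                        "r2": r2,
                        "adjacent": b == a + 1,
                    }
                )
    pairs = pd.DataFrame(
        rows,
        columns=["marker1", "marker2", "reference", "chrom", "distance_bp", "r2", "adjacent"],
    )
    if len(pairs):
        by_ref = (
            pairs.groupby("reference")["r2"]
            .agg(mean_r2="mean", n_pairs="count", p90=lambda s: s.quantile(0.9))
            .reset_index()
        )
        adjacent_mean = float(pairs.loc[pairs["adjacent"], "r2"].mean())
    else:
        by_ref = pd.DataFrame(columns=["reference", "mean_r2", "n_pairs", "p90"])
        adjacent_mean = float("nan")
    return LdReport(
        pairs=pairs.drop(columns="adjacent"),
        by_reference=by_ref,
        adjacent_mean=adjacent_mean,
        n_skipped=n_skipped,
    )


def pca_dosage(
    dosages: DosageMatrix, n_components: int = 10
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of the column-centered dosage matrix.

    Returns per-individual scores and the explained-variance fractions
    of the leading components.
    """
    X = dosages.complete_array()
    n, p = X.shape
    if n_components > min(n, p):
        raise ValueError("n_components exceeds min(n_individuals, n_markers)")
    Xc = X - X.mean(axis=0)
    total_var = float((Xc**2).sum())
    if total_var <= 0:
        raise ValueError("constant dosage matrix has no principal components")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :n_components] * S[:n_components]
    explained = (S[:n_components] ** 2) / total_var
    frame = pd.DataFrame(
        scores,
        index=dosages.individuals,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return frame, explained
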