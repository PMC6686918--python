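"""Allele-dosage containers, genotype calling and marker quality control.

Dosage here counts copies of the reference allele at a biallelic locus,
an integer in ``{0, .., ploidy}``.  Calling works marker-by-marker from
reference/alternative read depths: read counts for an individual of dose
``d`` are modelled as Binomial with success probability
``q_d = (d/ploidy) * (1 - 2*e) + e`` where ``e`` is the per-read miscall
probability, and the population at one marker is a ``ploidy + 1``
component binomial mixture whose weights are free.  An EM fit followed by
maximum-a-posteriori assignment gives the dosage call; low-posterior
calls are set missing.

The marker QC chain mirrors standard GBS practice for polyploids:
mean-depth filter, minor-allele-frequency filter, missingness filter,
then dose-frequency imputation.  ``diploidize`` collapses the three
tetraploid heterozygote classes to a single diploid heterozygote for the
tetraploid-versus-diploid coding comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "ReadCountTable",
    "DosageMatrix",
    "CallDiagnostics",
    "call_dosages",
    "filter_min_depth",
    "filter_maf",
    "filter_missing",
    "impute_dose_frequency",
    "diploidize",
    "filter_dd_informative",
    "redundancy_groups",
]


def _as_index(values: Iterable[str], name: str) -> pd.Index:
    idx = pd.Index(list(values), name=name)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {name} ids: {dups[:5]}")
    return idx


@dataclass
class ReadCountTable:
    """Per individual x marker reference/alternative read depths.

    ``ref`` and ``alt`` are ``(n_individuals, n_markers)`` integer arrays.
    ``metadata`` carries per-marker reference name, chromosome and 1-based
    position (columns ``reference``, ``chrom``, ``pos``), indexed by
    marker id.
    """

    ref: np.ndarray
    alt: np.ndarray
    individuals: pd.Index
    markers: pd.Index
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.ref = np.asarray(self.ref, dtype=np.int64)
        self.alt = np.asarray(self.alt, dtype=np.int64)
        self.individuals = _as_index(self.individuals, "individual")
        self.markers = _as_index(self.markers, "marker")
        if self.ref.shape != self.alt.shape:
            raise ValueError("ref and alt shapes differ")
        if self.ref.shape != (len(self.individuals), len(self.markers)):
            raise ValueError("count arrays do not match id dimensions")
        if (self.ref < 0).any() or (self.alt < 0).any():
            raise ValueError("read counts must be non-negative")
        if self.metadata is not None:
            self.metadata = self.metadata.loc[self.markers]

    @property
    def depth(self) -> np.ndarray:
        return self.ref + self.alt

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def subset_markers(self, keep: np.ndarray) -> "ReadCountTable":
        keep = np.asarray(keep)
        meta = self.metadata.iloc[keep] if self.metadata is not None else None
        return ReadCountTable(
            self.ref[:, keep],
            self.alt[:, keep],
            self.individuals,
            self.markers[keep],
            meta,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format (marker, individual, ref, alt) table."""
        ind, mark = np.meshgrid(
            np.arange(self.n_individuals), np.arange(self.n_markers), indexing="ij"
        )
        return pd.DataFrame(
            {
                "marker": self.markers[mark.ravel()],
                "individual": self.individuals[ind.ravel()],
                "ref": self.ref.ravel(),
                "alt": self.alt.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ReadCountTable":
        pivot_ref = frame.pivot(index="individual", columns="marker", values="ref")
        pivot_alt = frame.pivot(index="individual", columns="marker", values="alt")
        pivot_alt = pivot_alt.loc[pivot_ref.index, pivot_ref.columns]
        return cls(
            pivot_ref.to_numpy(dtype=np.int64),
            pivot_alt.to_numpy(dtype=np.int64),
            pivot_ref.index,
            pivot_ref.columns,
        )


@dataclass
class DosageMatrix:
    """Individuals x markers integer dosages with a missing sentinel.

    Entries lie in ``{0, .., ploidy}`` or equal :data:`MISSING` (-1).
    """

    data: np.ndarray
    individuals: pd.Index
    markers: pd.Index
    ploidy: int = 4
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int8)
        self.individuals = _as_index(self.individuals, "individual")
        self.markers = _as_index(self.markers, "marker")
        if self.ploidy < 2 or self.ploidy % 2:
            raise ValueError(f"ploidy must be an even integer >= 2, got {self.ploidy}")
        if self.data.shape != (len(self.individuals), len(self.markers)):
            raise ValueError("dosage array does not match id dimensions")
        bad = (self.data != MISSING) & ((self.data < 0) | (self.data > self.ploidy))
        if bad.any():
            raise ValueError("dosages outside 0..ploidy")
        if self.metadata is not None:
            self.metadata = self.metadata.loc[self.markers]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.data == MISSING

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def subset_markers(self, keep: np.ndarray) -> "DosageMatrix":
        keep = np.asarray(keep)
        meta = self.metadata.iloc[keep] if self.metadata is not None else None
        return DosageMatrix(
            self.data[:, keep], self.individuals, self.markers[keep], self.ploidy, meta
        )

    def subset_individuals(self, keep: np.ndarray) -> "DosageMatrix":
        keep = np.asarray(keep)
        return DosageMatrix(
            self.data[keep], self.individuals[keep], self.markers, self.ploidy, self.metadata
        )

    def complete_array(self) -> np.ndarray:
        """Float dosage array; raises if any entry is missing."""
        if self.missing_mask.any():
            raise ValueError("dosage matrix has missing entries; impute first")
        return self.data.astype(np.float64)

    def dose_frequencies(self) -> pd.DataFrame:
        """Observed per-marker dose frequency table (markers x doses)."""
        counts = np.stack(
            [(self.data == d).sum(axis=0) for d in range(self.ploidy + 1)], axis=1
        ).astype(np.float64)
        totals = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(totals > 0, counts / totals, np.nan)
        return pd.DataFrame(freq, index=self.markers, columns=range(self.ploidy + 1))

    def allele_frequency(self) -> np.ndarray:
        """Reference-allele frequency per marker over observed entries."""
        observed = ~self.missing_mask
        dose_sum = np.where(observed, self.data, 0).sum(axis=0).astype(np.float64)
        n_obs = observed.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_obs > 0, dose_sum / (self.ploidy * n_obs), np.nan)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.data, index=self.individuals, columns=self.markers)
        return frame.replace(MISSING, pd.NA)


@dataclass
class CallDiagnostics:
    """Per-marker fit report of the binomial-mixture dosage caller."""

    class_probs: pd.DataFrame  # markers x (ploidy+1) success probabilities q_d
    weights: pd.DataFrame  # markers x (ploidy+1) fitted mixing weights
    mean_depth: pd.Series
    mean_max_posterior: pd.Series
    converged: pd.Series
    posteriors: np.ndarray | None = None  # (individuals, markers, ploidy+1)


def _dose_success_probs(ploidy: int, seq_error: float) -> np.ndarray:
    d = np.arange(ploidy + 1, dtype=np.float64)
    return (d / ploidy) * (1.0 - 2.0 * seq_error) + seq_error


def _em_marker(
    ref: np.ndarray,
    depth: np.ndarray,
    q: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """EM over free mixing weights; returns (posteriors, weights, converged).

    Component success probabilities are fixed by ploidy and the error
    rate, so only the weights are free — the M step is a weighted mean.
    Log-binomial kernels keep deep markers stable.
    """
    n_comp = len(q)
    active = depth > 0
    r = ref[active].astype(np.float64)
    n = depth[active].astype(np.float64)
    # binomial log-kernel, constant term dropped (cancels in posterior)
    logq = np.log(q.clip(1e-12))
    log1mq = np.log((1.0 - q).clip(1e-12))
    loglik = r[:, None] * logq[None, :] + (n - r)[:, None] * log1mq[None, :]
    w = np.full(n_comp, 1.0 / n_comp)
    converged = False
    prev = -np.inf
    for _ in range(max_iter):
        logpost = loglik + np.log(w.clip(1e-300))
        m = logpost.max(axis=1, keepdims=True)
        post = np.exp(logpost - m)
        norm = post.sum(axis=1, keepdims=True)
        post /= norm
        obj = float((m.ravel() + np.log(norm.ravel())).sum())
        w = post.mean(axis=0)
        if abs(obj - prev) < tol * (1.0 + abs(obj)):
            converged = True
            break
        prev = obj
    full_post = np.full((len(ref), n_comp), np.nan)
    full_post[active] = post
    return full_post, w, converged


def call_dosages(
    counts: ReadCountTable,
    ploidy: int = 4,
    seq_error: float = 0.01,
    min_posterior: float = 0.8,
    max_iter: int = 200,
    tol: float = 1e-8,
    keep_posteriors: bool = False,
) -> tuple[DosageMatrix, CallDiagnostics]:
    """Call integer dosages from read counts by a binomial-mixture EM.

    Each individual is assigned the maximum-a-posteriori dosage class;
    assignments with posterior below ``min_posterior``, zero depth, or on
    markers whose EM failed to converge are set missing.
    """
    if ploidy not in (2, 4, 6, 8):
        raise ValueError(f"unsupported ploidy {ploidy}")
    if not 0.0 <= seq_error < 0.5:
        raise ValueError("seq_error must lie in [0, 0.5)")
    depth = counts.depth
    if not (depth.sum(axis=0) > 0).all():
        raise ValueError("every marker needs at least one individual with depth > 0")
    q = _dose_success_probs(ploidy, seq_error)
    n_ind, n_mark = counts.ref.shape
    calls = np.full((n_ind, n_mark), MISSING, dtype=np.int8)
    weights = np.full((n_mark, ploidy + 1), np.nan)
    conv = np.zeros(n_mark, dtype=bool)
    mean_post = np.full(n_mark, np.nan)
    all_post = (
        np.full((n_ind, n_mark, ploidy + 1), np.nan) if keep_posteriors else None
    )
    for j in range(n_mark):
        post, w, ok = _em_marker(counts.ref[:, j], depth[:, j], q, max_iter, tol)
        weights[j] = w
        conv[j] = ok
        if all_post is not None:
            all_post[:, j, :] = post
        if not ok:
            continue  # marker flagged, all calls stay missing
        with np.errstate(invalid="ignore"):
            best = np.nanargmax(np.where(np.isnan(post), -np.inf, post), axis=1)
            best_p = np.take_along_axis(post, best[:, None], axis=1).ravel()
        has_depth = depth[:, j] > 0
        accept = has_depth & (best_p >= min_posterior)
        calls[accept, j] = best[accept].astype(np.int8)
        if has_depth.any():
            mean_post[j] = np.nanmean(best_p[has_depth])
    diagnostics = CallDiagnostics(
        class_probs=pd.DataFrame(
            np.tile(q, (n_mark, 1)), index=counts.markers, columns=range(ploidy + 1)
        ),
        weights=pd.DataFrame(weights, index=counts.markers, columns=range(ploidy + 1)),
        mean_depth=pd.Series(depth.mean(axis=0), index=counts.markers),
        mean_max_posterior=pd.Series(mean_post, index=counts.markers),
        converged=pd.Series(conv, index=counts.markers),
        posteriors=all_post,
    )
    dosages = DosageMatrix(
        calls, counts.individuals, counts.markers, ploidy, counts.metadata
    )
    return dosages, diagnostics


def filter_min_depth(counts: ReadCountTable, min_mean_depth: float = 25) -> ReadCountTable:
    """Keep markers whose mean total depth across individuals is >= threshold."""
    keep = counts.depth.mean(axis=0) >= min_mean_depth
    return counts.subset_markers(np.flatnonzero(keep))


def filter_maf(dosages: DosageMatrix, min_maf: float = 0.01) -> DosageMatrix:
    """Drop markers whose minor-allele frequency is below ``min_maf``.

    Frequency is the mean observed dose divided by ploidy; boundary is
    inclusive (MAF exactly at the threshold is kept).  All-missing
    markers are removed.
    """
    p = dosages.allele_frequency()
    with np.errstate(invalid="ignore"):
        maf = np.minimum(p, 1.0 - p)
    keep = np.flatnonzero(~np.isnan(maf) & (maf >= min_maf))
    return dosages.subset_markers(keep)


def filter_missing(dosages: DosageMatrix, max_missing: float = 0.05) -> DosageMatrix:
    """Drop markers with strictly more than ``max_missing`` missing fraction."""
    frac = dosages.missing_mask.mean(axis=0)
    return dosages.subset_markers(np.flatnonzero(frac <= max_missing))


def impute_dose_frequency(
    dosages: DosageMatrix, rng: np.random.Generator | int | None = None
) -> DosageMatrix:
    """Fill missing entries by sampling each marker's observed dose frequencies.

    Observed entries are untouched; the output has no missing data.
    """
    rng = np.random.default_rng(rng)
    data = dosages.data.copy()
    for j in range(dosages.n_markers):
        col = data[:, j]
        miss = col == MISSING
        if not miss.any():
            continue
        observed = col[~miss]
        if observed.size == 0:
            raise ValueError(
                f"marker {dosages.markers[j]} is entirely missing; filter first"
            )
        doses, counts = np.unique(observed, return_counts=True)
        draws = rng.choice(doses, size=int(miss.sum()), p=counts / counts.sum())
        col[miss] = draws
    return DosageMatrix(
        data, dosages.individuals, dosages.markers, dosages.ploidy, dosages.metadata
    )


_DIPLOID_MAP = np.array([0, 1, 1, 1, 2], dtype=np.int8)


def diploidize(dosages: DosageMatrix) -> DosageMatrix:
    """Collapse tetraploid dosages to diploid coding {0 -> 0, 1..3 -> 1, 4 -> 2}.

    The three tetraploid heterozygote classes become a single diploid
    heterozygote; missing entries are preserved.  Only tetraploid input
    is accepted.
    """
    if dosages.ploidy != 4:
        raise ValueError("diploidize requires tetraploid (ploidy 4) input")
    data = dosages.data
    out = np.where(data == MISSING, MISSING, _DIPLOID_MAP[data.clip(min=0)])
    return DosageMatrix(
        out.astype(np.int8),
        dosages.individuals,
        dosages.markers,
        ploidy=2,
        metadata=dosages.metadata,
    )


def filter_dd_informative(dosages: DosageMatrix) -> DosageMatrix:
    """Drop markers whose observed doses are a subset of {0, 1}.

    Such markers become monomorphic-in-practice after diploidization in a
    closely related population, so they are removed before the coding
    comparison to define a common marker panel.
    """
    data = dosages.data
    informative = ((data != MISSING) & (data > 1)).any(axis=0)
    return dosages.subset_markers(np.flatnonzero(informative))


def redundancy_groups(dosages: DosageMatrix) -> dict:
    """Partition markers into groups carrying identical dosage vectors.

    Equality is missing-sensitive: two markers group together only when
    their calls and their missing masks agree everywhere.  Returns group
    membership, the unique/redundant counts and the percent unique.
    """
    frame = pd.DataFrame(dosages.data.T, index=dosages.markers)
    groups: dict[str, list] = {}
    for _, block in frame.groupby(list(frame.columns), sort=False):
        members = list(block.index)
        groups[members[0]] = members
    n_unique = len(groups)
    n_total = dosages.n_markers
    return {
        "groups": groups,
        "n_markers": n_total,
        "n_unique": n_unique,
        "n_redundant": n_total - n_unique,
        "percent_unique": 100.0 * n_unique / n_total if n_total else float("nan"),
    }
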