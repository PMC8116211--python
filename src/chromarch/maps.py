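"""Binned Hi-C contact maps: data model, text I/O, balancing, P(s) scaling.

Maps are stored dense (desk-scale genomes).  Two text formats are
supported: whitespace-separated dense matrices (one file per region) and
triplet TSV ``bin_i  bin_j  count`` with upper-triangle entries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from chromarch.genome import GenomeAssembly


@dataclass
class ContactMap:
    """A symmetric binned contact matrix with bin coordinates.

    Parameters
    ----------
    resolution
        Bin size in bp.
    counts
        Symmetric non-negative raw count matrix, one row/col per bin.
    bins
        DataFrame with columns ``chrom`` and ``start`` (bp), one row per bin.
        Single-region maps may pass ``None``; a single pseudo-chromosome is
        assumed.
    balanced
        Optional balanced layer (same shape), produced by :func:`balance`.
    mask
        Boolean per-bin validity; masked bins are excluded from balancing,
        scaling and compartment analysis.
    """

    resolution: int
    counts: np.ndarray
    bins: pd.DataFrame | None = None
    balanced: np.ndarray | None = None
    mask: np.ndarray | None = None
    assembly: GenomeAssembly | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n = self.counts.shape[0]
        if self.counts.shape != (n, n):
            raise ValueError("counts must be square")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if not np.allclose(self.counts, self.counts.T):
            warnings.warn("asymmetric input symmetrised as (M + M.T)/2")
            self.counts = (self.counts + self.counts.T) / 2.0
        if self.bins is None:
            self.bins = pd.DataFrame(
                {"chrom": ["region"] * n, "start": np.arange(n) * self.resolution}
            )
        if len(self.bins) != n:
            raise ValueError("bin table length does not match matrix")
        if self.mask is None:
            self.mask = np.ones(n, dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.bins["chrom"]))

    def chrom_slice(self, chrom: str) -> slice:
        idx = np.flatnonzero((self.bins["chrom"] == chrom).to_numpy())
        if idx.size == 0:
            raise KeyError(f"chromosome {chrom!r} not in map")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def layer(self, which: Literal["counts", "balanced"] = "balanced") -> np.ndarray:
        if which == "balanced":
            if self.balanced is None:
                raise ValueError("map has no balanced layer; call balance() first")
            return self.balanced
        return self.counts

    def same_bins(self, other: "ContactMap") -> bool:
        return (
            self.resolution == other.resolution
            and self.n_bins == other.n_bins
            and (self.bins["chrom"].to_numpy() == other.bins["chrom"].to_numpy()).all()
            and (self.bins["start"].to_numpy() == other.bins["start"].to_numpy()).all()
        )


# ---------------------------------------------------------------------------
# I/O


def load_map(
    path: str | Path,
    format: Literal["dense_text", "triplet"] = "dense_text",
    resolution: int = 10_000,
    n_bins: int | None = None,
) -> ContactMap:
    """Load a map from dense whitespace text or triplet TSV.

    Triplet files hold ``bin_i bin_j count`` (0-based bin indices, any
    triangle); missing entries are zero.  Asymmetric dense input is
    symmetrised with a warning; ragged rows or negative counts raise.
    """
    if format == "dense_text":
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.strip():
                    rows.append([float(x) for x in line.split()])
        if not rows:
            raise ValueError(f"{path}: empty dense matrix")
        width = len(rows[0])
        if any(len(r) != width for r in rows):
            raise ValueError(f"{path}: ragged dense matrix")
        mat = np.array(rows, dtype=float)
    elif format == "triplet":
        df = pd.read_csv(path, sep="\t", header=None, names=["i", "j", "count"], comment="#")
        size = n_bins if n_bins is not None else (int(max(df["i"].max(), df["j"].max())) + 1 if len(df) else 0)
        mat = np.zeros((size, size))
        for i, j, c in df.itertuples(index=False):
            mat[int(i), int(j)] = c
            mat[int(j), int(i)] = c
    else:
        raise ValueError(f"unknown format {format!r}")
    if (mat < 0).any():
        raise ValueError(f"{path}: negative count")
    return ContactMap(resolution=resolution, counts=mat)


def save_map(
    cmap: ContactMap,
    path: str | Path,
    format: Literal["dense_text", "triplet"] = "dense_text",
    layer: Literal["counts", "balanced"] = "counts",
) -> None:
    mat = cmap.layer(layer)
    if format == "dense_text":
        np.savetxt(path, mat, fmt="%.10g")
    elif format == "triplet":
        iu = np.triu_indices(cmap.n_bins)
        nz = mat[iu] != 0
        df = pd.DataFrame({"i": iu[0][nz], "j": iu[1][nz], "count": mat[iu][nz]})
        df.to_csv(path, sep="\t", header=False, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def write_bedgraph(
    cmap_bins: pd.DataFrame, values: np.ndarray, resolution: int, path: str | Path
) -> None:
    """Write a per-bin track as bedGraph (NaN bins skipped)."""
    with open(path, "w") as fh:
        for (chrom, start), v in zip(cmap_bins[["chrom", "start"]].itertuples(index=False), values):
            if np.isfinite(v):
                fh.write(f"{chrom}\t{start}\t{start + resolution}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# Balancing (iterative correction)


def balance(
    cmap: ContactMap,
    max_iter: int = 200,
    tol: float = 1e-5,
    min_nnz: int = 10,
    method: Literal["ice", "none"] = "ice",
) -> ContactMap:
    """Populate the balanced layer, by iterative correction or passthrough.

    ``method="ice"`` iteratively corrects the raw counts so all good rows
    sum equally; ``"none"`` copies the counts through (appropriate when
    per-bin coverage is uniform by construction, e.g. synthetic maps —
    iterative correction would otherwise partially absorb planted per-bin
    signal differences).  Bins with fewer than ``min_nnz`` non-zero
    entries are masked either way.  Non-convergence after ``max_iter``
    emits a warning and flags the result.
    """
    mat = cmap.counts.copy()
    n = mat.shape[0]
    nnz = (mat > 0).sum(axis=1)
    mask = cmap.mask & (nnz >= min(min_nnz, max(1, n - 1)))
    if method == "none":
        balanced = np.full((n, n), np.nan)
        idx = np.flatnonzero(mask)
        balanced[np.ix_(idx, idx)] = mat[np.ix_(idx, idx)]
        return replace(cmap, balanced=balanced, mask=mask, converged=True)
    work = mat[np.ix_(mask, mask)].copy()
    converged = False
    if work.size:
        bias = np.ones(work.shape[0])
        for _ in range(max_iter):
            s = work.sum(axis=1)
            mean_s = s[s > 0].mean() if (s > 0).any() else 0.0
            if mean_s == 0:
                break
            rel = s / mean_s
            rel[s == 0] = 1.0
            if np.abs(rel - 1.0).max() < tol:
                converged = True
                break
            work /= np.sqrt(np.outer(rel, rel))
        s = work.sum(axis=1)
        if (s > 0).any():
            work /= s[s > 0].mean()
    if not converged and work.size:
        warnings.warn(f"ICE did not converge after {max_iter} iterations")
    balanced = np.full((n, n), np.nan)
    idx = np.flatnonzero(mask)
    balanced[np.ix_(idx, idx)] = work
    return replace(cmap, balanced=balanced, mask=mask, converged=converged)


# ---------------------------------------------------------------------------
# Expected profile and distance decay


@dataclass
class ExpectedProfile:
    """Mean balanced contact per genomic-separation diagonal (one region)."""

    resolution: int
    values: np.ndarray  # index = separation in bins

    def at(self, sep_bins: np.ndarray) -> np.ndarray:
        return self.values[np.clip(sep_bins, 0, len(self.values) - 1)]


def expected_profile(cmap: ContactMap, chrom: str | None = None) -> ExpectedProfile:
    """Per-diagonal mean of the balanced layer over unmasked bins."""
    sl = cmap.chrom_slice(chrom) if chrom else slice(None)
    mat = cmap.layer("balanced")[sl, sl]
    mask = cmap.mask[sl]
    n = mat.shape[0]
    values = np.zeros(n)
    for d in range(n):
        diag = np.diagonal(mat, offset=d)
        ok = mask[: n - d] & mask[d:] & np.isfinite(diag)
        values[d] = diag[ok].mean() if ok.any() else np.nan
    return ExpectedProfile(cmap.resolution, values)


@dataclass
class DecayCurve:
    """Contact probability P(s) versus genomic separation, log-binned.

    ``probabilities`` integrate to one over the populated bins
    (unit-area convention); ``exponent`` is the least-squares slope of
    log10 P against log10 s within ``fit_range``.
    """

    separations: np.ndarray  # geometric bin centres, bp
    probabilities: np.ndarray
    fit_range: tuple[float, float]
    exponent: float


def decay_curve(
    cmap: ContactMap,
    bins_per_decade: int = 8,
    fit_range: tuple[float, float] = (100_000, 10_000_000),
    exclude: np.ndarray | None = None,
) -> DecayCurve:
    """Distance-decay P(s) of the balanced layer, intra-chromosomal only.

    ``exclude`` optionally masks bins (e.g. pericentromeric) out of the
    average.  Raises if fewer than three populated log-bins fall inside
    ``fit_range``.
    """
    bal = cmap.layer("balanced")
    res = cmap.resolution
    max_sep = cmap.n_bins * res
    edges = 10 ** np.arange(
        np.log10(res), np.log10(max_sep) + 1.0 / bins_per_decade, 1.0 / bins_per_decade
    )
    sums = np.zeros(len(edges) - 1)
    cnts = np.zeros(len(edges) - 1)
    use = cmap.mask.copy()
    if exclude is not None:
        use &= ~exclude
    for chrom in cmap.chromosomes:
        sl = cmap.chrom_slice(chrom)
        sub = bal[sl, sl]
        m = use[sl]
        n = sub.shape[0]
        for d in range(1, n):
            diag = np.diagonal(sub, offset=d)
            ok = m[: n - d] & m[d:] & np.isfinite(diag)
            if not ok.any():
                continue
            b = np.searchsorted(edges, d * res, side="right") - 1
            if 0 <= b < len(sums):
                sums[b] += diag[ok].sum()
                cnts[b] += ok.sum()
    with np.errstate(invalid="ignore"):
        p = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    centres = np.sqrt(edges[:-1] * edges[1:])
    widths = np.diff(edges)
    area = np.nansum(p * widths)
    if area > 0:
        p = p / area
    lo, hi = fit_range
    sel = (centres >= lo) & (centres <= hi) & np.isfinite(p) & (p > 0)
    if sel.sum() < 3:
        raise ValueError("fewer than 3 populated log-bins in fit range; exponent undefined")
    slope = np.polyfit(np.log10(centres[sel]), np.log10(p[sel]), 1)[0]
    return DecayCurve(centres, p, fit_range, float(slope))


# ---------------------------------------------------------------------------
# Differential maps and coarsening


def differential_map(a: ContactMap, b: ContactMap, pseudocount: float = 1.0) -> np.ndarray:
    """log2 ratio of two balanced maps scaled to equal total signal.

    Entries where either map is masked are NaN.  The pseudocount is in
    raw-count-equivalent units relative to the mean signal.
    """
    if not a.same_bins(b):
        raise ValueError("bin tables differ between maps")
    ma, mb = a.layer("balanced").copy(), b.layer("balanced").copy()
    sa, sb = np.nansum(ma), np.nansum(mb)
    if sa > 0:
        ma = ma / sa
    if sb > 0:
        mb = mb / sb
    # pseudocount expressed on the normalised scale
    scale = np.nanmean(ma[ma > 0]) if (ma > 0).any() else 1.0
    pc = pseudocount * scale
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.log2((ma + pc) / (mb + pc))
    bad = ~(a.mask[:, None] & a.mask[None, :] & b.mask[:, None] & b.mask[None, :])
    out[bad] = np.nan
    return out


def coarsen(cmap: ContactMap, factor: int) -> ContactMap:
    """Sum counts over factor x factor blocks; conserves total exactly.

    A trailing partial block is kept (summed over fewer bins).
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return cmap
    n = cmap.n_bins
    n_out = -(-n // factor)
    agg = np.zeros((n_out, n))
    for i in range(n_out):
        agg[i, i * factor : min((i + 1) * factor, n)] = 1.0
    counts = agg @ cmap.counts @ agg.T
    bins = cmap.bins.iloc[::factor].reset_index(drop=True)
    return ContactMap(
        resolution=cmap.resolution * factor,
        counts=counts,
        bins=bins,
        assembly=cmap.assembly,
    )
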