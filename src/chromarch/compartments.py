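"""A/B compartment analysis: eigenvector scores, saddle strength, insulation.

The compartment score is the leading eigenvector of the per-region Pearson
correlation matrix of the observed/expected contact map (the standard
construction), sign-oriented against an external reference track so that
positive scores mark the active (A) compartment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np
import pandas as pd

from chromarch.maps import ContactMap


@dataclass
class CompartmentTrack:
    """Per-bin compartment score with A/B labels.

    Labels follow the sign convention: A iff score > 0, B iff score < 0,
    undefined where the score is NaN (masked bins).
    """

    resolution: int
    scores: np.ndarray
    bins: pd.DataFrame  # chrom, start

    @property
    def labels(self) -> np.ndarray:
        out = np.full(len(self.scores), "undefined", dtype=object)
        out[self.scores > 0] = "A"
        out[self.scores < 0] = "B"
        return out

    def label_at(self, chrom: str, pos: int) -> str:
        sel = (self.bins["chrom"] == chrom).to_numpy()
        if not sel.any():
            return "unassigned"
        starts = self.bins["start"].to_numpy()[sel]
        idx = np.flatnonzero(sel)
        i = np.searchsorted(starts, pos, side="right") - 1
        if i < 0 or pos >= starts[i] + self.resolution:
            return "unassigned"
        s = self.scores[idx[i]]
        if not np.isfinite(s) or s == 0:
            return "unassigned"
        return "A" if s > 0 else "B"

    def flipped(self) -> "CompartmentTrack":
        return CompartmentTrack(self.resolution, -self.scores, self.bins)


def _oe(mat: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Observed/expected: divide each diagonal by its unmasked mean."""
    n = mat.shape[0]
    oe = np.full((n, n), np.nan)
    for d in range(n):
        diag = np.diagonal(mat, offset=d)
        ok = mask[: n - d] & mask[d:] & np.isfinite(diag)
        if not ok.any():
            continue
        m = diag[ok].mean()
        if m > 0:
            vals = diag / m
            idx = np.arange(n - d)
            oe[idx, idx + d] = vals
            oe[idx + d, idx] = vals
    return oe


def compartment_score(
    cmap: ContactMap,
    orientation: np.ndarray | None = None,
) -> CompartmentTrack:
    """Leading-eigenvector compartment score, computed per region/arm.

    For each chromosome of a balanced map: O/E matrix -> Pearson
    correlation matrix -> leading eigenvector.  The sign is flipped so the
    scores correlate positively with ``orientation`` (e.g. gene density or
    active-mark coverage); without a reference the sign is arbitrary.
    Degenerate (constant O/E) regions get undefined scores with a warning.
    """
    scores = np.full(cmap.n_bins, np.nan)
    for chrom in cmap.chromosomes:
        sl = cmap.chrom_slice(chrom)
        mat = cmap.layer("balanced")[sl, sl]
        mask = cmap.mask[sl]
        oe = _oe(mat, mask)
        good = mask & np.isfinite(oe).any(axis=1)
        sub = oe[np.ix_(good, good)]
        sub = np.where(np.isfinite(sub), sub, 1.0)
        if sub.shape[0] < 3 or np.allclose(sub.std(axis=0), 0):
            warnings.warn(f"degenerate O/E matrix for {chrom}; scores undefined")
            continue
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(sub)
        corr = np.where(np.isfinite(corr), corr, 0.0)
        w, v = np.linalg.eigh(corr)
        ev = v[:, -1]
        if np.allclose(w[-1], 0):
            warnings.warn(f"degenerate correlation matrix for {chrom}; scores undefined")
            continue
        region = scores[sl]
        region[good] = ev
        scores[sl] = region
    if orientation is not None:
        ok = np.isfinite(scores) & np.isfinite(orientation)
        if ok.any() and np.corrcoef(scores[ok], orientation[ok])[0, 1] < 0:
            scores = -scores
    return CompartmentTrack(cmap.resolution, scores, cmap.bins)


# ---------------------------------------------------------------------------
# Saddle and compartment strength


@dataclass
class StrengthReport:
    """Corner enrichments of a saddle matrix and derived strengths.

    strength_A = AA/AB, strength_B = BB/AB and the geometric-mean overall
    strength sqrt(AA*BB)/AB, where AA/BB/AB are mean observed/expected over
    the extreme score-quantile corners.
    """

    AA: float
    BB: float
    AB: float

    @property
    def strength_A(self) -> float:
        return self.AA / self.AB

    @property
    def strength_B(self) -> float:
        return self.BB / self.AB

    @property
    def strength_overall(self) -> float:
        return float(np.sqrt(self.AA * self.BB) / self.AB)


@dataclass
class SaddleMatrix:
    """Mean O/E enrichment pooled by compartment-score quantile pairs.

    Rows/columns are ordered by ascending score quantile (B-most first).
    Empty quantile pairs are NaN (flagged, never zero).  ``strata_sums`` /
    ``strata_counts`` keep the per-genomic-separation cell tallies
    (nq x nq x n_strata): corner strengths pool each separation stratum
    with one shared weight (the smallest pair count among the three
    corner classes at that stratum), so differences in which separations
    each corner samples cannot leak distance decay into the enrichment
    ratios, and sparse strata do not dominate the variance.
    """

    n_quantiles: int
    values: np.ndarray
    corner_fraction: float = 0.2
    strata_sums: np.ndarray | None = None
    strata_counts: np.ndarray | None = None

    def strength(self, corner_fraction: float | None = None) -> StrengthReport:
        cf = corner_fraction if corner_fraction is not None else self.corner_fraction
        k = max(1, int(round(self.n_quantiles * cf)))
        if self.strata_sums is not None:
            ss, sc = self.strata_sums, self.strata_counts

            def corner(rows, cols):
                s = ss[rows, :, :][:, cols, :].sum(axis=(0, 1))
                c = sc[rows, :, :][:, cols, :].sum(axis=(0, 1))
                return s, c

            lo, hi = np.arange(k), np.arange(self.n_quantiles - k, self.n_quantiles)
            bb_s, bb_c = corner(lo, lo)
            aa_s, aa_c = corner(hi, hi)
            ab_s, ab_c = corner(lo, hi)
            # common-strata, pair-count weighted pooling: one weight per
            # separation stratum shared by all three corner classes, so
            # the distance-decay factor cancels exactly while sparse
            # strata do not dominate the variance
            w = np.minimum(np.minimum(bb_c, aa_c), ab_c)
            if w.sum() > 0:
                def pooled(s, c):
                    ok = w > 0
                    return float(np.sum(w[ok] * s[ok] / c[ok]) / w[ok].sum())

                return StrengthReport(
                    AA=pooled(aa_s, aa_c), BB=pooled(bb_s, bb_c), AB=pooled(ab_s, ab_c)
                )
        v = self.values
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            bb = np.nanmean(v[:k, :k])
            aa = np.nanmean(v[-k:, -k:])
            ab = np.nanmean(np.concatenate([v[:k, -k:].ravel(), v[-k:, :k].ravel()]))
        return StrengthReport(AA=float(aa), BB=float(bb), AB=float(ab))


def saddle(
    cmap: ContactMap,
    track: CompartmentTrack,
    n_quantiles: int = 50,
    min_separation: int = 0,
    corner_fraction: float = 0.2,
) -> SaddleMatrix:
    """Score-sorted (saddle) enrichment matrix, intra-chromosomal.

    O/E values are pooled by the score-quantile pair of their two bins,
    stratified by genomic separation: the per-cell value is the mean over
    separations of the per-separation mean O/E.  Equal weighting of
    separations keeps the corner ratios free of distance-composition
    confounding (quantile pairs differ in how close their bins sit along
    the chain, and contact decay would otherwise leak into the
    enrichment).  Pairs closer than ``min_separation`` bp are excluded
    (used to show the compartment signal is not driven by short-range/TAD
    contacts).
    """
    if len(track.scores) != cmap.n_bins:
        raise ValueError("track and map bin counts differ")
    nq = n_quantiles
    sums = np.zeros((nq, nq))
    strata = np.zeros((nq, nq))
    max_bins = max(
        cmap.chrom_slice(c).stop - cmap.chrom_slice(c).start for c in cmap.chromosomes
    )
    sv_sum = np.zeros((nq, nq, max_bins))
    sv_cnt = np.zeros((nq, nq, max_bins))
    min_sep_bins = max(1, int(np.ceil(min_separation / cmap.resolution)))
    for chrom in cmap.chromosomes:
        sl = cmap.chrom_slice(chrom)
        mat = cmap.layer("balanced")[sl, sl]
        mask = cmap.mask[sl]
        sc = track.scores[sl]
        good = mask & np.isfinite(sc)
        if good.sum() < nq:
            continue
        oe = _oe(mat, mask)
        ranks = np.full(len(sc), -1)
        # tied scores (e.g. two-valued synthetic tracks) are broken by a
        # fixed pseudo-random permutation, not position: positional ties
        # would concentrate corner quantiles at one end of the arm and bias
        # which separations the corner cells sample
        tie = np.random.default_rng(0).permutation(int(good.sum()))
        order = np.lexsort((tie, sc[good]))
        q = np.minimum((np.arange(good.sum()) * nq) // good.sum(), nq - 1)
        ranks[np.flatnonzero(good)[order]] = q
        n = len(sc)
        for d in range(min_sep_bins, n):
            diag = np.diagonal(oe, offset=d)
            qi, qj = ranks[: n - d], ranks[d:]
            ok = (qi >= 0) & (qj >= 0) & np.isfinite(diag)
            if not ok.any():
                continue
            dsum = np.zeros((nq, nq))
            dcnt = np.zeros((nq, nq))
            lo = np.minimum(qi[ok], qj[ok])
            hi = np.maximum(qi[ok], qj[ok])
            np.add.at(dsum, (lo, hi), diag[ok])
            np.add.at(dcnt, (lo, hi), 1)
            cell = dcnt > 0
            sums[cell] += dsum[cell] / dcnt[cell]
            strata[cell] += 1
            sv_sum[:, :, d] += dsum
            sv_cnt[:, :, d] += dcnt
    sums = sums + np.triu(sums, 1).T
    strata = strata + np.triu(strata, 1).T
    lo_i, hi_i = np.triu_indices(nq, 1)
    sv_sum[hi_i, lo_i, :] = sv_sum[lo_i, hi_i, :]
    sv_cnt[hi_i, lo_i, :] = sv_cnt[lo_i, hi_i, :]
    with np.errstate(invalid="ignore"):
        values = np.where(strata > 0, sums / np.maximum(strata, 1), np.nan)
    return SaddleMatrix(nq, values, corner_fraction, sv_sum, sv_cnt)


def differential_saddle(a: SaddleMatrix, b: SaddleMatrix) -> np.ndarray:
    """Per-cell log2 ratio of two saddle matrices; NaN cells propagate."""
    if a.n_quantiles != b.n_quantiles:
        raise ValueError("saddle quantile counts differ")
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.log2(a.values / b.values)


def switching(a: CompartmentTrack, b: CompartmentTrack) -> float:
    """Fraction of jointly-defined bins whose compartment sign flips."""
    if len(a.scores) != len(b.scores):
        raise ValueError("tracks have different bin counts")
    ok = np.isfinite(a.scores) & np.isfinite(b.scores) & (a.scores != 0) & (b.scores != 0)
    if not ok.any():
        return 0.0
    return float((np.sign(a.scores[ok]) != np.sign(b.scores[ok])).mean())


# ---------------------------------------------------------------------------
# Insulation / TAD boundaries


@dataclass
class InsulationTrack:
    """Diamond insulation score and boundary calls.

    ``values`` is log2 of the mean balanced signal in the window x window
    square crossing each bin's diagonal, relative to the region median;
    boundaries are local minima exceeding the prominence threshold.
    """

    resolution: int
    window: int
    values: np.ndarray
    boundaries: np.ndarray


def insulation(
    cmap: ContactMap,
    window: int = 100_000,
    prominence: float = 0.1,
) -> InsulationTrack:
    """Windowed diamond insulation profile with local-minimum boundaries."""
    from scipy.signal import find_peaks

    w = max(2, int(round(window / cmap.resolution)))
    values = np.full(cmap.n_bins, np.nan)
    for chrom in cmap.chromosomes:
        sl = cmap.chrom_slice(chrom)
        mat = cmap.layer("balanced")[sl, sl]
        n = mat.shape[0]
        raw = np.full(n, np.nan)
        # square spans the w bins before i and the w bins from i on, so a
        # domain edge starting at bin i gives its unique minimum at i
        for i in range(w, n - w + 1):
            square = mat[i - w : i, i : i + w]
            if np.isfinite(square).any():
                raw[i] = np.nanmean(square)
        ok = np.isfinite(raw) & (raw > 0)
        if ok.any():
            med = np.median(raw[ok])
            with np.errstate(invalid="ignore", divide="ignore"):
                raw = np.log2(raw / med)
        values[sl] = raw
    filled = np.where(np.isfinite(values), values, np.nanmax(values) if np.isfinite(values).any() else 0.0)
    peaks, _ = find_peaks(-filled, prominence=prominence)
    peaks = peaks[np.isfinite(values[peaks])]
    return InsulationTrack(cmap.resolution, window, values, peaks)
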