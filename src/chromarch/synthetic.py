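"""Synthetic Hi-C maps and genomic tables with planted, recoverable structure.

The map generator combines power-law distance decay, a checkerboard A/B
compartment pattern of tunable contrast, an optional selective weakening of
B-B contacts (emulating heterochromatin-protein loss), pericentromeric
blocks, TAD boundaries and Poisson count noise.  Ground truth is always
returned alongside, and every generator is seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np
import pandas as pd

from chromarch.compartments import CompartmentTrack
from chromarch.genome import GenomeAssembly, toy_assembly
from chromarch.intervals import GenomicInterval, IntervalSet
from chromarch.maps import ContactMap


@dataclass(frozen=True)
class SyntheticMapSpec:
    """Parameters of one synthetic contact map.

    ``compartment_profile`` is a per-bin string over {A, B, C} (C =
    pericentromeric block); if None, alternating A/B blocks of
    ``block_bins`` are used.  ``checkerboard_contrast`` multiplies
    same-type expected contacts; ``b_weakening`` additionally multiplies
    B-B contacts (1 = none).  ``depth`` is the total expected count;
    ``noise=False`` returns the expectation itself for exact checks.
    """

    n_bins: int = 200
    resolution: int = 10_000
    decay_exponent: float = -1.0
    compartment_profile: str | None = None
    block_bins: int = 20
    block_layout: str = "random"
    profile_seed: int = 0
    checkerboard_contrast: float = 2.0
    b_weakening: float = 1.0
    tad_boundaries: tuple[int, ...] = ()
    tad_enrichment: float = 1.0
    peri_bins: int = 0
    depth: float = 1_000_000.0
    noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.decay_exponent >= 0:
            raise ValueError("decay exponent must be negative")
        if self.checkerboard_contrast < 1:
            raise ValueError("checkerboard contrast must be >= 1")
        if not 0 < self.b_weakening <= 1:
            raise ValueError("b_weakening must be in (0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")

    def profile(self) -> str:
        """Per-bin A/B/C type string.

        The default layout draws block lengths at random around
        ``block_bins`` (seeded by ``profile_seed``, independent of the
        count noise): genomic compartment blocks are irregular, and a
        strictly periodic layout would segregate same-type and cross-type
        bin pairs into disjoint genomic separations, distorting
        separation-stratified enrichment statistics.
        """
        if self.compartment_profile is not None:
            if len(self.compartment_profile) != self.n_bins:
                raise ValueError("profile length must equal n_bins")
            return self.compartment_profile
        out: list[str] = []
        t = "A"
        if self.block_layout == "random":
            rng = np.random.default_rng(self.profile_seed)
            lo = max(1, self.block_bins // 2)
            hi = max(lo + 1, 2 * self.block_bins)
            while len(out) < self.n_bins:
                out.extend(t * int(rng.integers(lo, hi)))
                t = "B" if t == "A" else "A"
        else:
            while len(out) < self.n_bins:
                out.extend(t * self.block_bins)
                t = "B" if t == "A" else "A"
        prof = "".join(out[: self.n_bins])
        if self.peri_bins > 0:
            prof = "C" * self.peri_bins + prof[self.peri_bins :]
        return prof


def _expected_matrix(spec: SyntheticMapSpec) -> tuple[np.ndarray, str]:
    prof = spec.profile()
    n = spec.n_bins
    types = np.array(list(prof))
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    decay = np.maximum(d, 1).astype(float) ** spec.decay_exponent
    c = spec.checkerboard_contrast
    same = types[:, None] == types[None, :]
    m = np.where(same, c, 1.0)
    both_b = (types[:, None] == "B") & (types[None, :] == "B")
    m = np.where(both_b, c * spec.b_weakening, m)
    both_c = (types[:, None] == "C") & (types[None, :] == "C")
    m = np.where(both_c, c * 1.5, m)  # pericentromeric blocks self-associate strongly
    expect = decay * m
    if spec.tad_boundaries and spec.tad_enrichment != 1.0:
        bounds = [0, *sorted(spec.tad_boundaries), n]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            expect[lo:hi, lo:hi] *= spec.tad_enrichment
    expect *= spec.depth / expect.sum()
    return expect, prof


def make_map(spec: SyntheticMapSpec) -> tuple[ContactMap, CompartmentTrack]:
    """Build a synthetic contact map plus its ground-truth compartment track.

    Expected contacts are depth-scaled s^gamma times the checkerboard
    factor; counts are Poisson unless ``spec.noise`` is False.  Ground
    truth scores are +1 (A), -1 (B), NaN (pericentromeric/masked).
    """
    expect, prof = _expected_matrix(spec)
    if spec.noise:
        rng = np.random.default_rng(spec.seed)
        upper = np.triu(rng.poisson(np.triu(expect)))
        counts = upper + np.triu(upper, 1).T
    else:
        counts = expect
    cmap = ContactMap(resolution=spec.resolution, counts=counts)
    scores = np.array([1.0 if t == "A" else (-1.0 if t == "B" else np.nan) for t in prof])
    track = CompartmentTrack(spec.resolution, scores, cmap.bins)
    return cmap, track


def paired_condition_maps(
    control: SyntheticMapSpec,
    gamma_shift: float = 0.0,
    b_weakening: float = 1.0,
) -> tuple[tuple[ContactMap, CompartmentTrack], tuple[ContactMap, CompartmentTrack]]:
    """Generate a (control, perturbed) map pair sharing a compartment profile.

    The perturbed condition has a milder decay (``gamma_shift`` added to
    the exponent) and/or selectively weakened B-B contacts
    (``b_weakening`` < 1), the two map-level signatures of
    heterochromatin-protein knockdown.  RNG streams are split from the
    control seed so the pair is reproducible and independent.
    """
    if control.decay_exponent + gamma_shift >= 0:
        raise ValueError("shifted decay exponent must stay negative")
    prof = control.profile()
    ctrl_spec = replace(control, compartment_profile=prof)
    kd_spec = replace(
        control,
        compartment_profile=prof,
        decay_exponent=control.decay_exponent + gamma_shift,
        b_weakening=control.b_weakening * b_weakening,
        seed=control.seed + 104729,  # split stream
    )
    return make_map(ctrl_spec), make_map(kd_spec)


# ---------------------------------------------------------------------------
# Peak / annotation tables


@dataclass(frozen=True)
class SyntheticTablesSpec:
    """Parameters for synthetic peak and annotation tables.

    Peak widths are log-normal; each placement category (pericentromeric,
    arm-B, arm-A) is rescaled so its sample median equals the requested
    median exactly, making printed-median checks deterministic.
    ``n_inside`` peaks are planted inside the pericentromeric annotation
    and ``n_outside`` within arms, of which ``b_fraction`` in B bins.
    """

    n_inside: int = 4394
    n_outside: int = 2213
    b_fraction: float = 0.6
    median_width_peri: int = 2000
    median_width_b: int = 730
    median_width_a: int = 500
    width_sigma: float = 0.5
    peri_fraction_of_chrom: float = 0.2
    compartment_block_bp: int = 200_000
    resolution: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.b_fraction <= 1:
            raise ValueError("b_fraction must be in [0, 1]")
        if not 0 < self.peri_fraction_of_chrom < 1:
            raise ValueError("peri fraction must be in (0, 1)")


def _widths(rng: np.random.Generator, n: int, median: int, sigma: float) -> np.ndarray:
    """Log-normal widths rescaled so the sample median is exactly ``median``."""
    if n == 0:
        return np.zeros(0, dtype=int)
    w = np.exp(rng.normal(0.0, sigma, size=n))
    w *= median / np.median(w)
    w = np.maximum(np.round(w).astype(int), 1)
    # rounding can nudge the order statistics; pin the middle element(s)
    order = np.argsort(w, kind="mergesort")
    mid = order[(n - 1) // 2 : n // 2 + 1]
    w[mid] = median
    return w


def make_tables(
    spec: SyntheticTablesSpec,
    assembly: GenomeAssembly | None = None,
) -> tuple[IntervalSet, IntervalSet, CompartmentTrack]:
    """Synthetic peak set, pericentromere annotation and compartment track.

    The annotation is one block at the start of each chromosome
    (``peri_fraction_of_chrom`` of its length); arm compartments alternate
    A/B blocks of ``compartment_block_bp``.  Peaks are planted with their
    midpoints inside the intended category, so classification and
    compartment assignment recover the planted counts exactly.
    """
    if assembly is None:
        assembly = toy_assembly(n_chrom=4, length=25_000_000)
    rng = np.random.default_rng(spec.seed)
    chroms = [c for c, _ in assembly.chromosomes]
    sizes = assembly.sizes

    peri, track_scores, track_bins = [], [], []
    peri_end = {}
    for chrom in chroms:
        L = sizes[chrom]
        pe = int(L * spec.peri_fraction_of_chrom)
        pe -= pe % spec.resolution
        peri_end[chrom] = pe
        peri.append(GenomicInterval(chrom, 0, pe))
        n_bins = L // spec.resolution
        block = spec.compartment_block_bp // spec.resolution
        for b in range(n_bins):
            start = b * spec.resolution
            track_bins.append((chrom, start))
            if start < pe:
                track_scores.append(np.nan)
            else:
                arm_bin = (start - pe) // spec.resolution
                track_scores.append(1.0 if (arm_bin // block) % 2 == 0 else -1.0)
    bins = pd.DataFrame(track_bins, columns=["chrom", "start"])
    track = CompartmentTrack(spec.resolution, np.array(track_scores), bins)
    annotation = IntervalSet(peri, label="pericentromere")

    scores = np.array(track_scores)
    a_bins = bins[(scores > 0)].reset_index(drop=True)
    b_bins = bins[(scores < 0)].reset_index(drop=True)

    def place(n: int, median: int, where: str) -> list[GenomicInterval]:
        widths = _widths(rng, n, median, spec.width_sigma)
        if where != "peri":
            # arm peaks must not reach back into the annotation block
            widths = np.minimum(widths, spec.resolution)
        out = []
        for w in widths:
            if where == "peri":
                chrom = chroms[rng.integers(len(chroms))]
                lo, hi = 0, peri_end[chrom]
                mid = int(rng.integers(lo + w, hi - w)) if hi - lo > 2 * w else (lo + hi) // 2
            else:
                pool = a_bins if where == "A" else b_bins
                row = pool.iloc[int(rng.integers(len(pool)))]
                chrom = row["chrom"]
                mid = int(row["start"]) + spec.resolution // 2
            start = max(0, mid - w // 2)
            end = min(sizes[chrom], start + w)
            out.append(GenomicInterval(chrom, start, end))
        return out

    n_b = int(round(spec.n_outside * spec.b_fraction))
    if n_b % 2 == 0 and 0 < n_b < spec.n_outside:  # odd count -> exact sample median
        n_b += 1
    n_a = spec.n_outside - n_b
    peaks = (
        place(spec.n_inside, spec.median_width_peri, "peri")
        + place(n_b, spec.median_width_b, "B")
        + place(n_a, spec.median_width_a, "A")
    )
    return IntervalSet(peaks, label="peaks"), annotation, track
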