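"""Inverse inference of bead-bead interaction energies from a contact map.

Given a target contact map for a multi-megabase region modelled as a chain
of 40-kb beads, per-pair interaction energies are fitted by damped
iterative Boltzmann inversion: simulate with the current energies, compare
simulated to target contact probabilities, and move each pair energy by a
capped multiple of kT * log(p_sim / p_target).  Bonded neighbours and the
diagonal are excluded (their contacts are bond-dominated).  The inferred
matrix carries a gauge freedom (a constant offset trades against overall
compaction), so class summaries are reported both raw and mean-centred.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import spearmanr

from chromarch.maps import ContactMap
from chromarch.polymer import (
    BeadTypeSequence,
    ConfinementSpec,
    SimulationConfig,
    TypeEnergyTable,
    ensemble_contact_map,
    run_mc,
)

_CLASS_PAIRS = ("AA", "AB", "BB")


@dataclass
class EnergyMatrix:
    """Symmetric per-bead-pair interaction energies in kT (negative =
    attractive) for a region chain, with per-bead A/B class labels."""

    E: np.ndarray
    class_labels: np.ndarray
    bead_size: int = 40_000
    region: tuple[str, int, int] | None = None

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)
        self.class_labels = np.asarray(self.class_labels)
        if self.E.shape[0] != self.E.shape[1]:
            raise ValueError("energy matrix must be square")
        if len(self.class_labels) != self.E.shape[0]:
            raise ValueError("label length does not match matrix")
        if not np.allclose(self.E, self.E.T):
            raise ValueError("energy matrix must be symmetric")

    @property
    def n_beads(self) -> int:
        return self.E.shape[0]

    def pair_mask(self, exclude_bonded: bool = True) -> np.ndarray:
        """Upper-triangle mask of pairs entering inference/summaries."""
        n = self.n_beads
        m = np.triu(np.ones((n, n), bool), k=2 if exclude_bonded else 1)
        return m

    def class_of_pair(self) -> np.ndarray:
        """n x n array of pair-class strings ('AA', 'AB', 'BB')."""
        lab = self.class_labels
        out = np.empty(self.E.shape, dtype=object)
        for i in range(self.n_beads):
            for j in range(self.n_beads):
                pair = "".join(sorted(lab[i] + lab[j]))
                out[i, j] = pair
        return out

    def class_means(self, centred: bool = False) -> dict[str, tuple[float, float, int]]:
        """Per-class (mean, s.e.m., n_pairs) of the pair energies."""
        mask = self.pair_mask()
        E = self.E - (self.E[mask].mean() if centred else 0.0)
        classes = self.class_of_pair()
        out = {}
        for cp in _CLASS_PAIRS:
            sel = mask & (classes == cp)
            vals = E[sel]
            n = int(sel.sum())
            sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            out[cp] = (float(vals.mean()) if n else float("nan"), sem, n)
        return out

    def save_tsv(self, path) -> None:
        iu = np.triu_indices(self.n_beads, k=1)
        with open(path, "w") as fh:
            fh.write("# i\tj\tE_kT\n")
            for i, j in zip(*iu):
                fh.write(f"{i}\t{j}\t{self.E[i, j]:.6g}\n")


@dataclass
class InferenceReport:
    """Diagnostics of one inference run."""

    iterations: int
    final_correlation: float
    correlations: list[float]
    converged: bool
    aborted: bool
    class_means: dict[str, tuple[float, float, int]]
    class_means_centred: dict[str, tuple[float, float, int]]


def class_pair_counts(
    labels: Sequence[str],
    exclude_bonded: bool = False,
) -> dict[str, int]:
    """Unordered class-pair counts for per-bead A/B labels.

    Without bonded exclusion these are the combinatorial counts
    n_A(n_A-1)/2, n_A*n_B, n_B(n_B-1)/2.  With ``exclude_bonded`` the
    chain-adjacent pair of each class combination is subtracted (labels are
    taken in chain order), which matches reporting conventions that drop
    bond-dominated neighbours.
    """
    lab = np.asarray(list(labels))
    n_a = int((lab == "A").sum())
    n_b = int((lab == "B").sum())
    counts = {"AA": n_a * (n_a - 1) // 2, "AB": n_a * n_b, "BB": n_b * (n_b - 1) // 2}
    if exclude_bonded:
        for x, y in zip(lab[:-1], lab[1:]):
            counts["".join(sorted(x + y))] -= 1
    return counts


def _smooth_energy(E: np.ndarray, radius: int) -> np.ndarray:
    """Boxcar-regularise a pair-energy matrix over (i, j) neighbourhoods.

    Per-pair iterative Boltzmann inversion is ill-conditioned at finite
    sampling; energies at the 40-kb bead scale vary smoothly (block
    structure), so a small moving average is the standard regularisation.
    Symmetry is preserved; the (excluded) diagonal band does not leak in.
    """
    n = E.shape[0]
    w = 2 * radius + 1
    valid = np.triu(np.ones((n, n)), k=2)
    valid = valid + valid.T
    num = np.zeros_like(E)
    den = np.zeros_like(E)
    for di in range(-radius, radius + 1):
        for dj in range(-radius, radius + 1):
            src_i = slice(max(0, -di), min(n, n - di))
            src_j = slice(max(0, -dj), min(n, n - dj))
            dst_i = slice(max(0, di), min(n, n + di))
            dst_j = slice(max(0, dj), min(n, n + dj))
            num[dst_i, dst_j] += (E * valid)[src_i, src_j]
            den[dst_i, dst_j] += valid[src_i, src_j]
    out = np.where(den > 0, num / np.maximum(den, 1), E)
    out = np.where(valid > 0, out, E)
    return (out + out.T) / 2.0


def _target_probabilities(target: ContactMap) -> np.ndarray:
    """Scale the target map to contact-probability units by matching the
    first off-diagonal (bonded neighbours are in near-certain contact)."""
    try:
        mat = target.layer("balanced").copy()
    except ValueError:
        mat = target.counts.copy()
    mat = np.where(np.isfinite(mat), mat, 0.0)
    d1 = np.diagonal(mat, offset=1)
    scale = d1[d1 > 0].mean() if (d1 > 0).any() else mat.max()
    if scale > 0:
        mat = mat / scale
    return np.clip(mat, 0.0, 1.0)


def infer_energies(
    target: ContactMap,
    seq: BeadTypeSequence,
    config: SimulationConfig,
    alpha: float = 0.5,
    max_rounds: int = 30,
    r_stop: float = 0.9,
    step_cap: float = 0.5,
    energy_bound: float = 5.0,
    confinement: ConfinementSpec | None = None,
    patience: int = 5,
    E0: np.ndarray | None = None,
    average_last: int = 8,
    smooth: int = 1,
    z_stop: float = 1.5,
) -> tuple[EnergyMatrix, InferenceReport]:
    """Fit per-pair energies so the simulated map reproduces the target.

    Update rule per round: E_ij <- E_ij + alpha * ln((p_sim+d)/(p_exp+d)),
    each step capped at +-``step_cap`` kT; the probability floor ``d`` is
    half the smallest nonzero target probability.  Stops when the Spearman
    correlation between simulated and target maps (pairs |i-j| >= 2)
    reaches ``r_stop``, and aborts with diagnostics when the best
    correlation has not improved for ``patience`` rounds.

    Near the fixed point the per-pair energies fluctuate around their
    stationary values with the sampling noise of each round's contact
    frequencies; the returned matrix is therefore the average over the
    last ``average_last`` visited rounds, which suppresses that noise
    without biasing the stationary point.
    """
    n = seq.n_beads
    if target.n_bins != n:
        raise ValueError("chain length must equal the number of target bins")
    labels = np.array(list("".join(seq.chains)))
    p_exp = _target_probabilities(target)
    nz = p_exp[p_exp > 0]
    # floor: half the smallest observed probability, but never below the
    # sampling resolution of one round (keeps chance-count log-ratios tame)
    n_round = max(
        1, (config.n_sweeps - config.equilibration_sweeps - 1) // config.sample_interval + 1
    )
    delta = max(0.5 * nz.min() if nz.size else 1e-4, 8.0 / n_round)
    iu = np.triu_indices(n, k=2)
    if confinement is None:
        confinement = ConfinementSpec.auto(n, packing=0.1, aspect=2.0)

    E = np.zeros((n, n)) if E0 is None else np.array(E0, dtype=float)
    zero_table = TypeEnergyTable(0, 0, 0, 0, 0, 0, 0)
    best_E, best_r = E.copy(), -np.inf
    history: list[np.ndarray] = []
    correlations: list[float] = []
    converged = aborted = False
    rounds = 0
    since_best = 0
    for rounds in range(1, max_rounds + 1):
        cfg_round = SimulationConfig(
            seed=config.seed + rounds,
            bond_length=config.bond_length,
            bond_k=config.bond_k,
            excluded_volume=config.excluded_volume,
            attraction_range=config.attraction_range,
            n_sweeps=config.n_sweeps,
            equilibration_sweeps=config.equilibration_sweeps,
            sample_interval=config.sample_interval,
            max_displacement=config.max_displacement,
        )
        ens = run_mc(seq, zero_table, confinement, cfg_round, pair_energies=E)
        sim = ensemble_contact_map(
            ens, contact_radius=config.attraction_range, min_samples=10,
            resolution=seq.bead_size,
        )
        p_sim = sim.counts
        history.append(E.copy())
        r = float(spearmanr(p_sim[iu], p_exp[iu]).statistic)
        correlations.append(r)
        # noise-consistency check: z-score of the per-pair probability
        # difference under binomial sampling noise (target assumed sampled
        # at the same depth).  Once the maps agree within noise, further
        # iterations would only absorb that noise into the energies.
        n_s = max(ens.n_samples, 1)
        p_bar = (p_sim + p_exp) / 2.0
        sd = np.sqrt(np.maximum(p_bar * (1 - p_bar), 1e-12) * 2.0 / n_s)
        informative = p_bar[iu] > 8.0 / n_s
        z = np.abs(p_sim[iu] - p_exp[iu])[informative] / sd[iu][informative]
        within_noise = informative.any() and float(np.median(z)) <= z_stop
        if r > best_r:
            best_r, best_E = r, E.copy()
            since_best = 0
        else:
            since_best += 1
        if r >= r_stop or within_noise:
            converged = True
            break
        if since_best >= patience:
            aborted = True
            break
        step = alpha * np.log((p_sim + delta) / (p_exp + delta))
        np.clip(step, -step_cap, step_cap, out=step)
        # pairs whose contact probability is below sampling resolution on
        # both sides carry no information; their energies shrink toward
        # zero (the prior) instead of ratcheting on chance observations
        support = 8.0 / max(ens.n_samples, 1)
        no_info = (p_sim <= support) & (p_exp <= support)
        step[no_info] = -0.5 * E[no_info]
        # bonded neighbours and diagonal stay out of the fit
        for k in (-1, 0, 1):
            idx = np.arange(max(0, -k), n - max(0, k))
            step[idx, idx + k] = 0.0
        E = np.clip(E + step, -energy_bound, energy_bound)
        E = (E + E.T) / 2.0

    k = max(1, min(average_last, len(history)))
    E_final = np.mean(history[-k:], axis=0) if history else best_E
    if smooth:
        E_final = _smooth_energy(E_final, smooth)
    em = EnergyMatrix(E=E_final, class_labels=labels, bead_size=seq.bead_size)
    report = InferenceReport(
        iterations=rounds,
        final_correlation=best_r,
        correlations=correlations,
        converged=converged,
        aborted=aborted,
        class_means=em.class_means(centred=False),
        class_means_centred=em.class_means(centred=True),
    )
    return em, report


def compare_energy_sets(a: EnergyMatrix, b: EnergyMatrix) -> dict[str, tuple[float, float, int]]:
    """Per-class mean +- s.e.m. of the element-wise energy difference a - b.

    Both matrices must share the region bead classes; differences are
    pooled over non-bonded pairs per unordered class pair.
    """
    if a.n_beads != b.n_beads or not (a.class_labels == b.class_labels).all():
        raise ValueError("energy matrices have mismatched labels")
    diff = a.E - b.E
    mask = a.pair_mask()
    classes = a.class_of_pair()
    out = {}
    for cp in _CLASS_PAIRS:
        sel = mask & (classes == cp)
        vals = diff[sel]
        n = int(sel.sum())
        sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        out[cp] = (float(vals.mean()) if n else float("nan"), sem, n)
    return out
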