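"""Block-copolymer chromatin model: Metropolis Monte Carlo in a cylindrical nucleus.

Chromosomes are chains of typed beads — A and B for the active and
inactive compartments, C for pericentromeric/telomeric heterochromatin —
confined in a cylinder whose apical cap attracts C beads (the Rabl
configuration: centromeres on top, arms reaching down).  Pair potentials
are a soft-core repulsion below one bead diameter plus a square-well
attraction out to ``attraction_range``; bonds are harmonic with hard
extension limits.  Energies are in units of kT.

The mutant transform multiplies the C-C attraction and the C-surface
attraction by a factor, mimicking heterochromatin-protein loss without
touching arm (A/B) interactions.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from numba import njit

from chromarch.maps import ContactMap

TYPE_CODE = {"A": 0, "B": 1, "C": 2}


@dataclass(frozen=True)
class BeadTypeSequence:
    """Per-chromosome bead-type strings over the alphabet {A, B, C}."""

    chains: tuple[str, ...]
    bead_size: int = 10_000

    def __post_init__(self) -> None:
        if not self.chains or any(len(c) == 0 for c in self.chains):
            raise ValueError("chains must be non-empty")
        bad = set("".join(self.chains)) - set("ABC")
        if bad:
            raise ValueError(f"unknown bead types {bad}")

    @property
    def n_beads(self) -> int:
        return sum(len(c) for c in self.chains)

    def type_codes(self) -> np.ndarray:
        return np.array([TYPE_CODE[t] for c in self.chains for t in c], dtype=np.int8)

    def chain_starts(self) -> np.ndarray:
        starts = np.cumsum([0] + [len(c) for c in self.chains])
        return starts.astype(np.int64)

    def chain_index(self) -> np.ndarray:
        return np.concatenate(
            [np.full(len(c), k, dtype=np.int64) for k, c in enumerate(self.chains)]
        )


@dataclass(frozen=True)
class TypeEnergyTable:
    """Square-well attraction depths (kT, >= 0) per unordered type pair,
    plus the C-bead attraction to the apical nuclear surface.

    Defaults are the calibrated wild-type set for the desk-scale
    whole-genome template (see :func:`calibrate_energies`): B-B attraction
    strong enough to compartmentalise arms, C-C and C-surface strong
    enough that the apical chromocenter is retained over the simulated
    window even with halved centromere/telomere blocks.
    """

    AA: float = 0.1
    BB: float = 0.5
    CC: float = 1.5
    AB: float = 0.05
    AC: float = 0.05
    BC: float = 0.05
    surf_C: float = 3.0

    def __post_init__(self) -> None:
        for k in ("AA", "BB", "CC", "AB", "AC", "BC", "surf_C"):
            if getattr(self, k) < 0:
                raise ValueError(f"attraction depth {k} must be >= 0 (depth convention)")

    def matrix(self) -> np.ndarray:
        m = np.zeros((3, 3))
        m[0, 0] = self.AA
        m[1, 1] = self.BB
        m[2, 2] = self.CC
        m[0, 1] = m[1, 0] = self.AB
        m[0, 2] = m[2, 0] = self.AC
        m[1, 2] = m[2, 1] = self.BC
        return m

    def scaled(self, factor: float, pairs: Sequence[str] | None = None) -> "TypeEnergyTable":
        """Return a copy with the given pair depths multiplied by ``factor``
        (all six pair entries when ``pairs`` is None; surf_C untouched)."""
        keys = list(pairs) if pairs is not None else ["AA", "BB", "CC", "AB", "AC", "BC"]
        return replace(self, **{k: getattr(self, k) * factor for k in keys})


def mutant_transform(energies: TypeEnergyTable, c_factor: float) -> TypeEnergyTable:
    """Heterochromatin-loss transform: scale C-C and C-surface attractions.

    ``c_factor`` in [0, 1]; all other pair energies are unchanged.
    """
    if not 0 <= c_factor <= 1:
        raise ValueError("c_factor must be in [0, 1]")
    return replace(energies, CC=energies.CC * c_factor, surf_C=energies.surf_C * c_factor)


@dataclass(frozen=True)
class ConfinementSpec:
    """Cylindrical nucleus: radius and height in bead diameters (sigma).

    The apical cap is the top disc (z = height); C beads within one sigma
    of it gain the surface attraction.  ``radius = inf`` disables
    confinement (used for free-chain reference checks).
    """

    radius: float
    height: float

    @staticmethod
    def auto(n_beads: int, packing: float = 0.1, aspect: float = 3.0) -> "ConfinementSpec":
        """Size the cylinder to a packing fraction, with height = aspect * radius."""
        r = (n_beads / (6.0 * packing * aspect)) ** (1.0 / 3.0)
        return ConfinementSpec(radius=r, height=aspect * r)

    @property
    def unbounded(self) -> bool:
        return not np.isfinite(self.radius)


FREE_SPACE = ConfinementSpec(radius=np.inf, height=np.inf)


@dataclass(frozen=True)
class SimulationConfig:
    """Monte-Carlo run parameters; kT = 1 throughout.

    ``excluded_volume`` is the soft-core repulsion cap in kT at full
    overlap; ``attraction_range`` the square-well outer radius in sigma.
    """

    seed: int
    bond_length: float = 1.0
    bond_k: float = 50.0
    excluded_volume: float = 4.0
    attraction_range: float = 1.5
    n_sweeps: int = 2000
    equilibration_sweeps: int = 500
    sample_interval: int = 10
    max_displacement: float = 0.35

    def __post_init__(self) -> None:
        for k in ("bond_length", "bond_k", "attraction_range", "n_sweeps",
                  "equilibration_sweeps", "sample_interval", "max_displacement"):
            if getattr(self, k) <= 0:
                raise ValueError(f"{k} must be positive")

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class Ensemble:
    """Sampled conformations from one MC run.

    ``configurations`` has shape (n_samples, n_beads, 3) in sigma units.
    Provenance records the config hash and seed for reproducibility.
    """

    configurations: np.ndarray
    types: np.ndarray
    chain_index: np.ndarray
    acceptance_rate: float
    provenance: dict

    @property
    def n_samples(self) -> int:
        return self.configurations.shape[0]

    @property
    def n_beads(self) -> int:
        return self.configurations.shape[1]


# ---------------------------------------------------------------------------
# Templates and initial conformations


def build_genome_template(
    n_chromosomes: int = 4,
    arm_beads: int = 130,
    centromere_beads: int = 10,
    telomere_beads: int = 5,
    arm_pattern: str | None = None,
    block_beads: int = 10,
    bead_size: int = 10_000,
) -> BeadTypeSequence:
    """Whole-genome chain template: telomere-arm-centromere-arm-telomere.

    Arms carry an A/B pattern, either supplied explicitly (``arm_pattern``,
    length <= arm_beads, tiled/truncated to fit) or alternating A/B blocks
    of ``block_beads`` beads.  Telomere and centromere blocks are C-type.
    """
    if min(n_chromosomes, arm_beads, centromere_beads, telomere_beads) < 1:
        raise ValueError("all template counts must be >= 1")
    if arm_pattern is not None:
        if len(arm_pattern) > arm_beads:
            raise ValueError("arm pattern longer than arm_beads")
        reps = -(-arm_beads // len(arm_pattern))
        arm = (arm_pattern * reps)[:arm_beads]
    else:
        blocks = []
        t = "A"
        while len("".join(blocks)) < arm_beads:
            blocks.append(t * block_beads)
            t = "B" if t == "A" else "A"
        arm = "".join(blocks)[:arm_beads]
    tel = "C" * telomere_beads
    cen = "C" * centromere_beads
    chain = tel + arm + cen + arm + tel
    return BeadTypeSequence(chains=(chain,) * n_chromosomes, bead_size=bead_size)


def template_from_labels(labels: Sequence[str], bead_size: int = 40_000) -> BeadTypeSequence:
    """Single-chain region template from per-bead A/B labels (e.g. a
    compartment track restricted to a multi-megabase window)."""
    return BeadTypeSequence(chains=("".join(labels),), bead_size=bead_size)


def _centromere_centres(seq: BeadTypeSequence) -> list[int]:
    """Index (within each chain) of the centromere-block centre: the middle
    of the longest internal C run, or the chain middle for pure-arm chains."""
    out = []
    for chain in seq.chains:
        best, best_len = len(chain) // 2, 0
        i = 0
        while i < len(chain):
            if chain[i] == "C":
                j = i
                while j < len(chain) and chain[j] == "C":
                    j += 1
                if 0 < i and j < len(chain) and j - i > best_len:  # internal run only
                    best, best_len = (i + j) // 2, j - i
                i = j
            else:
                i += 1
        out.append(best)
    return out


def rabl_initial_positions(
    seq: BeadTypeSequence,
    confinement: ConfinementSpec,
    bond_length: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Rabl-like start: centromeres near the apical cap, arms serpentining
    toward the base.  Steps are kept within the hard bond limits."""
    n = seq.n_beads
    pos = np.zeros((n, 3))
    starts = seq.chain_starts()
    centres = _centromere_centres(seq)
    n_chains = len(seq.chains)
    if confinement.unbounded:
        top, bottom, anchor_r = 0.0, -1e9, 0.0
    else:
        top, bottom = confinement.height - 0.5, 0.5
        # chains start as a tight apical bundle: centromeres within
        # attraction range of each other (post-mitotic chromocenter);
        # arms spread radially during equilibration
        anchor_r = min(1.5, 0.3 * confinement.radius)
    span = max(top - bottom, 1.0)
    step = 0.9 * bond_length
    for k in range(n_chains):
        ang = 2 * np.pi * k / max(n_chains, 1)
        xc, yc = anchor_r * np.cos(ang), anchor_r * np.sin(ang)
        s0, s1 = starts[k], starts[k + 1]
        cen = s0 + centres[k]
        for i in range(s0, s1):
            d = abs(i - cen)
            path = d * step
            n_bounce, rem = divmod(path, span)
            n_bounce = int(n_bounce)
            z = top - rem if n_bounce % 2 == 0 else bottom + rem
            side = -0.6 if i < cen else 0.6
            x = xc + side + 0.8 * (n_bounce % 2)
            y = yc + 0.1 * n_bounce
            pos[i] = (x, y, z if not confinement.unbounded else -path)
    if confinement.unbounded:
        # free chains: self-avoiding growth walk so the start is near the
        # excluded-volume coil state rather than a rod
        rng = np.random.default_rng(seed)
        for k in range(n_chains):
            s0, s1 = starts[k], starts[k + 1]
            pos[s0] = (20.0 * k, 0.0, 0.0)
            for i in range(s0 + 1, s1):
                best, best_pen = None, np.inf
                for _ in range(24):
                    v = rng.normal(size=3)
                    v *= bond_length / np.linalg.norm(v)
                    cand = pos[i - 1] + v
                    d2 = ((pos[s0:i] - cand) ** 2).sum(1)
                    pen = np.maximum(0.0, 1.0 - d2).sum()
                    if pen < best_pen:
                        best, best_pen = cand, pen
                    if pen == 0.0:
                        break
                pos[i] = best
    return pos


# ---------------------------------------------------------------------------
# The Metropolis kernel


@njit(cache=True)
def _mc_kernel(
    pos,
    types,
    chain_starts,
    eps,  # 3x3 signed well energies (negative = attractive)
    pair_energy,  # n x n signed well energies, used when use_pair_matrix
    use_pair_matrix,
    surf_eps,  # per-bead apical-surface well depth (>= 0)
    radius,
    height,
    bounded,
    bond_length,
    bond_k,
    e_rep,
    att_range,
    n_sweeps,
    equil_sweeps,
    sample_interval,
    max_disp,
    seed,
    samples,
):
    np.random.seed(seed)
    n = pos.shape[0]
    att2 = att_range * att_range
    lo = 0.7 * bond_length
    hi = 1.3 * bond_length
    lo2, hi2 = lo * lo, hi * hi
    delta = max_disp
    accepted = 0
    attempted = 0
    n_chains = chain_starts.shape[0] - 1
    # bonded neighbour lookup
    bond_prev = np.full(n, -1, np.int64)
    bond_next = np.full(n, -1, np.int64)
    for c in range(n_chains):
        for i in range(chain_starts[c], chain_starts[c + 1] - 1):
            bond_next[i] = i + 1
            bond_prev[i + 1] = i
    sample_count = 0
    tune_acc = 0
    tune_att = 0
    for sweep in range(n_sweeps):
        for _ in range(n):
            i = np.random.randint(0, n)
            ox, oy, oz = pos[i, 0], pos[i, 1], pos[i, 2]
            nx = ox + delta * (2.0 * np.random.random() - 1.0)
            ny = oy + delta * (2.0 * np.random.random() - 1.0)
            nz = oz + delta * (2.0 * np.random.random() - 1.0)
            attempted += 1
            tune_att += 1
            if bounded:
                if nz < 0.0 or nz > height or nx * nx + ny * ny > radius * radius:
                    continue
            # hard bond limits
            ok = True
            for b in (bond_prev[i], bond_next[i]):
                if b >= 0:
                    dx = nx - pos[b, 0]
                    dy = ny - pos[b, 1]
                    dz = nz - pos[b, 2]
                    r2 = dx * dx + dy * dy + dz * dz
                    if r2 < lo2 or r2 > hi2:
                        ok = False
                        break
            if not ok:
                continue
            dE = 0.0
            # bond terms
            for b in (bond_prev[i], bond_next[i]):
                if b >= 0:
                    dx = ox - pos[b, 0]
                    dy = oy - pos[b, 1]
                    dz = oz - pos[b, 2]
                    r_old = np.sqrt(dx * dx + dy * dy + dz * dz)
                    dx = nx - pos[b, 0]
                    dy = ny - pos[b, 1]
                    dz = nz - pos[b, 2]
                    r_new = np.sqrt(dx * dx + dy * dy + dz * dz)
                    dE += 0.5 * bond_k * (
                        (r_new - bond_length) ** 2 - (r_old - bond_length) ** 2
                    )
            # pair terms
            ti = types[i]
            for j in range(n):
                if j == i or j == bond_prev[i] or j == bond_next[i]:
                    continue
                dx = ox - pos[j, 0]
                dy = oy - pos[j, 1]
                dz = oz - pos[j, 2]
                r2o = dx * dx + dy * dy + dz * dz
                dx = nx - pos[j, 0]
                dy = ny - pos[j, 1]
                dz = nz - pos[j, 2]
                r2n = dx * dx + dy * dy + dz * dz
                if r2o > att2 and r2n > att2:
                    continue
                if use_pair_matrix:
                    well = pair_energy[i, j]
                else:
                    well = eps[ti, types[j]]
                uo = 0.0
                if r2o < 1.0:
                    uo = e_rep * (1.0 - r2o)
                elif r2o < att2:
                    uo = well
                un = 0.0
                if r2n < 1.0:
                    un = e_rep * (1.0 - r2n)
                elif r2n < att2:
                    un = well
                dE += un - uo
            # apical surface
            if bounded and surf_eps[i] > 0.0:
                if oz > height - 1.0:
                    dE += surf_eps[i]
                if nz > height - 1.0:
                    dE -= surf_eps[i]
            if dE <= 0.0 or np.random.random() < np.exp(-dE):
                pos[i, 0] = nx
                pos[i, 1] = ny
                pos[i, 2] = nz
                accepted += 1
                tune_acc += 1
        # displacement auto-tuning during equilibration
        if sweep < equil_sweeps and (sweep + 1) % 50 == 0 and tune_att > 0:
            rate = tune_acc / tune_att
            if rate < 0.3:
                delta *= 0.8
            elif rate > 0.6:
                delta = min(delta * 1.2, 1.0)
            tune_acc = 0
            tune_att = 0
        if sweep >= equil_sweeps and (sweep - equil_sweeps) % sample_interval == 0:
            if sample_count < samples.shape[0]:
                samples[sample_count] = pos
                sample_count += 1
    return accepted / max(attempted, 1), sample_count


def run_mc(
    seq: BeadTypeSequence,
    energies: TypeEnergyTable,
    confinement: ConfinementSpec | None = None,
    config: SimulationConfig | None = None,
    pair_energies: np.ndarray | None = None,
    initial: np.ndarray | None = None,
) -> Ensemble:
    """Run single-bead Metropolis MC and return a sampled ensemble.

    With ``pair_energies`` (an n x n signed matrix, negative = attractive)
    the per-type energy table is bypassed for the well depths — this is
    the mode the inverse-inference module uses.  Identical (seed, config,
    inputs) give bit-identical ensembles.
    """
    if config is None:
        config = SimulationConfig(seed=0)
    if confinement is None:
        confinement = ConfinementSpec.auto(seq.n_beads)
    types = seq.type_codes()
    n = seq.n_beads
    pos = (
        initial.copy()
        if initial is not None
        else rabl_initial_positions(seq, confinement, config.bond_length, seed=config.seed)
    )
    eps = -energies.matrix()  # depth -> signed well energy
    surf = np.where(types == TYPE_CODE["C"], energies.surf_C, 0.0).astype(np.float64)
    use_pair = pair_energies is not None
    pe = (
        np.ascontiguousarray(pair_energies, dtype=np.float64)
        if use_pair
        else np.zeros((1, 1))
    )
    n_samples = max(
        0, (config.n_sweeps - config.equilibration_sweeps - 1) // config.sample_interval + 1
    )
    samples = np.zeros((n_samples, n, 3))
    rate, got = _mc_kernel(
        pos,
        types,
        seq.chain_starts(),
        eps,
        pe,
        use_pair,
        surf,
        float(confinement.radius) if not confinement.unbounded else 0.0,
        float(confinement.height) if not confinement.unbounded else 0.0,
        not confinement.unbounded,
        config.bond_length,
        config.bond_k,
        config.excluded_volume,
        config.attraction_range,
        config.n_sweeps,
        config.equilibration_sweeps,
        config.sample_interval,
        config.max_displacement,
        int(config.seed) % (2**31),
        samples,
    )
    import warnings

    if not 0.2 <= rate <= 0.8:
        warnings.warn(f"MC acceptance rate {rate:.2f} outside [0.2, 0.8] after tuning")
    return Ensemble(
        configurations=samples[:got],
        types=types,
        chain_index=seq.chain_index(),
        acceptance_rate=rate,
        provenance={
            "config_hash": config.digest(),
            "seed": config.seed,
            "energies": energies.__dict__,
            "n_beads": n,
        },
    )


# ---------------------------------------------------------------------------
# Ensemble observables


def ensemble_contact_map(
    ensemble: Ensemble,
    contact_radius: float = 2.0,
    min_samples: int = 50,
    resolution: int = 40_000,
) -> ContactMap:
    """Contact-frequency map: fraction of sampled conformations in which a
    bead pair is closer than ``contact_radius``.  Diagonal is one."""
    if ensemble.n_samples < min_samples:
        raise ValueError(
            f"need >= {min_samples} samples, have {ensemble.n_samples}"
        )
    n = ensemble.n_beads
    freq = np.zeros((n, n))
    r2 = contact_radius**2
    for conf in ensemble.configurations:
        d2 = ((conf[:, None, :] - conf[None, :, :]) ** 2).sum(-1)
        freq += d2 < r2
    freq /= ensemble.n_samples
    np.fill_diagonal(freq, 1.0)
    return ContactMap(resolution=resolution, counts=freq, balanced=freq)


def ensemble_distance_map(ensemble: Ensemble) -> np.ndarray:
    """Mean pairwise Euclidean distance matrix over the ensemble."""
    n = ensemble.n_beads
    out = np.zeros((n, n))
    for conf in ensemble.configurations:
        out += np.sqrt(((conf[:, None, :] - conf[None, :, :]) ** 2).sum(-1))
    return out / max(ensemble.n_samples, 1)


def save_ensemble(ensemble: Ensemble, path) -> None:
    """Store an ensemble in an HDF5 container with its provenance."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("configurations", data=ensemble.configurations, compression="gzip")
        fh.create_dataset("types", data=ensemble.types)
        fh.create_dataset("chain_index", data=ensemble.chain_index)
        fh.attrs["acceptance_rate"] = ensemble.acceptance_rate
        fh.attrs["provenance"] = json.dumps(ensemble.provenance, default=str)


def load_ensemble(path) -> Ensemble:
    import h5py

    with h5py.File(path, "r") as fh:
        return Ensemble(
            configurations=fh["configurations"][...],
            types=fh["types"][...],
            chain_index=fh["chain_index"][...],
            acceptance_rate=float(fh.attrs["acceptance_rate"]),
            provenance=json.loads(fh.attrs["provenance"]),
        )


def merge_ensembles(ensembles: Sequence[Ensemble]) -> Ensemble:
    """Pool samples from independent replicas of the same system."""
    first = ensembles[0]
    for e in ensembles[1:]:
        if e.n_beads != first.n_beads or not np.array_equal(e.types, first.types):
            raise ValueError("ensembles are not replicas of the same system")
    return Ensemble(
        configurations=np.concatenate([e.configurations for e in ensembles]),
        types=first.types,
        chain_index=first.chain_index,
        acceptance_rate=float(np.mean([e.acceptance_rate for e in ensembles])),
        provenance={"merged": [e.provenance for e in ensembles]},
    )


def internal_distance_scaling(
    ensemble: Ensemble, min_sep: int = 2, max_sep: int | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Mean-squared internal distance <R^2(s)> versus chain separation and
    the fitted Flory exponent nu (from <R^2> ~ s^(2 nu))."""
    starts = np.flatnonzero(np.diff(ensemble.chain_index, prepend=-1))
    ends = np.append(starts[1:], ensemble.n_beads)
    max_len = int((ends - starts).max())
    if max_sep is None:
        max_sep = max_len - 1
    seps = np.arange(min_sep, max_sep + 1)
    r2 = np.zeros(len(seps))
    for si, s in enumerate(seps):
        acc, cnt = 0.0, 0
        for c0, c1 in zip(starts, ends):
            if c1 - c0 <= s:
                continue
            d = (
                ensemble.configurations[:, c0 + s : c1, :]
                - ensemble.configurations[:, c0 : c1 - s, :]
            )
            acc += (d**2).sum(-1).mean(0).sum()
            cnt += c1 - c0 - s
        r2[si] = acc / max(cnt, 1)
    good = r2 > 0
    slope = np.polyfit(np.log(seps[good]), np.log(r2[good]), 1)[0]
    return seps, r2, float(slope / 2.0)


def rabl_statistics(ensemble: Ensemble, contact_radius: float = 2.0) -> dict:
    """Summary statistics of nuclear organisation for a genome ensemble.

    Returns mean inter-chromosomal C-C distance (pericentromere/telomere
    clustering), mean inter-chromosomal arm-arm distance (arm alignment),
    the C-to-arm contact frequency, and the intra-arm compartment strength
    computed from the simulated contact map against the known bead types.
    """
    from chromarch.compartments import CompartmentTrack, saddle

    types = ensemble.types
    chain = ensemble.chain_index
    n = ensemble.n_beads
    is_c = types == TYPE_CODE["C"]
    is_arm = ~is_c
    inter = chain[:, None] != chain[None, :]

    # centromeric C = internal C runs (telomeric C beads sit at chain ends
    # inside the arm mass and dilute clustering statistics)
    is_cen = np.zeros(n, bool)
    starts_all = np.flatnonzero(np.diff(chain, prepend=-1))
    ends_all = np.append(starts_all[1:], n)
    for s0, s1 in zip(starts_all, ends_all):
        i = s0
        while i < s1:
            if is_c[i]:
                j = i
                while j < s1 and is_c[j]:
                    j += 1
                if i > s0 and j < s1:
                    is_cen[i:j] = True
                i = j
            else:
                i += 1

    # one fused pass: mean distances, contact frequencies and the
    # distal contact-class tallies share the same pair-distance evaluation
    r2 = contact_radius**2
    idx = np.arange(n)
    distal = (np.abs(idx[:, None] - idx[None, :]) > 20) | inter
    ca_pairs = distal & is_c[:, None] & is_arm[None, :]
    cen_arm_pairs = distal & is_cen[:, None] & is_arm[None, :]
    dmap = np.zeros((n, n))
    freq = np.zeros((n, n))
    ca_contacts = cen_arm_contacts = all_contacts = 0.0
    for conf in ensemble.configurations:
        d2 = ((conf[:, None, :] - conf[None, :, :]) ** 2).sum(-1)
        dmap += np.sqrt(d2)
        close = d2 < r2
        freq += close
        ca_contacts += (close & ca_pairs).sum()
        cen_arm_contacts += (close & cen_arm_pairs).sum()
        all_contacts += (close & distal).sum()
    n_samp = max(ensemble.n_samples, 1)
    dmap /= n_samp
    freq /= n_samp
    np.fill_diagonal(freq, 1.0)

    cc = inter & is_c[:, None] & is_c[None, :]
    aa = inter & is_arm[:, None] & is_arm[None, :]
    cen_cen = inter & is_cen[:, None] & is_cen[None, :]
    out = {
        "inter_cc_distance": float(dmap[cc].mean()) if cc.any() else float("nan"),
        "inter_cen_distance": float(dmap[cen_cen].mean()) if cen_cen.any() else float("nan"),
        "inter_arm_distance": float(dmap[aa].mean()) if aa.any() else float("nan"),
    }

    # arm alignment: distance between beads at the same chain coordinate in
    # different chromosomes.  In the Rabl state arms run in parallel from
    # the apical centromere cluster, so matched coordinates sit at similar
    # heights; losing the configuration scrambles them.  This is the
    # alignment-sensitive component of the inter-arm distance.
    starts = np.flatnonzero(np.diff(chain, prepend=-1))
    lengths = np.diff(np.append(starts, ensemble.n_beads))
    if len(starts) > 1 and len(set(lengths)) == 1:
        L = int(lengths[0])
        arm_local = np.flatnonzero(is_arm[:L])
        vals = []
        for a in range(len(starts)):
            for b in range(a + 1, len(starts)):
                ia = starts[a] + arm_local
                ib = starts[b] + arm_local
                vals.append(dmap[ia, ib].mean())
        out["arm_alignment_distance"] = float(np.mean(vals))
    else:
        out["arm_alignment_distance"] = float("nan")

    # C-to-arm mixing as the share of C-arm contacts among all distal
    # contacts — the observable of a depth-normalised contact map, where
    # lost heterochromatin-heterochromatin contacts re-weight the
    # remaining classes.  Chain-local pairs (separation <= 20 beads) are
    # topology-dominated and excluded.
    out["c_arm_contact_share"] = float(ca_contacts / max(all_contacts, 1))
    out["cen_arm_contact_share"] = float(cen_arm_contacts / max(all_contacts, 1))

    # intra-arm compartmentalisation: all arms share the A/B pattern, so
    # their contact submatrices are averaged before the saddle (one clean
    # estimate instead of several noisy per-arm ones)
    cmap_full = ContactMap(resolution=10_000, counts=freq, balanced=freq)
    arm_maps, arm_types = [], None
    for k in np.unique(chain):
        sel = np.flatnonzero((chain == k) & is_arm)
        brk = np.flatnonzero(np.diff(sel) > 1)
        for arm in np.split(sel, brk + 1):
            if len(arm) < 30:
                continue
            if arm_types is None:
                arm_types = types[arm]
            if len(arm) == len(arm_types) and np.array_equal(types[arm], arm_types):
                arm_maps.append(cmap_full.counts[np.ix_(arm, arm)])
    if arm_maps:
        sub = np.mean(arm_maps, axis=0)
        sub_map = ContactMap(resolution=10_000, counts=sub, balanced=sub)
        scores = np.where(arm_types == TYPE_CODE["A"], 1.0, -1.0)
        track = CompartmentTrack(10_000, scores, sub_map.bins)
        nq = min(10, len(arm_types) // 5)
        rep = saddle(sub_map, track, n_quantiles=nq, min_separation=20_000).strength()
        out["intra_arm_strength"] = float(rep.strength_overall)
    else:
        out["intra_arm_strength"] = float("nan")
    return out


def calibrate_energies(
    candidates: Sequence[TypeEnergyTable],
    seq: BeadTypeSequence,
    config: SimulationConfig,
    confinement: ConfinementSpec | None = None,
):
    """Grid-search utility: score candidate energy tables on a template.

    For each candidate, runs the simulation and reports the Rabl summary
    statistics (C-C clustering, arm alignment, intra-arm compartment
    strength).  Used to pick the shipped wild-type defaults; kept as a
    tool so the calibration is reproducible when the template changes.
    """
    import pandas as pd

    rows = []
    for en in candidates:
        ens = run_mc(seq, en, confinement, config)
        stats = rabl_statistics(ens)
        rows.append({**{k: getattr(en, k) for k in ("AA", "BB", "CC", "AB", "surf_C")}, **stats})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Phase sweep


def sweep_energies(
    seq: BeadTypeSequence,
    base: TypeEnergyTable,
    multipliers: Sequence[float],
    config: SimulationConfig,
    confinement: ConfinementSpec | None = None,
    mode: Literal["all", "BB-only"] = "all",
    contact_radius: float = 2.0,
    n_seeds: int = 1,
):
    """Scale attraction depths by each multiplier, simulate, and report the
    P(s) scaling exponent and saddle compartment strength per multiplier.

    ``mode="BB-only"`` scales only the B-B depth (the selective
    heterochromatin-weakening scenario); ``"all"`` scales every pair depth.
    Results are averaged over ``n_seeds`` independent replicas.
    """
    from chromarch.compartments import CompartmentTrack, saddle
    from chromarch.maps import decay_curve
    import pandas as pd

    if any(m <= 0 for m in multipliers):
        raise ValueError("multipliers must be positive")
    labels = np.array(list("".join(seq.chains)))
    scores = np.where(labels == "A", 1.0, -1.0)
    rows = []
    for m in multipliers:
        en = base.scaled(m, pairs=["BB"] if mode == "BB-only" else None)
        exps, s_all, s_b = [], [], []
        for k in range(n_seeds):
            cfg = replace(config, seed=config.seed + 1000 * k)
            ens = run_mc(seq, en, confinement, cfg)
            res = seq.bead_size
            cmap = ensemble_contact_map(ens, contact_radius, min_samples=10, resolution=res)
            curve = decay_curve(
                cmap,
                bins_per_decade=8,
                fit_range=(2.5 * res, seq.n_beads * res / 2),
            )
            track = CompartmentTrack(res, scores.copy(), cmap.bins)
            nq = min(20, seq.n_beads // 3)
            sad = saddle(cmap, track, n_quantiles=nq, min_separation=2 * res)
            rep = sad.strength()
            exps.append(curve.exponent)
            s_all.append(rep.strength_overall)
            s_b.append(rep.strength_B)
        rows.append(
            {
                "multiplier": m,
                "exponent": float(np.mean(exps)),
                "exponent_sem": float(np.std(exps) / np.sqrt(max(len(exps), 1))),
                "strength_overall": float(np.mean(s_all)),
                "strength_B": float(np.mean(s_b)),
            }
        )
    return pd.DataFrame(rows)
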