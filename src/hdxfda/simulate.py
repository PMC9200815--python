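"""Synthetic HDX-MS experiments with ground truth.

The generator produces centroided uptake time courses for a panel of
peptides under two conditions, mimicking how differential deuterium uptake
arises physically:

1. Each peptide gets a number of exchangeable amides drawn uniformly from
   5..25, a random amino-acid sequence of that length (for mass and carbon
   bookkeeping) and a charge state.
2. A per-peptide *incorporation schedule* D_1..D_m over the m exposure
   times is drawn by cumulatively summing a Dirichlet vector over the m-1
   post-zero time points with concentration alpha_j = 20/j, so D_1 = 0,
   D is non-decreasing and D_m = 1; earlier times receive larger
   concentration, matching fast-then-plateau exchange kinetics.
3. A condition effect is injected per post-zero time point with probability
   1 - null_prob: the second condition's incorporation increment at that
   time point is redrawn from its Dirichlet marginal and the cumulative
   schedule recomputed (clipped at 1).  A peptide is *perturbed* iff at
   least one such indicator fired; with the default null_prob = 0.95
   roughly 95% of time-point draws are null.
4. Isotope envelopes are simulated with a binomial model: heavy-carbon
   counts Binomial(n_carbons, 0.0107) convolved with deuterium counts
   Binomial(n_exchangeable, D), sampled as a finite population of ions.
   Centroids are computed by intensity-weighted mean and corrupted with
   Gaussian noise of standard deviation 0.05 Da.

Six preset designs cover 4-6 time points, 2-3 replicates, optional 5%
missingness and a sparse-effect variant (null_prob = 0.99).  Everything is
driven by a single ``numpy.random.Generator``, so a fixed seed reproduces a
dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import HDXDataset, IsotopeSpectrum, compute_centroid_mass, make_analyte_id

#: Mass added per incorporated deuterium (D - H), Da.
DELTA_MASS_D = 1.00628
#: Mass added per heavy carbon (13C - 12C), Da.
DELTA_MASS_C13 = 1.003355
#: Natural abundance of 13C.
P_C13 = 0.0107
PROTON_MASS = 1.00728
WATER_MASS = 18.010565

#: Monoisotopic residue masses (Da) and carbon counts of the 20 canonical
#: amino acids.
AMINO_ACIDS = {
    "A": (71.03711, 3), "R": (156.10111, 6), "N": (114.04293, 4),
    "D": (115.02694, 4), "C": (103.00919, 3), "E": (129.04259, 5),
    "Q": (128.05858, 5), "G": (57.02146, 2), "H": (137.05891, 6),
    "I": (113.08406, 6), "L": (113.08406, 6), "K": (128.09496, 6),
    "M": (131.04049, 5), "F": (147.06841, 9), "P": (97.05276, 5),
    "S": (87.03203, 3), "T": (101.04768, 4), "W": (186.07931, 11),
    "Y": (163.06333, 9), "V": (99.06841, 5),
}
_AA_LETTERS = sorted(AMINO_ACIDS)

#: Canonical exposure grid (seconds); a preset with m points takes the first m.
BASE_TIME_GRID = (0.0, 30.0, 240.0, 1800.0, 14400.0, 86400.0)

#: Ions sampled per simulated envelope.
N_IONS = 10000


@dataclass(frozen=True)
class Scenario:
    """A simulation design: grid size, replication, effect sparsity, noise."""

    m: int = 4
    R: int = 3
    C: int = 2
    missing_frac: float = 0.0
    null_prob: float = 0.95
    n_peptides: int = 500
    noise_sd: float = 0.05
    times: tuple[float, ...] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("need at least 2 time points")
        if self.R < 1:
            raise ValueError("need at least 1 replicate")
        if self.C != 2:
            raise ValueError("the simulation protocol is defined for 2 conditions")
        if not (0.0 <= self.missing_frac < 1.0):
            raise ValueError("missing_frac must lie in [0, 1)")
        if not (0.0 < self.null_prob <= 1.0):
            raise ValueError("null_prob must lie in (0, 1]")
        if self.times is not None and len(self.times) != self.m:
            raise ValueError("times must have length m")

    @property
    def time_grid(self) -> np.ndarray:
        if self.times is not None:
            return np.asarray(self.times, dtype=float)
        if self.m > len(BASE_TIME_GRID):
            raise ValueError("provide explicit times for m > 6")
        return np.asarray(BASE_TIME_GRID[: self.m])


def scenario_presets() -> dict[int, Scenario]:
    """The six standard simulation designs (500 peptides, 2 conditions)."""
    return {
        1: Scenario(m=4, R=3),
        2: Scenario(m=4, R=2),
        3: Scenario(m=5, R=2),
        4: Scenario(m=6, R=2),
        5: Scenario(m=6, R=2, missing_frac=0.05),
        6: Scenario(m=6, R=2, missing_frac=0.05, null_prob=0.99),
    }


def dirichlet_alpha(m: int) -> np.ndarray:
    """Concentration vector alpha_j = 20 / j over the m - 1 post-zero points."""
    if m < 2:
        raise ValueError("need at least 2 time points")
    return 20.0 / np.arange(1, m)


def sample_incorporation_schedule(m: int, rng: np.random.Generator) -> np.ndarray:
    """Draw a non-decreasing incorporation schedule D_1..D_m.

    pi ~ Dirichlet(alpha) over the m - 1 post-zero time points; D_1 = 0 and
    D_i is the cumulative sum of pi up to i - 1, so D_m = 1 exactly.
    """
    pi = rng.dirichlet(dirichlet_alpha(m))
    d = np.concatenate([[0.0], np.cumsum(pi)])
    d[-1] = 1.0
    return d


@dataclass(frozen=True)
class SimulatedPeptide:
    """Ground truth for one simulated peptide."""

    sequence: str
    start: int
    end: int
    charge: int
    n_exchangeable: int
    base_mass: float
    n_carbons: int
    schedules: dict[str, np.ndarray]
    z: np.ndarray  # condition-effect indicators over the m time points

    @property
    def analyte_id(self) -> str:
        return make_analyte_id(self.sequence, self.start, self.end, self.charge)

    @property
    def perturbed(self) -> bool:
        return bool(np.any(self.z == 1))


def _peptide_composition(sequence: str) -> tuple[float, int]:
    mass = WATER_MASS + sum(AMINO_ACIDS[aa][0] for aa in sequence)
    carbons = sum(AMINO_ACIDS[aa][1] for aa in sequence)
    return mass, carbons


def _envelope_pmf(n_carbons: int, n_exchangeable: int, d_frac: float):
    """Joint outcome masses (relative to the monoisotopic peptide) and
    probabilities of (heavy-carbon count, deuterium count)."""
    c_max = int(stats.binom.ppf(1.0 - 1e-10, n_carbons, P_C13)) + 1
    pc = stats.binom.pmf(np.arange(c_max + 1), n_carbons, P_C13)
    pd_ = stats.binom.pmf(np.arange(n_exchangeable + 1), n_exchangeable, d_frac)
    prob = np.outer(pc, pd_).ravel()
    c_idx, d_idx = np.meshgrid(
        np.arange(c_max + 1), np.arange(n_exchangeable + 1), indexing="ij"
    )
    shift = (c_idx * DELTA_MASS_C13 + d_idx * DELTA_MASS_D).ravel()
    order = np.argsort(shift, kind="stable")
    return shift[order], prob[order] / prob.sum()


def simulate_envelope(
    peptide: SimulatedPeptide,
    incorporation: float,
    rng: np.random.Generator,
    n_ions: int = N_IONS,
) -> tuple[IsotopeSpectrum, float]:
    """Sample an isotope envelope at a given incorporation level.

    A finite population of ions is drawn multinomially from the binomial
    isotope model (heavy carbons convolved with incorporated deuteriums);
    the returned centroid is the intensity-weighted neutral mass of the
    sampled envelope, so its expectation over draws shifts linearly with
    incorporation: n_exchangeable * incorporation * 1.00628 Da above the
    undeuterated centroid.
    """
    if not (0.0 <= incorporation <= 1.0):
        raise ValueError("incorporation must lie in [0, 1]")
    shift, prob = _envelope_pmf(peptide.n_carbons, peptide.n_exchangeable, incorporation)
    counts = rng.multinomial(n_ions, prob)
    masses = peptide.base_mass + shift
    z = peptide.charge
    mz = (masses + z * PROTON_MASS) / z
    spectrum = IsotopeSpectrum(mz=mz, intensity=counts.astype(float), charge=z)
    return spectrum, compute_centroid_mass(spectrum)


def _sample_peptide(m: int, rng: np.random.Generator, used: set) -> SimulatedPeptide:
    n_ex = int(rng.integers(5, 26))
    seq = "".join(rng.choice(_AA_LETTERS, size=n_ex))
    charge = int(rng.integers(1, 4))
    start = int(rng.integers(1, 400))
    while (seq, start, charge) in used:
        start = int(rng.integers(1, 400))
    used.add((seq, start, charge))
    mass, carbons = _peptide_composition(seq)
    return SimulatedPeptide(
        sequence=seq, start=start, end=start + n_ex - 1, charge=charge,
        n_exchangeable=n_ex, base_mass=mass, n_carbons=carbons,
        schedules={}, z=np.zeros(m, dtype=int),
    )


def _perturb_schedule(
    pi: np.ndarray, z_post: np.ndarray, alpha: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Condition-2 schedule: redraw flagged increments from their Dirichlet
    marginal Beta(alpha_j, sum(alpha) - alpha_j), then re-accumulate.

    The cumulative sum of the modified increments is clipped at 1; because
    increments stay non-negative the schedule remains non-decreasing without
    any repair step, and a redraw at the final time point genuinely moves
    the endpoint away from 1.
    """
    pi2 = pi.copy()
    total = alpha.sum()
    for j in np.flatnonzero(z_post):
        pi2[j] = rng.beta(alpha[j], total - alpha[j])
    d2 = np.concatenate([[0.0], np.minimum(np.cumsum(pi2), 1.0)])
    return d2


def simulate_experiment(
    scenario: Scenario, seed: int | None = None
) -> tuple[HDXDataset, pd.DataFrame]:
    """Simulate a full two-condition HDX-MS experiment with ground truth.

    Returns the dataset plus a truth table (analyte_id, perturbed, z) where
    ``perturbed`` flags peptides whose condition-2 schedule was resampled at
    one or more time points.  Deterministic for a fixed seed.
    """
    if seed is None:
        seed = scenario.seed
    rng = np.random.default_rng(seed)
    times = scenario.time_grid
    m = scenario.m
    alpha = dirichlet_alpha(m)
    conditions = ["A", "B"]

    rows: list[tuple] = []
    truth_rows: list[dict] = []
    used: set = set()
    for _ in range(scenario.n_peptides):
        pep = _sample_peptide(m, rng, used)
        pi = rng.dirichlet(alpha)
        d1 = np.concatenate([[0.0], np.cumsum(pi)])
        d1[-1] = 1.0
        z_post = (rng.random(m - 1) >= scenario.null_prob).astype(int)
        z = np.concatenate([[0], z_post])
        d2 = _perturb_schedule(pi, z_post, alpha, rng) if z_post.any() else d1
        schedules = {"A": d1, "B": d2}

        for cond in conditions:
            sched = schedules[cond]
            for i, t in enumerate(times):
                _, prob = pmf = _envelope_pmf(
                    pep.n_carbons, pep.n_exchangeable, sched[i]
                )
                shift = pmf[0]
                masses = pep.base_mass + shift
                for r in range(1, scenario.R + 1):
                    counts = rng.multinomial(N_IONS, prob)
                    centroid = float(np.dot(masses, counts)) / N_IONS
                    # Eq.-1 convention: (mean m/z) * z - z.
                    centroid = centroid + pep.charge * (PROTON_MASS - 1.0)
                    value = centroid + rng.normal(0.0, scenario.noise_sd)
                    rows.append(
                        (pep.sequence, pep.start, pep.end, pep.charge,
                         cond, str(r), float(t), value, "centroid_mass")
                    )
        truth_rows.append(
            {
                "analyte_id": pep.analyte_id,
                "perturbed": bool(z.any()),
                "z": "".join(map(str, z)),
            }
        )

    table = pd.DataFrame(
        rows,
        columns=[
            "analyte_sequence", "start", "end", "charge", "condition",
            "replicate", "exposure_s", "value", "value_kind",
        ],
    )
    if scenario.missing_frac > 0:
        drop = rng.random(len(table)) < scenario.missing_frac
        table.loc[drop, "value"] = np.nan
    truth = pd.DataFrame(truth_rows, columns=["analyte_id", "perturbed", "z"])
    return HDXDataset(table), truth
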