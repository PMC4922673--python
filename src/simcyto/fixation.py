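"""Forward simulation of whole-arm reciprocal-translocation establishment.

The model follows the Mendelian account of a reciprocal translocation
arising in male spermatogonia.  A translocation heterozygote undergoing
alternate disjunction sends both translocated chromosomes to one pole and
both typical chromosomes to the other, so balanced sperm are translocated or
typical in equal measure; random segregation of the sex chromosome
(chromosome II, unaffected by the interchange) makes half the sperm
X-bearing and half Y-bearing.  Imperfect disjunction (fidelity ``alpha`` < 1)
diverts gametes to unbalanced classes whose zygotes are inviable.  Females
produce one functional egg per meiosis, always balanced and X-bearing.

Gamete and cross arithmetic is exact (``fractions.Fraction``); the
population process layered on top is a discrete-generation two-sex
Wright-Fisher simulation with optional assortative mating by translocation
genotype and a viability advantage ``1 : 1 : 1+s`` for translocation
homozygotes.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping

import numpy as np

TYPICAL = "typical"
HETEROZYGOTE = "heterozygote"
HOMOZYGOTE = "homozygote"
GENOTYPES = (TYPICAL, HETEROZYGOTE, HOMOZYGOTE)

TRANSLOCATED = "translocated"
UNBALANCED = "unbalanced"


class SexError(ValueError):
    pass


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class IndividualGenotype:
    translocation: str            # typical | heterozygote | homozygote
    sex: str                      # "female" | "male"

    def __post_init__(self) -> None:
        if self.translocation not in GENOTYPES:
            raise ConfigError(f"unknown translocation genotype {self.translocation!r}")
        if self.sex not in ("female", "male"):
            raise ConfigError(f"unknown sex {self.sex!r}")


@dataclass(frozen=True)
class GameteDistribution:
    """Probability over (translocation complement, sex allele) classes."""

    classes: Mapping[tuple[str, str], Fraction]

    def __post_init__(self) -> None:
        if sum(self.classes.values()) != 1:
            raise ConfigError("gamete probabilities must sum to 1")

    def mass(self, complement: str | None = None, sex_allele: str | None = None) -> Fraction:
        total = Fraction(0)
        for (comp, allele), p in self.classes.items():
            if complement is not None and comp != complement:
                continue
            if sex_allele is not None and allele != sex_allele:
                continue
            total += p
        return total


def male_gametes(g: IndividualGenotype, alpha: Fraction | float = 1) -> GameteDistribution:
    """Sperm classes of a male under alternate disjunction fidelity ``alpha``.

    A heterozygote at alpha=1 yields the four balanced classes at 1/4 each;
    the (1-alpha) infidelity mass moves to unbalanced classes, split evenly
    over sex alleles.  Typical and homozygous males transmit their single
    complement with the X or Y at 1/2 each."""
    if g.sex != "male":
        raise SexError("male_gametes requires a male")
    alpha = Fraction(alpha)
    if not 0 <= alpha <= 1:
        raise ConfigError("alpha must lie in [0, 1]")
    if g.translocation == HETEROZYGOTE:
        quarter = alpha / 4
        bad = (1 - alpha) / 2
        classes = {
            (TRANSLOCATED, "X"): quarter, (TRANSLOCATED, "Y"): quarter,
            (TYPICAL, "X"): quarter, (TYPICAL, "Y"): quarter,
            (UNBALANCED, "X"): bad, (UNBALANCED, "Y"): bad,
        }
        return GameteDistribution({k: v for k, v in classes.items() if v > 0})
    comp = TRANSLOCATED if g.translocation == HOMOZYGOTE else TYPICAL
    return GameteDistribution({(comp, "X"): Fraction(1, 2), (comp, "Y"): Fraction(1, 2)})


def female_gametes(g: IndividualGenotype) -> GameteDistribution:
    """Functional-egg classes: one egg per meiosis, balanced, X-bearing."""
    if g.sex != "female":
        raise SexError("female_gametes requires a female")
    if g.translocation == HETEROZYGOTE:
        return GameteDistribution({(TRANSLOCATED, "X"): Fraction(1, 2),
                                   (TYPICAL, "X"): Fraction(1, 2)})
    comp = TRANSLOCATED if g.translocation == HOMOZYGOTE else TYPICAL
    return GameteDistribution({(comp, "X"): Fraction(1)})


@dataclass(frozen=True)
class CrossResult:
    viable: Mapping[str, Fraction]          # genotype -> probability among viable
    sex_ratio: Mapping[str, Fraction]       # among viable offspring
    unbalanced_fraction: Fraction


def cross(mother: IndividualGenotype, father: IndividualGenotype,
          alpha: Fraction | float = 1) -> CrossResult:
    """Exact offspring distribution of a cross, unbalanced zygotes removed
    and the remainder renormalised."""
    eggs = female_gametes(mother)
    sperm = male_gametes(father, alpha)
    geno: dict[str, Fraction] = {g: Fraction(0) for g in GENOTYPES}
    sex: dict[str, Fraction] = {"female": Fraction(0), "male": Fraction(0)}
    unbalanced = Fraction(0)
    for (ec, _), ep in eggs.classes.items():
        for (sc, sallele), sp in sperm.classes.items():
            p = ep * sp
            if UNBALANCED in (ec, sc):
                unbalanced += p
                continue
            n_transl = (ec == TRANSLOCATED) + (sc == TRANSLOCATED)
            geno[GENOTYPES[n_transl]] += p
            sex["male" if sallele == "Y" else "female"] += p
    viable = 1 - unbalanced
    if viable == 0:
        raise ConfigError("no viable offspring from this cross")
    return CrossResult({g: p / viable for g, p in geno.items()},
                       {s: p / viable for s, p in sex.items()},
                       unbalanced)


# ---------------------------------------------------------------------------
# population simulation


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the establishment simulation.

    N            population size (even; held constant, equal sex ratio)
    alpha        alternate-disjunction fidelity in [0, 1]
    s            viability advantage of translocation homozygotes (>= -1)
    a            assortative-mating strength in [0, 1]: probability a female's
                 mate is drawn from males of her own translocation class
    generations  maximum generations per replicate
    replicates   number of independent replicates
    seed         master seed; per-replicate streams derived deterministically
    """

    N: int = 20
    alpha: float = 1.0
    s: float = 0.0
    a: float = 0.0
    generations: int = 500
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2 or self.N % 2:
            raise ConfigError("N must be an even integer >= 2")
        if not 0 <= self.alpha <= 1:
            raise ConfigError("alpha must lie in [0, 1]")
        if not 0 <= self.a <= 1:
            raise ConfigError("a must lie in [0, 1]")
        if self.s < -1:
            raise ConfigError("s must be >= -1")
        if self.generations < 1 or self.replicates < 1:
            raise ConfigError("generations and replicates must be positive")


@dataclass
class TrajectoryResult:
    config: SimulationConfig
    fixed: np.ndarray                 # bool per replicate
    lost: np.ndarray                  # bool per replicate
    absorption_generation: np.ndarray # generation of fixation/loss (-1 if none)
    mean_weighted_freq: np.ndarray    # sex-weighted allele frequency per generation
    unbalanced_zygotes: int           # zygotes discarded across all replicates
    trajectories: list[np.ndarray] = field(default_factory=list)

    @property
    def fixation_probability(self) -> float:
        return float(self.fixed.mean())

    @property
    def mean_fixation_time(self) -> float:
        gens = self.absorption_generation[self.fixed]
        return float(gens.mean()) if gens.size else float("nan")


def _replicate_seeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n, dtype=np.uint64)]


def simulate_trajectory(cfg: SimulationConfig, record_trajectories: int = 1
                        ) -> TrajectoryResult:
    """Simulate the establishment of the translocation from a single
    heterozygous male in an otherwise typical population.

    Each generation N offspring are formed (N/2 of each sex): a mother is
    drawn uniformly among females, a father among males (biased to the
    mother's translocation class with probability ``a``), gametes are drawn,
    zygotes receiving an unbalanced paternal complement are discarded (the
    draw is repeated), and viability selection 1 : 1 : 1+s is applied by
    rejection.  The sex-weighted allele frequency (mean of the female-pool
    and male-pool frequencies) is the martingale coordinate of the neutral
    process."""
    half = cfg.N // 2
    fixed = np.zeros(cfg.replicates, dtype=bool)
    lost = np.zeros(cfg.replicates, dtype=bool)
    absorbed_at = np.full(cfg.replicates, -1, dtype=int)
    freq_sum = np.zeros(cfg.generations + 1)
    unbalanced_total = 0
    trajectories: list[np.ndarray] = []
    w_hom = 1.0 + cfg.s
    w_max = max(1.0, w_hom)
    weights = (1.0 / w_max, 1.0 / w_max, w_hom / w_max)

    for rep, seed in enumerate(_replicate_seeds(cfg.seed, cfg.replicates)):
        rng = random.Random(seed)
        # females indices 0..half-1, males half..N-1; genotype = copy count 0/1/2
        females = [0] * half
        males = [0] * half
        males[0] = 1  # the founding heterozygous male
        record = rep < record_trajectories
        traj = [] if record else None
        done_at = -1
        for gen in range(cfg.generations + 1):
            pf = sum(females) / (2 * half)
            pm = sum(males) / (2 * half)
            weighted = (pf + pm) / 2
            freq_sum[gen] += weighted
            if record:
                n_het = sum(g == 1 for g in females) + sum(g == 1 for g in males)
                n_hom = sum(g == 2 for g in females) + sum(g == 2 for g in males)
                traj.append((gen, 1 - (n_het + n_hom) / cfg.N, n_het / cfg.N,
                             n_hom / cfg.N))
            if done_at < 0:
                if weighted == 0:
                    lost[rep] = True
                    done_at = gen
                elif weighted == 1:
                    fixed[rep] = True
                    done_at = gen
            if done_at >= 0:
                # absorbed: frequency stays constant; extend the martingale record
                remaining = cfg.generations - gen
                if remaining:
                    freq_sum[gen + 1:] += weighted
                break
            if gen == cfg.generations:
                break
            new_f = []
            new_m = []
            by_class: dict[int, list[int]] = {}
            for g in males:
                by_class.setdefault(g, []).append(g)
            for i in range(cfg.N):
                attempts = 0
                while True:
                    attempts += 1
                    if attempts > 100000:
                        raise ConfigError(
                            "no viable offspring obtainable; check alpha/s settings")
                    mother = females[rng.randrange(half)]
                    # carrier females seek karyotype-matched males; the
                    # typical majority mates at random
                    if (mother != 0 and cfg.a > 0 and rng.random() < cfg.a
                            and by_class.get(mother)):
                        father = by_class[mother][0]  # class members are identical
                    else:
                        father = males[rng.randrange(half)]
                    # maternal gamete: always balanced, X-bearing
                    mg = 1 if mother == 2 else (rng.getrandbits(1) if mother == 1 else 0)
                    # paternal gamete: heterozygotes risk unbalanced classes
                    if father == 1:
                        if cfg.alpha < 1 and rng.random() >= cfg.alpha:
                            unbalanced_total += 1
                            continue  # inviable zygote; redraw parents
                        fg = rng.getrandbits(1)
                    else:
                        fg = 1 if father == 2 else 0
                    child = mg + fg
                    if cfg.s != 0 and rng.random() >= weights[child]:
                        continue  # viability rejection
                    break
                if i < half:
                    new_f.append(child)
                else:
                    new_m.append(child)
            females, males = new_f, new_m
        absorbed_at[rep] = done_at
        if record:
            trajectories.append(np.array(traj))

    return TrajectoryResult(cfg, fixed, lost, absorbed_at,
                            freq_sum / cfg.replicates, unbalanced_total,
                            trajectories)
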