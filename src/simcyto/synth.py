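"""Synthetic per-larva genotype tables with the structure of real surveys.

The generator emulates the data-generating structure of a polytene survey:
per-rearrangement genotypes drawn under Hardy-Weinberg proportions at a
target allele frequency, absolute linkage between nested inversion pairs
(one genotype draw shared), Y-linked inversion series assigned to males as
nested hemizygous configurations (X0Y1 carries the first inversion of the
chain, X0Y2 the first two, ...), and X/Y-exclusive pairs that make every
male a double heterozygote.  Constraints are enforced exactly for every
seed; only the unconstrained genotype draws are stochastic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np

from .popgen import LarvaRecord


class SpecError(ValueError):
    pass


@dataclass(frozen=True)
class PopulationSpec:
    """Recipe for one synthetic population.

    ``frequencies`` are target allele (rearranged-constituent) frequencies
    for autosomal rearrangements.  ``linked_pairs`` lists absolutely linked
    pairs sharing one genotype draw (the first name's frequency governs).
    ``y_series`` is an ordered chain of Y-linked inversion names with
    ``male_config_probs`` giving per-male probabilities of the configurations
    X0Y0, X0Y1, ... (X0Yk carries the first k chain members hemizygously);
    ``female_x_carrier_prob`` lets the first chain member occur rarely on a
    differentiated X in females.  ``xy_exclusive`` pairs (x_name, y_name)
    fix x_name homozygously in females and make males double heterozygotes
    (x_name on the X, y_name on the Y)."""

    species: str
    site: int
    n_females: int
    n_males: int
    frequencies: Mapping[str, float] = field(default_factory=dict)
    linked_pairs: tuple[tuple[str, str], ...] = ()
    y_series: tuple[str, ...] = ()
    male_config_probs: Mapping[str, float] = field(default_factory=dict)
    female_x_carrier_prob: float = 0.0
    xy_exclusive: tuple[tuple[str, str], ...] = ()
    hw_sampling: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_females < 0 or self.n_males < 0:
            raise SpecError("negative sample size")
        for name, f in self.frequencies.items():
            if not 0 <= f <= 1:
                raise SpecError(f"target frequency for {name} outside [0, 1]")
        for a, b in self.linked_pairs:
            if a == b:
                raise SpecError("linked pair must name two rearrangements")
        chain = set(self.y_series)
        if chain & set(self.frequencies):
            raise SpecError("Y-series members cannot also carry autosomal targets")
        if self.male_config_probs:
            if abs(sum(self.male_config_probs.values()) - 1) > 1e-9:
                raise SpecError("male configuration probabilities must sum to 1")
            for cfg in self.male_config_probs:
                k = _config_rank(cfg)
                if k > len(self.y_series):
                    raise SpecError(f"configuration {cfg} exceeds the Y-series length")
        for x_name, y_name in self.xy_exclusive:
            if x_name == y_name:
                raise SpecError("X/Y exclusive pair must name two rearrangements")


def _config_rank(cfg: str) -> int:
    # "X0Y3" -> 3
    return int(cfg.split("Y")[1])


def _draw_genotype(rng: np.random.Generator, p: float) -> int:
    a = rng.random() < p
    b = rng.random() < p
    return int(a) + int(b)


def generate_population(spec: PopulationSpec,
                        rng: np.random.Generator | None = None) -> list[LarvaRecord]:
    """Draw one population of larva records satisfying the spec exactly.

    With ``hw_sampling`` each autosomal genotype is two Bernoulli allele
    draws at the target frequency (Hardy-Weinberg proportions); without it
    genotype counts are allocated deterministically at the expected values,
    yielding a population whose realised frequency matches the target as
    closely as integer counts allow."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    n = spec.n_females + spec.n_males
    records: list[dict] = [
        {"sex": "female" if i < spec.n_females else "male",
         "genotypes": {}, "config": None}
        for i in range(n)
    ]

    linked_to = {}
    for a, b in spec.linked_pairs:
        linked_to[b] = a

    for name, p in spec.frequencies.items():
        if name in linked_to:
            continue  # filled from its partner below
        if spec.hw_sampling:
            draws = [_draw_genotype(rng, p) for _ in range(n)]
        else:
            total = round(2 * n * p)
            ii = min(n, total // 2)
            si = total - 2 * ii
            draws = [2] * ii + [1] * si + [0] * (n - ii - si)
        for rec, g in zip(records, draws):
            rec["genotypes"][name] = g
    for b, a in linked_to.items():
        if a not in spec.frequencies:
            raise SpecError(f"linked pair ({a}, {b}): {a} has no target frequency")
        for rec in records:
            rec["genotypes"][b] = rec["genotypes"][a]

    # Y-linked series: nested hemizygous male configurations
    if spec.y_series:
        configs = list(spec.male_config_probs) or ["X0Y0"]
        probs = [spec.male_config_probs.get(c, 1.0) for c in configs]
        for rec in records:
            for name in spec.y_series:
                rec["genotypes"][name] = 0
            if rec["sex"] == "male":
                cfg = configs[int(rng.choice(len(configs), p=probs))]
                rec["config"] = cfg
                for name in spec.y_series[:_config_rank(cfg)]:
                    rec["genotypes"][name] = 1
            else:
                if spec.y_series and rng.random() < spec.female_x_carrier_prob:
                    rec["config"] = "X0X1"
                    rec["genotypes"][spec.y_series[0]] = 1
                else:
                    rec["config"] = "X0X0"

    # X/Y exclusive pairs: females homozygous for the X marker, males double het
    for x_name, y_name in spec.xy_exclusive:
        for rec in records:
            if rec["sex"] == "female":
                rec["genotypes"][x_name] = 2
                rec["genotypes"][y_name] = 0
                rec["config"] = "X1X1"
            else:
                rec["genotypes"][x_name] = 1
                rec["genotypes"][y_name] = 1
                rec["config"] = "X1Y1"

    out = []
    for i, rec in enumerate(records):
        cfg = rec["config"]
        if cfg is None:
            cfg = "X0Y0" if rec["sex"] == "male" else "X0X0"
        out.append(LarvaRecord(
            larva_id=f"{spec.species}-s{spec.site}-{i + 1:03d}",
            site=spec.site, species=spec.species, sex=rec["sex"],
            genotypes=rec["genotypes"], sex_config=cfg))
    return out


def realized_frequencies(records: Sequence[LarvaRecord]) -> dict[str, Fraction]:
    """Realised rearranged-constituent frequency per rearrangement."""
    names: dict[str, list[int]] = {}
    for rec in records:
        for name, g in rec.genotypes.items():
            if g is not None:
                names.setdefault(name, []).append(g)
    return {name: Fraction(sum(v), 2 * len(v)) for name, v in names.items()}


def inject_hybrids(records: Sequence[LarvaRecord], k: int,
                   diagnostics_a: Mapping[str, float] | Sequence[str],
                   diagnostics_b: Mapping[str, float] | Sequence[str],
                   site: int | None = None) -> list[LarvaRecord]:
    """Append ``k`` synthetic F1 records heterozygous at every diagnostic of
    both parental sets, flagged ``synthetic_f1`` for truth tracking."""
    if k < 0:
        raise SpecError("k must be >= 0")
    out = list(records)
    names_a, names_b = list(diagnostics_a), list(diagnostics_b)
    template = set()
    for rec in records:
        template.update(rec.genotypes)
    site = site if site is not None else (records[0].site if records else 1)
    for i in range(k):
        genotypes = {name: 0 for name in template}
        for name in names_a + names_b:
            genotypes[name] = 1
        out.append(LarvaRecord(
            larva_id=f"F1-{i + 1:02d}", site=site, species="unassigned",
            sex="male" if i % 2 else "female", genotypes=genotypes,
            sex_config="X0Y0" if i % 2 else "X0X0",
            flags=frozenset({"synthetic_f1"})))
    return out
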