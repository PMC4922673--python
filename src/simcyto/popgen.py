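"""Population analysis of chromosomal rearrangements from per-larva genotypes.

The unit of observation is one Feulgen-stained larva: its collection site,
sex, per-rearrangement copy count (0/1/2 rearranged homologues, i.e. the
ss/si/ii genotype of an inversion), and its sex-chromosome configuration as
read from the polytene homologues (X0Y0 for microscopically undifferentiated
sex chromosomes, X0Y1... for a Y demarked by linked inversions, and so on).

From tables of such records the module computes the frequency of rearranged
constituents per species and site, Pearson chi-square tests of
Hardy-Weinberg proportions for common polymorphisms, sex-linkage
classification, sex-chromosome censuses, the sympatric hybrid screen, and
the shared-rearrangement accounting between taxa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from scipy.stats import chi2


class PopgenError(ValueError):
    pass


class UndefinedFrequencyError(PopgenError):
    """Frequency requested for an empty group: undefined, not zero."""


class DegenerateTestError(PopgenError):
    """Hardy-Weinberg test on a monomorphic sample."""


@dataclass(frozen=True)
class LarvaRecord:
    """One larva: site, sex, genotypes and sex-chromosome configuration."""

    larva_id: str
    site: int
    species: str
    sex: str                                  # "female" | "male"
    genotypes: Mapping[str, int | None]       # rearrangement -> copies 0/1/2, None = no data
    sex_config: str = "X0Y0"
    flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise PopgenError(f"{self.larva_id}: sex must be female or male")
        for name, g in self.genotypes.items():
            if g is not None and g not in (0, 1, 2):
                raise PopgenError(f"{self.larva_id}: copy count {g!r} for {name}")
        if self.sex == "female" and "Y" in self.sex_config.replace("?", ""):
            raise PopgenError(f"{self.larva_id}: female with Y configuration {self.sex_config}")

    def copies(self, name: str) -> int | None:
        return self.genotypes.get(name)


# ---------------------------------------------------------------------------
# presentation dialect of the frequency survey


def round_fraction(x: Fraction, digits: int = 2) -> Fraction:
    """Round-half-to-even at ``digits`` decimals, exactly (no float)."""
    scale = 10 ** digits
    return Fraction(round(x * scale), scale)


def format_frequency(x: Fraction) -> str:
    """Two-decimal rendering with ``<0.01`` for positive values below 0.01;
    ``1.00`` is reserved for true fixation (every larva carrying two copies)."""
    if x == 0:
        return ""
    if x < Fraction(1, 100):
        return "<0.01"
    r = round_fraction(x, 2)
    if r == 1 and x != 1:
        return "0.99"
    return f"{float(r):.2f}"


# ---------------------------------------------------------------------------
# frequencies


def rearranged_frequency(records: Sequence[LarvaRecord], name: str,
                         group_by: tuple[str, ...] = ("species", "site"),
                         ) -> dict[tuple, Fraction]:
    """Frequency of rearranged constituents per group: sum of copy counts over
    twice the number of larvae with data for ``name``."""
    groups: dict[tuple, list[int]] = {}
    for rec in records:
        key = tuple(getattr(rec, f) for f in group_by)
        g = rec.copies(name)
        groups.setdefault(key, [])
        if g is not None:
            groups[key].append(g)
    out = {}
    for key, counts in groups.items():
        if not counts:
            raise UndefinedFrequencyError(f"no data for {name} in group {key}")
        out[key] = Fraction(sum(counts), 2 * len(counts))
    return out


@dataclass
class FrequencyTable:
    """Rearrangement x (species, site) table of rearranged-constituent
    frequencies, with sex-linked entries reported categorically."""

    names: list[str]
    groups: list[tuple[str, int]]
    cells: dict[tuple[str, tuple[str, int]], Fraction] = field(default_factory=dict)
    marks: dict[tuple[str, tuple[str, int]], str] = field(default_factory=dict)
    group_sizes: dict[tuple[str, int], tuple[int, int]] = field(default_factory=dict)

    def cell_text(self, name: str, group: tuple[str, int]) -> str:
        key = (name, group)
        if key in self.marks:
            return self.marks[key]
        return format_frequency(self.cells.get(key, Fraction(0)))

    def species_frequency(self, name: str, species: str) -> Fraction:
        """Pool a rearrangement's frequency across a species' sites, weighting
        by constituent counts (larvae with data)."""
        num = den = 0
        for g in self.groups:
            if g[0] != species or (name, g) in self.marks:
                continue
            f = self.cells.get((name, g))
            if f is None:
                continue
            nf, nm = self.group_sizes[g]
            n2 = 2 * (nf + nm)
            num += f * n2
            den += n2
        if den == 0:
            raise UndefinedFrequencyError(f"no numeric data for {name} in {species}")
        return Fraction(num, den)

    def to_frame(self):
        """Rendered table as a pandas DataFrame (rearrangements x groups)."""
        import pandas as pd
        data = {f"{sp} site {site}": [self.cell_text(n, (sp, site))
                                      for n in self.names]
                for sp, site in self.groups}
        return pd.DataFrame(data, index=self.names)

    def present(self, name: str, species: str) -> bool:
        """Nonzero numeric frequency or a sex-linked mark in any site."""
        for g in self.groups:
            if g[0] != species:
                continue
            if (name, g) in self.marks:
                return True
            if self.cells.get((name, g), Fraction(0)) > 0:
                return True
        return False


LINKED_CALLS = ("X_linked", "Y_linked", "Y_linked_with_X_occurrence")
MARK_TEXT = {"X_linked": "X", "Y_linked": "Y", "Y_linked_with_X_occurrence": "Y/X"}


def frequency_table(records: Sequence[LarvaRecord],
                    names: Sequence[str] | None = None) -> FrequencyTable:
    """Build the full frequency table, routing sex-linked rearrangements to
    categorical marks (linkage is classified per species, pooled over sites)."""
    if names is None:
        seen: dict[str, None] = {}
        for rec in records:
            for n in rec.genotypes:
                seen.setdefault(n)
        names = list(seen)
    groups: list[tuple[str, int]] = []
    for rec in records:
        g = (rec.species, rec.site)
        if g not in groups:
            groups.append(g)
    table = FrequencyTable(list(names), groups)
    for g in groups:
        members = [r for r in records if (r.species, r.site) == g]
        table.group_sizes[g] = (sum(r.sex == "female" for r in members),
                                sum(r.sex == "male" for r in members))
    species_list = list(dict.fromkeys(g[0] for g in groups))
    linkage = {}
    for sp in species_list:
        sp_records = [r for r in records if r.species == sp]
        for name in names:
            call = classify_linkage(sp_records, name)
            if call.call in LINKED_CALLS:
                linkage[(name, sp)] = call
    for name in names:
        freqs = rearranged_frequency(records, name)
        for g in groups:
            f = freqs.get(g, Fraction(0))
            call = linkage.get((name, g[0]))
            if call is not None:
                if f > 0:
                    table.marks[(name, g)] = MARK_TEXT[call.call]
            else:
                table.cells[(name, g)] = f
    return table


# ---------------------------------------------------------------------------
# Hardy-Weinberg


@dataclass(frozen=True)
class HWTestResult:
    observed: tuple[int, int, int]     # (ss, si, ii)
    allele_freq: Fraction              # rearranged-allele frequency
    expected: tuple[float, float, float]
    chi_square: float
    df: int
    p_value: float
    reject: bool                       # at alpha = 0.05


def hw_test(ss: int, si: int, ii: int, alpha: float = 0.05) -> HWTestResult:
    """Pearson chi-square of observed genotype counts against Hardy-Weinberg
    proportions at the observed allele frequency; df = 1, no continuity
    correction."""
    n = ss + si + ii
    if n <= 0:
        raise PopgenError("empty sample")
    p = Fraction(si + 2 * ii, 2 * n)
    if p in (0, 1):
        raise DegenerateTestError("monomorphic sample: Hardy-Weinberg test undefined")
    q = 1 - p
    exp = (float(q * q * n), float(2 * p * q * n), float(p * p * n))
    stat = sum((o - e) ** 2 / e for o, e in zip((ss, si, ii), exp))
    pval = float(chi2.sf(stat, 1))
    return HWTestResult((ss, si, ii), p, exp, stat, 1, pval, pval < alpha)


def genotype_counts(records: Iterable[LarvaRecord], name: str) -> tuple[int, int, int]:
    """(ss, si, ii) counts over larvae with data for ``name``."""
    tally = [0, 0, 0]
    for rec in records:
        g = rec.copies(name)
        if g is not None:
            tally[g] += 1
    return tuple(tally)


# ---------------------------------------------------------------------------
# sex linkage

import re

_DIFF_Y = re.compile(r"Y[1-9]")
_DIFF_X = re.compile(r"X[1-9]")


@dataclass(frozen=True)
class LinkageCall:
    rearrangement: str
    call: str
    evidence: Mapping[str, Mapping[int, int]]   # sex -> copy count -> larvae


def classify_linkage(records: Sequence[LarvaRecord], name: str) -> LinkageCall:
    """Classify a rearrangement as fixed, autosomal-polymorphic or sex linked.

    Y linkage requires that every carrier be a male bearing a differentiated-Y
    configuration (the inversion is read on the Y homologue); an X-linked call
    requires homozygous carriage in every female and hemizygous carriage in
    every male.  Male-biased Y-type carriage accompanied by rare females whose
    configuration shows a differentiated X is called Y-linked with X
    occurrence (the inversion demarks both a genetic X and Y)."""
    evidence: dict[str, dict[int, int]] = {"female": {}, "male": {}}
    carriers: list[LarvaRecord] = []
    sexes = set()
    n_with_data = 0
    for rec in records:
        g = rec.copies(name)
        if g is None:
            continue
        n_with_data += 1
        sexes.add(rec.sex)
        evidence[rec.sex][g] = evidence[rec.sex].get(g, 0) + 1
        if g > 0:
            carriers.append(rec)
    ev = {s: dict(v) for s, v in evidence.items()}
    if n_with_data == 0 or len(sexes) < 2:
        return LinkageCall(name, "indeterminate", ev)
    if all(set(v) <= {2} for v in evidence.values()) and carriers:
        return LinkageCall(name, "fixed", ev)
    fem = evidence["female"]
    male = evidence["male"]
    if set(fem) == {2} and set(male) == {1}:
        return LinkageCall(name, "X_linked", ev)
    if carriers and all(r.copies(name) == 1 for r in carriers):
        male_carriers = [r for r in carriers if r.sex == "male"]
        female_carriers = [r for r in carriers if r.sex == "female"]
        if male_carriers and all(_DIFF_Y.search(r.sex_config) for r in male_carriers):
            if not female_carriers:
                return LinkageCall(name, "Y_linked", ev)
            if (all(_DIFF_X.search(r.sex_config) for r in female_carriers)
                    and len(female_carriers) < len(male_carriers)):
                return LinkageCall(name, "Y_linked_with_X_occurrence", ev)
    return LinkageCall(name, "autosomal_polymorphic", ev)


# ---------------------------------------------------------------------------
# sex-chromosome census


def sex_chromosome_census(records: Sequence[LarvaRecord], species: str
                          ) -> dict[str, dict[str, tuple[int, Fraction]]]:
    """Counts and percentages (one decimal, half-even) of sex-chromosome
    configurations, among males and among females separately.  Larvae whose
    configuration could not be attributed contribute to the denominator under
    their recorded label (e.g. ``unresolved``)."""
    members = [r for r in records if r.species == species]
    if not any(r.sex == "male" for r in members):
        raise PopgenError(f"no males recorded for {species}")
    out: dict[str, dict[str, tuple[int, Fraction]]] = {}
    for sex in ("female", "male"):
        subset = [r for r in members if r.sex == sex]
        total = len(subset)
        tally: dict[str, int] = {}
        for r in subset:
            tally[r.sex_config] = tally.get(r.sex_config, 0) + 1
        out[sex] = {cfg: (k, round_fraction(Fraction(100 * k, total), 1))
                    for cfg, k in sorted(tally.items())} if total else {}
    return out


# ---------------------------------------------------------------------------
# hybrid screen


@dataclass(frozen=True)
class HybridCandidate:
    larva_id: str
    het_a: tuple[str, ...]
    het_b: tuple[str, ...]
    completeness: Fraction      # fraction of both diagnostic sets heterozygous
    full: bool


@dataclass(frozen=True)
class HybridScreenResult:
    n_screened: int
    candidates: tuple[HybridCandidate, ...]


def hybrid_screen(records: Sequence[LarvaRecord],
                  diagnostics_a: Mapping[str, float] | Iterable[str],
                  diagnostics_b: Mapping[str, float] | Iterable[str]
                  ) -> HybridScreenResult:
    """Screen sympatric larvae for interspecific hybrids.

    Diagnostics are near-fixed rearrangements of each parental species; an F1
    would be heterozygous for diagnostics of both sets at once.  A larva is a
    candidate when heterozygous for at least one diagnostic from each set;
    completeness is the fraction of the combined diagnostics carried
    heterozygously, and a full hybrid carries them all."""
    set_a = list(diagnostics_a)
    set_b = list(diagnostics_b)
    if not set_a or not set_b:
        raise PopgenError("diagnostic sets must be non-empty")
    if set(set_a) & set(set_b):
        raise PopgenError("diagnostic sets must be disjoint")
    candidates = []
    for rec in records:
        het_a = tuple(n for n in set_a if rec.copies(n) == 1)
        het_b = tuple(n for n in set_b if rec.copies(n) == 1)
        if het_a and het_b:
            comp = Fraction(len(het_a) + len(het_b), len(set_a) + len(set_b))
            candidates.append(HybridCandidate(rec.larva_id, het_a, het_b, comp, comp == 1))
    return HybridScreenResult(len(records), tuple(candidates))


# ---------------------------------------------------------------------------
# shared-rearrangement accounting


def shared_rearrangement_accounting(table: FrequencyTable, taxa: tuple[str, str]
                                    ) -> tuple[int, int, int]:
    """(distinct, shared, shared-polymorphic) rearrangement counts for a pair
    of taxa.  Distinct counts every rearrangement with nonzero frequency or a
    sex-linked mark in either taxon; shared requires both; shared-polymorphic
    requires a frequency strictly between 0 and 1 in both."""
    t1, t2 = taxa
    for t in taxa:
        if not any(g[0] == t for g in table.groups):
            raise PopgenError(f"taxon {t!r} not in table")
    distinct = shared = shared_poly = 0
    for name in table.names:
        p1, p2 = table.present(name, t1), table.present(name, t2)
        if p1 or p2:
            distinct += 1
        if p1 and p2:
            shared += 1
            def poly(tax):
                fs = [table.cells.get((name, g)) for g in table.groups
                      if g[0] == tax and (name, g) in table.cells]
                fs = [f for f in fs if f is not None]
                if not fs:
                    return False
                pooled = table.species_frequency(name, tax)
                return 0 < pooled < 1
            if poly(t1) and poly(t2):
                shared_poly += 1
    return distinct, shared, shared_poly
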