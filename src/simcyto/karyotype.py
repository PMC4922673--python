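"""Banding sequences and chromosomal rearrangement operators.

Polytene chromosome arms are modelled as ordered sequences of band tokens.
Each token carries the section number of the subgeneric reference (standard)
map, an optional subband ordinal where a breakpoint or deletion falls inside
a section, and an orientation flag.  Band order, not strand, is what a
polytene map encodes, so comparisons are unsigned by default; the signed
model is kept so that inversion composition is an involution at full
resolution.

Rearrangements are named operators: paracentric inversions reverse a
half-open inter-token interval, whole-arm interchanges re-pair arms into new
chromosomes without touching band content, heterobands annotate a band, and
deletions remove a declared number of bands from one section.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

ARM_IDS = ("IS", "IL", "IIS", "IIL", "IIIS", "IIIL")

#: which chromosome each standard arm belongs to
ARM_CHROMOSOME = {
    "IS": "I", "IL": "I",
    "IIS": "II", "IIL": "II",
    "IIIS": "III", "IIIL": "III",
}


class KaryotypeError(ValueError):
    """Base class for rearrangement-algebra errors."""


class BreakpointError(KaryotypeError):
    """Inversion bounds out of range or not ordered."""


class InvalidKaryotypeError(KaryotypeError):
    """Arm pairing that orphans an arm or doubles a centric region."""


class RegistryError(KaryotypeError):
    """Reference to a rearrangement name absent from the registry."""


class IncomparableSequenceError(KaryotypeError):
    """Sequences whose band-token multisets differ."""


@dataclass(frozen=True)
class BandToken:
    """One band of the standard map: ``section`` 1-100, optional subband."""

    section: int
    subband: int = 0
    inverted: bool = False
    provisional: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.section <= 100:
            raise KaryotypeError(f"section {self.section} outside 1-100")

    @property
    def ident(self) -> tuple[int, int]:
        """Identity of the band irrespective of orientation."""
        return (self.section, self.subband)

    def flipped(self) -> "BandToken":
        return replace(self, inverted=not self.inverted)

    @property
    def label(self) -> str:
        base = str(self.section) if not self.subband else f"{self.section}.{self.subband}"
        return f"-{base}" if self.inverted else base

    @classmethod
    def parse(cls, text: str) -> "BandToken":
        inverted = text.startswith("-")
        body = text.lstrip("-")
        provisional = body.endswith("?")
        body = body.rstrip("?")
        if "." in body:
            sec, sub = body.split(".")
            return cls(int(sec), int(sub), inverted, provisional)
        return cls(int(body), 0, inverted, provisional)


@dataclass(frozen=True)
class ArmSequence:
    """Ordered band tokens of one chromosome arm plus landmark positions."""

    arm_id: str
    tokens: tuple[BandToken, ...]
    landmarks: Mapping[str, int] = field(default_factory=dict)
    centromere_end: str = "right"  # which end of the token list is proximal

    def __post_init__(self) -> None:
        if self.arm_id not in ARM_IDS:
            raise KaryotypeError(f"unknown arm id {self.arm_id!r}")
        if not self.tokens:
            raise KaryotypeError("arm sequence must be non-empty")
        if self.centromere_end not in ("left", "right"):
            raise KaryotypeError("centromere_end must be 'left' or 'right'")
        idents = [t.ident for t in self.tokens]
        if len(set(idents)) != len(idents):
            raise KaryotypeError(f"duplicate band tokens in {self.arm_id}")
        for name, pos in self.landmarks.items():
            if not 0 <= pos < len(self.tokens):
                raise KaryotypeError(f"landmark {name!r} position {pos} invalid")

    def __len__(self) -> int:
        return len(self.tokens)

    def idents(self) -> tuple[tuple[int, int], ...]:
        return tuple(t.ident for t in self.tokens)

    def labels(self) -> tuple[str, ...]:
        return tuple(t.label for t in self.tokens)

    def unsigned_equals(self, other: "ArmSequence") -> bool:
        """Compare band order only, ignoring orientation flags."""
        return self.idents() == other.idents()

    @classmethod
    def from_labels(cls, arm_id: str, labels: Iterable[str], *,
                    landmarks: Mapping[str, int] | None = None,
                    centromere_end: str = "right") -> "ArmSequence":
        toks = tuple(BandToken.parse(s) for s in labels)
        return cls(arm_id, toks, dict(landmarks or {}), centromere_end)


@dataclass(frozen=True)
class Chromosome:
    """Two arms joined through one centric region."""

    arms: tuple[str, str]          # arm ids, short-arm-style ordering
    centric_origin: str            # which standard chromosome donated Ce

    def __post_init__(self) -> None:
        if self.centric_origin not in ("I", "II", "III"):
            raise InvalidKaryotypeError(f"bad centric origin {self.centric_origin!r}")


@dataclass(frozen=True)
class Karyotype:
    """Haploid n=3 complement: six standard arms paired into 3 chromosomes."""

    chromosomes: tuple[Chromosome, Chromosome, Chromosome]
    arm_sequences: Mapping[str, ArmSequence] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arms = [a for c in self.chromosomes for a in c.arms]
        if sorted(arms) != sorted(ARM_IDS):
            raise InvalidKaryotypeError(
                f"arm pairing must use each standard arm exactly once, got {arms}")
        centrics = [c.centric_origin for c in self.chromosomes]
        if sorted(centrics) != ["I", "II", "III"]:
            raise InvalidKaryotypeError(f"centric regions duplicated or missing: {centrics}")

    @property
    def pairing(self) -> tuple[frozenset, ...]:
        return tuple(frozenset(c.arms) for c in self.chromosomes)

    def band_count(self) -> int:
        return sum(len(seq) for seq in self.arm_sequences.values())


@dataclass(frozen=True)
class Rearrangement:
    """A named rearrangement operator in standard coordinates.

    ``breakpoints`` are 0-based half-open inter-token positions for
    inversions; interchanges instead carry an arm re-pairing with a centric
    assignment; heterobands and deletions carry a section (and band count).
    ``status`` follows the map convention: fixed rearrangements italicised
    (``fixed_italic``), polymorphic ones roman.
    """

    name: str
    kind: str  # inversion | interchange | heteroband | deletion | unresolved_repattern
    arm_id: str = ""
    breakpoints: tuple[int, int] | None = None
    pairing: tuple[tuple[str, str], ...] | None = None
    centric_assignment: Mapping[str, str] | None = None
    section: int | None = None
    band_count: int | None = None
    status: str = "polymorphic_roman"
    coincident_with: tuple[str, ...] = ()
    mutually_exclusive_with: tuple[str, ...] = ()
    linked_with: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind == "inversion":
            if self.breakpoints is None or not self.breakpoints[0] < self.breakpoints[1]:
                raise BreakpointError(f"{self.name}: inversion breakpoints must satisfy left < right")
        elif self.kind == "interchange":
            if self.pairing is None or self.centric_assignment is None:
                raise KaryotypeError(f"{self.name}: interchange needs pairing and centric assignment")


# ---------------------------------------------------------------------------
# operators


def apply_inversion(seq: ArmSequence, left: int, right: int) -> ArmSequence:
    """Reverse tokens in ``[left, right)`` and flip their orientation flags."""
    if not (0 <= left < right <= len(seq)):
        raise BreakpointError(
            f"breakpoints ({left}, {right}) invalid for arm of length {len(seq)}")
    segment = tuple(t.flipped() for t in reversed(seq.tokens[left:right]))
    toks = seq.tokens[:left] + segment + seq.tokens[right:]
    return replace(seq, tokens=toks, landmarks={})


def apply_deletion(seq: ArmSequence, section: int, band_count: int) -> ArmSequence:
    """Remove exactly ``band_count`` bands of the named section."""
    hits = [t for t in seq.tokens if t.section == section]
    if len(hits) < band_count:
        raise BreakpointError(
            f"section {section} has {len(hits)} bands, cannot delete {band_count}")
    doomed = {t.ident for t in hits[:band_count]}
    toks = tuple(t for t in seq.tokens if t.ident not in doomed)
    return replace(seq, tokens=toks, landmarks={})


def apply_interchange(kt: Karyotype,
                      pairing: Sequence[Sequence[str]],
                      centric_assignment: Mapping[str, str] | None = None) -> Karyotype:
    """Re-pair the six arms into three chromosomes; band content untouched.

    ``centric_assignment`` maps "ARM1+ARM2" to the standard chromosome whose
    centric region travels with that new chromosome; by default each new
    chromosome keeps the centric region of its first listed arm, so that
    proximal- versus distal-break derivations of the same whole-arm
    interchange are both representable.
    """
    pairs = [tuple(p) for p in pairing]
    arms = [a for p in pairs for a in p]
    if len(pairs) != 3 or sorted(arms) != sorted(ARM_IDS):
        raise InvalidKaryotypeError(f"pairing {pairs} is not a perfect matching of the 6 arms")
    if centric_assignment is None:
        centric_assignment = {f"{a}+{b}": ARM_CHROMOSOME[a] for a, b in pairs}
    chromosomes = []
    for a, b in pairs:
        key = f"{a}+{b}"
        alt = f"{b}+{a}"
        origin = centric_assignment.get(key, centric_assignment.get(alt))
        if origin is None:
            raise InvalidKaryotypeError(f"no centric assignment for chromosome {key}")
        chromosomes.append(Chromosome((a, b), origin))
    return Karyotype(tuple(chromosomes), kt.arm_sequences)


def apply_step(state, rearr: Rearrangement):
    """Apply one registered rearrangement to an ArmSequence or Karyotype."""
    if rearr.kind == "inversion":
        if not isinstance(state, ArmSequence):
            raise KaryotypeError(f"{rearr.name}: inversion applies to an arm sequence")
        return apply_inversion(state, *rearr.breakpoints)
    if rearr.kind == "deletion":
        return apply_deletion(state, rearr.section, rearr.band_count)
    if rearr.kind == "heteroband":
        return state  # expression change only; band order untouched
    if rearr.kind == "interchange":
        if not isinstance(state, Karyotype):
            raise KaryotypeError(f"{rearr.name}: interchange applies to a karyotype")
        return apply_interchange(state, rearr.pairing, rearr.centric_assignment)
    if rearr.kind == "unresolved_repattern":
        raise KaryotypeError(f"{rearr.name}: unresolved repattern has no sequence action")
    raise KaryotypeError(f"unknown rearrangement kind {rearr.kind!r}")


# ---------------------------------------------------------------------------
# registry and derivation scenarios


class Registry:
    """Named rearrangements plus the standard arm sequences they act on."""

    def __init__(self, standard: Mapping[str, ArmSequence],
                 rearrangements: Mapping[str, Rearrangement]):
        self.standard = dict(standard)
        self.rearrangements = dict(rearrangements)

    def __contains__(self, name: str) -> bool:
        return name in self.rearrangements

    def __getitem__(self, name: str) -> Rearrangement:
        try:
            return self.rearrangements[name]
        except KeyError:
            raise RegistryError(f"rearrangement {name!r} not in registry") from None

    def names(self) -> list[str]:
        return list(self.rearrangements)

    def standard_karyotype(self) -> Karyotype:
        chromosomes = (
            Chromosome(("IS", "IL"), "I"),
            Chromosome(("IIS", "IIL"), "II"),
            Chromosome(("IIIS", "IIIL"), "III"),
        )
        return Karyotype(chromosomes, dict(self.standard))

    @classmethod
    def from_json(cls, karyotype_doc: Mapping, registry_doc: Mapping) -> "Registry":
        standard = {}
        for arm_id, spec in karyotype_doc["arms"].items():
            standard[arm_id] = ArmSequence.from_labels(
                arm_id, spec["tokens"], landmarks=spec.get("landmarks", {}),
                centromere_end=spec.get("centromere_end", "right"))
        rearrs = {}
        for entry in registry_doc["rearrangements"]:
            rearrs[entry["name"]] = Rearrangement(
                name=entry["name"],
                kind=entry["kind"],
                arm_id=entry.get("arm", ""),
                breakpoints=tuple(entry["breakpoints"]) if "breakpoints" in entry else None,
                pairing=tuple(tuple(p) for p in entry["pairing"]) if "pairing" in entry else None,
                centric_assignment=entry.get("centric_assignment"),
                section=entry.get("section"),
                band_count=entry.get("band_count"),
                status=entry.get("status", "polymorphic_roman"),
                coincident_with=tuple(entry.get("coincident_with", ())),
                mutually_exclusive_with=tuple(entry.get("mutually_exclusive_with", ())),
                linked_with=tuple(entry.get("linked_with", ())),
            )
        return cls(standard, rearrs)


def load_registry() -> Registry:
    """Load the packaged standard-sequence and rearrangement registry."""
    pkg = resources.files("simcyto.data")
    karyotype_doc = json.loads(pkg.joinpath("standard_karyotype.json").read_text())
    registry_doc = json.loads(pkg.joinpath("registry.json").read_text())
    return Registry.from_json(karyotype_doc, registry_doc)


@dataclass(frozen=True)
class Fragment:
    """A maximal run of the derived sequence that is contiguous in the start."""

    label: str
    derived_span: tuple[int, int]   # half-open slice of the derived sequence
    start_position: int             # index of the run's first band in the start
    reversed_in_derived: bool


@dataclass(frozen=True)
class DerivationScenario:
    """Named steps that should carry a start sequence onto an end sequence."""

    start_label: str
    arm_id: str
    steps: tuple[str, ...]
    end_labels: tuple[str, ...]     # expected band labels after the steps


def fragment_decomposition(derived: ArmSequence, start: ArmSequence) -> list[Fragment]:
    """Cut ``derived`` into maximal intervals contiguous (possibly reversed)
    in ``start`` and letter them so that alphabetical reordering, with
    orientation restored, reconstructs the start sequence."""
    pos = {t.ident: i for i, t in enumerate(start.tokens)}
    try:
        idx = [pos[t.ident] for t in derived.tokens]
    except KeyError as exc:
        raise IncomparableSequenceError(f"band {exc} absent from start sequence") from exc
    runs: list[tuple[int, int, bool]] = []
    i = 0
    n = len(idx)
    while i < n:
        j = i + 1
        if j < n and idx[j] == idx[i] + 1:
            while j + 1 < n and idx[j + 1] == idx[j] + 1:
                j += 1
            runs.append((i, j + 1, False))
        elif j < n and idx[j] == idx[i] - 1:
            while j + 1 < n and idx[j + 1] == idx[j] - 1:
                j += 1
            runs.append((i, j + 1, True))
        else:
            runs.append((i, i + 1, False))
        i = runs[-1][1]
    # letter fragments in order of their position along the start sequence
    def start_pos(run):
        a, b, rev = run
        return idx[b - 1] if rev else idx[a]
    ordered = sorted(runs, key=start_pos)
    letters = {}
    for k, run in enumerate(ordered):
        letters[run] = chr(ord("a") + k) if k < 26 else f"a{k}"
    return [Fragment(letters[r], (r[0], r[1]), start_pos(r), r[2])
            for r in runs]


def reorder_fragments(derived: ArmSequence, fragments: Sequence[Fragment]) -> tuple[tuple[int, int], ...]:
    """Concatenate fragments alphabetically, undoing reversals; returns idents."""
    out: list[tuple[int, int]] = []
    for frag in sorted(fragments, key=lambda f: f.label):
        a, b = frag.derived_span
        chunk = [t.ident for t in derived.tokens[a:b]]
        if frag.reversed_in_derived:
            chunk.reverse()
        out.extend(chunk)
    return tuple(out)


def verify_derivation(scenario: DerivationScenario, registry: Registry) -> tuple[bool, list[Fragment]]:
    """Check that composing the named steps onto the start reproduces the
    recorded end sequence, and return the fragment labelling of the end
    sequence relative to the start."""
    start = registry.standard[scenario.arm_id]
    state = start
    for name in scenario.steps:
        state = apply_step(state, registry[name])
    expected = tuple(BandToken.parse(s).ident for s in scenario.end_labels)
    ok = state.idents() == expected
    fragments = fragment_decomposition(state, start)
    return ok, fragments
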